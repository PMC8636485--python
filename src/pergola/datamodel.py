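"""Schema layer: label taxonomy, relationship vocabulary, blob classification.

The graph schema distinguishes three relationship categories:

* **provenance** (``GENERATED``, ``WAS_USED_BY``) — traces every data object
  back through the jobs that produced it to the biological sample of origin;
* **functional-domain** (``HAS_BIOLOGICAL_OME``, ``HAS_SEQUENCING_READS``,
  ``HAS_VARIANT_CALLS``, ``HAS_QC_DATA``) — relates data to the genome concept
  so domain subsets can be queried directly;
* **workflow-internal** (``LED_TO``, ``GENERATED_ATTEMPT``, ``AFTER``) — the
  packaged-workflow representation, kept out of provenance traversals so
  per-shard attempt nodes never clutter lineage results.

Blob classification parses sequencing metadata (sample, plate, read group,
mate pair) out of a bucket-style object path according to a configurable
grammar ``<plate>/<sample>/<datatype-dir>/<name>.<ext>``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import PurePosixPath
from typing import Any, Iterable, Mapping

import yaml

from .graphstore import GraphStore, NodeRecord

logger = logging.getLogger(__name__)

PROVENANCE = "provenance"
FUNCTIONAL = "functional-domain"
WORKFLOW_INTERNAL = "workflow-internal"
CATEGORIES = (PROVENANCE, FUNCTIONAL, WORKFLOW_INTERNAL)

#: Data types that must all exist for a genome before intermediates may be
#: purged and Fastq objects archived.
ESSENTIAL_TYPES = ("Cram", "Gvcf", "FastQC", "Flagstat", "Vcfstats")


class ModelError(Exception):
    pass


@dataclass(frozen=True)
class BlobMetadata:
    """Storage-object metadata as delivered by a bucket event."""

    bucket: str
    path: str
    size: int
    crc32c: str
    time_created: float = 0.0
    event_type: str = "created"

    def __post_init__(self) -> None:
        if not self.path:
            raise ModelError("blob path must be non-empty")
        if self.size < 0:
            raise ModelError("blob size must be >= 0")


@dataclass(frozen=True)
class RelationshipDef:
    type: str
    category: str
    endpoints: tuple[tuple[str, str], ...]


@dataclass
class ModelDescription:
    """Validated node/relationship schema plus classification grammar."""

    node_types: dict[str, dict[str, list[str]]]
    relationships: dict[str, RelationshipDef]
    classification: dict[str, Any]
    uniqueness: dict[str, list[str]]

    def validate(self) -> None:
        for rdef in self.relationships.values():
            if rdef.category not in CATEGORIES:
                raise ModelError(f"{rdef.type}: unknown category {rdef.category!r}")
            for start, end in rdef.endpoints:
                for lbl in (start, end):
                    if lbl not in self.node_types:
                        raise ModelError(f"{rdef.type}: endpoint label {lbl!r} is not a defined node type")
        for label in self.uniqueness:
            if label not in self.node_types:
                raise ModelError(f"uniqueness key on undefined label {label!r}")

    def category_of(self, rtype: str) -> str:
        return self.relationships[rtype].category

    def allowed_endpoints(self, rtype: str) -> tuple[tuple[str, str], ...]:
        return self.relationships[rtype].endpoints

    def register_constraints(self, store: GraphStore) -> None:
        for label, props in self.uniqueness.items():
            store.register_unique(label, props)

    def to_dict(self) -> dict[str, Any]:
        return {
            "nodes": {k: {kk: list(vv) for kk, vv in v.items()} for k, v in self.node_types.items()},
            "relationships": {
                r.type: {"category": r.category, "endpoints": [list(e) for e in r.endpoints]}
                for r in self.relationships.values()
            },
            "classification": self.classification,
            "uniqueness": {k: list(v) for k, v in self.uniqueness.items()},
        }


def _parse_model(raw: Mapping[str, Any]) -> ModelDescription:
    nodes: dict[str, dict[str, list[str]]] = {}
    for label, spec in (raw.get("nodes") or {}).items():
        if label in nodes:
            raise ModelError(f"duplicate node type {label!r}")
        nodes[label] = {
            "required": list((spec or {}).get("required") or []),
            "optional": list((spec or {}).get("optional") or []),
        }
    rels: dict[str, RelationshipDef] = {}
    for rtype, spec in (raw.get("relationships") or {}).items():
        if rtype in rels:
            raise ModelError(f"duplicate relationship type {rtype!r}")
        rels[rtype] = RelationshipDef(
            rtype, spec.get("category", ""),
            tuple((s, e) for s, e in spec.get("endpoints") or ()),
        )
    model = ModelDescription(
        node_types=nodes,
        relationships=rels,
        classification=raw.get("classification") or {},
        uniqueness={k: list(v) for k, v in (raw.get("uniqueness") or {}).items()},
    )
    model.validate()
    return model


def load_model(model_file: str | None = None) -> ModelDescription:
    """Load a model description (YAML); with no argument, the shipped default."""
    if model_file is None:
        text = resources.files("pergola.data").joinpath("model.yaml").read_text()
    else:
        with open(model_file) as fh:
            text = fh.read()
    return _parse_model(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Blob classification
# ---------------------------------------------------------------------------


def classify_blob(meta: BlobMetadata, model: ModelDescription) -> tuple[set[str], dict[str, Any]]:
    """Map a storage object to graph labels and properties.

    Pure function of the blob metadata: the path is parsed against the model's
    classification grammar.  Unclassifiable paths degrade to a bare ``Blob``
    with a warning rather than erroring — unknown objects must still be
    trackable.
    """
    props: dict[str, Any] = {
        "bucket": meta.bucket,
        "path": meta.path,
        "size": meta.size,
        "crc32c": meta.crc32c,
        "time_created": meta.time_created,
        "event_type": meta.event_type,
    }
    labels = {"Blob"}
    parts = PurePosixPath(meta.path).parts
    if len(parts) != 4:
        logger.warning("unclassifiable blob path %r (expected plate/sample/datadir/name)", meta.path)
        return labels, props
    plate, sample, datadir, name = parts
    props["plate_id"] = plate
    props["sample_id"] = sample

    cls = model.classification
    extra_label: str | None = None
    dir_spec = (cls.get("directories") or {}).get(datadir)
    if dir_spec is None:
        logger.warning("unknown datatype directory %r in %r", datadir, meta.path)
        return labels, props
    extra_label = dir_spec.get("label")
    props.update(dir_spec.get("properties") or {})
    for suffix, sspec in (cls.get("suffixes") or {}).items():
        if name.endswith(suffix):
            extra_label = sspec.get("label")
            props.update(sspec.get("properties") or {})
            break
    if extra_label:
        labels.add(extra_label)

    if extra_label in ("Fastq", "Ubam"):
        stem = name
        for ext in (".fastq.gz", ".fastq", ".ubam.sam", ".ubam", ".sam"):
            if stem.endswith(ext):
                stem = stem[: -len(ext)]
                break
        for token in stem.split("_")[1:]:
            if token.startswith("RG") and token[2:].isdigit():
                props["read_group"] = int(token[2:])
            elif token.startswith("R") and token[1:] in ("1", "2"):
                props["mate_pair"] = int(token[1:])
    return labels, props


def validate_node(node: NodeRecord, model: ModelDescription) -> list[str]:
    """Schema check: unknown labels and missing required properties.

    Violations are returned as data (strings), never raised — integrity
    reports aggregate them across the whole graph.
    """
    violations: list[str] = []
    for label in sorted(node.labels):
        spec = model.node_types.get(label)
        if spec is None:
            violations.append(f"node {node.id}: unknown label {label!r}")
            continue
        for prop in spec["required"]:
            if prop not in node.properties:
                violations.append(f"node {node.id} ({label}): missing required property {prop!r}")
    return violations


def validate_graph(store: GraphStore, model: ModelDescription) -> list[str]:
    """Sweep every node and relationship endpoint against the model."""
    violations: list[str] = []
    for node in store.nodes():
        violations.extend(validate_node(node, model))
    for rel in store.relationships():
        rdef = model.relationships.get(rel.type)
        if rdef is None:
            violations.append(f"rel {rel.id}: unknown type {rel.type!r}")
            continue
        start = store.node(rel.start_id)
        end = store.node(rel.end_id)
        if not any(s in start.labels and e in end.labels for s, e in rdef.endpoints):
            violations.append(
                f"rel {rel.id} ({rel.type}): endpoints {sorted(start.labels)} -> "
                f"{sorted(end.labels)} not allowed")
    return violations


def write_violation_report(violations: Iterable[str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("violation\n")
        for v in violations:
            fh.write(v.replace("\t", " ") + "\n")
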