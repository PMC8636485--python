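"""Synthetic sequencing deliveries and deterministic mock pipeline tools.

The orchestration engine only ever reacts to object *metadata* — paths,
checksums, read-group structure — so the fixtures generate the smallest
artefacts that carry realistic metadata structure: paired gzipped FASTQ files
per read group (pseudo-random ACGT, fixed qualities), a JSON delivery manifest
with per-file checksums and the expected read-group count, and mock stand-ins
for the real pipeline tools (FASTQ-to-uBAM conversion, a GATK-style
align/merge/scatter-call/gather/cram workflow, FastQC-, flagstat- and
vcfstats-like QC reporters).  Every tool is a pure function of its input
files: outputs embed input checksums, so end-to-end lineage is verifiable from
file content alone, and identical arguments yield byte-identical files.
"""

from __future__ import annotations

import gzip
import json
import random
import zlib
from pathlib import Path
from typing import Callable, Iterable

from .datamodel import BlobMetadata

DEFAULT_PLATE = "PLATE01"
DEFAULT_READ_GROUPS = 4
DEFAULT_READS_PER_FILE = 100
READ_LENGTH = 80


class FixtureError(Exception):
    pass


def file_crc32(path: str | Path) -> str:
    """Checksum used throughout as the blob `crc32c` property (zlib.crc32;
    only consistency matters, not parity with the cloud algorithm)."""
    with open(path, "rb") as fh:
        return f"{zlib.crc32(fh.read()) & 0xFFFFFFFF:08x}"


def blob_metadata_for(root: str | Path, path: str | Path, event_type: str = "created") -> BlobMetadata:
    """Build storage-object metadata for a file below the watched root."""
    p = Path(path)
    rel = p.relative_to(root).as_posix()
    return BlobMetadata(bucket=str(root), path=rel, size=p.stat().st_size,
                        crc32c=file_crc32(p), time_created=p.stat().st_mtime,
                        event_type=event_type)


# ---------------------------------------------------------------------------
# Delivery generation
# ---------------------------------------------------------------------------


def generate_delivery(root: str | Path, sample_id: str,
                      n_read_groups: int = DEFAULT_READ_GROUPS,
                      reads_per_file: int = DEFAULT_READS_PER_FILE,
                      seed: int = 0, plate_id: str = DEFAULT_PLATE) -> list[Path]:
    """Write one sample's sequencing delivery under ``root``.

    Layout: ``<plate>/<sample>/fastq/<sample>_RG<k>_R<1|2>.fastq.gz`` for each
    read group, plus ``<plate>/<sample>/manifest/<sample>_manifest.json``
    carrying the expected read-group count and per-file checksums.  Fully
    deterministic: same arguments, byte-identical files (gzip mtime pinned).

    Returns the created file paths, manifest last.
    """
    if n_read_groups < 1:
        raise FixtureError("n_read_groups must be >= 1")
    if reads_per_file < 1:
        raise FixtureError("reads_per_file must be >= 1")
    root = Path(root)
    base = root / plate_id / sample_id
    rng = random.Random((seed, sample_id).__repr__())
    created: list[Path] = []
    for rg in range(n_read_groups):
        for mate in (1, 2):
            path = base / "fastq" / f"{sample_id}_RG{rg}_R{mate}.fastq.gz"
            path.parent.mkdir(parents=True, exist_ok=True)
            lines = []
            for i in range(reads_per_file):
                seq = "".join(rng.choice("ACGT") for _ in range(READ_LENGTH))
                lines.append(f"@{sample_id}:RG{rg}:{i}/{mate}\n{seq}\n+\n{'I' * READ_LENGTH}\n")
            with gzip.GzipFile(path, "wb", mtime=0) as fh:
                fh.write("".join(lines).encode())
            created.append(path)
    manifest = {
        "sample_id": sample_id,
        "plate_id": plate_id,
        "expected_read_groups": n_read_groups,
        "files": {p.relative_to(root).as_posix(): file_crc32(p) for p in created},
    }
    mpath = base / "manifest" / f"{sample_id}_manifest.json"
    mpath.parent.mkdir(parents=True, exist_ok=True)
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    created.append(mpath)
    return created


def load_manifest(root: str | Path, manifest_relpath: str) -> dict:
    with open(Path(root) / manifest_relpath) as fh:
        return json.load(fh)


def verify_manifest(root: str | Path, manifest_relpath: str) -> dict[str, bool]:
    """Recompute per-file checksums against the manifest's expectations."""
    manifest = load_manifest(root, manifest_relpath)
    return {rel: file_crc32(Path(root) / rel) == crc
            for rel, crc in manifest["files"].items()}


# ---------------------------------------------------------------------------
# Mock tools
# ---------------------------------------------------------------------------
# Each tool: (inputs, root, params) -> list of output paths (relative files
# written under root/<plate>/<sample>/...).  params always carries sample_id
# and plate_id.


def _read_fastq(path: Path) -> list[tuple[str, str]]:
    opener = gzip.open if path.suffix == ".gz" else open
    reads = []
    with opener(path, "rt") as fh:
        block = []
        for line in fh:
            block.append(line.rstrip("\n"))
            if len(block) == 4:
                reads.append((block[0][1:], block[1]))
                block = []
    return reads


def _outpath(root: Path, params: dict, datadir: str, name: str) -> Path:
    p = root / params["plate_id"] / params["sample_id"] / datadir / name
    p.parent.mkdir(parents=True, exist_ok=True)
    return p


def fastq_to_ubam(inputs: list[str], root: str | Path, params: dict) -> list[Path]:
    """Pair both mates of one read group into an unaligned SAM: one record per
    read pair, sequence taken from mate 1."""
    root = Path(root)
    r1, r2 = sorted(inputs)
    reads1 = _read_fastq(root / r1)
    reads2 = _read_fastq(root / r2)
    if len(reads1) != len(reads2):
        raise FixtureError(f"mate files disagree: {len(reads1)} vs {len(reads2)} reads")
    sample, rg = params["sample_id"], params["read_group"]
    out = _outpath(root, params, "ubam", f"{sample}_RG{rg}.ubam.sam")
    lines = ["@HD\tVN:1.6\tSO:unsorted", f"@RG\tID:RG{rg}\tSM:{sample}"]
    for (name, seq), _ in zip(reads1, reads2):
        qname = name.split("/")[0]
        lines.append(f"{qname}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{'I' * len(seq)}")
    out.write_text("\n".join(lines) + "\n")
    return [out]


def align_readgroup(inputs: list[str], root: str | Path, params: dict) -> list[Path]:
    """Mock aligner: copies uBAM records to 'mapped' records on chr1."""
    root = Path(root)
    (ubam,) = inputs
    sample = params["sample_id"]
    rg = params["read_group"]
    out = _outpath(root, params, "intermediate", f"{sample}_RG{rg}.aligned.sam")
    lines = ["@HD\tVN:1.6\tSO:coordinate", "@SQ\tSN:chr1\tLN:248956422"]
    pos = 1000
    for line in (root / ubam).read_text().splitlines():
        if line.startswith("@"):
            continue
        fields = line.split("\t")
        lines.append(f"{fields[0]}\t0\tchr1\t{pos}\t60\t{len(fields[9])}M\t*\t0\t0\t{fields[9]}\t{fields[10]}")
        pos += 100
    out.write_text("\n".join(lines) + "\n")
    return [out]


def merge_bams(inputs: list[str], root: str | Path, params: dict) -> list[Path]:
    root = Path(root)
    sample = params["sample_id"]
    out = _outpath(root, params, "aligned", f"{sample}.merged.sam")
    header = ["@HD\tVN:1.6\tSO:coordinate", "@SQ\tSN:chr1\tLN:248956422"]
    records = []
    for rel in sorted(inputs):
        for line in (root / rel).read_text().splitlines():
            if not line.startswith("@"):
                records.append(line)
    out.write_text("\n".join(header + records) + "\n")
    return [out]


def variant_call_shard(inputs: list[str], root: str | Path, params: dict) -> list[Path]:
    """One scatter shard of the mock variant caller: deterministically derives
    'variant' records from the reads assigned to this shard."""
    root = Path(root)
    (bam,) = inputs
    sample, shard, width = params["sample_id"], params["shard"], params["scatter_width"]
    out = _outpath(root, params, "intermediate", f"{sample}.shard{shard:03d}.vcf")
    records = []
    i = 0
    for line in (root / bam).read_text().splitlines():
        if line.startswith("@"):
            continue
        if i % width == shard:
            fields = line.split("\t")
            pos = int(fields[3]) + shard
            ref = fields[9][0]
            alt = "ACGT"[(ord(ref) + i) % 4]
            records.append(f"chr1\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\tSHARD={shard}")
        i += 1
    out.write_text("\n".join(records) + ("\n" if records else ""))
    return [out]


def gather_gvcf(inputs: list[str], root: str | Path, params: dict) -> list[Path]:
    root = Path(root)
    sample = params["sample_id"]
    out = _outpath(root, params, "variants", f"{sample}.g.vcf")
    header = ["##fileformat=VCFv4.2",
              f"##source=mock-variant-caller",
              f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    records = []
    for rel in sorted(inputs):
        records.extend(l for l in (root / rel).read_text().splitlines() if l)
    out.write_text("\n".join(header + records) + "\n")
    return [out]


def make_cram(inputs: list[str], root: str | Path, params: dict) -> list[Path]:
    """CRAM placeholder: records the checksum of the alignment it compresses."""
    root = Path(root)
    (bam,) = inputs
    sample = params["sample_id"]
    out = _outpath(root, params, "cram", f"{sample}.cram")
    out.write_text(f"CRAM-PLACEHOLDER\tsource={bam}\tcrc32c={file_crc32(root / bam)}\n")
    return [out]


def fastqc_like(inputs: list[str], root: str | Path, params: dict) -> list[Path]:
    root = Path(root)
    (bam,) = inputs
    sample = params["sample_id"]
    reads = [l for l in (root / bam).read_text().splitlines() if not l.startswith("@")]
    gc = sum(l.split("\t")[9].count("G") + l.split("\t")[9].count("C") for l in reads)
    total_bases = sum(len(l.split("\t")[9]) for l in reads)
    out = _outpath(root, params, "qc", f"{sample}_fastqc.txt")
    out.write_text(
        ">>Basic Statistics\n"
        f"Filename\t{Path(bam).name}\n"
        f"Total Sequences\t{len(reads)}\n"
        f"%GC\t{100.0 * gc / max(total_bases, 1):.1f}\n"
        f"Source crc32c\t{file_crc32(root / bam)}\n"
        ">>END_MODULE\n")
    return [out]


def flagstat_like(inputs: list[str], root: str | Path, params: dict) -> list[Path]:
    root = Path(root)
    (bam,) = inputs
    sample = params["sample_id"]
    reads = [l for l in (root / bam).read_text().splitlines() if not l.startswith("@")]
    mapped = sum(1 for l in reads if int(l.split("\t")[1]) & 4 == 0)
    out = _outpath(root, params, "qc", f"{sample}_flagstat.txt")
    out.write_text(
        f"{len(reads)} + 0 in total (QC-passed reads + QC-failed reads)\n"
        f"{mapped} + 0 mapped ({100.0 * mapped / max(len(reads), 1):.2f}% : N/A)\n"
        f"# source crc32c {file_crc32(root / bam)}\n")
    return [out]


def vcfstats_like(inputs: list[str], root: str | Path, params: dict) -> list[Path]:
    """Counts table over the gathered gVCF; the SNV/indel split totals the
    record count, so downstream checks can recount the input."""
    root = Path(root)
    (vcf,) = inputs
    sample = params["sample_id"]
    records = [l for l in (root / vcf).read_text().splitlines()
               if l and not l.startswith("#")]
    snvs = sum(1 for l in records
               if len(l.split("\t")[3]) == 1 and len(l.split("\t")[4]) == 1)
    out = _outpath(root, params, "qc", f"{sample}_vcfstats.txt")
    out.write_text(
        f"Passed Filters               : {len(records)}\n"
        f"SNPs                         : {snvs}\n"
        f"Insertions/Deletions         : {len(records) - snvs}\n"
        f"Source crc32c                : {file_crc32(root / vcf)}\n")
    return [out]


MockTool = Callable[[list[str], str | Path, dict], list[Path]]

#: Task-name registry used by the local executor.
TASKS: dict[str, MockTool] = {
    "fastq-to-ubam": fastq_to_ubam,
    "align-per-readgroup": align_readgroup,
    "merge": merge_bams,
    "scatter-variant-call": variant_call_shard,
    "gather-gvcf": gather_gvcf,
    "cram": make_cram,
    "fastqc": fastqc_like,
    "flagstat": flagstat_like,
    "vcfstats": vcfstats_like,
}


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

#: Named study conditions for end-to-end runs: broker delivery policy plus
#: fault-injection knobs.  "duplicate-storm" reproduces heavy at-least-once
#: duplication; "adversarial" adds reordering (the naive-mode race window);
#: "scale-smoke" is the multi-sample fault-tolerance condition.
SCENARIOS: dict[str, dict] = {
    "happy-path": {
        "delivery": {"duplicate_probability": 0.0, "max_extra_deliveries": 0,
                     "reorder_window": 0},
        "failure_probability": 0.0, "preemption_probability": 0.0,
    },
    "duplicate-storm": {
        "delivery": {"duplicate_probability": 0.5, "max_extra_deliveries": 2,
                     "reorder_window": 0},
        "failure_probability": 0.0, "preemption_probability": 0.0,
    },
    "adversarial": {
        "delivery": {"duplicate_probability": 0.5, "max_extra_deliveries": 1,
                     "reorder_window": 4},
        "failure_probability": 0.0, "preemption_probability": 0.0,
    },
    "scale-smoke": {
        "delivery": {"duplicate_probability": 0.25, "max_extra_deliveries": 1,
                     "reorder_window": 0},
        "failure_probability": 0.15, "preemption_probability": 0.2,
    },
}


def scenario(name: str) -> dict:
    try:
        return json.loads(json.dumps(SCENARIOS[name]))  # deep copy
    except KeyError:
        raise FixtureError(f"unknown scenario {name!r}") from None
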