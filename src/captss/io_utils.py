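"""Readers, writers and run configuration shared by the pipeline stages.

Coordinate conventions: 0-based half-open internally and in BED output;
GFF3 input converts from 1-based inclusive.  FASTA and FASTQ readers accept
gzip-compressed files and CRLF line endings; FASTA sequence is normalised
to uppercase.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import logging
from pathlib import Path
from typing import Iterable, Iterator

import yaml

from .promoter_calling import GeneModel

log = logging.getLogger(__name__)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-contig FASTA -> {name: uppercase sequence}. Accepts gzip."""
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        genome[name] = "".join(chunks).upper()
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from FASTQ (gzip ok, CRLF tolerated)."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()  # +
            fh.readline()  # qualities
            yield header.strip()[1:].split()[0], seq


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def read_bed6(path: str | Path) -> list[tuple[str, int, int, str, float, str]]:
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"BED6 requires 6 fields, got {len(f)}: {line!r}")
            start, end = int(f[1]), int(f[2])
            if start < 0 or end < start:
                raise ValueError(f"invalid BED interval {line!r}")
            rows.append((f[0], start, end, f[3], float(f[4]), f[5]))
    return rows


def write_bed6(rows: Iterable[tuple[str, int, int, str, float, str]], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for contig, start, end, name, score, strand in rows:
            score_s = str(int(score)) if float(score).is_integer() else f"{score:g}"
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score_s}\t{strand}\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Gene models from GFF3 (gene/mRNA features; 1-based -> 0-based) or BED6."""
    path = Path(path)
    genes: list[GeneModel] = []
    skipped = 0
    if path.suffix.replace(".gz", "") in (".bed",) or path.name.endswith((".bed", ".bed.gz")):
        for contig, start, end, name, _score, strand in read_bed6(path):
            genes.append(GeneModel(gene_id=name, contig=contig, strand=strand, start=start, end=end))
        return genes
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                skipped += 1
                continue
            if f[2] not in ("gene", "mRNA", "transcript"):
                continue
            try:
                start = int(f[3]) - 1
                end = int(f[4])
            except ValueError:
                skipped += 1
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("Name") or f"{f[0]}:{start}"
            genes.append(GeneModel(gene_id=gid, contig=f[0], strand=f[6], start=start, end=end))
    if skipped:
        log.warning("read_gene_models: %d malformed records skipped", skipped)
    return genes


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclasses.dataclass
class PipelineConfig:
    """All thresholds of the pipeline; defaults are the published values."""

    seed: int = 0
    gap: int = 100
    seed_min_ppm: float = 0.5
    promoter_min_ppm: float = 1.0
    identity: float = 0.90
    kmer: int = 12
    island_window: int = 200
    island_gc_min: float = 0.5
    island_score_min: float = 0.6
    class_poor_max: float = 0.5
    class_rich_min: float = 0.6
    promoter_upstream: int = 499
    promoter_downstream: int = 501
    meta_halfwidth: int = 2000
    genome_window: int = 1000
    meta_window: int = 100
    sl_leaders: list[tuple[str, str]] | None = None
    strict_acceptor: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with _open_text(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "sl_leaders" in data and data["sl_leaders"] is not None:
            data["sl_leaders"] = [tuple(x) for x in data["sl_leaders"]]
        return cls(**data)

    def to_manifest(self, path: str | Path, extra: dict | None = None) -> None:
        payload = dataclasses.asdict(self)
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
            fh.write("\n")
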