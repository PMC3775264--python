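"""Sequence records, FASTA/FASTQ I/O, barcode demultiplexing and initial filters.

The demultiplexer models 454-style fusion reads: a sequencing adapter, a
fixed-length multiplex barcode and a degenerate forward primer precede the
amplicon insert.  Barcode matching is exact; the primer mismatch budget uses
the IUPAC set semantics from :mod:`gtamp.primers`.  Retention filters are
length- and mismatch-based only; quality scores are carried but unused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .primers import IUPAC_MASKS, mismatch_count, reverse_complement

logger = logging.getLogger(__name__)

_PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-.")
_DNA_CHARS = set(IUPAC_MASKS) | {"-", "."}


class ParseError(ValueError):
    """Raised when a sequence file cannot be parsed."""


@dataclass
class SequenceRecord:
    """One DNA or protein sequence with optional sample tag and qualities."""

    id: str
    seq: str
    sample: str | None = None
    qual: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id}: sequence must be non-empty")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"record {self.id}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FusionLayout:
    """Layout of a 454 fusion read: adapter + barcode + degenerate primer + insert.

    The fully-empty layout (no adapter, zero-length barcode, no primer) is the
    degenerate case used to pass already-trimmed reads through unchanged.
    An optional distal (reverse) primer may be trimmed off the read tail.
    """

    adapter: str = ""
    barcode_length: int = 0
    primer: str = ""
    reverse_primer: str = ""

    def __post_init__(self) -> None:
        if self.barcode_length < 0:
            raise ValueError("barcode_length must be >= 0")

    @property
    def insert_offset(self) -> int:
        return len(self.adapter) + self.barcode_length + len(self.primer)


@dataclass
class PipelineConfig:
    """Thresholds used across the pipeline.

    Defaults follow the workflow's published settings: forward-primer mismatch
    budget 2, minimum read length 300 bases, protein reads kept when longer
    than 100 residues with >= 30% identity to the nearest reference, 5% default
    clustering cutoff swept up to 30%, mismatch tiers 0/1/2 for primer
    coverage, and closest-match identity sub-bins at 90/75/50%.
    """

    max_primer_mismatch: int = 2
    min_read_length: int = 300
    min_protein_length: int = 100
    min_identity: float = 0.30
    cluster_cutoff: float = 0.05
    sweep_max: float = 0.30
    mismatch_tiers: list[int] = field(default_factory=lambda: [0, 1, 2])
    identity_bin_edges: list[float] = field(default_factory=lambda: [0.90, 0.75, 0.50])
    rng_seed: int = 1

    def __post_init__(self) -> None:
        for name in ("min_identity", "cluster_cutoff", "sweep_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.max_primer_mismatch < 0 or self.min_read_length < 0 or self.min_protein_length < 0:
            raise ValueError("thresholds must be non-negative")
        edges = self.identity_bin_edges
        if any(not 0.0 < e < 1.0 for e in edges) or any(
            a <= b for a, b in zip(edges, edges[1:])
        ):
            raise ValueError("identity_bin_edges must be strictly decreasing fractions")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat key=value config file (lists comma-separated)."""
        kwargs: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in ("max_primer_mismatch", "min_read_length", "min_protein_length", "rng_seed"):
                kwargs[key] = int(value)
            elif key in ("min_identity", "cluster_cutoff", "sweep_max"):
                kwargs[key] = float(value)
            elif key == "mismatch_tiers":
                kwargs[key] = [int(x) for x in value.split(",") if x]
            elif key == "identity_bin_edges":
                kwargs[key] = [float(x) for x in value.split(",") if x]
            else:
                raise ParseError(f"{path}:{lineno}: unknown key {key!r}")
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"max_primer_mismatch = {self.max_primer_mismatch}",
            f"min_read_length = {self.min_read_length}",
            f"min_protein_length = {self.min_protein_length}",
            f"min_identity = {self.min_identity}",
            f"cluster_cutoff = {self.cluster_cutoff}",
            f"sweep_max = {self.sweep_max}",
            "mismatch_tiers = " + ",".join(str(t) for t in self.mismatch_tiers),
            "identity_bin_edges = " + ",".join(str(e) for e in self.identity_bin_edges),
            f"rng_seed = {self.rng_seed}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("@"):
                    return "fastq"
                raise ParseError(f"{path}: unrecognized format (first record line {line[:20]!r})")
    raise ParseError(f"{path}: empty file")


def read_sequences(path: str | Path, kind: str = "dna") -> list[SequenceRecord]:
    """Read FASTA or FASTQ into records; order preserved, qualities retained.

    ``kind`` ('dna' or 'protein') is validated against the sequence alphabet.
    Duplicate ids raise an error.
    """
    if kind not in ("dna", "protein"):
        raise ValueError("kind must be 'dna' or 'protein'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    allowed = _DNA_CHARS if kind == "dna" else _PROTEIN_CHARS
    try:
        for rec in SeqIO.parse(str(path), fmt):
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            bad = set(seq) - allowed
            if bad:
                raise ParseError(
                    f"{path}: record {rec.id!r} has characters {sorted(bad)} "
                    f"not valid for kind={kind!r}"
                )
            qual = rec.letter_annotations.get("phred_quality")
            records.append(SequenceRecord(id=rec.id, seq=seq, qual=list(qual) if qual else None))
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: malformed {fmt} record ({exc})") from exc
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str | Path, fmt: str | None = None) -> None:
    """Write records as FASTA (unwrapped) or FASTQ (Sanger qualities)."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    with open(path, "w") as fh:
        for rec in records:
            if fmt == "fasta":
                fh.write(f">{rec.id}\n{rec.seq}\n")
            elif fmt == "fastq":
                if rec.qual is None:
                    raise ValueError(f"record {rec.id} has no qualities for FASTQ output")
                quals = "".join(chr(q + 33) for q in rec.qual)
                fh.write(f"@{rec.id}\n{rec.seq}\n+\n{quals}\n")
            else:
                raise ValueError(f"unknown format {fmt!r}")


def read_barcodes(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample, barcode) -> sample->barcode map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "barcode"], dtype=str)
    return dict(zip(df["sample"], df["barcode"].str.upper()))


@dataclass
class DemuxStats:
    """Per-sample counts for each demultiplexing stage."""

    total_reads: int
    matched_barcode: dict[str, int]
    passed_filters: dict[str, int]
    unassigned: int

    @property
    def discarded_short(self) -> dict[str, int]:
        return {
            s: self.matched_barcode[s] - self.passed_filters[s]
            for s in self.matched_barcode
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "Sample name": s,
                "Match barcode": self.matched_barcode[s],
                "Passed initial processing": self.passed_filters[s],
            }
            for s in self.matched_barcode
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class DemuxResult:
    assigned: dict[str, list[SequenceRecord]]
    unassigned: list[SequenceRecord]
    stats: DemuxStats


def demultiplex(
    reads: Sequence[SequenceRecord],
    barcodes: Mapping[str, str],
    layout: FusionLayout,
    cfg: PipelineConfig | None = None,
) -> DemuxResult:
    """Assign fusion reads to samples and trim them to the insert.

    A read is assigned iff its adapter and barcode match exactly and the
    degenerate forward primer matches with at most ``cfg.max_primer_mismatch``
    set-semantics mismatches at the expected offset.  Assigned reads are
    trimmed to the insert (distal reverse-primer tail trimmed when found);
    inserts shorter than ``cfg.min_read_length`` are discarded but counted.
    Reads failing adapter/barcode/primer matching are routed to the
    unassigned bin, never dropped silently.
    """
    cfg = cfg or PipelineConfig()
    bl = layout.barcode_length
    if any(len(b) != bl for b in barcodes.values()):
        raise ValueError("all barcodes must have length == layout.barcode_length")
    if len(set(barcodes.values())) != len(barcodes):
        raise ValueError("barcodes must be distinct")
    by_barcode = {b: s for s, b in barcodes.items()}

    assigned: dict[str, list[SequenceRecord]] = {s: [] for s in barcodes}
    matched = {s: 0 for s in barcodes}
    passed = {s: 0 for s in barcodes}
    unassigned: list[SequenceRecord] = []

    a_len = len(layout.adapter)
    p_len = len(layout.primer)
    rp_rc = reverse_complement(layout.reverse_primer) if layout.reverse_primer else ""

    for read in reads:
        seq = read.seq.upper()
        if len(seq) < layout.insert_offset or not seq.startswith(layout.adapter):
            unassigned.append(read)
            continue
        barcode = seq[a_len:a_len + bl]
        sample = by_barcode.get(barcode)
        if sample is None:
            unassigned.append(read)
            continue
        if p_len:
            try:
                mm = mismatch_count(layout.primer, seq[a_len + bl:a_len + bl + p_len])
            except ValueError:
                unassigned.append(read)
                continue
            if mm > cfg.max_primer_mismatch:
                unassigned.append(read)
                continue
        matched[sample] += 1
        start, end = layout.insert_offset, len(seq)
        if rp_rc and end - start >= len(rp_rc):
            # distal primer is optional on 454 reads: trim when present
            best_mm, best_off = None, None
            insert = seq[start:end]
            for off in range(len(insert) - len(rp_rc) + 1):
                mm = mismatch_count(rp_rc, insert[off:off + len(rp_rc)])
                if best_mm is None or mm < best_mm:
                    best_mm, best_off = mm, off
            if best_mm is not None and best_mm <= cfg.max_primer_mismatch:
                end = start + best_off
        insert_seq = seq[start:end]
        if len(insert_seq) < cfg.min_read_length:
            continue  # counted via matched - passed
        passed[sample] += 1
        qual = read.qual[start:end] if read.qual is not None else None
        assigned[sample].append(replace(read, seq=insert_seq, sample=sample, qual=qual))

    stats = DemuxStats(
        total_reads=len(reads),
        matched_barcode=matched,
        passed_filters=passed,
        unassigned=len(unassigned),
    )
    return DemuxResult(assigned=assigned, unassigned=unassigned, stats=stats)
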