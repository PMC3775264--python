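"""Seeded synthetic data with the structure the pipeline assumes.

The generator emulates gene-targeted 454 amplicon studies: protein reference
families at controlled within/between divergence with codon-consistent DNA
back-translations and a taxonomy sidecar; barcoded fusion reads (adapter +
barcode + degenerate-primer variant + insert) carrying single-base
homopolymer-style indels and planted primer-site mismatch tiers; and
multi-sample community profiles with log-normal abundances and per-OTU group
effects.  Everything is deterministic under the seed.

Divergence is planted with exact mutation counts: each family ancestor gets
round(L * between/2) substitutions from a common root and each member
round(L * within/2) substitutions from its ancestor, so pairwise
dissimilarities concentrate at the planted rates and within-family diameters
are bounded — which is what makes complete-linkage recovery well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import GroupDesign
from .primers import CODONS_OF, TaxonLineage, bases_of, expand_degenerate
from .seqio import FusionLayout, SequenceRecord, write_sequences

_AA = "ACDEFGHIKLMNPQRSTVWY"
_PHYLA = ["Proteobacteria", "Actinobacteria", "Firmicutes", "Bacteroidetes"]
_CLASSES = ["Alphaproteobacteria", "Betaproteobacteria", "Gammaproteobacteria", "Bacilli"]


@dataclass
class SimSpec:
    """Parameters of one synthetic study."""

    n_families: int = 3
    within_family_divergence: float = 0.03
    between_family_divergence: float = 0.30
    n_samples: int = 6
    reads_per_sample: int = 60
    frameshift_rate: float = 1.0            # mean single-base indels per read
    primer_mismatch_design: dict[int, int] | None = None  # tier -> read count
    group_effect: dict[str, float] = field(default_factory=dict)
    seed: int = 1
    protein_length: int = 120
    members_per_family: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.within_family_divergence <= 1.0
                and 0.0 <= self.between_family_divergence <= 1.0):
            raise ValueError("divergences must be in [0, 1]")
        if self.between_family_divergence <= self.within_family_divergence:
            raise ValueError("between-family divergence must exceed within-family")
        if self.frameshift_rate < 0:
            raise ValueError("frameshift_rate must be >= 0")
        if self.n_families < 1 or self.n_samples < 1 or self.reads_per_sample < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class ReferenceSet:
    """Simulated reference families with aligned proteins and DNA."""

    proteins: list[SequenceRecord]
    dna: list[SequenceRecord]
    taxonomy: dict[str, TaxonLineage]
    alignment: list[SequenceRecord]     # master alignment (gap-free here)
    family_of: dict[str, int]

    def ids(self) -> list[str]:
        return [r.id for r in self.proteins]

    def write(self, outdir: str | Path, prefix: str = "refs") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sequences(self.proteins, outdir / f"{prefix}_protein.fasta")
        write_sequences(self.dna, outdir / f"{prefix}_dna.fasta")
        write_sequences(self.alignment, outdir / f"{prefix}_aligned.fasta")
        rows = [
            {
                "id": rid,
                "phylum": lin.phylum,
                "class": lin.klass,
                "genus": lin.genus,
                "species": lin.species,
            }
            for rid, lin in self.taxonomy.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / f"{prefix}_taxonomy.tsv", sep="\t", index=False)


def _mutate(protein: str, n_mut: int, rng: np.random.Generator) -> str:
    """Substitute exactly n_mut positions to different residues."""
    if n_mut == 0:
        return protein
    seq = list(protein)
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    for p in positions:
        choices = [aa for aa in _AA if aa != seq[p]]
        seq[p] = choices[rng.integers(len(choices))]
    return "".join(seq)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = CODONS_OF[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def make_reference_family(spec: SimSpec, rng: np.random.Generator | None = None) -> ReferenceSet:
    """Simulate protein/DNA reference families with a taxonomy sidecar.

    Families are groups of ``members_per_family`` proteins mutated from family
    ancestors at the within rate; ancestors diverge from a common root at the
    between rate.  Deterministic under ``spec.seed``.
    """
    rng = rng or np.random.default_rng(spec.seed)
    L = spec.protein_length
    n_between = round(L * spec.between_family_divergence / 2)
    n_within = round(L * spec.within_family_divergence / 2)
    if n_between > L:
        raise ValueError("impossible divergence combination: more mutations than positions")
    if n_between == 0 and spec.n_families > 1:
        raise ValueError("impossible divergence combination: "
                         "between-family divergence rounds to zero mutations")

    root = "".join(_AA[k] for k in rng.integers(len(_AA), size=L))
    proteins: list[SequenceRecord] = []
    dna: list[SequenceRecord] = []
    taxonomy: dict[str, TaxonLineage] = {}
    family_of: dict[str, int] = {}
    for f in range(spec.n_families):
        ancestor = _mutate(root, n_between, rng)
        genus = f"Genus{f + 1}"
        for m in range(spec.members_per_family):
            member = _mutate(ancestor, n_within, rng)
            rid = f"F{f + 1}R{m + 1}"
            proteins.append(SequenceRecord(id=rid, seq=member))
            dna.append(SequenceRecord(id=rid, seq=_back_translate(member, rng)))
            taxonomy[rid] = TaxonLineage(
                phylum=_PHYLA[f % len(_PHYLA)],
                klass=_CLASSES[f % len(_CLASSES)],
                genus=genus,
                species=f"{genus} sp{m + 1}",
            )
            family_of[rid] = f
    alignment = [SequenceRecord(id=r.id, seq=r.seq) for r in proteins]
    return ReferenceSet(
        proteins=proteins, dna=dna, taxonomy=taxonomy,
        alignment=alignment, family_of=family_of,
    )


def default_barcodes(n: int, length: int = 10) -> dict[str, str]:
    """Deterministic distinct barcodes for n samples."""
    rng = np.random.default_rng(20130917)
    out: dict[str, str] = {}
    seen: set[str] = set()
    i = 0
    while len(out) < n:
        bc = "".join("ACGT"[k] for k in rng.integers(4, size=length))
        if bc not in seen:
            seen.add(bc)
            out[f"S{i + 1:02d}"] = bc
            i += 1
    return out


def _primer_variant(primer: str, n_mismatch: int, rng: np.random.Generator) -> str:
    """A concrete primer-site sequence with exactly n_mismatch set-mismatches."""
    pool = expand_degenerate(primer)
    site = list(pool[rng.integers(len(pool))])
    if n_mismatch > len(site):
        raise ValueError("more mismatches than primer positions")
    positions = rng.choice(len(site), size=n_mismatch, replace=False)
    for p in positions:
        outside = sorted(set("ACGT") - bases_of(primer[p]))
        if not outside:
            raise ValueError(f"primer position {p} is N; cannot plant a mismatch")
        site[p] = outside[rng.integers(len(outside))]
    return "".join(site)


def _plant_indels(
    seq: str,
    n: int,
    rng: np.random.Generator,
    margin: int = 9,
    min_separation: int = 45,
) -> str:
    """Plant n single-base indels in the interior of a sequence.

    Placement keeps the planted truth identifiable: indels within the
    terminal codons are indistinguishable from local-alignment end-trimming
    (hence the ``margin``), and an insertion/deletion pair a few bases apart
    locally restores the frame, so a score-optimal corrector rightly reads
    through it — the planted count of such a read is undefined.  Indels are
    therefore kept at least ``min_separation`` bases apart.
    """
    lo, hi = margin, len(seq) - margin
    if hi <= lo:
        lo, hi = 1, len(seq) - 1
    positions: list[int] = []
    for _ in range(n):
        for _attempt in range(200):
            pos = int(rng.integers(lo, hi))
            if all(abs(pos - p) >= min_separation for p in positions):
                positions.append(pos)
                break
        else:  # crowded sequence: fall back to any interior position
            positions.append(int(rng.integers(lo, hi)))
    for pos in sorted(positions, reverse=True):
        if rng.random() < 0.5:
            seq = seq[:pos] + seq[pos + 1:]                       # deletion
        else:
            base = "ACGT"[rng.integers(4)]
            seq = seq[:pos] + base + seq[pos:]                    # insertion
    return seq


def make_reads(
    spec: SimSpec,
    refs: ReferenceSet,
    layout: FusionLayout,
    barcodes: Mapping[str, str],
    profiles: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulate barcoded fusion reads plus a truth table.

    Each read is adapter + sample barcode + primer variant (with the planted
    mismatch count from ``spec.primer_mismatch_design``) + an insert drawn
    from a reference, with Poisson(``frameshift_rate``) single-base indels.
    ``profiles`` (samples × reference ids) biases the insert draw; default is
    uniform.  The truth table records source reference, sample, planted indel
    count and planted primer mismatches per read.
    """
    if not refs.dna:
        raise ValueError("reference set must be non-empty")
    rng = rng or np.random.default_rng(spec.seed + 1)
    samples = list(barcodes)
    if len(samples) < spec.n_samples:
        raise ValueError("not enough barcodes for n_samples")
    samples = samples[: spec.n_samples]

    total = spec.n_samples * spec.reads_per_sample
    design = spec.primer_mismatch_design or {0: total}
    if sum(design.values()) != total:
        raise ValueError("primer_mismatch_design counts must sum to total reads")
    tier_of_read = np.array(
        [t for t, c in sorted(design.items()) for _ in range(c)], dtype=int
    )
    rng.shuffle(tier_of_read)

    ref_ids = [r.id for r in refs.dna]
    dna_of = {r.id: r.seq for r in refs.dna}

    reads: list[SequenceRecord] = []
    truth_rows = []
    k = 0
    for sample in samples:
        if profiles is not None:
            weights = profiles.loc[sample, ref_ids].to_numpy(dtype=float)
            weights = weights / weights.sum()
        else:
            weights = None
        for _ in range(spec.reads_per_sample):
            src = ref_ids[rng.choice(len(ref_ids), p=weights)]
            insert = dna_of[src]
            n_indel = int(rng.poisson(spec.frameshift_rate))
            insert = _plant_indels(insert, n_indel, rng)
            n_mm = int(tier_of_read[k])
            primer_site = (
                _primer_variant(layout.primer, n_mm, rng) if layout.primer else ""
            )
            seq = layout.adapter + barcodes[sample] + primer_site + insert
            rid = f"read{k + 1:05d}"
            reads.append(
                SequenceRecord(id=rid, seq=seq, qual=[30] * len(seq))
            )
            truth_rows.append(
                {
                    "read_id": rid,
                    "sample": sample,
                    "source_ref": src,
                    "n_indels": n_indel,
                    "primer_mismatches": n_mm,
                }
            )
            k += 1
    return reads, pd.DataFrame(truth_rows)


def make_community(
    spec: SimSpec,
    n_otus: int = 50,
    noise_sigma: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroupDesign]:
    """Per-sample OTU relative-abundance profiles with optional group effects.

    Base abundances are log-normal and shared across samples; per-sample
    multiplicative log-normal noise makes replicates exchangeable under the
    null.  OTUs named in ``spec.group_effect`` are multiplied by their effect
    in treatment samples.  Samples are split into 'control' and 'treatment'
    halves; rows sum to 1.
    """
    if spec.n_samples < 2:
        raise ValueError("need >= 2 samples")
    rng = rng or np.random.default_rng(spec.seed + 2)
    otus = [f"OTU{k + 1:03d}" for k in range(n_otus)]
    samples = [f"S{i + 1:02d}" for i in range(spec.n_samples)]
    half = spec.n_samples // 2
    groups = {
        s: ("control" if i < half else "treatment") for i, s in enumerate(samples)
    }
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_otus)
    rows = []
    for s in samples:
        abund = base * rng.lognormal(mean=0.0, sigma=noise_sigma, size=n_otus)
        if groups[s] == "treatment":
            for otu, mult in spec.group_effect.items():
                if otu in otus:
                    abund[otus.index(otu)] *= mult
        rows.append(abund / abund.sum())
    profiles = pd.DataFrame(rows, index=samples, columns=otus)
    return profiles, GroupDesign(groups)
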