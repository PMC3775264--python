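"""IUPAC degenerate primer model.

Expansion of degenerate oligos into their concrete sequence pools, set-based
mismatch counting, in-silico probe-match coverage of a reference set by
mismatch tier, and degenerate primer design by back-translation of conserved
amino-acid windows.

Matching semantics are conservative: a reference position matches a primer
position iff the base set denoted by the reference character is a subset of
the base set denoted by the primer character.  An ambiguous reference base
not fully covered by the primer therefore counts as a mismatch.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

if TYPE_CHECKING:  # pragma: no cover
    from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

# Bitmask encoding of IUPAC nucleotide codes: A=1, C=2, G=4, T=8.
IUPAC_MASKS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}
_MASK_TO_CODE = {m: c for c, m in IUPAC_MASKS.items()}
_BASES = "ACGT"

# IUPAC complement: base sets complemented element-wise.
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

# The nifH fusion construct used for 454 amplicon sequencing: the forward
# fusion read is 454 A adapter + multiplex barcode + PolF; the reverse is the
# B adapter + PolR.  These are study inputs used by examples and acceptance.
ADAPTER_454_A = "CGTATCGCCTCCCTCGCGCCATCAG"
ADAPTER_454_B = "CTATGCGCCTTGCCAGCCCGCTCAG"
POLF = "TGCGAYCCSAARGCBGACTC"
POLR = "ATSGCCATCATYTCRCCGGA"
NIFH_BARCODE_LENGTH = 10


def bases_of(code: str) -> frozenset[str]:
    """Concrete bases denoted by one IUPAC code."""
    try:
        mask = IUPAC_MASKS[code]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {code!r}") from None
    return frozenset(b for b in _BASES if IUPAC_MASKS[b] & mask)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) DNA string."""
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r}") from None


@dataclass(frozen=True)
class DegeneratePrimer:
    """A degenerate oligo written over the IUPAC nucleotide alphabet."""

    name: str
    seq: str
    direction: str = "forward"  # forward | reverse

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("primer sequence must be non-empty")
        seq = self.seq.upper()
        for pos, c in enumerate(seq):
            if c not in IUPAC_MASKS:
                raise ValueError(f"invalid IUPAC code {c!r} at position {pos}")
        object.__setattr__(self, "seq", seq)
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be 'forward' or 'reverse'")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def degeneracy(self) -> int:
        """Number of concrete sequences in the pool (product of set sizes)."""
        d = 1
        for c in self.seq:
            d *= len(bases_of(c))
        return d


@dataclass(frozen=True)
class TaxonLineage:
    """Minimal lineage used for coverage rollups."""

    phylum: str = "unclassified"
    klass: str = "unclassified"
    genus: str = "unclassified"
    species: str = "unclassified"

    def __post_init__(self) -> None:
        if self.species != "unclassified" and not self.genus:
            raise ValueError("species requires a genus (or 'unclassified')")


def expand_degenerate(primer: DegeneratePrimer | str) -> list[str]:
    """All concrete sequences covered by the primer, lexicographically sorted."""
    seq = primer.seq if isinstance(primer, DegeneratePrimer) else primer
    sets = []
    for pos, c in enumerate(seq.upper()):
        if c not in IUPAC_MASKS:
            raise ValueError(f"invalid IUPAC code {c!r} at position {pos}")
        sets.append(sorted(bases_of(c)))
    return ["".join(p) for p in itertools.product(*sets)]


def mismatch_count(primer: DegeneratePrimer | str, site: str) -> int:
    """Set-based mismatches between a primer and an equal-length site.

    A position mismatches iff the site base set is not a subset of the primer
    code set.
    """
    pseq = primer.seq if isinstance(primer, DegeneratePrimer) else primer.upper()
    site = site.upper()
    if len(pseq) != len(site):
        raise ValueError(f"length mismatch: primer {len(pseq)} vs site {len(site)}")
    n = 0
    for pc, sc in zip(pseq, site):
        if sc not in IUPAC_MASKS:
            raise ValueError(f"invalid IUPAC code {sc!r} in site")
        if IUPAC_MASKS[sc] & ~IUPAC_MASKS[pc]:
            n += 1
    return n


def _encode_masks(seq: str) -> np.ndarray:
    try:
        return np.array([IUPAC_MASKS[c] for c in seq.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r}") from None


def best_binding_site(primer: DegeneratePrimer, ref_seq: str) -> tuple[int, int]:
    """(min mismatches, leftmost offset achieving it) on the scanned strand.

    Forward primers are scanned along the sense strand; reverse primers bind
    the antisense strand, so their binding site on the sense strand reads as
    the primer's reverse complement.
    """
    query = primer.seq if primer.direction == "forward" else reverse_complement(primer.seq)
    L = len(query)
    if len(ref_seq) < L:
        raise ValueError("reference shorter than primer")
    pmask = _encode_masks(query)
    rmask = _encode_masks(ref_seq)
    n_off = len(ref_seq) - L + 1
    windows = np.lib.stride_tricks.sliding_window_view(rmask, L)[:n_off]
    mm = np.count_nonzero(windows & ~pmask, axis=1)
    off = int(np.argmin(mm))  # argmin is leftmost on ties
    return int(mm[off]), off


@dataclass
class CoverageReport:
    """Probe-match coverage of a reference set by mismatch tier.

    ``hits[t]`` is the set of reference ids whose best binding site has at
    most ``t`` mismatches; tier sets are nested by construction.
    """

    primer_name: str
    tiers: list[int]
    hits: dict[int, set[str]]
    strain_counts: dict[int, int]
    species_counts: dict[int, int]
    taxon_counts: pd.DataFrame  # columns: rank, taxon, one column per tier
    excluded: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.taxon_counts.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "primer": self.primer_name,
            "tiers": {
                str(t): {"strains": self.strain_counts[t], "species": self.species_counts[t]}
                for t in self.tiers
            },
            "excluded": list(self.excluded),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def probe_match(
    primer: DegeneratePrimer,
    refs: Sequence["SequenceRecord"],
    taxonomy: Mapping[str, TaxonLineage] | None,
    tiers: Iterable[int] = (0, 1, 2),
) -> CoverageReport:
    """In-silico probe match of a degenerate primer against DNA references.

    Each reference is scanned at every offset on the appropriate strand; it is
    counted in tier ``t`` iff its best (minimum-mismatch) site has ≤ t
    mismatches.  Per-taxon rollups are produced at phylum/class/genus.
    """
    tiers = sorted(tiers)
    if not tiers:
        raise ValueError("at least one mismatch tier required")
    taxonomy = taxonomy or {}
    best: dict[str, int] = {}
    excluded: list[str] = []
    for ref in refs:
        try:
            mm, _ = best_binding_site(primer, ref.seq)
        except ValueError:
            excluded.append(ref.id)
            logger.warning("reference %s shorter than primer %s; excluded", ref.id, primer.name)
            continue
        best[ref.id] = mm

    hits = {t: {rid for rid, mm in best.items() if mm <= t} for t in tiers}
    strain_counts = {t: len(hits[t]) for t in tiers}

    def _species(rid: str) -> str:
        lin = taxonomy.get(rid)
        return lin.species if lin else "unclassified"

    species_counts = {
        t: len({_species(r) for r in hits[t] if _species(r) != "unclassified"})
        for t in tiers
    }

    rows = []
    for rank in ("phylum", "klass", "genus"):
        taxa = sorted(
            {getattr(taxonomy.get(rid, TaxonLineage()), rank) for rid in best}
        )
        for taxon in taxa:
            members = {
                rid for rid in best
                if getattr(taxonomy.get(rid, TaxonLineage()), rank) == taxon
            }
            row = {"rank": "class" if rank == "klass" else rank, "taxon": taxon,
                   "n_refs": len(members)}
            for t in tiers:
                row[f"mm<={t}"] = len(members & hits[t])
            rows.append(row)
    taxon_counts = pd.DataFrame(rows)

    return CoverageReport(
        primer_name=primer.name,
        tiers=list(tiers),
        hits=hits,
        strain_counts=strain_counts,
        species_counts=species_counts,
        taxon_counts=taxon_counts,
        excluded=excluded,
    )


# --- degenerate primer design from conserved protein windows ---------------

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: residue -> tuple of codons under the standard genetic code
CODONS_OF: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _STANDARD_TABLE.forward_table.items():
    CODONS_OF.setdefault(_aa, ())
    CODONS_OF[_aa] += (_codon,)
CODONS_OF = {aa: tuple(sorted(cs)) for aa, cs in CODONS_OF.items()}
STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)


def minimal_iupac(codons: Iterable[str]) -> str:
    """Minimal IUPAC string covering every codon in the set (column-wise union)."""
    codons = list(codons)
    if not codons:
        raise ValueError("empty codon set")
    length = len(codons[0])
    out = []
    for i in range(length):
        mask = 0
        for c in codons:
            mask |= IUPAC_MASKS[c[i]]
        out.append(_MASK_TO_CODE[mask])
    return "".join(out)


@dataclass(frozen=True)
class PrimerCandidate:
    primer: DegeneratePrimer
    start: int              # 0-based residue coordinate in the alignment
    end: int                # half-open
    motif: str              # amino-acid window, alternations bracketed
    degeneracy: int


def design_degenerate_primers(
    ref_alignment: Sequence["SequenceRecord"],
    window: int,
    max_degeneracy: int,
    name_prefix: str = "cand",
) -> list[PrimerCandidate]:
    """Design degenerate primers from conserved windows of a protein alignment.

    For every gap-free window of ``window`` aligned residue columns, the
    observed residues per column are back-translated under the standard code
    and collapsed column-wise into the minimal covering IUPAC string.
    Candidates whose degeneracy exceeds ``max_degeneracy`` are dropped.
    """
    if window < 1:
        raise ValueError("window must be >= 1 residue")
    if not ref_alignment:
        return []
    ncol = len(ref_alignment[0].seq)
    if any(len(r.seq) != ncol for r in ref_alignment):
        raise ValueError("alignment rows must have equal length")

    columns: list[set[str]] = []
    for i in range(ncol):
        residues = {r.seq[i].upper() for r in ref_alignment}
        columns.append(residues)

    out: list[PrimerCandidate] = []
    for start in range(0, ncol - window + 1):
        win = columns[start:start + window]
        if any("-" in col or "." in col for col in win):
            continue  # gapped column invalidates the window
        if any(aa not in CODONS_OF for col in win for aa in col):
            continue  # unknown residue (X, *) cannot be back-translated
        parts = []
        motif_parts = []
        degeneracy = 1
        for col in win:
            codons = [c for aa in sorted(col) for c in CODONS_OF[aa]]
            code = minimal_iupac(codons)
            parts.append(code)
            for c in code:
                degeneracy *= len(bases_of(c))
            motif_parts.append(
                sorted(col)[0] if len(col) == 1 else "[" + "".join(sorted(col)) + "]"
            )
        if degeneracy > max_degeneracy:
            continue
        primer = DegeneratePrimer(f"{name_prefix}_{start}", "".join(parts), "forward")
        out.append(
            PrimerCandidate(
                primer=primer,
                start=start,
                end=start + window,
                motif="".join(motif_parts),
                degeneracy=degeneracy,
            )
        )
    return out


def covered_codon_strings(candidate: PrimerCandidate) -> set[str]:
    """All codon strings back-translating the candidate's source window."""
    win_codons: list[list[str]] = []
    motif = candidate.motif
    i = 0
    residue_sets: list[list[str]] = []
    while i < len(motif):
        if motif[i] == "[":
            j = motif.index("]", i)
            residue_sets.append(list(motif[i + 1:j]))
            i = j + 1
        else:
            residue_sets.append([motif[i]])
            i += 1
    for residues in residue_sets:
        win_codons.append([c for aa in residues for c in CODONS_OF[aa]])
    return {"".join(p) for p in itertools.product(*win_codons)}
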