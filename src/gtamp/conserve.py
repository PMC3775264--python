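"""Positional conservation profiles and motif scanning.

Conservation is tallied per alignment column over non-gap residues, so ragged
amplicon coverage does not dilute the estimate.  Motifs are written in a
small pattern grammar — residue letters, ``X`` for any residue, ``[KR]`` for
alternation, ``{m,n}`` for a repetition range applied to the preceding token
(e.g. the Rieske dioxygenase iron-binding motif ``DX{2}HX{3,4}H``).
Repetitions are matched greedily (longest first, with backtracking) and hits
are the leftmost non-overlapping ones.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import SequenceRecord

_AA = "ACDEFGHIKLMNPQRSTVWY"


class PatternError(ValueError):
    """Malformed motif pattern; carries the offending position."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} at position {position}")
        self.position = position


@dataclass(frozen=True)
class MotifPattern:
    """A parsed motif pattern compiled to a regular expression."""

    pattern: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "_regex", _compile(self.pattern))

    @property
    def regex(self) -> "re.Pattern[str] | None":
        return self._regex  # type: ignore[attr-defined]


def _compile(pattern: str) -> "re.Pattern[str] | None":
    """Parse the motif grammar and compile to a Python regex.

    Returns None for the empty pattern (which matches nothing).
    """
    if not pattern:
        return None
    tokens: list[str] = []
    i = 0
    n = len(pattern)
    while i < n:
        c = pattern[i]
        if c == "[":
            j = pattern.find("]", i + 1)
            if j < 0:
                raise PatternError("unterminated '['", i)
            inner = pattern[i + 1:j]
            if not inner:
                raise PatternError("empty alternation", i)
            for k, r in enumerate(inner):
                if r not in _AA:
                    raise PatternError(f"invalid residue {r!r} in alternation", i + 1 + k)
            tokens.append(f"[{inner}]")
            i = j + 1
        elif c == "X":
            tokens.append(f"[{_AA}]")
            i += 1
        elif c in _AA:
            tokens.append(re.escape(c))
            i += 1
        elif c == "{":
            if not tokens:
                raise PatternError("repetition with no preceding token", i)
            j = pattern.find("}", i + 1)
            if j < 0:
                raise PatternError("unterminated '{'", i)
            body = pattern[i + 1:j]
            m = re.fullmatch(r"(\d+)(?:,(\d+))?", body)
            if not m:
                raise PatternError(f"malformed repetition {{{body}}}", i)
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            if hi < lo:
                raise PatternError("repetition range with m > n", i)
            # greedy {lo,hi}: regex tries the longest count first
            tokens[-1] = f"{tokens[-1]}{{{lo},{hi}}}"
            i = j + 1
        else:
            raise PatternError(f"invalid character {c!r}", i)
    return re.compile("".join(tokens))


@dataclass
class ConservationProfile:
    """Per-column residue frequencies, consensus and percent conservation."""

    column_counts: list[Counter]
    consensus: str
    percent_conserved: np.ndarray
    threshold: float

    def __len__(self) -> int:
        return len(self.column_counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(len(self)),
                "consensus": list(self.consensus),
                "percent": self.percent_conserved,
            }
        )


def conservation_profile(
    aligned: Sequence[SequenceRecord],
    consensus_threshold: float = 0.95,
) -> ConservationProfile:
    """Column-wise conservation of an alignment.

    Percent conserved is the modal residue frequency among non-gap residues;
    the consensus letter is that residue when its frequency reaches the
    threshold and ``'x'`` otherwise (modal ties go to the alphabetically
    first residue).  All-gap columns report 0 and ``'x'``.
    """
    if not aligned:
        raise ValueError("need at least one sequence")
    L = len(aligned[0].seq)
    if any(len(r.seq) != L for r in aligned):
        raise ValueError("aligned sequences must have equal length")

    counts: list[Counter] = []
    consensus = []
    percent = np.zeros(L)
    for j in range(L):
        col = Counter(
            r.seq[j].upper() for r in aligned if r.seq[j] not in ("-", ".")
        )
        counts.append(col)
        if not col:
            consensus.append("x")
            continue
        total = sum(col.values())
        modal = min(col, key=lambda aa: (-col[aa], aa))
        percent[j] = col[modal] / total
        consensus.append(modal if percent[j] >= consensus_threshold else "x")
    return ConservationProfile(
        column_counts=counts,
        consensus="".join(consensus),
        percent_conserved=percent,
        threshold=consensus_threshold,
    )


def motif_scan(protein: str | SequenceRecord, pattern: MotifPattern | str) -> list[tuple[int, int]]:
    """Leftmost non-overlapping motif hits as 0-based half-open spans."""
    seq = (protein.seq if isinstance(protein, SequenceRecord) else protein).upper()
    pat = pattern if isinstance(pattern, MotifPattern) else MotifPattern(pattern)
    if pat.regex is None:
        return []
    return [(m.start(), m.end()) for m in pat.regex.finditer(seq)]


def motif_prevalence(
    proteins: Sequence[SequenceRecord | str], pattern: MotifPattern | str
) -> float:
    """Fraction of sequences carrying at least one motif hit."""
    if not proteins:
        raise ValueError("need at least one sequence")
    pat = pattern if isinstance(pattern, MotifPattern) else MotifPattern(pattern)
    n_hit = sum(1 for p in proteins if motif_scan(p, pat))
    return n_hit / len(proteins)


def compare_profiles(
    obtained: ConservationProfile, reference: ConservationProfile
) -> pd.DataFrame:
    """Column-wise comparison of obtained vs reference conservation.

    The ``exceeds`` flag marks columns where the environmental (obtained)
    sequences are conserved at a higher rate than the references.
    """
    if len(obtained) != len(reference):
        raise ValueError(
            f"column count mismatch: {len(obtained)} vs {len(reference)}"
        )
    return pd.DataFrame(
        {
            "column": np.arange(len(obtained)),
            "consensus": list(obtained.consensus),
            "percent": obtained.percent_conserved,
            "reference_percent": reference.percent_conserved,
            "exceeds": obtained.percent_conserved > reference.percent_conserved,
        }
    )
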