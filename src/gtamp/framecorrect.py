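"""Frameshift-aware alignment of DNA reads against protein references.

Pyrosequencing homopolymer errors insert or delete single bases, shifting the
reading frame and wrecking naive six-frame translation.  The aligner here
performs a local dynamic-programming alignment of a DNA read directly against
a protein reference in which one reference residue may be consumed by

* 3 bases — an ordinary codon, scored by the substitution matrix;
* 2 bases — a deletion-type frameshift: the missing base is resolved to the
  completion (at any of the three codon positions) whose translation scores
  best, minus the frameshift penalty;
* 4 bases — an insertion-type frameshift: one of the four bases is dropped,
  again taking the best-scoring resolution, minus the penalty;

together with affine gaps in either sequence (reference residues skipped, or
whole read codons inserted).  Unaligned read ends are not penalized (local
mode).  The corrected protein is the translation emitted along the optimal
path with frameshift codons resolved, so a read carrying only indel errors is
restored to its source protein exactly.

Frameshift placement is guided by the reference, so it becomes ambiguous when
the nearest reference is highly divergent.  ``correct_reads`` therefore
offers a de-novo refinement pass in the style of FrameBot's de novo mode:
unique frameshift-free corrected proteins are recruited as additional
templates and distant reads are re-corrected against them.

Identity is reported over reference-residue columns of the optimal path
(substitution columns plus reference residues aligned to gaps).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .primers import STOP_CODONS, _STANDARD_TABLE
from .seqio import PipelineConfig, SequenceRecord

logger = logging.getLogger(__name__)

NEG = -1e9


@dataclass(frozen=True)
class AlignmentScoring:
    """Scoring parameters (penalties are magnitudes).

    A gap of length L costs ``gap_open + L * gap_extend``.  The frameshift
    penalty applies per 2- or 4-base consumption; the default (12) makes a
    frameshift costlier than a gap extension but cheaper than opening two
    gaps, which is what single-base 454 errors look like.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    frameshift_penalty: float = 12.0

    def __post_init__(self) -> None:
        if min(self.gap_open, self.gap_extend, self.frameshift_penalty) < 0:
            raise ValueError("penalties are magnitudes and must be >= 0")
        if self.frameshift_penalty <= self.gap_extend:
            raise ValueError("frameshift_penalty must exceed gap_extend")


@dataclass
class CorrectedRead:
    """A frameshift-corrected protein read with nearest-reference annotation."""

    id: str
    sample: str | None
    protein: str
    n_frameshifts: int
    nearest_ref: str
    identity: float
    aligned_length: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")
        if self.n_frameshifts < 0:
            raise ValueError("n_frameshifts must be >= 0")


@dataclass
class FrameshiftAlignment:
    """Optimal path of one read against one reference."""

    score: float
    protein: str
    n_frameshifts: int
    identity: float
    aligned_length: int          # reference-residue columns in the path
    ref_start: int
    ref_end: int
    dna_start: int
    dna_end: int
    columns: list[tuple[str, str]] = field(default_factory=list)  # (op, emitted aa)


class _Matrix:
    """Substitution matrix wrapped with an index over its alphabet."""

    _cache: dict[str, "_Matrix"] = {}

    def __init__(self, name: str) -> None:
        m = substitution_matrices.load(name)
        self.alphabet = str(m.alphabet)
        self.index = {aa: i for i, aa in enumerate(self.alphabet)}
        self.scores = np.array(m, dtype=np.float64)
        self.min_score = float(self.scores.min())

    @classmethod
    def get(cls, name: str) -> "_Matrix":
        if name not in cls._cache:
            cls._cache[name] = cls(name)
        return cls._cache[name]


_CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)


def translate_codon(codon: str) -> str:
    """Single-codon translation; stops and ambiguous codons map to 'X'."""
    if codon in STOP_CODONS:
        return "X"
    return _CODON_TO_AA.get(codon, "X")


def _codon_aa_index(codon: str, mat: _Matrix) -> tuple[int, bool]:
    """(matrix row for the codon's residue, is_stop)."""
    if codon in STOP_CODONS:
        return mat.index["X"], True
    aa = _CODON_TO_AA.get(codon)
    if aa is None:  # ambiguous base
        return mat.index["X"], False
    return mat.index[aa], False


def _fs2_candidates(d1: str, d2: str) -> list[str]:
    """Codons obtainable by inserting one base into a 2-base consumption."""
    out = []
    for b in "ACGT":
        out.extend((b + d1 + d2, d1 + b + d2, d1 + d2 + b))
    return out


def _fs4_candidates(quad: str) -> list[str]:
    """Codons obtainable by deleting one base from a 4-base consumption."""
    return [quad[:i] + quad[i + 1:] for i in range(4)]


class _ReadProfiles:
    """Reference-independent emission profiles of one read.

    For each base position i (number of bases consumed) and each consumption
    width, the best substitution score against every alphabet letter; built
    once per read and indexed by each reference's residue array.
    """

    def __init__(self, dseq: str, mat: _Matrix) -> None:
        n = len(dseq)
        A = len(mat.alphabet)
        self.E2 = np.full((n + 1, A), NEG)
        self.E3 = np.full((n + 1, A), NEG)
        self.E4 = np.full((n + 1, A), NEG)
        self.cand2: dict[int, list[tuple[int, bool]]] = {}
        self.cand4: dict[int, list[tuple[int, bool]]] = {}
        for i in range(2, n + 1):
            idx = [_codon_aa_index(c, mat) for c in _fs2_candidates(dseq[i - 2], dseq[i - 1])]
            self.cand2[i] = idx
            self.E2[i] = self._profile(idx, mat)
            if i >= 3:
                ai, stop = _codon_aa_index(dseq[i - 3:i], mat)
                # in-frame stop codons score the matrix minimum; never terminate
                self.E3[i] = mat.min_score if stop else mat.scores[ai]
            if i >= 4:
                idx = [_codon_aa_index(c, mat) for c in _fs4_candidates(dseq[i - 4:i])]
                self.cand4[i] = idx
                self.E4[i] = self._profile(idx, mat)

    @staticmethod
    def _profile(idx: list[tuple[int, bool]], mat: _Matrix) -> np.ndarray:
        rows = np.empty((len(idx), len(mat.alphabet)))
        for k, (ai, stop) in enumerate(idx):
            rows[k] = mat.min_score if stop else mat.scores[ai]
        return rows.max(axis=0)


try:  # optional JIT acceleration of the score scan
    from numba import njit as _njit

    @_njit(cache=False)
    def _score_kernel(e2, e3, e4, go, ge):  # pragma: no cover - jitted
        n1, m = e2.shape
        neg = -1e18
        P = np.full((n1, m + 1), neg)
        M = np.full((n1, m + 1), neg)
        Y = np.full((n1, m + 1), neg)
        for i in range(n1):
            P[i, 0] = 0.0
            M[i, 0] = 0.0
        best = 0.0
        for i in range(2, n1):
            for j in range(1, m + 1):
                v = P[i - 2, j - 1] + e2[i, j - 1]
                if i >= 3:
                    t = P[i - 3, j - 1] + e3[i, j - 1]
                    if t > v:
                        v = t
                if i >= 4:
                    t = P[i - 4, j - 1] + e4[i, j - 1]
                    if t > v:
                        v = t
                if v < 0.0:
                    v = 0.0
                M[i, j] = v
                if v > best:
                    best = v
            x = neg
            for j in range(1, m + 1):
                t = M[i, j - 1] - go - ge
                x = x - ge
                if t > x:
                    x = t
                y = neg
                if i >= 5:
                    a = M[i - 3, j] - go - ge
                    b = Y[i - 3, j] - ge
                    y = a if a > b else b
                Y[i, j] = y
                p = M[i, j]
                if x > p:
                    p = x
                if y > p:
                    p = y
                P[i, j] = p
        return best

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _score_core(
    dseq: str,
    rseq: str,
    scoring: AlignmentScoring,
    mat: _Matrix,
    prof: _ReadProfiles,
) -> float:
    """Score-only variant of the DP (no traceback bookkeeping)."""
    go, ge, fp = scoring.gap_open, scoring.gap_extend, scoring.frameshift_penalty
    n, m = len(dseq), len(rseq)
    ridx = np.array([mat.index.get(aa, mat.index["X"]) for aa in rseq], dtype=np.intp)
    e2 = prof.E2[:, ridx] - fp
    e3 = prof.E3[:, ridx]
    e4 = prof.E4[:, ridx] - fp
    if _HAVE_NUMBA:
        return float(_score_kernel(e2, e3, e4, go, ge))
    emit = {2: e2, 3: e3, 4: e4}
    M = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    P = np.full((n + 1, m + 1), NEG)
    P[:, 0] = 0.0
    M[:, 0] = 0.0
    jrange = np.arange(m)
    best = 0.0
    for i in range(2, n + 1):
        cands = [P[i - k, :m] + emit[k][i] for k in (2, 3, 4) if i - k >= 0]
        mrow = np.maximum(np.maximum.reduce(cands), 0.0)
        M[i, 1:] = mrow
        run = np.maximum.accumulate(M[i, :m] - go + jrange * ge)
        xrow = run - (jrange + 1) * ge
        if i >= 5:
            Y[i, 1:] = np.maximum(M[i - 3, 1:] - go - ge, Y[i - 3, 1:] - ge)
        P[i, 1:] = np.maximum(mrow, np.maximum(xrow, Y[i, 1:]))
        rb = float(mrow.max())
        if rb > best:
            best = rb
    return best


def _align_core(
    dseq: str,
    rseq: str,
    scoring: AlignmentScoring,
    mat: _Matrix,
    prof: _ReadProfiles,
) -> FrameshiftAlignment:
    go, ge, fp = scoring.gap_open, scoring.gap_extend, scoring.frameshift_penalty
    n, m = len(dseq), len(rseq)
    ridx = np.array([mat.index.get(aa, mat.index["X"]) for aa in rseq], dtype=np.intp)

    emit = {
        2: prof.E2[:, ridx] - fp,
        3: prof.E3[:, ridx],
        4: prof.E4[:, ridx] - fp,
    }

    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    # P[i][j]: best score of any state at (i, j); column 0 is a free local start.
    P = np.full((n + 1, m + 1), NEG)
    P[:, 0] = 0.0
    M[:, 0] = 0.0
    Pstate = np.zeros((n + 1, m + 1), dtype=np.uint8)       # argmax state per cell

    k_choice = np.zeros((n + 1, m + 1), dtype=np.uint8)     # 2, 3 or 4
    p_state = np.zeros((n + 1, m + 1), dtype=np.uint8)      # 0=M, 1=X, 2=Y at predecessor
    x_from_m = np.zeros((n + 1, m + 1), dtype=bool)
    y_from_m = np.zeros((n + 1, m + 1), dtype=bool)

    jrange = np.arange(m)
    best_score, best_i, best_j = 0.0, 0, 0

    for i in range(2, n + 1):
        cands = []
        ks = []
        for k in (2, 3, 4):
            if i - k < 0:
                continue
            cands.append(P[i - k, :m] + emit[k][i])
            ks.append(k)
        stacked = np.stack(cands)
        pick = np.argmax(stacked, axis=0)
        mrow = np.maximum(stacked[pick, jrange], 0.0)  # local floor
        M[i, 1:] = mrow
        k_arr = np.array(ks, dtype=np.uint8)[pick]
        k_choice[i, 1:] = k_arr
        # state of the predecessor cell (i - k, j - 1)
        p_state[i, 1:] = Pstate[i - k_arr.astype(np.intp), jrange]

        # X: gap in the read (reference residue skipped); scan along j.
        shifted = M[i, :m] - go + jrange * ge
        run = np.maximum.accumulate(shifted)
        xrow = run - (jrange + 1) * ge
        X[i, 1:] = xrow
        x_from_m[i, 1:] = M[i, :m] - go - ge >= xrow - 1e-9

        # Y: whole read codon inserted relative to the reference.
        if i >= 5:
            from_m = M[i - 3, 1:] - go - ge
            from_y = Y[i - 3, 1:] - ge
            Y[i, 1:] = np.maximum(from_m, from_y)
            y_from_m[i, 1:] = from_m >= from_y

        P[i, 1:] = np.maximum(M[i, 1:], np.maximum(X[i, 1:], Y[i, 1:]))
        Pstate[i, 1:] = np.argmax(
            np.stack([M[i, 1:], X[i, 1:], Y[i, 1:]]), axis=0
        ).astype(np.uint8)

        row_best = int(np.argmax(M[i, 1:])) + 1
        if M[i, row_best] > best_score + 1e-12:
            best_score, best_i, best_j = float(M[i, row_best]), i, row_best

    if best_score <= 0:
        # nothing alignable: emit an empty-path result
        return FrameshiftAlignment(
            score=0.0, protein="", n_frameshifts=0, identity=0.0,
            aligned_length=0, ref_start=0, ref_end=0, dna_start=0, dna_end=0,
        )

    # --- traceback ---------------------------------------------------------
    columns: list[tuple[str, str]] = []
    i, j, state = best_i, best_j, 0
    n_fs = 0
    matches = 0
    ref_cols = 0
    while True:
        if state == 0:  # M: a reference residue consumed by 2/3/4 read bases
            if j == 0 or M[i, j] <= 1e-12:
                break  # local path start (floor cell)
            k = int(k_choice[i, j])
            ref_aa = rseq[j - 1]
            if k == 3:
                emitted = translate_codon(dseq[i - 3:i])
            else:
                # resolve the frameshift to the best-scoring candidate codon
                idx_list = prof.cand2[i] if k == 2 else prof.cand4[i]
                rj = int(ridx[j - 1])
                best_val, emitted = None, "X"
                for ai, stop in idx_list:
                    val = mat.min_score if stop else float(mat.scores[ai, rj])
                    if best_val is None or val > best_val:
                        best_val = val
                        emitted = "X" if stop else mat.alphabet[ai]
                n_fs += 1
            columns.append(("M", emitted))
            ref_cols += 1
            if emitted == ref_aa:
                matches += 1
            prev = int(p_state[i, j])
            pi, pj = i - k, j - 1
            if P[pi, pj] <= 1e-12:
                i, j = pi, pj
                break
            i, j, state = pi, pj, prev
        elif state == 1:  # X: reference residue against a gap
            columns.append(("X", "-"))
            ref_cols += 1
            state = 0 if x_from_m[i, j] else 1
            j -= 1
        else:  # Y: read codon inserted relative to the reference
            columns.append(("Y", translate_codon(dseq[i - 3:i])))
            state = 0 if y_from_m[i, j] else 2
            i -= 3

    columns.reverse()
    protein = "".join(aa for op, aa in columns if op in ("M", "Y"))
    identity = matches / ref_cols if ref_cols else 0.0
    return FrameshiftAlignment(
        score=best_score,
        protein=protein,
        n_frameshifts=n_fs,
        identity=identity,
        aligned_length=ref_cols,
        ref_start=j,
        ref_end=best_j,
        dna_start=i,
        dna_end=best_i,
        columns=columns,
    )


def _check_dna(dseq: str) -> None:
    if len(dseq) < 3:
        raise ValueError("DNA shorter than one codon")
    bad = set(dseq) - set("ACGTN")
    if bad:
        raise ValueError(f"DNA read contains invalid characters {sorted(bad)}")


def frameshift_align(
    dna: SequenceRecord | str,
    ref: SequenceRecord | str,
    scoring: AlignmentScoring | None = None,
) -> FrameshiftAlignment:
    """Optimal local frameshift-aware alignment of a DNA read to a protein."""
    scoring = scoring or AlignmentScoring()
    dseq = (dna.seq if isinstance(dna, SequenceRecord) else dna).upper()
    rseq = (ref.seq if isinstance(ref, SequenceRecord) else ref).upper()
    _check_dna(dseq)
    if not rseq:
        raise ValueError("reference must be non-empty")
    mat = _Matrix.get(scoring.matrix_name)
    return _align_core(dseq, rseq, scoring, mat, _ReadProfiles(dseq, mat))


def _best_against(
    dseq: str,
    refs: Sequence[SequenceRecord],
    scoring: AlignmentScoring,
    mat: _Matrix,
    prof: _ReadProfiles,
) -> tuple[str, FrameshiftAlignment]:
    """Best-scoring reference; ties -> higher identity, then smaller ref id.

    A score-only scan over the reference set precedes the full traceback,
    which only runs for the top-scoring candidates.
    """
    ordered = sorted(refs, key=lambda r: r.id)
    scores = [_score_core(dseq, r.seq.upper(), scoring, mat, prof) for r in ordered]
    top = max(scores)
    best_id: str | None = None
    best_aln: FrameshiftAlignment | None = None
    for ref, score in zip(ordered, scores):
        if score < top - 1e-9:
            continue
        aln = _align_core(dseq, ref.seq.upper(), scoring, mat, prof)
        if best_aln is None or aln.identity > best_aln.identity + 1e-12:
            best_id, best_aln = ref.id, aln
    assert best_id is not None and best_aln is not None
    return best_id, best_aln


def nearest_reference(
    dna: SequenceRecord,
    refs: Sequence[SequenceRecord],
    scoring: AlignmentScoring | None = None,
) -> CorrectedRead:
    """Frameshift-align a read against every reference and keep the best.

    Best = maximum alignment score; ties broken by higher identity, then by
    lexicographically smaller reference id.
    """
    if not refs:
        raise ValueError("reference set must be non-empty")
    scoring = scoring or AlignmentScoring()
    dseq = dna.seq.upper()
    _check_dna(dseq)
    mat = _Matrix.get(scoring.matrix_name)
    prof = _ReadProfiles(dseq, mat)
    ref_id, aln = _best_against(dseq, refs, scoring, mat, prof)
    return CorrectedRead(
        id=dna.id,
        sample=dna.sample,
        protein=aln.protein,
        n_frameshifts=aln.n_frameshifts,
        nearest_ref=ref_id,
        identity=aln.identity,
        aligned_length=aln.aligned_length,
        score=aln.score,
    )


def correct_reads(
    reads: Sequence[SequenceRecord],
    refs: Sequence[SequenceRecord],
    scoring: AlignmentScoring | None = None,
    denovo: bool = False,
    denovo_identity: float = 0.90,
    max_templates: int = 50,
    denovo_rounds: int = 2,
) -> list[CorrectedRead]:
    """Frameshift-correct a batch of reads against a reference set.

    With ``denovo=True`` a refinement pass in the style of FrameBot's de novo
    mode runs after the first pass: frameshift-free corrected proteins seen at
    least twice (most abundant first, up to ``max_templates``) are recruited
    as templates, and reads whose nearest-reference identity fell below
    ``denovo_identity`` are re-corrected against the enlarged template set.
    Frameshift placement against a near-identical template is unambiguous, so
    this repairs resolution errors on reads far from any reference; the
    abundance screen keeps one-off aberrant corrections out of the template
    pool.  The reported ``nearest_ref`` and ``identity`` always refer to the
    real reference set.
    """
    scoring = scoring or AlignmentScoring()
    mat = _Matrix.get(scoring.matrix_name)
    out: list[CorrectedRead] = []
    profiles: dict[str, _ReadProfiles] = {}
    for read in reads:
        dseq = read.seq.upper()
        _check_dna(dseq)
        prof = _ReadProfiles(dseq, mat)
        profiles[read.id] = prof
        ref_id, aln = _best_against(dseq, refs, scoring, mat, prof)
        out.append(
            CorrectedRead(
                id=read.id, sample=read.sample, protein=aln.protein,
                n_frameshifts=aln.n_frameshifts, nearest_ref=ref_id,
                identity=aln.identity, aligned_length=aln.aligned_length,
                score=aln.score,
            )
        )
    if not denovo:
        return out

    by_id = {r.id: r for r in reads}
    for round_no in range(1, denovo_rounds + 1):
        if round_no == 1:
            # only frameshift-free corrections are credible templates so far
            pool_counts = Counter(
                r.protein for r in out if r.n_frameshifts == 0 and r.protein
            )
        else:
            # refined proteins join the pool; the abundance screen still
            # keeps idiosyncratic errors out
            pool_counts = Counter(r.protein for r in out if r.protein)
        templates = [
            SequenceRecord(id=f"denovo{k + 1:04d}", seq=prot)
            for k, (prot, count) in enumerate(
                sorted(pool_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:max_templates]
            )
            if count >= 2
        ]
        if not templates:
            break
        template_pool = list(refs) + templates
        n_refined = 0
        for k, cr in enumerate(out):
            if cr.identity >= denovo_identity:
                continue
            dseq = by_id[cr.id].seq.upper()
            _, aln = _best_against(dseq, template_pool, scoring, mat, profiles[cr.id])
            if aln.protein != cr.protein or aln.n_frameshifts != cr.n_frameshifts:
                n_refined += 1
            out[k] = replace(
                cr,
                protein=aln.protein,
                n_frameshifts=aln.n_frameshifts,
            )
        logger.info(
            "de novo refinement round %d re-corrected %d reads", round_no, n_refined
        )
        if n_refined == 0:
            break
    return out


def quality_filter(
    reads: Sequence[CorrectedRead],
    cfg: PipelineConfig | None = None,
) -> tuple[list[CorrectedRead], Mapping[str, int]]:
    """Keep reads longer than ``min_protein_length`` residues (strict) with
    identity >= ``min_identity`` to their nearest reference."""
    cfg = cfg or PipelineConfig()
    retained: list[CorrectedRead] = []
    n_short = n_lowid = 0
    for r in reads:
        if len(r.protein) <= cfg.min_protein_length:
            n_short += 1
            continue
        if r.identity < cfg.min_identity:
            n_lowid += 1
            continue
        retained.append(r)
    counts = {
        "input": len(reads),
        "failed_length": n_short,
        "failed_identity": n_lowid,
        "passed": len(retained),
    }
    return retained, counts
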