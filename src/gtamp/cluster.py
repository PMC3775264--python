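"""Protein-space OTU clustering and trees.

Pairwise amino-acid dissimilarities (pairwise-deletion gap handling),
complete-linkage (furthest-neighbor) agglomeration with a deterministic
tie-break, dissimilarity cutoff sweeps with inflection detection, medoid
representatives, novel-cluster flagging against a reference id set, and a
native neighbor-joining tree builder emitting Newick.

The distance container is scikit-bio's :class:`~skbio.DistanceMatrix`
(symmetric, zero-diagonal, id-labelled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix

from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

GAP_CHARS = ("-", ".")


@dataclass
class ClusterSet:
    """A partition of ids into OTUs at a stated dissimilarity cutoff."""

    cutoff: float
    clusters: list[frozenset[str]]
    representatives: list[str]
    novel: list[bool]

    def __post_init__(self) -> None:
        ids = [i for c in self.clusters for i in c]
        if len(ids) != len(set(ids)):
            raise ValueError("clusters must partition the ids")
        for rep, c in zip(self.representatives, self.clusters):
            if rep not in c:
                raise ValueError(f"representative {rep!r} not a member of its cluster")

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, (members, rep, novel) in enumerate(
            zip(self.clusters, self.representatives, self.novel)
        ):
            for mid in sorted(members):
                rows.append(
                    {
                        "otu_id": f"OTU{k + 1:04d}",
                        "member_id": mid,
                        "is_representative": mid == rep,
                        "is_novel": novel,
                        "cutoff": self.cutoff,
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SweepCurve:
    """OTU counts across a dissimilarity cutoff sweep."""

    cutoffs: np.ndarray
    otu_counts: np.ndarray
    inflection: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cutoff": self.cutoffs, "otus": self.otu_counts})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# --- alignment projection ---------------------------------------------------


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


def align_to_reference(
    proteins: Sequence[SequenceRecord],
    ref_alignment: Sequence[SequenceRecord],
    coverage_floor: float | None = None,
) -> list[SequenceRecord]:
    """Project query proteins onto the column space of a master alignment.

    Each query is locally aligned to its best-scoring reference (degapped);
    query residues are placed at the master columns of their aligned reference
    residues, residues falling in insertions relative to the master are
    dropped, and uncovered columns become gaps.  Queries with no alignable
    region are excluded (logged).  If ``coverage_floor`` is given, columns
    covered by fewer than that fraction of queries are masked to gaps.
    """
    if not ref_alignment:
        raise ValueError("reference alignment must be non-empty")
    ncol = len(ref_alignment[0].seq)
    if any(len(r.seq) != ncol for r in ref_alignment):
        raise ValueError("reference alignment rows must have equal length")
    if not proteins:
        return []

    aligner = _protein_aligner()
    refs = []
    for rec in ref_alignment:
        degapped = "".join(c for c in rec.seq if c not in GAP_CHARS)
        col_of = [i for i, c in enumerate(rec.seq) if c not in GAP_CHARS]
        refs.append((rec, degapped, col_of))

    out: list[SequenceRecord] = []
    for query in proteins:
        best = None
        for rec, degapped, col_of in refs:
            try:
                score = aligner.score(degapped, query.seq)
            except ValueError:
                continue
            key = (score, rec.id)
            if best is None or score > best[0][0] or (score == best[0][0] and rec.id < best[0][1]):
                best = (key, rec, degapped, col_of)
        if best is None or best[0][0] <= 0:
            logger.warning("query %s has no alignable region; excluded", query.id)
            continue
        _, rec, degapped, col_of = best
        aln = aligner.align(degapped, query.seq)[0]
        row = ["-"] * ncol
        for (rs, re), (qs, qe) in zip(*aln.aligned):
            for k in range(re - rs):
                row[col_of[rs + k]] = query.seq[qs + k]
        projected = "".join(row)
        if projected.strip("-"):
            out.append(replace(query, seq=projected))
        else:
            logger.warning("query %s has no alignable region; excluded", query.id)

    if coverage_floor is not None and out:
        cov = np.mean(
            [[c not in GAP_CHARS for c in rec.seq] for rec in out], axis=0
        )
        mask = cov < coverage_floor
        if mask.any():
            for i, rec in enumerate(out):
                masked = "".join(
                    "-" if mask[j] else c for j, c in enumerate(rec.seq)
                )
                out[i] = replace(rec, seq=masked)
    return out


# --- distances --------------------------------------------------------------


def aa_distance_matrix(aligned: Sequence[SequenceRecord]) -> DistanceMatrix:
    """Pairwise amino-acid dissimilarity with pairwise gap deletion.

    d(a, b) = differing positions / comparable positions, comparable meaning
    both residues non-gap; pairs sharing no comparable position get d = 1.
    """
    if len(aligned) < 2:
        raise ValueError("need at least 2 sequences")
    L = len(aligned[0].seq)
    if any(len(r.seq) != L for r in aligned):
        raise ValueError("aligned sequences must have equal length")
    ids = [r.id for r in aligned]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")

    arr = np.array([list(r.seq.upper()) for r in aligned])
    nongap = ~np.isin(arr, GAP_CHARS)
    ng = nongap.astype(np.float64)
    comparable = ng @ ng.T

    letters = np.unique(arr[nongap]) if nongap.any() else np.array([])
    same = np.zeros_like(comparable)
    for letter in letters:
        hit = ((arr == letter) & nongap).astype(np.float64)
        same += hit @ hit.T

    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(comparable > 0, (comparable - same) / comparable, 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, ids=ids)


# --- complete-linkage agglomeration ----------------------------------------


def _agglomerate(dist: DistanceMatrix) -> tuple[list[str], list[tuple[int, int, float]]]:
    """Full furthest-neighbor merge sequence.

    Ids are taken in lexicographic order; each merge is recorded as
    (position_i, position_j, linkage) with i < j over the *sorted-id*
    positions, the merged cluster keeping position i.  On tied linkages the
    pair whose smaller position (hence lexicographically least smallest
    member) comes first is merged, then the smaller second position.
    Complete-linkage merge heights are non-decreasing.
    """
    order = np.argsort(np.array(dist.ids, dtype=object))
    ids = [dist.ids[k] for k in order]
    D = dist.data[np.ix_(order, order)].astype(np.float64).copy()
    n = len(ids)
    INF = np.inf
    np.fill_diagonal(D, INF)
    active = np.ones(n, dtype=bool)
    merges: list[tuple[int, int, float]] = []
    work = D.copy()
    for _ in range(n - 1):
        flat = np.argmin(work)  # row-major first occurrence = deterministic tie-break
        i, j = divmod(int(flat), n)
        if i > j:
            i, j = j, i
        h = float(work[i, j])
        merges.append((i, j, h))
        # furthest-neighbor update: new cluster distance = max of the two rows
        newrow = np.maximum(work[i], work[j])
        work[i] = newrow
        work[:, i] = newrow
        work[i, i] = INF
        work[j, :] = INF
        work[:, j] = INF
        active[j] = False
    return ids, merges


def _partition_from_merges(
    ids: list[str], merges: Iterable[tuple[int, int, float]], cutoff: float
) -> list[frozenset[str]]:
    parent = list(range(len(ids)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j, h in merges:
        if h > cutoff + 1e-12:
            break
        ri, rj = find(i), find(j)
        parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, set[str]] = {}
    for k, name in enumerate(ids):
        groups.setdefault(find(k), set()).add(name)
    # deterministic cluster order: by smallest member id
    return [frozenset(groups[r]) for r in sorted(groups, key=lambda r: min(groups[r]))]


def representative(members: Iterable[str], dist: DistanceMatrix) -> str:
    """Medoid: member minimizing mean distance to the others; ties -> smallest id."""
    members = sorted(members)
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return members[0]
    idx = [dist.index(mid) for mid in members]
    sub = dist.data[np.ix_(idx, idx)]
    means = sub.sum(axis=1) / (len(members) - 1)
    return members[int(np.argmin(means))]  # argmin is first on ties; members sorted


def complete_linkage(dist: DistanceMatrix, cutoff: float) -> ClusterSet:
    """Furthest-neighbor clustering: merge while linkage <= cutoff.

    Every resulting cluster satisfies max intra-cluster distance <= cutoff
    (asserted on the output).
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    ids, merges = _agglomerate(dist)
    clusters = _partition_from_merges(ids, merges, cutoff)
    for members in clusters:
        if len(members) > 1:
            idx = [dist.index(mid) for mid in members]
            dmax = dist.data[np.ix_(idx, idx)].max()
            if dmax > cutoff + 1e-9:
                raise AssertionError(
                    f"complete-linkage violation: intra-cluster max {dmax} > {cutoff}"
                )
    reps = [representative(c, dist) for c in clusters]
    return ClusterSet(
        cutoff=cutoff,
        clusters=clusters,
        representatives=reps,
        novel=[False] * len(clusters),
    )


def flag_novel(clusters: ClusterSet, reference_ids: Iterable[str]) -> ClusterSet:
    """Mark clusters containing no reference sequence as novel."""
    refset = set(reference_ids)
    novel = [not (c & refset) for c in clusters.clusters]
    return ClusterSet(
        cutoff=clusters.cutoff,
        clusters=clusters.clusters,
        representatives=clusters.representatives,
        novel=novel,
    )


def cutoff_sweep(
    dist: DistanceMatrix,
    max_cutoff: float = 0.30,
    step: float = 0.01,
    subsample: int | None = None,
    seed: int | None = None,
) -> SweepCurve:
    """OTU counts across cutoffs in [0, max_cutoff].

    Optionally subsamples the ids without replacement (seeded) before the
    sweep.  The inflection point is the cutoff maximizing the discrete second
    difference of the count curve (ties -> smallest cutoff) — the point where
    within-group collapse gives way to the slow between-group regime.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if subsample is not None:
        if subsample > len(dist.ids):
            raise ValueError("subsample larger than number of sequences")
        rng = np.random.default_rng(seed)
        keep = sorted(rng.choice(len(dist.ids), size=subsample, replace=False))
        kept_ids = [dist.ids[k] for k in keep]
        dist = dist.filter(kept_ids)
    ids, merges = _agglomerate(dist)
    heights = np.array([h for _, _, h in merges])
    cutoffs = np.round(np.arange(0.0, max_cutoff + step / 2, step), 10)
    counts = np.array(
        [len(ids) - int(np.sum(heights <= c + 1e-12)) for c in cutoffs], dtype=int
    )
    if len(cutoffs) >= 3:
        d2 = counts[2:] - 2 * counts[1:-1] + counts[:-2]
        inflection = float(cutoffs[1 + int(np.argmax(d2))])
    else:
        inflection = float(cutoffs[0])
    return SweepCurve(cutoffs=cutoffs, otu_counts=counts, inflection=inflection)


# --- neighbor joining -------------------------------------------------------


def nj_tree(dist: DistanceMatrix) -> str:
    """Neighbor-joining tree in Newick form.

    Standard saitou-nei agglomeration with negative branch lengths clamped to
    zero (clamps are logged).  Requires >= 3 taxa; the result is the unrooted
    tree written with a basal trifurcation.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    labels = [_escape_newick(t) for t in dist.ids]
    nodes: list[str] = list(labels)
    D = dist.data.astype(np.float64).copy()
    n_clamped = 0

    def clamp(x: float) -> float:
        nonlocal n_clamped
        if x < 0:
            n_clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        N = len(nodes)
        r = D.sum(axis=1)
        Q = (N - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), N)  # row-major first = deterministic
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = clamp(0.5 * dij + (r[i] - r[j]) / (2 * (N - 2)))
        lj = clamp(dij - (0.5 * dij + (r[i] - r[j]) / (2 * (N - 2))))
        new_node = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        dk = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(N) if k not in (i, j)]
        newD = np.zeros((len(keep) + 1, len(keep) + 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = dk[keep]
        D = newD
        nodes = [nodes[k] for k in keep] + [new_node]

    a, b, c = D[0, 1], D[0, 2], D[1, 2]
    la = clamp(0.5 * (a + b - c))
    lb = clamp(0.5 * (a + c - b))
    lc = clamp(0.5 * (b + c - a))
    if n_clamped:
        logger.info("nj_tree: clamped %d negative branch lengths to 0", n_clamped)
    return f"({nodes[0]}:{la:.10g},{nodes[1]}:{lb:.10g},{nodes[2]}:{lc:.10g});"


def _escape_newick(label: str) -> str:
    if any(c in label for c in "();:, '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label
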