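"""OTU tables, diversity statistics and treatment comparisons.

Two binning routes build samples × OTUs count tables from corrected reads:
the supervised route assigns each read to its nearest-reference genus with an
identity sub-bin (>90%, 75–90%, 50–75%, <50% similar to closest match), the
unsupervised route counts de-novo cluster memberships and borrows the
representative's nearest-reference taxonomy.  Downstream: seeded rarefaction
without replacement, analytic rarefaction curves, bias-corrected Chao1
richness, Hellinger-transform principal component ordination, and per-OTU
one-way F-tests across treatment groups with Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from skbio.diversity.alpha import chao1 as _skbio_chao1
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterSet
from .framecorrect import CorrectedRead
from .primers import TaxonLineage

logger = logging.getLogger(__name__)


@dataclass
class OTUTable:
    """Samples × OTUs integer counts with optional per-OTU taxonomy."""

    counts: pd.DataFrame                    # index: samples, columns: otu ids
    taxonomy: pd.DataFrame | None = None    # index: otu ids

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any() or self.counts.columns.duplicated().any():
            raise ValueError("sample and OTU names must be unique")
        self.counts = self.counts.astype(int)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otus(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def total(self) -> int:
        return int(self.counts.values.sum())

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)

    def drop_empty_otus(self) -> "OTUTable":
        keep = self.counts.columns[self.counts.sum(axis=0) > 0]
        tax = self.taxonomy.loc[keep] if self.taxonomy is not None else None
        return OTUTable(counts=self.counts[keep].copy(), taxonomy=tax)

    def to_tsv(self, path) -> None:
        out = self.counts.T
        if self.taxonomy is not None:
            out = self.taxonomy.join(out, how="right")
        out.rename_axis("otu_id").to_csv(path, sep="\t")


@dataclass
class GroupDesign:
    """Sample -> treatment label mapping."""

    assignments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.assignments.values())) < 2:
            raise ValueError("need >= 2 groups")

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, grp in self.assignments.items():
            out.setdefault(grp, []).append(sample)
        return out

    @classmethod
    def from_tsv(cls, path) -> "GroupDesign":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
        return cls(dict(zip(df["sample"], df["group"])))


def identity_bin(identity: float, edges: Sequence[float] = (0.90, 0.75, 0.50)) -> str:
    """Closest-match identity sub-bin label; upper edges are strict.

    With the default edges a read >90% similar to its closest match falls in
    ">90", exactly 0.90 falls in "75-90", and the bottom bin is "<50".
    """
    if any(a <= b for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly decreasing")
    pct = [int(round(e * 100)) for e in edges]
    if identity > edges[0]:
        return f">{pct[0]}"
    for k in range(1, len(edges)):
        if identity > edges[k]:
            return f"{pct[k]}-{pct[k - 1]}"
    return f"<{pct[-1]}"


def closest_match_bin(
    reads: Sequence[CorrectedRead],
    taxonomy: Mapping[str, TaxonLineage],
    bin_edges: Sequence[float] = (0.90, 0.75, 0.50),
) -> OTUTable:
    """Supervised binning: OTU = (nearest-reference genus, identity sub-bin)."""
    rows: dict[str, dict[str, int]] = {}
    tax_rows: dict[str, dict[str, str]] = {}
    for read in reads:
        sample = read.sample or "unknown"
        if read.nearest_ref and read.nearest_ref in taxonomy:
            genus = taxonomy[read.nearest_ref].genus
            sub = identity_bin(read.identity, bin_edges)
            otu = f"{genus}|{sub}"
            tax_rows[otu] = {"genus": genus, "identity_bin": sub}
        elif read.nearest_ref:
            sub = identity_bin(read.identity, bin_edges)
            otu = f"unclassified|{sub}"
            tax_rows[otu] = {"genus": "unclassified", "identity_bin": sub}
        else:
            otu = "unassigned"
            tax_rows[otu] = {"genus": "unassigned", "identity_bin": ""}
        rows.setdefault(sample, {})
        rows[sample][otu] = rows[sample].get(otu, 0) + 1
    counts = (
        pd.DataFrame.from_dict(rows, orient="index")
        .fillna(0)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    tax = pd.DataFrame.from_dict(tax_rows, orient="index").loc[counts.columns]
    return OTUTable(counts=counts, taxonomy=tax)


def cluster_bin(
    clusters: ClusterSet,
    reads: Sequence[CorrectedRead],
    taxonomy: Mapping[str, TaxonLineage],
    samples: Sequence[str] | None = None,
    bin_edges: Sequence[float] = (0.90, 0.75, 0.50),
) -> OTUTable:
    """Unsupervised binning: one OTU per cluster, counts = members per sample.

    Taxonomy borrows the representative's nearest-reference genus with its
    identity sub-bin; a representative that is itself a reference sequence
    gets its own genus in the top sub-bin.  Cluster members that are not
    reads (reference sequences) contribute no counts.
    """
    by_id = {r.id: r for r in reads}
    sample_list = sorted(samples) if samples is not None else sorted(
        {r.sample or "unknown" for r in reads}
    )
    counts = pd.DataFrame(
        0, index=pd.Index(sample_list, dtype=object), columns=[], dtype=int
    )
    tax_rows = {}
    for k, (members, rep) in enumerate(zip(clusters.clusters, clusters.representatives)):
        otu = f"OTU{k + 1:04d}"
        counts[otu] = 0
        for mid in members:
            read = by_id.get(mid)
            if read is None:
                continue
            sample = read.sample or "unknown"
            if sample in counts.index:
                counts.loc[sample, otu] += 1
        if rep in taxonomy:
            genus, sub = taxonomy[rep].genus, identity_bin(1.0, bin_edges)
        elif rep in by_id and by_id[rep].nearest_ref in taxonomy:
            genus = taxonomy[by_id[rep].nearest_ref].genus
            sub = identity_bin(by_id[rep].identity, bin_edges)
        else:
            genus, sub = "unclassified", ""
        tax_rows[otu] = {"genus": genus, "identity_bin": sub}
    tax = pd.DataFrame.from_dict(tax_rows, orient="index").loc[counts.columns]
    return OTUTable(counts=counts, taxonomy=tax)


def rarefy(table: OTUTable, depth: int | None = None, seed: int | None = None) -> OTUTable:
    """Subsample every sample to equal depth without replacement (seeded).

    Default depth is the minimum sample total; OTUs left with all-zero counts
    are removed.  A depth exceeding any sample total is an error.
    """
    totals = table.sample_totals()
    if depth is None:
        depth = int(totals.min())
    if (totals < depth).any():
        too_small = list(totals.index[totals < depth])
        raise ValueError(f"depth {depth} exceeds totals of samples {too_small}")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(0, index=table.counts.index, columns=table.counts.columns, dtype=int)
    for sample in table.counts.index:
        row = table.counts.loc[sample].to_numpy()
        out.loc[sample] = rng.multivariate_hypergeometric(row, depth)
    return OTUTable(counts=out, taxonomy=table.taxonomy).drop_empty_otus()


def rarefaction_curve(counts: Sequence[int] | np.ndarray, depths: Sequence[int]) -> np.ndarray:
    """Analytic expected richness for one sample at each subsampling depth.

    E[S_d] = sum_i (1 - C(N - N_i, d) / C(N, d)); exactly the observed
    richness at d = N and monotone non-decreasing in d.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    N = int(counts.sum())
    out = np.empty(len(depths), dtype=float)

    def log_comb(a: np.ndarray, b: int) -> np.ndarray:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    for k, d in enumerate(depths):
        d = int(d)
        if d > N:
            raise ValueError(f"depth {d} exceeds sample total {N}")
        if d == 0:
            out[k] = 0.0
            continue
        rest = N - counts
        p_absent = np.zeros(len(counts))
        ok = rest >= d
        if ok.any():
            p_absent[ok] = np.exp(log_comb(rest[ok].astype(float), d) - log_comb(np.float64(N), d))
        out[k] = float(np.sum(1.0 - p_absent))
    return out


def chao1(counts: Sequence[int] | np.ndarray) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1)/(2(F2+1))."""
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    return float(_skbio_chao1(counts, bias_corrected=True))


@dataclass
class PCAResult:
    """Sample ordination from a Hellinger-transformed count table."""

    coordinates: pd.DataFrame           # samples × axes
    proportion_explained: np.ndarray
    loadings: pd.DataFrame              # otus × axes


def hellinger_pca(table: OTUTable) -> PCAResult:
    """Principal component analysis of Hellinger-transformed counts.

    Counts become sqrt(relative abundance); columns are centred; samples are
    projected via SVD.  Axis signs follow the convention that each axis's
    largest-magnitude loading is positive.
    """
    if len(table.samples) < 2 or len(table.otus) < 2:
        raise ValueError("need >= 2 samples and >= 2 OTUs")
    totals = table.sample_totals().to_numpy(dtype=float)
    if (totals == 0).any():
        empty = [s for s, t in zip(table.samples, totals) if t == 0]
        raise ValueError(f"zero-total samples {empty}")
    H = np.sqrt(table.counts.to_numpy(dtype=float) / totals[:, None])
    Xc = H - H.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # fix axis orientation: the largest-|loading| entry per axis is positive
    for a in range(len(S)):
        jmax = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, jmax] < 0:
            Vt[a] *= -1.0
            U[:, a] *= -1.0
    coords = U * S
    denom = float(np.sum(S**2))
    explained = S**2 / denom if denom > 0 else np.zeros_like(S)
    axes = [f"PC{k + 1}" for k in range(len(S))]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=table.counts.index, columns=axes),
        proportion_explained=explained,
        loadings=pd.DataFrame(Vt.T, index=table.counts.columns, columns=axes),
    )


def per_otu_ftest(
    table: OTUTable,
    design: GroupDesign,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """One-way F-test per OTU on relative abundances, BH-adjusted.

    Groups with fewer than 2 samples are excluded from the design (logged);
    at least 2 replicated groups are required.  Returns a frame with columns
    otu, F, p, p_adj, significant (adjusted p < fdr_q).
    """
    rel = table.relative_abundance()
    groups = []
    for name, samples in sorted(design.groups.items()):
        samples = [s for s in samples if s in rel.index]
        if len(samples) < 2:
            logger.warning("group %r has < 2 samples; excluded from F-tests", name)
            continue
        groups.append(rel.loc[samples].to_numpy(dtype=float))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")

    all_vals = np.vstack(groups)
    constant = np.all(np.isclose(all_vals, all_vals[0:1, :]), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = stats.f_oneway(*groups, axis=0)
    F = np.asarray(F, dtype=float)
    p = np.asarray(p, dtype=float)
    # identical values in every sample: no evidence of effect
    F[constant] = 0.0
    p[constant] = 1.0
    p = np.nan_to_num(p, nan=1.0)
    F = np.nan_to_num(F, nan=0.0)
    reject, p_adj, _, _ = multipletests(p, alpha=fdr_q, method="fdr_bh")
    return pd.DataFrame(
        {
            "otu": table.otus,
            "F": F,
            "p": p,
            "p_adj": p_adj,
            "significant": reject,
        }
    )
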