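"""OTU tables, rarefaction, richness, ordination and group tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from gtamp.community import (
    GroupDesign,
    OTUTable,
    chao1,
    closest_match_bin,
    cluster_bin,
    hellinger_pca,
    identity_bin,
    per_otu_ftest,
    rarefaction_curve,
    rarefy,
)
from gtamp.framecorrect import CorrectedRead
from gtamp.primers import TaxonLineage


def _read(rid, sample, ref, identity):
    return CorrectedRead(
        id=rid, sample=sample, protein="A" * 120, n_frameshifts=0,
        nearest_ref=ref, identity=identity, aligned_length=120,
    )


TAX = {
    "refB": TaxonLineage(genus="Bradyrhizobium"),
    "refA": TaxonLineage(genus="Azospirillum"),
}


class TestIdentityBins:
    @pytest.mark.parametrize(
        "identity,label",
        [
            (0.95, ">90"),
            (0.90, "75-90"),   # boundary falls to the lower bin
            (0.80, "75-90"),
            (0.75, "50-75"),
            (0.60, "50-75"),
            (0.50, "<50"),
            (0.10, "<50"),
        ],
    )
    def test_boundaries(self, identity, label):
        assert identity_bin(identity) == label


class TestClosestMatchBin:
    def test_high_identity_read_binned_to_genus(self):
        table = closest_match_bin([_read("r1", "s1", "refB", 0.95)], TAX)
        assert table.otus == ["Bradyrhizobium|>90"]
        assert table.counts.loc["s1", "Bradyrhizobium|>90"] == 1

    def test_planted_marginals_recovered(self, rng):
        genera = ["refB", "refA"]
        bins = [0.95, 0.85, 0.60, 0.30]
        reads = []
        expected: dict[tuple[str, str], int] = {}
        for k in range(1000):
            sample = f"s{k % 4}"
            ref = genera[k % 2]
            ident = bins[k % 4]
            reads.append(_read(f"r{k}", sample, ref, ident))
            key = (sample, f"{TAX[ref].genus}|{identity_bin(ident)}")
            expected[key] = expected.get(key, 0) + 1
        table = closest_match_bin(reads, TAX)
        assert table.total() == 1000
        for (sample, otu), count in expected.items():
            assert table.counts.loc[sample, otu] == count

    def test_read_without_reference_goes_unassigned(self):
        read = CorrectedRead(
            id="r1", sample="s1", protein="A" * 120, n_frameshifts=0,
            nearest_ref="", identity=0.0, aligned_length=0,
        )
        table = closest_match_bin([read], TAX)
        assert table.otus == ["unassigned"]


class TestClusterBin:
    def test_counts_match_membership(self, rng, small_refset):
        from gtamp.cluster import ClusterSet

        reads = [
            _read("r1", "s1", "refB", 0.95),
            _read("r2", "s1", "refB", 0.95),
            _read("r3", "s2", "refA", 0.80),
            _read("r4", "s2", "refA", 0.80),
            _read("r5", "s1", "refA", 0.80),
        ]
        cs = ClusterSet(
            cutoff=0.05,
            clusters=[frozenset({"r1", "r2"}), frozenset({"r3", "r5"}), frozenset({"r4"})],
            representatives=["r1", "r3", "r4"],
            novel=[False, True, True],
        )
        table = cluster_bin(cs, reads, TAX, samples=["s1", "s2"])
        assert table.total() == 5
        assert table.counts.loc["s1", "OTU0001"] == 2
        assert table.counts.loc["s2", "OTU0002"] == 1
        assert table.taxonomy.loc["OTU0001", "genus"] == "Bradyrhizobium"

    def test_empty_sample_row_retained(self):
        from gtamp.cluster import ClusterSet

        reads = [_read("r1", "s1", "refB", 0.95)]
        cs = ClusterSet(cutoff=0.05, clusters=[frozenset({"r1"})],
                        representatives=["r1"], novel=[True])
        table = cluster_bin(cs, reads, TAX, samples=["s1", "s2"])
        assert list(table.counts.loc["s2"]) == [0]


def _toy_table(rng, n_samples=4, n_otus=30, depth=250) -> OTUTable:
    base = rng.dirichlet(np.ones(n_otus) * 0.5)
    counts = np.vstack(
        [rng.multinomial(depth + 50 * i, base) for i in range(n_samples)]
    )
    return OTUTable(
        counts=pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"o{j}" for j in range(n_otus)],
        )
    )


class TestRarefy:
    def test_equal_totals_at_minimum(self, rng):
        table = _toy_table(rng)
        out = rarefy(table, seed=1)
        totals = out.sample_totals()
        assert (totals == table.sample_totals().min()).all()
        assert (out.counts.sum(axis=0) > 0).all()  # empty OTUs removed

    def test_same_seed_identical(self, rng):
        table = _toy_table(rng)
        a = rarefy(table, depth=200, seed=7)
        b = rarefy(table, depth=200, seed=7)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_depth_above_total_rejected(self, rng):
        table = _toy_table(rng)
        with pytest.raises(ValueError, match="depth"):
            rarefy(table, depth=10_000)

    def test_mean_richness_matches_hypergeometric_expectation(self, rng):
        table = _toy_table(rng, n_samples=1, n_otus=25, depth=300)
        counts = table.counts.iloc[0].to_numpy()
        depth = 80
        expected = rarefaction_curve(counts, [depth])[0]
        observed = []
        for seed in range(100):
            out = rarefy(table, depth=depth, seed=seed)
            observed.append(len(out.otus))
        mc = np.mean(observed)
        se = np.std(observed, ddof=1) / np.sqrt(len(observed))
        assert abs(mc - expected) <= 3 * max(se, 0.05)


class TestRarefactionCurve:
    def test_full_depth_gives_observed_richness(self, rng):
        counts = np.array([5, 3, 0, 9, 1, 2])
        N = counts.sum()
        assert rarefaction_curve(counts, [N])[0] == pytest.approx(5.0)

    def test_depth_one_gives_one(self):
        assert rarefaction_curve([4, 4, 4], [1])[0] == pytest.approx(1.0)

    def test_monotone_in_depth(self, rng):
        counts = rng.integers(0, 30, size=20)
        counts[0] = 5
        depths = range(1, int(counts.sum()) + 1, 7)
        curve = rarefaction_curve(counts, list(depths))
        assert (np.diff(curve) >= -1e-9).all()

    def test_matches_monte_carlo_subsampling(self, rng):
        counts = np.array([12, 7, 3, 1, 1, 25, 4])
        depth = 15
        expected = rarefaction_curve(counts, [depth])[0]
        g = np.random.default_rng(5)
        sims = [
            int((g.multivariate_hypergeometric(counts, depth) > 0).sum())
            for _ in range(10_000)
        ]
        mc = np.mean(sims)
        se = np.std(sims, ddof=1) / np.sqrt(len(sims))
        assert abs(mc - expected) <= 3 * se

    def test_depth_above_total_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            rarefaction_curve([2, 2], [10])


class TestChao1:
    def test_no_singletons_equals_observed(self):
        assert chao1([5, 5, 5]) == pytest.approx(3.0)

    def test_direct_formula_evaluation(self):
        # S_obs=5, F1=2, F2=2: 5 + 2*1/(2*3)
        assert chao1([1, 1, 2, 2, 3]) == pytest.approx(5 + 2 / 6)

    def test_never_below_observed(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 10, size=30)
            s_obs = int((counts > 0).sum())
            if s_obs:
                assert chao1(counts) >= s_obs - 1e-9


class TestHellingerPCA:
    def test_identical_samples_identical_coordinates(self):
        counts = pd.DataFrame(
            [[10, 5, 5], [10, 5, 5], [1, 9, 10]],
            index=["a", "b", "c"], columns=["o1", "o2", "o3"],
        )
        result = hellinger_pca(OTUTable(counts=counts))
        np.testing.assert_allclose(
            result.coordinates.loc["a"], result.coordinates.loc["b"], atol=1e-12
        )

    def test_hellinger_rows_unit_norm(self, rng):
        table = _toy_table(rng)
        H = np.sqrt(table.relative_abundance().to_numpy())
        np.testing.assert_allclose((H**2).sum(axis=1), 1.0)

    def test_coordinates_preserve_hellinger_distances(self, rng):
        table = _toy_table(rng, n_samples=6, n_otus=40)
        H = np.sqrt(table.relative_abundance().to_numpy())
        expected = squareform(pdist(H))
        coords = hellinger_pca(table).coordinates.to_numpy()
        got = squareform(pdist(coords))
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_variance_fractions_sum_to_one(self, rng):
        result = hellinger_pca(_toy_table(rng))
        assert result.proportion_explained.sum() == pytest.approx(1.0)

    def test_zero_total_sample_rejected(self):
        counts = pd.DataFrame([[0, 0], [3, 4]], index=["a", "b"], columns=["o1", "o2"])
        with pytest.raises(ValueError, match="zero-total"):
            hellinger_pca(OTUTable(counts=counts))


def _design(n_per_group=3):
    labels = {}
    for i in range(n_per_group):
        labels[f"c{i}"] = "corn"
        labels[f"p{i}"] = "prairie"
    return GroupDesign(labels)


def _null_table(rng, n_otus, n_per_group=3, depth=2000) -> OTUTable:
    base = rng.dirichlet(np.ones(n_otus))
    samples = [f"c{i}" for i in range(n_per_group)] + [f"p{i}" for i in range(n_per_group)]
    counts = np.vstack([rng.multinomial(depth, base) for _ in samples])
    return OTUTable(
        counts=pd.DataFrame(counts, index=samples, columns=[f"o{j}" for j in range(n_otus)])
    )


class TestPerOTUFtest:
    def test_constant_otu_gives_null_result(self, rng):
        # identical rows: every OTU has zero variance and no effect
        row = rng.integers(1, 50, size=10)
        counts = pd.DataFrame(
            [row] * 6,
            index=[f"c{i}" for i in range(3)] + [f"p{i}" for i in range(3)],
            columns=[f"o{j}" for j in range(10)],
        )
        res = per_otu_ftest(OTUTable(counts=counts), _design()).set_index("otu")
        assert (res["F"] == 0.0).all()
        assert (res["p"] == 1.0).all()

    def test_planted_effect_detected_among_nulls(self, rng):
        # one OTU shifted 0.1 -> 0.5 in relative abundance among 50 nulls
        n_otus = 51
        samples = [f"c{i}" for i in range(3)] + [f"p{i}" for i in range(3)]
        rows = []
        for s in samples:
            rel = rng.dirichlet(np.ones(n_otus - 1)) * (
                0.9 if s.startswith("c") else 0.5
            )
            target = 0.1 if s.startswith("c") else 0.5
            target *= float(rng.normal(1.0, 0.05))
            rows.append(np.concatenate([[target], rel]))
        counts = np.rint(np.vstack(rows) * 20_000).astype(int)
        table = OTUTable(
            counts=pd.DataFrame(counts, index=samples,
                                columns=[f"o{j}" for j in range(n_otus)])
        )
        res = per_otu_ftest(table, _design(), fdr_q=0.05)
        best = res.sort_values("p").iloc[0]
        assert best["otu"] == "o0"
        assert bool(best["significant"])

    def test_adjusted_p_not_below_raw(self, rng):
        res = per_otu_ftest(_null_table(rng, 40), _design())
        assert (res["p_adj"] >= res["p"] - 1e-12).all()

    def test_null_false_discovery_rate_controlled(self):
        # exchangeable community profiles with no group effect: every
        # discovery is false, so mean FDP across replicates must stay <= q
        from gtamp.simulate import SimSpec, make_community

        q = 0.05
        fdps = []
        for rep in range(50):
            spec = SimSpec(n_samples=6, seed=1000 + rep)
            profiles, design = make_community(spec, n_otus=1000)
            counts = np.rint(profiles.to_numpy() * 1_000_000).astype(int)
            table = OTUTable(
                counts=pd.DataFrame(counts, index=profiles.index,
                                    columns=profiles.columns)
            )
            res = per_otu_ftest(table, design, fdr_q=q)
            fdps.append(1.0 if int(res["significant"].sum()) > 0 else 0.0)
        assert np.mean(fdps) <= q + 0.03

    def test_underreplicated_group_excluded(self, rng):
        table = _null_table(rng, 10)
        design = GroupDesign(
            {"c0": "corn", "c1": "corn", "p0": "prairie", "p1": "prairie", "p2": "lone"}
        )
        res = per_otu_ftest(table, design)  # 'lone' silently excluded, logged
        assert len(res) == 10
        with pytest.raises(ValueError, match=">= 2 groups"):
            per_otu_ftest(
                table,
                GroupDesign({"c0": "corn", "p0": "prairie", "p1": "x", "p2": "y"}),
            )
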