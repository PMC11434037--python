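import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from hypoximm import deconv as dc
from hypoximm import regions as reg
from hypoximm import simulate as sim
from hypoximm.scoring import score_rank_enrichment, tex_signature
from hypoximm.types import ExpressionMatrix, RegionAssignment, ScoreVector, SpatialSlide


def _slide(values, coords=None, kind="lognorm"):
    n = values.shape[1]
    if coords is None:
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    return SpatialSlide(
        expr=ExpressionMatrix(
            [f"g{i}" for i in range(values.shape[0])],
            [f"s{j}" for j in range(n)], values, kind,
        ),
        array_row=np.zeros(n, dtype=int), array_col=np.arange(n),
        px_x=coords[:, 0], px_y=coords[:, 1],
    )


class TestBuildReference:
    def test_disjoint_markers_block_structure(self):
        rng = np.random.default_rng(0)
        n_cells = 30
        vals = rng.poisson(1.0, size=(20, 2 * n_cells)).astype(float)
        vals[:10, :n_cells] += rng.poisson(50, size=(10, n_cells))
        vals[10:, n_cells:] += rng.poisson(50, size=(10, n_cells))
        expr = ExpressionMatrix([f"g{i}" for i in range(20)],
                                [f"c{i}" for i in range(2 * n_cells)], vals)
        labels = ["A"] * n_cells + ["B"] * n_cells
        ref = dc.build_reference(expr, labels, top_k=10)
        assert set(ref.markers["A"]) == {f"g{i}" for i in range(10)}
        assert set(ref.markers["B"]) == {f"g{i}" for i in range(10, 20)}

    def test_single_type_rejected(self):
        expr = ExpressionMatrix(["g0"], [f"c{i}" for i in range(20)],
                                np.ones((1, 20)))
        with pytest.raises(ValueError, match="2 distinct"):
            dc.build_reference(expr, ["A"] * 20)

    def test_small_type_named_in_error(self):
        expr = ExpressionMatrix(["g0", "g1"], [f"c{i}" for i in range(15)],
                                np.ones((2, 15)))
        with pytest.raises(ValueError, match="'B'"):
            dc.build_reference(expr, ["A"] * 12 + ["B"] * 3)

    def test_simulated_types_recover_program_markers(self):
        params = sim.SlideSimParams(seed=0)
        sc_expr, labels = dc_labels = sim.simulate_celltype_reference(params, seed=1)
        ref = dc.build_reference(sc_expr, labels)
        programs = params.program_genes
        assert ref.markers["malignant"][0] in programs["malignancy"]
        assert ref.markers["macrophage"][0] in programs["macrophage"]
        assert ref.markers["stromal"][0] in programs["stroma"]


class TestDeconvolveSpots:
    def _ref(self):
        genes = [f"g{i}" for i in range(8)]
        vals = np.zeros((8, 2))
        vals[:4, 0] = 10.0
        vals[4:, 1] = 10.0
        return dc.ReferenceSignatureMatrix(
            genes, ["A", "B"], vals,
            markers={"A": genes[:4], "B": genes[4:]},
        )

    def test_exact_mixture(self):
        ref = self._ref()
        w = np.array([0.3, 0.7])
        y = ref.values @ w
        slide = _slide(np.tile(y[:, None], (1, 3)))
        props = dc.deconvolve_spots(slide, ref)
        np.testing.assert_allclose(props.to_numpy(),
                                   np.tile(w, (3, 1)), atol=1e-9)

    def test_zero_spot_missing(self):
        ref = self._ref()
        vals = np.zeros((8, 2))
        vals[:, 1] = ref.values @ np.array([0.5, 0.5])
        props = dc.deconvolve_spots(_slide(vals), ref)
        assert props.iloc[0].isna().all()
        assert props.iloc[1].notna().all()

    def test_noisy_recovery(self):
        """3-type mixtures at (0.2, 0.3, 0.5) with 5% multiplicative noise
        recover within 0.05 mean absolute error."""
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(30)]
        S = np.zeros((30, 3))
        for t in range(3):
            S[t * 10:(t + 1) * 10, t] = rng.uniform(5, 15, size=10)
        ref = dc.ReferenceSignatureMatrix(
            genes, ["A", "B", "C"], S,
            markers={c: genes[i * 10:(i + 1) * 10]
                     for i, c in enumerate("ABC")},
        )
        w = np.array([0.2, 0.3, 0.5])
        mean = S @ w
        Y = mean[:, None] + rng.normal(0, 0.05 * mean[:, None], size=(30, 100))
        Y = np.clip(Y, 0, None)
        props = dc.deconvolve_spots(_slide(Y), ref)
        err = np.abs(props.to_numpy() - w).mean(axis=0)
        assert (err < 0.05).all()

    def test_exact_recovery_on_simulated_reference(self):
        """Noiseless mixtures of the built reference columns recover
        proportions to 1e-6."""
        params = sim.SlideSimParams(seed=2)
        sc_expr, labels = sim.simulate_celltype_reference(params, seed=3)
        ref = dc.build_reference(sc_expr, labels)
        rng = np.random.default_rng(4)
        W = rng.dirichlet(np.ones(len(ref.cell_type_ids)), size=20)
        Y = ref.values @ W.T
        slide = SpatialSlide(
            expr=ExpressionMatrix(ref.gene_ids,
                                  [f"s{j}" for j in range(20)], Y, "lognorm"),
            array_row=np.zeros(20, dtype=int), array_col=np.arange(20),
            px_x=np.arange(20, dtype=float), px_y=np.zeros(20),
        )
        props = dc.deconvolve_spots(slide, ref)
        np.testing.assert_allclose(props.to_numpy(), W, atol=1e-6)


class TestGates:
    def test_alcam_median_split(self):
        vals = np.ones((2, 4))
        vals[0] = [2, 7, 20, 55]  # strictly increasing normalized ALCAM
        slide = _slide(vals, kind="raw_counts")
        props = pd.DataFrame({"macrophage": [1.0, 1, 1, 1]},
                             index=slide.spot_ids)
        out = dc.gate_alcam_macrophages(slide, props, gene="g0")
        assert list(out) == ["alcam_low_mac", "alcam_low_mac",
                             "alcam_high_mac", "alcam_high_mac"]

    def test_no_mac_spots_all_none(self):
        slide = _slide(np.ones((2, 4)), kind="raw_counts")
        props = pd.DataFrame({"macrophage": [0.0, 0, 0, 0]},
                             index=slide.spot_ids)
        out = dc.gate_alcam_macrophages(slide, props, gene="g0")
        assert (out == "none").all()

    def test_missing_gene_raises(self):
        slide = _slide(np.ones((2, 4)), kind="raw_counts")
        props = pd.DataFrame({"macrophage": np.ones(4)}, index=slide.spot_ids)
        with pytest.raises(ValueError, match="ALCAM"):
            dc.gate_alcam_macrophages(slide, props, gene="ALCAM")

    def test_alcam_high_enriched_in_boundary(self, strong_slide):
        """Boundary-elevated ALCAM produces boundary-enriched ALCAM-high
        macrophage spots (odds ratio > 1, Fisher p < 0.05)."""
        params = sim.SlideSimParams.strong_separation(seed=1)
        sc_expr, labels = sim.simulate_celltype_reference(params, seed=2)
        ref = dc.build_reference(sc_expr, labels)
        props = dc.deconvolve_spots(strong_slide, ref)
        gates = dc.gate_alcam_macrophages(strong_slide, props)
        assign = RegionAssignment(
            strong_slide.spot_ids, strong_slide.truth_region,
            np.zeros(strong_slide.n_spots, dtype=int),
        )
        enr = dc.region_enrichment(gates, assign,
                                   positive_label="alcam_high_mac")
        assert enr.loc["Bdy", "obs_over_exp"] > 1
        assert enr.loc["Bdy", "fisher_p"] < 0.05

    def test_tex_spots_zero_expression_empty(self):
        rng = np.random.default_rng(0)
        markers = list(tex_signature()["TEX"])
        genes = [f"g{i}" for i in range(20)] + markers
        vals = rng.poisson(5.0, size=(len(genes), 12)).astype(float)
        vals[20:] = 0.0  # all Tex markers silent everywhere
        slide = SpatialSlide(
            expr=ExpressionMatrix(genes, [f"s{j}" for j in range(12)], vals),
            array_row=np.zeros(12, dtype=int), array_col=np.arange(12),
            px_x=np.arange(12, dtype=float), px_y=np.zeros(12),
        )
        assert dc.identify_tex_spots(slide, tex_signature()) == []


class TestColocalize:
    def _graph(self):
        # path graph s0 - s1 - s2 - s3
        return reg.NeighborGraph(
            [f"s{i}" for i in range(4)],
            [[1], [0, 2], [1, 3], [2]], 1.0,
        )

    def test_same_spot_colocalized(self):
        out = dc.colocalize(["s1"], ["s1"], self._graph())
        assert out.loc["s1", "flag"] == "colocalized"

    def test_first_outer_circle_colocalized(self):
        out = dc.colocalize(["s1"], ["s2"], self._graph())
        assert out.loc["s1", "flag"] == "colocalized"
        assert out.loc["s1", "partners"] == "s2"

    def test_two_edges_away_not_colocalized(self):
        out = dc.colocalize(["s0"], ["s2"], self._graph())
        assert out.loc["s0", "flag"] == "not_colocalized"

    def test_order_invariance(self):
        g = self._graph()
        a = dc.colocalize(["s0", "s3"], ["s1", "s2"], g)
        b = dc.colocalize(["s3", "s0"], ["s2", "s1"], g)
        assert dict(a["flag"]) == dict(b["flag"])


def rank_sum_exact_p(a, b):
    """Exhaustive-permutation two-sided rank-sum p-value (oracle)."""
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    n_a = len(a)
    obs = ranks[:n_a].sum()
    null = [sum(ranks[list(c)]) for c in
            itertools.combinations(range(len(pooled)), n_a)]
    null = np.asarray(null)
    mean = null.mean()
    return float(np.mean(np.abs(null - mean) >= abs(obs - mean) - 1e-9))


class TestExhaustionContrast:
    def _coloc_table(self, flags):
        return pd.DataFrame(
            {"flag": flags, "partners": ""},
            index=[f"s{i}" for i in range(len(flags))],
        )

    def test_identical_distributions_p_one(self):
        scores = ScoreVector([f"s{i}" for i in range(6)],
                             [1, 2, 3, 1, 2, 3], "TEX", "mean_scaled")
        out = dc.compare_colocalized_exhaustion(
            scores, self._coloc_table(["colocalized"] * 3
                                      + ["not_colocalized"] * 3))
        assert out["p_value"] == pytest.approx(1.0)

    def test_separated_groups_exact_p(self):
        scores = ScoreVector([f"s{i}" for i in range(6)],
                             [4, 5, 6, 1, 2, 3], "TEX", "mean_scaled")
        out = dc.compare_colocalized_exhaustion(
            scores, self._coloc_table(["colocalized"] * 3
                                      + ["not_colocalized"] * 3))
        assert out["p_value"] == pytest.approx(0.1)
        assert out["median_colocalized"] > out["median_not_colocalized"]

    def test_empty_group_raises(self):
        scores = ScoreVector([f"s{i}" for i in range(4)], [1, 2, 3, 4],
                             "TEX", "mean_scaled")
        with pytest.raises(ValueError, match="colocalized"):
            dc.compare_colocalized_exhaustion(
                scores, self._coloc_table(["colocalized"] * 4))

    def test_matches_permutation_oracle_small_groups(self):
        """Wilcoxon p equals exhaustive-permutation exact p on all two-group
        splits with total n <= 10 (tie-free draws)."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            n_a = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 6))
            pool = rng.permutation(20)[: n_a + n_b].astype(float)
            a, b = pool[:n_a], pool[n_a:]
            scores = ScoreVector(
                [f"s{i}" for i in range(n_a + n_b)],
                np.concatenate([a, b]), "TEX", "mean_scaled",
            )
            table = self._coloc_table(["colocalized"] * n_a
                                      + ["not_colocalized"] * n_b)
            got = dc.compare_colocalized_exhaustion(scores, table)["p_value"]
            assert got == pytest.approx(rank_sum_exact_p(a, b), abs=1e-9)


class TestRegionEnrichment:
    def _assign(self, labels):
        return RegionAssignment(
            [f"s{i}" for i in range(len(labels))],
            np.array(labels, dtype=object),
            np.zeros(len(labels), dtype=int),
        )

    def test_uniform_labels_ratio_one(self):
        labels = ["Mal"] * 20 + ["Bdy"] * 20 + ["nMal"] * 20
        flags = pd.Series(([True, False] * 30)[:60],
                          index=[f"s{i}" for i in range(60)])
        enr = dc.region_enrichment(flags, self._assign(labels))
        assert np.allclose(enr["obs_over_exp"], 1.0)
        assert (enr["fisher_p"] > 0.5).all()

    def test_all_labeled_in_bdy(self):
        labels = ["Mal"] * 10 + ["Bdy"] * 10 + ["nMal"] * 10
        flags = pd.Series([False] * 10 + [True] * 5 + [False] * 15,
                          index=[f"s{i}" for i in range(30)])
        enr = dc.region_enrichment(flags, self._assign(labels))
        # all 5 labeled spots in Bdy: obs/exp = (5/5)/(10/30) = 3
        assert enr.loc["Bdy", "obs_over_exp"] == pytest.approx(3.0)
        table = [[5, 0], [5, 20]]
        assert enr.loc["Bdy", "fisher_p"] == pytest.approx(
            scipy.stats.fisher_exact(table)[1])

    def test_empty_label_set(self):
        labels = ["Mal"] * 5 + ["Bdy"] * 5 + ["nMal"] * 5
        flags = pd.Series(False, index=[f"s{i}" for i in range(15)])
        enr = dc.region_enrichment(flags, self._assign(labels))
        assert (enr["obs_over_exp"] == 0).all()
        assert (enr["fisher_p"] == 1.0).all()
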