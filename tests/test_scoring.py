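"""Anchor regression, residual z-scoring and gene-pair aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_library
from pairscan.errors import DegenerateFitError, UserInputError
from pairscan.library import build_all_by_all_catalog
from pairscan.scoring import (
    AnchorFit,
    ScoringConfig,
    compute_base_lfc,
    fit_anchor_model,
    score_anchors,
    score_gene_pairs,
    score_lfc,
    score_screen,
    zscore_residuals,
)
from pairscan.simulate import SimConfig, expected_lfc_oracle, simulate_screen


def ols_closed_form(x, y):
    """Independent oracle: m = cov(x,y)/var(x), b = ybar - m*xbar."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xb, yb = x.mean(), y.mean()
    m = ((x - xb) * (y - yb)).sum() / ((x - xb) ** 2).sum()
    return m, yb - m * xb


class TestComputeBaseLfc:
    def test_constant_control_pairings(self, toy_library, toy_catalog):
        y = pd.Series(-1.0, index=toy_catalog.constructs["construct_id"])
        base = compute_base_lfc(y, toy_catalog, toy_library)
        assert base.base.loc["GENE1_sp1", "base_lfc"] == pytest.approx(-1.0)
        # 2 NT guides of the opposite ortholog in the toy library
        assert base.base.loc["GENE1_sp1", "n_control_partners"] == 2

    def test_mean_of_three_control_pairs(self):
        lib = make_library(n_genes=1, guides_per=1, n_nt=3)
        cat = build_all_by_all_catalog(lib)
        y = pd.Series(0.0, index=cat.constructs["construct_id"])
        for i, v in enumerate((0.5, 1.5, 1.0)):
            y[f"GENE1_sp1;NT_sa{i + 1}"] = v
        base = compute_base_lfc(y, cat, lib)
        assert base.base.loc["GENE1_sp1", "base_lfc"] == pytest.approx(1.0)

    def test_guide_without_control_pairing_omitted(self, toy_library, toy_catalog):
        c = toy_catalog.constructs
        keep = ~((c["sp_guide_id"] == "GENE1_sp1") & (c["sa_category"] == "non_targeting"))
        y = pd.Series(0.5, index=c.loc[keep, "construct_id"])
        base = compute_base_lfc(y, toy_catalog, toy_library)
        assert "GENE1_sp1" not in base.base.index

    def test_no_control_guides_is_an_error(self):
        lib = make_library(n_genes=2, guides_per=1, n_nt=1)
        cat = build_all_by_all_catalog(lib)
        y = pd.Series(0.0, index=cat.constructs["construct_id"])
        with pytest.raises(UserInputError):
            compute_base_lfc(y, cat, lib, control_categories=frozenset({"safe_harbor"}))

    def test_fig1_partner_count_design(self):
        # 14 NT per ortholog -> each guide has 14 control partners
        lib = make_library(n_genes=2, guides_per=2, n_nt=14)
        cat = build_all_by_all_catalog(lib)
        y = pd.Series(-1.0, index=cat.constructs["construct_id"])
        base = compute_base_lfc(y, cat, lib)
        assert (base.base["n_control_partners"] == 14).all()


class TestAnchorFit:
    def test_collinear_points(self):
        fit, resid = fit_anchor_model("a", [0, 1, 2], [1, 3, 5], min_points=3)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_hand_ols(self):
        fit, resid = fit_anchor_model("a", [0, 1, 2], [0, 0, 3], min_points=3)
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(-0.5)
        np.testing.assert_allclose(resid, [0.5, -1.0, 0.5], atol=1e-12)

    def test_zero_variance_regressor(self):
        with pytest.raises(DegenerateFitError, match="zero-variance"):
            fit_anchor_model("a", [1, 1, 1], [0, 1, 2], min_points=3)

    def test_min_points_enforced(self):
        with pytest.raises(DegenerateFitError, match="min_points"):
            fit_anchor_model("a", [0, 1, 2], [0, 0, 3], min_points=10)

    def test_residual_mean_is_zero_by_construction(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        fit, resid = fit_anchor_model("a", x, y, min_points=10)
        assert abs(resid.mean()) < 1e-9

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(0, 10_000))
    def test_matches_closed_form_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 30))
        x = r.normal(size=n)
        x[0] += 1e-3  # guard against an all-equal draw
        y = r.normal(size=n) + r.normal() * x
        fit, _ = fit_anchor_model("a", x, y, min_points=2)
        m, b = ols_closed_form(x, y)
        assert fit.slope == pytest.approx(m, abs=1e-9)
        assert fit.intercept == pytest.approx(b, abs=1e-9)


class TestZscoreResiduals:
    def fit(self, n):
        return AnchorFit("a", 1.0, 0.0, n, 0.0, 1.0)

    def test_hand_zscore(self):
        z, degen = zscore_residuals(self.fit(3), [0.5, -1.0, 0.5])
        np.testing.assert_allclose(z, [0.57735, -1.15470, 0.57735], atol=1e-5)
        assert not degen

    def test_two_point_zscore_sample_sd(self):
        z, _ = zscore_residuals(self.fit(2), [-1.0, 1.0])
        np.testing.assert_allclose(z, [-0.7071068, 0.7071068], atol=1e-6)

    def test_degenerate_all_equal(self):
        z, degen = zscore_residuals(self.fit(3), [0.3, 0.3, 0.3])
        assert degen
        np.testing.assert_array_equal(z, 0.0)

    def test_single_residual_rejected(self):
        with pytest.raises(DegenerateFitError):
            zscore_residuals(self.fit(1), [0.5])

    def test_mean_zero_sd_one_property(self, rng):
        resid = rng.normal(size=200)
        z, _ = zscore_residuals(self.fit(200), resid)
        assert abs(z.mean()) < 1e-9
        assert abs(np.std(z, ddof=1) - 1) < 1e-9


def make_z_table(z_value=-2.0, n_genes=2, guides=2):
    """Hand-built residual z table: every construct of the (A,B) pair has z=z_value
    in both anchor orientations."""
    lib = make_library(n_genes=n_genes, guides_per=guides, n_nt=2)
    cat = build_all_by_all_catalog(lib)
    c = cat.constructs
    gg = c[c["pair_class"] == "gene_gene"]
    rows = []
    for r in gg.itertuples():
        for anchor_gene, anchor, partner in (
            (r.sp_gene, r.sp_guide_id, r.sa_guide_id),
            (r.sa_gene, r.sa_guide_id, r.sp_guide_id),
        ):
            rows.append({
                "construct_id": r.construct_id, "anchor_guide_id": anchor,
                "partner_guide_id": partner, "anchor_gene": anchor_gene,
                "partner_gene": r.sa_gene if anchor_gene == r.sp_gene else r.sp_gene,
                "gene_pair": r.gene_pair, "pair_class": r.pair_class,
                "y": -1.0, "x": 0.0, "expected": 0.0, "residual": z_value,
                "z": z_value,
            })
    return pd.DataFrame(rows), cat


class TestGenePairAggregation:
    def test_eight_constructs_of_minus_two(self):
        z_table, cat = make_z_table(-2.0)
        scores = score_gene_pairs(z_table, cat)
        row = scores[scores["gene_pair"] == "GENE1;GENE2"].iloc[0]
        assert row["n_constructs"] == 8
        assert row["S_I"] == pytest.approx(-16 / np.sqrt(8))
        assert row["S_J"] == pytest.approx(-16 / np.sqrt(8))
        assert row["z_gene"] == pytest.approx(-8.0)

    def test_all_zero_null(self):
        z_table, cat = make_z_table(0.0)
        scores = score_gene_pairs(z_table, cat)
        assert (scores["z_gene"] == 0).all()

    def test_symmetric_under_gene_relabeling(self):
        z_table, cat = make_z_table(-2.0)
        swapped = z_table.copy()
        relabel = {"GENE1": "GENE2", "GENE2": "GENE1"}
        for col in ("anchor_gene", "partner_gene"):
            swapped[col] = swapped[col].map(relabel)
        s1 = score_gene_pairs(z_table, cat)
        s2 = score_gene_pairs(swapped, cat)
        a = s1[s1["gene_pair"] == "GENE1;GENE2"]["z_gene"].iloc[0]
        b = s2[s2["gene_pair"] == "GENE1;GENE2"]["z_gene"].iloc[0]
        assert a == b

    def test_single_orientation_flagged_asymmetric(self):
        z_table, cat = make_z_table(-2.0)
        one_sided = z_table[z_table["anchor_gene"] == "GENE1"]
        scores = score_gene_pairs(one_sided, cat)
        row = scores[scores["gene_pair"] == "GENE1;GENE2"].iloc[0]
        assert row["flags"] == "asymmetric"
        # all 8 constructs keep their GENE1-anchored z of -2: S = -16/sqrt(8)
        assert row["z_gene"] == pytest.approx(-16 / np.sqrt(8))


class TestEndToEnd:
    def test_noiseless_null_scores_are_zero(self):
        cfg = SimConfig(n_genes=6, seed=5, efficiency_concentration=None)
        lib, cat, cm, truth = simulate_screen(cfg)
        oracle = expected_lfc_oracle(truth)
        scores = score_lfc(oracle.values[cfg.condition], cat, lib,
                           ScoringConfig(min_anchor_partners=2))
        gg = scores[scores["flags"] == ""]
        assert (gg["z_gene"].abs() < 1e-6).all()

    def test_injected_interaction_is_minimum(self):
        cfg = SimConfig(n_genes=8, seed=5, interactions=(("G0002", "G0007", -0.05),))
        lib, cat, cm, truth = simulate_screen(cfg)
        oracle = expected_lfc_oracle(truth)
        scores = score_lfc(oracle.values[cfg.condition], cat, lib,
                           ScoringConfig(min_anchor_partners=2))
        gg = scores[scores["flags"] == ""]
        best = gg.loc[gg["z_gene"].idxmin()]
        assert best["gene_pair"] == "G0002;G0007"

    def test_determinism_bit_identical(self):
        cfg = SimConfig(n_genes=5, seed=9)
        lib, cat, cm, _ = simulate_screen(cfg)
        s1 = score_screen(cm, lib, cat)
        s2 = score_screen(cm, lib, cat)
        pd.testing.assert_frame_equal(s1.gene_scores, s2.gene_scores)

    def test_average_then_score_equals_score_of_preaveraged(self):
        cfg = SimConfig(n_genes=5, seed=4)
        lib, cat, cm, _ = simulate_screen(cfg)
        scored = score_screen(cm, lib, cat)  # averages replicates internally
        from pairscan.lfc import average_replicates, compute_lfc, counts_to_log2rpm

        lfc = average_replicates(compute_lfc(counts_to_log2rpm(cm), cm.samples))
        manual = score_lfc(lfc.values[cfg.condition], cat, lib, ScoringConfig())
        merged = scored.gene_scores.drop(columns="condition")
        pd.testing.assert_frame_equal(
            merged.reset_index(drop=True), manual.reset_index(drop=True))

    def test_within_anchor_z_mean_zero_sd_one(self):
        cfg = SimConfig(n_genes=10, seed=2)
        lib, cat, cm, _ = simulate_screen(cfg)
        scored = score_screen(cm, lib, cat)
        ztab = scored.z_tables[cfg.condition]
        stats_by_anchor = ztab.groupby("anchor_guide_id")["z"].agg(["mean", "std", "size"])
        ok = stats_by_anchor[stats_by_anchor["size"] >= 2]
        assert (ok["mean"].abs() < 1e-9).all()
        assert ((ok["std"] - 1).abs() < 1e-9).all()


def test_null_z_gene_centred_with_bounded_overdispersion():
    """Null gene scores are centred at 0; combining correlated orientations by
    1/sqrt(2) leaves sd(z_gene) above 1 (bounded by sqrt(2))."""
    cfg = SimConfig(n_genes=60, seed=13)
    lib, cat, cm, _ = simulate_screen(cfg)
    scored = score_screen(cm, lib, cat)
    g = scored.gene_scores
    z = g.loc[~g["flags"].str.contains("same_gene"), "z_gene"]
    assert abs(z.mean()) < 0.08
    assert 1.0 < z.std() < np.sqrt(2) * 1.05
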