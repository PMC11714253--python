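"""Marker signature scoring and the relative-cytotoxicity statistic."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fluxcyte.immunoscore import (
    CYTOTOXICITY_MARKERS,
    TCELL_MARKERS,
    MarkerSet,
    SignatureScorer,
    cytotoxicity_profile,
    group_by_expression,
    signature_score,
)


@pytest.fixture
def two_marker_expr():
    return pd.DataFrame(
        {"s1": [0.0, 0.0], "s2": [np.e - 1, 0.0]}, index=["g1", "g2"]
    )


class TestSignatureScore:
    def test_zero_expression_scores_zero(self, two_marker_expr):
        s = signature_score(two_marker_expr, MarkerSet("m", ("g1", "g2")))
        assert s["s1"] == 0.0

    def test_log1p_arithmetic(self, two_marker_expr):
        s = signature_score(two_marker_expr, MarkerSet("m", ("g1",)))
        assert s["s2"] == pytest.approx(1.0) and s["s1"] == 0.0

    def test_matches_mean_log1p_oracle(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.lognormal(1, 1, (4, 10)),
                            index=["a", "b", "c", "d"],
                            columns=[f"s{i}" for i in range(10)])
        s = signature_score(expr, MarkerSet("m", ("a", "c")))
        expected = (np.log1p(expr.loc["a"]) + np.log1p(expr.loc["c"])) / 2
        assert np.allclose(s, expected)

    def test_missing_markers_dropped_all_missing_raises(self, two_marker_expr):
        s = signature_score(two_marker_expr, MarkerSet("m", ("g1", "gX")))
        assert s["s2"] == pytest.approx(1.0)
        with pytest.raises(ValueError, match="no marker"):
            signature_score(two_marker_expr, MarkerSet("m", ("gX", "gY")))

    def test_default_marker_lists(self):
        assert TCELL_MARKERS.genes == (
            "CD3E", "CD2", "CD3G", "CD3D", "SIRPG", "CD6", "TIGIT"
        )
        assert CYTOTOXICITY_MARKERS.genes == (
            "CD8A", "SLA2", "NKG7", "PRF1", "GZMA", "GZMH"
        )

    def test_scale_change_monotone_and_rank_stable(self):
        # mean-of-log1p is exactly rank-invariant under global scaling for a
        # single marker (log1p is monotone); for multi-marker sets the
        # per-gene compression differs, so only near-invariance can hold
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.lognormal(1, 1, (3, 20)),
                            index=["a", "b", "c"],
                            columns=[f"s{i}" for i in range(20)])
        single = MarkerSet("m", ("a",))
        base = signature_score(expr, single)
        scaled = signature_score(expr * 7.3, single)
        assert (base.rank() == scaled.rank()).all()
        assert (scaled >= base).all()  # monotone increase with scale
        multi = MarkerSet("m", ("a", "b"))
        rho = signature_score(expr, multi).rank().corr(
            signature_score(expr * 7.3, multi).rank()
        )
        assert rho > 0.95

    def test_transformer_interface(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.lognormal(1, 1, (len(TCELL_MARKERS.genes), 5)),
                            index=TCELL_MARKERS.genes,
                            columns=[f"s{i}" for i in range(5)])
        scorer = SignatureScorer(TCELL_MARKERS).fit(expr.T)
        out = scorer.transform(expr.T)
        assert out.shape == (5, 1)
        assert scorer.missing_markers_ == []


class TestCytotoxicityProfile:
    def test_zero_cytotoxic_score_gives_zero_ratio(self):
        expr = pd.DataFrame(
            {"s1": [5.0, 0.0], "s2": [2.0, 0.0]}, index=["CD3E", "CD8A"]
        )
        prof = cytotoxicity_profile(expr)
        assert (prof["relative_cytotoxicity"] == 0).all()

    def test_equal_scores_give_unit_ratio(self):
        expr = pd.DataFrame({"s1": [3.0, 3.0]}, index=["CD3E", "CD8A"])
        prof = cytotoxicity_profile(expr)
        assert prof.loc["s1", "relative_cytotoxicity"] == pytest.approx(1.0)

    def test_below_floor_abundance_is_undefined(self):
        expr = pd.DataFrame({"s1": [0.0, 4.0]}, index=["CD3E", "CD8A"])
        prof = cytotoxicity_profile(expr)
        assert np.isnan(prof.loc["s1", "relative_cytotoxicity"])

    def test_ratio_nonnegative_where_defined(self):
        rng = np.random.default_rng(2)
        genes = list(TCELL_MARKERS.genes) + list(CYTOTOXICITY_MARKERS.genes)
        expr = pd.DataFrame(rng.lognormal(0, 1, (len(genes), 30)),
                            index=genes, columns=[f"s{i}" for i in range(30)])
        prof = cytotoxicity_profile(expr)
        defined = prof["relative_cytotoxicity"].dropna()
        assert (defined >= 0).all()

    def test_planted_high_low_groups_recovered(self):
        # group A: cytotoxic markers 4x group B at equal T-cell abundance
        rng = np.random.default_rng(3)
        n = 50
        genes = list(TCELL_MARKERS.genes) + list(CYTOTOXICITY_MARKERS.genes)
        cols = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        rows = []
        for g in TCELL_MARKERS.genes:
            rows.append(rng.lognormal(1, 0.3, 2 * n))
        for g in CYTOTOXICITY_MARKERS.genes:
            base = rng.lognormal(1, 0.3, 2 * n)
            base[:n] *= 4.0
            rows.append(base)
        expr = pd.DataFrame(rows, index=genes, columns=cols)
        prof = cytotoxicity_profile(expr)
        a = prof.loc[[c for c in cols if c.startswith("a")], "relative_cytotoxicity"]
        b = prof.loc[[c for c in cols if c.startswith("b")], "relative_cytotoxicity"]
        assert a.mean() > b.mean()
        p = stats.mannwhitneyu(a, b, alternative="greater").pvalue
        assert p < 0.01


class TestGroupByExpression:
    def test_fraction_sizes(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame([rng.normal(size=10) + 10], index=["GLS"],
                            columns=[f"s{i}" for i in range(10)])
        top, bottom = group_by_expression(expr, "GLS", 0.4, 0.4)
        assert len(top) == 4 and len(bottom) == 4
        assert not set(top) & set(bottom)

    def test_cohort_sized_split(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame([rng.normal(size=505) + 10], index=["GLS"],
                            columns=[f"s{i}" for i in range(505)])
        top, bottom = group_by_expression(expr, "GLS", 0.4, 0.4)
        assert len(top) == 202 and len(bottom) == 202

    def test_ties_resolved_by_stable_order(self):
        expr = pd.DataFrame([[1.0] * 10], index=["g"],
                            columns=[f"s{i}" for i in range(10)])
        top, bottom = group_by_expression(expr, "g", 0.4, 0.4)
        assert len(top) == 4 and len(bottom) == 4
        assert top == [f"s{i}" for i in range(4)]

    def test_absent_gene_rejected(self):
        expr = pd.DataFrame([[1.0]], index=["g"], columns=["s"])
        with pytest.raises(KeyError):
            group_by_expression(expr, "nope")

    def test_bad_fractions_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["s1", "s2"])
        with pytest.raises(ValueError):
            group_by_expression(expr, "g", 0.7, 0.7)
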