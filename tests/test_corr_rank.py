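"""Pearson machinery and cross-cohort feature ranking."""
import numpy as np
import pandas as pd
import pytest

from fluxcyte.corr_rank import (
    Cohort,
    flux_effector_correlation,
    pearson,
    rank_features,
)
from fluxcyte.immunoscore import CYTOTOXICITY_MARKERS, TCELL_MARKERS


def pearson_oracle(x, y):
    """Independent covariance/variance implementation of the coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


def _cohort(name, rng, n=30, planted_slope=0.0, extra=None):
    """Synthetic cohort whose PLANTED gene tracks -slope * latent cytotoxicity."""
    samples = [f"{name}_s{i}" for i in range(n)]
    abundance = rng.lognormal(1, 0.4, n)
    rel = rng.lognormal(0, 0.5, n)
    rows, idx = [], []
    for g in TCELL_MARKERS.genes:
        rows.append(abundance * rng.lognormal(0, 0.1, n))
        idx.append(g)
    for g in CYTOTOXICITY_MARKERS.genes:
        rows.append(abundance * rel * rng.lognormal(0, 0.1, n))
        idx.append(g)
    z = (np.log(rel) - np.log(rel).mean()) / np.log(rel).std()
    rows.append(np.exp(1.0 + planted_slope * z + rng.normal(0, 0.1, n)))
    idx.append("PLANTED")
    for g, vals in (extra or {}).items():
        rows.append(vals)
        idx.append(g)
    expr = pd.DataFrame(rows, index=idx, columns=samples)
    return Cohort.from_expression(name, expr)


class TestPearson:
    def test_affine_relation_is_one(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        x = np.arange(5.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_textbook_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        assert pearson(x, y) == pytest.approx(0.8)

    def test_constant_vector_gives_missing_not_error(self):
        assert np.isnan(pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_pairwise_missing_removal(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 9.0, 8.0, 10.0]
        assert pearson(x, y) == pytest.approx(1.0)

    def test_fewer_than_three_pairs_is_missing(self):
        assert np.isnan(pearson([1.0, 2.0], [3.0, 4.0]))

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            assert pearson(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-12)


class TestRankFeatures:
    def test_single_cohort_average_equals_cohort_pcc(self):
        rng = np.random.default_rng(1)
        c = _cohort("c1", rng, planted_slope=-1.0)
        table = rank_features([c], ["PLANTED"])
        assert table.loc["PLANTED", "avg_pcc"] == pytest.approx(
            table.loc["PLANTED", "c1"]
        )

    def test_planted_anticorrelated_gene_ranks_first(self):
        rng = np.random.default_rng(2)
        cohorts = [_cohort(f"c{i}", rng, n=100, planted_slope=-2.0) for i in range(9)]
        features = ["PLANTED"] + list(TCELL_MARKERS.genes) + list(CYTOTOXICITY_MARKERS.genes)
        table = rank_features(cohorts, features)
        assert table.loc["PLANTED", "rank"] == 1
        assert table.loc["PLANTED", "avg_pcc"] < 0

    def test_missing_cohorts_average_over_defined_only(self):
        rng = np.random.default_rng(3)
        with_gene = [_cohort(f"a{i}", rng, extra={"EXTRA": rng.lognormal(0, 1, 30)})
                     for i in range(2)]
        without = [_cohort(f"b{i}", rng) for i in range(3)]
        table = rank_features(with_gene + without, ["EXTRA"])
        vals = table.loc["EXTRA", [c.name for c in with_gene]]
        assert table.loc["EXTRA", "avg_pcc"] == pytest.approx(vals.mean())
        assert table.loc["EXTRA", [c.name for c in without]].isna().all()

    def test_unmeasured_feature_emits_all_missing_row(self):
        rng = np.random.default_rng(4)
        table = rank_features([_cohort("c1", rng)], ["NOT_A_GENE"])
        assert table.loc["NOT_A_GENE"].drop("rank").isna().all()

    def test_invariant_to_cohort_order_and_sample_permutation(self):
        rng = np.random.default_rng(5)
        cohorts = [_cohort(f"c{i}", rng, planted_slope=-1.0) for i in range(3)]
        t1 = rank_features(cohorts, ["PLANTED", "CD8A"])
        shuffled = []
        perm_rng = np.random.default_rng(0)
        for c in cohorts[::-1]:
            cols = list(c.expr.columns)
            perm = perm_rng.permutation(cols)
            shuffled.append(Cohort(c.name, c.expr[perm], c.profile.loc[perm]))
        t2 = rank_features(shuffled, ["PLANTED", "CD8A"])
        assert np.allclose(
            t1["avg_pcc"].sort_index(), t2["avg_pcc"].sort_index(), equal_nan=True
        )
        assert (t1["rank"].sort_index() == t2["rank"].sort_index()).all()

    def test_rank_is_permutation_with_lexicographic_ties(self):
        prof = pd.DataFrame({"cd8_abundance": [1.0] * 6, "cytotoxic_level": [1.0] * 6,
                             "relative_cytotoxicity": np.linspace(0.5, 2.0, 6)},
                            index=[f"s{i}" for i in range(6)])
        expr = pd.DataFrame(
            [np.linspace(2.0, 0.5, 6), np.linspace(2.0, 0.5, 6)],
            index=["B_GENE", "A_GENE"], columns=prof.index,
        )
        table = rank_features([Cohort("c", expr, prof)], ["B_GENE", "A_GENE"])
        assert table.loc["A_GENE", "rank"] == 1  # tie broken lexicographically
        assert sorted(table["rank"]) == [1, 2]


class TestFluxEffector:
    def test_identical_series_correlates_perfectly(self):
        samples = [f"s{i}" for i in range(10)]
        vals = np.linspace(1, 5, 10)
        flux = pd.DataFrame({"M27": vals}, index=samples)
        expr = pd.DataFrame([vals], index=["GZMA"], columns=samples)
        out = flux_effector_correlation(flux, expr, ["GZMA"])
        assert out.loc["M27", "GZMA"] == pytest.approx(1.0)

    def test_absent_effector_gene_yields_missing_column(self):
        samples = [f"s{i}" for i in range(5)]
        flux = pd.DataFrame({"M27": np.arange(5.0)}, index=samples)
        expr = pd.DataFrame([np.arange(5.0)], index=["GZMA"], columns=samples)
        out = flux_effector_correlation(flux, expr, ["GZMA", "TNF"])
        assert out["TNF"].isna().all()
        assert out.loc["M27", "GZMA"] == pytest.approx(1.0)

    def test_no_shared_samples_rejected(self):
        flux = pd.DataFrame({"M27": [1.0, 2.0]}, index=["a", "b"])
        expr = pd.DataFrame([[1.0, 2.0]], index=["GZMA"], columns=["x", "y"])
        with pytest.raises(ValueError, match="shared samples"):
            flux_effector_correlation(flux, expr)

    def test_planted_negative_coupling_detected(self):
        rng = np.random.default_rng(8)
        n = 200
        samples = [f"s{i}" for i in range(n)]
        signal = rng.lognormal(0, 0.5, n)
        flux = pd.DataFrame({"M27": -0.8 * signal + rng.normal(0, 0.2, n) + 10},
                            index=samples)
        rows = [signal * rng.lognormal(0, 0.1, n) for _ in range(4)]
        expr = pd.DataFrame(rows, index=["GZMA", "TNF", "IFNG", "PRF1"],
                            columns=samples)
        out = flux_effector_correlation(flux, expr)
        assert (out.loc["M27"] < 0).all()
        assert (out.loc["M27"].abs() >= 0.5).all()
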