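import itertools
import math

import numpy as np
import pandas as pd
import pytest

import mtcexpr as m
from mtcexpr.qpcr import bonferroni, genorm_stepwise_ranking

CONTRAST = ("MEN2A-like", "MEN2B-like")


def exact_mann_whitney_p(a, b):
    """Two-sided p by full enumeration of label assignments (no ties)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    dist = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        grp = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        dist.append(sum(1 for x in grp for y in rest if x > y))
    dist = np.asarray(dist, float)
    p = 2 * min((dist <= u_obs).mean(), (dist >= u_obs).mean())
    return min(1.0, p)


class TestStandardCurve:
    def test_perfect_doubling_series(self):
        """2-fold dilutions with one extra Cq per step: slope = -1/log10(2)."""
        quantities = [2.0 ** (-d) for d in range(8)]
        cq = [20.0 + d for d in range(8)]
        fit = m.fit_standard_curve(quantities, cq, gene="NNAT")
        assert fit.slope == pytest.approx(-3.3219, abs=1e-4)
        assert fit.efficiency == pytest.approx(1.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_efficiency_from_slope(self):
        fit = m.StandardCurveFit(gene="X", slope=-3.6, intercept=20, r_squared=1.0)
        assert fit.efficiency == pytest.approx(10 ** (1 / 3.6) - 1, abs=1e-9)
        assert fit.efficiency == pytest.approx(0.8957, abs=1e-4)

    def test_noisy_series_reports_r_squared_below_one(self):
        rng = np.random.default_rng(0)
        quantities = [10.0 ** (-d) for d in range(8)]
        cq = [20 + 3.32 * d + rng.normal(0, 0.3) for d in range(8)]
        fit = m.fit_standard_curve(quantities, cq)
        assert 0.9 < fit.r_squared < 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            m.fit_standard_curve([1.0, 1.0, 1.0], [20, 21, 22])
        with pytest.raises(ValueError):
            m.fit_standard_curve([1.0, 0.5], [20, 21])
        with pytest.raises(ValueError):
            m.fit_standard_curve([1.0, -0.5, 0.25], [20, 21, 22])


class TestRelativeQuantity:
    def test_anchor_points(self):
        curve = m.StandardCurveFit(gene="X", slope=-3.5, intercept=22.0,
                                   r_squared=1.0)
        assert m.relative_quantity(22.0, curve) == pytest.approx(1.0)
        # one slope-unit above the intercept corresponds to a 10-fold dilution
        assert m.relative_quantity(22.0 + 3.5, curve) == pytest.approx(0.1)

    def test_round_trip_inverse(self):
        curve = m.StandardCurveFit(gene="X", slope=-3.321928, intercept=24.0,
                                   r_squared=1.0)
        q = np.array([0.01, 0.1, 1.0, 7.3])
        cq = curve.intercept + curve.slope * np.log10(q)
        assert np.allclose(m.relative_quantity(cq, curve), q)

    def test_zero_slope_rejected(self):
        curve = m.StandardCurveFit(gene="X", slope=0.0, intercept=20,
                                   r_squared=1.0)
        with pytest.raises(ValueError):
            m.relative_quantity(20.0, curve)


class TestGeNorm:
    def test_proportional_references_have_zero_m(self):
        q = pd.DataFrame({"g1": [1.0, 2.0, 4.0, 8.0],
                          "g2": [3.0, 6.0, 12.0, 24.0]},
                         index=list("abcd"))
        res = m.genorm_stability(q)
        assert np.allclose(res.stability, 0.0)

    def test_hand_computed_three_by_four_grid(self):
        """g1 and g2 proportional, g3 constant: the only varying log2 ratios
        are g1/g3 and g2/g3 = [0,1,2,3], whose sample SD is sqrt(5/3)."""
        q = pd.DataFrame({"g1": [1.0, 2.0, 4.0, 8.0],
                          "g2": [2.0, 4.0, 8.0, 16.0],
                          "g3": [1.0, 1.0, 1.0, 1.0]},
                         index=list("abcd"))
        res = m.genorm_stability(q)
        sd = math.sqrt(5.0 / 3.0)
        assert res.stability["g1"] == pytest.approx(sd / 2, abs=1e-12)
        assert res.stability["g2"] == pytest.approx(sd / 2, abs=1e-12)
        assert res.stability["g3"] == pytest.approx(sd, abs=1e-12)
        assert res.ranking[-1] == "g3"
        # NF is the per-sample geometric mean
        assert res.normalization_factor["a"] == pytest.approx((1 * 2 * 1) ** (1 / 3))
        assert res.normalization_factor["d"] == pytest.approx((8 * 16 * 1) ** (1 / 3))

    def test_sample_rescaling_equivariance(self, qpcr_dataset):
        refs = (
            qpcr_dataset.records.groupby(["sample_id", "gene"])["cq"].mean()
            .unstack()[qpcr_dataset.reference_genes]
        )
        q = 2.0 ** (-refs)  # any monotone positive transform will do here
        base = m.genorm_stability(q)
        scaled = q.copy()
        scaled.iloc[0] *= 7.5
        res = m.genorm_stability(scaled)
        assert np.allclose(res.stability, base.stability)
        assert res.normalization_factor.iloc[0] == pytest.approx(
            7.5 * base.normalization_factor.iloc[0]
        )
        assert np.allclose(res.normalization_factor.iloc[1:],
                           base.normalization_factor.iloc[1:])

    def test_reference_order_invariance(self):
        rng = np.random.default_rng(3)
        q = pd.DataFrame(2.0 ** rng.normal(0, 1, (6, 3)),
                         columns=["g1", "g2", "g3"])
        a = m.genorm_stability(q)
        b = m.genorm_stability(q[["g3", "g1", "g2"]])
        assert np.allclose(a.normalization_factor, b.normalization_factor)
        for g in ("g1", "g2", "g3"):
            assert a.stability[g] == pytest.approx(b.stability[g])

    def test_stepwise_ranking_drops_unstable_first(self):
        rng = np.random.default_rng(5)
        loading = 2.0 ** rng.normal(0, 1, 10)
        q = pd.DataFrame({
            "stable1": loading * 2 ** rng.normal(0, 0.02, 10),
            "stable2": 3 * loading * 2 ** rng.normal(0, 0.02, 10),
            "wild": loading * 2 ** rng.normal(0, 1.5, 10),
        })
        ranking = genorm_stepwise_ranking(q)
        assert ranking[0] == "wild"

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            m.genorm_stability(pd.DataFrame({"g1": [1.0, 2.0, 3.0]}))
        with pytest.raises(ValueError):
            m.genorm_stability(pd.DataFrame({"g1": [1.0, -2.0, 3.0],
                                             "g2": [1.0, 2.0, 3.0]}))


class TestMannWhitney:
    def test_hand_enumerated_example(self):
        """{1,2,3} vs {4,5,6}: U = 0 and the exact two-sided p is
        2/20 = 0.1 over the 20 equally likely arrangements."""
        u, p = m.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(m_, n_) for m_ in range(3, 7)
                                       for n_ in range(m_, 7)])
    def test_matches_enumeration_up_to_six_per_group(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(3):
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.8, 1, n2)
            _, p = m.mann_whitney(a, b)
            assert p == pytest.approx(exact_mann_whitney_p(a, b), abs=1e-12)

    def test_all_tied_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            _, p = m.mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_bonferroni_bounds(self):
        assert bonferroni(0.004, 9) == pytest.approx(0.036)
        assert bonferroni(0.5, 9) == 1.0
        assert bonferroni(1.0, 1) == 1.0
        with pytest.raises(ValueError):
            bonferroni(0.0, 9)


class TestValidateGenes:
    def test_identical_groups_are_null(self):
        ann = pd.DataFrame(
            {"mutation_class": ["MEN2A-like"] * 4 + ["MEN2B-like"] * 4},
            index=[f"s{i}" for i in range(8)],
        )
        q = pd.DataFrame({"g": [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]},
                         index=ann.index)
        nf = pd.Series(1.0, index=ann.index)
        with pytest.warns(UserWarning):
            # tied across groups -> tie-corrected path
            table = m.validate_genes(q * 0 + 2.0, nf, ann, CONTRAST)
        assert table.loc["g", "p_value"] == 1.0
        table = m.validate_genes(q, nf, ann, CONTRAST)
        assert table.loc["g", "fold_change"] == pytest.approx(1.0)
        assert table.loc["g", "p_value"] == 1.0

    def test_normalisation_divides_by_factor(self):
        ann = pd.DataFrame(
            {"mutation_class": ["MEN2A-like"] * 3 + ["MEN2B-like"] * 3},
            index=[f"s{i}" for i in range(6)],
        )
        # raw quantities differ only through loading; NF removes it entirely
        nf = pd.Series([1.0, 2.0, 4.0, 1.0, 2.0, 4.0], index=ann.index)
        q = pd.DataFrame({"g": 5.0 * nf})
        with pytest.warns(UserWarning):  # perfectly normalised -> all tied
            table = m.validate_genes(q, nf, ann, CONTRAST, n_tests=1)
        assert table.loc["g", "fold_change"] == pytest.approx(1.0)

    def test_small_groups_rejected(self):
        ann = pd.DataFrame({"mutation_class": ["MEN2A-like"] * 2
                            + ["MEN2B-like"] * 4},
                           index=[f"s{i}" for i in range(6)])
        q = pd.DataFrame({"g": np.arange(6.0) + 1}, index=ann.index)
        with pytest.raises(ValueError):
            m.validate_genes(q, pd.Series(1.0, index=ann.index), ann, CONTRAST)


class TestValidationPipeline:
    def test_planted_gene_significant_at_study_size(self, qpcr_dataset):
        res = m.QPCRValidation(qpcr_dataset, CONTRAST).fit()
        table = res.table
        assert table.loc["NNAT", "fold_change"] > 1.5
        assert table.loc["NNAT", "bonferroni_p"] < 0.05
        # Bonferroni uses the 9-gene family and never shrinks p
        assert (table["bonferroni_p"] >= table["p_value"]).all()
        assert (table["bonferroni_p"] <= 1.0).all()

    def test_planted_fold_changes_recovered_at_adequate_n(self):
        """With enough samples per class the group-mean ratio of normalised
        quantities recovers the planted fold changes within 20%."""
        cfg = m.QPCRSimConfig(
            class_sizes=(("MEN2A-like", 60), ("MEN2B-like", 60)), seed=21
        )
        res = m.QPCRValidation(m.generate_qpcr_dataset(cfg), CONTRAST).fit()
        assert res.table.loc["NNAT", "fold_change"] == pytest.approx(3.3, rel=0.2)
        assert res.table.loc["CDC14B", "fold_change"] == pytest.approx(2.8, rel=0.2)
        assert res.significant().index.isin(["NNAT", "CDC14B"]).all()

    def test_reference_genes_are_stable(self, qpcr_dataset):
        res = m.QPCRValidation(qpcr_dataset, CONTRAST).fit()
        assert (res.genorm.stability < 0.5).all()
        for curve in res.standard_curves.values():
            assert curve.efficiency == pytest.approx(1.0, abs=0.05)

    def test_missing_reference_records_rejected(self, qpcr_dataset):
        records = qpcr_dataset.records
        trimmed = records[~((records["sample_id"] == "VAL001")
                            & (records["gene"] == "HADHA"))]
        with pytest.raises(ValueError, match="VAL001"):
            m.QPCRDataset(trimmed, qpcr_dataset.standard_curves,
                          qpcr_dataset.reference_genes, qpcr_dataset.annotation)

    def test_fewer_than_two_references_rejected(self, qpcr_dataset):
        with pytest.raises(ValueError):
            m.QPCRDataset(qpcr_dataset.records, qpcr_dataset.standard_curves,
                          ["EIF3S10"], qpcr_dataset.annotation)
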