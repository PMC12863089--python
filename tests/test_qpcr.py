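"""Standard curves, Pfaffl ratios, absolute proxies and group tests."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import PLANTED_FOLDS
from halopha import synthetic_data as sd
from halopha.qpcr_expression import (
    StandardCurve,
    absolute_quantity,
    collapse_technical,
    compare_conditions,
    fit_all_curves,
    fit_standard_curve,
    pfaffl_ratio,
    reference_normalization_factor,
)


class TestStandardCurve:
    def test_ideal_slope_gives_efficiency_two(self):
        series = [(2.0, 20.0), (1.0, 23.3219), (0.0, 26.6438)]
        curve = fit_standard_curve(series, "g")
        assert curve.slope == pytest.approx(-3.3219, abs=1e-4)
        assert curve.efficiency == pytest.approx(2.000, abs=1e-4)

    def test_planted_efficiency_recovered_noise_free(self):
        spec = sd.QpcrSimSpec(efficiencies={"phaC1": 1.9}, seed=0)
        _, dil, _ = sd.generate_qpcr_dataset(spec)
        curves = fit_all_curves(dil)
        assert curves["phaC1"].efficiency == pytest.approx(1.900, abs=1e-6)
        assert curves["phaC1"].r_squared == pytest.approx(1.0, abs=1e-9)
        assert curves["tbp"].efficiency == pytest.approx(2.0, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_standard_curve([(0.0, 20.0), (0.0, 20.1)], "g")

    def test_efficiency_qc_warning(self):
        series = [(2.0, 20.0), (1.0, 22.0), (0.0, 24.0)]  # E = 10^(1/2) ≈ 3.16
        with pytest.warns(UserWarning, match="efficiency"):
            fit_standard_curve(series, "g")


class TestCollapseTechnical:
    def test_mean_of_technical_replicates(self):
        df = pd.DataFrame({
            "gene": ["g"] * 2, "condition": ["c"] * 2,
            "bio_rep": [1, 1], "tech_rep": [1, 2], "ct": [20.0, 20.2],
        })
        out = collapse_technical(df)
        assert out["ct"].tolist() == [pytest.approx(20.1)]

    def test_single_replicate_identity(self):
        df = pd.DataFrame({"gene": ["g"], "condition": ["c"],
                           "bio_rep": [1], "tech_rep": [1], "ct": [21.5]})
        assert collapse_technical(df)["ct"].tolist() == [21.5]

    def test_divergent_replicates_warn(self):
        df = pd.DataFrame({
            "gene": ["g"] * 2, "condition": ["c"] * 2,
            "bio_rep": [1, 1], "tech_rep": [1, 2], "ct": [20.0, 21.0],
        })
        with pytest.warns(UserWarning, match="diverge"):
            out = collapse_technical(df)
        assert out["ct"].tolist() == [pytest.approx(20.5)]


class TestNormalizationFactor:
    def test_geometric_mean(self):
        assert reference_normalization_factor({"tbp": 4.0, "ffs": 9.0}) == pytest.approx(6.0)

    def test_single_reference_identity(self):
        assert reference_normalization_factor({"tbp": 5.0}) == 5.0

    def test_order_invariant(self):
        a = reference_normalization_factor({"x": 2.0, "y": 8.0, "z": 4.0})
        b = reference_normalization_factor({"z": 4.0, "x": 2.0, "y": 8.0})
        assert a == b

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            reference_normalization_factor({"tbp": 0.0})


def _ct_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "condition", "bio_rep",
                                       "tech_rep", "ct"])


class TestPfaffl:
    def test_closed_form(self):
        # dCt_t = 3, dCt_r = 1, E = 2 everywhere -> R = 2^3 / 2^1 = 4
        rows = []
        for bio in (1, 2):
            rows += [("t", "ctrl", bio, 1, 25.0), ("t", "samp", bio, 1, 22.0),
                     ("r", "ctrl", bio, 1, 20.0), ("r", "samp", bio, 1, 19.0)]
        cmp_res = pfaffl_ratio(_ct_frame(rows), "t", ["r"],
                               {"t": 2.0, "r": 2.0}, "ctrl", "samp")
        assert cmp_res.ratio == pytest.approx(4.0)

    def test_null_case(self):
        rows = []
        for bio in (1, 2):
            rows += [("t", "ctrl", bio, 1, 25.0), ("t", "samp", bio, 1, 25.0),
                     ("r", "ctrl", bio, 1, 20.0), ("r", "samp", bio, 1, 20.0)]
        cmp_res = pfaffl_ratio(_ct_frame(rows), "t", ["r"],
                               {"t": 2.0, "r": 2.0}, "ctrl", "samp")
        assert cmp_res.ratio == 1.0
        assert cmp_res.p_value == 1.0

    def test_equivalent_to_ddct_when_e_is_two(self):
        """With all efficiencies exactly 2 the Pfaffl ratio equals 2^ΔΔCt."""
        rng = np.random.default_rng(4)
        rows = []
        cts = {}
        for gene in ("t", "r"):
            for cond in ("ctrl", "samp"):
                for bio in (1, 2, 3):
                    ct = float(rng.uniform(18, 30))
                    cts[(gene, cond, bio)] = ct
                    rows.append((gene, cond, bio, 1, ct))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pfaffl_ratio(_ct_frame(rows), "t", ["r"],
                               {"t": 2.0, "r": 2.0}, "ctrl", "samp")
        mean = lambda g, c: np.mean([cts[(g, c, b)] for b in (1, 2, 3)])
        ddct = (mean("t", "ctrl") - mean("t", "samp")) - \
               (mean("r", "ctrl") - mean("r", "samp"))
        assert res.ratio == pytest.approx(2.0 ** ddct, rel=1e-12)

    def test_planted_fold_changes_recovered_exactly(self, qpcr_noise_free):
        """Full chain (standard curves -> efficiencies -> dual-reference
        Pfaffl) returns the planted stationary/mid-exponential ratios."""
        spec, (ct, dil, _) = qpcr_noise_free
        curves = fit_all_curves(dil)
        for (gene, sample, control), fold in PLANTED_FOLDS.items():
            res = pfaffl_ratio(ct, gene, list(spec.reference_genes), curves,
                               control, sample)
            assert res.ratio == pytest.approx(fold, rel=1e-4)
            assert res.ratio_sd == pytest.approx(0.0, abs=1e-6)

    def test_plate_offset_invariance(self):
        """A uniform Ct shift on one condition cancels out of the ratio
        (exact when target and reference share an efficiency: the shift
        enters both the numerator and the normalisation factor)."""
        rows, shifted = [], []
        rng = np.random.default_rng(8)
        for gene in ("t", "r"):
            for cond in ("ctrl", "samp"):
                for bio in (1, 2, 3):
                    ct = float(rng.uniform(18, 30))
                    rows.append((gene, cond, bio, 1, ct))
                    shifted.append((gene, cond, bio, 1,
                                    ct + (1.7 if cond == "samp" else 0.0)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = pfaffl_ratio(_ct_frame(rows), "t", ["r"],
                                {"t": 1.95, "r": 1.95}, "ctrl", "samp")
            moved = pfaffl_ratio(_ct_frame(shifted), "t", ["r"],
                                 {"t": 1.95, "r": 1.95}, "ctrl", "samp")
        assert moved.ratio == pytest.approx(base.ratio, rel=1e-12)

    def test_missing_condition_is_an_error(self, qpcr_noise_free):
        spec, (ct, dil, _) = qpcr_noise_free
        with pytest.raises(ValueError, match="no Ct data"):
            pfaffl_ratio(ct, "phaC1", ["tbp"], fit_all_curves(dil),
                         "nonexistent", "stationary")

    def test_noisy_recovery_within_ten_percent_median(self):
        """ct noise sd 0.1, n_bio = 3: median relative ratio error < 10%
        across 200 simulation seeds."""
        errors = []
        for seed in range(200):
            spec = sd.QpcrSimSpec(
                genes=("phaC3",),
                fold_changes={("phaC3", "stationary", "mid_exponential"): 5.86},
                ct_noise_sd=0.1, seed=seed,
            )
            ct, dil, _ = sd.generate_qpcr_dataset(spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                curves = fit_all_curves(dil)
                res = pfaffl_ratio(ct, "phaC3", ["tbp", "ffs"], curves,
                                   "mid_exponential", "stationary")
            errors.append(abs(res.ratio - 5.86) / 5.86)
        assert np.median(errors) < 0.10


class TestAbsoluteQuantity:
    CURVE = StandardCurve("g", -3.3219280948873626, 22.0, 1.0)

    def test_intercept_definition(self):
        assert absolute_quantity(22.0, self.CURVE) == pytest.approx(1.0)

    def test_one_decade_per_slope(self):
        assert absolute_quantity(22.0 + self.CURVE.slope, self.CURVE) == \
            pytest.approx(10.0)

    def test_monotone_decreasing(self):
        qs = [absolute_quantity(ct, self.CURVE) for ct in (18.0, 22.0, 30.0)]
        assert qs == sorted(qs, reverse=True)

    def test_invalid_slope_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            absolute_quantity(20.0, StandardCurve("g", 1.0, 22.0, 1.0))

    def test_planted_hundredfold_template_ratio_recovered(self):
        """Two genes whose templates differ 100x: the standard-curve proxy
        recovers the ratio from noise-free Cts."""
        spec = sd.QpcrSimSpec(
            genes=("hi", "lo"), reference_genes=("tbp",),
            conditions=("one",),
            fold_changes={}, seed=0,
        )
        ct, dil, _ = sd.generate_qpcr_dataset(spec)
        curves = fit_all_curves(dil)
        ct_hi = ct.query("gene == 'hi'")["ct"].iloc[0] - math.log2(100)
        ct_lo = ct.query("gene == 'lo'")["ct"].iloc[0]
        q_hi = absolute_quantity(ct_hi, curves["hi"])
        q_lo = absolute_quantity(ct_lo, curves["lo"])
        assert q_hi / q_lo == pytest.approx(100.0, rel=1e-2)


class TestCompareConditions:
    def test_identical_groups_p_one(self):
        p, flags = compare_conditions([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(2)
        a = 1.0 + rng.normal(0, 1e-6, size=3)
        b = 5.0 + rng.normal(0, 1e-6, size=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, _ = compare_conditions(a, b)
        assert p < 1e-3

    def test_matches_textbook_t_statistic(self):
        """3-vs-3 equal-variance t-test agrees with the closed-form
        Student formula to 1e-10."""
        a = np.array([20.1, 20.5, 19.9])
        b = np.array([22.3, 21.9, 22.6])
        p, _ = compare_conditions(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        from scipy import stats as ss

        p_ref = 2 * ss.t.sf(abs(t), na + nb - 2)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            compare_conditions([1.0], [2.0, 3.0])

    def test_non_normal_group_flagged_not_blocked(self):
        rng = np.random.default_rng(0)
        a = np.concatenate([rng.normal(0, 0.01, 9), [50.0]])  # heavy outlier
        b = rng.normal(1, 0.01, 10)
        with pytest.warns(UserWarning, match="Shapiro"):
            p, flags = compare_conditions(a, b)
        assert flags[0] is False
        assert math.isfinite(p)
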