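import math

import numpy as np
import pytest

from fracrisk.core import BackgroundSet, ClassificationScheme, ToxicityParams
from fracrisk.indices import derive_er_scheme
from fracrisk.probabilistic import (
    DistributionSpec,
    class_probabilities,
    cumulative_curve,
    fit_distribution,
    folded_class_probability,
    propagate,
    screen_outliers,
    sensitivity_contributions,
)

BG = BackgroundSet(provenance="test", values={"A": 50.0, "B": 50.0, "C": 50.0,
                                              "D": 50.0, "E": 50.0, "F": 50.0})


class TestScreenOutliers:
    def test_gross_outlier_flagged(self):
        xs = [9.5, 10.1, 10.0, 9.8, 10.3, 9.9, 10.2, 9.7, 10.4, 9.6,
              10.0, 10.1, 9.9, 10.2, 9.8, 1000.0]
        labels = [f"S{i}" for i in range(16)]
        retained, kept_labels, flagged = screen_outliers(xs, labels)
        assert flagged == ["S15"]
        assert list(retained) == xs[:15]  # input order preserved
        assert kept_labels == labels[:15]

    def test_hand_computed_quartiles(self):
        # sorted xs = 1..8 plus 100: Q1 = 3, Q3 = 7 (linear interpolation at
        # positions 2 and 6), IQR = 4, upper fence 13 -> only 100 flagged
        xs = [5, 1, 100, 3, 7, 2, 8, 4, 6]
        _, _, flagged = screen_outliers(xs, labels=list("abcdefghi"))
        assert flagged == ["c"]

    def test_all_equal_nothing_flagged(self):
        retained, _, flagged = screen_outliers([5.0] * 10)
        assert flagged == []
        assert len(retained) == 10

    def test_too_few_observations_skips_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="fracrisk"):
            retained, _, flagged = screen_outliers([1.0, 2.0, 3.0])
        assert flagged == []
        assert len(retained) == 3
        assert caplog.records

    def test_clean_normal_sample_flag_rate(self):
        # boxplot fences flag ~0.7% of normal data; at n=16 over many
        # repetitions the average flag count stays well below one
        rng = np.random.default_rng(0)
        flags = [
            len(screen_outliers(rng.normal(10, 1, 16))[2]) for _ in range(200)
        ]
        assert np.mean(flags) < 0.5


class TestFitDistribution:
    def test_normal_parameter_recovery(self):
        rng = np.random.default_rng(1)
        spec = fit_distribution(rng.normal(50, 5, 10_000), screen=False)
        assert spec.family == "normal"
        assert spec.loc == pytest.approx(50, rel=0.02)
        assert spec.scale == pytest.approx(5, rel=0.02)

    def test_lognormal_parameter_recovery(self):
        rng = np.random.default_rng(2)
        spec = fit_distribution(rng.lognormal(2, 0.5, 10_000), screen=False)
        assert spec.family == "lognormal"
        assert spec.loc == pytest.approx(2, rel=0.02)
        assert spec.scale == pytest.approx(0.5, rel=0.02)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_distribution([3.0] * 20, screen=False)

    def test_too_small_sample(self):
        with pytest.raises(ValueError, match=">= 8"):
            fit_distribution([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])

    def test_neither_family_attaches_warning(self):
        rng = np.random.default_rng(3)
        xs = rng.uniform(0.01, 1, 500) ** 4  # neither normal nor lognormal
        spec = fit_distribution(xs, screen=False)
        assert spec.warning is not None

    def test_outliers_recorded_in_spec(self):
        xs = [10.0 + 0.1 * i for i in range(15)] + [1000.0]
        labels = [f"S{i}" for i in range(16)]
        spec = fit_distribution(xs, labels=labels)
        assert spec.outliers_removed == ("S15",)


def _point(metal, value):
    return DistributionSpec(metal=metal, family="point", loc=value, scale=0.0)


class TestPropagate:
    def test_point_mass_at_background_yields_er_equal_tr(self):
        tox = ToxicityParams(tr={"A": 10.0})
        result = propagate({"A": _point("A", 50.0)}, BG, tox, n=1000, seed=0)
        assert np.all(result.er_samples["A"] == 10.0)

    def test_seed_determinism(self):
        tox = ToxicityParams(tr={"A": 10.0, "B": 5.0})
        specs = {
            "A": DistributionSpec("A", "lognormal", 4.0, 0.5),
            "B": DistributionSpec("B", "normal", 60.0, 10.0),
        }
        r1 = propagate(specs, BG, tox, n=5000, seed=123)
        r2 = propagate(specs, BG, tox, n=5000, seed=123)
        assert np.array_equal(r1.ri_samples, r2.ri_samples)
        for m in specs:
            assert np.array_equal(r1.er_samples[m], r2.er_samples[m])
        assert r1.class_probs == r2.class_probs
        r3 = propagate(specs, BG, tox, n=5000, seed=124)
        assert not np.array_equal(r1.ri_samples, r3.ri_samples)

    @pytest.mark.parametrize(
        "spec",
        [
            DistributionSpec("A", "lognormal", 4.2, 0.6),
            DistributionSpec("A", "lognormal", 3.0, 1.0),
            DistributionSpec("A", "normal", 80.0, 40.0),  # heavy negative mass
        ],
    )
    def test_class_probabilities_match_folded_cdf(self, spec):
        # analytic oracle: fold the fitted CDF at the background value and
        # difference it at the class boundaries
        tox = ToxicityParams(tr={"A": 10.0})
        scheme = derive_er_scheme(tox)
        n = 50_000
        result = propagate({"A": spec}, BG, tox, er_scheme=scheme, n=n, seed=5)
        expected = folded_class_probability(spec, BG["A"], 10.0, scheme)
        for label, p in expected.items():
            se = math.sqrt(max(p * (1 - p), 1e-12) / n)
            got = result.class_probs["A"][label]
            assert abs(got - p) <= max(3 * se, 1e-4), (label, got, p)

    def test_negative_normal_draws_rejected(self):
        tox = ToxicityParams(tr={"A": 10.0})
        spec = DistributionSpec("A", "normal", 20.0, 30.0)
        result = propagate({"A": spec}, BG, tox, n=2000, seed=9)
        assert result.rejected_draws["A"] > 0
        # every folded Er is at least Tr
        assert result.er_samples["A"].min() >= 10.0

    def test_missing_background_errors(self):
        tox = ToxicityParams(tr={"Z": 5.0})
        with pytest.raises(ValueError, match="Z"):
            propagate({"Z": _point("Z", 1.0)}, BG, tox, n=1000, seed=0)

    def test_minimum_draws_enforced(self):
        tox = ToxicityParams(tr={"A": 10.0})
        with pytest.raises(ValueError):
            propagate({"A": _point("A", 50.0)}, BG, tox, n=10, seed=0)

    def test_location_shift_monotonicity(self):
        tox = ToxicityParams(tr={"A": 10.0})
        lo = DistributionSpec("A", "lognormal", 4.2, 0.5)
        hi = DistributionSpec("A", "lognormal", 4.8, 0.5)
        r_lo = propagate({"A": lo}, BG, tox, n=20_000, seed=11)
        r_hi = propagate({"A": hi}, BG, tox, n=20_000, seed=11)
        assert r_hi.er_samples["A"].mean() > r_lo.er_samples["A"].mean()
        assert r_hi.ri_samples.mean() > r_lo.ri_samples.mean()


class TestClassProbabilities:
    scheme = ClassificationScheme(
        kind="er", labels=("low", "high"), boundaries=(10.0,)
    )

    def test_all_below_first_boundary(self):
        probs = class_probabilities([1, 2, 3], self.scheme)
        assert probs == {"low": 1.0, "high": 0.0}

    def test_boundary_sample_goes_to_upper_interval(self):
        probs = class_probabilities([10.0], self.scheme)
        assert probs == {"low": 0.0, "high": 1.0}

    def test_uniform_split(self):
        rng = np.random.default_rng(6)
        xs = rng.uniform(0, 20, 100_000)
        probs = class_probabilities(xs, self.scheme)
        assert probs["low"] == pytest.approx(0.5, abs=0.01)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)


class TestCumulativeCurve:
    def test_single_value_step(self):
        v, c = cumulative_curve([5.0])
        assert list(v) == [5.0]
        assert list(c) == [1.0]

    def test_cdf_reaches_one_and_matches_median(self):
        rng = np.random.default_rng(7)
        xs = rng.normal(0, 1, 10_001)
        v, c = cumulative_curve(xs)
        assert c[-1] == 1.0
        # value at cumulative probability 0.5 equals the sample median
        median = v[np.searchsorted(c, 0.5)]
        assert median == pytest.approx(np.median(xs), abs=1e-12)


class TestSensitivity:
    def test_single_stochastic_source_dominates(self):
        tox = ToxicityParams(tr={"A": 10.0, "B": 5.0, "C": 1.0})
        specs = {
            "A": DistributionSpec("A", "lognormal", 4.5, 0.6),
            "B": _point("B", 70.0),
            "C": _point("C", 120.0),
        }
        result = propagate(specs, BG, tox, n=10_000, seed=8)
        assert result.sensitivity["A"] == pytest.approx(100.0, abs=0.5)
        assert sum(result.sensitivity.values()) == pytest.approx(100.0, abs=0.1)

    def test_equal_iid_inputs_share_equally(self):
        tox = ToxicityParams(tr={m: 1.0 for m in "ABCDEF"})
        specs = {m: DistributionSpec(m, "normal", 200.0, 20.0) for m in "ABCDEF"}
        result = propagate(specs, BG, tox, n=50_000, seed=9)
        for m in "ABCDEF":
            assert result.sensitivity[m] == pytest.approx(100 / 6, abs=1.5)

    def test_contribution_order_follows_variance_order(self):
        tox = ToxicityParams(tr={"A": 1.0, "B": 1.0, "C": 1.0})
        specs = {
            "A": DistributionSpec("A", "normal", 200.0, 40.0),
            "B": DistributionSpec("B", "normal", 200.0, 20.0),
            "C": DistributionSpec("C", "normal", 200.0, 5.0),
        }
        result = propagate(specs, BG, tox, n=50_000, seed=10)
        s = result.sensitivity
        assert s["A"] > s["B"] > s["C"]

    def test_zero_variance_ri_errors(self):
        tox = ToxicityParams(tr={"A": 10.0})
        result = propagate({"A": _point("A", 50.0)}, BG, tox, n=1000, seed=0)
        with pytest.raises(ValueError):
            sensitivity_contributions(result)
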