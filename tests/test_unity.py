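"""ROC/Youden cut-offs and the Gaussian similarity curve."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from emofusion import (
    GaussianSimilarityCurve,
    YoudenCutoff,
    bin_similarity,
    fit_similarity_gaussian,
    optimal_cutoff,
    roc_curve,
    subject_cutoffs,
)
from emofusion.exceptions import ConfigurationError, DegenerateRocError, FitError
from emofusion.unity import gaussian_profile


def brute_force_cutoff(abs_delta, judgments):
    """Independent exhaustive search: every candidate threshold, explicit tallies."""
    d = np.asarray(abs_delta, dtype=float)
    y = np.asarray(judgments, dtype=bool)
    uniq = sorted(set(d))
    candidates = [uniq[0] - 0.25]
    candidates += [(a + b) / 2.0 for a, b in zip(uniq[:-1], uniq[1:])]
    candidates += [uniq[-1] + 0.25]
    best = None
    for t in candidates:
        tp = sum(1 for di, yi in zip(d, y) if yi and di <= t)
        tn = sum(1 for di, yi in zip(d, y) if not yi and di > t)
        sens = tp / y.sum()
        spec = tn / (~y).sum()
        j = sens + spec - 1.0
        key = (-round(j, 12), round(abs(sens - spec), 12), t)
        if best is None or key < best[0]:
            best = (key, t, j, sens, spec)
    return best[1:]


def random_instance(rng, n, grid=True):
    if grid:
        d = rng.integers(0, 13, size=n) / 2.0  # half-point grid, tie-prone
    else:
        d = rng.uniform(0, 6, size=n)
    p = 1.0 / (1.0 + np.exp((d - rng.uniform(1, 4)) * rng.uniform(0.5, 3)))
    y = rng.random(n) < p
    if y.all() or not y.any():
        y[rng.integers(n)] = not y[0]
    return d, y


class TestRocCurve:
    def test_perfect_separation(self):
        pts = roc_curve([0, 1, 3, 4], ["similar", "similar", "not_similar", "not_similar"])
        best = optimal_cutoff(pts)
        assert best.tau == pytest.approx(2.0)
        assert best.j_max == pytest.approx(1.0)
        assert best.sensitivity == 1.0 and best.specificity == 1.0

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateRocError):
            roc_curve([0.5, 1.5], ["similar", "similar"])

    def test_candidate_set_brackets_data(self):
        pts = roc_curve([1.0, 2.0, 4.0], [True, True, False])
        assert pts["threshold"].min() == pytest.approx(0.75)
        assert pts["threshold"].max() == pytest.approx(4.25)
        assert len(pts) == 4

    def test_sensitivity_specificity_tallies(self):
        rng = np.random.default_rng(0)
        d, y = random_instance(rng, 50)
        pts = roc_curve(d, y)
        for _, row in pts.iterrows():
            pred = d <= row["threshold"]
            assert row["sensitivity"] == pytest.approx((pred & y).sum() / y.sum())
            assert row["specificity"] == pytest.approx((~pred & ~y).sum() / (~y).sum())


class TestOptimalCutoff:
    def test_tie_broken_by_sens_spec_gap(self):
        pts = pd.DataFrame([
            {"threshold": 1.0, "sensitivity": 0.9, "specificity": 0.6, "youden": 0.5},
            {"threshold": 2.0, "sensitivity": 0.75, "specificity": 0.75, "youden": 0.5},
        ])
        best = optimal_cutoff(pts)
        assert best.tau == 2.0
        assert best.tie_broken and best.tie_rule == "min_sens_spec_gap"

    def test_residual_tie_takes_smallest_threshold(self):
        pts = pd.DataFrame([
            {"threshold": 3.0, "sensitivity": 0.8, "specificity": 0.7, "youden": 0.5},
            {"threshold": 1.0, "sensitivity": 0.7, "specificity": 0.8, "youden": 0.5},
        ])
        best = optimal_cutoff(pts)
        assert best.tau == 1.0
        assert "smallest_threshold" in best.tie_rule

    @pytest.mark.parametrize("grid", [True, False])
    def test_matches_brute_force_on_random_instances(self, grid):
        rng = np.random.default_rng(17 if grid else 18)
        for _ in range(60):
            d, y = random_instance(rng, int(rng.integers(5, 120)), grid=grid)
            got = optimal_cutoff(roc_curve(d, y))
            tau, j, sens, spec = brute_force_cutoff(d, y)
            assert got.tau == pytest.approx(tau)
            assert got.j_max == pytest.approx(j)
            assert (got.sensitivity, got.specificity) == pytest.approx((sens, spec))

    def test_monotone_relabeling_preserves_operating_point(self):
        # a strictly increasing transform moves thresholds but not confusion counts
        rng = np.random.default_rng(4)
        d, y = random_instance(rng, 80, grid=False)
        base = optimal_cutoff(roc_curve(d, y))
        trans = optimal_cutoff(roc_curve(d**2, y))
        assert trans.j_max == pytest.approx(base.j_max)
        assert trans.sensitivity == pytest.approx(base.sensitivity)
        assert trans.specificity == pytest.approx(base.specificity)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 12), st.booleans()), min_size=4, max_size=60))
    def test_brute_force_equivalence_property(self, pairs):
        # half-point |delta| grid maximizes Youden ties; the tie rules must
        # still make the result identical to exhaustive search
        d = np.array([v / 2.0 for v, _ in pairs])
        y = np.array([b for _, b in pairs])
        assume(y.any() and not y.all())
        got = optimal_cutoff(roc_curve(d, y))
        tau, j, sens, spec = brute_force_cutoff(d, y)
        assert got.tau == pytest.approx(tau)
        assert got.j_max == pytest.approx(j)
        assert (got.sensitivity, got.specificity) == pytest.approx((sens, spec))

    def test_perfect_j_iff_separable(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(0, 6, size=40)
        y = d <= 2.7  # separable by construction
        assert optimal_cutoff(roc_curve(d, y)).j_max == pytest.approx(1.0)
        y[0] = not y[0]  # break separability
        assert optimal_cutoff(roc_curve(d, y)).j_max < 1.0


class TestYoudenCutoffEstimator:
    def test_sklearn_interface(self):
        est = YoudenCutoff()
        X = np.array([[0.0], [1.0], [3.0], [4.0]])
        y = np.array([1, 1, 0, 0])
        est.fit(X, y)
        assert est.cutoff_ == pytest.approx(2.0)
        assert est.predict(np.array([[1.5], [2.5]])).tolist() == [True, False]
        assert est.get_params() == {}

    def test_clone_compatible(self):
        from sklearn.base import clone

        clone(YoudenCutoff())


class TestSubjectCutoffs:
    def augmented(self, frames):
        return pd.concat(frames, ignore_index=True)

    def subject_frame(self, subject, delta, judged, emotion="angry"):
        return pd.DataFrame({
            "subject_id": subject,
            "rated_emotion": emotion,
            "delta_i": delta,
            "abs_delta_i": np.abs(delta),
            "similarity_judgment": np.where(judged, "similar", "not_similar"),
        })

    def test_recovers_planted_hard_threshold(self):
        rng = np.random.default_rng(6)
        delta = rng.uniform(-4, 4, size=144)
        judged = np.abs(delta) <= 2.5
        table, qc = subject_cutoffs(self.augmented([self.subject_frame("S1", delta, judged)]))
        assert not qc
        tau = table["tau"].iloc[0]
        below = np.abs(delta)[np.abs(delta) <= 2.5].max()
        above = np.abs(delta)[np.abs(delta) > 2.5].min()
        assert below <= tau <= above  # within one candidate step of the truth
        assert table["youden"].iloc[0] == pytest.approx(1.0)

    def test_degenerate_subject_flagged_not_fatal(self):
        rng = np.random.default_rng(7)
        delta = rng.uniform(-3, 3, size=40)
        good = self.subject_frame("S1", delta, np.abs(delta) <= 2)
        bad = self.subject_frame("S2", delta, np.ones(40, dtype=bool))
        table, qc = subject_cutoffs(self.augmented([good, bad]))
        assert table["subject_id"].tolist() == ["S1"]
        assert qc[0]["subject_id"] == "S2" and qc[0]["flag"] == "degenerate_roc"

    def test_by_emotion_scope_skips_missing_emotion(self):
        rng = np.random.default_rng(8)
        delta = rng.uniform(-3, 3, size=60)
        angry_only = self.subject_frame("S1", delta, np.abs(delta) <= 2, emotion="angry")
        table, _ = subject_cutoffs(angry_only, scope="by_emotion")
        assert table["scope"].tolist() == ["angry"]

    def test_identical_subjects_identical_results(self):
        rng = np.random.default_rng(9)
        delta = rng.uniform(-3, 3, size=80)
        judged = np.abs(delta) <= 1.8
        frames = [self.subject_frame(s, delta, judged) for s in ("S1", "S2")]
        table, _ = subject_cutoffs(self.augmented(frames))
        assert table["tau"].nunique() == 1
        assert table["youden"].nunique() == 1


class TestBinSimilarity:
    def trials(self, delta, judged, subject="S1"):
        return pd.DataFrame({
            "subject_id": subject,
            "delta_i": delta,
            "abs_delta_i": np.abs(delta),
            "similarity_judgment": np.where(judged, "similar", "not_similar"),
        })

    def test_half_open_bin_membership(self):
        df = self.trials(np.array([0.24, 0.25, -0.25, -0.26]), np.ones(4, dtype=bool))
        binned = bin_similarity(df, bin_width=0.5, per_subject=False)
        got = binned.per_subject.groupby("bin_center")["n_trials"].sum()
        assert got[0.0] == 2 and got[0.5] == 1 and got[-0.5] == 1

    def test_all_similar_gives_unit_proportions(self):
        df = self.trials(np.linspace(-2, 2, 40), np.ones(40, dtype=bool))
        binned = bin_similarity(df)
        assert (binned.table["p_similar"] == 1.0).all()

    def test_invalid_width_rejected(self):
        with pytest.raises(ConfigurationError):
            bin_similarity(self.trials(np.zeros(4), np.ones(4, dtype=bool)), bin_width=0.0)

    def test_pooled_proportions_match_generator_oracle(self):
        # Monte-Carlo oracle: per-bin mean of the curve over the deltas landing
        # in the bin must match the empirical similar-judgment frequency
        rng = np.random.default_rng(10)
        delta = rng.uniform(-3, 3, size=100_000)
        p = gaussian_profile(delta, 0.86, 0.21, 0.88)
        judged = rng.random(len(delta)) < p
        df = self.trials(delta, judged)
        binned = bin_similarity(df, per_subject=False)
        centers = np.floor(delta / 0.5 + 0.5) * 0.5
        for _, row in binned.table.iterrows():
            oracle = p[centers == row["bin_center"]].mean()
            assert row["p_similar"] == pytest.approx(oracle, abs=0.02)

    def test_subject_equal_weighting(self):
        # two subjects with unequal trial counts in the same bin: the group
        # proportion is the unweighted mean of their per-subject proportions
        a = self.trials(np.zeros(10), np.ones(10, dtype=bool), subject="S1")
        b = self.trials(np.zeros(30), np.zeros(30, dtype=bool), subject="S2")
        binned = bin_similarity(pd.concat([a, b], ignore_index=True), per_subject=True)
        assert binned.table["p_similar"].iloc[0] == pytest.approx(0.5)


class TestGaussianFit:
    def exact_bins(self, a, b, c, centers=None):
        x = np.arange(-3, 3.01, 0.5) if centers is None else centers
        return x, gaussian_profile(x, a, b, c)

    def test_zero_residual_fit_is_exact(self):
        x, y = self.exact_bins(1.0, 0.0, 1.0)
        est = GaussianSimilarityCurve().fit(x, y)
        assert est.amplitude_ == pytest.approx(1.0, abs=1e-6)
        assert est.center_ == pytest.approx(0.0, abs=1e-6)
        assert est.width_ == pytest.approx(1.0, abs=1e-6)
        assert est.ssr_ == pytest.approx(0.0, abs=1e-10)

    def test_symmetric_data_centers_at_zero(self):
        x, y = self.exact_bins(0.8, 0.0, 1.2)
        est = GaussianSimilarityCurve().fit(x, y)
        assert est.center_ == pytest.approx(0.0, abs=1e-6)

    def test_recovery_improves_with_per_bin_count(self):
        truth = (0.86, 0.21, 0.88)
        x = np.arange(-3, 3.01, 0.5)
        p = gaussian_profile(x, *truth)
        errors = {}
        for n in (100, 10_000):
            rng = np.random.default_rng(100 + n)
            y = rng.binomial(n, p) / n
            est = GaussianSimilarityCurve().fit(x, y, sample_weight=np.full(len(x), n))
            got = (est.amplitude_, est.center_, est.width_)
            errors[n] = max(abs(g - t) for g, t in zip(got, truth))
        assert errors[10_000] < errors[100]
        assert errors[10_000] < 0.05

    def test_too_few_bins_is_fit_error(self):
        with pytest.raises(FitError):
            GaussianSimilarityCurve().fit(np.array([0.0, 0.5, 1.0]), np.array([1.0, 0.5, 0.1]))

    def test_amplitude_bound_respected(self):
        x = np.arange(-2, 2.01, 0.5)
        y = np.full(len(x), 1.4)  # impossible proportions, fit must stay <= 1
        est = GaussianSimilarityCurve().fit(x, y)
        assert est.amplitude_ <= 1.0 + 1e-9

    def test_bootstrap_ci_brackets_estimate(self, small_dataset):
        from emofusion import attach_intensity_difference, unisensory_means

        summary = unisensory_means(small_dataset.unisensory)
        aug = attach_intensity_difference(small_dataset.multisensory, summary)
        fit = fit_similarity_gaussian(aug, n_boot=100, seed=3)
        assert fit.ci_method == "bootstrap"
        for name, value in (
            ("amplitude", fit.amplitude),
            ("center", fit.center),
            ("width", fit.width),
        ):
            lo, hi = fit.ci[name]
            assert lo <= hi
            assert lo - 0.15 <= value <= hi + 0.15

    def test_asymptotic_fallback_without_subject_bins(self):
        from emofusion.unity import BinnedSimilarity

        x, y = self.exact_bins(0.86, 0.21, 0.88)
        rng = np.random.default_rng(2)
        y = np.clip(y + rng.normal(0, 0.02, len(y)), 0, 1)
        bins = BinnedSimilarity(
            table=pd.DataFrame({"bin_center": x, "p_similar": y, "n_trials": 100}),
            bin_width=0.5,
        )
        fit = fit_similarity_gaussian(bins, ci_method="bootstrap")
        assert fit.ci_method == "asymptotic"  # no per-subject bins to resample
        assert fit.amplitude == pytest.approx(0.86, abs=0.1)
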