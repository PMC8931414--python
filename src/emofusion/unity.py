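"""Unity-assumption estimation: ROC/Youden cut-offs and the similarity curve.

A trial is classified "similar" when the absolute audiovisual intensity
difference ``|delta_i|`` is at or below a threshold.  Sweeping the threshold
over the empirical candidates (midpoints between consecutive sorted unique
values, plus sentinels below the minimum and above the maximum) traces the
ROC against the subject's actual similar / not-similar judgments; the optimal
cut-off maximizes the Youden index ``J = sensitivity + specificity - 1``, with
ties broken first by the minimum |sensitivity - specificity| and then by the
smaller threshold.

The group similarity curve is the proportion of "similar" judgments per
signed ``delta_i`` bin (subjects weighted equally), fitted by weighted least
squares with a scaled Gaussian ``y = a * exp(-((x - b) / c)**2)``.
Confidence intervals come from a nonparametric bootstrap over subjects by
default, or from the asymptotic Jacobian covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from .exceptions import ConfigurationError, DegenerateRocError, FitError

logger = logging.getLogger(__name__)

SENTINEL_STEP = 0.25


@dataclass
class CutoffResult:
    """Optimal unity cut-off for one subject (and emotion scope)."""

    subject_id: str
    tau: float
    j_max: float
    sensitivity: float
    specificity: float
    n_candidates: int
    tie_broken: bool
    tie_rule: str
    scope: str = "pooled"


@dataclass
class BinnedSimilarity:
    """Per-bin proportion of 'similar' judgments over signed delta_i."""

    table: pd.DataFrame  # bin_center, p_similar, n_trials [, n_subjects, sem]
    bin_width: float
    per_subject: Optional[pd.DataFrame] = None  # subject_id, bin_center, p_similar, n_trials


@dataclass
class GaussianFit:
    """Scaled-Gaussian similarity-curve fit with confidence intervals."""

    amplitude: float
    center: float
    width: float
    ci: dict[str, tuple[float, float]]
    ssr: float
    n_bins: int
    ci_method: str
    n_boot: int = 0
    converged: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        return gaussian_profile(np.asarray(x, dtype=float), self.amplitude, self.center, self.width)


def gaussian_profile(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """``a * exp(-((x - b) / c)**2)`` — note the width convention has no factor 2."""
    return a * np.exp(-(((x - b) / c) ** 2))


def _as_bool(judgments: Sequence) -> np.ndarray:
    arr = np.asarray(judgments)
    if arr.dtype == bool:
        return arr
    if arr.dtype.kind in "iuf":
        return arr.astype(bool)
    return arr == "similar"


def roc_curve(abs_delta: Sequence[float], judgments: Sequence) -> pd.DataFrame:
    """Empirical ROC of the rule "similar iff |delta_i| <= threshold".

    ``judgments`` may be booleans, 0/1, or the strings ``similar`` /
    ``not_similar``; the positive class is "judged similar".  Returns one row
    per candidate threshold with sensitivity, specificity and the Youden
    index.  Raises :class:`DegenerateRocError` when only one class is present.
    """
    d = np.asarray(abs_delta, dtype=float)
    y = _as_bool(judgments)
    if d.shape != y.shape or d.ndim != 1:
        raise ConfigurationError("abs_delta and judgments must be equal-length 1-d sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateRocError(
            f"need both classes, got {n_pos} similar / {n_neg} not-similar trials"
        )
    uniq = np.unique(d)
    candidates = np.concatenate(
        [[uniq[0] - SENTINEL_STEP], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + SENTINEL_STEP]]
    )
    rows = []
    for t in candidates:
        pred = d <= t
        sens = float((pred & y).sum() / n_pos)
        spec = float((~pred & ~y).sum() / n_neg)
        rows.append(
            {"threshold": float(t), "sensitivity": sens, "specificity": spec, "youden": sens + spec - 1.0}
        )
    return pd.DataFrame(rows)


def optimal_cutoff(points: pd.DataFrame, subject_id: str = "", scope: str = "pooled") -> CutoffResult:
    """Pick the threshold maximizing the Youden index.

    Ties on J are broken by the minimum |sensitivity - specificity|, residual
    ties by the smallest threshold; the result records whether a tie rule was
    applied.
    """
    if len(points) == 0:
        raise ConfigurationError("empty ROC point list")
    j = points["youden"].to_numpy()
    best_j = j.max()
    at_max = points[np.isclose(j, best_j, rtol=0.0, atol=1e-12)]
    tie_rule = "none"
    tie_broken = len(at_max) > 1
    if tie_broken:
        gap = (at_max["sensitivity"] - at_max["specificity"]).abs().to_numpy()
        at_gap = at_max[np.isclose(gap, gap.min(), rtol=0.0, atol=1e-12)]
        tie_rule = "min_sens_spec_gap"
        if len(at_gap) > 1:
            tie_rule = "min_sens_spec_gap+smallest_threshold"
        best = at_gap.loc[at_gap["threshold"].idxmin()]
    else:
        best = at_max.iloc[0]
    return CutoffResult(
        subject_id=subject_id,
        tau=float(best["threshold"]),
        j_max=float(best["youden"]),
        sensitivity=float(best["sensitivity"]),
        specificity=float(best["specificity"]),
        n_candidates=len(points),
        tie_broken=tie_broken,
        tie_rule=tie_rule,
        scope=scope,
    )


class YoudenCutoff(BaseEstimator, ClassifierMixin):
    """Youden-optimal unity cut-off as a one-feature threshold classifier.

    ``fit(X, y)`` takes absolute intensity differences (shape ``(n,)`` or
    ``(n, 1)``) and similar / not-similar labels; ``predict`` classifies new
    differences with the fitted cut-off.

    Attributes
    ----------
    cutoff_ : float
        The Youden-optimal threshold.
    youden_, sensitivity_, specificity_ : float
        Operating characteristics at the cut-off.
    roc_ : pandas.DataFrame
        The full candidate-threshold sweep.
    tie_broken_ : bool
    """

    def __init__(self) -> None:
        pass

    @staticmethod
    def _column(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ConfigurationError("YoudenCutoff expects a single feature")
            X = X[:, 0]
        return X

    def fit(self, X, y) -> "YoudenCutoff":
        d = self._column(X)
        self.roc_ = roc_curve(d, y)
        result = optimal_cutoff(self.roc_)
        self.cutoff_ = result.tau
        self.youden_ = result.j_max
        self.sensitivity_ = result.sensitivity
        self.specificity_ = result.specificity
        self.tie_broken_ = result.tie_broken
        self.result_ = result
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X) -> np.ndarray:
        return self._column(X) <= self.cutoff_


def subject_cutoffs(
    augmented: pd.DataFrame, scope: str = "pooled"
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-subject (optionally per-emotion) unity cut-offs with a QC list.

    Subjects (or subject-emotion cells) whose judgments are single-class are
    reported in the QC list and omitted from the result, not fatal.
    """
    if scope not in ("pooled", "by_emotion"):
        raise ConfigurationError(f"unknown scope {scope!r}")
    group_cols = ["subject_id"] if scope == "pooled" else ["subject_id", "rated_emotion"]
    rows, qc = [], []
    for key, grp in augmented.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        subject = key[0]
        label = "pooled" if scope == "pooled" else key[1]
        try:
            pts = roc_curve(grp["abs_delta_i"], grp["similarity_judgment"])
        except DegenerateRocError as err:
            qc.append({"subject_id": subject, "scope": label, "flag": "degenerate_roc", "detail": str(err)})
            logger.warning("subject %s (%s): %s", subject, label, err)
            continue
        res = optimal_cutoff(pts, subject_id=subject, scope=label)
        rows.append(
            {
                "subject_id": subject,
                "scope": label,
                "tau": res.tau,
                "youden": res.j_max,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
                "n_candidates": res.n_candidates,
                "tie_broken": res.tie_broken,
            }
        )
    columns = [
        "subject_id", "scope", "tau", "youden", "sensitivity", "specificity",
        "n_candidates", "tie_broken",
    ]
    return pd.DataFrame(rows, columns=columns), qc


def _bin_centers(delta: np.ndarray, width: float) -> np.ndarray:
    # half-open bins [center - w/2, center + w/2) on a grid of multiples of w
    return np.floor(delta / width + 0.5) * width


def bin_similarity(
    augmented: pd.DataFrame, bin_width: float = 0.5, per_subject: bool = True
) -> BinnedSimilarity:
    """Bin signed ``delta_i`` and tabulate the proportion judged similar.

    With ``per_subject=True`` the group proportion in each bin is the
    unweighted mean over the subjects contributing to it (with its SEM);
    otherwise trials are pooled directly.
    """
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be > 0")
    df = augmented.copy()
    df["bin_center"] = _bin_centers(df["delta_i"].to_numpy(dtype=float), bin_width)
    df["similar"] = _as_bool(df["similarity_judgment"]).astype(float)

    subj = (
        df.groupby(["subject_id", "bin_center"], as_index=False)
        .agg(p_similar=("similar", "mean"), n_trials=("similar", "size"))
    )
    if per_subject:
        table = (
            subj.groupby("bin_center", as_index=False)
            .agg(
                p_similar=("p_similar", "mean"),
                n_subjects=("p_similar", "size"),
                sem=("p_similar", "sem"),
                n_trials=("n_trials", "sum"),
            )
            .sort_values("bin_center", ignore_index=True)
        )
    else:
        table = (
            df.groupby("bin_center", as_index=False)
            .agg(p_similar=("similar", "mean"), n_trials=("similar", "size"))
            .sort_values("bin_center", ignore_index=True)
        )
    return BinnedSimilarity(table=table, bin_width=bin_width, per_subject=subj)


class GaussianSimilarityCurve(BaseEstimator, RegressorMixin):
    """Weighted least-squares fit of ``y = a * exp(-((x - b) / c)**2)``.

    ``fit(X, y, sample_weight)`` takes bin centers (``(n,)`` or ``(n, 1)``)
    and per-bin proportions; weights are typically per-bin trial counts.
    Multistart initialization over a small grid of centers and widths guards
    against local minima; the amplitude is bounded to [0, 1] and the width to
    positive values.

    Attributes
    ----------
    amplitude_, center_, width_ : float
    ssr_ : float
        Weighted sum of squared residuals at the optimum.
    converged_ : bool
    """

    def __init__(
        self,
        bound_amplitude: bool = True,
        center_starts: tuple = (-1.0, 0.0, 1.0),
        width_starts: tuple = (0.5, 1.0, 2.0),
        max_nfev: int = 2000,
    ) -> None:
        self.bound_amplitude = bound_amplitude
        self.center_starts = center_starts
        self.width_starts = width_starts
        self.max_nfev = max_nfev

    def fit(self, X, y, sample_weight=None) -> "GaussianSimilarityCurve":
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        y = np.asarray(y, dtype=float)
        w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        informative = w > 0
        if int(informative.sum()) < 4:
            raise FitError(f"need >= 4 informative bins, got {int(informative.sum())}")
        x, y, w = x[informative], y[informative], w[informative]
        sw = np.sqrt(w)

        def residuals(theta: np.ndarray) -> np.ndarray:
            return sw * (gaussian_profile(x, *theta) - y)

        hi_a = 1.0 if self.bound_amplitude else np.inf
        a0 = float(np.clip(y.max(), 1e-3, hi_a))
        best = None
        for b0 in self.center_starts:
            for c0 in self.width_starts:
                theta0 = np.clip([a0, b0, c0], [1e-6, -np.inf, 1e-6], [hi_a, np.inf, np.inf])
                try:
                    sol = optimize.least_squares(
                        residuals,
                        theta0,
                        bounds=([0.0, -np.inf, 1e-6], [hi_a, np.inf, np.inf]),
                        max_nfev=self.max_nfev,
                    )
                except Exception:  # pragma: no cover - scipy internal failure
                    continue
                if sol.success and (best is None or sol.cost < best.cost):
                    best = sol
        if best is None:
            raise FitError("Gaussian similarity fit failed from every start")
        self.amplitude_, self.center_, self.width_ = (float(v) for v in best.x)
        self.ssr_ = float(2.0 * best.cost)
        self.converged_ = bool(best.success)
        self.n_features_in_ = 1
        self._solution = best
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return gaussian_profile(x, self.amplitude_, self.center_, self.width_)

    def asymptotic_ci(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Jacobian-based normal-approximation confidence intervals."""
        from scipy.stats import norm

        sol = self._solution
        m = len(sol.fun)
        dof = max(m - 3, 1)
        sigma2 = 2.0 * sol.cost / dof
        jtj = sol.jac.T @ sol.jac
        cov = sigma2 * np.linalg.pinv(jtj)
        se = np.sqrt(np.diag(cov))
        z = norm.ppf(0.5 + level / 2.0)
        names = ("amplitude", "center", "width")
        est = (self.amplitude_, self.center_, self.width_)
        return {n: (float(e - z * s), float(e + z * s)) for n, e, s in zip(names, est, se)}


def _group_table(per_subject: pd.DataFrame) -> pd.DataFrame:
    return (
        per_subject.groupby("bin_center", as_index=False)
        .agg(p_similar=("p_similar", "mean"), n_trials=("n_trials", "sum"))
        .sort_values("bin_center", ignore_index=True)
    )


def fit_similarity_gaussian(
    data: Union[pd.DataFrame, BinnedSimilarity],
    bin_width: float = 0.5,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: Optional[int] = None,
    estimator: Optional[GaussianSimilarityCurve] = None,
) -> GaussianFit:
    """Fit the group similarity curve and attach 95% confidence intervals.

    ``data`` is either augmented multisensory trials (binned here) or a
    pre-binned :class:`BinnedSimilarity`.  The point fit uses per-bin means of
    per-subject proportions weighted by total trial counts.  Bootstrap CIs
    resample subjects with replacement (percentile intervals); they require
    per-subject information and otherwise fall back to the asymptotic method
    with a warning.
    """
    if isinstance(data, BinnedSimilarity):
        binned = data
    else:
        binned = bin_similarity(data, bin_width=bin_width, per_subject=True)
    est = estimator or GaussianSimilarityCurve()

    table = binned.table
    est.fit(table["bin_center"], table["p_similar"], sample_weight=table["n_trials"])

    per_subject = binned.per_subject
    method = ci_method
    if ci_method == "bootstrap" and (per_subject is None or per_subject["subject_id"].nunique() < 2):
        logger.warning("bootstrap CI needs per-subject bins; falling back to asymptotic")
        method = "asymptotic"

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        subjects = per_subject["subject_id"].unique()
        groups = {s: g for s, g in per_subject.groupby("subject_id")}
        draws = np.empty((n_boot, 3))
        refit = GaussianSimilarityCurve(
            bound_amplitude=est.bound_amplitude,
            center_starts=(est.center_,),
            width_starts=(est.width_,),
        )
        kept = 0
        for _ in range(n_boot):
            picked = rng.choice(subjects, size=len(subjects), replace=True)
            resampled = pd.concat([groups[s] for s in picked], ignore_index=True)
            g = _group_table(resampled)
            try:
                refit.fit(g["bin_center"], g["p_similar"], sample_weight=g["n_trials"])
            except FitError:
                continue
            draws[kept] = (refit.amplitude_, refit.center_, refit.width_)
            kept += 1
        if kept < max(10, n_boot // 10):
            raise FitError(f"bootstrap produced only {kept}/{n_boot} successful refits")
        lo, hi = np.percentile(draws[:kept], [2.5, 97.5], axis=0)
        ci = {
            name: (float(l), float(h))
            for name, l, h in zip(("amplitude", "center", "width"), lo, hi)
        }
    elif method == "asymptotic":
        ci = est.asymptotic_ci()
    else:
        raise ConfigurationError(f"unknown ci_method {ci_method!r}")

    return GaussianFit(
        amplitude=est.amplitude_,
        center=est.center_,
        width=est.width_,
        ci=ci,
        ssr=est.ssr_,
        n_bins=len(table),
        ci_method=method,
        n_boot=n_boot if method == "bootstrap" else 0,
        converged=est.converged_,
    )
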