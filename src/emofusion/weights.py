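"""Per-subject audiovisual integration weights and sensory-reliance scores.

Each subject's multisensory intensity ratings are regressed on the mean
unisensory ratings of the trial's face and voice components:

    rating_M = beta_v * mean_face + beta_a * mean_voice + c

by ordinary least squares, separately per (similarity, emotion) condition
cell and for pooled scopes.  The sensory reliance score is
``beta_v - beta_a`` (positive = visual-leaning) and the unisensory degree is
its absolute value.  The reliability-weighted account of cue combination
predicts reliance to track the subject's face-minus-voice recognition
accuracy advantage; :func:`reliability_correlation` tests that with a Pearson
correlation over subjects in the similar-judgment condition.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    InsufficientDataError,
    InsufficientVarianceError,
    SchemaError,
)
from .preprocess import AccuracyTable
from .stats import CorrelationResult, pearson

logger = logging.getLogger(__name__)

SIMILARITY_SCOPES = ("similar", "not_similar", "pooled")
EMOTION_SCOPES = ("angry", "happy", "pooled")
DEFAULT_MIN_TRIALS = 5


class IntegrationWeights(BaseEstimator, RegressorMixin):
    """OLS fusion-weight regression for one subject-condition cell.

    ``fit(X, y)`` takes a two-column design (face mean, voice mean) and the
    multisensory ratings.

    Attributes
    ----------
    coef_ : ndarray of shape (2,)
        ``(beta_v, beta_a)``.
    intercept_ : float
    reliance_ : float
        ``beta_v - beta_a``.
    unisensory_degree_ : float
        ``abs(beta_v - beta_a)``.
    r2_, resid_var_ : float
    n_trials_ : int
    """

    def __init__(self, min_trials: int = DEFAULT_MIN_TRIALS) -> None:
        self.min_trials = min_trials

    def fit(self, X, y) -> "IntegrationWeights":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise SchemaError("IntegrationWeights expects exactly two predictors (face, voice)")
        n = len(y)
        if n < self.min_trials:
            raise InsufficientDataError(f"{n} trials < minimum {self.min_trials}")
        design = np.column_stack([np.ones(n), X])
        if np.linalg.matrix_rank(design) < 3:
            raise InsufficientVarianceError("rank-deficient design (constant or collinear predictors)")
        beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        fitted = design @ beta
        resid = y - fitted
        tss = float(((y - y.mean()) ** 2).sum())
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.reliance_ = float(beta[1] - beta[2])
        self.unisensory_degree_ = abs(self.reliance_)
        self.n_trials_ = n
        dof = max(n - 3, 1)
        self.resid_var_ = float((resid**2).sum() / dof)
        self.r2_ = float(1.0 - (resid**2).sum() / tss) if tss > 0 else np.nan
        self.n_features_in_ = 2
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_


def _scope_mask(df: pd.DataFrame, similarity: str, emotion: str) -> pd.Series:
    mask = pd.Series(True, index=df.index)
    if similarity != "pooled":
        mask &= df["similarity_judgment"] == similarity
    if emotion != "pooled":
        mask &= df["rated_emotion"] == emotion
    return mask


def fit_integration_regression(
    augmented: pd.DataFrame,
    min_trials: int = DEFAULT_MIN_TRIALS,
    scopes: Optional[Sequence[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Fit the fusion regression per subject and scope.

    ``augmented`` must carry ``face_mean`` / ``voice_mean`` columns (from
    :func:`emofusion.preprocess.attach_intensity_difference`).  ``scopes``
    defaults to the full 3 x 3 grid of similarity and emotion scopes.  Cells
    with too few trials or a rank-deficient design are emitted with
    ``status`` set to the skip reason rather than dropped silently.
    """
    required = {"subject_id", "face_mean", "voice_mean", "rating", "similarity_judgment", "rated_emotion"}
    missing = sorted(required - set(augmented.columns))
    if missing:
        raise SchemaError(f"augmented table is missing columns: {missing}")
    if scopes is None:
        scopes = [(s, e) for s in SIMILARITY_SCOPES for e in EMOTION_SCOPES]

    rows = []
    for subject, grp in augmented.groupby("subject_id", sort=True):
        for similarity, emotion in scopes:
            cell = grp[_scope_mask(grp, similarity, emotion)]
            row = {
                "subject_id": subject,
                "similarity": similarity,
                "emotion": emotion,
                "n_trials": len(cell),
                "beta_v": np.nan,
                "beta_a": np.nan,
                "intercept": np.nan,
                "r2": np.nan,
                "resid_var": np.nan,
                "status": "ok",
            }
            try:
                est = IntegrationWeights(min_trials=min_trials).fit(
                    cell[["face_mean", "voice_mean"]].to_numpy(), cell["rating"].to_numpy()
                )
            except InsufficientDataError:
                row["status"] = "too_few_trials"
            except InsufficientVarianceError:
                row["status"] = "rank_deficient"
            else:
                row.update(
                    beta_v=est.coef_[0],
                    beta_a=est.coef_[1],
                    intercept=est.intercept_,
                    r2=est.r2_,
                    resid_var=est.resid_var_,
                )
            if row["status"] != "ok":
                logger.info(
                    "subject %s scope (%s, %s): regression skipped (%s, n=%d)",
                    subject, similarity, emotion, row["status"], len(cell),
                )
            rows.append(row)
    return pd.DataFrame(rows)


def reliance_scores(fits: pd.DataFrame) -> pd.DataFrame:
    """Derive reliance (``beta_v - beta_a``) and unisensory degree per fitted cell."""
    out = fits[fits["status"] == "ok"].copy()
    out["reliance"] = out["beta_v"] - out["beta_a"]
    out["unisensory_degree"] = out["reliance"].abs()
    return out[
        ["subject_id", "similarity", "emotion", "n_trials", "reliance", "unisensory_degree"]
    ].reset_index(drop=True)


def reliability_correlation(
    accuracy: AccuracyTable,
    reliance: pd.DataFrame,
    emotion: str = "pooled",
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Correlate similar-condition reliance with the face-voice accuracy advantage.

    The accuracy difference is (face accuracy - voice accuracy) per subject,
    restricted to the scoped emotion's cells when ``emotion`` is not
    ``pooled``.  Returns the Pearson result together with the per-subject
    pairs used, for audit.
    """
    if emotion not in EMOTION_SCOPES:
        raise SchemaError(f"unknown emotion scope {emotion!r}")
    if emotion == "pooled":
        acc = accuracy.overall.copy()
    else:
        cells = accuracy.cells[accuracy.cells["emotion"] == emotion]
        weighted = cells.assign(correct=cells["accuracy"] * cells["n_trials"])
        acc = (
            weighted.groupby(["subject_id", "modality"], as_index=False)
            .agg(correct=("correct", "sum"), n_trials=("n_trials", "sum"))
        )
        acc["accuracy"] = acc["correct"] / acc["n_trials"]
    wide = acc.pivot(index="subject_id", columns="modality", values="accuracy")
    if not {"face", "voice"} <= set(wide.columns):
        raise InsufficientDataError("accuracy table lacks face or voice rows")
    wide["acc_diff"] = wide["face"] - wide["voice"]

    rel = reliance[(reliance["similarity"] == "similar") & (reliance["emotion"] == emotion)]
    pairs = (
        rel.set_index("subject_id")[["reliance"]]
        .join(wide[["acc_diff"]], how="inner")
        .dropna()
        .reset_index()
    )
    if len(pairs) < 3:
        raise InsufficientDataError(f"only {len(pairs)} complete subject pairs (need >= 3)")
    result = pearson(pairs["acc_diff"].to_numpy(), pairs["reliance"].to_numpy())
    return result, pairs
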