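"""Summaries feeding the unity and integration analyses.

From the raw trial tables this module computes (1) per-condition emotion
recognition accuracy from the validation block, (2) per-stimulus and
per-condition mean unisensory intensity ratings, and (3) the audiovisual
intensity difference ``delta_i`` (face mean minus voice mean, on the trial's
rated emotion dimension) attached to every multisensory trial.

Neutral stimuli are rated on both the anger and happiness dimensions; their
means are kept separate per rated emotion, and a multisensory neutral
component uses the mean on the dimension the trial was rated on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .design import StimulusInventory
from .exceptions import CompletenessError, SchemaError

_UNI_REQUIRED = {"subject_id", "stimulus_id", "modality", "level", "rated_emotion", "rating"}
_VALID_REQUIRED = {"subject_id", "stimulus_id", "validation_response"}
_MULTI_REQUIRED = {
    "subject_id", "stimulus_id", "face_id", "voice_id", "face_level", "voice_level",
    "rated_emotion", "rating", "similarity_judgment",
}


def _check_columns(df: pd.DataFrame, required: set[str], name: str) -> None:
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"{name} table is missing columns: {missing}")


@dataclass
class AccuracyTable:
    """Recognition accuracy per condition cell and per modality overall."""

    cells: pd.DataFrame  # subject_id, modality, emotion, level, n_trials, accuracy
    overall: pd.DataFrame  # subject_id, modality, n_trials, accuracy


@dataclass
class UnisensorySummary:
    """Mean unisensory ratings per stimulus (and rated emotion) and per condition."""

    stimulus_means: pd.DataFrame  # subject_id, stimulus_id, modality, level, rated_emotion, mean_rating, n
    condition_means: pd.DataFrame  # subject_id, modality, rated_emotion, level, mean_rating, n


def recognition_accuracy(
    validation: pd.DataFrame, inventory: Optional[StimulusInventory] = None
) -> AccuracyTable:
    """Proportion of correct emotion identifications per condition and modality.

    The ground-truth label is the stimulus's own emotion; if the table lacks
    ``modality`` / ``emotion`` / ``level`` columns they are joined from the
    inventory, and rows with unknown stimulus ids raise a schema error.
    """
    _check_columns(validation, _VALID_REQUIRED, "validation")
    df = validation.copy()
    if not {"modality", "emotion", "level"} <= set(df.columns):
        if inventory is None:
            raise SchemaError(
                "validation table lacks modality/emotion/level and no inventory was given"
            )
        meta = inventory.unisensory_frame()[["stimulus_id", "modality", "emotion", "level"]]
        df = df.drop(columns=[c for c in ("modality", "emotion", "level") if c in df], errors="ignore")
        df = df.merge(meta, on="stimulus_id", how="left", validate="many_to_one")
        bad = df[df["modality"].isna()]
        if len(bad):
            raise SchemaError(
                f"validation rows with unknown stimulus ids: {sorted(bad['stimulus_id'].unique())}"
            )
    df["correct"] = (df["validation_response"] == df["emotion"]).astype(float)

    cells = (
        df.groupby(["subject_id", "modality", "emotion", "level"], as_index=False)
        .agg(n_trials=("correct", "size"), accuracy=("correct", "mean"))
    )
    overall = (
        df.groupby(["subject_id", "modality"], as_index=False)
        .agg(n_trials=("correct", "size"), accuracy=("correct", "mean"))
    )
    return AccuracyTable(cells=cells, overall=overall)


def unisensory_means(unisensory: pd.DataFrame) -> UnisensorySummary:
    """Mean rating per (subject, stimulus, rated emotion) and per condition cell."""
    _check_columns(unisensory, _UNI_REQUIRED, "unisensory")
    if len(unisensory) == 0:
        raise CompletenessError("unisensory table is empty")
    stim = (
        unisensory.groupby(
            ["subject_id", "stimulus_id", "modality", "level", "rated_emotion"], as_index=False
        )
        .agg(mean_rating=("rating", "mean"), n=("rating", "size"))
    )
    cond = (
        unisensory.groupby(["subject_id", "modality", "rated_emotion", "level"], as_index=False)
        .agg(mean_rating=("rating", "mean"), n=("rating", "size"))
    )
    return UnisensorySummary(stimulus_means=stim, condition_means=cond)


def attach_intensity_difference(
    multisensory: pd.DataFrame,
    summary: UnisensorySummary,
    granularity: str = "stimulus",
) -> pd.DataFrame:
    """Attach ``delta_i`` (face mean minus voice mean) to every multisensory trial.

    ``granularity="stimulus"`` (default) uses the subject's mean rating of the
    trial's specific face and voice on the rated emotion dimension;
    ``"condition"`` substitutes the subject's condition-level means for the
    component levels instead.
    """
    _check_columns(multisensory, _MULTI_REQUIRED, "multisensory")
    out = multisensory.copy()

    if granularity == "stimulus":
        means = summary.stimulus_means[["subject_id", "stimulus_id", "rated_emotion", "mean_rating"]]
        for side, id_col in (("face", "face_id"), ("voice", "voice_id")):
            m = means.rename(columns={"stimulus_id": id_col, "mean_rating": f"{side}_mean"})
            out = out.merge(m, on=["subject_id", id_col, "rated_emotion"], how="left")
    elif granularity == "condition":
        means = summary.condition_means
        for side, modality in (("face", "face"), ("voice", "voice")):
            m = means[means["modality"] == modality][
                ["subject_id", "rated_emotion", "level", "mean_rating"]
            ].rename(columns={"level": f"{side}_level", "mean_rating": f"{side}_mean"})
            out = out.merge(m, on=["subject_id", f"{side}_level", "rated_emotion"], how="left")
    else:
        raise SchemaError(f"unknown granularity {granularity!r}")

    missing = out[out["face_mean"].isna() | out["voice_mean"].isna()]
    if len(missing):
        ids = sorted(
            set(missing.loc[missing["face_mean"].isna(), "face_id"]).union(
                missing.loc[missing["voice_mean"].isna(), "voice_id"]
            )
        )
        raise CompletenessError(f"missing unisensory means for component stimuli: {ids}")

    out["delta_i"] = out["face_mean"] - out["voice_mean"]
    out["abs_delta_i"] = out["delta_i"].abs()
    return out
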