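"""End-to-end analysis orchestration over the four input tables.

:func:`analyze_dataset` chains preprocessing, unity-cutoff estimation, the
group similarity curve, the integration regressions and the inferential
tests in the order the analyses build on one another, and returns everything
in one result object.  The command-line ``analyze`` command and the
acceptance script are thin wrappers around it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .design import StimulusInventory
from .exceptions import (
    DegenerateRocError,
    EmofusionError,
    FitError,
    InsufficientDataError,
    InsufficientVarianceError,
)
from .preprocess import (
    AccuracyTable,
    UnisensorySummary,
    attach_intensity_difference,
    recognition_accuracy,
    unisensory_means,
)
from .stats import (
    AncovaResult,
    interaction_contrast,
    main_effect_contrast,
    paired_t,
    pearson,
    within_ancova,
)
from .unity import BinnedSimilarity, GaussianFit, bin_similarity, fit_similarity_gaussian, subject_cutoffs
from .weights import fit_integration_regression, reliability_correlation, reliance_scores

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResults:
    """Every table and fitted object the pipeline produces."""

    accuracy: AccuracyTable
    summary: UnisensorySummary
    augmented: pd.DataFrame
    cutoffs: pd.DataFrame
    bins: BinnedSimilarity
    gaussian: Optional[GaussianFit]
    fits: pd.DataFrame
    reliance: pd.DataFrame
    stats_report: pd.DataFrame
    ancovas: dict[str, AncovaResult] = field(default_factory=dict)
    qc: list[dict] = field(default_factory=list)


def _stat_row(label: str, kind: str, statistic: float, df1, df2, p: float,
              effect_size: float, n: int, note: str = "") -> dict:
    return {
        "label": label, "kind": kind, "statistic": statistic,
        "df1": df1, "df2": df2, "p": p, "effect_size": effect_size, "n": n, "note": note,
    }


def _ancova_rows(label: str, res: AncovaResult) -> list[dict]:
    rows = [
        _stat_row(label, "ancova_F", res.F, res.df1, res.df2, res.p, res.partial_eta_sq, res.n,
                  note=f"excluded={len(res.excluded)}")
    ]
    for ct in res.covariate_tests:
        rows.append(
            _stat_row(f"{label}_x_{ct.covariate}", "ancova_covariate_F", ct.F,
                      ct.df1, ct.df2, ct.p, ct.partial_eta_sq, res.n)
        )
    return rows


def _reliance_cells(reliance: pd.DataFrame, value: str) -> pd.DataFrame:
    cells = reliance[
        reliance["similarity"].isin(["similar", "not_similar"])
        & reliance["emotion"].isin(["angry", "happy"])
    ]
    wide = cells.pivot(index="subject_id", columns=["similarity", "emotion"], values=value)
    wide.columns = [tuple(c) for c in wide.columns]
    return wide


def analyze_dataset(
    unisensory: pd.DataFrame,
    multisensory: pd.DataFrame,
    validation: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    inventory: Optional[StimulusInventory] = None,
    analysis: Optional[AnalysisConfig] = None,
    seed: int = 0,
) -> AnalysisResults:
    """Run the full analysis pipeline on trial-level tables.

    ``covariates`` (questionnaire totals per subject) are optional; without
    them the ANCOVAs run covariate-free and covariate correlations are
    skipped.  ``seed`` drives only the bootstrap of the similarity-curve fit.
    """
    cfg = analysis or AnalysisConfig()
    cfg.validate()
    qc: list[dict] = []

    accuracy = recognition_accuracy(validation, inventory)
    logger.info("recognition accuracy: %d cell rows", len(accuracy.cells))
    summary = unisensory_means(unisensory)
    logger.info("unisensory means: %d stimulus rows", len(summary.stimulus_means))
    augmented = attach_intensity_difference(multisensory, summary, cfg.delta_granularity)
    logger.info("augmented multisensory trials: %d rows", len(augmented))

    cutoff_frames = []
    for scope in cfg.cutoff_scopes:
        table, scope_qc = subject_cutoffs(augmented, scope=scope)
        cutoff_frames.append(table)
        qc.extend(scope_qc)
    cutoffs = pd.concat(cutoff_frames, ignore_index=True) if cutoff_frames else pd.DataFrame()
    logger.info("cutoffs: %d rows, %d QC flags", len(cutoffs), len(qc))

    bins = bin_similarity(augmented, bin_width=cfg.bin_width, per_subject=True)
    try:
        gaussian = fit_similarity_gaussian(
            bins, ci_method=cfg.ci_method, n_boot=cfg.n_boot, seed=seed
        )
    except FitError as err:
        logger.warning("similarity-curve fit failed: %s", err)
        gaussian = None
        qc.append({"subject_id": "", "scope": "group", "flag": "gaussian_fit_failed", "detail": str(err)})

    fits = fit_integration_regression(augmented, min_trials=cfg.min_trials)
    for _, row in fits[fits["status"] != "ok"].iterrows():
        qc.append(
            {
                "subject_id": row["subject_id"],
                "scope": f"{row['similarity']}/{row['emotion']}",
                "flag": f"regression_{row['status']}",
                "detail": f"n={row['n_trials']}",
            }
        )
    reliance = reliance_scores(fits)
    logger.info("regression fits: %d rows (%d ok)", len(fits), len(reliance))

    cov_z = None
    if covariates is not None and len(covariates):
        cov_z = covariates.set_index("subject_id")[
            [c for c in ("aq", "tas", "depression", "anxiety", "stress") if c in covariates.columns]
        ]

    rows: list[dict] = []
    ancovas: dict[str, AncovaResult] = {}

    # --- behavioral summaries -------------------------------------------------
    acc_wide = accuracy.overall.pivot(index="subject_id", columns="modality", values="accuracy")
    if {"face", "voice"} <= set(acc_wide.columns):
        res = paired_t(acc_wide["face"].to_numpy(), acc_wide["voice"].to_numpy())
        rows.append(_stat_row("accuracy_face_vs_voice", "paired_t", res.t, res.df, None,
                              res.p, res.mean_diff, res.n))

    cond = summary.condition_means
    level_means = cond.pivot_table(index="subject_id", columns="level", values="mean_rating")
    for a, b in (("strong", "weak"), ("weak", "neutral")):
        if {a, b} <= set(level_means.columns):
            res = paired_t(level_means[a].to_numpy(), level_means[b].to_numpy())
            rows.append(_stat_row(f"rating_{a}_vs_{b}", "paired_t", res.t, res.df, None,
                                  res.p, res.mean_diff, res.n))
    emo_modal = cond[cond["level"].isin(["weak", "strong"])].pivot_table(
        index="subject_id", columns=["modality", "rated_emotion"], values="mean_rating"
    )
    for emotion in ("angry", "happy"):
        if ("face", emotion) in emo_modal.columns and ("voice", emotion) in emo_modal.columns:
            res = paired_t(
                emo_modal[("face", emotion)].to_numpy(), emo_modal[("voice", emotion)].to_numpy()
            )
            rows.append(_stat_row(f"rating_{emotion}_face_vs_voice", "paired_t", res.t, res.df,
                                  None, res.p, res.mean_diff, res.n))

    # --- unity cut-offs -------------------------------------------------------
    by_emotion = cutoffs[cutoffs["scope"].isin(["angry", "happy"])]
    if len(by_emotion):
        tau_wide = by_emotion.pivot(index="subject_id", columns="scope", values="tau")
        if {"angry", "happy"} <= set(tau_wide.columns):
            try:
                res = within_ancova(
                    tau_wide,
                    contrast={"happy": 1.0, "angry": -1.0},
                    covariates=cov_z,
                    effect="cutoff_emotion",
                )
                ancovas["cutoff_emotion"] = res
                rows.extend(_ancova_rows("cutoff_emotion", res))
            except EmofusionError as err:
                logger.warning("cutoff ANCOVA skipped: %s", err)

    # --- reliance and unisensory degree --------------------------------------
    for value, label in (("reliance", "reliance"), ("unisensory_degree", "unisensory_degree")):
        wide = _reliance_cells(reliance, value)
        if len(wide.columns) < 4:
            logger.warning("%s ANCOVA skipped: incomplete 2x2 cells", label)
            continue
        cells = list(wide.columns)
        effects = {
            f"{label}_emotion": main_effect_contrast(cells, factor=1, positive_level="happy"),
            f"{label}_similarity": main_effect_contrast(cells, factor=0, positive_level="similar"),
            f"{label}_emotion_x_similarity": interaction_contrast(cells, ("similar", "happy")),
        }
        for name, contrast in effects.items():
            try:
                res = within_ancova(wide, contrast=contrast, covariates=cov_z, effect=name)
                ancovas[name] = res
                rows.extend(_ancova_rows(name, res))
            except EmofusionError as err:
                logger.warning("%s ANCOVA skipped: %s", name, err)

    rel_emotion = reliance[(reliance["similarity"] == "pooled")
                           & reliance["emotion"].isin(["angry", "happy"])]
    rel_wide = rel_emotion.pivot(index="subject_id", columns="emotion", values="reliance").dropna()
    if {"angry", "happy"} <= set(rel_wide.columns) and len(rel_wide) >= 2:
        res = paired_t(rel_wide["angry"].to_numpy(), rel_wide["happy"].to_numpy())
        rows.append(_stat_row("reliance_angry_vs_happy", "paired_t", res.t, res.df, None,
                              res.p, res.mean_diff, res.n))
    rel_sim = reliance[(reliance["emotion"] == "pooled")
                       & reliance["similarity"].isin(["similar", "not_similar"])]
    sim_wide = rel_sim.pivot(index="subject_id", columns="similarity", values="reliance").dropna()
    if {"similar", "not_similar"} <= set(sim_wide.columns) and len(sim_wide) >= 2:
        res = paired_t(sim_wide["similar"].to_numpy(), sim_wide["not_similar"].to_numpy())
        rows.append(_stat_row("reliance_similar_vs_not_similar", "paired_t", res.t, res.df,
                              None, res.p, res.mean_diff, res.n))

    # --- covariate correlations and the reliability-weighted model ------------
    if cov_z is not None and "aq" in cov_z.columns:
        for emotion in ("angry", "happy"):
            sub = reliance[(reliance["similarity"] == "pooled") & (reliance["emotion"] == emotion)]
            joined = sub.set_index("subject_id")[["reliance"]].join(cov_z[["aq"]], how="inner").dropna()
            if len(joined) >= 3:
                try:
                    res = pearson(joined["aq"].to_numpy(), joined["reliance"].to_numpy())
                    rows.append(_stat_row(f"aq_vs_reliance_{emotion}", "pearson_r", res.r,
                                          res.n - 2, None, res.p, res.r, res.n))
                except InsufficientVarianceError as err:
                    logger.warning("AQ correlation (%s) skipped: %s", emotion, err)

    for emotion in ("pooled", "angry", "happy"):
        try:
            res, pairs = reliability_correlation(accuracy, reliance, emotion=emotion)
            rows.append(_stat_row(f"reliability_model_{emotion}", "pearson_r", res.r,
                                  res.n - 2, None, res.p, res.r, res.n))
        except (InsufficientDataError, InsufficientVarianceError) as err:
            logger.warning("reliability correlation (%s) skipped: %s", emotion, err)

    report = pd.DataFrame(rows)
    if len(report):
        report["note"] = report["note"].fillna("")
    return AnalysisResults(
        accuracy=accuracy,
        summary=summary,
        augmented=augmented,
        cutoffs=cutoffs,
        bins=bins,
        gaussian=gaussian,
        fits=fits,
        reliance=reliance,
        stats_report=report,
        ancovas=ancovas,
        qc=qc,
    )
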