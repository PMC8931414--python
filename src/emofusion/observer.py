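"""Synthetic observers for the audiovisual emotion-rating task.

Generative model
----------------
Each simulated subject carries a table of latent intensity means ``mu`` indexed
by (modality, rated emotion, level).  A unisensory trial draws a latent percept
``x = mu + Normal(0, sigma_modality)`` and reports ``clamp(round(x), 1, 7)``
(round half away from zero), with a small lapse probability of a uniform
random rating.

On a multisensory trial the subject draws undiscretized face and voice
percepts ``x_v, x_a`` the same way.  The similar / not-similar judgment is
gated by the latent percept difference ``d = x_v - x_a``:

* ``gaussian`` rule: ``P(similar) = a * exp(-((d - b) / c)**2)`` — a scaled
  Gaussian profile with amplitude ``a``, a face-positive center ``b`` and
  width ``c``;
* ``threshold`` rule: similar iff ``|d| <= tau`` (a hard unity criterion).

The unity state then selects fusion weights: the reported intensity is
``clamp(round(w_v * x_v + w_a * x_a + c0 + Normal(0, sigma_m)), 1, 7)`` with
weights that may differ by unity state and emotion.  Validation (emotion
identification) responses are correct with a per-condition probability,
errors spread uniformly over the remaining options.

Population sampling plants between-subject variation around the group means
and can couple questionnaire covariates to weight contrasts (for example an
anxiety effect on the emotion-by-unity reliance contrast) with configurable
linear coefficients, which recovery tests then try to detect.

Random streams are split per subject and per block with ``SeedSequence`` spawn
keys, so enlarging the population never perturbs existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import design as design_mod
from .design import (
    EMOTIONS,
    LEVELS,
    MODALITIES,
    DesignConfig,
    StimulusInventory,
    enumerate_multisensory_trials,
    enumerate_stimuli,
    enumerate_unisensory_trials,
    enumerate_validation_trials,
)
from .exceptions import ConfigurationError

UNITY_STATES = ("unified", "segregated")
VALIDATION_CHOICES = ("angry", "happy", "neutral", "none")
RATING_MIN, RATING_MAX = 1, 7

#: Group-level recognition accuracies per (modality, stimulus emotion, level).
DEFAULT_ACCURACY = {
    ("face", "angry", "strong"): 0.792,
    ("face", "angry", "weak"): 0.677,
    ("face", "happy", "strong"): 0.979,
    ("face", "happy", "weak"): 0.844,
    ("face", "neutral", "neutral"): 0.927,
    ("voice", "angry", "strong"): 0.938,
    ("voice", "angry", "weak"): 0.667,
    ("voice", "happy", "strong"): 0.641,
    ("voice", "happy", "weak"): 0.531,
    ("voice", "neutral", "neutral"): 0.953,
}

_COVARIATES = ("aq", "tas", "depression", "anxiety", "stress")

#: (mean, sd, lower, upper) of questionnaire totals in a nonclinical sample.
DEFAULT_COVARIATE_DISTS = {
    "aq": (17.0, 6.0, 0.0, 50.0),
    "tas": (45.0, 10.0, 20.0, 100.0),
    "depression": (8.0, 6.0, 0.0, 42.0),
    "anxiety": (6.0, 5.0, 0.0, 42.0),
    "stress": (10.0, 7.0, 0.0, 42.0),
}


def likert_discretize(x: np.ndarray) -> np.ndarray:
    """Round half away from zero, then clamp onto the 1..7 scale."""
    x = np.asarray(x, dtype=float)
    rounded = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return np.clip(rounded, RATING_MIN, RATING_MAX).astype(int)


@dataclass
class ObserverParams:
    """Generative parameters of one simulated subject."""

    subject_id: str
    mu: Mapping[tuple[str, str, str], float]  # (modality, rated_emotion, level) -> mean
    sigma_v: float = 0.3
    sigma_a: float = 0.3
    sim_rule: str = "gaussian"  # "gaussian" | "threshold"
    sim_a: float = 0.86
    sim_b: float = 0.21
    sim_c: float = 0.88
    sim_tau: float = 2.5
    w: Mapping[tuple[str, str], tuple[float, float, float]] = field(default_factory=dict)
    sigma_m: float = 0.5
    acc: Mapping[tuple[str, str, str], float] = field(default_factory=lambda: dict(DEFAULT_ACCURACY))
    lapse: float = 0.0
    #: Per-stimulus latent-intensity offsets (material heterogeneity within a
    #: condition); keyed by stimulus id, shared across subjects in a dataset.
    stimulus_offsets: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 <= self.sim_a <= 1.0:
            raise ConfigurationError(f"{self.subject_id}: sim_a must be in [0, 1]")
        if self.sim_c <= 0:
            raise ConfigurationError(f"{self.subject_id}: sim_c must be > 0")
        if self.sim_rule not in ("gaussian", "threshold"):
            raise ConfigurationError(f"{self.subject_id}: unknown sim_rule {self.sim_rule!r}")
        if self.sim_rule == "threshold" and self.sim_tau < 0:
            raise ConfigurationError(f"{self.subject_id}: sim_tau must be >= 0")
        for name in ("sigma_v", "sigma_a", "sigma_m"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{self.subject_id}: {name} must be >= 0")
        if not 0.0 <= self.lapse <= 1.0:
            raise ConfigurationError(f"{self.subject_id}: lapse must be in [0, 1]")
        for key, p in self.acc.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{self.subject_id}: acc{key} outside [0, 1]")
        for key in [(u, e) for u in UNITY_STATES for e in EMOTIONS]:
            if key not in self.w:
                raise ConfigurationError(f"{self.subject_id}: missing fusion weights for {key}")

    def p_similar(self, d: np.ndarray) -> np.ndarray:
        """Probability of a 'similar' judgment given the latent percept difference."""
        d = np.asarray(d, dtype=float)
        if self.sim_rule == "threshold":
            return (np.abs(d) <= self.sim_tau).astype(float)
        return self.sim_a * np.exp(-(((d - self.sim_b) / self.sim_c) ** 2))


@dataclass
class CovariateRecord:
    """Questionnaire totals of one subject."""

    subject_id: str
    aq: float
    tas: float
    depression: float
    anxiety: float
    stress: float


@dataclass
class CovariateEffect:
    """A planted linear link from a z-scored covariate to a weight contrast.

    ``contrast`` is one of ``mean``, ``emotion``, ``similarity`` or
    ``emotion_x_similarity``; the covariate shifts each (unity state, emotion)
    reliance cell by ``coef * z * h`` where ``h`` is the cell's contrast sign
    (happy/unified = +1, angry/segregated = -1, product for the interaction).
    """

    covariate: str
    contrast: str
    coef: float
    target: str = "reliance"

    def cell_sign(self, unity_state: str, emotion: str) -> float:
        s_e = 1.0 if emotion == "happy" else -1.0
        s_u = 1.0 if unity_state == "unified" else -1.0
        if self.contrast == "mean":
            return 1.0
        if self.contrast == "emotion":
            return s_e
        if self.contrast == "similarity":
            return s_u
        if self.contrast == "emotion_x_similarity":
            return s_e * s_u
        raise ConfigurationError(f"unknown contrast {self.contrast!r}")


@dataclass
class PopulationConfig:
    """Population distributions for :func:`sample_population`.

    Group means are anchored to the rating task's observed level means
    (neutral 1.78, weak 4.43, strong 5.99 Likert points, angry voices rated
    0.30 above angry faces), the group similarity curve (0.86, 0.21, 0.88)
    and reliance contrasts of -0.14 (angry) and +0.08 (happy).
    ``unity_reliance_offset`` can additionally shift reliance by unity state
    (+unified / -segregated); it defaults to zero.  Setting every ``*_sd``
    to zero collapses the population onto these means.
    """

    n_subjects: int = 48
    # latent intensity means per level, Likert points
    mu_neutral: float = 1.78
    mu_weak: float = 4.43
    mu_strong: float = 5.99
    angry_voice_offset: float = 0.30  # angry voices rated above angry faces
    subject_mu_sd: float = 0.5  # per-subject per-(modality, emotion) offset
    #: SD of per-stimulus intensity offsets (stimulus material heterogeneity
    #: within a condition, shared across subjects); gives the audiovisual
    #: intensity difference its quasi-continuous spread.
    stimulus_mu_sd: float = 0.4
    # unisensory trial-to-trial percept noise; most rating variance comes from
    # stimulus and subject heterogeneity, not trial noise
    sigma_v: float = 0.3
    sigma_a: float = 0.3
    # similarity-curve population
    sim_rule: str = "gaussian"
    sim_a_mean: float = 0.86
    sim_a_sd: float = 0.05
    sim_b_mean: float = 0.21
    sim_b_sd: float = 0.30
    sim_c_mean: float = 0.88
    sim_c_sd: float = 0.20
    sim_c_min: float = 0.30
    sim_tau_mean: float = 2.5
    sim_tau_sd: float = 0.7
    sim_tau_bounds: tuple[float, float] = (0.5, 5.5)
    # fusion weights: reliance = w_v - w_a with w_v + w_a = 1
    reliance_angry: float = -0.14
    reliance_happy: float = 0.08
    unity_reliance_offset: float = 0.0  # optional +unified / -segregated shift
    reliance_sd: float = 0.20
    intercept_mean: float = 0.0
    intercept_sd: float = 0.0
    sigma_m: float = 0.5
    lapse: float = 0.02
    # validation accuracy jitter: Beta concentration (0 disables jitter)
    acc_means: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_ACCURACY)
    )
    acc_kappa: float = 12.0
    covariate_dists: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_DISTS)
    )
    covariate_effects: Sequence[CovariateEffect] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        for name in (
            "subject_mu_sd", "stimulus_mu_sd", "sigma_v", "sigma_a", "sim_a_sd", "sim_b_sd",
            "sim_c_sd", "sim_tau_sd", "reliance_sd", "intercept_sd",
            "sigma_m", "acc_kappa",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.sim_rule not in ("gaussian", "threshold"):
            raise ConfigurationError(f"unknown sim_rule {self.sim_rule!r}")
        if not 0.0 <= self.lapse <= 1.0:
            raise ConfigurationError("lapse must be in [0, 1]")
        for name, (mean, sd, lo, hi) in self.covariate_dists.items():
            if name not in _COVARIATES:
                raise ConfigurationError(f"unknown covariate {name!r}")
            if sd < 0 or lo > hi:
                raise ConfigurationError(f"invalid distribution for covariate {name!r}")
        for eff in self.covariate_effects:
            if eff.covariate not in _COVARIATES:
                raise ConfigurationError(f"unknown covariate {eff.covariate!r} in effect")
            if eff.target != "reliance":
                raise ConfigurationError(f"unsupported effect target {eff.target!r}")
            eff.cell_sign("unified", "happy")  # validates the contrast name

    def level_mean(self, level: str) -> float:
        return {"neutral": self.mu_neutral, "weak": self.mu_weak, "strong": self.mu_strong}[level]


def _rng(seed: Union[int, np.random.SeedSequence, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def sample_population(
    config: Optional[PopulationConfig] = None,
    seed: Union[int, np.random.SeedSequence, None] = 0,
) -> list[tuple[ObserverParams, CovariateRecord]]:
    """Draw ``n_subjects`` generative parameter sets and covariate records.

    Per-subject streams are spawned from ``seed`` by subject index, so subject
    ``i`` is identical no matter how many subjects follow it.  Covariate
    effects use the population z-score of the covariate (its configured mean
    and SD), keeping planted coefficients independent of the sample drawn.
    """
    config = config or PopulationConfig()
    config.validate()
    base = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)

    out: list[tuple[ObserverParams, CovariateRecord]] = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=base.entropy, spawn_key=(*base.spawn_key, 0, i))
        )
        subject_id = f"S{i + 1:03d}"

        cov_vals = {}
        zs = {}
        for name in _COVARIATES:
            mean, sd, lo, hi = config.covariate_dists[name]
            raw = _trunc_normal(rng, mean, sd, lo, hi)
            cov_vals[name] = float(np.round(raw))
            zs[name] = (cov_vals[name] - mean) / sd if sd > 0 else 0.0
        covariates = CovariateRecord(subject_id=subject_id, **cov_vals)

        mu: dict[tuple[str, str, str], float] = {}
        for modality in MODALITIES:
            for emotion in EMOTIONS:
                offset = rng.normal(0.0, config.subject_mu_sd) if config.subject_mu_sd else 0.0
                for level in LEVELS:
                    m = config.level_mean(level) + offset
                    if (
                        modality == "voice"
                        and emotion == "angry"
                        and level in design_mod.EMOTIONAL_LEVELS
                    ):
                        m += config.angry_voice_offset
                    mu[(modality, emotion, level)] = float(np.clip(m, 1.0, 7.0))

        sim_a = _trunc_normal(rng, config.sim_a_mean, config.sim_a_sd, 0.0, 1.0)
        sim_b = float(rng.normal(config.sim_b_mean, config.sim_b_sd)) if config.sim_b_sd else config.sim_b_mean
        sim_c = _trunc_normal(rng, config.sim_c_mean, config.sim_c_sd, config.sim_c_min, np.inf)
        sim_tau = _trunc_normal(
            rng, config.sim_tau_mean, config.sim_tau_sd, *config.sim_tau_bounds
        )

        base_reliance = {"angry": config.reliance_angry, "happy": config.reliance_happy}
        w: dict[tuple[str, str], tuple[float, float, float]] = {}
        for unity_state in UNITY_STATES:
            for emotion in EMOTIONS:
                r = base_reliance[emotion]
                r += config.unity_reliance_offset * (1.0 if unity_state == "unified" else -1.0)
                for eff in config.covariate_effects:
                    r += eff.coef * zs[eff.covariate] * eff.cell_sign(unity_state, emotion)
                if config.reliance_sd:
                    r += rng.normal(0.0, config.reliance_sd)
                r = float(np.clip(r, -0.95, 0.95))
                c0 = float(rng.normal(config.intercept_mean, config.intercept_sd)) if config.intercept_sd else config.intercept_mean
                w[(unity_state, emotion)] = ((1.0 + r) / 2.0, (1.0 - r) / 2.0, c0)

        acc: dict[tuple[str, str, str], float] = {}
        for key, mean in config.acc_means.items():
            if config.acc_kappa > 0 and 0.0 < mean < 1.0:
                acc[key] = float(rng.beta(mean * config.acc_kappa, (1.0 - mean) * config.acc_kappa))
            else:
                acc[key] = float(mean)

        params = ObserverParams(
            subject_id=subject_id,
            mu=mu,
            sigma_v=config.sigma_v,
            sigma_a=config.sigma_a,
            sim_rule=config.sim_rule,
            sim_a=sim_a,
            sim_b=sim_b,
            sim_c=sim_c,
            sim_tau=sim_tau,
            w=w,
            sigma_m=config.sigma_m,
            acc=acc,
            lapse=config.lapse,
        )
        params.validate()
        out.append((params, covariates))
    return out


def _apply_lapse(rng: np.random.Generator, ratings: np.ndarray, lapse: float) -> np.ndarray:
    if lapse <= 0:
        return ratings
    mask = rng.random(len(ratings)) < lapse
    if mask.any():
        ratings = ratings.copy()
        ratings[mask] = rng.integers(RATING_MIN, RATING_MAX + 1, size=int(mask.sum()))
    return ratings


def simulate_unisensory(
    observer: ObserverParams,
    plan: pd.DataFrame,
    seed: Union[int, np.random.SeedSequence, np.random.Generator, None] = 0,
    record_latents: bool = False,
) -> pd.DataFrame:
    """Simulate the unisensory rating block for one observer."""
    rng = _rng(seed)
    n = len(plan)
    offsets = observer.stimulus_offsets
    mu = np.array(
        [
            observer.mu[(m, re, lv)] + offsets.get(sid, 0.0)
            for m, re, lv, sid in zip(
                plan["modality"], plan["rated_emotion"], plan["level"], plan["stimulus_id"]
            )
        ]
    )
    sigma = np.where(plan["modality"].to_numpy() == "face", observer.sigma_v, observer.sigma_a)
    x = mu + rng.normal(size=n) * sigma
    ratings = _apply_lapse(rng, likert_discretize(x), observer.lapse)

    out = plan.copy()
    out.insert(0, "subject_id", observer.subject_id)
    out["rating"] = ratings
    if record_latents:
        out["latent_x"] = x
    return out


def simulate_multisensory(
    observer: ObserverParams,
    plan: pd.DataFrame,
    seed: Union[int, np.random.SeedSequence, np.random.Generator, None] = 0,
    record_latents: bool = False,
) -> pd.DataFrame:
    """Simulate the multisensory block: unity-gated fusion plus similarity judgments."""
    rng = _rng(seed)
    n = len(plan)
    rated = plan["rated_emotion"].to_numpy()
    offsets = observer.stimulus_offsets
    mu_v = np.array(
        [
            observer.mu[("face", re, lv)] + offsets.get(fid, 0.0)
            for re, lv, fid in zip(rated, plan["face_level"], plan["face_id"])
        ]
    )
    mu_a = np.array(
        [
            observer.mu[("voice", re, lv)] + offsets.get(vid, 0.0)
            for re, lv, vid in zip(rated, plan["voice_level"], plan["voice_id"])
        ]
    )
    x_v = mu_v + rng.normal(size=n) * observer.sigma_v
    x_a = mu_a + rng.normal(size=n) * observer.sigma_a
    p_sim = observer.p_similar(x_v - x_a)
    unified = rng.random(n) < p_sim

    w_v = np.empty(n)
    w_a = np.empty(n)
    c0 = np.empty(n)
    for i in range(n):
        state = "unified" if unified[i] else "segregated"
        w_v[i], w_a[i], c0[i] = observer.w[(state, rated[i])]
    fused = w_v * x_v + w_a * x_a + c0 + rng.normal(size=n) * observer.sigma_m
    ratings = _apply_lapse(rng, likert_discretize(fused), observer.lapse)

    out = plan.copy()
    out.insert(0, "subject_id", observer.subject_id)
    out["rating"] = ratings
    out["similarity_judgment"] = np.where(unified, "similar", "not_similar")
    if record_latents:
        out["latent_x_v"] = x_v
        out["latent_x_a"] = x_a
        out["unity_state"] = np.where(unified, "unified", "segregated")
    return out


def simulate_validation(
    observer: ObserverParams,
    plan: pd.DataFrame,
    seed: Union[int, np.random.SeedSequence, np.random.Generator, None] = 0,
) -> pd.DataFrame:
    """Simulate the emotion-identification (validation) block."""
    rng = _rng(seed)
    n = len(plan)
    p = np.array(
        [observer.acc[(m, e, lv)] for m, e, lv in zip(plan["modality"], plan["emotion"], plan["level"])]
    )
    correct = rng.random(n) < p
    responses = []
    for i in range(n):
        truth = plan["emotion"].iloc[i]
        if correct[i]:
            responses.append(truth)
        else:
            others = [c for c in VALIDATION_CHOICES if c != truth]
            responses.append(others[rng.integers(len(others))])
    out = plan.copy()
    out.insert(0, "subject_id", observer.subject_id)
    out["validation_response"] = responses
    return out


@dataclass
class SimulatedDataset:
    """Trial tables, covariates and hidden truth for a simulated population."""

    unisensory: pd.DataFrame
    multisensory: pd.DataFrame
    validation: pd.DataFrame
    covariates: pd.DataFrame
    truth: pd.DataFrame
    inventory: StimulusInventory
    params: list[ObserverParams]


def _truth_rows(params: ObserverParams) -> list[dict]:
    rows = []

    def add(name: str, value: float) -> None:
        rows.append({"subject_id": params.subject_id, "parameter": name, "value": value})

    for name in ("sigma_v", "sigma_a", "sigma_m", "sim_a", "sim_b", "sim_c", "sim_tau", "lapse"):
        add(name, getattr(params, name))
    for (state, emotion), (w_v, w_a, c0) in sorted(params.w.items()):
        add(f"reliance_{state}_{emotion}", w_v - w_a)
        add(f"intercept_{state}_{emotion}", c0)
    for (modality, emotion, level), m in sorted(params.mu.items()):
        add(f"mu_{modality}_{emotion}_{level}", m)
    for (modality, emotion, level), p in sorted(params.acc.items()):
        add(f"acc_{modality}_{emotion}_{level}", p)
    for sid, off in sorted(params.stimulus_offsets.items()):
        add(f"stim_offset_{sid}", off)
    return rows


def simulate_dataset(
    pop_config: Optional[PopulationConfig] = None,
    design_config: Optional[DesignConfig] = None,
    seed: int = 0,
    record_latents: bool = False,
) -> SimulatedDataset:
    """Simulate a full study: population, per-subject plans, all three blocks.

    Trial order is re-randomized per subject; per-subject, per-block random
    streams are spawned from ``seed``.
    """
    pop_config = pop_config or PopulationConfig()
    inventory = enumerate_stimuli(design_config)
    base = np.random.SeedSequence(seed)
    population = sample_population(pop_config, seed=base)

    # stimulus-material offsets are a property of the stimulus set: drawn once
    # per dataset and shared by every subject
    offsets: dict[str, float] = {}
    if pop_config.stimulus_mu_sd > 0:
        stim_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=base.entropy, spawn_key=(*base.spawn_key, 1, 0))
        )
        for spec in inventory.unisensory:
            offsets[spec.stimulus_id] = float(stim_rng.normal(0.0, pop_config.stimulus_mu_sd))
    for params, _ in population:
        params.stimulus_offsets = offsets

    uni_frames, multi_frames, valid_frames, truth_rows = [], [], [], []
    cov_rows = []
    for i, (params, cov) in enumerate(population):
        def stream(block: int) -> np.random.SeedSequence:
            return np.random.SeedSequence(entropy=base.entropy, spawn_key=(*base.spawn_key, i + 2, block))

        order_rng = np.random.default_rng(stream(0))
        uni_plan = enumerate_unisensory_trials(inventory, seed=int(order_rng.integers(2**31)))
        multi_plan = enumerate_multisensory_trials(inventory, seed=int(order_rng.integers(2**31)))
        valid_plan = enumerate_validation_trials(inventory, seed=int(order_rng.integers(2**31)))

        uni_frames.append(simulate_unisensory(params, uni_plan, stream(1), record_latents))
        multi_frames.append(simulate_multisensory(params, multi_plan, stream(2), record_latents))
        valid_frames.append(simulate_validation(params, valid_plan, stream(3)))
        cov_rows.append(asdict(cov))
        truth_rows.extend(_truth_rows(params))

    return SimulatedDataset(
        unisensory=pd.concat(uni_frames, ignore_index=True),
        multisensory=pd.concat(multi_frames, ignore_index=True),
        validation=pd.concat(valid_frames, ignore_index=True),
        covariates=pd.DataFrame(cov_rows),
        truth=pd.DataFrame(truth_rows),
        inventory=inventory,
        params=[p for p, _ in population],
    )
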