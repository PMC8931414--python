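"""Factorial stimulus inventory and trial plans for the audiovisual emotion-rating task.

The experiment this package models crosses dynamic face videos and emotional
voice clips of two emotions (angry, happy) at three intensity levels (neutral,
weak, strong), two actors per gender and two genders.  Unisensory stimuli are
rated for emotional intensity on a 7-point Likert scale; audiovisual stimuli
combine a face and a voice of the same gender (and, unless neutral, the same
emotion category) and additionally receive a binary similar / not-similar
judgment.  This module enumerates the stimulus sets and the per-subject trial
plans, and exposes the frame-timing rule used to stretch a face video over a
voice clip.

With the default configuration the inventory holds 20 faces, 20 voices and 144
audiovisual combinations; the unisensory block has 96 trials and the
multisensory block 144.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, TimingError

EMOTIONS = ("angry", "happy")
LEVELS = ("neutral", "weak", "strong")
EMOTIONAL_LEVELS = ("weak", "strong")
GENDERS = ("female", "male")
MODALITIES = ("face", "voice")

#: Face morph sequences: 30 frames to the full expression, 15 frames to the
#: half-way expression, a single static frame for neutral.
FRAMES_BY_LEVEL = {"strong": 30, "weak": 15, "neutral": 1}

#: The final face frame is held for this long so the video does not end abruptly.
FINAL_FRAME_HOLD_S = 0.5

DEFAULT_FACE_ACTORS = {"female": ("F02", "F09"), "male": ("M06", "M11")}
DEFAULT_VOICE_ACTORS = {"female": ("F08", "F14"), "male": ("M03", "M15")}


@dataclass(frozen=True)
class StimulusSpec:
    """One unisensory stimulus (a face video or a voice clip)."""

    stimulus_id: str
    modality: str  # "face" | "voice"
    emotion: str  # "angry" | "happy" | "neutral"
    level: str  # "neutral" | "weak" | "strong"
    actor: str
    gender: str
    voice_duration_s: Optional[float] = None  # voices only
    n_frames: Optional[int] = None  # faces only

    def __post_init__(self) -> None:
        if (self.level == "neutral") != (self.emotion == "neutral"):
            raise ConfigurationError(
                f"{self.stimulus_id}: level is neutral iff emotion is neutral"
            )
        if self.modality == "face" and self.n_frames not in (1, 15, 30):
            raise ConfigurationError(f"{self.stimulus_id}: n_frames must be 1, 15 or 30")
        if self.modality == "face" and (self.n_frames == 1) != (self.level == "neutral"):
            raise ConfigurationError(f"{self.stimulus_id}: single-frame iff neutral")


@dataclass(frozen=True)
class AudiovisualSpec:
    """A face-voice pairing together with the emotion dimension it is rated on.

    Fully neutral pairings occur twice in the inventory, once per rated
    emotion, so that each audiovisual stimulus carries a well-defined rating
    question and the inventory decomposes as
    2 emotions x 9 level pairings x 4 actor pairings x 2 genders = 144.
    """

    stimulus_id: str
    face_id: str
    voice_id: str
    rated_emotion: str  # "angry" | "happy"
    gender: str
    face_level: str
    voice_level: str
    face_actor: str
    voice_actor: str
    voice_duration_s: float
    n_frames: int


@dataclass
class DesignConfig:
    """Parameters of the factorial design.

    ``voice_durations`` may pin the duration of individual voice clips by
    stimulus id; otherwise durations are drawn once from a truncated normal
    (mean 1.69 s, SD 0.31 s, floor ``voice_duration_min``) using
    ``duration_seed``.
    """

    face_actors: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {g: list(a) for g, a in DEFAULT_FACE_ACTORS.items()}
    )
    voice_actors: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {g: list(a) for g, a in DEFAULT_VOICE_ACTORS.items()}
    )
    voice_duration_mean: float = 1.69
    voice_duration_sd: float = 0.31
    voice_duration_min: float = 0.6
    voice_durations: Optional[Mapping[str, float]] = None
    duration_seed: int = 0

    def validate(self) -> None:
        for name, actors in (("face_actors", self.face_actors), ("voice_actors", self.voice_actors)):
            if set(actors) != set(GENDERS):
                raise ConfigurationError(f"{name} must map exactly the genders {GENDERS}")
            for g in GENDERS:
                ids = list(actors[g])
                if len(ids) < 1 or len(ids) != len(set(ids)):
                    raise ConfigurationError(f"{name}[{g!r}] needs >= 1 distinct actor ids")
        if self.voice_duration_sd < 0:
            raise ConfigurationError("voice_duration_sd must be >= 0")
        if self.voice_duration_min <= FINAL_FRAME_HOLD_S:
            raise ConfigurationError(
                f"voice_duration_min must exceed the {FINAL_FRAME_HOLD_S} s final-frame hold"
            )


@dataclass
class StimulusInventory:
    """The enumerated stimulus sets, indexable by stimulus id."""

    faces: list[StimulusSpec]
    voices: list[StimulusSpec]
    audiovisual: list[AudiovisualSpec]

    def __post_init__(self) -> None:
        self.by_id: dict[str, object] = {}
        for spec in [*self.faces, *self.voices, *self.audiovisual]:
            if spec.stimulus_id in self.by_id:
                raise ConfigurationError(f"duplicate stimulus id {spec.stimulus_id}")
            self.by_id[spec.stimulus_id] = spec

    @property
    def unisensory(self) -> list[StimulusSpec]:
        return [*self.faces, *self.voices]

    def unisensory_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stimulus_id": s.stimulus_id,
                "modality": s.modality,
                "emotion": s.emotion,
                "level": s.level,
                "actor": s.actor,
                "gender": s.gender,
                "voice_duration_s": s.voice_duration_s,
                "n_frames": s.n_frames,
            }
            for s in self.unisensory
        ]
        return pd.DataFrame(rows)

    def audiovisual_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stimulus_id": s.stimulus_id,
                "modality": "audiovisual",
                "face_id": s.face_id,
                "voice_id": s.voice_id,
                "rated_emotion": s.rated_emotion,
                "gender": s.gender,
                "face_level": s.face_level,
                "voice_level": s.voice_level,
                "face_actor": s.face_actor,
                "voice_actor": s.voice_actor,
                "voice_duration_s": s.voice_duration_s,
                "n_frames": s.n_frames,
            }
            for s in self.audiovisual
        ]
        return pd.DataFrame(rows)


def _conditions() -> list[tuple[str, str]]:
    """The five (emotion, level) stimulus conditions per modality."""
    conds = [(e, lv) for e in EMOTIONS for lv in EMOTIONAL_LEVELS]
    conds.append(("neutral", "neutral"))
    return conds


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lower: float) -> float:
    if sd == 0:
        return max(mean, lower)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= lower:
            return float(x)
    return lower


def enumerate_stimuli(config: Optional[DesignConfig] = None) -> StimulusInventory:
    """Enumerate the face, voice and audiovisual stimulus sets.

    Returns an inventory with ``(2 genders x n_actors x 5 conditions)`` faces
    and voices, and ``2 x 9 x (n_face_actors x n_voice_actors) x 2`` audiovisual
    pairings.  Defaults reproduce the 20 / 20 / 144 design.
    """
    config = config or DesignConfig()
    config.validate()
    rng = np.random.default_rng(config.duration_seed)

    faces: list[StimulusSpec] = []
    for gender in GENDERS:
        for actor in config.face_actors[gender]:
            for emotion, level in _conditions():
                faces.append(
                    StimulusSpec(
                        stimulus_id=f"face_{emotion}_{level}_{actor}",
                        modality="face",
                        emotion=emotion,
                        level=level,
                        actor=actor,
                        gender=gender,
                        n_frames=FRAMES_BY_LEVEL[level],
                    )
                )

    voices: list[StimulusSpec] = []
    for gender in GENDERS:
        for actor in config.voice_actors[gender]:
            for emotion, level in _conditions():
                sid = f"voice_{emotion}_{level}_{actor}"
                if config.voice_durations and sid in config.voice_durations:
                    dur = float(config.voice_durations[sid])
                else:
                    dur = _truncated_normal(
                        rng,
                        config.voice_duration_mean,
                        config.voice_duration_sd,
                        config.voice_duration_min,
                    )
                voices.append(
                    StimulusSpec(
                        stimulus_id=sid,
                        modality="voice",
                        emotion=emotion,
                        level=level,
                        actor=actor,
                        gender=gender,
                        voice_duration_s=dur,
                    )
                )

    face_by_key = {(s.gender, s.actor, s.level, s.emotion): s for s in faces}
    voice_by_key = {(s.gender, s.actor, s.level, s.emotion): s for s in voices}

    audiovisual: list[AudiovisualSpec] = []
    for rated in EMOTIONS:
        for gender in GENDERS:
            for face_level in LEVELS:
                for voice_level in LEVELS:
                    f_emo = rated if face_level != "neutral" else "neutral"
                    v_emo = rated if voice_level != "neutral" else "neutral"
                    for fa in config.face_actors[gender]:
                        for va in config.voice_actors[gender]:
                            face = face_by_key[(gender, fa, face_level, f_emo)]
                            voice = voice_by_key[(gender, va, voice_level, v_emo)]
                            audiovisual.append(
                                AudiovisualSpec(
                                    stimulus_id=f"av_{rated}_{face.stimulus_id}_{voice.stimulus_id}",
                                    face_id=face.stimulus_id,
                                    voice_id=voice.stimulus_id,
                                    rated_emotion=rated,
                                    gender=gender,
                                    face_level=face_level,
                                    voice_level=voice_level,
                                    face_actor=fa,
                                    voice_actor=va,
                                    voice_duration_s=voice.voice_duration_s,
                                    n_frames=face.n_frames,
                                )
                            )

    return StimulusInventory(faces=faces, voices=voices, audiovisual=audiovisual)


def _shuffled(df: pd.DataFrame, seed: Optional[int], block: str) -> pd.DataFrame:
    if len(df) and seed is not None:
        order = np.random.default_rng(seed).permutation(len(df))
        df = df.iloc[order]
    df = df.reset_index(drop=True)
    df.insert(0, "trial_index", np.arange(len(df)))
    df.insert(1, "block", block)
    return df


def enumerate_unisensory_trials(
    inventory: StimulusInventory, seed: Optional[int] = None
) -> pd.DataFrame:
    """Build the unisensory rating-block plan.

    Emotional stimuli appear twice (rated on their own emotion); neutral
    stimuli appear four times, twice per rated emotion.  The multiset of
    slots is fixed; only the order depends on ``seed``.
    """
    slots = []
    for s in inventory.unisensory:
        rated = EMOTIONS if s.emotion == "neutral" else (s.emotion,)
        for rated_emotion in rated:
            for rep in range(2):
                slots.append(
                    {
                        "stimulus_id": s.stimulus_id,
                        "modality": s.modality,
                        "emotion": s.emotion,
                        "level": s.level,
                        "rated_emotion": rated_emotion,
                        "repetition": rep,
                    }
                )
    return _shuffled(pd.DataFrame(slots), seed, "unisensory")


def enumerate_multisensory_trials(
    inventory: StimulusInventory, seed: Optional[int] = None
) -> pd.DataFrame:
    """Build the multisensory block plan: one slot per audiovisual stimulus.

    Fully neutral face-voice pairings occur under both rated emotions because
    they enter the inventory once per emotion.
    """
    slots = [
        {
            "stimulus_id": s.stimulus_id,
            "face_id": s.face_id,
            "voice_id": s.voice_id,
            "gender": s.gender,
            "face_level": s.face_level,
            "voice_level": s.voice_level,
            "rated_emotion": s.rated_emotion,
            "repetition": 0,
        }
        for s in inventory.audiovisual
    ]
    return _shuffled(pd.DataFrame(slots), seed, "multisensory")


def enumerate_validation_trials(
    inventory: StimulusInventory, seed: Optional[int] = None
) -> pd.DataFrame:
    """Build the stimulus-validation plan: each unisensory stimulus identified once."""
    slots = [
        {
            "stimulus_id": s.stimulus_id,
            "modality": s.modality,
            "emotion": s.emotion,
            "level": s.level,
        }
        for s in inventory.unisensory
    ]
    return _shuffled(pd.DataFrame(slots), seed, "validation")


def frame_duration(voice_duration_s: float, n_frames: int) -> int:
    """Milliseconds per face frame when a face video is stretched over a voice clip.

    The last frame is additionally held for 500 ms, so the morph sequence gets
    ``voice_duration_s - 0.5`` seconds split evenly over ``n_frames`` frames;
    the result is rounded to the nearest integer millisecond.  A 1.2 s voice
    over a 30-frame face gives (1200 - 500) / 30 = 23 ms.
    """
    if n_frames < 1:
        raise TimingError(f"n_frames must be >= 1, got {n_frames}")
    if voice_duration_s <= FINAL_FRAME_HOLD_S:
        raise TimingError(
            f"voice duration {voice_duration_s} s leaves no time for the frame "
            f"sequence after the {FINAL_FRAME_HOLD_S} s final-frame hold"
        )
    ms = (voice_duration_s - FINAL_FRAME_HOLD_S) * 1000.0 / n_frames
    return int(math.floor(ms + 0.5))
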