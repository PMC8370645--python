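"""Synthetic cohorts with the statistical structure of sliding-window
eye-movement feature signals.

Each generated signal is the sum of

* a smooth class-specific template (two low-frequency sinusoids with
  class-and-feature-specific frequencies and phases, amplitude
  ``class_effect_amplitude``) — so recordings of different document or
  sensitivity types are separable;
* a participant offset drawn once per (participant, feature) with standard
  deviation ``person_effect_sd`` — the biometric signature that makes person
  identification possible on clean data;
* AR(1) noise with coefficient ``ar_coefficient``, smoothed by a moving
  average over ``smoothing_window`` samples — emulating the strong temporal
  autocorrelation that sliding-window feature extraction induces.

Defaults mirror the structure of the public VR reading dataset: 20
participants, three document types (one recording per participant per type),
52 features of which the four wordbook counts are excluded from privacy and
utility computation, and a 0.5 s step; lengths are desk-scale (n = 512)
rather than recording-scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from ._rng import substream
from .data import FeatureCohort, FeatureSignal

__all__ = ["GeneratorSpec", "generate_cohort", "paper_shaped_preset", "PRESETS"]

_NAMED_FEATURES = (
    "fixation_rate", "fixation_duration_mean", "fixation_duration_sd",
    "saccade_rate", "saccade_amplitude_mean", "saccade_amplitude_sd",
    "ratio_large_saccade", "saccade_velocity_mean", "blink_rate",
    "blink_duration_mean", "pupil_diameter_mean", "pupil_diameter_sd",
)


def _feature_names(n_features: int) -> list:
    names = [f"wordbook_{i}" for i in range(1, 5)]
    names += list(_NAMED_FEATURES)
    names += [f"feature_{i:02d}" for i in range(len(names), n_features)]
    return names[:n_features]


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic cohort."""

    participants: int = 20
    classes: tuple = ("comics", "newspaper", "textbook")
    features: int = 52
    length: int = 512
    step_seconds: float = 0.5
    ar_coefficient: float = 0.95
    innovation_sd: float = 0.5
    person_effect_sd: float = 2.0
    class_effect_amplitude: float = 1.5
    smoothing_window: int = 10
    seed: int = 0
    #: recordings per participant; None means one recording per class, an int
    #: means that many sessions whose class labels cycle through ``classes``.
    sessions: int | None = None
    excluded_features: tuple = ()
    baseline: float = 10.0  # common offset keeping signal means away from zero

    def __post_init__(self) -> None:
        if self.participants < 2:
            raise ValueError("need at least 2 participants")
        if self.features < 1 or self.length < 1 or not self.step_seconds > 0:
            raise ValueError("invalid cohort dimensions")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.innovation_sd <= 0 or self.person_effect_sd < 0 \
                or self.class_effect_amplitude < 0 or self.smoothing_window < 0:
            raise ValueError("invalid noise/effect parameters")
        if self.length < self.smoothing_window + 1:
            raise ValueError("length must exceed smoothing_window")

    def recording_plan(self) -> list:
        """(recording_id, class_label) pairs for one participant."""
        if self.sessions is None:
            return [(cls, cls) for cls in self.classes]
        return [(f"s{j + 1}", self.classes[j % len(self.classes)])
                for j in range(self.sessions)]


def _ar1_smoothed(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    burn = 4 * spec.smoothing_window + 50
    innov = rng.normal(0.0, spec.innovation_sd, size=spec.length + burn)
    ar = lfilter([1.0], [1.0, -spec.ar_coefficient], innov)
    if spec.smoothing_window > 1:
        kernel = np.full(spec.smoothing_window, 1.0 / spec.smoothing_window)
        ar = np.convolve(ar, kernel, mode="same")
    return ar[burn:]


def generate_cohort(spec: GeneratorSpec) -> FeatureCohort:
    """Generate a cohort; bitwise reproducible under ``spec.seed``."""
    names = _feature_names(spec.features)
    t = np.arange(spec.length)
    signals = []
    plan = spec.recording_plan()
    templates: dict = {}
    for cls in {c for _, c in plan}:
        for fi, fname in enumerate(names):
            rng = substream(spec.seed, "template", cls, fname)
            f1, f2 = rng.uniform(0.5, 4.0, size=2)
            p1, p2 = rng.uniform(0.0, 2 * np.pi, size=2)
            templates[(cls, fname)] = spec.class_effect_amplitude * (
                np.sin(2 * np.pi * f1 * t / spec.length + p1)
                + 0.5 * np.sin(2 * np.pi * f2 * t / spec.length + p2))
    for p in range(1, spec.participants + 1):
        pid = f"p{p:02d}"
        for fname in names:
            offset_rng = substream(spec.seed, "person", pid, fname)
            offset = offset_rng.normal(0.0, spec.person_effect_sd) \
                if spec.person_effect_sd > 0 else 0.0
            for rid, cls in plan:
                noise = _ar1_smoothed(
                    spec, substream(spec.seed, "noise", pid, rid, fname))
                values = spec.baseline + templates[(cls, fname)] + offset + noise
                signals.append(FeatureSignal(pid, rid, cls, fname, values,
                                             spec.step_seconds))
    return FeatureCohort(signals, names, spec.excluded_features)


PRESETS = {
    # VR reading study shape: 20 participants x 3 document types = 60
    # recordings, 52 features (4 wordbook features excluded), 0.5 s step.
    "mpiidpeye_like": GeneratorSpec(
        participants=20,
        classes=("comics", "newspaper", "textbook"),
        features=52,
        step_seconds=0.5,
        excluded_features=tuple(f"wordbook_{i}" for i in range(1, 5)),
    ),
    # AR-style study shape: 17 participants x 3 sessions = 51 recordings with
    # binary scene-sensitivity labels, 1 s step.
    "mpiiprivaceye_like": GeneratorSpec(
        participants=17,
        classes=("sensitive", "nonsensitive"),
        sessions=3,
        features=52,
        step_seconds=1.0,
        excluded_features=tuple(f"wordbook_{i}" for i in range(1, 5)),
    ),
}


def paper_shaped_preset(name: str, **overrides) -> GeneratorSpec:
    """A :class:`GeneratorSpec` shaped like one of the public datasets."""
    try:
        spec = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") \
            from None
    return replace(spec, **overrides) if overrides else spec
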