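import numpy as np
import pytest

from eyedp.data import FeatureCohort, FeatureSignal
from eyedp.synthetic import GeneratorSpec, generate_cohort


def build_cohort(per_participant: dict, class_label: str = "reading",
                 step: float = 0.5, excluded=()) -> FeatureCohort:
    """Cohort from {participant: {feature: values}} with one recording each."""
    signals = []
    feature_names = []
    for pid, feats in per_participant.items():
        for fname, values in feats.items():
            if fname not in feature_names:
                feature_names.append(fname)
            signals.append(FeatureSignal(pid, "r1", class_label, fname,
                                         np.asarray(values, float), step))
    return FeatureCohort(signals, feature_names, excluded)


@pytest.fixture(scope="session")
def small_cohort() -> FeatureCohort:
    """5 participants x 2 classes x 3 features, n=96: fast desk-scale cohort."""
    spec = GeneratorSpec(participants=5, classes=("a", "b"), features=3,
                         length=96, smoothing_window=5, seed=42)
    return generate_cohort(spec)


@pytest.fixture()
def two_participant_cohort() -> FeatureCohort:
    return build_cohort({"p1": {"f": [1.0, 2.0]}, "p2": {"f": [4.0, 6.0]}})
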