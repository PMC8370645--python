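"""Domain types and CSV I/O for feature cohorts and private releases.

A *cohort* is the database in the differential-privacy sense: one real-valued
feature time series per (participant, recording, feature), where rows of the
on-disk CSV are sliding-window time steps and columns are named eye-movement
features (fixation, saccade, blink, pupil statistics and the like). Two
cohorts are *neighboring* when they differ in one participant's data.

CSV dialect: comma-separated, UTF-8, mandatory header row of feature names,
time ascending down rows, one file per (participant, recording). Class labels
(document type, privacy-sensitivity level, ...) are carried explicitly — via
the filename pattern or a sidecar manifest — never inferred from the values,
because mechanisms and sensitivities are applied separately per class.
Missing or non-numeric cells are rejected, not imputed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortFormatError",
    "DuplicateKeyError",
    "FeatureSignal",
    "FeatureCohort",
    "PrivateRelease",
    "CohortSchema",
    "load_cohort",
    "save_cohort",
    "save_release",
    "load_release",
    "apply_exclusions",
]


class CohortFormatError(ValueError):
    """Malformed input file: missing header, ragged rows, non-numeric cells, empty body."""


class DuplicateKeyError(ValueError):
    """Two signals share the same (participant, recording, feature) key."""


@dataclass(frozen=True)
class FeatureSignal:
    """One feature's time series for one recording of one participant."""

    participant_id: str
    recording_id: str
    class_label: str
    feature_name: str
    values: np.ndarray
    step_seconds: float

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 1:
            raise CohortFormatError(
                f"signal {self.key} must be a 1-D sequence of length >= 1"
            )
        if not np.all(np.isfinite(vals)):
            raise CohortFormatError(f"signal {self.key} contains non-finite values")
        if not self.step_seconds > 0:
            raise ValueError("step_seconds must be positive")

    @property
    def key(self) -> tuple:
        return (self.participant_id, self.recording_id, self.feature_name)

    @property
    def n(self) -> int:
        return int(self.values.size)


class FeatureCohort:
    """A collection of feature signals with a fixed feature-name order.

    Key uniqueness and per-(feature, class) step-size consistency are enforced
    at construction. ``excluded_features`` marks features (e.g. the wordbook
    counts whose minima are all zero) that are dropped from every downstream
    sensitivity, utility and privacy computation while remaining on disk.
    """

    def __init__(self, signals, feature_names=None, excluded_features=()):
        self._signals: dict = {}
        names_seen: list = []
        step_by_feature_class: dict = {}
        for sig in signals:
            if sig.key in self._signals:
                raise DuplicateKeyError(f"duplicate signal key {sig.key}")
            fc = (sig.feature_name, sig.class_label)
            prev = step_by_feature_class.setdefault(fc, sig.step_seconds)
            if prev != sig.step_seconds:
                raise ValueError(
                    f"inconsistent step_seconds for feature {sig.feature_name!r} "
                    f"in class {sig.class_label!r}"
                )
            self._signals[sig.key] = sig
            if sig.feature_name not in names_seen:
                names_seen.append(sig.feature_name)
        if feature_names is None:
            feature_names = names_seen
        else:
            feature_names = list(feature_names)
            unknown = set(names_seen) - set(feature_names)
            if unknown:
                raise ValueError(f"signals reference unlisted features: {sorted(unknown)}")
        self.feature_names = feature_names
        excluded = list(excluded_features)
        bad = set(excluded) - set(feature_names)
        if bad:
            raise KeyError(f"excluded features not in feature_names: {sorted(bad)}")
        self.excluded_features = excluded

    # -- accessors -----------------------------------------------------------
    @property
    def signals(self) -> list:
        return list(self._signals.values())

    @property
    def active_features(self) -> list:
        return [f for f in self.feature_names if f not in self.excluded_features]

    @property
    def participants(self) -> list:
        return sorted({s.participant_id for s in self._signals.values()})

    @property
    def classes(self) -> list:
        return sorted({s.class_label for s in self._signals.values()})

    @property
    def recordings(self) -> list:
        """Sorted unique (participant_id, recording_id, class_label) triples."""
        return sorted({(s.participant_id, s.recording_id, s.class_label)
                       for s in self._signals.values()})

    def __len__(self) -> int:
        return len(self._signals)

    def get(self, participant_id, recording_id, feature_name) -> FeatureSignal:
        return self._signals[(participant_id, recording_id, feature_name)]

    def signals_for(self, feature_name=None, class_label=None) -> list:
        out = []
        for sig in self._signals.values():
            if feature_name is not None and sig.feature_name != feature_name:
                continue
            if class_label is not None and sig.class_label != class_label:
                continue
            out.append(sig)
        return out

    def recording_matrix(self, participant_id, recording_id, features=None):
        """Time-by-feature matrix for one recording (active features by default)."""
        features = list(features) if features is not None else self.active_features
        cols = [self.get(participant_id, recording_id, f).values for f in features]
        lengths = {c.size for c in cols}
        if len(lengths) != 1:
            raise ValueError(
                f"features of recording ({participant_id}, {recording_id}) "
                "have unequal lengths"
            )
        return np.column_stack(cols)

    def with_signals(self, signals) -> "FeatureCohort":
        return FeatureCohort(signals, self.feature_names, self.excluded_features)


@dataclass(frozen=True)
class PrivateRelease:
    """A noisy cohort together with full mechanism provenance.

    ``k_map`` and ``lambda_map`` are keyed ``(feature, class, scope)`` where
    scope is ``None`` for a whole-signal application or the chunk index for
    chunked mechanisms.
    """

    cohort: FeatureCohort
    mechanism: str
    epsilon: float
    chunk_size: int | None
    k_map: dict
    lambda_map: dict
    seed: int

    def __post_init__(self) -> None:
        if self.mechanism not in {"lpa", "fpa", "cfpa", "dcfpa"}:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class CohortSchema:
    """How on-disk files map to cohort keys.

    ``filename_regex`` must expose named groups ``participant``, ``recording``
    and ``label``; alternatively a JSON ``manifest`` (filename -> metadata)
    supplies them, which also overrides ``step_seconds`` per file. The on-disk
    layout of the public eye-movement datasets is not standardized, hence the
    configurable adapter.
    """

    filename_regex: str = r"^(?P<participant>[^_]+)_(?P<recording>[^_]+)_(?P<label>[^.]+)\.csv$"
    step_seconds: float = 0.5
    manifest: dict | None = None

    def resolve(self, path: Path) -> tuple:
        name = path.name
        if self.manifest is not None:
            try:
                meta = self.manifest[name]
            except KeyError:
                raise CohortFormatError(f"{name} not present in schema manifest") from None
            return (str(meta["participant"]), str(meta["recording"]), str(meta["label"]),
                    float(meta.get("step_seconds", self.step_seconds)))
        m = re.match(self.filename_regex, name)
        if m is None:
            raise CohortFormatError(
                f"filename {name!r} does not match schema pattern {self.filename_regex!r}"
            )
        return (m.group("participant"), m.group("recording"), m.group("label"),
                self.step_seconds)


def _read_feature_frame(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, header=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CohortFormatError(f"{path}: {exc}") from exc
    if df.shape[0] < 1:
        raise CohortFormatError(f"{path}: no data rows (n >= 1 required)")
    if any(str(c).startswith("Unnamed:") for c in df.columns):
        raise CohortFormatError(f"{path}: missing or incomplete header row")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = [str(c) for c in numeric.columns[numeric.isna().any()]]
        raise CohortFormatError(
            f"{path}: non-numeric or missing cells in columns {bad}"
        )
    return numeric


def load_cohort(paths, schema: CohortSchema | None = None,
                excluded_features=()) -> FeatureCohort:
    """Load one CSV per (participant, recording) into a cohort."""
    schema = schema or CohortSchema()
    signals = []
    feature_names: list | None = None
    seen_recordings = set()
    for path in map(Path, paths):
        participant, recording, label, step = schema.resolve(path)
        if (participant, recording) in seen_recordings:
            raise DuplicateKeyError(
                f"duplicate (participant, recording) = ({participant}, {recording})"
            )
        seen_recordings.add((participant, recording))
        df = _read_feature_frame(path)
        cols = [str(c) for c in df.columns]
        if feature_names is None:
            feature_names = cols
        elif cols != feature_names:
            raise CohortFormatError(
                f"{path}: feature columns {cols} differ from first file {feature_names}"
            )
        for name in cols:
            signals.append(FeatureSignal(participant, recording, label, name,
                                         df[name].to_numpy(float), step))
    return FeatureCohort(signals, feature_names, excluded_features)


def apply_exclusions(cohort: FeatureCohort, names) -> FeatureCohort:
    """Return a cohort with ``names`` added to the exclusion list.

    Excluded features are omitted from all downstream sensitivity, utility and
    privacy computation; the input cohort is left unmodified.
    """
    names = list(names)
    unknown = set(names) - set(cohort.feature_names)
    if unknown:
        raise KeyError(f"unknown feature names: {sorted(unknown)}")
    merged = cohort.excluded_features + [n for n in names
                                         if n not in cohort.excluded_features]
    return FeatureCohort(cohort.signals, cohort.feature_names, merged)


# -- serialization -----------------------------------------------------------

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def _scope_key(feature, class_label, scope) -> str:
    chunk = "-" if scope is None else str(scope)
    return f"{feature}::{class_label}::{chunk}"


def _parse_scope_key(key: str) -> tuple:
    feature, class_label, chunk = key.split("::")
    return feature, class_label, None if chunk == "-" else int(chunk)


def save_cohort(cohort: FeatureCohort, out_dir) -> Path:
    """Write one CSV per recording plus a cohort manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for participant, recording, label in cohort.recordings:
        fname = f"{participant}_{recording}_{label}.csv"
        mat = cohort.recording_matrix(participant, recording, cohort.feature_names)
        step = cohort.get(participant, recording, cohort.feature_names[0]).step_seconds
        pd.DataFrame(mat, columns=cohort.feature_names).to_csv(
            out_dir / fname, index=False, float_format=_FLOAT_FMT)
        files[fname] = {"participant": participant, "recording": recording,
                        "label": label, "step_seconds": step}
    manifest = {
        "feature_names": cohort.feature_names,
        "excluded_features": cohort.excluded_features,
        "files": files,
    }
    manifest_path = out_dir / "cohort_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def load_cohort_dir(in_dir) -> FeatureCohort:
    """Load a cohort written by :func:`save_cohort`."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "cohort_manifest.json").read_text())
    schema = CohortSchema(manifest=manifest["files"])
    cohort = load_cohort([in_dir / f for f in sorted(manifest["files"])], schema,
                         manifest["excluded_features"])
    if cohort.feature_names != manifest["feature_names"]:
        raise CohortFormatError("column order differs from cohort manifest")
    return cohort


def save_release(release: PrivateRelease, out_dir) -> Path:
    """Write noisy CSVs (source column order) plus a provenance manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_manifest = save_cohort(release.cohort, out_dir)
    manifest = {
        "mechanism": release.mechanism,
        "epsilon": release.epsilon,
        "chunk_size": release.chunk_size,
        "seed": release.seed,
        "excluded_features": release.cohort.excluded_features,
        "k_map": {_scope_key(*k): int(v) for k, v in release.k_map.items()},
        "lambda_map": {_scope_key(*k): float(v) for k, v in release.lambda_map.items()},
        "cohort_manifest": cohort_manifest.name,
    }
    manifest_path = out_dir / "release_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def load_release(in_dir) -> PrivateRelease:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "release_manifest.json").read_text())
    cohort = load_cohort_dir(in_dir)
    return PrivateRelease(
        cohort=cohort,
        mechanism=meta["mechanism"],
        epsilon=meta["epsilon"],
        chunk_size=meta["chunk_size"],
        k_map={_parse_scope_key(k): v for k, v in meta["k_map"].items()},
        lambda_map={_parse_scope_key(k): v for k, v in meta["lambda_map"].items()},
        seed=meta["seed"],
    )
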