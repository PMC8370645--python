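"""Differentially private release mechanisms for feature time series.

Four mechanisms share one calibration logic:

* **LPA** — Laplace perturbation: adds i.i.d. ``Lap(Delta_1 / epsilon)`` noise
  directly to the signal.
* **FPA** — Fourier perturbation: keeps the first ``k`` DFT coefficients
  (the ``k`` lowest frequencies), adds ``Lap(lambda)`` noise independently to
  the real and imaginary part of each retained coefficient with
  ``lambda = sqrt(n*k) * Delta_2 / epsilon``, zero-pads and inverts. The
  ``sqrt(n*k)`` factor is the corrected scale required by the proof chain
  ``Delta_1(F_hat) <= sqrt(k) * Delta_2(F_hat) <= sqrt(n*k) * Delta_2(X)``.
* **CFPA** — chunked FPA: FPA applied independently to disjoint chunks with
  per-chunk sensitivities; the whole-signal guarantee is ``epsilon`` by
  parallel composition over disjoint chunks.
* **DCFPA** — difference-and-chunk FPA: inside each chunk the consecutive
  differences (first element preserved) are privatized with FPA using
  difference-scheme sensitivities, then rebuilt by prefix sums. The prefix-sum
  reconstruction is post-processing of the released noisy differences and
  consumes no extra budget.

Query sensitivity is the max over participant pairs of the L1/L2 distance
between their per-feature observation vectors, computed per class; shorter
vectors are zero-padded to the maximum length.

The scikit-learn style estimators (:class:`LaplacePerturbation` and friends)
wrap the array-level functions: ``fit`` computes the sensitivity table (and
selects transform-coefficient counts when ``k="auto"``) from a cohort,
``transform`` draws the noisy release.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ._rng import substream
from .data import FeatureCohort, FeatureSignal, PrivateRelease
from .transforms import chunk_partition, difference_transform

logger = logging.getLogger(__name__)

__all__ = [
    "SensitivityTable",
    "NoiseScale",
    "laplace_sample",
    "sensitivity",
    "lpa",
    "fpa",
    "calibrate_fpa_lambda",
    "cfpa",
    "dcfpa",
    "select_k",
    "compose_epsilon",
    "LaplacePerturbation",
    "FourierPerturbation",
    "ChunkedFourierPerturbation",
    "DifferenceChunkedFourierPerturbation",
    "make_mechanism",
    "EPSILON_GRID",
    "CHUNK_SIZES",
]

#: The evaluation grid of privacy budgets, from most to least private.
EPSILON_GRID = (0.48, 2.4, 4.8, 24.0, 48.0)

#: Power-of-two chunk sizes for which fast DFTs exist.
CHUNK_SIZES = (32, 64, 128)


# -- sensitivity -------------------------------------------------------------

@dataclass(frozen=True)
class SensitivityEntry:
    delta1: float
    delta2: float
    length: int  # scope length n (max over the participant vectors)

    def __post_init__(self) -> None:
        if self.delta1 < 0 or self.delta2 < 0:
            raise ValueError("sensitivities must be non-negative")
        if self.delta1 < self.delta2 - 1e-9:
            raise ValueError("Delta_1 must dominate Delta_2")


@dataclass(frozen=True)
class SensitivityTable:
    """Per-(feature, class, scope) L1/L2 query sensitivities.

    ``scope`` is ``None`` for a whole-signal query or a chunk index for
    chunked mechanisms. ``scheme`` records whether distances were computed on
    raw signals or on (within-chunk) consecutive-difference signals.
    """

    entries: dict
    scheme: str = "raw"
    chunk_size: int | None = None

    def delta(self, feature, class_label, scope=None, w: int = 2) -> float:
        entry = self.entries[(feature, class_label, scope)]
        return entry.delta1 if w == 1 else entry.delta2

    def entry(self, feature, class_label, scope=None) -> SensitivityEntry:
        return self.entries[(feature, class_label, scope)]

    def scopes(self, feature, class_label) -> list:
        return sorted((s for f, c, s in self.entries
                       if f == feature and c == class_label),
                      key=lambda s: -1 if s is None else s)


@dataclass(frozen=True)
class NoiseScale:
    """A Laplace scale together with the rule that produced it."""

    lam: float
    derivation: str  # "lpa" (Delta_1/eps) or "fpa" (sqrt(n k) Delta_2 / eps)

    def __post_init__(self) -> None:
        if not (self.lam >= 0 and math.isfinite(self.lam)):
            raise ValueError("lambda must be finite and non-negative")


def _grouped_vectors(cohort: FeatureCohort, feature: str, class_label: str):
    sigs = cohort.signals_for(feature, class_label)
    if not sigs:
        raise KeyError(f"no signals for feature {feature!r}, class {class_label!r}")
    participants = [s.participant_id for s in sigs]
    if len(set(participants)) < 2:
        raise ValueError(
            f"sensitivity of ({feature!r}, {class_label!r}) needs >= 2 participants"
        )
    return sigs, participants


def sensitivity(cohort: FeatureCohort, chunk_size: int | None = None,
                scheme: str = "raw") -> SensitivityTable:
    """Max-over-participant-pairs L1 and L2 sensitivities per feature and class.

    For each (feature, class) the observation vectors of all participant pairs
    are compared; shorter vectors are zero-padded to the maximum length n.
    With ``chunk_size`` set, distances are computed per chunk of the common
    partition of ``[0, n)``. With ``scheme="difference"`` the
    consecutive-difference transform is applied first (inside chunks when
    chunked, matching how the difference mechanism releases data).
    """
    if scheme not in {"raw", "difference"}:
        raise ValueError(f"unknown scheme {scheme!r}")
    entries: dict = {}
    for class_label in cohort.classes:
        for feature in cohort.active_features:
            sigs, participants = _grouped_vectors(cohort, feature, class_label)
            n_max = max(s.n for s in sigs)
            mat = np.zeros((len(sigs), n_max))
            for i, s in enumerate(sigs):
                mat[i, : s.n] = s.values
            if chunk_size is None:
                scope_slices = {None: slice(0, n_max)}
            else:
                part = chunk_partition(n_max, chunk_size)
                scope_slices = {j: slice(s, e) for j, (s, e) in enumerate(part.boundaries)}
            if scheme == "difference":
                transformed = np.empty_like(mat)
                for sl in scope_slices.values():
                    transformed[:, sl] = np.apply_along_axis(
                        difference_transform, 1, mat[:, sl])
                mat = transformed
            pid = np.asarray(participants)
            pair_mask = pid[:, None] != pid[None, :]
            diff = mat[:, None, :] - mat[None, :, :]
            for scope, sl in scope_slices.items():
                block = diff[:, :, sl]
                l1 = np.abs(block).sum(axis=2)
                l2 = np.sqrt((block ** 2).sum(axis=2))
                entries[(feature, class_label, scope)] = SensitivityEntry(
                    float(l1[pair_mask].max()), float(l2[pair_mask].max()),
                    sl.stop - sl.start)
    return SensitivityTable(entries, scheme=scheme, chunk_size=chunk_size)


# -- noise primitives --------------------------------------------------------

def laplace_sample(lam: float, count: int, rng: np.random.Generator) -> np.ndarray:
    """``count`` i.i.d. draws from the zero-mean Laplace density with scale ``lam``.

    The density is ``(1 / 2 lam) exp(-|h| / lam)`` with variance ``2 lam^2``.
    """
    if not lam > 0:
        raise ValueError("lambda must be positive")
    if count < 1:
        raise ValueError("count must be >= 1")
    return rng.laplace(0.0, lam, size=count)


def calibrate_fpa_lambda(n: int, k: int, delta2: float, epsilon: float) -> NoiseScale:
    """Noise scale ``lambda = sqrt(n*k) * Delta_2 / epsilon`` for the FPA."""
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= {n}, got {k}")
    if not epsilon > 0:
        raise ValueError("epsilon must be positive")
    if delta2 < 0:
        raise ValueError("Delta_2 must be non-negative")
    return NoiseScale(math.sqrt(n * k) * delta2 / epsilon, "fpa")


def _warn_degenerate(delta_name: str) -> None:
    logger.warning("%s is zero: mechanism releases without perturbation noise",
                   delta_name)


# Batch cores: produce (reps, n) noisy outputs from a single rng so that the
# estimators (reps=1) and the repeated-evaluation utilities share one code path.

def _lpa_batch(x: np.ndarray, lam: float, rng, reps: int) -> np.ndarray:
    if lam == 0.0:
        return np.tile(x, (reps, 1))
    return x[None, :] + lam * rng.laplace(0.0, 1.0, size=(reps, x.size))


def _fpa_batch(x: np.ndarray, k: int, lam: float, rng, reps: int) -> np.ndarray:
    n = x.size
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= {n}, got {k}")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    coeffs = np.fft.fft(x)[:k]
    spectra = np.zeros((reps, n), dtype=complex)
    spectra[:, :k] = coeffs
    if lam > 0:
        noise = rng.laplace(0.0, 1.0, size=(reps, k, 2))
        spectra[:, :k] += lam * (noise[..., 0] + 1j * noise[..., 1])
    return np.fft.ifft(spectra, axis=1).real


def _cfpa_batch(x, epsilon, chunk_size, k_of, delta2_of, rng, reps) -> np.ndarray:
    part = chunk_partition(x.size, chunk_size)
    out = np.empty((reps, x.size))
    for j, (s, e) in enumerate(part.boundaries):
        c = e - s
        k_j = k_of(j, c)
        lam = calibrate_fpa_lambda(c, k_j, delta2_of(j), epsilon).lam
        out[:, s:e] = _fpa_batch(x[s:e], k_j, lam, rng, reps)
    return out


def _dcfpa_batch(x, epsilon, chunk_size, k_of, delta2_of, rng, reps) -> np.ndarray:
    part = chunk_partition(x.size, chunk_size)
    out = np.empty((reps, x.size))
    for j, (s, e) in enumerate(part.boundaries):
        c = e - s
        k_j = k_of(j, c)
        lam = calibrate_fpa_lambda(c, k_j, delta2_of(j), epsilon).lam
        noisy_diff = _fpa_batch(difference_transform(x[s:e]), k_j, lam, rng, reps)
        out[:, s:e] = np.cumsum(noisy_diff, axis=1)
    return out


def _resolve_k(k_spec, scope, length):
    """Map a k specification (int broadcast or per-scope mapping) to a chunk."""
    if isinstance(k_spec, dict):
        try:
            k = k_spec[scope]
        except KeyError:
            raise KeyError(f"no k for chunk scope {scope}") from None
        if not 1 <= k <= length:
            raise ValueError(f"k={k} out of range for chunk of length {length}")
        return int(k)
    return min(int(k_spec), length)


# -- array-level mechanisms --------------------------------------------------

def lpa(x, delta1: float, epsilon: float, rng) -> np.ndarray:
    """Laplace perturbation: ``x + Lap^n(Delta_1 / epsilon)``."""
    x = np.asarray(x, dtype=float)
    if delta1 < 0:
        raise ValueError("Delta_1 must be non-negative")
    if not epsilon > 0:
        raise ValueError("epsilon must be positive")
    if delta1 == 0:
        _warn_degenerate("Delta_1")
        return x.copy()
    return _lpa_batch(x, delta1 / epsilon, rng, 1)[0]


def fpa(x, k: int, lam: float, rng) -> np.ndarray:
    """Fourier perturbation of a single signal at an explicit noise scale.

    DFT, retain the first ``k`` coefficients, add independent ``Lap(lam)``
    noise to the real and the imaginary part of each, zero-pad, inverse DFT,
    real part.
    """
    x = np.asarray(x, dtype=float)
    return _fpa_batch(x, k, lam, rng, 1)[0]


def cfpa(x, epsilon: float, chunk_size: int, k, delta2_per_chunk, rng) -> np.ndarray:
    """Chunked FPA with per-chunk sensitivities and coefficient counts.

    ``k`` may be an int (clamped to each chunk length) or a mapping
    chunk-index -> k. ``delta2_per_chunk`` maps chunk index -> chunk-level
    ``Delta_2``. Each chunk j of length c_j is privatized with
    ``lambda_j = sqrt(c_j * k_j) * Delta_2_j / epsilon``; the whole signal is
    ``epsilon``-DP by parallel composition.
    """
    x = np.asarray(x, dtype=float)
    if not epsilon > 0:
        raise ValueError("epsilon must be positive")

    def delta2_of(j):
        try:
            return delta2_per_chunk[j]
        except (KeyError, IndexError):
            raise KeyError(f"missing Delta_2 for chunk {j}") from None

    return _cfpa_batch(x, epsilon, chunk_size,
                       lambda j, c: _resolve_k(k, j, c), delta2_of, rng, 1)[0]


def dcfpa(x, epsilon: float, chunk_size: int, k, delta2_per_chunk, rng) -> np.ndarray:
    """Difference-and-chunk FPA (within-chunk differencing, first element kept).

    ``delta2_per_chunk`` must hold difference-scheme sensitivities. The noisy
    difference sequence is the released quantity; the prefix-sum
    reconstruction is post-processing and consumes no extra privacy budget.
    """
    x = np.asarray(x, dtype=float)
    if not epsilon > 0:
        raise ValueError("epsilon must be positive")

    def delta2_of(j):
        try:
            return delta2_per_chunk[j]
        except (KeyError, IndexError):
            raise KeyError(f"missing Delta_2 for chunk {j}") from None

    return _dcfpa_batch(x, epsilon, chunk_size,
                        lambda j, c: _resolve_k(k, j, c), delta2_of, rng, 1)[0]


def compose_epsilon(epsilons, structure: str = "sequential") -> float:
    """Total budget of composed mechanisms: sum (sequential) or max (disjoint)."""
    epsilons = list(epsilons)
    if not epsilons:
        raise ValueError("no epsilons to compose")
    if any(e <= 0 for e in epsilons):
        raise ValueError("all epsilons must be positive")
    if structure == "sequential":
        return float(sum(epsilons))
    if structure in {"disjoint", "parallel"}:
        return float(max(epsilons))
    raise ValueError(f"unknown composition structure {structure!r}")


# -- NMSE helper shared with k selection -------------------------------------

def _abs_nmse_batch(x: np.ndarray, outs: np.ndarray):
    """|NMSE| per repetition; repetitions with an undefined denominator dropped.

    Returns ``(values, n_undefined)``.
    """
    num = ((outs - x[None, :]) ** 2).mean(axis=1)
    den = x.mean() * outs.mean(axis=1)
    valid = den != 0.0
    return np.abs(num[valid] / den[valid]), int((~valid).sum())


def _default_candidates(length: int):
    cands = [1]
    while cands[-1] * 2 < length:
        cands.append(cands[-1] * 2)
    if cands[-1] != length:
        cands.append(length)
    return cands


def select_k(cohort: FeatureCohort, mechanism: str, epsilon: float,
             chunk_size: int | None = None, candidates=None, reps: int = 100,
             seed: int = 0, sens: SensitivityTable | None = None) -> dict:
    """Choose per-scope coefficient counts minimizing mean ``|NMSE|``.

    For each (feature, class, chunk) scope the candidate ``k`` minimizing the
    mean over ``reps`` noisy evaluations (and over the class's signals) of
    ``|NMSE|`` between original and privatized data is selected; ties break
    toward smaller ``k``. Returns a mapping ``(feature, class, scope) -> k``.
    """
    if mechanism not in {"fpa", "cfpa", "dcfpa"}:
        raise ValueError(f"k selection applies to FPA-family mechanisms, not {mechanism!r}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if candidates is not None and len(list(candidates)) == 0:
        raise ValueError("candidate set must be non-empty")
    if mechanism == "fpa":
        chunk_size = None
    elif chunk_size is None:
        raise ValueError(f"{mechanism} requires a chunk_size")
    scheme = "difference" if mechanism == "dcfpa" else "raw"
    if sens is None or sens.scheme != scheme or sens.chunk_size != chunk_size:
        sens = sensitivity(cohort, chunk_size=chunk_size, scheme=scheme)

    k_map: dict = {}
    for class_label in cohort.classes:
        for feature in cohort.active_features:
            sigs = cohort.signals_for(feature, class_label)
            for scope in sens.scopes(feature, class_label):
                entry = sens.entry(feature, class_label, scope)
                cands = sorted(candidates) if candidates is not None \
                    else _default_candidates(entry.length)
                cands = [k for k in cands if 1 <= k <= entry.length]
                if not cands:
                    raise ValueError(
                        f"no valid k candidates for scope length {entry.length}")
                scores = np.full(len(cands), np.nan)
                for ci, k in enumerate(cands):
                    vals = []
                    for sig in sigs:
                        if scope is None:
                            seg = sig.values
                        else:
                            s = scope * chunk_size
                            seg = sig.values[s: s + chunk_size]
                            if seg.size == 0:
                                continue
                        kk = min(k, seg.size)
                        lam = calibrate_fpa_lambda(
                            entry.length, kk, entry.delta2, epsilon).lam
                        rng = substream(seed, "select_k", feature, class_label,
                                        -1 if scope is None else scope,
                                        sig.participant_id, sig.recording_id, k)
                        if mechanism == "dcfpa":
                            outs = np.cumsum(
                                _fpa_batch(difference_transform(seg), kk, lam,
                                           rng, reps), axis=1)
                        else:
                            outs = _fpa_batch(seg, kk, lam, rng, reps)
                        v, n_undef = _abs_nmse_batch(seg, outs)
                        if n_undef:
                            logger.warning(
                                "select_k: %d/%d undefined NMSE denominators "
                                "for (%s, %s)", n_undef, reps, feature, class_label)
                        if v.size:
                            vals.append(v.mean())
                    if vals:
                        scores[ci] = float(np.mean(vals))
                if np.all(np.isnan(scores)):
                    raise ValueError(
                        f"all candidate scores undefined for ({feature}, {class_label})")
                best = int(np.nanargmin(scores))  # first minimum -> smaller k on ties
                k_map[(feature, class_label, scope)] = cands[best]
    return k_map


# -- estimators --------------------------------------------------------------

class _BaseMechanism(BaseEstimator):
    """Shared fit/transform plumbing for the four release mechanisms.

    ``fit`` computes the sensitivity table from the cohort (the database) and
    — for the Fourier family with ``k="auto"`` — selects coefficient counts by
    repeated noisy evaluation. ``transform`` draws a fresh noisy release with
    per-signal substreams of ``random_state``. Each feature is released as its
    own query at the configured ``epsilon``; the cross-feature total under
    sequential composition is reported in the release provenance via
    :func:`compose_epsilon`, not enforced.
    """

    name = ""
    _scheme = "raw"

    def __init__(self, epsilon: float = 1.0, random_state: int = 0):
        self.epsilon = epsilon
        self.random_state = random_state

    # subclass hooks ---------------------------------------------------------
    def _chunk_size(self):
        return None

    def _fit_extra(self, cohort):
        pass

    def _check_fitted(self):
        if not hasattr(self, "sensitivity_table_"):
            raise RuntimeError("mechanism must be fitted before transform")

    def fit(self, cohort: FeatureCohort, y=None):
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        self.sensitivity_table_ = sensitivity(
            cohort, chunk_size=self._chunk_size(), scheme=self._scheme)
        self.feature_names_ = list(cohort.active_features)
        self.classes_ = list(cohort.classes)
        self._fit_extra(cohort)
        return self

    def sample_outputs(self, values, feature, class_label, rng,
                       reps: int = 1) -> np.ndarray:
        """Draw ``reps`` independent noisy releases of one signal, shape (reps, n)."""
        raise NotImplementedError

    def transform(self, cohort: FeatureCohort) -> PrivateRelease:
        self._check_fitted()
        noisy = []
        lambda_map: dict = {}
        k_map: dict = {}
        for sig in cohort.signals:
            if sig.feature_name in cohort.excluded_features:
                noisy.append(sig)
                continue
            rng = substream(self.random_state, "release", self.name,
                            sig.feature_name, sig.class_label,
                            sig.participant_id, sig.recording_id)
            out = self.sample_outputs(sig.values, sig.feature_name,
                                      sig.class_label, rng, reps=1)[0]
            noisy.append(FeatureSignal(sig.participant_id, sig.recording_id,
                                       sig.class_label, sig.feature_name,
                                       out, sig.step_seconds))
            self._record_provenance(sig, k_map, lambda_map)
        release = PrivateRelease(
            cohort=cohort.with_signals(noisy),
            mechanism=self.name,
            epsilon=self.epsilon,
            chunk_size=self._chunk_size(),
            k_map=k_map,
            lambda_map=lambda_map,
            seed=self.random_state,
        )
        self.release_ = release
        return release

    def fit_transform(self, cohort: FeatureCohort, y=None) -> PrivateRelease:
        return self.fit(cohort).transform(cohort)

    def _record_provenance(self, sig, k_map, lambda_map):
        raise NotImplementedError


class LaplacePerturbation(_BaseMechanism):
    """LPA: i.i.d. Laplace noise at scale ``Delta_1 / epsilon`` per feature/class."""

    name = "lpa"

    def _lambda(self, feature, class_label) -> float:
        d1 = self.sensitivity_table_.delta(feature, class_label, None, w=1)
        if d1 == 0:
            _warn_degenerate("Delta_1")
        return d1 / self.epsilon

    def sample_outputs(self, values, feature, class_label, rng, reps=1):
        self._check_fitted()
        x = np.asarray(values, dtype=float)
        return _lpa_batch(x, self._lambda(feature, class_label), rng, reps)

    def _record_provenance(self, sig, k_map, lambda_map):
        key = (sig.feature_name, sig.class_label, None)
        k_map[key] = sig.n
        lambda_map[key] = self._lambda(sig.feature_name, sig.class_label)


class _FourierFamily(_BaseMechanism):
    """Common k-handling for FPA, CFPA, DCFPA.

    ``k`` may be a positive int (clamped to the scope length), ``"auto"``
    (selected in ``fit`` by minimizing mean ``|NMSE|`` over ``reps`` noisy
    evaluations per scope), or an explicit ``(feature, class, scope) -> k``
    mapping.
    """

    def __init__(self, epsilon: float = 1.0, k="auto", candidates=None,
                 reps: int = 100, random_state: int = 0):
        super().__init__(epsilon=epsilon, random_state=random_state)
        self.k = k
        self.candidates = candidates
        self.reps = reps

    def _fit_extra(self, cohort):
        if isinstance(self.k, str):
            if self.k != "auto":
                raise ValueError(f"k must be an int, a mapping or 'auto', got {self.k!r}")
            self.k_map_ = select_k(cohort, self.name, self.epsilon,
                                   chunk_size=self._chunk_size(),
                                   candidates=self.candidates, reps=self.reps,
                                   seed=self.random_state,
                                   sens=self.sensitivity_table_)
        elif isinstance(self.k, dict):
            self.k_map_ = dict(self.k)
        else:
            if int(self.k) < 1:
                raise ValueError("k must be >= 1")
            self.k_map_ = {
                key: min(int(self.k), entry.length)
                for key, entry in self.sensitivity_table_.entries.items()
            }

    def _k_for(self, feature, class_label, scope, length) -> int:
        k = self.k_map_[(feature, class_label, scope)]
        return min(int(k), length)

    def _scope_lambda(self, feature, class_label, scope, length) -> tuple:
        entry = self.sensitivity_table_.entry(feature, class_label, scope)
        k = self._k_for(feature, class_label, scope, length)
        lam = calibrate_fpa_lambda(entry.length, k, entry.delta2, self.epsilon).lam
        if entry.delta2 == 0:
            _warn_degenerate("Delta_2")
        return k, lam


class FourierPerturbation(_FourierFamily):
    """FPA applied to the whole signal."""

    name = "fpa"

    def sample_outputs(self, values, feature, class_label, rng, reps=1):
        self._check_fitted()
        x = np.asarray(values, dtype=float)
        k, lam = self._scope_lambda(feature, class_label, None, x.size)
        return _fpa_batch(x, k, lam, rng, reps)

    def _record_provenance(self, sig, k_map, lambda_map):
        key = (sig.feature_name, sig.class_label, None)
        k, lam = self._scope_lambda(sig.feature_name, sig.class_label, None, sig.n)
        k_map[key], lambda_map[key] = k, lam


class _ChunkedFamily(_FourierFamily):
    def __init__(self, epsilon: float = 1.0, chunk_size: int = 64, k="auto",
                 candidates=None, reps: int = 100, random_state: int = 0):
        super().__init__(epsilon=epsilon, k=k, candidates=candidates, reps=reps,
                         random_state=random_state)
        self.chunk_size = chunk_size

    def _chunk_size(self):
        if int(self.chunk_size) < 1:
            raise ValueError("chunk_size must be >= 1")
        return int(self.chunk_size)

    _batch = None  # set by subclass

    def sample_outputs(self, values, feature, class_label, rng, reps=1):
        self._check_fitted()
        x = np.asarray(values, dtype=float)

        def k_of(j, c):
            return self._scope_lambda(feature, class_label, j, c)[0]

        def delta2_of(j):
            return self.sensitivity_table_.entry(feature, class_label, j).delta2

        return type(self)._batch(x, self.epsilon, self._chunk_size(),
                                 k_of, delta2_of, rng, reps)

    def _record_provenance(self, sig, k_map, lambda_map):
        part = chunk_partition(sig.n, self._chunk_size())
        for j, (s, e) in enumerate(part.boundaries):
            key = (sig.feature_name, sig.class_label, j)
            k, lam = self._scope_lambda(sig.feature_name, sig.class_label, j, e - s)
            k_map[key], lambda_map[key] = k, lam


class ChunkedFourierPerturbation(_ChunkedFamily):
    """CFPA: independent FPA per disjoint chunk with chunk-level sensitivities."""

    name = "cfpa"
    _batch = staticmethod(_cfpa_batch)


class DifferenceChunkedFourierPerturbation(_ChunkedFamily):
    """DCFPA: within-chunk differencing, FPA on differences, prefix-sum rebuild."""

    name = "dcfpa"
    _scheme = "difference"
    _batch = staticmethod(_dcfpa_batch)


_MECHANISMS = {
    "lpa": LaplacePerturbation,
    "fpa": FourierPerturbation,
    "cfpa": ChunkedFourierPerturbation,
    "dcfpa": DifferenceChunkedFourierPerturbation,
}


def make_mechanism(name: str, **params) -> _BaseMechanism:
    """Instantiate a mechanism by its stable identifier (lpa/fpa/cfpa/dcfpa)."""
    try:
        cls = _MECHANISMS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown mechanism {name!r}; "
                         f"choose from {sorted(_MECHANISMS)}") from None
    return cls(**params)
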