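import itertools

import numpy as np
import pytest

from eyedp._rng import substream
from eyedp.mechanisms import (
    ChunkedFourierPerturbation,
    DifferenceChunkedFourierPerturbation,
    FourierPerturbation,
    LaplacePerturbation,
    calibrate_fpa_lambda,
    cfpa,
    compose_epsilon,
    dcfpa,
    fpa,
    laplace_sample,
    lpa,
    select_k,
    sensitivity,
)
from conftest import build_cohort


# -- Laplace sampling --------------------------------------------------------

def test_laplace_moments_match_density():
    draws = laplace_sample(1.0, 10 ** 6, substream(0, "lap"))
    assert abs(draws.mean()) < 0.01
    assert draws.var() == pytest.approx(2.0, abs=0.05)
    wide = laplace_sample(2.0, 10 ** 6, substream(0, "lap2"))
    assert wide.var() / draws.var() == pytest.approx(4.0, rel=0.05)


def test_laplace_sample_is_reproducible_and_validated():
    a = laplace_sample(1.0, 100, substream(5, "x"))
    b = laplace_sample(1.0, 100, substream(5, "x"))
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError):
        laplace_sample(0.0, 10, substream(0))


# -- sensitivity -------------------------------------------------------------

def test_sensitivity_hand_example(two_participant_cohort):
    table = sensitivity(two_participant_cohort)
    entry = table.entry("f", "reading")
    assert entry.delta1 == pytest.approx(7.0)   # |1-4| + |2-6|
    assert entry.delta2 == pytest.approx(5.0)   # sqrt(9 + 16)


def test_sensitivity_zero_for_identical_participants():
    cohort = build_cohort({"p1": {"f": [2.0, 3.0]}, "p2": {"f": [2.0, 3.0]}})
    entry = sensitivity(cohort).entry("f", "reading")
    assert entry.delta1 == entry.delta2 == 0.0


def test_sensitivity_matches_exhaustive_pairwise_maximum():
    rng = np.random.default_rng(9)
    vectors = {f"p{i}": rng.normal(size=16) for i in range(5)}
    cohort = build_cohort({p: {"f": v} for p, v in vectors.items()})
    table = sensitivity(cohort)
    best1 = max(np.abs(a - b).sum()
                for a, b in itertools.combinations(vectors.values(), 2))
    best2 = max(np.linalg.norm(a - b)
                for a, b in itertools.combinations(vectors.values(), 2))
    assert table.delta("f", "reading", w=1) == pytest.approx(best1)
    assert table.delta("f", "reading", w=2) == pytest.approx(best2)


def test_sensitivity_zero_pads_unequal_lengths():
    # Eq-style padding: shorter vector extended with zeros to the longer length
    cohort = build_cohort({"p1": {"f": [3.0, 4.0, 2.0]}, "p2": {"f": [3.0]}})
    entry = sensitivity(cohort).entry("f", "reading")
    assert entry.delta1 == pytest.approx(6.0)
    assert entry.delta2 == pytest.approx(np.sqrt(16 + 4))
    assert entry.length == 3


def test_sensitivity_requires_two_participants():
    cohort = build_cohort({"p1": {"f": [1.0, 2.0]}})
    with pytest.raises(ValueError):
        sensitivity(cohort)


def test_sensitivity_invariants_on_random_cohort(small_cohort):
    whole = sensitivity(small_cohort)
    chunked = sensitivity(small_cohort, chunk_size=32)
    for (feature, cls, scope), entry in chunked.entries.items():
        assert entry.delta1 >= entry.delta2 - 1e-9
        assert entry.delta2 <= whole.entry(feature, cls).delta2 + 1e-9


# -- proof-chain inequalities ------------------------------------------------

def test_truncated_spectrum_sensitivity_proof_chain():
    """Delta_1(F_hat) <= sqrt(k) Delta_2(F_hat) <= sqrt(n k) Delta_2(X)."""
    rng = np.random.default_rng(17)
    for _ in range(200):
        n = int(rng.integers(8, 129))
        x, y = rng.normal(size=n), rng.normal(size=n)
        diff_spec = np.fft.fft(x) - np.fft.fft(y)  # DFT linearity
        mods = np.abs(diff_spec)
        d1_hat = np.cumsum(mods)                  # Delta_1 of k-truncated diff
        d2_hat = np.sqrt(np.cumsum(mods ** 2))    # Delta_2 of k-truncated diff
        ks = np.arange(1, n + 1)
        d2_x = np.linalg.norm(x - y)
        assert np.all(d1_hat <= np.sqrt(ks) * d2_hat + 1e-9)
        assert np.all(d2_hat <= np.sqrt(n) * d2_x + 1e-9)


# -- noise-scale calibration -------------------------------------------------

@pytest.mark.parametrize("n, k, delta2, eps, expected", [
    (64, 4, 2.0, 1.0, 32.0),
    (64, 64, 2.0, 1.0, 128.0),
    (64, 8, 0.0, 1.0, 0.0),
])
def test_fpa_lambda_formula(n, k, delta2, eps, expected):
    assert calibrate_fpa_lambda(n, k, delta2, eps).lam == pytest.approx(expected)


def test_fpa_lambda_rejects_invalid_ranges():
    for bad in [(4, 0, 1.0, 1.0), (4, 5, 1.0, 1.0), (4, 2, 1.0, 0.0),
                (4, 2, -1.0, 1.0)]:
        with pytest.raises(ValueError):
            calibrate_fpa_lambda(*bad)


# -- array-level mechanisms --------------------------------------------------

def test_lpa_noise_scale_and_degenerate_case():
    x = np.zeros(10 ** 5)
    out = lpa(x, delta1=1.0, epsilon=1.0, rng=substream(1, "lpa"))
    assert out.var() == pytest.approx(2.0, rel=0.05)  # Var Lap(1) = 2
    np.testing.assert_array_equal(lpa(x[:10], 0.0, 0.7, substream(0)), x[:10])
    with pytest.raises(ValueError):
        lpa(x[:10], -1.0, 1.0, substream(0))


def test_fpa_identity_and_truncation_oracle():
    x = np.array([3.0, 1.0, 3.0, 1.0])
    rng = substream(0)
    np.testing.assert_allclose(fpa(x, k=4, lam=0.0, rng=rng), x, atol=1e-9)
    np.testing.assert_allclose(fpa(np.ones(4), k=1, lam=0.0, rng=rng),
                               np.ones(4), atol=1e-12)
    # O(n^2) truncation oracle for k=2
    n = x.size
    j, t = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    F = (x * np.exp(-2j * np.pi * j * t / n)).sum(axis=1)
    F[2:] = 0
    expected = (F[:, None] * np.exp(2j * np.pi * j * t / n)).sum(axis=0).real / n
    np.testing.assert_allclose(fpa(x, k=2, lam=0.0, rng=rng), expected, atol=1e-9)
    np.testing.assert_allclose(expected, [2, 2, 2, 2], atol=1e-12)
    with pytest.raises(ValueError):
        fpa(x, k=5, lam=0.0, rng=rng)


def test_cfpa_reductions():
    rng = np.random.default_rng(2)
    x = rng.normal(size=96)
    # single covering chunk, no noise, full k: identity
    out = cfpa(x, 1.0, chunk_size=128, k=96, delta2_per_chunk={0: 0.0},
               rng=substream(0))
    np.testing.assert_allclose(out, x, atol=1e-9)
    # three chunks, noiseless, k = chunk length: partition identity
    out = cfpa(x, 1.0, chunk_size=32, k=32,
               delta2_per_chunk={0: 0.0, 1: 0.0, 2: 0.0}, rng=substream(0))
    np.testing.assert_allclose(out, x, atol=1e-9)
    with pytest.raises(KeyError):
        cfpa(x, 1.0, 32, 32, {0: 0.0, 1: 0.0}, substream(0))  # missing chunk 2


def test_dcfpa_identity_chain_and_constant_signal_oracle():
    rng = np.random.default_rng(4)
    x = rng.normal(size=64)
    out = dcfpa(x, 1.0, chunk_size=32, k=32,
                delta2_per_chunk={0: 0.0, 1: 0.0}, rng=substream(0))
    np.testing.assert_allclose(out, x, atol=1e-9)

    # constant signal, k < c, noiseless: equals truncated-spectrum prefix sums
    const = np.full(8, 5.0)
    k = 3
    d = np.r_[const[0], np.diff(const)]           # impulse 5, 0, ..., 0
    n = d.size
    j, t = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    F = (d * np.exp(-2j * np.pi * j * t / n)).sum(axis=1)
    F[k:] = 0
    recon = (F[:, None] * np.exp(2j * np.pi * j * t / n)).sum(axis=0).real / n
    expected = np.cumsum(recon)
    got = dcfpa(const, 1.0, chunk_size=8, k=k, delta2_per_chunk={0: 0.0},
                rng=substream(0))
    np.testing.assert_allclose(got, expected, atol=1e-9)


def test_dcfpa_single_element_chunks_behave_like_lpa():
    # c = 1: each sample is its own chunk; differencing is the identity and
    # the per-sample release is x_t + Laplace noise, i.e. LPA-like.
    x = np.array([1.0, -2.0, 3.0])
    out = dcfpa(x, 1.0, chunk_size=1, k=1,
                delta2_per_chunk={0: 0.0, 1: 0.0, 2: 0.0}, rng=substream(0))
    np.testing.assert_allclose(out, x, atol=1e-12)


# -- estimators --------------------------------------------------------------

@pytest.mark.parametrize("factory", [
    lambda: LaplacePerturbation(epsilon=1.0, random_state=3),
    lambda: FourierPerturbation(epsilon=1.0, k=10 ** 9, random_state=3),
    lambda: ChunkedFourierPerturbation(epsilon=1.0, chunk_size=32, k=10 ** 9,
                                       random_state=3),
    lambda: DifferenceChunkedFourierPerturbation(epsilon=1.0, chunk_size=32,
                                                 k=10 ** 9, random_state=3),
])
def test_mechanisms_are_identity_maps_in_noiseless_full_k_limit(factory):
    """Identical participants give zero sensitivity, hence lambda = 0; with k
    clamped to the scope length every mechanism must reproduce its input."""
    values = np.sin(np.linspace(0, 5, 96)) + 2.0
    cohort = build_cohort({"p1": {"f": values}, "p2": {"f": values.copy()}})
    release = factory().fit_transform(cohort)
    for sig in release.cohort.signals:
        np.testing.assert_allclose(sig.values, values, atol=1e-9)


def test_transform_is_reproducible_and_records_provenance(small_cohort):
    mech = ChunkedFourierPerturbation(epsilon=2.4, chunk_size=32, k=4,
                                      random_state=11)
    rel1 = mech.fit_transform(small_cohort)
    rel2 = ChunkedFourierPerturbation(epsilon=2.4, chunk_size=32, k=4,
                                      random_state=11).fit_transform(small_cohort)
    for sig in rel1.cohort.signals:
        np.testing.assert_array_equal(sig.values,
                                      rel2.cohort.get(*sig.key).values)
    # provenance: every chunk of every (feature, class) carries k and lambda
    n = small_cohort.signals[0].n
    n_chunks = -(-n // 32)
    expected_keys = {(f, c, j) for f in small_cohort.active_features
                     for c in small_cohort.classes for j in range(n_chunks)}
    assert set(rel1.k_map) == expected_keys
    assert all(lam > 0 for lam in rel1.lambda_map.values())
    assert rel1.epsilon == 2.4 and rel1.mechanism == "cfpa"


def test_estimator_get_params_round_trip():
    mech = DifferenceChunkedFourierPerturbation(epsilon=4.8, chunk_size=128,
                                                k=6, reps=50, random_state=2)
    params = mech.get_params()
    clone = DifferenceChunkedFourierPerturbation(**params)
    assert clone.get_params() == params


# -- k selection -------------------------------------------------------------

def _dc_dominated_cohort(n=32, participants=4, noise=0.001, offset_sd=1.0,
                         seed=0):
    """Near-constant signals whose participant offsets carry the sensitivity."""
    rng = np.random.default_rng(seed)
    base = np.full(n, 10.0)
    return build_cohort({
        f"p{i}": {"f": base + rng.normal(0, offset_sd) + rng.normal(0, noise, n)}
        for i in range(participants)
    })


def test_select_k_prefers_small_k_when_energy_is_low_frequency():
    # DC-dominated signals: perturbation error grows with k through
    # lambda = sqrt(n k) Delta_2 / eps while reconstruction error is ~0
    # beyond the DC coefficient, so the smallest k wins.
    cohort = _dc_dominated_cohort()
    k_map = select_k(cohort, "fpa", epsilon=5.0, reps=25, seed=1)
    assert k_map[("f", "reading", None)] <= 4


def test_select_k_prefers_max_k_for_white_noise_without_noise_budget():
    rng = np.random.default_rng(5)
    cohort = build_cohort({f"p{i}": {"f": 10.0 + rng.normal(size=32)}
                           for i in range(4)})
    k_map = select_k(cohort, "fpa", epsilon=1e12, reps=5, seed=1,
                     candidates=[1, 2, 4, 8, 16, 32])
    assert k_map[("f", "reading", None)] == 32


def test_select_k_is_deterministic_even_with_one_rep():
    cohort = _dc_dominated_cohort(seed=3)
    a = select_k(cohort, "cfpa", epsilon=2.4, chunk_size=16, reps=1, seed=9)
    b = select_k(cohort, "cfpa", epsilon=2.4, chunk_size=16, reps=1, seed=9)
    assert a == b
    with pytest.raises(ValueError):
        select_k(cohort, "fpa", epsilon=1.0, candidates=[], reps=1)
    with pytest.raises(ValueError):
        select_k(cohort, "lpa", epsilon=1.0)


# -- composition -------------------------------------------------------------

def test_epsilon_composition_rules():
    assert compose_epsilon([1.0, 1.0, 1.0], "disjoint") == 1.0
    assert compose_epsilon([0.5, 0.5], "sequential") == 1.0
    assert compose_epsilon([0.7], "disjoint") == 0.7
    assert compose_epsilon([0.7], "sequential") == 0.7
    with pytest.raises(ValueError):
        compose_epsilon([], "sequential")
    with pytest.raises(ValueError):
        compose_epsilon([1.0, -1.0], "sequential")
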