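# eyedp — differential privacy for eye-movement feature signals

Eye trackers embedded in VR/AR headsets stream per-window feature signals
(fixation, saccade, blink and pupil statistics) that are rich enough to
re-identify the wearer. `eyedp` is a toolkit for releasing such multivariate
feature time series under ε-differential privacy while accounting for the
strong *temporal correlation* that sliding-window feature extraction induces —
the property that makes naive noise addition leak more than its nominal ε
suggests. It is aimed at researchers releasing behavioral-biometrics datasets
and at practitioners evaluating the privacy/utility trade-off of such
releases.

## Mechanisms

All four mechanisms calibrate Laplace noise to a *query sensitivity*: for a
feature f, Δ_w(Xⁿ) = max_{p,q} ‖Xⁿ,(p,f) − Xⁿ,(q,f)‖_w over participant pairs
(p, q), with shorter observation vectors zero-padded to the maximum length n.

| Mechanism | Release | Noise scale λ |
|---|---|---|
| **LPA**   | Xⁿ + Lapⁿ(λ) | Δ₁(Xⁿ)/ε |
| **FPA**   | noise the first k DFT coefficients, zero-pad, invert | √(nk)·Δ₂(Xⁿ)/ε |
| **CFPA**  | FPA per disjoint chunk (c ∈ {32, 64, 128}) with chunk-level Δ₂ | √(c·k)·Δ₂(chunk)/ε per chunk |
| **DCFPA** | within-chunk consecutive differences → FPA → prefix sums | √(c·k)·Δ₂(diff chunk)/ε per chunk |

The √(nk) factor in the FPA scale follows from the sensitivity chain
Δ₁(F̂ⁿ) ≤ √k·Δ₂(F̂ⁿ) ≤ √(nk)·Δ₂(Xⁿ) for the k-truncated non-unitary DFT
spectrum; the test suite verifies these inequalities on thousands of random
vector pairs. Chunks compose in parallel (disjoint inputs), so each signal's
guarantee stays ε; the DCFPA's prefix-sum reconstruction is post-processing
and consumes no budget. Differencing drastically reduces sample correlations,
which is what keeps the *effective* privacy level of the release close to the
nominal ε in the presence of correlation-exploiting adversaries.

Utility is measured by NMSE = (1/n)·Σ(Xᵢ−X̃ᵢ)² / (X̄·X̃̄) and its reciprocal
1/|NMSE|; the number of retained coefficients k is chosen per feature, class
and chunk by minimizing mean |NMSE| over 100 noisy evaluations. An empirical
DP audit (histogram log-ratio test on neighboring inputs), correlation
profiling, and classification protocols (leave-one-person-out class
prediction; a first-half/second-half person-identification attack with
majority voting) complete the evaluation loop.

## Worked example

```python
from eyedp import (DifferenceChunkedFourierPerturbation, ClassificationProtocol,
                   generate_cohort, paper_shaped_preset, run_protocol,
                   utility_report)

cohort = generate_cohort(paper_shaped_preset("mpiidpeye_like"))  # 20 participants, 3 document types

mech = DifferenceChunkedFourierPerturbation(epsilon=2.4, chunk_size=64,
                                            k="auto", reps=100, random_state=0)
release = mech.fit_transform(cohort)          # fit: sensitivities + k selection
report = utility_report(cohort, mech, reps=100, seed=0)
print(f"mean |NMSE| = {report.aggregate_abs_nmse:.2f}")

protocol = ClassificationProtocol(task="person_identification", window=5, seed=0)
clean = run_protocol(cohort, protocol)
private = run_protocol(release, protocol)
print(f"person-ID accuracy: clean {clean.accuracy('random_forest'):.2f}, "
      f"private {private.accuracy('random_forest'):.2f} "
      f"(chance {clean.chance_level:.2f})")
```

On the default synthetic cohort this prints:

```
mean |NMSE| = 75.26
person-ID accuracy: clean 1.00, private 0.07 (chance 0.05)
```

i.e. the clean signals identify every participant perfectly, while the
difference-chunk release at ε = 2.4 drives the attack to chance level — the
privacy behavior the mechanism is designed for.

The same pipeline is scriptable from the shell:

```
eyedp synth --preset mpiidpeye_like --seed 0 --out cohort/
eyedp privatize --in cohort/ --out releases/ --mechanism dcfpa --chunk-size 64 --seed 0
eyedp classify --in releases/eps_2.4 --out attack/ --task person_identification --window 5
```

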