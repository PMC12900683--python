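# plvnet

Phase-locking-value (PLV) analysis of resting-state EEG brain networks,
built for studies that compare functional connectivity between groups
(e.g. adolescents with subclinical depressive symptoms vs. healthy
controls) and across intervention conditions, together with the
behavioral instruments such studies use (PANAS affect scores, CES-D /
PHQ-9 screening).

Because raw EEG from such studies is rarely shareable, the package pairs
every analysis stage with a synthetic coupled-oscillator generator whose
pairwise phase coupling is prescribed exactly, so the whole pipeline is
testable end to end against known ground truth.

## What it computes

**Connectivity.** For regions *i*, *j* with instantaneous Hilbert phases
φᵢ(t), φⱼ(t) of the band-limited signal (θ 4–8 Hz, α 8–14 Hz, β 14–30 Hz),

    PLV = (1/T) · | Σₜ exp( i·(φᵢ(t) − φⱼ(t)) ) |  ∈ [0, 1]

assembled into a symmetric 78×78 matrix on a 5-network parcellation
(SMN, DAN, SN, DMN, CEN) and summarised as 10 inter-network means and 5
intra-network ("activity") means per subject and band.

**Inference.**
- Student's pooled two-sample t-tests (raw data or printed summaries);
- the network-based statistic (NBS): suprathreshold edges at p < 0.05
  form sign-coherent connected components whose sizes are referred to a
  permutation null of the maximum component size (2000 permutations,
  component p < 0.05), controlling family-wise error over all edges;
- balanced 2×3 between-subjects ANOVA with partial η² =
  SS_effect/(SS_effect+SS_error) and Bonferroni post-hocs, as
  statsmodels-style model/results classes (`FactorialANOVA`,
  `NetworkBasedStatistic`);
- Pearson correlation of post−pre network-metric changes against affect
  changes;
- a priori power analysis from the noncentral t / F distributions.

**Preprocessing.** 1–30 Hz band-pass and 48–52 Hz notch (zero-phase
Butterworth), mastoid re-referencing, ICA-based artifact-component
removal, ±70 μV segment rejection, and a strict >300 s retention rule.

**Synthetic data.** Region signals `A·cos(2π f_c t + φ_r(t))` whose
pairwise phase offsets are von Mises distributed: a pair with offset
concentration κ locks at PLV = I₁(κ)/I₀(κ), inverted by
`kappa_for_plv`. Cohort simulations impose group×condition offsets on
named network pairs and draw PANAS scores from per-cell normal
distributions truncated to the 10–50 scale range.

## Worked example

```python
from plvnet import (OscillatorSpec, simulate_region_signals, plv,
                    ttest_from_summary, power_min_n, PowerQuery,
                    nbs, simulate_edge_cohort)

# Published-summary worked examples
pa = ttest_from_summary(19.260, 2.813, 50, 30.083, 1.867, 48)
print(f"baseline PA contrast: t({pa.df:.0f}) = {pa.t:.3f}, p = {pa.p:.2e}")
print("minimum total N:", power_min_n(PowerQuery("two_sample_t", 0.80, 0.05, 0.95)))

# A coupled pair with a prescribed PLV of 0.7
spec = OscillatorSpec(n_regions=2, fs=256, duration=120, band="alpha",
                      pair_plv={(0, 1): 0.7}, seed=1)
rec, phases = simulate_region_signals(spec, return_phases=True)
print(f"prescribed PLV 0.70 -> empirical {plv(phases[0], phases[1]):.3f}")

# NBS recovers a planted +0.2-PLV clique on 5 of 20 regions (n=15/15)
clique = {(i, j): 0.2 for i in range(5) for j in range(i + 1, 5)}
ctrl, pairs = simulate_edge_cohort(15, 20, noise_sd=0.04, seed=10)
case, _ = simulate_edge_cohort(15, 20, noise_sd=0.04, edge_offsets=clique, seed=11)
top = nbs(case, ctrl, n_perm=500, seed=0, pairs=pairs).significant_components[0]
print(f"NBS: component of {top.size} edges, sign {top.sign:+d}, p = {top.p:.4f}")
```

prints

```
baseline PA contrast: t(96) = -22.345, p = 8.11e-40
minimum total N: 84
prescribed PLV 0.70 -> empirical 0.702
NBS: component of 15 edges, sign +1, p = 0.0100
```

The t of −22.3 on 96 df says the subclinical group's positive-affect
mean sits about 22 standard errors below the control mean; N = 84 is the
smallest equal-allocation design that reaches 95% power for a large
(d = 0.8) group difference; the NBS component of 15 edges (the 10
planted edges plus chance-attached neighbours) is larger than the
permutation null's maximum in 99% of label shuffles.

A full pipeline run (simulate → preprocess → connectivity → summaries →
statistics) is one call or one shell command:

```bash
plvnet run-all --config config.yaml --seed 7 --out results/run1
```

with every threshold (band edges, notch, ±70 μV, 300 s, α levels,
permutation count) surfaced in the YAML config; see
`plvnet.pipeline.RunConfig`.

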