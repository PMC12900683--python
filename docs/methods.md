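# Methods

This note records the models, parameter choices and numerical decisions
behind plvnet, in the order data flows through the pipeline.

## Synthetic coupled oscillators

Each region emits `x_r(t) = A·cos(2π f_c t + φ_r(t)) + ε(t)` with the
carrier `f_c` at the band midpoint (θ 6 Hz, α 11 Hz, β 22 Hz),
amplitude `A = 10 μV` and white Gaussian noise `ε` of 0.1·A by default —
enough to be visible, small enough that the narrowband phase stays well
defined after band-pass filtering.

**Pairwise coupling.** The phase offset between a coupled pair is drawn
i.i.d. von Mises(0, κ) per sample, chosen because it gives a closed-form
asymptotic PLV: the modulus of the mean phasor of a von Mises variable
is the Bessel ratio I₁(κ)/I₀(κ). `kappa_for_plv` inverts this by Brent's
method to 1e-6; a target of exactly 1 is realised as an identical phase
series (κ → ∞ limit). Pair targets are laid out over a spanning forest
of the pair graph (each tree edge's offset is drawn directly, so its
PLV is exact); a cycle of targets is over-determined and rejected.
Unlinked pairs receive the `base_plv` target through a shared reference:
every region deviates from the reference with concentration κ(√base), so
any two of them lock at (√base)² = base.

**Cohort-level targets.** A design cell's targets are the intra- and
inter-network bases plus the cell's effect offsets, clipped to [0, 1]
with a logged warning. Ten independent inter-network targets cannot be
realised by pairwise von Mises links alone, so cohorts use a two-level
construction: regions deviate from their network's hub phase with
κ(√intra), and the five hub phases are wrapped Gaussian with covariance
chosen so that hub pair PLV equals inter/√(intra_A·intra_B) (wrapped
Gaussian phase differences give PLV = exp(−Var/2) in closed form). The
hub correlation matrix is projected to the nearest correlation matrix
when needed; an inter target above √(intra_A·intra_B) is unattainable
under this hierarchy and saturates. All targets, and any clipping, are
recorded in the run manifest.

**Slow vs. fast phase modulation.** With per-sample i.i.d. offsets
(`phase_hold = 0`, the default) the empirical PLV of the generated
*phases* converges at the Monte-Carlo rate — |PLV − ρ| < 3/√T holds
comfortably at T = 30720 — but the modulation is spectrally broadband,
so it cannot be recovered from the *signal* after narrowband filtering.
Cohort simulations therefore default to `phase_hold = 0.5 s`: offsets
are redrawn every 0.5 s and held, which leaves the marginal law (and
hence the expected PLV) unchanged while confining the modulation to
roughly ±2 Hz around the carrier, inside every analysis band. The cost
is a smaller effective sample count — one draw per block — so a 120-s
recording yields ≈240 independent draws and subject-level PLV estimates
with a measured between-subject sd of ≈0.04. Measured through the full
filter+Hilbert pipeline on a 20-region cohort, planted network offsets
of +0.2/+0.3 are recovered as mean PLV differences of 0.20/0.25.

**What the generator does not emulate.** No volume conduction or source
leakage, no 1/f background, no cross-frequency structure, and coupling
is stationary. Phase modulation sidebands also leak across band
boundaries, so a coupling planted "in" one band is partially visible in
the others. Passing tests therefore demonstrate the correctness of the
estimators and the calibration of the statistics, not robustness to
real EEG artifacts beyond the classes injected deliberately (blinks,
50 Hz line noise, amplitude spikes).

## Preprocessing

Chain order: drop auxiliary channels (VEOG/HEOG) → 1–30 Hz band-pass →
48–52 Hz notch → mastoid (M1/M2) re-reference → ICA artifact removal →
±70 μV rejection → retention rule. Filters are 4th-order Butterworth
applied forward–backward (`sosfiltfilt`), giving zero phase in steady
state; the contracts are attenuation-based (out-of-band tone < 5% RMS,
in-band tone within 5%, ≥20 dB in the notch), so any compliant
realisation passes. Boundary samples of a padding-based forward–backward
filter are not exactly reversal-symmetric; the pipeline absorbs this by
trimming 1 s per edge before phase extraction, and the zero-phase
property test checks the interior of a zero-padded signal where the
identity holds below 1e-6.

Artifact components are identified by decomposing the recording with
FastICA and zeroing components whose absolute Pearson correlation with
a supplied template time series (e.g. a VEOG channel recorded before
dropping) reaches 0.7 — a conventional template-correlation criterion;
the threshold is configurable and logged per subject. Rejection splits
the recording into 1-s windows and drops any window containing a sample
beyond ±70 μV on any row; a subject passes only if strictly more than
300 s survive (the rule is strict on purpose: exactly 300 s is an
exclusion). Both window length and the component criterion are pipeline
configuration, not facts about any particular dataset.

## Connectivity

Instantaneous phase is the angle of the analytic signal of the
band-passed row, with 1 s trimmed per edge against Hilbert boundary
transients; a numerically silent row has no phase and is an error.
PLV is computed over the full retained series in a single window, on the
complex unit circle (wrapping convention is irrelevant), and all pairs
at once via a Gram product of unit phasors — verified in tests against
the literal pairwise double loop to 1e-12. "Single-network activity" is
interpreted as the mean PLV over within-network region pairs; the main
alternative reading (band power) is deliberately not implemented as an
activity metric, and the interpretation is surfaced in the summary
tables' `metric_type` column.

The packaged parcellation has 78 regions named R01–R78 in five blocks
(SMN 14, DAN 14, SN 14, DMN 22, CEN 14). No computation depends on
anatomical identity, only on the partition, so neutral names are used;
any region→network TSV can be substituted.

## Statistics

**t-tests** are Student's pooled-variance form (df = n_a + n_b − 2).
Back-computing the published baseline contrasts from their printed
summaries matches the pooled form (−22.345 vs printed −22.351), which is
why pooled rather than Welch is the default; `ttest_from_summary` is
exactly consistent with `ttest_ind` by construction.

**NBS.** Per-edge two-sided pooled t; edges with p < 0.05 are
suprathreshold. Components are formed within each contrast direction
separately (sign-coherent components) and their edge counts are referred
to the permutation distribution of the maximum component size over both
directions (group labels shuffled without replacement from one seeded
generator; p = (1+#{null ≥ size})/(1+n_perm), so never exactly zero).
Sign-coherent formation is the standard two-sided handling and matters
in practice: pooling both signs into one graph lets the 5%-rate
background percolate and drops the detection rate for a planted
10-edge clique from ~100% to ~70% in our calibration setting; the pooled
variant remains available (`sign_split=False`), as does node-count
component size. Measured over 200 null cohorts (15 vs 15, 20 regions,
500 permutations) the family-wise significant-component rate is 0.045 at
α = 0.05.

**ANOVA.** The 2×3 design is analysed as a balanced between-subjects
factorial (every cell contains distinct subjects), decomposed in closed
form; SS terms sum to the total to 1e-12 and the results match
statsmodels OLS + anova_lm to 1e-9 in tests. Partial η² =
SS_effect/(SS_effect+SS_error). Unbalanced input is rejected with the
observed cell counts rather than silently reweighted.
`two_way_anova_from_summary` applies the same decomposition to printed
cell means/SDs; reconstructing the published affect interaction terms
this way lands within ~4% of the printed F values but not exactly on
them (and the printed partial η² values are larger than any
between-subjects reconstruction), consistent with the source analysis
using an error-term construction it does not fully specify. The
reconstruction is therefore treated as a 10% consistency band, not an
equality.

**Power analysis** evaluates achieved power from the noncentral t
(noncentrality d·√(n/2), df = N−2, two-sided) or noncentral F
(λ = f²·N) and searches total N upward (step 2 for equal-allocation t,
step 1 for F). The published design sizes are reproduced exactly: 84
for d = 0.80/α 0.05/power 0.95, and 64 for f = 0.40/α 0.05/power 0.80
with a 2-df effect in a 6-cell design.

**Multiplicity.** Within each band the 15 network metrics form one
Bonferroni family by default (config-exposed); NBS handles edge-level
multiplicity by design.

## Pipeline and problem sizes

Runs are driven by a single `RunConfig` (YAML-loadable); every run
writes TSV tables plus a JSON manifest carrying the config hash, seed
and package versions, and identical configurations are byte-identical
across runs. In the intervention analysis, brain–behavior correlations
use post − pre change scores when a paired pre-intervention cohort is
available (simulate mode generates one automatically); otherwise they
fall back to post-only values and say so in the manifest.

Unit tests run on desk-scale problems (10–20 regions, 25–120 s); the
acceptance suite exercises the full 78-region contract on a 12-subject,
310-s cohort (310 s so that the strict >300 s retention rule is
genuinely applied) and calibrates NBS on 200 edge-level cohorts —
edge-level rather than signal-level because the calibration concerns the
statistic, with the edge noise sd set to 0.04, the measured
between-subject edge-PLV spread of the signal generator at its cohort
defaults.

## Known limitations

- Sensor→region mapping (source localisation) is out of scope: region-
  space recordings are a first-class input, and sensor-space data only
  pass through preprocessing.
- The cohort hierarchy cannot realise inter-network targets above the
  geometric mean of the two intra targets; such targets saturate and are
  logged.
- Permutation p-values are exchangeability-based; with strong localised
  effects the null partially regenerates the effect, which is the usual
  conservatism of the max-statistic approach.
- The EDF writer covers the subset of EDF+ needed for round-tripping
  synthetic fixtures (16-bit, 1-s records, integer sampling rates); it
  is not a general-purpose exporter.
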