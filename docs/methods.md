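# Methods

## The KNDy core

The arcuate KNDy population is described by three ordinary differential
equations for dynorphin activity `D`, NKB activity `N` and population
firing `v` (all dimensionless; time in minutes):

```
τ_D dD/dt = k_D·H(v; K_vD, n_vD) − D
τ_N dN/dt = (k_N0 + k_N·H(v; K_vN, n_vN)) / (1 + (D/K_DN)^n_DN) − N
τ_v dv/dt = v_max·F(I_net) − v,   I_net = g_Nv·H(N; K_Nv, n_Nv) + I0 + I_exc − I_inh
```

with `H(x; K, n) = x^n/(K^n + x^n)` and `F(x) = H(max(x,0); K_F, n_F)`.
The oscillation mechanism is fast NKB-mediated recurrent excitation
(v→N→v) terminated by slowly accumulating dynorphin, which divisively
suppresses NKB secretion; when dynorphin clears, basal NKB secretion
`k_N0` re-ignites the burst.  The basal term is a deliberate design
choice: it decouples the lower (ignition) threshold from the upper
(depolarisation-silencing) threshold of the net input, because ignition
is carried by `g_Nv·H(k_N0)` while silencing depends on `F(I_net)` alone.
Without it the pulsatile input band is too narrow to host the six
experimental operating points.  Biologically it corresponds to
activity-independent basal neuropeptide release.

Increasing net drive sweeps the model through silent →
pulsatile → quiescent-high regimes.  With the committed defaults
(`src/mepdsim/configs/calibrated_default.yaml`) the pulsatile band spans
net inputs of roughly −0.17 to +0.45, with burst period falling
monotonically from ~44 min near the lower edge to ~10 min at the upper
edge; above the band the system settles, after a damped oscillatory
transient, into a steady state at `v = F(I_net)` (≈0.3–0.5 v_max) with
dynorphin saturated and NKB suppressed.  This is the model's
depolarisation-silenced state.  Defaults were chosen by coarse grid
search so that (i) the uncoupled core at zero external input pulses with
a ~17-min period, inside the ultradian range of ovariectomised mice, and
(ii) under the basal amygdala tone the coupled system pulses every
~27 min, matching reported control interpulse intervals (25–31 min).

Integration uses adaptive RK45 (`scipy.integrate.solve_ivp`) with
relative tolerance 1e-6 and absolute tolerance 1e-8, dense output
resampled to a 0.1-min grid; the solver restarts at protocol switch
times so discontinuous inputs never cross a step.  Convergence is tested
(halving the tolerance changes `v` by <1e-4 of `v_max` and the measured
period by <0.5%), not assumed.

## The MePD circuit

Four populations relax with a common 2-min time constant toward
rectified-logistic targets: Kiss1 `K` (clamped to 0 basally, +1 under
light), GABA interneurons `G1 ← K`, a glutamatergic population
`E ← K`, and GABAergic efferents
`G2 ← g0 + (1−β_glu)·w_EG2·E − ((1−β_A)·w_A + (1−β_B)·w_B)·G1`.
Output to the arcuate network is `I_exc = w_Eout·E`, `I_inh = w_G2out·G2`.
The circuit is feed-forward, so its steady state has a closed form; the
root-finding oracle in the tests confirms it.

Design choices:

- **Basal Kiss1 quiescence** (`kappa0 = 0`). Antagonists act only through
  kisspeptin-driven tone, so every drug-alone arm is exactly null — the
  observed in-vivo pattern. With steep G1/E sigmoids the basal
  contamination of the drug conditions is below 1e-9.
- **GABA_A : GABA_B split.** The four required G2 operating points
  (basal 0.406; full disinhibition 0.388; GABA_B-blocked ≈0.72, which
  cancels the direct glutamatergic excitation; GABA_A-blocked ≈0.87,
  which overwhelms it) are mutually consistent with a logistic response
  only at a weight ratio near 1.7:1; the committed values are
  `w_A = 0.5925`, `w_B = 0.3491` with slope 4.  A more asymmetric split
  (e.g. 4:1) cannot make GABA_B blockade null while GABA_A blockade
  reverses the output.  The qualitative asymmetry — fast GABA_A
  inhibition dominates the disinhibitory chain — is preserved.
- **Glutamate blockade is intra-MePD only**: `β_glu` removes the E→G2
  synapse but not the E→arcuate projection, since infused antagonists
  reach MePD receptors only.  Under light this removes the efferent
  inhibition while leaving direct excitation intact, pushing net drive
  (≈+0.54) over the upper threshold.
- **Drug kinetics** are a step to full blockade at the bolus time
  (50 min), held through the session; no pharmacokinetics are modelled.
- **5-Hz stimulation** is abstracted to a constant Kiss1 increment while
  the light is on; no stimulation-frequency dependence is modelled.
- The disinhibition ordering (light lowers G2) holds whenever the
  G1→G2 inhibitory weight exceeds the intra-MePD glutamate drive
  (J − W < 0 in logit units); with weak inhibitory weights the ordering
  genuinely reverses, so the invariant is tested under joint scaling of
  the three weights rather than for arbitrary parameter sets.

## Regime classification and event counting

Burst events are upward crossings of `frac·max(v)` (default frac 0.5)
that are later followed by a downward crossing — a terminal rise into a
sustained plateau is not an event.  A window is `silent` if `v` stays
below 0.1 `v_max`; `pulsatile` if it contains ≥2 completed events or a
peak-to-trough excursion ≥0.25 `v_max` (slow bursting that completes
fewer than two cycles); otherwise `quiescent_high`.  The excursion
clause is needed because the depolarised plateau sits at `F(I_net)` ≈
0.3–0.5 `v_max`, below the crossing threshold of windows that also
contain full-height bursts, so a purely threshold-based rule would
confuse slow pulsing with quiescence.

After light onset in the glutamate-blockade arm the trajectory rings for
~20–30 min (a damped oscillation into the depolarised focus) and can
emit one or two completed events before settling; the corresponding
in-vivo observation is an LH pulse immediately around stimulation onset
with cessation only once the laser is on.  Cessation and the reported
regime are therefore assessed on the final 45 min of the session
(105–150 min), and the `ceased` label takes precedence over the
interpulse-interval ratio.

## Synthetic LH data

Pulse trains are Gamma renewal processes (default interval CV 0.2, the
minimal quasi-periodic choice given that only group means ± SEM are
reported); the first pulse is uniformly offset within one mean interval.
Interval statistics switch from the control to the treatment setting at
60 min.  Serum LH is baseline plus per-pulse lognormal amplitudes
(mean 2 ng/ml, CV 0.3) decaying exponentially (τ = 15 min), sampled
every 5 min for 150 min, then multiplied by independent lognormal assay
noise with mean 1 and CV 4.6% (the intra-assay figure; the 10.2%
inter-assay variation is not applied by default since each experiment
uses one assay run).  Amplitude, baseline and clearance defaults are
plausibility choices tuned to resemble published OVX-mouse LH traces,
not biological estimates — the generator is a test harness for the
pipeline, and passing recovery tests demonstrates pipeline correctness
under this renewal model, not under real secretion dynamics (no
diurnal drift, no amplitude–interval correlation, no missing samples).

## Pulse detection and IPI analysis

The detector scans for local maxima and calls a pulse when the rise from
the preceding nadir exceeds both `min_rise_frac` (0.2) times the nadir
level and `k_sigma` (3) assay-noise standard deviations of it, with a
10-min refractory period.  On noisy synthetic cohorts at the default
settings it achieves ≥95% sensitivity with a false-call rate ≤0.1/h.
It is a deliberately simple two-threshold stand-in for published LH
peak-detection algorithms, whose exact parameterisations are not
reproducible here; no detector-level agreement with them is claimed.

Windows are pre = (0, 60] and post = (60, 150] minutes (a call at
exactly 60 min belongs to pre).  Windows with fewer than two calls carry
no interval information and are censored at 90 min — the zero-pulse rule
extended to the one-pulse case, with flags propagated so sensitivity
analyses can exclude censored animals.  Censored values enter group
means at the ceiling.

`compare_windows` delegates the time × treatment analysis to a mixed
ANOVA (window within-animal, arm between-animal; `pingouin.mixed_anova`).
With Gaussian animal effects its interaction test holds its nominal 5%
level (empirically ≈4% at 500 replicates); applied to pipeline output it
is conservative (≈2%), because grid quantisation (intervals are
multiples of 2.5 min) and 90-min censoring fatten the tails away from
normality.  How censored values should enter the ANOVA is genuinely
ambiguous; they are included at the ceiling here.

## Problem sizes

The committed study sizes are those of the in-vivo design: 8 arms with
group sizes (7, 4, 5, 5, 5, 5, 6, 4), 31 samples per animal.  Monte-Carlo
checks use 50 cohort replicates for IPI recovery, 10⁴ replicates for the
assay-noise CV, 500/200 replicates for the type-I/power checks, and a
20-draw ±10% weight-perturbation set for the direction-table robustness
property; these sizes give sampling errors comfortably below the asserted
tolerances.

## Known limitations

- The model is a lumped mean-field caricature: no spiking, no spatial
  structure, no estrogen feedback (animals are ovariectomised without
  replacement), unilateral stimulation treated as bilateral.
- The equations are this package's own minimal re-expression of the
  KNDy-oscillator concept; equivalence with any previously published
  implementation is not claimed, only the qualitative response pattern.
- Antagonist doses are abstracted to blockade fractions of 1; no
  dose–response information is represented.
- The quiescent-high plateau sits at mid-range firing rather than near
  `v_max`; what is robust is its phenomenology (elevated, non-pulsatile,
  entered via an upper input threshold), not its absolute level.
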