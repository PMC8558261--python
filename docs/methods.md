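# Methods

`taucable` implements a passive compartmental-cable analysis of dendritic
signalling in layer III neocortical pyramidal neurons, comparing wild-type
(WT) and rTg4510 tau-P301L transgenic (TG) populations. This note records
the model, its assumptions, the numerical choices, and what the synthetic
data do and do not establish.

## The model

Each neuron is a branched passive cable. Dendrites are discretized into
isopotential cylindrical compartments coupled by axial resistances; the
soma is a single isopotential sphere. The state equation is

    C dV/dt = −G V + I(t) − g_syn(t) (V − E′),

with `C` the diagonal membrane-capacitance matrix, `G` the symmetric
leak-plus-axial conductance matrix, and `V` the deviation from rest. The
passive system is affine, so the resting potential (−75 mV WT, −65 mV TG)
enters only through the synaptic driving force `E′ = E_syn − E_rest`
(E_syn = 0 mV).

**Discretization rule.** No compartment is longer than 37 μm or 0.2 space
constants, λ = √(d·Rm/(4Ra)), evaluated with the spine-corrected membrane
resistance Rm/q and, conservatively, the narrowest diameter of the
unbranched section being divided. Because Rm is itself fitted, every fit
candidate re-compartmentalizes the morphology, so the rule always holds for
the parameters in force. Each compartment's diameter is the length-weighted
mean of the underlying reconstruction segments, whose own diameters are
the mean of their two endpoint radii ×2 (a segment leaving the soma takes
its distal diameter — the soma is a sphere, not a cable). Axial coupling
between adjacent compartment centres sums two half-cylinder resistances,
each with its own diameter; the soma contributes none.

**Spines.** Spines are not geometric objects. Each dendritic compartment's
specific capacitance and leak conductance are multiplied by
q = (A_spines + A_dendrite)/A_dendrite, with A_spines = ρ·l·1.5 μm² at
linear density ρ = 1.25 /μm (WT) or 1.00 /μm (TG). For a cylinder this
reduces to q = 1 + ρ·s/(π·d). The soma keeps q = 1. Electrotonic
quantities (λ, L) use the corrected Rm/q throughout.

**Units.** Internally μm, ms, mV, nA, MΩ, μS and nF, a dimensionally
closed set (MΩ·nF = ms, μS·mV = nA). Specific constants keep their
conventional units (Ω·cm², μF/cm², Ω·cm) at the API surface; all
conversions live in `taucable.units` and are tested.

## Membrane fitting

A two-step fit per neuron, mirroring the experimental protocol:

1. **Rm** is found by bracketed Brent iteration (initial bracket
   10³–10⁶ Ω·cm², widened once, relative tolerance 10⁻³) so that the
   steady somatic response to constant current gives the group's mean
   input resistance, Rin = ΔV/I (197 MΩ WT, 228 MΩ TG).
2. **Cm** (bracket 0.1–10 μF/cm²) so that a simulated 200-ms depolarizing
   somatic current step (+10 pA; results are amplitude-independent by
   linearity) reaches 63% of the peak depolarization at the group's mean
   time constant (32.5 ms WT, 35.2 ms TG).

Both maps are strictly increasing for a passive neuron, so the roots are
unique. The "63%" criterion is implemented as the 1 − 1/e level of the
steady-state plateau (computed exactly from the steady solver rather than
read off the 200-ms trace, which sits within a fraction of a percent of
it); on an isopotential sphere the measured τ63 then equals Rm·Cm to
within one integration step. The 63% crossing is located by linear
interpolation between grid points. Axial resistivity is fixed at
150 Ω·cm. Each neuron is fitted to its group's *mean* targets, as in the
study; per-neuron targets are accepted through the same interface.

## Solvers

* **Steady state**: sparse LU solve of G·V = I·e_site; Kirchhoff balance
  (Σ G_i V_i = I) holds to 10⁻⁹ relative.
* **Phasor**: (G + iωC)·Ṽ = I·e_site for sinusoidal drive; |Ṽ| is the
  settled amplitude. Cross-checked against the time domain at 50 Hz.
* **Time domain**: Crank–Nicolson at dt = 0.025 ms, unconditionally
  stable and second-order. Current sources are evaluated at half steps.
  The alpha-conductance synapse g(t) = g_max·(t/t_peak)·e^(1−t/t_peak)
  (g_max = 0.25 nS, t_peak = 0.5 ms) is also evaluated at half steps and
  folded into the implicit matrix; since only single diagonal entries
  change, the step reuses one LU factorization with a Sherman–Morrison
  (rank-k Woodbury) correction. A batched variant runs one single-synapse
  simulation per dendritic site simultaneously, one column each, against
  the same factorization — this is what makes whole-neuron EPSP-shape
  tables affordable (seconds per neuron).

## Descriptors

Per dendritic-compartment midpoint (the modelled synaptic locus):
steady-state and 50-Hz voltage transfer (somatic/local amplitude ratio),
current transfer (fraction of injected charge absorbed at the soma,
computed with the soma clamped to rest and equal, by reciprocity, to the
somatofugal voltage transfer — an identity the tests verify to 10⁻⁸),
centroid delays (local, propagation, total), somatic EPSP 10–90% rise
time and half-width from the alpha synapse, and electrotonic distance
L = Σ l_k/λ_k along the soma path (half of the site's own compartment).

Delays deserve a note. The centroid delay of a linear system is
independent of the transient input's shape, and equals the logarithmic
derivative of the transfer impedance at zero frequency:
−Z′_ij(0)/Z_ij(0) = [G⁻¹CG⁻¹]_ij/[G⁻¹]_ij. The descriptor table uses this
exact moment identity (two multi-right-hand-side solves per neuron); the
simulation route — trapezoid centroids of baseline-subtracted 400-ms
Crank–Nicolson traces under an alpha current — is implemented as the
`delays()` operation and agrees with the moment route to ~0.01 ms, which
is asserted in the tests. The input centroid uses the half-step current
samples the integrator actually delivers, so discontinuous pulses carry
no O(dt) bias.

Area-weighted summaries Σ A_i·D_i/Σ A_i weight each site by its receptive
surface. A_i includes the spine membrane (q·A_d) by default — surface as
a proxy for synapse count should count spines — with a switch for smooth
areas; the source protocol does not say which was used. Mean and
within-cell variance (ddof = 1) of L over sites are the two
pattern-recognition predictors.

## Group comparison statistics

Two graph families per descriptor × arbor × scale: descriptor vs path
distance (distance dependence) and fraction of arbor surface vs
descriptor value (surface distribution). Normalized scales express the
binning axis as a percentage of each neuron's own maximum, landing every
neuron's maximum in the last bin. Default bin widths — 50 μm for absolute
distance, 10% normalized, 0.05 for transfers, 2 ms for delays and
half-widths, 1 ms for rise times — are package conventions mirroring the
granularity of the published graphs; all are configurable. Each neuron
contributes at most one value per bin (the bin mean of its sites, or its
surface fraction), so neurons are the independent units. In surface mode
a neuron contributes values (including zeros) only between its first and
last occupied bins.

Each graph gets a two-way fixed-effects ANOVA (group × bin, type-II sums
of squares via statsmodels OLS) and per-bin two-sample t tests (pooled
variance, consistent with the ANOVA; Mann–Whitney available) with
Bonferroni correction over the eligible bins — those with at least three
values in both groups. Scalar quantities (fitted Rm/Cm, area-weighted
means, electrotonic predictors) use two-sided Mann–Whitney. Distribution
identity (length vs surface area) uses a Kolmogorov–Smirnov statistic on
cumulative binned curves with the classical asymptotic p at effective
n = number of bins — approximate, because weighted fractions are not
i.i.d. samples, and flagged as such. The headline vulnerability metric is
the percentage of eligible intervals flagged by the post hoc tests,
aggregated per descriptor/arbor/scale and combined.

**A calibration caveat.** On exchangeable data (neuron-bin values drawn
i.i.d.) the cascade holds its nominal size: 5% group-effect rejections
over 400 seeded null replicates, asserted in the acceptance tests. Under
a *morphological* null — both pseudo-groups drawn from the same generator
preset — the overall ANOVA group effect is anti-conservative (rejection
≈ 0.3), because a neuron's values across bins are correlated
(neuron-level random effects that a fixed-effects ANOVA ignores). The
per-bin Bonferroni flags, on which the percent-significant metric rests,
remain conservative under that null (false-flag fraction ≲ 2% of
eligible bins, also asserted). Overall ANOVA p-values on real comparison
graphs should therefore be read as descriptive; the interval-level
conclusions are the calibrated ones. A mixed-effects model would address
this but is outside the analysis being reproduced.

## Synthetic populations

The generator emulates two pyramidal-like populations so the entire
pipeline runs without any reconstruction files. A neuron is a spherical
soma (WT 146.2 μm², TG 205.2 μm², the groups' mean reconstructed areas),
3–5 basal stems grown as a Galton–Watson branching process (branch
probability per segment, truncated at depth 6) with lognormal segment
lengths, per-order diameter taper and a path-length cap, plus an apical
trunk with stochastic obliques and a terminal tuft whose segment lengths
scale with `tuft_size_factor`. All randomness comes from one
`numpy.random.default_rng(seed)` (PCG64): a seed determines the SWC
output bit-exactly.

Preset contrasts (TG-like vs WT-like): spine density 1.00 vs 1.25 /μm,
tuft scale 0.6 vs 1.0, thinner stems (1.3 vs 1.6 μm), larger soma, and
near-matched total membrane area (slightly longer inter-branch segments).
The area matching is deliberate: the study's central negative finding is
that fitting each group to its own Rin/τ means yields statistically
indistinguishable Rm and Cm, with Cm near 1 μF/cm² — so the generator is
calibrated to reproduce that regime, and does (WT Cm ≈ 1.0–1.3, groups
overlapping). With these presets the populations also reproduce the
study's positive signature: area-weighted total delays significantly
larger in TG-like neurons in both arbors (≈ 42 → 46 ms apical,
36 → 40 ms basal at n = 10+10) with unchanged electrotonic predictors.
Tree sizes give ≈ 100–300 injection sites per neuron, matching the
reported range.

What the synthetic data are *not*: statistically faithful replicas of the
NeuroMorpho reconstructions. They lack realistic branch-angle statistics,
diameter profiles (taper within segments), 3D space-filling, and
within-group morphometric covariances. Passing tests therefore establish
correctness of the machinery and reproducibility of the study's
qualitative group signature under study-like conditions, not a
quantitative reproduction of the published group numbers, which would
require the original reconstructions.

## Problem sizes and runtimes

Defaults chosen as the package's own working sizes: the packaged demo
runs 10+10 neurons end to end (fits ≈ 2 s and EPSP-shape tables ≈ 7 s per
neuron on one core); the statistics null calibrations use 400 i.i.d.
replicates and 40 generator replicates of 5+5 neurons with the cheap
(non-EPSP) descriptors; the qualitative-signature check uses 10+10
neurons. Simulation windows: 400 ms for centroid/EPSP measurements
(> 10τ; centroid truncation error < 10⁻³ ms), 200 ms for τ63.

## Known limitations

* Passive membrane only — no Na⁺/K⁺/I_h, no NMDA voltage dependence; the
  analysis inherits this assumption from the study design.
* Compartments are untapered cylinders; intra-compartment taper is
  averaged away.
* The KS p-value on weighted binned distributions is approximate (see
  above).
* Multi-point somata collapse to one sphere (override or mean-radius
  convention); no shrinkage correction or morphology repair.
* The fixed-effects ANOVA caveat above.
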