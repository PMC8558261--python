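# taucable

Passive compartmental-cable analysis of dendritic signalling in layer III
neocortical pyramidal neurons: wild-type (WT) versus rTg4510 tau-P301L
transgenic (TG) mice.

Tauopathy remodels pyramidal-cell dendrites — spine loss, apical-tuft
atrophy, thinner dendrites — while leaving somatic passive properties
almost untouched. `taucable` asks what those morphological changes do to
*subthreshold dendritic signalling*. It builds morphologically detailed
passive cable models from SWC reconstructions (or from its own seeded
synthetic populations), fits each neuron's specific membrane constants to
measured physiology, and quantifies how well every dendritic site talks to
the soma, with full group-comparison statistics. It is aimed at
computational neuroscientists studying dendritic integration and
neurodegeneration.

## Model

Dendrites are divided into isopotential cylinders (≤ 37 μm and ≤ 0.2λ,
λ = √(d·Rm/4Ra)), the soma is a single sphere, and the passive cable
system

    C dV/dt = −G V + I(t) − g_syn(t)(V − E′)

is solved in steady state, in the frequency domain, and in time
(Crank–Nicolson, dt = 0.025 ms). Dendritic spines are folded into each
compartment's specific capacitance and conductance via
q = (A_spines + A_dend)/A_dend (1.25 spines/μm WT, 1.00 TG, 1.5 μm²
each). Per neuron, a two-step fit finds Rm from the somatic input
resistance (Rin = ΔV/I; 197 MΩ WT, 228 MΩ TG) and then Cm from the
membrane time constant (63%-of-peak on a 200-ms step; 32.5 ms WT,
35.2 ms TG), with Ra = 150 Ω·cm.

For every dendritic compartment midpoint the package computes:

* steady-state and 50-Hz **voltage transfer** V_soma/V_site;
* **current transfer** — the fraction of injected charge reaching the
  soma, equal by reciprocity to the somatofugal voltage transfer;
* **centroid delays** — local, propagation, and total;
* somatic **EPSP shape** (10–90% rise time, half-width) for an alpha
  synapse (g_max 0.25 nS, t_peak 0.5 ms, E_syn 0 mV);
* **electrotonic distance** L = Σ l_k/λ_k, whose per-neuron mean and
  variance predict synaptic input pattern-recognition capability.

Descriptors are summarized as area-weighted means Σ A_i·D_i/Σ A_i and
compared between groups with two-way ANOVA + Bonferroni post hoc tests
per distance/descriptor bin (bins need ≥ 3 neurons per group),
Mann–Whitney tests on scalars, and Kolmogorov–Smirnov identity tests for
the length vs surface-area distributions. See `docs/methods.md` for the
full account.

## Worked example

Fit and analyze one synthetic WT-like neuron:

```python
from taucable.cable_model import MembraneParams, compartmentalize
from taucable.fitting import WT_TARGETS, fit_membrane
from taucable.synthetic_data import load_presets, sample_population
from taucable.descriptors import descriptor_table, area_weighted_mean

m = sample_population(load_presets()["wt_like"], 1, 42)[0]
p0 = MembraneParams(E_leak=-75.0, spine_density=1.25)
fitted, rep = fit_membrane(m, WT_TARGETS, p0)
print(f"Rm = {rep.Rm:.0f} ohm cm2, Cm = {rep.Cm:.3f} uF/cm2")
print(f"achieved Rin = {rep.achieved_Rin:.2f} MOhm, tau63 = {rep.achieved_tau:.3f} ms")

model = compartmentalize(m, fitted)
tbl = descriptor_table(model)
print(f"awm delay apical: {area_weighted_mean(tbl, 'delay_total', 'apical'):.1f} ms")
print(f"awm delay basal:  {area_weighted_mean(tbl, 'delay_total', 'basal'):.1f} ms")
```

prints

```
Rm = 24598 ohm cm2, Cm = 1.681 uF/cm2
achieved Rin = 197.00 MOhm, tau63 = 32.500 ms
awm delay apical: 45.0 ms
awm delay basal:  37.2 ms
```

i.e. the fit reproduces the WT group's measured input resistance and time
constant exactly, and an average synapse (weighted by receptive surface,
a proxy for synapse count) is felt at the soma ≈ 37–45 ms after its
current flows, depending on the arbor.

The full pipeline — generate both populations, fit every neuron, build
all descriptor tables and comparison statistics — runs from one command
(≈ 6 minutes for the packaged 10+10 demo):

```bash
taucable demo --out-dir demo_run --seed 1
taucable report demo_run
```

The report tabulates group means with Mann–Whitney p-values (e.g.
area-weighted total delays 36.2 → 39.9 ms basal, p = 0.001, with
unchanged electrotonic predictors and specific Rm/Cm) and the percentage
of intervals with significant WT/TG differences per descriptor — delays
being the most altered descriptor and current transfer the least, in both
arbors. Individual stages are available as `taucable generate / fit /
descriptors / compare`, driven by a YAML config.

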