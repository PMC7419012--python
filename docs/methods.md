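# Methods

This note documents the models, estimators and numerical choices behind
`olivenet`, in the package's own words.

## The biophysical network model

Each model neuron has six compartments: a soma, a main dendrite and four
glomerular spine compartments.  The soma carries an inactivating Na current
(g_Na = 110 mS/cm², raised from the classic olivary value to move the
coupled network into an irregular-firing regime), a delayed-rectifier K
current (18 mS/cm²), a low-threshold Ca current (1.6 mS/cm² mean, see
heterogeneity below), an h-current (0.25 mS/cm²) and leak; the dendrite
carries a high-threshold Ca current (4.5 mS/cm²), a Ca-gated K current
(35 mS/cm²) and leak, plus a first-order Ca pool driven by the Ca current.
Gating kinetics follow the canonical olivary soma/dendrite formulation; every
rate constant is exposed through `NeuronParams`.

The four spines per neuron carry the couplings.  Each spine holds one gap
junction to the matching spine of one of the four grid neighbours
(conductance g_c, drawn per junction uniformly within ±20% of the configured
mean) and a GABAergic conductance g_i.  Because the spine membrane area is
negligible next to its axial (g_s = 0.1 mS/cm²), junctional and synaptic
conductances, spine voltages are solved quasi-statically: for each junction a
2×2 linear node system gives both spine voltages at once.  This removes the
stiffest time scale exactly at steady state while preserving the coupling
circuit, which is what the effective coupling

    g_eff = g_s · g_c / (2 g_c + g_i + g_s)

summarizes: the series path dendrite → spine → gap junction → spine →
dendrite, shunted by the GABAergic conductance.

The GABAergic conductance acts through two routes.  A tonic fraction
(`tonic_fraction`, default 0.1) is always open — this is the component probed
by the noise-free coupling-coefficient protocol, where the printed values
differ between conditions almost entirely through g_i.  The remainder gates
the spine inhibitory synapses: each spine IPSP has amplitude
`spine_inh_gain · g_i` (default gain 0.45), so lowering g_i
(the picrotoxin condition) both opens the junctional path and disinhibits
the cell.

### Calibration

The study design fixes g_Na, g_s and the varied (g_i, g_c); everything else
is a modelling choice.  We calibrated the free parameters once, against the
model-side statistics the analysis itself defines, using two tools:

1. a steady-state linearization of the full network (fixed point via root
   finding, Jacobian by finite differences), giving the small-signal
   coupling coefficient and the eigenvalue structure of the resting state.
   The requirement that the hyperpolarized network reproduces coupling
   coefficients of ~0.012 (control) and ~0.019 (GABA-A block), while the
   resting state remains an unstable focus near 4–8 Hz (the olivary
   subthreshold oscillation), jointly pins the soma–dendrite coupling
   (g_int = 0.25), the glomerular coupling scale (`spine_scale` = 1.1, the
   factor converting spine-local conductance densities into reference-area
   currents), the tonic GABA fraction and the h-current density;
2. simulation scans of the noisy network, setting the synaptic event
   amplitudes (excitatory 0.007, inhibitory 0.001 mS/cm² per event; decay
   1 ms / 5 ms) so that the network at the control-condition conductance
   means fires ~1.4 spikes/s and at the picrotoxin means ~2.2 spikes/s with
   10-ms pairwise synchrony ~0.11.

Per-neuron heterogeneity of the low-threshold Ca conductance (±30%,
uniform) detunes the natural oscillation frequencies; without it the nine
cells settle onto identical limit cycles and coupling changes phase but not
rate.  Synapse counts are 10/80/10 (soma/dendrite/spines), each excitatory
and inhibitory, driven by independent Poisson generators; inhibitory rates
of 10/20/50/70 Hz define the four candidate models of the inference.

### Integration and protocols

Fixed-step integration at dt = 0.05 ms (exponential Euler on gating
variables, forward Euler on voltages); a convergence test checks that
halving dt changes noise-free rates by <5%.  Spikes are upward crossings of
−20 mV at the soma with a 10-ms lockout — one somatic event per olivary
discharge.  Injected currents are referenced to total cell area and
delivered to the soma.  The coupling-coefficient protocol holds all somata
with −1 µA/cm², steps the centre soma by −1 µA/cm² for 2 s after an 8-s
settling period, verifies baseline drift < 0.01 mV/s, and averages the four
neighbour/master steady-state deflection ratios (steady state = last 20% of
each window).

### Known limitations of the model

- The carbenoxolone condition's strong rate suppression does not reproduce:
  in our calibration the weaker inhibition of that condition (lower g_i than
  control) offsets its weaker coupling, leaving its rate near the control
  value instead of ~0.4 spikes/s.  The picrotoxin > control rate ordering is
  robust.
- The simulated coupling coefficient is nearly flat along g_c (the junction
  transfer saturates once g_c ≫ g_s plus the tonic shunt) but steep along
  g_i, so CC is not a clean one-dimensional function of g_eff over the full
  conductance square.  Over the condition-ranged sweep the cubic CC ~ g_eff
  regression explains ~80% of the variance on average, but the
  finite-sample R² scatters between sweeps (~0.64–0.87 for 60-point
  samples), so sweep-based reports average several independent samples.
- The complexity entropy (below) rises with effective coupling and
  saturates; the falling branch at strong coupling — synchronized rhythmic
  firing suppressing complexity — does not materialize, because synaptic
  noise diffuses the collective oscillation phase even at the strongest
  couplings sampled.  The fitted peak of the complexity-versus-coupling
  curve is therefore poorly determined, scattering between ~0.031 and
  ~0.047 mS/cm² across network realizations instead of marking a robust
  interior optimum.

## Features and inference

Each neuron-segment is summarized by 67 features: rate (1), local variation
(1), 25 auto-correlogram bins (50-ms bins, 0–1.25 s), 20 pair-averaged
cross-correlogram bins (10-ms bins, ±100 ms) and 20 pair-averaged
minimal-distance fractions (50-ms bins).  The composition is a
reconstruction from the named feature families and printed bin widths, and
is fully configurable.  Correlogram bins hold per-reference-spike partner
probabilities, computed identically for simulated and recorded data.
Sentinel (undefined) entries of near-silent segments are imputed with the
library median before the z-scored PCA; three components are retained.

Inference is grid-based: 50-s segments, an isotropic Gaussian likelihood in
the 3-dim PCA space whose scale defaults to the library's median
nearest-neighbour projection distance, and a flat prior over the grid.  The
neuron-level posterior multiplies segment likelihoods smoothed with a
Gaussian of width σ on the parameter grid; σ is selected from a logarithmic
candidate grid (0.05–2 grid units) by minimizing the mean PCA error between
the data segments and the library vector at the resulting point estimate.
Evidences are grid averages of the segment likelihoods (the model-evidence
integral as a Riemann sum on the grid support), and the four noise-level
models are averaged with evidence-proportional weights under a uniform model
prior.  Point estimates are marginal posterior means.  The g_eff → CC
mapping is a polynomial fit to noise-free protocol sweeps.

## Population metrics

Synchrony is the zero-lag correlation coefficient of 10-ms binarized trains
(multiple spikes per bin clip to 1); per-neuron synchrony averages over all
partners, skipping zero-variance sentinels.  Dimensionality is the
participation ratio 1/Σλ̃² of the covariance eigenvalues of per-neuron rates
sampled in 50-s windows slid by 10 ms; it ranges from 1 to N and is
reported normalized by N when ensembles of different size are compared.  The
sliding-window variant computes both metrics at the 10-ms timescale inside
5–50-s windows advanced in 1-s steps and reports their correlation.

## Complexity entropy

Spike trains are sampled in 50-s windows every 2 s.  Window pairs are
compared with a spike-train edit distance (insert/delete cost 1, shift cost
0.2 per second); to remove the discontinuity caused by spikes crossing
window borders, each window derives four variants including the single
nearest spike outside each edge, and the minimum over the 16 derived pairs
is used.  The matrix is repaired to its shortest-path closure, thresholded
at a fixed 10% recurrence rate (threshold = 10% quantile of off-diagonal
distances; main diagonal excluded from the rate and recurrent by
construction), and the Shannon entropy H (bits) of the diagonal-line-length
histogram (minimum line length 2) is summarized as 1/H.

The line-length entropy depends on the number of sampled windows: at 100 s
only 26 windows exist and 1/H is an order of magnitude above the scale
obtained at the study's native 500-s recordings (226 windows).  The
package's sweep protocols use 300-s simulations (126 windows), the shortest
duration that reproduces the native scale (1/H ≈ 0.20–0.24).

Model-side chaos is quantified directly: Benettin/QR Lyapunov spectra
(RK4 reference trajectory, tangent propagation via the Jacobian or finite
differences, re-orthonormalization every 0.05 time units, with a tangent
warm-up phase discarded so the frame aligns with the Oseledets subspaces)
and the Kaplan–Yorke dimension.  The complexity ↔ λ₁ link is an OLS
regression utility (`entropy_lyapunov_map`).

## Surrogate generators

The common-source surrogate plants synchrony: a hidden mother Poisson train
of the target rate is copied into each neuron with probability p (Gaussian
jitter, default 2 ms — well inside the 10-ms synchrony bin), topped up with
an independent Poisson train at rate (1−p)·rate so per-neuron rates match
the target for every p.  Measured synchrony is continuous and monotone in p,
which makes the generator a controllable test bed for the synchrony and
dimensionality estimators.  Surrogates emulate the first-order statistics of
the three pharmacological conditions (rates ~0.4/1.3/2.2 spikes/s,
synchrony ~0.02/0.06/0.19) but none of the rhythmicity, refractoriness or
spatial structure of olivary recordings — tests passing on surrogates
validate the estimators, not the biology.

## Problem sizes

Default analysis sizes were chosen to make the full pipeline and its checks
run comfortably on a single CPU: condition simulations of 150 s (averaged
over three network realizations), conductance sweeps of 16 points at 300 s,
coupling-coefficient sweeps of 50–60 protocol runs, and coarse 5×5
inference libraries at 100 s per grid point for recovery experiments.  All
sizes scale up through the public APIs (the full 41×41 grid at 500 s per
point is a `run_parameter_grid` call away).
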