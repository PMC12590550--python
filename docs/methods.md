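# Methods

## Scope and modelling stance

`pvrhythm` tests one mechanism at desk scale: with the total synaptic input
to PV+ fast-spiking basket cells (FSBCs) held fixed, routing that input to
supralinear versus sublinear dendritic branches should bidirectionally
switch interneuron firing, the circuit's E/I balance, and the slow versus
fast LFP components of a small hippocampal microcircuit. The package
deliberately does **not** reimplement multicompartmental conductance-based
neurons, anatomical reconstructions, or a volume-conductor extracellular
electrode. Those are replaced by:

* a **two-layer FSBC**: per-branch nonlinear transfer feeding an
  exponential integrate-and-fire (EIF) soma;
* **single-compartment EIF pyramidal cells (PCs)** with spike-triggered
  adaptation and purely linear synaptic collection (compartment tags only
  scale current delivery);
* a **synaptic-current LFP proxy**: the sum over PCs of the absolute
  synaptic currents they receive, mean-subtracted.

This preserves exactly the degrees of freedom the hypothesis is about —
placement × integration mode — while making a 30-trial experiment a matter
of seconds.

## Dendritic transfer

Branch drive `x` is the instantaneous excitatory conductance (CP-AMPA plus
magnesium-gated NMDA) mapped onto that branch, in nS.

* Sublinear: `g_sub(x) = x / (1 + x/σ)`, strictly concave, saturating at
  `σ = 6 nS`. Concavity makes dispersed placement more effective than
  clustered on these branches, and caps what any single branch can pass.
* Supralinear: `g_sup(x) = x + A/(1+e^{-(x-θ)/k}) − A/(1+e^{θ/k})`, the
  linear response plus a sigmoidal local-spike boost: threshold `θ = 3 nS`
  (a few near-coincident synapse pairs), boost `A = 6 nS`, slope
  `k = θ/3 = 1 nS`. The softened slope (rather than a near-step) keeps the
  boost from chattering on and off with fast synaptic noise.
* Somatic coupling weights `w_supra = 1.0`, `w_sub = 0.4` encode the
  stronger forward propagation of the large supralinear branches.

The somatic drive `Σ_b w_b g_mode(x_b)` acts as an excitatory conductance
at the FSBC soma. It is bounded by `w_supra Σx + n_supra·A` — local spikes
add bounded extra drive, never unbounded amplification.

## Cells

EIF update `τ dV/dt = −(V−E_L) + Δ_T e^{(V−V_T)/Δ_T} + R_m (I_syn − w)`,
spike at `V ≥ −25 mV`, reset and refractory hold, adaptation
`dw/dt = −w/τ_w`, `w += b` per spike.

|            | τ_m | E_L | V_T | Δ_T | reset | refr. | R_m | b (nA) | τ_w |
|------------|-----|-----|-----|-----|-------|-------|-----|--------|-----|
| PC         | 20 ms | −70 | −50 | 2 | −60 | 3 ms | 120 MΩ | 0.02 | 250 ms |
| FSBC       | 10 ms | −65 | −48 | 1 | −58 | 1 ms | 80 MΩ | 0 (non-adapting) | — |

Per-trial heterogeneity: resting potentials jittered uniformly ±1.5 mV from
the trial seed. The dynamics are otherwise deterministic; trial-to-trial
variability comes entirely from the random wiring, placement, and input
realizations, as in the study design this emulates.

## Synapses

Difference-of-exponentials conductances, peak-normalized; events queued at
spike time + 1 ms and applied on the next 0.1 ms step.

| kind | rise/decay (ms) | reversal (mV) | where |
|------|-----------------|---------------|-------|
| AMPA | 0.5 / 2 | 0 | onto PCs |
| CP-AMPA | 0.2 / 1 | 0 | onto FSBC branches |
| NMDA | 2 / 50 | 0 | both; gate `1/(1+([Mg]/3.57)e^{−0.062V})`, [Mg]=1 mM |
| GABA_A (FSBC→PC) | 0.2 / 2 | −72 | perisomatic |
| GABA_A (autapse) | 0.5 / 8 | −72 | FSBC soma |

Peak conductances (nS): input→PC AMPA 5.5 / NMDA 1.0; PC→PC 4.0 / 1.0;
input→FSBC CP-AMPA 1.0 / NMDA 0.4; PC→FSBC 3.5 / 0.8; FSBC→PC GABA 3.5 per
contact (13 contacts per target PC); autapse 100. A single `scale` factor
multiplies the whole table for the ±15% sensitivity sweep.

Deliberate choices here:

* The **autapse** is large and slow relative to the transmission IPSC: it
  functions as the fast-spiking cell's pacing conductance, so that an FSBC
  under sustained drive fires a regular gamma-range train whose frequency
  grows with drive. This is the reduced stand-in for the intrinsic and
  autaptic machinery that makes real FSBCs precise fast oscillators.
* The **perisomatic IPSC is fast (2 ms)** so the gamma comb it imprints on
  the LFP proxy is not low-pass filtered away.
* The **GABA reversal (−72 mV)** sits just below both resting potentials:
  inhibition is mostly shunting. With a strongly hyperpolarizing reversal,
  the arm with the most inhibition (supralinear placement) would trivially
  dominate every LFP band through driving-force growth, masking the
  PC-activity-dependent slow component the comparison is about.
* The conductance table is a calibrated stand-in, not measured values: it
  was tuned once against two constraints — an isolated FSBC receiving only
  its 7 artificial inputs stays subthreshold (the deliberate design of the
  input layer), and PCs fire on theta cycles — and then frozen.

## Input layer

22 artificial neurons; homogeneous Poisson candidates (40 Hz each) thinned
by `p(t) = (sin(2π f_θ t/1000 + φ)+1)/2 > 0.7`, `f_θ = 4 Hz` by default.
Thinning retains the fraction `(π − 2 asin 0.4)/(2π) ≈ 0.369` of
candidates, in a contiguous window around each theta peak — so the input is
a theta burst train, not a sinusoid. Phase is exposed as a *fraction of a
cycle* (`φ_radians = 2π·frac`); the sensitivity shift of 0.5 means half a
cycle. Each PC samples 5, each FSBC 7 of the 22 sources per trial.

## Microcircuit and protocols

Counts per trial: 20 PCs, 2 FSBCs; 7 PC→PC targets per PC (AMPA+NMDA per
contact); 15 PC sources per FSBC (CP-AMPA+NMDA pairs); 5 target PCs × 13
GABA_A contacts per FSBC; one autapse each. The 22 placement-controlled
pairs per FSBC (15 local + 7 input) are assigned to branches by protocol:
dispersed (each pair an independent random eligible branch) or clustered
(4 random eligible branches, 5–7 pairs each); eligibility is all branches,
supralinear only, or sublinear only; tree variants replace every branch
with the mode-mean geometry ("purely supralinear/sublinear trees").
Simulation: 12,000 ms at 0.1 ms (the analysis default throughout), first
200 ms discarded, LFP at 10 kHz.

Synthetic trees: 30 branches per FSBC, 12 supralinear (diameter 1.0–1.6 µm,
length 80–160 µm) and 18 sublinear (0.4–0.8 µm, 20–60 µm), drawn once per
experiment. These are configurable placeholders reproducing the qualitative
volume/input-resistance contrast, not reconstructions.

## Experiments and statistics

`run_experiment` uses a paired-seed design: within a trial index all arms
share connectivity, input spikes and membrane jitter; only placement
differs. Thirty trials per arm. Group tests: Kruskal–Wallis (tie-corrected,
χ² approximation) with Holm-adjusted pairwise Mann–Whitney post-hocs
(named in the source literature only as "a post-hoc correction"; Holm is
the conservative distribution-free choice). Mann–Whitney p-values are exact
by enumeration for min(n) ≤ 8 (midrank ties) and normal-approximated with
tie and continuity corrections above. Directional claims use one-sided
Mann–Whitney at α = 0.05.

The synapse-count sweep holds the 7 input pairs fixed and varies local
pairs (sampling PC sources with replacement above 20); default levels
{11, 22, 33, 44, 66}. The sensitivity catalogue re-runs the three arms
under conductance ×1.15, ×0.85, `f_θ = 5 Hz`, and the half-cycle phase
shift.

## Spectral and coupling analysis

* Band-pass: 4th-order Butterworth, zero-phase (forward-backward), bands
  3–10 and 30–200 Hz.
* Welch: segment length fs/0.4 (25,000 samples at 10 kHz), Hann window,
  50% overlap, constant detrend; band peak = (argmax, max) on the raw PSD
  restricted to the band, ties to the lowest frequency (the band-passed
  route is available as well).
* PAC: complex Morlet, ω₀ = 6; phase at 15 linear levels 1–15 Hz, amplitude
  at 50 linear levels 30–180 Hz (the 30–180 coupling grid is kept distinct
  from the 30–200 analysis band); 18 phase bins; `MI = (ln N − H(P))/ln N`
  with empty bins taking their zero-probability limit and the all-zero
  amplitude case defined as 0. Traces are FIR-decimated to 1 kHz first, and
  two wavelet scales of both the phase and the amplitude row are discarded
  at each end (capped at a quarter of the trace per side).

## What the synthetic generators do and do not emulate

The coupled test signal `sin(2πf_s t) + a[1+κ sin(2πf_s t)]sin(2πf_f t) +
noise` maps κ monotonically onto MI and carries its ground truth in
metadata. Its default Gaussian background (σ = 1, comparable to the
carrier) is load-bearing: for a noiseless line spectrum the Morlet phase is
leakage-driven everywhere off the lines, and the constant-Q comodulogram
forms a plateau skewed toward the upper sideband rather than a peak at
(f_slow, f_fast). Coupling only localizes against a broadband floor — which
real field potentials always provide. Passing fixtures therefore validate
the pipeline for broadband-background signals; they say nothing about line
spectra, and nothing about real-data artifacts (nonstationarity, 1/f
slope, volume conduction) the generator does not model.

The circuit itself is likewise an idealization: two interneurons cannot
produce population-averaged gamma, so the fast band is carried by the
pacing combs of the individual FSBCs riding on the theta-harmonic scaffold
of the burst-gated input currents.

## Known limitations

* **Sensitivity edges.** The fast-band argmax of both placement arms can
  fall on the same theta-harmonic bin when the gamma comb weakens: under
  conductance ×0.85 and under 5 Hz theta (whose 6th harmonic sits exactly
  at the 30 Hz band edge) the fast-peak-frequency ordering, and at ×0.85
  the slow-power ordering, become statistical ties at 30 trials. Rate, E/I
  and fast-peak-power orderings persist under all four perturbations.
* **High synaptic loads.** At 66 pairs per FSBC the sublinear arm's added
  broadband fast power catches up with the supralinear arm's (whose comb
  smears as its pacing gets drive-dominated); the fast-power separation is
  significant at 11–44 pairs.
* **Coupling direction under clustering.** In this reduced model the
  clustered purely-supralinear-tree configuration shows slightly *higher*
  maximum MI than the purely-sublinear one (strong theta-nested gamma is,
  by construction, strongly phase-amplitude coupled). The reported
  comparison is computed by `scripts/acceptance.py`; treat its direction as
  a property of the proxy + reduced dynamics, not a validated prediction.
* The E/I index `mean PC rate / (mean FSBC rate + ε)` diverges toward ε⁻¹
  scale when the basket cells are silent; compare it only within an
  experiment.
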