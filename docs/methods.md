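# Methods

## Model

`hstheta` simulates a conductance-based spiking network of the hippocampal
CA1 region and the medial septum, and quantifies how multiplicative changes
to specific pyramidal-cell conductances — the modeled electrophysiological
action of beta-amyloid — reshape the network's theta (4–7 Hz) rhythm.

Four populations are simulated (sizes fixed at 10 pyramidal, 100 basket,
30 OLM, 50 septal GABAergic cells). Pyramidal cells are two-compartment
(soma, dendrite) Hodgkin–Huxley models coupled through a conductance `g_c`
with somatic area fraction `p`; soma carries I_Na, I_K, leak, L-type I_Ca,
I_h and I_A; the dendrite carries leak, I_Ca, I_h, I_A (higher density than
the soma), the calcium-activated I_AHP and the BK-type I_CT, each BK/AHP
channel gated by its own first-order calcium pool
`d[Ca]/dt = −B·k·I_Ca − [Ca]/τ_Ca`. Basket cells are one-compartment
fast-spiking cells (I_Na, I_K, leak); OLM cells add I_Ca, I_h and I_AHP;
septal GABAergic (MSGABA) cells add a slowly activating/inactivating
potassium current I_KS whose slow kinetics make the isolated cell a 4–8 Hz
pacemaker: the gate builds up over spikes (activation τ ≈ 120 ms engaged
only at spike voltages) and relaxes during silence, producing rhythmic
single-spike firing. All gating follows standard Hodgkin–Huxley forms
(alpha/beta rate pairs or steady-state/time-constant pairs), declared in
the parameter file and shared between cell classes where appropriate.

Synapses are transmitter-typed: pyramidal→basket AMPA, pyramidal→OLM
AMPA+NMDA (Jahr–Stevens magnesium block), all other projections GABA_A.
Gating is a dual exponential (difference of exponentials, unit peak per
presynaptic spike). Connectivity is sparse and random with a fixed
per-target in-degree. The default wiring is: pyramidal→{basket, OLM},
basket→pyramidal soma, OLM→pyramidal dendrite (slow, τ_decay 50 ms),
basket→basket, MSGABA→{basket, OLM, MSGABA}, OLM→MSGABA. The
septal-to-OLM line — supported by septohippocampal anatomy, where septal
GABAergic fibers preferentially target hippocampal interneurons — is the
structural element that lets the septal pacemaker time the OLM volleys
while their *size* is set by pyramidal recruitment; without it the
hippocampal loop free-runs and its frequency tracks pyramidal excitability
instead of the pacemaker.

Every number is configuration: the shipped `config/default.yaml` is the
"control" (healthy) condition. The primary literature for this circuit
does not pin most constants in its running text, so the defaults were
assembled from the standard source-model families for each cell class and
tuned **once** so the control network expresses the target state: a robust
5–5.5 Hz field rhythm, very sparsely firing pyramids (mean rate below 0.1 Hz in control —
most CA1 pyramidal cells are near-silent at any given moment, and the
recruitment margin is exactly what the perturbation study probes), tonically active baskets gated by the
septal rhythm, and OLM volleys per theta cycle. Perturbation experiments
never re-tune anything; they multiply one targeted parameter.

## Why the A-current perturbation works the way it does

In the control state most pyramidal cells sit just below threshold: the
A-current's subthreshold window (linear a·b activation, half-activation
−45 mV) holds the dendrite hyperpolarized, and periodic OLM/basket
inhibition defines theta-phase windows. Reducing `g_A` (the modeled
amyloid block) has two compounding effects: the dendrite depolarizes
tonically, which both recruits previously silent cells into the rhythm and
enlarges the driving force of every dendritic IPSC; and recruited cells
fire inside the septally-timed windows, so their output amplifies the OLM
theta volley rather than dispersing it. Relative theta power, pyramidal
coherence and firing rate therefore rise together, while the rhythm's
frequency stays pinned by the septal pacemaker. Reducing the delayed
rectifier or scaling the calcium/BK system leaves the subthreshold balance
essentially untouched (I_K and I_CT act during spikes; the AHP pool
operates near calcium saturation), which is why those ladders are
negative controls. Strong A-block in both compartments eventually pushes
the network off the sparse regime: coherence and rate keep growing but
relative theta power peaks and then declines as activity spreads across
the cycle; the dendrite-only ladder used for the theta contrast stays in
the rising regime at scales ≥ 0.6.

## Signals and statistics

The LFP proxy is the summed synaptic current onto the pyramidal
population, recorded as 1-ms block averages, low-passed at 40 Hz
(4th-order Butterworth, zero-phase forward–backward). Spectra average
magnitude-squared FFTs of 2-s Hann-tapered segments with 50% overlap
(0.5 Hz resolution). Relative band power is the percentage of total
(0, 40] Hz power, DC excluded, lower band edge exclusive / upper
inclusive, so {0–4, 4–7, 7–40} partitions to exactly 100%. Autocorrelation
(for the rhythmicity contrast) uses the summed pyramidal membrane
potential.

Population coherence is the binary-bin coefficient: trains binned at
τ = 10 ms over the 9-s post-transient window, pairwise
κ = Σ X·Y / √(ΣX·ΣY), averaged over all unordered pairs; silent trains
contribute κ = 0 (a silent neuron is maximally unsynchronized). Firing
rates use raw spike counts over the post-transient window.

A *trial* is a seeded 10-s integration with 1.5 mV membrane noise; the
first 1 s is discarded. Each trial redraws drives, connectome and noise
from trial-indexed seeds — one trial = one simulated patient. Condition
groups run 15 trials; trial seeds are shared across conditions, giving a
matched (paired) design, which the single-trial matched-noise contrasts
require and which only makes the unpaired one-way ANOVA conservative.
Each condition is compared to control with a separate one-way ANOVA
(F = MS_between/MS_within), with no family-wise correction — a documented
limitation. Degenerate inputs (zero within-group variance) yield p = 0
with a warning; fully identical groups yield F = 0, p = 1.

## Numerics

Fixed step dt = 0.05 ms, with a predictor–corrector scheme built for stiff
conductance models: an exponential-Euler predictor for each membrane
potential (conductances frozen over the step), gate updates by
exponential-Euler via (x_inf, exp(−dt/τ)) lookup tables on a 0.05 mV grid
evaluated at the predictor's midpoint voltage (cancelling the lag of the
quasi-instantaneous Na activation), then a Heun-like corrector that
recomputes the conductance products from the end-of-step gates — and the
predictor voltages for the soma–dendrite coupling — and redoes the
voltage update with averaged coefficients. The corrector runs only while
the membrane moves faster than 0.1 mV per step; subthreshold, the
predictor is already step-converged. Synaptic rise/decay and calcium
pools use exact exponential updates; calcium is clamped at zero and gate
values are convex combinations so they remain in [0, 1] by construction.
Membrane noise is an exact-discretization Ornstein–Uhlenbeck voltage term
(τ = 1 ms, stationary SD 1.5 mV) whose increments are added to every
compartment; the normals are pre-drawn with NumPy's PCG64 generator so
runs are bit-reproducible given the three seeds (connectome, drive,
noise). Initial conditions: V at the leak reversal, gates at their steady
state for that voltage, calcium pools empty.

Accuracy at the default step, measured against a dt/10 reference:
fast-spiking interneuron period within 0.5%, septal pacemaker within
~1.5%, two-compartment pyramid within ~2%; halving dt changes the
15-trial mean relative theta power of the control network by ~1.5%. All
group contrasts are computed at identical dt, so the residual bias is
common mode. Spike detection: upward crossings of 0 mV with a 2-ms
refractory merge.

Problem sizes in the shipped tests are those of the study protocol itself
(190 neurons, 10-s trials, 15 trials per group); single-cell checks use
1–4 s runs.

## Surrogates

The surrogate module generates the two signal families the analysis
consumes, with known ground truth: (i) spike trains from von-Mises-
modulated inhomogeneous Poisson processes (thinning), whose concentration
parameter maps monotonically from asynchronous to tightly phase-clustered
while the time-averaged rate stays calibrated; (ii) band-limited time
series built on a 0.5 Hz grid over (0, 40] Hz from equal-amplitude
random-phase components plus a theta tone whose amplitude is set
analytically so the expected relative theta power equals a requested
fraction (with no tone the share is the bandwidth ratio 3/40). These
surrogates exercise spectral estimation, coherence and the ANOVA pipeline
end-to-end (power > 0.9 for a large constructed effect at n = 15; type-I
error ≈ 5% under the null) without the biophysics. They deliberately do
not mimic conductance-model waveforms; passing surrogate tests validates
the analysis stages, not the network model.

## Known limitations

- Relative theta power is non-monotone across very deep A-block: below
  ~0.5× dendritic g_A (and for strong both-compartment block) the extra
  excitability begins to disperse the rhythm and theta share declines;
  the model makes the study's point in the 1.0–0.6 range.
- No family-wise error correction across condition ladders.
- Single dendritic compartment; no temperature dependence; no stochastic
  channel gating; no synaptic plasticity or cholinergic neuromodulation.
- The absolute scale of drives and conductances is model-specific; only
  relative, within-study contrasts are interpretable.
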