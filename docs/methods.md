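# Methods

`telofret` analyzes single-molecule FRET recordings of telomerase–DNA
complexes and quantifies telomerase primer-extension assays.  Because no
public raw traces exist for this assay, the package ships a synthetic-data
generator whose presets encode the published kinetic values; every analysis
stage is validated by recovering those values from its own simulations.

## The kinetic model

A surface-immobilized telomeric primer carries a donor dye (Cy3); telomerase
carries an acceptor (Cy5) in its RNA subunit.  A trajectory is modelled as:

- an **unbound** phase: donor-only emission; binding occurs with a fixed
  per-frame probability `k_on_frame` (geometric waiting time);
- a **bound** phase: the enzyme–DNA complex alternates between a *docked*
  conformation (RNA–DNA hybrid in the active site) and an *alternative*
  conformation (DNA 3′ end displaced), a continuous-time two-state process
  with rates `k_da` (docked → alternative) and `k_ad` (alternative →
  docked), so dwell times are exponential with means 1/k_da and 1/k_ad;
- **FRET termination** by the first of acceptor photobleaching or enzyme
  dissociation.  These are experimentally indistinguishable, so the
  simulator merges them into a single rate (`k_off +
  bleach_rate_acceptor`); after termination the trace returns to donor-only
  emission.  Donor photobleaching truncates the trace entirely.

Emission is rendered per camera frame (integration time 0.1 s in all
presets).  A frame containing a transition emits the occupancy-weighted
mixture of the states it straddles (motion blur), which is both physically
correct for CCD integration and a deliberate stress test for the
idealization stage.  Channel noise is Gaussian with variance `a + b·mean`
(read noise floor plus a shot-noise term); defaults `a = 800`, `b = 2` at a
total intensity of 1000 a.u. put the FRET-domain noise at σ ≈ 0.02–0.04,
typical of single-molecule TIRF data.

Detection bookkeeping: binding enhances the donor's apparent brightness, so
the summed detected intensity drops by the factor γ on binding.  The
simulator emits bound-phase totals `I0/γ` split as
`IA = E·I0 / (1 + E(γ−1))`, `ID = I0/γ − IA`, which makes the two standard
identities hold exactly: the per-trace estimator
`γ̂ = (ID+IA)_pre / (ID+IA)_bound` recovers γ, and the corrected efficiency
`E = IA/(IA + γ·ID)` recovers the state mean.  Default `γ_true = 1.2` (the
magnitude of protein-induced Cy3 enhancement is not published; 1.2 is a
plausible mid-range value and the estimator is validated against whatever
value the model carries).

### Presets

| preset | docked / alt FRET | 1/k_da | 1/k_ad |
|---|---|---|---|
| `wt-u36`   | 0.75 / 0.25 | 5.0 s | 0.8 s |
| `l14a-u36` | 0.75 / 0.25 | 0.5 s | 0.9 s |
| `wt-u63`   | 0.50 / 0.90 | 5.0 s | 0.8 s |
| `l14a-u63` | 0.50 / 0.90 | 0.5 s | 0.9 s |

U36/U63 are the two acceptor labelling positions; they report the same
conformations with inverted FRET contrast (for U63 the *docked* state is
the mid-FRET 0.5 state and the *alternative* state is the high-FRET 0.9
state).  Rates are reciprocals of the published mean dwell times.  Binding,
dissociation and bleaching rates (`k_on_frame = 0.01/frame`, `k_off = 0.01
s⁻¹`, acceptor bleach 0.01 s⁻¹, donor bleach 0.005 s⁻¹) are unpublished;
they were fixed once at values giving minutes-scale events and multi-dwell
binding windows, and all parameter-recovery checks run against these
conditions.  The simulator is strictly two-bound-state; the transient
mid-FRET heterogeneity seen in some mutant recordings is deliberately not
modelled.

## Trace processing

γ̂ is computed per trace from 10-frame windows on each side of the binding
onset, excluding the 2 frames adjacent to the transition (blur guard).
Traces with too little pre-binding baseline fall back to γ = 1 with a
warning; because such traces cannot actually be corrected, the pooled
pipeline excludes them from model fitting (keeping them biases the fitted
alternative-state mean upward by ~0.006 at default conditions).

Events are maximal runs of E ≥ 0.12 lasting ≥ 3 frames (0.12 is roughly
midway between the unbound mean 0.0 and the lowest bound mean 0.25, minus a
noise margin).  Efficiencies are clamped to [−0.2, 1.2]; frames outside
that range are excluded from histograms.  Histograms pool every in-event
frame across traces (bin width 0.05) and are density-normalized.

## HMM idealization

A 3-state Gaussian-emission hidden Markov model (unbound + two bound
conformations) is fit by Baum–Welch EM with scaled forward–backward
recursions, batched across traces.  Defaults: means initialized at the
published state positions (0/0.25/0.75 or 0/0.5/0.9), σ₀ = 0.1, 0.9
self-transition, tol = 1e-6 relative log-likelihood, ≤ 500 iterations.
The fit is pooled across the dataset with shared parameters — short traces
under-constrain per-trace fits — with a per-trace mode retained for
fidelity to the original trace-by-trace protocol.  Fitting uses full traces
including unbound stretches (the lowest state absorbs the baseline).

Numerical choices: emission densities floored at 1e-300; start/transition
probabilities floored at 1e-10 before renormalization so finite data cannot
zero out a state; states reported sorted by mean; Viterbi ties break toward
the lower state index.  If a state's emission σ falls below 1e-3 the σ is
clamped (the correct behaviour for genuinely noiseless segments); a strict
mode (`on_degenerate="restart"`) instead re-seeds up to 3 restarts and then
errors.  EM monotonicity and equivalence of the decoder with brute-force
path enumeration (traces ≤ 8 frames) are asserted in the test suite, and
the forward likelihood and Viterbi path are cross-checked against an
independent HMM library.

## Dwell-time kinetics

Within each event the idealized path is projected onto the two bound
states (isolated unbound-labelled frames merge into the neighbouring run,
so per-event dwell durations sum exactly to the event duration).  The first
and last dwell of each event are boundary-censored and excluded from fits
by default.  Pooled durations are histogrammed (default bin 0.2 s — two
frames; a bin comparable to τ itself would leave the fit only the tail,
which is the part most distorted by blur-merged dwells) and fit by
unweighted least squares to `A₀·exp(−x/τ) + y₀`, dropping the first bin
(dwells near the frame time are systematically missed).  Poisson-weighted
fitting was evaluated and rejected: it up-weights the sparse tail and
biases τ low by 15–20% on these data.  A truncation-corrected closed-form
estimate (mean minus minimum observed dwell) is reported as a cross-check;
fits require ≥ 100 dwells unless explicitly overridden.

## Register model and NAP quantification

The RNA template default is 5′-CAACCCCAA-3′ with a 3-nt 3′-terminal
alignment region, reconstructed as the unique 9-mer consistent with the
published basepair counts; pairing is strict Watson–Crick (no G·U wobble),
registers are 0-based from the template 5′ end, and the duplex spans the
contiguous complementary run anchored at the primer 3′ terminus.

Two register notions are deliberately distinct:

- `duplex_potential` — the maximal contiguous run over all registers (ties
  to the 5′-most register).  This reproduces the published binding-assay
  series: 5 bp for (TG)₈T₂G₃ through 9 bp for (TG)₈T₂G₄T₂G, 8 bp for
  (GGGGTT)₃.
- `annealing_register` — the initiation register for an extension
  reaction: the duplex must sit flush with the template 3′ end, engage the
  full alignment region, and leave at least one templating base.  Only
  this rule staggers the six telomeric-repeat permutants over 3–8 bp with
  (GGGGTT)₃ maximal; a pure maximal-run rule would assign (GGGTTG)₃ the
  9-bp register (its 3′-terminal 9 nt are identical to (TG)₈T₂G₄T₂G's),
  which contradicts the extension-assay design.

Template translocation requires the product 3′ end at the template 5′
boundary and realigns it onto the alignment region — a 3-bp duplex at
register 6 for the defaults.

Gel lanes are consumed as band tables (image processing is out of scope).
Quantification follows the printed recipe: each band's intensity is divided
by its labeled-dG count (the α-³²P-dGTP specific-activity correction; the
register walk supplies the count), NAP is the corrected sum over the first
repeat addition band and everything above it divided by the recovery
control, and per-enzyme values are reported relative to the
maximal-duplex-potential primer, which is exactly 1.  The generative gel
model (per-duplex-length extension probabilities, a translocation success
probability, binomial molecule cascades) is artifact plumbing: its
parameters were chosen to produce the qualitative published pattern
(wild-type NAP rising with duplex potential; the L14A mutant crippled on
short hybrids and unable to translocate) and only arithmetic identities —
count conservation, correction round trips, normalization — are asserted
quantitatively.

## What the simulations do and do not show

Passing recovery tests show the estimators are consistent with the model
they assume: exponential two-state exchange, Gaussian noise, a single
binding event per trace, ideal baselines.  Real recordings add baseline
drift, blinking, multi-step photobleaching, heterogeneous molecules and
overlapping events, none of which are emulated; performance there is not
claimed.  Two quantified, inherent biases at the default conditions:

- **Motion blur vs. emission means.**  Frames straddling a transition lie
  between the state means, so a Gaussian HMM's fitted means shift toward
  each other in proportion to the transition density.  For 0.5-s docked
  dwells at 100-ms frames (the L14A presets) ≈ 40% of docked frames are
  mixed and the fitted docked mean lands near 0.70–0.71 rather than 0.75 —
  even averaging frames by their true majority-occupancy labels gives
  0.727.  Wild-type fits (50-frame dwells) are essentially unbiased.
- **Termination selection vs. dwell times.**  With a competing
  FRET-termination rate k_term, fully observed dwells are Exp(k + k_term),
  so wild-type docked τ estimates center near 4.6–4.9 s rather than 5.0 s.
  Blur-merging of sub-frame excursions partially offsets this.  Both
  effects sit well inside the ±20% recovery bands, except the L14A docked
  emission mean noted above.

## Analysis scales

Default validation scales: 300 traces × 800 frames (U36 presets; ≈ 240
analyzable binding events, ≈ 1 000–4 500 dwells per state) and 160 × 800
for the U63 presets, where only emission means are consumed.  All
randomness flows from a single master seed through spawned child streams,
so identical seeds reproduce datasets bit for bit.
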