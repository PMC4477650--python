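# telofret

Single-molecule FRET kinetic analysis and extension-assay quantification
for telomerase–DNA complexes.

Telomerase copies a short RNA template into telomeric DNA.  In
single-molecule FRET binding assays, a DNA primer bound inside the enzyme
exchanges between a *docked* conformation (RNA–DNA hybrid in the active
site, poised for synthesis) and an *alternative* conformation (DNA 3′ end
displaced), and the stability of the docked state tracks how many basepairs
the primer can form with the template.  `telofret` implements the complete
computational workflow for this kind of experiment, for people analyzing
two-channel fluorescence trajectories or quantifying primer-extension gels:

- **trace processing** — per-frame FRET efficiency
  `E = I_A / (I_A + γ·I_D)` with the per-trace correction factor
  `γ̂ = (I_D + I_A)_before-binding / (I_D + I_A)_bound`, binding-event
  detection and pooled FRET histograms;
- **idealization** — a 3-state Gaussian-emission hidden Markov model
  (unbound + two bound conformations) fit by Baum–Welch EM, with Viterbi
  most-probable paths, exposed as a scikit-learn-style estimator
  (`GaussianHMM(...).fit(X, lengths).predict(X)`);
- **dwell kinetics** — boundary-censored dwell extraction and exponential
  histogram fits `y = A₀·e^(−x/τ) + y₀`, where τ is the mean dwell time of
  a conformation (`ExponentialDwellModel`);
- **duplex register model** — primer–template annealing registers,
  RNA–DNA duplex-forming potential and the post-translocation 3-bp
  realignment on the 9-nt template 5′-CAACCCCAA-3′;
- **gel quantification** — nucleotide addition processivity (NAP):
  band-wise specific-activity correction by labeled-dG count, recovery
  -control normalization, and per-enzyme NAP relative to the
  maximal-duplex primer (GGGGTT)₃;
- **synthetic data** — a seeded trajectory/gel simulator (photobleaching,
  donor enhancement, motion blur, exponential state dwells) whose bundled
  presets encode the published kinetics, so the whole pipeline is testable
  without experimental downloads.

## Worked example

Simulate a wild-type dataset at the published kinetics (docked/alternative
states at 0.75/0.25 FRET, mean dwell times 5 s and 0.8 s, 100 ms frames)
and run the full analysis:

```python
import telofret as tf
from telofret.pipeline import idealize_dataset, dwell_fits

model = tf.KINETIC_PRESETS["wt-u36"]
traces = tf.simulate_dataset(model, n_traces=300, n_frames=800, seed=1)
run = idealize_dataset(traces, scheme="u36")
fits = dwell_fits(run)
```

which prints (exactly, for this seed):

```
binding events analyzed : 236
fitted state means      : unbound=0.009, alternative=0.276, docked=0.750
tau_docked              : 4.66 s  (n=1095 dwells)
tau_alternative         : 0.74 s  (n=1201 dwells)
```

The HMM recovers the unbound baseline and both bound-state FRET means, and
the dwell fits recover the simulated mean dwell times (τ_docked is pulled a
few percent below 5 s because dwells competing with FRET termination are
slightly foreshortened; see `docs/methods.md` for the bias budget).  The
same pipeline on the `l14a-u36` preset — a TEN-domain mutant whose docked
dwell is ten-fold shorter — yields τ_docked ≈ 0.54 s against τ_alt ≈ 0.97 s,
reproducing the order-of-magnitude destabilization of the docked state with
the alternative state untouched.

The register model is available directly:

```python
>>> tf.duplex_potential(tf.PrimerSpec("p", "TG" * 8 + "TTGGG")).duplex_len
5
>>> [tf.annealing_register(p).duplex_len for p in tf.PERMUTANT_PRIMERS]
[6, 7, 8, 3, 4, 5]
```

A `telofret` command-line tool wraps the same stages
(`telofret simulate traces`, `fret`, `idealize`, `dwell`, `duplex`, `nap`);
every subcommand reads and writes plain CSV/JSON (traces also HDF5).

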