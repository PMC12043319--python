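# mwsumd

Engine-agnostic **multiple-walker supervised molecular dynamics (mwSuMD)** —
adaptive sampling of rare events (ligand binding and unbinding, domain
motions, coupling transitions) by *supervision* instead of biasing forces,
with a built-in Langevin propagator and analytic toy landscapes so the whole
algorithm runs and is testable on a laptop.

## The method

Classical MD rarely crosses the free-energy barriers that separate, say, a
solvated peptide from its receptor-bound pose. Supervised MD attacks this
without modifying the Hamiltonian: the simulation is cut into short unbiased
time windows, a scalar metric of progress is monitored over each window, and
only windows that progress are kept.

In the **multiple-walker** variant, each supervision cycle seeds a *batch*
of `n` walkers from a single parent state. All walkers share the parent's
exact coordinates *and* velocities and differ only in their stochastic
thermostat streams. After the window of duration `Δt` has elapsed, one
walker is selected and extended; one walker per batch is *always*
productive, and the winner's velocities are never reassigned, so the
accepted pathway is a continuous, unbiased trajectory.

Three acceptance rules decide the winner, given the supervised metric X
sampled over the window:

- **slope** — ordinary least-squares slope of X vs time; the most negative
  slope wins when X should decrease (binding), the most positive when it
  should increase (unbinding).
- **SMscore** (one metric) —

      SMscore = √( X_lastframe · X̄ )

  where `X_lastframe` is the value in the window's final frame and `X̄` the
  window average. Lowest wins for a decreasing metric, highest for an
  increasing one.
- **DMscore** (two metrics X′, X″) —

      DMscore = [ (X′_lastframe / X̄′_batch − 1) + (X″_lastframe / X̄″_batch − 1) ] · 100

  with the batch averages taken over *all* walkers of the current batch; an
  addend whose metric is set to decrease is multiplied by −1 so positive
  always means progress, and the highest score wins. When a last-frame value
  equals its batch mean, that addend is null and the other metric decides.

The single-walker ancestor (SuMD) is included for comparison: one window at
a time, slope acceptance, and a tabu-like rejection move — revert the
coordinates to the window start and redraw Maxwell–Boltzmann velocities.

Supported metrics: centroid distance between two atom selections, RMSD to a
reference after Kabsch superposition (with independent *fit* and *measure*
selections), and atomic contact counts. Multi-stage protocols chain stages
with exact state continuity, each with its own metrics, acceptance rule,
window length, walker count and termination rule (metric threshold,
productive-time limit, or batch count).

## Worked example

Run the bundled double-well demo — one coarse bead that must cross a
6 k_BT barrier to reach a target 10 Å away, supervised by the
centroid distance with the SMscore rule (10 walkers × 2 ps windows):

```bash
$ mwsumd demo run double-well-smscore -O run1
stage cross_barrier: threshold after 11 batches
```

The supervised walker crossed the barrier after 11 supervision cycles, i.e.
22 ps of productive time and 220 ps of total propagated time — an
unsupervised simulation of this system typically needs thousands of
picoseconds (see the benchmark below). `run1/` now contains:

- `protocol_log.jsonl` — one JSON line per batch with every walker's seed,
  score and final metric value, plus the chosen walker; together with the
  master seed this replays the run bit-for-bit,
- `merged_trajectory.xyz` — the concatenated winning windows,
- `batches.csv`, `manifest.json` — tabulated scores and run outcomes.

The same protocol can be written as YAML and run with `mwsumd run`; see
`mwsumd demo list` for the other recipes (single-walker SuMD with tabu
restarts, two-metric DMscore docking on the binding-funnel toy, and an
unbinding protocol with a 40 Å stop rule). `mwsumd benchmark` compares
protocols at matched total propagated time, and `mwsumd analyze` computes
contact/hydrogen-bond persistency tables over merged replicas (H-bond
criterion: donor–acceptor distance ≤ 3.3 Å and D–H···A angle ≥ 120°).

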