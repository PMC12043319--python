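# Methods

This note records the model choices behind the package: what the supervisor
implements, what the toy propagator and landscapes emulate, the numerical
conventions, and the decisions taken where the design was genuinely open.

## Supervision model

A *protocol* is an ordered list of *stages*. A stage owns one or two metric
specifications, an acceptance rule, a window duration (ps), a walker count,
and a termination rule. Within a stage the supervisor loops:

1. seed `n_walkers` windows from the current state — identical coordinates
   and velocities, per-walker stochastic seeds;
2. propagate each walker for exactly `window_ps`;
3. evaluate each supervised metric over the window (every emitted frame by
   default, always including the final frame);
4. score the walkers (slope, SMscore or DMscore) and select exactly one
   winner; ties break to the lowest walker index;
5. continue from the winner's final state — bit-identical, with **no
   velocity reassignment** — until the termination rule fires.

Exactly one walker per batch is productive, so productive time advances by
`window_ps` per batch and total propagated cost by
`n_walkers × window_ps`. Both are logged per batch; the log plus the master
seed replays a run bit-for-bit with the built-in propagator.

Design points that were open and the choices made:

- **DMscore batch means.** The batch average X̄_batch can be read as the
  pooled mean of all sampled values across walkers, the mean of per-walker
  window means, or the mean of last-frame values. We pool all sampled
  values; with equal samples per walker this equals the mean of per-walker
  window means. The pooled values are what the per-batch log records, so
  the choice is auditable.
- **DMscore winner.** The sign convention (decrease-direction addends
  multiplied by −1) makes positive mean progress, so the highest score
  wins.
- **Window mean.** X̄ includes the final sample.
- **Slope acceptance in multi-walker mode** never restarts: the best slope
  wins even if all slopes are unfavorable, consistent with one walker per
  batch always being productive. Continue/restart slope semantics exist
  only in single-walker mode.
- **Single-walker (SuMD) restart target.** A rejected window reverts the
  coordinates to the window *start* and redraws Maxwell–Boltzmann
  velocities with a fresh seed. Slope favorability is strict
  (slope exactly 0 is unfavorable), so frozen dynamics restart forever
  until the consecutive-failure cap — a deliberate property, covered by a
  test.
- **Seeds.** Per-walker seeds are a 64-bit BLAKE2 hash of (master seed,
  stage label, batch index, walker index); inserting or reordering stages
  does not shift other stages' streams.
- **Budget exhaustion** (the `max_batches` safety cap) is an outcome
  recorded in the log, not an exception: supervision legitimately fails to
  reach a target.
- **Threshold comparators** are explicit in config ("reached 40 Å" → `>=`,
  "less than 4 Å" → `<`), avoiding any hidden convention.

## Metrics

- *Centroid distance*: Euclidean distance between geometric centers of two
  selections; mass weighting is an opt-in flag (both conventions are used
  in practice).
- *RMSD to reference*: the Kabsch transform is computed on the
  `fit_selection` only and then applied to the `measure_selection`, which
  may differ (fit on a rigid receptor core, measure on a ligand or a mobile
  helix). The rotation is forced proper (det +1) by flipping the smallest
  singular direction; collinear fit atoms are a hard error rather than an
  arbitrary rotation.
- *Contact count*: unordered atom pairs across two selections within a
  cutoff, `≤` inclusive, self-pairs excluded, each pair counted once.
- Sampling grid: every emitted frame of the window by default. The
  appropriate intra-window sampling interval is system-dependent;
  `sample_interval` overrides it, and the final frame is always included
  because the scores depend on it.

## Toy propagator

BAOAB Langevin splitting over analytic potentials, chosen for its
configurational accuracy at moderate timesteps; at zero friction it reduces
to velocity Verlet and conserves energy (checked to 1e-4 relative over one
oscillator period at dt = period/1000). Units are Å, ps, amu, K with
energies in kcal/mol (1 kcal/mol = 418.4 amu·Å²/ps²). Atoms listed as
`frozen` by a potential (marker particles) receive zero force and pinned
zero velocity. Propagation is bitwise deterministic per seed — the property
the replay guarantee rests on.

The external-engine adapter contract (write state → invoke engine → read
trajectory + final state) is exercised by a mock engine that routes the
built-in integrator through explicit PDB/velocity-table/XYZ files. It
demonstrates engine-agnosticism; no real MD engine is invoked, and a
production adapter would additionally carry topology/force-field files.

## Toy systems and what they do (not) show

All systems are generated programmatically; barriers are stated in k_BT and
converted at the construction temperature (default 300 K), so tests are
thermostat-independent.

- **Double well**: one bead (100 amu) in `E = B((x/a)²−1)²`, barrier
  B = 6 k_BT, minima ±5 Å, lateral harmonic confinement, friction 5 ps⁻¹,
  dt = 0.02 ps. The 100 amu mass and 5 ps⁻¹ friction were chosen so the
  unsupervised mean first-passage time (several nanoseconds, Kramers
  estimate confirmed by simulation) vastly exceeds the 2 ps supervision
  window — the regime the method is designed for. A frozen marker at the
  target minimum turns "distance to target" into an ordinary centroid
  distance. An optional linear `tilt` term biases one basin for
  equilibrium-occupancy checks.
- **Müller–Brown**: the canonical three-minimum surface with the standard
  literature constants, scaled so its corrugation is a few k_BT; used for
  minimum-finding and gradient checks.
- **Binding funnel**: a mobile ligand bead approaching a ring of
  harmonically restrained receptor beads; short-range Gaussian site
  attraction (8 k_BT), a weak long-range funnel bias, lateral confinement
  and repulsive cores. Binding protocols supervise the ligand–site centroid
  distance downward; the unbinding variant starts bound, supervises it
  upward and stops at 40 Å.

The benchmark harness compares protocols at **matched total propagated
time** (walkers × window × batches), the fair analogue of wall-clock cost
for a method whose batches run in parallel but still consume compute.

These landscapes have the *structure* the algorithm assumes — a supervised
scalar with funneled or barrier-separated topography — but none of the
ruggedness, anisotropic friction, or metric degeneracy of solvated
biomolecules. Passing benchmarks here shows the selection machinery
accelerates barrier crossings under its stated assumptions; it does not
predict speedups for any particular molecular system.

## Analysis conventions

- Hydrogen bond: donor–acceptor distance ≤ 3.3 Å AND D–H···A angle
  (measured at H) ≥ 120°, both boundaries inclusive. Donor hydrogens are
  supplied explicitly; no bond perception.
- Contacts: heavy atoms only by default, cutoff 4.0 Å (configurable and
  echoed in every report's metadata sidecar); a residue pair is in contact
  in a frame iff at least one atom pair is within the cutoff.
- Persistency: percentage of frames carrying the interaction over the
  merged frames of all replicas — invariant to replica order.
- Second-half summaries: mean ± *population* SD over frames with index
  ≥ ⌈n/2⌉ (the later frame is kept when n is odd).

## Numerical checks and problem sizes

The acceptance script and test suite size their simulations for a single
CPU: 20 paired replicates for the double-well benchmark at a 2000 ps
propagated-time budget per replicate; 20 replicates at 3000 ps for the
funnel unbinding comparison; six pooled 6 ns runs (light 25 amu bead,
friction 2 ps⁻¹, 1.5 k_BT barrier with a 1 k_BT tilt) for the
basin-occupancy check, where the crossing statistics — not the integrator —
limit the accuracy; 2 ns for thermostat recovery. The occupancy reference
is the exact 1-D partition-function ratio computed by quadrature. Kabsch
superposition is validated against a brute-force quaternion-grid rotation
search (150k coarse samples plus three local refinement passes), and the
OLS slope against a dense grid search with the intercept profiled out.

## Known limitations

- The PDB dialect is deliberately narrow: ATOM/HETATM/TER/END, altloc
  blank/'A' only (others skipped with a warning), no insertion codes.
- No periodic boundaries, constraints, barostats or real force fields; the
  propagator is a desk-scale stand-in whose job is to realize the
  propagation contract exactly.
- Contact detection is O(pairs) per frame — fine for toy systems and small
  proteins, not for large membranes.
- The mock engine proves the adapter file contract, not process management
  (queues, retries, GPUs) for production engines.
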