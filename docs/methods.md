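# Methods

This note documents the model, the conventions the implementation fixes where
the method leaves a choice open, the numerical machinery, what the synthetic
generators do and do not emulate, and the known limitations.

## Pipeline overview

Trajectories (per-individual 2-D positions in mm on a common frame grid) are
resampled to the analysis step Δt, converted to unit headings by backward
finite differences, binarized per individual into ON/OFF interaction states,
and summarised by a state-by-node transition probability matrix (TPM). All
integrated-information quantities are computed from that TPM, per collective
state.

### Binarization

An individual is ON at a step iff all three hold (conjunction):

- **distance**: some other individual is strictly within ζ (strict `<`);
- **visual field**: some other individual lies strictly within η of the focal
  heading, where η = VF/2 and the compared vector points *from the focal
  individual to the neighbour*. This convention makes VF < 2π a rear blind
  spot and VF = 2π identically ON, which is what the heat-map axis requires.
  The alternative orientation (vector negated, putting the blind spot in
  front) is available as `visual_vector="as_printed"` but is not the default,
  because only the to-neighbour form reproduces the "blind spot behind the
  animal" geometry.
- **turning rate**: the angle between consecutive headings is ≥ δ
  (non-strict). δ is a per-step threshold; thresholds quoted in rad/s are
  converted by multiplying with Δt (`BinarizationParams.from_rate`).

Headings are backward differences; a zero-displacement step carries the
previous heading forward (counted and logged), steps before an individual's
first displacement are flagged undefined and force the visual and turning
functions OFF. The first step of a series is dropped because the turning rate
needs two consecutive headings.

Boundary comparisons get an absolute slack of 1e-12 rad: `arccos` round-off
can place an exactly-at-threshold turn one ulp below δ.

### TPM estimation

Entry (s, i) of the state-by-node TPM is the fraction of observed transitions
out of collective state s in which node i was ON next. States never visited
are filled with the maximum-entropy value 0.5 — Φ needs a fully specified TPM
and 0.5 is the same "no constraint" convention the unconstrained repertoires
use; optional Laplace smoothing is available instead. Visit counts are kept as
`occupancy` so that time-weighted aggregates remain possible. Nodes are
conditionally independent given the past state; the state-by-state matrix is
the row-wise product of per-node marginals. State codes are little-endian
(node 1 = least significant bit) everywhere, including file formats.

## Integrated information (IIT 3.0)

### Repertoires

The **effect repertoire** of mechanism M over purview Z conditions each
purview node's transition probability on M clamped to its current state,
marginalising all other inputs uniformly, and takes the product over purview
nodes (virtual-element construction — effect repertoires factorise by
definition). The **cause repertoire** inverts each mechanism node's likelihood
with a uniform prior over past purview states, marginalising non-purview past
nodes uniformly, multiplies the per-node likelihood vectors and renormalises.
A mechanism state with zero probability under every past purview state has an
undefined cause repertoire; its φ_cause is 0 (signalled, not raised).

### Mechanism-level φ

Partitions of a mechanism/purview pair are unordered two-part splits
((M1, Z1), (M2, Z2)) with M1/M2 partitioning the mechanism and Z1/Z2 the
purview; a part may have an empty mechanism (unconstrained over its purview
part) or an empty purview, but not both. φ of a purview is the Hamming-ground
EMD between the intact repertoire and the best (least different) partitioned
repertoire; φ^max maximises over purviews, and a concept requires both
φ^max_cause > 0 and φ^max_effect > 0, with concept φ their minimum.

Purview ties keep the first maximum in ascending purview-bitmask order
(smallest purview, lowest node indices). This is recorded so leadership
matching is deterministic; on generic (continuous-valued) TPMs ties have
measure zero.

### System-level Φ

A system cut severs the directed inputs from one part into the other,
replacing them with independent maximum-entropy noise (uniform
marginalisation over the severed past bits). Φ at a state is the minimum,
over cuts, of the extended EMD between the intact cause–effect structure and
the cut structure. The cut search is either exhaustive (all 2(2^(N−1)−1)
directed bipartitions) or the default **cut-one** approximation (the 2N cuts
isolating a single node in either direction); cut-one Φ ≥ exhaustive Φ always,
since the minimum runs over a subset. Cuts are searched in a deterministic
order (smaller from-part first, then lexicographic); ties keep the earliest
cut.

The **extended EMD** transports each intact concept's φ mass onto the cut
structure's concepts or onto the *null concept* (uniform cause, unconstrained
effect marginals); the deficit side is padded at the null concept. The ground
cost between two concepts is the cause-repertoire EMD plus the
effect-repertoire EMD over the full subsystem state space. The null concept is
taken from the intact subsystem, fixing the intact→cut orientation of the
distance (the unconstrained effect marginals are in fact invariant under
cuts, since cutting only replaces averages by averages).

States with zero probability under every predecessor are unreachable: their
cause side is undefined, Φ is reported as 0 and flagged.

### Subsystems and the major complex

Φ over a proper subsystem reduces the TPM by uniform marginalisation over
external past nodes (the same maximum-entropy convention as everywhere else;
the alternative — freezing external nodes at their current state — would make
the reduced TPM state-dependent and is not implemented). The major complex
enumerates all subsets of size ≥ 2 (singletons score 0) and returns the
Φ-maximising subsystem, practical for N ≤ 8.

### ⟨Φ⟩ weighting

"Mean Φ" can weight the 2^N collective states equally (`by_state`, the
heat-map default) or by observed occupancy (`by_time`). Both are computed from
the same per-state table; the choice is recorded in the output. σ(Φ), max and
min follow the same weighting.

## Numerical machinery

- **EMD** is solved exactly as a dense transportation problem by successive
  shortest augmenting paths with Johnson potentials (Dijkstra on the residual
  bipartite graph). Supports are tiny (≤ 2^N points a side, ≤ 63 in concept
  space), so dense scans dominate and each solve is microseconds. The solver
  is validated against an explicit `scipy.optimize.linprog` transport LP.
- Two exact reductions keep the Φ computation fast without approximating
  anything: (i) effect repertoires are products, and the Hamming-ground EMD
  between product distributions equals the sum of per-node marginal
  differences (the product coupling attains the per-coordinate lower bound);
  (ii) expanded cause repertoires are `rep ⊗ uniform`, and a shared uniform
  factor transports at zero cost, so concept-to-concept cause distances reduce
  to the union of the two purviews.
- Partition minima use the bound EMD ≥ ½‖p−q‖₁ (the minimum ground distance
  is 1): partitioned repertoires are collected with their L1 gaps and
  transported in ascending-L1 order, stopping once the bound exceeds the
  running minimum. This prunes most transport solves and is exact.
- φ values ≤ 1e-10 are treated as zero (reducible); identical concepts in the
  two structures cancel before the concept-space transport (zero ground cost
  is optimal because the ground distance is a metric).
- Kernels are numba-jitted (`cache=True`); cold-start compilation is a few
  seconds per process.

The implementation is cross-checked, repertoire-by-repertoire and Φ-by-Φ,
against an independent brute-force enumeration (`tests/oracles.py`) that
shares no code with the package and solves every EMD as an explicit LP.

## Synthetic data

### Boids schools

The zone model updates all agents synchronously: repulsion away from
neighbours within R, alignment with the headings of agents within O (self
included, providing heading persistence), attraction toward neighbours in the
O..A shell; each rule is scaled by the coupling C, the three vectors are
summed and averaged, the heading is rotated by Gaussian noise, and the
position advances by v along the new heading, with reflective walls in a
3000 × 2500 mm arena (periodic available for sensitivity checks). A zero rule
sum (e.g. C = 0) keeps the previous heading, so C = 0 with zero noise gives
straight lines until a wall.

Defaults per group size: R = 10 mm (body length), O = 120 mm (typical
neighbour distance), A = ∞, Δt = 0.05 s, per-step displacement v of
8.47–12.4 mm and heading-noise SD of 0.17–0.23 rad. v is a *per-step*
displacement: 8.47–12.4 mm per 0.05 s reproduces the observed average speeds
of 170–250 mm/s, whereas reading those numbers as mm/s would give essentially
stationary animals. Agents start at random positions within O of the arena
centre.

With these defaults the simulated school is cohesive (mean neighbour distance
≈ 55 mm once settled — tighter than the 80–140 mm spacing of the real schools
the radii were matched to; the zone model equilibrates near its repulsion
radius and reproduces the spacing only qualitatively). What the simulator does
*not* emulate: speed variation, individual differences, wall-following
behaviour, tracking noise, or any designated leader. Passing tests on Boids
data therefore demonstrates the machinery and qualitative size/coupling
effects, not fish-specific structure.

### Random Markov chains

The size-effect baseline draws every conditional ON-probability of a
state-by-node TPM independently from Uniform(0, 1) (the natural maximal-
ignorance choice; the baseline values depend on this distribution). Per chain,
Φ is computed at all 2^N states with cut-one; σ(Φ(N)) is the SD across states,
averaged over chains. At N = 2/3/4 with 100 chains this reproduces the
published baseline (≈ 0.04/0.09/0.19) within the published spreads. N = 5 is
supported by the same code path but costs ≈ 2 min per chain, so the shipped
baselines stop at N = 4 (problem sizes used: 100 chains for N ≤ 4 in the
acceptance script; 100/100/40 chains in the test suite).

### Fixtures

`make_fixture` provides deterministic objects with verified ground truths:
`copy_pair` (mutual copy; single-node concepts, Φ = 1 at the all-ON state,
major complex {1,2} — note the joint mechanism of a pure copy system
factorizes exactly and specifies *no* concept), `independent_pair`
(factorized, Φ = 0 everywhere), `and_gate_triple` (feedforward, Φ = 0),
`leader_chain` (single-file trajectory, agent 1 always the positional
leader), and `leader_school` — a 5-node TPM estimated from a seeded Boids
school binarized at ζ = 700 mm, VF = 1.6π, the parameter point of the worked
leadership example. Its verified pattern: Φ(11111) exceeds Φ at every
single-OFF state, and the MIP at each single-OFF state isolates the OFF
individual. It is a synthetic stand-in constructed by the package's own
pipeline, not an empirical TPM.

## Sweeps and comparisons

Heat maps run the full pipeline per (ζ, VF) cell at fixed δ (default grid:
ζ ∈ {100..1000} mm step 100; VF ∈ {1.0π..2.0π} step 0.2π plus 1.9π). Cells
with identical binarized series are computed once; failing cells become NaN
with the error recorded in the metadata. The "matrix distance" between heat
maps is the Frobenius norm of the difference divided by √(cell count), so a
uniform offset c gives |c| (mean absolute difference available via `kind`);
since the norm is a convention, only relative comparisons between groups
should be interpreted. The baseline-adjusted distance subtracts the pooled
mean intra-group distance from the mean inter-group distance and can be
negative. Group tests (Welch t, Wilcoxon signed-rank, Mann–Whitney U) are
scipy's, two-sided, with no multiple-testing correction.

## Information measures

MI and summed TE are plug-in (maximum-likelihood) estimates in bits, history
length 1, 0·log 0 := 0, no bias correction. TE's occasional ×100 scaling in
displays is presentation only and never applied to returned values.

## Limitations

- Cost grows as ~16^N per state (mechanisms × purviews × partitions); N ≤ 5
  is comfortable, N ≤ 8 the practical ceiling for the major complex.
- The cut-one Φ is an upper bound on the exhaustive Φ; for N ≤ 4 both are
  available and tested against each other.
- Plug-in MI/TE are biased upward on short series; the TPM's 0.5 fill for
  unvisited states injects maximal uncertainty into rarely-visited regions of
  state space, which matters when occupancy is highly concentrated.
- Only first-order (one-step) Markov structure is modelled; longer histories
  and continuous-valued interaction strengths are out of scope.
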