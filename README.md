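# flockphi

Integrated-information analysis of collective motion in small animal groups.

Small fish schools (and other animal collectives of 2–5 individuals) are more
than the sum of their pairwise interactions, but standard information-theoretic
measures — mutual information between successive group states, summed pairwise
transfer entropy — only describe what the group *does*. `flockphi` implements
the complementary "what the group *is*" analysis: it binarizes multi-agent
trajectories into collective ON/OFF interaction states, estimates the Markov
transition structure, and computes **integrated information Φ (IIT 3.0)** with
a minimum-information-partition (MIP) search. The MIP additionally yields a
notion of *leadership*: when exactly one individual is OFF and the system MIP
isolates that individual, the group's causal structure singles it out — and the
cut direction distinguishes passive from active leadership.

The package is aimed at researchers in collective behaviour and systems
biology who have (or simulate) 2-D trajectory data for small groups and want
per-state Φ values, heat maps over interaction-parameter grids, and leadership
diagnostics — without a reference to any external Φ solver.

## The quantities

For a group of N individuals, each individual's state at time t is

&nbsp;&nbsp;s_i(t) = D_i(t) ∧ B_i(t) ∧ T_i(t),

the conjunction of a **distance** function (ON iff some neighbour is strictly
within ζ mm), a **visual-field** function (ON iff some neighbour lies strictly
within η = VF/2 of the heading — VF < 2π is a rear blind spot), and a
**turning-rate** function (ON iff the heading change is ≥ δ). The collective
state X(t) ∈ {0,1}^N follows a Markov process summarised by a state-by-node
TPM: P(x_i(t) = 1 | X(t−Δt) = s).

From the TPM, for every collective state:

- **cause/effect repertoires** — distributions over a purview's past/future
  states obtained by clamping a mechanism (node subset) to its current state
  and marginalising everything else with the maximum-entropy distribution;
- **φ (small phi)** — the earth mover's distance (Hamming ground metric)
  between a repertoire and its minimum-information partition, maximised over
  purviews; mechanisms irreducible on both sides specify *concepts*;
- **Φ (big phi)** — the extended EMD between the intact cause–effect structure
  C(S) and the structure after the least-destructive unidirectional cut:
  Φ = min over cuts of D(C(S), C(S_cut)). The search uses either all directed
  bipartitions or the 2N single-node "cut one" approximation (default);
- **comparison measures** — MI = H(X(t)) − H(X(t)|X(t−Δt)) and the sum of
  pairwise transfer entropies, both plug-in estimates in bits;
- **leadership** — the matching rate between the single-OFF individual and the
  positional leader (furthest along the mean heading), and the rate at which
  the MIP isolates the OFF individual.

## Worked example

Simulate a school of three, binarize with a 400 mm interaction radius and a
1.6π visual field, and compute everything:

```python
import math
from flockphi import BinarizationParams, binarize, estimate_tpm, phi_over_series
from flockphi.info import mutual_information, transfer_entropy_sum
from flockphi.synth import BoidsParams, simulate_boids

traj = simulate_boids(BoidsParams(n=3, seed=42), steps=20000)
params = BinarizationParams(zeta=400.0, visual_field=1.6 * math.pi, delta=0.0, dt=0.05)
series = binarize(traj, params)
summary = phi_over_series(estimate_tpm(series), series=series)

print(f"<Phi> = {summary.mean:.3f}  sigma(Phi) = {summary.sd:.3f}  max = {summary.max:.3f}")
for state, value in sorted(summary.per_state.items()):
    print(f"  Phi{state} = {value:.3f}   MIP: {summary.mips[state]}")
print(f"MI = {mutual_information(series):.3f} bits  sum TE = {transfer_entropy_sum(series):.3f} bits")
```

prints

```
<Phi> = 0.150  sigma(Phi) = 0.054  max = 0.243
  Phi(0, 0, 0) = 0.129   MIP: {1,2} -/-> {3}
  Phi(0, 0, 1) = 0.065   MIP: {1,3} -/-> {2}
  Phi(0, 1, 0) = 0.114   MIP: {1,2} -/-> {3}
  Phi(0, 1, 1) = 0.179   MIP: {1} -/-> {2,3}
  Phi(1, 0, 0) = 0.103   MIP: {2,3} -/-> {1}
  Phi(1, 0, 1) = 0.189   MIP: {2} -/-> {1,3}
  Phi(1, 1, 0) = 0.183   MIP: {3} -/-> {1,2}
  Phi(1, 1, 1) = 0.243   MIP: {2} -/-> {1,3}
MI = 0.578 bits  sum TE = 0.011 bits
```

The all-ON state is the most integrated; at every single-OFF state the MIP
isolates exactly the OFF individual, the signature used for leadership
detection. Each Φ value is per collective state; `⟨Φ⟩` averages the 2^N states
(occupancy weighting is available via `weighting="by_time"`).

The same pipeline is scriptable from the shell:

```bash
flockphi simulate --n 4 --steps 20000 --seed 1 --out runs/sim
flockphi sweep --input runs/sim/trajectory.csv --measure phi --out runs/sweep
flockphi leadership --input runs/sim/trajectory.csv --distance 700 \
    --visual-field 1.6 --out runs/lead
flockphi markov-baseline --n 3 --reps 100 --seed 1 --out runs/mb
```

## Layout

- `flockphi.trajectory` — trajectory IO, resampling, headings
- `flockphi.binarize` — ON/OFF state functions and their conjunction
- `flockphi.tpm` — state-by-node TPM estimation, expansion, IO, connectivity
- `flockphi.phi` — repertoires, concepts, cause–effect structures, Φ, MIP,
  major complex (numba kernels in `flockphi._kernels`)
- `flockphi.info` — mutual information and summed transfer entropy
- `flockphi.leadership` — single-OFF/positional/MIP leadership diagnostics
- `flockphi.sweeps` — parameter-grid heat maps, matrix distances, group tests
- `flockphi.synth` — Boids simulator, random Markov chains, fixtures
- `flockphi.cli` — the `flockphi` command

See `docs/methods.md` for the modelling conventions, numerical choices and
their rationale.
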