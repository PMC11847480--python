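# complexdyn

Trajectory analysis for multi-chain cytokine–receptor complexes — the kind of
1 : 1 : 1 signaling assembly a four-helix-bundle ligand (LIF-like) forms with
two receptor chains (gp130-like and LIFR-like), each contributing two
membrane-proximal domains to the binding core.  The package re-implements, as
a tested and reusable pipeline, the standard battery of analyses used to
characterize how such a ligand engages its two receptors:

- **Fluctuations** — per-residue RMSF about the trajectory-average structure
  after Kabsch superposition, and the crystallographic conversion
  *B = (8π²/3)·RMSF²*.
- **Buried surface area** — Shrake–Rupley SASA (deterministic golden-spiral
  quadrature) and the complexation bookkeeping
  *BSA = SASA(A) + SASA(B) − SASA(A∪B)*, per snapshot, with a per-residue
  decomposition and the ≥ 38 Å² interface-contact rule.
- **Interaction occupancy** — hydrogen-bond (3.5 Å / 30°) and
  hydrophobic-contact occupancies for monitored atom pairs.
- **Dynamic cross-correlation** —
  *C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)* over Cα displacements.
- **Conformational states** — four descriptors per frame (two
  ligand–receptor angles, two cross-receptor domain distances), Gaussian
  mixture clustering by EM with BIC/AIC model selection, PCA, and
  representative-frame extraction.
- **Free-energy landscapes** — Boltzmann inversion
  *ΔG = −kT·ln(p/p_max)* of the 2-D angle histogram at T = 310 K.

Because production MD trajectories are rarely shareable, the package ships a
first-class **synthetic-complex generator**: a three-chain Cα-trace toy
complex whose trajectories have *designed* ground truth — metastable
inter-domain geometries visited by a sticky Markov chain, a residue–residue
displacement correlation structure, and donor–acceptor pairs toggling with a
designed occupancy.  Every analysis stage can therefore be validated against
known truth, end to end, in seconds.

## Worked example

```python
from complexdyn import build_toy_complex, preset, simulate_trajectory
from complexdyn import (extract_features, select_k, free_energy_landscape,
                        hbond_occupancy)

spec = preset("three-state", seed=11, n_frames=5000)
toy = build_toy_complex(spec)
traj, truth = simulate_trajectory(toy)

feats = extract_features(
    traj, toy.domains["L"],
    (toy.domains["G1"], toy.domains["G2"]),
    (toy.domains["R1"], toy.domains["R2"]),
)
ks = select_k(feats, range(1, 7), seed=0, n_restarts=3)
grid = free_energy_landscape(
    feats.df["angle_a_deg"].to_numpy(), feats.df["angle_b_deg"].to_numpy()
)
hb = hbond_occupancy(traj, "chain L and resid 24 and name NZ",
                     "chain R and resid 120 and name OE1")
print(f"chosen K          : {ks.chosen_k}")
print(f"landscape minimum : {grid.min_center[0]:.1f} deg, "
      f"{grid.min_center[1]:.1f} deg")
print(f"H-bond occupancy  : {hb.occupancy:.1%}")
```

prints

```
chosen K          : 3
landscape minimum : 60.0 deg, 57.0 deg
H-bond occupancy  : 39.5%
```

The generator's default three-state design places its dominant state at a
60° ligand–receptor-A angle and a 57° ligand–receptor-B angle with three
metastable geometries and a 40 % hydrogen-bond occupancy; the pipeline
recovers the state count by BIC, the stable geometry as the free-energy
minimum, and the designed occupancy from the distance series — which is
exactly what the printed numbers show.

## Command line

```sh
complexdyn synth --preset three-state --seed 7 --frames 1000
complexdyn run --config run.yaml --seed 7 --out results/
complexdyn bsa --traj traj.pdb --group-a "chain A" --group-b "chain B" \
    --probe 1.4 --points 960 --interval 1
complexdyn monitor --traj traj.pdb --atom-1 "chain A and resid 181 and name NZ" \
    --atom-2 "chain B and resid 313 and name OD1" --kind hbond
```

A YAML config drives full runs (`complexdyn run`): input paths or a
synthetic preset, domain definitions (label, chain, inclusive residue
ranges), monitors, and analysis parameters (probe radius, quadrature points,
contact threshold, K range, bins, temperature, frame spacing).  Unknown keys
are rejected before any computation; every output CSV embeds the package
version, seed and config hash.

To analyze a deposited complex structure (e.g. a downloaded cryo-EM model of
the ligand–receptor core), point `complexdyn bsa` at the PDB file with the
two chain selections; both the total-ΔSASA and per-side interface-area
conventions are reported so values can be compared against published
numbers under either convention.

### Selection mini-language

`chain A and resid 70:82 and name CA` — predicates `chain`, `resid`
(number, comma list, or inclusive `start:end` range), `name`, `element`,
combined with `and`/`or` and parentheses (`and` binds tighter).

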