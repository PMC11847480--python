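# Methods

This note documents the models and numerical choices behind each pipeline
stage, what the synthetic generator does and does not emulate, and the known
limitations.

## Structures, trajectories and selections

Structures are fixed-width PDB (wwPDB v3.3 columns); trajectories are
multi-model PDB files over one topology with frame times defaulting to
`index × dt` (dt = 1 ns, the snapshot spacing used throughout the analyses).
Author residue numbering is preserved verbatim and insertion codes are
rejected rather than merged, so a residue reference like "K181" is always
unambiguous.  Alternate locations keep the highest-occupancy copy (ties
resolve to altloc A).  Hydrogens are kept if present and never added.
Binary trajectory formats and mmCIF are out of scope: plain-text fixtures
are diffable, and the analyses are format-agnostic once coordinates are in
memory.

## Superposition, RMSF and B-factors

Kabsch superposition solves the least-squares rigid transform by SVD with
the reflection branch corrected (det = +1); fits with fewer than three or
collinear atoms are rejected.  RMSF uses the trajectory-average structure as
reference: frames are first fitted to frame 0, the average is computed once,
and the frames are refitted to that average — the standard two-pass scheme,
which is exact for the stationary fluctuations the generator produces.
RMSF is reported per residue from its Cα atom (matching residue-wise
fluctuation plots; side-chain atoms would silently inflate values).  The
B-factor conversion is B = (8π²/3)·RMSF², and a PDB with B in the
temperature-factor column can be written for structure coloring.

## SASA and buried surface area

Shrake–Rupley accessibility is evaluated with a deterministic Fibonacci
(golden-spiral) point set on each atom's probe-extended sphere instead of
random sampling: runs are reproducible without seeds.  The point set is
fixed in the lab frame, so rotating a structure perturbs totals slightly
(≲0.15 % at 960 points, ≲0.06 % at 3840); translations are exact.  Neighbor
search uses a k-d tree; results are independent of the search structure.
Atom radii come from a named set — default "chothia" heavy-atom values
(C 1.87, N 1.65, O 1.40, S 1.85 Å), with "bondi" selectable and unknown
elements falling back to 1.8 Å with a warning.  The probe radius defaults to
1.4 Å (water).  Whether deposited-structure literature values include
hydrogens or other radii conventions varies, which is why both the radii set
and the hydrogen handling are configuration, not constants.

Buried surface area is SASA(A) + SASA(B) − SASA(A∪B), where "alone" removes
the partner's atoms entirely.  The default reported convention is this
total ΔSASA; the per-side convention (half the total) is always written
alongside because published interface areas use either.  Small negative
per-frame values from quadrature noise are clipped to zero with a debug log
line.  The per-residue decomposition (residue SASA alone minus in complex)
sums to the group total by construction; residues burying more than
θ = 38 Å² on average against the partner are flagged as interface contacts.

## Interaction occupancies

Hydrogen bonds use the common geometric criterion: donor–acceptor heavy-atom
distance ≤ 3.5 Å, plus an H–donor–acceptor angle ≤ 30° when hydrogens exist.
The default mode is heavy-atom-only because Cα-trace fixtures and many
deposited models carry no hydrogens; in with-H mode, frames whose donor has
no covalently bonded hydrogen (within 1.25 Å) fall back to the distance
criterion.  Donors that resolve to carbon raise an error unless explicitly
overridden.  Hydrophobic contacts use a plain distance cutoff (default
4.5 Å).  Multi-acceptor monitors report one series per acceptor plus a
per-frame bond count.

## Dynamic cross-correlation

C_ij is the normalized covariance of Cα displacement 3-vectors about the
mean structure — the full 3-D inner product, not a per-axis variant.  By
default frames are superposed (on the analysed Cα set) before displacements
are measured, which is what a tumbling MD system requires; the fit can be
disabled.  The choice matters: fitting estimates and removes a rigid-body
component, and on the synthetic trajectories — which have no global motion
by construction — that estimated component absorbs part of the designed
correlated fluctuation (a designed 0.8 block reads ≈0.72 after fitting at
2000 frames).  Validation against the designed covariance therefore runs
with the fit disabled; the fit selection used is recorded in the output.
Zero-variance residues get zero off-diagonal entries with a warning.

## Conformational states and landscapes

Four descriptors per frame: the angle each receptor's two domain COMs
subtend at the ligand COM (degrees), and two cross-receptor domain COM
distances (Å).  COMs are mass-weighted by default (configurable — published
angle definitions rarely say).  An alternative "axis-to-com" angle
definition (ligand principal axis vs. the vector to the combined receptor
COM) is selectable and tagged in the output; the principal-axis sign is
fixed toward the ligand's N-terminal half to prevent 180° frame-to-frame
flips.

Angles and distances are incommensurate, so features are z-scored before
mixture fitting and PCA, with the standardization parameters stored and
cluster means reported back in physical units.  The Gaussian mixture is
fitted by EM with k-means++-style seeding, full covariances with a 10⁻⁶
diagonal floor, best-of-restarts selection by final log-likelihood, and a
monotonicity assertion on the likelihood trace.  The stopping tolerance is
10⁻⁶ on the per-sample log-likelihood improvement — tight enough that the
closed-form checks hold to numerical precision, loose enough that
high-K fits on well-separated data do not crawl along degenerate plateaus.
Model order is argmin BIC with the full BIC/AIC table emitted (AIC is
reported, and when the two disagree BIC wins); exact ties resolve to the
smaller K.  Representatives are the hard-assigned frames nearest each
cluster mean in standardized space (ties → earliest frame); a Mahalanobis
metric is available but not default, since the plain Euclidean reading of
"closest to the cluster center" is the conventional one.

The free-energy landscape is the Boltzmann inversion ΔG = −kT ln(p/p_max) of
the 2-D histogram over the two angles (default 32 × 32 bins spanning the
data range padded by 1 %), at T = 310 K.  kT is the primary unit; kJ/mol
uses k_B = 0.0083145 kJ/(mol·K).  Empty bins are capped at
(max occupied ΔG + 1) kT so exported surfaces stay finite; the cap is
recorded.  The reported minimum is the lowest occupied bin's center plus the
frame whose angles lie nearest it.  A landscape over all four features is
deliberately out of scope — the two angles are the axes of interest.

## The synthetic generator

The generator emulates exactly the statistical structure the analyses
estimate, and nothing else:

- **Geometry.** Chains are a helical Cα trace (ligand) and serpentine
  strand blocks (receptor domains); the shapes are arbitrary and irrelevant
  — only COM positions and designed statistics matter.  Monitored residues
  carry one pseudo-side-chain atom so atom-level monitors are exercisable.
- **States.** Each metastable state specifies two angles and two distances.
  Receptors are placed rigidly so these are realized *exactly* before
  noise: the two-domain COM pair is positioned isoceles about the ligand
  COM (fixing the angle), and the remaining freedom — receptor-B azimuth
  and domain-axis tilt — is solved numerically for the two distances.
  Infeasible designs raise a geometry error.  The default three-state
  design puts the dominant state (weight 0.5) at 60°/57° with minor states
  inside the 52–62° and 55–59° bands, mimicking a complex whose
  ligand–receptor-B interface fluctuates less than its ligand–receptor-A
  interface.
- **Dynamics.** States follow a sticky first-order Markov chain
  (T = sI + (1−s)·1πᵀ, default s = 0.95), the simplest process with
  controllable metastability and stationary law π.  Note the
  autocorrelation this implies: occupancy estimates carry an effective
  sample size of n(1−s)/(1+s), which any goodness-of-fit check must use.
- **Noise.** Zero-mean Gaussian displacements per residue (default sd
  0.35 Å per axis, so RMSF = √3·0.35 ≈ 0.61 Å), identical across the atoms
  of a residue.  Correlation blocks use a one-factor model: every residue
  in a block's union loads √|ρ| on a shared latent 3-vector, with the sign
  split across groups for negative ρ.  All pairwise correlations inside
  the union equal ρ and the covariance is positive semidefinite by
  construction — which a naive "cross-group ρ, within-group 0" target is
  not.  Defaults: a +0.8 block coupling the ligand core to receptor-B's
  first domain and a −0.4 block coupling receptor-A's second domain to the
  ligand, echoing the correlated/anticorrelated pattern seen in such
  complexes.
- **H-bonds.** Each monitored pair toggles in contact (2.65–2.95 Å) or out
  (5.5–7.0 Å) by independent Bernoulli draws at the designed occupancy
  (default 40 %).  Because the toy chains never touch, the reporter atom is
  moved to the acceptor's neighborhood; the rest of its chain is translated
  to keep the chain COM fixed, so whole-chain features stay exactly on
  design.  Per-frame contact truth is written to the JSON sidecar.
- **Reproducibility.** One seeded generator drives every draw; a fixed
  seed gives bit-identical trajectories, PDB output and downstream feature
  tables.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: force-field physics, solvent, side-chain packing,
anisotropic or position-dependent fluctuations, state-dependent noise,
global tumbling (superposition is exercised by explicitly added rigid
motions in tests), and any coupling between the H-bond toggles and the
conformational states.

## Problem sizes and numerical tolerances

Validation runs use 1000–5000 frames: 2000 frames put the designed 0.8
block correlation within ±0.05 and isotropic RMSF within 5 %, 1000 frames
put a 40 % occupancy within ±5 points (99 % binomial band), and 5000 frames
resolve the landscape minimum to one bin (≈0.3°).  The analytic SASA checks
use 960–3840 quadrature points (isolated sphere to 1 %, two-sphere burial
to 2 %, mutual agreement to 1 %).  Landscape validation against an analytic
2-D Gaussian potential uses 2×10⁵ samples and compares bins by mean
absolute deviation (≤0.2 kT over ≥50-count bins) with a per-bin bound on
well-populated bins, since a single ~50-count bin carries ≈0.14 kT of
irreducible Poisson noise.

## Known limitations

- SASA quadrature orientation jitter (above) — use more points where
  sub-0.1 % orientation stability matters.
- The fixed-width writer limits coordinates to |x| < 10⁴ Å and residue
  numbers to four digits.
- The GMM assumes full covariances; a diagonal option is not exposed.
- Landscape minima are bin centers; no kernel smoothing or reweighting is
  applied.
- The selection language has no `not` operator and no per-atom wildcards.
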