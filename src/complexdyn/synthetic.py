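"""Synthetic multi-chain complexes and trajectories with known ground truth.

The generator emulates the statistical structure the analysis stages estimate,
without any MD engine: a three-chain complex (ligand L plus two two-domain
receptors G and R), harmonic positional noise with a designed residue-residue
correlation structure, a designed set of metastable inter-domain geometries
visited by a sticky first-order Markov chain, and donor-acceptor pairs whose
contact state toggles with a designed occupancy.

Per metastable state the two receptors are rigidly placed so that the state's
two ligand-receptor angles (vertex at the ligand COM) and two cross-receptor
domain distances are realized *exactly* before noise; the remaining placement
freedom (the azimuth of receptor R and the out-of-plane tilt of its domain
axis) is solved numerically.  Correlated noise uses a one-factor model per
correlation block: every residue in a block's union loads sqrt(|rho|) on a
shared latent 3-vector (sign split across the two groups for negative rho),
so any pair inside the union has displacement correlation exactly rho and the
implied covariance is positive semidefinite by construction.

Chain geometry itself (a helical ligand trace, serpentine receptor domains)
is arbitrary and irrelevant to the analyses; only the designed statistics
matter.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .structure_io import DomainDefinition, Structure, Trajectory

__all__ = [
    "SyntheticSpecError",
    "GeometryError",
    "StateSpec",
    "HBondPairSpec",
    "CorrelationBlock",
    "SyntheticSpec",
    "ToyComplex",
    "build_toy_complex",
    "simulate_trajectory",
    "preset",
    "PRESETS",
    "save_sidecar",
]


class SyntheticSpecError(ValueError):
    """Raised for invalid generator specifications."""


class GeometryError(ValueError):
    """Raised when a designed geometry cannot be realized without overlap."""


@dataclass(frozen=True)
class StateSpec:
    """One metastable inter-domain geometry.

    ``angle_lg`` / ``angle_lr``: ligand-receptor angles in degrees (vertex at
    the ligand COM, rays to the receptor's two domain COMs).  ``dist_1``:
    COM distance G1-R2 (Å); ``dist_2``: COM distance G2-R1 (Å).  ``weight``
    is the designed stationary probability.
    """

    angle_lg: float
    angle_lr: float
    dist_1: float
    dist_2: float
    weight: float


@dataclass(frozen=True)
class HBondPairSpec:
    """A donor/acceptor atom pair with a designed contact occupancy.

    Atoms are addressed as (chain_id, res_seq, atom_name); the named atoms
    are created as pseudo-side-chain atoms on the CA trace.
    """

    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    occupancy: float


@dataclass(frozen=True)
class CorrelationBlock:
    """Target displacement correlation rho between two residue groups.

    Groups are (chain_id, (first_res, last_res)) inclusive ranges.  All pairs
    inside the union of the two groups receive correlation |rho| with the
    sign pattern (+,+)/(-,-) within groups and sign(rho) across them.
    """

    group_a: tuple[str, tuple[int, int]]
    group_b: tuple[str, tuple[int, int]]
    rho: float


# residue names assigned to pseudo-side-chain atoms, by atom name
_PSEUDO_RESNAMES = {
    "NZ": "LYS", "OE1": "GLU", "OE2": "GLU", "OD1": "ASN", "OD2": "ASP",
    "OG": "SER", "CD2": "LEU", "CG1": "VAL", "CG2": "ILE", "CZ": "PHE",
    "NE2": "HIS", "ND1": "HIS", "NH1": "ARG",
}


def _default_states() -> list[StateSpec]:
    # the dominant state sits at the designed stable geometry (60 deg toward
    # receptor G, 57 deg toward receptor R); the two minor states stay inside
    # the designed angular ranges (52-62 and 55-59 deg)
    return [
        StateSpec(angle_lg=60.0, angle_lr=57.0, dist_1=58.0, dist_2=44.0, weight=0.5),
        StateSpec(angle_lg=54.0, angle_lr=55.5, dist_1=62.0, dist_2=40.0, weight=0.3),
        StateSpec(angle_lg=62.0, angle_lr=58.5, dist_1=54.0, dist_2=48.0, weight=0.2),
    ]


def _default_blocks() -> list[CorrelationBlock]:
    # ligand core moves in concert with receptor R's first domain; receptor
    # G's second domain anticorrelates with the ligand core
    return [
        CorrelationBlock(("L", (15, 30)), ("R", (10, 25)), 0.8),
        CorrelationBlock(("G", (110, 125)), ("L", (32, 44)), -0.4),
    ]


def _default_hbonds() -> list[HBondPairSpec]:
    return [HBondPairSpec(donor=("L", 24, "NZ"), acceptor=("R", 120, "OE1"),
                          occupancy=0.40)]


@dataclass
class SyntheticSpec:
    """Full ground-truth design for one synthetic complex + trajectory."""

    n_ligand: int = 50
    n_g1: int = 40
    n_g2: int = 40
    n_r1: int = 40
    n_r2: int = 40
    fluctuation_sd: float = 0.35  # Å per axis per residue
    correlation_blocks: list[CorrelationBlock] = field(default_factory=_default_blocks)
    states: list[StateSpec] = field(default_factory=_default_states)
    transition_stickiness: float = 0.95
    hbond_pairs: list[HBondPairSpec] = field(default_factory=_default_hbonds)
    n_frames: int = 2000
    dt: float = 1.0  # ns between frames
    seed: int = 0

    def validate(self) -> None:
        for label, n in (("ligand", self.n_ligand), ("G1", self.n_g1),
                         ("G2", self.n_g2), ("R1", self.n_r1), ("R2", self.n_r2)):
            if n < 4:
                raise SyntheticSpecError(
                    f"domain {label} has {n} residues; at least 4 required"
                )
        if self.fluctuation_sd <= 0:
            raise SyntheticSpecError("fluctuation_sd must be > 0")
        if not self.states:
            raise SyntheticSpecError("at least one state required")
        w = np.array([s.weight for s in self.states], float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise SyntheticSpecError(
                f"state weights must be non-negative and sum to 1 (got {w.sum()})"
            )
        if not (0.0 <= self.transition_stickiness <= 1.0):
            raise SyntheticSpecError("transition_stickiness must be in [0, 1]")
        for hb in self.hbond_pairs:
            if not (0.0 <= hb.occupancy <= 1.0):
                raise SyntheticSpecError(
                    f"hbond occupancy {hb.occupancy} outside [0, 1]"
                )
        for blk in self.correlation_blocks:
            if not (-1.0 <= blk.rho <= 1.0):
                raise SyntheticSpecError(f"block correlation {blk.rho} outside [-1, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ----------------------------------------------------------------------
# Chain templates
# ----------------------------------------------------------------------

def _helix_trace(n: int, rise: float = 1.5, turn_deg: float = 100.0,
                 radius: float = 2.3) -> np.ndarray:
    t = np.arange(n)
    ang = np.radians(turn_deg) * t
    xyz = np.stack(
        [radius * np.cos(ang), radius * np.sin(ang), rise * t], axis=1
    )
    return xyz - xyz.mean(axis=0)


def _sheet_block(n: int, per_strand: int = 8, d_res: float = 3.4,
                 d_strand: float = 4.8) -> np.ndarray:
    """Serpentine CA block: strands of ``per_strand`` residues, alternating."""
    coords = np.empty((n, 3))
    for i in range(n):
        row, col = divmod(i, per_strand)
        y = col if row % 2 == 0 else per_strand - 1 - col
        coords[i] = (row * d_strand, y * d_res, 0.3 * (i % 2))
    return coords - coords.mean(axis=0)


@dataclass
class ToyComplex:
    """A built synthetic complex: topology, domain definitions and templates.

    ``local_coords`` holds each chain's unplaced template; ``structure``
    carries the chains placed in the first designed state's geometry.
    """

    structure: Structure
    domains: dict[str, DomainDefinition]
    spec: SyntheticSpec
    local_coords: dict[str, np.ndarray]
    chain_slices: dict[str, np.ndarray]
    atom_residue_index: np.ndarray
    residue_ids: list[tuple[str, int]]

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)


def _chain_atoms(chain_id: str, res_seqs: list[int], ca_coords: np.ndarray,
                 pseudo: dict[int, str]):
    """Emit atom attribute rows for one chain (CA trace + pseudo atoms)."""
    rows = []
    for r, xyz in zip(res_seqs, ca_coords):
        res_name = _PSEUDO_RESNAMES.get(pseudo.get(r, ""), "GLY") if r in pseudo \
            else "GLY"
        rows.append(("CA", "C", res_name, r, xyz))
        if r in pseudo:
            name = pseudo[r]
            elem = next((c for c in name if c.isalpha()), "C").upper()
            # deterministic 1.5 Å offset, radially away from the chain centroid
            direction = xyz - ca_coords.mean(axis=0)
            nrm = np.linalg.norm(direction)
            direction = direction / nrm if nrm > 1e-9 else np.array([1.0, 0, 0])
            rows.append((name, elem, _PSEUDO_RESNAMES.get(name, "UNK"), r,
                         xyz + 1.5 * direction))
    return [(chain_id, *row) for row in rows]


def build_toy_complex(spec: SyntheticSpec | None = None) -> ToyComplex:
    """Build the CA-trace pseudo-complex described by ``spec``.

    Chains: L (ligand helix), G (two serpentine domains, residues 1..n_g1 and
    101..100+n_g2), R (same layout).  Residues referenced by H-bond monitors
    carry one pseudo-side-chain atom so atom-level monitors are exercisable.
    Deterministic: identical specs produce byte-identical PDB output.
    """
    spec = spec or SyntheticSpec()
    spec.validate()

    pseudo: dict[str, dict[int, str]] = {"L": {}, "G": {}, "R": {}}
    for hb in spec.hbond_pairs:
        for chain, res, name in (hb.donor, hb.acceptor):
            if chain not in pseudo:
                raise SyntheticSpecError(f"unknown chain {chain!r} in hbond pair")
            pseudo[chain][res] = name

    lig = _helix_trace(spec.n_ligand)
    g1 = _sheet_block(spec.n_g1)
    g2 = _sheet_block(spec.n_g2) + np.array([30.0, 0.0, 0.0])
    r1 = _sheet_block(spec.n_r1)
    r2 = _sheet_block(spec.n_r2) + np.array([30.0, 0.0, 0.0])

    chains = {
        "L": (list(range(1, spec.n_ligand + 1)), lig),
        "G": (list(range(1, spec.n_g1 + 1)) + list(range(101, 101 + spec.n_g2)),
              np.vstack([g1, g2])),
        "R": (list(range(1, spec.n_r1 + 1)) + list(range(101, 101 + spec.n_r2)),
              np.vstack([r1, r2])),
    }

    rows = []
    for cid, (res_seqs, coords) in chains.items():
        for chain, res, name in [(cid, r, pseudo[cid].get(r)) for r in pseudo[cid]]:
            if res not in res_seqs:
                raise SyntheticSpecError(
                    f"hbond monitor references residue {res} absent from chain "
                    f"{chain}"
                )
        rows.extend(_chain_atoms(cid, res_seqs, coords, pseudo[cid]))

    n = len(rows)
    structure = Structure(
        serial=np.arange(1, n + 1),
        atom_name=np.array([r[1] for r in rows], dtype=object),
        element=np.array([r[2] for r in rows], dtype=object),
        res_name=np.array([r[3] for r in rows], dtype=object),
        res_seq=np.array([r[4] for r in rows]),
        chain_id=np.array([r[0] for r in rows], dtype=object),
        coords=np.array([r[5] for r in rows]),
    )

    domains = {
        "L": DomainDefinition("L", "L", [(1, spec.n_ligand)]),
        "G1": DomainDefinition("G1", "G", [(1, spec.n_g1)]),
        "G2": DomainDefinition("G2", "G", [(101, 100 + spec.n_g2)]),
        "R1": DomainDefinition("R1", "R", [(1, spec.n_r1)]),
        "R2": DomainDefinition("R2", "R", [(101, 100 + spec.n_r2)]),
    }

    chain_slices = {cid: idx for cid, idx in structure.chain_index.items()}
    local_coords = {cid: structure.coords[idx].copy()
                    for cid, idx in chain_slices.items()}

    res_ids = structure.residue_ids()
    res_lookup = {rid: k for k, rid in enumerate(res_ids)}
    atom_res = np.array(
        [res_lookup[(str(c), int(r))]
         for c, r in zip(structure.chain_id, structure.res_seq)]
    )

    toy = ToyComplex(
        structure=structure,
        domains=domains,
        spec=spec,
        local_coords=local_coords,
        chain_slices=chain_slices,
        atom_residue_index=atom_res,
        residue_ids=res_ids,
    )
    # place the chains in the first state's geometry so the topology file is
    # already a sane snapshot
    templates = _state_templates(toy)
    toy.structure.coords[:] = templates[0]
    return toy


# ----------------------------------------------------------------------
# Rigid placement realizing a state's angles/distances exactly
# ----------------------------------------------------------------------

def _com(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return (masses[:, None] * coords).sum(axis=0) / masses.sum()


def _frame(p1: np.ndarray, p2: np.ndarray, ref_dir: np.ndarray) -> np.ndarray:
    e1 = p2 - p1
    e1 = e1 / np.linalg.norm(e1)
    a = ref_dir - np.dot(ref_dir, e1) * e1
    if np.linalg.norm(a) < 1e-9:
        a = np.array([0.0, 0.0, 1.0]) - e1[2] * e1
        if np.linalg.norm(a) < 1e-9:
            a = np.array([1.0, 0.0, 0.0]) - e1[0] * e1
    e2 = a / np.linalg.norm(a)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=1)  # columns


def _map_rigid(coords: np.ndarray, p1: np.ndarray, p2: np.ndarray,
               ref_dir: np.ndarray, q1: np.ndarray, q2: np.ndarray,
               target_ref_dir: np.ndarray) -> np.ndarray:
    """Rigidly move ``coords`` so the (p1, p2) pair lands on (q1, q2)."""
    E = _frame(p1, p2, ref_dir)
    F = _frame(q1, q2, target_ref_dir)
    R = F @ E.T
    mid_local = 0.5 * (p1 + p2)
    mid_target = 0.5 * (q1 + q2)
    return (coords - mid_local) @ R.T + mid_target


def _isoceles_placement(s: float, theta_deg: float):
    """Distance rho from the vertex to both points and midpoint distance d for
    an isoceles pair with separation ``s`` subtending ``theta`` at the vertex."""
    theta = np.radians(theta_deg)
    if theta <= 0 or theta >= np.pi:
        raise GeometryError(f"angle {theta_deg} deg outside (0, 180)")
    rho = s / (2.0 * np.sin(theta / 2.0))
    d = rho * np.cos(theta / 2.0)
    return rho, d


def _solve_state_placement(state: StateSpec, s_g: float, s_r: float):
    """Return target COM positions for (G1, G2, R1, R2) with the ligand COM at
    the origin, realizing the state's two angles and two distances exactly."""
    _, d_g = _isoceles_placement(s_g, state.angle_lg)
    _, d_r = _isoceles_placement(s_r, state.angle_lr)
    g1_t = np.array([d_g, +s_g / 2.0, 0.0])
    g2_t = np.array([d_g, -s_g / 2.0, 0.0])

    def r_coms(alpha: float, beta: float):
        u = np.array([np.cos(alpha), np.sin(alpha), 0.0])
        w = np.array([-np.sin(alpha), np.cos(alpha), 0.0])
        v = np.cos(beta) * w + np.sin(beta) * np.array([0.0, 0.0, 1.0])
        m = d_r * u
        r1_t = m + (s_r / 2.0) * v
        r2_t = m - (s_r / 2.0) * v
        return r1_t, r2_t

    def residual(x):
        r1_t, r2_t = r_coms(x[0], x[1])
        return [
            np.linalg.norm(g1_t - r2_t) - state.dist_1,
            np.linalg.norm(g2_t - r1_t) - state.dist_2,
        ]

    starts = [(np.radians(a), np.radians(b))
              for a in (180.0, 150.0, 210.0, 120.0, 240.0, 90.0, 270.0)
              for b in (0.0, 45.0, -45.0, 80.0, -80.0)]
    for x0 in starts:
        sol = least_squares(residual, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if np.linalg.norm(sol.fun) < 1e-8:
            r1_t, r2_t = r_coms(sol.x[0], sol.x[1])
            return g1_t, g2_t, r1_t, r2_t
    raise GeometryError(
        f"cannot realize state geometry (angles {state.angle_lg}/"
        f"{state.angle_lr} deg, distances {state.dist_1}/{state.dist_2} Å) "
        "with the current chain dimensions; try larger separations"
    )


def _state_templates(toy: ToyComplex) -> np.ndarray:
    """Per-state full-complex coordinate templates (n_states, n_atoms, 3)."""
    s = toy.structure
    masses = s.masses()
    idx_l = toy.chain_slices["L"]
    idx_g = toy.chain_slices["G"]
    idx_r = toy.chain_slices["R"]
    dom_idx = {k: d.resolve(s).indices for k, d in toy.domains.items()}

    lig_local = toy.local_coords["L"]
    g_local = toy.local_coords["G"]
    r_local = toy.local_coords["R"]

    lig_com = _com(lig_local, masses[idx_l])
    lig_placed = lig_local - lig_com  # ligand COM at the origin

    # local domain COMs (positions within each chain's template)
    pos_in_g = {int(i): k for k, i in enumerate(idx_g)}
    pos_in_r = {int(i): k for k, i in enumerate(idx_r)}
    g1_l = _com(g_local[[pos_in_g[int(i)] for i in dom_idx["G1"]]],
                masses[dom_idx["G1"]])
    g2_l = _com(g_local[[pos_in_g[int(i)] for i in dom_idx["G2"]]],
                masses[dom_idx["G2"]])
    r1_l = _com(r_local[[pos_in_r[int(i)] for i in dom_idx["R1"]]],
                masses[dom_idx["R1"]])
    r2_l = _com(r_local[[pos_in_r[int(i)] for i in dom_idx["R2"]]],
                masses[dom_idx["R2"]])
    s_g = float(np.linalg.norm(g2_l - g1_l))
    s_r = float(np.linalg.norm(r2_l - r1_l))

    g_centroid = g_local.mean(axis=0)
    r_centroid = r_local.mean(axis=0)

    templates = np.empty((len(toy.spec.states), s.n_atoms, 3))
    for k, state in enumerate(toy.spec.states):
        g1_t, g2_t, r1_t, r2_t = _solve_state_placement(state, s_g, s_r)
        u_g = 0.5 * (g1_t + g2_t)
        u_g = u_g / np.linalg.norm(u_g)
        u_r = 0.5 * (r1_t + r2_t)
        u_r = u_r / np.linalg.norm(u_r)
        g_placed = _map_rigid(g_local, g1_l, g2_l,
                              g_centroid - 0.5 * (g1_l + g2_l),
                              g1_t, g2_t, u_g)
        r_placed = _map_rigid(r_local, r1_l, r2_l,
                              r_centroid - 0.5 * (r1_l + r2_l),
                              r1_t, r2_t, u_r)
        frame = np.empty((s.n_atoms, 3))
        frame[idx_l] = lig_placed
        frame[idx_g] = g_placed
        frame[idx_r] = r_placed
        templates[k] = frame
        _check_overlap(frame, idx_l, idx_g, idx_r)
    return templates


def _check_overlap(frame: np.ndarray, *chain_indices, cutoff: float = 1.0) -> None:
    from scipy.spatial import cKDTree

    for a in range(len(chain_indices)):
        for b in range(a + 1, len(chain_indices)):
            ta = cKDTree(frame[chain_indices[a]])
            d, _ = ta.query(frame[chain_indices[b]], k=1)
            if np.min(d) < cutoff:
                raise GeometryError(
                    "designed state places chains closer than "
                    f"{cutoff} Å (min distance {np.min(d):.2f} Å); "
                    "try larger separations"
                )


# ----------------------------------------------------------------------
# Trajectory simulation
# ----------------------------------------------------------------------

def _sample_states(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Sticky Markov chain: stay w.p. s, otherwise jump to the stationary law.

    The transition matrix T = s*I + (1-s)*1 pi^T has stationary distribution
    pi for every stickiness s in [0, 1).
    """
    pi = np.array([st.weight for st in spec.states], float)
    s = spec.transition_stickiness
    states = np.empty(spec.n_frames, dtype=np.int64)
    states[0] = rng.choice(len(pi), p=pi)
    stay = rng.random(spec.n_frames) < s
    jumps = rng.choice(len(pi), size=spec.n_frames, p=pi)
    for t in range(1, spec.n_frames):
        states[t] = states[t - 1] if stay[t] else jumps[t]
    return states


def _residue_range_indices(toy: ToyComplex, group) -> np.ndarray:
    chain, (lo, hi) = group
    out = [k for k, (c, r) in enumerate(toy.residue_ids)
           if c == chain and lo <= r <= hi]
    if not out:
        raise SyntheticSpecError(
            f"correlation group {group!r} matches no residues"
        )
    return np.asarray(out)


def _residue_noise(toy: ToyComplex, spec: SyntheticSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """(n_frames, n_residues, 3) correlated Gaussian displacements."""
    n_res = toy.n_residues
    eps = rng.standard_normal((spec.n_frames, n_res, 3))
    claimed = np.zeros(n_res, dtype=bool)
    for blk in spec.correlation_blocks:
        ia = _residue_range_indices(toy, blk.group_a)
        ib = _residue_range_indices(toy, blk.group_b)
        union = np.union1d(ia, ib)
        if claimed[union].any():
            raise SyntheticSpecError(
                "correlation blocks overlap; each residue may belong to at "
                "most one block"
            )
        claimed[union] = True
        rho = blk.rho
        if rho == 0.0:
            continue
        f = rng.standard_normal((spec.n_frames, 1, 3))
        sign = np.where(np.isin(union, ia), 1.0, np.sign(rho))
        eps[:, union, :] = (
            np.sqrt(1.0 - abs(rho)) * eps[:, union, :]
            + np.sqrt(abs(rho)) * sign[None, :, None] * f
        )
    return spec.fluctuation_sd * eps


def simulate_trajectory(toy: ToyComplex, spec: SyntheticSpec | None = None):
    """Simulate a trajectory; returns ``(trajectory, sidecar)``.

    The sidecar dict is the machine-readable ground truth: the per-frame
    state path, per-frame H-bond contact booleans and realized occupancies,
    the designed per-state features and the noise design.  Reproducible for
    a fixed seed.
    """
    spec = spec or toy.spec
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    templates = _state_templates(toy)
    states = _sample_states(spec, rng)
    noise = _residue_noise(toy, spec, rng)

    coords = templates[states]  # (n_frames, n_atoms, 3)
    coords = coords + noise[:, toy.atom_residue_index, :]

    s = toy.structure
    sidecar_hbonds = {}
    name_of = s.atom_name.astype(str)
    chain_of = s.chain_id.astype(str)
    res_of = s.res_seq
    for hb in spec.hbond_pairs:
        def _atom_idx(spec3):
            c, r, nm = spec3
            hits = np.flatnonzero((chain_of == c) & (res_of == r) & (name_of == nm))
            if len(hits) != 1:
                raise SyntheticSpecError(f"monitor atom {spec3!r} not unique")
            return int(hits[0])

        d_i = _atom_idx(hb.donor)
        a_i = _atom_idx(hb.acceptor)
        ca_hits = np.flatnonzero(
            (chain_of == hb.donor[0]) & (res_of == hb.donor[1]) & (name_of == "CA")
        )
        ca_i = int(ca_hits[0])
        contact = rng.random(spec.n_frames) < hb.occupancy
        d_in = rng.uniform(2.65, 2.95, size=spec.n_frames)
        d_out = rng.uniform(5.5, 7.0, size=spec.n_frames)
        dist = np.where(contact, d_in, d_out)
        direction = coords[:, ca_i, :] - coords[:, a_i, :]
        nrm = np.linalg.norm(direction, axis=1, keepdims=True)
        nrm[nrm < 1e-9] = 1.0
        direction = direction / nrm
        new_pos = coords[:, a_i, :] + dist[:, None] * direction
        # moving the reporter atom would drag its chain's COM (and hence the
        # designed angles); compensate by translating the rest of the chain so
        # the chain COM -- and every whole-chain feature -- is preserved
        masses = s.masses()
        chain_idx = np.flatnonzero(chain_of == hb.donor[0])
        others = chain_idx[chain_idx != d_i]
        m_d = masses[d_i]
        delta = new_pos - coords[:, d_i, :]
        coords[:, d_i, :] = new_pos
        coords[:, others, :] -= (m_d / masses[others].sum()) * delta[:, None, :]
        label = "{}:{}:{}--{}:{}:{}".format(*hb.donor, *hb.acceptor)
        sidecar_hbonds[label] = {
            "designed_occupancy": hb.occupancy,
            "contact": contact.astype(int).tolist(),
            "realized_occupancy": float(contact.mean()),
        }

    traj = Trajectory(
        topology=s,
        coords=coords,
        times=np.arange(spec.n_frames, dtype=float) * spec.dt,
    )
    sidecar = {
        "seed": spec.seed,
        "spec": spec.to_dict(),
        "states": states.tolist(),
        "state_occupancy": np.bincount(states, minlength=len(spec.states))
        .astype(float).tolist(),
        "designed_features_per_state": [
            {"angle_lg": st.angle_lg, "angle_lr": st.angle_lr,
             "dist_1": st.dist_1, "dist_2": st.dist_2, "weight": st.weight}
            for st in spec.states
        ],
        "hbonds": sidecar_hbonds,
    }
    return traj, sidecar


def save_sidecar(sidecar: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(sidecar, fh, indent=1)


# ----------------------------------------------------------------------
# Presets
# ----------------------------------------------------------------------

def _three_state(seed: int = 0, n_frames: int = 2000) -> SyntheticSpec:
    return SyntheticSpec(seed=seed, n_frames=n_frames)


def _single_state(seed: int = 0, n_frames: int = 1000) -> SyntheticSpec:
    return SyntheticSpec(
        states=[StateSpec(60.0, 57.0, 58.0, 44.0, 1.0)],
        seed=seed,
        n_frames=n_frames,
    )


def _single_state_noise_free(seed: int = 0, n_frames: int = 50) -> SyntheticSpec:
    spec = _single_state(seed=seed, n_frames=n_frames)
    spec.fluctuation_sd = 1e-12
    spec.correlation_blocks = []
    spec.hbond_pairs = []
    return spec


PRESETS = {
    "three-state": _three_state,
    "single-state": _single_state,
    "single-state-noise-free": _single_state_noise_free,
}


def preset(name: str, **kwargs) -> SyntheticSpec:
    """Return a named preset spec (``three-state``, ``single-state``, ...)."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise SyntheticSpecError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return factory(**kwargs)
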