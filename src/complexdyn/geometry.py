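"""Superposition, fluctuation and geometric monitors.

Implements the geometric primitives every downstream stage leans on: Kabsch
least-squares superposition, per-residue RMSF about the trajectory-average
structure, the crystallographic B-factor conversion B = (8*pi^2/3) * RMSF^2,
mass-weighted centers of mass, inter-domain angles and atom-pair distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import (
    DomainDefinition,
    Selection,
    SelectionError,
    Structure,
    Trajectory,
    resolve_selection,
    write_pdb,
)

__all__ = [
    "DegenerateFitError",
    "FluctuationSeries",
    "ScalarSeries",
    "superpose_kabsch",
    "apply_transform",
    "superpose_trajectory",
    "rmsf",
    "rmsf_to_bfactor",
    "write_bfactor_pdb",
    "center_of_mass",
    "domain_angle",
    "pair_distance",
    "BFACTOR_PREFACTOR",
]

#: B = (8*pi^2 / 3) * RMSF^2
BFACTOR_PREFACTOR = 8.0 * np.pi**2 / 3.0


class DegenerateFitError(ValueError):
    """Raised when a superposition fit is underdetermined (<3 atoms, collinear)."""


def _as_indices(structure: Structure, selection) -> np.ndarray:
    """Accept a Selection, an index array, an expression string, or a domain."""
    if selection is None:
        return np.arange(structure.n_atoms)
    if isinstance(selection, Selection):
        return selection.indices
    if isinstance(selection, DomainDefinition):
        return selection.resolve(structure).indices
    if isinstance(selection, str):
        return resolve_selection(structure, selection).indices
    return np.asarray(selection, dtype=int)


def _check_not_collinear(coords: np.ndarray) -> None:
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = max(s[0], 1.0)
    if s[1] / scale < 1e-8:
        raise DegenerateFitError("fit atoms are collinear (or coincident)")


def superpose_kabsch(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with the proper rotation
    (det = +1; the reflection branch is corrected) such that
    ``rotation @ x + translation`` maps mobile coordinates onto the reference.
    RMSD (Å) is evaluated over the fit atoms after the transform.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    if len(mobile) < 3:
        raise DegenerateFitError("need at least 3 fit atoms")
    _check_not_collinear(reference)
    _check_not_collinear(mobile)
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, float)
    w = w / w.sum()
    cm = (w[:, None] * mobile).sum(axis=0)
    cr = (w[:, None] * reference).sum(axis=0)
    H = (w[:, None] * (mobile - cm)).T @ (reference - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt((w * ((moved - reference) ** 2).sum(axis=1)).sum()))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ np.asarray(rotation).T + translation


def superpose_trajectory(trajectory: Trajectory, fit_selection=None):
    """Superpose every frame onto the trajectory-average structure.

    Procedure: fit all frames onto frame 0 (over the fit selection), compute
    the average structure once, then refit the original frames onto that
    average.  Returns ``(aligned_coords, mean_coords)``.
    """
    fit_idx = _as_indices(trajectory.topology, fit_selection)
    if len(fit_idx) == 0:
        raise SelectionError("fit selection resolved to zero atoms")
    frames = trajectory.coords
    ref = frames[0][fit_idx]
    aligned = np.empty_like(frames)
    for k in range(trajectory.n_frames):
        R, t, _ = superpose_kabsch(frames[k][fit_idx], ref)
        aligned[k] = apply_transform(frames[k], R, t)
    mean1 = aligned.mean(axis=0)
    ref2 = mean1[fit_idx]
    for k in range(trajectory.n_frames):
        R, t, _ = superpose_kabsch(frames[k][fit_idx], ref2)
        aligned[k] = apply_transform(frames[k], R, t)
    return aligned, aligned.mean(axis=0)


# ----------------------------------------------------------------------
# RMSF / B-factor
# ----------------------------------------------------------------------

@dataclass
class FluctuationSeries:
    """Per-residue RMSF (Å), optionally with derived B-factors (Å^2)."""

    chain_ids: np.ndarray
    res_seqs: np.ndarray
    rmsf: np.ndarray
    b_factor: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {
            "chain": self.chain_ids,
            "res_seq": self.res_seqs,
            "rmsf_A": self.rmsf,
        }
        if self.b_factor is not None:
            data["b_factor_A2"] = self.b_factor
        return pd.DataFrame(data)


def rmsf(trajectory: Trajectory, analysis_selection=None,
         fit_selection=None) -> FluctuationSeries:
    """Per-residue RMSF about the trajectory-average structure.

    Each residue is represented by its CA atom; frames are superposed onto
    the average structure over ``fit_selection`` (default: the analysed CA
    atoms themselves) before fluctuations are measured.
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    topo = trajectory.topology
    idx = _as_indices(topo, analysis_selection)
    if len(idx) == 0:
        raise SelectionError("analysis selection resolved to zero atoms")
    ca_mask = topo.atom_name.astype(str) == "CA"
    ca_idx = np.array([i for i in idx if ca_mask[i]], dtype=int)
    if len(ca_idx) == 0:
        raise SelectionError("analysis selection contains no CA atoms")
    if fit_selection is None:
        fit_idx = ca_idx
    else:
        fit_idx = _as_indices(topo, fit_selection)
    aligned, mean = superpose_trajectory(trajectory, fit_idx)
    disp = aligned[:, ca_idx, :] - mean[ca_idx]
    values = np.sqrt((disp**2).sum(axis=2).mean(axis=0))
    return FluctuationSeries(
        chain_ids=topo.chain_id[ca_idx].astype(str),
        res_seqs=topo.res_seq[ca_idx].copy(),
        rmsf=values,
    )


def rmsf_to_bfactor(series: FluctuationSeries) -> FluctuationSeries:
    """Populate B = (8*pi^2/3) * RMSF^2 (Å^2)."""
    return FluctuationSeries(
        chain_ids=series.chain_ids,
        res_seqs=series.res_seqs,
        rmsf=series.rmsf,
        b_factor=BFACTOR_PREFACTOR * series.rmsf**2,
    )


def write_bfactor_pdb(structure: Structure, series: FluctuationSeries,
                      path) -> None:
    """Write a PDB with each residue's converted B-factor in the B column."""
    if series.b_factor is None:
        series = rmsf_to_bfactor(series)
    lookup = {
        (str(c), int(r)): float(b)
        for c, r, b in zip(series.chain_ids, series.res_seqs, series.b_factor)
    }
    b = np.array(
        [
            lookup.get((str(c), int(r)), 0.0)
            for c, r in zip(structure.chain_id, structure.res_seq)
        ]
    )
    write_pdb(structure, path, b_factors=b)


# ----------------------------------------------------------------------
# Monitors
# ----------------------------------------------------------------------

@dataclass
class ScalarSeries:
    """A per-frame scalar monitor (angle in degrees or distance in Å)."""

    values: np.ndarray
    times: np.ndarray
    kind: str  # "angle" | "distance"
    label: str = ""
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.values)),
                "time_ns": self.times,
                "value": self.values,
            }
        )


def center_of_mass(structure: Structure, selection=None,
                   coords: np.ndarray | None = None,
                   mass_weighted: bool = True) -> np.ndarray:
    """Center of mass (default) or geometric center of a selection."""
    idx = _as_indices(structure, selection)
    if len(idx) == 0:
        raise SelectionError("center_of_mass: empty selection")
    xyz = structure.coords if coords is None else np.asarray(coords, float)
    pts = xyz[idx]
    if not mass_weighted:
        return pts.mean(axis=0)
    m = structure.masses()[idx]
    return (m[:, None] * pts).sum(axis=0) / m.sum()


def _com_series(trajectory: Trajectory, idx: np.ndarray,
                mass_weighted: bool) -> np.ndarray:
    pts = trajectory.coords[:, idx, :]
    if not mass_weighted:
        return pts.mean(axis=1)
    m = trajectory.topology.masses()[idx]
    return (m[None, :, None] * pts).sum(axis=1) / m.sum()


def _angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < 1e-12) or np.any(nv < 1e-12):
        raise ValueError("degenerate geometry: zero-length ray in angle")
    cosang = np.clip((u * v).sum(axis=-1) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def _principal_axis(coords: np.ndarray, n_half: int) -> np.ndarray:
    """First principal axis of a (n,3) cloud, sign fixed toward the first
    ``n_half`` points (the N-terminal half) to avoid frame-to-frame flips."""
    centered = coords - coords.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    axis = Vt[0]
    toward_n = coords[:n_half].mean(axis=0) - coords.mean(axis=0)
    if np.dot(axis, toward_n) < 0:
        axis = -axis
    return axis


def domain_angle(trajectory: Trajectory, ligand, domain_a, domain_b,
                 definition: str = "vertex-at-ligand",
                 mass_weighted: bool = True) -> ScalarSeries:
    """Per-frame angle between a ligand and the two domains of one receptor.

    ``vertex-at-ligand`` (default): the angle at the ligand COM subtended by
    the rays to COM(domain_a) and COM(domain_b).  ``axis-to-com``: the angle
    between the ligand's first principal axis (over its CA atoms, sign fixed
    toward its N-terminal half) and the vector from the ligand COM to
    COM(domain_a + domain_b).
    """
    topo = trajectory.topology
    lig_idx = _as_indices(topo, ligand)
    a_idx = _as_indices(topo, domain_a)
    b_idx = _as_indices(topo, domain_b)
    for name, idx in (("ligand", lig_idx), ("domain_a", a_idx), ("domain_b", b_idx)):
        if len(idx) == 0:
            raise SelectionError(f"domain_angle: {name} selection is empty")
    com_l = _com_series(trajectory, lig_idx, mass_weighted)
    com_a = _com_series(trajectory, a_idx, mass_weighted)
    com_b = _com_series(trajectory, b_idx, mass_weighted)
    if definition == "vertex-at-ligand":
        values = _angle_deg(com_a - com_l, com_b - com_l)
    elif definition == "axis-to-com":
        ca_mask = topo.atom_name.astype(str) == "CA"
        lig_ca = np.array([i for i in lig_idx if ca_mask[i]], dtype=int)
        if len(lig_ca) < 3:
            raise SelectionError("axis-to-com definition needs >=3 ligand CA atoms")
        com_ab = _com_series(trajectory, np.concatenate([a_idx, b_idx]),
                             mass_weighted)
        n_half = max(1, len(lig_ca) // 2)
        values = np.empty(trajectory.n_frames)
        for k in range(trajectory.n_frames):
            axis = _principal_axis(trajectory.coords[k][lig_ca], n_half)
            values[k] = _angle_deg(axis[None, :], (com_ab[k] - com_l[k])[None, :])[0]
    else:
        raise ValueError(f"unknown angle definition {definition!r}")
    return ScalarSeries(
        values=values,
        times=trajectory.times.copy(),
        kind="angle",
        meta={"definition": definition, "mass_weighted": mass_weighted},
    )


def _single_atom(structure: Structure, spec) -> int:
    idx = _as_indices(structure, spec)
    if len(idx) != 1:
        raise SelectionError(
            f"atom spec {spec!r} resolved to {len(idx)} atoms (need exactly 1)"
        )
    return int(idx[0])


def pair_distance(trajectory: Trajectory, spec1, spec2) -> ScalarSeries:
    """Per-frame Euclidean distance (Å) between two single-atom selections."""
    i = _single_atom(trajectory.topology, spec1)
    j = _single_atom(trajectory.topology, spec2)
    d = np.linalg.norm(trajectory.coords[:, i, :] - trajectory.coords[:, j, :],
                       axis=1)
    return ScalarSeries(
        values=d,
        times=trajectory.times.copy(),
        kind="distance",
        label=f"{spec1}--{spec2}",
        meta={"atom_1": str(spec1), "atom_2": str(spec2)},
    )
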