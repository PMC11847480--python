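"""Solvent-accessible surface area and buried-interface decomposition.

SASA uses the Shrake-Rupley construction with a deterministic Fibonacci
(golden-spiral) quadrature on each atom's probe-extended sphere instead of
random point sampling: reproducible without seeds, at the cost of a small
(<~0.1 % on totals) orientation jitter because the point set is fixed in the
lab frame.

Buried surface area follows the standard complexation bookkeeping

    BSA_total = SASA(A alone) + SASA(B alone) - SASA(A u B),

where "alone" removes the partner's atoms entirely.  The per-side convention
divides by two.  The per-residue decomposition (residue SASA alone minus in
the complex) sums to the total exactly, and residues burying more than a
threshold (default 38 Å^2) against the partner are flagged as interface
contacts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Selection, SelectionError, Structure, Trajectory
from .geometry import _as_indices

__all__ = [
    "RADII_SETS",
    "SASAResult",
    "BSASeries",
    "ResidueBurialMap",
    "fibonacci_sphere",
    "sasa_shrake_rupley",
    "buried_surface_area",
    "bsa_timeseries",
    "residue_burial_map",
]

logger = logging.getLogger(__name__)

#: heavy-atom van der Waals radii (Å) by element
RADII_SETS: dict[str, dict[str, float]] = {
    "chothia": {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "H": 1.00, "P": 1.90},
    "bondi": {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80},
}

DEFAULT_RADIUS = 1.8


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors from the golden-spiral construction."""
    if n < 1:
        raise ValueError("need at least one quadrature point")
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def atom_radii(structure: Structure, indices: np.ndarray,
               radii_set: str = "chothia",
               default_radius: float = DEFAULT_RADIUS) -> np.ndarray:
    try:
        table = RADII_SETS[radii_set]
    except KeyError:
        raise ValueError(
            f"unknown radii set {radii_set!r}; available: {sorted(RADII_SETS)}"
        ) from None
    radii = np.empty(len(indices))
    unknown: set[str] = set()
    for k, i in enumerate(indices):
        el = str(structure.element[i]).upper()
        if el in table:
            radii[k] = table[el]
        else:
            radii[k] = default_radius
            unknown.add(el)
    if unknown:
        warnings.warn(
            f"elements {sorted(unknown)} not in radii set {radii_set!r}; "
            f"using default radius {default_radius} Å"
        )
    return radii


def _sasa_areas(coords: np.ndarray, radii: np.ndarray, probe: float,
                points: np.ndarray) -> np.ndarray:
    """Per-atom accessible areas (Å^2); occlusion only among the given atoms."""
    n = len(coords)
    ext = radii + probe
    areas = np.empty(n)
    tree = cKDTree(coords)
    r_max = ext.max()
    for i in range(n):
        sphere = coords[i] + ext[i] * points
        neigh = tree.query_ball_point(coords[i], ext[i] + r_max)
        accessible = np.ones(len(points), dtype=bool)
        for j in neigh:
            if j == i:
                continue
            d2 = ((sphere - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 >= ext[j] ** 2
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.mean()
    return areas


@dataclass
class SASAResult:
    """Per-atom accessible areas with residue and chain aggregations."""

    atom_indices: np.ndarray
    atom_areas: np.ndarray
    chain_ids: np.ndarray
    res_seqs: np.ndarray
    res_names: np.ndarray
    probe_radius: float
    n_points: int
    radii_set: str

    @property
    def total(self) -> float:
        return float(self.atom_areas.sum())

    def per_residue(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chain": self.chain_ids,
                "res_seq": self.res_seqs,
                "res_name": self.res_names,
                "area_A2": self.atom_areas,
            }
        )
        return (
            df.groupby(["chain", "res_seq", "res_name"], sort=False)["area_A2"]
            .sum()
            .reset_index()
        )

    def per_chain(self) -> pd.DataFrame:
        df = pd.DataFrame({"chain": self.chain_ids, "area_A2": self.atom_areas})
        return df.groupby("chain", sort=False)["area_A2"].sum().reset_index()


def sasa_shrake_rupley(structure: Structure, selection=None,
                       coords: np.ndarray | None = None,
                       probe_radius: float = 1.4, n_points: int = 960,
                       radii_set: str = "chothia",
                       default_radius: float = DEFAULT_RADIUS) -> SASAResult:
    """Shrake-Rupley SASA of a selection, with only those atoms present.

    Deterministic golden-spiral quadrature (no RNG); atom radii looked up by
    element in the named set (default Chothia-style heavy-atom radii).
    """
    if n_points < 26:
        raise ValueError("n_points must be >= 26")
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    idx = _as_indices(structure, selection)
    if len(idx) == 0:
        raise SelectionError("SASA: empty selection")
    xyz = structure.coords if coords is None else np.asarray(coords, float)
    radii = atom_radii(structure, idx, radii_set, default_radius)
    areas = _sasa_areas(xyz[idx], radii, probe_radius, fibonacci_sphere(n_points))
    return SASAResult(
        atom_indices=idx,
        atom_areas=areas,
        chain_ids=structure.chain_id[idx].astype(str),
        res_seqs=structure.res_seq[idx].copy(),
        res_names=structure.res_name[idx].astype(str),
        probe_radius=probe_radius,
        n_points=n_points,
        radii_set=radii_set,
    )


def _check_disjoint(idx_a: np.ndarray, idx_b: np.ndarray) -> None:
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("interface groups overlap; they must be disjoint")


def buried_surface_area(structure: Structure, group_a, group_b,
                        coords: np.ndarray | None = None,
                        convention: str = "total",
                        probe_radius: float = 1.4, n_points: int = 960,
                        radii_set: str = "chothia") -> float:
    """Buried surface area (Å^2) between two disjoint atom groups.

    ``convention="total"`` returns SASA(A) + SASA(B) - SASA(A u B);
    ``"per-side"`` halves it.  Small negative values from quadrature noise
    are clipped to zero.
    """
    if convention not in ("total", "per-side"):
        raise ValueError(f"unknown BSA convention {convention!r}")
    idx_a = _as_indices(structure, group_a)
    idx_b = _as_indices(structure, group_b)
    _check_disjoint(idx_a, idx_b)
    kw = dict(coords=coords, probe_radius=probe_radius, n_points=n_points,
              radii_set=radii_set)
    sasa_a = sasa_shrake_rupley(structure, idx_a, **kw).total
    sasa_b = sasa_shrake_rupley(structure, idx_b, **kw).total
    sasa_ab = sasa_shrake_rupley(structure, np.concatenate([idx_a, idx_b]),
                                 **kw).total
    bsa = sasa_a + sasa_b - sasa_ab
    if bsa < 0:
        logger.debug("clipping negative per-frame BSA %.4f Å^2 to 0", bsa)
        bsa = 0.0
    return bsa / 2.0 if convention == "per-side" else bsa


@dataclass
class BSASeries:
    """Per-frame buried surface area for one named interface."""

    frames: np.ndarray
    times: np.ndarray
    bsa_total: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def bsa_per_side(self) -> np.ndarray:
        return self.bsa_total / 2.0

    @property
    def mean(self) -> float:
        return float(self.bsa_total.mean())

    @property
    def sd(self) -> float:
        return float(self.bsa_total.std(ddof=0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "time_ns": self.times,
                "bsa_total_A2": self.bsa_total,
                "bsa_per_side_A2": self.bsa_per_side,
            }
        )


def _sampled_frames(trajectory: Trajectory, interval_ns: float) -> np.ndarray:
    if trajectory.n_frames > 1:
        dt = float(trajectory.times[1] - trajectory.times[0])
    else:
        dt = interval_ns
    if interval_ns < dt - 1e-9:
        raise ValueError(
            f"sampling interval {interval_ns} ns is below the frame spacing "
            f"{dt} ns"
        )
    stride = max(1, int(round(interval_ns / dt)))
    idx = np.arange(0, trajectory.n_frames, stride)
    if idx.size == 0:
        raise ValueError("no frames at the requested sampling interval")
    return idx


def bsa_timeseries(trajectory: Trajectory, group_a, group_b,
                   interval_ns: float = 1.0, probe_radius: float = 1.4,
                   n_points: int = 960, radii_set: str = "chothia",
                   label: str = "") -> BSASeries:
    """BSA per snapshot sampled at ``interval_ns`` starting at time zero."""
    topo = trajectory.topology
    idx_a = _as_indices(topo, group_a)
    idx_b = _as_indices(topo, group_b)
    _check_disjoint(idx_a, idx_b)
    sel = _sampled_frames(trajectory, interval_ns)
    values = np.array(
        [
            buried_surface_area(
                topo, idx_a, idx_b, coords=trajectory.coords[k],
                probe_radius=probe_radius, n_points=n_points,
                radii_set=radii_set,
            )
            for k in sel
        ]
    )
    return BSASeries(
        frames=sel,
        times=trajectory.times[sel],
        bsa_total=values,
        label=label,
        meta={"interval_ns": interval_ns, "probe_radius": probe_radius,
              "n_points": n_points, "radii_set": radii_set},
    )


@dataclass
class ResidueBurialMap:
    """Mean per-residue buried area against the partner group."""

    table: pd.DataFrame  # chain, res_seq, res_name, mean_buried_A2, contact
    threshold: float
    meta: dict = field(default_factory=dict)

    @property
    def contact_set(self) -> list[tuple[str, int]]:
        hit = self.table[self.table["contact"]]
        return list(zip(hit["chain"], hit["res_seq"]))


def residue_burial_map(trajectory: Trajectory, group_a, group_b,
                       threshold: float = 38.0, interval_ns: float = 1.0,
                       probe_radius: float = 1.4, n_points: int = 960,
                       radii_set: str = "chothia") -> ResidueBurialMap:
    """Per-residue buried area, averaged over sampled frames.

    A residue's buried area is its SASA with only its own group present minus
    its SASA in the two-group complex; residues whose mean exceeds
    ``threshold`` (default 38 Å^2) form the interface contact set.
    """
    topo = trajectory.topology
    idx_a = _as_indices(topo, group_a)
    idx_b = _as_indices(topo, group_b)
    _check_disjoint(idx_a, idx_b)
    sel = _sampled_frames(trajectory, interval_ns)
    both = np.concatenate([idx_a, idx_b])
    kw = dict(probe_radius=probe_radius, n_points=n_points, radii_set=radii_set)

    acc: pd.DataFrame | None = None
    for k in sel:
        xyz = trajectory.coords[k]
        alone = pd.concat(
            [
                sasa_shrake_rupley(topo, idx_a, coords=xyz, **kw).per_residue(),
                sasa_shrake_rupley(topo, idx_b, coords=xyz, **kw).per_residue(),
            ]
        )
        complexed = sasa_shrake_rupley(topo, both, coords=xyz, **kw).per_residue()
        merged = alone.merge(
            complexed, on=["chain", "res_seq", "res_name"],
            suffixes=("_alone", "_complex"),
        )
        merged["buried"] = merged["area_A2_alone"] - merged["area_A2_complex"]
        part = merged[["chain", "res_seq", "res_name", "buried"]]
        acc = part if acc is None else acc.assign(buried=acc["buried"].to_numpy()
                                                  + part["buried"].to_numpy())
    table = acc.copy()
    table["mean_buried_A2"] = table.pop("buried") / len(sel)
    table["contact"] = table["mean_buried_A2"] > threshold
    return ResidueBurialMap(
        table=table.reset_index(drop=True),
        threshold=threshold,
        meta={"interval_ns": interval_ns, "probe_radius": probe_radius,
              "n_points": n_points, "radii_set": radii_set,
              "n_frames_sampled": len(sel)},
    )
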