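"""Hydrogen-bond and hydrophobic-contact occupancy monitors.

Criteria follow the common geometric convention (donor-acceptor heavy-atom
distance <= 3.5 Å; hydrogen-donor-acceptor angle <= 30 deg when hydrogens are
present).  The default mode is heavy-atom-only because CA-trace synthetic
fixtures and many deposited PDB files carry no hydrogens; with-H mode adds
the angle criterion for donors that do have a covalently bonded hydrogen
(within 1.25 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import _single_atom
from .structure_io import SelectionError, Trajectory

__all__ = [
    "ChemistryError",
    "HBondCriteria",
    "OccupancySeries",
    "hbond_occupancy",
    "contact_occupancy",
    "hbond_profile",
]


class ChemistryError(ValueError):
    """Raised when a monitor's chemistry is implausible (e.g. carbon donor)."""


@dataclass(frozen=True)
class HBondCriteria:
    distance_cutoff: float = 3.5  # donor-acceptor heavy-atom distance, Å
    angle_cutoff: float = 30.0  # H-D-A angle, degrees (with-H mode only)
    mode: str = "heavy-atom-only"  # or "geometric-with-H"

    def __post_init__(self):
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.mode not in ("heavy-atom-only", "geometric-with-H"):
            raise ValueError(f"unknown H-bond mode {self.mode!r}")


@dataclass
class OccupancySeries:
    """Per-frame bond/contact booleans with the summary occupancy fraction."""

    frames: np.ndarray
    times: np.ndarray
    distances: np.ndarray
    bonded: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def occupancy(self) -> float:
        return float(self.bonded.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "time_ns": self.times,
                "distance_A": self.distances,
                "bonded": self.bonded.astype(int),
            }
        )


def _pair_distances(trajectory: Trajectory, i: int, j: int) -> np.ndarray:
    return np.linalg.norm(
        trajectory.coords[:, i, :] - trajectory.coords[:, j, :], axis=1
    )


def hbond_occupancy(trajectory: Trajectory, donor, acceptor,
                    criteria: HBondCriteria | None = None,
                    allow_any_donor: bool = False) -> OccupancySeries:
    """Hydrogen-bond occupancy for one donor/acceptor heavy-atom pair.

    In heavy-atom-only mode a bond is present iff the donor-acceptor distance
    is within the cutoff; with-H mode additionally requires a hydrogen within
    1.25 Å of the donor whose H-donor-acceptor angle is within the angle
    cutoff (frames whose donor carries no hydrogen fall back to the distance
    criterion).
    """
    criteria = criteria or HBondCriteria()
    topo = trajectory.topology
    d_i = _single_atom(topo, donor)
    a_i = _single_atom(topo, acceptor)
    d_el = str(topo.element[d_i]).upper()
    if d_el not in ("N", "O") and not allow_any_donor:
        raise ChemistryError(
            f"donor {donor!r} is element {d_el}, not a conventional N/O "
            "hydrogen-bond donor; pass allow_any_donor=True to override"
        )
    dist = _pair_distances(trajectory, d_i, a_i)
    bonded = dist <= criteria.distance_cutoff

    if criteria.mode == "geometric-with-H":
        h_mask = np.char.upper(topo.element.astype(str)) == "H"
        h_idx = np.flatnonzero(h_mask)
        if len(h_idx):
            d_pos = trajectory.coords[:, d_i, :]
            a_pos = trajectory.coords[:, a_i, :]
            ok_angle = np.zeros(trajectory.n_frames, dtype=bool)
            has_h = np.zeros(trajectory.n_frames, dtype=bool)
            for h in h_idx:
                h_pos = trajectory.coords[:, h, :]
                dh = np.linalg.norm(h_pos - d_pos, axis=1)
                attached = dh <= 1.25
                if not attached.any():
                    continue
                has_h |= attached
                u = h_pos - d_pos
                v = a_pos - d_pos
                cosang = (u * v).sum(axis=1) / (
                    np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
                )
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                # H-D-A angle: deviation of the D->H direction from D->A
                ok_angle |= attached & (ang <= criteria.angle_cutoff)
            bonded = bonded & (ok_angle | ~has_h)

    return OccupancySeries(
        frames=np.arange(trajectory.n_frames),
        times=trajectory.times.copy(),
        distances=dist,
        bonded=bonded,
        label=f"{donor}--{acceptor}",
        meta={"criteria": dataclass_to_dict(criteria), "kind": "hbond"},
    )


def dataclass_to_dict(obj) -> dict:
    import dataclasses

    return dataclasses.asdict(obj)


def contact_occupancy(trajectory: Trajectory, spec1, spec2,
                      cutoff: float = 4.5) -> OccupancySeries:
    """Distance-cutoff contact occupancy for one atom pair (default 4.5 Å)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    topo = trajectory.topology
    i = _single_atom(topo, spec1)
    j = _single_atom(topo, spec2)
    dist = _pair_distances(trajectory, i, j)
    return OccupancySeries(
        frames=np.arange(trajectory.n_frames),
        times=trajectory.times.copy(),
        distances=dist,
        bonded=dist <= cutoff,
        label=f"{spec1}--{spec2}",
        meta={"cutoff": cutoff, "kind": "contact"},
    )


def hbond_profile(trajectory: Trajectory, donor, acceptors: list,
                  criteria: HBondCriteria | None = None,
                  allow_any_donor: bool = False):
    """Per-acceptor occupancy series for one donor plus a per-frame bond count.

    Mirrors multi-acceptor monitors (one donor tested against several
    candidate acceptors, e.g. a lysine amine against a serine hydroxyl and an
    asparagine carbonyl): returns ``(series_by_label, counts)`` where
    ``counts[t]`` is the number of simultaneously satisfied bonds in frame t.
    """
    series = {}
    counts = np.zeros(trajectory.n_frames, dtype=int)
    for acc in acceptors:
        s = hbond_occupancy(trajectory, donor, acc, criteria, allow_any_donor)
        series[s.label] = s
        counts += s.bonded.astype(int)
    return series, counts
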