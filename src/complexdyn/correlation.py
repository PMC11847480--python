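"""Dynamic cross-correlation of CA displacement vectors.

C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>) with dr_i(t) the deviation
of residue i's CA from its trajectory-average position after superposition.
The dot product is the full 3-D inner product (the standard DCCM definition,
not a per-axis variant).  Whether frames are superposed before measuring the
displacements materially changes C, so the fit selection used is recorded in
the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import _as_indices, superpose_trajectory
from .structure_io import SelectionError, Trajectory

__all__ = ["DCCMatrix", "dccm"]


@dataclass
class DCCMatrix:
    """Residue-residue displacement correlation matrix."""

    matrix: np.ndarray
    chain_ids: np.ndarray
    res_seqs: np.ndarray
    fitted: bool
    meta: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return [f"{c}{r}" for c, r in zip(self.chain_ids, self.res_seqs)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def block_mean(self, rows: np.ndarray, cols: np.ndarray) -> float:
        """Mean correlation over a rectangular residue block (by position)."""
        return float(self.matrix[np.ix_(rows, cols)].mean())


def dccm(trajectory: Trajectory, residue_selection=None, fit: bool = True,
         fit_selection=None) -> DCCMatrix:
    """Dynamic cross-correlation matrix over the CA atoms of a selection.

    Frames are superposed onto the trajectory-average structure over
    ``fit_selection`` (default: the analysed CA atoms) unless ``fit=False``.
    Residues with zero displacement variance get off-diagonal 0 / diagonal 1
    with a warning.
    """
    if trajectory.n_frames < 2:
        raise ValueError("DCCM requires at least 2 frames")
    topo = trajectory.topology
    idx = _as_indices(topo, residue_selection)
    ca_mask = topo.atom_name.astype(str) == "CA"
    ca_idx = np.array([i for i in idx if ca_mask[i]], dtype=int)
    if len(ca_idx) < 2:
        raise SelectionError("DCCM needs at least 2 CA atoms in the selection")

    if fit:
        aligned, mean = superpose_trajectory(
            trajectory, ca_idx if fit_selection is None else fit_selection
        )
    else:
        aligned = trajectory.coords
        mean = aligned.mean(axis=0)

    disp = aligned[:, ca_idx, :] - mean[ca_idx]  # (T, n, 3)
    cov = np.tensordot(disp, disp, axes=([0, 2], [0, 2])) / trajectory.n_frames
    var = np.diag(cov).copy()
    dead = var < 1e-12
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} residues have zero displacement variance; "
            "their correlations are reported as 0"
        )
        var[dead] = 1.0
    denom = np.sqrt(np.outer(var, var))
    C = cov / denom
    C[dead, :] = 0.0
    C[:, dead] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    return DCCMatrix(
        matrix=C,
        chain_ids=topo.chain_id[ca_idx].astype(str),
        res_seqs=topo.res_seq[ca_idx].copy(),
        fitted=fit,
        meta={"n_frames": trajectory.n_frames,
              "fit_selection": "analysed CA" if fit and fit_selection is None
              else str(fit_selection) if fit else "none"},
    )
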