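"""End-to-end orchestration: one config in, a report bundle out.

Stage order: features -> RMSF/B-factor -> BSA -> monitors -> DCCM ->
clustering -> landscape.  Every CSV carries a metadata header (package
version, seed, config hash) so any artifact is self-describing; identical
config + seed reproduce byte-identical CSV bodies.  A failing stage aborts
the run with the stage name while retaining partial outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash, preflight
from .correlation import dccm
from .geometry import pair_distance, rmsf, rmsf_to_bfactor, write_bfactor_pdb
from .interactions import HBondCriteria, contact_occupancy, hbond_occupancy
from .states import (
    extract_features,
    free_energy_landscape,
    representative_frames,
    select_k,
)
from .structure_io import DomainDefinition, Trajectory, read_trajectory, write_pdb
from .surface import bsa_timeseries, residue_burial_map
from .synthetic import build_toy_complex, preset, save_sidecar, simulate_trajectory

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger("complexdyn.pipeline")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_csv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    header = "".join(
        f"# {k}: {v}\n" for k, v in meta.items()
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.6f")


def _domain_lookup(config: RunConfig, toy=None) -> dict[str, DomainDefinition]:
    if toy is not None and not config.domains:
        return toy.domains
    return {
        d.label: DomainDefinition(d.label, d.chain,
                                  [tuple(r) for r in d.residues])
        for d in config.domains
    }


def run_pipeline(config: RunConfig, output_dir=None) -> dict:
    """Execute the full analysis; returns a summary dict of key results."""
    preflight(config)
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)

    meta = {
        "complexdyn_version": __version__,
        "seed": config.seed,
        "config_sha": config_hash(config),
    }
    params = config.analysis
    summary: dict = {"config_sha": meta["config_sha"]}
    stage = "setup"
    t_stage = time.time()

    def tick(next_stage: str):
        nonlocal stage, t_stage
        logger.info("stage %s finished in %.2f s", stage, time.time() - t_stage)
        stage = next_stage
        t_stage = time.time()

    try:
        # ------------------------------------------------------ inputs
        if config.synthetic_preset:
            kwargs = {"seed": config.seed}
            if config.synthetic_frames:
                kwargs["n_frames"] = config.synthetic_frames
            spec = preset(config.synthetic_preset, **kwargs)
            toy = build_toy_complex(spec)
            traj, sidecar = simulate_trajectory(toy)
            save_sidecar(sidecar, out / "ground_truth.json")
            write_pdb(toy.structure, out / "topology.pdb",
                      header_remarks=[f"synthetic preset "
                                      f"{config.synthetic_preset} seed "
                                      f"{config.seed}"])
            domains = _domain_lookup(config, toy)
            ligand_label = config.ligand or "L"
            ra = config.receptor_a or ("G1", "G2")
            rb = config.receptor_b or ("R1", "R2")
        else:
            traj = read_trajectory(config.trajectory, dt=params.dt)
            toy = None
            domains = _domain_lookup(config)
            ligand_label = config.ligand
            ra, rb = config.receptor_a, config.receptor_b
        ligand = domains[ligand_label]
        rec_a = (domains[ra[0]], domains[ra[1]])
        rec_b = (domains[rb[0]], domains[rb[1]])
        tick("features")

        # ---------------------------------------------------- features
        features = extract_features(
            traj, ligand, rec_a, rec_b,
            angle_definition=params.angle_definition,
            mass_weighted=params.mass_weighted_com,
        )
        _write_csv(features.df, out / "features.csv",
                   {**meta, **{k: v for k, v in features.meta.items()}})
        tick("rmsf")

        # -------------------------------------------------------- RMSF
        fluct = rmsf_to_bfactor(rmsf(traj))
        _write_csv(fluct.to_frame(), out / "rmsf_bfactor.csv", meta)
        write_bfactor_pdb(traj.topology, fluct, out / "bfactor.pdb")
        summary["mean_rmsf_A"] = float(fluct.rmsf.mean())
        tick("bsa")

        # --------------------------------------------------------- BSA
        chain_of = {label: d.chain_id for label, d in domains.items()}
        lig_chain = chain_of[ligand_label]
        for tag, pair in (("a", ra), ("b", rb)):
            partner_chain = chain_of[pair[0]]
            series = bsa_timeseries(
                traj, f"chain {lig_chain}", f"chain {partner_chain}",
                interval_ns=params.bsa_interval_ns,
                probe_radius=params.probe_radius, n_points=params.n_points,
                radii_set=params.radii_set,
                label=f"{lig_chain}-{partner_chain}",
            )
            _write_csv(series.to_frame(), out / f"bsa_{tag}.csv",
                       {**meta, "interface": series.label,
                        "mean_A2": f"{series.mean:.4f}",
                        "sd_A2": f"{series.sd:.4f}"})
            burial = residue_burial_map(
                traj, f"chain {lig_chain}", f"chain {partner_chain}",
                threshold=params.contact_threshold,
                interval_ns=params.bsa_interval_ns,
                probe_radius=params.probe_radius, n_points=params.n_points,
                radii_set=params.radii_set,
            )
            _write_csv(burial.table, out / f"residue_burial_{tag}.csv",
                       {**meta, "interface": series.label,
                        "threshold_A2": params.contact_threshold})
            summary[f"bsa_mean_{tag}_A2"] = series.mean
        tick("monitors")

        # ---------------------------------------------------- monitors
        criteria = HBondCriteria(
            distance_cutoff=params.hbond_distance_cutoff,
            angle_cutoff=params.hbond_angle_cutoff,
        )
        monitor_rows = []
        for mon in config.monitors:
            if mon.kind == "hbond":
                s = hbond_occupancy(traj, mon.atom_1, mon.atom_2, criteria)
            elif mon.kind == "contact":
                s = contact_occupancy(traj, mon.atom_1, mon.atom_2,
                                      mon.cutoff or params.contact_cutoff)
            else:
                s = pair_distance(traj, mon.atom_1, mon.atom_2)
            df = s.to_frame()
            _write_csv(df, out / f"monitor_{mon.label}.csv",
                       {**meta, "label": mon.label, "kind": mon.kind})
            row = {"label": mon.label, "kind": mon.kind}
            if hasattr(s, "occupancy"):
                row["occupancy"] = s.occupancy
            monitor_rows.append(row)
        if toy is not None:
            # synthetic runs automatically monitor the designed H-bond pairs
            for hb in toy.spec.hbond_pairs:
                d = "chain {} and resid {} and name {}".format(*hb.donor)
                a = "chain {} and resid {} and name {}".format(*hb.acceptor)
                s = hbond_occupancy(traj, d, a, criteria)
                label = "hbond_{}_{}_{}".format(hb.donor[0], hb.donor[1],
                                                hb.donor[2])
                _write_csv(s.to_frame(), out / f"monitor_{label}.csv",
                           {**meta, "label": label, "kind": "hbond",
                            "designed_occupancy": hb.occupancy})
                monitor_rows.append({"label": label, "kind": "hbond",
                                     "occupancy": s.occupancy,
                                     "designed": hb.occupancy})
        with open(out / "monitors.json", "w") as fh:
            json.dump(monitor_rows, fh, indent=1)
        if monitor_rows and "occupancy" in monitor_rows[-1]:
            summary["hbond_occupancy"] = monitor_rows[-1]["occupancy"]
        tick("dccm")

        # -------------------------------------------------------- DCCM
        matrix = dccm(traj)
        _write_csv(matrix.to_frame().reset_index().rename(
            columns={"index": "residue"}), out / "dccm.csv", meta)
        tick("clustering")

        # -------------------------------------------------- clustering
        ks = select_k(features, range(params.k_min, params.k_max + 1),
                      seed=config.seed, n_restarts=params.n_restarts)
        _write_csv(ks.table, out / "k_selection.csv", meta)
        model = ks.models[ks.chosen_k]
        with open(out / "gmm.json", "w") as fh:
            json.dump(model.to_dict(), fh, indent=1)
        labels = pd.DataFrame(
            {"frame": features.df["frame"], "cluster": model.labels}
        )
        _write_csv(labels, out / "labels.csv", meta)
        reps = representative_frames(features, model)
        for k, frame_idx in reps.items():
            write_pdb(traj.topology, out / f"cluster_{k}.pdb",
                      coords=traj.coords[frame_idx],
                      header_remarks=[f"representative frame {frame_idx} of "
                                      f"cluster {k}"])
        summary["chosen_k"] = ks.chosen_k
        summary["representatives"] = reps
        tick("landscape")

        # --------------------------------------------------- landscape
        grid = free_energy_landscape(
            features.df["angle_a_deg"].to_numpy(),
            features.df["angle_b_deg"].to_numpy(),
            n_bins=params.landscape_bins,
            temperature=params.temperature,
        )
        _write_csv(grid.to_frame(), out / "landscape.csv",
                   {**meta, "temperature_K": params.temperature,
                    "cap_kT": f"{grid.cap_kt:.4f}",
                    "min_center": f"{grid.min_center[0]:.3f},"
                                  f"{grid.min_center[1]:.3f}"})
        write_pdb(traj.topology, out / "landscape_min.pdb",
                  coords=traj.coords[grid.min_frame],
                  header_remarks=[f"frame {grid.min_frame} nearest the "
                                  "free-energy minimum"])
        summary["landscape_min_angle_a_deg"] = grid.min_center[0]
        summary["landscape_min_angle_b_deg"] = grid.min_center[1]
        summary["landscape_min_frame"] = grid.min_frame
        tick("done")
    except PipelineError:
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary
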