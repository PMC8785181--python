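"""Readers and writers for the plain-text interchange formats.

Scan tables are two-column angle/energy files (whitespace or comma
separated, '#' comments — XVG-style files read fine).  Vector trajectories
travel as CSV (traj, frame, x, y, z) with a JSON sidecar holding dt and the
label.  Decays are CSV (bin_start_ns, counts) with a JSON header carrying
the repetition period; FLIM stacks use NumPy's .npz container with keys
``counts`` (ny, nx, n_bins) and ``period_ns``.  Fitted torsional parameters
round-trip through a small JSON schema, and a GROMACS-style topology
fragment writer emits the dihedral lines in kJ/mol (conversion factor
4.184).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .phasor import DecayHistogram, DecayStack
from .torsion import KCAL_TO_KJ, CosineSeries, TorsionalProfile
from .trajectory import VectorTrajectory

__all__ = [
    "read_scan_table", "write_scan_table",
    "read_vector_trajectory", "write_vector_trajectory",
    "read_decay", "write_decay",
    "read_decay_stack", "write_decay_stack",
    "read_cosine_series", "write_cosine_series",
    "write_topology_fragment",
]


def read_scan_table(path) -> TorsionalProfile:
    df = pd.read_csv(path, sep=r"[,\s]+", comment="#", header=None,
                     engine="python", skip_blank_lines=True)
    if df.shape[1] < 2:
        raise ValueError("scan table needs two columns (angle_deg, energy)")
    order = np.argsort(df.iloc[:, 0].to_numpy(float))
    return TorsionalProfile.from_raw(df.iloc[order, 0].to_numpy(float),
                                     df.iloc[order, 1].to_numpy(float))


def write_scan_table(profile: TorsionalProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("# angle_deg  energy_kcal_per_mol\n")
        for a, e in zip(profile.angles, profile.energies):
            fh.write(f"{a:.6f} {e:.10f}\n")


def write_vector_trajectory(traj: VectorTrajectory, csv_path) -> None:
    csv_path = Path(csv_path)
    nt, nf, _ = traj.vectors.shape
    idx = np.indices((nt, nf)).reshape(2, -1)
    df = pd.DataFrame({"traj": idx[0], "frame": idx[1]})
    df[["x", "y", "z"]] = traj.vectors.reshape(-1, 3)
    df.to_csv(csv_path, index=False)
    meta = {"dt_ps": traj.dt, "label": traj.label, "n_traj": nt,
            "n_frames": nf}
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_vector_trajectory(csv_path) -> VectorTrajectory:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    v = df[["x", "y", "z"]].to_numpy(float).reshape(
        meta["n_traj"], meta["n_frames"], 3)
    return VectorTrajectory(vectors=v, dt=meta["dt_ps"],
                            label=meta.get("label", ""))


def write_decay(decay: DecayHistogram, csv_path) -> None:
    csv_path = Path(csv_path)
    starts = np.arange(decay.n_bins) * decay.bin_width
    pd.DataFrame({"bin_start_ns": starts, "counts": decay.counts}
                 ).to_csv(csv_path, index=False)
    csv_path.with_suffix(".json").write_text(json.dumps(
        {"period_ns": decay.period, "n_bins": decay.n_bins}, indent=1))


def read_decay(csv_path) -> DecayHistogram:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    return DecayHistogram(counts=df["counts"].to_numpy(np.int64),
                          period=meta["period_ns"])


def write_decay_stack(stack: DecayStack, path) -> None:
    np.savez(path, counts=stack.counts, period_ns=stack.period)


def read_decay_stack(path) -> DecayStack:
    with np.load(path) as data:
        return DecayStack(counts=data["counts"],
                          period=float(data["period_ns"]))


def write_cosine_series(series_map: dict, path) -> None:
    """JSON schema: {name: {"terms": [[k_kcal, n, gamma_deg], ...],
    "offset_kcal": o}}."""
    doc = {name: {"terms": [list(t) for t in s.terms],
                  "offset_kcal": s.offset}
           for name, s in series_map.items()}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_cosine_series(path) -> dict:
    doc = json.loads(Path(path).read_text())
    return {name: CosineSeries(terms=tuple(tuple(t) for t in d["terms"]),
                               offset=d.get("offset_kcal", 0.0))
            for name, d in doc.items()}


def write_topology_fragment(series_map: dict, path,
                            atoms: dict | None = None) -> None:
    """GROMACS-style ``[ dihedrals ]`` fragment (funct 9, proper dihedrals):
    one line per cosine term with the phase in degrees and the force
    constant converted to kJ/mol (x 4.184).  ``atoms`` optionally maps each
    dihedral name to its four atom indices."""
    lines = ["; generated by rotorprobe: k(1 + cos(n phi - gamma)) "
             "convention, kcal/mol converted to kJ/mol (x 4.184)",
             "[ dihedrals ]",
             ";  ai    aj    ak    al  funct   phase   k (kJ/mol)   mult"]
    for name, series in series_map.items():
        ai = atoms.get(name, (1, 2, 3, 4)) if atoms else (1, 2, 3, 4)
        lines.append(f"; {name}")
        for k, n, g in series.terms:
            lines.append("  ".join(f"{a:>4d}" for a in ai)
                         + f"    9  {g:8.2f}  {k * KCAL_TO_KJ:12.6f}  {n:4d}")
    Path(path).write_text("\n".join(lines) + "\n")
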