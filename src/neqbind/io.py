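"""Readers and writers for the pipeline's text formats.

Work series come as two-column whitespace-separated files in the xvg
dialect (``#``/``@`` comment lines tolerated), one file per transition,
listed in a CSV manifest.  Trajectories are accepted as whitespace XYZ
frames or long-format CSV with a sidecar mass table.  Established
binary trajectory readers (mdtraj / MDAnalysis) can be used upstream to
produce these text forms; binary formats are deliberately out of scope
here.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .entropy import GeometrySeries, TrajectoryEnsemble
from .work import DhdlSeries

__all__ = [
    "read_xvg",
    "write_xvg",
    "read_dhdl_file",
    "read_work_manifest",
    "read_xyz_trajectory",
    "read_csv_trajectory",
    "read_masses",
    "read_geometry_series",
    "write_geometry_series",
]

MANIFEST_COLUMNS = ["host", "guest", "forcefield", "pose", "repeat", "direction", "path"]


def read_xvg(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column xvg-style file, skipping '#'/'@' lines."""
    xs, ys = [], []
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith(("#", "@")):
            continue
        fields = s.split()
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        try:
            xs.append(float(fields[0]))
            ys.append(float(fields[1]))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric value") from None
    x, y = np.array(xs), np.array(ys)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError(f"{path}: non-finite value in series")
    return x, y


def write_xvg(path: str | Path, x: np.ndarray, y: np.ndarray, comment: str = "") -> None:
    lines = []
    if comment:
        lines.extend(f"# {c}" for c in comment.splitlines())
    lines.extend(f"{a:.10g} {b:.10g}" for a, b in zip(x, y))
    Path(path).write_text("\n".join(lines) + "\n")


def read_dhdl_file(path: str | Path, direction: str = "forward") -> DhdlSeries:
    """Read a per-transition dH/dlambda file into a series.

    The first column is lambda along the transition's own path (0->1
    forward, 1->0 reverse); the second is dH/dlambda in kJ/mol.
    """
    lam, dhdl = read_xvg(path)
    try:
        return DhdlSeries(lambda_values=lam, dhdl_values=dhdl, direction=direction)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def read_work_manifest(path: str | Path) -> pd.DataFrame:
    """Read a transition manifest CSV.

    Required columns: direction, pose, repeat, path; optional grouping
    columns host, guest, forcefield (defaulted when absent).  Relative
    paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("direction", "pose", "repeat", "path"):
        if col not in df.columns:
            raise ValueError(f"{path}: manifest is missing column {col!r}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty manifest")
    for col, default in (("host", "host"), ("guest", "guest"), ("forcefield", "ff")):
        if col not in df.columns:
            df[col] = default
    bad = set(df["direction"].unique()) - {"forward", "reverse"}
    if bad:
        raise ValueError(f"{path}: unknown direction value(s) {sorted(bad)}")
    df["path"] = [
        str((path.parent / p).resolve()) if not Path(p).is_absolute() else p
        for p in df["path"]
    ]
    missing = [p for p in df["path"] if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing file(s): {missing[:3]}")
    return df[MANIFEST_COLUMNS]


def read_xyz_trajectory(
    path: str | Path, masses: np.ndarray, label: str = ""
) -> TrajectoryEnsemble:
    """Read a multi-frame XYZ-style file (nm coordinates).

    Each frame: an atom-count line, a comment line, then one
    ``name x y z`` line per atom.
    """
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: truncated frame at line {i + 1}")
        coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in block], dtype=float
        )
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return TrajectoryEnsemble(
        coordinates=np.stack(frames), masses=np.asarray(masses, float), label=label
    )


def read_csv_trajectory(
    path: str | Path, masses: np.ndarray, label: str = ""
) -> TrajectoryEnsemble:
    """Read a long-format trajectory CSV with columns frame, atom, x, y, z."""
    df = pd.read_csv(path)
    for col in ("frame", "atom", "x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df = df.sort_values(["frame", "atom"])
    n_atoms = df["atom"].nunique()
    n_frames = df["frame"].nunique()
    if len(df) != n_atoms * n_frames:
        raise ValueError(f"{path}: ragged trajectory (frames differ in atom count)")
    coords = df[["x", "y", "z"]].to_numpy().reshape(n_frames, n_atoms, 3)
    return TrajectoryEnsemble(
        coordinates=coords, masses=np.asarray(masses, float), label=label
    )


def read_masses(path: str | Path) -> np.ndarray:
    """Read a per-atom mass sidecar CSV with columns atom, mass_amu."""
    df = pd.read_csv(path)
    for col in ("atom", "mass_amu"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df.sort_values("atom")["mass_amu"].to_numpy(dtype=float)


def read_geometry_series(path: str | Path) -> GeometrySeries:
    """Read a geometry trace CSV with columns frame, com_distance_nm,
    orientation_cos."""
    df = pd.read_csv(path).sort_values("frame")
    for col in ("com_distance_nm", "orientation_cos"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return GeometrySeries(
        com_distance=df["com_distance_nm"].to_numpy(float),
        orientation_cos=df["orientation_cos"].to_numpy(float),
    )


def write_geometry_series(path: str | Path, series: GeometrySeries) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(series.n_frames),
            "com_distance_nm": series.com_distance,
            "orientation_cos": series.orientation_cos,
        }
    ).to_csv(path, index=False)
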