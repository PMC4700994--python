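"""Plain-text file formats and run configuration.

Trajectories are tab-separated columns (replica, step, time, ion, species,
x, y, z) under ``#``-prefixed header lines carrying the format version,
seed and a digest of the resolved configuration.  PMF grids are dense
row-major text matrices with ``NA`` for masked cells.  Everything round
trips at 9 significant digits; desk-scale data volumes make text the right
trade (diffable, versionable) over binary containers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .dynamics import Trajectory
from .wham import PMFGrid

__all__ = [
    "FORMAT_VERSION",
    "write_trajectory",
    "read_trajectory",
    "write_pmf_grid",
    "read_pmf_grid",
    "load_config",
    "dump_config",
    "config_digest",
    "TrajectoryParseError",
]

FORMAT_VERSION = "1"
_COLUMNS = ["replica", "step", "time", "ion", "species", "x", "y", "z"]


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; message names the offending line."""


def config_digest(config: dict[str, Any]) -> str:
    """Stable short digest of a resolved configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_trajectory(
    trajectories: Sequence[Trajectory],
    path: str | Path,
    header: dict[str, Any] | None = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# format_version\t{FORMAT_VERSION}\n")
        for key, val in (header or {}).items():
            fh.write(f"# {key}\t{val}\n")
        fh.write("# " + "\t".join(_COLUMNS) + "\n")
        for traj in trajectories:
            steps = (
                traj.step_index
                if traj.step_index is not None
                else np.zeros(traj.times.size, dtype=int)
            )
            for t in range(traj.times.size):
                for ion in range(traj.n_ions):
                    x, y, z = traj.positions[t, ion]
                    fh.write(
                        f"{traj.replica}\t{int(steps[t])}\t{traj.times[t]:.9g}\t"
                        f"{ion}\t{traj.species[ion]}\t{x:.9g}\t{y:.9g}\t{z:.9g}\n"
                    )


def read_trajectory(path: str | Path, strict: bool = True) -> list[Trajectory]:
    """Parse a trajectory file back into per-replica :class:`Trajectory`.

    ``strict`` rejects rows with extra columns; the lenient mode ignores
    trailing columns (foreign dialects) with the standard eight intact.
    """
    path = Path(path)
    rows: list[tuple] = []
    saw_header = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                saw_header = True
                continue
            parts = line.split("\t")
            if len(parts) < 8 or (strict and len(parts) != 8):
                raise TrajectoryParseError(
                    f"{path}:{lineno}: expected 8 tab-separated columns, got {len(parts)}"
                )
            try:
                rows.append(
                    (
                        int(parts[0]),
                        int(parts[1]),
                        float(parts[2]),
                        int(parts[3]),
                        parts[4],
                        float(parts[5]),
                        float(parts[6]),
                        float(parts[7]),
                    )
                )
            except ValueError as exc:
                raise TrajectoryParseError(f"{path}:{lineno}: {exc}") from None
    if not saw_header:
        raise TrajectoryParseError(f"{path}: missing '#' header lines")
    if not rows:
        raise TrajectoryParseError(f"{path}: no data records")

    out = []
    replicas = sorted({r[0] for r in rows})
    for rep in replicas:
        rep_rows = [r for r in rows if r[0] == rep]
        ions = sorted({r[3] for r in rep_rows})
        times = sorted({r[2] for r in rep_rows})
        t_index = {t: i for i, t in enumerate(times)}
        pos = np.full((len(times), len(ions), 3), np.nan)
        steps = np.zeros(len(times), dtype=int)
        species = [""] * len(ions)
        for _, step, t, ion, sp, x, y, z in rep_rows:
            ti = t_index[t]
            pos[ti, ion] = (x, y, z)
            steps[ti] = step
            species[ion] = sp
        if np.isnan(pos).any():
            raise TrajectoryParseError(
                f"{path}: replica {rep} has missing ion records"
            )
        out.append(
            Trajectory(
                times=np.array(times),
                positions=pos,
                species=tuple(species),
                step_index=steps,
                replica=rep,
            )
        )
    return out


def write_pmf_grid(grid: PMFGrid, path: str | Path, header: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# format_version\t{FORMAT_VERSION}\n")
        fh.write(f"# dimension\t{grid.ndim}\n")
        for ax, e in enumerate(grid.edges):
            fh.write(
                f"# axis{ax}\tmin={e[0]:.9g}\tmax={e[-1]:.9g}\tbin={e[1] - e[0]:.9g}\n"
            )
        fh.write(f"# temperature\t{grid.temperature:.9g}\n")
        fh.write(f"# converged\t{grid.converged}\n")
        fh.write(f"# iterations\t{grid.iterations}\n")
        fh.write(f"# residual\t{grid.residual:.9g}\n")
        fh.write("# offset_convention\tmin_unmasked=0\n")
        for key, val in (header or {}).items():
            fh.write(f"# {key}\t{val}\n")
        vals = np.atleast_2d(grid.values.filled(np.nan))
        for row in vals:
            fh.write(
                "\t".join("NA" if not np.isfinite(v) else f"{v:.9g}" for v in row)
                + "\n"
            )


def read_pmf_grid(path: str | Path) -> PMFGrid:
    path = Path(path)
    meta: dict[str, str] = {}
    axes: dict[int, tuple[float, float, float]] = {}
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if parts[0].startswith("axis"):
                    ax = int(parts[0][4:])
                    kv = dict(p.split("=") for p in parts[1:])
                    axes[ax] = (float(kv["min"]), float(kv["max"]), float(kv["bin"]))
                elif len(parts) >= 2:
                    meta[parts[0]] = parts[1]
            elif line:
                rows.append(
                    [np.nan if p == "NA" else float(p) for p in line.split("\t")]
                )
    vals = np.array(rows)
    ndim = int(meta.get("dimension", "2"))
    edges = []
    for ax in sorted(axes):
        lo, hi, bw = axes[ax]
        edges.append(np.arange(lo, hi + 0.5 * bw, bw))
    if ndim == 1:
        vals = vals.ravel()
    expected = tuple(len(e) - 1 for e in edges)
    if vals.shape != expected:
        raise ValueError(
            f"{path}: matrix shape {vals.shape} does not match axis specs {expected}"
        )
    masked = np.ma.masked_invalid(vals)
    return PMFGrid(
        edges=tuple(edges),
        values=masked,
        temperature=float(meta.get("temperature", 300.0)),
        converged=meta.get("converged", "True") == "True",
        iterations=int(meta.get("iterations", 0)),
        residual=float(meta.get("residual", 0.0)),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KNOWN_SECTIONS = {
    "landscape", "sim", "pull", "umbrella", "analysis", "seed", "output", "digest",
}

_DEFAULTS: dict[str, dict[str, Any]] = {
    "sim": {
        "temperature": 300.0,
        "diffusion": 0.2,
        "timestep": 0.01,
        "recording_interval": 0.1,
        "noise_enabled": True,
    },
    "umbrella": {
        "spacing": 0.5,
        "k_umb": 10.0,
        "bin_width": 0.5,
        "tol": 1e-7,
        "max_iter": 100000,
        "n_frames": 20000,
    },
    "analysis": {
        "delta_diag": 1.0,
        "theta_occ": 0.2,
        "bin_width": 0.5,
    },
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML run configuration, rejecting unknown top-level sections
    and materializing all defaults into the returned mapping."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    cfg: dict[str, Any] = {}
    for section, defaults in _DEFAULTS.items():
        merged = dict(defaults)
        merged.update(raw.get(section) or {})
        cfg[section] = merged
    for section in _KNOWN_SECTIONS - set(_DEFAULTS) - {"digest"}:
        if section in raw:
            cfg[section] = raw[section]
    cfg.setdefault("seed", 0)
    cfg["digest"] = config_digest({k: v for k, v in cfg.items() if k != "digest"})
    return cfg


def dump_config(cfg: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
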