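"""File formats: medium/geometry YAML configs, transient CSV files with
metadata sidecars, and HDF5 persistence of Monte Carlo results."""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import yaml

from .media import DetectionGeometry, OpticalLayer, TimeGrid, Transient, TwoLayerMedium
from .mc_simulator import MCResult

__all__ = [
    "load_medium",
    "save_medium",
    "write_transient",
    "read_transient",
    "save_mc_result",
    "load_mc_result",
]


def load_medium(path) -> TwoLayerMedium:
    """Read a two-layer medium from YAML/JSON.

    Expected keys: ``layers`` (list of {mua, musp, n, thickness_cm}; the
    bottom layer may omit thickness_cm or use .inf) and ``ambient_n``.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    layers = cfg["layers"]
    if len(layers) != 2:
        raise ValueError(f"expected exactly 2 layers, got {len(layers)}")

    def mk(entry, default_thickness=math.inf):
        return OpticalLayer(
            mua=float(entry["mua"]),
            musp=float(entry["musp"]),
            n=float(entry.get("n", 1.4)),
            thickness=float(entry.get("thickness_cm", default_thickness)),
        )

    return TwoLayerMedium(
        top=mk(layers[0]),
        bottom=mk(layers[1]),
        n_ambient=float(cfg.get("ambient_n", 1.0)),
    )


def save_medium(medium: TwoLayerMedium, path) -> None:
    cfg = {
        "layers": [
            {
                "mua": medium.top.mua,
                "musp": medium.top.musp,
                "n": medium.top.n,
                "thickness_cm": medium.top.thickness,
            },
            {"mua": medium.bottom.mua, "musp": medium.bottom.musp, "n": medium.bottom.n},
        ],
        "ambient_n": medium.n_ambient,
    }
    Path(path).write_text(yaml.safe_dump(cfg))


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_transient(transient: Transient, path, integration_time: float | None = None) -> None:
    """Write ``time_ns,value`` CSV plus a metadata sidecar."""
    path = Path(path)
    data = np.column_stack([transient.t, transient.values])
    header = "time_ns,value"
    np.savetxt(path, data, delimiter=",", header=header, comments="")
    meta = {
        "kind": transient.kind,
        "t_start_ns": transient.grid.t_start,
        "t_end_ns": transient.grid.t_end,
        "n_bins": transient.grid.n_bins,
    }
    if transient.geometry is not None:
        meta["rho_cm"] = transient.geometry.rho
        meta["wavelength_nm"] = transient.geometry.wavelength
    if integration_time is not None:
        meta["integration_time_s"] = integration_time
    _sidecar(path).write_text(yaml.safe_dump(meta))


def read_transient(path) -> Transient:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    meta = {}
    if _sidecar(path).exists():
        meta = yaml.safe_load(_sidecar(path).read_text()) or {}
    t = data[:, 0]
    values = data[:, 1]
    dt = float(np.median(np.diff(t)))
    grid = TimeGrid(
        float(meta.get("t_start_ns", t[0] - dt / 2)),
        float(meta.get("t_end_ns", t[-1] + dt / 2)),
        int(meta.get("n_bins", len(t))),
    )
    geometry = None
    if "rho_cm" in meta:
        geometry = DetectionGeometry(
            rho=float(meta["rho_cm"]), wavelength=float(meta.get("wavelength_nm", 800.0))
        )
    return Transient(grid, values, meta.get("kind", "model_density"), geometry)


def save_mc_result(result: MCResult, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("dtof", data=result.dtof)
        f.create_dataset("dtof_sq", data=result.dtof_sq)
        f.create_dataset("hits", data=result.hits)
        f.create_dataset("pathlen_sums", data=result.pathlen_sums)
        f.attrs["t_start"] = result.grid.t_start
        f.attrs["t_end"] = result.grid.t_end
        f.attrs["n_bins"] = result.grid.n_bins
        f.attrs["n_launched"] = result.n_launched
        f.attrs["seed"] = result.seed
        f.attrs["annulus"] = result.annulus
        for k, v in result.totals.items():
            f.attrs[f"total_{k}"] = v


def load_mc_result(path) -> MCResult:
    import h5py

    with h5py.File(path, "r") as f:
        grid = TimeGrid(float(f.attrs["t_start"]), float(f.attrs["t_end"]), int(f.attrs["n_bins"]))
        totals = {
            k[len("total_"):]: float(v) for k, v in f.attrs.items() if k.startswith("total_")
        }
        return MCResult(
            grid=grid,
            dtof=f["dtof"][:],
            dtof_sq=f["dtof_sq"][:],
            hits=f["hits"][:],
            pathlen_sums=f["pathlen_sums"][:],
            n_launched=int(f.attrs["n_launched"]),
            seed=int(f.attrs["seed"]),
            totals=totals,
            annulus=tuple(f.attrs["annulus"]),
        )
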