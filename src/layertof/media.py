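"""Domain containers for layered turbid media and time-resolved reflectance.

Units used throughout the package: lengths in cm, absorption and reduced
scattering coefficients in cm^-1, time in ns, wavelengths in nm.  The vacuum
speed of light is ``C_CM_PER_NS``; the energy speed inside a layer of
refractive index ``n`` is ``C_CM_PER_NS / n``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "C_CM_PER_NS",
    "OpticalLayer",
    "TwoLayerMedium",
    "DetectionGeometry",
    "TimeGrid",
    "Transient",
]

#: vacuum speed of light, cm/ns
C_CM_PER_NS = 29.9792458


@dataclass(frozen=True)
class OpticalLayer:
    """One homogeneous layer of a diffusive medium.

    Parameters
    ----------
    mua : float
        Absorption coefficient, cm^-1 (>= 0).
    musp : float
        Reduced scattering coefficient, cm^-1 (> 0).
    n : float
        Refractive index (>= 1).
    thickness : float
        Layer thickness, cm (> 0; ``math.inf`` for a semi-infinite layer).
    """

    mua: float
    musp: float
    n: float = 1.4
    thickness: float = math.inf

    def __post_init__(self) -> None:
        if not (self.mua >= 0):
            raise ValueError(f"mua must be >= 0, got {self.mua}")
        if not (self.musp > 0):
            raise ValueError(f"musp must be > 0, got {self.musp}")
        if not (self.n >= 1):
            raise ValueError(f"refractive index must be >= 1, got {self.n}")
        if not (self.thickness > 0):
            raise ValueError(f"thickness must be > 0, got {self.thickness}")
        if self.mua > self.musp:
            warnings.warn(
                f"mua={self.mua} exceeds musp={self.musp}: the diffusion "
                "approximation is not valid for this layer",
                stacklevel=3,
            )

    @property
    def v(self) -> float:
        """Energy speed of light in the layer, cm/ns."""
        return C_CM_PER_NS / self.n

    def with_mua(self, mua: float) -> "OpticalLayer":
        """Copy of the layer with a different absorption coefficient."""
        return replace(self, mua=mua)


@dataclass(frozen=True)
class TwoLayerMedium:
    """A finite top layer over a semi-infinite bottom layer.

    In the transabdominal-oximetry setting the top layer is the maternal
    tissue (thickness known, e.g. from ultrasound) and the bottom layer the
    fetal tissue whose absorption is the quantity of interest.
    """

    top: OpticalLayer
    bottom: OpticalLayer
    n_ambient: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.top.thickness):
            raise ValueError("top layer must have finite thickness")
        if math.isfinite(self.bottom.thickness):
            raise ValueError("bottom layer must be semi-infinite")
        if not (self.n_ambient >= 1):
            raise ValueError("ambient refractive index must be >= 1")

    @property
    def layers(self) -> tuple[OpticalLayer, OpticalLayer]:
        return (self.top, self.bottom)

    def with_muas(self, mua_top: float, mua_bottom: float) -> "TwoLayerMedium":
        return replace(
            self, top=self.top.with_mua(mua_top), bottom=self.bottom.with_mua(mua_bottom)
        )


@dataclass(frozen=True)
class DetectionGeometry:
    """Source-detector separation and probing wavelength."""

    rho: float
    wavelength: float = 800.0

    def __post_init__(self) -> None:
        if not (self.rho > 0):
            raise ValueError(f"source-detector separation must be > 0, got {self.rho}")
        if not (600.0 <= self.wavelength <= 1000.0):
            raise ValueError(
                "wavelength must lie in [600, 1000] nm (extinction-table "
                f"coverage), got {self.wavelength}"
            )


@dataclass(frozen=True)
class TimeGrid:
    """Uniform arrival-time axis, ns."""

    t_start: float
    t_end: float
    n_bins: int

    def __post_init__(self) -> None:
        if not (0 <= self.t_start < self.t_end):
            raise ValueError("need 0 <= t_start < t_end")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")

    @property
    def dt(self) -> float:
        return (self.t_end - self.t_start) / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.t_start, self.t_end, self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.edges[:-1] + 0.5 * self.dt


@dataclass(frozen=True)
class Transient:
    """Time-binned diffuse reflectance at one wavelength and one separation.

    ``kind`` distinguishes a model photon density (photons cm^-2 ns^-1,
    arbitrary amplitude) from measured integer counts.
    """

    grid: TimeGrid
    values: np.ndarray
    kind: str = "model_density"  # or "counts"
    geometry: DetectionGeometry | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.grid.n_bins,):
            raise ValueError(
                f"values shape {values.shape} does not match grid with "
                f"{self.grid.n_bins} bins"
            )
        if np.any(values < 0):
            raise ValueError("transient values must be nonnegative")
        if self.kind not in ("model_density", "counts"):
            raise ValueError(f"unknown transient kind {self.kind!r}")
        if self.kind == "counts" and not np.allclose(values, np.round(values)):
            raise ValueError("counts-kind transient must hold integers")
        object.__setattr__(self, "values", values)

    @property
    def t(self) -> np.ndarray:
        return self.grid.centers

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def scaled(self, factor: float) -> "Transient":
        return Transient(self.grid, self.values * factor, "model_density", self.geometry)
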