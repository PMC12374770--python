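"""Hemoglobin spectroscopy: absorption synthesis, two-wavelength unmixing,
and tissue-oxygenation-index (TOI) time series.

The tissue oxygenation index is ``TOI = 100 * [HbO2] / ([HbO2] + [Hb])``.
Absorption mixes linearly in the chromophore concentrations (modified
Beer-Lambert, decadic extinction table with an explicit ln(10) factor):

    mua(lambda) = ln(10) * (eps_HbO2(lambda) c_HbO2 + eps_Hb(lambda) c_Hb)
                  + background(lambda)

Inverting the 2x2 system at two wavelengths straddling the ~800 nm
isosbestic point yields the relative concentrations and hence the TOI.
Negative unmixed concentrations are retained and flagged (clipping would
silently bias the TOI); the TOI is reported as NaN in that case.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExtinctionTable",
    "HemodynamicState",
    "UnmixResult",
    "load_default_extinction_table",
    "mua_from_state",
    "unmix_two_wavelengths",
    "toi_timeseries",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class ExtinctionTable:
    """Tabulated molar extinction coefficients of HbO2 and Hb.

    ``convention`` records whether the coefficients are decadic (base-10
    Beer-Lambert, the common tabulation) or natural-log based.  All lookups
    interpolate linearly between rows.
    """

    wavelengths: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray
    convention: str = "decadic"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        eo = np.asarray(self.eps_hbo2, dtype=float)
        eh = np.asarray(self.eps_hb, dtype=float)
        if wl.ndim != 1 or len(wl) < 2 or wl.shape != eo.shape or wl.shape != eh.shape:
            raise ValueError("table columns must be 1-D and of equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(eo <= 0) or np.any(eh <= 0):
            raise ValueError("extinction coefficients must be positive")
        if self.convention not in ("decadic", "natural"):
            raise ValueError(f"unknown convention {self.convention!r}")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "eps_hbo2", eo)
        object.__setattr__(self, "eps_hb", eh)

    @property
    def ln_factor(self) -> float:
        """Factor converting decadic extinction to a natural-log mua."""
        return LN10 if self.convention == "decadic" else 1.0

    def _interp(self, wavelength: float, values: np.ndarray) -> float:
        if not (self.wavelengths[0] <= wavelength <= self.wavelengths[-1]):
            raise ValueError(
                f"wavelength {wavelength} nm outside table range "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}] nm"
            )
        return float(np.interp(wavelength, self.wavelengths, values))

    def eps(self, wavelength: float) -> tuple[float, float]:
        """(eps_HbO2, eps_Hb) at ``wavelength`` by linear interpolation."""
        return (
            self._interp(wavelength, self.eps_hbo2),
            self._interp(wavelength, self.eps_hb),
        )

    def isosbestic_wavelength(self, lo: float = 780.0, hi: float = 820.0) -> float:
        """Wavelength in [lo, hi] where eps_HbO2 - eps_Hb changes sign."""
        wl = np.linspace(lo, hi, 801)
        diff = np.array([self._interp(w, self.eps_hbo2) - self._interp(w, self.eps_hb) for w in wl])
        sign_changes = np.where(np.diff(np.sign(diff)) != 0)[0]
        if len(sign_changes) != 1:
            raise ValueError(
                f"expected exactly one isosbestic crossing in [{lo}, {hi}] nm, "
                f"found {len(sign_changes)}"
            )
        i = sign_changes[0]
        # linear root between grid points
        w0, w1, d0, d1 = wl[i], wl[i + 1], diff[i], diff[i + 1]
        return float(w0 - d0 * (w1 - w0) / (d1 - d0))


def load_default_extinction_table() -> ExtinctionTable:
    """Load the bundled synthetic extinction compilation (600-1000 nm)."""
    ref = importlib.resources.files("layertof.data") / "hb_extinction_synthetic.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#", names=["wavelength_nm", "eps_hbo2", "eps_hb"])
    table = ExtinctionTable(
        df["wavelength_nm"].to_numpy(),
        df["eps_hbo2"].to_numpy(),
        df["eps_hb"].to_numpy(),
        convention="decadic",
    )
    table.isosbestic_wavelength()  # validates the single crossing near 800 nm
    return table


@dataclass(frozen=True)
class HemodynamicState:
    """Relative HbO2/Hb concentrations (mol/L or arbitrary units) plus an
    optional non-hemoglobin background absorption per wavelength (cm^-1)."""

    c_hbo2: float
    c_hb: float
    background: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.c_hbo2 < 0 or self.c_hb < 0:
            raise ValueError("concentrations must be nonnegative")

    @property
    def total(self) -> float:
        return self.c_hbo2 + self.c_hb

    @property
    def toi(self) -> float:
        """Tissue oxygenation index, percent."""
        if self.total == 0:
            return float("nan")
        return 100.0 * self.c_hbo2 / self.total

    @classmethod
    def from_toi(cls, toi_pct: float, total: float, **kw) -> "HemodynamicState":
        if not (0.0 <= toi_pct <= 100.0):
            raise ValueError("TOI must lie in [0, 100] %")
        return cls(c_hbo2=total * toi_pct / 100.0, c_hb=total * (1.0 - toi_pct / 100.0), **kw)


@dataclass(frozen=True)
class UnmixResult:
    """Solved concentrations from two-wavelength unmixing.

    Negative concentrations are physically impossible and indicate noise or
    model mismatch; they are kept in the record with ``valid=False`` and the
    TOI set to NaN rather than clipped.
    """

    c_hbo2: float
    c_hb: float

    @property
    def valid(self) -> bool:
        return self.c_hbo2 >= 0 and self.c_hb >= 0 and (self.c_hbo2 + self.c_hb) > 0

    @property
    def toi(self) -> float:
        if not self.valid:
            return float("nan")
        return 100.0 * self.c_hbo2 / (self.c_hbo2 + self.c_hb)


def mua_from_state(
    state: HemodynamicState, table: ExtinctionTable, wavelength: float
) -> float:
    """Absorption coefficient (cm^-1) of a hemodynamic state at ``wavelength``."""
    eo, eh = table.eps(wavelength)
    bg = state.background.get(wavelength, 0.0)
    return table.ln_factor * (eo * state.c_hbo2 + eh * state.c_hb) + bg


def unmix_two_wavelengths(
    mua_a: float,
    mua_b: float,
    table: ExtinctionTable,
    wavelengths: tuple[float, float] = (740.0, 850.0),
) -> UnmixResult:
    """Solve the 2x2 Beer-Lambert system for (c_HbO2, c_Hb).

    ``mua_a``/``mua_b`` are the absorption coefficients at
    ``wavelengths[0]``/``wavelengths[1]``.  The matrix is nonsingular when
    the two wavelengths straddle the isosbestic point.
    """
    e = np.array([table.eps(w) for w in wavelengths])  # rows: [eps_hbo2, eps_hb]
    m = table.ln_factor * np.column_stack([e[:, 0], e[:, 1]])
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"extinction matrix at {wavelengths} nm is singular (cond={cond:.2e})"
        )
    c = np.linalg.solve(m, np.array([mua_a, mua_b], dtype=float))
    # snap solver rounding residue to zero; genuine negatives stay flagged
    floor = -1e-9 * max(np.abs(c).max(), 1e-300)
    c[(c < 0) & (c >= floor)] = 0.0
    return UnmixResult(c_hbo2=float(c[0]), c_hb=float(c[1]))


def toi_timeseries(
    frames,
    table: ExtinctionTable | None = None,
    wavelengths: tuple[float, float] = (740.0, 850.0),
    param: str = "mua2",
) -> pd.DataFrame:
    """Convert a per-frame, per-wavelength fit stream into a TOI series.

    Parameters
    ----------
    frames : iterable of (timestamp, wavelength, FitResult)
        One fit per wavelength per timestamp; frames are paired across
        wavelengths by exact timestamp.
    table : extinction table (bundled default if None).
    param : which fitted coefficient carries the chromophore signal
        (default the deep-layer absorption ``"mua2"``).

    Returns
    -------
    DataFrame with columns ``time_s, c_hbo2, c_hb, toi_pct`` (NaN rows where
    either fit failed to converge or the unmixing went negative).
    """
    if table is None:
        table = load_default_extinction_table()
    by_time: dict[float, dict[float, object]] = {}
    for ts, wl, fit in frames:
        by_time.setdefault(ts, {})[wl] = fit
    offenders = {
        ts: sorted(d) for ts, d in by_time.items() if set(d) != set(wavelengths)
    }
    if offenders:
        raise ValueError(
            "frames not paired across wavelengths "
            f"{wavelengths}; offending timestamps: {offenders}"
        )
    rows = []
    for ts in sorted(by_time):
        fit_a, fit_b = (by_time[ts][w] for w in wavelengths)
        if not (fit_a.converged and fit_b.converged):
            rows.append((ts, np.nan, np.nan, np.nan))
            continue
        res = unmix_two_wavelengths(
            fit_a.estimates[param], fit_b.estimates[param], table, wavelengths
        )
        rows.append((ts, res.c_hbo2, res.c_hb, res.toi))
    return pd.DataFrame(rows, columns=["time_s", "c_hbo2", "c_hb", "toi_pct"])
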