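"""Raw TCSPC histogram conditioning: background subtraction, time-zero and
amplitude calibration against a reference medium, cropping and rebinning.

A TCSPC measurement is shifted in time by the (unknown) laser emission time
t0 and scaled by the (unknown) product of source power, integration time,
detection efficiency and fiber throughput.  Both are estimated once per
wavelength by least-squares matching of a measurement on a reference medium
of known optical properties to the corresponding model transient, then
applied to every subsequent frame of the session.  The instrument response
is treated as ideal after the t0 shift (no deconvolution); the pipeline
normalizes against theory instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffusion_forward import semi_infinite_td_reflectance, two_layer_td_reflectance
from .media import DetectionGeometry, OpticalLayer, TimeGrid, Transient, TwoLayerMedium

__all__ = [
    "RawHistogram",
    "InstrumentCalibration",
    "CalibrationError",
    "estimate_calibration",
    "apply_calibration",
    "crop_and_rebin",
    "subtract_background",
]


class CalibrationError(RuntimeError):
    """Raised when a calibration histogram carries no usable peak."""


@dataclass(frozen=True)
class RawHistogram:
    """Raw TCSPC channel histogram.

    ``channel_width`` is in ps; channel ``i`` covers
    ``[i, i+1) * channel_width``.
    """

    channel_width: float
    counts: np.ndarray
    integration_time: float = 1.0
    wavelength: float = 800.0
    rho: float = 2.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if self.channel_width <= 0:
            raise ValueError("channel width must be positive")
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", counts)

    @property
    def times(self) -> np.ndarray:
        """Channel centers, ns."""
        return (np.arange(len(self.counts)) + 0.5) * self.channel_width * 1e-3

    @property
    def grid(self) -> TimeGrid:
        dt = self.channel_width * 1e-3
        return TimeGrid(0.0, dt * len(self.counts), len(self.counts))


@dataclass(frozen=True)
class InstrumentCalibration:
    """Per-wavelength laser time offset (ns) and amplitude factor such that
    ``measured(t) ~= amplitude_factor * model(t - t0)``."""

    t0: float
    amplitude_factor: float
    wavelength: float = 800.0

    def __post_init__(self) -> None:
        if self.amplitude_factor <= 0:
            raise ValueError("amplitude factor must be positive")


def subtract_background(counts: np.ndarray, edge_fraction: float = 0.02) -> np.ndarray:
    """Remove a constant dark/background offset estimated from channels
    strictly before the rising edge (the first channel reaching
    ``edge_fraction`` of the peak), flooring at zero.  Histograms whose
    signal starts within the first few channels are returned unchanged."""
    counts = np.asarray(counts, dtype=float)
    peak = int(np.argmax(counts))
    if counts[peak] <= 0:
        return counts.copy()
    rising = np.nonzero(counts[: peak + 1] >= edge_fraction * counts[peak])[0]
    edge = rising[0] if len(rising) else 0
    if edge < 8:
        return counts.copy()
    level = float(np.median(counts[: edge - 4]))
    return np.maximum(counts - level, 0.0)


def _model_on_channels(
    raw: RawHistogram,
    reference_medium,
    geometry: DetectionGeometry,
) -> np.ndarray:
    grid = raw.grid
    if isinstance(reference_medium, TwoLayerMedium):
        model = two_layer_td_reflectance(reference_medium, geometry, grid)
    elif isinstance(reference_medium, OpticalLayer):
        model = semi_infinite_td_reflectance(reference_medium, 1.0, geometry, grid)
    else:
        raise TypeError("reference medium must be OpticalLayer or TwoLayerMedium")
    return model.values


def estimate_calibration(
    raw: RawHistogram,
    reference_medium,
    geometry: DetectionGeometry,
    max_shift_fraction: float = 0.5,
) -> InstrumentCalibration:
    """Estimate (t0, amplitude) from a measurement on a reference medium.

    Scans integer channel shifts of the model transient against the
    background-subtracted histogram; at each shift the optimal amplitude is
    closed-form, and the best shift is refined to sub-channel resolution by
    parabolic interpolation of the loss.
    """
    y = subtract_background(raw.counts)
    if y.sum() <= 0 or np.count_nonzero(y) < 3 or np.ptp(y) == 0:
        raise CalibrationError("histogram is empty or flat; cannot calibrate")
    m = _model_on_channels(raw, reference_medium, geometry)
    if m.max() <= 0:
        raise CalibrationError("reference model transient is zero on the channel grid")
    n = len(y)
    dt = raw.channel_width * 1e-3
    max_shift = int(max_shift_fraction * n)
    shifts = np.arange(0, max_shift)
    # weighted least squares with Poisson variance; weights from data
    w = 1.0 / np.maximum(y, 1.0)
    losses = np.full(len(shifts), np.inf)
    amps = np.zeros(len(shifts))
    for i, k in enumerate(shifts):
        mk = np.zeros(n)
        mk[k:] = m[: n - k]
        den = float((w * mk * mk).sum())
        if den <= 0:
            continue
        a = float((w * mk * y).sum()) / den
        if a <= 0:
            continue
        r = y - a * mk
        losses[i] = float((w * r * r).sum())
        amps[i] = a
    best = int(np.argmin(losses))
    if not np.isfinite(losses[best]):
        raise CalibrationError("no shift produced a valid model overlap")
    # parabolic refinement of the discrete loss minimum
    t0 = shifts[best] * dt
    if 0 < best < len(shifts) - 1 and np.isfinite(losses[best - 1]) and np.isfinite(losses[best + 1]):
        l0, l1, l2 = losses[best - 1], losses[best], losses[best + 1]
        denom = l0 - 2 * l1 + l2
        if denom > 0:
            t0 += 0.5 * dt * (l0 - l2) / denom
    return InstrumentCalibration(
        t0=float(t0), amplitude_factor=float(amps[best]), wavelength=raw.wavelength
    )


def _rebin_conserving(
    old_edges: np.ndarray, values: np.ndarray, new_edges: np.ndarray
) -> np.ndarray:
    """Redistribute histogram mass onto new edges (overlap-weighted)."""
    cum = np.concatenate([[0.0], np.cumsum(values)])
    cum_at = np.interp(new_edges, old_edges, cum, left=0.0, right=cum[-1])
    return np.diff(cum_at)


def apply_calibration(
    raw: RawHistogram,
    cal: InstrumentCalibration,
    grid: TimeGrid,
) -> Transient:
    """Shift a histogram to time zero, normalize its amplitude and rebin it
    onto ``grid`` (bin-sum preserving).

    The output is a calibrated model-scale transient (no longer integer
    counts).  Parts of ``grid`` outside the shifted data are zero-filled.
    """
    y = subtract_background(raw.counts)
    old_edges = np.arange(len(y) + 1) * raw.channel_width * 1e-3 - cal.t0
    values = _rebin_conserving(old_edges, y, grid.edges)
    return Transient(
        grid,
        values / cal.amplitude_factor,
        "model_density",
        DetectionGeometry(rho=raw.rho, wavelength=raw.wavelength),
    )


def crop_and_rebin(
    transient: Transient, window: tuple[float, float] | None = None, factor: int = 1
) -> Transient:
    """Crop a transient to a time window and merge groups of ``factor`` bins.

    Counts-kind transients are summed within merged bins (count conserving);
    model densities are averaged (density is per-ns).  Trailing bins that do
    not fill a complete group are dropped.
    """
    grid = transient.grid
    values = transient.values
    if window is not None:
        lo, hi = window
        keep = (grid.centers >= lo) & (grid.centers <= hi)
        if not np.any(keep):
            raise ValueError(f"window {window} selects no bins")
        idx = np.nonzero(keep)[0]
        values = values[idx]
        grid = TimeGrid(grid.edges[idx[0]], grid.edges[idx[-1] + 1], len(idx))
    if factor < 1:
        raise ValueError("rebin factor must be >= 1")
    if factor > 1:
        n = (len(values) // factor) * factor
        if n == 0:
            raise ValueError("rebin factor larger than the number of bins")
        chunks = values[:n].reshape(-1, factor)
        values = chunks.sum(axis=1) if transient.kind == "counts" else chunks.mean(axis=1)
        grid = TimeGrid(grid.t_start, grid.t_start + grid.dt * n, n // factor)
    return Transient(grid, values, transient.kind, transient.geometry)


def default_fit_window(
    values: np.ndarray,
    centers: np.ndarray,
    rise_fraction: float = 0.5,
    tail_fraction: float = 1e-3,
) -> tuple[float, float]:
    """Default inversion window: from where the rising edge first reaches
    ``rise_fraction`` of the peak to the last bin above ``tail_fraction`` of
    the peak.

    The early cut avoids bins that are instrument-response dominated in real
    measurements; the tail extends deep (0.1% of peak) because the
    late-arriving photons carry most of the deep-layer information and the
    Poisson-weighted losses down-weight their low counts appropriately.
    """
    peak = values.max()
    if peak <= 0:
        raise ValueError("transient is empty")
    above_half = np.nonzero(values >= rise_fraction * peak)[0]
    above_tail = np.nonzero(values >= tail_fraction * peak)[0]
    return float(centers[above_half[0]]), float(centers[above_tail[-1]])
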