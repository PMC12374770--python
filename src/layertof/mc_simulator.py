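"""Layered time-resolved Monte Carlo photon transport.

MCML-style transport in a stack of plane-parallel layers: implicit-capture
weighting (per interaction the weight is multiplied by the single-scattering
albedo), Henyey-Greenstein scattering, Fresnel reflection/refraction at the
surface and at internal index steps, and Russian-roulette termination.
Photons escaping the top surface into an annular detector are histogrammed
by optical arrival time ``t = sum_i n_i L_i / c``; for every detected photon
the geometric pathlength spent in each layer is accumulated, which enables
Beer-Lambert perturbation re-weighting of the detected distribution of times
of flight (DTOF) for fast pulsatile-signal synthesis.

Randomness is counter-based: each photon derives an independent generator
state from (seed, photon index) via SplitMix64, so results are bit-identical
for a given seed regardless of batching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .media import C_CM_PER_NS, DetectionGeometry, OpticalLayer, TimeGrid, Transient, TwoLayerMedium

__all__ = [
    "MCLayer",
    "MCConfig",
    "MCResult",
    "run_layered_mc",
    "mc_layers_from_medium",
    "perturb_transient",
    "sample_counts",
]


@dataclass(frozen=True)
class MCLayer:
    """One layer for Monte Carlo transport (full scattering description).

    Consistency with the diffusion-level :class:`~layertof.media.OpticalLayer`
    requires ``mus * (1 - g) == musp``.
    """

    mua: float
    mus: float
    g: float
    n: float
    thickness: float

    def __post_init__(self) -> None:
        if self.mua < 0:
            raise ValueError("mua must be >= 0")
        if self.mus <= 0:
            raise ValueError("mus must be > 0")
        if not (-1.0 < self.g < 1.0):
            raise ValueError("anisotropy g must lie in (-1, 1)")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")

    @property
    def musp(self) -> float:
        return self.mus * (1.0 - self.g)

    @classmethod
    def from_optical(cls, layer: OpticalLayer, g: float = 0.9) -> "MCLayer":
        return cls(
            mua=layer.mua,
            mus=layer.musp / (1.0 - g),
            g=g,
            n=layer.n,
            thickness=layer.thickness,
        )


def mc_layers_from_medium(medium: TwoLayerMedium, g: float = 0.9) -> list[MCLayer]:
    """MC layer stack matching a two-layer diffusion medium (mus = musp/(1-g))."""
    return [MCLayer.from_optical(medium.top, g), MCLayer.from_optical(medium.bottom, g)]


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo run configuration.

    The detector is an annulus ``[rho - half_width, rho + half_width]`` on
    the top surface; all exit angles are accepted unless ``na`` (with
    ``n_ambient``) restricts the acceptance cone.
    """

    n_photons: int
    seed: int
    rho: float
    half_width: float = 0.05
    t_max: float = 5.0
    n_bins: int = 200
    n_ambient: float = 1.0
    weight_threshold: float = 1e-4
    survival: float = 0.1
    na: float | None = None

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("need at least one photon")
        if self.half_width <= 0:
            raise ValueError("annulus half-width must be > 0")
        if not (0.0 < self.survival < 1.0):
            raise ValueError("roulette survival probability must be in (0, 1)")
        if self.rho - self.half_width < 0:
            raise ValueError("annulus extends below rho = 0")

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(0.0, self.t_max, self.n_bins)


@dataclass
class MCResult:
    """Detected DTOF with per-layer partial-pathlength sums.

    ``dtof`` is the summed detected photon weight per arrival-time bin (not
    normalized), ``dtof_sq`` the summed squared weights (for standard
    errors), ``hits`` the detected photon count per bin, and
    ``pathlen_sums[i, j]`` the pathlength-weighted detected weight of layer
    ``i`` in bin ``j`` (cm), so ``pathlen_sums[i] / dtof`` is the mean
    partial pathlength of layer ``i`` per bin.
    """

    grid: TimeGrid
    dtof: np.ndarray
    dtof_sq: np.ndarray
    hits: np.ndarray
    pathlen_sums: np.ndarray
    n_launched: int
    seed: int
    totals: dict = field(default_factory=dict)
    annulus: tuple[float, float] = (0.0, 0.0)

    @property
    def empty(self) -> bool:
        """True when no photon reached the detector."""
        return int(self.hits.sum()) == 0

    @property
    def n_detected(self) -> int:
        return int(self.hits.sum())

    def standard_error(self) -> np.ndarray:
        """Per-bin standard error of the summed detected weight."""
        return np.sqrt(np.maximum(self.dtof_sq - self.dtof**2 / max(self.n_launched, 1), 0.0))

    def mean_pathlengths(self) -> np.ndarray:
        """Mean per-layer pathlength per bin, cm (0 where the bin is empty)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.pathlen_sums / self.dtof
        return np.where(self.dtof > 0, out, 0.0)

    def density(self) -> Transient:
        """DTOF as physical reflectance density, photons cm^-2 ns^-1 per
        launched photon."""
        area = np.pi * (self.annulus[1] ** 2 - self.annulus[0] ** 2)
        values = self.dtof / (self.n_launched * area * self.grid.dt)
        return Transient(self.grid, values, "model_density")


# ---------------------------------------------------------------------------
# numba transport kernel
# ---------------------------------------------------------------------------

_U64 = np.uint64


@njit(cache=True, inline="always", fastmath=True)
def _mix64(z):
    z = (z + _U64(0x9E3779B97F4A7C15)) & _U64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)) & _U64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)) & _U64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> _U64(31))


@njit(cache=True, inline="always", fastmath=True)
def _next_u64(state):
    # xorshift64* step; state must be nonzero
    x = state
    x ^= x >> _U64(12)
    x ^= (x << _U64(25)) & _U64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> _U64(27)
    out = (x * _U64(0x2545F4914F6CDD1D)) & _U64(0xFFFFFFFFFFFFFFFF)
    return x, out


@njit(cache=True, inline="always", fastmath=True)
def _uniform(state):
    state, u = _next_u64(state)
    return state, (np.float64(u >> _U64(11)) + 0.5) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always", fastmath=True)
def _fresnel_scalar(n_i, n_t, cos_i):
    if n_i == n_t:
        return 0.0
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n_i / n_t) ** 2 * sin_i2
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n_i * cos_i - n_t * cos_t) / (n_i * cos_i + n_t * cos_t)
    rp = (n_i * cos_t - n_t * cos_i) / (n_i * cos_t + n_t * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True)
def _transport(
    mua,
    mus,
    g,
    n_layer,
    z_top,
    z_bot,
    n_ambient,
    n_photons,
    seed,
    rho_min,
    rho_max,
    cos_accept,
    t_max,
    n_bins,
    w_thresh,
    p_surv,
):
    n_layers = mua.shape[0]
    dtof = np.zeros(n_bins)
    dtof_sq = np.zeros(n_bins)
    hits = np.zeros(n_bins, dtype=np.int64)
    path = np.zeros((n_layers, n_bins))
    # weight ledger: [detected, escaped_top_undetected, transmitted_bottom,
    #                 absorbed, roulette_net, time_expired]
    ledger = np.zeros(6)
    c = C_CM_PER_NS
    dt = t_max / n_bins
    opt_max = c * t_max  # optical pathlength bound for the time window

    # specular reflection at launch
    r_sp = _fresnel_scalar(n_ambient, n_layer[0], 1.0)
    w0 = 1.0 - r_sp

    lpath = np.zeros(n_layers)
    for p in range(n_photons):
        state = _mix64(_U64(seed) ^ (_U64(p) * _U64(0xA0761D6478BD642F)))
        if state == _U64(0):
            state = _U64(0x9E3779B97F4A7C15)
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = w0
        layer = 0
        opt = 0.0
        for i in range(n_layers):
            lpath[i] = 0.0
        alive = True
        while alive:
            state, xi = _uniform(state)
            mut = mua[layer] + mus[layer]
            s_left = -np.log(xi)
            while s_left > 0.0:
                step = s_left / mut
                # distance to layer boundary along uz
                if uz > 0.0:
                    db = (z_bot[layer] - z) / uz
                elif uz < 0.0:
                    db = (z_top[layer] - z) / uz
                else:
                    db = 1e30
                if db < step:
                    # move to boundary
                    x += ux * db
                    y += uy * db
                    z += uz * db
                    lpath[layer] += db
                    opt += n_layer[layer] * db
                    s_left -= db * mut
                    if opt > opt_max:
                        ledger[5] += w
                        alive = False
                        break
                    if uz < 0.0:
                        # hitting the top of this layer
                        if layer == 0:
                            cos_i = -uz
                            rf = _fresnel_scalar(n_layer[0], n_ambient, cos_i)
                            state, xi2 = _uniform(state)
                            if xi2 < rf:
                                uz = -uz
                            else:
                                # escapes through the surface
                                t = opt / c
                                r = np.sqrt(x * x + y * y)
                                detected = rho_min <= r <= rho_max and t < t_max
                                if detected and cos_accept > 0.0:
                                    # refraction steepens the exit angle
                                    sin_t = n_layer[0] * np.sqrt(
                                        max(1.0 - cos_i * cos_i, 0.0)
                                    ) / n_ambient
                                    cos_out = np.sqrt(max(1.0 - sin_t * sin_t, 0.0))
                                    detected = cos_out >= cos_accept
                                if detected:
                                    b = int(t / dt)
                                    if b >= n_bins:
                                        b = n_bins - 1
                                    dtof[b] += w
                                    dtof_sq[b] += w * w
                                    hits[b] += 1
                                    for i in range(n_layers):
                                        path[i, b] += w * lpath[i]
                                    ledger[0] += w
                                else:
                                    ledger[1] += w
                                alive = False
                                break
                        else:
                            n_i = n_layer[layer]
                            n_t = n_layer[layer - 1]
                            rf = _fresnel_scalar(n_i, n_t, -uz)
                            reflected = False
                            if rf > 0.0:
                                state, xi2 = _uniform(state)
                                reflected = xi2 < rf
                            if reflected:
                                uz = -uz
                            else:
                                if n_i != n_t:
                                    sin_i = np.sqrt(max(1.0 - uz * uz, 0.0))
                                    sin_t = n_i * sin_i / n_t
                                    scale = sin_t / sin_i if sin_i > 0 else 0.0
                                    ux *= scale
                                    uy *= scale
                                    uz = -np.sqrt(max(1.0 - sin_t * sin_t, 0.0))
                                layer -= 1
                                mut = mua[layer] + mus[layer]
                    else:
                        # hitting the bottom of this layer
                        if layer == n_layers - 1:
                            # semi-infinite bottom is encoded with a huge
                            # z_bot; reaching it means transmission
                            ledger[2] += w
                            alive = False
                            break
                        n_i = n_layer[layer]
                        n_t = n_layer[layer + 1]
                        rf = _fresnel_scalar(n_i, n_t, uz)
                        reflected = False
                        if rf > 0.0:
                            state, xi2 = _uniform(state)
                            reflected = xi2 < rf
                        if reflected:
                            uz = -uz
                        else:
                            if n_i != n_t:
                                sin_i = np.sqrt(max(1.0 - uz * uz, 0.0))
                                sin_t = n_i * sin_i / n_t
                                scale = sin_t / sin_i if sin_i > 0 else 0.0
                                ux *= scale
                                uy *= scale
                                uz = np.sqrt(max(1.0 - sin_t * sin_t, 0.0))
                            layer += 1
                            mut = mua[layer] + mus[layer]
                else:
                    x += ux * step
                    y += uy * step
                    z += uz * step
                    lpath[layer] += step
                    opt += n_layer[layer] * step
                    s_left = 0.0
                    if opt > opt_max:
                        ledger[5] += w
                        alive = False
                        break
                    # implicit-capture absorption
                    dw = w * mua[layer] / mut
                    w -= dw
                    ledger[3] += dw
                    # Henyey-Greenstein scattering
                    state, xi3 = _uniform(state)
                    gg = g[layer]
                    if gg != 0.0:
                        tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * xi3)
                        cos_t = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                    else:
                        cos_t = 2.0 * xi3 - 1.0
                    if cos_t > 1.0:
                        cos_t = 1.0
                    elif cos_t < -1.0:
                        cos_t = -1.0
                    sin_t = np.sqrt(1.0 - cos_t * cos_t)
                    state, xi4 = _uniform(state)
                    phi = 2.0 * np.pi * xi4
                    cos_p = np.cos(phi)
                    sin_p = np.sin(phi)
                    if abs(uz) > 0.99999:
                        ux = sin_t * cos_p
                        uy = sin_t * sin_p
                        uz = cos_t if uz > 0.0 else -cos_t
                    else:
                        den = np.sqrt(1.0 - uz * uz)
                        ux_n = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
                        uy_n = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
                        uz_n = -sin_t * cos_p * den + uz * cos_t
                        ux, uy, uz = ux_n, uy_n, uz_n
                    # roulette
                    if w < w_thresh:
                        state, xi5 = _uniform(state)
                        if xi5 < p_surv:
                            ledger[4] -= w * (1.0 / p_surv - 1.0)
                            w /= p_surv
                        else:
                            ledger[4] += w
                            alive = False
                            break
    return dtof, dtof_sq, hits, path, ledger, w0


def run_layered_mc(layers: list[MCLayer], config: MCConfig) -> MCResult:
    """Run layered time-resolved Monte Carlo transport.

    A pencil beam enters at the origin along +z.  Returns the detected DTOF
    with per-layer pathlength sums; an all-zero result (``result.empty``)
    signals that no photon reached the detector, which is not an error.
    """
    if len(layers) < 1:
        raise ValueError("need at least one layer")
    mua = np.array([la.mua for la in layers], dtype=float)
    mus = np.array([la.mus for la in layers], dtype=float)
    g = np.array([la.g for la in layers], dtype=float)
    n_layer = np.array([la.n for la in layers], dtype=float)
    thick = np.array([la.thickness for la in layers], dtype=float)
    z_edges = np.concatenate([[0.0], np.cumsum(thick)])
    if not np.isfinite(z_edges[-1]):
        z_edges[-1] = 1e30
    z_top = z_edges[:-1]
    z_bot = z_edges[1:]
    cos_accept = 0.0
    if config.na is not None:
        cos_accept = float(np.sqrt(max(1.0 - (config.na / config.n_ambient) ** 2, 0.0)))
    dtof, dtof_sq, hits, path, ledger, w0 = _transport(
        mua,
        mus,
        g,
        n_layer,
        z_top,
        z_bot,
        config.n_ambient,
        config.n_photons,
        config.seed % (2**63),
        config.rho - config.half_width,
        config.rho + config.half_width,
        cos_accept,
        config.t_max,
        config.n_bins,
        config.weight_threshold,
        config.survival,
    )
    totals = {
        "launched": config.n_photons * w0,
        "specular": config.n_photons * (1.0 - w0),
        "detected": ledger[0],
        "escaped_top": ledger[1],
        "transmitted": ledger[2],
        "absorbed": ledger[3],
        "roulette_net": ledger[4],
        "time_expired": ledger[5],
    }
    return MCResult(
        grid=config.grid,
        dtof=dtof,
        dtof_sq=dtof_sq,
        hits=hits,
        pathlen_sums=path,
        n_launched=config.n_photons,
        seed=config.seed,
        totals=totals,
        annulus=(config.rho - config.half_width, config.rho + config.half_width),
    )


# ---------------------------------------------------------------------------
# perturbation re-weighting and shot noise
# ---------------------------------------------------------------------------

def perturb_transient(base: MCResult, delta_mua, base_mua=None) -> Transient:
    """Beer-Lambert re-weighting of a detected DTOF for per-layer absorption
    changes ``delta_mua`` (cm^-1).

    Each bin is multiplied by ``exp(-sum_i dmua_i * Lbar_i(t))`` where
    ``Lbar_i`` is the mean detected pathlength in layer ``i`` for that
    arrival-time bin.  Exact in expectation for the weighting method when
    the scattering coefficients are unchanged.  When ``base_mua`` is given,
    perturbations above 20% of the baseline trigger a warning.
    """
    if base.pathlen_sums is None or base.pathlen_sums.size == 0:
        raise ValueError("base MCResult lacks per-layer pathlength sums")
    delta = np.asarray(delta_mua, dtype=float)
    if delta.shape != (base.pathlen_sums.shape[0],):
        raise ValueError(
            f"delta_mua must have one entry per layer "
            f"({base.pathlen_sums.shape[0]}), got shape {delta.shape}"
        )
    if base_mua is not None:
        warn_if_large_perturbation(delta, base_mua)
    lbar = base.mean_pathlengths()
    factor = np.exp(-delta @ lbar)
    values = base.dtof * factor
    return Transient(base.grid, values, "model_density")


def warn_if_large_perturbation(delta_mua, base_mua, limit: float = 0.2) -> None:
    """Emit a warning when |delta| exceeds ``limit`` of the baseline mua."""
    delta = np.asarray(delta_mua, dtype=float)
    base = np.asarray(base_mua, dtype=float)
    rel = np.abs(delta) / np.where(base > 0, base, np.inf)
    if np.any(rel > limit):
        warnings.warn(
            f"perturbation {delta} exceeds {limit:.0%} of baseline {base}; "
            "first-order pathlength re-weighting may be inaccurate",
            stacklevel=3,
        )


def sample_counts(transient: Transient, total_counts: float, seed: int) -> Transient:
    """Poisson shot-noise realization of a model transient.

    Per-bin independent Poisson draws with means proportional to the input,
    scaled so the expected total equals ``total_counts``.
    """
    if total_counts < 0:
        raise ValueError("total_counts must be >= 0")
    values = np.asarray(transient.values, dtype=float)
    if np.any(values < 0):
        raise ValueError("input transient has negative bins")
    total = values.sum()
    if total_counts == 0 or total == 0:
        counts = np.zeros_like(values)
    else:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(values * (total_counts / total)).astype(float)
    return Transient(transient.grid, counts, "counts", transient.geometry)
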