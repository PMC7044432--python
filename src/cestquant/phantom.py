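"""Synthetic ground-truth phantoms, voxelwise mapping and comparison statistics.

Builds digital phantoms (circular tubes with assigned concentration and
exchange-rate values on a smooth B0 field), simulates the per-voxel
Z-spectrum stack, applies a trained network voxelwise, and provides the
statistical comparisons used to judge agreement: ROI summaries, Pearson
correlation with t-test p-value, Bland-Altman analysis, area-weighted
patch downsampling, and mono-exponential recovery fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .ann import TrainedNetwork
from .datagen import GenerationConfig, generate_training_set, simulate_labeled

__all__ = [
    "TubeLayout",
    "GroundTruthMaps",
    "ParameterMaps",
    "ComparisonStats",
    "default_tube_layout",
    "make_ground_truth",
    "simulate_stack",
    "quantify_map",
    "roi_stats",
    "correlation",
    "bland_altman",
    "downsample_patch_mean",
    "fit_recovery",
]


@dataclass(frozen=True)
class TubeLayout:
    """Circular tube positions (fractions of image size) and values."""

    centers: tuple[tuple[float, float], ...]  # (row, col) fractions in (0, 1)
    radii: tuple[float, ...]  # fraction of min(shape)
    concentrations_mm: tuple[float, ...]
    exchange_rates_hz: tuple[float, ...]

    def __post_init__(self):
        n = len(self.centers)
        if not (len(self.radii) == len(self.concentrations_mm) == len(self.exchange_rates_hz) == n):
            raise ValueError("layout fields must have equal lengths")


def default_tube_layout() -> TubeLayout:
    """Five tubes at 10/20/40/60/80 mM arranged on a ring.

    Exchange rates are spread over the phantom label range so that the
    rate map is informative as well.
    """
    angles = np.linspace(0, 2 * np.pi, 6)[:5] + np.pi / 2
    centers = tuple((0.5 + 0.28 * np.sin(a), 0.5 + 0.28 * np.cos(a)) for a in angles)
    return TubeLayout(
        centers=centers,
        radii=(0.13,) * 5,
        concentrations_mm=(10.0, 20.0, 40.0, 60.0, 80.0),
        exchange_rates_hz=(150.0, 200.0, 250.0, 300.0, 350.0),
    )


@dataclass
class GroundTruthMaps:
    """Per-voxel truth for phantom evaluation; labels 0 = background."""

    concentration_mm: np.ndarray
    exchange_rate_hz: np.ndarray
    b0_ppm: np.ndarray
    b1_ut: np.ndarray
    roi_labels: np.ndarray

    def __post_init__(self):
        shapes = {
            m.shape
            for m in (
                self.concentration_mm,
                self.exchange_rate_hz,
                self.b0_ppm,
                self.b1_ut,
                self.roi_labels,
            )
        }
        if len(shapes) != 1:
            raise ValueError(f"all maps must share one shape, got {shapes}")

    @property
    def shape(self):
        return self.concentration_mm.shape


@dataclass
class ParameterMaps:
    """Voxelwise estimates with a validity mask."""

    maps: dict[str, np.ndarray]
    mask: np.ndarray


@dataclass
class ComparisonStats:
    r: float
    p_value: float
    bias: float
    loa_low: float
    loa_high: float
    n: int


def make_ground_truth(
    layout: TubeLayout | None = None,
    shape: tuple[int, int] = (256, 256),
    b0_range_ppm: tuple[float, float] = (-0.4, 0.4),
    b1_range_ut: tuple[float, float] = (0.6, 0.6),
    seed: int = 0,
) -> GroundTruthMaps:
    """Digital tube phantom with a smooth second-order B0 field.

    The B0 (and optionally B1) ground truth is a random second-order
    2D polynomial rescaled to the requested range, mimicking a shim
    field; tube interiors carry the layout's concentration and
    exchange-rate values.
    """
    layout = layout or default_tube_layout()
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    conc = np.zeros(shape)
    rate = np.zeros(shape)
    labels = np.zeros(shape, dtype=int)
    rmin = min(h, w)
    occupied = np.zeros(shape, dtype=bool)
    for i, ((fr, fc), frad) in enumerate(zip(layout.centers, layout.radii)):
        mask = (rr - fr * h) ** 2 + (cc - fc * w) ** 2 <= (frad * rmin) ** 2
        if not mask.any():
            raise ValueError(f"tube {i} lies outside the image bounds")
        if (mask & occupied).any():
            raise ValueError(f"tube {i} overlaps a previous tube")
        occupied |= mask
        conc[mask] = layout.concentrations_mm[i]
        rate[mask] = layout.exchange_rates_hz[i]
        labels[mask] = i + 1

    rng = np.random.default_rng(seed)

    def smooth_field(lo, hi):
        if lo == hi:
            return np.full(shape, lo)
        x = (cc - w / 2) / w
        y = (rr - h / 2) / h
        coef = rng.normal(size=6)
        f = (
            coef[0]
            + coef[1] * x
            + coef[2] * y
            + coef[3] * x * y
            + coef[4] * x**2
            + coef[5] * y**2
        )
        f = (f - f.min()) / (f.max() - f.min())
        return lo + f * (hi - lo)

    return GroundTruthMaps(
        concentration_mm=conc,
        exchange_rate_hz=rate,
        b0_ppm=smooth_field(*b0_range_ppm),
        b1_ut=smooth_field(*b1_range_ut),
        roi_labels=labels,
    )


def simulate_stack(
    maps: GroundTruthMaps,
    config: GenerationConfig,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate the (H, W, n_offsets) Z-spectrum stack voxel by voxel.

    Background voxels (concentration 0) reduce to the water-only (plus
    any semisolid pool) spectrum.  Identical parameter vectors are
    simulated once and broadcast, which makes piecewise-constant
    phantoms cheap.  Noise per ``config.noise_sd`` is added with the
    given seed (``None`` -> ``config.seed``).
    """
    h, w = maps.shape
    m = len(config.offsets_ppm)
    params = np.stack(
        [
            maps.concentration_mm.ravel(),
            np.where(
                maps.exchange_rate_hz.ravel() > 0,
                maps.exchange_rate_hz.ravel(),
                config.ranges.exchange_rate_hz[0],
            ),
            maps.b0_ppm.ravel(),
            maps.b1_ut.ravel(),
        ],
        axis=1,
    )
    stack = np.empty((h * w, m))
    uniq, inv = np.unique(params, axis=0, return_inverse=True)
    for j, (conc, k, b0, b1) in enumerate(uniq):
        try:
            z = simulate_labeled(config, conc, k, b0, b1)
        except Exception as exc:  # pragma: no cover
            vox = int(np.argmax(inv == j))
            raise RuntimeError(f"simulation failed at voxel {divmod(vox, w)}") from exc
        stack[inv == j] = z.intensities
    sd = config.noise_sd
    if sd > 0:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        stack = stack + rng.normal(0.0, sd, size=stack.shape)
    return stack.reshape(h, w, m)


def quantify_map(net: TrainedNetwork, stack: np.ndarray, mask: np.ndarray | None = None) -> ParameterMaps:
    """Apply a trained network voxelwise to a Z-spectrum stack.

    One vectorized forward pass over the masked voxels; no per-voxel
    refitting.  Unmasked voxels are NaN in the output maps.
    """
    h, w, m = stack.shape
    if m != net.sizes[0]:
        raise ValueError(
            f"stack has {m} offsets but the network expects {net.sizes[0]}"
        )
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    flat = stack[mask]
    pred = net.predict(flat)
    maps = {}
    for i, name in enumerate(net.label_names):
        out = np.full((h, w), np.nan)
        out[mask] = pred[:, i]
        maps[name] = out
    return ParameterMaps(maps=maps, mask=mask.copy())


def roi_stats(values: np.ndarray, labels: np.ndarray) -> dict[int, dict[str, float]]:
    """Mean, sd and voxel count of ``values`` per nonzero ROI label."""
    out = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        v = values[labels == lab]
        v = v[np.isfinite(v)]
        out[int(lab)] = {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "n": int(len(v)),
        }
    return out


def correlation(a, b) -> tuple[float, float]:
    """Pearson R and two-sided t-test p-value for paired arrays."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) != len(b):
        raise ValueError("paired arrays must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def bland_altman(a, b) -> ComparisonStats:
    """Bland-Altman agreement: bias and 95% limits of agreement.

    ``bias = mean(a - b)``; limits are ``bias +/- 1.96 * sd(a - b)``
    under the normal model.  Also reports the Pearson correlation of
    the pair for convenience.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) != len(b):
        raise ValueError("paired arrays must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    r, p = correlation(a, b) if np.std(a) > 0 and np.std(b) > 0 else (1.0, 0.0)
    return ComparisonStats(
        r=r,
        p_value=p,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=len(a),
    )


def _overlap_weights(n_src: int, n_dst: int) -> np.ndarray:
    """(n_dst, n_src) fractional coverage of source cells by target patches."""
    if n_dst > n_src:
        raise ValueError(f"target size {n_dst} exceeds source size {n_src}")
    edges_dst = np.linspace(0.0, n_src, n_dst + 1)
    W = np.zeros((n_dst, n_src))
    for i in range(n_dst):
        a, b = edges_dst[i], edges_dst[i + 1]
        lo = int(np.floor(a))
        hi = int(np.ceil(b))
        for j in range(lo, hi):
            W[i, j] = min(b, j + 1) - max(a, j)
    return W / (n_src / n_dst)


def downsample_patch_mean(src: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Patch-average downsampling with exact fractional-boundary weighting.

    Each target cell is the area-weighted mean of the source cells its
    patch covers, so non-integer ratios (e.g. 72 -> 16) are handled
    without cropping and the global mean is conserved exactly.
    """
    h, w = src.shape
    th, tw = target_shape
    Wr = _overlap_weights(h, th)
    Wc = _overlap_weights(w, tw)
    return Wr @ src @ Wc.T


def fit_recovery(times_s, values_mm):
    """Mono-exponential recovery fit v(t) = v_end - dv * exp(-t / tau).

    Returns ``(tau_s, v_end, dv, converged)``.  A flat series has no
    identifiable time constant and is flagged (``converged=False``).
    """
    t = np.asarray(times_s, dtype=float)
    v = np.asarray(values_mm, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    dv0 = v[-1] - v[0]
    if np.std(v) < 1e-12 or abs(dv0) < 1e-12:
        return float("nan"), float(np.mean(v)), 0.0, False

    def model(tt, v_end, dv, tau):
        return v_end - dv * np.exp(-tt / tau)

    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            v,
            p0=[v[-1], dv0, max((t[-1] - t[0]) / 3.0, 1e-6)],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        return float("nan"), float(v[-1]), float(dv0), False
    v_end, dv, tau = popt
    return float(tau), float(v_end), float(dv), True
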