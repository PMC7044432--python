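"""Annotated Z-spectrum datasets for training the inverse model.

Two presets are shipped: a phosphocreatine phantom at 3 T (two
guanidinium CEST pools at 1.95 and 2.5 ppm, fixed B1) and human
skeletal muscle at 3 T (single 2.5 ppm PCr pool plus a super-Lorentzian
magnetization-transfer background, B1 treated as a quantifiable
parameter).  Quantifiable parameters are sampled independently and
uniformly from configured ranges, spectra are simulated with the
Bloch-McConnell forward model, and Gaussian noise is added.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np

from .bmc import (
    FieldState,
    PoolParams,
    SaturationParams,
    ScannerConfig,
    ZSpectrum,
    concentration_to_fraction,
    simulate_zspectrum,
    water_pool,
    water_pool_index,
)

__all__ = [
    "LabelRanges",
    "GenerationConfig",
    "TrainingSet",
    "phantom_preset",
    "invivo_preset",
    "generate_training_set",
    "simulate_labeled",
    "resample_spectrum",
    "PHANTOM_K_RATIO",
]

#: Exchange-rate ratio between the 1.95 and 2.5 ppm guanidinium pools,
#: measured on a PCr phantom at 37 degC: k(2.5 ppm) = 2.19 * k(1.95 ppm).
PHANTOM_K_RATIO = 2.19


@dataclass(frozen=True)
class LabelRanges:
    """Uniform sampling ranges for the quantifiable parameters.

    Each entry is a ``(lo, hi)`` tuple; a degenerate range (``lo == hi``)
    fixes the parameter.  ``b1_ut`` fixed means B1 is not a label.
    """

    concentration_mm: tuple[float, float]
    exchange_rate_hz: tuple[float, float]
    b0_ppm: tuple[float, float]
    b1_ut: tuple[float, float] = (0.6, 0.6)
    water_t2_s: tuple[float, float] = (0.0, 0.0)  # (0,0) -> use pool template value

    def __post_init__(self):
        for name in ("concentration_mm", "exchange_rate_hz", "b0_ppm", "b1_ut", "water_t2_s"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lo ({lo}) > hi ({hi})")

    @property
    def b1_is_label(self) -> bool:
        return self.b1_ut[0] < self.b1_ut[1]


@dataclass(frozen=True)
class GenerationConfig:
    """Everything needed to generate one annotated dataset."""

    preset: str
    pools: tuple[PoolParams, ...]
    saturation: SaturationParams
    offsets_ppm: np.ndarray
    ranges: LabelRanges
    noise_sd: float
    n_samples: int = 100_000
    seed: int = 0
    protons_per_molecule: float = 2.0
    scanner: ScannerConfig = field(default_factory=ScannerConfig)

    def __post_init__(self):
        object.__setattr__(self, "offsets_ppm", np.asarray(self.offsets_ppm, dtype=float))
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def label_names(self) -> list[str]:
        names = ["concentration_mm", "exchange_rate_hz", "b0_ppm"]
        if self.ranges.b1_is_label:
            names.append("b1_ut")
        return names

    def config_hash(self) -> str:
        d = asdict(self)
        d["offsets_ppm"] = list(self.offsets_ppm)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class TrainingSet:
    """Aligned spectra (X) and labels (Y) with generation provenance."""

    X: np.ndarray
    Y: np.ndarray
    label_names: list[str]
    offsets_ppm: np.ndarray
    provenance: dict

    def __post_init__(self):
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        if not (np.isfinite(self.X).all() and np.isfinite(self.Y).all()):
            raise ValueError("dataset contains non-finite values")

    def __len__(self) -> int:
        return self.X.shape[0]


def phantom_preset(n_samples: int = 100_000, seed: int = 0) -> GenerationConfig:
    """PCr phantom at 3 T.

    Three mobile pools: water (T1 2.6 s, T2 1.8 s) and the two
    guanidinium CEST pools at 1.95 and 2.5 ppm (T1 0.05 s, T2 0.02 s)
    whose exchange rates are locked to the ratio 1:2.19.  Saturation
    0.6 uT for 10 s; 50 equally spaced offsets on [0.5, 4] ppm.
    Sampled labels: concentration 5-85 mM, exchange rate at 1.95 ppm
    50-200 Hz (the stored label is the 2.5 ppm rate), B0 +/-0.4 ppm.
    B1 fixed at 0.6 uT; noise sd 0.0015.
    """
    pools = (
        water_pool(2.6, 1.8),
        PoolParams(1.95, 0.05, 0.02, 0.0, 0.0, name="pcr_1.95"),
        PoolParams(2.5, 0.05, 0.02, 0.0, 0.0, name="pcr_2.5"),
    )
    ranges = LabelRanges(
        concentration_mm=(5.0, 85.0),
        # label range for the 2.5 ppm rate: 2.19 * [50, 200] Hz sampled at 1.95 ppm
        exchange_rate_hz=(50.0 * PHANTOM_K_RATIO, 200.0 * PHANTOM_K_RATIO),
        b0_ppm=(-0.4, 0.4),
        b1_ut=(0.6, 0.6),
    )
    return GenerationConfig(
        preset="phantom",
        pools=pools,
        saturation=SaturationParams(0.6, 10.0),
        offsets_ppm=np.linspace(0.5, 4.0, 50),
        ranges=ranges,
        noise_sd=0.0015,
        n_samples=n_samples,
        seed=seed,
    )


def invivo_preset(n_samples: int = 100_000, seed: int = 0) -> GenerationConfig:
    """Human skeletal muscle at 3 T.

    Water (T1 1.2 s, T2 sampled 15-35 ms as a nuisance variable), one
    PCr guanidinium pool at 2.5 ppm, and a super-Lorentzian
    magnetization-transfer background (8 M exchanging protons, 30 Hz,
    T1 1 s, T2 9.1 us).  Saturation 0.6 uT for 800 ms; 50 offsets on
    [1.3, 3.5] ppm.  Sampled labels: concentration 0-100 mM, exchange
    rate 80-230 Hz, B0 +/-0.25 ppm, B1 0.5-0.7 uT; noise sd 0.0035.
    """
    pools = (
        water_pool(1.2, 0.025),
        PoolParams(2.5, 0.05, 0.02, 0.0, 0.0, name="pcr_2.5"),
        PoolParams(
            0.0, 1.0, 9.1e-6, 8.0 / 111.2, 30.0, "super_lorentzian", name="mtc"
        ),
    )
    ranges = LabelRanges(
        concentration_mm=(0.0, 100.0),
        exchange_rate_hz=(80.0, 230.0),
        b0_ppm=(-0.25, 0.25),
        b1_ut=(0.5, 0.7),
        water_t2_s=(0.015, 0.035),
    )
    return GenerationConfig(
        preset="invivo",
        pools=pools,
        saturation=SaturationParams(0.6, 0.8),
        offsets_ppm=np.linspace(1.3, 3.5, 50),
        ranges=ranges,
        noise_sd=0.0035,
        n_samples=n_samples,
        seed=seed,
    )


def _materialize_pools(
    config: GenerationConfig,
    concentration_mm: float,
    exchange_rate_hz: float,
    water_t2_s: float | None = None,
) -> list[PoolParams]:
    """Fill the preset's pool template with one sample's parameters.

    ``exchange_rate_hz`` is the rate of the reference (2.5 ppm) pool;
    for the phantom preset the 1.95 ppm pool gets that rate divided by
    the fixed ratio.
    """
    frac = float(
        concentration_to_fraction(concentration_mm, config.protons_per_molecule)
    )
    pools = []
    for p in config.pools:
        if p.is_water:
            if water_t2_s is not None:
                p = replace(p, t2_s=water_t2_s)
        elif p.lineshape == "lorentzian":
            if p.chemical_shift_ppm == 2.5:
                p = replace(p, proton_fraction=frac, exchange_rate_hz=exchange_rate_hz)
            else:  # secondary guanidinium pool, rate locked to the 2.5 ppm rate
                p = replace(
                    p,
                    proton_fraction=frac,
                    exchange_rate_hz=exchange_rate_hz / PHANTOM_K_RATIO,
                )
        pools.append(p)
    return pools


def simulate_labeled(
    config: GenerationConfig,
    concentration_mm: float,
    exchange_rate_hz: float,
    b0_ppm: float = 0.0,
    b1_ut: float | None = None,
    water_t2_s: float | None = None,
) -> ZSpectrum:
    """Noiseless forward simulation for one label vector under a preset."""
    pools = _materialize_pools(config, concentration_mm, exchange_rate_hz, water_t2_s)
    nominal_b1 = config.saturation.b1_amplitude_ut
    scale = 1.0 if b1_ut is None else b1_ut / nominal_b1
    return simulate_zspectrum(
        pools,
        config.saturation,
        config.offsets_ppm,
        FieldState(b0_shift_ppm=b0_ppm, b1_scale=scale),
        config.scanner,
    )


def generate_training_set(
    config: GenerationConfig,
    n_samples: int | None = None,
    seed: int | None = None,
) -> TrainingSet:
    """Sample labels, simulate spectra, add noise.

    The result is a pure function of ``(config, seed)``: labels are
    drawn i.i.d. uniform from the configured ranges with a seeded
    generator, and the same generator stream supplies the noise.
    """
    n = config.n_samples if n_samples is None else int(n_samples)
    sd = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(sd)
    r = config.ranges

    conc = rng.uniform(*r.concentration_mm, size=n)
    k = rng.uniform(*r.exchange_rate_hz, size=n)
    b0 = rng.uniform(*r.b0_ppm, size=n)
    b1 = rng.uniform(*r.b1_ut, size=n) if r.b1_is_label else np.full(n, r.b1_ut[0])
    if r.water_t2_s != (0.0, 0.0):
        wt2 = rng.uniform(*r.water_t2_s, size=n)
    else:
        wt2 = np.full(n, np.nan)

    m = len(config.offsets_ppm)
    X = np.empty((n, m))
    for i in range(n):
        try:
            z = simulate_labeled(
                config,
                conc[i],
                k[i],
                b0[i],
                b1[i],
                None if np.isnan(wt2[i]) else wt2[i],
            )
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"simulation failed for sample {i}") from exc
        X[i] = z.intensities
    if config.noise_sd > 0:
        X += rng.normal(0.0, config.noise_sd, size=X.shape)

    cols = [conc, k, b0] + ([b1] if r.b1_is_label else [])
    Y = np.column_stack(cols)
    prov = {
        "preset": config.preset,
        "config_hash": config.config_hash(),
        "seed": sd,
        "n_samples": n,
        "ranges": {
            "concentration_mm": list(r.concentration_mm),
            "exchange_rate_hz": list(r.exchange_rate_hz),
            "b0_ppm": list(r.b0_ppm),
            "b1_ut": list(r.b1_ut),
        },
    }
    return TrainingSet(X, Y, config.label_names, config.offsets_ppm.copy(), prov)


def resample_spectrum(z: ZSpectrum, target_offsets_ppm) -> ZSpectrum:
    """Linearly interpolate a spectrum onto a different offset grid.

    Used to map spectra acquired on variable-increment grids onto the
    equal-interval training grid.  Extrapolation is refused.
    """
    target = np.asarray(target_offsets_ppm, dtype=float)
    order = np.argsort(z.offsets_ppm)
    x, y = z.offsets_ppm[order], z.intensities[order]
    if target.min() < x[0] - 1e-9 or target.max() > x[-1] + 1e-9:
        raise ValueError(
            f"target grid [{target.min()}, {target.max()}] extends beyond "
            f"acquired range [{x[0]}, {x[-1]}]"
        )
    return ZSpectrum(target, np.interp(target, x, y))
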