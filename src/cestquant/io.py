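"""File formats: spectra as CSV, image stacks as NIfTI + JSON sidecar,
datasets as HDF5, configs and provenance as JSON.

NIfTI has no semantics for a spectral axis, so the saturation offsets
of a stack travel in a JSON sidecar whose length must match the last
data dimension.  Offsets are sorted on read with the data permuted
consistently.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .bmc import FieldState, PoolParams, SaturationParams, ZSpectrum
from .datagen import TrainingSet

__all__ = [
    "read_zspectrum_csv",
    "write_zspectrum_csv",
    "read_zspectrum_stack",
    "write_zspectrum_stack",
    "save_training_set",
    "load_training_set",
    "save_parameter_maps",
    "pools_from_json",
    "pools_to_json",
    "write_provenance",
]


def write_zspectrum_csv(z: ZSpectrum, path) -> None:
    pd.DataFrame({"offset_ppm": z.offsets_ppm, "z": z.intensities}).to_csv(
        path, index=False
    )


def read_zspectrum_csv(path) -> ZSpectrum:
    df = pd.read_csv(path)
    for col in ("offset_ppm", "z"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return ZSpectrum(df["offset_ppm"].to_numpy(), df["z"].to_numpy())


def write_zspectrum_stack(stack: np.ndarray, offsets_ppm, path, sidecar_path=None) -> None:
    """Write an (H, W, n_offsets) stack as NIfTI with a JSON offsets sidecar."""
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix("").with_suffix(".offsets.json")
    nib.save(nib.Nifti1Image(np.asarray(stack, dtype=np.float64), np.eye(4)), path)
    with open(sidecar, "w") as fh:
        json.dump({"offsets_ppm": list(np.asarray(offsets_ppm, dtype=float))}, fh)


def read_zspectrum_stack(path, sidecar_path=None) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI Z-spectrum stack and its offsets sidecar.

    Returns ``(stack, offsets_ppm)`` with offsets ascending and the
    spectral axis of the data permuted to match.
    """
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix("").with_suffix(".offsets.json")
    img = nib.load(path)
    stack = np.asarray(img.dataobj, dtype=float)
    if stack.ndim == 4 and stack.shape[2] == 1:  # allow (H, W, 1, m)
        stack = stack[:, :, 0, :]
    if stack.ndim != 3:
        raise ValueError(f"{path}: expected a 3D (H, W, offsets) stack, got shape {stack.shape}")
    with open(sidecar) as fh:
        offsets = np.asarray(json.load(fh)["offsets_ppm"], dtype=float)
    if len(offsets) != stack.shape[-1]:
        raise ValueError(
            f"{sidecar}: sidecar lists {len(offsets)} offsets but {path} has "
            f"{stack.shape[-1]} along the spectral dimension"
        )
    if not np.isfinite(stack).all():
        raise ValueError(f"{path}: stack contains non-finite values")
    order = np.argsort(offsets)
    return stack[..., order], offsets[order]


def save_training_set(ts: TrainingSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=ts.X)
        f.create_dataset("Y", data=ts.Y)
        f.create_dataset("offsets_ppm", data=ts.offsets_ppm)
        f.attrs["label_names"] = json.dumps(ts.label_names)
        f.attrs["provenance"] = json.dumps(ts.provenance)


def load_training_set(path) -> TrainingSet:
    with h5py.File(path, "r") as f:
        return TrainingSet(
            X=f["X"][()],
            Y=f["Y"][()],
            offsets_ppm=f["offsets_ppm"][()],
            label_names=json.loads(f.attrs["label_names"]),
            provenance=json.loads(f.attrs["provenance"]),
        )


def export_training_set_csv(ts: TrainingSet, path) -> None:
    """Human-readable wide CSV (labels first, then one column per offset).

    Intended for small sets; HDF5 is the round-trip format.
    """
    cols = {name: ts.Y[:, i] for i, name in enumerate(ts.label_names)}
    for j, off in enumerate(ts.offsets_ppm):
        cols[f"z_{off:.4f}ppm"] = ts.X[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def save_parameter_maps(maps: dict[str, np.ndarray], out_dir, prefix: str = "map") -> list[Path]:
    """One NIfTI per parameter map; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr in maps.items():
        p = out_dir / f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), np.eye(4)), p)
        written.append(p)
    return written


def pools_to_json(pools) -> list[dict]:
    return [
        {
            "name": p.name,
            "shift_ppm": p.chemical_shift_ppm,
            "T1_s": p.t1_s,
            "T2_s": p.t2_s,
            "proton_fraction": p.proton_fraction,
            "exchange_rate_Hz": p.exchange_rate_hz,
            "lineshape": p.lineshape,
        }
        for p in pools
    ]


def pools_from_json(entries: list[dict]) -> list[PoolParams]:
    return [
        PoolParams(
            chemical_shift_ppm=e["shift_ppm"],
            t1_s=e["T1_s"],
            t2_s=e["T2_s"],
            proton_fraction=e["proton_fraction"],
            exchange_rate_hz=e.get("exchange_rate_Hz", 0.0),
            lineshape=e.get("lineshape", "lorentzian"),
            name=e.get("name", ""),
        )
        for e in entries
    ]


def save_quicklook_png(arr: np.ndarray, path, title: str = "", units: str = "") -> None:
    """Single-map PNG quicklook with a colorbar (NaNs shown blank)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.4))
    im = ax.imshow(arr, origin="lower", interpolation="nearest")
    cb = fig.colorbar(im, ax=ax, fraction=0.046)
    if units:
        cb.set_label(units)
    if title:
        ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_provenance(path, **info) -> None:
    """Record how an artifact was produced (config, seed, versions)."""
    import cestquant

    info.setdefault("cestquant_version", getattr(cestquant, "__version__", "unknown"))
    info.setdefault("numpy_version", np.__version__)
    with open(path, "w") as fh:
        json.dump(info, fh, indent=2, default=str)
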