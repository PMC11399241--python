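"""Containers and exchange formats.

Two dialects hold the 4-D stacks and reconstructed hypercubes:

* a single HDF5 container (arrays + axis datasets, schema version and a
  JSON metadata attribute) — the round-trippable default;
* a directory of per-delay TIFF frames plus CSV reference spectra and a
  JSON sidecar for axes/metadata, for interoperability with image tools.

Transient maps and decay-associated spectra are exchanged as CSV
(first column the time axis, header row the wavelengths; DAS one column
per component with lifetimes in the header).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .globalfit import DasFit
from .kernels import Irf
from .reconstruct import Hypercube, TransientMap
from .simulate import RawStack

__all__ = [
    "SCHEMA_VERSION", "IxflimIOError",
    "save_stack", "load_stack", "save_stack_tiff_dir", "load_stack_tiff_dir",
    "save_cube", "load_cube",
    "save_transient_map", "load_transient_map",
    "save_das", "load_das",
]

SCHEMA_VERSION = 1


class IxflimIOError(RuntimeError):
    """Malformed, truncated or schema-incompatible container."""


def _check_schema(version) -> None:
    if version is None:
        raise IxflimIOError("file carries no ixflim schema version; refusing "
                            "to guess the layout")
    if int(version) != SCHEMA_VERSION:
        raise IxflimIOError(
            f"schema version {version} not supported (expected "
            f"{SCHEMA_VERSION})")


# ---------------------------------------------------------------- HDF5 stack

def save_stack(path, stack: RawStack) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["ixflim_schema"] = SCHEMA_VERSION
        f.attrs["kind"] = "raw_stack"
        f.attrs["metadata"] = json.dumps(stack.metadata)
        f.create_dataset("counts", data=stack.counts, compression="gzip")
        f.create_dataset("t_axis", data=stack.t_axis)
        f.create_dataset("tau_axis", data=stack.tau_axis)
        f.create_dataset("wavelength_grid", data=stack.wavelength_grid)
        f.create_dataset("reference_spectra", data=stack.reference_spectra)


def load_stack(path) -> RawStack:
    try:
        with h5py.File(path, "r") as f:
            _check_schema(f.attrs.get("ixflim_schema"))
            if f.attrs.get("kind") != "raw_stack":
                raise IxflimIOError(f"{path} is not a raw-stack container")
            try:
                return RawStack(
                    counts=f["counts"][()],
                    t_axis=f["t_axis"][()],
                    tau_axis=f["tau_axis"][()],
                    wavelength_grid=f["wavelength_grid"][()],
                    reference_spectra=f["reference_spectra"][()],
                    metadata=json.loads(f.attrs.get("metadata", "{}")),
                )
            except (KeyError, ValueError) as exc:
                raise IxflimIOError(f"malformed stack container: {exc}") from exc
    except OSError as exc:
        raise IxflimIOError(f"cannot read {path}: {exc}") from exc


# ------------------------------------------------------- TIFF directory stack

def save_stack_tiff_dir(path, stack: RawStack) -> None:
    """Per-delay TIFF frames (each a (t, y, x) volume) + CSV references."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for j in range(stack.counts.shape[0]):
        tifffile.imwrite(root / f"frame_{j:05d}.tif",
                         np.asarray(stack.counts[j], dtype=np.float32))
    ref = pd.DataFrame(stack.reference_spectra.T,
                       columns=[f"tau_{j:05d}" for j in
                                range(stack.counts.shape[0])])
    ref.insert(0, "wavelength_nm", stack.wavelength_grid)
    ref.to_csv(root / "reference_spectra.csv", index=False)
    sidecar = {
        "ixflim_schema": SCHEMA_VERSION,
        "kind": "raw_stack",
        "t_axis_ns": stack.t_axis.tolist(),
        "tau_axis_fs": stack.tau_axis.tolist(),
        "metadata": stack.metadata,
    }
    (root / "axes.json").write_text(json.dumps(sidecar, indent=1))


def load_stack_tiff_dir(path) -> RawStack:
    root = Path(path)
    sidecar_path = root / "axes.json"
    if not sidecar_path.exists():
        raise IxflimIOError(f"{root} has no axes.json sidecar")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise IxflimIOError(f"unreadable axes.json: {exc}") from exc
    _check_schema(sidecar.get("ixflim_schema"))
    try:
        t_axis = np.asarray(sidecar["t_axis_ns"], dtype=float)
        tau_axis = np.asarray(sidecar["tau_axis_fs"], dtype=float)
    except (KeyError, TypeError, ValueError) as exc:
        raise IxflimIOError(f"malformed axis metadata: {exc}") from exc
    frames = sorted(root.glob("frame_*.tif"))
    if len(frames) != tau_axis.size:
        raise IxflimIOError(
            f"found {len(frames)} TIFF frames but tau_axis lists "
            f"{tau_axis.size} delays")
    counts = np.stack([tifffile.imread(p) for p in frames])
    ref = pd.read_csv(root / "reference_spectra.csv")
    wavelength_grid = ref["wavelength_nm"].to_numpy()
    reference = ref.drop(columns="wavelength_nm").to_numpy().T
    try:
        return RawStack(counts=counts, t_axis=t_axis, tau_axis=tau_axis,
                        wavelength_grid=wavelength_grid,
                        reference_spectra=reference,
                        metadata=sidecar.get("metadata", {}))
    except ValueError as exc:
        raise IxflimIOError(f"inconsistent stack dialect: {exc}") from exc


# ----------------------------------------------------------------- hypercube

def save_cube(path, cube: Hypercube) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["ixflim_schema"] = SCHEMA_VERSION
        f.attrs["kind"] = "hypercube"
        f.attrs["normalized"] = bool(cube.normalized)
        f.attrs["metadata"] = json.dumps(cube.metadata)
        f.create_dataset("values", data=cube.values, compression="gzip")
        f.create_dataset("lambda_axis", data=cube.lambda_axis)
        f.create_dataset("t_axis", data=cube.t_axis)
        f.create_dataset("laser_reference", data=cube.laser_reference)
        f.create_dataset("valid_mask", data=cube.valid_mask)
        if cube.variance is not None:
            f.create_dataset("variance", data=cube.variance,
                             compression="gzip")


def load_cube(path) -> Hypercube:
    try:
        with h5py.File(path, "r") as f:
            _check_schema(f.attrs.get("ixflim_schema"))
            if f.attrs.get("kind") != "hypercube":
                raise IxflimIOError(f"{path} is not a hypercube container")
            return Hypercube(
                values=f["values"][()],
                lambda_axis=f["lambda_axis"][()],
                t_axis=f["t_axis"][()],
                laser_reference=f["laser_reference"][()],
                valid_mask=f["valid_mask"][()].astype(bool),
                normalized=bool(f.attrs["normalized"]),
                variance=f["variance"][()] if "variance" in f else None,
                metadata=json.loads(f.attrs.get("metadata", "{}")),
            )
    except OSError as exc:
        raise IxflimIOError(f"cannot read {path}: {exc}") from exc


# ------------------------------------------------------------- CSV exchange

def save_transient_map(path, tmap: TransientMap) -> None:
    """CSV: first column the time axis (ns), header row the wavelengths."""
    df = pd.DataFrame(tmap.values.T,
                      columns=[f"{lam:.3f}" for lam in tmap.lambda_axis])
    df.insert(0, "time_ns", tmap.t_axis)
    df.to_csv(path, index=False)


def load_transient_map(path, normalized: bool = False) -> TransientMap:
    df = pd.read_csv(path)
    if "time_ns" not in df.columns:
        raise IxflimIOError("transient-map CSV lacks the time_ns column")
    t_axis = df["time_ns"].to_numpy()
    rest = df.drop(columns="time_ns")
    try:
        lam = np.array([float(c) for c in rest.columns])
    except ValueError as exc:
        raise IxflimIOError(f"non-numeric wavelength header: {exc}") from exc
    values = rest.to_numpy().T
    return TransientMap(values=values, lambda_axis=lam, t_axis=t_axis,
                        valid_mask=np.ones(lam.size, dtype=bool),
                        normalized=normalized, roi={"source": str(path)})


def save_das(path, fit: DasFit) -> None:
    """One spectrum column per component; lifetimes in the header."""
    cols = {f"tau_{1e3 * tau:.1f}ps": fit.spectra[i]
            for i, tau in enumerate(fit.lifetimes)}
    df = pd.DataFrame(cols)
    df.insert(0, "wavelength_nm", fit.lambda_axis)
    df.to_csv(path, index=False)


def load_das(path, irf: Irf | None = None) -> DasFit:
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise IxflimIOError("DAS CSV lacks the wavelength_nm column")
    lam = df["wavelength_nm"].to_numpy()
    rest = df.drop(columns="wavelength_nm")
    try:
        lifetimes = np.array(
            [float(c.removeprefix("tau_").removesuffix("ps")) * 1e-3
             for c in rest.columns])
    except ValueError as exc:
        raise IxflimIOError(f"malformed DAS header: {exc}") from exc
    n = lifetimes.size
    return DasFit(rates=1.0 / lifetimes, spectra=rest.to_numpy().T,
                  lambda_axis=lam, irf=irf or Irf(),
                  residual_norm=np.nan, chi2_reduced=np.nan,
                  rate_stderr=np.full(n, np.nan),
                  covariance=np.full((n, n), np.nan),
                  n_data=0, success=True, message="loaded from CSV")
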