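"""File I/O: NIfTI stacks and maps, b-value tables, decay-curve and
spectrum CSVs, and Table-style summary exports.

Formats
-------
* 4-D stacks and 3-D maps: NIfTI (.nii / .nii.gz) via nibabel; maps are
  written as float32 with NaN background.
* b-values: plain text, FSL bval style (whitespace- or line-separated).
* decay curves: CSV with header ``b_s_per_mm2,intensity``.
* spectra: CSV with header ``D_mm2_per_s,weight`` plus a ``.meta`` sidecar
  of ``key = value`` lines (mu, alpha, chi2 ratio, sigma2, grid spec).
* group summary: CSV mirroring the subinterval table layout
  (``subinterval,lower_D,upper_D,SaDw_groupA,SaDw_groupB,delta``).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import BValueSchedule, DGrid, DecayCurve, RoiMask
from .fit import Spectrum
from .analysis import SubintervalPartition, TestResult, WeightSummary

__all__ = [
    "ParseError",
    "read_stack", "read_mask", "write_map",
    "read_bvals", "write_bvals",
    "read_curve_csv", "write_curve_csv",
    "read_spectrum_csv", "write_spectrum_csv",
    "write_summary_csv", "write_sdw_long_csv", "write_tests_csv",
    "read_partition_csv", "write_partition_csv",
    "load_config", "dump_config",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the file and location."""


def read_stack(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4-D NIfTI stack; returns ``(data, affine)``."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ParseError(f"{path}: expected a 4-D stack, got {data.ndim}-D")
    return data, img.affine


def read_mask(path, label: str = "") -> tuple[RoiMask, np.ndarray]:
    """Load a 3-D NIfTI mask (nonzero = inside)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ParseError(f"{path}: expected a 3-D mask, got {data.ndim}-D")
    return RoiMask(data != 0, label=label or Path(str(path)).stem), img.affine


def write_map(path, values: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write a float map as NIfTI (float32, NaN background preserved)."""
    affine = np.eye(4) if affine is None else affine
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    nib.save(img, str(path))


def read_map(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def read_bvals(path) -> BValueSchedule:
    """Read an FSL-style b-value file (one value per line or one row)."""
    try:
        values = np.loadtxt(str(path), dtype=float).ravel()
    except ValueError as exc:
        raise ParseError(f"{path}: malformed b-value file ({exc})") from None
    return BValueSchedule(values)


def write_bvals(path, schedule: BValueSchedule) -> None:
    np.savetxt(str(path), schedule.values.reshape(-1, 1), fmt="%.6g")


def read_curve_csv(path) -> DecayCurve:
    """Read a decay curve CSV with header ``b_s_per_mm2,intensity``."""
    df = pd.read_csv(path)
    expected = ["b_s_per_mm2", "intensity"]
    if list(df.columns[:2]) != expected:
        raise ParseError(f"{path}: expected header {','.join(expected)}")
    for col in expected:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {row}")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax()) + 2
            raise ParseError(f"{path}: missing value in column {col!r} at line {row}")
        df[col] = numeric
    return DecayCurve(BValueSchedule(df["b_s_per_mm2"].to_numpy()),
                      df["intensity"].to_numpy())


def write_curve_csv(path, curve: DecayCurve) -> None:
    pd.DataFrame(
        {"b_s_per_mm2": curve.schedule.values, "intensity": curve.intensities}
    ).to_csv(path, index=False, float_format="%.10g")


def write_spectrum_csv(path, spectrum: Spectrum, sigma2: float | None = None,
                       alpha: float | None = None) -> None:
    """Write a spectrum CSV and its ``.meta`` sidecar."""
    path = Path(str(path))
    pd.DataFrame(
        {"D_mm2_per_s": spectrum.grid.values, "weight": spectrum.weights}
    ).to_csv(path, index=False, float_format="%.10g")
    meta = {
        "mu": spectrum.mu,
        "chi2_ratio": spectrum.chi2_ratio,
        "alpha": alpha,
        "sigma2": sigma2,
        "grid_n": len(spectrum.grid),
        "grid_d_min": spectrum.grid.d_min,
        "grid_d_max": spectrum.grid.d_max,
    }
    with open(path.with_suffix(path.suffix + ".meta"), "w") as fh:
        for key, value in meta.items():
            fh.write(f"{key} = {value}\n")


def read_spectrum_csv(path) -> Spectrum:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["D_mm2_per_s", "weight"]:
        raise ParseError(f"{path}: expected header D_mm2_per_s,weight")
    d = df["D_mm2_per_s"].to_numpy(dtype=float)
    grid = DGrid(d, d_min=float(d[0]), d_max=float(d[-1]))
    meta_path = Path(str(path)).with_suffix(Path(str(path)).suffix + ".meta")
    mu, ratio = 0.0, 1.0
    if meta_path.exists():
        for line in meta_path.read_text().splitlines():
            if "=" not in line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "mu" and value != "None":
                mu = float(value)
            elif key == "chi2_ratio" and value != "None":
                ratio = float(value)
    return Spectrum(grid, df["weight"].to_numpy(dtype=float), mu=mu, chi2_ratio=ratio)


def write_summary_csv(path, summary: WeightSummary,
                      label_a: str = "groupA", label_b: str = "groupB") -> None:
    """Table-style per-subinterval summary of S_aDw and its group difference."""
    rows = []
    for k in range(summary.n_subintervals):
        lo, hi = summary.partition.bounds(k)
        rows.append({
            "subinterval": k + 1,
            "lower_D": lo,
            "upper_D": hi,
            f"SaDw_{label_a}": summary.sadw_a[k],
            f"SaDw_{label_b}": summary.sadw_b[k],
            "delta": summary.delta[k],
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def write_sdw_long_csv(path, summary: WeightSummary,
                       label_a: str = "groupA", label_b: str = "groupB") -> None:
    """Per-subject S_Dw in long format (group, subject, subinterval, SDw)."""
    rows = []
    for label, sdw in ((label_a, summary.sdw_a), (label_b, summary.sdw_b)):
        for subject in range(sdw.shape[0]):
            for k in range(sdw.shape[1]):
                rows.append({
                    "group": label, "subject": subject,
                    "subinterval": k + 1, "SDw": sdw[subject, k],
                })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def write_tests_csv(path, tests: list[TestResult]) -> None:
    pd.DataFrame([
        {"subinterval": t.subinterval + 1, "t": t.t, "p": t.p,
         "n_groupA": t.n_a, "n_groupB": t.n_b, "significant": t.significant}
        for t in tests
    ]).to_csv(path, index=False, float_format="%.6g")


def write_partition_csv(path, partition: SubintervalPartition) -> None:
    pd.DataFrame({"boundary_D_mm2_per_s": partition.boundaries}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_partition_csv(path, grid: DGrid) -> SubintervalPartition:
    df = pd.read_csv(path)
    if "boundary_D_mm2_per_s" not in df.columns:
        raise ParseError(f"{path}: expected column boundary_D_mm2_per_s")
    return SubintervalPartition(df["boundary_D_mm2_per_s"].to_numpy(dtype=float), grid)


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return config


def dump_config(path, config: dict) -> None:
    """Write the resolved configuration next to outputs (reproducibility)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
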