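"""Spectra container, CSV I/O and the NIR preprocessing chain.

The container is a thin wrapper over a wavelength grid (nm), an absorbance
matrix (samples x channels) and a per-sample metadata table.  Every
preprocessing operation returns a new :class:`SpectraSet` and appends a
:class:`TransformRecord`, so a pipeline is replayable from the provenance
list.

Preprocessing operations implemented here:

``mask_regions``
    Keep only channels inside a list of closed wavelength ranges (the
    instrument regions below 1100 nm and 1850-2050 nm are dropped this way).
``snv``
    Standard Normal Variate: per-spectrum centering and unit-variance
    scaling, removing multiplicative scatter gain and additive offset.
``savitzky_golay``
    Local least-squares polynomial smoothing / differentiation per spectrum.
``difference_spectra``
    Subtract the channel-wise mean of a background (solvent) set, isolating
    the solute-plus-hydration-change signal.
``standardize_columns``
    Channel-wise autoscaling across samples, returning a scaler that applies
    the identical transform to held-out spectra.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

META_COLUMNS = ["id", "analyte", "concentration_mM", "replicate"]


@dataclass(frozen=True)
class TransformRecord:
    """One applied transform: name, parameters, wall-clock timestamp."""

    name: str
    params: dict
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds")
    )


@dataclass
class SpectraSet:
    """Wavelength grid (nm), absorbance matrix and per-sample metadata.

    Invariants (checked in ``__post_init__`` and after every transform):
    the grid is strictly increasing, the matrix has one column per grid
    point and one row per metadata record, and no transform introduces NaN.
    """

    grid: np.ndarray            # (p,) wavelengths, nm, strictly increasing
    absorbance: np.ndarray      # (n, p) absorbance units
    meta: pd.DataFrame          # n rows; columns META_COLUMNS
    provenance: list[TransformRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.grid.ndim != 1 or self.grid.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        n, p = self.absorbance.shape
        if p != self.grid.size:
            raise ValueError(
                f"absorbance has {p} channels but grid has {self.grid.size}"
            )
        if len(self.meta) != n:
            raise ValueError(f"meta has {len(self.meta)} rows for {n} spectra")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    def _derive(self, absorbance, record: TransformRecord, grid=None) -> "SpectraSet":
        out = SpectraSet(
            grid=self.grid.copy() if grid is None else grid,
            absorbance=absorbance,
            meta=self.meta.copy().reset_index(drop=True),
            provenance=[*self.provenance, record],
        )
        return out

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            grid=self.grid.copy(),
            absorbance=self.absorbance.copy(),
            meta=self.meta.copy().reset_index(drop=True),
            provenance=list(self.provenance),
        )


# ---------------------------------------------------------------------------
# CSV I/O.  Dialect: leading columns id,analyte,concentration_mM,replicate,
# remaining headers are wavelengths in nm; '.' decimal, UTF-8.
# ---------------------------------------------------------------------------

def write_spectra_table(sset: SpectraSet, path) -> None:
    """Write a SpectraSet as CSV (metadata columns then wavelength columns)."""
    wl_cols = [f"{w:.6g}" for w in sset.grid]
    df = pd.concat(
        [
            sset.meta[META_COLUMNS].reset_index(drop=True),
            pd.DataFrame(sset.absorbance, columns=wl_cols),
        ],
        axis=1,
    )
    df.to_csv(path, index=False)


def read_spectra_table(path) -> SpectraSet:
    """Read the CSV dialect written by :func:`write_spectra_table`.

    Raises ``ValueError`` with a descriptive message on non-monotone or
    duplicated wavelength headers, ragged rows or unparseable concentrations.
    """
    with open(path, encoding="utf-8") as fh:
        raw_header = next(csv.reader(fh))
    raw_wl = [c for c in raw_header if c not in META_COLUMNS]
    if len(set(raw_wl)) != len(raw_wl):
        raise ValueError("duplicated wavelength column in header")
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spectra table missing metadata columns: {missing}")
    wl_cols = [c for c in df.columns if c not in META_COLUMNS]
    try:
        grid = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header: {exc}") from exc
    if np.any(np.diff(grid) <= 0):
        raise ValueError("wavelength headers are not strictly increasing")
    conc = pd.to_numeric(df["concentration_mM"], errors="coerce")
    if conc.isna().any():
        bad = df.loc[conc.isna(), "id"].tolist()[:5]
        raise ValueError(f"unparseable concentration_mM for samples {bad}")
    meta = df[META_COLUMNS].copy()
    meta["concentration_mM"] = conc
    absorbance = df[wl_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(absorbance)):
        raise ValueError("spectra table contains missing/non-numeric absorbance")
    return SpectraSet(grid=grid, absorbance=absorbance, meta=meta)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def mask_regions(sset: SpectraSet, include_ranges) -> SpectraSet:
    """Keep only channels whose wavelength lies in any closed [lo, hi] range."""
    include_ranges = [(float(lo), float(hi)) for lo, hi in include_ranges]
    keep = np.zeros(sset.n_channels, dtype=bool)
    for lo, hi in include_ranges:
        keep |= (sset.grid >= lo) & (sset.grid <= hi)
    if not keep.any():
        raise ValueError(f"mask_regions: no channels inside {include_ranges}")
    rec = TransformRecord("mask_regions", {"include_ranges": include_ranges})
    return sset._derive(sset.absorbance[:, keep], rec, grid=sset.grid[keep])


def snv(sset: SpectraSet) -> SpectraSet:
    """Standard Normal Variate: (row - row mean) / row sd, sd with n-1."""
    if sset.n_channels < 2:
        raise ValueError("SNV needs at least 2 channels per spectrum")
    mu = sset.absorbance.mean(axis=1, keepdims=True)
    sd = sset.absorbance.std(axis=1, ddof=1, keepdims=True)
    flat = np.where(sd.ravel() == 0)[0]
    if flat.size:
        ids = sset.meta["id"].iloc[flat].tolist()
        raise ValueError(f"SNV undefined for constant spectra: samples {ids}")
    rec = TransformRecord("snv", {})
    return sset._derive((sset.absorbance - mu) / sd, rec)


def savitzky_golay(
    sset: SpectraSet, window: int = 9, polyorder: int = 2, derivative_order: int = 0
) -> SpectraSet:
    """Savitzky-Golay smoothing / differentiation per spectrum.

    Edges are handled by evaluating the polynomial fitted to the last full
    window ('interp' mode), so a global polynomial of degree <= polyorder is
    reproduced exactly everywhere.  Derivatives are with respect to channel
    index scaled by the (uniform) grid spacing.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if derivative_order > polyorder:
        raise ValueError("derivative_order must not exceed polyorder")
    if window >= sset.n_channels:
        raise ValueError(
            f"window {window} must be smaller than channel count {sset.n_channels}"
        )
    delta = float(np.mean(np.diff(sset.grid)))
    out = savgol_filter(
        sset.absorbance, window_length=window, polyorder=polyorder,
        deriv=derivative_order, delta=delta, axis=1, mode="interp",
    )
    rec = TransformRecord(
        "savitzky_golay",
        {"window": window, "polyorder": polyorder, "derivative_order": derivative_order},
    )
    return sset._derive(out, rec)


def difference_spectra(sset: SpectraSet, background: SpectraSet) -> SpectraSet:
    """Subtract the channel-wise mean of the background rows from every sample."""
    if sset.grid.size != background.grid.size or np.any(sset.grid != background.grid):
        if sset.grid.size == background.grid.size:
            i = int(np.argmax(sset.grid != background.grid))
            raise ValueError(
                f"grid mismatch at index {i}: {sset.grid[i]} nm vs "
                f"{background.grid[i]} nm"
            )
        raise ValueError(
            f"grid mismatch: {sset.grid.size} vs {background.grid.size} channels"
        )
    bg_mean = background.absorbance.mean(axis=0)
    rec = TransformRecord("difference_spectra", {"n_background": background.n_samples})
    return sset._derive(sset.absorbance - bg_mean, rec)


@dataclass(frozen=True)
class ColumnScaler:
    """Channel-wise centering/scaling fitted on a training set."""

    mean: np.ndarray
    scale: np.ndarray           # 1.0 for zero-variance channels (center only)
    zero_variance: np.ndarray   # boolean flags

    def apply(self, absorbance: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(absorbance) - self.mean) / self.scale


def standardize_columns(sset: SpectraSet):
    """Autoscale each channel across samples; return (set, ColumnScaler).

    Zero-variance channels are centered only and flagged in the scaler (a
    warning record is appended to provenance rather than raising).
    """
    if sset.n_samples < 2:
        raise ValueError("column standardization needs at least 2 samples")
    mean = sset.absorbance.mean(axis=0)
    sd = sset.absorbance.std(axis=0, ddof=1)
    zero = sd == 0
    scale = np.where(zero, 1.0, sd)
    scaler = ColumnScaler(mean=mean, scale=scale, zero_variance=zero)
    rec = TransformRecord(
        "standardize_columns", {"n_zero_variance_channels": int(zero.sum())}
    )
    return sset._derive(scaler.apply(sset.absorbance), rec), scaler
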