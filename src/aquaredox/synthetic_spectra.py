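"""Synthetic NIR concentration-series generator with exact ground truth.

Emulates transmittance series of redox couples (GSH/GSSG, NADH/NAD+) in PBS:
1-10 mM in 1 mM steps, 25 replicate spectra per level, on a 1100-2400 nm
instrument grid.  Each spectrum is a Beer-Lambert mixture

    A(lambda) = gain * (background(lambda) + c * signature(lambda))
                + offset + slope * (lambda - lambda_mid) + noise,

where ``background`` is the PBS water spectrum (first overtone near 1450 nm
plus the combination band near 1940 nm), ``signature`` is the analyte's
molar solvation signature (Gaussian bands; positive solvation-shell bands
near 1362/1381 nm for reduced species, a negative water-displacement band at
1450 nm, amide combination bands at 2175/2279 nm), ``gain`` is a
multiplicative scatter factor and offset/slope are baseline artifacts.

The generator returns the sampled spectra together with a
:class:`GroundTruth` record (per-sample analyte, concentration, outlier
flag, and the noiseless background and molar signatures), so every
downstream claim — band positions in regression vectors, outlier recovery,
linearity — can be checked against construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from aquaredox.spectra_core import SpectraSet


@dataclass(frozen=True)
class AnalyteSignature:
    """Molar solvation signature: a sum of Gaussian bands.

    ``band_amplitudes_per_mM`` are absorbance units per mM and may be
    negative (water-displacement bands).
    """

    name: str
    band_centers: tuple      # nm
    band_widths: tuple       # Gaussian sigma, nm
    band_amplitudes_per_mM: tuple  # AU / mM

    def __post_init__(self):
        if not (len(self.band_centers) == len(self.band_widths)
                == len(self.band_amplitudes_per_mM)):
            raise ValueError(f"{self.name}: band lists must have equal length")
        if any(w <= 0 for w in self.band_widths):
            raise ValueError(f"{self.name}: band widths must be positive")

    def molar_spectrum(self, grid: np.ndarray) -> np.ndarray:
        """Signature at 1 mM on the given grid (AU per mM per channel)."""
        grid = np.asarray(grid, dtype=float)
        lo, hi = grid[0], grid[-1]
        out = np.zeros_like(grid)
        for c, w, a in zip(self.band_centers, self.band_widths,
                           self.band_amplitudes_per_mM):
            if not (lo <= c <= hi):
                raise ValueError(
                    f"{self.name}: band at {c} nm outside grid [{lo}, {hi}] nm"
                )
            out += a * np.exp(-0.5 * ((grid - c) / w) ** 2)
        return out


# Default signatures.  Reduced species carry the 1362/1381 nm first-shell
# hydration bands; oxidized species lack them and displace more bulk water
# (deeper negative 1450 nm band).  Both glutathione forms share the amide
# combination bands at 2175/2279 nm.  Amplitudes are set so the 10 mM bands
# are a few percent of the background absorbance; they are tunable model
# parameters, not measured molar absorptivities.
GSH = AnalyteSignature(
    name="GSH",
    band_centers=(1362.0, 1381.0, 1450.0, 2175.0, 2279.0),
    band_widths=(6.0, 6.0, 35.0, 15.0, 15.0),
    band_amplitudes_per_mM=(2.0e-3, 1.6e-3, -1.2e-3, 1.0e-3, 1.0e-3),
)
GSSG = AnalyteSignature(
    name="GSSG",
    band_centers=(1450.0, 2175.0, 2279.0),
    band_widths=(35.0, 15.0, 15.0),
    band_amplitudes_per_mM=(-2.4e-3, 1.0e-3, 1.0e-3),
)
NADH = AnalyteSignature(
    name="NADH",
    band_centers=(1363.0, 1450.0, 2175.0, 2279.0),
    band_widths=(6.0, 35.0, 15.0, 15.0),
    band_amplitudes_per_mM=(2.0e-3, -1.2e-3, 1.0e-3, 1.0e-3),
)
NAD_PLUS = AnalyteSignature(
    name="NAD+",
    band_centers=(1383.0, 1450.0, 2175.0, 2279.0),
    band_widths=(6.0, 35.0, 15.0, 15.0),
    band_amplitudes_per_mM=(1.4e-3, -2.0e-3, 1.0e-3, 1.0e-3),
)
SIGNATURES = {s.name: s for s in (GSH, GSSG, NADH, NAD_PLUS)}


@dataclass(frozen=True)
class ExperimentDesign:
    """Concentration-series design: analytes x levels x replicates."""

    analytes: tuple = (GSH, GSSG)
    concentrations_mM: tuple = tuple(float(c) for c in range(1, 11))
    replicates_per_level: int = 25
    grid_start_nm: float = 1100.0
    grid_stop_nm: float = 2400.0
    grid_step_nm: float = 2.0
    noise_sd: float = 1e-3          # AU, additive per channel
    scatter_gain_sd: float = 0.01   # multiplicative, unitless
    baseline_offset_sd: float = 5e-4  # AU
    baseline_slope_sd: float = 1e-7   # AU / nm
    outlier_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(c <= 0 for c in self.concentrations_mM):
            raise ValueError("concentrations must be positive")
        if self.replicates_per_level < 1:
            raise ValueError("replicates_per_level must be >= 1")
        if self.grid_step_nm <= 0:
            raise ValueError("grid step must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier_fraction must be in [0, 1]")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop_nm - self.grid_start_nm) / self.grid_step_nm)) + 1
        return self.grid_start_nm + self.grid_step_nm * np.arange(n)


@dataclass
class GroundTruth:
    """What the generator actually put into each spectrum."""

    per_sample: pd.DataFrame        # id, analyte, concentration_mM, replicate, outlier
    background: np.ndarray          # noiseless PBS spectrum on the grid
    molar_signatures: dict          # analyte name -> noiseless 1 mM signature


# PBS background: broad water first-overtone band near 1450 nm, the stronger
# combination-region band near 1940 nm (masked out downstream), mild offset.
_BG_BANDS = ((1450.0, 70.0, 0.55), (1940.0, 90.0, 1.10))  # (center, sigma, AU)
_BG_OFFSET = 0.08


def pbs_background(grid: np.ndarray) -> np.ndarray:
    """Deterministic noiseless PBS absorbance spectrum on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavelength grid")
    out = np.full_like(grid, _BG_OFFSET)
    for c, w, a in _BG_BANDS:
        out += a * np.exp(-0.5 * ((grid - c) / w) ** 2)
    return out


def generate_spectra_set(design: ExperimentDesign):
    """Sample a full concentration-series dataset.

    Returns ``(SpectraSet, GroundTruth)``.  Reproducible: identical design
    (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(design.seed)
    grid = design.grid
    bg = pbs_background(grid)
    lam_mid = 0.5 * (grid[0] + grid[-1])

    signatures = {a.name: a.molar_spectrum(grid) for a in design.analytes}

    rows, meta = [], []
    for analyte in design.analytes:
        sig = signatures[analyte.name]
        for conc in design.concentrations_mM:
            clean = bg + conc * sig
            for rep in range(design.replicates_per_level):
                gain = 1.0 + design.scatter_gain_sd * rng.standard_normal()
                offset = design.baseline_offset_sd * rng.standard_normal()
                slope = design.baseline_slope_sd * rng.standard_normal()
                noise = design.noise_sd * rng.standard_normal(grid.size)
                rows.append(gain * clean + offset + slope * (grid - lam_mid) + noise)
                meta.append(
                    {
                        "id": f"{analyte.name}_{conc:g}mM_r{rep:02d}",
                        "analyte": analyte.name,
                        "concentration_mM": float(conc),
                        "replicate": rep,
                    }
                )

    sset = SpectraSet(
        grid=grid, absorbance=np.vstack(rows), meta=pd.DataFrame(meta)
    )
    truth_df = sset.meta.copy()
    truth_df["outlier"] = False
    truth = GroundTruth(
        per_sample=truth_df, background=bg, molar_signatures=signatures
    )

    if design.outlier_fraction > 0:
        sset, flags = inject_outliers(
            sset, design.outlier_fraction, magnitude=0.5,
            seed=design.seed + 1,
        )
        truth.per_sample["outlier"] = flags
    return sset, truth


def generate_mixture_set(
    pairs_mM=None,
    replicates_per_level: int = 25,
    analytes=(GSH, GSSG),
    noise_sd: float = 1e-3,
    scatter_gain_sd: float = 0.01,
    seed: int = 0,
    grid: np.ndarray | None = None,
):
    """Two-analyte mixture series (default: the GSH:GSSG pairing scheme
    1:4.5, 2:4, ..., 9:0.5 mM, i.e. GSSG at half the molar deficit of GSH).

    Returns ``(SpectraSet, Y)`` where ``Y`` is samples x 2 true
    concentrations in the order of ``analytes``.
    """
    if pairs_mM is None:
        pairs_mM = [(float(g), (10.0 - g) / 2.0) for g in range(1, 10)]
    design = ExperimentDesign()
    grid = design.grid if grid is None else np.asarray(grid, dtype=float)
    bg = pbs_background(grid)
    sigs = [a.molar_spectrum(grid) for a in analytes]
    rng = np.random.default_rng(seed)

    rows, meta, ys = [], [], []
    for c1, c2 in pairs_mM:
        clean = bg + c1 * sigs[0] + c2 * sigs[1]
        for rep in range(replicates_per_level):
            gain = 1.0 + scatter_gain_sd * rng.standard_normal()
            noise = noise_sd * rng.standard_normal(grid.size)
            rows.append(gain * clean + noise)
            meta.append(
                {
                    "id": f"mix_{c1:g}_{c2:g}_r{rep:02d}",
                    "analyte": f"{analytes[0].name}+{analytes[1].name}",
                    "concentration_mM": float(c1),
                    "replicate": rep,
                }
            )
            ys.append((c1, c2))
    sset = SpectraSet(grid=grid, absorbance=np.vstack(rows), meta=pd.DataFrame(meta))
    return sset, np.asarray(ys, dtype=float)


def inject_outliers(sset: SpectraSet, fraction: float, magnitude: float, seed: int):
    """Perturb floor(fraction * n) randomly chosen spectra with a gross
    artifact: a constant offset plus a smooth full-range ripple of
    amplitude ``magnitude`` (random phase) plus a narrow spike.

    Returns ``(new SpectraSet, boolean flags)``.  The ripple distorts the
    spectral *shape* across the whole grid, so the artifact survives
    row-wise normalization (SNV) and region masking and is caught by the
    PCA/Mahalanobis screen.
    """
    if not 0 <= fraction <= 0.5:
        raise ValueError("outlier fraction must be in [0, 0.5]")
    if magnitude <= 0:
        raise ValueError("outlier magnitude must be positive")
    n = sset.n_samples
    k = int(np.floor(fraction * n))
    flags = np.zeros(n, dtype=bool)
    out = sset.copy()
    if k:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=k, replace=False)
        flags[idx] = True
        spike_ch = rng.integers(0, sset.n_channels, size=k)
        phases = rng.uniform(0, 2 * np.pi, size=k)
        for i, ch, phi in zip(idx, spike_ch, phases):
            ripple = magnitude * np.sin(2 * np.pi * sset.grid / 200.0 + phi)
            out.absorbance[i] += magnitude + ripple
            out.absorbance[i, ch] += 5.0 * magnitude
    from aquaredox.spectra_core import TransformRecord

    out.provenance.append(
        TransformRecord(
            "inject_outliers",
            {"fraction": fraction, "magnitude": magnitude, "seed": seed, "n_flagged": k},
        )
    )
    return out, flags
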