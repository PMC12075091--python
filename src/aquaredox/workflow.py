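"""End-to-end drivers tying generators, preprocessing, modeling and
hydration analysis into the two reproducible workflows.

``run_spectra_quant``
    concentration series -> mask -> SNV -> Savitzky-Golay -> PCA/Mahalanobis
    outlier screen -> difference vs PBS -> OSC(1) -> NIPALS PLS ->
    leave-one-out CV -> regression-vector peaks.
``run_mixture_quant``
    two-analyte mixtures -> mask 1300-1600 nm -> difference vs PBS ->
    PCR (two responses) -> leave-five-spectra-out CV -> dual peaks.
    No SNV/SG in this branch by design.
``run_hydration``
    solvation trajectory -> S-water RDF (first peak, coordination number)
    -> directional H-bond intervals -> interaction scores, total and per
    sulfur.

Every run is reproducible from (config, seed); the returned report embeds
both.  Configs are flat dataclasses loadable from YAML; unknown keys are
rejected.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from aquaredox import chemometrics as chem
from aquaredox import hydration as hyd
from aquaredox import spectra_core as core
from aquaredox import synthetic_spectra as synth
from aquaredox import synthetic_trajectory as straj

log = logging.getLogger("aquaredox")

DEFAULT_MASK = ((1100.0, 1850.0), (2050.0, 2400.0))
WATER_FIRST_OVERTONE = (1300.0, 1600.0)


def _rel_prominence(b, grid, window, frac: float = 0.05) -> float:
    """Prominence floor at ``frac`` of the largest |b| inside the window —
    suppresses noise wiggles without touching designed bands."""
    sel = (grid >= window[0]) & (grid <= window[1])
    return float(frac * np.max(np.abs(np.asarray(b)[sel])))


def _stage(name: str, **info):
    log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in info.items()))


@dataclass
class SpectraQuantConfig:
    analyte: str = "GSH"
    seed: int = 0
    outlier_fraction: float = 0.0
    mask: tuple = DEFAULT_MASK
    sg_window: int = 9
    sg_polyorder: int = 2
    osc_components: int = 1
    n_lv: int | str = "auto"          # int or "auto" (CV-minimizing, cap 10)
    max_lv: int = 10
    cv_scheme: str = "loo"
    peak_window: tuple = WATER_FIRST_OVERTONE
    replicates_per_level: int = 25


@dataclass
class MixtureQuantConfig:
    seed: int = 0
    mask: tuple = (WATER_FIRST_OVERTONE,)
    k_pc: int | str = "auto"
    max_pc: int = 10
    k_out: int = 5
    replicates_per_level: int = 25


@dataclass
class HydrationConfig:
    solute_kind: str = "thiol"
    n_waters: int = 200
    n_frames: int = 2000
    box: tuple = (30.0, 30.0, 30.0)
    occupancy: float = 0.6
    mean_residence: float = 20.0
    seed: int = 0
    bin_width: float = 0.1
    r_max: float | None = 10.0
    min_persistence: int = 1
    weight_exponent: float = 0.0
    last_frames: int | None = None    # analyze only the trailing window
    xyz_path: str | None = None       # analyze an existing trajectory instead
    topology_path: str | None = None


def load_config(path, kind: str):
    """Load a flat YAML config; unknown keys are errors."""
    cls = {
        "spectra_quant": SpectraQuantConfig,
        "mixture_quant": MixtureQuantConfig,
        "hydration": HydrationConfig,
    }[kind]
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys for {kind}: {sorted(unknown)}")
    for key in ("mask", "box", "peak_window"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(
                tuple(v) if isinstance(v, list) else v for v in data[key]
            )
    return cls(**data)


# ---------------------------------------------------------------------------
# Spectra quantification (single analyte series)
# ---------------------------------------------------------------------------

def preprocess_series(sset, cfg: SpectraQuantConfig):
    """mask -> SNV -> SG, applied identically to samples and background."""
    grid = sset.grid
    bg = core.SpectraSet(
        grid=grid,
        absorbance=np.tile(synth.pbs_background(grid), (2, 1)),
        meta=pd.DataFrame(
            {"id": ["PBS_0", "PBS_1"], "analyte": "PBS",
             "concentration_mM": 0.0, "replicate": [0, 1]}
        ),
    )
    chain = []
    for s in (sset, bg):
        s = core.mask_regions(s, cfg.mask)
        s = core.snv(s)
        s = core.savitzky_golay(s, window=cfg.sg_window, polyorder=cfg.sg_polyorder)
        chain.append(s)
    return chain[0], chain[1]


def run_spectra_quant(config: SpectraQuantConfig) -> dict:
    """Single-analyte concentration calibration; returns the run report."""
    cfg = config
    sig = synth.SIGNATURES[cfg.analyte]
    design = synth.ExperimentDesign(
        analytes=(sig,), outlier_fraction=cfg.outlier_fraction, seed=cfg.seed,
        replicates_per_level=cfg.replicates_per_level,
    )
    _stage("generate", analyte=cfg.analyte, seed=cfg.seed)
    sset, truth = synth.generate_spectra_set(design)

    _stage("preprocess", mask=cfg.mask, sg_window=cfg.sg_window)
    proc, bg = preprocess_series(sset, cfg)

    _stage("outlier_screen")
    pca, report = chem.screen_outliers(proc.absorbance)
    kept = report.kept
    removed_ids = proc.meta["id"][report.removed].tolist()

    diff = core.difference_spectra(proc, bg)
    X = diff.absorbance[kept]
    y = proc.meta["concentration_mM"].to_numpy()[kept]

    if cfg.n_lv == "auto":
        n_lv = chem.select_n_lv(X, y, max_lv=cfg.max_lv, seed=cfg.seed,
                                osc_components=cfg.osc_components)
    else:
        n_lv = int(cfg.n_lv)
    _stage("cross_validate", scheme=cfg.cv_scheme, n_lv=n_lv,
           osc=cfg.osc_components)
    cv = chem.cross_validate(X, y, scheme=cfg.cv_scheme, seed=cfg.seed,
                             n_lv=n_lv, osc_components=cfg.osc_components)

    # final model on all kept samples for the regression vector
    Xc = X
    if cfg.osc_components:
        osc, Xc = chem.fit_osc(Xc, y, n_components=cfg.osc_components)
    model = chem.fit_plsr(Xc, y, n_lv=n_lv, grid=diff.grid)
    peaks = chem.regression_vector_peaks(
        model, wavelength_window=cfg.peak_window,
        min_prominence=_rel_prominence(model.b, diff.grid, cfg.peak_window),
    )

    rmse_cal, r2_cal = chem.metrics(y, chem.predict(model, Xc))
    report_out = {
        "workflow": "spectra_quant",
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "n_samples": int(sset.n_samples),
        "n_removed_outliers": int(report.removed.sum()),
        "removed_ids": removed_ids,
        "true_outlier_ids": truth.per_sample["id"][
            truth.per_sample["outlier"]].tolist(),
        "n_lv": n_lv,
        "cv": {
            "scheme": cv.scheme, "rmse_mM": cv.rmse, "r2": cv.r2,
            "residual_mean_mM": float(np.mean(cv.y_pred - cv.y_true)),
            "residual_se_mM": float(np.std(cv.y_pred - cv.y_true, ddof=1)
                                    / np.sqrt(cv.y_true.size)),
        },
        "calibration": {"rmse_mM": rmse_cal, "r2": r2_cal},
        "peaks_nm": peaks[:5],
        "regression_vector": {"grid_nm": diff.grid.tolist(),
                              "b": model.b.tolist()},
    }
    return report_out


# ---------------------------------------------------------------------------
# Mixture quantification (PCR, two responses)
# ---------------------------------------------------------------------------

def run_mixture_quant(config: MixtureQuantConfig) -> dict:
    cfg = config
    _stage("generate_mixtures", seed=cfg.seed)
    sset, Y = synth.generate_mixture_set(
        seed=cfg.seed, replicates_per_level=cfg.replicates_per_level
    )
    bg = core.SpectraSet(
        grid=sset.grid,
        absorbance=np.tile(synth.pbs_background(sset.grid), (2, 1)),
        meta=pd.DataFrame(
            {"id": ["PBS_0", "PBS_1"], "analyte": "PBS",
             "concentration_mM": 0.0, "replicate": [0, 1]}
        ),
    )
    # the mixture branch: restrict to the water first overtone, subtract
    # PBS; no SNV/SG.
    proc = core.mask_regions(sset, cfg.mask)
    bgp = core.mask_regions(bg, cfg.mask)
    diff = core.difference_spectra(proc, bgp)
    X = diff.absorbance

    if cfg.k_pc == "auto":
        best, best_rmse = 1, np.inf
        for k in range(1, cfg.max_pc + 1):
            cv_k = chem.cross_validate(X, Y, scheme="leave_k_out",
                                       k_out=cfg.k_out, seed=cfg.seed,
                                       model="pcr", k_pc=k)
            if cv_k.rmse < best_rmse - 1e-12:
                best, best_rmse = k, cv_k.rmse
        k_pc = best
    else:
        k_pc = int(cfg.k_pc)
    _stage("cross_validate", scheme="leave_k_out", k_out=cfg.k_out, k_pc=k_pc)
    cv = chem.cross_validate(X, Y, scheme="leave_k_out", k_out=cfg.k_out,
                             seed=cfg.seed, model="pcr", k_pc=k_pc)
    model = chem.fit_pcr(X, Y, k=k_pc, grid=diff.grid)
    per_analyte = {}
    for j, name in enumerate(("GSH", "GSSG")):
        rmse_j, r2_j = chem.metrics(Y[:, j], cv.y_pred[:, j])
        peaks = chem.regression_vector_peaks(
            model.B[:, j], wavelength_window=WATER_FIRST_OVERTONE,
            grid=diff.grid,
            min_prominence=_rel_prominence(model.B[:, j], diff.grid,
                                           WATER_FIRST_OVERTONE),
        )
        per_analyte[name] = {"rmse_mM": rmse_j, "r2": r2_j,
                             "peaks_nm": peaks[:5]}
    return {
        "workflow": "mixture_quant",
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "k_pc": k_pc,
        "per_analyte": per_analyte,
        "regression_vectors": {"grid_nm": diff.grid.tolist(),
                               "B": model.B.tolist()},
    }


# ---------------------------------------------------------------------------
# Hydration
# ---------------------------------------------------------------------------

def run_hydration(config: HydrationConfig) -> dict:
    cfg = config
    if cfg.xyz_path:
        _stage("read_trajectory", xyz=cfg.xyz_path)
        traj = hyd.read_trajectory(cfg.xyz_path, cfg.topology_path)
        schedule = None
    else:
        _stage("generate_trajectory", kind=cfg.solute_kind, seed=cfg.seed)
        traj, schedule = straj.generate_solvation_trajectory(
            solute_kind=cfg.solute_kind, n_waters=cfg.n_waters,
            n_frames=cfg.n_frames, box=cfg.box, occupancy=cfg.occupancy,
            mean_residence=cfg.mean_residence, seed=cfg.seed,
        )
    n_sulfur = traj.topology.atoms_with_role("sulfur").size

    _stage("rdf", bin_width=cfg.bin_width)
    rdf = hyd.compute_rdf(traj, "sulfur", "water_oxygen",
                          bin_width=cfg.bin_width, r_max=cfg.r_max)
    try:
        r_peak, g_peak = hyd.first_peak(rdf, min_g=1.0)
        # a first-shell peak must stand significantly above the bulk
        # expectation; Poisson ripples around g = 1 do not count
        i = int(np.argmin(np.abs(rdf.bin_centers - r_peak)))
        half = 0.5 * rdf.bin_width
        v_shell = 4.0 / 3.0 * np.pi * ((rdf.bin_centers[i] + half) ** 3
                                       - (rdf.bin_centers[i] - half) ** 3)
        n_exp = rdf.bulk_density * v_shell * n_sulfur * traj.n_frames
        z = (g_peak - 1.0) * n_exp / np.sqrt(max(n_exp, 1.0))
        if z < 5.0 and g_peak < 1.5:
            raise ValueError("no significant first-shell peak")
        peak_info = {"r_A": r_peak, "g": g_peak}
        # coordination number up to the first minimum after the peak
        after = rdf.bin_centers > r_peak
        gmin_idx = np.argmin(rdf.g[after][: int(3.0 / cfg.bin_width)])
        r_min = float(rdf.bin_centers[after][gmin_idx])
        n_coord = hyd.coordination_number(rdf, r_min)
        peak_info["first_minimum_A"] = r_min
        peak_info["coordination_number"] = n_coord
    except ValueError:
        peak_info = {"note": "no first-shell structure (no RDF peak)"}

    window = None
    if cfg.last_frames:
        window = (max(0, traj.n_frames - cfg.last_frames), traj.n_frames - 1)
    _stage("hbond_intervals", window=window)
    ivs = hyd.bond_intervals(traj, window=window)
    scores = {
        d: hyd.interaction_score(ivs, d, cfg.min_persistence,
                                 cfg.weight_exponent)
        for d in ("OH-S", "SH-O")
    }
    summary = hyd.per_sulfur_summary(scores, n_sulfur)
    return {
        "workflow": "hydration",
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "n_sulfur": int(n_sulfur),
        "rdf_first_peak": peak_info,
        "scores": summary,
        "n_schedule_intervals": None if schedule is None
        else len(schedule.intervals),
    }


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
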