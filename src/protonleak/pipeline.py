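"""End-to-end orchestration: simulate -> conductance -> inhibition -> fcs -> turnover.

A run is driven by an :class:`ExperimentConfig` (YAML on disk), executes the
requested stages in dependency order inside an output directory, writes one
JSON record per stage plus a run manifest with SHA-256 hashes of every file
produced, and is idempotent for a fixed seed (manifests differ only by
timestamp).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .conductance import fit_ohmic_conductance
from .dose_response import bootstrap_ci, compare_compounds, fit_inhibition
from .exceptions import InvalidInputError, StageDependencyError
from .fcs import fit_autocorrelation, protein_lipid_ratio, proteins_per_liposome
from .io import (read_dose_csv, read_fcs_csv, read_iv_csv, write_dose_csv,
                 write_fcs_csv, write_iv_csv, _jsonable)
from .synth import GeneratorConfig, gen_dose_response, gen_fcs_curve, gen_iv_trace
from .turnover import nernst_potential, protein_surface_density, turnover_number

__all__ = ["ExperimentConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "conductance", "inhibition", "fcs_count", "turnover")

# files each stage consumes -> the stage that produces them
_STAGE_INPUTS = {
    "conductance": {"iv_ref": "simulate", "iv_control": "simulate", "iv_shifted": "simulate"},
    "inhibition": {"dose": "simulate"},
    "fcs_count": {"fcs_before": "simulate", "fcs_after": "simulate"},
}
_STAGE_DEPS = {"turnover": ("conductance", "fcs_count")}


@dataclass
class ExperimentConfig:
    """Structured description of one experiment / simulation run."""

    seed: int = 0
    temperature_K: float = 306.0
    membrane_area_cm2: float = 1.13e-4
    buffer: dict = field(default_factory=lambda: {
        "Na2SO4_mM": 50.0, "Tris_mM": 10.0, "MES_mM": 10.0, "EGTA_mM": 0.6,
        "pH_cis": 7.34, "pH_trans": 7.34,
    })
    lipid_composition: dict = field(default_factory=lambda: {"PC": 45.0, "PE": 45.0, "CL": 10.0})
    fatty_acid: dict = field(default_factory=lambda: {"species": "AA", "mol_percent": 15.0})
    stages: tuple = STAGES
    simulate: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # external file paths per input key
    analysis: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in ("pH_cis", "pH_trans"):
            ph = float(self.buffer.get(key, 7.0))
            if not 0.0 <= ph <= 14.0:
                raise InvalidInputError(f"{key} = {ph} outside [0, 14]")
        total = sum(float(v) for v in self.lipid_composition.values())
        if abs(total - 100.0) > 0.1:
            raise InvalidInputError(f"lipid mol% sums to {total}, not 100 +/- 0.1")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise InvalidInputError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def check_dependencies(self) -> None:
        """Every requested stage must get its inputs from an earlier requested
        stage or from an existing external file; otherwise raise naming the
        missing stage."""
        requested = set(self.stages)
        for stage in self.stages:
            for key, producer in _STAGE_INPUTS.get(stage, {}).items():
                if producer in requested:
                    continue
                path = self.inputs.get(key)
                if path is None or not Path(path).exists():
                    raise StageDependencyError(
                        f"stage '{stage}' needs input '{key}' but stage "
                        f"'{producer}' is not requested and no existing file is configured"
                    )
            for dep in _STAGE_DEPS.get(stage, ()):
                if dep not in requested:
                    raise StageDependencyError(
                        f"stage '{stage}' requires stage '{dep}' to run first"
                    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))


def _input_path(cfg: ExperimentConfig, out: Path, key: str, default_name: str) -> Path:
    if key in cfg.inputs:
        return Path(cfg.inputs[key])
    return out / default_name


# ---------------------------------------------------------------- stages

def _stage_simulate(cfg: ExperimentConfig, out: Path) -> list[Path]:
    sim = cfg.simulate
    area = cfg.membrane_area_cm2
    iv = sim.get("iv", {})
    g_total = float(iv.get("G_total", 1750.0))
    g_control = float(iv.get("G_control", 440.0))
    shift = float(iv.get("reversal_shift_mV", 49.0))
    noise_i = float(iv.get("noise_sd_current", 0.5))
    grid = np.asarray(iv.get("voltage_grid", np.arange(-50.0, 51.0, 10.0)), dtype=float)

    # distinct sub-seeds per generated object, all derived from the run seed
    sub = iter(np.random.SeedSequence(cfg.seed).generate_state(16).tolist())

    def gcfg(**kw) -> GeneratorConfig:
        return GeneratorConfig(seed=next(sub) % (2**31), voltage_grid=grid,
                               noise_sd_current=noise_i, **kw)

    files = []
    for name, g_true, offset in (
        ("iv_ref.csv", g_total, 0.0),
        ("iv_control.csv", g_control, 0.0),
        ("iv_shifted.csv", g_total, shift),
    ):
        trace = gen_iv_trace(g_true, area, 0.0, offset, gcfg())
        trace.temperature = cfg.temperature_K
        write_iv_csv(trace, out / name)
        files.append(out / name)

    dose = sim.get("dose", {})
    noise_cv = float(dose.get("noise_cv", 0.05))
    compounds = dose.get("compounds", {
        "CATR": {"ec50_uM": 18.9, "imax_pct": 64.2},
        "BA": {"ec50_uM": 32.3, "imax_pct": 44.3},
    })
    series = []
    for comp in sorted(compounds):
        p = compounds[comp]
        c = GeneratorConfig(seed=next(sub) % (2**31), noise_cv_conductance=noise_cv)
        series.append(gen_dose_response(float(p["ec50_uM"]), float(p["imax_pct"]),
                                        cfg=c, compound=comp))
    import pandas as pd

    frames = [pd.DataFrame({"conc_uM": s.concentration, "rel_conductance": s.rel_conductance,
                            "compound": s.compound, "replicate": 0}) for s in series]
    (out / "dose.csv").write_text(pd.concat(frames).to_csv(index=False))
    files.append(out / "dose.csv")

    fcs = sim.get("fcs", {})
    noise_scale = float(fcs.get("noise_scale", 0.02))
    for name, n_true, tau, label in (
        ("fcs_before.csv", float(fcs.get("n_before", 1.60)),
         float(fcs.get("tauD_before_s", 1.45e-3)), "before-SDS"),
        ("fcs_after.csv", float(fcs.get("n_after", 13.83)),
         float(fcs.get("tauD_after_s", 1.0e-4)), "after-SDS"),
    ):
        c = GeneratorConfig(seed=next(sub) % (2**31), correlation_noise_scale=noise_scale)
        write_fcs_csv(gen_fcs_curve(n_true, tau, c, label=label), out / name)
        files.append(out / name)
    return files


def _stage_conductance(cfg: ExperimentConfig, out: Path) -> list[Path]:
    window = tuple(cfg.analysis.get("fit_window_mV", (-50.0, 50.0)))
    record = {}
    for key, name in (("iv_ref", "iv_ref.csv"), ("iv_control", "iv_control.csv"),
                      ("iv_shifted", "iv_shifted.csv")):
        trace = read_iv_csv(_input_path(cfg, out, key, name))
        res = fit_ohmic_conductance(trace, window)
        record[key] = {
            "G_specific_nS_cm2": res.G_specific,
            "intercept_U0_mV": res.intercept_U0,
            "r_squared": res.r_squared,
            "n_points": res.n_points,
            "fit_window_mV": list(res.fit_window),
        }
    record["G_protein_nS_cm2"] = (
        record["iv_ref"]["G_specific_nS_cm2"] - record["iv_control"]["G_specific_nS_cm2"]
    )
    path = out / "conductance.json"
    _write_json(path, record)
    return [path]


def _stage_inhibition(cfg: ExperimentConfig, out: Path) -> list[Path]:
    n_boot = int(cfg.analysis.get("n_boot", 300))
    free_hill = bool(cfg.analysis.get("free_hill", False))
    fix_hill = None if free_hill else 1.0
    series = read_dose_csv(_input_path(cfg, out, "dose", "dose.csv"))
    fits = []
    for k, s in enumerate(series):
        f = fit_inhibition(s, fix_hill=fix_hill)
        f.ci_ec50, f.ci_imax = bootstrap_ci(
            s, n_boot=n_boot, seed=(cfg.seed + 1000 + k) % (2**31), fix_hill=fix_hill)
        fits.append(f)
    record = {f.compound: {
        "ec50_uM": f.ec50, "imax_pct": f.imax, "hill": f.hill,
        "ci_ec50_uM": list(f.ci_ec50), "ci_imax_pct": list(f.ci_imax),
        "converged": f.converged, "reliable": f.reliable,
    } for f in fits}
    path = out / "inhibition.json"
    _write_json(path, record)
    paths = [path]
    if len(fits) >= 2:
        table = compare_compounds(fits)
        tsv = out / "inhibition_summary.tsv"
        tsv.write_text(table.to_csv(sep="\t", index=False))
        paths.append(tsv)
    return paths


def _stage_fcs_count(cfg: ExperimentConfig, out: Path) -> list[Path]:
    r_nm = float(cfg.analysis.get("radius_nm", 50.0))
    a_l = float(cfg.analysis.get("area_per_lipid_nm2", 0.6))
    before = fit_autocorrelation(read_fcs_csv(_input_path(cfg, out, "fcs_before", "fcs_before.csv")))
    after = fit_autocorrelation(read_fcs_csv(_input_path(cfg, out, "fcs_after", "fcs_after.csv")))
    n_per = proteins_per_liposome(after.n, before.n)
    stoich = protein_lipid_ratio(n_per, r_nm, a_l)
    record = {
        "n_before": before.n, "tauD_before_s": before.tau_D, "D_before_um2_s": before.D,
        "n_after": after.n, "tauD_after_s": after.tau_D, "D_after_um2_s": after.D,
        "proteins_per_liposome": n_per,
        "lipids_per_liposome": stoich.N_lipids_per_liposome,
        "rho_protein_per_lipid": stoich.rho,
        "lipids_per_protein": stoich.one_to,
        "ratio_display": stoich.one_to_display,
        "radius_nm": r_nm, "area_per_lipid_nm2": a_l,
    }
    path = out / "stoichiometry.json"
    _write_json(path, record)
    return [path]


def _stage_turnover(cfg: ExperimentConfig, out: Path) -> list[Path]:
    cond = json.loads((out / "conductance.json").read_text())
    stoich = json.loads((out / "stoichiometry.json").read_text())
    g_mode = str(cfg.analysis.get("g_mode", "protein"))
    delta_u = cond["iv_shifted"]["intercept_U0_mV"] - cond["iv_ref"]["intercept_U0_mV"]
    g_h = cond["G_protein_nS_cm2"] if g_mode == "protein" else cond["iv_ref"]["G_specific_nS_cm2"]
    sigma = protein_surface_density(stoich["rho_protein_per_lipid"],
                                    stoich["area_per_lipid_nm2"])
    delta_ph = float(cfg.buffer.get("pH_shifted_cis", cfg.buffer["pH_cis"] + 1.0)) - float(
        cfg.buffer["pH_trans"])
    res = turnover_number(g_h, delta_u, sigma, delta_pH=delta_ph,
                          temperature=cfg.temperature_K, g_mode=g_mode)
    record = {
        "k_turnover_per_s": res.k_turnover,
        "flux_density_mol_s_cm2": res.flux_density,
        "sigma_protein_per_cm2": res.sigma_protein,
        "G_H_nS_cm2": res.G_H,
        "delta_U_rev_mV": res.delta_U_rev,
        "U_nernst_mV": res.U_nernst,
        "transference_ratio": res.transference_ratio,
        "transference_flag": res.transference_flag,
        "constants": {"F_C_mol": res.F, "N_A_per_mol": res.N_A, "R_J_mol_K": res.R},
        "provenance": res.provenance,
    }
    path = out / "turnover.json"
    _write_json(path, record)
    return [path]


_RUNNERS = {
    "simulate": _stage_simulate,
    "conductance": _stage_conductance,
    "inhibition": _stage_inhibition,
    "fcs_count": _stage_fcs_count,
    "turnover": _stage_turnover,
}


def run_pipeline(cfg: ExperimentConfig, out_dir: str | Path) -> dict:
    """Execute the requested stages and write a manifest.

    Stages run in the fixed dependency order; a stage failure is recorded in
    the manifest (status ``failed`` with the diagnostic) and later stages are
    not attempted.  Returns the manifest dict, which is also written to
    ``manifest.json``.
    """
    cfg.check_dependencies()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "status": "ok",
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        try:
            files = _RUNNERS[stage](cfg, out)
        except Exception as exc:  # recorded, not swallowed silently
            manifest["stages"][stage] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
            manifest["status"] = "partial"
            break
        manifest["stages"][stage] = {
            "status": "ok",
            "outputs": {f.name: _sha256(f) for f in files},
        }
    _write_json(out / "manifest.json", manifest)
    return manifest
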