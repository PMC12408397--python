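"""End-to-end orchestration: joint CD + viscosity + thermodynamics
reconstruction from one configuration.

The pipeline mirrors the full analysis: pre-screen the conformer ensemble
for dissimilar structures, fit simplex-constrained weights to the target CD
spectrum from many restarts, break ties between near-equivalent fits by the
most negative weighted average folding free energy, keep the top-weight
conformers, average their intrinsic viscosities, predict the dilute-regime
viscosity profile, fit the Huggins constant on the full Einstein relation,
and summarise the folding thermodynamics.  Every stage failure aborts with
the stage name; all randomness flows from one seed recorded in the outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ppmoens import cd_deconvolution as cd
from ppmoens import io_formats as iof
from ppmoens import structure_metrics as sm
from ppmoens import thermodynamics as thermo
from ppmoens import viscosity_model as vm

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name in the message."""


@dataclass
class PipelineConfig:
    """Paths and settings for one full analysis run."""

    basis_path: str
    target_spectrum_path: str
    energies_path: str | None = None
    viscosity_path: str | None = None
    per_conformer_viscosity_path: str | None = None
    ensemble_path: str | None = None
    nucleotides: str = ""
    peptide: str = ""

    iterations: int = 10_000
    learning_rate: float = 0.05
    restarts: int = 20
    mse_tolerance: float = 0.05
    weight_threshold: float = 0.05
    prescreen_threshold: float | None = None
    eta_solvent: float = vm.DEFAULT_ETA_SOLVENT
    intrinsic_viscosity: float | None = None   # None -> ensemble average
    profile_concentrations: list[float] = field(
        default_factory=lambda: list(np.arange(0.0, 101.0, 10.0)))
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig, seed: int | None = None) -> dict:
    """Execute the full analysis; returns the result manifest."""
    if seed is not None:
        config.seed = seed
    bundle = iof.ResultBundle()
    meta: dict = {"seed": config.seed}

    @_stage("read_inputs")
    def _read():
        basis_df = pd.read_csv(config.basis_path)
        grid = basis_df.iloc[:, 0].to_numpy(float)
        basis = cd.BasisSpectra(grid, basis_df.iloc[:, 1:].to_numpy(float).T)
        target = iof.read_spectrum(config.target_spectrum_path)
        return basis, target

    basis, target = _read()

    @_stage("resample_target")
    def _resample():
        return cd.resample_to_grid(target, basis.grid)

    target_on_grid = _resample()

    ensemble = None
    if config.ensemble_path:
        @_stage("read_ensemble")
        def _ens():
            seq = iof.PPMOSequence.from_strings(config.nucleotides,
                                                config.peptide)
            ens = iof.read_ensemble(config.ensemble_path, seq)
            if config.prescreen_threshold:
                ens = sm.prescreen_dissimilar(ens, config.prescreen_threshold)
            return ens
        ensemble = _ens()

    @_stage("fit_weights")
    def _fit():
        fc = cd.FitConfig(iterations=config.iterations,
                          learning_rate=config.learning_rate,
                          seed=config.seed, restarts=config.restarts)
        return cd.fit_weights(basis, target_on_grid, fc)

    fit = _fit()

    thermo_result = None
    if config.energies_path:
        @_stage("thermodynamics")
        def _thermo():
            table = iof.read_energy_table(config.energies_path)
            if len(table) != basis.n_conformers:
                raise ValueError(
                    f"{len(table)} energy records for "
                    f"{basis.n_conformers} basis spectra")
            return thermo.folding_deltas(table)
        thermo_result = _thermo()

        @_stage("select_by_free_energy")
        def _select():
            return cd.select_by_free_energy(
                fit.restarts or [fit], thermo_result.dG,
                config.mse_tolerance)
        fit = _select()

    @_stage("top_conformers")
    def _top():
        return cd.top_conformers(fit, config.weight_threshold)

    selected, coverage = _top()
    meta.update(mse=fit.mse, mean_dG=fit.mean_dG, coverage=coverage,
                iterations=config.iterations, restarts=config.restarts,
                n_selected=len(selected))

    w = fit.weights.weights
    bundle.weights = w
    order = np.argsort(-w, kind="stable")
    bundle.cd_fit = pd.DataFrame({
        "conformer_id": order + 1,
        "weight": w[order],
        "cumulative": np.cumsum(w[order]),
    })
    bundle.fitted_spectrum = fit.fitted_spectrum
    bundle.fit_meta = meta

    if config.per_conformer_viscosity_path or config.viscosity_path:
        @_stage("viscosity")
        def _visc():
            if config.intrinsic_viscosity is not None:
                iv = float(config.intrinsic_viscosity)
            else:
                if not config.per_conformer_viscosity_path:
                    raise ValueError(
                        "need per-conformer viscosities or a fixed "
                        "intrinsic_viscosity")
                eta_df = pd.read_csv(config.per_conformer_viscosity_path)
                eta_i = eta_df.iloc[:, -1].to_numpy(float)
                idx = [i for i, _ in selected]
                wsel = np.array([wi for _, wi in selected])
                if not idx:
                    raise ValueError("no conformers above weight threshold")
                iv = vm.mean_intrinsic_viscosity(eta_i[idx], wsel)
            visc_fit: dict = {"eta_solvent": config.eta_solvent,
                              "intrinsic_viscosity": iv}
            if config.viscosity_path:
                data = iof.read_viscosity_table(config.viscosity_path)
                k_h, sse = vm.fit_huggins(data, config.eta_solvent, iv)
                visc_fit.update(huggins=k_h, sse=sse)
            else:
                visc_fit.update(huggins=0.0, sse=float("nan"))
            params = vm.HydroParams(config.eta_solvent, iv,
                                    visc_fit["huggins"])
            profile = vm.predict_profile(
                params, np.asarray(config.profile_concentrations, float),
                linear=True)
            return visc_fit, profile
        bundle.viscosity_fit, bundle.predicted_profile = _visc()

    if thermo_result is not None:
        @_stage("thermo_summaries")
        def _summaries():
            thermo_result.mean_dG = thermo.weighted_mean_dG(thermo_result, w)
            thermo_result.mean_dH = float(np.dot(w, thermo_result.dH)
                                          / w.sum())
            hist = thermo.distribution_histogram(thermo_result.dG)
            return thermo_result.to_frame(), hist.to_frame()
        bundle.thermo, bundle.thermo_hist = _summaries()
        meta["mean_dH"] = thermo_result.mean_dH

    if ensemble is not None:
        @_stage("interaction_map")
        def _imap():
            rows = "nucleotide"
            cols = ("amino_acid" if ensemble.sequence.peptide
                    else "nucleotide")
            imap = sm.time_fraction_map(ensemble, rows, cols)
            return imap.to_frame()
        bundle.interaction_map = _imap()

        @_stage("metrics")
        def _metrics():
            return sm.metrics_table(ensemble)
        bundle.metrics = _metrics()

    @_stage("write_results")
    def _write():
        return iof.write_results(bundle, config.out_dir)

    return _write()
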