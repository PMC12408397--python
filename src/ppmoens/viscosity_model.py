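"""Einstein/Huggins viscosity model for dilute-to-concentrated solutions.

The solution viscosity follows

    eta(C) = eta_s * (1 + [eta] c + k_H [eta]^2 c^2),

where eta_s is the solvent viscosity (mPa s), [eta] the intrinsic viscosity
(cm^3/g), k_H the dimensionless Huggins constant and c the mass
concentration in g/cm^3.  User-facing concentrations are in mg/mL as in
experimental viscosity profiles; the fixed factor 1000 converts to g/cm^3
so that [eta]*c is dimensionless.

The ensemble-averaged intrinsic viscosity is the population-weighted mean
of per-conformer values (computed externally, e.g. by bead-model
hydrodynamics), [eta]_th = sum_i w_i eta_i / sum_i w_i.  Since the model is
linear in k_H, the Huggins fit with eta_s and [eta] held fixed is an exact
closed-form least-squares solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ppmoens.io_formats import ViscosityDataset

__all__ = [
    "HydroParams",
    "MG_PER_ML_TO_G_PER_CM3",
    "mean_intrinsic_viscosity",
    "einstein_eta",
    "fit_huggins",
    "fit_intrinsic_viscosity",
    "predict_profile",
]

# mg/mL -> g/cm^3
MG_PER_ML_TO_G_PER_CM3 = 1e-3

#: Solvent (water) viscosity default, mPa s, as estimated from the
#: y-intercept of experimental viscosity profiles.
DEFAULT_ETA_SOLVENT = 0.909


@dataclass(frozen=True)
class HydroParams:
    """(eta_s, [eta], k_H) triple of the Einstein/Huggins relation."""

    eta_solvent: float = DEFAULT_ETA_SOLVENT   # mPa s
    intrinsic_viscosity: float = 0.0           # cm^3/g
    huggins: float = 0.0                       # dimensionless

    def __post_init__(self):
        if self.eta_solvent <= 0:
            raise ValueError("solvent viscosity must be positive")
        if self.intrinsic_viscosity < 0:
            raise ValueError("intrinsic viscosity must be non-negative")


def mean_intrinsic_viscosity(per_conformer, weights) -> float:
    """Weighted mean [eta]_th = sum w_i eta_i / sum w_i (cm^3/g).

    ``weights`` need not be normalised (e.g. when restricted to the
    top-weight conformers); the denominator handles the renormalisation.
    """
    eta = np.asarray(per_conformer, dtype=float)
    w = np.asarray(getattr(weights, "weights", weights), dtype=float)
    if eta.shape != w.shape:
        raise ValueError(f"{len(eta)} viscosities but {len(w)} weights")
    if np.any(eta <= 0):
        raise ValueError("per-conformer intrinsic viscosities must be positive")
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    return float(np.dot(w, eta) / w.sum())


def einstein_eta(params: HydroParams, concentration) -> np.ndarray | float:
    """eta(C) = eta_s (1 + [eta] c + k_H [eta]^2 c^2) with C in mg/mL."""
    C = np.asarray(concentration, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be non-negative")
    c = C * MG_PER_ML_TO_G_PER_CM3
    iv = params.intrinsic_viscosity
    eta = params.eta_solvent * (1.0 + iv * c + params.huggins * iv * iv * c * c)
    return float(eta) if np.isscalar(concentration) else eta


def fit_huggins(data: ViscosityDataset, eta_solvent: float,
                intrinsic_viscosity: float) -> tuple[float, float]:
    """Least-squares Huggins constant with eta_s and [eta] held fixed.

    eta is linear in k_H, so the unweighted least-squares estimate is the
    exact closed-form projection of the residual (eta - dilute law) onto
    the quadratic regressor eta_s [eta]^2 c^2.  Returns
    ``(huggins, residual_sse)``.
    """
    if eta_solvent <= 0 or intrinsic_viscosity < 0:
        raise ValueError("invalid fixed parameters")
    c = data.concentrations * MG_PER_ML_TO_G_PER_CM3
    if np.all(c == 0):
        raise ValueError("all concentrations are zero; k_H is unidentifiable")
    base = eta_solvent * (1.0 + intrinsic_viscosity * c)
    x = eta_solvent * intrinsic_viscosity ** 2 * c * c
    resid = data.viscosities - base
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("quadratic regressor vanishes; k_H is unidentifiable")
    k_h = float(np.dot(x, resid) / denom)
    sse = float(np.sum((resid - k_h * x) ** 2))
    return k_h, sse


def fit_intrinsic_viscosity(data: ViscosityDataset,
                            eta_solvent: float) -> tuple[float, float]:
    """Intrinsic viscosity from the dilute-regime law eta = eta_s(1+[eta]c).

    Least-squares slope through the origin of (eta/eta_s - 1) versus c in
    g/cm^3.  Returns ``(intrinsic_viscosity, residual_sse)`` with the SSE on
    the reduced-viscosity scale.
    """
    if eta_solvent <= 0:
        raise ValueError("solvent viscosity must be positive")
    c = data.concentrations * MG_PER_ML_TO_G_PER_CM3
    if np.all(c == 0):
        raise ValueError("all concentrations are zero")
    y = data.viscosities / eta_solvent - 1.0
    iv = float(np.dot(c, y) / np.dot(c, c))
    sse = float(np.sum((y - iv * c) ** 2))
    return iv, sse


def predict_profile(params: HydroParams, concentrations,
                    linear: bool = False,
                    temperature: float = 298.15) -> ViscosityDataset:
    """Evaluate the model at each concentration (mg/mL).

    ``linear=True`` forces k_H to zero, reproducing the dilute-regime
    prediction eta = eta_s (1 + [eta] c).
    """
    C = np.asarray(concentrations, dtype=float)
    if C.size == 0:
        out = ViscosityDataset.__new__(ViscosityDataset)
        out.concentrations = np.empty(0)
        out.viscosities = np.empty(0)
        out.temperature = temperature
        return out
    p = HydroParams(params.eta_solvent, params.intrinsic_viscosity,
                    0.0 if linear else params.huggins)
    return ViscosityDataset(C, einstein_eta(p, C), temperature)
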