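"""Deconvolution of a measured CD spectrum into conformer population
weights.

The observed mean-residue ellipticity is modelled as a population-weighted
superposition of per-conformer basis spectra,

    Theta_th(lambda) = sum_i w_i theta_i(lambda),   sum_i w_i = 1, w_i >= 0,

and the weights are found by minimising the mean squared error to the
measurement.  The simplex constraint is enforced by construction through a
softmax parameterisation of the weights; the resulting smooth unconstrained
problem is solved with the Adam optimizer (10,000 iterations by default)
from several random restarts.  Because different weight vectors can fit the
spectrum almost equally well, a thermodynamic tie-break selects, among all
restarts with comparable MSE, the one with the most negative weighted
average folding free energy <dG> = sum_i w_i dG_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ppmoens.io_formats import Spectrum

__all__ = [
    "BasisSpectra",
    "WeightVector",
    "FitResult",
    "FitConfig",
    "default_grid",
    "resample_to_grid",
    "compose_spectrum",
    "mse",
    "fit_weights",
    "select_by_free_energy",
    "top_conformers",
]


def default_grid() -> np.ndarray:
    """Default wavelength grid: 200-330 nm in 1-nm steps (131 points)."""
    return np.arange(200.0, 331.0, 1.0)


@dataclass
class BasisSpectra:
    """N per-conformer CD spectra theta_i(lambda) on one shared grid."""

    grid: np.ndarray      # (m,) wavelengths, nm
    matrix: np.ndarray    # (N, m) ellipticity, row i = theta_i

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.grid.ndim != 1 or len(self.grid) < 2:
            raise ValueError("grid needs at least 2 wavelengths")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.matrix.shape[1] != len(self.grid):
            raise ValueError("matrix columns must match the grid")
        if self.matrix.shape[0] < 1:
            raise ValueError("need at least one basis spectrum")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite basis spectra")

    @property
    def n_conformers(self) -> int:
        return self.matrix.shape[0]

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.grid.copy(), self.matrix[i].copy())


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class WeightVector:
    """Simplex-constrained population weights with their softmax pre-image."""

    weights: np.ndarray
    logits: np.ndarray
    seed: int = 0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        l = np.asarray(self.logits, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "logits", l)
        if w.shape != l.shape or w.ndim != 1:
            raise ValueError("weights and logits must be 1-D of equal length")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")

    @classmethod
    def from_logits(cls, logits: np.ndarray, seed: int = 0) -> "WeightVector":
        logits = np.asarray(logits, dtype=float)
        return cls(_softmax(logits), logits, seed)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class FitResult:
    """Outcome of one weight fit (possibly the best of several restarts)."""

    weights: WeightVector
    mse: float
    fitted_spectrum: Spectrum
    n_iterations: int
    converged: bool
    mean_dG: float | None = None
    degenerate: bool = False
    restarts: list["FitResult"] = field(default_factory=list)
    mse_history: np.ndarray | None = None  # raw per-iteration MSE (orig scale)


@dataclass
class FitConfig:
    """Optimizer settings.

    The iteration count follows the published protocol; the learning rate
    and Adam moment constants are conventional defaults that converge for
    range-normalised spectra.
    """

    iterations: int = 10_000
    learning_rate: float = 0.05
    seed: int = 0
    restarts: int = 20
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    normalize: bool = True   # mean-center/range-normalise internally
    keep_history: bool = False


def resample_to_grid(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``grid``; exact at coincident samples.
    Extrapolation outside the measured span is refused."""
    grid = np.asarray(grid, dtype=float)
    if grid.min() < spectrum.wavelengths[0] - 1e-9 \
            or grid.max() > spectrum.wavelengths[-1] + 1e-9:
        raise ValueError(
            f"grid [{grid.min():g}, {grid.max():g}] nm exceeds the measured "
            f"span [{spectrum.wavelengths[0]:g}, "
            f"{spectrum.wavelengths[-1]:g}] nm")
    values = np.interp(grid, spectrum.wavelengths, spectrum.ellipticity)
    return Spectrum(grid, values)


def compose_spectrum(basis: BasisSpectra, weights) -> Spectrum:
    """Pointwise weighted superposition Theta_th = sum_i w_i theta_i."""
    w = weights.weights if isinstance(weights, WeightVector) \
        else np.asarray(weights, dtype=float)
    if len(w) != basis.n_conformers:
        raise ValueError(
            f"{len(w)} weights for {basis.n_conformers} basis spectra")
    return Spectrum(basis.grid.copy(), w @ basis.matrix)


def mse(target: Spectrum, model: Spectrum) -> float:
    """Mean squared pointwise difference; grids must coincide."""
    if len(target) != len(model) \
            or not np.allclose(target.wavelengths, model.wavelengths):
        raise ValueError("spectra are on different wavelength grids")
    d = target.ellipticity - model.ellipticity
    return float(np.mean(d * d))


def fit_weights(basis: BasisSpectra, target: Spectrum,
                config: FitConfig | None = None) -> FitResult:
    """Fit simplex-constrained weights to ``target`` by Adam on the softmax
    logits, minimising the MSE.

    All restarts run in parallel (vectorised) with logits initialised
    uniformly in [-1, 1] from seeds ``seed+0 .. seed+restarts-1``.  The
    returned result is the best restart; every restart's outcome is kept in
    ``result.restarts`` so a thermodynamic tie-break can be applied
    afterwards.  MSE is reported on the original ellipticity scale.
    """
    config = config or FitConfig()
    if len(target) != len(basis.grid) \
            or not np.allclose(target.wavelengths, basis.grid):
        raise ValueError("target spectrum is not on the basis grid")
    if not np.all(np.isfinite(target.ellipticity)):
        raise ValueError("non-finite target spectrum")

    n, m = basis.matrix.shape
    y = target.ellipticity

    degenerate = n > 1 and float(np.ptp(basis.matrix, axis=0).max()) == 0.0

    if n == 1:
        w = WeightVector(np.array([1.0]), np.array([0.0]), config.seed)
        fitted = compose_spectrum(basis, w)
        return FitResult(weights=w, mse=mse(target, fitted),
                         fitted_spectrum=fitted, n_iterations=0,
                         converged=True, degenerate=degenerate)

    # internal normalisation for conditioning: subtract the target mean and
    # divide by the target range.  Because sum(w)=1, subtracting the same
    # constant from every basis row leaves the model consistent, and the
    # minimiser is unchanged; MSE scales by scale^2.
    if config.normalize:
        shift = float(np.mean(y))
        scale = float(np.ptp(y)) or 1.0
    else:
        shift, scale = 0.0, 1.0
    yn = (y - shift) / scale
    bn = (basis.matrix - shift) / scale

    r = max(1, config.restarts)
    logits = np.empty((r, n))
    for k in range(r):
        rng = np.random.default_rng(config.seed + k)
        logits[k] = rng.uniform(-1.0, 1.0, size=n)

    m1 = np.zeros_like(logits)
    m2 = np.zeros_like(logits)
    best_logits = logits.copy()
    w = _softmax(logits)
    resid = w @ bn - yn
    cur = np.mean(resid * resid, axis=1)
    best = cur.copy()
    history = np.empty((r, config.iterations + 1)) if config.keep_history \
        else None
    if history is not None:
        history[:, 0] = cur

    for t in range(1, config.iterations + 1):
        # dMSE/dw_i = (2/m) sum_j resid_j * theta_ij ; chain through softmax
        g_w = (2.0 / m) * resid @ bn.T
        gdot = np.sum(w * g_w, axis=1, keepdims=True)
        g = w * (g_w - gdot)

        m1 = config.beta1 * m1 + (1 - config.beta1) * g
        m2 = config.beta2 * m2 + (1 - config.beta2) * g * g
        m1h = m1 / (1 - config.beta1 ** t)
        m2h = m2 / (1 - config.beta2 ** t)
        logits = logits - config.learning_rate * m1h / (np.sqrt(m2h)
                                                        + config.eps)

        w = _softmax(logits)
        resid = w @ bn - yn
        cur = np.mean(resid * resid, axis=1)
        improved = cur < best
        best_logits[improved] = logits[improved]
        best[improved] = cur[improved]
        if history is not None:
            history[:, t] = cur

    scale2 = scale * scale
    restart_results: list[FitResult] = []
    for k in range(r):
        wv = WeightVector.from_logits(best_logits[k], seed=config.seed + k)
        fitted = compose_spectrum(basis, wv)
        restart_results.append(FitResult(
            weights=wv, mse=float(best[k] * scale2), fitted_spectrum=fitted,
            n_iterations=config.iterations, converged=True,
            degenerate=degenerate,
            mse_history=history[k] * scale2 if history is not None else None))

    order = np.argsort([fr.mse for fr in restart_results], kind="stable")
    winner = restart_results[int(order[0])]
    return FitResult(weights=winner.weights, mse=winner.mse,
                     fitted_spectrum=winner.fitted_spectrum,
                     n_iterations=config.iterations, converged=True,
                     degenerate=degenerate, restarts=restart_results,
                     mse_history=winner.mse_history)


def select_by_free_energy(candidates: Sequence[FitResult],
                          energies: np.ndarray,
                          mse_tolerance: float = 0.05) -> FitResult:
    """Thermodynamic tie-break among near-equivalent fits.

    Candidates whose MSE is within ``(1 + mse_tolerance) * min MSE`` are
    feasible; among them the one with the most negative weighted average
    folding free energy <dG> = sum_i w_i dG_i is returned.  ``mean_dG`` is
    populated on every candidate.
    """
    if not candidates:
        raise ValueError("no fit candidates")
    energies = np.asarray(energies, dtype=float)
    for c in candidates:
        if len(c.weights) != len(energies):
            raise ValueError("energy list length does not match weights")
        w = c.weights.weights
        c.mean_dG = float(np.dot(w, energies) / w.sum())
    best_mse = min(c.mse for c in candidates)
    feasible = [c for c in candidates
                if c.mse <= (1.0 + mse_tolerance) * best_mse]
    return min(feasible, key=lambda c: (c.mean_dG, c.mse))


def top_conformers(result: FitResult, threshold: float = 0.05
                   ) -> tuple[list[tuple[int, float]], float]:
    """Conformers with weight >= threshold, sorted by descending weight
    (ties broken by lower conformer index), plus their cumulative coverage.

    Conformer indices are 0-based positions in the basis.
    """
    w = result.weights.weights
    selected = [(int(i), float(w[i])) for i in np.flatnonzero(w >= threshold)]
    selected.sort(key=lambda t: (-t[1], t[0]))
    coverage = float(sum(wi for _, wi in selected))
    return selected, coverage
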