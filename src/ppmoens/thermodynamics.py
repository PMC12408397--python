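"""Folding thermodynamics bookkeeping.

Per-conformer enthalpies H and entropies S (from an external energy
decomposition, e.g. MM/GBSA with normal-mode entropies) are differenced
against an unfolded reference state,

    dH_j = H_j - H_ref,   dS_j = S_j - S_ref,   dG_j = dH_j - T dS_j,

at a fixed temperature (default 300 K).  Ensemble summaries are the
population-weighted means and histogram-based probability distributions of
dH and dG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from ppmoens.io_formats import EnergyTable

__all__ = [
    "ThermoResult",
    "Histogram",
    "folding_deltas",
    "weighted_mean_dG",
    "distribution_histogram",
]

DEFAULT_TEMPERATURE = 300.0  # K


@dataclass
class ThermoResult:
    """Per-conformer folding deltas (kcal/mol; dS in kcal/mol/K)."""

    dH: np.ndarray
    dS: np.ndarray
    dG: np.ndarray
    temperature: float
    mean_dH: float | None = None
    mean_dG: float | None = None

    def __len__(self) -> int:
        return len(self.dG)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "conformer_id": np.arange(1, len(self) + 1),
            "dH": self.dH, "dS": self.dS, "dG": self.dG,
        })


class Histogram(NamedTuple):
    bin_edges: np.ndarray
    probabilities: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_left": self.bin_edges[:-1],
                             "bin_right": self.bin_edges[1:],
                             "probability": self.probabilities})


def folding_deltas(table: EnergyTable) -> ThermoResult:
    """Folding dH/dS/dG for every conformer against the unfolded reference."""
    h_ref, s_ref = table.reference
    dH = table.records["H"].to_numpy(dtype=float) - h_ref
    dS = table.records["S"].to_numpy(dtype=float) - s_ref
    dG = dH - table.temperature * dS
    return ThermoResult(dH=dH, dS=dS, dG=dG, temperature=table.temperature)


def weighted_mean_dG(result: ThermoResult, weights) -> float:
    """<dG> = sum w_i dG_i / sum w_i (kcal/mol)."""
    w = np.asarray(getattr(weights, "weights", weights), dtype=float)
    if len(w) != len(result):
        raise ValueError(f"{len(w)} weights for {len(result)} conformers")
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    return float(np.dot(w, result.dG) / w.sum())


def distribution_histogram(values, bin_width: float = 10.0) -> Histogram:
    """Histogram-based probability estimate with edges aligned to integer
    multiples of ``bin_width``.

    Probabilities are counts/total, summing to one exactly.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to histogram")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    i_lo = int(np.floor(v.min() / bin_width))
    i_hi = int(np.floor(v.max() / bin_width)) + 1
    edges = bin_width * np.arange(i_lo, i_hi + 1)
    # guard against division rounding leaving a value outside the edges
    while edges[0] > v.min():
        edges = np.concatenate([[edges[0] - bin_width], edges])
    while edges[-1] < v.max():
        edges = np.concatenate([edges, [edges[-1] + bin_width]])
    counts, _ = np.histogram(v, bins=edges)
    return Histogram(bin_edges=edges, probabilities=counts / counts.sum(),
                     counts=counts)
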