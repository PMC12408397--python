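"""Seeded generators for every pipeline input, with known ground truth.

The generators emulate the *statistical structure* of the study inputs —
conformer ensembles with planted base stacks/pairs, per-conformer CD basis
spectra and a noisy observed superposition, Einstein-relation viscosity
curves, residue-contact schedules and broad folding-energy distributions —
not their chemistry.  Planted interactions are built directly from the
classification geometry (parallel frames at 3.4 A vertical offset for
stacks; coplanar frames with an inserted D-H...A triple for pairs), and all
other inter-base geometry is constructed so that no unplanned interaction
can satisfy any classifier cutoff.  Every generator is a pure function of
its config: identical seed, identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from ppmoens.cd_deconvolution import BasisSpectra, compose_spectrum, default_grid
from ppmoens.io_formats import (
    ATOMIC_MASSES,
    Conformer,
    ConformerEnsemble,
    EnergyTable,
    PPMOSequence,
    Spectrum,
    ViscosityDataset,
)
from ppmoens.viscosity_model import HydroParams, einstein_eta

import pandas as pd

__all__ = [
    "GeneratorConfig",
    "gen_ensemble",
    "gen_trajectory",
    "gen_basis_spectra",
    "gen_observed_spectrum",
    "gen_viscosity_dataset",
    "gen_energy_table",
]

# geometric constants of the planted structures
RING_RADIUS = 1.39        # A, six-membered aromatic ring
STACK_RISE = 3.4          # A vertical offset of a planted stack
STACK_SLIDE_MAX = 0.9     # A lateral offset (< 2.5 A rho cutoff)
PAIR_SEPARATION = 7.0     # A centroid-centroid distance of a planted pair
HBOND_DA = 2.9            # A donor-acceptor distance of the planted H-bond
CLUSTER_SPACING = 40.0    # A between cluster anchors (>> every cutoff)
MAX_TILT_DEG = 8.0        # per-cluster out-of-plane tilt bound; keeps every
                          # cross-cluster rho far above the 2.5 A cutoff
BACKBONE_STEP = 6.1       # A between consecutive P atoms of the random walk
PEPTIDE_STEP = 3.8        # A between consecutive CA sites


@dataclass
class GeneratorConfig:
    """Study-condition defaults for all generators.

    Defaults correspond to the 25-mer conjugate: 25 bases, a 7-residue
    -GlyArg6 peptide, an ensemble of 5,500 conformers, a 200-330 nm CD grid
    in 1-nm steps (131 points), planted secondary structure inside the
    reported 4-6 base-pair / 5-11 base-stack regime, and a viscosity noise
    scale of 0.02 mPa s (~2% instrument repeatability at the solvent
    baseline).
    """

    seed: int = 0
    n_conformers: int = 5500
    n_nucleotides: int = 25
    n_peptide_residues: int = 7
    planted_stacks: int = 8
    planted_pairs: int = 4
    contact_schedule: tuple[tuple[tuple[int, int], float], ...] = ()
    noise_sd_spectrum: float = 0.0
    noise_sd_viscosity: float = 0.02
    weight_truth: np.ndarray | None = None
    band_count_range: tuple[int, int] = (2, 5)
    grid: np.ndarray = field(default_factory=default_grid)

    def __post_init__(self):
        for name in ("n_conformers", "n_nucleotides", "n_peptide_residues",
                     "planted_stacks", "planted_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.noise_sd_spectrum < 0 or self.noise_sd_viscosity < 0:
            raise ValueError("noise SDs must be non-negative")
        for (_pair, f) in self.contact_schedule:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"contact fraction {f} outside [0, 1]")
        if self.weight_truth is not None:
            w = np.asarray(self.weight_truth, dtype=float)
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("weight_truth must lie on the simplex")
            self.weight_truth = w

    def sequence(self) -> PPMOSequence:
        bases = tuple("ACGT"[i % 4] for i in range(self.n_nucleotides))
        pep = ("G",) + ("R",) * (self.n_peptide_residues - 1) \
            if self.n_peptide_residues else ()
        return PPMOSequence(bases, pep)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator per logical stream, all derived from seed."""
        return np.random.default_rng([self.seed, stream])


# ---------------------------------------------------------------------------
# conformer ensembles with planted stacks/pairs
# ---------------------------------------------------------------------------

# local hexagon template; C2 (the in-plane anchor atom) at angle 0
_RING_NAMES = ("C2", "N3", "C4", "C5", "C6", "N1")


def _ring_coords(rotation_deg: float) -> np.ndarray:
    ang = np.radians(rotation_deg + 60.0 * np.arange(6))
    return RING_RADIUS * np.column_stack(
        [np.cos(ang), np.sin(ang), np.zeros(6)])


def _self_avoiding_walk(rng: np.random.Generator, n: int, step: float,
                        start: np.ndarray, min_sep: float = 4.0) -> np.ndarray:
    pts = [start]
    for _ in range(1, n):
        for _attempt in range(200):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            cand = pts[-1] + step * v
            if all(np.linalg.norm(cand - p) >= min_sep for p in pts[:-1]):
                pts.append(cand)
                break
        else:  # pragma: no cover - extremely unlikely at these densities
            raise RuntimeError("self-avoiding walk failed to extend")
    return np.array(pts)


def _cluster_rotation(rng: np.random.Generator) -> np.ndarray:
    """Random in-plane spin composed with a small out-of-plane tilt."""
    spin = Rotation.from_euler("z", rng.uniform(0, 360), degrees=True)
    axis_ang = rng.uniform(0, 2 * np.pi)
    axis = np.array([np.cos(axis_ang), np.sin(axis_ang), 0.0])
    tilt = Rotation.from_rotvec(
        np.radians(rng.uniform(0, MAX_TILT_DEG)) * axis)
    return (tilt * spin).as_matrix()


def gen_ensemble(config: GeneratorConfig
                 ) -> tuple[ConformerEnsemble, dict]:
    """Generate an ensemble with exactly the planted stacks and pairs.

    Layout: base rings sit at cluster anchors on a wide planar grid
    (spacing 40 A), each cluster rigidly rotated with an out-of-plane tilt
    bounded at 8 deg.  Stack clusters hold two parallel rings at 3.4 A rise
    and < 1 A slide; pair clusters hold two coplanar rings 7 A apart joined
    by an inserted N4-H4...O2 triple satisfying the hydrogen-bond criteria.
    Backbone P atoms form a separate self-avoiding random walk (6.1 A
    step), so end-to-end distance and radius of gyration vary across
    conformers while the planted truth stays fixed.  Returns the ensemble
    and a truth dict with the planted pair/stack residue tuples.
    """
    n_nt = config.n_nucleotides
    need = 2 * (config.planted_stacks + config.planted_pairs)
    if need > n_nt:
        raise ValueError(
            f"{config.planted_stacks} stacks + {config.planted_pairs} pairs "
            f"need {need} bases but only {n_nt} nucleotides are available")

    rng = config.rng(1)
    seq = config.sequence()

    # assign shuffled residue indices (1-based) to cluster slots
    order = rng.permutation(n_nt) + 1
    stacks = [(int(order[2 * s]), int(order[2 * s + 1]))
              for s in range(config.planted_stacks)]
    off = 2 * config.planted_stacks
    pairs = [(int(order[off + 2 * p]), int(order[off + 2 * p + 1]))
             for p in range(config.planted_pairs)]
    singles = [int(i) for i in order[off + 2 * config.planted_pairs:]]

    clusters: list[tuple[str, tuple[int, ...]]] = (
        [("stack", s) for s in stacks] + [("pair", p) for p in pairs]
        + [("single", (s,)) for s in singles])
    n_clusters = len(clusters)
    cols = max(1, int(np.ceil(np.sqrt(n_clusters))))
    anchors = np.array([[CLUSTER_SPACING * (c % cols),
                         CLUSTER_SPACING * (c // cols), 0.0]
                        for c in range(n_clusters)])

    # --- static atom template (identity arrays shared by all conformers) ---
    names: list[str] = []
    elements: list[str] = []
    res_idx: list[int] = []
    kinds: list[str] = []
    res_names: list[str] = []

    donor_residues = {p[0] for p in pairs}
    acceptor_residues = {p[1] for p in pairs}

    def _add(res: int, kind: str, rname: str, atom_names: Sequence[str]):
        for an in atom_names:
            names.append(an)
            elements.append(an[0])  # first letter is the element here
            res_idx.append(res)
            kinds.append(kind)
            res_names.append(rname)

    for i in range(1, n_nt + 1):
        rname = "MO" + seq.nucleotides[i - 1]
        atoms = ["P", *_RING_NAMES]
        if i in donor_residues:
            atoms += ["N4", "H4"]
        if i in acceptor_residues:
            atoms += ["O2"]
        _add(i, "nucleotide", rname, atoms)
    for j in range(config.n_peptide_residues):
        res = n_nt + 1 + j
        aa = seq.peptide[j]
        rname = {"G": "GLY", "R": "ARG"}.get(aa, "GLY")
        atoms = ["N", "H", "CA", "C", "O"]
        if aa == "R":
            atoms += ["CZ", "NE", "HE", "NH1", "NH2"]
        _add(res, "amino_acid", rname, atoms)

    names_a = np.array(names)
    elements_a = np.array(elements)
    res_idx_a = np.array(res_idx)
    kinds_a = np.array(kinds)
    res_names_a = np.array(res_names)
    masses_a = np.array([ATOMIC_MASSES[e] for e in elements_a])
    n_atoms = len(names_a)

    # per-residue atom slices for fast placement
    slices = {int(r): np.flatnonzero(res_idx_a == r)
              for r in np.unique(res_idx_a)}

    def _place_ring(pos: np.ndarray, res: int, center: np.ndarray,
                    R: np.ndarray, ring_rot: float,
                    extra: dict[str, np.ndarray] | None = None):
        """Write ring (and optional extra local atoms) into pos; P is left
        untouched (placed from the backbone walk)."""
        idx = slices[res]
        local = {}
        ring = _ring_coords(ring_rot)
        for k, an in enumerate(_RING_NAMES):
            local[an] = ring[k]
        if extra:
            local.update(extra)
        for a in idx:
            an = names_a[a]
            if an == "P":
                continue
            pos[a] = center + R @ local[an]

    conformers: list[Conformer] = []
    for _frame in range(config.n_conformers):
        pos = np.zeros((n_atoms, 3))

        for c, (ckind, members) in enumerate(clusters):
            R = _cluster_rotation(rng)
            anchor = anchors[c]
            if ckind == "stack":
                k, j = members
                slide = rng.uniform(0, STACK_SLIDE_MAX)
                slide_ang = rng.uniform(0, 2 * np.pi)
                offset = np.array([slide * np.cos(slide_ang),
                                   slide * np.sin(slide_ang), STACK_RISE])
                _place_ring(pos, k, anchor + R @ np.zeros(3), R,
                            rng.uniform(0, 360))
                _place_ring(pos, j, anchor + R @ offset, R,
                            rng.uniform(0, 360))
            elif ckind == "pair":
                k, j = members
                gap = (PAIR_SEPARATION - HBOND_DA) / 2.0  # exocyclic reach
                # exocyclic donor/acceptor atoms sit on the inter-base axis
                # (independent of the freely spun rings) so the planted
                # N4-H4...O2 triple always meets the hydrogen-bond criteria
                extra_k = {"N4": np.array([gap, 0.0, 0.0]),
                           "H4": np.array([gap + 1.0, 0.0, 0.0])}
                extra_j = {"O2": np.array([-gap, 0.0, 0.0])}
                _place_ring(pos, k, anchor, R,
                            rng.uniform(0, 360), extra=extra_k)
                _place_ring(pos, j,
                            anchor + R @ np.array([PAIR_SEPARATION, 0, 0]),
                            R, rng.uniform(0, 360), extra=extra_j)
            else:
                (k,) = members
                _place_ring(pos, k, anchor, R, rng.uniform(0, 360))

        # nucleotide backbone: self-avoiding P walk in a region far below
        # the base plane (|dz| >> every interaction cutoff)
        p_walk = _self_avoiding_walk(
            rng, n_nt, BACKBONE_STEP, np.array([0.0, 0.0, -60.0]))
        for i in range(1, n_nt + 1):
            idx = slices[i]
            a = idx[names_a[idx] == "P"][0]
            pos[a] = p_walk[i - 1]

        # peptide: compact random walk in its own region
        if config.n_peptide_residues:
            pep_walk = _self_avoiding_walk(
                rng, config.n_peptide_residues, PEPTIDE_STEP,
                np.array([0.0, 0.0, -120.0]), min_sep=3.0)
            for j in range(config.n_peptide_residues):
                res = n_nt + 1 + j
                site = pep_walk[j]
                local = {"N": np.array([-1.2, 0.4, 0.0]),
                         "H": np.array([-1.9, 1.1, 0.0]),
                         "CA": np.zeros(3),
                         "C": np.array([1.3, 0.6, 0.0]),
                         "O": np.array([1.6, 1.8, 0.0]),
                         "CZ": np.array([0.0, -3.5, 0.8]),
                         "NE": np.array([0.0, -2.3, 0.4]),
                         "HE": np.array([0.8, -1.9, 0.4]),
                         "NH1": np.array([1.1, -4.2, 1.0]),
                         "NH2": np.array([-1.1, -4.2, 1.0])}
                Rp = Rotation.random(random_state=rng).as_matrix()
                for a in slices[res]:
                    pos[a] = site + Rp @ local[names_a[a]]

        conformers.append(Conformer(
            elements=elements_a, names=names_a, residue_indices=res_idx_a,
            residue_kinds=kinds_a, positions=pos, masses=masses_a,
            residue_names=res_names_a))

    truth = {
        "stacked_pairs": sorted(tuple(sorted(s)) for s in stacks),
        "paired_pairs": sorted(tuple(sorted(p)) for p in pairs),
        "n_bs": len(stacks),
        "n_bp": len(pairs),
    }
    return ConformerEnsemble(conformers, seq, "synthetic"), truth


# ---------------------------------------------------------------------------
# contact-schedule trajectories
# ---------------------------------------------------------------------------

def gen_trajectory(config: GeneratorConfig) -> ConformerEnsemble:
    """Trajectory with scheduled Bernoulli contacts.

    Residues are single-atom beads at sites 25 A apart; for each scheduled
    pair ``((i, j), f)`` residue j is placed 5 A from residue i's site
    (inside the 7.5 A COM cutoff) with independent per-frame probability
    ``f``, and at its own site (>= 20 A from everything) otherwise.  Each
    residue may appear in at most one schedule entry.
    """
    seq = config.sequence()
    n_res = seq.n_residues
    seen: set[int] = set()
    for (pair, f) in config.contact_schedule:
        i, j = pair
        for r in (i, j):
            if not 1 <= r <= n_res:
                raise ValueError(f"scheduled residue {r} outside 1..{n_res}")
            if r in seen:
                raise ValueError(
                    f"residue {r} appears in more than one schedule entry")
            seen.add(r)

    kinds = np.array(seq.residue_kinds())
    res_names = np.array(seq.residue_names())
    sites = np.array([[25.0 * i, 0.0, 0.0] for i in range(n_res)])
    rng = config.rng(2)

    elements = np.array(["P"] * n_res)
    names = np.array(["P"] * n_res)
    res_idx = np.arange(1, n_res + 1)
    masses = np.full(n_res, ATOMIC_MASSES["P"])

    conformers = []
    for _frame in range(config.n_conformers):
        pos = sites.copy()
        for (pair, f) in config.contact_schedule:
            i, j = pair
            if rng.random() < f:
                pos[j - 1] = sites[i - 1] + np.array([5.0, 0.0, 0.0])
        conformers.append(Conformer(
            elements=elements, names=names, residue_indices=res_idx,
            residue_kinds=kinds, positions=pos, masses=masses,
            residue_names=res_names))
    return ConformerEnsemble(conformers, seq, "synthetic-trajectory")


# ---------------------------------------------------------------------------
# CD spectra
# ---------------------------------------------------------------------------

def gen_basis_spectra(config: GeneratorConfig,
                      n_basis: int | None = None,
                      max_cosine: float = 0.95,
                      well_separated: bool = False) -> BasisSpectra:
    """Per-conformer basis spectra as sums of 2-5 signed Gaussian bands.

    Band centers lie in 205-290 nm and widths in 5-20 nm, echoing the
    210/240/270 nm features of measured morpholino CD spectra.  Pairwise
    cosine similarity of rows is kept below ``max_cosine`` by resampling a
    too-similar row (at most 100 attempts).

    ``well_separated=True`` instead stratifies each conformer's dominant
    band over the 205-290 nm range (one stratum per conformer, width
    4-6 nm, plus one weak overlapping band).  Smooth band mixtures are
    nearly collinear even at modest pairwise cosine, which makes weights
    statistically unidentifiable under noise; stratified dominant bands
    keep the basis well conditioned so noisy weight recovery is meaningful.
    """
    n = config.n_conformers if n_basis is None else n_basis
    grid = np.asarray(config.grid, dtype=float)
    rng = config.rng(3)
    lo, hi = config.band_count_range
    strata = np.linspace(205.0, 290.0, n + 1)

    def _band(c, w, a):
        return a * np.exp(-0.5 * ((grid - c) / w) ** 2)

    def _row(i: int) -> np.ndarray:
        if well_separated:
            main = _band(rng.uniform(strata[i] + 1, strata[i + 1] - 1),
                         rng.uniform(4.0, 6.0),
                         rng.choice([-1.0, 1.0]) * rng.uniform(6.0, 10.0))
            weak = _band(rng.uniform(205.0, 290.0), rng.uniform(5.0, 20.0),
                         rng.uniform(-1.0, 1.0))
            return main + weak
        k = int(rng.integers(lo, hi + 1))
        centers = rng.uniform(205.0, 290.0, size=k)
        widths = rng.uniform(5.0, 20.0, size=k)
        amps = rng.uniform(-10.0, 10.0, size=k)
        return np.sum([_band(c, w, a)
                       for c, w, a in zip(centers, widths, amps)], axis=0)

    rows: list[np.ndarray] = []
    for _i in range(n):
        for _attempt in range(100):
            cand = _row(_i)
            cn = np.linalg.norm(cand)
            if cn == 0:
                continue
            ok = all(np.dot(cand, r) / (cn * np.linalg.norm(r)) < max_cosine
                     for r in rows)
            if ok:
                rows.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not draw basis spectrum {_i + 1} with pairwise "
                f"cosine < {max_cosine} in 100 attempts")
    return BasisSpectra(grid, np.array(rows))


def gen_observed_spectrum(basis: BasisSpectra, weight_truth,
                          noise_sd: float, seed: int = 0) -> Spectrum:
    """Weighted superposition of the basis plus i.i.d. Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    w = np.asarray(getattr(weight_truth, "weights", weight_truth), float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weight_truth must lie on the simplex")
    clean = compose_spectrum(basis, w)
    rng = np.random.default_rng([seed, 4])
    noise = rng.normal(0.0, noise_sd, size=len(clean)) if noise_sd else 0.0
    return Spectrum(clean.wavelengths, clean.ellipticity + noise)


# ---------------------------------------------------------------------------
# viscosity
# ---------------------------------------------------------------------------

def gen_viscosity_dataset(params: HydroParams, concentrations,
                          noise_sd: float = 0.0, seed: int = 0,
                          linear: bool = False,
                          temperature: float = 298.15) -> ViscosityDataset:
    """Einstein-relation viscosity curve plus Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    C = np.asarray(concentrations, dtype=float)
    p = HydroParams(params.eta_solvent, params.intrinsic_viscosity,
                    0.0 if linear else params.huggins)
    eta = np.atleast_1d(einstein_eta(p, C))
    if noise_sd:
        rng = np.random.default_rng([seed, 5])
        eta = eta + rng.normal(0.0, noise_sd, size=eta.shape)
    return ViscosityDataset(C, eta, temperature)


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

# Defaults place the folding deltas in the reported ranges: dH spanning
# roughly -250..0 kcal/mol and dG roughly -200..50 kcal/mol at 300 K.
DH_MEAN, DH_SD = -125.0, 40.0        # kcal/mol
TDS_MEAN, TDS_SD = -45.0, 30.0       # kcal/mol at 300 K


def gen_energy_table(config: GeneratorConfig,
                     compactness=None, rho: float = 0.8,
                     temperature: float = 300.0) -> EnergyTable:
    """Per-conformer H/S records with a zero reference state.

    H ~ Normal(-125, 40) kcal/mol and T*S ~ Normal(-45, 30) kcal/mol are
    drawn independently, so dG = dH - T dS is Normal(-80, 50).  The five
    enthalpy components are a random additive split of H.  If a
    ``compactness`` score per conformer is given, H is correlated with it
    (coefficient ``rho``; more compact, more negative H).
    """
    n = config.n_conformers
    if n < 1:
        raise ValueError("need at least one conformer")
    if DH_SD <= 0 or TDS_SD <= 0:
        raise ValueError("energy SDs must be positive")
    rng = config.rng(6)
    z_h = rng.normal(size=n)
    if compactness is not None:
        comp = np.asarray(compactness, dtype=float)
        if len(comp) != n:
            raise ValueError("compactness length must equal n_conformers")
        z_c = (comp - comp.mean()) / (comp.std() or 1.0)
        z_h = rho * (-z_c) + np.sqrt(max(0.0, 1.0 - rho * rho)) * z_h
    H = DH_MEAN + DH_SD * z_h
    S = (TDS_MEAN + TDS_SD * rng.normal(size=n)) / temperature

    parts = rng.normal(0.0, 20.0, size=(n, 4))
    records = pd.DataFrame({
        "H": H, "S": S,
        "E_int": parts[:, 0], "E_C": parts[:, 1], "E_vdW": parts[:, 2],
        "E_p": parts[:, 3], "E_np": H - parts.sum(axis=1),
    })
    return EnergyTable(records, reference=(0.0, 0.0), temperature=temperature)
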