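"""Per-conformer and per-trajectory structural observables.

Implements the geometric vocabulary used to describe partially folded
oligonucleotide-peptide conjugates:

* end-to-end distance X (P atoms of the first and last nucleotide),
* mass-weighted radius of gyration Rg,
* solvent-accessible surface area (Shrake-Rupley),
* base-fixed coordinate frames and the stack/pair classification built on
  them (vertical offset z, in-plane offset rho, inter-normal angle theta),
* geometric hydrogen bonds (donor-acceptor distance < 3.3 A and
  D-H...A angle > 140 deg),
* residue-residue contacts (center-of-mass distance < 7.5 A) and their
  time-fraction maps over an ensemble.

Classification cutoffs use strict inequalities; an exact tie is a
non-interaction.  theta is folded to [0, 90] deg because plane normals from
a least-squares fit are sign-ambiguous.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from ppmoens.io_formats import Conformer, ConformerEnsemble, PPMOSequence

logger = logging.getLogger(__name__)

__all__ = [
    "BaseFrame",
    "PairGeometry",
    "HBond",
    "InteractionMap",
    "base_frame",
    "end_to_end_distance",
    "radius_of_gyration",
    "sasa",
    "detect_hbonds",
    "pair_geometry",
    "classify_stacking",
    "classify_pairing",
    "count_pairs_stacks",
    "interaction_matrix",
    "time_fraction_map",
    "prescreen_dissimilar",
    "metrics_table",
    "resolve_residues",
    "display_label",
]

# geometric cutoffs (strict inequalities)
STACK_Z_MIN = 2.0        # A: |z_kj| and |z_jk| must exceed this
STACK_RHO_MAX = 2.5      # A: rho_kj or rho_jk must be below this
STACK_THETA_MAX = 40.0   # deg
PAIR_THETA_MAX = 60.0    # deg
HBOND_DA_MAX = 3.3       # A donor-acceptor
HBOND_ANGLE_MIN = 140.0  # deg D-H-A
CONTACT_CUTOFF = 7.5     # A residue COM-COM
DH_COVALENT_MAX = 1.2    # A: hydrogen counts as bonded to a donor below this

RING_ATOM_NAMES = ("N1", "C2", "N3", "C4", "C5", "C6")
X_ANCHOR_ATOM = "C2"  # fixes the in-plane axis; present in both ring systems

# Bondi van der Waals radii (A)
VDW_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "P": 1.8, "S": 1.8}

# atoms belonging to the backbone (morpholino ring + phosphorodiamidate
# linkage + linker); everything else in a nucleotide residue is "base"
BACKBONE_ATOM_NAMES = frozenset(
    {"P", "O1P", "O2P", "OP1", "OP2", "N", "CA", "C", "O", "H", "HA"})


@dataclass(frozen=True)
class BaseFrame:
    """Right-handed orthonormal coordinate system fixed to one nucleobase.

    The origin is the unweighted centroid of the six-membered-ring atoms;
    the z-axis is the unit normal of the least-squares ring plane and the
    x- and y-axes lie in the plane of the base (x anchored at C2).
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    residue_index: int


@dataclass(frozen=True)
class PairGeometry:
    """Mutual geometry of two base frames k and j.

    ``z_kj`` is the signed displacement of base j's origin along base k's
    z-axis, ``rho_kj`` the in-plane distance sqrt(x^2 + y^2) in k's frame;
    ``theta_kj`` is the angle between the two plane normals, folded to
    [0, 90] deg.
    """

    z_kj: float
    z_jk: float
    rho_kj: float
    rho_jk: float
    theta_kj: float


@dataclass(frozen=True)
class HBond:
    """Geometric hydrogen bond D-H...A."""

    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    donor_residue: int
    acceptor_residue: int
    d_DA: float
    angle_DHA: float


@dataclass
class InteractionMap:
    """Residue-pair interaction time fractions over an ensemble.

    ``time_fraction[r, c]`` is the fraction of conformers in which the
    residue pair interacts under the chosen criterion; display labels use
    3'-end numbering for nucleotides.
    """

    row_labels: list[str]
    col_labels: list[str]
    row_indices: np.ndarray
    col_indices: np.ndarray
    time_fraction: np.ndarray
    interaction_kind: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.time_fraction, index=self.row_labels,
                            columns=self.col_labels)


# ---------------------------------------------------------------------------
# residue selection and labelling
# ---------------------------------------------------------------------------

def resolve_residues(conformer: Conformer, selector) -> np.ndarray:
    """Resolve a residue selector to a sorted array of residue indices.

    Selectors: ``"nucleotide" | "amino_acid" | "linker" | "all"``, an
    iterable of 1-based residue indices, or a callable
    ``(residue_index, kind) -> bool``.
    """
    all_idx = np.unique(conformer.residue_indices)
    if isinstance(selector, str):
        if selector == "all":
            return all_idx
        if selector in ("nucleotide", "amino_acid", "linker"):
            return np.unique(
                conformer.residue_indices[conformer.residue_kinds == selector])
        raise ValueError(f"unknown residue selector {selector!r}")
    if callable(selector):
        kinds = {int(i): conformer.residue_kinds[conformer.residue_indices == i][0]
                 for i in all_idx}
        return np.array([i for i in all_idx if selector(int(i), kinds[int(i)])])
    idx = np.asarray(sorted(int(i) for i in selector))
    if idx.size == 0:
        raise ValueError("empty residue selector")
    missing = set(idx) - set(all_idx.tolist())
    if missing:
        raise ValueError(f"selector names absent residues {sorted(missing)}")
    return idx


def display_label(sequence: PPMOSequence, residue_index: int) -> str:
    """Display label for a residue, numbering nucleotides from the 3' end
    (the 3'-terminal base is number 1) and peptide residues from the
    attachment point."""
    offset = int(sequence.has_mteg_linker)
    n_nt = sequence.n_nucleotides
    if residue_index <= offset:
        return "MTEG"
    nt_pos = residue_index - offset
    if nt_pos <= n_nt:
        base = sequence.nucleotides[nt_pos - 1]
        return f"{base}{n_nt - nt_pos + 1}"
    pep_pos = nt_pos - n_nt
    from ppmoens.io_formats import AA_THREE
    return f"{AA_THREE[sequence.peptide[pep_pos - 1]]}{pep_pos}"


# ---------------------------------------------------------------------------
# scalar observables
# ---------------------------------------------------------------------------

def end_to_end_distance(conformer: Conformer) -> float:
    """Distance X between the P atoms of the first and last nucleotide."""
    nts = conformer.nucleotide_indices()
    if len(nts) < 1:
        raise ValueError("conformer has no nucleotide residues")
    pos = []
    for res in (nts[0], nts[-1]):
        mask = conformer.residue_mask(res) & (conformer.names == "P")
        if not mask.any():
            raise ValueError(f"residue {res} lacks a P atom")
        pos.append(conformer.positions[mask][0])
    return float(np.linalg.norm(pos[1] - pos[0]))


def radius_of_gyration(conformer: Conformer) -> float:
    """Mass-weighted Rg about the center of mass, all atoms included."""
    m = conformer.masses
    total = m.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    com = (conformer.positions * m[:, None]).sum(axis=0) / total
    r2 = np.sum((conformer.positions - com) ** 2, axis=1)
    return float(np.sqrt((m * r2).sum() / total))


@lru_cache(maxsize=8)
def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden-spiral
    lattice)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(conformer: Conformer, probe_radius: float = 1.4,
         n_points: int = 960,
         radii: dict[str, float] | None = None) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area.

    Returns ``(total, per_residue)`` in A^2; ``per_residue`` follows the
    sorted order of residue indices and sums to the total.
    """
    radii = VDW_RADII if radii is None else radii
    missing = sorted({e.capitalize() for e in conformer.elements}
                     - set(radii))
    if missing:
        raise ValueError(f"no van der Waals radius for element(s) {missing}")
    r = np.array([radii[e.capitalize()] for e in conformer.elements])
    r_ext = r + probe_radius
    pos = conformer.positions
    sphere = _sphere_points(n_points)

    tree = cKDTree(pos)
    max_ext = r_ext.max()
    per_atom = np.zeros(conformer.n_atoms)
    for i in range(conformer.n_atoms):
        pts = pos[i] + r_ext[i] * sphere
        neighbors = tree.query_ball_point(pos[i], r_ext[i] + max_ext)
        neighbors = [j for j in neighbors if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - pos[j]) ** 2, axis=1)
            accessible &= d2 >= r_ext[j] ** 2
        per_atom[i] = 4.0 * np.pi * r_ext[i] ** 2 * accessible.mean()

    residues = np.unique(conformer.residue_indices)
    per_res = np.array([per_atom[conformer.residue_indices == res].sum()
                        for res in residues])
    return float(per_atom.sum()), per_res


# ---------------------------------------------------------------------------
# base frames and stack/pair classification
# ---------------------------------------------------------------------------

def base_frame(conformer: Conformer, residue_index: int) -> BaseFrame:
    """Base-fixed frame of one nucleotide from its six-membered ring."""
    mask = conformer.residue_mask(residue_index)
    if not mask.any():
        raise ValueError(f"no residue {residue_index}")
    names = conformer.names[mask]
    pos = conformer.positions[mask]
    ring_sel = np.isin(names, RING_ATOM_NAMES)
    ring = pos[ring_sel]
    if len(ring) < 3:
        have = sorted(set(names[ring_sel]))
        raise ValueError(
            f"residue {residue_index}: only {len(ring)} ring atoms {have}; "
            "need at least 3 for a plane fit")
    origin = ring.mean(axis=0)
    centered = ring - origin
    # least-squares plane normal = singular vector of smallest singular value
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8:
        raise ValueError(f"residue {residue_index}: ring atoms are collinear")
    z = vt[2]
    # deterministic sign: largest-magnitude component positive
    k = int(np.argmax(np.abs(z)))
    if z[k] < 0:
        z = -z

    anchor_sel = names == X_ANCHOR_ATOM
    if not anchor_sel.any():
        raise ValueError(
            f"residue {residue_index}: missing x-axis anchor atom "
            f"{X_ANCHOR_ATOM}")
    v = pos[anchor_sel][0] - origin
    v_in_plane = v - np.dot(v, z) * z
    norm = np.linalg.norm(v_in_plane)
    if norm < 1e-8:
        raise ValueError(
            f"residue {residue_index}: anchor atom lies on the plane normal")
    x = v_in_plane / norm
    y = np.cross(z, x)
    return BaseFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z,
                     residue_index=int(residue_index))


def pair_geometry(frame_k: BaseFrame, frame_j: BaseFrame) -> PairGeometry:
    """Mutual displacement/orientation of two base frames."""
    d = frame_j.origin - frame_k.origin
    z_kj = float(np.dot(d, frame_k.z_axis))
    z_jk = float(np.dot(-d, frame_j.z_axis))
    d2 = float(np.dot(d, d))
    rho_kj = float(np.sqrt(max(d2 - z_kj ** 2, 0.0)))
    rho_jk = float(np.sqrt(max(d2 - z_jk ** 2, 0.0)))
    cos_t = abs(float(np.dot(frame_k.z_axis, frame_j.z_axis)))
    theta = float(np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0))))
    return PairGeometry(z_kj=z_kj, z_jk=z_jk, rho_kj=rho_kj, rho_jk=rho_jk,
                        theta_kj=theta)


def classify_stacking(frame_k: BaseFrame,
                      frame_j: BaseFrame) -> tuple[bool, PairGeometry]:
    """Two bases are stacked iff (|z_kj| > 2 and |z_jk| > 2) and
    (rho_kj < 2.5 or rho_jk < 2.5) and theta < 40 deg."""
    g = pair_geometry(frame_k, frame_j)
    stacked = (abs(g.z_kj) > STACK_Z_MIN and abs(g.z_jk) > STACK_Z_MIN
               and (g.rho_kj < STACK_RHO_MAX or g.rho_jk < STACK_RHO_MAX)
               and g.theta_kj < STACK_THETA_MAX)
    return stacked, g


def classify_pairing(frame_k: BaseFrame, frame_j: BaseFrame,
                     hbonds_kj: Sequence[HBond],
                     stacked_kj: bool) -> bool:
    """Non-stacked bases are paired iff theta < 60 deg and at least one
    base-base hydrogen bond links them.  Stacking takes precedence."""
    if stacked_kj:
        return False
    g = pair_geometry(frame_k, frame_j)
    return g.theta_kj < PAIR_THETA_MAX and len(hbonds_kj) >= 1


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _hbond_roles() -> dict:
    """Donor/acceptor atom-name tables per residue kind, from the editable
    package config."""
    text = (resources.files("ppmoens") / "data" / "hbond_roles.yaml").read_text()
    return yaml.safe_load(text)


# potential-donor atoms seen without a bonded hydrogen, warned once each
_warned_unprotonated: set[tuple[str, str]] = set()


def _donor_triples(conformer: Conformer, residues: np.ndarray,
                   allowed_names: set[str]) -> list[tuple[int, int]]:
    """(donor, hydrogen) atom index pairs: donor heavy atoms with a hydrogen
    of the same residue within covalent range."""
    triples = []
    for res in residues:
        mask = conformer.residue_mask(res)
        idx = np.flatnonzero(mask)
        names = conformer.names[idx]
        elements = np.char.capitalize(conformer.elements[idx].astype(str))
        h_idx = idx[elements == "H"]
        d_idx = idx[np.isin(names, sorted(allowed_names))]
        for d in d_idx:
            bonded = [h for h in h_idx
                      if np.linalg.norm(conformer.positions[h]
                                        - conformer.positions[d])
                      < DH_COVALENT_MAX]
            if not bonded:
                key = (str(conformer.residue_names[d]), str(conformer.names[d]))
                if key not in _warned_unprotonated:
                    _warned_unprotonated.add(key)
                    logger.warning(
                        "donor atom %s of residue type %s has no bonded "
                        "hydrogen; skipped (reported once per atom type)",
                        key[1], key[0])
                continue
            for h in bonded:
                triples.append((int(d), int(h)))
    return triples


def detect_hbonds(conformer: Conformer, donor_group, acceptor_group,
                  base_only: bool = False,
                  d_da_max: float = HBOND_DA_MAX,
                  angle_min: float = HBOND_ANGLE_MIN) -> list[HBond]:
    """All D-H...A triples with d(D,A) < 3.3 A and angle(D-H-A) > 140 deg.

    ``donor_group``/``acceptor_group`` are residue selectors restricting the
    scan (e.g. PMO vs. peptide).  ``base_only`` drops backbone donor and
    acceptor atom names, leaving nucleobase functional groups only.
    """
    roles = _hbond_roles()
    donors = resolve_residues(conformer, donor_group)
    acceptors = resolve_residues(conformer, acceptor_group)

    def _names(table: dict, kinds: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for k in kinds:
            out |= set(table.get(k) or [])
        if base_only:
            out -= BACKBONE_ATOM_NAMES
        return out

    kinds_of = lambda residues: {
        conformer.residue_kinds[conformer.residue_indices == r][0]
        for r in residues}
    donor_names = _names(roles["donors"], kinds_of(donors))
    acceptor_names = _names(roles["acceptors"], kinds_of(acceptors))

    dh = _donor_triples(conformer, donors, donor_names)
    acc_mask = (np.isin(conformer.residue_indices, acceptors)
                & np.isin(conformer.names, sorted(acceptor_names)))
    acc_idx = np.flatnonzero(acc_mask)
    if not dh or acc_idx.size == 0:
        return []

    pos = conformer.positions
    out: list[HBond] = []
    for d, h in dh:
        d_res = int(conformer.residue_indices[d])
        vec = pos[acc_idx] - pos[d]
        dist = np.linalg.norm(vec, axis=1)
        for a, dda in zip(acc_idx[dist < d_da_max], dist[dist < d_da_max]):
            a = int(a)
            if int(conformer.residue_indices[a]) == d_res:
                continue  # no intra-residue hydrogen bonds
            u = pos[d] - pos[h]
            v = pos[a] - pos[h]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu < 1e-9 or nv < 1e-9:
                continue
            ang = np.degrees(np.arccos(np.clip(np.dot(u, v) / (nu * nv),
                                               -1.0, 1.0)))
            if ang > angle_min:
                out.append(HBond(donor_atom=d, hydrogen_atom=h,
                                 acceptor_atom=a, donor_residue=d_res,
                                 acceptor_residue=int(
                                     conformer.residue_indices[a]),
                                 d_DA=float(dda), angle_DHA=float(ang)))
    return out


# ---------------------------------------------------------------------------
# pair/stack counting
# ---------------------------------------------------------------------------

def count_pairs_stacks(conformer: Conformer) -> tuple[int, int]:
    """(N_BP, N_BS) over all unordered base pairs of the conformer.

    Each pair is counted at most once; pairing is only evaluated on
    non-stacked pairs.
    """
    nts = conformer.nucleotide_indices()
    frames = {int(r): base_frame(conformer, int(r)) for r in nts}
    hbonds = detect_hbonds(conformer, "nucleotide", "nucleotide",
                           base_only=True)
    hb_by_pair: dict[frozenset, list[HBond]] = {}
    for hb in hbonds:
        hb_by_pair.setdefault(
            frozenset((hb.donor_residue, hb.acceptor_residue)), []).append(hb)

    n_bp = n_bs = 0
    for ai in range(len(nts)):
        for bi in range(ai + 1, len(nts)):
            k, j = int(nts[ai]), int(nts[bi])
            stacked, _ = classify_stacking(frames[k], frames[j])
            if stacked:
                n_bs += 1
            elif classify_pairing(frames[k], frames[j],
                                  hb_by_pair.get(frozenset((k, j)), []),
                                  stacked):
                n_bp += 1
    return n_bp, n_bs


# ---------------------------------------------------------------------------
# residue contacts
# ---------------------------------------------------------------------------

def _atom_subset_mask(conformer: Conformer, residue: int,
                      subset: str | None) -> np.ndarray:
    mask = conformer.residue_mask(residue)
    if subset is None or subset == "all":
        return mask
    names = conformer.names
    if subset == "base":
        return mask & ~np.isin(names, sorted(BACKBONE_ATOM_NAMES))
    if subset == "backbone":
        return mask & np.isin(names, sorted(BACKBONE_ATOM_NAMES))
    if subset == "sidechain":
        return mask & ~np.isin(names, sorted(BACKBONE_ATOM_NAMES))
    raise ValueError(f"unknown atom subset {subset!r}")


def _residue_com(conformer: Conformer, residue: int,
                 subset: str | None = None) -> np.ndarray:
    mask = _atom_subset_mask(conformer, residue, subset)
    if not mask.any():
        raise ValueError(
            f"residue {residue} has no atoms in subset {subset!r}")
    m = conformer.masses[mask]
    return (conformer.positions[mask] * m[:, None]).sum(axis=0) / m.sum()


def interaction_matrix(conformer: Conformer, rows, cols,
                       cutoff: float = CONTACT_CUTOFF,
                       row_subset: str | None = None,
                       col_subset: str | None = None) -> np.ndarray:
    """Boolean matrix: entry true iff the mass-weighted center-of-mass
    distance of the residue pair is below ``cutoff``; self-pairs false."""
    row_idx = resolve_residues(conformer, rows)
    col_idx = resolve_residues(conformer, cols)
    row_com = np.array([_residue_com(conformer, int(r), row_subset)
                        for r in row_idx])
    col_com = np.array([_residue_com(conformer, int(c), col_subset)
                        for c in col_idx])
    d = np.linalg.norm(row_com[:, None, :] - col_com[None, :, :], axis=2)
    mat = d < cutoff
    same = row_idx[:, None] == col_idx[None, :]
    mat[same] = False
    return mat


INTERACTION_KINDS = ("any_contact", "base_base", "base_arg_sidechain",
                     "backbone_arg", "hbond_only")


def _interaction_bool(conformer: Conformer, row_idx: np.ndarray,
                      col_idx: np.ndarray, kind: str,
                      cutoff: float) -> np.ndarray:
    subset = {
        "any_contact": (None, None),
        "base_base": ("base", "base"),
        "base_arg_sidechain": ("base", "sidechain"),
        "backbone_arg": ("backbone", "sidechain"),
    }
    if kind in subset:
        rs, cs = subset[kind]
        return interaction_matrix(conformer, row_idx, col_idx, cutoff,
                                  row_subset=rs, col_subset=cs)
    if kind == "hbond_only":
        mat = np.zeros((len(row_idx), len(col_idx)), dtype=bool)
        pos_r = {int(r): i for i, r in enumerate(row_idx)}
        pos_c = {int(c): i for i, c in enumerate(col_idx)}
        # scan both donor->acceptor directions
        for grp_a, grp_b in ((row_idx, col_idx), (col_idx, row_idx)):
            for hb in detect_hbonds(conformer, grp_a, grp_b):
                r, c = hb.donor_residue, hb.acceptor_residue
                if r in pos_r and c in pos_c:
                    mat[pos_r[r], pos_c[c]] = True
                if c in pos_r and r in pos_c:
                    mat[pos_r[c], pos_c[r]] = True
        return mat
    raise ValueError(f"unknown interaction kind {kind!r}; "
                     f"choose from {INTERACTION_KINDS}")


def time_fraction_map(ensemble: ConformerEnsemble, rows, cols,
                      kind: str = "any_contact",
                      cutoff: float = CONTACT_CUTOFF) -> InteractionMap:
    """Fraction of conformers in which each residue pair interacts.

    Entries are exact rational counts k/n.  Display labels number the
    nucleotides from the 3' end.
    """
    ref = ensemble.conformers[0]
    row_idx = resolve_residues(ref, rows)
    col_idx = resolve_residues(ref, cols)
    counts = np.zeros((len(row_idx), len(col_idx)), dtype=np.int64)
    for conf in ensemble:
        counts += _interaction_bool(conf, row_idx, col_idx, kind, cutoff)
    frac = counts / len(ensemble)
    seq = ensemble.sequence
    return InteractionMap(
        row_labels=[display_label(seq, int(r)) for r in row_idx],
        col_labels=[display_label(seq, int(c)) for c in col_idx],
        row_indices=row_idx, col_indices=col_idx,
        time_fraction=frac, interaction_kind=kind)


# ---------------------------------------------------------------------------
# ensemble pre-screening
# ---------------------------------------------------------------------------

def _frame_origin_rmsd(a: Conformer, b: Conformer) -> float:
    """RMSD of base-frame origins after optimal (Kabsch) superposition."""
    nts = a.nucleotide_indices()
    pa = np.array([base_frame(a, int(r)).origin for r in nts])
    pb = np.array([base_frame(b, int(r)).origin for r in nts])
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        _, rssd = Rotation.align_vectors(pa, pb)
    return float(rssd / np.sqrt(len(pa)))


def prescreen_dissimilar(ensemble: ConformerEnsemble, threshold: float,
                         metric: Callable[[Conformer, Conformer], float]
                         | None = None) -> ConformerEnsemble:
    """Greedy dissimilarity filter: walk the ensemble in order and keep a
    conformer iff its dissimilarity to every kept conformer is >= threshold.

    The default metric is the RMSD of base-frame origins after optimal
    superposition; any symmetric non-negative dissimilarity (e.g. an eRMSD
    implementation) may be plugged in.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    metric = metric or _frame_origin_rmsd
    kept: list[int] = []
    for i, conf in enumerate(ensemble):
        if all(metric(ensemble.conformers[k], conf) >= threshold
               for k in kept):
            kept.append(i)
    return ensemble.subset(kept)


# ---------------------------------------------------------------------------
# per-conformer metrics table
# ---------------------------------------------------------------------------

def metrics_table(ensemble: ConformerEnsemble,
                  include_sasa: bool = True) -> pd.DataFrame:
    """Per-conformer observables mirroring the time profiles of a
    trajectory: X, Rg, SASA, N_BP, N_BS, and the PMO-peptide (N_hb) and
    intra-peptide (n_hb) hydrogen-bond counts."""
    rows = []
    has_pep = len(ensemble.sequence.peptide) > 0
    for i, conf in enumerate(ensemble, start=1):
        n_bp, n_bs = count_pairs_stacks(conf)
        rec = {
            "conformer_id": i,
            "X": end_to_end_distance(conf),
            "Rg": radius_of_gyration(conf),
            "N_BP": n_bp,
            "N_BS": n_bs,
        }
        if include_sasa:
            rec["SASA"] = sasa(conf)[0]
        if has_pep:
            rec["N_hb"] = (
                len(detect_hbonds(conf, "nucleotide", "amino_acid"))
                + len(detect_hbonds(conf, "amino_acid", "nucleotide")))
            rec["n_hb"] = len(detect_hbonds(conf, "amino_acid", "amino_acid"))
        rows.append(rec)
    return pd.DataFrame(rows)
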