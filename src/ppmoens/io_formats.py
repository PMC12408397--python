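"""Readers and writers for every external representation used by the
pipeline: multi-model PDB conformer ensembles, two-column CD spectra,
viscosity-concentration tables, per-conformer energy/entropy tables and the
JSON result manifest.

Internal conventions
--------------------
* Residues are numbered 1-based from the 5' end (nucleotides first, then
  the 3'-attached peptide N->C; an optional MTEG linker precedes the
  nucleotides).  Reporting code re-indexes from the 3' end at output time.
* Coordinates are in Angstrom; PDB MODEL/ENDMDL blocks define conformers.
* CSV/TSV use "." as decimal separator; the delimiter is sniffed between
  comma and tab.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "ParseError",
    "PPMOSequence",
    "Conformer",
    "ConformerEnsemble",
    "Spectrum",
    "ViscosityDataset",
    "EnergyTable",
    "ResultBundle",
    "ATOMIC_MASSES",
    "DEFAULT_RESIDUE_MAP",
    "read_ensemble",
    "write_ensemble",
    "read_spectrum",
    "write_spectrum",
    "read_viscosity_table",
    "read_energy_table",
    "write_results",
]


class ParseError(ValueError):
    """Malformed input file."""


# Standard atomic masses (Da) for the elements occurring in PPMOs.
ATOMIC_MASSES: Mapping[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}

VALID_BASES = ("A", "C", "G", "T")

# Residue names used when writing PDB files: "MO"+base for the morpholino
# nucleotides, standard three-letter codes for amino acids, TEG for the
# 5'-linker.  The reader accepts a user-supplied name->base map because no
# community standard exists for morpholino residue naming.
DEFAULT_RESIDUE_MAP: Mapping[str, str] = {
    "MOA": "A",
    "MOC": "C",
    "MOG": "G",
    "MOT": "T",
}

AA_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_ONE = {v: k for k, v in AA_THREE.items()}


@dataclass(frozen=True)
class PPMOSequence:
    """Chemical identity of one conjugate: bases 5'->3', peptide attached at
    the 3' end (may be empty for a plain PMO), optional 5' MTEG linker."""

    nucleotides: tuple[str, ...]
    peptide: tuple[str, ...] = ()
    has_mteg_linker: bool = False

    def __post_init__(self):
        if len(self.nucleotides) < 1:
            raise ValueError("sequence needs at least one nucleotide")
        bad = [b for b in self.nucleotides if b not in VALID_BASES]
        if bad:
            raise ValueError(f"invalid base codes {bad}; allowed: {VALID_BASES}")
        bad_aa = [a for a in self.peptide if a not in AA_THREE]
        if bad_aa:
            raise ValueError(f"invalid amino-acid codes {bad_aa}")

    @property
    def n_nucleotides(self) -> int:
        return len(self.nucleotides)

    @property
    def n_residues(self) -> int:
        return int(self.has_mteg_linker) + len(self.nucleotides) + len(self.peptide)

    def residue_kinds(self) -> list[str]:
        """Kind of each residue in internal order (linker, 5'->3' bases,
        peptide N->C)."""
        kinds = ["linker"] * int(self.has_mteg_linker)
        kinds += ["nucleotide"] * len(self.nucleotides)
        kinds += ["amino_acid"] * len(self.peptide)
        return kinds

    def residue_names(self) -> list[str]:
        names = ["TEG"] * int(self.has_mteg_linker)
        names += ["MO" + b for b in self.nucleotides]
        names += [AA_THREE[a] for a in self.peptide]
        return names

    @classmethod
    def from_strings(cls, nucleotides: str, peptide: str = "",
                     has_mteg_linker: bool = False) -> "PPMOSequence":
        return cls(tuple(nucleotides), tuple(peptide), has_mteg_linker)


@dataclass
class Conformer:
    """One frame of an ensemble, stored as parallel numpy arrays.

    ``residue_indices`` are 1-based counting from the 5' end / N-terminus
    of the internal residue order.
    """

    elements: np.ndarray          # (n,) str
    names: np.ndarray             # (n,) str atom names
    residue_indices: np.ndarray   # (n,) int, 1-based
    residue_kinds: np.ndarray     # (n,) str in {nucleotide, amino_acid, linker}
    positions: np.ndarray         # (n, 3) float, Angstrom
    masses: np.ndarray            # (n,) float, Da
    residue_names: np.ndarray | None = None  # (n,) str PDB residue names

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atom coordinates")
        n = len(self.positions)
        for arr_name in ("elements", "names", "residue_indices",
                         "residue_kinds", "masses"):
            arr = np.asarray(getattr(self, arr_name))
            if len(arr) != n:
                raise ValueError(f"{arr_name} length {len(arr)} != {n} atoms")
            setattr(self, arr_name, arr)
        if self.residue_names is None:
            self.residue_names = np.array(["UNK"] * n)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def residue_mask(self, residue_index: int) -> np.ndarray:
        return self.residue_indices == residue_index

    def nucleotide_indices(self) -> np.ndarray:
        """Sorted residue indices of all nucleotide residues."""
        return np.unique(self.residue_indices[self.residue_kinds == "nucleotide"])

    def peptide_indices(self) -> np.ndarray:
        return np.unique(self.residue_indices[self.residue_kinds == "amino_acid"])


@dataclass
class ConformerEnsemble:
    """Ordered, annotation-consistent set of conformers of one conjugate."""

    conformers: list[Conformer]
    sequence: PPMOSequence
    source_label: str = ""

    def __post_init__(self):
        if not self.conformers:
            raise ValueError("ensemble must contain at least one conformer")
        n0 = self.conformers[0].n_atoms
        for i, c in enumerate(self.conformers):
            if c.n_atoms != n0:
                raise ValueError(
                    f"conformer {i + 1} has {c.n_atoms} atoms, expected {n0}")

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return ConformerEnsemble(self.conformers[i], self.sequence,
                                     self.source_label)
        return self.conformers[i]

    def subset(self, indices: Iterable[int]) -> "ConformerEnsemble":
        return ConformerEnsemble([self.conformers[i] for i in indices],
                                 self.sequence, self.source_label)


@dataclass
class Spectrum:
    """CD spectrum: wavelengths in nm (strictly increasing) and mean-residue
    molar ellipticity in deg cm^2 dmol^-1."""

    wavelengths: np.ndarray
    ellipticity: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.wavelengths.shape != self.ellipticity.shape:
            raise ValueError("wavelength and ellipticity lengths differ")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) < 1:
            raise ValueError("spectrum must be a non-empty 1-D table")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return len(self.wavelengths)


@dataclass
class ViscosityDataset:
    """Solution viscosity eta (mPa s) versus mass concentration C (mg/mL)."""

    concentrations: np.ndarray
    viscosities: np.ndarray
    temperature: float = 298.15

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viscosities = np.asarray(self.viscosities, dtype=float)
        if self.concentrations.shape != self.viscosities.shape:
            raise ValueError("concentration and viscosity lengths differ")
        if len(self.concentrations) < 1:
            raise ValueError("viscosity dataset must contain at least one point")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if len(np.unique(self.concentrations)) != len(self.concentrations):
            raise ValueError("duplicate concentrations")
        if np.any(self.viscosities <= 0):
            raise ValueError("viscosities must be positive")
        order = np.argsort(self.concentrations)
        self.concentrations = self.concentrations[order]
        self.viscosities = self.viscosities[order]

    def __len__(self) -> int:
        return len(self.concentrations)


ENERGY_COMPONENTS = ("E_int", "E_C", "E_vdW", "E_p", "E_np")


@dataclass
class EnergyTable:
    """Per-conformer enthalpy H and entropy S with an unfolded-reference
    record, from which folding deltas are formed.

    H and the optional components are in kcal/mol; S in kcal/mol/K.  When
    components are present they must sum to H (the enthalpy decomposition
    into internal, Coulomb, van der Waals, polar and nonpolar solvation
    terms is additive by construction).
    """

    records: pd.DataFrame          # columns H, S and optionally components
    reference: tuple[float, float]  # (H_ref, S_ref)
    temperature: float = 300.0

    def __post_init__(self):
        if "H" not in self.records or "S" not in self.records:
            raise ValueError("energy table requires H and S columns")
        if len(self.records) < 1:
            raise ValueError("energy table is empty")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        present = [c for c in ENERGY_COMPONENTS if c in self.records]
        if present:
            if len(present) != len(ENERGY_COMPONENTS):
                raise ValueError(
                    f"partial component set {present}; provide all of "
                    f"{ENERGY_COMPONENTS} or none")
            total = self.records[list(ENERGY_COMPONENTS)].sum(axis=1)
            if not np.allclose(total, self.records["H"], atol=1e-6):
                raise ValueError("energy components do not sum to H")

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------

def _model_atom_counts(text: str) -> list[int]:
    """Atoms per MODEL block, read directly from the record stream so that a
    mismatch can be reported with its model index before any parsing."""
    counts, current, in_model = [], 0, False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model, current = True, 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM") and in_model:
            current += 1
    if not counts:  # single-model file without MODEL records
        n = sum(1 for line in text.splitlines()
                if line[:6].strip() in ("ATOM", "HETATM"))
        if n:
            counts = [n]
    return counts


def read_ensemble(path, sequence: PPMOSequence,
                  residue_map: Mapping[str, str] | None = None,
                  source_label: str | None = None) -> ConformerEnsemble:
    """Read a multi-model PDB file into a :class:`ConformerEnsemble`.

    Residues are mapped onto ``sequence`` in file order; ``residue_map``
    translates non-standard nucleotide residue names to base codes
    (default :data:`DEFAULT_RESIDUE_MAP`).
    """
    path = Path(path)
    text = path.read_text()
    counts = _model_atom_counts(text)
    if not counts:
        raise ParseError(f"{path}: no ATOM records found")
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts, start=1) if c != counts[0])
        raise ParseError(
            f"{path}: model {bad} atom count {counts[bad - 1]} differs from "
            f"model 1 ({counts[0]})")

    pdb_file = pdb.PDBFile.read(io.StringIO(text))
    stack = pdb_file.get_structure(model=None)  # AtomArrayStack
    residue_map = dict(DEFAULT_RESIDUE_MAP if residue_map is None else residue_map)

    res_ids = stack.res_id
    # remap file residue ids onto contiguous internal 1..n indices in order
    # of first appearance
    _, first = np.unique(res_ids, return_index=True)
    file_order = res_ids[np.sort(first)]
    id_to_internal = {rid: i + 1 for i, rid in enumerate(file_order)}
    internal = np.array([id_to_internal[r] for r in res_ids])

    kinds_by_res = sequence.residue_kinds()
    if len(file_order) != sequence.n_residues:
        raise ParseError(
            f"{path}: file has {len(file_order)} residues but the sequence "
            f"defines {sequence.n_residues}")

    res_names = stack.res_name
    known = set(residue_map) | set(AA_THREE.values()) | {"TEG"}
    unknown = sorted(set(res_names) - known)
    if unknown:
        raise ParseError(f"{path}: unknown residue name(s) {unknown}")

    elements = stack.element
    masses = np.array([ATOMIC_MASSES[e.capitalize()] for e in elements])
    kinds = np.array([kinds_by_res[i - 1] for i in internal])

    conformers = []
    for m in range(stack.stack_depth()):
        conformers.append(Conformer(
            elements=elements.copy(),
            names=stack.atom_name.copy(),
            residue_indices=internal.copy(),
            residue_kinds=kinds.copy(),
            positions=np.asarray(stack.coord[m], dtype=float),
            masses=masses.copy(),
            residue_names=res_names.copy(),
        ))
    return ConformerEnsemble(conformers, sequence,
                             source_label or path.name)


def write_ensemble(ensemble: ConformerEnsemble, path) -> Path:
    """Write an ensemble as multi-model PDB (one MODEL per conformer)."""
    path = Path(path)
    ref = ensemble.conformers[0]
    n = ref.n_atoms
    atoms = struc.AtomArray(n)
    atoms.coord = ref.positions.astype(np.float32)
    atoms.atom_name = ref.names.astype("U6")
    atoms.element = np.char.upper(ref.elements.astype("U2"))
    atoms.res_id = ref.residue_indices.astype(int)
    atoms.res_name = ref.residue_names.astype("U5")
    atoms.chain_id = np.array(["A"] * n)
    atoms.hetero = np.array([True] * n)

    stack = struc.stack([atoms] * len(ensemble))
    stack.coord = np.stack([c.positions for c in ensemble.conformers]
                           ).astype(np.float32)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
    return path


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def _read_table(path, expected_cols: int | None = None) -> pd.DataFrame:
    """Read a CSV/TSV with sniffed delimiter and optional header."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ParseError(f"{path}: empty file")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    first = text.splitlines()[0].split(sep)

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = 0 if not all(_is_number(t) for t in first) else None
    df = pd.read_csv(io.StringIO(text), sep=sep, header=header)
    if expected_cols is not None and df.shape[1] != expected_cols:
        raise ParseError(
            f"{path}: expected {expected_cols} columns, got {df.shape[1]}")
    return df


def read_spectrum(path) -> Spectrum:
    """Read a two-column wavelength/ellipticity table; rows may be unsorted
    but duplicate wavelengths are rejected."""
    df = _read_table(path, expected_cols=2)
    if len(df) < 2:
        raise ParseError(f"{path}: a spectrum needs at least 2 rows")
    try:
        wl = df.iloc[:, 0].astype(float).to_numpy()
        el = df.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        bad = _first_non_numeric_row(df)
        raise ParseError(f"{path}: non-numeric value in data row {bad}") from exc
    if np.any(~np.isfinite(wl)) or np.any(~np.isfinite(el)):
        bad = int(np.argmax(~(np.isfinite(wl) & np.isfinite(el)))) + 1
        raise ParseError(f"{path}: non-numeric value in data row {bad}")
    order = np.argsort(wl)
    wl, el = wl[order], el[order]
    if np.any(np.diff(wl) == 0):
        dup = wl[np.argmax(np.diff(wl) == 0)]
        raise ParseError(f"{path}: duplicate wavelength {dup:g} nm")
    return Spectrum(wl, el)


def _first_non_numeric_row(df: pd.DataFrame) -> int:
    for i, row in enumerate(df.itertuples(index=False), start=1):
        for v in row:
            try:
                float(v)
            except (TypeError, ValueError):
                return i
    return -1


def write_spectrum(spectrum: Spectrum, path) -> Path:
    path = Path(path)
    pd.DataFrame({"wavelength_nm": spectrum.wavelengths,
                  "ellipticity": spectrum.ellipticity}).to_csv(path, index=False)
    return path


def read_viscosity_table(path, temperature: float = 298.15) -> ViscosityDataset:
    """Read a viscosity table with columns C_mg_per_mL, eta_mPa_s."""
    df = _read_table(path, expected_cols=2)
    try:
        c = df.iloc[:, 0].astype(float).to_numpy()
        eta = df.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric viscosity table entry") from exc
    return ViscosityDataset(c, eta, temperature)


def read_energy_table(path, temperature: float = 300.0) -> EnergyTable:
    """Read a per-conformer energy table.

    Columns: ``conformer_id, H, S`` plus optional components
    ``E_int, E_C, E_vdW, E_p, E_np``.  The unfolded reference is the row
    whose ``conformer_id`` equals ``"reference"``.
    """
    df = _read_table(path)
    cols = [str(c) for c in df.columns]
    if "H" not in cols or "S" not in cols:
        raise ParseError(f"{path}: energy table requires H and S columns")
    idcol = cols[0]
    mask = df[idcol].astype(str) == "reference"
    if not mask.any():
        raise ParseError(f"{path}: no 'reference' row found")
    ref = df[mask].iloc[0]
    body = df[~mask].reset_index(drop=True)
    keep = [c for c in ("H", "S", *ENERGY_COMPONENTS) if c in cols]
    return EnergyTable(body[keep].astype(float),
                       (float(ref["H"]), float(ref["S"])),
                       temperature)


# ---------------------------------------------------------------------------
# result bundle
# ---------------------------------------------------------------------------

@dataclass
class ResultBundle:
    """Everything one analysis run may produce; any field may be absent."""

    weights: np.ndarray | None = None          # per-conformer weights
    cd_fit: pd.DataFrame | None = None         # conformer_id, weight, cumulative
    fitted_spectrum: Spectrum | None = None
    fit_meta: dict | None = None
    metrics: pd.DataFrame | None = None        # per-conformer observables
    interaction_map: pd.DataFrame | None = None  # labelled time fractions
    viscosity_fit: dict | None = None
    predicted_profile: ViscosityDataset | None = None
    thermo: pd.DataFrame | None = None         # conformer_id, dH, dS, dG
    thermo_hist: pd.DataFrame | None = None    # bin_left, bin_right, probability
    extra: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(bundle: ResultBundle, out_dir) -> dict:
    """Write every present bundle field under deterministic file names and
    return the manifest (also written as manifest.json with checksums)."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    written: list[Path] = []

    def _csv(df: pd.DataFrame, name: str, sep=","):
        p = out / name
        df.to_csv(p, index=False, sep=sep, float_format="%.10g")
        written.append(p)

    def _json(obj, name: str):
        p = out / name
        p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float)
                     + "\n")
        written.append(p)

    if bundle.weights is not None:
        _csv(pd.DataFrame({"conformer_id": np.arange(1, len(bundle.weights) + 1),
                           "weight": np.asarray(bundle.weights, float)}),
             "weights.csv")
    if bundle.cd_fit is not None:
        _csv(bundle.cd_fit, "cd_fit.csv")
    if bundle.fitted_spectrum is not None:
        _csv(pd.DataFrame({"wavelength_nm": bundle.fitted_spectrum.wavelengths,
                           "ellipticity": bundle.fitted_spectrum.ellipticity}),
             "fitted_spectrum.csv")
    if bundle.fit_meta is not None:
        _json(bundle.fit_meta, "fit_meta.json")
    if bundle.metrics is not None:
        _csv(bundle.metrics, "metrics.csv")
    if bundle.interaction_map is not None:
        p = out / "interaction_map.tsv"
        bundle.interaction_map.to_csv(p, sep="\t", float_format="%.10g")
        written.append(p)
    if bundle.viscosity_fit is not None:
        _json(bundle.viscosity_fit, "viscosity_fit.json")
    if bundle.predicted_profile is not None:
        _csv(pd.DataFrame({"C_mg_per_mL": bundle.predicted_profile.concentrations,
                           "eta_mPa_s": bundle.predicted_profile.viscosities}),
             "predicted_profile.csv")
    if bundle.thermo is not None:
        _csv(bundle.thermo, "thermo.csv")
    if bundle.thermo_hist is not None:
        _csv(bundle.thermo_hist, "thermo_hist.csv")
    for name, obj in sorted(bundle.extra.items()):
        _json(obj, f"{name}.json")

    manifest = {"artifacts": {p.name: _sha256(p) for p in sorted(written)}}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["files"] = sorted([p.name for p in written] + ["manifest.json"])
    return manifest
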