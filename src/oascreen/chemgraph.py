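"""Molecular graphs and physico-chemical atom/bond descriptors.

Molecules are handled as heavy-atom graphs (implicit hydrogens; the
hydrogen count enters as an atom descriptor).  Every atom carries a
fixed-length standardized descriptor vector and every bond a short
bond-descriptor vector; these feed the radial-basis atom similarity in
:mod:`oascreen.assignment`.  Standardization uses fixed affine ranges
declared in the descriptor configuration — never data-dependent — so
that similarities are stable across screening libraries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdPartialCharges
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "DescriptorConfig",
    "DEFAULT_DESCRIPTOR_CONFIG",
    "MoleculeGraph",
    "ScreeningDataset",
    "DatasetRecord",
    "ParseError",
    "molecule_from_smiles",
    "read_smiles",
    "read_sdf",
    "read_manifest",
    "compute_descriptors",
    "topo_distance",
]

# Pauling electronegativities for the elements routinely seen in drug-like
# molecules; anything else falls back to 2.0 (a mid-scale neutral value).
_ELECTRONEGATIVITY = {
    1: 2.20, 3: 0.98, 5: 2.04, 6: 2.55, 7: 3.04, 8: 3.44, 9: 3.98,
    11: 0.93, 14: 1.90, 15: 2.19, 16: 2.58, 17: 3.16, 35: 2.96, 53: 2.66,
}

_HYBRIDIZATION_CODE = {
    Chem.HybridizationType.UNSPECIFIED: 0,
    Chem.HybridizationType.S: 1,
    Chem.HybridizationType.SP: 2,
    Chem.HybridizationType.SP2: 3,
    Chem.HybridizationType.SP3: 4,
    Chem.HybridizationType.SP3D: 5,
    Chem.HybridizationType.SP3D2: 6,
}


class ParseError(Exception):
    """A single molecule record failed to parse; carries source context."""

    def __init__(self, source: str, message: str):
        super().__init__(f"{source}: {message}")
        self.source = source
        self.message = message


def _electronegativity(atom: Chem.Atom) -> float:
    return _ELECTRONEGATIVITY.get(atom.GetAtomicNum(), 2.0)


def _partial_charge(atom: Chem.Atom) -> float:
    # Gasteiger charge, precomputed on the owning molecule.
    q = atom.GetDoubleProp("_GasteigerCharge") if atom.HasProp("_GasteigerCharge") else float("nan")
    return q


def _atom_conjugated(atom: Chem.Atom) -> float:
    return float(any(b.GetIsConjugated() for b in atom.GetBonds()))


# name -> (raw value function, fixed affine range (lo, hi))
_ATOM_DESCRIPTORS: dict[str, tuple[Callable[[Chem.Atom], float], tuple[float, float]]] = {
    "electronegativity": (_electronegativity, (0.7, 4.0)),
    "mass": (lambda a: a.GetMass(), (1.0, 130.0)),
    "degree": (lambda a: float(a.GetDegree()), (0.0, 4.0)),
    "total_h": (lambda a: float(a.GetTotalNumHs()), (0.0, 4.0)),
    "formal_charge": (lambda a: float(a.GetFormalCharge()), (-2.0, 2.0)),
    "aromatic": (lambda a: float(a.GetIsAromatic()), (0.0, 1.0)),
    "in_ring": (lambda a: float(a.IsInRing()), (0.0, 1.0)),
    "hybridization": (lambda a: float(_HYBRIDIZATION_CODE.get(a.GetHybridization(), 0)), (0.0, 6.0)),
    "partial_charge": (_partial_charge, (-1.0, 1.0)),
    "conjugated": (_atom_conjugated, (0.0, 1.0)),
}

_BOND_DESCRIPTORS: dict[str, tuple[Callable[[Chem.Bond], float], tuple[float, float]]] = {
    "order": (lambda b: float(b.GetBondTypeAsDouble()), (1.0, 3.0)),
    "aromatic": (lambda b: float(b.GetIsAromatic()), (0.0, 1.0)),
    "ring": (lambda b: float(b.IsInRing()), (0.0, 1.0)),
    "conjugated": (lambda b: float(b.GetIsConjugated()), (0.0, 1.0)),
}

# Raw value imputed when a descriptor is undefined for an atom (e.g. the
# charge model fails to converge): the descriptor's neutral value.
_NEUTRAL_RAW = {"partial_charge": 0.0}


@dataclass(frozen=True)
class DescriptorConfig:
    """Names and fixed standardization ranges of the descriptor set.

    ``k_a``/``k_b`` (vector lengths) follow from the name tuples.  Ranges
    are per-descriptor affine scales ``x -> (x - lo) / (hi - lo)`` with
    constants fixed per run, so no descriptor dominates the RBF.
    """

    atom_names: tuple[str, ...] = tuple(_ATOM_DESCRIPTORS)
    bond_names: tuple[str, ...] = tuple(_BOND_DESCRIPTORS)
    atom_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: v[1] for k, v in _ATOM_DESCRIPTORS.items()}
    )
    bond_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: v[1] for k, v in _BOND_DESCRIPTORS.items()}
    )

    @property
    def k_a(self) -> int:
        return len(self.atom_names)

    @property
    def k_b(self) -> int:
        return len(self.bond_names)


DEFAULT_DESCRIPTOR_CONFIG = DescriptorConfig()


@dataclass
class MoleculeGraph:
    """Heavy-atom molecular graph with descriptor vectors.

    Atom indices are stable 0-based RDKit indices of the hydrogen-suppressed
    molecule and remain valid across all operations in a run.
    """

    mol: Chem.Mol
    source_id: str
    smiles: str
    atom_descriptors: np.ndarray | None = None  # (m, k_a) standardized
    bond_descriptors: np.ndarray | None = None  # (n_directed_edges, k_b)
    neighbors: list[np.ndarray] | None = None   # per-atom neighbor indices
    edge_index: list[np.ndarray] | None = None  # per-atom rows into bond_descriptors
    distances: np.ndarray | None = None         # topological distance matrix
    config: DescriptorConfig | None = None

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_atoms


@dataclass
class DatasetRecord:
    id: str
    molecule: MoleculeGraph
    label: str  # "active" | "decoy"
    cluster: str | None = None


@dataclass
class ScreeningDataset:
    """Labeled (and optionally chemotype-clustered) screening library."""

    records: list[DatasetRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("dataset record ids must be unique")
        clustered = any(r.cluster is not None for r in self.records if r.label == "active")
        if clustered:
            missing = [r.id for r in self.records if r.label == "active" and r.cluster is None]
            if missing:
                raise ValueError(f"actives without cluster in a clustered dataset: {missing}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label == "active" for r in self.records], dtype=bool)

    @property
    def clusters(self) -> list[str | None]:
        return [r.cluster for r in self.records]

    @property
    def molecules(self) -> list[MoleculeGraph]:
        return [r.molecule for r in self.records]

    @property
    def n_actives(self) -> int:
        return int(self.labels.sum())

    @property
    def n_decoys(self) -> int:
        return len(self) - self.n_actives

    def subset(self, indices: Sequence[int]) -> "ScreeningDataset":
        return ScreeningDataset([self.records[i] for i in indices])


def molecule_from_smiles(smiles: str, source_id: str,
                         config: DescriptorConfig = DEFAULT_DESCRIPTOR_CONFIG) -> MoleculeGraph:
    """Parse one SMILES into a descriptor-annotated :class:`MoleculeGraph`."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(source_id, f"unparsable SMILES {smiles!r}")
    graph = MoleculeGraph(mol=mol, source_id=source_id, smiles=smiles)
    return compute_descriptors(graph, config)


def read_smiles(path, config: DescriptorConfig = DEFAULT_DESCRIPTOR_CONFIG,
                errors: list[ParseError] | None = None) -> list[MoleculeGraph]:
    """Read a .smi file (one SMILES per line, optional trailing id token).

    Unparsable lines are collected into ``errors`` (and warned about); the
    run continues.  Ids default to the 1-based line number when absent.
    """
    molecules: list[MoleculeGraph] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else str(lineno)
            try:
                molecules.append(molecule_from_smiles(smiles, mol_id, config))
            except ParseError as exc:
                warnings.warn(str(exc), stacklevel=2)
                if errors is not None:
                    errors.append(exc)
    return molecules


def read_sdf(path, config: DescriptorConfig = DEFAULT_DESCRIPTOR_CONFIG,
             id_property: str | None = None,
             errors: list[ParseError] | None = None) -> list[MoleculeGraph]:
    """Read an SDF (V2000/V3000); explicit hydrogens are suppressed.

    The molecule title (or ``id_property`` when given) is used as id,
    falling back to the 1-based record number.
    """
    import os

    molecules: list[MoleculeGraph] = []
    if os.path.getsize(path) == 0:
        return molecules
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for recno, mol in enumerate(supplier, start=1):
        if mol is None:
            exc = ParseError(f"record {recno}", "malformed SDF record")
            warnings.warn(str(exc), stacklevel=2)
            if errors is not None:
                errors.append(exc)
            continue
        if id_property is not None and mol.HasProp(id_property):
            mol_id = mol.GetProp(id_property)
        elif mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            mol_id = mol.GetProp("_Name").strip()
        else:
            mol_id = str(recno)
        graph = MoleculeGraph(mol=mol, source_id=mol_id, smiles=Chem.MolToSmiles(mol))
        molecules.append(compute_descriptors(graph, config))
    return molecules


def read_manifest(path, delimiter: str | None = None,
                  config: DescriptorConfig = DEFAULT_DESCRIPTOR_CONFIG,
                  errors: list[ParseError] | None = None) -> ScreeningDataset:
    """Read a dataset manifest (columns id, smiles, label[, cluster])."""
    import pandas as pd

    frame = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    required = {"id", "smiles", "label"}
    if not required.issubset(frame.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}, got {list(frame.columns)}")
    records: list[DatasetRecord] = []
    for row in frame.itertuples(index=False):
        label = str(row.label).strip().lower()
        if label not in ("active", "decoy"):
            raise ValueError(f"record {row.id}: label must be active|decoy, got {row.label!r}")
        cluster = None
        if "cluster" in frame.columns:
            raw = getattr(row, "cluster")
            if raw is not None and not (isinstance(raw, float) and math.isnan(raw)) and str(raw).strip():
                cluster = str(raw).strip()
        try:
            molecule = molecule_from_smiles(str(row.smiles), str(row.id), config)
        except ParseError as exc:
            warnings.warn(str(exc), stacklevel=2)
            if errors is not None:
                errors.append(exc)
            continue
        records.append(DatasetRecord(id=str(row.id), molecule=molecule, label=label, cluster=cluster))
    return ScreeningDataset(records)


def _standardize(raw: np.ndarray, names: Sequence[str],
                 ranges: dict[str, tuple[float, float]]) -> np.ndarray:
    lo = np.array([ranges[n][0] for n in names])
    hi = np.array([ranges[n][1] for n in names])
    return (raw - lo) / (hi - lo)


def compute_descriptors(graph: MoleculeGraph,
                        config: DescriptorConfig = DEFAULT_DESCRIPTOR_CONFIG) -> MoleculeGraph:
    """Populate atom/bond descriptor vectors, adjacency and distances.

    Descriptor computation is a pure function of the graph and config.
    An undefined value (e.g. a failed charge model) is imputed with the
    descriptor's neutral raw value and a warning is emitted.
    """
    mol = graph.mol
    if mol.GetNumAtoms() == 0:
        raise ValueError(f"molecule {graph.source_id!r} has no heavy atoms")
    try:
        rdPartialCharges.ComputeGasteigerCharges(mol)
    except Exception:  # charge model failure: impute neutral downstream
        pass

    atom_raw = np.empty((mol.GetNumAtoms(), config.k_a))
    for i, atom in enumerate(mol.GetAtoms()):
        for d, name in enumerate(config.atom_names):
            func = _ATOM_DESCRIPTORS[name][0]
            value = func(atom)
            if not math.isfinite(value):
                value = _NEUTRAL_RAW.get(name, 0.0)
                warnings.warn(
                    f"{graph.source_id}: descriptor {name!r} undefined for atom {i}; "
                    f"imputed neutral value {value}", stacklevel=2)
            atom_raw[i, d] = value
    graph.atom_descriptors = _standardize(atom_raw, config.atom_names, config.atom_ranges)

    # Directed edge table: row e holds the bond descriptors of edge i->nb,
    # aligned with the per-atom neighbor lists.
    neighbors: list[np.ndarray] = []
    edge_index: list[np.ndarray] = []
    edge_rows: list[np.ndarray] = []
    counter = 0
    for i, atom in enumerate(mol.GetAtoms()):
        nbs, rows = [], []
        for bond in atom.GetBonds():
            nb = bond.GetOtherAtom(atom).GetIdx()
            raw = np.array([_BOND_DESCRIPTORS[n][0](bond) for n in config.bond_names])
            edge_rows.append(raw)
            nbs.append(nb)
            rows.append(counter)
            counter += 1
        neighbors.append(np.array(nbs, dtype=np.intp))
        edge_index.append(np.array(rows, dtype=np.intp))
    if edge_rows:
        bond_raw = np.vstack(edge_rows)
        graph.bond_descriptors = _standardize(bond_raw, config.bond_names, config.bond_ranges)
    else:
        graph.bond_descriptors = np.empty((0, config.k_b))
    graph.neighbors = neighbors
    graph.edge_index = edge_index

    dist = Chem.GetDistanceMatrix(mol).copy()
    dist[dist > 1e6] = np.inf  # disconnected fragments
    graph.distances = dist
    graph.config = config
    return graph


def topo_distance(graph: MoleculeGraph, i: int, j: int) -> float:
    """Topological (shortest bond path) distance; ``inf`` if disconnected."""
    if graph.distances is None:
        compute_descriptors(graph, graph.config or DEFAULT_DESCRIPTOR_CONFIG)
    m = graph.n_atoms
    if not (0 <= i < m and 0 <= j < m):
        raise IndexError(f"atom index out of range for molecule with {m} atoms")
    d = graph.distances[i, j]
    return float("inf") if math.isinf(d) else float(int(d)) if d == int(d) else float(d)
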