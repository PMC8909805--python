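"""Pharmacophore feature perception on posed 3-D molecules.

Perception rules (deliberately simple, fully documented so results are
reproducible):

* **aromatic** — every smallest ring whose atoms are all aromatic-flagged;
  the feature point is the unweighted centroid of the ring atoms.
* **donor** — any N or O bearing at least one hydrogen (explicit atom, an
  RDKit-derived total, or implied by standard valence); point on the heavy
  atom.
* **acceptor** — any O with no positive formal charge (carbonyl, ether,
  hydroxyl oxygens), and any N with no hydrogens, no positive charge and not
  part of an amide (pyridine-type nitrogen); point on the heavy atom.
* **hydrophobic** — each connected component of three or more non-aromatic
  carbons none of which touches a heteroatom, centroid of the component;
  additionally each methyl carbon hanging off an aromatic ring becomes a
  single-atom hydrophobic point.

No directional information (ring normals, donor projections) is used: the
matching stage works purely with distance tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .model import FeatureKind

__all__ = [
    "Molecule3D",
    "DetectedFeature",
    "PerceptionError",
    "perceive_features",
    "feature_census",
    "read_sdf",
    "write_feature_table",
]


class PerceptionError(ValueError):
    """Raised for molecules that cannot be perceived (empty, no coordinates)."""


@dataclass(frozen=True)
class Molecule3D:
    """A single posed conformer.

    ``atoms`` holds ``(element_symbol, formal_charge, aromatic_flag)`` per
    atom; ``bonds`` holds ``(i, j, order)`` with aromatic bonds encoded as
    order 1.5.  ``h_counts``, when given, is the per-atom total hydrogen
    count (as RDKit reports it); when absent, hydrogens are inferred from
    standard element valences.
    """

    mol_id: str
    conf_id: int
    atoms: tuple[tuple[str, int, bool], ...]
    bonds: tuple[tuple[int, int, float], ...]
    coords: np.ndarray
    h_counts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(tuple(a) for a in self.atoms))
        object.__setattr__(self, "bonds", tuple(tuple(b) for b in self.bonds))
        coords = np.asarray(self.coords, dtype=float)
        n = len(self.atoms)
        if n == 0:
            raise PerceptionError(f"{self.mol_id}: molecule has no atoms")
        if coords.shape != (n, 3):
            raise PerceptionError(
                f"{self.mol_id}: coords shape {coords.shape} does not match "
                f"{n} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise PerceptionError(f"{self.mol_id}: non-finite coordinates")
        object.__setattr__(self, "coords", coords)
        if self.conf_id < 0:
            raise PerceptionError(f"{self.mol_id}: conf_id must be >= 0")
        for i, j, _order in self.bonds:
            if i == j:
                raise PerceptionError(f"{self.mol_id}: self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise PerceptionError(f"{self.mol_id}: bond ({i},{j}) out of range")
        if self.h_counts is not None and len(self.h_counts) != n:
            raise PerceptionError(f"{self.mol_id}: h_counts length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule3D":
        """Return a copy with coordinates rigidly transformed (x -> R x + t)."""
        new = self.coords @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return Molecule3D(
            self.mol_id, self.conf_id, self.atoms, self.bonds, new, self.h_counts
        )

    @classmethod
    def from_rdkit(cls, mol, mol_id: str | None = None, conf_id: int = 0) -> "Molecule3D":
        """Build from an RDKit Mol carrying a 3-D conformer."""
        if mol is None:
            raise PerceptionError("cannot build Molecule3D from None")
        if mol.GetNumConformers() == 0:
            raise PerceptionError("RDKit molecule has no conformer (no 3-D coordinates)")
        conf = mol.GetConformer()
        atoms = tuple(
            (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic())
            for a in mol.GetAtoms()
        )
        bonds = tuple(
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
             1.5 if b.GetIsAromatic() else float(b.GetBondTypeAsDouble()))
            for b in mol.GetBonds()
        )
        coords = np.array(
            [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
              conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())]
        )
        h_counts = tuple(a.GetTotalNumHs(includeNeighbors=True) for a in mol.GetAtoms())
        if mol_id is None:
            mol_id = mol.GetProp("MOL_ID") if mol.HasProp("MOL_ID") else (
                mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name")
                else "mol"
            )
        return cls(mol_id, conf_id, atoms, bonds, coords, h_counts)


@dataclass(frozen=True)
class DetectedFeature:
    """A perceived pharmacophore point: kind, centroid (Å) and its atoms."""

    kind: FeatureKind
    centroid: np.ndarray
    atom_indices: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))
        object.__setattr__(self, "atom_indices", frozenset(self.atom_indices))
        if not self.atom_indices:
            raise PerceptionError("feature with no contributing atoms")


# standard valences used to imply hydrogens when no explicit counts are given
_DEFAULT_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3,
                    "F": 1, "Cl": 1, "Br": 1, "I": 1, "H": 1}

_HETERO = {"N", "O", "S", "P", "F", "Cl", "Br", "I"}


def _hydrogen_counts(mol: Molecule3D) -> list[int]:
    """Total hydrogens per heavy atom (explicit neighbours + implied)."""
    if mol.h_counts is not None:
        return list(mol.h_counts)
    n = mol.n_atoms
    order_sum = [0.0] * n
    explicit_h = [0] * n
    for i, j, order in mol.bonds:
        order_sum[i] += order
        order_sum[j] += order
        if mol.atoms[j][0] == "H":
            explicit_h[i] += 1
        if mol.atoms[i][0] == "H":
            explicit_h[j] += 1
    counts = []
    for idx, (sym, charge, _arom) in enumerate(mol.atoms):
        valence = _DEFAULT_VALENCE.get(sym)
        if valence is None:
            counts.append(explicit_h[idx])
            continue
        if sym in ("N", "O", "P", "S"):
            valence += charge  # N+ -> 4, O- -> 1, etc.
        elif sym == "C":
            valence -= abs(charge)
        implied = max(0, int(round(valence - order_sum[idx])))
        counts.append(explicit_h[idx] + implied)
    return counts


def _bond_graph(mol: Molecule3D) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    g.add_edges_from((i, j) for i, j, _ in mol.bonds)
    return g


def _aromatic_rings(mol: Molecule3D, graph: nx.Graph) -> list[list[int]]:
    """Smallest rings (5 or 6 atoms) whose members are all aromatic-flagged."""
    aromatic = [i for i in range(mol.n_atoms) if mol.atoms[i][2]]
    if len(aromatic) < 5:
        return []
    sub = graph.subgraph(aromatic)
    rings = []
    for cycle in nx.minimum_cycle_basis(sub):
        if 5 <= len(cycle) <= 6 and all(mol.atoms[i][2] for i in cycle):
            rings.append(sorted(cycle))
    rings.sort()
    return rings


def perceive_features(mol: Molecule3D) -> list[DetectedFeature]:
    """Detect pharmacophore features on one posed conformer.

    Deterministic: the result is ordered by kind (aromatic, hydrophobic,
    donor, acceptor) and, within a kind, by the smallest contributing atom
    index.

    Raises
    ------
    PerceptionError
        For an empty molecule or one without valid coordinates (these are
        enforced at :class:`Molecule3D` construction).
    """
    graph = _bond_graph(mol)
    h_counts = _hydrogen_counts(mol)
    coords = mol.coords
    features: list[DetectedFeature] = []

    # aromatic rings
    ring_atoms: set[int] = set()
    for ring in _aromatic_rings(mol, graph):
        ring_atoms.update(ring)
        features.append(
            DetectedFeature(FeatureKind.AROMATIC, coords[ring].mean(axis=0), ring)
        )

    # hydrophobic patches: components of >=3 non-aromatic carbons with no
    # heteroatom neighbour; aromatic carbons never join a patch
    def _is_patch_carbon(i: int) -> bool:
        sym, _charge, arom = mol.atoms[i]
        if sym != "C" or arom:
            return False
        return all(
            mol.atoms[j][0] in ("C", "H") for j in graph.neighbors(i)
        )

    patch_eligible = [i for i in range(mol.n_atoms) if _is_patch_carbon(i)]
    hydrophobic: list[list[int]] = []
    for comp in nx.connected_components(graph.subgraph(patch_eligible)):
        if len(comp) >= 3:
            hydrophobic.append(sorted(comp))
    # methyl substituents on aromatic rings as single-atom points
    for i in range(mol.n_atoms):
        sym, _charge, arom = mol.atoms[i]
        if sym != "C" or arom:
            continue
        heavy_nb = [j for j in graph.neighbors(i) if mol.atoms[j][0] != "H"]
        if len(heavy_nb) == 1 and mol.atoms[heavy_nb[0]][2]:
            hydrophobic.append([i])
    hydrophobic.sort()
    for comp in hydrophobic:
        features.append(
            DetectedFeature(FeatureKind.HYDROPHOBIC, coords[comp].mean(axis=0), comp)
        )

    # donors and acceptors on heavy atoms
    donors: list[int] = []
    acceptors: list[int] = []
    for i, (sym, charge, arom) in enumerate(mol.atoms):
        if sym not in ("N", "O"):
            continue
        has_h = h_counts[i] >= 1
        if has_h:
            donors.append(i)
        if charge > 0:
            continue
        if sym == "O":
            acceptors.append(i)
        elif not has_h and not _is_amide_nitrogen(mol, graph, i):
            acceptors.append(i)
    for i in donors:
        features.append(DetectedFeature(FeatureKind.DONOR, coords[i], [i]))
    for i in acceptors:
        features.append(DetectedFeature(FeatureKind.ACCEPTOR, coords[i], [i]))

    return features


def _is_amide_nitrogen(mol: Molecule3D, graph: nx.Graph, i: int) -> bool:
    """True when atom i is a nitrogen bonded to a carbonyl carbon."""
    double_bonded_o = {
        (a, b) for a, b, order in mol.bonds
        if order == 2.0 and {mol.atoms[a][0], mol.atoms[b][0]} == {"C", "O"}
    }
    carbonyl_carbons = {
        (a if mol.atoms[a][0] == "C" else b) for a, b in double_bonded_o
    }
    return any(j in carbonyl_carbons for j in graph.neighbors(i))


def feature_census(mol: Molecule3D) -> dict[FeatureKind, int]:
    """Count perceived features per kind; values sum to the feature total."""
    counts = {kind: 0 for kind in FeatureKind}
    for feat in perceive_features(mol):
        counts[feat.kind] += 1
    return counts


# --------------------------------------------------------------------------
# SDF input / feature-table output
# --------------------------------------------------------------------------


def read_sdf(path: str | Path) -> list[Molecule3D]:
    """Read a (multi-record, V2000) SDF into posed conformers.

    Conformers of one molecule are separate records sharing a ``MOL_ID``
    property; ``CONF_ID`` gives the conformer index and defaults to the
    record's position within its molecule.  Records RDKit cannot parse are
    skipped.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SDF not found: {path}")
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    mols: list[Molecule3D] = []
    seen_per_id: dict[str, int] = {}
    for rec_idx, rdmol in enumerate(supplier):
        if rdmol is None:
            continue
        if rdmol.HasProp("MOL_ID"):
            mol_id = rdmol.GetProp("MOL_ID")
        elif rdmol.HasProp("_Name") and rdmol.GetProp("_Name"):
            mol_id = rdmol.GetProp("_Name")
        else:
            mol_id = f"record{rec_idx}"
        if rdmol.HasProp("CONF_ID"):
            conf_id = int(rdmol.GetProp("CONF_ID"))
        else:
            conf_id = seen_per_id.get(mol_id, 0)
        seen_per_id[mol_id] = conf_id + 1
        mols.append(Molecule3D.from_rdkit(rdmol, mol_id=mol_id, conf_id=conf_id))
    return mols


def write_feature_table(mols: Iterable[Molecule3D], path: str | Path) -> None:
    """Write perceived features for a set of conformers as a TSV table."""
    import pandas as pd

    rows = []
    for mol in mols:
        for feat in perceive_features(mol):
            rows.append(
                {
                    "mol_id": mol.mol_id,
                    "conf_id": mol.conf_id,
                    "kind": feat.kind.value,
                    "x": feat.centroid[0],
                    "y": feat.centroid[1],
                    "z": feat.centroid[2],
                    "atom_indices": ",".join(map(str, sorted(feat.atom_indices))),
                }
            )
    pd.DataFrame(
        rows,
        columns=["mol_id", "conf_id", "kind", "x", "y", "z", "atom_indices"],
    ).to_csv(path, sep="\t", index=False)
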