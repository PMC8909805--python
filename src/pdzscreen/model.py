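"""Pharmacophore model definition, validation and (de)serialisation.

A pharmacophore model is an ordered set of typed spatial queries — aromatic,
hydrophobic, hydrogen-bond donor and acceptor points — each with a spherical
distance tolerance and an optional *must-have* flag.  A pose is accepted when
it matches at least ``min_match`` queries including every required one.

The shipped default model encodes the Dishevelled-1 (DVL1) PDZ selectivity
pharmacophore: seven queries (three aromatic, two hydrophobic, one donor, one
acceptor), with the hydrophobic query for the Leu12/Val75/Ile81 sub-pocket —
the feature that discriminates the DVL1 groove from NHERF1 PDZ1 — marked as
required.  Polar queries carry a 2.0 Å tolerance, hydrophobic and aromatic
queries 2.5 Å; aromatic and hydrophobic features are treated as mutually
interchangeable during matching.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FeatureKind",
    "Query",
    "PharmacophoreModel",
    "ModelError",
    "default_tolerance",
    "load_model",
    "save_model",
    "build_default_dvl1_model",
]


class ModelError(ValueError):
    """Raised when a pharmacophore model file or definition is invalid."""


class FeatureKind(str, enum.Enum):
    """The four pharmacophore feature types.

    Aromatic and hydrophobic are mutually compatible for matching (a ring can
    occupy a hydrophobic site and vice versa); donor and acceptor each match
    only their own kind.
    """

    AROMATIC = "aromatic"
    HYDROPHOBIC = "hydrophobic"
    DONOR = "donor"
    ACCEPTOR = "acceptor"

    @property
    def is_polar(self) -> bool:
        return self in (FeatureKind.DONOR, FeatureKind.ACCEPTOR)

    def compatible_with(self, other: "FeatureKind") -> bool:
        if self.is_polar or other.is_polar:
            return self is other
        return True  # aromatic <-> hydrophobic equivalence


#: Default tolerance radii in Å: 2.0 for polar queries, 2.5 for
#: hydrophobic/aromatic ones.
POLAR_TOLERANCE = 2.0
APOLAR_TOLERANCE = 2.5


def default_tolerance(kind: FeatureKind) -> float:
    """Default tolerance sphere radius (Å) for a query of the given kind."""
    return POLAR_TOLERANCE if kind.is_polar else APOLAR_TOLERANCE


@dataclass(frozen=True)
class Query:
    """One pharmacophore query: a typed point with a tolerance sphere.

    Parameters
    ----------
    id : str
        Short unique identifier within the model.
    kind : FeatureKind
        Feature type the query accepts (subject to compatibility rules).
    position : (3,) array
        Query centre in the model frame, Å.
    tolerance : float
        Tolerance sphere radius, Å.  Must be positive.
    required : bool
        Must-have flag: a pose missing this query is rejected regardless of
        its total match count.
    """

    id: str
    kind: FeatureKind
    position: np.ndarray
    tolerance: float
    required: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ModelError(f"query {self.id!r}: position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ModelError(f"query {self.id!r}: non-finite position")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "kind", FeatureKind(self.kind))
        if not (self.tolerance > 0):
            raise ModelError(
                f"query {self.id!r}: tolerance must be > 0, got {self.tolerance}"
            )


@dataclass(frozen=True)
class PharmacophoreModel:
    """An ordered collection of queries plus the minimum-match rule."""

    name: str
    queries: tuple[Query, ...]
    min_match: int = 5

    def __post_init__(self) -> None:
        queries = tuple(self.queries)
        object.__setattr__(self, "queries", queries)
        if len(queries) == 0:
            raise ModelError(f"model {self.name!r}: must define at least one query")
        ids = [q.id for q in queries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ModelError(f"model {self.name!r}: duplicate query ids {sorted(dupes)}")
        if not (1 <= self.min_match <= len(queries)):
            raise ModelError(
                f"model {self.name!r}: min_match={self.min_match} outside "
                f"[1, {len(queries)}]"
            )

    @property
    def query_count(self) -> int:
        return len(self.queries)

    @property
    def required_ids(self) -> tuple[str, ...]:
        return tuple(q.id for q in self.queries if q.required)

    def kind_counts(self) -> dict[FeatureKind, int]:
        counts = {kind: 0 for kind in FeatureKind}
        for q in self.queries:
            counts[q.kind] += 1
        return counts

    def positions(self) -> np.ndarray:
        """(n_queries, 3) array of query centres."""
        return np.array([q.position for q in self.queries])


# --------------------------------------------------------------------------
# JSON (de)serialisation.
#
# Schema: {"name": str, "min_match": int?, "queries": [
#   {"id": str, "kind": "aromatic|hydrophobic|donor|acceptor",
#    "xyz": [x, y, z], "tolerance": float?, "required": bool?}, ...]}
# Omitted tolerances default by kind (2.0 polar / 2.5 hydrophobic-aromatic);
# omitted min_match defaults to 5; omitted required defaults to false.
# --------------------------------------------------------------------------


def load_model(path: str | Path) -> PharmacophoreModel:
    """Load and validate a pharmacophore model from a JSON file.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ModelError
        On malformed schema, unknown feature kind, duplicate query ids,
        zero queries, or ``min_match`` exceeding the query count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "queries" not in doc:
        raise ModelError(f"{path}: expected an object with a 'queries' list")
    raw_queries = doc["queries"]
    if not isinstance(raw_queries, list):
        raise ModelError(f"{path}: 'queries' must be a list")

    queries = []
    for i, raw in enumerate(raw_queries):
        if not isinstance(raw, dict):
            raise ModelError(f"{path}: query #{i} is not an object")
        missing = {"id", "kind", "xyz"} - raw.keys()
        if missing:
            raise ModelError(f"{path}: query #{i} missing fields {sorted(missing)}")
        try:
            kind = FeatureKind(raw["kind"])
        except ValueError:
            raise ModelError(
                f"{path}: query {raw.get('id', i)!r} has unknown kind "
                f"{raw['kind']!r}"
            ) from None
        tolerance = raw.get("tolerance")
        if tolerance is None:
            tolerance = default_tolerance(kind)
        queries.append(
            Query(
                id=str(raw["id"]),
                kind=kind,
                position=np.asarray(raw["xyz"], dtype=float),
                tolerance=float(tolerance),
                required=bool(raw.get("required", False)),
            )
        )

    return PharmacophoreModel(
        name=str(doc.get("name", path.stem)),
        queries=tuple(queries),
        min_match=int(doc.get("min_match", 5)),
    )


def save_model(model: PharmacophoreModel, path: str | Path) -> None:
    """Write a model to JSON; ``load_model`` round-trips it exactly."""
    doc = {
        "name": model.name,
        "min_match": model.min_match,
        "queries": [
            {
                "id": q.id,
                "kind": q.kind.value,
                "xyz": [float(x) for x in q.position],
                "tolerance": q.tolerance,
                "required": q.required,
            }
            for q in model.queries
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


# --------------------------------------------------------------------------
# Default DVL1 selectivity model.
#
# No experimental coordinates exist for the query points (the receptor model
# is not public), so the default uses an idealised right-handed frame built
# from the described binding mode of the lead indole-2-carboxamide: three
# aromatic anchors (dimethylphenyl ring engaging Arg69/Arg72, indole ring at
# Val68, pyridine ring at Ile14/Val75), a donor point for the indole NH
# backbone hydrogen bond, an acceptor point for the carboxamide oxygen, one
# generic hydrophobic anchor, and the required hydrophobic query for the
# Leu12/Val75/Ile81 sub-pocket.  Aromatic-aromatic centroid separations fall
# in the 5-9 Å range typical of a PDZ groove, and every inter-query
# separation exceeds 4 Å (larger than any tolerance sphere) so that distinct
# queries can never be satisfied by a single feature position.
# --------------------------------------------------------------------------

_DVL1_QUERIES: tuple[tuple[str, FeatureKind, tuple[float, float, float], bool], ...] = (
    ("ar1", FeatureKind.AROMATIC, (0.0, 0.0, 0.0), False),   # dimethylphenyl site
    ("ar2", FeatureKind.AROMATIC, (5.2, 0.0, 0.0), False),   # indole site
    ("ar3", FeatureKind.AROMATIC, (2.6, 4.5, 0.0), False),   # pyridine site
    ("hyd_subpocket", FeatureKind.HYDROPHOBIC, (2.6, 1.5, 4.0), True),  # Leu12/Val75/Ile81
    ("hyd2", FeatureKind.HYDROPHOBIC, (-2.0, -3.5, 1.0), False),
    ("don", FeatureKind.DONOR, (6.5, 3.5, -1.5), False),     # indole NH -> Ile16 backbone
    ("acc", FeatureKind.ACCEPTOR, (-1.5, 3.0, -2.5), False), # carboxamide oxygen
)


def build_default_dvl1_model() -> PharmacophoreModel:
    """Construct the shipped 7-query DVL1 selectivity model.

    Composition: 3 aromatic + 2 hydrophobic + 1 donor + 1 acceptor queries,
    ``min_match`` of 5, and exactly one required hydrophobic query (the
    selectivity sub-pocket).  Tolerances are the kind defaults.
    """
    queries = tuple(
        Query(
            id=qid,
            kind=kind,
            position=np.array(xyz, dtype=float),
            tolerance=default_tolerance(kind),
            required=required,
        )
        for qid, kind, xyz, required in _DVL1_QUERIES
    )
    return PharmacophoreModel(name="dvl1-selectivity", queries=queries, min_match=5)
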