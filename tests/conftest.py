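import itertools

import numpy as np
import pytest

from pdzscreen import (
    DetectedFeature,
    FeatureKind,
    Molecule3D,
    PharmacophoreModel,
    Query,
    build_default_dvl1_model,
)


@pytest.fixture(scope="session")
def dvl1_model() -> PharmacophoreModel:
    return build_default_dvl1_model()


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation via QR decomposition."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def embed_3d(smiles: str, seed: int = 11) -> Molecule3D:
    """Posed conformer from SMILES via RDKit ETKDG embedding."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    assert AllChem.EmbedMolecule(mol, randomSeed=seed) == 0
    return Molecule3D.from_rdkit(mol, mol_id=smiles)


def brute_force_match(features, model: PharmacophoreModel):
    """Independent exhaustive oracle for pre-aligned matching.

    Enumerates every injective kind-compatible within-tolerance assignment,
    maximising the match count and breaking ties by lower matched-pair RMSD.
    Returns (n_matched, accepted).
    """
    queries = model.queries
    nf = len(features)
    cand = [
        [
            fi
            for fi in range(nf)
            if q.kind.compatible_with(features[fi].kind)
            and np.linalg.norm(features[fi].centroid - q.position) <= q.tolerance
        ]
        for q in queries
    ]
    best = {"n": 0, "rmsd": float("inf"), "pairs": []}

    def rec(qi: int, used: set, pairs: list) -> None:
        if qi == len(queries):
            n = len(pairs)
            if n == 0:
                return
            ss = sum(
                np.linalg.norm(features[fi].centroid - queries[k].position) ** 2
                for k, fi in pairs
            )
            rmsd = (ss / n) ** 0.5
            if n > best["n"] or (n == best["n"] and rmsd < best["rmsd"] - 1e-12):
                best.update(n=n, rmsd=rmsd, pairs=list(pairs))
            return
        rec(qi + 1, used, pairs)
        for fi in cand[qi]:
            if fi not in used:
                used.add(fi)
                pairs.append((qi, fi))
                rec(qi + 1, used, pairs)
                pairs.pop()
                used.discard(fi)

    rec(0, set(), [])
    matched_ids = {queries[k].id for k, _ in best["pairs"]}
    accepted = best["n"] >= model.min_match and all(
        rid in matched_ids for rid in model.required_ids
    )
    return best["n"], accepted


def random_instance(seed: int):
    """A small random (features, model) matching instance for oracle tests."""
    rng = np.random.default_rng(seed)
    kinds = list(FeatureKind)
    nq = int(rng.integers(2, 8))
    nf = int(rng.integers(1, 11))
    queries = tuple(
        Query(
            id=f"q{i}",
            kind=kinds[rng.integers(4)],
            position=rng.uniform(-5, 5, 3),
            tolerance=float(rng.uniform(0.5, 3.0)),
            required=bool(rng.random() < 0.2),
        )
        for i in range(nq)
    )
    model = PharmacophoreModel("rand", queries, min_match=int(rng.integers(1, nq + 1)))
    features = [
        DetectedFeature(kinds[rng.integers(4)], rng.uniform(-6, 6, 3), [0])
        for _ in range(nf)
    ]
    return features, model
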