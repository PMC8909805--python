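"""Synthetic-data generators: planted-truth screening libraries, FRET
saturation curves, dose-response series.

The library generator emulates the *structure* of the original screen (a
multi-conformer docked library with a known outcome per molecule) at a
configurable scale, using minimal synthetic scaffolds whose atoms are chosen
to trigger the documented perception rules — benzene hexagons for aromatic
points, short alkane chains for hydrophobic patches, an amine nitrogen for
donors, a carbonyl oxygen for acceptors — rather than drug-like chemistry:
the surface under test is geometric matching, not chemical realism.

Actives are constructed to satisfy the acceptance rule by construction
(every planted feature lands inside its query's tolerance sphere, required
queries always included); decoys violate it in one of four documented ways.
Guarantees hold in the pre-aligned frame, the screen's default mode.

Curve generators produce the study's measurement designs: a 2-38 μM
protein titration read out as normalised fluorescence, and log-spaced dose
series with multiplicative Gaussian noise (fluorescence/absorbance error
scales with intensity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import BindingCurve, DoseResponse, apparent_kd, hyperbolic, logistic4
from .model import FeatureKind, PharmacophoreModel, Query

__all__ = [
    "DECOY_MODES",
    "LibrarySpec",
    "GeneratorError",
    "generate_library",
    "generate_binding_curve",
    "generate_dose_response",
    "default_titration",
    "default_doses",
]

DECOY_MODES = (
    "missing_required",
    "too_few_features",
    "displaced_beyond_tolerance",
    "kind_mismatch",
)

#: Planted feature offsets are capped at this radius (Å) so a feature planted
#: for one query can never stray into a *different* query's tolerance sphere
#: (the default model keeps all inter-query separations above 4 Å).
_OFFSET_CAP = 1.5


class GeneratorError(ValueError):
    """Raised for generator specs that cannot guarantee their ground truth."""


@dataclass(frozen=True)
class LibrarySpec:
    """Parameters of a planted-truth screening library.

    ``jitter_sd`` is the positional noise (Å) on planted feature points; it
    must stay below half the smallest query tolerance or the active
    construction guarantee breaks (the generator refuses).  ``decoy_modes``
    cycles over the decoy molecules; the default exercises all four failure
    modes.
    """

    n_molecules: int = 200
    n_conformers: int = 10
    frac_active: float = 0.25
    seed: int = 0
    jitter_sd: float = 0.0
    decoy_modes: tuple[str, ...] = DECOY_MODES

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_active <= 1.0):
            raise GeneratorError("frac_active must be in [0, 1]")
        if self.jitter_sd < 0:
            raise GeneratorError("jitter_sd must be >= 0")
        if self.n_conformers < 1:
            raise GeneratorError("n_conformers must be >= 1")
        if self.n_molecules < 1:
            raise GeneratorError("n_molecules must be >= 1")
        unknown = set(self.decoy_modes) - set(DECOY_MODES)
        if unknown:
            raise GeneratorError(f"unknown decoy modes {sorted(unknown)}")
        if not self.decoy_modes:
            raise GeneratorError("decoy_modes must not be empty")


# --------------------------------------------------------------------------
# Fragment construction (RDKit)
# --------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _fragment_geometry(
    kind: FeatureKind, center: np.ndarray, rng: np.random.Generator
) -> tuple[list[tuple[str, int]], list[tuple[int, int, int]], np.ndarray]:
    """Atoms (symbol, charge), bonds (i, j, order code) and coordinates of a
    minimal fragment whose perceived feature point sits exactly at `center`.

    Bond order codes follow RDKit BondType values: 1 single, 2 double,
    12 aromatic.
    """
    rot = _random_rotation(rng)
    if kind is FeatureKind.AROMATIC:
        # regular hexagon, C-C 1.39 Å -> circumradius 1.39 Å; centroid = center
        ang = np.arange(6) * np.pi / 3.0
        local = 1.39 * np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])
        coords = local @ rot.T + center
        atoms = [("C", 0)] * 6
        bonds = [(i, (i + 1) % 6, 12) for i in range(6)]
        return atoms, bonds, coords
    if kind is FeatureKind.HYDROPHOBIC:
        # three collinear sp3 carbons; centroid = middle carbon = center
        local = np.array([[-1.5, 0.0, 0.0], [0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
        coords = local @ rot.T + center
        return [("C", 0)] * 3, [(0, 1, 1), (1, 2, 1)], coords
    if kind is FeatureKind.DONOR:
        # amine nitrogen (implicit hydrogens); donor point on the N
        return [("N", 0)], [], center.reshape(1, 3)
    # acceptor: carbonyl oxygen; acceptor point on the O
    direction = rot @ np.array([1.0, 0.0, 0.0])
    coords = np.vstack([center, center + 1.22 * direction])  # O, C
    return [("O", 0), ("C", 0)], [(0, 1, 2)], coords


def _build_rdkit_conformer(
    placements: list[tuple[FeatureKind, np.ndarray]],
    rng: np.random.Generator,
    mol_id: str,
    conf_id: int,
):
    """Assemble one multi-fragment pseudo-molecule as a sanitised RDKit Mol."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    all_coords: list[np.ndarray] = []
    for kind, center in placements:
        atoms, bonds, coords = _fragment_geometry(kind, np.asarray(center), rng)
        base = rw.GetNumAtoms()
        for sym, charge in atoms:
            atom = Chem.Atom(sym)
            atom.SetFormalCharge(charge)
            rw.AddAtom(atom)
        for i, j, code in bonds:
            bt = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                  12: Chem.BondType.AROMATIC}[code]
            rw.AddBond(base + i, base + j, bt)
            if code == 12:
                rw.GetAtomWithIdx(base + i).SetIsAromatic(True)
                rw.GetAtomWithIdx(base + j).SetIsAromatic(True)
        all_coords.append(coords)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    xyz = np.vstack(all_coords)
    for i, (x, y, z) in enumerate(xyz):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    mol.AddConformer(conf, assignId=True)
    mol.SetProp("_Name", mol_id)
    mol.SetProp("MOL_ID", mol_id)
    mol.SetProp("CONF_ID", str(conf_id))
    return mol


# --------------------------------------------------------------------------
# Library generation
# --------------------------------------------------------------------------


def _jitter(rng: np.random.Generator, sd: float) -> np.ndarray:
    """Gaussian positional noise truncated at 2 sd in norm, so a planted
    point placed within (tolerance − 2·sd) stays inside the tolerance."""
    if sd == 0:
        return np.zeros(3)
    v = rng.normal(0.0, sd, size=3)
    norm = np.linalg.norm(v)
    if norm > 2.0 * sd:
        v *= (2.0 * sd) / norm
    return v


def _planted_point(
    query: Query, rng: np.random.Generator, jitter_sd: float
) -> np.ndarray:
    margin = min(query.tolerance - 2.0 * jitter_sd, _OFFSET_CAP)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    offset = direction * rng.uniform(0.0, margin) + _jitter(rng, jitter_sd)
    # hard cap keeps the point inside its own sphere and outside all others
    cap = min(query.tolerance, _OFFSET_CAP)
    norm = np.linalg.norm(offset)
    if norm > cap:
        offset *= cap / norm
    return query.position + offset


_MISMATCH_KIND = {
    FeatureKind.AROMATIC: FeatureKind.DONOR,
    FeatureKind.HYDROPHOBIC: FeatureKind.DONOR,
    FeatureKind.DONOR: FeatureKind.HYDROPHOBIC,
    FeatureKind.ACCEPTOR: FeatureKind.HYDROPHOBIC,
}


def generate_library(
    spec: LibrarySpec,
    model: PharmacophoreModel,
    sdf_path: str | Path,
    truth_path: str | Path | None = None,
) -> tuple[Path, pd.DataFrame]:
    """Emit a planted-truth multi-conformer SDF library and its truth table.

    Actives carry one conformer (the planted best) whose pseudo-atoms
    realise at least ``min_match`` kind-compatible features including every
    required query, each inside its tolerance sphere; the other conformers
    are rigidly displaced far outside every sphere.  Decoys violate the
    acceptance rule in the mode recorded per molecule: ``missing_required``
    (all non-required queries planted), ``too_few_features`` (min_match − 1
    planted), ``displaced_beyond_tolerance`` (full set, then displaced), or
    ``kind_mismatch`` (polar and apolar fragment kinds swapped in place).

    Deterministic for a fixed seed (byte-identical outputs).  Returns the
    SDF path and the truth table (also written as TSV next to the SDF, or to
    ``truth_path``).
    """
    from rdkit import Chem

    if spec.jitter_sd >= min(q.tolerance for q in model.queries) / 2.0:
        raise GeneratorError(
            "jitter_sd too large to guarantee active construction "
            "(must be < half the smallest tolerance)"
        )
    q_pos = model.positions()
    seps = np.linalg.norm(q_pos[:, None, :] - q_pos[None, :, :], axis=2)
    max_sep = float(seps.max())
    off_diag = seps[~np.eye(len(q_pos), dtype=bool)]
    max_tol = max(q.tolerance for q in model.queries)
    if off_diag.min() <= max_tol + _OFFSET_CAP:
        raise GeneratorError(
            "model queries too close together for guaranteed decoy truth "
            f"(min separation {off_diag.min():.2f} Å)"
        )
    displacement = max_sep + 2.0 * max_tol + 1.0  # provably clears all spheres

    rng = np.random.default_rng(spec.seed)
    n_active = int(round(spec.frac_active * spec.n_molecules))
    width = max(4, len(str(spec.n_molecules)))
    is_active = np.zeros(spec.n_molecules, dtype=bool)
    is_active[rng.permutation(spec.n_molecules)[:n_active]] = True

    required = [q for q in model.queries if q.required]
    optional = [q for q in model.queries if not q.required]

    sdf_path = Path(sdf_path)
    writer = Chem.SDWriter(str(sdf_path))
    writer.SetForceV3000(False)
    truth_rows = []
    decoy_counter = 0
    for idx in range(spec.n_molecules):
        mol_id = f"mol{idx:0{width}d}"
        active = bool(is_active[idx])
        if active:
            decoy_mode = ""
            n_plant = int(rng.integers(model.min_match, model.query_count + 1))
            extra = list(rng.permutation(len(optional))[: n_plant - len(required)])
            planted_queries = required + [optional[k] for k in sorted(extra)]
            best_conf = int(rng.integers(spec.n_conformers))
        else:
            decoy_mode = spec.decoy_modes[decoy_counter % len(spec.decoy_modes)]
            decoy_counter += 1
            best_conf = -1
        for conf_id in range(spec.n_conformers):
            if active:
                placements = [
                    (q.kind, _planted_point(q, rng, spec.jitter_sd))
                    for q in planted_queries
                ]
                displaced = conf_id != best_conf
            else:
                placements, displaced = _decoy_placements(
                    decoy_mode, model, required, optional, rng, spec.jitter_sd
                )
            if displaced:
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                placements = [
                    (kind, point + displacement * u) for kind, point in placements
                ]
            mol = _build_rdkit_conformer(placements, rng, mol_id, conf_id)
            writer.write(mol)
        truth_rows.append(
            {
                "mol_id": mol_id,
                "is_active": active,
                "decoy_mode": decoy_mode,
                "best_conf_id": best_conf if active else "",
            }
        )
    writer.close()

    truth = pd.DataFrame(
        truth_rows, columns=["mol_id", "is_active", "decoy_mode", "best_conf_id"]
    )
    if truth_path is None:
        truth_path = sdf_path.with_suffix(".truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)
    return sdf_path, truth


def _decoy_placements(
    mode: str,
    model: PharmacophoreModel,
    required: list[Query],
    optional: list[Query],
    rng: np.random.Generator,
    jitter_sd: float,
) -> tuple[list[tuple[FeatureKind, np.ndarray]], bool]:
    """Fragment placements for one decoy conformer, plus a displacement flag."""
    if mode == "missing_required":
        queries = optional
        kinds = [q.kind for q in queries]
        displaced = False
    elif mode == "too_few_features":
        n_plant = model.min_match - 1
        take = list(rng.permutation(len(optional))[: n_plant - len(required)])
        queries = required + [optional[k] for k in sorted(take)]
        kinds = [q.kind for q in queries]
        displaced = False
    elif mode == "displaced_beyond_tolerance":
        queries = list(model.queries)
        kinds = [q.kind for q in queries]
        displaced = True
    elif mode == "kind_mismatch":
        queries = list(model.queries)
        kinds = [_MISMATCH_KIND[q.kind] for q in queries]
        displaced = False
    else:  # pragma: no cover - spec validation catches this earlier
        raise GeneratorError(f"unknown decoy mode {mode!r}")
    placements = [
        (kind, _planted_point(q, rng, jitter_sd))
        for kind, q in zip(kinds, queries)
    ]
    return placements, displaced


# --------------------------------------------------------------------------
# Curve generation
# --------------------------------------------------------------------------


def default_titration(n_points: int = 10) -> np.ndarray:
    """The study's FRET titration design: 2-38 μM PDZ domain, linear."""
    return np.linspace(2.0, 38.0, n_points)


def default_doses(ec50: float, n_points: int = 8) -> np.ndarray:
    """Log-spaced doses spanning 0.01x to 100x the generating EC50."""
    return ec50 * np.logspace(-2.0, 2.0, n_points)


def generate_binding_curve(
    kd: float,
    ki: float | None = None,
    inhibitor_conc: float = 0.0,
    concentrations: np.ndarray | None = None,
    noise_sd_frac: float = 0.0,
    seed: int = 0,
    f0: float = 0.0,
    fmax: float = 1.0,
) -> BindingCurve:
    """Simulate a saturation titration, optionally under competition.

    The signal follows ``F0 + Fmax·c/(Kd_app + c)`` with
    ``Kd_app = Kd·(1 + [I]/Ki)`` when an inhibitor is present, multiplied by
    ``1 + N(0, noise_sd_frac)`` per point.  Deterministic for a fixed seed.
    """
    if kd <= 0:
        raise GeneratorError("Kd must be positive")
    if noise_sd_frac < 0:
        raise GeneratorError("noise_sd_frac must be >= 0")
    if inhibitor_conc < 0:
        raise GeneratorError("inhibitor_conc must be >= 0")
    conc = default_titration() if concentrations is None else np.asarray(
        concentrations, dtype=float
    )
    kd_app = kd if ki is None else apparent_kd(kd, ki, inhibitor_conc)
    signal = hyperbolic(conc, kd_app, fmax, f0)
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        signal = signal * (1.0 + rng.normal(0.0, noise_sd_frac, size=conc.shape))
    return BindingCurve(
        concentrations=conc, signal=signal, inhibitor_conc=inhibitor_conc
    )


def generate_dose_response(
    ec50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    doses: np.ndarray | None = None,
    noise_sd_frac: float = 0.0,
    seed: int = 0,
    replicate: int = 0,
) -> DoseResponse:
    """Simulate a 4PL dose-response series with multiplicative noise."""
    if ec50 <= 0:
        raise GeneratorError("EC50 must be positive")
    if noise_sd_frac < 0:
        raise GeneratorError("noise_sd_frac must be >= 0")
    d = default_doses(ec50) if doses is None else np.asarray(doses, dtype=float)
    resp = logistic4(d, ec50, hill, top, bottom)
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        resp = resp * (1.0 + rng.normal(0.0, noise_sd_frac, size=d.shape))
    return DoseResponse(doses=d, response=resp, replicate=replicate)
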