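"""Library screening: best-conformer matching, acceptance, ranking.

Mirrors the virtual-screening protocol that produced the DVL1 hit series: a
multi-conformer library (the original campaign used ~7000 molecules with 10
docked conformations each) is matched conformer by conformer against the
pharmacophore model; each molecule is represented by its best-fitness
conformer, acceptance requires matching at least ``min_match`` queries
including every must-have one, and the accepted molecules are ranked by
fitness to produce a shortlist (the study inspected the top 500).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .match import MatchResult, match_pose
from .model import PharmacophoreModel
from .perceive import Molecule3D, perceive_features, read_sdf

__all__ = ["ScreenConfig", "ScreenRecord", "ScreenError", "screen_library",
           "screen_molecules", "shortlist", "write_screen_table"]

log = logging.getLogger(__name__)


class ScreenError(ValueError):
    """Raised for invalid screening configuration or inputs."""


@dataclass(frozen=True)
class ScreenConfig:
    """Screening protocol parameters.

    ``n_conformers_expected`` is a protocol parameter, not a validity rule:
    molecules with fewer conformers are screened with a warning.
    """

    n_conformers_expected: int = 10
    top_n: int = 500
    mode: Literal["prealigned", "align"] = "prealigned"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ScreenError("top_n must be >= 1")
        if self.n_conformers_expected < 1:
            raise ScreenError("n_conformers_expected must be >= 1")
        if self.mode not in ("prealigned", "align"):
            raise ScreenError(f"unknown mode {self.mode!r}")


@dataclass
class ScreenRecord:
    """Per-molecule screening outcome (best conformer)."""

    mol_id: str
    best_conf_id: int
    fitness: float
    n_matched: int
    accepted: bool
    rank: int | None = None


def screen_molecules(
    mols: Sequence[Molecule3D],
    model: PharmacophoreModel,
    config: ScreenConfig | None = None,
) -> list[ScreenRecord]:
    """Screen already-loaded conformers; see :func:`screen_library`."""
    config = config or ScreenConfig()
    by_mol: dict[str, list[Molecule3D]] = {}
    for mol in mols:
        by_mol.setdefault(mol.mol_id, []).append(mol)
    if not by_mol:
        raise ScreenError("no molecules to screen")

    records: list[ScreenRecord] = []
    n_conformers = 0
    for mol_id in sorted(by_mol):
        conformers = sorted(by_mol[mol_id], key=lambda m: m.conf_id)
        if len(conformers) < config.n_conformers_expected:
            log.warning(
                "%s: %d conformer(s), expected %d — screening anyway",
                mol_id, len(conformers), config.n_conformers_expected,
            )
        best: MatchResult | None = None
        for conf in conformers:
            n_conformers += 1
            result = match_pose(
                perceive_features(conf), model, mode=config.mode,
                mol_id=mol_id, conf_id=conf.conf_id,
            )
            if best is None or result.fitness > best.fitness:
                best = result
        assert best is not None
        records.append(
            ScreenRecord(
                mol_id=mol_id,
                best_conf_id=best.conf_id,
                fitness=best.fitness,
                n_matched=best.n_matched,
                accepted=best.accepted,
            )
        )

    # fitness descending, ties broken by mol_id for a stable, order-free output
    records.sort(key=lambda r: (-r.fitness, r.mol_id))
    rank = 0
    for rec in records:
        if rec.accepted and rank < config.top_n:
            rank += 1
            rec.rank = rank
    n_accepted = sum(r.accepted for r in records)
    log.info(
        "screened %d molecules (%d conformers): %d accepted, %d shortlisted",
        len(records), n_conformers, n_accepted, rank,
    )
    return records


def screen_library(
    sdf_path: str | Path,
    model: PharmacophoreModel,
    config: ScreenConfig | None = None,
) -> list[ScreenRecord]:
    """Run the full screen on a multi-conformer SDF library.

    Conformers are grouped by the ``MOL_ID`` SDF property (robust to
    re-sorted files); each molecule is scored by its best-fitness conformer
    and accepted iff that conformer passes the model's acceptance rule.  The
    returned records are sorted by fitness (descending, ties by mol_id);
    ranks 1..K are assigned to the top ``config.top_n`` accepted molecules.
    """
    mols = read_sdf(sdf_path)
    if not mols:
        raise ScreenError(f"no readable molecules in {sdf_path}")
    return screen_molecules(mols, model, config)


def shortlist(records: Sequence[ScreenRecord], top_n: int) -> list[ScreenRecord]:
    """The ranked head of a screen: min(top_n, accepted count) records."""
    if top_n < 1:
        raise ScreenError("top_n must be >= 1")
    ranked = [r for r in records if r.rank is not None]
    ranked.sort(key=lambda r: r.rank)
    return ranked[:top_n]


def write_screen_table(records: Iterable[ScreenRecord], path: str | Path) -> None:
    """Write screen records as a TSV report."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "mol_id": r.mol_id,
                "best_conf_id": r.best_conf_id,
                "fitness": r.fitness,
                "n_matched": r.n_matched,
                "accepted": r.accepted,
                "rank": "" if r.rank is None else r.rank,
            }
            for r in records
        ],
        columns=["mol_id", "best_conf_id", "fitness", "n_matched", "accepted", "rank"],
    ).to_csv(path, sep="\t", index=False)
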