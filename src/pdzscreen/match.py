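"""Tolerance-sphere matching of perceived features against a model.

A match is an injective assignment of model queries to detected features in
which every assigned pair is kind-compatible (aromatic and hydrophobic are
interchangeable; donor and acceptor match only themselves) and lies within
the query's tolerance sphere.  The matcher maximises the number of matched
queries, breaking ties by lower RMSD over the matched pairs and then by
lexicographic query-id order.  A pose is *accepted* when it matches at least
``min_match`` queries including every required one.

Two modes:

* ``prealigned`` — feature coordinates are already in the model frame (the
  normal case when poses come from docking);
* ``align`` — a rigid transform of the pose is searched jointly with the
  assignment (exact enumeration on small instances, seed-and-extend
  otherwise).

Fitness is ``n_matched − mean(distance_i / tolerance_i)`` over the matched
pairs: unit-free, strictly increasing in the match count (the residual term
is always < 1) and decreasing in the normalised residuals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import FeatureKind, PharmacophoreModel
from .perceive import DetectedFeature

__all__ = [
    "MatchResult",
    "MatchError",
    "kabsch_superpose",
    "match_pose",
    "fitness_score",
    "write_match_table",
]

#: Above this count of kind-compatible injective seed assignments the
#: align-mode search falls back from exact enumeration to seed-and-extend.
EXACT_ALIGN_CAP = 100_000

_INFEASIBLE = 1.0e6  # assignment cost sentinel; >> any feasible squared distance


class MatchError(ValueError):
    """Raised for invalid matching inputs (empty model, bad point sets)."""


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one conformer's features against a model."""

    mol_id: str
    conf_id: int
    assignment: dict[str, int]          # query id -> feature index (injective)
    n_matched: int
    rmsd_matched: float                 # Å over matched pairs, post-alignment
    fitness: float
    accepted: bool
    mode: Literal["prealigned", "align"]
    distances: tuple[float, ...] = ()   # per matched pair, query-id order


def kabsch_superpose(
    P: np.ndarray, Q: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of point set P onto Q.

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (det +1) and ``t``
    a translation such that ``P @ R.T + t`` best approximates ``Q``.

    Raises
    ------
    MatchError
        If the sets are empty or of unequal size.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P.size == 0 or Q.size == 0:
        raise MatchError("kabsch_superpose: empty point set")
    if P.shape != Q.shape:
        raise MatchError(f"kabsch_superpose: size mismatch {P.shape} vs {Q.shape}")

    cP, cQ = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cP).T @ (Q - cQ)
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cQ - R @ cP
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return R, t, rmsd


# --------------------------------------------------------------------------
# Assignment search
# --------------------------------------------------------------------------


def _best_assignment(
    q_pos: np.ndarray,
    q_tol: np.ndarray,
    q_kinds: Sequence[FeatureKind],
    f_pos: np.ndarray,
    f_kinds: Sequence[FeatureKind],
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Maximum-cardinality, minimum-squared-distance feasible assignment.

    Solved as a rectangular linear assignment with squared distance as the
    cost of feasible pairs and a large sentinel for infeasible ones: the
    solver then first maximises the number of feasible pairs and, among
    those, minimises the total squared residual (hence the matched-pair
    RMSD).  Returns the matched ``(query_idx, feature_idx)`` pairs and their
    distances.
    """
    nq, nf = len(q_pos), len(f_pos)
    if nf == 0:
        return [], np.empty(0)
    dist = np.linalg.norm(q_pos[:, None, :] - f_pos[None, :, :], axis=2)
    feasible = dist <= q_tol[:, None]
    for qi in range(nq):
        for fi in range(nf):
            if not q_kinds[qi].compatible_with(f_kinds[fi]):
                feasible[qi, fi] = False
    cost = np.where(feasible, dist ** 2, _INFEASIBLE)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(qi, fi) for qi, fi in zip(rows, cols) if feasible[qi, fi]]
    return pairs, dist[tuple(zip(*pairs))] if pairs else np.empty(0)


def match_pose(
    features: Sequence[DetectedFeature],
    model: PharmacophoreModel,
    mode: Literal["prealigned", "align"] = "prealigned",
    mol_id: str = "",
    conf_id: int = 0,
) -> MatchResult:
    """Match one conformer's detected features against a pharmacophore model.

    In ``prealigned`` mode feature centroids are taken as already expressed
    in the model frame.  In ``align`` mode a rigid transform of the pose is
    optimised jointly with the assignment; the reported distances and RMSD
    are measured after alignment.
    """
    if model is None or model.query_count == 0:
        raise MatchError("match_pose: empty model")
    if mode not in ("prealigned", "align"):
        raise MatchError(f"match_pose: unknown mode {mode!r}")

    q_pos = model.positions()
    q_tol = np.array([q.tolerance for q in model.queries])
    q_kinds = [q.kind for q in model.queries]
    f_pos = np.array([f.centroid for f in features]).reshape(len(features), 3)
    f_kinds = [f.kind for f in features]

    if mode == "prealigned" or len(features) == 0:
        pairs, dists = _best_assignment(q_pos, q_tol, q_kinds, f_pos, f_kinds)
    else:
        pairs, dists = _align_search(q_pos, q_tol, q_kinds, f_pos, f_kinds)

    assignment = {model.queries[qi].id: fi for qi, fi in pairs}
    n_matched = len(pairs)
    rmsd = float(np.sqrt((dists ** 2).mean())) if n_matched else float("nan")
    matched_ids = set(assignment)
    accepted = n_matched >= model.min_match and all(
        rid in matched_ids for rid in model.required_ids
    )
    # order distances by query id for a reproducible report
    order = np.argsort([model.queries[qi].id for qi, _ in pairs]) if pairs else []
    dist_by_id = tuple(float(dists[k]) for k in order)
    tol_by_pair = np.array([q_tol[qi] for qi, _ in pairs])
    fitness = _fitness(n_matched, dists, tol_by_pair)
    return MatchResult(
        mol_id=mol_id,
        conf_id=conf_id,
        assignment=assignment,
        n_matched=n_matched,
        rmsd_matched=rmsd,
        fitness=fitness,
        accepted=accepted,
        mode=mode,
        distances=dist_by_id,
    )


def _fitness(n_matched: int, dists: np.ndarray, tols: np.ndarray) -> float:
    if n_matched == 0:
        return 0.0
    return float(n_matched - np.mean(dists / tols))


def fitness_score(result: MatchResult, model: PharmacophoreModel) -> float:
    """Fitness of a match: ``n_matched − mean(distance/tolerance)``.

    Bounded in ``(n_matched − 1, n_matched]``, so any result matching more
    queries outranks any result matching fewer, and tighter geometry wins
    within a match count.  Rejected poses are still scored.
    """
    if result.n_matched == 0:
        return 0.0
    tol = {q.id: q.tolerance for q in model.queries}
    tols = np.array([tol[qid] for qid in sorted(result.assignment)])
    dists = np.asarray(result.distances)
    if len(dists) != result.n_matched:
        raise MatchError("fitness_score: result lacks per-pair distances")
    return _fitness(result.n_matched, dists, tols)


# --------------------------------------------------------------------------
# Align-mode search
# --------------------------------------------------------------------------


def _compatible_candidates(
    q_kinds: Sequence[FeatureKind], f_kinds: Sequence[FeatureKind]
) -> list[list[int]]:
    return [
        [fi for fi, fk in enumerate(f_kinds) if qk.compatible_with(fk)]
        for qk in q_kinds
    ]


def _count_assignments(cands: list[list[int]], size: int) -> int:
    """Number of injective assignments over `size`-query subsets (capped)."""
    total = 0
    nq = len(cands)
    for subset in itertools.combinations(range(nq), size):
        prod = 1
        for qi in subset:
            prod *= len(cands[qi])
            if prod > EXACT_ALIGN_CAP:
                break
        total += prod
        if total > EXACT_ALIGN_CAP:
            return total
    return total


def _iter_injective(cands: list[list[int]], subset: tuple[int, ...]):
    """Yield injective feature choices for the given query subset."""
    def rec(pos: int, used: set[int], acc: list[int]):
        if pos == len(subset):
            yield list(acc)
            return
        for fi in cands[subset[pos]]:
            if fi not in used:
                used.add(fi)
                acc.append(fi)
                yield from rec(pos + 1, used, acc)
                acc.pop()
                used.discard(fi)

    yield from rec(0, set(), [])


def _align_search(
    q_pos: np.ndarray,
    q_tol: np.ndarray,
    q_kinds: Sequence[FeatureKind],
    f_pos: np.ndarray,
    f_kinds: Sequence[FeatureKind],
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Joint rigid-transform + assignment search.

    Exact on small instances: every injective kind-compatible assignment of
    every size (3 up to min(n_queries, n_features)) is Kabsch-aligned and
    kept if all its pairs land inside tolerance, provided the number of
    candidate assignments stays below :data:`EXACT_ALIGN_CAP`.  Otherwise a
    seed-and-extend heuristic aligns 3-pair seeds whose internal distance
    geometry is consistent, then greedily re-assigns and re-aligns.
    """
    nq, nf = len(q_pos), len(f_pos)
    max_size = min(nq, nf)
    cands = _compatible_candidates(q_kinds, f_kinds)

    best: tuple[int, float, list[tuple[int, int]], np.ndarray] = (0, 0.0, [], np.empty(0))

    def consider(pairs: list[tuple[int, int]], dists: np.ndarray) -> None:
        nonlocal best
        if not pairs:
            return
        rmsd = float(np.sqrt((dists ** 2).mean()))
        n = len(pairs)
        if n > best[0] or (n == best[0] and rmsd < best[1] - 1e-12):
            best = (n, rmsd, pairs, dists)

    if max_size < 3:
        # Degenerate poses: 1 point always superposable exactly; 2 points
        # constrained only by their separation.
        for subset in itertools.combinations(range(nq), max_size):
            for choice in _iter_injective(cands, subset):
                pairs = list(zip(subset, choice))
                if max_size == 1:
                    dists = np.zeros(1)
                else:
                    dq = np.linalg.norm(q_pos[subset[0]] - q_pos[subset[1]])
                    df = np.linalg.norm(f_pos[choice[0]] - f_pos[choice[1]])
                    resid = abs(dq - df) / 2.0
                    dists = np.full(2, resid)
                if np.all(dists <= q_tol[list(subset)]):
                    consider(pairs, dists)
        return best[2], best[3]

    total = sum(_count_assignments(cands, s) for s in range(3, max_size + 1))
    if total <= EXACT_ALIGN_CAP:
        for size in range(3, max_size + 1):
            for subset in itertools.combinations(range(nq), size):
                tol_sub = q_tol[list(subset)]
                for choice in _iter_injective(cands, subset):
                    P = f_pos[choice]
                    Q = q_pos[list(subset)]
                    R, t, _ = kabsch_superpose(P, Q)
                    moved = P @ R.T + t
                    dists = np.linalg.norm(moved - Q, axis=1)
                    if np.all(dists <= tol_sub):
                        consider(list(zip(subset, choice)), dists)
        return best[2], best[3]

    # seed-and-extend heuristic
    for q_seed in itertools.combinations(range(nq), 3):
        tol_seed = q_tol[list(q_seed)]
        for f_seed in _iter_injective(cands, q_seed):
            ok = True
            for (a, b) in itertools.combinations(range(3), 2):
                dq = np.linalg.norm(q_pos[q_seed[a]] - q_pos[q_seed[b]])
                df = np.linalg.norm(f_pos[f_seed[a]] - f_pos[f_seed[b]])
                if abs(dq - df) > tol_seed[a] + tol_seed[b]:
                    ok = False
                    break
            if not ok:
                continue
            R, t, _ = kabsch_superpose(f_pos[list(f_seed)], q_pos[list(q_seed)])
            pairs: list[tuple[int, int]] = []
            dists = np.empty(0)
            for _ in range(3):  # assign / re-align rounds
                moved = f_pos @ R.T + t
                pairs, dists = _best_assignment(
                    q_pos, q_tol, q_kinds, moved, f_kinds
                )
                if len(pairs) < 3:
                    break
                R, t, _ = kabsch_superpose(
                    f_pos[[fi for _, fi in pairs]],
                    q_pos[[qi for qi, _ in pairs]],
                )
            consider(pairs, dists)
    return best[2], best[3]


def write_match_table(
    results: Iterable[MatchResult], path
) -> None:
    """Write match results as a TSV report."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "mol_id": r.mol_id,
                "conf_id": r.conf_id,
                "n_matched": r.n_matched,
                "rmsd_matched": r.rmsd_matched,
                "fitness": r.fitness,
                "accepted": r.accepted,
                "assignment": ";".join(
                    f"{qid}:{fi}" for qid, fi in sorted(r.assignment.items())
                ),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "mol_id", "conf_id", "n_matched", "rmsd_matched",
            "fitness", "accepted", "assignment",
        ],
    ).to_csv(path, sep="\t", index=False)
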