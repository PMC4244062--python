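"""Stochastic greedy search for constrained maximum-LOD pedigrees.

Breeding biology often bounds how many mates a parent can have within a
spawning window: a full-sib pedigree allows exactly one mate per parent, a
half-sib pedigree at most two.  The search draws many independent random
pedigrees — offspring visited in random order, each taking its highest-LOD
parent-pair option that keeps every named parent within the mate limit —
and keeps the pedigree with the maximum total LOD.  Visiting offspring in
random order lets large families claim their shared parents early in at
least some draws, which is where high-likelihood solutions come from.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

DEFAULT_N_RESTARTS = 5000

#: partner label standing in for a missing parent when counting matings.
#: A family with a missing partner still occupies one mating slot for the
#: named parent: (s1, missing) plus (s1, d2) gives s1 two mates.
MISSING_MATE = "<missing>"

Option = tuple[str | None, str | None, float]


@dataclass
class PedigreeSolution:
    """One constrained pedigree: offspring -> (sire?, dam?) with total LOD."""

    assignments: dict[str, tuple[str | None, str | None]]
    total_lod: float
    max_mates: int | None
    restart_index: int = 0

    @property
    def n_families(self) -> int:
        fams = {
            pair for pair in self.assignments.values() if pair != (None, None)
        }
        return len(fams)


def _check_feasible(
    sire: str | None,
    dam: str | None,
    mates: Mapping[tuple[str, str], set],
    max_mates: int | None,
) -> bool:
    if max_mates is None:
        return True
    if sire is not None:
        partners = mates[("sire", sire)]
        key = dam if dam is not None else MISSING_MATE
        if key not in partners and len(partners) >= max_mates:
            return False
    if dam is not None:
        partners = mates[("dam", dam)]
        key = sire if sire is not None else MISSING_MATE
        if key not in partners and len(partners) >= max_mates:
            return False
    return True


def _prepared_options(
    scores: Mapping[str, Sequence[Option]],
) -> dict[str, tuple[list[Option], list[tuple[int, int]]]]:
    """Sort each offspring's positive-LOD options descending; mark tie runs."""
    prepared = {}
    for off, options in scores.items():
        opts = sorted(
            (o for o in options if np.isfinite(o[2]) and o[2] > 0.0),
            key=lambda o: (-o[2], o[0] or "", o[1] or ""),
        )
        runs = []
        i = 0
        while i < len(opts):
            j = i + 1
            while j < len(opts) and opts[j][2] == opts[i][2]:
                j += 1
            runs.append((i, j))
            i = j
        prepared[off] = (opts, runs)
    return prepared


def greedy_random_pedigree(
    scores: Mapping[str, Sequence[Option]],
    max_mates: int | None,
    rng: np.random.Generator,
    restart_index: int = 0,
    _prepared=None,
) -> PedigreeSolution:
    """One random greedy pedigree draw.

    ``scores`` maps each offspring to its options (sire?, dam?, lod); pair
    options carry None for the absent parent.  Offspring are visited in a
    uniformly random order and take their best feasible positive-LOD
    option; equal-LOD options are tried in random order.  An offspring with
    no feasible positive option is left with both parents missing (LOD
    contribution zero).
    """
    prepared = _prepared if _prepared is not None else _prepared_options(scores)
    offspring = list(prepared)
    order = rng.permutation(len(offspring))
    mates: dict[tuple[str, str], set] = defaultdict(set)
    assignments: dict[str, tuple[str | None, str | None]] = {}
    total = 0.0
    for idx in order:
        off = offspring[idx]
        opts, runs = prepared[off]
        chosen: Option | None = None
        for lo, hi in runs:
            if hi - lo == 1:
                candidates: Iterable[int] = (lo,)
            else:
                candidates = lo + rng.permutation(hi - lo)
            for k in candidates:
                sire, dam, lod = opts[k]
                if _check_feasible(sire, dam, mates, max_mates):
                    chosen = opts[k]
                    break
            if chosen is not None:
                break
        if chosen is None:
            assignments[off] = (None, None)
            continue
        sire, dam, lod = chosen
        assignments[off] = (sire, dam)
        total += lod
        if sire is not None:
            mates[("sire", sire)].add(dam if dam is not None else MISSING_MATE)
        if dam is not None:
            mates[("dam", dam)].add(sire if sire is not None else MISSING_MATE)
    return PedigreeSolution(assignments, total, max_mates, restart_index)


def stochastic_search(
    scores: Mapping[str, Sequence[Option]],
    max_mates: int | None,
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: int = 0,
) -> PedigreeSolution:
    """Best pedigree over independent random greedy draws.

    Each restart draws its own generator from (seed, restart) so the result
    is reproducible and restarts could run in parallel.  Returns the
    incumbent with its restart index — on well-separated data the optimum
    typically appears within the first fraction of the restarts.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    prepared = _prepared_options(scores)
    best: PedigreeSolution | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, r])
        sol = greedy_random_pedigree(scores, max_mates, rng, restart_index=r,
                                     _prepared=prepared)
        if best is None or sol.total_lod > best.total_lod:
            best = sol
    assert best is not None
    return best


def audit_constraints(solution: PedigreeSolution) -> bool:
    """Independent feasibility check: no parent exceeds its mate limit."""
    if solution.max_mates is None:
        return True
    mates: dict[tuple[str, str], set] = defaultdict(set)
    for sire, dam in solution.assignments.values():
        if sire is not None:
            mates[("sire", sire)].add(dam if dam is not None else MISSING_MATE)
        if dam is not None:
            mates[("dam", dam)].add(sire if sire is not None else MISSING_MATE)
    return all(len(v) <= solution.max_mates for v in mates.values())


def pedigree_summary(solution: PedigreeSolution) -> dict:
    """Family/sire/dam counts and total LOD for a pedigree solution."""
    families: dict[tuple[str | None, str | None], int] = defaultdict(int)
    for pair in solution.assignments.values():
        if pair != (None, None):
            families[pair] += 1
    sires = {s for s, _ in families if s is not None}
    dams = {d for _, d in families if d is not None}
    return {
        "n_offspring": len(solution.assignments),
        "n_families": len(families),
        "n_sires": len(sires),
        "n_dams": len(dams),
        "n_missing_sire_families": sum(1 for s, _ in families if s is None),
        "n_missing_dam_families": sum(1 for _, d in families if d is None),
        "n_both_missing_offspring": sum(
            1 for pair in solution.assignments.values() if pair == (None, None)
        ),
        "largest_family": max(families.values(), default=0),
        "total_lod": solution.total_lod,
        "restart_index": solution.restart_index,
        "max_mates": solution.max_mates,
    }
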