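"""Per-gene deduplication of homotrimer UMIs as a minimum set-cover problem.

Let ``S`` be the multiset of sequenced homotrimer UMIs attached to one gene
(and, in single-cell data, one cell).  For a sequenced UMI ``s`` the
candidate set ``C(s)`` contains every monomer sequence obtainable by picking,
in each trimer block, one of the bases actually observed in that block.  A
collapsed UMI ``c`` *explains* ``s`` whenever ``c ∈ C(s)``, and the number of
original molecules is estimated as the cardinality of the smallest set of
collapsed UMIs that together explain every sequenced UMI — a minimum set
cover over the subsets ``S_c = {s : c ∈ C(s)}``.

Production counting uses the classical greedy algorithm (repeatedly add the
candidate explaining the most still-unexplained UMIs), which carries the
(ln|S| + 1) approximation guarantee.  An exact solver — exhaustive search in
order of increasing cardinality, or integer linear programming via HiGHS —
serves as a validation oracle on small instances.

Groups in which every UMI collapses conclusively by majority vote skip the
cover entirely: the count is the number of distinct majority-collapsed
sequences.  The cover machinery engages only when at least one block of some
read is inconclusive (three distinct bases), which is exactly when reads can
no longer be resolved independently.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass
from math import prod
from typing import Iterable, Sequence

import numpy as np

from .codec import DNA_SET, filter_umis, iter_blocks, majority_collapse

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateCapExceeded",
    "CandidateMap",
    "CoverSolution",
    "DedupResult",
    "candidate_collapses",
    "build_candidate_map",
    "greedy_cover",
    "exact_cover",
    "dedup_group",
    "dedup_table",
]


class CandidateCapExceeded(ValueError):
    """Raised when a read's candidate enumeration would exceed the cap."""


def candidate_collapses(umi: str, cap: int = 4096) -> frozenset[str]:
    """Enumerate C(s): every monomer obtainable from the observed per-block bases.

    A clean block contributes its one base; a 2-of-3 block contributes both
    observed bases; an all-distinct block contributes three.  The product of
    the per-block choices is computed up front and compared against ``cap``
    before enumeration.  A block with no ACGT base yields an empty set (the
    read is undecodable).
    """
    per_block: list[list[str]] = []
    for block in iter_blocks(umi):
        bases = sorted(set(b for b in block.upper() if b in DNA_SET))
        if not bases:
            return frozenset()
        per_block.append(bases)
    n = prod(len(b) for b in per_block)
    if n > cap:
        raise CandidateCapExceeded(
            f"read would enumerate {n} candidate collapses (cap {cap})"
        )
    return frozenset("".join(p) for p in itertools.product(*per_block))


@dataclass
class CandidateMap:
    """The subsets ``S_c`` of a UMI group, keyed by collapsed candidate ``c``.

    ``members`` are the distinct raw homotrimer strings of the group (read
    multiplicity does not change which molecules exist, so coverage is
    evaluated over distinct strings).  ``sets[c]`` is the set of members
    explained by ``c``.  ``dropped`` lists members discarded because their
    candidate enumeration exceeded the cap.
    """

    members: tuple[str, ...]
    sets: dict[str, frozenset[str]]
    dropped: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class CoverSolution:
    """A set of collapsed UMIs explaining every member of a group."""

    chosen: tuple[str, ...]
    assignment: dict[str, str]
    optimal: bool = False

    @property
    def molecule_count(self) -> int:
        return len(self.chosen)


def build_candidate_map(members: Iterable[str], cap: int = 4096) -> CandidateMap:
    """Build the ``c -> S_c`` map for a group of (filtered) homotrimer UMIs."""
    distinct = list(dict.fromkeys(members))
    sets: dict[str, set[str]] = defaultdict(set)
    kept: list[str] = []
    dropped: list[str] = []
    for s in distinct:
        try:
            cands = candidate_collapses(s, cap=cap)
        except CandidateCapExceeded as exc:
            logger.warning("dropping read from group: %s", exc)
            dropped.append(s)
            continue
        if not cands:
            logger.warning("dropping undecodable read (no ACGT base in a block)")
            dropped.append(s)
            continue
        kept.append(s)
        for c in cands:
            sets[c].add(s)
    return CandidateMap(
        members=tuple(kept),
        sets={c: frozenset(v) for c, v in sets.items()},
        dropped=tuple(dropped),
    )


def greedy_cover(cmap: CandidateMap) -> CoverSolution:
    """Greedy minimum set cover: largest marginal coverage first.

    Ties on marginal coverage break toward the lexicographically smallest
    collapsed sequence, making the output deterministic.
    """
    if not cmap.members:
        raise ValueError("cannot cover an empty group")
    uncovered = set(cmap.members)
    chosen: list[str] = []
    assignment: dict[str, str] = {}
    while uncovered:
        best = max(
            cmap.sets.items(),
            key=lambda kv: (len(kv[1] & uncovered), _lex_key(kv[0])),
        )
        c, covers = best
        gain = covers & uncovered
        if not gain:  # unreachable if the map is well-formed
            raise RuntimeError("greedy stalled: member with no candidate")
        for s in gain:
            assignment[s] = c
        uncovered -= gain
        chosen.append(c)
    return CoverSolution(chosen=tuple(chosen), assignment=assignment, optimal=False)


def _lex_key(c: str) -> tuple[int, ...]:
    # max() picks the largest key, so invert character order for "smallest wins"
    return tuple(-ord(ch) for ch in c)


def _bitmask_sets(cmap: CandidateMap) -> tuple[dict[str, int], int]:
    index = {s: i for i, s in enumerate(cmap.members)}
    full = (1 << len(cmap.members)) - 1
    masks = {}
    for c, covers in cmap.sets.items():
        m = 0
        for s in covers:
            m |= 1 << index[s]
        masks[c] = m
    return masks, full


def exact_cover(
    cmap: CandidateMap, limit: int = 20, backend: str = "exhaustive"
) -> CoverSolution:
    """Provably minimum-cardinality cover; a validation oracle for the greedy.

    ``backend='exhaustive'`` searches candidate subsets in order of
    increasing cardinality over bitset representations, bounded above by the
    greedy solution.  ``backend='ilp'`` solves the standard covering integer
    program with HiGHS (one binary variable per candidate, one >=1 row per
    member); both backends return a minimum cover.  Instances with more than
    ``limit`` members are refused — the oracle is for validation, not
    production.
    """
    if not cmap.members:
        raise ValueError("cannot cover an empty group")
    if len(cmap.members) > limit:
        raise ValueError(
            f"exact cover limited to {limit} distinct UMIs, got {len(cmap.members)}"
        )
    if backend == "ilp":
        return _exact_ilp(cmap)
    if backend != "exhaustive":
        raise ValueError(f"unknown exact_cover backend: {backend!r}")
    masks, full = _bitmask_sets(cmap)
    # candidates with identical coverage are interchangeable: keep the
    # lexicographically smallest representative of each coverage set
    rep: dict[int, str] = {}
    for c in sorted(masks):
        m = masks[c]
        if m not in rep:
            rep[m] = c
    cand = sorted(rep.items(), key=lambda kv: kv[1])
    upper = greedy_cover(cmap)
    for k in range(1, len(upper.chosen) + 1):
        for combo in itertools.combinations(cand, k):
            m = 0
            for mask, _ in combo:
                m |= mask
            if m == full:
                chosen = tuple(sorted(c for _, c in combo))
                return CoverSolution(
                    chosen=chosen,
                    assignment=_assign(cmap, chosen),
                    optimal=True,
                )
    # the greedy solution itself is feasible, so we always return above
    raise RuntimeError("exhaustive search failed to find a feasible cover")


def _assign(cmap: CandidateMap, chosen: Sequence[str]) -> dict[str, str]:
    assignment = {}
    for s in cmap.members:
        for c in chosen:
            if s in cmap.sets[c]:
                assignment[s] = c
                break
    return assignment


def _exact_ilp(cmap: CandidateMap) -> CoverSolution:
    from scipy.optimize import LinearConstraint, milp
    from scipy.sparse import lil_matrix

    cands = sorted(cmap.sets)
    index = {s: i for i, s in enumerate(cmap.members)}
    A = lil_matrix((len(cmap.members), len(cands)))
    for j, c in enumerate(cands):
        for s in cmap.sets[c]:
            A[index[s], j] = 1
    res = milp(
        c=np.ones(len(cands)),
        constraints=LinearConstraint(A.tocsr(), lb=1, ub=np.inf),
        integrality=np.ones(len(cands)),
        bounds=(0, 1),
    )
    if not res.success:  # pragma: no cover - covering LPs are always feasible
        raise RuntimeError(f"ILP solver failed: {res.message}")
    chosen = tuple(sorted(c for c, x in zip(cands, res.x) if x > 0.5))
    return CoverSolution(chosen=chosen, assignment=_assign(cmap, chosen), optimal=True)


@dataclass
class DedupResult:
    """Outcome of deduplicating one UMI group."""

    molecule_count: int
    method: str  # "majority" | "setcover" | "empty"
    collapsed: tuple[str, ...] = ()
    solution: CoverSolution | None = None
    n_reads: int = 0
    n_filtered: int = 0
    n_dropped: int = 0


def dedup_group(
    members: Sequence[str],
    max_errors: int = 3,
    cap: int = 4096,
    exact: bool = False,
    exact_limit: int = 20,
) -> DedupResult:
    """Count molecules in one gene's (or cell-gene's) homotrimer UMI group.

    Pipeline: drop reads with more than ``max_errors`` block errors; if every
    surviving read collapses conclusively, count distinct majority-collapsed
    monomers; otherwise solve the set cover over the distinct raw strings
    (greedy, or the exact oracle when ``exact=True``).
    """
    kept, filtered = filter_umis(list(members), max_errors)
    if not kept:
        logger.warning("group empty after error filtering (%d reads)", len(members))
        return DedupResult(0, "empty", n_reads=len(members), n_filtered=len(filtered))
    collapsed = [majority_collapse(u) for u in kept]
    if all(c is not None for c in collapsed):
        distinct = tuple(sorted(set(collapsed)))  # type: ignore[arg-type]
        return DedupResult(
            molecule_count=len(distinct),
            method="majority",
            collapsed=distinct,
            n_reads=len(members),
            n_filtered=len(filtered),
        )
    cmap = build_candidate_map(kept, cap=cap)
    if not cmap.members:
        return DedupResult(
            0,
            "empty",
            n_reads=len(members),
            n_filtered=len(filtered),
            n_dropped=len(cmap.dropped),
        )
    sol = (
        exact_cover(cmap, limit=exact_limit)
        if exact
        else greedy_cover(cmap)
    )
    return DedupResult(
        molecule_count=sol.molecule_count,
        method="setcover",
        collapsed=sol.chosen,
        solution=sol,
        n_reads=len(members),
        n_filtered=len(filtered),
        n_dropped=len(cmap.dropped),
    )


def dedup_table(
    tagged_reads: Iterable[tuple[str, str | tuple[str, str], str]],
    max_errors: int = 3,
    cap: int = 4096,
) -> tuple["pd.DataFrame", dict[str, int]]:
    """Deduplicate a stream of ``(read_id, group_key, homotrimer_umi)`` records.

    ``group_key`` is a gene id, or a ``(cell_barcode, gene)`` pair in
    single-cell mode.  Returns a tidy count table (one row per group) and a
    skip log keyed by reason.  Reads with a missing key or empty UMI are
    skipped, never fatal.
    """
    import pandas as pd

    groups: dict[str | tuple[str, str], list[str]] = defaultdict(list)
    skipped: dict[str, int] = defaultdict(int)
    for read_id, key, umi in tagged_reads:
        if key is None or key == "" or (isinstance(key, tuple) and not all(key)):
            skipped["missing_group_key"] += 1
            continue
        if not umi or len(umi) % 3:
            skipped["bad_umi_length"] += 1
            continue
        groups[key].append(umi)
    rows = []
    for key in sorted(groups):
        res = dedup_group(groups[key], max_errors=max_errors, cap=cap)
        if isinstance(key, tuple):
            rows.append(
                {"cell": key[0], "gene": key[1], "count": res.molecule_count,
                 "method": res.method, "n_reads": res.n_reads}
            )
        else:
            rows.append(
                {"gene": key, "count": res.molecule_count,
                 "method": res.method, "n_reads": res.n_reads}
            )
    cols = (
        ["cell", "gene", "count", "method", "n_reads"]
        if rows and "cell" in rows[0]
        else ["gene", "count", "method", "n_reads"]
    )
    table = pd.DataFrame(rows, columns=cols)
    return table, dict(skipped)
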