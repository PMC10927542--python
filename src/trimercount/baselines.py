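"""Monomer-UMI comparison methods: first/random-base collapse and directional dedup.

These reproduce, minimally, the monomer-based counting strategies the
homotrimer approach is benchmarked against, so benchmarks run without any
external deduplication tool.  A homotrimer read enters the monomer world by
collapsing each trimer block to a single base — either its first base (the
deterministic convention) or a uniformly random one — after which reads are
deduplicated on monomer UMI strings alone.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .codec import hamming, iter_blocks

__all__ = [
    "collapse_first_base",
    "collapse_random_base",
    "directional_networks",
    "directional_dedup",
    "naive_unique",
]


def collapse_first_base(umi: str) -> str:
    """Collapse a homotrimer UMI by taking the first base of each block."""
    return "".join(b[0] for b in iter_blocks(umi.upper()))


def collapse_random_base(
    umi: str, rng: np.random.Generator | int | None = None
) -> str:
    """Collapse by sampling one of the three positions uniformly per block.

    Unanimous blocks are unaffected by the draw; disagreeing blocks propagate
    each observed base with probability proportional to its multiplicity.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    blocks = iter_blocks(umi.upper())
    picks = rng.integers(0, 3, size=len(blocks))
    return "".join(b[p] for b, p in zip(blocks, picks))


def directional_networks(counts: Mapping[str, int]) -> list[str]:
    """Directional network collapse of a monomer UMI count map.

    A directed edge u -> v exists when Hamming(u, v) == 1 and
    count(u) >= 2 * count(v) - 1: v is then treated as an error copy of the
    more abundant u.  Nodes are visited in order of descending count (ties
    lexicographic); each unvisited node seeds a new network and absorbs
    everything reachable through directional edges.  Returns the network
    roots, i.e. the retained molecule representatives.
    """
    if not counts:
        raise ValueError("empty UMI count map")
    order = sorted(counts, key=lambda u: (-counts[u], u))
    visited: set[str] = set()
    roots: list[str] = []
    for root in order:
        if root in visited:
            continue
        roots.append(root)
        stack = [root]
        visited.add(root)
        while stack:
            u = stack.pop()
            for v in order:
                if v in visited:
                    continue
                if hamming(u, v) == 1 and counts[u] >= 2 * counts[v] - 1:
                    visited.add(v)
                    stack.append(v)
    return roots


def directional_dedup(counts: Mapping[str, int]) -> int:
    """Molecule count under the directional method: number of UMI networks."""
    return len(directional_networks(counts))


def naive_unique(counts: Mapping[str, int]) -> int:
    """Lower-bound baseline: the number of distinct monomer UMIs."""
    return len(counts)
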