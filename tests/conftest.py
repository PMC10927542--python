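"""Shared fixtures: random homotrimer groups and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

DNA = "ACGT"


def random_monomer(rng: np.random.Generator, length: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, size=length))


def encode(monomer: str) -> str:
    return "".join(b * 3 for b in monomer)


def substitute(seq: str, pos: int, rng: np.random.Generator) -> str:
    """Replace the base at pos with a different one, uniformly."""
    old = seq[pos]
    new = DNA[(DNA.index(old) + 1 + int(rng.integers(3))) % 4]
    return seq[:pos] + new + seq[pos + 1 :]


def make_random_group(
    rng: np.random.Generator,
    n_true: int,
    n_reads: int,
    n_blocks: int,
    max_subs: int = 3,
) -> tuple[list[str], list[str]]:
    """A UMI group: reads drawn from n_true molecules, each with <= max_subs
    substitutions at distinct positions (which bounds the block-error load by
    max_subs)."""
    truths = [random_monomer(rng, n_blocks) for _ in range(n_true)]
    reads = []
    for _ in range(n_reads):
        base = encode(truths[int(rng.integers(n_true))])
        n_subs = int(rng.integers(0, max_subs + 1))
        for pos in rng.choice(len(base), size=n_subs, replace=False):
            base = substitute(base, int(pos), rng)
        reads.append(base)
    return truths, reads


# --- independent set-cover oracle (no imports from the package) -------------

def oracle_candidates(umi: str) -> set[str]:
    """C(s) recomputed from the definition: per-block observed bases, product."""
    blocks = [umi[i : i + 3] for i in range(0, len(umi), 3)]
    per_block = [sorted(set(b) & set(DNA)) for b in blocks]
    return {"".join(p) for p in itertools.product(*per_block)}


def oracle_min_cover(members: list[str]) -> int:
    """Minimum number of collapsed UMIs covering all members, by brute force
    over every subset of the candidate union, smallest cardinality first."""
    members = list(dict.fromkeys(members))
    cand = sorted(set().union(*(oracle_candidates(s) for s in members)))
    covers = {c: {s for s in members if c in oracle_candidates(s)} for c in cand}
    for k in range(1, len(members) + 1):
        for combo in itertools.combinations(cand, k):
            covered = set().union(*(covers[c] for c in combo))
            if len(covered) == len(members):
                return k
    raise AssertionError("no cover found")  # pragma: no cover


def oracle_block_errors(umi: str) -> int:
    """Per-block minimum substitutions to unanimity, recomputed directly."""
    total = 0
    for i in range(0, len(umi), 3):
        block = umi[i : i + 3]
        total += min(sum(ch != t for ch in block) for t in DNA)
    return total


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
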