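"""Homotrimer UMI encoding, error detection and majority-vote correction.

A homotrimer UMI encodes each monomer base ``b`` of a B-base UMI as the
triplet block ``bbb``, giving a raw sequence of length 3B.  Because every
block is synthesized unanimous, within-block disagreement after PCR and
sequencing directly reveals substitution errors, and the modal base of each
block corrects them:

* one substitution leaves a 2-of-3 majority — the vote restores the base;
* two identical substitutions in one block flip the vote (uncorrectable);
* three distinct bases leave the block *inconclusive* — no majority exists
  and the caller decides whether to pick a base at random (simulation-style
  collapsing) or to defer to set-cover deduplication (counting-style).

The per-block error count is ``3 - multiplicity(modal base)``: the minimum
number of substitutions needed to make the block unanimous again (0 for a
clean block, 1 for a 2-of-3 block, 2 for an all-distinct block).  Summed over
blocks it is the UMI error load used by the read filters.

All sequences are uppercase strings over ACGT; ``N`` (or any other IUPAC
ambiguity code) is tolerated on input but never wins a vote.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np

DNA = "ACGT"
DNA_SET = frozenset(DNA)

__all__ = [
    "DNA",
    "encode_homotrimer",
    "iter_blocks",
    "block_vote",
    "majority_collapse",
    "count_umi_errors",
    "filter_umis",
    "hamming",
    "resegment",
]


def encode_homotrimer(monomer: str) -> str:
    """Expand a monomer UMI into its homotrimer form (``"GACT"`` -> ``"GGGAAACCCTTT"``).

    This is the synthesis direction: the inverse of :func:`majority_collapse`
    on error-free reads.  Raises ``ValueError`` on an empty or non-ACGT input.
    """
    monomer = monomer.upper()
    if not monomer:
        raise ValueError("monomer UMI must be non-empty")
    bad = set(monomer) - DNA_SET
    if bad:
        raise ValueError(f"non-ACGT characters in monomer UMI: {sorted(bad)}")
    return "".join(b * 3 for b in monomer)


def iter_blocks(umi: str) -> list[str]:
    """Split a raw homotrimer sequence into its trimer blocks.

    Raises ``ValueError`` if the length is zero or not a multiple of 3.
    """
    if not umi or len(umi) % 3:
        raise ValueError(
            f"homotrimer UMI length must be a positive multiple of 3, got {len(umi)}"
        )
    return [umi[i : i + 3] for i in range(0, len(umi), 3)]


def block_vote(block: str) -> tuple[str | None, int]:
    """Majority vote on one trimer block.

    Returns ``(modal_base, errors)`` where ``errors = 3 - multiplicity`` of
    the modal base.  If no ACGT base reaches multiplicity 2 the block is
    inconclusive and ``(None, 2)`` is returned.  Ambiguity codes such as N
    count toward nothing: they can lose a vote but never win one.
    """
    if len(block) != 3:
        raise ValueError(f"trimer block must have length 3, got {block!r}")
    block = block.upper()
    counts = Counter(b for b in block if b in DNA_SET)
    if counts:
        base, mult = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        if mult >= 2:
            return base, 3 - mult
    return None, 2


def majority_collapse(
    umi: str,
    random_fallback: bool = False,
    rng: np.random.Generator | int | None = None,
) -> str | None:
    """Collapse a homotrimer UMI to its monomer form by per-block majority vote.

    Inconclusive blocks (three distinct bases) are resolved according to
    ``random_fallback``:

    * ``False`` (counting mode) — return ``None`` so the caller can route the
      read to set-cover deduplication instead of forcing a base;
    * ``True`` (simulation mode) — pick uniformly among the bases occurring
      in the block, using ``rng`` (a seed or ``numpy`` Generator).
    """
    blocks = iter_blocks(umi)
    if random_fallback and not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out: list[str] = []
    for block in blocks:
        base, _ = block_vote(block)
        if base is None:
            if not random_fallback:
                return None
            choices = sorted(set(b for b in block.upper() if b in DNA_SET)) or list(DNA)
            base = choices[int(rng.integers(len(choices)))]
        out.append(base)
    return "".join(out)


def count_umi_errors(umi: str) -> int:
    """Total substitution load of a homotrimer UMI: sum of per-block errors."""
    return sum(block_vote(b)[1] for b in iter_blocks(umi))


def filter_umis(
    umis: Sequence[str], max_errors: int
) -> tuple[list[str], list[str]]:
    """Partition UMIs into (kept, dropped) by error load, preserving order.

    ``kept`` holds UMIs with ``count_umi_errors <= max_errors``.  The two
    lists together are exactly the input.  The set-cover path uses
    ``max_errors=3``; the more permissive bulk long-read path uses 5.
    """
    if max_errors < 0:
        raise ValueError("max_errors must be >= 0")
    kept: list[str] = []
    dropped: list[str] = []
    for u in umis:
        (kept if count_umi_errors(u) <= max_errors else dropped).append(u)
    return kept, dropped


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _chunk_cost(chunk: str) -> int:
    """Substitutions needed to make a chunk a homopolymer (N never modal)."""
    counts = Counter(b for b in chunk if b in DNA_SET)
    best = max(counts.values()) if counts else 0
    return len(chunk) - best


def _normalize_chunk(chunk: str) -> str:
    """Squeeze or pad a re-segmented chunk to a 3-base block.

    Long chunks drop minority bases first (the vote outcome is preserved);
    short chunks are padded with N so a missing base cannot manufacture a
    majority that was never observed.
    """
    chunk = chunk.upper()
    if len(chunk) == 3:
        return chunk
    if len(chunk) < 3:
        return chunk + "N" * (3 - len(chunk))
    counts = Counter(b for b in chunk if b in DNA_SET)
    if counts:
        modal, _ = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
    else:
        modal = None
    keep = [b for b in chunk if b == modal][:3]
    for b in chunk:
        if len(keep) == 3:
            break
        if b != modal:
            keep.append(b)
    return "".join(keep[:3])


def resegment(seq: str, n_blocks: int, max_indels: int = 2) -> str | None:
    """Re-chunk an indel-bearing read segment into ``n_blocks`` trimer blocks.

    Dynamic program over block boundaries: each block consumes between
    ``3 - max_indels`` and ``3 + max_indels`` bases (at least 1), the total
    deviation from 3 bases per block is capped at ``max_indels``, and the
    objective is the summed substitution cost of the chunks plus the indel
    deviation.  Returns the normalized 3*n_blocks homotrimer string, or
    ``None`` when no segmentation fits within the indel budget.
    """
    seq = seq.upper()
    L = len(seq)
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if abs(L - 3 * n_blocks) > max_indels:
        return None
    lo = max(1, 3 - max_indels)
    hi = 3 + max_indels
    # layer b maps (consumed, indels_used) -> (cost, parent state in layer b-1)
    Entry = tuple[float, tuple[int, int] | None]
    dp: dict[tuple[int, int], Entry] = {(0, 0): (0.0, None)}
    layers: list[dict[tuple[int, int], Entry]] = []
    for _ in range(n_blocks):
        nxt: dict[tuple[int, int], Entry] = {}
        for (i, d), (cost, _) in dp.items():
            for w in range(lo, hi + 1):
                j = i + w
                if j > L:
                    break
                d2 = d + abs(w - 3)
                if d2 > max_indels:
                    continue
                c2 = cost + _chunk_cost(seq[i:j]) + abs(w - 3)
                key = (j, d2)
                if key not in nxt or c2 < nxt[key][0]:
                    nxt[key] = (c2, (i, d))
        if not nxt:
            return None
        layers.append(nxt)
        dp = nxt
    finals = [k for k in layers[-1] if k[0] == L]
    if not finals:
        return None
    key = min(finals, key=lambda k: layers[-1][k][0])
    cuts = [key[0]]
    for layer in reversed(layers):
        key = layer[key][1]  # type: ignore[assignment]
        cuts.append(key[0])
    cuts.reverse()
    blocks = [_normalize_chunk(seq[cuts[k] : cuts[k + 1]]) for k in range(n_blocks)]
    return "".join(blocks)
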