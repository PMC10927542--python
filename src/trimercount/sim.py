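"""PCR amplification and sequencing-error simulator for UMI-tagged reads.

The amplification of a molecule pool across PCR cycles is a Galton–Watson
branching process: at cycle *i* with pool size ``m``, the number of reads
amplified is ``n ~ Binomial(m, α)`` for amplification rate ``α``, the ``n``
templates are drawn uniformly without replacement, and each contributes one
new copy, so ``m' = m + n`` exactly and ``E[m_final] = m0 · (1 + α)^cycles``.

Base errors ride a second branching process: if a cycle synthesizes ``t``
bases in total, the number of substitution errors is drawn as
``v ~ NBinom(r, q)`` with per-base success probability ``q = 1 − P_e`` and
``r = q·t`` (so ``E[v] = r(1−q)/q = t·P_e``), the ``v`` error positions are
chosen uniformly without replacement among the ``t`` newly synthesized
bases, and each hit base is replaced by one of the other three uniformly.
Only newly synthesized copies can acquire errors in a cycle; templates are
never retouched.  Sequencing reuses the same machinery over the sampled
reads with its own error rate.

Every simulated read carries its ground-truth molecule id from birth through
sampling and error injection, so downstream deduplication methods can be
scored against the exact number and identity of the original molecules.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .codec import DNA, encode_homotrimer, majority_collapse
from . import baselines
from .setcover import dedup_group

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "MoleculePool",
    "CycleStats",
    "Replicate",
    "SimResult",
    "generate_true_umis",
    "amplify_cycle",
    "inject_errors",
    "pcr_cycle",
    "sequence_pool",
    "run_simulation",
    "evaluate_methods",
]


@dataclass
class SimConfig:
    """Simulation settings.

    Defaults follow the simulated-UMI study conditions: 50 molecules with
    12-base (monomer) homotrimer UMIs, 12 PCR cycles at amplification rate
    0.85 (the middle of the 0.8–1.0 operating range), PCR error rate
    3.6e-6 per synthesized base, sequencing depth 400, sequencing error rate
    1e-3, and 50 replicates.
    """

    umi_num: int = 50
    umi_len: int = 12
    trimer: bool = True
    ampl_rate: float = 0.85
    pcr_err: float = 3.6e-6
    seq_err: float = 1e-3
    pcr_cycles: int = 12
    seq_depth: int = 400
    perm_num: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.umi_num < 1 or self.umi_len < 1:
            raise ValueError("umi_num and umi_len must be positive")
        if not (0.0 <= self.ampl_rate <= 1.0):
            raise ValueError("ampl_rate must be in [0, 1]")
        for name in ("pcr_err", "seq_err"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.pcr_cycles < 0 or self.seq_depth < 1 or self.perm_num < 1:
            raise ValueError("pcr_cycles must be >= 0; seq_depth, perm_num >= 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class MoleculePool:
    """The read population at some point of the PCR.

    ``seqs`` holds one sequence per read; it may be ``None`` for
    bookkeeping-only pools used in branching-moment studies, where only the
    ancestry arrays are tracked (amplification statistics are identical —
    the sequences play no role in the branching process itself).
    ``true_id[i]`` is the index of read i's founding molecule and
    ``birth[i]`` the PCR cycle at which read i was synthesized (0 for the
    founders).
    """

    seqs: list[str] | None
    true_id: np.ndarray
    birth: np.ndarray

    @classmethod
    def from_umis(cls, umis: Sequence[str] | None, n: int | None = None) -> "MoleculePool":
        if umis is None:
            if n is None:
                raise ValueError("need umis or a pool size")
            return cls(None, np.arange(n, dtype=np.int64), np.zeros(n, dtype=np.int64))
        n = len(umis)
        return cls(list(umis), np.arange(n, dtype=np.int64), np.zeros(n, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.true_id)


@dataclass
class CycleStats:
    """Per-cycle accounting of the two branching processes."""

    cycle: int
    m_before: int
    n_amplified: int
    t_bases: int
    v_errors: int
    u_cumulative: int
    r: float
    q: float

    @property
    def m_after(self) -> int:
        return self.m_before + self.n_amplified


def generate_true_umis(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Draw the founding molecules' UMIs.

    Returns ``(monomers, seqs)`` where ``seqs`` are the sequences actually
    carried by reads: the homotrimer expansion in trimer mode, the monomer
    itself otherwise.  Bases are uniform; uniqueness is not enforced, but
    collisions are logged since they silently lower the effective molecule
    count.
    """
    draws = rng.integers(0, 4, size=(config.umi_num, config.umi_len))
    monomers = ["".join(DNA[b] for b in row) for row in draws]
    n_dup = config.umi_num - len(set(monomers))
    if n_dup:
        logger.warning("%d collision(s) among %d simulated UMIs", n_dup, config.umi_num)
    seqs = [encode_homotrimer(m) for m in monomers] if config.trimer else list(monomers)
    return monomers, seqs


def amplify_cycle(
    pool: MoleculePool, ampl_rate: float, rng: np.random.Generator, cycle: int = -1
) -> tuple[MoleculePool, int]:
    """One PCR duplication step: ``n ~ Binomial(m, α)`` templates copied once.

    Templates are chosen uniformly without replacement; the pool grows by
    exactly ``n`` (conservation ``m' = m + n``).  Copies are appended with
    ``birth=cycle`` and are the only reads eligible for error injection this
    cycle.  Returns the grown pool (same object, mutated) and ``n``.
    """
    m = len(pool)
    if m == 0:
        raise ValueError("cannot amplify an empty pool")
    n = int(rng.binomial(m, ampl_rate))
    if n == 0:
        return pool, 0
    idx = rng.choice(m, size=n, replace=False)
    pool.true_id = np.concatenate([pool.true_id, pool.true_id[idx]])
    pool.birth = np.concatenate([pool.birth, np.full(n, cycle, dtype=np.int64)])
    if pool.seqs is not None:
        pool.seqs.extend(pool.seqs[i] for i in idx)
    return pool, n


def inject_errors(
    seqs: Sequence[str], p_err: float, rng: np.random.Generator
) -> tuple[list[str], int]:
    """Substitution errors over a batch of newly synthesized sequences.

    With ``t`` total bases, draws ``v ~ NBinom(r=q·t, q=1−p_err)`` (real-
    valued r, so ``E[v] = t·p_err``), caps v at t, picks v distinct base
    positions uniformly, and substitutes each hit base by one of the other
    three uniformly.  Returns the (new) list of sequences and v.
    """
    if not (0.0 <= p_err < 1.0):
        raise ValueError("p_err must be in [0, 1)")
    seqs = list(seqs)
    t = sum(len(s) for s in seqs)
    if t == 0 or p_err == 0.0:
        return seqs, 0
    q = 1.0 - p_err
    r = q * t
    v = int(rng.negative_binomial(r, q))
    v = min(v, t)
    if v == 0:
        return seqs, 0
    flat = rng.choice(t, size=v, replace=False)
    flat.sort()
    lens = np.array([len(s) for s in seqs])
    bounds = np.cumsum(lens)
    read_idx = np.searchsorted(bounds, flat, side="right")
    offsets = flat - (bounds[read_idx] - lens[read_idx])
    subs = rng.integers(0, 3, size=v)
    mutable: dict[int, list[str]] = {}
    for ri, off, s3 in zip(read_idx, offsets, subs):
        ri = int(ri)
        if ri not in mutable:
            mutable[ri] = list(seqs[ri])
        old = mutable[ri][off]
        alternatives = [b for b in DNA if b != old]
        # non-ACGT base: any of the four is "one of the remaining three"
        mutable[ri][off] = alternatives[int(s3) % len(alternatives)] if old in DNA else DNA[int(rng.integers(4))]
    for ri, chars in mutable.items():
        seqs[ri] = "".join(chars)
    return seqs, v


def pcr_cycle(
    pool: MoleculePool,
    ampl_rate: float,
    pcr_err: float,
    rng: np.random.Generator,
    cycle: int,
    u_before: int,
) -> CycleStats:
    """Amplify the pool one cycle and inject PCR errors into the new copies."""
    m_before = len(pool)
    pool, n = amplify_cycle(pool, ampl_rate, rng, cycle=cycle)
    t = v = 0
    if pool.seqs is not None and n:
        new = pool.seqs[m_before:]
        t = sum(len(s) for s in new)
        mutated, v = inject_errors(new, pcr_err, rng)
        pool.seqs[m_before:] = mutated
    q = 1.0 - pcr_err
    return CycleStats(
        cycle=cycle,
        m_before=m_before,
        n_amplified=n,
        t_bases=t,
        v_errors=v,
        u_cumulative=u_before + v,
        r=q * t,
        q=q,
    )


def sequence_pool(
    pool: MoleculePool,
    seq_depth: int,
    seq_err: float,
    rng: np.random.Generator,
) -> tuple[list[str], np.ndarray, int]:
    """Sample reads to depth and apply sequencing errors.

    Sampling is uniform without replacement when the pool is at least as
    large as the requested depth, with replacement otherwise.  Returns the
    sequenced reads, their ground-truth molecule ids, and the number of
    sequencing errors injected.
    """
    if pool.seqs is None:
        raise ValueError("sequencing requires a pool with sequences")
    m = len(pool)
    if m == 0:
        raise ValueError("cannot sequence an empty pool")
    replace = seq_depth > m
    if replace:
        logger.warning("depth %d exceeds pool size %d; sampling with replacement", seq_depth, m)
    idx = rng.choice(m, size=seq_depth, replace=replace)
    reads = [pool.seqs[i] for i in idx]
    reads, v = inject_errors(reads, seq_err, rng)
    return reads, pool.true_id[idx].copy(), v


@dataclass
class Replicate:
    """One simulated library with its ground truth."""

    index: int
    true_monomers: list[str]
    true_seqs: list[str]
    read_ids: list[str]
    reads: list[str]
    read_truth: np.ndarray
    cycle_stats: list[CycleStats]
    n_seq_errors: int


@dataclass
class SimResult:
    config: SimConfig
    replicates: list[Replicate]


def run_simulation(config: SimConfig) -> SimResult:
    """Run the full generate → PCR → sequence pipeline for every replicate.

    Randomness is fully determined by ``config.seed``: each replicate gets an
    independent child stream, so results are byte-stable across runs.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.perm_num)
    replicates = []
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        monomers, seqs = generate_true_umis(config, rng)
        pool = MoleculePool.from_umis(seqs)
        stats: list[CycleStats] = []
        u = 0
        for cycle in range(1, config.pcr_cycles + 1):
            cs = pcr_cycle(pool, config.ampl_rate, config.pcr_err, rng, cycle, u)
            u = cs.u_cumulative
            stats.append(cs)
        reads, truth, v_seq = sequence_pool(pool, config.seq_depth, config.seq_err, rng)
        ids = [f"rep{rep}.read{k}_{reads[k]}" for k in range(len(reads))]
        replicates.append(
            Replicate(
                index=rep,
                true_monomers=monomers,
                true_seqs=seqs,
                read_ids=ids,
                reads=reads,
                read_truth=truth,
                cycle_stats=stats,
                n_seq_errors=v_seq,
            )
        )
    return SimResult(config=config, replicates=replicates)


METHODS = ("naive", "directional", "majority", "setcover")


def _estimate(method: str, reads: Sequence[str], trimer: bool, rng: np.random.Generator):
    """Molecule count and recovered UMI set for one method on one replicate."""
    if method in ("naive", "directional"):
        monomers = [baselines.collapse_first_base(r) for r in reads] if trimer else list(reads)
        counts = Counter(monomers)
        if method == "naive":
            return baselines.naive_unique(counts), set(counts)
        roots = baselines.directional_networks(counts)
        return len(roots), set(roots)
    if not trimer:
        raise ValueError(f"method {method!r} requires homotrimer reads")
    if method == "majority":
        collapsed = {majority_collapse(r, random_fallback=True, rng=rng) for r in reads}
        return len(collapsed), collapsed
    if method == "setcover":
        res = dedup_group(reads)
        return res.molecule_count, set(res.collapsed)
    raise ValueError(f"unknown method {method!r}")


def evaluate_methods(
    result: SimResult, methods: Sequence[str] = METHODS
) -> "pd.DataFrame":
    """Score deduplication methods against the simulator's ground truth.

    One row per replicate per method: the estimated molecule count, its
    absolute deviation from the true molecule number, and the fraction of
    true UMIs exactly recovered by the method's retained monomer set.
    """
    import pandas as pd

    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    rows = []
    truth_n = result.config.umi_num
    rng = np.random.default_rng(np.random.SeedSequence(result.config.seed).spawn(1)[0])
    for rep in result.replicates:
        true_set = set(rep.true_monomers)
        for method in methods:
            count, recovered = _estimate(method, rep.reads, result.config.trimer, rng)
            rows.append(
                {
                    "replicate": rep.index,
                    "method": method,
                    "count": count,
                    "true_count": truth_n,
                    "abs_deviation": abs(count - truth_n),
                    "frac_recovered": len(true_set & recovered) / truth_n,
                }
            )
    return pd.DataFrame(rows)
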