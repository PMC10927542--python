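"""File-format plumbing: FASTQ, TSV tables, Matrix Market count matrices.

Readers are gzip-aware (pysam's FASTX parser); writers emit plain text, or
gzip when the target filename ends in ``.gz``.  Count matrices follow the
cells x genes Matrix Market convention with ``barcodes.tsv`` and
``features.tsv`` sidecars, the layout single-cell toolkits ingest directly.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "read_fastq",
    "write_fastq",
    "write_truth",
    "read_truth",
    "write_cycle_stats",
    "write_counts_tsv",
    "write_counts_mtx",
    "write_json",
]


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str | None]]:
    """Yield ``(name, sequence, quality)`` from a FASTQ(.gz) file."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence, entry.quality


def _open_text(path: Path, mode: str = "wt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode.rstrip("t") if "b" in mode else mode)


def write_fastq(
    path: str | Path,
    reads: Iterable[tuple[str, str] | tuple[str, str, str]],
    default_quality: str = "I",
) -> int:
    """Write ``(name, seq[, qual])`` records as FASTQ; returns record count."""
    path = Path(path)
    n = 0
    with _open_text(path) as fh:
        for rec in reads:
            name, seq = rec[0], rec[1]
            qual = rec[2] if len(rec) > 2 and rec[2] else default_quality * len(seq)
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def write_truth(path: str | Path, pairs: Iterable[tuple[str, int | str]]) -> None:
    """Ground-truth map read_id -> true molecule id, as two-column TSV."""
    with _open_text(Path(path)) as fh:
        fh.write("read_id\ttrue_umi_id\n")
        for read_id, true_id in pairs:
            fh.write(f"{read_id}\t{true_id}\n")


def read_truth(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["read_id"], df["true_umi_id"]))


def write_cycle_stats(path: str | Path, result) -> None:
    """Per-replicate per-cycle branching statistics as TSV."""
    rows = []
    for rep in result.replicates:
        for cs in rep.cycle_stats:
            rows.append(
                {
                    "replicate": rep.index,
                    "cycle": cs.cycle,
                    "m_before": cs.m_before,
                    "n_amplified": cs.n_amplified,
                    "m_after": cs.m_after,
                    "t_bases": cs.t_bases,
                    "v_errors": cs.v_errors,
                    "u_cumulative": cs.u_cumulative,
                    "r": cs.r,
                    "q": cs.q,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_counts_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_counts_mtx(outdir: str | Path, table: pd.DataFrame) -> None:
    """Cells x genes sparse matrix (matrix.mtx + barcodes.tsv + features.tsv).

    ``table`` must have columns cell, gene, count (the single-cell output of
    the deduplicator).
    """
    from scipy import io as sio
    from scipy.sparse import coo_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells = sorted(table["cell"].unique())
    genes = sorted(table["gene"].unique())
    ci = {c: i for i, c in enumerate(cells)}
    gi = {g: i for i, g in enumerate(genes)}
    mat = coo_matrix(
        (
            table["count"].to_numpy(),
            (
                table["cell"].map(ci).to_numpy(),
                table["gene"].map(gi).to_numpy(),
            ),
        ),
        shape=(len(cells), len(genes)),
    )
    sio.mmwrite(str(outdir / "matrix.mtx"), mat)
    (outdir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in cells))
    (outdir / "features.tsv").write_text("".join(f"{g}\n" for g in genes))


def write_json(path: str | Path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
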