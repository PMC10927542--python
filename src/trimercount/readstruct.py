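"""Locating UMIs, CMIs and cell barcodes inside raw long reads.

Long-read cDNA libraries place the UMI/CMI next to a fixed primer (anchor)
sequence, but reads arrive in either orientation and anchors are observed
with errors.  The workflow implemented here is:

1. orient the read — a poly-T run means the read is reverse-complemented;
2. locate the anchor by mismatch-tolerant sliding-window search;
3. cut the configured number of bases next to the anchor as the UMI (and,
   for droplet protocols, the cell barcode), applying structural length
   filters;
4. append barcode/UMI to the read name with ``_`` delimiters (the read-name
   convention downstream counting expects);
5. for single-cell data, build a frequency-ranked barcode whitelist and
   assign each read to its unique within-2-mismatches entry.

Gene assignment is read from the ``XT`` tag of an aligned SAM/BAM, or from a
plain three-column TSV when no aligner is in the loop.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .codec import hamming

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractionConfig",
    "ReadRecord",
    "revcomp",
    "orient_read",
    "find_anchor",
    "extract_umi",
    "whitelist_barcodes",
    "tag_reads_with_genes",
]

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (ACGTN alphabet)."""
    return seq.upper().translate(_RC)[::-1]


@dataclass
class ExtractionConfig:
    """Where to find the UMI (and barcode) within an oriented read.

    ``anchor`` is the primer sequence flanking the UMI; ``umi_side`` says on
    which side of the anchor the UMI sits.  ``min_segment_length`` rejects
    reads whose extracted barcode+UMI segment is shorter than the structural
    minimum (48 bases for the droplet protocol: 3x16 barcode + ... trimer
    blocks must all be present for majority voting to be meaningful).
    """

    anchor: str = "GTACTCTGCGTTGATACCACTGCTT"
    max_anchor_mismatch: int = 2
    umi_length: int = 30
    umi_side: str = "upstream"  # "upstream" | "downstream" of the anchor
    barcode_length: int = 0
    polyA_run: int = 9
    min_segment_length: int = 0
    require_orientation: bool = True  # False: reads are already forward

    def __post_init__(self) -> None:
        self.anchor = self.anchor.upper()
        if set(self.anchor) - set("ACGT"):
            raise ValueError("anchor must be an ACGT string")
        if self.max_anchor_mismatch < 0:
            raise ValueError("max_anchor_mismatch must be >= 0")
        if self.umi_side not in ("upstream", "downstream"):
            raise ValueError("umi_side must be 'upstream' or 'downstream'")


@dataclass
class ReadRecord:
    """A read after (attempted) UMI/barcode extraction."""

    id: str
    sequence: str
    quality: str | None = None
    flipped: bool | None = None
    barcode: str | None = None
    umi: str | None = None
    gene: str | None = None
    reject_reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.reject_reason is None

    @property
    def tagged_id(self) -> str:
        """Read id with barcode and UMI appended, underscore-delimited."""
        parts = [self.id]
        if self.barcode:
            parts.append(self.barcode)
        if self.umi:
            parts.append(self.umi)
        return "_".join(parts)


def orient_read(seq: str, polyA_run: int = 9) -> tuple[str, bool | None]:
    """Put a read in poly-A orientation.

    A poly-T run of at least ``polyA_run`` bases marks a reverse-complemented
    read: it is flipped and ``True`` returned.  Otherwise a poly-A run means
    the read already faces forward (``False``).  If neither marker occurs the
    read is unorientable and ``None`` is returned with the sequence
    untouched; callers skip such reads.
    """
    seq = seq.upper()
    if "T" * polyA_run in seq:
        return revcomp(seq), True
    if "A" * polyA_run in seq:
        return seq, False
    return seq, None


def find_anchor(seq: str, anchor: str, max_mismatch: int = 2) -> int | None:
    """Leftmost position where ``anchor`` matches within ``max_mismatch``.

    Plain sliding-window Hamming comparison with early abandon; returns
    ``None`` when no window qualifies.  Leftmost-first makes ties
    deterministic.
    """
    seq, anchor = seq.upper(), anchor.upper()
    k = len(anchor)
    if k == 0 or k > len(seq):
        return None
    for start in range(len(seq) - k + 1):
        mm = 0
        for a, b in zip(anchor, seq[start : start + k]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return start
    return None


def extract_umi(
    read_id: str,
    seq: str,
    config: ExtractionConfig,
    quality: str | None = None,
) -> ReadRecord:
    """Extract the UMI (and optional upstream barcode) adjacent to the anchor.

    The read is oriented first.  The UMI is the ``umi_length`` bases on the
    configured side of the anchor; with ``barcode_length > 0`` the barcode is
    taken immediately beyond the UMI (barcode, then UMI, then anchor).  A
    read is rejected — with a machine-readable reason — when it cannot be
    oriented, the anchor is absent, fewer bases than requested are
    available, or the barcode+UMI segment is shorter than
    ``min_segment_length``.
    """
    if config.require_orientation:
        oriented, flipped = orient_read(seq, config.polyA_run)
        if flipped is None:
            return ReadRecord(read_id, seq, quality, reject_reason="unoriented")
    else:
        oriented, flipped = seq.upper(), False
    pos = find_anchor(oriented, config.anchor, config.max_anchor_mismatch)
    if pos is None:
        return ReadRecord(read_id, oriented, quality, flipped, reject_reason="anchor_not_found")
    seg_len = config.umi_length + config.barcode_length
    if config.umi_side == "upstream":
        end = pos
        start = end - seg_len
    else:
        start = pos + len(config.anchor)
        end = start + seg_len
    if start < 0 or end > len(oriented):
        return ReadRecord(read_id, oriented, quality, flipped, reject_reason="segment_truncated")
    segment = oriented[start:end]
    if len(segment) < config.min_segment_length:
        return ReadRecord(read_id, oriented, quality, flipped, reject_reason="segment_too_short")
    if config.barcode_length:
        barcode, umi = segment[: config.barcode_length], segment[config.barcode_length :]
    else:
        barcode, umi = None, segment
    return ReadRecord(read_id, oriented, quality, flipped, barcode=barcode, umi=umi)


def whitelist_barcodes(
    barcodes: Iterable[str],
    expected_cells: int,
    max_mismatch: int = 2,
) -> tuple[list[str], dict[str, str | None]]:
    """Frequency-ranked barcode whitelist and per-barcode assignment.

    The whitelist is the ``expected_cells`` most frequent barcodes; barcodes
    tied with the last included count are all kept (logged).  Every observed
    barcode is then assigned to the whitelist entry within ``max_mismatch``
    at minimal distance; ties between two equally near entries leave the
    barcode unassigned (``None``).
    """
    if expected_cells < 1:
        raise ValueError("expected_cells must be >= 1")
    counts = Counter(b.upper() for b in barcodes)
    if not counts:
        return [], {}
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > expected_cells:
        cutoff = ranked[expected_cells - 1][1]
        wl = [b for b, c in ranked if c >= cutoff]
        if len(wl) > expected_cells:
            logger.info(
                "barcode frequency tie at cutoff %d: keeping %d barcodes for %d expected cells",
                cutoff, len(wl), expected_cells,
            )
    else:
        wl = [b for b, _ in ranked]
    wl_set = set(wl)
    assignment: dict[str, str | None] = {}
    for b in counts:
        if b in wl_set:
            assignment[b] = b
            continue
        best_d: int | None = None
        best: str | None = None
        ambiguous = False
        for w in wl:
            if len(w) != len(b):
                continue
            d = hamming(b, w)
            if d > max_mismatch:
                continue
            if best_d is None or d < best_d:
                best_d, best, ambiguous = d, w, False
            elif d == best_d:
                ambiguous = True
        assignment[b] = None if (best is None or ambiguous) else best
    return wl, assignment


def _umi_from_name(name: str) -> str | None:
    if "_" not in name:
        return None
    return name.rsplit("_", 1)[1] or None


def tag_reads_with_genes(
    source: str | Path,
    gene_tag: str = "XT",
) -> Iterator[tuple[str, str, str]]:
    """Yield ``(read_id, gene, umi)`` from a gene-tagged SAM/BAM or a TSV.

    SAM/BAM records must carry the gene in ``gene_tag`` and the UMI as the
    final ``_``-delimited token of the read name.  A ``.tsv`` file is the
    alignment-free fallback with columns read_id, gene, umi.  Unmapped,
    untagged or malformed records are skipped and counted in the log.
    """
    source = Path(source)
    skipped: Counter[str] = Counter()
    if source.suffix.lower() in (".tsv", ".txt"):
        with open(source) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3 or not all(parts[:3]):
                    skipped["malformed_row"] += 1
                    continue
                yield parts[0], parts[1], parts[2]
    else:
        import pysam

        with pysam.AlignmentFile(str(source), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    skipped["unmapped_or_secondary"] += 1
                    continue
                if not rec.has_tag(gene_tag):
                    skipped["no_gene_tag"] += 1
                    continue
                umi = _umi_from_name(rec.query_name or "")
                if umi is None:
                    skipped["no_umi_in_name"] += 1
                    continue
                name = rec.query_name.rsplit("_", 1)[0]
                yield name, str(rec.get_tag(gene_tag)), umi
    if skipped:
        logger.info("tag_reads_with_genes skipped: %s", dict(skipped))
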