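"""iCLIP-specific preprocessing.

iCLIP libraries carry a random barcode at the read 5' end that
distinguishes PCR duplicates from independent cDNAs, and the protocol
truncates reverse transcription at the crosslink nucleotide, so binding
evidence lives one base upstream of each mapped cDNA rather than in
mutations. Two helpers implement this: pre-mapping FASTQ deduplication and
barcode trimming, and post-mapping expansion of the crosslink nucleotide
into per-base cDNA count tracks.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio import SeqIO

from .ingest import AlignedTag

logger = logging.getLogger(__name__)


@dataclass
class BarcodeScheme:
    """5' barcode layout: random-barcode nucleotides followed by an
    optional fixed experimental (sample) barcode, both trimmed."""

    barcode_length: int
    experimental_barcode_length: int = 0

    def __post_init__(self) -> None:
        if self.barcode_length <= 0:
            raise ValueError("barcode_length must be > 0")
        if self.experimental_barcode_length < 0:
            raise ValueError("experimental_barcode_length must be >= 0")

    @property
    def total(self) -> int:
        return self.barcode_length + self.experimental_barcode_length


@dataclass
class CrosslinkConfig:
    """Crosslink-nucleotide expansion half-width; the count window spans
    ``2 * expansion_width + 1`` bases centred on the crosslink base."""

    expansion_width: int = 2

    def __post_init__(self) -> None:
        if self.expansion_width < 0:
            raise ValueError("expansion_width must be >= 0")


@dataclass
class BarcodeSummary:
    reads_in: int = 0
    duplicates_removed: int = 0
    too_short: int = 0

    @property
    def reads_out(self) -> int:
        return self.reads_in - self.duplicates_removed - self.too_short


def _open_text(path: str, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def remove_barcodes(
    fastq_in: str, fastq_out: str, scheme: BarcodeScheme
) -> BarcodeSummary:
    """Deduplicate an iCLIP FASTQ by random barcode and trim the barcodes.

    Reads identical over their full sequence (random barcode plus insert)
    are PCR duplicates; the first occurrence is kept. Reads whose sequence
    differs anywhere — including only in the random barcode — are
    independent cDNAs and are all retained. Barcodes (random plus
    experimental) are trimmed from the 5' end of surviving reads, with
    qualities trimmed in register.
    """
    summary = BarcodeSummary()
    seen: set[str] = set()
    with _open_text(fastq_in, "r") as ih, _open_text(fastq_out, "w") as oh:
        for rec in SeqIO.parse(ih, "fastq"):
            summary.reads_in += 1
            seq = str(rec.seq)
            if len(seq) <= scheme.total:
                logger.warning(
                    "read %s shorter than combined barcode length (%d <= %d); skipped",
                    rec.id, len(seq), scheme.total,
                )
                summary.too_short += 1
                continue
            if seq in seen:
                summary.duplicates_removed += 1
                continue
            seen.add(seq)
            SeqIO.write(rec[scheme.total:], oh, "fastq")
    logger.info(
        "barcode dedup: %d reads in, %d duplicates removed, %d too short, %d out",
        summary.reads_in, summary.duplicates_removed, summary.too_short,
        summary.reads_out,
    )
    return summary


def expand_crosslink_sites(
    tags: Iterable[AlignedTag], config: CrosslinkConfig
) -> dict[tuple[str, str, int], np.ndarray]:
    """Turn mapped iCLIP cDNAs into per-base crosslink count tracks.

    The crosslink nucleotide is the reference base immediately upstream of
    the cDNA 5' end: position ``start - 1`` for a ``+`` tag, position
    ``end`` (0-based half-open) for a ``-`` tag. Each cDNA adds 1 to every
    base in ``[crosslink - w, crosslink + w]``; windows reaching below
    position 0 are truncated there. Returns arrays keyed by
    ``(chrom, strand, condition)``.
    """
    w = config.expansion_width
    tracks: dict[tuple[str, str, int], np.ndarray] = {}
    truncated = 0
    for tag in tags:
        x = tag.start - 1 if tag.strand == "+" else tag.end
        lo, hi = x - w, x + w + 1
        if lo < 0:
            truncated += 1
            lo = 0
        if hi <= 0:
            continue
        key = (tag.chrom, tag.strand, tag.condition)
        arr = tracks.get(key)
        if arr is None or hi > arr.size:
            new = np.zeros(max(hi, 2 * (arr.size if arr is not None else 256)), dtype=np.int64)
            if arr is not None:
                new[: arr.size] = arr
            tracks[key] = arr = new
        arr[lo:hi] += 1
    if truncated:
        logger.info("%d crosslink windows truncated at contig position 0", truncated)
    return tracks


def crosslink_event_tracks(
    tags: Iterable[AlignedTag],
) -> dict[tuple[str, str, int], np.ndarray]:
    """Single-base crosslink event counts (expansion width 0), used for
    per-cluster cDNA counting."""
    return expand_crosslink_sites(tags, CrosslinkConfig(expansion_width=0))
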