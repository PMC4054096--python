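"""Strand-specific SAM ingestion for CLIP-seq tags.

Reads alignments with :mod:`pysam`, converts them to strand-aware tags in
0-based half-open coordinates, collapses PCR duplicates sharing identical
mapping coordinates and strand (HITS-CLIP / PAR-CLIP libraries; iCLIP
libraries are deduplicated pre-mapping by random barcode, see
:mod:`clipdiff.iclip`), and extracts the protocol's characteristic
mutations from each record: deletions from the CIGAR string, or T->C /
G->A substitutions from the MD tag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam

logger = logging.getLogger(__name__)

MUTATION_TYPES = ("deletion", "T2C", "G2A", "none")

# substitution profile per tag strand: (ref_base, alt_base) as stored on the
# forward reference. A T->C conversion on a minus-strand transcript reads as
# A->G in reference orientation.
_SUBSTITUTION_PROFILE = {
    "T2C": {"+": ("T", "C"), "-": ("A", "G")},
    "G2A": {"+": ("G", "A"), "-": ("C", "T")},
}


@dataclass(frozen=True)
class Mutation:
    """One characteristic mutation observed on a tag.

    ``kind`` is ``"deletion"`` or ``"substitution"``. Positions are 0-based
    reference coordinates. Deletions carry no ``alt_base``; their
    ``ref_base`` may be ``"N"`` when the record has no MD tag.
    """

    kind: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: Optional[str]
    strand: str

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if not self.ref_base or not self.alt_base:
                raise ValueError("substitution requires ref and alt bases")
            if self.ref_base == self.alt_base:
                raise ValueError("substitution ref and alt must differ")
        elif self.kind == "deletion":
            if self.alt_base is not None:
                raise ValueError("deletion carries no alt base")
        else:
            raise ValueError(f"unknown mutation kind {self.kind!r}")


@dataclass
class AlignedTag:
    """A collapsed, strand-specific aligned tag.

    ``start``/``end`` are 0-based half-open; ``condition`` is 1 or 2.
    """

    chrom: str
    start: int
    end: int
    strand: str
    condition: int
    mutations: list[Mutation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty tag span [{self.start},{self.end})")
        if self.condition not in (1, 2):
            raise ValueError("condition must be 1 or 2")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class IngestConfig:
    """How to read one pair of SAM files.

    ``mutation_type`` selects which characteristic mutations are profiled
    (``deletion`` for HITS-CLIP, ``T2C``/``G2A`` for PAR-CLIP, ``none`` to
    skip profiling); it is fixed for a run and applied identically to both
    conditions.
    """

    mutation_type: str = "none"
    paired_end: bool = False
    min_mapping_quality: int = 0

    def __post_init__(self) -> None:
        if self.mutation_type not in MUTATION_TYPES:
            raise ValueError(
                f"mutation_type must be one of {MUTATION_TYPES}, got {self.mutation_type!r}"
            )
        if self.min_mapping_quality < 0:
            raise ValueError("min_mapping_quality must be >= 0")


def _record_strand(rec: pysam.AlignedSegment) -> str:
    return "-" if rec.is_reverse else "+"


def extract_mutations(rec: pysam.AlignedSegment, config: IngestConfig) -> list[Mutation]:
    """Collect the configured characteristic mutations from one mapped record.

    Deletions are located through CIGAR ``D`` operations; substitutions
    through the MD tag (via pysam's aligned-pairs reconstruction), so no
    reference FASTA is needed. Only mutations matching
    ``config.mutation_type`` are returned, complemented on minus-strand
    tags (T->C on ``+`` corresponds to A->G on ``-``).
    """
    mtype = config.mutation_type
    if mtype == "none":
        return []
    strand = _record_strand(rec)
    chrom = rec.reference_name
    out: list[Mutation] = []
    has_md = rec.has_tag("MD")
    if mtype in ("T2C", "G2A"):
        if not has_md:
            raise ValueError(
                f"substitution profiling ({mtype}) requires MD tags, but record "
                f"{rec.query_name!r} has none; realign with MD tags or use "
                "mutation_type 'deletion'/'none'"
            )
        want_ref, want_alt = _SUBSTITUTION_PROFILE[mtype][strand]
        query = rec.query_sequence
        for qpos, rpos, ref in rec.get_aligned_pairs(with_seq=True):
            if qpos is None or rpos is None or ref is None:
                continue
            if ref.islower():  # pysam lowercases mismatched reference bases
                ref_base = ref.upper()
                alt_base = query[qpos].upper()
                if ref_base == want_ref and alt_base == want_alt:
                    out.append(
                        Mutation("substitution", chrom, rpos, ref_base, alt_base, strand)
                    )
    else:  # deletions
        if has_md:
            pairs = rec.get_aligned_pairs(with_seq=True)
        else:
            pairs = [(q, r, None) for q, r in rec.get_aligned_pairs()]
        for qpos, rpos, ref in pairs:
            if qpos is None and rpos is not None:  # reference base deleted from read
                ref_base = ref.upper() if ref else "N"
                out.append(Mutation("deletion", chrom, rpos, ref_base, None, strand))
    return out


def _fragment_span(rec: pysam.AlignedSegment) -> tuple[int, int]:
    """Outer coordinates of a properly-paired fragment, from read1."""
    left = min(rec.reference_start, rec.next_reference_start)
    return left, left + abs(rec.template_length)


def read_alignments(
    sam_path: str, condition: int, config: IngestConfig
) -> Iterator[AlignedTag]:
    """Yield one :class:`AlignedTag` per mapped record (or proper pair).

    Unmapped, secondary and supplementary records are skipped, as are
    records below ``config.min_mapping_quality``. In paired-end mode a
    properly-paired fragment contributes a single tag spanning the outer
    fragment coordinates (emitted at read1, with read1's strand and
    mutations); orphan mates are treated as single-end.
    """
    if condition not in (1, 2):
        raise ValueError("condition must be 1 or 2")
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < config.min_mapping_quality:
                continue
            if rec.cigartuples is None:
                logger.warning("record %s has no CIGAR; skipped", rec.query_name)
                continue
            try:
                muts = extract_mutations(rec, config)
            except ValueError:
                raise
            except Exception as exc:  # inconsistent MD/CIGAR etc.
                logger.warning(
                    "record %s: inconsistent alignment tags (%s); skipped",
                    rec.query_name,
                    exc,
                )
                continue
            if config.paired_end and rec.is_paired and rec.is_proper_pair:
                if not rec.is_read1:
                    continue  # fragment counted once, at read1
                if rec.template_length == 0:
                    logger.warning(
                        "proper pair %s has TLEN 0; treated as single-end",
                        rec.query_name,
                    )
                    start, end = rec.reference_start, rec.reference_end
                else:
                    start, end = _fragment_span(rec)
            else:
                start, end = rec.reference_start, rec.reference_end
            yield AlignedTag(
                chrom=rec.reference_name,
                start=start,
                end=end,
                strand=_record_strand(rec),
                condition=condition,
                mutations=muts,
            )


def collapse_duplicates(tags: Iterable[AlignedTag]) -> list[AlignedTag]:
    """Collapse PCR duplicates sharing (chrom, start, end, strand).

    One tag survives per key, keeping the first-seen tag's identity; the
    surviving tag's mutation list is the union of the duplicates' distinct
    mutations, each counted once, so PCR amplification cannot inflate
    mutation counts. Output order is first-occurrence order (deterministic).
    """
    seen: dict[tuple, AlignedTag] = {}
    for tag in tags:
        kept = seen.get(tag.key)
        if kept is None:
            seen[tag.key] = AlignedTag(
                tag.chrom, tag.start, tag.end, tag.strand, tag.condition,
                list(dict.fromkeys(tag.mutations)),
            )
        else:
            if kept.condition != tag.condition:
                raise ValueError("collapse_duplicates expects tags from one condition")
            for mut in tag.mutations:
                if mut not in kept.mutations:
                    kept.mutations.append(mut)
    return list(seen.values())


def write_mutation_table(tags: Iterable[AlignedTag], path: str) -> int:
    """Write collected mutations as tab-delimited text; returns line count.

    Columns: chrom, 0-based position, strand, kind, ref, alt, condition.
    """
    n = 0
    with open(path, "w") as out:
        out.write("chrom\tpos\tstrand\tkind\tref\talt\tcondition\n")
        for tag in tags:
            for m in tag.mutations:
                out.write(
                    f"{m.chrom}\t{m.pos}\t{m.strand}\t{m.kind}\t{m.ref_base}\t"
                    f"{m.alt_base or '.'}\t{tag.condition}\n"
                )
                n += 1
    return n
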