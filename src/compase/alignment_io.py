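"""BED/BAM input handling and count-table output.

Gene intervals come from BED4+ files (0-based half-open, name in the 4th
column); homologous genes are paired across the two parental annotations
by exact name match.  Per-read alignment statistics (alignment score,
mismatch count, optional hit count) are pulled from coordinate-sorted,
indexed BAM files via pysam.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pysam

from .errors import FormatError, InputError, TagError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneInterval:
    """A named gene region in one parental coordinate system (BED semantics)."""

    name: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("gene interval must have a non-empty name")
        if self.end <= self.start:
            raise FormatError(
                f"gene {self.name!r}: end ({self.end}) must exceed start ({self.start})"
            )


@dataclass(frozen=True)
class HomologPair:
    """The same gene in both parental coordinate systems."""

    name: str
    interval_p1: GeneInterval
    interval_p2: GeneInterval

    def __post_init__(self) -> None:
        if not (self.interval_p1.name == self.interval_p2.name == self.name):
            raise FormatError(
                f"homolog pair {self.name!r}: interval names do not match"
            )


@dataclass(frozen=True)
class ReadStats:
    """Per-read (per-fragment) alignment statistics from one parental BAM.

    For paired-end data the two mates are merged: ``alignment_score`` and
    ``mismatches`` are sums over the observed mates, so a fragment carries
    one record per parent.
    """

    read_id: str
    alignment_score: Optional[int] = None
    mismatches: Optional[int] = None
    hit_count: Optional[int] = None
    mapped: bool = True

    def __post_init__(self) -> None:
        if self.mapped:
            if self.mismatches is not None and self.mismatches < 0:
                raise ValueError("mismatches must be non-negative")
        else:
            if self.alignment_score is not None or self.mismatches is not None:
                raise ValueError("unmapped reads carry no alignment statistics")


@dataclass(frozen=True)
class TagConfig:
    """Which BAM tags hold the alignment score and mismatch count.

    Defaults follow the STAR aligner (``AS`` / ``nM``).  BWA and Bowtie2
    users should set ``nm_tag="NM"``.  ``star_mode`` reads the NH tag to
    detect multi-mappers instead of relying on read-name collisions;
    ``binom_mode`` switches ambiguous-read resolution from deterministic
    proportional allocation to a seeded binomial draw.
    """

    as_tag: str = "AS"
    nm_tag: str = "nM"
    star_mode: bool = False
    binom_mode: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for label in (self.as_tag, self.nm_tag):
            if len(label) != 2:
                raise FormatError(f"tag label {label!r} must be exactly two characters")


def read_bed(path: str | Path) -> list[GeneInterval]:
    """Parse a BED4+ file into gene intervals, preserving file order.

    Coordinates are 0-based half-open per the BED standard.  Columns
    beyond the 4th are ignored; empty lines and ``#``/``track``/``browser``
    lines are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"BED file not found: {path}")
    intervals: list[GeneInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 4 tab-separated columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: end ({end}) must exceed start ({start})"
                )
            intervals.append(GeneInterval(name=name, chrom=chrom, start=start, end=end))
    return intervals


def match_homologs(
    bed_p1: Iterable[GeneInterval], bed_p2: Iterable[GeneInterval]
) -> tuple[list[HomologPair], list[str]]:
    """Pair genes across the two parental annotations by exact name.

    Returns the pairs in parent-1 order plus the names present in only
    one annotation (these are excluded from counting, with a warning).
    """
    p1 = list(bed_p1)
    p2 = list(bed_p2)
    for label, intervals in (("parent-1", p1), ("parent-2", p2)):
        names = Counter(iv.name for iv in intervals)
        dups = [n for n, c in names.items() if c > 1]
        if dups:
            raise FormatError(f"duplicate gene name(s) in {label} BED: {sorted(dups)}")
    by_name_p2 = {iv.name: iv for iv in p2}
    pairs: list[HomologPair] = []
    unmatched: list[str] = []
    for iv in p1:
        other = by_name_p2.get(iv.name)
        if other is None:
            unmatched.append(iv.name)
        else:
            pairs.append(HomologPair(name=iv.name, interval_p1=iv, interval_p2=other))
    matched = {p.name for p in pairs}
    unmatched.extend(iv.name for iv in p2 if iv.name not in matched)
    if unmatched:
        logger.warning(
            "%d gene(s) present in only one BED file are excluded: %s",
            len(unmatched),
            ", ".join(unmatched[:10]) + ("..." if len(unmatched) > 10 else ""),
        )
    if not pairs:
        raise InputError("no gene names are shared between the two BED files")
    return pairs, unmatched


@dataclass
class ExtractionLog:
    """Tallies accumulated while extracting read statistics."""

    records_used: int = 0
    records_missing_tags: int = 0

    def merge(self, other: "ExtractionLog") -> None:
        self.records_used += other.records_used
        self.records_missing_tags += other.records_missing_tags


def _is_counted(rec: pysam.AlignedSegment) -> bool:
    return not (rec.is_unmapped or rec.is_secondary or rec.is_supplementary)


def extract_read_stats(
    bam: pysam.AlignmentFile,
    interval: GeneInterval,
    config: TagConfig,
    log: Optional[ExtractionLog] = None,
) -> dict[str, ReadStats]:
    """Collect one ReadStats per fragment overlapping ``interval``.

    Alignments overlapping the interval by >= 1 bp are considered;
    unmapped, secondary and supplementary records are skipped.  When a
    read name yields several primary records for the same mate
    (multi-mapper), the best-scoring record wins (ties: fewest
    mismatches, then first encountered).  Paired mates are then merged
    by summing alignment scores and mismatch counts.

    Records lacking the configured AS or NM tag are tallied; if more
    than half of the records in the region lack them, a :class:`TagError`
    suggests the tag labels are wrong for this aligner.
    """
    if interval.chrom not in bam.references:
        raise InputError(
            f"reference {interval.chrom!r} (gene {interval.name!r}) not in BAM header"
        )
    local = ExtractionLog()
    # best record per (read name, mate slot)
    best: dict[tuple[str, int], tuple[int, int, int]] = {}
    order = 0
    for rec in bam.fetch(interval.chrom, interval.start, interval.end):
        if not _is_counted(rec):
            continue
        try:
            score = int(rec.get_tag(config.as_tag))
            nm = int(rec.get_tag(config.nm_tag))
        except KeyError:
            local.records_missing_tags += 1
            continue
        local.records_used += 1
        if config.star_mode:
            try:
                hits = int(rec.get_tag("NH"))
            except KeyError:
                hits = 1
        else:
            hits = 1
        mate = 2 if (rec.is_paired and rec.is_read2) else 1
        key = (rec.query_name, mate)
        prev = best.get(key)
        # higher score wins; ties by fewer mismatches, then first encountered
        cand = (score, nm, order, hits)
        order += 1
        if prev is None or (cand[0], -cand[1]) > (prev[0], -prev[1]):
            best[key] = cand
    total = local.records_used + local.records_missing_tags
    if total > 0 and local.records_missing_tags > 0.5 * total:
        raise TagError(
            f"{local.records_missing_tags}/{total} records near {interval.name!r} lack "
            f"the {config.as_tag!r}/{config.nm_tag!r} tags; check --AS_tag/--NM_tag"
        )
    if log is not None:
        log.merge(local)
    merged: dict[str, ReadStats] = {}
    for (name, _mate), (score, nm, _order, hits) in sorted(
        best.items(), key=lambda kv: kv[1][2]
    ):
        prev = merged.get(name)
        if prev is None:
            merged[name] = ReadStats(
                read_id=name, alignment_score=score, mismatches=nm, hit_count=hits
            )
        else:
            merged[name] = ReadStats(
                read_id=name,
                alignment_score=prev.alignment_score + score,
                mismatches=prev.mismatches + nm,
                hit_count=max(prev.hit_count or 1, hits),
            )
    return merged


def write_counts(records, path: str | Path, sample_name: str) -> None:
    """Write the per-gene count table (TSV) in parent-1 BED order."""
    records = list(records)
    if not records:
        raise InputError("no count records to write")
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write(f"# sample={sample_name}\n")
            fh.write(
                "gene\tcount_p1\tcount_p2\tcount_ambiguous\tresolved_p1\tresolved_p2\n"
            )
            for rec in records:
                fh.write(
                    f"{rec.gene}\t{rec.count_p1}\t{rec.count_p2}\t"
                    f"{rec.count_ambiguous}\t{rec.resolved_p1}\t{rec.resolved_p2}\n"
                )
    except OSError as exc:
        raise InputError(f"cannot write counts to {path}: {exc}") from exc
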