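"""RNA-seq read simulation with known allelic origins.

Expression fold-changes between alleles (cis effects) and between
parents (cis + trans) are drawn from signed exponential distributions
with point masses at zero; fragment counts per replicate follow a
negative-binomial model (Poisson at dispersion 0).  Error-free
fixed-length reads are drawn uniformly along each allelic transcript
and written to a pair of coordinate-sorted BAM files — one per parent —
in which every read is placed, gaplessly and full-length, at its true
offset, with alignment-score and mismatch tags computed by an oracle
aligner.  Because the two alleles differ only by substitutions, the
gapless alignment at the true offset is optimal, so these BAMs are
exactly what an aligner with perfect sensitivity would produce.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from .alignment_io import ReadStats, TagConfig
from .errors import InputError
from .sequence_sim import CodingSequencePair

CATEGORIES = (
    "conserved",
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_x_trans",
    "compensatory",
)


@dataclass(frozen=True)
class ExpressionDesign:
    """Per-gene expression architecture for the simulation.

    ``cis_lfc`` is the allelic log2 fold-change inside the hybrid
    (allele 1 over allele 2); the parental log2 fold-change is
    ``cis_lfc + trans_lfc``.  ``base_mean`` is the expected fragment
    count per allele per replicate at fold-change 1.
    """

    gene: str
    base_mean: float
    cis_lfc: float
    trans_lfc: float
    pi_null_cis: float
    pi_null_trans: float
    lfc_rate: float

    def __post_init__(self) -> None:
        if self.base_mean <= 0:
            raise InputError("base_mean must be positive")

    @property
    def parental_lfc(self) -> float:
        return self.cis_lfc + self.trans_lfc

    @property
    def true_category(self) -> str:
        """Regulatory-divergence category implied by the architecture."""
        c, t = self.cis_lfc, self.trans_lfc
        if c == 0 and t == 0:
            return "conserved"
        if t == 0:
            return "cis_only"
        if c == 0:
            return "trans_only"
        if c + t == 0:
            return "compensatory"
        return "cis_plus_trans" if (c > 0) == (t > 0) else "cis_x_trans"


@dataclass(frozen=True)
class SimulatedRead:
    """One error-free read with its ground-truth origin."""

    read_id: str
    gene: str
    true_origin: str  # "P1" or "P2"
    start_offset: int
    sequence: str


def sample_effects(
    n_genes: int,
    rng: np.random.Generator,
    lfc_rate: float = 0.5,
    pi_null_cis: float = 0.3,
    pi_null_trans: float = 0.3,
    base_mean: float = 200.0,
    gene_names: Optional[Sequence[str]] = None,
) -> list[ExpressionDesign]:
    """Draw the cis/trans effect architecture for every gene.

    With probability ``pi_null_*`` an effect is exactly zero; otherwise
    its magnitude is Exponential(rate) in log2 units with a random sign.
    Allele and parent fold-changes come from independent draws.
    """
    if not (0 <= pi_null_cis <= 1 and 0 <= pi_null_trans <= 1):
        raise InputError("pi_null probabilities must lie in [0, 1]")
    if lfc_rate <= 0:
        raise InputError("lfc_rate must be positive")
    if gene_names is None:
        width = max(4, len(str(n_genes)))
        gene_names = [f"gene_{i + 1:0{width}d}" for i in range(n_genes)]

    def draw(pi_null: float) -> float:
        if rng.random() < pi_null:
            return 0.0
        mag = rng.exponential(1.0 / lfc_rate)
        return mag if rng.random() < 0.5 else -mag

    return [
        ExpressionDesign(
            gene=gene_names[i],
            base_mean=base_mean,
            cis_lfc=draw(pi_null_cis),
            trans_lfc=draw(pi_null_trans),
            pi_null_cis=pi_null_cis,
            pi_null_trans=pi_null_trans,
            lfc_rate=lfc_rate,
        )
        for i in range(n_genes)
    ]


def _nb_draw(
    mean: float, dispersion: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """NB2 sampling (var = mean + dispersion * mean^2); Poisson at 0."""
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    return rng.negative_binomial(n, n / (n + mean), size=size)


def simulate_fragment_counts(
    design: ExpressionDesign,
    n_replicates: int,
    dispersion: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-replicate fragment counts for the four expression tracks.

    The log2 fold-change is applied symmetrically (+lfc/2 to one side,
    -lfc/2 to the other) so the ratio of expected counts equals 2**lfc.
    Tracks ``a1``/``a2`` are the hybrid alleles (cis effect only);
    ``p1``/``p2`` are the homozygous parents (cis + trans).
    """
    if dispersion < 0:
        raise InputError("dispersion must be >= 0")
    half_a = design.cis_lfc / 2.0
    half_p = design.parental_lfc / 2.0
    means = {
        "a1": design.base_mean * 2.0 ** half_a,
        "a2": design.base_mean * 2.0 ** -half_a,
        "p1": design.base_mean * 2.0 ** half_p,
        "p2": design.base_mean * 2.0 ** -half_p,
    }
    return {
        track: _nb_draw(m, dispersion, n_replicates, rng)
        for track, m in means.items()
    }


def generate_reads(
    pair: CodingSequencePair,
    count_p1: int,
    count_p2: int,
    read_length: int,
    rng: np.random.Generator,
) -> list[SimulatedRead]:
    """Draw error-free reads from both alleles at uniform start offsets."""
    reads: list[SimulatedRead] = []
    for origin, seq, count in (
        ("P1", pair.seq_p1, count_p1),
        ("P2", pair.seq_p2, count_p2),
    ):
        length = len(seq)
        if read_length > length:
            raise InputError(
                f"read_length {read_length} exceeds transcript length {length} "
                f"({pair.gene})"
            )
        offsets = rng.integers(0, length - read_length + 1, size=count)
        for i, off in enumerate(offsets):
            off = int(off)
            reads.append(
                SimulatedRead(
                    read_id=f"{pair.gene}|{origin}|{i:06d}",
                    gene=pair.gene,
                    true_origin=origin,
                    start_offset=off,
                    sequence=seq[off : off + read_length],
                )
            )
    return reads


def divergent_positions(pair: CodingSequencePair) -> np.ndarray:
    """Sorted 0-based positions where the two alleles differ."""
    a = np.frombuffer(pair.seq_p1.encode(), dtype="S1")
    b = np.frombuffer(pair.seq_p2.encode(), dtype="S1")
    return np.flatnonzero(a != b)


def zero_coverage_offset_fraction(
    pair: CodingSequencePair, read_length: int
) -> float:
    """Fraction of read start offsets covering no divergent site.

    Computed exactly from the divergent-site positions: a read starting
    at offset s covers a site d iff s <= d < s + read_length.  This is
    the expected ambiguous fraction for uniformly placed error-free
    reads on this gene.
    """
    length = len(pair.seq_p1)
    if read_length > length:
        raise InputError("read_length exceeds transcript length")
    n_offsets = length - read_length + 1
    div = divergent_positions(pair)
    covered = np.zeros(n_offsets, dtype=bool)
    for d in div:
        lo = max(0, int(d) - read_length + 1)
        hi = min(n_offsets - 1, int(d))
        if hi >= lo:
            covered[lo : hi + 1] = True
    return float((~covered).sum()) / n_offsets


def oracle_align(read: SimulatedRead, reference: str) -> ReadStats:
    """Score a read against one parental allele at its true offset.

    NM is the Hamming distance to the reference substring; the
    alignment score follows a BWA-MEM-like scheme (+1 per match, -4 per
    mismatch): AS = read_length - 5 * NM.
    """
    sub = reference[read.start_offset : read.start_offset + len(read.sequence)]
    if len(sub) != len(read.sequence):
        raise InputError("read extends past the reference end")
    a = np.frombuffer(read.sequence.encode(), dtype="S1")
    b = np.frombuffer(sub.encode(), dtype="S1")
    nm = int((a != b).sum())
    return ReadStats(
        read_id=read.read_id,
        alignment_score=len(read.sequence) - 5 * nm,
        mismatches=nm,
        hit_count=1,
    )


def emit_bam_pair(
    reads: Iterable[SimulatedRead],
    pairs: Sequence[CodingSequencePair],
    tag_config: TagConfig,
    out_prefix: str | Path,
) -> tuple[Path, Path, Path, Path]:
    """Write the two parental BAMs (sorted, indexed) plus BED4 files.

    Every read appears in both BAMs, aligned gaplessly and full-length
    at its true offset, with AS/NM tags from the oracle aligner against
    that parent's allele.  Each transcript is its own reference
    sequence; the BED files span the full transcripts.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    pair_by_gene = {p.gene: p for p in pairs}
    by_gene: dict[str, list[SimulatedRead]] = {p.gene: [] for p in pairs}
    for read in reads:
        if read.gene not in by_gene:
            raise InputError(f"read {read.read_id} references unknown gene {read.gene}")
        by_gene[read.gene].append(read)

    paths: list[Path] = []
    for side, attr in (("p1", "seq_p1"), ("p2", "seq_p2")):
        bam_path = out_prefix.with_name(out_prefix.name + f".{side}.bam")
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": p.gene, "LN": len(getattr(p, attr))} for p in pairs
            ],
        }
        with pysam.AlignmentFile(str(bam_path), "wb", header=header) as out:
            for ref_id, p in enumerate(pairs):
                ref_seq = getattr(p, attr)
                div = divergent_positions(p)
                gene_reads = sorted(by_gene[p.gene], key=lambda r: r.start_offset)
                offs = np.array([r.start_offset for r in gene_reads], dtype=np.int64)
                if offs.size:
                    # mismatches vs this parent = divergent sites covered,
                    # zero when the read originates from this parent
                    covered = np.searchsorted(div, offs + len(gene_reads[0].sequence))
                    covered = covered - np.searchsorted(div, offs)
                for i, read in enumerate(gene_reads):
                    nm = (
                        0
                        if read.true_origin.lower() == side
                        else int(covered[i])
                    )
                    seg = pysam.AlignedSegment(out.header)
                    seg.query_name = read.read_id
                    seg.flag = 0
                    seg.reference_id = ref_id
                    seg.reference_start = read.start_offset
                    seg.mapping_quality = 60
                    seg.cigartuples = [(0, len(read.sequence))]
                    seg.query_sequence = read.sequence
                    seg.set_tags(
                        [
                            (tag_config.as_tag, len(read.sequence) - 5 * nm, "i"),
                            (tag_config.nm_tag, nm, "i"),
                            ("NH", 1, "i"),
                        ]
                    )
                    out.write(seg)
        pysam.index(str(bam_path))
        bed_path = out_prefix.with_name(out_prefix.name + f".{side}.bed")
        with open(bed_path, "w") as fh:
            for p in pairs:
                fh.write(f"{p.gene}\t0\t{len(getattr(p, attr))}\t{p.gene}\n")
        paths.extend([bam_path, bed_path])
    return tuple(paths)  # type: ignore[return-value]
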