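"""Simulation of allelic coding-sequence pairs with synonymous divergence.

Protein lengths are drawn from a truncated Gamma distribution; random
coding sequences are built from uniform sense codons (ATG start, stop
end); a divergent allele is produced by letting each degenerate codon
mutate to one of its synonymous alternatives with a probability
calibrated so that the expected realized divergence (synonymous
substitutions per synonymous site) equals the requested target dS.
Because only synonymous replacements are made, the two alleles always
translate to the identical protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .errors import InputError

BASES = "ACGT"
STOP_CODONS: tuple[str, ...] = tuple(standard_dna_table.stop_codons)
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))  # 61 codons

# synonymous family = codons encoding the same amino acid (serine's two
# codon boxes form one 6-member family: mutation replaces whole codons)
_FAMILY: dict[str, list[str]] = {}
for _c, _aa in CODON_TO_AA.items():
    _FAMILY.setdefault(_aa, []).append(_c)
SYN_ALTERNATIVES: dict[str, tuple[str, ...]] = {
    c: tuple(sorted(set(_FAMILY[CODON_TO_AA[c]]) - {c})) for c in SENSE_CODONS
}


def _synonymous_sites(codon: str) -> float:
    """Nei–Gojobori synonymous-site count of one sense codon.

    The number of the nine possible single-nucleotide changes that are
    synonymous (changes to stop codons count as non-synonymous),
    divided by three.
    """
    aa = CODON_TO_AA[codon]
    syn = 0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if CODON_TO_AA.get(alt) == aa:
                syn += 1
    return syn / 3.0


SYN_SITES: dict[str, float] = {c: _synonymous_sites(c) for c in SENSE_CODONS}

# vectorized lookup tables indexed by position in SENSE_CODONS
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_SITES_ARR = np.array([SYN_SITES[c] for c in SENSE_CODONS])
_N_ALTS_ARR = np.array([len(SYN_ALTERNATIVES[c]) for c in SENSE_CODONS])


@dataclass(frozen=True)
class SimulationParams:
    """Conditions for a coding-sequence divergence simulation.

    Defaults reproduce the validation design: 1000 genes with protein
    lengths from Gamma(shape=1.35, scale=1000 aa) truncated at 300 aa,
    and a target synonymous divergence chosen from {0.001, 0.01, 0.1}
    substitutions per synonymous site.
    """

    n_genes: int = 1000
    gamma_shape: float = 1.35
    gamma_scale: float = 1000.0
    min_length_aa: int = 300
    ds_target: float = 0.01
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_length_aa < 1:
            raise InputError("min_length_aa must be >= 1")
        if not 0.0 < self.ds_target < 1.0:
            raise InputError("ds_target must lie in (0, 1)")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise InputError("gamma parameters must be positive")


@dataclass(frozen=True)
class CodingSequencePair:
    """Two allelic coding sequences differing only at synonymous sites."""

    gene: str
    seq_p1: str
    seq_p2: str
    ds_target: float
    ds_realized: float


def _validate_cds(seq: str) -> None:
    if len(seq) % 3 != 0 or len(seq) < 9:
        raise InputError("CDS length must be a positive multiple of 3 (>= 9 nt)")
    if any(b not in BASES for b in seq):
        raise InputError("CDS contains non-ACGT characters")
    if not seq.startswith("ATG"):
        raise InputError("CDS must start with ATG")
    if seq[-3:] not in STOP_CODONS:
        raise InputError("CDS must end with a stop codon")
    for i in range(0, len(seq) - 3, 3):
        if seq[i : i + 3] in STOP_CODONS:
            raise InputError(f"internal stop codon at nt {i}")


def translate(seq: str) -> str:
    """Translate a validated CDS (stop codon excluded)."""
    return "".join(CODON_TO_AA[seq[i : i + 3]] for i in range(0, len(seq) - 3, 3))


def sample_protein_lengths(
    params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw protein lengths (aa) from the truncated Gamma distribution.

    Each draw is rounded to the nearest integer and redrawn until it
    reaches ``min_length_aa`` (rejection sampling).
    """
    out = np.empty(params.n_genes, dtype=np.int64)
    filled = 0
    while filled < params.n_genes:
        need = params.n_genes - filled
        draws = np.rint(
            rng.gamma(params.gamma_shape, params.gamma_scale, size=need)
        ).astype(np.int64)
        keep = draws[draws >= params.min_length_aa]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def random_cds(length_aa: int, rng: np.random.Generator) -> str:
    """Build a random CDS of ``length_aa`` amino acids plus a stop codon.

    Starts with ATG; the remaining length_aa - 1 codons are uniform over
    all 61 sense codons (no codon-usage bias); ends with one of the
    three stop codons chosen uniformly.
    """
    if length_aa < 2:
        raise InputError("length_aa must be >= 2")
    idx = rng.integers(0, len(SENSE_CODONS), size=length_aa - 1)
    internal = "".join(SENSE_CODONS[i] for i in idx)
    stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
    return "ATG" + internal + stop


def _codon_indices(seq: str) -> np.ndarray:
    """Indices into SENSE_CODONS for every codon except the stop."""
    return np.fromiter(
        (_CODON_INDEX[seq[i : i + 3]] for i in range(0, len(seq) - 3, 3)),
        dtype=np.int64,
        count=len(seq) // 3 - 1,
    )


def diverge_synonymous(
    seq: str, ds_target: float, rng: np.random.Generator
) -> tuple[str, float]:
    """Create a synonymously divergent copy of a CDS.

    Every degenerate codon (one with >= 1 synonymous alternative) mutates
    independently with probability q = ds_target * S / M, where S is the
    sequence's total synonymous-site count and M its number of mutable
    codons; a mutating codon is replaced by one of its synonymous
    alternatives uniformly.  Under this one-event-per-codon model the
    expected realized divergence equals ds_target.  ATG, TGG and the
    stop codon never change.  Returns the copy and the realized
    divergence as measured by :func:`compute_ds`.
    """
    _validate_cds(seq)
    idx = _codon_indices(seq)
    n_alts = _N_ALTS_ARR[idx]
    mutable = n_alts >= 1
    n_mutable = int(mutable.sum())
    total_sites = float(_SITES_ARR[idx].sum())
    if n_mutable == 0 or total_sites == 0.0:
        return seq, 0.0
    q = min(1.0, ds_target * total_sites / n_mutable)
    hits = mutable & (rng.random(idx.size) < q)
    codons = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
    for pos in np.flatnonzero(hits):
        alts = SYN_ALTERNATIVES[codons[pos]]
        codons[pos] = alts[rng.integers(0, len(alts))]
    mutated = "".join(codons) + seq[-3:]
    return mutated, compute_ds(seq, mutated)


def compute_ds(seq1: str, seq2: str) -> float:
    """Synonymous divergence between two alleles of the same protein.

    The alleles must be equal-length valid CDSs with identical
    translations.  Divergence is the number of differing codons divided
    by the synonymous-site total (mean of the two sequences' per-codon
    Nei–Gojobori site counts, stop codon excluded).  Because the alleles
    differ only synonymously and the mutation model replaces whole
    codons (one event per codon), each differing codon is one
    substitution.
    """
    if len(seq1) != len(seq2):
        raise InputError("sequences must have equal length")
    _validate_cds(seq1)
    _validate_cds(seq2)
    if translate(seq1) != translate(seq2):
        raise InputError("sequences must translate to the identical protein")
    idx1 = _codon_indices(seq1)
    idx2 = _codon_indices(seq2)
    diffs = int((idx1 != idx2).sum())
    sites = 0.5 * float(_SITES_ARR[idx1].sum() + _SITES_ARR[idx2].sum())
    if sites == 0.0:
        return 0.0
    return diffs / sites


def simulate_sequence_pairs(
    params: SimulationParams, rng: Optional[np.random.Generator] = None
) -> list[CodingSequencePair]:
    """Run the full sequence pipeline: lengths -> CDS -> divergent allele."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    lengths = sample_protein_lengths(params, rng)
    width = max(4, len(str(params.n_genes)))
    pairs = []
    for i, length in enumerate(lengths):
        seq1 = random_cds(int(length), rng)
        seq2, ds_real = diverge_synonymous(seq1, params.ds_target, rng)
        pairs.append(
            CodingSequencePair(
                gene=f"gene_{i + 1:0{width}d}",
                seq_p1=seq1,
                seq_p2=seq2,
                ds_target=params.ds_target,
                ds_realized=ds_real,
            )
        )
    return pairs


def write_references(
    pairs: Sequence[CodingSequencePair], out_prefix: str | Path
) -> tuple[Path, Path, Path, Path]:
    """Write per-parent FASTA references and matching full-span BED4 files."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for side, attr in (("p1", "seq_p1"), ("p2", "seq_p2")):
        fasta = out_prefix.with_name(out_prefix.name + f".{side}.fasta")
        bed = out_prefix.with_name(out_prefix.name + f".{side}.bed")
        records = [
            SeqRecord(Seq(getattr(p, attr)), id=p.gene, description="")
            for p in pairs
        ]
        seqio_write(records, str(fasta), "fasta")
        with open(bed, "w") as fh:
            for p in pairs:
                fh.write(f"{p.gene}\t0\t{len(getattr(p, attr))}\t{p.gene}\n")
        paths.extend([fasta, bed])
    return tuple(paths)  # type: ignore[return-value]
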