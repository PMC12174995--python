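# Methods

## The counting model

An F1 hybrid carries one allele of each gene from each parent. Mapping its
RNA-seq reads to a single reference biases counts toward the reference
allele; competitive mapping avoids this by aligning the same reads
independently to *both* parental references and letting the two alignments
compete read by read. For each fragment the counter compares the
alignment score (AS tag) on the two sides; the higher score wins. On equal
scores the mismatch count (NM/nM tag) breaks the tie — fewer mismatches
wins. A fragment tied on both statistics is *ambiguous*; this happens
essentially when the read covers no site at which the two alleles differ.
Comparison order (score first, mismatches second) follows the principle
that the score is the aligner's own summary of alignment quality; the
mismatch count refines it.

Per gene `g`, with `n1` and `n2` unambiguous fragments assigned to
parents 1 and 2 and `A` ambiguous fragments, ambiguous counts are
re-allocated with the allelic proportion

    p = n1 / (n1 + n2)        (p = 1/2 when n1 + n2 = 0)

either deterministically — `round(p·A)` fragments to parent 1
(round-half-to-even on the exact rational) and the remainder to parent 2 —
or, in binomial mode, by drawing the parent-1 share from `Binomial(A, p)`
with a user-supplied seed. Both modes conserve fragments exactly:
`resolved_1 + resolved_2 = n1 + n2 + A` per gene.

Further behavioural decisions, made where the counting contract was
genuinely open:

- **One-sided reads.** A fragment found (within the homologous intervals)
  in only one parental BAM is assigned to that parent rather than
  discarded: "aligns better" degenerates naturally to the only available
  alignment. The run summary reports totals so users can quantify this.
- **Overlap policy.** A read belongs to a gene if its alignment overlaps
  the BED interval by ≥ 1 bp; reads overlapping two or more gene intervals
  of the *same* parent are discarded from all genes, mirroring the default
  of standard feature counters.
- **Multi-mappers.** Among primary records sharing a read name, the
  best-scoring record is kept (ties: fewest mismatches, then first
  encountered). The NH tag is consulted only in `--star` mode; this is an
  optimisation, not a semantic change.
- **Paired ends.** Mates sharing a read name are merged by summing AS and
  NM over observed mates, so a fragment is counted once.
- **Coordinates.** BED and internal coordinates are 0-based half-open;
  strand is ignored (unstranded counting).
- **Tags.** Defaults are STAR's `AS`/`nM`; BWA and Bowtie2 users pass
  `--NM_tag NM`. If more than half of the records in a region lack the
  configured tags, the run aborts with a hint that the labels are wrong.

## The simulation framework

The validation asks: given two alleles that differ only at synonymous
sites at a known density, how accurately does competitive counting recover
allele-specific counts and downstream regulatory inference? Every layer of
the simulation is seeded and reproducible.

**Coding sequences.** Protein lengths are drawn from
Gamma(shape = 1.35, scale = 1000 aa), rounded and redrawn until ≥ 300 aa
(rejection), for 1000 genes by default. A random CDS starts with ATG,
continues with codons drawn uniformly from the 61 sense codons (no
codon-usage bias), and ends with a uniform stop codon.

**Synonymous divergence.** Each degenerate codon (≥ 1 synonymous
alternative; families follow the standard genetic code, with serine's two
boxes one 6-member family because mutation replaces whole codons) mutates
independently with probability

    q = min(1, dS_target · S / M)

where `S` is the sequence's Nei–Gojobori synonymous-site total and `M` its
number of mutable codons; a mutating codon is replaced by a uniformly
chosen synonymous alternative. Under this one-event-per-codon model the
expected realized divergence — differing codons per synonymous site, with
sites averaged over the two alleles — equals `dS_target`; the realized
value is computed (`compute_ds`) and reported per gene, so downstream
results condition on realized rather than target divergence. Nonsynonymous
change, indels, transition bias and codon-usage bias are deliberately
absent: the quantity under study is divergence-driven read ambiguity, and
the two alleles always translate identically.

**Expression architecture.** Per gene, the allelic (cis) log2 fold-change
is 0 with probability 0.3 (point-mass null) and otherwise
±Exponential(rate = 0.5) — mean |log2FC| of 2, i.e. a typical 4-fold
change, chosen as realistic for interspecific regulatory divergence. The
trans effect is an independent draw with the same scheme; the parental
log2 fold-change is their sum. This point-mass architecture makes truth
well-defined: a gene is truly allelically DE iff its cis effect is nonzero,
and its true regulatory category follows from which effects are nonzero
and whether their signs agree (exact cancellation, the compensatory case,
has probability zero under continuous draws and is reported as
not-applicable).

**Fragment counts and reads.** Each track (hybrid alleles A1/A2, parents
P1/P2) gets per-replicate counts from NB2 with mean
`base_mean · 2^(±lfc/2)` (the half-effect applied symmetrically so the
mean ratio is exactly `2^lfc`) and dispersion 0 by default — Poisson.
Defaults: 200 expected fragments per allele per replicate, 3 replicates,
100-nt single-end error-free reads with uniform start offsets. Poisson
sampling (rather than overdispersed NB) is the default because the exact
binomial/Fisher tests used downstream are calibrated under it, and because
error-free, equidispersed data isolate the mapping-driven error that the
framework is built to measure. Real data add sequencing error,
overdispersion, mapping loss and fragment-length effects; passing these
simulations therefore bounds the mapping-algorithm error, not total
real-data error.

**Oracle alignment.** Because the alleles differ only by substitutions,
the gapless alignment of an error-free read at its true offset is optimal
on both references. The oracle aligner therefore computes NM as the
Hamming distance at the true offset and a BWA-MEM-like score
`AS = read_length − 5·NM` (+1 match, −4 mismatch), and the emitted BAM
pair places every read in both parental BAMs at its true offset,
coordinate-sorted and indexed, with AS/NM/NH tags. A read's origin
reference always scores ≥ the other reference, with equality exactly when
the read covers no divergent site — so the expected ambiguous fraction per
gene is computable in closed form from the divergent-site positions
(`zero_coverage_offset_fraction`) and is checked against observation.

## Statistics

Replicates are pooled (summed) before testing; replicate-level dispersion
modelling is out of scope. Three two-sided exact tests per gene:

- **allelic DE**: exact binomial test of `a1` vs `a1 + a2` against the
  null proportion `p0` (the library-size ratio; 0.5 in the balanced
  simulations);
- **parental DE**: the same test on `p1` vs `p1 + p2`;
- **trans contrast**: Fisher exact test on `[[a1, a2], [p1, p2]]` — the
  parental ratio differing from the allelic ratio is the signature of a
  trans effect.

Benjamini–Hochberg adjustment is applied separately within each family,
and significance at adjusted α = 0.05 feeds the category table
(P = parental, A = allelic, T = trans): none → conserved; P·A →
cis-only; P·T → trans-only; A·T → compensatory; P·A·T → cis + trans or
cis × trans by whether the allelic and (parental − allelic) log-ratio
effects share a sign; every other combination → ambiguous. The decision
table lives in one function (`classify_regulatory`) for easy revision.

Accuracy metrics: per-gene `Δ log2FC = log2((a1+1)/(a2+1))` under true
minus estimated counts, summarised by mean and sd; allelic-DE
false-negative, false-positive and total error rates (percent); per-category
false-negative rates and their mean over non-empty categories; and the
mean resolved/true ratio for the lower-expressed allele of
lowest-quartile-expression genes (the low-divergence overestimation
factor).

The exact-test classification replaces a negative-binomial GLM engine
(DESeq2-style) so the pipeline is fully self-contained; this is the
largest intended deviation of the validation layer and shifts absolute
error rates (see limitations).

## Problem sizes and numerical notes

The shipped validation runs use 1000 genes per divergence level
(dS ∈ {0.001, 0.01, 0.1}) at the default depth — about 1.2 M fragments
and two 1.2 M-record BAMs per level — which completes in a few minutes
per level on one core. Monte-Carlo checks in the test suite use 3 s.e.
bands (4.5 σ where 61 categories are tested simultaneously); exact-test
implementations are verified against enumeration oracles over all 2×2
tables with total ≤ 30. Deterministic rounding is performed on exact
rationals to make round-half-to-even unambiguous. All randomness flows
from a single seed through independent spawned streams per stage, so every
artifact (FASTA, BAM, truth table, summaries) is bit-reproducible.

## Known limitations

- At dS = 0.001 almost every read is ambiguous, so per-gene allocation
  rests on very few informative reads: resolved counts are then strongly
  noisy (heavy-tailed Δ log2FC) and the exact tests anticonservative,
  because proportional allocation propagates the allelic-proportion
  estimate into all ambiguous reads. This error mode is intrinsic to
  competitive counting at low divergence; its magnitude here depends
  directly on sequencing depth (Δ log2FC spread scales roughly as
  depth^(−1/2)) and on the fold-change architecture.
- With constant per-gene base expression and symmetric fold-change
  application, the lowest-count quartile consists of the most *balanced*
  genes, whose resolved counts are nearly unbiased — the simulation
  therefore produces little of the low-expression overestimation seen
  when baseline expression varies across genes.
- Single-end, error-free reads only; no mapping loss; the parental tracks
  are counted from their simulated truth (standard feature counting of
  homozygous parental reads is not re-modelled).
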