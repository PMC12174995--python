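"""Regulatory-divergence statistics on allele-specific counts.

Differential expression between alleles and between parents is tested
with exact binomial tests on pooled counts, and the cis/trans contrast
(parental ratio vs allelic ratio) with a Fisher exact test, following
the classical inheritance-mode framework for hybrid ASE: a gene is
cis-divergent when the hybrid allelic ratio departs from 1, trans
effects show up as a parental ratio that differs from the allelic one.
Benjamini-Hochberg control is applied within each test family before
genes are classified into regulatory categories, and classification
accuracy is summarised as false-negative / false-positive / total
error rates against simulation truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .read_sim import CATEGORIES

CALL_CATEGORIES = CATEGORIES + ("ambiguous",)


@dataclass(frozen=True)
class GeneExpressionSummary:
    """Pooled (replicate-summed) counts for one gene.

    ``a1``/``a2`` are the hybrid allelic counts, ``p1``/``p2`` the
    parental counts.  The library ratios give the null proportion for
    the binomial tests (side-1 total over grand total across the gene
    set); 0.5 for balanced designs.
    """

    gene: str
    a1: int
    a2: int
    p1: int
    p2: int
    lib_ratio_hybrid: float = 0.5
    lib_ratio_parental: float = 0.5

    def __post_init__(self) -> None:
        if min(self.a1, self.a2, self.p1, self.p2) < 0:
            raise InputError("counts must be non-negative")
        for r in (self.lib_ratio_hybrid, self.lib_ratio_parental):
            if not 0.0 < r < 1.0:
                raise InputError("library ratios must lie in (0, 1)")


@dataclass(frozen=True)
class RegulatoryCall:
    """Category assignment for one gene with its adjusted p-values."""

    gene: str
    category: str
    q_parental: float
    q_allelic: float
    q_trans: float

    def __post_init__(self) -> None:
        if self.category not in CALL_CATEGORIES:
            raise InputError(f"unknown category {self.category!r}")


def log2fc_difference(
    true_counts: Mapping[str, tuple[int, int]],
    est_counts: Mapping[str, tuple[int, int]],
    pseudocount: float = 1.0,
) -> tuple[pd.Series, float, float]:
    """Per-gene difference in allelic log2 fold-change, true minus estimated.

    delta = log2((t1+c)/(t2+c)) - log2((e1+c)/(e2+c)).  Returns the
    per-gene deltas (indexed by gene) with their mean and standard
    deviation over genes.
    """
    if pseudocount <= 0:
        raise InputError("pseudocount must be positive")
    if set(true_counts) != set(est_counts):
        raise InputError("true and estimated count tables cover different genes")
    genes = list(true_counts)
    c = pseudocount
    deltas = pd.Series(
        [
            math.log2((true_counts[g][0] + c) / (true_counts[g][1] + c))
            - math.log2((est_counts[g][0] + c) / (est_counts[g][1] + c))
            for g in genes
        ],
        index=genes,
        name="delta_log2fc",
    )
    mean = float(deltas.mean())
    sd = float(deltas.std(ddof=1)) if len(deltas) > 1 else 0.0
    return deltas, mean, sd


def binomial_ratio_test(x: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value (minimum-likelihood method).

    Sums the probabilities of all outcomes no more likely than the
    observed one.  n = 0 returns 1 by convention.
    """
    if not 0.0 < p0 < 1.0:
        raise InputError("p0 must lie in (0, 1)")
    if not 0 <= x <= n:
        raise InputError("need 0 <= x <= n")
    if n == 0:
        return 1.0
    return float(stats.binomtest(x, n, p0).pvalue)


def fisher_trans_test(a1: int, a2: int, p1: int, p2: int) -> float:
    """Two-sided Fisher exact p-value on the table [[a1, a2], [p1, p2]].

    Tests whether the parental ratio differs from the hybrid allelic
    ratio — the trans component of regulatory divergence.  An all-zero
    table returns 1.
    """
    if min(a1, a2, p1, p2) < 0:
        raise InputError("counts must be non-negative")
    if a1 + a2 + p1 + p2 == 0:
        return 1.0
    return float(stats.fisher_exact([[a1, a2], [p1, p2]])[1])


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _signed_log_ratio(x: int, y: int, c: float = 0.5) -> float:
    return math.log2((x + c) / (y + c))


def classify_regulatory(
    summary: GeneExpressionSummary,
    q_parental: float,
    q_allelic: float,
    q_trans: float,
    alpha: float = 0.05,
) -> RegulatoryCall:
    """Assign one gene to a regulatory-divergence category.

    With P = parental DE, A = allelic DE, T = trans (ratio difference),
    each significant at ``alpha`` on BH-adjusted p-values:

    ========== ========== ========== =================================
    P          A          T          category
    ========== ========== ========== =================================
    no         no         no         conserved
    yes        yes        no         cis_only
    yes        no         yes        trans_only
    no         yes        yes        compensatory
    yes        yes        yes        cis_plus_trans / cis_x_trans,
                                     by agreement of the allelic and
                                     trans (parental - allelic) effect
                                     signs
    otherwise                        ambiguous
    ========== ========== ========== =================================
    """
    P = q_parental < alpha
    A = q_allelic < alpha
    T = q_trans < alpha
    if not P and not A and not T:
        category = "conserved"
    elif P and A and not T:
        category = "cis_only"
    elif P and not A and T:
        category = "trans_only"
    elif not P and A and T:
        category = "compensatory"
    elif P and A and T:
        allelic_effect = _signed_log_ratio(summary.a1, summary.a2)
        parental_effect = _signed_log_ratio(summary.p1, summary.p2)
        trans_effect = parental_effect - allelic_effect
        prod = allelic_effect * trans_effect
        if prod > 0:
            category = "cis_plus_trans"
        elif prod < 0:
            category = "cis_x_trans"
        else:
            category = "ambiguous"
    else:
        category = "ambiguous"
    return RegulatoryCall(
        gene=summary.gene,
        category=category,
        q_parental=q_parental,
        q_allelic=q_allelic,
        q_trans=q_trans,
    )


def classify_gene_set(
    summaries: Sequence[GeneExpressionSummary], alpha: float = 0.05
) -> list[RegulatoryCall]:
    """Run the three exact tests over a gene set and classify each gene.

    BH adjustment is applied separately within each of the three test
    families (parental DE, allelic DE, trans contrast).
    """
    if not summaries:
        return []
    p_par = [
        binomial_ratio_test(s.p1, s.p1 + s.p2, s.lib_ratio_parental)
        for s in summaries
    ]
    p_all = [
        binomial_ratio_test(s.a1, s.a1 + s.a2, s.lib_ratio_hybrid) for s in summaries
    ]
    p_trans = [fisher_trans_test(s.a1, s.a2, s.p1, s.p2) for s in summaries]
    q_par = bh_adjust(p_par)
    q_all = bh_adjust(p_all)
    q_trans = bh_adjust(p_trans)
    return [
        classify_regulatory(s, q_par[i], q_all[i], q_trans[i], alpha=alpha)
        for i, s in enumerate(summaries)
    ]


@dataclass(frozen=True)
class ErrorRates:
    """Error rates (percent) against simulation truth."""

    fn_allelic: float
    fp_allelic: float
    total_error_allelic: float
    category_fn: dict[str, float]  # NaN-free: inapplicable categories omitted
    mean_category_fn: float


def error_rates(
    truth_de: Mapping[str, bool],
    truth_category: Mapping[str, str],
    calls: Sequence[RegulatoryCall],
    alpha: float = 0.05,
) -> ErrorRates:
    """False-negative / false-positive / total error for allelic DE, and
    per-category false-negative rates for the regulatory classification.

    A gene counts as called allelically DE when its adjusted allelic
    p-value is below ``alpha``.  Truly empty categories are omitted from
    ``category_fn`` and from its mean.  All rates are percentages.
    """
    call_by_gene = {c.gene: c for c in calls}
    if set(call_by_gene) != set(truth_de) or set(call_by_gene) != set(
        truth_category
    ):
        raise InputError("truth tables and calls cover different genes")
    genes = list(call_by_gene)
    n = len(genes)
    truly_de = [g for g in genes if truth_de[g]]
    truly_not = [g for g in genes if not truth_de[g]]
    called_de = {g for g in genes if call_by_gene[g].q_allelic < alpha}
    fn = (
        100.0 * sum(1 for g in truly_de if g not in called_de) / len(truly_de)
        if truly_de
        else float("nan")
    )
    fp = (
        100.0 * sum(1 for g in truly_not if g in called_de) / len(truly_not)
        if truly_not
        else float("nan")
    )
    wrong = sum(
        1 for g in genes if (g in called_de) != truth_de[g]
    )
    total = 100.0 * wrong / n if n else float("nan")
    category_fn: dict[str, float] = {}
    for cat in CATEGORIES:
        members = [g for g in genes if truth_category[g] == cat]
        if not members:
            continue
        missed = sum(1 for g in members if call_by_gene[g].category != cat)
        category_fn[cat] = 100.0 * missed / len(members)
    mean_fn = (
        float(np.mean(list(category_fn.values()))) if category_fn else float("nan")
    )
    return ErrorRates(
        fn_allelic=fn,
        fp_allelic=fp,
        total_error_allelic=total,
        category_fn=category_fn,
        mean_category_fn=mean_fn,
    )
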