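"""Chromosomal traffic, cancer-type specificity, and translated candidates.

Traffic analysis asks whether pseudogene generation (parent location) and
insertion (pseudogene location) depart from proportional null models: each
chromosome generates pseudogenes in proportion to its protein-coding gene
count and receives them in proportion to its length. Departures for the X
chromosome versus the autosomes are tested with Fisher's exact test.

Cancer-type specificity labels genes from per-type expression shares (type
mean / sum of all type means): type-specific needs the focal share > 15% with
every other share < 5%; ubiquitous needs max share < 30% with each of the
top-5 shares > 5%. All inequalities are strict. Only cancer types with more
than 5 normal and more than 5 tumor samples are retained for differential
analyses.

A pseudogene is a translated candidate when both sequence-based coding
predictors flag it, its maximum ribosome-profiling FPKM reaches 1, and it
harbors at least one actively translated ORF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import AnnotationSet, ValidationError

TYPE_SPECIFIC_MIN_SHARE = 0.15  # strict >
TYPE_SPECIFIC_OTHER_MAX = 0.05  # strict <
UBIQUITOUS_MAX_SHARE = 0.30  # strict <
UBIQUITOUS_TOP5_MIN = 0.05  # strict >
RETENTION_MIN_SAMPLES = 5  # strict >, per group
RIBO_FPKM_MIN = 1.0  # inclusive >=


# ---------------------------------------------------------------------------
# Chromosomal traffic
# ---------------------------------------------------------------------------


def traffic_expectation(
    annotations: AnnotationSet, parent_chroms: dict[str, str] | None = None
) -> pd.DataFrame:
    """Observed and expected pseudogene generation/insertion counts per chromosome.

    Generation is attributed to the parent gene's chromosome (``parent_chroms``
    overrides/extends parent links in the annotation); insertion to the
    pseudogene's own chromosome. Expected generation is proportional to
    protein-coding gene counts, expected insertion to chromosome length; both
    expectations sum to the total pseudogene count.
    """
    layout = annotations.layout
    chroms = layout.chromosomes
    coding_counts = pd.Series(0, index=chroms, dtype=int)
    for g in annotations.coding_genes():
        coding_counts[g.chrom] += 1
    observed_ins = pd.Series(0, index=chroms, dtype=int)
    observed_gen = pd.Series(0, index=chroms, dtype=int)
    pseudos = annotations.pseudogenes()
    for g in pseudos:
        observed_ins[g.chrom] += 1
        parent = (parent_chroms or {}).get(g.gene_id)
        if parent is None and g.parent_gene is not None and g.parent_gene in annotations:
            parent = annotations[g.parent_gene].chrom
        if parent is not None:
            observed_gen[parent] += 1
    total = len(pseudos)
    total_gen = int(observed_gen.sum())
    lengths = pd.Series(layout.lengths, dtype=float)
    if coding_counts.sum() <= 0 or lengths.sum() <= 0:
        raise ValidationError("traffic expectation needs coding genes and lengths")
    expected_gen = total_gen * coding_counts / coding_counts.sum()
    expected_ins = total * lengths / lengths.sum()
    return pd.DataFrame(
        {
            "coding_genes": coding_counts,
            "length_bp": lengths.astype(int),
            "observed_generation": observed_gen,
            "expected_generation": expected_gen,
            "observed_insertion": observed_ins,
            "expected_insertion": expected_ins,
        }
    )


@dataclass
class FisherResult:
    table: np.ndarray
    odds_ratio: float  # conditional MLE; NaN when undefined (zero margin)
    sample_odds_ratio: float  # ad/bc; inf/NaN when a denominator cell is 0
    p_value: float
    odds_ratio_defined: bool


# relative slack when comparing hypergeometric probabilities, so that exact
# ties (e.g. symmetric tables) are counted despite float rounding
_PMF_TIE_RTOL = 1e-7


def fisher_two_sided_p(table) -> float:
    """Two-sided Fisher exact p by hypergeometric tail summation.

    Conditions on both margins of the 2x2 table and sums the probabilities of
    every table no more probable than the observed one.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("need a 2x2 table of non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n_total, r1, c1 = a + b + c + d, a + b, a + c
    if n_total == 0:
        return 1.0
    support = np.arange(max(0, c1 - (n_total - r1)), min(r1, c1) + 1)
    logpmf = (
        _lbinom(r1, support)
        + _lbinom(n_total - r1, c1 - support)
        - _lbinom(n_total, c1)
    )
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    observed = pmf[support == a][0]
    p = pmf[pmf <= observed * (1.0 + _PMF_TIE_RTOL)].sum()
    return float(min(1.0, p))


def _lbinom(n, k):
    from scipy.special import gammaln

    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def traffic_test(table, or_kind: str = "conditional") -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table (X/autosome x class).

    The p-value sums hypergeometric probabilities of all tables (with the
    observed margins) no more probable than the observed one. The odds ratio
    is the conditional maximum-likelihood estimate (``or_kind="conditional"``)
    or the sample ad/bc (``or_kind="sample"``); the sample value is always
    reported alongside. A zero margin makes the odds ratio undefined and the
    p-value 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("need a 2x2 table of non-negative integers")
    a, b, c, d = int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])
    sample_or = a * d / (b * c) if b * c > 0 else (np.inf if a * d > 0 else np.nan)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return FisherResult(t, float("nan"), sample_or, 1.0, False)
    p = fisher_two_sided_p(t)
    if or_kind == "conditional":
        odds = float(stats.contingency.odds_ratio(t, kind="conditional").statistic)
    elif or_kind == "sample":
        odds = sample_or
    else:
        raise ValueError(f"unknown or_kind {or_kind!r}")
    return FisherResult(t, odds, sample_or, p, True)


# ---------------------------------------------------------------------------
# Cancer-type specificity
# ---------------------------------------------------------------------------


@dataclass
class CancerShareProfile:
    gene_id: str
    shares: pd.Series  # per cancer type, sums to 1 for nonzero genes
    label: str  # "type_specific:<type>" | "ubiquitous" | "other"
    zero_expression: bool = False


def cancer_shares(type_means: pd.Series) -> pd.Series:
    """Per-type expression shares from per-type mean expression."""
    total = type_means.sum()
    if total <= 0:
        return type_means * 0.0
    return type_means / total


def classify_cancer_specificity(type_means: pd.Series) -> CancerShareProfile:
    """Label one gene from its per-type mean expression.

    type-specific(t): share_t > 0.15 and every other share < 0.05;
    ubiquitous: max share < 0.30 and each of the top-5 shares > 0.05;
    otherwise other. Strict inequalities throughout; an all-zero gene is
    "other" with the zero-expression flag set.
    """
    if len(type_means) < 2:
        raise ValidationError("need >= 2 cancer types")
    gene_id = type_means.name if type_means.name is not None else ""
    if type_means.sum() <= 0:
        return CancerShareProfile(gene_id, type_means * 0.0, "other", True)
    shares = cancer_shares(type_means)
    ranked = shares.sort_values(ascending=False)
    top = ranked.index[0]
    others = shares.drop(top)
    if shares[top] > TYPE_SPECIFIC_MIN_SHARE and (others < TYPE_SPECIFIC_OTHER_MAX).all():
        return CancerShareProfile(gene_id, shares, f"type_specific:{top}")
    top5 = ranked.iloc[: min(5, len(ranked))]
    if ranked.iloc[0] < UBIQUITOUS_MAX_SHARE and (top5 > UBIQUITOUS_TOP5_MIN).all():
        return CancerShareProfile(gene_id, shares, "ubiquitous")
    return CancerShareProfile(gene_id, shares, "other")


def classify_cancer_matrix(
    matrix: pd.DataFrame, sample_types: pd.Series, tumor_only: pd.Series | None = None
) -> pd.DataFrame:
    """Label every gene of a cancer expression matrix.

    ``sample_types`` maps sample -> cancer type; ``tumor_only`` optionally
    restricts the per-type means to tumor samples. Genes with zero reads in
    all samples are dropped first (they carry no signal to label).
    """
    cols = matrix.columns
    if tumor_only is not None:
        cols = [c for c in cols if tumor_only.get(c, True)]
    sub = matrix[cols]
    nonzero = sub.sum(axis=1) > 0
    sub = sub.loc[nonzero]
    type_means = sub.T.groupby(sample_types.reindex(cols)).mean().T
    rows = []
    for gene_id, means in type_means.iterrows():
        prof = classify_cancer_specificity(means.rename(gene_id))
        rows.append(
            {
                "gene_id": gene_id,
                "label": prof.label,
                "max_share": prof.shares.max(),
                "zero_expression": prof.zero_expression,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def retain_cancer_types(sample_counts: pd.DataFrame) -> list[str]:
    """Cancer types with more than 5 normal AND more than 5 tumor samples.

    ``sample_counts`` has columns ``normal`` and ``tumor`` indexed by type.
    """
    keep = (sample_counts["normal"] > RETENTION_MIN_SAMPLES) & (
        sample_counts["tumor"] > RETENTION_MIN_SAMPLES
    )
    return list(sample_counts.index[keep])


# ---------------------------------------------------------------------------
# Translated candidates
# ---------------------------------------------------------------------------


@dataclass
class TranslationCall:
    gene_id: str
    predictor_a: bool  # e.g. CPC2-style flag
    predictor_b: bool  # e.g. CPAT-style flag
    ribo_fpkm: float  # max FPKM across ribosome-profiling samples
    orf_count: int
    translated: bool


def call_translated(
    gene_id: str,
    predictor_a: bool,
    predictor_b: bool,
    ribo_fpkm: float,
    orf_count: int,
) -> TranslationCall:
    """Translated iff both coding predictors agree, ribo FPKM >= 1 and >= 1 ORF."""
    if ribo_fpkm < 0 or orf_count < 0:
        raise ValidationError("ribo FPKM and ORF count must be non-negative")
    translated = (
        bool(predictor_a)
        and bool(predictor_b)
        and ribo_fpkm >= RIBO_FPKM_MIN
        and orf_count >= 1
    )
    return TranslationCall(
        gene_id, bool(predictor_a), bool(predictor_b), float(ribo_fpkm),
        int(orf_count), translated,
    )
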