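"""Count normalization and spatiotemporal expression specificity.

Expression is quantified from uniquely mapped read counts (the count matrix is
the input boundary; alignment and counting are upstream). Two normalizations
are supported: FPKM (reads per kilobase of merged exonic length per million
counted reads) and CPM (counts per million). Specificity uses the tau index,

    tau = sum_i (1 - y_i) / (n - 1),   y_i = x_i / max_i(x_i),

over n conditions (tissues, or developmental stages within a tissue), ranging
from 0 for uniform expression to 1 for single-condition expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ValidationError


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one RNA-seq sample."""

    sample_id: str
    tissue: str
    stage: str
    time_days: float  # time after conception; > 0 for developmental samples
    sex: str
    replicate: int
    library_size: int  # total uniquely mapped, assigned reads
    cancer_type: str | None = None

    def __post_init__(self):
        if self.library_size <= 0:
            raise ValidationError(f"{self.sample_id}: library size must be positive")
        if self.time_days is not None and self.time_days <= 0:
            raise ValidationError(f"{self.sample_id}: time after conception must be > 0")


@dataclass
class ExpressionTensor:
    """Raw counts (gene x sample) with sample metadata and gene lengths."""

    gene_ids: list[str]
    samples: list[SampleMeta]
    counts: np.ndarray  # shape (n_genes, n_samples), non-negative ints
    lengths: dict[str, int] | None = None  # merged exonic length per gene, bp

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValidationError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.gene_ids)}, {len(self.samples)})"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.samples]).set_index("sample_id")

    def to_tsv(self, counts_path, meta_path) -> None:
        pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids).to_csv(
            counts_path, sep="\t", index_label="gene_id"
        )
        self.meta_frame().to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, meta_path, lengths=None) -> "ExpressionTensor":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        samples = [
            SampleMeta(
                sample_id=str(sid),
                tissue=row["tissue"],
                stage=str(row["stage"]),
                time_days=float(row["time_days"]),
                sex=row["sex"],
                replicate=int(row["replicate"]),
                library_size=int(row["library_size"]),
                cancer_type=row.get("cancer_type") if "cancer_type" in meta else None,
            )
            for sid, row in meta.iterrows()
        ]
        counts = counts[[s.sample_id for s in samples]]
        return cls(list(counts.index), samples, counts.to_numpy(), lengths)


def normalize(tensor: ExpressionTensor, mode: str = "FPKM") -> pd.DataFrame:
    """FPKM or CPM matrix (gene x sample) from raw counts.

    FPKM_gs = count_gs / (length_g / 1e3) / (libsize_s / 1e6);
    CPM_gs  = count_gs / (libsize_s / 1e6). Library sizes come from the
    sample metadata (counted reads), not from column sums.
    """
    libsizes = np.array([s.library_size for s in tensor.samples], dtype=float)
    if mode.upper() == "CPM":
        mat = tensor.counts / (libsizes / 1e6)
    elif mode.upper() == "FPKM":
        if tensor.lengths is None:
            raise ValidationError("FPKM requires merged exonic lengths")
        lengths = np.array(
            [tensor.lengths[g] for g in tensor.gene_ids], dtype=float
        )
        if (lengths <= 0).any():
            raise ValidationError("non-positive gene length")
        mat = tensor.counts / (lengths[:, None] / 1e3) / (libsizes[None, :] / 1e6)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return pd.DataFrame(mat, index=tensor.gene_ids, columns=tensor.sample_ids)


def tau(values) -> float:
    """Specificity index over conditions; 0 = uniform, 1 = single-condition.

    Returns NaN with a warning for an all-zero vector (undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("tau needs a 1-D vector over >= 2 conditions")
    if (x < 0).any():
        raise ValidationError("tau is defined for non-negative expression values")
    m = x.max()
    if m == 0:
        warnings.warn("tau undefined for all-zero expression vector", stacklevel=2)
        return float("nan")
    y = x / m
    return float((1.0 - y).sum() / (len(x) - 1))


def _condition_means(
    matrix: pd.DataFrame, groups: pd.Series, agg: str = "mean"
) -> pd.DataFrame:
    """Per-gene aggregate over sample groups (columns grouped by label)."""
    if agg not in {"mean", "median"}:
        raise ValueError(f"unknown aggregation {agg!r}")
    return matrix.T.groupby(groups).agg(agg).T


@dataclass
class SpecificityScores:
    """Tissue/stage specificity results for one normalized matrix."""

    tissue_tau: pd.Series  # per gene
    stage_tau: pd.DataFrame  # gene x tissue
    tissue_means: pd.DataFrame  # gene x tissue
    max_tissue: pd.Series = field(default=None)
    max_tissue_tie: pd.Series = field(default=None)


def tissue_and_stage_specificity(
    matrix: pd.DataFrame, samples: list[SampleMeta], agg: str = "mean"
) -> SpecificityScores:
    """Tau across tissues, and across developmental stages within each tissue.

    Tissue tau is computed over per-tissue aggregates of the normalized values
    (stages, sexes and replicates pooled); stage tau over per-stage aggregates
    within one tissue. Genes with no expression get NaN.
    """
    meta = pd.DataFrame(
        {
            "tissue": [s.tissue for s in samples],
            "stage": [s.stage for s in samples],
        },
        index=[s.sample_id for s in samples],
    )
    tissue_means = _condition_means(matrix, meta["tissue"], agg)
    if tissue_means.shape[1] < 2:
        raise ValidationError("tissue tau needs >= 2 tissues")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tissue_tau = tissue_means.apply(lambda row: tau(row.to_numpy()), axis=1)

    stage_cols = {}
    for tissue in tissue_means.columns:
        cols = meta.index[meta["tissue"] == tissue]
        sub = matrix[cols]
        stages = meta.loc[cols, "stage"]
        if stages.nunique() < 2:
            continue
        stage_means = _condition_means(sub, stages, agg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stage_cols[tissue] = stage_means.apply(
                lambda row: tau(row.to_numpy()), axis=1
            )
    stage_tau = pd.DataFrame(stage_cols, index=matrix.index)
    max_tissue, tie = max_expression_tissue(matrix, samples, agg=agg)
    return SpecificityScores(tissue_tau, stage_tau, tissue_means, max_tissue, tie)


def expressed_proportion(
    matrix: pd.DataFrame, cutoffs, biotypes: pd.Series | None = None
) -> pd.DataFrame:
    """Proportion of genes expressed (max over samples >= cutoff) per cutoff.

    With a per-gene ``biotypes`` series the proportions are reported per
    biotype; rows are cutoffs. Proportions are monotone non-increasing in the
    cutoff by construction.
    """
    cutoffs = list(cutoffs)
    if any(c < 0 for c in cutoffs):
        raise ValidationError("cutoffs must be non-negative")
    maxima = matrix.max(axis=1)
    groups = biotypes.reindex(matrix.index) if biotypes is not None else pd.Series(
        "all", index=matrix.index
    )
    rows = {}
    for c in cutoffs:
        expressed = maxima >= c if c > 0 else maxima > 0
        rows[c] = expressed.groupby(groups).mean()
    return pd.DataFrame(rows).T.rename_axis("cutoff")


def max_expression_tissue(
    matrix: pd.DataFrame, samples: list[SampleMeta], agg: str = "mean"
) -> tuple[pd.Series, pd.Series]:
    """Tissue of maximum per-tissue aggregate expression for each expressed gene.

    Ties break lexicographically and are flagged. Unexpressed genes get NaN.
    """
    tissues = pd.Series(
        [s.tissue for s in samples], index=[s.sample_id for s in samples]
    )
    means = _condition_means(matrix, tissues, agg)
    means = means[sorted(means.columns)]
    arr = means.to_numpy()
    best = means.columns[arr.argmax(axis=1)]
    tie = (arr == arr.max(axis=1, keepdims=True)).sum(axis=1) > 1
    expressed = arr.max(axis=1) > 0
    out = pd.Series(best, index=matrix.index, name="max_tissue")
    out[~expressed] = np.nan
    return out, pd.Series(tie & expressed, index=matrix.index, name="max_tissue_tie")
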