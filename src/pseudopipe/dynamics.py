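"""Developmentally dynamic pseudogene (DDP) detection and co-expression.

A pseudogene is developmentally dynamic in a tissue when an ordinary
least-squares fit of its expression on a cubic polynomial in log
time-after-conception explains more than 30% of the variance (R^2 > 0.3,
strict). A gene dynamic in at least one tissue is a DDP. DDPs whose
expression tracks their parent coding gene too closely (Pearson R >= 0.6,
signed) are excluded downstream as potential mis-mapping artefacts.

The co-expression network links pseudogenes to coding genes at |R| > 0.90
and two-sided P < 0.01 (exact t-transform, df = n - 2), with testis samples
excluded because of their globally permissive transcription.

The implementation is the stated computation itself (polynomial-in-log-time
OLS plus the R^2 threshold); it deliberately does not reproduce the stepwise
significance machinery of time-course packages such as maSigPro.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import ValidationError
from .expression import SampleMeta

DDP_R2_THRESHOLD = 0.3  # strict >
PARENT_R_CUTOFF = 0.6  # signed, >= excludes
EDGE_R_CUTOFF = 0.90  # |R| >, strict
EDGE_P_CUTOFF = 0.01  # <, strict


@dataclass
class TrendFit:
    """One gene x tissue polynomial trend fit."""

    gene_id: str
    tissue: str
    degree: int
    coef: np.ndarray  # intercept first, then ln t, (ln t)^2, ...
    r2: float
    n: int


def _design(times: np.ndarray, degree: int) -> np.ndarray:
    logt = np.log(times)
    return np.vander(logt, degree + 1, increasing=True)


def _r2_matrix(Y: np.ndarray, times: np.ndarray, degree: int) -> tuple[np.ndarray, np.ndarray]:
    """R^2 and coefficients for every row of Y against the shared design.

    One QR factorization serves all genes; constant rows get R^2 = 0 by the
    declared convention (zero total sum of squares).
    """
    X = _design(times, degree)
    Q, R = np.linalg.qr(X)
    coefs = np.linalg.solve(R, Q.T @ Y.T).T
    fitted = coefs @ X.T
    resid = Y - fitted
    ss_res = (resid**2).sum(axis=1)
    ss_tot = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    return np.clip(r2, 0.0, 1.0), coefs


def fit_trend(
    values,
    times,
    degree: int = 3,
    gene_id: str = "",
    tissue: str = "",
    response: str = "log1p",
) -> TrendFit:
    """OLS fit of one gene's expression on a degree-3 polynomial in ln(time).

    ``values`` are CPM over the samples of one tissue; replicates enter as
    separate observations at the same time. ``response`` is "log1p"
    (default; log1p-transformed CPM) or "raw".
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValidationError("values and times must be matching 1-D vectors")
    if (t <= 0).any():
        raise ValidationError("times after conception must be positive")
    n_distinct = len(np.unique(t))
    if n_distinct < degree + 1:
        raise ValidationError(
            f"degenerate design for gene {gene_id!r} in tissue {tissue!r}: "
            f"{n_distinct} distinct times < degree+1 = {degree + 1}"
        )
    if len(y) < degree + 2:
        raise ValidationError(
            f"gene {gene_id!r} in tissue {tissue!r}: need >= {degree + 2} samples"
        )
    if response == "log1p":
        y = np.log1p(y)
    elif response != "raw":
        raise ValueError(f"unknown response {response!r}")
    r2, coefs = _r2_matrix(y[None, :], t, degree)
    return TrendFit(gene_id, tissue, degree, coefs[0], float(r2[0]), len(y))


def call_ddps(r2: pd.DataFrame, threshold: float = DDP_R2_THRESHOLD) -> pd.DataFrame:
    """DDP calls from a gene x tissue R^2 table.

    Dynamic in a tissue iff R^2 strictly exceeds the threshold; DDP iff
    dynamic in at least one tissue. NaN R^2 (tissue not fitted) never counts.
    """
    flags = r2.gt(threshold)
    out = flags.add_prefix("dynamic_")
    out["ddp"] = flags.any(axis=1)
    return out


def parent_correlation_filter(
    matrix: pd.DataFrame,
    parent_map: dict[str, str | None],
    cutoff: float = PARENT_R_CUTOFF,
) -> pd.DataFrame:
    """Pearson correlation of each pseudogene with its parent coding gene.

    Correlation is computed across matched samples of ``matrix`` (genes x
    samples, containing both pseudogenes and parents). A pseudogene is
    excluded iff signed R >= cutoff; missing or absent parents leave R as NaN
    and the gene retained.
    """
    rows = []
    for pseudo, parent in parent_map.items():
        r = np.nan
        if parent is not None and parent in matrix.index and pseudo in matrix.index:
            x = matrix.loc[pseudo].to_numpy(dtype=float)
            y = matrix.loc[parent].to_numpy(dtype=float)
            if x.std() > 0 and y.std() > 0:
                r = float(np.corrcoef(x, y)[0, 1])
        rows.append(
            {
                "gene_id": pseudo,
                "parent_gene": parent,
                "parent_r": r,
                "excluded": bool(r >= cutoff) if not np.isnan(r) else False,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value for Pearson R via the exact t-transform, df = n-2."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def coexpression_network(
    matrix: pd.DataFrame,
    samples: list[SampleMeta],
    pseudogene_ids,
    coding_ids,
    r_cut: float = EDGE_R_CUTOFF,
    p_cut: float = EDGE_P_CUTOFF,
    exclude_tissues=("testis",),
) -> tuple[pd.DataFrame, pd.Series, list[tuple[str, str]]]:
    """All-pairs pseudogene x coding-gene co-expression edges.

    Samples from ``exclude_tissues`` are dropped first. Every retained pair is
    scored by Pearson R and its two-sided t-transform p; an edge is kept iff
    |R| > r_cut and p < p_cut. Returns (edges, per-gene connectivity,
    skipped zero-variance genes with reason).
    """
    keep = [s.sample_id for s in samples if s.tissue not in set(exclude_tissues)]
    if len(keep) < 4:
        raise ValidationError(f"need >= 4 retained samples, have {len(keep)}")
    sub = matrix[keep]
    n = len(keep)

    skipped: list[tuple[str, str]] = []

    def usable(ids):
        out = []
        for g in ids:
            if sub.loc[g].std() == 0:
                skipped.append((g, "zero variance across retained samples"))
            else:
                out.append(g)
        return out

    pseudo = usable(list(pseudogene_ids))
    coding = usable(list(coding_ids))
    if not pseudo or not coding:
        return (
            pd.DataFrame(columns=["pseudogene", "coding_gene", "r", "p", "n"]),
            pd.Series(dtype=int),
            skipped,
        )

    def zscore(ids):
        arr = sub.loc[ids].to_numpy(dtype=float)
        arr = arr - arr.mean(axis=1, keepdims=True)
        return arr / np.sqrt((arr**2).sum(axis=1, keepdims=True))

    R = zscore(pseudo) @ zscore(coding).T
    P = pearson_p(R, n)
    pi, ci = np.where((np.abs(R) > r_cut) & (P < p_cut))
    edges = pd.DataFrame(
        {
            "pseudogene": [pseudo[i] for i in pi],
            "coding_gene": [coding[j] for j in ci],
            "r": R[pi, ci],
            "p": P[pi, ci],
            "n": n,
        }
    ).sort_values(["pseudogene", "coding_gene"], ignore_index=True)
    connectivity = (
        pd.concat([edges["pseudogene"], edges["coding_gene"]])
        .value_counts()
        .rename("connectivity")
    )
    return edges, connectivity, skipped


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class DevelopmentalTrendModel:
    """Per-tissue cubic trend fits for every gene in a CPM matrix.

    Parameters
    ----------
    cpm : pandas.DataFrame
        Genes x samples CPM matrix.
    samples : list[SampleMeta]
        Must carry tissue and time-after-conception for every column.
    degree : int
        Polynomial degree in ln(time); 3 by default.
    response : str
        "log1p" (default) fits log1p(CPM); "raw" fits CPM directly.
    """

    def __init__(
        self,
        cpm: pd.DataFrame,
        samples: list[SampleMeta],
        degree: int = 3,
        response: str = "log1p",
    ):
        if response not in {"log1p", "raw"}:
            raise ValueError(f"unknown response {response!r}")
        by_id = {s.sample_id: s for s in samples}
        missing = [c for c in cpm.columns if c not in by_id]
        if missing:
            raise ValidationError(f"samples missing metadata: {missing[:5]}")
        self.cpm = cpm
        self.samples = [by_id[c] for c in cpm.columns]
        self.degree = degree
        self.response = response

    def fit(self) -> "TrendResults":
        tissues = sorted({s.tissue for s in self.samples})
        r2_cols = {}
        coef_store: dict[str, np.ndarray] = {}
        n_used = {}
        for tissue in tissues:
            cols = [s.sample_id for s in self.samples if s.tissue == tissue]
            times = np.array(
                [s.time_days for s in self.samples if s.tissue == tissue], dtype=float
            )
            if len(np.unique(times)) < self.degree + 1 or len(cols) < self.degree + 2:
                raise ValidationError(
                    f"tissue {tissue!r}: insufficient design for degree {self.degree} "
                    f"({len(np.unique(times))} distinct times, {len(cols)} samples)"
                )
            Y = self.cpm[cols].to_numpy(dtype=float)
            if self.response == "log1p":
                Y = np.log1p(Y)
            r2, coefs = _r2_matrix(Y, times, self.degree)
            r2_cols[tissue] = pd.Series(r2, index=self.cpm.index)
            coef_store[tissue] = coefs
            n_used[tissue] = len(cols)
        r2 = pd.DataFrame(r2_cols)
        return TrendResults(self, r2, coef_store, n_used)


class TrendResults:
    """Gene x tissue R^2 table plus DDP calling and filtering helpers."""

    def __init__(self, model, r2: pd.DataFrame, coefs, n_used):
        self.model = model
        self.r2 = r2
        self.coefs = coefs
        self.n_used = n_used
        self._parent_filter: pd.DataFrame | None = None

    def call_ddps(self, threshold: float = DDP_R2_THRESHOLD) -> pd.DataFrame:
        return call_ddps(self.r2, threshold)

    def apply_parent_filter(
        self,
        matrix: pd.DataFrame,
        parent_map: dict[str, str | None],
        cutoff: float = PARENT_R_CUTOFF,
    ) -> pd.DataFrame:
        self._parent_filter = parent_correlation_filter(matrix, parent_map, cutoff)
        return self._parent_filter

    def ddp_table(self, threshold: float = DDP_R2_THRESHOLD) -> pd.DataFrame:
        """Full per-gene report: per-tissue R^2 and flags, DDP flag, parent filter."""
        calls = self.call_ddps(threshold)
        table = self.r2.add_prefix("r2_").join(calls)
        if self._parent_filter is not None:
            table = table.join(self._parent_filter[["parent_r", "excluded"]])
        else:
            table["parent_r"] = np.nan
            table["excluded"] = False
        table["ddp_retained"] = table["ddp"] & ~table["excluded"].fillna(False)
        return table

    def summary(self, threshold: float = DDP_R2_THRESHOLD) -> str:
        calls = self.call_ddps(threshold)
        lines = [
            "Developmental trend fits",
            "=" * 48,
            f"genes                 : {len(self.r2)}",
            f"degree (in ln t)      : {self.model.degree}",
            f"response              : {self.model.response}(CPM)",
            f"R^2 threshold         : > {threshold}",
        ]
        for tissue in self.r2.columns:
            n_dyn = int(calls[f"dynamic_{tissue}"].sum())
            lines.append(
                f"dynamic in {tissue:<11}: {n_dyn} (n={self.n_used[tissue]} samples)"
            )
        n_ddp = int(calls["ddp"].sum())
        lines.append(f"DDPs (>=1 tissue)     : {n_ddp} "
                     f"({100 * n_ddp / len(self.r2):.1f}%)")
        if self._parent_filter is not None:
            n_exc = int((self._parent_filter["excluded"]).sum())
            lines.append(f"parent-R excluded     : {n_exc} (R >= {PARENT_R_CUTOFF})")
        return "\n".join(lines)

    def plot_r2(self, ax=None, bins=40):
        """Histogram of R^2 pooled over tissues with the DDP threshold marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.r2.to_numpy().ravel(), bins=bins)
        ax.axvline(DDP_R2_THRESHOLD, color="red", linestyle="--")
        ax.set_xlabel("R$^2$ (cubic in ln t)")
        ax.set_ylabel("gene x tissue fits")
        return ax
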