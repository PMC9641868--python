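"""Regulatory-feature overlap metrics for region classes.

Compares promoters/gene bodies of coding genes, dynamic pseudogenes,
non-dynamic pseudogenes and shuffled intergenic controls on: transcription
factor diversity (distinct TF names bound), chromHMM state counts (distinct
states with a qualifying >= 2 bp overlap, honouring the literal "more than
1 base pair" rule), GWAS SNP counts and per-kb density, RBP site counts, and
distance from each TSS to the nearest m6A site. Class differences are tested
with the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import FeatureTrack, ValidationError, merge_intervals, total_length

CHROMHMM_MIN_OVERLAP_BP = 2  # "more than 1 base pair"
DEFAULT_MIN_OVERLAP_BP = 1


def _overlap_bp(region: tuple[int, int], site: tuple[int, int]) -> int:
    return max(0, min(region[1], site[1]) - max(region[0], site[0]))


def tf_diversity(
    region: tuple[str, int, int],
    tf_track: FeatureTrack,
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP,
) -> int:
    """Number of distinct TF names with qualifying overlap of the region."""
    chrom, start, end = region
    names = {
        subtype
        for s, e, subtype in tf_track.on(chrom)
        if _overlap_bp((start, end), (s, e)) >= min_overlap_bp
    }
    return len(names)


def distinct_subtype_count(
    region: tuple[str, int, int],
    track: FeatureTrack,
    min_overlap_bp: int,
) -> int:
    """Distinct subtype labels (e.g. chromHMM states) overlapping a region."""
    return tf_diversity(region, track, min_overlap_bp)


def site_count(
    region: tuple[str, int, int],
    track: FeatureTrack,
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP,
) -> int:
    """Number of individual sites with qualifying overlap of the region."""
    chrom, start, end = region
    return sum(
        1
        for s, e, _ in track.on(chrom)
        if _overlap_bp((start, end), (s, e)) >= min_overlap_bp
    )


def snp_density(
    regions: list[tuple[str, int, int]], snps: FeatureTrack
) -> tuple[int, float]:
    """SNP count in a region set and the per-kb rate over merged region length.

    SNPs are single-base features; the rate is
    count / (merged length / 1000).
    """
    for _, s, e, _ in snps.records:
        if e - s != 1:
            raise ValidationError("SNP features must be single-base intervals")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in regions:
        by_chrom.setdefault(chrom, []).append((s, e))
    merged = {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}
    length = sum(total_length(ivs) for ivs in merged.values())
    if length == 0:
        raise ValidationError("zero total region length")
    count = 0
    for chrom, ivs in merged.items():
        positions = [s for s, e, _ in snps.on(chrom)]
        for pos in positions:
            if any(s <= pos < e for s, e in ivs):
                count += 1
    return count, count / (length / 1000.0)


def nearest_site_distance(
    anchors: list[tuple[str, int]], sites: FeatureTrack
) -> np.ndarray:
    """Minimum absolute bp distance from each anchor point to any site.

    Distance is measured to interval edges and is 0 inside a site; anchors on
    chromosomes without sites get NaN.
    """
    out = np.full(len(anchors), np.nan)
    for i, (chrom, pos) in enumerate(anchors):
        ivs = sites.on(chrom)
        if not ivs:
            continue
        best = np.inf
        for s, e, _ in ivs:
            if s <= pos < e:
                best = 0
                break
            best = min(best, abs(pos - s), abs(pos - (e - 1)))
        out[i] = best
    return out


@dataclass
class RegulatoryProfile:
    """Per-region regulatory metrics."""

    region_id: str
    region_class: str  # coding | DDP | non-dynamic | shuffled
    tf_diversity: int
    chromhmm_states: int
    snp_count: int
    snp_per_kb: float
    rbp_count: int
    m6a_distance: float  # bp from the region's anchor (TSS); NaN if no site


def profile_regions(
    regions: pd.DataFrame,
    tf_track: FeatureTrack | None = None,
    chromhmm_track: FeatureTrack | None = None,
    snp_track: FeatureTrack | None = None,
    rbp_track: FeatureTrack | None = None,
    m6a_track: FeatureTrack | None = None,
) -> pd.DataFrame:
    """Regulatory profile for a region table.

    ``regions`` needs columns chrom, start, end, region_class and optionally
    ``anchor`` (TSS position; defaults to the region start) indexed by region
    id. Missing tracks leave their metric as NaN.
    """
    rows = []
    for region_id, r in regions.iterrows():
        region = (r["chrom"], int(r["start"]), int(r["end"]))
        anchor = int(r["anchor"]) if "anchor" in regions.columns and not pd.isna(r.get("anchor")) else region[1]
        length_kb = (region[2] - region[1]) / 1000.0
        snp_n = site_count(region, snp_track) if snp_track is not None else np.nan
        rows.append(
            {
                "region_id": region_id,
                "region_class": r["region_class"],
                "tf_diversity": tf_diversity(region, tf_track)
                if tf_track is not None
                else np.nan,
                "chromhmm_states": distinct_subtype_count(
                    region, chromhmm_track, CHROMHMM_MIN_OVERLAP_BP
                )
                if chromhmm_track is not None
                else np.nan,
                "snp_count": snp_n,
                "snp_per_kb": snp_n / length_kb if snp_track is not None else np.nan,
                "rbp_count": site_count(region, rbp_track)
                if rbp_track is not None
                else np.nan,
                "m6a_distance": nearest_site_distance(
                    [(region[0], anchor)], m6a_track
                )[0]
                if m6a_track is not None
                else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("region_id")


EXACT_MAX_N = 20  # per group; above this use the tie-corrected normal approximation


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small untied samples (both n <= 20), tie-corrected
    normal approximation otherwise; all-tied data returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("rank-sum test needs >= 2 observations per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def class_comparison(
    profiles: pd.DataFrame,
    pairs=(("DDP", "non-dynamic"), ("DDP", "shuffled")),
    metrics=("tf_diversity", "chromhmm_states", "snp_per_kb", "rbp_count", "m6a_distance"),
) -> pd.DataFrame:
    """Per-class medians and pairwise rank-sum p-values for each metric.

    One row per (metric, class_a, class_b) with group medians and the
    two-sided Wilcoxon rank-sum p-value.
    """
    classes = profiles["region_class"].unique()
    rows = []
    for metric in metrics:
        if metric not in profiles.columns or profiles[metric].isna().all():
            continue
        for a, b in pairs:
            if a not in classes or b not in classes:
                continue
            xa = profiles.loc[profiles["region_class"] == a, metric].dropna()
            xb = profiles.loc[profiles["region_class"] == b, metric].dropna()
            if len(xa) < 2 or len(xb) < 2:
                continue
            rows.append(
                {
                    "metric": metric,
                    "class_a": a,
                    "class_b": b,
                    "median_a": float(np.median(xa)),
                    "median_b": float(np.median(xb)),
                    "p_value": rank_sum_test(xa, xb),
                    "n_a": len(xa),
                    "n_b": len(xb),
                }
            )
    return pd.DataFrame(rows)
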