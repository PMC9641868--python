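"""Core genomic data model and interval algebra.

All coordinates are 0-based half-open ``[start, end)`` on the forward strand,
the BED convention. GFF3 input/output is converted at the I/O boundary
(:mod:`pseudopipe.annotation_io`).

The types here — :class:`GenomeLayout`, :class:`GeneRecord`,
:class:`AnnotationSet`, :class:`FeatureTrack` — are shared by every analysis
stage: origin dating consumes exon intervals, the regulatory metrics consume
promoters and feature tracks, and the intergenic shuffler consumes gene spans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

PSEUDOGENE_BIOTYPES = frozenset(
    {
        "processed_pseudogene",
        "unprocessed_pseudogene",
        "unitary_pseudogene",
        "polymorphic_pseudogene",
    }
)
KNOWN_BIOTYPES = PSEUDOGENE_BIOTYPES | {"protein_coding", "lncRNA"}


class ValidationError(ValueError):
    """Raised when a record violates a structural invariant."""


def merge_intervals(intervals):
    """Merge overlapping/adjacent half-open intervals into a sorted disjoint list.

    Parameters
    ----------
    intervals : iterable of (int, int)

    Returns
    -------
    list of (int, int)
        Sorted, pairwise-disjoint, non-adjacent intervals covering the same bases.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValidationError(f"empty or inverted interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def total_length(intervals) -> int:
    """Total number of bases covered by the union of the intervals."""
    return sum(e - s for s, e in merge_intervals(intervals)) if intervals else 0


def intersect_length(a, b) -> int:
    """Bases shared between two interval sets (union of a ∩ union of b)."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    i = j = covered = 0
    while i < len(ma) and j < len(mb):
        s = max(ma[i][0], mb[j][0])
        e = min(ma[i][1], mb[j][1])
        if s < e:
            covered += e - s
        if ma[i][1] <= mb[j][1]:
            i += 1
        else:
            j += 1
    return covered


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names, lengths (bp) and sex-chromosome flags."""

    lengths: dict[str, int]
    sex_chromosomes: frozenset[str] = frozenset({"chrX", "chrY"})

    def __post_init__(self):
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def autosomes(self) -> list[str]:
        return [c for c in self.lengths if c not in self.sex_chromosomes]

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.lengths:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= self.lengths[chrom]):
            raise ValidationError(
                f"interval [{start}, {end}) outside {chrom} (length {self.lengths[chrom]})"
            )


@dataclass
class GeneRecord:
    """A gene or pseudogene with its merged exon structure.

    Exons are stored merged and sorted; ``parent_gene`` links a pseudogene to
    the protein-coding gene it derives from and must be absent for coding genes.
    """

    gene_id: str
    biotype: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    parent_gene: str | None = None

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.biotype not in KNOWN_BIOTYPES:
            raise ValidationError(f"{self.gene_id}: unknown biotype {self.biotype!r}")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: no exons")
        if self.biotype == "protein_coding" and self.parent_gene is not None:
            raise ValidationError(f"{self.gene_id}: coding gene cannot have a parent")
        self.exons = merge_intervals(self.exons)

    @property
    def is_pseudogene(self) -> bool:
        return self.biotype in PSEUDOGENE_BIOTYPES

    @property
    def span(self) -> tuple[int, int]:
        """Full gene body span (first exon start to last exon end)."""
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class AnnotationSet:
    """A genome layout plus its gene records, indexed by gene id."""

    layout: GenomeLayout
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes}")
        for g in self.genes:
            for s, e in g.exons:
                self.layout.check_interval(g.chrom, s, e)
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def pseudogenes(self) -> list[GeneRecord]:
        return [g for g in self.genes if g.is_pseudogene]

    def coding_genes(self) -> list[GeneRecord]:
        return [g for g in self.genes if g.biotype == "protein_coding"]

    def unresolved_parents(self) -> list[str]:
        """Pseudogenes whose parent id does not resolve to a coding gene."""
        out = []
        for g in self.pseudogenes():
            if g.parent_gene is not None:
                parent = self._by_id.get(g.parent_gene)
                if parent is None or parent.biotype != "protein_coding":
                    out.append(g.gene_id)
        return out


@dataclass
class FeatureTrack:
    """A class of genomic features (TF sites, SNPs, m6A peaks, repeats, ...).

    ``records`` are ``(chrom, start, end, subtype)`` with the usual half-open
    convention; ``subtype`` carries the TF name or chromHMM state where the
    feature class requires one.
    """

    feature_class: str
    records: list[tuple[str, int, int, str]] = field(default_factory=list)

    _REQUIRE_SUBTYPE = {"TF", "chromHMM-state"}

    def __post_init__(self):
        for chrom, s, e, subtype in self.records:
            if e <= s:
                raise ValidationError(f"empty feature interval [{s}, {e}) on {chrom}")
            if self.feature_class in self._REQUIRE_SUBTYPE and not subtype:
                raise ValidationError(
                    f"{self.feature_class} feature on {chrom} lacks a subtype label"
                )
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, s, e, subtype in self.records:
            by_chrom.setdefault(chrom, []).append((int(s), int(e), subtype))
        for ivs in by_chrom.values():
            ivs.sort()
        self._by_chrom = by_chrom

    def __len__(self) -> int:
        return len(self.records)

    def on(self, chrom: str) -> list[tuple[int, int, str]]:
        """Sorted features on one chromosome as (start, end, subtype)."""
        return self._by_chrom.get(chrom, [])

    def intervals_on(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for s, e, _ in self.on(chrom)]

    def validate_against(self, layout: GenomeLayout) -> None:
        for chrom, s, e, _ in self.records:
            layout.check_interval(chrom, s, e)


# ---------------------------------------------------------------------------
# Gene-level coordinate derivations
# ---------------------------------------------------------------------------


def merged_exonic_length(gene: GeneRecord) -> int:
    """Non-redundant exonic length: total bp in the union of the exons."""
    return total_length(gene.exons)


def derive_tss(gene: GeneRecord, mode: str = "stranded") -> int:
    """Transcription start site of a gene.

    mode="stranded" (default) takes the 5'-most coordinate in transcript
    orientation: the smallest exon start on +, the largest exon end on -.
    mode="naive_start" always takes the smallest exon start, the literal
    "starting coordinate of the first exon" reading.
    """
    if mode == "stranded":
        return gene.exons[0][0] if gene.strand == "+" else gene.exons[-1][1]
    if mode == "naive_start":
        return gene.exons[0][0]
    raise ValueError(f"unknown tss mode {mode!r}")


def derive_promoter(
    gene: GeneRecord,
    layout: GenomeLayout,
    upstream: int = 2000,
    downstream: int = 1000,
    tss_mode: str = "stranded",
) -> tuple[int, int]:
    """Promoter window around the TSS, 2 kb upstream to 1 kb downstream.

    Oriented by strand and clipped to chromosome bounds; always contains
    the TSS.
    """
    tss = derive_tss(gene, mode=tss_mode)
    if gene.strand == "+" or tss_mode == "naive_start":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream, tss + upstream
    chrom_len = layout.lengths[gene.chrom]
    return max(0, start), min(chrom_len, end)


# ---------------------------------------------------------------------------
# Overlap machinery
# ---------------------------------------------------------------------------


@dataclass
class OverlapResult:
    """Per-query-interval coverage by a subject interval set."""

    covered_bp: np.ndarray  # int, per query interval
    fraction: np.ndarray  # float in [0, 1]
    flag: np.ndarray  # bool, covered_bp >= min_overlap_bp


def overlap_fraction(
    queries: list[tuple[int, int]],
    subjects: list[tuple[int, int]],
    min_overlap_bp: int = 1,
) -> OverlapResult:
    """Coverage of each query interval by the union of the subject intervals.

    The flag marks queries with at least ``min_overlap_bp`` covered bases
    (default 1; the chromHMM-state annotation rule uses 2, honouring the
    literal "more than 1 base pair").
    """
    merged = merge_intervals(subjects) if subjects else []
    covered = np.zeros(len(queries), dtype=int)
    for i, (qs, qe) in enumerate(queries):
        if qe <= qs:
            raise ValidationError(f"empty query interval [{qs}, {qe})")
        covered[i] = intersect_length([(qs, qe)], merged) if merged else 0
    lengths = np.array([qe - qs for qs, qe in queries], dtype=int)
    fraction = covered / lengths if len(queries) else np.zeros(0)
    return OverlapResult(covered, fraction, covered >= min_overlap_bp)


def shuffle_intergenic(
    layout: GenomeLayout,
    annotations: AnnotationSet,
    length: int = 3000,
    n: int = 1,
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, int, int]]:
    """Draw ``n`` non-overlapping intergenic windows of exactly ``length`` bp.

    Windows never overlap any annotated gene body (full exon-to-exon span) and
    are pairwise disjoint; the draw is reproducible under ``seed``. Raises if
    the intergenic space cannot host the request.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gaps: list[tuple[str, int, int]] = []
    spans_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.lengths}
    for g in annotations.genes:
        spans_by_chrom[g.chrom].append(g.span)
    for chrom, chrom_len in layout.lengths.items():
        merged = merge_intervals(spans_by_chrom[chrom]) if spans_by_chrom[chrom] else []
        pos = 0
        for s, e in merged:
            if s - pos >= length:
                gaps.append((chrom, pos, s))
            pos = max(pos, e)
        if chrom_len - pos >= length:
            gaps.append((chrom, pos, chrom_len))

    capacity = sum((ge - gs) // length for _, gs, ge in gaps)
    if capacity < n:
        raise ValidationError(
            f"intergenic space hosts at most {capacity} windows of {length} bp; "
            f"{n} requested"
        )

    chosen: list[tuple[str, int, int]] = []
    taken: dict[str, list[tuple[int, int]]] = {}
    weights = np.array([ge - gs - length + 1 for _, gs, ge in gaps], dtype=float)
    attempts = 0
    max_attempts = 1000 * n
    while len(chosen) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValidationError(
                f"placed only {len(chosen)}/{n} windows after {max_attempts} draws; "
                "intergenic space too fragmented"
            )
        gi = rng.choice(len(gaps), p=weights / weights.sum())
        chrom, gs, ge = gaps[gi]
        start = int(rng.integers(gs, ge - length + 1))
        window = (start, start + length)
        if any(ws < window[1] and window[0] < we for ws, we in taken.get(chrom, [])):
            continue
        taken.setdefault(chrom, []).append(window)
        chosen.append((chrom, window[0], window[1]))
    return chosen
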