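"""Synteny-based pseudogene origin dating.

A pseudogene is dated by where its sequence still exists in related genomes:
if reciprocal-best whole-genome-alignment blocks cover its exons in an
outgroup, the locus predates the split with that outgroup. Presence/absence
across a ladder of successively older outgroups is resolved under Dollo
parsimony — a pseudogene arises once and may be lost repeatedly — so the
origin branch is the internode immediately older than the most distant
species showing presence, taken over the gene's most ancient exon. The age
reported for a gene is the midpoint (myr) of its origin branch.

Before dating, Y-linked pseudogenes are removed (the Y is saturated with
transposable elements) and so are pseudogenes with more than 70% of their
merged exonic bases covered by repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (
    AnnotationSet,
    FeatureTrack,
    GeneRecord,
    ValidationError,
    intersect_length,
    merge_intervals,
    merged_exonic_length,
)

REPEAT_COVER_MAX = 0.70  # strict >: a gene at exactly 0.70 is retained


@dataclass(frozen=True)
class Branch:
    """A phylogenetic internode with divergence-time bounds (myr).

    ``t_old > t_young >= 0``; a gene originating on this branch arose in the
    half-open age window ``(t_old, t_young]`` and is reported at the midpoint.
    """

    name: str
    t_old: float
    t_young: float

    def __post_init__(self):
        if not self.t_old > self.t_young >= 0:
            raise ValidationError(
                f"branch {self.name}: need t_old > t_young >= 0, "
                f"got ({self.t_old}, {self.t_young})"
            )

    @property
    def midpoint(self) -> float:
        return (self.t_old + self.t_young) / 2.0


class BranchTable:
    """Ladder phylogeny of the focal species: outgroups ordered by divergence time.

    Parameters
    ----------
    divergence_times : dict[str, float]
        Species -> divergence time from the focal species (myr). Times must be
        distinct and positive; the tree must be a ladder (each outgroup joins
        the backbone at its own depth), which is the only shape this table can
        represent — anything else must be rejected upstream.
    root_cap : float, optional
        Older bound for the open-ended oldest branch. Defaults to 1.5x the
        oldest divergence time so that a midpoint age exists for it.
    """

    def __init__(self, divergence_times: dict[str, float], root_cap: float | None = None):
        if not divergence_times:
            raise ValidationError("empty divergence-time table")
        times = list(divergence_times.values())
        if any(t <= 0 for t in times):
            raise ValidationError("divergence times must be positive")
        if len(set(times)) != len(times):
            raise ValidationError(
                "duplicate divergence times: a ladder phylogeny needs distinct "
                "depths per outgroup (non-ladder trees are not representable)"
            )
        self.species_times = dict(
            sorted(divergence_times.items(), key=lambda kv: kv[1])
        )
        sorted_times = list(self.species_times.values())
        if root_cap is None:
            root_cap = 1.5 * sorted_times[-1]
        if root_cap <= sorted_times[-1]:
            raise ValidationError("root cap must exceed the oldest divergence time")
        self.root_cap = float(root_cap)
        bounds = [0.0] + sorted_times + [self.root_cap]
        self.branches: list[Branch] = [
            Branch(name=f"b{i}", t_old=bounds[i + 1], t_young=bounds[i])
            for i in range(len(bounds) - 1)
        ]
        self._by_young = {b.t_young: b for b in self.branches}

    @property
    def species(self) -> list[str]:
        return list(self.species_times)

    def __len__(self) -> int:
        return len(self.branches)

    def youngest(self) -> Branch:
        return self.branches[0]

    def branch_for_presence_depth(self, t_star: float | None) -> Branch:
        """Branch whose younger bound equals the deepest presence time.

        ``t_star`` is the divergence time of the most distant species with
        ortholog presence, or None when no species shows presence (the gene is
        then focal-lineage-specific and dates to the youngest branch).
        """
        if t_star is None:
            return self.youngest()
        branch = self._by_young.get(t_star)
        if branch is None:
            raise ValidationError(f"no branch with younger bound {t_star}")
        return branch

    @classmethod
    def from_tsv(cls, path, root_cap: float | None = None) -> "BranchTable":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["species", "divergence_myr"])
        return cls(dict(zip(df["species"], df["divergence_myr"].astype(float))), root_cap)


@dataclass
class OrthologyMap:
    """Reciprocal-best alignment blocks between the focal genome and one species."""

    species: str
    # (focal_chrom, focal_start, focal_end, target_chrom, target_start,
    #  target_end, strand, reciprocal_best)
    blocks: list[tuple] = field(default_factory=list)

    def __post_init__(self):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for b in self.blocks:
            if len(b) != 8:
                raise ValidationError(f"orthology block needs 8 fields, got {len(b)}")
            if b[7]:
                by_chrom.setdefault(b[0], []).append((int(b[1]), int(b[2])))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, _e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValidationError(
                        f"{self.species}: reciprocal-best blocks overlap on {chrom} "
                        f"near {s2}"
                    )
        self._best_by_chrom = by_chrom

    def best_blocks_on(self, chrom: str) -> list[tuple[int, int]]:
        """Sorted reciprocal-best focal intervals on one chromosome."""
        return self._best_by_chrom.get(chrom, [])

    @classmethod
    def from_tsv(cls, path, species: str) -> "OrthologyMap":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["focal_chrom", "focal_start", "focal_end", "target_chrom",
                   "target_start", "target_end", "strand", "reciprocal_best"],
        )
        blocks = [
            (r.focal_chrom, int(r.focal_start), int(r.focal_end), r.target_chrom,
             int(r.target_start), int(r.target_end), r.strand,
             bool(int(r.reciprocal_best)))
            for r in df.itertuples()
        ]
        return cls(species, blocks)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for b in self.blocks:
                fh.write(
                    f"{b[0]}\t{b[1]}\t{b[2]}\t{b[3]}\t{b[4]}\t{b[5]}\t{b[6]}\t{int(b[7])}\n"
                )


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def exon_presence(
    exon: tuple[int, int], chrom: str, omap: OrthologyMap, min_cov: float = 0.5
) -> tuple[bool, float]:
    """Ortholog presence of one exon in one species.

    Present iff reciprocal-best blocks cover at least ``min_cov`` of the exon
    length; non-reciprocal blocks never contribute.
    """
    if not 0 < min_cov <= 1:
        raise ValidationError(f"min_cov must be in (0, 1], got {min_cov}")
    blocks = omap.best_blocks_on(chrom)
    length = exon[1] - exon[0]
    covered = intersect_length([exon], blocks) if blocks else 0
    fraction = covered / length
    return fraction >= min_cov, fraction


def assign_origin_branch(presence: dict[str, bool], branches: BranchTable) -> Branch:
    """Dollo-parsimony origin branch for one exon's per-species presence calls.

    The origin immediately predates the most distant split showing presence;
    absence in younger species is treated as loss or alignment failure, never
    as evidence of independent gain. No presence anywhere dates the exon to
    the youngest (focal-lineage-specific) branch.
    """
    unknown = set(presence) - set(branches.species)
    if unknown:
        raise ValidationError(f"species not in branch table: {sorted(unknown)}")
    present_times = [branches.species_times[sp] for sp, p in presence.items() if p]
    t_star = max(present_times) if present_times else None
    return branches.branch_for_presence_depth(t_star)


def date_pseudogene(exon_branches: list[Branch], branches: BranchTable) -> Branch:
    """Gene origin branch = most ancient exon branch (largest older bound)."""
    if not exon_branches:
        raise ValidationError("no exon branch assignments")
    return max(exon_branches, key=lambda b: b.t_old)


def filter_for_dating(
    annotations: AnnotationSet, repeats: FeatureTrack | None = None
) -> pd.DataFrame:
    """Partition pseudogenes into dating-eligible and excluded sets.

    Exclusions: Y-linked pseudogenes (``excluded_chrY``) and pseudogenes with
    strictly more than 70% of merged exonic bases covered by repeats
    (``excluded_repeat``). Returns one row per pseudogene with columns
    ``status`` and ``repeat_fraction``.
    """
    y_chroms = {
        c for c in annotations.layout.sex_chromosomes if c.removeprefix("chr") == "Y"
    }
    rows = []
    for g in annotations.pseudogenes():
        if g.chrom in y_chroms:
            status, frac = "excluded_chrY", np.nan
        else:
            if repeats is not None:
                cov = intersect_length(g.exons, repeats.intervals_on(g.chrom))
                frac = cov / merged_exonic_length(g)
            else:
                frac = 0.0
            status = "excluded_repeat" if frac > REPEAT_COVER_MAX else "retained"
        rows.append({"gene_id": g.gene_id, "status": status, "repeat_fraction": frac})
    df = pd.DataFrame(rows, columns=["gene_id", "status", "repeat_fraction"])
    return df.set_index("gene_id")


def age_distribution(
    assignments: pd.DataFrame, annotations: AnnotationSet
) -> tuple[pd.Series, pd.DataFrame]:
    """Branch counts and per-branch chromosome-class proportions.

    Returns ``(counts, proportions)``: counts is dated genes per branch;
    proportions is branch x {autosome, X, ...} with rows summing to 1.
    """
    dated = assignments[assignments["status"] == "dated"]
    if dated.empty:
        raise ValidationError("no dated pseudogenes")
    counts = dated["branch"].value_counts().sort_index()
    sex = annotations.layout.sex_chromosomes

    def chrom_class(gene_id):
        chrom = annotations[gene_id].chrom
        return chrom.removeprefix("chr") if chrom in sex else "autosome"

    classes = pd.Series({gid: chrom_class(gid) for gid in dated.index}, name="class")
    table = pd.crosstab(dated["branch"], classes)
    proportions = table.div(table.sum(axis=1), axis=0)
    return counts, proportions


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class DatingModel:
    """Dates every pseudogene in an annotation set from orthology evidence.

    Parameters
    ----------
    annotations : AnnotationSet
    orthology_maps : list[OrthologyMap]
        One map per outgroup species; every map species must appear in the
        branch table.
    branch_table : BranchTable
    repeats : FeatureTrack, optional
        Repeat annotation used by the >70% exonic-coverage filter.
    min_cov : float
        Minimum reciprocal-best coverage of an exon to call presence (0.5).
    exclude_unmappable : bool
        If True, genes with zero aligned bases in every species are excluded
        (status ``excluded_unmappable``) instead of dated to the youngest
        branch. Off by default: under Dollo parsimony universal absence is a
        legitimate focal-lineage-specific call.
    """

    def __init__(
        self,
        annotations: AnnotationSet,
        orthology_maps: list[OrthologyMap],
        branch_table: BranchTable,
        repeats: FeatureTrack | None = None,
        min_cov: float = 0.5,
        exclude_unmappable: bool = False,
    ):
        species = {m.species for m in orthology_maps}
        missing = species - set(branch_table.species)
        if missing:
            raise ValidationError(f"orthology species missing from branch table: {missing}")
        self.annotations = annotations
        self.orthology_maps = orthology_maps
        self.branch_table = branch_table
        self.repeats = repeats
        self.min_cov = min_cov
        self.exclude_unmappable = exclude_unmappable

    def fit(self) -> "DatingResults":
        filt = filter_for_dating(self.annotations, self.repeats)
        presence_rows = []
        rows = []
        for gene_id, frow in filt.iterrows():
            gene = self.annotations[gene_id]
            if frow["status"] != "retained":
                rows.append(self._row(gene_id, None, frow["status"], []))
                continue
            exon_branches = []
            any_coverage = False
            for ei, exon in enumerate(gene.exons):
                presence = {}
                for omap in self.orthology_maps:
                    present, fraction = exon_presence(
                        exon, gene.chrom, omap, self.min_cov
                    )
                    presence[omap.species] = present
                    any_coverage = any_coverage or fraction > 0
                    presence_rows.append(
                        {
                            "gene_id": gene_id,
                            "exon_index": ei,
                            "species": omap.species,
                            "present": present,
                            "fraction": fraction,
                        }
                    )
                exon_branches.append(assign_origin_branch(presence, self.branch_table))
            if self.exclude_unmappable and not any_coverage:
                rows.append(self._row(gene_id, None, "excluded_unmappable", []))
                continue
            branch = date_pseudogene(exon_branches, self.branch_table)
            rows.append(self._row(gene_id, branch, "dated", exon_branches))
        assignments = pd.DataFrame(
            rows,
            columns=["gene_id", "branch", "t_old", "t_young", "age_myr", "status",
                     "exon_branches"],
        ).set_index("gene_id")
        presence = pd.DataFrame(
            presence_rows,
            columns=["gene_id", "exon_index", "species", "present", "fraction"],
        )
        return DatingResults(self, assignments, presence, filt)

    @staticmethod
    def _row(gene_id, branch, status, exon_branches):
        return {
            "gene_id": gene_id,
            "branch": branch.name if branch else None,
            "t_old": branch.t_old if branch else np.nan,
            "t_young": branch.t_young if branch else np.nan,
            "age_myr": branch.midpoint if branch else np.nan,
            "status": status,
            "exon_branches": ",".join(b.name for b in exon_branches),
        }


class DatingResults:
    """Per-pseudogene origin branches and ages, with filter provenance.

    Attributes
    ----------
    assignments : pandas.DataFrame
        Indexed by gene id: branch name, branch bounds, midpoint age (myr),
        filter status and per-exon branch names.
    presence : pandas.DataFrame
        Long-format per-gene/per-exon/per-species presence calls with covered
        fractions.
    """

    def __init__(self, model: DatingModel, assignments, presence, filter_report):
        self.model = model
        self.assignments = assignments
        self.presence = presence
        self.filter_report = filter_report

    @property
    def dated(self) -> pd.DataFrame:
        return self.assignments[self.assignments["status"] == "dated"]

    @property
    def retained_fraction(self) -> float:
        n = len(self.assignments)
        return len(self.dated) / n if n else np.nan

    def age_distribution(self) -> tuple[pd.Series, pd.DataFrame]:
        return age_distribution(self.assignments, self.model.annotations)

    def to_tsv(self, path) -> None:
        self.assignments.to_csv(path, sep="\t")

    def summary(self) -> str:
        counts = self.assignments["status"].value_counts()
        lines = [
            "Pseudogene origin dating",
            "=" * 48,
            f"pseudogenes considered : {len(self.assignments)}",
            f"dated                  : {counts.get('dated', 0)} "
            f"({100 * self.retained_fraction:.1f}%)",
        ]
        for status in ("excluded_chrY", "excluded_repeat", "excluded_unmappable"):
            if counts.get(status, 0):
                lines.append(f"{status:<23}: {counts[status]}")
        if counts.get("dated", 0):
            branch_counts, _ = self.age_distribution()
            lines.append("-" * 48)
            lines.append("branch (t_old..t_young myr)   age   n")
            for b in self.model.branch_table.branches:
                n = branch_counts.get(b.name, 0)
                lines.append(
                    f"{b.name:<6}({b.t_old:7.1f}..{b.t_young:6.1f})  {b.midpoint:7.1f}  {n}"
                )
        return "\n".join(lines)

    def plot_age_distribution(self, ax=None):
        """Bar plot of dated pseudogene counts per branch midpoint age."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        branch_counts, _ = self.age_distribution()
        branches = self.model.branch_table.branches
        ages = [b.midpoint for b in branches]
        ns = [branch_counts.get(b.name, 0) for b in branches]
        ax.bar(range(len(branches)), ns, tick_label=[f"{a:.0f}" for a in ages])
        ax.set_xlabel("branch midpoint age (myr)")
        ax.set_ylabel("pseudogenes")
        return ax
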