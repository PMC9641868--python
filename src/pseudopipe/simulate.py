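"""Synthetic scenario generator with recorded ground truth.

Emulates every input the pipeline consumes so each stage can be tested
against known truth without any external download:

* a dated ladder phylogeny and per-species reciprocal-best alignment blocks
  consistent with each pseudogene's planted origin branch (dropout removes
  evidence, never adds it);
* a developmental expression tensor — negative-binomial counts over tissues,
  stages, sexes and replicates, with planted cubic-in-log-time trends,
  planted tissue-specific genes and a testis-enhanced subset;
* feature tracks (TF sites, single-base SNPs, m6A peaks, a chromHMM tiling)
  with planted enrichment at dynamic-pseudogene promoters;
* a multi-type cancer count matrix with planted type-specific and
  ubiquitous genes.

Everything is drawn from one seeded generator, so a scenario is byte-for-byte
reproducible, and the default scenario is deliberately small (500 pseudogenes,
200 coding genes, 5 tissues x 8 stages x 2 sexes x 2 replicates) so the whole
pipeline runs end-to-end in minutes on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation_io import write_feature_track, write_gff3
from .dating import BranchTable, OrthologyMap
from .dynamics import _r2_matrix
from .expression import ExpressionTensor, SampleMeta
from .genome import (
    AnnotationSet,
    FeatureTrack,
    GeneRecord,
    GenomeLayout,
    ValidationError,
    derive_promoter,
    derive_tss,
    merged_exonic_length,
)

# human outgroup ladder with TimeTree-style divergence times (myr)
DEFAULT_LADDER = {
    "chimpanzee": 6.7,
    "macaque": 29.4,
    "mouse": 90.0,
    "opossum": 160.0,
    "platypus": 180.0,
    "chicken": 319.0,
    "frog": 352.0,
    "zebrafish": 435.0,
}

DEFAULT_STAGE_TIMES = {
    "e10.5": 10.5,
    "e12.5": 12.5,
    "e14.5": 14.5,
    "e17.5": 17.5,
    "P1": 21.0,
    "P5": 25.0,
    "P15": 35.0,
    "P70": 90.0,
}

DEFAULT_TISSUES = ["brain", "cerebellum", "heart", "liver", "testis"]


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic scenario; defaults are the study conditions."""

    seed: int = 0
    # phylogeny
    ladder: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LADDER))
    root_cap_factor: float = 1.5
    # genome
    n_autosomes: int = 4
    autosome_length: int = 1_500_000
    x_length: int = 1_000_000
    y_length: int = 300_000
    # genes
    n_pseudogenes: int = 500
    n_coding: int = 200
    branch_weights: tuple = (0.25, 0.15, 0.12, 0.12, 0.08, 0.08, 0.08, 0.06, 0.06)
    biotype_weights: dict[str, float] = field(
        default_factory=lambda: {
            "processed_pseudogene": 0.70,
            "unprocessed_pseudogene": 0.25,
            "unitary_pseudogene": 0.04,
            "polymorphic_pseudogene": 0.01,
        }
    )
    fraction_chrY: float = 0.04
    fraction_repeat_excluded: float = 0.05
    fraction_with_parent: float = 0.9
    dropout: float = 0.0  # per (exon, species) presence dropout
    coverage_low: float = 0.8  # planted block coverage of an exon, uniform low..1
    decoy_rate: float = 0.1  # non-reciprocal decoy blocks in absent species
    # expression
    tissues: list[str] = field(default_factory=lambda: list(DEFAULT_TISSUES))
    stage_times: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_TIMES)
    )
    replicates: int = 2
    sexes: tuple = ("F", "M")
    nb_dispersion: float = 0.1
    base_log_mean: float = np.log(30.0)
    base_log_sd: float = 1.0
    fraction_dynamic: float = 0.2
    trend_amplitude: float = 1.0  # SD of the planted log-mean across stages
    dynamic_min_base: float = 20.0  # counts; trends are planted on expressed genes
    fraction_tissue_specific: float = 0.2
    testis_factor: float = 5.0
    testis_fraction: float = 0.25
    # counted reads outside the simulated gene set (bulk transcriptome);
    # keeps library size nearly independent of any one gene's trajectory
    library_background_reads: int = 300_000
    # feature tracks
    tf_subtypes: int = 20
    tf_background_sites: int = 5000
    tf_promoter_enrichment: float = 2.0  # at dynamic-pseudogene promoters
    snp_per_bp: float = 5e-4
    snp_promoter_enrichment: float = 2.5
    m6a_background_sites: int = 1500
    m6a_site_length: int = 50
    chromhmm_states: int = 15
    chromhmm_segment: int = 5000
    # cancer
    n_cancer_types: int = 33
    n_cancer_genes: int = 200
    n_type_specific: int = 30
    n_ubiquitous: int = 30
    cancer_noise_sd: float = 0.0  # lognormal sd; 0 = deterministic means
    tumor_samples_low: int = 6
    tumor_samples_high: int = 12
    normal_samples_low: int = 2
    normal_samples_high: int = 10

    def validate(self) -> None:
        fracs = {
            "fraction_chrY": self.fraction_chrY,
            "fraction_repeat_excluded": self.fraction_repeat_excluded,
            "fraction_with_parent": self.fraction_with_parent,
            "dropout": self.dropout,
            "fraction_dynamic": self.fraction_dynamic,
            "fraction_tissue_specific": self.fraction_tissue_specific,
            "testis_fraction": self.testis_fraction,
            "decoy_rate": self.decoy_rate,
        }
        for name, v in fracs.items():
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.fraction_dynamic + self.fraction_tissue_specific > 1:
            raise ValidationError("dynamic + tissue-specific fractions exceed 1")
        if any(t <= 0 for t in self.stage_times.values()):
            raise ValidationError("stage times must be positive")
        if abs(sum(self.branch_weights) - 1) > 1e-9:
            raise ValidationError("branch weights must sum to 1")
        n_branches = len(self.ladder) + 1
        if len(self.branch_weights) != n_branches:
            raise ValidationError(
                f"need {n_branches} branch weights, got {len(self.branch_weights)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class TruthSet:
    """Planted ground truth for every generated entity."""

    pseudogenes: pd.DataFrame  # branch, age, dynamics, specificity, filters
    cancer: pd.DataFrame  # planted label per cancer gene
    track_params: dict  # planted enrichment parameters


@dataclass
class Scenario:
    config: ScenarioConfig
    layout: GenomeLayout
    annotations: AnnotationSet
    repeats: FeatureTrack
    branch_table: BranchTable
    orthology_maps: list[OrthologyMap]
    tensor: ExpressionTensor
    tf_track: FeatureTrack
    snp_track: FeatureTrack
    m6a_track: FeatureTrack
    chromhmm_track: FeatureTrack
    cancer_counts: pd.DataFrame
    cancer_meta: pd.DataFrame  # sample -> (cancer_type, tumor)
    truth: TruthSet

    def write(self, outdir) -> dict:
        """Write every input file plus the truth tables; returns the manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "orthology").mkdir(exist_ok=True)
        manifest = {}

        with open(out / "genome.chrom.sizes", "w") as fh:
            for name, length in self.layout.lengths.items():
                fh.write(f"{name}\t{length}\n")
        manifest["chrom_sizes"] = "genome.chrom.sizes"

        write_gff3(self.annotations, out / "annotation.gff3")
        manifest["annotation"] = "annotation.gff3"
        write_feature_track(self.repeats, out / "repeats.bed")
        manifest["repeats"] = "repeats.bed"

        with open(out / "divergence_times.tsv", "w") as fh:
            for sp, t in self.branch_table.species_times.items():
                fh.write(f"{sp}\t{t}\n")
        manifest["divergence_times"] = "divergence_times.tsv"

        for omap in self.orthology_maps:
            rel = f"orthology/{omap.species}.tsv"
            omap.to_tsv(out / rel)
            manifest[f"orthology_{omap.species}"] = rel

        self.tensor.to_tsv(out / "counts.tsv", out / "samples.tsv")
        manifest["counts"] = "counts.tsv"
        manifest["samples"] = "samples.tsv"

        for name, track in [
            ("tf", self.tf_track),
            ("snp", self.snp_track),
            ("m6a", self.m6a_track),
            ("chromhmm", self.chromhmm_track),
        ]:
            write_feature_track(track, out / f"{name}.bed")
            manifest[f"track_{name}"] = f"{name}.bed"

        self.cancer_counts.to_csv(out / "cancer_counts.tsv", sep="\t",
                                  index_label="gene_id")
        self.cancer_meta.to_csv(out / "cancer_samples.tsv", sep="\t",
                                index_label="sample_id")
        manifest["cancer_counts"] = "cancer_counts.tsv"
        manifest["cancer_samples"] = "cancer_samples.tsv"

        self.truth.pseudogenes.to_csv(out / "truth_pseudogenes.tsv", sep="\t")
        self.truth.cancer.to_csv(out / "truth_cancer.tsv", sep="\t")
        with open(out / "truth_tracks.json", "w") as fh:
            json.dump(self.truth.track_params, fh, indent=2, sort_keys=True)
        manifest["truth_pseudogenes"] = "truth_pseudogenes.tsv"
        manifest["truth_cancer"] = "truth_cancer.tsv"
        manifest["truth_tracks"] = "truth_tracks.json"

        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------


def _nb_draw(rng, mean, dispersion):
    """NB(mean, alpha) draws with variance mu + alpha*mu^2; zero mean -> zero."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        n = 1.0 / dispersion
        p = n / (n + mean[pos])
        out[pos] = rng.negative_binomial(n, p)
    return out


def _make_layout(cfg: ScenarioConfig) -> GenomeLayout:
    lengths = {f"chr{i + 1}": cfg.autosome_length for i in range(cfg.n_autosomes)}
    lengths["chrX"] = cfg.x_length
    lengths["chrY"] = cfg.y_length
    return GenomeLayout(lengths)


def _place_genes(rng, cfg: ScenarioConfig, layout: GenomeLayout):
    """Assign non-overlapping exon structures for coding genes and pseudogenes.

    Pseudogene chromosomes are drawn in proportion to chromosome length (the
    insertion null), apart from the planted chrY subset; coding genes go to
    autosomes and X in proportion to length.
    """
    cursors = {c: 2000 for c in layout.lengths}

    def place(chrom, n_exons, exon_len_range, intron_range):
        start = cursors[chrom]
        exons = []
        pos = start
        for i in range(n_exons):
            length = int(rng.integers(*exon_len_range))
            exons.append((pos, pos + length))
            pos += length
            if i < n_exons - 1:
                pos += int(rng.integers(*intron_range))
        cursors[chrom] = pos + int(rng.integers(1000, 3000))
        if pos > layout.lengths[chrom]:
            return None
        return exons

    def pick_chrom(candidates):
        lens = np.array([layout.lengths[c] for c in candidates], dtype=float)
        for _ in range(20):
            chrom = candidates[rng.choice(len(candidates), p=lens / lens.sum())]
            if layout.lengths[chrom] - cursors[chrom] > 10_000:
                return chrom
        # fall back to the chromosome with the most remaining room
        return max(candidates, key=lambda c: layout.lengths[c] - cursors[c])

    non_y = [c for c in layout.lengths if c != "chrY"]
    coding = []
    for i in range(cfg.n_coding):
        chrom = pick_chrom(non_y)
        exons = place(chrom, int(rng.integers(3, 9)), (100, 400), (200, 1000))
        if exons is None:
            raise ValidationError("genome too small for the coding gene plan")
        coding.append(
            GeneRecord(
                gene_id=f"CG{i:04d}",
                biotype="protein_coding",
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                exons=exons,
            )
        )

    biotypes = list(cfg.biotype_weights)
    bio_w = np.array([cfg.biotype_weights[b] for b in biotypes], dtype=float)
    bio_w /= bio_w.sum()
    n_y = int(round(cfg.fraction_chrY * cfg.n_pseudogenes))
    pseudo = []
    for i in range(cfg.n_pseudogenes):
        chrom = "chrY" if i < n_y else pick_chrom(non_y)
        biotype = biotypes[rng.choice(len(biotypes), p=bio_w)]
        if biotype == "processed_pseudogene":
            exons = place(chrom, 1 if rng.random() < 0.7 else 2, (300, 2000), (200, 800))
        else:
            exons = place(chrom, int(rng.integers(2, 7)), (100, 400), (200, 1000))
        if exons is None:
            raise ValidationError("genome too small for the pseudogene plan")
        parent = (
            coding[int(rng.integers(len(coding)))].gene_id
            if rng.random() < cfg.fraction_with_parent
            else None
        )
        pseudo.append(
            GeneRecord(
                gene_id=f"PG{i:04d}",
                biotype=biotype,
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                exons=exons,
                parent_gene=parent,
            )
        )
    return coding, pseudo


def _plant_repeats(rng, cfg, layout, pseudo, excluded_ids):
    """Repeat track: heavy coverage (~85%) on the planted excluded subset plus
    a sparse genomic background that stays far from the 70% threshold."""
    records = []
    for g in pseudo:
        if g.gene_id in excluded_ids:
            for s, e in g.exons:
                length = e - s
                cov = int(np.ceil(0.85 * length))
                records.append((g.chrom, s, s + cov, "planted_repeat"))
    for _ in range(100):
        chrom = list(layout.lengths)[int(rng.integers(len(layout.lengths)))]
        length = int(rng.integers(200, 1000))
        start = int(rng.integers(0, layout.lengths[chrom] - length))
        records.append((chrom, start, start + length, "bg_repeat"))
    return FeatureTrack("repeat", records)


def _plant_orthology(rng, cfg, branch_table, pseudo, truth_branch):
    """Reciprocal-best blocks per species, consistent with planted origins.

    A species carries a block for an exon iff it diverged after the origin
    branch's older bound, the block survives dropout, and it covers a uniform
    0.8..1.0 fraction of the exon. Species older than the origin may get a
    non-reciprocal decoy block, which carries no presence evidence.
    """
    maps = []
    for species, div_time in branch_table.species_times.items():
        blocks = []
        cursor = 1000
        for g in pseudo:
            branch = truth_branch[g.gene_id]
            carries = div_time < branch.t_old and div_time <= branch.t_young
            for s, e in g.exons:
                length = e - s
                if carries:
                    if cfg.dropout > 0 and rng.random() < cfg.dropout:
                        continue
                    cov = rng.uniform(cfg.coverage_low, 1.0)
                    cov_len = max(1, int(np.floor(cov * length)))
                    offset = int(rng.integers(0, length - cov_len + 1))
                    fs, fe = s + offset, s + offset + cov_len
                    blocks.append(
                        (g.chrom, fs, fe, f"{species}_chr1", cursor, cursor + cov_len,
                         "+", True)
                    )
                    cursor += cov_len + 100
                elif rng.random() < cfg.decoy_rate:
                    blocks.append(
                        (g.chrom, s, e, f"{species}_chr9", cursor, cursor + length,
                         "+", False)
                    )
                    cursor += length + 100
        maps.append(OrthologyMap(species, blocks))
    return maps


def _trend_values(rng, stage_times: np.ndarray, amplitude: float) -> np.ndarray:
    """Centered cubic-in-ln(t) profile over the stages with SD = amplitude."""
    z = np.log(stage_times)
    z = (z - z.mean()) / z.std()
    for _ in range(100):
        coef = rng.standard_normal(3)
        v = coef[0] * z + coef[1] * z**2 + coef[2] * z**3
        if v.std() > 1e-8:
            break
    v = (v - v.mean()) / v.std()
    return v * amplitude


def _plant_expression(rng, cfg: ScenarioConfig, pseudo, coding, lengths):
    """Counts tensor with planted trends, tissue specificity and testis boost."""
    genes = [g.gene_id for g in pseudo] + [g.gene_id for g in coding]
    n_genes = len(genes)
    stage_names = list(cfg.stage_times)
    stage_t = np.array([cfg.stage_times[s] for s in stage_names])
    tissues = cfg.tissues

    base = np.exp(rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=n_genes))

    n_pseudo = len(pseudo)
    pseudo_idx = rng.permutation(n_pseudo)
    n_dyn = int(round(cfg.fraction_dynamic * n_pseudo))
    n_spec = int(round(cfg.fraction_tissue_specific * n_pseudo))
    dyn_idx = pseudo_idx[:n_dyn]
    spec_idx = pseudo_idx[n_dyn : n_dyn + n_spec]
    base[dyn_idx] = np.maximum(base[dyn_idx], cfg.dynamic_min_base)

    dyn_tissue = {
        int(i): tissues[int(rng.integers(len(tissues)))] for i in dyn_idx
    }
    spec_tissue = {
        int(i): tissues[int(rng.integers(len(tissues)))] for i in spec_idx
    }
    # testis boost on a random quarter of the non-specific pseudogenes
    eligible = np.setdiff1d(np.arange(n_pseudo), spec_idx)
    n_testis = int(round(cfg.testis_fraction * n_pseudo))
    testis_idx = set(
        int(i) for i in rng.choice(eligible, size=min(n_testis, len(eligible)),
                                   replace=False)
    )

    trend = {
        int(i): _trend_values(rng, stage_t, cfg.trend_amplitude) for i in dyn_idx
    }

    samples: list[SampleMeta] = []
    columns = []
    for tissue in tissues:
        mean_stage = np.tile(base[:, None], (1, len(stage_names)))
        for gi, tis in spec_tissue.items():
            if tis != tissue:
                mean_stage[gi, :] = 0.0
        if tissue == "testis":
            for gi in testis_idx:
                mean_stage[gi, :] *= cfg.testis_factor
        for gi, tis in dyn_tissue.items():
            if tis == tissue:
                mean_stage[gi, :] = mean_stage[gi, :] * np.exp(trend[gi])
        for si, stage in enumerate(stage_names):
            for sex in cfg.sexes:
                for rep in range(1, cfg.replicates + 1):
                    counts = _nb_draw(rng, mean_stage[:, si], cfg.nb_dispersion)
                    sid = f"{tissue}_{stage}_{sex}_r{rep}"
                    columns.append((sid, counts))
                    samples.append(
                        SampleMeta(
                            sample_id=sid,
                            tissue=tissue,
                            stage=stage,
                            time_days=cfg.stage_times[stage],
                            sex=sex,
                            replicate=rep,
                            library_size=1,  # patched below with column totals
                        )
                    )
    counts = np.column_stack([c for _, c in columns])
    libsizes = counts.sum(axis=0) + cfg.library_background_reads
    samples = [
        SampleMeta(
            sample_id=s.sample_id, tissue=s.tissue, stage=s.stage,
            time_days=s.time_days, sex=s.sex, replicate=s.replicate,
            library_size=int(max(1, libsizes[i])),
        )
        for i, s in enumerate(samples)
    ]
    tensor = ExpressionTensor(genes, samples, counts, lengths)
    truth = {
        "dynamic_tissue": {pseudo[i].gene_id: t for i, t in dyn_tissue.items()},
        "specific_tissue": {pseudo[i].gene_id: t for i, t in spec_tissue.items()},
        "testis_enhanced": {pseudo[i].gene_id for i in testis_idx},
    }
    return tensor, truth


def _plant_tracks(rng, cfg, layout, annotations, dynamic_ids):
    """TF, SNP, m6A and chromHMM tracks with dynamic-promoter enrichment."""
    chroms = list(layout.lengths)
    chrom_lens = np.array([layout.lengths[c] for c in chroms], dtype=float)
    p_chrom = chrom_lens / chrom_lens.sum()
    genome_len = chrom_lens.sum()

    def random_interval(length):
        ci = rng.choice(len(chroms), p=p_chrom)
        chrom = chroms[ci]
        start = int(rng.integers(0, layout.lengths[chrom] - length))
        return chrom, start, start + length

    promoters = {
        g.gene_id: (g.chrom, *derive_promoter(g, layout))
        for g in annotations.genes
    }
    dyn_promoters = [promoters[g] for g in dynamic_ids if g in promoters]

    # TF sites: uniform background + extra sites in dynamic promoters
    tf_records = []
    site_len = 15
    for _ in range(cfg.tf_background_sites):
        chrom, s, e = random_interval(site_len)
        tf_records.append((chrom, s, e, f"TF{int(rng.integers(cfg.tf_subtypes)):02d}"))
    base_rate = cfg.tf_background_sites * 3000 / genome_len  # sites per promoter
    extra_mean = (cfg.tf_promoter_enrichment - 1.0) * base_rate
    for chrom, ps, pe in dyn_promoters:
        for _ in range(rng.poisson(extra_mean)):
            start = int(rng.integers(ps, max(ps + 1, pe - site_len)))
            tf_records.append(
                (chrom, start, start + site_len,
                 f"TF{int(rng.integers(cfg.tf_subtypes)):02d}")
            )
    tf_track = FeatureTrack("TF", tf_records)

    # SNPs: single-base background + promoter enrichment (all promoters)
    snp_records = []
    n_bg = rng.poisson(cfg.snp_per_bp * genome_len)
    for _ in range(n_bg):
        chrom, s, e = random_interval(1)
        snp_records.append((chrom, s, e, "snp"))
    extra_per_promoter = (cfg.snp_promoter_enrichment - 1.0) * cfg.snp_per_bp * 3000
    for chrom, ps, pe in promoters.values():
        for _ in range(rng.poisson(extra_per_promoter)):
            pos = int(rng.integers(ps, pe))
            snp_records.append((chrom, pos, pos + 1, "snp"))
    snp_track = FeatureTrack("SNP", snp_records)

    # m6A: background peaks + one peak close to each dynamic TSS
    m6a_records = []
    for _ in range(cfg.m6a_background_sites):
        chrom, s, e = random_interval(cfg.m6a_site_length)
        m6a_records.append((chrom, s, e, "m6a"))
    for gid in dynamic_ids:
        if gid not in annotations:
            continue
        g = annotations[gid]
        tss = derive_tss(g)
        start = max(0, tss + int(rng.integers(-200, 200)))
        end = min(layout.lengths[g.chrom], start + cfg.m6a_site_length)
        if end > start:
            m6a_records.append((g.chrom, start, end, "m6a"))
    m6a_track = FeatureTrack("m6A", m6a_records)

    # chromHMM: full tiling with random segment states
    hmm_records = []
    for chrom in chroms:
        pos = 0
        while pos < layout.lengths[chrom]:
            seg = int(rng.integers(cfg.chromhmm_segment // 2, cfg.chromhmm_segment * 2))
            end = min(layout.lengths[chrom], pos + seg)
            state = f"state{int(rng.integers(cfg.chromhmm_states)) + 1:02d}"
            hmm_records.append((chrom, pos, end, state))
            pos = end
    chromhmm_track = FeatureTrack("chromHMM-state", hmm_records)

    params = {
        "tf_promoter_enrichment": cfg.tf_promoter_enrichment,
        "snp_promoter_enrichment": cfg.snp_promoter_enrichment,
        "tf_background_sites": cfg.tf_background_sites,
        "snp_per_bp": cfg.snp_per_bp,
    }
    return tf_track, snp_track, m6a_track, chromhmm_track, params


def _plant_cancer(rng, cfg: ScenarioConfig, gene_ids):
    """Cancer count matrix with planted type-specific and ubiquitous genes."""
    types = [f"CT{i + 1:02d}" for i in range(cfg.n_cancer_types)]
    genes = list(gene_ids)[: cfg.n_cancer_genes]
    n_genes = len(genes)
    if cfg.n_type_specific + cfg.n_ubiquitous > n_genes:
        raise ValidationError("more planted cancer genes than cancer genes")
    order = rng.permutation(n_genes)
    spec_rows = order[: cfg.n_type_specific]
    ubiq_rows = order[cfg.n_type_specific : cfg.n_type_specific + cfg.n_ubiquitous]

    means = np.exp(rng.normal(np.log(20.0), 1.0, size=(n_genes, len(types))))
    labels = {}
    for gi in spec_rows:
        focal = int(rng.integers(len(types)))
        means[gi, :] = 2.0  # every other share ~ 2/(2*32+500) << 5%
        means[gi, focal] = 500.0
        labels[genes[gi]] = f"type_specific:{types[focal]}"
    for gi in ubiq_rows:
        dominant = rng.choice(len(types), size=6, replace=False)
        means[gi, :] = 2.0  # background shares ~1%
        means[gi, dominant] = 100.0  # six ~12% shares: max<30%, top5 each >5%
        labels[genes[gi]] = "ubiquitous"
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "label": [labels.get(g, "other") for g in genes],
        }
    ).set_index("gene_id")

    sample_ids, sample_type, sample_tumor = [], [], []
    cols = []
    for ti, ctype in enumerate(types):
        n_tumor = int(rng.integers(cfg.tumor_samples_low, cfg.tumor_samples_high + 1))
        n_normal = int(rng.integers(cfg.normal_samples_low, cfg.normal_samples_high + 1))
        for k in range(n_tumor):
            sample_ids.append(f"{ctype}_T{k + 1:02d}")
            sample_type.append(ctype)
            sample_tumor.append(True)
            cols.append(means[:, ti])
        for k in range(n_normal):
            sample_ids.append(f"{ctype}_N{k + 1:02d}")
            sample_type.append(ctype)
            sample_tumor.append(False)
            cols.append(means[:, ti] * 0.8)
    mat = np.column_stack(cols)
    if cfg.cancer_noise_sd > 0:
        mat = mat * np.exp(rng.normal(0.0, cfg.cancer_noise_sd, size=mat.shape))
    counts = pd.DataFrame(np.round(mat).astype(int), index=genes, columns=sample_ids)
    meta = pd.DataFrame(
        {"cancer_type": sample_type, "tumor": sample_tumor}, index=sample_ids
    )
    return counts, meta, truth


def generate_scenario(config: ScenarioConfig | None = None) -> Scenario:
    """Generate every pipeline input plus the ground-truth tables."""
    cfg = config or ScenarioConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    layout = _make_layout(cfg)
    branch_table = BranchTable(
        cfg.ladder, root_cap=cfg.root_cap_factor * max(cfg.ladder.values())
    )

    coding, pseudo = _place_genes(rng, cfg, layout)
    annotations = AnnotationSet(layout, coding + pseudo)

    weights = np.asarray(cfg.branch_weights, dtype=float)
    branch_idx = rng.choice(len(branch_table.branches), size=len(pseudo), p=weights)
    truth_branch = {
        g.gene_id: branch_table.branches[int(bi)] for g, bi in zip(pseudo, branch_idx)
    }

    non_y = [g for g in pseudo if g.chrom != "chrY"]
    n_rep = int(round(cfg.fraction_repeat_excluded * len(pseudo)))
    rep_excluded = {
        g.gene_id
        for g in [non_y[int(i)] for i in rng.choice(len(non_y), n_rep, replace=False)]
    }
    repeats = _plant_repeats(rng, cfg, layout, pseudo, rep_excluded)

    orthology_maps = _plant_orthology(rng, cfg, branch_table, pseudo, truth_branch)

    lengths = {g.gene_id: merged_exonic_length(g) for g in coding + pseudo}
    tensor, expr_truth = _plant_expression(rng, cfg, pseudo, coding, lengths)

    dynamic_ids = sorted(expr_truth["dynamic_tissue"])
    tf_track, snp_track, m6a_track, chromhmm_track, track_params = _plant_tracks(
        rng, cfg, layout, annotations, dynamic_ids
    )

    cancer_counts, cancer_meta, cancer_truth = _plant_cancer(
        rng, cfg, [g.gene_id for g in pseudo]
    )

    rows = []
    for g in pseudo:
        b = truth_branch[g.gene_id]
        rows.append(
            {
                "gene_id": g.gene_id,
                "branch": b.name,
                "age_myr": b.midpoint,
                "chrom": g.chrom,
                "biotype": g.biotype,
                "parent_gene": g.parent_gene or "",
                "planted_repeat_excluded": g.gene_id in rep_excluded,
                "on_chrY": g.chrom == "chrY",
                "dynamic_tissue": expr_truth["dynamic_tissue"].get(g.gene_id, ""),
                "is_dynamic": g.gene_id in expr_truth["dynamic_tissue"],
                "specific_tissue": expr_truth["specific_tissue"].get(g.gene_id, ""),
                "testis_enhanced": g.gene_id in expr_truth["testis_enhanced"],
            }
        )
    truth_pseudo = pd.DataFrame(rows).set_index("gene_id")

    truth = TruthSet(truth_pseudo, cancer_truth, track_params)
    return Scenario(
        config=cfg,
        layout=layout,
        annotations=annotations,
        repeats=repeats,
        branch_table=branch_table,
        orthology_maps=orthology_maps,
        tensor=tensor,
        tf_track=tf_track,
        snp_track=snp_track,
        m6a_track=m6a_track,
        chromhmm_track=chromhmm_track,
        cancer_counts=cancer_counts,
        cancer_meta=cancer_meta,
        truth=truth,
    )


def null_r2_reference(
    n: int, degree: int = 3, replicates: int = 2000, seed: int = 0
) -> np.ndarray:
    """Empirical null R^2 distribution for the polynomial trend fit.

    Responses are pure iid Gaussian noise over ``n`` samples; the returned
    draws follow the exact Beta(degree/2, (n-degree-1)/2) law whose mean is
    degree/(n-1). Used to calibrate the R^2 > 0.3 DDP rule.
    """
    if n <= degree + 1:
        raise ValidationError(f"need n > degree+1 = {degree + 1}, got n = {n}")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    times = np.geomspace(10.5, 90.0, n)
    Y = rng.standard_normal((replicates, n))
    r2, _ = _r2_matrix(Y, times, degree)
    return r2


def traffic_null_replicates(
    coding_x: int, coding_autosome: int, n_pseudogenes: int,
    replicates: int = 1000, seed: int = 0,
) -> np.ndarray:
    """Fisher p-values under the proportional generation null.

    Each replicate draws pseudogene parent chromosomes and an equally
    proportional coding-gene comparison sample as independent binomials with
    the same X-chromosome probability, then tests the 2x2 table
    (parents vs coding genes, X vs autosome). Used for type-I calibration of
    the traffic test.
    """
    from .classification import fisher_two_sided_p

    rng = np.random.default_rng(seed)
    n_coding = coding_x + coding_autosome
    p_x = coding_x / n_coding
    out = np.empty(replicates)
    for i in range(replicates):
        gen_x = rng.binomial(n_pseudogenes, p_x)
        ref_x = rng.binomial(n_coding, p_x)
        table = [[gen_x, n_pseudogenes - gen_x], [ref_x, n_coding - ref_x]]
        out[i] = fisher_two_sided_p(table)
    return out
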