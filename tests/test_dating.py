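"""Branch assignment, filters and origin-recovery on planted truth."""

import numpy as np
import pandas as pd
import pytest

from pseudopipe import (
    AnnotationSet,
    BranchTable,
    DatingModel,
    FeatureTrack,
    GeneRecord,
    GenomeLayout,
    OrthologyMap,
    ValidationError,
    assign_origin_branch,
    date_pseudogene,
    exon_presence,
    filter_for_dating,
)
from pseudopipe.dating import age_distribution

from .oracles import brute_covered_bp

LADDER = {"sp90": 90.0, "sp160": 160.0, "sp320": 320.0}


@pytest.fixture
def branches():
    return BranchTable(LADDER)


class TestBranchTable:
    def test_branch_bounds_partition_root_cap(self, branches):
        bounds = [(b.t_old, b.t_young) for b in branches.branches]
        assert bounds == [(90.0, 0.0), (160.0, 90.0), (320.0, 160.0), (480.0, 320.0)]

    def test_midpoints_inside_bounds(self, branches):
        for b in branches.branches:
            assert b.t_young < b.midpoint < b.t_old

    def test_default_root_cap_is_1_5x_oldest(self, branches):
        assert branches.root_cap == pytest.approx(480.0)

    def test_duplicate_depths_rejected_as_non_ladder(self):
        with pytest.raises(ValidationError, match="ladder"):
            BranchTable({"a": 90.0, "b": 90.0})


class TestAssignOriginBranch:
    def test_presence_only_in_youngest_species(self, branches):
        b = assign_origin_branch({"sp90": True, "sp160": False, "sp320": False}, branches)
        assert (b.t_old, b.t_young) == (160.0, 90.0)
        assert b.midpoint == pytest.approx(125.0)

    def test_intermediate_absence_is_loss_under_dollo(self, branches):
        b = assign_origin_branch({"sp90": False, "sp160": True, "sp320": False}, branches)
        assert (b.t_old, b.t_young) == (320.0, 160.0)
        assert b.midpoint == pytest.approx(240.0)

    def test_no_presence_dates_to_focal_branch(self, branches):
        b = assign_origin_branch({"sp90": False, "sp160": False, "sp320": False}, branches)
        assert b.midpoint == pytest.approx(45.0)

    def test_unknown_species_rejected(self, branches):
        with pytest.raises(ValidationError):
            assign_origin_branch({"weasel": True}, branches)

    def test_monotone_in_presence_depth(self, branches):
        """Adding presence in a more distant species never yields a younger branch."""
        rng = np.random.default_rng(0)
        species = list(LADDER)
        for _ in range(200):
            presence = {sp: bool(rng.integers(2)) for sp in species}
            base = assign_origin_branch(presence, branches)
            absent = [sp for sp in species if not presence[sp]]
            if not absent:
                continue
            more = dict(presence)
            more[absent[int(rng.integers(len(absent)))]] = True
            deeper = assign_origin_branch(more, branches)
            assert deeper.t_old >= base.t_old


class TestExonPresence:
    def _map(self, blocks):
        return OrthologyMap("sp90", blocks)

    def test_full_coverage(self):
        omap = self._map([("chr1", 0, 100, "t", 0, 100, "+", True)])
        present, frac = exon_presence((0, 100), "chr1", omap)
        assert present and frac == pytest.approx(1.0)

    def test_partial_coverage_below_threshold(self):
        omap = self._map(
            [
                ("chr1", 0, 25, "t", 0, 25, "+", True),
                ("chr1", 60, 75, "t", 100, 115, "+", True),
            ]
        )
        present, frac = exon_presence((0, 100), "chr1", omap, min_cov=0.5)
        assert not present
        assert frac == pytest.approx(0.4)

    def test_no_blocks_on_chromosome(self):
        omap = self._map([("chr2", 0, 100, "t", 0, 100, "+", True)])
        present, frac = exon_presence((0, 100), "chr1", omap)
        assert not present and frac == 0.0

    def test_non_reciprocal_blocks_ignored(self):
        omap = self._map([("chr1", 0, 100, "t", 0, 100, "+", False)])
        present, frac = exon_presence((0, 100), "chr1", omap)
        assert not present and frac == 0.0

    def test_coverage_matches_per_base_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            starts = np.sort(rng.choice(np.arange(0, 2000, 40), 8, replace=False))
            blocks = [
                ("chr1", int(s), int(s + rng.integers(1, 35)), "t", 0, 1, "+", True)
                for s in starts
            ]
            omap = self._map(blocks)
            exon = (300, 900)
            _, frac = exon_presence(exon, "chr1", omap)
            expected = brute_covered_bp(
                exon, [(b[1], b[2]) for b in blocks], 2100
            ) / (exon[1] - exon[0])
            assert frac == pytest.approx(expected)


class TestDatePseudogene:
    def test_most_ancient_exon_wins(self, branches):
        b1 = branches.branches[1]  # (160, 90]
        b2 = branches.branches[2]  # (320, 160]
        assert date_pseudogene([b1, b2], branches) is b2

    def test_single_exon(self, branches):
        b = branches.branches[0]
        assert date_pseudogene([b], branches) is b


class TestFilterForDating:
    def _annotations(self):
        layout = GenomeLayout({"chr1": 100_000, "chrY": 50_000})
        genes = [
            GeneRecord("y1", "processed_pseudogene", "chrY", "+", [(0, 500)]),
            GeneRecord("r71", "processed_pseudogene", "chr1", "+", [(0, 1000)]),
            GeneRecord("r70", "processed_pseudogene", "chr1", "+", [(2000, 3000)]),
            GeneRecord("ok", "processed_pseudogene", "chr1", "+", [(5000, 5600)]),
        ]
        return AnnotationSet(layout, genes)

    def test_boundary_is_strictly_greater_than_70_percent(self):
        ann = self._annotations()
        repeats = FeatureTrack(
            "repeat",
            [
                ("chr1", 0, 710, "rep"),  # 71.0% of r71
                ("chr1", 2000, 2700, "rep"),  # exactly 70.0% of r70
            ],
        )
        report = filter_for_dating(ann, repeats)
        assert report.loc["y1", "status"] == "excluded_chrY"
        assert report.loc["r71", "status"] == "excluded_repeat"
        assert report.loc["r70", "status"] == "retained"
        assert report.loc["r70", "repeat_fraction"] == pytest.approx(0.70)
        assert report.loc["ok", "status"] == "retained"

    def test_no_repeat_track_retains_everything_off_y(self):
        report = filter_for_dating(self._annotations(), None)
        assert (report.drop("y1")["status"] == "retained").all()


class TestRecoveryOnSyntheticTruth:
    def test_noise_free_recovery_is_complete(self, scenario):
        res = DatingModel(
            scenario.annotations,
            scenario.orthology_maps,
            scenario.branch_table,
            repeats=scenario.repeats,
        ).fit()
        joined = res.dated.join(scenario.truth.pseudogenes, rsuffix="_true")
        assert len(joined) > 400
        assert (joined["branch"] == joined["branch_true"]).all()

    def test_recovery_with_dropout_stays_high(self, dropout_scenario):
        sc = dropout_scenario
        res = DatingModel(
            sc.annotations, sc.orthology_maps, sc.branch_table, repeats=sc.repeats
        ).fit()
        joined = res.dated.join(sc.truth.pseudogenes, rsuffix="_true")
        assert (joined["branch"] == joined["branch_true"]).mean() >= 0.90

    def test_planted_exclusions_are_excluded(self, scenario):
        res = DatingModel(
            scenario.annotations,
            scenario.orthology_maps,
            scenario.branch_table,
            repeats=scenario.repeats,
        ).fit()
        truth = scenario.truth.pseudogenes
        on_y = truth.index[truth["on_chrY"]]
        assert (res.assignments.loc[on_y, "status"] == "excluded_chrY").all()
        planted_rep = truth.index[truth["planted_repeat_excluded"]]
        assert (
            res.assignments.loc[planted_rep, "status"] == "excluded_repeat"
        ).all()


class TestAgeDistribution:
    def test_counts_and_chromosome_proportions(self, branches):
        layout = GenomeLayout({"chr1": 10_000, "chrX": 10_000, "chrY": 1000})
        genes = [
            GeneRecord(f"p{i}", "processed_pseudogene",
                       "chrX" if i < 2 else "chr1", "+", [(i * 100, i * 100 + 50)])
            for i in range(5)
        ]
        ann = AnnotationSet(layout, genes)
        assignments = pd.DataFrame(
            {
                "branch": ["b1", "b1", "b1", "b0", "b0"],
                "status": ["dated"] * 5,
            },
            index=[g.gene_id for g in genes],
        )
        counts, props = age_distribution(assignments, ann)
        assert counts["b1"] == 3 and counts["b0"] == 2
        assert counts.sum() == 5
        assert np.allclose(props.sum(axis=1), 1.0)
        assert props.loc["b1", "X"] == pytest.approx(2 / 3)
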