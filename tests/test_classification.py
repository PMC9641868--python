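"""Traffic enrichment, cancer-type labels, retention and translation calls."""

import numpy as np
import pandas as pd
import pytest

from pseudopipe import (
    AnnotationSet,
    GeneRecord,
    GenomeLayout,
    ValidationError,
    call_translated,
    classify_cancer_matrix,
    classify_cancer_specificity,
    retain_cancer_types,
    traffic_expectation,
    traffic_test,
)
from pseudopipe.classification import fisher_two_sided_p

from .oracles import fisher_enum_p, nch_expectation


class TestTrafficExpectation:
    def _annotations(self, coding_per_chrom, pseudo_chroms, parents):
        lengths = {"chr1": 100_000, "chr2": 100_000}
        genes = []
        pos = {c: 0 for c in lengths}

        def add(gene_id, biotype, chrom, parent=None):
            s = pos[chrom]
            genes.append(
                GeneRecord(gene_id, biotype, chrom, "+", [(s, s + 100)], parent)
            )
            pos[chrom] += 200

        k = 0
        for chrom, n in coding_per_chrom.items():
            for _ in range(n):
                add(f"c{k}", "protein_coding", chrom)
                k += 1
        for i, chrom in enumerate(pseudo_chroms):
            add(f"p{i}", "processed_pseudogene", chrom, parents[i])
        return AnnotationSet(GenomeLayout(lengths, frozenset()), genes)

    def test_generation_proportional_to_coding_counts(self):
        ann = self._annotations(
            {"chr1": 9, "chr2": 1},
            ["chr1"] * 10,
            [f"c{i % 10}" for i in range(10)],
        )
        table = traffic_expectation(ann)
        assert table["expected_generation"].sum() == pytest.approx(10)
        assert table.loc["chr1", "expected_generation"] == pytest.approx(9.0)
        assert table.loc["chr2", "expected_generation"] == pytest.approx(1.0)

    def test_equal_lengths_give_equal_expected_insertions(self):
        ann = self._annotations({"chr1": 2, "chr2": 2}, ["chr1", "chr1"], ["c0", "c1"])
        table = traffic_expectation(ann)
        assert table.loc["chr1", "expected_insertion"] == pytest.approx(
            table.loc["chr2", "expected_insertion"]
        )
        assert table["expected_insertion"].sum() == pytest.approx(2)

    def test_observed_counts_match_hand_tally(self):
        ann = self._annotations(
            {"chr1": 3, "chr2": 1},
            ["chr1", "chr2", "chr2"],
            ["c0", "c0", "c3"],
        )
        table = traffic_expectation(ann)
        assert table["observed_insertion"].tolist() == [1, 2]
        assert table["observed_generation"].tolist() == [2, 1]


class TestTrafficTest:
    def test_matches_enumeration_oracle_on_reference_table(self):
        res = traffic_test([[1, 9], [11, 3]])
        assert res.p_value == pytest.approx(fisher_enum_p([[1, 9], [11, 3]]), rel=1e-9)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            t = rng.integers(0, 25, size=(2, 2))
            assert fisher_two_sided_p(t) == pytest.approx(
                fisher_enum_p(t.tolist()), rel=1e-9, abs=1e-12
            )

    def test_matches_scipy_fisher_exact(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        for _ in range(200):
            t = rng.integers(0, 50, size=(2, 2))
            assert fisher_two_sided_p(t) == pytest.approx(
                stats.fisher_exact(t)[1], rel=1e-9, abs=1e-12
            )

    def test_identical_row_proportions(self):
        res = traffic_test([[10, 20], [20, 40]])
        assert res.p_value == pytest.approx(1.0, abs=0.05)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.1)

    def test_zero_margin_gives_p_one_and_undefined_or(self):
        res = traffic_test([[0, 0], [3, 5]])
        assert res.p_value == 1.0
        assert not res.odds_ratio_defined
        assert np.isnan(res.odds_ratio)

    def test_conditional_or_solves_the_score_equation(self):
        """The conditional MLE makes the noncentral-hypergeometric mean equal
        the observed cell count."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            t = rng.integers(1, 20, size=(2, 2))
            res = traffic_test(t)
            if not np.isfinite(res.odds_ratio) or res.odds_ratio <= 0:
                continue
            assert nch_expectation(t.tolist(), res.odds_ratio) == pytest.approx(
                float(t[0, 0]), abs=1e-4
            )

    def test_type_one_error_under_proportional_null(self):
        from pseudopipe import traffic_null_replicates

        ps = traffic_null_replicates(30, 170, 500, replicates=1000, seed=0)
        assert (ps < 0.05).mean() <= 0.06


class TestCancerSpecificity:
    def _means(self, values, n_types=33):
        vals = list(values) + [0.0] * (n_types - len(values))
        return pd.Series(vals, index=[f"CT{i + 1:02d}" for i in range(n_types)],
                         name="g1")

    def test_clear_type_specific(self):
        means = self._means([20.0] + [0.5] * 32)
        prof = classify_cancer_specificity(means)
        assert prof.label == "type_specific:CT01"
        assert prof.shares.sum() == pytest.approx(1.0)

    def test_ubiquitous_pattern(self):
        means = self._means([10, 9, 8, 7, 6] + [0.2] * 28)
        assert classify_cancer_specificity(means).label == "ubiquitous"

    def test_focal_share_exactly_15_percent_is_not_specific(self):
        # focal exactly 15%, others split far below 5% each
        means = self._means([15.0] + [85.0 / 32] * 32)
        prof = classify_cancer_specificity(means)
        assert prof.shares.iloc[0] == pytest.approx(0.15)
        assert not prof.label.startswith("type_specific")

    def test_other_share_exactly_5_percent_blocks_specific(self):
        means = self._means([90.0, 5.0] + [5.0 / 31] * 31)
        shares = classify_cancer_specificity(means).shares
        assert shares.iloc[1] == pytest.approx(0.05)
        assert classify_cancer_specificity(means).label == "other"

    def test_max_share_exactly_30_percent_blocks_ubiquitous(self):
        means = self._means([30.0, 20.0, 20.0, 15.0, 15.0])
        prof = classify_cancer_specificity(means)
        assert prof.shares.max() == pytest.approx(0.30)
        assert prof.label == "other"

    def test_all_zero_gene_flagged(self):
        prof = classify_cancer_specificity(self._means([]))
        assert prof.label == "other" and prof.zero_expression

    def test_planted_labels_recovered_noise_free(self, scenario):
        labels = classify_cancer_matrix(
            scenario.cancer_counts,
            scenario.cancer_meta["cancer_type"],
            tumor_only=scenario.cancer_meta["tumor"],
        )
        truth = scenario.truth.cancer
        planted = truth[truth["label"] != "other"]
        joined = labels.join(planted, how="inner", rsuffix="_true")
        assert len(joined) == len(planted)
        assert (joined["label"] == joined["label_true"]).all()


class TestRetention:
    def test_boundary_is_strictly_more_than_five(self):
        counts = pd.DataFrame(
            {"normal": [6, 5, 0, 12], "tumor": [6, 50, 0, 5]},
            index=["keep", "dropA", "dropB", "dropC"],
        )
        assert retain_cancer_types(counts) == ["keep"]

    def test_scenario_retention_matches_hand_filter(self, scenario):
        meta = scenario.cancer_meta
        counts = pd.DataFrame(
            {
                "normal": meta[~meta["tumor"]].groupby("cancer_type").size(),
                "tumor": meta[meta["tumor"]].groupby("cancer_type").size(),
            }
        ).fillna(0)
        retained = retain_cancer_types(counts)
        for ctype in counts.index:
            expected = counts.loc[ctype, "normal"] > 5 and counts.loc[ctype, "tumor"] > 5
            assert (ctype in retained) == expected


class TestTranslationCall:
    @pytest.mark.parametrize(
        "a, b, fpkm, orfs, expected",
        [
            (True, True, 1.0, 1, True),  # boundary FPKM inclusive
            (True, False, 50.0, 3, False),
            (True, True, 0.9, 2, False),
            (True, True, 2.0, 0, False),
            (False, True, 2.0, 2, False),
        ],
    )
    def test_rule(self, a, b, fpkm, orfs, expected):
        assert call_translated("g", a, b, fpkm, orfs).translated is expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            call_translated("g", True, True, -1.0, 1)
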