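import itertools

import numpy as np
import pytest

import mirdrugsurv as mds
from mirdrugsurv.concordance import DEFAULT_GENE_FDR
from mirdrugsurv.screen import MarkerResult


class TestClassifyConsistency:
    # the full truth table: inhibit pairs agree when directions are opposite,
    # activate pairs when they coincide
    TRUTH = {
        ("inhibit", "high_better", "low_better"): "consistent",
        ("inhibit", "low_better", "high_better"): "consistent",
        ("inhibit", "high_better", "high_better"): "inconsistent",
        ("inhibit", "low_better", "low_better"): "inconsistent",
        ("activate", "high_better", "high_better"): "consistent",
        ("activate", "low_better", "low_better"): "consistent",
        ("activate", "high_better", "low_better"): "inconsistent",
        ("activate", "low_better", "high_better"): "inconsistent",
    }

    @pytest.mark.parametrize("key", sorted(TRUTH))
    def test_exhaustive_truth_table(self, key):
        assert mds.classify_consistency(*key) == self.TRUTH[key]

    @pytest.mark.parametrize(
        "dirs", list(itertools.product(["high_better", "low_better"], repeat=2))
    )
    def test_unknown_regulation_is_unknown(self, dirs):
        assert mds.classify_consistency("unknown", *dirs) == "unknown"

    def test_invariant_under_flipping_both_directions(self):
        flip = {"high_better": "low_better", "low_better": "high_better"}
        for (reg, md, gd), verdict in self.TRUTH.items():
            assert mds.classify_consistency(reg, flip[md], flip[gd]) == verdict

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError):
            mds.classify_consistency("represses", "high_better", "low_better")
        with pytest.raises(ValueError):
            mds.classify_consistency("inhibit", "up", "low_better")


class TestExpressionCorrelation:
    def test_negative_relationship_detected(self, rng):
        x = rng.normal(4, 1, 30)
        y = -2.0 * x + rng.normal(0, 0.1, 30)
        slope, p = mds.expression_correlation(x, y)
        assert slope == pytest.approx(-2.0, abs=0.1)
        assert p < 0.05

    def test_matches_closed_form_ols(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        slope, p = mds.expression_correlation(x, y)
        # closed-form slope and t-test computed independently
        b = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        resid = y - (y.mean() + b * (x - x.mean()))
        se = np.sqrt(resid @ resid / (23 * np.sum((x - x.mean()) ** 2)))
        from scipy import stats as sps

        t = b / se
        assert slope == pytest.approx(b, rel=1e-9)
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 23), rel=1e-9)

    def test_null_pvalues_roughly_uniform(self, rng):
        ps = []
        for _ in range(200):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            ps.append(mds.expression_correlation(x, y)[1])
        from scipy import stats as sps

        assert sps.kstest(ps, "uniform").statistic < 0.12

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mds.expression_correlation([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            mds.expression_correlation([1.0, 2.0], [1.0, 2.0])

    def test_missing_pairs_dropped(self):
        x = [1.0, 2.0, 3.0, np.nan, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, np.nan]
        slope, _ = mds.expression_correlation(x, y)
        assert slope == pytest.approx(2.0)


def _marker(feature, cancer="CT1", drug="drugA", fdr=0.01, direction="low"):
    m = MarkerResult(feature, cancer, drug, 10, 10)
    m.logrank = mds.LogrankResult(9.0, 0.0027, 10, 10, 8, 4)
    m.p_value = 0.0027
    m.fdr = fdr
    m.better_survival_class = direction
    return m


class TestMediatedCombinations:
    def _pairs(self):
        return [
            mds.TargetPair("mirA", "g1", "inhibit"),
            mds.TargetPair("mirA", "g2", "inhibit"),
            mds.TargetPair("mirB", "g1", "activate"),
        ]

    def test_one_mirna_two_significant_targets(self):
        combos = mds.mediated_combinations(
            [_marker("mirA")],
            [_marker("g1", fdr=0.001), _marker("g2", fdr=0.005)],
            self._pairs(),
        )
        assert {(c.mirna_id, c.gene_id) for c in combos} == {("mirA", "g1"), ("mirA", "g2")}

    def test_shared_target_yields_two_combinations(self):
        combos = mds.mediated_combinations(
            [_marker("mirA"), _marker("mirB")],
            [_marker("g1", fdr=0.001)],
            self._pairs(),
        )
        assert {(c.mirna_id, c.gene_id) for c in combos} == {("mirA", "g1"), ("mirB", "g1")}
        regs = {c.mirna_id: c.regulation for c in combos}
        assert regs == {"mirA": "inhibit", "mirB": "activate"}

    def test_gene_fdr_cut_applied(self):
        combos = mds.mediated_combinations(
            [_marker("mirA")],
            [_marker("g1", fdr=0.05)],  # above the 0.01 gene threshold
            self._pairs(),
        )
        assert combos == []
        assert DEFAULT_GENE_FDR == 0.01

    def test_cross_group_pairs_not_combined(self):
        combos = mds.mediated_combinations(
            [_marker("mirA", drug="drugA")],
            [_marker("g1", drug="drugB", fdr=0.001)],
            self._pairs(),
        )
        assert combos == []

    def test_no_significant_genes_empty(self):
        assert mds.mediated_combinations([_marker("mirA")], [], self._pairs()) == []


class TestEndToEndConcordance:
    def test_planted_inhibitory_target_recovered_and_consistent(self, demo_screen):
        cohort = demo_screen["cohort"]
        markers = [
            r
            for r in demo_screen["results"]
            if r.significant(0.1) and r.drug_specific and r.feature_id == "mir-plant-1"
        ]
        assert markers
        gene_thresholds = mds.fit_all_thresholds(cohort.genes)
        group_map = {(g.cancer_type, g.drug): g for g in demo_screen["groups"]}
        gene_results = mds.screen_targets(
            markers,
            cohort.pairs,
            cohort.genes,
            gene_thresholds,
            demo_screen["clinical_by_id"],
            group_map,
        )
        planted_gene = [r for r in gene_results if r.feature_id == "gene-plant-1"]
        assert planted_gene and planted_gene[0].tested
        assert planted_gene[0].fdr < 0.01
        combos = mds.mediated_combinations(markers, gene_results, cohort.pairs)
        assert [(c.mirna_id, c.gene_id) for c in combos] == [
            ("mir-plant-1", "gene-plant-1")
        ]
        records = mds.build_concordance_records(
            combos, cohort.mirna, cohort.genes, group_map
        )
        rec = records[0]
        assert rec.corr_slope < 0
        assert rec.corr_p < 0.05 and rec.corr_significant
        # inhibitory pair with opposite survival directions
        assert rec.mirna_direction != rec.gene_direction
        assert rec.verdict == "consistent"

    def test_summary_counts_partition_combinations(self, demo_screen):
        recs = [
            mds.ConcordanceRecord(
                "m", "g", "CT1", "drugA", reg, -1.0, 0.01, True, md, gd,
                mds.classify_consistency(reg, md, gd),
            )
            for reg in ("inhibit", "activate", "unknown")
            for md in ("high_better", "low_better")
            for gd in ("high_better", "low_better")
        ]
        n = len(recs)
        counts = {
            v: sum(1 for r in recs if r.verdict == v)
            for v in ("consistent", "inconsistent", "unknown")
        }
        assert sum(counts.values()) == n
        assert counts["unknown"] == 4
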