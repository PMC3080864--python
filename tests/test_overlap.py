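"""Subset scans, tail overlap, rank correlation, GWAS intersection."""

import numpy as np
import pandas as pd
import pytest

import ecoscan as es
from ecoscan.io_formats import ValidationError
from ecoscan.rank_stats import RankTable
from ecoscan.overlap import gwas_overlap, rank_correlation, subset_scan, tail_overlap


def _series(values, ids=None):
    ids = ids if ids is not None else [f"s{i}" for i in range(len(values))]
    return pd.Series(values, index=ids)


class TestTailOverlap:
    def test_product_rule_expectation(self):
        n = 10_000
        rng = np.random.default_rng(0)
        qa = _series(rng.permutation(np.arange(1, n + 1) / n))
        qb = _series(rng.permutation(np.arange(1, n + 1) / n))
        report = tail_overlap(qa, qb, 0.01)
        assert report.expected == pytest.approx(1.0)
        assert report.venn["both"] == report.observed

    def test_identical_ranks_fold(self):
        n = 1000
        q = _series(np.arange(1, n + 1) / n)
        report = tail_overlap(q, q, 0.05)
        assert report.observed == 50
        assert report.fold == pytest.approx(n / 50)

    def test_independent_null_within_poisson_band(self):
        """Independent rank vectors: overlap of two 1% tails of 10,000 SNPs
        is Poisson(1); stay within its 99.6% band across 100 seeds."""
        n = 10_000
        base = np.arange(1, n + 1) / n
        outside = 0
        obs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            qa = _series(rng.permutation(base))
            qb = _series(rng.permutation(base))
            o = tail_overlap(qa, qb, 0.01).observed
            obs.append(o)
            outside += o > 4
        assert outside <= 3
        assert np.mean(obs) == pytest.approx(1.0, abs=0.4)

    def test_empty_universe_raises(self):
        with pytest.raises(ValidationError):
            tail_overlap(_series([0.1], ["a"]), _series([0.1], ["b"]), 0.05)


class TestRankCorrelation:
    def test_identity_and_reversal(self):
        q = _series(np.linspace(0.01, 1, 50))
        assert rank_correlation(q, q) == pytest.approx(1.0)
        rev = _series(q.to_numpy()[::-1], list(q.index))
        assert rank_correlation(q, rev) == pytest.approx(-1.0)

    def test_hand_computed_four_points(self):
        a = _series([1, 2, 3, 4], list("abcd"))
        b = _series([2, 1, 4, 3], list("abcd"))
        assert rank_correlation(a, b) == pytest.approx(0.6)


class TestSubsetScan:
    def test_worldwide_subset_identical_to_worldwide_scan(self, small_data):
        counts, env, panel = small_data["counts"], small_data["env"], small_data["panel"]
        res_sub, ranks_sub = subset_scan(counts, env, panel, "worldwide", seed=7)
        models = es.estimate_covariance_models(counts, panel, seed=7)
        res_ww = es.scan(counts, env, models, panel)
        ranks_ww = es.rank_scan(res_ww, counts, panel)
        assert np.array_equal(
            res_sub.bf_matrix(), res_ww.bf_matrix(), equal_nan=True
        )  # bit-exact
        assert np.array_equal(
            ranks_sub.q_matrix(), ranks_ww.q_matrix(), equal_nan=True
        )

    def test_covariance_dimension_matches_subset(self, small_data):
        counts, panel = small_data["counts"], small_data["panel"]
        models = es.estimate_covariance_models(
            counts, panel, population_set="AWE", seed=1, min_controls=100
        )
        assert all(len(m.populations) == len(panel.subsets["AWE"]) for m in models.values())

    def test_tiny_subset_rejected(self, small_data):
        counts, env, panel = small_data["counts"], small_data["env"], small_data["panel"]
        with pytest.raises(ValidationError, match="at least 3"):
            subset_scan(counts, env, panel, panel.populations[:2])

    def test_region_restricted_signal_found_only_in_its_subset(self, small_data):
        """A frequency cline planted across Europe only (an AWE-exclusive
        region here) ranks far better in the AWE scan than in AEA."""
        counts, env, panel = small_data["counts"], small_data["env"], small_data["panel"]
        regions = panel.table.set_index("population")["region"]
        awe = panel.subsets["AWE"]
        z = ((env - env.loc[awe].mean()) / env.loc[awe].std(ddof=0))["abs_latitude"]
        k = counts.k.copy()
        row = 10
        for j, pop in enumerate(counts.populations):
            theta = 0.5 + (0.4 * np.clip(z[pop], -2, 2) if regions[pop] == "Europe" else 0.0)
            k[row, j] = int(round(counts.n[row, j] * np.clip(theta, 0.05, 0.95)))
        planted = es.AlleleCountMatrix(counts.snps.copy(), counts.populations, k, counts.n)
        sid = counts.snps["snp_id"].iloc[row]
        _, ranks_awe = subset_scan(planted, env, panel, "AWE", seed=1, min_controls=100)
        _, ranks_aea = subset_scan(planted, env, panel, "AEA", seed=1, min_controls=100)
        q_awe = ranks_awe.table.set_index("snp_id").loc[sid, "q.abs_latitude"]
        q_aea = ranks_aea.table.set_index("snp_id").loc[sid, "q.abs_latitude"]
        assert q_awe < 0.1
        assert q_awe < q_aea


def _mini_rank_table(qs, ids):
    n = len(ids)
    return RankTable(
        table=pd.DataFrame(
            {
                "snp_id": ids,
                "chrom": "chr1",
                "pos": np.arange(n) * 1000,
                "panel": "A",
                "bin": "A:0",
                "q.var1": qs,
                "min_rank": qs,
            }
        ),
        variables=["var1"],
        population_set="worldwide",
        binning="european",
    )


class TestGwasOverlap:
    def test_threshold_filters(self):
        rt = _mini_rank_table([4e-4, 6e-4, 4e-4], ["rs1", "rs2", "rs3"])
        catalog = pd.DataFrame(
            {
                "snp_id": ["rs1", "rs2", "rs3"],
                "trait": ["height", "psoriasis", "ldl"],
                "p_value": [1e-6, 1e-8, 2e-5],
            }
        )
        out = gwas_overlap(rt, catalog)
        # rs1 passes both; rs2 fails the rank filter; rs3 fails the p filter
        assert out["snp_id"].tolist() == ["rs1"]
        assert out["best_variable"].iloc[0] == "var1"

    def test_double_filter_matches_direct_recomputation(self, small_data, small_pipeline):
        result, _ = small_pipeline
        counts, panel = small_data["counts"], small_data["panel"]
        ranks_eu = es.rank_scan(result, counts, panel, binning="european")
        rng = np.random.default_rng(8)
        ids = rng.choice(ranks_eu.table["snp_id"], size=50, replace=False)
        catalog = pd.DataFrame(
            {"snp_id": ids, "trait": "trait", "p_value": rng.uniform(1e-9, 1e-2, 50)}
        )
        out = gwas_overlap(ranks_eu, catalog, rank_cutoff=0.02, p_cutoff=1e-3)
        # independent recomputation straight from the tables
        tab = ranks_eu.table.set_index("snp_id")
        qcols = [f"q.{v}" for v in ranks_eu.variables]
        expect = {
            row["snp_id"]
            for _, row in catalog.iterrows()
            if row["p_value"] < 1e-3 and (tab.loc[row["snp_id"], qcols] < 0.02).any()
        }
        assert set(out["snp_id"]) == expect

    def test_invariant_to_catalog_row_order(self, small_pipeline, small_data):
        result, _ = small_pipeline
        counts, panel = small_data["counts"], small_data["panel"]
        ranks_eu = es.rank_scan(result, counts, panel, binning="european")
        rng = np.random.default_rng(9)
        ids = rng.choice(ranks_eu.table["snp_id"], size=30, replace=False)
        catalog = pd.DataFrame(
            {"snp_id": ids, "trait": "t", "p_value": rng.uniform(1e-8, 1e-2, 30)}
        )
        a = gwas_overlap(ranks_eu, catalog, rank_cutoff=0.05, p_cutoff=1e-3)
        b = gwas_overlap(
            ranks_eu, catalog.sample(frac=1, random_state=1), rank_cutoff=0.05, p_cutoff=1e-3
        )
        pd.testing.assert_frame_equal(a, b)

    def test_empty_result_allowed(self):
        rt = _mini_rank_table([0.5], ["rs1"])
        catalog = pd.DataFrame({"snp_id": ["rs1"], "trait": ["t"], "p_value": [0.5]})
        out = gwas_overlap(rt, catalog)
        assert len(out) == 0
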