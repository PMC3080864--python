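"""Generator correctness: tree covariance, confounding, drift variance,
planted effects, annotation planting, determinism."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ecoscan as es
from ecoscan.synthetic_data import TreeNode, drift_covariance
from ecoscan.io_formats import PopulationPanel


def test_star_tree_gives_diagonal_covariance():
    root = TreeNode(children=[TreeNode(branch_length=0.3, name=f"p{i}") for i in range(4)])
    names, omega = drift_covariance(root)
    assert np.allclose(omega, 0.3 * np.eye(4))
    assert names == [f"p{i}" for i in range(4)]


def test_clade_shares_stem_branch():
    clade = TreeNode(
        branch_length=0.2,
        children=[TreeNode(branch_length=0.05, name="a"), TreeNode(branch_length=0.07, name="b")],
    )
    root = TreeNode(children=[clade, TreeNode(branch_length=0.4, name="c")])
    names, omega = drift_covariance(root)
    i, j = names.index("a"), names.index("b")
    assert omega[i, j] == pytest.approx(0.2)       # shared stem only
    assert omega[i, i] == pytest.approx(0.25)      # stem + own tip
    assert omega[names.index("c"), i] == 0.0


def test_structure_is_positive_definite_with_regional_blocks(small_data):
    omega = small_data["omega_true"]
    assert np.all(np.linalg.eigvalsh(omega) > 0)
    panel = small_data["panel"]
    regions = panel.table.set_index("population")["region"]
    pops = panel.populations
    same, diff = [], []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            (same if regions[pops[i]] == regions[pops[j]] else diff).append(omega[i, j])
    assert np.mean(same) > np.mean(diff)  # within-region clades are tighter


def test_generators_are_pure_functions_of_seed(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        a = es.simulate_dataset(small_config)
        b = es.simulate_dataset(small_config)
    assert np.array_equal(a["counts"].k, b["counts"].k)
    assert a["env"].equals(b["env"])
    assert a["truth"].table.equals(b["truth"].table)
    assert a["annotations"].equals(b["annotations"])
    assert a["gene_sets"].sets == b["gene_sets"].sets


def test_unconfounded_environment_independent_of_structure():
    """rho = 0: correlation between each variable and the leading structure
    axis matches the exact null (Fisher-z) over 500 replicates."""
    cfg = es.SimulationConfig(seed=11)
    omega, panel, _ = es.sample_population_structure(cfg)
    axis = np.linalg.eigh(omega)[1][:, -1]
    L = len(panel.populations)
    rng = np.random.default_rng(123)
    zs = []
    for _ in range(500):
        env = es.sample_environment(panel, omega, rho=0.0, rng=rng)
        for var in env.columns:
            r = np.corrcoef(env[var], axis)[0, 1]
            zs.append(abs(np.arctanh(r) * np.sqrt(L - 3)))
    mean_abs_z = np.mean(zs)
    # E|z| = sqrt(2/pi) ~ 0.798 under independence; generous 4-sigma band
    assert mean_abs_z < np.sqrt(2 / np.pi) + 4 * np.sqrt(1 - 2 / np.pi) / np.sqrt(len(zs))


def test_fully_confounded_environment_clusters_by_clade():
    clades = [
        TreeNode(branch_length=0.9, children=[TreeNode(branch_length=0.05, name=f"a{i}") for i in range(5)]),
        TreeNode(branch_length=0.9, children=[TreeNode(branch_length=0.05, name=f"b{i}") for i in range(5)]),
    ]
    names, omega = drift_covariance(TreeNode(children=clades))
    table = pd.DataFrame(
        {"population": names, "region": ["A"] * 5 + ["B"] * 5, "n_chromosomes": 100}
    )
    panel = PopulationPanel(table)
    env = es.sample_environment(panel, omega, rho=1.0, rng=5)
    v = ((env - env.mean()) / env.std(ddof=0)).to_numpy()
    groups = np.array([0] * 5 + [1] * 5)
    within = np.mean([v[groups == g].var(axis=0).mean() for g in (0, 1)])
    assert within < 0.35  # shared clade drift dominates within-clade spread


def _flat_panel(n_pops, n_chrom):
    table = pd.DataFrame(
        {
            "population": [f"p{i}" for i in range(n_pops)],
            "region": "Europe",
            "n_chromosomes": n_chrom,
        }
    )
    return PopulationPanel(table)


def test_null_drift_variance_matches_closed_form():
    """With Omega = c I and no effects, the mean squared standardized
    deviation is (c + 1/n)(1 - 1/L) (the centering factor) to MC accuracy."""
    L, n, c, S = 6, 400, 0.05, 4000
    panel = _flat_panel(L, n)
    omega = c * np.eye(L)
    cfg = es.SimulationConfig(
        seed=5, n_populations=L, region_sizes={"Europe": L}, n_snps=S,
        fraction_effect=0.0, eps_bounds=(0.4, 0.6),
        panel_proportions={"panelA": 1.0}, panel_eps_beta={"panelA": (5.0, 5.0)},
    )
    rng = np.random.default_rng(5)
    env = es.sample_environment(panel, omega + 1e-9 * np.eye(L), 0.0, rng)
    counts, _ = es.simulate_allele_counts(panel, omega, env, cfg, rng)
    from ecoscan.null_model import pooled_frequency, standardize_frequencies

    eps = pooled_frequency(counts.k, counts.n)
    y = standardize_frequencies(counts.k, counts.n, eps)
    expected = (c + 1.0 / n) * (1.0 - 1.0 / L)
    assert np.mean(y**2) == pytest.approx(expected, rel=0.05)


def test_planted_effect_tracks_environment():
    """A 5x-drift-scale effect makes the sample frequency strongly rank-
    correlated with its variable across populations."""
    cfg = es.SimulationConfig(seed=9, n_snps=400, fraction_effect=0.1, effect_beta_rel=5.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        data = es.simulate_dataset(cfg)
    truth, counts, env = data["truth"].table, data["counts"], data["env"]
    z = (env - env.mean()) / env.std(ddof=0)
    freqs = counts.frequencies()
    id_to_row = {s: i for i, s in enumerate(counts.snps["snp_id"])}
    rhos = [
        abs(stats.spearmanr(freqs[id_to_row[row["snp_id"]]], z[row["variable"]]).statistic)
        for _, row in truth.loc[truth["effect"]].iterrows()
    ]
    assert np.median(rhos) > 0.85
    assert min(rhos) > 0.5


def test_large_effects_trigger_clipping_warning():
    cfg = es.SimulationConfig(seed=2, n_snps=500, fraction_effect=0.2, effect_beta_rel=8.0)
    omega, panel, _ = es.sample_population_structure(cfg)
    rng = np.random.default_rng(2)
    env = es.sample_environment(panel, omega, 0.5, rng)
    with pytest.warns(UserWarning, match="clipping"):
        es.simulate_allele_counts(panel, omega, env, cfg, rng)


class TestAnnotations:
    def test_relative_risk_one_spreads_effects_uniformly(self):
        cfg = es.SimulationConfig(
            seed=3, n_snps=3000, fraction_effect=0.3,
            rr_genic=1.0, rr_nonsynonymous=1.0, n_enriched_sets=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            data = es.simulate_dataset(cfg)
        ann = data["annotations"].set_index("snp_id")
        truth = data["truth"].table
        eff_classes = ann.loc[truth.loc[truth["effect"], "snp_id"], "class"]
        counts = eff_classes.value_counts()
        expected = np.array([cfg.p_nonsynonymous, cfg.p_genic, 1 - cfg.p_nonsynonymous - cfg.p_genic])
        observed = np.array([counts.get(c, 0) for c in ("nonsynonymous", "genic", "nongenic")])
        p = stats.chisquare(observed, expected * observed.sum()).pvalue
        assert p > 0.001

    def test_no_nonsynonymous_when_proportion_zero(self):
        cfg = es.SimulationConfig(seed=4, n_snps=500, p_nonsynonymous=0.0, rr_nonsynonymous=1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            data = es.simulate_dataset(cfg)
        assert (data["annotations"]["class"] != "nonsynonymous").all()

    def test_enriched_sets_carry_excess_effect_genes(self, small_data):
        ann = small_data["annotations"]
        truth = small_data["truth"].table
        effect_genes = set(
            ann.loc[
                ann["snp_id"].isin(truth.loc[truth["effect"], "snp_id"])
                & (ann["gene_id"] != ""),
                "gene_id",
            ]
        )
        sets = small_data["gene_sets"]
        hits = {
            name: len(effect_genes & sets.genes(name)) for name in sets.sets
        }
        enriched = [v for k, v in hits.items() if "enriched" in k]
        random_sets = [v for k, v in hits.items() if "enriched" not in k]
        assert min(enriched) > 2 * max(np.mean(random_sets), 0.5)
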