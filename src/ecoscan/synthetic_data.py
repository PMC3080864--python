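"""Synthetic datasets with the statistical structure the scan assumes.

The generator is the scan's generative twin: drift is modeled directly on
the frequency scale as a multivariate normal with covariance
``eps (1 - eps) Omega_true`` (``Omega_true`` built from a random
bifurcating population tree via shared branch lengths), frequencies are
clipped away from the boundaries, and observed counts are binomial draws.
A configurable fraction of SNPs carries a true linear effect of one
environmental variable, preferentially placed in genic/nonsynonymous
classes and in designated gene sets, so that parameter recovery and
enrichment power are meaningful end-to-end tests.  Environments can be
confounded with population structure through a mixing weight ``rho``.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    AlleleCountMatrix,
    GeneSetCollection,
    PopulationPanel,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "TreeNode",
    "drift_covariance",
    "sample_population_structure",
    "sample_environment",
    "simulate_allele_counts",
    "assign_annotations",
    "simulate_dataset",
    "DEFAULT_ENV_VARIABLES",
]

#: Default environmental variables with (offset, scale) used to map the
#: unit-variance latent variable into plausible native units.
DEFAULT_ENV_VARIABLES: dict[str, tuple[float, float]] = {
    "abs_latitude": (30.0, 15.0),
    "summer_max_temp": (25.0, 8.0),
    "winter_min_temp": (0.0, 12.0),
    "summer_precip_rate": (3.0, 2.0),
    "winter_precip_rate": (3.0, 2.0),
    "summer_rel_humidity": (65.0, 15.0),
    "winter_rel_humidity": (60.0, 15.0),
    "summer_solar_rad": (250.0, 60.0),
    "winter_solar_rad": (150.0, 60.0),
}

DEFAULT_REGION_SIZES: dict[str, int] = {
    "sub-Saharan Africa": 12,
    "Europe": 10,
    "Middle East": 6,
    "West Asia": 6,
    "East Asia": 12,
    "Oceania": 4,
    "Americas": 10,
}

#: Per-panel Beta(a, b) parameters for the derived-allele frequency anchor;
#: array SNP discovery favors common alleles, with panel-specific skews.
DEFAULT_PANEL_EPS_BETA: dict[str, tuple[float, float]] = {
    "panelA": (1.6, 1.6),
    "panelB": (2.0, 1.4),
    "panelC": (1.4, 2.0),
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    Defaults describe a desk-scale worldwide scan: 60 populations in 7
    regions with 16-160 chromosomes each, 3 ascertainment panels, 20,000
    SNPs every 150 kb on 22 contigs (3 Gb-proportional genome), 2% of SNPs
    with a true linear effect on one variable at |beta| ~ 3x the drift
    scale, effects enriched 3-fold in genic and 5-fold in nonsynonymous
    SNPs, and 2 of 14 gene sets planted as enriched.
    """

    seed: int
    n_populations: int = 60
    region_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REGION_SIZES)
    )
    n_chromosomes_range: tuple[int, int] = (16, 160)
    panel_proportions: dict[str, float] = field(
        default_factory=lambda: {"panelA": 0.5, "panelB": 0.3, "panelC": 0.2}
    )
    panel_eps_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_EPS_BETA)
    )
    eps_bounds: tuple[float, float] = (0.02, 0.98)
    n_snps: int = 20_000
    snp_spacing: int = 150_000
    n_contigs: int = 22
    fraction_effect: float = 0.02
    beta_scale: float = 3.0          # sd of beta relative to the drift scale
    effect_beta_rel: float | None = None  # fixed |beta|/drift-scale instead of N(0, beta_scale)
    confounding_rho: float = 0.5
    env_variables: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ENV_VARIABLES)
    )
    within_branch_scale: float = 0.004
    between_branch_scale: float = 0.012
    tip_branch_scale: float = 0.008
    p_nonsynonymous: float = 0.04
    p_genic: float = 0.36            # genic but not nonsynonymous
    rr_genic: float = 3.0            # relative risk of effect status for genic SNPs
    rr_nonsynonymous: float = 5.0
    gene_span: int = 300_000
    n_gene_sets: int = 14
    genes_per_set: int = 50
    n_enriched_sets: int = 2
    enriched_weight: float = 10.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("SimulationConfig requires a seed")
        for name, frac in [
            ("fraction_effect", self.fraction_effect),
            ("confounding_rho", self.confounding_rho),
            ("p_nonsynonymous", self.p_nonsynonymous),
            ("p_genic", self.p_genic),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {frac}")
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")
        if self.p_nonsynonymous + self.p_genic > 1.0:
            raise ValidationError("class proportions exceed 1")
        if sum(self.region_sizes.values()) < self.n_populations:
            raise ValidationError(
                f"n_populations={self.n_populations} exceeds region capacity "
                f"{sum(self.region_sizes.values())}"
            )

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Population tree and drift covariance


@dataclass
class TreeNode:
    """A rooted population tree node; ``branch_length`` is the edge above it."""

    branch_length: float = 0.0
    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def drift_covariance(root: TreeNode) -> tuple[list[str], np.ndarray]:
    """Covariance implied by shared branch lengths below the root.

    ``Omega[i, j]`` is the summed length of branches on the shared part of
    the root-to-tip paths of leaves i and j; the diagonal is the total
    root-to-tip length.  A star tree therefore gives a diagonal matrix,
    and two leaves under a clade whose stem has length ``s`` share exactly
    ``s`` (plus any deeper shared stems).
    """
    leaves = root.leaves()
    names = [leaf.name or f"leaf{i}" for i, leaf in enumerate(leaves)]
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    L = len(leaves)
    omega = np.zeros((L, L))

    def visit(node: TreeNode, is_root: bool) -> np.ndarray:
        nonlocal omega
        ind = np.zeros(L)
        if not node.children:
            ind[index[id(node)]] = 1.0
        for c in node.children:
            ind += visit(c, False)
        if not is_root and node.branch_length:
            omega += node.branch_length * np.outer(ind, ind)
        return ind

    visit(root, True)
    return names, omega


def _random_join(nodes: list[TreeNode], rng, scale: float) -> TreeNode:
    """Randomly join subtrees pairwise; internal stems ~ Exp(scale)."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(branch_length=float(rng.exponential(scale)), children=[a, b])
        nodes.append(parent)
    return nodes[0]


def sample_population_structure(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, PopulationPanel, TreeNode]:
    """Random bifurcating population tree and its drift covariance.

    Populations are grouped into regions; within-region stems are drawn
    with a shorter scale than the region-joining stems, so regional clades
    are tight relative to between-region divergence.  Tip branches are
    strictly positive, making ``Omega_true`` strictly positive definite.
    Also assigns per-population chromosome counts and the standard subsets
    (worldwide, AWE, AEA).
    """
    if config.n_populations < 3:
        raise ValidationError("need at least 3 populations")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    sizes = dict(config.region_sizes)
    total = sum(sizes.values())
    # trim regions proportionally if capacity exceeds n_populations
    alloc: dict[str, int] = {}
    remaining = config.n_populations
    for r, cap in sizes.items():
        take = min(cap, max(1, round(cap * config.n_populations / total)))
        take = min(take, remaining - (len(sizes) - len(alloc) - 1))
        alloc[r] = max(1, take)
        remaining -= alloc[r]
    while remaining > 0:
        for r in alloc:
            if remaining == 0:
                break
            if alloc[r] < sizes[r]:
                alloc[r] += 1
                remaining -= 1
    while remaining < 0:
        for r in sorted(alloc, key=alloc.get, reverse=True):
            if remaining == 0:
                break
            if alloc[r] > 1:
                alloc[r] -= 1
                remaining += 1

    region_roots = []
    rows = []
    for region, m in alloc.items():
        tips = []
        for i in range(m):
            pop = f"{region.replace(' ', '_')}_{i:02d}"
            tip = TreeNode(
                branch_length=float(config.tip_branch_scale * rng.uniform(0.5, 1.5)),
                name=pop,
            )
            tips.append(tip)
            rows.append({"population": pop, "region": region})
        sub = _random_join(tips, rng, config.within_branch_scale) if m > 1 else tips[0]
        region_roots.append(sub)
    root = _random_join(region_roots, rng, config.between_branch_scale)
    root.branch_length = 0.0

    names, omega = drift_covariance(root)
    order = {n: i for i, n in enumerate(names)}
    rows.sort(key=lambda r: order[r["population"]])
    table = pd.DataFrame(rows)
    lo, hi = config.n_chromosomes_range
    table["n_chromosomes"] = 2 * rng.integers(lo // 2, hi // 2 + 1, size=len(table))

    awe_regions = {"sub-Saharan Africa", "Europe", "Middle East", "West Asia"}
    aea_regions = {"sub-Saharan Africa", "East Asia", "Oceania"}
    subsets = {
        "worldwide": table["population"].tolist(),
        "AWE": table.loc[table["region"].isin(awe_regions), "population"].tolist(),
        "AEA": table.loc[table["region"].isin(aea_regions), "population"].tolist(),
    }
    subsets = {k: v for k, v in subsets.items() if v}
    panel = PopulationPanel(table, subsets)
    return omega, panel, root


# ---------------------------------------------------------------------------
# Environment


def sample_environment(
    panel: PopulationPanel,
    omega_true: np.ndarray,
    rho: float,
    rng: np.random.Generator | int,
    variables: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Environmental variables confounded with structure by weight ``rho``.

    Each variable is ``rho * s + (1 - rho) * e`` where ``s`` is drawn with
    the correlation structure of ``Omega_true`` (unit variances) and ``e``
    is iid standard normal, then mapped affinely into native units.  At
    ``rho = 0`` variables are independent of structure; at ``rho = 1``
    they cluster by clade.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValidationError("confounding rho must be in [0, 1]")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    variables = dict(DEFAULT_ENV_VARIABLES) if variables is None else variables
    L = len(panel.populations)
    diag = np.sqrt(np.diag(omega_true))
    corr = omega_true / np.outer(diag, diag)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(L))
    data = {}
    for var, (loc, scale) in variables.items():
        s = chol @ rng.standard_normal(L)
        e = rng.standard_normal(L)
        v = rho * s + (1.0 - rho) * e
        data[var] = loc + scale * v
    return pd.DataFrame(data, index=pd.Index(panel.populations, name="population"))


# ---------------------------------------------------------------------------
# Allele counts with planted effects


@dataclass
class TruthLabels:
    """Ground truth for simulated SNPs.

    One row per SNP: the frequency anchor ``epsilon``, the effect flag,
    the affected variable (empty if none), the raw-scale effect size
    ``beta`` (frequency change per sd of the variable), the drift scale
    ``sqrt(eps (1-eps) mean-diag(Omega))`` the effect is calibrated
    against, and the generating covariance id.
    """

    table: pd.DataFrame
    covariance_id: str = "omega_true"

    @property
    def effect_ids(self) -> list[str]:
        return self.table.loc[self.table["effect"], "snp_id"].tolist()


def _truncated_beta(rng, a: float, b: float, lo: float, hi: float, size: int) -> np.ndarray:
    u = rng.uniform(stats.beta.cdf(lo, a, b), stats.beta.cdf(hi, a, b), size=size)
    return stats.beta.ppf(u, a, b)


def simulate_allele_counts(
    panel: PopulationPanel,
    omega_true: np.ndarray,
    env: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[AlleleCountMatrix, TruthLabels]:
    """Draw allele counts under the drift model with planted linear effects.

    For each SNP: the anchor frequency ``eps`` comes from its panel's
    truncated Beta; latent frequencies are
    ``x ~ N(eps 1 + beta z, eps (1-eps) Omega_true)`` with ``z`` the
    standardized affected variable (``beta = 0`` for null SNPs); ``x`` is
    clipped to ``[1/(2 n-bar), 1 - 1/(2 n-bar)]``; counts are
    ``Binomial(n_l, theta_l)``.  Genome coordinates are laid out at
    ``snp_spacing`` across ``n_contigs`` contigs.  Warns if clipping
    touches more than 10% of effect-SNP frequencies.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pops = panel.populations
    L = len(pops)
    S = config.n_snps
    n_chrom = panel.n_chromosomes.astype(np.int64)
    env = env.loc[pops]
    z = (env - env.mean()) / env.std(ddof=0)
    z_mat = z.to_numpy(dtype=float)
    var_names = list(env.columns)

    labels = list(config.panel_proportions)
    probs = np.array([config.panel_proportions[p] for p in labels], dtype=float)
    probs = probs / probs.sum()
    snp_panel = rng.choice(labels, size=S, p=probs)

    lo, hi = config.eps_bounds
    eps = np.empty(S)
    for pl in labels:
        a, b = config.panel_eps_beta.get(pl, (1.5, 1.5))
        rows = snp_panel == pl
        eps[rows] = _truncated_beta(rng, a, b, lo, hi, int(rows.sum()))

    drift_scale = np.sqrt(eps * (1.0 - eps) * float(np.mean(np.diag(omega_true))))
    effect = rng.random(S) < config.fraction_effect
    var_idx = rng.integers(0, len(var_names), size=S)
    if config.effect_beta_rel is not None:
        beta_rel = config.effect_beta_rel * rng.choice([-1.0, 1.0], size=S)
    else:
        beta_rel = rng.normal(0.0, config.beta_scale, size=S)
    beta = np.where(effect, beta_rel * drift_scale, 0.0)

    chol = np.linalg.cholesky(omega_true + 1e-12 * np.eye(L))
    g = rng.standard_normal((S, L)) @ chol.T
    mean = eps[:, None] + beta[:, None] * z_mat[:, var_idx].T
    x = mean + np.sqrt(eps * (1.0 - eps))[:, None] * g

    n_bar = float(n_chrom.mean())
    clip_lo, clip_hi = 1.0 / (2.0 * n_bar), 1.0 - 1.0 / (2.0 * n_bar)
    clipped = (x < clip_lo) | (x > clip_hi)
    theta = np.clip(x, clip_lo, clip_hi)
    if effect.any():
        frac_clip = clipped[effect].mean()
        if frac_clip > 0.10:
            warnings.warn(
                f"clipping affected {frac_clip:.1%} of effect-SNP frequencies "
                f"({int(clipped[effect].sum())} values); effect sizes may be "
                "attenuated at the boundaries",
                stacklevel=2,
            )
    k = rng.binomial(n_chrom[None, :].repeat(S, axis=0), theta)
    n = np.broadcast_to(n_chrom, (S, L)).copy()

    per_contig = -(-S // config.n_contigs)  # ceil
    idx = np.arange(S)
    chrom = np.array([f"chr{c + 1}" for c in idx // per_contig])
    pos = (idx % per_contig).astype(np.int64) * config.snp_spacing
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in idx],
            "chrom": chrom,
            "pos": pos,
            "panel": snp_panel,
        }
    )
    counts = AlleleCountMatrix(snps, list(pops), k.astype(np.int64), n)

    truth = pd.DataFrame(
        {
            "snp_id": snps["snp_id"],
            "epsilon": eps,
            "effect": effect,
            "variable": np.where(effect, np.array(var_names, dtype=object)[var_idx], ""),
            "beta": beta,
            "beta_rel": np.where(effect, beta_rel, 0.0),
            "drift_scale": drift_scale,
        }
    )
    return counts, TruthLabels(truth)


# ---------------------------------------------------------------------------
# Annotations and gene sets


def assign_annotations(
    counts: AlleleCountMatrix,
    truth: TruthLabels,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, GeneSetCollection]:
    """Assign functional classes, gene ids and gene sets.

    Null SNPs get class probabilities (NS, genic, nongenic) from the
    config; effect SNPs get those probabilities reweighted by the per-class
    relative risks and renormalized, which plants the configured genic/NS
    excess among effect SNPs.  Genic SNPs map to positional genes
    (``gene_span`` windows); gene sets are random draws over genes, with
    designated enriched sets drawing effect-bearing genes at
    ``enriched_weight``-fold weight.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    S = counts.n_snps
    base = np.array(
        [config.p_nonsynonymous, config.p_genic, 1.0 - config.p_nonsynonymous - config.p_genic]
    )
    rr = np.array([config.rr_nonsynonymous, config.rr_genic, 1.0])
    eff_probs = base * rr
    eff_probs = eff_probs / eff_probs.sum()
    effect = truth.table["effect"].to_numpy(dtype=bool)
    classes = np.empty(S, dtype=object)
    names = np.array(["nonsynonymous", "genic", "nongenic"], dtype=object)
    n_eff = int(effect.sum())
    if n_eff:
        classes[effect] = rng.choice(names, size=n_eff, p=eff_probs)
    classes[~effect] = rng.choice(names, size=S - n_eff, p=base)

    chrom = counts.snps["chrom"].to_numpy()
    pos = counts.snps["pos"].to_numpy()
    gene_ids = np.where(
        classes == "nongenic",
        "",
        np.char.add(
            np.char.add("G_", chrom.astype(str)),
            np.char.add("_", (pos // config.gene_span).astype(str)),
        ),
    )
    ann = pd.DataFrame(
        {"snp_id": counts.snps["snp_id"], "class": classes, "gene_id": gene_ids}
    )

    genic = ann["gene_id"] != ""
    gene_universe = np.array(sorted(ann.loc[genic, "gene_id"].unique()))
    effect_genes = set(ann.loc[genic & effect, "gene_id"])
    if config.n_enriched_sets and config.fraction_effect > 0 and not effect_genes:
        raise ValidationError(
            "infeasible planting: enriched gene sets requested but no genic effect SNPs"
        )
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    gps = min(config.genes_per_set, len(gene_universe))
    for i in range(config.n_gene_sets):
        enriched = i < config.n_enriched_sets and len(effect_genes) > 0
        if enriched:
            w = np.where(
                np.isin(gene_universe, list(effect_genes)), config.enriched_weight, 1.0
            )
            w = w / w.sum()
            members = rng.choice(gene_universe, size=gps, replace=False, p=w)
        else:
            members = rng.choice(gene_universe, size=gps, replace=False)
        name = f"set{i:02d}" + ("_enriched" if enriched else "")
        sets[name] = sorted(members)
        descriptions[name] = "planted-enriched" if enriched else "random"
    return ann, GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# One-call convenience


def simulate_dataset(config: SimulationConfig):
    """Generate the full synthetic study: panel, environment, counts, truth,
    annotations and gene sets, all from one seed.

    Returns a dict with keys ``panel, omega_true, tree, env, counts,
    truth, annotations, gene_sets``.
    """
    rng = np.random.default_rng(config.seed)
    omega, panel, tree = sample_population_structure(config, rng)
    env = sample_environment(panel, omega, config.confounding_rho, rng, config.env_variables)
    counts, truth = simulate_allele_counts(panel, omega, env, config, rng)
    ann, sets = assign_annotations(counts, truth, config, rng)
    return {
        "panel": panel,
        "omega_true": omega,
        "tree": tree,
        "env": env,
        "counts": counts,
        "truth": truth,
        "annotations": ann,
        "gene_sets": sets,
    }
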