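"""Cross-analysis comparisons.

Population-subset scans (covariance re-estimated within the subset so that
region-restricted ecoclines are detectable), tail-overlap statistics
between two rank tables (observed vs. the product-rule expectation under
independence, with Venn region counts), Spearman correlation of per-SNP
minimum ranks, and the GWAS-catalog intersection (strong selection signal
AND strong trait association, with European-frequency binning since most
GWAS are European-ancestry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AlleleCountMatrix, PopulationPanel, ValidationError
from .null_model import estimate_covariance_models
from .env_scan import ScanResult, scan
from .rank_stats import RankTable, rank_scan

__all__ = [
    "OverlapReport",
    "GWAS_RANK_CUTOFF",
    "GWAS_P_CUTOFF",
    "subset_scan",
    "tail_overlap",
    "rank_correlation",
    "gwas_overlap",
]

#: Default per-variable rank and GWAS p-value filters for the catalog overlap.
GWAS_RANK_CUTOFF = 5e-4
GWAS_P_CUTOFF = 1e-5


@dataclass
class OverlapReport:
    """Tail overlap between two analyses at one cutoff."""

    label_a: str
    label_b: str
    cutoff: float
    n_shared: int
    observed: int
    expected: float
    fold: float
    venn: dict  # keys: only_a, only_b, both, neither

    def as_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "cutoff": self.cutoff,
            "n_shared": self.n_shared,
            "observed": self.observed,
            "expected": self.expected,
            "fold": self.fold,
            **{f"venn_{k}": v for k, v in self.venn.items()},
        }


def subset_scan(
    counts: AlleleCountMatrix,
    env: pd.DataFrame,
    panel: PopulationPanel,
    subset: str | list[str] | None = "worldwide",
    tau: float = 1.0,
    n_controls: int = 20_000,
    seed: int = 0,
    binning: str = "global",
    min_controls: int | None = None,
) -> tuple[ScanResult, RankTable]:
    """Full scan + rank pipeline on one population subset.

    The covariance matrices are re-estimated per ascertainment panel on the
    subset's populations before scanning; SNPs monomorphic within the
    subset are excluded there (they may still be scanned worldwide).
    ``subset_scan(..., "worldwide")`` is by construction identical to the
    worldwide pipeline.
    """
    pops = panel.subset_populations(subset)
    if len(pops) < 3:
        raise ValidationError("population subset must contain at least 3 populations")
    label = subset if isinstance(subset, str) else "custom"
    models = estimate_covariance_models(
        counts,
        panel,
        population_set=pops,
        n_controls=n_controls,
        seed=seed,
        min_controls=min_controls,
    )
    for m in models.values():
        m.population_set = label
    result = scan(counts, env, models, panel, population_set=pops, tau=tau, set_label=label)
    ranks = rank_scan(result, counts, panel, binning=binning)
    return result, ranks


def tail_overlap(
    ranks_a: pd.Series | RankTable,
    ranks_b: pd.Series | RankTable,
    cutoff: float,
    label_a: str = "A",
    label_b: str = "B",
) -> OverlapReport:
    """Observed vs. expected-under-independence overlap of two lower tails.

    Restricted to the shared SNP universe (SNPs ranked in both analyses).
    Expected count is ``N * (|tail_A| / N) * (|tail_B| / N)``.
    """
    qa = ranks_a.min_ranks() if isinstance(ranks_a, RankTable) else ranks_a
    qb = ranks_b.min_ranks() if isinstance(ranks_b, RankTable) else ranks_b
    shared = qa.index.intersection(qb.index)
    n = len(shared)
    if n == 0:
        raise ValidationError("tail_overlap: empty shared SNP universe")
    in_a = qa.loc[shared] <= cutoff
    in_b = qb.loc[shared] <= cutoff
    observed = int((in_a & in_b).sum())
    expected = n * (in_a.sum() / n) * (in_b.sum() / n)
    fold = observed / expected if expected > 0 else float("nan")
    venn = {
        "only_a": int((in_a & ~in_b).sum()),
        "only_b": int((~in_a & in_b).sum()),
        "both": observed,
        "neither": int((~in_a & ~in_b).sum()),
    }
    return OverlapReport(label_a, label_b, cutoff, n, observed, float(expected), float(fold), venn)


def rank_correlation(
    minranks_a: pd.Series | RankTable, minranks_b: pd.Series | RankTable
) -> float:
    """Spearman correlation of per-SNP minimum ranks over the shared universe."""
    qa = minranks_a.min_ranks() if isinstance(minranks_a, RankTable) else minranks_a
    qb = minranks_b.min_ranks() if isinstance(minranks_b, RankTable) else minranks_b
    shared = qa.index.intersection(qb.index)
    if len(shared) < 2:
        raise ValidationError("rank_correlation needs at least 2 shared SNPs")
    rho = stats.spearmanr(qa.loc[shared], qb.loc[shared]).statistic
    return float(rho)


def gwas_overlap(
    rank_tables: dict[str, RankTable] | RankTable,
    catalog: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    rank_cutoff: float = GWAS_RANK_CUTOFF,
    p_cutoff: float = GWAS_P_CUTOFF,
) -> pd.DataFrame:
    """Catalog SNPs passing both the selection-rank and the GWAS-p filters.

    A catalog entry is retained when its SNP has any per-variable
    transformed rank below ``rank_cutoff`` in a rank table (computed with
    European-frequency binning for comparability with European-ancestry
    GWAS) AND its association p-value is below ``p_cutoff``.  One output
    row per (SNP, trait, population set) with the best variable, its rank
    and its log10 BF if available; invariant to catalog row order.
    """
    if isinstance(rank_tables, RankTable):
        rank_tables = {rank_tables.population_set: rank_tables}
    gene_of = (
        annotations.set_index("snp_id")["gene_id"]
        if annotations is not None
        else pd.Series(dtype=object)
    )
    catalog = catalog.sort_values(["snp_id", "trait"], kind="mergesort").reset_index(drop=True)
    rows = []
    for set_label, rt in sorted(rank_tables.items()):
        qcols = [f"q.{v}" for v in rt.variables]
        tab = rt.table.set_index("snp_id")
        hits = catalog.loc[
            (catalog["p_value"] < p_cutoff) & catalog["snp_id"].isin(tab.index)
        ]
        for _, entry in hits.iterrows():
            q = tab.loc[entry["snp_id"], qcols].astype(float)
            if not (q < rank_cutoff).any():
                continue
            best = q.idxmin()
            rows.append(
                {
                    "snp_id": entry["snp_id"],
                    "trait": entry["trait"],
                    "gwas_p": entry["p_value"],
                    "population_set": set_label,
                    "best_variable": best[len("q."):],
                    "rank": float(q.min()),
                    "gene_id": gene_of.get(entry["snp_id"], ""),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id", "trait", "gwas_p", "population_set",
            "best_variable", "rank", "gene_id",
        ],
    )
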