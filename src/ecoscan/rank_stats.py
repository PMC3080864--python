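"""Within-bin transformed rank statistics ("empirical p-values").

Bayes factors are not comparable across ascertainment panels or allele-
frequency classes, so SNPs are stratified into bins (ascertainment panel x
derived-allele-frequency decile; 3 panels x 10 deciles = 30 bins at the
default) and each SNP is ranked only against the SNPs in its own bin.  The
transformed rank statistic is ``q = rank / N`` within the bin (descending
BF; the strongest SNP gets ``q = 1/N``), and the per-SNP minimum of ``q``
across variables summarizes the evidence over the whole climate panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AlleleCountMatrix, PopulationPanel, ValidationError
from .null_model import pooled_frequency
from .env_scan import ScanResult

__all__ = [
    "RankTable",
    "assign_bins",
    "transformed_rank",
    "min_rank",
    "rank_scan",
]

logger = logging.getLogger(__name__)

#: Bins smaller than this are merged with the adjacent lower bin.
MIN_BIN_SIZE = 50

#: Tolerance lifting exact decile boundaries (k/n arithmetic) onto the float grid.
_BOUNDARY_EPS = 1e-9


@dataclass
class RankTable:
    """Transformed rank statistics for one scan.

    ``table``: one row per ranked SNP with ``snp_id, chrom, pos, panel,
    bin``, one ``q.<variable>`` column per variable, and ``min_rank``.
    Within each (bin, variable) the q values are exactly the multiset
    {1/N, 2/N, ..., 1}.
    """

    table: pd.DataFrame
    variables: list[str]
    population_set: str = "worldwide"
    binning: str = "global"

    def q_matrix(self) -> np.ndarray:
        return self.table[[f"q.{v}" for v in self.variables]].to_numpy(dtype=float)

    def min_ranks(self) -> pd.Series:
        return self.table.set_index("snp_id")["min_rank"]


def assign_bins(
    freqs: np.ndarray,
    panel_labels: np.ndarray,
    n_bins: int = 10,
    min_bin_size: int = MIN_BIN_SIZE,
) -> np.ndarray:
    """Assign each SNP a bin id ``"<panel>:<decile>"``.

    Deciles are equal-width half-open intervals on (0,1): frequency 0.10
    falls in decile 1 ([0.1, 0.2)), and the top decile is capped at index
    ``n_bins - 1``.  Within each panel, deciles holding fewer than
    ``min_bin_size`` SNPs are merged with the adjacent lower decile
    (recursively; a sparse lowest decile merges upward); merges are logged.
    """
    freqs = np.asarray(freqs, dtype=float)
    panel_labels = np.asarray(panel_labels)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValidationError("bin frequencies must lie in [0, 1]")
    deciles = np.minimum(
        np.floor(freqs * n_bins + _BOUNDARY_EPS).astype(int), n_bins - 1
    )
    deciles = np.maximum(deciles, 0)

    out = np.empty(len(freqs), dtype=object)
    for pl in np.unique(panel_labels):
        in_panel = panel_labels == pl
        counts = np.bincount(deciles[in_panel], minlength=n_bins)
        # groups of occupied deciles, ascending; sparse groups merge into the
        # adjacent lower group (the lowest merges upward) until all are full
        groups: list[tuple[int, list[int], int]] = [
            (b, [b], int(counts[b])) for b in range(n_bins) if counts[b] > 0
        ]
        while len(groups) > 1:
            sparse = [i for i, (_, _, size) in enumerate(groups) if size < min_bin_size]
            if not sparse:
                break
            i = sparse[-1]
            j = i - 1 if i > 0 else 1
            _, members, size = groups[i]
            label, tgt_members, tgt_size = groups[j]
            logger.info(
                "assign_bins: panel %s deciles %s (%d SNPs) merged into bin %d",
                pl, members, size, label,
            )
            groups[min(i, j)] = (label, sorted(tgt_members + members), tgt_size + size)
            del groups[max(i, j)]
        mapping = np.arange(n_bins)
        for label, members, _ in groups:
            for b in members:
                mapping[b] = label
        out[in_panel] = [f"{pl}:{mapping[d]}" for d in deciles[in_panel]]
    return out


def transformed_rank(log10_bfs: np.ndarray, snp_ids: np.ndarray) -> np.ndarray:
    """Rank statistics within one bin for one variable.

    SNPs are sorted by descending log10 BF, ties broken by ascending
    snp_id; ``q = rank / N`` so the strongest SNP gets ``1/N`` and the
    weakest exactly 1.
    """
    bfs = np.asarray(log10_bfs, dtype=float)
    ids = np.asarray(snp_ids)
    if len(bfs) == 0:
        raise ValidationError("transformed_rank: empty bin")
    order = np.lexsort((ids, -bfs))
    n = len(bfs)
    q = np.empty(n, dtype=float)
    q[order] = np.arange(1, n + 1) / n
    return q


def min_rank(q_matrix: np.ndarray) -> np.ndarray:
    """Per-SNP minimum transformed rank across variables (NaN-ignoring)."""
    q = np.asarray(q_matrix, dtype=float)
    if q.ndim != 2 or q.shape[1] == 0:
        raise ValidationError("min_rank needs at least one ranked variable")
    if np.isnan(q).all(axis=1).any():
        raise ValidationError("min_rank: a SNP has no ranked variable")
    return np.nanmin(q, axis=1)


def rank_scan(
    scan_result: ScanResult,
    counts: AlleleCountMatrix,
    panel: PopulationPanel,
    binning: str = "global",
    european_regions: tuple[str, ...] = ("Europe",),
    n_bins: int = 10,
    min_bin_size: int = MIN_BIN_SIZE,
) -> RankTable:
    """Build the RankTable for a scan.

    ``binning="global"`` bins on the pooled derived-allele frequency over
    the scanned population set (the scan's own ``eps_hat``);
    ``binning="european"`` bins on the pooled frequency over populations
    whose region is in ``european_regions`` (used for GWAS-catalog
    comparisons, since most GWAS are European-ancestry).  SNPs flagged
    ``excluded`` by the scan are not ranked.
    """
    tab = scan_result.table
    keep = ~tab["excluded"].to_numpy(dtype=bool)
    tab = tab.loc[keep].reset_index(drop=True)
    if len(tab) == 0:
        raise ValidationError("rank_scan: no non-excluded SNPs")

    if binning == "global":
        freqs = tab["eps_hat"].to_numpy(dtype=float)
    elif binning == "european":
        regions = panel.regions_of(panel.populations)
        euro_pops = [p for p in panel.populations if regions[p] in european_regions]
        if not euro_pops:
            raise ValidationError("no populations in the European region list")
        sub = counts.restrict(euro_pops)
        id_to_row = pd.Series(np.arange(sub.n_snps), index=sub.snps["snp_id"])
        rows = id_to_row.loc[tab["snp_id"]].to_numpy()
        tot = sub.n[rows].sum(axis=1)
        if np.any(tot == 0):
            raise ValidationError("a SNP has no European chromosome counts")
        freqs = sub.k[rows].sum(axis=1) / tot
    else:
        raise ValidationError(f"unknown binning scheme {binning!r}")

    bins = assign_bins(freqs, tab["panel"].to_numpy(), n_bins, min_bin_size)
    out = tab[["snp_id", "chrom", "pos", "panel"]].copy()
    out["bin"] = bins
    ids = tab["snp_id"].to_numpy()
    for var in scan_result.variables:
        col = tab[f"log10bf.{var}"].to_numpy(dtype=float)
        q = np.full(len(tab), np.nan)
        ok = np.isfinite(col)
        for b in np.unique(bins[ok]):
            rows = np.flatnonzero(ok & (bins == b))
            q[rows] = transformed_rank(col[rows], ids[rows])
        out[f"q.{var}"] = q
    out["min_rank"] = min_rank(
        out[[f"q.{v}" for v in scan_result.variables]].to_numpy(dtype=float)
    )
    return RankTable(
        table=out,
        variables=list(scan_result.variables),
        population_set=scan_result.population_set,
        binning=binning,
    )
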