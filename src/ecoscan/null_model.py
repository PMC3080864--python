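"""Population-structure null model.

The null for the scan is that, after standardization, the vector of
population allele-frequency deviations for a SNP is multivariate normal
with mean zero and covariance ``Omega + D``: ``Omega`` captures correlated
drift due to shared population history and ``D`` the binomial sampling
noise from finite chromosome counts (``D_ll = 1/n_l``).  ``Omega`` is
estimated per ascertainment panel and per population set from a large set
of randomly chosen control SNPs by a moment estimator with a sampling-noise
correction and a PSD projection.

Identifiability note: the per-SNP frequency anchor is the pooled
(count-weighted) sample frequency, so deviations are centered at the
weighted mean and the component of the drift covariance along the all-ones
vector is absorbed by the anchor.  The estimator is consistent for the
centered covariance ``P (Omega + D) P^T - D`` with ``P = I - 1 w^T``; the
scan uses the same centered deviations, so null and statistic are mutually
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .io_formats import AlleleCountMatrix, PopulationPanel, ValidationError

__all__ = [
    "CovarianceModel",
    "pooled_frequency",
    "standardize_frequencies",
    "estimate_covariance",
    "estimate_covariance_models",
    "centered_covariance_target",
]

#: Relative eigenvalue floor applied when projecting the estimate to PSD.
PSD_FLOOR_REL = 1e-6


@dataclass
class CovarianceModel:
    """Estimated drift covariance plus sampling-variance diagonal.

    ``omega`` is the drift covariance on the standardized-frequency scale
    (symmetric, PSD after eigenvalue flooring); ``d`` holds the per-
    population sampling variances ``1/n_l`` (``n_l`` = mean chromosome
    count over control SNPs).
    """

    populations: list[str]
    omega: np.ndarray
    d: np.ndarray
    panel: str | None = None
    population_set: str = "worldwide"
    n_control_snps: int = 0
    _cho: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        L = len(self.populations)
        self.omega = np.asarray(self.omega, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.omega.shape != (L, L) or self.d.shape != (L,):
            raise ValidationError("covariance model dimensions inconsistent")
        if not np.allclose(self.omega, self.omega.T, atol=1e-10):
            raise ValidationError("omega is not symmetric")
        if np.any(self.d <= 0):
            raise ValidationError("sampling-variance diagonal must be strictly positive")

    @property
    def sigma(self) -> np.ndarray:
        """Total null covariance ``Omega + D``."""
        return self.omega + np.diag(self.d)

    def cho(self):
        """Cached Cholesky factorization of sigma."""
        if self._cho is None:
            object.__setattr__(self, "_cho", cho_factor(self.sigma))
        return self._cho

    def solve(self, b: np.ndarray) -> np.ndarray:
        return cho_solve(self.cho(), b)

    def permute(self, order: np.ndarray) -> "CovarianceModel":
        """Consistently reorder populations (equivariance helper)."""
        return CovarianceModel(
            [self.populations[i] for i in order],
            self.omega[np.ix_(order, order)],
            self.d[order],
            self.panel,
            self.population_set,
            self.n_control_snps,
        )


def pooled_frequency(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Pooled derived-allele frequency ``sum(k) / sum(n)`` per SNP.

    Accepts 1-D (one SNP) or 2-D (SNP x population) arrays.  A pooled
    frequency of exactly 0 or 1 marks the SNP monomorphic in this
    population set; callers exclude such SNPs from covariance estimation,
    scanning and ranking.
    """
    k = np.atleast_2d(np.asarray(k))
    n = np.atleast_2d(np.asarray(n))
    tot = n.sum(axis=1)
    if np.any(tot <= 0):
        raise ValidationError("pooled_frequency: total chromosome count is zero")
    eps = k.sum(axis=1) / tot
    return eps if eps.size > 1 else eps.reshape(-1)


def monomorphic_mask(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """True where the SNP is monomorphic (pooled frequency 0 or 1)."""
    eps = pooled_frequency(k, n)
    return (eps <= 0.0) | (eps >= 1.0)


def standardize_frequencies(k: np.ndarray, n: np.ndarray, eps: np.ndarray | float) -> np.ndarray:
    """Standardized frequency deviations ``(k/n - eps) / sqrt(eps (1-eps))``.

    Populations with ``n == 0`` (per-SNP missingness) yield NaN and are
    masked downstream.  ``eps`` must be strictly inside (0, 1).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    eps_arr = np.asarray(eps, dtype=float)
    if np.any((eps_arr <= 0) | (eps_arr >= 1)):
        raise ValidationError("standardize_frequencies: monomorphic SNP (eps in {0,1})")
    scale = np.sqrt(eps_arr * (1.0 - eps_arr))
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    if np.ndim(eps_arr) == 1 and np.ndim(p_hat) == 2:
        return (p_hat - eps_arr[:, None]) / scale[:, None]
    return (p_hat - eps_arr) / scale


def _psd_project(m: np.ndarray, floor_rel: float = PSD_FLOOR_REL) -> tuple[np.ndarray, float]:
    """Project a symmetric matrix to PSD by eigenvalue flooring."""
    m = 0.5 * (m + m.T)
    vals, vecs = np.linalg.eigh(m)
    pos = vals[vals > 0]
    floor = floor_rel * (pos.mean() if len(pos) else 1.0)
    vals = np.maximum(vals, floor)
    out = (vecs * vals) @ vecs.T
    return 0.5 * (out + out.T), floor


def estimate_covariance(
    counts: AlleleCountMatrix,
    panel: PopulationPanel,
    snp_panel: str | None = None,
    population_set: str | list[str] | None = None,
    n_controls: int = 20_000,
    seed: int = 0,
    min_controls: int | None = None,
) -> CovarianceModel:
    """Estimate the drift covariance from randomly chosen control SNPs.

    Controls are a seeded uniform subset (without replacement) of the
    non-monomorphic SNPs in the given ascertainment panel.  The raw moment
    matrix ``C = mean(y y^T)`` over controls (pairwise-complete when some
    populations are masked per SNP) is corrected for sampling noise,
    ``Omega = C - D`` with ``D_ll = 1 / mean(n_l)``, then projected to PSD
    by flooring eigenvalues at ``1e-6`` times the mean positive eigenvalue.
    """
    pops = panel.subset_populations(population_set)
    sub = counts.restrict(pops)
    if snp_panel is not None:
        in_panel = (sub.snps["panel"] == snp_panel).to_numpy()
    else:
        in_panel = np.ones(sub.n_snps, dtype=bool)
    if not in_panel.any():
        raise ValidationError(f"no SNPs in ascertainment panel {snp_panel!r}")
    k = sub.k[in_panel]
    n = sub.n[in_panel]
    eps = pooled_frequency(k, n)
    poly = (eps > 0.0) & (eps < 1.0)
    if (n[poly].sum(axis=0) == 0).any():
        j = int(np.argmax(n[poly].sum(axis=0) == 0))
        raise ValidationError(f"population {pops[j]!r} has no data across control SNPs")
    avail = int(poly.sum())
    L = len(pops)
    needed = max(500, 5 * L) if min_controls is None else min_controls
    if avail < needed:
        raise ValidationError(
            f"too few non-monomorphic control SNPs: {avail} < required {needed}"
        )
    rng = np.random.default_rng(seed)
    poly_idx = np.flatnonzero(poly)
    m = min(n_controls, avail)
    chosen = np.sort(rng.choice(poly_idx, size=m, replace=False))
    y = standardize_frequencies(k[chosen], n[chosen], eps[chosen])

    mask = np.isfinite(y)
    if mask.all():
        c = (y.T @ y) / m
    else:
        yz = np.where(mask, y, 0.0)
        pair_counts = mask.astype(float).T @ mask.astype(float)
        if (pair_counts == 0).any():
            raise ValidationError("a population pair has no jointly observed control SNPs")
        c = (yz.T @ yz) / pair_counts

    n_bar = np.where(mask, n[chosen], np.nan)
    n_bar = np.nanmean(n_bar, axis=0)
    d = 1.0 / n_bar
    omega, _ = _psd_project(c - np.diag(d))
    return CovarianceModel(
        populations=list(pops),
        omega=omega,
        d=d,
        panel=snp_panel,
        population_set=population_set if isinstance(population_set, str) else (
            "worldwide" if population_set is None else "custom"
        ),
        n_control_snps=m,
    )


def estimate_covariance_models(
    counts: AlleleCountMatrix,
    panel: PopulationPanel,
    population_set: str | list[str] | None = None,
    n_controls: int = 20_000,
    seed: int = 0,
    min_controls: int | None = None,
) -> dict[str, CovarianceModel]:
    """One CovarianceModel per ascertainment panel present in ``counts``."""
    out = {}
    for snp_panel in sorted(counts.snps["panel"].unique()):
        out[snp_panel] = estimate_covariance(
            counts,
            panel,
            snp_panel=snp_panel,
            population_set=population_set,
            n_controls=n_controls,
            seed=seed,
            min_controls=min_controls,
        )
    return out


def centered_covariance_target(
    omega_true: np.ndarray, n_chromosomes: np.ndarray
) -> np.ndarray:
    """Large-sample limit of the covariance estimator for a known generator.

    With the pooled-frequency anchor, the estimator converges to
    ``P (Omega + D) P^T - D`` where ``P = I - 1 w^T`` and ``w`` are the
    chromosome-count weights.  Used by consistency tests, not by the
    pipeline itself.
    """
    n = np.asarray(n_chromosomes, dtype=float)
    w = n / n.sum()
    L = len(n)
    p = np.eye(L) - np.outer(np.ones(L), w)
    d = np.diag(1.0 / n)
    s = np.asarray(omega_true, dtype=float) + d
    return p @ s @ p.T - d
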