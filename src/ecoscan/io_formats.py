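"""Domain types and tabular readers/writers.

All external files are plain TSV (tab-separated, UTF-8, ``.`` decimal, no
quoting; lines starting with ``#`` before the header are comments), except
gene sets, which use the standard GMT format.  In-memory containers keep a
canonical population order (the panel order) regardless of file column
order, and every reader validates its invariants up front rather than
failing downstream.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "PopulationPanel",
    "AlleleCountMatrix",
    "GeneSetCollection",
    "REGIONS",
    "read_population_panel",
    "write_population_panel",
    "read_allele_counts",
    "write_allele_counts",
    "read_environment",
    "write_environment",
    "read_annotations",
    "write_annotations",
    "read_gene_sets",
    "write_gene_sets",
    "read_gwas_catalog",
    "write_gwas_catalog",
    "write_scan_results",
    "read_scan_results",
    "write_rank_table",
    "read_rank_table",
    "write_enrichment_report",
    "read_tsv",
    "write_tsv",
    "file_checksum",
]

#: Canonical region labels for worldwide human population panels.
REGIONS = (
    "sub-Saharan Africa",
    "Europe",
    "Middle East",
    "West Asia",
    "East Asia",
    "Oceania",
    "Americas",
)

FUNCTIONAL_CLASSES = ("nonsynonymous", "genic", "nongenic")


class ValidationError(ValueError):
    """An input table violated a declared invariant.

    The message always names the offending row/column/value so that a user
    can locate the problem in the file.
    """


# ---------------------------------------------------------------------------
# TSV plumbing


def read_tsv(path) -> pd.DataFrame:
    """Read a TSV file, skipping '#'-prefixed comment lines before the header."""
    return pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str})


def write_tsv(df: pd.DataFrame, path, float_format: str | None = None) -> str:
    """Write a DataFrame as TSV with deterministic column order (as given)."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
    return str(path)


def file_checksum(path) -> str:
    """SHA-256 of a file, used for run logging."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Population panel


@dataclass
class PopulationPanel:
    """The sampled populations: ids, region labels, chromosome counts, subsets.

    ``subsets`` maps a subset name (e.g. ``"worldwide"``, ``"AWE"``,
    ``"AEA"``) to an ordered list of population ids; every subset is a
    nonempty sub-list of the worldwide list, and ``"worldwide"`` is always
    present.
    """

    table: pd.DataFrame  # columns: population, region, n_chromosomes
    subsets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"population", "region", "n_chromosomes"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValidationError(f"panel table missing columns: {sorted(missing)}")
        pops = self.table["population"].tolist()
        if len(set(pops)) != len(pops):
            dup = self.table["population"][self.table["population"].duplicated()]
            raise ValidationError(f"duplicate population id: {dup.iloc[0]!r}")
        bad = self.table.loc[self.table["n_chromosomes"] < 2, "population"]
        if len(bad):
            raise ValidationError(f"population {bad.iloc[0]!r} has n_chromosomes < 2")
        self.subsets.setdefault("worldwide", list(pops))
        for name, members in self.subsets.items():
            if not members:
                raise ValidationError(f"subset {name!r} is empty")
            unknown = set(members) - set(pops)
            if unknown:
                raise ValidationError(
                    f"subset {name!r} names unknown populations: {sorted(unknown)}"
                )

    @property
    def populations(self) -> list[str]:
        return self.table["population"].tolist()

    @property
    def n_chromosomes(self) -> np.ndarray:
        return self.table["n_chromosomes"].to_numpy()

    def subset_populations(self, subset: str | list[str] | None) -> list[str]:
        """Resolve a subset name (or explicit list, or None=worldwide) to ids."""
        if subset is None:
            return self.populations
        if isinstance(subset, str):
            if subset not in self.subsets:
                raise KeyError(f"unknown population subset {subset!r}")
            return list(self.subsets[subset])
        unknown = set(subset) - set(self.populations)
        if unknown:
            raise ValidationError(f"unknown populations: {sorted(unknown)}")
        return list(subset)

    def regions_of(self, populations: list[str]) -> pd.Series:
        t = self.table.set_index("population")
        return t.loc[populations, "region"]


def read_population_panel(path) -> PopulationPanel:
    df = read_tsv(path)
    subset_cols = [c for c in df.columns if c.startswith("subset.")]
    subsets = {}
    for col in subset_cols:
        name = col[len("subset."):]
        subsets[name] = df.loc[df[col].astype(bool), "population"].tolist()
    core = df[["population", "region", "n_chromosomes"]].copy()
    return PopulationPanel(core, subsets)


def write_population_panel(panel: PopulationPanel, path) -> str:
    df = panel.table.copy()
    for name, members in panel.subsets.items():
        if name == "worldwide":
            continue
        df[f"subset.{name}"] = df["population"].isin(members).astype(int)
    return write_tsv(df, path)


# ---------------------------------------------------------------------------
# Allele counts


@dataclass
class AlleleCountMatrix:
    """Per-SNP, per-population derived/total chromosome counts.

    ``snps`` has one row per SNP with columns ``snp_id, chrom, pos, panel``
    (positions 0-based); ``k`` and ``n`` are ``(n_snps, n_populations)``
    integer arrays aligned with ``populations`` (canonical panel order).
    Missing per-SNP genotypes are represented by a reduced ``n``, never by
    sentinel counts.
    """

    snps: pd.DataFrame
    populations: list[str]
    k: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        self.k = np.asarray(self.k)
        self.n = np.asarray(self.n)
        req = {"snp_id", "chrom", "pos", "panel"}
        missing = req - set(self.snps.columns)
        if missing:
            raise ValidationError(f"snp table missing columns: {sorted(missing)}")
        s, p = self.k.shape
        if self.n.shape != (s, p) or len(self.snps) != s or len(self.populations) != p:
            raise ValidationError("allele count matrix dimensions are inconsistent")
        if not (np.issubdtype(self.k.dtype, np.integer) and np.issubdtype(self.n.dtype, np.integer)):
            raise ValidationError("allele counts must be integers")
        ids = self.snps["snp_id"]
        if ids.duplicated().any():
            raise ValidationError(f"duplicate snp_id: {ids[ids.duplicated()].iloc[0]!r}")
        if (self.k < 0).any() or (self.n < 0).any():
            raise ValidationError("negative allele counts")
        bad = np.argwhere(self.k > self.n)
        if len(bad):
            i, j = bad[0]
            raise ValidationError(
                f"k > n at snp {ids.iloc[i]!r}, population {self.populations[j]!r} "
                f"(k={self.k[i, j]}, n={self.n[i, j]})"
            )

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def population_index(self, populations: list[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.populations)}
        try:
            return np.array([lookup[p] for p in populations], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"unknown population {exc.args[0]!r}") from exc

    def restrict(self, populations: list[str]) -> "AlleleCountMatrix":
        """Return a view on a subset of populations, preserving SNP order."""
        idx = self.population_index(populations)
        return AlleleCountMatrix(self.snps.copy(), list(populations), self.k[:, idx], self.n[:, idx])

    def frequencies(self) -> np.ndarray:
        """Per-population sample frequencies (NaN where n == 0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n > 0, self.k / np.maximum(self.n, 1), np.nan)


def read_allele_counts(path, panel: PopulationPanel | None = None) -> AlleleCountMatrix:
    """Read an allele-count TSV (``snp_id chrom pos panel`` then ``<pop>.k``/``<pop>.n``).

    If ``panel`` is given, populations are matched by name and reordered to
    the panel's canonical order; populations in the file but not the panel
    raise, as do panel populations absent from the file.
    """
    df = read_tsv(path)
    fixed = ["snp_id", "chrom", "pos", "panel"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ValidationError(f"allele count table missing columns: {missing}")
    kcols = [c for c in df.columns if c.endswith(".k")]
    pops_in_file = [c[:-2] for c in kcols]
    for p in pops_in_file:
        if f"{p}.n" not in df.columns:
            raise ValidationError(f"population {p!r} has a .k column but no .n column")
    if panel is not None:
        extra = set(pops_in_file) - set(panel.populations)
        if extra:
            raise ValidationError(f"populations not in panel: {sorted(extra)}")
        absent = set(panel.populations) - set(pops_in_file)
        if absent:
            raise ValidationError(f"panel populations missing from file: {sorted(absent)}")
        pops = panel.populations
    else:
        pops = pops_in_file
    for p in pops:
        for suffix in (".k", ".n"):
            col = df[p + suffix]
            if not np.issubdtype(col.dtype, np.integer):
                if not np.all(np.mod(col.dropna(), 1) == 0):
                    raise ValidationError(f"non-integer counts in column {p + suffix!r}")
    k = df[[f"{p}.k" for p in pops]].to_numpy(dtype=np.int64)
    n = df[[f"{p}.n" for p in pops]].to_numpy(dtype=np.int64)
    snps = df[fixed].copy()
    snps["pos"] = snps["pos"].astype(np.int64)
    return AlleleCountMatrix(snps, list(pops), k, n)


def write_allele_counts(counts: AlleleCountMatrix, path) -> str:
    df = counts.snps.copy()
    for j, p in enumerate(counts.populations):
        df[f"{p}.k"] = counts.k[:, j]
        df[f"{p}.n"] = counts.n[:, j]
    return write_tsv(df, path)


# ---------------------------------------------------------------------------
# Environment table


def read_environment(path, panel: PopulationPanel | None = None) -> pd.DataFrame:
    """Read an environment TSV (``population`` + one column per variable).

    Returns a DataFrame indexed by population in canonical panel order with
    one float column per environmental variable.
    """
    df = read_tsv(path)
    if "population" not in df.columns:
        raise ValidationError("environment table missing 'population' column")
    df = df.set_index("population")
    if df.index.duplicated().any():
        raise ValidationError(
            f"duplicate population row: {df.index[df.index.duplicated()][0]!r}"
        )
    if not np.all(np.isfinite(df.to_numpy(dtype=float))):
        bad = df.columns[~np.isfinite(df.to_numpy(dtype=float)).all(axis=0)][0]
        raise ValidationError(f"non-finite values in environment variable {bad!r}")
    if panel is not None:
        absent = set(panel.populations) - set(df.index)
        if absent:
            raise ValidationError(
                f"environment table missing populations: {sorted(absent)}"
            )
        df = df.loc[panel.populations]
    return df.astype(float)


def write_environment(env: pd.DataFrame, path) -> str:
    return write_tsv(env.reset_index().rename(columns={"index": "population"}), path)


# ---------------------------------------------------------------------------
# Annotations


def read_annotations(path, counts: AlleleCountMatrix | None = None, permissive: bool = False) -> pd.DataFrame:
    """Read a SNP annotation TSV (``snp_id  class  gene_id``).

    Classes must be one of nonsynonymous/genic/nongenic; nonsynonymous rows
    must carry a gene_id.  Unknown SNPs (not in ``counts``) raise unless
    ``permissive``.
    """
    df = read_tsv(path)
    req = {"snp_id", "class", "gene_id"}
    missing = req - set(df.columns)
    if missing:
        raise ValidationError(f"annotation table missing columns: {sorted(missing)}")
    df = df.copy()
    df["gene_id"] = df["gene_id"].fillna("").astype(str)
    bad = ~df["class"].isin(FUNCTIONAL_CLASSES)
    if bad.any():
        raise ValidationError(f"unknown functional class {df.loc[bad, 'class'].iloc[0]!r}")
    ns_nogene = (df["class"] == "nonsynonymous") & (df["gene_id"] == "")
    if ns_nogene.any():
        raise ValidationError(
            f"nonsynonymous snp {df.loc[ns_nogene, 'snp_id'].iloc[0]!r} has no gene_id"
        )
    if counts is not None:
        unknown = set(df["snp_id"]) - set(counts.snps["snp_id"])
        if unknown and not permissive:
            raise ValidationError(
                f"annotation names {len(unknown)} SNPs absent from the count matrix, "
                f"e.g. {sorted(unknown)[0]!r}"
            )
        if unknown:
            df = df[~df["snp_id"].isin(unknown)].reset_index(drop=True)
    return df


def write_annotations(ann: pd.DataFrame, path) -> str:
    return write_tsv(ann[["snp_id", "class", "gene_id"]], path)


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets with a free-text provenance/description per set."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, name: str) -> set[str]:
        return set(self.sets[name])


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: ``name <tab> description <tab> gene1 <tab> gene2 ...``."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"malformed GMT line {lineno}: fewer than 3 tab-separated fields"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValidationError(f"duplicate gene set name {name!r} (line {lineno})")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> str:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")
    return str(path)


# ---------------------------------------------------------------------------
# GWAS catalog


def read_gwas_catalog(path) -> pd.DataFrame:
    """Read a GWAS catalog extract TSV (``snp_id  trait  p_value``)."""
    df = read_tsv(path)
    req = {"snp_id", "trait", "p_value"}
    missing = req - set(df.columns)
    if missing:
        raise ValidationError(f"GWAS catalog missing columns: {sorted(missing)}")
    bad = ~((df["p_value"] > 0) & (df["p_value"] <= 1))
    if bad.any():
        row = df.loc[bad].iloc[0]
        raise ValidationError(
            f"GWAS p-value out of (0,1] for snp {row['snp_id']!r}: {row['p_value']}"
        )
    if df.duplicated(subset=["snp_id", "trait"]).any():
        row = df[df.duplicated(subset=["snp_id", "trait"])].iloc[0]
        raise ValidationError(f"duplicate (snp_id, trait) pair: {(row['snp_id'], row['trait'])}")
    return df.reset_index(drop=True)


def write_gwas_catalog(catalog: pd.DataFrame, path) -> str:
    return write_tsv(catalog[["snp_id", "trait", "p_value"]], path)


# ---------------------------------------------------------------------------
# Result writers (scan / rank / enrichment)


def write_scan_results(scan_result, path) -> str:
    """Write a ScanResult as TSV; log10 BF columns fixed at 4 decimals.

    Byte-deterministic for a given object: column order is snp metadata
    followed by per-variable BF columns in scan order.
    """
    df = scan_result.table.copy()
    bf_cols = [c for c in df.columns if c.startswith("log10bf.")]
    for c in bf_cols:
        df[c] = df[c].map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
    buf = io.StringIO()
    buf.write(f"# population_set={scan_result.population_set}\ttau={scan_result.tau}\n")
    df.to_csv(buf, sep="\t", index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
    return str(path)


def read_scan_results(path):
    from .env_scan import ScanResult

    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    meta = dict(
        item.split("=", 1) for item in header.lstrip("#").strip().split("\t") if "=" in item
    )
    df = read_tsv(path)
    variables = [c[len("log10bf."):] for c in df.columns if c.startswith("log10bf.")]
    return ScanResult(
        table=df,
        variables=variables,
        population_set=meta.get("population_set", "worldwide"),
        tau=float(meta.get("tau", "1.0")),
    )


def write_rank_table(rank_table, path) -> str:
    """Write a RankTable as TSV; rank statistics at full (repr) precision."""
    df = rank_table.table.copy()
    buf = io.StringIO()
    buf.write(
        f"# population_set={rank_table.population_set}\tbinning={rank_table.binning}\n"
    )
    df.to_csv(buf, sep="\t", index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
    return str(path)


def read_rank_table(path):
    from .rank_stats import RankTable

    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    meta = dict(
        item.split("=", 1) for item in header.lstrip("#").strip().split("\t") if "=" in item
    )
    df = read_tsv(path)
    variables = [c[len("q."):] for c in df.columns if c.startswith("q.")]
    return RankTable(
        table=df,
        variables=variables,
        population_set=meta.get("population_set", "worldwide"),
        binning=meta.get("binning", "global"),
    )


def write_enrichment_report(report, path) -> str:
    """Write an EnrichmentReport summary as TSV (one row per comparison x cutoff)."""
    df = report.summary.copy()
    for c in ("ratio", "frac_enriched"):
        df[c] = df[c].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    return write_tsv(df, path)
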