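# ecoscan

Genome scans for spatially-varying selection from allele-frequency /
environment correlations, with population structure as the null.

`ecoscan` is for population geneticists who want to ask, SNP by SNP,
whether derived-allele frequencies across a worldwide panel of population
samples track an environmental gradient (temperature, precipitation,
humidity, solar radiation, latitude) more strongly than shared population
history alone can explain — and then whether the strongest signals
concentrate in functional sequence classes, in particular gene sets, in
geographic population subsets, or among GWAS-associated variants.

## The model

For one SNP, let `k_l / n_l` be the derived-allele count over `n_l`
sampled chromosomes in population `l`, and let
`ε̂ = Σk / Σn` be the pooled frequency.  Standardized deviations

    y_l = (k_l/n_l − ε̂) / sqrt(ε̂(1−ε̂))

are modeled under the null as multivariate normal,
`y ~ N(0, Σ)`, `Σ = Ω + D`, where `Ω` is the across-population drift
covariance (estimated per ascertainment panel from a large random set of
control SNPs) and `D = diag(1/n_l)` accounts for binomial sampling.  The
alternative adds a linear effect of a standardized environmental variable
`z`: `y ~ N(βz, Σ)` with conjugate prior `β ~ N(0, τ²)`.  Integrating `β`
gives a closed-form Bayes factor,

    A = zᵀΣ⁻¹z,  b = zᵀΣ⁻¹y,
    BF = (1 + τ²A)^(−1/2) · exp( τ²b² / (2(1 + τ²A)) ).

Because BFs are not comparable across ascertainment schemes or frequency
classes — and can be inflated when the null is imperfect — inference uses
the **transformed rank statistic** (an "empirical p-value"): SNPs are
binned by ascertainment panel × derived-allele-frequency decile (30 bins
for 3 panels) and each SNP's BF is ranked only within its bin,
`q = rank/N ∈ (0, 1]`, small = strong.  The per-SNP minimum of `q` across
all variables summarizes evidence for climate as a whole.

Functional enrichment compares the proportion of genic (or
nonsynonymous, or gene-set) SNPs in the lower rank tail (cutoffs 5%, 1%,
0.5%) to the proportion of nongenic SNPs there.  Significance comes from
a **500-kb block bootstrap** (1000 replicates resampling genome segments,
respecting linkage disequilibrium); an enrichment is significant
(one-tailed) when ≥95% of replicates have ratio > 1 (`*`), with `**` at
97.5% and `***` at 99%.  Subset scans (e.g. Africa + Western Eurasia,
Africa + East Asia + Oceania) re-estimate `Ω` within the subset; overlap
and Spearman statistics compare analyses; GWAS-catalog intersection uses
European-frequency binning.

A first-class synthetic-data module generates the whole study design —
a random population tree and its drift covariance, structure-confounded
environments, binomial allele counts with planted linear effects enriched
in genic/NS classes and designated gene sets — so every stage is testable
end to end without external data.

## Worked example

```python
import ecoscan as es
from ecoscan.enrichment import block_bootstrap_enrichment

cfg = es.SimulationConfig(seed=1)          # 60 populations, 20,000 SNPs
data = es.simulate_dataset(cfg)
result, ranks = es.subset_scan(
    data["counts"], data["env"], data["panel"], "worldwide", seed=1
)

cls = data["annotations"].set_index("snp_id")["class"]
ids = ranks.table["snp_id"].map(cls)
report = block_bootstrap_enrichment(
    ranks,
    ids.isin(["genic", "nonsynonymous"]).to_numpy(),
    (ids == "nongenic").to_numpy(),
    seed=1, comparison="genic:nongenic",
)
print(report.summary[["comparison", "cutoff", "ratio", "frac_enriched", "tier"]]
      .to_string(index=False))
```

prints

```
    comparison  cutoff    ratio  frac_enriched tier
genic:nongenic   0.050 1.517803            1.0  ***
genic:nongenic   0.010 2.769286            1.0  ***
genic:nongenic   0.005 3.301443            1.0  ***
```

With the default generator (2% of SNPs carry a true effect, enriched
3-fold in genic SNPs), genic SNPs are 1.5× over-represented among the top
5% of minimum ranks, rising to 3.3× in the top 0.5%, and every one of the
1000 block-bootstrap replicates is enriched (`***`).  The planted signal
is also visible per SNP — median minimum rank 0.0023 for effect SNPs
versus 0.0823 for null SNPs on the same run.

The same pipeline is scriptable from the shell:

```sh
ecoscan simulate --seed 1 --out-dir run/
ecoscan rank --counts run/allele_counts.tsv --panel run/panel.tsv \
             --env run/environment.tsv --seed 1 --out-dir run/
ecoscan enrich --ranks run/ranks.worldwide.global.tsv \
               --annotations run/annotations.tsv --seed 1 --out-dir run/
ecoscan calibrate
```

`ecoscan calibrate` prints the genome-wide significance arithmetic for a
full-size scan: a Bonferroni p-value threshold of `0.05 / (650,000 × 9) =
8.5e-09` and its minimum-Bayes-factor calibration
`log10 BF = log10(−1/(e·p·ln p)) = 6.36`.

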