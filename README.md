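# bsaqtl

Bulked-segregant QTL mapping toolkit for F2 populations with two extreme
phenotype bulks and two inbred parents. The package covers the full desk
side of a BSA-seq experiment:

- **simdata** — synthetic data generator: F2 meiosis (Poisson crossovers, no
  interference), single-QTL trait model, two-tail truncation selection into
  bulks, Poisson×Binomial read-depth sampling, plus fixture generators for
  recombinant fine-mapping tables, germplasm panels and qPCR Ct tables.
- **varfilter** — VCF/TSV ingestion (allele depths for parent_dwarf,
  parent_tall, bulk_dwarf, bulk_tall), quality filtering (biallelic,
  QUAL ≥ 30, MQ ≥ 30, parent depth ≥ 10, bulk depth ≥ 15, opposite-homozygous
  parents) with a per-rule removal report, and polarization by parental
  allele origin.
- **bsastats** — per-site ΔSNP-index, 2×2 allele-count G statistic and
  Euclidean distance (ED, ED⁴ = (√2·|Δ|)⁴), each tricube-smoothed along the
  chromosome (default 1 Mb window, i.e. 500 kb kernel half-width).
- **regions** — empirical quantile thresholds (default 0.999), candidate
  region calling with a ≥ 10-variant rule and optional run merging,
  cross-method consensus with reciprocal-overlap reporting, closed-interval
  span arithmetic, and GFF3-based variant/gene summaries with BED export.
- **finemap** — substitution mapping: intersect, across recombinants, the
  marker positions whose genotype is consistent with the observed phenotype
  under a declared inheritance model (dominant-tall by default).
- **germplasm** — haplotype definition from panel SNPs, one-way ANOVA with
  Duncan's multiple range test (compact letter display via
  `scipy.stats.studentized_range`), per-site t-tests, haplotype frequency
  breakdowns by market class / region, and 2^−ΔΔCt expression contrasts.
- **cli** — `bsaqtl` command with one subcommand per stage plus `demo`,
  which runs the whole pipeline end-to-end on synthetic data and writes a
  reproducibility manifest.

Coordinates are 1-based fully closed everywhere except BED export.

## Command line

```sh
# end-to-end demo on synthetic data (six stages, deterministic per seed)
bsaqtl demo --seed 1 --outdir demo_run

# or stage by stage
bsaqtl simulate --seed 1 --qtl-position 55000000 --additive-effect 30 \
    --out-vcf variants.vcf
bsaqtl varfilter --vcf variants.vcf --out filtered.tsv --report report.json
bsaqtl bsastats --table filtered.tsv --window-kb 1000 --out stats.tsv
bsaqtl regions --stats stats.tsv --q 0.999 --min-sites 10 --out regions.tsv
bsaqtl finemap --markers markers.tsv --profiles profiles.tsv --out fm.json
bsaqtl germplasm --panel panel.tsv --alpha 0.05 --out-prefix panel_out
```

`bsaqtl <subcommand> --help` documents every option. Sample-name → role
mapping for VCFs defaults to `P1/P2/BulkL/BulkH` and can be overridden with
a YAML file via `--roles`.

## Python API sketch

```python
from bsaqtl import simdata, varfilter, bsastats, regions

cfg = simdata.SimConfig(seed=1, qtl_position=55_000_000,
                        additive_effect=30.0, residual_sd=10.0)
truth, table = simdata.simulate_experiment(cfg)
filtered, report = varfilter.apply_filters(table)
stats = bsastats.compute_stats(varfilter.polarize(filtered))
thr = regions.compute_threshold(stats["ed4_smoothed"], q=0.999)
called = regions.call_regions(stats, "ed4_smoothed", thr, min_sites=10)
```
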