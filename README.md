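# egburden

Constraint, mutational burden, and de novo enrichment analysis of human
orthologs of mouse-essential genes.

Genes whose homozygous knockout is lethal in the mouse (essential genes, EG)
are expected to be under strong purifying selection in humans. This package
implements the full analysis pipeline for testing that expectation from
population sequencing data, for statistical geneticists working with
phenotype-derived gene sets:

* **Gene-set construction** — classify human genes as EG (≥1 homozygous
  lethal-phenotype annotation on a one-to-one mouse ortholog; lethal wins over
  non-lethal, heterozygote-only annotations are disregarded), NLG (homozygous
  non-lethal phenotype only), or OTHER, and attach annotation flags
  (disease-gene lists, haploinsufficiency, top-10% ubiquitous expression by
  CV rank, brain over-expression at p ≤ 1e-4).
* **Variant accounting** — parse an effect-annotated multi-sample VCF into
  typed records: the broad exonic-missense class (non-synonymous coding,
  splice sites, stop gain/loss, start changes), its loss-of-function (LoF)
  subset (stop and splice disruptions), PolyPhen2 ∩ SIFT damaging consensus,
  allele frequencies from genotypes (af = AC / 2N_called), and the rare
  (<1%) stratum.
* **Constraint statistics** — length-corrected per-gene variant rates with
  Z-score and log1p transforms, one-sided Wilcoxon comparisons (paired within
  samples), two-sided Fisher exact tests with odds ratios and Woolf
  confidence intervals, site-frequency-spectrum excess profiles, promoter
  conservation summaries (TSS ± 100 bp).
* **Per-individual load** — per-sample counts of missense / damaging / LoF
  carriage per gene set and frequency stratum, the within-sample
  missense/synonymous ratio, LoF fraction, and het/hom LoF ratio.
* **De novo enrichment** — the matched-gene permutation test: each de novo
  event's gene is exchanged (with replacement) for a random gene of similar
  total exon length (±100 bp) and GC content (±2.5%), giving a length- and
  GC-adjusted odds ratio

  `adjusted OR = [obs/(n − obs)] / [exp/(n − exp)]`

  with `exp` the permutation expectation of in-set events, an add-one
  permutation p-value, and per-study SEs from the replicate log-odds spread,
  combined by inverse-variance fixed-effects meta-analysis with Cochran's Q.
* **Synthetic data** — generators for every input (gene universe, phenotype
  and ortholog tables, annotated cohort VCF under Hardy–Weinberg with a
  rare-skewed allele-frequency law, conservation track, substitution-rate and
  expression tables, de novo event lists with a tunable true enrichment
  odds), so the whole pipeline runs with known ground truth and no downloads.

## Worked example

Simulate a small study suite with a known case-arm enrichment odds of 1.4 and
run the matched permutation test:

```python
import pandas as pd
from egburden import synthetic_data as sd
from egburden import denovo_enrichment as dn

genes = sd.generate_gene_universe(
    sd.UniverseConfig(n_genes=20_029, eg_length_multiplier=1.0, seed=100)
)
events = pd.concat(
    [
        sd.simulate_denovo_study(
            genes,
            sd.DeNovoStudyConfig(
                study_id=f"study{i}", n_case_events=300, n_control_events=100,
                true_or=1.4, seed=10 + i,
            ),
        )
        for i in range(4)
    ],
    ignore_index=True,
)
report = dn.run_denovo_analysis(events, genes, "EG", n_perm=2000, seed=3)
for arm in ("case", "control"):
    m = report[arm]["meta"]
    print(f"{arm}: OR={m.combined_or:.2f} "
          f"CI=({m.ci95[0]:.2f}, {m.ci95[1]:.2f}) p={m.meta_p:.1e} "
          f"Q={m.cochran_q:.2f} (q_p={m.q_p:.2f})")
```

```
case: OR=1.48 CI=(1.24, 1.75) p=8.8e-06 Q=0.78 (q_p=0.85)
control: OR=0.97 CI=(0.71, 1.34) p=8.7e-01 Q=2.55 (q_p=0.47)
```

The case arm recovers the generative enrichment odds (true value 1.4 inside
the CI; the null excluded), the control arm — generated without enrichment —
does not, and Cochran's Q shows no between-study heterogeneity in either arm.

The same pipeline is available from the shell:

```bash
egburden simulate -c config.yaml -o run/bundle
egburden classify  --phenotypes run/bundle/phenotypes.tsv \
    --orthologs run/bundle/orthologs.tsv --universe run/bundle/universe.tsv \
    --lethal-codes run/bundle/lethal_codes.txt -o run/genes_classified.tsv
egburden annotate --vcf run/bundle/cohort.vcf -o run/variants.tsv
egburden constraint --genes run/genes_classified.tsv --variants run/variants.tsv \
    --metrics run/bundle/gene_metrics.tsv --track run/bundle/conservation.bedgraph \
    -o run/constraint
egburden burden --genes run/genes_classified.tsv --vcf run/bundle/cohort.vcf -o run/burden
egburden denovo --events run/bundle/denovo_events.tsv \
    --universe run/genes_classified.tsv --gene-set EG --n-perm 2000 --seed 1 -o run/denovo
egburden report --run-dir run -o run/report --seed 1
```

## Layout

```
src/egburden/
  synthetic_data.py     input generators with known ground truth
  gene_catalog.py       EG/NLG/OTHER classification and annotation flags
  variant_annotation.py VCF parsing, effect classes, damaging consensus, AF
  constraint_stats.py   rates, Wilcoxon/Fisher, SFS, promoter conservation
  individual_burden.py  per-sample mutational load
  denovo_enrichment.py  matched permutation + fixed-effects meta-analysis
  experiments.py        self-contained validation experiments
  cli.py                subcommand pipeline (simulate … report)
docs/methods.md         model and design notes
tests/                  pytest suite (unit, property, acceptance)
```
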