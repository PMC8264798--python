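# cernet

Dysregulated lncRNA–miRNA–mRNA network analysis for tumor-vs-normal
transcriptome cohorts.

Cancer transcriptomes dysregulate messenger RNAs together with the
non-coding RNAs that regulate them.  A common systems-level view is the
competing-endogenous-RNA (ceRNA) design: miRNAs sit between the lncRNAs and
mRNAs they bind, and a *dysregulated network* keeps only the
miRNA–target interactions that are (i) supported by AGO CLIP binding
evidence, (ii) between differentially expressed molecules, and (iii)
backed by strong expression correlation.  Modules of such a network are
candidate prognostic units: their expression can stratify patients into
groups with different survival.

`cernet` implements that full analysis as a reusable, tested pipeline:

1. **Class partitioning** — genes are routed to mRNA / lncRNA / miRNA by
   GENCODE biotype (`protein_coding` → mRNA; `lncRNA`, `lincRNA`,
   `antisense`, `processed_transcript`, `sense_intronic`,
   `sense_overlapping`, `TEC` → lncRNA; `miRNA` → miRNA).
2. **Differential expression** — genes expressed in <10% of samples are
   dropped; per-gene Welch *t*-test on log₂(x + c); DE means
   *p* < 0.05 and linear fold change FC = max(m_T/m_N, m_N/m_T) > 2.
3. **Network construction** — AGO-supported miRNA–target pairs between DE
   molecules are kept when the Pearson correlation across all samples
   satisfies |r| > 0.3 and *p* < 0.01 (from t = r·√((n−2)/(1−r²))); a
   miRNA must retain both an mRNA and a lncRNA edge to stay.
4. **Module detection** — deterministic |r|-ordered agglomerative
   union–find with a size cap, emitting connected tri-class modules.
5. **Survival analysis** — per module, tumor samples are split by k-means
   (k = 2) on z-scored log₂ expression of the module RNAs; groups are
   compared by the log-rank test, and module expression tumor-vs-normal by
   a Wilcoxon rank-sum test.
6. **Gene-set scoring** — hypergeometric over-representation with BH
   adjustment, preranked GSEA, single-sample GSEA (ssGSEA, exponent
   τ = 0.25), co-expression-based annotation of ncRNAs (top-500 mRNAs by
   average r), and module–pathway score correlations.

Because the public cohorts behind such studies are access-controlled and
version-dependent, the package ships a first-class **synthetic cohort
generator** (`cernet.synthetic`) that plants every signal the pipeline is
supposed to recover — DE genes with configurable log₂ fold change, miRNA
regulons with anti-correlated targets, decoy interactions, star-shaped
tri-class modules, an exponential survival hazard driven by the first
module's expression, and DE-enriched gene sets — and returns the ground
truth for evaluation.

## Worked example

Run the default synthetic study end-to-end (takes a few seconds):

```python
from cernet import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(out_dir="run", seed=11))
print(report["stages"]["de"]["mRNA"])
print({k: v for k, v in report["stages"]["network"].items()
       if k in ("edges", "nodes", "class_counts")})
for row in report["stages"]["survival"][:2]:
    print(row["module_id"], round(row["chi_square"], 2),
          f"p={row['p_logrank']:.2e}", row["direction"])
```

prints

```
{'tested': 500, 'filtered_out': 0, 'up': 33, 'down': 41}
{'edges': 66, 'nodes': 73, 'class_counts': {'mRNA': 47, 'lncRNA': 17, 'miRNA': 9}}
M1 0.65 p=4.20e-01 down
M2 27.76 p=1.38e-07 up
```

Reading: of 500 simulated mRNAs, 74 pass the DE gates; the two-step filter
keeps 66 of 272 candidate interactions, giving a 73-node tri-class
network.  Module M2 — one of the two planted modules — splits the 60 tumor
samples into groups whose survival differs at log-rank χ² = 27.8
(p ≈ 1×10⁻⁷), and its expression is higher in tumors ("up"), exactly the
planted prognostic signal.  The same run is available from the shell:

```bash
cernet simulate --out fixtures --seed 2
cernet de --expr fixtures/expression_mrna.tsv --samples fixtures/samples.tsv --out de_mrna.tsv
cernet pipeline --config cfg.yaml
```

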