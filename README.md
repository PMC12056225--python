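# vpptbench

Ancestry-aware benchmarking of **variant pathogenicity prediction tools**
(VPPTs) and consensus classification of variants of uncertain significance.

Genetic testing guidelines and curated clinical databases are heavily biased
toward European-ancestry data, so the in-silico tools used to score variant
deleteriousness perform differently on African-derived genomes. `vpptbench`
implements the full evaluation and classification workflow needed to measure
and act on that gap:

1. **Benchmark construction** — positive (PV: Pathogenic / Likely pathogenic)
   and negative (BV: Benign / Likely benign) variant sets are built per cohort
   from ClinVar clinical-significance strings and InterVar ACMG-AMP
   classifications, restricted to rare SNVs (cohort MAF < 1%), and merged with
   configurable conflict handling.
2. **Tool binarization** — a declarative registry of 54 VPPTs turns each
   tool's dbNSFP-style score or prediction code into
   deleterious / benign / no-call, using each tool's published cut-off and
   inequality (e.g. CADD > 20, SiPhy ≥ 12.17).
3. **Performance metrics** — for each tool and benchmark, from the confusion
   counts TP/FP/TN/FN (no-calls excluded):

   Sen = TP/(TP+FN)  Spec = TN/(TN+FP)  FPR = FP/(TN+FP)  FNR = FN/(TP+FN)

   MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

   plus mean rows, paired tool-wise tests (paired *t* / Wilcoxon), per-capita
   rates and fold changes.
4. **Workflow selection** — ancestry-specific top-10 tool sets: exclude tools
   with FPR > 0.3 and non-coding-only tools, keep one member per
   near-duplicate tool family, rank by sensitivity.
5. **VUS → PDV → POV classification** — variants of uncertain significance
   (rare, unlabelled, globally rare in a gnomAD-style reference) become
   *potentially deleterious variants* when the 10-tool workflow reaches
   consensus or the variant is a stop-gain/splice change, and *potentially
   oncogenic variants* when additionally flagged as predicted
   loss-of-function (pLoF) or oncogenic by a Cancer Genome
   Interpreter-style annotation.
6. **Synthetic cohorts** — a seeded generator produces paired
   African/European-shaped cohorts with known truth and closed-form per-tool
   operating points, so the whole pipeline is testable end-to-end without any
   controlled-access data.

The package ships two reference tables: the published per-tool
sensitivity/specificity/FPR/FNR/MCC values for the African and European
ACMG-AMP benchmark cohorts, and the cohort-level count summary (patients,
SNVs, benchmark sizes, PDV/POV counts).

## Worked example

Select the African-ancestry workflow from the packaged reference metrics:

```sh
$ vpptbench select --use-reference AFR --out workflow_AFR.yaml
MetaSVM CADD MutationTaster Eigen-raw phyloP100way-vertebrate DANN BayesDel-noAF LRT MVP GERP-RS
```

Six of these tools (MetaSVM, CADD, Eigen-raw, BayesDel-noAF,
phyloP100way-vertebrate, MVP) are shared with the European workflow;
MutationTaster, DANN, LRT and GERP-RS are African-specific picks.

Run the full pipeline on a small synthetic two-cohort dataset:

```sh
$ vpptbench run-all --seed 2 --scale 0.1 --out demo/
```

The printed JSON summary includes, for the African-shaped cohort:

```json
"AFR": {
  "n_input": 2000,
  "n_rare": 559,
  "benchmark": {"merged": {"positives": 4, "negatives": 67}},
  "stages": {"vus": 475, "pdv": 5, "pov": 0},
  "rates": {"pv_per_patient": 0.08, "pv_pov_per_patient": 0.08}
}
```

i.e. of 2,000 simulated SNVs, 559 are rare; 4 PVs and 67 BVs carry
surfaced clinical labels and form the merged benchmark; of the remaining 475
VUS, 5 pass the unanimity consensus or stop-gain/splice route. The bundle
written to `demo/` also contains per-benchmark 54-tool metric tables with a
mean row, the selected workflow files, classified-variant TSVs, and a
machine-readable manifest; `vpptbench audit --dir demo/` re-derives every
summary count from the TSVs. Outputs carry no timestamps — the same seed
reproduces the bundle byte for byte.

### Library use

```python
import vpptbench as vb

registry = vb.get_registry()                  # the 54-tool registry
variants = vb.read_variant_table("cohort.tsv", cohort="AFR")
rare = vb.filter_rare(variants)               # MAF < 1%
bench = vb.merge_benchmarks(vb.build_benchmark(rare, "clinvar"),
                            vb.build_benchmark(rare, "intervar"))
calls = vb.call_matrix(rare, registry=registry)
perfs = vb.evaluate_all_tools(bench, calls)   # Sen/Spec/FPR/FNR/MCC per tool
```

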