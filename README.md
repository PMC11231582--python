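# retrobench

A fully synthetic, reproducible benchmark of **locus-specific vs
family-level quantification of endogenous retrovirus (ERV) expression**
across sequencing technologies.

ERV families such as HML-2 consist of dozens of genomic integrations
descended from near-identical ancestors.  Young integrations are almost
perfect repeats, so short RNA-seq reads from them align equally well to
several loci, and a per-locus expression estimate silently redistributes
those multi-mapping fragments.  `retrobench` measures that redistribution
bias under controlled, fully known conditions: it synthesizes an
age-stratified 30-locus family (plus one exact-duplicate locus), simulates
truth-tagged reads under six technology layouts at equalized coverage,
aligns and quantifies them three ways, and reports per-locus bias.

For each locus with `assigned` simulated fragments and `mapped` counted
fragments the package reports

* percent error = |assigned − mapped| / assigned × 100
* fold change = mapped / assigned, with loci called *falsely upregulated*
  (fold > 1.1) or *falsely downregulated* (fold < 0.9)
* family recovery = 100 × Σ mapped (any locus) / Σ assigned

Quantification strategies:

* **naive** — best-hit counting with random tie-breaks (standard
  locus-specific analysis)
* **em** — MAP-EM reassignment of ambiguous fragments over a mixture of
  source loci (softmax score weights, Dirichlet pseudo-count prior;
  defaults `max_iter=200`, `theta_prior=200000`)
* **family** — fragments with ≥1 accepted hit anywhere in the family

See `docs/methods.md` for the model, parameters and limitations.

## Worked example

```python
from retrobench import ExperimentConfig, run_experiment

cfg = ExperimentConfig(master_seed=1, profiles=["pacbio_hifi"])
reports = run_experiment(cfg, "scratch/demo")
s = reports["pacbio_hifi"].summary
print("naive: median PE %.2f%%, up %d, down %d"
      % (s["naive"]["median_percent_error"], s["naive"]["n_up"], s["naive"]["n_down"]))
print("family recovery %.2f%%" % s["family"]["recovery_percent"])
```

prints

```
naive: median PE 0.00%, up 0, down 1
family recovery 100.00%
```

i.e. with accurate 750 nt (HiFi-like) reads the locus-specific analysis is
exact everywhere except at the one locus that has an identical duplicate in
the annotation: best-hit counting splits its reads ~50/50 with the twin
(fold change ≈ 0.5, falsely downregulated), while the family total recovers
100 % of simulated fragments.  The EM reassignment consolidates the tied
reads onto a single locus and removes that error.  The same experiment with
76 nt reads (`profiles=["illumina76se"]`) shows the young-locus
multi-mapping bias appear (median naive percent error ≈ 0.8 %, young-locus
median ≈ 3 %), and the high-error long-read profile
(`profiles=["pacbio_standard"]`) shows the strict-alignment collapse: all
30 loci falsely down, family recovery ≈ 35 %.

The same pipeline is scriptable from the shell:

```bash
retrobench run-all --seed 1 --outdir scratch/full --profiles illumina150se
retrobench compare scratch/full/illumina150se_report.tsv --out scratch/cmp.tsv
```

Each run directory contains the genome FASTA, locus BED and metadata TSV,
per-profile FASTQ and truth tables, hit tables, counts and per-locus bias
reports — all plain text.

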