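# medipmap

MeDIP-seq methylome profiling and differential-methylation analysis for
pooled-sample studies, built for designs like the four-group broiler
comparison it mirrors: the high/low body-weight tails of two chicken
breeds (`WRR_h`, `WRR_l`, `XH_h`, `XH_l`), each sequenced as one pooled
MeDIP library. The package takes a reference genome, gene models, repeat
annotation and uniquely aligned reads, and produces the full descriptive
and comparative analysis such studies report — plus a synthetic-data
generator with planted ground truth so every stage is testable without
any download.

## What it computes

* **CpG islands** — sliding 100 bp windows score each position with the
  moving-average GC fraction and observed/expected CpG ratio
  (O/E = #CpG · L / (#C · #G)); islands are maximal passing runs, trimmed
  to their terminal CpGs and re-validated against the classical criteria
  *length ≥ 200 bp, GC > 0.5, O/E > 0.6*.
* **Methylation peaks** — a deterministic Poisson caller with a dynamic
  local background: reads extended to the fragment length, counted in
  tiling windows, and a window is enriched when
  P(X ≥ k | λ_local) < 10⁻⁵ with λ_local = max(λ_genome, λ_5k, λ_10k).
  Real MACS output can be substituted as plain BED.
* **Methylome profile** — read classification (CGI / gene body / repeat /
  other), peak counts per genomic component (promoter = TSS ± 2 kb, UTRs,
  exon, intron, intergenic, CGI, repeats; a peak counts once per component
  it overlaps, once in the deduplicated total), methylation densities in
  peaks/Mb, repeat-family percentages, methylated-CGI summaries and
  size-bin distributions.
* **Differential methylation** — per gene × region (upstream 2 k, 5′UTR,
  exon, intron, 3′UTR, downstream 2 k, promoter, gene body), two-sided
  Fisher exact test on the 2×2 read-count table, fold change on
  pseudocounted counts-per-million; called when fold ≥ 2 (either
  direction) and p < 0.01; *up* means greater coverage in the **second**
  sample of the contrast. Contrast intersections give shared-gene counts.
* **Term enrichment** — hypergeometric or EASE (one study hit removed)
  upper-tail p against a user-supplied gene→term map, Benjamini–Hochberg
  adjusted, filtered at p < 0.005 and adjusted p < 0.05.
* **Bisulfite-clone validation** — in-silico conversion, global alignment
  of clones to the converted reference, per-CpG C/T calls, ASCII lollipop
  diagrams and peak/bisulfite concordance reports.

## Worked example

Run the full synthetic pipeline (simulate → islands → peaks → profile →
differential → enrichment → bisulfite):

```sh
medipmap run-all --seed 1 --out out/
```

which prints `{"outputs": 23, "out": "out/"}` and writes, among others,
`out/table_read_stats.tsv`:

```
sample  total_unique  cgi    gene_body  repeat  other  pct_cgi  pct_gene_body  pct_repeat  pct_other
WRR_h   100000        759    42065      9863    47313  0.76     42.06         9.86        47.31
```

— under 1 % of unique reads fall in CpG islands (islands are
hypomethylated, so MeDIP enrichment avoids them) while gene bodies and
repeats carry most of the methylation signal. `out/table_dmg_counts.tsv`
counts differential calls per contrast, region and direction, and
`out/bisulfite_report.tsv` shows each simulated amplicon agreeing with
its peak status, e.g. `AMP2  high  0.850  True  agree`.

Individual stages are exposed as subcommands (`simulate`, `scan-cgi`,
`call-peaks`, `profile`, `diff`, `enrich`, `bisulfite`) and as plain
library functions (`medipmap.scan_cpg_islands`, `medipmap.call_peaks`,
`medipmap.compare_contrast`, ...).

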