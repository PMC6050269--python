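# mfsomics

Multi-omics analysis of complex-karyotype sarcoma cohorts (the motivating
disease is myxofibrosarcoma): driver-gene significance under a Poisson
background model, purity/ploidy-adjusted copy-number calling with focal
amplification/homozygous-deletion rules, paired-cluster fusion-transcript
detection from discordant RNA read pairs, extreme-group differential
expression, Infinium-style methylation subtyping, and the integration
statistics connecting methylation subtypes to drivers and survival. A
seeded synthetic cohort generator with planted ground truth makes every
stage testable without access to controlled patient data.

Intended users: cancer-genomics analysts and methods developers who want a
transparent, fully tested re-implementation of this class of cohort
pipeline, and a simulator for benchmarking each stage.

## The models at the core

**Driver significance.** Per gene, the aggregate count of non-silent
mutations plus focal CN events is tested against
X ~ Poisson(λ_g), λ_g = Σ_c r_c L_g N + r_CNA N (class rates r_c estimated
cohort-wide, L_g = CDS length, N samples), with upper-tail p = P(X ≥ obs).
Companion binomial tests score positional recurrence (activation) and
truncating-class enrichment (inactivation). Per-test BH q values are
combined as a geometric mean; genes with rank-sum-depressed allele
fractions (subclonal passengers) are removed; drivers are called at
combined q < 0.1.

**Copy number.** adjusted CN = [1 − (1 − R(x))/purity] × ploidy, where
R(x) is the median-normalized tumor/normal depth ratio. log2 adjusted CN is
segmented by circular binary segmentation (two-breakpoint Z scan, MAD
noise scale, minimum 5 probes). Segments with adjusted CN ≥ 6 are
amplifications; segments with adjusted CN ≤ 0 are homozygous deletions
unless their raw ratio exceeds 0.5 — the ratio a true deletion would show
at the cohort-average purity of 0.5 — in which case they are discarded as
purity artifacts.

**Fusions.** 50-bp read ends are chained into forward/reverse clusters
(≤ 300 bp neighbour gap, ≤ 1000 bp span); cluster pairs linked by read
pairs become candidates, filtered for one perfect pair, realignment
artifacts across duplicated sequence, and support (≥ 2 pairs in-frame,
≥ 3 otherwise), with frame decided by codon phase across the cluster-edge
breakpoints.

**Methylation.** M = log2(β/(1−β)); probes with |CV of M| > 60 feed
Euclidean/Ward hierarchical clustering into subtypes A/B/C; one-vs-rest
Wilcoxon rank-sum tests report cluster-specific hypermethylation at
q < 0.2. Kaplan–Meier/log-rank, χ² association, and Student-t burden
comparisons integrate the layers.

See `docs/methods.md` for assumptions, parameter defaults, numerics and
limitations.

## Worked example

Simulate a 41-sample cohort (60 genes, planted driver, CN events, fusion,
3 methylation clusters) and run every stage:

```
$ printf 'n_genes: 60\nn_samples: 41\nseed: 11\n' > demo/cohort.yaml
$ mfsomics simulate --config demo/cohort.yaml --outdir demo
wrote 10 cohort files to demo
$ mfsomics cna --outdir demo
segmented 41 samples; 146 focal gene calls
$ mfsomics smg --outdir demo
4 significantly mutated genes (combined q < 0.1)
$ mfsomics fusion --outdir demo
1 fusion transcripts reported
$ mfsomics methyl --outdir demo
582 variable probes; clusters: {'A': 14, 'B': 14, 'C': 13}
$ mfsomics expr --outdir demo
490 genes quantified
$ mfsomics integrate --outdir demo
log-rank across clusters: statistic=12.752, p=0.0017
$ mfsomics report --outdir demo
wrote demo/report.md
```

What the numbers mean: the four driver calls are the genes inside the
planted amplification and deletion, which enter the aggregated Poisson
test through their focal events — e.g. `smg.tsv` shows G0011 with 41
aggregated events against an expectation of 2.7 (combined q ≈ 3e-11). The
planted 50× point-mutation driver G0001 ranks next (10 mutations observed)
but at this small cohort size stays just above the q < 0.1 call threshold;
the larger simulations run by the test suite and the acceptance script
(1000 genes × 100 samples) call it at rank 1 essentially always. The
fusion stage reports exactly the planted in-frame event with its five
supporting pairs and no paralog decoys:

```
gene5   gene3   breakpoint5  breakpoint3  n_pairs  n_perfect  frame
G0005   G0010   800          650          5        1          in-frame
```

The methylation stage recovers the three planted subtypes (14/14/13
samples), and the log-rank p = 0.0017 reflects the cluster-dependent
survival hazards built into the simulator.

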