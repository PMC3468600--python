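# circaparam

Characterization of circadian genes in a peripheral tissue, built as a
tested, reusable pipeline.  Starting from a dense temporal expression matrix
(probes x circadian-time points, log10 intensities), the package

1. **detects rhythmic rows** with a JTK-style nonparametric scan — Kendall S
   against reference cosines over a period x phase grid, with an *exact*
   permutation null computed for the reference's tie pattern by
   generating-function convolution — plus a model-library matcher (cosine,
   spike, box, sawtooth templates) that rescues non-cosine rhythms the rank
   scan misses; calls are combined at a Benjamini–Hochberg q threshold
   (default q < 0.001);
2. **partitions gene loci** into liver circadian genes (LCG), liver-expressed
   non-liver-circadian genes (LNLCG), liver-expressed non-circadian genes
   (LNCG) and unexpressed remainders, after reducing probes to one
   representative per locus under a period/phase consistency filter and
   estimating the expressed/non-expressed cutoff from the bimodal expression
   density;
3. **compares genomic parameters** across the sets: windowed neighbor-gene
   counts, gene-density/GC correlations over autosomes, structure length
   medians, head-to-head divergent rhythmic pairs, binding sites within
   50 kb of a TSS, promoter methylation within 2 kb of a TSS;
4. **compares expression features**: peak-to-trough amplitude
   (95th/5th percentile of linear intensities), ranked 300-gene expression
   bins, temporal and cross-tissue mean/SD, expression breadth over a
   46-tissue matrix, mRNA half-lives, all with one-sided Wilcoxon rank-sum
   tests;
5. **clusters LCG temporal profiles** by consensus NMF (KL divergence,
   multiplicative updates, 20 random restarts, rank 3) into phase-coherent
   co-expression groups labelled by the temporal windows dawn [CT22, 2),
   day [2, 10), dusk [10, 14) and night [14, 22);
6. **flags phase-specific terms and miRNA targets** with the pairwise
   criterion: at least 3 of 4 comparisons (other clusters + non-circadian
   background) with P < 0.05 and enrichment fold > 1.5; miRNA target sites
   are exact seed complements (miRNA bases 2–8) in 3'-UTR sequences.

A first-class synthetic-data generator (`circaparam.simulate`) produces
every input with known ground truth — planted rhythmic fractions with exact
counts, waveforms, phases concentrated in the four temporal windows,
head-to-head pairs, tissue breadths, binding sites, methylation, half-lives,
seed sites — so every stage is scored against truth.  See
`docs/methods.md` for the model and all conventions.

## Worked example

Run the full pipeline on 1,500 synthetic loci (30% planted rhythmic):

```sh
circaparam run --n-loci 1500 --rhythmic-fraction 0.3 --seed 1 --out run1/
```

which prints (abridged):

```
- loci: 1500; planted rhythmic: 450
- expression cutoff (log10): 1.396
- LCG: 451; LNLCG: 364; LNCG: 460; expressed (AL): 1275
- false positive rate vs negative controls: 0.0%

- density_vs_gc: R = 0.92, P = 2.74e-08
- lcg_pct_vs_gc: R = -0.86, P = 2.01e-06
- divergent rhythmic pairs: 3

- mean amplitude LCG: 3.79
- mean amplitude LNCG: 1.31
- amplitude LNCG < LCG one-sided P: <2.2e-16
- temporal STD LNCG < LCG one-sided P: <2.2e-16
- mean mRNA half-life: LCG: 7.44 h, ..., LNCG: 9.42 h

- cluster 0: 194 genes, window night, mean phase CT14.6
- cluster 1: 153 genes, window day, mean phase CT6.9
- cluster 2: 104 genes, window dawn, mean phase CT23.7
- BP:day_process in day (3/4 comparisons pass)

LCG recovery vs planted truth: F1 = 0.999 (451 called / 450 planted)
```

Reading the numbers: the detector recalls the 450 planted rhythmic loci
almost exactly (F1 0.999) with no hits among the negative-control genes;
the estimated expression cutoff (1.396) lands at the planted bimodal
midpoint; gene density correlates positively with chromosomal GC while the
rhythmic-gene share correlates negatively, as planted; the rhythmic set
shows the planted contrasts — higher amplitude, higher temporal SD, shorter
half-life; and the temporal clusters recover the planted phase windows with
their phase-specific annotation terms.

The `simulate`, `detect` and `classify` subcommands expose the stages over
TSV/GFF3/FASTA files so any step can be run standalone; library functions
(`circaparam.genome`, `circaparam.expression`, `circaparam.clustering`,
`circaparam.enrichment`) cover the finer-grained analyses.

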