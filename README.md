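# mtasepref

Deep-enzymology analysis of bacterial DNA-(cytosine C5)-methyltransferase
(MTase) specificity and flanking sequence preferences, built around hairpin
bisulfite sequencing of randomized substrate libraries — with a fully
seedable simulator so every stage of the analysis is verifiable by parameter
recovery against known ground truth.

## The problem

MTases such as M.SssI (CG), M.HhaI (GCGC), M.HaeIII (GGCC), M.HpaII/M.MspI
(CCGG) and M.AluI (AGCT) methylate a cytosine inside a short recognition
motif, but their activity also depends strongly on the bases *flanking* the
motif, and on how far a site deviates from the cognate motif (near-cognate
sites differ by one base).  Measuring this requires methylation rates across
thousands to millions of sequence contexts at once.  The deep-enzymology
design solves this with substrate libraries carrying the target C in a
randomized context: after methylation, bisulfite conversion turns every
unmethylated C into T, a stem-loop links both strands into one sequencing
read, and each read reports jointly the molecule's original sequence
(reconstructed from the two strands) and its methylation state.

## The statistics

For each flank position *i* and base *N*, the preference profile is the
observed/expected enrichment

    o/e_N(i) = freq(N at i | methylated reads) / freq(N at i | all reads)

with per-position effect size

    E_i = sqrt((A_i-1)^2 + (C_i-1)^2 + (G_i-1)^2 + (T_i-1)^2)

over the four o/e values.  Methylation levels are also averaged in NN-X-NN
(256) and NNN-X-NNN (4096) flanking bins; bins with zero methylated reads at
coverage *n* are bounded by `p = 1 - alpha^(1/n)` (e.g. 0.35% at n=847,
alpha=0.05).  A multiplicative expansion Act(context) = prod_i f_i(N_i) with
f_i = o/e turns the profile into relative activities for all 65,536 N4-X-N4
contexts, which can be correlated with DNA shape feature tables (MGW, EP,
Roll, ProT, ...).  Specificity is quantified as rate folds: endpoint
methylation maps to an apparent first-order rate k ∝ -ln(1 - m), independent
experiments are placed on a *virtual time axis* defined by cognate-site
progress, and fold = k_cognate / k_variant.  Radioactive progress curves are
fitted as CPM(t) = A(1 - e^(-kt)) with initial rate v0 = A·k.

The simulator generates the matching ground truth: molecules drawn from the
library designs (N9-motif-N9, or N10-C[N]-N10 with a 3:1 CpH:CpG mix), a
target C methylated with P = 1 - exp(-k_eff·t) where k_eff is a product of
per-position base factors, motif-variant factors and optional pairwise
interaction terms, then strand-wise bisulfite conversion, hairpin read
assembly, sequencing errors, PCR duplicates and quality strings.

## Worked example

Simulate an M.HhaI-style experiment under a known preference model, process
the reads, and fit the flanking preference profile:

```python
import mtasepref as mp

model = mp.PreferenceModel(
    motif="GCGC", target_index=2,
    flank_factors={
        -2: {"A": 0.6, "C": 2.0, "G": 0.8, "T": 1.0},
        -1: {"A": 1.0, "C": 1.5, "G": 0.5, "T": 1.1},
        +1: {"A": 1.4, "C": 0.7, "G": 1.3, "T": 1.0},
        +2: {"A": 1.0, "C": 1.0, "G": 1.6, "T": 0.9},
    },
)
design = mp.motif_design("GCGC", 2)
t = mp.time_for_target_methylation(model, design, 0.3)   # -> 0.2823
reads, manifest = mp.simulate_experiment(design, model, 50_000, t, seed=1,
                                         conv_rate=0.995)
raw = [mp.RawRead(r.id, str(r.seq), r.letter_annotations["phred_quality"])
       for r in reads]
processed, stats = mp.process_reads(raw, design)
res = mp.FlankingPreferenceModel(processed, design, "GCGC", 2,
                                 mp.default_positions(2)).fit()
print(res.summary())
```

prints

```
Flanking sequence preference profile
============================================
motif: GCGC (target C at position 2)
reads in pool: 50000   methylated: 15116   (30.2%)

o/e enrichment (rows: flank position):
        A      C      G      T
-2  0.643  1.605  0.787  0.967
-1  0.996  1.341  0.587  1.076
 1  1.212  0.710  1.150  0.927
 2  0.930  0.929  1.298  0.844

effect size per position:
-2    0.735
-1    0.541
 1    0.396
 2    0.351
```

The recovered o/e values rank the simulated factors correctly at every
position — e.g. the planted 2.0× preference for C(-2) comes back as o/e 1.6
(o/e compresses rate factors because methylation saturates), and the 0.5×
disfavour of G(-1) as 0.59.  `res.bins(3)` gives the 4096-bin methylation
table, `res.activity(4)` the 65,536-context activity vector for shape
correlation, and `mp.specificity_folds(...)` the near-cognate fold table
from a CN-library run.

The same pipeline is available from the shell:

```
mtasepref simulate --enzyme M.HhaI --n-molecules 50000 --time 0.28 --seed 1 --out run/
mtasepref process --fastq run/reads.fastq --design run/design.yaml --out run/proc/
mtasepref preferences --processed run/proc/processed.tsv --design run/design.yaml \
    --enzyme M.HhaI --out run/pref/
```

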