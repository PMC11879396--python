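# Methods

## Substrate model and simulator

A substrate molecule is a double-stranded oligo: constant left arm
(`GAGTGTGACTAGGCTCTCACTGCC`), a variable window, and a constant right arm
(`GAGAGGAGACCTAGTGAGAAG`).  Two library designs are provided:

* **CN specificity library** (`cn_design`): 10 randomized bases, the fixed
  target C, a mixed position (CpH : CpG at a 3:1 molar ratio, H uniform over
  {A,C,T} — note this makes the position uniform over all four bases), and
  10 more randomized bases.  This library exposes every near-cognate frame
  of every enzyme around one fixed C.
* **Motif preference library** (`motif_design`): the full recognition motif
  fixed in the centre of the window with 9 randomized bases per side.
  CG-type substrates can be hemimethylated (`hemimethylated=True`): the
  bottom-strand C of the palindromic core is pre-methylated, which focuses
  enzymatic turnover on the top strand and is never counted as an event.

**Hairpin geometry.** In the wet protocol the methylated duplex is
restriction-digested and a stem-loop oligo (`GAGAAGGGATGTGGATACACATCCCT`)
ligated to the cut end, so one read traverses top strand, loop, bottom
strand.  The digestion is abstracted to a single parameter: the design keeps
a 3' stub of the right arm sized so that the full hairpin spans
`hairpin_length` nucleotides (default 128, the conventional trim length).
This reproduces the information content of the protocol — both strands of
the variable window co-located within one trimmed read — without modelling
restriction-site placement.

**Rate model.** Each molecule's target C methylates as a first-order
reaction, `P(methylated at t) = 1 - exp(-k_eff t)` with

    k_eff = k_base x motif_factor(variant) x prod_i f_i(N_i) x prod complex terms

`f_i(N)` are per-flank-position per-base multipliers; the cognate motif has
factor 1 by convention and motif variants not listed get factor 0; optional
`complex_terms` couple pairs of flank positions multiplicatively on top of
the per-position factors (a controlled violation of multiplicativity used to
exercise the combinatorial-effect scan).  `k_base` has units of inverse time;
all times are expressed in units of `1/k_base` unless a model states
otherwise.

**Conversion and reads.** The whole continuous hairpin strand is converted:
unmethylated C -> T with probability `conv_rate` (default 0.995 — a typical
kit efficiency; the protocol's actual efficiency is not known, so this is a
free simulator parameter), methylated C -> T with
`inappropriate_conv_rate` (default 0).  Substitution errors are applied at
`error_rate` (no indels).  Qualities are constant Q37 by default, or a
two-state good/bad per-base model so that the Q20 filter can be exercised.
A configurable fraction of molecules is emitted in k >= 2 verbatim copies to
exercise deduplication.  All stages draw from `numpy` generators seeded from
one integer; identical seeds give byte-identical FASTQ.

## Read processing

Stages: trim to a fixed length (default: the design's full hairpin span; use
128 for longer raw sequencer output), quality filter (mean Phred >= 20 by
default — the common reading of a per-read quality threshold — with a
per-base option), exact-duplicate removal (first occurrence kept; no UMIs
exist, so full-sequence identity is the only defensible criterion), then
two-strand reconstruction.

The constant left arm, stem-loop and right stub anchor the fixed layout
(no indels are modelled, so anchoring verifies rather than searches); each
anchor tolerates one bisulfite-aware mismatch (template C matches read C or
T).  At each window position the original base is inferred from the pair
(u = top base, l = bottom base reoriented to top orientation):

    (A,A)->A   (T,T)->T   (T,C)->C unmethylated   (C,C)->C methylated
    (G,A)->G, bottom C unmethylated   (G,G)->G, bottom C methylated

Any other pair, or an N, rejects the read with a reason code.  Only
top-strand methylation calls feed downstream analyses; bottom calls are kept
for QC.

**Error propagation.** Bisulfite conversion removes part of the
complementarity redundancy: a single top-strand A read as G produces the
valid pair (G,A) and is accepted as a true G.  The expected wrong-flank
fraction is therefore ~ W·e/3 per read (W = window length, e = substitution
error rate), not quadratic in e; at e = 0 reconstruction is exact.  The test
suite asserts this analytic bound.

## Preference analysis

o/e is computed per position over the full read pool of the selected motif
(methylated + unmethylated) as denominator.  No pseudocounts are added;
counts are retained for uncertainty bookkeeping, zero pool frequencies yield
missing (not infinite) values, and near-cognate profiles are gated by a
minimum number of methylated reads (default 50 in the examples) because
low-coverage profiles show trends only.  The weighted mean of o/e with pool
frequencies as weights is 1 at every position by construction (tested to
1e-9).

The per-position effect size uses all four bases.  A historical variant of
the formula that duplicates the T term and omits G is available behind
`printed_variant=True` for audit; the symmetric four-base form is the
default because the statistic is meant to capture enrichment or depletion of
*each* base.

The activity expansion multiplies raw o/e values (no renormalisation) over
flank positions; the default half-width is 4 (65,536 contexts), with any
half-width up to the library flank supported.  Ranking ties are broken by
lexicographic context order.

**Combinatorial-effect scan.** Observed bin methylation implies an apparent
rate log k = log(-ln(1-m)); under a purely multiplicative model this differs
from log Act only by a constant.  Bins are flagged when their centred
log-rate residual exceeds a quantile (default 0.99) of the residual
distribution.  A pure rank comparison is reported (rank columns, Spearman r)
but not used for flagging: when an interaction is present, the marginal o/e
values partially absorb it, so the interacting context keeps a rank
consistent with the multiplicative prediction and only the rate-scale
residual isolates it.  m is clipped away from {0,1} by half an event; bins
below a coverage threshold are excluded.

## Specificity

Near-cognate variants are the 3L single-mismatch motifs; reads are assigned
to the frame around the fixed central C of the CN library, so variants that
would change that C itself are enumerated but necessarily have zero
coverage.  Sites deviating by more than one base are aggregated into a
single no-detectable-methylation check.

The virtual time axis assigns experiment j the pseudo-time
`t_j = -ln(1 - m_cognate,j)` (cognate rate 1 and amplitude 1 by
construction); variant rates are then fitted on that axis with amplitude
fixed at 1, since the asymptote of any site is complete methylation of the
library.  A single pooled endpoint reduces to the closed form
`fold = ln(1-m_cog)/ln(1-m_var)`.  Variants with zero events get a
lower-bound fold from `p = 1 - alpha^(1/n)` evaluated at the largest
pseudo-time (the conservative choice).  Mutant-vs-wild-type specificity
changes are reported as `(k_var/k_cog)_mutant / (k_var/k_cog)_WT`.

## Profile comparison

Profiles are flattened to position x base vectors; Pearson r and RMSD are
computed over pairwise-complete entries with the count reported.  The
default window is the positions shared by both profiles (-6..+6 in the
standard analyses; the window is configurable because published panels
sometimes show only -3..+3).  Constant vectors yield r = NaN, handled
explicitly, while RMSD remains defined.  Replicate agreement uses Pearson r
over the 256 NN-X-NN bin means with a configurable merge threshold; pooling
reads and then binning is exactly the coverage-weighted combination of
per-replicate counts (tested exactly).

## DNA shape

Shape prediction is consumed, never computed: tab-separated tables with
columns `parameter:position` over all contexts of a motif.  Base-pair-step
parameters are assigned to the left base of the step, so they carry one
fewer position label.  N6 tables are marginalised to N4 by averaging over
the outer bases (marginalisation commutes with the intrinsic mean, tested).
Activity-shape association is plain Pearson r per (parameter, position)
across contexts, with constant features reported missing.  |r| > 0.4 is
conventionally read as strong and > 0.3 as notable; these thresholds are
presentation only.  A synthetic shape generator (values linear in the
one-hot sequence, optionally one parameter affine in log activity) provides
closed-form oracles for tests; it is synthetic and does not model real DNA
mechanics.

## Kinetics

`CPM(t) = A(1 - e^(-kt))` is fitted by unweighted nonlinear least squares
(scipy `curve_fit`, bounds A,k >= 0; A0 = max signal, k0 from a log-linear
fit).  v0 = A·k.  All-zero signals return k = 0 with A flagged undefined.
Replicates are fitted separately and their v0 averaged afterwards
(mean ± SD).  Duplicating data points changes the residual count but not the
optimum (tested to 1e-6).

## Problem sizes and what the tests show

The default verification sizes are 10^4 molecules for round-trip fidelity,
2x10^5 for parameter recovery (chosen so binomial noise on per-position o/e
is well below the log-factor spread of the [0.5, 2] log-uniform ground
truth), 10^5 per replicate for reproducibility checks and 10^3 for exact
oracle equivalence.  The simulator emulates randomized-library composition,
first-order kinetics, strand-specific conversion, duplicates, substitution
errors and quality structure; it does not emulate PCR amplification bias,
chimeras, indels, context-dependent error rates or coverage skews of real
sequencers.  Passing recovery tests therefore demonstrates correctness of
the analysis pipeline under the stated generative model, not robustness to
every artefact of real NGS data.  Headline biological magnitudes
(fold-specificities in the thousands) require the sequencing depth of real
experiments and are not reproduced at these simulation sizes.
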