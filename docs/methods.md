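# Methods

This note documents the models, parameter choices and numerical conventions
behind `bactx`, and what the synthetic benchmark does and does not show
about real data.

## Coordinates and formats

All coordinates are 1-based and fully inclusive on both ends (the GFF3
convention); strands are `+`/`-`. A feature's `start` is always its leftmost
genomic base, so the translation start (TLS) of a minus-strand CDS is its
`end`. Interval length is `|start − end| + 1`; `feature_length` also offers
the bare coordinate difference because published feature tables sometimes
mix the two conventions, and the discrepancy is then the caller's to
resolve, not ours to guess.

Interchange is plain text: GFF3 for annotation, FASTA for the genome, and
three TSV dialects (per-position read starts, single mappings, paired
fragments). A read-start TSV carries `# library:` and `# total_mapped:`
header comments; `total_mapped` is part of the profile's meaning (it is the
RPKM denominator) and must survive serialization, since it can legitimately
exceed the sum of stored counts when the profile covers a subregion of the
library.

## TSS detection

Automatic calling applies three strict inequalities at every covered
position: count > *T* (default 6), count/previous > *R* (default 6), and a
same-orientation protein-coding TLS within *X* = 500 nt downstream.
Choices the rule text leaves open:

* **Zero previous count** passes the ratio criterion: a step from zero reads
  is the sharpest possible accumulation.
* **"Previous position"** is the adjacent position upstream in transcription
  direction (p−1 on `+`, p+1 on `-`).
* **Distance** is TLS_first_base − TSS (mirrored on `-`) and must be ≥ 0.

Manual curation is replaced by two deterministic, auditable heuristics:

* **Near-miss rescue**: a position failing exactly one of the two count
  criteria by at most `rescue_margin` (1) reads is rescued iff
  whole-transcriptome coverage ≥ 1 at each of the 20 positions starting at
  the putative TSS. "One read short" means count ∈ (T−1, T] for the
  background criterion and (count+1)/prev > R for the ratio criterion.
* **False-positive flag**: a candidate is flagged iff its count is below
  half the maximum within ±`fp_window` (50) nt on its strand *and* at least
  3 other positions in that window exceed *T* — the signature of an uneven
  gradient of read starts inside a highly covered region rather than a
  discrete 5′ end. The window is interpreted as a half-width; both
  sub-parameters are exposed in the config.

Candidates whose nearest downstream feature within *X* is a rRNA or tRNA
are removed (stable-RNA 5′ ends survive 5′ enrichment). The bookkeeping
identity `automatic − false_positive − stable_rna + rescued = final` holds
by construction and is asserted in tests.

## Classification, UTRs, novel transcripts

Class precedence is utr > intragenic > antisense > intergenic; the
gene-associated branch wins first, and a TSS inside gene A but within *X*
of gene B is utr-of-B only if it lies outside all same-strand CDS bodies.
UTR length is TLS − TSS (0 means the TSS sits on the start codon);
"leaderless" is < 10 nt. The UTR histogram uses bins 1–5, 6–10, …,
496–500 and a final >500 bin (a length-0 UTR counts in the first bin); the
median is the lower central value for even n, matching how small printed
medians are typically derived.

Antisense classification consults detected 5′-UTR intervals and
3′-UTRs estimated by the same coverage extension used for novel
transcripts: extend downstream while whole-transcriptome coverage ≥ 1,
tolerating gaps ≤ 5 nt (configurable; the choice is a compromise between
fragmentation dropouts and run-through into the next transcript). Novel
transcripts are emitted only when longer than 20 nt.

TLS corrections: an intragenic sense TSS in the first half of a CDS
proposes the nearest in-frame ATG/GTG/TTG at or downstream of the TSS and
before the CDS midpoint as the corrected start.

## Motif discovery

The EM is ZOOPS (zero or one site per sequence): parameters are a PWM, a
site-occurrence prior γ, and a positional prior; the background is 0-order,
estimated once from the input windows and held fixed. An AT-rich genome
(GC ≈ 0.39) makes a uniform background wrong, which is why the background
is data-derived. Three design points matter in practice:

* **Positional prior.** A smoothed categorical distribution over the site's
  distance from the window 3′ end is learned in the M-step (smoothing
  α = 0.02 per distance value). Promoter elements and RBSs sit at nearly
  fixed spacings from the TSS/TLS anchoring their windows; without the
  prior, chance TATAAT-like hexamers in AT-rich background capture several
  percent of the site assignments and corrupt spacer statistics. When
  planted offsets are genuinely uniform the learned prior stays near-flat.
* **Search windows.** The −10 element is searched in the TSS-proximal 22 nt
  of each 70-nt upstream window and the −35 in the spacing-compatible 28-nt
  suffix of the subsequence upstream of each found −10. Core-promoter
  geometry justifies both; operationally, a full-window search lets the
  GC-richer −35 win the likelihood in an AT-rich background (G/C matches
  carry ~50 % more log-odds per base than A/T matches), returning the wrong
  element first.
* **Phase-shift polishing.** After the seeded restarts (default 20,
  pseudocount 0.25 per base, tolerance 1e-6), the best model is re-run from
  ±1-column-shifted PWMs and the best objective kept; plain EM otherwise
  sometimes converges to the motif shifted by one column, which biases every
  spacer by exactly 1 nt.

The monitored EM objective is the data log-likelihood plus the Dirichlet
smoothing terms for the PWM and positional prior (the M-step is a MAP
update, so only this penalized objective is guaranteed non-decreasing; the
trace is exposed on the model and asserted monotone in tests). A sequence
is assigned a site only when its posterior probability of containing one is
≥ 0.5. With the default input-estimated background, an input of identical
sequences (e.g. all-A) carries no signal relative to its own background and
the EM correctly reports no motif; the textbook all-A degenerate fixed
point appears when a uniform background is supplied explicitly.

Consensus coding: per column, the most frequent base is upper-case above
80 % frequency, lower-case above 40 %, else `n`. Printed percentages are
rounded half away from zero to one decimal everywhere (this reproduces the
conventional 959/1,270 → 75.5 style of report arithmetic).

For the RBS analysis each gene contributes one upstream window (20 nt
before the TLS), only genes with a 5′-UTR of ≥ 10 nt are analyzed, and the
longest UTR is used when a gene has several TSSs (the most inclusive
choice; which TSS to use is otherwise arbitrary).

## Operon inference

A fragment bridges a junction iff it covers the last base of the upstream
gene and the first base of the downstream gene; a fragment inside the gap
alone connects nothing. Overlapping same-strand genes are bridged by any
fragment covering the junction point. The joining threshold is 4 bridging
fragments; intervening opposite-strand genes do not break a chain. The
"functionally related" manual rescue becomes an explicit optional input: a
junction one fragment short of the threshold is joined iff both genes share
the same non-empty label, and the join is flagged. Suboperons are suffixes
of the member list headed by an internal utr-class TSS; the primary TSS of
an operon is its first gene's most upstream (longest-UTR) TSS when one
exists.

## Abundance

N counts the feature positions with ≥ 1 read start on the feature's strand
— not the feature length. This reading makes ln(0) terms impossible and
avoids double-penalizing sparse coverage (the length already divides the
final value); the alternative is available behind `use_feature_length`.
The final value is R_norm / (length/1000) / (total_mapped/10⁶) with
per-replicon totals; cross-replicon comparison of these values is not
meaningful and is not offered. Class boundaries are lower-exclusive:
exactly 16 is still low, exactly 1600 still high.

## Synthetic-data generator

The generator emulates the statistical structure the detection procedures
assume; its defaults are the package's study conditions.

* **Layout**: 100 transcription units (operon sizes skewed to 1–2 genes,
  max 8), genes 200–1,200 nt, intra-operon gaps 20–80 nt, inter-unit gaps
  150–400 nt, both strands, GC content 0.386.
* **Promoters/RBS**: −35, triangular 15/17/19 spacer, −10, uniform 4–10
  spacer, TSS; RBS a uniform 5–10 nt before each TLS; TG planted
  immediately before 33 % of −10 elements and explicitly excluded elsewhere
  so the planted extended fraction is exact. PWMs default to 0.92
  conservation per consensus base (~8.8 bits at width 6) — the strongly
  planted regime in which EM site recovery is near-complete; at 0.85, ~5 %
  of planted sites draw ≥ 3 non-consensus bases and are genuinely
  unrecoverable, which is a property of the planting, not the search.
  5′-UTR lengths are 12 + Gamma(1.6, 35) nt: mode ≈ 30 nt with a long right
  tail, median ≈ 50 nt.
* **5′-enriched library**: Poisson(50 × tier multiplier) read starts at
  each true TSS over Poisson(0.2) background within transcribed intervals
  plus a Poisson(0.01) genomic floor (residual processed 5′ ends).
  Negative-binomial overdispersion of the peak is available behind
  `overdispersion`, default off — Poisson is the simplest model that makes
  the T/R thresholds meaningful.
* **Whole-transcriptome library**: fragments with uniform 100–800 nt
  lengths, 5′ starts uniform within each transcript at a tier-specific rate
  (0.006 / 0.06 / 0.6 / 6 starts per position for low / middle / high /
  very-high), truncated at transcript 3′ ends, plus 6–12 planted bridging
  fragments per internal junction. The profile's `total_mapped` is set to
  an effective library size of 10⁶: the simulated replicon is ~20× smaller
  than a real bacterial genome, and modeling the depth explicitly keeps the
  absolute log-RPKM class bands (16/160/1600) meaningful — expected values
  land mid-band at ≈ 6 / 56 / 556 / 5,500. Tier mixing is 5/53/40/2 %.
* **Determinism**: all randomness derives from one integer seed via
  independent named streams; identical parameters give byte-identical
  outputs.

What passing the synthetic benchmark does **not** show: robustness to
overdispersed peaks, condition-mixture effects (real libraries pool many
growth conditions), sequencing error, mapping ambiguity, processed-RNA 5′
ends at internal sites, or weakly conserved motifs (a realistic −35 is
closer to 50–70 % conservation; recovery there is partial by nature).
Problem sizes throughout (100-unit genomes for recovery, 250 units for
spacer statistics, 20 EM replicates of 150×50-mers) are the package's
benchmark conditions, chosen to estimate each metric with adequate
precision.

## Degenerate inputs and tie-breaks

* Empty read-start files yield empty profiles with `total_mapped` 0.
* A TSS with no downstream feature within *X* is kept for the novel path.
* `evaluate_calls` with no predictions reports recall 0 and precision
  not-a-value (None).
* Operon member lists are in transcription order; on `-` that is descending
  coordinate.
* The EM requires ≥ 10 sequences; sequences shorter than the motif width
  contribute background only; an all-too-short input is an error.
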