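# Methods

This note documents the models, defaults and numerical choices behind
`crispramp`, and what the synthetic data do and do not establish about real
amplicon-sequencing runs.

## The analysis model

The pipeline classifies each merged amplicon read against the reference
into WT, Deletion, Insertion, or Delin (a deletion accompanied by an
insertion), with single-nucleotide substitutions deliberately ignored —
both because Illumina substitution errors vastly outnumber true point
mutations at usable depths and because Cas9 repair outcomes of interest
are indels at the cut site.

### Mate merging

An overlap-consensus merge (the role an external merger such as PEAR plays
in a production run, re-implemented here so the whole chain is testable):
all overlap lengths o ≥ `min_overlap` (default 10) between R1 and the
reverse-complemented R2 are scored by matching bases; the overlap with the
most matches wins, ties going to the longer overlap, and is accepted if
its mismatch fraction is ≤ `max_mismatch_frac` (default 0.25).  Consensus
rules in the overlap: the base of the higher-quality mate (R1 on exact
ties); error probability of agreeing bases is the product p1·p2 floored at
1e-4/3 (≈ Q45) so no base ever claims certainty; disagreeing bases keep
the winning mate's error probability.  Failures to merge drop the pair and
are attributed to the merge stage.

### Read filters

* **Quality:** keep iff the maximum per-base error probability is ≤ 0.05
  (inclusive), i.e. the worst base is at least Phred ≈ 13.  This is the
  per-base reading of a "maximum base error-probability" rule — the
  strictest defensible interpretation; the threshold is a parameter
  (`max_err_prob`).
* **Primer containment:** "contains part of both primer sequences" is
  operationalized as an exact k-mer (k = 10) of the forward primer fully
  inside the first 30 bases, and of the reverse-primer annealing region
  (reference orientation) inside the last 30 bases.  Both k and the window
  are parameters; an exact-substring rule was chosen over approximate
  matching because a 10-mer survives anywhere in a 20 bp primer unless two
  errors land ≤ 10 bp apart.

### Alignment and event extraction

Global Needleman–Wunsch/Gotoh alignment with affine gaps, vectorized in
numpy row by row (the deletion state is resolved per row with a running
maximum, which is exact because re-opening a gap from a gap-ended state is
always dominated by extension).  Scores: match +2, mismatch −3, gap of
length L costs 6 + L (open −6, extend −1 per gapped base; equivalently
Biopython's open −7 / extend −1).  These favor one contiguous indel at the
cut over scattered substitutions: a 1 bp difference is cheaper as a
substitution (−3) than as a gap pair, so isolated sequencing errors never
become indel calls, while any length change must be a gap.  Traceback
tie-breaks are deterministic: diagonal, then deletion, then insertion, and
gap extension before a fresh opening.

Gaps are then shifted maximally leftward (a gap run moves left through a
matching column when the move preserves both sequences and the score), so
every equivalent placement of an indel in repeated sequence collapses to
one canonical signature — required for support counting to be meaningful.

Events are maximal runs of non-match columns.  A run with reference gaps
only is an Insertion, read gaps only a Deletion, both a Delin (any
substitution columns inside a mixed run contribute their reference base to
the deleted interval and their read base to the insertion); a run of
substitutions only is discarded.  A Deletion and an Insertion separated by
at least one match column are two events, not a Delin — contiguity is the
most literal reading of "accompanied by".

One consequence worth stating: the canonical form of an edit is defined by
optimal alignment under this scoring, not by the naive description of how
the edit was made.  A "delete ACG, insert T" delin whose inserted base
matches a deleted one may optimally align as a substitution plus a smaller
deletion, and an equal-length delin is indistinguishable from
substitutions and therefore invisible.  The test suite's oracle
(exhaustive enumeration of co-optimal alignments on ≤ 30 bp instances)
encodes exactly this definition.

### Event filters and read classification

Events must start strictly more than `margin` = 5 bp after the forward
primer's end and end strictly more than 5 bp before the reverse primer's
start (the published rule names the event start; it is applied
symmetrically to the end, strict on both sides).  Event identity is the
exact tuple (class, ref_start, ref_end, inserted sequence) after left
alignment; signatures seen in fewer than `min_support` = 2 distinct reads
are removed, and a read whose every event is removed reverts to WT.
Support is counted over the pooled sample set handed to the caller, after
position filtering.  A read retaining events of different classes is
classified Delin and flagged (`multi_event`); such reads are rare.

Percentages are computed over reads passing all filters — the denominator
convention for every reported fraction.

## The simulator

`amplicon_sim` generates what the analysis assumes: a 283–490 bp amplicon
whose protospacer carries exactly one diagnostic recognition site (NcoI
CCATGG or DdeI CTNAG) overlapping the cut, an NGG PAM, and a blunt cut
placed 3 bp upstream of the PAM (the canonical SpCas9 cut; mutations
cluster directly upstream of the PAM but the offset itself is a
convention here).  Primers occupy the amplicon's first and last 20 bases.

Positive-control defaults, chosen to reflect an insertion-dominated
spectrum with ~23% edited reads:

| parameter | default | rationale |
| --- | --- | --- |
| edited_fraction | 0.23 | positive-control operating point |
| class weights | Ins 0.65 / Del 0.25 / Delin 0.10 | insertions 4–5× deletions, delins minor |
| ins sizes | P(1 bp) = 0.8, geometric tail (p = 0.35) to 72 bp | 1 bp insertions dominate |
| 1 bp insertion bases | A 0.45 / T 0.45 / C 0.05 / G 0.05 | A-rule: polymerases fill non-instructional sites with dAMP, biasing single-base insertions to A/T |
| deletion sizes | geometric (p = 0.2) over 1–46 bp | small deletions dominate, bounded tail |
| read length | 200 | mates overlap the 283 bp amplicon by ≥ 100 bp and still overlap after a 72 bp insertion |
| qualities | Phred ~ N(mean_q = 30, sd 3), clipped to [2, 40] | no quality model is published; clipped normal is a plain surrogate |
| errors | substitution at 10^(−Q/10) per base | Illumina-style; no indel errors |

Repair outcomes recur rather than being arbitrary strings: insertions
longer than 1 bp are tandem duplications of the sequence 5′ of the cut
(the dominant templated outcome at real loci), deletions take a
deterministic cut-centred interval per size, and a delin's fill-in is a
deterministic function of its deleted interval, drawn from bases absent
from the deleted run and its flanks so that the delin's canonical form
keeps its class, and with an inserted length different from the deleted
length (an equal-length fill-in is a substitution run, which the taxonomy
ignores).  This concentration is what makes the "seen at least twice"
support filter remove only genuinely rare outcomes, as it does in real
data where independent cells converge on the same repair products.

What the simulator does **not** model: PCR cycle noise and chimeras,
indel sequencing errors, quality-by-cycle profiles, microhomology-driven
deletion endpoints, sample demultiplexing.  Passing tests therefore show
that the analysis recovers truth under the stated statistical structure,
not that it is robust to every artifact of a real sequencing run.

## Assay calculators

* **Pre-digestion enrichment:** templates with an intact site survive
  digestion with probability 1 − e (default e = 0.9, a configurable
  efficiency; complete digestion is rarely achieved on genomic DNA).  A
  mutant fraction f is observed after enrichment as
  f′ = f / (f + (1 − f)(1 − e)); `enrichment_correct` applies the exact
  inverse f = f′(1 − e) / (1 − f′e).  The pair is validated as exact
  inverses and against a Monte-Carlo pool.
* **T7EI:** with cleaved fraction fc = cleaved / (intact + cleaved),
  percent indels = 100·(1 − sqrt(1 − fc)): reannealing a mutant fraction m
  with abundant WT yields heteroduplexes at 1 − (1 − m)², neglecting
  mutant/mutant homoduplexes and enzyme inefficiency.  The raw cleaved
  percentage is available as a flag since gel semi-quantification
  conventions differ.
* **Colony counts:** per-plate titer = colonies · dilution / volume;
  plates are combined by a count-weighted mean (weighting by colonies
  approximates inverse-variance weighting under Poisson counting).  The
  frequency divides resistant colonies by viable cells screened; its 95%
  CI is the exact (Garwood) Poisson interval on the resistant count —
  counting error dominates when resistant colonies are few.  Per-replicate
  frequencies with mean ± SEM are also provided, since replicate-level
  variation (co-cultivation efficiency) exceeds counting error in
  practice.  "Directly upstream of the PAM" is quantified as within 10 bp
  upstream, inclusive, for mutation-position classification.

## Reproducibility and problem sizes

A single seed fans out to per-stage child seeds through numpy's
`SeedSequence`, making every run a pure function of (config, seed);
reruns are byte-identical.  The acceptance script simulates 5,000 pairs
per scenario — large enough that the 3-binomial-SD recovery bands are a
few percentage points wide, small enough to run in seconds — and the
exhaustive alignment oracle covers every single edit (deletions ≤ 5 bp,
insertions ≤ 3 bp, delins ≤ 3+3) on references up to 30 bp.

## Known limitations

* The event caller targets a single amplicon; multi-locus or structural
  variants beyond the amplicon are out of scope.
* Substitution calling is intentionally absent; a real point-mutation
  screen needs a different error model.
* The "seen at least twice" rule is applied to whatever read set is handed
  to the caller; pooling across samples before or after filtering changes
  its meaning, so pool deliberately.
* Real target loci are not reproduced — the simulator generates sequences
  satisfying the stated geometry, since the published loci are not
  available as machine-readable text.
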