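# Methods

## Problem and scope

`rilpipe` reimplements, as a tested library, the computational core of a
chaperone-centered RNA–RNA interactome analysis for bacteria. The input
is a proximity-ligation sequencing library (RIL-seq-style): RNAs bound
to an immunoprecipitated RNA chaperone (Hfq) are trimmed and ligated, so
each sequenced mate pair derives either from one RNA (a *single*
fragment) or from two distinct, co-bound RNAs joined by the ligase (a
*chimeric* fragment, evidence of an sRNA–mRNA pairing event). The
pipeline classifies fragments, calls statistically supported interacting
region pairs (S-chimeras), assigns genes, quantifies features, and —
because the protocols need rRNA removal — designs DASH depletion guide
pools. A generative simulator supplies libraries with known ground truth
so every stage can be validated without sequencing data.

The pipeline consumes already-mapped mate pairs (BEDPE); demultiplexing,
trimming, and alignment are out of scope, as are negative-binomial
differential-expression inference and Circos rendering (link tables are
emitted, drawing is not).

## Fragment classification

Mate strands are first resolved to transcript strands: in a
reverse-stranded library the sequenced strand is the complement of the
transcript, so both mates flip (`transcript_strand`; an involution).
A pair is **Single** iff both mates share a chromosome and transcript
strand, mate 1 is the transcript-5′ piece of the construct (inward
orientation), and the inter-mate gap is at most `max_gap` (default
1000 nt, exposed as `--max-gap`); its locus is the merged interval.
Everything else is **Chimeric**, ordered RNA1–RNA2 by construct
position (mate 1 = RNA1, the ligation-upstream piece). Proximal
same-strand pairs that fail only the orientation check are chimeras
with ambiguous construct order; they are ordered by (chrom, start) for
determinism. The published chimera-calling tool does not document its
exact rule; this operationalization captures "two proximal RNA
molecules read as one" and keeps every choice a named parameter.

## S-chimera calling

Chimeras are binned by the midpoint of each locus onto ordered pairs of
fixed 100-nt windows per strand. Ordered pairs are deliberately not
symmetrized; by convention the mRNA region appears in RNA1 and the sRNA
in RNA2. For each observed window pair, with `a` joint chimeras,
marginals `n_a` (RNA1 in window 1) and `n_b` (RNA2 in window 2), and
library total `T`, the one-sided Fisher's exact p-value is the
hypergeometric upper tail P(X ≥ a) with population `T`, `n_a` successes
and `n_b` draws (`scipy.stats.hypergeom.sf`); the odds ratio is
(a·d)/(b·c) with the +∞ convention when b·c = 0 and a·d > 0.

Significant (p < α, default 0.05) window pairs adjacent in both
dimensions are merged into maximal region pairs (union–find over the
8-neighborhood of window-index pairs); each merged region pair sums its
supporting chimeras and keeps the minimum p. The ≥5-fragment floor is
applied to the merged total — the floor qualifies a *reported pair of
RNAs*, which is the merged region, not an arbitrary window slice. No
multiple-testing correction is applied beyond these two printed
thresholds; optional Benjamini–Hochberg is available behind a
non-default flag. Chimeras outside every S-chimera region pair
(membership by the same midpoint rule, orientation respected) are
filtered as non-specific, which makes retained-chimera counts exactly
equal the summed `interactions` column.

Gene assignment uses the read-share rule: per region, reads overlapping
each same-strand feature (≥1 shared base) are counted; if the top
feature's share of feature-overlapping reads is strictly greater than
0.7 it is assigned exclusively, otherwise all overlapping features are
kept in decreasing share order. A region overlapping no feature falls
back to the nearest same-strand feature with a `.near` suffix — an
explicit, flagged fallback for an input situation the rule does not
cover.

### Statistical behavior worth knowing

The exact test is calibrated *per test*: over the fixed universe of
margin-positive window pairs, the null rejection rate is below α
(discreteness makes it conservative; ~0.01 observed). Restricting
attention to *observed* pairs (n_ab ≥ 1) is not a valid error-rate
frame: a singleton chimera between two low-abundance windows is already
"significant" on its own, which is precisely the pathology the
≥5-fragment floor guards against. The test suite measures type-I error
in the calibrated frame and separately verifies that the floor blocks
sparse-but-extreme pairs.

## Annotation construction

Internal coordinates are 0-based half-open; GFF3 I/O converts to/from
1-based inclusive. From a base annotation (genes, sRNA/tRNA/rRNA,
curated UTRs) the composer derives:

* **EST5UTR / EST3UTR** — up to 100 nt beyond each coding gene end,
  truncated at the nearest same-strand feature. When the predicted UTRs
  of two facing genes would overlap inside one gap, the gap is split
  deterministically (each side capped at half, unused room ceded to the
  other) so predicted UTRs never overlap anything on their strand.
  `--skip-if-known` (default on) suppresses prediction where a curated
  UTR already names the gene.
* **AS** — one antisense feature per coding region, identical
  coordinates, opposite strand, named `<gene>.AS`; overlapping genes
  yield overlapping AS features (no merging, keeping per-gene names).
* **IGR / TU** — strand-specific maximal gaps between the merged
  footprint of *all* stranded features (base + predicted UTRs + AS),
  recomputed after the union; gaps strictly shorter than 100 nt are TU
  (likely within one transcription unit), the rest IGR, named
  `left.right.TYPE`. IGR∪TU therefore exactly tiles the internal
  feature-free space per strand — a tested invariant.

Chromosomes are treated as linear: terminal regions receive UTR
extensions but no wraparound IGR. Gene names containing periods are
rejected (the period is the derived-name delimiter).

## Quantification

Single and chimeric fragments alike are counted per feature with
multi-overlap semantics (a fragment overlapping k same-strand features
increments all k; chimeras contribute each locus once); orphan
fragments are tallied under a reserved `unassigned` row. Libraries are
normalized with median-of-ratios size factors; fold changes are
pseudocounted (default 1.0) mean ratios against a reference sample
group; IP/Total enrichment is log2((IP+pc)/(Total+pc)), positive =
bound. This deliberately replaces dispersion-shrinkage
differential-expression modeling: the claims here concern the
interactome pipeline, not negative-binomial inference. Per-pair chimera
tables are normalized by library totals before cross-strain ratio
displays.

## DASH guide design

Target regions (rRNA loci in practice) are scanned on both strands for
NGG PAMs; each PAM with ≥20 nt available 5′ on its strand and a
protospacer overlapping a target region yields a candidate
(reverse-strand protospacers reported as reverse complements; Ns never
match). Filters: 0.30 < GC < 0.80 (strict); heterodimer Tm ≤ 40 °C;
3′-end stability Tm ≤ 30 °C. Melting temperatures come from the
nearest-neighbor model (`Bio.SeqUtils.MeltingTemp.Tm_NN`, default salt
and strand concentrations): heterodimer Tm is computed on the longest
perfect heteroduplex between protospacer and amplification primer
(longest common substring against the primer's reverse complement), end
stability on the protospacer's 3′-terminal 5-mer. The primer is a
required input — the published protocol names the thresholds but not
the primer or thermodynamic engine, so both are explicit here, and
"metric ≤ threshold passes" is the declared direction. Off-target
search is exact-match protospacer+NGG on both strands; a guide is
discarded if *any* occurrence lies outside the target regions (repeats
inside targets, as in rRNA operons, are fine). Final oligos are
`T7 promoter (TTCTAATACGACTCACTATA) + protospacer + scaffold
(GTTTTAGAGCTAGAAATAGC)`, 60 nt, deduplicated, in deterministic order.
The published pool size (822 guides for *E. coli* rRNA) depends on the
external genome/annotation versions and is not a reproduction target.

## The generative model

Each of `n_fragments` captured events is, independently:

* a **planted chimera** with probability `p_lig · ρ · (1 − ε)` — a
  planted (sRNA, mRNA, λ) triple is drawn ∝ λ; each partner contributes
  one mate scattered ±30 nt around a fixed per-pair interaction site at
  the feature midpoint, with fragment lengths ~ Normal(25, 5) truncated
  at 15 nt. RNA1 = mRNA, RNA2 = sRNA (mRNA-first convention);
* a **background chimera** with probability `p_lig · ε` — two loci
  drawn independently ∝ expression weight, uniform position within each
  feature (abundance-driven random ligation);
* otherwise a **single fragment** within one feature drawn ∝ weight.

Expression weights are log-uniform over two decades so abundant species
dominate the background, as tRNA/rRNA chimeras do in real in-vivo
ligation libraries. Mate strands are emitted as aligned strands
(flipped when the library is reverse-stranded, the default), so the
pipeline's strand resolution is genuinely exercised.

`ρ` (chimera retention) carries the strain effect and `p_lig` the
protocol. Defaults are chosen once to match the reported regimes:
`p_lig = 0.20`, `ρ_WT = 0.75`, `ε = 0.03` give a wild-type chimera
fraction of ~15% and (at ρ/100) a rim-mutant fraction of ~0.7%;
`p_lig = 0.022` gives the ~1.7% fraction of in-vivo ligation
(iRIL-seq-like); the RIP-like protocol forces `p_lig = 0`. Strain
scenarios scale ρ by 1/100 (in-vitro ligation protocol) or 1/10
(in-vivo), expressing pair dissociation from the mutant chaperone
during capture; the mutant is *not* modeled as a change in λ
specificity (a per-pair λ override exists for that). Planted pairs
exclude same-strand partners closer than 2 kb, which would otherwise be
correctly — and unrecoverably — classified as one merged single
fragment by the distance rule.

Default study sizes: a 200-kb genome with 40 mRNAs, 20 sRNAs, 5 tRNAs,
2 rRNAs; 20 planted pairs with λ ∈ [0.5, 2]; 20,000 fragments, giving
~3,000 wild-type chimeras with every planted pair expected ≥ 15
supporting fragments. All randomness flows from one seed
(`numpy.random.default_rng` with derived streams for genome, planting,
and library); identical configuration + seed yields byte-identical
outputs.

### What the simulator does not model

Sequence-level base-pairing energetics, read errors, multi-mapping,
crosslinking chemistry, positional biases along transcripts, and
overdispersed (non-multinomial) capture. Passing recovery tests
therefore shows that the *statistics and bookkeeping* behave as
specified under a faithful idealization of the capture process — not
that the pipeline is robust to every artifact of real libraries.

## Numerical choices

* Fisher p-values: `hypergeom.sf(a−1, T, n_a, n_b)`; the test suite's
  independent oracle enumerates the pmf from exact integer binomial
  coefficients and takes per-margin suffix sums in a padded matrix
  (a flat cumulative sum across margins of wildly different magnitude
  loses small terms). Agreement is ≤ 1e-15 over all ~7·10⁷ feasible
  tables with T ≤ 200.
* Degenerate odds ratios: ∞ when b·c = 0 with a·d > 0, NaN for 0/0.
* Empty libraries report a chimera fraction of 0 with a warning.
* Window membership and region membership both use locus midpoints, so
  filtering and counting are mutually consistent (conservation is
  asserted, not hoped for).
* Merged S-chimera regions keep the minimum-p window's p and odds
  ratio; re-testing merged regions against re-binned margins would be a
  different statistic and is intentionally not done.
* Size factors require at least one feature nonzero in every sample;
  the error message advises pseudocounting, which `run_pipeline` does
  (+1) before IP/Total enrichment.

## Known limitations

* The exact contingency construction of the original published
  significance tool is undocumented; this package fixes a canonical
  over-representation test and exposes every threshold. Agreement with
  the original tool bit-for-bit is a non-goal.
* Region merging is rectangle-maximal over significant windows; two
  interactions closer than one window on both axes merge into one
  reported pair.
* Multi-mapped reads are out of scope (one best mapping per mate).
* At desk scale the S-chimera count saturates at the number of planted
  pairs, so mutant fold-drops are floor-limited (reported as ≥; the
  retention sweep, which is monotone, carries the quantitative
  contrast).

## Problem sizes used by the test suite and acceptance script

Full Fisher sweep to T = 200 in tests (~90 s) and T = 120 in the
acceptance script; 20 null libraries of 5,000 fragments; wild-type and
mutant scenarios at 20,000 fragments; 100 random toy genomes for
annotation invariants; toy genomes of a few kb for guide design. These
sizes were chosen so the entire validation runs in minutes on one CPU
while every Monte-Carlo band stays at 3σ.
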