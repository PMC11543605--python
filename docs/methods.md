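# Methods

This note records the models implemented in `isoeval`, the choices made where
a published definition leaves room, and what the synthetic benchmark does and
does not establish about real data.

## Coordinates and identity

All internal coordinates are 0-based half-open; GTF I/O converts to and from
the 1-based inclusive convention at the boundary, so interval arithmetic is
unambiguous everywhere else. A transcript's identity for structural
comparison is its junction chain: the exact ordered list of intron
coordinates on (chromosome, strand). Chain identity is never fuzzed — end
variability is handled exclusively at TSS/TTS evaluation with the end
window, mirroring the separation between junction accuracy and end accuracy
in spike-in style evaluations. Splice-site identity is the exact genomic
coordinate *and role*: a position annotated only as an acceptor counts as a
novel donor when a query uses it as one.

## Structural classification

Categories are assigned with precedence FSM > ISM > NNC > fusion > NIC >
other:

* FSM: chain present in the reference chain index. When several references
  share the chain, the match minimizing |ΔTSS| + |ΔTTS| is reported
  (deterministic, end-aware tie-break; ties broken lexicographically).
* ISM: the chain is a consecutive, *proper* sub-run of one reference chain.
  A non-consecutive subset of one reference's junctions is not ISM; it falls
  through to the novelty categories.
* NNC: any donor or acceptor absent from the strand-aware reference site
  sets. This check runs before NIC because a single novel site makes the
  transcript "not in catalog" regardless of what else it contains.
* fusion: all sites annotated but the query spans two or more disjoint
  same-strand reference loci. Fusion is tested between NNC and NIC: if it
  were tested after NIC, the NIC "junction-combination" catch-all would
  absorb every all-annotated-site fusion and the subtype would be
  unreachable; if before NNC, transcripts bridging loci with novel sites
  would escape the unconditional novel-site rule.
* NIC: all sites annotated; the reason is resolved in the order intron
  retention (a query exon strictly containing an annotated intron of a
  same-strand overlapping reference, both flanking splice sites inside the
  exon) → novel junction from known sites (a query intron absent from the
  junction set) → junction combination (all junctions known, the ordered
  combination new).

The novelty categories apply only to queries *associated* with the catalog:
same-strand span overlap with a locus, or at least one shared annotated
splice site or junction. Unassociated queries are "other" — antisense when
they overlap a locus only on the opposite strand, intergenic otherwise. This
gate is what makes an antisense copy of a gene antisense rather than NNC.

Mono-exon queries have no chain, so FSM is never assigned. They are called
mono-exon-match when a same-strand mono-exon reference overlaps with both
ends within the window; otherwise genic (same-strand span overlap),
antisense, or intergenic. This rule is a design choice: published category
systems leave unspliced models under-specified, and the window-based rule is
the natural analog of the reference-match definition.

"Within 50 nt" is inclusive (≤ 50) everywhere; the boundary is tested
explicitly. Enlarging the window can only turn end flags from false to true.

Support flags degrade gracefully: absent evidence components leave their
clauses false (for SRTM/SNTM composition) while submission-level profile
fields that *require* the missing component (canonical-site percentages
without a genome, short-read support without junction counts) are reported
as unavailable, never as zero. Canonical introns are GT-AG, GC-AG, or AT-AC
read strand-aware from the genome; the poly(A) scan looks for AATAAA or
ATTAAA within 50 bases upstream of the 3' end on the transcript strand.

## Detection scoring

Truth-side counts operationalize the named metrics (no printed formulas
exist for them): TP = truth transcripts with at least one prediction whose
chain matches and whose both ends are within the window; PTP = chain match
only; FN = no chain match. Prediction-side: precision = chain-and-end
matching predictions / all predictions; FP = predictions matching no truth
chain; redundancy = chain-matching predictions / distinct truth transcripts
matched (≥ 1 when defined, undefined when nothing matches). Non-redundant
precision is reported as distinct-truth-matching predictions / all
predictions — the definition is not published, so the field is documented as
this package's reading. Mono-exon truth transcripts (long unspliced
spike-in analogs) have no chain and are matched by same-strand overlap, with
the same end-window upgrade. F1 = 2PR/(P+R), 0 when both are 0.

## Quantification statistics

* SCC uses average ranks on ties (scipy); an independent transcription of
  the rank-covariance formula backs it in the tests. Constant vectors make
  rank correlation undefined; NaN is returned and reported as missing.
* The evaluation id set for SCC/NRMSE/PET is all ground-truth transcripts;
  estimates missing an id contribute 0, penalizing non-detection. MRD
  additionally restricts to θ_i > 0 because of the division.
* IM: CV_ig = s_ig/u_ig on log(TPM+1), with s_ig using the 1/R
  denominator — the defining formula is printed that way even though the
  surrounding prose says "sample s.d."; a `ddof` argument exposes the n−1
  reading. Cells with u_ig = 0 (all-zero transcript in a group) are
  excluded and counted. NRMSE's s_Θ has no printed denominator and uses the
  sample (n−1) convention.
* The CV curve behind ACVC is integrated by the trapezoidal rule over 50
  equal-frequency bins of u_ig (bin means on both axes). The published
  curves fix neither the binning nor the integrator; equal-frequency bins
  keep the heavy low-abundance tail from dominating the grid.
* C(α) counts agreement events (both replicate values < α or both ≥ α) over
  all (transcript, group, replicate-pair) triples. The scalar CM is C(1) on
  the log(TPM+1) scale and ACC integrates the default grid α ∈ [0, 10] in
  steps of 0.1 — consistent in magnitude with published ACC values near 9.5;
  both the grid and the scalar point are explicit arguments. C(0) = 1 holds
  identically because log(TPM+1) ≥ 0. Natural logarithms are used
  throughout; CV is base-invariant but CM/ACC are not, so the base choice is
  part of the metric definition here.
* RE bins estimates into M (default 100) bins of width max(Θ̂)/M, indexed
  from 0 with the top edge inclusive so the maximum is always counted.
  A constant profile lands in one bin and gives RE = 0 exactly, matching
  the stated limit independent of edge conventions; an all-zero vector
  returns 0 by convention.
* K-value: columns of the exon-isoform matrix are the distinct exact
  (start, end) exon intervals of the gene ("what counts as one exon across
  isoforms" is otherwise undefined); an alternative disjoint-segment
  construction is available via `mode="segments"`. K is the ratio of the
  largest to smallest of the min(I, E) singular values; σ_min below
  10⁻¹²·σ_max reports +inf (rank-deficient structure, e.g. duplicated
  isoform rows).
* Cell mixing: expected = w·a + (1−w)·b over the id union, renormalized to
  10⁶ TPM (a mixture of two TPM vectors is again a relative abundance).
  `recover_mixing_ratio` grid-searches w (default step 0.01) minimizing
  NRMSE.
* The feature-stratified report recomputes SCC/MRD/NRMSE inside bins of
  per-transcript features (truth TPM, exon count, length, isoforms per
  gene, K); "normalized MRD" is the min–max normalization of MRD across the
  bins of one feature — a display convention, flagged as such. Empty bins
  report missing values.

## Synthetic benchmark

The generator emulates the statistical structure the evaluators consume, not
biology. Defaults: 20 non-overlapping genes on one chromosome, 2–4 isoforms
per gene built from 5–9 exon slots (exons 80–300 nt, introns 200–1500 nt),
500 queries drawn from a 50/15/15/10/10 FSM/ISM/NIC/NNC/other mix — a
reference-guided-pipeline-like category profile — with terminal-end jitter
of sd 20 nt (comfortably inside the 50 nt evaluation window), truth
abundances log-normal (meanlog 1, sdlog 1.5; heavy-tailed, many TPM ≤ 2
transcripts) normalized to 10⁶, multiplicative log-normal replicate noise of
sd 0.3 on 2 groups × 3 replicates with 5% dropout, and a 0.5 mixing ratio.

Constructions guarantee labels at generation time: FSM copies a reference;
ISM keeps a consecutive intron run; NIC skips an exon slot unused by any
reference isoform (novel junction, known sites) or merges two exons across
an internal intron (retention); NNC shifts one splice site by 3–12 nt to an
unannotated position; "other" is an antisense copy or an intergenic
mono-exon model. Each construction is checked against the chain index and
site sets, so recovery is exact at zero jitter. End jitter touches only
terminal exon ends and therefore never changes a category. Truth, noise, and
dropout use independent seed streams, so varying one parameter (the noise
ladder) holds the other draws fixed; identical seeds give byte-identical
output files.

What passing these tests does **not** show: robustness to alignment
artifacts, truncated or chimeric reads, overlapping genes, paralogs,
unannotated loci at scale, or realistic sequence composition — the genome
is random with motifs stamped in, and noncanonical splice motifs (when
enabled) can collide at shared splice sites of overlapping introns, where
the last stamp wins.

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale inputs — tens of
genes, hundreds of queries, formula checks on vectors of length ≤ 6, bound
checks over 1,000 randomized small instances — sizes at which every oracle
can be computed by direct enumeration. All randomness flows from explicit
integer seeds via numpy's `default_rng`; hypothesis-based property tests are
derandomized.

## Known limitations

* ISM matching is genome-wide over references sharing a junction with the
  query; a same-chain reference at a *different* locus (impossible here,
  since chains embed coordinates) cannot arise, but the "same locus"
  requirement is implicit rather than checked.
* The fusion call counts overlapped same-strand loci by span, so a query
  inside one gene that merely pokes into a neighbor's span without sharing
  structure would also be called fusion.
* `junction_profile` treats the distinct-junction set of a submission as the
  denominator; per-transcript weighting would give different percentages.
* Duplicate transcript ids in one GTF are detected only insofar as they
  produce an invalid merged exon list (overlapping/duplicate exons), which
  is how they manifest after attribute-based grouping.
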