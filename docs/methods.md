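# Methods

## The detection model

A TIP is evidenced by *junction read pairs*: one mate matching a TE family
consensus, the other matching unique genomic sequence next to the
insertion point. The caller never attempts base-pair breakpoints — the
unit of assertion is a `(family, 10-kb window)` event per accession. This
windowed contract is what makes panel-scale scanning cheap (no whole-genome
read mapping) and is also the resolution at which all downstream joins
(validation, orthology, GWAS phenotypes) operate.

Support counting uses distinct pair ids; PCR/optical duplicates are not
collapsed. Insertions also present in the reference are reported like any
other event — the method detects TE-adjacency evidence per window and does
not subtract reference genotypes. Accessions are processed independently
and opened-window sets merged by set union, so results are independent of
processing order and trivially parallel.

### Two-pass thresholds

Opening requires ≥ 5 supporting pairs in at least one accession; rescue
requires ≥ 2 pairs, evaluated for *all* accessions (including the opener —
the `pass` field records which regime a call met) but only inside opened
windows. Both thresholds are parameters (`open_threshold`,
`rescue_threshold`) with defaults 5 and 2. Lowering the opening threshold
can only add opened windows, and every pass-1 call survives pass-2 rules;
both properties are asserted in the test suite.

## Alignment layer

One internal seed-and-extend aligner serves every stage, so detection,
mappability and validation share a single definition of "places uniquely".

* **Seeding**: exact 21-mers against a sorted-array index of the targets,
  both strands indexed. Query coordinates are always reported in the
  query's own orientation; target coordinates on the forward strand.
* **Extension**: seeds on one diagonal are extended gaplessly and scored
  +1/−2 (maximal-scoring segment); seed clusters spreading over several
  diagonals (indels present) are resolved with banded bit-vector edit
  distance (edlib), the semi-global result trimmed back to a local
  alignment at cigar-run granularity and re-scored with +1 match, −2
  mismatch, −4 gap open, −1 gap extend.
* **Significance gate**: an alignment qualifies when it covers ≥ 80 bp of
  the query at ≥ 95 % identity (anchoring; both configurable). A fixed
  length-and-identity gate replaces e-value cut-offs deliberately:
  e-values depend on database size, a gate does not. Read-vs-consensus
  matching uses a looser gate (≥ 50 bp at ≥ 90 %) because a junction mate
  may only partially overlap the element.
* **Uniqueness**: a placement is unique iff it passes the gate and either
  no second placement passes or the best score beats the runner-up by
  ≥ 10 (micro-homology at repeat edges should not discard a read whose
  placement is otherwise obvious). The same rule, applied to 100-bp tiles,
  *is* the mappability definition, so the track is by construction the
  detectability bound of anchoring.
* **Ties** between families are broken toward the lexicographically
  smallest family id and flagged, never silently dropped.

Known heuristic limits: a qualifying placement with mismatches spaced
closer than the seed length everywhere (≤ 20 bp apart across its whole
span) has no exact seed and can be missed; with the simulator's error
regimes this is astronomically rare, and the oracle-equivalence tests use
error-free queries where seeding is complete.

## Mappability

Each 10-kb window is cut into non-overlapping 100-bp tiles (trailing
fragments < 100 bp are excluded from numerator and denominator; the paper
trail for "sliced" does not fix a step, and non-overlapping tiles make the
fraction an unweighted average over disjoint evidence). A tile with more
than 10 Ns is non-unique by definition. A fast path skips full anchoring
for tiles whose k-mers all occur exactly once across both strands of the
genome — such tiles cannot have a second exact k-length match anywhere —
and the remainder are anchored for real.

## Long-read validation

A long read is a junction read when its best consensus hit covers at most
80 % of the read (more means the read lies inside an element and carries
no junction). Up to two 300-bp flanks adjacent to the TE interval are
mapped under a stringent gate (≥ 250 bp at ≥ 90 % identity, unique); the
flank base adjacent to the TE gives the insertion coordinate. Single-flank
evidence is accepted and labelled (`flank_side`). Insertions are
de-duplicated to (family, window) loci before comparison.

Comparison with short-read calls is per (family, window) with one
concession to the grid: paired-end support spreads up to about an insert
size around a junction, so a call for a junction within 500 bp of a window
edge may land in the adjacent window. A long-read insertion that close to
an edge snaps to the neighbouring window when that window (and not its
own) was called. Each insertion contributes exactly one locus, keeping
TP + FP = calls and TP + FN = loci exact; `boundary_margin=0` restores
strict same-window matching. Following the source method's usage,
*specificity* is the fraction of short-read calls confirmed and
*sensitivity* the fraction of long-read loci recovered.

## Paleontology

Full elements are discovered by querying each assembly with the family's
RT domain (or a configured low-copy internal probe for non-coding
LARD-type families), merging hits closer than one consensus length,
extending 1.5 consensus lengths to each side and requiring two
non-overlapping LTR placements (≥ 50 % of the LTR at ≥ 85 %); the element
is trimmed to the outer LTR bounds. Solo LTRs and heavily truncated copies
are rejected by construction.

**Dating.** Identity is taken from the largest local alignment between the
element's two halves (only the LTRs align). Age = (1 − identity)/(2r),
r = 1.3 × 10⁻⁸ substitutions/site/year. No multiple-hit correction is
applied by default: at the identities in play (≥ 0.96) the Jukes–Cantor
correction is ≲ 2 % of the age, well inside the binomial noise of a 1–2 kb
LTR; it is available behind a flag. The round-trip tests (2-kb LTRs,
200 replicates per age) recover 10⁵–10⁶-year ages within 3 % in the mean.

**Orthology.** 300 bp upstream of the element (plus strand of the source
assembly; strand is not inferred) must produce exactly one hit covering
≥ 90 % of its length in the target assembly; the 15 kb downstream of that
anchor is scanned for a consensus match. Unresolved flanks (0 or > 1 hits,
or an element too close to the contig edge) exclude the element.
Presence/absence across the three assemblies maps to seven categories;
group-specific categories are validated at ≥ 60 % carrier frequency in the
matching varietal group, shared categories at ≥ 80 % in every implicated
group, with elements joined to matrix rows via the window containing the
element start (the join the source leaves unstated).

## The simulator

The generator emulates the study conditions at desk scale, defaults chosen
once: a 2-Mb i.i.d. background at GC 0.44 with planted duplicated blocks
(2–12-kb units, 2–4 copies, a quarter inverted) totalling 40 % of the
genome; 12 accessions; 60 insertion loci of 2 LTR families assigned
frequencies from Beta(0.3, 5) — an L-shape putting most loci at 1–2
carriers, re-drawn so every locus has at least one carrier; clean
full-length splice-ins with a 5-bp target-site duplication and no nesting;
2×100-bp pairs at 15× with 350 ± 50-bp inserts and 0.5 % uniform
substitution error, constant Phred-30 qualities; long reads with
log-normal lengths (median 8 kb) at 11×, errors split evenly between
substitution, insertion and deletion. LTR divergence is simulated by
independent per-site substitution at probability r·t on each LTR copy
(≈ 2rt between them). Library, reference, panel and each accession's reads
draw from independently spawned RNG streams of one master seed, and all
outputs are byte-reproducible per seed.

What the simulator does *not* model — indel sequencing errors in short
reads, nested/truncated insertions, solo-LTR formation, segregating SNPs
between accessions, non-uniform coverage — bounds what green tests mean:
they demonstrate the pipeline's logic and its mappability-limited
behaviour, not robustness to every artefact of real libraries.

### Scoring detection against truth

A call matches a truth locus of the same family carried by that accession
when the locus lies within the call window extended by 500 bp (≈ insert
mean + 3 SD): anchors land up to an insert size from the junction, so
calls can legitimately spill into the neighbouring window. Recall is
reported overall and restricted to windows with mappability ≥ 0.8; the
missed remainder is concentrated where junction flanks fall in duplicated
sequence, which is the mechanism the mappability track exists to expose.

## Numerical / design notes

* Coordinates are 0-based half-open throughout; GFF/GTF converted on
  ingest; `window_id` fixed as `chrom:start-end` for cross-run joins.
* The final short window of each chromosome is tiled as a short window,
  not discarded.
* Activity classes are an explicit heuristic (Recent: ≥ 80 % of events
  below frequency 0.05; Old: strictly more than 50 % above 0.5 — strict so
  a uniform spread reads Continuous): the class boundaries are labelled
  as configurable output, not inferred constants.
* Gene distances are window-to-gene at 10-kb resolution, never
  breakpoint-to-gene.
* Degenerate inputs: empty genomes, empty libraries, empty accession
  subsets, zero/negative clock rates and identities outside [0, 1] raise
  `ValueError`; orphan or failed accessions are dropped from the matrix
  with a logged warning.
* Problem sizes in the test suite (400-kb module fixtures, the 2-Mb
  acceptance study, a 1-Mb oracle genome, 200 dating replicates) were
  chosen as the smallest scales at which the statistical claims are
  meaningfully testable.
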