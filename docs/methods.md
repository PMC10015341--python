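# Methods

## Problem setting

Somatic mutations can create or destroy splice sites far from the essential
GT/AG intron ends. Sequence-based predictors score such variants (four
delta scores per variant: acceptor/donor × gain/loss, each with a base
offset locating the affected site), but a score is not evidence that the
tumor actually mis-splices. `runjkit` quantifies that evidence directly
from the tumor's RNA-seq alignment, normalized against control panels, and
propagates confirmed events into consequence reclassification and
mutational-signature attribution.

## Event model

Each variant×gene record carries delta scores (ds_ag, ds_al, ds_dg, ds_dl)
in [0,1] and signed offsets (dp_*). The strongest score defines the
variant's event; ties are broken by the fixed order AL > DL > AG > DG so
results never depend on iteration order. Events with ds ≥ 0.5 (the
predictor's recommended operating point, configurable) are considered
significant. Gains and losses are represented as (event_type, non-negative
ds); thresholds therefore apply to score magnitude.

The affected site is `site_pos = pos + dp`. For loss events the relevant
canonical boundary is the essential site closest to `site_pos` in the gene
model; for gains it is the nearest canonical site of the same kind (used
for position spectra and junction context). The gene model is read from
GTF via gffutils; when a gene has several transcripts the representative is
chosen by canonical tag, then longest CDS, then longest exonic span, with
transcript id as the final deterministic tie-break. Junction canonicality,
by contrast, is judged against the **union** of all annotated introns of
the gene, so ordinary alternative isoforms are not mistaken for abnormal
splicing.

### Position conventions

Mutated-base positions relative to the closest essential site are reported
transcript-oriented:

* donor-relative: 0 = last exonic base, +k = k-th intronic base, negative
  values exonic;
* acceptor-relative: −k = k-th intronic base upstream, +k = k-th exonic
  base, no 0.

These conventions reproduce the donor hotspot positions (0 and +5) and the
acceptor-gain window (−15 … +3) used in event-position spectra. Minus-strand
genes mirror genomic order; the simulator round-trips both strands.

### Gain-site coordinate convention

Predictor offsets do not themselves define which base a "novel site" names.
We fix: a novel donor's `site_pos` is the last exonic base of the
novel/truncated exon; a novel acceptor's `site_pos` is the first exonic
base after the novel junction (both transcript-oriented). The simulator and
the classifier share this convention, and the VCF emitter computes offsets
so a parsed record recovers the intended site exactly.

## Read classification

Evaluation position p: for losses, the first intronic base adjacent to the
lost site — every read crossing p is then naturally either retained or
spliced; for gains, the novel site itself. Reads crossing p are fetched
with MapQ ≥ 20 (default), excluding duplicates and secondary/supplementary
alignments; a read whose N-gap spans p crosses it by splicing and is
included.

Each read receives exactly one call:

* **abnormal_direct** — losses: aligned bases on both sides of the lost
  exon/intron boundary (retention); gains: a junction whose edge coincides
  exactly with the novel site.
* **abnormal_other** — any other non-canonical junction overlapping the
  decision point (±3 bp): cryptic-site junctions, exon skipping.
* **normal** — a canonical junction spanning p, or (for gains) contiguous
  alignment through the novel site.
* **uninformative** — soft-clipped within 3 bp of the decision point, or no
  usable signal. The original formulation partitions reads binarily; we add
  this explicit bucket because forcing clipped reads into either class
  injects noise. Uninformative reads never enter denominators.

Junction matching is exact-coordinate; the ±3 bp window applies only to
clip detection and junction-overlap screening. In `direct` counting mode,
abnormal_other reads are excluded from both tallies (they carry no evidence
for or against the direct consequence); in `all` mode they count as
abnormal. Mates sharing a query name are counted once per fragment; a
normal/abnormal conflict between mates resolves to abnormal. Duplicate and
mate policies are our choices — the original method does not specify them.

## RUNJ and validation

RUNJ = #Mₐ/(#Mₐ+#Mₙ) − #Cₐ/(#Cₐ+#Cₙ), with panel counts pooled by
summation across samples (matching the single C-pair in the formula). If
the tumor has no informative coverage the score is NA. If the panel has no
informative coverage the control fraction is defined as 0 and the locus is
flagged low-coverage rather than dropped, keeping sparsely covered loci
validatable but auditable.

Validation requires all of: (i) #Mₐ ≥ 2 — the `all`-mode abnormal count by
default (a superset of direct; configurable); (ii) either PON score
≥ 0.01; (iii) either POT score ≥ 0.01, or POT not applicable (no eligible
unmutated tumor, or zero POT coverage at p). Thresholds are applied to the
signed score as written, so a control excess (negative RUNJ) never
validates. The POT is drawn deterministically (seeded shuffle) from tumors
without a somatic mutation at the locus, up to 5 samples.

## Signature attribution

Single-base substitutions are classified into the 96 trinucleotide contexts
on the pyrimidine strand (purine references reverse-complemented with their
flanks). Given per-sample exposures e (normalized activities, taken as
input — extraction is out of scope) and a catalog f of per-signature
context probabilities, the per-mutation posterior is
P(s|m) = eₛ·fₛ(ctx)/Σₛ′eₛ′·fₛ′(ctx); rows sum to 1 and mutations with an
all-zero denominator are excluded with a count. The contribution of a
signature to a mutation set is Σ_{m∈S} P(s|m), which is conserved exactly
across any partition of the set. Splice mutations are essential-splice
annotations plus cryptic events with ds ≥ 0.5.

Enrichment per signature uses a two-sided Wilcoxon rank-sum test on the
pooled per-mutation P(s|m) values, splice vs other (scipy's Mann–Whitney U:
exact for small tie-free groups, tie-corrected normal approximation
otherwise, which is at least as exact as switching at n = 50). Raw
p-values are reported; a Benjamini–Hochberg column is emitted alongside for
convenience. Per-sample aggregate comparisons are a possible alternative to
the pooled comparison; we implement the pooled form as the literal reading
of "the distribution of probabilities P(m,s) between splice mutations and
others".

## Synthetic data

The simulator emits pre-aligned, coordinate-sorted, indexed BAMs with
analytically constructed CIGARs — no aligner is involved, so tests exercise
classification, not alignment, and every read carries an exact truth label.
Read classes: canonical junction, intron retention, novel-site junction
(gains), cryptic-site junction (site 10 bp into the exon for losses, ±5–6
bp from the novel site for gains), exon skipping, and boundary soft-clips.
The default gene model has 4 exons of 200 bp separated by 300 bp introns;
default reads are 100 bp single-end, MapQ 60, with ≥8 bp junction
overhangs. Each crossing read is abnormal-direct with probability f;
per-class exact counts can be requested instead. Default study conditions
mirror the validation setting: depth 200 crossing reads, panels of 5
samples with f = 0, abnormal fractions spanning 0.05–0.80 (the observed
range from a few percent of transcripts to near-complete switching, e.g.
the 12% novel-acceptor usage scenario). Mutation sets are drawn
signature-first (signature from exposures, context from its 96-vector,
strand orientation uniform) with flanks written into a matching miniature
FASTA.

What the simulator does **not** emulate: sequencing errors and base
qualities, alignment artifacts (misplaced multi-mappers, splice-junction
realignment slop beyond clean soft-clips), expression-level variation
across genes, paired-end fragment geometry, and real intron/exon length
distributions. Passing tests therefore demonstrate correctness of the
counting and decision machinery under idealized alignments, not robustness
to aligner noise.

## Numerical and design choices

* Coordinates: 1-based inclusive at all VCF/GTF-facing interfaces, 0-based
  half-open internally.
* All randomness (panel selection, simulation) flows from explicit integer
  seeds; repeated runs are byte-identical, and output provenance headers
  carry version, config hash and seed but no timestamps.
* Degenerate inputs: empty event lists, empty panels, genes absent from the
  model (positions flagged unresolvable and excluded from spectra),
  single-exon genes (no essential sites — an error for site lookups), and
  n = 1 enrichment groups (finite exact p) are all defined behaviors with
  tests.
* Problem sizes in the test-suite and acceptance script (depth 200, 10–20
  seeds per fraction, n = 2000 mutation sets, 200 null replicates) were
  chosen as the smallest sizes at which the binomial/rank-sum guarantees
  being checked are sharp.

## Known limitations

* Validation uses fixed thresholds, not per-event significance tests; very
  deep loci could validate on sub-percent effects (RUNJ ≥ 0.01 is absolute).
* The direct/all distinction relies on exact junction coordinates; aligners
  that shift junctions within repeats would require a matching tolerance.
* Exposure vectors are trusted as given; attribution quality degrades if
  they were estimated from few mutations.
* The CLI validates one tumor per invocation; cohort-scale runs are a loop
  over tumors by design.
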