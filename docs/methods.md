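# Methods

## Problem and model

Bulk RNA-seq fusion callers emit large raw candidate lists dominated by
artifacts. `conjoinscan` implements the downstream computation that turns such
a raw list into a curated set of candidate fusion transcripts and separates
two biologically distinct classes:

* **conjoined genes (CGs)** — read-through / cis-splicing chimeras of two
  *adjacent or overlapping* genes on the same chromosome, requiring no
  genomic rearrangement;
* **rearrangement fusions** — inter-chromosomal translocations and
  intra-chromosomal events between *distant* genes, compatible with
  deletions or inversions.

The pipeline has four stages: a six-rule filter cascade, a genomic
configuration classifier, a junction-spanning read screen across external
cohorts, and a specificity partition (normal-shared / cancer-shared /
leukemia-specific).

## Filter cascade

Rules are applied in a fixed order; each also gets evaluated independently on
the raw list so the report can show per-rule incidences that are
order-independent (those fractions may sum above 1 because one event can
violate several rules — only the sequential removals sum with the survivors
to the raw count).

1. **blacklist** — gene pairs / genomic regions curated by the upstream
   caller; matching is unordered on the gene pair, and either breakpoint
   falling inside a blacklist region also removes the event.
2. **shared_breakpoint** — an exact breakpoint coordinate recurring across
   ≥ 2 events with *distinct* gene pairs marks all sharers as promiscuous
   artifacts. Breakpoint variants of a single gene pair are retained: the
   same pair observed with two junction variants is two legitimate events.
3. **genomic_match** — the full junction sequence aligning contiguously
   (no gaps, either strand) to the reference within a mismatch budget
   (default 2 over the whole junction) indicates a junction collinear with
   the genome rather than a splice joint. Implemented with pigeonhole
   seeding: with ≤ m mismatches at least one of m+1 equal chunks matches
   exactly, so exact chunk hits anchor full-length Hamming verification.
4. **flank_coverage** — minimum pileup depth over four 50 bp windows
   (up/downstream of each breakpoint) below 10 removes the event.
5. **incidence** — junction-supporting reads as a fraction of all reads at
   the breakpoint below 5% removes the event. The numerator is the caller's
   seed-read count; the denominator adds the linear pileup depth at each
   breakpoint base; the two parent-locus fractions are averaged. Events
   with zero evidence at both loci are removed with reason "no evidence".
6. **junction_support** — the original reads are remapped onto the junction
   sequence; fewer than 1 read spanning the joint with ≥ 8 bases on *both*
   sides removes the event (one-sided matches never count).

Boundary semantics are strict-below throughout: depth exactly 10 and
incidence exactly 5% survive. The cascade is idempotent (removals only
shrink breakpoint-sharing sets), and every removed event carries an audit
trail of the rules it violates.

Thresholds (FilterConfig defaults): `min_flank_depth=10`, `min_incidence=0.05`
(the two domain-anchored values), `flank_window=50 bp`,
`max_junction_mismatches=2`, `min_overhang=8 bp`,
`min_spanning_reads_after_remap=1`, `shared_breakpoint_min_partners=2`. The
last five are gap-filling defaults chosen once: 50 bp ≈ two-thirds of a read
length so a window reflects local coverage rather than single-base noise;
2 mismatches tolerates sequencing error over a ~136 bp junction without
admitting diverged paralogs; 8 bp overhang makes a chance one-side extension
(4⁻⁸ per placement) negligible.

## Event classifier

Scope is breakpoint chromosome equality. Category:

* `inter_translocation` — different chromosomes;
* `conjoined_gene` — same chromosome and the partner gene intervals overlap,
  or the intervening annotated gene count ≤ `max_intervening_genes`
  (default 0) and the intergenic gap ≤ `max_distance` (default 2 Mb);
* `intra_distant` — everything else intra-chromosomal.

The 2 Mb / zero-intervening defaults were chosen so that every published CG
row (largest printed gap ≈ 1 Mb) qualifies while the printed distant intra
pairs do not; both are configurable because the field has no single numeric
definition of "contiguous". Orientation compares the partner genes' strands
(same / opposite / unknown), sourced from the gene model and falling back to
strands carried on the call. No transcription-direction constraint is
imposed on CGs: read-through products are observed from both +/+ pairs with
descending coordinates and opposite-strand neighbors, so adjacency — not
strand — is the criterion. "Intervening" counts genes overlapping the open
gap between the two partner intervals; a gene merely poking into the gap
counts, since it still interposes a gene boundary in the read-through path.

## Junction screen

For each candidate a junction mini-reference is built: a 5′ arm ending at
the 5′ breakpoint and a 3′ arm starting at the 3′ breakpoint, each cut
strand-aware from the genome (reverse-complemented for − strand genes),
default arm length = read_length − min_overhang = 68 bp, so any read placed
with the minimum overhang fits entirely on the junction. Reads are aligned
ungapped with ≤ 2 mismatches, seeded by exact 13-mers probed at fixed stride
along the read in both orientations. A read is *spanning* iff it covers
≥ 8 bp on each side of the joint; one-arm matches are excluded as false
positives. On an error-free 68/68 junction the number of distinct spanning
placements of a 76-mer is the closed form L − 2·O + 1 = 61, which the test
suite checks against brute-force enumeration.

Per-cohort screening yields a presence matrix of `positives/screened` cells;
a sample is positive when it has ≥ `presence_min_reads` (default 1) spanning
reads. Screening is junction-local: whether a read would map better
elsewhere in the genome is deliberately not adjudicated.

## Specificity partition

Cohorts carry a class (`normal`, `solid_tumor`, `leukemia`); each screened
event gets exactly one label:

* `normal_shared` — present in any normal-class cohort **or** annotated with
  a non-tumoral association in a database snapshot;
* `cancer_shared` — otherwise, present in ≥ 1 solid-tumor cohort;
* `leukemia_specific` — otherwise, present in ≥ 1 leukemia cohort (the own
  study cohort counts as leukemia);
* `unclassifiable` — absent everywhere (reported separately).

Database *membership* alone never disqualifies leukemia specificity — only an
explicit non-tumoral flag does, since curated CG databases mix tumoral and
non-tumoral provenance. Adding normal-cohort evidence can only move an event
toward `normal_shared` (monotone safety, property-tested).

`summarize_cohort` reports per-sample event burden (mean and range, overall
and per risk group), counting an event present in k samples as k incidences.

## Packaged fixtures

`conjoinscan.fixtures` ships three TSVs transcribed from the published
tables: the 25-row cancer-associated CG census (11 shared with solid tumors,
14 leukemia-restricted, including two breakpoint variants of one gene pair —
events are breakpoint-resolved throughout, which is what makes the
leukemia-restricted set total 14), the 16-row fusion list, and the 10-patient
cohort table (4 SR / 6 HR). The mini gene model accompanying them is
*synthetic*: each gene is a nominal ±1.5 kb window around its printed
breakpoint, with filler genes inserted between the distant intra-chromosomal
pairs whose printed gap is under 2 Mb, mirroring the fact that in the real
genome those pairs are separated by annotated genes. It supports the
classifier exactly as far as the printed columns constrain it and no further.

## Synthetic data generator

The generator emulates the evidence structure the cascade assumes, not a
full transcriptome experiment:

* genome: uniform-random A/C/G/T chromosomes (default 4 × 120 kb);
* gene model: 120 non-nested genes, lengths 1.5–3 kb, gaps 300–800 bp,
  random strands, 2–4 exons each, emitted as valid GTF;
* reads: 76 bp paired-end (fragment 200 ± 30 bp, base error rate 10⁻³),
  uniform over each gene span at mean depth 30× — one transcript per gene;
  splicing, library biases and quality-score realism are out of scope;
* true events (12 CG + 5 translocation + 5 distant-intra by default): CGs
  join a donor exon boundary of one gene to an acceptor boundary of its
  immediate neighbor; chimeric reads across each planted junction are drawn
  so the spanning fraction at the breakpoint matches the event's incidence
  (15–35%), binomially by default, by rounding in `exact_incidence` mode;
* artifacts, 5 per class, each violating exactly one rule: blacklisted
  pairs, one promiscuous breakpoint reused across ≥ 2 gene pairs, junctions
  copied contiguously from the genome, gene pairs covered at 4× (below the
  10× cutoff), events at ~3% incidence (simulated at 60× so one or two
  spanning reads sit safely below 5%), and events whose claimed seed reads
  have no spanning read support.

Two constructive guarantees keep the recovery property deterministic rather
than probabilistic: breakpoint flanks of retained events are topped up to
twice the depth cutoff where Poisson sampling left them short, and spanning
counts are clamped to the minimum giving twice the incidence cutoff
(low-incidence artifacts are conversely clamped below 0.9× the cutoff, with
a manifest warning if the margin cannot be met). Alignments are emitted
directly from simulation coordinates — no aligner — and chimeric pairs
appear in the FASTQ only, as an aligner against the linear genome would not
place them. Identical parameters (including seed) reproduce a byte-identical
bundle; each stage derives a child seed so stages can be run individually.

Passing tests on these bundles therefore demonstrate the cascade's rule
logic, not robustness to multi-mapping, splice isoforms, GC bias or
annotation errors in real data.

## Numerical choices and degenerate inputs

* Coordinates are 1-based inclusive at every interface (GTF, `chr:pos`
  breakpoints); half-open arithmetic is internal only.
* Ties/degenerate cases: identical breakpoints classify as intra; duplicate
  gene annotations merge to their union span; genes missing from the model
  classify as `intra_distant` with a logged warning and undefined distance;
  junction arms truncated by a contig end below the minimum overhang raise.
* Malformed fusion-table rows are collected with line numbers in a parse
  report, never silently dropped.
* The per-patient burden figure is reported but not asserted against any
  external value: the printed per-event sample lists do not reconstruct a
  unique per-patient counting rule.

## Problem sizes

Defaults are desk-scale by design: a full bundle is ~55k read pairs and
generates in ~2 s; the full cascade on its 52 raw calls runs in ~1.5 s; the
acceptance script completes in a few seconds.
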