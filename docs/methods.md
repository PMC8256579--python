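# Methods

## The assay and its data model

A transgenic rodent reporter assay measures in vivo mutagenesis by rescuing
a bacterial reporter gene (here the ~459-nt *E. coli gpt* coding sequence
carried on lambda EG10) from tissue DNA and selecting mutant colonies with
6-thioguanine. The observable unit is the animal: a titer *T* (rescued
phages assayed, order 10^5–10^6), a count *M* of confirmed resistant
colonies, and a sequence-derived mutation for each sequenced colony.
Mutant frequency is *M/T*. Because a single mutational event in the tissue
can expand clonally before rescue, colonies within one animal carrying the
identical mutation — same position, kind, reference and alternate alleles —
are collapsed to one *independent mutation*; the independent count over *T*
is the clonally corrected frequency. Identical mutations in different
animals never collapse: they are biologically independent.

## Coordinates and sequence context

All positions are 1-based on the coding strand, position 1 = first base of
the start codon. The packaged reference carries a calibration self-test:
positions 110 and 115 must be CpG sites and 92 and 113 must be the 3' G of
5'-GpG-3', the anchor sites of the assay literature; loading fails loudly
if the bundled sequence or its numbering offset is ever wrong.

CpG membership of a substitution means the mutated G:C pair participates
in a CG dinucleotide on either strand (CpG is its own reverse complement,
so this covers the G and the C of the pair). GpG context is coding-strand
specific: the substituted position is the 3' G of 5'-GpG-3'.

"A-runs" are maximal mononucleotide runs of the A:T base pair — runs of A
*or* T on the coding strand — of length ≥ 3 (configurable
`run_min_length`). The literature labels the first run of this gene
"7–12" in its run table while describing it as "nucleotides 8–12" in
text; the annotated maximal run is 8–12 (position 7 is a G), and this
package reports the maximal-run interval. A run substitution counts as
in-run when its position lies inside the interval (the 3'-terminal base of
a run, as in an AAAA→AAAC row, is in-run); counting the base one position
3' of a run is available behind `include_flank` (default off).

## Variant calling and indel normalization

Colony sequences (typically a PCR amplicon that contains the full gene)
are aligned with unit edit costs, the reference aligned end-to-end and
amplicon flanks free (edlib infix mode). Unit costs make a single-base
substitution strictly cheaper than an insertion+deletion pair, so that
tie-break is inherent. Gap columns become deletion/insertion events;
substitutions at adjacent positions stay separate events. Every indel is
left-aligned to its 5'-most equivalent placement (the placement set is
exactly those yielding the identical mutant sequence), deletions split by
the aligner across a repeat are re-fused, and insertions that normalize to
one anchor merge. Left alignment is the canonical choice because any
within-run placement is equivalent and run-level bookkeeping needs one
representative.

Alignment identity below a floor (default 90%) is rejected as not a
plausible mutant. Edits at the extreme gene boundary can admit several
equal-cost readings once flanks are unknown (e.g. a substitution of the
terminal base versus deleting it and reading the mutant base as flank);
the caller resolves these deterministically, preferring readings that
keep the reference fully covered, and the synthetic generator emits only
events whose called representation equals the generated event, so truth
tables and called tables agree exactly. The oracle-equivalence test
excludes the handful of boundary edits with alternative readings, which
it detects independently by brute-force window enumeration.

## Spectrum classification

Substitutions are classified at the base-pair level: the class of
(ref, alt) equals the class of their complements, giving six classes from
twelve ordered base pairs. Colonies map to one of ten spectrum rows; a
colony with two or more events (or a complex event) is "Other" — the
minimal rule that keeps one category per colony and column totals equal to
sequenced-mutant counts. Colonies with no detectable event (resistant but
sequence-identical over the window) count toward mutant frequency but are
excluded from spectrum denominators. Insertions are one row regardless of
size; the size stays on the event. Percentages are computed per group as
count/total rounded half-up to integers.

## Group summaries and statistics

Per-category group frequencies are computed per animal and averaged
(mean ± sample SD, n−1, across animals — the convention that matches
error bars over small animal groups); the pooled-count/pooled-titer
alternative is exposed as an option. Groups here are small (3–5 animals)
and unbalanced.

Fisher's exact test on 2×2 tables uses exact rational arithmetic
(`fractions.Fraction`) over the hypergeometric distribution: one-sided
p is the tail in the direction of the observed association; two-sided p is
the point-probability definition (sum of all margin-fixed tables whose
probability does not exceed the observed table's). Exact rational
comparison avoids floating-point tie tolerances entirely. Both sidedness
conventions are always reported: for borderline comparisons (e.g. A-run
mutant proportions 30/149 vs 12/107) the one-sided p can cross 0.05 while
the two-sided p does not, and a result should not silently depend on the
convention. Note the point-probability two-sided p is *not* bounded by
twice the one-sided p (the del+ins comparison 38/149 vs 2/28 exceeds that
bound slightly); that bound belongs to the doubling convention.

Tukey all-pairs comparisons use the classical one-way-ANOVA pooled
within-group variance and the studentized-range distribution with the
Tukey–Kramer standard error for unbalanced groups, on untransformed
per-animal frequencies; significance is flagged at 0.05 and 0.01.

## Hotspots and A-run enrichment

A hotspot is a (position, change-class) pair supported by independent
mutations in ≥ `min_animals` (default 3) distinct animals of one treatment
group. Support is computed after clonal correction, so duplicating any
colony within an animal can never change a call (tested as an invariant).
Identity is per change, not bare position, because tallies record specific
changes at each site; a position-level union is trivially derived from the
per-change calls. Events inside multi-event ("Other") colonies contribute
to position tallies.

The A-run table has one row per (run, mutated sequence) with per-group
mutant and independent counts; mutated sequences are rendered the way run
tables print them (deleted bases as `d`, insertions appended,
substitutions in place), so bundled fixtures reproduce published rows
exactly. Enrichment comparisons build 2×2 tables of in-run counts versus
totals and use the exact test above.

## Synthetic-assay generator

The generator's defaults are the study conditions it emulates: four groups
(two genotypes × two doses) of 4/5/3/4 animals; log-normal titers with
median 7×10^5 (σ_log = 0.3), matching titers that yield the published
per-animal colony counts; per-group total independent rates of 0.40, 0.64,
3.14 and 2.67 ×10^-5 per locus (the published group-level independent
frequencies) split across spectrum classes in the published per-group
proportions; geometric clonal copy number with mean 1/0.7 ≈ 1.43
(multiplicative crypt-lineage expansion; the resulting mutant/independent
frequency ratio ≈ 1.5 matches the published ratio); and a 5% fraction of
resistant colonies with no detectable event.

Within the G:C→A:T class, CpG sites carry weight 6 and the four anchor
sites carry preset hotspot weights; weights reshape the site distribution
while the class rate stays the class total. The preset weights were chosen
analytically so that per-animal expected independent hits at
92/110/113/115 sit near 1 in dosed knockout groups — the regime in which
those sites reach ≥3-animal support, as published — and lower in vehicle
groups. In knockout groups, 70% of the indel rate is routed through a
per-run A:T slippage channel (single-base deletion, +1/+2 insertions with
a 0.2 two-base fraction); the remainder is uniform over positions.

Mechanics per animal: independent mutation count ~ Poisson(T × total
rate); sites/alleles drawn from the per-identity rate map; each
independent mutation expands into Geometric(p) ≥ 1 colonies; no-event
colonies added at the configured fraction. The seed fixes everything;
identical seeds give byte-identical FASTA/TSV fixtures.

**Saturation and what recovery tests show.** Clonal correction cannot
distinguish two truly independent hits of the same (position, alleles)
within one animal — in the real assay or in the simulation. The distinct
count at a site of rate *r* has expectation 1 − exp(−*T r*), so under
hotspot concentration the clonally corrected count sits 15–20% below the
raw generating rate for the concentrated class. `expected_independent_counts`
computes this expectation exactly from the rate map, and the recovery
tests check the pipeline against it (3 SE over ≥100 seeds), plus against
the raw rate in a low-concentration configuration where the two targets
coincide. The truth table records every generated colony event, so both
views (pre- and post-collapse) are recoverable. Events at the extreme
gene boundary whose called representation would be ambiguous are excluded
from generation (a ~1% rate mass effect), mirroring the real assay's
inability to score such edits.

What the generator does **not** emulate: sequencing errors and mixed
peaks, mutation spectra outside the reporter window, plating/packaging
efficiency, per-copy (80 copies/haploid) normalization, sex effects, and
any mechanistic adduct chemistry. Passing recovery tests therefore shows
the pipeline is faithful to its own data model, not that real data are
this clean.

## Numerical and interface choices

- Rounding of table percentages is half-up (floor(x+0.5)) for
  determinism.
- Sample SD uses n−1; a single-animal group reports NaN SD.
- All-zero Fisher tables return p = 1.
- The mutation-table format is TSV with columns animal_id, colony_id,
  position, ref_allele, alt_allele, kind; kind `none` registers a colony
  with no event. Reference alleles are validated on ingestion and indels
  left-aligned.
- Colony FASTA record IDs are `animalID|colonyID` (delimiter
  configurable).
- Problem sizes in the test suite (single-edit enumeration on references
  ≤ 50 nt, Fisher enumeration for margins ≤ 30, 10^4 Tukey null
  datasets, 100-seed recovery runs) keep the full suite under half a
  minute on one core while leaving Monte-Carlo error well inside the
  tested tolerances.

## Known limitations

- Boundary-of-gene edits are canonicalized, not uniquely resolvable;
  counts at positions 1–3 and the last three positions are conventional.
- The "Other" category rule (≥2 events or complex) is the minimal
  consistent reading of published tables, which leave it undefined.
- Whether published per-type group frequencies used pooled or per-animal
  averaged titers is unstated; per-animal averaging is the default here,
  pooled is an option.
- The Tukey variant used by the original analyses (transformation, exact
  unbalanced handling) is unstated; Tukey–Kramer on raw frequencies is
  this package's choice, with a log-transform left to the caller.
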