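# gptspectrum

Mutation-spectrum analysis for transgenic rodent *gpt* delta reporter-gene
assays.

In the *gpt* delta assay, lambda EG10 phages carrying the *E. coli gpt*
(guanine phosphoribosyltransferase) gene are rescued from mouse genomic DNA
and plated in bacteria; 6-thioguanine kills cells expressing functional Gpt,
so resistant colonies carry a mutated reporter. Sequencing the resistant
colonies yields, per animal, a list of mutations in a ~459-nt gene. This
package covers the downstream analysis:

- **Mutant frequency** MF = mutant colonies / titer (the dilution-corrected
  colony count on non-selective plates), per animal.
- **Clonal correction**: colonies from one animal with the identical
  mutation (same position, kind and alleles) are presumed descendants of
  one mutational event; collapsing them gives the **independent mutation
  frequency** = independent mutations / titer.
- **Spectrum classification** into the ten standard categories: the six
  strand-normalized base-pair substitution classes (G:C→A:T, A:T→G:C,
  G:C→T:A, G:C→C:G, A:T→T:A, A:T→C:G), single-base deletion, deletion ≥ 2,
  insertion, and "other" (multi-event colonies), with CpG / 5'-GpG-3' /
  mononucleotide-run context flags.
- **Hotspot calling**: a nucleotide (with a specific change) mutated
  independently in ≥ 3 animals of a treatment group.
- **A-run analysis**: slippage-prone runs of 3–5 A:T base pairs, with
  per-run mutant and independent counts and Fisher's exact enrichment
  tests.
- **Group statistics**: exact-rational Fisher 2×2 tests and Tukey–Kramer
  studentized-range comparisons of per-animal frequencies.
- **Synthetic assays**: a generator emulating the full study design
  (groups × animals × titers × weighted spectra × clonal expansion) so the
  whole pipeline runs and is testable with no external data.

Variant calling from colony sequences uses unit-cost global alignment
(edlib) with the reference embedded in free amplicon flanks; indels are
left-aligned to their 5'-most placement so run-level bookkeeping is
canonical.

## Worked example

The package bundles the packaged *gpt* reference (numbering anchored so
that positions 110/115 are CpG sites and 92/113 are 3'-GpG sites) and
example datasets shaped like a four-group mismatch-repair-knockout /
potassium-bromate study. Building the spectrum table:

```python
from gptspectrum import datasets, load_gpt_reference, spectrum_table
from gptspectrum.hotspots import arun_table, arun_totals, proportion_test

ref = load_gpt_reference()
table = spectrum_table(datasets.spectrum_fixture(ref), ref)
print(table.to_frame().to_string())
```

```
             bearing_vehicle        bearing_kbro3        ko_vehicle        ko_kbro3
                           n      %             n      %          n      %        n      %
G:C->A:T                   3   30.0            10   36.0         51   48.0       60   40.0
  (CpG site)               1    NaN             8    NaN         20    NaN       35    NaN
A:T->G:C                   0    0.0             2    7.0         13   12.0       25   17.0
G:C->T:A                   2   20.0             8   29.0         10    9.0       19   13.0
G:C->C:G                   0    0.0             1    4.0          0    0.0        1    1.0
A:T->T:A                   0    0.0             2    7.0          4    4.0        2    1.0
A:T->C:G                   1   10.0             0    0.0          6    6.0        2    1.0
Deletion 1                 2   20.0             2    7.0         17   16.0       26   17.0
Deletion >=2               1   10.0             3   11.0          0    0.0        0    0.0
Insertion                  1   10.0             0    0.0          6    6.0       12    8.0
Other                      0    0.0             0    0.0          0    0.0        2    1.0
Total                     10  100.0            28  100.0        107  100.0      149  100.0
```

Each column pair is one treatment group (genotype × dose): colony counts
per category and their integer percentages of sequenced mutants; the CpG
sub-row counts the G:C→A:T colonies at CpG dinucleotides. Clonal
correction and the A-run summary:

```python
totals = arun_totals(arun_table(datasets.arun_fixture(ref), ref))
print(totals)
res = proportion_test(38, 149, 2, 28)   # del+ins colonies vs totals
print(res.odds_ratio, res.p_two_sided, res.p_one_sided)
```

```
{'ko_vehicle': (12, 6), 'ko_kbro3': (30, 21)}
4.45 0.0461 0.0225
```

So of 30 mutant colonies in A-runs in the dosed knockout group, clonal
correction leaves 21 independent mutations (12 → 6 in the vehicle group),
and the combined single-base deletion+insertion proportion (38/149 vs
2/28) is significantly enriched (two-sided exact p = 0.046). Both
sidedness conventions are always reported because borderline comparisons
can differ between them.

## Command line

```sh
gptspectrum simulate --seed 11 --out sim/        # synthetic study (FASTA + TSVs)
gptspectrum analyze --fasta sim/colonies.fasta \
    --metadata sim/metadata.tsv --out reports/   # full report tables
```

`analyze` writes per-colony classifications, per-animal frequencies, the
spectrum table, hotspot and A-run reports, Tukey comparisons and Fisher
enrichment tests as TSV files.

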