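"""Mutation-spectrum classification.

Substitutions are classified at the base-pair level into the six
strand-normalized classes used in reporter-gene spectrum tables
(G:C->A:T, A:T->G:C, G:C->T:A, G:C->C:G, A:T->T:A, A:T->C:G), so a G>A
change and its complement C>T fall in the same class. Colonies map to the
ten spectrum rows: the six substitution classes, single-base deletion,
deletion of two or more bases, insertion (any size), and "other" for
colonies with multiple or complex events.

Context flags record whether a G:C substitution falls in a CpG
dinucleotide (on either strand) or at the 3' G of 5'-GpG-3' on the coding
strand, and whether an event lies in an annotated A:T mononucleotide run.
"""

from __future__ import annotations

import pandas as pd

from .events import (
    COMPLEX,
    DELETION,
    INSERTION,
    SUBSTITUTION,
    ContextFlags,
    MutantColony,
    MutationEvent,
)
from .reference import COMPLEMENT, ReferenceGene, is_gpg_context

GC_TO_AT = "GC_to_AT"
AT_TO_GC = "AT_to_GC"
GC_TO_TA = "GC_to_TA"
GC_TO_CG = "GC_to_CG"
AT_TO_TA = "AT_to_TA"
AT_TO_CG = "AT_to_CG"
DELETION_1 = "deletion_1"
DELETION_GE2 = "deletion_ge2"
INSERTION_CAT = "insertion"
OTHER = "other"
NO_MUTATION = "no_mutation"

#: The ten spectrum-table categories, in display order.
TABLE_CATEGORIES = (
    GC_TO_AT,
    AT_TO_GC,
    GC_TO_TA,
    GC_TO_CG,
    AT_TO_TA,
    AT_TO_CG,
    DELETION_1,
    DELETION_GE2,
    INSERTION_CAT,
    OTHER,
)

SUBSTITUTION_CLASSES = (GC_TO_AT, AT_TO_GC, GC_TO_TA, GC_TO_CG, AT_TO_TA, AT_TO_CG)

DISPLAY_LABELS = {
    GC_TO_AT: "G:C->A:T",
    AT_TO_GC: "A:T->G:C",
    GC_TO_TA: "G:C->T:A",
    GC_TO_CG: "G:C->C:G",
    AT_TO_TA: "A:T->T:A",
    AT_TO_CG: "A:T->C:G",
    DELETION_1: "Deletion 1",
    DELETION_GE2: "Deletion >=2",
    INSERTION_CAT: "Insertion",
    OTHER: "Other",
}

# pair-level classes keyed by the purine representative of the reference pair
_CLASS_BY_PAIR = {
    ("G", "A"): GC_TO_AT,
    ("G", "T"): GC_TO_TA,
    ("G", "C"): GC_TO_CG,
    ("A", "G"): AT_TO_GC,
    ("A", "T"): AT_TO_TA,
    ("A", "C"): AT_TO_CG,
}


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """Strand-normalized base-pair class of a single-base substitution.

    Complementary changes classify identically: (G,A) and (C,T) are both
    G:C->A:T.
    """
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base not in COMPLEMENT or alt_base not in COMPLEMENT:
        raise ValueError(f"bases must be A/C/G/T, got {ref_base!r}>{alt_base!r}")
    if ref_base == alt_base:
        raise ValueError(f"ref and alt base are both {ref_base!r}")
    if ref_base in ("C", "T"):  # normalize to the purine on the other strand
        ref_base, alt_base = COMPLEMENT[ref_base], COMPLEMENT[alt_base]
    return _CLASS_BY_PAIR[(ref_base, alt_base)]


def classify_event(event: MutationEvent) -> str:
    """Spectrum category of one event taken in isolation."""
    if event.kind == SUBSTITUTION:
        return classify_substitution(event.ref_allele, event.alt_allele)
    if event.kind == DELETION:
        return DELETION_1 if event.size == 1 else DELETION_GE2
    if event.kind == INSERTION:
        return INSERTION_CAT
    return OTHER


def assign_context(
    event: MutationEvent, ref: ReferenceGene, include_flank: bool = False
) -> MutationEvent:
    """Attach CpG/GpG/run context flags (and the event category) to an event.

    CpG membership means the mutated G:C pair participates in a CG
    dinucleotide on either strand; GpG means the substituted position is
    the 3' G of 5'-GpG-3' on the coding strand. The run flag is set when a
    substitution lies inside an A:T run of at least the annotated minimum
    length (optionally also one base 3' of it, ``include_flank``), or when
    an indel's bases match the run base and its left-aligned placement
    touches the run interval.
    """
    is_cpg = False
    is_gpg = False
    run = None
    if event.kind == SUBSTITUTION:
        if event.ref_allele in ("G", "C"):
            is_cpg = ref.is_cpg_site(event.position)
            is_gpg = is_gpg_context(ref, event.position)
        else:
            run = ref.run_at(event.position)
            if run is not None and not run.is_at_run:
                run = None
            if run is None and include_flank and event.position > 1:
                left = ref.run_at(event.position - 1)
                if left is not None and left.is_at_run and left.end == event.position - 1:
                    run = left
    elif event.kind in (DELETION, INSERTION):
        bases = event.ref_allele or event.alt_allele
        if len(set(bases)) == 1 and bases[0] in ("A", "T"):
            # left-aligned placement: a deletion starts at the run start, an
            # insertion is anchored at the base 5' of the run
            touch = event.position if event.kind == DELETION else event.position + 1
            for r in ref.a_runs:
                if r.base == bases[0] and r.start <= touch <= r.end:
                    run = r
                    break
    return event.with_category(classify_event(event)).with_context(
        ContextFlags(is_cpg=is_cpg, is_gpg=is_gpg, run=run)
    )


def categorize_colony(colony: MutantColony, ref: ReferenceGene) -> str:
    """Single spectrum category of a colony.

    One event maps to its own class; two or more events, or any complex
    event, map to "other"; no event maps to the ``no_mutation`` sentinel,
    which is excluded from spectrum denominators.
    """
    if len(colony.events) == 0:
        return NO_MUTATION
    if len(colony.events) >= 2 or any(e.kind == COMPLEX for e in colony.events):
        return OTHER
    return classify_event(colony.events[0])


def annotate_colony(
    colony: MutantColony, ref: ReferenceGene, include_flank: bool = False
) -> MutantColony:
    """Colony with every event context-annotated and classified."""
    return MutantColony(
        animal_id=colony.animal_id,
        colony_id=colony.colony_id,
        events=tuple(assign_context(e, ref, include_flank=include_flank) for e in colony.events),
    )


def colony_table(
    colonies: list[MutantColony], ref: ReferenceGene, include_flank: bool = False
) -> pd.DataFrame:
    """Per-colony classified table (one row per event, plus empty colonies)."""
    rows = []
    for colony in colonies:
        category = categorize_colony(colony, ref)
        if not colony.events:
            rows.append(
                dict(
                    animal_id=colony.animal_id,
                    colony_id=colony.colony_id,
                    position=pd.NA,
                    kind="none",
                    ref_allele="",
                    alt_allele="",
                    category=category,
                    is_cpg=False,
                    is_gpg=False,
                    run_start=pd.NA,
                    run_end=pd.NA,
                    run_base="",
                )
            )
            continue
        for ev in colony.events:
            ev = assign_context(ev, ref, include_flank=include_flank)
            ctx = ev.context
            rows.append(
                dict(
                    animal_id=colony.animal_id,
                    colony_id=colony.colony_id,
                    position=ev.position,
                    kind=ev.kind,
                    ref_allele=ev.ref_allele,
                    alt_allele=ev.alt_allele,
                    category=category,
                    is_cpg=ctx.is_cpg,
                    is_gpg=ctx.is_gpg,
                    run_start=ctx.run.start if ctx.run else pd.NA,
                    run_end=ctx.run.end if ctx.run else pd.NA,
                    run_base=ctx.run.base if ctx.run else "",
                )
            )
    return pd.DataFrame(rows)
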