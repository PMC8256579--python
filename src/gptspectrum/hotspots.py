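"""Hotspot calling and A-run enrichment.

A mutation hotspot is a nucleotide (with a specific change class) at which
an independent mutation occurred in at least ``min_animals`` animals of one
treatment group — counting animals, not colonies, so clonal expansion
within an animal can never create a hotspot.

The A-run table summarizes mutations in mononucleotide A:T runs (slippage
deletions/insertions and run substitutions) per treatment group, with both
raw mutant counts and clonally corrected independent counts, and the
enrichment tests compare A-run or indel proportions between groups with
Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .classify import assign_context, classify_event
from .events import DELETION, INSERTION, SUBSTITUTION, ContextFlags, MutationEvent
from .metrics import AnimalAssay, group_assays, independent_events
from .reference import ReferenceGene, Run
from .stats import Fisher2x2Result, fisher_exact_2x2


@dataclass(frozen=True)
class HotspotCall:
    group_id: str
    position: int
    category: str
    supporting_animals: frozenset[str]
    is_hotspot: bool
    context: Optional[ContextFlags] = None

    @property
    def n_animals(self) -> int:
        return len(self.supporting_animals)


def call_hotspots(
    assays: Sequence[AnimalAssay],
    ref: ReferenceGene,
    min_animals: int = 3,
) -> list[HotspotCall]:
    """Tally per-(position, change-class) animal support within one group.

    Every (position, category) seen as an independent mutation in at least
    one animal yields a call; ``is_hotspot`` flags support by
    ``min_animals`` or more distinct animals. Clonal copies within an
    animal count once by construction (support is computed on clonally
    corrected events).
    """
    groups = {a.group_id for a in assays}
    if len(groups) > 1:
        raise ValueError(f"assays span multiple groups: {sorted(groups)}")
    group_id = next(iter(groups)) if groups else ""
    support: dict[tuple[int, str], set[str]] = {}
    representative: dict[tuple[int, str], MutationEvent] = {}
    for assay in assays:
        for mut in independent_events(assay.colonies):
            key = (mut.event.position, classify_event(mut.event))
            support.setdefault(key, set()).add(assay.animal_id)
            representative.setdefault(key, mut.event)
    calls = []
    for (position, category), animals in sorted(support.items()):
        ev = assign_context(representative[(position, category)], ref)
        calls.append(
            HotspotCall(
                group_id=group_id,
                position=position,
                category=category,
                supporting_animals=frozenset(animals),
                is_hotspot=len(animals) >= min_animals,
                context=ev.context,
            )
        )
    return calls


def hotspot_table(calls: Sequence[HotspotCall]) -> pd.DataFrame:
    rows = [
        dict(
            group_id=c.group_id,
            position=c.position,
            category=c.category,
            n_animals=c.n_animals,
            animals=",".join(sorted(c.supporting_animals)),
            is_hotspot=c.is_hotspot,
            is_cpg=c.context.is_cpg if c.context else False,
            is_gpg=c.context.is_gpg if c.context else False,
        )
        for c in calls
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ARunRecord:
    """One (A-run, mutated-sequence) row with per-group counts.

    ``mutated_description`` renders the run after the mutation the way
    run-summary tables print it: deleted bases as ``d`` (e.g. ``AAAd``),
    insertions appended (``AAAAA`` for +A in a 4-A run), substitutions in
    place (``TTC``, ``AAAC``).
    """

    run: Run
    original_sequence: str
    mutated_description: str
    per_group: Mapping[str, tuple[int, int]]  # group -> (mutant, independent)


def _describe_run_mutation(run: Run, original: str, ev: MutationEvent) -> str:
    if ev.kind == DELETION:
        k = ev.size
        return original[: run.length - k] + "d" * k
    if ev.kind == INSERTION:
        return original + ev.alt_allele
    if ev.kind == SUBSTITUTION:
        offset = ev.position - run.start
        return original[:offset] + ev.alt_allele + original[offset + 1 :]
    return original + "?"


def arun_table(
    assays: Sequence[AnimalAssay],
    ref: ReferenceGene,
    include_flank: bool = False,
) -> list[ARunRecord]:
    """Per-(run, mutation) mutant and independent counts by group.

    Mutant counts tally every colony event whose context lies in an A:T
    run; independent counts tally the clonally corrected events per animal.
    """
    grouped = group_assays(assays)
    row_keys: list[tuple[Run, str]] = []
    mutant_counts: dict[tuple[Run, str], dict[str, int]] = {}
    independent_counts: dict[tuple[Run, str], dict[str, int]] = {}

    def row_for(ev: MutationEvent) -> Optional[tuple[Run, str]]:
        ev = assign_context(ev, ref, include_flank=include_flank)
        run = ev.context.run
        if run is None:
            return None
        original = ref.slice(run.start, run.end)
        return (run, _describe_run_mutation(run, original, ev))

    for gid, group in grouped.items():
        for assay in group:
            for colony in assay.colonies:
                for ev in colony.events:
                    key = row_for(ev)
                    if key is None:
                        continue
                    if key not in mutant_counts:
                        row_keys.append(key)
                        mutant_counts[key] = {}
                        independent_counts[key] = {}
                    mutant_counts[key][gid] = mutant_counts[key].get(gid, 0) + 1
            for mut in independent_events(assay.colonies):
                key = row_for(mut.event)
                if key is None:
                    continue
                if key not in mutant_counts:
                    row_keys.append(key)
                    mutant_counts[key] = {}
                    independent_counts[key] = {}
                independent_counts[key][gid] = independent_counts[key].get(gid, 0) + 1
    row_keys.sort(key=lambda k: (k[0].start, k[1]))
    records = []
    for run, desc in row_keys:
        per_group = {
            gid: (
                mutant_counts[(run, desc)].get(gid, 0),
                independent_counts[(run, desc)].get(gid, 0),
            )
            for gid in grouped
        }
        records.append(
            ARunRecord(
                run=run,
                original_sequence=ref.slice(run.start, run.end),
                mutated_description=desc,
                per_group=per_group,
            )
        )
    return records


def arun_totals(records: Sequence[ARunRecord]) -> dict[str, tuple[int, int]]:
    """Per-group (mutant, independent) totals over all A-run rows."""
    totals: dict[str, list[int]] = {}
    for rec in records:
        for gid, (m, i) in rec.per_group.items():
            totals.setdefault(gid, [0, 0])
            totals[gid][0] += m
            totals[gid][1] += i
    return {gid: (m, i) for gid, (m, i) in totals.items()}


def arun_frame(records: Sequence[ARunRecord]) -> pd.DataFrame:
    """A-run table as a DataFrame, one row per (run, mutated sequence)."""
    groups: list[str] = []
    for rec in records:
        for gid in rec.per_group:
            if gid not in groups:
                groups.append(gid)
    rows = []
    for rec in records:
        row = dict(
            run_start=rec.run.start,
            run_end=rec.run.end,
            original=rec.original_sequence,
            mutated=rec.mutated_description,
        )
        for gid in groups:
            m, i = rec.per_group.get(gid, (0, 0))
            row[f"{gid}_mutants"] = m
            row[f"{gid}_independent"] = i
        rows.append(row)
    return pd.DataFrame(rows)


def proportion_test(
    count_a: int, total_a: int, count_b: int, total_b: int
) -> Fisher2x2Result:
    """Fisher's exact test comparing two proportions count/total."""
    for count, total in ((count_a, total_a), (count_b, total_b)):
        if count < 0 or total < 0 or count > total:
            raise ValueError(f"inconsistent counts {count}/{total}")
    return fisher_exact_2x2(
        [[count_a, total_a - count_a], [count_b, total_b - count_b]]
    )
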