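"""Per-animal assay metrics and group summaries.

Mutant frequency is the number of confirmed 6-TG-resistant colonies
divided by the titer (dilution-corrected colony count on non-selective
plates). Clonal correction collapses identical mutations within one animal
to a single independent mutation — multiple colonies carrying the same
change are presumed descendants of one mutational event in the tissue —
and the independent mutation frequency divides the independent count by
the titer. Group summaries are means with sample SD across animals, the
convention for small treatment groups; a pooled-count alternative is
provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .classify import (
    GC_TO_AT,
    NO_MUTATION,
    TABLE_CATEGORIES,
    categorize_colony,
    classify_event,
    assign_context,
)
from .events import MutantColony, MutationEvent
from .reference import ReferenceGene


@dataclass(frozen=True)
class AnimalAssay:
    """One animal's reporter-gene assay."""

    animal_id: str
    group_id: str
    genotype: str = "unknown"  # e.g. Msh2_bearing / Msh2_KO
    dose_g_per_l: float = 0.0
    sex: str = "unknown"
    titer: int = 0
    mutant_count: int = 0
    colonies: tuple[MutantColony, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.titer <= 0:
            raise ValueError(f"animal {self.animal_id}: titer must be positive")
        if self.mutant_count < 0:
            raise ValueError(f"animal {self.animal_id}: negative mutant_count")
        if len(self.colonies) > self.mutant_count:
            raise ValueError(
                f"animal {self.animal_id}: {len(self.colonies)} sequenced colonies "
                f"exceed mutant_count {self.mutant_count}"
            )
        for colony in self.colonies:
            if colony.animal_id != self.animal_id:
                raise ValueError(
                    f"colony {colony.colony_id} belongs to animal "
                    f"{colony.animal_id}, not {self.animal_id}"
                )


@dataclass(frozen=True)
class IndependentMutation:
    """A clonally corrected mutation within one animal."""

    animal_id: str
    event: MutationEvent
    clonal_count: int


def mutant_frequency(assay: AnimalAssay) -> float:
    """Mutant colonies per rescued phage: mutant_count / titer."""
    return assay.mutant_count / assay.titer


def independent_events(colonies: Sequence[MutantColony]) -> list[IndependentMutation]:
    """Clonal correction: collapse identical mutations within one animal.

    Events identical in (position, kind, ref allele, alt allele) collapse
    to one representative carrying the clonal count. All colonies must come
    from a single animal; identical changes in different animals are
    biologically independent and never collapse.
    """
    animals = {c.animal_id for c in colonies}
    if len(animals) > 1:
        raise ValueError(f"colonies span multiple animals: {sorted(animals)}")
    counts: dict[tuple, MutationEvent] = {}
    tally: dict[tuple, int] = {}
    for colony in colonies:
        for ev in colony.events:
            key = ev.identity
            if key not in counts:
                counts[key] = ev
                tally[key] = 0
            tally[key] += 1
    animal_id = next(iter(animals)) if animals else ""
    out = [
        IndependentMutation(animal_id=animal_id, event=counts[k], clonal_count=tally[k])
        for k in counts
    ]
    out.sort(key=lambda m: (m.event.position, m.event.kind))
    return out


def independent_mutation_frequency(assay: AnimalAssay) -> float:
    """Independent (clonally corrected) mutations per rescued phage."""
    return len(independent_events(assay.colonies)) / assay.titer


def _animal_count(
    assay: AnimalAssay,
    ref: ReferenceGene,
    category: Optional[str],
    independent: bool,
) -> int:
    if independent:
        muts = independent_events(assay.colonies)
        if category is None:
            return len(muts)
        return sum(1 for m in muts if classify_event(m.event) == category)
    if category is None:
        return assay.mutant_count
    return sum(1 for c in assay.colonies if categorize_colony(c, ref) == category)


@dataclass(frozen=True)
class FrequencySummary:
    """Per-animal frequencies with their group mean and sample SD."""

    per_animal: dict[str, float]
    group_mean: float
    group_sd: float
    pooled_frequency: Optional[float] = None


def group_summary(
    assays: Sequence[AnimalAssay],
    ref: ReferenceGene,
    category: Optional[str] = None,
    independent: bool = False,
    pooled: bool = False,
) -> FrequencySummary:
    """Group mean +/- SD of per-animal frequencies.

    ``category`` filters to one spectrum category (colony category, or the
    event's own class when ``independent``); ``category=None`` gives the
    total mutant (or independent mutation) frequency. The default averages
    per-animal frequencies; ``pooled`` additionally reports the
    pooled-count / pooled-titer alternative.
    """
    if not assays:
        raise ValueError("empty group")
    per_animal: dict[str, float] = {}
    total_count = 0
    total_titer = 0
    for assay in assays:
        n = _animal_count(assay, ref, category, independent)
        per_animal[assay.animal_id] = n / assay.titer
        total_count += n
        total_titer += assay.titer
    values = list(per_animal.values())
    mean = sum(values) / len(values)
    if len(values) >= 2:
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - 1))
    else:
        sd = float("nan")
    return FrequencySummary(
        per_animal=per_animal,
        group_mean=mean,
        group_sd=sd,
        pooled_frequency=(total_count / total_titer) if pooled else None,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def group_assays(assays: Sequence[AnimalAssay]) -> dict[str, list[AnimalAssay]]:
    """Assays grouped by group_id, preserving first-appearance order."""
    grouped: dict[str, list[AnimalAssay]] = {}
    for a in assays:
        grouped.setdefault(a.group_id, []).append(a)
    return grouped


@dataclass(frozen=True)
class SpectrumTable:
    """Per-group mutation-category counts and integer percentages.

    ``counts`` maps group -> category -> colony count; ``cpg_subcounts``
    holds, per group, how many G:C->A:T colonies fall at CpG sites (a
    subset, displayed as a parenthetical sub-row); ``totals`` count
    categorized colonies (those with at least one event).
    """

    counts: dict[str, dict[str, int]]
    cpg_subcounts: dict[str, int]
    totals: dict[str, int]

    @property
    def groups(self) -> list[str]:
        return list(self.counts)

    def percentages(self, group: str) -> dict[str, int]:
        total = self.totals[group]
        if total == 0:
            return {c: 0 for c in TABLE_CATEGORIES}
        return {
            c: _round_half_up(100.0 * self.counts[group][c] / total)
            for c in TABLE_CATEGORIES
        }

    def to_frame(self) -> pd.DataFrame:
        """Spectrum table as a DataFrame (rows: categories, CpG sub-row, total)."""
        from .classify import DISPLAY_LABELS

        data = {}
        for g in self.groups:
            pct = self.percentages(g)
            col_n, col_p = [], []
            for c in TABLE_CATEGORIES:
                col_n.append(self.counts[g][c])
                col_p.append(pct[c])
                if c == GC_TO_AT:
                    col_n.append(self.cpg_subcounts[g])
                    col_p.append(None)
            col_n.append(self.totals[g])
            col_p.append(100 if self.totals[g] else 0)
            data[(g, "n")] = col_n
            data[(g, "%")] = col_p
        index = []
        for c in TABLE_CATEGORIES:
            index.append(DISPLAY_LABELS[c])
            if c == GC_TO_AT:
                index.append("  (CpG site)")
        index.append("Total")
        return pd.DataFrame(data, index=index)


def spectrum_table(assays: Sequence[AnimalAssay], ref: ReferenceGene) -> SpectrumTable:
    """Spectrum-table counts per treatment group.

    Colonies without a detectable event are excluded from both counts and
    totals (they still contribute to mutant frequency).
    """
    grouped = group_assays(assays)
    counts: dict[str, dict[str, int]] = {}
    cpg: dict[str, int] = {}
    totals: dict[str, int] = {}
    for gid, group in grouped.items():
        counts[gid] = {c: 0 for c in TABLE_CATEGORIES}
        cpg[gid] = 0
        totals[gid] = 0
        for assay in group:
            for colony in assay.colonies:
                cat = categorize_colony(colony, ref)
                if cat == NO_MUTATION:
                    continue
                counts[gid][cat] += 1
                totals[gid] += 1
                if cat == GC_TO_AT:
                    ev = assign_context(colony.events[0], ref)
                    if ev.context.is_cpg:
                        cpg[gid] += 1
    return SpectrumTable(counts=counts, cpg_subcounts=cpg, totals=totals)


def frequency_table(assays: Sequence[AnimalAssay], ref: ReferenceGene) -> pd.DataFrame:
    """Per-animal frequency report (one row per animal)."""
    rows = []
    for a in assays:
        ind = independent_events(a.colonies)
        rows.append(
            dict(
                animal_id=a.animal_id,
                group_id=a.group_id,
                genotype=a.genotype,
                dose_g_per_l=a.dose_g_per_l,
                sex=a.sex,
                titer=a.titer,
                mutant_count=a.mutant_count,
                mutant_frequency=mutant_frequency(a),
                independent_count=len(ind),
                independent_frequency=len(ind) / a.titer,
            )
        )
    return pd.DataFrame(rows)
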