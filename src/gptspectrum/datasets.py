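"""Bundled example datasets shaped like a published four-group study.

These encode the observed result tables of a mismatch-repair-knockout
(Msh2-KO) / potassium-bromate study on gpt delta mice as concrete colony
fixtures: per-group spectrum-table category counts, and the per-A-run
mutant and independent-mutation counts, realized as animals, colonies and
events on the packaged gpt reference. They let every pipeline stage run —
and be checked against the published aggregate numbers — without any
external data.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .classify import (
    AT_TO_CG,
    AT_TO_GC,
    AT_TO_TA,
    DELETION_1,
    DELETION_GE2,
    GC_TO_AT,
    GC_TO_CG,
    GC_TO_TA,
    INSERTION_CAT,
    OTHER,
)
from .events import DELETION, INSERTION, SUBSTITUTION, MutantColony, MutationEvent
from .metrics import AnimalAssay
from .reference import ReferenceGene

GROUPS = ("bearing_vehicle", "bearing_kbro3", "ko_vehicle", "ko_kbro3")

_GROUP_DESIGN = {
    "bearing_vehicle": ("Msh2_bearing", 0.0, 4),
    "bearing_kbro3": ("Msh2_bearing", 1.5, 5),
    "ko_vehicle": ("Msh2_KO", 0.0, 3),
    "ko_kbro3": ("Msh2_KO", 1.5, 4),
}

#: Spectrum-table category counts per group (columns of the published
#: spectrum table), with the CpG sub-count of the G:C->A:T row.
TABLE1_COUNTS: dict[str, dict[str, int]] = {
    "bearing_vehicle": {
        GC_TO_AT: 3, AT_TO_GC: 0, GC_TO_TA: 2, GC_TO_CG: 0, AT_TO_TA: 0,
        AT_TO_CG: 1, DELETION_1: 2, DELETION_GE2: 1, INSERTION_CAT: 1, OTHER: 0,
    },
    "bearing_kbro3": {
        GC_TO_AT: 10, AT_TO_GC: 2, GC_TO_TA: 8, GC_TO_CG: 1, AT_TO_TA: 2,
        AT_TO_CG: 0, DELETION_1: 2, DELETION_GE2: 3, INSERTION_CAT: 0, OTHER: 0,
    },
    "ko_vehicle": {
        GC_TO_AT: 51, AT_TO_GC: 13, GC_TO_TA: 10, GC_TO_CG: 0, AT_TO_TA: 4,
        AT_TO_CG: 6, DELETION_1: 17, DELETION_GE2: 0, INSERTION_CAT: 6, OTHER: 0,
    },
    "ko_kbro3": {
        GC_TO_AT: 60, AT_TO_GC: 25, GC_TO_TA: 19, GC_TO_CG: 1, AT_TO_TA: 2,
        AT_TO_CG: 2, DELETION_1: 26, DELETION_GE2: 0, INSERTION_CAT: 12, OTHER: 2,
    },
}

TABLE1_CPG_SUBCOUNTS = {
    "bearing_vehicle": 1,
    "bearing_kbro3": 8,
    "ko_vehicle": 20,
    "ko_kbro3": 35,
}

_FIXTURE_TITER = 700_000


def _spectrum_events(ref: ReferenceGene) -> dict[str, list]:
    """Concrete event builders per category on the gpt reference."""

    def sub(p: int, alt: str) -> MutationEvent:
        return MutationEvent(
            position=p, kind=SUBSTITUTION, ref_allele=ref.base(p), alt_allele=alt
        )

    return {
        # CpG-site and non-CpG G:C->A:T variants (positions 110 and 92)
        "GC_to_AT_cpg": lambda: (sub(110, "A"),),
        "GC_to_AT_noncpg": lambda: (sub(92, "A"),),
        AT_TO_GC: lambda: (sub(8, "G"),),
        GC_TO_TA: lambda: (sub(3, "T"),),
        GC_TO_CG: lambda: (sub(3, "C"),),
        AT_TO_TA: lambda: (sub(4, "T"),),
        AT_TO_CG: lambda: (sub(4, "C"),),
        DELETION_1: lambda: (
            MutationEvent(position=2, kind=DELETION, ref_allele=ref.base(2)),
        ),
        DELETION_GE2: lambda: (
            MutationEvent(position=2, kind=DELETION, ref_allele=ref.slice(2, 3)),
        ),
        INSERTION_CAT: lambda: (
            MutationEvent(position=2, kind=INSERTION, alt_allele="C"),
        ),
        OTHER: lambda: (sub(3, "T"), sub(4, "T")),
    }


def spectrum_fixture(ref: ReferenceGene) -> list[AnimalAssay]:
    """Assays whose colony categories realize ``TABLE1_COUNTS`` exactly.

    Colonies are distributed round-robin over the animals of each group;
    G:C->A:T colonies are split between a CpG site and a non-CpG site to
    realize the CpG sub-counts.
    """
    builders = _spectrum_events(ref)
    assays = []
    for gid in GROUPS:
        genotype, dose, n_animals = _GROUP_DESIGN[gid]
        per_animal_colonies: list[list[MutantColony]] = [[] for _ in range(n_animals)]
        counter = 0

        def place(events: tuple[MutationEvent, ...]) -> None:
            nonlocal counter
            a = counter % n_animals
            animal_id = f"{gid}-{a + 1}"
            per_animal_colonies[a].append(
                MutantColony(
                    animal_id=animal_id,
                    colony_id=f"c{counter + 1}",
                    events=events,
                )
            )
            counter += 1

        counts = TABLE1_COUNTS[gid]
        cpg_n = TABLE1_CPG_SUBCOUNTS[gid]
        for _ in range(cpg_n):
            place(builders["GC_to_AT_cpg"]())
        for _ in range(counts[GC_TO_AT] - cpg_n):
            place(builders["GC_to_AT_noncpg"]())
        for cat in (
            AT_TO_GC, GC_TO_TA, GC_TO_CG, AT_TO_TA, AT_TO_CG,
            DELETION_1, DELETION_GE2, INSERTION_CAT, OTHER,
        ):
            for _ in range(counts[cat]):
                place(builders[cat]())
        for a in range(n_animals):
            colonies = tuple(per_animal_colonies[a])
            assays.append(
                AnimalAssay(
                    animal_id=f"{gid}-{a + 1}",
                    group_id=gid,
                    genotype=genotype,
                    dose_g_per_l=dose,
                    sex="unknown",
                    titer=_FIXTURE_TITER,
                    mutant_count=len(colonies),
                    colonies=colonies,
                )
            )
    return assays


# Per-A-run rows of the published run summary for the two knockout groups:
# (run_start, run_end, event spec, vehicle (mutants, independent),
# oxidant-dosed (mutants, independent)). Event specs: ("del",) single-base
# deletion at the run start; ("ins", bases) insertion 5' of the run;
# ("sub", position, alt) substitution inside the run.
ARUN_ROWS: tuple = (
    (8, 12, ("del",), (3, 1), (6, 3)),
    (88, 90, ("del",), (1, 1), (2, 1)),
    (173, 175, ("sub", 175, "C"), (0, 0), (2, 1)),
    (179, 181, ("sub", 181, "C"), (0, 0), (1, 1)),
    (179, 181, ("ins", "T"), (0, 0), (1, 1)),
    (214, 216, ("ins", "A"), (0, 0), (1, 1)),
    (223, 225, ("del",), (1, 1), (2, 2)),
    (315, 318, ("del",), (4, 1), (3, 3)),
    (325, 327, ("del",), (0, 0), (1, 1)),
    (342, 345, ("del",), (2, 1), (5, 2)),
    (342, 345, ("ins", "AA"), (0, 0), (2, 1)),
    (342, 345, ("ins", "A"), (0, 0), (2, 2)),
    (342, 345, ("sub", 345, "C"), (1, 1), (2, 2)),
)

#: (mutants, independent) totals over the rows above, per group.
ARUN_TOTALS = {"ko_vehicle": (12, 6), "ko_kbro3": (30, 21)}


def _arun_event(ref: ReferenceGene, start: int, spec: tuple) -> MutationEvent:
    if spec[0] == "del":
        return MutationEvent(position=start, kind=DELETION, ref_allele=ref.base(start))
    if spec[0] == "ins":
        return MutationEvent(position=start - 1, kind=INSERTION, alt_allele=spec[1])
    if spec[0] == "sub":
        _, pos, alt = spec
        return MutationEvent(
            position=pos, kind=SUBSTITUTION, ref_allele=ref.base(pos), alt_allele=alt
        )
    raise ValueError(f"unknown A-run event spec {spec!r}")


def arun_fixture(
    ref: ReferenceGene, rng: Optional[np.random.Generator] = None
) -> list[AnimalAssay]:
    """Knockout-group assays realizing ``ARUN_ROWS`` exactly.

    Each row contributes its independent count as distinct animals carrying
    the row's mutation, with clonal copies splitting the mutant count as
    evenly as possible. Which animals carry which mutation is arbitrary
    (optionally shuffled by ``rng``); clonal correction per animal is
    invariant to the assignment.
    """
    designs = {"ko_vehicle": 3, "ko_kbro3": 4}
    per_animal: dict[str, list[MutantColony]] = {}
    animal_ids = {
        gid: [f"{gid}-{a + 1}" for a in range(n)] for gid, n in designs.items()
    }
    for ids in animal_ids.values():
        for aid in ids:
            per_animal[aid] = []
    offset = 0
    for start, end, spec, vehicle, dosed in ARUN_ROWS:
        event = _arun_event(ref, start, spec)
        for gid, (mutants, independent) in (
            ("ko_vehicle", vehicle),
            ("ko_kbro3", dosed),
        ):
            if independent == 0:
                continue
            ids = list(animal_ids[gid])
            if rng is not None:
                rng.shuffle(ids)
            else:
                ids = ids[offset % len(ids) :] + ids[: offset % len(ids)]
            base_copies, extra = divmod(mutants, independent)
            for j in range(independent):
                copies = base_copies + (1 if j < extra else 0)
                aid = ids[j]
                for _ in range(copies):
                    per_animal[aid].append(
                        MutantColony(
                            animal_id=aid,
                            colony_id=f"c{len(per_animal[aid]) + 1}",
                            events=(event,),
                        )
                    )
        offset += 1
    assays = []
    for gid, n in designs.items():
        genotype, dose, _ = _GROUP_DESIGN[gid]
        for aid in animal_ids[gid]:
            colonies = tuple(per_animal[aid])
            assays.append(
                AnimalAssay(
                    animal_id=aid,
                    group_id=gid,
                    genotype=genotype,
                    dose_g_per_l=dose,
                    sex="unknown",
                    titer=_FIXTURE_TITER,
                    mutant_count=max(len(colonies), 1),
                    colonies=colonies,
                )
            )
    return assays


def hotspot_fixture(ref: ReferenceGene) -> list[AnimalAssay]:
    """A four-animal group with hotspot support exactly at 92/110/113/115.

    Independent G->A events at the four hotspot positions occur in three or
    four of the animals (one with clonal copies, which must not change any
    call), and background positions occur in at most two animals.
    """

    def g_to_a(p: int) -> MutationEvent:
        return MutationEvent(
            position=p, kind=SUBSTITUTION, ref_allele=ref.base(p), alt_allele="A"
        )

    gid = "ko_kbro3"
    support = {92: (1, 2, 3), 110: (1, 2, 3, 4), 113: (2, 3, 4), 115: (1, 3, 4)}
    background = {64: (1, 2), 143: (3,), 416: (2, 4)}
    colonies: dict[int, list[MutantColony]] = {a: [] for a in (1, 2, 3, 4)}
    for pos, animals in {**support, **background}.items():
        for a in animals:
            copies = 3 if (pos == 110 and a == 1) else 1  # clonal expansion
            for _ in range(copies):
                aid = f"{gid}-{a}"
                colonies[a].append(
                    MutantColony(
                        animal_id=aid,
                        colony_id=f"c{len(colonies[a]) + 1}",
                        events=(g_to_a(pos),),
                    )
                )
    return [
        AnimalAssay(
            animal_id=f"{gid}-{a}",
            group_id=gid,
            genotype="Msh2_KO",
            dose_g_per_l=1.5,
            sex="unknown",
            titer=_FIXTURE_TITER,
            mutant_count=len(colonies[a]),
            colonies=tuple(colonies[a]),
        )
        for a in (1, 2, 3, 4)
    ]
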