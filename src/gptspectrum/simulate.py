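"""Synthetic reporter-gene assay generator.

Emulates the data structure of a transgenic-rodent reporter assay: a small
number of treatment groups (genotype x dose), 3-5 animals per group,
per-animal titers of order 1e5-1e6 rescued phages, per-locus mutation
rates of order 1e-6-1e-4 split across spectrum classes, CpG- and
hotspot-weighted substitution placement, slippage indels in A:T runs, and
within-animal clonal expansion of independent mutations into multiple
colonies.

Mechanics, per animal: the titer is log-normal; the number of independent
mutations is Poisson with mean titer x total per-locus rate; each mutation
draws its site and alleles from a per-identity rate map (class rate spread
over eligible sites, multiplied at CpG sites, configured hotspot
positions, and A:T runs); each independent mutation is expanded into a
geometric number of colonies (>=1); a configurable fraction of resistant
colonies carries no detectable event. Two independent mutations may
coincide at one site within an animal and then legitimately collapse under
clonal correction, exactly as in the real assay; ``expected_independent_counts``
gives the analytic expectation of the clonally corrected (distinct-event)
counts under this saturation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .calling import apply_events, call_events, normalize_indel, write_mutation_table
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
    SUBSTITUTION_CLASSES,
    classify_event,
)
from .events import DELETION, INSERTION, SUBSTITUTION, MutantColony, MutationEvent
from .metrics import AnimalAssay
from .reference import COMPLEMENT, ReferenceGene

# alt base for each substitution class given the coding-strand ref base
_ALT_FOR_CLASS = {
    GC_TO_AT: {"G": "A", "C": "T"},
    GC_TO_TA: {"G": "T", "C": "A"},
    GC_TO_CG: {"G": "C", "C": "G"},
    AT_TO_GC: {"A": "G", "T": "C"},
    AT_TO_TA: {"A": "T", "T": "A"},
    AT_TO_CG: {"A": "C", "T": "G"},
}


@dataclass(frozen=True)
class GroupDesign:
    """One treatment group: labels, size, and optional rate overrides."""

    group_id: str
    genotype: str
    dose_g_per_l: float
    n_animals: int
    rates: Optional[Mapping[str, float]] = None
    arun_indel_rate: Optional[float] = None
    hotspot_multipliers: Optional[Mapping[int, float]] = None


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic study; the seed fixes everything.

    Rates are per rescued phage (per locus). ``base_rate_per_class`` is the
    default split of the total mutation rate over spectrum classes; groups
    may override it. ``cpg_multiplier`` (>=1) up-weights CpG sites and
    ``hotspot_multipliers`` up-weight specific positions within the
    G:C->A:T class (the class rate stays the class total; the multipliers
    reshape its site distribution). ``arun_indel_rate`` is a per-run rate
    of slippage
    events in each annotated A:T run (split between single-base deletion
    and +1/+2 insertions). ``clonal_p`` is the geometric success
    probability for colonies per independent mutation (mean copies
    1/clonal_p); ``no_mutation_fraction`` is the probability that a
    resistant colony shows no detectable event in the reporter window.
    """

    seed: int
    groups: tuple[GroupDesign, ...]
    titer_log_mean: float = math.log(7.0e5)
    titer_log_sigma: float = 0.3
    base_rate_per_class: Mapping[str, float] = field(
        default_factory=lambda: {GC_TO_AT: 2.0e-6, GC_TO_TA: 1.0e-6, DELETION_1: 5.0e-7}
    )
    cpg_multiplier: float = 6.0
    hotspot_multipliers: Mapping[int, float] = field(default_factory=dict)
    arun_indel_rate: float = 0.0
    insertion_two_base_fraction: float = 0.2
    clonal_p: float = 0.7
    no_mutation_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.clonal_p <= 1.0:
            raise ValueError("clonal_p must be in (0, 1]")
        if not 0.0 <= self.no_mutation_fraction < 1.0:
            raise ValueError("no_mutation_fraction must be in [0, 1)")
        if self.cpg_multiplier < 1.0:
            raise ValueError("cpg_multiplier must be >= 1")
        for c, r in self.base_rate_per_class.items():
            if r < 0:
                raise ValueError(f"negative rate for class {c}")


def event_rate_map(
    config: SimulationConfig, ref: ReferenceGene, group: GroupDesign
) -> dict[tuple, tuple[MutationEvent, float]]:
    """Per-identity event rates for one group.

    Every possible generated event, already left-normalized, keyed by its
    clonal identity (position, kind, alleles), with its per-locus rate.
    Equivalent placements (e.g. deleting any base of one homopolymer run)
    accumulate onto one identity.
    """
    rates = dict(group.rates if group.rates is not None else config.base_rate_per_class)
    hotspots = dict(
        group.hotspot_multipliers
        if group.hotspot_multipliers is not None
        else config.hotspot_multipliers
    )
    arun_rate = (
        group.arun_indel_rate
        if group.arun_indel_rate is not None
        else config.arun_indel_rate
    )
    out: dict[tuple, tuple[MutationEvent, float]] = {}
    refseq = ref.numbered_sequence

    def add(event: MutationEvent, rate: float) -> None:
        if rate <= 0:
            return
        event = normalize_indel(event, ref)
        if event.position <= 3 or event.position >= len(ref) - 2:
            # events at the gene boundary can be unrecoverable or admit a
            # different equal-cost reading once amplicon flanks are
            # unknown; generate only what the read-out identifies exactly
            if call_events(ref, apply_events(ref, [event])) != [event]:
                return
        key = event.identity
        if key in out:
            out[key] = (out[key][0], out[key][1] + rate)
        else:
            out[key] = (event, rate)

    n = len(ref)
    gc_sites = [p for p in ref.positions if ref.base(p) in "GC"]
    at_sites = [p for p in ref.positions if ref.base(p) in "AT"]
    for cls in SUBSTITUTION_CLASSES:
        r = rates.get(cls, 0.0)
        if r <= 0:
            continue
        sites = gc_sites if cls.startswith("GC") else at_sites
        weights = []
        for p in sites:
            w = 1.0
            if cls == GC_TO_AT:
                if ref.is_cpg_site(p):
                    w *= config.cpg_multiplier
                w *= hotspots.get(p, 1.0)
            weights.append(w)
        # the class rate is the class total; multipliers reshape how it is
        # distributed over eligible sites
        total_w = sum(weights)
        for p, w in zip(sites, weights):
            b = ref.base(p)
            add(
                MutationEvent(
                    position=p, kind=SUBSTITUTION, ref_allele=b,
                    alt_allele=_ALT_FOR_CLASS[cls][b],
                ),
                r * w / total_w,
            )
    r = rates.get(DELETION_1, 0.0)
    if r > 0:
        for p in ref.positions:
            add(MutationEvent(position=p, kind=DELETION, ref_allele=ref.base(p)), r / n)
    r = rates.get(DELETION_GE2, 0.0)
    if r > 0:
        for p in range(1, n):
            add(
                MutationEvent(position=p, kind=DELETION, ref_allele=ref.slice(p, p + 1)),
                r / (n - 1),
            )
    r = rates.get(INSERTION_CAT, 0.0)
    if r > 0:
        # slippage-style duplication of the base at the anchor
        for p in ref.positions:
            add(MutationEvent(position=p, kind=INSERTION, alt_allele=ref.base(p)), r / n)
    if arun_rate > 0:
        two = config.insertion_two_base_fraction
        for run in ref.a_runs:
            b = run.base
            add(
                MutationEvent(position=run.start, kind=DELETION, ref_allele=b),
                arun_rate,
            )
            add(
                MutationEvent(position=run.start - 1, kind=INSERTION, alt_allele=b)
                if run.start > 1
                else MutationEvent(position=0, kind=INSERTION, alt_allele=b),
                arun_rate * (1.0 - two),
            )
            add(
                MutationEvent(position=run.start - 1, kind=INSERTION, alt_allele=b * 2)
                if run.start > 1
                else MutationEvent(position=0, kind=INSERTION, alt_allele=b * 2),
                arun_rate * two,
            )
    return out


def expected_independent_counts(
    config: SimulationConfig,
    ref: ReferenceGene,
    group: GroupDesign,
    titer: float,
) -> dict[str, float]:
    """Analytic expectation of clonally corrected counts per category.

    The assay cannot distinguish two independent hits of the same identity
    within one animal, so the expected distinct count at a site with
    per-locus rate r is 1 - exp(-titer * r), summed over identities. At low
    per-site rates this approaches the raw expectation titer * r.
    """
    out: dict[str, float] = {}
    for event, rate in event_rate_map(config, ref, group).values():
        cat = classify_event(event)
        out[cat] = out.get(cat, 0.0) + (1.0 - math.exp(-titer * rate))
    return out


def simulate_assay(config: SimulationConfig, ref: ReferenceGene) -> list[AnimalAssay]:
    """Draw a complete synthetic study; deterministic under the config seed."""
    rng = np.random.default_rng(config.seed)
    assays: list[AnimalAssay] = []
    mean_copies = 1.0 / config.clonal_p
    f0 = config.no_mutation_fraction
    for group in config.groups:
        rate_map = list(event_rate_map(config, ref, group).values())
        events = [ev for ev, _ in rate_map]
        rates = np.array([r for _, r in rate_map])
        total_rate = float(rates.sum())
        probs = rates / total_rate if total_rate > 0 else None
        for k in range(group.n_animals):
            animal_id = f"{group.group_id}-{k + 1}"
            titer = int(
                round(rng.lognormal(config.titer_log_mean, config.titer_log_sigma))
            )
            titer = max(titer, 1)
            expected_mutants = total_rate * titer * mean_copies / (1.0 - f0)
            if expected_mutants > titer / 10.0:
                raise ValueError(
                    f"unrealistic configuration: expected {expected_mutants:.0f} "
                    f"mutant colonies for titer {titer}"
                )
            n_indep = rng.poisson(total_rate * titer) if total_rate > 0 else 0
            colonies: list[MutantColony] = []
            if n_indep > 0:
                idx = rng.choice(len(events), size=n_indep, p=probs)
                copies = rng.geometric(config.clonal_p, size=n_indep)
                for i, (event_i, n_cop) in enumerate(zip(idx, copies)):
                    for _ in range(int(n_cop)):
                        colonies.append(
                            MutantColony(
                                animal_id=animal_id,
                                colony_id=f"c{len(colonies) + 1}",
                                events=(events[int(event_i)],),
                            )
                        )
            n_with_events = len(colonies)
            lam0 = total_rate * titer * mean_copies * f0 / (1.0 - f0)
            n_empty = rng.poisson(lam0) if lam0 > 0 else 0
            for _ in range(n_empty):
                colonies.append(
                    MutantColony(
                        animal_id=animal_id,
                        colony_id=f"c{len(colonies) + 1}",
                        events=(),
                    )
                )
            sex = "M" if (k % 2 == 0) else "F"
            assays.append(
                AnimalAssay(
                    animal_id=animal_id,
                    group_id=group.group_id,
                    genotype=group.genotype,
                    dose_g_per_l=group.dose_g_per_l,
                    sex=sex,
                    titer=titer,
                    mutant_count=n_with_events + n_empty,
                    colonies=tuple(colonies),
                )
            )
    return assays


def write_fixture(
    assays: Sequence[AnimalAssay],
    ref: ReferenceGene,
    out_dir: str | Path,
    id_delimiter: str = "|",
) -> dict[str, Path]:
    """Emit colony FASTA, metadata TSV and truth TSV for a set of assays.

    The FASTA holds each colony's mutant sequence rebuilt by applying its
    events to the reference; record IDs are ``animalID|colonyID``. The
    truth table is a mutation table of the generating events (one row per
    colony event, kind ``none`` for colonies without events), which
    round-trips through ``read_mutation_table``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "colonies.fasta"
    with open(fasta_path, "w") as fh:
        for assay in assays:
            for colony in assay.colonies:
                seq = apply_events(ref, list(colony.events))
                fh.write(f">{colony.animal_id}{id_delimiter}{colony.colony_id}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
    meta_path = out_dir / "metadata.tsv"
    pd.DataFrame(
        [
            dict(
                animal_id=a.animal_id,
                group_id=a.group_id,
                genotype=a.genotype,
                dose_g_per_l=a.dose_g_per_l,
                sex=a.sex,
                titer=a.titer,
                mutant_count=a.mutant_count,
            )
            for a in assays
        ]
    ).to_csv(meta_path, sep="\t", index=False)
    truth_path = out_dir / "truth.tsv"
    write_mutation_table(
        [colony for a in assays for colony in a.colonies], truth_path
    )
    return {"fasta": fasta_path, "metadata": meta_path, "truth": truth_path}


# -- study-like presets ----------------------------------------------------

# Spectrum-class proportions and total independent per-locus rates emulating
# the four groups of a mismatch-repair-knockout / potassium-bromate study
# design: two genotypes (Msh2-bearing, Msh2-KO) at 0 or 1.5 g/L oxidant for
# 28 days. Proportions approximate published spectrum shares per group;
# they are emulation targets for the generator, not measurements.
_PRESET_PROPORTIONS = {
    "bearing_vehicle": {
        GC_TO_AT: 3, GC_TO_TA: 2, AT_TO_CG: 1, DELETION_1: 2, DELETION_GE2: 1,
        INSERTION_CAT: 1,
    },
    "bearing_kbro3": {
        GC_TO_AT: 10, AT_TO_GC: 2, GC_TO_TA: 8, GC_TO_CG: 1, AT_TO_TA: 2,
        DELETION_1: 2, DELETION_GE2: 3,
    },
    "ko_vehicle": {
        GC_TO_AT: 51, AT_TO_GC: 13, GC_TO_TA: 10, AT_TO_TA: 4, AT_TO_CG: 6,
        DELETION_1: 17, INSERTION_CAT: 6,
    },
    "ko_kbro3": {
        GC_TO_AT: 60, AT_TO_GC: 25, GC_TO_TA: 19, GC_TO_CG: 1, AT_TO_TA: 2,
        AT_TO_CG: 2, DELETION_1: 26, INSERTION_CAT: 12,
    },
}

# total independent mutation frequency targets per group (per locus)
_PRESET_TOTAL_RATES = {
    "bearing_vehicle": 0.40e-5,
    "bearing_kbro3": 0.64e-5,
    "ko_vehicle": 3.14e-5,
    "ko_kbro3": 2.67e-5,
}

_PRESET_DESIGN = {
    "bearing_vehicle": ("Msh2_bearing", 0.0, 4),
    "bearing_kbro3": ("Msh2_bearing", 1.5, 5),
    "ko_vehicle": ("Msh2_KO", 0.0, 3),
    "ko_kbro3": ("Msh2_KO", 1.5, 4),
}

# G:C->A:T hotspot amplification at the two classic CpG sites and the two
# GpG-context sites; stronger under oxidant dosing
# Multipliers are relative to an unweighted (non-CpG) site; 110/115 sit on
# CpG dinucleotides and get the CpG weight on top, which is why the GpG-only
# sites 92/113 need much larger raw multipliers for a comparable share.
# Under the preset titers these give per-animal per-site expected
# independent-hit rates near 1 at the four sites in dosed knockout groups
# (site support in 3+ of 4 animals, the published hotspot regime) and
# sub-threshold support in vehicle groups except position 110.
_PRESET_HOTSPOTS_DOSED = {92: 320.0, 110: 65.0, 113: 320.0, 115: 55.0}
_PRESET_HOTSPOTS_VEHICLE = {92: 55.0, 110: 28.0, 113: 55.0, 115: 9.0}

#: fraction of the indel rate routed through the A:T-run slippage channel
#: in mismatch-repair-knockout groups
_PRESET_ARUN_SHARE = 0.7


def study_preset(seed: int, ref: ReferenceGene) -> SimulationConfig:
    """Four-group study configuration emulating the assay's observed regime."""
    groups = []
    n_runs = max(len(ref.a_runs), 1)
    for gid, (genotype, dose, n_animals) in _PRESET_DESIGN.items():
        props = _PRESET_PROPORTIONS[gid]
        total = sum(props.values())
        rate = _PRESET_TOTAL_RATES[gid]
        rates = {c: rate * k / total for c, k in props.items()}
        arun = None
        if genotype == "Msh2_KO":
            indel_rate = rates.get(DELETION_1, 0.0) + rates.get(INSERTION_CAT, 0.0)
            arun = _PRESET_ARUN_SHARE * indel_rate / (2.0 * n_runs)
            for c in (DELETION_1, INSERTION_CAT):
                if c in rates:
                    rates[c] *= 1.0 - _PRESET_ARUN_SHARE
        hotspots = _PRESET_HOTSPOTS_DOSED if dose > 0 else _PRESET_HOTSPOTS_VEHICLE
        groups.append(
            GroupDesign(
                group_id=gid,
                genotype=genotype,
                dose_g_per_l=dose,
                n_animals=n_animals,
                rates=rates,
                arun_indel_rate=arun,
                hotspot_multipliers=hotspots,
            )
        )
    return SimulationConfig(seed=seed, groups=tuple(groups))


# -- YAML round trip (CLI) -------------------------------------------------


def config_to_dict(config: SimulationConfig) -> dict:
    return dict(
        seed=config.seed,
        titer_log_mean=config.titer_log_mean,
        titer_log_sigma=config.titer_log_sigma,
        base_rate_per_class=dict(config.base_rate_per_class),
        cpg_multiplier=config.cpg_multiplier,
        hotspot_multipliers={int(k): v for k, v in config.hotspot_multipliers.items()},
        arun_indel_rate=config.arun_indel_rate,
        insertion_two_base_fraction=config.insertion_two_base_fraction,
        clonal_p=config.clonal_p,
        no_mutation_fraction=config.no_mutation_fraction,
        groups=[
            dict(
                group_id=g.group_id,
                genotype=g.genotype,
                dose_g_per_l=g.dose_g_per_l,
                n_animals=g.n_animals,
                rates=dict(g.rates) if g.rates is not None else None,
                arun_indel_rate=g.arun_indel_rate,
                hotspot_multipliers=(
                    {int(k): v for k, v in g.hotspot_multipliers.items()}
                    if g.hotspot_multipliers is not None
                    else None
                ),
            )
            for g in config.groups
        ],
    )


def config_from_dict(data: Mapping) -> SimulationConfig:
    groups = tuple(
        GroupDesign(
            group_id=g["group_id"],
            genotype=g.get("genotype", "unknown"),
            dose_g_per_l=float(g.get("dose_g_per_l", 0.0)),
            n_animals=int(g["n_animals"]),
            rates=g.get("rates"),
            arun_indel_rate=g.get("arun_indel_rate"),
            hotspot_multipliers=(
                {int(k): float(v) for k, v in g["hotspot_multipliers"].items()}
                if g.get("hotspot_multipliers")
                else None
            ),
        )
        for g in data["groups"]
    )
    kwargs = {
        k: data[k]
        for k in (
            "titer_log_mean",
            "titer_log_sigma",
            "base_rate_per_class",
            "cpg_multiplier",
            "arun_indel_rate",
            "insertion_two_base_fraction",
            "clonal_p",
            "no_mutation_fraction",
        )
        if k in data
    }
    if "hotspot_multipliers" in data:
        kwargs["hotspot_multipliers"] = {
            int(k): float(v) for k, v in data["hotspot_multipliers"].items()
        }
    return SimulationConfig(seed=int(data["seed"]), groups=groups, **kwargs)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: SimulationConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
    return path
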