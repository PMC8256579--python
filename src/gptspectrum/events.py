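"""Mutation events and mutant colonies.

A sequenced 6-thioguanine-resistant colony carries zero or more variants
relative to the reporter gene. Events use 1-based reference numbering:
substitutions at the changed base, deletions at the first deleted base
after left-alignment, insertions anchored at the reference base immediately
5' of the inserted bases (anchor 0 means an insertion before position 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .reference import Run

SUBSTITUTION = "substitution"
DELETION = "deletion"
INSERTION = "insertion"
COMPLEX = "complex"

KINDS = (SUBSTITUTION, DELETION, INSERTION, COMPLEX)


@dataclass(frozen=True)
class ContextFlags:
    """Sequence context of an event.

    ``is_cpg``/``is_gpg`` are meaningful for substitutions at G:C pairs;
    ``run`` is set when the event lies inside an annotated A:T run (for
    indels: when the inserted/deleted bases match the run base and the
    left-aligned placement touches the run interval).
    """

    is_cpg: bool = False
    is_gpg: bool = False
    run: Optional[Run] = None


@dataclass(frozen=True)
class MutationEvent:
    position: int
    kind: str
    ref_allele: str = ""
    alt_allele: str = ""
    category: Optional[str] = None
    context: Optional[ContextFlags] = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.kind == SUBSTITUTION:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("substitution alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("substitution ref and alt alleles are equal")
        elif self.kind == DELETION:
            if self.alt_allele or not self.ref_allele:
                raise ValueError("deletion needs ref_allele and empty alt_allele")
        elif self.kind == INSERTION:
            if self.ref_allele or not self.alt_allele:
                raise ValueError("insertion needs alt_allele and empty ref_allele")

    @property
    def size(self) -> int:
        if self.kind == DELETION:
            return len(self.ref_allele)
        if self.kind == INSERTION:
            return len(self.alt_allele)
        return max(len(self.ref_allele), len(self.alt_allele), 1)

    @property
    def identity(self) -> tuple[int, str, str, str]:
        """Key under which clonal copies of one mutation are identical."""
        return (self.position, self.kind, self.ref_allele, self.alt_allele)

    def with_category(self, category: str) -> "MutationEvent":
        return replace(self, category=category)

    def with_context(self, context: ContextFlags) -> "MutationEvent":
        return replace(self, context=context)

    def describe(self) -> str:
        if self.kind == SUBSTITUTION:
            return f"{self.ref_allele}{self.position}{self.alt_allele}"
        if self.kind == DELETION:
            return f"del{self.position}{self.ref_allele}"
        if self.kind == INSERTION:
            return f"ins{self.position}+{self.alt_allele}"
        return f"complex{self.position}{self.ref_allele}>{self.alt_allele}"


@dataclass(frozen=True)
class MutantColony:
    """One confirmed 6-TG-resistant colony and its called events.

    A colony with no detectable event (resistant but sequence-identical to
    the reference) has an empty event list; it counts toward the mutant
    frequency denominator's numerator but not toward spectra.
    """

    animal_id: str
    colony_id: str
    events: tuple[MutationEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "events", tuple(sorted(self.events, key=lambda e: (e.position, e.kind)))
        )
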