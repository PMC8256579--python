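"""Reference gene model: coordinates, CpG sites, and mononucleotide runs.

The transgenic-rodent reporter assay scores mutations on a short bacterial
gene (canonically the ~0.46-kb *E. coli gpt* coding sequence rescued from
lambda EG10). All downstream bookkeeping — hotspot positions, CpG context of
G:C→A:T transitions, and slippage indels inside mononucleotide runs — is
expressed in 1-based coordinates on the coding strand, so the reference
model fixes that numbering once and derives the sequence-context annotation
eagerly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

VALID_BASES = frozenset("ACGT")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class Run:
    """A maximal mononucleotide run on the coding strand.

    ``start`` and ``end`` are 1-based inclusive positions in the reference
    numbering. A run of A or T on the coding strand is an "A-run" at the
    base-pair level (an A:T tract); runs of C or G are retained for
    completeness but are not A-runs.
    """

    base: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_at_run(self) -> bool:
        return self.base in ("A", "T")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class ReferenceGene:
    """An annotated reference coding sequence.

    ``numbering_offset`` is the 0-based index in ``sequence`` of the
    nucleotide reported as position 1, so FASTA files that carry flanking
    vector sequence can still be numbered from the start codon.

    ``cpg_positions`` holds every 1-based position participating in a
    5'-CG-3' dinucleotide (both the C and the G). Because CpG is its own
    reverse complement, a G:C pair at any of these positions is a CpG site
    regardless of which strand carries the G.
    """

    name: str
    sequence: str
    numbering_offset: int = 0
    run_min_length: int = 3
    cpg_positions: frozenset[int] = field(init=False)
    runs: tuple[Run, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence is empty")
        for i, b in enumerate(self.sequence):
            if b not in VALID_BASES:
                raise ValueError(
                    f"non-ACGT character {b!r} in reference at index {i}"
                )
        if not (0 <= self.numbering_offset < len(self.sequence)):
            raise ValueError(
                f"numbering_offset {self.numbering_offset} outside sequence "
                f"of length {len(self.sequence)}"
            )
        object.__setattr__(self, "cpg_positions", self._find_cpg_positions())
        object.__setattr__(self, "runs", self._find_runs())

    # -- coordinates ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.sequence) - self.numbering_offset

    @property
    def positions(self) -> range:
        """All valid 1-based positions."""
        return range(1, len(self) + 1)

    def base(self, position: int) -> str:
        """Base at a 1-based position in the reference numbering."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return self.sequence[self.numbering_offset + position - 1]

    def slice(self, start: int, end: int) -> str:
        """Bases from ``start`` to ``end`` inclusive (1-based)."""
        if start < 1 or end > len(self) or start > end:
            raise IndexError(f"bad slice {start}..{end} for 1..{len(self)}")
        off = self.numbering_offset
        return self.sequence[off + start - 1 : off + end]

    @property
    def numbered_sequence(self) -> str:
        """The part of the sequence covered by the 1-based numbering."""
        return self.sequence[self.numbering_offset :]

    # -- annotation ----------------------------------------------------

    def _find_cpg_positions(self) -> frozenset[int]:
        seq = self.sequence[self.numbering_offset :]
        out: set[int] = set()
        for i in range(len(seq) - 1):
            if seq[i] == "C" and seq[i + 1] == "G":
                out.add(i + 1)
                out.add(i + 2)
        return frozenset(out)

    def _find_runs(self) -> tuple[Run, ...]:
        seq = self.sequence[self.numbering_offset :]
        runs: list[Run] = []
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            if j - i >= self.run_min_length:
                runs.append(Run(base=seq[i], start=i + 1, end=j))
            i = j
        return tuple(runs)

    @property
    def a_runs(self) -> tuple[Run, ...]:
        """Maximal A:T-pair runs (A or T on the coding strand)."""
        return tuple(r for r in self.runs if r.is_at_run)

    def run_at(self, position: int, base: str | None = None) -> Run | None:
        """The annotated run containing ``position`` (optionally of ``base``)."""
        for r in self.runs:
            if position in r and (base is None or r.base == base):
                return r
        return None

    def is_cpg_site(self, position: int) -> bool:
        """True iff the base pair at ``position`` is part of a CpG dinucleotide."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return position in self.cpg_positions


def is_gpg_context(ref: ReferenceGene, position: int) -> bool:
    """True iff ``position`` is the 3' G of 5'-GpG-3' on the coding strand.

    Position 1 has no 5' neighbour and is never in GpG context.
    """
    if not 1 <= position <= len(ref):
        raise IndexError(f"position {position} outside 1..{len(ref)}")
    if position == 1:
        return False
    return ref.base(position) == "G" and ref.base(position - 1) == "G"


def load_reference(
    fasta_path: str | Path,
    numbering_offset: int = 0,
    run_min_length: int = 3,
) -> ReferenceGene:
    """Load a single-record FASTA as an annotated reference gene.

    Raises ``ValueError`` for multi-record files, empty files and non-ACGT
    characters (naming the offending position).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"no FASTA records in {fasta_path}")
    if len(records) > 1:
        raise ValueError(
            f"expected a single-record FASTA, found {len(records)} records "
            f"in {fasta_path}"
        )
    rec = records[0]
    return ReferenceGene(
        name=rec.id,
        sequence=str(rec.seq).upper(),
        numbering_offset=numbering_offset,
        run_min_length=run_min_length,
    )


# Calibration anchors for the packaged gpt reference. The assay literature
# numbers the gene from the first base of the start codon; under that
# numbering the two classic spontaneous G:C->A:T sites fall at CpG
# dinucleotides 110 and 115 and the oxidative-stress-associated sites 92 and
# 113 are each the 3' G of 5'-GpG-3'. These anchors pin the packaged
# sequence and its offset; a wrong fixture fails loudly at load time.
_GPT_CPG_ANCHORS = (110, 115)
_GPT_GPG_ANCHORS = (92, 113)


def load_gpt_reference(run_min_length: int = 3) -> ReferenceGene:
    """The packaged *E. coli gpt* coding sequence, calibration-checked."""
    with resources.as_file(
        resources.files("gptspectrum.data").joinpath("gpt.fasta")
    ) as path:
        ref = load_reference(path, numbering_offset=0, run_min_length=run_min_length)
    for p in _GPT_CPG_ANCHORS:
        if not ref.is_cpg_site(p):
            raise RuntimeError(
                f"packaged gpt reference failed calibration: position {p} "
                "is not a CpG site under the packaged numbering"
            )
    for p in _GPT_GPG_ANCHORS:
        if not is_gpg_context(ref, p):
            raise RuntimeError(
                f"packaged gpt reference failed calibration: position {p} "
                "is not the 3' G of a GpG dinucleotide"
            )
    return ref


def remap_positions_to_reverse(positions: Iterable[int], length: int) -> set[int]:
    """Map 1-based positions onto the reverse-complement coordinate system."""
    return {length - p + 1 for p in positions}
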