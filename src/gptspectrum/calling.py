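"""Variant calling from mutant-colony sequences.

Colony sequences (typically a PCR amplicon fully covering the reporter
gene) are aligned to the reference with unit edit costs; the reference must
align end-to-end while amplicon flanks are free. Indels are left-aligned to
their 5'-most equivalent placement on the coding strand, the canonical
choice for run-level bookkeeping, and gap columns that are equivalent under
repeat slippage are merged into single events.
"""

from __future__ import annotations

import re
from pathlib import Path

import edlib
import pandas as pd

from .events import (
    COMPLEX,
    DELETION,
    INSERTION,
    KINDS,
    SUBSTITUTION,
    MutantColony,
    MutationEvent,
)
from .reference import VALID_BASES, ReferenceGene

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def normalize_indel(event: MutationEvent, ref: ReferenceGene) -> MutationEvent:
    """Shift an indel to its 5'-most equivalent placement (left alignment).

    Substitutions and complex events are returned unchanged. The operation
    is idempotent and preserves the alternate sequence: a placement is only
    explored when applying the shifted event yields an identical mutant.
    """
    if event.kind == DELETION:
        pos, k = event.position, len(event.ref_allele)
        # deleting ref[pos..pos+k-1] == deleting ref[pos-1..pos+k-2]
        # iff the base 5' of the gap equals the last deleted base
        while pos > 1 and ref.base(pos - 1) == ref.base(pos + k - 1):
            pos -= 1
        if pos == event.position:
            return event
        return MutationEvent(
            position=pos,
            kind=DELETION,
            ref_allele=ref.slice(pos, pos + k - 1),
            category=event.category,
            context=event.context,
        )
    if event.kind == INSERTION:
        anchor = event.position
        alt = event.alt_allele
        # inserting alt after ``anchor`` == inserting rot(alt) after
        # ``anchor - 1`` iff the anchor base equals the last inserted base
        while anchor >= 1 and ref.base(anchor) == alt[-1]:
            alt = ref.base(anchor) + alt[:-1]
            anchor -= 1
        if anchor == event.position:
            return event
        return MutationEvent(
            position=anchor,
            kind=INSERTION,
            alt_allele=alt,
            category=event.category,
            context=event.context,
        )
    return event


def _merge_equivalent_indels(
    events: list[MutationEvent], ref: ReferenceGene
) -> list[MutationEvent]:
    """Merge indels that normalize to one placement (split repeat gaps)."""
    merged: dict[tuple[int, str], MutationEvent] = {}
    out: list[MutationEvent] = []
    for ev in events:
        if ev.kind not in (DELETION, INSERTION):
            out.append(ev)
            continue
        key = (ev.position, ev.kind)
        if key not in merged:
            merged[key] = ev
            continue
        prev = merged[key]
        if ev.kind == DELETION:
            k = len(prev.ref_allele) + len(ev.ref_allele)
            merged[key] = MutationEvent(
                position=prev.position,
                kind=DELETION,
                ref_allele=ref.slice(prev.position, prev.position + k - 1),
            )
        else:
            merged[key] = normalize_indel(
                MutationEvent(
                    position=prev.position,
                    kind=INSERTION,
                    alt_allele=prev.alt_allele + ev.alt_allele,
                ),
                ref,
            )
    out.extend(merged.values())
    return out


def call_events(
    ref: ReferenceGene,
    mutant_sequence: str,
    min_identity: float = 0.9,
) -> list[MutationEvent]:
    """Call mutation events from a colony sequence by global alignment.

    The mutant sequence must cover the full reference region; flanking
    amplicon sequence is tolerated and ignored. Only events inside the
    reference coordinate window are reported.

    Raises ``ValueError`` for non-ACGT characters and for sequences whose
    alignment identity to the reference falls below ``min_identity``.
    """
    query = mutant_sequence.upper()
    for i, b in enumerate(query):
        if b not in VALID_BASES:
            raise ValueError(f"non-ACGT character {b!r} in mutant sequence at index {i}")
    refseq = ref.numbered_sequence
    # infix mode: the reference aligns end-to-end, amplicon flanks are free
    aln = edlib.align(refseq, query, mode="HW", task="path")
    identity = 1.0 - aln["editDistance"] / len(refseq)
    if identity < min_identity:
        raise ValueError(
            f"not a plausible mutant of this reference "
            f"(alignment identity {identity:.3f} < {min_identity})"
        )
    t = aln["locations"][0][0]  # target cursor
    t_end = aln["locations"][0][1] + 1  # one past the located window
    ops = [(int(c), op) for c, op in _CIGAR_RE.findall(aln["cigar"])]
    # With free flanks, a substitution at a reference boundary scores the
    # same as deleting the reference base and pushing the mutant base into
    # the flank. The mutant covers the full reference by contract, so
    # repair such terminal reference-deletions into substitutions when
    # unused flank bases exist.
    if ops and ops[0][1] == "I":
        k = min(ops[0][0], t)
        if k:
            ops[0] = (ops[0][0] - k, "I")
            ops.insert(0, (k, "X"))
            t -= k
    if ops and ops[-1][1] == "I":
        m = ops[-1][0]
        k = min(m, len(query) - t_end)
        if k:
            ops[-1] = (m - k, "I")
            ops.append((k, "X"))
    i = 0  # reference cursor (0-based)
    events: list[MutationEvent] = []
    for n, op in ops:
        if n == 0:
            continue
        if op == "=":
            i += n
            t += n
        elif op == "X":
            for j in range(n):
                if refseq[i + j] != query[t + j]:
                    events.append(
                        MutationEvent(
                            position=i + j + 1,
                            kind=SUBSTITUTION,
                            ref_allele=refseq[i + j],
                            alt_allele=query[t + j],
                        )
                    )
            i += n
            t += n
        elif op == "I":  # reference bases absent from the mutant: deletion
            events.append(
                MutationEvent(
                    position=i + 1,
                    kind=DELETION,
                    ref_allele=refseq[i : i + n],
                )
            )
            i += n
        elif op == "D":  # mutant bases absent from the reference: insertion
            events.append(
                MutationEvent(
                    position=i,
                    kind=INSERTION,
                    alt_allele=query[t : t + n],
                )
            )
            t += n
    events = [normalize_indel(e, ref) for e in events]
    events = _merge_equivalent_indels(events, ref)
    events.sort(key=lambda e: (e.position, e.kind))
    events = _merge_adjacent_deletions(events, ref)
    return events


def _merge_adjacent_deletions(
    events: list[MutationEvent], ref: ReferenceGene
) -> list[MutationEvent]:
    """Fuse contiguous deletion events into one (a split multi-base gap)."""
    out: list[MutationEvent] = []
    for ev in events:
        prev = out[-1] if out else None
        if (
            prev is not None
            and prev.kind == DELETION
            and ev.kind == DELETION
            and ev.position == prev.position + prev.size
        ):
            out[-1] = normalize_indel(
                MutationEvent(
                    position=prev.position,
                    kind=DELETION,
                    ref_allele=prev.ref_allele + ev.ref_allele,
                ),
                ref,
            )
        else:
            out.append(ev)
    return out


def apply_events(ref: ReferenceGene, events: list[MutationEvent]) -> str:
    """Rebuild the mutant sequence of the reference window from events.

    Events must be mutually non-overlapping; they are applied 3'->5' so
    coordinates stay valid.
    """
    seq = list(ref.numbered_sequence)

    def sort_key(ev: MutationEvent) -> float:
        # an insertion after position p happens between p and p+1
        return ev.position + (0.5 if ev.kind == INSERTION else 0.0)

    for ev in sorted(events, key=sort_key, reverse=True):
        idx = ev.position - 1
        if ev.kind == SUBSTITUTION:
            if seq[idx] != ev.ref_allele:
                raise ValueError(f"ref allele mismatch applying {ev.describe()}")
            seq[idx] = ev.alt_allele
        elif ev.kind == DELETION:
            if "".join(seq[idx : idx + len(ev.ref_allele)]) != ev.ref_allele:
                raise ValueError(f"ref allele mismatch applying {ev.describe()}")
            del seq[idx : idx + len(ev.ref_allele)]
        elif ev.kind == INSERTION:
            seq[ev.position : ev.position] = list(ev.alt_allele)
        else:
            raise ValueError("cannot apply a complex event to a sequence")
    return "".join(seq)


_TABLE_COLUMNS = ("animal_id", "colony_id", "position", "ref_allele", "alt_allele", "kind")


def read_mutation_table(
    tsv_path: str | Path, ref: ReferenceGene, delimiter: str = "\t"
) -> list[MutantColony]:
    """Ingest a pre-called mutation table as a list of mutant colonies.

    Expected columns: animal_id, colony_id, position, ref_allele,
    alt_allele, kind. A row of kind ``none`` registers a colony with no
    detectable event. Reference alleles are validated against the reference
    sequence; indels are left-aligned on ingestion.
    """
    df = pd.read_csv(tsv_path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table is missing columns {missing}")
    colonies: dict[tuple[str, str], list[MutationEvent]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        key = (str(row.animal_id), str(row.colony_id))
        colonies.setdefault(key, [])
        kind = row.kind.strip().lower()
        if kind in ("none", ""):
            continue
        if kind not in KINDS:
            raise ValueError(f"row {row_no}: unknown mutation kind {row.kind!r}")
        position = int(row.position)
        ref_allele = row.ref_allele.strip().upper().replace("-", "")
        alt_allele = row.alt_allele.strip().upper().replace("-", "")
        if kind in (SUBSTITUTION, DELETION, COMPLEX) and ref_allele:
            observed = ref.slice(position, position + len(ref_allele) - 1)
            if observed != ref_allele:
                raise ValueError(
                    f"row {row_no}: ref_allele {ref_allele!r} does not match "
                    f"reference {observed!r} at position {position}"
                )
        event = MutationEvent(
            position=position, kind=kind, ref_allele=ref_allele, alt_allele=alt_allele
        )
        colonies[key].append(normalize_indel(event, ref))
    return [
        MutantColony(animal_id=a, colony_id=c, events=tuple(evs))
        for (a, c), evs in colonies.items()
    ]


def write_mutation_table(
    colonies: list[MutantColony], path: str | Path, delimiter: str = "\t"
) -> Path:
    """Write colonies to a mutation table readable by ``read_mutation_table``."""
    rows = []
    for col in colonies:
        if not col.events:
            rows.append(
                dict(
                    animal_id=col.animal_id,
                    colony_id=col.colony_id,
                    position=0,
                    ref_allele="",
                    alt_allele="",
                    kind="none",
                )
            )
        for ev in col.events:
            rows.append(
                dict(
                    animal_id=col.animal_id,
                    colony_id=col.colony_id,
                    position=ev.position,
                    ref_allele=ev.ref_allele,
                    alt_allele=ev.alt_allele,
                    kind=ev.kind,
                )
            )
    path = Path(path)
    pd.DataFrame(rows, columns=list(_TABLE_COLUMNS)).to_csv(path, sep=delimiter, index=False)
    return path
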