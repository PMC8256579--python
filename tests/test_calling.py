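"""Variant calling: alignment-based event extraction and indel normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gptspectrum.calling import (
    apply_events,
    call_events,
    normalize_indel,
    read_mutation_table,
    write_mutation_table,
)
from gptspectrum.events import DELETION, INSERTION, SUBSTITUTION, MutationEvent
from gptspectrum.reference import ReferenceGene

BASES = "ACGT"


def levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def has_alternative_reading(mutant: str, refseq: str) -> bool:
    """True when some proper window of the mutant is within one edit of the
    reference, i.e. a different single-edit interpretation exists once
    amplicon flanks are unknown (only possible at the gene boundary)."""
    n = len(refseq)
    for a in range(len(mutant)):
        for length in (n - 1, n, n + 1):
            b = a + length
            if b > len(mutant) or (a == 0 and b == len(mutant)):
                continue
            if levenshtein(refseq, mutant[a:b]) <= 1:
                return True
    return False


def all_single_edits(ref: ReferenceGene):
    """Independent oracle: enumerate every single-base edit of a reference."""
    n = len(ref)
    for p in range(1, n + 1):
        for alt in BASES:
            if alt != ref.base(p):
                yield MutationEvent(
                    position=p, kind=SUBSTITUTION, ref_allele=ref.base(p), alt_allele=alt
                )
        yield MutationEvent(position=p, kind=DELETION, ref_allele=ref.base(p))
    for anchor in range(0, n + 1):
        for alt in BASES:
            yield MutationEvent(position=anchor, kind=INSERTION, alt_allele=alt)


class TestCallEvents:
    def test_identical_sequence_yields_no_events(self, toy):
        assert call_events(toy, toy.numbered_sequence) == []

    def test_single_substitution(self, toy):
        mutant = "ATGACATAAAAACGCGT"
        events = call_events(toy, mutant)
        assert len(events) == 1
        ev = events[0]
        assert (ev.position, ev.kind, ev.ref_allele, ev.alt_allele) == (
            6, SUBSTITUTION, "G", "A",
        )

    def test_run_deletion_left_aligned(self, toy):
        mutant = "ATGACGTAAAACGCGT"  # one A removed from the 8-12 run
        events = call_events(toy, mutant)
        assert len(events) == 1
        ev = events[0]
        assert (ev.position, ev.kind, ev.ref_allele, ev.size) == (8, DELETION, "A", 1)

    def test_split_run_gaps_merge_to_one_deletion(self, toy):
        # remove two As from the run; any gap placement must canonicalize
        # to a single 2-base deletion at the run start
        mutant = "ATGACGTAAACGCGT"
        events = call_events(toy, mutant, min_identity=0.85)
        assert len(events) == 1
        ev = events[0]
        assert (ev.position, ev.kind, ev.ref_allele) == (8, DELETION, "AA")

    def test_amplicon_flanks_ignored(self, toy):
        mutant = "GGCCGG" + "ATGACATAAAAACGCGT" + "CCGGTT"
        events = call_events(toy, mutant)
        assert [(e.position, e.kind) for e in events] == [(6, SUBSTITUTION)]

    def test_non_acgt_rejected(self, toy):
        with pytest.raises(ValueError, match="non-ACGT"):
            call_events(toy, "ATGACGTNAAAACGCGT")

    def test_implausible_sequence_rejected(self, gpt):
        with pytest.raises(ValueError, match="not a plausible mutant"):
            call_events(gpt, "ACGT" * 120)

    @pytest.mark.parametrize(
        "sequence",
        [
            "ATGACGTAAAAACGCGT",  # toy: CpG cluster + 5-A run
            "ATTTTGCCCCATGCGCGTATATATACCA",  # runs and dinucleotide repeats
            "CATTGCAGGTAGGGTTTAACCAGCGCATTACGGTTCAGGACCAGCATAAC",  # len 50
        ],
    )
    def test_single_edit_oracle_equivalence(self, sequence):
        """Every unambiguous single-base edit is recovered exactly.

        Edits at the gene boundary can admit several equal-cost readings
        once amplicon flanks are unknown (e.g. a substitution of the last
        base vs. deleting it and reading the mutant base as flank); the
        oracle excludes mutants with such alternative readings, which it
        detects independently by brute-force window enumeration.
        """
        ref = ReferenceGene(name="r", sequence=sequence)
        refseq = ref.numbered_sequence
        checked = 0
        for edit in all_single_edits(ref):
            mutant = apply_events(ref, [edit])
            if has_alternative_reading(mutant, refseq):
                continue
            expected = normalize_indel(edit, ref)
            assert call_events(ref, mutant) == [expected], edit
            checked += 1
        assert checked > 4 * len(ref)

    def test_round_trip_reconstruction(self, gpt):
        """Applying called events to the reference rebuilds the mutant."""
        rng = np.random.default_rng(7)
        refseq = gpt.numbered_sequence
        for _ in range(40):
            positions = sorted(rng.choice(range(20, 430, 30), size=3, replace=False))
            events = []
            for p in positions:
                kind = rng.choice([SUBSTITUTION, DELETION, INSERTION])
                p = int(p)
                if kind == SUBSTITUTION:
                    alt = rng.choice([b for b in BASES if b != gpt.base(p)])
                    events.append(
                        MutationEvent(
                            position=p, kind=SUBSTITUTION,
                            ref_allele=gpt.base(p), alt_allele=str(alt),
                        )
                    )
                elif kind == DELETION:
                    events.append(
                        MutationEvent(position=p, kind=DELETION, ref_allele=gpt.base(p))
                    )
                else:
                    events.append(
                        MutationEvent(
                            position=p, kind=INSERTION, alt_allele=str(rng.choice(list(BASES)))
                        )
                    )
            mutant = apply_events(gpt, events)
            if refseq in mutant:
                continue
            recalled = call_events(gpt, mutant)
            assert apply_events(gpt, recalled) == mutant


class TestNormalizeIndel:
    def test_run_deletion_shifts_to_run_start(self, toy):
        ev = MutationEvent(position=11, kind=DELETION, ref_allele="A")
        assert normalize_indel(ev, toy).position == 8

    def test_run_insertion_anchors_at_five_prime_boundary(self, toy):
        ev = MutationEvent(position=10, kind=INSERTION, alt_allele="AA")
        norm = normalize_indel(ev, toy)
        assert (norm.position, norm.alt_allele) == (7, "AA")

    def test_non_repetitive_deletion_unchanged(self):
        ref = ReferenceGene(name="r", sequence="ACGT")
        ev = MutationEvent(position=3, kind=DELETION, ref_allele="G")
        assert normalize_indel(ev, ref) == ev

    def test_substitution_returned_unchanged(self, toy):
        ev = MutationEvent(
            position=6, kind=SUBSTITUTION, ref_allele="G", alt_allele="A"
        )
        assert normalize_indel(ev, toy) is ev

    @given(
        seq=st.text(alphabet="ACGT", min_size=4, max_size=30),
        pos=st.integers(min_value=1, max_value=30),
        size=st.integers(min_value=1, max_value=3),
    )
    @settings(max_examples=200, derandomize=True)
    def test_idempotent_and_sequence_preserving(self, seq, pos, size):
        if pos + size - 1 > len(seq):
            return
        ref = ReferenceGene(name="h", sequence=seq)
        ev = MutationEvent(
            position=pos, kind=DELETION, ref_allele=ref.slice(pos, pos + size - 1)
        )
        norm = normalize_indel(ev, ref)
        assert normalize_indel(norm, ref) == norm
        assert apply_events(ref, [norm]) == apply_events(ref, [ev])


class TestMutationTable:
    def test_round_trip_with_validation(self, gpt, tmp_path):
        path = tmp_path / "tab.tsv"
        path.write_text(
            "animal_id\tcolony_id\tposition\tref_allele\talt_allele\tkind\n"
            "a1\tc1\t110\tG\tA\tsubstitution\n"
            "a1\tc2\t11\tA\t\tdeletion\n"
            "a2\tc1\t0\t\t\tnone\n"
        )
        colonies = read_mutation_table(path, gpt)
        assert len(colonies) == 3
        by_key = {(c.animal_id, c.colony_id): c for c in colonies}
        sub = by_key[("a1", "c1")].events[0]
        assert (sub.position, sub.ref_allele, sub.alt_allele) == (110, "G", "A")
        # the run deletion is left-aligned on ingestion (run 8-12)
        assert by_key[("a1", "c2")].events[0].position == 8
        assert by_key[("a2", "c1")].events == ()
        out = tmp_path / "echo.tsv"
        write_mutation_table(colonies, out)
        assert [c.events for c in read_mutation_table(out, gpt)] == [
            c.events for c in colonies
        ]

    def test_ref_allele_mismatch_names_row(self, gpt, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "animal_id\tcolony_id\tposition\tref_allele\talt_allele\tkind\n"
            "a1\tc1\t110\tT\tA\tsubstitution\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_mutation_table(path, gpt)

    def test_unknown_kind_rejected(self, gpt, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "animal_id\tcolony_id\tposition\tref_allele\talt_allele\tkind\n"
            "a1\tc1\t110\tG\tA\tinversion\n"
        )
        with pytest.raises(ValueError, match="unknown mutation kind"):
            read_mutation_table(path, gpt)

    def test_two_rows_one_colony(self, gpt, tmp_path):
        path = tmp_path / "tab.tsv"
        path.write_text(
            "animal_id\tcolony_id\tposition\tref_allele\talt_allele\tkind\n"
            "a1\tc1\t110\tG\tA\tsubstitution\n"
            "a1\tc1\t92\tG\tA\tsubstitution\n"
        )
        colonies = read_mutation_table(path, gpt)
        assert len(colonies) == 1
        assert len(colonies[0].events) == 2
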