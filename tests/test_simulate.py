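"""Synthetic-assay generator: determinism, recovery, hotspot power."""

import math

import numpy as np
import pytest

from gptspectrum.classify import GC_TO_AT, GC_TO_TA, DELETION_1, classify_event
from gptspectrum.hotspots import call_hotspots
from gptspectrum.metrics import independent_events
from gptspectrum.simulate import (
    GroupDesign,
    SimulationConfig,
    event_rate_map,
    expected_independent_counts,
    simulate_assay,
    study_preset,
    write_fixture,
)


def small_config(seed, **overrides):
    kwargs = dict(
        seed=seed,
        groups=(
            GroupDesign(group_id="g1", genotype="Msh2_KO", dose_g_per_l=0.0, n_animals=3),
        ),
        base_rate_per_class={GC_TO_AT: 9.0e-6, GC_TO_TA: 6.0e-6, DELETION_1: 5.0e-6},
        cpg_multiplier=1.0,
        clonal_p=0.7,
        no_mutation_fraction=0.05,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, gpt, tmp_path):
        for d in ("one", "two"):
            cfg = study_preset(42, gpt)
            paths = write_fixture(simulate_assay(cfg, gpt), gpt, tmp_path / d)
        for name in ("colonies.fasta", "metadata.tsv", "truth.tsv"):
            assert (tmp_path / "one" / name).read_bytes() == (
                tmp_path / "two" / name
            ).read_bytes()

    def test_different_seeds_differ(self, gpt):
        a = simulate_assay(study_preset(1, gpt), gpt)
        b = simulate_assay(study_preset(2, gpt), gpt)
        assert [x.titer for x in a] != [x.titer for x in b]


class TestEdgeCases:
    def test_zero_rates_give_empty_spectra(self, gpt):
        cfg = small_config(0, base_rate_per_class={})
        assays = simulate_assay(cfg, gpt)
        assert all(len(a.colonies) == 0 for a in assays)
        assert all(a.mutant_count == 0 for a in assays)

    def test_unrealistic_rates_rejected(self, gpt):
        cfg = small_config(0, base_rate_per_class={GC_TO_AT: 0.5})
        with pytest.raises(ValueError, match="unrealistic"):
            simulate_assay(cfg, gpt)

    def test_empty_assay_list_writes_valid_files(self, gpt, tmp_path):
        paths = write_fixture([], gpt, tmp_path)
        assert paths["fasta"].read_text() == ""
        header = paths["truth"].read_text().splitlines()[0]
        assert header.split("\t") == [
            "animal_id", "colony_id", "position", "ref_allele", "alt_allele", "kind",
        ]


class TestClonalCorrectionRecovery:
    def test_pipeline_independent_counts_match_truth_exactly(self, gpt):
        """Clonal correction recovers the generated distinct mutations.

        Identity is (position, kind, alleles), so independent mutations that
        coincide by chance legitimately collapse; the comparison is against
        distinct generated identities per animal.
        """
        assays = simulate_assay(study_preset(9, gpt), gpt)
        for assay in assays:
            truth_distinct = {
                ev.identity for c in assay.colonies for ev in c.events
            }
            assert len(independent_events(assay.colonies)) == len(truth_distinct)


class TestParameterRecovery:
    def test_pooled_class_proportion_within_three_se(self, gpt):
        """A 50-animal run recovers the configured class mix (binomial SE)."""
        cfg = small_config(
            77,
            groups=(
                GroupDesign(
                    group_id="big", genotype="Msh2_KO", dose_g_per_l=0.0, n_animals=50
                ),
            ),
        )
        total_rate = sum(cfg.base_rate_per_class.values())
        p_true = cfg.base_rate_per_class[GC_TO_AT] / total_rate  # 0.45
        assays = simulate_assay(cfg, gpt)
        events = [
            m.event for a in assays for m in independent_events(a.colonies)
        ]
        n = len(events)
        k = sum(1 for e in events if classify_event(e) == GC_TO_AT)
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert n > 500
        assert abs(k / n - p_true) < 3 * se

    def test_expected_independent_counts_tracks_simulation(self, gpt):
        """Mean clonally corrected counts match the analytic expectation."""
        observed = {}
        expected = {}
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = small_config(1000 + seed)
            assays = simulate_assay(cfg, gpt)
            for a in assays:
                exp = expected_independent_counts(cfg, gpt, cfg.groups[0], a.titer)
                for cat, v in exp.items():
                    expected[cat] = expected.get(cat, 0.0) + v
                for m in independent_events(a.colonies):
                    cat = classify_event(m.event)
                    observed[cat] = observed.get(cat, 0) + 1
        for cat, exp_total in expected.items():
            if exp_total < 50:
                continue
            se = math.sqrt(exp_total)  # Poisson-scale error
            assert abs(observed.get(cat, 0) - exp_total) < 3 * se, cat


class TestHotspotPower:
    def test_hotspot_called_in_majority_of_seeds(self, gpt):
        called = 0
        n_seeds = 12
        for seed in range(n_seeds):
            cfg = small_config(
                seed,
                groups=(
                    GroupDesign(
                        group_id="g", genotype="Msh2_KO", dose_g_per_l=1.5, n_animals=4
                    ),
                ),
                hotspot_multipliers={110: 80.0},
            )
            assays = simulate_assay(cfg, gpt)
            calls = call_hotspots(assays, gpt)
            if any(c.position == 110 and c.is_hotspot for c in calls):
                called += 1
        assert called > n_seeds / 2

    def test_hotspots_rare_without_multipliers(self, gpt):
        total_calls = 0
        n_seeds = 12
        for seed in range(n_seeds):
            cfg = small_config(
                seed,
                base_rate_per_class={GC_TO_AT: 2.0e-6, GC_TO_TA: 1.0e-6},
                groups=(
                    GroupDesign(
                        group_id="g", genotype="Msh2_KO", dose_g_per_l=0.0, n_animals=4
                    ),
                ),
            )
            assays = simulate_assay(cfg, gpt)
            total_calls += sum(c.is_hotspot for c in call_hotspots(assays, gpt))
        assert total_calls <= n_seeds / 4

    def test_rate_map_identities_are_normalized_and_unique(self, gpt):
        cfg = study_preset(0, gpt)
        for group in cfg.groups:
            rate_map = event_rate_map(cfg, gpt, group)
            for key, (event, rate) in rate_map.items():
                assert key == event.identity
                assert rate > 0
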