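"""Generator correctness: references, abundances, libraries, experiments."""

import itertools
import io

import numpy as np
import pandas as pd
import pytest

from mirsat import (
    AbundanceProfile,
    CompositionProfile,
    ExperimentTruth,
    MatureReference,
    SimConfig,
    build_reference,
    simulate_abundances,
    simulate_experiment,
    simulate_count_experiment,
    simulate_library,
    write_fastq,
)


class TestBuildReference:
    def test_single_entry_boundary(self):
        ref = build_reference(1, length_range=(22, 22), seed=7)
        assert len(ref) == 1 and len(ref.sequences[0]) == 22

    def test_seed_determinism(self):
        a = build_reference(100, length_range=(20, 23), seed=1)
        b = build_reference(100, length_range=(20, 23), seed=1)
        assert a == b

    def test_pairwise_separation_brute_force(self):
        """Exhaustive pairwise scan: same-length sequences differ at >= 3 sites."""
        ref = build_reference(50, length_range=(20, 23), seed=3)
        for a, b in itertools.combinations(ref.sequences, 2):
            if len(a) == len(b):
                assert sum(x != y for x, y in zip(a, b)) >= 3

    def test_impossible_separation_fails_explicitly(self):
        with pytest.raises(ValueError, match="cannot place"):
            build_reference(500, length_range=(18, 18), seed=0,
                            min_distance=12, max_tries_per_entry=20)

    def test_invalid_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_reference(5, length_range=(10, 12), seed=0)


class TestAbundances:
    def test_single_entry_gets_all_mass(self):
        ref = build_reference(1, seed=1)
        prof = simulate_abundances(ref, seed=2)
        assert prof.weights[ref.ids[0]] == pytest.approx(1.0)

    def test_seed_determinism(self, small_ref):
        a = simulate_abundances(small_ref, seed=9)
        b = simulate_abundances(small_ref, seed=9)
        assert a.weights == b.weights

    def test_long_tail_property(self):
        """Top 10 miRNAs carry most of the mass; >=20% sit below 1/(10n)."""
        ref = build_reference(300, seed=42)
        prof = simulate_abundances(ref, seed=43)
        w = np.sort(np.array(list(prof.weights.values())))[::-1]
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert w[:10].sum() > 0.5
        assert (w < 1 / (10 * 300)).mean() >= 0.20

    def test_empty_reference_fails(self):
        with pytest.raises(ValueError):
            simulate_abundances(MatureReference((), ()), seed=0)

    def test_bad_shape_fails(self, small_ref):
        with pytest.raises(ValueError):
            simulate_abundances(small_ref, shape=0.0)


class TestCompositionProfile:
    def test_fractions_sum_to_one(self):
        for comp in (CompositionProfile.muscle_like(), CompositionProfile.plasma_like()):
            assert sum(comp.as_tuple()) == pytest.approx(1.0, abs=1e-9)

    def test_postclip_targets(self):
        muscle = CompositionProfile.muscle_like().postclip_fractions()
        assert muscle["mirna"] == pytest.approx(0.68)
        assert muscle["ncrna"] == pytest.approx(0.07)
        assert muscle["repeat"] == pytest.approx(0.03)
        plasma = CompositionProfile.plasma_like().postclip_fractions()
        assert plasma["mirna"] == pytest.approx(0.21)
        assert plasma["ncrna"] == pytest.approx(0.25)
        assert plasma["repeat"] == pytest.approx(0.0021)

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            CompositionProfile(0.9, 0.2, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            CompositionProfile(-0.1, 0.5, 0.3, 0.2, 0.1)


class TestSimulateLibrary:
    def test_pure_mirna_reads_start_with_mature_sequence(self, small_ref, small_profile, small_decoys):
        comp = CompositionProfile(1.0, 0.0, 0.0, 0.0, 0.0)
        cfg = SimConfig(n_reads=500, isomir_rate=0.0, snv_rate=0.0, seed=2)
        lib = simulate_library(small_ref, small_profile, comp, cfg, decoys=small_decoys)
        by_id = dict(zip(small_ref.ids, small_ref.sequences))
        for read, (_, row) in zip(lib.reads, lib.ledger.iterrows()):
            assert read.sequence.startswith(by_id[row.source_id])

    def test_zero_reads(self, small_ref, small_profile, small_decoys):
        cfg = SimConfig(n_reads=0, seed=1)
        lib = simulate_library(small_ref, small_profile,
                               CompositionProfile.muscle_like(), cfg, decoys=small_decoys)
        assert lib.reads == [] and len(lib.ledger) == 0

    def test_category_fractions_multinomial(self, small_ref, small_profile, small_decoys):
        """Realized ledger fractions lie within 4 SE of the generator parameters."""
        comp = CompositionProfile.muscle_like()
        cfg = SimConfig(n_reads=100_000, seed=11)
        lib = simulate_library(small_ref, small_profile, comp, cfg, decoys=small_decoys)
        observed = lib.ledger.category.value_counts(normalize=True)
        for cat, f in zip(("mirna", "ncrna", "repeat", "unclassified", "adapter_dimer"),
                          comp.as_tuple()):
            se = np.sqrt(f * (1 - f) / cfg.n_reads)
            assert abs(observed.get(cat, 0.0) - f) < 4 * se, cat

    def test_ledger_conserves_read_count(self, muscle_library):
        assert len(muscle_library.ledger) == len(muscle_library.reads) == 20_000
        assert muscle_library.ledger.read_id.is_unique

    def test_seed_gives_byte_identical_output(self, small_ref, small_profile, small_decoys):
        cfg = SimConfig(n_reads=2_000, seed=13)
        outs = []
        for _ in range(2):
            lib = simulate_library(small_ref, small_profile,
                                   CompositionProfile.plasma_like(), cfg, decoys=small_decoys)
            buf = io.StringIO()
            for r in lib.reads:
                buf.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
            outs.append(buf.getvalue() + lib.ledger.to_csv(sep="\t"))
        assert outs[0] == outs[1]

    def test_adapter_dimer_reads_start_with_adapter(self, muscle_library):
        dimers = set(muscle_library.ledger.query("category == 'adapter_dimer'").read_id)
        for r in muscle_library.reads:
            if r.id in dimers:
                assert r.sequence.startswith(SimConfig(n_reads=1).adapter)

    def test_read_length_too_short_fails(self):
        with pytest.raises(ValueError, match="read_length"):
            SimConfig(n_reads=10, read_length=17)


class TestSimulateExperiment:
    def test_null_design_has_equal_expected_proportions(self, small_ref, small_profile, small_decoys):
        truth = ExperimentTruth(n_per_group=2, log2_fc={}, dispersion=0.0)
        cfg = SimConfig(n_reads=2_000, seed=3)
        exp = simulate_experiment(small_ref, small_profile, truth,
                                  CompositionProfile.muscle_like(), cfg, decoys=small_decoys)
        assert np.allclose(exp.truth_table.weight_group1, exp.truth_table.weight_group2)
        assert not exp.truth_table.is_de.any()

    def test_injected_fold_change_doubles_twice(self, small_ref, small_decoys):
        """log2FC = 2 on one miRNA yields a group count ratio near 4."""
        ref = small_ref
        flat = AbundanceProfile({m: 1 / len(ref) for m in ref.ids})
        target = ref.ids[0]
        truth = ExperimentTruth(n_per_group=3, log2_fc={target: 2.0}, dispersion=0.0)
        cfg = SimConfig(n_reads=60_000, seed=21, isomir_rate=0.0, snv_rate=0.0)
        exp = simulate_experiment(ref, flat, truth, CompositionProfile(1, 0, 0, 0, 0),
                                  cfg, decoys=small_decoys)
        counts = {"group1": 0, "group2": 0}
        for name, lib in exp.libraries.items():
            counts[exp.groups[name]] += (lib.ledger.source_id == target).sum()
        # expected proportions: w2/w1 = 4 / renorm; per-read totals equal
        w1 = exp.truth_table.set_index("miRNA").weight_group1[target]
        w2 = exp.truth_table.set_index("miRNA").weight_group2[target]
        expected_ratio = w2 / w1
        assert expected_ratio == pytest.approx(4 / (1 + 3 / len(ref)), rel=1e-9)
        observed = counts["group2"] / counts["group1"]
        sd = expected_ratio * np.sqrt(1 / counts["group1"] + 1 / counts["group2"])
        assert abs(observed - expected_ratio) < 4 * sd

    def test_default_design_emits_eighteen_libraries(self, small_ref, small_profile, small_decoys):
        truth = ExperimentTruth()  # default 9 per group
        cfg = SimConfig(n_reads=200, seed=5)
        exp = simulate_experiment(small_ref, small_profile, truth,
                                  CompositionProfile.muscle_like(), cfg, decoys=small_decoys)
        assert len(exp.libraries) == 18
        assert sorted(set(exp.groups.values())) == ["group1", "group2"]

    def test_fold_change_on_absent_mirna_fails(self, small_ref, small_profile, small_decoys):
        truth = ExperimentTruth(n_per_group=2, log2_fc={"no-such-miR": 1.0})
        with pytest.raises(ValueError, match="absent"):
            simulate_experiment(small_ref, small_profile, truth,
                                CompositionProfile.muscle_like(),
                                SimConfig(n_reads=100, seed=1), decoys=small_decoys)


class TestCountExperiment:
    def test_poisson_null_matches_expectations(self, small_ref, small_profile):
        truth = ExperimentTruth(n_per_group=9, dispersion=0.0)
        table, labels = simulate_count_experiment(small_ref, small_profile, truth,
                                                  mean_mapped_reads=50_000, seed=8)
        assert table.counts.shape == (20, 18)
        assert labels.count("group1") == labels.count("group2") == 9
        w = small_profile.aligned_to(small_ref)
        observed = table.counts.sum(axis=1).to_numpy() / table.counts.values.sum()
        assert np.corrcoef(observed, w)[0, 1] > 0.999
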