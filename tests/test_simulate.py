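import numpy as np
import pytest

from gbskaryo.genome import Chromosome, GenomeModel
from gbskaryo.simulate import (
    DosageEvent,
    Genotype,
    SimulationConfig,
    SimulationConfigError,
    demo_config,
    load_config,
    read_truth,
    simulate_cohort,
    write_truth,
)


def one_chrom_genome(length=20_000_000, cen=9_000_000):
    return GenomeModel((Chromosome("1A", "A", length, cen),))


def config(genome, genotypes, seed=1, **kw):
    return SimulationConfig(genome=genome, genotypes=tuple(genotypes), seed=seed, **kw)


class TestValidation:
    def test_overlapping_events_rejected_with_name(self):
        genome = one_chrom_genome()
        events = (
            DosageEvent("1A", "arm:L", 0),
            DosageEvent("1A", "whole_chromosome", 1),
        )
        with pytest.raises(SimulationConfigError, match="bad_plant"):
            config(genome, [Genotype("ok"), Genotype("bad_plant", events)])

    def test_requires_one_event_free_genotype(self):
        genome = one_chrom_genome()
        with pytest.raises(SimulationConfigError, match="control"):
            config(genome, [Genotype("t", (DosageEvent("1A", "arm:S", 1),))])

    def test_copy_number_range(self):
        with pytest.raises(SimulationConfigError):
            DosageEvent("1A", "whole_chromosome", 5)


class TestSimulateCohort:
    def test_deterministic_given_seed(self):
        cfg = demo_config(seed=7)
        m1, _, _ = simulate_cohort(cfg)
        m2, _, _ = simulate_cohort(cfg)
        np.testing.assert_array_equal(m1.counts, m2.counts)

    def test_different_seed_differs(self):
        m1, _, _ = simulate_cohort(demo_config(seed=1))
        m2, _, _ = simulate_cohort(demo_config(seed=2))
        assert (m1.counts != m2.counts).any()

    def test_genotype_order_does_not_change_own_counts(self):
        genome = one_chrom_genome()
        a = Genotype("plantA")
        b = Genotype("plantB", (DosageEvent("1A", "arm:L", 1),))
        c = Genotype("plantC")
        m1, _, _ = simulate_cohort(config(genome, [a, b, c]))
        m2, _, _ = simulate_cohort(config(genome, [c, b, a]))
        np.testing.assert_array_equal(m1.row("plantB"), m2.row("plantB"))
        np.testing.assert_array_equal(m1.row("plantA"), m2.row("plantA"))

    def test_event_free_marked_control(self):
        genome = one_chrom_genome()
        _, sheet, _ = simulate_cohort(
            config(genome, [Genotype("ctrl"),
                            Genotype("aneu", (DosageEvent("1A", "arm:S", 1),))])
        )
        assert sheet.role_of("ctrl") == "control"
        assert sheet.role_of("aneu") == "test"

    def test_whole_chromosome_zero_with_zero_floor_is_all_zeros(self):
        genome = GenomeModel(
            (
                Chromosome("1A", "A", 20_000_000, 9_000_000),
                Chromosome("1R", "R", 20_000_000, 9_000_000),
            )
        )
        cfg = config(
            genome,
            [Genotype("ctrl"),
             Genotype("null1R", (DosageEvent("1R", "whole_chromosome", 0),))],
            cross_mapping_floor=0.0,
        )
        matrix, _, _ = simulate_cohort(cfg)
        sl = matrix.grid.chrom_slice("1R")
        assert matrix.row("null1R")[sl].sum() == 0
        assert matrix.row("null1R")[: sl.start].sum() > 0

    @pytest.mark.parametrize("copy_number", [0, 1, 2, 3, 4])
    def test_mean_structure_within_three_se(self, copy_number):
        """Empirical mean per dosage class within 3 SE of the analytic mean.

        One 250 Mb chromosome (250 bins) carries the event; density is held
        flat (sigma 0) so the analytic per-bin mean is exact.
        """
        genome = GenomeModel(
            (
                Chromosome("1A", "A", 250_000_000, 100_000_000),
                Chromosome("2A", "A", 250_000_000, 100_000_000),
            )
        )
        floor = 0.02
        dispersion = 0.05
        cfg = config(
            genome,
            [Genotype("ctrl"),
             Genotype("t", (DosageEvent("1A", "whole_chromosome", copy_number),))],
            density_sigma=0.0,
            library_size_sigma=0.0,
            dispersion=dispersion,
            cross_mapping_floor=floor,
            library_size_mean=500_000.0,
        )
        matrix, _, _ = simulate_cohort(cfg)
        sl = matrix.grid.chrom_slice("1A")
        observed = matrix.row("t")[sl]
        n = observed.size
        assert n >= 200
        mu = 500_000.0 / 500 * max(copy_number / 2, floor)
        var = mu + dispersion * mu**2
        se = np.sqrt(var / n)
        assert abs(observed.mean() - mu) < 3 * se

    def test_poisson_limit_null_cohort_log2_near_zero(self):
        """Dispersion 0, no events: cohort log2 ratios scatter tightly around 0."""
        from gbskaryo.normalize import normalize_counts

        genome = one_chrom_genome(length=100_000_000, cen=45_000_000)
        cfg = config(
            genome,
            [Genotype(f"c{i}") for i in range(4)],
            dispersion=0.0,
            library_size_mean=1_000_000.0,
        )
        matrix, sheet, _ = simulate_cohort(cfg)
        norm = normalize_counts(matrix, sheet)
        assert abs(np.nanmean(norm.log2ratio)) < 0.02


class TestTruth:
    def test_arm_events_expand_and_2n(self):
        genome = one_chrom_genome(length=20_000_000, cen=9_000_000)
        cfg = config(
            genome,
            [Genotype("ctrl"), Genotype("dt", (DosageEvent("1A", "arm:L", 0),))],
        )
        _, _, truth = simulate_cohort(cfg)
        assert truth.arm_cn["dt"][("1A", "S")] == 2
        assert truth.arm_cn["dt"][("1A", "L")] == 0
        # a ditelosomic still contributes one chromosome body pair
        assert truth.expected_2n["dt"] == 2
        assert truth.expected_2n["ctrl"] == 2

    def test_truth_round_trip(self, tmp_path):
        cfg = demo_config(seed=3)
        _, _, truth = simulate_cohort(cfg)
        ev, sm = tmp_path / "ev.tsv", tmp_path / "sm.tsv"
        write_truth(truth, cfg.genome, ev, sm)
        back = read_truth(ev, sm, cfg.genome)
        assert dict(back.expected_2n) == dict(truth.expected_2n)
        assert {k: dict(v) for k, v in back.arm_cn.items()} == {
            k: dict(v) for k, v in truth.arm_cn.items()
        }
        for name in truth.events:
            assert set(back.events[name]) == set(truth.events[name])

    def test_empty_events_still_writes_summary(self, tmp_path):
        genome = one_chrom_genome()
        cfg = config(genome, [Genotype("ctrl")])
        _, _, truth = simulate_cohort(cfg)
        ev, sm = tmp_path / "ev.tsv", tmp_path / "sm.tsv"
        write_truth(truth, genome, ev, sm)
        assert ev.read_text().count("\n") == 1  # header only
        assert "ctrl" in sm.read_text()


def test_yaml_config_round_trip(tmp_path):
    cfg_text = """
seed: 5
dispersion: 0.0
library_size_mean: 100000
genotypes:
  - name: ctrl
  - name: dt
    events:
      - {chrom: 4B, scope: "arm:L", copy_number: 0}
  - name: del
    events:
      - {chrom: 6A, scope: segment, copy_number: 1, start: 40000000, end: 44000000}
"""
    path = tmp_path / "sim.yaml"
    path.write_text(cfg_text)
    cfg = load_config(path)
    assert cfg.seed == 5
    assert cfg.dispersion == 0.0
    assert cfg.genotypes[1].events[0].scope == "arm:L"
    assert cfg.genotypes[2].events[0].start == 40_000_000
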