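"""Ground-truth and reproducibility guarantees of the simulators."""

import numpy as np
import pandas as pd
import pytest

from rloopkit import imaging3d
from rloopkit.synthetic import (
    FibreSimConfig,
    GenomicsSimConfig,
    KineticsSimConfig,
    VolumeSimConfig,
    gen_fibre_population,
    gen_gene_peak_table,
    gen_growth_plate,
    gen_locus_trace,
    gen_two_channel_volume,
)


class TestFibrePopulation:
    def test_no_stall_no_noise_gives_unit_ratios(self):
        pop = gen_fibre_population(
            FibreSimConfig(n_tracks=50, speed_sd=0.0, stall_prob=0.0, seed=1))
        ratios = pop.pairs["left_um"] / pop.pairs["right_um"]
        assert np.allclose(ratios, 1.0)
        assert (pop.pairs["stalled_arm"] == "none").all()

    def test_certain_stall_halves_one_arm(self):
        pop = gen_fibre_population(
            FibreSimConfig(n_tracks=40, speed_sd=0.0, stall_prob=1.0,
                           stall_severity=0.5, seed=2))
        longer = pop.pairs[["left_um", "right_um"]].max(axis=1)
        shorter = pop.pairs[["left_um", "right_um"]].min(axis=1)
        assert np.allclose(longer / shorter, 2.0)
        assert (pop.pairs["stalled_arm"] != "none").all()

    def test_empty_population(self):
        pop = gen_fibre_population(FibreSimConfig(n_tracks=0))
        assert len(pop.pairs) == 0 and len(pop.tracks) == 0

    def test_length_is_speed_times_pulse_over_conversion(self):
        pop = gen_fibre_population(FibreSimConfig(n_tracks=30, stall_prob=0.0, seed=3))
        expected = pop.pairs["left_speed_kb_min"] * 20.0 / 2.59
        assert np.allclose(pop.pairs["left_um"], expected)

    def test_reproducible(self):
        a = gen_fibre_population(FibreSimConfig(n_tracks=20, stall_prob=0.3, seed=7))
        b = gen_fibre_population(FibreSimConfig(n_tracks=20, stall_prob=0.3, seed=7))
        pd.testing.assert_frame_equal(a.pairs, b.pairs)
        pd.testing.assert_frame_equal(a.tracks, b.tracks)

    @pytest.mark.parametrize("bad", [
        dict(mean_speed=0), dict(stall_prob=1.5), dict(pulse_min_first=0),
        dict(n_tracks=-1), dict(stall_prob=0.5, stall_severity=1.0),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            FibreSimConfig(**bad)


class TestTwoChannelVolume:
    def test_full_colocalization_shares_voxels(self):
        cfg = VolumeSimConfig(shape=(32, 48, 48), n_objects_a=8, n_objects_b=8,
                              coloc_fraction=1.0, noise_sd=0.0, seed=5)
        sim = gen_two_channel_volume(cfg)
        shared = (sim.channel_a > 0) & (sim.channel_b > 0)
        # every B object contains at least one shared voxel
        objs_b = imaging3d.segment_objects(
            imaging3d.Volume(sim.channel_b), 0.0, min_voxels=1, channel="B")
        for obj in objs_b:
            coords = np.unravel_index(obj.voxel_indices, sim.channel_b.shape)
            assert shared[coords].any()

    def test_zero_colocalization_shares_nothing(self):
        cfg = VolumeSimConfig(shape=(32, 48, 48), n_objects_a=6, n_objects_b=6,
                              coloc_fraction=0.0, noise_sd=0.0, seed=6)
        sim = gen_two_channel_volume(cfg)
        assert not ((sim.channel_a > 0) & (sim.channel_b > 0)).any()

    def test_truth_coloc_count_binomial_across_seeds(self):
        # truth coloc count should behave like Binomial(n_b, p) over seeds
        n_b, p, n_seeds = 200, 0.4, 100
        counts = []
        for s in range(n_seeds):
            cfg = VolumeSimConfig(shape=(48, 96, 96), n_objects_a=30, n_objects_b=n_b,
                                  coloc_fraction=p, noise_sd=0.0, radius_mean=1.8,
                                  radius_sd=0.2, seed=s)
            counts.append(int(gen_two_channel_volume(cfg).truth.query(
                "channel == 'B'")["coloc"].sum()))
        counts = np.asarray(counts)
        mean_se = np.sqrt(n_b * p * (1 - p) / n_seeds)
        assert abs(counts.mean() - n_b * p) < 4 * mean_se
        binom_sd = np.sqrt(n_b * p * (1 - p))
        assert 0.7 * binom_sd < counts.std(ddof=1) < 1.3 * binom_sd

    def test_reproducible(self):
        cfg = VolumeSimConfig(shape=(24, 32, 32), n_objects_a=4, n_objects_b=4, seed=9)
        a, b = gen_two_channel_volume(cfg), gen_two_channel_volume(cfg)
        assert np.array_equal(a.channel_a, b.channel_a)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            VolumeSimConfig(coloc_fraction=1.2)
        with pytest.raises(ValueError):
            VolumeSimConfig(shape=(0, 10, 10))


class TestLocusTrace:
    def test_no_resolution_latent_nondecreasing(self):
        cfg = KineticsSimConfig(resolution_rate=0.0, reporter_noise_sd=0.0,
                                normalizer_noise_sd=0.0, seed=1)
        sim = gen_locus_trace(cfg)
        assert (np.diff(sim.latent_n) >= 0).all()

    def test_no_formation_latent_decays_to_zero(self):
        cfg = KineticsSimConfig(formation_rate=0.0, n0=100,
                                resolution_rate=0.05, seed=2)
        sim = gen_locus_trace(cfg)
        assert (np.diff(sim.latent_n) <= 0).all()
        assert sim.latent_n[-1] == 0

    def test_latent_path_integer_nonnegative(self):
        for seed in range(5):
            sim = gen_locus_trace(KineticsSimConfig(seed=seed))
            assert sim.latent_n.dtype.kind == "i"
            assert (sim.latent_n >= 0).all()

    def test_stationary_mean_matches_immigration_death_oracle(self):
        # M/M/infinity stationary mean is formation/resolution
        lam, mu = 0.6, 0.02
        means = []
        for seed in range(30):
            cfg = KineticsSimConfig(formation_rate=lam, resolution_rate=mu,
                                    n0=int(lam / mu), duration_min=3000, seed=seed)
            sim = gen_locus_trace(cfg)
            means.append(sim.latent_n[len(sim.latent_n) // 2:].mean())
        mc_se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - lam / mu) < 4 * max(mc_se, 1e-9)

    def test_frame_count_and_spacing(self):
        sim = gen_locus_trace(KineticsSimConfig(seed=0))
        assert len(sim.trace) == 251  # 1500 min at 6-min intervals, inclusive
        assert np.allclose(np.diff(sim.trace["t_min"]), 6.0)

    def test_reporter_floored_positive(self):
        cfg = KineticsSimConfig(formation_rate=0.0, n0=0, reporter_noise_sd=3.0, seed=3)
        sim = gen_locus_trace(cfg)
        assert (sim.trace["reporter"] > 0).all()


class TestGenePeakTable:
    def test_confounder_only_partial_correlation_vanishes(self):
        from rloopkit.genomics import pairwise_correlation, partial_correlation
        sim = gen_gene_peak_table(GenomicsSimConfig(
            n_genes=4000, direct_association=0.0, seed=4))
        g = sim.genes
        pw = pairwise_correlation(g["ino80_count"], g["drip_count"], method="pearson")
        pc = partial_correlation(g["ino80_count"], g["drip_count"], g["expression"])
        assert pw.r > 0.3 and pw.p < 1e-10
        assert abs(pc.r) < 0.06

    def test_no_confounder_pairwise_equals_partial(self):
        from rloopkit.genomics import pairwise_correlation, partial_correlation
        sim = gen_gene_peak_table(GenomicsSimConfig(
            n_genes=3000, expression_effect=0.0, direct_association=0.8, seed=5))
        g = sim.genes
        pw = pairwise_correlation(g["ino80_count"], g["drip_count"], method="pearson")
        pc = partial_correlation(g["ino80_count"], g["drip_count"], g["expression"])
        assert pc.r == pytest.approx(pw.r, abs=0.03)

    def test_segmentation_partitions_toy_genome(self):
        sim = gen_gene_peak_table(GenomicsSimConfig(n_genes=100, seed=6))
        st = sim.states.sort_values("start")
        assert (st["end"].to_numpy()[:-1] == st["start"].to_numpy()[1:]).all()
        assert st["start"].iloc[0] == 0
        assert st["state"].nunique() == 20

    def test_peak_counts_match_gene_table(self):
        from rloopkit.genomics import count_peaks_per_gene
        sim = gen_gene_peak_table(GenomicsSimConfig(n_genes=200, seed=7))
        counted = count_peaks_per_gene(sim.peaks_a, sim.genes)
        assert (counted.to_numpy() == sim.genes["ino80_count"].to_numpy()).all()

    def test_peaks_are_200bp(self):
        sim = gen_gene_peak_table(GenomicsSimConfig(n_genes=50, seed=8))
        assert ((sim.peaks_a["end"] - sim.peaks_a["start"]) == 200).all()


class TestGrowthPlate:
    def test_null_interaction_no_noise_exact(self):
        plate = gen_growth_plate(0.5, 0.8, interaction=1.0, noise_sd=0.0, seed=0)
        combined = plate.query("condition == 'combined'")["growth_frac"]
        assert np.allclose(combined, 0.5 * 0.8)

    def test_interaction_scales_combined_growth(self):
        plate = gen_growth_plate(0.2, 0.9, interaction=4.0, noise_sd=0.0, seed=0)
        combined = plate.query("condition == 'combined'")["growth_frac"].mean()
        assert combined == pytest.approx(0.2 * 0.9 * 4.0)

    def test_well_noise_matches_requested_sd(self):
        sds = []
        for seed in range(200):
            plate = gen_growth_plate(0.4, 0.9, noise_sd=0.05, n_wells=8, seed=seed)
            sds.append(plate.query("condition == 'combined'")["growth_frac"].std(ddof=1))
        assert np.mean(sds) == pytest.approx(0.05, rel=0.15)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gen_growth_plate(0.0, 0.5)
        with pytest.raises(ValueError):
            gen_growth_plate(0.5, 0.5, n_wells=0)
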