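"""The synthetic-study generator: determinism, planted structure, round-trips."""

import numpy as np
import pandas as pd
import pytest

import chromdyn as cd
from chromdyn.motifs import scan_sequences
from chromdyn.simulate import (
    ARCHETYPE_MULTIPLIERS,
    ExpressionConfig,
    MotifConfig,
    ScreenConfig,
    SimulationConfig,
    expected_condition_z,
    simulate_accessibility,
    simulate_all,
    simulate_expression,
    simulate_genes,
    simulate_screen,
    simulate_sequences,
    write_study,
)


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_cfg):
        a = simulate_all(small_cfg)
        b = simulate_all(small_cfg)
        pd.testing.assert_frame_equal(a.counts.values, b.counts.values)
        pd.testing.assert_frame_equal(a.screen.counts, b.screen.counts)
        assert a.sequences == b.sequences
        assert a.truth.peak_group == b.truth.peak_group

    def test_different_seeds_differ(self, small_cfg):
        import dataclasses

        other = dataclasses.replace(small_cfg, seed=small_cfg.seed + 1)
        a, b = simulate_all(small_cfg), simulate_all(other)
        assert not a.counts.values.equals(b.counts.values)


class TestAccessibility:
    def test_archetype_mean_ratio_matches_multipliers(self):
        cfg = SimulationConfig(seed=3, depth_jitter_sdlog=0.0)
        _, counts, truth = simulate_accessibility(cfg)
        means = counts.condition_means()
        for group, (v, e, l) in ARCHETYPE_MULTIPLIERS.items():
            peaks = [p for p, g in truth.peak_group.items() if g == group]
            ratio = means.loc[peaks, "early"].sum() / means.loc[peaks, "invitro"].sum()
            assert ratio == pytest.approx(e / v, rel=0.15)

    def test_poisson_limit_totals_match_depth(self):
        cfg = SimulationConfig(seed=4, nb_dispersion=0.0, depth_jitter_sdlog=0.0)
        _, counts, _ = simulate_accessibility(cfg)
        np.testing.assert_allclose(counts.totals.values, cfg.depth, rtol=0.05)

    def test_static_peaks_have_unit_multiplier(self):
        cfg = SimulationConfig(seed=5, depth_jitter_sdlog=0.0)
        _, counts, truth = simulate_accessibility(cfg)
        means = counts.condition_means()
        static = [p for p, g in truth.peak_group.items() if g == "static"]
        ratio = means.loc[static, "early"].sum() / means.loc[static, "invitro"].sum()
        assert ratio == pytest.approx(1.0, rel=0.05)

    def test_truth_partitions_every_peak(self, small_study):
        assert set(small_study.truth.peak_group) == {iv.id for iv in small_study.universe}
        assert set(small_study.truth.peak_archetype) == set(small_study.truth.peak_group)


class TestExpression:
    def test_tpm_columns_sum_to_one_million(self, small_study):
        np.testing.assert_allclose(
            small_study.expression.values.sum(axis=0), 1e6, atol=1e-3
        )

    def test_perfect_concordance_recovers_trajectory(self):
        cfg = SimulationConfig(
            seed=6,
            peaks_per_archetype=30,
            n_static_peaks=30,
            expression=ExpressionConfig(concordance=1.0, noise_sd=0.0, replicate_sd=0.0),
        )
        universe, counts, truth = simulate_accessibility(cfg)
        genes = simulate_genes(cfg, universe, truth)
        expr = simulate_expression(cfg, truth, genes)
        cond = np.log2(expr.condition_means())
        for gid, group in list(truth.gene_group.items())[:50]:
            prof = cond.loc[gid].values
            traj = truth.group_ztraj[group]
            r = np.corrcoef(prof, traj)[0, 1]
            # per-condition TPM renormalization perturbs the profile slightly
            assert r > 0.98

    def test_zero_concordance_decouples_expression(self):
        cfg = SimulationConfig(
            seed=7,
            peaks_per_archetype=150,
            n_static_peaks=50,
            expression=ExpressionConfig(concordance=0.0, noise_sd=0.3),
        )
        universe, counts, truth = simulate_accessibility(cfg)
        genes = simulate_genes(cfg, universe, truth)
        expr = simulate_expression(cfg, truth, genes)
        cond = np.log2(expr.condition_means())
        rs = []
        for gid, group in truth.gene_group.items():
            prof = cond.loc[gid].values
            if prof.std(ddof=1) == 0:
                continue
            traj = truth.group_ztraj[group]
            rs.append(np.corrcoef(prof, traj)[0, 1])
        rs = np.asarray(rs)
        # independent 3-point profiles: r = cos(uniform angle), E|r| = 2/pi,
        # E r = 0 — decoupled expression should sit at that baseline
        assert abs(np.mean(np.abs(rs)) - 2 / np.pi) < 0.06
        assert abs(np.mean(rs)) < 0.1


class TestSequences:
    def test_full_plant_rate_always_detected(self):
        cfg = SimulationConfig(
            seed=8,
            peaks_per_archetype=15,
            n_static_peaks=10,
            motif=MotifConfig(plant_rate=1.0, background_rate=0.0),
        )
        universe, counts, truth = simulate_accessibility(cfg)
        seqs, pfms = simulate_sequences(cfg, universe, truth)
        for motif_id, counts_mat in pfms.items():
            group = truth.motif_group[motif_id]
            own = [p for p, g in truth.peak_group.items() if g == group]
            pwm = cd.MotifPWM.from_counts(motif_id, counts_mat)
            hits = scan_sequences({p: seqs[p] for p in own}, pwm, rel_threshold=0.8)
            assert hits["hit"].all()

    def test_zero_plant_rate_no_flags(self):
        cfg = SimulationConfig(
            seed=9,
            peaks_per_archetype=10,
            n_static_peaks=5,
            motif=MotifConfig(plant_rate=0.0, background_rate=0.0),
        )
        universe, counts, truth = simulate_accessibility(cfg)
        seqs, _ = simulate_sequences(cfg, universe, truth)
        assert all(len(v) == 0 for v in truth.region_motifs.values())

    def test_sequence_lengths_match_regions(self, small_study):
        for iv in small_study.universe:
            assert len(small_study.sequences[iv.id]) == len(iv)


class TestScreen:
    def test_null_screen_lfc_centered(self):
        cfg = SimulationConfig(
            seed=10,
            screen=ScreenConfig(
                n_invivo_specific=0, n_invitro_specific=0, n_common=0,
                positive_control_lfc=0.0,
            ),
        )
        table, truth = simulate_screen(cfg)
        gene, _ = cd.gene_lfc(table, "invivo_final")
        targets = truth.index[truth["role"] == "target"]
        assert gene.loc[targets].abs().mean() < 0.15

    def test_library_composition(self, default_study):
        guides = default_study.screen.guides
        assert (guides["role"] == "target").sum() == 78 * 4
        assert (guides["role"] == "positive_control").sum() == 11 * 4
        assert (guides["role"] == "nontargeting").sum() == 25

    def test_planted_effects_recorded(self, default_study):
        truth = default_study.truth.screen_genes
        t = truth[truth["role"] == "target"]
        assert ((t["lfc_invivo"] < 0) & (t["lfc_invitro"] == 0)).sum() == 8
        assert ((t["lfc_invitro"] < 0) & (t["lfc_invivo"] == 0)).sum() == 3
        assert ((t["lfc_invitro"] < 0) & (t["lfc_invivo"] < 0)).sum() == 6


class TestRoundTrip:
    def test_emitted_files_parse_with_package_readers(self, tmp_path, small_study):
        paths = write_study(small_study, tmp_path)
        genome = cd.read_genome(paths["genome"])
        assert genome == small_study.config.genome
        universe = cd.read_bed(paths["universe"], dialect="bed6", genome=genome)
        assert [(iv.chrom, iv.start, iv.end, iv.id) for iv in universe] == [
            (iv.chrom, iv.start, iv.end, iv.id) for iv in small_study.universe
        ]
        counts = cd.SampleMatrix.read(paths["counts"], paths["sample_metadata"])
        pd.testing.assert_frame_equal(
            counts.values, small_study.counts.values, check_dtype=False
        )
        genes = cd.read_gene_models(paths["gene_models"])
        assert len(genes) == len(small_study.genes)
        sets = cd.read_gmt(paths["gene_sets"])
        assert sets == small_study.truth.gene_sets
        seqs = cd.read_fasta(paths["sequences"])
        assert seqs == small_study.sequences
        pwms = cd.read_jaspar(paths["pfms"])
        assert {p.motif_id for p in pwms} == set(small_study.pfms)
        screen = cd.read_screen_table(paths["screen_counts"], paths["screen_metadata"])
        pd.testing.assert_frame_equal(screen.counts, small_study.screen.counts)

    def test_ground_truth_json_written(self, tmp_path, small_study):
        import json

        paths = write_study(small_study, tmp_path)
        with open(paths["truth"]) as fh:
            payload = json.load(fh)
        assert payload["peak_group"] == small_study.truth.peak_group
        assert len(payload["screen_genes"]) == len(small_study.truth.screen_genes)


class TestExpectedConditionZ:
    def test_weighted_z_profile(self):
        reps = {"invitro": 3, "early": 3, "late": 5}
        prof = expected_condition_z((1.0, 4.0, 1.0), reps)
        vals = np.repeat([1.0, 4.0, 1.0], [3, 3, 5])
        z = (vals - vals.mean()) / vals.std(ddof=1)
        assert prof["invitro"] == pytest.approx(z[0])
        assert prof["early"] == pytest.approx(z[3])

    def test_archetype_labels_cover_gains_and_losses(self):
        reps = {"invitro": 3, "early": 3, "late": 5}
        labels = {
            g: cd.annotate_archetype(expected_condition_z(m, reps))
            for g, m in ARCHETYPE_MULTIPLIERS.items()
        }
        assert labels["early_gain"] == "early_gain"
        assert labels["pan_gain_a"] == labels["pan_gain_b"] == "pan_gain"
        assert labels["late_gain"] == "late_gain"
        assert labels["early_loss"] == "early_loss"
        assert labels["pan_loss_a"] == labels["pan_loss_b"] == "pan_loss"
        assert labels["late_loss"] == "late_loss"
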