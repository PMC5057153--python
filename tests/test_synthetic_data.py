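"""The generator's contracts: determinism, ground-truth consistency, and the
constructed signal structure (pause peak, initiation vs elongation effects)."""

import numpy as np
import pandas as pd
import pytest

from polpause.quantify import metagene_profile, region_occupancy
from polpause.synthetic_data import (SimulationConfig, simulate_annotation,
                                     simulate_design, simulate_experiment,
                                     simulate_polii_coverage, simulate_rna_counts,
                                     write_dataset)


def _noise_free(seed=0, **kw):
    defaults = dict(seed=seed, n_genes=40, noise_dispersion=0.0,
                    rna_library_jitter=0.0, gene_length_range=(1200, 2400))
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(seed=123, n_genes=25)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(simulate_experiment(cfg), d1)
        write_dataset(simulate_experiment(cfg), d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_experiment(SimulationConfig(seed=1, n_genes=25))
        b = simulate_experiment(SimulationConfig(seed=2, n_genes=25))
        assert not a.rna_counts.equals(b.rna_counts)


class TestAnnotation:
    def test_genes_do_not_overlap(self, small_exp):
        by_chrom = {}
        for g in small_exp.genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for ivals in by_chrom.values():
            ivals.sort()
            assert all(e1 <= s2 for (_, e1), (s2, _) in zip(ivals, ivals[1:]))

    def test_labels_cover_every_gene(self, small_exp):
        assert set(small_exp.truth.archetype) == {g.gene_id for g in small_exp.genes}

    def test_zero_are_fraction_means_no_pentamer(self):
        cfg = SimulationConfig(seed=3, n_genes=40, are_fraction=0.0)
        _, seqs, truth = simulate_annotation(cfg)
        for gid, has in truth.are_status.items():
            assert not has and "ATTTA" not in seqs[gid]

    def test_single_designated_extreme_responder(self, small_exp):
        truth = small_exp.truth
        ups = truth.genes_of_archetype("elongation_up")
        assert truth.aqp2_like in ups
        effects = truth.elongation_effect_log2
        assert effects[truth.aqp2_like] == small_exp.config.aqp2_like_effect_log2
        assert all(effects[g] < effects[truth.aqp2_like] for g in ups
                   if g != truth.aqp2_like)

    def test_genome_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_annotation(SimulationConfig(seed=0, n_genes=40, n_chroms=1,
                                                 chrom_length=10_000))

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(archetype_fractions={"initiation_only": 0.5,
                                                  "elongation_up": 0.1,
                                                  "elongation_down": 0.1,
                                                  "unresponsive": 0.1})


class TestCoverage:
    def test_noise_free_unresponsive_gene_equal_and_peaked(self):
        cfg = _noise_free(archetype_fractions={"unresponsive": 1.0,
                                               "initiation_only": 0.0,
                                               "elongation_up": 0.0,
                                               "elongation_down": 0.0})
        genes, _, truth = simulate_annotation(cfg)
        tracks = simulate_polii_coverage(genes, truth, cfg)
        g = genes[0]
        veh = region_occupancy(tracks["chip_vehicle_1"], g, cfg.ppr_len)
        dda = region_occupancy(tracks["chip_ddavp_1"], g, cfg.ppr_len)
        assert veh == dda
        ppr_depth = veh.ppr / cfg.ppr_len
        body_depth = veh.beyond / (g.length - cfg.ppr_len)
        assert ppr_depth / body_depth == pytest.approx(cfg.pause_peak_height)

    def test_initiation_gene_changes_only_in_ppr(self):
        cfg = _noise_free(archetype_fractions={"unresponsive": 0.0,
                                               "initiation_only": 1.0,
                                               "elongation_up": 0.0,
                                               "elongation_down": 0.0})
        genes, _, truth = simulate_annotation(cfg)
        tracks = simulate_polii_coverage(genes, truth, cfg)
        for g in genes[:10]:
            veh = region_occupancy(tracks["chip_vehicle_1"], g, cfg.ppr_len)
            dda = region_occupancy(tracks["chip_ddavp_1"], g, cfg.ppr_len)
            assert dda.beyond == pytest.approx(veh.beyond)
            assert dda.ppr > veh.ppr

    def test_elongation_effect_scales_beyond_ppr_depth(self):
        """A +2 log2 elongation effect quadruples beyond-PPR depth, within
        sampling error across seeds."""
        ratios = []
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, n_genes=30, noise_dispersion=0.02,
                                   gene_length_range=(1200, 2400),
                                   elongation_effect_range_log2=(2.0, 2.0),
                                   aqp2_like_effect_log2=2.0,
                                   archetype_fractions={"unresponsive": 0.5,
                                                        "initiation_only": 0.0,
                                                        "elongation_up": 0.5,
                                                        "elongation_down": 0.0})
            genes, _, truth = simulate_annotation(cfg)
            tracks = simulate_polii_coverage(genes, truth, cfg)
            for gid in truth.genes_of_archetype("elongation_up"):
                g = next(x for x in genes if x.gene_id == gid)
                veh = region_occupancy(tracks["chip_vehicle_1"], g, cfg.ppr_len)
                dda = region_occupancy(tracks["chip_ddavp_1"], g, cfg.ppr_len)
                ratios.append(dda.beyond / veh.beyond)
        assert np.mean(ratios) == pytest.approx(4.0, rel=0.05)

    def test_metagene_increase_confined_to_five_prime_bins(self):
        """With the dominant initiation-only response, the dDAVP metagene
        exceeds vehicle only in the 5'-most body bins."""
        cfg = SimulationConfig(seed=9, n_genes=60, gene_length_range=(1200, 2400),
                               archetype_fractions={"unresponsive": 0.3,
                                                    "initiation_only": 0.7,
                                                    "elongation_up": 0.0,
                                                    "elongation_down": 0.0})
        genes, _, truth = simulate_annotation(cfg)
        tracks = simulate_polii_coverage(genes, truth, cfg)
        cond_tracks = {"vehicle": [tracks[f"chip_vehicle_{i}"] for i in (1, 2, 3)],
                       "ddavp": [tracks[f"chip_ddavp_{i}"] for i in (1, 2, 3)]}
        prof = metagene_profile(cond_tracks, genes, body_bins=50, normalize=False)
        body_v = prof.profiles["vehicle"][prof.body_slice]
        body_d = prof.profiles["ddavp"][prof.body_slice]
        # the PPR covers at most the first third of the shortest gene
        assert body_d[:5].sum() > 1.1 * body_v[:5].sum()
        tail_ratio = body_d[25:].sum() / body_v[25:].sum()
        assert tail_ratio == pytest.approx(1.0, abs=0.05)


class TestRNACounts:
    def test_noise_free_unresponsive_ratio_is_one(self):
        cfg = _noise_free(archetype_fractions={"unresponsive": 1.0,
                                               "initiation_only": 0.0,
                                               "elongation_up": 0.0,
                                               "elongation_down": 0.0})
        genes, _, truth = simulate_annotation(cfg)
        counts = simulate_rna_counts(genes, truth, cfg)
        veh = counts[[c for c in counts if c.startswith("rna_vehicle")]].mean(axis=1)
        dda = counts[[c for c in counts if c.startswith("rna_ddavp")]].mean(axis=1)
        assert np.allclose(dda / veh, 1.0)

    def test_extreme_responder_effect_recovered(self):
        """Measured mean log2 ratio of the designated gene stays within +-0.5
        of the configured +4.5 at default noise, across seeds."""
        errs = []
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, n_genes=60,
                                   gene_length_range=(1200, 2400))
            genes, _, truth = simulate_annotation(cfg)
            counts = simulate_rna_counts(genes, truth, cfg)
            row = counts.loc[truth.aqp2_like]
            veh = row[[c for c in counts if c.startswith("rna_vehicle")]].mean()
            dda = row[[c for c in counts if c.startswith("rna_ddavp")]].mean()
            errs.append(np.log2(dda / veh) - 4.5)
        assert max(abs(e) for e in errs) < 0.5

    def test_column_sums_track_library_factors(self):
        factors = [1.0] * 9 + [0.5] * 4 + [2.0] * 5
        cfg = _noise_free(rna_library_factors=factors,
                          archetype_fractions={"unresponsive": 1.0,
                                               "initiation_only": 0.0,
                                               "elongation_up": 0.0,
                                               "elongation_down": 0.0})
        genes, _, truth = simulate_annotation(cfg)
        counts = simulate_rna_counts(genes, truth, cfg)
        sums = counts.sum(axis=0).values
        assert np.allclose(sums / sums[0], factors)

    def test_design_matches_study_layout(self):
        design = simulate_design(SimulationConfig())
        assert len(design.samples("rna", "vehicle")) == 9
        assert len(design.samples("rna", "ddavp")) == 9
        assert len(design.chip_pairs()) == 3
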