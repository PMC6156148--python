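"""Synthetic-data generators: determinism, placement, planted-parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from airechrom import genomic_signal as gs
from airechrom import synthetic as syn


def small_config(**kw):
    defaults = dict(n_genes=60, chrom_lengths={"chr1": 3_000_000}, seed=7)
    defaults.update(kw)
    return syn.SimulationConfig(**defaults)


def one_mark_config(effect: float, **kw):
    """Single mark with a planted shift in AIRE_DEPENDENT genes only."""
    return small_config(
        mark_effects={"H3K27me3": {"AIRE_DEPENDENT": effect}}, **kw)


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(syn.ConfigError, match="sum to 1"):
            small_config(category_proportions={
                "AIRE_DEPENDENT": 0.5, "AIRE_ENHANCED": 0.2,
                "AIRE_INDEPENDENT_TRA": 0.2, "OTHER": 0.2})

    def test_unknown_effect_category_rejected(self):
        with pytest.raises(syn.ConfigError, match="unknown"):
            small_config(mark_effects={"H3K27me3": {"NOT_A_CATEGORY": 1.0}})

    def test_nonpositive_chromosome_rejected(self):
        with pytest.raises(syn.ConfigError):
            small_config(chrom_lengths={"chr1": 0})


class TestGenerateTruth:
    def test_each_gene_appears_exactly_once(self):
        truth = syn.generate_truth(small_config())
        assert truth.table.index.is_unique and len(truth.table) == 60

    def test_exact_category_counts(self):
        cfg = small_config(n_genes=100)
        truth = syn.generate_truth(cfg)
        counts = truth.table["category"].value_counts()
        assert counts["AIRE_DEPENDENT"] == 8
        assert counts["AIRE_ENHANCED"] == 12
        assert counts["AIRE_INDEPENDENT_TRA"] == 30
        assert counts["OTHER"] == 50


class TestGenerateAnnotation:
    def test_same_seed_identical_annotation(self):
        cfg = small_config()
        a = syn.generate_annotation(cfg)
        b = syn.generate_annotation(cfg)
        assert a.tss == b.tss and a.gene_bodies == b.gene_bodies

    def test_bounds_on_single_chromosome(self):
        cfg = small_config(n_genes=10, chrom_lengths={"chr1": 10_000_000})
        ann = syn.generate_annotation(cfg)
        assert len(ann.tss) == 10
        for sites in ann.tss.values():
            for chrom, pos, strand in sites:
                assert chrom == "chr1" and 0 <= pos < 10_000_000

    def test_pairwise_spacing_exceeds_twice_window(self):
        cfg = small_config(n_genes=40, n_transcripts_per_gene=1.0)
        ann = syn.generate_annotation(cfg)
        positions = sorted(p for sites in ann.tss.values()
                           for _, p, _ in sites)
        # brute-force pairwise scan over all TSSs of distinct genes
        dmin = min(b - a for a, b in zip(positions, positions[1:]))
        assert dmin >= 2 * cfg.feature_window_bp

    def test_genome_too_small_raises_sizing_error(self):
        with pytest.raises(syn.SizingError):
            syn.generate_annotation(
                small_config(n_genes=500, chrom_lengths={"chr1": 100_000}))

    def test_every_gene_has_at_least_one_transcript(self):
        ann = syn.generate_annotation(small_config(n_transcripts_per_gene=2.5))
        assert all(len(sites) >= 1 for sites in ann.tss.values())


def ratio_tracks(tracks, pseudocount=0.5):
    return {mark: gs.chip_input_ratio(gs.scale_to_library(pair["chip"]),
                                      gs.scale_to_library(pair["input"]),
                                      pseudocount)
            for mark, pair in tracks.items()}


class TestSimulateChipTracks:
    def test_same_seed_identical_tracks(self):
        cfg = one_mark_config(1.0)
        truth = syn.generate_truth(cfg)
        ann = syn.generate_annotation(cfg)
        t1 = syn.simulate_chip_tracks(ann, truth, cfg)
        t2 = syn.simulate_chip_tracks(ann, truth, cfg)
        assert t1["H3K27me3"]["chip"] == t2["H3K27me3"]["chip"]
        assert t1["H3K27me3"]["input"] == t2["H3K27me3"]["input"]

    def test_noiseless_single_gene_ratio_is_exp_shift(self):
        cfg = one_mark_config(1.2, n_genes=1, noise_sd=0.0, track_noise_sd=0.0,
                              category_proportions={"AIRE_DEPENDENT": 1.0,
                                                    "AIRE_ENHANCED": 0.0,
                                                    "AIRE_INDEPENDENT_TRA": 0.0,
                                                    "OTHER": 0.0})
        truth = syn.generate_truth(cfg)
        ann = syn.generate_annotation(cfg)
        tracks = syn.simulate_chip_tracks(ann, truth, cfg)
        chrom, pos, _ = ann.tss["g00000"][0]
        chip = gs.scale_to_library(tracks["H3K27me3"]["chip"])
        inp = gs.scale_to_library(tracks["H3K27me3"]["input"])
        ratio = chip.value_at(chrom, pos) / inp.value_at(chrom, pos)
        assert ratio == pytest.approx(np.exp(1.2), rel=1e-12)

    def test_zero_effects_leave_categories_indistinguishable(self):
        cfg = small_config(
            n_genes=400,
            chrom_lengths={"chr1": 10_000_000},
            mark_effects={"H3K27me3": {}},
            category_proportions={"AIRE_DEPENDENT": 0.5, "AIRE_ENHANCED": 0.0,
                                  "AIRE_INDEPENDENT_TRA": 0.0, "OTHER": 0.5})
        truth = syn.generate_truth(cfg)
        ann = syn.generate_annotation(cfg)
        tracks = syn.simulate_chip_tracks(ann, truth, cfg)
        fm = gs.build_feature_matrix(ratio_tracks(tracks), ann, truth.categories)
        x = np.log(fm.values.loc[truth.genes_in("AIRE_DEPENDENT"), "H3K27me3"])
        y = np.log(fm.values.loc[truth.genes_in("OTHER"), "H3K27me3"])
        assert stats.ttest_ind(x, y).pvalue > 0.01

    def test_planted_shift_recovered_at_scale(self):
        """+1.0 log-shift for H3K27me3 in AIRE_DEPENDENT recovers 1.0 +/- 0.1
        as the mean log feature difference vs OTHER at 2,000 genes."""
        cfg = one_mark_config(
            1.0, n_genes=2000,
            chrom_lengths={"chr1": 30_000_000, "chr2": 20_000_000},
            category_proportions={"AIRE_DEPENDENT": 0.5, "AIRE_ENHANCED": 0.0,
                                  "AIRE_INDEPENDENT_TRA": 0.0, "OTHER": 0.5})
        truth = syn.generate_truth(cfg)
        ann = syn.generate_annotation(cfg)
        tracks = syn.simulate_chip_tracks(ann, truth, cfg)
        fm = gs.build_feature_matrix(ratio_tracks(tracks, pseudocount=1e-6),
                                     ann, truth.categories)
        logf = np.log(fm.values["H3K27me3"])
        diff = (logf[truth.genes_in("AIRE_DEPENDENT")].mean()
                - logf[truth.genes_in("OTHER")].mean())
        assert diff == pytest.approx(1.0, abs=0.1)

    def test_metagene_bump_peaks_at_tss(self):
        cfg = one_mark_config(
            1.5, n_genes=80, chrom_lengths={"chr1": 5_000_000},
            category_proportions={"AIRE_DEPENDENT": 0.5, "AIRE_ENHANCED": 0.0,
                                  "AIRE_INDEPENDENT_TRA": 0.0, "OTHER": 0.5})
        truth = syn.generate_truth(cfg)
        ann = syn.generate_annotation(cfg)
        tracks = syn.simulate_chip_tracks(ann, truth, cfg)
        prof = gs.metagene_profile(ratio_tracks(tracks)["H3K27me3"], ann,
                                   truth.categories, window_bp=5000, bin_bp=50)
        dep = prof.medians["AIRE_DEPENDENT"]
        assert abs(dep.idxmax()) <= 50  # maximum in a bin touching the TSS


class TestSimulateExpressionAtlas:
    def test_requires_two_tissues(self):
        cfg = small_config(n_tissues=1)
        truth = syn.generate_truth(cfg)
        with pytest.raises(syn.ConfigError, match="n_tissues"):
            syn.simulate_expression_atlas(truth, cfg)

    def test_values_nonnegative_and_deterministic(self):
        cfg = small_config()
        truth = syn.generate_truth(cfg)
        a = syn.simulate_expression_atlas(truth, cfg)
        b = syn.simulate_expression_atlas(truth, cfg)
        assert (a.to_numpy() >= 0).all()
        assert a.equals(b)

    def test_tra_categories_reach_target_tau(self):
        from airechrom.specificity import tau_table
        cfg = small_config(n_genes=1000, chrom_lengths={"chr1": 40_000_000})
        truth = syn.generate_truth(cfg)
        atlas = syn.simulate_expression_atlas(truth, cfg)
        taus = tau_table(atlas)["tau"]
        tra_like = truth.table["category"] != "OTHER"
        assert (taus[tra_like] >= 0.8).mean() >= 0.9
        assert (taus[~tra_like] < 0.5).all()


class TestSimulateSingleCell:
    def test_zero_proportion_never_detected(self):
        cfg = small_config(n_genes=5)
        truth = syn.generate_truth(cfg)
        truth.table["true_detection"] = 0.0
        cells = syn.simulate_single_cell(truth, cfg)
        assert (cells.counts.loc[cells.gene_rows] == 0).all().all()

    def test_binomial_detection_fraction(self):
        cfg = small_config(n_genes=5, n_cells=1000)
        truth = syn.generate_truth(cfg)
        truth.table["true_detection"] = 0.5
        cells = syn.simulate_single_cell(truth, cfg)
        frac = (cells.counts.loc[cells.gene_rows] > 0).mean(axis=1)
        assert np.allclose(frac, 0.5, atol=0.05)

    def test_identical_seeds_identical_matrices(self):
        cfg = small_config()
        truth = syn.generate_truth(cfg)
        a = syn.simulate_single_cell(truth, cfg)
        b = syn.simulate_single_cell(truth, cfg)
        assert a.counts.equals(b.counts)
        assert a.spikein_molecules.equals(b.spikein_molecules)

    def test_invalid_proportion_rejected(self):
        cfg = small_config(n_genes=3)
        truth = syn.generate_truth(cfg)
        truth.table["true_detection"] = 1.5
        with pytest.raises(syn.ConfigError):
            syn.simulate_single_cell(truth, cfg)

    def test_spikein_counts_track_molecules(self):
        cfg = small_config(n_cells=50)
        truth = syn.generate_truth(cfg)
        cells = syn.simulate_single_cell(truth, cfg)
        mol = cells.spikein_molecules
        mean_counts = cells.counts.loc[mol.index].mean(axis=1)
        big = mol > 100   # above rounding/detection floor
        ratio = mean_counts[big] / mol[big]
        assert ratio.between(0.05, 0.2).all()   # capture efficiency ~0.1


class TestSimulatePeaks:
    def test_zero_peaks_gives_empty_set(self):
        cfg = small_config()
        ann = syn.generate_annotation(cfg)
        peaks = syn.simulate_peaks(ann, 1.0, cfg, n_peaks=0)
        assert peaks.is_empty()

    def test_peaks_deterministic_and_in_bounds(self):
        cfg = small_config()
        ann = syn.generate_annotation(cfg)
        a = syn.simulate_peaks(ann, 3.0, cfg, n_peaks=200)
        b = syn.simulate_peaks(ann, 3.0, cfg, n_peaks=200)
        assert a.data.keys() == b.data.keys()
        for chrom in a.chroms():
            assert np.array_equal(a.data[chrom][0], b.data[chrom][0])
            assert a.data[chrom][1].max() <= cfg.chrom_lengths[chrom]

    def test_nonpositive_enrichment_rejected(self):
        cfg = small_config()
        ann = syn.generate_annotation(cfg)
        with pytest.raises(syn.ConfigError):
            syn.simulate_peaks(ann, 0.0, cfg)


def test_write_outputs_round_trips(tmp_path):
    cfg = small_config(n_genes=20, mark_effects={"H3K27me3": {}})
    paths = syn.write_outputs(tmp_path, cfg)
    truth = pd.read_csv(paths["truth.tsv"], sep="\t", index_col=0)
    assert len(truth) == 20
    ann = gs.read_tss_bed(paths["tss.bed"], chrom_lengths=cfg.chrom_lengths)
    assert sorted(ann.tss) == sorted(truth.index)
    track = gs.read_bedgraph(paths["H3K27me3.chip.bedgraph"],
                             library_size=cfg.chip_library_size)
    regenerated = syn.simulate_chip_tracks(
        syn.generate_annotation(cfg), syn.generate_truth(cfg), cfg)
    assert track == regenerated["H3K27me3"]["chip"]
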