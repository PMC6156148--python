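"""Track IO, ChIP/input ratios, TSS-window features, metagene profiles."""

import numpy as np
import pandas as pd
import pytest

from airechrom import genomic_signal as gs
from conftest import (
    naive_bin_means,
    naive_ratio,
    naive_tss_max,
    random_track,
    track_to_base_array,
)


def make_track(intervals, library=1e6, chrom="chr1"):
    s = np.array([a for a, _, _ in intervals])
    e = np.array([b for _, b, _ in intervals])
    v = np.array([x for _, _, x in intervals], dtype=float)
    return gs.SignalTrack(data={chrom: (s, e, v)}, library_size=library)


class TestBedgraphIO:
    def test_single_record(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t100\t2.5\n")
        t = gs.read_bedgraph(p, library_size=1e6)
        (s, e, v) = t.data["chr1"]
        assert list(s) == [0] and list(e) == [100] and list(v) == [2.5]

    def test_overlapping_records_rejected(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t100\t1\nchr1\t50\t150\t2\n")
        with pytest.raises(gs.TrackError, match="overlap"):
            gs.read_bedgraph(p, library_size=1e6)

    @pytest.mark.parametrize("content,msg", [
        ("chr1\t0\tx\t1\n", "non-numeric"),
        ("chr1\t10\t5\t1\n", "end <= start"),
        ("chr1\t0\t5\t-1\n", "negative"),
    ])
    def test_malformed_lines(self, tmp_path, content, msg):
        p = tmp_path / "t.bedgraph"
        p.write_text(content)
        with pytest.raises(gs.TrackError, match=msg):
            gs.read_bedgraph(p, library_size=1e6)

    def test_roundtrip_random_records(self, tmp_path, rng):
        t = random_track(rng, length=200_000, n_intervals=1000)
        p = tmp_path / "t.bedgraph"
        gs.write_bedgraph(t, p)
        assert gs.read_bedgraph(p, library_size=t.library_size) == t


class TestScaleToLibrary:
    def test_identity_at_nominal_library(self):
        t = make_track([(0, 10, 3.0)], library=1e6)
        assert gs.scale_to_library(t).data["chr1"][2][0] == 3.0

    def test_linear_scaling(self):
        t = make_track([(0, 10, 3.0)], library=2e6)
        assert gs.scale_to_library(t).data["chr1"][2][0] == 1.5

    def test_idempotent_after_normalization(self):
        t = make_track([(0, 10, 3.0)], library=2e6)
        once = gs.scale_to_library(t)
        assert gs.scale_to_library(once) == once

    def test_rejects_nonpositive_library(self):
        with pytest.raises(gs.TrackError):
            gs.SignalTrack(data={}, library_size=0)


class TestChipInputRatio:
    def test_identical_tracks_give_unity(self):
        t = make_track([(0, 100, 4.0), (200, 300, 1.0)])
        r = gs.chip_input_ratio(t, t, pseudocount=0.5)
        assert np.allclose(r.data["chr1"][2], 1.0)

    def test_direct_arithmetic(self):
        chip = make_track([(0, 100, 4.0)])
        inp = make_track([(0, 100, 1.0)])
        r = gs.chip_input_ratio(chip, inp, pseudocount=1.0)
        assert r.data["chr1"][2][0] == pytest.approx(2.5)

    def test_rejects_nonpositive_pseudocount(self):
        t = make_track([(0, 10, 1.0)])
        with pytest.raises(gs.TrackError):
            gs.chip_input_ratio(t, t, pseudocount=0)

    def test_rejects_unscaled_tracks(self):
        t = make_track([(0, 10, 1.0)], library=2e6)
        with pytest.raises(gs.TrackError, match="scaled"):
            gs.chip_input_ratio(t, t)

    def test_matches_per_base_oracle(self, rng):
        L = 10_000
        for _ in range(10):
            chip = random_track(rng, L, 30)
            inp = random_track(rng, L, 25)
            r = gs.chip_input_ratio(chip, inp, pseudocount=0.5)
            got = track_to_base_array(r, "chr1", L, default=gs.DEFAULT_RATIO)
            want = naive_ratio(track_to_base_array(chip, "chr1", L),
                               track_to_base_array(inp, "chr1", L), 0.5)
            # bases covered by neither track default to 1 in both conventions
            neither = (track_to_base_array(chip, "chr1", L, -1) == -1) \
                & (track_to_base_array(inp, "chr1", L, -1) == -1)
            want[neither] = gs.DEFAULT_RATIO
            assert np.allclose(got, want)


class TestTssMaxSignal:
    def test_constant_track(self, toy_annotation):
        r = make_track([(0, 10_000, 1.0)])
        feats = gs.tss_max_signal(r, toy_annotation, window_bp=1000)
        assert np.allclose(feats, 1.0)

    def test_max_across_transcripts(self, toy_annotation):
        # peak value 5.0 only under gB's second TSS (6400)
        r = make_track([(0, 6300, 1.0), (6300, 6500, 5.0), (6500, 10_000, 1.0)])
        feats = gs.tss_max_signal(r, toy_annotation, window_bp=1000)
        assert feats["gB"] == 5.0

    def test_uncovered_window_defaults_to_unity(self, toy_annotation):
        r = make_track([(0, 100, 0.2)])  # far from both genes
        feats = gs.tss_max_signal(r, toy_annotation, window_bp=1000)
        assert np.allclose(feats, gs.DEFAULT_RATIO)

    def test_low_coverage_window_includes_default(self, toy_annotation):
        # window partially covered by sub-unity values: default 1 wins
        r = make_track([(2900, 3100, 0.2)])
        feats = gs.tss_max_signal(r, toy_annotation, window_bp=1000)
        assert feats["gA"] == gs.DEFAULT_RATIO

    def test_matches_per_base_oracle(self, rng):
        L = 50_000
        for _ in range(20):
            track = random_track(rng, L, 40)
            positions = sorted(rng.choice(np.arange(2000, L - 2000), 5,
                                          replace=False))
            ann = gs.TssAnnotation(
                tss={f"g{i}": [("chr1", int(p), "+")]
                     for i, p in enumerate(positions)},
                chrom_lengths={"chr1": L})
            feats = gs.tss_max_signal(track, ann, window_bp=1000)
            base = track_to_base_array(track, "chr1", L,
                                       default=gs.DEFAULT_RATIO)
            for i, p in enumerate(positions):
                assert feats[f"g{i}"] == pytest.approx(
                    naive_tss_max(base, [p], 1000))

    def test_invariant_to_interval_splitting(self, toy_annotation):
        whole = make_track([(2000, 4000, 3.0)])
        split = make_track([(2000, 2500, 3.0), (2500, 3100, 3.0),
                            (3100, 4000, 3.0)])
        a = gs.tss_max_signal(whole, toy_annotation, 1000)
        b = gs.tss_max_signal(split, toy_annotation, 1000)
        assert a.equals(b)

    def test_invariant_to_transcript_order(self, toy_annotation):
        r = make_track([(5000, 7000, 2.0)])
        flipped = gs.TssAnnotation(
            tss={"gA": toy_annotation.tss["gA"],
                 "gB": toy_annotation.tss["gB"][::-1]},
            chrom_lengths=toy_annotation.chrom_lengths)
        assert gs.tss_max_signal(r, toy_annotation, 1000).equals(
            gs.tss_max_signal(r, flipped, 1000))


class TestFeatureMatrix:
    def test_composition_and_shape(self, toy_annotation):
        r1 = make_track([(2000, 4000, 2.0)])
        r2 = make_track([(5000, 7000, 4.0)])
        cats = {"gA": "AIRE_DEPENDENT", "gB": "OTHER"}
        fm = gs.build_feature_matrix({"m1": r1, "m2": r2}, toy_annotation, cats)
        assert fm.values.shape == (2, 2)
        for mark, track in (("m1", r1), ("m2", r2)):
            assert fm.values[mark].equals(
                gs.tss_max_signal(track, toy_annotation, 1000).rename(mark))

    def test_order_invariance(self, toy_annotation):
        r = make_track([(2000, 4000, 2.0)])
        cats = {"gB": "OTHER", "gA": "AIRE_DEPENDENT"}
        a = gs.build_feature_matrix({"m": r}, toy_annotation, cats)
        b = gs.build_feature_matrix({"m": r}, toy_annotation,
                                    dict(reversed(list(cats.items()))))
        assert a.values.equals(b.values)

    def test_missing_category_is_an_error(self, toy_annotation):
        r = make_track([(0, 10_000, 1.0)])
        with pytest.raises(gs.TrackError, match="gB"):
            gs.build_feature_matrix({"m": r}, toy_annotation,
                                    {"gA": "OTHER"})


class TestMetageneProfile:
    def test_constant_track_gives_flat_profile(self, toy_annotation):
        r = make_track([(0, 10_000, 2.0)])
        prof = gs.metagene_profile(r, toy_annotation,
                                   {"gA": "OTHER", "gB": "OTHER"},
                                   window_bp=2000, bin_bp=100)
        assert np.allclose(prof.medians["OTHER"], 2.0)

    def test_minus_strand_profile_is_mirrored(self):
        # asymmetric signal: elevated only downstream (3') of the TSS
        ann_plus = gs.TssAnnotation(tss={"g": [("chr1", 5000, "+")]},
                                    chrom_lengths={"chr1": 10_000})
        ann_minus = gs.TssAnnotation(tss={"g": [("chr1", 5000, "-")]},
                                     chrom_lengths={"chr1": 10_000})
        up = make_track([(3000, 5000, 1.0), (5000, 7000, 4.0)])
        prof_p = gs.metagene_profile(up, ann_plus, {"g": "OTHER"}, 1000, 100)
        prof_m = gs.metagene_profile(up, ann_minus, {"g": "OTHER"}, 1000, 100)
        # on the minus strand the elevated side is upstream in oriented coords
        assert prof_p.medians["OTHER"].iloc[-1] == pytest.approx(4.0)
        assert prof_m.medians["OTHER"].iloc[0] == pytest.approx(4.0)
        assert np.allclose(prof_p.medians["OTHER"].to_numpy()[::-1][:9],
                           prof_m.medians["OTHER"].to_numpy()[:9])

    def test_matches_per_base_oracle(self, rng):
        L = 30_000
        for _ in range(5):
            track = random_track(rng, L, 30)
            pos = int(rng.integers(6000, L - 6000))
            strand = "+" if rng.random() < 0.5 else "-"
            ann = gs.TssAnnotation(tss={"g": [("chr1", pos, strand)]},
                                   chrom_lengths={"chr1": L})
            prof = gs.metagene_profile(track, ann, {"g": "OTHER"},
                                       window_bp=5000, bin_bp=50)
            base = track_to_base_array(track, "chr1", L,
                                       default=gs.DEFAULT_RATIO)
            want = naive_bin_means(base, pos, strand, 5000, 50)
            assert np.allclose(prof.medians["OTHER"].to_numpy(), want,
                               equal_nan=True)

    def test_empty_category_omitted(self, toy_annotation, caplog):
        r = make_track([(0, 10_000, 1.0)])
        prof = gs.metagene_profile(r, toy_annotation,
                                   {"gA": "OTHER", "gB": "OTHER"}, 2000, 100)
        assert list(prof.medians.columns) == ["OTHER"]

    def test_window_must_divide_into_bins(self, toy_annotation):
        r = make_track([(0, 10_000, 1.0)])
        with pytest.raises(gs.TrackError):
            gs.metagene_profile(r, toy_annotation, {"gA": "OTHER", "gB": "OTHER"},
                                window_bp=1001, bin_bp=50)


def test_pool_tracks_sums_values_and_libraries():
    a = make_track([(0, 100, 2.0)], library=1e6)
    b = make_track([(50, 150, 3.0)], library=2e6)
    pooled = gs.pool_tracks([a, b])
    assert pooled.library_size == 3e6
    assert pooled.value_at("chr1", 0) == 2.0
    assert pooled.value_at("chr1", 75) == 5.0
    assert pooled.value_at("chr1", 120) == 3.0
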