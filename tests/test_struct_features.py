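import math

import numpy as np
import pytest

from ribofold_te.iolib import ReactivityTrack, ValidationError
from ribofold_te.struct_features import (
    assemble_structural_features,
    bin_edges,
    bin_profile,
    cds_head_reactivity,
    fold_mfe,
    import_external_mfe,
    mfe_features,
    structural_feature_names,
    structural_feature_table,
)

from _oracles import max_pairs_enumeration
from conftest import constant_track, make_transcript


class TestBinProfile:
    def test_constant_track_fills_all_bins(self):
        t = make_transcript(len_utr5=20, len_cds=21, len_utr3=20)
        profile = bin_profile(constant_track(t, 0.5), t)
        np.testing.assert_allclose(profile.bins, 0.5)
        assert profile.bins.size == 60

    def test_two_nt_bins_average_hand_checked(self):
        # region of 40 nt holding values 0..39 in 20 bins: bin k = 2k + 0.5
        t = make_transcript(len_utr5=40, len_cds=21, len_utr3=20)
        values = np.concatenate([np.arange(40.0), np.zeros(41)])
        profile = bin_profile(ReactivityTrack(t.transcript_id, "vivo", values), t)
        np.testing.assert_allclose(profile.bins[:20], 2 * np.arange(20) + 0.5)

    def test_region_mean_conserved_for_gap_free_track(self):
        rng = np.random.default_rng(0)
        t = make_transcript(len_utr5=37, len_cds=66, len_utr3=53)
        values = rng.random(t.length)
        profile = bin_profile(ReactivityTrack(t.transcript_id, "vivo", values), t)
        for r_idx, region in enumerate(("utr5", "cds", "utr3")):
            a, b = t.region_bounds(region)
            edges = bin_edges(b - a, 20)
            weights = np.diff(edges)
            bins = profile.bins[20 * r_idx : 20 * (r_idx + 1)]
            ok = weights > 0
            assert np.average(bins[ok], weights=weights[ok]) == pytest.approx(
                values[a:b].mean(), abs=1e-9
            )

    def test_bin_edges_partition_every_region_exactly(self):
        for L in [1, 5, 19, 20, 21, 40, 59, 97]:
            edges = bin_edges(L, 20)
            assert edges[0] == 0 and edges[-1] == L
            assert np.all(np.diff(edges) >= 0)
            # each nucleotide in exactly one bin
            covered = np.concatenate([np.arange(edges[k], edges[k + 1]) for k in range(20)])
            np.testing.assert_array_equal(covered, np.arange(L))

    def test_monotone_track_gives_monotone_bins(self):
        t = make_transcript(len_utr5=20, len_cds=57, len_utr3=33)
        values = np.linspace(0, 1, t.length)
        profile = bin_profile(ReactivityTrack(t.transcript_id, "vivo", values), t)
        for r in range(3):
            bins = profile.bins[20 * r : 20 * (r + 1)]
            bins = bins[~np.isnan(bins)]
            assert np.all(np.diff(bins) >= 0)

    def test_zero_length_region_gives_missing_bins(self):
        t = make_transcript(len_utr5=0, len_cds=60, len_utr3=40)
        profile = bin_profile(constant_track(t, 0.3), t)
        assert np.all(np.isnan(profile.bins[:20]))
        assert np.all(~np.isnan(profile.bins[20:]))

    def test_length_mismatch_error(self):
        t = make_transcript()
        with pytest.raises(ValidationError):
            bin_profile(ReactivityTrack("t1", "vivo", np.zeros(t.length + 1)), t)

    def test_all_missing_bin_is_missing(self):
        t = make_transcript(len_utr5=20, len_cds=21, len_utr3=20)
        values = np.full(t.length, 0.4)
        values[:1] = np.nan  # utr5 bin 0 covers exactly 1 nt
        profile = bin_profile(ReactivityTrack(t.transcript_id, "vivo", values), t)
        assert math.isnan(profile.bins[0])


class TestCdsHead:
    def test_constant_track(self):
        t = make_transcript(len_utr5=20, len_cds=24, len_utr3=22)
        assert cds_head_reactivity(constant_track(t, 0.7), t) == pytest.approx(0.7)

    def test_averages_exactly_first_18_nt(self):
        t = make_transcript(len_utr5=10, len_cds=30, len_utr3=10)
        values = np.zeros(t.length)
        values[10:28] = 1.0  # the 18 head nucleotides
        values[28:] = 100.0
        track = ReactivityTrack(t.transcript_id, "vivo", values)
        assert cds_head_reactivity(track, t) == pytest.approx(1.0)

    def test_short_cds_or_all_missing_head_is_missing(self):
        short = make_transcript(len_utr5=10, len_cds=15, len_utr3=10)
        assert math.isnan(cds_head_reactivity(constant_track(short, 0.5), short))
        t = make_transcript(len_utr5=10, len_cds=30, len_utr3=10)
        values = np.full(t.length, 0.5)
        values[10:28] = np.nan
        assert math.isnan(cds_head_reactivity(ReactivityTrack(t.transcript_id, "vivo", values), t))


class TestFolder:
    @pytest.mark.parametrize(
        "seq,expected",
        [("AAAAA", 0.0), ("GC", 0.0), ("GGGAAACCC", -3.0)],
        ids=["no_complement", "loop_constraint", "triple_stem"],
    )
    def test_known_foldings(self, seq, expected):
        assert fold_mfe(seq) == expected

    def test_matches_structure_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 15))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert fold_mfe(seq) == -max_pairs_enumeration(seq), seq

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            fold_mfe("")


class TestMfeFeatures:
    def test_ten_scoped_features_all_nonpositive(self):
        t = make_transcript(len_utr5=20, len_cds=24, len_utr3=22)
        f = mfe_features(t)
        assert len(f) == 10
        raw = [v for k, v in f.items() if not k.endswith("per_nt")]
        assert all(v <= 0 for v in raw)

    def test_external_energies_replace_builtin(self):
        t = make_transcript()
        f = mfe_features(t, external={"whole": -12.3, "cds": -8.0})
        assert f["insilico_mfe_whole"] == -12.3
        assert f["insilico_mfe_whole_per_nt"] == pytest.approx(-12.3 / t.length)
        assert f["insilico_mfe_utr5"] == fold_mfe(t.region_seq("utr5"))


class TestExternalMfeTable:
    def _write(self, path, rows):
        cols = ["transcript_id"] + [f"mfe_{s}" for s in ("whole", "utr5", "cds", "utr3", "cds_head")]
        path.write_text("\t".join(cols) + "\n" + "\n".join("\t".join(map(str, r)) for r in rows) + "\n")

    def test_parse(self, tmp_path):
        p = tmp_path / "mfe.tsv"
        self._write(p, [("t1", -12.3, -2.1, -8.0, -1.9, -0.4)])
        out = import_external_mfe(p)
        assert out["t1"]["whole"] == -12.3 and out["t1"]["cds_head"] == -0.4

    def test_positive_energy_error(self, tmp_path):
        p = tmp_path / "mfe.tsv"
        self._write(p, [("t1", 1.5, -2.1, -8.0, -1.9, -0.4)])
        with pytest.raises(ValidationError):
            import_external_mfe(p)

    def test_missing_scope_column_error(self, tmp_path):
        p = tmp_path / "mfe.tsv"
        p.write_text("transcript_id\tmfe_whole\nt1\t-2.0\n")
        with pytest.raises(ValidationError):
            import_external_mfe(p)


class TestStructuralAssembly:
    def test_default_census_is_132(self):
        assert len(structural_feature_names()) == 132
        t = make_transcript(len_utr5=20, len_cds=24, len_utr3=22)
        tracks = {"vivo": constant_track(t, 0.5), "vitro": constant_track(t, 0.4, "vitro")}
        assert len(assemble_structural_features(t, tracks)) == 132

    def test_absent_condition_flagged_missing(self):
        t = make_transcript(len_utr5=20, len_cds=24, len_utr3=22)
        f = assemble_structural_features(t, {"vivo": constant_track(t, 0.5)})
        assert math.isnan(f["vitro_bin_00"]) and math.isnan(f["vitro_cds_head"])
        assert f["vivo_bin_00"] == pytest.approx(0.5)

    def test_feature_names_stable_across_transcripts(self):
        txs = [make_transcript(f"t{i}", 20, 24, 22, seed=i) for i in range(2)]
        df = structural_feature_table(
            txs,
            [constant_track(t, 0.5) for t in txs],
            [constant_track(t, 0.4, "vitro") for t in txs],
        )
        assert df.shape == (2, 132)
        assert list(df.columns) == structural_feature_names()
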