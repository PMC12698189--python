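"""Conversion-track extraction: strand assignment, pileup, normalization,
serialization and QC."""

import itertools

import numpy as np
import pandas as pd
import pysam
import pytest

import foottrack as ft
from foottrack.tracks import (MalformedInputError, SignalTrack, assign_read_strand,
                              deserialize_track, serialize_track)
from tests.conftest import (dataset_to_files, extract_from_dataset, make_track,
                            uniform_signal)


def _make_read(ref, start, seq, qname="r1", header=None, tags=None):
    header = header or pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrT", "LN": len(ref)}]})
    a = pysam.AlignedSegment(header)
    a.query_name = qname
    a.query_sequence = seq
    a.flag = 0
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = 60
    a.cigarstring = f"{len(seq)}M"
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    if tags:
        a.set_tags(tags)
    return a


class TestAssignReadStrand:
    def test_one_sided_ct_pattern_is_plus(self):
        ref = "CACACACACA"
        read = _make_read(ref, 0, "TATATACACA")  # 3 C->T, 0 G->A
        assert assign_read_strand(read, ref) == "+"

    def test_no_mismatches_is_undetermined(self):
        ref = "ACGTACGTAC"
        read = _make_read(ref, 0, ref)
        assert assign_read_strand(read, ref) == "undetermined"

    def test_tie_is_undetermined(self):
        ref = "CCCGGGAAAA"
        read = _make_read(ref, 0, "TTTAAAAAAA")  # 3 C->T vs 3 G->A
        assert assign_read_strand(read, ref) == "undetermined"

    def test_tag_wins_over_mismatch_pattern(self):
        ref = "CACACACACA"
        read = _make_read(ref, 0, "TATATACACA", tags=[("XG", "GA")])
        assert assign_read_strand(read, ref, strand_tag="XG") == "-"

    def test_exhaustive_small_mismatch_vectors(self):
        """Majority rule matches a brute-force per-base classifier for every
        (C->T, G->A) mismatch combination up to 4+4."""
        def brute_force(ref, qry):
            ct = sum(1 for r, q in zip(ref, qry) if r == "C" and q == "T")
            ga = sum(1 for r, q in zip(ref, qry) if r == "G" and q == "A")
            return "+" if ct > ga else ("-" if ga > ct else "undetermined")

        rng = np.random.default_rng(0)
        for n_ct, n_ga in itertools.product(range(5), range(5)):
            ref = ["C"] * 5 + ["G"] * 5 + ["A"] * 5
            qry = list(ref)
            for i in rng.permutation(5)[:n_ct]:
                qry[i] = "T"
            for i in rng.permutation(5)[:n_ga]:
                qry[5 + i] = "A"
            ref_s, qry_s = "".join(ref), "".join(qry)
            read = _make_read(ref_s, 0, qry_s)
            assert assign_read_strand(read, ref_s) == brute_force(ref_s, qry_s)

    def test_unmapped_read_rejected(self):
        read = _make_read("ACGT", 0, "ACGT")
        read.flag = 4
        with pytest.raises(MalformedInputError):
            assign_read_strand(read, "ACGT")


class TestExtract:
    def test_matches_brute_force_recount(self, tmp_path):
        """The pileup equals an independent per-molecule recount of the
        simulator's conversion events, exactly."""
        cfg = ft.SimulationConfig(seed=3, contigs={"chrSim": 3000},
                                  ocrs=[("chrSim", 500, 2500)],
                                  n_molecules=100, fragment_len_mean=200)
        ref = ft.simulate_reference(cfg)
        ds = ft.simulate_molecules(ref, cfg)
        track = extract_from_dataset(ds, tmp_path)

        expected: dict = {}
        n_obs = 0
        for mol in ds.truth.molecules:
            # strand-undetermined molecules are dropped by the extractor
            ct = int(mol.converted.sum()) if mol.strand == "+" else 0
            ga = int(mol.converted.sum()) if mol.strand == "-" else 0
            if ct == ga:
                continue
            for pos, conv in zip(mol.cytosine_pos, mol.converted):
                key = (mol.chrom, int(pos), mol.strand)
                nt, nc = expected.get(key, (0, 0))
                expected[key] = (nt + 1, nc + int(conv))
                n_obs += 1
        got = {(r.chrom, r.pos, r.strand): (r.n_total, r.n_conv)
               for r in track.data.itertuples()}
        assert got == expected
        assert int(track.data["n_total"].sum()) == n_obs

    def test_track_invariants(self, occupancy_track):
        d = occupancy_track.data
        assert (d["n_conv"] <= d["n_total"]).all()
        assert (d["n_conv"] >= 0).all()
        k = len(d["context"].iloc[0])
        assert (d["context"].str[k // 2] == "C").all()
        assert not d.duplicated(["chrom", "pos", "strand"]).any()
        assert (d.groupby("chrom")["pos"].diff().dropna() > 0).all()

    def test_global_rate_definition(self, occupancy_track):
        d = occupancy_track.data
        sub = d[d["n_total"] >= 3]
        expected = sub["n_conv"].sum() / sub["n_total"].sum()
        assert occupancy_track.global_rate == pytest.approx(expected, abs=1e-12)

    def test_contig_mismatch_names_contig(self, tmp_path, occupancy_dataset):
        sam, _ = dataset_to_files(occupancy_dataset, tmp_path)
        with pytest.raises(ValueError, match="chrSim"):
            ft.extract_conversion_track(sam, {"chrOther": "ACGT" * 100},
                                        min_mapq=0, min_baseq=0)

    def test_empty_input_flags_undefined_rate(self, tmp_path):
        sam = tmp_path / "empty.sam"
        sam.write_text("@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chrT\tLN:100\n")
        track = ft.extract_conversion_track(str(sam), {"chrT": "ACGT" * 25})
        assert track.is_empty
        assert track.global_rate is None

    def test_overlapping_mates_counted_once(self, tmp_path):
        ref = "AACAACAACA" * 4
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "chrT", "LN": len(ref)}]}
        sam = str(tmp_path / "pair.sam")
        with pysam.AlignmentFile(sam, "w",
                                 header=pysam.AlignmentHeader.from_dict(header)) as out:
            for flag, qname in ((65, "frag"), (129, "frag")):
                a = _make_read(ref, 0, "AATAATAACA" + ref[10:20],
                               qname=qname, header=out.header)
                a.flag = flag  # paired, both mates over the same span
                out.write(a)
        track = ft.extract_conversion_track(sam, {"chrT": ref},
                                            min_mapq=0, min_baseq=0)
        assert (track.data["n_total"] == 1).all()


class TestNormalize:
    def test_identity_and_scaling(self):
        track = make_track([("c", 5, "+", 3, 10, "ACA"), ("c", 9, "+", 3, 10, "TCA")])
        assert track.global_rate == pytest.approx(0.3)
        same = ft.normalize_track(track, 0.3)
        assert np.allclose(same.data["rate"], 0.3)
        up = ft.normalize_track(track, 0.6)
        assert np.allclose(up.data["rate"], 0.6)

    def test_idempotent_at_own_rate(self, occupancy_track):
        once = ft.normalize_track(occupancy_track, occupancy_track.global_rate)
        raw = SignalTrack.from_counts(occupancy_track)
        assert np.allclose(once.data["rate"], raw.data["rate"])

    def test_zero_rate_rejected(self):
        track = make_track([("c", 5, "+", 0, 10, "ACA")])
        with pytest.raises(ValueError, match="normalize"):
            ft.normalize_track(track, 0.3)

    def test_dose_collapse_after_normalization(self, tmp_path):
        """Two naked samples differing only in enzyme dose overlay after
        rescaling to a common reference rate."""
        tracks = []
        for i, rate in enumerate((0.2, 0.4)):
            cfg = ft.SimulationConfig(seed=21, contigs={"chrN": 8000}, naked=True,
                                      naked_rate=rate, n_molecules=5000,
                                      fragment_len_mean=150)
            ref = ft.simulate_reference(cfg)
            ds = ft.simulate_molecules(ref, cfg)
            sub = tmp_path / str(i)
            sub.mkdir()
            tracks.append(extract_from_dataset(ds, sub))
        sigs = [ft.normalize_track(t, 0.3) for t in tracks]
        profiles = []
        for sig in sigs:  # average profile in 500 bp bins
            d = sig.data
            binned = d.groupby(d["pos"] // 500).apply(
                lambda s: np.average(s["rate"], weights=s["n_total"]),
                include_groups=False)
            profiles.append(binned)
        gap = (profiles[0] - profiles[1]).abs().max()
        assert gap < 0.02


class TestSerialization:
    def test_round_trip_exact(self, occupancy_track, tmp_path):
        paths = serialize_track(occupancy_track, str(tmp_path / "t"))
        back = deserialize_track(paths["tsv"])
        pd.testing.assert_frame_equal(back.data, occupancy_track.data)
        assert back.global_rate == occupancy_track.global_rate
        assert back.sample_id == occupancy_track.sample_id

    def test_empty_round_trip(self, tmp_path):
        empty = ft.ConversionTrack(pd.DataFrame(
            columns=["chrom", "pos", "strand", "n_conv", "n_total", "context"]))
        paths = serialize_track(empty, str(tmp_path / "e"))
        back = deserialize_track(paths["tsv"])
        assert back.is_empty and back.global_rate is None

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("# header\nchr1\t5\t+\t1\t2\tACA\nchr1\tnotanint\t+\t1\t2\tACA\n")
        with pytest.raises(ValueError, match=":3"):
            deserialize_track(str(p))

    def test_bedgraph_intervals_are_width_one(self, occupancy_track, tmp_path):
        paths = serialize_track(occupancy_track, str(tmp_path / "t"))
        bed = pd.read_csv(paths["plus.rate"], sep="\t", skiprows=1, header=None)
        assert ((bed[2] - bed[1]) == 1).all()


class TestQC:
    @pytest.mark.parametrize("rate,expected", [(0.30, "pass"), (0.45, "warn"),
                                               (0.10, "warn")])
    def test_optimal_window(self, rate, expected):
        n = 1000
        track = make_track([("c", 2 * i + 1, "+", int(rate * 100), 100, "ACA")
                            for i in range(n)])
        report = ft.qc_conversion_rate(track)
        assert report.status == expected
        assert report.global_rate == pytest.approx(rate)

    def test_strand_balance_on_symmetric_data(self, naked_track):
        report = ft.qc_conversion_rate(naked_track, bounds=(0, 1))
        r = report.strand_rates
        assert abs(r["+"] - r["-"]) < 0.02
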