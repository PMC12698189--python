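"""Motif scanning, footprint strategies S1/S2, annotation, differential binding."""

import numpy as np
import pandas as pd
import pytest

import foottrack as ft
from foottrack.denovo import (annotate_footprints, bh_adjust,
                              cluster_motifs_by_similarity,
                              detect_footprint_regions_s2, differential_binding,
                              footprint_scan_scores_s1, global_background_rate,
                              local_background_rate, quantile_normalize_pair,
                              scan_motifs)
from foottrack.simulate import revcomp
from tests.conftest import extract_from_dataset, make_signal, uniform_signal

CONSENSUS = "TGACGTCACGCG"


def test_bh_matches_brute_force_oracle():
    """q-values equal the step-up definition computed from scratch."""
    def oracle(p):
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        prev = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            rank = m - rank_from_top
            prev = min(prev, p[idx] * m / rank)
            q[idx] = prev
        return q

    rng = np.random.default_rng(4)
    for n in (1, 10, 1000):
        p = rng.uniform(0, 1, n)
        np.testing.assert_allclose(bh_adjust(p), oracle(p), atol=1e-12)
    assert (bh_adjust(np.array([0.01, 0.02, 0.5]))
            >= np.array([0.01, 0.02, 0.5])).all()  # q >= p under BH


class TestScanMotifs:
    def test_planted_consensus_recovered_on_both_strands(self):
        rng = np.random.default_rng(5)
        bg = "".join(rng.choice(list("ACGT"), 3000))
        seq = (bg[:1000] + CONSENSUS + bg[1000:2000] + revcomp(CONSENSUS)
               + bg[2000:])
        model = ft.MotifModel.from_consensus("M1", CONSENSUS)
        hits = scan_motifs({"chrT": seq}, [model], [("chrT", 0, len(seq))])
        spots = {(h.start, h.strand) for h in hits}
        assert (1000, "+") in spots
        assert (2000 + len(CONSENSUS), "-") in spots

    def test_nothing_outside_search_regions(self):
        seq = "A" * 500 + CONSENSUS + "A" * 500
        model = ft.MotifModel.from_consensus("M1", CONSENSUS)
        hits = scan_motifs({"chrT": seq}, [model], [("chrT", 0, 400)])
        assert hits == []

    def test_threshold_calibration_on_random_sequence(self):
        """At p=1e-4 the per-strand-position hit rate on random sequence sits
        within 3 SE of 1e-4."""
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), 120_000))
        counts = np.array([[8, 1, 2, 12, 3, 2, 10, 2],
                           [3, 12, 2, 1, 2, 3, 2, 2],
                           [3, 1, 11, 1, 2, 9, 2, 2],
                           [2, 2, 1, 2, 9, 2, 2, 10]], dtype=float)
        model = ft.MotifModel("M2", "M2", counts)
        hits = scan_motifs({"chrT": seq}, [model], [("chrT", 0, len(seq))],
                           pvalue_threshold=1e-4)
        n_positions = 2 * (len(seq) - model.length + 1)
        expected = 1e-4 * n_positions
        # overlap resolution only removes hits; allow the band on the raw rate
        assert abs(len(hits) - expected) < 3 * np.sqrt(expected) + 2

    def test_zero_column_without_pseudocount_rejected(self):
        counts = np.ones((4, 6))
        counts[:, 2] = 0.0
        model = ft.MotifModel("M0", "M0", counts, pseudocount=0.0)
        with pytest.raises(ValueError, match="pseudocount"):
            scan_motifs({"c": "ACGT" * 100}, [model], [("c", 0, 400)])


class TestBackgrounds:
    def test_uniform_track_same_in_both_modes(self):
        sig = uniform_signal("c", 0, 2000, 0.4)
        local = local_background_rate(sig, ("c", 900, 950))
        glob = global_background_rate(sig, [("c", 0, 2000)])
        assert local == pytest.approx(0.4)
        assert glob == pytest.approx(0.4)

    def test_local_exceeds_global_inside_hot_peak(self):
        pts = [("c", p, 0.8 if 800 <= p < 1200 else 0.2) for p in range(0, 2000, 2)]
        sig = make_signal(pts)
        local = local_background_rate(sig, ("c", 980, 1020))
        glob = global_background_rate(sig, [("c", 0, 2000)])
        assert local > glob

    def test_contig_edge_is_one_sided(self):
        sig = uniform_signal("c", 0, 300, 0.4)
        val = local_background_rate(sig, ("c", 0, 30), span=200)
        assert val == pytest.approx(0.4)

    def test_span_must_exceed_interval(self):
        sig = uniform_signal("c", 0, 300, 0.4)
        with pytest.raises(ValueError, match="span"):
            local_background_rate(sig, ("c", 0, 250), span=200)


def _occupied_region_dataset(seed, theta=0.9, n_molecules=2000, consensus=CONSENSUS):
    cfg = ft.SimulationConfig(
        seed=seed, contigs={"chrSim": 5000}, ocrs=[("chrSim", 500, 4500)],
        tf_sites=[ft.TFSite("TF1", consensus, 2400, theta)],
        n_molecules=n_molecules, restrict_to=[("chrSim", 1000, 4000)],
        fragment_len_mean=250, fragment_len_sd=40)
    ref = ft.simulate_reference(cfg)
    return ft.simulate_molecules(ref, cfg), cfg


class TestS2:
    def test_extreme_depletion_called(self):
        """A window of heavily covered cytosines at 10% conversion against a
        50% background is unambiguously significant."""
        pts = [("c", p, 0.1 if 1000 <= p < 1012 else 0.5)
               for p in range(0, 2000, 2)]
        sig = make_signal(pts, n_total=100)
        calls, windows = detect_footprint_regions_s2(
            sig, [("c", 0, 2000)], return_windows=True)
        assert len(calls) == 1
        assert calls[0].start >= 995 and calls[0].end <= 1015
        core = windows[(windows["start"] >= 998) & (windows["end"] <= 1013)]
        assert (core["p_value"] < 1e-15).any()

    def test_planted_footprint_recall_and_boundaries(self, tmp_path):
        ds, cfg = _occupied_region_dataset(seed=60)
        track = extract_from_dataset(ds, tmp_path)
        sig = ft.SignalTrack.from_counts(track)
        calls = detect_footprint_regions_s2(sig, [("chrSim", 1000, 4000)])
        true = (2400, 2400 + len(CONSENSUS))
        overlapping = [c for c in calls if c.start < true[1] and c.end > true[0]]
        assert overlapping, "planted footprint missed"
        best = overlapping[0]
        assert abs(best.start - true[0]) <= 3
        assert abs(best.end - true[1]) <= 3
        assert best.depth_score > 0

    def test_null_fdr_small(self, tmp_path):
        """Open chromatin with no footprints: few windows reach q < 0.05."""
        cfg = ft.SimulationConfig(seed=61, contigs={"chrSim": 4000},
                                  ocrs=[("chrSim", 0, 4000)], n_molecules=1500,
                                  restrict_to=[("chrSim", 800, 3200)],
                                  fragment_len_mean=250)
        ref = ft.simulate_reference(cfg)
        ds = ft.simulate_molecules(ref, cfg)
        track = extract_from_dataset(ds, tmp_path)
        sig = ft.SignalTrack.from_counts(track)
        _, windows = detect_footprint_regions_s2(
            sig, [("chrSim", 1000, 3000)], return_windows=True)
        valid = windows[windows["valid"]]
        assert (valid["q_value"] < 0.05).mean() <= 0.05


class TestS1:
    def test_bound_vs_unbound_separation(self, tmp_path):
        """Planted bound sites score above matched unbound motif occurrences
        (ROC AUC >= 0.9)."""
        scores = {}
        for label, theta, seed in (("bound", 0.9, 70), ("unbound", 0.0, 71)):
            ds, cfg = _occupied_region_dataset(seed=seed, theta=theta)
            sub = tmp_path / label
            sub.mkdir()
            track = extract_from_dataset(ds, sub)
            sig = ft.SignalTrack.from_counts(track)
            sites = [ft.BindingSite("chrSim", 2400, 2400 + len(CONSENSUS), "+",
                                    "M1", "TF1")]
            df = footprint_scan_scores_s1(sig, sites, [("chrSim", 1000, 4000)],
                                          rng=np.random.default_rng(seed))
            scores[label] = df
        assert scores["bound"]["score"].iloc[0] > scores["unbound"]["score"].iloc[0]
        assert scores["bound"]["q_value"].iloc[0] < 0.05
        assert scores["unbound"]["q_value"].iloc[0] > 0.05

    def test_no_cytosine_site_excluded_with_report(self):
        sig = uniform_signal("c", 0, 4000, 0.4)
        gap_site = ft.BindingSite("c", 5000, 5012, "+", "M1", "TF1")  # off data
        df = footprint_scan_scores_s1(sig, [gap_site], [("c", 0, 4000)],
                                      rng=np.random.default_rng(0))
        assert len(df) == 0
        assert len(df.attrs["excluded"]) == 1

    def test_too_few_null_draws_aborts(self):
        sig = make_signal([("c", p, 0.4) for p in range(0, 40, 2)])
        site = ft.BindingSite("c", 10, 22, "+", "M1", "TF1")
        with pytest.raises(RuntimeError, match="null"):
            footprint_scan_scores_s1(sig, [site], [("c", 0, 30)], n_null=50,
                                     rng=np.random.default_rng(0))


class TestAnnotate:
    def _fp(self, start, end):
        return ft.FootprintCall("c", start, end, 0.3, 1e-6, 1e-5, "local")

    def test_matched_and_unmatched(self):
        sites = [ft.BindingSite("c", 100, 112, "+", "M1", "TF1")]
        out = annotate_footprints([self._fp(100, 112), self._fp(500, 520)],
                                  sites, [("c", 0, 2000)])
        t = out["table"].sort_values("start")
        assert list(t["matched"]) == [True, False]
        assert out["matched_fraction"] == pytest.approx(0.5)

    def test_density_per_200bp(self):
        fps = [self._fp(s, s + 10) for s in range(0, 4000, 100)]
        out = annotate_footprints(fps, [], [("c", 0, 2000)])
        assert out["density_per_200bp"] == pytest.approx(len(fps) * 200 / 2000)

    def test_half_motif_overlap_rule(self):
        sites = [ft.BindingSite("c", 100, 120, "+", "M1", "TF1")]
        just_enough = annotate_footprints([self._fp(110, 140)], sites, [("c", 0, 500)])
        too_little = annotate_footprints([self._fp(111, 140)], sites, [("c", 0, 500)])
        assert just_enough["table"]["matched"].iloc[0]
        assert not too_little["table"]["matched"].iloc[0]


def _scored_frame(rng, motif_ids, base=0.2, bump=None):
    rows = []
    for i, mid in enumerate(motif_ids):
        score = rng.normal(base, 0.05)
        if bump and mid == bump[0]:
            score += bump[1]
        rows.append(("c", 100 * i, 100 * i + 12, mid, score))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "motif_id", "score"])


class TestDifferential:
    def _universe(self):
        rng = np.random.default_rng(8)
        motif_ids = [f"M{k}" for k in range(6) for _ in range(80)]
        clusters = {f"C{k}": [f"M{k}"] for k in range(6)}
        return rng, motif_ids, clusters

    def test_identical_conditions_null(self):
        rng, motif_ids, clusters = self._universe()
        a = _scored_frame(rng, motif_ids)
        res = differential_binding(a, a.copy(), clusters,
                                   rng=np.random.default_rng(0), n_perm=2000)
        assert all(r.differential_score == 0 for r in res)
        assert all(r.q_value > 0.05 for r in res)

    def test_label_swap_flips_signs(self):
        rng, motif_ids, clusters = self._universe()
        a = _scored_frame(rng, motif_ids)
        b = _scored_frame(rng, motif_ids, bump=("M2", -0.1))
        fwd = differential_binding(a, b, clusters, rng=np.random.default_rng(1),
                                   n_perm=2000)
        rev = differential_binding(b, a, clusters, rng=np.random.default_rng(1),
                                   n_perm=2000)
        f = {r.tf_cluster: r.differential_score for r in fwd}
        r = {x.tf_cluster: x.differential_score for x in rev}
        for k in f:
            assert f[k] == pytest.approx(-r[k], abs=1e-12)

    def test_spiked_cluster_is_top_negative_hit(self):
        rng, motif_ids, clusters = self._universe()
        a = _scored_frame(rng, motif_ids)
        b = _scored_frame(rng, motif_ids, bump=("M3", -0.15))
        res = differential_binding(a, b, clusters, rng=np.random.default_rng(2))
        ranked = sorted(res, key=lambda r: r.differential_score)
        assert ranked[0].tf_cluster == "C3"
        assert ranked[0].q_value < 0.05
        assert ranked[0].direction == "down"
        others = [r for r in res if r.tf_cluster != "C3"]
        assert np.mean([r.q_value >= 0.05 for r in others]) >= 0.95

    def test_underpowered_flag(self):
        rng = np.random.default_rng(3)
        a = _scored_frame(rng, ["M0"] * 10)
        res = differential_binding(a, a.copy(), {"C0": ["M0"]},
                                   rng=np.random.default_rng(0), n_perm=500)
        assert res[0].underpowered


def test_quantile_normalization_equalizes_distributions():
    rng = np.random.default_rng(11)
    a, b = rng.normal(0, 1, 500), rng.normal(2, 3, 500)
    qa, qb = quantile_normalize_pair(a, b)
    np.testing.assert_allclose(np.sort(qa), np.sort(qb))


def test_motif_clustering_groups_similar_pwms():
    m1 = ft.MotifModel.from_consensus("A1", "TGACGTCA")
    m2 = ft.MotifModel.from_consensus("A2", "TGACGTCA")
    m3 = ft.MotifModel.from_consensus("B1", "CCCGGATATT")
    clusters = cluster_motifs_by_similarity([m1, m2, m3])
    grouped = [set(v) for v in clusters.values()]
    assert {"A1", "A2"} in grouped
    assert {"B1"} in grouped
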