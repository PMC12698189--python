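"""Calibration experiments: end-to-end pipeline checks on simulated data.

Each routine generates synthetic converted reads under known truth, runs the
full pipeline (SAM/FASTA on disk -> extraction -> correction/quantification)
and measures how well the known parameters are recovered.  They serve both
as the package's acceptance benchmarks and as worked examples of complete
analyses; all randomness flows from the caller's seed.

Problem sizes default to the smallest instances at which the measured
quantities are stable (documented per routine); they are parameters, not
constants.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import bias as bias_mod
from . import denovo, molecule, quant, tracks
from .quant import BindingSite
from .simulate import SimulationConfig, TFSite, simulate_molecules, simulate_reference
from .tracks import SignalTrack


def _rng_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def pipeline_track(dataset, workdir: str | None = None) -> tracks.ConversionTrack:
    """Write SAM + FASTA and run the real extraction path."""
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        fasta = str(Path(tmp) / "ref.fa")
        sam = str(Path(tmp) / "reads.sam")
        dataset.write_fasta(fasta)
        dataset.write_sam(sam)
        return tracks.extract_conversion_track(sam, fasta, min_mapq=0, min_baseq=0)


def fos_definition_check() -> dict:
    """FOS on constructed tracks: fully protected motif under 0.5 flanks
    scores exactly 0.5; a uniform track scores exactly 0."""
    site = BindingSite("c", 100, 112, "+", "M", "TF")
    pts = ([("c", p, "+", 0.5, 100) for p in range(50, 100, 2)]
           + [("c", p, "+", 0.0, 100) for p in range(100, 112, 2)]
           + [("c", p, "+", 0.5, 100) for p in range(112, 162, 2)])
    protected = SignalTrack(pd.DataFrame(
        pts, columns=["chrom", "pos", "strand", "rate", "n_total"]))
    uniform = SignalTrack(pd.DataFrame(
        [("c", p, "+", 0.3, 100) for p in range(0, 300, 2)],
        columns=["chrom", "pos", "strand", "rate", "n_total"]))
    return {
        "fos_fully_protected": float(quant.compute_fos(protected, site).fos),
        "fos_uniform_track": float(quant.compute_fos(uniform, site).fos),
    }


def bias_flatness(seed: int, contig_len: int = 100_000,
                  n_molecules: int = 20_000) -> dict:
    """Protein-free simulation with a 2x TC-context preference: fit the bias
    model on one sample and correct an independent replicate.

    Reports the TC/GC fitted rate ratio and the ratio of corrected to
    uncorrected per-context coefficient of variation."""
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(2):
        cfg = SimulationConfig(
            seed=_rng_seed(rng), contigs={"chrN": contig_len}, naked=True,
            naked_rate=0.3, context_bias={"TC": 2.0}, n_molecules=n_molecules,
            fragment_len_mean=200, fragment_len_sd=30)
        ref = simulate_reference(cfg)
        samples.append(pipeline_track(simulate_molecules(ref, cfg)))
    fit_track, apply_track = samples
    model = bias_mod.fit_bias_model(fit_track)
    sig = bias_mod.correct_track(apply_track, model)

    t = model.table.set_index("context")
    tc = [c for c in t.index if c[0] == "T"]
    gc = [c for c in t.index if c[0] == "G"]
    tc_gc = (np.average(t.loc[tc, "expected_rate"], weights=t.loc[tc, "count"])
             / np.average(t.loc[gc, "expected_rate"], weights=t.loc[gc, "count"]))

    d = apply_track.data.copy()
    d["raw"] = d["n_conv"] / d["n_total"]
    d = d.merge(sig.data[["chrom", "pos", "strand", "rate"]],
                on=["chrom", "pos", "strand"])

    def context_cv(col):
        means = d.groupby("context").apply(
            lambda s: np.average(s[col], weights=s["n_total"]),
            include_groups=False)
        return float(means.std() / means.mean())

    return {
        "tc_gc_rate_ratio": float(tc_gc),
        "corrected_over_uncorrected_cv": context_cv("rate") / context_cv("raw"),
        "n_molecules": 2 * n_molecules,
    }


_FOS_CONSENSUS = "TGACGTCACGCG"


def _one_site_fos(seed, theta, n_molecules, p_open, p_protected):
    cfg = SimulationConfig(
        seed=seed, contigs={"chrSim": 4000}, ocrs=[("chrSim", 500, 3500)],
        tf_sites=[TFSite("TF1", _FOS_CONSENSUS, 2000, theta)],
        p_open=p_open, p_protected=p_protected, n_molecules=n_molecules,
        restrict_to=[("chrSim", 1600, 2400)], fragment_len_mean=250,
        fragment_len_sd=40)
    ref = simulate_reference(cfg)
    track = pipeline_track(simulate_molecules(ref, cfg))
    sig = SignalTrack.from_counts(track)
    site = BindingSite("chrSim", 2000, 2000 + len(_FOS_CONSENSUS), "+", "M", "TF1")
    return quant.compute_fos(sig, site).fos


def occupancy_fos_sweep(seed: int, thetas=tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
                        n_molecules: int = 2000, replicates: int = 5,
                        p_open: float = 0.6, p_protected: float = 0.05) -> dict:
    """Mean FOS across an occupancy grid versus the closed-form expectation
    theta * (p_open - p_protected) under the generative model."""
    rng = np.random.default_rng(seed)
    rows = []
    for theta in thetas:
        vals = [_one_site_fos(_rng_seed(rng), theta, n_molecules, p_open,
                              p_protected) for _ in range(replicates)]
        vals = np.array(vals)
        rows.append((theta, vals.mean(), vals.std(ddof=1) / np.sqrt(replicates),
                     theta * (p_open - p_protected)))
    table = pd.DataFrame(rows, columns=["theta", "mean_fos", "se", "expected"])
    dev = (table["mean_fos"] - table["expected"]).to_numpy()
    z = dev / table["se"].to_numpy()
    return {
        "table": table,
        "max_abs_error": float(np.abs(dev).max()),
        "max_abs_z": float(np.abs(z).max()),
        "chi2": float((z**2).sum()),
        "n_thetas": len(table),
        "monotone": bool((np.diff(table["mean_fos"]) > 0).all()),
    }


_MOLECULE_CONSENSUS = "CG" * 10  # 10 informative cytosines per strand


def bound_fraction_sweep(seed: int,
                         thetas=tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
                         n_molecules: int = 2000, p_open: float = 0.8,
                         p_protected: float = 0.05) -> dict:
    """Single-molecule bound fractions across the occupancy grid.

    Uses a cytosine-rich site (10 per strand) so per-read calls are well
    determined at the default 1/3 / 2/3 thresholds."""
    rng = np.random.default_rng(seed)
    rows = []
    for theta in thetas:
        cfg = SimulationConfig(
            seed=_rng_seed(rng), contigs={"chrSim": 3000},
            ocrs=[("chrSim", 500, 2500)],
            tf_sites=[TFSite("TF1", _MOLECULE_CONSENSUS, 1500, theta)],
            p_open=p_open, p_protected=p_protected, n_molecules=n_molecules,
            restrict_to=[("chrSim", 1350, 1700)], fragment_len_mean=300)
        ref = simulate_reference(cfg)
        ds = simulate_molecules(ref, cfg)
        with tempfile.TemporaryDirectory() as tmp:
            fasta, sam = str(Path(tmp) / "r.fa"), str(Path(tmp) / "r.sam")
            ds.write_fasta(fasta)
            ds.write_sam(sam)
            observations = tracks.iter_read_observations(sam, fasta, min_mapq=0,
                                                         min_baseq=0)
        site = BindingSite("chrSim", 1500, 1500 + len(_MOLECULE_CONSENSUS),
                           "+", "M", "TF1")
        calls = molecule.classify_molecules(observations, site)
        bf = molecule.site_bound_fraction(calls)
        rows.append((theta, bf.fraction, bf.n_determinate))
    table = pd.DataFrame(rows, columns=["theta", "bound_fraction", "n_determinate"])
    err = (table["bound_fraction"] - table["theta"]).abs()
    return {"table": table, "max_abs_error": float(err.max()),
            "n_molecules_per_theta": n_molecules}


def s2_null_fdr(seed: int, replicates: int = 50, region_len: int = 2000,
                n_molecules: int = 600) -> dict:
    """Uniform-null simulations: fraction of S2 windows reaching q < 0.05."""
    rng = np.random.default_rng(seed)
    fractions, n_sig, n_valid = [], 0, 0
    for _ in range(replicates):
        cfg = SimulationConfig(
            seed=_rng_seed(rng), contigs={"chrSim": region_len + 1000},
            ocrs=[("chrSim", 0, region_len + 1000)], n_molecules=n_molecules,
            restrict_to=[("chrSim", 300, region_len + 700)],
            fragment_len_mean=250)
        ref = simulate_reference(cfg)
        track = pipeline_track(simulate_molecules(ref, cfg))
        sig = SignalTrack.from_counts(track)
        _, windows = denovo.detect_footprint_regions_s2(
            sig, [("chrSim", 500, 500 + region_len)], return_windows=True)
        valid = windows[windows["valid"]]
        sig_n = int((valid["q_value"] < 0.05).sum())
        n_sig += sig_n
        n_valid += len(valid)
        fractions.append(sig_n / len(valid) if len(valid) else 0.0)
    fractions = np.array(fractions)
    return {
        "fdr": n_sig / n_valid if n_valid else 0.0,
        "mc_error": float(fractions.std(ddof=1) / np.sqrt(replicates)),
        "n_windows": n_valid,
        "n_replicates": replicates,
    }


def s2_footprint_recovery(seed: int, replicates: int = 10,
                          n_molecules: int = 2000, theta: float = 0.9) -> dict:
    """Planted 12 bp footprints: recall and boundary placement of S2 calls."""
    rng = np.random.default_rng(seed)
    consensus = _FOS_CONSENSUS  # 12 bp
    recovered, boundary_errors = 0, []
    for _ in range(replicates):
        cfg = SimulationConfig(
            seed=_rng_seed(rng), contigs={"chrSim": 4000},
            ocrs=[("chrSim", 500, 3500)],
            tf_sites=[TFSite("TF1", consensus, 2000, theta)],
            n_molecules=n_molecules, restrict_to=[("chrSim", 1000, 3000)],
            fragment_len_mean=250)
        ref = simulate_reference(cfg)
        track = pipeline_track(simulate_molecules(ref, cfg))
        sig = SignalTrack.from_counts(track)
        calls = denovo.detect_footprint_regions_s2(sig, [("chrSim", 1200, 2800)])
        true = (2000, 2000 + len(consensus))
        hit = [c for c in calls if c.start < true[1] and c.end > true[0]]
        if hit:
            recovered += 1
            best = hit[0]
            boundary_errors.append((abs(best.start - true[0])
                                    + abs(best.end - true[1])) / 2)
    return {
        "recall": recovered / replicates,
        "mean_boundary_error_bp": (float(np.mean(boundary_errors))
                                   if boundary_errors else float("nan")),
        "n_replicates": replicates,
    }


def differential_spikein(seed: int, n_clusters: int = 21,
                         sites_per_cluster: int = 25, coverage: float = 50.0,
                         theta_base: float = 0.8, theta_spiked: float = 0.1) -> dict:
    """Two-condition spike-in: one TF cluster loses occupancy, all others
    are held constant; measures whether the spiked cluster is the top
    negative differential hit and how many unchanged clusters stay
    non-significant."""
    rng = np.random.default_rng(seed)
    spacing = 300
    n_sites = n_clusters * sites_per_cluster
    contig_len = (n_sites + 4) * spacing
    order = rng.permutation(n_sites)
    site_specs, universe = [], []
    for rank, site_idx in enumerate(order):
        cluster = site_idx % n_clusters
        pos = (rank + 2) * spacing
        site_specs.append((pos, cluster))
        universe.append(BindingSite("chrD", pos, pos + len(_FOS_CONSENSUS), "+",
                                    f"M{cluster}", f"TF{cluster}"))
    n_mol = int(contig_len * coverage / 250)

    def run_condition(spike: bool):
        tf_sites = [
            TFSite(f"s{i}", _FOS_CONSENSUS, pos,
                   theta_spiked if (spike and cluster == 0) else theta_base,
                   chrom="chrD")
            for i, (pos, cluster) in enumerate(site_specs)]
        cfg = SimulationConfig(
            seed=_rng_seed(rng), contigs={"chrD": contig_len},
            ocrs=[("chrD", 0, contig_len)], tf_sites=tf_sites,
            n_molecules=n_mol, fragment_len_mean=250)
        ref = simulate_reference(cfg)
        track = pipeline_track(simulate_molecules(ref, cfg))
        sig = SignalTrack.from_counts(track)
        rows = []
        for s in universe:
            rec = quant.compute_fos(sig, s)
            if rec.valid:
                rows.append((s.chrom, s.start, s.end, s.motif_id, rec.fos))
        return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                           "motif_id", "score"])

    scored_a = run_condition(spike=False)
    scored_b = run_condition(spike=True)
    clusters = {f"C{k}": [f"M{k}"] for k in range(n_clusters)}
    results = denovo.differential_binding(scored_a, scored_b, clusters,
                                          rng=np.random.default_rng(_rng_seed(rng)))
    ranked = sorted(results, key=lambda r: r.differential_score)
    spiked = next(r for r in results if r.tf_cluster == "C0")
    others = [r for r in results if r.tf_cluster != "C0"]
    return {
        "spiked_is_top_negative": ranked[0].tf_cluster == "C0",
        "spiked_q": spiked.q_value,
        "spiked_direction": spiked.direction,
        "unchanged_nonsignificant_fraction": float(
            np.mean([r.q_value >= 0.05 for r in others])),
        "n_clusters": n_clusters,
    }


def dynamics_series(seed: int, n_sites: int = 40, coverage: float = 60.0,
                    theta: float = 0.7, p_open_control: float = 0.6,
                    p_open_treated: float = 0.3) -> dict:
    """Chromatin-remodeler-inhibition regime: accessibility (p_open) halves
    while TF occupancy (theta) stays constant.

    Flanking accessibility is read off the raw corrected rates; TFOS is
    computed on tracks normalized to a common reference conversion rate, the
    standard cross-sample procedure when global conversion differs between
    conditions.  The expected phenotype: flanking-accessibility change ratio
    strongly negative, TFOS change ratio mild."""
    rng = np.random.default_rng(seed)
    spacing = 400
    contig_len = (n_sites + 4) * spacing
    positions = [(i + 2) * spacing for i in range(n_sites)]
    tf_sites = [TFSite(f"s{i}", _FOS_CONSENSUS, p, theta, chrom="chrT")
                for i, p in enumerate(positions)]
    universe = [BindingSite("chrT", p, p + len(_FOS_CONSENSUS), "+", "M", "TF")
                for p in positions]
    n_mol = int(contig_len * coverage / 250)

    def run(p_open):
        cfg = SimulationConfig(
            seed=_rng_seed(rng), contigs={"chrT": contig_len},
            ocrs=[("chrT", 0, contig_len)], tf_sites=tf_sites, p_open=p_open,
            n_molecules=n_mol, fragment_len_mean=250)
        ref = simulate_reference(cfg)
        return pipeline_track(simulate_molecules(ref, cfg))

    control, treated = run(p_open_control), run(p_open_treated)
    reference_rate = control.global_rate

    def measure(track):
        raw = SignalTrack.from_counts(track)
        norm = tracks.normalize_track(track, reference_rate)
        flank = np.nanmean([quant.flanking_accessibility(raw, s)[0]
                            for s in universe])
        recs = [quant.compute_fos(norm, s) for s in universe]
        return float(flank), quant.compute_tfos(recs, tf_name="TF").tfos

    flank_c, tfos_c = measure(control)
    flank_t, tfos_t = measure(treated)
    return {
        "flank_access_change_ratio": quant.change_ratio(flank_t, flank_c,
                                                        n_sites=n_sites,
                                                        min_sites=1),
        "tfos_change_ratio": quant.change_ratio(tfos_t, tfos_c,
                                                n_sites=n_sites, min_sites=1),
        "n_sites": n_sites,
    }


def oracle_equivalences(seed: int) -> dict:
    """Exact agreement of core primitives with brute-force re-implementations:
    pileup counting, BH correction, windowed smoothing, interval assignment."""
    rng = np.random.default_rng(seed)
    out = {}

    # pileup vs per-molecule recount
    cfg = SimulationConfig(seed=_rng_seed(rng), contigs={"chrSim": 3000},
                           ocrs=[("chrSim", 500, 2500)], n_molecules=100,
                           fragment_len_mean=200)
    ref = simulate_reference(cfg)
    ds = simulate_molecules(ref, cfg)
    track = pipeline_track(ds)
    expected: dict = {}
    for mol in ds.truth.molecules:
        if len(mol.cytosine_pos) == 0 or not mol.converted.any():
            continue  # undetermined-strand molecules are dropped upstream
        for pos, conv in zip(mol.cytosine_pos, mol.converted):
            key = (mol.chrom, int(pos), mol.strand)
            nt, nc = expected.get(key, (0, 0))
            expected[key] = (nt + 1, nc + int(conv))
    got = {(r.chrom, r.pos, r.strand): (r.n_total, r.n_conv)
           for r in track.data.itertuples()}
    out["pileup_exact"] = got == expected

    # BH vs step-up definition
    p = rng.uniform(0, 1, 800)
    m = len(p)
    order = np.argsort(p)
    q_oracle = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        prev = min(prev, p[idx] * m / (m - rank_from_top))
        q_oracle[idx] = prev
    out["bh_exact"] = bool(np.allclose(denovo.bh_adjust(p), q_oracle, atol=1e-12))

    # smoothing vs brute-force windowed mean
    pos = np.sort(rng.choice(np.arange(2000), 300, replace=False))
    rates = rng.random(300)
    sig = SignalTrack(pd.DataFrame({"chrom": "c", "pos": pos, "strand": "+",
                                    "rate": rates, "n_total": 10}))
    sm = molecule.smooth_track(sig, window=5)
    lookup = dict(zip(pos, rates))
    ok = all(np.isclose(v, np.mean([lookup[q] for q in range(p0 - 2, p0 + 3)
                                    if q in lookup]))
             for p0, v in zip(sm["pos"], sm["rate_smooth"]))
    out["smoothing_exact"] = bool(ok)

    # interval assignment vs linear scan
    regions = {f"L{k}": [("c", int(s), int(s) + int(w))
                         for s, w in zip(rng.integers(0, 5000, 25),
                                         rng.integers(10, 400, 25))]
               for k in range(3)}
    sites = [BindingSite("c", int(p), int(p) + 10) for p in
             rng.integers(0, 5200, 150)]
    table = quant.stratify_sites(sites, regions)
    got_pairs = {(r.site_index, r.label) for r in table.itertuples()}
    exp_pairs = set()
    for i, s in enumerate(sites):
        hits = [lab for lab, ivs in regions.items()
                if any(a <= s.center < b for _, a, b in ivs)]
        for lab in hits or ["background"]:
            exp_pairs.add((i, lab))
    out["interval_assignment_exact"] = got_pairs == exp_pairs
    out["all_exact"] = all(out.values())
    return out
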