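"""TF occupancy at known binding sites.

The footprint occupancy score (FOS) of a binding site is the mean corrected
conversion rate over the two 50 bp flanks minus the mean over the motif
itself: a bound factor shields motif cytosines, so deeper depletion means
higher occupancy.  TFOS averages FOS over a factor's sites, optionally
within one chromatin class (open/closed regions, histone-mark strata).  The
mean flank rate alone is the flanking chromatin accessibility, and relative
score changes between conditions ((treated - control) / control) track
occupancy and accessibility dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .tracks import SignalTrack


@dataclass
class BindingSite:
    chrom: str
    start: int
    end: int
    strand: str = "+"
    motif_id: str = ""
    tf_name: str = ""
    source: str = "scanned"  # or 'chip_defined'
    score: float | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"binding site end <= start: {self}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class FOSRecord:
    site: BindingSite
    motif_rate: float
    flank_rate: float
    n_motif_c: int
    n_flank_c: int
    fos: float
    valid: bool
    reason: str = ""
    truncated: bool = False


@dataclass
class TFOSRecord:
    tf_name: str
    region_label: str
    n_sites: int
    tfos: float
    positive_fraction: float
    flank_access: float
    reason_counts: dict = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return self.n_sites == 0


def _region_mean(pos: np.ndarray, rate: np.ndarray,
                 intervals: list) -> tuple[float, int]:
    vals = []
    for s, e in intervals:
        lo, hi = np.searchsorted(pos, (s, e))
        vals.append(rate[lo:hi])
    v = np.concatenate(vals) if vals else np.empty(0)
    v = v[np.isfinite(v)]
    return (float(v.mean()) if len(v) else float("nan")), int(len(v))


def compute_fos(signal: SignalTrack, site: BindingSite, flank: int = 50,
                min_c: int = 2) -> FOSRecord:
    """Footprint occupancy score: mean flank rate minus mean motif rate.

    Both strands are pooled; records with fewer than min_c informative
    cytosines on either side are marked invalid (guards AT-rich motifs that
    carry too few cytosines to score).
    """
    arrays = signal.chrom_arrays()
    if site.chrom not in arrays:
        return FOSRecord(site, np.nan, np.nan, 0, 0, np.nan, False, "no data on contig")
    pos, rate, _ = arrays[site.chrom]
    motif_rate, n_motif = _region_mean(pos, rate, [(site.start, site.end)])
    flank_rate, n_flank = _region_mean(
        pos, rate, [(site.start - flank, site.start), (site.end, site.end + flank)])
    fos = flank_rate - motif_rate
    if n_motif < min_c:
        return FOSRecord(site, motif_rate, flank_rate, n_motif, n_flank, fos,
                         False, "too few motif cytosines")
    if n_flank < min_c:
        return FOSRecord(site, motif_rate, flank_rate, n_motif, n_flank, fos,
                         False, "too few flank cytosines")
    return FOSRecord(site, motif_rate, flank_rate, n_motif, n_flank, fos, True)


def flanking_accessibility(signal: SignalTrack, site: BindingSite,
                           flank: int = 50) -> tuple[float, bool]:
    """Mean corrected rate over the 50 bp windows on both sides of the motif.

    Returns (rate, truncated): truncated flags a site whose flank runs off
    the contig end, in which case only the existing flank contributes.
    """
    arrays = signal.chrom_arrays()
    if site.chrom not in arrays:
        return float("nan"), False
    pos, rate, _ = arrays[site.chrom]
    contig_hi = int(pos[-1]) + 1 if len(pos) else 0
    left = (max(site.start - flank, 0), site.start)
    right = (site.end, site.end + flank)
    truncated = site.start - flank < 0 or site.end + flank > contig_hi
    val, _ = _region_mean(pos, rate, [left, right])
    return val, truncated


def compute_tfos(fos_records: list, tf_name: str = "", region_label: str = "all",
                 region_filter=None, positive_only: bool = False) -> TFOSRecord:
    """Average FOS over a factor's valid sites.

    region_filter, if given, is a callable BindingSite -> bool (for example a
    closure over one chromatin-class interval set).  positive_only restricts
    to sites with FOS > 0, the variant used when correlating against
    ChIP-seq strength.
    """
    reasons: dict = {}
    kept = []
    for rec in fos_records:
        if region_filter is not None and not region_filter(rec.site):
            continue
        if not rec.valid:
            reasons[rec.reason] = reasons.get(rec.reason, 0) + 1
            continue
        if positive_only and not rec.fos > 0:
            reasons["non-positive FOS"] = reasons.get("non-positive FOS", 0) + 1
            continue
        kept.append(rec)
    if not kept:
        return TFOSRecord(tf_name, region_label, 0, float("nan"), float("nan"),
                          float("nan"), reasons)
    fos = np.array([r.fos for r in kept])
    flank = np.array([r.flank_rate for r in kept])
    return TFOSRecord(tf_name, region_label, len(kept), float(fos.mean()),
                      float((fos > 0).mean()), float(flank.mean()), reasons)


def change_ratio(score_treated: float, score_control: float,
                 control_floor: float = 0.02, n_sites: int | None = None,
                 min_sites: int = 200) -> float:
    """Relative score change (treated - control) / control.

    Controls with unrobust scores (below control_floor, or supported by too
    few sites) are excluded rather than producing unstable ratios.
    """
    if not np.isfinite(score_control) or score_control < control_floor:
        raise ValueError(
            f"control score {score_control} below robustness floor {control_floor}")
    if n_sites is not None and n_sites < min_sites:
        raise ValueError(f"control supported by {n_sites} sites < {min_sites}")
    return (score_treated - score_control) / score_control


def tfos_change_table(treated: dict, control: dict, control_floor: float = 0.02,
                      min_sites: int = 200) -> pd.DataFrame:
    """Per-TF change ratios between two conditions of TFOSRecord dicts
    (tf_name -> record); TFs failing the robustness floor are reported with
    the exclusion reason and a NaN ratio."""
    rows = []
    for tf, ctl in control.items():
        trt = treated.get(tf)
        if trt is None:
            continue
        try:
            ratio = change_ratio(trt.tfos, ctl.tfos, control_floor,
                                 n_sites=ctl.n_sites, min_sites=min_sites)
            rows.append((tf, trt.tfos, ctl.tfos, ratio, ""))
        except ValueError as exc:
            rows.append((tf, trt.tfos, ctl.tfos, float("nan"), str(exc)))
    return pd.DataFrame(rows, columns=["tf_name", "tfos_treated", "tfos_control",
                                       "change_ratio", "excluded_reason"])


def profile_matrix(signal: SignalTrack, sites: list,
                   half_window: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Per-site positional rate matrix around motif centers.

    Rows are sites, columns run -half_window..+half_window relative to the
    motif center floor((start+end)/2); minus-strand rows are reversed so the
    motif 5' end is always on the left.  Cells without an informative
    cytosine are NaN; np.nanmean over columns gives the average profile.
    """
    arrays = signal.chrom_arrays()
    width = 2 * half_window + 1
    mat = np.full((len(sites), width), np.nan)
    offsets = np.arange(-half_window, half_window + 1)
    for i, site in enumerate(sites):
        if site.chrom not in arrays:
            continue
        pos, rate, _ = arrays[site.chrom]
        c = site.center
        lo, hi = np.searchsorted(pos, (c - half_window, c + half_window + 1))
        cols = pos[lo:hi] - (c - half_window)
        mat[i, cols] = rate[lo:hi]
        if site.strand == "-":
            mat[i] = mat[i, ::-1]
    return mat, offsets


def stratify_sites(sites: list, labeled_region_sets: dict,
                   priority: list | None = None) -> pd.DataFrame:
    """Assign each site to a chromatin-class label by its motif center.

    Returns a long-form table (site_index, label, primary): every matching
    label is retained as a row, and `primary` marks the single assignment
    chosen by the priority order (first label listed wins on overlap).
    Sites matching nothing get the label 'background'.
    """
    priority = priority if priority is not None else list(labeled_region_sets)
    trees: dict = {}
    for label, regions in labeled_region_sets.items():
        for chrom, start, end in regions:
            if end > start:
                trees.setdefault((label, chrom), IntervalTree()).addi(start, end)
    rows = []
    for idx, site in enumerate(sites):
        hits = [lab for lab in labeled_region_sets
                if (lab, site.chrom) in trees
                and trees[(lab, site.chrom)].overlaps_point(site.center)]
        if not hits:
            rows.append((idx, "background", True))
            continue
        primary = min(hits, key=lambda lab: priority.index(lab)
                      if lab in priority else len(priority))
        for lab in hits:
            rows.append((idx, lab, lab == primary))
    return pd.DataFrame(rows, columns=["site_index", "label", "primary"])


def read_sites_bed(path: str, source: str = "chip_defined") -> list:
    """BED6 binding sites; the name field carries motif_id[:tf_name]."""
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            name = parts[3] if len(parts) > 3 else ""
            motif_id, _, tf = name.partition(":")
            score = float(parts[4]) if len(parts) > 4 and parts[4] not in (".", "") else None
            strand = parts[5] if len(parts) > 5 else "+"
            sites.append(BindingSite(parts[0], int(parts[1]), int(parts[2]),
                                     strand, motif_id, tf or motif_id, source, score))
    return sites


def fos_table(records: list) -> pd.DataFrame:
    rows = [(r.site.chrom, r.site.start, r.site.end, r.site.strand,
             r.site.motif_id, r.site.tf_name, r.motif_rate, r.flank_rate,
             r.n_motif_c, r.n_flank_c, r.fos, r.valid, r.reason)
            for r in records]
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "strand", "motif_id", "tf_name",
        "motif_rate", "flank_rate", "n_motif_c", "n_flank_c", "fos",
        "valid", "reason"])
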