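"""Single-molecule and single-cell occupancy.

Each sequenced molecule carries its own conversion record: cytosines inside
a motif window that stayed unconverted on a read imply the site was
protein-bound on that molecule, converted cytosines imply it was free.  A
read is called bound when at most a third of its informative motif
cytosines converted, unbound when at least two thirds did, ambiguous in
between or when it covers too few cytosines.  Joint calls of two sites on
the same molecule give co-occupancy contingency tables; per-barcode
aggregation gives single-cell tracks.

Calls use raw per-read conversion: context-bias correction is a rate-level
transform and does not apply to single binary base calls, so the assessment
window instead requires a minimum number of cytosines to dilute context
effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .tracks import ConversionTrack, ReadObservation, SignalTrack, TRACK_COLUMNS
from .quant import BindingSite


@dataclass
class MoleculeCallParams:
    pad: int = 2  # assessment window = motif +/- pad
    min_c: int = 2
    t_bound: float = 1 / 3  # bound when converted fraction <= t_bound
    t_unbound: float = 2 / 3  # unbound when >= t_unbound


@dataclass
class MoleculeCall:
    read_id: str
    site: BindingSite
    n_informative: int
    n_converted: int
    state: str  # 'bound' | 'unbound' | 'ambiguous'


def classify_molecule(observation: ReadObservation, site: BindingSite,
                      params: MoleculeCallParams | None = None) -> MoleculeCall | None:
    """Call one molecule bound/unbound/ambiguous at one site.

    Returns None (no call) when the read has no conversion call inside the
    assessment window at all; a covered-but-thin window is ambiguous.
    """
    params = params or MoleculeCallParams()
    lo, hi = site.start - params.pad, site.end + params.pad
    inside = [(pos, conv) for chrom, pos, _, conv in observation.calls
              if chrom == site.chrom and lo <= pos < hi]
    if not inside:
        return None
    n_inf = len(inside)
    n_conv = sum(1 for _, conv in inside if conv)
    if n_inf < params.min_c:
        state = "ambiguous"
    else:
        frac = n_conv / n_inf
        if frac <= params.t_bound:
            state = "bound"
        elif frac >= params.t_unbound:
            state = "unbound"
        else:
            state = "ambiguous"
    return MoleculeCall(observation.read_id, site, n_inf, n_conv, state)


def classify_molecules(observations: list, site: BindingSite,
                       params: MoleculeCallParams | None = None) -> list:
    calls = []
    for obs in observations:
        call = classify_molecule(obs, site, params)
        if call is not None:
            calls.append(call)
    return calls


@dataclass
class BoundFraction:
    fraction: float
    ci_low: float
    ci_high: float
    n_bound: int
    n_unbound: int
    n_ambiguous: int

    @property
    def n_determinate(self) -> int:
        return self.n_bound + self.n_unbound


def site_bound_fraction(calls: list) -> BoundFraction:
    """Bound / (bound + unbound) with a Wilson 95% CI; ambiguous molecules
    are excluded from the ratio but counted."""
    n_b = sum(1 for c in calls if c.state == "bound")
    n_u = sum(1 for c in calls if c.state == "unbound")
    n_a = sum(1 for c in calls if c.state == "ambiguous")
    if n_b + n_u == 0:
        raise ValueError("no determinate molecule calls at this site")
    lo, hi = proportion_confint(n_b, n_b + n_u, alpha=0.05, method="wilson")
    return BoundFraction(n_b / (n_b + n_u), float(lo), float(hi), n_b, n_u, n_a)


@dataclass
class CooccupancyTable:
    site_a: BindingSite
    site_b: BindingSite
    n_bb: int
    n_bu: int
    n_ub: int
    n_uu: int
    odds_ratio: float
    fisher_p: float
    low_power: bool

    @property
    def n_joint(self) -> int:
        return self.n_bb + self.n_bu + self.n_ub + self.n_uu

    def fractions(self) -> dict:
        n = self.n_joint
        return {k: getattr(self, f"n_{k}") / n if n else float("nan")
                for k in ("bb", "bu", "ub", "uu")}


def cooccupancy(calls_a: list, calls_b: list,
                min_joint: int = 20) -> CooccupancyTable:
    """Joint bound/unbound states of two sites over shared molecules.

    Only molecules determinate at both sites enter the 2x2 table; the odds
    ratio is Haldane-corrected (+0.5 per cell) and the p-value is a
    two-sided Fisher exact test.
    """
    a = {c.read_id: c.state for c in calls_a if c.state != "ambiguous"}
    b = {c.read_id: c.state for c in calls_b if c.state != "ambiguous"}
    n = {"bb": 0, "bu": 0, "ub": 0, "uu": 0}
    for rid, sa in a.items():
        sb = b.get(rid)
        if sb is None:
            continue
        key = ("b" if sa == "bound" else "u") + ("b" if sb == "bound" else "u")
        n[key] += 1
    table = [[n["bb"], n["bu"]], [n["ub"], n["uu"]]]
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    oddsr = ((n["bb"] + 0.5) * (n["uu"] + 0.5)) / ((n["bu"] + 0.5) * (n["ub"] + 0.5))
    total = sum(n.values())
    site_a = calls_a[0].site if calls_a else None
    site_b = calls_b[0].site if calls_b else None
    return CooccupancyTable(site_a, site_b, n["bb"], n["bu"], n["ub"], n["uu"],
                            float(oddsr), float(fisher_p), total < min_joint)


def calls_table(calls: list) -> pd.DataFrame:
    rows = [(c.read_id, c.site.chrom, c.site.start, c.site.end, c.site.motif_id,
             c.n_informative, c.n_converted, c.state) for c in calls]
    return pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end",
                                       "motif_id", "n_informative",
                                       "n_converted", "state"])


# ---------------------------------------------------------------------------
# single cells

def _track_from_calls(calls: list, sample_id: str) -> ConversionTrack:
    counts: dict = {}
    for chrom, pos, strand, conv in calls:
        key = (chrom, pos, strand)
        nt, nc = counts.get(key, (0, 0))
        counts[key] = (nt + 1, nc + (1 if conv else 0))
    rows = [(c, p, s, nc, nt, "NCN") for (c, p, s), (nt, nc) in sorted(counts.items())]
    data = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    track = ConversionTrack(data, sample_id=sample_id)
    track.global_rate = track.compute_global_rate(min_total=1)
    return track


def per_cell_tracks(observations: list, whitelist: set | None = None) -> dict:
    """One conversion track per barcode plus a merged track.

    Reads without a barcode land in 'unassigned'; with a whitelist,
    non-listed barcodes are routed to 'unassigned' as well.  The merged
    track sums the per-cell counts exactly (the whitelist filter applies to
    cells and merged alike).
    """
    by_cell: dict = {}
    for obs in observations:
        bc = obs.barcode
        if bc is None or (whitelist is not None and bc not in whitelist):
            bc = "unassigned"
        by_cell.setdefault(bc, []).extend(obs.calls)
    tracks = {bc: _track_from_calls(calls, sample_id=bc)
              for bc, calls in by_cell.items()}
    merged_calls = [call for bc, calls in by_cell.items() if bc != "unassigned"
                    for call in calls]
    tracks["merged"] = _track_from_calls(merged_calls, sample_id="merged")
    return tracks


def smooth_track(signal, window: int = 5) -> pd.DataFrame:
    """Centered moving average over informative positions within +/- window//2 bp.

    Accepts a SignalTrack or a ConversionTrack; positions with no
    informative cytosine anywhere in their window stay absent (missing, not
    zero), matching sparse single-cell data where empty stretches are
    rendered as no-data.
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    half = window // 2
    if isinstance(signal, ConversionTrack):
        signal = SignalTrack.from_counts(signal)
    out = []
    for chrom, (pos, rate, _) in signal.chrom_arrays().items():
        finite = np.isfinite(rate)
        pos_f, rate_f = pos[finite], rate[finite]
        csum = np.concatenate([[0.0], np.cumsum(rate_f)])
        lo = np.searchsorted(pos_f, pos - half)
        hi = np.searchsorted(pos_f, pos + half + 1)
        n = hi - lo
        smoothed = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
        out.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                 "rate_smooth": smoothed}))
    return (pd.concat(out, ignore_index=True) if out
            else pd.DataFrame(columns=["chrom", "pos", "rate_smooth"]))
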