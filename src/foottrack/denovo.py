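"""De novo footprint prediction and differential TF binding.

Two complementary strategies over bias-corrected conversion tracks restricted
to open chromatin:

* FootprintScan (S1) scores every motif occurrence by its conversion
  depletion against a local or global background and calibrates significance
  with an empirical positional null drawn from the same search regions.
* FootprintRegion (S2) first calls conversion-depleted intervals with a
  one-sided binomial test in sliding windows (BH-corrected), then scans for
  motifs inside the called regions.

Differential binding between two conditions compares cluster-level mean
footprint scores after quantile normalization, with a size-matched random
resampling null providing z and p values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from Bio import motifs as bio_motifs
from Bio.motifs.thresholds import ScoreDistribution

from .tracks import SignalTrack
from .quant import BindingSite

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_UNIFORM_BG = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# motif models and scanning

@dataclass
class MotifModel:
    motif_id: str
    tf_name: str
    counts: np.ndarray  # 4 x L, rows A,C,G,T
    background: dict = field(default_factory=lambda: dict(_UNIFORM_BG))
    pseudocount: float = 0.5

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError("motif matrix must be 4 x L with L >= 4")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def pwm(self) -> np.ndarray:
        c = self.counts + self.pseudocount
        return c / c.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        bg = np.array([self.background[b] for b in "ACGT"])[:, None]
        with np.errstate(divide="raise"):
            return np.log2(self.pwm / bg)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.counts, axis=0))

    def score_threshold(self, pvalue: float = 1e-4, precision: int = 10 ** 4) -> float:
        """Log-odds cutoff whose tail probability under the background equals
        `pvalue`, from the exact score distribution (dynamic programming)."""
        bio = self._to_biopython()
        pssm = bio.counts.normalize(pseudocounts=self.pseudocount).log_odds(
            self.background)
        dist = ScoreDistribution(pssm=pssm, background=self.background,
                                 precision=precision)
        return float(dist.threshold_fpr(pvalue))

    def _to_biopython(self):
        instances = {b: list(self.counts["ACGT".index(b)]) for b in "ACGT"}
        m = bio_motifs.Motif(alphabet="ACGT",
                             counts={b: instances[b] for b in "ACGT"})
        return m

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str, weight: float = 100.0,
                       off: float = 1.0, tf_name: str = "") -> "MotifModel":
        counts = np.full((4, len(consensus)), off)
        for j, base in enumerate(consensus.upper()):
            counts[_CODE[base], j] = weight
        return cls(motif_id, tf_name or motif_id, counts)

    @classmethod
    def from_biopython(cls, motif, motif_id: str | None = None) -> "MotifModel":
        counts = np.array([list(motif.counts[b]) for b in "ACGT"], dtype=float)
        mid = motif_id or getattr(motif, "matrix_id", None) or motif.name or "motif"
        return cls(mid, motif.name or mid, counts)


def load_motifs(path: str, fmt: str = "jaspar") -> list:
    """Read JASPAR PFM or MEME minimal motif files."""
    parser_fmt = {"jaspar": "jaspar", "pfm": "pfm-four-columns",
                  "meme": "minimal"}.get(fmt, fmt)
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, parser_fmt)
        return [MotifModel.from_biopython(m) for m in parsed]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(256, 4, dtype=np.int8)
    for base, i in _CODE.items():
        code[ord(base)] = i
    return code[arr]


def _scan_scores(codes: np.ndarray, lo_matrix: np.ndarray) -> np.ndarray:
    """Log-odds score at each start position; windows containing N score -inf."""
    L = lo_matrix.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    padded = np.vstack([lo_matrix, np.full((1, L), -np.inf)])
    scores = np.zeros(n)
    for j in range(L):
        scores += padded[codes[j: j + n], j]
    return scores


def _resolve_overlaps(hits: list) -> list:
    """Among overlapping hits of one motif (either strand), keep the best score."""
    hits = sorted(hits, key=lambda h: -h.score)
    kept: list = []
    for h in hits:
        if any(k.chrom == h.chrom and h.start < k.end and k.start < h.end
               for k in kept):
            continue
        kept.append(h)
    return sorted(kept, key=lambda h: (h.chrom, h.start))


def scan_motifs(reference: dict, motif_models: list, regions: list,
                pvalue_threshold: float = 1e-4) -> list:
    """PWM scan of both strands restricted to the given search regions.

    Thresholds are calibrated per motif so a random background position
    passes with probability `pvalue_threshold`.  Overlapping hits of the
    same motif are resolved to the best-scoring one.
    """
    out: list = []
    for model in motif_models:
        if np.any(model.counts.sum(axis=0) == 0) and model.pseudocount == 0:
            raise ValueError(f"motif {model.motif_id} has a zero column and no pseudocount")
        thr = model.score_threshold(pvalue_threshold)
        lo = model.log_odds
        L = model.length
        hits: list = []
        for chrom, start, end in regions:
            seq = reference[chrom][start:end]
            codes = _encode(seq)
            fwd = _scan_scores(codes, lo)
            rc = np.where(codes == 4, 4, 3 - codes)[::-1]
            rev = _scan_scores(rc, lo)
            for i in np.flatnonzero(fwd >= thr):
                hits.append(BindingSite(chrom, start + i, start + i + L, "+",
                                        model.motif_id, model.tf_name, "scanned",
                                        float(fwd[i])))
            for i in np.flatnonzero(rev >= thr):
                j = len(codes) - L - i  # map the rc hit back to forward coordinates
                hits.append(BindingSite(chrom, start + j, start + j + L, "-",
                                        model.motif_id, model.tf_name, "scanned",
                                        float(rev[i])))
        out.extend(_resolve_overlaps(hits))
    return out


# ---------------------------------------------------------------------------
# backgrounds

def local_background_rate(signal: SignalTrack, interval: tuple,
                          span: int = 200) -> float:
    """Mean corrected rate over +/- span around an interval, excluding it.

    Returns NaN when no informative cytosine falls in the ring; callers fall
    back to the global background.
    """
    chrom, start, end = interval
    if span <= end - start:
        raise ValueError("background span must exceed the interval width")
    arrays = signal.chrom_arrays()
    if chrom not in arrays:
        return float("nan")
    pos, rate, _ = arrays[chrom]
    l0, l1 = np.searchsorted(pos, (start - span, start))
    r0, r1 = np.searchsorted(pos, (end, end + span))
    vals = np.concatenate([rate[l0:l1], rate[r0:r1]])
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if len(vals) else float("nan")


def global_background_rate(signal: SignalTrack, regions: list) -> float:
    """Mean corrected rate over all cytosines inside the search regions."""
    arrays = signal.chrom_arrays()
    vals = []
    for chrom, start, end in regions:
        if chrom not in arrays:
            continue
        pos, rate, _ = arrays[chrom]
        lo, hi = np.searchsorted(pos, (start, end))
        vals.append(rate[lo:hi])
    v = np.concatenate(vals) if vals else np.empty(0)
    v = v[np.isfinite(v)]
    return float(v.mean()) if len(v) else float("nan")


# ---------------------------------------------------------------------------
# strategy S2: binomial footprint regions

@dataclass
class FootprintCall:
    chrom: str
    start: int
    end: int
    depth_score: float
    p_value: float
    q_value: float
    background_mode: str
    matched_motifs: list = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class S2Params:
    window: int = 15
    step: int = 1
    min_c: int = 3
    background: str = "local"  # or 'global'
    span: int = 200
    alpha: float = 0.05
    min_width: int = 6
    merge_gap: int = 5


def _window_table(signal: SignalTrack, region: tuple, params: S2Params,
                  global_p0: float) -> pd.DataFrame | None:
    chrom, start, end = region
    arrays = signal.chrom_arrays()
    if chrom not in arrays:
        return None
    pos, rate, ntot = arrays[chrom]
    lo, hi = np.searchsorted(pos, (start - params.span, end + params.span))
    if hi <= lo:
        return None
    pos, rate, ntot = pos[lo:hi], rate[lo:hi], ntot[lo:hi]
    # per-cytosine pseudo-counts on the corrected-rate scale: x = rate * n
    nconv = rate * ntot
    width = (end + params.span) - (start - params.span)
    origin = start - params.span
    nt_bp = np.zeros(width)
    nc_bp = np.zeros(width)
    cy_bp = np.zeros(width)
    idx = pos - origin
    nt_bp[idx] = ntot
    nc_bp[idx] = nconv
    cy_bp[idx] = 1.0
    ct, cc, cy = (np.concatenate([[0.0], np.cumsum(a)]) for a in (nt_bp, nc_bp, cy_bp))

    starts = np.arange(start - origin, end - origin - params.window + 1, params.step)
    if len(starts) == 0:
        return None
    w = params.window
    n = ct[starts + w] - ct[starts]
    x = cc[starts + w] - cc[starts]
    c = cy[starts + w] - cy[starts]
    if params.background == "local":
        s = params.span
        ring_lo = np.maximum(starts - s, 0)
        ring_hi = np.minimum(starts + w + s, width)
        bn = (ct[ring_hi] - ct[ring_lo]) - n
        bx = (cc[ring_hi] - cc[ring_lo]) - x
        with np.errstate(invalid="ignore", divide="ignore"):
            p0 = np.where(bn > 0, bx / np.maximum(bn, 1e-300), np.nan)
        p0 = np.where(np.isfinite(p0), p0, global_p0)
    else:
        p0 = np.full(len(starts), global_p0)
    valid = (c >= params.min_c) & (n > 0) & np.isfinite(p0) & (p0 > 0)
    return pd.DataFrame({
        "chrom": chrom, "start": starts + origin,
        "end": starts + origin + w,
        "n": np.round(n).astype(np.int64), "x": x, "c": c.astype(np.int64),
        "p0": p0, "valid": valid,
    })


def detect_footprint_regions_s2(signal: SignalTrack, search_regions: list,
                                params: S2Params | None = None,
                                return_windows: bool = False):
    """Binomial sliding-window footprint calling (strategy S2).

    Per window the read counts over its cytosines are tested one-sided for
    conversion below the background rate p0; BH controls the FDR across all
    windows; significant windows are merged (gap <= merge_gap) and trimmed
    to their depleted cytosines.
    """
    params = params or S2Params()
    global_p0 = global_background_rate(signal, search_regions)
    if not np.isfinite(global_p0):
        raise ValueError("no informative cytosines in the search regions")
    tables = []
    for region in search_regions:
        t = _window_table(signal, region, params, global_p0)
        if t is not None:
            tables.append(t)
    if not tables:
        empty = pd.DataFrame()
        return ([], empty) if return_windows else []
    windows = pd.concat(tables, ignore_index=True)
    v = windows["valid"].to_numpy()
    p = np.ones(len(windows))
    p[v] = stats.binom.cdf(np.floor(windows.loc[v, "x"]).astype(np.int64),
                           windows.loc[v, "n"], windows.loc[v, "p0"])
    windows["p_value"] = p
    q = np.full(len(windows), np.nan)
    if v.any():
        q[v] = bh_adjust(p[v])
    windows["q_value"] = q
    with np.errstate(invalid="ignore"):
        depleted = (windows["x"] / windows["n"].clip(lower=1)) < windows["p0"]
    windows["significant"] = v & (windows["q_value"] < params.alpha) & depleted

    calls = []
    arrays = signal.chrom_arrays()
    sig = windows[windows["significant"]]
    for chrom, sub in sig.groupby("chrom"):
        sub = sub.sort_values("start")
        merged: list = []
        for _, row in sub.iterrows():
            if merged and row["start"] <= merged[-1][1] + params.merge_gap:
                merged[-1][1] = max(merged[-1][1], int(row["end"]))
            else:
                merged.append([int(row["start"]), int(row["end"])])
        pos, rate, ntot = arrays[chrom]
        for ms, me in merged:
            lo, hi = np.searchsorted(pos, (ms, me))
            if hi <= lo:
                continue
            cpos, crate, cn = pos[lo:hi], rate[lo:hi], ntot[lo:hi]
            p0 = np.nanmean(sub.loc[(sub["start"] < me) & (sub["end"] > ms), "p0"])
            # trim to individually depleted cytosines: one-sided binomial at 0.05
            cyt_p = stats.binom.cdf(np.round(crate * cn).astype(np.int64),
                                    cn, p0)
            below = (crate < p0) & (cyt_p < 0.05)
            if not below.any():
                continue
            first, last = np.flatnonzero(below)[[0, -1]]
            s, e = int(cpos[first]), int(cpos[last]) + 1
            if e - s < params.min_width:
                continue
            lo2, hi2 = np.searchsorted(pos, (s, e))
            n = float(ntot[lo2:hi2].sum())
            x = float((rate[lo2:hi2] * ntot[lo2:hi2]).sum())
            in_span = sub.loc[(sub["start"] < e) & (sub["end"] > s)]
            calls.append(FootprintCall(
                chrom, s, e, depth_score=float(p0 - x / max(n, 1.0)),
                p_value=float(in_span["p_value"].min()),
                q_value=float(in_span["q_value"].min()),
                background_mode=params.background))
    calls.sort(key=lambda c: (c.chrom, c.start))
    return (calls, windows) if return_windows else calls


# ---------------------------------------------------------------------------
# strategy S1: motif-score scan

def footprint_scan_scores_s1(signal: SignalTrack, candidate_sites: list,
                             search_regions: list, background: str = "local",
                             span: int = 200, flank: int = 50, min_c: int = 2,
                             n_null: int = 1000, min_null: int = 100,
                             rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Score motif occurrences by conversion depletion (strategy S1).

    footprint score = background rate - motif mean rate, with the background
    either the local ring around the site or the global region-wide mean.
    Significance comes from an empirical null of size-matched random
    positions drawn within the same search regions; BH is applied per motif.
    """
    rng = rng if rng is not None else np.random.default_rng()
    arrays = signal.chrom_arrays()
    global_p0 = global_background_rate(signal, search_regions)

    def motif_stats(chrom, start, end):
        if chrom not in arrays:
            return np.nan, 0
        pos, rate, _ = arrays[chrom]
        lo, hi = np.searchsorted(pos, (start, end))
        vals = rate[lo:hi]
        vals = vals[np.isfinite(vals)]
        return (float(vals.mean()) if len(vals) else np.nan), len(vals)

    def score_at(chrom, start, end):
        m, n = motif_stats(chrom, start, end)
        if n < min_c:
            return np.nan, n
        if background == "local":
            bg = local_background_rate(signal, (chrom, start, end), span)
            if not np.isfinite(bg):
                bg = global_p0
        else:
            bg = global_p0
        return bg - m, n

    region_arr = [(c, s, e) for c, s, e in search_regions]
    lengths = np.array([e - s for _, s, e in region_arr], dtype=float)
    weights = lengths / lengths.sum()

    null_cache: dict = {}

    def null_scores(L: int) -> np.ndarray:
        if L in null_cache:
            return null_cache[L]
        vals = []
        for _ in range(n_null):
            c, s, e = region_arr[rng.choice(len(region_arr), p=weights)]
            if e - s <= L:
                continue
            st = int(rng.integers(s, e - L))
            sc, _ = score_at(c, st, st + L)
            if np.isfinite(sc):
                vals.append(sc)
        null_cache[L] = np.sort(np.array(vals))
        return null_cache[L]

    rows, excluded = [], []
    for site in candidate_sites:
        sc, n_c = score_at(site.chrom, site.start, site.end)
        if not np.isfinite(sc):
            excluded.append((site.motif_id, site.chrom, site.start,
                             "too few motif cytosines"))
            continue
        null = null_scores(site.end - site.start)
        if len(null) < min_null:
            raise RuntimeError(
                f"motif {site.motif_id}: only {len(null)} valid null draws "
                f"(< {min_null}); enlarge the search regions or n_null")
        # rank-based upper-tail probability with add-one smoothing
        ge = len(null) - np.searchsorted(null, sc, side="left")
        pval = (1 + ge) / (1 + len(null))
        rows.append((site.chrom, site.start, site.end, site.strand,
                     site.motif_id, site.tf_name, n_c, sc, pval))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                     "motif_id", "tf_name", "n_motif_c",
                                     "score", "p_value"])
    df["q_value"] = np.nan
    for motif_id, sub in df.groupby("motif_id"):
        df.loc[sub.index, "q_value"] = bh_adjust(sub["p_value"].to_numpy())
    df.attrs["excluded"] = pd.DataFrame(
        excluded, columns=["motif_id", "chrom", "start", "reason"])
    df.attrs["background_mode"] = background
    return df


# ---------------------------------------------------------------------------
# annotation, density, differential binding

def annotate_footprints(footprints: list, motif_sites: list,
                        searched_regions: list,
                        covered_bp: int | None = None,
                        min_overlap_frac: float = 0.5) -> dict:
    """Label footprints motif-matched or unmatched and compute density.

    A footprint matches a motif site when their overlap covers at least
    `min_overlap_frac` of the motif length.  Density is footprints per
    200 bp of searched region span (and per covered bp when supplied,
    since the two denominators answer different questions).
    """
    by_chrom: dict = {}
    for s in motif_sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    rows = []
    for fp in footprints:
        matched = []
        for s in by_chrom.get(fp.chrom, []):
            ov = min(fp.end, s.end) - max(fp.start, s.start)
            if ov >= min_overlap_frac * (s.end - s.start):
                matched.append(s.motif_id)
        fp.matched_motifs = matched
        rows.append((fp.chrom, fp.start, fp.end, fp.width, fp.depth_score,
                     bool(matched), ",".join(matched)))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "width",
                                        "depth_score", "matched", "motif_ids"])
    total_bp = sum(e - s for _, s, e in searched_regions)
    out = {
        "table": table,
        "n_footprints": len(footprints),
        "matched_fraction": float(table["matched"].mean()) if len(table) else float("nan"),
        "density_per_200bp": 200.0 * len(footprints) / total_bp if total_bp else float("nan"),
        "width_by_class": {
            str(k): sub["width"].describe().to_dict()
            for k, sub in table.groupby("matched")} if len(table) else {},
    }
    if covered_bp:
        out["density_per_200bp_covered"] = 200.0 * len(footprints) / covered_bp
    return out


def quantile_normalize_pair(a: np.ndarray, b: np.ndarray) -> tuple:
    """Map both vectors onto the mean of their sorted values (ties by rank)."""
    order_a, order_b = np.argsort(a, kind="stable"), np.argsort(b, kind="stable")
    mean_sorted = (a[order_a] + b[order_b]) / 2
    qa, qb = np.empty_like(a), np.empty_like(b)
    qa[order_a] = mean_sorted
    qb[order_b] = mean_sorted
    return qa, qb


@dataclass
class DifferentialTFResult:
    tf_cluster: str
    score_a: float
    score_b: float
    differential_score: float
    z: float
    p_value: float
    q_value: float
    direction: str
    n_sites: int
    underpowered: bool


def differential_binding(scored_sites_a: pd.DataFrame, scored_sites_b: pd.DataFrame,
                         motif_clusters: dict, n_perm: int = 10_000,
                         min_sites: int = 50,
                         rng: np.random.Generator | None = None) -> list:
    """Cluster-level differential footprint scores between two conditions.

    Both inputs must score the same candidate-site universe (matched on
    chrom/start/end/motif_id).  Scores are quantile-normalized across
    conditions; each cluster's mean difference is compared with a null of
    size-matched random site draws, giving z, a two-sided normal p, and BH q.
    Because quantile normalization forces the overall score distributions to
    agree, a genuine shift in one cluster leaks a small compensatory shift
    into all others; cluster differences are therefore re-centered on their
    median (robust under the assumption that most clusters are unchanged)
    before the z is formed.  The permutation z is an explicit stand-in for
    an unspecified test statistic and is labeled as such in the output.
    """
    rng = rng if rng is not None else np.random.default_rng()
    key = ["chrom", "start", "end", "motif_id"]
    merged = scored_sites_a.merge(scored_sites_b, on=key, suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("conditions share no candidate sites")
    qa, qb = quantile_normalize_pair(merged["score_a"].to_numpy(float),
                                     merged["score_b"].to_numpy(float))
    diff = qb - qa
    motif_ids = merged["motif_id"].to_numpy()

    cluster_stats = []
    for cluster, members in motif_clusters.items():
        mask = np.isin(motif_ids, list(members))
        size = int(mask.sum())
        if size == 0:
            continue
        cluster_stats.append((cluster, mask, size, float(diff[mask].mean())))
    if not cluster_stats:
        return []
    center = float(np.median([d for *_, d in cluster_stats]))

    results = []
    null_by_size: dict = {}
    for cluster, mask, size, d in cluster_stats:
        if size not in null_by_size:
            draws = rng.integers(0, len(diff), size=(n_perm, size))
            null_by_size[size] = diff[draws].mean(axis=1)
        null = null_by_size[size]
        sd = float(null.std(ddof=1))
        z = (d - center) / sd if sd > 0 else 0.0
        p = float(2 * stats.norm.sf(abs(z)))
        results.append(DifferentialTFResult(
            cluster, float(qa[mask].mean()), float(qb[mask].mean()), d, z, p,
            np.nan, "up" if d > 0 else ("down" if d < 0 else "none"),
            size, size < min_sites))
    qvals = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qvals):
        r.q_value = float(q)
    return results


def cluster_motifs_by_similarity(models: list, r_threshold: float = 0.8) -> dict:
    """Default motif clustering: single-linkage on Pearson correlation of
    aligned PWM columns (best ungapped offset, both orientations)."""
    def best_corr(m1: MotifModel, m2: MotifModel) -> float:
        def corr(a, b):
            L = min(a.shape[1], b.shape[1])
            best = -1.0
            for off in range(-(b.shape[1] - 4), a.shape[1] - 3):
                lo_a, hi_a = max(0, off), min(a.shape[1], off + b.shape[1])
                if hi_a - lo_a < 4:
                    continue
                x = a[:, lo_a:hi_a].ravel()
                y = b[:, lo_a - off: hi_a - off].ravel()
                if x.std() == 0 or y.std() == 0:
                    continue
                best = max(best, float(np.corrcoef(x, y)[0, 1]))
            return best
        p1, p2 = m1.pwm, m2.pwm
        rc = p2[::-1, ::-1]
        return max(corr(p1, p2), corr(p1, rc))

    parent = list(range(len(models)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            if best_corr(models[i], models[j]) >= r_threshold:
                parent[find(i)] = find(j)
    clusters: dict = {}
    for i, m in enumerate(models):
        clusters.setdefault(find(i), []).append(m.motif_id)
    return {f"cluster_{models[root].motif_id}": ids
            for root, ids in clusters.items()}
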