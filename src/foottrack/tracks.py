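"""Per-cytosine conversion tracks from converted-read alignments.

A conversion track records, for every covered cytosine on its own strand,
how many reads had a determinate base there (``n_total``) and how many
reported the converted base (``n_conv``: T at a top-strand C, A at a
bottom-strand C, which appears as G->A on the top-strand read sequence).
The per-cytosine rate ``n_conv / n_total`` is the raw accessibility signal
that all downstream footprint analysis consumes.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
import pyfaidx

from .simulate import revcomp

TRACK_COLUMNS = ["chrom", "pos", "strand", "n_conv", "n_total", "context"]

#: CIGAR ops that consume both query and reference (M, =, X)
_MATCH_OPS = {0, 7, 8}


class MalformedInputError(ValueError):
    """Raised when an alignment cannot be interpreted under the conversion model."""


@dataclass
class ConversionTrack:
    """Stranded per-cytosine conversion counts with sequence context."""

    data: pd.DataFrame
    sample_id: str = ""
    global_rate: float | None = None

    def __post_init__(self):
        if list(self.data.columns) != TRACK_COLUMNS:
            self.data = self.data.reindex(columns=TRACK_COLUMNS)
        if len(self.data):
            self.data = self.data.astype(
                {"pos": np.int64, "n_conv": np.int64, "n_total": np.int64})

    @property
    def is_empty(self) -> bool:
        return len(self.data) == 0

    def rates(self) -> np.ndarray:
        return self.data["n_conv"].to_numpy() / self.data["n_total"].to_numpy()

    def compute_global_rate(self, min_total: int = 3,
                            exclude_contigs: tuple = ()) -> float | None:
        """Genome-wide conversion fraction over cytosines with n_total >= min_total."""
        d = self.data
        mask = d["n_total"] >= min_total
        if exclude_contigs:
            mask &= ~d["chrom"].isin(exclude_contigs)
        tot = int(d.loc[mask, "n_total"].sum())
        if tot == 0:
            return None
        return float(d.loc[mask, "n_conv"].sum() / tot)


@dataclass
class ReadObservation:
    """Per-molecule conversion calls, the carrier for single-molecule analysis."""

    read_id: str
    molecule_strand: str  # '+', '-' or 'undetermined'
    barcode: str | None
    calls: list  # (chrom, pos, strand, converted)


@dataclass
class SignalTrack:
    """Per-cytosine rate signal (normalized or bias-corrected), strand-pooled
    by position when queried."""

    data: pd.DataFrame  # chrom, pos, strand, rate, n_total
    sample_id: str = ""
    _index: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_counts(cls, track: ConversionTrack) -> "SignalTrack":
        d = track.data
        df = pd.DataFrame({
            "chrom": d["chrom"], "pos": d["pos"], "strand": d["strand"],
            "rate": d["n_conv"].to_numpy() / d["n_total"].to_numpy(),
            "n_total": d["n_total"],
        })
        return cls(df, sample_id=track.sample_id)

    def chrom_arrays(self) -> dict:
        """chrom -> (positions sorted, rates, n_total); a genomic position holds a
        cytosine on at most one strand, so pooling strands keeps positions unique."""
        if not self._index:
            for chrom, sub in self.data.groupby("chrom", sort=True):
                sub = sub.sort_values("pos")
                self._index[chrom] = (
                    sub["pos"].to_numpy(np.int64),
                    sub["rate"].to_numpy(float),
                    sub["n_total"].to_numpy(np.int64),
                )
        return self._index


def _read_matched_pairs(read: pysam.AlignedSegment):
    """(query_idx, ref_pos) arrays over CIGAR match ops; fast path for pure-match."""
    cig = read.cigartuples
    if cig is None:
        raise MalformedInputError(f"read {read.query_name} has no CIGAR")
    if all(op in _MATCH_OPS for op, _ in cig):
        n = read.query_length
        q = np.arange(n)
        r = read.reference_start + np.arange(n)
        return q, r
    pairs = read.get_aligned_pairs(matches_only=True)
    if not pairs:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    arr = np.asarray(pairs, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def assign_read_strand(read: pysam.AlignedSegment, reference_window: str,
                       window_start: int | None = None,
                       strand_tag: str | None = None) -> str:
    """Infer which strand of the molecule carried the deamination marks.

    C->U conversion on the top strand shows as C->T mismatches against the
    reference; conversion on the bottom strand shows as G->A.  A
    conversion-strand tag from the aligner, when present, wins outright.
    Ties and uninformative reads are 'undetermined'.
    """
    if read.is_unmapped:
        raise MalformedInputError(f"read {read.query_name} is unmapped")
    if strand_tag and read.has_tag(strand_tag):
        val = read.get_tag(strand_tag)
        if val in ("CT", "+"):
            return "+"
        if val in ("GA", "-"):
            return "-"
    start = read.reference_start if window_start is None else window_start
    if read.reference_start < start or read.reference_end > start + len(reference_window):
        raise MalformedInputError(
            f"read {read.query_name} alignment exceeds the reference window")
    q_idx, r_pos = _read_matched_pairs(read)
    if len(q_idx) == 0:
        return "undetermined"
    ref = np.frombuffer(reference_window.upper().encode(), dtype="S1")[r_pos - start]
    qry = np.frombuffer(read.query_sequence.upper().encode(), dtype="S1")[q_idx]
    ct = int(np.sum((ref == b"C") & (qry == b"T")))
    ga = int(np.sum((ref == b"G") & (qry == b"A")))
    if ct > ga:
        return "+"
    if ga > ct:
        return "-"
    return "undetermined"


def _load_reference(reference) -> dict:
    if isinstance(reference, dict):
        return {c: s.upper() for c, s in reference.items()}
    if isinstance(reference, str):
        fa = pyfaidx.Fasta(reference)
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
    if isinstance(reference, pyfaidx.Fasta):
        return {name: str(reference[name][:]).upper() for name in reference.keys()}
    raise TypeError("reference must be a path, a pyfaidx.Fasta, or a dict")


def _context_at(ref: str, pos: int, strand: str, k: int) -> str:
    half = k // 2
    lo, hi = pos - half, pos + half + 1
    ctx = ref[max(lo, 0): hi]
    if lo < 0:
        ctx = "N" * (-lo) + ctx
    if len(ctx) < k:
        ctx = ctx + "N" * (k - len(ctx))
    return revcomp(ctx) if strand == "-" else ctx


def _passing_reads(af, min_mapq: int, dedup: bool):
    for read in af:
        if (read.is_unmapped or read.is_secondary or read.is_supplementary
                or read.is_qcfail):
            continue
        if dedup and read.is_duplicate:
            continue
        if read.mapping_quality < min_mapq:
            continue
        yield read


def _read_calls(read, refs: dict, min_baseq: int, strand_tag: str | None):
    """One read -> (strand, ref positions of its strand's Cs, converted flags,
    base qualities).  Bases inconsistent with the conversion model are dropped."""
    chrom = read.reference_name
    if chrom not in refs:
        raise ValueError(f"alignment contig {chrom!r} absent from the reference")
    ref_str = refs[chrom]
    strand = assign_read_strand(read, ref_str, window_start=0, strand_tag=strand_tag)
    if strand == "undetermined":
        return strand, None, None, None
    q_idx, r_pos = _read_matched_pairs(read)
    ref = np.frombuffer(ref_str.encode(), dtype="S1")[r_pos]
    qry = np.frombuffer(read.query_sequence.upper().encode(), dtype="S1")[q_idx]
    quals = read.query_qualities
    qual = np.asarray(quals, dtype=np.int64)[q_idx] if quals is not None else None
    if strand == "+":
        at_c = ref == b"C"
        conv, unconv = qry == b"T", qry == b"C"
    else:
        at_c = ref == b"G"
        conv, unconv = qry == b"A", qry == b"G"
    keep = at_c & (conv | unconv)
    if qual is not None and min_baseq > 0:
        keep &= qual >= min_baseq
    bq = qual[keep] if qual is not None else np.full(int(keep.sum()), 255)
    return strand, r_pos[keep], conv[keep], bq


def extract_conversion_track(alignments, reference, *, min_mapq: int = 20,
                             min_baseq: int = 20, dedup: bool = True,
                             strand_tag: str | None = None, context_k: int = 3,
                             min_total_for_rate: int = 3,
                             exclude_contigs: tuple = (),
                             sample_id: str = "") -> ConversionTrack:
    """Pile up conversion evidence per cytosine from a converted-read alignment.

    Overlapping mate positions of one fragment are counted once (the
    higher-base-quality observation wins).  Read bases other than {C,T} at a
    top-strand C (resp. {G,A} at a bottom-strand C) are sequencing error under
    the conversion model and are excluded from n_total.
    """
    refs = _load_reference(reference)
    own_handle = isinstance(alignments, str)
    af = pysam.AlignmentFile(alignments, check_sq=False) if own_handle else alignments

    counts = {}  # (chrom, strand) -> (n_total array, n_conv array)
    pending = {}  # fragment-level store for overlapping paired mates

    def _bump(chrom, strand, pos, conv):
        key = (chrom, strand)
        if key not in counts:
            n = len(refs[chrom])
            counts[key] = (np.zeros(n, np.int32), np.zeros(n, np.int32))
        nt, nc = counts[key]
        np.add.at(nt, pos, 1)
        if np.any(conv):
            np.add.at(nc, pos[conv], 1)

    try:
        for read in _passing_reads(af, min_mapq, dedup):
            strand, pos, conv, bq = _read_calls(read, refs, min_baseq, strand_tag)
            if pos is None or len(pos) == 0:
                continue
            if read.is_paired:
                frag = pending.setdefault((read.query_name, strand,
                                           read.reference_name), {})
                for p, cv, q in zip(pos, conv, bq):
                    prev = frag.get(p)
                    if prev is None or q > prev[1]:
                        frag[int(p)] = (bool(cv), int(q))
            else:
                _bump(read.reference_name, strand, pos, conv)
    finally:
        if own_handle:
            af.close()

    for (_, strand, chrom), frag in pending.items():
        pos = np.fromiter(frag.keys(), dtype=np.int64)
        conv = np.fromiter((v[0] for v in frag.values()), dtype=bool)
        _bump(chrom, strand, pos, conv)

    frames = []
    for (chrom, strand) in sorted(counts):
        nt, nc = counts[(chrom, strand)]
        pos = np.flatnonzero(nt)
        ref = refs[chrom]
        ctx = [_context_at(ref, int(p), strand, context_k) for p in pos]
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "strand": strand,
            "n_conv": nc[pos], "n_total": nt[pos], "context": ctx,
        }))
    if frames:
        data = (pd.concat(frames, ignore_index=True)
                .sort_values(["chrom", "pos"], kind="stable")
                .reset_index(drop=True))
    else:
        data = pd.DataFrame(columns=TRACK_COLUMNS)
    track = ConversionTrack(data, sample_id=sample_id)
    track.global_rate = track.compute_global_rate(min_total_for_rate, exclude_contigs)
    return track


def iter_read_observations(alignments, reference, *, min_mapq: int = 20,
                           min_baseq: int = 20, dedup: bool = True,
                           strand_tag: str | None = None,
                           barcode_tag: str = "CB") -> list:
    """Per-read conversion calls for single-molecule / single-cell analysis."""
    refs = _load_reference(reference)
    own_handle = isinstance(alignments, str)
    af = pysam.AlignmentFile(alignments, check_sq=False) if own_handle else alignments
    observations = []
    try:
        for read in _passing_reads(af, min_mapq, dedup):
            strand, pos, conv, _ = _read_calls(read, refs, min_baseq, strand_tag)
            if strand == "undetermined":
                continue
            barcode = read.get_tag(barcode_tag) if read.has_tag(barcode_tag) else None
            chrom = read.reference_name
            calls = [(chrom, int(p), strand, bool(c)) for p, c in zip(pos, conv)]
            observations.append(ReadObservation(read.query_name, strand, barcode, calls))
    finally:
        if own_handle:
            af.close()
    return observations


def normalize_track(track: ConversionTrack, reference_rate: float) -> SignalTrack:
    """Scale per-cytosine rates by reference_rate / global_rate, clipped to [0,1].

    Puts samples converted at different enzyme doses on one scale so their
    average profiles can be overlaid.
    """
    if not track.global_rate:
        raise ValueError("cannot normalize: track global_rate is zero or undefined")
    sig = SignalTrack.from_counts(track)
    sig.data["rate"] = np.clip(
        sig.data["rate"] * (reference_rate / track.global_rate), 0.0, 1.0)
    return sig


@dataclass
class QCReport:
    global_rate: float
    status: str  # 'pass' or 'warn'
    bounds: tuple
    per_context: pd.DataFrame
    strand_rates: dict


def qc_conversion_rate(track: ConversionTrack,
                       bounds: tuple = (0.25, 0.40)) -> QCReport:
    """Flag samples outside the optimal 25%-40% genome-wide conversion window."""
    if track.is_empty:
        raise ValueError("QC requires a nonempty track")
    rate = track.global_rate
    if rate is None:
        rate = track.compute_global_rate(min_total=1)
    status = "pass" if bounds[0] <= rate <= bounds[1] else "warn"
    d = track.data
    per_context = (d.groupby("context")
                   .agg(n_conv=("n_conv", "sum"), n_total=("n_total", "sum"))
                   .assign(rate=lambda t: t["n_conv"] / t["n_total"])
                   .reset_index())
    strand_rates = {
        s: float(sub["n_conv"].sum() / sub["n_total"].sum())
        for s, sub in d.groupby("strand") if sub["n_total"].sum() > 0
    }
    return QCReport(float(rate), status, bounds, per_context, strand_rates)


# ---------------------------------------------------------------------------
# serialization

_TSV_HEADER = (
    "# foottrack cytosine report\n"
    "# coordinates: 0-based, half-open; pos is the cytosine on its own strand\n"
    "# columns: chrom pos strand n_conv n_total context\n"
)


def serialize_track(track: ConversionTrack, out_prefix: str,
                    bedgraph: bool = True) -> dict:
    """Write the cytosine-report TSV (lossless) and per-strand bedGraph pairs."""
    paths = {"tsv": f"{out_prefix}.cytosine.tsv"}
    with open(paths["tsv"], "w") as fh:
        fh.write(_TSV_HEADER)
        fh.write(f"# sample_id={track.sample_id}\n")
        gr = "NA" if track.global_rate is None else repr(track.global_rate)
        fh.write(f"# global_rate={gr}\n")
        track.data.to_csv(fh, sep="\t", header=False, index=False)
    if bedgraph:
        for strand, tag in (("+", "plus"), ("-", "minus")):
            sub = track.data[track.data["strand"] == strand]
            rate = sub["n_conv"].to_numpy() / np.maximum(sub["n_total"].to_numpy(), 1)
            for kind, vals in (("rate", rate), ("coverage", sub["n_total"])):
                p = f"{out_prefix}.{tag}.{kind}.bedGraph"
                paths[f"{tag}.{kind}"] = p
                bed = pd.DataFrame({"chrom": sub["chrom"], "start": sub["pos"],
                                    "end": sub["pos"] + 1, "value": np.asarray(vals)})
                with open(p, "w") as fh:
                    fh.write(f"track type=bedGraph name={track.sample_id}_{tag}_{kind}\n")
                    bed.to_csv(fh, sep="\t", header=False, index=False)
    return paths


def deserialize_track(tsv_path: str) -> ConversionTrack:
    sample_id, global_rate = "", None
    rows = []
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("sample_id="):
                    sample_id = body.split("=", 1)[1]
                elif body.startswith("global_rate="):
                    val = body.split("=", 1)[1]
                    global_rate = None if val == "NA" else float(val)
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{tsv_path}:{lineno}: expected 6 fields, got {len(parts)}")
            try:
                rows.append((parts[0], int(parts[1]), parts[2],
                             int(parts[3]), int(parts[4]), parts[5]))
            except ValueError as exc:
                raise ValueError(f"{tsv_path}:{lineno}: {exc}") from None
    data = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return ConversionTrack(data, sample_id=sample_id, global_rate=global_rate)
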