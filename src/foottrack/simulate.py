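"""Synthetic deaminase-footprinting data with known ground truth.

The generative model: double-stranded DNA deaminases convert cytosines to
uracil (read out as C->T on the molecule's own strand) wherever the DNA is
accessible.  DNA wrapped in nucleosomes or covered by a bound transcription
factor is protected and converts only at a low residual rate.  Each
simulated molecule independently draws its TF occupancy (Bernoulli theta per
site), its nucleosome positions (phased arrays with Gaussian jitter in
closed chromatin), and then converts each cytosine on its strand with

    p = p_protected                       if the cytosine is masked
    p = min(1, p_open * bias(context))    otherwise

so that enzyme sequence-context preference, footprint depth and occupancy
level are all separately controllable and recoverable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class TFSite:
    """A planted TF binding site with per-molecule Bernoulli occupancy."""

    name: str
    consensus: str
    pos: int  # 0-based start on the top strand
    theta: float
    chrom: str = "chrSim"
    strand: str = "+"
    footprint_pad: int = 0

    @property
    def end(self) -> int:
        return self.pos + len(self.consensus)

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.pos - self.footprint_pad, self.end + self.footprint_pad)


@dataclass
class SimulationConfig:
    seed: int = 0
    contigs: dict = field(default_factory=lambda: {"chrSim": 100_000})
    gc: float = 0.41
    ocrs: list = field(default_factory=list)  # (chrom, start, end)
    tf_sites: list = field(default_factory=list)
    nucleosomes: bool = True
    nucleosome_width: int = 147
    nucleosome_repeat: int = 190
    nucleosome_jitter_sd: float = 10.0
    p_open: float = 0.6
    p_protected: float = 0.05
    context_bias: dict = field(default_factory=dict)  # context -> multiplier
    n_molecules: int = 2000
    fragment_len_mean: float = 300.0
    fragment_len_sd: float = 60.0
    fragment_len_min: int = 50
    per_base_error: float = 0.0
    n_cells: int = 0
    naked: bool = False
    naked_rate: float | None = None
    restrict_to: list | None = None  # fragment sampling intervals

    def validate(self) -> None:
        for p in (self.gc, self.p_open, self.p_protected, self.per_base_error):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.naked_rate is not None and not 0.0 <= self.naked_rate <= 1.0:
            raise ValueError("naked_rate out of [0,1]")
        for site in self.tf_sites:
            if not 0.0 <= site.theta <= 1.0:
                raise ValueError(f"theta out of [0,1] for site {site.name}")


@dataclass
class SimRead:
    read_id: str
    chrom: str
    start: int  # 0-based, top strand
    strand: str  # molecule strand: '+' converted C->T, '-' converted G->A
    seq: str  # top-strand sequence after conversion and error
    barcode: str | None = None

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass
class MoleculeTruth:
    read_id: str
    chrom: str
    start: int
    strand: str
    bound: dict  # site name -> bool
    protected_intervals: list  # (start, end) on the contig, clipped to fragment
    cytosine_pos: np.ndarray  # contig coords of Cs on the molecule strand
    expected_p: np.ndarray  # conversion probability used per cytosine
    converted: np.ndarray  # bool draw per cytosine


@dataclass
class TruthTable:
    sites: list
    molecules: list

    def site_bound_fraction(self, name: str) -> float:
        flags = [m.bound[name] for m in self.molecules if name in m.bound]
        return float(np.mean(flags)) if flags else float("nan")


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: dict
    reads: list
    truth: TruthTable

    def write_sam(self, path: str, strand_tag: str | None = None) -> None:
        write_sam(self.reads, self.reference, path, strand_tag=strand_tag)

    def write_fasta(self, path: str) -> None:
        write_fasta(self.reference, path)


def simulate_reference(config: SimulationConfig, rng: np.random.Generator | None = None,
                       allow_overlap: bool = False) -> dict:
    """Random sequence at the requested GC with motif consensi planted.

    Minus-strand sites are planted as the reverse complement so that the
    consensus reads on the annotated strand.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    probs = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2])
    reference = {}
    for chrom, length in config.contigs.items():
        arr = rng.choice(_BASES, size=length, p=probs)
        reference[chrom] = arr.tobytes().decode()
    planted: dict = {}
    for site in config.tf_sites:
        seq = site.consensus.upper() if site.strand == "+" else revcomp(site.consensus.upper())
        if site.chrom not in reference:
            raise ValueError(f"site {site.name} on unknown contig {site.chrom}")
        if not allow_overlap:
            for (c, s, e), other in planted.items():
                if c == site.chrom and site.pos < e and s < site.end:
                    raise ValueError(f"planted motifs overlap: {site.name} and {other}")
        planted[(site.chrom, site.pos, site.end)] = site.name
        ref = reference[site.chrom]
        reference[site.chrom] = ref[: site.pos] + seq + ref[site.end:]
    return reference


def _context_multiplier(context: str, bias: dict) -> float:
    if not bias:
        return 1.0
    if context in bias:
        return bias[context]
    k = len(context)
    dinuc = context[k // 2 - 1: k // 2 + 1]  # 5' neighbor + C
    return bias.get(dinuc, 1.0)


def _closed_spans(length: int, ocrs: list) -> list:
    """Complement of the OCR set over [0, length)."""
    spans, cursor = [], 0
    for s, e in sorted(ocrs):
        if s > cursor:
            spans.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        spans.append((cursor, length))
    return spans


def simulate_molecules(reference: dict, config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Draw converted molecules and the truth needed to verify every step."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    intervals = config.restrict_to
    if intervals is None:
        intervals = [(c, 0, len(seq)) for c, seq in reference.items()]
    weights = np.array([e - s for _, s, e in intervals], dtype=float)
    weights /= weights.sum()

    closed_by_chrom = {
        c: _closed_spans(len(seq), [(s, e) for cc, s, e in config.ocrs if cc == c])
        for c, seq in reference.items()
    }
    sites_by_chrom: dict = {}
    for site in config.tf_sites:
        sites_by_chrom.setdefault(site.chrom, []).append(site)

    ref_arrays = {c: np.frombuffer(seq.encode(), dtype="S1") for c, seq in reference.items()}
    reads, molecules = [], []
    barcodes = [f"CELL{i:03d}" for i in range(config.n_cells)] if config.n_cells else None
    base_rate = config.naked_rate if config.naked_rate is not None else config.p_open

    for i in range(config.n_molecules):
        chrom, iv_s, iv_e = intervals[rng.choice(len(intervals), p=weights)]
        contig_len = len(reference[chrom])
        length = int(np.clip(round(rng.normal(config.fragment_len_mean, config.fragment_len_sd)),
                             config.fragment_len_min, contig_len))
        center = int(rng.integers(iv_s, iv_e))
        start = int(np.clip(center - length // 2, 0, contig_len - length))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        barcode = barcodes[int(rng.integers(config.n_cells))] if barcodes else None
        read_id = f"mol{i:07d}"

        bound: dict = {}
        protected: list = []
        if not config.naked:
            for site in sites_by_chrom.get(chrom, []):
                fs, fe = site.footprint
                if fe > start and fs < end:  # any overlap: the molecule has a state
                    is_bound = bool(rng.random() < site.theta)
                    bound[site.name] = is_bound
                    if is_bound:
                        protected.append((max(fs, start), min(fe, end)))
            if config.nucleosomes:
                for cs, ce in closed_by_chrom[chrom]:
                    if ce <= start or cs >= end:
                        continue
                    anchor = cs + rng.normal(0.0, config.nucleosome_jitter_sd)
                    k0 = max(0, int((start - anchor) // config.nucleosome_repeat) - 1)
                    k = k0
                    while True:
                        ns = anchor + k * config.nucleosome_repeat
                        ne = ns + config.nucleosome_width
                        if ns >= min(ce, end):
                            break
                        lo, hi = max(int(round(ns)), cs, start), min(int(round(ne)), ce, end)
                        if hi > lo:
                            protected.append((lo, hi))
                        k += 1

        frag = ref_arrays[chrom][start:end]
        mask = np.zeros(length, dtype=bool)
        for ps, pe in protected:
            mask[max(ps - start, 0): max(pe - start, 0)] = True

        target = b"C" if strand == "+" else b"G"
        cyt_local = np.flatnonzero(frag == target)
        cyt_pos = cyt_local + start
        ref_str = reference[chrom]
        p = np.empty(len(cyt_local))
        for j, pos in enumerate(cyt_pos):
            ctx = ref_str[max(pos - 1, 0): pos + 2]
            if len(ctx) < 3:
                ctx = ctx.rjust(3, "N") if pos == 0 else ctx.ljust(3, "N")
            if strand == "-":
                ctx = revcomp(ctx)
            mult = _context_multiplier(ctx, config.context_bias)
            if config.naked:
                p[j] = min(1.0, base_rate * mult)
            elif mask[cyt_local[j]]:
                p[j] = config.p_protected
            else:
                p[j] = min(1.0, config.p_open * mult)
        converted = rng.random(len(p)) < p

        out = frag.copy()
        conv_base = b"T" if strand == "+" else b"A"
        out[cyt_local[converted]] = conv_base
        if config.per_base_error > 0:
            err = rng.random(length) < config.per_base_error
            if err.any():
                idx = np.flatnonzero(err)
                shift = rng.integers(1, 4, size=len(idx))
                codes = np.searchsorted(_BASES, out[idx])
                out[idx] = _BASES[(codes + shift) % 4]

        reads.append(SimRead(read_id, chrom, start, strand, out.tobytes().decode(), barcode))
        molecules.append(MoleculeTruth(read_id, chrom, start, strand, bound,
                                       protected, cyt_pos, p, converted))
    return SimulatedDataset(config, reference, reads,
                            TruthTable(list(config.tf_sites), molecules))


def simulate_condition_series(config: SimulationConfig, theta_schedule: dict,
                              reference: dict | None = None) -> dict:
    """One dataset per timepoint over a shared reference and site layout.

    theta_schedule: label -> {"theta": {tf_name: value, ...}, "p_open": value}
    (both keys optional per timepoint).
    """
    reference = reference if reference is not None else simulate_reference(config)
    known = {s.name for s in config.tf_sites}
    datasets = {}
    for idx, (label, overrides) in enumerate(theta_schedule.items()):
        for name in overrides.get("theta", {}):
            if name not in known:
                raise ValueError(f"schedule references unknown TF {name!r}")
        cfg = copy.deepcopy(config)
        cfg.tf_sites = [replace(s, theta=overrides.get("theta", {}).get(s.name, s.theta))
                        for s in cfg.tf_sites]
        if "p_open" in overrides:
            cfg.p_open = overrides["p_open"]
        rng = np.random.default_rng([config.seed, idx])
        datasets[label] = simulate_molecules(reference, cfg, rng)
    return datasets


def write_fasta(reference: dict, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def write_sam(reads: list, reference: dict, path: str,
              strand_tag: str | None = None) -> None:
    """Coordinate-sorted SAM of perfectly aligned single-end reads.

    Conversion strand is encoded in the base changes themselves (C->T for
    '+' molecules, G->A for '-'); optionally also emitted as a two-letter
    tag ('CT'/'GA') so tag-first strand assignment can be exercised.
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": len(s)} for c, s in reference.items()]}
    order = {c: i for i, c in enumerate(reference)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read in sorted(reads, key=lambda r: (order[r.chrom], r.start)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.read_id
            a.query_sequence = read.seq
            a.flag = 0
            a.reference_id = order[read.chrom]
            a.reference_start = read.start
            a.mapping_quality = 60
            a.cigarstring = f"{len(read.seq)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
            tags = []
            if strand_tag:
                tags.append((strand_tag, "CT" if read.strand == "+" else "GA"))
            if read.barcode:
                tags.append(("CB", read.barcode))
            if tags:
                a.set_tags(tags)
            out.write(a)
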