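"""Enzyme sequence-context bias: fit on naked DNA, correct chromatin tracks.

Double-stranded DNA deaminases prefer some flanking-base contexts (notably a
5' T over a 5' G), so raw conversion rates confound enzyme preference with
chromatin protection.  A protein-free (naked DNA) control isolates the
enzyme's preference: the expected conversion rate per length-k context,
relative to the genome-wide rate, is the bias probability.  Correction
rescales each cytosine's observed rate by genome_rate / expected_rate(context)
so only protection-driven depletion remains.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import ConversionTrack, SignalTrack


def all_contexts(k: int) -> list:
    """Every length-k context with C at the center."""
    half = k // 2
    sides = ["".join(p) for p in itertools.product("ACGT", repeat=half)]
    return [a + "C" + b for a in sides for b in sides]


@dataclass
class BiasModel:
    k: int
    table: pd.DataFrame  # context, expected_rate (NaN if missing), count, low_confidence
    genome_rate: float
    min_count: int = 200
    stranded_tables: dict | None = None  # '+'/'-' -> table, when strands disagree

    def expected_rate(self, context: str, strand: str | None = None) -> float:
        table = self.table
        if self.stranded_tables and strand in self.stranded_tables:
            table = self.stranded_tables[strand]
        row = table.loc[table["context"] == context]
        if row.empty:
            return float("nan")
        return float(row["expected_rate"].iloc[0])

    def to_files(self, tsv_path: str, json_path: str | None = None) -> None:
        self.table.to_csv(tsv_path, sep="\t", index=False)
        meta = {"k": self.k, "genome_rate": self.genome_rate,
                "min_count": self.min_count}
        with open(json_path or tsv_path.replace(".tsv", ".json"), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def from_files(cls, tsv_path: str, json_path: str | None = None) -> "BiasModel":
        table = pd.read_csv(tsv_path, sep="\t")
        with open(json_path or tsv_path.replace(".tsv", ".json")) as fh:
            meta = json.load(fh)
        return cls(k=meta["k"], table=table, genome_rate=meta["genome_rate"],
                   min_count=meta.get("min_count", 200))


def _context_table(data: pd.DataFrame, k: int, min_count: int) -> pd.DataFrame:
    agg = (data.groupby("context")
           .agg(n_conv=("n_conv", "sum"), n_total=("n_total", "sum")))
    rows = []
    for ctx in all_contexts(k):
        if ctx in agg.index and agg.loc[ctx, "n_total"] > 0:
            nt = int(agg.loc[ctx, "n_total"])
            rate = float(agg.loc[ctx, "n_conv"] / nt)
            rows.append((ctx, rate, nt, nt < min_count))
        else:
            rows.append((ctx, float("nan"), 0, True))
    return pd.DataFrame(rows, columns=["context", "expected_rate", "count",
                                       "low_confidence"])


def fit_bias_model(naked_track: ConversionTrack, k: int = 3,
                   min_count: int = 200,
                   strand_divergence: float = 0.10) -> BiasModel:
    """Per-context expected conversion rates from a protein-free control.

    The fit pools strands; if the two strands' overall rates differ by more
    than `strand_divergence` (relative), per-strand tables are kept as well
    and used for strand-aware correction.
    """
    if k % 2 == 0:
        raise ValueError("context width k must be odd")
    if naked_track.is_empty:
        raise ValueError("cannot fit a bias model on an empty track")
    data = naked_track.data
    ctx_len = data["context"].str.len()
    if not (ctx_len == k).all():
        raise ValueError(f"track contexts are not width {k}; re-extract with context_k={k}")
    genome_rate = float(data["n_conv"].sum() / data["n_total"].sum())
    table = _context_table(data, k, min_count)
    stranded = None
    by_strand = {s: sub for s, sub in data.groupby("strand")}
    if set(by_strand) == {"+", "-"}:
        rates = {s: sub["n_conv"].sum() / sub["n_total"].sum()
                 for s, sub in by_strand.items()}
        mean = (rates["+"] + rates["-"]) / 2
        if mean > 0 and abs(rates["+"] - rates["-"]) / mean > strand_divergence:
            stranded = {s: _context_table(sub, k, min_count)
                        for s, sub in by_strand.items()}
    return BiasModel(k=k, table=table, genome_rate=genome_rate,
                     min_count=min_count, stranded_tables=stranded)


def correct_track(track: ConversionTrack, model: BiasModel,
                  cap: float = 1.0) -> SignalTrack:
    """Rescale observed rates to remove enzyme context preference.

    corrected = observed * genome_rate / expected_rate(context), clipped to
    [0, cap].  Low-confidence or missing contexts fall back to the genome
    rate (no correction); contexts the control says never convert are
    uncorrectable and dropped with n_total set on the remaining records.
    """
    if model.genome_rate <= 0:
        raise ValueError("bias model genome_rate must be positive")
    sig = SignalTrack.from_counts(track)
    d = track.data

    def factors(table: pd.DataFrame) -> pd.Series:
        exp = table.set_index("context")["expected_rate"].copy()
        low = table.set_index("context")["low_confidence"]
        exp[low | exp.isna()] = model.genome_rate
        return model.genome_rate / exp

    if model.stranded_tables:
        fac = pd.Series(np.nan, index=d.index)
        for strand, table in model.stranded_tables.items():
            m = d["strand"] == strand
            fac[m] = d.loc[m, "context"].map(factors(table)).to_numpy()
    else:
        fac = d["context"].map(factors(model.table))
    uncorrectable = ~np.isfinite(fac.to_numpy())
    sig.data["rate"] = np.clip(sig.data["rate"].to_numpy() * fac.to_numpy(), 0.0, cap)
    if uncorrectable.any():
        sig.data = sig.data.loc[~uncorrectable].reset_index(drop=True)
    return sig


def bias_report(track: ConversionTrack, model: BiasModel) -> pd.DataFrame:
    """Per-context observed vs expected table, sorted by |log ratio|."""
    if track.is_empty:
        return pd.DataFrame(columns=["context", "observed_rate", "expected_rate",
                                     "ratio", "count"])
    obs = (track.data.groupby("context")
           .agg(n_conv=("n_conv", "sum"), n_total=("n_total", "sum")))
    obs["observed_rate"] = obs["n_conv"] / obs["n_total"]
    merged = (obs.reset_index()
              .merge(model.table[["context", "expected_rate"]], on="context",
                     how="left"))
    merged["ratio"] = merged["observed_rate"] / merged["expected_rate"]
    merged["count"] = merged["n_total"]
    with np.errstate(divide="ignore", invalid="ignore"):
        order = np.abs(np.log(merged["ratio"].to_numpy(float)))
    merged["_order"] = np.where(np.isfinite(order), order, -np.inf)
    out = (merged.sort_values("_order", ascending=False)
           .drop(columns=["_order", "n_conv", "n_total"])
           .reset_index(drop=True))
    return out[["context", "observed_rate", "expected_rate", "ratio", "count"]]
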