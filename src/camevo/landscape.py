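"""Windowed genome-composition statistics and spatial distribution of DE
genes.

Windows tile each scaffold from position 0; the last partial window is kept
with its actual length.  A gene belongs to the window containing its start.
GC content is computed over A/C/G/T only (N excluded from the denominator);
repeat content is the soft-masked (lowercase) fraction.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment_stats import StatResult, kendall_tau_b, shapiro_wilk, welch_t
from .io_formats import GeneModel, GenomeSequences


def _gc_fraction(seq: str) -> float:
    up = seq.upper()
    acgt = sum(up.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (up.count("G") + up.count("C")) / acgt


def _masked_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    return sum(c.islower() for c in seq) / len(seq)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _coverage_in_window(merged: Sequence[tuple[int, int]], lo: int, hi: int) -> int:
    return sum(max(0, min(e, hi) - max(s, lo)) for s, e in merged)


def window_stats(genome: GenomeSequences, genes: Sequence[GeneModel],
                 window: int = 1_000_000) -> pd.DataFrame:
    """Per-window gene count (genes starting in the window), soft-masked
    fraction and GC fraction."""
    if window <= 0:
        raise ValueError("window must be positive")
    starts_by_scaffold: dict[str, list[int]] = {}
    for g in genes:
        starts_by_scaffold.setdefault(g.scaffold_id, []).append(g.start)
    rows = []
    for sid in genome.scaffold_ids:
        seq = genome[sid]
        starts = np.array(sorted(starts_by_scaffold.get(sid, [])))
        for lo in range(0, len(seq), window):
            hi = min(lo + window, len(seq))
            chunk = seq[lo:hi]
            n_genes = int(((starts >= lo) & (starts < hi)).sum())
            rows.append({"scaffold": sid, "start": lo, "end": hi,
                         "gene_count": n_genes,
                         "masked_fraction": _masked_fraction(chunk),
                         "gc_fraction": _gc_fraction(chunk)})
    return pd.DataFrame(rows)


def window_stats_fine(genome: GenomeSequences, genes: Sequence[GeneModel],
                      robust_status: Mapping[str, str] | None = None,
                      window: int = 100_000) -> pd.DataFrame:
    """Fine-grained windows: TE (masked) fraction, overall GC, GC within
    masked positions only, merged genic fraction, and the fraction of genic
    positions belonging to non-robust genes."""
    genes_by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_scaffold.setdefault(g.scaffold_id, []).append(g)
    rows = []
    for sid in genome.scaffold_ids:
        seq = genome[sid]
        sc_genes = genes_by_scaffold.get(sid, [])
        merged_all = merge_intervals([(g.start, g.end) for g in sc_genes])
        merged_nonrobust = merge_intervals(
            [(g.start, g.end) for g in sc_genes
             if robust_status is not None
             and robust_status.get(g.gene_id) == "NOT-ROBUST"])
        for lo in range(0, len(seq), window):
            hi = min(lo + window, len(seq))
            chunk = seq[lo:hi]
            masked = [c for c in chunk if c.islower()]
            genic = _coverage_in_window(merged_all, lo, hi)
            nonrobust = _coverage_in_window(merged_nonrobust, lo, hi)
            rows.append({
                "scaffold": sid, "start": lo, "end": hi,
                "te_fraction": _masked_fraction(chunk),
                "gc_all": _gc_fraction(chunk),
                "gc_in_te": _gc_fraction("".join(masked)) if masked else float("nan"),
                "genic_fraction": genic / (hi - lo),
                "nonrobust_gene_fraction": nonrobust / genic if genic else float("nan"),
            })
    return pd.DataFrame(rows)


def correlate(series_x, series_y) -> dict:
    """Kendall tau-b with asymptotic p plus Shapiro-Wilk normality p for
    each series (the diagnostic that motivates the rank test)."""
    x = np.asarray(series_x, float)
    y = np.asarray(series_y, float)
    res = kendall_tau_b(x, y)
    return {"tau_b": res.statistic, "p": res.p,
            "shapiro_p_x": shapiro_wilk(x), "shapiro_p_y": shapiro_wilk(y)}


def repetitive_to_exonic(scaffold_stats_a: pd.DataFrame,
                         scaffold_stats_b: pd.DataFrame) -> dict:
    """Per-scaffold masked/exonic base ratios per species, Welch's t between
    species and the ratio of means.  Input frames need columns
    ``repetitive_bases`` and ``exonic_bases``; zero-exon scaffolds are
    skipped with a warning note."""
    def ratios(df: pd.DataFrame) -> np.ndarray:
        ok = df["exonic_bases"] > 0
        return (df.loc[ok, "repetitive_bases"] / df.loc[ok, "exonic_bases"]).to_numpy()

    ra, rb = ratios(scaffold_stats_a), ratios(scaffold_stats_b)
    res: StatResult = welch_t(ra, rb)
    return {"ratios_a": ra, "ratios_b": rb,
            "t": res.statistic, "p": res.p,
            "ratio_of_means": float(ra.mean() / rb.mean()) if rb.mean() else float("nan"),
            "n_skipped_a": int((scaffold_stats_a["exonic_bases"] <= 0).sum()),
            "n_skipped_b": int((scaffold_stats_b["exonic_bases"] <= 0).sum())}


def de_spatial(genes: Sequence[GeneModel], de_flags: Mapping[str, bool],
               scaffold_lengths: Mapping[str, int],
               window: int = 1_000_000) -> tuple[pd.DataFrame, dict]:
    """Per-window DE-gene density and proportion, plus the Kendall
    correlation of per-scaffold DE count with scaffold length."""
    rows = []
    per_scaffold_de: dict[str, int] = {sid: 0 for sid in scaffold_lengths}
    genes_by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_scaffold.setdefault(g.scaffold_id, []).append(g)
        if de_flags.get(g.gene_id, False):
            per_scaffold_de[g.scaffold_id] = per_scaffold_de.get(g.scaffold_id, 0) + 1
    for sid, length in scaffold_lengths.items():
        sc_genes = genes_by_scaffold.get(sid, [])
        for lo in range(0, length, window):
            hi = min(lo + window, length)
            in_win = [g for g in sc_genes if lo <= g.start < hi]
            n_de = sum(de_flags.get(g.gene_id, False) for g in in_win)
            rows.append({"scaffold": sid, "start": lo, "end": hi,
                         "de_count": n_de, "gene_count": len(in_win),
                         "de_proportion": n_de / len(in_win) if in_win else float("nan")})
    df = pd.DataFrame(rows)
    sids = sorted(scaffold_lengths)
    counts = [per_scaffold_de.get(s, 0) for s in sids]
    lengths = [scaffold_lengths[s] for s in sids]
    corr = correlate(counts, lengths) if len(sids) >= 3 else \
        {"tau_b": float("nan"), "p": float("nan"),
         "shapiro_p_x": float("nan"), "shapiro_p_y": float("nan")}
    return df, corr
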