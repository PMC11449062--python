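"""Diel metabolite statistics: MTIC normalization, 24-h accumulation, fold
differences, species comparison, and PCA of metabolic composition.

The design mirrors the study layout: two species x six accessions x six
timepoints (D+1, D+5, D+9, N+1, N+5, N+9 under a 12-h light cycle; mapped
to 1, 5, 9, 13, 17, 21 hours after lights-on).  Abundances are GC-MS peak
areas normalized against each sample's main total ion count (MTIC), hence
unitless ratios.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .enrichment_stats import StatResult, mann_whitney

TIMEPOINT_HOURS = {"D+1": 1.0, "D+5": 5.0, "D+9": 9.0,
                   "N+1": 13.0, "N+5": 17.0, "N+9": 21.0}

META_COLUMNS = ("species", "accession", "timepoint")


def mtic_normalize(raw_areas: pd.DataFrame, per_sample_mtic: pd.Series) -> pd.DataFrame:
    """Divide each sample's summed compound areas by that sample's MTIC.

    ``raw_areas``: samples x compounds (plus the species/accession/timepoint
    metadata columns, passed through).  Samples with MTIC <= 0 are dropped
    with a warning.
    """
    mtic = per_sample_mtic.reindex(raw_areas.index)
    bad = mtic.index[(mtic <= 0) | mtic.isna()]
    if len(bad):
        warnings.warn(f"dropping {len(bad)} sample(s) with non-positive MTIC")
    keep = raw_areas.index.difference(bad)
    out = raw_areas.loc[keep].copy()
    compounds = [c for c in out.columns if c not in META_COLUMNS]
    out[compounds] = out[compounds].div(mtic.loc[keep], axis=0)
    return out


def accumulation(series) -> float:
    """Max minus min abundance over one accession's time series."""
    vals = pd.Series(series).dropna()
    if len(vals) < 2:
        return float("nan")
    return float(vals.max() - vals.min())


def per_accession_accumulation(table: pd.DataFrame, compound: str) -> pd.DataFrame:
    """24-h accumulation per (species, accession)."""
    rows = []
    for (sp, acc), grp in table.groupby(["species", "accession"]):
        rows.append({"species": sp, "accession": acc,
                     "accumulation": accumulation(grp[compound])})
    return pd.DataFrame(rows)


def median_fold(table: pd.DataFrame, compound: str,
                species: str | None = None) -> dict:
    """Peak/trough timepoints of the per-timepoint median abundance and
    their fold ratio (max median / min median)."""
    sub = table if species is None else table[table["species"] == species]
    med = sub.groupby("timepoint")[compound].median().dropna()
    if len(med) < 2:
        raise ValueError("need medians at >= 2 timepoints")
    peak, trough = med.idxmax(), med.idxmin()
    if med[trough] == 0:
        return {"peak_time": peak, "trough_time": trough,
                "fold": float("inf"), "flag": "zero trough median"}
    return {"peak_time": peak, "trough_time": trough,
            "fold": float(med[peak] / med[trough])}


def species_accumulation_test(table: pd.DataFrame, compound: str,
                              species_pair: tuple[str, str] = ("F", "L")) -> StatResult:
    """Two-sided (exact at n=6 vs 6) Mann-Whitney on per-accession 24-h
    accumulations between species; the fold of median accumulations rides
    in the notes."""
    acc = per_accession_accumulation(table, compound)
    x = acc.loc[acc["species"] == species_pair[0], "accumulation"].dropna().to_numpy()
    y = acc.loc[acc["species"] == species_pair[1], "accumulation"].dropna().to_numpy()
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 accessions per species")
    res = mann_whitney(x, y)
    med_y = float(np.median(y))
    res.notes["median_fold"] = float(np.median(x) / med_y) if med_y else float("nan")
    return res


def metabolite_pca(table: pd.DataFrame, n_components: int = 2) -> dict:
    """PCA of metabolic composition (samples x compounds).

    Missing values are imputed with the compound median; compounds are
    centered and scaled to unit variance (they span orders of magnitude);
    scores come from the SVD of the standardized matrix.  Zero-variance
    compounds are dropped with a warning.
    """
    compounds = [c for c in table.columns if c not in META_COLUMNS]
    X = table[compounds].apply(pd.to_numeric).copy()
    X = X.fillna(X.median())
    sd = X.std(ddof=1)
    zero_var = sd.index[(sd == 0) | sd.isna()]
    if len(zero_var):
        warnings.warn(f"dropping {len(zero_var)} zero-variance compound(s)")
        X = X.drop(columns=list(zero_var))
        sd = sd.drop(list(zero_var))
    Z = (X - X.mean()) / sd
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    var = S ** 2 / (len(Z) - 1)
    var_frac = var / var.sum()
    k = min(n_components, len(S))
    scores = pd.DataFrame(U[:, :k] * S[:k], index=table.index,
                          columns=[f"PC{i+1}" for i in range(k)])
    loadings = pd.DataFrame(Vt[:k].T, index=X.columns,
                            columns=[f"PC{i+1}" for i in range(k)])
    return {"scores": scores, "loadings": loadings,
            "variance_fraction": var_frac[:k],
            "variance_fraction_all": var_frac}
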