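"""Shared statistical kernels plus orthogroup-category and GO enrichment.

Every test returns a :class:`StatResult` so downstream tables carry the test
name, the statistic, raw and adjusted p-values and an effect size together.
The 2x2 chi-square applies the Yates continuity correction by default,
matching R's ``chisq.test`` behaviour on 2x2 tables, because the study's
contingency tests were run in R.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class StatResult:
    test: str
    statistic: float
    p: float
    adjusted_p: float | None = None
    effect_size: float | None = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def chi_square_2x2(table, continuity: bool = True) -> StatResult:
    """2x2 chi-square test of independence with optional Yates correction.

    A zero row or column margin makes the test degenerate; by convention the
    result is p=1 with a ``degenerate`` note.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return StatResult("chi-square", 0.0, 1.0, notes={"degenerate": True})
    stat, p, _, _ = stats.chi2_contingency(t, correction=continuity)
    odds = _odds_ratio(t)
    return StatResult("chi-square", float(stat), float(p), effect_size=odds,
                      notes={"continuity": continuity})


def fisher_exact_2x2(table) -> StatResult:
    """Two-sided Fisher's exact test (hypergeometric point-probability rule)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return StatResult("fisher-exact", np.nan, 1.0, notes={"degenerate": True})
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return StatResult("fisher-exact", float(odds), float(p),
                      effect_size=_odds_ratio(t))


def _odds_ratio(t: np.ndarray) -> float:
    denom = t[0, 1] * t[1, 0]
    if denom == 0:
        return np.inf if t[0, 0] * t[1, 1] > 0 else np.nan
    return float(t[0, 0] * t[1, 1] / denom)


def mann_whitney(x, y, exact_threshold: int = 20) -> StatResult:
    """Two-sided Mann-Whitney U.

    Exact when both samples have n <= ``exact_threshold`` and there are no
    ties across the pooled data; otherwise the tie-corrected normal
    approximation (with continuity correction) is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    use_exact = no_ties and len(x) <= exact_threshold and len(y) <= exact_threshold
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if use_exact else "asymptotic")
    return StatResult("mann-whitney-u", float(res.statistic), float(res.pvalue),
                      notes={"method": "exact" if use_exact else "asymptotic",
                             "median_x": float(np.median(x)),
                             "median_y": float(np.median(y)),
                             "mean_x": float(np.mean(x)),
                             "mean_y": float(np.mean(y))})


def welch_t(x, y) -> StatResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch's t needs at least 2 observations per group")
    res = stats.ttest_ind(x, y, equal_var=False)
    return StatResult("welch-t", float(res.statistic), float(res.pvalue),
                      notes={"mean_x": float(np.mean(x)), "mean_y": float(np.mean(y))})


def shapiro_wilk(x) -> float:
    """Shapiro-Wilk normality p-value (diagnostic only)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0:
        return float("nan")
    return float(stats.shapiro(x).pvalue)


def kendall_tau_b(x, y) -> StatResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length series of at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult("kendall-tau-b", np.nan, np.nan,
                          notes={"degenerate": "constant series"})
    res = stats.kendalltau(x, y, variant="b")
    return StatResult("kendall-tau-b", float(res.statistic), float(res.pvalue),
                      effect_size=float(res.statistic))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Orthogroup-category enrichment
# ---------------------------------------------------------------------------

CATEGORIES_TESTED = ("F=1:L=1", "F>L", "F<L", "F=L(>1)")


def category_enrichment(categories: dict[str, str],
                        de_flags: dict[str, bool],
                        cam_flags: dict[str, bool] | None = None) -> pd.DataFrame:
    """Test relative-family-size categories for enrichment among DE orthogroups.

    For each category c, a 2x2 table [[DE & c, DE & not-c], [nonDE & c,
    nonDE & not-c]] is tested by chi-square; for the CAM-DE subset versus
    non-CAM DE orthogroups Fisher's exact test is used instead (small
    counts).  Species-unique orthogroups must already be excluded from
    ``categories``.  Returns one row per category per comparison with
    BH-adjusted p within each comparison.
    """
    ogs = [og for og, c in categories.items() if c in CATEGORIES_TESTED]
    if not any(de_flags.get(og, False) for og in ogs):
        raise ValueError("empty DE orthogroup set")
    rows = []

    def run(target_ogs, other_ogs, comparison, test):
        for cat in CATEGORIES_TESTED:
            a = sum(categories[og] == cat for og in target_ogs)
            b = len(target_ogs) - a
            c = sum(categories[og] == cat for og in other_ogs)
            d = len(other_ogs) - c
            res = (fisher_exact_2x2 if test == "fisher" else chi_square_2x2)(
                [[a, b], [c, d]])
            p_t = a / len(target_ogs) if target_ogs else np.nan
            p_o = c / len(other_ogs) if other_ogs else np.nan
            fold = p_t / p_o if p_o else np.nan
            rows.append({"comparison": comparison, "category": cat,
                         "target_count": a, "target_total": len(target_ogs),
                         "other_count": c, "other_total": len(other_ogs),
                         "test": res.test, "statistic": res.statistic,
                         "p": res.p, "fold": fold})

    de = [og for og in ogs if de_flags.get(og, False)]
    non_de = [og for og in ogs if not de_flags.get(og, False)]
    run(de, non_de, "DE_vs_nonDE", "chi2")
    if cam_flags is not None:
        cam_de = [og for og in de if cam_flags.get(og, False)]
        other_de = [og for og in de if not cam_flags.get(og, False)]
        if cam_de:
            run(cam_de, other_de, "CAMDE_vs_nonCAMDE", "fisher")
    df = pd.DataFrame(rows)
    df["adjusted_p"] = np.nan
    for comp in df["comparison"].unique():
        mask = df["comparison"] == comp
        df.loc[mask, "adjusted_p"] = bh_adjust(df.loc[mask, "p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

def propagate_annotations(gene2terms: dict[str, set[str]],
                          parents: dict[str, set[str]]) -> dict[str, set[str]]:
    """Extend each gene's GO annotation with all ancestors (is_a/part_of)."""
    cache: dict[str, set[str]] = {}

    def ancestors(term: str) -> set[str]:
        if term not in cache:
            cache[term] = set()  # cycle guard; GO is a DAG
            out = set()
            for p in parents.get(term, ()):  # direct parents
                out.add(p)
                out |= ancestors(p)
            cache[term] = out
        return cache[term]

    out = {}
    for gene, terms in gene2terms.items():
        full = set(terms)
        for t in terms:
            full |= ancestors(t)
        out[gene] = full
    return out


def go_enrichment(target_genes, background_genes,
                  gene2terms: dict[str, set[str]],
                  parents: dict[str, set[str]] | None = None,
                  top_n: int | None = None) -> pd.DataFrame:
    """Classic per-term Fisher's exact GO enrichment with ancestor propagation.

    The target must be a subset of the background.  Terms never annotated in
    the background are skipped.  Returns a table sorted by p with BH column.
    """
    target = set(target_genes)
    background = set(background_genes)
    annot = propagate_annotations(
        {g: set(ts) for g, ts in gene2terms.items()}, parents or {})
    term2bg: dict[str, int] = {}
    term2target: dict[str, int] = {}
    for gene in background:
        for term in annot.get(gene, ()):
            term2bg[term] = term2bg.get(term, 0) + 1
            if gene in target:
                term2target[term] = term2target.get(term, 0) + 1
    rows = []
    n_t, n_b = len(target), len(background)
    for term, bg_count in term2bg.items():
        k = term2target.get(term, 0)
        table = [[k, n_t - k], [bg_count - k, (n_b - n_t) - (bg_count - k)]]
        res = fisher_exact_2x2(table)
        rows.append({"term": term, "target_count": k, "background_count": bg_count,
                     "p": res.p, "odds_ratio": res.effect_size})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["adjusted_p"] = bh_adjust(df["p"].to_numpy())
    df = df.sort_values("p", kind="stable").reset_index(drop=True)
    if top_n is not None:
        df = df.head(top_n)
    return df


def candidate_gene_lookup(candidate_ids_outgroup,
                          orthogroups,
                          focal_species=("F", "L")) -> dict[str, set[str]]:
    """Map outgroup candidate gene ids to focal-species genes that share an
    orthogroup with them.  Unknown ids are skipped."""
    wanted = set(candidate_ids_outgroup)
    out: dict[str, set[str]] = {sp: set() for sp in focal_species}
    for og in orthogroups:
        if wanted & set(og.genes_by_species.get("A", [])):
            for sp in focal_species:
                out[sp] |= set(og.genes_by_species.get(sp, []))
    return out
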