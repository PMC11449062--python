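"""Diel time-course differential expression between two species.

Exon-level counts are summed to gene level, TMM-normalized, filtered at
mean cpm >= 1 and tested gene-by-gene with a two-stage polynomial
regression on log2(cpm + 1) (maSigPro-style): stage 1 keeps genes whose
full species-by-time model beats the intercept (overall F-test, BH across
genes); stage 2 prunes terms by backward elimination, and a gene is called
differentially expressed between species when the pruned model retains a
species main effect or any species-by-time interaction and explains enough
variance (R^2 >= 0.6 by default).  Species L (T. leiboldiana) is the
regression baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .enrichment_stats import bh_adjust

DEFAULT_DEGREE = 3
DEFAULT_ALPHA = 0.05
DEFAULT_RSQ_MIN = 0.6


@dataclass
class SampleDesign:
    """Per-sample annotation: species label, genotype (replicate accession)
    and time in hours into the 24-h cycle (0 = first sampled point, one
    hour after lights-off)."""

    sample_ids: list[str]
    species: list[str]
    genotype: list[str]
    time: list[float]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not len(self.species) == len(self.genotype) == len(self.time) == n:
            raise ValueError("design columns have unequal lengths")

    @classmethod
    def from_sample_ids(cls, sample_ids) -> "SampleDesign":
        """Parse ids of the form ``<species>_<genotype>_t<hours>``."""
        species, genotype, time = [], [], []
        for sid in sample_ids:
            sp, gt, t = sid.rsplit("_", 2)
            species.append(sp)
            genotype.append(gt)
            time.append(float(t.lstrip("t")))
        return cls(list(sample_ids), species, genotype, time)


@dataclass
class DEResult:
    gene_id: str
    p_stage1: float
    adj_p_stage1: float
    selected_terms: list[str] = field(default_factory=list)
    r_squared: float = float("nan")
    is_de: bool = False
    cluster_id: int | None = None


# ---------------------------------------------------------------------------
# Count processing
# ---------------------------------------------------------------------------

def exon_to_gene_counts(exon_matrix: pd.DataFrame,
                        exon_to_gene: dict[str, str] | None = None) -> pd.DataFrame:
    """Sum exon rows to gene rows, per sample.

    By default the parent gene is everything before the last ``.exon<k>``
    suffix of the exon id; a mapping can be supplied instead.  Every exon
    must have a parent.
    """
    if exon_to_gene is None:
        exon_to_gene = {}
        for eid in exon_matrix.index:
            if ".exon" not in eid:
                raise ValueError(f"exon {eid!r} has no parent gene")
            exon_to_gene[eid] = eid.rsplit(".exon", 1)[0]
    missing = [e for e in exon_matrix.index if e not in exon_to_gene]
    if missing:
        raise ValueError(f"exon(s) without parent gene: {missing[:5]}")
    parents = pd.Index([exon_to_gene[e] for e in exon_matrix.index], name="gene_id")
    return exon_matrix.groupby(parents, sort=False).sum()


def tmm_normalize(gene_matrix: pd.DataFrame,
                  ref_column: str | None = None,
                  trim_m: float = 0.30,
                  trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (Robinson-Oshlack).

    Per sample versus a reference column, genes zero in either library are
    dropped, the 30% tails of M (log2 expression ratio) and the 5% tails of
    A (average log2 abundance) are trimmed, and the factor is the weighted
    mean of the remaining M with inverse approximate (delta-method binomial)
    variances as weights.  Factors are rescaled to geometric mean 1.  The
    reference defaults to the sample whose upper-quartile count fraction is
    closest to the mean upper quartile.
    """
    counts = gene_matrix.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = gene_matrix.columns[lib == 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    if ref_column is None:
        q75 = np.array([np.quantile(counts[:, k] / lib[k], 0.75)
                        for k in range(counts.shape[1])])
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = gene_matrix.columns.get_loc(ref_column)
    ref = counts[:, ref_idx]
    n_ref = lib[ref_idx]
    log_factors = np.zeros(counts.shape[1])
    for k in range(counts.shape[1]):
        if k == ref_idx:
            continue
        obs = counts[:, k]
        n_obs = lib[k]
        keep = (obs > 0) & (ref > 0)
        if keep.sum() == 0:
            continue
        p_obs, p_ref = obs[keep] / n_obs, ref[keep] / n_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # variance of M via the delta method on two binomial proportions
        w = (n_obs - obs[keep]) / (n_obs * obs[keep]) + (n_ref - ref[keep]) / (n_ref * ref[keep])
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        sel = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if sel.sum() == 0 or np.sum(1.0 / w[sel]) == 0:
            continue
        log_factors[k] = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=gene_matrix.columns, name="tmm_factor")


def cpm(gene_matrix: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    lib = gene_matrix.sum(axis=0)
    eff = lib * (factors if factors is not None else 1.0)
    return gene_matrix / eff * 1e6


def cpm_filter(gene_matrix: pd.DataFrame, factors: pd.Series,
               min_mean_cpm: float = 1.0) -> pd.DataFrame:
    """Keep genes with mean cpm across all samples >= 1 (boundary kept)."""
    mean_cpm = cpm(gene_matrix, factors).mean(axis=1)
    return gene_matrix.loc[mean_cpm >= min_mean_cpm]


def tpm(gene_matrix: pd.DataFrame, exonic_length_kb: pd.Series) -> pd.DataFrame:
    """Transcripts per million: reads per kb of exon (RPK) rescaled so each
    sample sums to 10^6."""
    lengths = exonic_length_kb.reindex(gene_matrix.index)
    if lengths.isna().any():
        raise ValueError("missing exonic length for some genes")
    if (lengths <= 0).any():
        raise ValueError("zero or negative exonic length")
    rpk = gene_matrix.div(lengths, axis=0)
    return rpk / rpk.sum(axis=0) * 1e6


# ---------------------------------------------------------------------------
# Two-stage regression DE
# ---------------------------------------------------------------------------

def _design_matrix(design: SampleDesign, baseline_species: str, degree: int):
    """Columns: intercept, species indicator, t^k, and species x t^k terms.
    Time is scaled to [0, 1] to keep the polynomial well conditioned."""
    t = np.asarray(design.time, dtype=float)
    t = t / max(t.max(), 1.0)
    s = np.asarray([0.0 if sp == baseline_species else 1.0 for sp in design.species])
    cols = [np.ones_like(t), s]
    names = ["intercept", "species"]
    for k in range(1, degree + 1):
        cols.append(t ** k)
        names.append(f"t^{k}")
    for k in range(1, degree + 1):
        cols.append(s * t ** k)
        names.append(f"species:t^{k}")
    return np.column_stack(cols), names


def _ols_fit(X: np.ndarray, y: np.ndarray):
    """Least-squares fit returning (beta, rss, per-term two-sided p)."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - rank
    if df <= 0:
        return beta, rss, np.full(p, np.nan)
    sigma2 = rss / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 1e-300))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    return beta, rss, pvals


def timecourse_de(gene_matrix: pd.DataFrame,
                  design: SampleDesign,
                  baseline_species: str = "L",
                  factors: pd.Series | None = None,
                  degree: int = DEFAULT_DEGREE,
                  alpha: float = DEFAULT_ALPHA,
                  rsq_min: float = DEFAULT_RSQ_MIN) -> list[DEResult]:
    """Two-stage polynomial-regression caller for between-species diel DE.

    Operates on log2(cpm+1).  See the module docstring for the procedure.
    """
    n_time = len(set(design.time))
    if degree > n_time - 1:
        raise ValueError(f"degree {degree} too high for {n_time} time points")
    X, names = _design_matrix(design, baseline_species, degree)
    n, p_full = X.shape
    if np.linalg.matrix_rank(X) < p_full:
        raise ValueError("rank-deficient full design")
    Y = np.log2(cpm(gene_matrix, factors).to_numpy(dtype=float) + 1.0)

    # Stage 1: overall regression F-test, vectorized across genes
    beta = np.linalg.lstsq(X, Y.T, rcond=None)[0]
    fitted = (X @ beta).T
    rss = ((Y - fitted) ** 2).sum(axis=1)
    tss = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df1, df2 = p_full - 1, n - p_full
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((tss - rss) / df1) / (rss / df2)
    p1 = np.where(tss > 0, stats.f.sf(f, df1, df2), 1.0)
    p1 = np.where(np.isfinite(p1), p1, 0.0)  # rss==0 with signal -> p 0
    adj1 = bh_adjust(p1)

    results = []
    for i, gene_id in enumerate(gene_matrix.index):
        res = DEResult(gene_id, float(p1[i]), float(adj1[i]))
        if adj1[i] <= alpha:
            sel = _backward_select(X, names, Y[i], alpha)
            if sel is not None:
                terms, rsq = sel
                res.selected_terms = terms
                res.r_squared = rsq
                species_term = any(t == "species" or t.startswith("species:")
                                   for t in terms)
                res.is_de = species_term and rsq >= rsq_min
        results.append(res)
    return results


def _backward_select(X, names, y, alpha):
    """Backward-stepwise elimination at significance level ``alpha``; the
    intercept is never dropped.  Returns (kept term names, R^2)."""
    keep = list(range(X.shape[1]))
    while len(keep) > 1:
        _, _, pvals = _ols_fit(X[:, keep], y)
        candidates = [(pv, j) for j, pv in enumerate(pvals) if keep[j] != 0]
        worst_p, worst_j = max(candidates, key=lambda t: (np.nan_to_num(t[0], nan=1.0)))
        if np.isnan(worst_p) or worst_p > alpha:
            keep.pop(worst_j)
        else:
            break
    beta, rss, _ = _ols_fit(X[:, keep], y)
    tss = float(((y - y.mean()) ** 2).sum())
    rsq = 1.0 - rss / tss if tss > 0 else 0.0
    return [names[k] for k in keep if k != 0], rsq


# ---------------------------------------------------------------------------
# Clustering and curves
# ---------------------------------------------------------------------------

def de_profiles(tpm_matrix: pd.DataFrame, design: SampleDesign,
                gene_ids) -> pd.DataFrame:
    """Per-gene concatenated per-species mean median-centered log TPM profile."""
    log_tpm = np.log2(tpm_matrix.loc[list(gene_ids)] + 1.0)
    blocks = []
    for sp in sorted(set(design.species)):
        for t in sorted(set(design.time)):
            cols = [sid for sid, s, tt in
                    zip(design.sample_ids, design.species, design.time)
                    if s == sp and tt == t]
            if cols:
                mean = log_tpm[cols].mean(axis=1)
                blocks.append((f"{sp}_t{t:g}", mean - mean.median()))
    return pd.DataFrame({name: col for name, col in blocks})


def cluster_de(profiles: pd.DataFrame, max_k: int = 12,
               improvement: float = 0.10, seed: int = 0) -> pd.Series:
    """Average-linkage hierarchical clustering on 1 - Pearson correlation,
    with the number of modules K picked by a k-means elbow (smallest k
    whose within-cluster-SS improvement over k-1 falls below 10%)."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 DE genes to cluster")
    P = profiles.to_numpy(dtype=float)
    sd = P.std(axis=1)
    Z = np.where(sd[:, None] > 0, (P - P.mean(axis=1, keepdims=True)) /
                 np.where(sd[:, None] > 0, sd[:, None], 1.0), 0.0)
    corr = np.clip(Z @ Z.T / P.shape[1], -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    max_k = min(max_k, len(profiles))
    wss = {}
    for k in range(1, max_k + 1):
        km = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(Z)
        wss[k] = km.inertia_ if km.inertia_ > 0 else 1e-12
    # elbow: stop at the first k whose gain is <10% of the total spread
    K = max_k
    for k in range(2, max_k + 1):
        if (wss[k - 1] - wss[k]) / wss[1] < improvement:
            K = k - 1
            break
    K = max(K, 1)
    condensed = dist[np.triu_indices(len(profiles), k=1)]
    tree = linkage(condensed, method="average")
    labels = fcluster(tree, t=K, criterion="maxclust")
    return pd.Series(labels, index=profiles.index, name="cluster_id")


def expression_curves(tpm_matrix: pd.DataFrame, design: SampleDesign,
                      gene_ids, mode: str = "mean_sd") -> pd.DataFrame:
    """Expression curves for plotting.

    ``mean_sd``: per species x time mean TPM and sd across accessions.
    ``median_centered``: per-gene log TPM minus the across-genes median at
    each species x time point.
    """
    sub = tpm_matrix.loc[list(gene_ids)]
    keys = sorted({(s, t) for s, t in zip(design.species, design.time)})
    if mode == "mean_sd":
        rows = []
        for g in sub.index:
            for sp, t in keys:
                cols = [sid for sid, s, tt in
                        zip(design.sample_ids, design.species, design.time)
                        if s == sp and tt == t]
                vals = sub.loc[g, cols].to_numpy(dtype=float)
                rows.append({"gene_id": g, "species": sp, "time": t,
                             "mean_tpm": float(vals.mean()),
                             "sd_tpm": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0})
        return pd.DataFrame(rows)
    if mode == "median_centered":
        log_tpm = np.log2(sub + 1.0)
        rows = []
        for sp, t in keys:
            cols = [sid for sid, s, tt in
                    zip(design.sample_ids, design.species, design.time)
                    if s == sp and tt == t]
            mean_log = log_tpm[cols].mean(axis=1)
            centered = mean_log - mean_log.median()
            for g in sub.index:
                rows.append({"gene_id": g, "species": sp, "time": t,
                             "centered_log_tpm": float(centered[g])})
        return pd.DataFrame(rows)
    raise ValueError(f"unknown mode {mode!r}")
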