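"""Pairwise dN/dS (omega) estimation under a Goldman-Yang codon model with a
likelihood-ratio test against neutrality (omega = 1).

The model acts on the 61 sense codons of the universal code.  Instantaneous
rates are zero for multi-nucleotide changes and otherwise

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous],

with codon frequencies pi from F3x4 (positional nucleotide frequencies
estimated jointly from both sequences) and Q scaled to one expected
substitution per codon per unit time.  The model is time-reversible, so the
pairwise likelihood depends only on the total divergence t:
L = prod_sites pi_a P(t)_{a,b}.  The free model maximizes lnL over
(t, kappa, omega); the null fixes omega = 1; 2*dlnL is referred to
chi-square(1).  dN and dS are derived from t, omega and the model's
proportions of synonymous/nonsynonymous change, with per-site denominators
taken at omega = 1 (the mutational opportunity), so dN/dS equals omega
exactly.

A Nei-Gojobori (1986) counting estimator with Jukes-Cantor correction is
provided as an independent cross-check, never as the primary estimate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.optimize import minimize
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .enrichment_stats import StatResult, bh_adjust, mann_whitney

NUCS = "TCAG"
STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple(
    a + b + c
    for a in NUCS for b in NUCS for c in NUCS
    if a + b + c not in STOP_CODONS
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@lru_cache(maxsize=None)
def _codon_aa(codon: str) -> str:
    return str(Seq(codon).translate())


def _single_changes():
    """(i, j, is_transition, is_synonymous) for all single-nt codon pairs."""
    out = []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            a, b = diffs[0]
            out.append((i, j, frozenset((a, b)) in _TRANSITIONS,
                        _codon_aa(ci) == _codon_aa(cj)))
    return out

_SINGLE = _single_changes()
_I = np.array([x[0] for x in _SINGLE])
_J = np.array([x[1] for x in _SINGLE])
_TS = np.array([x[2] for x in _SINGLE])
_SYN = np.array([x[3] for x in _SINGLE])


# ---------------------------------------------------------------------------
# Model machinery
# ---------------------------------------------------------------------------

def f3x4_frequencies(codons1, codons2) -> np.ndarray:
    """F3x4 sense-codon frequencies from both sequences' positional
    nucleotide compositions, normalized over the 61 sense codons."""
    pos_freq = np.full((3, 4), 1e-6)
    for codon in itertools.chain(codons1, codons2):
        for p, nt in enumerate(codon):
            if nt in NUCS:
                pos_freq[p, NUCS.index(nt)] += 1.0
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    pi = np.array([
        pos_freq[0, NUCS.index(c[0])]
        * pos_freq[1, NUCS.index(c[1])]
        * pos_freq[2, NUCS.index(c[2])]
        for c in SENSE_CODONS
    ])
    return pi / pi.sum()


def build_rate_matrix(pi: np.ndarray, kappa: float, omega: float) -> np.ndarray:
    """Scaled GY-type Q (rows sum to 0; expected rate 1 per unit time)."""
    Q = np.zeros((N_CODONS, N_CODONS))
    rates = np.where(_TS, kappa, 1.0) * np.where(_SYN, 1.0, omega) * pi[_J]
    Q[_I, _J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(pi @ np.diag(Q))
    if scale <= 0:
        raise ValueError("degenerate rate matrix")
    return Q / scale


def _syn_proportions(pi: np.ndarray, kappa: float, omega: float) -> tuple[float, float]:
    """Proportions (rho_S, rho_N) of substitutions that are synonymous /
    nonsynonymous under the scaled model."""
    rates = np.where(_TS, kappa, 1.0) * np.where(_SYN, 1.0, omega) * pi[_J] * pi[_I]
    total = rates.sum()
    syn = rates[_SYN].sum()
    return syn / total, (total - syn) / total


def transition_matrix(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via symmetrization (the model is reversible)."""
    d = np.sqrt(pi)
    A = Q * d[:, None] / d[None, :]
    A = (A + A.T) / 2.0
    lam, U = np.linalg.eigh(A)
    P = (U * np.exp(lam * t)) @ U.T
    P = P / d[:, None] * d[None, :]
    return np.clip(P, 0.0, None)


def _pattern_counts(codons1, codons2) -> np.ndarray:
    """61x61 matrix of aligned codon-pair counts (gapless columns only)."""
    N = np.zeros((N_CODONS, N_CODONS))
    for c1, c2 in zip(codons1, codons2):
        i, j = CODON_INDEX.get(c1), CODON_INDEX.get(c2)
        if i is not None and j is not None:
            N[i, j] += 1.0
    return N


def _loglik(N: np.ndarray, pi: np.ndarray, t: float, kappa: float,
            omega: float) -> float:
    Q = build_rate_matrix(pi, kappa, omega)
    P = transition_matrix(Q, pi, t)
    with np.errstate(divide="ignore"):
        L = np.log(np.maximum(pi[:, None] * P, 1e-300))
    return float((N * L).sum())


@dataclass
class CodonPairResult:
    pair_id: str
    n_codons: int
    n_variant_sites: int
    omega: float = float("nan")
    dn: float = float("nan")
    ds: float = float("nan")
    kappa: float = float("nan")
    t: float = float("nan")
    lnl_free: float = float("nan")
    lnl_fixed: float = float("nan")
    lrt: float = float("nan")
    p: float = float("nan")
    adjusted_p: float = float("nan")
    flags: set[str] = field(default_factory=set)


T_BOUNDS = (1e-6, 50.0)
KAPPA_BOUNDS = (0.05, 100.0)
OMEGA_BOUNDS = (1e-4, 999.0)
OMEGA_CAP = 999.0


def _maximize(N, pi, fix_omega: float | None, starts=(0.2, 1.0, 3.0)):
    """Bounded quasi-Newton maximization of the pair log-likelihood."""
    best = None
    if fix_omega is None:
        def nll(x):
            return -_loglik(N, pi, x[0], x[1], x[2])
        for w0 in starts:
            res = minimize(nll, x0=np.array([0.3, 2.0, w0]), method="L-BFGS-B",
                           bounds=[T_BOUNDS, KAPPA_BOUNDS, OMEGA_BOUNDS])
            if best is None or res.fun < best.fun:
                best = res
        t, kappa, omega = best.x
    else:
        def nll(x):
            return -_loglik(N, pi, x[0], x[1], fix_omega)
        best = minimize(nll, x0=np.array([0.3, 2.0]), method="L-BFGS-B",
                        bounds=[T_BOUNDS, KAPPA_BOUNDS])
        t, kappa = best.x
        omega = fix_omega
    return float(-best.fun), float(t), float(kappa), float(omega)


def pairwise_dnds_ml(codons1, codons2, pair_id: str = "pair") -> CodonPairResult:
    """ML fit of the pairwise codon model; LRT against omega = 1.

    Input: two equal-length lists of aligned codons (gap-containing columns
    already removed, or given as triples containing '-' which are skipped).
    """
    codons1 = [c.upper() for c in codons1]
    codons2 = [c.upper() for c in codons2]
    keep = [(a, b) for a, b in zip(codons1, codons2)
            if a in CODON_INDEX and b in CODON_INDEX]
    n_var = count_variant_sites(codons1, codons2)
    result = CodonPairResult(pair_id, len(keep), n_var)
    if not keep:
        result.flags.add("empty")
        return result
    if n_var == 0:
        result.omega, result.dn, result.ds, result.t = float("nan"), 0.0, 0.0, 0.0
        result.flags.add("identical")
        return result
    c1, c2 = zip(*keep)
    pi = f3x4_frequencies(c1, c2)
    N = _pattern_counts(c1, c2)
    lnl_free, t, kappa, omega = _maximize(N, pi, None)
    lnl_fixed, _, _, _ = _maximize(N, pi, 1.0)
    lrt = max(0.0, 2.0 * (lnl_free - lnl_fixed))
    rho_s, rho_n = _syn_proportions(pi, kappa, omega)
    rho_s1, rho_n1 = _syn_proportions(pi, kappa, 1.0)
    ds = t * rho_s / (3.0 * rho_s1)
    dn = t * rho_n / (3.0 * rho_n1)
    if ds < 1e-6:
        result.flags.add("dS_zero")
        omega = OMEGA_CAP
    result.omega, result.dn, result.ds = float(omega), float(dn), float(ds)
    result.kappa, result.t = float(kappa), float(t)
    result.lnl_free, result.lnl_fixed, result.lrt = lnl_free, lnl_fixed, lrt
    result.p = float(stats.chi2.sf(lrt, df=1))
    return result


# ---------------------------------------------------------------------------
# Alignment and filters
# ---------------------------------------------------------------------------

def _strip_terminal_stop(cds: str) -> str:
    cds = cds.upper()
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def _check_cds(cds: str, name: str) -> str:
    if len(cds) % 3 != 0:
        raise ValueError(f"{name}: CDS length not a multiple of 3")
    cds = _strip_terminal_stop(cds)
    for k in range(0, len(cds), 3):
        if cds[k:k + 3] in STOP_CODONS:
            raise ValueError(f"{name}: internal stop codon")
    return cds


def codon_align(cds1: str, cds2: str) -> tuple[list[str], list[str]]:
    """Protein-guided codon alignment.

    Translate, align globally (BLOSUM62, gap open 10 / extend 0.5),
    back-translate gaps as codon triples.  Terminal stop codons are stripped
    first; an internal stop raises.  Returns two equal-length codon lists
    where a gap codon is '---'.
    """
    cds1, cds2 = _check_cds(cds1, "cds1"), _check_cds(cds2, "cds2")
    prot1, prot2 = str(Seq(cds1).translate()), str(Seq(cds2).translate())
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(prot1, prot2)[0]
    a1, a2 = str(aln[0]), str(aln[1])
    out1, out2 = [], []
    i1 = i2 = 0
    for x, y in zip(a1, a2):
        if x == "-":
            out1.append("---")
        else:
            out1.append(cds1[3 * i1:3 * i1 + 3])
            i1 += 1
        if y == "-":
            out2.append("---")
        else:
            out2.append(cds2[3 * i2:3 * i2 + 3])
            i2 += 1
    return out1, out2


def count_variant_sites(codons1, codons2) -> int:
    """Differing nucleotide columns, gap columns excluded."""
    n = 0
    for c1, c2 in zip(codons1, codons2):
        if "-" in c1 or "-" in c2:
            continue
        n += sum(a != b for a, b in zip(c1.upper(), c2.upper()))
    return n


def filter_ortholog_pairs(pairs) -> list:
    """Keep (pair_id, cds1, complete1, cds2, complete2) tuples that are not
    (both incomplete) and whose length difference is at most 20% of each
    gene's length."""
    kept = []
    for pair_id, cds1, complete1, cds2, complete2 in pairs:
        if not complete1 and not complete2:
            continue
        l1, l2 = len(cds1), len(cds2)
        # a difference reaching 20% of either gene's length removes the pair
        if abs(l1 - l2) >= 0.2 * min(l1, l2):
            continue
        kept.append((pair_id, cds1, complete1, cds2, complete2))
    return kept


# ---------------------------------------------------------------------------
# Nei-Gojobori cross-check
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts for one codon (of 3 total)."""
    syn = 0.0
    for p in range(3):
        alts = [codon[:p] + n + codon[p + 1:] for n in "ACGT" if n != codon[p]]
        alts = [a for a in alts if a not in STOP_CODONS]
        if not alts:
            continue
        frac = sum(_codon_aa(a) == _codon_aa(codon) for a in alts) / 3.0
        syn += frac
    return syn, 3.0 - syn


def _ng86_path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous differences over all mutational
    paths between two codons, skipping paths through stop codons."""
    positions = [p for p in range(3) if c1[p] != c2[p]]
    if not positions:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(positions):
        cur = c1
        sd = nd = 0.0
        ok = True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _codon_aa(cur) == _codon_aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:  # all paths blocked: count every change as nonsynonymous
        return 0.0, float(len(positions))
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def ng86_dnds(codons1, codons2) -> tuple[float, float, float]:
    """Nei-Gojobori 1986 (dN, dS, omega) with Jukes-Cantor correction.

    omega is NaN when no synonymous change is observed or a proportion is
    outside the JC domain.
    """
    S = Ns = Sd = Nd = 0.0
    for c1, c2 in zip(codons1, codons2):
        c1, c2 = c1.upper(), c2.upper()
        if "-" in c1 or "-" in c2 or c1 not in CODON_INDEX or c2 not in CODON_INDEX:
            continue
        s1, n1 = _ng86_sites(c1)
        s2, n2 = _ng86_sites(c2)
        S += (s1 + s2) / 2.0
        Ns += (n1 + n2) / 2.0
        sd, nd = _ng86_path_diffs(c1, c2)
        Sd += sd
        Nd += nd

    def jc(p):
        if p <= 0:
            return 0.0
        if p >= 0.75:
            return float("nan")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    ds = jc(Sd / S) if S > 0 else float("nan")
    dn = jc(Nd / Ns) if Ns > 0 else float("nan")
    omega = dn / ds if ds and ds > 0 else float("nan")
    return dn, ds, omega


# ---------------------------------------------------------------------------
# Cohort-level operations
# ---------------------------------------------------------------------------

def adjust_and_select(results, fdr: float = 0.05) -> list[CodonPairResult]:
    """BH-adjust LRT p-values in place; return candidates with omega > 1 and
    adjusted p < ``fdr``."""
    tested = [r for r in results if not math.isnan(r.p)]
    if tested:
        adj = bh_adjust([r.p for r in tested])
        for r, a in zip(tested, adj):
            r.adjusted_p = float(a)
    return [r for r in tested if r.omega > 1.0 and r.adjusted_p < fdr]


def scaffold_dnds_compare(results, scaffold_of: dict[str, str],
                          rearranged_ids, min_variant_sites: int = 5):
    """Per-scaffold omega distributions plus a two-sided Mann-Whitney test of
    each rearranged scaffold against all non-rearranged scaffolds pooled.
    Only pairs with >= ``min_variant_sites`` variant sites enter."""
    rearranged = set(rearranged_ids)
    unknown = rearranged - set(scaffold_of.values())
    if unknown:
        raise ValueError(f"rearranged scaffold(s) not present: {sorted(unknown)}")
    by_scaffold: dict[str, list[float]] = {}
    for r in results:
        if r.n_variant_sites < min_variant_sites or math.isnan(r.omega):
            continue
        sid = scaffold_of.get(r.pair_id)
        if sid is not None:
            by_scaffold.setdefault(sid, []).append(r.omega)
    pooled = [w for sid, ws in by_scaffold.items()
              if sid not in rearranged for w in ws]
    tests = {}
    for sid in sorted(rearranged):
        ws = by_scaffold.get(sid, [])
        if ws and pooled:
            tests[sid] = mann_whitney(ws, pooled)
        else:
            tests[sid] = StatResult("mann-whitney-u", float("nan"), float("nan"),
                                    notes={"degenerate": "empty group"})
    medians = {sid: float(np.median(ws)) for sid, ws in by_scaffold.items()}
    return medians, tests


def duplicate_dnds(orthogroups, cds_by_gene: dict[str, str]):
    """omega for duplicated orthogroups: the single outgroup-conformation
    ortholog against each paralog, for orthogroups that keep a 1:2:1 or
    1:1:2 (A:F:L) conformation after size correction."""
    out = []
    for og in orthogroups:
        eff = {sp: og.effective_count(sp) for sp in ("A", "F", "L")}
        if eff == {"A": 1, "F": 2, "L": 1}:
            dup_sp, single_sp = "F", "L"
        elif eff == {"A": 1, "F": 1, "L": 2}:
            dup_sp, single_sp = "L", "F"
        else:
            continue
        if og.count(dup_sp) != 2 or og.count(single_sp) != 1:
            continue  # conformation changed by correction
        single = og.genes_by_species[single_sp][0]
        for paralog in og.genes_by_species[dup_sp]:
            if single not in cds_by_gene or paralog not in cds_by_gene:
                continue
            a1, a2 = codon_align(cds_by_gene[single], cds_by_gene[paralog])
            res = pairwise_dnds_ml(a1, a2, pair_id=f"{og.orthogroup_id}:{single}-{paralog}")
            out.append(res)
    return out
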