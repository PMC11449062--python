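"""Codon-model dN/dS: matrix invariants, a brute-force likelihood oracle,
parameter recovery, filters, counting cross-check and cohort operations."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import kstest

from camevo import molecular_evolution as me
from camevo import synthetic_data as sd
from camevo.io_formats import OrthogroupRecord


# ---------------------------------------------------------------------------
# Independent brute-force likelihood oracle (own codon table, explicit expm)
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_CODE = {}
_AAS = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, (_a, _b, _c) in enumerate(itertools.product(_BASES, repeat=3)):
    _CODE[_a + _b + _c] = _AAS[_i]
ORACLE_CODONS = [c for c in _CODE if _CODE[c] != "*"]


def oracle_loglik(pairs, pi, t, kappa, omega):
    """lnL of aligned codon pairs via an explicit 61x61 rate matrix and
    scipy's matrix exponential."""
    n = len(ORACLE_CODONS)
    Q = np.zeros((n, n))
    for i, ci in enumerate(ORACLE_CODONS):
        for j, cj in enumerate(ORACLE_CODONS):
            if i == j:
                continue
            diffs = [(x, y) for x, y in zip(ci, cj) if x != y]
            if len(diffs) != 1:
                continue
            rate = pi[j]
            if diffs[0][0] + diffs[0][1] in ("AG", "GA", "CT", "TC"):
                rate *= kappa
            if _CODE[ci] != _CODE[cj]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q /= -np.dot(pi, np.diag(Q))
    P = expm(Q * t)
    idx = {c: i for i, c in enumerate(ORACLE_CODONS)}
    lnl = 0.0
    for c1, c2 in pairs:
        lnl += math.log(pi[idx[c1]] * P[idx[c1], idx[c2]])
    return lnl


class TestModelInvariants:
    def test_rate_matrix_rows_sum_to_zero(self):
        pi = np.full(61, 1 / 61)
        Q = me.build_rate_matrix(pi, 2.0, 0.5)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_unit_expected_rate(self):
        pi = me.f3x4_frequencies(["ATG", "CCT"], ["GGG", "TTT"])
        Q = me.build_rate_matrix(pi, 3.0, 0.7)
        assert -np.dot(pi, np.diag(Q)) == pytest.approx(1.0)

    def test_transition_probabilities_stochastic(self):
        pi = np.full(61, 1 / 61)
        Q = me.build_rate_matrix(pi, 2.0, 1.5)
        for t in (0.0, 0.3, 5.0):
            P = me.transition_matrix(Q, pi, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert (P >= 0).all()
        assert np.allclose(me.transition_matrix(Q, pi, 0.0), np.eye(61),
                           atol=1e-10)

    def test_stationarity(self):
        pi = me.f3x4_frequencies(["ATG", "CCT", "GAA"], ["GGG", "TTT"])
        Q = me.build_rate_matrix(pi, 2.0, 0.5)
        P = me.transition_matrix(Q, pi, 1.7)
        assert np.allclose(pi @ P, pi, atol=1e-10)


class TestPairwiseML:
    def test_identical_sequences(self):
        codons = ["ATG", "CCT", "GAA", "TTT"] * 5
        r = me.pairwise_dnds_ml(codons, codons)
        assert "identical" in r.flags
        assert r.dn == 0.0 and r.ds == 0.0
        assert math.isnan(r.p)

    def test_loglik_matches_bruteforce_oracle_on_toy_alignment(self):
        c1 = ["ATG", "CCT", "GAA", "TTT", "AAA", "CGT"]
        c2 = ["ATG", "CCA", "GAA", "TTC", "AAG", "CGT"]
        r = me.pairwise_dnds_ml(c1, c2)
        pi = me.f3x4_frequencies(c1, c2)
        lnl = oracle_loglik(list(zip(c1, c2)), pi, r.t, r.kappa, r.omega)
        assert r.lnl_free == pytest.approx(lnl, abs=1e-6)
        # grid around the fit finds nothing better
        best = -np.inf
        for t in np.linspace(max(r.t - 0.1, 1e-4), r.t + 0.1, 5):
            for k in np.linspace(max(r.kappa - 1, 0.1), r.kappa + 1, 5):
                for w in np.linspace(max(r.omega - 0.3, 1e-3), r.omega + 0.3, 5):
                    best = max(best, oracle_loglik(list(zip(c1, c2)), pi, t, k, w))
        assert r.lnl_free >= best - 1e-6

    def test_free_likelihood_dominates_fixed(self):
        for seed in range(4):
            c1, c2 = sd.simulate_codon_pair(200, omega=0.5, kappa=2.0, t=0.4,
                                            seed=seed)
            r = me.pairwise_dnds_ml(c1, c2)
            assert r.lnl_free >= r.lnl_fixed - 1e-8
            assert r.lrt >= 0.0

    def test_parameter_recovery_long_alignment(self):
        c1, c2 = sd.simulate_codon_pair(50_000, omega=1.0, kappa=2.0, t=0.5,
                                        seed=77)
        r = me.pairwise_dnds_ml(c1, c2)
        assert 0.95 <= r.omega <= 1.05
        assert 1.8 <= r.kappa <= 2.2

    def test_dnds_ratio_consistent_with_omega(self):
        c1, c2 = sd.simulate_codon_pair(5000, omega=0.3, kappa=2.0, t=0.4,
                                        seed=5)
        r = me.pairwise_dnds_ml(c1, c2)
        assert r.dn / r.ds == pytest.approx(r.omega, rel=1e-6)


class TestAlignmentAndFilters:
    def test_identical_cds_align_gapless(self):
        cds = "ATGCCTGAATTTAAA"
        a1, a2 = me.codon_align(cds, cds)
        assert a1 == a2
        assert "---" not in a1

    def test_single_codon_insertion_one_gap(self):
        cds1 = "ATGCCTGAATTTAAACGTGGC"
        cds2 = "ATGCCTGAAGGGTTTAAACGTGGC"  # one extra codon (GGG)
        a1, a2 = me.codon_align(cds1, cds2)
        assert a1.count("---") == 1
        assert a2.count("---") == 0
        assert len(a1) == len(a2)
        assert "".join(c for c in a1 if c != "---") == cds1

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            me.codon_align("ATGTAACCT", "ATGCCTCCT")

    def test_terminal_stop_stripped(self):
        a1, a2 = me.codon_align("ATGCCTTAA", "ATGCCTTGA")
        assert a1 == a2 == ["ATG", "CCT"]

    def test_variant_site_count_matches_brute_force(self, rng):
        for _ in range(25):
            c1, c2 = sd.simulate_codon_pair(40, omega=1.0, kappa=2.0,
                                            t=float(rng.uniform(0, 1)),
                                            seed=int(rng.integers(1e6)))
            naive = sum(a != b for x, y in zip(c1, c2) for a, b in zip(x, y))
            assert me.count_variant_sites(c1, c2) == naive

    @pytest.mark.parametrize("l1,l2,c1,c2,kept", [
        (300, 360, True, True, False),   # 60 > 0.2*300
        (300, 350, True, True, True),    # 50 <= 60 and <= 70
        (300, 300, True, False, True),   # one incomplete is fine
        (300, 300, False, False, False),  # both incomplete
    ])
    def test_pair_filter_rules(self, l1, l2, c1, c2, kept):
        pairs = [("p", "A" * l1, c1, "A" * l2, c2)]
        assert bool(me.filter_ortholog_pairs(pairs)) == kept


class TestNG86:
    def test_identical_zero(self):
        codons = ["ATG", "CCT"] * 3
        dn, ds, w = me.ng86_dnds(codons, codons)
        assert dn == 0.0 and ds == 0.0 and math.isnan(w)

    def test_single_synonymous_change(self):
        c1 = ["ATG", "CCT", "GAA", "TTT", "AAA", "CGT", "GGC", "CTT"]
        c2 = ["ATG", "CCA", "GAA", "TTT", "AAA", "CGT", "GGC", "CTT"]
        # CCT->CCA is synonymous (Pro); alignment long enough for JC
        dn, ds, w = me.ng86_dnds(c1, c2)
        assert dn == 0.0 and ds > 0.0 and w == 0.0

    def test_agrees_with_ml_without_transition_bias(self):
        """With kappa = 1 the counting method's equal-rate assumption holds
        and NG86 tracks the ML estimate."""
        for om, t, seed in [(0.2, 0.3, 1), (0.5, 0.2, 2), (2.0, 0.2, 3)]:
            c1, c2 = sd.simulate_codon_pair(6000, omega=om, kappa=1.0, t=t,
                                            seed=seed)
            r = me.pairwise_dnds_ml(c1, c2)
            _, _, w = me.ng86_dnds(c1, c2)
            assert abs(r.omega - w) / r.omega < 0.15


class TestSelection:
    def _result(self, pid, omega, p, nvar=10):
        r = me.CodonPairResult(pid, 100, nvar)
        r.omega, r.p = omega, p
        return r

    def test_bh_and_candidate_rule(self):
        results = [self._result("a", 2.0, 0.001),
                   self._result("b", 0.2, 0.001),
                   self._result("c", 3.0, 0.9)]
        cands = me.adjust_and_select(results, fdr=0.05)
        assert [r.pair_id for r in cands] == ["a"]  # omega>1 AND adj p<0.05

    def test_scaffold_compare_identical_sets(self, rng):
        results = []
        omegas = rng.uniform(0.05, 0.6, size=40)
        for i, w in enumerate(omegas):
            r = self._result(f"p{i}", float(w), 0.5)
            results.append(r)
        scaffold_of = {f"p{i}": ("r1" if i < 20 else "n1") for i in range(40)}
        # make the two scaffold distributions literally identical
        for i in range(20):
            results[i + 20].omega = results[i].omega
        medians, tests = me.scaffold_dnds_compare(results, scaffold_of, ["r1"])
        assert tests["r1"].p == pytest.approx(1.0)
        assert medians["r1"] == pytest.approx(medians["n1"])

    def test_scaffold_compare_null_p_uniform(self, rng):
        """Rearranged scaffold drawn from the same distribution: p-values
        uniform over replicates (KS test)."""
        pvals = []
        for _ in range(200):
            omegas = rng.exponential(0.3, size=120)
            results = [self._result(f"p{i}", float(w), 0.5)
                       for i, w in enumerate(omegas)]
            scaffold_of = {f"p{i}": ("r1" if i < 40 else "n1")
                           for i in range(120)}
            _, tests = me.scaffold_dnds_compare(results, scaffold_of, ["r1"])
            pvals.append(tests["r1"].p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_scaffold_compare_shift_power(self, rng):
        hits = 0
        reps = 25
        for _ in range(reps):
            base = rng.exponential(0.3, size=400)
            results = []
            for i, w in enumerate(base):
                shift = 0.1 if i < 200 else 0.0
                results.append(self._result(f"p{i}", float(w + shift), 0.5))
            scaffold_of = {f"p{i}": ("r1" if i < 200 else "n1")
                           for i in range(400)}
            _, tests = me.scaffold_dnds_compare(results, scaffold_of, ["r1"])
            hits += tests["r1"].p < 0.05
        assert hits / reps >= 0.8

    def test_unknown_rearranged_id_errors(self):
        with pytest.raises(ValueError):
            me.scaffold_dnds_compare([], {"p1": "s1"}, ["nope"])

    def test_min_variant_sites_filter(self):
        results = [self._result("p1", 0.5, 0.5, nvar=4),
                   self._result("p2", 0.5, 0.5, nvar=5)]
        scaffold_of = {"p1": "s1", "p2": "s1"}
        medians, _ = me.scaffold_dnds_compare(results, scaffold_of, [])
        assert medians == {"s1": 0.5}  # only the 5-variant pair counted


class TestDuplicateDnds:
    def _cds(self, n=30, seed=0):
        c1, _ = sd.simulate_codon_pair(n, 1.0, 2.0, 0.0, seed=seed)
        return "".join(c1)

    def test_one_two_one_yields_two_results(self):
        cds = self._cds()
        og = OrthogroupRecord("OG1", {"A": ["a1"], "F": ["f1", "f2"], "L": ["l1"]})
        out = me.duplicate_dnds([og], {"l1": cds, "f1": cds, "f2": cds})
        assert len(out) == 2
        assert all("identical" in r.flags for r in out)

    def test_corrected_conformation_respected(self):
        og = OrthogroupRecord("OG1", {"A": ["a1"], "F": ["f1", "f2"], "L": ["l1"]})
        og.corrected = {"A": 1, "F": 1, "L": 1}  # haplotig collapse
        assert me.duplicate_dnds([og], {}) == []
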