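"""Expression pipeline: count aggregation, normalization invariants, the
two-stage DE caller, clustering and curves."""

import numpy as np
import pandas as pd
import pytest

from camevo import diel_expression as de
from camevo import synthetic_data as sd
from camevo.io_formats import GeneModel


def _design(n_reps=3, timepoints=(0, 4, 8, 12, 16, 20)):
    ids = [f"{sp}_g{r+1}_t{t}" for sp in ("F", "L")
           for r in range(n_reps) for t in timepoints]
    return de.SampleDesign.from_sample_ids(ids)


def _null_truth_and_genes(n_genes, n_de=0, amp=1.5, b=500.0, disp=0.1, seed=0):
    """Minimal gene models plus planted truth for count simulation."""
    rng = np.random.default_rng(seed)
    genes, truth = {}, sd.SyntheticTruth()
    for i in range(n_genes):
        gid = f"g{i:04d}"
        genes[gid] = GeneModel(gene_id=gid, scaffold_id="s1", start=0, end=300,
                               strand="+", exons=[(0, 150), (150, 300)])
        phi = float(rng.uniform(0, 24))
        is_de = i < n_de
        truth.gene_params[gid] = {
            "b": b, "A_F": amp if is_de else 0.0, "A_L": 0.0,
            "phi_F": phi, "phi_L": phi, "dispersion": disp}
        if is_de:
            truth.de_genes[gid] = truth.gene_params[gid]
    return genes, truth


class TestExonToGene:
    def test_sums_exons(self):
        m = pd.DataFrame({"s1": [3, 4, 5]},
                         index=["g1.exon1", "g1.exon2", "g1.exon3"])
        out = de.exon_to_gene_counts(m)
        assert out.loc["g1", "s1"] == 12

    def test_single_exon_identity(self):
        m = pd.DataFrame({"s1": [7]}, index=["g1.exon1"])
        assert de.exon_to_gene_counts(m).loc["g1", "s1"] == 7

    def test_column_sums_preserved(self, rng):
        m = pd.DataFrame(rng.integers(0, 50, size=(30, 4)),
                         index=[f"g{i//3}.exon{i%3+1}" for i in range(30)])
        out = de.exon_to_gene_counts(m)
        assert (out.sum() == m.sum()).all()

    def test_orphan_exon_errors(self):
        m = pd.DataFrame({"s1": [1]}, index=["weird_id"])
        with pytest.raises(ValueError):
            de.exon_to_gene_counts(m)


class TestTMM:
    def test_identical_columns_unit_factors(self, rng):
        col = rng.integers(1, 200, size=100)
        m = pd.DataFrame({f"s{i}": col for i in range(4)})
        assert np.allclose(de.tmm_normalize(m), 1.0)

    def test_pure_depth_difference_gives_unit_factors(self, rng):
        col = rng.integers(10, 200, size=200)
        m = pd.DataFrame({"a": col, "b": 2 * col})
        f = de.tmm_normalize(m)
        assert np.allclose(f, 1.0, atol=1e-8)

    def test_geometric_mean_one(self, rng):
        m = pd.DataFrame(rng.integers(0, 300, size=(300, 5)),
                         columns=list("abcde"))
        f = de.tmm_normalize(m)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_invariant_to_gene_order(self, rng):
        m = pd.DataFrame(rng.integers(0, 300, size=(200, 4)))
        perm = rng.permutation(len(m))
        f1 = de.tmm_normalize(m)
        f2 = de.tmm_normalize(m.iloc[perm])
        assert np.allclose(f1, f2)

    def test_all_zero_sample_errors(self):
        m = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            de.tmm_normalize(m)

    def test_composition_bias_compensated(self, rng):
        """A sample where half the counts migrate into a few very high
        genes gets a factor below 1 relative to the reference."""
        base = rng.integers(50, 150, size=400)
        other = base.copy()
        other[:8] = other[:8] * 60  # few dominant genes eat sequencing depth
        m = pd.DataFrame({"a": base, "b": other, "c": base, "d": base})
        f = de.tmm_normalize(m)
        # shrinking b's effective library corrects its non-dominant cpm upward
        assert f["b"] < 1.0 < f["a"]


class TestCpmTpm:
    def test_cpm_filter_removes_zero_gene(self):
        m = pd.DataFrame({"a": [0, 100], "b": [0, 100]}, index=["g0", "g1"])
        f = pd.Series(1.0, index=m.columns)
        out = de.cpm_filter(m, f)
        assert list(out.index) == ["g1"]

    def test_cpm_filter_boundary_kept_and_idempotent(self):
        # gene g0 at exactly mean cpm 1.0 given library size 10^6
        m = pd.DataFrame({"a": [1, 999_999], "b": [1, 999_999]},
                         index=["g0", "g1"])
        f = pd.Series(1.0, index=m.columns)
        out = de.cpm_filter(m, f)
        assert "g0" in out.index
        assert de.cpm_filter(out, f).equals(out)

    def test_tpm_formula(self):
        m = pd.DataFrame({"a": [10, 10]}, index=["g1", "g2"])
        lengths = pd.Series([1.0, 2.0], index=["g1", "g2"])
        t = de.tpm(m, lengths)
        assert t.loc["g1", "a"] == pytest.approx(666_666.6667)
        assert t.loc["g2", "a"] == pytest.approx(333_333.3333)

    def test_tpm_single_gene(self):
        t = de.tpm(pd.DataFrame({"a": [5]}, index=["g1"]),
                   pd.Series([2.0], index=["g1"]))
        assert t.loc["g1", "a"] == pytest.approx(1e6)

    def test_tpm_columns_sum_to_million(self, rng):
        m = pd.DataFrame(rng.integers(1, 500, size=(50, 6)))
        lengths = pd.Series(rng.uniform(0.2, 5.0, size=50), index=m.index)
        t = de.tpm(m, lengths)
        assert np.allclose(t.sum(), 1e6, rtol=1e-9)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            de.tpm(pd.DataFrame({"a": [1]}, index=["g1"]),
                   pd.Series([0.0], index=["g1"]))


class TestTimecourseDE:
    def test_planted_interaction_detected_null_left_alone(self):
        genes, truth = _null_truth_and_genes(300, n_de=40, seed=3)
        counts = sd.simulate_diel_counts(genes, truth, n_reps=6, seed=3)
        gm = de.exon_to_gene_counts(counts)
        factors = de.tmm_normalize(gm)
        design = de.SampleDesign.from_sample_ids(gm.columns)
        res = de.timecourse_de(gm, design, factors=factors)
        called = {r.gene_id for r in res if r.is_de}
        planted = set(truth.de_genes)
        power = len(called & planted) / len(planted)
        fp = len(called - planted) / (len(res) - len(planted))
        assert power >= 0.9
        assert fp <= 0.08

    def test_de_calls_stable_under_relabeling_within_cells(self, rng):
        """Replicates are exchangeable within a species x time cell."""
        genes, truth = _null_truth_and_genes(60, n_de=15, seed=9)
        counts = sd.simulate_diel_counts(genes, truth, n_reps=4, seed=9)
        gm = de.exon_to_gene_counts(counts)
        design = de.SampleDesign.from_sample_ids(gm.columns)
        res1 = {r.gene_id: r.is_de for r in de.timecourse_de(gm, design)}
        # permute replicate columns within each (species, time) cell
        cols = list(gm.columns)
        new_order = []
        for sp in ("F", "L"):
            for t in sorted(set(design.time)):
                cell = [c for c, s, tt in zip(design.sample_ids, design.species,
                                              design.time) if s == sp and tt == t]
                new_order.extend(rng.permutation(cell))
        gm2 = gm[new_order]
        design2 = de.SampleDesign.from_sample_ids(gm2.columns)
        res2 = {r.gene_id: r.is_de for r in de.timecourse_de(gm2, design2)}
        assert res1 == res2

    def test_degree_exceeding_timepoints_errors(self):
        genes, truth = _null_truth_and_genes(5)
        counts = sd.simulate_diel_counts(genes, truth, n_reps=2,
                                         timepoints=(0, 12), seed=1)
        gm = de.exon_to_gene_counts(counts)
        design = de.SampleDesign.from_sample_ids(gm.columns)
        with pytest.raises(ValueError, match="degree"):
            de.timecourse_de(gm, design, degree=3)


class TestClusteringCurves:
    def _antiphase_profiles(self, n_per_group=15, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        rows = {}
        for i in range(n_per_group):
            rows[f"a{i}"] = np.sin(t) + rng.normal(0, noise, size=12)
        for i in range(n_per_group):
            rows[f"b{i}"] = -np.sin(t) + rng.normal(0, noise, size=12)
        return pd.DataFrame(rows).T

    def test_antiphase_groups_split_cleanly(self):
        profiles = self._antiphase_profiles()
        labels = de.cluster_de(profiles)
        a = set(labels[[i for i in labels.index if i.startswith("a")]])
        b = set(labels[[i for i in labels.index if i.startswith("b")]])
        assert labels.nunique() == 2
        assert a.isdisjoint(b)

    def test_duplicate_profiles_cocluster(self):
        profiles = self._antiphase_profiles()
        profiles.loc["dup"] = profiles.loc["a0"]
        labels = de.cluster_de(profiles)
        assert labels["dup"] == labels["a0"]

    def test_labels_stable_under_gene_order(self, rng):
        profiles = self._antiphase_profiles()
        perm = profiles.iloc[rng.permutation(len(profiles))]
        l1, l2 = de.cluster_de(profiles), de.cluster_de(perm)
        # same partition up to relabeling
        for g1 in profiles.index:
            for g2 in profiles.index:
                assert (l1[g1] == l1[g2]) == (l2[g1] == l2[g2])

    def test_median_centered_curves_zero_for_identical_genes(self):
        tpm = pd.DataFrame(np.tile([[10, 20, 30, 40]], (5, 1)),
                           index=[f"g{i}" for i in range(5)],
                           columns=["F_g1_t0", "F_g1_t4", "L_g1_t0", "L_g1_t4"])
        design = de.SampleDesign.from_sample_ids(tpm.columns)
        curves = de.expression_curves(tpm, design, tpm.index, "median_centered")
        assert np.allclose(curves["centered_log_tpm"], 0.0)

    def test_mean_sd_curve_values(self):
        tpm = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g1"],
                           columns=["F_g1_t0", "F_g2_t0", "F_g3_t0"])
        design = de.SampleDesign.from_sample_ids(tpm.columns)
        curves = de.expression_curves(tpm, design, ["g1"], "mean_sd")
        assert curves["mean_tpm"].iloc[0] == pytest.approx(2.0)
        assert curves["sd_tpm"].iloc[0] == pytest.approx(1.0)

    def test_median_centering_leaves_median_zero(self, rng):
        tpm = pd.DataFrame(rng.uniform(1, 100, size=(9, 4)),
                           index=[f"g{i}" for i in range(9)],
                           columns=["F_g1_t0", "F_g1_t4", "L_g1_t0", "L_g1_t4"])
        design = de.SampleDesign.from_sample_ids(tpm.columns)
        curves = de.expression_curves(tpm, design, tpm.index, "median_centered")
        for (_, _), grp in curves.groupby(["species", "time"]):
            assert np.median(grp["centered_log_tpm"]) == pytest.approx(0.0)
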