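import numpy as np
import pytest

from famqls import (
    GenotypeMatrix,
    KinshipMatrix,
    PhenotypeReplicates,
    compute_kinship,
    mqls_statistic,
    per_family_tests,
    ql_allele_freq,
    three_generation_pedigree,
    wqls_statistic,
)
from famqls import test_markers as run_marker_tests
from famqls.qls import (
    STATUS_DEGENERATE,
    STATUS_MONOMORPHIC,
    STATUS_SINGLE_CLASS,
)


def allelic_chisq(y: np.ndarray, z: np.ndarray) -> float:
    """Independent oracle: classical allelic chi-square from the 2x2 table of
    minor/major allele counts in cases vs controls (no continuity correction)."""
    a = 2 * y[z == 1].sum()          # minor alleles in cases
    b = 2 * len(y[z == 1]) - a       # major alleles in cases
    c = 2 * y[z == 0].sum()
    d = 2 * len(y[z == 0]) - c
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestQlAlleleFreq:
    def test_unrelated_reduces_to_mean(self):
        y = np.array([0.0, 0.5, 1.0, 0.5])
        assert ql_allele_freq(y, 0.5 * np.eye(4)) == pytest.approx(0.5)

    def test_all_zero(self):
        assert ql_allele_freq(np.zeros(3), 0.5 * np.eye(3)) == 0.0

    def test_parent_offspring_pair_hand_solve(self):
        phi = np.array([[0.5, 0.25], [0.25, 0.5]])
        assert ql_allele_freq(np.array([0.5, 0.0]), phi) == pytest.approx(0.25)

    def test_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ql_allele_freq(np.array([0.5, np.nan]), 0.5 * np.eye(2))


class TestWorkedExample:
    """4 unrelated individuals: 2 cases with one rare allele, 2 controls with none."""

    y = np.array([0.5, 0.5, 0.0, 0.0])
    z = np.array([1.0, 1.0, 0.0, 0.0])
    phi = 0.5 * np.eye(4)

    def test_mqls_score_variance_statistic(self):
        res = mqls_statistic(self.y, self.z, 0.5, self.phi)
        assert res.score_u == pytest.approx(0.5)
        assert res.var_u == pytest.approx(0.09375)
        assert res.statistic == pytest.approx(8 / 3)
        assert res.ql_freq == pytest.approx(0.25)

    def test_equals_allelic_chisq(self):
        res = mqls_statistic(self.y, self.z, 0.5, self.phi)
        assert res.statistic == pytest.approx(allelic_chisq(self.y, self.z))

    def test_wqls_equals_mqls_for_unrelated_at_case_fraction(self):
        m = mqls_statistic(self.y, self.z, 0.5, self.phi)
        w = wqls_statistic(self.y, self.z, self.phi)
        assert w.statistic == pytest.approx(m.statistic, abs=1e-12)


def _random_unrelated(rng, n):
    p = rng.uniform(0.05, 0.5)
    y = rng.binomial(2, p, size=n) / 2.0
    z = np.zeros(n)
    z[rng.choice(n, size=rng.integers(2, n - 1), replace=False)] = 1.0
    if np.ptp(y) == 0:  # avoid monomorphic draws
        y[rng.integers(n)] = 0.5
    return y, z


class TestAllelicChisqOracle:
    """For unrelated samples both tests reduce to the classical allelic test."""

    @pytest.mark.parametrize("test_name", ["mqls", "wqls"])
    def test_fifty_random_datasets(self, test_name):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(20, 201))
            y, z = _random_unrelated(rng, n)
            phi = 0.5 * np.eye(n)
            expected = allelic_chisq(y, z)
            if test_name == "mqls":
                got = mqls_statistic(y, z, z.mean(), phi).statistic
            else:
                got = wqls_statistic(y, z, phi).statistic
            assert abs(got - expected) < 1e-10


class TestInvariances:
    def _family_data(self):
        ped = three_generation_pedigree(2, 3)
        kin = compute_kinship(ped)
        rng = np.random.default_rng(5)
        y = rng.choice([0.0, 0.5, 1.0], size=ped.n, p=[0.7, 0.2, 0.1])
        z = (rng.random(ped.n) < 0.3).astype(float)
        z[0], z[1] = 1.0, 0.0  # ensure both classes
        if np.ptp(y) == 0:
            y[0] = 0.5
        return ped, kin, y, z

    def test_dosage_reflection_leaves_statistic_unchanged(self):
        _, kin, y, z = self._family_data()
        for fn in (
            lambda yy: mqls_statistic(yy, z, 0.3, kin),
            lambda yy: wqls_statistic(yy, z, kin),
        ):
            a, b = fn(y), fn(1.0 - y)
            assert b.statistic == pytest.approx(a.statistic, rel=1e-10)
            assert b.ql_freq == pytest.approx(1.0 - a.ql_freq)

    def test_joint_permutation_invariance(self):
        _, kin, y, z = self._family_data()
        dense = kin.dense()
        rng = np.random.default_rng(11)
        base_m = mqls_statistic(y, z, 0.3, dense).statistic
        base_w = wqls_statistic(y, z, dense).statistic
        for _ in range(3):
            perm = rng.permutation(len(y))
            phi_p = dense[np.ix_(perm, perm)]
            assert mqls_statistic(y[perm], z[perm], 0.3, phi_p).statistic == pytest.approx(base_m, rel=1e-10)
            assert wqls_statistic(y[perm], z[perm], phi_p).statistic == pytest.approx(base_w, rel=1e-10)


class TestUntestableFlags:
    def test_constant_dosage_is_monomorphic(self):
        res = mqls_statistic(np.zeros(4), np.array([1, 0, 1, 0.0]), 0.3, 0.5 * np.eye(4))
        assert res.status == STATUS_MONOMORPHIC
        assert np.isnan(res.p_value) and np.isnan(res.statistic)

    @pytest.mark.parametrize("z", [np.ones(4), np.zeros(4)])
    def test_single_phenotype_class(self, z):
        y = np.array([0.5, 0.0, 0.5, 0.0])
        assert wqls_statistic(y, z, 0.5 * np.eye(4)).status == STATUS_SINGLE_CLASS
        assert mqls_statistic(y, z, 0.3, 0.5 * np.eye(4)).status == STATUS_SINGLE_CLASS

    def test_bad_prevalence_rejected(self):
        y = np.array([0.5, 0.0])
        z = np.array([1.0, 0.0])
        for k in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="prevalence"):
                mqls_statistic(y, z, k, 0.5 * np.eye(2))


class TestTestMarkers:
    def _setup(self):
        ped = three_generation_pedigree(2, 3)
        kin = compute_kinship(ped)
        rng = np.random.default_rng(3)
        dosages = rng.choice([0.0, 0.5, 1.0], size=(ped.n, 10), p=[0.8, 0.15, 0.05])
        dosages[0, :] = 0.0      # guarantee every column polymorphic ...
        dosages[1, :] = 0.5
        dosages[:, 3] = 0.0      # ... except these two monomorphic ones
        dosages[:, 7] = 1.0
        g = GenotypeMatrix(dosages, [f"M{j}" for j in range(10)], ped.sample_ids)
        z = (rng.random(ped.n) < 0.3).astype(float)
        z[:2] = [1.0, 0.0]
        ph = PhenotypeReplicates(sample_ids=ped.sample_ids, values=z[:, None])
        return ped, kin, g, ph

    def test_flags_monomorphic_but_keeps_order(self):
        _, kin, g, ph = self._setup()
        res = run_marker_tests(g, ph, 0, kin, test="mqls", prevalence=0.3)
        assert [r.marker_id for r in res] == [f"M{j}" for j in range(10)]
        statuses = [r.status for r in res]
        assert statuses[3] == STATUS_MONOMORPHIC and statuses[7] == STATUS_MONOMORPHIC
        assert sum(s == "ok" for s in statuses) == 8

    def test_batch_path_matches_scalar_path(self):
        _, kin, g, ph = self._setup()
        z = ph.replicate(0)
        for test_name in ("mqls", "wqls"):
            res = run_marker_tests(g, ph, 0, kin, test=test_name, prevalence=0.3)
            for r in res:
                y = g.column(r.marker_id)
                if test_name == "mqls":
                    ref = mqls_statistic(y, z, 0.3, kin)
                else:
                    ref = wqls_statistic(y, z, kin)
                if r.testable:
                    assert r.statistic == pytest.approx(ref.statistic, rel=1e-12)
                    assert r.p_value == pytest.approx(ref.p_value, rel=1e-12)
                else:
                    assert r.status == ref.status

    def test_missing_genotype_dropped_listwise(self):
        ped, kin, g, ph = self._setup()
        g.dosages[4, 0] = np.nan
        res = run_marker_tests(g, ph, 0, kin, test="mqls", prevalence=0.3)
        assert res[0].n_used == ped.n - 1
        keep = np.ones(ped.n, dtype=bool)
        keep[4] = False
        ref = mqls_statistic(
            g.dosages[keep, 0], ph.replicate(0)[keep], 0.3, kin.submatrix(keep)
        )
        assert res[0].statistic == pytest.approx(ref.statistic, rel=1e-12)

    def test_missing_phenotype_dropped(self):
        ped, kin, g, ph = self._setup()
        ph.values[2, 0] = np.nan
        res = run_marker_tests(g, ph, 0, kin, test="wqls")
        assert all(r.n_used == ped.n - 1 for r in res)

    def test_mqls_requires_prevalence(self):
        _, kin, g, ph = self._setup()
        with pytest.raises(ValueError, match="prevalence"):
            run_marker_tests(g, ph, 0, kin, test="mqls")

    def test_collapsed_genes_keyed_by_name(self, bundle, bundle_kinship):
        from famqls import collapse_all

        collapsed = collapse_all(bundle.genotypes, bundle.annotation)
        res = run_marker_tests(
            collapsed, bundle.phenotypes, 0, bundle_kinship, test="mqls", prevalence=0.3
        )
        assert [r.marker_id for r in res] == [c.gene for c in collapsed]


class TestPerFamily:
    def test_private_variant_testable_only_in_carrier_family(self, bundle, bundle_kinship):
        g = bundle.genotypes.subset_markers(["PRIV1"])
        fam = per_family_tests(
            g, bundle.phenotypes, 0, bundle.pedigree, bundle_kinship,
            test="mqls", prevalence=0.3,
        )
        assert fam["F01"][0].testable
        for fid in bundle.pedigree.family_ids:
            if fid != "F01":
                assert fam[fid][0].status == STATUS_MONOMORPHIC

    def test_scope_labels(self, bundle, bundle_kinship):
        g = bundle.genotypes.subset_markers(["PRIV1"])
        fam = per_family_tests(
            g, bundle.phenotypes, 0, bundle.pedigree, bundle_kinship,
            test="wqls",
        )
        assert fam["F02"][0].scope == "family:F02"

    def test_family_with_cases_only_is_untestable(self):
        ped = three_generation_pedigree(2, 2)
        kin = compute_kinship(ped)
        rng = np.random.default_rng(1)
        g = GenotypeMatrix(
            rng.choice([0.0, 0.5], size=(ped.n, 2), p=[0.7, 0.3]),
            ["M0", "M1"],
            ped.sample_ids,
        )
        z = np.zeros(ped.n)
        z[ped.family_rows("F01")] = 1.0  # F01 all cases
        z[ped.family_rows("F02")[0]] = 1.0
        ph = PhenotypeReplicates(sample_ids=ped.sample_ids, values=z[:, None])
        fam = per_family_tests(g, ph, 0, ped, kin, test="mqls", prevalence=0.3)
        assert all(r.status == STATUS_SINGLE_CLASS for r in fam["F01"])
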