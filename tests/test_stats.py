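"""Diversity, FST, beta_ST, singletons, Tajima's D, Mantel — against oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from expansionload.genotypes import MISSING
from expansionload.stats import (beta_st, bh_adjust, diversity, mantel,
                                 ols_report, singleton_rarefaction, tajimas_d,
                                 wc_fst, ibd_and_gradient_report)

from conftest import make_gm, make_popmap


# ---------------------------------------------------------------------------
# brute-force oracles (naive loops, independent of the implementation)
# ---------------------------------------------------------------------------

def naive_diversity(columns):
    """Per-site Ho/He/pi via explicit loops; columns = genotypes of one pop."""
    hos, hes, pis = [], [], []
    for col in columns:
        col = [g for g in col if g != MISSING]
        n = len(col)
        if n == 0:
            continue
        hos.append(sum(1 for g in col if g == 1) / n)
        copies = []
        for g in col:
            copies += [1] * g + [0] * (2 - g)
        m = len(copies)
        if m < 2:
            continue
        diff = same = 0
        for a, b in itertools.combinations(range(m), 2):
            if copies[a] != copies[b]:
                diff += 1
            else:
                same += 1
        pis.append(diff / (diff + same))
        p = sum(copies) / m
        hes.append((m / (m - 1)) * (1 - p**2 - (1 - p)**2))
    return np.mean(hos), np.mean(hes), np.mean(pis)


def naive_wc_theta(cols1, cols2):
    """Ratio-of-sums Weir-Cockerham theta from the printed 1984 formulas."""
    num = den = 0.0
    for c1, c2 in zip(cols1, cols2):
        c1 = [g for g in c1 if g != MISSING]
        c2 = [g for g in c2 if g != MISSING]
        n1, n2 = len(c1), len(c2)
        if n1 == 0 or n2 == 0:
            continue
        p1 = sum(c1) / (2 * n1)
        p2 = sum(c2) / (2 * n2)
        h1 = sum(1 for g in c1 if g == 1) / n1
        h2 = sum(1 for g in c2 if g == 1) / n2
        r = 2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar)**2 + n2 * (p2 - pbar)**2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def naive_beta(columns_by_pop):
    """beta_i via exhaustive allele-copy pair counting."""
    pops = list(columns_by_pop)
    m_within, m_between_sum = {}, []
    copies = {p: [] for p in pops}
    for p in pops:
        for col in columns_by_pop[p]:
            copies[p].append([x for g in col if g != MISSING
                              for x in ([1] * g + [0] * (2 - g))])
    n_sites = len(next(iter(copies.values())))
    for p in pops:
        vals = []
        for s in range(n_sites):
            cp = copies[p][s]
            pairs = match = 0
            for a, b in itertools.combinations(range(len(cp)), 2):
                pairs += 1
                match += cp[a] == cp[b]
            vals.append(match / pairs)
        m_within[p] = np.mean(vals)
    mb_per_site = []
    for s in range(n_sites):
        vals = []
        for pa, pb in itertools.combinations(pops, 2):
            pairs = match = 0
            for x in copies[pa][s]:
                for y in copies[pb][s]:
                    pairs += 1
                    match += x == y
            vals.append(match / pairs)
        mb_per_site.append(np.mean(vals))
    mb = np.mean(mb_per_site)
    return {p: (m_within[p] - mb) / (1 - mb) for p in pops}


def naive_tajima(xi):
    """Direct transcription of the printed formulas."""
    n = len(xi) - 1
    S = sum(xi[1:n])
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = sum(i * (n - i) * xi[i] for i in range(1, n)) / (n * (n - 1) / 2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestDiversity:
    def test_all_homozygous_ref(self):
        gm = make_gm([[0, 0], [0, 0]])
        pm = make_popmap({"ind1": "p", "ind2": "p"})
        row = diversity(gm, pm, compute_tajimas_d=False).per_population.iloc[0]
        assert row["Ho"] == row["He"] == row["pi"] == 0

    def test_single_site_closed_form(self):
        gm = make_gm([[1, 1]])
        pm = make_popmap({"ind1": "p", "ind2": "p"})
        row = diversity(gm, pm, compute_tajimas_d=False).per_population.iloc[0]
        assert row["Ho"] == 1.0
        assert abs(row["He"] - 2 / 3) < 1e-12

    def test_matches_naive_loop_on_random_matrix(self):
        rng = np.random.default_rng(9)
        rows = rng.integers(0, 3, size=(50, 16)).tolist()
        for r in rows[:5]:
            r[0] = MISSING
        gm = make_gm(rows)
        assignment = {f"ind{i + 1}": f"p{i % 4}" for i in range(16)}
        pm = make_popmap(assignment)
        table = diversity(gm, pm, compute_tajimas_d=False).per_population
        for _, row in table.iterrows():
            members = [i for i, (k, v) in enumerate(assignment.items())
                       if v == row["population"]]
            cols = [[rows[s][i] for i in members] for s in range(50)]
            ho, he, pi = naive_diversity(cols)
            assert abs(row["Ho"] - ho) < 1e-10
            assert abs(row["He"] - he) < 1e-10
            assert abs(row["pi"] - pi) < 1e-10


class TestWcFst:
    def _fst(self, rows, n1):
        gm = make_gm(rows)
        n = len(rows[0])
        pm = make_popmap({f"ind{i + 1}": ("a" if i < n1 else "b")
                          for i in range(n)})
        return gm, pm

    def test_fixed_difference_is_one(self):
        gm, pm = self._fst([[2] * 5 + [0] * 5] * 4, 5)
        assert abs(wc_fst(gm, pm, "a", "b") - 1) < 1e-12

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(2)
        rows = []
        for _ in range(1000):
            p = rng.uniform(0.2, 0.8)
            g = rng.binomial(2, p, size=20)
            rows.append(list(g))
        gm, pm = self._fst(rows, 10)
        assert abs(wc_fst(gm, pm, "a", "b")) < 0.05

    def test_monomorphic_is_nan(self):
        gm, pm = self._fst([[0] * 8], 4)
        assert np.isnan(wc_fst(gm, pm, "a", "b"))

    def test_matches_naive_formulas(self):
        rng = np.random.default_rng(5)
        rows = rng.integers(0, 3, size=(20, 20)).tolist()
        gm, pm = self._fst(rows, 10)
        theta = wc_fst(gm, pm, "a", "b")
        oracle = naive_wc_theta([r[:10] for r in rows], [r[10:] for r in rows])
        assert abs(theta - oracle) < 1e-10


class TestBetaSt:
    def test_identical_populations_near_zero(self):
        # identical tables leave only the O(1/copies) without-replacement
        # correction between M_i and M_B, so beta shrinks with sample size
        rng = np.random.default_rng(1)
        block = rng.integers(0, 3, size=(60, 60))
        rows = np.hstack([block, block]).tolist()
        gm = make_gm(rows)
        pm = make_popmap({f"ind{i + 1}": ("a" if i < 60 else "b")
                          for i in range(120)})
        res = beta_st(gm, pm, n_boot=50, seed=0)
        assert np.all(np.abs(res["beta"]) < 0.02)
        assert res["beta"].iloc[0] == res["beta"].iloc[1]

    def test_private_alleles_give_negative_beta(self):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(80):
            anc = [rng.binomial(2, 0.2) for _ in range(6)]  # pop a: private
            rows.append(anc + [0] * 12)
        gm = make_gm(rows)
        pm = make_popmap({f"ind{i + 1}": f"p{i // 6}" for i in range(18)})
        res = beta_st(gm, pm, n_boot=50, seed=0).set_index("population")
        assert res.loc["p0", "beta"] < 0
        assert res.loc["p0", "beta"] < res.loc["p1", "beta"]

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(7)
        rows = rng.integers(0, 3, size=(30, 9)).tolist()
        # keep every site polymorphic dataset-wide to avoid 1 - M_B = 0 issues
        gm = make_gm(rows)
        assignment = {f"ind{i + 1}": f"p{i // 3}" for i in range(9)}
        pm = make_popmap(assignment)
        res = beta_st(gm, pm, n_boot=10, seed=0).set_index("population")
        cols = {p: [[rows[s][i] for i, (k, v) in
                     enumerate(assignment.items()) if v == p]
                    for s in range(30)] for p in ("p0", "p1", "p2")}
        oracle = naive_beta(cols)
        for p, b in oracle.items():
            assert abs(res.loc[p, "beta"] - b) < 1e-10

    def test_bootstrap_brackets_point_and_is_seeded(self):
        rng = np.random.default_rng(8)
        rows = rng.integers(0, 3, size=(40, 8)).tolist()
        gm = make_gm(rows)
        pm = make_popmap({f"ind{i + 1}": f"p{i // 4}" for i in range(8)})
        r1 = beta_st(gm, pm, n_boot=200, seed=5)
        r2 = beta_st(gm, pm, n_boot=200, seed=5)
        pd.testing.assert_frame_equal(r1, r2)
        assert np.all(r1["ci_low"] <= r1["beta"] + 1e-9)
        assert np.all(r1["beta"] <= r1["ci_high"] + 1e-9)

    def test_exchangeable_populations_beta_near_zero(self):
        # individuals drawn from one panmictic pool and split at random:
        # no population is ancestral, so every beta must hover around 0
        rng = np.random.default_rng(17)
        p = rng.uniform(0.1, 0.9, size=200)
        rows = [list(rng.binomial(2, pj, size=30)) for pj in p]
        gm = make_gm(rows)
        betas = []
        for perm_seed in range(5):
            order = list(np.random.default_rng(perm_seed).permutation(30))
            pm = make_popmap({f"ind{i + 1}": f"p{order.index(i) // 10}"
                              for i in range(30)})
            res = beta_st(gm, pm, n_boot=10, seed=0)
            betas.extend(res["beta"].tolist())
        assert abs(np.mean(betas)) < 0.02
        assert max(np.abs(betas)) < 0.1

    def test_single_population_errors(self):
        gm = make_gm([[0, 1]])
        pm = make_popmap({"ind1": "p", "ind2": "p"})
        with pytest.raises(ValueError):
            beta_st(gm, pm)


class TestSingletons:
    def test_definition_single_heterozygote(self):
        rows = [[1] + [0] * 27]  # alt allele in exactly one individual (pop a)
        gm = make_gm(rows)
        pm = make_popmap({f"ind{i + 1}": ("a" if i < 14 else "b")
                          for i in range(28)})
        res = singleton_rarefaction(gm, pm, subsample=13, reps=40, seed=0)
        per = res["per_population"].set_index("population")
        counts = res["replicate_counts"]
        # exactly 1 singleton for pop a in every replicate containing ind1
        assert per.loc["b", "mean_singletons"] == 0
        assert set(np.unique(counts[:, 0])) <= {0, 1}
        assert 0 < per.loc["a", "mean_singletons"] <= 1

    def test_monomorphic_counts_zero(self):
        gm = make_gm([[0] * 26, [2] * 26])
        pm = make_popmap({f"ind{i + 1}": ("a" if i < 13 else "b")
                          for i in range(26)})
        res = singleton_rarefaction(gm, pm, subsample=13, reps=5, seed=1)
        assert res["per_population"]["mean_singletons"].sum() == 0

    def test_replayed_subsamples_match_recount(self):
        rng = np.random.default_rng(11)
        rows = rng.integers(0, 3, size=(40, 30)).tolist()
        gm = make_gm(rows)
        pm = make_popmap({f"ind{i + 1}": ("a" if i < 15 else "b")
                          for i in range(30)})
        res = singleton_rarefaction(gm, pm, subsample=13, reps=10, seed=21)
        # replay: regenerate the same subsample sequence and recount naively
        members = {p: pm.members(p, gm.individuals) for p in ("a", "b")}
        rng2 = np.random.default_rng(21)
        for rep in range(10):
            chosen = np.concatenate([rng2.choice(members[p], size=13,
                                                 replace=False)
                                     for p in ("a", "b")])
            counts = {"a": 0, "b": 0}
            v = gm.values[chosen]
            for s in range(gm.n_sites):
                col = v[:, s]
                called = col != MISSING
                alt = int(col[called].sum())
                copies = int(2 * called.sum())
                if alt == 0 or alt == copies:
                    continue
                minor = col if 2 * alt <= copies else 2 - col
                carriers = np.flatnonzero((minor > 0) & called)
                if len(carriers) == 1:
                    pop = "a" if carriers[0] < 13 else "b"
                    counts[pop] += 1
            assert res["replicate_counts"][rep, 0] == counts["a"]
            assert res["replicate_counts"][rep, 1] == counts["b"]

    def test_small_population_dropped_with_warning(self):
        gm = make_gm([[0, 1] * 8])
        pm = make_popmap({f"ind{i + 1}": ("a" if i < 13 else "b")
                          for i in range(16)})
        with pytest.warns(UserWarning, match="dropped"):
            res = singleton_rarefaction(gm, pm, subsample=13, reps=2, seed=0)
        assert list(res["per_population"]["population"]) == ["a"]


class TestTajimasD:
    def test_hand_computed_small_case(self):
        xi = np.array([0.0, 3, 2, 1, 0])  # n = 4
        assert abs(tajimas_d(xi) - naive_tajima([0, 3, 2, 1, 0])) < 1e-12
        assert abs(tajimas_d(xi) - 0.17965) < 5e-5  # frozen hand value

    def test_all_singletons_negative(self):
        xi = np.zeros(11)
        xi[1] = 20
        assert tajimas_d(xi) < 0

    def test_no_segregating_sites_warns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(tajimas_d(np.zeros(11)))

    def test_equilibrium_mean_near_zero(self):
        # coalescent engine: equilibrium one-population spectra, many loci
        from expansionload.coalescent import expected_branchlengths
        rng = np.random.default_rng(0)
        bl = expected_branchlengths(10, 0, t_split=0.0, n_reps=200_000, seed=3)
        p = bl[1:10, 0] / bl[1:10, 0].sum()
        ds = []
        for _ in range(300):
            xi = np.zeros(11)
            xi[1:10] = rng.multinomial(40, p)
            ds.append(tajimas_d(xi))
        assert abs(np.mean(ds)) < 0.06


class TestMantel:
    def _mat(self, values, labels):
        return pd.DataFrame(values, index=labels, columns=labels)

    def test_perfect_monotone(self):
        labels = list("abcd")
        d = np.array([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0]],
                     dtype=float)
        r, p = mantel(self._mat(d, labels), self._mat(2 * d, labels))
        assert abs(r - 1) < 1e-12
        # smallest achievable exact p over 24 permutations
        assert p <= 4 / 24 + 1e-12

    def test_exact_p_equals_enumeration(self):
        rng = np.random.default_rng(6)
        labels = list("abcd")
        x = rng.random((4, 4))
        x = (x + x.T) / 2
        np.fill_diagonal(x, 0)
        y = rng.random((4, 4))
        y = (y + y.T) / 2
        np.fill_diagonal(y, 0)
        r, p = mantel(self._mat(x, labels), self._mat(y, labels))
        tri = np.triu_indices(4, 1)
        robs = np.corrcoef(x[tri], y[tri])[0, 1]
        count = 0
        for perm in itertools.permutations(range(4)):
            yp = y[np.ix_(perm, perm)]
            count += abs(np.corrcoef(x[tri], yp[tri])[0, 1]) >= abs(robs) - 1e-12
        assert abs(r - robs) < 1e-12
        assert abs(p - count / 24) < 1e-12

    def test_label_mismatch_errors(self):
        a = self._mat(np.zeros((3, 3)), list("abc"))
        b = self._mat(np.zeros((3, 3)), list("abd"))
        with pytest.raises(ValueError):
            mantel(a, b)


class TestOls:
    def test_exact_line(self):
        x = np.arange(10.0)
        rep = ols_report(x, 3 * x + 1)
        assert abs(rep["slope"] - 3) < 1e-12 and abs(rep["r2"] - 1) < 1e-12

    def test_orthogonal_slope_zero(self):
        x = np.array([-2.0, -1, 0, 1, 2])
        y = np.array([1.0, -1, 0, -1, 1])  # even function: cov(x, y) = 0
        assert abs(ols_report(x, y)["slope"]) < 1e-12

    def test_normal_equation_solution(self):
        rng = np.random.default_rng(12)
        x = rng.random(10)
        y = rng.random(10)
        rep = ols_report(x, y)
        X = np.vstack([x, np.ones(10)]).T
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert abs(rep["slope"] - beta[0]) < 1e-10
        assert abs(rep["intercept"] - beta[1]) < 1e-10

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            ols_report([1, 1, 1], [1, 2, 3])


def test_bh_adjust_matches_definition():
    p = np.array([0.01, 0.04, 0.03, 0.2])
    # manual BH: sort, p*(n/rank), cumulative min from the largest rank
    expected = np.array([0.04, 0.053333333333333337, 0.053333333333333337, 0.2])
    np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)


def test_gradient_report_on_constant_he():
    rng = np.random.default_rng(1)
    rows = rng.integers(0, 3, size=(60, 12)).tolist()
    gm = make_gm(rows)
    pm = make_popmap({f"ind{i + 1}": f"p{i // 3}" for i in range(12)})
    rep = ibd_and_gradient_report(gm, pm, n_boot=20, mantel_perms=100, seed=0)
    assert set(rep["regressions"]["response"]) == {"He", "beta",
                                                   "fst_vs_source", "tajimas_d"}
    assert rep["source_population"] == "p0"
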