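"""Pedigree relationship matrices and the weighted animal-model fit."""

import numpy as np
import pandas as pd
import pytest

from lethalscan.carrier_association import (Pedigree, build_a_inverse,
                                            build_a_matrix,
                                            filter_trait_records,
                                            fit_animal_model,
                                            inbreeding_coefficients,
                                            run_association)
from lethalscan.haplotype_scan import CarrierStatus


def random_pedigree(n, n_founders, rng, prefix="a"):
    triples = [(f"{prefix}{i}", None, None) for i in range(n_founders)]
    for i in range(n_founders, n):
        s, d = rng.integers(0, i, 2)
        triples.append((f"{prefix}{i}", f"{prefix}{s}", f"{prefix}{d}"))
    return Pedigree.from_triples(triples)


def a_matrix_oracle(ped):
    """Recursive definition of the relationship matrix, memoized."""
    from functools import lru_cache
    sire, dam = ped.sire, ped.dam

    @lru_cache(maxsize=None)
    def a(i, j):
        if i < j:
            i, j = j, i
        if i == j:
            s, d = sire[i], dam[i]
            return 1.0 + (0.5 * a(s, d) if s >= 0 and d >= 0 else 0.0)
        s, d = sire[i], dam[i]
        out = 0.0
        if s >= 0:
            out += 0.5 * a(s, j)
        if d >= 0:
            out += 0.5 * a(d, j)
        return out

    n = len(ped)
    return np.array([[a(i, j) for j in range(n)] for i in range(n)])


class TestPedigree:
    def test_topological_sort_and_implicit_founders(self):
        ped = Pedigree.from_triples([("kid", "pa", "ma"), ("pa", None, None)])
        idx = ped.index
        assert idx["pa"] < idx["kid"] and idx["ma"] < idx["kid"]
        assert len(ped) == 3  # 'ma' added as founder

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            Pedigree.from_triples([("a", "b", None), ("b", "a", None)])

    def test_prune_keeps_ancestors(self, rng):
        ped = random_pedigree(30, 5, rng)
        sub = ped.prune_to([ped.animals[-1]])
        assert ped.animals[-1] in sub.animals
        # every kept non-founder's parents are kept too
        idx = sub.index
        for i in range(len(sub)):
            for p in (sub.sire[i], sub.dam[i]):
                assert p == -1 or p < i


class TestAMatrix:
    def test_two_unrelated_founders(self):
        ped = Pedigree.from_triples([("x", None, None), ("y", None, None)])
        assert np.array_equal(build_a_matrix(ped), np.eye(2))

    def test_parent_offspring_trio(self):
        ped = Pedigree.from_triples([("s", None, None), ("d", None, None),
                                     ("kid", "s", "d")])
        a = build_a_matrix(ped)
        i = ped.index
        assert a[i["s"], i["kid"]] == 0.5
        assert a[i["d"], i["kid"]] == 0.5
        assert a[i["s"], i["d"]] == 0.0
        assert np.all(np.diag(a) == 1.0)

    def test_full_sibs_half_related(self):
        ped = Pedigree.from_triples([("s", None, None), ("d", None, None),
                                     ("k1", "s", "d"), ("k2", "s", "d")])
        a = build_a_matrix(ped)
        i = ped.index
        assert a[i["k1"], i["k2"]] == 0.5

    def test_matches_recursive_oracle_on_random_pedigrees(self, rng):
        for trial in range(4):
            ped = random_pedigree(50, 8, rng, prefix=f"t{trial}_")
            got = build_a_matrix(ped)
            want = a_matrix_oracle(ped)
            assert np.allclose(got, want, atol=1e-12)

    def test_positive_semidefinite(self, rng):
        ped = random_pedigree(40, 6, rng)
        eig = np.linalg.eigvalsh(build_a_matrix(ped))
        assert eig.min() > -1e-10

    def test_inverse_consistent_with_tabular(self, rng):
        ped = random_pedigree(60, 10, rng)
        a = build_a_matrix(ped)
        ainv = build_a_inverse(ped).toarray()
        assert np.abs(a @ ainv - np.eye(len(ped))).max() < 1e-10

    def test_inbreeding_matches_diagonal(self, rng):
        ped = random_pedigree(80, 6, rng)
        f = inbreeding_coefficients(ped)
        assert np.allclose(f, np.diag(build_a_matrix(ped)) - 1.0, atol=1e-12)
        assert f.max() > 0  # random matings in a small pedigree create inbreeding


def gls_oracle(records, ped, ratio):
    a = build_a_matrix(ped)
    idx = ped.index
    rows = [idx[an] for an in records["animal"]]
    n = len(records)
    z = np.zeros((n, len(ped)))
    z[np.arange(n), rows] = 1.0
    w = records["weight"].to_numpy(float)
    y = records["debv"].to_numpy(float)
    x = np.column_stack([np.ones(n), records["dosage"].to_numpy(float)])
    v = ratio * z @ a @ z.T + np.diag(1.0 / w)
    vi = np.linalg.inv(v)
    xvx = x.T @ vi @ x
    beta = np.linalg.solve(xvx, x.T @ vi @ y)
    resid = y - x @ beta
    sigma_e2 = float(resid @ vi @ resid / (n - 2))
    se = np.sqrt(sigma_e2 * np.linalg.inv(xvx)[1, 1])
    return beta, se, sigma_e2


class TestAnimalModel:
    def make_records(self, ped, rng, n=150, beta=-0.4):
        animals = list(rng.choice(ped.animals, size=n, replace=False))
        dosage = rng.integers(0, 2, n).astype(float)
        w = rng.uniform(0.5, 2.0, n)
        y = 1.0 + beta * dosage + rng.normal(0, 0.5, n)
        return pd.DataFrame({"animal": animals, "debv": y, "weight": w,
                             "dosage": dosage})

    def test_matches_direct_gls_inversion(self, rng):
        ped = random_pedigree(200, 30, rng)
        records = self.make_records(ped, rng, n=150)
        for ratio in (0.1, 0.5, 2.0):
            fit = fit_animal_model(records, ped, ratio)
            (mu, beta), se, s2 = gls_oracle(records, ped, ratio)
            assert fit.mu_hat == pytest.approx(mu, rel=1e-8)
            assert fit.effect == pytest.approx(beta, rel=1e-8)
            assert fit.effect_se == pytest.approx(se, rel=1e-8)
            assert fit.sigma_e2 == pytest.approx(s2, rel=1e-8)

    def test_zero_ratio_collapses_to_weighted_least_squares(self, rng):
        ped = random_pedigree(100, 20, rng)
        records = self.make_records(ped, rng, n=80)
        fit = fit_animal_model(records, ped, 0.0)
        x = np.column_stack([np.ones(len(records)), records["dosage"]])
        w = records["weight"].to_numpy(float)
        beta = np.linalg.solve(x.T @ (w[:, None] * x),
                               x.T @ (w * records["debv"].to_numpy(float)))
        assert fit.effect == pytest.approx(beta[1], rel=1e-10)

    def test_identity_relationship_equal_weights_is_ridge(self, rng):
        # founders only: A = I, so the animal effect is plain ridge shrinkage
        ped = Pedigree.from_triples([(f"f{i}", None, None) for i in range(60)])
        records = pd.DataFrame({
            "animal": [f"f{i}" for i in range(60)],
            "debv": rng.normal(0, 1, 60),
            "weight": np.ones(60),
            "dosage": rng.integers(0, 2, 60).astype(float),
        })
        ratio = 0.7
        fit = fit_animal_model(records, ped, ratio)
        x = np.column_stack([np.ones(60), records["dosage"]])
        v = ratio * np.eye(60) + np.eye(60)
        vi = np.linalg.inv(v)
        beta = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ records["debv"])
        assert fit.effect == pytest.approx(beta[1], rel=1e-10)

    def test_constant_dosage_rejected(self, rng):
        ped = random_pedigree(50, 10, rng)
        records = self.make_records(ped, rng, n=40)
        records["dosage"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_animal_model(records, ped, 0.5)

    def test_null_permutations_control_type_one_error(self, rng):
        # permuted dosages on null data: -log10(p) > 5 should essentially
        # never occur in a handful of replicates
        ped = random_pedigree(300, 60, rng)
        base = self.make_records(ped, rng, n=250, beta=0.0)
        hits = 0
        for _ in range(10):
            rec = base.copy()
            rec["dosage"] = rng.permutation(rec["dosage"].to_numpy())
            if rec["dosage"].nunique() < 2:
                continue
            fit = fit_animal_model(rec, ped, 0.3)
            hits += fit.minus_log10_p > 5
        assert hits == 0


class TestRunAssociation:
    def test_filters_and_table_layout(self, rng):
        ped = random_pedigree(400, 80, rng)
        n = 350
        animals = list(rng.choice(ped.animals, size=n, replace=False))
        dosage = {a: int(rng.random() < 0.1) for a in animals}
        frame = pd.DataFrame({
            "animal": animals,
            "debv": rng.normal(0, 1, n) - 0.4 * np.array([dosage[a] for a in animals]),
            "reliability": rng.uniform(0.05, 0.95, n),
            "weight": rng.uniform(0, 2, n),
        })
        kept = filter_trait_records(frame)
        assert (kept["reliability"] > 0.20).all() and (kept["weight"] > 0).all()
        carriers = CarrierStatus(dosage=dosage)
        table = run_association({"growth": frame}, carriers, ped, heritability=0.3)
        assert list(table.columns) == ["trait", "n_noncarriers", "n_carriers",
                                       "effect", "se", "minus_log10_p", "significant"]
        assert len(table) == 1
        row = table.iloc[0]
        assert row.n_carriers + row.n_noncarriers == len(
            kept[kept.animal.isin(dosage)])

    def test_sparse_trait_skipped(self, rng):
        ped = random_pedigree(50, 10, rng)
        frame = pd.DataFrame({
            "animal": ped.animals[:20],
            "debv": rng.normal(0, 1, 20),
            "reliability": np.full(20, 0.9),
            "weight": np.ones(20),
        })
        carriers = CarrierStatus(dosage={a: 0 for a in ped.animals})
        with pytest.warns(UserWarning, match="skipped"):
            table = run_association({"tiny": frame}, carriers, ped, 0.3)
        assert len(table) == 0
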