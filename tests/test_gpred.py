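import numpy as np
import pandas as pd
import pytest

from ufcpred import gpred


def _random_dosage(rng, n, p, maf_range=(0.1, 0.5)):
    freq = rng.uniform(*maf_range, p)
    X = rng.binomial(1, freq, (n, p)) * 2  # DH-like {0,2}
    return pd.DataFrame(X, index=[f"L{i:04d}" for i in range(n)],
                        columns=[f"M{j:04d}" for j in range(p)], dtype=float)


class TestMarkerQC:
    def test_clean_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.integers(0, 3, (40, 8)).astype(float))
        X.iloc[0] = 1.0  # guarantee intermediate frequencies
        res = gpred.marker_qc(X)
        if len(res.kept) == 8:
            pd.testing.assert_frame_equal(res.X, X)

    def test_constructed_filter_counts(self):
        """10 markers: 3 at MAF 0.04, 2 with 10% missing, 5 clean -> 5 kept."""
        n = 50
        rng = np.random.default_rng(1)
        cols = {}
        for j in range(3):  # MAF 0.04: 4 carriers of dosage 1 among 50
            v = np.zeros(n)
            v[:4] = 1.0
            cols[f"low{j}"] = v
        for j in range(2):  # 10% missing, healthy MAF
            v = rng.integers(0, 3, n).astype(float)
            v[:2] = 0.0
            v[2:4] = 2.0
            v[rng.choice(n, 5, replace=False)] = np.nan
            cols[f"miss{j}"] = v
        for j in range(5):
            v = rng.integers(0, 3, n).astype(float)
            v[:10] = 0.0
            v[10:20] = 2.0
            cols[f"ok{j}"] = v
        X = pd.DataFrame(cols)
        res = gpred.marker_qc(X)
        assert sorted(res.kept) == sorted([f"ok{j}" for j in range(5)])
        assert len(res.dropped_maf) == 3
        assert len(res.dropped_missing) == 2

    def test_imputation_uses_allele_frequency(self):
        v = np.array([0.0, 2.0, 2.0, 2.0, np.nan])
        X = pd.DataFrame({"m": v, "anchor": [0, 1, 2, 1, 0.0]})
        res = gpred.marker_qc(X, max_missing=0.5)
        assert res.X.loc[4, "m"] == pytest.approx(2 * 0.75)

    def test_all_markers_dropped_raises(self):
        X = pd.DataFrame({"m": np.zeros(20)})
        with pytest.raises(ValueError):
            gpred.marker_qc(X)


class TestGRM:
    def test_identical_genotypes_exchangeable(self):
        rng = np.random.default_rng(2)
        X = _random_dosage(rng, 3, 50)
        X.iloc[1] = X.iloc[0]
        g = gpred.compute_grm(X)
        assert g.G[0, 0] == pytest.approx(g.G[1, 1])
        assert g.G[0, 1] == pytest.approx(g.G[0, 0])

    def test_symmetric_psd(self):
        rng = np.random.default_rng(3)
        g = gpred.compute_grm(_random_dosage(rng, 60, 300))
        assert np.allclose(g.G, g.G.T)
        assert np.linalg.eigvalsh(g.G).min() >= -1e-8

    def test_unrelated_population_mean_diagonal_near_one(self):
        rng = np.random.default_rng(4)
        freq = rng.uniform(0.05, 0.95, 2000)
        X = rng.binomial(2, freq, (500, 2000)).astype(float)
        g = gpred.compute_grm(pd.DataFrame(X))
        assert 0.95 < np.mean(np.diag(g.G)) < 1.05

    def test_monomorphic_rejected(self):
        X = pd.DataFrame(np.zeros((5, 4)))
        with pytest.raises(ValueError):
            gpred.compute_grm(X)


def _phenotypes(rng, X, n_qtl=50, h2=0.8):
    p = X.shape[1]
    qtl = rng.choice(p, n_qtl, replace=False)
    alpha = np.zeros(p)
    alpha[qtl] = rng.normal(0, 1, n_qtl)
    g = X.to_numpy() @ alpha
    g = (g - g.mean()) / g.std()
    noise_sd = np.sqrt((1 - h2) / h2)
    y = g + rng.normal(0, noise_sd, len(g))
    return pd.Series(y, index=X.index), g, alpha


class TestGBLUP:
    def test_near_noiseless_fit_tracks_phenotype(self):
        rng = np.random.default_rng(5)
        X = _random_dosage(rng, 200, 400)
        y, g, _ = _phenotypes(rng, X, h2=0.9999)
        grm = gpred.compute_grm(X)
        _, s2g, s2e, gebv = gpred.fit_gblup(y, grm)
        assert np.corrcoef(gebv[y.index], y)[0, 1] > 0.999

    def test_equivalence_with_rrblup(self):
        """GBLUP line effects equal the RRBLUP marker-effect fit mapped
        through the centered genotypes (matched variance components)."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, p = rng.integers(60, 200), rng.integers(100, 500)
            X = _random_dosage(rng, int(n), int(p))
            y, _, _ = _phenotypes(rng, X, n_qtl=min(30, int(p)), h2=0.6)
            grm = gpred.compute_grm(X)
            _, _, _, gebv = gpred.fit_gblup(y, grm)
            me = gpred.fit_rrblup(y, X)
            assert np.max(np.abs(gebv - me.gebv(X))) < 1e-6

    def test_prediction_of_unphenotyped_lines(self):
        rng = np.random.default_rng(6)
        X = _random_dosage(rng, 300, 500)
        y, g, _ = _phenotypes(rng, X, h2=0.9)
        grm = gpred.compute_grm(X)
        train = list(X.index[:250])
        test = list(X.index[250:])
        _, _, _, gebv = gpred.fit_gblup(y.loc[train], grm, train=train)
        assert np.corrcoef(gebv[test], g[250:])[0, 1] > 0.5

    def test_minimum_training_size(self):
        rng = np.random.default_rng(7)
        X = _random_dosage(rng, 20, 30)
        grm = gpred.compute_grm(X)
        y = pd.Series(rng.normal(0, 1, 5), index=X.index[:5])
        with pytest.raises(ValueError):
            gpred.fit_gblup(y, grm)


class TestRRBLUP:
    def test_single_marker_least_squares_limit(self):
        """One marker, no noise: the effect approaches half the dosage-class
        difference as the ridge penalty vanishes."""
        rng = np.random.default_rng(8)
        d = np.array([0.0, 2.0] * 30)
        X = pd.DataFrame({"m": d}, index=[f"L{i}" for i in range(60)])
        y = pd.Series(1.0 * d + rng.normal(0, 1e-4, 60), index=X.index)
        me = gpred.fit_rrblup(y, X)
        class_diff = y[d == 2].mean() - y[d == 0].mean()
        assert me.alpha["m"] == pytest.approx(class_diff / 2, rel=1e-2)

    def test_effect_recovery(self):
        rng = np.random.default_rng(9)
        X = _random_dosage(rng, 500, 1000)
        y, _, alpha = _phenotypes(rng, X, n_qtl=1000, h2=0.8)
        me = gpred.fit_rrblup(y, X)
        assert np.corrcoef(me.alpha.to_numpy(), alpha)[0, 1] > 0.3

    def test_no_markers_rejected(self):
        y = pd.Series([1.0] * 10)
        with pytest.raises(ValueError):
            gpred.fit_rrblup(y, pd.DataFrame(index=y.index))


def _family_structured_population(seed=10, n_fam=25, fam_size=20, p=1000,
                                 n_qtl=50, h2=0.9999):
    """DH families from few founders: the relatedness a GRM can exploit."""
    from ufcpred.crossing import CrossSpec, PhasedGenotype, make_cross, \
        produce_dh_family
    from ufcpred.genmap import build_genetic_map
    rng = np.random.default_rng(seed)
    gmap = build_genetic_map(7, p // 7, 150.0, rng)
    founders = {f"F{i}": PhasedGenotype.from_dosage(
        f"F{i}", rng.integers(0, 2, gmap.n_markers) * 2) for i in range(8)}
    rows, ids = [], []
    for k in range(n_fam):
        pa, pb = rng.choice(list(founders), 2, replace=False)
        f1 = make_cross(CrossSpec(f"FAM{k}", (pa, pb)), founders, gmap, rng)
        for line in produce_dh_family(f1, fam_size, gmap, rng):
            rows.append(line.dosage)
            ids.append(line.id)
    X = pd.DataFrame(np.array(rows, dtype=float), index=ids,
                     columns=gmap.marker)
    y, g, alpha = _phenotypes(rng, X, n_qtl=n_qtl, h2=h2)
    return X, y, g


class TestCrossValidation:
    def test_high_signal_approaches_one(self):
        """Noiseless genetic values in a family-structured population are
        predicted almost perfectly by five-fold cross-validation."""
        X, y, g = _family_structured_population()
        grm = gpred.compute_grm(X)
        r = gpred.cross_validate_5fold(y, grm, n_rep=1, seed=0)
        assert r > 0.95

    def test_permuted_phenotypes_give_null(self):
        rng = np.random.default_rng(11)
        X = _random_dosage(rng, 500, 400)
        y, _, _ = _phenotypes(rng, X, h2=0.9)
        yp = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        grm = gpred.compute_grm(X)
        r = gpred.cross_validate_5fold(yp, grm, n_rep=1, seed=1)
        assert abs(r) < 0.1

    def test_determinism(self):
        rng = np.random.default_rng(12)
        X = _random_dosage(rng, 100, 200)
        y, _, _ = _phenotypes(rng, X, h2=0.7)
        grm = gpred.compute_grm(X)
        a = gpred.cross_validate_5fold(y, grm, n_rep=1, seed=3)
        b = gpred.cross_validate_5fold(y, grm, n_rep=1, seed=3)
        assert a == b

    def test_folds_require_enough_genotypes(self):
        rng = np.random.default_rng(13)
        X = _random_dosage(rng, 20, 50)
        y = pd.Series(rng.normal(0, 1, 20), index=X.index)
        with pytest.raises(ValueError):
            gpred.cross_validate_5fold(y, gpred.compute_grm(X), n_rep=1)


class TestLeaveOneCycleOut:
    def test_exchangeable_cycles_match_5fold(self):
        """Cycles cut from one unstructured population predict about as well
        as random folds."""
        rng = np.random.default_rng(14)
        X = _random_dosage(rng, 400, 600)
        y, _, _ = _phenotypes(rng, X, n_qtl=40, h2=0.9)
        grm = gpred.compute_grm(X)
        cycles = pd.Series([f"C{i % 4}" for i in range(400)], index=X.index)
        per_cycle = gpred.leave_one_cycle_out(y, grm, cycles)
        r5 = gpred.cross_validate_5fold(y, grm, n_rep=2, seed=0)
        assert len(per_cycle) == 4
        assert abs(per_cycle.mean() - r5) < 0.1
        assert np.all(np.abs(per_cycle - r5) < 0.25)

    def test_unlinked_holdout_cycle_is_null(self):
        """A held-out cycle with independent genotypes and an independent
        architecture carries no transferable signal."""
        rng = np.random.default_rng(15)
        Xa = _random_dosage(rng, 300, 400)
        Xb = _random_dosage(rng, 100, 400)
        Xb.index = [f"B{i}" for i in range(100)]
        ya, _, _ = _phenotypes(rng, Xa, h2=0.9)
        yb = pd.Series(rng.normal(0, 1, 100), index=Xb.index)
        X = pd.concat([Xa, Xb])
        y = pd.concat([ya, yb])
        grm = gpred.compute_grm(X)
        cycles = pd.Series(["train"] * 300 + ["held"] * 100, index=X.index)
        res = gpred.leave_one_cycle_out(y, grm, cycles)
        assert abs(res["held"]) < 0.25

    def test_small_cycle_skipped(self):
        rng = np.random.default_rng(16)
        X = _random_dosage(rng, 60, 100)
        y, _, _ = _phenotypes(rng, X, h2=0.8)
        grm = gpred.compute_grm(X)
        cycles = pd.Series(["A"] * 30 + ["C"] * 28 + ["B"] * 2, index=X.index)
        with pytest.warns(UserWarning, match="skipped"):
            res = gpred.leave_one_cycle_out(y, grm, cycles)
        assert "B" not in res.index
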