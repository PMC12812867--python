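import numpy as np
import pandas as pd
import pytest

import mtmepred as mp
from mtmepred.data_io import DataError, PhenotypeTable
from mtmepred.prepare import (
    IncidenceMatrix,
    assemble_covariates,
    make_incidence,
    prepare_data,
)
from mtmepred.relationship import RelationshipMatrix, chol_upper, ensure_pd


class TestMakeIncidence:
    def test_first_appearance_order(self):
        Z = make_incidence(["E1", "E1", "E2"])
        assert Z.cols == ["E1", "E2"]
        np.testing.assert_array_equal(Z.values, [[1, 0], [1, 0], [0, 1]])

    def test_single_level(self):
        Z = make_incidence(["x"] * 4)
        np.testing.assert_array_equal(Z.values, np.ones((4, 1)))

    def test_column_sums_are_level_counts(self):
        rng = np.random.default_rng(4)
        labels = list(rng.choice(["a", "b", "c"], size=12))
        Z = make_incidence(labels)
        for j, lv in enumerate(Z.cols):
            assert Z.values[:, j].sum() == labels.count(lv)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            make_incidence([])


def random_pd(n, seed):
    rng = np.random.default_rng(seed)
    B = rng.standard_normal((n, n))
    return B @ B.T + n * np.eye(n)


class TestAssembleCovariates:
    def setup_blocks(self, n, e, records):
        inds = [f"i{k}" for k in range(n)]
        envs = [f"E{k + 1}" for k in range(e)]
        rec_ind = [inds[r % n] for r in range(records)]
        rec_env = [envs[(r // n) % e] for r in range(records)]
        ze = IncidenceMatrix(
            rec_env, envs,
            np.array([[1.0 if x == lv else 0.0 for lv in envs] for x in rec_env]),
        )
        zg = IncidenceMatrix(
            rec_ind, inds,
            np.array([[1.0 if x == iv else 0.0 for iv in inds] for x in rec_ind]),
        )
        zge_levels = [f"{iv}:{lv}" for lv in envs for iv in inds]
        Zge = np.zeros((records, n * e))
        for r, (s, en) in enumerate(zip(rec_ind, rec_env)):
            Zge[r, envs.index(en) * n + inds.index(s)] = 1.0
        zge = IncidenceMatrix([f"r{r}" for r in range(records)], zge_levels, Zge)
        return ze, zg, zge

    def test_gram_matrices_reproduce_covariances(self):
        n, e = 3, 2
        G = random_pd(n, 1)
        rm = RelationshipMatrix([f"i{k}" for k in range(n)], G)
        Q = chol_upper(ensure_pd(rm))
        ze, zg, zge = self.setup_blocks(n, e, n * e)
        X, blocks = assemble_covariates(ze, zg, zge, Q)
        a, b = blocks["genotype"]
        B = X[:, a:b]
        np.testing.assert_allclose(B @ B.T, zg.values @ G @ zg.values.T, atol=1e-8)
        a, b = blocks["gxe"]
        Bge = X[:, a:b]
        np.testing.assert_allclose(
            Bge @ Bge.T,
            zge.values @ np.kron(np.eye(e), G) @ zge.values.T,
            atol=1e-8,
        )

    def test_single_environment_kronecker(self):
        n = 4
        G = random_pd(n, 2)
        Q = chol_upper(ensure_pd(RelationshipMatrix([f"i{k}" for k in range(n)], G)))
        ze, zg, zge = self.setup_blocks(n, 1, n)
        X, blocks = assemble_covariates(ze, zg, zge, Q)
        np.testing.assert_array_equal(X[:, : blocks["env"][1]], np.ones((n, 1)))
        a, b = blocks["genotype"]
        c, d = blocks["gxe"]
        np.testing.assert_allclose(X[:, a:b], X[:, c:d], atol=1e-12)

    def test_identity_relationship_passes_zg_through(self):
        n = 3
        Q = chol_upper(RelationshipMatrix([f"i{k}" for k in range(n)], np.eye(n)))
        ze, zg, zge = self.setup_blocks(n, 2, n * 2)
        X, blocks = assemble_covariates(ze, zg, zge, Q)
        a, b = blocks["genotype"]
        np.testing.assert_array_equal(X[:, a:b], zg.values)

    def test_dimension_mismatch_named(self):
        ze, zg, zge = self.setup_blocks(3, 2, 6)
        with pytest.raises(ValueError, match="transform rows"):
            assemble_covariates(ze, zg, zge, np.zeros((5, 4)))


class TestPrepareData:
    def test_utue_raw_passthrough(self, ue_study):
        mm = ue_study.markers
        ds = prepare_data(ue_study.phenotypes, mm, multi_trait=False)
        assert ds.approach == "UTUE"
        assert ds.X.shape == (60, mm.n_markers)
        assert ds.Y.shape == (60, 1)
        assert ds.blocks == {"genotype": (0, mm.n_markers)}
        np.testing.assert_array_equal(ds.X, mm.dosages)

    def test_utue_relationship_covariance_preserved(self, ue_study):
        G = mp.vanraden_g(ue_study.markers)
        ds = prepare_data(ue_study.phenotypes, G, multi_trait=False)
        Gpd = ensure_pd(G)
        np.testing.assert_allclose(ds.X @ ds.X.T, Gpd.values, atol=1e-8)

    def test_mtme_dimensions(self):
        # n=4 individuals, e=2 environments, t=3 traits -> X 8x(2+4+8), Y 8x3
        n, e, t = 4, 2, 3
        ids = [f"i{k}" for k in range(n) for _ in range(e)]
        envs = [f"E{j + 1}" for _ in range(n) for j in range(e)]
        rng = np.random.default_rng(0)
        ph = PhenotypeTable(
            ids, pd.DataFrame(rng.standard_normal((n * e, t)),
                              columns=["t1", "t2", "t3"]), envs
        )
        G = RelationshipMatrix([f"i{k}" for k in range(n)], random_pd(n, 3))
        ds = prepare_data(ph, G, environments=["E1", "E2"], multi_trait=True)
        assert ds.approach == "MTME"
        assert ds.X.shape == (8, 2 + 4 + 8)
        assert ds.Y.shape == (8, 3)
        assert ds.blocks == {"env": (0, 2), "genotype": (2, 6), "gxe": (6, 14)}

    def test_ut_is_column_slice_of_mt(self, me_study):
        cfg = mp.SimConfig(n_individuals=30, n_markers=60, n_traits=2,
                           heritabilities=(0.5, 0.5), n_environments=2, seed=8)
        st = mp.simulate_study(cfg)
        G = mp.vanraden_g(st.markers)
        ph = mp.complete_case_alignment(st.phenotypes, ["E1", "E2"])
        mt = prepare_data(ph, G, environments=["E1", "E2"], multi_trait=True)
        for j, trait in enumerate(mt.trait_names):
            ut = prepare_data(ph, G, environments=["E1", "E2"],
                              multi_trait=False, trait=trait)
            np.testing.assert_array_equal(ut.Y[:, 0], mt.Y[:, j])
            np.testing.assert_array_equal(ut.X, mt.X)

    def test_record_order_invariant_to_input_shuffle(self, me_study):
        G = mp.vanraden_g(me_study.markers)
        ph = me_study.phenotypes
        ds = prepare_data(ph, G, environments=["E1", "E2"])
        rng = np.random.default_rng(11)
        perm = rng.permutation(ph.n_records)
        shuffled = PhenotypeTable(
            [ph.sample_ids[i] for i in perm],
            ph.traits.iloc[perm].reset_index(drop=True),
            [ph.environment[i] for i in perm],
        )
        ds2 = prepare_data(shuffled, G, environments=["E1", "E2"])
        # identical records per (id, env): same Y, and the same covariate
        # geometry (the Gram matrix is what any kernel model consumes; the
        # Cholesky basis itself may rotate with individual order)
        key = {(s, e): i for i, (s, e) in enumerate(zip(ds.sample_ids, ds.env_labels))}
        order = [key[(s, e)] for s, e in zip(ds2.sample_ids, ds2.env_labels)]
        np.testing.assert_allclose(ds2.Y, ds.Y[order], atol=1e-12)
        K1 = ds.X @ ds.X.T
        K2 = ds2.X @ ds2.X.T
        np.testing.assert_allclose(K2, K1[np.ix_(order, order)], atol=1e-8)
        # kernel (GBLUP) predictions per record are therefore unchanged
        from mtmepred.gblup import ridge_model_factory

        f1 = ridge_model_factory(1.0)(ds.X[:80], ds.Y[:80], 0)
        # same training records, expressed in the shuffled dataset's basis
        inv = {v: k for k, v in enumerate(order)}
        tr2 = sorted(inv[i] for i in range(80))
        f2 = ridge_model_factory(1.0)(ds2.X[tr2], ds2.Y[tr2], 0)
        p1 = f1(ds.X)
        p2 = f2(ds2.X)
        np.testing.assert_allclose(p2, p1[order], atol=1e-6)

    def test_id_mismatch_errors(self, ue_study):
        G = mp.vanraden_g(ue_study.markers)
        bad = PhenotypeTable(["nosuch1", "nosuch2", "nosuch3"],
                             pd.DataFrame({"t": [1.0, 2.0, 3.0]}))
        with pytest.raises(DataError, match="do not match"):
            prepare_data(bad, G)

    def test_me_without_environments_errors(self, me_study):
        G = mp.vanraden_g(me_study.markers)
        with pytest.raises(DataError, match="environments"):
            prepare_data(me_study.phenotypes, G)

    def test_serialization_round_trip(self, tmp_path, utue_ds):
        utue_ds.to_dir(tmp_path / "ds")
        back = mp.PreparedDataset.from_dir(tmp_path / "ds")
        np.testing.assert_allclose(back.X, utue_ds.X, atol=1e-12)
        np.testing.assert_allclose(back.Y, utue_ds.Y, atol=1e-12)
        assert back.approach == utue_ds.approach
        assert back.blocks == utue_ds.blocks
        assert back.sample_ids == utue_ds.sample_ids
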