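"""Robust correlation, adjacency, TOM, module detection and iteration."""

import numpy as np
import pandas as pd
import pytest

from tec_coexnet.coexnet import (
    ModuleAssignment,
    NetworkConfig,
    bicor,
    correlation_matrix,
    detect_modules,
    iterative_wgcna,
    module_eigengenes,
    module_membership,
    signed_adjacency,
    tom_similarity,
)
from tec_coexnet.simulate import UNASSIGNED, SimulationConfig, simulate_cohort, simulate_expression


def bicor_oracle(x, y):
    """Direct implementation of the biweight midcorrelation formula."""
    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    a, b = weights(np.asarray(x, float)), weights(np.asarray(y, float))
    return float(a @ b / np.sqrt((a**2).sum() * (b**2).sum()))


class TestBicor:
    def test_self_and_negated(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        assert bicor(x, x) == pytest.approx(1.0)
        assert bicor(x, -x) == pytest.approx(-1.0)

    def test_outlier_robustness_and_formula(self):
        x = np.arange(1.0, 21.0)
        y = x.copy()
        y[-1] = 200.0  # gross outlier
        b = bicor(x, y)
        pearson = np.corrcoef(x, y)[0, 1]
        assert b > pearson
        assert b == pytest.approx(bicor_oracle(x, y), abs=1e-12)

    def test_matches_formula_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=(2, 15))
            assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)

    def test_mad_zero_falls_back_to_pearson(self):
        # >50% identical values: MAD = 0, Pearson fallback
        x = np.array([1.0, 1.0, 1.0, 1.0, 2.0, 3.0])
        y = np.array([0.5, 1.5, 1.0, 2.0, 2.5, 3.5])
        expected = np.corrcoef(x, y)[0, 1]
        # y has nonzero MAD; oracle with mixed preparation
        got = bicor(x, y)
        assert np.isfinite(got) and -1 <= got <= 1
        xc = x - x.mean()
        def wprep(v):
            med = np.median(v)
            mad = np.median(np.abs(v - med))
            u = (v - med) / (9 * mad)
            w = (1 - u**2) ** 2 * (np.abs(u) < 1)
            return (v - med) * w
        yb = wprep(y)
        manual = xc @ yb / np.sqrt((xc**2).sum() * (yb**2).sum())
        assert got == pytest.approx(manual, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bicor([1, 2, 3], [1, 2])


class TestAdjacency:
    def test_closed_forms_at_limits(self):
        C = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=list("ab"), columns=list("ab"))
        assert signed_adjacency(C, 12).iloc[0, 1] == pytest.approx(1.0)
        C.iloc[0, 1] = C.iloc[1, 0] = -1.0
        assert signed_adjacency(C, 12).iloc[0, 1] == pytest.approx(0.0)
        C.iloc[0, 1] = C.iloc[1, 0] = 0.0
        assert signed_adjacency(C, 12).iloc[0, 1] == pytest.approx(0.5**12)

    def test_bounds_symmetry_unit_diagonal(self):
        rng = np.random.default_rng(1)
        M = rng.uniform(-1, 1, size=(10, 10))
        C = pd.DataFrame((M + M.T) / 2)
        np.fill_diagonal(C.values, 1.0)
        A = signed_adjacency(C, 6).to_numpy()
        assert ((A >= 0) & (A <= 1)).all()
        np.testing.assert_allclose(A, A.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(A), 1.0)


def tom_oracle(A):
    """Naive triple-loop evaluation of the topological overlap formula."""
    A = np.asarray(A, float).copy()
    np.fill_diagonal(A, 0.0)
    n = len(A)
    k = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


class TestTOM:
    def test_three_gene_hand_value(self):
        A = pd.DataFrame(np.full((3, 3), 0.5))
        np.fill_diagonal(A.values, 1.0)
        T = tom_similarity(A)
        # (0.5*0.5 + 0.5) / (min(1,1) + 1 - 0.5) = 0.75 / 1.5
        assert T.iloc[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_disconnected_graph(self):
        A = pd.DataFrame(np.eye(4))
        T = tom_similarity(A).to_numpy()
        assert (T[~np.eye(4, dtype=bool)] == 0).all()

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            M = rng.uniform(0, 1, size=(10, 10))
            A = (M + M.T) / 2
            np.fill_diagonal(A, 1.0)
            T = tom_similarity(pd.DataFrame(A)).to_numpy()
            np.testing.assert_allclose(T, tom_oracle(A), atol=1e-12)


def _planted(seed, sizes, noise=0.0, n_noise=0, **kw):
    cfg = SimulationConfig(
        seed=seed, n_subjects=5, fraction_missing=0.0, n_modules=len(sizes),
        module_sizes=sizes, origin_effects=(0.0,) * len(sizes),
        activation_effects=(0.0,) * len(sizes), subject_sd=0.0,
        noise_sd=noise, n_background_genes=n_noise, background_high_weight=1.0,
        loading_range=(1.0, 1.0) if noise == 0 else (0.7, 1.0), **kw,
    )
    ann = simulate_cohort(cfg)
    return simulate_expression(cfg, ann)


class TestDetectModules:
    def test_two_noiseless_blocks_recovered(self):
        X, truth = _planted(0, (50, 50))
        C = correlation_matrix(X)
        T = tom_similarity(signed_adjacency(C))
        assignment = detect_modules(T, NetworkConfig(), X=X)
        assert len(assignment.module_sizes) == 2
        labels = assignment.module_of_gene
        for m in ("M1", "M2"):
            truths = {truth.true_module_of_gene[g] for g in assignment.genes_of(m)}
            assert len(truths) == 1

    def test_min_size_dissolves_everything(self):
        X, _ = _planted(1, (40, 40))
        C = correlation_matrix(X)
        T = tom_similarity(signed_adjacency(C))
        cfg = NetworkConfig(min_module_size=40, pam_stage=False)
        assignment = detect_modules(T, cfg)
        assert (assignment.module_of_gene == UNASSIGNED).all() or (
            assignment.module_sizes >= 40
        ).all()

    def test_too_few_genes_raises(self):
        X, _ = _planted(2, (40,))
        T = tom_similarity(signed_adjacency(correlation_matrix(X)))
        with pytest.raises(ValueError):
            detect_modules(T, NetworkConfig(min_module_size=30))


class TestEigengenes:
    def test_identical_genes_give_common_profile(self):
        profile = np.sin(np.arange(12.0))
        X = pd.DataFrame([profile] * 5, index=[f"g{i}" for i in range(5)],
                         columns=[f"s{j}" for j in range(12)])
        assignment = ModuleAssignment(pd.Series("M1", index=X.index))
        eig = module_eigengenes(X, assignment)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(eig.loc["M1"].to_numpy(), z, atol=1e-10)
        kme = module_membership(X, eig)
        np.testing.assert_allclose(kme["M1"], 1.0, atol=1e-10)

    def test_orientation_follows_module_genes(self):
        """Flipping every module gene flips the oriented eigengene with it:
        the orientation rule keeps the mean gene correlation non-negative,
        so the profile-vs-genes relationship is invariant."""
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(6, 10)))
        X.index = [f"g{i}" for i in range(6)]
        assignment = ModuleAssignment(pd.Series("M1", index=X.index))
        e1 = module_eigengenes(X, assignment)
        e2 = module_eigengenes(-X, assignment)
        np.testing.assert_allclose(e1.to_numpy(), -e2.to_numpy(), atol=1e-10)
        for frame, eig in ((X, e1), (-X, e2)):
            kme = module_membership(frame, eig, method="pearson")
            assert kme["M1"].mean() >= 0

    def test_unit_variance_and_svd_oracle(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(8, 15)), index=[f"g{i}" for i in range(8)])
        assignment = ModuleAssignment(pd.Series("M1", index=X.index))
        eig = module_eigengenes(X, assignment)
        assert eig.loc["M1"].std(ddof=1) == pytest.approx(1.0)
        Z = ((X.T - X.mean(axis=1)) / X.std(axis=1, ddof=1)).T.to_numpy()
        _, s, Vt = np.linalg.svd(Z, full_matrices=False)
        expected = Vt[0] / np.std(Vt[0], ddof=1)
        got = eig.loc["M1"].to_numpy()
        np.testing.assert_allclose(np.abs(got), np.abs(expected), atol=1e-8)
        # the reported profile carries the leading singular direction: its
        # correlation-weighted variance share matches the SVD oracle
        share = ((Z @ got) ** 2).sum() / ((got @ got) * (Z**2).sum())
        assert share == pytest.approx(s[0] ** 2 / (s**2).sum(), abs=1e-10)


class TestIterativeWGCNA:
    def test_noiseless_modules_converge_without_pruning(self):
        X, truth = _planted(5, (40, 50))
        assignment, eig, kme = iterative_wgcna(X, NetworkConfig())
        assert assignment.converged
        sizes = sorted(assignment.module_sizes)
        assert sizes == [40, 50]
        # zero pruned: every gene keeps its module through the iterations
        assert (assignment.module_of_gene != UNASSIGNED).all()

    def test_noise_genes_end_unassigned(self):
        rates = []
        for seed in range(3):
            X, truth = _planted(seed, (60, 60), noise=0.3, n_noise=150)
            assignment, _, _ = iterative_wgcna(X, NetworkConfig())
            noise = [g for g, m in truth.true_module_of_gene.items() if m == UNASSIGNED]
            rates.append(
                np.mean([assignment.module_of_gene[g] == UNASSIGNED for g in noise])
            )
        assert np.mean(rates) >= 0.9

    def test_zero_threshold_matches_single_pass(self):
        X, _ = _planted(6, (40, 40), noise=0.2)
        cfg = NetworkConfig(mm_prune_threshold=0.0)
        assignment, _, _ = iterative_wgcna(X, cfg)
        T = tom_similarity(signed_adjacency(correlation_matrix(X)))
        single = detect_modules(T, cfg, X=X)
        pd.testing.assert_series_equal(
            assignment.module_of_gene, single.module_of_gene, check_names=False
        )

    def test_median_kme_of_surviving_modules_clears_threshold(self):
        X, _ = _planted(7, (50, 60), noise=0.3, n_noise=100)
        cfg = NetworkConfig()
        assignment, eig, kme = iterative_wgcna(X, cfg)
        for m in assignment.module_sizes.index:
            genes = assignment.genes_of(m)
            assert kme.loc[genes, m].median() >= cfg.mm_prune_threshold

    def test_gene_order_and_positive_affine_invariance(self):
        X, _ = _planted(8, (40, 40), noise=0.2)
        assignment1, _, _ = iterative_wgcna(X, NetworkConfig())
        shuffled = X.sample(frac=1, random_state=0)
        scaled = (shuffled.T * np.linspace(0.5, 2.0, len(shuffled))).T + 3.0
        assignment2, _, _ = iterative_wgcna(scaled, NetworkConfig())
        got = assignment2.module_of_gene[X.index]
        # same partition (module names may permute)
        table = pd.crosstab(assignment1.module_of_gene, got)
        assert (table.gt(0).sum(axis=1) == 1).all()
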