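"""DCCM and domain-score computations against brute-force oracles."""

import numpy as np
import pytest

import ensemblekit as ek
from ensemblekit.correlation import DCCMatrix
from ensemblekit.errors import UndefinedCorrelationError
from ensemblekit.essential import CovarianceModel
from ensemblekit.structure import AtomSelection


def wrap_covariance(matrix, structure=None):
    """Embed a raw 3N×3N matrix into a CovarianceModel over a CA chain."""
    n = matrix.shape[0] // 3
    if structure is None:
        structure = ek.make_toy_structure(max(n, 2), "extended")
        structure = structure.subset(np.arange(n))
    return CovarianceModel(
        mean_coords=structure.coords[:n],
        matrix=np.asarray(matrix, dtype=float),
        structure=structure,
        analysis_indices=np.arange(n),
        fit_selection=AtomSelection.ca(),
        reference_coords=structure.coords,
        n_frames_used=2,
    )


def random_dccm(rng, n):
    """Random valid correlation matrix: unit diagonal, symmetric, |c|<=1."""
    a = rng.normal(size=(n, n + 3))
    c = a @ a.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    return DCCMatrix(matrix=c, residue_ids=np.arange(1, n + 1))


def random_domain_map(rng, n, max_domains=5):
    k = int(rng.integers(2, max_domains + 1))
    edges = np.sort(rng.choice(np.arange(2, n + 1), size=k - 1, replace=False))
    bounds = np.concatenate([[1], edges, [n + 1]])
    return ek.domain_map_from_dict(
        {f"D{i}": [[int(bounds[i]), int(bounds[i + 1] - 1)]]
         for i in range(len(bounds) - 1)})


class TestComputeDccm:
    def test_diagonal_covariance_gives_identity(self):
        cov = wrap_covariance(np.diag(np.arange(1.0, 16.0)))
        dccm = ek.compute_dccm(cov)
        np.testing.assert_allclose(dccm.matrix, np.eye(5), atol=1e-14)

    def test_exact_antiphase_minus_one(self, chain_ca_5):
        """Two residues moving in exact antiphase along x correlate at −1."""
        base = chain_ca_5.coords
        frames = []
        for d in (0.1, -0.1, 0.05, -0.05):
            f = base.copy()
            f[0, 0] += d
            f[1, 0] -= d
            frames.append(f)
        traj = ek.TrajectoryEnsemble(
            structure=chain_ca_5, atom_indices=np.arange(5),
            frames=np.asarray(frames), times=np.arange(4.0))
        cov = ek.build_covariance(traj, superpose=False)
        cov.matrix += 1e-12 * np.eye(15)   # give static residues self-variance
        dccm = ek.compute_dccm(cov)
        assert dccm.matrix[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_zero_self_variance_names_residue(self):
        m = np.zeros((6, 6))
        m[0, 0] = m[1, 1] = m[2, 2] = 1.0     # residue 1 moves, residue 2 static
        with pytest.raises(UndefinedCorrelationError, match="residue 2"):
            ek.compute_dccm(wrap_covariance(m))

    def test_planted_interdomain_correlation(self, small_planted_ensemble):
        spec, traj, truth = small_planted_ensemble
        cov = ek.build_covariance(traj, superpose=False)
        dccm = ek.compute_dccm(cov)
        inter = dccm.matrix[:25, 25:]
        assert abs(inter.mean() - (-0.8)) <= 0.05
        # entrywise planted-truth recovery at the 3/sqrt(F) sampling scale
        assert np.abs(dccm.matrix - truth.dccm).max() <= 3.0 / np.sqrt(spec.n_frames)

    def test_dccm_bounds_and_unit_diagonal(self, small_planted_ensemble):
        _, traj, _ = small_planted_ensemble
        dccm = ek.compute_dccm(ek.build_covariance(traj, superpose=False))
        assert np.abs(np.diag(dccm.matrix) - 1).max() <= 1e-12
        assert np.abs(dccm.matrix).max() <= 1 + 1e-9
        assert np.abs(dccm.matrix - dccm.matrix.T).max() <= 1e-12


class TestResidueScores:
    def test_identity_dccm_zero_scores(self):
        dccm = DCCMatrix(matrix=np.eye(4), residue_ids=np.arange(1, 5))
        dmap = ek.domain_map_from_dict({"A": [[1, 2]], "B": [[3, 4]]})
        scores = ek.residue_scores(dccm, dmap)
        assert np.abs(scores.table["cs_total"]).max() == 0.0

    def test_hand_computed_three_residue_example(self):
        matrix = np.array([[1.0, 0.5, -0.2],
                           [0.5, 1.0, 0.1],
                           [-0.2, 0.1, 1.0]])
        dccm = DCCMatrix(matrix=matrix, residue_ids=np.array([1, 2, 3]))
        dmap = ek.domain_map_from_dict({"A": [[1, 2]], "B": [[3, 3]]})
        scores = ek.residue_scores(dccm, dmap)
        assert scores.cs_total(1) == pytest.approx(0.3)
        assert scores.cs_intra(1) == pytest.approx(0.5)
        assert scores.cs_inter(1, "B") == pytest.approx(-0.2)

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_triple_loop_oracle(self, trial):
        """Scores equal an O(N²·D) brute-force loop over residue pairs."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(6, 61))
        dccm = random_dccm(rng, n)
        dmap = random_domain_map(rng, n)
        scores = ek.residue_scores(dccm, dmap)
        res_ids = dccm.residue_ids
        for i, ri in enumerate(res_ids):
            total = intra = 0.0
            inter = {name: 0.0 for name in dmap.names}
            for j, rj in enumerate(res_ids):
                if i == j:
                    continue
                total += dccm.matrix[i, j]
                if dmap.domain_of(rj) == dmap.domain_of(ri):
                    intra += dccm.matrix[i, j]
                else:
                    inter[dmap.domain_of(rj)] += dccm.matrix[i, j]
            assert scores.cs_total(ri) == pytest.approx(total, abs=1e-12)
            assert scores.cs_intra(ri) == pytest.approx(intra, abs=1e-12)
            for name in dmap.names:
                if name != dmap.domain_of(ri):
                    assert scores.cs_inter(ri, name) == pytest.approx(
                        inter[name], abs=1e-12)

    def test_decomposition_identity(self, rng):
        """cs_intra + Σ_b cs_inter[b] = cs_total for covered residues."""
        n = 40
        dccm = random_dccm(rng, n)
        dmap = random_domain_map(rng, n)
        scores = ek.residue_scores(dccm, dmap)
        t = scores.table
        inter_cols = [c for c in t.columns if c.startswith("inter:")]
        recomposed = t["cs_intra"].fillna(0) + t[inter_cols].sum(
            axis=1, skipna=True)
        np.testing.assert_allclose(recomposed, t["cs_total"], atol=1e-10)


class TestDomainScoreMatrix:
    def test_matches_block_sum_oracle(self, rng):
        n = 30
        dccm = random_dccm(rng, n)
        dmap = random_domain_map(rng, n)
        scores = ek.residue_scores(dccm, dmap)
        dsm = ek.domain_score_matrix(scores, dmap)
        names = dmap.names
        for a, na in enumerate(names):
            ra = [i for i, r in enumerate(dccm.residue_ids)
                  if dmap.domain_of(r) == na]
            for b, nb in enumerate(names):
                rb = [i for i, r in enumerate(dccm.residue_ids)
                      if dmap.domain_of(r) == nb]
                brute = sum(dccm.matrix[i, j] for i in ra for j in rb if i != j)
                assert dsm.matrix[a, b] == pytest.approx(brute, abs=1e-10)
        assert np.abs(dsm.matrix - dsm.matrix.T).max() <= 1e-10

    def test_per_pair_normalization(self, rng):
        n = 20
        dccm = random_dccm(rng, n)
        dmap = ek.domain_map_from_dict({"A": [[1, 12]], "B": [[13, 20]]})
        scores = ek.residue_scores(dccm, dmap)
        raw = ek.domain_score_matrix(scores, dmap, normalization="raw-sum")
        per = ek.domain_score_matrix(scores, dmap,
                                     normalization="per-residue-pair")
        assert per.matrix[0, 1] == pytest.approx(raw.matrix[0, 1] / (12 * 8))
        assert per.matrix[0, 0] == pytest.approx(raw.matrix[0, 0] / (12 * 11))

    def test_single_residue_domains_reduce_to_dccm(self):
        n = 4
        rng = np.random.default_rng(3)
        dccm = random_dccm(rng, n)
        dmap = ek.domain_map_from_dict({f"R{i}": [[i, i]]
                                        for i in range(1, n + 1)})
        scores = ek.residue_scores(dccm, dmap)
        dsm = ek.domain_score_matrix(scores, dmap)
        off = ~np.eye(n, dtype=bool)
        np.testing.assert_allclose(dsm.matrix[off], dccm.matrix[off],
                                   atol=1e-12)
        np.testing.assert_allclose(np.diag(dsm.matrix), 0.0, atol=1e-12)


class TestDccmDifference:
    def test_self_difference_zero_and_antisymmetry(self, rng):
        d1 = random_dccm(rng, 10)
        d2 = random_dccm(rng, 10)
        assert np.abs(ek.dccm_difference(d1, d1).matrix).max() == 0.0
        ab = ek.dccm_difference(d1, d2).matrix
        ba = ek.dccm_difference(d2, d1).matrix
        np.testing.assert_array_equal(ab, -ba)
        assert np.abs(ab).max() <= 2.0

    def test_mismatched_residues_rejected(self, rng):
        d1 = random_dccm(rng, 10)
        d2 = random_dccm(rng, 11)
        with pytest.raises(ValueError):
            ek.dccm_difference(d1, d2)

    def test_planted_sign_flip_difference(self, helix_ca_50):
        """+0.5 vs −0.5 planted coupling differs by ≈1.0 between blocks."""
        specs = []
        for r12 in (0.5, -0.5):
            specs.append(ek.FactorModelSpec(
                residues_per_domain=(25, 25),
                factor_correlation=np.array([[1.0, r12], [r12, 1.0]]),
                n_frames=5000, seed=77))
        dccms = []
        for spec in specs:
            traj, _ = ek.sample_ensemble(spec, helix_ca_50)
            dccms.append(ek.compute_dccm(
                ek.build_covariance(traj, superpose=False)))
        diff = ek.dccm_difference(dccms[0], dccms[1])
        inter = diff.matrix[:25, 25:]
        assert abs(inter.mean() - 1.0) <= 0.07
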