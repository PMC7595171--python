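"""Superposition, PCA, subvectors, order parameters, and classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import nsh2kit as nk
from nsh2kit.analysis import superpose
from nsh2kit.ensembles import SelectionSpec, StructureEnsemble


def _rotate_frame(ens, seed=0, translate=(0.5, -0.2, 0.1)):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng)
    coords = ens.coordinates[0] @ rot.as_matrix().T + np.asarray(translate)
    return ens.with_coordinates(coords[None])


class TestSuperpose:
    def test_identity(self, two_state_clean):
        ref = two_state_clean.alpha_reference
        fitted, rmsd = superpose(ref, ref, nk.core_fit_selection())
        assert rmsd[0] == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(fitted.coordinates, ref.coordinates, atol=1e-12)

    def test_removes_rigid_motion(self, two_state_clean):
        ref = two_state_clean.alpha_reference
        moved = _rotate_frame(ref, seed=1)
        fitted, rmsd = superpose(moved, ref, nk.core_fit_selection())
        assert rmsd[0] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(fitted.coordinates, ref.coordinates, atol=1e-9)

    def test_matches_independent_kabsch_oracle(self, two_state_clean):
        """RMSD after noisy fitting matches scipy's independent Kabsch
        (Rotation.align_vectors) to 1e-6 A."""
        ref = two_state_clean.alpha_reference
        rng = np.random.default_rng(2)
        noisy = ref.with_coordinates(
            (ref.coordinates[0] + 0.05 * rng.standard_normal(
                ref.coordinates[0].shape))[None]
        )
        sel = nk.core_fit_selection()
        _, rmsd = superpose(noisy, ref, sel)
        idx = sel.resolve(ref)
        p = noisy.coordinates[0, idx] - noisy.coordinates[0, idx].mean(axis=0)
        q = ref.coordinates[0, idx] - ref.coordinates[0, idx].mean(axis=0)
        _, oracle_rssd = Rotation.align_vectors(q, p)
        oracle_rmsd = 10.0 * oracle_rssd / np.sqrt(len(idx))
        assert rmsd[0] == pytest.approx(oracle_rmsd, abs=1e-6)

    def test_idempotent(self, two_state_noisy):
        ens = two_state_noisy.ensemble
        ref = two_state_noisy.alpha_reference
        once, _ = superpose(ens, ref, nk.core_fit_selection())
        twice, _ = superpose(once, ref, nk.core_fit_selection())
        assert np.max(np.abs(twice.coordinates - once.coordinates)) < 1e-9

    def test_degenerate_selection_rejected(self):
        coords = np.zeros((1, 4, 3))
        coords[0, :, 0] = [0, 1, 2, 3]  # collinear
        ens = StructureEnsemble(coords, [1, 2, 3, 4], ["ALA"] * 4, ["CA"] * 4)
        with pytest.raises(ValueError, match="collinear"):
            superpose(ens, ens, SelectionSpec(((1, 4),), atom_names=None))


class TestPca:
    def test_two_frames_single_mode(self, two_state_clean):
        res = two_state_clean
        pair = StructureEnsemble(
            np.stack([res.alpha_reference.coordinates[0],
                      res.beta_reference.coordinates[0]]),
            res.ensemble.residue_numbers, res.ensemble.residue_names,
            res.ensemble.atom_names,
        )
        cvs = nk.pca(pair, nk.analysis_selection(), n_vectors=5)
        assert cvs[0].eigenvalue > 0
        assert all(cv.eigenvalue < 1e-20 for cv in cvs[1:])
        idx = nk.analysis_selection().resolve(pair)
        diff = pair.coordinates[1, idx] - pair.coordinates[0, idx]
        diff /= np.linalg.norm(diff)
        assert abs(np.sum(cvs[0].vector * diff)) == pytest.approx(1.0, abs=1e-10)

    def test_recovers_generator_mode(self):
        res = nk.build_two_state_ensemble(500, 0.5, noise_sd=0.1, seed=33)
        ens, _ = superpose(res.ensemble, res.alpha_reference,
                           nk.core_fit_selection())
        cv = nk.pca(ens, nk.analysis_selection())[0]
        idx = nk.analysis_selection().resolve(ens)
        mode = res.mode[idx]
        mode /= np.linalg.norm(mode)
        assert abs(np.sum(cv.vector * mode)) > 0.99

    def test_variance_fractions_sum_to_one(self, two_state_noisy):
        sub = two_state_noisy.ensemble
        small = StructureEnsemble(
            sub.coordinates[:30], sub.residue_numbers, sub.residue_names,
            sub.atom_names,
        )
        cvs = nk.pca(small, nk.analysis_selection(), n_vectors=10**6)
        assert sum(cv.variance_fraction for cv in cvs) == pytest.approx(1.0, abs=1e-8)
        eigs = [cv.eigenvalue for cv in cvs]
        assert all(a >= b - 1e-15 for a, b in zip(eigs, eigs[1:]))

    def test_vectors_orthonormal(self, two_state_noisy):
        cvs = nk.pca(two_state_noisy.ensemble, nk.analysis_selection(),
                     fit_selection=nk.core_fit_selection(), n_vectors=4)
        mat = np.stack([cv.vector.ravel() for cv in cvs])
        np.testing.assert_allclose(mat @ mat.T, np.eye(4), atol=1e-10)

    def test_single_frame_rejected(self, two_state_clean):
        with pytest.raises(ValueError):
            nk.pca(two_state_clean.alpha_reference, nk.analysis_selection())


class TestProjection:
    def test_mean_projects_to_zero_and_unit_step(self, two_state_noisy):
        ens, _ = superpose(two_state_noisy.ensemble,
                           two_state_noisy.alpha_reference,
                           nk.core_fit_selection())
        cv = nk.pca(ens, nk.analysis_selection())[0]
        idx = cv.resolve_indices(ens)
        mean_frame = ens.coordinates[0].copy()
        mean_frame[idx] = cv.mean_structure
        base = ens.with_coordinates(mean_frame[None])
        assert nk.project(base, cv)[0] == pytest.approx(0.0, abs=1e-12)
        stepped = mean_frame.copy()
        stepped[idx] += 0.1 * cv.vector
        assert nk.project(ens.with_coordinates(stepped[None]), cv)[0] == (
            pytest.approx(0.1, abs=1e-12)
        )

    def test_projection_variance_equals_eigenvalue(self, two_state_noisy):
        ens, _ = superpose(two_state_noisy.ensemble,
                           two_state_noisy.alpha_reference,
                           nk.core_fit_selection())
        cv = nk.pca(ens, nk.analysis_selection())[0]
        eta = nk.project(ens, cv)
        assert np.var(eta, ddof=1) == pytest.approx(cv.eigenvalue, rel=1e-8)


class TestSubvector:
    def test_full_selection_returns_parent(self, two_state_noisy):
        ens, _ = superpose(two_state_noisy.ensemble,
                           two_state_noisy.alpha_reference,
                           nk.core_fit_selection())
        cv = nk.pca(ens, nk.analysis_selection())[0]
        sub = nk.subvector(cv, ens, nk.analysis_selection())
        assert abs(np.sum(sub.vector * cv.vector)) == pytest.approx(1.0, abs=1e-10)

    def test_equals_normalized_restriction(self, two_state_noisy):
        ens, _ = superpose(two_state_noisy.ensemble,
                           two_state_noisy.alpha_reference,
                           nk.core_fit_selection())
        cv = nk.pca(ens, nk.analysis_selection())[0]
        for sel in (nk.py_loop_selection(), nk.plus5_selection()):
            sub = nk.subvector(cv, ens, sel)
            sub_idx = sel.resolve(ens)
            cv_idx = cv.resolve_indices(ens)
            pos = {int(a): i for i, a in enumerate(cv_idx)}
            restriction = cv.vector[[pos[int(a)] for a in sub_idx]]
            restriction = restriction / np.linalg.norm(restriction)
            assert abs(np.sum(sub.vector * restriction)) >= 0.999

    def test_zero_restriction_rejected(self, two_state_noisy):
        """A mode that moves only +5-site atoms has no pY-loop subvector."""
        ens, _ = superpose(two_state_noisy.ensemble,
                           two_state_noisy.alpha_reference,
                           nk.core_fit_selection())
        cv = nk.pca(ens, nk.analysis_selection())[0]
        plus5_idx = nk.plus5_selection().resolve(ens)
        cv_idx = cv.resolve_indices(ens)
        mask = np.isin(cv_idx, plus5_idx)
        vec = np.zeros_like(cv.vector)
        vec[mask] = cv.vector[mask]
        vec /= np.linalg.norm(vec)
        cv_plus5_only = nk.CollectiveVector(
            mean_structure=cv.mean_structure, vector=vec,
            eigenvalue=cv.eigenvalue, variance_fraction=cv.variance_fraction,
            residue_numbers=cv.residue_numbers, atom_names=cv.atom_names,
        )
        with pytest.raises(ValueError, match="no weight"):
            nk.subvector(cv_plus5_only, ens, nk.py_loop_selection())


class TestOrderParametersAndPearson:
    def test_missing_anchor_names_atom(self, two_state_clean):
        ens = two_state_clean.alpha_reference
        keep = ~((ens.residue_numbers == 58) & (ens.atom_names == "N"))
        trimmed = StructureEnsemble(
            ens.coordinates[:, keep, :], ens.residue_numbers[keep],
            ens.residue_names[keep], ens.atom_names[keep],
        )
        with pytest.raises(KeyError, match="N of residue 58"):
            nk.order_parameters(trimmed)

    def test_pearson_exact_cases(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert nk.pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert nk.pearson(x, -x) == pytest.approx(-1.0)
        # by definition: sum(dx*dy)=5.5, sum(dx^2)=5, sum(dy^2)=8.75
        assert nk.pearson(x, [1, 3, 2, 5]) == pytest.approx(5.5 / np.sqrt(43.75))

    def test_pearson_preconditions(self):
        with pytest.raises(ValueError):
            nk.pearson([1, 2], [3, 4])
        with pytest.raises(ValueError):
            nk.pearson([1, 1, 1], [1, 2, 3])

    def test_coupling_sign_structure(self, two_state_noisy):
        """Sheet spread anticorrelates with pY opening; pY opening correlates
        positively with +5 opening — the default coupling mode."""
        ops = nk.order_parameters(two_state_noisy.ensemble)
        assert nk.pearson(ops.sheet, ops.pY) < 0
        assert nk.pearson(ops.pY, ops.plus5) > 0

    def test_flipped_coupling_mode(self):
        res = nk.build_two_state_ensemble(
            500, 0.5, coupling_mode={"py_vs_plus5": -1}, noise_sd=0.2, seed=4
        )
        ops = nk.order_parameters(res.ensemble)
        assert nk.pearson(ops.pY, ops.plus5) < 0
        assert nk.pearson(ops.sheet, ops.pY) < 0


class TestClassification:
    def test_reference_frames(self, two_state_clean):
        assert nk.classify_states(
            nk.order_parameters(two_state_clean.alpha_reference)
        ).labels[0] == "alpha"
        assert nk.classify_states(
            nk.order_parameters(two_state_clean.beta_reference)
        ).labels[0] == "beta"

    def test_recovers_generator_labels(self, two_state_noisy):
        cls = nk.classify_states(nk.order_parameters(two_state_noisy.ensemble))
        accuracy = np.mean(cls.labels == two_state_noisy.labels)
        assert accuracy >= 0.98
        assert cls.alpha_fraction == pytest.approx(0.7, abs=0.05)
        lo, hi = cls.fractions["alpha"][1:]
        assert lo < cls.alpha_fraction < hi

    def test_projection_mode_agrees_with_order_parameters(self, two_state_noisy):
        ens, _ = superpose(two_state_noisy.ensemble,
                           two_state_noisy.alpha_reference,
                           nk.core_fit_selection())
        cv = nk.pca(ens, nk.analysis_selection())[0]
        sub_py = nk.subvector(cv, ens, nk.py_loop_selection())
        sub_p5 = nk.subvector(cv, ens, nk.plus5_selection())
        proj_cls = nk.classify_by_projection(
            ens, sub_py, sub_p5,
            two_state_noisy.alpha_reference, two_state_noisy.beta_reference,
        )
        accuracy = np.mean(proj_cls.labels == two_state_noisy.labels)
        assert accuracy >= 0.95

    def test_out_of_range_threshold_logged(self, two_state_clean):
        ops = nk.order_parameters(two_state_clean.alpha_reference)
        cls = nk.classify_states(ops, thresholds={"pY": 99.0})
        assert any("outside the data range" in msg for msg in cls.log)
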