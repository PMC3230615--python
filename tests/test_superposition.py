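import numpy as np
import pytest

from conftest import family_from_arrays, random_ungapped_family
from oracles import quaternion_fit_rmsd, quaternion_generalized_procrustes
from spca.superposition import (
    RigidTransform,
    generalized_superpose,
    kabsch_fit,
    refine_on_conservative,
)


def random_rigid(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return RigidTransform(rotation=rot, translation=rng.uniform(-10, 10, 3))


class TestKabsch:
    def test_identity_when_already_fitted(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        tf, rmsd = kabsch_fit(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-9)

    def test_exact_rigid_recovery(self):
        target = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 1]])
        rot90 = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        mobile = target @ rot90.T + np.array([1.0, 2.0, 3.0])
        tf, rmsd = kabsch_fit(mobile, target)
        assert rmsd < 1e-9
        np.testing.assert_allclose(tf.apply(mobile), target, atol=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_rmsd_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mobile = rng.normal(size=(5, 3))
        target = rng.normal(size=(5, 3))
        _, rmsd = kabsch_fit(mobile, target)
        assert rmsd == pytest.approx(quaternion_fit_rmsd(mobile, target), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_rmsd_invariant_under_common_rigid_motion(self, seed):
        rng = np.random.default_rng(100 + seed)
        mobile = rng.normal(size=(6, 3))
        target = rng.normal(size=(6, 3))
        _, rmsd = kabsch_fit(mobile, target)
        tf = random_rigid(rng)
        _, rmsd2 = kabsch_fit(tf.apply(mobile), tf.apply(target))
        assert rmsd2 == pytest.approx(rmsd, abs=1e-9)

    def test_proper_rotation_even_for_reflected_input(self):
        rng = np.random.default_rng(0)
        mobile = rng.normal(size=(10, 3))
        target = mobile * np.array([1.0, 1.0, -1.0])  # mirror image
        tf, _ = kabsch_fit(mobile, target)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch_fit(line, line)
        with pytest.raises(ValueError, match="3 points"):
            kabsch_fit(line[:2], line[:2])

    def test_weighted_fit_prefers_heavy_points(self):
        mobile = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        target = mobile.copy()
        target[3] += [0.0, 0.0, 2.0]  # outlier at the light point
        w = np.array([1.0, 1.0, 1.0, 1e-9])
        tf, _ = kabsch_fit(mobile, target, weights=w)
        np.testing.assert_allclose(tf.apply(mobile)[:3], target[:3], atol=1e-4)

    def test_transform_inverse_is_identity(self):
        rng = np.random.default_rng(5)
        tf = random_rigid(rng)
        pts = rng.normal(size=(7, 3))
        np.testing.assert_allclose(tf.inverse().apply(tf.apply(pts)), pts, atol=1e-9)


def rigid_copies_family(rng, n=8, length=10):
    """N rigid copies of a single random structure (no internal noise)."""
    base = rng.normal(size=(length, 3)) * 3.0
    alpha = np.empty((n, length, 3))
    for i in range(n):
        alpha[i] = random_rigid(rng).apply(base)
    letters = np.full((n, length), "A")
    return family_from_arrays(letters, alpha), base


class TestGeneralizedSuperpose:
    def test_rigid_family_collapses_to_zero_scatter(self):
        rng = np.random.default_rng(11)
        fam, _ = rigid_copies_family(rng, n=8, length=10)
        out, report = generalized_superpose(fam)
        mean = out.alpha.mean(axis=0)
        scatter = np.sqrt(((out.alpha - mean) ** 2).sum(axis=2).mean())
        assert scatter < 1e-6
        assert report.converged

    def test_single_protein_returned_unchanged(self):
        fam = family_from_arrays(
            [["A", "A", "A"]], np.arange(9, dtype=float).reshape(1, 3, 3)
        )
        out, report = generalized_superpose(fam)
        assert report.iterations == 1
        np.testing.assert_array_equal(out.alpha, fam.alpha)

    def test_mean_matches_long_iteration_oracle(self):
        rng = np.random.default_rng(42)
        fam, _ = rigid_copies_family(rng, n=5, length=8)
        fam.alpha += rng.normal(scale=0.05, size=fam.alpha.shape)
        fam.mass_center = fam.alpha.copy()
        out, _ = generalized_superpose(fam, tol=1e-12, max_iter=500)
        ours = out.alpha.mean(axis=0)
        oracle_mean = quaternion_generalized_procrustes(fam.alpha.copy(), n_iter=200)
        # both means live in an arbitrary common frame: superpose them
        assert quaternion_fit_rmsd(ours, oracle_mean) < 1e-6

    def test_rmsd_trace_non_increasing(self):
        rng = np.random.default_rng(13)
        fam, _ = rigid_copies_family(rng, n=6, length=9)
        fam.alpha += rng.normal(scale=0.3, size=fam.alpha.shape)
        fam.mass_center = fam.alpha.copy()
        _, report = generalized_superpose(fam)
        trace = np.array(report.rmsd_trace)
        assert (np.diff(trace) <= 1e-9).all()

    def test_internal_geometry_preserved(self):
        rng = np.random.default_rng(17)
        fam, _ = rigid_copies_family(rng, n=4, length=7)
        before = fam.alpha.copy()
        out, _ = generalized_superpose(fam)
        for i in range(fam.n_proteins):
            d0 = np.linalg.norm(before[i][:, None] - before[i][None, :], axis=2)
            d1 = np.linalg.norm(out.alpha[i][:, None] - out.alpha[i][None, :], axis=2)
            np.testing.assert_allclose(d1, d0, atol=1e-9)
        assert (out.gap_mask == fam.gap_mask).all()
        assert (out.sequences == fam.sequences).all()

    def test_gap_cells_ignored_and_preserved(self):
        rng = np.random.default_rng(23)
        fam, _ = rigid_copies_family(rng, n=5, length=8)
        fam.sequences[0, 2] = "-"
        fam.alpha[0, 2] = np.nan
        fam.mass_center[0, 2] = np.nan
        out, _ = generalized_superpose(fam, tol=1e-12, max_iter=500)
        assert np.isnan(out.alpha[0, 2]).all()
        mean = np.nanmean(out.alpha, axis=0)
        scatter = np.sqrt(np.nanmean(((out.alpha - mean) ** 2).sum(axis=2)))
        assert scatter < 1e-6

    def test_too_few_usable_columns_rejected(self):
        fam = family_from_arrays(
            [["A", "A"], ["A", "A"]], np.zeros((2, 2, 3))
        )
        with pytest.raises(ValueError, match="usable columns"):
            generalized_superpose(fam)


class TestRefineOnConservative:
    def test_conservative_columns_collapse(self):
        rng = np.random.default_rng(31)
        n, length = 6, 10
        base = rng.normal(size=(length, 3)) * 3.0
        cons = np.array([0, 3, 5, 8])
        alpha = np.empty((n, length, 3))
        for i in range(n):
            noisy = base.copy()
            others = np.setdiff1d(np.arange(length), cons)
            noisy[others] += rng.normal(scale=1.0, size=(others.size, 3))
            alpha[i] = random_rigid(rng).apply(noisy)
        fam = family_from_arrays(np.full((n, length), "A"), alpha)
        out, _ = refine_on_conservative(fam, cons, tol=1e-10, max_iter=300)
        mean = out.alpha[:, cons].mean(axis=0)
        scatter = np.sqrt(((out.alpha[:, cons] - mean) ** 2).sum(axis=2).mean())
        assert scatter < 1e-6

    def test_all_columns_equals_unmasked_run(self):
        rng = np.random.default_rng(37)
        fam, _ = rigid_copies_family(rng, n=5, length=8)
        fam.alpha += rng.normal(scale=0.1, size=fam.alpha.shape)
        fam.mass_center = fam.alpha.copy()
        a, _ = refine_on_conservative(fam, np.arange(fam.length))
        b, _ = generalized_superpose(fam)
        np.testing.assert_allclose(a.alpha, b.alpha, atol=1e-12)

    def test_refinement_never_worsens_conservative_rmsd(self):
        rng = np.random.default_rng(41)
        n, length = 8, 12
        base = rng.normal(size=(length, 3)) * 3.0
        cons = np.array([1, 4, 7, 10])
        alpha = np.empty((n, length, 3))
        for i in range(n):
            noisy = base.copy()
            others = np.setdiff1d(np.arange(length), cons)
            noisy[others] += rng.normal(scale=0.8, size=(others.size, 3))
            alpha[i] = noisy
        fam = family_from_arrays(np.full((n, length), "A"), alpha)
        first, _ = generalized_superpose(fam)

        def cons_rmsd(f):
            mean = f.alpha[:, cons].mean(axis=0)
            return np.sqrt(((f.alpha[:, cons] - mean) ** 2).sum(axis=2).mean())

        before = cons_rmsd(first)
        refined, _ = refine_on_conservative(first, cons)
        assert cons_rmsd(refined) <= before + 1e-9

    def test_empty_conservative_set_rejected(self):
        fam = family_from_arrays([["A", "A", "A"]], np.zeros((1, 3, 3)))
        with pytest.raises(ValueError):
            refine_on_conservative(fam, np.array([], dtype=int))
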