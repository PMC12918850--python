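"""Superposition engine and all-window RMSD: oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from fibrilfold import (
    correspond_by_numbering,
    kabsch_superpose,
    localized_rmsd,
    make_serpentine_rung,
    perturb_region,
    rank_folds,
    region_rmsd,
    render_heatmap,
    window_rmsd_matrix,
)
from fibrilfold.rmsd import WindowRMSDMatrix
from tests.conftest import make_chain, random_chain


def rotation_grid_rmsd(X, Y, n_grid=3000, seed=0):
    """Independent oracle: minimum RMSD over rigid motions by quaternion
    grid search refined locally (no SVD)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    def cost_rotvec(v):
        R = Rotation.from_rotvec(v).as_matrix()
        return np.sqrt(((Xc - Yc @ R.T) ** 2).sum() / len(X))

    rng = np.random.RandomState(seed)
    candidates = Rotation.random(n_grid, random_state=rng)
    costs = [cost_rotvec(r.as_rotvec()) for r in candidates]
    best = candidates[int(np.argmin(costs))].as_rotvec()
    res = minimize(cost_rotvec, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return float(res.fun)


def scipy_window_rmsd(X, Y):
    """Second independent route: scipy's Kabsch (align_vectors rssd)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    _, rssd = Rotation.align_vectors(Xc, Yc)
    return float(rssd / np.sqrt(len(X)))


class TestKabsch:
    def test_identical_sets_zero(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(X, X)
        assert rmsd <= 1e-12
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, np.zeros(3), atol=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        R0 = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        Y = X @ R0.T + np.array([5.0, -3.0, 2.0])
        _, _, rmsd = kabsch_superpose(X, Y)
        assert rmsd <= 1e-9

    def test_matches_quaternion_grid_oracle(self):
        """Fixed 4-point sets: SVD optimum equals a grid-search-plus-refine
        optimum over rotations to 1e-4 Å."""
        X = np.array([[0.0, 0, 0], [3.8, 0, 0], [3.8, 4.8, 0], [0, 4.8, 1.0]])
        Y = np.array([[0.2, 0, 0.1], [3.5, 0.4, 0], [4.0, 4.5, -0.3], [0, 5.0, 0.9]])
        _, _, rmsd = kabsch_superpose(X, Y)
        oracle = rotation_grid_rmsd(X, Y)
        assert rmsd == pytest.approx(oracle, abs=1e-4)
        assert rmsd <= oracle + 1e-9  # SVD result is the global optimum

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        X, Y = rng.normal(size=(15, 3)), rng.normal(size=(15, 3))
        _, _, fwd = kabsch_superpose(X, Y)
        _, _, rev = kabsch_superpose(Y, X)
        assert fwd == pytest.approx(rev, abs=1e-9)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            X, Y = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
            R, _, _ = kabsch_superpose(X, Y)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_mirror_image_not_scored_as_identical(self):
        """Reflections are excluded: a mirrored chiral set keeps RMSD > 0."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 3))
        Y = X * np.array([1.0, 1.0, -1.0])  # reflection
        _, _, rmsd = kabsch_superpose(X, Y)
        assert rmsd > 0.1

    def test_degenerate_collinear_points_still_optimal(self):
        X = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        Y = np.array([[0.0, 0, 0], [0, 1, 0], [0, 2, 0], [0, 3, 0]])
        _, _, rmsd = kabsch_superpose(X, Y)
        assert rmsd <= 1e-9  # rotation about the line aligns them exactly

    def test_single_point(self):
        R, t, rmsd = kabsch_superpose(np.array([[1.0, 2, 3]]), np.array([[4.0, 5, 6]]))
        assert rmsd <= 1e-12

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.empty((0, 3)), np.empty((0, 3)))

    @given(n=st.integers(3, 25), seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_rigid_invariance_property(self, n, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        R0 = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        Y = X @ R0.T + rng.normal(size=3) * 10
        _, _, rmsd = kabsch_superpose(X, Y)
        assert rmsd <= 1e-9


class TestWindowMatrix:
    def test_self_comparison_all_zero(self, rung):
        m = window_rmsd_matrix(rung, rung)
        assert np.all(m.values() <= 1e-9)
        assert localized_rmsd(m) <= 1e-9

    def test_entry_count_formula(self, small_rung):
        m = window_rmsd_matrix(small_rung, small_rung, min_window=3)
        L, w = len(small_rung), 3
        assert len(m) == (L - w + 1) * (L - w + 2) // 2

    def test_entry_count_with_segments(self):
        """Windows never span a correspondence gap, so counts add per segment."""
        a = make_serpentine_rung(n_residues=30, start_res=1)
        kept = [r for r in a.residues if not (11 <= r.number <= 15)]
        from fibrilfold.structure import ResidueChain

        b = ResidueChain("B", kept)
        m = window_rmsd_matrix(a, b, min_window=3)
        expected = sum(
            (L - 3 + 1) * (L - 3 + 2) // 2 for L in (10, 15)
        )
        assert len(m) == expected

    def test_symmetry_a_b(self, small_rung):
        bumped = perturb_region(small_rung, (5, 15), 2.0, seed=7)
        fwd = window_rmsd_matrix(small_rung, bumped)
        rev = window_rmsd_matrix(bumped, small_rung)
        for key, value in fwd.entries.items():
            assert rev.entries[key] == pytest.approx(value, abs=1e-9)

    def test_rigid_motion_changes_nothing(self, small_rung):
        moved = rotate_chain(small_rung, angle_deg=73.0, shift=(4.0, -2.0, 9.0))
        base = window_rmsd_matrix(small_rung, small_rung)
        vs_moved = window_rmsd_matrix(small_rung, moved)
        for key in base.entries:
            assert abs(base.entries[key] - vs_moved.entries[key]) <= 1e-9

    def test_entries_match_independent_oracle(self, small_rung):
        """Every window entry equals scipy's independent Kabsch route."""
        bumped = perturb_region(small_rung, (8, 18), 1.5, seed=11)
        corr = correspond_by_numbering(small_rung, bumped)
        m = window_rmsd_matrix(small_rung, bumped, corr)
        Xall = small_rung.ca_coords()
        Yall = bumped.ca_coords()
        for (start, length), value in m.entries.items():
            X = Xall[start : start + length]
            Y = Yall[start : start + length]
            assert value == pytest.approx(scipy_window_rmsd(X, Y), abs=1e-8)

    def test_optimality_nesting(self, small_rung):
        """A sub-window's own optimal RMSD never exceeds its residual under
        the enclosing window's superposition."""
        rng = np.random.default_rng(13)
        noisy = make_chain(
            small_rung.ca_coords() + rng.normal(0, 0.8, (len(small_rung), 3)),
            start=1, chain_id="B",
        )
        X = small_rung.ca_coords()
        Y = noisy.ca_coords()
        m = window_rmsd_matrix(small_rung, noisy)
        big_start, big_len = 0, len(small_rung)
        R, t, _ = kabsch_superpose(X, Y)
        Yfit = Y @ R.T + t
        for (start, length), opt in m.entries.items():
            inherited = np.sqrt(
                ((X[start : start + length] - Yfit[start : start + length]) ** 2)
                .sum() / length
            )
            assert opt <= inherited + 1e-9

    def test_localized_bump_elevates_only_overlapping_windows(self, rung):
        """A 3 Å bump on residues 313-333 leaves windows wholly outside it at
        zero and raises windows covering it."""
        bumped = perturb_region(rung, (313, 333), 3.0, seed=5)
        corr = correspond_by_numbering(rung, bumped)
        m = window_rmsd_matrix(rung, bumped, corr)
        numbers = corr.numbers_a()
        lo = np.searchsorted(numbers, 313)
        hi = np.searchsorted(numbers, 333, side="right") - 1
        for (start, length), value in m.entries.items():
            end = start + length - 1
            if end < lo or start > hi:
                assert value <= 1e-6, (start, length)
        inside = [
            v for (s, L), v in m.entries.items() if s <= lo and s + L - 1 >= hi
        ]
        assert inside and min(inside) > 0.5

    def test_all_segments_too_short_warns_empty(self):
        a = make_serpentine_rung(n_residues=8, start_res=1)
        b_nums = [1, 2, 5, 6]  # segments of length 2 < min_window
        from tests.test_align import chain_from_numbers

        b = chain_from_numbers(b_nums, chain_id="B")
        corr = correspond_by_numbering(a, b)
        with pytest.warns(UserWarning, match="min_window"):
            m = window_rmsd_matrix(a, b, corr)
        assert len(m) == 0
        with pytest.raises(ValueError, match="no admissible windows"):
            localized_rmsd(m)


def rotate_chain(chain, angle_deg, shift):
    from fibrilfold.structure import Residue, ResidueChain

    R = Rotation.from_euler("xyz", [angle_deg, 10.0, -20.0], degrees=True).as_matrix()
    shift = np.asarray(shift, float)
    residues = [
        Residue(r.number, r.aa, {k: R @ v + shift for k, v in r.atoms.items()})
        for r in chain.residues
    ]
    return ResidueChain(chain.chain_id, residues)


class TestLocalizedRMSD:
    def test_mean_of_entries(self):
        m = WindowRMSDMatrix(
            id_a="a", id_b="b",
            entries={(0, 3): 1.0, (1, 3): 3.0},
            min_window=3, atom_set=("CA",),
            start_numbers_a=np.arange(1, 6), start_numbers_b=np.arange(1, 6),
        )
        assert localized_rmsd(m) == pytest.approx(2.0)

    def test_monotone_under_entrywise_increase(self, small_rung):
        bumped = perturb_region(small_rung, (5, 20), 1.0, seed=3)
        m = window_rmsd_matrix(small_rung, bumped)
        raised = WindowRMSDMatrix(
            id_a=m.id_a, id_b=m.id_b,
            entries={k: v + 0.25 for k, v in m.entries.items()},
            min_window=m.min_window, atom_set=m.atom_set,
            start_numbers_a=m.start_numbers_a, start_numbers_b=m.start_numbers_b,
        )
        assert localized_rmsd(raised) > localized_rmsd(m)

    def test_brute_force_mean(self, small_rung):
        bumped = perturb_region(small_rung, (3, 12), 0.7, seed=9)
        corr = correspond_by_numbering(small_rung, bumped)
        m = window_rmsd_matrix(small_rung, bumped, corr)
        X, Y = small_rung.ca_coords(), bumped.ca_coords()
        naive = []
        n = len(small_rung)
        for length in range(3, n + 1):
            for start in range(0, n - length + 1):
                naive.append(scipy_window_rmsd(X[start:start + length],
                                               Y[start:start + length]))
        assert localized_rmsd(m) == pytest.approx(float(np.mean(naive)), abs=1e-8)


class TestRegionRMSD:
    def test_self_zero(self, rung):
        assert region_rmsd(rung, rung, start_res=290, end_res=311) <= 1e-9

    def test_unpaired_residue_named_in_error(self):
        from tests.test_align import chain_from_numbers

        a = chain_from_numbers(range(1, 21))
        b = chain_from_numbers([n for n in range(1, 21) if n != 10], chain_id="B")
        with pytest.raises(ValueError, match=r"\[10\]"):
            region_rmsd(a, b, start_res=5, end_res=15)

    def test_localized_region_value(self, rung):
        bumped = perturb_region(rung, (313, 333), 3.0, seed=5)
        clean = region_rmsd(rung, bumped, start_res=273, end_res=310)
        hot = region_rmsd(rung, bumped, start_res=313, end_res=333)
        assert clean <= 1e-9
        assert hot > 0.5


class TestRankFolds:
    def test_query_in_library_ranks_first_with_zero(self, rung):
        library = {
            "self": rung,
            "bumped": perturb_region(rung, (300, 340), 2.0, seed=1),
        }
        ranked = rank_folds(rung, library)
        assert ranked[0].label == "self"
        assert ranked[0].localized_rmsd <= 1e-9
        assert ranked[1].localized_rmsd > ranked[0].localized_rmsd

    def test_ordering_matches_perturbation_size(self, rung):
        library = {
            "big": perturb_region(rung, (300, 340), 4.0, seed=2),
            "small": perturb_region(rung, (300, 340), 0.5, seed=2),
            "medium": perturb_region(rung, (300, 340), 2.0, seed=2),
        }
        ranked = rank_folds(rung, library)
        assert [r.label for r in ranked] == ["small", "medium", "big"]

    def test_identical_copies_tie_break_by_label(self, rung):
        library = {"zeta": rung, "alpha": rung}
        ranked = rank_folds(rung, library)
        assert [r.label for r in ranked] == ["alpha", "zeta"]

    def test_incomparable_member_reported_not_dropped(self, rung):
        from tests.test_align import chain_from_numbers

        stranger = chain_from_numbers(range(1000, 1010), chain_id="B")
        with pytest.warns(UserWarning, match="no admissible window"):
            ranked = rank_folds(rung, {"self": rung, "stranger": stranger})
        labels = {r.label: r for r in ranked}
        assert not labels["stranger"].comparable
        assert ranked[-1].label == "stranger"


class TestHeatmap:
    def test_renders_png_svg_and_metadata(self, small_rung, tmp_path):
        bumped = perturb_region(small_rung, (8, 16), 2.0, seed=4)
        m = window_rmsd_matrix(small_rung, bumped)
        written = render_heatmap(m, tmp_path / "map.png")
        assert {p.suffix for p in written} == {".png", ".svg"}
        assert all(p.exists() and p.stat().st_size > 0 for p in written)
        assert (tmp_path / "map.json").exists()

    def test_empty_matrix_errors_without_writing(self, tmp_path):
        m = WindowRMSDMatrix(
            id_a="a", id_b="b", entries={}, min_window=3, atom_set=("CA",),
            start_numbers_a=np.array([]), start_numbers_b=np.array([]),
        )
        with pytest.raises(ValueError, match="empty"):
            render_heatmap(m, tmp_path / "none.png")
        assert not (tmp_path / "none.png").exists()

    def test_tsv_export_columns(self, small_rung, tmp_path):
        m = window_rmsd_matrix(small_rung, small_rung)
        out = tmp_path / "matrix.tsv"
        m.to_tsv(out)
        header = out.read_text().splitlines()[0]
        assert header == "start_res\tend_res\tlength\trmsd_A"
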