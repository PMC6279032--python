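import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynalign import (AlignParams, ModeAlignError, align_mode_pair,
                      build_hessian, compute_dss, constrained_score,
                      extract_matches, residue_profiles, residue_score,
                      score_matrix, slow_modes)
from dynalign import fixtures as fx
from dynalign.structure_io import extract_nodes
from conftest import random_rotation
from oracles import brute_force_matches


# ---------------------------------------------------------------------------
# per-cell scores
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("u, v, expected", [
    ((1, 0, 0), (1, 0, 0), 0.3),     # parallel: 1 - C
    ((1, 0, 0), (0, 1, 0), -0.7),    # orthogonal: -C
    ((1, 0, 0), (-1, 0, 0), -1.7),   # antiparallel: -1 - C
])
def test_residue_score_analytic(u, v, expected):
    assert residue_score(np.array(u, float), np.array(v, float), C=0.7) \
        == pytest.approx(expected, abs=1e-12)


def test_residue_score_rejects_zero_vector():
    with pytest.raises(ModeAlignError):
        residue_score(np.zeros(3), np.array([1.0, 0, 0]))


@pytest.mark.parametrize("r, expected", [
    (5.0, 0.3),    # within the constraint
    (12.0, -1.0),  # beyond R_c: exactly -1
    (10.0, 0.3),   # boundary inclusive
])
def test_constrained_score(r, expected):
    u = np.array([1.0, 0, 0])
    assert constrained_score(u, u, r, C=0.7, r_c=10.0) \
        == pytest.approx(expected, abs=1e-12)


@settings(derandomize=True, max_examples=30)
@given(st.integers(0, 2**31 - 1))
def test_residue_score_bounded(seed):
    rng = np.random.default_rng(seed)
    u, v = rng.normal(size=(2, 3))
    s = residue_score(u, v, C=0.7)
    assert -1.7 - 1e-12 <= s <= 0.3 + 1e-12


# ---------------------------------------------------------------------------
# score matrices
# ---------------------------------------------------------------------------

def test_self_score_matrix_diagonal(bundle_nodes, bundle_modes):
    coords = bundle_nodes.coords
    sm = score_matrix(bundle_modes.vectors[0], bundle_modes.vectors[0],
                      coords, coords, sign=1)
    np.testing.assert_allclose(np.diag(sm.matrix), 0.3, atol=1e-12)
    sm_neg = score_matrix(bundle_modes.vectors[0], bundle_modes.vectors[0],
                          coords, coords, sign=-1)
    np.testing.assert_allclose(np.diag(sm_neg.matrix), -1.7, atol=1e-12)


def test_score_matrix_matches_scalar_recomputation():
    rng = np.random.default_rng(21)
    ua, vb = rng.normal(size=(2, 9, 3))
    ca = rng.normal(scale=6.0, size=(9, 3))
    cb = rng.normal(scale=6.0, size=(9, 3))
    params = AlignParams()
    sm = score_matrix(ua, vb, ca, cb, sign=1, params=params)
    for i in range(9):
        for j in range(9):
            r = float(np.linalg.norm(ca[i] - cb[j]))
            assert sm.matrix[i, j] == pytest.approx(
                constrained_score(ua[i], vb[j], r), abs=1e-9)


def test_score_matrix_distance_constraint_off():
    rng = np.random.default_rng(22)
    ua, vb = rng.normal(size=(2, 8, 3))
    far = rng.normal(scale=100.0, size=(8, 3))
    params = AlignParams(use_distance_constraint=False)
    sm = score_matrix(ua, vb, far, -far, params=params)
    assert (sm.matrix > -1.0).any()  # no clamping despite huge distances


# ---------------------------------------------------------------------------
# match extraction
# ---------------------------------------------------------------------------

def test_seeded_diagonal_run_extracted_exactly():
    S = np.full((10, 10), -1.0)
    for t in range(8):
        S[1 + t, 1 + t] = 0.3
    matches = extract_matches(S, AlignParams())
    assert len(matches) == 1
    m = matches[0]
    assert (m.i_start, m.j_start, m.length) == (1, 1, 8)
    assert m.score == pytest.approx(2.4, abs=1e-12)
    # independent confirmation
    assert brute_force_matches(S)[0] == pytest.approx((2.4, 1, 1, 8))


def test_run_shorter_than_min_len_is_dropped():
    # surrounding cells are negative enough that no 7-cell extension of the
    # 6-cell positive run stays net positive
    S = np.full((10, 10), -2.0)
    for t in range(6):
        S[2 + t, 2 + t] = 0.3
    assert extract_matches(S, AlignParams()) == []


@pytest.mark.parametrize("seed", range(25))
def test_extraction_equals_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    S = rng.uniform(-0.6, 0.4, size=(20, 20))
    got = extract_matches(S, AlignParams())
    got.sort(key=lambda m: (m.i_start, m.j_start))
    expected = brute_force_matches(S)
    expected.sort(key=lambda e: (e[1], e[2]))
    assert len(got) == len(expected)
    for m, (sc, i0, j0, L) in zip(got, expected):
        assert (m.i_start, m.j_start, m.length) == (i0, j0, L)
        assert m.score == pytest.approx(sc, abs=1e-12)


def test_match_cap_respected():
    # four positive runs on four separate diagonals; cap keeps only three
    S = np.full((60, 60), -2.0)
    for offset in (0, 14, 28, 42):
        for t in range(8):
            S[offset + t, offset + t] = 0.3
    params = AlignParams(min_len=7, max_matches_per_pair=3)
    assert len(extract_matches(S, params)) == 3
    assert len(extract_matches(S, AlignParams(min_len=7))) == 4


# ---------------------------------------------------------------------------
# sign handling
# ---------------------------------------------------------------------------

def test_self_mode_pair_prefers_plus(bundle_nodes, bundle_modes):
    coords = bundle_nodes.coords
    sign, matches = align_mode_pair(bundle_modes.vectors[0],
                                    bundle_modes.vectors[0], coords, coords)
    assert sign == 1
    assert matches[0].length == len(coords)


def test_negated_mode_flips_sign_same_matches(bundle_nodes, bundle_modes):
    coords = bundle_nodes.coords
    _, plus = align_mode_pair(bundle_modes.vectors[0],
                              bundle_modes.vectors[0], coords, coords)
    sign, minus = align_mode_pair(bundle_modes.vectors[0],
                                  -bundle_modes.vectors[0], coords, coords)
    assert sign == -1
    assert [(m.i_start, m.j_start, m.length) for m in minus] \
        == [(m.i_start, m.j_start, m.length) for m in plus]
    assert minus[0].score == plus[0].score


def test_chosen_sign_is_never_worse():
    rng = np.random.default_rng(30)
    for _ in range(10):
        ua, vb = rng.normal(size=(2, 15, 3))
        ca = rng.normal(scale=3.0, size=(15, 3))
        params = AlignParams(min_len=3)
        sign, matches = align_mode_pair(ua, vb, ca, ca, params)
        other = extract_matches(
            score_matrix(ua, vb, ca, ca, sign=-sign, params=params), params)
        best = matches[0].score if matches else 0.0
        best_other = other[0].score if other else 0.0
        assert best >= best_other


# ---------------------------------------------------------------------------
# DSS
# ---------------------------------------------------------------------------

def _random_pair(seed, n_helices=3, helix_len=10, sigma=0.4):
    base = fx.make_bundle(n_helices, helix_len)
    sa = fx.perturb(base, sigma, seed * 2 + 1)
    sb = fx.perturb(base, sigma, seed * 2 + 2)
    na, nb = extract_nodes(sa), extract_nodes(sb)
    ma = slow_modes(build_hessian(na), n_keep=12)
    mb = slow_modes(build_hessian(nb), n_keep=12)
    return ma, mb, na.coords, nb.coords


def test_self_dss_lower_bound(bundle_nodes, bundle_modes):
    """Self-comparison: each of the n diagonal mode pairs contributes a
    full-length match at 1 - C per residue, so DSS >= n (1 - C) = 3.6."""
    res = compute_dss(bundle_modes, bundle_modes,
                      bundle_nodes.coords, bundle_nodes.coords)
    assert res.dss >= 12 * 0.3


def test_dss_symmetric():
    ma, mb, ca, cb = _random_pair(40)
    ab = compute_dss(ma, mb, ca, cb).dss
    ba = compute_dss(mb, ma, cb, ca).dss
    assert abs(ab - ba) < 1e-9


def test_dss_invariant_to_mode_sign_flip():
    ma, mb, ca, cb = _random_pair(41)
    base = compute_dss(ma, mb, ca, cb).dss
    flipped = mb.vectors.copy()
    flipped[3] *= -1.0
    flipped[7] *= -1.0
    assert abs(compute_dss(ma, flipped, ca, cb).dss - base) < 1e-9


def test_dss_invariant_to_mode_rescaling():
    ma, mb, ca, cb = _random_pair(42)
    base = compute_dss(ma, mb, ca, cb).dss
    assert abs(compute_dss(ma, mb.vectors * 7.3, ca, cb).dss - base) < 1e-9


def test_dss_invariant_to_joint_rigid_motion():
    ma, mb, ca, cb = _random_pair(43)
    base = compute_dss(ma, mb, ca, cb).dss
    rng = np.random.default_rng(43)
    R = random_rotation(rng)
    t = rng.normal(scale=20.0, size=3)
    moved = compute_dss(ma.vectors @ R.T, mb.vectors @ R.T,
                        ca @ R.T + t, cb @ R.T + t).dss
    assert abs(moved - base) < 1e-9


def test_dss_requires_enough_modes(bundle_nodes, bundle_modes):
    with pytest.raises(ModeAlignError):
        compute_dss(bundle_modes.vectors[:5], bundle_modes.vectors[:5],
                    bundle_nodes.coords, bundle_nodes.coords,
                    AlignParams(n_modes=12))


def test_profiles_reproduce_dss(bundle_nodes, bundle_modes):
    res = compute_dss(bundle_modes, bundle_modes,
                      bundle_nodes.coords, bundle_nodes.coords)
    assert (res.profile_a.mean() + res.profile_b.mean()) / 2 \
        == pytest.approx(res.dss, abs=1e-12)
    ta, tb = residue_profiles(res, bundle_nodes, bundle_nodes)
    assert list(ta.columns) == ["chain", "residue", "kind", "r_score"]
    np.testing.assert_array_equal(ta["r_score"].to_numpy(), res.profile_a)
    # every residue collects at least 1 - C from each of the n self pairs
    assert (res.profile_a >= 12 * 0.3 - 1e-9).all()


def test_selected_matches_number_at_most_2n():
    ma, mb, ca, cb = _random_pair(44)
    res = compute_dss(ma, mb, ca, cb)
    assert len(res.selected_matches) <= 24
    scores = sorted((m.score for m in res.matches), reverse=True)
    sel = sorted((m.score for m in res.selected_matches), reverse=True)
    assert sel == scores[:len(sel)]
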