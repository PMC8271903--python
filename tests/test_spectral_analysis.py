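"""Band-information ranking and JM / J_Bh separability statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rededge
from rededge.spectral_analysis import (
    BandStats,
    ClassSignature,
    abs_ranking,
    band_statistics,
    class_signatures,
    j_bh_distance,
    jm_distance,
)


def _table(columns: dict[str, np.ndarray]) -> pd.DataFrame:
    frame = pd.DataFrame(columns)
    n = len(frame)
    frame.insert(0, "role", "train")
    frame.insert(0, "class", "c")
    frame.insert(0, "col", np.arange(n) % 7)
    frame.insert(0, "row", np.arange(n) // 7)
    return frame


# ---------------------------------------------------------------------------
# band statistics
# ---------------------------------------------------------------------------


def test_band_statistics_match_definitional_pearson():
    rng = np.random.default_rng(0)
    cov = np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.5], [0.2, 0.5, 1.0]])
    x = rng.multivariate_normal([0, 0, 0], cov, size=4000)
    table = _table({"a": x[:, 0], "b": x[:, 1], "c": x[:, 2]})
    stats = band_statistics(table, ("a", "b", "c"))
    for i, s in enumerate(stats):
        assert s.sigma == pytest.approx(x[:, i].std(ddof=1))

    def pearson(u, v):
        um, vm = u - u.mean(), v - v.mean()
        return float((um @ vm) / np.sqrt((um @ um) * (vm @ vm)))

    assert stats[1].r_prev == pytest.approx(pearson(x[:, 0], x[:, 1]))
    assert stats[1].r_next == pytest.approx(pearson(x[:, 1], x[:, 2]))
    assert stats[0].r_prev is None and stats[-1].r_next is None


def test_constant_band_and_duplicate_neighbor():
    x = np.random.default_rng(1).random(50)
    table = _table({"a": np.full(50, 0.3), "b": x, "c": x.copy()})
    with pytest.warns(UserWarning, match="constant"):
        stats = band_statistics(table, ("a", "b", "c"))
    assert stats[0].sigma == 0.0
    assert stats[1].r_prev == 0.0  # against the constant band
    assert stats[1].r_next == pytest.approx(1.0)  # duplicated as neighbor


def test_abs_hand_example_and_endpoints():
    """sigma 2 with neighbor correlations 0.4 / 0.6 scores 2 / 0.5 = 4."""
    stats = [
        BandStats("first", 5.0, None, 0.9),
        BandStats("mid", 2.0, 0.4, 0.6),
        BandStats("last", 7.0, 0.8, None),
    ]
    ranked = abs_ranking(stats)
    by_band = {s.band: s for s in ranked}
    assert by_band["mid"].abs_index == pytest.approx(4.0)
    assert by_band["mid"].rank == 1
    # endpoints: index 0, shared bottom rank
    assert by_band["first"].abs_index == 0.0
    assert by_band["first"].rank == by_band["last"].rank == 2


def test_abs_homogeneity_in_sigma():
    """Doubling an interior band's sigma doubles its index and never worsens
    its rank (correlations fixed)."""
    def make(sig):
        return [
            BandStats("e1", 1.0, None, 0.5),
            BandStats("x", sig, 0.5, 0.5),
            BandStats("y", 3.0, 0.5, 0.5),
            BandStats("e2", 1.0, 0.5, None),
        ]

    first = {s.band: s for s in abs_ranking(make(2.0))}
    second = {s.band: s for s in abs_ranking(make(4.0))}
    assert second["x"].abs_index == pytest.approx(2 * first["x"].abs_index)
    assert second["x"].rank <= first["x"].rank


def test_abs_recovers_information_order_on_scene(small_scene):
    """On the default synthetic scene the information ranking puts the NIR
    and red-edge bands above the visible bands."""
    _, raster, _, _ = small_scene
    ranked = abs_ranking(band_statistics(raster))
    by_band = {s.band: s for s in ranked}
    assert by_band["P"].rank == by_band["Y"].rank == 7
    for broad in ("NIR", "RE1", "RE2"):
        for visible in ("B", "G"):
            assert by_band[broad].rank < by_band[visible].rank


# ---------------------------------------------------------------------------
# class signatures
# ---------------------------------------------------------------------------


def test_signatures_recover_planted_gaussian():
    rng = np.random.default_rng(2)
    n = 3000
    mu = np.array([1.0, -2.0])
    cov = np.array([[2.0, 0.7], [0.7, 1.0]])
    x = rng.multivariate_normal(mu, cov, size=n)
    table = _table({"u": x[:, 0], "v": x[:, 1]})
    sig = class_signatures(table, ["u", "v"])[0]
    assert sig.n_pixels == n
    se = np.sqrt(np.diag(cov) / n)
    assert np.all(np.abs(sig.mu - mu) < 3 * se)
    assert not sig.degenerate


def test_identical_pixels_flagged_degenerate():
    table = _table({"u": np.full(10, 1.0), "v": np.full(10, 2.0)})
    with pytest.warns(UserWarning, match="regularized"):
        sig = class_signatures(table, ["u", "v"])[0]
    assert sig.degenerate


def test_signature_count_conservation(small_scene):
    _, raster, _, samples = small_scene
    pixels = rededge.extract_pixels(raster, samples, role="train")
    for sig in class_signatures(pixels, ["R", "G", "B", "NIR"]):
        assert sig.n_pixels == (pixels["class"] == sig.class_label).sum()


# ---------------------------------------------------------------------------
# JM distance
# ---------------------------------------------------------------------------


def _sig(label, mu, cov, n=100, bands=("x",)):
    return ClassSignature(label, np.atleast_1d(mu), np.atleast_2d(cov), n,
                          tuple(bands))


def test_jm_identity_and_closed_form():
    a = _sig("a", 0.0, 1.0)
    assert jm_distance(a, a) == (0.0, 0.0)
    b = _sig("b", 2.0, 1.0)
    bhatt, jm = jm_distance(a, b)
    assert bhatt == pytest.approx(0.5)
    assert jm == pytest.approx(2 * (1 - np.exp(-0.5)))


def test_jm_saturates_at_two():
    a = _sig("a", 0.0, 1.0)
    far = _sig("b", 1e4, 1.0)
    assert jm_distance(a, far)[1] == pytest.approx(2.0)


def test_jm_dimension_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        jm_distance(_sig("a", 0.0, 1.0),
                    _sig("b", [0, 0], np.eye(2), bands=("x", "y")))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    mu=st.lists(st.floats(-5, 5), min_size=2, max_size=2),
    var=st.lists(st.floats(0.1, 4), min_size=2, max_size=2),
    rho=st.floats(-0.8, 0.8),
)
def test_jm_symmetry_and_bounds(mu, var, rho):
    cov_a = np.array([[var[0], rho * np.sqrt(var[0] * var[1])],
                      [rho * np.sqrt(var[0] * var[1]), var[1]]])
    a = _sig("a", [0.0, 0.0], np.eye(2), bands=("x", "y"))
    b = _sig("b", mu, cov_a, bands=("x", "y"))
    b_ab, jm_ab = jm_distance(a, b)
    b_ba, jm_ba = jm_distance(b, a)
    assert jm_ab == pytest.approx(jm_ba, abs=1e-9)
    assert b_ab == pytest.approx(b_ba, abs=1e-9)
    assert 0.0 <= jm_ab <= 2.0


# ---------------------------------------------------------------------------
# J_Bh
# ---------------------------------------------------------------------------


def test_jbh_single_pair_reduction():
    a = _sig("a", 0.0, 1.0, n=50)
    b = _sig("b", 2.0, 1.0, n=50)
    report = j_bh_distance([a, b])
    jm = jm_distance(a, b)[1]
    assert report.j_bh == pytest.approx(0.5 * jm**2)


def test_jbh_zero_for_identical_classes():
    sigs = [_sig(f"c{i}", 0.3, 0.01, n=10) for i in range(4)]
    assert j_bh_distance(sigs).j_bh == pytest.approx(0.0)


def test_jbh_matches_explicit_double_loop():
    rng = np.random.default_rng(4)
    sigs = []
    for i in range(4):
        mu = rng.normal(0, 1, 3)
        m = rng.normal(0, 1, (3, 3))
        sigs.append(ClassSignature(f"c{i}", mu, m @ m.T + 0.5 * np.eye(3),
                                   int(rng.integers(50, 500)),
                                   ("x", "y", "z")))
    for convention in ("sqrt", "product"):
        report = j_bh_distance(sigs, convention)
        total_n = sum(s.n_pixels for s in sigs)
        expected = 0.0
        for i in range(4):
            for j in range(i + 1, 4):
                p_i = sigs[i].n_pixels / total_n
                p_j = sigs[j].n_pixels / total_n
                w = np.sqrt(p_i * p_j) if convention == "sqrt" else p_i * p_j
                expected += w * jm_distance(sigs[i], sigs[j])[1] ** 2
        assert report.j_bh == pytest.approx(expected)
        assert report.j_bh <= report.upper_bound + 1e-9


def test_jbh_unknown_convention():
    sigs = [_sig("a", 0.0, 1.0), _sig("b", 1.0, 1.0)]
    with pytest.raises(ValueError, match="convention"):
        j_bh_distance(sigs, "geometric")


def test_jbh_monotone_in_pairwise_jm():
    """Moving one class away from the others (raising its pairwise JM,
    leaving other pairs unchanged) never decreases J_Bh."""
    others = [_sig("a", 0.0, 1.0), _sig("b", 5.0, 1.0)]
    previous = None
    for shift in (10.0, 12.0, 20.0):
        report = j_bh_distance(others + [_sig("c", shift, 1.0)])
        if previous is not None:
            assert report.j_bh >= previous - 1e-12
        previous = report.j_bh


def test_scheme_nesting_on_scene(small_scene):
    """Adding a red-edge band with class signal never hurts separability:
    the four spectral schemes order A-4 > A-2, A-3 > A-1."""
    _, raster, _, samples = small_scene
    pixels = rededge.extract_pixels(raster, samples, role="train")
    jbh = {}
    subsets = {
        "A-1": ["R", "G", "B", "NIR"],
        "A-2": ["R", "G", "B", "NIR", "RE1"],
        "A-3": ["R", "G", "B", "NIR", "RE2"],
        "A-4": ["R", "G", "B", "NIR", "RE1", "RE2"],
    }
    for scheme, bands in subsets.items():
        jbh[scheme] = j_bh_distance(class_signatures(pixels, bands)).j_bh
    assert jbh["A-4"] > jbh["A-2"] > jbh["A-1"]
    assert jbh["A-4"] > jbh["A-3"] > jbh["A-1"]
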