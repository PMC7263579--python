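"""Texture descriptors vs independent brute-force oracles on toy maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t1tex.texture import (
    DIRECTIONS_DEG,
    GLCM_STATS,
    GLRLM_STATS,
    GLCMConfig,
    GLRLMConfig,
    LBPConfig,
    QuantizationConfig,
    extract_all,
    feature_names,
    glcm_features,
    glrlm_features,
    histogram_features,
    lbp_features,
    quantize,
)
from t1tex.texture import _glcm_stats_from_probs  # white-box: checkerboard identity


# ------------------------------------------------------------------- oracles

def histogram_oracle(v):
    v = np.asarray(v, dtype=float).ravel()
    m = sum(v) / len(v)
    var = sum((x - m) ** 2 for x in v) / len(v)
    if var == 0:
        return np.array([m, 0.0] + [0.0] * 8)
    sd = var**0.5
    out = [m, var]
    for k in range(3, 11):
        out.append(sum((x - m) ** k for x in v) / len(v) / sd**k)
    return np.array(out)


GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_oracle(q, d, levels):
    """Pooled symmetric co-occurrence stats at displacement d: explicit pair loop."""
    h, w = q.shape
    C = np.zeros((levels, levels))
    for deg, (dr, dc) in GLCM_OFFSETS.items():
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr * d, c + dc * d
                if 0 <= r2 < h and 0 <= c2 < w:
                    C[q[r, c], q[r2, c2]] += 1
                    C[q[r2, c2], q[r, c]] += 1
    p = C / C.sum()
    i = np.arange(levels)
    px = p.sum(axis=1)
    mu = (i * px).sum()
    sig2 = ((i - mu) ** 2 * px).sum()
    asm = (p**2).sum()
    contrast = sum(
        (a - b) ** 2 * p[a, b] for a in range(levels) for b in range(levels)
    )
    hom2 = sum(p[a, b] / (1 + (a - b) ** 2) for a in range(levels) for b in range(levels))
    ent = -sum(x * np.log2(x) for x in p.ravel() if x > 0)
    corr = (
        (sum(a * b * p[a, b] for a in range(levels) for b in range(levels)) - mu * mu)
        / sig2
        if sig2 > 0
        else 0.0
    )
    sos = sum((a - mu) ** 2 * p[a, b] for a in range(levels) for b in range(levels))
    return np.array([asm, contrast, hom2, ent, corr, sos])


def runs_oracle(q, deg, levels):
    """Exhaustive maximal-run enumeration along each directional scan line."""
    h, w = q.shape
    if deg == 0:
        lines = [list(q[r]) for r in range(h)]
    elif deg == 90:
        lines = [list(q[:, c]) for c in range(w)]
    elif deg == 135:
        lines = [list(np.asarray(q).diagonal(k)) for k in range(-(h - 1), w)]
    else:  # 45
        lines = [list(np.flipud(q).diagonal(k)) for k in range(-(h - 1), w)]
    M = np.zeros((levels, max(h, w)))
    for line in lines:
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            M[line[i], j - i - 1] += 1
            i = j
    Nr, Np = M.sum(), h * w
    sre = lre = gln = rln = lgre = hgre = srlge = srhge = lrlge = lrhge = 0.0
    for lvl in range(levels):
        for ln in range(M.shape[1]):
            m = M[lvl, ln]
            if m == 0:
                continue
            jj, iw = ln + 1, lvl + 1
            sre += m / jj**2
            lre += m * jj**2
            lgre += m / iw**2
            hgre += m * iw**2
            srlge += m / (iw**2 * jj**2)
            srhge += m * iw**2 / jj**2
            lrlge += m * jj**2 / iw**2
            lrhge += m * iw**2 * jj**2
    gln = (M.sum(axis=1) ** 2).sum()
    rln = (M.sum(axis=0) ** 2).sum()
    return (
        np.array([sre, lre, gln, rln, Nr * Nr / Np, lgre, hgre, srlge, srhge, lrlge, lrhge])
        / Nr
    )


def lbp_oracle(v, P, R):
    """Naive per-pixel LBP: explicit bilinear sampling and rotation handling."""
    h, w = v.shape
    m = int(np.ceil(R))
    hist = np.zeros(P + 2)
    for r in range(m, h - m):
        for c in range(w - m * 2):
            cc = c + m
            center = v[r, cc]
            tol = 1e-9 * max(1.0, abs(center))
            bits = []
            for p in range(P):
                ang = 2 * np.pi * p / P
                x = cc + R * np.cos(ang)
                y = r - R * np.sin(ang)
                x0, y0 = int(np.floor(x)), int(np.floor(y))
                tx, ty = x - x0, y - y0
                nb = (
                    (1 - ty) * (1 - tx) * v[y0, x0]
                    + (1 - ty) * tx * v[y0, min(x0 + 1, w - 1)]
                    + ty * (1 - tx) * v[min(y0 + 1, h - 1), x0]
                    + ty * tx * v[min(y0 + 1, h - 1), min(x0 + 1, w - 1)]
                )
                bits.append(1 if nb - center >= -tol else 0)
            # rotation-invariant classification: minimize the binary word over
            # all rotations, then classify by uniformity
            words = [
                sum(bits[(p + s) % P] << p for p in range(P)) for s in range(P)
            ]
            _ = min(words)  # canonical rotation (uniform test is rotation-invariant)
            transitions = sum(bits[p] != bits[(p + 1) % P] for p in range(P))
            code = sum(bits) if transitions <= 2 else P + 1
            hist[code] += 1
    return hist / hist.sum()


# --------------------------------------------------------------------- tests

class TestQuantize:
    def test_identity_on_level_valued_map(self):
        v = np.arange(32, dtype=float).reshape(4, 8)
        assert np.array_equal(quantize(v, QuantizationConfig(32)), v.astype(int))

    def test_constant_map_all_level_zero(self):
        assert np.array_equal(quantize(np.full((4, 4), 7.0)), np.zeros((4, 4), dtype=int))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 64))
    def test_matches_per_pixel_formula(self, seed, n):
        v = np.random.default_rng(seed).uniform(900, 1300, (6, 7))
        q = quantize(v, QuantizationConfig(n))
        lo, hi = v.min(), v.max()
        oracle = np.clip(np.floor(n * (v - lo) / (hi - lo)), 0, n - 1).astype(int)
        assert np.array_equal(q, oracle)
        assert q.min() >= 0 and q.max() == n - 1


class TestHistogram:
    def test_constant_map(self):
        out = histogram_features(np.full((5, 5), 1100.0))
        assert out[0] == 1100.0
        assert np.array_equal(out[1:], np.zeros(9))

    def test_two_point_symmetric(self):
        out = histogram_features(np.array([0.0, 2.0] * 8))
        assert np.allclose(out[:4], [1.0, 1.0, 0.0, 1.0])

    def test_matches_moment_summation_oracle(self):
        v = np.random.default_rng(42).normal(1100, 30, (12, 12))
        assert np.allclose(histogram_features(v), histogram_oracle(v), rtol=1e-10)


class TestGLCM:
    def test_constant_map_degenerate_conventions(self):
        out = glcm_features(np.zeros((12, 12), dtype=int), n_levels=32).reshape(6, 10)
        assert np.allclose(out[0], 1.0)   # ASM
        assert np.allclose(out[1], 0.0)   # Contrast
        assert np.allclose(out[2], 1.0)   # Homogeneity2
        assert np.allclose(out[3], 0.0)   # Entropy
        assert np.allclose(out[4], 0.0)   # Correlation (sigma = 0 convention)
        assert np.allclose(out[5], 0.0)   # SumOfSquares

    def test_checkerboard_single_direction_algebra(self):
        # two-level checkerboard at d=1, horizontal: p(0,1)=p(1,0)=0.5
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        asm, contrast, *_ = _glcm_stats_from_probs(p)
        assert asm == 0.5
        assert contrast == 1.0

    def test_all_60_match_pair_enumeration_oracle(self):
        # 12x12 so pixel pairs exist at every displacement 1..10
        q = np.random.default_rng(3).integers(0, 4, (12, 12))
        got = glcm_features(q, n_levels=4).reshape(6, 10)
        for di, d in enumerate(range(1, 11)):
            assert np.allclose(got[:, di], glcm_oracle(q, d, 4), rtol=1e-10)

    def test_probability_matrices_sum_to_one(self):
        # ASM of a 1-level map is 1 iff normalization holds; generic map: check
        # via the oracle path in test_all_60; here assert the count identity
        q = np.random.default_rng(9).integers(0, 3, (12, 12))
        out = glcm_features(q, n_levels=3)
        assert np.all(np.isfinite(out))


class TestGLRLM:
    def test_single_run_algebra(self):
        q = np.zeros((1, 8), dtype=int)
        got = dict(zip(GLRLM_STATS, runs_oracle(q, 0, 1)))
        mine = glrlm_features(q, GLRLMConfig(directions=(0,)), n_levels=1)
        named = dict(zip(GLRLM_STATS, mine))
        for stats in (got, named):
            assert np.isclose(stats["SRE"], 1 / 64)
            assert np.isclose(stats["LRE"], 64)
            assert np.isclose(stats["RP"], 1 / 8)
            assert np.isclose(stats["RLN"], 1)
            assert np.isclose(stats["GLN"], 1)

    def test_all_runs_length_one(self):
        # (i + 2j) mod 4: no two neighbors share a level in any direction
        i, j = np.mgrid[0:8, 0:8]
        q = (i + 2 * j) % 4
        out = glrlm_features(q, n_levels=4).reshape(11, 4)
        named = dict(zip(GLRLM_STATS, out))
        assert np.allclose(named["SRE"], 1.0)
        assert np.allclose(named["LRE"], 1.0)
        assert np.allclose(named["RP"], 1.0)

    def test_all_44_match_run_enumeration_oracle(self):
        q = np.random.default_rng(5).integers(0, 4, (8, 8))
        got = glrlm_features(q, n_levels=4).reshape(11, 4)
        for di, deg in enumerate(DIRECTIONS_DEG):
            assert np.allclose(got[:, di], runs_oracle(q, deg, 4), rtol=1e-10)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            glrlm_features(np.zeros((0, 0), dtype=int))


class TestLBP:
    def test_constant_map_all_ones_code(self):
        hist = lbp_features(np.full((20, 20), 1100.0))
        assert hist.sum() == pytest.approx(1.0)
        # all-ones uniform pattern: P ones -> 1-based bin P + 1
        assert hist[36] == pytest.approx(1.0)
        assert np.all(hist[:36] == 0) and hist[37] == 0

    def test_histogram_normalized(self):
        v = np.random.default_rng(0).normal(0, 1, (15, 18))
        assert lbp_features(v).sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("P,R", [(8, 1.0), (8, 2.0), (36, 2.0)])
    def test_matches_naive_threshold_and_rotate_oracle(self, P, R):
        v = np.random.default_rng(11).normal(1100, 30, (16, 16))
        got = lbp_features(v, LBPConfig(n_points=P, radius=R))
        assert np.allclose(got, lbp_oracle(v, P, R), rtol=1e-10)

    def test_map_smaller_than_neighborhood_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            lbp_features(np.ones((4, 30)), LBPConfig(36, 2.0))


class TestExtractAll:
    def test_family_sizes_and_total(self):
        names = feature_names()
        assert len(names) == 152
        assert sum(n in dict.fromkeys(names) for n in names) == 152  # unique
        assert len([n for n in names if n.startswith("LBP(")]) == 38
        glrlm_n = [n for n in names if any(n.startswith(s + "(") for s in GLRLM_STATS)]
        glcm_n = [n for n in names if any(n.startswith(s + "(d") for s in GLCM_STATS)]
        assert len(glrlm_n) == 44
        assert len(glcm_n) == 60
        assert "GLN(135)" in names and "SRHGE(0)" in names and "LBP(8)" in names

    def test_constant_map_is_total(self):
        vec = extract_all(np.full((160, 192), 1100.0))
        assert len(vec) == 152
        assert np.all(np.isfinite(vec.to_numpy()))

    def test_intensity_shift_moves_only_histogram_mean(self):
        v = np.random.default_rng(2).normal(1100, 40, (64, 96))
        a = extract_all(v)
        b = extract_all(v + 250.0)
        assert b["Mean"] == pytest.approx(a["Mean"] + 250.0)
        rest = [n for n in a.index if n != "Mean"]
        assert np.allclose(a[rest], b[rest], rtol=1e-8)

    def test_landmark_column_roll_barely_moves_lbp_on_homogeneous_map(self):
        v = np.random.default_rng(4).normal(1100, 25, (160, 192))
        a = extract_all(v)
        b = extract_all(np.roll(v, 48, axis=1))
        lbp_cols = [n for n in a.index if n.startswith("LBP(")]
        assert np.abs(a[lbp_cols] - b[lbp_cols]).max() < 0.02
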