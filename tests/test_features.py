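"""Oracle and property tests for the nine nonlinear features.

Brute-force oracles (explicit double loops over pairs/templates/diagonals)
are implemented here, independently of the package's vectorized code, and
their outputs define the expected values.
"""

import warnings

import numpy as np
import pytest

from emofuse.channels import ChannelSet
from emofuse.features import (
    FeatureParams,
    PhaseSpace,
    autocorr_delay,
    channel_features,
    correlation_dimension,
    delay_embed,
    differential_entropy,
    eps_for_recurrence_rate,
    extract_features,
    higuchi_fd,
    largest_lyapunov,
    recurrence_matrix,
    rqa,
    sample_entropy,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------


def brute_sample_entropy(x, m, r_frac):
    """Richman-Moorman SampEn by explicit template double loop."""
    x = np.asarray(x, float)
    n = len(x)
    tol = r_frac * x.std()
    nt = n - m
    B = A = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= tol:
                B += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= tol:
                A += 1
    if B == 0:
        return 0.0
    if A == 0:
        return -np.log(2.0 / ((n - m - 1) * (n - m)))
    return -np.log(A / B)


def brute_rqa(R, l_min):
    """Diagonal-line scan by explicit loops; defines the RQA convention."""
    R = np.asarray(R)
    n = R.shape[0]
    off = sum(int(R[i, j]) for i in range(n) for j in range(n) if i != j)
    rr = off / (n * n - n)
    lengths = []
    for k in list(range(-(n - 1), 0)) + list(range(1, n)):
        run = 0
        for i in range(n):
            j = i + k
            if 0 <= j < n and R[i, j]:
                run += 1
            else:
                if run:
                    lengths.append(run)
                run = 0
        if run:
            lengths.append(run)
    long = [l for l in lengths if l >= l_min]
    if off == 0 or not long:
        return rr, 0.0, 0.0, 0.0
    det = sum(long) / off
    L = sum(long) / len(long)
    _, counts = np.unique(long, return_counts=True)
    p = counts / counts.sum()
    ent = float(-(p * np.log(p)).sum())
    return rr, det, L, ent


def brute_recurrence(traj, eps):
    n = len(traj)
    R = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for j in range(n):
            R[i, j] = np.linalg.norm(traj[i] - traj[j]) <= eps
    return R


# ---------------------------------------------------------------------------
# delay embedding
# ---------------------------------------------------------------------------


class TestDelayEmbed:
    def test_basic_example(self):
        ps = delay_embed([1, 2, 3, 4], m=2, tau=1)
        np.testing.assert_array_equal(ps.trajectory, [[1, 2], [2, 3], [3, 4]])

    def test_m1_identity(self):
        x = np.arange(7.0)
        ps = delay_embed(x, m=1, tau=3)
        np.testing.assert_array_equal(ps.trajectory[:, 0], x)

    @pytest.mark.parametrize("m", [1, 2, 3, 5])
    @pytest.mark.parametrize("tau", [1, 2, 4])
    def test_point_count_formula(self, m, tau):
        n = 40
        ps = delay_embed(np.random.default_rng(0).standard_normal(n), m, tau)
        assert ps.n_points == n - (m - 1) * tau

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            delay_embed([1, 2, 3], m=4, tau=2)


class TestCorrelationDimension:
    def test_line_segment_dimension_one(self, rng):
        pts = rng.uniform(0, 1, 500)
        traj = np.column_stack([pts, 0.5 * pts + 0.3])
        cd = correlation_dimension(PhaseSpace(traj, 2, 1))
        assert abs(cd - 1.0) <= 0.1

    def test_square_dimension_two(self, rng):
        traj = rng.uniform(0, 1, (500, 2))
        cd = correlation_dimension(PhaseSpace(traj, 2, 1))
        assert abs(cd - 2.0) <= 0.15

    def test_constant_series_zero(self):
        traj = np.zeros((200, 2))
        assert correlation_dimension(PhaseSpace(traj, 2, 1)) == 0.0

    def test_matches_bruteforce_pair_counting(self, rng):
        """C(r) from an explicit double loop reproduces the slope."""
        traj = rng.uniform(0, 1, (150, 2))
        ps = PhaseSpace(traj, 2, 1)
        radii = np.geomspace(0.05, 0.3, 6)
        n = len(traj)
        C = []
        for r in radii:
            cnt = sum(
                np.linalg.norm(traj[i] - traj[j]) <= r
                for i in range(n)
                for j in range(i + 1, n)
            )
            C.append(cnt / (n * (n - 1) / 2))
        expected = np.polyfit(np.log(radii), np.log(C), 1)[0]
        got = correlation_dimension(ps, radii=radii)
        assert got == pytest.approx(expected, abs=1e-9)


class TestHiguchiFD:
    def test_straight_ramp_near_one(self):
        assert abs(higuchi_fd(np.linspace(0, 1, 2000)) - 1.0) <= 0.05

    def test_white_noise_near_two(self):
        vals = [
            higuchi_fd(np.random.default_rng(s).standard_normal(4096))
            for s in range(20)
        ]
        assert abs(np.mean(vals) - 2.0) <= 0.1

    def test_sine_between_one_and_one_point_five(self):
        t = np.arange(2000) / 100.0
        fd = higuchi_fd(np.sin(2 * np.pi * 1.3 * t))
        assert 1.0 <= fd <= 1.5


class TestLargestLyapunov:
    def test_sine_near_zero(self):
        fs = 100.0 / 3.0
        s = np.sin(2 * np.pi * 3.7 * np.arange(3000) / 100.0)[::3]
        ps = delay_embed(s, 8, 4)
        lle = largest_lyapunov(ps, fs=fs, theiler=32)
        assert abs(lle) <= 0.05 * fs / ps.n_points

    def test_logistic_map_ln2(self):
        """The r=4 logistic map's exponent is ln 2 per iteration."""
        z = np.empty(3000)
        z[0] = 0.4
        for i in range(1, 3000):
            z[i] = 4.0 * z[i - 1] * (1.0 - z[i - 1])
        lle = largest_lyapunov(delay_embed(z, 1, 1), fs=1.0, theiler=5)
        assert abs(lle - np.log(2.0)) <= 0.1

    def test_white_noise_positive(self, rng):
        lle = largest_lyapunov(delay_embed(rng.standard_normal(1500), 5, 1),
                               fs=1.0, theiler=5)
        assert lle > 0


class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert sample_entropy(np.ones(100)) == 0.0

    def test_alternating_series_zero(self):
        """x = 1,2,1,2,...: every m-match extends to an (m+1)-match."""
        x = np.tile([1.0, 2.0], 50)
        assert sample_entropy(x, m=2, r=0.2) == pytest.approx(
            brute_sample_entropy(x, 2, 0.2), abs=1e-12
        )
        assert sample_entropy(x, m=2, r=0.2) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_template_counting(self, seed):
        x = np.random.default_rng(seed).standard_normal(120)
        assert sample_entropy(x, m=2, r=0.25) == pytest.approx(
            brute_sample_entropy(x, 2, 0.25), abs=1e-12
        )

    def test_shuffling_does_not_decrease_entropy(self):
        """A random permutation is at least as irregular as the sorted series."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(300)
            shuffled = sample_entropy(x, m=2, r=0.2)
            ordered = sample_entropy(np.sort(x), m=2, r=0.2)
            assert shuffled >= ordered - 1e-12


class TestRecurrence:
    def test_eps_above_diameter_all_ones(self, rng):
        traj = rng.standard_normal((20, 3))
        diam = max(
            np.linalg.norm(a - b) for a in traj for b in traj
        )
        R = recurrence_matrix(PhaseSpace(traj, 3, 1), diam + 1e-9)
        assert R.all()

    def test_eps_zero_identity(self, rng):
        traj = rng.standard_normal((15, 2))
        R = recurrence_matrix(PhaseSpace(traj, 2, 1), 0.0)
        np.testing.assert_array_equal(R, np.eye(15, dtype=np.uint8))

    def test_matches_bruteforce_double_loop(self, rng):
        traj = rng.standard_normal((40, 2))
        eps = 0.8
        R = recurrence_matrix(PhaseSpace(traj, 2, 1), eps)
        np.testing.assert_array_equal(R, brute_recurrence(traj, eps))


class TestRQA:
    def test_all_ones_oracle_values(self):
        """All-ones 10x10 at l_min=2: the brute-force diagonal scan gives
        RR=1, DET=88/90, L=5.5, ENT=ln 8 (lengths 2..9, two lines each)."""
        R = np.ones((10, 10), dtype=np.uint8)
        out = rqa(R, l_min=2)
        expected = brute_rqa(R, 2)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        rr, det, L, ent = out
        assert rr == 1.0
        assert det == pytest.approx(88 / 90)
        assert L == pytest.approx(5.5)
        assert ent == pytest.approx(np.log(8.0))

    def test_identity_matrix_no_recurrence(self):
        rr, det, L, ent = rqa(np.eye(12, dtype=np.uint8), l_min=2)
        assert (rr, det, L, ent) == (0.0, 0.0, 0.0, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        D = rng.random((25, 25))
        D = (D + D.T) / 2
        R = (D < 0.35).astype(np.uint8)
        np.fill_diagonal(R, 1)
        np.testing.assert_allclose(rqa(R, 2), brute_rqa(R, 2), atol=1e-12)

    def test_periodic_more_deterministic_than_noise_at_equal_rr(self, rng):
        t = np.arange(1200) / 100.0
        sine = np.sin(2 * np.pi * 2.1 * t)
        noise = rng.standard_normal(1200)

        def det_of(x):
            ps = delay_embed(x, 5, 3)
            eps = eps_for_recurrence_rate(ps, 0.05)
            return rqa(recurrence_matrix(ps, eps), 2)[1]

        assert det_of(sine) > det_of(noise)

    def test_determinism_bounds(self, rng):
        ps = delay_embed(rng.standard_normal(300), 3, 2)
        eps = eps_for_recurrence_rate(ps, 0.05)
        rr, det, L, _ = rqa(recurrence_matrix(ps, eps), 2)
        assert 0.0 <= det <= 1.0
        if det > 0:
            assert L >= 2


class TestDifferentialEntropy:
    def test_unit_variance_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        x = (x - x.mean()) / x.std(ddof=1)
        assert differential_entropy(x) == pytest.approx(
            0.5 * np.log(2 * np.pi * np.e), abs=1e-12
        )

    def test_scaling_law(self, rng):
        x = rng.standard_normal(500)
        assert differential_entropy(2 * x) - differential_entropy(x) == pytest.approx(
            np.log(2.0), abs=1e-12
        )

    def test_gaussian_sample_close_to_closed_form(self):
        x = np.random.default_rng(1).normal(0, 1.0, 10000)
        assert abs(differential_entropy(x) - 0.5 * np.log(2 * np.pi * np.e)) < 0.05


class TestInvariances:
    def test_offset_invariance(self, rng):
        x = np.sin(np.arange(800) / 5.0) + 0.3 * rng.standard_normal(800)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = channel_features(x, 100.0)
            f2 = channel_features(x + 7.5, 100.0)
        for key in f1:
            assert f1[key] == pytest.approx(f2[key], rel=1e-8), key

    def test_scale_behaviour(self, rng):
        """Scale-free features are unchanged by positive rescaling; DeEn
        shifts by exactly ln(scale)."""
        x = np.sin(np.arange(800) / 5.0) + 0.3 * rng.standard_normal(800)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = channel_features(x, 100.0)
            f2 = channel_features(3.0 * x, 100.0)
        for key in ("CD", "FD", "LLE", "SpEn", "RR", "DET", "L", "ENT"):
            assert f1[key] == pytest.approx(f2[key], rel=1e-6, abs=1e-9), key
        assert f2["DeEn"] - f1["DeEn"] == pytest.approx(np.log(3.0), abs=1e-9)


class TestExtractFeatures:
    def test_table_shape_names_and_determinism(self, small_epochs):
        channels = ChannelSet(indices=(0, 2), labels=("Fp1", "F3"),
                              class_label="intersection")
        params = FeatureParams(max_points=400)
        t1 = extract_features(small_epochs[:6], channels, params)
        t2 = extract_features(small_epochs[:6], channels, params)
        assert t1.equals(t2)
        feature_cols = [c for c in t1.columns if c not in ("quarter", "arousal", "valence")]
        assert len(feature_cols) == 18  # 9 features x 2 channels
        assert "Fp1_SpEn" in t1.columns and "F3_DeEn" in t1.columns
        assert not t1[feature_cols].isna().any().any()
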