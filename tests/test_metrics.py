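import numpy as np
import pytest

from echocount import (
    UndefinedStatisticError,
    coverage_report_2d,
    coverage_report_3d,
    delta_f,
    delta_p,
    delta_pa,
    delta_ps,
    estimate_total,
    p_f,
    p_fs,
    relative_count_error,
)


def brute_force_stats(lo, lf):
    """Independent oracle: explicit loops over cells, straight from the
    definitions of the coverage-error statistics."""
    lo = np.asarray(lo, dtype=int)
    lf = np.asarray(lf, dtype=int)
    if lo.ndim == 2:
        lo, lf = lo[:, :, None], lf[:, :, None]
    M, N, K = lo.shape
    sum_o = sum_f = sum_s = 0
    for m in range(M):
        for n in range(N):
            for k in range(K):
                sum_o += lo[m, n, k]
                sum_f += lf[m, n, k]
                sum_s += lo[m, n, k] * lf[m, n, k]
    size = M * N * K
    out = {"df": 100 * sum_s / sum_o if sum_o else None,
           "pf": 100 * sum_f / size}
    if sum_o:
        out["dp"] = abs(out["df"] - out["pf"])
    if sum_f:
        out["est"] = sum_s * size / sum_f
        if sum_o:
            out["dpa"] = 100 * abs(out["est"] - sum_o) / sum_o
    return out


class TestHandCases2D:
    def test_full_and_empty_coverage(self):
        lo = np.zeros((5, 5), bool)
        lo[2, 2] = lo[0, 1] = True
        assert delta_f(lo, np.ones((5, 5), bool)) == 100.0
        assert delta_f(lo, np.zeros((5, 5), bool)) == 0.0
        assert delta_p(lo, np.ones((5, 5), bool)) == 0.0

    def test_four_fish_two_covered(self):
        lo = np.zeros((5, 5), bool)
        lo[0, 0] = lo[1, 1] = lo[2, 2] = lo[3, 3] = True
        lf = np.zeros((5, 5), bool)
        lf[:, 0:2] = True  # covers the fish at (0,0) and (1,1)
        assert delta_f(lo, lf) == 50.0
        assert p_f(lf) == 40.0
        assert delta_p(lo, lf) == pytest.approx(10.0)

    def test_uniform_fish_make_delta_p_zero(self):
        lo = np.ones((6, 8), bool)
        lf = np.zeros((6, 8), bool)
        lf[:, :3] = True
        assert delta_p(lo, lf) == pytest.approx(0.0)

    def test_empty_grid_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            delta_f(np.zeros((3, 3), bool), np.ones((3, 3), bool))

    def test_p_f_arithmetic(self):
        lf = np.zeros((5, 5), bool)
        lf.ravel()[:10] = True
        assert p_f(lf) == 40.0


class TestHandCases3D:
    def _sixty_in_half(self):
        lo = np.zeros((10, 10, 10), bool)
        lf = np.zeros((10, 10, 10), bool)
        lf[:, :, :5] = True  # half the volume
        flat = lo.reshape(-1)
        covered_idx = np.flatnonzero(lf.reshape(-1))
        uncovered_idx = np.flatnonzero(~lf.reshape(-1))
        flat[covered_idx[:60]] = True
        flat[uncovered_idx[:40]] = True
        return lo, lf

    def test_sixty_of_hundred_in_half_volume(self):
        lo, lf = self._sixty_in_half()
        assert p_fs(lf) == 50.0
        assert delta_ps(lo, lf) == pytest.approx(10.0)
        assert estimate_total(lo, lf) == pytest.approx(120.0)
        assert delta_pa(lo, lf) == pytest.approx(20.0)

    def test_full_coverage_recovers_exact_count(self):
        lo = np.zeros((4, 5, 6), bool)
        lo.reshape(-1)[::7] = True
        lf = np.ones((4, 5, 6), bool)
        assert estimate_total(lo, lf) == lo.sum()
        assert delta_pa(lo, lf) == 0.0
        assert delta_ps(lo, lf) == 0.0

    def test_uniform_fish_are_estimated_exactly(self):
        lo = np.ones((5, 5, 4), bool)
        lf = np.zeros((5, 5, 4), bool)
        lf[:, :2, :] = True
        assert delta_pa(lo, lf) == 0.0

    def test_as_printed_variant_ignores_fish_locations(self):
        lo, lf = self._sixty_in_half()
        printed = delta_ps(lo, lf, as_printed=True)
        assert printed == pytest.approx(abs(100 * 500 / 100 - 50.0))

    def test_empty_mask_is_undefined(self):
        lo = np.ones((3, 3, 3), bool)
        with pytest.raises(UndefinedStatisticError):
            estimate_total(lo, np.zeros((3, 3, 3), bool))


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("shape", [(5, 7), (10, 10), (4, 5, 6), (10, 10, 10)])
    def test_matches_loop_oracle_exactly(self, shape, rng):
        for _ in range(5):
            lo = rng.random(shape) < 0.3
            lf = rng.random(shape) < 0.4
            if not lo.any() or not lf.any():
                continue
            ref = brute_force_stats(lo, lf)
            if len(shape) == 2:
                assert delta_f(lo, lf) == ref["df"]
                assert p_f(lf) == ref["pf"]
                assert delta_p(lo, lf) == ref["dp"]
            else:
                assert p_fs(lf) == ref["pf"]
                assert estimate_total(lo, lf) == ref["est"]
                assert delta_pa(lo, lf) == ref["dpa"]
                assert delta_ps(lo, lf) == abs(ref["df"] - ref["pf"])

    def test_transposition_invariance(self, rng):
        lo = rng.random((6, 9)) < 0.25
        lf = rng.random((6, 9)) < 0.5
        lo[0, 0] = lf[0, 0] = True
        assert delta_f(lo, lf) == delta_f(lo.T, lf.T)
        assert p_f(lf) == p_f(lf.T)


class TestRelativeCountError:
    @pytest.mark.parametrize("estimated,reference,expected",
                             [(502, 548, 8), (245, 226, 8), (37, 37, 0)])
    def test_verification_pond_errors(self, estimated, reference, expected):
        assert relative_count_error(estimated, reference) == expected

    def test_round_half_up(self):
        # 100*|29-20|/20 = 45 -> check a genuine .5 case: |8.3|... use 8.5%
        assert relative_count_error(217, 200) == 9  # 8.5 rounds up
        assert relative_count_error(217, 200, rounded=False) == pytest.approx(8.5)

    def test_zero_reference_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            relative_count_error(5, 0)


class TestReports:
    def test_2d_report_fields(self, rng):
        lo = rng.random((8, 8)) < 0.3
        lo[0, 0] = True
        lf = np.zeros((8, 8), bool)
        lf[:, :4] = True
        rep = coverage_report_2d(lo, lf)
        assert rep.p_f == 50.0
        assert rep.delta_p == pytest.approx(abs(rep.delta_f - rep.p_f))
        assert rep.detected_count <= rep.fish_count
        assert set(rep.to_dict()) >= {"delta_f", "p_f", "delta_p", "detected_count"}

    def test_3d_report_full_coverage(self):
        lo = np.zeros((3, 3, 3), bool)
        lo[1, 1, 1] = True
        rep = coverage_report_3d(lo, np.ones((3, 3, 3), bool))
        assert rep.delta_pa == 0.0 and rep.estimated_count == 1.0
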