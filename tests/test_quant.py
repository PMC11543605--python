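"""Quantification statistics against independent step-by-step transcriptions
of their defining formulas, plus bound and invariance properties."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoeval.quant import (
    QuantMatrix,
    consistency,
    evaluate_mixing,
    exon_isoform_matrix,
    irreproducibility,
    k_value,
    mixing_expected,
    mrd,
    nrmse,
    pet,
    recover_mixing_ratio,
    replicate_stats,
    resolution_entropy,
    scc,
    stratified_report,
)

from conftest import tm

TOL = 1e-10


def series(values, ids=None):
    values = list(values)
    ids = ids or [f"t{i}" for i in range(len(values))]
    return pd.Series([float(v) for v in values], index=ids)


# ---------------------------------------------------------------------------
# independent oracle transcriptions (loops and explicit formulas only)


def _ranks(values):
    """Average ranks (1-based) with ties."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def scc_oracle(est, truth):
    rg_t, rg_e = _ranks(list(truth)), _ranks(list(est))
    n = len(rg_t)
    mt, me = sum(rg_t) / n, sum(rg_e) / n
    cov = sum((a - mt) * (b - me) for a, b in zip(rg_t, rg_e)) / (n - 1)
    st_ = math.sqrt(sum((a - mt) ** 2 for a in rg_t) / (n - 1))
    se = math.sqrt(sum((b - me) ** 2 for b in rg_e) / (n - 1))
    return cov / (st_ * se)


def mrd_oracle(est, truth):
    rel = sorted(
        abs(t - e) / t for t, e in zip(truth, est) if t > 0
    )
    n = len(rel)
    return rel[n // 2] if n % 2 else (rel[n // 2 - 1] + rel[n // 2]) / 2


def nrmse_oracle(est, truth):
    n = len(truth)
    rmse = math.sqrt(sum((t - e) ** 2 for t, e in zip(truth, est)) / n)
    mean_t = sum(truth) / n
    s = math.sqrt(sum((t - mean_t) ** 2 for t in truth) / (n - 1))
    return rmse / s


def im_oracle(cube):
    """cube: I x G x R array of TPM. Returns IM with the 1/R s.d."""
    I, G, R = cube.shape
    cvs = []
    for i in range(I):
        for g in range(G):
            logs = [math.log(cube[i, g, r] + 1) for r in range(R)]
            u = sum(logs) / R
            if u == 0:
                continue
            s = math.sqrt(sum((x - u) ** 2 for x in logs) / R)
            cvs.append(s / u)
    return math.sqrt(sum(c * c for c in cvs) / len(cvs))


def c_alpha_oracle(cube, alpha):
    I, G, R = cube.shape
    agree = total = 0
    for i in range(I):
        for g in range(G):
            for r1, r2 in combinations(range(R), 2):
                a = math.log(cube[i, g, r1] + 1)
                b = math.log(cube[i, g, r2] + 1)
                agree += int((a < alpha) == (b < alpha))
                total += 1
    return agree / total


def re_oracle(values, M):
    top = max(values)
    if top <= 0:
        return 0.0
    alpha = top / M
    counts = [0] * M
    for v in values:
        m = min(int(v / alpha), M - 1)
        counts[m] += 1
    total = sum(counts)
    return -sum(
        (c / total) * math.log(c / total) for c in counts if c > 0
    )


def pet_oracle(est, truth_ids, lookup):
    return 100.0 * sum(lookup.get(t, 0.0) > 0 for t in truth_ids) / len(truth_ids)


# ---------------------------------------------------------------------------
# ground-truth metrics


class TestSCC:
    def test_identity(self):
        t = series([1, 5, 3, 9])
        assert scc(t, t) == pytest.approx(1.0, abs=TOL)

    def test_rank_reversal(self):
        t = series([1, 2, 3, 4])
        e = series([4, 3, 2, 1])
        assert scc(e, t) == pytest.approx(-1.0, abs=TOL)

    def test_hand_value(self):
        t = series([1, 2, 3, 4])
        e = series([1, 3, 2, 4])
        assert scc(e, t) == pytest.approx(0.8, abs=TOL)

    def test_constant_vector_missing(self):
        assert math.isnan(scc(series([2, 2, 2]), series([1, 2, 3])))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.lognormal(1, 1, 6)
        e = rng.lognormal(1, 1, 6)
        assert scc(series(e), series(t)) == pytest.approx(
            scc_oracle(e, t), abs=TOL
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        t = rng.lognormal(1, 1, 20)
        e = rng.lognormal(1, 1, 20)
        base = scc(series(e), series(t))
        assert scc(series(np.sqrt(e)), series(t * 10)) == pytest.approx(base, abs=TOL)


class TestMRD:
    def test_identity_zero(self):
        t = series([1, 5, 3])
        assert mrd(t, t) == 0.0

    def test_hand_values(self):
        assert mrd(series([5, 20]), series([10, 10])) == pytest.approx(0.75, abs=TOL)
        assert mrd(series([5]), series([4])) == pytest.approx(0.25, abs=TOL)

    def test_zero_truth_excluded(self):
        t = series([0, 10])
        e = series([999, 10])
        assert mrd(e, t) == 0.0

    def test_all_zero_truth_error(self):
        with pytest.raises(ValueError):
            mrd(series([1, 2]), series([0, 0]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed + 10)
        t = rng.lognormal(1, 1, 6)
        e = rng.lognormal(1, 1, 6)
        assert mrd(series(e), series(t)) == pytest.approx(mrd_oracle(e, t), abs=TOL)


class TestNRMSE:
    def test_identity_zero(self):
        t = series([1, 5, 3])
        assert nrmse(t, t) == 0.0

    def test_hand_value(self):
        assert nrmse(series([0, 0]), series([0, 10])) == pytest.approx(1.0, abs=TOL)

    def test_joint_scale_invariance(self):
        rng = np.random.default_rng(1)
        t = rng.lognormal(1, 1, 15)
        e = rng.lognormal(1, 1, 15)
        base = nrmse(series(e), series(t))
        assert nrmse(series(7.3 * e), series(7.3 * t)) == pytest.approx(base, abs=TOL)

    def test_constant_truth_error(self):
        with pytest.raises(ValueError):
            nrmse(series([1, 2]), series([5, 5]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed + 20)
        t = rng.lognormal(1, 1, 6)
        e = rng.lognormal(1, 1, 6)
        assert nrmse(series(e), series(t)) == pytest.approx(nrmse_oracle(e, t), abs=TOL)


class TestPET:
    def test_counts(self):
        e = series([1, 0, 2, 0], ids=["a", "b", "c", "d"])
        assert pet(e, ["a", "b", "c", "d"]) == 50.0
        assert pet(e, ["a", "c"]) == 100.0
        assert pet(e, ["b", "d"]) == 0.0
        assert pet(e, ["a", "b", "c", "x"]) == 50.0  # unreported id counts as 0

    def test_three_of_four(self):
        e = series([1, 1, 1, 0])
        assert pet(e, list(e.index)) == pytest.approx(75.0, abs=TOL)


# ---------------------------------------------------------------------------
# replicate statistics


def cube_matrix(cube):
    I, G, R = cube.shape
    return QuantMatrix.from_arrays(
        [f"t{i}" for i in range(I)],
        [f"g{g}" for g in range(G)],
        [f"r{r}" for r in range(R)],
        cube,
    )


class TestIrreproducibility:
    def test_identical_replicates_zero(self):
        cube = np.tile(np.array([[[5.0]], [[2.0]]]), (1, 2, 3))
        res = irreproducibility(cube_matrix(cube))
        assert res.im == pytest.approx(0.0, abs=1e-12)
        assert res.acvc == pytest.approx(0.0, abs=1e-12)

    def test_single_cell_hand_value(self):
        # one transcript, one group, R=2, log(TPM+1) values 1 and 3:
        # u = 2, s = sqrt(((1-2)^2+(3-2)^2)/2) = 1, CV = 1/2, IM = 1/2
        cube = np.array([[[math.e - 1, math.e**3 - 1]]])
        res = irreproducibility(cube_matrix(cube))
        assert res.im == pytest.approx(0.5, abs=TOL)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed + 30)
        cube = rng.lognormal(1, 1, (6, 2, 3))
        res = irreproducibility(cube_matrix(cube))
        assert res.im == pytest.approx(im_oracle(cube), abs=TOL)

    def test_all_zero_transcripts_excluded_with_count(self):
        cube = np.zeros((3, 1, 2))
        cube[0] = [[1.0, 2.0]]
        res = irreproducibility(cube_matrix(cube))
        assert res.n_excluded == 2

    def test_single_replicate_error(self):
        with pytest.raises(ValueError):
            irreproducibility(cube_matrix(np.ones((2, 1, 1))))


class TestConsistency:
    def test_alpha_zero_is_one(self):
        rng = np.random.default_rng(2)
        q = cube_matrix(rng.lognormal(1, 1, (10, 2, 3)))
        curve = consistency(q, alphas=[0.0, 1.0, 2.0])
        assert curve.values[0] == 1.0

    def test_alpha_above_max_is_one(self):
        q = cube_matrix(np.full((4, 1, 2), 3.0))
        curve = consistency(q, alphas=[100.0])
        assert curve.values[0] == 1.0

    def test_hand_disagreement(self):
        # log values 0.5 and 1.5 around alpha = 1: the pair disagrees
        cube = np.array([[[math.e**0.5 - 1, math.e**1.5 - 1]]])
        curve = consistency(cube_matrix(cube), alphas=[1.0])
        assert curve.values[0] == 0.0
        assert curve.cm == 0.0

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.5])
    def test_matches_oracle(self, alpha):
        rng = np.random.default_rng(40)
        cube = rng.lognormal(1, 1, (6, 2, 3))
        curve = consistency(cube_matrix(cube), alphas=[alpha])
        assert curve.values[0] == pytest.approx(c_alpha_oracle(cube, alpha), abs=TOL)

    def test_acc_bounded_by_grid_length(self):
        rng = np.random.default_rng(41)
        q = cube_matrix(rng.lognormal(1, 1, (10, 1, 3)))
        curve = consistency(q)
        assert 0.0 <= curve.acc <= curve.alphas[-1] - curve.alphas[0]


class TestResolutionEntropy:
    def test_all_equal_zero(self):
        assert resolution_entropy(series([10.0] * 50)) == 0.0

    def test_uniform_fill_reaches_ln_m(self):
        M = 10
        # one value per bin midpoint
        vals = [(m + 0.5) * (100.0 / M) for m in range(M)]
        assert resolution_entropy(series(vals), M=M) == pytest.approx(
            math.log(M), abs=TOL
        )

    def test_two_equal_mass_bins(self):
        vals = [1.0] * 5 + [100.0] * 5
        assert resolution_entropy(series(vals), M=10) == pytest.approx(
            math.log(2), abs=TOL
        )

    def test_all_zero_convention(self):
        assert resolution_entropy(series([0.0, 0.0])) == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed + 50)
        vals = rng.lognormal(1, 2, 6)
        assert resolution_entropy(series(vals), M=5) == pytest.approx(
            re_oracle(list(vals), 5), abs=TOL
        )


# ---------------------------------------------------------------------------
# K-value


class TestKValue:
    def test_single_isoform(self):
        assert k_value([tm("a", [(0, 100), (200, 300)])]) == pytest.approx(1.0)

    def test_upper_triangular_closed_form(self):
        # A = [[1,1],[0,1]]: A^T A has eigenvalues (3 ± sqrt(5))/2, so
        # K = sqrt((3+sqrt(5))/(3-sqrt(5))) = (3+sqrt(5))/2 (the golden
        # ratio squared)
        iso1 = tm("a", [(0, 100), (200, 300)])
        iso2 = tm("b", [(200, 300)])
        k = k_value([iso1, iso2])
        assert k == pytest.approx((3 + math.sqrt(5)) / 2, abs=1e-9)

    def test_duplicate_rows_infinite(self):
        iso1 = tm("a", [(0, 100), (200, 300)])
        iso2 = tm("b", [(0, 100), (200, 300)])
        assert math.isinf(k_value([iso1, iso2]))

    def test_disjoint_exons_orthogonal_rows(self):
        iso1 = tm("a", [(0, 100)])
        iso2 = tm("b", [(200, 300)])
        assert k_value([iso1, iso2]) == pytest.approx(1.0)

    def test_matrix_construction(self):
        iso1 = tm("a", [(0, 100), (200, 300)])
        iso2 = tm("b", [(0, 100), (400, 500)])
        A = exon_isoform_matrix([iso1, iso2])
        assert A.shape == (2, 3)
        assert A.sum() == 4

    def test_segment_mode_splits_nested_exons(self):
        iso1 = tm("a", [(0, 300)])
        iso2 = tm("b", [(0, 100)])
        A = exon_isoform_matrix([iso1, iso2], mode="segments")
        assert A.shape == (2, 2)
        assert A[0].tolist() == [1, 1] and A[1].tolist() == [1, 0]


# ---------------------------------------------------------------------------
# mixing


class TestMixing:
    def test_w_one_returns_a(self):
        a, b = series([2e5, 8e5]), series([6e5, 4e5])
        assert np.allclose(mixing_expected(a, b, 1.0), a)

    def test_equal_components_any_w(self):
        a = series([3e5, 7e5])
        for w in (0.0, 0.3, 1.0):
            assert np.allclose(mixing_expected(a, a, w), a)

    def test_hand_weighted_mean(self):
        a, b = series([2e5, 8e5]), series([6e5, 4e5])
        assert np.allclose(mixing_expected(a, b, 0.5), [4e5, 6e5])

    def test_invalid_ratio(self):
        a = series([1.0])
        with pytest.raises(ValueError):
            mixing_expected(a, a, 1.5)

    def test_perfect_observation_ideal_metrics(self):
        a, b = series([2e5, 8e5, 1e5]), series([6e5, 4e5, 2e5])
        obs = mixing_expected(a, b, 0.3)
        m = evaluate_mixing(obs, a, b, 0.3)
        assert m["SCC"] == pytest.approx(1.0, abs=TOL)
        assert m["MRD"] == pytest.approx(0.0, abs=TOL)
        assert m["NRMSE"] == pytest.approx(0.0, abs=TOL)

    def test_permutation_disrupts_scc(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(3, 1, 30)
        a = series(vals)
        b = series(rng.lognormal(3, 1, 30))
        obs = mixing_expected(a, b, 0.5)
        shuffled = pd.Series(rng.permutation(obs.values), index=obs.index)
        assert evaluate_mixing(shuffled, a, b, 0.5)["SCC"] < 1.0

    def test_grid_search_recovers_w(self):
        rng = np.random.default_rng(4)
        a = series(rng.lognormal(3, 1.5, 50))
        b = series(rng.lognormal(3, 1.5, 50))
        for true_w in (0.2, 0.5, 0.75):
            obs = mixing_expected(a, b, true_w)
            assert recover_mixing_ratio(obs, a, b) == pytest.approx(true_w, abs=0.011)


# ---------------------------------------------------------------------------
# stratified reporting


class TestStratifiedReport:
    def test_single_bin_equals_global(self):
        rng = np.random.default_rng(6)
        t = series(rng.lognormal(1, 1, 40))
        e = pd.Series(t.values * np.exp(rng.normal(0, 0.3, 40)), index=t.index)
        feats = pd.DataFrame({"tpm": t.values}, index=t.index)
        rep = stratified_report(e, t, feats, {"tpm": [0, float(t.max()) + 1]})
        assert len(rep) == 1
        assert rep.iloc[0]["MRD"] == pytest.approx(mrd(e, t), abs=TOL)
        assert rep.iloc[0]["SCC"] == pytest.approx(scc(e, t), abs=TOL)

    def test_low_abundance_bin_has_higher_mrd(self):
        rng = np.random.default_rng(7)
        t = series(np.concatenate([rng.uniform(0.2, 2, 150), rng.uniform(10, 100, 150)]))
        # additive noise of fixed scale: relatively larger on low-TPM transcripts
        e = pd.Series(
            np.abs(t.values + rng.normal(0, 1.0, 300)), index=t.index
        )
        feats = pd.DataFrame({"tpm": t.values}, index=t.index)
        rep = stratified_report(e, t, feats, {"tpm": [0, 2, 1000]}).set_index("bin_low")
        assert rep.loc[0]["MRD"] > rep.loc[2]["MRD"]
        assert rep.loc[0]["normalized_MRD"] == 1.0

    def test_bins_partition_counts(self):
        t = series(range(1, 21))
        e = t.copy()
        feats = pd.DataFrame({"x": t.values}, index=t.index)
        rep = stratified_report(e, t, feats, {"x": [0, 5, 10, 25]})
        assert rep["n"].sum() == 20

    def test_empty_bin_missing_not_zero(self):
        t = series([1.0, 2.0, 3.0])
        feats = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=t.index)
        rep = stratified_report(t, t, feats, {"x": [100, 200]})
        assert rep.iloc[0]["n"] == 0
        assert math.isnan(rep.iloc[0]["MRD"])


# ---------------------------------------------------------------------------
# randomized bound checks


@given(st.integers(0, 10_000))
@settings(max_examples=250, derandomize=True, deadline=None)
def test_randomized_bounds(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 12))
    vals = rng.lognormal(1, 2, n)
    M = int(rng.integers(2, 50))
    re_val = resolution_entropy(series(vals), M=M)
    assert 0.0 <= re_val <= math.log(M) + TOL

    cube = rng.lognormal(1, 1, (n, 1, int(rng.integers(2, 5))))
    q = cube_matrix(cube)
    curve = consistency(q, alphas=[0.0, float(rng.uniform(0, 5))])
    assert curve.values[0] == 1.0
    assert np.all((0.0 <= curve.values) & (curve.values <= 1.0))

    t = series(vals)
    e = series(rng.lognormal(1, 2, n))
    c = float(rng.uniform(0.1, 10))
    assert nrmse(series(c * e.values), series(c * t.values)) == pytest.approx(
        nrmse(e, t), rel=1e-9
    )
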