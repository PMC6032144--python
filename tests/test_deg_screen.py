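"""Pairwise chip comparisons, the DEG screen and marker-candidate filters."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from discqc import (
    CandidateCriteria,
    DEGRecord,
    ExpressionMatrix,
    ValidationError,
    detection_call,
    pairwise_compare,
    screen_degs,
    select_candidates,
    wilcoxon_signed_rank_p,
)
from discqc.synthetic import SimulationConfig, simulate_expression


def signed_rank_enumeration_p(log_ratios):
    """Oracle: full 2^n enumeration of sign assignments."""
    r = np.asarray(log_ratios, dtype=float)
    r = r[r != 0]
    n = r.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(r))
    w = ranks[r > 0].sum()
    ws = np.array(
        [
            sum(rk for s, rk in zip(signs, ranks) if s)
            for signs in itertools.product([0, 1], repeat=n)
        ]
    )
    return min(1.0, 2.0 * min((ws <= w).mean(), (ws >= w).mean()))


def make_matrix(signal, groups, probes=None, floor=100.0):
    G, C = np.asarray(signal).shape
    chip_ids = [f"c{i}" for i in range(C)]
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(G)],
        chip_ids=chip_ids,
        groups={c: g for c, g in zip(chip_ids, groups)},
        signal=np.asarray(signal, dtype=float),
        probe_signals=probes,
        detection_floor=floor,
    )


class TestDetectionCall:
    @pytest.mark.parametrize(
        "signal,floor,expected",
        [(800, 100, "detected"), (99.9, 100, "not_detected"),
         (100, 100, "detected")],
    )
    def test_threshold(self, signal, floor, expected):
        assert detection_call(signal, floor) == expected

    def test_nonpositive_signal_rejected(self):
        with pytest.raises(ValidationError):
            detection_call(0.0, 100.0)
        with pytest.raises(ValidationError):
            detection_call(10.0, -1.0)


class TestSignedRank:
    @pytest.mark.parametrize("n", [5, 6, 7, 8, 9, 10])
    def test_exact_p_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(25):
            r = rng.normal(0.4, 1.0, size=n)
            assert wilcoxon_signed_rank_p(r) == pytest.approx(
                signed_rank_enumeration_p(r), abs=1e-12
            )

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(0)
        for n in (6, 11, 15):
            r = rng.normal(0.3, 1.0, size=n)
            assert wilcoxon_signed_rank_p(r) == pytest.approx(
                stats.wilcoxon(r, method="exact").pvalue, abs=1e-12
            )

    def test_all_zero_ratios(self):
        assert wilcoxon_signed_rank_p(np.zeros(8)) == 1.0

    def test_zeros_are_dropped(self):
        r = np.array([0.0, 0.5, 0.7, -0.1, 0.9, 0.3, 0.0])
        assert wilcoxon_signed_rank_p(r) == pytest.approx(
            signed_rank_enumeration_p(r), abs=1e-12
        )


class TestPairwiseCompare:
    def test_constant_eightfold_ratio(self):
        af = np.full(11, 800.0)
        np_ = np.full(11, 100.0)
        c = pairwise_compare(af, np_)
        assert c.slr == pytest.approx(3.0)
        assert c.fc == pytest.approx(8.0)
        assert c.change_call == "increased"

    def test_identical_probe_vectors(self):
        v = np.linspace(50, 500, 11)
        c = pairwise_compare(v, v)
        assert c.slr == 0.0 and c.fc == 1.0
        assert c.p == 1.0
        assert c.change_call == "no_change"

    def test_fc_is_power_of_slr(self):
        rng = np.random.default_rng(1)
        a, b = rng.lognormal(5, 1, 9), rng.lognormal(5, 1, 9)
        c = pairwise_compare(a, b)
        assert c.fc == pytest.approx(2.0**c.slr, rel=1e-15)

    def test_swap_negates_slr(self):
        rng = np.random.default_rng(2)
        a, b = rng.lognormal(5, 1, 7), rng.lognormal(5, 1, 7)
        assert pairwise_compare(a, b).slr == pytest.approx(
            -pairwise_compare(b, a).slr, abs=1e-12
        )

    def test_mixed_sign_ratios_exact_p(self):
        a = np.array([100.0, 210.0, 95.0, 300.0, 140.0, 80.0])
        b = np.array([120.0, 200.0, 100.0, 240.0, 150.0, 90.0])
        c = pairwise_compare(a, b)
        assert c.p == pytest.approx(
            signed_rank_enumeration_p(np.log2(a / b)), abs=1e-12
        )

    @pytest.mark.parametrize(
        "a,b",
        [(np.ones(4), np.ones(4)),  # too few probes
         (np.ones(6), np.ones(5)),  # mismatched
         (np.array([1, 2, 3, 4, 0.0, 6]), np.ones(6))],  # zero signal
    )
    def test_invalid_inputs(self, a, b):
        with pytest.raises(ValidationError):
            pairwise_compare(a, b)


class TestScreen:
    def test_noiseless_planted_gene(self):
        """AF 800 on 11 chips vs NP 100 on 9: FC 8 on every one of 99 pairs."""
        nA, nB, P = 11, 9, 11
        signal = np.array([[800.0] * nA + [100.0] * nB])
        probes = np.tile(signal[:, :, None], (1, 1, P))
        m = make_matrix(signal, ["AF"] * nA + ["NP"] * nB, probes)
        degs = screen_degs(m)
        assert len(degs) == 1
        d = degs[0]
        assert d.direction == "AF_up"
        assert d.fc_mean == pytest.approx(8.0)
        assert d.fc_sd == 0.0
        assert d.change_pct == 100.0
        assert d.detection_pct_af == 100.0 and d.detection_pct_np == 100.0

    def test_constant_gene_not_retained(self):
        signal = np.full((1, 8), 500.0)
        probes = np.tile(signal[:, :, None], (1, 1, 11))
        m = make_matrix(signal, ["AF"] * 4 + ["NP"] * 4, probes)
        assert screen_degs(m) == []

    def test_antisymmetry_under_group_swap(self, small_sim_config):
        matrix, _ = simulate_expression(small_sim_config)
        fwd = {d.gene_id: d for d in screen_degs(matrix)}
        rev = {d.gene_id: d for d in screen_degs(matrix.swapped_groups())}
        assert set(fwd) == set(rev)
        for g, d in fwd.items():
            assert rev[g].direction != d.direction
            assert rev[g].fc_mean == pytest.approx(d.fc_mean, rel=1e-12)

    def test_change_pct_respects_consistency(self, small_sim_config):
        matrix, _ = simulate_expression(small_sim_config)
        for consistency in (0.8, 1.0):
            for d in screen_degs(matrix, consistency=consistency):
                assert d.change_pct >= 100.0 * consistency - 1e-9

    def test_planted_truth_recovered(self, small_sim_config):
        matrix, truth = simulate_expression(small_sim_config)
        degs = screen_degs(matrix)
        called = {d.gene_id for d in degs}
        planted = {
            g for g, lab in zip(matrix.gene_ids, truth.gene_labels)
            if lab != "null"
        }
        tp = len(called & planted)
        assert tp / len(planted) >= 0.9
        assert tp / len(called) >= 0.9

    def test_af_up_pattern_has_zero_np_detection(self):
        """At zero noise the on/off pattern yields NP detection% = 0."""
        config = SimulationConfig(seed=7, n_genes=200, n_af_up=10, n_np_up=6,
                                  n_af_chips=5, n_np_chips=4, probes_per_set=7,
                                  noise_sigma=0.0)
        matrix, truth = simulate_expression(config)
        label = dict(zip(matrix.gene_ids, truth.gene_labels))
        for d in screen_degs(matrix):
            if label[d.gene_id] == "AF_up":
                assert d.detection_pct_np == 0.0

    def test_false_positive_rate_among_nulls(self):
        config = SimulationConfig(seed=19, n_genes=600, n_af_up=0, n_np_up=0,
                                  n_af_chips=6, n_np_chips=5)
        matrix, _ = simulate_expression(config)
        assert len(screen_degs(matrix)) / 600 <= 0.01

    def test_requires_two_chips_per_group(self):
        m = make_matrix([[1.0, 2.0, 3.0]], ["AF", "NP", "NP"])
        with pytest.raises(ValidationError, match="2 chips"):
            screen_degs(m)

    def test_signal_only_matrix_uses_fc_margin(self):
        """Without probe replicates the change call rests on FC alone."""
        signal = np.array([[900.0] * 3 + [100.0] * 3, [100.0] * 6])
        m = make_matrix(signal, ["AF"] * 3 + ["NP"] * 3)
        degs = screen_degs(m)
        assert [d.gene_id for d in degs] == ["g0"]
        assert math.isnan(degs[0].p_median)


def make_deg(gene="g", direction="AF_up", fc_mean=30.0, p_median=0.01,
             detection_pct_np=0.0, signal_mean_np=50.0, **kw):
    defaults = dict(
        gene_id=gene, direction=direction, fc_mean=fc_mean, fc_sd=1.0,
        change_pct=100.0, detection_pct_af=100.0,
        detection_pct_np=detection_pct_np, p_median=p_median,
        signal_mean_af=1000.0, signal_mean_np=signal_mean_np,
    )
    defaults.update(kw)
    return DEGRecord(**defaults)


class TestSelectCandidates:
    def test_af_candidate_accepted(self):
        af, _ = select_candidates([make_deg()], noise_floor=100.0)
        assert [d.gene_id for d in af] == ["g"]

    def test_af_rejected_when_detected_in_np(self):
        af, _ = select_candidates(
            [make_deg(detection_pct_np=20.0)], noise_floor=100.0
        )
        assert af == []

    def test_af_rejected_below_fc_floor(self):
        af, _ = select_candidates([make_deg(fc_mean=20.0)], noise_floor=100.0)
        assert af == []

    def test_np_candidate_needs_stable_signal(self):
        good = make_deg("a", "NP_up", fc_mean=3.5, detection_pct_np=100.0,
                        signal_mean_np=500.0)
        weak_signal = make_deg("b", "NP_up", fc_mean=3.5,
                               detection_pct_np=100.0, signal_mean_np=150.0)
        _, np_c = select_candidates([good, weak_signal], noise_floor=100.0)
        assert [d.gene_id for d in np_c] == ["a"]

    def test_exclusion_list_removes_before_topk(self):
        degs = [make_deg(f"g{i}", fc_mean=100.0 - i) for i in range(30)]
        crit = CandidateCriteria(exclusion_list=frozenset({"g0"}))
        af, _ = select_candidates(degs, crit, noise_floor=100.0)
        assert "g0" not in {d.gene_id for d in af}
        assert len(af) == 25  # the window refills after exclusion

    def test_ranking_tie_broken_by_gene_id(self):
        degs = [make_deg("b", fc_mean=30.0), make_deg("a", fc_mean=30.0)]
        crit = CandidateCriteria(top_k_af=1)
        af, _ = select_candidates(degs, crit, noise_floor=100.0)
        assert [d.gene_id for d in af] == ["a"]

    def test_empty_deg_list_rejected(self):
        with pytest.raises(ValidationError):
            select_candidates([], noise_floor=100.0)
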