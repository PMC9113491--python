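import numpy as np
import pytest

from phylosim import (Approach, IndelModel, RateModel, SequenceState,
                      SimulationConfig, build_model, choose_approach,
                      equivalence_check, gillespie_branch, parse_newick,
                      probmatrix_branch, sample_root_sequence,
                      sample_site_rates, simulate_alignment,
                      yule_harding_tree, assign_branch_lengths,
                      BranchLengthDistribution)
from phylosim.engine import calibrate_switching

from test_models import jc_p_same
from test_trees import build_balanced, build_caterpillar


def make_state(model, rate_model, L, rng):
    codes = sample_root_sequence(model, L, rng)
    rates = sample_site_rates(rate_model or RateModel.constant(), L, rng).rates
    return SequenceState(codes, rates)


class TestChooseApproach:
    def test_discrete_threshold_examples(self):
        rm = RateModel.discrete_gamma(0.5, 4)
        assert choose_approach(1000, 0.001, rm) is Approach.RATE_MATRIX
        assert choose_approach(30_000, 0.1, rm) is Approach.PROB_MATRIX

    def test_continuous_threshold_example(self):
        rm = RateModel.continuous_gamma(0.5)
        assert choose_approach(100, 0.17, rm) is Approach.RATE_MATRIX
        assert choose_approach(100, 0.18, rm) is Approach.PROB_MATRIX

    def test_homogeneous_uses_discrete_threshold(self):
        assert choose_approach(1000, 0.00222, RateModel.constant()) \
            is Approach.RATE_MATRIX
        assert choose_approach(1000, 0.00223, RateModel.constant()) \
            is Approach.PROB_MATRIX

    def test_tie_uses_prob_matrix(self):
        rm = RateModel.constant()
        assert choose_approach(1000, 2.226 / 1000, rm) is Approach.PROB_MATRIX

    def test_threshold_override(self):
        cfg = SimulationConfig(length=10, switch_discrete=5.0)
        assert choose_approach(10, 0.45, RateModel.constant(), cfg) \
            is Approach.RATE_MATRIX


class TestGillespieBranch:
    def test_t_zero_identity(self, jc, rng):
        state = make_state(jc, None, 50, rng)
        res = gillespie_branch(state, 0.0, jc, rng=rng)
        np.testing.assert_array_equal(res.state.states, state.states)
        assert res.n_substitutions == 0

    def test_negative_t_rejected(self, jc, rng):
        with pytest.raises(ValueError):
            gillespie_branch(make_state(jc, None, 10, rng), -0.1, jc, rng=rng)

    def test_event_count_poisson_mean(self, jc):
        # under a normalized Q at unit rates the total leave-rate is L, so
        # the substitution-event count is Poisson(L * t)
        rng = np.random.default_rng(8)
        L, t, reps = 200, 0.2, 2000
        state = make_state(jc, None, L, rng)
        lam = L * t
        counts = [gillespie_branch(state, t, jc, rng=rng).n_substitutions
                  for _ in range(reps)]
        se = np.sqrt(lam / reps)
        assert abs(np.mean(counts) - lam) < 4 * se

    def test_invariant_sites_never_substituted(self, jc):
        rng = np.random.default_rng(3)
        rm = RateModel.invariant(0.5)
        state = make_state(jc, rm, 400, rng)
        frozen = state.rates == 0
        res = gillespie_branch(state, 2.0, jc, rm, rng=rng)
        np.testing.assert_array_equal(res.state.states[frozen],
                                      state.states[frozen])

    def test_insertion_first_order_rate(self, jc):
        # substitutions pinned at zero; expected insertions ~ r_I(L+1)t
        rng = np.random.default_rng(15)
        L, t, reps, r_ins = 100, 0.01, 20_000, 0.03
        indel = IndelModel.default(r_ins, 0.0)
        state = make_state(jc, None, L, rng)
        expected = r_ins * (L + 1) * t
        n = sum(gillespie_branch(state, t, jc, None, indel, rng,
                                 pin_substitutions=True).n_insertions
                for _ in range(reps))
        se = np.sqrt(expected / reps)
        assert abs(n / reps - expected) < 4 * se

    def test_deletions_zero_rates_and_gap(self, jc):
        rng = np.random.default_rng(4)
        indel = IndelModel.default(0.0, 0.5)
        state = make_state(jc, None, 60, rng)
        res = gillespie_branch(state, 1.0, jc, None, indel, rng)
        gaps = res.state.states < 0
        assert gaps.any()
        assert (res.state.rates[gaps] == 0).all()

    def test_all_gap_termination(self, jc):
        rng = np.random.default_rng(5)
        indel = IndelModel(r_ins=0.0, r_del=50.0,
                           ins_dist=IndelModel.default(1, 1).ins_dist,
                           del_dist=IndelModel.default(1, 1).del_dist)
        state = make_state(jc, None, 10, rng)
        res = gillespie_branch(state, 10.0, jc, None, indel, rng)
        assert res.state.n_residues == 0

    def test_determinism(self, jc):
        state = make_state(jc, None, 80, np.random.default_rng(0))
        indel = IndelModel.default(0.05, 0.05)
        a = gillespie_branch(state, 0.5, jc, None, indel,
                             np.random.default_rng(99))
        b = gillespie_branch(state, 0.5, jc, None, indel,
                             np.random.default_rng(99))
        np.testing.assert_array_equal(a.state.states, b.state.states)
        assert a.insertions == b.insertions


class TestProbMatrixBranch:
    def test_t_zero_identity(self, jc, rng):
        state = make_state(jc, None, 50, rng)
        res = probmatrix_branch(state, 0.0, jc, rng=rng)
        np.testing.assert_array_equal(res.state.states, state.states)

    def test_jc_unchanged_fraction(self, jc):
        rng = np.random.default_rng(21)
        L = 200_000  # L independent single-site replicates
        state = make_state(jc, None, L, rng)
        res = probmatrix_branch(state, 0.5, jc, rng=rng)
        frac = (res.state.states == state.states).mean()
        p = jc_p_same(0.5)
        assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / L)

    def test_discrete_gamma_builds_k_matrices(self, moderate_gtr):
        rng = np.random.default_rng(2)
        rm = RateModel.discrete_gamma(0.5, 4)
        state = make_state(moderate_gtr, rm, 2000, rng)
        before = moderate_gtr.n_matrix_builds
        probmatrix_branch(state, 0.3, moderate_gtr, rm, rng=rng)
        assert moderate_gtr.n_matrix_builds - before == 4

    def test_gap_sites_stay_gaps(self, jc, rng):
        states = np.array([0, -1, 1, -1, 2], dtype=np.int16)
        rates = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        res = probmatrix_branch(SequenceState(states, rates), 0.7, jc, rng=rng)
        assert (res.state.states[[1, 3]] == -1).all()


class TestSimulateAlignment:
    def test_zero_branch_lengths_copy_root(self, jc):
        tree = parse_newick("((A:0.0,B:0.0):0.0,C:0.0);")
        cfg = SimulationConfig(length=30, seed=11)
        out = simulate_alignment(tree, jc, config=cfg)
        seqs = {name: s for name, s in out["rows"]}
        assert seqs["A"] == seqs["B"] == seqs["C"]

    def test_width_without_indels(self, jc, rng):
        tree = yule_harding_tree(12, rng)
        assign_branch_lengths(tree, BranchLengthDistribution.exponential(0.1),
                              rng)
        out = simulate_alignment(tree, jc,
                                 config=SimulationConfig(length=77, seed=1))
        assert out["width"] == 77
        assert all(len(s) == 77 for _, s in out["rows"])

    def test_missing_branch_lengths_error(self, jc):
        tree = parse_newick("((A,B),C);")
        with pytest.raises(ValueError):
            simulate_alignment(tree, jc,
                               config=SimulationConfig(length=10, seed=0))

    def test_user_root_sequence(self, jc):
        tree = parse_newick("(A:0.0,B:0.0);")
        cfg = SimulationConfig(length=4, seed=0, root_sequence="ACGT")
        out = simulate_alignment(tree, jc, config=cfg)
        assert dict(out["rows"])["A"] == "ACGT"

    def test_alphabet_mismatch_rejected(self, jc):
        tree = parse_newick("(A:0.1,B:0.1);")
        cfg = SimulationConfig(length=4, seed=0, root_sequence="ACGX")
        with pytest.raises(ValueError):
            simulate_alignment(tree, jc, config=cfg)

    def test_stationarity_long_branches(self, jc):
        tree = parse_newick("(A:5.0,B:5.0);")
        cfg = SimulationConfig(length=40_000, seed=3,
                               approach=Approach.PROB_MATRIX)
        out = simulate_alignment(tree, jc, config=cfg)
        chars = "".join(s for _, s in out["rows"])
        L = len(chars)
        se = np.sqrt(0.25 * 0.75 / L)
        for c in "ACGT":
            assert abs(chars.count(c) / L - 0.25) < 4 * se

    def test_streaming_memory_balanced(self, jc):
        tree = build_balanced(10)  # 1024 tips

        class Sink:
            def __init__(self):
                self.rows = []

            def write_row(self, name, seq):
                self.rows.append((name, seq))

        sink = Sink()
        cfg = SimulationConfig(length=20, seed=6)
        out = simulate_alignment(tree, jc, config=cfg, sink=sink)
        assert len(sink.rows) == 1024
        assert out["peak_live"] <= 11  # log2(1024) + 1

    def test_streaming_memory_caterpillar(self, jc):
        tree = build_caterpillar(1024)
        cfg = SimulationConfig(length=10, seed=6)

        class Sink:
            def write_row(self, name, seq):
                pass

        out = simulate_alignment(tree, jc, config=cfg, sink=Sink())
        n = 1024
        assert out["peak_live"] <= n
        assert out["peak_live"] <= (2 * n - 1) / 2

    def test_determinism_byte_identical(self, moderate_gtr):
        tree = parse_newick("((A:0.3,B:0.2):0.1,(C:0.4,D:0.1):0.2);")
        rm = RateModel.discrete_gamma(0.5, 4, p_inv=0.1)
        indel = IndelModel.default(0.05, 0.08)
        cfg = SimulationConfig(length=60, seed=17)
        a = simulate_alignment(tree, moderate_gtr, rm, indel, cfg)
        b = simulate_alignment(tree, moderate_gtr, rm, indel, cfg)
        assert a["rows"] == b["rows"]

    def test_rows_equal_length_with_indels(self, moderate_gtr, rng):
        tree = yule_harding_tree(10, rng)
        assign_branch_lengths(tree, BranchLengthDistribution.exponential(0.2),
                              rng)
        indel = IndelModel.default(0.1, 0.1)
        out = simulate_alignment(tree, moderate_gtr, None, indel,
                                 SimulationConfig(length=50, seed=23))
        widths = {len(s) for _, s in out["rows"]}
        assert len(widths) == 1

    def test_gap_monotonicity(self, moderate_gtr):
        # a site deleted on a branch (residue in the parent row, gap in the
        # child row) is a gap in every descendant of that branch
        tree = parse_newick("((A:0.5,B:0.5)ab:0.5,(C:0.5,D:0.5)cd:0.5)root;")
        indel = IndelModel.default(0.1, 0.3)
        cfg = SimulationConfig(length=40, seed=29, write_ancestral=True,
                               streaming=False)
        out = simulate_alignment(tree, moderate_gtr, None, indel, cfg)
        rows = dict(out["rows"])
        deleted_seen = 0
        for anc, kids in (("ab", "AB"), ("cd", "CD")):
            for i, (top, mid) in enumerate(zip(rows["root"], rows[anc])):
                if top != "-" and mid == "-":  # deleted on the anc branch
                    deleted_seen += 1
                    for kid in kids:
                        assert rows[kid][i] == "-"
        assert deleted_seen > 0  # the test actually exercised deletions

    def test_eventlog_matches_naive(self, moderate_gtr):
        master = np.random.default_rng(31)
        rm = RateModel.discrete_gamma(0.5, 4)
        for case in range(25):
            n_tips = int(master.integers(2, 9))
            L = int(master.integers(5, 51))
            tree = yule_harding_tree(n_tips, master)
            assign_branch_lengths(
                tree, BranchLengthDistribution.exponential(0.3), master)
            indel = IndelModel.default(0.1, 0.1)
            cfg = SimulationConfig(length=L, seed=int(master.integers(2**31)))
            a = simulate_alignment(tree, moderate_gtr, rm, indel, cfg,
                                   assembler="eventlog")
            b = simulate_alignment(tree, moderate_gtr, rm, indel, cfg,
                                   assembler="naive")
            assert a["rows"] == b["rows"], f"case {case} diverged"


class TestEquivalence:
    def test_same_law(self, moderate_gtr):
        rng = np.random.default_rng(41)
        rm = RateModel.discrete_gamma(0.5, 4)
        rep = equivalence_check(moderate_gtr, rm, L=2000, t=0.3, n_reps=500,
                                rng=rng)
        assert rep["p_value"] > 0.001

    def test_negative_control(self, moderate_gtr, jc):
        rng = np.random.default_rng(43)
        corrupted = build_model("GTR", params=(5.0, 0.2, 5.0, 0.2, 5.0, 0.2),
                                freqs=(0.3, 0.2, 0.2, 0.3))
        rep = equivalence_check(moderate_gtr, None, L=2000, t=0.3, n_reps=500,
                                rng=rng, model_b=corrupted)
        assert rep["p_value"] < 1e-6

    def test_t_zero_degenerate(self, jc, rng):
        rep = equivalence_check(jc, None, L=100, t=0.0, n_reps=20, rng=rng)
        assert rep["degenerate"] and rep["p_value"] == 1.0


class TestCalibration:
    def test_synthetic_cost_model(self, jc):
        # injected costs: rate path c1*L*t, prob path c2 (constant), with
        # c2/c1 = 3, so the crossover satisfies L*t = 3 exactly
        def timer(approach, L, t):
            return 1.0 * L * t if approach == "rate" else 3.0

        out = calibrate_switching(jc, None, [1000, 2000, 5000, 10_000],
                                  timer=timer, iterations=50)
        assert out["constant"] == pytest.approx(3.0, rel=1e-2)

    def test_single_length_grid(self, jc):
        def timer(approach, L, t):
            return 2.0 * L * t if approach == "rate" else 5.0 * L * 0.001

        out = calibrate_switching(jc, None, [4000], timer=timer,
                                  iterations=50)
        L, t_star = out["crossovers"][0]
        assert out["constant"] == pytest.approx(L * t_star)

    def test_real_timings_informational(self, jc, rng):
        out = calibrate_switching(jc, None, [300], rng=rng, iterations=8,
                                  t_bounds=(1e-4, 1.0))
        assert out["constant"] > 0 and np.isfinite(out["constant"])
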