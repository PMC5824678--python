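import numpy as np
import pytest

import rangedec as rd
from conftest import make_system, path_adjacency, tip_table
from oracles import (
    bruteforce_likelihood,
    ode_branch,
    oracle_clado,
    oracle_generator,
)


class TestGenerator:
    def test_two_area_rates(self, sys2):
        space = rd.enumerate_ranges(sys2)
        Q = rd.build_generator(space, rd.uniform_multipliers(sys2), rd.DECParams(0.3, 0.07))
        iA, iAB = space.index_of[0b01], space.index_of[0b11]
        assert Q[iA, iAB] == pytest.approx(0.3)  # gain B from A
        assert Q[iAB, iA] == pytest.approx(0.07)  # lose B
        assert Q[iA, 0] == pytest.approx(0.07)  # singleton loss to empty
        assert (Q[0] == 0).all()  # empty range absorbing

    def test_gain_rate_sums_over_source_areas(self, sys3):
        text = (
            "\tA\tB\tC\n"
            "A\t1\t0.8\t0.6\n"
            "B\t0.8\t1\t0.4\n"
            "C\t0.2\t0.4\t1\n"
        )
        with pytest.warns(UserWarning):
            mult = rd.load_matrix(text, sys3)
        space = rd.enumerate_ranges(sys3)
        d = 0.5
        Q = rd.build_generator(space, mult, rd.DECParams(d, 0.0))
        iAB, iABC = space.index_of[0b011], space.index_of[0b111]
        assert Q[iAB, iABC] == pytest.approx(d * (0.6 + 0.4))  # m(A,C)+m(B,C)

    def test_zero_dispersal_leaves_only_losses(self, sys3):
        space = rd.enumerate_ranges(sys3)
        Q = rd.build_generator(space, rd.uniform_multipliers(sys3), rd.DECParams(0.0, 0.2))
        off = Q - np.diag(np.diag(Q))
        # every positive rate must be a one-area loss
        for i, j in zip(*np.nonzero(off)):
            fb, tb = space.ranges[i].bits, space.ranges[j].bits
            assert (fb & ~tb).bit_count() == 1 and not (tb & ~fb)
        np.testing.assert_allclose(Q.sum(axis=1), 0, atol=1e-12)

    @pytest.mark.parametrize("constrained,max_size", [(False, None), (True, None), (True, 2), (False, 2)])
    def test_matches_rule_oracle(self, sys4_path, constrained, max_size):
        space = rd.enumerate_ranges(sys4_path, constrained=constrained, max_size=max_size)
        mult = rd.build_multipliers_from_graph(sys4_path)
        params = rd.DECParams(0.13, 0.045)
        Q = rd.build_generator(space, mult, params)
        Q_oracle = oracle_generator(space, mult.m, params.d, params.e)
        np.testing.assert_allclose(Q, Q_oracle, atol=1e-14)
        np.testing.assert_allclose(Q.sum(axis=1), 0, atol=1e-12)

    def test_constrained_exit_modes_differ_only_via_empty_range(self, sys4_path):
        space = rd.enumerate_ranges(sys4_path, constrained=True)
        mult = rd.uniform_multipliers(sys4_path)
        params = rd.DECParams(0.1, 0.05)
        Qa = rd.build_generator(space, mult, params, connectivity_exit="absorb")
        Qd = rd.build_generator(space, mult, params, connectivity_exit="drop")
        np.testing.assert_allclose(Qa[:, 1:] - np.diag(np.diag(Qa))[:, 1:],
                                   Qd[:, 1:] - np.diag(np.diag(Qd))[:, 1:], atol=1e-14)
        assert (Qa[:, 0] >= Qd[:, 0]).all() and (Qa[:, 0] > Qd[:, 0]).any()


class TestBranchTransition:
    def test_zero_length_branch_is_identity(self, sys2):
        space = rd.enumerate_ranges(sys2)
        epochs = rd.EpochSet.single(rd.uniform_multipliers(sys2), 10.0)
        P = rd.branch_transition(space, epochs, rd.DECParams(0.2, 0.1), 3.0, 3.0)
        np.testing.assert_allclose(P, np.eye(len(space)), atol=1e-14)

    def test_null_rates_give_identity(self, sys3):
        space = rd.enumerate_ranges(sys3)
        epochs = rd.EpochSet.single(rd.uniform_multipliers(sys3), 10.0)
        P = rd.branch_transition(space, epochs, rd.DECParams(0.0, 0.0), 9.0, 0.0)
        np.testing.assert_allclose(P, np.eye(len(space)), atol=1e-12)

    def test_matches_ode_oracle_across_epochs(self, sys2):
        space = rd.enumerate_ranges(sys2)
        m1 = rd.uniform_multipliers(sys2)
        m2 = rd.DispersalMultipliers(np.array([[1.0, 0.3], [0.7, 1.0]]))
        epochs = rd.EpochSet([5.0, 2.0], [m1, m2])
        params = rd.DECParams(0.1, 0.05)
        P = rd.branch_transition(space, epochs, params, 4.0, 1.0)
        P_ode = ode_branch(space, epochs, params.d, params.e, 4.0, 1.0)
        np.testing.assert_allclose(P, P_ode, atol=1e-8)
        np.testing.assert_allclose(P.sum(axis=1), 1, atol=1e-10)

    def test_rows_stochastic_including_empty_range(self, sys4_path):
        space = rd.enumerate_ranges(sys4_path, constrained=True)
        epochs = rd.EpochSet.single(rd.build_multipliers_from_graph(sys4_path), 20.0)
        P = rd.branch_transition(space, epochs, rd.DECParams(0.4, 0.2), 15.0, 0.0)
        np.testing.assert_allclose(P.sum(axis=1), 1, atol=1e-10)
        assert (P >= 0).all()


class TestCladoOutcomes:
    def test_single_area_sympatry(self, sys3):
        space = rd.enumerate_ranges(sys3)
        outs = rd.clado_outcomes(rd.Range(0b001), space)
        assert len(outs) == 1
        o = outs[0]
        assert o.left.bits == o.right.bits == 0b001
        assert o.prob == 1.0 and o.kind == "sympatry"

    def test_two_area_range_has_six_outcomes(self, sys3):
        space = rd.enumerate_ranges(sys3)
        outs = rd.clado_outcomes(rd.Range(0b011), space)
        assert len(outs) == 6
        assert all(o.prob == pytest.approx(1 / 6) for o in outs)
        kinds = sorted(o.kind for o in outs)
        assert kinds.count("vicariance") == 2
        assert kinds.count("subset_sympatry") == 4
        for o in outs:
            assert o.left.bits | o.right.bits == 0b011

    def test_three_area_range_has_twelve_outcomes(self, sys3):
        space = rd.enumerate_ranges(sys3)
        outs = rd.clado_outcomes(rd.Range(0b111), space)
        assert len(outs) == 12
        assert all(o.prob == pytest.approx(1 / 12) for o in outs)

    def test_constrained_space_drops_and_renormalizes(self, sys3_path):
        space = rd.enumerate_ranges(sys3_path, constrained=True)
        outs = rd.clado_outcomes(rd.Range(0b111), space)
        # vicariance B | AC is impossible (AC disconnected): 10 outcomes remain
        assert len(outs) == 10
        assert sum(o.prob for o in outs) == pytest.approx(1.0)
        assert all(o.prob == pytest.approx(1 / 10) for o in outs)

    @pytest.mark.parametrize("constrained", [False, True])
    def test_matches_enumeration_oracle(self, sys4_path, constrained):
        space = rd.enumerate_ranges(sys4_path, constrained=constrained)
        for r in space.ranges[1:]:
            got = sorted(
                (o.left.bits, o.right.bits, o.prob, o.kind)
                for o in rd.clado_outcomes(r, space)
            )
            assert got == pytest.approx(oracle_clado(r.bits, space))

    def test_empty_ancestor_rejected(self, sys3):
        space = rd.enumerate_ranges(sys3)
        with pytest.raises(ValueError, match="non-empty"):
            rd.clado_outcomes(rd.Range(0), space)


class TestTreeLikelihood:
    def test_single_area_system_certain_outcome(self):
        sys1 = make_system(1)
        space = rd.enumerate_ranges(sys1)
        tree = rd.read_newick("(a:1,b:1);")
        table = tip_table(sys1, a="A", b="A")
        epochs = rd.EpochSet.single(rd.uniform_multipliers(sys1), 1.0)
        nll = rd.tree_likelihood(tree, table, space, epochs, rd.DECParams(0.5, 0.0))
        assert nll == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self, sys2, cherry):
        space = rd.enumerate_ranges(sys2)
        epochs = rd.EpochSet.single(rd.uniform_multipliers(sys2), cherry.height)
        table = tip_table(sys2, a="A", b="AB", c="B", d="A")
        for d, e in [(0.1, 0.05), (0.5, 0.3), (0.02, 0.2)]:
            nll = rd.tree_likelihood(tree=cherry, tip_ranges=table, space=space,
                                     epochs=epochs, params=rd.DECParams(d, e))
            oracle = bruteforce_likelihood(cherry, table, space, epochs, d, e)
            assert nll == pytest.approx(oracle, rel=1e-8)

    def test_area_permutation_invariance_under_matrix_i(self, sys3, cherry):
        space = rd.enumerate_ranges(sys3)
        epochs = rd.EpochSet.single(rd.uniform_multipliers(sys3), cherry.height)
        params = rd.DECParams(0.2, 0.05)
        base = tip_table(sys3, a="A", b="AB", c="C", d="B")
        # permute (A,B,C) -> (C,A,B)
        perm = {"A": "C", "B": "A", "C": "B"}
        mapped = tip_table(
            sys3,
            **{
                k: "".join(perm[ch] for ch in v)
                for k, v in {"a": "A", "b": "AB", "c": "C", "d": "B"}.items()
            },
        )
        nll1 = rd.tree_likelihood(cherry, base, space, epochs, params)
        nll2 = rd.tree_likelihood(cherry, mapped, space, epochs, params)
        assert nll1 == pytest.approx(nll2, abs=1e-10)

    def test_multiplier_scale_confounding_with_d(self, sys3, cherry):
        space = rd.enumerate_ranges(sys3)
        table = tip_table(sys3, a="A", b="AB", c="C", d="B")
        c = 0.5
        m_full = rd.uniform_multipliers(sys3)
        m_half = rd.DispersalMultipliers(np.full((3, 3), c), validate=False)
        nll1 = rd.tree_likelihood(
            cherry, table, space, rd.EpochSet.single(m_full, 2.0), rd.DECParams(0.2 * c, 0.05)
        )
        nll2 = rd.tree_likelihood(
            cherry, table, space, rd.EpochSet.single(m_half, 2.0), rd.DECParams(0.2, 0.05)
        )
        assert nll1 == pytest.approx(nll2, abs=1e-10)

    def test_one_epoch_equals_three_identical_epochs(self, sys3, cherry):
        space = rd.enumerate_ranges(sys3)
        table = tip_table(sys3, a="A", b="AB", c="C", d="B")
        mult = rd.uniform_multipliers(sys3)
        params = rd.DECParams(0.15, 0.04)
        nll1 = rd.tree_likelihood(cherry, table, space, rd.EpochSet.single(mult, 2.0), params)
        nll3 = rd.tree_likelihood(
            cherry, table, space, rd.EpochSet.uniform([2.0, 1.2, 0.4], mult), params
        )
        assert nll1 == pytest.approx(nll3, abs=1e-10)

    def test_tip_outside_constrained_space_names_tip(self, sys3_path, cherry):
        space = rd.enumerate_ranges(sys3_path, constrained=True)
        table = tip_table(sys3_path, a="AC", b="A", c="B", d="C")
        epochs = rd.EpochSet.single(rd.uniform_multipliers(sys3_path), 2.0)
        with pytest.raises(ValueError, match="'a'"):
            rd.tree_likelihood(cherry, table, space, epochs, rd.DECParams(0.1, 0.1))


class TestFit:
    def test_identical_single_area_tips_drive_rates_to_zero(self, sys2, cherry):
        space = rd.enumerate_ranges(sys2)
        table = tip_table(sys2, a="A", b="A", c="A", d="A")
        epochs = rd.EpochSet.single(rd.uniform_multipliers(sys2), cherry.height)
        res = rd.fit_dec(cherry, table, space, epochs)
        assert res.params.d < 1e-6  # no expansion signal
        assert res.converged

    def test_refit_from_mle_is_fixed_point(self, sys2, cherry):
        space = rd.enumerate_ranges(sys2)
        table = tip_table(sys2, a="A", b="AB", c="B", d="A")
        epochs = rd.EpochSet.single(rd.uniform_multipliers(sys2), cherry.height)
        res = rd.fit_dec(cherry, table, space, epochs)
        again = rd.DECModel(cherry, table, space, epochs).fit(
            starts=((res.params.d, res.params.e),)
        )
        assert res.neg_log_likelihood - again.neg_log_likelihood < 1e-6

    def test_summary_mentions_estimates(self, sys2, cherry):
        space = rd.enumerate_ranges(sys2)
        table = tip_table(sys2, a="A", b="AB", c="B", d="A")
        epochs = rd.EpochSet.single(rd.uniform_multipliers(sys2), cherry.height)
        res = rd.fit_dec(cherry, table, space, epochs)
        text = res.summary()
        assert "-lnL" in text and "dispersal rate" in text

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            rd.DECParams(-0.1, 0.0)
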