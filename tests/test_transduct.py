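"""Gain computations: LMI route, frequency-sweep oracle, static formulas."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_stable_system
from netflux import (GRNModel, IOSubsystem, PathwayModel, SolverConfig,
                     brl_matrix, compare_conditions, hinf_oracle,
                     min_dynamic_gain, static_transductivity,
                     static_transfer, transductivity_table)
from netflux.errors import DimensionError, SingularModelError


class TestBRLMatrix:
    def test_scalar_boundary_block(self):
        """c=0.5, b=1, D=1, P=2, rho=4 sits exactly on the feasibility boundary."""
        block = brl_matrix([[0.5]], [[1.0]], [[1.0]], [[2.0]], 4.0)
        np.testing.assert_allclose(block, [[-0.5, 1.0], [1.0, -2.0]])
        assert abs(np.linalg.det(block)) < 1e-12
        assert np.max(np.linalg.eigvalsh(block)) <= 1e-12

    def test_zero_system_strictly_negative(self):
        block = brl_matrix(np.zeros((2, 2)), np.zeros((2, 1)),
                           np.zeros((1, 2)), 3.0 * np.eye(2), 1.0)
        assert np.max(np.linalg.eigvalsh(block)) < 0

    def test_symmetric_for_random_inputs(self, rng):
        for _ in range(20):
            n, m = rng.integers(1, 6), rng.integers(1, 4)
            A, B, _ = random_stable_system(rng, n, m)
            P = rng.normal(size=(n, n))
            P = P @ P.T + np.eye(n)
            block = brl_matrix(A, B, np.eye(n), P, float(rng.uniform(0.5, 5)))
            np.testing.assert_array_equal(block, block.T)

    def test_asymmetric_P_rejected(self):
        with pytest.raises(DimensionError, match="symmetric"):
            brl_matrix(np.eye(2) * 0.5, np.ones((2, 1)), np.eye(2),
                       [[1.0, 0.5], [0.0, 1.0]], 1.0)


class TestDynamicGain:
    @pytest.mark.parametrize("c,b", [(0.5, 1.0), (-0.5, 1.0), (0.9, 1.0),
                                     (-0.9, 2.0), (0.5, -3.0)])
    def test_scalar_closed_form(self, c, b):
        ch = IOSubsystem(A_sub=[[c]], B_sub=[[b]], D_out=[[1.0]])
        res = min_dynamic_gain(ch)
        expect = abs(b) / (1 - abs(c))
        assert res.feasible
        assert abs(res.gain - expect) <= 1e-4 * expect
        assert abs(res.rho_raw - expect ** 2) <= 1e-3 * expect ** 2

    def test_scalar_certificate(self):
        res = min_dynamic_gain(IOSubsystem([[0.5]], [[1.0]], [[1.0]]))
        assert abs(res.rho_raw - 4.0) < 1e-6
        np.testing.assert_allclose(res.certificate, [[2.0]], rtol=1e-4)
        block = brl_matrix([[0.5]], [[1.0]], [[1.0]], res.certificate,
                           res.rho_raw)
        assert np.max(np.linalg.eigvalsh(block)) <= 1e-8

    def test_memoryless_delay_gain_is_sigma_max_B(self, rng):
        B = rng.normal(size=(3, 2))
        ch = IOSubsystem(np.zeros((3, 3)), B, np.eye(3))
        res = min_dynamic_gain(ch)
        np.testing.assert_allclose(res.gain, np.linalg.norm(B, 2), rtol=1e-8)

    def test_two_node_flat_response(self):
        ch = IOSubsystem([[0.0, 0.5], [0.0, 0.0]], [[0.0], [1.0]], np.eye(2))
        res = min_dynamic_gain(ch)
        np.testing.assert_allclose(res.gain, np.sqrt(1.25), rtol=1e-8)

    def test_unstable_channel_reports_infinite_gain(self):
        res = min_dynamic_gain(IOSubsystem([[1.0]], [[1.0]], [[1.0]]))
        assert res.gain == np.inf and not res.feasible

    def test_agrees_with_frequency_sweep(self, rng):
        for trial in range(15):
            trng = np.random.default_rng(500 + trial)
            n = int(trng.integers(2, 7))
            A, B, D = random_stable_system(trng, n, m=int(trng.integers(1, 3)),
                                           radius=float(trng.uniform(0.3, 0.9)),
                                           p_out=None if trial % 2 else 1)
            ch = IOSubsystem(A, B, D)
            g = min_dynamic_gain(ch).gain
            o = hinf_oracle(ch, grid_size=2048)
            assert abs(g - o) / o <= 1e-3

    def test_boundary_certificate_bracketing(self, rng):
        """Feasible just above rho_min, infeasible clearly below it."""
        from netflux.transduct import _brl_certificate
        cfg = SolverConfig()
        A, B, D = random_stable_system(rng, 4, m=2)
        res = min_dynamic_gain(IOSubsystem(A, B, D))
        assert _brl_certificate(A, B, D, res.rho_raw * (1 + 1e-6), cfg) is not None
        assert _brl_certificate(A, B, D, res.rho_raw * (1 - 1e-2), cfg) is None

    def test_homogeneity_in_B(self, rng):
        A, B, D = random_stable_system(rng, 3, m=1)
        ch1 = IOSubsystem(A, B, D)
        ch3 = IOSubsystem(A, 3.0 * B, D)
        g1 = min_dynamic_gain(ch1).gain
        g3 = min_dynamic_gain(ch3).gain
        assert abs(g3 - 3 * g1) <= 1e-7 * g3

    def test_dynamic_gain_dominates_dc_gain(self, rng):
        for trial in range(10):
            trng = np.random.default_rng(900 + trial)
            A, B, D = random_stable_system(trng, 4, m=2)
            dc = np.linalg.norm(D @ np.linalg.solve(np.eye(4) - A, B), 2)
            g = min_dynamic_gain(IOSubsystem(A, B, D)).gain
            assert g >= dc - 1e-8 * max(dc, 1)


class TestOracle:
    @pytest.mark.parametrize("c,expect_at", [(0.5, 0.0), (-0.5, np.pi)])
    def test_scalar_peak_location(self, c, expect_at):
        ch = IOSubsystem([[c]], [[1.0]], [[1.0]])
        assert abs(hinf_oracle(ch) - 2.0) < 1e-9

    def test_unstable_returns_inf(self):
        assert hinf_oracle(IOSubsystem([[1.1]], [[1.0]], [[1.0]])) == np.inf


class TestStaticEngine:
    def test_c_zero_transfer_is_DB(self, rng):
        B = rng.normal(size=(3, 2))
        m = PathwayModel(C=np.zeros((3, 3)), H=np.zeros(3), B=B,
                         node_ids=["a", "b", "c"], input_ids=["u1", "u2"],
                         semantics="static")
        tm = static_transfer(m)
        np.testing.assert_allclose(tm.T, B)

    def test_scalar_static_transfer(self):
        m = PathwayModel(C=[[0.5]], H=[0.0], B=[[1.0]], node_ids=["p"],
                         input_ids=["u"], semantics="static")
        np.testing.assert_allclose(static_transfer(m).T, [[2.0]])

    def test_grn_chain_path_product(self, chain_grn):
        tm = static_transfer(chain_grn, target="g3", source="g1")
        np.testing.assert_allclose(tm.T, [[0.2]], atol=1e-15)
        res = static_transductivity(chain_grn, target="g3", source="g1")
        assert abs(res.gain - 0.2) <= 1e-15

    def test_single_edge_grn_gain_is_weight(self):
        A = np.zeros((3, 3))
        A[2, 0] = 0.7
        g = GRNModel(A=A, node_ids=["g1", "g2", "g3"], semantics="static")
        assert abs(static_transductivity(g, target="g3", source="g1").gain
                   - 0.7) < 1e-15

    def test_scaling_B_scales_gain(self, rng):
        C = rng.normal(size=(3, 3)) * 0.2
        B = rng.normal(size=(3, 2))
        kw = dict(H=np.zeros(3), node_ids=["a", "b", "c"],
                  input_ids=["u1", "u2"], semantics="static")
        g1 = static_transductivity(PathwayModel(C=C, B=B, **kw)).gain
        g3 = static_transductivity(PathwayModel(C=C, B=3 * B, **kw)).gain
        assert abs(g3 - 3 * g1) <= 1e-9 * g3

    def test_all_output_gain_sigma_max(self):
        m = PathwayModel(C=[[0.0, 0.5], [0.0, 0.0]], H=[0, 0], B=[[0.0], [1.0]],
                         node_ids=["a", "b"], input_ids=["u"], semantics="static")
        np.testing.assert_allclose(static_transductivity(m).gain,
                                   np.sqrt(1.25), rtol=1e-12)

    def test_singular_raises(self):
        m = PathwayModel(C=[[1.0]], H=[0.0], B=[[1.0]], node_ids=["p"],
                         input_ids=["u"], semantics="static")
        with pytest.raises(SingularModelError):
            static_transfer(m)


class TestTables:
    def _static_model(self, rng, n=3, l=2):
        C = rng.normal(size=(n, n)) * 0.2
        return PathwayModel(C=C, H=rng.normal(size=n),
                            B=rng.normal(size=(n, l)),
                            node_ids=[f"p{i}" for i in range(n)],
                            input_ids=[f"u{j}" for j in range(l)],
                            semantics="static")

    def test_batch_equals_single_calls(self, rng):
        m = self._static_model(rng)
        table = transductivity_table(m, targets=["p0", "p2"])
        assert len(table) == 2
        for _, row in table.iterrows():
            single = static_transductivity(m, target=row["target"])
            assert row["gain"] == pytest.approx(single.gain, rel=1e-12)

    def test_per_input_columns_match_scalar_formula(self, rng):
        m = self._static_model(rng)
        table = transductivity_table(m, targets=["p1"], per_input=True)
        assert len(table) == 2
        for _, row in table.iterrows():
            expect = static_transductivity(m, target="p1",
                                           source=row["source"]).gain
            assert row["gain"] == pytest.approx(expect, rel=1e-12)

    def test_full_output_dominates_single_nodes(self, rng):
        for trial in range(10):
            trng = np.random.default_rng(300 + trial)
            m = self._static_model(trng, n=4)
            full = static_transductivity(m).gain
            for node in m.node_ids:
                assert static_transductivity(m, target=node).gain <= full + 1e-12

    def test_selector_bound_dynamic(self, rng):
        A, B, _ = random_stable_system(rng, 4, m=2)
        full = min_dynamic_gain(IOSubsystem(A, B, np.eye(4))).gain
        e1 = np.zeros((1, 4))
        e1[0, 1] = 1.0
        single = min_dynamic_gain(IOSubsystem(A, B, e1)).gain
        assert single <= full + 1e-8 * full


class TestCompareConditions:
    def _tables(self, rng):
        m = TestTables._static_model(TestTables(), rng)
        return transductivity_table(m), m

    def test_identical_tables_all_unchanged(self, rng):
        t, _ = self._tables(rng)
        cmp = compare_conditions(t, t)
        assert np.all(cmp["diff"] == 0.0)
        assert np.all(cmp["ratio"] == 1.0)
        assert np.all(cmp["flag"] == "unchanged")

    def test_weakened_edge_flags_downstream_only(self):
        """Halving one pathway edge changes exactly the downstream targets."""
        from netflux import perturb_edge
        # u -> p0 -> p1 -> p2 ; separate branch u -> p3
        C = np.zeros((4, 4))
        C[1, 0] = 0.6
        C[2, 1] = 0.5
        B = np.zeros((4, 1))
        B[0, 0] = 1.0
        B[3, 0] = 0.8
        m_a = PathwayModel(C=C, H=np.zeros(4), B=B,
                           node_ids=["p0", "p1", "p2", "p3"], input_ids=["u"],
                           semantics="static")
        m_b = perturb_edge(m_a, "p1", "p2", 0.5)
        cmp = compare_conditions(transductivity_table(m_a),
                                 transductivity_table(m_b))
        by_target = cmp.set_index("target")
        assert by_target.loc["p2", "flag"] == "loss-of-transductivity"
        assert by_target.loc["p2", "ratio"] == pytest.approx(0.5)
        for unaffected in ("p0", "p1", "p3"):
            assert by_target.loc[unaffected, "flag"] == "unchanged"
            assert by_target.loc[unaffected, "ratio"] == pytest.approx(1.0)

    def test_mismatched_channels_error_lists_difference(self, rng):
        t, m = self._tables(rng)
        with pytest.raises(DimensionError, match="p0"):
            compare_conditions(t, t[t["target"] != "p0"])

    def test_zero_denominator_protected(self):
        t = pd.DataFrame({"channel": ["x"], "source": ["s"], "target": ["t"],
                          "gain": [0.0]})
        t2 = t.assign(gain=[1.0])
        cmp = compare_conditions(t, t2)
        assert cmp["ratio"].iloc[0] == np.inf
        assert cmp["zero_denominator"].iloc[0]
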