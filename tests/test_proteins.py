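import numpy as np
import pytest

from lassokit.proteins import (
    ChainNotFoundError,
    LoopReport,
    chain_threading_probability,
    classify_protein_lasso,
    expected_vs_observed,
    extract_lassos,
    read_chain,
    select_candidates,
    threading_probability,
)
from lassokit.stats import SurfaceFitParams
from lassokit.surface import LassoClassLabel

from conftest import threaded_lasso_ca_trace, write_synthetic_lasso_pdb


@pytest.fixture
def surface_fit():
    """Synthetic probability-surface parameters with positive rates."""
    return SurfaceFitParams(
        p_inf=0.19,
        c_alpha_t=0.3, alpha_t=0.08,
        c_alpha_n=0.25, alpha_n=0.05,
        c_beta_t=0.1, beta_t=0.006,
        c_beta_n=0.15, beta_n=0.009,
        covariance=np.empty((0, 0)),
    )


@pytest.fixture
def lasso_pdb(tmp_path):
    coords = threaded_lasso_ca_trace(40, (5, 30))
    path = tmp_path / "lasso.pdb"
    write_synthetic_lasso_pdb(path, coords, bridge=(5, 30))
    return path


class TestReadChain:
    def test_ssbond_record(self, lasso_pdb):
        chain = read_chain(lasso_pdb, "A")
        assert chain.n_residues == 40
        assert chain.bridges == [(5, 30)]

    def test_geometric_sg_detection(self, tmp_path):
        coords = threaded_lasso_ca_trace(40, (5, 30))
        path = tmp_path / "nossbond.pdb"
        write_synthetic_lasso_pdb(
            path, coords, bridge=(5, 30), ssbond_record=False, sg_atoms=True
        )
        chain = read_chain(path, "A")
        assert chain.bridges == [(5, 30)]

    def test_no_cysteines_no_bridges(self, tmp_path):
        coords = threaded_lasso_ca_trace(20, (3, 15))
        path = tmp_path / "plain.pdb"
        write_synthetic_lasso_pdb(path, coords, bridge=None)
        chain = read_chain(path, "A")
        assert chain.bridges == []

    def test_missing_chain_raises(self, lasso_pdb):
        with pytest.raises(ChainNotFoundError):
            read_chain(lasso_pdb, "B")

    def test_extra_bridges_accepted(self, tmp_path):
        coords = threaded_lasso_ca_trace(30, (4, 20))
        path = tmp_path / "amide.pdb"
        write_synthetic_lasso_pdb(path, coords, bridge=None)
        chain = read_chain(path, "A", extra_bridges=[(4, 20)])
        assert chain.bridges == [(4, 20)]


class TestExtraction:
    def test_partition_arithmetic(self, lasso_pdb):
        chain = read_chain(lasso_pdb, "A")
        loops = extract_lassos(chain)
        assert len(loops) == 1
        bl = loops[0]
        assert bl.n == 26
        assert bl.tail_lengths == (4, 10)
        # loop + tails partition the chain
        assert bl.n + sum(bl.tail_lengths) == chain.n_residues

    def test_terminal_bridge_no_tails(self, tmp_path):
        coords = threaded_lasso_ca_trace(40, (1, 40))
        path = tmp_path / "full.pdb"
        write_synthetic_lasso_pdb(path, coords, bridge=(1, 40))
        bl = extract_lassos(read_chain(path, "A"))[0]
        assert bl.n == 40
        assert bl.tail_lengths == (0, 0)
        assert bl.tails == []

    def test_two_bridges_two_loops(self, tmp_path):
        coords = threaded_lasso_ca_trace(40, (5, 30))
        path = tmp_path / "two.pdb"
        write_synthetic_lasso_pdb(path, coords, bridge=(5, 30))
        chain = read_chain(path, "A", extra_bridges=[(8, 25)])
        assert len(extract_lassos(chain)) == 2


class TestClassification:
    def test_threaded_fixture_is_l1(self, lasso_pdb):
        chain = read_chain(lasso_pdb, "A")
        bl = extract_lassos(chain)[0]
        label, _ = classify_protein_lasso(bl)
        assert label.label == "L1"

    def test_unthreaded_fixture_is_l0(self, tmp_path):
        coords = threaded_lasso_ca_trace(40, (5, 30)).copy()
        # push the C-tail sideways so it no longer passes through the loop
        coords[30:, 0] += 3.0
        coords[30:, 2] = -0.5
        path = tmp_path / "trivial.pdb"
        write_synthetic_lasso_pdb(path, coords, bridge=(5, 30))
        bl = extract_lassos(read_chain(path, "A"))[0]
        label, _ = classify_protein_lasso(bl)
        assert label.label == "L0"


class TestThreadingProbability:
    def test_inclusion_exclusion_hand_case(self, surface_fit):
        from lassokit.proteins import BridgeLoop

        # two tails with p1 = p2 = 0.5 -> P(>=1) = 0.75; realise by
        # patching per-tail probabilities through a stub fit
        class Stub:
            p_inf = 0.19

            def __call__(self, n, t):
                return np.float64(0.5)

        bl = BridgeLoop(
            loop_coords=np.zeros((10, 3)), n=10, tails=[None, None],
            tail_lengths=(5, 5), bridge=(1, 10),
        )
        est = threading_probability(bl, Stub())
        assert est.p_any == pytest.approx(0.75)

    def test_no_tails_no_threading(self, surface_fit):
        from lassokit.proteins import BridgeLoop

        bl = BridgeLoop(
            loop_coords=np.zeros((10, 3)), n=10, tails=[],
            tail_lengths=(0, 0), bridge=(1, 10),
        )
        est = threading_probability(bl, surface_fit)
        assert est.p_any == 0.0

    def test_asymptotic_tail(self, surface_fit):
        from lassokit.proteins import BridgeLoop

        bl = BridgeLoop(
            loop_coords=np.zeros((10, 3)), n=10**6, tails=[None],
            tail_lengths=(10**6, 0), bridge=(1, 10),
        )
        est = threading_probability(bl, surface_fit)
        assert est.p_any == pytest.approx(1 - surface_fit.p_inf, abs=1e-6)

    def test_monotone_in_tail_length(self, surface_fit):
        """P(>=1) never decreases as a tail grows, at fixed loop size."""
        from lassokit.proteins import BridgeLoop

        ps = []
        for t in (1, 5, 20, 80, 300):
            bl = BridgeLoop(
                loop_coords=np.zeros((10, 3)), n=50, tails=[None],
                tail_lengths=(t, 0), bridge=(1, 10),
            )
            ps.append(threading_probability(bl, surface_fit).p_any)
        assert all(b >= a - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_chain_inclusion_exclusion(self, surface_fit):
        from lassokit.proteins import ThreadingEstimate

        ests = [
            ThreadingEstimate((0.5,), 0.5, 0.5),
            ThreadingEstimate((0.5,), 0.5, 0.5),
        ]
        assert chain_threading_probability(ests) == pytest.approx(0.75)


class TestSelection:
    def _report(self, n_pierce, p):
        from lassokit.proteins import BridgeLoop, ThreadingEstimate

        return LoopReport(
            loop=BridgeLoop(np.zeros((5, 3)), 5, [], (0, 0), (1, 5)),
            label=LassoClassLabel(f"L{n_pierce}" if n_pierce else "L0", n_pierce),
            estimate=ThreadingEstimate((p,), p, p),
        )

    def test_selection_rules(self):
        reports = [
            self._report(1, 0.1),   # selected
            self._report(1, 0.5),   # observed but probable
            self._report(0, 0.05),  # improbable but trivial
        ]
        selected = select_candidates(reports, threshold=0.2)
        assert len(selected) == 1
        assert selected[0] is reports[0]
        assert [r.candidate for r in reports] == [True, False, False]


class TestExpectedVsObserved:
    def test_expected_sum(self):
        df = expected_vs_observed(
            chain_lengths=[100] * 10,
            p_any=[0.3] * 10,
            observed_nontrivial=[True] * 3 + [False] * 7,
            bin_width=50,
        )
        assert len(df) == 1
        assert df["expected"].iloc[0] == pytest.approx(3.0)
        assert df["observed"].iloc[0] == 3

    def test_empty_bins_omitted(self):
        df = expected_vs_observed([40, 400], [0.1, 0.2], [False, True], bin_width=50)
        assert set(df["bin"]) == {0, 400}

    def test_all_trivial(self):
        df = expected_vs_observed([60, 70, 80], [0.2] * 3, [False] * 3)
        assert (df["observed"] == 0).all()
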