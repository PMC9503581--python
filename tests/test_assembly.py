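import numpy as np
import pytest

from ssassign.assembly import (
    assemble,
    assess_quality,
    attach_correlations,
    find_roots,
    gate_quality,
    optimize_tolerances,
)
from ssassign.config import PipelineConfig
from ssassign.model import Peak, PeakList, ProteinSequence, RootTriple
from ssassign.profiles import get_profile
from ssassign.synth import SyntheticOptions, generate_peaklists
from tests.conftest import BENCHMARK_EXPERIMENTS


def _pl(name, rows):
    profile = get_profile(name)
    return PeakList(profile.name, profile.dimensionality, profile.axis_nuclei,
                    [Peak(tuple(r)) for r in rows])


class TestFindRoots:
    def test_direct_canco_readoff(self):
        pl = _pl("CANCO", [[54.9, 120.3, 176.0]])
        roots = find_roots([pl], 0.2, 0.3)
        assert len(roots) == 1
        r = roots[0]
        assert (r.co_prev, r.n, r.ca) == pytest.approx((176.0, 120.3, 54.9))

    def test_join_nco_nca(self):
        # join oracle: single pair sharing the nitrogen within tolerance
        nco = _pl("NCO", [[120.3, 176.0]])
        nca = _pl("NCA", [[120.3, 54.9]])
        roots = find_roots([nco, nca], 0.2, 0.3)
        assert len(roots) == 1
        r = roots[0]
        assert (r.co_prev, r.n, r.ca) == pytest.approx((176.0, 120.3, 54.9))

    def test_join_outside_tolerance(self):
        nco = _pl("NCO", [[120.3, 176.0]])
        nca = _pl("NCA", [[121.0, 54.9]])
        assert find_roots([nco, nca], 0.2, 0.3) == []

    def test_near_duplicates_merge(self):
        # merge oracle: all coordinates within tolerance -> one centroid root
        pl = _pl("CANCO", [[54.90, 120.30, 176.00], [54.91, 120.31, 176.01]])
        roots = find_roots([pl], 0.2, 0.3)
        assert len(roots) == 1
        assert roots[0].ca == pytest.approx(54.905)
        assert roots[0].weight == 2

    def test_no_roots_is_empty_not_error(self):
        assert find_roots([_pl("NCA", [[120.0, 55.0]])], 0.2, 0.3) == []


class TestAttachCorrelations:
    def root(self):
        return RootTriple(co_prev=176.0, n=120.3, ca=54.9)

    def test_ncacb_fills_own_cb(self):
        pl = _pl("NCACB-3D", [[120.3, 54.9, 31.2]])
        m = attach_correlations([self.root()], [pl], 0.2, 0.3)
        assert m.systems[0].own["CB"] == pytest.approx(31.2)

    def test_ncocacb_fills_prev(self):
        # strip carries CA(i-1) and CB(i-1); with a direct CA(i-1) anchor
        # from NCOCA both are named
        ncoca = _pl("NCOCA", [[120.3, 176.0, 58.3]])
        ncocacb = _pl("NCOCACB", [[120.3, 176.0, 58.3], [120.3, 176.0, 29.9]])
        m = attach_correlations([self.root()], [ncoca, ncocacb], 0.2, 0.3)
        assert m.systems[0].prev["CA"] == pytest.approx(58.3)
        assert m.systems[0].prev["CB"] == pytest.approx(29.9)

    def test_bare_root(self):
        m = attach_correlations([self.root()], [], 0.2, 0.3)
        s = m.systems[0]
        assert s.own == {"CA": pytest.approx(54.9)}
        assert s.prev == {"C": pytest.approx(176.0)}
        assert s.own_cx == [] and s.prev_cx == []

    def test_ncacx_fills_cx_bag(self):
        pl = _pl("NCACX", [[120.3, 54.9, 31.2], [120.3, 54.9, 24.7]])
        m = attach_correlations([self.root()], [pl], 0.2, 0.3)
        assert m.systems[0].own_cx == pytest.approx([24.7, 31.2])

    def test_support_audit_trail(self):
        pl = _pl("NCACB-3D", [[120.3, 54.9, 31.2]])
        m = attach_correlations([self.root()], [pl], 0.2, 0.3)
        sup = m.systems[0].support
        assert any(c.experiment == "NCACB-3D" and c.atom == "CB" for c in sup)


class TestAssessQuality:
    def test_clean_data_quality_one(self, seq24, clean_lists24, stats):
        m = assemble(clean_lists24, 0.2, 0.3, stats)
        q = assess_quality(m, seq24)
        assert q == pytest.approx(1.0)

    def test_no_peaks_quality_zero(self, seq24):
        m = assemble([], 0.2, 0.3)
        assert assess_quality(m, seq24) == 0.0

    def test_half_systems_removed(self, seq24, clean_lists24, stats):
        m = assemble(clean_lists24, 0.2, 0.3, stats)
        kept = m.systems[::2]
        for i, s in enumerate(kept):
            s.id = i
        m.systems = kept
        from ssassign.engine import link_spin_systems
        links = link_spin_systems(m, 0.2)
        q = assess_quality(m, seq24, links=links)
        q_sys = len(kept) / (len(seq24) - 1)
        q_link = min(len(links) / (len(seq24) - 2),
                     (len(seq24) - 2) / max(1, len(links)))
        assert q == pytest.approx(np.sqrt(q_sys * q_link))

    def test_empty_sequence_error(self):
        m = assemble([], 0.2, 0.3)
        with pytest.raises(ValueError):
            assess_quality(m, ProteinSequence(""))


class TestOptimizeTolerances:
    def test_clean_picks_smallest_grid_point(self, seq24, clean_lists24, stats):
        matrix, tol, trace = optimize_tolerances(clean_lists24, seq24,
                                                 stats=stats)
        assert tol == (0.2, 0.3)
        assert matrix.quality == pytest.approx(1.0)
        assert len(trace) == 9

    def test_empty_peak_lists(self, seq24):
        matrix, tol, trace = optimize_tolerances([], seq24)
        assert matrix.quality == 0.0
        assert all(q == 0.0 for _, q in trace)
        assert len(matrix.systems) == 0

    @pytest.mark.slow
    def test_jittered_data_prefers_wider_carbon_tolerance(self, seq24,
                                                          table24, stats):
        # Monte-Carlo: with 0.15 ppm carbon jitter the 0.2 grid point should
        # lose to a wider tolerance in the majority of seeds
        profiles = [get_profile(e) for e in BENCHMARK_EXPERIMENTS]
        wider = 0
        n_seeds = 20
        for seed in range(n_seeds):
            lists = list(generate_peaklists(
                table24, seq24, profiles,
                SyntheticOptions(jitter_c=0.15, seed=seed)).values())
            _, tol, _ = optimize_tolerances(lists, seq24, stats=stats)
            if tol[0] >= 0.35:
                wider += 1
        assert wider > n_seeds / 2


class TestGateQuality:
    def test_high_quality_proceeds(self):
        assert gate_quality(1.0, 0.3).proceed

    def test_zero_terminates_with_message(self):
        d = gate_quality(0.0, 0.3)
        assert not d.proceed
        assert "more information is required" in d.message

    def test_boundary_is_closed(self):
        assert gate_quality(0.3, 0.3).proceed


class TestDeterminism:
    def test_assembly_deterministic(self, clean_lists24, stats):
        m1 = assemble(clean_lists24, 0.2, 0.3, stats)
        m2 = assemble(clean_lists24, 0.2, 0.3, stats)
        snap = lambda m: [(s.root.n, s.root.ca, sorted(s.own.items()),
                           sorted(s.prev.items()), s.own_cx, s.prev_cx)
                          for s in m.systems]
        assert snap(m1) == snap(m2)

    def test_monotone_in_true_peaks(self, seq24, table24, stats):
        # adding expected peaks never lowers quality on clean data
        profiles = [get_profile(e) for e in BENCHMARK_EXPERIMENTS]
        full = list(generate_peaklists(table24, seq24, profiles,
                                       SyntheticOptions(seed=5)).values())
        partial = [PeakList(pl.experiment_name, pl.dimensionality,
                            pl.axis_nuclei, pl.peaks[:len(pl.peaks) // 2])
                   for pl in full]
        q_partial = assess_quality(assemble(partial, 0.2, 0.3, stats), seq24)
        q_full = assess_quality(assemble(full, 0.2, 0.3, stats), seq24)
        assert q_full >= q_partial
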