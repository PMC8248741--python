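import numpy as np
import pytest
from scipy.integrate import solve_ivp

from p2ca.bifurcation import (OscillatoryRegion, classify_trajectory,
                              fast_equilibrium, fast_rhs, map_region)
from p2ca.params import ModelParameters
from p2ca.simulation import Protocol, equilibrate, run_protocol


@pytest.fixture(scope="module")
def region(params):
    return map_region(resolution=(60, 60), p=params)


def simulate_fast(ip3, ca_er, p, ca0, h0, t_end=400.0):
    f = fast_rhs(ip3, ca_er, p)
    sol = solve_ivp(lambda t, y: f(y[0], y[1]), (0, t_end), [ca0, h0],
                    method="LSODA", rtol=1e-9, atol=1e-11, dense_output=False,
                    t_eval=np.linspace(0, t_end, 4000))
    return sol.t, sol.y[0]


def late_amplitude(ip3, ca_er, p, window=0.25, t_end=400.0):
    """Peak-to-peak amplitude of the fast-subsystem attractor."""
    pt = fast_equilibrium(ip3, ca_er, p)
    t, ca = simulate_fast(ip3, ca_er, p, pt.ca_i * 1.05 + 1e-3, pt.h, t_end)
    tail = ca[int((1 - window) * len(ca)):]
    return float(np.ptp(tail))


class TestFastEquilibrium:
    def test_closed_ip3r_always_stable(self, params):
        # without IP3 the release channel is shut: the fast subsystem has a
        # unique stable equilibrium for any store content
        for ca_er in (5.0, 30.0, 63.0, 200.0):
            pt = fast_equilibrium(0.0, ca_er, params)
            assert not pt.oscillatory
            assert pt.eigenvalues.real.max() < 0

    def test_negative_parameters_rejected(self, params):
        with pytest.raises(ValueError):
            fast_equilibrium(-0.1, 50.0, params)

    def test_equilibrium_is_fixed_point(self, params):
        pt = fast_equilibrium(0.4, 30.0, params)
        f = fast_rhs(0.4, 30.0, params)
        dca, dh = f(pt.ca_i, pt.h)
        assert abs(dca) < 1e-9 and abs(dh) < 1e-9


class TestRegion:
    def test_region_nonempty_with_boundary(self, region):
        assert region.oscillatory.sum() > 0
        assert region.flagged == 0
        assert len(region.boundary) >= 1

    def test_empty_region_without_cicr(self, params):
        reg0 = map_region(resolution=(15, 15),
                          p=params.replace(v_ip3r=0.0))
        assert reg0.oscillatory.sum() == 0

    def test_boundary_periods_physiological(self, region, params):
        # linear frequency at Hopf points corresponds to periods of
        # seconds to tens of seconds
        poly = max(region.boundary, key=len)
        for ip3, ca_er in poly[:: max(1, len(poly) // 6)]:
            pt = fast_equilibrium(float(ip3), float(ca_er), params)
            if pt.frequency_hz > 0:
                period = 1.0 / pt.frequency_hz
                assert 2.0 < period < 80.0

    def test_classification_agrees_with_simulation(self, region, params, rng):
        # oracle: long-run integration of the fast subsystem shows a limit
        # cycle iff the linearization predicts an unstable focus
        osc_idx = np.argwhere(region.oscillatory)
        sta_idx = np.argwhere(~region.oscillatory & (region.re_lambda < -1e-3))
        pick_o = osc_idx[rng.choice(len(osc_idx), 3, replace=False)]
        pick_s = sta_idx[rng.choice(len(sta_idx), 3, replace=False)]
        for i, j in pick_o:
            amp = late_amplitude(region.ip3_grid[i], region.ca_er_grid[j], params)
            assert amp > 1e-3, "predicted oscillatory but trajectory settled"
        for i, j in pick_s:
            amp = late_amplitude(region.ip3_grid[i], region.ca_er_grid[j], params)
            assert amp < 1e-4, "predicted stable but trajectory oscillates"

    def test_hopf_crossing_switches_dynamics(self, region, params):
        # nudging Ca_ER +/-5% across a boundary point toggles damped vs
        # sustained oscillations
        poly = max(region.boundary, key=len)
        ip3_b, ca_er_b = poly[len(poly) // 2]
        inner = fast_equilibrium(float(ip3_b), float(ca_er_b) * 0.95, params)
        outer = fast_equilibrium(float(ip3_b), float(ca_er_b) * 1.05, params)
        # one side must be oscillatory and the other not (direction depends
        # on which branch of the boundary was hit)
        assert inner.oscillatory != outer.oscillatory
        osc, sta = (inner, outer) if inner.oscillatory else (outer, inner)
        amp_osc = late_amplitude(osc.ip3, osc.ca_er, params)
        amp_sta = late_amplitude(sta.ip3, sta.ca_er, params)
        assert amp_osc > 10 * max(amp_sta, 1e-6)

    def test_supercritical_amplitude_grows_from_zero(self, region, params):
        # limit-cycle amplitude grows continuously from zero across the
        # boundary (supercritical Hopf): with the Hopf point located by
        # bisection, amplitudes just inside are small and grow with the
        # distance into the region (~sqrt scaling)
        poly = max(region.boundary, key=len)
        ip3_b, ca_er_b = (float(v) for v in poly[len(poly) // 2])
        inner, outer = ca_er_b * 0.9, ca_er_b * 1.1
        if not fast_equilibrium(ip3_b, inner, params).oscillatory:
            inner, outer = outer, inner
        assert fast_equilibrium(ip3_b, inner, params).oscillatory
        assert not fast_equilibrium(ip3_b, outer, params).oscillatory
        inward = np.sign(inner - outer) * ca_er_b  # unit step into the region
        for _ in range(40):   # bisection on the eigenvalue real part
            mid = 0.5 * (inner + outer)
            if fast_equilibrium(ip3_b, mid, params).oscillatory:
                inner = mid
            else:
                outer = mid
        hopf = 0.5 * (inner + outer)
        amps = [late_amplitude(ip3_b, hopf + eps * inward, params,
                               t_end=800.0)
                for eps in (0.01, 0.04, 0.16)]
        assert amps[0] < amps[1] < amps[2]
        assert amps[0] < 0.55 * amps[2]

    def test_refinement_stability(self, params, region):
        # the oscillatory mask is stable under refinement up to one coarse
        # cell around the boundary
        coarse = map_region(resolution=(30, 30), p=params)
        fine_on_coarse = np.zeros_like(coarse.oscillatory)
        for a, ip3 in enumerate(coarse.ip3_grid):
            i = np.argmin(np.abs(region.ip3_grid - ip3))
            for b, ca in enumerate(coarse.ca_er_grid):
                j = np.argmin(np.abs(region.ca_er_grid - ca))
                fine_on_coarse[a, b] = region.oscillatory[i, j]
        disagree = coarse.oscillatory ^ fine_on_coarse
        # disagreements may only hug the boundary of the coarse mask
        from scipy.ndimage import binary_dilation
        edge = binary_dilation(coarse.oscillatory) & ~coarse.oscillatory
        edge |= binary_dilation(~coarse.oscillatory) & coarse.oscillatory
        assert (disagree & ~edge).sum() == 0


class TestTrajectoryClassification:
    def test_low_dose_stays_outside(self, params, region):
        rest = equilibrate(params, knockout="p2x7")
        res = run_protocol(Protocol(atp=1e-7, knockout="p2x7"), params, rest)
        label, dwell = classify_trajectory(res, region)
        assert label == "outside" and dwell == 0.0

    def test_moderate_dose_dwells(self, params, region):
        rest = equilibrate(params, knockout="p2x7")
        res = run_protocol(Protocol(atp=1e-5, knockout="p2x7"), params, rest)
        label, dwell = classify_trajectory(res, region)
        assert label == "dwells" and dwell >= 10.0

    def test_synthetic_brief_crossing_transits(self, region):
        # a trajectory that only clips the oscillatory region for a few
        # seconds is labelled as transiting
        from types import SimpleNamespace
        ii, jj = np.argwhere(region.oscillatory).T
        ip3_in = region.ip3_grid[ii[len(ii) // 2]]
        ca_in = region.ca_er_grid[jj[len(jj) // 2]]
        n = 1200
        ip3 = np.full(n, region.ip3_grid[0])
        ca = np.full(n, region.ca_er_grid[-1])
        ip3[:30] = ip3_in
        ca[:30] = ca_in      # 3 s inside
        states = np.zeros((n, 16))
        states[:, 2] = ip3
        states[:, 1] = ca
        res = SimpleNamespace(time=np.arange(n) * 0.1, states=states,
                              ip3=ip3, ca_er=ca)
        label, dwell = classify_trajectory(res, region)
        assert label == "transits"
        assert 0 < dwell < 10.0
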