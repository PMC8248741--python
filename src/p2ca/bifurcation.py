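"""Slow-fast analysis: mapping the oscillatory region of the IP₃R subsystem.

[IP₃] and [Ca²⁺]_ER vary on timescales of minutes while cytosolic Ca²⁺ and
the IP₃R inactivation gate h relax within seconds.  Freezing the slow pair as
parameters (and dropping the P2X7 flux, i.e. the P2Y2-only submodel) leaves a
two-variable fast subsystem

    dCa_i/dt = f_c (J_INleak − J_PMCA + J_IP3R + J_ERleak − J_SERCA)
    dh/dt    = (h∞ − h)/τ_h

whose equilibria and their stability organize the response repertoire: where
the equilibrium is an unstable focus the fast subsystem orbits a limit cycle
(Ca²⁺ oscillations); elsewhere it sits at a stable steady state.  The
boundary, where a complex eigenvalue pair crosses the imaginary axis, is a
Hopf bifurcation curve in the (IP₃, Ca_ER) plane.  Full-model trajectories
projected onto this plane either stay outside the oscillatory region (low
dose), dwell inside it (intermediate dose, sustained oscillations) or cross
it briefly (high dose, wide transient).

Equilibria are located by a dense sign-scan over Ca_i followed by Brent
bracketing (at equilibrium h = h∞(Ca_i), reducing the problem to one
dimension); eigenvalues come from the analytic structure via central finite
differences of the 2-D vector field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from skimage import measure

from .params import ModelParameters
from .simulation import SimulationResult, resting_closed_form

__all__ = ["FastSubsystemPoint", "OscillatoryRegion", "fast_equilibrium",
           "map_region", "classify_trajectory", "fast_rhs"]


def fast_rhs(ip3: float, ca_er: float, p: ModelParameters):
    """The 2-D fast subsystem f(ca_i, h) at frozen (IP₃, Ca_ER), J_P2X7 = 0."""
    m_inf = ip3 / (ip3 + p.d1)
    q2_gate = p.d2 * (ip3 + p.d1) / (ip3 + p.d3)

    def f(ca_i: float, h: float) -> tuple[float, float]:
        ca = ca_i if ca_i > 0 else 0.0
        n_inf = ca / (ca + p.d5)
        j_ip3r = p.v_ip3r * (m_inf * n_inf * h) ** 3 * (ca_er - ca)
        j_erleak = p.v_erleak * (ca_er - ca)
        j_pmca = p.v_pmca * ca * ca / (ca * ca + p.k_pmca**2)
        j_serca = p.v_serca * ca * ca / (ca * ca + p.k_serca**2)
        dca = p.f_c * (p.j_inleak + j_ip3r + j_erleak - j_pmca - j_serca)
        h_inf = q2_gate / (q2_gate + ca)
        dh = (h_inf - h) * p.a2 * (q2_gate + ca)
        return dca, dh

    return f


@dataclass
class FastSubsystemPoint:
    """Fast-subsystem equilibrium at one (IP₃, Ca_ER) parameter point."""

    ip3: float
    ca_er: float
    ca_i: float
    h: float
    eigenvalues: np.ndarray
    n_equilibria: int = 1

    @property
    def oscillatory(self) -> bool:
        """Unstable focus: positive real part with nonzero imaginary part."""
        lead = self.eigenvalues[np.argmax(self.eigenvalues.real)]
        return bool(lead.real > 0 and abs(lead.imag) > 0)

    @property
    def frequency_hz(self) -> float:
        """Linear oscillation frequency |Im λ|/2π at the equilibrium."""
        return float(np.abs(self.eigenvalues.imag).max() / (2 * np.pi))


@dataclass
class OscillatoryRegion:
    """Grid classification of the (IP₃, Ca_ER) plane with Hopf boundary."""

    ip3_grid: np.ndarray
    ca_er_grid: np.ndarray
    re_lambda: np.ndarray        # (n_ip3, n_ca_er) leading real part
    im_lambda: np.ndarray
    oscillatory: np.ndarray      # boolean mask
    boundary: list = field(default_factory=list)  # list of (n,2) arrays [ip3, ca_er]
    flagged: int = 0

    def contains(self, ip3, ca_er) -> np.ndarray:
        """Membership of points in the oscillatory region.

        Bilinear interpolation of the leading eigenvalue real part; points
        outside the scanned window are classified as non-oscillatory.
        """
        from scipy.interpolate import RegularGridInterpolator
        interp = RegularGridInterpolator(
            (self.ip3_grid, self.ca_er_grid), self.re_lambda,
            bounds_error=False, fill_value=-1.0)
        pts = np.column_stack([np.atleast_1d(ip3), np.atleast_1d(ca_er)])
        return interp(pts) > 0

    def to_csv(self, path: str | Path) -> None:
        ii, jj = np.meshgrid(range(len(self.ip3_grid)),
                             range(len(self.ca_er_grid)), indexing="ij")
        df = pd.DataFrame({
            "ip3": self.ip3_grid[ii.ravel()],
            "ca_er": self.ca_er_grid[jj.ravel()],
            "re_lambda": self.re_lambda.ravel(),
            "im_lambda": self.im_lambda.ravel(),
            "oscillatory": self.oscillatory.ravel().astype(int),
        })
        df.to_csv(path, index=False)

    def boundary_to_csv(self, path: str | Path) -> None:
        frames = []
        for k, poly in enumerate(self.boundary):
            frames.append(pd.DataFrame(
                {"segment": k, "ip3": poly[:, 0], "ca_er": poly[:, 1]}))
        out = (pd.concat(frames) if frames
               else pd.DataFrame(columns=["segment", "ip3", "ca_er"]))
        out.to_csv(path, index=False)


def _equilibrium_candidates(ip3: float, ca_er: float, p: ModelParameters,
                            n_scan: int = 400) -> list[float]:
    """All fixed points of the reduced 1-D problem g(ca) = dCa/dt|_{h=h∞}."""
    f = fast_rhs(ip3, ca_er, p)

    def g(ca: float) -> float:
        q2_gate = p.d2 * (ip3 + p.d1) / (ip3 + p.d3)
        return f(ca, q2_gate / (q2_gate + ca))[0]

    grid = np.logspace(-4, np.log10(max(ca_er, 10.0)), n_scan)
    vals = np.array([g(c) for c in grid])
    roots = []
    sign = np.sign(vals)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-12))
    # exact zeros on the grid (rare)
    roots.extend(grid[vals == 0.0])
    return sorted(roots)


def _jacobian(f, ca: float, h: float, rel: float = 1e-6) -> np.ndarray:
    d_ca = max(abs(ca), 1e-3) * rel
    d_h = max(abs(h), 1e-3) * rel
    f_ca_p, f_ca_m = f(ca + d_ca, h), f(ca - d_ca, h)
    f_h_p, f_h_m = f(ca, h + d_h), f(ca, h - d_h)
    return np.array([
        [(f_ca_p[0] - f_ca_m[0]) / (2 * d_ca), (f_h_p[0] - f_h_m[0]) / (2 * d_h)],
        [(f_ca_p[1] - f_ca_m[1]) / (2 * d_ca), (f_h_p[1] - f_h_m[1]) / (2 * d_h)],
    ])


def fast_equilibrium(ip3: float, ca_er: float, p: ModelParameters) -> FastSubsystemPoint:
    """Fixed point of the fast subsystem with eigenvalues of its Jacobian.

    When several equilibria coexist the one with the largest real part is
    reported (the point is classified oscillatory only if *no* equilibrium
    is stable, so bistable points count as non-oscillatory).

    Raises ``RuntimeError`` if no equilibrium is found.
    """
    if ip3 < 0 or ca_er < 0:
        raise ValueError("ip3 and ca_er must be non-negative")
    roots = _equilibrium_candidates(ip3, ca_er, p)
    if not roots:
        raise RuntimeError(
            f"no fast-subsystem equilibrium at IP3={ip3}, Ca_ER={ca_er}")
    f = fast_rhs(ip3, ca_er, p)
    q2_gate = p.d2 * (ip3 + p.d1) / (ip3 + p.d3)
    best = None
    any_stable = False
    for ca in roots:
        h = q2_gate / (q2_gate + ca)
        eig = np.linalg.eigvals(_jacobian(f, ca, h))
        if eig.real.max() <= 0:
            any_stable = True
        if best is None or eig.real.max() > best[2].real.max():
            best = (ca, h, eig)
    ca, h, eig = best
    if any_stable:
        # report the stable equilibrium: the fast subsystem settles there
        for ca2 in roots:
            h2 = q2_gate / (q2_gate + ca2)
            eig2 = np.linalg.eigvals(_jacobian(f, ca2, h2))
            if eig2.real.max() <= 0:
                ca, h, eig = ca2, h2, eig2
                break
    return FastSubsystemPoint(ip3=ip3, ca_er=ca_er, ca_i=ca, h=h,
                              eigenvalues=eig, n_equilibria=len(roots))


def map_region(ip3_range: tuple[float, float] = (0.0, 3.0),
               ca_er_range: tuple[float, float] | None = None,
               resolution: tuple[int, int] = (80, 80),
               p: ModelParameters | None = None) -> OscillatoryRegion:
    """Classify a dense (IP₃, Ca_ER) grid and extract the Hopf boundary.

    Defaults: IP₃ from 0 to the saturating steady state α/δ = 3 μM; Ca_ER
    from 10% of its resting value up to the resting value.
    """
    p = p or ModelParameters()
    if ca_er_range is None:
        _, ca_er_rest, _ = resting_closed_form(p)
        ca_er_range = (0.1 * ca_er_rest, ca_er_rest)
    if min(resolution) < 2:
        raise ValueError("resolution must be at least 2x2")
    ip3s = np.linspace(ip3_range[0], ip3_range[1], resolution[0])
    ca_ers = np.linspace(ca_er_range[0], ca_er_range[1], resolution[1])
    re = np.full(resolution, np.nan)
    im = np.full(resolution, np.nan)
    flagged = 0
    for i, ip3 in enumerate(ip3s):
        for j, ca_er in enumerate(ca_ers):
            try:
                pt = fast_equilibrium(float(ip3), float(ca_er), p)
            except RuntimeError:
                flagged += 1
                continue
            lead = pt.eigenvalues[np.argmax(pt.eigenvalues.real)]
            re[i, j] = lead.real
            im[i, j] = abs(lead.imag)
    osc = (re > 0) & (im > 0)
    boundary = []
    re_f = np.nan_to_num(re, nan=-1.0)
    for contour in measure.find_contours(re_f, 0.0):
        ip3_c = np.interp(contour[:, 0], np.arange(len(ip3s)), ip3s)
        ca_er_c = np.interp(contour[:, 1], np.arange(len(ca_ers)), ca_ers)
        boundary.append(np.column_stack([ip3_c, ca_er_c]))
    return OscillatoryRegion(ip3_grid=ip3s, ca_er_grid=ca_ers, re_lambda=re_f,
                             im_lambda=np.nan_to_num(im), oscillatory=osc,
                             boundary=boundary, flagged=flagged)


def classify_trajectory(result: SimulationResult, region: OscillatoryRegion,
                        dwell_threshold: float = 10.0) -> tuple[str, float]:
    """Label a trajectory by its residence in the oscillatory region.

    Projects (IP₃(t), Ca_ER(t)) onto the mapped plane and accumulates the
    time spent inside.  Returns ``(label, dwell_seconds)`` with label
    ``"outside"`` (never enters), ``"transits"`` (inside for less than the
    threshold, about one oscillation period) or ``"dwells"``.
    """
    ip3 = result.ip3
    ca_er = result.ca_er
    if ip3.max() > region.ip3_grid[-1] * 1.5 and ca_er.min() < region.ca_er_grid[0] / 1.5:
        raise ValueError("trajectory leaves the mapped window on both axes; "
                         "remap the region with wider ranges")
    inside = region.contains(ip3, ca_er)
    dt = np.median(np.diff(result.time))
    dwell = float(inside.sum() * dt)
    if dwell == 0.0:
        return "outside", dwell
    if dwell < dwell_threshold:
        return "transits", dwell
    return "dwells", dwell
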