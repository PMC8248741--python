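"""State variables, fluxes, gating and the full right-hand side.

The model couples three calcium-handling components:

* a two-compartment (cytosol/ER) flux balance for free Ca²⁺, with a constant
  inward plasma-membrane leak, PMCA and SERCA pumps (Hill functions, n = 2),
  an ER leak and IP₃R-mediated Ca²⁺-induced Ca²⁺ release (CICR);
* Li-Rinzel IP₃R gating: instantaneous activation by IP₃ (m∞) and Ca²⁺ (n∞),
  slow Ca²⁺-dependent inactivation through the gate h, giving the open
  probability O = m∞³ n∞³ h³, biphasic in cytosolic Ca²⁺;
* a 12-state Markov scheme for the P2X7 receptor channel, with naive,
  sensitized and desensitized rows of four states each (0–3 ATP molecules
  bound; two or more bound opens the pore).

The dynamical state has 16 components: [Ca²⁺]_i, [Ca²⁺]_ER, [IP₃], h and the
12 Markov occupancy fractions.  ATP is an external (constant) input in molar;
IP₃ production through the P2Y2 receptor saturates at k_atp (in μM).

Markov topology
---------------
Rows are ATP-binding ladders.  Naive: C1→C2→Q1→Q2 with binding rates
k2·[ATP], k4·[ATP], k6·[ATP] and unbinding k1, k3, k5.  Sensitized:
C4→C3→Q3→Q4 with binding k7·[ATP] on each step and the same unbinding rates
(C4 is the zero-bound sensitized resting state, the vertical partner of C1).
Desensitized: D1→D2→D3→D4, mirroring the sensitized ladder.  Vertical
transitions: slow sensitization at L1 from singly/doubly bound naive states
(C2→C3, Q1→Q3) and fast use-dependent sensitization at L3 from the fully
occupied open state (Q2→Q4); recovery at L2 through the 1-bound closed
sensitized state (C3→C2).  Desensitization is occupancy-dependent along the
naive row (C2→D2 at H2_C2, Q1→D3 at H2_Q1, Q2→D4 at H2_Q2); sensitization
stabilizes the open conformation, so ATP-bound sensitized states desensitize
only at the basal rate H2_C2 (C3→D2, Q3→D3, Q4→D4).  Recovery from the
desensitized row runs at H1 to the naive counterparts.  Only ATP-bound
states cross rows, so both C1 and C4 are exact rest states at [ATP] = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters

__all__ = [
    "ModelState",
    "FluxVector",
    "MARKOV_STATES",
    "N_STATES",
    "gating_functions",
    "ip3r_open_probability",
    "ip3r_flux",
    "pump_flux",
    "er_leak_flux",
    "p2x7_transition_matrix",
    "p2x7_generator_parts",
    "p2x7_flux",
    "full_rhs",
    "rhs_function",
    "KNOCKOUTS",
]

#: Order of the Markov occupancy fractions in the state vector (entries 4:16).
MARKOV_STATES = ("C1", "C2", "Q1", "Q2", "C3", "C4", "Q3", "Q4",
                 "D1", "D2", "D3", "D4")
_IDX = {name: i for i, name in enumerate(MARKOV_STATES)}
_OPEN = np.array([_IDX[s] for s in ("Q1", "Q2", "Q3", "Q4")])

N_STATES = 4 + len(MARKOV_STATES)

KNOCKOUTS = ("none", "p2y2", "p2x7")


@dataclass
class ModelState:
    """One point of the 16-dimensional model state.

    Concentrations in μM; ``h`` and the Markov fractions are dimensionless.
    """

    ca_i: float
    ca_er: float
    ip3: float
    h: float
    C1: float = 0.0
    C2: float = 0.0
    Q1: float = 0.0
    Q2: float = 0.0
    C3: float = 0.0
    C4: float = 0.0
    Q3: float = 0.0
    Q4: float = 0.0
    D1: float = 0.0
    D2: float = 0.0
    D3: float = 0.0
    D4: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.ca_i, self.ca_er, self.ip3, self.h]
            + [getattr(self, s) for s in MARKOV_STATES]
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (N_STATES,):
            raise ValueError(f"state vector must have length {N_STATES}")
        markov = dict(zip(MARKOV_STATES, y[4:]))
        return cls(ca_i=y[0], ca_er=y[1], ip3=y[2], h=y[3], **markov)

    @property
    def markov(self) -> np.ndarray:
        return self.as_array()[4:]

    @property
    def open_fraction(self) -> float:
        """Total fraction of P2X7 receptors with an open pore (ΣQ)."""
        return self.Q1 + self.Q2 + self.Q3 + self.Q4

    def validate(self, tol: float = 1e-9) -> None:
        if min(self.ca_i, self.ca_er, self.ip3) < 0:
            raise ValueError("concentrations must be non-negative")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must lie in [0, 1]")
        m = self.markov
        if m.min() < -tol or m.max() > 1 + tol:
            raise ValueError("Markov fractions must lie in [0, 1]")
        if abs(m.sum() - 1.0) > tol:
            raise ValueError(
                f"Markov fractions must sum to 1 (got {m.sum():.12f})"
            )


@dataclass
class FluxVector:
    """The six Ca²⁺ fluxes (μM/s) at one state and one [ATP]."""

    j_inleak: float
    j_p2x7: float
    j_pmca: float
    j_ip3r: float
    j_erleak: float
    j_serca: float

    @property
    def net_cytosolic(self) -> float:
        """Sum entering the cytosolic balance (before the f_c scaling)."""
        return (self.j_inleak + self.j_p2x7 - self.j_pmca
                + self.j_ip3r + self.j_erleak - self.j_serca)


# ---------------------------------------------------------------------------
# gating and fluxes
# ---------------------------------------------------------------------------

def gating_functions(ip3, ca_i, p: ModelParameters):
    """Li-Rinzel gating: (m∞, n∞, h∞, τ_h, Q2_gate).

    m∞ = IP₃/(IP₃+d1) and n∞ = Ca/(Ca+d5) are the instantaneous activation
    gates; the inactivation gate relaxes to h∞ = Q₂/(Q₂+Ca) with time
    constant τ_h = 1/(a2 (Q₂+Ca)), where Q₂ = d2 (IP₃+d1)/(IP₃+d3) (μM) is
    the effective Ca²⁺ dissociation constant of the inactivation site.  The
    returned ``Q2_gate`` is this auxiliary quantity, distinct from the
    Markov state of the same name.
    """
    ip3 = np.asarray(ip3, dtype=float)
    ca_i = np.asarray(ca_i, dtype=float)
    if np.any(ip3 < 0) or np.any(ca_i < 0):
        raise ValueError("IP3 and Ca_i must be non-negative")
    m_inf = ip3 / (ip3 + p.d1)
    n_inf = ca_i / (ca_i + p.d5)
    q2_gate = p.d2 * (ip3 + p.d1) / (ip3 + p.d3)
    h_inf = q2_gate / (q2_gate + ca_i)
    tau_h = 1.0 / (p.a2 * (q2_gate + ca_i))
    return m_inf, n_inf, h_inf, tau_h, q2_gate


def ip3r_open_probability(ip3, ca_i, h, p: ModelParameters):
    """O = m∞³ n∞³ h³, biphasic in Ca_i at fixed IP₃ when h = h∞(Ca_i)."""
    m_inf, n_inf, _, _, _ = gating_functions(ip3, ca_i, p)
    return (m_inf * n_inf * np.asarray(h)) ** 3


def ip3r_flux(state: ModelState, p: ModelParameters) -> float:
    """CICR flux through IP₃Rs, v_ip3r·O·([Ca]_ER − [Ca]_i), μM/s."""
    o = ip3r_open_probability(state.ip3, state.ca_i, state.h, p)
    return float(p.v_ip3r * o * (state.ca_er - state.ca_i))


def pump_flux(ca_i, v, k):
    """Hill pump (n = 2): v·Ca²/(Ca²+k²); used for both PMCA and SERCA."""
    ca_i = np.asarray(ca_i, dtype=float)
    return v * ca_i**2 / (ca_i**2 + k**2)


def er_leak_flux(state: ModelState, p: ModelParameters) -> float:
    """Passive ER leak, v_erleak·([Ca]_ER − [Ca]_i), μM/s."""
    return float(p.v_erleak * (state.ca_er - state.ca_i))


# ---------------------------------------------------------------------------
# P2X7 Markov scheme
# ---------------------------------------------------------------------------

def _transitions(p: ModelParameters):
    """Yield (source, target, constant rate, ATP-proportional rate)."""
    if p.binding_multiplicities:
        bind_mult, unbind_mult = (3.0, 2.0, 1.0), (1.0, 2.0, 3.0)
    else:
        bind_mult = unbind_mult = (1.0, 1.0, 1.0)
    k7 = p.k7_effective

    def ladder(states, kon):
        for step, (a, b) in enumerate(zip(states[:-1], states[1:])):
            yield (a, b, 0.0, bind_mult[step] * kon[step])
            yield (b, a, unbind_mult[step] * (p.k1, p.k3, p.k5)[step], 0.0)

    yield from ladder(("C1", "C2", "Q1", "Q2"), (p.k2, p.k4, p.k6))
    yield from ladder(("C4", "C3", "Q3", "Q4"), (k7, k7, k7))
    if p.desensitized_ladder:
        yield from ladder(("D1", "D2", "D3", "D4"), (k7, k7, k7))
    # sensitization: slow from bound naive states, fast use-dependent from
    # the fully occupied open state; recovery through the 1-bound closed state
    yield ("C2", "C3", p.l1, 0.0)
    yield ("Q1", "Q3", p.l1, 0.0)
    yield ("Q2", "Q4", p.l3, 0.0)
    yield ("C3", "C2", p.l2, 0.0)
    # desensitization: occupancy-dependent along the naive row; sensitization
    # stabilizes the receptor, leaving only the basal 1-bound rate
    yield ("C2", "D2", p.h2_c2, 0.0)
    yield ("Q1", "D3", p.h2_q1, 0.0)
    yield ("Q2", "D4", p.h2_q2, 0.0)
    yield ("C3", "D2", p.h2_c2, 0.0)
    yield ("Q3", "D3", p.h2_c2, 0.0)
    yield ("Q4", "D4", p.h2_c2, 0.0)
    # recovery from the desensitized row to the naive counterparts
    for d, c in (("D1", "C1"), ("D2", "C2"), ("D3", "Q1"), ("D4", "Q2")):
        yield (d, c, p.h1, 0.0)


def p2x7_generator_parts(p: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """Decompose the generator as G(ATP) = G0 + [ATP]·G1.

    G0 carries the ATP-independent rates (unbinding, row transitions), G1 the
    binding rates per molar.  Column sums of both parts are zero, so any
    G(ATP) conserves total receptor fraction.
    """
    n = len(MARKOV_STATES)
    g0 = np.zeros((n, n))
    g1 = np.zeros((n, n))
    for src, dst, rate0, rate1 in _transitions(p):
        i, j = _IDX[dst], _IDX[src]
        g0[i, j] += rate0
        g0[j, j] -= rate0
        g1[i, j] += rate1
        g1[j, j] -= rate1
    return g0, g1


def p2x7_transition_matrix(atp: float, p: ModelParameters) -> np.ndarray:
    """Generator matrix G such that d(markov)/dt = G @ markov; [ATP] in M."""
    if atp < 0:
        raise ValueError("ATP concentration must be non-negative")
    g0, g1 = p2x7_generator_parts(p)
    return g0 + atp * g1


def p2x7_flux(state: ModelState, p: ModelParameters) -> tuple[float, float]:
    """(I_P2X7 in A, J_P2X7 in μM/s) at the given state.

    I = g_x7·ΣQ·(V−E); J = −f_ca·I/(zF·V_osteo) converted to μM/s.  J is
    non-negative whenever the membrane potential sits below the reversal
    potential (inward Ca²⁺ current).
    """
    sq = state.open_fraction
    if p.g_x7_units == "molar_rate":
        return 0.0, p.p2x7_flux_coefficient * sq
    current = p.g_x7 * sq * (p.v_mem - p.e_rev)
    return current, p.p2x7_flux_coefficient * sq


# ---------------------------------------------------------------------------
# full system
# ---------------------------------------------------------------------------

def compute_fluxes(y: np.ndarray, atp: float, p: ModelParameters,
                   knockout: str = "none") -> FluxVector:
    """All six fluxes at a raw state vector (knockout rule applied)."""
    _check_knockout(knockout)
    ca_i = max(y[0], 0.0)
    ca_er = y[1]
    ip3 = max(y[2], 0.0)
    h = y[3]
    m_inf = ip3 / (ip3 + p.d1)
    n_inf = ca_i / (ca_i + p.d5)
    if knockout == "p2y2":
        j_ip3r = 0.0
    else:
        j_ip3r = p.v_ip3r * (m_inf * n_inf * h) ** 3 * (ca_er - ca_i)
    if knockout == "p2x7":
        j_p2x7 = 0.0
    else:
        j_p2x7 = p.p2x7_flux_coefficient * float(np.sum(y[4:][_OPEN]))
    return FluxVector(
        j_inleak=p.j_inleak,
        j_p2x7=j_p2x7,
        j_pmca=float(pump_flux(ca_i, p.v_pmca, p.k_pmca)),
        j_ip3r=j_ip3r,
        j_erleak=p.v_erleak * (ca_er - ca_i),
        j_serca=float(pump_flux(ca_i, p.v_serca, p.k_serca)),
    )


def _check_knockout(knockout: str) -> None:
    if knockout not in KNOCKOUTS:
        raise ValueError(f"unknown knockout {knockout!r}; expected one of {KNOCKOUTS}")


def rhs_function(atp: float, p: ModelParameters, knockout: str = "none"):
    """Build a fast ``f(t, y) -> dy/dt`` closure for constant [ATP] (molar).

    The Markov generator is assembled once; the IP₃ production term uses
    [ATP] converted to μM to match k_atp.
    """
    _check_knockout(knockout)
    if atp < 0:
        raise ValueError("ATP concentration must be non-negative")
    if knockout == "p2x7":
        # knockout cells express no P2X7 receptors: the occupancy block is
        # frozen, making the output exactly independent of P2X7 parameters
        gen = np.zeros((len(MARKOV_STATES), len(MARKOV_STATES)))
    else:
        g0, g1 = p2x7_generator_parts(p)
        gen = g0 + atp * g1
    atp_um = atp * 1e6
    ip3_production = p.alpha_atp * atp_um / (atp_um + p.k_atp) if atp_um > 0 else 0.0
    x7_coef = 0.0 if knockout == "p2x7" else p.p2x7_flux_coefficient
    ko_p2y2 = knockout == "p2y2"
    d1, d2, d3, d5 = p.d1, p.d2, p.d3, p.d5

    def f(t: float, y: np.ndarray) -> np.ndarray:
        ca_i = y[0] if y[0] > 0.0 else 0.0
        ca_er = y[1]
        ip3 = y[2] if y[2] > 0.0 else 0.0
        h = y[3]
        markov = y[4:]

        m_inf = ip3 / (ip3 + d1)
        n_inf = ca_i / (ca_i + d5)
        q2_gate = d2 * (ip3 + d1) / (ip3 + d3)
        h_inf = q2_gate / (q2_gate + ca_i)
        inv_tau = p.a2 * (q2_gate + ca_i)

        j_ip3r = 0.0 if ko_p2y2 else p.v_ip3r * (m_inf * n_inf * h) ** 3 * (ca_er - ca_i)
        j_erleak = p.v_erleak * (ca_er - ca_i)
        j_pmca = p.v_pmca * ca_i * ca_i / (ca_i * ca_i + p.k_pmca * p.k_pmca)
        j_serca = p.v_serca * ca_i * ca_i / (ca_i * ca_i + p.k_serca * p.k_serca)
        j_x7 = x7_coef * (markov[2] + markov[3] + markov[6] + markov[7])

        dy = np.empty_like(y)
        dy[0] = p.f_c * (p.j_inleak + j_x7 - j_pmca + j_ip3r + j_erleak - j_serca)
        dy[1] = p.f_er * p.gamma * (j_serca - j_ip3r - j_erleak)
        dy[2] = ip3_production - p.delta * ip3
        dy[3] = (h_inf - h) * inv_tau
        dy[4:] = gen @ markov
        return dy

    return f


def full_rhs(state: ModelState, atp: float, p: ModelParameters,
             knockout: str = "none") -> np.ndarray:
    """d(state)/dt for the full 16-dimensional system; [ATP] in molar."""
    return rhs_function(atp, p, knockout)(0.0, state.as_array())
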