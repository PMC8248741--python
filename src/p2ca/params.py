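"""Model parameters for the coupled P2Y2R–IP3R–P2X7R calcium model.

All constants of the osteoblast model live in a single frozen-by-convention
dataclass, :class:`ModelParameters`.  Concentrations are in μM, rates in 1/s
(ATP-binding rates in M⁻¹s⁻¹, acting on [ATP] expressed in molar), potentials
in volts, volumes in liters.  The default instance is the published parameter
set of the model; it can be round-tripped through a flat YAML mapping.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

#: Faraday constant, C/mol.
FARADAY = 96485.0
#: Valence of the calcium ion.
CA_VALENCE = 2


@dataclass
class ModelParameters:
    """Every constant of the osteoblast P2Y2/P2X7 calcium model.

    Attributes
    ----------
    f_c, f_er : float
        Fraction of free (unbuffered) Ca²⁺ in cytosol and ER; 0 < f_c < f_er < 1.
    gamma : float
        Cytosol/ER volume ratio.
    j_inleak : float
        Constant inward plasma-membrane Ca²⁺ leak, μM/s.
    v_pmca, k_pmca : float
        PMCA maximal rate (μM/s) and Ca²⁺ affinity (μM); Hill coefficient 2.
    v_serca, k_serca : float
        SERCA maximal rate (μM/s) and Ca²⁺ affinity (μM); Hill coefficient 2.
    v_erleak : float
        ER leak rate constant, 1/s.
    d1, d2, d3, d5 : float
        Li-Rinzel IP₃R dissociation constants, μM.
    a2 : float
        Ca²⁺ binding rate to the IP₃R inactivation site, μM⁻¹s⁻¹.
    v_ip3r : float
        Maximal IP₃R flux, μM/s.
    g_x7 : float
        Open-state P2X7R conductance.  Interpreted according to ``g_x7_units``:
        ``"siemens"`` (default, whole-cell conductance in S, giving a maximal
        Ca²⁺ flux of ≈55 μM/s) or ``"molar_rate"`` (raw value read as a molar
        flux rate in M/s per unit open fraction).
    e_rev, v_mem : float
        Reversal potential and (fixed) membrane potential, V.
    k1, k3, k5 : float
        ATP unbinding rates along a receptor row, 1/s.
    k2, k4, k6 : float
        Naive-row ATP binding rates, M⁻¹s⁻¹.
    k7 : float
        Sensitized-row (and desensitized-ladder) ATP binding rate, M⁻¹s⁻¹.
    l1, l2, l3 : float
        Naive↔sensitized transition rates, 1/s.
    h1 : float
        Recovery rate from the desensitized row, 1/s.
    h2_c2, h2_q1, h2_q2 : float
        State-dependent desensitization rates from C2, Q1, Q2; increasing with
        ATP occupancy (h2_c2 < h2_q1 < h2_q2).
    f_ca : float
        Fraction of the P2X7R cation current carried by Ca²⁺.
    v_osteo : float
        Osteoblast volume, L.
    alpha_atp, k_atp, delta : float
        IP₃ production: maximal rate (μM/s), half-maximal [ATP] (μM) and IP₃
        degradation rate (1/s).
    binding_multiplicities : bool
        If True, ladder binding steps carry statistical factors (3, 2, 1) and
        unbinding steps (1, 2, 3) for the three ATP sites.  Default off.
    desensitized_ladder : bool
        If True (default) the desensitized row supports ATP binding/unbinding
        transitions mirroring the sensitized row.
    """

    # buffering & scaling
    f_c: float = 0.01
    f_er: float = 0.025
    gamma: float = 9.0
    # plasma-membrane fluxes
    j_inleak: float = 0.15
    v_pmca: float = 30.0
    k_pmca: float = 0.45
    # ER fluxes
    v_serca: float = 22.5
    k_serca: float = 0.105
    v_erleak: float = 0.03
    # Li-Rinzel IP3R
    d1: float = 0.13
    d2: float = 1.049
    d3: float = 0.9434
    d5: float = 0.08234
    a2: float = 0.2
    v_ip3r: float = 15.0
    # P2X7R
    g_x7: float = 2.5e-8
    e_rev: float = 0.0
    v_mem: float = -0.06
    k1: float = 0.3
    k2: float = 1265.0
    k3: float = 2.4
    k4: float = 1581.0
    k5: float = 1.58
    k6: float = 221.0
    k7: float = 316.0
    l1: float = 0.0001
    l2: float = 0.004
    l3: float = 0.3
    h1: float = 0.001
    h2_c2: float = 0.01
    h2_q1: float = 0.05
    h2_q2: float = 0.8
    f_ca: float = 0.046
    v_osteo: float = 6.5e-12
    # IP3 dynamics
    alpha_atp: float = 0.03
    k_atp: float = 1.0
    delta: float = 0.01
    # interpretation switches (not physical constants)
    g_x7_units: str = "siemens"
    binding_multiplicities: bool = False
    desensitized_ladder: bool = True
    restore_sensitized_affinity: bool = True

    #: BzATP→ATP affinity rescale applied to the published binding rates.
    BZATP_RESCALE = 31.625

    _POSITIVE = (
        "gamma", "k_pmca", "k_serca",
        "d1", "d2", "d3", "d5", "a2", "g_x7", "k1", "k2",
        "k3", "k4", "k5", "k6", "k7", "l1", "l2", "l3", "h1", "h2_c2",
        "h2_q1", "h2_q2", "f_ca", "v_osteo", "alpha_atp", "k_atp", "delta",
    )
    # maximal flux rates; zero disables the pathway (e.g. closed-cell limits)
    _NON_NEGATIVE = ("j_inleak", "v_pmca", "v_serca", "v_erleak", "v_ip3r")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check physical invariants; raise ValueError on violation."""
        for name in self._POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        for name in self._NON_NEGATIVE:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be non-negative")
        if not (0 < self.f_c < self.f_er < 1):
            raise ValueError("buffering fractions must satisfy 0 < f_c < f_er < 1")
        if not (0 < self.f_ca < 1):
            raise ValueError("f_ca must lie in (0, 1)")
        if not (self.h2_c2 < self.h2_q1 < self.h2_q2):
            raise ValueError(
                "desensitization rates must increase with ATP occupancy "
                "(h2_c2 < h2_q1 < h2_q2)"
            )
        if self.g_x7_units not in ("siemens", "molar_rate"):
            raise ValueError("g_x7_units must be 'siemens' or 'molar_rate'")

    @property
    def k7_effective(self) -> float:
        """Sensitized-row binding rate actually used by the gating scheme.

        The published table lists k7 after the BzATP→ATP affinity rescale
        (÷31.625), but the model requires k7 > k2, k4, k6 for the sensitized
        row to carry a higher open probability, and the sensitized-pool
        dose-response only saturates within the physiological [ATP] range if
        k7·[ATP] outruns the row unbinding rates by 1e-3 M.  With
        ``restore_sensitized_affinity`` (default) k7 therefore enters the
        transition matrix at its unrescaled value, k7 × 31.625 ≈ 1e4 M⁻¹s⁻¹.
        """
        if self.restore_sensitized_affinity:
            return self.k7 * self.BZATP_RESCALE
        return self.k7

    # -- flux helper constants -------------------------------------------------

    @property
    def p2x7_flux_coefficient(self) -> float:
        """μM/s of Ca²⁺ influx per unit total open P2X7R fraction.

        In the default conductance interpretation this is
        ``-f_ca * g_x7 * (v_mem - e_rev) / (z F V_osteo)`` converted M→μM.
        """
        if self.g_x7_units == "molar_rate":
            return self.f_ca * self.g_x7 * 1e6
        current_per_open = self.g_x7 * (self.v_mem - self.e_rev)  # A
        return -self.f_ca * current_per_open / (CA_VALENCE * FARADAY * self.v_osteo) * 1e6

    # -- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**mapping)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        mapping = yaml.safe_load(Path(path).read_text())
        if not isinstance(mapping, dict):
            raise ValueError(f"parameter file {path} is not a flat mapping")
        return cls.from_dict(mapping)

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields changed (and re-validated)."""
        return dataclasses.replace(self, **changes)


def default_parameters() -> ModelParameters:
    """The published osteoblast parameter set (shipped YAML; falls back to
    the in-code defaults, which are identical)."""
    try:
        with resources.files("p2ca.data").joinpath("parameters.yaml").open() as fh:
            return ModelParameters.from_dict(yaml.safe_load(fh))
    except FileNotFoundError:  # pragma: no cover - defensive
        return ModelParameters()
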