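"""Porin model: geometry/electrostatics parameters and the steric term.

A general porin is summarised by four numbers: its internal electrostatic
potential ``V_pore`` (negative for cation-selective pores such as OmpF),
its characteristic transversal electric field ``E_pore``, and the mean and
fluctuation of its constriction-region cross-section.  The steric
permeation penalty is the log-probability that a molecule's projected
cross-section, drawn from its conformational distribution, fits through
the fluctuating constriction:

    U_steric = ln Phi( (A_pore - MPA) / sqrt(sd_pore^2 + sd_MPA^2 + eps^2) )

with Phi the standard normal CDF and ``eps`` a small regulariser keeping
the denominator positive for rigid molecules in a rigid pore.  The term is
always <= 0, tends to 0 for molecules much smaller than the pore and to
-inf for molecules much larger, and becomes *less* negative when either
the molecule or the pore is more flexible — flexibility rescues molecules
whose mean size exceeds the constriction.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.special import log_ndtr

__all__ = [
    "PoreModel",
    "ScoringCoefficients",
    "steric_term",
    "GLYCINE_REFERENCE",
]

#: Regulariser (A^2) added in quadrature to the size-fluctuation widths.
STERIC_EPSILON = 0.1


@dataclass
class PoreModel:
    """Parameters of one general porin.

    Units: ``v_pore`` mV, ``e_pore`` mV/A, areas A^2.  ``glycine_score``
    is the reference score anchoring the percent scale at 100% for
    glycine; it is set by calibration under the active coefficients, not
    by hand.
    """

    name: str = "OmpF"
    v_pore: float = -30.0
    e_pore: float = 6.0
    pore_area_mean: float = 50.0
    pore_area_sd: float = 9.0
    glycine_score: float | None = None

    def __post_init__(self) -> None:
        if self.pore_area_mean <= 0:
            raise ValueError("pore_area_mean must be positive")
        if self.pore_area_sd < 0:
            raise ValueError("pore_area_sd must be non-negative")


@dataclass
class ScoringCoefficients:
    """Weights (alpha, beta, gamma, delta) of the permeability score."""

    alpha: float
    beta: float
    gamma: float
    delta: float

    def __post_init__(self) -> None:
        import math

        for name in ("alpha", "beta", "gamma", "delta"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"coefficient {name} must be finite")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.alpha, self.beta, self.gamma, self.delta)


def steric_term(mpa_mean: float, mpa_sd: float, pore: PoreModel) -> float:
    """Size-exclusion penalty, always <= 0 (natural-log scale).

    ``ln Phi(z)`` with ``z = (A_pore - MPA) / sqrt(sd_p^2 + sd_m^2 + eps^2)``
    computed via :func:`scipy.special.log_ndtr` for stability far in the
    tail.  Both size distributions enter through the quadrature width, so
    increasing either fluctuation moves the term toward 0 whenever the
    molecule is larger than the pore.
    """
    if mpa_mean <= 0:
        raise ValueError("mpa_mean must be positive")
    if mpa_sd < 0:
        raise ValueError("mpa_sd must be non-negative")
    width = (
        pore.pore_area_sd**2 + mpa_sd**2 + STERIC_EPSILON**2
    ) ** 0.5
    z = (pore.pore_area_mean - mpa_mean) / width
    return float(log_ndtr(z))


#: Descriptor fixture anchoring the glycine-relative percent scale.
#: Synthetic illustrative values for the glycine zwitterion (small, rigid,
#: large dipole, very hydrophilic) — not measured or published numbers.
GLYCINE_REFERENCE: dict = {
    "id": "glycine",
    "net_charge": 0,
    "total_dipole": 14.0,
    "transversal_dipole": 11.0,
    "mpa_mean": 24.0,
    "mpa_sd": 1.2,
    "alogp": -3.2,
}
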