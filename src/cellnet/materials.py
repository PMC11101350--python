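"""Fibre bond materials and the analytic parameter pipeline.

Every fibre segment ("bond") of the discrete network model carries a
bilinear force law characterised by a tensile modulus ``K_t`` and a
compressive modulus ``K_c`` (both in nN, i.e. force per unit strain) and
an activation ``a`` that multiplicatively shortens the rest length:
``r_a = a * r0``.  An activated fibre (``a < 1``) is pre-tensioned in
situ, modelling myosin-driven contraction.

The default material table holds one entry per fibre class of the HUVEC
model.  The stiffness and activation of the actin components trace back
to a small set of measured quantities; the functions below reproduce
those derivations so the provenance of each number stays executable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class FibreClass(str, Enum):
    """Classes of bonds occurring in a cell network."""

    CORTEX = "cortex"
    MEMBRANE = "membrane"
    NUCLEAR_MEMBRANE = "nuclear_membrane"
    NUCLEAR_ACTIN = "nuclear_actin"
    VENTRAL_SF = "ventral_SF"
    PERINUCLEAR_SF = "perinuclear_SF"
    JUNCTION = "junction"


@dataclass(frozen=True)
class BondMaterial:
    """Bilinear bond material.

    Parameters
    ----------
    K_t : float
        Tensile stiffness in nN (force per unit elastic strain).
    K_c : float
        Compressive stiffness in nN.
    a : float
        Activation in (0, 1]; ``a = 1`` means no active shortening.
    """

    K_t: float
    K_c: float
    a: float = 1.0

    def __post_init__(self) -> None:
        if self.K_t < 0 or self.K_c < 0:
            raise ValueError("stiffnesses must be non-negative")
        if not (0.0 < self.a <= 1.0):
            raise ValueError(f"activation must lie in (0, 1], got {self.a}")


# ---------------------------------------------------------------------------
# Analytic parameter derivations
# ---------------------------------------------------------------------------

#: Spring constant of a single actin filament, nN/μm (Kojima et al.).
ACTIN_SPRING_CONSTANT = 43.7
#: Assumed average cortical filament length, μm.
ACTIN_FILAMENT_LENGTH = 1.5
#: Measured activation of ventral stress fibres (Deguchi et al.).
VENTRAL_SF_ACTIVATION = 0.81
#: Measured ventral stress fibre stiffness, nN.
VENTRAL_SF_STIFFNESS = 20.2

#: Neo-Hookean C10 of the silicone substrate, kPa.
SUBSTRATE_C10 = 1.166
#: Neo-Hookean D1 of the substrate, MPa^-1 (near-incompressible).
SUBSTRATE_D1 = 1.2008

#: Ratio of compressive to tensile stiffness assumed for all slender fibres.
COMPRESSION_RATIO = 0.1


def cortex_stiffness(
    spring_constant: float = ACTIN_SPRING_CONSTANT,
    filament_length: float = ACTIN_FILAMENT_LENGTH,
) -> float:
    """Cortical actin filament stiffness (nN) from the measured spring
    constant (nN/μm) referred to the assumed mean filament length (μm)."""
    return spring_constant / filament_length


def perinuclear_sf_stiffness(ventral: float = VENTRAL_SF_STIFFNESS) -> float:
    """Effective in-plane stiffness of perinuclear stress fibres (nN).

    Perinuclear fibres arch over the nucleus and are inclined out of the
    representation plane, so only a quarter of the ventral stiffness is
    attributed to their planar projection.
    """
    return ventral / 4.0


def cortex_activation(a_ventral: float = VENTRAL_SF_ACTIVATION) -> float:
    """Cortical actin activation: a quarter of the ventral SF active
    shortening, i.e. ``1 - (1 - a_SF) / 4``."""
    return 1.0 - (1.0 - a_ventral) / 4.0


def substrate_young_modulus(c10: float = SUBSTRATE_C10) -> float:
    """Small-strain Young's modulus (kPa) of a neo-Hookean solid in the
    incompressible limit, ``E = 6 C10``."""
    return 6.0 * c10


def equibiaxial_stretch_strain(area_strain: float = 0.10) -> float:
    """Linear boundary strain ``sqrt(1 + eps_A) - 1`` producing a given
    far-field area strain."""
    if area_strain < -1.0:
        raise ValueError("area strain below -100% is unphysical")
    return (1.0 + area_strain) ** 0.5 - 1.0


def derived_parameters() -> dict[str, float]:
    """The analytic parameter pipeline, rounded as conventionally printed.

    Returns the headline derived constants of the HUVEC model: substrate
    modulus, equibiaxial boundary strain for 10% area strain, cortex bond
    stiffness, perinuclear SF stiffness, and cortex activation.
    """
    return {
        "substrate_E_kPa": round(substrate_young_modulus(), 0),
        "equibiaxial_strain_10pct": round(equibiaxial_stretch_strain(0.10), 2),
        "cortex_K_t_nN": round(cortex_stiffness(), 1),
        "perinuclear_K_t_nN": round(perinuclear_sf_stiffness(), 2),
        "cortex_activation": round(cortex_activation(), 2),
    }


def _with_compression(K_t: float, a: float) -> BondMaterial:
    return BondMaterial(K_t=K_t, K_c=COMPRESSION_RATIO * K_t, a=a)


#: Default bond material table of the HUVEC model.  Stiffnesses in nN.
#: The nuclear membrane and nuclear actin are quasi-rigid placeholders
#: (the nucleus is modelled as an effectively rigid body); the cellular
#: membrane is orders of magnitude softer than the actin network and
#: mainly traces the cell boundary.
DEFAULT_MATERIALS: dict[FibreClass, BondMaterial] = {
    FibreClass.CORTEX: _with_compression(29.1, 0.95),
    FibreClass.VENTRAL_SF: _with_compression(20.2, 0.81),
    FibreClass.PERINUCLEAR_SF: _with_compression(5.05, 0.9),
    FibreClass.NUCLEAR_ACTIN: BondMaterial(K_t=1000.0, K_c=100.0, a=1.0),
    FibreClass.MEMBRANE: BondMaterial(K_t=0.1, K_c=0.01, a=1.0),
    FibreClass.NUCLEAR_MEMBRANE: BondMaterial(K_t=1000.0, K_c=100.0, a=1.0),
    # The junction law between cells is a configurable placeholder; no
    # validated law exists for tight/adherens junctions in this framework.
    FibreClass.JUNCTION: BondMaterial(K_t=100.0, K_c=100.0, a=1.0),
}
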