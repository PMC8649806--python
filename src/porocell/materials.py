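"""Material and loading descriptions for linear poroelasticity.

Units used throughout the package: lengths in micrometres (um), time in
seconds, pressures and moduli in kilopascals (kPa).  The poroelastic
diffusion constant ``D`` therefore carries um^2/s and the derived Darcy
permeability ``k = D / M`` carries um^2 / (kPa s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PoroelasticMaterial", "RampLoad", "LayeredMaterial"]


@dataclass(frozen=True)
class PoroelasticMaterial:
    """Isotropic drained elastic skeleton plus a consolidation coefficient.

    Parameters
    ----------
    E : float
        Drained Young's modulus of the solid network, kPa.
    nu : float
        Drained Poisson ratio, ``0 <= nu < 0.5``.  The incompressible
        limit ``nu = 0.5`` makes the confined (oedometric) modulus
        diverge and is rejected.
    D : float
        Poroelastic diffusion constant, um^2/s.  Sets the pressure
        relaxation timescale ``t_p ~ H^2 / D`` of a layer of thickness H.
    """

    E: float
    nu: float
    D: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"Young's modulus must be positive, got E={self.E}")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError(
                "Drained Poisson ratio must satisfy 0 <= nu < 0.5 "
                f"(nu=0.5 is the incompressible network limit), got nu={self.nu}"
            )
        if not self.D > 0:
            raise ValueError(f"Diffusion constant must be positive, got D={self.D}")

    @property
    def G(self) -> float:
        """Drained shear modulus, kPa."""
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def lam(self) -> float:
        """Drained first Lame constant, kPa."""
        return self.E * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))

    @property
    def K_bulk(self) -> float:
        """Drained bulk modulus, kPa."""
        return self.E / (3.0 * (1.0 - 2.0 * self.nu))

    @property
    def M_oed(self) -> float:
        """Confined (oedometric) modulus ``2G(1-nu)/(1-2nu)``, kPa."""
        return 2.0 * self.G * (1.0 - self.nu) / (1.0 - 2.0 * self.nu)

    @property
    def k_perm(self) -> float:
        """Darcy permeability ``k = D / M``, um^2/(kPa s).

        This mapping makes the 1D reduction of the Biot equations a pure
        diffusion equation for the pore pressure with coefficient ``D``.
        """
        return self.D / self.M_oed

    @property
    def C10(self) -> float:
        """Neo-Hookean shear coefficient ``G/2``, kPa (small-strain match)."""
        return self.G / 2.0

    @property
    def D1_vol(self) -> float:
        """Neo-Hookean volumetric coefficient ``2/K_bulk``, 1/kPa."""
        return 2.0 / self.K_bulk


@dataclass(frozen=True)
class RampLoad:
    """Effective-pressure boundary forcing with a finite rise time.

    The effective pressure ``P_eff = (p_o - p_i) - (Pi_o - Pi_i)`` lumps
    hydrostatic and osmotic imbalances across the cell boundary into one
    driving pressure: positive values drive fluid in (swelling), negative
    values drive fluid out (deswelling).  The boundary forcing rises
    linearly from zero to ``P_eff`` over the rise time ``t_r`` and stays
    constant afterwards; ``t_r = 0`` is a step.
    """

    P_eff: float
    t_r: float = 0.0

    def __post_init__(self) -> None:
        if self.t_r < 0:
            raise ValueError(f"Rise time must be >= 0, got t_r={self.t_r}")

    def pressure_at(self, t):
        """Boundary effective pressure at time(s) ``t`` (kPa)."""
        t = np.asarray(t, dtype=float)
        if self.t_r == 0.0:
            out = np.where(t >= 0.0, self.P_eff, 0.0)
        else:
            out = self.P_eff * np.clip(t / self.t_r, 0.0, 1.0)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class LayeredMaterial:
    """Bulk material with a distinct thin top (membrane) layer.

    Only the diffusion constant differs between layers by default: the
    membrane layer occupies the top ``membrane_thickness`` of the domain
    and transports fluid with the membrane material's ``D``.
    """

    bulk: PoroelasticMaterial
    membrane: PoroelasticMaterial
    membrane_thickness: float = 0.5  # um; 500 nm default

    def __post_init__(self) -> None:
        if not self.membrane_thickness > 0:
            raise ValueError("membrane_thickness must be positive")
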