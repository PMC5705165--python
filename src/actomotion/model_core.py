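"""Model parameters and crowding-limited effective transport coefficients.

The model describes a thin lamellipodial actin sheet as a 2D continuum on a
moving domain.  The actin flow ``u`` obeys a viscous/adhesive force balance
driven by myosin contraction, and myosin ``m`` is advected by the flow and
diffuses.  Everything downstream works with the dimensionless form, governed
by

* ``alpha``  -- viscosity-adhesion length parameter, eta / (L^2 xi); the ratio
  of the mechanical interaction length sqrt(eta/xi) to the cell size, squared.
* ``beta``   -- myosin contractility constant, sigma M0 / (D xi).
* ``mu_tot`` -- total dimensionless myosin, conserved by the transport step.
* ``v0``     -- actin polymerization rate constant, V0 L / D.
* ``k``      -- area-preservation strength, K L^3 / D.

Crowding of myosin motors caps the advective velocity (hard cutoff at
``mmax_u``) and lowers the diffusivity (linear decrease toward ``mmax_d``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

logger = logging.getLogger("actomotion")

#: floor for the effective diffusivity; keeps the transport operator
#: parabolic if m ever exceeds mmax_d (which a valid run never does).
EPS_DIFF = 1e-6

Variant = Literal["ZV", "ZS"]


class DomainError(ValueError):
    """Raised when an input violates a model-domain precondition."""


@dataclass(frozen=True)
class DimensionalParameters:
    """Dimensional model constants (effective 2D units).

    ``L = sqrt(A0/pi)`` is the derived length unit: the radius of a circular
    cell with the target area.
    """

    eta: float          # actin viscosity, force*time/length
    sigma: float        # contractile force per unit myosin density
    xi: float           # adhesion drag coefficient
    D: float            # myosin diffusivity, length^2/time
    M0: float           # myosin concentration unit / inhibition threshold
    V0: float           # actin growth rate constant, length/time
    K: float            # area sensitivity of protrusion
    A0: float           # target cell area, length^2
    Mmax_u: float       # crowding cutoff for advection
    Mmax_d: float       # crowding cutoff for diffusion

    def __post_init__(self) -> None:
        for name in ("eta", "sigma", "xi", "D", "M0", "V0", "K", "A0",
                     "Mmax_u", "Mmax_d"):
            if not getattr(self, name) > 0:
                raise DomainError(f"dimensional parameter {name!r} must be "
                                  f"strictly positive, got {getattr(self, name)}")
        if not self.Mmax_u < self.Mmax_d:
            raise DomainError("Mmax_u must be smaller than Mmax_d")

    @property
    def L(self) -> float:
        """Length unit: radius of the circle with the target area."""
        return math.sqrt(self.A0 / math.pi)


@dataclass(frozen=True)
class DimensionlessParameters:
    """Dimensionless governing constants of the ZV / ZS models.

    Defaults are the fixed reference values beta=5, k=1.5, a0=pi,
    mmax_u=15, mmax_d=125; alpha, mu_tot and v0 are the three parameters
    worth scanning.
    """

    variant: Variant
    alpha: float = 0.5
    beta: float = 5.0
    mu_tot: float = 1.5 * math.pi
    v0: float = 2.5
    k: float = 1.5
    a0: float = math.pi
    g: float = 0.2            # steepness of the initial myosin gradient
    mmax_u: float = 15.0
    mmax_d: float = 125.0

    def __post_init__(self) -> None:
        if self.variant not in ("ZV", "ZS"):
            raise DomainError(f"variant must be 'ZV' or 'ZS', got {self.variant!r}")
        checks = {
            "alpha": self.alpha > 0,
            "beta": self.beta > 0,
            "mu_tot": self.mu_tot > 0,
            "v0": self.v0 >= 0,
            "k": self.k >= 0,
            "a0": self.a0 > 0,
            "mmax_u": 0 < self.mmax_u,
            "mmax_d": self.mmax_u < self.mmax_d,
        }
        for name, ok in checks.items():
            if not ok:
                raise DomainError(f"dimensionless parameter {name!r} violates "
                                  "its positivity/ordering constraint")
        if not 0.0 <= self.g <= 1.0:
            raise DomainError(f"gradient steepness g must lie in [0, 1], got {self.g}")

    @property
    def n_exp(self) -> int:
        """Exponent of the area-preservation term: 2 for ZS, 0 for ZV."""
        return 2 if self.variant == "ZS" else 0

    def with_(self, **kw) -> "DimensionlessParameters":
        return replace(self, **kw)


def nondimensionalize(p: DimensionalParameters,
                      variant: Variant = "ZS",
                      g: float = 0.2) -> DimensionlessParameters:
    """Map dimensional constants to the dimensionless parameter set.

    Units: length L = sqrt(A0/pi), time L^2/D, myosin concentration M0.
    """
    L = p.L
    return DimensionlessParameters(
        variant=variant,
        alpha=p.eta / (L ** 2 * p.xi),
        beta=p.sigma * p.M0 / (p.D * p.xi),
        v0=p.V0 * L / p.D,
        k=p.K * L ** 3 / p.D,
        a0=p.A0 / L ** 2,
        g=g,
        mmax_u=p.Mmax_u / p.M0,
        mmax_d=p.Mmax_d / p.M0,
        # mu_tot is an initial-condition invariant, not a material constant;
        # keep the class default unless the caller overrides it.
    )


def effective_advection_factor(m, mmax_u: float):
    """Crowding factor multiplying the actin velocity: 1 - m/mmax_u below the
    cutoff and exactly zero at or above it (myosin clusters jam)."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise DomainError("myosin density must be non-negative")
    fac = np.where(m < mmax_u, 1.0 - m / mmax_u, 0.0)
    return fac if fac.ndim else float(fac)


def effective_diffusivity(m, mmax_d: float):
    """Crowding-reduced diffusivity 1 - m/mmax_d, floored at EPS_DIFF.

    The cutoff is chosen above any density a valid run reaches; if the floor
    ever fires a warning is logged (the run left the intended regime).
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise DomainError("myosin density must be non-negative")
    d = 1.0 - m / mmax_d
    if np.any(d <= EPS_DIFF):
        logger.warning("effective diffusivity floored at %g: myosin density "
                       "reached %.3g >= mmax_d=%g", EPS_DIFF, float(np.max(m)), mmax_d)
        d = np.maximum(d, EPS_DIFF)
    return d if d.ndim else float(d)
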