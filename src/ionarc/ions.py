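"""Ion species registry and relativistic kinematics.

All three clinical beams (p, 4He, 12C) share the same per-nucleon kinematics:
kinetic energy is quoted in MeV/u and the nucleon rest energy 931.494 MeV is
used for every ion (isotope mass defects are ignored; the error on beta is
<0.1% at therapeutic energies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: nucleon rest energy used for all kinematics, MeV
NUCLEON_REST_ENERGY_MEV = 931.494


@dataclass(frozen=True)
class IonSpecies:
    """A primary beam species with its clinical delivery settings.

    ``min_fluence_threshold`` is the minimum number of particles per delivered
    spot (spots below it are pruned), ``default_spot_spacing`` the lateral
    raster spacing in mm, ``initial_spot_sigma`` the Gaussian focus sigma at
    isocenter in mm.
    """

    label: str
    Z: int
    A: int
    min_fluence_threshold: float
    default_spot_spacing: float
    initial_spot_sigma: float

    def __post_init__(self) -> None:
        if (self.Z, self.A) not in {(1, 1), (2, 4), (6, 12)}:
            raise ValueError(f"unsupported ion (Z={self.Z}, A={self.A})")
        if self.min_fluence_threshold <= 0:
            raise ValueError("min_fluence_threshold must be positive")


PROTON = IonSpecies("proton", 1, 1, 5.8e5, 4.8, 5.1)
HELIUM = IonSpecies("helium", 2, 4, 1.3e5, 2.4, 3.4)
CARBON = IonSpecies("carbon", 6, 12, 1.5e4, 2.4, 2.5)

_REGISTRY = {ion.label: ion for ion in (PROTON, HELIUM, CARBON)}
_ALIASES = {"p": "proton", "h": "proton", "he": "helium", "4he": "helium",
            "c": "carbon", "12c": "carbon"}


def get_ion(label: str) -> IonSpecies:
    """Look up a species by label (``proton``/``helium``/``carbon`` or aliases)."""
    key = label.strip().lower()
    key = _ALIASES.get(key, key)
    try:
        return _REGISTRY[key]
    except KeyError:
        raise KeyError(f"unknown ion species {label!r}") from None


def beta_from_energy(energy_mev_u):
    """Relativistic speed v/c from kinetic energy per nucleon (MeV/u).

    beta = sqrt(1 - 1/gamma^2) with gamma = 1 + T/m_u c^2; identical for all
    ions under the per-nucleon convention.
    """
    e = np.asarray(energy_mev_u, dtype=float)
    if np.any(e < 0):
        raise ValueError("kinetic energy must be non-negative")
    gamma = 1.0 + e / NUCLEON_REST_ENERGY_MEV
    beta = np.sqrt(1.0 - 1.0 / gamma**2)
    return beta if beta.ndim else float(beta)


def zeff_barkas(Z, beta):
    """Barkas effective charge Z_eff = Z (1 - exp(-125 beta Z^(-2/3))).

    Accounts for electron pickup by slow ions; Z_eff -> Z at therapeutic
    speeds and -> 0 for a stopped particle (returned with a warning).
    """
    z = np.asarray(Z, dtype=float)
    b = np.asarray(beta, dtype=float)
    if np.any(z < 1):
        raise ValueError("charge number must be >= 1")
    if np.any(b < 0) or np.any(b >= 1):
        raise ValueError("beta must lie in [0, 1)")
    if np.any(b == 0):
        warnings.warn("beta=0: stopped particle has Z_eff=0", stacklevel=2)
    out = z * (1.0 - np.exp(-125.0 * b * z ** (-2.0 / 3.0)))
    return out if out.ndim else float(out)


def rqe(Z, beta):
    """Radiation-quality parameter (Z_eff/beta)^2."""
    b = np.asarray(beta, dtype=float)
    if np.any(b <= 0):
        raise ValueError("beta must be positive for RQE")
    out = (zeff_barkas(Z, b) / b) ** 2
    return out if np.ndim(out) else float(out)


def rqe_from_energy(ion: IonSpecies, energy_mev_u):
    """(Z_eff/beta)^2 of a species at kinetic energy per nucleon (MeV/u)."""
    return rqe(ion.Z, beta_from_energy(energy_mev_u))
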