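"""Modified microdosimetric kinetic model (mMKM) and mixed-field effective dose.

The linear-quadratic alpha of each field component follows from the
saturation-corrected dose-mean specific energy per event, z1D*, of a
sub-nuclear domain (radius R_d) inside a nucleus (radius R_n):

    alpha_ion = alpha_x + beta_x * z1D*,    beta_ion = beta_x.

z1D* is computed with an amorphous-track model: the Kiefer-Chatterjee radial
dose profile of a single ion (core + 1/r^2 penumbra, normalized to the track
LET) is averaged over the domain cross-section at impact parameter b, and the
overkill saturation is applied through the y* construction,

    z1D* = z0^2 * int (1 - exp(-z(b)^2/z0^2)) 2 pi b db / int z(b) 2 pi b db,

with the saturation parameter z0 = y0 / (rho pi R_d^2) and
y0 = rho pi R_d R_n^2 sqrt(2 / (beta_x (R_d^2 + R_n^2))) determined by the
nucleus radius. Mixed fields mix dose-weighted: alpha_bar = sum d_j a_j / D,
sqrt(beta_bar) = sum d_j sqrt(b_j) / D; the RBE-weighted dose is the photon
dose with equal log survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from ionarc.ions import get_ion, beta_from_energy, zeff_barkas
from ionarc.stopping import stopping_power

#: keV per unit mass of 1 um^3 water, expressed in Gy
KEV_PER_UM3_TO_GY = 0.1602176634


@dataclass(frozen=True)
class PhotonLQParams:
    """Reference photon tissue response; defaults give (alpha/beta)_x = 2 Gy."""

    alpha_x: float = 0.05   # Gy^-1
    beta_x: float = 0.025   # Gy^-2

    def __post_init__(self):
        if self.alpha_x <= 0 or self.beta_x <= 0:
            raise ValueError("photon LQ parameters must be positive")


@dataclass(frozen=True)
class MKMParams:
    """Geometry of the mMKM: domain and nucleus radii in um."""

    domain_radius: float = 0.3
    nucleus_radius: float = 3.6

    def __post_init__(self):
        if not 0 < self.domain_radius < self.nucleus_radius:
            raise ValueError("need 0 < R_d < R_n")

    def saturation_y0(self, photon: PhotonLQParams) -> float:
        """Saturation lineal energy y0 (keV/um) from the nucleus radius."""
        rd, rn = self.domain_radius, self.nucleus_radius
        return (np.pi * rd * rn**2 / KEV_PER_UM3_TO_GY
                * np.sqrt(2.0 / (photon.beta_x * (rd**2 + rn**2))))

    def saturation_z0(self, photon: PhotonLQParams) -> float:
        """Saturation specific energy z0 = y0/(rho pi R_d^2), in Gy."""
        rd, rn = self.domain_radius, self.nucleus_radius
        return rn**2 / rd * np.sqrt(2.0 / (photon.beta_x * (rd**2 + rn**2)))


@dataclass(frozen=True)
class ComponentLQ:
    alpha_ion: float   # Gy^-1
    beta_ion: float    # Gy^-2
    z1d_star: float    # Gy


@dataclass
class MixedFieldVoxel:
    """Local mixed field: per-component (dose, LQ, RQE) plus total dose."""

    doses: np.ndarray          # Gy, per component
    alphas: np.ndarray         # Gy^-1
    betas: np.ndarray          # Gy^-2
    rqes: np.ndarray | None = None

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.betas = np.asarray(self.betas, dtype=float)
        if self.rqes is not None:
            self.rqes = np.asarray(self.rqes, dtype=float)
        if np.any(self.doses < 0):
            raise ValueError("component doses must be non-negative")

    @property
    def total_dose(self) -> float:
        return float(self.doses.sum())


# --- Kiefer-Chatterjee track structure -------------------------------------

_KC_KP = 1.25e-4  # Gy um^2, penumbra dose constant


def _kc_profile(Z: int, A: int, energy: float):
    """Radial dose D(r) [Gy] of one ion: core radius, penumbra radius, levels."""
    beta = max(beta_from_energy(max(energy, 1.0)), 1e-4)
    zeff = zeff_barkas(Z, beta)
    rqe = (zeff / beta) ** 2
    let = stopping_power(Z, A, energy)  # keV/um
    r_pen = 0.0616 * max(energy, 1.0) ** 1.7           # um
    r_core = max(0.0116 * beta, 1e-4)                  # um
    r_pen = max(r_pen, 2.0 * r_core)
    total = let * KEV_PER_UM3_TO_GY                    # Gy um^2 (integral of D over area)
    kp = _KC_KP * rqe
    pen_integral = 2.0 * np.pi * kp * np.log(r_pen / r_core)
    if pen_integral < total:
        d_core = (total - pen_integral) / (np.pi * r_core**2)
    else:
        kp = total / (2.0 * np.pi * np.log(r_pen / r_core))
        d_core = kp / r_core**2
    return r_core, r_pen, d_core, kp


def _domain_mean_dose(b: np.ndarray, rd: float, r_core: float, r_pen: float,
                      d_core: float, kp: float) -> np.ndarray:
    """Mean dose z(b) [Gy] over a domain of radius rd at impact parameter b."""
    # radial integration grid: resolve the core and the 1/r^2 penumbra
    r = np.unique(np.concatenate([
        np.linspace(0.0, 2.0 * rd, 160),
        np.geomspace(max(r_core / 10.0, 1e-6), r_pen, 220),
    ]))
    r = r[r > 0]
    dose_r = np.where(r < r_core, d_core, np.where(r <= r_pen, kp / r**2, 0.0))

    bb = b[:, None]
    rr = r[None, :]
    # arc length of the circle of track-distance r inside the domain disc
    cosarg = (bb**2 + rr**2 - rd**2) / (2.0 * bb * rr + 1e-300)
    theta = np.arccos(np.clip(cosarg, -1.0, 1.0))
    full = (rr <= rd - bb)  # circle fully inside the domain
    weight = np.where(full, 2.0 * np.pi * rr, 2.0 * theta * rr)
    integ = np.trapezoid(weight * dose_r[None, :], r, axis=1)
    z = integ / (np.pi * rd**2)
    # on-axis domain (b ~ 0): direct area average
    small = b < 1e-9
    if small.any():
        inside = r <= rd
        z0 = np.trapezoid(2.0 * np.pi * r[inside] * dose_r[inside], r[inside]) / (np.pi * rd**2)
        z[small] = z0
    return z


def z1d_star_single(Z: int, A: int, energy: float,
                    params: MKMParams = MKMParams(),
                    photon: PhotonLQParams = PhotonLQParams()) -> float:
    """Saturation-corrected dose-mean specific energy per event, Gy."""
    rd = params.domain_radius
    r_core, r_pen, d_core, kp = _kc_profile(Z, A, energy)
    b = np.unique(np.concatenate([
        np.linspace(0.0, 3.0 * rd, 140),
        np.geomspace(3.0 * rd, r_pen + rd, 200),
    ]))
    z = _domain_mean_dose(b, rd, r_core, r_pen, d_core, kp)
    z0 = params.saturation_z0(photon)
    num = z0**2 * np.trapezoid((1.0 - np.exp(-(z / z0) ** 2)) * 2.0 * np.pi * b, b)
    den = np.trapezoid(z * 2.0 * np.pi * b, b)
    if den <= 0:
        return 0.0
    return float(num / den)


@lru_cache(maxsize=32)
def _z1d_table(species_label: str, params: MKMParams, photon: PhotonLQParams):
    """Log-energy z1D* lookup table for one species."""
    ion = get_ion(species_label)
    e = np.geomspace(1.0, 1000.0, 90)
    z = np.array([z1d_star_single(ion.Z, ion.A, ei, params, photon) for ei in e])
    return np.log(e), z


def z1d_star(species_label: str, energy, params: MKMParams = MKMParams(),
             photon: PhotonLQParams = PhotonLQParams()) -> np.ndarray:
    """z1D* (Gy) of a species at kinetic energy MeV/u, via table interpolation."""
    log_e, z = _z1d_table(species_label, params, photon)
    e = np.clip(np.asarray(energy, dtype=float), 1.0, 1000.0)
    out = np.interp(np.log(e), log_e, z)
    return out if out.ndim else float(out)


def z1d_star_table(species_label: str, params: MKMParams = MKMParams(),
                   photon: PhotonLQParams = PhotonLQParams()):
    """(energy, z1D*) arrays of the cached table, e.g. for CSV export."""
    log_e, z = _z1d_table(species_label, params, photon)
    return np.exp(log_e), z.copy()


def alpha_beta_ion(species_label: str, energy,
                   photon: PhotonLQParams = PhotonLQParams(),
                   params: MKMParams = MKMParams()) -> ComponentLQ:
    """mMKM LQ parameters of one component: alpha = alpha_x + beta_x z1D*."""
    z = z1d_star(species_label, energy, params, photon)
    return ComponentLQ(
        alpha_ion=photon.alpha_x + photon.beta_x * z,
        beta_ion=photon.beta_x,
        z1d_star=z,
    )


def mix_lq(voxel: MixedFieldVoxel) -> tuple:
    """Dose-weighted mixed-field (alpha_bar, beta_bar).

    alpha mixes linearly, sqrt(beta) mixes linearly (Zaider-Rossi).
    Raises on zero total dose (undefined, not zero).
    """
    d = voxel.total_dose
    if d <= 0:
        raise ValueError("mixed-field LQ undefined at zero dose")
    alpha_bar = float(np.sum(voxel.doses * voxel.alphas) / d)
    beta_bar = float(np.sum(voxel.doses * np.sqrt(voxel.betas)) / d) ** 2
    return alpha_bar, beta_bar


def effective_dose_from_lq(alpha_bar, beta_bar, dose,
                           photon: PhotonLQParams = PhotonLQParams()):
    """Photon-equivalent (RBE-weighted) dose with equal -ln(survival)."""
    d = np.asarray(dose, dtype=float)
    e = alpha_bar * d + beta_bar * d**2  # -ln S
    ax, bx = photon.alpha_x, photon.beta_x
    out = (-ax + np.sqrt(ax**2 + 4.0 * bx * e)) / (2.0 * bx)
    return out if out.ndim else float(out)


def effective_dose(voxel: MixedFieldVoxel,
                   photon: PhotonLQParams = PhotonLQParams()) -> float:
    """Per-fraction RBE-weighted dose (GyRBE) of one mixed-field voxel."""
    d = voxel.total_dose
    if d == 0:
        return 0.0
    alpha_bar, beta_bar = mix_lq(voxel)
    return effective_dose_from_lq(alpha_bar, beta_bar, d, photon)
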