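"""Hypoxia reduction factor (HRF/OER) model parameterized in (Z_eff/beta)^2.

For photons the HRF depends on oxygen tension alone,

    HRF_ph(pO2) = (m K + pO2) / (K + pO2),

with m = 2.94 (anoxic limit) and K = 0.129 %O2. For ions the radiation
quality RQE = (Z_eff/beta)^2 pulls the HRF back toward 1 (high-LET tracks are
oxygen-independent),

    HRF_ion(RQE, pO2) = (a HRF_ph(pO2) + RQE^gamma) / (a + RQE^gamma),

with a = 2.988e6 and gamma = 2.169. The HRF acts as a dose-modifying factor
on the LQ parameters of each mixed-field component: alpha -> alpha/HRF,
beta -> beta/HRF^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ionarc.mkm import (
    ComponentLQ,
    MixedFieldVoxel,
    PhotonLQParams,
    effective_dose,
    mix_lq,
)


@dataclass(frozen=True)
class HypoxiaParams:
    m: float = 2.94          # anoxic photon HRF limit
    K: float = 0.129         # half-effect oxygen tension, %O2
    a: float = 2.988e6       # RQE scale of the ion HRF
    gamma: float = 2.169     # RQE exponent
    reference_dose: float = 2.0   # Gy, for survival-based HRF extraction
    survival_level: float = 0.1   # S used when reducing data via the LQ form

    def __post_init__(self):
        if self.m <= 1 or min(self.K, self.a, self.gamma) <= 0:
            raise ValueError("invalid hypoxia parameters")


@dataclass(frozen=True)
class HypoxicLQ:
    alpha_h: float
    beta_h: float
    hrf: float


def hrf_photon(pO2, params: HypoxiaParams = HypoxiaParams()):
    """Photon hypoxia reduction factor; decreasing in pO2, in (1, m]."""
    p = np.asarray(pO2, dtype=float)
    if np.any(p < 0):
        raise ValueError("pO2 must be non-negative")
    out = (params.m * params.K + p) / (params.K + p)
    return out if out.ndim else float(out)


def hrf_ion(rqe, pO2, params: HypoxiaParams = HypoxiaParams()):
    """Ion hypoxia reduction factor, bounded by [1, HRF_ph(pO2)].

    Tends to HRF_ph as RQE -> 0 and to 1 as RQE -> inf (high-LET limit).
    """
    q = np.asarray(rqe, dtype=float)
    if np.any(q <= 0):
        raise ValueError("RQE must be positive")
    qg = q**params.gamma
    out = (params.a * hrf_photon(pO2, params) + qg) / (params.a + qg)
    return out if out.ndim else float(out)


def hrf_from_lq(alpha_h, beta_h, alpha_n, beta_n, survival) -> float:
    """HRF from hypoxic/normoxic LQ parameters at a given survival level.

    Ratio of iso-effect doses: D(S) = [sqrt(a^2 - 4 b ln S) - a] / (2 b), so
    HRF = ([sqrt(a_h^2 - 4 b_h lnS) - a_h] / [sqrt(a_n^2 - 4 b_n lnS) - a_n])
          * (b_n / b_h). Dose-modifying inputs (a/H, b/H^2) return exactly H
    at every survival level.
    """
    if not 0 < survival < 1:
        raise ValueError("survival must lie in (0, 1)")
    if min(alpha_h, beta_h, alpha_n, beta_n) <= 0:
        raise ValueError("LQ parameters must be positive")
    ln_s = np.log(survival)
    num = np.sqrt(alpha_h**2 - 4.0 * beta_h * ln_s) - alpha_h
    den = np.sqrt(alpha_n**2 - 4.0 * beta_n * ln_s) - alpha_n
    return float(num / den * (beta_n / beta_h))


def apply_hrf(component: ComponentLQ, rqe: float, pO2: float,
              params: HypoxiaParams = HypoxiaParams()) -> HypoxicLQ:
    """Scale one component's LQ parameters by its own HRF (Eqs. alpha/H, beta/H^2)."""
    h = hrf_ion(rqe, pO2, params)
    return HypoxicLQ(alpha_h=component.alpha_ion / h,
                     beta_h=component.beta_ion / h**2,
                     hrf=h)


def d_oer_rbe(voxel: MixedFieldVoxel, pO2: float,
              photon: PhotonLQParams = PhotonLQParams(),
              params: HypoxiaParams = HypoxiaParams()) -> float:
    """Hypoxic effective dose (GyRBE) of a mixed-field voxel.

    Each component is reduced by the HRF at its own RQE, the field is mixed
    dose-weighted, and the result inverted through the photon LQ curve.
    """
    if pO2 is None:
        raise ValueError("pO2 required for hypoxic effective dose")
    if voxel.rqes is None:
        raise ValueError("voxel lacks per-component RQE values")
    if voxel.total_dose == 0:
        return 0.0
    h = hrf_ion(voxel.rqes, pO2, params)
    hypoxic = MixedFieldVoxel(
        doses=voxel.doses,
        alphas=voxel.alphas / h,
        betas=voxel.betas / h**2,
        rqes=voxel.rqes,
    )
    return effective_dose(hypoxic, photon)


def delta_oer(d_rbe, d_oer):
    """Hypoxia dose-reduction ratio Delta_OER = D_RBE / D_OER,RBE (>= 1)."""
    d_oer = np.asarray(d_oer, dtype=float)
    if np.any(d_oer <= 0):
        raise ValueError("D_OER,RBE must be positive")
    out = np.asarray(d_rbe, dtype=float) / d_oer
    return out if out.ndim else float(out)
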