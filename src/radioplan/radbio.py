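"""Radiobiological response models and dose-effect conversions.

This module implements the dose-response machinery used throughout the
package:

* linear-quadratic (LQ) iso-effect conversions between a physical total
  dose delivered in ``N`` equal fractions and the biologically equivalent
  doses ``EQD0`` (infinitesimal fraction reference) and ``EQD2`` (2 Gy per
  fraction reference);
* the Poisson tumor control probability (TCP) model on a voxelised dose
  distribution with homogeneous clonogen density ``rho`` and LQ
  radiosensitivity ``alpha``;
* the relative-seriality normal tissue complication probability (NTCP)
  model with organ-architecture parameter ``s``;
* the composite plan-level probabilities: probability of benefit ``P_B``
  (joint tumor control over all targets), probability of injury ``P_I``
  (complement of joint complication-free survival over all organs at
  risk), and the complication-free tumor control ``P_+ = P_B * (1 - P_I)``;
* analytic inversions: the iso-effective uniform dose (the uniform EQD2
  reproducing a given TCP or NTCP) and the physical total dose producing a
  requested response level, used to derive gEUD sampling ranges;
* the generalized equivalent uniform dose (gEUD), the power-mean of the
  voxel doses with volume-effect exponent ``a``.

A differential DVH and a voxel list are interchangeable here: a DVH is a
:class:`DoseDistribution` whose "voxels" are dose bins with the bin volume
attached.  All probabilities are accumulated in log space so that products
over many voxels neither underflow nor lose precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

__all__ = [
    "FractionationScheme",
    "DoseDistribution",
    "TCPParams",
    "NTCPParams",
    "ResponseSummary",
    "eqd0",
    "eqd2",
    "physical_dose_from_eqd2",
    "tcp_poisson",
    "voxel_complication_response",
    "ntcp_relative_seriality",
    "p_benefit",
    "p_injury",
    "p_plus",
    "compute_response_summary",
    "iso_effective_uniform_dose_tcp",
    "iso_effective_uniform_dose_ntcp",
    "geud",
    "uniform_dose_for_level",
]

#: ln(ln 2), the constant anchoring the voxel sigmoid at 50% response.
_LN_LN2 = float(np.log(np.log(2.0)))

#: Probability clipping bounds applied before any logarithm.
_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


class ParameterError(ValueError):
    """A radiobiological parameter violates its admissible range."""


@dataclass(frozen=True)
class FractionationScheme:
    """Equal-fraction delivery scheme: per-voxel fraction dose is D_i / N."""

    n_fractions: int

    def __post_init__(self) -> None:
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ParameterError(
                f"n_fractions must be a positive integer, got {self.n_fractions!r}"
            )


@dataclass(frozen=True)
class TCPParams:
    """Poisson TCP model parameters for one target volume.

    Attributes
    ----------
    rho : float
        Clonogenic cell density in cells/cm^3.
    alpha : float
        Linear radiosensitivity in 1/Gy.
    alpha_beta : float
        LQ fractionation sensitivity alpha/beta in Gy.
    """

    rho: float
    alpha: float
    alpha_beta: float

    def __post_init__(self) -> None:
        for name in ("rho", "alpha", "alpha_beta"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)!r}")


@dataclass(frozen=True)
class NTCPParams:
    """Relative-seriality NTCP model parameters for one organ at risk.

    Attributes
    ----------
    d50 : float
        Uniform EQD2 (Gy) giving 50% complication probability.
    gamma : float
        Maximum normalized slope of the dose-response curve.
    alpha_beta : float
        LQ alpha/beta in Gy used for the EQD2 conversion.
    seriality : float
        Organ architecture parameter s (parallel s->0, serial s large).
    """

    d50: float
    gamma: float
    alpha_beta: float
    seriality: float

    def __post_init__(self) -> None:
        if not self.d50 > 0:
            raise ParameterError(f"d50 must be > 0, got {self.d50!r}")
        if not self.gamma > 0:
            raise ParameterError(f"gamma must be > 0, got {self.gamma!r}")
        if not self.alpha_beta > 0:
            raise ParameterError(f"alpha_beta must be > 0, got {self.alpha_beta!r}")
        if not self.seriality > 0:
            raise ParameterError(f"seriality must be > 0, got {self.seriality!r}")


@dataclass(frozen=True)
class DoseDistribution:
    """Per-voxel total physical dose with voxel volumes and fractionation.

    The unit every response model consumes.  ``voxel_dose`` holds the total
    physical dose (Gy) accumulated over all fractions; ``voxel_volume`` the
    voxel (or DVH-bin) volumes in cm^3.
    """

    voxel_dose: np.ndarray
    voxel_volume: np.ndarray
    scheme: FractionationScheme

    def __post_init__(self) -> None:
        dose = np.atleast_1d(np.asarray(self.voxel_dose, dtype=float))
        vol = np.atleast_1d(np.asarray(self.voxel_volume, dtype=float))
        if vol.size == 1 and dose.size > 1:
            vol = np.full(dose.shape, float(vol))
        if dose.shape != vol.shape:
            raise ValueError(
                f"voxel_dose and voxel_volume must have equal length "
                f"({dose.shape} vs {vol.shape})"
            )
        if dose.size == 0:
            raise ValueError("empty dose distribution")
        if np.any(dose < 0):
            raise ValueError("doses must be non-negative")
        if np.any(vol <= 0):
            raise ValueError("voxel volumes must be positive")
        object.__setattr__(self, "voxel_dose", dose)
        object.__setattr__(self, "voxel_volume", vol)

    @property
    def total_volume(self) -> float:
        return float(self.voxel_volume.sum())

    @classmethod
    def uniform(
        cls, dose: float, volume: float, scheme: FractionationScheme
    ) -> "DoseDistribution":
        """A single-voxel distribution: the whole volume at one dose."""
        return cls(np.array([dose]), np.array([volume]), scheme)


@dataclass(frozen=True)
class ResponseSummary:
    """Plan-level radiobiological scorecard.

    Holds the per-target TCPs, per-OAR NTCPs, and the composite
    probabilities P_B, P_I and P_+ = P_B * (1 - P_I).
    """

    tcp_by_target: Mapping[str, float]
    ntcp_by_oar: Mapping[str, float]
    p_benefit: float
    p_injury: float
    p_plus: float

    def __post_init__(self) -> None:
        for label, p in {**dict(self.tcp_by_target), **dict(self.ntcp_by_oar)}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {label!r} out of [0,1]: {p}")
        pb = p_benefit(list(self.tcp_by_target.values()))
        pi = p_injury(list(self.ntcp_by_oar.values()))
        if abs(self.p_benefit - pb) > 1e-12 or abs(self.p_injury - pi) > 1e-12:
            raise ValueError("p_benefit/p_injury inconsistent with components")
        if abs(self.p_plus - self.p_benefit * (1.0 - self.p_injury)) > 1e-12:
            raise ValueError("p_plus must equal p_benefit * (1 - p_injury)")

    @classmethod
    def from_probabilities(
        cls,
        tcp_by_target: Mapping[str, float],
        ntcp_by_oar: Mapping[str, float],
    ) -> "ResponseSummary":
        pb = p_benefit(list(tcp_by_target.values()))
        pi = p_injury(list(ntcp_by_oar.values()))
        return cls(
            tcp_by_target=dict(tcp_by_target),
            ntcp_by_oar=dict(ntcp_by_oar),
            p_benefit=pb,
            p_injury=pi,
            p_plus=pb * (1.0 - pi),
        )


# ---------------------------------------------------------------------------
# LQ iso-effect conversions
# ---------------------------------------------------------------------------

def eqd0(
    total_dose: Union[float, np.ndarray],
    scheme: FractionationScheme,
    alpha_beta: float,
) -> Union[float, np.ndarray]:
    """Biologically effective dose D * (1 + (D/N) / (alpha/beta)).

    This is the LQ iso-effect expressed against an infinitesimal fraction
    dose reference (alpha-only killing), per-voxel when ``total_dose`` is an
    array.
    """
    if not alpha_beta > 0:
        raise ParameterError(f"alpha/beta must be > 0, got {alpha_beta!r}")
    d = np.asarray(total_dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("total dose must be non-negative")
    out = d * (1.0 + (d / scheme.n_fractions) / alpha_beta)
    return float(out) if np.isscalar(total_dose) or out.ndim == 0 else out


def eqd2(
    total_dose: Union[float, np.ndarray],
    scheme: FractionationScheme,
    alpha_beta: float,
) -> Union[float, np.ndarray]:
    """Iso-effective dose in 2 Gy fractions: EQD0 / (1 + 2/(alpha/beta))."""
    return eqd0(total_dose, scheme, alpha_beta) / (1.0 + 2.0 / alpha_beta)


def physical_dose_from_eqd2(
    eqd2_value: Union[float, np.ndarray],
    scheme: FractionationScheme,
    alpha_beta: float,
) -> Union[float, np.ndarray]:
    """Invert :func:`eqd2`: the total physical dose in N fractions whose
    EQD2 equals ``eqd2_value``.

    Solves the quadratic D^2/(N * ab) + D - E * (1 + 2/ab) = 0 for its
    unique non-negative root.
    """
    if not alpha_beta > 0:
        raise ParameterError(f"alpha/beta must be > 0, got {alpha_beta!r}")
    e = np.asarray(eqd2_value, dtype=float)
    if np.any(e < 0):
        raise ValueError("EQD2 must be non-negative")
    nab = scheme.n_fractions * alpha_beta
    c = e * (1.0 + 2.0 / alpha_beta)
    out = 0.5 * nab * (np.sqrt(1.0 + 4.0 * c / nab) - 1.0)
    return float(out) if np.isscalar(eqd2_value) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Tumor control
# ---------------------------------------------------------------------------

def tcp_poisson(dist: DoseDistribution, params: TCPParams) -> float:
    """Poisson TCP over a voxelised dose distribution.

    TCP = prod_i exp(-rho * v_i * exp(-alpha * EQD0_i)); the product is a
    single exponential of a sum, so it is evaluated in log space by
    construction.
    """
    e0 = eqd0(dist.voxel_dose, dist.scheme, params.alpha_beta)
    # expected surviving clonogens per voxel
    survivors = params.rho * dist.voxel_volume * np.exp(-params.alpha * np.asarray(e0))
    log_tcp = -float(np.sum(survivors))
    return float(np.exp(log_tcp))


# ---------------------------------------------------------------------------
# Normal tissue complication
# ---------------------------------------------------------------------------

def voxel_complication_response(
    eqd2_i: Union[float, np.ndarray], params: NTCPParams
) -> Union[float, np.ndarray]:
    """Per-voxel sigmoid complication response P(D_i).

    P = exp(-exp(e*gamma - (EQD2_i/D50) * (e*gamma - ln ln 2))).
    At EQD2 = D50 the exponent collapses to ln ln 2, giving exactly 1/2;
    the response is strictly increasing in dose.
    """
    e = np.asarray(eqd2_i, dtype=float)
    eg = np.e * params.gamma
    out = np.exp(-np.exp(eg - (e / params.d50) * (eg - _LN_LN2)))
    return float(out) if np.isscalar(eqd2_i) or out.ndim == 0 else out


def ntcp_relative_seriality(dist: DoseDistribution, params: NTCPParams) -> float:
    """Relative-seriality NTCP over a voxelised dose distribution.

    NTCP = [1 - prod_i (1 - P(D_i)^s)^(v_i/V)]^(1/s), with P(D_i) the voxel
    sigmoid evaluated at the voxel EQD2.  The product is accumulated as a
    volume-weighted sum of log(1 - P^s).

    The 1/s power acts on the whole bracket, which is what gives the model
    its defining properties: uniform whole-organ irradiation reduces NTCP
    to the voxel response P for every s, serial organs (large s) respond
    to the hottest subvolume, and parallel organs (s -> 0) are protected
    when only a fraction of the volume is irradiated.
    """
    s = params.seriality
    e2 = np.asarray(eqd2(dist.voxel_dose, dist.scheme, params.alpha_beta))
    p = np.clip(np.asarray(voxel_complication_response(e2, params)), _P_FLOOR, _P_CEIL)
    frac = dist.voxel_volume / dist.total_volume
    # log(1 - P^s) via exp(s log P); P^s clipped away from 1 by the P ceiling
    log_term = np.log1p(-np.exp(s * np.log(p)))
    log_survival = float(np.sum(frac * log_term))
    # NTCP = (1 - exp(sum))^(1/s), evaluated via logs for tiny arguments
    one_minus = -np.expm1(log_survival)
    if one_minus <= 0.0:
        return 0.0
    return float(np.exp(np.log(one_minus) / s))


# ---------------------------------------------------------------------------
# Composite plan probabilities
# ---------------------------------------------------------------------------

def _check_probs(values: Sequence[float], what: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size and (np.any(arr < 0) or np.any(arr > 1)):
        raise ValueError(f"{what} must lie in [0, 1]")
    return arr


def p_benefit(tcps: Sequence[float]) -> float:
    """Probability of benefit: the product of all target TCPs."""
    arr = _check_probs(tcps, "TCP values")
    if arr.size == 0:
        raise ValueError("p_benefit requires at least one TCP")
    clipped = np.clip(arr, _P_FLOOR, 1.0)
    return float(np.exp(np.sum(np.log(clipped)))) if np.all(arr > 0) else 0.0


def p_injury(ntcps: Sequence[float]) -> float:
    """Probability of injury: 1 - prod_i (1 - NTCP_i); empty list -> 0."""
    arr = _check_probs(ntcps, "NTCP values")
    if arr.size == 0:
        return 0.0
    if np.any(arr >= 1.0):
        return 1.0
    return float(-np.expm1(np.sum(np.log1p(-arr))))


def p_plus(pb: float, pi: float) -> float:
    """Complication-free tumor control P_+ = P_B * (1 - P_I)."""
    _check_probs([pb, pi], "P_B and P_I")
    return float(pb * (1.0 - pi))


def compute_response_summary(
    target_doses: Mapping[str, DoseDistribution],
    target_params: Mapping[str, TCPParams],
    oar_doses: Mapping[str, DoseDistribution],
    oar_params: Mapping[str, NTCPParams],
) -> ResponseSummary:
    """Evaluate TCP/NTCP per structure and compose P_B, P_I and P_+."""
    tcp = {
        name: tcp_poisson(dist, target_params[name])
        for name, dist in target_doses.items()
    }
    ntcp = {
        name: ntcp_relative_seriality(dist, oar_params[name])
        for name, dist in oar_doses.items()
    }
    return ResponseSummary.from_probabilities(tcp, ntcp)


# ---------------------------------------------------------------------------
# Iso-effective uniform doses and level inversions
# ---------------------------------------------------------------------------

def iso_effective_uniform_dose_tcp(
    tcp: float, params: TCPParams, volume: float
) -> float:
    """Uniform EQD2 reproducing a given TCP on a structure of given volume.

    D = [ln(rho V) - ln(-ln TCP)] / [alpha * (1 + 2/(alpha/beta))].
    """
    if not 0.0 < tcp < 1.0:
        raise ValueError(f"TCP must lie strictly in (0, 1), got {tcp!r}")
    if not volume > 0:
        raise ValueError("volume must be positive")
    num = np.log(params.rho * volume) - np.log(-np.log(tcp))
    den = params.alpha * (1.0 + 2.0 / params.alpha_beta)
    return float(num / den)


def iso_effective_uniform_dose_ntcp(ntcp: float, params: NTCPParams) -> float:
    """Uniform EQD2 at which the voxel sigmoid equals the given NTCP.

    D = D50 * [e*gamma - ln(-ln NTCP)] / [e*gamma - ln ln 2].

    Note this inverts the per-voxel response P, not the s-composed organ
    NTCP; for uniform whole-organ irradiation the two coincide only when
    s = 1 (see the methods note).
    """
    if not 0.0 < ntcp < 1.0:
        raise ValueError(f"NTCP must lie strictly in (0, 1), got {ntcp!r}")
    eg = np.e * params.gamma
    return float(params.d50 * (eg - np.log(-np.log(ntcp))) / (eg - _LN_LN2))


def uniform_dose_for_level(
    level: float,
    model: Union[TCPParams, NTCPParams],
    volume: float | None,
    scheme: FractionationScheme,
) -> float:
    """Physical total dose (N fractions) whose uniform delivery to the full
    structure yields the requested TCP or NTCP level.

    Composes the iso-effective uniform EQD2 with the EQD2 -> physical dose
    inversion for the structure's alpha/beta.
    """
    if isinstance(model, TCPParams):
        if volume is None:
            raise ValueError("TCP level inversion requires the structure volume")
        e2 = iso_effective_uniform_dose_tcp(level, model, volume)
    elif isinstance(model, NTCPParams):
        e2 = iso_effective_uniform_dose_ntcp(level, model)
    else:  # pragma: no cover - type guard
        raise TypeError(f"unsupported model type {type(model)!r}")
    return physical_dose_from_eqd2(max(e2, 0.0), scheme, model.alpha_beta)


# ---------------------------------------------------------------------------
# Generalized equivalent uniform dose
# ---------------------------------------------------------------------------

def geud(dist: DoseDistribution, a: float) -> float:
    """Generalized EUD: the volume-weighted power mean of voxel doses.

    gEUD = (sum_i (v_i/V) D_i^a)^(1/a).  Large positive ``a`` approaches
    the maximum dose (upper objectives), large negative ``a`` the minimum
    (lower objectives).  The sum is rescaled by the maximum (a > 0) or
    minimum (a < 0) dose so that |a| = 40 stays in floating-point range at
    clinical dose levels.
    """
    if a == 0:
        raise ParameterError("gEUD exponent a must be nonzero")
    d = dist.voxel_dose
    frac = dist.voxel_volume / dist.total_volume
    if a < 0 and np.any(d <= 0):
        # a cold voxel forces the power mean to zero; documented convention
        return 0.0
    ref = float(d.max()) if a > 0 else float(d.min())
    if ref == 0.0:
        return 0.0
    mean_pow = float(np.sum(frac * (d / ref) ** a))
    return ref * mean_pow ** (1.0 / a)
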