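"""Radiobiological model unit and property tests.

Independent oracles: naive direct-product TCP/NTCP evaluation, bisection
inversions, and hand-evaluated closed forms.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import radioplan.radbio as rb

S20 = rb.FractionationScheme(20)


# ---------------------------------------------------------------------------
# naive oracles (plain products, no log-space tricks)
# ---------------------------------------------------------------------------

def naive_tcp(dose, vol, scheme, p: rb.TCPParams) -> float:
    e0 = dose * (1 + (dose / scheme.n_fractions) / p.alpha_beta)
    return float(np.prod(np.exp(-p.rho * vol * np.exp(-p.alpha * e0))))


def naive_ntcp(dose, vol, scheme, p: rb.NTCPParams) -> float:
    e2 = dose * (1 + (dose / scheme.n_fractions) / p.alpha_beta) / (1 + 2 / p.alpha_beta)
    eg = np.e * p.gamma
    resp = np.exp(-np.exp(eg - (e2 / p.d50) * (eg - np.log(np.log(2)))))
    inner = np.prod((1 - resp**p.seriality) ** (vol / vol.sum()))
    return float((1 - inner) ** (1 / p.seriality))


# ---------------------------------------------------------------------------
# LQ conversions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dose, n, ab, expected",
    [
        (60.0, 20, 1.6, 172.5),  # 60 * (1 + 3/1.6)
        (0.0, 20, 1.6, 0.0),
        (40.0, 20, 3.0, 66.6667),  # 40 * (1 + 2/3)
    ],
)
def test_eqd0_hand_values(dose, n, ab, expected):
    assert rb.eqd0(dose, rb.FractionationScheme(n), ab) == pytest.approx(expected, abs=1e-3)


@pytest.mark.parametrize(
    "dose, n, ab, expected, decimals",
    [
        (60.0, 20, 1.6, 76.7, 1),
        (70.0, 20, 1.6, 99.17, 2),
        (40.0, 20, 3.0, 40.0, 2),  # 2 Gy/fx is the reference fractionation
    ],
)
def test_eqd2_hand_values(dose, n, ab, expected, decimals):
    got = rb.eqd2(dose, rb.FractionationScheme(n), ab)
    assert round(got, decimals) == pytest.approx(expected)


@given(ab=st.floats(0.5, 10.0), n=st.integers(1, 40))
@settings(max_examples=50, deadline=None)
def test_eqd2_identity_at_reference_fraction_dose(ab, n):
    """A plan delivering exactly 2 Gy per fraction is its own EQD2."""
    dose = 2.0 * n
    assert rb.eqd2(dose, rb.FractionationScheme(n), ab) == pytest.approx(dose, rel=1e-12)


@pytest.mark.parametrize("dose", [10.0, 25.0, 40.0, 60.0, 77.7, 100.0])
def test_eqd2_inversion_round_trip(dose):
    e = rb.eqd2(dose, S20, 1.6)
    assert rb.physical_dose_from_eqd2(e, S20, 1.6) == pytest.approx(dose, rel=1e-10)


def test_eqd2_inversion_examples():
    assert rb.physical_dose_from_eqd2(76.667, S20, 1.6) == pytest.approx(60.0, abs=1e-3)
    assert rb.physical_dose_from_eqd2(0.0, S20, 1.6) == 0.0
    with pytest.raises(ValueError):
        rb.physical_dose_from_eqd2(-1.0, S20, 1.6)


def test_parameter_validation():
    with pytest.raises(rb.ParameterError):
        rb.eqd0(60.0, S20, -1.0)
    with pytest.raises(rb.ParameterError):
        rb.FractionationScheme(0)
    with pytest.raises(rb.ParameterError):
        rb.TCPParams(rho=-1, alpha=0.1, alpha_beta=1.6)
    with pytest.raises(rb.ParameterError):
        rb.NTCPParams(d50=80, gamma=1.8, alpha_beta=3.0, seriality=0.0)


# ---------------------------------------------------------------------------
# TCP
# ---------------------------------------------------------------------------

def test_tcp_uniform_half_control():
    """Uniform EQD0 = 172.88 Gy over 2.76 cm^3 at rho = 2.8e8, alpha = 0.1205
    sits at the 50% control point (alpha*EQD0 = ln(rho V) - ln(-ln 0.5))."""
    p = rb.TCPParams(rho=2.8e8, alpha=0.1205, alpha_beta=1.6)
    dose = rb.physical_dose_from_eqd2(172.88 / (1 + 2 / 1.6), S20, 1.6)
    dist = rb.DoseDistribution.uniform(dose, 2.76, S20)
    assert rb.tcp_poisson(dist, p) == pytest.approx(0.5, abs=2e-3)


def test_tcp_zero_dose_is_hopeless():
    p = rb.TCPParams(rho=2.8e8, alpha=0.1205, alpha_beta=1.6)
    dist = rb.DoseDistribution.uniform(0.0, 10.0, S20)
    assert rb.tcp_poisson(dist, p) <= 1e-100


def test_tcp_voxel_split_invariance():
    """Splitting a voxel into equal-dose halves leaves TCP unchanged."""
    p = rb.TCPParams(rho=1e6, alpha=0.2, alpha_beta=3.0)
    whole = rb.DoseDistribution(np.array([55.0]), np.array([10.0]), S20)
    halves = rb.DoseDistribution(np.array([55.0, 55.0]), np.array([5.0, 5.0]), S20)
    assert rb.tcp_poisson(whole, p) == pytest.approx(rb.tcp_poisson(halves, p), rel=1e-14)


@given(seed=st.integers(0, 1000))
@settings(max_examples=30, deadline=None)
def test_tcp_ntcp_match_naive_products(seed):
    """Log-space accumulation equals plain products on moderate cases."""
    rng = np.random.default_rng(seed)
    n = rng.integers(1, 100)
    dose = rng.uniform(20.0, 70.0, n)
    vol = rng.uniform(0.05, 1.0, n)
    tp = rb.TCPParams(rho=1e6, alpha=0.15, alpha_beta=2.0)
    np_ = rb.NTCPParams(d50=70.0, gamma=2.0, alpha_beta=3.0, seriality=0.8)
    dist = rb.DoseDistribution(dose, vol, S20)
    assert rb.tcp_poisson(dist, tp) == pytest.approx(
        naive_tcp(dose, vol, S20, tp), rel=1e-10
    )
    assert rb.ntcp_relative_seriality(dist, np_) == pytest.approx(
        naive_ntcp(dose, vol, S20, np_), rel=1e-10
    )


@given(seed=st.integers(0, 1000))
@settings(max_examples=25, deadline=None)
def test_response_monotone_in_dose(seed):
    """TCP and NTCP never decrease under a voxelwise dose increase."""
    rng = np.random.default_rng(seed)
    n = rng.integers(2, 30)
    dose = rng.uniform(10.0, 60.0, n)
    bump = np.zeros(n)
    bump[rng.integers(0, n)] = rng.uniform(0.5, 10.0)
    vol = rng.uniform(0.1, 1.0, n)
    tp = rb.TCPParams(rho=1e7, alpha=0.12, alpha_beta=1.6)
    np_ = rb.NTCPParams(d50=65.0, gamma=2.2, alpha_beta=3.0, seriality=1.1)
    lo = rb.DoseDistribution(dose, vol, S20)
    hi = rb.DoseDistribution(dose + bump, vol, S20)
    assert rb.tcp_poisson(hi, tp) >= rb.tcp_poisson(lo, tp)
    assert rb.ntcp_relative_seriality(hi, np_) >= rb.ntcp_relative_seriality(lo, np_)


# ---------------------------------------------------------------------------
# NTCP voxel response and organ model
# ---------------------------------------------------------------------------

def test_voxel_response_anchors():
    rectum = rb.NTCPParams(d50=80.0, gamma=1.79, alpha_beta=3.0, seriality=0.75)
    bladder = rb.NTCPParams(d50=80.0, gamma=2.59, alpha_beta=3.0, seriality=1.3)
    # EQD2 = D50 -> exactly one half, any slope
    assert rb.voxel_complication_response(80.0, rectum) == pytest.approx(0.5, abs=1e-15)
    # zero dose: double-exponential collapse, exp(-e^(e*gamma))
    assert rb.voxel_complication_response(0.0, rectum) < 1e-50
    # EQD2 = 2*D50 with gamma = 2.59: direct evaluation of the sigmoid
    assert rb.voxel_complication_response(160.0, bladder) == pytest.approx(0.99958, abs=5e-5)


def test_voxel_response_increasing():
    p = rb.NTCPParams(d50=70.0, gamma=2.5, alpha_beta=3.0, seriality=0.7)
    grid = np.linspace(0.0, 200.0, 400)
    resp = np.asarray(rb.voxel_complication_response(grid, p))
    assert np.all(np.diff(resp) >= 0)
    # strictly increasing wherever the response is representable
    alive = resp > 1e-200
    assert np.all(np.diff(resp[alive]) > 0)


def test_ntcp_uniform_reduces_to_voxel_response():
    """Defining property of relative seriality: uniform whole-organ
    irradiation gives NTCP equal to the voxel response, for every s."""
    for s in (0.14, 0.75, 1.0, 1.3, 3.0):
        p = rb.NTCPParams(d50=80.0, gamma=2.0, alpha_beta=3.0, seriality=s)
        for e2 in (40.0, 80.0, 110.0):
            dose = rb.physical_dose_from_eqd2(e2, S20, 3.0)
            dist = rb.DoseDistribution.uniform(dose, 25.0, S20)
            assert rb.ntcp_relative_seriality(dist, p) == pytest.approx(
                rb.voxel_complication_response(e2, p), rel=1e-9
            )


def test_ntcp_at_d50_and_zero():
    p = rb.NTCPParams(d50=80.0, gamma=1.79, alpha_beta=3.0, seriality=1.0)
    at_d50 = rb.DoseDistribution.uniform(
        rb.physical_dose_from_eqd2(80.0, S20, 3.0), 50.0, S20
    )
    assert rb.ntcp_relative_seriality(at_d50, p) == pytest.approx(0.5, rel=1e-9)
    cold = rb.DoseDistribution.uniform(0.0, 50.0, S20)
    assert rb.ntcp_relative_seriality(cold, p) < 1e-12


def test_ntcp_parallel_organ_partial_volume_protection():
    """With small s, sparing most of the organ keeps NTCP far below the
    voxel response of the irradiated subvolume."""
    p = rb.NTCPParams(d50=60.0, gamma=2.1, alpha_beta=3.0, seriality=0.14)
    partial = rb.DoseDistribution(
        np.array([60.0 * 20 / 18.0, 0.0]), np.array([5.0, 45.0]), S20
    )
    assert rb.ntcp_relative_seriality(partial, p) < 0.01


# ---------------------------------------------------------------------------
# Composite probabilities
# ---------------------------------------------------------------------------

def test_composite_probability_worked_example():
    """Published worked example: TCPs 99.90/99.88/99.93 % compose to
    P_B = 99.71 %, and with P_I = 0.04 % give P_+ = 99.67 %."""
    pb = rb.p_benefit([0.9990, 0.9988, 0.9993])
    assert round(100 * pb, 2) == pytest.approx(99.71)
    pp = rb.p_plus(pb, 0.0004)
    assert round(100 * pp, 2) == pytest.approx(99.67)


def test_composite_probability_edge_cases():
    assert rb.p_plus(1.0, 0.0) == 1.0
    assert rb.p_injury([]) == 0.0
    assert rb.p_injury([0.1, 0.2]) == pytest.approx(1 - 0.9 * 0.8, rel=1e-12)
    with pytest.raises(ValueError):
        rb.p_benefit([1.2])
    with pytest.raises(ValueError):
        rb.p_injury([-0.1])
    with pytest.raises(ValueError):
        rb.p_benefit([])


def test_response_summary_identities():
    s = rb.ResponseSummary.from_probabilities(
        {"a": 0.99, "b": 0.98}, {"x": 0.01, "y": 0.02}
    )
    assert s.p_benefit == pytest.approx(0.99 * 0.98, abs=1e-12)
    assert s.p_injury == pytest.approx(1 - 0.99 * 0.98, abs=1e-12)
    assert s.p_plus == pytest.approx(s.p_benefit * (1 - s.p_injury), abs=1e-12)
    with pytest.raises(ValueError):
        rb.ResponseSummary({"a": 0.9}, {}, p_benefit=0.5, p_injury=0.0, p_plus=0.5)


# ---------------------------------------------------------------------------
# Iso-effective uniform doses and level inversion
# ---------------------------------------------------------------------------

def test_iso_effective_tcp_closed_form():
    p = rb.TCPParams(rho=2.8e8, alpha=0.1205, alpha_beta=1.6)
    assert rb.iso_effective_uniform_dose_tcp(0.5, p, 2.76) == pytest.approx(
        76.83, abs=0.01
    )


@pytest.mark.parametrize("tcp", [0.85, 0.99, 0.9999])
def test_iso_effective_tcp_round_trip(tcp):
    p = rb.TCPParams(rho=2.8e8, alpha=0.1205, alpha_beta=1.6)
    e2 = rb.iso_effective_uniform_dose_tcp(tcp, p, 2.76)
    dose = rb.physical_dose_from_eqd2(e2, S20, p.alpha_beta)
    dist = rb.DoseDistribution.uniform(dose, 2.76, S20)
    assert rb.tcp_poisson(dist, p) == pytest.approx(tcp, rel=1e-9)


def test_iso_effective_tcp_monotone_and_domain():
    p = rb.TCPParams(rho=1e7, alpha=0.15, alpha_beta=2.0)
    assert rb.iso_effective_uniform_dose_tcp(
        0.9999, p, 10.0
    ) > rb.iso_effective_uniform_dose_tcp(0.85, p, 10.0)
    with pytest.raises(ValueError):
        rb.iso_effective_uniform_dose_tcp(1.0, p, 10.0)
    with pytest.raises(ValueError):
        rb.iso_effective_uniform_dose_tcp(0.0, p, 10.0)


def test_iso_effective_ntcp_inverts_voxel_response():
    bladder = rb.NTCPParams(d50=80.0, gamma=2.59, alpha_beta=3.0, seriality=1.3)
    assert rb.iso_effective_uniform_dose_ntcp(0.5, bladder) == pytest.approx(80.0, rel=1e-12)
    # bisection oracle for the 10% level
    lo, hi = 0.0, 200.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if rb.voxel_complication_response(mid, bladder) < 0.1:
            lo = mid
        else:
            hi = mid
    x = rb.iso_effective_uniform_dose_ntcp(0.1, bladder)
    assert x == pytest.approx(0.5 * (lo + hi), rel=1e-9)
    assert rb.voxel_complication_response(x, bladder) == pytest.approx(0.1, rel=1e-9)
    levels = np.linspace(0.01, 0.99, 25)
    doses = [rb.iso_effective_uniform_dose_ntcp(v, bladder) for v in levels]
    assert np.all(np.diff(doses) > 0)


def test_uniform_dose_for_level_forward_checks():
    p = rb.TCPParams(rho=2.8e8, alpha=0.1205, alpha_beta=1.6)
    for level in (0.85, 0.9999):
        d = rb.uniform_dose_for_level(level, p, 2.76, S20)
        dist = rb.DoseDistribution.uniform(d, 2.76, S20)
        assert rb.tcp_poisson(dist, p) == pytest.approx(level, abs=1e-6)
    assert rb.uniform_dose_for_level(0.9999, p, 2.76, S20) > rb.uniform_dose_for_level(
        0.85, p, 2.76, S20
    )
    # smaller structure needs less dose for the same control level
    assert rb.uniform_dose_for_level(0.9, p, 1.0, S20) < rb.uniform_dose_for_level(
        0.9, p, 30.0, S20
    )
    oar = rb.NTCPParams(d50=80.0, gamma=1.79, alpha_beta=3.0, seriality=0.75)
    d = rb.uniform_dose_for_level(0.1, oar, None, S20)
    dist = rb.DoseDistribution.uniform(d, 50.0, S20)
    assert rb.ntcp_relative_seriality(dist, oar) == pytest.approx(0.1, abs=1e-6)


# ---------------------------------------------------------------------------
# gEUD
# ---------------------------------------------------------------------------

def test_geud_special_cases():
    d = rb.DoseDistribution(np.array([30.0, 50.0, 70.0]), np.array([1.0, 2.0, 1.0]), S20)
    assert rb.geud(d, 1.0) == pytest.approx(np.average([30, 50, 70], weights=[1, 2, 1]))
    uni = rb.DoseDistribution.uniform(63.0, 10.0, S20)
    for a in (-40.0, -1.0, 1.0, 40.0):
        assert rb.geud(uni, a) == pytest.approx(63.0, rel=1e-12)


def test_geud_large_exponent_stable():
    """Equal-volume {60, 70} Gy with a = 40: power-mean hand value."""
    d = rb.DoseDistribution(np.array([60.0, 70.0]), np.array([1.0, 1.0]), S20)
    assert rb.geud(d, 40.0) == pytest.approx(68.8010, abs=1e-3)
    # a = -40 leans to the minimum
    assert rb.geud(d, -40.0) == pytest.approx(61.06, abs=0.05)


def test_geud_conventions_and_errors():
    d = rb.DoseDistribution(np.array([0.0, 60.0]), np.array([1.0, 1.0]), S20)
    assert rb.geud(d, -40.0) == 0.0  # cold voxel convention for lower objectives
    with pytest.raises(rb.ParameterError):
        rb.geud(d, 0.0)


@given(scale=st.floats(0.1, 3.0), seed=st.integers(0, 100))
@settings(max_examples=25, deadline=None)
def test_geud_scale_equivariance(scale, seed):
    rng = np.random.default_rng(seed)
    dose = rng.uniform(1.0, 80.0, 12)
    vol = rng.uniform(0.1, 1.0, 12)
    d1 = rb.DoseDistribution(dose, vol, S20)
    d2 = rb.DoseDistribution(scale * dose, vol, S20)
    for a in (-40.0, 2.0, 40.0):
        assert rb.geud(d2, a) == pytest.approx(scale * rb.geud(d1, a), rel=1e-9)
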