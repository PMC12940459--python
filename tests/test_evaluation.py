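"""DVH, dose-volume metrics, constraint checking and gamma-index tests."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

import radioplan as rp
from radioplan import datasets
from radioplan.evaluation import (
    ClinicalConstraint,
    CumulativeDVH,
    GammaCriteria,
    MissingStructureError,
    build_dvh,
    cumulative,
    dose_at_volume,
    eqd2_dvh,
    evaluate_constraints,
    gamma_pass_rate,
    homogeneity_index,
    volume_at_dose,
)
from radioplan.radbio import DoseDistribution, FractionationScheme

S20 = FractionationScheme(20)


# ---------------------------------------------------------------------------
# DVH construction
# ---------------------------------------------------------------------------

def test_uniform_dose_occupies_single_bin():
    dist = DoseDistribution.uniform(60.0, 40.0, S20)
    dvh = build_dvh(dist, bin_width=0.05)
    assert np.count_nonzero(dvh.bin_volume) == 1
    assert dvh.total_volume == pytest.approx(40.0, rel=1e-12)


def test_dvh_volume_conservation_and_cumulative_shape():
    rng = np.random.default_rng(0)
    dist = DoseDistribution(rng.uniform(0, 75, 500), rng.uniform(0.01, 0.2, 500), S20)
    dvh = build_dvh(dist, bin_width=0.1)
    assert dvh.total_volume == pytest.approx(dist.total_volume, rel=1e-9)
    cdvh = cumulative(dvh)
    assert cdvh.volume[0] == pytest.approx(dist.total_volume, rel=1e-9)
    assert np.all(np.diff(cdvh.volume) <= 1e-12)
    assert volume_at_dose(cdvh, 0.0, relative=False) == pytest.approx(
        dvh.bin_volume.sum(), rel=1e-12
    )


def test_metrics_from_voxels_and_fine_dvh_agree():
    rng = np.random.default_rng(3)
    doses = rng.uniform(40, 70, 2000)
    dist = DoseDistribution(doses, np.full(2000, 0.01), S20)
    bin_width = 0.05
    cdvh = cumulative(build_dvh(dist, bin_width))
    for pct in (2.0, 50.0, 98.0):
        exact = np.percentile(doses, 100 - pct)
        assert dose_at_volume(cdvh, pct) == pytest.approx(exact, abs=2 * bin_width)


# ---------------------------------------------------------------------------
# Point metrics and homogeneity
# ---------------------------------------------------------------------------

def test_point_metrics_uniform_dose():
    cdvh = cumulative(build_dvh(DoseDistribution.uniform(60.0, 40.0, S20), 0.05))
    assert dose_at_volume(cdvh, 98.0) == pytest.approx(60.0, abs=0.1)
    assert dose_at_volume(cdvh, 2.0) == pytest.approx(60.0, abs=0.1)
    assert volume_at_dose(cdvh, 0.0) == pytest.approx(100.0)
    assert homogeneity_index(cdvh) == pytest.approx(0.0, abs=0.01)


def test_point_metrics_two_level_distribution():
    dist = DoseDistribution(np.array([50.0, 70.0]), np.array([1.0, 1.0]), S20)
    cdvh = cumulative(build_dvh(dist, 0.05))
    d50 = dose_at_volume(cdvh, 50.0)
    assert 50.0 <= d50 <= 70.0
    assert volume_at_dose(cdvh, 50.0) == pytest.approx(100.0)
    assert volume_at_dose(cdvh, 60.0) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        dose_at_volume(cdvh, 0.0)
    with pytest.raises(ValueError):
        dose_at_volume(cdvh, 100.0)


def test_homogeneity_index_hand_value_and_scaling():
    # curve engineered so D2% = 70, D50% = 63, D98% = 58.8
    cdvh = CumulativeDVH(
        dose=np.array([0.0, 58.8, 63.0, 70.0]),
        volume=np.array([100.0, 98.0, 50.0, 2.0]),
    )
    assert homogeneity_index(cdvh) == pytest.approx((70 - 58.8) / 63.0, rel=1e-12)
    doubled = CumulativeDVH(dose=2 * cdvh.dose, volume=cdvh.volume)
    assert homogeneity_index(doubled) == pytest.approx(homogeneity_index(cdvh), rel=1e-12)


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------

def test_cold_oar_passes_all_constraints():
    dvh = build_dvh(DoseDistribution.uniform(0.0, 50.0, S20), 0.5, "bladder")
    constraints = [
        c for c in datasets.clinical_constraints("physical_20fx")
        if c.structure == "bladder"
    ]
    report = evaluate_constraints({"bladder": dvh}, constraints)
    assert report["passed"].all()


def test_volume_constraint_failure_reports_measured_value():
    # 60% of the bladder at 45 Gy against V_40Gy <= 50%
    dist = DoseDistribution(np.array([45.0, 20.0]), np.array([30.0, 20.0]), S20)
    dvh = build_dvh(dist, 0.1, "bladder")
    c = ClinicalConstraint("bladder", "V_at_dose", "le", 50.0, "pct", dose_gy=40.0)
    report = evaluate_constraints({"bladder": dvh}, [c])
    assert not report.loc[0, "passed"]
    assert report.loc[0, "measured"] == pytest.approx(60.0, abs=0.5)


def test_constraint_fixture_offers_both_dose_scales():
    phys = datasets.clinical_constraints("physical_20fx")
    eqd2 = datasets.clinical_constraints("eqd2")
    assert {c.structure for c in phys} == {c.structure for c in eqd2}
    # spot checks against the protocol table
    rectum_v60 = [c for c in phys if c.structure == "rectum" and c.dose_gy == 60.0]
    assert rectum_v60[0].limit == 3.0 and rectum_v60[0].unit == "pct"
    bladder_abs = [c for c in eqd2 if c.structure == "bladder" and c.unit == "cm3"]
    assert bladder_abs[0].dose_gy == pytest.approx(85.1)
    with pytest.raises(KeyError):
        datasets.clinical_constraints("nope")


def test_missing_structure_is_a_configuration_error():
    dvh = build_dvh(DoseDistribution.uniform(10.0, 5.0, S20), 0.5, "rectum")
    c = ClinicalConstraint("bladder", "D_max", "le", 47.0, "Gy")
    with pytest.raises(MissingStructureError):
        evaluate_constraints({"rectum": dvh}, [c])


def test_eqd2_dvh_transform_matches_scalar_conversion():
    dvh = build_dvh(DoseDistribution.uniform(60.0, 40.0, S20), 0.05, "ptv2")
    out = eqd2_dvh(dvh, S20, 1.6)
    assert out.bin_edges[-1] == pytest.approx(
        rp.eqd2(float(dvh.bin_edges[-1]), S20, 1.6), rel=1e-12
    )
    assert out.total_volume == pytest.approx(dvh.total_volume)


# ---------------------------------------------------------------------------
# Gamma index
# ---------------------------------------------------------------------------

def gamma_oracle(ref, ev, spacing, crit):
    """Exhaustive gamma search: per-point loop over every sub-voxel offset
    within the capped radius (no sorting, no early exit)."""
    ref = np.asarray(ref, float)
    ev = np.asarray(ev, float)
    spacing = np.asarray(spacing, float)
    axes = [np.arange(n) * s for n, s in zip(ref.shape, spacing)]
    interp = RegularGridInterpolator(axes, ref, bounds_error=False, fill_value=np.nan)
    tol = crit.dose_tolerance * ref.max()
    radius = crit.search_radius_factor * crit.dta_mm
    k = int(np.floor(radius / crit.search_step_mm))
    one = np.arange(-k, k + 1) * crit.search_step_mm
    mesh = np.meshgrid(*([one] * ref.ndim), indexing="ij")
    offs = np.stack([m.ravel() for m in mesh], axis=1)
    offs = offs[np.sum(offs**2, axis=1) <= radius**2 + 1e-9]
    passed = total = 0
    for idx in np.argwhere(ev >= crit.low_dose_threshold * ref.max()):
        pt = idx * spacing
        rd = interp(pt + offs)
        ok = ~np.isnan(rd)
        g2 = ((ev[tuple(idx)] - rd[ok]) / tol) ** 2 + np.sum(
            offs[ok] ** 2, axis=1
        ) / crit.dta_mm**2
        total += 1
        passed += bool(np.sqrt(g2.min()) <= 1 + 1e-12)
    return 100.0 * passed / total


def test_gamma_identical_grids_pass_fully():
    rng = np.random.default_rng(1)
    grid = rng.uniform(10, 70, (8, 8, 6))
    assert gamma_pass_rate(grid, grid, [2.5, 2.5, 2.5]) == 100.0


def test_gamma_within_global_dose_tolerance_passes():
    rng = np.random.default_rng(2)
    ref = rng.uniform(30, 70, (8, 8, 6))
    assert gamma_pass_rate(ref, 1.02 * ref, [2.5, 2.5, 2.5]) == 100.0


def test_gamma_shifted_gradient_fails_in_the_penumbra():
    """A steep 1-D profile shifted by 5 mm exceeds a 2 mm DTA with a tight
    dose tolerance; oracle agrees point by point."""
    x = np.arange(60) * 1.0  # 1 mm spacing
    ref = 70.0 / (1.0 + np.exp(-(x - 30.0)))
    ev = 70.0 / (1.0 + np.exp(-(x - 35.0)))
    crit = GammaCriteria(dose_tolerance=0.01, dta_mm=2.0)
    rate = gamma_pass_rate(ref, ev, [1.0], crit)
    assert rate < 100.0
    assert rate == pytest.approx(gamma_oracle(ref, ev, [1.0], crit), abs=1e-9)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_gamma_equals_exhaustive_oracle_on_random_grids(seed):
    rng = np.random.default_rng(seed)
    ref = rng.uniform(0, 70, (12, 12))
    ev = ref + rng.normal(0, 2.0, ref.shape)
    crit = GammaCriteria()
    assert gamma_pass_rate(ref, ev, [2.0, 2.0], crit) == pytest.approx(
        gamma_oracle(ref, ev, [2.0, 2.0], crit), abs=1e-9
    )


def test_gamma_pass_rate_monotone_in_criteria():
    rng = np.random.default_rng(7)
    ref = rng.uniform(0, 70, (10, 10))
    ev = ref + rng.normal(0, 2.5, ref.shape)
    base = gamma_pass_rate(ref, ev, [2.5, 2.5], GammaCriteria())
    looser_dose = gamma_pass_rate(
        ref, ev, [2.5, 2.5], GammaCriteria(dose_tolerance=0.06)
    )
    looser_dta = gamma_pass_rate(ref, ev, [2.5, 2.5], GammaCriteria(dta_mm=4.0))
    assert looser_dose >= base
    assert looser_dta >= base


def test_gamma_input_validation():
    grid = np.ones((4, 4))
    with pytest.raises(ValueError):
        gamma_pass_rate(grid, np.ones((5, 4)), [1, 1])
    with pytest.raises(ValueError):
        gamma_pass_rate(np.zeros((4, 4)), grid, [1, 1])  # zero reference max
    with pytest.raises(ValueError):
        gamma_pass_rate(grid, 0.0 * grid, [1, 1])  # nothing above threshold
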