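"""Synthetic cohort generator: determinism, calibration, closure, selection."""

import numpy as np
import pandas as pd
import pytest

from toricpred.cohort import (
    CohortConfig,
    TruncNormalSpec,
    generate_cohort,
    sample_truncnorm,
    select_toricity,
)
from toricpred.double_angle import Astigmatism, vec_add
from toricpred.io import cohort_records
from toricpred.optics import VergenceContext, iol_cyl_to_corneal


def test_same_seed_identical_cohorts():
    cfg = CohortConfig(seed=101, n_eyes=25)
    c1, t1 = generate_cohort(cfg)
    c2, t2 = generate_cohort(cfg)
    pd.testing.assert_frame_equal(c1, c2)
    pd.testing.assert_frame_equal(t1, t2)


def test_different_seed_differs():
    c1, _ = generate_cohort(CohortConfig(seed=101, n_eyes=25))
    c2, _ = generate_cohort(CohortConfig(seed=102, n_eyes=25))
    assert not c1.equals(c2)


def test_noise_free_devices_equal_truth(noise_free_cfg, noise_free_cohort):
    cohort, truth = noise_free_cohort
    np.testing.assert_allclose(
        cohort["iolmaster_mag_d"], truth["true_anterior_mag_d"], atol=1e-12
    )
    np.testing.assert_allclose(
        cohort["wavefront_mag_d"], truth["true_total_mag_d"], atol=1e-12
    )
    # wavefront axis matches true total axis (up to zero-magnitude canonicalization)
    np.testing.assert_allclose(
        cohort["wavefront_axis_deg"], truth["true_total_axis_deg"], atol=1e-9
    )


def test_truth_composition_invariant(noise_free_cohort):
    """True postop cylinder = true preop total ⊕ IOL vector ⊕ true SICA."""
    cohort, truth = noise_free_cohort
    for (_, c), (_, t) in zip(cohort.iterrows(), truth.iterrows()):
        total = Astigmatism(t["true_total_mag_d"], t["true_total_axis_deg"])
        for tp in ("1m", "3m"):
            ivec = Astigmatism(t["iol_corneal_cyl_d"], c[f"observed_axis_{tp}_deg"] + 90.0)
            sica = Astigmatism(t[f"true_sica_{tp}_mag_d"], t[f"true_sica_{tp}_axis_deg"])
            composed = vec_add(vec_add(total, ivec), sica)
            stated = Astigmatism(
                t[f"true_postop_cyl_{tp}_mag_d"], t[f"true_postop_cyl_{tp}_axis_deg"]
            )
            assert composed.isclose(stated, tol=1e-9)


def test_truncnorm_mean_calibration(rng):
    spec = TruncNormalSpec(mean=0.26, sd=0.20, lo=0.10, hi=0.70)
    x = sample_truncnorm(spec, rng, 200_000)
    assert x.mean() == pytest.approx(0.26, abs=3.0 * x.std() / np.sqrt(x.size))
    assert x.min() >= 0.10 and x.max() <= 0.70


def test_truncnorm_degenerate_and_validation(rng):
    spec = TruncNormalSpec(mean=0.5, sd=0.0, lo=0.0, hi=1.0)
    assert np.all(sample_truncnorm(spec, rng, 5) == 0.5)
    with pytest.raises(ValueError):
        TruncNormalSpec(mean=2.0, sd=0.1, lo=0.0, hi=1.0)  # mean outside bounds
    with pytest.raises(ValueError):
        TruncNormalSpec(mean=0.5, sd=0.1, lo=1.0, hi=0.0)  # infeasible interval


def test_posterior_magnitudes_law_of_large_numbers():
    cfg = CohortConfig(seed=77, n_eyes=10_000, wtr_fraction=1.0)
    _, truth = generate_cohort(cfg)
    mags = truth["true_posterior_mag_d"]
    se = mags.std() / np.sqrt(len(mags))
    assert mags.mean() == pytest.approx(0.56, abs=3 * se)


def test_subgroup_axes_respect_bands():
    cohort, truth = generate_cohort(CohortConfig(seed=9, n_eyes=400).noise_free())
    wtr = truth["subgroup"] == "WTR"
    ant_axis = truth["true_anterior_axis_deg"]
    assert ((ant_axis[wtr] >= 60) & (ant_axis[wtr] <= 120)).all()
    atr_ax = ant_axis[~wtr]
    assert ((atr_ax <= 30) | (atr_ax >= 150)).all()


def test_select_toricity_brute_force():
    ctx = VergenceContext(12.0, 5.0, 23.98, 43.5, 118.5)
    cfg = CohortConfig(seed=1, toricity_steps_d=[1.0, 1.5, 2.0, 2.25])
    predicted = Astigmatism(1.69, 90.0)
    step, intended = select_toricity(predicted, 19.4, ctx, cfg)
    # incision at 180°: subtracting the assumed-SICA vector adds 0.5 D at 90°
    target = vec_add(predicted, Astigmatism(cfg.assumed_sica_d, 90.0))
    dists = {
        s: abs(iol_cyl_to_corneal(s, 19.4, ctx) - target.magnitude)
        for s in cfg.toricity_steps_d
    }
    assert step == min(sorted(dists), key=lambda s: (dists[s], s))
    assert intended == pytest.approx(target.axis)


def test_select_toricity_tie_breaks_low(monkeypatch):
    # two steps with identical corneal-plane equivalents → lower toricity wins
    monkeypatch.setattr(
        "toricpred.cohort.iol_cyl_to_corneal", lambda step, sph, ctx: 1.5
    )
    ctx = VergenceContext(12.0, 5.0, 23.98, 43.5, 118.5)
    cfg_tie = CohortConfig(seed=1, toricity_steps_d=[3.0, 1.0])
    step_tie, _ = select_toricity(Astigmatism(1.0, 90.0), 19.4, ctx, cfg_tie)
    assert step_tie == 1.0


def test_select_toricity_empty_steps_raises():
    ctx = VergenceContext(12.0, 5.0, 23.98, 43.5, 118.5)
    with pytest.raises(ValueError):
        select_toricity(Astigmatism(1.0, 90.0), 19.4, ctx,
                        CohortConfig(seed=1, toricity_steps_d=[]))


def test_records_round_trip_through_schema(noise_free_cohort):
    cohort, _ = noise_free_cohort
    recs = list(cohort_records(cohort))
    assert len(recs) == len(cohort)
    r = recs[0]
    assert r.anterior.r_steep_mm <= r.anterior.r_flat_mm
    assert 0 <= r.subgroup_axis_deg < 180
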