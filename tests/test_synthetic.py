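import numpy as np
import pytest

import petratio as pr
from petratio.synthetic import (
    DEFAULT_PLASMA,
    PLASMA_TO_BLOOD,
    PlasmaModel,
    default_frame_schedule,
    generate_plasma_input,
    generate_true_cohort,
    read_cohort,
    synthesize_tac,
    write_cohort,
)


class TestPlasmaModel:
    def test_zero_amplitudes_give_zero_curve(self):
        model = PlasmaModel(amplitudes=(0, 0, 0), decay_rates=(3.0, 0.35, 0.01),
                            peak_time=1.5)
        t = np.linspace(0, 60, 500)
        np.testing.assert_array_equal(model(t), 0.0)

    def test_argmax_at_peak_time_on_fine_grid(self):
        model = PlasmaModel(amplitudes=(50, 10, 5), decay_rates=(3.0, 0.35, 0.01),
                            peak_time=1.0)
        t = np.arange(0, 10, 0.01)
        assert t[np.argmax(model(t))] == pytest.approx(1.0)

    def test_tail_integral_matches_closed_form(self):
        # with peak_time → 0 the whole curve is the tri-exponential tail
        amps, rates = (50.0, 10.0, 5.0), (3.0, 0.35, 0.01)
        model = PlasmaModel(amplitudes=amps, decay_rates=rates, peak_time=1e-6)
        t = np.arange(0, 3000, 0.01)
        numeric = np.trapezoid(model(t), t)
        closed = sum(a / r for a, r in zip(amps, rates))
        assert numeric == pytest.approx(closed, rel=1e-3)

    def test_nonpositive_decay_rejected(self):
        with pytest.raises(ValueError):
            PlasmaModel(amplitudes=(1, 1, 1), decay_rates=(1.0, -0.1, 0.01),
                        peak_time=1.0)

    def test_plasma_to_blood_ratio(self):
        inp = generate_plasma_input(DEFAULT_PLASMA, np.linspace(0, 60, 100))
        np.testing.assert_allclose(inp.plasma_parent,
                                   PLASMA_TO_BLOOD * inp.whole_blood)
        assert np.all(inp.plasma_parent <= inp.whole_blood + 1e-12)

    def test_non_ascending_times_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            generate_plasma_input(DEFAULT_PLASMA, np.array([0.0, 2.0, 1.0]))


class TestTrueCohort:
    def test_genotype_vt_ratio_with_degenerate_variance(self):
        spec = pr.CohortSpec(n_hab=2, n_mab=2, between_subject_cv=0.0,
                             within_subject_cv=0.0, region_noise_cv=0.0, seed=0)
        states = generate_true_cohort(spec)
        hab = [s.true_vt("frontal_cortex") for s in states if s.genotype == "HAB"]
        mab = [s.true_vt("frontal_cortex") for s in states if s.genotype == "MAB"]
        # all same-genotype scans identical
        assert np.ptp(hab) == 0 and np.ptp(mab) == 0
        assert hab[0] / mab[0] == pytest.approx(3.9 / 2.2, rel=1e-12)
        assert hab[0] == pytest.approx(3.9, rel=1e-12)

    def test_latent_factor_mean_converges_to_one(self):
        spec = pr.CohortSpec(n_hab=500, n_mab=500, seed=1)
        states = generate_true_cohort(spec)
        factors = np.array([s.latent_factor for s in states if s.scan_index == 1])
        se = factors.std(ddof=1) / np.sqrt(factors.size)
        assert abs(factors.mean() - 1.0) < 2 * se + 1e-12

    def test_vb_and_delay_within_configured_ranges(self):
        states = generate_true_cohort(pr.CohortSpec(seed=2))
        for s in states:
            assert 0.027 <= s.vB <= 0.064
            assert abs(s.delay) <= 1.0 / 3.0

    def test_interregional_truth_correlations_exceed_09(self):
        # region noise ≪ subject variance → near-collinear regional V_T
        spec = pr.CohortSpec(n_hab=40, n_mab=40, seed=3)
        states = generate_true_cohort(spec)
        hab = np.array([[s.params[r].vt for r in spec.tissue_rois]
                        for s in states if s.genotype == "HAB"])
        corr = np.corrcoef(hab.T)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.all(off > 0.9)

    def test_cohort_too_small_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            pr.CohortSpec(n_hab=1, n_mab=0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="vb_range"):
            pr.CohortSpec(vb_range=(0.0, 0.2))
        with pytest.raises(ValueError, match="non-overlapping"):
            pr.CohortSpec(frame_schedule=[(0.0, 2.0), (1.0, 2.0)])
        with pytest.raises(ValueError, match="whole_brain"):
            pr.CohortSpec(roi_names=("frontal_cortex", "cerebellum"))


@pytest.fixture(scope="module")
def scan_state():
    spec = pr.CohortSpec(seed=5)
    cohort = pr.generate_cohort(spec)
    return spec, cohort.scans[0]


class TestSynthesizeTac:
    def test_noise_free_equals_forward_model(self, scan_state):
        spec, scan = scan_state
        rng = np.random.default_rng(0)
        tac = synthesize_tac(scan.state, "frontal_cortex", scan.input_function,
                             spec.frame_schedule, 0.0, rng)
        model = pr.twotcm_forward(scan.state.params["frontal_cortex"],
                                  scan.input_function,
                                  tac.frame_start, tac.frame_duration)
        np.testing.assert_allclose(tac.activity, model, atol=1e-8)

    def test_zero_kinetics_and_blood_give_zero_tac(self, scan_state):
        spec, scan = scan_state
        state = scan.state
        silent = pr.KineticParams(K1=0.0, k2=0.08, k3=0.01, k4=0.05, vB=0.0,
                                  delay=state.delay)
        state2 = type(state)(
            subject_id=state.subject_id, scan_index=state.scan_index,
            genotype=state.genotype, latent_factor=state.latent_factor,
            scan_factor=state.scan_factor, params={"frontal_cortex": silent},
            vB=0.0, delay=state.delay, injected_dose_MBq=state.injected_dose_MBq,
            body_weight_kg=state.body_weight_kg, plasma_scale=state.plasma_scale)
        tac = synthesize_tac(state2, "frontal_cortex", scan.input_function,
                             spec.frame_schedule, 0.0, np.random.default_rng(0))
        np.testing.assert_allclose(tac.activity, 0.0, atol=1e-14)

    def test_same_rng_seed_gives_bit_identical_tacs(self, scan_state):
        spec, scan = scan_state
        a = synthesize_tac(scan.state, "thalamus", scan.input_function,
                           spec.frame_schedule, 0.025, np.random.default_rng(42))
        b = synthesize_tac(scan.state, "thalamus", scan.input_function,
                           spec.frame_schedule, 0.025, np.random.default_rng(42))
        np.testing.assert_array_equal(a.activity, b.activity)

    def test_unknown_roi_rejected(self, scan_state):
        spec, scan = scan_state
        with pytest.raises(KeyError, match="hippocampus"):
            synthesize_tac(scan.state, "hippocampus", scan.input_function,
                           spec.frame_schedule, 0.0, np.random.default_rng(0))

    def test_noise_residuals_have_zero_mean(self, scan_state):
        # z-test over 10^4 standardized frame residuals at alpha = 0.01
        spec, scan = scan_state
        rng = np.random.default_rng(123)
        clean = synthesize_tac(scan.state, "frontal_cortex", scan.input_function,
                               spec.frame_schedule, 0.0, np.random.default_rng(0))
        sd = spec.noise_scale * np.sqrt(clean.activity / clean.frame_duration)
        ok = sd > 0  # a positive delay can leave the very first frame empty
        zs = []
        while len(zs) * int(ok.sum()) < 10_000:
            noisy = synthesize_tac(scan.state, "frontal_cortex", scan.input_function,
                                   spec.frame_schedule, spec.noise_scale, rng)
            zs.append((noisy.activity[ok] - clean.activity[ok]) / sd[ok])
        z = np.concatenate(zs)
        assert abs(z.mean()) * np.sqrt(z.size) < 2.576  # alpha = 0.01

    def test_whole_brain_is_mean_of_tissue_curves(self, scan_state):
        spec, scan = scan_state
        wb = synthesize_tac(scan.state, "whole_brain", scan.input_function,
                            spec.frame_schedule, 0.0, np.random.default_rng(0))
        curves = [pr.twotcm_forward(p, scan.input_function, wb.frame_start,
                                    wb.frame_duration)
                  for p in scan.state.params.values()]
        np.testing.assert_allclose(wb.activity, np.mean(curves, axis=0), atol=1e-10)


class TestCohortDeterminismAndIO:
    def test_identical_spec_yields_bit_identical_cohorts(self):
        a = pr.generate_cohort(pr.CohortSpec(seed=9))
        b = pr.generate_cohort(pr.CohortSpec(seed=9))
        for sa, sb in zip(a.scans, b.scans):
            for roi in sa.tacs:
                np.testing.assert_array_equal(sa.tacs[roi].activity,
                                              sb.tacs[roi].activity)
            np.testing.assert_array_equal(sa.input_function.plasma_parent,
                                          sb.input_function.plasma_parent)

    def test_write_cohort_file_counts(self, tmp_path):
        cohort = pr.generate_cohort(pr.CohortSpec(seed=1))
        manifest = write_cohort(cohort, tmp_path)
        assert len(manifest["scans"]) == 24
        assert len(list(tmp_path.glob("*_tacs.tsv"))) == 24
        assert len(list(tmp_path.glob("*_blood.tsv"))) == 24
        assert (tmp_path / "metadata.tsv").exists()

    def test_empty_cohort_writes_metadata_only(self, tmp_path):
        cohort = pr.SyntheticCohort(spec=pr.CohortSpec(seed=0), scans=[])
        manifest = write_cohort(cohort, tmp_path)
        assert manifest["scans"] == []
        assert (tmp_path / "metadata.tsv").exists()
        assert list(tmp_path.glob("*_tacs.tsv")) == []

    def test_roundtrip_through_readers(self, tmp_path):
        cohort = pr.generate_cohort(pr.CohortSpec(n_hab=1, n_mab=1, seed=4))
        write_cohort(cohort, tmp_path)
        back = read_cohort(tmp_path)
        assert len(back) == 4
        by_id = {m.scan_id: (m, t, i) for m, t, i in back}
        for scan in cohort.scans:
            meta, tacs, inp = by_id[scan.meta.scan_id]
            assert meta.genotype == scan.meta.genotype
            for roi, tac in scan.tacs.items():
                np.testing.assert_allclose(tacs[roi].activity, tac.activity,
                                           rtol=1e-6)
            np.testing.assert_allclose(inp.plasma_parent,
                                       scan.input_function.plasma_parent, rtol=1e-6)


def test_default_frame_schedule_spans_one_hour():
    frames = default_frame_schedule()
    assert frames[0][0] == 0.0
    assert frames[-1][0] + frames[-1][1] == pytest.approx(60.0)
    assert len(frames) == 25
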