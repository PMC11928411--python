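"""Generator-level checks: planted structure, closed forms, determinism."""

import numpy as np
import pytest

from renalsmi.errors import ValidationError
from renalsmi.simulate import (
    CineSpec,
    CohortSpec,
    GroupParams,
    NoiseSpec,
    TicSpec,
    TraceSpec,
    VesselSpec,
    generate_cine,
    generate_cohort,
    generate_histology,
    generate_tic,
    generate_velocity_trace,
)
from renalsmi.stats import pearson_corr

from conftest import small_cine_spec


class TestCineGenerator:
    @pytest.mark.parametrize(
        "m,expected",
        [(0.0, 0.0), (0.3, 2 * 0.3 / 1.3), (0.5, 2 * 0.5 / 1.5)],
    )
    def test_true_irpi_closed_form(self, m, expected):
        spec = small_cine_spec(m=m)
        _, truth = generate_cine(spec)
        assert truth.true_irpi[0] == pytest.approx(expected, abs=1e-12)

    def test_identical_seed_bit_identical(self):
        a, _ = generate_cine(small_cine_spec(seed=11, noise_off=False))
        b, _ = generate_cine(small_cine_spec(seed=11, noise_off=False))
        assert np.array_equal(a.frames, b.frames)

    def test_different_seed_differs(self):
        a, _ = generate_cine(small_cine_spec(seed=1))
        b, _ = generate_cine(small_cine_spec(seed=2))
        assert not np.array_equal(a.frames, b.frames)

    def test_planted_occupancy_has_zero_mean_modulation(self, clean_cine):
        # full cycles in the clip -> time-average of p(t) equals p0
        _, truth = clean_cine
        for spec, p_t in zip(truth.vessel_specs, truth.occupancy):
            assert p_t.mean() == pytest.approx(spec.p0, abs=1e-9)

    def test_empirical_occupancy_tracks_planted_binomial(self, clean_cine):
        # per-frame flow fraction inside the vessel vs planted p(t):
        # essentially all frames inside 3 binomial SDs, none far outside
        _, truth = clean_cine
        vmask = truth.vessel_masks[0]
        n = int(vmask.sum())
        assert n >= 1500  # ~2000 px vessel
        frac = truth.flow_masks[:, vmask].mean(axis=1)
        p_t = truth.occupancy[0]
        sd = np.sqrt(p_t * (1 - p_t) / n)
        z = np.abs(frac - p_t) / sd
        assert (z <= 3).mean() >= 0.98
        assert z.max() <= 5.0

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(frame_rate=40.0), "frame_rate"),  # < 10 frames per cycle
            (dict(duration=0.4), "duration"),  # < 3 cycles
            (dict(height=0), "height"),
        ],
    )
    def test_spec_validation_names_field(self, kwargs, field):
        base = dict(
            height=64, width=64, frame_rate=120.0, duration=1.0, heart_rate=330.0
        )
        base.update(kwargs)
        with pytest.raises(ValidationError, match=field):
            CineSpec(**base)

    def test_vessel_occupancy_ceiling(self):
        with pytest.raises(ValidationError, match="p0"):
            VesselSpec(
                vessel_class="interlobular",
                path=((0, 0), (5, 5)),
                width=3,
                p0=0.8,
                m=0.5,
            )


class TestTicGenerator:
    def test_noise_free_peak_at_t0_plus_alpha_beta(self):
        spec = TicSpec(t0=1.0, alpha=2.0, beta=1.5, noise_sigma=0.0)
        tic, truth = generate_tic(spec)
        assert truth.ttp == pytest.approx(3.0)
        t_peak = tic.t[np.argmax(tic.intensity)]
        assert t_peak == pytest.approx(4.0, abs=1.0 / spec.frame_rate)

    def test_intensity_at_onset_equals_baseline(self):
        spec = TicSpec(t0=1.0, noise_sigma=0.0, frame_rate=10.0)  # t0 on-grid
        tic, _ = generate_tic(spec)
        i0 = np.searchsorted(tic.t, 1.0)
        assert tic.intensity[i0] == pytest.approx(spec.baseline, abs=1e-12)

    def test_duration_too_short_rejected(self):
        with pytest.raises(ValidationError, match="duration"):
            TicSpec(t0=1.0, alpha=2.0, beta=1.5, duration=3.5)


class TestVelocityTraces:
    def test_arterial_planted_ri(self):
        _, truth = generate_velocity_trace("arterial", 100.0, 39.0)
        assert truth.ri == pytest.approx(0.61)

    def test_continuous_zero_ripple_has_zero_vii(self):
        _, truth = generate_velocity_trace(
            "venous_continuous", 30.0, 30.0, TraceSpec(noise_sigma=0.0)
        )
        assert truth.vii == pytest.approx(0.0)

    def test_biphasic_planted_vii(self):
        _, truth = generate_velocity_trace("venous_biphasic", 30.0, 21.0)
        assert truth.vii == pytest.approx(0.30)

    def test_monophasic_reaches_near_zero(self):
        trace, truth = generate_velocity_trace(
            "venous_monophasic", 30.0, 0.0, TraceSpec(noise_sigma=0.0)
        )
        assert truth.vii >= 0.95
        assert trace.v.min() <= 0.05 * trace.v.max()

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValidationError, match="peak"):
            generate_velocity_trace("arterial", 0.0, 0.0)


class TestHistologyGenerator:
    def test_zero_fraction_paints_no_edema(self):
        image, truth = generate_histology(edema_fraction=0.0, seed=1)
        assert truth.edema_mask.sum() == 0
        assert truth.realized_fraction == 0.0

    def test_full_fraction_paints_all_tissue(self):
        _, truth = generate_histology(edema_fraction=1.0, seed=1)
        assert truth.parenchyma_mask.sum() == 0
        assert truth.realized_fraction == 1.0

    def test_realized_fraction_close_to_request(self):
        _, truth = generate_histology(edema_fraction=0.223, seed=3)
        assert truth.realized_fraction == pytest.approx(0.223, abs=0.01)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="edema_fraction"):
            generate_histology(edema_fraction=1.2)


class TestCohortGenerator:
    def test_moment_matching_large_n(self):
        spec = CohortSpec(n_control=100_000, n_hf=100_000, seed=5)
        table, _ = generate_cohort(spec)
        for var, p in spec.variables.items():
            for group, mean in (
                ("control", p.mean_control),
                ("HF", p.mean_hf),
            ):
                sample = table.loc[table.group == group, var].mean() * p.output_scale
                assert sample == pytest.approx(mean, rel=0.01), (var, group)

    def test_perfect_correlation_with_identical_groups(self):
        # rho = 1 with matching group parameters: IRPI and ln RMP are the
        # same affine function of one latent draw -> sample Pearson exactly 1
        variables = {
            "rmp": GroupParams(5.0, 0.7, 5.0, 0.7 * np.sqrt(5 / 9)),
            "irpi_interlobular": GroupParams(
                0.5, 0.05, 0.5, 0.05 * np.sqrt(5 / 9), family="normal"
            ),
        }
        spec = CohortSpec(
            variables=variables,
            planted_correlations={("irpi_interlobular", "rmp"): 1.0},
            seed=2,
        )
        table, _ = generate_cohort(spec)
        r, _ = pearson_corr(table["irpi_interlobular"], np.log(table["rmp"]))
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_non_psd_target_rejected_naming_pair(self):
        # identical groups (matched SDs) so the planted values pass through
        # unchanged; +0.9 and -0.9 to the same partner with a positive
        # default cvp~rmp entry is jointly impossible
        eq = np.sqrt(5 / 9)
        variables = {
            "cvp": GroupParams(10.0, 1.0, 10.0, 1.0 * eq),
            "rmp": GroupParams(5.0, 1.0, 5.0, 1.0 * eq),
            "irpi_interlobular": GroupParams(
                0.5, 0.05, 0.5, 0.05 * eq, family="normal"
            ),
        }
        spec = CohortSpec(
            variables=variables,
            planted_correlations={
                ("irpi_interlobular", "cvp"): 0.9,
                ("irpi_interlobular", "rmp"): -0.9,
            },
            seed=0,
        )
        with pytest.raises(ValidationError, match="positive semi-definite"):
            generate_cohort(spec)

    def test_determinism(self):
        a, _ = generate_cohort(CohortSpec(seed=9))
        b, _ = generate_cohort(CohortSpec(seed=9))
        assert a.equals(b)

    def test_default_spec_group_sizes(self):
        table, _ = generate_cohort(CohortSpec(seed=0))
        assert (table.group == "control").sum() == 5
        assert (table.group == "HF").sum() == 9
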