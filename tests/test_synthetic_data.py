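import io

import numpy as np
import pandas as pd
import pytest

from pbmkit.errors import ConfigurationError, ContractError
from pbmkit.motif_scan import best_site_score, score_window
from pbmkit.normalization import ma_table
from pbmkit.synthetic_data import (
    PbmSimConfig,
    simulate_pbm_experiment,
    simulate_sequences_with_sites,
    simulate_titration,
)


def _null_config(**overrides):
    base = dict(
        n_sequences=50,
        seq_length=100,
        spots_per_sequence=4,
        slides_per_group=2,
        n_groups=1,
        frac_bound=0.0,
        bound_effect=1.0,
        frac_differential=0.0,
        dye_bias_amplitude=0.0,
        slide_scale_sd=0.0,
        spot_noise_sd=0.0,
        group_names=("recombinant",),
        seed=7,
    )
    base.update(overrides)
    return PbmSimConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("frac_bound", -0.1),
            ("frac_bound", 1.5),
            ("frac_differential", 2.0),
            ("n_sequences", 0),
            ("spots_per_sequence", 0),
            ("spot_noise_sd", -1.0),
            ("n_groups", 3),
        ],
    )
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ConfigurationError):
            _null_config(**{field: value})

    def test_slides_per_group_broadcasts(self):
        cfg = PbmSimConfig(n_sequences=10, spots_per_sequence=2, slides_per_group=3, n_groups=2)
        assert cfg.slides_per_group == (3, 3)


class TestSimulatePbm:
    def test_no_signal_no_noise_gives_exact_zero_m(self):
        arrays, _ = simulate_pbm_experiment(_null_config())
        for slide in arrays.slides:
            tab = ma_table(slide.spots)
            np.testing.assert_array_equal(tab["M"].to_numpy(), 0.0)

    def test_zero_noise_recovers_true_effects_exactly(self):
        cfg = _null_config(frac_bound=0.2, bound_effect=1.5)
        arrays, truth = simulate_pbm_experiment(cfg)
        tab = ma_table(arrays.slides[0].spots)
        recovered = tab.groupby("sequence_id")["M"].mean()
        for seq_id, effect in truth.effects.items():
            assert recovered[seq_id] == pytest.approx(effect, abs=1e-12)

    def test_seed_fixes_every_byte(self):
        cfg = _null_config(frac_bound=0.1, spot_noise_sd=0.3, dye_bias_amplitude=0.5)
        out = []
        for _ in range(2):
            arrays, _ = simulate_pbm_experiment(_null_config(frac_bound=0.1, spot_noise_sd=0.3, dye_bias_amplitude=0.5))
            buf = io.StringIO()
            frames = []
            for slide in arrays.slides:
                frames.append(
                    pd.DataFrame(
                        [(s.sequence_id, s.red_fg, s.red_bg, s.green_fg, s.green_bg) for s in slide.spots]
                    )
                )
            pd.concat(frames).to_csv(buf)
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_bound_mean_matches_generation_parameters(self):
        """Law of large numbers: per-sequence aggregated M over the flagged
        (truly bound) sequences averages to the planted effect."""
        cfg = PbmSimConfig(
            n_sequences=2000,
            seq_length=100,
            spots_per_sequence=20,
            slides_per_group=1,
            n_groups=1,
            frac_bound=0.05,
            bound_effect=1.0,
            frac_differential=0.0,
            dye_bias_amplitude=0.0,
            slide_scale_sd=0.0,
            spot_noise_sd=0.25,
            group_names=("recombinant",),
            seed=11,
        )
        arrays, truth = simulate_pbm_experiment(cfg)
        tab = ma_table(arrays.slides[0].spots)
        per_seq = tab.groupby("sequence_id")["M"].median()
        bound_mean = per_seq[sorted(truth.bound_ids)].mean()
        assert bound_mean == pytest.approx(1.0, abs=0.05)

    def test_differential_applied_to_group2_only(self):
        cfg = PbmSimConfig(
            n_sequences=100,
            seq_length=100,
            spots_per_sequence=4,
            slides_per_group=2,
            n_groups=2,
            frac_bound=0.0,
            frac_differential=0.2,
            differential_effect=1.0,
            dye_bias_amplitude=0.0,
            slide_scale_sd=0.0,
            spot_noise_sd=0.0,
            seed=13,
        )
        arrays, truth = simulate_pbm_experiment(cfg)
        normal = ma_table(arrays.slides[0].spots).groupby("sequence_id")["M"].mean()
        cancer = ma_table(arrays.slides[-1].spots).groupby("sequence_id")["M"].mean()
        for seq_id, d in truth.differential.items():
            assert normal[seq_id] == pytest.approx(0.0, abs=1e-12)
            assert cancer[seq_id] == pytest.approx(d, abs=1e-12)
        signs = {np.sign(d) for d in truth.differential.values() if d != 0}
        assert signs == {-1.0, 1.0}  # both directions planted

    def test_arrayset_passes_validation_and_design_shape(self):
        cfg = PbmSimConfig(
            n_sequences=20, seq_length=50, spots_per_sequence=3,
            slides_per_group=(4, 8), n_groups=2, seed=1,
        )
        arrays, _ = simulate_pbm_experiment(cfg)
        arrays.validate()
        assert arrays.groups.count("normal") == 4
        assert arrays.groups.count("cancer") == 8


class TestSimulateSequences:
    def test_planting_rate_zero_records_no_sites(self, simple_pwm):
        _, truth = simulate_sequences_with_sites(20, 50, simple_pwm, 0.0, seed=1)
        assert truth.site_positions == {}

    def test_planting_rate_one_plants_consensus_everywhere(self, simple_pwm):
        records, truth = simulate_sequences_with_sites(20, 50, simple_pwm, 1.0, seed=2)
        assert len(truth.site_positions) == 20
        for rec in records:
            pos, strand = truth.site_positions[rec.id]
            assert 0 <= pos <= 50 - simple_pwm.width
            assert score_window(simple_pwm, rec.sequence, pos, strand) == pytest.approx(
                simple_pwm.max_score
            )

    def test_rescan_recovers_maximal_score_at_recorded_position(self, ap2_like_pwm):
        records, truth = simulate_sequences_with_sites(30, 80, ap2_like_pwm, 1.0, seed=3)
        for rec in records:
            hit = best_site_score(ap2_like_pwm, rec.sequence, rec.id)
            assert hit.score == pytest.approx(ap2_like_pwm.max_score)

    def test_length_shorter_than_width_rejected(self, ap2_like_pwm):
        with pytest.raises(ContractError):
            simulate_sequences_with_sites(5, ap2_like_pwm.width - 1, ap2_like_pwm, 0.5)


class TestSimulateTitration:
    def test_half_saturation_identity(self):
        series = simulate_titration(100.0, 200.0, [0.0, 50.0, 100.0, 400.0])
        idx = list(series.concentrations).index(100.0)
        assert series.responses[idx] == pytest.approx(100.0)

    def test_zero_concentration_zero_response(self):
        series = simulate_titration(100.0, 200.0, [0.0, 50.0, 100.0, 400.0])
        assert series.responses[0] == 0.0

    def test_closed_form_value(self):
        series = simulate_titration(100.0, 200.0, [0.0, 100.0, 300.0, 400.0])
        idx = list(series.concentrations).index(300.0)
        assert series.responses[idx] == pytest.approx(150.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_titration(100.0, 200.0, [-1.0, 1.0, 2.0, 3.0])

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_titration(0.0, 200.0, [0.0, 1.0, 2.0, 3.0])
        with pytest.raises(ConfigurationError):
            simulate_titration(10.0, -5.0, [0.0, 1.0, 2.0, 3.0])
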