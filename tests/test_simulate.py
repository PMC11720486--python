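"""Design arithmetic, determinism and calibration of the trial simulator."""

import numpy as np
import pandas as pd
import pytest

from awarekit import simulate
from awarekit.errors import ConfigurationError, InvalidDesignError
from awarekit.simulate import DesignSpec, GenerativeParams


def _design_one_block(spec, seed=0):
    rng = np.random.default_rng(seed)
    d = simulate.build_design(spec, rng)
    return d[d["block"] == spec.blocks[0]]


class TestBuildDesign:
    def test_catch_count_320_block(self):
        spec = DesignSpec(n_participants=1, blocks=("single",))
        block = _design_one_block(spec)
        assert len(block) == 320
        assert (block["prime_identity"] == "none").sum() == 64

    def test_present_trials_balanced(self):
        spec = DesignSpec(n_participants=1, blocks=("single",))
        block = _design_one_block(spec)
        present = block[block["prime_identity"] != "none"]
        assert present["prime_identity"].value_counts().tolist() == [128, 128]
        by_shape = present.groupby("prime_identity")["congruent"].apply(
            lambda s: (s.eq(True).sum(), s.eq(False).sum())
        )
        assert all(t == (64, 64) for t in by_shape)

    def test_zero_catch_proportion(self):
        spec = DesignSpec(n_participants=1, blocks=("single",), catch_proportion=0.0)
        block = _design_one_block(spec)
        assert (block["prime_identity"] == "none").sum() == 0
        assert block["congruent"].eq(True).sum() == 160
        assert block["congruent"].eq(False).sum() == 160

    def test_seed_changes_order_not_content(self):
        spec = DesignSpec(n_participants=1, blocks=("single",))
        a = _design_one_block(spec, seed=1)
        b = _design_one_block(spec, seed=2)
        cols = ["prime_identity", "congruent", "probe_identity"]
        key = lambda df: sorted(map(tuple, df[cols].astype(str).to_numpy()))
        assert key(a) == key(b)  # same multiset of trial specs
        assert not a[cols].reset_index(drop=True).equals(b[cols].reset_index(drop=True))

    def test_invalid_design_rejected(self):
        with pytest.raises(InvalidDesignError):
            DesignSpec(trials_per_block=0)
        with pytest.raises(InvalidDesignError):
            DesignSpec(catch_proportion=1.0)


class TestSoa:
    @pytest.mark.parametrize("setting", ["immediate", "isi"])
    def test_soa_107ms_both_mask_settings(self, setting):
        """Both masking configurations give the same 8-frame (107 ms) SOA."""
        durations = simulate.mask_settings()[setting]
        soa = simulate.soa_ms(DesignSpec(event_durations_ms=durations))
        assert soa == pytest.approx(8 * simulate.FRAME_MS)
        assert round(soa) == 107

    def test_zero_durations(self):
        durations = dict(simulate.DEFAULT_DURATIONS_MS, prime=0, isi=0, backward_mask=0)
        assert simulate.soa_ms(DesignSpec(event_durations_ms=durations)) == 0.0

    def test_missing_key_is_configuration_error(self):
        durations = {"prime": 40, "isi": 0}
        with pytest.raises(ConfigurationError):
            simulate.soa_ms(DesignSpec(event_durations_ms=durations))


class TestSimulateExperiment:
    def test_row_count(self):
        spec = DesignSpec(n_participants=2, blocks=("single",), seed=3)
        trials = simulate.simulate_experiment(spec, GenerativeParams())
        assert len(trials) == 640

    def test_determinism_byte_identical(self, tmp_path):
        spec = DesignSpec(n_participants=2, blocks=("single", "multiple"), seed=5)
        params = GenerativeParams()
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        simulate.write_trials_csv(simulate.simulate_experiment(spec, params), p1)
        simulate.write_trials_csv(simulate.simulate_experiment(spec, params), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_participant_regenerable_in_isolation(self):
        params = GenerativeParams()
        spec = DesignSpec(n_participants=3, blocks=("single",), seed=9)
        full = simulate.simulate_experiment(spec, params)
        rng = simulate.participant_rng(9, 2)
        solo = simulate.simulate_participant(
            params, simulate.build_design(spec, rng), rng, participant=2
        )
        pd.testing.assert_frame_equal(
            full[full["participant"] == 2].reset_index(drop=True), solo
        )

    def test_csv_roundtrip(self, tmp_path, small_cohort):
        path = tmp_path / "trials.csv"
        simulate.write_trials_csv(small_cohort, path)
        back = simulate.read_trials_csv(path)
        assert back["congruent"].isna().sum() == small_cohort["congruent"].isna().sum()
        np.testing.assert_allclose(back["rt_ms"], small_cohort["rt_ms"], rtol=1e-12)


class TestCalibration:
    def test_null_effect_mean_rt_difference_below_1ms(self):
        params = simulate.null_params()
        spec = DesignSpec(
            n_participants=1, blocks=("single",), trials_per_block=100_000,
            catch_proportion=0.0, seed=21,
        )
        trials = simulate.simulate_experiment(spec, params)
        cong = trials[trials["congruent"].eq(True)]["rt_ms"].mean()
        incong = trials[trials["congruent"].eq(False)]["rt_ms"].mean()
        assert abs(incong - cong) < 1.0

    def test_null_classes_give_zero_dprime_at_large_n(self):
        from awarekit import sdt

        params = simulate.null_params()
        spec = DesignSpec(
            n_participants=1, blocks=("visibility",), trials_per_block=100_000,
            seed=23,
        )
        trials = simulate.simulate_experiment(spec, params)
        d_obj = sdt.dprime(sdt.counts_objective(trials)).d_prime
        d_subj = sdt.dprime(sdt.counts_subjective(trials)).d_prime
        assert abs(d_obj) < 0.02
        assert abs(d_subj) < 0.02

    def test_congruency_effect_recovers_alpha(self):
        """Cohort mean congruency effect is an unbiased estimate of alpha.

        Fifty replicate cohorts of 20 participants x 256 prime trials with
        a pure awareness-independent effect of 30 ms; the grand mean of the
        raw (untrimmed) congruency effects must fall within 2 SEM of 30.
        """
        alpha = 30.0
        means = []
        for rep in range(50):
            params = GenerativeParams(alpha_ms=alpha, beta_ms=0.0)
            spec = DesignSpec(
                n_participants=20, blocks=("single",), seed=1000 + rep
            )
            trials = simulate.simulate_experiment(spec, params)
            per = trials.groupby("participant").apply(
                lambda df: df[df["congruent"].eq(False)]["rt_ms"].mean()
                - df[df["congruent"].eq(True)]["rt_ms"].mean(),
                include_groups=False,
            )
            means.append(per.mean())
        grand = np.mean(means)
        sem = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(grand - alpha) < 2 * sem
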