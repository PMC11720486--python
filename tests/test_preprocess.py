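"""Trial trimming, PAS selection, exclusion rules and priming effects."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from awarekit import preprocess
from awarekit.errors import DegenerateInputError


def _trials(rts, correct=None, congruent=None, pas=None):
    n = len(rts)
    return pd.DataFrame(
        {
            "participant": 0,
            "block": "single",
            "rt_ms": rts,
            "probe_correct": correct if correct is not None else [True] * n,
            "congruent": pd.array(
                congruent if congruent is not None else [True] * n, dtype="boolean"
            ),
            "pas": pas if pas is not None else [1] * n,
            "prime_identity": "square",
        }
    )


class TestTrimRts:
    def test_absolute_window(self):
        kept, audit = preprocess.trim_rts(_trials([150, 500, 600, 2500]))
        assert sorted(kept["rt_ms"]) == [500, 600]
        assert audit.n_removed_window == 2
        assert audit.n_removed_sd == 0

    def test_boundary_rts_kept(self):
        kept, _ = preprocess.trim_rts(_trials([200.0, 2000.0, 500.0]))
        assert len(kept) == 3

    def test_zero_spread_no_sd_removals(self):
        kept, audit = preprocess.trim_rts(_trials([600.0] * 10))
        assert audit.n_removed_sd == 0
        assert len(kept) == 10

    def test_incorrect_removed_only_for_rt_analysis(self):
        df = _trials([500, 600, 700], correct=[True, False, True])
        kept_rt, audit_rt = preprocess.trim_rts(df, for_rt_analysis=True)
        kept_all, audit_all = preprocess.trim_rts(df, for_rt_analysis=False)
        assert audit_rt.n_removed_incorrect == 1 and len(kept_rt) == 2
        assert audit_all.n_removed_incorrect == 0 and len(kept_all) == 3

    def test_sd_pass_matches_brute_force(self):
        rng = np.random.default_rng(4)
        rts = np.exp(rng.normal(np.log(600), 0.15, 100))
        rts = np.concatenate([rts, [1900.0, 1950.0, 250.0]])  # planted outliers
        _, audit = preprocess.trim_rts(_trials(rts))
        # independent brute-force pass over the window survivors
        win = rts[(rts >= 200) & (rts <= 2000)]
        m, s = win.mean(), win.std(ddof=1)
        expected = int(((win < m - 2 * s) | (win > m + 2 * s)).sum())
        assert audit.n_removed_sd == expected
        assert audit.n_removed_sd >= 2  # catches the planted extremes

    def test_empty_window_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            preprocess.trim_rts(_trials([100.0, 2500.0]))

    @given(
        st.lists(st.floats(min_value=1.0, max_value=3000.0), min_size=3, max_size=60)
    )
    @settings(max_examples=50, deadline=None)
    def test_steps_one_two_idempotent(self, rts):
        """Re-running the window+accuracy steps removes nothing further."""
        df = _trials(rts)
        try:
            kept, _ = preprocess.trim_rts(df)
        except DegenerateInputError:
            return
        _, audit2 = preprocess.trim_rts(kept)
        assert audit2.n_removed_incorrect == 0
        assert audit2.n_removed_window == 0


class TestSelectPas1:
    def test_all_pas1_identity(self):
        df = _trials([500] * 25, pas=[1] * 25, congruent=[True, False] * 12 + [True])
        kept, warn = preprocess.select_pas1(df)
        assert len(kept) == 25 and not warn

    def test_no_pas1_warns(self):
        df = _trials([500] * 4, pas=[2, 3, 4, 2])
        kept, warn = preprocess.select_pas1(df)
        assert len(kept) == 0 and warn

    def test_mixed_counts(self):
        pas = [1, 2, 1, 3, 1, 4, 2, 1]
        df = _trials([500] * 8, pas=pas)
        kept, _ = preprocess.select_pas1(df)
        assert len(kept) == pas.count(1)


class TestExclusionFlags:
    def _cohort(self, accuracy_n=(75, 100), pas4_catch=0, n_catch=64):
        """One participant with given accuracy and PAS-4 catch reports."""
        n_correct, n_total = accuracy_n
        rows = []
        for i in range(n_total):
            rows.append(
                {
                    "participant": 1,
                    "block": "multiple",
                    "prime_identity": "square" if i >= n_catch else "none",
                    "probe_correct": i < n_correct,
                    "pas": 4 if i < pas4_catch else 1,
                    "rt_ms": 500.0,
                    "congruent": pd.NA,
                }
            )
        return pd.DataFrame(rows)

    def test_accuracy_exactly_75_not_excluded(self):
        flags = preprocess.exclusion_flags(self._cohort(accuracy_n=(75, 100)))
        assert not flags["low_accuracy"].iloc[0]

    def test_accuracy_below_75_excluded(self):
        flags = preprocess.exclusion_flags(self._cohort(accuracy_n=(74, 100)))
        assert flags["low_accuracy"].iloc[0]

    @pytest.mark.parametrize("n_pas4,excluded", [(7, True), (6, False)])
    def test_pas4_catch_rule(self, n_pas4, excluded):
        # 7/64 = 10.9% > 10%; 6/64 = 9.4% <= 10%
        flags = preprocess.exclusion_flags(self._cohort(pas4_catch=n_pas4))
        assert bool(flags["pas4_catch_abuse"].iloc[0]) is excluded

    def test_missing_block_gives_na(self):
        df = self._cohort()
        df["block"] = "visibility"
        flags = preprocess.exclusion_flags(df)
        assert flags["low_accuracy"].isna().iloc[0]


class TestCohortEffects:
    def test_pas1_selection_order_switch(self, small_cohort):
        """Selecting PAS-1 before vs after the SD pass can keep different
        trials, but both orders produce one effect per usable participant."""
        from awarekit import preprocess as pp

        after = pp.cohort_effects(small_cohort, "multiple", pas1_only=True)
        before = pp.cohort_effects(
            small_cohort, "multiple", pas1_only=True, pas1_before_trim=True
        )
        assert set(after["participant"]) == set(before["participant"])
        # the SD window differs between orders, so counts may differ slightly
        merged = after.merge(before, on="participant", suffixes=("_a", "_b"))
        assert (
            (merged["n_congruent_a"] - merged["n_congruent_b"]).abs() <= 10
        ).all()


class TestCongruencyEffect:
    def test_exact_effect(self):
        df = _trials([500, 500, 530, 530], congruent=[True, True, False, False])
        eff = preprocess.congruency_effect(df)
        assert eff.effect_ms == pytest.approx(30.0)
        assert eff.effect_se_ms == pytest.approx(0.0)

    def test_label_swap_negates(self):
        rng = np.random.default_rng(8)
        rts = rng.normal(600, 40, 40)
        cong = [True, False] * 20
        a = preprocess.congruency_effect(_trials(rts, congruent=cong))
        b = preprocess.congruency_effect(
            _trials(rts, congruent=[not c for c in cong])
        )
        assert a.effect_ms == pytest.approx(-b.effect_ms)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        rts = rng.normal(600, 50, 60)
        cong = rng.random(60) < 0.5
        if cong.all() or not cong.any():
            cong[0] = not cong[0]
        eff = preprocess.congruency_effect(_trials(rts, congruent=list(cong)))
        c, i = rts[cong], rts[~cong]
        assert eff.effect_ms == pytest.approx(i.mean() - c.mean(), abs=1e-12)
        assert eff.effect_se_ms == pytest.approx(
            np.sqrt(c.var(ddof=1) / len(c) + i.var(ddof=1) / len(i)), abs=1e-12
        )

    def test_empty_cell_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            preprocess.congruency_effect(_trials([500, 510], congruent=[True, True]))
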