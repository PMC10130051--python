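"""Signal-to-noise ratios, main effects, delta ranking and best levels."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from taguchigrow import (
    best_levels,
    compute_sn_table,
    generate_l27,
    main_effects,
    simulate_responses,
    sn_ratio,
)
from taguchigrow.simulate import SyntheticModelSpec
from taguchigrow.sn import IncompleteDesignError, SNDomainError, SNTable

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


class TestSnRatio:
    def test_unit_value_is_zero_db(self):
        assert sn_ratio([1.0], "larger") == pytest.approx(0.0, abs=1e-12)

    def test_ten_is_twenty_db(self):
        assert sn_ratio([10.0], "larger") == pytest.approx(20.0, rel=1e-12)

    def test_study_run25_fresh_leaf(self):
        assert sn_ratio([52.50], "larger") == pytest.approx(34.40, abs=0.005)

    @given(st.lists(positive, min_size=1, max_size=8))
    def test_larger_matches_definition(self, values):
        expected = -10 * math.log10(np.mean([1 / v**2 for v in values]))
        assert sn_ratio(values, "larger") == pytest.approx(expected, rel=1e-12)

    @given(st.lists(positive, min_size=1, max_size=8))
    def test_smaller_matches_definition(self, values):
        expected = -10 * math.log10(np.mean([v**2 for v in values]))
        assert sn_ratio(values, "smaller") == pytest.approx(expected, rel=1e-12)

    def test_nominal_matches_definition(self):
        values = [9.5, 10.2, 10.1]
        expected = 10 * math.log10(np.mean(values) ** 2 / np.var(values, ddof=1))
        assert sn_ratio(values, "nominal") == pytest.approx(expected, rel=1e-12)

    @given(st.lists(positive, min_size=1, max_size=6), st.integers(0, 5))
    def test_larger_is_strictly_monotone(self, values, idx):
        """Increasing any single input strictly increases larger-is-better S/N."""
        idx = idx % len(values)
        bumped = list(values)
        bumped[idx] = bumped[idx] * 1.5
        assert sn_ratio(bumped, "larger") > sn_ratio(values, "larger")

    def test_domain_errors(self):
        with pytest.raises(SNDomainError):
            sn_ratio([1.0, -2.0], "larger")
        with pytest.raises(SNDomainError):
            sn_ratio([], "larger")
        with pytest.raises(SNDomainError):
            sn_ratio([5.0], "nominal")
        with pytest.raises(SNDomainError):
            sn_ratio([5.0, 5.0], "nominal")  # zero variance


class TestSnTable:
    def test_lettuce_fresh_leaf_argmax_run(self, dm, lettuce):
        sn = compute_sn_table(lettuce, "fresh_leaf")
        assert len(sn.sn) == 27
        assert np.isfinite(sn.sn).all()
        assert sn.sn.idxmax() == 25  # largest fresh-leaf mass in the table

    def test_constant_input_constant_sn(self, dm):
        spec = SyntheticModelSpec(main_effects={}, noise_sd=0.0, baseline=7.0)
        table = simulate_responses(spec, dm)
        sn = compute_sn_table(table, "fresh_leaf")
        assert sn.sn.nunique() == 1

    def test_missing_run_is_an_error(self, basil):
        truncated = basil.subset(["dry_leaf"])
        truncated.records = truncated.records[truncated.records["run"] != 13]
        with pytest.raises(IncompleteDesignError, match=r"\[13\]"):
            compute_sn_table(truncated, "dry_leaf")


class TestMainEffects:
    def test_lettuce_fresh_leaf_ec_levels(self, dm, lettuce):
        """Brute-force-derived EC level means for lettuce fresh leaf mass."""
        me = main_effects(dm, compute_sn_table(lettuce, "fresh_leaf"))
        assert me.level_means("ec") == pytest.approx(
            [26.40, 30.40, 27.68], abs=0.005
        )
        assert me.table.loc["ec", "delta_db"] == pytest.approx(4.00, abs=0.005)
        assert me.table.loc["ec", "best_level"] == 2
        assert me.table.loc["ec", "rank"] == 1

    def test_balance_identity(self, dm, lettuce, basil):
        """On a balanced array the mean of level means equals the grand mean."""
        for table in (lettuce, basil):
            for parameter in table.parameters:
                me = main_effects(dm, compute_sn_table(table, parameter))
                for factor in me.factors:
                    assert np.mean(me.level_means(factor)) == pytest.approx(
                        me.grand_mean_db, abs=1e-9
                    )

    def test_ranks_are_permutation(self, dm, lettuce):
        me = main_effects(dm, compute_sn_table(lettuce, "chlorophyll"))
        assert sorted(me.table["rank"]) == [1, 2, 3, 4, 5, 6]
        assert (me.table["delta_db"] >= 0).all()

    def test_constant_sn_ties_follow_factor_order(self, dm):
        spec = SyntheticModelSpec(main_effects={}, noise_sd=0.0)
        me = main_effects(dm, compute_sn_table(simulate_responses(spec, dm), "fresh_leaf"))
        assert (me.table["delta_db"] == 0).all()
        assert list(me.table["rank"]) == [1, 2, 3, 4, 5, 6]  # design order
        assert me.table["delta_tied"].all()
        assert me.table["best_tied"].all()
        assert all(v == 1 for v in best_levels(me).values())  # lowest level

    def test_single_active_factor_ranks_first(self, dm):
        spec = SyntheticModelSpec(
            main_effects={"night_temp": (-0.1, 0.0, 0.1)}, noise_sd=0.0
        )
        me = main_effects(dm, compute_sn_table(simulate_responses(spec, dm), "fresh_leaf"))
        assert me.table.loc["night_temp", "rank"] == 1
        assert best_levels(me)["night_temp"] == 3

    def test_ordering_matches_log_mean_ordering(self, dm, lettuce, basil):
        """At n=1 the S/N argmax level equals the mean-log argmax level."""
        for table in (lettuce, basil):
            for parameter in ("fresh_leaf", "chlorophyll", "K"):
                sn = compute_sn_table(table, parameter)
                me = main_effects(dm, sn)
                logs = np.log10(table.series(parameter).loc[dm.runs].to_numpy())
                for factor in me.factors:
                    codes = dm.column(factor).to_numpy()
                    log_means = [logs[codes == k].mean() for k in (1, 2, 3)]
                    assert best_levels(me)[factor] == int(np.argmax(log_means)) + 1

    def test_run_set_mismatch(self, dm, lettuce):
        sn = compute_sn_table(lettuce, "fresh_leaf")
        short = SNTable(sn.species, sn.parameter, sn.sn.iloc[:-1], sn.criterion)
        with pytest.raises(IncompleteDesignError):
            main_effects(dm, short)


class TestBestLevels:
    def test_lettuce_fresh_leaf_ec(self, dm, lettuce):
        me = main_effects(dm, compute_sn_table(lettuce, "fresh_leaf"))
        assert best_levels(me)["ec"] == 2  # 0.9 dS/m

    def test_basil_fresh_leaf_ec(self, dm, basil):
        me = main_effects(dm, compute_sn_table(basil, "fresh_leaf"))
        assert best_levels(me)["ec"] == 3  # 1.2 dS/m
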