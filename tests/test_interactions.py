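"""Cell means and interaction-plot non-parallelism screening."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from taguchigrow import (
    cell_means,
    compute_sn_table,
    interaction_summary,
    nonparallelism_score,
    rank_pairs,
    simulate_responses,
)
from taguchigrow.simulate import SyntheticModelSpec

finite_cells = arrays(
    float, (3, 3), elements=st.floats(min_value=-50, max_value=50, allow_nan=False)
)


def brute_force_score(m):
    """Independent oracle: evaluate the definition cell by cell."""
    m = np.asarray(m, float)
    grand = m.mean()
    worst = 0.0
    for i in range(3):
        for j in range(3):
            additive = m[i].mean() + m[:, j].mean() - grand
            worst = max(worst, abs(m[i, j] - additive))
    return worst


class TestCellMeans:
    def test_every_cell_averages_three_runs(self, dm, lettuce):
        sn = compute_sn_table(lettuce, "fresh_leaf")
        values = sn.sn
        mat = cell_means(dm, sn, "ec", "humidity")
        for i in (1, 2, 3):
            for j in (1, 2, 3):
                runs = [
                    r
                    for r in dm.runs
                    if dm.codes.loc[r, "ec"] == i and dm.codes.loc[r, "humidity"] == j
                ]
                assert len(runs) == 3  # forced by strength-2 balance
                assert mat.loc[i, j] == pytest.approx(values.loc[runs].mean())

    def test_constant_table_constant_matrix(self, dm):
        spec = SyntheticModelSpec(main_effects={}, noise_sd=0.0)
        sn = compute_sn_table(simulate_responses(spec, dm), "fresh_leaf")
        mat = cell_means(dm, sn, "co2", "led").to_numpy()
        assert np.allclose(mat, mat[0, 0])

    def test_identical_factors_rejected(self, dm, lettuce):
        sn = compute_sn_table(lettuce, "fresh_leaf")
        with pytest.raises(ValueError):
            cell_means(dm, sn, "ec", "ec")


class TestScore:
    def test_additive_matrix_scores_zero(self):
        r, c = np.array([1.0, -2.0, 4.0]), np.array([0.5, 0.0, -3.0])
        assert nonparallelism_score(np.add.outer(r, c)) == pytest.approx(0.0, abs=1e-12)

    def test_constant_matrix_scores_zero(self):
        assert nonparallelism_score(np.full((3, 3), 7.3)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_single_cell_bump(self):
        """Bumping one cell of an additive matrix by d leaves a residual of
        d*(1 - 1/3 - 1/3 + 1/9) = 4d/9 in that cell (the centering identity),
        which the max-residual score picks up."""
        base = np.add.outer([1.0, 2.0, 3.0], [0.0, 1.0, -1.0])
        for d in (0.9, -2.7):
            bumped = base.copy()
            bumped[1, 2] += d
            assert nonparallelism_score(bumped) == pytest.approx(abs(d) * 4 / 9)
            assert nonparallelism_score(bumped) == pytest.approx(
                brute_force_score(bumped)
            )

    @given(finite_cells)
    def test_matches_brute_force_definition(self, m):
        assert nonparallelism_score(m) == pytest.approx(
            brute_force_score(m), abs=1e-9
        )

    @given(finite_cells, st.floats(min_value=-100, max_value=100, allow_nan=False))
    def test_shift_and_transpose_invariance(self, m, shift):
        score = nonparallelism_score(m)
        assert nonparallelism_score(m + shift) == pytest.approx(score, abs=1e-9)
        assert nonparallelism_score(m.T) == pytest.approx(score, abs=1e-9)

    @given(finite_cells)
    def test_zero_iff_profile_lines_parallel(self, m):
        """Score 0 is equivalent to all profile lines being parallel:
        every pair of rows differs by a constant."""
        rows_parallel = all(
            np.allclose(m[i] - m[0], (m[i] - m[0]).mean(), atol=1e-9)
            for i in (1, 2)
        )
        assert (nonparallelism_score(m) < 1e-9) == rows_parallel


def _centered_interaction(d):
    """Doubly centered 3x3 table with a d-sized (3,3) corner pattern."""
    t = np.zeros((3, 3))
    t[2, 2] = d
    t[2, 0] = t[0, 2] = -d / 2
    t[0, 0] = d / 4
    t -= t.mean(axis=0, keepdims=True)
    t -= t.mean(axis=1, keepdims=True)
    return t


class TestScreening:
    def test_additive_synthetic_all_zero(self, dm):
        spec = SyntheticModelSpec(
            main_effects={"ec": (-0.1, 0.0, 0.1), "led": (0.05, 0.0, -0.05)},
            noise_sd=0.0,
        )
        sn = compute_sn_table(simulate_responses(spec, dm), "fresh_leaf")
        summary = interaction_summary(dm, sn)
        assert len(summary.pairs) == 15
        assert (summary.pairs["score_db"] < 1e-9).all()
        assert not summary.pairs["interacting"].any()

    def test_injected_interaction_ranks_first(self, dm):
        spec = SyntheticModelSpec(
            main_effects={"ec": (-0.1, 0.0, 0.1), "led": (0.05, 0.0, -0.05)},
            interaction_effects={("ec", "humidity"): _centered_interaction(0.08)},
            noise_sd=0.0,
        )
        sn = compute_sn_table(simulate_responses(spec, dm), "fresh_leaf")
        ranked = rank_pairs(interaction_summary(dm, sn))
        top = ranked.iloc[0]
        assert {top["factor_a"], top["factor_b"]} == {"ec", "humidity"}
        assert top["score_db"] > 0
        assert top["interacting"]

    def test_uniform_threshold_override(self, dm, lettuce):
        sn = compute_sn_table(lettuce, "fresh_leaf")
        ranked = rank_pairs(interaction_summary(dm, sn), threshold=100.0)
        assert not ranked["interacting"].any()
        with pytest.raises(ValueError):
            rank_pairs(interaction_summary(dm, sn), threshold=-1.0)

    @pytest.mark.parametrize("species_fixture", ["lettuce", "basil"])
    def test_ec_humidity_among_lowest_on_growth_data(
        self, dm, lettuce, basil, species_fixture
    ):
        """The study's finding: no synergy between nutrient concentration
        and relative humidity on growth responses."""
        table = {"lettuce": lettuce, "basil": basil}[species_fixture]
        sn = compute_sn_table(table, "fresh_leaf")
        summary = interaction_summary(dm, sn)
        # the published judgment comes from the plotted raw profiles
        by_raw = summary.pairs.sort_values(
            "raw_score_db", ascending=False
        ).reset_index(drop=True)
        position = by_raw.index[
            (by_raw["factor_a"] == "ec") & (by_raw["factor_b"] == "humidity")
        ][0]
        assert position >= 10  # bottom third of the 15 pairs
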