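"""Association statistics against hand-written brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metallobsh.errors import InsufficientDataError, InvalidInputError
from metallobsh.simulate import simulate_metabolome
from metallobsh.stats import (
    PrevalenceTable,
    bh_adjust,
    chi_square_proportions,
    correlate_multiomics,
    half_min_pseudocount,
    prevalence_from_presence,
    spearman,
)

from oracles import chi2_2x2_closed_form, chi2_cells, rank_then_pearson, step_up_bh


class TestSpearman:
    def test_perfect_monotone_relations(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman(x, [2.0, 4.0, 9.0, 16.0, 30.0]).rho == pytest.approx(1.0)
        assert spearman(x, [5.0, 4.0, 2.0, 1.0, 0.5]).rho == pytest.approx(-1.0)

    def test_tied_vectors_match_rank_then_pearson_oracle(self, rng):
        for _ in range(30):
            x = rng.integers(0, 6, size=20).astype(float)  # heavy ties
            y = rng.integers(0, 6, size=20).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            assert spearman(x, y).rho == pytest.approx(rank_then_pearson(x, y))

    def test_missing_values_dropped_pairwise(self):
        x = [1, 2, np.nan, 4, 5, 6]
        y = [2, 4, 5, np.nan, 10, 12]
        res = spearman(x, y)
        assert res.n == 4
        assert res.rho == pytest.approx(1.0)

    def test_insufficient_and_constant_inputs(self):
        with pytest.raises(InsufficientDataError):
            spearman([1, 2, 3], [1, 2, 3])
        res = spearman([1.0] * 10, list(range(10)))
        assert res.undefined and np.isnan(res.rho)

    def test_invariance_under_monotone_transform(self, rng):
        x = rng.uniform(0.1, 10, size=50)
        y = rng.uniform(0.1, 10, size=50)
        base = spearman(x, y).rho
        assert spearman(np.log2(x), y).rho == pytest.approx(base)
        assert spearman(x, np.log10(y)).rho == pytest.approx(base)
        assert spearman(np.exp(x), y**3).rho == pytest.approx(base)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_identical_ps_unchanged(self):
        out = bh_adjust([0.2] * 5)
        assert np.allclose(out, 0.2)

    def test_hand_computed_step_up_sequence(self):
        p = [0.01, 0.02, 0.03, 0.5]
        assert np.allclose(bh_adjust(p), [0.04, 0.04, 0.04, 0.5])

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 30)))
            assert np.allclose(bh_adjust(p), step_up_bh(list(p)))

    def test_invalid_p_rejected(self):
        with pytest.raises(InvalidInputError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(InvalidInputError):
            bh_adjust([1.5])

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=20))
    def test_bounded_and_order_consistent(self, p):
        adj = bh_adjust(p)
        assert np.all(adj <= 1.0) and np.all(adj >= np.asarray(p) * 0.999999)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        table = PrevalenceTable(["a", "b"], [40, 80], [10, 20])
        chi2, p, df = chi_square_proportions(table)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_2x2_closed_form_oracle(self, rng):
        for _ in range(30):
            a, b, c, d = (int(rng.integers(1, 50)) for _ in range(4))
            table = PrevalenceTable(["g1", "g2"], [a + b, c + d], [a, c])
            chi2, _, _ = chi_square_proportions(table)
            assert chi2 == pytest.approx(chi2_2x2_closed_form(a, b, c, d))

    def test_three_group_cell_sum_oracle(self, rng):
        for _ in range(20):
            totals = rng.integers(10, 100, size=3)
            detected = [int(rng.integers(1, t)) for t in totals]
            table = PrevalenceTable(["a", "b", "c"], [int(t) for t in totals], detected)
            chi2, _, df = chi_square_proportions(table)
            assert df == 2
            assert chi2 == pytest.approx(chi2_cells(detected, totals))

    def test_p_decreases_as_proportions_diverge(self):
        near = chi_square_proportions(PrevalenceTable(["a", "b"], [100, 100], [50, 55]))[1]
        far = chi_square_proportions(PrevalenceTable(["a", "b"], [100, 100], [50, 80]))[1]
        assert far < near

    def test_degenerate_table_rejected(self):
        with pytest.raises(InvalidInputError):
            chi_square_proportions(PrevalenceTable(["a", "b"], [10, 10], [0, 0]))

    def test_prevalence_from_presence_aggregation(self):
        presence = pd.Series([True, False, True, True], index=list("wxyz"))
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("wxyz"))
        table = prevalence_from_presence(presence, groups)
        assert table.groups == ["g1", "g2"]
        assert table.n_detected == [1, 2]
        assert table.n_samples == [2, 2]


class TestHalfMinPseudocount:
    def test_direct_rule(self):
        shifted, pc = half_min_pseudocount(np.array([[0.0, 2.0, 4.0]]))
        assert pc == 1.0
        assert np.allclose(shifted, [[1.0, 3.0, 5.0]])

    def test_no_zeros_still_half_min(self):
        _, pc = half_min_pseudocount(np.array([[4.0, 2.0, 8.0]]))
        assert pc == 1.0

    def test_random_sparse_matches_scan_oracle(self, rng):
        m = rng.uniform(0, 5, size=(10, 8))
        m[rng.random(m.shape) < 0.4] = 0.0
        if (m > 0).any():
            _, pc = half_min_pseudocount(m)
            assert pc == min(v for v in m.ravel() if v > 0) / 2.0

    def test_all_zero_rejected(self):
        with pytest.raises(InvalidInputError):
            half_min_pseudocount(np.zeros((3, 3)))


class TestCorrelateMultiomics:
    def test_identical_metabolite_gives_rho_one_and_minimal_p(self, rng):
        abundance = pd.Series(rng.uniform(0, 1, 50), index=[f"s{i}" for i in range(50)])
        panel = pd.DataFrame(
            {"self": abundance, "noise": rng.uniform(0, 1, 50)}, index=abundance.index
        )
        records = {r.metabolite_id: r for r in correlate_multiomics(abundance, panel)}
        assert records["self"].rho == pytest.approx(1.0)
        assert records["self"].p_adj == min(r.p_adj for r in records.values())

    def test_permuted_metabolite_is_null(self, rng):
        n = 200
        abundance = pd.Series(rng.uniform(0, 1, n), index=[f"s{i}" for i in range(n)])
        permuted = pd.DataFrame(
            {"perm": rng.permutation(abundance.to_numpy())}, index=abundance.index
        )
        rec = correlate_multiomics(abundance, permuted)[0]
        assert abs(rec.rho) < 0.2

    def test_planted_negative_coupling_recovered(self):
        """Mean realized Spearman over 20 seeds within 0.1 of the -0.45 target."""
        rhos = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            abundance = pd.Series(
                rng.lognormal(0, 1, 209), index=[f"s{i}" for i in range(209)]
            )
            panel = simulate_metabolome(abundance, rng, rho_target=-0.45)
            rec = next(
                r
                for r in correlate_multiomics(abundance, panel)
                if r.metabolite_id == "taurocholate"
            )
            assert rec.n == 209
            rhos.append(rec.rho)
        assert all(r < 0 for r in rhos)
        assert abs(float(np.mean(rhos)) - (-0.45)) < 0.1

    def test_no_paired_samples_warns_and_returns_empty(self, rng):
        abundance = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        panel = pd.DataFrame({"m": [1.0, 2.0]}, index=["x", "y"])
        with pytest.warns(UserWarning):
            assert correlate_multiomics(abundance, panel) == []
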