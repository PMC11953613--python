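"""Cell-type-specific callers: criterion arithmetic, rule composition,
oracle equivalence on random instances, and threshold monotonicity."""
import math

import numpy as np
import pandas as pd
import pytest

from cellsplice import (
    DegCall,
    ExpressionMatrix,
    SpecificityThresholds,
    SpliceEvent,
    call_deg,
    call_dse,
    fold_change,
    overlap_summary,
    upset_counts,
)
from cellsplice.specificity import dpsi_global, dpsi_min, psi_range
from conftest import make_psi_matrix, make_samples
from oracles import oracle_call_deg, oracle_call_dse


def _row(values: dict[str, float]) -> tuple[pd.Series, pd.Series]:
    row = pd.Series(values, dtype=float)
    mask = row.notna()
    return row, mask


class TestDpsiArithmetic:
    def test_global_dpsi_pooled_mean(self):
        samples = make_samples({"A": 2, "B": 2, "C": 2, "D": 2})
        row, mask = _row({"A_r1": 80, "A_r2": 80, "B_r1": 50, "B_r2": 50,
                          "C_r1": 50, "C_r2": 50, "D_r1": 50, "D_r2": 50})
        assert dpsi_global(row, mask, samples, "A") == pytest.approx(30.0)

    def test_global_dpsi_null_case(self):
        samples = make_samples({"A": 2, "B": 2})
        row, mask = _row({"A_r1": 50, "A_r2": 50, "B_r1": 40, "B_r2": 60})
        assert dpsi_global(row, mask, samples, "A") == pytest.approx(0.0)

    def test_global_dpsi_unbalanced_replicates(self):
        samples = make_samples({"A": 2, "B": 2, "C": 2})
        row, mask = _row({"A_r1": 90, "A_r2": 70, "B_r1": 40, "B_r2": 60,
                          "C_r1": 50, "C_r2": 50})
        assert dpsi_global(row, mask, samples, "A") == pytest.approx(30.0)

    def test_min_dpsi_picks_smallest_magnitude(self):
        samples = make_samples({"A": 2, "B": 2, "C": 2, "D": 2})
        row, mask = _row({"A_r1": 80, "A_r2": 80, "B_r1": 50, "B_r2": 50,
                          "C_r1": 55, "C_r2": 55, "D_r1": 60, "D_r2": 60})
        assert dpsi_min(row, mask, samples, "A") == pytest.approx(20.0)

    def test_min_dpsi_sign_preserved(self):
        samples = make_samples({"A": 2, "B": 2, "C": 2})
        row, mask = _row({"A_r1": 40, "A_r2": 40, "B_r1": 70, "B_r2": 70,
                          "C_r1": 90, "C_r2": 90})
        assert dpsi_min(row, mask, samples, "A") == pytest.approx(-30.0)

    def test_min_dpsi_equality_is_zero(self):
        samples = make_samples({"A": 2, "B": 2})
        row, mask = _row({"A_r1": 80, "A_r2": 80, "B_r1": 80, "B_r2": 80})
        assert dpsi_min(row, mask, samples, "A") == pytest.approx(0.0)

    def test_psi_range_max_of_maxima(self):
        samples = make_samples({"A": 1, "B": 1, "C": 1, "D": 1})
        row, mask = _row({"A_r1": 90, "B_r1": 50, "C_r1": 50, "D_r1": 50})
        assert psi_range(row, mask, samples) == pytest.approx(40.0)

    def test_psi_range_boundary(self):
        samples = make_samples({"A": 1, "B": 1})
        row, mask = _row({"A_r1": 51, "B_r1": 50})
        assert psi_range(row, mask, samples) == pytest.approx(1.0)

    def test_insufficient_target_coverage_undefined(self):
        samples = make_samples({"A": 2, "B": 2})
        row, mask = _row({"A_r1": 80, "A_r2": float("nan"),
                          "B_r1": 50, "B_r2": 50})
        assert math.isnan(dpsi_global(row, mask, samples, "A"))


class TestCallDse:
    def _psi(self, per_ct: dict[str, list[float]]):
        data = {}
        for ct, vals in per_ct.items():
            for r, v in enumerate(vals, start=1):
                data[f"{ct}_r{r}"] = v
        values = pd.DataFrame([data], index=["ev1"])
        return make_psi_matrix(values)

    def test_single_specific_cell_type(self):
        psi = self._psi({"A": [90, 90], "B": [50, 50], "C": [50, 50], "D": [50, 50]})
        samples = make_samples({"A": 2, "B": 2, "C": 2, "D": 2})
        calls = call_dse(psi, samples)
        assert len(calls) == 1
        c = calls[0]
        assert (c.cell_type, c.direction) == ("A", "up")
        assert c.dpsi_global == pytest.approx(40.0)
        assert c.dpsi_min == pytest.approx(40.0)
        assert c.psi_range == pytest.approx(40.0)

    def test_below_global_threshold_no_call(self):
        psi = self._psi({"A": [70, 70], "B": [50, 50], "C": [50, 50], "D": [50, 50]})
        samples = make_samples({"A": 2, "B": 2, "C": 2, "D": 2})
        assert call_dse(psi, samples) == []

    def test_opposite_directions_both_callable(self):
        psi = self._psi({"A": [90, 90], "B": [20, 20], "C": [55, 55], "D": [55, 55]})
        samples = make_samples({"A": 2, "B": 2, "C": 2, "D": 2})
        calls = call_dse(psi, samples)
        got = {(c.cell_type, c.direction) for c in calls}
        # oracle agreement checked in the equivalence test; here the
        # directional split must be coherent
        assert got == {("A", "up"), ("B", "down")}

    def test_fewer_than_min_cell_types_skipped(self):
        psi = self._psi({"A": [90, 90], "B": [50, 50], "C": [50, 50]})
        samples = make_samples({"A": 2, "B": 2, "C": 2})
        assert call_dse(psi, samples) == []

    def test_organs_called_independently(self):
        psi = self._psi({"A": [90, 90], "B": [50, 50], "C": [50, 50], "D": [50, 50],
                         "E": [95, 95], "F": [30, 30], "G": [30, 30], "H": [30, 30]})
        samples = (make_samples({"A": 2, "B": 2, "C": 2, "D": 2}, organ="root")
                   + make_samples({"E": 2, "F": 2, "G": 2, "H": 2}, organ="aerial"))
        calls = call_dse(psi, samples)
        assert {(c.cell_type, c.organ) for c in calls} == {("A", "root"), ("E", "aerial")}

    def test_boundary_equality_fails_strict_rules(self):
        # dpsi_global exactly 25 fails '>' but psi_range 2 passes '>='
        psi = self._psi({"A": [75, 75], "B": [50, 50], "C": [50, 50], "D": [50, 50]})
        samples = make_samples({"A": 2, "B": 2, "C": 2, "D": 2})
        assert call_dse(psi, samples) == []
        lenient = SpecificityThresholds(strict_dpsi=False)
        assert len(call_dse(psi, samples, lenient)) == 1


class TestFoldChange:
    @pytest.mark.parametrize("a,b,pc,expected", [
        (10, 10, 0.01, 1.0),
        (100, 10, 0.0, 10.0),
        (0, 0, 0.01, 1.0),
    ])
    def test_examples(self, a, b, pc, expected):
        assert fold_change(a, b, pc) == pytest.approx(expected)


class TestCallDeg:
    def _expr(self, per_ct: dict[str, list[float]]):
        data = {}
        for ct, vals in per_ct.items():
            for r, v in enumerate(vals, start=1):
                data[f"{ct}_r{r}"] = float(v)
        crpkm = pd.DataFrame([data], index=pd.Index(["g1"], name="gene_id"))
        ones = crpkm * 0 + 1
        return ExpressionMatrix(raw=crpkm, mappable_positions=pd.Series([1], index=crpkm.index),
                                crpkm=crpkm, norm_counts=crpkm,
                                size_factors=pd.Series(1.0, index=crpkm.columns))

    def test_clear_up_call(self):
        expr = self._expr({"A": [100] * 3, "B": [10] * 3, "C": [10] * 3, "D": [10] * 3})
        samples = make_samples({"A": 3, "B": 3, "C": 3, "D": 3})
        calls = call_deg(expr, samples)
        assert [(c.gene_id, c.cell_type, c.direction) for c in calls] == [("g1", "A", "up")]
        assert calls[0].log2_fc_global == pytest.approx(np.log2(100.01 / 10.01))

    def test_each_fc_below_threshold_no_call(self):
        expr = self._expr({"A": [8] * 3, "B": [5] * 3, "C": [5] * 3, "D": [5] * 3})
        samples = make_samples({"A": 3, "B": 3, "C": 3, "D": 3})
        assert call_deg(expr, samples) == []

    def test_eligibility_precedes_fold_change(self):
        # 8-fold but every median < 5: the gene is never considered
        expr = self._expr({"A": [4] * 3, "B": [0.5] * 3, "C": [0.5] * 3, "D": [0.5] * 3})
        samples = make_samples({"A": 3, "B": 3, "C": 3, "D": 3})
        assert call_deg(expr, samples) == []

    def test_down_call_direction(self):
        expr = self._expr({"A": [1] * 3, "B": [50] * 3, "C": [40] * 3, "D": [60] * 3})
        samples = make_samples({"A": 3, "B": 3, "C": 3, "D": 3})
        calls = call_deg(expr, samples)
        assert [(c.cell_type, c.direction) for c in calls] == [("A", "down")]


def _random_dse_instance(rng):
    """One organ, 4 cell types, 2-3 replicates, uniform PSI with random
    missingness."""
    reps = {ct: int(rng.integers(2, 4)) for ct in "ABCD"}
    samples = make_samples(reps)
    n_events = 8
    cols = [s.sample_id for s in samples]
    vals = rng.uniform(0, 100, size=(n_events, len(cols)))
    miss = rng.random(vals.shape) < 0.2
    vals[miss] = np.nan
    values = pd.DataFrame(np.round(vals, 2), columns=cols,
                          index=[f"e{i}" for i in range(n_events)])
    return values, samples


def _random_deg_instance(rng):
    reps = {ct: int(rng.integers(2, 4)) for ct in "ABCD"}
    samples = make_samples(reps)
    cols = [s.sample_id for s in samples]
    vals = np.exp(rng.normal(np.log(5), 1.5, size=(6, len(cols))))
    crpkm = pd.DataFrame(np.round(vals, 4), columns=cols,
                         index=pd.Index([f"g{i}" for i in range(6)], name="gene_id"))
    expr = ExpressionMatrix(raw=crpkm, mappable_positions=pd.Series(1, index=crpkm.index),
                            crpkm=crpkm, norm_counts=crpkm,
                            size_factors=pd.Series(1.0, index=cols))
    return expr, samples


class TestOracleEquivalence:
    def test_dse_matches_straight_line_oracle(self):
        """500 seeded random instances: the caller agrees exactly with
        an independent plain-loop evaluation of the three criteria."""
        rng = np.random.default_rng(2024)
        th = SpecificityThresholds()
        total_calls = 0
        for _ in range(500):
            values, samples = _random_dse_instance(rng)
            psi = make_psi_matrix(values)
            calls = call_dse(psi, samples, th)
            got = {(c.event_id, c.cell_type, c.organ):
                   (round(c.dpsi_global, 9), round(c.dpsi_min, 9),
                    round(c.psi_range, 9), c.direction) for c in calls}
            rows = {e: {s: (None if math.isnan(values.at[e, s]) else values.at[e, s])
                        for s in values.columns} for e in values.index}
            expected = oracle_call_dse(rows, [(s.sample_id, s.cell_type, s.organ)
                                              for s in samples], th)
            expected = {k: (round(v[0], 9), round(v[1], 9), round(v[2], 9), v[3])
                        for k, v in expected.items()}
            assert got == expected
            total_calls += len(calls)
        assert total_calls > 100  # instances genuinely exercise the rules

    def test_deg_matches_straight_line_oracle(self):
        rng = np.random.default_rng(777)
        th = SpecificityThresholds()
        total_calls = 0
        for _ in range(500):
            expr, samples = _random_deg_instance(rng)
            calls = call_deg(expr, samples, th)
            got = {(c.gene_id, c.cell_type, c.organ): c.direction for c in calls}
            rows = {g: dict(expr.crpkm.loc[g]) for g in expr.gene_ids}
            expected = oracle_call_deg(rows, [(s.sample_id, s.cell_type, s.organ)
                                              for s in samples], th)
            assert got == expected
            total_calls += len(calls)
        assert total_calls > 100


class TestThresholdMonotonicity:
    def test_raising_thresholds_never_adds_calls(self):
        """100 seeded instances: the call set is antitone in every
        threshold."""
        rng = np.random.default_rng(5)
        base = SpecificityThresholds()
        bumps = [
            {"global_dpsi": 35.0}, {"min_dpsi": 22.0, "global_dpsi": 25.0},
            {"min_psi_range": 10.0},
            {"deg_fc_each": 3.0}, {"deg_fc_global": 8.0}, {"deg_abs_diff": 5.0},
            {"deg_min_median_crpkm": 10.0},
        ]
        for i in range(100):
            values, samples = _random_dse_instance(rng)
            psi = make_psi_matrix(values)
            expr, dsamples = _random_deg_instance(rng)
            bump = bumps[i % len(bumps)]
            raised = base.replace(**bump)
            dse_base = {(c.event_id, c.cell_type) for c in call_dse(psi, samples, base)}
            dse_raised = {(c.event_id, c.cell_type) for c in call_dse(psi, samples, raised)}
            assert dse_raised <= dse_base
            deg_base = {(c.gene_id, c.cell_type) for c in call_deg(expr, dsamples, base)}
            deg_raised = {(c.gene_id, c.cell_type) for c in call_deg(expr, dsamples, raised)}
            assert deg_raised <= deg_base


class TestOverlapSummary:
    def _events(self):
        return [SpliceEvent(f"e{i}", f"g{i}", "IR", f"chr1:{i + 1}-{i + 2}")
                for i in range(5)]

    def _dse(self, pairs):
        from cellsplice import SpecificCall
        return [SpecificCall(e, ct, "root", 30.0, 20.0, 10.0, "up") for e, ct in pairs]

    def _deg(self, pairs):
        return [DegCall(g, ct, "root", 3.0, "up", 50.0, 5.0) for g, ct in pairs]

    def test_set_algebra(self):
        deg = self._deg([("g1", "A"), ("g2", "A")])
        dse = self._dse([("e2", "B"), ("e3", "B")])  # genes g2, g3
        out = overlap_summary(deg, dse, self._events())
        assert (out["n_deg_genes"], out["n_dsg_genes"], out["n_overlap_genes"]) == (2, 2, 1)

    def test_disjoint_sets(self):
        out = overlap_summary(self._deg([("g1", "A")]), self._dse([("e3", "B")]),
                              self._events())
        assert out["n_overlap_genes"] == 0

    def test_upset_partition(self):
        """Exclusive patterns partition the called items."""
        dse = self._dse([("e1", "A"), ("e1", "B"), ("e2", "A"), ("e3", "C")])
        out = overlap_summary([], dse, self._events())
        patterns = out["dse_upset"]
        assert sum(patterns.values()) == 3  # e1, e2, e3
        assert patterns[("A", "B")] == 1
        assert patterns[("A",)] == 1 and patterns[("C",)] == 1

    def test_upset_counts_exclusive(self):
        got = upset_counts({"x": {"A"}, "y": {"A"}, "z": {"A", "B"}})
        assert got == {("A",): 2, ("A", "B"): 1}
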