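"""Preprocessing: residualization, PC1 composites, change scores,
correlation screen."""

import numpy as np
import pandas as pd
import pytest

from bcnkit.ci_tests import ci_test
from bcnkit.exceptions import DegenerateDataError, InvalidInputError
from bcnkit.preprocess import (
    CohortTable,
    PC1Composite,
    change_score,
    correlation_table,
    pc1_composite,
    residualize,
)


def make_cohort(seed=0, n=400, n_sites=8):
    rng = np.random.default_rng(seed)
    site = rng.integers(0, n_sites, size=n)
    sex = rng.integers(0, 2, size=n)
    data = pd.DataFrame({
        "u": rng.normal(size=n) + 0.3 * site + 0.4 * sex,
        "v": rng.normal(size=n) - 0.2 * site,
        "w": rng.normal(size=n),
    })
    return CohortTable(data, pd.DataFrame({"site": site, "sex": sex}))


def nuisance_indicators(table: CohortTable) -> np.ndarray:
    cols = []
    for c in table.nuisance.columns:
        s = table.nuisance[c].astype(str)
        for lev in sorted(s.unique())[1:]:
            cols.append((s == lev).to_numpy(float))
    return np.column_stack(cols)


class TestResidualize:
    def test_residuals_orthogonal_to_every_indicator(self):
        table = residualize(make_cohort())
        ind = nuisance_indicators(table)
        for col in table.columns:
            y = table.data[col].to_numpy()
            for j in range(ind.shape[1]):
                r = np.corrcoef(y, ind[:, j])[0, 1]
                assert abs(r) < 1e-10

    def test_pure_site_effect_vanishes(self):
        rng = np.random.default_rng(1)
        site = rng.integers(0, 4, size=200)
        sex = rng.integers(0, 2, size=200)
        table = CohortTable(
            pd.DataFrame({"t": site.astype(float) * 2.0 + sex}),
            pd.DataFrame({"site": site, "sex": sex}),
        )
        out = residualize(table)
        assert out.data["t"].var() < 1e-20

    def test_orthogonal_target_only_recentred(self):
        rng = np.random.default_rng(2)
        n = 300
        # balanced +-1 design orthogonal to an alternating site pattern
        site = np.arange(n) % 2
        sex = (np.arange(n) // 2) % 2
        t = rng.normal(size=n)
        # project out the nuisance space explicitly, then shift
        design = np.column_stack([np.ones(n), site, sex])
        t_orth = t - design @ np.linalg.lstsq(design, t, rcond=None)[0] + 5.0
        table = CohortTable(
            pd.DataFrame({"t": t_orth}),
            pd.DataFrame({"site": site, "sex": sex}),
        )
        out = residualize(table)
        assert np.allclose(out.data["t"], t_orth - 5.0, atol=1e-10)

    def test_idempotent(self):
        once = residualize(make_cohort(3))
        twice = residualize(once)
        for col in once.columns:
            assert np.allclose(once.data[col], twice.data[col], atol=1e-10)

    def test_constant_column_rejected(self):
        table = make_cohort(4)
        table.data["const"] = 1.0
        with pytest.raises(DegenerateDataError):
            residualize(table)


class TestPC1Composite:
    def test_identical_columns(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        table = CohortTable(pd.DataFrame({"a": x, "b": x.copy()}))
        res = pc1_composite(table, ["a", "b"])
        assert res.eigenvalue == pytest.approx(2.0, abs=1e-12)
        assert res.pct_variance == pytest.approx(100.0, abs=1e-10)

    @pytest.mark.parametrize("r", [0.8, 0.5, 0.3])
    def test_closed_form_eigenvalue_two_columns(self, r):
        """lambda1 = 1 + r for standardized pairs (exactly, via construction
        of data with the prescribed sample correlation)."""
        rng = np.random.default_rng(6)
        n = 500
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        # Gram-Schmidt so the sample correlation is exactly r
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)
        b /= b.std()
        mixed = r * a + np.sqrt(1 - r * r) * b
        table = CohortTable(pd.DataFrame({"a": a, "m": mixed}))
        res = pc1_composite(table, ["a", "m"])
        assert res.eigenvalue == pytest.approx(1 + r, abs=1e-10)
        assert res.pct_variance == pytest.approx((1 + r) / 2 * 100, abs=1e-8)

    def test_independent_columns(self):
        rng = np.random.default_rng(7)
        table = CohortTable(pd.DataFrame({
            "a": rng.normal(size=20000), "b": rng.normal(size=20000)
        }))
        res = pc1_composite(table, ["a", "b"])
        assert res.eigenvalue == pytest.approx(1.0, abs=0.05)
        assert res.pct_variance == pytest.approx(50.0, abs=2.5)

    def test_sign_convention_first_column_positive(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        table = CohortTable(pd.DataFrame({"a": x, "b": -x + 0.1 * rng.normal(size=200)}))
        res = pc1_composite(table, ["b", "a"])  # order should not matter
        assert res.loadings[list(res.columns).index("a")] > 0

    def test_column_order_invariance(self):
        table = make_cohort(9)
        r1 = pc1_composite(table, ["u", "v"])
        r2 = pc1_composite(table, ["v", "u"])
        assert np.allclose(r1.scores, r2.scores, atol=1e-10)

    def test_constant_input_rejected(self):
        table = CohortTable(pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)}))
        with pytest.raises(DegenerateDataError):
            pc1_composite(table, ["a", "b"])

    def test_transformer_adds_and_drops_columns(self):
        table = make_cohort(10)
        est = PC1Composite(["u", "v"], name="comp").fit(table)
        out = est.transform(table)
        assert "comp" in out.data.columns
        assert "u" not in out.data.columns


class TestChangeScore:
    def test_identical_waves_give_zero(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=100)
        table = CohortTable(pd.DataFrame({"b": x, "f": x.copy()}))
        out = change_score(table, "b", "f", name="d")
        assert np.allclose(out.data["d"], 0.0)

    def test_unit_shift_gives_ones(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=100)
        table = CohortTable(pd.DataFrame({"b": x, "f": x + 1.0}))
        out = change_score(table, "b", "f", name="d")
        assert np.allclose(out.data["d"], 1.0)

    def test_name_collision_rejected(self):
        table = CohortTable(pd.DataFrame({"b": np.arange(10.0),
                                          "f": np.arange(10.0)}))
        with pytest.raises(InvalidInputError):
            change_score(table, "b", "f", name="b")


class TestCorrelationTable:
    def test_diagonal_and_symmetry(self):
        table = make_cohort(13)
        r, p = correlation_table(table)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)
        assert np.allclose(p, p.T)

    def test_independent_columns_small_r(self):
        rng = np.random.default_rng(14)
        table = CohortTable(pd.DataFrame(
            rng.normal(size=(10000, 3)), columns=list("abc")
        ))
        r, _ = correlation_table(table)
        off = r.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_matches_pearson_ci_test(self):
        table = make_cohort(15)
        r, p = correlation_table(table)
        res = ci_test(table, "u", "v", method="pearson")
        assert r.loc["u", "v"] == pytest.approx(res.partial_r, abs=1e-12)
        assert p.loc["u", "v"] == pytest.approx(res.p_value, rel=1e-9)


class TestCohortTable:
    def test_missing_values_rejected(self):
        frame = pd.DataFrame({"a": [1.0, np.nan]})
        with pytest.raises(InvalidInputError):
            CohortTable(frame)

    def test_from_frame_drops_incomplete_rows_with_log(self):
        frame = pd.DataFrame({
            "a": [1.0, np.nan, 3.0], "site": [0, 1, 2]
        })
        table = CohortTable.from_frame(frame, nuisance_columns=["site"])
        assert table.n == 2
        assert any("dropped 1 rows" in m for m in table.provenance)
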