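"""Variable curation, encoding, and control down-sampling."""

import numpy as np
import pandas as pd
import pytest

import bamscan as bs


def _raw(columns: dict, meta_rows: dict) -> bs.RawTable:
    data = pd.DataFrame(columns)
    data.index.name = "participant"
    meta = pd.DataFrame.from_dict(
        meta_rows, orient="index",
        columns=["type", "field", "instance", "exempt_levels"],
    )
    return bs.RawTable(data, meta)


@pytest.fixture
def repeated_raw():
    n = 40
    rng = np.random.default_rng(0)
    cols, meta = {}, {}
    for f in range(5):
        for inst in (0, 1, 2):
            name = f"f{f}_i{inst}"
            cols[name] = rng.standard_normal(n)
            meta[name] = ("continuous", f"f{f}", inst, False)
    return _raw(cols, meta)


class TestSelectFirstInstance:
    def test_keeps_instance_zero(self, repeated_raw):
        out = bs.select_first_instance(repeated_raw)
        assert sorted(out.data.columns) == [f"f{f}_i0" for f in range(5)]

    def test_single_instance_unchanged(self):
        raw = _raw({"a": [1.0, 2.0]}, {"a": ("continuous", "a", 0, False)})
        assert list(bs.select_first_instance(raw).data.columns) == ["a"]

    def test_dispositions_logged(self, repeated_raw):
        report = bs.EncodingReport()
        bs.select_first_instance(repeated_raw, report)
        dropped = report.to_frame()
        assert len(dropped) == 10  # 5 fields x 2 later instances
        assert (dropped["disposition"] == "excluded").all()


class TestFilterVariables:
    def _levels_raw(self, n_levels, exempt=False):
        n = 400
        rng = np.random.default_rng(1)
        vals = rng.integers(0, n_levels, n).astype(float)
        # force every level to appear
        vals[:n_levels] = np.arange(n_levels)
        return _raw({"fac": vals}, {"fac": ("factor", "fac", 0, exempt)})

    def test_factor_level_cap_is_strict(self):
        assert list(bs.filter_variables(self._levels_raw(51)).data.columns) == []
        assert list(bs.filter_variables(self._levels_raw(50)).data.columns) == ["fac"]

    def test_exemption_lifts_the_cap(self):
        # mirrors the self-reported-illness exemption
        assert list(
            bs.filter_variables(self._levels_raw(60, exempt=True)).data.columns
        ) == ["fac"]

    def test_missingness_boundary_is_strict(self):
        n = 100
        base = np.arange(n, dtype=float)
        x15, x16 = base.copy(), base.copy()
        x15[:15] = np.nan
        x16[:16] = np.nan
        raw = _raw(
            {"ok": x15, "bad": x16},
            {"ok": ("continuous", "ok", 0, False),
             "bad": ("continuous", "bad", 0, False)},
        )
        out = bs.filter_variables(raw, max_missing=0.15)
        assert list(out.data.columns) == ["ok"]


class TestImputation:
    def test_mean_fill(self):
        raw = _raw({"a": [1.0, 2.0, np.nan]}, {"a": ("continuous", "a", 0, False)})
        out = bs.impute_continuous(raw)
        assert out.data["a"].tolist() == [1.0, 2.0, 1.5]

    def test_mean_conserved(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal(200)
        vals[rng.choice(200, 30, replace=False)] = np.nan
        raw = _raw({"a": vals}, {"a": ("continuous", "a", 0, False)})
        pre = np.nanmean(vals)
        out = bs.impute_continuous(raw)
        assert out.data["a"].mean() == pytest.approx(pre, abs=1e-12)
        assert not out.data["a"].isna().any()

    def test_integer_columns_not_rounded(self):
        raw = _raw({"a": [1.0, 2.0, np.nan]}, {"a": ("integer", "a", 0, False)})
        assert bs.impute_continuous(raw).data["a"].tolist() == [1.0, 2.0, 1.5]


class TestEncodeFactors:
    def test_frequency_floor(self):
        n = 1000
        vals = np.array(["A"] * 600 + ["B"] * 399 + ["C"] * 1, dtype=object)
        raw = _raw({"fac": vals}, {"fac": ("factor", "fac", 0, False)})
        enc = bs.encode_factors(raw, min_freq=0.002)
        assert sorted(enc.columns) == ["fac:A", "fac:B"]
        assert enc["fac:A"].sum() == 600

    def test_binary_factor_yields_both_levels(self):
        # both levels of a binary factor qualify, giving two complementary
        # indicators (which the collinearity rule keeps out of one model)
        vals = np.array([0.0, 1.0] * 50)
        raw = _raw({"sex": vals}, {"sex": ("factor", "sex", 0, False)})
        enc = bs.encode_factors(raw)
        assert sorted(enc.columns) == ["sex:0.0", "sex:1.0"]
        assert np.allclose(enc["sex:0.0"] + enc["sex:1.0"], 1.0)

    def test_missing_is_a_level_without_indicator(self):
        vals = np.array(["A"] * 50 + [None] * 50, dtype=object)
        raw = _raw({"fac": vals}, {"fac": ("factor", "fac", 0, False)})
        enc = bs.encode_factors(raw, min_freq=0.002)
        assert list(enc.columns) == ["fac:A"]
        assert enc["fac:A"].sum() == 50  # missing rows contribute 0

    def test_column_count_matches_hand_count(self):
        rng = np.random.default_rng(3)
        n = 500
        raw = _raw(
            {
                "f1": rng.choice(["a", "b", "c"], n),          # 3 common levels
                "f2": rng.choice(["x", "y"], n),               # 2 common levels
                "f3": np.array(["p"] * (n - 1) + ["q"]),       # q below floor
            },
            {k: ("factor", k, 0, False) for k in ("f1", "f2", "f3")},
        )
        enc = bs.encode_factors(raw, min_freq=0.002)
        assert enc.shape[1] == 3 + 2 + 1


class TestEncodeEventCodes:
    def _events(self):
        return pd.DataFrame(
            {
                "participant": [0, 1, 2, 3, 4, 5, 0],
                "code": ["J22", "J22", "J22", "F03", "F03", "U07", "J22"],
                "date": ["2019-05-01", "2018-01-01", "2019-12-31",
                         "2017-06-15", "2019-11-30", "2020-03-01", "2019-06-01"],
            }
        )

    def test_indicator_matches_brute_force(self):
        participants = pd.Index(range(10))
        enc = bs.encode_event_codes(self._events(), participants, min_freq=0.05)
        # brute force: J22 carriers {0,1,2}, F03 {3,4}; U07 dated 2020 -> dropped
        assert sorted(enc.columns) == ["F03", "J22"]
        assert enc["J22"].tolist() == [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        assert enc["F03"].tolist() == [0, 0, 0, 1, 1, 0, 0, 0, 0, 0]

    def test_post_cutoff_events_do_not_count(self):
        participants = pd.Index(range(10))
        enc = bs.encode_event_codes(self._events(), participants, min_freq=0.05)
        assert "U07" not in enc.columns

    def test_frequency_floor(self):
        participants = pd.Index(range(1000))
        ev = pd.DataFrame(
            {"participant": [0], "code": ["rare"], "date": ["2019-01-01"]}
        )
        enc = bs.encode_event_codes(ev, participants, min_freq=0.002)
        assert enc.shape[1] == 0  # 0.1% < 0.2% floor

    def test_undated_events_warn_and_drop(self):
        participants = pd.Index(range(10))
        ev = pd.DataFrame(
            {"participant": [0, 1], "code": ["X", "X"], "date": ["2019-01-01", None]}
        )
        with pytest.warns(UserWarning, match="undated"):
            enc = bs.encode_event_codes(ev, participants, min_freq=0.05)
        assert enc["X"].sum() == 1


class TestDownsampleControls:
    def _data(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((100, 2))
        y = np.zeros(100)
        y[:10] = 1
        return bs.Dataset(X, y)

    def test_cases_preserved_exactly(self):
        out = bs.downsample_controls(self._data(), 30, seed=0)
        assert out.y.sum() == 10
        assert out.n == 40

    def test_all_controls_is_identity_up_to_order(self):
        data = self._data()
        out = bs.downsample_controls(data, 90, seed=0)
        assert out.n == data.n
        assert np.allclose(np.sort(out.X[:, 0]), np.sort(data.X[:, 0]))

    def test_seeded_reproducibility(self):
        a = bs.downsample_controls(self._data(), 30, seed=5)
        b = bs.downsample_controls(self._data(), 30, seed=5)
        assert np.array_equal(a.X, b.X)

    def test_rejects_oversampling(self):
        with pytest.raises(ValueError):
            bs.downsample_controls(self._data(), 91, seed=0)


class TestBuildDataset:
    def test_pipeline_decomposition_and_no_missing(self):
        """Emitted column count decomposes as numeric covariates +
        factor-level indicators + event-code indicators, with no missing
        values left."""
        rng = np.random.default_rng(5)
        n = 500
        cont = rng.standard_normal(n)
        cont[:20] = np.nan
        too_missing = np.where(np.arange(n) < 100, np.nan, 1.0 * np.arange(n))
        cols = {
            "age_i0": cont,
            "age_i1": rng.standard_normal(n),       # dropped: repeated measure
            "gappy": too_missing,                    # dropped: 20% missing
            "smoke": rng.choice(["never", "ever"], n),
        }
        meta = {
            "age_i0": ("continuous", "age", 0, False),
            "age_i1": ("continuous", "age", 1, False),
            "gappy": ("continuous", "gappy", 0, False),
            "smoke": ("factor", "smoke", 0, False),
        }
        raw = _raw(cols, meta)
        events = pd.DataFrame(
            {
                "participant": rng.choice(n, 50),
                "code": ["J22"] * 50,
                "date": ["2019-01-01"] * 50,
            }
        )
        outcome = pd.Series((rng.random(n) < 0.3).astype(float), index=raw.data.index)
        data, report = bs.build_dataset(raw, outcome, events)
        assert data.nu == 1 + 2 + 1  # age + two smoke levels + J22
        assert not np.isnan(data.X).any()
        dispositions = report.to_frame()
        assert set(dispositions["column"]) >= {"age_i1", "gappy", "smoke", "J22"}
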