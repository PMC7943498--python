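"""Feature extraction: column identities, oracle equality, masking."""

import numpy as np
import pandas as pd
import pytest

from abpbench import (
    derive_channels,
    extract_highrate_features,
    extract_minute_features,
)
from conftest import random_minutes

TYPES = ("sbp", "dbp", "map", "hr", "pp", "sbp_hr", "dbp_hr", "sbp_map", "map_dbp")


def naive_channels(row):
    sbp, dbp, map_, hr = row
    div = lambda a, b: np.nan if b == 0 else a / b
    return {
        "sbp": sbp, "dbp": dbp, "map": map_, "hr": hr, "pp": sbp - dbp,
        "sbp_hr": div(sbp, hr), "dbp_hr": div(dbp, hr),
        "sbp_map": div(sbp, map_), "map_dbp": div(map_, dbp),
    }


def naive_features(frame, neighbor_step, n_neighbors):
    """Loop oracle for one mode: dict of column -> list over rows."""
    chans = [naive_channels((r.sbp, r.dbp, r.map, r.hr)) for r in frame.itertuples()]
    n = len(chans)
    cols = {}
    for typ in TYPES:
        v = [c[typ] for c in chans]
        cols[typ] = v
        for k in range(-n_neighbors, n_neighbors + 1):
            if k == 0:
                continue
            col = []
            for i in range(n):
                j = i + k * neighbor_step
                col.append(v[i] - v[j] if 0 <= j < n else np.nan)
            cols[f"{typ}_lag{k:+d}"] = col
    for sig in ("hr", "dbp", "sbp", "map"):
        v = [c[sig] for c in chans]
        med, dmed, rdmed = [], [], []
        for i in range(n):
            idx = [i + k * neighbor_step for k in range(-n_neighbors, n_neighbors + 1)]
            if all(0 <= j < n for j in idx):
                m = float(np.median([v[j] for j in idx]))
                med.append(m)
                dmed.append(v[i] - m)
                rdmed.append(np.nan if m == 0 else (v[i] - m) / m)
            else:
                med.append(np.nan), dmed.append(np.nan), rdmed.append(np.nan)
        cols[f"{sig}_med"], cols[f"{sig}_dmed"], cols[f"{sig}_rdmed"] = med, dmed, rdmed
    return cols


class TestDeriveChannels:
    def test_arithmetic_example(self):
        out = derive_channels(120.0, 60.0, 80.0, 60.0)
        assert out["pp"] == 60
        assert out["sbp_hr"] == 2.0
        assert out["sbp_map"] == 1.5
        assert out["map_dbp"] == pytest.approx(4 / 3)

    def test_zero_denominator_flags_missing(self):
        out = derive_channels(120.0, 60.0, 80.0, 0.0)
        assert np.isnan(out["sbp_hr"]) and np.isnan(out["dbp_hr"])
        assert out["sbp_map"] == 1.5  # unaffected ratios survive

    def test_matches_naive_recomputation(self, rng):
        pts = rng.normal([120, 60, 80, 70], 10, size=(30, 4))
        out = derive_channels(*pts.T)
        for i, row in enumerate(pts):
            for k, v in naive_channels(row).items():
                assert out[k][i] == pytest.approx(v)


class TestMinuteFeatures:
    def test_paper_mode_has_111_columns(self, rng):
        fm = extract_minute_features(random_minutes(rng, 20))
        assert fm.n_features == 111

    def test_extended_mode_has_123_columns(self, rng):
        assert extract_minute_features(random_minutes(rng, 20), mode="extended").n_features == 123

    def test_constant_series_zeroes_differences(self, rng):
        m = random_minutes(rng, 15)
        for c in ("sbp", "dbp", "map", "hr"):
            m[c] = {"sbp": 120.0, "dbp": 60.0, "map": 80.0, "hr": 70.0}[c]
        fm = extract_minute_features(m)
        usable = fm.usable()
        diff_cols = [c for c in fm.feature_columns if "_lag" in c or c.endswith(("dmed", "rdmed"))]
        assert np.allclose(usable[diff_cols].to_numpy(), 0.0)

    def test_translation_leaves_differences_unchanged(self, rng):
        m = random_minutes(rng, 25)
        fm1 = extract_minute_features(m)
        shifted = m.copy()
        for c in ("sbp", "dbp", "map"):
            shifted[c] = shifted[c] + 17.0
        fm2 = extract_minute_features(shifted)
        # additive channels only: ratio features rightly move with the level
        diff_cols = [c for c in fm1.feature_columns
                     if "_lag" in c and c.split("_lag")[0] in ("sbp", "dbp", "map", "hr", "pp")]
        a = fm1.usable()[diff_cols].to_numpy()
        b = fm2.usable()[diff_cols].to_numpy()
        assert np.allclose(a, b)

    def test_exactly_edge_rows_masked_when_gap_free(self, rng):
        fm = extract_minute_features(random_minutes(rng, 30))
        expect = np.ones(30, dtype=bool)
        expect[:5] = expect[-5:] = False
        assert (fm.valid == expect).all()

    def test_internal_gap_masks_surrounding_windows(self, rng):
        m = random_minutes(rng, 30)
        m = m[m.t_end_s != 15 * 60].reset_index(drop=True)  # drop one minute
        fm = extract_minute_features(m)
        t = fm.data["t_end_s"].to_numpy()
        affected = np.abs(t - 15 * 60) <= 5 * 60
        assert not fm.valid[affected].any()
        assert fm.valid[(~affected) & (t >= 6 * 60) & (t <= 24 * 60)].all()

    def test_too_few_records_masks_everything(self, rng):
        with pytest.warns(UserWarning, match="masked"):
            fm = extract_minute_features(random_minutes(rng, 8))
        assert not fm.valid.any()

    def test_matches_loop_oracle_on_random_series(self, rng):
        m = random_minutes(rng, 50)
        m.loc[3, "hr"] = 0.0  # exercise the zero-denominator path
        fm = extract_minute_features(m)
        oracle = naive_features(m, neighbor_step=1, n_neighbors=5)
        for col, expect in oracle.items():
            got = fm.data[col].to_numpy()
            for i in range(len(m)):
                if not fm.valid[i]:
                    continue
                e = expect[i]
                assert (np.isnan(e) and np.isnan(got[i])) or got[i] == pytest.approx(e), col


class TestHighRateFeatures:
    def test_paper_mode_has_291_columns(self, session):
        fm = extract_highrate_features(session.vitals)
        assert fm.n_features == 291

    def test_extended_mode_has_303_columns(self, session):
        assert extract_highrate_features(session.vitals, mode="extended").n_features == 303

    def test_constant_series_zeroes_differences(self):
        t = np.arange(0, 700 * 5, 5)
        vit = pd.DataFrame({"t_s": t, "sbp": 120.0, "dbp": 60.0, "map": 80.0, "hr": 70.0})
        fm = extract_highrate_features(vit)
        diff_cols = [c for c in fm.feature_columns if "_lag" in c]
        assert np.allclose(fm.usable()[diff_cols].to_numpy(), 0.0)

    def test_neighbors_are_20s_apart(self, rng):
        """The ±1 neighbor difference spans 4 samples (20 s), not 1."""
        n = 200
        t = np.arange(n) * 5
        v = rng.normal(100, 15, n)
        vit = pd.DataFrame({"t_s": t, "sbp": v, "dbp": v / 2, "map": v * 2 / 3, "hr": 70.0})
        fm = extract_highrate_features(vit)
        i = 100
        assert fm.data.loc[i, "sbp_lag-1"] == pytest.approx(v[i] - v[i - 4])
        assert fm.data.loc[i, "sbp_lag+15"] == pytest.approx(v[i] - v[i + 60])

    def test_matches_loop_oracle_on_random_series(self, rng):
        n = 150
        sbp = rng.normal(120, 10, n)
        dbp = rng.normal(60, 6, n)
        vit = pd.DataFrame({"t_s": np.arange(n) * 5, "sbp": sbp, "dbp": dbp,
                            "map": dbp + (sbp - dbp) / 3, "hr": rng.normal(70, 8, n)})
        fm = extract_highrate_features(vit)
        oracle = naive_features(vit, neighbor_step=4, n_neighbors=15)
        for col, expect in oracle.items():
            got = fm.data[col].to_numpy()
            for i in range(n):
                if fm.valid[i]:
                    assert got[i] == pytest.approx(expect[i]), col

    def test_edge_masking_covers_the_300s_window(self, session):
        fm = extract_highrate_features(session.vitals)
        n = len(session.vitals)
        expect = np.ones(n, dtype=bool)
        expect[:60] = expect[-60:] = False
        assert (fm.valid == expect).all()
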