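"""Scale tables: filters, aggregation, window coverage, standardization,
and response conservation."""

import numpy as np
import pandas as pd
import pytest

from foragedive.aggregate import (EmptyTableError, attach_context,
                                  build_bout_table, build_dive_table,
                                  build_night_table, build_window_table,
                                  destandardize, standardize)
from foragedive.synthetic import DIVE_PREDICTORS


def make_dives(n=12, individual="A", bout=1, start0=0.0, cycle=200.0,
               deep=True, count=2, night=0):
    """A uniform block of synthetic analysis-ready dive rows."""
    rows = []
    for i in range(n):
        start = start0 + i * cycle
        rows.append({
            "individual_id": individual, "bout_id": bout, "night": night,
            "start_s": start, "end_s": start + 120.0,
            "dive_duration": 120.0, "post_dive_interval": cycle - 120.0,
            "surface_duration": cycle - 120.0,
            "deep": deep, "degenerate": False, "included": True,
            "pca_count": count,
            "max_depth": 40.0 if deep else 10.0,
            "descent_rate": 1.0, "ascent_rate": 1.0, "bottom_duration": 60.0,
            "depth_variation_bottom": 2.0, "steps_descent": 1, "steps_ascent": 0,
            "steps_descending_bottom": 1, "steps_ascending_bottom": 1, "wiggles": 1,
        })
    return pd.DataFrame(rows)


class TestDiveTable:
    def test_shallow_and_excluded_dives_filtered(self):
        df = pd.concat([make_dives(8), make_dives(2, deep=False, start0=1e5)],
                       ignore_index=True)
        df.loc[0, "included"] = False
        table = build_dive_table(df)
        assert len(table.df) == 7

    def test_values_pass_through_verbatim(self):
        table = build_dive_table(make_dives(5))
        assert (table.df["descent_rate"] == 1.0).all()
        assert (table.df["pca_count"] == 2).all()

    def test_empty_result_names_filters(self):
        with pytest.raises(EmptyTableError, match="deep"):
            build_dive_table(make_dives(5, deep=False))


class TestBoutTable:
    def test_response_is_summed_and_predictors_averaged(self):
        df = make_dives(10)
        df.loc[df.index[:3], "pca_count"] = [2, 3, 0]
        table = build_bout_table(df)
        assert len(table.df) == 1
        row = table.df.iloc[0]
        assert row["pca_count"] == df["pca_count"].sum()
        assert row["n_dives"] == 10
        assert row["max_depth"] == 40.0
        assert row["pct_time_deep"] > 85.0

    def test_low_coverage_bout_dropped(self):
        df = make_dives(10)
        # intersperse shallow-dive time: halve coverage by doubling the span
        df.loc[df.index[-1], "end_s"] += 2000.0
        df.loc[df.index[-1], "dive_duration"] += 2000.0
        df.loc[df.index[-1], "deep"] = False  # long tail not deep
        with pytest.raises(EmptyTableError):
            build_bout_table(df)


class TestWindowTable:
    def test_fully_paved_windows_kept_and_conserved(self):
        # 37 dives x 200-s cycles: the bout spans past 7200 s, so four full
        # 30-min windows tile it, covering the first 36 dive starts
        df = make_dives(37, cycle=200.0)
        t30 = build_window_table(df, 1800)
        assert len(t30.df) == 4
        assert t30.df["pca_count"].sum() == 2 * 36
        assert (t30.df["pct_time_deep"] > 99.0).all()

    def test_sparse_window_excluded(self):
        # one 100-s deep cycle inside an 1800-s window: ~5.6 % coverage
        df = make_dives(1, cycle=1800.0)
        df["end_s"] = df["start_s"] + 80.0
        df["dive_duration"] = 80.0
        df["post_dive_interval"] = 20.0
        df.loc[len(df)] = df.iloc[0].to_dict() | {"start_s": 1800.0, "end_s": 3600.0,
                                                  "dive_duration": 1800.0}
        with pytest.raises(EmptyTableError):
            build_window_table(df.iloc[:1], 1800)

    def test_partial_trailing_window_dropped(self):
        df = make_dives(10, cycle=200.0)  # 2000 s bout: one 1800-s window
        t = build_window_table(df, 1800)
        assert len(t.df) == 1

    def test_nested_window_consistency(self):
        df = make_dives(37, cycle=200.0)
        t30 = build_window_table(df, 1800)
        t120 = build_window_table(df, 7200)
        assert t120.df["pca_count"].iloc[0] == t30.df["pca_count"].sum()


class TestNightTable:
    def test_complete_nights_counted(self):
        df = pd.concat([make_dives(6, night=0),
                        make_dives(6, night=1, start0=86400.0, bout=2)],
                       ignore_index=True)
        nights = {"A": [(0, 28800), (86400, 115200)]}
        t = build_night_table(df, nights, {"A": (0.0, 120000.0)})
        assert len(t.df) == 2
        assert t.df["pca_count"].tolist() == [12, 12]

    def test_incomplete_night_excluded(self):
        df = make_dives(6, night=0)
        nights = {"A": [(0, 28800)]}
        t_ok = build_night_table(df, nights, {"A": (0.0, 30000.0)})
        assert len(t_ok.df) == 1
        with pytest.raises(EmptyTableError):
            build_night_table(df, nights, {"A": (0.0, 20000.0)})  # logger stopped


class TestStandardize:
    def test_self_standardization_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        df = make_dives(50)
        for p in DIVE_PREDICTORS:
            df[p] = rng.normal(3.0, 2.0, len(df))
        df["max_depth"] = rng.normal(40.0, 5.0, len(df))
        table = standardize(build_dive_table(df))
        for p in table.predictors:
            assert abs(table.df[p].mean()) < 1e-9
            assert table.df[p].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_train_stats_preserve_shift_on_test(self):
        rng = np.random.default_rng(1)
        df = make_dives(50)
        for p in DIVE_PREDICTORS:
            df[p] = rng.normal(0.0, 1.0, len(df))
        df["max_depth"] = rng.normal(40.0, 5.0, len(df))
        train = standardize(build_dive_table(df))
        df2 = df.copy()
        df2["descent_rate"] += 5.0
        test = standardize(build_dive_table(df2), stats=train.stats)
        assert test.df["descent_rate"].mean() > 3.0

    def test_round_trip(self):
        rng = np.random.default_rng(2)
        df = make_dives(30)
        for p in DIVE_PREDICTORS:
            df[p] = rng.normal(3.0, 2.0, len(df))
        df["max_depth"] = rng.normal(40.0, 5.0, len(df))
        table = build_dive_table(df)
        back = destandardize(standardize(table))
        for p in table.predictors:
            assert np.allclose(back.df[p], table.df[p])

    def test_zero_variance_column_named(self):
        df = make_dives(30)
        with pytest.raises(ValueError, match="max_depth|descent_rate"):
            standardize(build_dive_table(df))


def test_attach_context_assigns_nights_and_surface_duration():
    df = make_dives(3, cycle=300.0)
    out = attach_context(df.drop(columns=["night", "surface_duration"]),
                         {"A": [(0, 200), (600, 2000)]})
    assert out["night"].tolist() == [0, -1, 1]
    assert (out["surface_duration"] == out["post_dive_interval"]).all()


def test_response_conservation_on_simulated_trip(small_trip):
    cfg, depth, accel, truth = small_trip
    from foragedive.bouts import allocate_bouts
    from foragedive.pca import assign_events_to_dives, detect_events
    from foragedive.segmentation import correct_surface_offset, segment_dives
    dives = segment_dives(correct_surface_offset(depth))
    from foragedive.features import add_features
    dives = add_features(dives, correct_surface_offset(depth))
    dives, _ = allocate_bouts(dives)
    dives, _ = assign_events_to_dives(detect_events(accel), dives)
    dives.insert(0, "individual_id", "ID001")
    dives = attach_context(dives, {"ID001": truth.night_windows})
    dive_t = build_dive_table(dives)
    bout_t = build_bout_table(dives)
    for _, row in bout_t.df.iterrows():
        sub = dive_t.df[(dive_t.df.bout_id == row.bout_id)]
        assert row["pca_count"] == sub["pca_count"].sum()
    try:
        w = build_window_table(dives, 1800)
        for _, row in w.df.iterrows():
            sub = dive_t.df[(dive_t.df.bout_id == row.bout_id)
                            & (dive_t.df.start_s >= row.start_s)
                            & (dive_t.df.start_s < row.end_s)]
            assert row["pca_count"] == sub["pca_count"].sum()
    except EmptyTableError:
        pass
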