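"""Screening statistics: stars, KD screen, compartments, cells, ddCt."""

import numpy as np
import pandas as pd
import pytest

from lncsig.screen import (
    DdctInput,
    compartment_profile,
    ddct,
    filter_droplets,
    group_t_test,
    kd_screen,
    label_cells,
    marker_differential,
    star_category,
)
from lncsig.synthetic import simulate_cells


class TestStarCategory:
    @pytest.mark.parametrize(
        "p,star",
        [
            (0.2, "ns"), (0.0500001, "ns"),
            (0.05, "*"), (0.03, "*"), (0.0100001, "*"),
            (0.01, "**"), (0.0010001, "**"),
            (0.001, "***"), (0.0001001, "***"),
            (0.0001, "****"), (1e-5, "****"),
        ],
    )
    def test_boundaries(self, p, star):
        assert star_category(p) == star

    def test_monotone_in_p(self):
        order = {"****": 4, "***": 3, "**": 2, "*": 1, "ns": 0}
        ps = np.sort(np.random.default_rng(0).uniform(0, 1, 200))
        stars = [order[star_category(p)] for p in ps]
        assert all(a >= b for a, b in zip(stars, stars[1:]))


class TestGroupTTest:
    def test_identical_groups_ns(self):
        p, star, direction = group_t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0 and star == "ns" and direction == 0

    def test_strong_shift_significant_with_direction(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, 10)
        b = rng.normal(5, 0.1, 10)
        p, star, direction = group_t_test(a, b)
        assert p <= 0.0001 and star == "****" and direction == 1

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            group_t_test([1.0], [1.0, 2.0])


class TestKdScreen:
    def test_halved_kd_detected_down(self):
        rng = np.random.default_rng(1)
        means = {f"ctl{i}": float(v) for i, v in enumerate(rng.normal(10, 0.3, 5))}
        means.update({f"kd{i}": float(v) for i, v in enumerate(rng.normal(5, 0.3, 5))})
        out = kd_screen(means, [f"ctl{i}" for i in range(5)],
                        {"KD_X": [f"kd{i}" for i in range(5)]})
        row = out.iloc[0]
        assert row["direction"] == -1 and row["p"] < 0.001 and not row["excluded"]

    def test_null_kd_mostly_ns(self):
        rng = np.random.default_rng(2)
        n_sig = 0
        for seed in range(40):
            vals = rng.normal(10, 1, 10)
            means = {f"s{i}": float(v) for i, v in enumerate(vals)}
            out = kd_screen(means, [f"s{i}" for i in range(5)],
                            {"kd": [f"s{i}" for i in range(5, 10)]})
            n_sig += int(out["p"].iloc[0] <= 0.05)
        assert n_sig <= 7  # ~5% expected; generous binomial bound

    def test_singleton_kd_flagged_excluded(self):
        means = {"c1": 1.0, "c2": 1.1, "k1": 0.2}
        out = kd_screen(means, ["c1", "c2"], {"solo": ["k1"]})
        assert bool(out["excluded"].iloc[0]) and np.isnan(out["p"].iloc[0])


class TestCompartmentProfile:
    def test_shares(self):
        shares, dominant = compartment_profile({"chromatin": 2, "nucleus": 0, "cytoplasm": 2})
        assert shares == {"chromatin": 0.5, "nucleus": 0.0, "cytoplasm": 0.5}

    def test_dominant(self):
        _, dominant = compartment_profile({"chromatin": 0, "nucleus": 0, "cytoplasm": 5})
        assert dominant == "cytoplasm"

    def test_random_vectors_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            shares, _ = compartment_profile(
                {f"f{i}": float(v) for i, v in enumerate(rng.uniform(0.01, 5, 3))}
            )
            assert sum(shares.values()) == pytest.approx(1.0)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            compartment_profile({"a": 0.0, "b": 0.0})


class TestCellLabeling:
    def test_threshold_boundary_inclusive(self):
        lab = label_cells(pd.Series([0.1, 0.099, 0.5, -1.0]))
        assert list(lab.positive) == [True, False, True, False]
        assert lab.n_positive == 2

    def test_all_zero_no_positives(self):
        assert label_cells(pd.Series([0.0] * 5)).n_positive == 0

    def test_droplet_filter(self):
        m = pd.DataFrame({"g1": [9999, 10000, 20000], "g2": [0, 0, 0]},
                         index=["c1", "c2", "c3"])
        kept = filter_droplets(m, 10000)
        assert list(kept.index) == ["c2", "c3"]


class TestMarkerDifferential:
    def test_planted_marker_recovered(self):
        raw, scaled, truth = simulate_cells(n_cells=400, n_genes=40, seed=5)
        labeling = label_cells(scaled["MARKER"], 0.1)
        table = marker_differential(raw.drop(columns=["MARKER"]), labeling)
        found_up = set(table.loc[(table["significant"]) & (table["direction"] > 0), "gene"])
        assert set(truth.marker_features) <= found_up

    def test_small_lfc_excluded_regardless_of_p(self):
        rng = np.random.default_rng(6)
        n = 400
        labels = pd.Series([True] * (n // 2) + [False] * (n // 2),
                           index=[f"c{i}" for i in range(n)])
        # tiny but consistent shift: |lfc| < 0.15 excludes the gene
        x = np.concatenate([rng.normal(10.0, 0.05, n // 2), rng.normal(10.5, 0.05, n // 2)])
        m = pd.DataFrame({"g": x}, index=labels.index)
        lab = label_cells(pd.Series(np.where(labels, 1.0, 0.0), index=labels.index), 0.5)
        table = marker_differential(m, lab, min_lfc=0.15)
        assert len(table) == 0

    def test_random_labels_control_false_positives(self):
        rng = np.random.default_rng(7)
        n_sig = 0
        n_total = 0
        for seed in range(20):
            raw, scaled, _ = simulate_cells(n_cells=150, n_genes=30,
                                            n_de_genes=0, seed=100 + seed)
            random_scaled = pd.Series(rng.normal(0, 1, len(raw)), index=raw.index)
            lab = label_cells(random_scaled, 0.0)
            table = marker_differential(raw.drop(columns=["MARKER"]), lab)
            n_sig += int(table["significant"].sum()) if len(table) else 0
            n_total += raw.shape[1] - 1
        assert n_sig / n_total <= 0.05

    def test_empty_class_rejected(self):
        m = pd.DataFrame({"g": [1.0, 2.0]}, index=["c1", "c2"])
        lab = label_cells(pd.Series([1.0, 1.0], index=m.index), 0.1)
        with pytest.raises(ValueError, match="empty"):
            marker_differential(m, lab)


class TestDdct:
    def test_calibrator_dct_gives_rq_one(self):
        inp = DdctInput({"a": [10.0], "b": [10.0]}, {"a": [5.0], "b": [5.0]}, ["a"])
        out = ddct(inp).set_index("sample")
        assert out.loc["b", "rq"] == pytest.approx(1.0)

    def test_ddct_minus_one_doubles(self):
        inp = DdctInput({"cal": [10.0], "s": [9.0]}, {"cal": [5.0], "s": [5.0]}, ["cal"])
        out = ddct(inp).set_index("sample")
        assert out.loc["s", "ddct"] == pytest.approx(-1.0)
        assert out.loc["s", "rq"] == pytest.approx(2.0)

    def test_triplicate_closed_form(self):
        # target (20,21,22) vs ref 15: dCt = 6; calibrator dCt = 4 -> ddCt 2, RQ 0.25
        inp = DdctInput(
            {"cal": [19.0], "s": [20.0, 21.0, 22.0]},
            {"cal": [15.0], "s": [15.0, 15.0, 15.0]},
            ["cal"],
        )
        out = ddct(inp).set_index("sample")
        assert out.loc["s", "dct"] == pytest.approx(6.0)
        assert out.loc["s", "ddct"] == pytest.approx(2.0)
        assert out.loc["s", "rq"] == pytest.approx(0.25)

    def test_global_ct_shift_invariance(self):
        base = DdctInput({"cal": [18.0], "s": [20.0]}, {"cal": [15.0], "s": [14.0]}, ["cal"])
        shifted = DdctInput({"cal": [21.0], "s": [23.0]}, {"cal": [18.0], "s": [17.0]}, ["cal"])
        pd.testing.assert_series_equal(ddct(base)["rq"], ddct(shifted)["rq"])

    def test_missing_reference_named(self):
        with pytest.raises(ValueError, match="sampleX"):
            DdctInput({"sampleX": [10.0]}, {}, ["sampleX"])
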