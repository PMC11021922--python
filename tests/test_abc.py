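"""Reference-table construction, model choice and POD validation on small
synthetic problems (the expensive desk-scale run lives in test_acceptance)."""

import numpy as np
import pandas as pd
import pytest

from refugia.inference import (
    ReferenceTable,
    SummaryStatVector,
    build_reference_table,
    flag_names,
    model_choice,
    rejection_posteriors,
    stat_names,
    validate_model_choice,
)
from refugia.inference.reference import PARAM_COLUMNS

TINY_SIZES = {"A": 3, "C": 4, "S": 5}


def gaussian_table(rng, centers, n_per=200, spread=1.0):
    """Hand-built table: first two stats informative, rest noise."""
    rows = []
    for sid, center in centers.items():
        stats = rng.normal(0, spread, size=(n_per, 39))
        stats[:, 0] += center[0]
        stats[:, 1] += center[1]
        for row in stats:
            d = {"scenario": sid}
            d.update({c: np.nan for c in PARAM_COLUMNS})
            d.update(dict(zip(stat_names(), row)))
            d.update({f: 0 for f in flag_names()})
            rows.append(d)
    return ReferenceTable(pd.DataFrame(rows))


def target(values=None):
    v = np.zeros(39)
    if values is not None:
        v[: len(values)] = values
    return SummaryStatVector(v, np.zeros(3, dtype=bool))


class TestBuildReferenceTable:
    @pytest.fixture(scope="class")
    def small_table(self):
        return build_reference_table(
            (1, 2, 3), n_per_scenario=100, region_sizes=TINY_SIZES, seed=7
        )

    def test_row_count(self, small_table):
        assert small_table.n_rows == 300
        counts = small_table.df["scenario"].value_counts()
        assert set(counts) == {100}

    def test_determinism(self, small_table):
        again = build_reference_table(
            (1, 2, 3), n_per_scenario=100, region_sizes=TINY_SIZES, seed=7
        )
        pd.testing.assert_frame_equal(small_table.df, again.df)

    def test_parameter_layout(self, small_table):
        df = small_table.df
        s1 = df[df["scenario"] == 1]
        s3 = df[df["scenario"] == 3]
        assert s1["param_ra"].isna().all()
        assert s3["param_ra"].notna().all()
        assert s1["param_t2"].notna().all()
        assert df[df["scenario"] == 2]["param_tc"].notna().all()

    def test_csv_roundtrip(self, small_table, tmp_path):
        path = tmp_path / "table.csv"
        small_table.to_csv(path)
        loaded = ReferenceTable.from_csv(path)
        np.testing.assert_allclose(loaded.stats, small_table.stats)
        np.testing.assert_allclose(loaded.mad, small_table.mad)

    def test_min_rows_enforced(self):
        with pytest.raises(ValueError, match="100"):
            build_reference_table((1, 2), n_per_scenario=50, seed=0)

    def test_degenerate_column_warns(self):
        rng = np.random.default_rng(0)
        rows = []
        for sid in (1, 2):
            for _ in range(20):
                d = {"scenario": sid}
                d.update(dict(zip(stat_names(), rng.normal(size=39))))
                rows.append(d)
        df = pd.DataFrame(rows)
        df[stat_names()[5]] = 1.0  # constant column
        with pytest.warns(UserWarning, match="MAD=0"):
            table = ReferenceTable(df)
        assert table.mad[5] == 1.0


class TestModelChoice:
    def test_separation_limit(self):
        rng = np.random.default_rng(0)
        table = gaussian_table(
            rng, {1: (50, 50), 2: (0, 0), 3: (-50, 50)}, spread=0.5
        )
        res = model_choice(target(), table, n_closest=60)
        assert res.posteriors[2] > 0.99
        assert res.best_scenario() == 2

    def test_symmetric_scenarios_near_uniform(self):
        rng = np.random.default_rng(1)
        table = gaussian_table(
            rng, {1: (0, 0), 2: (0, 0), 3: (0, 0)}, n_per=1000
        )
        res = model_choice(target(), table, n_closest=600)
        for p in res.posteriors.values():
            assert p == pytest.approx(1 / 3, abs=0.12)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(2)
        table = gaussian_table(rng, {1: (2, 0), 2: (0, 2), 3: (1, 1)})
        for seed in range(5):
            t = target(np.random.default_rng(seed).normal(size=2))
            res = model_choice(t, table, n_closest=60)
            assert sum(res.posteriors.values()) == pytest.approx(1.0, abs=1e-9)

    def test_n_closest_too_small(self):
        rng = np.random.default_rng(3)
        table = gaussian_table(rng, {1: (0, 0), 2: (1, 1)})
        with pytest.raises(ValueError, match="too small"):
            model_choice(target(), table, n_closest=15)

    def test_n_closest_too_large(self):
        rng = np.random.default_rng(3)
        table = gaussian_table(rng, {1: (0, 0), 2: (1, 1)})
        with pytest.raises(ValueError, match="exceeds"):
            model_choice(target(), table, n_closest=10**6)

    def test_single_class_falls_back_to_rejection(self):
        rng = np.random.default_rng(4)
        table = gaussian_table(
            rng, {1: (0, 0), 2: (500, 500), 3: (500, -500)}, spread=0.1
        )
        with pytest.warns(UserWarning, match="rejection"):
            res = model_choice(target(), table, n_closest=30)
        assert res.method == "rejection"
        assert res.posteriors[1] == 1.0

    def test_rejection_and_logistic_agree_when_separated(self):
        rng = np.random.default_rng(5)
        table = gaussian_table(
            rng, {1: (10, 0), 2: (0, 0), 3: (0, 10)}, n_per=500
        )
        res = model_choice(target(), table, n_closest=150)
        props, _, _ = rejection_posteriors(target(), table, 150)
        for sid in (1, 2, 3):
            assert abs(res.posteriors[sid] - props[sid]) < 0.15


class TestValidation:
    def test_identical_scenarios_chance_level(self, monkeypatch):
        # scenario labels carry no signal -> Type I around 2/3
        rng = np.random.default_rng(6)
        table = gaussian_table(
            rng, {1: (0, 0), 2: (0, 0), 3: (0, 0)}, n_per=300
        )
        from refugia.inference import validate as vmod

        calls = {"n": 0}

        def fake_simulate(scenario, params, sizes, model, priors, rng_):
            calls["n"] += 1
            raise RuntimeError("patched")

        # patch the POD simulation to draw from the same null distribution
        def fake_summary(aln, part):
            return target(np.random.default_rng(calls["n"]).normal(size=2))

        def fake_sim(scenario, params, sizes, model, priors, rng_):
            calls["n"] += 1

            class DS:
                alignment = None
                partition = None

            return DS()

        monkeypatch.setattr(vmod, "simulate_dataset", fake_sim)
        monkeypatch.setattr(vmod, "summary_vector", fake_summary)
        report = validate_model_choice(table, 30, n_closest=90, seed=1)
        assert report.confusion.to_numpy().sum() == 90
        for s in (1, 2, 3):
            assert 0 <= report.type_i[s] <= 1
            assert 0 <= report.type_ii[s] <= 1
            assert report.confusion.loc[s].sum() == 30
        assert np.mean([report.type_i[s] for s in (1, 2, 3)]) == pytest.approx(
            2 / 3, abs=0.2
        )

    def test_min_pods_enforced(self):
        rng = np.random.default_rng(7)
        table = gaussian_table(rng, {1: (0, 0), 2: (1, 1)})
        with pytest.raises(ValueError, match="10"):
            validate_model_choice(table, 5)

    def test_separable_scenarios_low_error(self):
        # end-to-end on real simulations with extreme N_e separation
        from refugia.scenarios import PriorSet

        table = build_reference_table(
            (1, 2, 3), n_per_scenario=150, region_sizes=TINY_SIZES, seed=11
        )
        report = validate_model_choice(
            table, 12, n_closest=45, region_sizes=TINY_SIZES, seed=12
        )
        assert report.confusion.to_numpy().sum() == 36
        for s in (1, 2, 3):
            assert report.confusion.loc[s].sum() == 12
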