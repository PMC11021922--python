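import numpy as np
import pytest

from refugia.popgen import pairwise_diff_stats
from refugia.scenarios import (
    AdmixSpec,
    MergeSpec,
    MutationModel,
    PriorSet,
    ResizeSpec,
    StrandedLineagesError,
    build_scenario,
    evolve_sequences,
    generations_to_years,
    initial_sizes,
    mutation_rate_per_generation,
    sample_parameters,
    simulate_dataset,
    simulate_genealogy,
)

MID_PARAMS = {
    "N_A": 2000.0,
    "N_C": 2000.0,
    "N_S": 2000.0,
    "N_ANC": 2000.0,
    "t1": 600.0,
    "t2": 50_000.0,
    "ta": 400.0,
    "tb": 800.0,
    "tc": 50_000.0,
    "ra": 0.5,
}


class TestPriors:
    def test_rate_conversion(self):
        assert mutation_rate_per_generation() == pytest.approx(6.512e-7)
        assert float(f"{mutation_rate_per_generation():.2g}") == 6.5e-7

    def test_generations_to_years(self):
        assert generations_to_years(100_000) == pytest.approx(880_000)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            PriorSet(deep_low=1000, shallow_high=1250)

    def test_sample_bounds_and_mean(self):
        rng = np.random.default_rng(0)
        priors = PriorSet()
        draws = np.array(
            [
                sample_parameters(1, priors, rng)["N_A"]
                for _ in range(100_000)
            ]
        )
        assert draws.min() >= 10
        assert draws.max() <= 100_000
        assert draws.mean() == pytest.approx(50_005, rel=0.01)

    def test_scenario2_time_ordering(self):
        rng = np.random.default_rng(1)
        for _ in range(2000):
            p = sample_parameters(2, None, rng)
            assert p["ta"] <= p["tb"]
            assert p["tc"] >= 1250

    def test_deep_time_lower_bound(self):
        rng = np.random.default_rng(2)
        t2 = [sample_parameters(1, None, rng)["t2"] for _ in range(5000)]
        assert min(t2) >= 1250


class TestBuildScenario:
    def test_scenario1_structure(self):
        sc = build_scenario(1)
        assert len(sc.events) == 3  # C->S then the double merge into ANC
        times = [e.time_param for e in sc.events]
        assert times.count("t2") == 2
        concrete = sc.instantiate(MID_PARAMS)
        assert concrete[-1][0] == 50_000.0

    def test_scenario3_has_admixture(self):
        sc = build_scenario(3)
        admix = [e for e in sc.events if isinstance(e, AdmixSpec)]
        assert len(admix) == 1
        assert admix[0].prob_param == "ra"
        assert admix[0].dest_a == "A"

    def test_scenario2_structure(self):
        sc = build_scenario(2)
        kinds = [type(e) for e in sc.events]
        assert kinds == [MergeSpec, MergeSpec, ResizeSpec]

    def test_unknown_id(self):
        with pytest.raises(ValueError):
            build_scenario(4)

    def test_initial_sizes(self):
        sizes = initial_sizes(MID_PARAMS)
        assert sizes == {"A": 2000.0, "C": 2000.0, "S": 2000.0, "ANC": 2000.0}


class TestSimulateGenealogy:
    def test_invariants(self):
        rng = np.random.default_rng(0)
        for sid in (1, 2, 3):
            sc = build_scenario(sid)
            g = simulate_genealogy(sc, MID_PARAMS, {"A": 4, "C": 5, "S": 6}, rng)
            n = g.n_tips
            assert n == 15
            assert len(g.time) == 2 * n - 1
            assert g.parent[g.root] == -1
            for v in range(2 * n - 2):
                assert g.time[g.parent[v]] > g.time[v] or (
                    g.time[g.parent[v]] == g.time[v] == 0.0
                )
            assert (g.time[:n] == 0).all()

    def test_pair_coalescence_mean(self):
        rng = np.random.default_rng(1)
        sc = build_scenario(1)
        params = dict(MID_PARAMS, N_S=1000.0, t1=0.0, t2=1e9, N_ANC=1000.0)
        # effectively one population of N=1000 holding both lineages
        times = [
            simulate_genealogy(sc, params, {"S": 2}, rng).tmrca
            for _ in range(20_000)
        ]
        assert np.mean(times) == pytest.approx(1000.0, rel=0.02)

    def test_cross_coalescence_respects_t2(self):
        rng = np.random.default_rng(2)
        sc = build_scenario(1)
        params = dict(MID_PARAMS, t2=100_000.0, N_A=1000.0, N_S=1000.0)
        for _ in range(20):
            g = simulate_genealogy(sc, params, {"A": 3, "S": 3}, rng)
            # the MRCA of any A tip and any S tip lies at or beyond t2
            above = [
                i for i in range(g.n_tips, 2 * g.n_tips - 1)
                if g.time[i] >= 100_000.0
            ]
            # walk up from tip 0 (an A tip) until an ancestor also covers S
            anc = set()
            v = 0
            while v != -1:
                anc.add(v)
                v = g.parent[v]
            v = g.n_tips - 1  # an S tip
            while v not in anc:
                v = g.parent[v]
            assert g.time[v] >= 100_000.0
            assert above  # at least the root

    def test_admixture_proportion(self):
        rng = np.random.default_rng(3)
        sc = build_scenario(3)
        params = dict(MID_PARAMS, ra=0.999, t2=1e5)
        # with ra ~ 1 the C lineages join A: the C/A cross-coalescences
        # should mostly happen before t2, C/S ones after
        n_pre_t2 = 0
        n_total = 0
        for _ in range(50):
            g = simulate_genealogy(sc, params, {"A": 2, "C": 2, "S": 2}, rng)
            for i in range(g.n_tips, 2 * g.n_tips - 1):
                n_total += 1
                if g.time[i] < params["t2"]:
                    n_pre_t2 += 1
        assert n_pre_t2 / n_total > 0.5

    def test_stranded_lineages_detected(self):
        rng = np.random.default_rng(4)
        sc = build_scenario(1)
        # remove the deep merges by putting samples in a pop with no event
        bad = MergeSpec("t1", "C", "S")
        from refugia.scenarios.events import DemographicScenario

        broken = DemographicScenario(9, (bad,), ("N_A", "N_C", "N_S", "N_ANC", "t1"))
        with pytest.raises(StrandedLineagesError):
            simulate_genealogy(broken, MID_PARAMS, {"A": 2, "S": 2}, rng)

    def test_too_few_samples(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            simulate_genealogy(build_scenario(1), MID_PARAMS, {"A": 1}, rng)

    def test_newick_export(self):
        rng = np.random.default_rng(6)
        g = simulate_genealogy(
            build_scenario(1), MID_PARAMS, {"A": 2, "C": 2, "S": 2}, rng
        )
        nwk = g.to_newick()
        assert nwk.endswith(";")
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 6


class TestEvolveSequences:
    def test_mu_zero_rejected(self):
        with pytest.raises(ValueError):
            MutationModel(mu=0)

    def test_tiny_mu_identical(self):
        rng = np.random.default_rng(0)
        g = simulate_genealogy(
            build_scenario(1), MID_PARAMS, {"A": 2, "C": 2, "S": 2}, rng
        )
        aln = evolve_sequences(g, MutationModel(mu=1e-300), rng)
        assert len(set(aln.sequences)) == 1

    def test_high_kappa_all_transitions(self):
        rng = np.random.default_rng(1)
        model = MutationModel(
            kappa=1e6, base_freqs=(0.25, 0.25, 0.25, 0.25),
            prop_invariant=0.0, gamma_shape=1e9, mu=5e-6, length=2000,
        )
        sc = build_scenario(1)
        params = dict(MID_PARAMS, N_S=500.0, t1=0.0, t2=1e9)
        ts = tv = 0
        for _ in range(20):
            g = simulate_genealogy(sc, params, {"S": 2}, rng)
            aln = evolve_sequences(g, model, rng)
            a, b = aln.matrix
            diff = a != b
            pair = {(0, 2), (2, 0), (1, 3), (3, 1)}
            ts += sum(
                (int(x), int(y)) in pair for x, y in zip(a[diff], b[diff])
            )
            tv += int(diff.sum()) - sum(
                (int(x), int(y)) in pair for x, y in zip(a[diff], b[diff])
            )
        assert ts > 0
        assert tv / max(ts + tv, 1) < 0.02

    def test_pairwise_divergence_matches_poisson_expectation(self):
        rng = np.random.default_rng(2)
        T = 2000.0
        model = MutationModel(length=20_000)
        sc = build_scenario(1)
        # two lineages forced to coalesce exactly-ish at t2 via tiny ANC
        params = dict(
            MID_PARAMS, t1=0.0, t2=T, N_A=1e12, N_S=1e12, N_ANC=1e-6
        )
        diffs = []
        for _ in range(60):
            g = simulate_genealogy(sc, params, {"A": 1, "S": 1}, rng)
            assert g.tmrca == pytest.approx(T, rel=1e-6)
            aln = evolve_sequences(g, model, rng)
            mean, _ = pairwise_diff_stats(aln)
            diffs.append(mean)
        expected = 2 * T * model.mu * model.length
        assert np.mean(diffs) == pytest.approx(expected, rel=0.05)


class TestSimulateDataset:
    def test_default_design_sizes(self):
        ds = simulate_dataset(1, MID_PARAMS, rng=0)
        assert ds.alignment.n == 202
        sizes = {
            r: sum(1 for x in ds.partition.region if x == r)
            for r in set(ds.partition.region)
        }
        assert sizes == {"Aleutians": 18, "Central": 87, "South": 97}

    def test_determinism(self):
        a = simulate_dataset(3, None, {"A": 3, "C": 4, "S": 5}, rng=42)
        b = simulate_dataset(3, None, {"A": 3, "C": 4, "S": 5}, rng=42)
        assert a.alignment.sequences == b.alignment.sequences
        assert a.params == b.params

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            simulate_dataset(1, MID_PARAMS, {"A": 0, "C": 2, "S": 2}, rng=0)


def test_single_population_pi_matches_theta():
    # one population of N=1000: E[pi] per site = 2 N mu
    rng = np.random.default_rng(9)
    sc = build_scenario(1)
    params = dict(MID_PARAMS, N_S=1000.0, t1=0.0, t2=1e9)
    model = MutationModel(length=5000, prop_invariant=0.0, gamma_shape=1e9)
    pis = []
    for _ in range(2000):
        g = simulate_genealogy(sc, params, {"S": 2}, rng)
        aln = evolve_sequences(g, model, rng)
        mean, _ = pairwise_diff_stats(aln)
        pis.append(mean / model.length)
    expected = 2 * 1000 * model.mu
    assert np.mean(pis) == pytest.approx(expected, rel=0.05)


def test_scenario1_fst_signature():
    # deep A split vs shallow C split: F_ST(A,S) should exceed F_ST(C,S)
    from refugia.inference import summary_vector

    rng = np.random.default_rng(10)
    params = dict(MID_PARAMS, t2=80_000.0, t1=200.0)
    fst_as, fst_cs = [], []
    for _ in range(40):
        ds = simulate_dataset(1, params, {"A": 6, "C": 6, "S": 6}, rng=rng)
        vec = summary_vector(ds.alignment, ds.partition)
        names = vec.names
        fst_as.append(vec.values[names.index("AS_hudson_fst")])
        fst_cs.append(vec.values[names.index("CS_hudson_fst")])
    assert np.mean(fst_as) > np.mean(fst_cs)
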