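"""Statistics on trajectories and endpoints."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from kcatevo.analysis import (
    CorrelationResult,
    adaptation_speed_test,
    correlate_log,
    detect_fitness_jumps,
    endpoint_correlation_matrix,
    epistasis_diagnostics,
    iterations_to_half_growth,
    pairwise_endpoint_fitness,
    reaction_molecular_weight,
    selection_pressure_correlates,
    wilcoxon_rank_sum,
)
from kcatevo.evolution import (
    EvolutionConfig,
    MutationEvent,
    Trajectory,
    build_constrained_set,
    greedy_adaptation,
    initial_kcats,
    run_evolution,
)
from kcatevo.gpr import parse_gpr
from kcatevo.moment import KcatVector, solve_moment


def _kv(values):
    return KcatVector(dict(values), {r: "unconstrained" for r in values})


class TestCorrelateLog:
    def test_identity_gives_r_one(self):
        x = {f"r{i}": float(v) for i, v in enumerate([0.1, 1, 10, 100])}
        res = correlate_log(x, dict(x))
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_matches_longhand_formula(self, rng):
        """R, t and p agree with a from-scratch computation to 1e-12."""
        for _ in range(20):
            n = int(rng.integers(5, 40))
            x = {f"r{i}": float(10 ** rng.normal(0, 1)) for i in range(n)}
            y = {f"r{i}": float(10 ** rng.normal(0, 1)) for i in range(n)}
            res = correlate_log(x, y)
            a = np.log10([x[k] for k in sorted(x)])
            b = np.log10([y[k] for k in sorted(y)])
            am, bm = a - a.mean(), b - b.mean()
            r = float((am * bm).sum() / math.sqrt((am**2).sum() * (bm**2).sum()))
            t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
            from scipy.stats import t as tdist

            p = 2 * float(tdist.sf(abs(t), n - 2))
            assert res.r == pytest.approx(r, abs=1e-12)
            assert res.t == pytest.approx(t, abs=1e-9)
            assert res.p == pytest.approx(p, abs=1e-12)
            assert res.t == pytest.approx(
                res.r * math.sqrt(res.n - 2) / math.sqrt(1 - res.r**2), abs=1e-9
            )

    def test_permuted_values_uncorrelated(self, rng):
        x = {f"r{i}": float(10 ** rng.normal(0, 1)) for i in range(100)}
        vals = list(x.values())
        rng.shuffle(vals)
        y = dict(zip(x.keys(), vals))
        res = correlate_log(x, y)
        assert abs(res.r) < 0.3

    def test_too_few_or_constant_inputs_error(self):
        with pytest.raises(ValueError):
            correlate_log({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
        const = {f"r{i}": 1.0 for i in range(5)}
        varying = {f"r{i}": float(i + 1) for i in range(5)}
        with pytest.raises(ValueError, match="variance"):
            correlate_log(const, varying)

    def test_scope_filter(self):
        x = {"a": 1.0, "b": 10.0, "c": 100.0, "d": 5.0}
        y = {"a": 1.0, "b": 10.0, "c": 100.0, "d": 1e6}
        res = correlate_log(x, y, scope={"a", "b", "c"})
        assert res.n == 3 and res.r == pytest.approx(1.0)


class TestEndpointCorrelationMatrix:
    def test_identical_replicates(self):
        kv = _kv({"a": 1.0, "b": 10.0, "c": 100.0})
        R = endpoint_correlation_matrix([kv, kv.copy(), kv.copy()])
        assert np.allclose(R, 1.0)

    def test_initial_constant_vector_errors(self):
        kv = _kv({"a": 1.0, "b": 10.0, "c": 100.0})
        const = _kv({"a": 1e-3, "b": 1e-3, "c": 1e-3})
        with pytest.raises(ValueError):
            endpoint_correlation_matrix([kv, const])


class TestWilcoxonRankSum:
    def test_identical_groups_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_separated_groups_exact_enumeration(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)  # 2 of the 20 rank assignments

    @pytest.mark.parametrize("n,m", [(3, 3), (4, 5), (6, 6), (8, 8)])
    def test_exact_matches_brute_force(self, n, m, rng):
        """Enumeration-based p equals an independent brute-force count."""
        from scipy.stats import rankdata

        x = list(rng.normal(size=n).round(1))  # rounding forces some ties
        y = list(rng.normal(size=m).round(1))
        w_obs, p = wilcoxon_rank_sum(x, y)
        ranks = rankdata(x + y)
        expected = n * (n + m + 1) / 2
        d = abs(w_obs - expected)
        hits = sum(
            1
            for idx in itertools.combinations(range(n + m), n)
            if abs(float(ranks[list(idx)].sum()) - expected) >= d - 1e-12
        )
        assert p == pytest.approx(hits / math.comb(n + m, n))

    def test_large_samples_use_normal_approximation(self, rng):
        x = list(rng.normal(0, 1, size=30))
        y = list(rng.normal(1, 1, size=30))
        _, p = wilcoxon_rank_sum(x, y)
        from scipy.stats import mannwhitneyu

        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(float(ref))


def _toy_trajectory(events, mu_end, initial=None):
    initial = initial or _kv({"R1": 1e-3})
    return Trajectory(events=events, endpoint=initial.copy(), mu_end=mu_end,
                      initial=initial)


def _event(i, rid, mu_before, mu_after, fixed=True):
    return MutationEvent(iteration=i, reaction_id=rid, alpha=1.5,
                         direction="increase", kcat_before=1e-3, kcat_after=1.5e-3,
                         mu_before=mu_before, mu_after=mu_after,
                         s=1 - mu_before / mu_after if mu_after else 0.0,
                         pi=0.1, fixed=fixed)


class TestEpistasisDiagnostics:
    def test_empty_trajectory_empty_table(self):
        df = epistasis_diagnostics(_toy_trajectory([], 1e-3))
        assert len(df) == 0
        assert set(df.columns) >= {"iteration", "reaction_id", "s", "mu_before"}

    def test_records_and_counts(self):
        events = [_event(0, "R1", 0.1, 0.2), _event(1, "R2", 0.2, 0.25),
                  _event(2, "R1", 0.25, 0.3), _event(3, "R3", 0.3, 0.3, fixed=False)]
        df = epistasis_diagnostics(_toy_trajectory(events, 0.3))
        assert len(df) == 3  # fixed only
        assert df.loc[df.reaction_id == "R1", "n_fixed_reaction"].tolist() == [2, 2]

    def test_greedy_run_shows_diminishing_returns(self, dre):
        """s of the most-mutated reaction falls as background growth rises."""
        from scipy.stats import spearmanr

        model, spec, flags = dre
        traj = greedy_adaptation(model, initial_kcats(model, flags))
        df = epistasis_diagnostics(traj)
        top = df["reaction_id"].value_counts().index[0]
        sub = df[df.reaction_id == top]
        rho = spearmanr(sub["mu_before"], sub["s"]).statistic
        assert rho < -0.9


class TestDetectFitnessJumps:
    def test_uniform_gains_no_jumps(self, linear5):
        events = [_event(i, "R1", 0.1 + 0.01 * i, 0.11 + 0.01 * i) for i in range(10)]
        df = detect_fitness_jumps(_toy_trajectory(events, 0.2), linear5)
        assert df.empty

    def test_infinite_threshold_empty(self, linear5):
        events = [_event(0, "R1", 0.1, 0.2), _event(1, "R2", 0.2, 5.0)]
        df = detect_fitness_jumps(_toy_trajectory(events, 5.0), linear5,
                                  threshold_factor=math.inf)
        assert df.empty

    def test_multifunctional_gene_ranks_first(self):
        """Releasing a shared-enzyme plateau yields the largest gains."""
        from kcatevo.fixtures import FixtureSpec, make_linear_pathway
        from kcatevo.model import MetabolicModel

        spec = FixtureSpec(n_reactions=4, gene_mws=[5e4, 8e4, 8e4, 2e4],
                           biomass_coefficients={1: 3e3, 4: 1.0},
                           constrained=frozenset({1}))
        model = make_linear_pathway(spec)
        model.reaction("R3").gpr = parse_gpr("g2")
        model.gene_weights.pop("g3")
        model = MetabolicModel(id="mf", metabolites=model.metabolites,
                               reactions=model.reactions,
                               gene_weights=model.gene_weights,
                               biomass_reaction_id="BIOMASS",
                               declared_genes=frozenset(model.gene_weights))
        model.validate()
        flags = build_constrained_set(model)
        kcats = initial_kcats(model, flags)
        kcats.values["R2"] = 0.1  # one active site has already drifted up
        traj = greedy_adaptation(model, kcats)
        ranking = detect_fitness_jumps(traj, model, threshold_factor=10.0)
        assert not ranking.empty
        assert ranking.iloc[0]["gene"] == "g2"


class TestAdaptationSpeed:
    def test_half_crossing_index(self):
        events = [_event(0, "R1", 0.1, 0.2), _event(5, "R1", 0.2, 0.6),
                  _event(9, "R1", 0.6, 1.0)]
        traj = _toy_trajectory(events, 1.0)
        assert iterations_to_half_growth(traj) == 5

    def test_multifunctional_pathway_slows_adaptation(self):
        """Splitting a shared gene into two independent genes speeds the walk."""
        from kcatevo.fixtures import FixtureSpec, make_linear_pathway
        from kcatevo.model import MetabolicModel

        def build(shared):
            spec = FixtureSpec(n_reactions=3, gene_mws=[5e4, 8e4, 8e4],
                               biomass_coefficients={1: 3e3, 3: 1.0},
                               constrained=frozenset({1}))
            m = make_linear_pathway(spec)
            if shared:
                m.reaction("R3").gpr = parse_gpr("g2")
                m.gene_weights.pop("g3")
                m = MetabolicModel(id="mf", metabolites=m.metabolites,
                                   reactions=m.reactions,
                                   gene_weights=m.gene_weights,
                                   biomass_reaction_id="BIOMASS",
                                   declared_genes=frozenset(m.gene_weights))
                m.validate()
            return m

        mm, ctrl = build(True), build(False)
        fl_mm, fl_ctrl = build_constrained_set(mm), build_constrained_set(ctrl)
        runs_mm, runs_ctrl = [], []
        # a small population makes drift across the neutral plateau visible
        for seed in (1, 2, 3):
            cfg = EvolutionConfig(n_iterations=20_000, rng_seed=seed, N_e=100.0,
                                  record_all_proposals=False)
            runs_mm.append(run_evolution(mm, cfg, flags=fl_mm))
            runs_ctrl.append(run_evolution(ctrl, cfg, flags=fl_ctrl))
        half_mm = [iterations_to_half_growth(t) for t in runs_mm]
        half_ctrl = [iterations_to_half_growth(t) for t in runs_ctrl]
        assert np.mean(half_mm) > np.mean(half_ctrl)  # one-sided check
        stat, p = adaptation_speed_test(runs_mm, runs_ctrl)
        assert 0 < p <= 1


class TestReactionMolecularWeight:
    def test_or_picks_lightest_isozyme(self):
        gpr = parse_gpr("gA or gB")
        assert reaction_molecular_weight(gpr, {"gA": 3e4, "gB": 5e4}) == 3e4

    @pytest.mark.parametrize("mode,expected", [("max", 3e4), ("min", 8e4), ("sum_mw", 8e4)])
    def test_and_follows_capacity_semantics(self, mode, expected):
        gpr = parse_gpr("gA and gB")
        assert reaction_molecular_weight(gpr, {"gA": 3e4, "gB": 5e4}, mode) == expected


class TestSelectionPressureCorrelates:
    def test_flux_and_mw_correlates_positive_on_standard_fixture(self, standard):
        model, spec, flags = standard
        cfg = EvolutionConfig(n_iterations=6000, rng_seed=9, record_all_proposals=False)
        traj = run_evolution(model, cfg, flags=flags)
        r_flux, r_mw = selection_pressure_correlates(traj.endpoint, model, [None])
        assert r_flux.r > 0
        assert isinstance(r_mw, CorrelationResult)

    def test_constant_endpoint_errors(self, standard):
        model, spec, flags = standard
        kv = initial_kcats(model, flags)
        with pytest.raises(ValueError):
            selection_pressure_correlates(kv, model, [None])


class TestPairwiseEndpointFitness:
    def test_identical_endpoints_equal_growth(self, trajectory_toy):
        model, spec, flags = trajectory_toy
        kv = initial_kcats(model, flags)
        kv.values.update({"R2": 0.5, "R3": 0.1})
        df = pairwise_endpoint_fitness(model, [kv, kv.copy()])
        row = df.iloc[0]
        assert row["mu_mean_vector"] == pytest.approx(row["mu_end_i"], rel=1e-9)
        assert row["intermediate"]

    def test_table_consistent_with_direct_solves(self, isozyme):
        rids = isozyme.enzymatic_reaction_ids()
        a = _kv({r: 1.0 for r in rids})
        b = _kv({r: 1.0 for r in rids})
        a.values["R1a"], a.values["R1b"] = 10.0, 0.1   # divergent isozymes
        b.values["R1a"], b.values["R1b"] = 0.1, 10.0
        df = pairwise_endpoint_fitness(isozyme, [a, b])
        row = df.iloc[0]
        for kv, col in ((a, "mu_end_i"), (b, "mu_end_j")):
            assert row[col] == pytest.approx(
                solve_moment(isozyme, kv).growth_rate, rel=1e-9
            )
        merged = _kv({r: math.sqrt(a.values[r] * b.values[r]) for r in rids})
        assert row["mu_mean_vector"] == pytest.approx(
            solve_moment(isozyme, merged).growth_rate, rel=1e-9
        )

    def test_replicate_runs_show_no_fitness_valleys(self, trajectory_toy):
        model, spec, flags = trajectory_toy
        endpoints = []
        for seed in (21, 22, 23):
            cfg = EvolutionConfig(n_iterations=2500, rng_seed=seed,
                                  record_all_proposals=False)
            endpoints.append(run_evolution(model, cfg, flags=flags).endpoint)
        df = pairwise_endpoint_fitness(model, endpoints)
        assert df["intermediate"].all()
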