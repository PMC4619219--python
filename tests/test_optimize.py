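import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gen3d import synthetic
from gen3d.optimize import (
    Ensemble,
    OptimizerConfig,
    adaptation_move,
    adaptation_run,
    build_model,
    ga_crossover,
    ga_mutate,
    ga_run,
    ga_select,
    sa_accept,
    sa_run,
    select_final,
)
from gen3d.scoring import Scorer, Structure3D, evaluate

from oracles import random_instance


def make_scorer(freq):
    return Scorer(np.asarray(freq))


def two_locus_contact(d2):
    coords = np.array([[0.0, 0, 0], [math.sqrt(d2), 0, 0]])
    freq = np.array([[0, 1], [1, 0]])
    return Structure3D(coords), make_scorer(freq)


class TestAdaptationMove:
    def test_no_worsening_contract(self, rng):
        # structure already at its best reachable score: nothing is accepted
        s, scorer = two_locus_contact(1.0)  # contact + bond both satisfied
        for _ in range(20):
            out, accepted = adaptation_move(s, scorer, 1, trials=1, rng=rng)
            assert not accepted
            assert np.array_equal(out.coords, s.coords)

    def test_far_contact_closed_with_high_probability(self):
        accepted_count = 0
        for seed in range(100):
            s, scorer = two_locus_contact(10.0)
            out, accepted = adaptation_move(
                s, scorer, 1, trials=64, rng=np.random.default_rng(seed)
            )
            if accepted:
                accepted_count += 1
                d2 = float(((out.coords[0] - out.coords[1]) ** 2).sum())
                assert d2 <= 7.0
        assert accepted_count > 90

    def test_last_locus_only_moves_suffix_of_one(self):
        s, scorer = two_locus_contact(10.0)
        out, accepted = adaptation_move(
            s, scorer, 1, trials=64, rng=np.random.default_rng(0)
        )
        assert accepted
        assert np.array_equal(out.coords[0], s.coords[0])
        assert not np.array_equal(out.coords[1], s.coords[1])

    def test_suffix_translation_moves_all_downstream(self, rng):
        truth = synthetic.generate(12, seed=3)
        scorer = make_scorer(truth.matrix.freq)
        s = Structure3D(rng.normal(size=(12, 3)))
        for _ in range(50):
            out, accepted = adaptation_move(s, scorer, 4, trials=10, rng=rng)
            if accepted:
                delta = out.coords - s.coords
                assert np.allclose(delta[:4], 0)
                # one shared translation applied to loci 4..n-1
                assert np.allclose(delta[4:], delta[4], atol=1e-12)
                break
        else:
            pytest.skip("no accepted move in 50 attempts")

    def test_score_never_decreases(self, rng):
        coords, freq = random_instance(rng, n_max=15, n_min=8)
        scorer = make_scorer(freq)
        s = Structure3D(coords)
        before = scorer.total(s)
        for i in range(len(s)):
            s, _ = adaptation_move(s, scorer, i, trials=5, rng=rng)
        assert scorer.total(s) >= before

    def test_index_out_of_range(self, rng):
        s, scorer = two_locus_contact(1.0)
        with pytest.raises(ValueError):
            adaptation_move(s, scorer, 2, rng=rng)


class TestAdaptationRun:
    def test_perfect_structure_yields_singleton_ensemble(self):
        truth = synthetic.generate(15, seed=2)
        # the truth scores CS=NS=IF=100; only MS cap below 100 and bonds of
        # 1.5 um are inside the restraints, so no strict improvement exists
        scorer = make_scorer(truth.matrix.freq)
        cfg = OptimizerConfig(adapt_iters=30, seed=1)
        ens = adaptation_run(truth.truth, scorer, cfg)
        assert len(ens) == 1
        assert np.array_equal(ens.members[0][0].coords, truth.truth.coords)

    def test_monotone_best_history(self, tiny_cfg):
        truth = synthetic.generate(20, seed=4)
        scorer = make_scorer(truth.matrix.freq)
        rng = np.random.default_rng(0)
        s0 = Structure3D(rng.normal(size=(20, 3)))
        ens = adaptation_run(s0, scorer, tiny_cfg, rng)
        hist = ens.best_history
        assert len(hist) == tiny_cfg.adapt_iters + 1
        assert all(b >= a for a, b in zip(hist, hist[1:]))
        assert ens.best_score >= hist[0]

    def test_deterministic(self, tiny_cfg):
        truth = synthetic.generate(15, seed=6)
        scorer = make_scorer(truth.matrix.freq)
        s0 = Structure3D(np.random.default_rng(1).normal(size=(15, 3)))
        e1 = adaptation_run(s0, scorer, tiny_cfg, np.random.default_rng(42))
        e2 = adaptation_run(s0, scorer, tiny_cfg, np.random.default_rng(42))
        assert len(e1) == len(e2)
        for (sa, ra), (sb, rb) in zip(e1.members, e2.members):
            assert np.array_equal(sa.coords, sb.coords)
            assert ra.total == rb.total

    def test_ensemble_capped(self):
        truth = synthetic.generate(20, seed=8)
        scorer = make_scorer(truth.matrix.freq)
        cfg = OptimizerConfig(adapt_iters=200, ensemble_max=5, seed=3)
        s0 = Structure3D(np.random.default_rng(2).normal(size=(20, 3)))
        ens = adaptation_run(s0, scorer, cfg, np.random.default_rng(3))
        assert 1 <= len(ens) <= 5


class TestSAAccept:
    def test_equal_scores_accepted(self, rng):
        assert sa_accept(80.0, 80.0, 1.0, rng)

    def test_better_always_accepted(self, rng):
        assert sa_accept(50.0, 60.0, 1e-6, rng)

    def test_boltzmann_frequency(self):
        rng = np.random.default_rng(123)
        draws = 100_000
        hits = sum(sa_accept(80.0, 70.0, 10.0, rng) for _ in range(draws))
        assert hits / draws == pytest.approx(math.exp(-1), abs=0.01)

    def test_vanishing_temperature_rejects(self):
        rng = np.random.default_rng(5)
        hits = sum(sa_accept(80.0, 70.0, 1e-9, rng) for _ in range(1000))
        assert hits == 0

    def test_nonpositive_temperature_error(self, rng):
        with pytest.raises(ValueError):
            sa_accept(80.0, 70.0, 0.0, rng)


class TestSARun:
    def _ensemble(self, scorer, n, seed, k=3):
        rng = np.random.default_rng(seed)
        members = []
        for _ in range(k):
            s = Structure3D(rng.normal(size=(n, 3)))
            members.append((s, scorer.report(s)))
        return Ensemble(members=members)

    def test_zero_iterations_unchanged(self, rng):
        truth = synthetic.generate(12, seed=9)
        scorer = make_scorer(truth.matrix.freq)
        ens = self._ensemble(scorer, 12, 0)
        cfg = OptimizerConfig(adapt_iters=0, sa_iters=0, seed=1)
        out = sa_run(ens, scorer, cfg, rng)
        assert len(out) == len(ens)
        for (sa, _), (sb, _) in zip(ens.members, out.members):
            assert np.array_equal(sa.coords, sb.coords)

    def test_best_ever_retention(self):
        truth = synthetic.generate(15, seed=10)
        scorer = make_scorer(truth.matrix.freq)
        ens = self._ensemble(scorer, 15, 1)
        cfg = OptimizerConfig(sa_iters=8, adapt_trials=5, seed=2)
        out = sa_run(ens, scorer, cfg, np.random.default_rng(2))
        for (_, r_in), (_, r_out) in zip(ens.members, out.members):
            assert r_out.total >= r_in.total

    def test_deterministic(self):
        truth = synthetic.generate(12, seed=11)
        scorer = make_scorer(truth.matrix.freq)
        ens = self._ensemble(scorer, 12, 4)
        cfg = OptimizerConfig(sa_iters=5, adapt_trials=4, seed=0)
        o1 = sa_run(ens, scorer, cfg, np.random.default_rng(7))
        o2 = sa_run(ens, scorer, cfg, np.random.default_rng(7))
        for (sa, _), (sb, _) in zip(o1.members, o2.members):
            assert np.array_equal(sa.coords, sb.coords)


class TestGASelect:
    def _ensemble_with_scores(self, scores):
        # wrap plain scores in minimal members; structure content irrelevant
        from gen3d.scoring import ScoreReport

        members = []
        for k, score in enumerate(scores):
            rep = ScoreReport(
                cs=score, ns=score, if_score=score, ms=score,
                total=score, labels=np.zeros((2, 2), dtype=np.int8),
            )
            members.append((Structure3D(np.full((2, 3), float(k))), rep))
        return Ensemble(members=members)

    def test_top_half(self):
        ens = self._ensemble_with_scores([90.0, 80.0, 70.0, 60.0])
        out = ga_select(ens, 0.5)
        assert [r.total for _, r in out.members] == [90.0, 80.0]

    def test_keep_all(self):
        ens = self._ensemble_with_scores([50.0, 60.0])
        out = ga_select(ens, 1.0)
        assert len(out) == 2

    def test_ties_prefer_earlier(self):
        ens = self._ensemble_with_scores([70.0, 70.0, 70.0, 60.0])
        out = ga_select(ens, 0.5)
        assert np.array_equal(out.members[0][0].coords, np.full((2, 3), 0.0))
        assert np.array_equal(out.members[1][0].coords, np.full((2, 3), 1.0))

    def test_matches_sort_and_slice_oracle(self, rng):
        scores = list(rng.uniform(0, 100, size=11))
        ens = self._ensemble_with_scores(scores)
        out = ga_select(ens, 0.4)
        want = sorted(scores, reverse=True)[: math.ceil(0.4 * 11)]
        assert sorted((r.total for _, r in out.members), reverse=True) == want

    def test_at_least_one_survivor(self):
        ens = self._ensemble_with_scores([42.0])
        assert len(ga_select(ens, 0.01)) == 1

    def test_invalid_frac(self):
        ens = self._ensemble_with_scores([1.0])
        with pytest.raises(ValueError):
            ga_select(ens, 0.0)


class TestGACrossover:
    def test_worked_example_point_2(self):
        # symbolic parents: row k of A is (k+1, 0, 0), of B is (-(k+1), 0, 0)
        a = Structure3D(np.array([[k + 1.0, 0, 0] for k in range(5)]))
        b = Structure3D(np.array([[-(k + 1.0), 0, 0] for k in range(5)]))
        c1, c2 = ga_crossover(a, b, 2)
        assert list(c1.coords[:, 0]) == [1, 2, -3, -4, -5]  # A1 A2 B3 B4 B5
        assert list(c2.coords[:, 0]) == [-1, -2, 3, 4, 5]  # B1 B2 A3 A4 A5

    def test_identical_parents_give_identical_children(self, rng):
        a = Structure3D(rng.normal(size=(6, 3)))
        c1, c2 = ga_crossover(a, a.copy(), 1)
        assert np.array_equal(c1.coords, a.coords)
        assert np.array_equal(c2.coords, a.coords)

    def test_children_partition_parent_coordinates(self, rng):
        a = Structure3D(rng.normal(size=(8, 3)))
        b = Structure3D(rng.normal(size=(8, 3)))
        point = 3
        c1, c2 = ga_crossover(a, b, point)
        assert np.array_equal(c1.coords[:point], a.coords[:point])
        assert np.array_equal(c1.coords[point:], b.coords[point:])
        assert np.array_equal(c2.coords[:point], b.coords[:point])
        assert np.array_equal(c2.coords[point:], a.coords[point:])

    @settings(max_examples=25, deadline=None)
    @given(
        st.integers(min_value=2, max_value=12),
        st.integers(min_value=0, max_value=2**32 - 1),
    )
    def test_partition_property(self, n, seed):
        rng = np.random.default_rng(seed)
        a = Structure3D(rng.normal(size=(n, 3)))
        b = Structure3D(rng.normal(size=(n, 3)))
        point = int(rng.integers(1, n))
        c1, c2 = ga_crossover(a, b, point)
        merged = np.sort(np.vstack([c1.coords, c2.coords]), axis=0)
        parents = np.sort(np.vstack([a.coords, b.coords]), axis=0)
        assert np.array_equal(merged, parents)

    def test_length_mismatch_error(self, rng):
        a = Structure3D(rng.normal(size=(5, 3)))
        b = Structure3D(rng.normal(size=(6, 3)))
        with pytest.raises(ValueError):
            ga_crossover(a, b, 2)

    def test_point_out_of_range(self, rng):
        a = Structure3D(rng.normal(size=(5, 3)))
        for bad in (0, 5, 7):
            with pytest.raises(ValueError):
                ga_crossover(a, a, bad)


class TestGAMutate:
    def test_zero_mutations_identity(self, rng):
        coords, freq = random_instance(rng, n_max=10)
        scorer = make_scorer(freq)
        s = Structure3D(coords)
        out = ga_mutate(s, scorer, 0, rng)
        assert np.array_equal(out.coords, s.coords)

    def test_score_non_decreasing(self, rng):
        coords, freq = random_instance(rng, n_max=15, n_min=8)
        scorer = make_scorer(freq)
        s = Structure3D(coords)
        before = scorer.total(s)
        out = ga_mutate(s, scorer, 500, rng)
        assert scorer.total(out) >= before

    def test_reaches_single_point_grid_optimum_on_toy(self):
        # 3-locus toy with the middle point misplaced; a dense grid over
        # single-point displacements bounds what one mutation can achieve
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [1.0, 1.0, 0]])
        freq = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        scorer = make_scorer(freq)

        grid_best = scorer.total(Structure3D(coords))
        ticks = np.linspace(-1, 1, 21)
        for k in range(3):
            for dx in ticks:
                for dy in ticks:
                    for dz in ticks:
                        v = np.array([dx, dy, dz])
                        if v @ v > 1.0:
                            continue  # mutations have length below 1 um
                        cand = coords.copy()
                        cand[k] += v
                        grid_best = max(grid_best, scorer.total(Structure3D(cand)))

        out = ga_mutate(Structure3D(coords), scorer, 10_000,
                        np.random.default_rng(0))
        assert scorer.total(out) >= grid_best - 1.0

    def test_deterministic(self, rng):
        coords, freq = random_instance(rng, n_max=10)
        scorer = make_scorer(freq)
        o1 = ga_mutate(Structure3D(coords), scorer, 200, np.random.default_rng(5))
        o2 = ga_mutate(Structure3D(coords), scorer, 200, np.random.default_rng(5))
        assert np.array_equal(o1.coords, o2.coords)

    def test_negative_count_error(self, rng):
        s, scorer = two_locus_contact(1.0)
        with pytest.raises(ValueError):
            ga_mutate(s, scorer, -1, rng)


class TestGARun:
    def test_singleton_degenerates_to_mutation(self, rng):
        truth = synthetic.generate(10, seed=12)
        scorer = make_scorer(truth.matrix.freq)
        s = Structure3D(rng.normal(size=(10, 3)))
        ens = Ensemble(members=[(s, scorer.report(s))])
        cfg = OptimizerConfig(ga_mutations=100, seed=0)
        out = ga_run(ens, scorer, cfg, np.random.default_rng(1))
        assert len(out) == 1
        assert out.members[0][1].total >= ens.members[0][1].total

    def test_best_score_monotone(self):
        truth = synthetic.generate(14, seed=13)
        scorer = make_scorer(truth.matrix.freq)
        rng = np.random.default_rng(3)
        members = []
        for _ in range(6):
            s = Structure3D(rng.normal(size=(14, 3)))
            members.append((s, scorer.report(s)))
        ens = Ensemble(members=members)
        cfg = OptimizerConfig(ga_mutations=150, ga_keep_frac=0.5, seed=0)
        out = ga_run(ens, scorer, cfg, np.random.default_rng(4))
        assert out.best_score >= ens.best_score

    def test_deterministic(self):
        truth = synthetic.generate(10, seed=14)
        scorer = make_scorer(truth.matrix.freq)
        rng = np.random.default_rng(9)
        members = [
            (Structure3D(rng.normal(size=(10, 3))), None) for _ in range(4)
        ]
        members = [(s, scorer.report(s)) for s, _ in members]
        ens = Ensemble(members=members)
        cfg = OptimizerConfig(ga_mutations=80, seed=0)
        o1 = ga_run(ens, scorer, cfg, np.random.default_rng(6))
        o2 = ga_run(ens, scorer, cfg, np.random.default_rng(6))
        for (sa, _), (sb, _) in zip(o1.members, o2.members):
            assert np.array_equal(sa.coords, sb.coords)


class TestSelectFinal:
    def test_picks_highest(self):
        helper = TestGASelect()
        ens = helper._ensemble_with_scores([77.5, 81.2])
        s, rep = select_final(ens)
        assert rep.total == 81.2

    def test_singleton(self):
        helper = TestGASelect()
        ens = helper._ensemble_with_scores([33.0])
        assert select_final(ens)[1].total == 33.0

    def test_matches_max_oracle(self, rng):
        helper = TestGASelect()
        scores = list(rng.uniform(0, 100, size=9))
        ens = helper._ensemble_with_scores(scores)
        assert select_final(ens)[1].total == max(scores)

    def test_empty_ensemble_error(self):
        with pytest.raises(ValueError):
            Ensemble(members=[])


class TestBuildModel:
    def test_pipeline_monotone_and_lengths(self, tiny_cfg):
        truth = synthetic.generate(18, seed=21)
        structure, report, ensemble = build_model(truth.matrix, tiny_cfg)
        assert len(structure) == 18
        hist = ensemble.best_history
        assert all(b >= a for a, b in zip(hist, hist[1:]))
        assert report.total >= hist[-1] - 1e-9
        for member, _ in ensemble.members:
            assert len(member) == 18

    def test_deterministic(self, tiny_cfg):
        truth = synthetic.generate(15, seed=22)
        s1, r1, _ = build_model(truth.matrix, tiny_cfg)
        s2, r2, _ = build_model(truth.matrix, tiny_cfg)
        assert np.array_equal(s1.coords, s2.coords)
        assert r1.to_dict() == r2.to_dict()

    def test_incremental_totals_agree_with_fresh_evaluation(self, tiny_cfg):
        truth = synthetic.generate(16, seed=23)
        structure, report, _ = build_model(truth.matrix, tiny_cfg)
        fresh = evaluate(structure, truth.matrix)
        assert report.total == pytest.approx(fresh.total, abs=1e-9)


class TestOptimizerConfig:
    def test_defaults_follow_protocol(self):
        cfg = OptimizerConfig()
        assert cfg.adapt_iters == 50_000
        assert cfg.adapt_trials == 10
        assert cfg.sa_iters == 50
        assert cfg.ga_mutations == 10_000

    @pytest.mark.parametrize("kwargs", [
        {"adapt_trials": 0},
        {"sa_T0": 0.0},
        {"sa_cooling": 1.0},
        {"ga_keep_frac": 1.5},
        {"ensemble_max": 0},
        {"adapt_iters": -1},
    ])
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            OptimizerConfig(**kwargs)
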