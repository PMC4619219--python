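"""Three-stage stochastic refinement: adaptation → SA → genetic algorithm.

* **Adaptation** — iterated local search: at a locus ``i``, try several
  random translations applied to loci ``i..n−1``, keep the best one only
  if it strictly improves the total score.  One iteration attempts a move
  at every locus in random order.  Improving iterations are snapshot into
  an ensemble.
* **Simulated annealing** — each ensemble member independently proposes a
  candidate via one adaptation pass whose moves are applied
  unconditionally; the candidate is accepted by the Boltzmann criterion
  ``exp(−(E − E_new)/T)`` under geometric cooling.  A best-ever archive
  per member guarantees final scores never fall below entry scores.
* **Genetic algorithm** — selection of the top-scoring fraction,
  single-point coordinate crossover between random disjoint pairs
  (children appended), then score-gated single-point mutations.

The best-scoring member of the final ensemble is the model.

All moves update pairwise squared distances incrementally: a suffix
translation only changes pairs crossing the cut, a point mutation only
pairs touching the moved locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .init import initial_structure, random_vector, random_vectors
from .scoring import Scorer, ScoreReport, Structure3D

__all__ = [
    "OptimizerConfig",
    "Ensemble",
    "adaptation_move",
    "adaptation_run",
    "sa_accept",
    "sa_run",
    "ga_select",
    "ga_crossover",
    "ga_mutate",
    "ga_run",
    "select_final",
    "build_model",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """All knobs of the three-stage optimizer.

    Defaults follow the published protocol (50,000 adaptation iterations
    of 10 trials per move, 50 SA rounds, 10,000 mutations); scale the
    iteration counts down for small synthetic instances.
    """

    adapt_iters: int = 50_000
    adapt_trials: int = 10
    sa_iters: int = 50
    sa_T0: float = 1.0
    sa_cooling: float = 0.95
    ga_keep_frac: float = 0.5
    ga_mutations: int = 10_000
    ensemble_max: int = 50
    seed: int = 0
    init_mode: str = "auto"

    def __post_init__(self) -> None:
        if self.adapt_iters < 0 or self.sa_iters < 0 or self.ga_mutations < 0:
            raise ValueError("iteration counts must be non-negative")
        if self.adapt_trials < 1:
            raise ValueError("adapt_trials must be at least 1")
        if self.ensemble_max < 1:
            raise ValueError("ensemble_max must be at least 1")
        if self.sa_T0 <= 0:
            raise ValueError("sa_T0 must be positive")
        if not 0.0 < self.sa_cooling < 1.0:
            raise ValueError("sa_cooling must be in (0, 1)")
        if not 0.0 < self.ga_keep_frac <= 1.0:
            raise ValueError("ga_keep_frac must be in (0, 1]")


@dataclass
class Ensemble:
    """A population of scored structures.

    ``best_history`` (when present) records the best running total score
    after each adaptation iteration, including the initial score.
    """

    members: list[tuple[Structure3D, ScoreReport]]
    best_history: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must be non-empty")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def scores(self) -> np.ndarray:
        return np.array([report.total for _, report in self.members])

    @property
    def best_score(self) -> float:
        return float(self.scores.max())


# ---------------------------------------------------------------------------
# Incremental move engine


class _State:
    """Mutable structure plus cached pair/bond squared distances and counts."""

    __slots__ = ("sc", "coords", "pd2", "bd2", "sat_c", "sat_n", "sat_if",
                 "sat_b", "total")

    def __init__(self, scorer: Scorer, coords: np.ndarray) -> None:
        self.sc = scorer
        self.coords = np.array(coords, dtype=float)
        scorer._check_len(self.coords)
        self.pd2 = scorer.pair_d2(self.coords)
        self.bd2 = scorer.bond_d2(self.coords)
        self.sat_c, self.sat_n, self.sat_if, self.sat_b = scorer.counts(
            self.pd2, self.bd2
        )
        self.total = scorer.total_from_counts(
            self.sat_c, self.sat_n, self.sat_if, self.sat_b
        )

    def copy(self) -> "_State":
        other = object.__new__(_State)
        other.sc = self.sc
        other.coords = self.coords.copy()
        other.pd2 = self.pd2.copy()
        other.bd2 = self.bd2.copy()
        other.sat_c = self.sat_c
        other.sat_n = self.sat_n
        other.sat_if = self.sat_if
        other.sat_b = self.sat_b
        other.total = self.total
        return other

    def structure(self) -> Structure3D:
        return Structure3D(self.coords.copy())

    def _totals_for(self, sat_c, sat_n, sat_if, sat_b) -> np.ndarray:
        """Vectorized weighted totals over candidate count vectors."""
        sc = self.sc
        w = sc.weights
        num = np.zeros(np.broadcast(sat_c, sat_b).shape, dtype=float)
        den = 0.0
        if sc.n_contact:
            num = num + w.w_cs * (np.asarray(sat_c) * 100.0 / sc.n_contact)
            den += w.w_cs
        if sc.n_noncontact:
            num = num + w.w_ns * (np.asarray(sat_n) * 100.0 / sc.n_noncontact)
            den += w.w_ns
        if sc.total_if:
            num = num + w.w_if * (np.asarray(sat_if) * 100.0 / sc.total_if)
            den += w.w_if
        if sc.n >= 2:
            num = num + w.w_ms * (np.asarray(sat_b) * 100.0 / sc.n)
            den += w.w_ms
        if den == 0:
            raise ValueError("all sub-scores not-applicable")
        return num / den

    def attempt_suffix(self, i: int, vectors: np.ndarray, force: bool = False) -> bool:
        """Try translating loci ``i..n−1`` by each candidate vector.

        Applies the best-scoring candidate when it strictly improves the
        total (or unconditionally with ``force``).  Returns whether a
        move was applied.
        """
        sc = self.sc
        t = sc.thresholds
        V = np.atleast_2d(vectors)
        n_trials = V.shape[0]
        idx = sc.suffix_pairs(i)

        contact_a = sc.contact[idx]
        f_a = sc.pair_freq[idx]
        d2_cur = self.pd2[idx]
        near_cur = d2_cur <= t.contact_d2
        cur_c = int(np.count_nonzero(near_cur & contact_a))
        cur_n = int(np.count_nonzero(~near_cur & ~contact_a))
        cur_if = float(f_a[near_cur & contact_a].sum())

        diff = self.coords[sc.ii[idx]] - self.coords[sc.jj[idx]]
        # suffix endpoint jj moves by +v, so the pair difference becomes diff − v
        nd = diff[:, None, :] - V[None, :, :]
        d2_new = np.einsum("atk,atk->at", nd, nd)
        near_new = d2_new <= t.contact_d2
        new_c = np.count_nonzero(near_new & contact_a[:, None], axis=0)
        new_n = np.count_nonzero(~near_new & ~contact_a[:, None], axis=0)
        new_if = (f_a[:, None] * (near_new & contact_a[:, None])).sum(axis=0)

        sat_c = self.sat_c - cur_c + new_c
        sat_n = self.sat_n - cur_n + new_n
        sat_if = self.sat_if - cur_if + new_if

        if i >= 1:
            b_cur = self.bd2[i - 1]
            cur_b = int(t.min_d2 <= b_cur <= t.max_d2)
            bdiff = self.coords[i - 1] - self.coords[i]
            nb = bdiff[None, :] - V
            b2_new = np.einsum("tk,tk->t", nb, nb)
            new_b = ((b2_new >= t.min_d2) & (b2_new <= t.max_d2)).astype(int)
            sat_b = self.sat_b - cur_b + new_b
        else:
            b2_new = None
            sat_b = np.full(n_trials, self.sat_b)

        totals = self._totals_for(sat_c, sat_n, sat_if, sat_b)
        best = int(np.argmax(totals))
        if not force and not (totals[best] > self.total):
            return False

        self.coords[i:] += V[best]
        self.pd2[idx] = d2_new[:, best]
        if b2_new is not None:
            self.bd2[i - 1] = b2_new[best]
        self.sat_c = int(sat_c[best])
        self.sat_n = int(sat_n[best])
        self.sat_if = float(sat_if[best])
        self.sat_b = int(sat_b[best])
        self.total = float(totals[best])
        return True

    def attempt_mutation(self, k: int, v: np.ndarray) -> bool:
        """Displace locus *k* alone by *v*; keep iff the total strictly improves."""
        sc = self.sc
        t = sc.thresholds
        idx, sign = sc.point_pairs(k)

        contact_a = sc.contact[idx]
        f_a = sc.pair_freq[idx]
        d2_cur = self.pd2[idx]
        near_cur = d2_cur <= t.contact_d2
        cur_c = int(np.count_nonzero(near_cur & contact_a))
        cur_n = int(np.count_nonzero(~near_cur & ~contact_a))
        cur_if = float(f_a[near_cur & contact_a].sum())

        diff = self.coords[sc.ii[idx]] - self.coords[sc.jj[idx]]
        nd = diff + sign[:, None] * v[None, :]
        d2_new = np.einsum("ak,ak->a", nd, nd)
        near_new = d2_new <= t.contact_d2
        new_c = int(np.count_nonzero(near_new & contact_a))
        new_n = int(np.count_nonzero(~near_new & ~contact_a))
        new_if = float(f_a[near_new & contact_a].sum())

        bonds: list[tuple[int, float]] = []
        cur_b_sat = 0
        new_b_sat = 0
        if k >= 1:  # bond (k−1, k): vector coords[k] − coords[k−1] gains +v
            old = self.bd2[k - 1]
            nbv = (self.coords[k] - self.coords[k - 1]) + v
            b2 = float(np.dot(nbv, nbv))
            cur_b_sat += int(t.min_d2 <= old <= t.max_d2)
            new_b_sat += int(t.min_d2 <= b2 <= t.max_d2)
            bonds.append((k - 1, b2))
        if k <= sc.n - 2:  # bond (k, k+1): vector coords[k+1] − coords[k] loses v
            old = self.bd2[k]
            nbv = (self.coords[k + 1] - self.coords[k]) - v
            b2 = float(np.dot(nbv, nbv))
            cur_b_sat += int(t.min_d2 <= old <= t.max_d2)
            new_b_sat += int(t.min_d2 <= b2 <= t.max_d2)
            bonds.append((k, b2))

        sat_c = self.sat_c - cur_c + new_c
        sat_n = self.sat_n - cur_n + new_n
        sat_if = self.sat_if - cur_if + new_if
        sat_b = self.sat_b - cur_b_sat + new_b_sat
        total = float(self._totals_for(sat_c, sat_n, sat_if, sat_b))
        if not (total > self.total):
            return False

        self.coords[k] += v
        self.pd2[idx] = d2_new
        for b, b2 in bonds:
            self.bd2[b] = b2
        self.sat_c, self.sat_n, self.sat_if, self.sat_b = sat_c, sat_n, sat_if, sat_b
        self.total = total
        return True

    def adaptation_pass(
        self, rng: np.random.Generator, trials: int, force: bool = False
    ) -> None:
        """One iteration: attempt a move at every locus in random order."""
        for i in rng.permutation(self.sc.n):
            self.attempt_suffix(int(i), random_vectors(rng, trials), force=force)


def _coords(s) -> np.ndarray:
    return s.coords if isinstance(s, Structure3D) else np.asarray(s, dtype=float)


# ---------------------------------------------------------------------------
# Adaptation


def adaptation_move(
    s,
    scorer: Scorer,
    i: int,
    trials: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[Structure3D, bool]:
    """Single adaptation move at locus *i* (translates loci ``i..n−1``).

    Generates *trials* candidate vectors, evaluates each, and applies the
    best only if it strictly improves the total score.
    """
    if not 0 <= i < scorer.n:
        raise ValueError(f"locus index {i} out of range for n={scorer.n}")
    if rng is None:
        rng = np.random.default_rng()
    state = _State(scorer, _coords(s))
    accepted = state.attempt_suffix(i, random_vectors(rng, trials))
    return state.structure(), accepted


def adaptation_run(
    s0,
    scorer: Scorer,
    cfg: OptimizerConfig,
    rng: np.random.Generator | None = None,
) -> Ensemble:
    """Run adaptation and collect an ensemble of improving snapshots.

    The starting structure is always a member, so the ensemble is
    non-empty even when no iteration improves.  The ensemble is capped at
    ``cfg.ensemble_max`` highest-scoring snapshots.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    state = _State(scorer, _coords(s0))
    members: list[tuple[Structure3D, ScoreReport]] = [
        (state.structure(), scorer.report(state.structure()))
    ]
    best_history = [state.total]
    for _ in range(cfg.adapt_iters):
        before = state.total
        state.adaptation_pass(rng, cfg.adapt_trials)
        if state.total > before:
            snap = state.structure()
            members.append((snap, scorer.report(snap)))
            if len(members) > cfg.ensemble_max:
                worst = min(
                    range(len(members)), key=lambda idx: members[idx][1].total
                )
                del members[worst]
        best_history.append(state.total)
    return Ensemble(members=members, best_history=best_history)


# ---------------------------------------------------------------------------
# Simulated annealing


def sa_accept(
    e_current: float, e_new: float, temperature: float, rng: np.random.Generator
) -> bool:
    """Boltzmann acceptance for a maximization problem.

    Always accepts when ``e_new ≥ e_current``; otherwise accepts iff
    ``exp(−(e_current − e_new)/T) > u`` for ``u`` uniform on [0, 1).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if e_new >= e_current:
        return True
    return math.exp(-(e_current - e_new) / temperature) > rng.random()


def sa_run(
    ensemble: Ensemble,
    scorer: Scorer,
    cfg: OptimizerConfig,
    rng: np.random.Generator | None = None,
) -> Ensemble:
    """Independent SA refinement of every ensemble member.

    Each round ``k`` (temperature ``T0·cooling^k``) proposes one
    adaptation pass with unconditional moves and resolves it with
    ``sa_accept``.  Each member's best-ever structure is returned, so
    final scores never fall below entry scores.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    currents = [_State(scorer, structure.coords) for structure, _ in ensemble.members]
    bests = [state.copy() for state in currents]
    for k in range(cfg.sa_iters):
        temperature = cfg.sa_T0 * cfg.sa_cooling**k
        for m, current in enumerate(currents):
            candidate = current.copy()
            candidate.adaptation_pass(rng, cfg.adapt_trials, force=True)
            if sa_accept(current.total, candidate.total, temperature, rng):
                currents[m] = candidate
                if candidate.total > bests[m].total:
                    bests[m] = candidate.copy()
    members = []
    for state in bests:
        snap = state.structure()
        members.append((snap, scorer.report(snap)))
    return Ensemble(members=members)


# ---------------------------------------------------------------------------
# Genetic algorithm


def ga_select(ensemble: Ensemble, keep_frac: float) -> Ensemble:
    """Keep the top ``ceil(keep_frac·|e|)`` members by total score.

    Ties break toward earlier index; original member order is preserved
    among survivors.
    """
    if not 0.0 < keep_frac <= 1.0:
        raise ValueError("keep_frac must be in (0, 1]")
    scores = ensemble.scores
    k = max(1, math.ceil(keep_frac * len(ensemble)))
    order = np.argsort(-scores, kind="stable")[:k]
    keep = np.sort(order)
    return Ensemble(members=[ensemble.members[i] for i in keep])


def ga_crossover(a, b, point: int) -> tuple[Structure3D, Structure3D]:
    """Single-point coordinate crossover.

    ``child1 = a[:point] + b[point:]`` and symmetrically for ``child2``.
    """
    ca, cb = _coords(a), _coords(b)
    if ca.shape != cb.shape:
        raise ValueError("parents must have the same number of loci")
    n = ca.shape[0]
    if not 1 <= point < n:
        raise ValueError(f"crossover point must be in [1, {n - 1}], got {point}")
    child1 = np.vstack([ca[:point], cb[point:]])
    child2 = np.vstack([cb[:point], ca[point:]])
    return Structure3D(child1), Structure3D(child2)


def ga_mutate(
    s,
    scorer: Scorer,
    n_mut: int,
    rng: np.random.Generator | None = None,
) -> Structure3D:
    """Apply *n_mut* score-gated single-point random displacements.

    Each mutation moves one random locus by a random vector and is kept
    only when the total score strictly increases, so the final score is
    never below the input score.
    """
    if n_mut < 0:
        raise ValueError("n_mut must be non-negative")
    if rng is None:
        rng = np.random.default_rng()
    state = _State(scorer, _coords(s))
    for _ in range(n_mut):
        k = int(rng.integers(scorer.n))
        state.attempt_mutation(k, random_vector(rng))
    return state.structure()


def ga_run(
    ensemble: Ensemble,
    scorer: Scorer,
    cfg: OptimizerConfig,
    rng: np.random.Generator | None = None,
) -> Ensemble:
    """Selection → crossover (children appended) → mutation."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    survivors = ga_select(ensemble, cfg.ga_keep_frac)
    members = list(survivors.members)
    n = scorer.n
    if len(members) >= 2 and n >= 2:
        perm = rng.permutation(len(members))
        for p in range(len(members) // 2):
            ia, ib = int(perm[2 * p]), int(perm[2 * p + 1])
            point = int(rng.integers(1, n))
            c1, c2 = ga_crossover(members[ia][0], members[ib][0], point)
            members.append((c1, scorer.report(c1)))
            members.append((c2, scorer.report(c2)))
    mutated = []
    for structure, _ in members:
        out = ga_mutate(structure, scorer, cfg.ga_mutations, rng)
        mutated.append((out, scorer.report(out)))
    return Ensemble(members=mutated)


# ---------------------------------------------------------------------------
# Pipeline


def select_final(ensemble: Ensemble) -> tuple[Structure3D, ScoreReport]:
    """The highest-scoring member (ties → lowest index)."""
    scores = ensemble.scores
    best = int(np.argmax(scores))
    return ensemble.members[best]


def build_model(
    matrix,
    cfg: OptimizerConfig | None = None,
    thresholds=None,
    weights=None,
) -> tuple[Structure3D, ScoreReport, Ensemble]:
    """Full pipeline: init → adaptation → SA → GA → best member.

    Deterministic under a fixed ``cfg.seed``: a single generator drives
    initialization and all three stages in sequence.
    """
    cfg = cfg or OptimizerConfig()
    scorer = Scorer(matrix, thresholds, weights)
    rng = np.random.default_rng(cfg.seed)
    s0 = initial_structure(scorer.n, rng, cfg.init_mode)
    ens = adaptation_run(s0, scorer, cfg, rng)
    history = ens.best_history
    ens = sa_run(ens, scorer, cfg, rng)
    ens = ga_run(ens, scorer, cfg, rng)
    ens.best_history = history
    structure, report = select_final(ens)
    return structure, report, ens
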