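"""Contact-satisfaction scoring of 3D chromosome models.

A model is scored against its contact matrix with four percentage
sub-scores:

* **CS** — fraction of contact pairs (``freq > 0``) whose squared
  inter-locus distance is at or below the contact threshold;
* **NS** — fraction of non-contact pairs (``freq == 0``) whose squared
  distance exceeds the threshold;
* **IF** — like CS but weighted by the interaction frequency of each pair;
* **MS** — fraction of regions whose chain-adjacent bond length lies within
  the minimum/maximum distance restraints (denominator is the region
  count, not the bond count).

The total score is the weighted average of the applicable sub-scores
(default weights 2, 2, 3, 1).  All thresholds compare *squared* distances;
no square roots are taken inside scoring loops.  Diagonal entries of the
matrix are never scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NOT_APPLICABLE",
    "is_applicable",
    "Structure3D",
    "ScoreThresholds",
    "ScoreWeights",
    "ScoreReport",
    "Scorer",
    "pair_satisfaction",
    "score_cs",
    "score_ns",
    "score_if",
    "score_ms",
    "score_total",
    "unsat_distance_summary",
    "evaluate",
]

#: Sentinel for sub-scores that cannot be computed (e.g. MS with a single
#: locus, or CS on a matrix with no contacts).  Not-applicable sub-scores
#: drop out of the weighted total; their weight is renormalized away.
NOT_APPLICABLE: float = math.nan

# Heat-map label codes.
LABEL_EXCLUDED = 0
LABEL_CONTACT_SAT = 1
LABEL_CONTACT_UNSAT = 2
LABEL_NONCONTACT_SAT = 3
LABEL_NONCONTACT_UNSAT = 4


def is_applicable(value: float) -> bool:
    """True when *value* is a real sub-score, False for NOT_APPLICABLE."""
    return not math.isnan(value)


@dataclass
class Structure3D:
    """An ordered chain of 3D loci, one point per retained matrix region.

    Coordinates are in micrometres.  Point ``k`` corresponds to retained
    region ``k`` of the paired contact matrix.
    """

    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError(f"coords must have shape (n, 3), got {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValueError("coords contain non-finite values")
        self.coords = c

    def __len__(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Structure3D":
        return Structure3D(self.coords.copy())


@dataclass(frozen=True)
class ScoreThresholds:
    """Squared-distance thresholds (μm²) used by the sub-scores."""

    contact_d2: float = 7.0
    max_d2: float = 20.25
    min_d2: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.min_d2 < self.contact_d2 < self.max_d2):
            raise ValueError(
                "thresholds must satisfy 0 < min_d2 < contact_d2 < max_d2, "
                f"got min={self.min_d2} contact={self.contact_d2} max={self.max_d2}"
            )


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the four sub-scores in the weighted-average total."""

    w_cs: float = 2.0
    w_ns: float = 2.0
    w_if: float = 3.0
    w_ms: float = 1.0

    def __post_init__(self) -> None:
        ws = (self.w_cs, self.w_ns, self.w_if, self.w_ms)
        if any(w < 0 for w in ws):
            raise ValueError("weights must be non-negative")
        if sum(ws) <= 0:
            raise ValueError("at least one weight must be positive")


@dataclass
class ScoreReport:
    """The four sub-scores, weighted total and per-pair satisfaction labels.

    ``labels`` is the symmetric n×n heat-map matrix over
    ``{0, 1, 2, 3, 4}``: 1 contact satisfied, 2 contact unsatisfied,
    3 non-contact satisfied, 4 non-contact unsatisfied, 0 diagonal /
    excluded.  Distances in the unsatisfied-pair summaries are plain
    (non-squared) micrometres.
    """

    cs: float
    ns: float
    if_score: float
    ms: float
    total: float
    labels: np.ndarray = field(repr=False)
    mean_unsat_contact_dist: float = NOT_APPLICABLE
    mean_unsat_noncontact_dist: float = NOT_APPLICABLE

    def to_dict(self) -> dict:
        """JSON-safe summary (labels omitted; NaN mapped to None)."""

        def clean(x: float):
            return None if math.isnan(x) else float(x)

        return {
            "cs": clean(self.cs),
            "ns": clean(self.ns),
            "if": clean(self.if_score),
            "ms": clean(self.ms),
            "total": clean(self.total),
            "mean_unsat_contact_dist": clean(self.mean_unsat_contact_dist),
            "mean_unsat_noncontact_dist": clean(self.mean_unsat_noncontact_dist),
        }


def _freq_array(matrix) -> np.ndarray:
    """Accept a ContactMatrix-like object (``.freq``) or a plain array."""
    freq = getattr(matrix, "freq", matrix)
    freq = np.asarray(freq)
    if freq.ndim != 2 or freq.shape[0] != freq.shape[1]:
        raise ValueError(f"contact matrix must be square, got shape {freq.shape}")
    return freq


def _coords_array(s) -> np.ndarray:
    return s.coords if isinstance(s, Structure3D) else np.asarray(s, dtype=float)


def pair_satisfaction(
    s, matrix, thresholds: ScoreThresholds | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Label every locus pair and return ``(labels, squared_distances)``.

    For each off-diagonal pair ``(i, j)``: contact pairs (``freq > 0``)
    get label 1 when ``d² ≤ contact_d2`` else 2; non-contact pairs get
    label 3 when ``d² > contact_d2`` else 4.  The diagonal is 0.
    """
    t = thresholds or ScoreThresholds()
    coords = _coords_array(s)
    freq = _freq_array(matrix)
    n = freq.shape[0]
    if coords.shape[0] != n:
        raise ValueError(
            f"structure has {coords.shape[0]} loci but matrix has {n} regions"
        )

    diff = coords[:, None, :] - coords[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)

    contact = freq > 0
    near = d2 <= t.contact_d2
    labels = np.where(
        contact,
        np.where(near, LABEL_CONTACT_SAT, LABEL_CONTACT_UNSAT),
        np.where(near, LABEL_NONCONTACT_UNSAT, LABEL_NONCONTACT_SAT),
    ).astype(np.int8)
    np.fill_diagonal(labels, LABEL_EXCLUDED)
    return labels, d2


def _upper(labels: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(labels.shape[0], k=1)
    return np.asarray(labels)[iu]


def score_cs(labels: np.ndarray) -> float:
    """Percentage of contact pairs satisfied: ``100 · #1 / (#1 + #2)``."""
    lab = _upper(labels)
    sat = int(np.count_nonzero(lab == LABEL_CONTACT_SAT))
    total = sat + int(np.count_nonzero(lab == LABEL_CONTACT_UNSAT))
    if total == 0:
        return NOT_APPLICABLE
    return sat * 100.0 / total


def score_ns(labels: np.ndarray) -> float:
    """Percentage of non-contact pairs satisfied: ``100 · #3 / (#3 + #4)``."""
    lab = _upper(labels)
    sat = int(np.count_nonzero(lab == LABEL_NONCONTACT_SAT))
    total = sat + int(np.count_nonzero(lab == LABEL_NONCONTACT_UNSAT))
    if total == 0:
        return NOT_APPLICABLE
    return sat * 100.0 / total


def score_if(labels: np.ndarray, matrix) -> float:
    """Frequency-weighted contact satisfaction.

    ``100 · Σ C_ij·freq_ij / Σ freq_ij`` over off-diagonal contact pairs,
    where ``C_ij`` is 1 for satisfied contacts and 0 otherwise.
    """
    freq = _freq_array(matrix)
    lab = np.asarray(labels)
    iu = np.triu_indices(freq.shape[0], k=1)
    f = freq[iu].astype(float)
    l_up = lab[iu]
    total_if = float(f[f > 0].sum())
    if total_if == 0:
        return NOT_APPLICABLE
    sat_if = float(f[l_up == LABEL_CONTACT_SAT].sum())
    return sat_if * 100.0 / total_if


def score_ms(s, thresholds: ScoreThresholds | None = None) -> float:
    """Max/min adjacent-distance satisfaction.

    A bond ``(k, k+1)`` is satisfied when ``min_d2 ≤ d² ≤ max_d2``.  The
    denominator is the *region* count n (as printed in the source
    formula), so a perfect chain scores ``100·(n−1)/n``.
    """
    t = thresholds or ScoreThresholds()
    coords = _coords_array(s)
    n = coords.shape[0]
    if n < 2:
        return NOT_APPLICABLE
    bond = coords[1:] - coords[:-1]
    d2 = np.einsum("ij,ij->i", bond, bond)
    sat = int(np.count_nonzero((d2 >= t.min_d2) & (d2 <= t.max_d2)))
    return sat * 100.0 / n


def score_total(
    cs: float,
    ns: float,
    if_score: float,
    ms: float,
    weights: ScoreWeights | None = None,
) -> float:
    """Weighted average of the applicable sub-scores.

    Not-applicable sub-scores are excluded together with their weights
    (renormalization) rather than contributing zero.
    """
    w = weights or ScoreWeights()
    parts = [
        (cs, w.w_cs),
        (ns, w.w_ns),
        (if_score, w.w_if),
        (ms, w.w_ms),
    ]
    num = 0.0
    den = 0.0
    for score, weight in parts:
        if is_applicable(score):
            num += weight * score
            den += weight
    if den == 0:
        raise ValueError("all sub-scores are not-applicable; total undefined")
    return num / den


def unsat_distance_summary(
    labels: np.ndarray, d2: np.ndarray
) -> tuple[float, float]:
    """Mean distances (μm) of unsatisfied contacts and non-contacts.

    Returns ``(mean over label-2 pairs, mean over label-4 pairs)``;
    NOT_APPLICABLE when a class is empty.
    """
    lab = np.asarray(labels)
    iu = np.triu_indices(lab.shape[0], k=1)
    l_up = lab[iu]
    d_up = np.sqrt(np.asarray(d2, dtype=float)[iu])
    out = []
    for code in (LABEL_CONTACT_UNSAT, LABEL_NONCONTACT_UNSAT):
        sel = d_up[l_up == code]
        out.append(float(sel.mean()) if sel.size else NOT_APPLICABLE)
    return out[0], out[1]


def evaluate(
    s,
    matrix,
    thresholds: ScoreThresholds | None = None,
    weights: ScoreWeights | None = None,
) -> ScoreReport:
    """Full score report for a structure against its contact matrix."""
    t = thresholds or ScoreThresholds()
    w = weights or ScoreWeights()
    labels, d2 = pair_satisfaction(s, matrix, t)
    cs = score_cs(labels)
    ns = score_ns(labels)
    ifs = score_if(labels, matrix)
    ms = score_ms(s, t)
    total = score_total(cs, ns, ifs, ms, w)
    mc, mn = unsat_distance_summary(labels, d2)
    return ScoreReport(
        cs=cs,
        ns=ns,
        if_score=ifs,
        ms=ms,
        total=total,
        labels=labels,
        mean_unsat_contact_dist=mc,
        mean_unsat_noncontact_dist=mn,
    )


class Scorer:
    """Matrix-bound scorer with precomputed pair bookkeeping.

    Binds a contact matrix, thresholds and weights once so the optimizer
    can evaluate many candidate structures cheaply.  Pair data are stored
    over the strict upper triangle (``i < j``); the diagonal never enters
    any count.
    """

    def __init__(
        self,
        matrix,
        thresholds: ScoreThresholds | None = None,
        weights: ScoreWeights | None = None,
    ) -> None:
        self.matrix = matrix
        self.thresholds = thresholds or ScoreThresholds()
        self.weights = weights or ScoreWeights()
        freq = _freq_array(matrix)
        self.n = freq.shape[0]
        self.ii, self.jj = np.triu_indices(self.n, k=1)
        self.pair_freq = freq[self.ii, self.jj].astype(float)
        self.contact = self.pair_freq > 0
        self.n_contact = int(self.contact.sum())
        self.n_noncontact = int(self.pair_freq.size - self.n_contact)
        self.total_if = float(self.pair_freq[self.contact].sum())
        self._suffix_cache: dict[int, np.ndarray] = {}
        self._point_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    # -- geometry -----------------------------------------------------

    def pair_d2(self, coords: np.ndarray) -> np.ndarray:
        diff = coords[self.ii] - coords[self.jj]
        return np.einsum("ij,ij->i", diff, diff)

    def bond_d2(self, coords: np.ndarray) -> np.ndarray:
        bond = coords[1:] - coords[:-1]
        return np.einsum("ij,ij->i", bond, bond)

    def suffix_pairs(self, i: int) -> np.ndarray:
        """Indices of pairs crossing the prefix/suffix cut at locus *i*."""
        idx = self._suffix_cache.get(i)
        if idx is None:
            idx = np.nonzero((self.ii < i) & (self.jj >= i))[0]
            self._suffix_cache[i] = idx
        return idx

    def point_pairs(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Pair indices touching locus *k* and the sign of its endpoint.

        Returns ``(idx, sign)`` where moving locus k by ``v`` changes
        the stored pair difference ``coords[ii]-coords[jj]`` by
        ``sign·v`` (+1 when k is the row endpoint, −1 for the column).
        """
        cached = self._point_cache.get(k)
        if cached is None:
            row = self.ii == k
            col = self.jj == k
            idx = np.nonzero(row | col)[0]
            sign = np.where(row[idx], 1.0, -1.0)
            cached = (idx, sign)
            self._point_cache[k] = cached
        return cached

    # -- counts → scores ----------------------------------------------

    def counts(self, pair_d2: np.ndarray, bond_d2: np.ndarray) -> tuple:
        """(sat contacts, sat non-contacts, sat IF mass, sat bonds)."""
        near = pair_d2 <= self.thresholds.contact_d2
        sat_c = int(np.count_nonzero(near & self.contact))
        sat_n = int(np.count_nonzero(~near & ~self.contact))
        sat_if = float(self.pair_freq[near & self.contact].sum())
        sat_b = int(
            np.count_nonzero(
                (bond_d2 >= self.thresholds.min_d2)
                & (bond_d2 <= self.thresholds.max_d2)
            )
        )
        return sat_c, sat_n, sat_if, sat_b

    def subscores_from_counts(
        self, sat_c: int, sat_n: int, sat_if: float, sat_b: int
    ) -> tuple[float, float, float, float]:
        cs = sat_c * 100.0 / self.n_contact if self.n_contact else NOT_APPLICABLE
        ns = sat_n * 100.0 / self.n_noncontact if self.n_noncontact else NOT_APPLICABLE
        ifs = sat_if * 100.0 / self.total_if if self.total_if else NOT_APPLICABLE
        ms = sat_b * 100.0 / self.n if self.n >= 2 else NOT_APPLICABLE
        return cs, ns, ifs, ms

    def total_from_counts(
        self, sat_c: int, sat_n: int, sat_if: float, sat_b: int
    ) -> float:
        cs, ns, ifs, ms = self.subscores_from_counts(sat_c, sat_n, sat_if, sat_b)
        return score_total(cs, ns, ifs, ms, self.weights)

    def total(self, s) -> float:
        """Weighted total score of a structure (fast path, no labels)."""
        coords = _coords_array(s)
        self._check_len(coords)
        return self.total_from_counts(
            *self.counts(self.pair_d2(coords), self.bond_d2(coords))
        )

    def report(self, s) -> ScoreReport:
        """Full ScoreReport (labels, unsatisfied-distance means)."""
        return evaluate(s, self.matrix, self.thresholds, self.weights)

    def _check_len(self, coords: np.ndarray) -> None:
        if coords.shape[0] != self.n:
            raise ValueError(
                f"structure has {coords.shape[0]} loci, matrix has {self.n}"
            )
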