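"""Synthetic ground-truth structures and the contact matrices they imply.

Used by tests and validation protocols: a confined random walk provides a
known 3D chain, and thresholding its pairwise squared distances yields a
contact matrix that the optimizer should be able to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hic_io import ContactMatrix
from .scoring import Structure3D

__all__ = ["SyntheticTruth", "make_truth", "truth_to_matrix", "generate"]

DEFAULT_RESOLUTION = 1_000_000


@dataclass
class SyntheticTruth:
    """A ground-truth chain, the matrix it implies, and the parameters used.

    ``dropped_pairs`` lists the (i, j) contact entries zeroed by dropout
    noise; before dropout the matrix is exactly the thresholding of the
    truth's pairwise squared distances at ``contact_d2``.
    """

    truth: Structure3D
    matrix: ContactMatrix
    params: dict = field(default_factory=dict)
    dropped_pairs: list[tuple[int, int]] = field(default_factory=list)


def make_truth(
    n: int,
    bond_len: float = 1.5,
    confine_r: float = 6.0,
    rng: np.random.Generator | None = None,
) -> Structure3D:
    """Random walk with fixed bond length confined to a sphere.

    Every bond has length exactly *bond_len* and every point lies within
    *confine_r* of the origin.  A step that would exit the sphere has its
    radial component reflected; in the rare case that still exits, fresh
    directions are drawn until one stays inside.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if bond_len <= 0 or confine_r <= 0:
        raise ValueError("bond_len and confine_r must be positive")
    if confine_r < bond_len:
        raise ValueError("confine_r must be at least bond_len")
    if rng is None:
        rng = np.random.default_rng()

    coords = np.zeros((n, 3))
    for i in range(1, n):
        prev = coords[i - 1]
        step = _unit(rng) * bond_len
        cand = prev + step
        if np.dot(cand, cand) > confine_r**2:
            # reflect the radial component of the step at the boundary
            r = np.linalg.norm(prev)
            if r > 0:
                nhat = prev / r
                step = step - 2.0 * np.dot(step, nhat) * nhat
                cand = prev + step
            while np.dot(cand, cand) > confine_r**2:
                cand = prev + _unit(rng) * bond_len
        coords[i] = cand
    return Structure3D(coords)


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else np.array([1.0, 0.0, 0.0])


def truth_to_matrix(
    s: Structure3D,
    contact_d2: float = 7.0,
    freq_law: str = "binary",
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    poisson_lam: float = 4.0,
    resolution: int = DEFAULT_RESOLUTION,
) -> tuple[ContactMatrix, list[tuple[int, int]]]:
    """Threshold a structure's squared distances into a contact matrix.

    A pair (i < j) is a contact iff ``d² ≤ contact_d2``.  ``"binary"``
    sets frequency 1; ``"poisson"`` draws ``1 + Poisson(λ/d²)`` counts,
    mimicking Hi-C distance decay.  Dropout independently zeroes contact
    entries (symmetrically) at the given rate.  Returns the matrix and
    the list of dropped pairs.
    """
    if contact_d2 <= 0:
        raise ValueError("contact_d2 must be positive")
    if not 0.0 <= dropout <= 1.0:
        raise ValueError("dropout must be in [0, 1]")
    if freq_law not in ("binary", "poisson"):
        raise ValueError(f"unknown freq_law {freq_law!r}")
    if rng is None:
        rng = np.random.default_rng()

    coords = s.coords
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    freq = np.zeros((n, n), dtype=np.int64)
    ii, jj = np.triu_indices(n, k=1)
    contact = d2[ii, jj] <= contact_d2
    if freq_law == "binary":
        counts = contact.astype(np.int64)
    else:
        lam = poisson_lam / np.maximum(d2[ii, jj], 1e-9)
        counts = np.where(contact, 1 + rng.poisson(lam), 0)
    freq[ii, jj] = counts
    freq[jj, ii] = counts

    dropped: list[tuple[int, int]] = []
    if dropout > 0:
        drop = contact & (rng.random(ii.size) < dropout)
        for i, j in zip(ii[drop], jj[drop]):
            freq[i, j] = 0
            freq[j, i] = 0
            dropped.append((int(i), int(j)))

    matrix = ContactMatrix(freq=freq, resolution=resolution, origin=0)
    return matrix, dropped


def generate(
    n: int,
    bond_len: float = 1.5,
    confine_r: float = 6.0,
    contact_d2: float = 7.0,
    freq_law: str = "binary",
    dropout: float = 0.0,
    seed: int | None = None,
) -> SyntheticTruth:
    """One-call fixture: truth chain plus its implied contact matrix."""
    rng = np.random.default_rng(seed)
    truth = make_truth(n, bond_len=bond_len, confine_r=confine_r, rng=rng)
    matrix, dropped = truth_to_matrix(
        truth, contact_d2=contact_d2, freq_law=freq_law, dropout=dropout, rng=rng
    )
    return SyntheticTruth(
        truth=truth,
        matrix=matrix,
        params={
            "n": n,
            "bond_len": bond_len,
            "confine_r": confine_r,
            "contact_d2": contact_d2,
            "freq_law": freq_law,
            "dropout": dropout,
            "seed": seed,
        },
        dropped_pairs=dropped,
    )
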