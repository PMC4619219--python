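"""Random initial conformations: chain growth or a random sphere.

Large chromosomes (> 200 regions) start from a grown chain built one
locus at a time; smaller ones start from random points on a sphere of
radius 1 μm.
"""

from __future__ import annotations

import numpy as np

from .scoring import Structure3D

__all__ = [
    "GROWTH_THRESHOLD",
    "random_vector",
    "growth_init",
    "sphere_init",
    "choose_init",
    "initial_structure",
]

#: Region count above which growth initialization is used.
GROWTH_THRESHOLD = 200


def random_vector(rng: np.random.Generator, max_len: float = 1.0) -> np.ndarray:
    """A vector with isotropic direction and uniform length in [0, max_len).

    Directions are drawn by normalizing standard-normal triples, which is
    exactly uniform on the sphere.
    """
    return random_vectors(rng, 1, max_len)[0]


def random_vectors(
    rng: np.random.Generator, count: int, max_len: float = 1.0
) -> np.ndarray:
    """``count`` independent random vectors, shape ``(count, 3)``."""
    v = rng.standard_normal((count, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # a zero normal triple is a measure-zero event; guard anyway
    norms[norms == 0] = 1.0
    lengths = rng.random(count) * max_len
    return v / norms * lengths[:, None]


def growth_init(n: int, rng: np.random.Generator) -> Structure3D:
    """Grow a chain one locus at a time: ``R_i = R_{i-1} + r``.

    ``R_0`` is at the origin; each step vector has random direction and
    random length in [0, 1) μm.  No self-avoidance is imposed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    steps = random_vectors(rng, n - 1) if n > 1 else np.empty((0, 3))
    coords = np.vstack([np.zeros((1, 3)), np.cumsum(steps, axis=0)])
    return Structure3D(coords)


def sphere_init(
    n: int, radius: float = 1.0, rng: np.random.Generator | None = None
) -> Structure3D:
    """``n`` points uniformly distributed on a sphere surface."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if rng is None:
        rng = np.random.default_rng()
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return Structure3D(v / norms * radius)


def choose_init(n: int, threshold: int = GROWTH_THRESHOLD) -> str:
    """``"growth"`` for chains longer than *threshold*, else ``"sphere"``."""
    if n < 1:
        raise ValueError("n must be at least 1")
    return "growth" if n > threshold else "sphere"


def initial_structure(
    n: int, rng: np.random.Generator, mode: str = "auto"
) -> Structure3D:
    """Dispatch on *mode* (``auto``, ``growth`` or ``sphere``)."""
    if mode == "auto":
        mode = choose_init(n)
    if mode == "growth":
        return growth_init(n, rng)
    if mode == "sphere":
        return sphere_init(n, rng=rng)
    raise ValueError(f"unknown init mode {mode!r}")
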