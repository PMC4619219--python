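"""Model output and validation protocols.

Writes bead-model PDB files (one CA pseudo-atom per locus, consecutive
loci connected), dumps heat-map label matrices, splits contact
satisfaction into short/long range, and runs the two consistency checks:
convergence (two seeds, same matrix) and robustness-by-recovery (rebuild
from a model's own thresholded contact matrix).

Model similarity is measured as the Spearman correlation of the two
models' pairwise-distance matrices, which is invariant to superposition
and mirroring.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from . import scoring
from .optimize import OptimizerConfig, build_model
from .scoring import (
    NOT_APPLICABLE,
    ScoreThresholds,
    ScoreWeights,
    Structure3D,
)
from .synthetic import truth_to_matrix

__all__ = [
    "write_pdb",
    "read_pdb",
    "heatmap_matrix",
    "render_heatmap",
    "range_split",
    "distance_spearman",
    "convergence_test",
    "recovery_test",
]

HEATMAP_COLORS = {
    0: "#bdbdbd",  # excluded / diagonal
    1: "#d7191c",  # contact satisfied (red)
    2: "#ffffff",  # contact unsatisfied (white)
    3: "#abd9e9",  # non-contact satisfied (light blue)
    4: "#2c7bb6",  # non-contact unsatisfied (dark blue)
}


def write_pdb(s: Structure3D, path, scale: float = 1.0) -> None:
    """Write one CA pseudo-atom per locus, chained with CONECT records.

    Coordinates are multiplied by *scale* before writing (PDB columns are
    fixed-width; values must stay below 10,000 in magnitude).
    """
    coords = s.coords * scale
    if coords.shape[0] == 0:
        raise ValueError("cannot write an empty structure")
    if np.abs(coords).max() >= 10000:
        raise ValueError(
            "scaled coordinates exceed PDB column width; lower --pdb-scale"
        )
    lines = []
    for k, (x, y, z) in enumerate(coords, start=1):
        lines.append(
            f"ATOM  {k:>5d}  CA  GLY A{k:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    for k in range(1, coords.shape[0]):
        lines.append(f"CONECT{k:>5d}{k + 1:>5d}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_pdb(path, scale: float = 1.0) -> Structure3D:
    """Read ATOM/HETATM records back into a structure (divides by *scale*)."""
    coords = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("ATOM  ", "HETATM")):
                coords.append(
                    (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                )
    if not coords:
        raise ValueError(f"no ATOM records found in {path}")
    return Structure3D(np.array(coords) / scale)


def heatmap_matrix(labels: np.ndarray, path) -> None:
    """Write the {0,1,2,3,4} label matrix as integer TSV."""
    np.savetxt(path, np.asarray(labels, dtype=int), fmt="%d", delimiter="\t")


def render_heatmap(labels: np.ndarray, path) -> None:
    """Render the label matrix with the standard four-class color legend."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    cmap = ListedColormap([HEATMAP_COLORS[c] for c in range(5)])
    norm = BoundaryNorm(np.arange(-0.5, 5.5), cmap.N)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(np.asarray(labels), cmap=cmap, norm=norm, interpolation="nearest")
    cbar = fig.colorbar(im, ticks=range(5))
    cbar.ax.set_yticklabels(
        [
            "excluded",
            "contact satisfied",
            "contact unsatisfied",
            "non-contact satisfied",
            "non-contact unsatisfied",
        ]
    )
    ax.set_xlabel("region")
    ax.set_ylabel("region")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def range_split(labels: np.ndarray, cutoff: int = 10) -> tuple[float, float]:
    """Contact satisfaction split into short range (|i−j| ≤ cutoff) and long.

    Returns ``(short_cs, long_cs)``; a class with no contact pairs is
    NOT_APPLICABLE.
    """
    lab = np.asarray(labels)
    n = lab.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    sep = jj - ii
    out = []
    for sel in (sep <= cutoff, sep > cutoff):
        l_sel = lab[ii[sel], jj[sel]]
        sat = int(np.count_nonzero(l_sel == scoring.LABEL_CONTACT_SAT))
        tot = sat + int(np.count_nonzero(l_sel == scoring.LABEL_CONTACT_UNSAT))
        out.append(sat * 100.0 / tot if tot else NOT_APPLICABLE)
    return out[0], out[1]


def distance_spearman(a: Structure3D, b: Structure3D) -> float:
    """Spearman correlation of the two models' pairwise-distance vectors."""
    da, db = pdist(a.coords), pdist(b.coords)
    rho = spearmanr(da, db).statistic
    return float(rho)


def _clean(x: float):
    return None if (isinstance(x, float) and math.isnan(x)) else x


def convergence_test(
    matrix,
    cfg: OptimizerConfig,
    seeds: tuple[int, int],
    thresholds: ScoreThresholds | None = None,
    weights: ScoreWeights | None = None,
) -> dict:
    """Build the same matrix twice with different seeds and compare.

    Reports both score summaries, the absolute score gap, and the
    Spearman correlation of the two models' distance matrices.
    """
    from dataclasses import replace

    results = []
    for seed in seeds:
        structure, report, _ = build_model(
            matrix, replace(cfg, seed=seed), thresholds, weights
        )
        results.append((structure, report))
    (sa, ra), (sb, rb) = results
    return {
        "seeds": list(seeds),
        "report_a": ra.to_dict(),
        "report_b": rb.to_dict(),
        "score_gap": abs(ra.total - rb.total),
        "distance_spearman": distance_spearman(sa, sb),
        "structures": (sa, sb),
    }


def recovery_test(
    matrix,
    cfg: OptimizerConfig,
    seed: int,
    thresholds: ScoreThresholds | None = None,
    weights: ScoreWeights | None = None,
) -> dict:
    """Robustness by recovery.

    Builds model A from *matrix*; derives a binary contact matrix from A
    at the contact threshold; builds model B from that matrix; reports
    the A-vs-B distance Spearman and B's CS/NS against A's derived
    matrix (plus A's scores against the input matrix).
    """
    from dataclasses import replace

    t = thresholds or ScoreThresholds()
    model_a, report_a, _ = build_model(
        matrix, replace(cfg, seed=seed), thresholds, weights
    )
    derived, _ = truth_to_matrix(model_a, contact_d2=t.contact_d2, freq_law="binary")
    model_b, report_b, _ = build_model(
        derived, replace(cfg, seed=seed + 1), thresholds, weights
    )
    return {
        "seed": seed,
        "report_a": report_a.to_dict(),
        "report_b": report_b.to_dict(),
        "cs_b": _clean(report_b.cs),
        "ns_b": _clean(report_b.ns),
        "distance_spearman": distance_spearman(model_a, model_b),
        "structures": (model_a, model_b),
        "derived_matrix": derived,
    }
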