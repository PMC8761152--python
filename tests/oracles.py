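"""Independent brute-force oracles used to cross-check the production code.

These deliberately avoid the production code paths: the RMSD minimiser
searches rotation space numerically instead of using the closed-form
solution, the thickness recomputation averages coordinates in plain
Python, and the TM-score oracle seeds the shared refinement routine from
every contiguous window instead of the strided production schedule.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from memqa.superposition import refine_from_seed


def brute_force_rmsd(query: np.ndarray, reference: np.ndarray,
                     n_grid: int = 1500, seed: int = 0) -> float:
    """Minimal RMSD over proper rotations by grid search + local polish.

    For each candidate rotation the optimal translation is the centroid
    match, so only SO(3) is searched: a random rotation grid picks the
    basin, Nelder-Mead on the rotation vector polishes it.
    """
    q = query - query.mean(axis=0)
    r = reference - reference.mean(axis=0)

    def rmsd_of(rot: np.ndarray) -> float:
        return float(np.sqrt(np.mean(np.sum((q @ rot.T - r) ** 2, axis=1))))

    rng = np.random.default_rng(seed)
    grid = Rotation.random(n_grid, rng=rng)
    best_rot = min(grid, key=lambda g: rmsd_of(g.as_matrix()))

    def objective(rotvec: np.ndarray) -> float:
        return rmsd_of(Rotation.from_rotvec(rotvec).as_matrix())

    res = minimize(objective, best_rot.as_rotvec(), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
    return float(res.fun)


def exhaustive_tm_score(q: np.ndarray, r: np.ndarray, l_norm: int) -> float:
    """TM-score maximised over every contiguous seed window of length >= 4."""
    from memqa.superposition import d0

    scale = d0(l_norm)
    n = q.shape[0]
    best = -1.0
    for length in range(4, n + 1):
        for start in range(0, n - length + 1):
            total, _, _ = refine_from_seed(q, r, np.arange(start, start + length), scale)
            best = max(best, total)
    return best / l_norm


def python_thickness(structure, annotation) -> float:
    """Thickness via explicit coordinate averaging, no numpy reductions."""
    from memqa.topology_io import assign_membrane_sides

    side1, side2 = assign_membrane_sides(annotation)
    centroids = []
    for positions in (side1, side2):
        sx = sy = sz = 0.0
        count = 0
        for pos in positions:
            res = structure.find(pos)
            if res is not None and res.ca_coord is not None:
                x, y, z = res.ca_coord
                sx, sy, sz = sx + x, sy + y, sz + z
                count += 1
        centroids.append((sx / count, sy / count, sz / count))
    (x1, y1, z1), (x2, y2, z2) = centroids
    return ((x1 - x2) ** 2 + (y1 - y2) ** 2 + (z1 - z2) ** 2) ** 0.5
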