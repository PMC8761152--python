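"""Rigid-body structural comparison: Kabsch, TM-score, GDT_TS, alignment.

The TM-score of an aligned residue pair list under a rigid superposition is

    TM = (1 / L_norm) * sum_i 1 / (1 + (d_i / d0(L_norm))^2)

with the length-dependent scale ``d0(L) = 1.24 (L - 15)^(1/3) - 1.8`` A,
floored at 0.5 A.  The score is maximised over superpositions with the
standard fragment-seeded iterative search: superpose on a seed window,
repeatedly re-superpose on the close pairs until the inclusion set is
stable, keep the best score over all seeds.  GDT_TS reuses the same
search per distance cutoff (1, 2, 4, 8 A).

``structural_align`` builds a sequence-independent monotone residue
correspondence by iterating superposition and dynamic programming over the
distance-derived score matrix — a distance-only variant of the TM-align
heuristic (no secondary-structure term).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, UnderdeterminedError
from .structure_io import Structure

__all__ = [
    "Correspondence",
    "SuperpositionResult",
    "identity_correspondence",
    "kabsch_superpose",
    "d0",
    "tm_score",
    "gdt_ts",
    "structural_align",
]

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
#: Affine gap penalty of the alignment DP (TM-align convention).
GAP_OPEN = -0.6
GAP_EXTEND = 0.0


@dataclass
class Correspondence:
    """A monotone residue mapping between two structures.

    ``pairs`` holds 0-based indices into the C-alpha-bearing residue
    sequences of query and reference; both index columns are strictly
    increasing (sequential alignment, no duplicates).
    """

    pairs: list[tuple[int, int]]
    query_id: str = ""
    reference_id: str = ""

    def __post_init__(self) -> None:
        prev_q = prev_r = -1
        for q, r in self.pairs:
            if q <= prev_q or r <= prev_r:
                raise ValueError("correspondence must be strictly increasing")
            prev_q, prev_r = q, r

    def __len__(self) -> int:
        return len(self.pairs)

    def query_indices(self) -> np.ndarray:
        return np.array([q for q, _ in self.pairs], dtype=int)

    def reference_indices(self) -> np.ndarray:
        return np.array([r for _, r in self.pairs], dtype=int)


@dataclass
class SuperpositionResult:
    """Scores and the score-optimal rigid transform of one comparison."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    tm_score: float
    gdt_ts: float
    n_aligned: int
    normalization_length: int
    tm_score_query_norm: float | None = None


def identity_correspondence(n: int, query_id: str = "", reference_id: str = "") -> Correspondence:
    return Correspondence([(i, i) for i in range(n)], query_id, reference_id)


def kabsch_superpose(
    query_coords: np.ndarray, reference_coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition of paired point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ q + translation`` minimises the RMSD to the reference
    over all proper rotations (closed-form SVD solution).
    """
    q = np.asarray(query_coords, dtype=float)
    r = np.asarray(reference_coords, dtype=float)
    if q.shape != r.shape or q.ndim != 2 or q.shape[1] != 3:
        raise ValueError(f"coordinate arrays must both be (N, 3); got {q.shape}, {r.shape}")
    n = q.shape[0]
    if n < 3:
        raise UnderdeterminedError(f"need at least 3 pairs, got {n}")
    qc = q.mean(axis=0)
    rc = r.mean(axis=0)
    qd = q - qc
    rd = r - rc
    # Collinear point sets leave a rotation axis free.
    if np.linalg.matrix_rank(qd, tol=1e-8) < 2:
        raise UnderdeterminedError("degenerate (collinear) geometry")
    h = qd.T @ rd
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = rc - rot @ qc
    moved = qd @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - rd) ** 2, axis=1))))
    return rot, trans, rmsd


def _kabsch_transform(q: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation/translation part of the Kabsch fit, without degeneracy checks."""
    qc = q.mean(axis=0)
    rc = r.mean(axis=0)
    h = (q - qc).T @ (r - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, rc - rot @ qc


def d0(L: int) -> float:
    """TM-score distance scale for normalisation length ``L`` (A)."""
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if L <= 15:
        return 0.5
    return max(0.5, 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8)


def _pair_distances(rot: np.ndarray, trans: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    return np.linalg.norm(q @ rot.T + trans - r, axis=1)


def _tm_sum(dists: np.ndarray, scale: float) -> float:
    return float(np.sum(1.0 / (1.0 + (dists / scale) ** 2)))


def _cutoff_schedule(scale: float, iteration: int, shrink_iters: int = 5) -> float:
    """Inclusion cutoff: from d0 toward d0/2 + 1 over early iterations, floor 3 A."""
    f = min(iteration, shrink_iters) / shrink_iters
    return max(3.0, scale * (1.0 - f) + (scale / 2.0 + 1.0) * f)


def refine_from_seed(
    q: np.ndarray,
    r: np.ndarray,
    seed_indices: np.ndarray,
    scale: float,
    max_iter: int = 20,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Iterative superposition extension from a seed subset.

    Superposes on the seed, then repeatedly re-superposes on the pairs
    closer than the (shrinking) cutoff until that inclusion set is stable
    or ``max_iter`` is hit.  Returns the best raw TM sum seen (over all
    pairs) and the corresponding transform.  Shared by the production
    search and by exhaustive-seed test oracles.
    """
    subset = np.asarray(seed_indices, dtype=int)
    best_sum = -1.0
    best_rot = np.eye(3)
    best_trans = np.zeros(3)
    prev: frozenset[int] | None = None
    for it in range(max_iter):
        if subset.size < 3:
            break
        rot, trans = _kabsch_transform(q[subset], r[subset])
        dists = _pair_distances(rot, trans, q, r)
        total = _tm_sum(dists, scale)
        if total > best_sum:
            best_sum = total
            best_rot, best_trans = rot, trans
        cutoff = _cutoff_schedule(scale, it)
        included = np.nonzero(dists < cutoff)[0]
        if included.size < 4:
            included = np.argsort(dists)[:4]
        key = frozenset(included.tolist())
        if key == prev:
            break
        prev = key
        subset = included
    return best_sum, best_rot, best_trans


def _seed_windows(n: int, max_offsets: int = 40) -> list[np.ndarray]:
    """Seed windows of lengths n, n/2, n/4 (>=4) at strided offsets.

    Short chains (n <= 30) are seeded exhaustively from every window of
    every length >= 4 — cheap at that size and it removes any dependence
    on the coarse length schedule where single-window basins matter most.
    """
    if n <= 30:
        lengths: list[int] | set[int] = list(range(n, 3, -1))
    else:
        lengths = sorted({n, max(4, n // 2), max(4, n // 4)}, reverse=True)
    windows: list[np.ndarray] = []
    for length in lengths:
        n_off = n - length + 1
        stride = max(1, int(np.ceil(n_off / max_offsets)))
        for start in range(0, n_off, stride):
            windows.append(np.arange(start, start + length))
    return windows


def _tm_search(
    q: np.ndarray, r: np.ndarray, scale: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Best raw TM sum over the fragment-seeded iterative search."""
    best = (-1.0, np.eye(3), np.zeros(3))
    for window in _seed_windows(q.shape[0]):
        total, rot, trans = refine_from_seed(q, r, window, scale)
        if total > best[0]:
            best = (total, rot, trans)
    return best


def _aligned_coords(
    query: Structure, reference: Structure, corr: Correspondence
) -> tuple[np.ndarray, np.ndarray]:
    if len(corr) == 0:
        raise AlignmentError("empty correspondence")
    qcoords = query.ca_array()
    rcoords = reference.ca_array()
    qi = corr.query_indices()
    ri = corr.reference_indices()
    if qi[-1] >= qcoords.shape[0] or ri[-1] >= rcoords.shape[0]:
        raise AlignmentError("correspondence indexes beyond the C-alpha trace")
    return qcoords[qi], rcoords[ri]


def _gdt_fraction(q: np.ndarray, r: np.ndarray, cutoff: float) -> float:
    """Max fraction of pairs simultaneously fittable within ``cutoff``."""
    n = q.shape[0]
    best = 0
    for window in _seed_windows(n):
        subset = window
        prev: frozenset[int] | None = None
        for _ in range(20):
            if subset.size < 3:
                break
            rot, trans = _kabsch_transform(q[subset], r[subset])
            dists = _pair_distances(rot, trans, q, r)
            count = int(np.sum(dists <= cutoff))
            if count > best:
                best = count
            included = np.nonzero(dists <= cutoff)[0]
            if included.size < 4:
                included = np.argsort(dists)[:4]
            key = frozenset(included.tolist())
            if key == prev:
                break
            prev = key
            subset = included
        if best == n:
            break
    return best / n


def gdt_ts(query: Structure, reference: Structure, corr: Correspondence) -> float:
    """Global Distance Test (total score), 0-100.

    Mean over the 1/2/4/8 A cutoffs of the maximal percentage of aligned
    pairs simultaneously superposable within the cutoff, maximised with
    the same seed-and-extend search used for the TM-score.
    """
    q, r = _aligned_coords(query, reference, corr)
    if q.shape[0] < 3:
        raise AlignmentError("need at least 3 aligned pairs for GDT_TS")
    return 100.0 * float(np.mean([_gdt_fraction(q, r, c) for c in GDT_CUTOFFS]))


def tm_score(
    query: Structure,
    reference: Structure,
    corr: Correspondence,
    normalization: str = "reference",
    compute_gdt: bool = True,
) -> SuperpositionResult:
    """TM-score (and companions) of a correspondence between two structures.

    The score is normalised by the full C-alpha length of the chosen
    structure (``reference`` by default); the value under the other
    normalisation is reported alongside.  ``rmsd`` is the Kabsch-minimal
    RMSD over all aligned pairs; rotation/translation belong to the
    TM-score-optimal superposition.
    """
    if normalization not in ("reference", "query"):
        raise ValueError(f"normalization must be 'reference' or 'query', got {normalization!r}")
    q, r = _aligned_coords(query, reference, corr)
    if q.shape[0] < 3:
        raise AlignmentError("need at least 3 aligned pairs")
    l_ref = len(reference.ca_residues())
    l_query = len(query.ca_residues())
    l_norm = l_ref if normalization == "reference" else l_query
    scale = d0(l_norm)
    total, rot, trans = _tm_search(q, r, scale)
    score = total / l_norm
    # Same optimal sum read off under the other normalisation length.
    l_other = l_query if normalization == "reference" else l_ref
    other_total, _, _ = (total, rot, trans) if d0(l_other) == scale else _tm_search(q, r, d0(l_other))
    other_score = other_total / l_other
    _, _, rmsd = kabsch_superpose(q, r)
    gdt = gdt_ts(query, reference, corr) if compute_gdt else float("nan")
    return SuperpositionResult(
        rotation=rot,
        translation=trans,
        rmsd=rmsd,
        tm_score=float(np.clip(score, 0.0, 1.0)),
        gdt_ts=gdt,
        n_aligned=q.shape[0],
        normalization_length=l_norm,
        tm_score_query_norm=float(np.clip(other_score, 0.0, 1.0))
        if normalization == "reference"
        else float(np.clip(score, 0.0, 1.0)),
    )


# ---------------------------------------------------------------------------
# Sequence-independent alignment
# ---------------------------------------------------------------------------

try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _dp_traceback_py(S: np.ndarray, gap_open: float) -> list[tuple[int, int]]:
    """Needleman-Wunsch with affine gaps (extension 0) and free end gaps."""
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in reference (consume query)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in query (consume reference)
    M[0, 0] = 0.0
    # free terminal gaps
    Ix[1:, 0] = 0.0
    Iy[0, 1:] = 0.0
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sm = S[i - 1, j - 1]
            best = M[i - 1, j - 1]
            ptr = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                ptr = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + sm
            ptrM[i, j] = ptr
            open_x = M[i - 1, j] + gap_open
            ext_x = Ix[i - 1, j]
            if open_x >= ext_x:
                Ix[i, j] = open_x
                ptrX[i, j] = 0
            else:
                Ix[i, j] = ext_x
                ptrX[i, j] = 1
            open_y = M[i, j - 1] + gap_open
            ext_y = Iy[i, j - 1]
            if open_y >= ext_y:
                Iy[i, j] = open_y
                ptrY[i, j] = 0
            else:
                Iy[i, j] = ext_y
                ptrY[i, j] = 1
    return _traceback(M, Ix, Iy, ptrM, ptrX, ptrY, n, m)


def _traceback(M, Ix, Iy, ptrM, ptrX, ptrY, n, m) -> list[tuple[int, int]]:
    # Free end gaps: best over the three states at (n, m).
    state = int(np.argmax([M[n, m], Ix[n, m], Iy[n, m]]))
    i, j = n, m
    pairs: list[tuple[int, int]] = []
    while i > 0 and j > 0:
        if state == 0:
            pairs.append((i - 1, j - 1))
            state = int(ptrM[i, j])
            i -= 1
            j -= 1
        elif state == 1:
            nxt = int(ptrX[i, j])
            i -= 1
            state = nxt if i > 0 and j > 0 else 1
        else:
            nxt = int(ptrY[i, j])
            j -= 1
            state = nxt if i > 0 and j > 0 else 2
    pairs.reverse()
    return pairs


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _dp_tables_nb(S, gap_open):  # pragma: no cover - numba-compiled
        n, m = S.shape
        NEG = -1e30
        M = np.full((n + 1, m + 1), NEG)
        Ix = np.full((n + 1, m + 1), NEG)
        Iy = np.full((n + 1, m + 1), NEG)
        M[0, 0] = 0.0
        for i in range(1, n + 1):
            Ix[i, 0] = 0.0
        for j in range(1, m + 1):
            Iy[0, j] = 0.0
        ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
        ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
        ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                best = M[i - 1, j - 1]
                ptr = 0
                if Ix[i - 1, j - 1] > best:
                    best = Ix[i - 1, j - 1]
                    ptr = 1
                if Iy[i - 1, j - 1] > best:
                    best = Iy[i - 1, j - 1]
                    ptr = 2
                M[i, j] = best + S[i - 1, j - 1]
                ptrM[i, j] = ptr
                open_x = M[i - 1, j] + gap_open
                if open_x >= Ix[i - 1, j]:
                    Ix[i, j] = open_x
                    ptrX[i, j] = 0
                else:
                    Ix[i, j] = Ix[i - 1, j]
                    ptrX[i, j] = 1
                open_y = M[i, j - 1] + gap_open
                if open_y >= Iy[i, j - 1]:
                    Iy[i, j] = open_y
                    ptrY[i, j] = 0
                else:
                    Iy[i, j] = Iy[i, j - 1]
                    ptrY[i, j] = 1
        return M, Ix, Iy, ptrM, ptrX, ptrY

    def _dp_align(S: np.ndarray, gap_open: float = GAP_OPEN) -> list[tuple[int, int]]:
        n, m = S.shape
        M, Ix, Iy, ptrM, ptrX, ptrY = _dp_tables_nb(
            np.ascontiguousarray(S, dtype=np.float64), gap_open
        )
        return _traceback(M, Ix, Iy, ptrM, ptrX, ptrY, n, m)

else:

    def _dp_align(S: np.ndarray, gap_open: float = GAP_OPEN) -> list[tuple[int, int]]:
        return _dp_traceback_py(np.asarray(S, dtype=float), gap_open)


def _quick_tm(q: np.ndarray, r: np.ndarray, pairs: list[tuple[int, int]], scale: float) -> float:
    """TM sum of a candidate correspondence after Kabsch on its own pairs."""
    if len(pairs) < 3:
        return -1.0
    qi = np.array([p for p, _ in pairs])
    ri = np.array([p for _, p in pairs])
    rot, trans = _kabsch_transform(q[qi], r[ri])
    dists = _pair_distances(rot, trans, q[qi], r[ri])
    return _tm_sum(dists, scale)


def structural_align(
    query: Structure,
    reference: Structure,
    n_seeds: int = 3,
    max_iter: int = 30,
) -> Correspondence:
    """Sequence-independent monotone alignment of two C-alpha traces.

    Initial candidates come from gapless threading of the query against
    the reference at every offset; the most promising seeds (ranked by the
    TM sum after superposing on the overlap) are refined by iterating
    superpose -> dynamic programming over ``S_ij = 1/(1 + (d_ij/d0)^2)``
    -> superpose until the correspondence is stable or ``max_iter``
    rounds.  The best-scoring correspondence is returned.
    """
    qc = query.ca_array()
    rc = reference.ca_array()
    nq, nr = qc.shape[0], rc.shape[0]
    if nq < 8 or nr < 8:
        raise AlignmentError(f"need >= 8 C-alpha positions on both sides (got {nq}, {nr})")
    scale = d0(min(nq, nr))

    # (a) gapless threading at all offsets
    min_overlap = 8
    scored_offsets: list[tuple[float, int]] = []
    for offset in range(-(nr - min_overlap), nq - min_overlap + 1):
        q_lo = max(0, offset)
        q_hi = min(nq, nr + offset)
        if q_hi - q_lo < min_overlap:
            continue
        qi = np.arange(q_lo, q_hi)
        ri = qi - offset
        rot, trans = _kabsch_transform(qc[qi], rc[ri])
        dists = _pair_distances(rot, trans, qc[qi], rc[ri])
        scored_offsets.append((_tm_sum(dists, scale), offset))
    scored_offsets.sort(key=lambda t: (-t[0], t[1]))

    best_pairs: list[tuple[int, int]] | None = None
    best_score = -1.0
    for _, offset in scored_offsets[:n_seeds]:
        q_lo = max(0, offset)
        q_hi = min(nq, nr + offset)
        pairs = [(i, i - offset) for i in range(q_lo, q_hi)]
        prev: list[tuple[int, int]] | None = None
        for _ in range(max_iter):
            qi = np.array([p for p, _ in pairs])
            ri = np.array([p for _, p in pairs])
            rot, trans = _kabsch_transform(qc[qi], rc[ri])
            moved = qc @ rot.T + trans
            diff = moved[:, None, :] - rc[None, :, :]
            dmat = np.sqrt(np.sum(diff * diff, axis=2))
            S = 1.0 / (1.0 + (dmat / scale) ** 2)
            new_pairs = _dp_align(S)
            if len(new_pairs) < 3:
                break
            score = _quick_tm(qc, rc, new_pairs, scale)
            if score > best_score:
                best_score = score
                best_pairs = new_pairs
            if new_pairs == prev or new_pairs == pairs:
                break
            prev = pairs
            pairs = new_pairs
        else:
            pass
        # Also consider the raw threading seed itself.
        seed_pairs = [(i, i - offset) for i in range(q_lo, q_hi)]
        seed_score = _quick_tm(qc, rc, seed_pairs, scale)
        if seed_score > best_score:
            best_score = seed_score
            best_pairs = seed_pairs
    if best_pairs is None:
        raise AlignmentError(
            f"no alignment found between {query.id!r} and {reference.id!r}"
        )
    return Correspondence(best_pairs, query_id=query.id, reference_id=reference.id)
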