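"""Native pairwise structural alignment of CA traces.

The screening currency of the whole package is the TM-score: for a residue
correspondence between two chains superposed by a rigid transform,

    TM = (1 / L_norm) * sum_i 1 / (1 + (d_i / d0(L_norm))**2)

where d_i are the aligned CA-CA distances and d0(L) = 1.24 * (L - 15)**(1/3)
- 1.8 Å is the length-dependent normalization scale (floored so short chains
stay defined). A TM-score above ~0.5-0.6 indicates a shared fold; the
screens call similarity at 0.6 (anti-CRISPR / counter-defense) or 0.65
(defense candidates), always on the score normalized by the shorter chain.

The alignment search is a TM-align-style heuristic: initial correspondences
come from gapless threading of the shorter chain onto the longer at every
offset and from Kabsch superpositions of short fragment pairs; each
promising seed is refined by iterative dynamic programming on the score
matrix S(i, j) = 1 / (1 + (d_ij / d0)**2) with a flat gap penalty and free
terminal gaps, alternating with TM-optimal re-superposition, until the
correspondence stabilises. The heuristic is deterministic for a fixed
configuration. It approximates what US-align computes with default
parameters and can differ from it on hard pairs; all thresholds in the
screens therefore come with constructed fixtures whose true similarity is
known by design.

Superposition itself is the closed-form Kabsch algorithm (sign-corrected
SVD, so reflections are never returned).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from numba import njit

from .io_formats import StructureModel


@dataclass(frozen=True)
class AlignConfig:
    """Parameters of the heuristic alignment search."""

    d0_floor: float = 0.5          # Å; keeps d0 defined below ~22 residues
    gap_open: float = -0.6         # flat DP gap penalty, no extension term
    max_iterations: int = 20       # DP/superposition rounds per seed
    seed_fragment_length: int = 20
    convergence: float = 1e-6      # stop when TM improves by less
    fragment_stride: int = 4       # fragment-seed grid spacing
    max_refined_seeds: int = 8     # seeds taken into full DP refinement

    def __post_init__(self) -> None:
        if self.d0_floor <= 0:
            raise ValueError("d0_floor must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be ≥ 1")


DEFAULT_CONFIG = AlignConfig()


@dataclass
class StructuralAlignment:
    """A residue correspondence with its rigid transform and TM-scores.

    ``pairs`` is strictly increasing in both coordinates (sequential
    alignment, no crossings). Each TM normalization uses its own d0.
    """

    query_id: str
    target_id: str
    pairs: list[tuple[int, int]]
    rotation: np.ndarray      # 3x3, orthonormal, det +1
    translation: np.ndarray   # 3-vector, Å
    rmsd: float               # Å over aligned pairs, under the TM-best transform
    tm_query: float
    tm_target: float
    tm_shorter: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Primitives

def kabsch_superpose(P: np.ndarray, Q: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns (rotation, translation, rmsd) minimizing
    ``|| rotation @ P.T + translation - Q.T ||`` over proper rotations
    (reflections are excluded by sign-correcting the smallest singular
    vector). Degenerate (rank-deficient) inputs still return a minimizer.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("superposition needs at least 3 paired points")
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(Q))):
        raise ValueError("non-finite coordinates")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return R, t, rmsd


def tm_d0(L_norm: int, d0_floor: float = 0.5) -> float:
    """TM-score distance scale d0 = 1.24 * (L - 15)**(1/3) - 1.8, floored."""
    if L_norm < 1:
        raise ValueError("L_norm must be ≥ 1")
    if L_norm > 15:
        d0 = 1.24 * (L_norm - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = -1.8
    return max(d0, d0_floor)


def _tm_of_transform(P: np.ndarray, Q: np.ndarray, R: np.ndarray,
                     t: np.ndarray, L_norm: int, d0: float) -> float:
    d2 = ((P @ R.T + t - Q) ** 2).sum(axis=1)
    return float((1.0 / (1.0 + d2 / d0 ** 2)).sum() / L_norm)


def tm_from_pairs(query: StructureModel, target: StructureModel,
                  pairs: Sequence[tuple[int, int]], L_norm: int,
                  config: AlignConfig = DEFAULT_CONFIG,
                  ) -> tuple[float, float, np.ndarray, np.ndarray, list[float]]:
    """TM-score of a fixed correspondence, maximized over superpositions.

    Starts from Kabsch on all pairs, then iterates re-superposition on the
    close subset (d_i < max(2 d0, 4.5 Å)), keeping the best TM seen; also
    tries superpositions seeded from sliding windows of the pair list.
    Returns (tm, rmsd, rotation, translation, trace) where ``trace`` is the
    running best TM per iteration (non-decreasing by construction) and
    ``rmsd`` is over all pairs under the best transform.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    qi = np.array([p[0] for p in pairs])
    ti = np.array([p[1] for p in pairs])
    P = query.coords[qi]
    Q = target.coords[ti]
    d0 = tm_d0(L_norm, config.d0_floor)
    cutoff = max(2.0 * d0, 4.5)

    best_tm = -1.0
    best_Rt: tuple[np.ndarray, np.ndarray] | None = None
    trace: list[float] = []

    def consider(R: np.ndarray, t: np.ndarray) -> float:
        nonlocal best_tm, best_Rt
        tm = _tm_of_transform(P, Q, R, t, L_norm, d0)
        if tm > best_tm:
            best_tm, best_Rt = tm, (R, t)
        return tm

    def refine(R: np.ndarray, t: np.ndarray) -> None:
        prev = consider(R, t)
        trace.append(best_tm)
        for _ in range(config.max_iterations):
            d = np.linalg.norm(P @ R.T + t - Q, axis=1)
            sel = d < cutoff
            if sel.sum() < 3:
                sel = np.argsort(d)[:3]
            R, t, _ = kabsch_superpose(P[sel], Q[sel])
            tm = consider(R, t)
            trace.append(best_tm)
            if abs(tm - prev) < config.convergence:
                break
            prev = tm

    R0, t0, _ = kabsch_superpose(P, Q)
    refine(R0, t0)
    w = config.seed_fragment_length
    if len(pairs) > w:
        for s in range(0, len(pairs) - w + 1, max(1, config.fragment_stride)):
            Rw, tw, _ = kabsch_superpose(P[s:s + w], Q[s:s + w])
            refine(Rw, tw)

    R, t = best_Rt  # type: ignore[misc]
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
    return best_tm, rmsd, R, t, trace


# ---------------------------------------------------------------------------
# DP alignment search

@njit(cache=True)
def _dp_align(S, gap):  # pragma: no cover - numba
    """Semi-global DP on similarity matrix S with flat gap penalty.

    Terminal gaps are free (borders start at 0); traceback ties prefer
    diagonal, then up, then left. Returns the matched index pairs.
    """
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            up = H[i - 1, j] + (gap if j != m else 0.0)
            left = H[i, j - 1] + (gap if i != n else 0.0)
            best = diag
            p = 0
            if up > best:
                best = up
                p = 1
            if left > best:
                best = left
                p = 2
            H[i, j] = best
            ptr[i, j] = p
    out_i = np.empty(min(n, m), dtype=np.int64)
    out_j = np.empty(min(n, m), dtype=np.int64)
    k = 0
    i, j = n, m
    while i > 0 and j > 0:
        p = ptr[i, j]
        if p == 0:
            out_i[k] = i - 1
            out_j[k] = j - 1
            k += 1
            i -= 1
            j -= 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    return out_i[:k][::-1].copy(), out_j[:k][::-1].copy()


def _optimize_tm_light(P: np.ndarray, Q: np.ndarray, qi: np.ndarray,
                       ti: np.ndarray, L_norm: int, d0: float,
                       max_iter: int = 10, tol: float = 1e-6
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """Cheap TM maximization for a fixed correspondence (Kabsch + close-
    subset iteration, no fragment seeds); used inside the DP search loop."""
    Pp, Qp = P[qi], Q[ti]
    cutoff = max(2.0 * d0, 4.5)
    R, t, _ = kabsch_superpose(Pp, Qp)
    best_tm = _tm_of_transform(Pp, Qp, R, t, L_norm, d0)
    best_Rt = (R, t)
    prev = best_tm
    for _ in range(max_iter):
        d = np.linalg.norm(Pp @ R.T + t - Qp, axis=1)
        sel = d < cutoff
        if sel.sum() < 3:
            sel = np.argsort(d)[:3]
        R, t, _ = kabsch_superpose(Pp[sel], Qp[sel])
        tm = _tm_of_transform(Pp, Qp, R, t, L_norm, d0)
        if tm > best_tm:
            best_tm, best_Rt = tm, (R, t)
        if abs(tm - prev) < tol:
            break
        prev = tm
    return best_tm, best_Rt[0], best_Rt[1]


def _score_matrix(P: np.ndarray, Q: np.ndarray, R: np.ndarray,
                  t: np.ndarray, d0: float) -> np.ndarray:
    moved = P @ R.T + t
    d2 = ((moved[:, None, :] - Q[None, :, :]) ** 2).sum(axis=2)
    return 1.0 / (1.0 + d2 / d0 ** 2)


def _tm_all_norms(query: StructureModel, target: StructureModel,
                  pairs: list[tuple[int, int]], config: AlignConfig):
    nq, nt = len(query), len(target)
    tm_q, rmsd_q, Rq, tq, _ = tm_from_pairs(query, target, pairs, nq, config)
    tm_t, rmsd_t, Rt, tt, _ = tm_from_pairs(query, target, pairs, nt, config)
    if nq <= nt:
        tm_s, rmsd, R, t = tm_q, rmsd_q, Rq, tq
    else:
        tm_s, rmsd, R, t = tm_t, rmsd_t, Rt, tt
    return tm_q, tm_t, tm_s, rmsd, R, t


def structure_align(query: StructureModel, target: StructureModel,
                    config: AlignConfig = DEFAULT_CONFIG) -> StructuralAlignment:
    """Heuristic optimal-TM structural alignment of two CA traces.

    Seeds from gapless threading at all offsets and from fragment-pair
    superpositions; the best seeds are expanded by iterative DP
    (score matrix under the current superposition -> new correspondence ->
    new TM-optimal superposition) to convergence. The reported alignment is
    the best by TM normalized to the shorter chain; all three
    normalizations are filled, each with its own d0. Deterministic for a
    fixed configuration.
    """
    P, Q = query.coords, target.coords
    n, m = len(P), len(Q)
    if n < 3 or m < 3:
        raise ValueError("both structures need at least 3 residues")
    L_short = min(n, m)
    d0 = tm_d0(L_short, config.d0_floor)

    # --- collect seed transforms, each scored by the TM of the diagonal
    # correspondence it implies (so threading and fragment seeds compare)
    seeds: list[tuple[float, np.ndarray, np.ndarray]] = []

    def diag_pairs(offset: int) -> tuple[np.ndarray, np.ndarray]:
        lo = max(0, -offset)
        hi = min(n, m - offset)
        qi = np.arange(lo, hi)
        return qi, qi + offset

    def add_seed(fit_qi: np.ndarray, fit_ti: np.ndarray, offset: int) -> None:
        R, t, _ = kabsch_superpose(P[fit_qi], Q[fit_ti])
        qi, ti = diag_pairs(offset)
        moved = P[qi] @ R.T + t
        d2 = ((moved - Q[ti]) ** 2).sum(axis=1)
        tm = float((1.0 / (1.0 + d2 / d0 ** 2)).sum() / L_short)
        seeds.append((tm, R, t))

    # (a) gapless threading of the shorter chain onto the longer
    for off in range(-(n - 3), m - 2):
        qi, ti = diag_pairs(off)
        if len(qi) >= 3:
            add_seed(qi, ti, off)

    # (b) fragment-pair superpositions on a strided grid
    w = min(config.seed_fragment_length, L_short)
    if w >= 3:
        stride = max(1, config.fragment_stride)
        for i0 in range(0, n - w + 1, stride):
            for j0 in range(0, m - w + 1, stride):
                add_seed(np.arange(i0, i0 + w), np.arange(j0, j0 + w),
                         j0 - i0)

    seeds.sort(key=lambda s: -s[0])

    # --- iterative DP refinement of the best seeds
    best: tuple[float, list[tuple[int, int]]] | None = None
    for tm0, R, t in seeds[:config.max_refined_seeds]:
        prev_tm = -1.0
        prev_pairs: tuple = ()
        for _ in range(config.max_iterations):
            S = _score_matrix(P, Q, R, t, d0)
            oi, oj = _dp_align(S, config.gap_open)
            if len(oi) < 3:
                break
            tm, R, t = _optimize_tm_light(P, Q, oi, oj, L_short, d0,
                                          tol=config.convergence)
            if best is None or tm > best[0]:
                best = (tm, list(zip(oi.tolist(), oj.tolist())))
            key = (oi.tobytes(), oj.tobytes())
            if abs(tm - prev_tm) < config.convergence or key == prev_pairs:
                break
            prev_tm, prev_pairs = tm, key

    if best is None:  # no DP seed produced ≥3 pairs; fall back to threading
        off_pairs = [(i, i) for i in range(L_short)]
        best = (0.0, off_pairs)

    tm_q, tm_t, tm_s, rmsd, R, t = _tm_all_norms(query, target, best[1], config)
    return StructuralAlignment(
        query_id=query.protein_id, target_id=target.protein_id,
        pairs=best[1], rotation=R, translation=t, rmsd=rmsd,
        tm_query=tm_q, tm_target=tm_t, tm_shorter=tm_s,
    )


def all_vs_all(models: Sequence[StructureModel],
               config: AlignConfig = DEFAULT_CONFIG) -> list[StructuralAlignment]:
    """Align every unordered pair of models (query = lexicographically
    smaller id); diagonal omitted."""
    if len(models) < 2:
        raise ValueError("all-vs-all needs at least 2 models")
    by_id = sorted(models, key=lambda m: m.protein_id)
    return [structure_align(a, b, config) for a, b in combinations(by_id, 2)]


def tm_matrix(alignments: Sequence[StructuralAlignment]) -> "object":
    """Square tm_shorter matrix view of an all-vs-all result (pandas)."""
    import pandas as pd

    ids = sorted({a.query_id for a in alignments} | {a.target_id for a in alignments})
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for a in alignments:
        mat.loc[a.query_id, a.target_id] = a.tm_shorter
        mat.loc[a.target_id, a.query_id] = a.tm_shorter
    return mat
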