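"""Pairwise sequence alignment, greedy identity clustering, and the
sequence-divergence exclusion filter.

These fill the roles USEARCH and BLASTP play at catalog scale, at desk
scale and with fully deterministic behaviour:

* :func:`global_align` / :func:`local_align` — Needleman-Wunsch and
  Smith-Waterman with affine gaps (Gotoh), deterministic traceback
  preferring diagonal over up over left.
* :func:`karlin_altschul_evalue` — ``E = K * m * n * exp(-lambda * S)``,
  the extreme-value statistics behind a BLAST E-value threshold.
* :func:`greedy_cluster` — greedy centroid clustering at an identity
  threshold, the operation behind "clustered at 95% identity ... with
  centroids being the representative sequence".
* :func:`divergence_filter` — exclude candidates with detectable sequence
  similarity to any reference (identity > 30% or E-value < 0.1), keeping
  only remote-homolog territory for the structural screens.

Gap convention: a gap of length k costs ``gap_open + gap_extend * k``
(BLAST "existence/extension" semantics). Scoring defaults are BLOSUM62
with open 11 / extend 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .io_formats import ProteinRecord

_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}

_NEG = -1e30  # -inf stand-in that survives float32 arithmetic


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (positive costs)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    @property
    def matrix(self) -> np.ndarray:
        return _load_matrix(self.matrix_name)


@lru_cache(maxsize=4)
def _load_matrix(name: str) -> np.ndarray:
    raw = substitution_matrices.load(name)
    mat = np.zeros((len(_ALPHABET), len(_ALPHABET)))
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            mat[i, j] = raw[a, b]
    return mat


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class KarlinAltschulParams:
    """Extreme-value parameters of the local-alignment score distribution.

    Defaults are the standard gapped BLOSUM62 (open 11 / extend 1)
    constants.
    """

    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


DEFAULT_KA = KarlinAltschulParams()


@dataclass
class PairwiseSeqAlignment:
    """One pairwise alignment with identity bookkeeping.

    ``pairs`` lists aligned columns as (index in a, index in b), with
    ``None`` marking a gap on that side. ``identity`` is identical columns
    over all alignment columns (terminal gaps included for global
    alignments; a local alignment has no terminal gaps by construction).
    """

    query_id: str
    target_id: str
    pairs: list[tuple[int | None, int | None]]
    n_identical: int
    n_columns: int
    score: float
    evalue: float = math.inf

    @property
    def identity(self) -> float:
        return self.n_identical / self.n_columns if self.n_columns else 0.0


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} outside alphabet") from None


@njit(cache=True)
def _gotoh_fill(a, b, sub, gap_open, gap_extend, local):  # pragma: no cover
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in b (consumes a; "up")
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in a (consumes b; "left")
    # pointers: 0=diag(M), 1=up(Ix), 2=left(Iy); per-state provenance
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    if not local:
        for i in range(1, n + 1):
            Ix[i, 0] = -(gap_open + gap_extend * i)
            ptrX[i, 0] = 1
        for j in range(1, m + 1):
            Iy[0, j] = -(gap_open + gap_extend * j)
            ptrY[0, j] = 2
    else:
        for i in range(n + 1):
            M[i, 0] = 0.0
        for j in range(m + 1):
            M[0, j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            # M: diagonal move from the best state at (i-1, j-1)
            best = M[i - 1, j - 1]
            ptr = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                ptr = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                ptr = 2
            val = best + s
            if local and val < 0.0:
                val = 0.0
            M[i, j] = val
            ptrM[i, j] = ptr
            # Ix: gap in b, move down; open from M, extend from Ix
            open_x = M[i - 1, j] - (gap_open + gap_extend)
            ext_x = Ix[i - 1, j] - gap_extend
            if open_x >= ext_x:
                Ix[i, j] = open_x
                ptrX[i, j] = 0
            else:
                Ix[i, j] = ext_x
                ptrX[i, j] = 1
            # Iy: gap in a, move right; open from M, extend from Iy
            open_y = M[i, j - 1] - (gap_open + gap_extend)
            ext_y = Iy[i, j - 1] - gap_extend
            if open_y >= ext_y:
                Iy[i, j] = open_y
                ptrY[i, j] = 0
            else:
                Iy[i, j] = ext_y
                ptrY[i, j] = 2
    return M, Ix, Iy, ptrM, ptrX, ptrY


def _traceback(a_seq: str, b_seq: str, M, Ix, Iy, ptrM, ptrX, ptrY,
               i: int, j: int, state: int, local: bool
               ) -> list[tuple[int | None, int | None]]:
    pairs: list[tuple[int | None, int | None]] = []
    while i > 0 or j > 0:
        if local and state == 0 and M[i, j] == 0.0:
            break
        if state == 0:
            prev = ptrM[i, j]
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            state = prev
        elif state == 1:
            prev = ptrX[i, j]
            pairs.append((i - 1, None))
            i -= 1
            state = prev
        else:
            prev = ptrY[i, j]
            pairs.append((None, j - 1))
            j -= 1
            state = prev
    pairs.reverse()
    return pairs


def _finish(a_id, b_id, a_seq, b_seq, pairs, score) -> PairwiseSeqAlignment:
    n_ident = sum(
        1 for i, j in pairs
        if i is not None and j is not None and a_seq[i] == b_seq[j]
    )
    return PairwiseSeqAlignment(
        query_id=a_id, target_id=b_id, pairs=pairs,
        n_identical=n_ident, n_columns=len(pairs), score=float(score),
    )


def global_align(a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING,
                 a_id: str = "a", b_id: str = "b") -> PairwiseSeqAlignment:
    """Optimal global (Needleman-Wunsch) alignment under affine gaps.

    Identity counts identical columns over ALL alignment columns, terminal
    gaps included — the strict denominator used for clustering. Traceback
    ties prefer diagonal, then up (gap in b), then left.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ea, eb = _encode(a), _encode(b)
    M, Ix, Iy, pM, pX, pY = _gotoh_fill(
        ea, eb, scoring.matrix, scoring.gap_open, scoring.gap_extend, False)
    n, m = len(a), len(b)
    score = max(M[n, m], Ix[n, m], Iy[n, m])
    if M[n, m] == score:
        state = 0
    elif Ix[n, m] == score:
        state = 1
    else:
        state = 2
    pairs = _traceback(a, b, M, Ix, Iy, pM, pX, pY, n, m, state, False)
    return _finish(a_id, b_id, a, b, pairs, score)


def local_align(a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING,
                ka: KarlinAltschulParams = DEFAULT_KA,
                db_residues: int | None = None,
                a_id: str = "a", b_id: str = "b") -> PairwiseSeqAlignment:
    """Optimal local (Smith-Waterman) alignment; E-value attached.

    ``db_residues`` is the effective database size n in the Karlin-Altschul
    formula; it defaults to len(b) (single-target search).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ea, eb = _encode(a), _encode(b)
    M, Ix, Iy, pM, pX, pY = _gotoh_fill(
        ea, eb, scoring.matrix, scoring.gap_open, scoring.gap_extend, True)
    # first (row-major) occurrence of the maximum, for determinism
    flat = int(np.argmax(M))
    i, j = divmod(flat, M.shape[1])
    score = M[i, j]
    pairs = _traceback(a, b, M, Ix, Iy, pM, pX, pY, i, j, 0, True) if score > 0 else []
    aln = _finish(a_id, b_id, a, b, pairs, score)
    n_db = db_residues if db_residues is not None else len(b)
    aln.evalue = karlin_altschul_evalue(aln.score, len(a), n_db, ka)
    return aln


def karlin_altschul_evalue(score: float, m: int, n: int,
                           params: KarlinAltschulParams = DEFAULT_KA) -> float:
    """Expected number of chance local alignments scoring ≥ ``score``.

    ``E = K * m * n * exp(-lambda * score)`` for query length m against a
    database of n residues.
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be ≥ 1")
    return params.K * m * n * math.exp(-params.lam * score)


# ---------------------------------------------------------------------------
# Clustering

@dataclass
class ProteinCluster:
    cluster_id: str
    centroid_id: str
    member_ids: list[str] = field(default_factory=list)
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.centroid_id not in self.member_ids:
            raise ValueError("centroid must be a member of its cluster")


def greedy_cluster(records: Sequence[ProteinRecord], threshold: float,
                   scoring: ScoringScheme = DEFAULT_SCORING
                   ) -> list[ProteinCluster]:
    """Greedy centroid clustering at a global-identity threshold.

    Records are seeded longest-first (ties by id); each record joins the
    first existing centroid (in creation order) whose global-alignment
    identity reaches the threshold, else founds a new cluster. The output
    partitions the input and is fully deterministic.
    """
    if not records:
        raise ValueError("no records to cluster")
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    order = sorted(records, key=lambda r: (-r.length, r.protein_id))
    clusters: list[ProteinCluster] = []
    centroid_seqs: list[str] = []
    for rec in order:
        placed = False
        for cl, cseq in zip(clusters, centroid_seqs):
            aln = global_align(rec.sequence, cseq, scoring)
            if aln.identity >= threshold:
                cl.member_ids.append(rec.protein_id)
                placed = True
                break
        if not placed:
            clusters.append(ProteinCluster(
                cluster_id=f"cluster_{len(clusters):05d}",
                centroid_id=rec.protein_id,
                member_ids=[rec.protein_id],
                threshold=threshold,
            ))
            centroid_seqs.append(rec.sequence)
    return clusters


# ---------------------------------------------------------------------------
# Divergence exclusion (the remote-homolog gate)

@dataclass(frozen=True)
class Exclusion:
    candidate_id: str
    reference_id: str
    criterion: str  # "identity" or "evalue"
    value: float


def divergence_filter(candidates: Sequence[ProteinRecord],
                      references: Sequence[ProteinRecord],
                      max_identity: float = 0.30,
                      evalue_cut: float = 0.1,
                      scoring: ScoringScheme = DEFAULT_SCORING,
                      ka: KarlinAltschulParams = DEFAULT_KA,
                      hit_evalue: float = 10.0,
                      hsp_min_cover: float = 0.5,
                      ) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, Exclusion]]]:
    """Exclude candidates with detectable sequence similarity to any reference.

    A candidate is excluded as soon as one reference yields a local
    alignment with identity > ``max_identity`` OR E-value < ``evalue_cut``;
    the triggering reference and criterion are recorded.

    The identity criterion only applies to alignments that carry homology
    evidence at all: the HSP must be a reportable hit (E ≤ ``hit_evalue``,
    default 10, the BLASTP reporting threshold) and must span at least
    ``hsp_min_cover`` of the shorter of the two sequences. The optimal
    local alignment of two unrelated proteins is almost always a
    few-residue chance match with high percent identity; without the span
    condition the literal identity rule would discard essentially every
    candidate, related or not. E-values use the summed reference lengths
    as database size.
    """
    if not references:
        raise ValueError("reference set is empty")
    db_n = sum(r.length for r in references)
    retained: list[ProteinRecord] = []
    excluded: list[tuple[ProteinRecord, Exclusion]] = []
    for cand in candidates:
        verdict: Exclusion | None = None
        for ref in references:
            aln = local_align(cand.sequence, ref.sequence, scoring, ka,
                              db_residues=db_n,
                              a_id=cand.protein_id, b_id=ref.protein_id)
            min_cols = hsp_min_cover * min(cand.length, ref.length)
            if (aln.n_columns >= min_cols and aln.evalue <= hit_evalue
                    and aln.identity > max_identity):
                verdict = Exclusion(cand.protein_id, ref.protein_id,
                                    "identity", aln.identity)
                break
            if aln.evalue < evalue_cut:
                verdict = Exclusion(cand.protein_id, ref.protein_id,
                                    "evalue", aln.evalue)
                break
        if verdict is None:
            retained.append(cand)
        else:
            excluded.append((cand, verdict))
    return retained, excluded
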