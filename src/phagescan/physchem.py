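"""Peptide net charge, isoelectric point, and the acidity filter.

Experimentally validated anti-CRISPR proteins are predominantly acidic, so
candidate screening discards sequences whose isoelectric point (pI) exceeds
7. The charge model is the standard Henderson-Hasselbalch ampholyte sum:
at a given pH each basic group (N-terminus, K, R, H) contributes
``+1 / (1 + 10**(pH - pKa))`` and each acidic group (C-terminus, D, E, C, Y)
contributes ``-1 / (1 + 10**(pKa - pH))``. The net charge is strictly
decreasing in pH, so the pI is the unique root, found here by bisection.

Absolute pI values depend on the pKa table; the default is the EMBOSS set.
The ≤7 / >7 partition is robust to the table choice for strongly acidic or
basic sequences, which is what the screen relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_formats import ProteinRecord

_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class PkaTable:
    """Acid-dissociation constants for the ionizable groups of a peptide.

    Defaults are the EMBOSS pKa values.
    """

    N_term: float = 8.6
    C_term: float = 3.6
    K: float = 10.8
    R: float = 12.5
    H: float = 6.5
    D: float = 3.9
    E: float = 4.1
    C: float = 8.5
    Y: float = 10.1

    def __post_init__(self) -> None:
        for name in ("N_term", "C_term", *_BASIC, *_ACIDIC):
            v = getattr(self, name)
            if not (0 < v < 14):
                raise ValueError(f"pKa {name}={v} outside (0, 14)")


DEFAULT_PKA = PkaTable()

_KNOWN = frozenset("ACDEFGHIKLMNPQRSTVWYX")


def net_charge(sequence: str, pH: float, pka: PkaTable = DEFAULT_PKA) -> float:
    """Net charge of a peptide at ``pH`` in elementary charge units.

    X residues carry no ionizable group. Raises on any other character
    outside the one-letter alphabet, or on pH outside (0, 14).
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not (0 < pH < 14):
        raise ValueError(f"pH {pH} outside (0, 14)")
    bad = set(sequence) - _KNOWN
    if bad:
        raise ValueError(f"unknown residue(s) {sorted(bad)} in sequence")

    def basic(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pk))

    def acidic(pk: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pk - pH))

    charge = basic(pka.N_term) + acidic(pka.C_term)
    for aa in _BASIC:
        n = sequence.count(aa)
        if n:
            charge += n * basic(getattr(pka, aa))
    for aa in _ACIDIC:
        n = sequence.count(aa)
        if n:
            charge += n * acidic(getattr(pka, aa))
    return charge


def isoelectric_point(sequence: str, pka: PkaTable = DEFAULT_PKA,
                      tol: float = 1e-4) -> float:
    """pH at which the peptide's net charge vanishes, by bisection on [0, 14].

    The charge is strictly monotone decreasing in pH and the termini
    guarantee one basic and one acidic group, so the root exists and is
    unique. Raises if |charge| has not fallen below ``tol`` after 100
    iterations (cannot happen for a sane pKa table; guards corrupt input).
    """
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"pI bisection did not converge to |charge| < {tol} in 100 iterations"
    )


def pi_filter(records: Sequence[ProteinRecord], max_pi: float = 7.0,
              pka: PkaTable = DEFAULT_PKA
              ) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition records into (pI ≤ max_pi, pI > max_pi).

    A pI of exactly ``max_pi`` is retained: the screen discards only
    strictly basic sequences.
    """
    retained: list[ProteinRecord] = []
    excluded: list[ProteinRecord] = []
    for rec in records:
        if isoelectric_point(rec.sequence, pka) <= max_pi:
            retained.append(rec)
        else:
            excluded.append(rec)
    return retained, excluded
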