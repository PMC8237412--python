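"""Pairwise dN/dS by the Pamilo-Bianchi-Li (PBL) counting method.

The method partitions codon positions into 0-, 2- and 4-fold degeneracy
classes, tallies transition- and transversion-type differences per class,
applies the Kimura two-parameter (K2P) correction within each class, and
combines the corrected components into a nonsynonymous distance dN (per
nonsynonymous site) and a synonymous distance dS (per synonymous site):

    A_i, B_i = K2P components of (P_i, Q_i) = (S_i/L_i, V_i/L_i)
    dS = (L2*A2 + L4*A4) / (L2 + L4) + B4
    dN = A0 + (L0*B0 + L2*B2) / (L0 + L2)

Conventions (documented in the methods note):

* Degeneracy of a position is taken from each sequence's own codon and the
  two classifications are averaged, so a site that is 2-fold in one sequence
  and 4-fold in the other contributes 0.5 to L2 and 0.5 to L4, and an
  observed difference splits its tally the same way.
* At 2-fold sites the tally is routed by synonymy of the single-base change
  (synonymous -> S2, nonsynonymous -> V2), so the rare synonymous
  transversion at a 2-fold site is counted as synonymous (Li-1993-style).
  At 0- and 4-fold sites S/V is the plain transition/transversion split.
* Differing sites are classified transition vs transversion from the base
  pair alone; no pathway enumeration is done for multi-hit codons.
* Codons containing gaps/ambiguity, or that are stops in either sequence,
  are excluded pairwise.

Saturation of a K2P logarithm flags the affected distance invalid rather
than raising: the population layer excludes and counts invalid pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np

from .codon_code import (
    BASES,
    CODONS,
    GeneticCode,
    degeneracy,
    is_synonymous_change,
    is_transition,
)
from .errors import ComputationError, InputError

_CLASS_POS = {0: 0, 2: 1, 4: 2}  # degeneracy class -> column index


@dataclass(frozen=True)
class PairwiseCounts:
    """PBL site and difference tallies for one sequence pair.

    ``L`` values are mean site counts per degeneracy class (averaged over the
    two sequences, so they may be half-integral); ``S``/``V`` are the
    transition-routed and transversion-routed difference counts per class.
    """

    L0: float
    L2: float
    L4: float
    S0: float
    S2: float
    S4: float
    V0: float
    V2: float
    V4: float
    codons_compared: int

    def __post_init__(self) -> None:
        if self.codons_compared <= 0:
            raise ComputationError("no comparable codons in pair")
        total = self.L0 + self.L2 + self.L4
        if not math.isclose(total, 3 * self.codons_compared, rel_tol=0, abs_tol=1e-9):
            raise InputError(
                f"site classes sum to {total}, expected {3 * self.codons_compared}"
            )


class K2PComponents(NamedTuple):
    """K2P transition (A) and transversion (B) distance components."""

    A: float
    B: float
    valid: bool


@dataclass(frozen=True)
class PairwiseDnDs:
    """PBL distances and their per-class K2P components for one pair."""

    dN: float
    dS: float
    A0: float
    A2: float
    A4: float
    B0: float
    B2: float
    B4: float
    valid_dN: bool
    valid_dS: bool


# ---------------------------------------------------------------------------
# precomputed per-code lookup tables over ordered codon pairs
# ---------------------------------------------------------------------------


class PairTables:
    """Vectorised lookup tables for one genetic code.

    ``L[c]`` gives the per-class site contribution of codon ``c`` (columns
    0/2/4-fold); ``S[a*64+b]`` and ``V[a*64+b]`` give the per-class routed
    difference contributions of the ordered codon pair, already averaged over
    the two sequences' classifications. ``sense[c]`` marks sense codons.
    """

    def __init__(self, code: GeneticCode):
        self.code = code
        n = len(CODONS)
        self.sense = np.zeros(n, dtype=bool)
        self.L = np.zeros((n, 3))
        for i, c in enumerate(CODONS):
            if code.is_stop(c):
                continue
            self.sense[i] = True
            for cls in degeneracy(c, code):
                self.L[i, _CLASS_POS[cls]] += 1.0
        self.S = np.zeros((n * n, 3))
        self.V = np.zeros((n * n, 3))
        sense_codons = [c for c in CODONS if not code.is_stop(c)]
        idx = {c: i for i, c in enumerate(CODONS)}
        for a in sense_codons:
            for b in sense_codons:
                if a == b:
                    continue
                k = idx[a] * n + idx[b]
                for pos in range(3):
                    if a[pos] == b[pos]:
                        continue
                    ts = is_transition(a[pos], b[pos])
                    for this, other in ((a, b), (b, a)):
                        cls = degeneracy(this, code)[pos]
                        if cls == 2:
                            syn = is_synonymous_change(this, pos, other[pos], code)
                            target = self.S if syn else self.V
                        else:
                            target = self.S if ts else self.V
                        target[k, _CLASS_POS[cls]] += 0.5


@lru_cache(maxsize=4)
def pair_tables(table_id: int) -> PairTables:
    from .codon_code import build_code

    return PairTables(build_code(table_id))


# ---------------------------------------------------------------------------
# sequence encoding
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, -1, dtype=np.int32)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode_codons(seq: str) -> np.ndarray:
    """Encode a nucleotide string as codon indices (0..63; -1 = ambiguous/gap).

    Length must be a multiple of 3.
    """
    if len(seq) % 3:
        raise InputError(f"sequence length {len(seq)} is not a multiple of 3")
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    tri = arr.reshape(-1, 3)
    out = tri[:, 0] * 16 + tri[:, 1] * 4 + tri[:, 2]
    out[(tri < 0).any(axis=1)] = -1
    return out


def encode_alignment(sequences: Sequence[str]) -> np.ndarray:
    """Stack :func:`encode_codons` over equal-length sequences (rows)."""
    rows = [encode_codons(s) for s in sequences]
    if len({r.size for r in rows}) > 1:
        raise InputError("sequences have unequal codon counts")
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# counting and distances
# ---------------------------------------------------------------------------


def _as_encoded(seq, tables: PairTables) -> np.ndarray:
    if isinstance(seq, str):
        return encode_codons(seq)
    return np.asarray(seq)


def count_pair(seq_a, seq_b, code: GeneticCode) -> PairwiseCounts:
    """Tally PBL sites and differences for one frame-aligned pair.

    Accepts nucleotide strings or pre-encoded codon-index arrays of equal
    length. Codons that are ambiguous or stop in either sequence are excluded
    pairwise; zero comparable codons raises :class:`ComputationError`.
    """
    tables = pair_tables(code.table_id)
    a = _as_encoded(seq_a, tables)
    b = _as_encoded(seq_b, tables)
    if a.size != b.size:
        raise InputError("sequences have unequal codon counts")
    ok = (a >= 0) & (b >= 0)
    ok &= tables.sense[np.where(ok, a, 0)] & tables.sense[np.where(ok, b, 0)]
    a, b = a[ok], b[ok]
    if a.size == 0:
        raise ComputationError("zero comparable codons in pair")
    L = (tables.L[a] + tables.L[b]).sum(axis=0) / 2.0
    k = a * 64 + b
    S = tables.S[k].sum(axis=0)
    V = tables.V[k].sum(axis=0)
    return PairwiseCounts(
        L0=L[0], L2=L[1], L4=L[2],
        S0=S[0], S2=S[1], S4=S[2],
        V0=V[0], V2=V[1], V4=V[2],
        codons_compared=int(a.size),
    )


def k2p_components(P: float, Q: float) -> K2PComponents:
    """K2P transition/transversion components for proportions (P, Q).

        A = 1/2 ln(1/(1-2P-Q)) - 1/4 ln(1/(1-2Q));  B = 1/2 ln(1/(1-2Q))

    Outside the logarithm domain (1-2P-Q <= 0 or 1-2Q <= 0) the pair is
    saturated: components are returned as NaN with ``valid=False``.
    """
    if P < 0 or Q < 0 or P + Q > 1:
        raise InputError(f"invalid proportions P={P}, Q={Q}")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PComponents(math.nan, math.nan, False)
    A = 0.5 * math.log(1.0 / w1) - 0.25 * math.log(1.0 / w2)
    B = 0.5 * math.log(1.0 / w2)
    return K2PComponents(A, B, True)


def _class_components(L: float, S: float, V: float) -> K2PComponents:
    if L <= 0:
        # empty class: contributes zero with zero weight
        return K2PComponents(0.0, 0.0, True)
    return k2p_components(S / L, V / L)


def pair_dnds(counts: PairwiseCounts) -> PairwiseDnDs:
    """PBL dN and dS from class tallies (see module docstring for formulas)."""
    c = counts
    if c.L2 + c.L4 <= 0:
        raise ComputationError("no synonymous sites (L2 + L4 = 0)")
    if c.L0 + c.L2 <= 0:
        raise ComputationError("no nonsynonymous sites (L0 + L2 = 0)")
    A0, B0, ok0 = _class_components(c.L0, c.S0, c.V0)
    A2, B2, ok2 = _class_components(c.L2, c.S2, c.V2)
    A4, B4, ok4 = _class_components(c.L4, c.S4, c.V4)
    valid_dS = ok2 and ok4
    valid_dN = ok0 and ok2
    dS = (c.L2 * A2 + c.L4 * A4) / (c.L2 + c.L4) + B4 if valid_dS else math.nan
    dN = A0 + (c.L0 * B0 + c.L2 * B2) / (c.L0 + c.L2) if valid_dN else math.nan
    return PairwiseDnDs(
        dN=dN, dS=dS,
        A0=A0, A2=A2, A4=A4, B0=B0, B2=B2, B4=B4,
        valid_dN=valid_dN, valid_dS=valid_dS,
    )


def pair_dnds_from_seqs(seq_a, seq_b, code: GeneticCode) -> PairwiseDnDs:
    """Convenience: :func:`count_pair` then :func:`pair_dnds`."""
    return pair_dnds(count_pair(seq_a, seq_b, code))


def dnds_matrices(sequences: Sequence[str], ids: Sequence[str], code: GeneticCode):
    """Pairwise dN and dS matrices as DataFrames (ids x ids), NaN where invalid."""
    import pandas as pd

    enc = encode_alignment(sequences)
    n = enc.shape[0]
    dn = np.zeros((n, n))
    ds = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = pair_dnds(count_pair(enc[i], enc[j], code))
            dn[i, j] = dn[j, i] = res.dN if res.valid_dN else math.nan
            ds[i, j] = ds[j, i] = res.dS if res.valid_dS else math.nan
    return (
        pd.DataFrame(dn, index=list(ids), columns=list(ids)),
        pd.DataFrame(ds, index=list(ids), columns=list(ids)),
    )
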