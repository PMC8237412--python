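"""Independent brute-force PBL dN/dS oracle for cross-checking mitoload.pbl.

Deliberately shares no code with the package: degeneracy, routing and K2P
are re-derived per site directly from biopython's codon tables with plain
Python loops. Slow but transparent.
"""

import math

from Bio.Data import CodonTable

BASES = "ACGT"
PURINES = {"A", "G"}


def _aa(codon, tab):
    if codon in tab.stop_codons:
        return "*"
    return tab.forward_table.get(codon)  # None for ambiguous


def _degeneracy(codon, pos, tab):
    syn = 0
    for x in BASES:
        if x == codon[pos]:
            continue
        m = codon[:pos] + x + codon[pos + 1 :]
        if _aa(m, tab) not in (None, "*") and _aa(m, tab) == _aa(codon, tab):
            syn += 1
    return 4 if syn == 3 else (0 if syn == 0 else 2)


def _k2p(P, Q):
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return None, None
    return (
        0.5 * math.log(1 / w1) - 0.25 * math.log(1 / w2),
        0.5 * math.log(1 / w2),
    )


def oracle_counts(seq_a, seq_b, table_id=2):
    """Per-class (L, S, V) dicts keyed by degeneracy class, plus codon count."""
    tab = CodonTable.unambiguous_dna_by_id[table_id]
    L = {0: 0.0, 2: 0.0, 4: 0.0}
    S = {0: 0.0, 2: 0.0, 4: 0.0}
    V = {0: 0.0, 2: 0.0, 4: 0.0}
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper()
        if _aa(ca, tab) in (None, "*") or _aa(cb, tab) in (None, "*"):
            continue
        n_codons += 1
        for pos in range(3):
            L[_degeneracy(ca, pos, tab)] += 0.5
            L[_degeneracy(cb, pos, tab)] += 0.5
            if ca[pos] == cb[pos]:
                continue
            ts = (ca[pos] in PURINES) == (cb[pos] in PURINES)
            for this, other in ((ca, cb), (cb, ca)):
                cls = _degeneracy(this, pos, tab)
                if cls == 2:
                    m = this[:pos] + other[pos] + this[pos + 1 :]
                    syn = (
                        _aa(m, tab) not in (None, "*")
                        and _aa(m, tab) == _aa(this, tab)
                    )
                    (S if syn else V)[2] += 0.5
                else:
                    (S if ts else V)[cls] += 0.5
    return L, S, V, n_codons


def oracle_dnds(seq_a, seq_b, table_id=2):
    """(dN, dS) with None for saturated/undefined components."""
    L, S, V, n = oracle_counts(seq_a, seq_b, table_id)
    if n == 0:
        return None, None
    comp = {}
    for cls in (0, 2, 4):
        if L[cls] > 0:
            comp[cls] = _k2p(S[cls] / L[cls], V[cls] / L[cls])
        else:
            comp[cls] = (0.0, 0.0)
    dS = dN = None
    A2, B2 = comp[2]
    A4, B4 = comp[4]
    A0, B0 = comp[0]
    if L[2] + L[4] > 0 and A2 is not None and A4 is not None:
        dS = (L[2] * A2 + L[4] * A4) / (L[2] + L[4]) + B4
    if L[0] + L[2] > 0 and A0 is not None and B2 is not None:
        dN = A0 + (L[0] * B0 + L[2] * B2) / (L[0] + L[2])
    return dN, dS
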