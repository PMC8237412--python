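"""Breed age from within-breed coalescence distance.

The age of a breed is taken as the time to the most recent common ancestor
of its sampled mitogenomes: a coalescence distance in substitutions per
site, divided by the per-site per-year mitochondrial mutation rate
(default 2.043e-8). Two distance-based height estimators are provided:

* ``upgma_root`` (default): root height of the UPGMA tree built from the
  K2P pairwise distance matrix — the natural estimator for an ultrametric
  (clock-like) intraspecific genealogy;
* ``half_mean_pairwise``: half the mean off-diagonal pairwise distance.

Both equal d/2 for a two-sequence breed. The estimator tag is recorded in
every output so results are never conflated with model-based (Bayesian
coalescent) ages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform

from .errors import ComputationError, InputError
from .sequence_io import CodonAlignment

DEFAULT_MU = 2.043e-8  # substitutions per site per year
_METHODS = ("upgma_root", "half_mean_pairwise")


@dataclass(frozen=True)
class AgeEstimate:
    """Coalescence distance (subs/site) and its conversion to years."""

    breed: str
    coalescence_distance: float
    mu: float
    age_years: float
    method: str
    n_samples: int


# ---------------------------------------------------------------------------
# K2P nucleotide distances
# ---------------------------------------------------------------------------

_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def k2p_distance(seq_a: str | np.ndarray, seq_b: str | np.ndarray) -> float:
    """Kimura 2-parameter distance with pairwise deletion of ambiguous sites.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q), with P and Q the observed
    transition and transversion proportions. Saturation (log argument <= 0)
    raises :class:`ComputationError` — unrealistic within a species.
    """
    a = _encode(seq_a)
    b = _encode(seq_b)
    if a.size != b.size:
        raise InputError("sequences have unequal lengths")
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    if n == 0:
        raise ComputationError("no comparable sites")
    diff = ok & (a != b)
    # bases encoded A=0 C=1 G=2 T=3: transition iff both purine (0,2) or both
    # pyrimidine (1,3), i.e. same parity
    ts = int((diff & ((a % 2) == (b % 2))).sum())
    tv = int(diff.sum()) - ts
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ComputationError("K2P saturation (intraspecific data should not saturate)")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def _encode(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def whole_alignment_distances(sequences: Sequence[str]) -> np.ndarray:
    """Symmetric K2P distance matrix over all aligned sites of >= 2 sequences."""
    if len(sequences) < 2:
        raise InputError("distance matrix needs at least 2 sequences")
    enc = [_encode(s) for s in sequences]
    n = len(enc)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance(enc[i], enc[j])
    return d


# ---------------------------------------------------------------------------
# coalescence height and age
# ---------------------------------------------------------------------------


def coalescence_distance(matrix: np.ndarray, method: str = "upgma_root") -> float:
    """Height of the sample's common ancestor, in substitutions per site.

    ``upgma_root``: root height of the UPGMA (average-linkage) tree;
    ``half_mean_pairwise``: mean off-diagonal distance / 2.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.ndim != 2 or matrix.shape[1] != n:
        raise InputError("distance matrix must be square")
    if n < 2:
        raise InputError("coalescence distance needs n >= 2")
    if method == "half_mean_pairwise":
        off = matrix[np.triu_indices(n, k=1)]
        return float(off.mean() / 2.0) + 0.0  # + 0.0 normalises -0.0
    if method == "upgma_root":
        if n == 2:
            return float(matrix[0, 1] / 2.0)
        linkage = average(squareform(matrix, checks=False))
        return float(linkage[-1, 2] / 2.0) + 0.0
    raise InputError(f"unknown method {method!r}; choose from {_METHODS}")


def upgma_newick(matrix: np.ndarray, labels: Sequence[str]) -> str:
    """UPGMA tree as a newick string (branch lengths in subs/site)."""
    matrix = np.asarray(matrix, dtype=float)
    linkage = average(squareform(matrix, checks=False))
    root = to_tree(linkage)

    def walk(node, parent_height):
        height = node.dist / 2.0
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height - 0.0:.10g}"
        left = walk(node.left, height)
        right = walk(node.right, height)
        return f"({left},{right}):{parent_height - height:.10g}"

    height = root.dist / 2.0
    left = walk(root.left, height)
    right = walk(root.right, height)
    return f"({left},{right});"


def age_years(distance: float, mu: float = DEFAULT_MU) -> float:
    """Convert a coalescence distance (subs/site) into years: distance / mu."""
    if mu <= 0:
        raise InputError("mutation rate mu must be > 0")
    if distance < 0:
        raise InputError("coalescence distance must be >= 0")
    return distance / mu


def estimate_breed_ages(
    alignment: CodonAlignment,
    mu: float = DEFAULT_MU,
    method: str = "upgma_root",
    breeds: Sequence[str] | None = None,
) -> tuple[list[AgeEstimate], pd.DataFrame]:
    """Per-breed coalescence distance and age for every breed with >= 2 samples.

    Returns (estimates, tidy table). Breeds with fewer than two samples are
    skipped (no within-breed genealogy to measure).
    """
    estimates = []
    for breed in breeds if breeds is not None else alignment.breeds():
        idx = alignment.rows_for_breed(breed)
        if len(idx) < 2:
            continue
        seqs = [alignment.sequences[i] for i in idx]
        dist = coalescence_distance(whole_alignment_distances(seqs), method)
        estimates.append(
            AgeEstimate(
                breed=breed,
                coalescence_distance=dist,
                mu=mu,
                age_years=age_years(dist, mu),
                method=method,
                n_samples=len(idx),
            )
        )
    table = pd.DataFrame(
        [
            {
                "breed": e.breed, "n": e.n_samples,
                "coalescence_distance": e.coalescence_distance,
                "mu": e.mu, "age_years": e.age_years, "method": e.method,
            }
            for e in estimates
        ]
    )
    return estimates, table
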