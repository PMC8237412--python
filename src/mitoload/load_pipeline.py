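"""Per-breed deleterious mutation load from a codon alignment.

For each breed the pipeline estimates nucleotide diversities at
nonsynonymous (piN) and synonymous (piS) sites as unweighted means of PBL
pairwise distances over all within-breed pairs, their ratio

    omega_P = piN / piS,

the interspecies divergence ratio against an outgroup (here cow vs bison)

    omega_S = dN / dS  (means over ingroup x outgroup pairs),

and the fraction of segregating nonsynonymous variants that are deleterious

    delta = (omega_P - omega_S) / omega_P.

Elevated omega_P relative to omega_S indicates an excess of amino-acid
polymorphism that selection has not yet purged; delta expresses that excess
as a proportion. Standard errors come from bootstrap resampling of codon
columns (default 100 replicates), with the same resampled column set applied
to the ingroup and the outgroup so that omega_P and omega_S covary.

Breed inclusion mirrors the study design: more than four individuals
(n >= 5) and at least one synonymous and one nonsynonymous segregating
change, classified by the PBL site routing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .codon_code import GeneticCode, build_code
from .errors import ComputationError, InputError
from .pbl import count_pair, encode_alignment, pair_dnds
from .sequence_io import CodonAlignment

MIN_BREED_SAMPLES = 5  # "more than four individuals"


@dataclass(frozen=True)
class BootstrapConfig:
    """Codon-column bootstrap settings (unit of resampling is the codon)."""

    n_replicates: int = 100
    seed: int = 0
    unit: str = "codon"

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise InputError("bootstrap needs n_replicates >= 2")
        if self.unit != "codon":
            raise InputError(f"unsupported resampling unit: {self.unit}")


@dataclass
class BreedLoadEstimate:
    """Point estimates and bootstrap SEs of the load summary for one breed."""

    breed: str
    n_samples: int
    pi_N: float
    pi_S: float
    omega_P: float
    omega_S: float
    delta: float
    se_omega_P: float
    se_delta: float
    n_boot: int
    n_invalid_pairs: int

    @property
    def delta_negative(self) -> bool:
        """True when omega_P < omega_S (diagnostic, not an error)."""
        return self.delta < 0


# ---------------------------------------------------------------------------
# filters and point estimates
# ---------------------------------------------------------------------------


def _segregating_change_classes(enc: np.ndarray, code: GeneticCode) -> tuple[float, float]:
    """(synonymous, nonsynonymous) routed difference totals over all pairs.

    Synonymous tally = S2 + S4 + V4 (changes the PBL routing sends to dS);
    nonsynonymous = S0 + V0 + V2.
    """
    syn = nonsyn = 0.0
    for i, j in combinations(range(enc.shape[0]), 2):
        try:
            c = count_pair(enc[i], enc[j], code)
        except ComputationError:
            continue
        syn += c.S2 + c.S4 + c.V4
        nonsyn += c.S0 + c.V0 + c.V2
    return syn, nonsyn


def breed_filter(
    alignment: CodonAlignment, code: GeneticCode | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Apply the study's breed inclusion criteria.

    Included breeds have >= 5 samples and at least one synonymous and one
    nonsynonymous segregating change. Returns (included breeds, report with
    the failed criterion per excluded breed).
    """
    code = code or build_code(2)
    included, rows = [], []
    for breed in alignment.breeds():
        idx = alignment.rows_for_breed(breed)
        n = len(idx)
        if n < MIN_BREED_SAMPLES:
            rows.append({"breed": breed, "n": n, "included": False,
                         "reason": "n <= 4"})
            continue
        enc = encode_alignment([alignment.sequences[i] for i in idx])
        syn, nonsyn = _segregating_change_classes(enc, code)
        if syn == 0 and nonsyn == 0:
            reason = "no variants"
        elif syn == 0:
            reason = "no synonymous variant"
        elif nonsyn == 0:
            reason = "no nonsynonymous variant"
        else:
            included.append(breed)
            rows.append({"breed": breed, "n": n, "included": True, "reason": ""})
            continue
        rows.append({"breed": breed, "n": n, "included": False, "reason": reason})
    report = pd.DataFrame(rows, columns=["breed", "n", "included", "reason"])
    return included, report


def _pair_distance_lists(
    rows_a: np.ndarray, rows_b: np.ndarray | None, code: GeneticCode
) -> tuple[list[float], list[float], int]:
    """Valid pairwise (dN, dS) over within-rows_a pairs or rows_a x rows_b."""
    dns, dss = [], []
    n_invalid = 0
    if rows_b is None:
        pairs = combinations(range(rows_a.shape[0]), 2)
        get = lambda i, j: (rows_a[i], rows_a[j])
    else:
        pairs = ((i, j) for i in range(rows_a.shape[0])
                 for j in range(rows_b.shape[0]))
        get = lambda i, j: (rows_a[i], rows_b[j])
    for i, j in pairs:
        a, b = get(i, j)
        res = pair_dnds(count_pair(a, b, code))
        if res.valid_dN and res.valid_dS:
            dns.append(res.dN)
            dss.append(res.dS)
        else:
            n_invalid += 1
    return dns, dss, n_invalid


def pi_n_pi_s(
    sequences: Sequence[str] | np.ndarray, code: GeneticCode | None = None
) -> tuple[float, float, int]:
    """Mean pairwise dN and dS over all n(n-1)/2 pairs of one breed.

    Saturated (invalid) pairs are excluded from both means and counted;
    all-invalid raises :class:`ComputationError`.
    """
    code = code or build_code(2)
    enc = sequences if isinstance(sequences, np.ndarray) else encode_alignment(sequences)
    if enc.shape[0] < 2:
        raise InputError("piN/piS needs at least 2 sequences")
    dns, dss, n_invalid = _pair_distance_lists(enc, None, code)
    if not dns:
        raise ComputationError("all pairwise distances invalid (saturated)")
    return float(np.mean(dns)), float(np.mean(dss)), n_invalid


def omega_p(pi_N: float, pi_S: float) -> float:
    """piN/piS; piS = 0 raises (the breed filter should have excluded it)."""
    if pi_S <= 0:
        raise ComputationError(
            "pi_S is zero: breed has no synonymous diversity (see breed_filter)"
        )
    return pi_N / pi_S


def interspecies_omega_s(
    ingroup: CodonAlignment | np.ndarray | Sequence[str],
    outgroup: str | Sequence[str] | np.ndarray,
    code: GeneticCode | None = None,
) -> tuple[float, float, float]:
    """(dN, dS, omega_S) between an ingroup alignment and outgroup sequence(s).

    dN and dS are means of valid pairwise values over all ingroup x outgroup
    pairs; omega_S = dN/dS. dS = 0 or no valid pair raises.
    """
    code = code or build_code(2)
    if isinstance(ingroup, CodonAlignment):
        ingroup = ingroup.sequences
    enc_in = ingroup if isinstance(ingroup, np.ndarray) else encode_alignment(list(ingroup))
    if isinstance(outgroup, str):
        outgroup = [outgroup]
    enc_out = outgroup if isinstance(outgroup, np.ndarray) else encode_alignment(list(outgroup))
    dns, dss, _n_invalid = _pair_distance_lists(enc_in, enc_out, code)
    if not dns:
        raise ComputationError("no valid ingroup-outgroup pair (saturation)")
    d_N, d_S = float(np.mean(dns)), float(np.mean(dss))
    if d_S <= 0:
        raise ComputationError("interspecies dS is zero; omega_S undefined")
    return d_N, d_S, d_N / d_S


def delta(omega_P: float, omega_S: float) -> float:
    """Deleterious fraction (omega_P - omega_S) / omega_P.

    Always <= 1 (since omega_S >= 0); may be negative when omega_P < omega_S,
    which callers should treat as a diagnostic, not an error.
    """
    if omega_P <= 0:
        raise ComputationError("delta undefined for omega_P <= 0")
    if omega_S < 0:
        raise InputError("omega_S must be >= 0")
    return (omega_P - omega_S) / omega_P


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _draw_column_sets(n_codons: int, config: BootstrapConfig) -> np.ndarray:
    rng = np.random.default_rng(config.seed)
    return rng.integers(0, n_codons, size=(config.n_replicates, n_codons))


def _replicate_stats(
    breed_enc: np.ndarray,
    omega_s_enc: np.ndarray,
    out_enc: np.ndarray,
    cols: np.ndarray,
    code: GeneticCode,
) -> tuple[float, float] | None:
    """(omega_P, delta) for one resampled column set, or None if degenerate."""
    try:
        pi_n, pi_s, _ = pi_n_pi_s(breed_enc[:, cols], code)
        if pi_s <= 0 or pi_n <= 0:
            return None
        _, _, w_s = interspecies_omega_s(
            omega_s_enc[:, cols], out_enc[:, cols], code
        )
    except ComputationError:
        return None
    w_p = pi_n / pi_s
    return w_p, (w_p - w_s) / w_p


def bootstrap_load(
    breed_alignment: CodonAlignment | np.ndarray,
    outgroup: str | Sequence[str] | np.ndarray,
    config: BootstrapConfig,
    code: GeneticCode | None = None,
    omega_s_rows: np.ndarray | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Bootstrap SEs of omega_P and delta for one breed.

    Codon columns are resampled with replacement; each resampled column set
    is applied to both the breed alignment and the outgroup comparison so
    omega_P and omega_S covary within a replicate. ``omega_s_rows`` selects
    the ingroup rows used for the omega_S side (defaults to the breed's own
    rows; the full-study driver passes the pooled ingroup). Replicates with
    zero synonymous signal are dropped and counted; more than 50% degenerate
    replicates raises.

    Returns (se_omega_P, se_delta, replicate table).
    """
    code = code or build_code(2)
    if isinstance(breed_alignment, CodonAlignment):
        breed_enc = encode_alignment(breed_alignment.sequences)
    else:
        breed_enc = breed_alignment
    if isinstance(outgroup, str):
        outgroup = [outgroup]
    out_enc = outgroup if isinstance(outgroup, np.ndarray) else encode_alignment(list(outgroup))
    omega_s_enc = breed_enc if omega_s_rows is None else omega_s_rows

    col_sets = _draw_column_sets(breed_enc.shape[1], config)
    rows = []
    for r, cols in enumerate(col_sets):
        stats = _replicate_stats(breed_enc, omega_s_enc, out_enc, cols, code)
        if stats is None:
            rows.append({"replicate": r, "omega_P": math.nan,
                         "delta": math.nan, "degenerate": True})
        else:
            rows.append({"replicate": r, "omega_P": stats[0],
                         "delta": stats[1], "degenerate": False})
    table = pd.DataFrame(rows)
    good = table[~table["degenerate"]]
    if len(good) < config.n_replicates / 2:
        raise ComputationError(
            f"{config.n_replicates - len(good)}/{config.n_replicates} "
            "bootstrap replicates degenerate"
        )
    se_wp = float(good["omega_P"].std(ddof=1))
    se_delta = float(good["delta"].std(ddof=1))
    return se_wp, se_delta, table


# ---------------------------------------------------------------------------
# full-study driver
# ---------------------------------------------------------------------------


def analyze_breeds(
    alignment: CodonAlignment,
    outgroup: str | Sequence[str],
    config: BootstrapConfig | None = None,
    code: GeneticCode | None = None,
    per_breed_omega_s: bool = False,
) -> tuple[list[BreedLoadEstimate], pd.DataFrame]:
    """Run filters, point estimates and bootstraps for every breed.

    omega_S is computed once from the pooled ingroup-vs-outgroup comparison
    and shared by all breeds (matching a single cow-vs-bison species
    comparison); set ``per_breed_omega_s`` to use each breed's own outgroup
    comparison instead. Bootstrap replicates share one sequence of resampled
    column sets across breeds so replicate omega_S (computed on the shared
    ingroup) covaries with every breed's replicate omega_P.

    Returns (estimates, breed filter report).
    """
    code = code or build_code(2)
    config = config or BootstrapConfig()
    included, report = breed_filter(alignment, code)
    if isinstance(outgroup, str):
        outgroup = [outgroup]
    out_enc = encode_alignment(list(outgroup))
    full_enc = encode_alignment(alignment.sequences)
    included_rows = [i for i, b in enumerate(alignment.breed_labels) if b in included]
    pooled_enc = full_enc[included_rows]
    _, _, pooled_omega_s = interspecies_omega_s(pooled_enc, out_enc, code)

    col_sets = _draw_column_sets(full_enc.shape[1], config)
    # pooled omega_S per replicate, shared by every breed's delta replicates
    pooled_ws_reps = np.full(config.n_replicates, math.nan)
    if not per_breed_omega_s:
        for r, cols in enumerate(col_sets):
            try:
                _, _, pooled_ws_reps[r] = interspecies_omega_s(
                    pooled_enc[:, cols], out_enc[:, cols], code
                )
            except ComputationError:
                pass

    estimates = []
    for breed in included:
        idx = alignment.rows_for_breed(breed)
        breed_enc = full_enc[idx]
        pi_n, pi_s, n_invalid = pi_n_pi_s(breed_enc, code)
        w_p = omega_p(pi_n, pi_s)
        if per_breed_omega_s:
            _, _, w_s = interspecies_omega_s(breed_enc, out_enc, code)
        else:
            w_s = pooled_omega_s
        d = delta(w_p, w_s)

        wp_reps = np.full(config.n_replicates, math.nan)
        ws_reps = pooled_ws_reps.copy()
        for r, cols in enumerate(col_sets):
            try:
                rn, rs, _ = pi_n_pi_s(breed_enc[:, cols], code)
                if rs > 0:
                    wp_reps[r] = rn / rs
                if per_breed_omega_s:
                    _, _, ws_reps[r] = interspecies_omega_s(
                        breed_enc[:, cols], out_enc[:, cols], code
                    )
            except ComputationError:
                pass
        good_wp = ~np.isnan(wp_reps)
        # delta additionally needs omega_P > 0 in the replicate
        good_d = good_wp & ~np.isnan(ws_reps) & (wp_reps > 0)
        if good_d.sum() < config.n_replicates / 2:
            raise ComputationError(
                f"breed {breed}: >50% bootstrap replicates degenerate"
            )
        d_reps = (wp_reps[good_d] - ws_reps[good_d]) / wp_reps[good_d]
        estimates.append(
            BreedLoadEstimate(
                breed=breed, n_samples=len(idx),
                pi_N=pi_n, pi_S=pi_s, omega_P=w_p, omega_S=w_s, delta=d,
                se_omega_P=float(np.std(wp_reps[good_wp], ddof=1)),
                se_delta=float(np.std(d_reps, ddof=1)),
                n_boot=int(good_d.sum()),
                n_invalid_pairs=n_invalid,
            )
        )
    return estimates, report


def estimates_to_frame(estimates: Sequence[BreedLoadEstimate]) -> pd.DataFrame:
    """Per-breed load table (the table behind the per-breed omega_P figure)."""
    return pd.DataFrame(
        [
            {
                "breed": e.breed, "n": e.n_samples,
                "pi_N": e.pi_N, "pi_S": e.pi_S,
                "omega_P": e.omega_P, "se_omega_P": e.se_omega_P,
                "omega_S": e.omega_S,
                "delta": e.delta, "se_delta": e.se_delta,
                "n_invalid_pairs": e.n_invalid_pairs, "n_boot": e.n_boot,
            }
            for e in estimates
        ]
    )
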