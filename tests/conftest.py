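import numpy as np
import pytest

from mitoload.codon_code import build_code
from mitoload.synthetic_data import SimConfig, simulate_study


@pytest.fixture(scope="session")
def code2():
    return build_code(2)


@pytest.fixture(scope="session")
def small_study():
    """A small simulated cohort: 4 breeds x 6 samples, 600 codons."""
    config = SimConfig(n_breeds=4, samples_per_breed=6, n_codons=600, seed=7)
    alignment, outgroup, truth = simulate_study(config)
    return config, alignment, outgroup, truth


def random_codon_pair(rng: np.random.Generator, n_codons: int, p_mut: float = 0.15):
    """A random sense-codon sequence and a mutated copy (may hit stops/ambiguity)."""
    from mitoload.codon_code import CODONS

    code = build_code(2)
    sense = [c for c in CODONS if not code.is_stop(c)]
    a = [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]
    b = []
    for codon in a:
        codon = list(codon)
        if rng.random() < p_mut:
            pos = rng.integers(0, 3)
            codon[pos] = "ACGT"[rng.integers(0, 4)]
        b.append("".join(codon))
    return "".join(a), "".join(b)
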