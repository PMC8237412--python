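"""Breed filters, diversity ratios, delta and the codon bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoload.errors import ComputationError
from mitoload.load_pipeline import (
    BootstrapConfig,
    analyze_breeds,
    bootstrap_load,
    breed_filter,
    delta,
    estimates_to_frame,
    interspecies_omega_s,
    omega_p,
    pi_n_pi_s,
)
from mitoload.pbl import pair_dnds_from_seqs
from mitoload.sequence_io import CodonAlignment


def _aln(breed_to_seqs):
    ids, labels, seqs = [], [], []
    for breed, ss in breed_to_seqs.items():
        for i, s in enumerate(ss):
            ids.append(f"{breed}_{i}")
            labels.append(breed)
            seqs.append(s)
    return CodonAlignment(ids, labels, seqs)


BASE = "GGG" * 40
SYN_VAR = "GGA" + "GGG" * 39  # third-position change at a 4-fold site


class TestBreedFilter:
    def test_small_breed_excluded(self):
        aln = _aln({"small": [BASE] * 4, "big": [BASE, SYN_VAR] * 3})
        included, report = breed_filter(aln)
        row = report.set_index("breed").loc["small"]
        assert not row["included"] and "n" in row["reason"]

    def test_invariant_breed_excluded(self):
        aln = _aln({"mono": [BASE] * 6})
        included, report = breed_filter(aln)
        assert included == []
        assert report.iloc[0]["reason"] == "no variants"

    def test_syn_only_breed_excluded(self):
        aln = _aln({"syn": [BASE] * 4 + [SYN_VAR] * 2})
        included, report = breed_filter(aln)
        assert included == []
        assert "nonsynonymous" in report.iloc[0]["reason"]

    def test_breed_with_both_variant_classes_included(self, small_study, code2):
        _config, alignment, _outgroup, truth = small_study
        included, _report = breed_filter(alignment, code2)
        # the oldest simulated breed is deep enough to carry both classes
        assert truth.breeds[-1].breed in included


class TestPiNPiS:
    def test_two_sequences_equal_single_pair(self, code2):
        a = "ATAGGGGGGGGGTTA"
        b = "ATGGGGGGGGGATTA"
        pin, pis, inv = pi_n_pi_s([a, b], code2)
        pair = pair_dnds_from_seqs(a, b, code2)
        assert (pin, pis, inv) == (pair.dN, pair.dS, 0)

    def test_three_sequences_two_identical_average(self, code2):
        a = "GGG" * 30
        b = "GGA" + "GGG" * 29
        pair = pair_dnds_from_seqs(a, b, code2)
        pin, pis, _ = pi_n_pi_s([a, a, b], code2)
        assert pis == pytest.approx((0 + pair.dS + pair.dS) / 3, abs=1e-15)
        assert pin == 0.0

    def test_duplicating_every_sequence_rescales_pi_predictably(self, small_study, code2):
        """Duplicates add zero-distance pairs: pi scales by exactly 2(n-1)/(2n-1).

        The mean over all n(n-1)/2 pairs treats identical copies as distinct
        individuals, so pure duplication dilutes diversity by a known factor
        rather than leaving it unchanged.
        """
        _config, alignment, _outgroup, truth = small_study
        rows = alignment.rows_for_breed(truth.breeds[-1].breed)
        seqs = [alignment.sequences[i] for i in rows]
        n = len(seqs)
        factor = 2 * (n - 1) / (2 * n - 1)
        base = pi_n_pi_s(seqs, code2)
        doubled = pi_n_pi_s(seqs * 2, code2)
        assert doubled[0] == pytest.approx(base[0] * factor, rel=1e-12)
        assert doubled[1] == pytest.approx(base[1] * factor, rel=1e-12)


class TestRatios:
    def test_omega_p_arithmetic(self):
        assert omega_p(0.002, 0.010) == pytest.approx(0.2)
        assert omega_p(0.0, 0.01) == 0.0

    def test_omega_p_undefined_without_synonymous_diversity(self):
        with pytest.raises(ComputationError, match="breed_filter"):
            omega_p(0.01, 0.0)

    def test_single_pair_interspecies_equals_pair_dnds(self, code2):
        a = "ATAGGGGGGGGGTTA"
        b = "ATGGGGGGGGGATTA"
        d_n, d_s, w = interspecies_omega_s([a], b, code2)
        pair = pair_dnds_from_seqs(a, b, code2)
        assert (d_n, d_s) == (pair.dN, pair.dS)
        assert w == pair.dN / pair.dS

    def test_identical_outgroup_gives_error(self, code2):
        a = "GGG" * 20
        with pytest.raises(ComputationError):
            interspecies_omega_s([a], a, code2)

    def test_divergence_omega_recovery(self, code2):
        """omega_S estimate approaches the simulated divergence omega."""
        from mitoload.synthetic_data import SimConfig, simulate_study

        config = SimConfig(n_breeds=1, samples_per_breed=2, n_codons=2000,
                           root_height_per_breed=(1e-4,),
                           omega_poly_per_breed=(0.3,),
                           omega_div=0.1, outgroup_depth=0.05, seed=13)
        alignment, outgroup, _truth = simulate_study(config)
        _, _, w = interspecies_omega_s(alignment.sequences, outgroup, code2)
        assert w == pytest.approx(0.1, abs=0.03)


class TestDelta:
    def test_equal_ratios_give_zero(self):
        assert delta(0.3, 0.3) == 0.0

    def test_zero_divergence_ratio_gives_one(self):
        assert delta(0.3, 0.0) == 1.0

    def test_undefined_for_nonpositive_omega_p(self):
        with pytest.raises(ComputationError):
            delta(0.0, 0.1)

    @settings(deadline=None, derandomize=True)
    @given(
        omega=st.floats(0.1, 1.0, allow_nan=False),
        x=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_delta_identity(self, omega, x):
        """delta(w, w*(1-x)) recovers x for any load fraction x."""
        assert delta(omega, omega * (1.0 - x)) == pytest.approx(x, abs=1e-12)

    def test_negative_delta_reported_not_clamped(self):
        assert delta(0.1, 0.2) == pytest.approx(-1.0)


class TestBootstrap:
    def test_config_validation(self):
        with pytest.raises(Exception):
            BootstrapConfig(n_replicates=1)

    def test_fixed_seed_reproducible(self, small_study, code2):
        _config, alignment, outgroup, truth = small_study
        rows = alignment.rows_for_breed(truth.breeds[-1].breed)
        breed = alignment.subset(rows)
        cfg = BootstrapConfig(n_replicates=40, seed=9)
        first = bootstrap_load(breed, outgroup, cfg, code2)
        second = bootstrap_load(breed, outgroup, cfg, code2)
        assert first[0] == second[0] and first[1] == second[1]
        assert first[2].equals(second[2])
        assert first[0] > 0 and first[1] > 0

    def test_replicate_mean_near_point_estimate(self, small_study, code2):
        _config, alignment, outgroup, truth = small_study
        rows = alignment.rows_for_breed(truth.breeds[-1].breed)
        breed = alignment.subset(rows)
        cfg = BootstrapConfig(n_replicates=60, seed=3)
        se_wp, se_d, table = bootstrap_load(breed, outgroup, cfg, code2)
        pin, pis, _ = pi_n_pi_s(breed.sequences, code2)
        point = pin / pis
        good = table[~table["degenerate"]]
        assert abs(good["omega_P"].mean() - point) < 3 * se_wp

    def test_se_shrinks_with_alignment_length(self, code2):
        """Bootstrap SE falls as codon columns are added (~1/sqrt scaling)."""
        from mitoload.synthetic_data import SimConfig, simulate_study

        ses = {}
        for n_codons in (300, 1200):
            vals = []
            for seed in range(8):
                config = SimConfig(
                    n_breeds=1, samples_per_breed=6, n_codons=n_codons,
                    root_height_per_breed=(3e-3,),
                    omega_poly_per_breed=(0.4,), seed=100 + seed,
                )
                alignment, outgroup, _ = simulate_study(config)
                try:
                    se_wp, _, _ = bootstrap_load(
                        alignment, outgroup,
                        BootstrapConfig(n_replicates=30, seed=seed), code2,
                    )
                except ComputationError:
                    continue
                vals.append(se_wp)
            ses[n_codons] = np.median(vals)
        assert ses[1200] < ses[300]


class TestAnalyzeBreeds:
    def test_full_run_shapes_and_shared_omega_s(self, small_study, code2):
        _config, alignment, outgroup, _truth = small_study
        estimates, report = analyze_breeds(
            alignment, outgroup, BootstrapConfig(n_replicates=30, seed=1), code2
        )
        assert len(estimates) >= 1
        assert len(set(e.omega_S for e in estimates)) == 1  # pooled, shared
        frame = estimates_to_frame(estimates)
        assert set(frame.columns) >= {"breed", "pi_N", "pi_S", "omega_P",
                                      "se_omega_P", "delta", "se_delta"}
        for e in estimates:
            assert e.delta <= 1.0
            assert e.pi_N >= 0 and e.pi_S > 0
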