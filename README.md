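# mitoload

Deleterious mitochondrial mutation load across cattle breeds: per-breed
πN/πS by the Pamilo–Bianchi–Li method, the deleterious fraction δ of
segregating amino-acid variants, distance-based breed ages, and the
age–load correlation — plus a coalescent codon simulator so every stage is
testable against known truth without downloading data.

## The problem

Domestication and breed formation shrink effective population sizes, so
selection removes harmful amino-acid variants less efficiently: young,
recently bottlenecked breeds are expected to carry proportionally more
deleterious nonsynonymous SNPs than old ones. For mitochondrial
protein-coding genes this can be quantified from sequence alone:

- **ωP = πN/πS** — the ratio of nonsynonymous to synonymous nucleotide
  diversity within a breed. Elevated ωP means amino-acid polymorphism that
  selection has not (yet) purged.
- **ωS = dN/dS** — the same ratio at the species level (cow vs bison
  divergence), which proxies the effectively neutral fraction of
  amino-acid changes, since mostly neutral changes reach fixation.
- **δ = (ωP − ωS)/ωP** — the fraction of segregating nonsynonymous
  variants that are deleterious: the excess of within-breed amino-acid
  polymorphism over the neutrally fixable fraction.

πN and πS are mean pairwise distances estimated with the
Pamilo–Bianchi–Li (PBL) counting method: codon positions are partitioned
into 0-, 2- and 4-fold degeneracy classes under the vertebrate
mitochondrial code (NCBI table 2), transition/transversion differences are
tallied per class, corrected with the Kimura 2-parameter model, and
combined:

    dS = (L2·A2 + L4·A4)/(L2 + L4) + B4
    dN = A0 + (L0·B0 + L2·B2)/(L0 + L2)

where Li are class site counts and Ai/Bi the per-class K2P
transition/transversion components. Standard errors come from
bootstrapping codon columns (100 replicates). Breed age is the within-breed
coalescence distance (UPGMA root height of the K2P distance matrix) divided
by the mitochondrial rate μ = 2.043 × 10⁻⁸ substitutions/site/year, and the
headline statistic is the Pearson correlation of log10(age) with log10(δ).

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort whose truth is known (18 breeds × 10 mitogenomes, 11,229 bp of
concatenated coding sequence, a bison-like outgroup at 0.05 subs/site with
divergence ω = 0.1, and per-breed polymorphism ω decaying from 0.6 in the
youngest breed to 0.15 in the oldest):

```bash
python analysis/01_simulate_study.py
python analysis/02_estimate_load.py
python analysis/03_estimate_breed_ages.py
python analysis/04_correlate_age_load.py
```

which prints (seed 1):

```
omega_S (pooled vs outgroup): 0.1015 (simulated at 0.1)
delta within 3 bootstrap SEs of truth: 100% of 17 breeds; median |error| 0.072
...
median relative height error: 18.4%
age range: 6540..338997 years
...
omega_P fold range across breeds: 5.08
headline: log-log Pearson r = -0.72, p = 0.0013 over 17 breeds
```

Read: the interspecies ωS estimate recovers the simulated divergence ratio
(0.10); every included breed's estimated deleterious fraction δ falls
within 3 bootstrap SEs of its true value; breed ages span the
~8 Kyr–340 Kyr range implied by the simulated genealogy heights; and
young breeds carry proportionally more deleterious variation (negative
log–log correlation), mirroring the pattern reported for real cattle
breeds. One simulated breed is excluded by the inclusion filter (it has no
segregating nonsynonymous variant) — the same filter applied to real
cohorts.

The same stages are available as a console tool for real data
(GenBank flat files in, TSVs out):

```bash
mitoload extract *.gb --out alignment.fasta --report report.tsv
mitoload load --alignment alignment.fasta --outgroup bison.fasta --out load.tsv
mitoload age --alignment alignment.fasta --out age.tsv
mitoload correlate --load-table load.tsv --age-table age.tsv \
    --out-summary corr.tsv --out-scatter scatter.tsv
```

## Layout

- `src/mitoload/` — the library (each analysis stage is an importable module)
- `analysis/` — numbered narrative drivers over the library
- `tests/` — pytest suite, including an independent brute-force PBL oracle
- `docs/methods.md` — model, conventions, parameter choices, limitations
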