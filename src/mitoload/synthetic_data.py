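"""Coalescent codon simulator with separate polymorphism- and divergence-level omega.

The generator emulates the structure of the cattle mitogenome study: per
breed, an independent Kingman-coalescent genealogy (rescaled so root-to-tip
height is an exact, chosen number of substitutions per site — the "breed
age" knob) over which codon sequences evolve; an outgroup sequence at
species-level divergence evolved with a divergence omega; and a shared
ancestral codon sequence so within-breed polymorphism and cow-vs-outgroup
divergence are measured on the same alignment.

Substitution model: per codon, each of the nine single-base neighbours is
proposed at relative rate kappa (transitions) or 1 (transversions), weighted
by 1 for synonymous and ``omega`` for nonsynonymous changes; proposals that
would create a stop codon carry the nonsynonymous weight but are rejected
when drawn (time advances, no change). Rates are normalised so one unit of
branch length equals one expected substitution per nucleotide site at the
root composition. Every realized substitution is logged, so the ground
truth (realized synonymous/nonsynonymous counts, true genealogy heights,
implied true delta = 1 - omega_div/omega_poly) ships with every dataset.

Defaults mirror the study scale: 18 breeds, 10 samples each, 3,743 codons
(11,229 bp), genealogy heights spanning 1.7e-4 to 7e-3 subs/site (the 8.3
Kyr to 340 Kyr breed-age range at mu = 2.043e-8/site/year), omega_poly
decaying from 0.6 to 0.15 as breeds get older, omega_div = 0.1 at outgroup
depth 0.05 subs/site, kappa = 10 (mammalian mitochondrial transition bias).

What this generator does NOT emulate: shared haplogroup structure between
breeds, selection dynamics (omega values are imposed rates, not evolved),
indels, sequencing error, or rate variation along the genome.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .codon_code import BASES, CODONS, GeneticCode, build_code, is_transition
from .errors import InputError
from .sequence_io import CANONICAL_GENES, CodonAlignment, write_fasta_alignment

DEFAULT_MU = 2.043e-8


@dataclass(frozen=True)
class SimConfig:
    """Study-scale simulation settings; ``None`` lists use the defaults above."""

    n_breeds: int = 18
    samples_per_breed: int = 10
    n_codons: int = 3743
    root_height_per_breed: tuple[float, ...] | None = None
    omega_poly_per_breed: tuple[float, ...] | None = None
    omega_div: float = 0.1
    outgroup_depth: float = 0.05
    kappa: float = 10.0
    mu_per_year: float = DEFAULT_MU
    table_id: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_breed < 2:
            raise InputError("samples_per_breed must be >= 2")
        if self.kappa <= 0 or self.outgroup_depth <= 0 or self.mu_per_year <= 0:
            raise InputError("rates must be > 0")
        if self.omega_div < 0:
            raise InputError("omega values must be >= 0")
        for name in ("root_height_per_breed", "omega_poly_per_breed"):
            v = getattr(self, name)
            if v is not None:
                if len(v) != self.n_breeds:
                    raise InputError(f"{name} must have n_breeds entries")
                if any(x < 0 for x in v):
                    raise InputError(f"{name} entries must be >= 0")

    def resolved_heights(self) -> np.ndarray:
        if self.root_height_per_breed is not None:
            return np.asarray(self.root_height_per_breed, dtype=float)
        return np.geomspace(1.7e-4, 7e-3, self.n_breeds)

    def resolved_omega_poly(self) -> np.ndarray:
        if self.omega_poly_per_breed is not None:
            return np.asarray(self.omega_poly_per_breed, dtype=float)
        # deleterious load decays with breed age: omega_poly log-linear in
        # genealogy height, 0.6 for the youngest breed down to 0.15
        h = np.log(self.resolved_heights())
        frac = (h - h.min()) / (h.max() - h.min()) if h.max() > h.min() else np.zeros_like(h)
        return 0.6 - frac * (0.6 - 0.15)


@dataclass
class BreedTruth:
    breed: str
    root_height: float
    omega_poly: float
    true_delta: float
    n_syn_subs: int
    n_nonsyn_subs: int
    newick: str


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated dataset."""

    breeds: list[BreedTruth]
    outgroup_n_syn: int
    outgroup_n_nonsyn: int
    omega_div: float
    outgroup_depth: float

    def frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "breed": b.breed, "root_height": b.root_height,
                    "omega_poly": b.omega_poly, "true_delta": b.true_delta,
                    "n_syn_subs": b.n_syn_subs, "n_nonsyn_subs": b.n_nonsyn_subs,
                }
                for b in self.breeds
            ]
        )


# ---------------------------------------------------------------------------
# genealogy
# ---------------------------------------------------------------------------


def simulate_genealogy(
    n_samples: int,
    root_height: float,
    seed: int | np.random.Generator,
    labels: Sequence[str] | None = None,
) -> dendropy.Tree:
    """Kingman-coalescent topology rescaled to an exact ultrametric root height.

    Branch lengths are in substitutions per site. With ``root_height = 0``
    the tree is a star of zero-length branches.
    """
    if n_samples < 2:
        raise InputError("genealogy needs n_samples >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = list(labels) if labels is not None else [f"s{i+1}" for i in range(n_samples)]
    if len(labels) != n_samples:
        raise InputError("labels length must equal n_samples")

    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        node.height = 0.0
        nodes.append(node)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        parent.height = t
        # pop j first so index i stays valid
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent.add_child(left)
        parent.add_child(right)
        nodes.append(parent)
    root = nodes[0]
    scale = root_height / root.height if root.height > 0 else 0.0
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    for node in tree.preorder_node_iter():
        node.height *= scale
        if node.parent_node is not None:
            node.edge.length = node.parent_node.height - node.height
        else:
            node.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# codon evolution
# ---------------------------------------------------------------------------


class _RateTables:
    """Per-codon neighbour targets/rates for one (omega, kappa, code)."""

    def __init__(self, omega: float, kappa: float, code: GeneticCode):
        n = len(CODONS)
        self.targets = np.zeros((n, 9), dtype=np.int32)
        self.rates = np.zeros((n, 9))
        self.is_syn = np.zeros((n, 9), dtype=bool)
        self.is_stop_target = np.zeros((n, 9), dtype=bool)
        self.is_ts = np.zeros((n, 9), dtype=bool)
        self.total = np.zeros(n)
        for ci, codon in enumerate(CODONS):
            if code.is_stop(codon):
                continue
            aa = code.translate(codon)
            k = 0
            for pos in range(3):
                for b in BASES:
                    if b == codon[pos]:
                        continue
                    mut = codon[:pos] + b + codon[pos + 1 :]
                    aa_new = code.translate(mut)
                    stop = aa_new == "*"
                    syn = (not stop) and aa_new == aa
                    ts = is_transition(codon[pos], b)
                    rate = (kappa if ts else 1.0) * (1.0 if syn else omega)
                    self.targets[ci, k] = CODONS.index(mut)
                    self.rates[ci, k] = rate
                    self.is_syn[ci, k] = syn
                    self.is_stop_target[ci, k] = stop
                    self.is_ts[ci, k] = ts
                    k += 1
            self.total[ci] = self.rates[ci].sum()


_rate_cache: dict[tuple[float, float, int], _RateTables] = {}


def _rate_tables(omega: float, kappa: float, code: GeneticCode) -> _RateTables:
    key = (float(omega), float(kappa), code.table_id)
    if key not in _rate_cache:
        _rate_cache[key] = _RateTables(omega, kappa, code)
    return _rate_cache[key]


def _evolve_branch(
    seq: np.ndarray,
    length: float,
    tables: _RateTables,
    rng: np.random.Generator,
    counts: dict,
) -> np.ndarray:
    """Evolve ``seq`` (codon indices, modified copy returned) along one branch.

    ``length`` is in expected substitutions per nucleotide site at the
    normalisation stored in ``counts['_norm']``.
    """
    seq = seq.copy()
    if length <= 0:
        return seq
    norm = counts["_norm"]  # events per unit branch length at reference R
    rates = tables.total[seq].copy()
    R = rates.sum()
    t = 0.0
    while True:
        if R <= 0:
            return seq
        lam = (R / counts["_R0"]) * norm
        t += rng.exponential(1.0 / lam)
        if t >= length:
            return seq
        # choose codon proportional to its total rate
        u = rng.random() * R
        csum = np.cumsum(rates)
        i = int(np.searchsorted(csum, u, side="right"))
        i = min(i, seq.size - 1)
        ci = seq[i]
        nbr_rates = tables.rates[ci]
        v = rng.random() * nbr_rates.sum()
        k = int(np.searchsorted(np.cumsum(nbr_rates), v, side="right"))
        k = min(k, 8)
        if tables.is_stop_target[ci, k]:
            counts["n_rejected_stop"] += 1
            continue
        seq[i] = tables.targets[ci, k]
        if tables.is_syn[ci, k]:
            counts["n_syn"] += 1
        else:
            counts["n_nonsyn"] += 1
        if tables.is_ts[ci, k]:
            counts["n_ts"] += 1
        else:
            counts["n_tv"] += 1
        delta_r = tables.total[seq[i]] - rates[i]
        rates[i] = tables.total[seq[i]]
        R += delta_r


def evolve_codons(
    tree: dendropy.Tree,
    root_sequence: np.ndarray | str,
    omega: float,
    kappa: float,
    seed: int | np.random.Generator,
    code: GeneticCode | None = None,
) -> tuple[dict[str, np.ndarray], dict]:
    """Evolve a stop-free codon sequence down a genealogy.

    Returns (tip label -> codon index array, realized substitution counts
    with keys n_syn, n_nonsyn, n_ts, n_tv, n_rejected_stop).
    """
    code = code or build_code(2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = _as_codon_indices(root_sequence)
    tables = _rate_tables(omega, kappa, code)
    if any(code.is_stop(CODONS[i]) for i in root):
        raise InputError("root sequence contains stop codons")
    n_sites = 3 * root.size
    counts = {
        "n_syn": 0, "n_nonsyn": 0, "n_ts": 0, "n_tv": 0, "n_rejected_stop": 0,
        "_R0": tables.total[root].sum(),
        "_norm": float(n_sites),
    }
    tips: dict[str, np.ndarray] = {}

    def descend(node, seq):
        for child in node.child_nodes():
            child_seq = _evolve_branch(seq, child.edge.length or 0.0, tables, rng, counts)
            if child.is_leaf():
                tips[child.taxon.label] = child_seq
            else:
                descend(child, child_seq)

    descend(tree.seed_node, root)
    counts = {k: v for k, v in counts.items() if not k.startswith("_")}
    return tips, counts


def _as_codon_indices(seq) -> np.ndarray:
    if isinstance(seq, str):
        from .pbl import encode_codons

        arr = encode_codons(seq)
        if (arr < 0).any():
            raise InputError("root sequence contains ambiguous bases")
        return arr
    return np.asarray(seq, dtype=np.int64)


def codons_to_str(indices: np.ndarray) -> str:
    return "".join(CODONS[i] for i in indices)


def random_sense_codons(
    n_codons: int, rng: np.random.Generator, code: GeneticCode
) -> np.ndarray:
    """Uniform draw of sense-codon indices (the simulated ancestral sequence)."""
    sense_idx = np.array([i for i, c in enumerate(CODONS) if not code.is_stop(c)])
    return sense_idx[rng.integers(0, sense_idx.size, size=n_codons)]


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------


def _gene_boundaries(n_codons: int) -> list[tuple[str, int, int]]:
    """Partition the alignment into 13 named 'genes' of near-equal length."""
    n_genes = len(CANONICAL_GENES)
    base, extra = divmod(n_codons, n_genes)
    boundaries = []
    offset = 0
    for g_i, gene in enumerate(CANONICAL_GENES):
        codons = base + (1 if g_i < extra else 0)
        boundaries.append((gene, offset, codons * 3))
        offset += codons * 3
    return boundaries


def simulate_study(config: SimConfig) -> tuple[CodonAlignment, str, SimTruth]:
    """Simulate the full study: breed alignments, outgroup, ground truth.

    All breeds share one ancestral codon sequence; the outgroup evolves from
    it at ``outgroup_depth`` with ``omega_div``; each breed's samples evolve
    over an independent genealogy with that breed's ``omega_poly``. Identical
    configs (including seed) give byte-identical outputs.
    """
    code = build_code(config.table_id)
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(2 + config.n_breeds)
    rng_root = np.random.default_rng(child_seeds[0])
    rng_out = np.random.default_rng(child_seeds[1])

    root = random_sense_codons(config.n_codons, rng_root, code)
    heights = config.resolved_heights()
    omega_poly = config.resolved_omega_poly()

    # outgroup: a single branch at species depth
    out_tree = dendropy.Tree()
    tip = dendropy.Node(taxon=dendropy.Taxon("outgroup"))
    out_tree.seed_node.add_child(tip)
    tip.edge.length = config.outgroup_depth
    out_tips, out_counts = evolve_codons(
        out_tree, root, config.omega_div, config.kappa, rng_out, code
    )
    outgroup_seq = codons_to_str(out_tips["outgroup"])

    sample_ids, breed_labels, sequences = [], [], []
    breed_truths = []
    for b in range(config.n_breeds):
        breed = f"Breed{b+1:02d}"
        rng_b = np.random.default_rng(child_seeds[2 + b])
        labels = [f"{breed}_s{i+1:02d}" for i in range(config.samples_per_breed)]
        tree = simulate_genealogy(config.samples_per_breed, heights[b], rng_b, labels)
        tips, counts = evolve_codons(tree, root, omega_poly[b], config.kappa, rng_b, code)
        for lab in labels:
            sample_ids.append(lab)
            breed_labels.append(breed)
            sequences.append(codons_to_str(tips[lab]))
        true_delta = 1.0 - config.omega_div / omega_poly[b] if omega_poly[b] > 0 else float("nan")
        breed_truths.append(
            BreedTruth(
                breed=breed, root_height=float(heights[b]),
                omega_poly=float(omega_poly[b]), true_delta=float(true_delta),
                n_syn_subs=counts["n_syn"], n_nonsyn_subs=counts["n_nonsyn"],
                newick=tree.as_string(schema="newick").strip(),
            )
        )
    alignment = CodonAlignment(
        sample_ids, breed_labels, sequences, _gene_boundaries(config.n_codons)
    )
    truth = SimTruth(
        breeds=breed_truths,
        outgroup_n_syn=out_counts["n_syn"],
        outgroup_n_nonsyn=out_counts["n_nonsyn"],
        omega_div=config.omega_div,
        outgroup_depth=config.outgroup_depth,
    )
    return alignment, outgroup_seq, truth


# ---------------------------------------------------------------------------
# fixture writers
# ---------------------------------------------------------------------------


def write_genbank_fixtures(
    alignment: CodonAlignment,
    out_dir: str | Path,
    organism: str = "Bos taurus",
    minus_strand_genes: Sequence[str] = ("ND6",),
) -> list[Path]:
    """One minimal valid GenBank flat file per sample (synthetic records).

    Each gene is written as its alignment slice plus a TAA stop, as a CDS
    feature with /gene and /breed source qualifiers; genes named in
    ``minus_strand_genes`` are stored reverse-complemented with strand -1,
    mirroring real vertebrate mitogenome annotation. Extraction round-trips
    to the original alignment.
    """
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO
    from .sequence_io import reverse_complement

    if not alignment.gene_boundaries:
        raise InputError("alignment has no gene boundaries to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sid, breed, seq in zip(
        alignment.sample_ids, alignment.breed_labels, alignment.sequences
    ):
        segments = []
        features = []
        offset = 0
        for gene, start, glen in alignment.gene_boundaries:
            cds = seq[start : start + glen] + "TAA"
            strand = -1 if gene in minus_strand_genes else 1
            segment = reverse_complement(cds) if strand == -1 else cds
            features.append(
                SeqFeature(
                    FeatureLocation(offset, offset + len(segment), strand=strand),
                    type="CDS",
                    qualifiers={"gene": [gene]},
                )
            )
            segments.append(segment)
            offset += len(segment)
        genome = "".join(segments)
        source = SeqFeature(
            FeatureLocation(0, len(genome)),
            type="source",
            qualifiers={"organism": [organism], "breed": [breed]},
        )
        rec = SeqRecord(
            Seq(genome),
            id=sid,
            name=sid[:16],
            description=f"{organism} mitochondrion, synthetic fixture",
            annotations={"molecule_type": "DNA", "organism": organism},
            features=[source] + features,
        )
        path = out_dir / f"{sid}.gb"
        SeqIO.write(rec, str(path), "genbank")
        paths.append(path)
    return paths


def save_dataset(
    alignment: CodonAlignment,
    outgroup_seq: str,
    truth: SimTruth,
    config: SimConfig,
    out_dir: str | Path,
    genbank: bool = False,
) -> Path:
    """Write FASTA, truth TSV, newick genealogies and config under one directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta_alignment(alignment, out_dir / "alignment.fasta")
    with open(out_dir / "outgroup.fasta", "w") as fh:
        fh.write(">outgroup\n")
        for i in range(0, len(outgroup_seq), 70):
            fh.write(outgroup_seq[i : i + 70] + "\n")
    truth.frame().to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    trees = out_dir / "trees"
    trees.mkdir(exist_ok=True)
    for b in truth.breeds:
        (trees / f"{b.breed}.nwk").write_text(b.newick + "\n")
    cfg = asdict(config)
    (out_dir / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")
    if genbank:
        write_genbank_fixtures(alignment, out_dir / "genbank")
    return out_dir
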