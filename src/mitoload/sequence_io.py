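"""Reading mitogenome records and building concatenated codon alignments.

The pipeline works on the 13 mitochondrial protein-coding genes. This module
reads GenBank flat files (multi-record), extracts the annotated CDS per
gene, trims terminal stop codons (complete or incomplete, per the
mitochondrial polyadenylation convention), and concatenates the genes in a
fixed canonical order into an equal-length codon "super alignment" with
per-sample breed labels.

No alignment is performed: bovine mito CDS are length-conserved, so equal
per-gene lengths are enforced and violations raise, signalling that an
external aligner is required.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .codon_code import build_code
from .errors import InputError

log = logging.getLogger(__name__)

#: canonical vertebrate mitochondrial gene order (H-strand transcription order)
CANONICAL_GENES = (
    "ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "CYTB",
)

# synonym -> canonical name; keys are normalized (uppercase, alnum only).
# Unmatched names fail loudly: silent misassignment would corrupt the
# concatenation.
_SYNONYMS: dict[str, str] = {}


def _norm(name: str) -> str:
    return re.sub(r"[^A-Z0-9]", "", name.upper())


def _register(canonical: str, *names: str) -> None:
    for n in (canonical, *names):
        _SYNONYMS[_norm(n)] = canonical


for _i in (1, 2, 3, 4, 5, 6):
    _register(f"ND{_i}", f"NAD{_i}", f"NADH{_i}",
              f"NADH dehydrogenase subunit {_i}", f"MT-ND{_i}")
_register("ND4L", "NAD4L", "NADH4L", "NADH dehydrogenase subunit 4L", "MT-ND4L")
for _i, _r in ((1, "I"), (2, "II"), (3, "III")):
    _register(f"COX{_i}", f"CO{_i}", f"COX{_r}", f"CO{_r}", f"MT-CO{_i}",
              f"cytochrome c oxidase subunit {_i}",
              f"cytochrome c oxidase subunit {_r}")
_register("ATP6", "ATPASE6", "ATPase 6", "ATP synthase F0 subunit 6", "MT-ATP6")
_register("ATP8", "ATPASE8", "ATPase 8", "ATP synthase F0 subunit 8", "MT-ATP8")
_register("CYTB", "COB", "CYB", "cytochrome b", "MT-CYB")


def normalize_gene_name(name: str) -> str | None:
    """Map a gene/product name to its canonical symbol, or None if unknown."""
    return _SYNONYMS.get(_norm(name))


@dataclass
class MitoRecord:
    """One annotated mitogenome: sequence plus CDS feature coordinates.

    Coordinates are 0-based half-open on the stored sequence; strand is
    +1/-1. ``breed`` is None when the record carries no breed qualifier.
    """

    accession: str
    organism: str
    breed: str | None
    genome_seq: str
    cds_features: list[tuple[str, int, int, int]]  # (name, start, end, strand)


@dataclass
class CodonAlignment:
    """Equal-length, frame-aligned coding sequences with breed labels."""

    sample_ids: list[str]
    breed_labels: list[str]
    sequences: list[str]
    gene_boundaries: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not (len(self.breed_labels) == len(self.sequences) == n):
            raise InputError("sample_ids, breed_labels, sequences must be parallel")
        if len(set(self.sample_ids)) != n:
            raise InputError("sample_ids are not unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise InputError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.sequences and len(self.sequences[0]) % 3:
            raise InputError("alignment length is not a multiple of 3")
        for g, _start, glen in self.gene_boundaries:
            if glen % 3:
                raise InputError(f"gene {g} length {glen} not a multiple of 3")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def breeds(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.breed_labels:
            seen.setdefault(b, None)
        return list(seen)

    def rows_for_breed(self, breed: str) -> list[int]:
        return [i for i, b in enumerate(self.breed_labels) if b == breed]

    def subset(self, rows: Sequence[int]) -> "CodonAlignment":
        return CodonAlignment(
            sample_ids=[self.sample_ids[i] for i in rows],
            breed_labels=[self.breed_labels[i] for i in rows],
            sequences=[self.sequences[i] for i in rows],
            gene_boundaries=list(self.gene_boundaries),
        )


# ---------------------------------------------------------------------------
# GenBank reading
# ---------------------------------------------------------------------------


def _breed_from_source(feature) -> str | None:
    quals = feature.qualifiers
    if "breed" in quals:
        return quals["breed"][0]
    for note in quals.get("note", []):
        m = re.search(r"breed[:=]\s*([^;]+)", note, flags=re.IGNORECASE)
        if m:
            return m.group(1).strip()
    return None


def read_genbank(path: str | Path) -> list[MitoRecord]:
    """Parse a (possibly multi-record) GenBank flat file into MitoRecords.

    CDS names are taken from the ``gene`` qualifier, falling back to
    ``product``; features without locatable coordinates are skipped with a
    warning. Malformed files raise :class:`InputError` naming the record.
    """
    records: list[MitoRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise InputError(f"malformed GenBank file {path}: {exc}") from exc
    if not parsed:
        raise InputError(f"no GenBank records found in {path}")
    for rec in parsed:
        breed = None
        organism = rec.annotations.get("organism", "")
        cds: list[tuple[str, int, int, int]] = []
        for feat in rec.features:
            if feat.type == "source":
                breed = breed or _breed_from_source(feat)
            elif feat.type == "CDS":
                if feat.location is None:
                    log.warning(
                        "record %s: CDS without coordinates skipped", rec.id
                    )
                    continue
                name = (feat.qualifiers.get("gene")
                        or feat.qualifiers.get("product") or [None])[0]
                if name is None:
                    log.warning("record %s: unnamed CDS skipped", rec.id)
                    continue
                start = int(feat.location.start)
                end = int(feat.location.end)
                strand = -1 if feat.location.strand == -1 else 1
                if start < 0 or end > len(rec.seq):
                    raise InputError(
                        f"record {rec.id}: CDS {name} outside sequence bounds"
                    )
                cds.append((name, start, end, strand))
        records.append(
            MitoRecord(
                accession=rec.id,
                organism=organism,
                breed=breed,
                genome_seq=str(rec.seq).upper(),
                cds_features=cds,
            )
        )
    return records


_REVCOMP = str.maketrans("ACGTRYKMBDHVNacgtrykmbdhvn",
                         "TGCAYRMKVHDBNtgcayrmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def _trim_stop(seq: str, gene: str, accession: str, table_id: int = 2) -> str:
    """Trim a complete or incomplete terminal stop so length % 3 == 0."""
    overhang = len(seq) % 3
    if overhang:
        seq = seq[:-overhang]  # incomplete stop completed by polyadenylation
    if len(seq) < 3:
        raise InputError(f"record {accession}: CDS {gene} too short after trim")
    code = build_code(table_id)
    if code.is_stop(seq[-3:]):
        seq = seq[:-3]
    if len(seq) % 3:
        raise InputError(
            f"record {accession}: CDS {gene} length {len(seq)} not reducible "
            "to a multiple of 3"
        )
    return seq


def extract_cds(
    record: MitoRecord,
    gene_set: Sequence[str] = CANONICAL_GENES,
    table_id: int = 2,
) -> list[tuple[str, str]]:
    """Extract the requested genes from one record, in canonical order.

    Minus-strand features are reverse-complemented; terminal stops trimmed.
    A requested gene missing from the record raises :class:`InputError`
    naming the gene.
    """
    found: dict[str, str] = {}
    for name, start, end, strand in record.cds_features:
        canon = normalize_gene_name(name)
        if canon is None or canon not in gene_set:
            continue
        if canon in found:
            raise InputError(
                f"record {record.accession}: duplicate CDS for gene {canon}"
            )
        seq = record.genome_seq[start:end]
        if strand == -1:
            seq = reverse_complement(seq)
        found[canon] = _trim_stop(seq, canon, record.accession, table_id)
    missing = [g for g in gene_set if g not in found]
    if missing:
        raise InputError(
            f"record {record.accession}: missing gene(s) {', '.join(missing)}"
        )
    return [(g, found[g]) for g in gene_set]


def concatenate(
    records: Iterable[MitoRecord],
    gene_set: Sequence[str] = CANONICAL_GENES,
    breed_table: Mapping[str, str] | None = None,
    table_id: int = 2,
) -> tuple[CodonAlignment, pd.DataFrame]:
    """Concatenate per-record gene extractions into one codon alignment.

    Records failing extraction are dropped and reported in the returned
    extraction report (accession, genes_found, included, reason). A per-gene
    length disagreement across records raises, naming the gene and records:
    that signals an external aligner is needed.
    """
    rows = []
    kept: list[tuple[MitoRecord, list[tuple[str, str]]]] = []
    for rec in records:
        try:
            genes = extract_cds(rec, gene_set, table_id)
        except InputError as exc:
            log.warning("excluding %s: %s", rec.accession, exc)
            rows.append({"accession": rec.accession, "genes_found": 0,
                         "included": False, "reason": str(exc)})
            continue
        kept.append((rec, genes))
        rows.append({"accession": rec.accession, "genes_found": len(genes),
                     "included": True, "reason": ""})
    report = pd.DataFrame(rows, columns=["accession", "genes_found",
                                         "included", "reason"])
    if not kept:
        raise InputError("no records passed gene extraction")

    ref_rec, ref_genes = kept[0]
    lengths = {g: len(s) for g, s in ref_genes}
    for rec, genes in kept[1:]:
        for g, s in genes:
            if len(s) != lengths[g]:
                raise InputError(
                    f"gene {g}: length {len(s)} in {rec.accession} vs "
                    f"{lengths[g]} in {ref_rec.accession}; sequences must be "
                    "aligned externally"
                )
    boundaries = []
    offset = 0
    for g in gene_set:
        boundaries.append((g, offset, lengths[g]))
        offset += lengths[g]
    sample_ids, labels, seqs = [], [], []
    for rec, genes in kept:
        sample_ids.append(rec.accession)
        breed = rec.breed
        if breed_table and rec.accession in breed_table:
            breed = breed_table[rec.accession]
        labels.append(breed or "")
        seqs.append("".join(s for _g, s in genes))
    return (
        CodonAlignment(sample_ids, labels, seqs, boundaries),
        report,
    )


# ---------------------------------------------------------------------------
# FASTA and tables
# ---------------------------------------------------------------------------

_BREED_RE = re.compile(r"breed=(\S+)")


def read_fasta_alignment(
    path: str | Path,
    breed_table: Mapping[str, str] | None = None,
) -> CodonAlignment:
    """Read an equal-length multi-FASTA codon alignment.

    Breed labels come from the breed table when given, else from a
    ``breed=NAME`` token in the FASTA description, else empty.
    """
    ids, labels, seqs = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        m = _BREED_RE.search(rec.description)
        if breed_table and rec.id in breed_table:
            labels.append(breed_table[rec.id])
        else:
            labels.append(m.group(1) if m else "")
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise InputError(f"no FASTA records in {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise InputError(f"unequal FASTA sequence lengths in {path}: {sorted(lengths)}")
    if next(iter(lengths)) % 3:
        raise InputError(f"alignment length {next(iter(lengths))} breaks codon frame")
    return CodonAlignment(ids, labels, seqs)


def write_fasta_alignment(alignment: CodonAlignment, path: str | Path) -> None:
    """Write the alignment as FASTA with ``breed=`` tokens in descriptions."""
    with open(path, "w") as fh:
        for sid, breed, seq in zip(
            alignment.sample_ids, alignment.breed_labels, alignment.sequences
        ):
            header = f">{sid}" + (f" breed={breed}" if breed else "")
            fh.write(header + "\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_breed_splits(alignment: CodonAlignment, out_dir: str | Path) -> list[Path]:
    """One FASTA per breed under ``out_dir``; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for breed in alignment.breeds():
        sub = alignment.subset(alignment.rows_for_breed(breed))
        p = out_dir / f"{re.sub(r'[^A-Za-z0-9_-]', '_', breed) or 'unlabelled'}.fasta"
        write_fasta_alignment(sub, p)
        paths.append(p)
    return paths


def read_breed_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, breed) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"breed table {path} needs two tab-separated columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
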