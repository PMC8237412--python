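"""GenBank/FASTA reading, CDS extraction, concatenation round-trips."""

import pytest

from mitoload.errors import InputError
from mitoload.sequence_io import (
    CANONICAL_GENES,
    CodonAlignment,
    MitoRecord,
    concatenate,
    extract_cds,
    normalize_gene_name,
    read_breed_table,
    read_fasta_alignment,
    read_genbank,
    reverse_complement,
    write_fasta_alignment,
)
from mitoload.synthetic_data import (
    SimConfig,
    simulate_study,
    write_genbank_fixtures,
)


@pytest.fixture(scope="module")
def fixture_dataset(tmp_path_factory):
    """Simulated cohort written out as GenBank flat files."""
    config = SimConfig(n_breeds=2, samples_per_breed=3, n_codons=260, seed=42)
    alignment, outgroup, truth = simulate_study(config)
    out = tmp_path_factory.mktemp("gb")
    paths = write_genbank_fixtures(alignment, out)
    return alignment, sorted(paths)


class TestGeneNames:
    @pytest.mark.parametrize(
        "raw, canonical",
        [
            ("COI", "COX1"), ("coxI", "COX1"), ("MT-CO1", "COX1"),
            ("ATPase 6", "ATP6"), ("cytb", "CYTB"), ("cytochrome b", "CYTB"),
            ("NADH dehydrogenase subunit 4L", "ND4L"), ("nad2", "ND2"),
        ],
    )
    def test_synonyms_resolve(self, raw, canonical):
        assert normalize_gene_name(raw) == canonical

    def test_unknown_names_do_not_fuzzy_match(self):
        assert normalize_gene_name("COX1-like pseudogene") is None
        assert normalize_gene_name("ND7") is None


class TestReadGenbank:
    def test_fixture_round_trip_counts(self, fixture_dataset):
        alignment, paths = fixture_dataset
        records = []
        for p in paths:
            records.extend(read_genbank(p))
        assert len(records) == alignment.n_samples
        assert all(len(r.cds_features) == 13 for r in records)
        assert [r.breed for r in records] == alignment.breed_labels

    def test_missing_file_of_records_raises(self, tmp_path):
        empty = tmp_path / "empty.gb"
        empty.write_text("")
        with pytest.raises(InputError):
            read_genbank(empty)

    def test_record_without_breed_qualifier(self, fixture_dataset, tmp_path):
        _alignment, paths = fixture_dataset
        text = paths[0].read_text().replace('/breed="Breed01"\n', "")
        stripped = tmp_path / "nobreed.gb"
        stripped.write_text(text)
        (rec,) = read_genbank(stripped)
        assert rec.breed is None


class TestExtractCds:
    def test_round_trip_equals_simulated_genes(self, fixture_dataset):
        alignment, paths = fixture_dataset
        (rec,) = read_genbank(paths[0])
        genes = extract_cds(rec)
        row = alignment.sample_ids.index(rec.accession)
        for (gene, start, glen), (name, seq) in zip(alignment.gene_boundaries, genes):
            assert name == gene
            assert seq == alignment.sequences[row][start : start + glen]

    def test_minus_strand_gene_is_reverse_complemented(self, fixture_dataset):
        # the fixture writer stores ND6 on the minus strand
        _alignment, paths = fixture_dataset
        (rec,) = read_genbank(paths[0])
        nd6 = next(f for f in rec.cds_features
                   if normalize_gene_name(f[0]) == "ND6")
        _name, start, end, strand = nd6
        assert strand == -1
        extracted = dict(extract_cds(rec))["ND6"]
        genomic = rec.genome_seq[start:end]
        assert reverse_complement(genomic).startswith(extracted)

    def test_complete_stop_trimmed(self):
        rec = MitoRecord(
            accession="x", organism="Bos taurus", breed=None,
            genome_seq="ATGGCCGCA" + "TAA",
            cds_features=[("ND1", 0, 12, 1)],
        )
        (gene,) = extract_cds(rec, gene_set=("ND1",))
        assert gene == ("ND1", "ATGGCCGCA")

    def test_incomplete_stop_trimmed_to_frame(self):
        # mito polyadenylation convention: CDS ends in a bare T or TA
        rec = MitoRecord(
            accession="x", organism="Bos taurus", breed=None,
            genome_seq="ATGGCCGCAT",
            cds_features=[("ND1", 0, 10, 1)],
        )
        (gene,) = extract_cds(rec, gene_set=("ND1",))
        assert gene == ("ND1", "ATGGCCGCA")

    def test_missing_gene_raises_named_error(self, fixture_dataset, tmp_path):
        _alignment, paths = fixture_dataset
        (rec,) = read_genbank(paths[0])
        rec.cds_features = [f for f in rec.cds_features
                            if normalize_gene_name(f[0]) != "ND2"]
        with pytest.raises(InputError, match="ND2"):
            extract_cds(rec)


class TestConcatenate:
    def test_alignment_length_is_sum_of_trimmed_genes(self, fixture_dataset):
        alignment, paths = fixture_dataset
        records = [r for p in paths for r in read_genbank(p)]
        result, report = concatenate(records)
        assert result.length == sum(g for _n, _s, g in result.gene_boundaries)
        assert result.sequences == alignment.sequences
        assert result.breed_labels == alignment.breed_labels
        assert report["included"].all()

    def test_record_order_changes_rows_not_columns(self, fixture_dataset):
        _alignment, paths = fixture_dataset
        records = [r for p in paths for r in read_genbank(p)]
        fwd, _ = concatenate(records)
        rev, _ = concatenate(records[::-1])
        assert sorted(fwd.sample_ids) == sorted(rev.sample_ids)
        for sid in fwd.sample_ids:
            i, j = fwd.sample_ids.index(sid), rev.sample_ids.index(sid)
            assert fwd.sequences[i] == rev.sequences[j]

    def test_gene_length_disagreement_names_gene(self, fixture_dataset):
        _alignment, paths = fixture_dataset
        records = [r for p in paths for r in read_genbank(p)]
        # shorten ND2 by two codons in one record (one codon would cancel
        # against stop trimming: the written gene ends in TAA)
        rec = records[1]
        feats = []
        for name, start, end, strand in rec.cds_features:
            if normalize_gene_name(name) == "ND2":
                end -= 6
            feats.append((name, start, end, strand))
        rec.cds_features = feats
        with pytest.raises(InputError, match="ND2"):
            concatenate(records)

    def test_failing_record_dropped_and_reported(self, fixture_dataset):
        _alignment, paths = fixture_dataset
        records = [r for p in paths for r in read_genbank(p)]
        records[0].cds_features = records[0].cds_features[:-1]  # drop a gene
        result, report = concatenate(records)
        assert result.n_samples == len(records) - 1
        excluded = report[~report["included"]]
        assert list(excluded["accession"]) == [records[0].accession]


class TestFasta:
    def test_round_trip_preserves_sequences_and_breeds(self, small_study, tmp_path):
        _config, alignment, _outgroup, _truth = small_study
        path = tmp_path / "aln.fasta"
        write_fasta_alignment(alignment, path)
        back = read_fasta_alignment(path)
        assert back.sample_ids == alignment.sample_ids
        assert back.breed_labels == alignment.breed_labels
        assert back.sequences == alignment.sequences

    def test_three_equal_sequences(self, tmp_path):
        path = tmp_path / "t.fasta"
        seq = "ACG" * 10
        path.write_text(f">a\n{seq}\n>b\n{seq}\n>c\n{seq}\n")
        aln = read_fasta_alignment(path)
        assert aln.n_samples == 3 and aln.length == 30

    def test_frame_error(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a\n" + "A" * 31 + "\n>b\n" + "C" * 31 + "\n")
        with pytest.raises(InputError):
            read_fasta_alignment(path)

    def test_unequal_lengths_error(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a\nACGACG\n>b\nACG\n")
        with pytest.raises(InputError):
            read_fasta_alignment(path)

    def test_breed_table_overrides_headers(self, tmp_path):
        fasta = tmp_path / "t.fasta"
        fasta.write_text(">a breed=X\nACG\n>b\nACG\n")
        table = tmp_path / "breeds.tsv"
        table.write_text("a\tHolstein\nb\tJersey\n")
        aln = read_fasta_alignment(fasta, read_breed_table(table))
        assert aln.breed_labels == ["Holstein", "Jersey"]


class TestCodonAlignment:
    def test_invariants_enforced(self):
        with pytest.raises(InputError):
            CodonAlignment(["a", "a"], ["x", "x"], ["ACG", "ACG"])  # dup ids
        with pytest.raises(InputError):
            CodonAlignment(["a", "b"], ["x", "x"], ["ACG", "ACGACG"])
        with pytest.raises(InputError):
            CodonAlignment(["a"], ["x"], ["ACGA"])

    def test_canonical_gene_set_is_13(self):
        assert len(CANONICAL_GENES) == 13
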