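"""Fixrank parsing, taxonomy mapping, community Z_C, sample filters."""

import numpy as np
import pytest

from redoxzc.community import (
    ClassifiedRead, SampleRecord, community_reference_proteome, filter_samples,
    map_taxa, metaproteome_zc, read_psm_counts, read_rdp_fixrank,
    subsample_counts, MANUAL_MAPPINGS,
)
from redoxzc.composition import AminoAcidTally, zc_from_tally
from redoxzc.refdb import ReferenceDatabase, ReferenceProteome


def _fixrank_row(read_id, *triplets):
    cells = [read_id, "", "-"]
    for name, rank, conf in triplets:
        cells += [name, rank, str(conf)]
    return "\t".join(cells)


GENUS_ROW = _fixrank_row(
    "r1",
    ("Bacteria", "domain", 1.0), ("Proteobacteria", "phylum", 1.0),
    ("Gammaproteobacteria", "class", 0.99), ("Enterobacterales", "order", 0.99),
    ("Enterobacteriaceae", "family", 0.98), ("Escherichia/Shigella", "genus", 0.95),
)
DOMAIN_ONLY_ROW = _fixrank_row("r2", ("Bacteria", "domain", 1.0))
CHLOROPLAST_ROW = _fixrank_row(
    "r3",
    ("Bacteria", "domain", 1.0), ("Cyanobacteria/Chloroplast", "phylum", 1.0),
    ("Chloroplast", "class", 0.97),
)
CLASS_ROW = _fixrank_row(
    "r4",
    ("Bacteria", "domain", 1.0), ("Cyanobacteria/Chloroplast", "phylum", 0.7),
    ("Cyanobacteria", "class", 0.95),
)


def _db():
    db = ReferenceDatabase()
    db.add(ReferenceProteome(
        "Escherichia", "genus", AminoAcidTally.from_counts({"G": 1, "A": 1})
    ))
    db.add(ReferenceProteome(
        "Cyanobacteria", "phylum", AminoAcidTally.from_counts({"G": 2})
    ))
    db.add(ReferenceProteome(
        "Luteitalea", "genus", AminoAcidTally.from_counts({"L": 3})
    ))
    return db


def test_fixrank_parses_genus_level_read(tmp_path):
    path = tmp_path / "s1.tsv"
    path.write_text(GENUS_ROW + "\n")
    reads = read_rdp_fixrank(path)
    assert len(reads) == 1
    read = reads[0]
    assert read.lowest_rank == "genus"
    assert read.lowest_taxon == "Escherichia/Shigella"
    assert read.domain == "Bacteria"
    assert read.sample_id == "s1"


def test_fixrank_drops_domain_only_and_chloroplast(tmp_path):
    path = tmp_path / "s.tsv"
    path.write_text("\n".join([GENUS_ROW, DOMAIN_ONLY_ROW, CHLOROPLAST_ROW]) + "\n")
    reads = read_rdp_fixrank(path)
    assert [r.lowest_taxon for r in reads] == ["Escherichia/Shigella"]


def test_fixrank_empty_file_warns(tmp_path, caplog):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    with caplog.at_level("WARNING"):
        assert read_rdp_fixrank(path) == []
    assert "no usable classifications" in caplog.text


def test_fixrank_malformed_row_reports_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(GENUS_ROW + "\nr9\tBacteria\tdomain\n")
    with pytest.raises(ValueError, match="bad.tsv:2"):
        read_rdp_fixrank(path)


def test_fixrank_confidence_refilter(tmp_path):
    path = tmp_path / "s.tsv"
    path.write_text(CLASS_ROW + "\n")
    # default: deepest usable rank is the class-level call
    assert read_rdp_fixrank(path)[0].lowest_rank == "class"
    # re-thresholding at 0.8 removes the low-confidence phylum call only
    reads = read_rdp_fixrank(path, min_confidence=0.8)
    assert reads[0].lowest_rank == "class"
    assert read_rdp_fixrank(path, min_confidence=0.96) == []


def test_manual_mapping_within_and_cross_level():
    db = _db()
    reads = [
        ClassifiedRead("s", "Bacteria", "genus", "Escherichia/Shigella", 0.95),
        ClassifiedRead("s", "Bacteria", "genus", "Gp6", 0.9),
        ClassifiedRead("s", "Bacteria", "class", "Cyanobacteria", 0.9),
        ClassifiedRead("s", "Bacteria", "genus", "Nosuchgenus", 0.9),
    ]
    counts, report = map_taxa(reads, db)
    assert counts[("genus", "Escherichia")] == 1
    assert counts[("genus", "Luteitalea")] == 1
    assert counts[("phylum", "Cyanobacteria")] == 1  # cross-level redirect
    assert report.n_mapped == 3
    assert report.unmapped == {("genus", "Nosuchgenus"): 1}
    assert report.pct_mapped == pytest.approx(75.0)


def test_no_archaeal_manual_mappings():
    archaeal_like = [k for k in MANUAL_MAPPINGS if "archae" in k[1].lower()]
    assert archaeal_like == []


def test_community_proteome_single_taxon_identity():
    db = _db()
    s = SampleRecord("s", "Bacteria", {("genus", "Escherichia"): 7})
    tally = community_reference_proteome(s, db)
    np.testing.assert_allclose(
        tally.counts, db.get("genus", "Escherichia").mean_tally.counts
    )


def test_community_proteome_equal_counts_average():
    db = _db()
    s = SampleRecord(
        "s", "Bacteria",
        {("genus", "Escherichia"): 50, ("genus", "Luteitalea"): 50},
    )
    tally = community_reference_proteome(s, db)
    expected = 0.5 * (
        db.get("genus", "Escherichia").mean_tally.counts
        + db.get("genus", "Luteitalea").mean_tally.counts
    )
    np.testing.assert_allclose(tally.counts, expected)
    zc = zc_from_tally(tally)
    members = [db.get("genus", "Escherichia").zc, db.get("genus", "Luteitalea").zc]
    assert min(members) <= zc <= max(members)


def test_doubling_counts_leaves_community_unchanged():
    db = _db()
    counts = {("genus", "Escherichia"): 30, ("genus", "Luteitalea"): 10}
    t1 = community_reference_proteome(SampleRecord("s", "Bacteria", counts), db)
    t2 = community_reference_proteome(
        SampleRecord("s", "Bacteria", {k: 2 * v for k, v in counts.items()}), db
    )
    np.testing.assert_allclose(t1.counts, t2.counts, atol=1e-12)


def test_community_proteome_requires_counts():
    with pytest.raises(ValueError):
        community_reference_proteome(SampleRecord("s", "Bacteria", {}), _db())


def test_sample_read_count_filter_boundary():
    mk = lambda n, dom="Bacteria", sid="s": SampleRecord(
        sid, dom, {("genus", "Escherichia"): n}
    )
    kept, log = filter_samples([mk(99), mk(100)])
    assert len(kept) == 1 and kept[0].n_classified == 100
    assert len(log) == 1


def test_archaeal_dataset_minimum_samples():
    bact = [SampleRecord(f"b{i}", "Bacteria", {("genus", "x"): 200})
            for i in range(4)]
    arch = [SampleRecord(f"a{i}", "Archaea", {("genus", "y"): 200})
            for i in range(3)]
    kept, log = filter_samples(bact + arch)
    assert all(s.domain == "Bacteria" for s in kept)
    assert any("archaeal" in line for line in log)
    # with four archaeal samples the set survives
    arch4 = arch + [SampleRecord("a3", "Archaea", {("genus", "y"): 200})]
    kept, _ = filter_samples(bact + arch4)
    assert sum(s.domain == "Archaea" for s in kept) == 4


def _protein_fasta(tmp_path):
    path = tmp_path / "prot.fasta"
    path.write_text(">p1\nGG\n>p2\nLLL\n")
    return path


def test_metaproteome_single_protein(tmp_path):
    path = _protein_fasta(tmp_path)
    assert metaproteome_zc({"p1": 1}, path) == pytest.approx(1.0)


def test_metaproteome_spectral_count_weighting(tmp_path):
    path = _protein_fasta(tmp_path)
    # oracle: 2x p1 + 1x p2 summed then Z_C via the composition module
    acc = AminoAcidTally.from_counts({"G": 4, "L": 3})
    assert metaproteome_zc({"p1": 2, "p2": 1}, path) == pytest.approx(
        zc_from_tally(acc), abs=1e-14
    )


def test_metaproteome_rejects_decoys_and_unknown_ids(tmp_path):
    path = _protein_fasta(tmp_path)
    with pytest.raises(ValueError, match="decoy"):
        metaproteome_zc({"REV_p1": 1, "p1": 2}, path)
    with pytest.raises(KeyError, match="p9"):
        metaproteome_zc({"p9": 1}, path)


def test_psm_counts_reader(tmp_path):
    path = tmp_path / "psm.tsv"
    path.write_text("protein_id\tspectral_count\np1\t3\np2\t1\n")
    assert read_psm_counts(path) == {"p1": 3.0, "p2": 1.0}


def test_subsampler_is_seeded_and_preserves_totals():
    counts = {("genus", "a"): 60, ("genus", "b"): 40}
    sub1 = subsample_counts(counts, 50, seed=1)
    sub2 = subsample_counts(counts, 50, seed=1)
    assert sub1 == sub2
    assert sum(sub1.values()) == 50
    assert subsample_counts(counts, 1000, seed=1) == {
        ("genus", "a"): 60, ("genus", "b"): 40
    }
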