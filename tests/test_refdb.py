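"""Reference-proteome averaging rules and database round trips."""

import numpy as np
import pytest

from redoxzc.composition import AminoAcidTally, zc_from_tally, AA_CARBON
from redoxzc.refdb import (
    BelowThresholdError, ReferenceDatabase, ReferenceProteome, aggregate_rank,
    build_database, species_reference, tallies_from_fasta,
)
from redoxzc.synth import make_reference_db, write_fasta


def _tally(**counts):
    return AminoAcidTally.from_counts(counts)


def test_species_reference_is_mean_over_proteins():
    ref = species_reference(
        "sp", [_tally(G=2), _tally(A=6)], min_proteins=1
    )
    assert ref.mean_tally.as_dict()["G"] == pytest.approx(1.0)
    assert ref.mean_tally.as_dict()["A"] == pytest.approx(3.0)
    assert ref.n_proteins == 2


def test_species_sequence_count_filter():
    proteins = [_tally(G=10)] * 499
    with pytest.raises(BelowThresholdError):
        species_reference("sparse", proteins)
    ref = species_reference("dense", proteins + [_tally(G=10)])
    assert ref.n_proteins == 500
    assert ref.mean_tally.as_dict()["G"] == pytest.approx(10.0)


def test_species_reference_rejects_empty():
    with pytest.raises(ValueError):
        species_reference("none", [])


def test_aggregate_single_species_is_identity():
    sp = species_reference("sp", [_tally(G=4)], min_proteins=1)
    genus = aggregate_rank([sp], "genus", "G1")
    np.testing.assert_allclose(genus.mean_tally.counts, sp.mean_tally.counts)
    assert genus.n_species == 1


def test_aggregate_is_unweighted_mean_of_species():
    a = species_reference("a", [_tally(G=1)], min_proteins=1)
    b = species_reference("b", [_tally(A=1)], min_proteins=1)
    genus = aggregate_rank([a, b], "genus", "G1")
    assert genus.mean_tally.as_dict()["G"] == pytest.approx(0.5)
    assert genus.mean_tally.as_dict()["A"] == pytest.approx(0.5)


def test_aggregate_zc_is_carbon_weighted_mean_of_members():
    a = species_reference("a", [_tally(G=2, A=1)], min_proteins=1)
    b = species_reference("b", [_tally(L=3)], min_proteins=1)
    genus = aggregate_rank([a, b], "genus", "G1")
    # oracle: weights are each member's total carbon in its mean tally
    weights = [float((r.mean_tally.counts * AA_CARBON).sum()) for r in (a, b)]
    zcs = [r.zc for r in (a, b)]
    expected = np.average(zcs, weights=weights)
    assert genus.zc == pytest.approx(expected, abs=1e-12)


def test_duplicating_proteins_of_one_species_changes_nothing_upstream():
    """Equal-species weighting: proteome size must not leak into genera."""
    a_proteins = [_tally(G=1), _tally(A=2)]
    b_proteins = [_tally(L=5)]
    genus1 = aggregate_rank(
        [species_reference("a", a_proteins, min_proteins=1),
         species_reference("b", b_proteins, min_proteins=1)],
        "genus", "G1",
    )
    genus2 = aggregate_rank(
        [species_reference("a", a_proteins * 7, min_proteins=1),
         species_reference("b", b_proteins, min_proteins=1)],
        "genus", "G1",
    )
    np.testing.assert_allclose(
        genus1.mean_tally.counts, genus2.mean_tally.counts, atol=1e-14
    )


def test_aggregation_is_permutation_invariant():
    refs = [
        species_reference(f"s{i}", [_tally(G=i + 1, L=2 * i + 1)], min_proteins=1)
        for i in range(5)
    ]
    fwd = aggregate_rank(refs, "family", "F")
    rev = aggregate_rank(refs[::-1], "family", "F")
    np.testing.assert_allclose(fwd.mean_tally.counts, rev.mean_tally.counts)


def test_rank_validation():
    sp = species_reference("sp", [_tally(G=1)], min_proteins=1)
    with pytest.raises(ValueError):
        aggregate_rank([sp], "species", "x")
    with pytest.raises(ValueError):
        aggregate_rank([], "genus", "x")
    with pytest.raises(ValueError):
        ReferenceProteome("x", "kingdom", _tally(G=1))


def test_cross_rank_name_collisions_are_legal():
    db = ReferenceDatabase()
    db.add(ReferenceProteome("Cyanobacteria", "class", _tally(G=1)))
    db.add(ReferenceProteome("Cyanobacteria", "phylum", _tally(A=1)))
    assert db.get("class", "Cyanobacteria").zc != db.get("phylum", "Cyanobacteria").zc


def test_database_csv_round_trip(tmp_path, small_db):
    path = tmp_path / "db.csv"
    small_db.to_csv(path)
    back = ReferenceDatabase.from_csv(path)
    assert back.taxa() == small_db.taxa()
    for rank, name in small_db.taxa():
        np.testing.assert_allclose(
            back.get(rank, name).mean_tally.counts,
            small_db.get(rank, name).mean_tally.counts,
            rtol=1e-12,
        )


def test_fasta_grouping_and_rebuild(tmp_path):
    db, records = make_reference_db(
        3, zc_low=-0.3, zc_high=-0.1, proteins_per_species=4,
        protein_length=200, seed=2,
    )
    path = tmp_path / "ref.fasta"
    write_fasta(records, path)
    grouped = tallies_from_fasta(path)
    assert len(grouped) == 3
    rebuilt = build_database(
        grouped, lineage={}, min_proteins=1
    )
    # FASTA carries integer residue counts, so Z_C matches only approximately
    for p in db:
        sp = rebuilt.get("species", p.taxon_name)
        assert sp is not None
        assert zc_from_tally(sp.mean_tally) == pytest.approx(p.zc, abs=5e-3)


def test_fasta_header_without_taxon_label_fails(tmp_path):
    path = tmp_path / "bad.fasta"
    path.write_text(">p1 no label here\nGGGG\n")
    with pytest.raises(ValueError):
        tallies_from_fasta(path)
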