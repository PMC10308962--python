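"""Reference proteomes: mean amino-acid compositions of taxa.

A species reference proteome is the arithmetic mean amino-acid composition
over all of the species' protein sequences (equal weight per protein).
Higher ranks (genus .. phylum) are the unweighted mean of their member
species' means, so species with different proteome sizes contribute
equally.  Species with fewer than 500 protein sequences are excluded by
default; the threshold is configurable so small demonstration databases
can be built.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .composition import AMINO_ACIDS, AminoAcidTally, mean_tally, zc_from_tally

logger = logging.getLogger(__name__)

__all__ = [
    "RANKS",
    "ReferenceProteome",
    "ReferenceDatabase",
    "species_reference",
    "aggregate_rank",
    "tallies_from_fasta",
    "MIN_PROTEINS_PER_SPECIES",
]

#: Allowed ranks, most to least specific.  Species appears only inside the
#: builder; query-side lookups use genus .. phylum.
RANKS: tuple[str, ...] = ("species", "genus", "family", "order", "class", "phylum")

#: Species with fewer reference protein sequences than this are excluded.
MIN_PROTEINS_PER_SPECIES = 500


class BelowThresholdError(ValueError):
    """A species had too few reference sequences to build a proteome."""


@dataclass
class ReferenceProteome:
    taxon_name: str
    rank: str
    mean_tally: AminoAcidTally
    n_species: int = 1
    n_proteins: int = 0

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if self.n_species < 1:
            raise ValueError("a reference proteome needs at least one species")
        if self.mean_tally.n_residues <= 0:
            raise ValueError("reference proteome tally is empty")

    @property
    def zc(self) -> float:
        return zc_from_tally(self.mean_tally)


def species_reference(
    taxon_name: str,
    proteins: Sequence[AminoAcidTally],
    min_proteins: int = MIN_PROTEINS_PER_SPECIES,
) -> ReferenceProteome:
    """Mean amino-acid composition over a species' proteins.

    Raises :class:`BelowThresholdError` (an explicit filtered status, not a
    silent drop) when the species has fewer than ``min_proteins`` sequences.
    """
    if len(proteins) == 0:
        raise ValueError(f"no protein sequences for species {taxon_name!r}")
    if len(proteins) < min_proteins:
        raise BelowThresholdError(
            f"species {taxon_name!r} has {len(proteins)} reference sequences "
            f"(< {min_proteins}); excluded"
        )
    return ReferenceProteome(
        taxon_name=taxon_name,
        rank="species",
        mean_tally=mean_tally(proteins),
        n_species=1,
        n_proteins=len(proteins),
    )


def aggregate_rank(
    species_refs: Sequence[ReferenceProteome],
    target_rank: str,
    target_name: str,
) -> ReferenceProteome:
    """Unweighted mean of species mean compositions for a higher-rank taxon."""
    if target_rank not in RANKS or target_rank == "species":
        raise ValueError(f"invalid aggregation rank {target_rank!r}")
    if len(species_refs) == 0:
        raise ValueError(f"no member species for {target_rank} {target_name!r}")
    for ref in species_refs:
        if ref.rank != "species":
            raise ValueError("aggregate_rank expects species-level inputs")
    return ReferenceProteome(
        taxon_name=target_name,
        rank=target_rank,
        mean_tally=mean_tally([r.mean_tally for r in species_refs]),
        n_species=len(species_refs),
        n_proteins=sum(r.n_proteins for r in species_refs),
    )


#: Default FASTA header pattern: ``>protein_id [tax=Genus species]`` or
#: ``>protein_id species=...``; any pattern with a ``taxon`` group works.
DEFAULT_HEADER_REGEX = r"\[tax=(?P<taxon>[^\]]+)\]"


def tallies_from_fasta(
    path: str | Path, header_regex: str = DEFAULT_HEADER_REGEX
) -> dict[str, list[AminoAcidTally]]:
    """Group protein tallies by the taxon label embedded in FASTA headers."""
    pattern = re.compile(header_regex)
    grouped: dict[str, list[AminoAcidTally]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        m = pattern.search(record.description)
        if m is None:
            raise ValueError(
                f"FASTA header {record.description!r} does not match taxon "
                f"pattern {header_regex!r}"
            )
        grouped.setdefault(m.group("taxon"), []).append(
            AminoAcidTally.from_sequence(str(record.seq))
        )
    return grouped


class ReferenceDatabase:
    """Reference proteomes keyed by (rank, taxon name).

    Name collisions across ranks are legal and required: cross-level
    taxonomy mappings can point a class-level name at a phylum-level entry.
    """

    #: CSV column order, fixed for byte-reproducible round trips.
    CSV_COLUMNS = ["rank", "taxon"] + list(AMINO_ACIDS) + ["n_species", "n_proteins"]

    def __init__(self, proteomes: Iterable[ReferenceProteome] = ()) -> None:
        self._entries: dict[tuple[str, str], ReferenceProteome] = {}
        for p in proteomes:
            self.add(p)

    def add(self, proteome: ReferenceProteome) -> None:
        key = (proteome.rank, proteome.taxon_name)
        if key in self._entries:
            raise KeyError(f"duplicate reference proteome for {key}")
        self._entries[key] = proteome

    def get(self, rank: str, name: str) -> ReferenceProteome | None:
        return self._entries.get((rank, name))

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def taxa(self) -> list[tuple[str, str]]:
        return sorted(self._entries)

    def zc_table(self) -> pd.DataFrame:
        rows = [
            {"rank": p.rank, "taxon": p.taxon_name, "Zc": p.zc, "n_species": p.n_species}
            for p in self._entries.values()
        ]
        return pd.DataFrame(rows).sort_values(["rank", "taxon"]).reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for (rank, name), p in sorted(self._entries.items()):
            row: dict[str, object] = {"rank": rank, "taxon": name}
            row.update(p.mean_tally.as_dict())
            row["n_species"] = p.n_species
            row["n_proteins"] = p.n_proteins
            rows.append(row)
        pd.DataFrame(rows, columns=self.CSV_COLUMNS).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceDatabase":
        df = pd.read_csv(path)
        missing = set(cls.CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"reference DB {path} missing columns {sorted(missing)}")
        db = cls()
        for _, row in df.iterrows():
            tally = AminoAcidTally(np.array([row[a] for a in AMINO_ACIDS], float))
            db.add(
                ReferenceProteome(
                    taxon_name=str(row["taxon"]),
                    rank=str(row["rank"]),
                    mean_tally=tally,
                    n_species=int(row["n_species"]),
                    n_proteins=int(row["n_proteins"]),
                )
            )
        return db


def build_database(
    species_proteins: Mapping[str, Sequence[AminoAcidTally]],
    lineage: Mapping[str, Mapping[str, str]],
    min_proteins: int = MIN_PROTEINS_PER_SPECIES,
) -> ReferenceDatabase:
    """Build species references and aggregate them up the given lineages.

    ``lineage`` maps species name -> {rank: taxon name} for any subset of
    genus .. phylum.  Species failing the sequence-count filter are logged
    and excluded from every level.
    """
    kept: dict[str, ReferenceProteome] = {}
    for sp, proteins in species_proteins.items():
        try:
            kept[sp] = species_reference(sp, proteins, min_proteins=min_proteins)
        except BelowThresholdError as exc:
            logger.info("%s", exc)
    db = ReferenceDatabase(kept.values())
    for rank in ("genus", "family", "order", "class", "phylum"):
        groups: dict[str, list[ReferenceProteome]] = {}
        for sp, ref in kept.items():
            name = lineage.get(sp, {}).get(rank)
            if name is not None:
                groups.setdefault(name, []).append(ref)
        for name, members in groups.items():
            db.add(aggregate_rank(members, rank, name))
    return db
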