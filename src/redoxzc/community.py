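"""Per-sample community reference proteomes from 16S taxonomic classifications.

Reads RDP Classifier fixed-rank ("fixrank") output, maps RDP taxon names to
the reference database (NCBI-style names) through automatic rank+name
matching plus a curated manual mapping table, and computes the
classification-count-weighted mean amino-acid composition of each sample:
the community reference proteome.  Also computes metaproteome Z_C from
spectral counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .composition import AminoAcidTally, zc_from_tally
from .refdb import ReferenceDatabase

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifiedRead",
    "SampleRecord",
    "MANUAL_MAPPINGS",
    "read_rdp_fixrank",
    "map_taxa",
    "community_reference_proteome",
    "filter_samples",
    "metaproteome_zc",
    "subsample_counts",
]

#: Ranks usable for reference-proteome lookup, most specific first.
QUERY_RANKS = ("genus", "family", "order", "class", "phylum")

#: Classifications at these levels or to these names are discarded outright.
_DROP_NAMES = {"Chloroplast", "Eukaryota", "cellular organisms"}
_DROP_RANKS = {"rootrank", "norank", "domain", "superkingdom"}

#: Curated RDP -> NCBI taxonomy mappings: (rank_from, name_from) ->
#: (rank_to, name_to).  Within-level renames plus a few cross-level moves
#: (e.g. RDP class Cyanobacteria to the NCBI phylum of the same name).
#: No manual mappings exist for archaeal taxa.
MANUAL_MAPPINGS: dict[tuple[str, str], tuple[str, str]] = {
    ("genus", "Escherichia/Shigella"): ("genus", "Escherichia"),
    ("genus", "Gp1"): ("genus", "Acidobacterium"),
    ("genus", "Gp6"): ("genus", "Luteitalea"),
    ("genus", "GpI"): ("genus", "Nostoc"),
    ("genus", "GpIIa"): ("genus", "Synechococcus"),
    ("genus", "GpVI"): ("genus", "Pseudanabaena"),
    ("family", "Family II"): ("family", "Synechococcaceae"),
    ("family", "Ruminococcaceae"): ("family", "Oscillospiraceae"),
    ("order", "Clostridiales"): ("order", "Eubacteriales"),
    ("order", "Rhizobiales"): ("order", "Hyphomicrobiales"),
    ("class", "Planctomycetacia"): ("class", "Planctomycetia"),
    ("phylum", "Cyanobacteria/Chloroplast"): ("phylum", "Cyanobacteria"),
    ("genus", "Subdivision3_genera_incertae_sedis"): ("family", "Verrucomicrobia subdivision 3"),
    ("genus", "Spartobacteria_genera_incertae_sedis"): ("class", "Spartobacteria"),
    ("class", "Cyanobacteria"): ("phylum", "Cyanobacteria"),
    ("class", "Actinobacteria"): ("phylum", "Actinobacteria"),
}


@dataclass(frozen=True)
class ClassifiedRead:
    sample_id: str
    domain: str
    lowest_rank: str
    lowest_taxon: str
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if self.lowest_rank not in QUERY_RANKS:
            raise ValueError(f"rank {self.lowest_rank!r} outside genus..phylum")


@dataclass
class SampleRecord:
    """Mapped taxon counts for one sample within one domain."""

    sample_id: str
    domain: str
    counts: dict[tuple[str, str], float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative taxon count")

    @property
    def n_classified(self) -> float:
        return float(sum(self.counts.values()))


def read_rdp_fixrank(
    path: str | Path,
    sample_id: str | None = None,
    min_confidence: float | None = None,
) -> list[ClassifiedRead]:
    """Parse RDP Classifier fixrank TSV into classified reads.

    Each row carries a read id followed by (name, rank, confidence) triplets
    from domain down to genus.  The lowest assigned rank between genus and
    phylum is retained; rows classified only to the root or domain level, or
    to Chloroplast or Eukaryota, are dropped.  ``min_confidence`` optionally
    re-thresholds on the classifier's per-rank confidence (the classifier
    itself already applied its 80% cutoff, so the default is no re-filter).
    """
    path = Path(path)
    sample = sample_id if sample_id is not None else path.stem
    reads: list[ClassifiedRead] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            # skip read id and the optional orientation marker column(s)
            rest = [f for f in fields[1:] if f not in ("", "-", "+")]
            if len(rest) % 3 != 0 or not rest:
                raise ValueError(f"{path}:{lineno}: malformed fixrank row")
            triplets = []
            for i in range(0, len(rest), 3):
                name, rank, conf = rest[i], rest[i + 1], rest[i + 2]
                try:
                    triplets.append((name, rank.lower(), float(conf)))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: bad confidence value {conf!r}"
                    ) from exc
            domain = next(
                (n for n, r, _ in triplets if r in ("domain", "superkingdom")), ""
            )
            if domain in ("Eukaryota",) or any(
                n in _DROP_NAMES for n, _, _ in triplets
            ):
                n_dropped += 1
                continue
            usable = [
                (n, r, c)
                for n, r, c in triplets
                if r in QUERY_RANKS
                and n not in _DROP_NAMES
                and (min_confidence is None or c >= min_confidence)
            ]
            if not usable:
                n_dropped += 1  # classified only at root/domain level
                continue
            # deepest assigned rank wins; fixrank rows are ordered shallow->deep
            name, rank, conf = max(usable, key=lambda t: QUERY_RANKS[::-1].index(t[1]))
            reads.append(ClassifiedRead(sample, domain, rank, name, conf))
    if not reads:
        logger.warning("no usable classifications in %s (%d dropped)", path, n_dropped)
    return reads


@dataclass
class MappingReport:
    n_total: int
    n_mapped: int
    n_manual: int
    unmapped: dict[tuple[str, str], int]

    @property
    def pct_mapped(self) -> float:
        return 100.0 * self.n_mapped / self.n_total if self.n_total else float("nan")


def map_taxa(
    reads: Sequence[ClassifiedRead],
    db: ReferenceDatabase,
    manual_map: Mapping[tuple[str, str], tuple[str, str]] | None = None,
) -> tuple[dict[tuple[str, str], float], MappingReport]:
    """Resolve classified reads against the reference database.

    A read's (rank, name) is matched directly, else redirected through the
    manual mapping table (which may change rank), else counted unmapped and
    omitted.  Unmapped is a reported outcome, not an error.
    """
    if manual_map is None:
        manual_map = MANUAL_MAPPINGS
    counts: dict[tuple[str, str], float] = {}
    unmapped: dict[tuple[str, str], int] = {}
    n_mapped = 0
    n_manual = 0
    for read in reads:
        key = (read.lowest_rank, read.lowest_taxon)
        target = key if key in db else None
        if target is None and key in manual_map:
            candidate = manual_map[key]
            if candidate in db:
                target = candidate
                n_manual += 1
        if target is None:
            unmapped[key] = unmapped.get(key, 0) + 1
        else:
            counts[target] = counts.get(target, 0.0) + 1.0
            n_mapped += 1
    report = MappingReport(len(reads), n_mapped, n_manual, unmapped)
    return counts, report


def samples_from_reads(
    reads: Sequence[ClassifiedRead],
    db: ReferenceDatabase,
    manual_map: Mapping[tuple[str, str], tuple[str, str]] | None = None,
    domains: Sequence[str] = ("Bacteria", "Archaea"),
    metadata: Mapping[str, Mapping] | None = None,
) -> tuple[list[SampleRecord], dict[tuple[str, str], MappingReport]]:
    """Group reads by (sample, domain), map them, and build sample records.

    For domain-specific primer libraries pass a single-element ``domains``;
    for universal primers the default splits by classifier-assigned domain.
    """
    grouped: dict[tuple[str, str], list[ClassifiedRead]] = {}
    for read in reads:
        if read.domain in domains:
            grouped.setdefault((read.sample_id, read.domain), []).append(read)
    records: list[SampleRecord] = []
    reports: dict[tuple[str, str], MappingReport] = {}
    for (sample_id, domain), group in sorted(grouped.items()):
        counts, report = map_taxa(group, db, manual_map)
        reports[(sample_id, domain)] = report
        meta = dict(metadata.get(sample_id, {})) if metadata else {}
        records.append(SampleRecord(sample_id, domain, counts, meta))
    return records, reports


def community_reference_proteome(
    sample: SampleRecord, db: ReferenceDatabase
) -> AminoAcidTally:
    """Count-weighted mean amino-acid composition of a sample's community.

    Each mapped taxon's reference composition is multiplied by its
    classification count; the sum is divided by the total mapped count.
    """
    total = sample.n_classified
    if total <= 0:
        raise ValueError(f"sample {sample.sample_id!r} has no mapped counts")
    acc = np.zeros(20)
    for (rank, name), count in sample.counts.items():
        ref = db.get(rank, name)
        if ref is None:
            raise KeyError(f"taxon ({rank}, {name}) absent from reference DB")
        acc += count * ref.mean_tally.counts
    return AminoAcidTally(acc / total)


def filter_samples(
    samples: Sequence[SampleRecord],
    min_reads: int = 100,
    min_archaeal_samples: int = 4,
) -> tuple[list[SampleRecord], list[str]]:
    """Apply the per-domain sample filters.

    Samples with fewer than ``min_reads`` mapped lowest-level assignments in
    a domain are dropped for that domain (boundary inclusive: exactly 100 is
    retained).  If fewer than ``min_archaeal_samples`` archaeal samples
    remain, the archaeal set is dropped entirely.
    """
    exclusion_log: list[str] = []
    retained: list[SampleRecord] = []
    for s in samples:
        if s.n_classified < min_reads:
            exclusion_log.append(
                f"{s.sample_id} [{s.domain}]: {s.n_classified:.0f} mapped reads "
                f"< {min_reads}"
            )
        else:
            retained.append(s)
    archaeal = [s for s in retained if s.domain == "Archaea"]
    if archaeal and len(archaeal) < min_archaeal_samples:
        exclusion_log.append(
            f"archaeal set: only {len(archaeal)} samples remain "
            f"(< {min_archaeal_samples}); archaeal analysis skipped"
        )
        retained = [s for s in retained if s.domain != "Archaea"]
    return retained, exclusion_log


#: ID prefixes that mark decoy/contaminant entries in metaproteome searches.
_DECOY_PREFIXES = ("REV_", "REV__", "DECOY_", "rev_", "CON_", "CON__", "cont_")


def metaproteome_zc(
    psm_counts: Mapping[str, float], protein_fasta: str | Path
) -> float:
    """Z_C of a metaproteome from per-protein spectral counts.

    Each identified protein's amino-acid composition is multiplied by its
    number of peptide-spectrum matches; the weighted compositions are summed
    and Z_C computed on the total.  Contaminant/decoy-prefixed IDs must be
    removed upstream and are rejected here; IDs missing from the FASTA raise
    an error listing all offenders.
    """
    decoys = [pid for pid in psm_counts if pid.startswith(_DECOY_PREFIXES)]
    if decoys:
        raise ValueError(
            f"decoy/contaminant IDs present in spectral counts: {sorted(decoys)}"
        )
    sequences = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(protein_fasta), "fasta")
    }
    missing = sorted(set(psm_counts) - set(sequences))
    if missing:
        raise KeyError(f"protein IDs not found in FASTA: {missing}")
    acc = np.zeros(20)
    for pid, count in psm_counts.items():
        if count < 0:
            raise ValueError(f"negative spectral count for {pid!r}")
        acc += count * AminoAcidTally.from_sequence(sequences[pid]).counts
    return zc_from_tally(AminoAcidTally(acc))


def read_psm_counts(path: str | Path) -> dict[str, float]:
    """Read a two-column (protein_id, spectral_count) TSV."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns protein_id, spectral_count")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def subsample_counts(
    counts: Mapping[tuple[str, str], float], depth: int, seed: int
) -> dict[tuple[str, str], int]:
    """Draw ``depth`` reads without replacement from integer taxon counts.

    Utility for parity experiments with fixed-depth subsampling; not part of
    the default pipeline.
    """
    keys = sorted(counts)
    totals = np.array([counts[k] for k in keys])
    if not np.allclose(totals, np.round(totals)):
        raise ValueError("subsampling requires integer counts")
    totals = totals.astype(int)
    n = int(totals.sum())
    if depth >= n:
        return {k: int(t) for k, t in zip(keys, totals)}
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.repeat(np.arange(len(keys)), totals), depth, replace=False)
    out = np.bincount(chosen, minlength=len(keys))
    return {k: int(c) for k, c in zip(keys, out) if c > 0}
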