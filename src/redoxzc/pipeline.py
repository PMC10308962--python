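"""End-to-end orchestration: files -> sample Z_C -> fits -> tally tables.

Thin glue over the other modules; every step is also usable on its own.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import (
    MappingReport, SampleRecord, community_reference_proteome, filter_samples,
    read_rdp_fixrank, samples_from_reads,
)
from .composition import zc_from_tally
from .geochem import eh_to_eh7, o2_to_uM
from .refdb import ReferenceDatabase
from .stats import RegressionFit, ols_fit, tally_table
from .synth import SurveySpec, SyntheticSurvey, make_survey

logger = logging.getLogger(__name__)

__all__ = [
    "load_metadata",
    "samples_from_fixrank_dir",
    "per_sample_zc_table",
    "dataset_fits",
    "fits_from_survey",
    "slope_recovery_experiment",
    "tally_frame",
]

METADATA_COLUMNS = [
    "sample_id", "dataset", "environment", "Eh_mV", "pH", "T_C",
    "O2_value", "O2_unit",
]


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sample metadata CSV and derive Eh7 (mV) and O2 (uM).

    Missing pH and temperature default to 7 and 25 degC in the correction;
    missing O2 propagates as NaN.
    """
    df = pd.read_csv(path)
    missing = set(METADATA_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns {sorted(missing)}")
    eh7 = []
    for _, row in df.iterrows():
        pH = None if pd.isna(row["pH"]) else float(row["pH"])
        T = None if pd.isna(row["T_C"]) else float(row["T_C"])
        eh7.append(eh_to_eh7(float(row["Eh_mV"]), pH, T))
    df["Eh7_mV"] = eh7
    if "O2_value" in df.columns and "O2_unit" in df.columns:
        o2 = []
        for _, row in df.iterrows():
            if pd.isna(row["O2_value"]):
                o2.append(np.nan)
            else:
                T = 25.0 if pd.isna(row["T_C"]) else float(row["T_C"])
                o2.append(o2_to_uM(float(row["O2_value"]), str(row["O2_unit"]), T))
        df["O2_uM"] = o2
    return df


def samples_from_fixrank_dir(
    fixrank_dir: str | Path,
    db: ReferenceDatabase,
    metadata: pd.DataFrame | None = None,
    domains: Sequence[str] = ("Bacteria", "Archaea"),
    min_confidence: float | None = None,
) -> tuple[list[SampleRecord], dict[tuple[str, str], MappingReport]]:
    """Read every ``*.tsv`` fixrank file in a directory into sample records."""
    meta_map: Mapping[str, Mapping] = {}
    if metadata is not None:
        meta_map = {
            str(row["sample_id"]): row.to_dict() for _, row in metadata.iterrows()
        }
    reads = []
    for path in sorted(Path(fixrank_dir).glob("*.tsv")):
        reads.extend(read_rdp_fixrank(path, min_confidence=min_confidence))
    return samples_from_reads(reads, db, domains=domains, metadata=meta_map)


def per_sample_zc_table(
    samples: Sequence[SampleRecord],
    db: ReferenceDatabase,
    reports: Mapping[tuple[str, str], MappingReport] | None = None,
) -> pd.DataFrame:
    """Community Z_C per (sample, domain); fixed column order."""
    rows = []
    for s in samples:
        zc = zc_from_tally(community_reference_proteome(s, db))
        rep = reports.get((s.sample_id, s.domain)) if reports else None
        rows.append({
            "sample_id": s.sample_id,
            "domain": s.domain,
            "n_classified": rep.n_total if rep else int(s.n_classified),
            "n_mapped": rep.n_mapped if rep else int(s.n_classified),
            "pct_mapped": rep.pct_mapped if rep else 100.0,
            "Zc": zc,
        })
    return pd.DataFrame(
        rows,
        columns=["sample_id", "domain", "n_classified", "n_mapped",
                 "pct_mapped", "Zc"],
    )


def dataset_fits(
    zc_table: pd.DataFrame, metadata: pd.DataFrame
) -> list[RegressionFit]:
    """One Eh7 (V) vs Z_C regression per (dataset, domain)."""
    merged = zc_table.merge(
        metadata[["sample_id", "dataset", "environment", "Eh7_mV"]],
        on="sample_id", how="inner",
    )
    fits = []
    for (dataset, domain), grp in merged.groupby(["dataset", "domain"], sort=True):
        if len(grp) < 3:
            logger.warning("dataset %s [%s]: only %d samples; skipped",
                           dataset, domain, len(grp))
            continue
        fits.append(ols_fit(
            grp["Eh7_mV"].to_numpy() / 1000.0, grp["Zc"].to_numpy(),
            dataset=str(dataset), domain=str(domain),
            environment=str(grp["environment"].iloc[0]),
        ))
    return fits


def fits_from_survey(
    survey: SyntheticSurvey, db: ReferenceDatabase, apply_filters: bool = True
) -> list[RegressionFit]:
    """Run the pipeline on an in-memory synthetic survey.

    Exercises the same steps as the file path (community proteome,
    Nernst correction from the stored Eh/pH/T, per-dataset OLS) without
    touching disk.
    """
    samples = [
        SampleRecord(
            sample_id=s.sample_id, domain="Bacteria", counts=dict(s.counts),
            metadata={"dataset": s.dataset, "environment": s.environment,
                      "Eh_mV": s.eh_mV, "pH": s.pH, "T_C": s.T_C},
        )
        for s in survey.samples
    ]
    if apply_filters:
        samples, _ = filter_samples(samples)
    by_dataset: dict[str, list[SampleRecord]] = {}
    for rec in samples:
        by_dataset.setdefault(rec.metadata["dataset"], []).append(rec)
    fits = []
    for dataset, group in sorted(by_dataset.items()):
        if len(group) < 3:
            continue
        x = np.array([
            eh_to_eh7(r.metadata["Eh_mV"], r.metadata["pH"], r.metadata["T_C"])
            for r in group
        ]) / 1000.0
        y = np.array([
            zc_from_tally(community_reference_proteome(r, db)) for r in group
        ])
        fits.append(ols_fit(
            x, y, dataset=dataset, domain="Bacteria",
            environment=group[0].metadata["environment"],
        ))
    return fits


def slope_recovery_experiment(
    true_slope: float,
    db: ReferenceDatabase,
    n_replicates: int = 200,
    n_samples: int = 30,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> dict[str, float]:
    """Repeatedly generate a one-dataset survey and re-analyze it.

    Each replicate runs the full in-memory pipeline (exact two-pool counts,
    Nernst correction, community Z_C, OLS) on a fresh survey with the given
    true slope.  Returns the fraction of replicates whose 95% CI covers the
    truth and the fraction flagged significant (CI excluding zero) -- the
    latter is the realized type-I error rate when ``true_slope`` is 0.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) >> 1
    n_cover = 0
    n_significant = 0
    for s in child_seeds:
        spec = SurveySpec(
            n_datasets=1, samples_per_dataset=n_samples,
            true_slope=true_slope, noise_sd=noise_sd, seed=int(s),
        )
        fit = fits_from_survey(make_survey(spec, db, exact=True), db)[0]
        lo, hi = fit.ci
        n_cover += lo <= true_slope <= hi
        n_significant += fit.significant
    return {
        "coverage": n_cover / n_replicates,
        "significant_rate": n_significant / n_replicates,
        "n_replicates": n_replicates,
    }


def tally_frame(fits: Sequence[RegressionFit], filtered: bool = False) -> pd.DataFrame:
    """Tally table as a DataFrame in fixed column order."""
    from .stats import format_p
    rows = tally_table(fits, filtered=filtered)
    return pd.DataFrame(
        [{
            "environment": t.label, "N_tot": t.N_tot, "N_pos": t.N_pos,
            "N_neg": t.N_neg, "P": t.P, "P_printed": format_p(t.P),
        } for t in rows],
        columns=["environment", "N_tot", "N_pos", "N_neg", "P", "P_printed"],
    )
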