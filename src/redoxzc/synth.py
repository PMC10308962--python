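"""Synthetic fixtures: reference databases, 16S surveys, Gibbs tables.

Everything the pipeline consumes can be generated here without downloads.
The generator induces the Eh7-Z_C coupling by two-pool mixing: every
community is a blend of a reduced endmember taxon and an oxidized
endmember taxon (leucine-rich vs glycine-rich compositions), echoing the
Clostridia-vs-Proteobacteria shifts seen down a Winogradsky column.  The
mixing fraction has an exact analytic inverse, so a target community Z_C
can be realized exactly and the pipeline's recovered regression slope can
be compared against the generator's truth.

Default survey conditions mirror a typical field compilation: 30 samples
per data set, Eh7 spanning -300..+300 mV, a true slope of 0.016 per volt
(the magnitude of a global pan-environment fit), Gaussian Z_C noise of
0.01 (reproducing a weak-but-real correlation, r ~ 0.3), and 10,000
classified reads per sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .composition import AminoAcidTally, zc_from_tally
from .geochem import eh7_to_eh
from .refdb import ReferenceDatabase, ReferenceProteome
from .thermo import (
    BasisSet, GibbsEntry, GibbsTable, balance_reaction, default_basis_entries,
)
from .composition import ElementalFormula, formula_from_tally, normalize_per_residue
from .geochem import LN10, R_GAS

__all__ = [
    "SurveySpec",
    "SyntheticSurvey",
    "make_reference_db",
    "make_survey",
    "make_gibbs_fixture",
    "write_survey",
]

#: Endmember amino acids: glycine (Z_C = +1) and leucine (Z_C = -1).
_OXIDIZED_AA = "G"
_REDUCED_AA = "L"

ENVIRONMENTS = (
    "River & seawater", "Lake & pond", "Geothermal", "Hyperalkaline",
    "Groundwater", "Sediment", "Soil",
)


def _gly_fraction_for_zc(zc: float) -> float:
    """Residue fraction of glycine (vs leucine) whose carbon-weighted mix
    realizes a target Z_C; exact inverse of the two-component mixture."""
    if not -1.0 <= zc <= 1.0:
        raise ValueError(
            f"target Z_C {zc} unreachable from the Gly/Leu endmembers [-1, 1]"
        )
    return (3.0 + 3.0 * zc) / (4.0 + 2.0 * zc)


def make_reference_db(
    n_taxa: int,
    zc_low: float = -0.35,
    zc_high: float = -0.05,
    proteins_per_species: int = 20,
    protein_length: int = 300,
    seed: int = 0,
    domain: str = "Bacteria",
) -> tuple[ReferenceDatabase, list[tuple[str, str]]]:
    """A genus-level reference database with evenly spaced Z_C targets.

    Returns the database (tallies are the exact fractional mixtures, so
    realized Z_C hits each target to machine precision) and a list of
    (header, sequence) FASTA records whose integer residue counts
    approximate the same compositions.  Deterministic under ``seed``.
    """
    if n_taxa < 1:
        raise ValueError("need at least one taxon")
    targets = np.linspace(zc_low, zc_high, n_taxa)
    rng = np.random.default_rng(seed)
    db = ReferenceDatabase()
    records: list[tuple[str, str]] = []
    for i, zc in enumerate(targets):
        x = _gly_fraction_for_zc(float(zc))
        name = f"{domain[:3]}genus_{i:03d}"
        tally = AminoAcidTally.from_counts({
            _OXIDIZED_AA: x * protein_length,
            _REDUCED_AA: (1.0 - x) * protein_length,
        })
        db.add(ReferenceProteome(
            taxon_name=name, rank="genus", mean_tally=tally,
            n_species=1, n_proteins=proteins_per_species,
        ))
        # integer-residue FASTA companion; rounding spread across proteins
        k_total = int(round(x * protein_length * proteins_per_species))
        base, extra = divmod(k_total, proteins_per_species)
        for j in range(proteins_per_species):
            n_gly = base + (1 if j < extra else 0)
            seq = [_OXIDIZED_AA] * n_gly + [_REDUCED_AA] * (protein_length - n_gly)
            rng.shuffle(seq)
            header = f"sp{i:03d}_p{j:03d} [tax={name}]"
            records.append((header, "".join(seq)))
    return db, records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k:k + width] + "\n")


@dataclass(frozen=True)
class SurveySpec:
    """Conditions for a synthetic 16S survey with a known Eh7-Z_C slope."""

    n_datasets: int = 10
    samples_per_dataset: int = 30
    eh7_range_mV: tuple[float, float] = (-300.0, 300.0)
    true_slope: float = 0.016          # Z_C per volt
    noise_sd: float = 0.01             # Z_C units
    reads_per_sample: int = 10000
    environments: tuple[str, ...] = ENVIRONMENTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eh7_range_mV[0] >= self.eh7_range_mV[1]:
            raise ValueError("degenerate Eh7 range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")


@dataclass
class SyntheticSample:
    sample_id: str
    dataset: str
    environment: str
    eh7_mV: float
    pH: float
    T_C: float
    eh_mV: float
    o2_mg_L: float
    target_zc: float
    counts: dict[tuple[str, str], float]


@dataclass
class SyntheticSurvey:
    spec: SurveySpec
    samples: list[SyntheticSample]
    intercept: float                   # Z_C at Eh7 = 0

    def truth(self) -> dict:
        return {
            "true_slope_per_V": self.spec.true_slope,
            "intercept_zc": self.intercept,
            "noise_sd": self.spec.noise_sd,
            "n_datasets": self.spec.n_datasets,
            "samples_per_dataset": self.spec.samples_per_dataset,
            "seed": self.spec.seed,
        }


def make_survey(
    spec: SurveySpec,
    db: ReferenceDatabase,
    exact: bool = True,
) -> SyntheticSurvey:
    """Generate per-sample taxon counts whose community Z_C tracks Eh7.

    Per sample: Eh7 is uniform on the configured range; the target
    community Z_C is ``a + true_slope * Eh7(V) + N(0, noise_sd)``; counts
    for the two endmember taxa are set by the exact mixing inverse.  Eh is
    back-computed from Eh7 through a randomized pH in [4, 9] so the
    pipeline's own Nernst correction is exercised.  ``exact=True`` keeps
    fractional counts (no multinomial sampling), giving deterministic,
    quantization-free parameter recovery; ``exact=False`` draws whole
    reads.
    """
    rng = np.random.default_rng(spec.seed)
    taxa = sorted(db, key=lambda p: p.zc)
    t_lo, t_hi = taxa[0], taxa[-1]
    z_lo, z_hi = t_lo.zc, t_hi.zc
    if z_hi - z_lo <= 0:
        raise ValueError("reference DB spans no Z_C range")
    c_lo = float((t_lo.mean_tally.counts * _carbons()).sum())
    c_hi = float((t_hi.mean_tally.counts * _carbons()).sum())
    lo_mV, hi_mV = spec.eh7_range_mV
    # center the target band inside the DB span
    intercept = 0.5 * (z_lo + z_hi) - spec.true_slope * 0.5 * (lo_mV + hi_mV) / 1000.0

    samples: list[SyntheticSample] = []
    for d in range(spec.n_datasets):
        env = spec.environments[d % len(spec.environments)]
        dataset = f"synth{d:02d}"
        for s in range(spec.samples_per_dataset):
            eh7 = rng.uniform(lo_mV, hi_mV)
            target = (
                intercept
                + spec.true_slope * eh7 / 1000.0
                + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
            )
            if not z_lo <= target <= z_hi:
                raise ValueError(
                    f"target Z_C {target:.4f} outside reference DB span "
                    f"[{z_lo:.4f}, {z_hi:.4f}]; widen the DB or lower the noise"
                )
            # carbon-weighted two-pool mixing, exact inverse
            rho = (c_lo * (target - z_lo)) / (c_hi * (z_hi - target)) \
                if target < z_hi else np.inf
            p_hi = 1.0 if np.isinf(rho) else rho / (1.0 + rho)
            if exact:
                n_hi = p_hi * spec.reads_per_sample
                n_lo = spec.reads_per_sample - n_hi
            else:
                n_hi = float(rng.binomial(spec.reads_per_sample, p_hi))
                n_lo = spec.reads_per_sample - n_hi
            counts: dict[tuple[str, str], float] = {}
            if n_lo > 0:
                counts[("genus", t_lo.taxon_name)] = n_lo
            if n_hi > 0:
                counts[("genus", t_hi.taxon_name)] = n_hi
            pH = rng.uniform(4.0, 9.0)
            T_C = 25.0
            eh = eh7_to_eh(eh7, pH, T_C)
            o2 = max(0.0, 8.0 * (eh7 - lo_mV) / (hi_mV - lo_mV))
            samples.append(SyntheticSample(
                sample_id=f"{dataset}_s{s:03d}", dataset=dataset,
                environment=env, eh7_mV=eh7, pH=pH, T_C=T_C, eh_mV=eh,
                o2_mg_L=o2, target_zc=target, counts=counts,
            ))
    return SyntheticSurvey(spec=spec, samples=samples, intercept=intercept)


def _carbons() -> np.ndarray:
    from .composition import AA_CARBON
    return AA_CARBON


_FIXRANK_LINEAGE = (
    ("Synthphylum", "phylum"), ("Synthclass", "class"),
    ("Synthorder", "order"), ("Synthfamily", "family"),
)


def write_survey(survey: SyntheticSurvey, out_dir: str | Path) -> dict[str, Path]:
    """Write fixrank TSVs (one per sample), the metadata CSV and truth JSON.

    Fractional counts are rounded to whole reads (largest-remainder), since
    fixrank files carry one row per classified read.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixrank_dir = out / "fixrank"
    fixrank_dir.mkdir(exist_ok=True)
    meta_rows = []
    for sample in survey.samples:
        rows = []
        read_no = 0
        for (rank, taxon), count in sorted(sample.counts.items()):
            for _ in range(int(round(count))):
                lineage = "\t".join(
                    f"{name}\t{rk}\t1.0" for name, rk in _FIXRANK_LINEAGE
                )
                rows.append(
                    f"read_{read_no:06d}\t\t-\tBacteria\tdomain\t1.0\t"
                    f"{lineage}\t{taxon}\t{rank}\t0.99"
                )
                read_no += 1
        (fixrank_dir / f"{sample.sample_id}.tsv").write_text(
            "\n".join(rows) + "\n"
        )
        meta_rows.append({
            "sample_id": sample.sample_id, "dataset": sample.dataset,
            "environment": sample.environment, "Eh_mV": sample.eh_mV,
            "pH": sample.pH, "T_C": sample.T_C,
            "O2_value": sample.o2_mg_L, "O2_unit": "mg_L",
        })
    import pandas as pd
    meta_path = out / "metadata.csv"
    pd.DataFrame(
        meta_rows,
        columns=["sample_id", "dataset", "environment", "Eh_mV", "pH", "T_C",
                 "O2_value", "O2_unit"],
    ).to_csv(meta_path, index=False)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(survey.truth(), indent=2) + "\n")
    return {"fixrank_dir": fixrank_dir, "metadata": meta_path, "truth": truth_path}


def make_gibbs_fixture(
    db: ReferenceDatabase,
    seed: int = 0,
    eh_breaks_mV: tuple[float, float] = (-400.0, 100.0),
    T_C: float = 25.0,
) -> GibbsTable:
    """A demonstration Gibbs table whose stability sequence steps up in Z_C.

    Synthetic by construction: the six basis species get literature-scale
    ΔG°f values, and each proteome's per-residue ΔG°f is solved so that, at
    pH 7, the stability handoffs between taxa (ordered by Z_C) fall at
    evenly spaced Eh values inside ``eh_breaks_mV``.  Because the formation
    reaction of a reduced proteome consumes more electrons, its Gibbs line
    steepens faster with Eh, so the winner sequence along Eh follows
    increasing Z_C -- the stepwise profile the stability model predicts.
    """
    basis = BasisSet()
    table = GibbsTable(default_basis_entries())
    taxa = sorted(db, key=lambda p: p.zc)
    if not taxa:
        raise ValueError("reference DB is empty")
    T_K = T_C + 273.15
    rt_ln10 = R_GAS * T_K * LN10
    basis_dg0 = table.basis_dg0(basis)
    fixed_log_a = np.array(
        [basis.fixed_log_activity[n] for n in basis.names[:4]] + [0.0, 0.0]
    )
    # per-residue neutral formulas and their reaction coefficients
    formulas, slopes, offsets = [], [], []
    for p in taxa:
        f = formula_from_tally(normalize_per_residue(p.mean_tally), polymerized=True)
        f = ElementalFormula(f.c, f.h, f.n, f.o, f.s, z=0.0)
        nu = balance_reaction(f, basis)
        formulas.append(f)
        slopes.append(rt_ln10 * nu[5])                       # dG per unit pe
        offsets.append(-float(nu @ basis_dg0)
                       - rt_ln10 * float(nu @ fixed_log_a)
                       + rt_ln10 * nu[4] * 7.0)              # pH-7 terms sans dG0
    slopes = np.array(slopes)
    if len(taxa) > 1 and not np.all(np.diff(slopes) < 0):
        raise ValueError("taxon compositions do not give a monotone envelope")
    rng = np.random.default_rng(seed)
    k = len(taxa)
    from .thermo import eh_to_pe
    if k > 1:
        breaks_mV = np.linspace(*eh_breaks_mV, k + 1)[1:-1]
        jitter = 0.05 * (eh_breaks_mV[1] - eh_breaks_mV[0]) / k
        breaks_mV = breaks_mV + rng.uniform(-jitter, jitter, size=k - 1)
        breaks_pe = np.asarray(eh_to_pe(breaks_mV, T_C))
    else:
        breaks_pe = np.array([])
    # anchor the first line well above zero: proteomes are unstable relative
    # to the basis across the diagram, as in any realistic setting
    pe_mid = float(eh_to_pe(0.5 * sum(eh_breaks_mV), T_C))
    b = np.empty(k)
    b[0] = 5e4 - slopes[0] * pe_mid
    for i in range(k - 1):
        b[i + 1] = b[i] + (slopes[i] - slopes[i + 1]) * breaks_pe[i]
    for i, p in enumerate(taxa):
        dg0 = b[i] - offsets[i]
        table.add(GibbsEntry(
            species=p.taxon_name, kind="proteome", formula=formulas[i],
            dG0_J_mol=float(dg0), log_activity=None,
        ))
    return table
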