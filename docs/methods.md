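# Methods

This note records the models implemented in `redoxzc`, the conventions and
parameter choices behind them, and what the synthetic fixtures do and do
not establish.

## Carbon oxidation state

For a molecule C_c H_h N_n O_o S_s the average oxidation state of carbon
is `Z_C = (-h + 3n + 2o + 2s)/c`; formal charge does not enter.  For
proteins and proteomes Z_C is computed as the carbon-weighted mean of the
per-amino-acid values, which is algebraically identical to applying the
formula to the summed composition: condensation removes H2O, whose
`-h + 2o` contribution is zero and which carries no carbon.  The property
suite asserts this identity to 1e-12 on random fractional tallies.

Amino-acid elemental formulas are the standard neutral free forms, bundled
as a table; sidechain ionization is irrelevant to Z_C because charge is
ignored.  Ambiguous residue codes (B, J, Z, X, U, O) are dropped from
sequences with a logged count — they are rare and carry no defined
composition.  Fractional tallies are first-class throughout, since means
over proteins and species are fractional.

## Reference proteomes

A species reference proteome is the arithmetic mean amino-acid composition
over the species' protein sequences (equal weight per sequence).  Species
with fewer than 500 sequences are excluded; the threshold is configurable
so desk-scale demonstration databases can use small proteomes.  Higher
ranks (genus through phylum) are unweighted means over member species'
means, so proteome size does not leak into higher-level references —
duplicating every protein of one species changes nothing upstream, which
is tested.  A species is treated as a single pool of sequences; no
sub-species structure is modeled.  The database is keyed by (rank, name),
and name collisions across ranks are deliberately legal because the
taxonomy mappings include cross-level redirects.

## Community assembly

RDP Classifier fixed-rank output is parsed row-wise; the lowest assigned
rank from genus to phylum is kept, and rows classified only to the root or
domain level, or to Chloroplast or Eukaryota, are dropped.  Confidence
re-thresholding is off by default — the classifier has already applied its
80% cutoff — but can be enabled.  Taxon names are resolved against the
reference database by rank and name, then through the curated manual
mapping table (within-level renames such as Escherichia/Shigella →
Escherichia and cross-level moves such as class Cyanobacteria → phylum
Cyanobacteria; the table contains no archaeal entries).  Unmapped
assignments are counted and omitted, never errors.  The community
reference proteome is the classification-count-weighted mean composition
of the mapped taxa; it is scale-invariant in the counts.

Samples with fewer than 100 mapped lowest-level assignments in a domain
are excluded for that domain (exactly 100 is retained), and an archaeal
sample set that falls below four samples is dropped entirely.  The
100-read cutoff is applied to *mapped* lowest-level assignments; applying
it before mapping would be the other defensible reading, and with the high
mapping rates seen in practice the difference is small.  For
domain-specific primers only that domain's assignments are kept; for
universal primers assignments are split by classifier-assigned domain.
Mitochondrial reads are not filtered.  A seeded fixed-depth count
subsampler is provided for parity experiments but is not part of the
default pipeline.

Metaproteome Z_C weights each identified protein's composition by its
spectral count and computes Z_C on the sum.  Decoy/contaminant-prefixed
IDs must be removed upstream and are rejected; a simplified two-column
TSV (protein_id, spectral_count) plus the search FASTA is the interface.

## Redox corrections and oxygen

Eh is handled internally in mV vs SHE; regression slopes are reported per
volt.  `Eh7 = Eh + nernst_slope(T)·(7 − pH)` with
`nernst_slope = −ln(10)·R·T/F` (−59.16 mV/pH at 25 °C); missing pH or
temperature default to 7 and 25 °C, making the correction the identity.
The correction is exactly invertible, which the tests assert to 1e-9 mV.

Oxygen concentrations are normalized to µM: mg/L via the molar mass of O2
(31.9988 g/mol); percent air saturation via a pluggable saturation model,
by default the Benson–Krause (1984) correlation for water-saturated air at
1 atm (valid 0–40 °C, ~258 µM at 25 °C).  Values reported as zero or
below detection pass through as zero.  The saturation model is checked by
properties (monotone decreasing over 5–40 °C, ±5% of published tables at
25 °C) rather than exact values, since several defensible correlations
exist.

## Metastable-equilibrium stability model

Proteomes are compared through formation reactions from six basis species
— glutamine, glutamic acid, cysteine, H2O, H+, e− — whose 6×6 composition
matrix over (C, H, N, O, S, charge) is nonsingular, so coefficients are
the unique solution of a linear system and recomposition is exact.  Fixed
activities are log a(Gln) = −3.2, log a(Glu) = −4.5, log a(Cys) = −3.6,
log a(H2O) = 0; a(H+) = 10^−pH and a(e−) = 10^−pe with
pe = F·Eh/(ln10·R·T).  The Gibbs energy per residue is
`dG = dG0_r + RT ln Q`; the target's activity is its stored value for
basis species (so a basis-species target sits at equilibrium) and unity
for proteomes.  Coefficients are written with the basis on the reactant
side, so a formation that consumes electrons is penalized as Eh rises;
one pe unit (+59.16 mV at 25 °C) changes dG by `nu_e·RT·ln10`.

Standard Gibbs energies are **data**, not computation: group-additivity
derivation (and its temperature dependence) is a separate project, so the
model consumes a GibbsTable CSV and ships a synthetic demonstration
fixture.  Stability diagrams are computed at 25 °C.

The per-residue proteome formula is the mean *free* amino-acid formula
(no water subtraction).  This convention makes a single-amino-acid tally
chemically identical to the corresponding basis species and leaves Z_C
unchanged; the backbone-residue convention (minus one water per residue)
would shift all dG values through the water chemical potential without
changing relative stabilities at log a(H2O) = 0.  Per-residue charge is
taken from the GibbsTable entry (default 0) rather than recomputed from an
ionization model.

Since dG is affine in pH and pe, stability boundaries are straight lines
with slope `−(Δnu_H+/Δnu_e−)·ln10·RT/F`.  For electrically neutral
per-residue formulas charge balance forces `nu_H+ = nu_e−`, so every
boundary has exactly the Nernst slope and Z_C–Eh profiles at different pH
collapse onto one curve under the Eh7 transform — the model-side rationale
for regressing Z_C on Eh7.  The tests verify the boundary slope against a
256×256 grid trace to <1%, and the collapse analytically via exact
envelope breakpoints.  Ties in the winner search go to the lowest input
index and are logged.  The default grid is pH 0–14, Eh −600..+1000 mV,
256×256 nodes, which resolves boundary slopes well below the 1% test
tolerance.  The water window is drawn from the H2/H+ line (E0 = 0) and
the O2/H2O line (E0 = 1229 mV at 25 °C from the ΔG°f of water) at 1 bar
gas fugacity.

## Incomplete-equilibrium simulation

Equilibrium Z_C is sampled from the pH-7 step profile at equal Eh7
intervals (endpoints included).  A random taxon pool is drawn repeatedly
(seeded, without replacement) until its OLS slope against the Eh7 grid is
below a tolerance, default |m| < 0.005/V — an order of magnitude below
the smallest global slope of interest.  The mixture
`w_eq·zc_eq + (1−w_eq)·zc_rand` with `w_eq = 0.20` then has slope exactly
`w_eq·m_eq + (1−w_eq)·m_rand` by linearity of least squares (asserted to
1e-12); with the equilibrium profile scaled to 0.665/V the mixture slope
is 0.133/V.  The random component also widens the slope's confidence
interval, which is checked on a seeded fixture rather than asserted as an
(incorrect) algebraic inequality.

## Statistics

Regressions are ordinary least squares of Z_C on Eh7 in volts; the slope
is reported as m ± MOE95 where MOE95 = t(0.975, N−2) × SE(slope).  The t
rather than normal quantile is used because it is standard OLS practice
and behaves sensibly in degenerate (perfect-fit) cases; at the sample
sizes involved the difference is negligible.  A fit is "significant" when
the 95% CI excludes zero.  Sign tallies across data sets use the exact
one-sided binomial tail P(X ≥ k) at p = 1/2, computed with integer
arithmetic so the value is exact to the last float bit (scipy's binomial
survival function is the independent cross-check in tests).  Printed P
values use three decimals with round-half-even above 1e-3 and five
decimals below, matching tabulated conventions; raw values are always
kept.  The two-group Z_C comparison is a pooled-variance two-sided t-test.
No multiple-testing correction is applied beyond the binomial framing
itself.

## Synthetic data: what it emulates and what it does not

The generator induces the Eh7–Z_C coupling by two-pool mixing between a
reduced (leucine-rich, Z_C = −1 endmember) and an oxidized (glycine-rich,
+1 endmember) composition — the simplest mechanism with an exact analytic
inverse, echoing the oxidized-Proteobacteria vs reduced-Clostridia shifts
seen down sediment redox gradients.  Reference-database taxa are placed at
evenly spaced Z_C targets; the database tallies hit the targets to machine
precision, while the companion FASTA quantizes to integer residues and so
realizes them to ~1e-3.  Default survey conditions: 30 samples per data
set, Eh7 uniform on −300..+300 mV, true slope 0.016/V, Gaussian Z_C noise
of 0.01 (together reproducing a weak-but-real pooled correlation,
r ≈ 0.27), 10,000 classified reads per sample, pH randomized in 4–9 so
the pipeline's own Nernst correction is exercised via the back-computed
Eh.  An `exact` mode keeps fractional counts (no multinomial draw, no
per-read quantization) for machine-precision parameter recovery; written
fixrank files necessarily round to whole reads.

The Gibbs fixture solves per-proteome ΔG°f values so that pH-7 stability
handoffs fall at evenly spaced (slightly jittered) Eh values between −400
and +100 mV, with all proteomes unstable (positive dG) relative to the
basis — qualitatively the configuration expected for real proteomes.

Passing tests on this synthetic world demonstrate that the pipeline's
arithmetic, filters and statistics are correct and that parameters are
recovered without bias at nominal coverage (95% CI coverage ≈ 95%,
significance-filter type-I error ≈ 5%).  They do not demonstrate anything
about real communities: the generator has no amplification bias, no
taxonomy-mapping failures, no compositional noise beyond the two-pool
blend, and no phylogenetic structure.  Against a user-supplied
RefSeq-derived reference database the same code supports the external
checks (methanogen species Z_C spanning ≈ −0.22 to −0.15 and a global
pan-environment slope near 0.016 ± 0.002/V with r ≈ 0.28 at N ≈ 2,800
samples), but those require data that are not bundled and are outside the
automated suite.

## Problem sizes and numerical choices

The acceptance script runs the survey-recovery experiment at 93 data sets
× 30 samples (N = 2,790 pooled samples, the scale of a full field
compilation), 200 replicates for CI-coverage and 500 for type-I error;
boundary-slope checks use a 256×256 grid.  Reaction balancing requires a
residual below 1e-9 (scaled); profile breakpoints are exact line
intersections, not lattice reads.  Replicate seeds are spawned from a
single SeedSequence so every reported number is a pure function of the
top-level seed.
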