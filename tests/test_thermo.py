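"""Reaction balancing, Gibbs energies, and Eh-pH stability diagrams."""

import numpy as np
import pytest

from redoxzc.composition import AminoAcidTally, ElementalFormula
from redoxzc.geochem import FARADAY, LN10, R_GAS, eh_to_eh7, nernst_slope
from redoxzc.thermo import (
    BasisSet, GibbsEntry, GibbsTable, balance_reaction, default_basis_entries,
    delta_g_per_residue, eh_to_pe, stability_grid, water_limits,
    zc_vs_eh_profile,
)

RT_LN10 = R_GAS * 298.15 * LN10


@pytest.fixture(scope="module")
def basis():
    return BasisSet()


@pytest.fixture(scope="module")
def basis_gibbs():
    return GibbsTable(default_basis_entries())


def test_balance_basis_member_is_unit_vector(basis):
    nu = balance_reaction(ElementalFormula(5, 10, 2, 3, 0, 0), basis)
    np.testing.assert_allclose(nu, [1, 0, 0, 0, 0, 0], atol=1e-12)


def test_balance_hydrogen_gas(basis):
    # H2 = 2H+ + 2e-
    nu = balance_reaction(ElementalFormula(0, 2, 0, 0, 0, 0), basis)
    np.testing.assert_allclose(nu, [0, 0, 0, 0, 2, 2], atol=1e-12)


def test_balance_oxygen_gas(basis):
    # O2 = 2H2O - 4H+ - 4e-
    nu = balance_reaction(ElementalFormula(0, 0, 0, 2, 0, 0), basis)
    np.testing.assert_allclose(nu, [0, 0, 0, 2, -4, -4], atol=1e-12)


def test_balance_recomposition_exact(basis):
    targets = [
        ElementalFormula(3, 7, 1, 2, 0, 0),          # alanine
        ElementalFormula(4.2, 8.1, 1.3, 2.2, 0.1, 0.5),  # fractional proteome-like
    ]
    for target in targets:
        nu = balance_reaction(target, basis)
        np.testing.assert_allclose(
            nu @ basis.matrix, target.as_vector(), atol=1e-9
        )


def test_singular_basis_rejected():
    mat = np.ones((6, 6))
    with pytest.raises(ValueError, match="singular"):
        BasisSet(matrix=mat)


def test_basis_species_at_assigned_activity_is_at_equilibrium(basis, basis_gibbs):
    for eh, pH in [(0.0, 7.0), (250.0, 5.0), (-300.0, 9.0)]:
        dg = delta_g_per_residue(
            "glutamine", basis_gibbs, basis, eh_mV=eh, pH=pH,
            tally=AminoAcidTally.from_counts({"Q": 1}),
        )
        assert dg == pytest.approx(0.0, abs=1e-8)


def test_missing_gibbs_entry_names_species(basis_gibbs):
    with pytest.raises(KeyError, match="unobtainium"):
        delta_g_per_residue("unobtainium", basis_gibbs)


def _proteome_table(entries):
    table = GibbsTable(default_basis_entries())
    for e in entries:
        table.add(e)
    return table


ALA = GibbsEntry("ala-res", "proteome", ElementalFormula(3, 7, 1, 2, 0, 0), -100000.0)


def test_delta_g_affine_in_pH_and_eh(basis):
    gibbs = _proteome_table([ALA])
    f = lambda eh, ph: delta_g_per_residue("ala-res", gibbs, basis, eh, ph)
    # affine in pH at fixed Eh
    assert f(100.0, 6.0) - f(100.0, 5.0) == pytest.approx(
        f(100.0, 9.0) - f(100.0, 8.0), rel=1e-12
    )
    # affine in Eh at fixed pH: midpoint interpolates exactly
    assert f(150.0, 7.0) == pytest.approx(
        0.5 * (f(100.0, 7.0) + f(200.0, 7.0)), rel=1e-12
    )


def test_eh_step_changes_dg_by_electron_count(basis):
    """One decade of electron activity (+59.16 mV at 25 degC) moves dG by
    nu_e * RT * ln10 per residue: formations that consume electrons are
    penalized by rising Eh."""
    gibbs = _proteome_table([ALA])
    nu = balance_reaction(ALA.formula, basis)
    step_mV = -nernst_slope(25.0)  # one pe unit
    d1 = delta_g_per_residue("ala-res", gibbs, basis, 0.0, 7.0)
    d2 = delta_g_per_residue("ala-res", gibbs, basis, step_mV, 7.0)
    assert d2 - d1 == pytest.approx(nu[5] * RT_LN10, rel=1e-9)
    assert nu[5] > 0  # alanine formation consumes electrons


def test_identical_proteomes_tie_broken_by_lowest_index():
    twin = GibbsEntry("twin", "proteome", ALA.formula, ALA.dG0_J_mol)
    gibbs = _proteome_table([ALA, twin])
    grid = stability_grid(["ala-res", "twin"], gibbs, shape=(8, 8))
    assert np.all(grid.winner == 0)


def test_grid_requires_proteomes_and_size(basis_gibbs):
    with pytest.raises(ValueError):
        stability_grid([], basis_gibbs)
    gibbs = _proteome_table([ALA])
    with pytest.raises(ValueError):
        stability_grid(["ala-res"], gibbs, shape=(1, 8))


def _two_proteome_charged_table():
    """Two proteome entries whose charges differ, so the stability boundary
    is *not* Nernstian; dG0 of B is chosen to put the boundary at
    (Eh = 0, pH = 7)."""
    a = GibbsEntry("A", "proteome", ElementalFormula(3, 7, 1, 2, 0, 0.0), -5e4)
    basis = BasisSet()
    table = GibbsTable(default_basis_entries())
    table.add(a)
    b_formula = ElementalFormula(2, 5, 1, 2, 0, 0.6)
    # solve dG0_B so dG_A == dG_B at Eh=0, pH=7
    table.add(GibbsEntry("B", "proteome", b_formula, 0.0))
    dg_a = delta_g_per_residue("A", table, basis, 0.0, 7.0)
    dg_b0 = delta_g_per_residue("B", table, basis, 0.0, 7.0)
    table_final = GibbsTable(default_basis_entries())
    table_final.add(a)
    table_final.add(GibbsEntry("B", "proteome", b_formula, dg_a - dg_b0))
    return table_final, basis


def test_boundary_slope_matches_analytic_formula():
    table, basis = _two_proteome_charged_table()
    nu_a = balance_reaction(table.get("A").formula, basis)
    nu_b = balance_reaction(table.get("B").formula, basis)
    d_nu_h = nu_a[4] - nu_b[4]
    d_nu_e = nu_a[5] - nu_b[5]
    analytic_mV_per_pH = -(d_nu_h / d_nu_e) * LN10 * R_GAS * 298.15 / FARADAY * 1e3
    assert analytic_mV_per_pH != pytest.approx(nernst_slope(25.0), rel=1e-3)

    grid = stability_grid(
        ["A", "B"], table, eh_range_mV=(-700.0, 700.0), ph_range=(0.0, 14.0),
        shape=(256, 256),
    )
    # trace the winner flip along Eh for every pH column
    boundary_ph, boundary_eh = [], []
    for j, ph in enumerate(grid.pH):
        col = grid.winner[:, j]
        flips = np.flatnonzero(np.diff(col))
        if len(flips) == 1:
            k = flips[0]
            boundary_ph.append(ph)
            boundary_eh.append(0.5 * (grid.eh_mV[k] + grid.eh_mV[k + 1]))
    assert len(boundary_ph) > 100
    slope = np.polyfit(boundary_ph, boundary_eh, 1)[0]
    assert slope == pytest.approx(analytic_mV_per_pH, rel=0.01)


def test_water_window():
    lo, hi = water_limits(0.0)
    assert lo == pytest.approx(0.0, abs=1e-9)
    assert hi == pytest.approx(1229.0, abs=1.0)
    lo7, hi7 = water_limits(7.0)
    assert lo7 == pytest.approx(-414.1, abs=0.5)
    assert hi7 == pytest.approx(814.9, abs=0.5)
    # parallel lines: window width is pH independent
    widths = [np.subtract(*water_limits(ph)[::-1]) for ph in (0.0, 4.0, 10.0)]
    assert np.ptp(widths) == pytest.approx(0.0, abs=1e-9)


def test_profile_single_proteome_is_constant():
    gibbs = _proteome_table([ALA])
    grid = stability_grid(["ala-res"], gibbs, shape=(8, 8))
    prof = zc_vs_eh_profile(grid, 7.0)
    assert prof.n_segments == 1
    assert np.all(prof.lookup(np.linspace(-600, 1000, 7)) == prof.zc[0])
    with pytest.raises(ValueError):
        zc_vs_eh_profile(grid, 20.0)


def test_profile_stepwise_zc_increase_and_collapse(small_db, gibbs_fixture):
    """With neutral per-residue formulas every boundary is exactly
    Nernstian, so winner Z_C steps up along Eh and the pH 5/7/9 profiles
    coincide once Eh is corrected to Eh7."""
    names = [p.taxon_name for p in sorted(small_db, key=lambda p: p.zc)]
    grid = stability_grid(
        names, gibbs_fixture, eh_range_mV=(-700.0, 400.0), shape=(64, 64)
    )
    profiles = {ph: zc_vs_eh_profile(grid, ph) for ph in (5.0, 7.0, 9.0)}
    for prof in profiles.values():
        assert np.all(np.diff(prof.zc) > 0)          # stepwise increase
        assert prof.n_segments <= len(names)
    ref = profiles[7.0]
    for ph in (5.0, 9.0):
        prof = profiles[ph]
        assert len(prof.zc) == len(ref.zc)
        np.testing.assert_allclose(prof.zc, ref.zc)
        eh7_edges = eh_to_eh7(prof.edges[1:-1], ph, 25.0)
        np.testing.assert_allclose(eh7_edges, ref.edges[1:-1], atol=1e-6)


def test_winner_sensitive_to_common_basis_energy_shift(small_db, gibbs_fixture):
    """Proteomes with different stoichiometries respond differently to a
    uniform shift of the basis-species energies, so the winner map moves;
    a uniform shift of the proteome energies themselves cannot move it."""
    names = [p.taxon_name for p in sorted(small_db, key=lambda p: p.zc)]
    kw = dict(eh_range_mV=(-700.0, 400.0), shape=(32, 32))
    grid0 = stability_grid(names, gibbs_fixture, **kw)

    def shifted(table, kinds, delta):
        out = GibbsTable()
        for name in [*table.proteome_names(),
                     *[e.species for e in default_basis_entries()]]:
            e = table.get(name)
            shift = delta if e.kind in kinds else 0.0
            out.add(GibbsEntry(e.species, e.kind, e.formula,
                               e.dG0_J_mol + shift, e.log_activity))
        return out

    grid_basis = stability_grid(
        names, shifted(gibbs_fixture, {"basis"}, 5e3), **kw)
    assert np.any(grid_basis.winner != grid0.winner)
    grid_prot = stability_grid(
        names, shifted(gibbs_fixture, {"proteome"}, 5e3), **kw)
    np.testing.assert_array_equal(grid_prot.winner, grid0.winner)


def test_eh_to_pe_at_25C():
    # 59.16 mV is one pe unit
    assert eh_to_pe(-nernst_slope(25.0)) == pytest.approx(1.0, rel=1e-9)
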