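"""CSDA Monte Carlo: sampling, geometry scoring, S-values, determinism."""

import dataclasses
import math

import numpy as np
import pytest

from celldose.stopping import StoppingModel, bethe_stopping_keV_per_um
from celldose.transport import (
    KEV_TO_JOULE,
    CellPhantom,
    ElectronSpectrum,
    TransportResult,
    csda_deposit,
    nuclear_dose_share_mc,
    read_spectrum,
    run_s_value_mc,
    sample_emission_point,
)
from celldose.synthetic import toy_spectrum


# ---------------------------------------------------------------- sampling

def test_sampling_containment(phantom):
    rng = np.random.default_rng(7)
    r_central = np.linalg.norm(sample_emission_point("central_sphere", phantom, rng, 2000), axis=1)
    assert np.all(r_central <= phantom.r_source_um + 1e-12)
    r_shell = np.linalg.norm(sample_emission_point("cytoplasm_shell", phantom, rng, 2000), axis=1)
    assert np.all(r_shell >= phantom.r_nucleus_um - 1e-12)
    assert np.all(r_shell <= phantom.r_cell_um + 1e-12)


def test_sampling_uniform_in_volume(phantom):
    """For uniform-in-ball sampling, E[(r/R)^3] = 1/2 (analytic moment)."""
    rng = np.random.default_rng(11)
    r = np.linalg.norm(sample_emission_point("nucleus", phantom, rng, 100_000), axis=1)
    m3 = np.mean((r / phantom.r_nucleus_um) ** 3)
    assert m3 == pytest.approx(0.5, abs=3.0 * 0.29 / math.sqrt(100_000))


def test_sampling_unknown_region(phantom):
    with pytest.raises(ValueError, match="unknown source region"):
        sample_emission_point("mitochondria", phantom, 0)


# ---------------------------------------------------------------- stopping model

def test_stopping_table_monotone_and_positive(water_model):
    assert np.all(water_model.stopping_kev_um > 0)
    r = water_model.csda_range_um(np.geomspace(0.02, 150.0, 50))
    assert np.all(np.diff(r) > 0)


def test_range_energy_inversion_round_trip(water_model):
    e = np.geomspace(0.05, 150.0, 40)
    back = water_model.energy_from_range(water_model.csda_range_um(e))
    assert back == pytest.approx(e, rel=1e-9)


def test_stopping_model_rejects_nonpositive_power():
    with pytest.raises(ValueError, match="non-positive stopping power"):
        StoppingModel(np.array([0.01, 1.0, 10.0]), np.array([1.0, -2.0, 1.0]))


# ---------------------------------------------------------------- single tracks

def test_low_energy_electron_fully_absorbed_in_nucleus(phantom, water_model):
    """50 eV range is ~1 nm; everything stays in the nucleus."""
    dep = csda_deposit((0.0, 0.0, 0.0), (0.0, 0.0, 1.0), 0.05, phantom, water_model)
    assert dep["nucleus"] == pytest.approx(0.05, rel=1e-12)
    assert dep["cytoplasm"] == 0.0
    assert dep["escaped"] == 0.0


@pytest.mark.parametrize("energy", [0.03, 0.4, 2.0, 15.0, 120.0])
def test_track_energy_conservation(energy, phantom, water_model):
    rng = np.random.default_rng(3)
    for _ in range(20):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        p = sample_emission_point("nucleus", phantom, rng)[0]
        dep = csda_deposit(p, u, energy, phantom, water_model)
        total = dep["nucleus"] + dep["cytoplasm"] + dep["escaped"]
        assert total == pytest.approx(energy, rel=1e-9)


def test_chord_split_matches_independent_ode_integration(phantom, water_model):
    """Region split of a boundary-bridging track vs a fine Euler slowdown.

    A track starting at (1.5, 0, 0) along +x crosses the nucleus boundary
    after 0.5 um. The energy is chosen so the CSDA range is ~1 um, i.e. the
    track dies in the cytoplasm. The oracle integrates dE/ds = -S(E) with
    50k Euler steps directly on the raw stopping table, independently of
    the range-inversion machinery.
    """
    energy = float(water_model.energy_from_range(1.0))  # range ~1 um
    dep = csda_deposit((1.5, 0.0, 0.0), (1.0, 0.0, 0.0), energy, phantom, water_model)

    e_grid = water_model.energies_kev
    s_grid = water_model.stopping_kev_um
    e, ds = energy, 1.0 / 50_000
    path, e_at_boundary = 0.0, None
    while e > water_model.floor_kev and path < 4.0:
        e -= np.interp(e, e_grid, s_grid) * ds
        path += ds
        if e_at_boundary is None and path >= 0.5:
            e_at_boundary = max(e, 0.0)
    expected_nucleus = energy - e_at_boundary
    assert dep["nucleus"] == pytest.approx(expected_nucleus, rel=0.01)
    assert dep["escaped"] == 0.0
    assert dep["cytoplasm"] == pytest.approx(energy - dep["nucleus"], rel=1e-9)


def test_csda_deposit_input_validation(phantom, water_model):
    with pytest.raises(ValueError, match="unit vector"):
        csda_deposit((0, 0, 0), (0, 0, 2.0), 1.0, phantom, water_model)
    with pytest.raises(ValueError, match="inside the cell"):
        csda_deposit((9.0, 0, 0), (0, 0, 1.0), 1.0, phantom, water_model)


# ---------------------------------------------------------------- spectrum runs

def test_single_line_full_absorption_closed_form(phantom, water_model):
    """A 0.1 keV line from the central sphere gives S(N<-src) = E/m_N exactly."""
    spec = ElectronSpectrum(((0.1, 1.0),), label="line")
    res = run_s_value_mc(spec, phantom, "central_sphere", 5_000, 42, water_model)
    expected = 0.1 * KEV_TO_JOULE / phantom.mass_nucleus_kg
    assert res.s_values["nucleus"]["value"] == pytest.approx(expected, rel=1e-12)
    assert res.s_values["nucleus"]["se"] <= 1e-12 * expected  # constant deposits
    assert res.edep_cytoplasm_kev_per_decay == 0.0


def test_yield_linearity(phantom, water_model):
    spec = toy_spectrum("tc99m_like")
    r1 = run_s_value_mc(spec, phantom, "central_sphere", 4_000, 5, water_model)
    r2 = run_s_value_mc(spec.scaled(2.0), phantom, "central_sphere", 4_000, 5, water_model)
    assert r2.s_values["nucleus"]["value"] == pytest.approx(
        2 * r1.s_values["nucleus"]["value"], rel=1e-12
    )
    assert r2.edep_escaped_kev_per_decay == pytest.approx(
        2 * r1.edep_escaped_kev_per_decay, rel=1e-12
    )


def test_seed_determinism(phantom, water_model):
    spec = toy_spectrum("tc99m_like")
    a = run_s_value_mc(spec, phantom, "central_sphere", 3_000, 123, water_model)
    b = run_s_value_mc(spec, phantom, "central_sphere", 3_000, 123, water_model)
    assert dataclasses.asdict(a) == dataclasses.asdict(b)


def test_aggregate_energy_conservation(phantom, water_model):
    spec = toy_spectrum("tc99m_like")
    res = run_s_value_mc(spec, phantom, "cytoplasm_shell", 5_000, 9, water_model)
    assert res.total_emitted_kev_per_decay == pytest.approx(
        spec.total_energy_kev_per_decay, rel=1e-9
    )


def test_standard_error_shrinks_as_sqrt_n(phantom, water_model):
    """4x the histories should halve the standard error (within a loose band)."""
    spec = ElectronSpectrum(((120.0, 1.0),), label="ic")
    se = []
    for n, seed in [(2_000, 1), (8_000, 1)]:
        r = run_s_value_mc(spec, phantom, "cytoplasm_shell", n, seed, water_model)
        se.append(r.s_values["nucleus"]["se"])
    ratio = se[0] / se[1]
    assert 1.4 < ratio < 2.8


def test_geometry_limit_thin_cytoplasm(water_model):
    """As the nucleus fills the cell, cytoplasm deposit vanishes."""
    ph = CellPhantom(r_source_um=0.7, r_nucleus_um=3.999, r_cell_um=4.0)
    res = run_s_value_mc(toy_spectrum("low_energy_only"), ph, "central_sphere", 2_000, 2, water_model)
    assert res.edep_cytoplasm_kev_per_decay == pytest.approx(0.0, abs=1e-12)


def test_homogeneous_source_local_absorption_analytic(phantom, water_model):
    """Fully locally-absorbed spectrum from a homogeneous nucleus source:
    S(N<-N) -> sum(y E)/m_N (ranges are nm-scale, boundary leakage ~0)."""
    spec = toy_spectrum("low_energy_only")
    res = run_s_value_mc(spec, phantom, "nucleus", 20_000, 8, water_model)
    expected = spec.total_energy_kev_per_decay * KEV_TO_JOULE / phantom.mass_nucleus_kg
    assert res.s_values["nucleus"]["value"] == pytest.approx(expected, rel=1e-2)


def test_nuclear_dose_share_definitions(phantom):
    def result(n_kev, c_kev):
        return TransportResult(
            edep_nucleus_kev_per_decay=n_kev,
            edep_cytoplasm_kev_per_decay=c_kev,
            edep_escaped_kev_per_decay=0.0,
            s_values={},
            source_region="central_sphere",
            n_histories=1,
            seed=0,
        )

    assert nuclear_dose_share_mc(result(1.0, 0.0), phantom) == 1.0
    # equal *doses* means deposits proportional to masses
    ratio = phantom.mass_cytoplasm_kg / phantom.mass_nucleus_kg
    assert nuclear_dose_share_mc(result(1.0, ratio), phantom) == pytest.approx(0.5)
    with pytest.raises(ZeroDivisionError):
        nuclear_dose_share_mc(result(0.0, 0.0), phantom)


def test_phantom_validation_and_masses():
    with pytest.raises(ValueError):
        CellPhantom(r_source_um=3.0, r_nucleus_um=2.0)
    ph = CellPhantom()
    # 2 um water sphere: 4/3 pi 8 um^3 = 3.351e-14 kg
    assert ph.mass_nucleus_kg == pytest.approx(3.351e-14, rel=1e-3)
    assert ph.mass_cytoplasm_kg == pytest.approx(7.0 * ph.mass_nucleus_kg, rel=1e-12)


def test_empty_or_invalid_spectrum_rejected():
    with pytest.raises(ValueError):
        ElectronSpectrum(())
    with pytest.raises(ValueError):
        ElectronSpectrum(((-1.0, 1.0),))


def test_read_spectrum_formats_and_errors(tmp_path):
    p = tmp_path / "spec.txt"
    p.write_text("# energy_keV yield\n0.5 2.0\n1.2, 0.3  # comma also fine\n")
    spec = read_spectrum(p)
    assert spec.lines == ((0.5, 2.0), (1.2, 0.3))
    bad = tmp_path / "bad.txt"
    bad.write_text("0.5 2.0\noops\n")
    with pytest.raises(ValueError, match="bad.txt:2"):
        read_spectrum(bad)


def test_bethe_parameterization_sane_values():
    """Spot values of the packaged parameterization against reference
    collision stopping powers for water (coarse agreement only)."""
    assert bethe_stopping_keV_per_um(10.0) == pytest.approx(2.2, rel=0.1)
    assert bethe_stopping_keV_per_um(1.0) == pytest.approx(12.6, rel=0.1)
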