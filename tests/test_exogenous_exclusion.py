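"""Theoretical ion generation, ppm matching, and correlation propagation."""

import numpy as np
import pytest

from zebramet import (
    ExogenousCompound,
    FeatureMeta,
    SampleMeta,
    correlation_propagation,
    exclude_exogenous,
    load_default_compounds,
    match_exogenous,
    theoretical_ions,
)
from zebramet.exogenous_exclusion import NEUTRON_MASS

from conftest import make_table

# monoisotopic masses computed up front with an independent formula-mass
# tool, frozen here as oracles for the formula-parsing path
KNOWN_MASSES = {
    "C8H18N2O4S": 238.098728,  # HEPES
    "C8H9NO2": 151.063329,  # paracetamol
    "C9H14N5O4P": 287.078341,  # tenofovir
}


class TestTheoreticalIons:
    def test_protonated_monoisotopic_mz(self):
        c = ExogenousCompound("x", monoisotopic_mass=100.0, adducts=("M+H",), max_isotope=0)
        (ion,) = theoretical_ions([c])
        assert ion.mz == pytest.approx(101.007276, abs=1e-9)

    @pytest.mark.parametrize("formula,mass", sorted(KNOWN_MASSES.items()))
    def test_formula_masses_match_independent_tool(self, formula, mass):
        c = ExogenousCompound("x", formula=formula, adducts=("M+H",), max_isotope=0)
        (ion,) = theoretical_ions([c])
        assert ion.mz == pytest.approx(mass + 1.007276, abs=1e-5)

    def test_ion_counting(self):
        c = ExogenousCompound(
            "x", monoisotopic_mass=200.0, adducts=("M+H", "M+Na", "M+K"), max_isotope=2
        )
        ions = theoretical_ions([c])
        assert len(ions) == 9
        # isotope spacing is one neutron mass
        mh = sorted(i.mz for i in ions if i.adduct == "M+H")
        assert mh[1] - mh[0] == pytest.approx(NEUTRON_MASS)
        na = next(i for i in ions if i.adduct == "M+Na" and i.isotope == 0)
        assert na.mz == pytest.approx(200.0 + 22.989218)

    def test_unparseable_formula_names_compound(self):
        c = ExogenousCompound("mystery", formula="Xx9Qq2")
        with pytest.raises(ValueError, match="mystery"):
            theoretical_ions([c])

    def test_shipped_default_list(self):
        compounds = load_default_compounds()
        assert {c.name for c in compounds} == {
            "HEPES",
            "gentamicin",
            "paracetamol",
            "tenofovir_disoproxil",
            "tenofovir",
        }
        hepes = next(c for c in compounds if c.name == "HEPES")
        ions = theoretical_ions([hepes])
        mh = next(i for i in ions if i.adduct == "M+H" and i.isotope == 0)
        assert mh.mz == pytest.approx(KNOWN_MASSES["C8H18N2O4S"] + 1.007276, abs=1e-5)


class TestMassMatch:
    def _feature(self, mz, fid="F1"):
        return FeatureMeta(fid, mz=mz, rt=60.0)

    def test_exact_match_is_zero_ppm(self):
        c = ExogenousCompound("x", monoisotopic_mass=300.0, adducts=("M+H",), max_isotope=0)
        ions = theoretical_ions([c])
        hits = match_exogenous([self._feature(ions[0].mz)], ions)
        assert hits["F1"].ppm == 0.0

    def test_ten_ppm_error_misses_at_five_ppm_tolerance(self):
        c = ExogenousCompound("x", monoisotopic_mass=300.0, adducts=("M+H",), max_isotope=0)
        ions = theoretical_ions([c])
        off = self._feature(ions[0].mz * (1 + 10e-6))
        assert match_exogenous([off], ions) == {}
        # while an error just under the tolerance still matches
        edge = self._feature(ions[0].mz * (1 + 4.9e-6))
        assert "F1" in match_exogenous([edge], ions)

    def test_lowest_ppm_ion_reported(self):
        ions = theoretical_ions(
            [
                ExogenousCompound("near", monoisotopic_mass=299.9995, adducts=("M+H",), max_isotope=0),
                ExogenousCompound("far", monoisotopic_mass=300.0005, adducts=("M+H",), max_isotope=0),
            ]
        )
        hit = match_exogenous([self._feature(301.0068)], ions)["F1"]
        assert hit.compound == "near"


def correlated_fixture():
    """1 contaminant parent + 2 proportional satellites + 10 background
    features over 12 biological samples."""
    rng = np.random.default_rng(42)
    n = 12
    parent = rng.lognormal(3, 0.5, size=n)
    sat1 = 2.0 * parent
    sat2 = 0.25 * parent
    background = rng.lognormal(3, 0.5, size=(10, n))
    matrix = np.vstack([parent, sat1, sat2, background])
    compound = ExogenousCompound(
        "contam", monoisotopic_mass=400.0, adducts=("M+H",), max_isotope=0
    )
    mz = [401.007276, 422.989218, 402.010631] + list(
        np.linspace(150, 900, 10)
    )
    meta = [SampleMeta(f"S{i + 1}", "biological", block=1) for i in range(n)]
    return make_table(matrix, meta, mz=mz), compound


class TestCorrelationPropagation:
    def test_proportional_satellite_returned_at_r_one(self):
        table, _ = correlated_fixture()
        hits = correlation_propagation(table, {"F1"})
        assert {"F2", "F3"} <= set(hits)
        for anchor, r in (hits["F2"], hits["F3"]):
            assert anchor == "F1"
            assert r == pytest.approx(1.0)

    def test_independent_features_not_returned(self):
        table, _ = correlated_fixture()
        hits = correlation_propagation(table, {"F1"})
        background = {f"F{j}" for j in range(4, 14)}
        assert not background & set(hits)

    def test_anticorrelated_feature_never_excluded(self):
        # signed threshold: a perfect anti-correlate (r = -1) stays
        rng = np.random.default_rng(0)
        anchor = rng.lognormal(3, 0.5, size=10)
        anti = anchor.max() + anchor.min() - anchor  # r = -1 exactly
        table = make_table(np.vstack([anchor, anti]))
        assert correlation_propagation(table, {"F1"}) == {}

    def test_constant_feature_has_zero_correlation(self):
        table = make_table(
            np.vstack([np.arange(1.0, 6.0), np.full(5, 3.0)])
        )
        assert correlation_propagation(table, {"F1"}) == {}

    def test_unknown_anchor_rejected(self):
        table, _ = correlated_fixture()
        with pytest.raises(KeyError, match="nope"):
            correlation_propagation(table, {"nope"})

    def test_needs_three_in_scope_samples(self):
        table = make_table(np.ones((2, 2)) * [[1.0, 2.0]])
        with pytest.raises(ValueError, match="3 in-scope"):
            correlation_propagation(table, {"F1"})


class TestExcludeExogenous:
    def test_composite_fixture_removes_family(self):
        table, compound = correlated_fixture()
        out, report = exclude_exogenous(table, [compound])
        assert report.excluded_ids == {"F1", "F2", "F3"}
        assert out.n_features == 10
        assert report.n_surviving == 10
        # step-1 and step-2 sets are disjoint
        assert not set(report.step1) & set(report.step2)

    def test_empty_compound_list_is_identity(self):
        table, _ = correlated_fixture()
        out, report = exclude_exogenous(table, [])
        assert out.n_features == table.n_features
        assert report.step1 == {} and report.step2 == {}

    def test_no_mass_match_means_no_step2(self):
        table, _ = correlated_fixture()
        ghost = ExogenousCompound(
            "ghost", monoisotopic_mass=950.0, adducts=("M+H",), max_isotope=0
        )
        out, report = exclude_exogenous(table, [ghost])
        assert report.step1 == {} and report.step2 == {}
        assert out.n_features == table.n_features

    def test_simulated_contaminant_recovery(self, study_metrics):
        """All parents mass-matched, >= 95% satellites captured, <= 2%
        background casualties, averaged over the 20-seed study."""
        assert all(m.parent_removal == 1.0 for m in study_metrics)
        assert np.mean([m.satellite_removal for m in study_metrics]) >= 0.95
        assert np.mean([m.background_exclusion for m in study_metrics]) <= 0.02
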