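import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stomaspec.fixtures import make_reflectance
from stomaspec.spectral import DEFAULT_GRID, Spectrum, SpectrumError, WavelengthGrid
from stomaspec.visual import (CatchTable, activity_profile, binning_discriminable,
                              binning_pattern, catch_table, contrast_between,
                              contrast_difference, normalize_catches, quantum_catch,
                              row_activation)

GRID_400_500 = WavelengthGrid(400, 500, 1)


def flat(v, kind, grid=DEFAULT_GRID):
    return Spectrum(grid, np.full(len(grid), float(v)), kind)


class TestQuantumCatch:
    def test_unit_integrand_gives_interval_length(self):
        s = flat(1, "sensitivity", GRID_400_500)
        r = flat(1, "reflectance", GRID_400_500)
        i = flat(1, "irradiance", GRID_400_500)
        assert quantum_catch(s, r, i) == pytest.approx(100.0)

    def test_linear_in_illuminant(self, daylight, retina):
        refl = make_reflectance(0.3)
        ch = retina.channel("R2P")
        q1 = quantum_catch(ch.sensitivity, refl, daylight)
        q2 = quantum_catch(ch.sensitivity, refl, daylight * 2.0)
        assert q2 == pytest.approx(2 * q1, rel=1e-12)

    def test_matches_fine_riemann_oracle(self):
        # independent oracle: 0.01-nm midpoint Riemann sum of the same integrand
        wl = DEFAULT_GRID.wavelengths
        gauss = np.exp(-0.5 * ((wl - 500) / 30.0) ** 2)
        s = Spectrum(DEFAULT_GRID, gauss, "sensitivity")
        q = quantum_catch(s, flat(1, "reflectance"), flat(1, "irradiance"))
        fine = np.arange(300.0, 750.0, 0.01) + 0.005
        oracle = np.sum(np.exp(-0.5 * ((fine - 500) / 30.0) ** 2)) * 0.01
        assert q == pytest.approx(oracle, rel=1e-6)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(SpectrumError):
            quantum_catch(flat(1, "sensitivity", GRID_400_500),
                          flat(1, "reflectance"), flat(1, "irradiance"))


class TestCatchTables:
    def test_one_entry_per_channel(self, retina, daylight):
        t = catch_table(retina, make_reflectance(0.15), daylight)
        assert len(t.entries) == 12 and set(t.entries) == set(retina.labels)

    def test_zero_illuminant_annihilates(self, retina):
        t = catch_table(retina, make_reflectance(0.15), flat(0, "irradiance"))
        assert all(v == 0 for v in t.entries.values())

    def test_disjoint_support_gives_zero_catch(self, retina):
        wl = DEFAULT_GRID.wavelengths
        red_only = Spectrum(DEFAULT_GRID, np.where(wl > 610, 1.0, 0.0), "irradiance")
        cut = np.where(wl <= 560, 1.0, 0.0)
        sens = Spectrum(DEFAULT_GRID, cut, "sensitivity")
        assert quantum_catch(sens, flat(1, "reflectance"), red_only) == 0.0

    def test_normalization_reference_becomes_one(self, retina, daylight):
        t1 = catch_table(retina, make_reflectance(0.15), daylight, "grey0.15", "natural")
        t2 = catch_table(retina, make_reflectance("blue"), daylight, "blue", "natural")
        n1, n2 = normalize_catches([t1, t2], ("R2P", "grey0.15", "natural"))
        assert n1["R2P"] == pytest.approx(1.0)
        # common scalar: ratios unchanged
        assert (n2["R1D"] / n2["R2P"]) == pytest.approx(t2["R1D"] / t2["R2P"])
        # idempotent on the already-normalized tables
        again = normalize_catches([n1, n2], ("R2P", "grey0.15", "natural"))
        assert again[0]["R2P"] == pytest.approx(1.0)

    def test_missing_or_zero_reference_rejected(self, retina, daylight):
        t = catch_table(retina, make_reflectance(0.15), daylight, "grey0.15", "natural")
        with pytest.raises(KeyError):
            normalize_catches([t], ("R2P", "nope", "natural"))
        z = CatchTable({k: 0.0 for k in t.entries}, "z", "natural")
        with pytest.raises(ValueError):
            normalize_catches([z], ("R2P", "z", "natural"))


def table_from_pairs(retina, pairs, normalized=True):
    entries = {lab: 1.0 for lab in retina.labels}
    entries.update(pairs)
    return CatchTable(entries, "x", "illum",
                      normalization=("R2P", "ref", "natural") if normalized else "raw")


class TestActivityProfiles:
    @pytest.mark.parametrize("qd,qp,expected", [
        (3.0, 3.0, 0.0), (math.e, 1.0, 1.0), (2.0, 1.0, math.log(2))])
    def test_log_opponency_closed_forms(self, retina, qd, qp, expected):
        t = table_from_pairs(retina, {"R1D": qd, "R1P": qp})
        prof = activity_profile(retina, t)
        assert prof.values[1] == pytest.approx(expected)

    def test_floor_marks_row_undefined(self, retina):
        t = table_from_pairs(retina, {"R3D": 0.0})
        prof = activity_profile(retina, t)
        assert prof.values[3] is None and 3 not in prof.defined_rows()

    def test_normalized_opponency_form(self, retina):
        t = table_from_pairs(retina, {"R1D": 2.0, "R1P": 1.0})
        prof = activity_profile(retina, t, form="normalized")
        assert prof.values[1] == pytest.approx(1.0 / 3.0)


class TestContrastDifference:
    def test_self_comparison_is_zero(self, retina, daylight):
        ct = contrast_between(retina, make_reflectance("green"), make_reflectance("green"),
                              daylight)
        assert all(v == pytest.approx(0.0) for v in ct.cd.values() if v is not None)

    def test_antisymmetry(self, retina, daylight):
        x, y = make_reflectance("green"), make_reflectance(0.3)
        cxy = contrast_between(retina, x, y, daylight)
        cyx = contrast_between(retina, y, x, daylight)
        for r in cxy.cd:
            if cxy.cd[r] is not None:
                assert cxy.cd[r] == pytest.approx(-cyx.cd[r])

    def test_illuminant_mismatch_rejected(self, retina):
        ta = table_from_pairs(retina, {})
        tb = CatchTable(ta.entries, "x", "other-illum", ta.normalization)
        with pytest.raises(ValueError, match="illuminant"):
            contrast_difference(activity_profile(retina, ta),
                                activity_profile(retina, tb))

    def test_grey_metamers_have_zero_contrast(self, retina, library):
        # flat greys of any two optical densities differ by a scalar only
        for illum in ("natural", "blue-tent", "green-tent", "red-tent"):
            ct = contrast_between(retina, make_reflectance(0.15), make_reflectance(0.9),
                                  library["illuminants"][illum])
            for v in ct.cd.values():
                if v is not None:
                    assert v == pytest.approx(0.0, abs=1e-9)

    def test_illuminant_rescaling_invariance(self, retina, daylight):
        x, y = make_reflectance("red"), make_reflectance(0.6)
        c1 = contrast_between(retina, x, y, daylight)
        c2 = contrast_between(retina, x, y, daylight * 37.5)
        for r in c1.cd:
            if c1.cd[r] is not None:
                assert c2.cd[r] == pytest.approx(c1.cd[r], rel=1e-9)


class TestRowActivation:
    def test_raw_table_rejected(self, retina, daylight):
        t = catch_table(retina, make_reflectance(0.15), daylight)
        with pytest.raises(ValueError, match="normalized"):
            row_activation(t)

    def test_all_unit_catches_activate_all_rows(self, retina):
        t = table_from_pairs(retina, {})
        assert row_activation(t, retina=retina) == {1, 2, 3, 4}

    def test_threshold_zero_needs_only_positive_catch(self, retina):
        t = table_from_pairs(retina, {"R1D": 1e-9})
        assert row_activation(t, threshold=0.0, retina=retina) == {1, 2, 3, 4}

    def test_red_tent_silences_short_rows(self, retina, library):
        t = catch_table(retina, make_reflectance(0.15),
                        library["illuminants"]["red-tent"], "grey0.15", "red-tent")
        ref = catch_table(retina, make_reflectance(0.15),
                          library["illuminants"]["natural"], "grey0.15", "natural")
        n = normalize_catches([t, ref], ("R2P", "grey0.15", "natural"))[0]
        active = row_activation(n, retina=retina)
        assert 0 < len(active) < 4  # some rows silenced, some reporting


class TestBinning:
    def test_max_rescale_and_dominant(self, retina, daylight):
        t = CatchTable({"a": 1.0, "b": 2.0, "c": 4.0}, "x", "i")
        p = binning_pattern(t)
        np.testing.assert_allclose(p.values, [0.25, 0.5, 1.0])
        assert p.dominant == "c" and not p.tie

    def test_scale_invariance(self):
        t1 = CatchTable({"a": 1.0, "b": 2.0}, "x", "i")
        t2 = CatchTable({"a": 5.0, "b": 10.0}, "x", "i")
        d, dist = binning_discriminable(binning_pattern(t1), binning_pattern(t2))
        assert not d and dist == 0.0

    def test_grey_metamers_share_pattern(self, retina, daylight):
        p1 = binning_pattern(catch_table(retina, make_reflectance(0.15), daylight), retina)
        p2 = binning_pattern(catch_table(retina, make_reflectance(0.9), daylight), retina)
        d, dist = binning_discriminable(p1, p2)
        assert not d and dist == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_dominance_is_discriminable(self):
        pa = binning_pattern(CatchTable({"a": 1.0, "b": 0.0}, "x", "i"))
        pb = binning_pattern(CatchTable({"a": 0.0, "b": 1.0}, "y", "i"))
        d, dist = binning_discriminable(pa, pb, tolerance=0.5)
        assert d and dist == 1.0

    def test_all_zero_pattern_undefined(self):
        p = binning_pattern(CatchTable({"a": 0.0, "b": 0.0}, "x", "i"))
        assert not p.defined

    def test_tie_flagged_lowest_index_wins(self):
        p = binning_pattern(CatchTable({"a": 2.0, "b": 2.0}, "x", "i"))
        assert p.tie and p.dominant == "a"

    def test_length_mismatch_rejected(self):
        pa = binning_pattern(CatchTable({"a": 1.0}, "x", "i"))
        pb = binning_pattern(CatchTable({"a": 1.0, "b": 1.0}, "y", "i"))
        with pytest.raises(ValueError):
            binning_discriminable(pa, pb)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.01, 100), min_size=8, max_size=8),
       st.floats(0.1, 10))
def test_profile_and_pattern_illuminant_scale_invariance(qs, c, ):
    """Multiplying all catches by c>0 changes no opponent signal or pattern."""
    from stomaspec.retina import default_retina

    retina = default_retina()
    labels = [f"R{r}{t}" for r in (1, 2, 3, 4) for t in "DP"]
    base = dict(zip(labels, qs))
    base.update({f"R8-{r}": 1.0 for r in (1, 2, 3, 4)})
    t1 = CatchTable(base, "x", "i")
    t2 = CatchTable({k: c * v for k, v in base.items()}, "x", "i")
    p1, p2 = activity_profile(retina, t1), activity_profile(retina, t2)
    for r in (1, 2, 3, 4):
        assert p2.values[r] == pytest.approx(p1.values[r], rel=1e-9, abs=1e-9)
    b1, b2 = binning_pattern(t1), binning_pattern(t2)
    np.testing.assert_allclose(b1.values, b2.values, rtol=1e-9)
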