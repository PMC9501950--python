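import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from antiradical.charge_transfer import (DamConfig, accepting_power,
                                         acceptance_index, build_dam_table,
                                         classify_sector, donating_power,
                                         donation_index,
                                         donor_acceptor_point,
                                         reference_accepting_power,
                                         reference_donating_power)
from antiradical.errors import ConfigurationError, DegenerateHardnessError
from antiradical.species_io import F_REFERENCE, NA_REFERENCE, ReferenceAtom

ia_pairs = st.tuples(
    st.floats(min_value=-20.0, max_value=30.0, allow_nan=False),
    st.floats(min_value=-20.0, max_value=30.0, allow_nan=False),
).filter(lambda p: p[0] - p[1] > 1e-6)


class TestPowers:
    @pytest.mark.parametrize("I,A,expected", [
        (7.15, 0.07, 4.09),   # flavanone-like
        (9.74, 3.06, 9.75),   # ascorbic-like
    ])
    def test_donating_power_two_decimals(self, I, A, expected):
        assert round(donating_power(I, A), 2) == expected

    @pytest.mark.parametrize("I,A,expected", [
        (7.15, 0.07, 0.48),
        (9.74, 3.06, 3.35),
    ])
    def test_accepting_power_two_decimals(self, I, A, expected):
        assert round(accepting_power(I, A), 2) == expected

    def test_donating_numerator_vanishes(self):
        # A = -3I zeroes (3I + A)^2
        assert donating_power(1.0, -3.0) == 0.0

    def test_accepting_numerator_vanishes(self):
        # I = -3A zeroes (I + 3A)^2
        assert accepting_power(3.0, -1.0) == 0.0

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateHardnessError):
            donating_power(5.0, 5.0)
        with pytest.raises(DegenerateHardnessError):
            accepting_power(4.0, 5.0)

    @given(ia_pairs)
    def test_difference_identity_is_chi(self, pair):
        # omega_minus - omega_plus == (I + A) / 2, algebraically
        I, A = pair
        lhs = donating_power(I, A) - accepting_power(I, A)
        assert lhs == pytest.approx((I + A) / 2.0, rel=1e-9, abs=1e-9)

    def test_monotone_in_I_at_fixed_A(self):
        # d(omega_minus)/dI = (3I+A)(3I-7A)/(16(I-A)^2): strictly positive
        # once I > 7A/3, which covers every physically sensible I/A pair
        A = 0.5
        grid = np.linspace(7 * A / 3 + 0.1, A + 20, 200)
        vals = [donating_power(I, A) for I in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_monotone_in_A_at_fixed_I(self):
        # d(omega_plus)/dA = (I+3A)(7I-3A)/(16(I-A)^2): positive for A > -I/3
        I = 9.0
        grid = np.linspace(-I / 3 + 0.1, I - 0.5, 200)
        vals = [accepting_power(I, A) for A in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestIndices:
    def test_na_self_normalizes(self):
        w = reference_donating_power(NA_REFERENCE)
        assert donation_index(w, NA_REFERENCE) == 1.0

    def test_f_self_normalizes(self):
        w = reference_accepting_power(F_REFERENCE)
        assert acceptance_index(w, F_REFERENCE) == 1.0

    @pytest.mark.parametrize("I,A,expected", [
        (7.15, 0.07, 1.18),
        (9.74, 3.06, 2.81),
    ])
    def test_rd_against_default_na(self, I, A, expected):
        assert round(donation_index(donating_power(I, A)), 2) == expected

    @pytest.mark.parametrize("I,A,expected", [
        (7.15, 0.07, 0.14),
        (8.03, 2.99, 1.05),
    ])
    def test_ra_against_default_f(self, I, A, expected):
        assert round(acceptance_index(accepting_power(I, A)), 2) == expected

    def test_default_reference_power_oracle(self, gas_ia):
        """The default anchors must reproduce the printed power/index
        ratios within 1%: omega_minus/Rd ~ 3.47 and omega_plus/Ra ~ 3.40."""
        na_power = reference_donating_power(NA_REFERENCE)
        f_power = reference_accepting_power(F_REFERENCE)
        printed = {  # (omega_minus, omega_plus, Rd, Ra) at 2 dp
            "lupinifolin": (4.09, 0.48, 1.18, 0.14),
            "citflavanone": (4.06, 0.45, 1.17, 0.13),
            "lonchocarpol_a": (3.97, 0.40, 1.14, 0.12),
            "quercetin": (9.10, 3.59, 2.62, 1.05),
            "ascorbic_acid": (9.75, 3.35, 2.81, 0.98),
        }
        for wm, wp, rd, ra in printed.values():
            assert wm / rd == pytest.approx(na_power, rel=0.01)
            assert wp / ra == pytest.approx(f_power, rel=0.022)

    def test_zero_reference_power_is_configuration_error(self):
        # A = -3I makes the donating power vanish
        degenerate = ReferenceAtom("X", 1.0, -3.0)
        with pytest.raises(ConfigurationError):
            donation_index(4.0, degenerate)

    @given(ia_pairs, st.floats(min_value=0.1, max_value=10.0))
    def test_scale_invariance(self, pair, scale):
        """Rd/Ra unchanged when compound and reference I/A share a unit."""
        I, A = pair
        if donating_power(I, A) == 0 or accepting_power(I, A) == 0:
            return
        ref_d = NA_REFERENCE
        ref_d_scaled = ReferenceAtom("Na", ref_d.ionization_potential * scale,
                                     ref_d.electron_affinity * scale)
        rd = donation_index(donating_power(I, A), ref_d)
        rd_scaled = donation_index(donating_power(I * scale, A * scale),
                                   ref_d_scaled)
        assert rd_scaled == pytest.approx(rd, rel=1e-9)


class TestSectors:
    def test_quadrant_labels(self):
        cfg = DamConfig()
        assert classify_sector(0.5, 0.5, cfg) == "electron donor (antioxidant) sector"
        assert classify_sector(1.5, 1.5, cfg) == "anti-reductant (electron acceptor) sector"
        assert classify_sector(1.5, 0.5, cfg) == "amphoteric (donor and acceptor) sector"
        assert classify_sector(0.5, 1.5, cfg) == "weak electron-transfer sector"

    def test_boundary_goes_to_lower_side(self):
        cfg = DamConfig()
        assert classify_sector(1.0, 1.0, cfg) == "electron donor (antioxidant) sector"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_sector(-0.1, 0.5)

    def test_boundaries_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            DamConfig(rd_boundary=0.0)


class TestDamTable:
    def _points(self, ia, phase="gas"):
        return [donor_acceptor_point(cid, phase, I, A)
                for cid, (I, A) in ia.items()]

    def test_five_compound_table(self, gas_ia):
        df = build_dam_table(self._points(gas_ia))
        body = df[~df["is_reference"]]
        assert len(body) == 5
        by_id = body.set_index("compound_id")
        assert round(by_id.loc["lupinifolin", "Rd"], 2) == 1.18
        assert round(by_id.loc["lupinifolin", "Ra"], 2) == 0.14
        assert round(by_id.loc["quercetin", "Ra"], 2) == 1.05
        assert round(by_id.loc["ascorbic_acid", "Rd"], 2) == 2.81
        # deterministic ordering
        assert list(body["compound_id"]) == sorted(body["compound_id"])

    def test_relative_rule_matches_reading(self, gas_ia):
        """Flavanones land donor-leaning, standards acceptor-leaning."""
        df = build_dam_table(self._points(gas_ia))
        rel = df[~df["is_reference"]].set_index("compound_id")["sector_relative"]
        for cid in ("lupinifolin", "citflavanone", "lonchocarpol_a"):
            assert rel[cid] == "donor-leaning"
        for cid in ("quercetin", "ascorbic_acid"):
            assert rel[cid] == "acceptor-leaning"

    def test_empty_points_keep_anchors(self):
        df = build_dam_table([])
        assert len(df) == 2
        assert df["is_reference"].all()
        anchors = df.set_index("compound_id")
        assert anchors.loc["Na (donor reference)", "Rd"] == 1.0
        assert anchors.loc["F (acceptor reference)", "Ra"] == 1.0

    def test_two_phases_one_compound(self, gas_ia, methanol_ia):
        points = (self._points({"lupinifolin": gas_ia["lupinifolin"]}, "gas")
                  + self._points({"lupinifolin": methanol_ia["lupinifolin"]},
                                 "methanol"))
        df = build_dam_table(points)
        body = df[~df["is_reference"]]
        assert len(body) == 2
        assert set(body["phase"]) == {"gas", "methanol"}
        assert set(body["compound_id"]) == {"lupinifolin"}
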