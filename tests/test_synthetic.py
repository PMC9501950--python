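import numpy as np
import pytest

from antiradical.charge_transfer import donor_acceptor_point
from antiradical.errors import GenerationError
from antiradical.reactivity import electron_affinity, global_descriptors, \
    ionization_potential
from antiradical.species_io import ChargeState, read_compound_table
from antiradical.synthetic import (CompoundSpec, SyntheticSpec,
                                   gen_dose_response, gen_energy_triplet,
                                   gen_panel, paper_like,
                                   paper_like_fixture_path)
from antiradical.units import HARTREE_TO_EV


class TestEnergyTriplet:
    def test_round_trip_to_targets(self):
        triplet = gen_energy_triplet(7.15, 0.07, -687.963, "gas")
        by_state = {sp.charge_state: sp.energy_hartree for sp in triplet}
        I = ionization_potential(by_state[ChargeState.CATION],
                                 by_state[ChargeState.NEUTRAL])
        A = electron_affinity(by_state[ChargeState.NEUTRAL],
                              by_state[ChargeState.ANION])
        assert I == pytest.approx(7.15, abs=1e-9)
        assert A == pytest.approx(0.07, abs=1e-9)

    def test_zero_affinity_degenerate_anion_energy(self):
        triplet = gen_energy_triplet(1.0, 0.0, 0.0, "gas")
        by_state = {sp.charge_state: sp.energy_hartree for sp in triplet}
        assert by_state[ChargeState.CATION] == pytest.approx(1.0 / HARTREE_TO_EV)
        assert by_state[ChargeState.ANION] == 0.0

    def test_precondition(self):
        with pytest.raises(GenerationError):
            gen_energy_triplet(1.0, 2.0, 0.0, "gas")

    @pytest.mark.parametrize("I,A", [(7.24, -0.10), (9.74, 3.06), (0.5, -0.5)])
    def test_descriptor_round_trip_below_1e9(self, I, A):
        triplet = gen_energy_triplet(I, A, -123.456, "gas")
        by_state = {sp.charge_state: sp.energy_hartree for sp in triplet}
        I2 = ionization_potential(by_state[ChargeState.CATION],
                                  by_state[ChargeState.NEUTRAL])
        A2 = electron_affinity(by_state[ChargeState.NEUTRAL],
                               by_state[ChargeState.ANION])
        assert abs(I2 - I) < 1e-9
        assert abs(A2 - A) < 1e-9


class TestDoseResponse:
    def test_midpoint_exact(self):
        curve = gen_dose_response(100.0, 2.0, [100.0, 200.0, 400.0], 0.0, 0)
        assert curve.points[0].inhibition == 50.0

    def test_closed_form_at_ten_fold(self):
        curve = gen_dose_response(10.0, 1.0, [100.0], 0.0, 0)
        assert curve.points[0].inhibition == pytest.approx(100.0 / 1.1)

    def test_seed_determinism(self):
        a = gen_dose_response(100.0, 1.0, [10, 100, 1000], 0.05, 42)
        b = gen_dose_response(100.0, 1.0, [10, 100, 1000], 0.05, 42)
        assert [(p.concentration, p.inhibition) for p in a.points] == \
               [(p.concentration, p.inhibition) for p in b.points]

    def test_clamping(self):
        # enormous noise forces values out of range; all must stay clamped
        curve = gen_dose_response(100.0, 1.0, [100.0] * 50, 5.0, 1)
        assert all(-10.0 <= p.inhibition <= 110.0 for p in curve.points)

    def test_preconditions(self):
        with pytest.raises(GenerationError):
            gen_dose_response(-1.0, 1.0, [10.0], 0.0, 0)
        with pytest.raises(GenerationError):
            gen_dose_response(10.0, 1.0, [0.0], 0.0, 0)


class TestSpecValidation:
    def test_target_ordering_enforced(self):
        with pytest.raises(GenerationError):
            CompoundSpec("c", {"gas": (1.0, 2.0)})

    def test_concentrations_increasing(self):
        with pytest.raises(GenerationError):
            SyntheticSpec(seed=0, compounds=(), concentrations=(10.0, 5.0))

    def test_noise_nonnegative(self):
        with pytest.raises(GenerationError):
            SyntheticSpec(seed=0, compounds=(), noise_sd=-0.1)


class TestPanel:
    def test_paper_like_preset_contents(self, gas_ia, methanol_ia):
        spec = paper_like()
        by_id = {c.compound_id: c for c in spec.compounds}
        assert len(by_id) == 5
        for cid, (I, A) in gas_ia.items():
            assert by_id[cid].targets["gas"] == (I, A)
        for cid, (I, A) in methanol_ia.items():
            assert by_id[cid].targets["methanol"] == (I, A)

    def test_deterministic_byte_identical(self):
        spec = paper_like(seed=7, noise_sd=0.03)
        p1, p2 = gen_panel(spec), gen_panel(spec)
        assert p1.ia_values_csv == p2.ia_values_csv
        assert p1.energies_csv == p2.energies_csv
        assert p1.assay_csv == p2.assay_csv

    def test_panel_readable_by_species_io(self, tmp_path):
        paths = gen_panel(paper_like()).write(tmp_path)
        recs_ia = read_compound_table(paths["ia_values"], "ia_values")
        recs_en = read_compound_table(paths["energies"], "energies")
        assert len(recs_ia) == len(recs_en) == 5
        # the two dialects agree about I/A
        en_by_id = {r.compound_id: r for r in recs_en}
        for rec in recs_ia:
            for phase, ia in rec.ia_override.items():
                computed = en_by_id[rec.compound_id].get_ia(phase)
                assert computed.I == pytest.approx(ia.I, abs=1e-9)
                assert computed.A == pytest.approx(ia.A, abs=1e-9)

    def test_bundled_fixture_in_sync(self):
        """The versioned fixture equals a fresh generation byte-for-byte."""
        panel = gen_panel(paper_like(seed=2022, noise_sd=0.02))
        for name, text in (("ia_values", panel.ia_values_csv),
                           ("energies", panel.energies_csv),
                           ("assay", panel.assay_csv)):
            assert paper_like_fixture_path(name).read_text() == text

    def test_noisy_curve_refit_recovers(self):
        from antiradical.assay import fit_ic50
        curve = gen_dose_response(128.64, 1.0,
                                  [5, 15, 45, 135, 405, 1215, 3645, 10935],
                                  noise_sd=0.02, seed=1)
        fit = fit_ic50(curve, model="four_parameter_logistic")
        assert fit.ic50 == pytest.approx(128.64, rel=0.05)

    def test_noisy_panel_median_recovery(self):
        from antiradical.assay import fit_ic50
        spec = paper_like(seed=1, noise_sd=0.02)
        panel = gen_panel(spec)
        curves = {c.compound_id: c
                  for c in read_assay_table_from_text(panel.assay_csv)}
        truth = {c.compound_id: c.true_ic50 for c in spec.compounds}
        rel_errors = []
        for cid, curve in curves.items():
            fit = fit_ic50(curve, model="four_parameter_logistic")
            rel_errors.append(abs(fit.ic50 - truth[cid]) / truth[cid])
        assert float(np.median(rel_errors)) < 0.05


def read_assay_table_from_text(text):
    import tempfile
    from pathlib import Path
    from antiradical.assay import read_assay_table
    with tempfile.TemporaryDirectory() as d:
        p = Path(d) / "assay.csv"
        p.write_text(text)
        return read_assay_table(p)


class TestFullRecovery:
    def test_noise_free_pipeline_recovers_everything(self):
        """Every descriptor and DAM coordinate from generated energies
        equals its closed-form target to 1e-6 relative."""
        spec = paper_like(noise_sd=0.0)
        for comp in spec.compounds:
            for phase, (I, A) in comp.targets.items():
                triplet = gen_energy_triplet(I, A, spec.neutral_energy_base,
                                             phase, comp.compound_id)
                by_state = {sp.charge_state: sp.energy_hartree for sp in triplet}
                I2 = ionization_potential(by_state[ChargeState.CATION],
                                          by_state[ChargeState.NEUTRAL])
                A2 = electron_affinity(by_state[ChargeState.NEUTRAL],
                                       by_state[ChargeState.ANION])
                want = global_descriptors(I, A, "standard")
                got = global_descriptors(I2, A2, "standard")
                for attrname in ("I", "A", "eta", "S", "chi", "mu", "omega"):
                    w, g = getattr(want, attrname), getattr(got, attrname)
                    assert g == pytest.approx(w, rel=1e-6, abs=1e-9)
                want_p = donor_acceptor_point(comp.compound_id, phase, I, A)
                got_p = donor_acceptor_point(comp.compound_id, phase, I2, A2)
                assert got_p.Rd == pytest.approx(want_p.Rd, rel=1e-6)
                assert got_p.Ra == pytest.approx(want_p.Ra, rel=1e-6)
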