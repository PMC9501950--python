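import pytest

# Published-style gas-phase vertical I/A (eV) used across the tests. The
# citflavanone electron affinity is the higher-precision -0.01 value.
GAS_IA = {
    "lupinifolin": (7.15, 0.07),
    "citflavanone": (7.24, -0.01),
    "lonchocarpol_a": (7.24, -0.10),
    "quercetin": (8.03, 2.99),
    "ascorbic_acid": (9.74, 3.06),
}

METHANOL_IA = {
    "lupinifolin": (5.77, 1.71),
    "citflavanone": (5.76, 1.74),
    "lonchocarpol_a": (5.98, 1.65),
}

GAS_HOMO = {
    "lupinifolin": -5.7590,
    "citflavanone": -5.7835,
    "lonchocarpol_a": -5.8950,
}

IC50_PPM = {
    "lupinifolin": 128.64,
    "citflavanone": 548.72,
    "lonchocarpol_a": 441.49,
    "quercetin": 8.14,
    "ascorbic_acid": 4.53,
}


@pytest.fixture
def gas_ia():
    return dict(GAS_IA)


@pytest.fixture
def methanol_ia():
    return dict(METHANOL_IA)


@pytest.fixture
def gas_homo():
    return dict(GAS_HOMO)


@pytest.fixture
def ic50_ppm():
    return dict(IC50_PPM)


@pytest.fixture
def ia_csv(tmp_path, gas_ia):
    """A minimal ia_values table for the five gas-phase compounds."""
    lines = ["compound_id,phase,I_eV,A_eV"]
    for cid, (I, A) in gas_ia.items():
        lines.append(f"{cid},gas,{I},{A}")
    path = tmp_path / "compounds.csv"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def energies_csv(tmp_path):
    """A 3-row energies table for one compound (neutral/cation/anion, gas)."""
    path = tmp_path / "energies.csv"
    path.write_text(
        "compound_id,charge_state,phase,energy_hartree\n"
        "cmp1,neutral,gas,-687.963\n"
        "cmp1,cation,gas,-687.700\n"
        "cmp1,anion,gas,-687.970\n"
    )
    return path
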