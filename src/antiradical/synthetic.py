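"""Synthetic inputs with known ground truth for end-to-end testing.

Energy triplets are generated by inverting the vertical I/A definitions
around an arbitrary neutral base energy (only differences matter
downstream), so recomputing descriptors from the generated energies
recovers the targets exactly. Dose-response curves follow a logistic with
multiplicative Gaussian noise. Energies are exact by design: the
quantum-chemical side of the pipeline is deterministic, noise belongs to
the assay only.

One ``numpy`` generator seeded from a single integer drives all
randomness; there is no global state.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .assay import DosePoint, DoseResponseCurve
from .errors import GenerationError
from .species_io import (ChargeState, CompoundRecord, IaPair, SpeciesEnergy,
                         write_compound_table)
from .units import HARTREE_TO_EV

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompoundSpec:
    """Targets for one synthetic compound."""

    compound_id: str
    targets: Dict[str, Tuple[float, float]]  # phase -> (I_eV, A_eV)
    homo: Optional[float] = None  # eV
    lumo: Optional[float] = None  # eV
    true_ic50: Optional[float] = None  # ppm
    hill_slope: float = 1.0

    def __post_init__(self):
        for phase, (I, A) in self.targets.items():
            if not I > A:
                raise GenerationError(
                    f"{self.compound_id}/{phase}: target I must exceed A "
                    f"({I} <= {A})"
                )
        if self.true_ic50 is not None and not self.true_ic50 > 0:
            raise GenerationError(f"{self.compound_id}: IC50 must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int
    compounds: Tuple[CompoundSpec, ...]
    neutral_energy_base: float = -500.0  # hartree; arbitrary, only deltas matter
    concentrations: Tuple[float, ...] = (2.0, 6.0, 18.0, 54.0, 162.0, 486.0,
                                         1458.0, 4374.0)  # ppm
    noise_sd: float = 0.0  # relative fraction, assay only

    def __post_init__(self):
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be >= 0")
        concs = self.concentrations
        if any(c <= 0 for c in concs) or any(
                b <= a for a, b in zip(concs, concs[1:])):
            raise GenerationError("concentrations must be positive and strictly increasing")


def gen_energy_triplet(target_I: float, target_A: float,
                       neutral_energy_base: float, phase: str,
                       compound_id: str = "synthetic",
                       factor: float = HARTREE_TO_EV) -> List[SpeciesEnergy]:
    """Invert I = E(cation) - E(neutral) and A = E(neutral) - E(anion).

    Returns [neutral, cation, anion] whose recomputed I/A equal the eV
    targets exactly (up to float round-off).
    """
    if not target_I > target_A:
        raise GenerationError(
            f"target I must exceed A ({target_I} <= {target_A})"
        )
    base = neutral_energy_base
    mk = lambda cs, e: SpeciesEnergy(compound_id=compound_id, charge_state=cs,
                                     phase=phase, energy_hartree=e,
                                     method_tag="synthetic")
    return [
        mk(ChargeState.NEUTRAL, base),
        mk(ChargeState.CATION, base + target_I / factor),
        mk(ChargeState.ANION, base - target_A / factor),
    ]


def gen_dose_response(true_ic50: float, hill_slope: float,
                      concentrations: Sequence[float], noise_sd: float,
                      seed: int) -> DoseResponseCurve:
    """Logistic inhibition(c) = 100 / (1 + (IC50/c)^hill) with multiplicative
    Gaussian noise of relative sd *noise_sd*, clamped to [-10, 110]."""
    if not true_ic50 > 0:
        raise GenerationError("true_ic50 must be positive")
    if any(c <= 0 for c in concentrations):
        raise GenerationError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    points = []
    n_clamped = 0
    for c in concentrations:
        inh = 100.0 / (1.0 + (true_ic50 / c) ** hill_slope)
        if noise_sd > 0:
            inh *= 1.0 + rng.normal(0.0, noise_sd)
        clamped = min(max(inh, -10.0), 110.0)
        if clamped != inh:
            n_clamped += 1
        points.append(DosePoint(float(c), float(clamped)))
    if n_clamped:
        log.info("dose-response clamped %d point(s) to [-10, 110]", n_clamped)
    return DoseResponseCurve("synthetic", points)


@dataclass(frozen=True)
class PanelTables:
    """CSV text of the generated panel, in the pipeline's own dialects."""

    ia_values_csv: str
    energies_csv: str
    assay_csv: str

    def write(self, out_dir) -> dict:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, text in (("ia_values", self.ia_values_csv),
                           ("energies", self.energies_csv),
                           ("assay", self.assay_csv)):
            p = out_dir / f"panel_{name}.csv"
            p.write_text(text)
            paths[name] = p
        return paths


def _records_from_spec(spec: SyntheticSpec) -> List[CompoundRecord]:
    records = []
    for comp in spec.compounds:
        rec = CompoundRecord(compound_id=comp.compound_id,
                             homo=comp.homo, lumo=comp.lumo,
                             ic50=comp.true_ic50)
        for phase in sorted(comp.targets):
            I, A = comp.targets[phase]
            rec.ia_override[phase] = IaPair(I=I, A=A)
            for sp in gen_energy_triplet(I, A, spec.neutral_energy_base,
                                         phase, comp.compound_id):
                rec.add_species(sp)
        records.append(rec)
    return records


def gen_panel(spec: SyntheticSpec) -> PanelTables:
    """Generate the full panel as canonical CSV text.

    Byte-identical for a fixed spec (the seed drives only the assay noise).
    The ia_values and energies tables describe the same compounds and are
    mutually consistent by construction.
    """
    records = _records_from_spec(spec)

    def table_text(dialect: str) -> str:
        import tempfile
        buf = Path(tempfile.mkstemp(suffix=".csv")[1])
        try:
            write_compound_table(records, buf, dialect)
            return buf.read_text()
        finally:
            buf.unlink()

    assay_lines = ["compound_id,concentration_ppm,inhibition_pct"]
    for k, comp in enumerate(spec.compounds):
        if comp.true_ic50 is None:
            continue
        curve = gen_dose_response(comp.true_ic50, comp.hill_slope,
                                  spec.concentrations, spec.noise_sd,
                                  seed=spec.seed + k)
        for p in curve.points:
            assay_lines.append(
                f"{comp.compound_id},{p.concentration!r},{p.inhibition!r}"
            )
    return PanelTables(
        ia_values_csv=table_text("ia_values"),
        energies_csv=table_text("energies"),
        assay_csv="\n".join(assay_lines) + "\n",
    )


def paper_like_fixture_path(table: str) -> Path:
    """Path to a bundled fixture table: 'ia_values', 'energies' or 'assay'.

    The bundled files are ``gen_panel(paper_like(seed=2022, noise_sd=0.02))``
    frozen into the package (a test asserts they stay in sync).
    """
    if table not in ("ia_values", "energies", "assay"):
        raise ValueError(f"unknown fixture table {table!r}")
    path = Path(__file__).parent / "data" / f"paper_like_{table}.csv"
    if not path.exists():
        raise FileNotFoundError(path)
    return path


def paper_like(seed: int = 2022, noise_sd: float = 0.0) -> SyntheticSpec:
    """Preset panel: five compounds with published-style gas-phase I/A,
    methanol I/A for the three flavanones, gas-phase HOMO energies, and
    true IC50s for the logistic dose-response curves.

    The citflavanone gas-phase electron affinity uses the higher-precision
    -0.01 eV value (its companion table prints -0.00 at two decimals).
    """
    compounds = (
        CompoundSpec("lupinifolin",
                     {"gas": (7.15, 0.07), "methanol": (5.77, 1.71)},
                     homo=-5.7590, true_ic50=128.64),
        CompoundSpec("citflavanone",
                     {"gas": (7.24, -0.01), "methanol": (5.76, 1.74)},
                     homo=-5.7835, true_ic50=548.72),
        CompoundSpec("lonchocarpol_a",
                     {"gas": (7.24, -0.10), "methanol": (5.98, 1.65)},
                     homo=-5.8950, true_ic50=441.49),
        CompoundSpec("quercetin", {"gas": (8.03, 2.99)}, true_ic50=8.14),
        CompoundSpec("ascorbic_acid", {"gas": (9.74, 3.06)}, true_ic50=4.53),
    )
    return SyntheticSpec(seed=seed, compounds=compounds, noise_sd=noise_sd)
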