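"""Compound/species data model and tabular readers/writers.

Two delimited-text dialects are supported (CSV or TSV, autodetected by file
extension):

``energies``
    columns ``compound_id, charge_state, phase, energy_hartree`` plus the
    optional columns below. Total electronic energies, hartree only.
``ia_values``
    columns ``compound_id, phase, I_eV, A_eV`` plus optionals. Pre-computed
    vertical ionization potential / electron affinity, eV only.

Optional columns for both dialects: ``display_name``, ``method_tag``,
``homo_eV``, ``lumo_eV``, ``ic50_ppm``.

Keeping the two dialects strictly separated (hartree in one, eV in the
other) prevents silent unit mix-ups.
"""

from __future__ import annotations

import csv
import enum
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

from .errors import DuplicateRecordError, FormatError
from .units import HARTREE_TO_EV, hartree_to_ev

log = logging.getLogger(__name__)

KNOWN_PHASES = ("gas", "methanol")

#: matches a printed negative zero such as "-0.00"
_NEG_ZERO = re.compile(r"^-0(\.0+)?$")


class ChargeState(str, enum.Enum):
    NEUTRAL = "neutral"
    CATION = "cation"
    ANION = "anion"


@dataclass(frozen=True)
class SpeciesEnergy:
    """Total electronic energy of one charge state of one compound."""

    compound_id: str
    charge_state: ChargeState
    phase: str
    energy_hartree: float
    method_tag: str = ""

    def __post_init__(self):
        if not math.isfinite(self.energy_hartree):
            raise ValueError(
                f"{self.compound_id}/{self.charge_state.value}/{self.phase}: "
                f"energy must be finite"
            )


@dataclass(frozen=True)
class ReferenceAtom:
    """Atomic anchor for the donor-acceptor map (Na donor, F acceptor)."""

    symbol: str
    ionization_potential: float  # eV
    electron_affinity: float     # eV

    def __post_init__(self):
        if not self.ionization_potential > self.electron_affinity:
            raise ValueError(
                f"reference atom {self.symbol}: I must exceed A "
                f"({self.ionization_potential} <= {self.electron_affinity})"
            )


#: Default references: experimental atomic I/A in eV.
NA_REFERENCE = ReferenceAtom("Na", 5.139, 0.548)
F_REFERENCE = ReferenceAtom("F", 17.423, 3.401)


class IaPair(NamedTuple):
    """Pre-computed vertical (I, A) in eV for one phase."""

    I: float
    A: float


@dataclass
class CompoundRecord:
    """One compound: per-phase species energies and/or I/A overrides,
    optional frontier orbitals and assay data."""

    compound_id: str
    display_name: str = ""
    species: dict = field(default_factory=dict)      # (ChargeState, phase) -> SpeciesEnergy
    ia_override: dict = field(default_factory=dict)  # phase -> IaPair (eV)
    homo: Optional[float] = None  # eV
    lumo: Optional[float] = None  # eV
    assay: Optional[object] = None  # DoseResponseCurve, attached by callers
    ic50: Optional[float] = None  # ppm
    notes: list = field(default_factory=list)

    def add_species(self, sp: SpeciesEnergy) -> None:
        key = (sp.charge_state, sp.phase)
        if key in self.species:
            raise DuplicateRecordError(
                f"duplicate species for ({sp.compound_id}, "
                f"{sp.charge_state.value}, {sp.phase})"
            )
        self.species[key] = sp

    def phases(self) -> list:
        """All phases with any data, sorted."""
        seen = {phase for _, phase in self.species}
        seen.update(self.ia_override)
        return sorted(seen)

    def has_triplet(self, phase: str) -> bool:
        return all((cs, phase) in self.species for cs in ChargeState)

    def get_ia(self, phase: str, factor: float = HARTREE_TO_EV) -> Optional[IaPair]:
        """Vertical (I, A) in eV for *phase*: the override wins over an
        energy triplet (with a logged notice), else I/A are computed from
        the neutral/cation/anion energies; ``None`` if neither is present."""
        override = self.ia_override.get(phase)
        triplet = self.has_triplet(phase)
        if override is not None:
            if triplet:
                log.info(
                    "%s/%s: both energy triplet and I/A override present; "
                    "override wins", self.compound_id, phase,
                )
            return override
        if not triplet:
            return None
        e_neutral = self.species[(ChargeState.NEUTRAL, phase)].energy_hartree
        e_cation = self.species[(ChargeState.CATION, phase)].energy_hartree
        e_anion = self.species[(ChargeState.ANION, phase)].energy_hartree
        return IaPair(
            I=hartree_to_ev(e_cation - e_neutral, factor),
            A=hartree_to_ev(e_neutral - e_anion, factor),
        )


@dataclass
class ValidationReport:
    """Which downstream stages a record can feed in a given phase."""

    compound_id: str
    phase: str
    eligible: dict = field(default_factory=dict)  # stage -> bool
    reasons: dict = field(default_factory=dict)   # stage -> str

    STAGES = ("descriptors", "dam", "fmo", "assay")


def validate_record(rec: CompoundRecord, phase: str) -> ValidationReport:
    """Report-only eligibility check; never raises."""
    report = ValidationReport(rec.compound_id, phase)
    has_ia = rec.get_ia(phase) is not None
    for stage in ("descriptors", "dam"):
        report.eligible[stage] = has_ia
        report.reasons[stage] = (
            "I/A available (override or energy triplet)" if has_ia
            else f"no I/A override and no complete energy triplet for phase {phase!r}"
        )
    has_fmo = rec.homo is not None
    report.eligible["fmo"] = has_fmo
    report.reasons["fmo"] = (
        "HOMO energy present" if has_fmo else "no HOMO energy"
    )
    has_assay = rec.assay is not None or rec.ic50 is not None
    report.eligible["assay"] = has_assay
    report.reasons["assay"] = (
        "dose-response curve or IC50 present" if has_assay
        else "no assay data"
    )
    return report


# ---------------------------------------------------------------------------
# readers / writers

_ENERGIES_REQUIRED = ("compound_id", "charge_state", "phase", "energy_hartree")
_IA_REQUIRED = ("compound_id", "phase", "I_eV", "A_eV")
_OPTIONAL = ("display_name", "method_tag", "homo_eV", "lumo_eV", "ic50_ppm")


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _parse_float(text: str, column: str, row_id: str):
    """Parse a float cell; returns (value, negative_zero_flag)."""
    text = text.strip()
    if _NEG_ZERO.match(text):
        return 0.0, True
    try:
        return float(text), False
    except ValueError as exc:
        raise FormatError(
            f"row {row_id!r}: column {column!r} is not a number: {text!r}"
        ) from exc


def _optional_float(row: dict, column: str, row_id: str):
    raw = row.get(column)
    if raw is None or raw.strip() == "":
        return None
    value, _ = _parse_float(raw, column, row_id)
    return value


def read_compound_table(path, dialect: str) -> list:
    """Read a compound table in the given dialect into CompoundRecords.

    Records preserve first-seen order of compound_id. A printed negative
    zero (e.g. ``-0.00`` for an electron affinity) is parsed as 0.0 and the
    sign is surfaced in the record's ``notes``.
    """
    path = Path(path)
    if dialect not in ("energies", "ia_values"):
        raise ValueError(f"unknown dialect {dialect!r}")
    required = _ENERGIES_REQUIRED if dialect == "energies" else _IA_REQUIRED

    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_delimiter_for(path))
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise FormatError(
                    f"{path.name}: missing required column {col!r} "
                    f"for dialect {dialect!r}"
                )
        rows = list(reader)

    records: dict = {}
    seen_ia: set = set()
    for i, row in enumerate(rows, start=2):  # header is line 1
        cid = row["compound_id"].strip()
        row_id = f"{path.name}:{i} ({cid})"
        rec = records.get(cid)
        if rec is None:
            rec = records[cid] = CompoundRecord(compound_id=cid)
        if row.get("display_name", "").strip():
            rec.display_name = row["display_name"].strip()

        phase = row["phase"].strip()
        if dialect == "energies":
            try:
                cs = ChargeState(row["charge_state"].strip())
            except ValueError:
                raise FormatError(
                    f"row {row_id}: unknown charge_state "
                    f"{row['charge_state']!r}"
                ) from None
            energy, _ = _parse_float(row["energy_hartree"], "energy_hartree", row_id)
            rec.add_species(SpeciesEnergy(
                compound_id=cid, charge_state=cs, phase=phase,
                energy_hartree=energy,
                method_tag=row.get("method_tag", "").strip(),
            ))
        else:
            if (cid, phase) in seen_ia:
                raise DuplicateRecordError(
                    f"duplicate ia_values row for ({cid}, {phase})"
                )
            seen_ia.add((cid, phase))
            i_val, i_negz = _parse_float(row["I_eV"], "I_eV", row_id)
            a_val, a_negz = _parse_float(row["A_eV"], "A_eV", row_id)
            for col, flag in (("I_eV", i_negz), ("A_eV", a_negz)):
                if flag:
                    rec.notes.append(
                        f"{col} printed as negative zero for phase {phase!r}; "
                        f"parsed as 0.0"
                    )
            rec.ia_override[phase] = IaPair(I=i_val, A=a_val)

        homo = _optional_float(row, "homo_eV", row_id)
        if homo is not None:
            rec.homo = homo
        lumo = _optional_float(row, "lumo_eV", row_id)
        if lumo is not None:
            rec.lumo = lumo
        ic50 = _optional_float(row, "ic50_ppm", row_id)
        if ic50 is not None:
            rec.ic50 = ic50

    return list(records.values())


def _fmt(x) -> str:
    """Canonical numeric cell: shortest text that round-trips the float."""
    if x is None:
        return ""
    return repr(float(x))


def write_compound_table(records: Iterable[CompoundRecord], path,
                         dialect: str) -> None:
    """Canonical writer: fixed column order, shortest-round-trip decimals.

    Writing the output of :func:`read_compound_table` reproduces the
    numeric content exactly (write -> read -> write is byte-identical).
    """
    path = Path(path)
    delim = _delimiter_for(path)
    if dialect == "energies":
        cols = list(_ENERGIES_REQUIRED) + list(_OPTIONAL)
    elif dialect == "ia_values":
        cols = list(_IA_REQUIRED) + list(_OPTIONAL)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(cols)
        for rec in records:
            extras = {
                "display_name": rec.display_name,
                "method_tag": "",
                "homo_eV": _fmt(rec.homo),
                "lumo_eV": _fmt(rec.lumo),
                "ic50_ppm": _fmt(rec.ic50),
            }
            if dialect == "energies":
                for (cs, phase), sp in sorted(
                    rec.species.items(), key=lambda kv: (kv[0][1], kv[0][0].value)
                ):
                    writer.writerow([
                        rec.compound_id, cs.value, phase,
                        _fmt(sp.energy_hartree), extras["display_name"],
                        sp.method_tag, extras["homo_eV"], extras["lumo_eV"],
                        extras["ic50_ppm"],
                    ])
            else:
                for phase in sorted(rec.ia_override):
                    ia = rec.ia_override[phase]
                    writer.writerow([
                        rec.compound_id, phase, _fmt(ia.I), _fmt(ia.A),
                        extras["display_name"], extras["method_tag"],
                        extras["homo_eV"], extras["lumo_eV"],
                        extras["ic50_ppm"],
                    ])
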