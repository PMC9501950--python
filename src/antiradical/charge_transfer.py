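"""Electro-donating/accepting powers, Rd/Ra indices and the donor-acceptor map.

omega_minus = (3I + A)^2 / (16 (I - A))   electro-donating power (eV)
omega_plus  = (I + 3A)^2 / (16 (I - A))   electro-accepting power (eV)

A *lower* omega_minus means a better electron donor; a *higher* omega_plus
means a better electron acceptor. Rd and Ra normalize these against atomic
anchors (sodium for donation, fluorine for acceptance), whose powers are
computed from configured experimental atomic I/A — never hard-coded.

The donor-acceptor map (DAM) scatters Rd against Ra. Because published
sector geometry is typically under-specified, two classifications are
emitted side by side: an absolute quadrant rule against fixed boundaries
(default Rd = Ra = 1, the anchors) and a relative rule against the dataset
(donor-leaning when Rd is at or below the per-phase median and Ra is below
the boundary).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import ConfigurationError, DegenerateHardnessError
from .species_io import F_REFERENCE, NA_REFERENCE, ReferenceAtom

log = logging.getLogger(__name__)

DEFAULT_SECTOR_LABELS = {
    ("low", "low"): "electron donor (antioxidant) sector",
    ("high", "high"): "anti-reductant (electron acceptor) sector",
    ("low", "high"): "amphoteric (donor and acceptor) sector",
    ("high", "low"): "weak electron-transfer sector",
}


@dataclass(frozen=True)
class DonorAcceptorPoint:
    compound_id: str
    phase: str
    omega_minus: float  # eV
    omega_plus: float   # eV
    Rd: float
    Ra: float
    sector: str = ""


@dataclass(frozen=True)
class DamConfig:
    """References, boundaries and labels for DAM construction."""

    donor_reference: ReferenceAtom = NA_REFERENCE
    acceptor_reference: ReferenceAtom = F_REFERENCE
    rd_boundary: float = 1.0
    ra_boundary: float = 1.0
    sector_labels: dict = field(default_factory=lambda: dict(DEFAULT_SECTOR_LABELS))

    def __post_init__(self):
        if self.rd_boundary <= 0 or self.ra_boundary <= 0:
            raise ConfigurationError("DAM boundaries must be positive")


def donating_power(I: float, A: float) -> float:
    """Electro-donating power omega_minus = (3I + A)^2 / (16 (I - A)), eV."""
    if not (math.isfinite(I) and math.isfinite(A)):
        raise ValueError("I and A must be finite")
    if I <= A:
        raise DegenerateHardnessError(I, A)
    return (3.0 * I + A) ** 2 / (16.0 * (I - A))


def accepting_power(I: float, A: float) -> float:
    """Electro-accepting power omega_plus = (I + 3A)^2 / (16 (I - A)), eV."""
    if not (math.isfinite(I) and math.isfinite(A)):
        raise ValueError("I and A must be finite")
    if I <= A:
        raise DegenerateHardnessError(I, A)
    return (I + 3.0 * A) ** 2 / (16.0 * (I - A))


def reference_donating_power(ref: ReferenceAtom) -> float:
    """omega_minus of an atomic reference from its configured I/A."""
    return donating_power(ref.ionization_potential, ref.electron_affinity)


def reference_accepting_power(ref: ReferenceAtom) -> float:
    """omega_plus of an atomic reference from its configured I/A."""
    return accepting_power(ref.ionization_potential, ref.electron_affinity)


def donation_index(omega_minus_compound: float,
                   donor_reference: ReferenceAtom = NA_REFERENCE) -> float:
    """Rd = omega_minus(compound) / omega_minus(donor reference)."""
    ref_power = reference_donating_power(donor_reference)
    if ref_power == 0:
        raise ConfigurationError(
            f"donor reference {donor_reference.symbol} has zero donating power"
        )
    return omega_minus_compound / ref_power


def acceptance_index(omega_plus_compound: float,
                     acceptor_reference: ReferenceAtom = F_REFERENCE) -> float:
    """Ra = omega_plus(compound) / omega_plus(acceptor reference)."""
    ref_power = reference_accepting_power(acceptor_reference)
    if ref_power == 0:
        raise ConfigurationError(
            f"acceptor reference {acceptor_reference.symbol} has zero accepting power"
        )
    return omega_plus_compound / ref_power


def donor_acceptor_point(compound_id: str, phase: str, I: float, A: float,
                         cfg: Optional[DamConfig] = None) -> DonorAcceptorPoint:
    """Full DAM point for one compound/phase from its vertical I and A."""
    cfg = cfg or DamConfig()
    w_minus = donating_power(I, A)
    w_plus = accepting_power(I, A)
    rd = donation_index(w_minus, cfg.donor_reference)
    ra = acceptance_index(w_plus, cfg.acceptor_reference)
    return DonorAcceptorPoint(
        compound_id=compound_id, phase=phase, omega_minus=w_minus,
        omega_plus=w_plus, Rd=rd, Ra=ra,
        sector=classify_sector(ra, rd, cfg),
    )


def classify_sector(Ra: float, Rd: float, cfg: Optional[DamConfig] = None) -> str:
    """Absolute quadrant label; values equal to a boundary go to the lower side."""
    cfg = cfg or DamConfig()
    if Ra < 0 or Rd < 0:
        raise ValueError("Ra and Rd must be non-negative")
    rd_side = "low" if Rd <= cfg.rd_boundary else "high"
    ra_side = "low" if Ra <= cfg.ra_boundary else "high"
    return cfg.sector_labels[(rd_side, ra_side)]


def _relative_label(Rd: float, Ra: float, rd_median: float, cfg: DamConfig) -> str:
    # the anchors define "good donor" (Ra below boundary) while the median
    # splits the dataset's own donation scale
    if Rd <= rd_median and Ra < cfg.ra_boundary:
        return "donor-leaning"
    return "acceptor-leaning"


DAM_COLUMNS = ("compound_id", "phase", "Ra", "Rd", "sector_absolute",
               "sector_relative", "is_reference")


def build_dam_table(points: Iterable[DonorAcceptorPoint],
                    cfg: Optional[DamConfig] = None) -> pd.DataFrame:
    """Plot-ready DAM table: one row per point plus the two reference anchors.

    Points are ordered by (compound_id, phase); anchors come last. The
    donor anchor sits at Rd = 1 by self-normalization, the acceptor anchor
    at Ra = 1; each anchor's other coordinate is computed against the
    opposite reference. Anchors are always present, even for zero points.
    """
    cfg = cfg or DamConfig()
    points = sorted(points, key=lambda p: (p.compound_id, p.phase))

    rows = []
    for p in points:
        rows.append({
            "compound_id": p.compound_id, "phase": p.phase,
            "Ra": p.Ra, "Rd": p.Rd,
            "sector_absolute": classify_sector(p.Ra, p.Rd, cfg),
            "sector_relative": "",  # filled per phase below
            "is_reference": False,
        })

    df = pd.DataFrame(rows, columns=DAM_COLUMNS)
    if len(df):
        for phase, group in df.groupby("phase"):
            rd_median = group["Rd"].median()
            df.loc[group.index, "sector_relative"] = [
                _relative_label(rd, ra, rd_median, cfg)
                for rd, ra in zip(group["Rd"], group["Ra"])
            ]

    donor, acceptor = cfg.donor_reference, cfg.acceptor_reference
    anchors = pd.DataFrame([
        {
            "compound_id": f"{donor.symbol} (donor reference)", "phase": "reference",
            "Ra": acceptance_index(
                accepting_power(donor.ionization_potential, donor.electron_affinity),
                acceptor),
            "Rd": 1.0,
            "sector_absolute": "reference anchor",
            "sector_relative": "reference anchor",
            "is_reference": True,
        },
        {
            "compound_id": f"{acceptor.symbol} (acceptor reference)", "phase": "reference",
            "Ra": 1.0,
            "Rd": donation_index(
                donating_power(acceptor.ionization_potential, acceptor.electron_affinity),
                donor),
            "sector_absolute": "reference anchor",
            "sector_relative": "reference anchor",
            "is_reference": True,
        },
    ], columns=DAM_COLUMNS)

    if not len(df):
        return anchors
    return pd.concat([df, anchors], ignore_index=True)
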