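"""Vertical I/A and the seven global conceptual-DFT reactivity descriptors.

Two conventions are supported and never mixed in one table:

``standard``
    the literature definitions — softness S = 1/(2*eta) in 1/eV and
    electrophilicity omega = mu**2 / (2*eta) in eV.
``paper_replication``
    softness evaluated as 1/(2*eta) with eta in hartree and the result
    multiplied by the hartree-to-eV factor (numerically F**2 / (2*eta_eV)),
    and electrophilicity evaluated as mu**2 / 2 in atomic units and
    expressed back in eV (numerically mu_eV**2 / (2*F)). These reproduce
    published tables that applied the mu**2/2 form directly.

The identities chi = -mu and eta = (I - A)/2 hold exactly in both.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .errors import ConventionMismatchError, DegenerateHardnessError
from .units import HARTREE_TO_EV, hartree_to_ev

log = logging.getLogger(__name__)

CONVENTIONS = ("paper_replication", "standard")


@dataclass(frozen=True)
class GlobalDescriptors:
    """The seven global descriptors for one compound in one phase (eV,
    except S whose unit depends on the convention)."""

    compound_id: str
    phase: str
    I: float
    A: float
    eta: float
    S: float
    chi: float
    mu: float
    omega: float
    convention: str
    notices: tuple = ()

    def as_dict(self) -> dict:
        return {
            "compound_id": self.compound_id,
            "phase": self.phase,
            "I_eV": self.I,
            "A_eV": self.A,
            "eta_eV": self.eta,
            "S": self.S,
            "chi_eV": self.chi,
            "mu_eV": self.mu,
            "omega_eV": self.omega,
            "convention": self.convention,
        }


def ionization_potential(e_cation: float, e_neutral: float,
                         factor: float = HARTREE_TO_EV) -> float:
    """Vertical ionization potential I = E(cation) - E(neutral), in eV.

    Inputs are total electronic energies in hartree. A negative result is
    legal (and logged) — it signals inconsistent input energies rather
    than an arithmetic problem.
    """
    value = hartree_to_ev(e_cation - e_neutral, factor)
    if value < 0:
        log.warning("negative ionization potential %.6f eV", value)
    return value


def electron_affinity(e_neutral: float, e_anion: float,
                      factor: float = HARTREE_TO_EV) -> float:
    """Vertical electron affinity A = E(neutral) - E(anion), in eV.

    Negative values describe a vertically metastable anion; they are
    allowed and logged as a notice, not an error.
    """
    value = hartree_to_ev(e_neutral - e_anion, factor)
    if value < 0:
        log.info("negative electron affinity %.6f eV (metastable vertical anion)", value)
    return value


def global_descriptors(I: float, A: float,
                       convention: str = "paper_replication",
                       compound_id: str = "", phase: str = "",
                       factor: float = HARTREE_TO_EV) -> GlobalDescriptors:
    """Compute eta, S, chi, mu, omega from vertical I and A (eV).

    Raises
    ------
    DegenerateHardnessError
        if I <= A (zero or negative gap: S and omega are undefined).
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if not (math.isfinite(I) and math.isfinite(A)):
        raise ValueError("I and A must be finite")
    if I <= A:
        raise DegenerateHardnessError(I, A, compound_id)

    eta = (I - A) / 2.0
    chi = (I + A) / 2.0
    mu = -chi
    notices = []
    if A < 0:
        notices.append("negative electron affinity (metastable vertical anion)")
    if I < 0:
        notices.append("negative ionization potential")

    if convention == "standard":
        S = 1.0 / (2.0 * eta)              # 1/eV
        omega = mu * mu / (2.0 * eta)      # eV
    else:
        # atomic-unit evaluation expressed back in eV
        S = factor * factor / (2.0 * eta)  # == factor * 1/(2*eta_hartree)... /factor
        omega = mu * mu / (2.0 * factor)   # == hartree_to_ev(mu_au**2 / 2)

    return GlobalDescriptors(
        compound_id=compound_id, phase=phase, I=I, A=A, eta=eta, S=S,
        chi=chi, mu=mu, omega=omega, convention=convention,
        notices=tuple(notices),
    )


def descriptors_from_energies(e_neutral: float, e_cation: float,
                              e_anion: float, *, convention: str = "paper_replication",
                              compound_id: str = "", phase: str = "",
                              factor: float = HARTREE_TO_EV) -> GlobalDescriptors:
    """Convenience: I/A from a hartree energy triplet, then descriptors."""
    I = ionization_potential(e_cation, e_neutral, factor)
    A = electron_affinity(e_neutral, e_anion, factor)
    return global_descriptors(I, A, convention=convention,
                              compound_id=compound_id, phase=phase,
                              factor=factor)


DESCRIPTOR_COLUMNS = ("compound_id", "phase", "I_eV", "A_eV", "eta_eV", "S",
                      "chi_eV", "mu_eV", "omega_eV", "convention")


def write_descriptor_table(descriptors: Iterable[GlobalDescriptors],
                           csv_path, json_path: Optional[object] = None) -> None:
    """Write the descriptor table: CSV at 2-decimal display precision plus
    an optional machine-readable JSON with full precision.

    Refuses to mix conventions in one table.
    """
    rows = [d.as_dict() for d in descriptors]
    conventions = {r["convention"] for r in rows}
    if len(conventions) > 1:
        raise ConventionMismatchError(
            f"cannot mix conventions in one table: {sorted(conventions)}"
        )
    csv_path = Path(csv_path)
    with csv_path.open("w", newline="") as fh:
        fh.write(",".join(DESCRIPTOR_COLUMNS) + "\n")
        for r in rows:
            cells = []
            for col in DESCRIPTOR_COLUMNS:
                v = r[col]
                cells.append(f"{v:.2f}" if isinstance(v, float) else str(v))
            fh.write(",".join(cells) + "\n")
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=2) + "\n")
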