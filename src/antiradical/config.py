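"""Pipeline configuration: one flat key-value file (YAML) controls the
conversion factor, reference atoms, DAM boundaries, assay model and
correlation descriptor, plus the input paths for a full run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .charge_transfer import DamConfig
from .errors import ConfigurationError
from .species_io import F_REFERENCE, NA_REFERENCE, ReferenceAtom
from .units import HARTREE_TO_EV

#: documented keys accepted in a config file
CONFIG_KEYS = (
    "hartree_to_ev",
    "na_ionization_potential", "na_electron_affinity",
    "f_ionization_potential", "f_electron_affinity",
    "rd_boundary", "ra_boundary",
    "assay_fit_model", "correlation_descriptor", "convention",
    "compounds_path", "compounds_dialect", "assay_path",
    "phases", "seed",
)


@dataclass
class PipelineConfig:
    hartree_to_ev: float = HARTREE_TO_EV
    na_ionization_potential: float = NA_REFERENCE.ionization_potential
    na_electron_affinity: float = NA_REFERENCE.electron_affinity
    f_ionization_potential: float = F_REFERENCE.ionization_potential
    f_electron_affinity: float = F_REFERENCE.electron_affinity
    rd_boundary: float = 1.0
    ra_boundary: float = 1.0
    assay_fit_model: str = "loglinear_interpolation"
    correlation_descriptor: str = "I"
    convention: str = "paper_replication"
    compounds_path: Optional[str] = None
    compounds_dialect: str = "ia_values"
    assay_path: Optional[str] = None
    phases: Optional[Tuple[str, ...]] = None  # None = all phases found
    seed: int = 0

    @property
    def donor_reference(self) -> ReferenceAtom:
        return ReferenceAtom("Na", self.na_ionization_potential,
                             self.na_electron_affinity)

    @property
    def acceptor_reference(self) -> ReferenceAtom:
        return ReferenceAtom("F", self.f_ionization_potential,
                             self.f_electron_affinity)

    def dam_config(self) -> DamConfig:
        return DamConfig(donor_reference=self.donor_reference,
                         acceptor_reference=self.acceptor_reference,
                         rd_boundary=self.rd_boundary,
                         ra_boundary=self.ra_boundary)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a key-value mapping")
        unknown = set(raw) - set(CONFIG_KEYS)
        if unknown:
            raise ConfigurationError(
                f"{path}: unknown config keys {sorted(unknown)}"
            )
        if "phases" in raw and raw["phases"] is not None:
            raw["phases"] = tuple(raw["phases"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
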