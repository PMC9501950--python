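"""Full-analysis orchestration.

Fixed stage order (for reproducible logs and reports): descriptors per
phase -> donor-acceptor map -> gas/solvent comparison -> frontier-orbital
ranking -> assay IC50s -> descriptor-IC50 correlations. A failure for one
compound is isolated and recorded; the rest of the run proceeds. Given the
same config and inputs, the machine-readable outputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .assay import (CorrelationResult, DoseResponseCurve, fit_ic50,
                    pearson_correlation, read_assay_table)
from .charge_transfer import (DonorAcceptorPoint, build_dam_table,
                              donor_acceptor_point)
from .config import PipelineConfig
from .errors import AntiradicalError
from .fmo import FrontierOrbitals, koopmans_consistency, rank_by_homo
from .reactivity import GlobalDescriptors, global_descriptors
from .species_io import CompoundRecord, read_compound_table

log = logging.getLogger(__name__)

#: descriptor columns available as correlation x-variables
CORRELATION_DESCRIPTORS = ("I", "A", "eta", "S", "chi", "mu", "omega",
                           "omega_minus", "omega_plus", "Rd", "Ra", "homo")


@dataclass(frozen=True)
class PhaseShift:
    """Solvent-minus-gas differences for one compound, with a qualitative
    reading reported as text rather than enforced as a sign rule."""

    compound_id: str
    delta_I: float
    delta_A: float
    delta_Rd: float
    delta_Ra: float
    summary: str


def compare_phases(gas: Tuple[GlobalDescriptors, DonorAcceptorPoint],
                   solvent: Tuple[GlobalDescriptors, DonorAcceptorPoint]) -> PhaseShift:
    """Elementwise solvent - gas shift for one compound."""
    gd, gp = gas
    sd, sp = solvent
    if gd.compound_id != sd.compound_id:
        raise ValueError(
            f"compound mismatch: {gd.compound_id!r} vs {sd.compound_id!r}"
        )
    delta_i = sd.I - gd.I
    delta_a = sd.A - gd.A
    parts = []
    parts.append("I decreased" if delta_i < 0 else
                 "I increased" if delta_i > 0 else "I unchanged")
    parts.append("A increased" if delta_a > 0 else
                 "A decreased" if delta_a < 0 else "A unchanged")
    if delta_i < 0 and delta_a > 0:
        parts.append("(donor weakened / acceptor strengthened reading)")
    return PhaseShift(
        compound_id=gd.compound_id,
        delta_I=delta_i, delta_A=delta_a,
        delta_Rd=sp.Rd - gp.Rd, delta_Ra=sp.Ra - gp.Ra,
        summary="; ".join(parts),
    )


@dataclass
class ReportBundle:
    descriptors: pd.DataFrame
    dam: pd.DataFrame
    phase_shifts: pd.DataFrame
    fmo: pd.DataFrame
    assay: pd.DataFrame
    correlations: pd.DataFrame
    residuals: pd.DataFrame
    metadata: dict
    errors: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    TABLES = ("descriptors", "dam", "phase_shifts", "fmo", "assay",
              "correlations", "residuals")

    def write(self, out_dir, format: str = "csv") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in self.TABLES:
            df: pd.DataFrame = getattr(self, name)
            if format == "csv":
                df.to_csv(out_dir / f"{name}.csv", index=False)
            else:
                df.to_json(out_dir / f"{name}.json", orient="records", indent=2)
        meta = dict(self.metadata)
        meta["errors"] = self.errors
        meta["warnings"] = self.warnings
        (out_dir / "run_metadata.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n"
        )


def _descriptor_stage(records: Sequence[CompoundRecord],
                      cfg: PipelineConfig,
                      errors: List[str]) -> List[GlobalDescriptors]:
    out = []
    for rec in records:
        phases = cfg.phases or rec.phases()
        for phase in phases:
            ia = rec.get_ia(phase, cfg.hartree_to_ev)
            if ia is None:
                log.info("descriptors %s/%s: skipped (no I/A)",
                         rec.compound_id, phase)
                continue
            try:
                out.append(global_descriptors(
                    ia.I, ia.A, convention=cfg.convention,
                    compound_id=rec.compound_id, phase=phase,
                    factor=cfg.hartree_to_ev))
                log.info("descriptors %s/%s: ok", rec.compound_id, phase)
            except AntiradicalError as exc:
                errors.append(f"descriptors {rec.compound_id}/{phase}: {exc}")
                log.error("descriptors %s/%s: %s", rec.compound_id, phase, exc)
    return out


def _dam_stage(records: Sequence[CompoundRecord], cfg: PipelineConfig,
               errors: List[str]) -> List[DonorAcceptorPoint]:
    dam_cfg = cfg.dam_config()
    points = []
    for rec in records:
        phases = cfg.phases or rec.phases()
        for phase in phases:
            ia = rec.get_ia(phase, cfg.hartree_to_ev)
            if ia is None:
                continue
            try:
                points.append(donor_acceptor_point(
                    rec.compound_id, phase, ia.I, ia.A, dam_cfg))
                log.info("dam %s/%s: ok", rec.compound_id, phase)
            except AntiradicalError as exc:
                errors.append(f"dam {rec.compound_id}/{phase}: {exc}")
                log.error("dam %s/%s: %s", rec.compound_id, phase, exc)
    return points


def _phase_stage(descriptors: Sequence[GlobalDescriptors],
                 points: Sequence[DonorAcceptorPoint],
                 solvent_phases: Sequence[str]) -> List[PhaseShift]:
    by_key_d = {(d.compound_id, d.phase): d for d in descriptors}
    by_key_p = {(p.compound_id, p.phase): p for p in points}
    shifts = []
    for (cid, phase), d in sorted(by_key_d.items()):
        if phase == "gas":
            continue
        gas_d = by_key_d.get((cid, "gas"))
        gas_p = by_key_p.get((cid, "gas"))
        solv_p = by_key_p.get((cid, phase))
        if gas_d is None or gas_p is None or solv_p is None:
            log.info("phases %s/%s: skipped (missing counterpart)", cid, phase)
            continue
        shifts.append(compare_phases((gas_d, gas_p), (d, solv_p)))
        log.info("phases %s/%s: ok", cid, phase)
    return shifts


def _fmo_stage(records: Sequence[CompoundRecord],
               descriptors: Sequence[GlobalDescriptors]) -> pd.DataFrame:
    orbitals = [FrontierOrbitals(rec.compound_id, "gas", rec.homo, rec.lumo)
                for rec in records if rec.homo is not None]
    if not orbitals:
        return pd.DataFrame(columns=["compound_id", "phase", "homo_eV",
                                     "lumo_eV", "gap_eV", "donor_rank"])
    ranked = rank_by_homo(orbitals)
    gas_desc = [d for d in descriptors if d.phase == "gas"]
    report = koopmans_consistency(ranked, gas_desc)
    rows = []
    for rank, orb in enumerate(ranked, start=1):
        rows.append({
            "compound_id": orb.compound_id, "phase": orb.phase,
            "homo_eV": orb.homo, "lumo_eV": orb.lumo, "gap_eV": orb.gap,
            "donor_rank": rank,
        })
    df = pd.DataFrame(rows)
    df.attrs["koopmans_concordance"] = report.concordance
    return df


def _assay_stage(curves: Sequence[DoseResponseCurve], cfg: PipelineConfig,
                 errors: List[str]) -> pd.DataFrame:
    rows = []
    for curve in curves:
        try:
            fit = fit_ic50(curve, model=cfg.assay_fit_model)
            rows.append({
                "compound_id": curve.compound_id, "ic50_ppm": fit.ic50,
                "model": fit.model, "extrapolated": fit.extrapolated,
            })
            log.info("assay %s: IC50 %.4g ppm", curve.compound_id, fit.ic50)
        except AntiradicalError as exc:
            errors.append(f"assay {curve.compound_id}: {exc}")
            log.error("assay %s: %s", curve.compound_id, exc)
    return pd.DataFrame(rows, columns=["compound_id", "ic50_ppm", "model",
                                       "extrapolated"])


def _correlation_stage(descriptors: Sequence[GlobalDescriptors],
                       points: Sequence[DonorAcceptorPoint],
                       records: Sequence[CompoundRecord],
                       assay_df: pd.DataFrame,
                       errors: List[str]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    ic50 = {}
    if len(assay_df):
        ic50.update(dict(zip(assay_df["compound_id"], assay_df["ic50_ppm"])))
    for rec in records:  # explicit IC50 column loses to a fitted curve
        if rec.compound_id not in ic50 and rec.ic50 is not None:
            ic50[rec.compound_id] = rec.ic50

    values: Dict[str, Dict[str, float]] = {}
    for d in descriptors:
        if d.phase != "gas":
            continue
        values.setdefault(d.compound_id, {}).update(
            I=d.I, A=d.A, eta=d.eta, S=d.S, chi=d.chi, mu=d.mu, omega=d.omega)
    for p in points:
        if p.phase != "gas":
            continue
        values.setdefault(p.compound_id, {}).update(
            omega_minus=p.omega_minus, omega_plus=p.omega_plus,
            Rd=p.Rd, Ra=p.Ra)
    for rec in records:
        if rec.homo is not None:
            values.setdefault(rec.compound_id, {})["homo"] = rec.homo

    corr_rows, resid_rows = [], []
    for name in CORRELATION_DESCRIPTORS:
        ids = sorted(cid for cid in values
                     if name in values[cid] and cid in ic50)
        if len(ids) < 3:
            continue
        x = [values[cid][name] for cid in ids]
        y = [ic50[cid] for cid in ids]
        try:
            res = pearson_correlation(x, y, descriptor_used=name)
        except (AntiradicalError, ValueError) as exc:
            errors.append(f"correlate {name}: {exc}")
            continue
        corr_rows.append({"descriptor": name, "r": res.r, "slope": res.slope,
                          "intercept": res.intercept, "n": res.n})
        for cid, resid in zip(ids, res.residuals):
            resid_rows.append({"descriptor": name, "compound_id": cid,
                               "residual_ppm": resid})
        log.info("correlate %s: r=%.4f (n=%d)", name, res.r, res.n)
    return (pd.DataFrame(corr_rows, columns=["descriptor", "r", "slope",
                                             "intercept", "n"]),
            pd.DataFrame(resid_rows, columns=["descriptor", "compound_id",
                                              "residual_ppm"]))


def run_pipeline(config, records: Optional[Sequence[CompoundRecord]] = None,
                 curves: Optional[Sequence[DoseResponseCurve]] = None) -> ReportBundle:
    """Execute every stage and assemble a ReportBundle.

    *config* is a :class:`PipelineConfig` or a path to a config file.
    Records/curves can be injected directly (tests) or read from the paths
    in the config.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)

    if records is None:
        records = (read_compound_table(config.compounds_path,
                                       config.compounds_dialect)
                   if config.compounds_path else [])
    if curves is None:
        curves = (read_assay_table(config.assay_path)
                  if config.assay_path else [])
    if not records:
        log.warning("run_pipeline: empty compound list")

    errors: List[str] = []
    warnings: List[str] = [] if records else ["empty compound list"]

    descriptors = _descriptor_stage(records, config, errors)
    points = _dam_stage(records, config, errors)
    dam_df = build_dam_table(points, config.dam_config())
    shifts = _phase_stage(descriptors, points,
                          [p for p in (config.phases or ()) if p != "gas"])
    fmo_df = _fmo_stage(records, descriptors)
    assay_df = _assay_stage(curves, config, errors)
    corr_df, resid_df = _correlation_stage(descriptors, points, records,
                                           assay_df, errors)

    desc_df = pd.DataFrame(
        [d.as_dict() for d in sorted(descriptors,
                                     key=lambda d: (d.compound_id, d.phase))],
        columns=["compound_id", "phase", "I_eV", "A_eV", "eta_eV", "S",
                 "chi_eV", "mu_eV", "omega_eV", "convention"])
    shift_df = pd.DataFrame(
        [{"compound_id": s.compound_id, "delta_I_eV": s.delta_I,
          "delta_A_eV": s.delta_A, "delta_Rd": s.delta_Rd,
          "delta_Ra": s.delta_Ra, "summary": s.summary} for s in shifts],
        columns=["compound_id", "delta_I_eV", "delta_A_eV", "delta_Rd",
                 "delta_Ra", "summary"])

    metadata = {
        "convention": config.convention,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    return ReportBundle(
        descriptors=desc_df, dam=dam_df, phase_shifts=shift_df, fmo=fmo_df,
        assay=assay_df, correlations=corr_df, residuals=resid_df,
        metadata=metadata, errors=errors, warnings=warnings,
    )
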