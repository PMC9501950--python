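# antiradical

Antiradical (antioxidant) profiling from vertical ionization energies:
conceptual-DFT global reactivity descriptors, electro-donating/accepting
powers, donor–acceptor maps (DAM), frontier-orbital ranking, and DPPH
dose–response statistics — plus a synthetic-data generator so the whole
pipeline is testable without any quantum-chemistry package.

The pipeline *consumes* energies; it never runs DFT. Inputs are either
total electronic energy triplets (neutral/cation/anion, hartree) or
pre-computed vertical I/A values (eV).

## What it computes

- **Vertical I/A** — I = E(cation) − E(neutral), A = E(neutral) − E(anion),
  converted with a single configurable hartree→eV factor (27.211386).
- **Global descriptors** — hardness η = (I−A)/2, softness S, electronegativity
  χ = (I+A)/2, chemical potential μ = −χ, electrophilicity ω. Two conventions:
  `standard` (S = 1/2η in eV⁻¹, ω = μ²/2η in eV) and `paper_replication`
  (S and ω evaluated in atomic units and expressed back in eV, matching
  published tables that applied ω = μ²/2 directly).
- **Charge-transfer powers & DAM** — ω⁻ = (3I+A)²/16(I−A),
  ω⁺ = (I+3A)²/16(I−A); Rd and Ra normalize them against Na
  (I = 5.139 eV, A = 0.548 eV) and F (I = 17.423 eV, A = 3.401 eV) atomic
  anchors; the DAM table carries both an absolute quadrant sector and a
  dataset-relative donor/acceptor label.
- **Phase comparison** — solvent-minus-gas shifts of I, A, Rd, Ra.
- **FMO** — HOMO/LUMO gap, donor ranking by HOMO, and pairwise concordance
  of the HOMO ranking with the I ordering.
- **Assay** — percent inhibition, IC50 by log-linear interpolation (default)
  or a constrained four-parameter logistic fit, and Pearson correlation of
  any descriptor against IC50 with residuals.

## CLI

```bash
antiradical synth --seed 2022 --out-dir panel/          # synthetic panel
antiradical profile --input panel/panel_ia_values.csv   # descriptors + DAM
antiradical phases  --input panel/panel_ia_values.csv   # gas vs solvent
antiradical fmo     --input panel/panel_ia_values.csv
antiradical assay   --input panel/panel_assay.csv --model four_parameter_logistic
antiradical correlate --input panel/panel_ia_values.csv --assay-input panel/panel_assay.csv
antiradical all --config config.yaml --out-dir report/
```

Shared flags: `--convention {paper,standard}`, `--phase`, `--seed`,
`--out-dir`, `--format {csv,json}`. A config file is a flat YAML mapping;
documented keys include `hartree_to_ev`, the four reference-atom I/A
values, `rd_boundary`/`ra_boundary`, `assay_fit_model`,
`correlation_descriptor`, `convention`, `compounds_path`,
`compounds_dialect`, `assay_path`, `phases`, `seed`.

### Input dialects

- `energies`: `compound_id, charge_state, phase, energy_hartree`
  (+ optional `display_name, method_tag, homo_eV, lumo_eV, ic50_ppm`)
- `ia_values`: `compound_id, phase, I_eV, A_eV` (+ same optionals)
- assay: `compound_id, concentration_ppm, inhibition_pct` or
  `compound_id, concentration_ppm, absorbance_sample, absorbance_control`

CSV/TSV is autodetected from the extension. A bundled synthetic panel with
published-style targets lives in `src/antiradical/data/` and is
regenerated deterministically by `antiradical synth`.

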