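# Example: 5-marker human whole-blood panel on a conventional cytometer.
# No FMO controls: thresholds come from density valleys in the (arcsinh-
# transformed) pooled samples. Lineage rules are illustrative, not a
# clinical reference.
paths:
  samples: samples        # directory of .fcs (or .csv) sample files
  fmos: null              # no FMOs for this panel
  metadata: metadata.csv  # sample_id, group, timepoint
  outcome: null
  output: out

channels:
  - {detector: FSC-A,        marker: FSC-A,    role: scatter_area}
  - {detector: FSC-H,        marker: FSC-H,    role: scatter_height}
  - {detector: SSC-A,        marker: SSC-A,    role: side_scatter}
  - {detector: APC-Cy7-A,    marker: Zombie,   role: viability}
  - {detector: BV510-A,      marker: CD45,     role: marker}
  - {detector: FITC-A,       marker: CD3,      role: marker}
  - {detector: PE-A,         marker: CD19,     role: marker}
  - {detector: BV421-A,      marker: HLA-DR,   role: marker}
  - {detector: APC-A,        marker: CD27,     role: marker}

transform:
  kind: arcsinh
  cofactor: 150

gates:
  singlet: {enabled: true, band_factor: 2.5}
  debris:  {enabled: true}
  live:    {enabled: true}

thresholds:
  quantile: 0.99   # used only for markers that do get an FMO or override
  overrides: {}    # e.g. {CD27: 1.5} to pin a cutoff manually

filter:
  min_percent: 0.5
  constraints: {CD45: 1}   # leukocytes only

lineage:
  default_label: unknown
  rules:
    - {field: lineage, label: T cell, constraints: {CD45: 1, CD3: 1, CD19: 0}}
    - {field: lineage, label: B cell, constraints: {CD45: 1, CD3: 0, CD19: 1}}
    - {field: subset,  label: memory T,  constraints: {CD3: 1, CD27: 1}}

stats:
  correlation_method: pearson
  ttest_variant: welch
  enable_fdr: false
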