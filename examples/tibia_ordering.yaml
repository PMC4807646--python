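# Block-ordering config: boxes listed response-to-background.
# Box 0: tibia pQCT phenotype; box 1: body habitus; box 2: circulating
# biomarkers; final context box: age. Pass to run_pipeline or
# BlockOrdering.from_yaml.
boxes:
- kind: response
  variables:
  - name: csa_dis
    log: true
    units: mm^2
  - name: vbmd_dis
    log: true
    units: mg/cm^3
  - name: csa_dia
    log: true
    units: mm^2
  - name: cort_area
    log: true
    units: mm^2
  - name: cort_vbmd
    log: true
    units: mg/cm^3
- kind: response
  variables:
  - name: lean_mass
    log: true
    units: kg
  - name: fm_pct
    log: true
    units: '%'
  - name: height
    log: true
    units: m
- kind: response
  variables:
  - name: leptin
    log: true
    units: ug/L
  - name: adiponectin
    log: true
    units: ug/L
  - name: osteocalcin
    log: true
    units: ug/L
  - name: ucoc
    log: true
    units: ug/L
  - name: phylloquinone
    log: true
    units: ug/L
- kind: context
  variables:
  - name: age
    log: true
    units: y
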