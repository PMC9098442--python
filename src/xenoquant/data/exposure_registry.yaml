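# High-exposure scenario inputs for the breast-milk infant risk assessment:
# per-analyte assumed concentration (ng/mL; the maximum quantified breast-milk
# level, or the LOQ where the analyte was only seen below it), adult
# health-based guidance values (ug/kg bw/day) with their kind, and chemical
# class. Guidance values are data, not code: they track EFSA opinions and can
# be edited without touching the package.
#
# alt_guidance holds a more conservative guidance value discussed alongside
# the primary one (Dutch RIVM TDI for pyrrolizidine alkaloids).
analytes:
  - name: Bisphenol A (BPA)
    chemical_class: plasticizer
    assumed_conc: 0.40
    assumed_from: loq
    guidance: {kind: TDI, value: 4.0, source: EFSA}
  - name: Bisphenol F (BPF)
    chemical_class: plasticizer
    assumed_conc: 0.028
    assumed_from: loq
  - name: Bisphenol S (BPS)
    chemical_class: plasticizer
    assumed_conc: 0.051
    assumed_from: max_quantified
  - name: Mono-n-butyl phthalate (MBP)
    chemical_class: plasticizer
    assumed_conc: 6.4
    assumed_from: max_quantified
  - name: Perfluorooctanoic acid (PFOA)
    chemical_class: PFAS
    assumed_conc: 0.092
    assumed_from: loq
    guidance: {kind: TDI, value: 0.63, source: EFSA}
  - name: Perfluorooctanesulfonic acid (PFOS)
    chemical_class: PFAS
    assumed_conc: 0.048
    assumed_from: max_quantified
    guidance: {kind: TDI, value: 0.63, source: EFSA}
  - name: Prochloraz
    chemical_class: industrial
    assumed_conc: 0.082
    assumed_from: max_quantified
    guidance: {kind: ADI, value: 100, source: EFSA}
  - name: 8-prenylnaringenin
    chemical_class: phytoestrogen
    assumed_conc: 0.23
    assumed_from: max_quantified
  - name: Daidzein
    chemical_class: phytoestrogen
    assumed_conc: 0.14
    assumed_from: max_quantified
  - name: Enterodiol
    chemical_class: phytoestrogen
    assumed_conc: 0.025
    assumed_from: max_quantified
  - name: Enterolactone
    chemical_class: phytoestrogen
    assumed_conc: 0.17
    assumed_from: loq
  - name: Glycitein
    chemical_class: phytoestrogen
    assumed_conc: 0.011
    assumed_from: max_quantified
  - name: Isoxanthohumol
    chemical_class: phytoestrogen
    assumed_conc: 0.078
    assumed_from: max_quantified
  - name: Resveratrol
    chemical_class: phytoestrogen
    assumed_conc: 0.30
    assumed_from: loq
  - name: Xanthohumol
    chemical_class: phytoestrogen
    assumed_conc: 0.22
    assumed_from: loq
  - name: Alternariol
    chemical_class: mycoestrogen
    assumed_conc: 0.51
    assumed_from: max_quantified
  - name: Benzophenone 1
    chemical_class: personal-care
    assumed_conc: 0.039
    assumed_from: max_quantified
    guidance: {kind: ADI, value: 30, source: SCCS}
  - name: Benzophenone 2
    chemical_class: personal-care
    assumed_conc: 0.020
    assumed_from: max_quantified
  - name: Butylparaben (BP)
    chemical_class: personal-care
    assumed_conc: 0.036
    assumed_from: max_quantified
    guidance: {kind: ADI, value: 2000, source: EFSA}
  - name: Ethylparaben (EP)
    chemical_class: personal-care
    assumed_conc: 0.13
    assumed_from: max_quantified
    guidance: {kind: ADI, value: 10000, source: EFSA}
  - name: Methylparaben (MP)
    chemical_class: personal-care
    assumed_conc: 23
    assumed_from: max_quantified
    guidance: {kind: ADI, value: 10000, source: EFSA}
  - name: Propylparaben (PP)
    chemical_class: personal-care
    assumed_conc: 16
    assumed_from: max_quantified
    guidance: {kind: ADI, value: 2000, source: EFSA}
  - name: Anisodamine
    chemical_class: phytotoxin
    assumed_conc: 0.031
    assumed_from: max_quantified
  - name: Jacobine-N-oxide
    chemical_class: phytotoxin
    assumed_conc: 0.11
    assumed_from: max_quantified
    guidance: {kind: BMDL10, value: 70, source: EFSA}
    alt_guidance: {kind: TDI, value: 0.1, source: RIVM}
  - name: Riddelliin-N-oxide
    chemical_class: phytotoxin
    assumed_conc: 0.021
    assumed_from: loq
    guidance: {kind: BMDL10, value: 70, source: EFSA}
  - name: Scopolamine
    chemical_class: phytotoxin
    assumed_conc: 0.0004
    assumed_from: max_quantified
    guidance: {kind: TDI, value: 0.016, source: EFSA}
  - name: PhIP
    chemical_class: food-processing
    assumed_conc: 0.042
    assumed_from: loq
    guidance: {kind: BMDL10, value: 480, source: literature}
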