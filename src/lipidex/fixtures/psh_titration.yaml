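# Presenilin-homologue protease (PSH, 33 kDa) with the three main E. coli
# polar lipids added at 50 uM, titrated with nonylglucoside (NG) from the
# solubilization baseline 0.2 % w/v up to 0.5 %. All binding is annular:
# one exchangeable site per lipid class, displaced steeply above the NG CMC.
name: psh_titration
kind: titration
protein:
  name: PSH
  average_mass: 33000.0
  charge_states: [10, 13]
detergent:
  name: NG
  average_mass: 306.4
  cmc: 0.2
lipid_conc: 50.0        # uM, effective free-lipid scale shared with K_L
lipids:
  - species: {name: POPE, lipid_class: PE, formula: C39H76NO8P}
    sites:
      - {K_L: 25.0, K_D: 0.001}
  - species: {name: POPG, lipid_class: PG, formula: C40H77O10P}
    sites:
      - {K_L: 25.0, K_D: 0.001}
  - species: {name: CDL, lipid_class: CDL, formula: C77H142O17P2}
    sites:
      - {K_L: 25.0, K_D: 0.001}
charge_envelope: {10: 0.2, 11: 0.45, 12: 0.25, 13: 0.1}
peak_fwhm: 1.2          # m/z; resolves POPE from POPG (31 Da) at z = 10-13
noise_sd: 0.01
mz_grid: [2400.0, 3700.0, 0.2]
seed: 11
titration:
  detergent_concs: [0.2, 0.275, 0.35, 0.425, 0.5]
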