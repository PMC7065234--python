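# Lipid flippase MurJ (57 kDa) with a 2-fold excess of its substrate
# lipid-II, titrated with octylglucoside (OG) on top of an LDAO baseline.
# Site 1 is the buried active site: detergent-protected, so one lipid-II
# survives the harshest competition step; the two additional lipid-II
# positions are annular and are stripped. The CMC given for OG is the
# effective value in mixed OG/LDAO micelles. Raising OG also mitigates
# LDAO charge stripping, shifting the envelope to higher charge states
# (charge_envelope_high at the top of the titration).
name: murj_lipid2
kind: titration
protein:
  name: MurJ
  average_mass: 57000.0
  charge_states: [13, 17]
detergent:
  name: OG
  average_mass: 292.4
  cmc: 0.05
lipid_conc: 10.0        # uM lipid-II, 2-fold excess over protein
lipids:
  - species: {name: lipid-II, lipid_class: lipid-II, formula: C94H156N8O26P2}
    sites:
      - {K_L: 1.0, protected: true}   # active site
      - {K_L: 8.0, K_D: 0.02}
      - {K_L: 30.0, K_D: 0.02}
charge_envelope: {13: 0.2, 14: 0.4, 15: 0.3, 16: 0.1, 17: 0.0}
charge_envelope_high: {13: 0.0, 14: 0.1, 15: 0.3, 16: 0.4, 17: 0.2}
peak_fwhm: 5.0
noise_sd: 0.005
mz_grid: [3250.0, 4900.0, 0.25]
seed: 23
titration:
  detergent_concs: [0.0, 0.125, 0.25, 0.375, 0.5]
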