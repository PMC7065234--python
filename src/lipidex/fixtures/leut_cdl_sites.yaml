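# Three cardiolipin-binding sites on the leucine transporter LeuT dimer,
# each named by its flanking-residue pair. The interfacial R88/K376 site is
# slow (k_off < 10 us^-1, high occupancy); R453/R446 is intermediate;
# the peripheral R11/I441 site is fast (> 70 us^-1). Rates are synthetic
# ground truth for the dwell-time generators; traces carry brief rattling
# detachments that the dual-cutoff/gap-merge extraction must absorb.
name: leut_cdl_sites
kind: kinetics
sites:
  - {site_id: R88/K376, label: dimer interface, k_on: 100.0, k_off_true: 8.0, n_events: 3000}
  - {site_id: R453/R446, label: two-arginine site, k_on: 30.0, k_off_true: 32.5, n_events: 5000}
  - {site_id: R11/I441, label: peripheral site, k_on: 25.0, k_off_true: 75.0, n_events: 5000}
trace:
  dt: 0.5               # ns per frame
  duration: 50000.0     # ns per simulated trace
  rattle_rate: 5.0      # us^-1 of bound time
  rattle_mean: 2.0      # ns
gap_tolerance: 5.0      # ns
d_on: 0.55              # nm
d_off: 1.0              # nm
n_boot: 500
seed: 7
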