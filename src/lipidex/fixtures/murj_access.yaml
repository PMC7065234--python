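# Accessibility of four MurJ residues to the acyl chains of the lipid-II
# stem (undecaprenyl-pyrophosphate) across the transporter's conformational
# states. F256 faces the membrane and is reachable in every state; the
# active-site residues R18/R24/R255 are sporadically accessed in the inward
# states, fully exposed in the outward state, and unreachable (k_on = 0)
# in the inward-closed state. Rates are synthetic truths in us^-1;
# frequency converges to k_on/(k_on + k_off).
name: murj_access
kind: accessibility
states:
  inward-open:
    F256: {k_on: 60.0, k_off: 40.0}
    R18: {k_on: 2.0, k_off: 60.0}
    R24: {k_on: 1.5, k_off: 60.0}
    R255: {k_on: 1.5, k_off: 60.0}
  inward-occluded:
    F256: {k_on: 60.0, k_off: 40.0}
    R18: {k_on: 2.5, k_off: 60.0}
    R24: {k_on: 2.0, k_off: 60.0}
    R255: {k_on: 2.0, k_off: 60.0}
  inward-closed:
    F256: {k_on: 60.0, k_off: 40.0}
    R18: {k_on: 0.0, k_off: 60.0}
    R24: {k_on: 0.0, k_off: 60.0}
    R255: {k_on: 0.0, k_off: 60.0}
  outward:
    F256: {k_on: 60.0, k_off: 40.0}
    R18: {k_on: 25.0, k_off: 60.0}
    R24: {k_on: 20.0, k_off: 60.0}
    R255: {k_on: 20.0, k_off: 60.0}
trace:
  dt: 1.0               # ns per frame
  duration: 20000.0     # ns per trace
d_contact: 0.55         # nm
seed: 31
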