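# lipidex

Membrane proteins carry two kinds of bound lipid: **annular** lipids that
coat the transmembrane surface non-specifically and exchange rapidly with
the bulk (or with detergent, once the protein is solubilized), and
**non-annular / specific** lipids held at defined sites — an oligomer
interface, a buried active site — that resist exchange and often matter
functionally. `lipidex` implements the two complementary computational
readouts used to tell them apart:

1. **Detergent-competition native MS.** An intact protein of mass *M*
   appears at m/z = (*M* + *z*·1.00728)/*z* for each charge *z*; every bound
   lipid adds its mass/*z*. The package picks peaks, assigns
   (charge, adduct-count) compositions against a candidate lipid list,
   quantifies adduct-count fractions by peak area, and fits the titration
   with a competitive occupancy isotherm

       θ = (L/K_L) / (1 + L/K_L + D_eff/K_D),    D_eff = max(0, D − CMC),

   where *L* is the lipid concentration, *D* the detergent concentration,
   and only detergent above its critical micelle concentration competes.
   Each binding position gets a retention index R = θ(max D)/θ(min D):
   R ≤ 0.5 means annular (displaced), R > 0.5 means non-annular (retained).

2. **Residency-time kinetics from contact traces.** Per-site lipid contact
   distances (e.g. from coarse-grained simulation) are binarized with a
   dual-cutoff (hysteresis) rule — bound below d_on, released only above
   d_off — so brief "rattling" detachments do not shred one long dwell into
   many. Dwells are extracted with gap merging and trace-end censoring, and
   the dissociation rate is the censored exponential MLE

       k_off = n_uncensored / Σ durations     (reported in μs⁻¹),

   with a percentile-bootstrap confidence interval and a Kaplan–Meier
   survival curve as cross-check. Sites are ranked by k_off and compared by
   fold ratio; per-conformational-state contact frequencies quantify how
   accessible active-site residues are to a substrate lipid.

Seeded generators (`lipidex.synthetic`) produce spectra, titrations and
two-state binding trajectories with known ground truth, so the entire chain
is testable offline. Packaged fixtures model the three study systems: a
33 kDa presenilin-homologue protease whose lipids are all annular
(`psh_titration`), a leucine-transporter dimer with a slow interfacial
cardiolipin site (`leut_cdl_sites`), and a 57 kDa lipid-II flippase that
keeps exactly one substrate lipid in its protected active site
(`murj_lipid2`, `murj_access`).

## Worked example

Estimate k_off for a site with a true dissociation rate of 32.5 μs⁻¹ from
5000 simulated binding events:

```python
from lipidex import simulate_dwell_times, estimate_koff

dwells = simulate_dwell_times(32.5, 5000, seed=7)
est = estimate_koff(dwells, n_boot=1000, seed=7)
print(f"k_off = {est.k_off:.2f} us^-1 (95% CI {est.ci_low:.2f}-{est.ci_high:.2f})")
```

prints

```
k_off = 32.69 us^-1 (95% CI 31.83-33.60)
```

i.e. the estimator recovers the true rate (mean residency 1000/32.69 ≈
30.6 ns) with a tight CI at this event count. Running the full
spectrum → assignment → competition pipeline on the flippase fixture:

```python
from lipidex.pipeline import RunConfig, run

report = run(RunConfig.from_dict({"analysis": "titration", "fixture": "murj_lipid2"}))
print(report.tables["competition_fits"][["label", "retention_index", "classification"]])
```

```
         label  retention_index classification
lipid-II[pos1]            0.982    non-annular
lipid-II[pos2]            0.052        annular
lipid-II[pos3]            0.000        annular
```

The first (highest-affinity) lipid-II position keeps 98 % of its occupancy
at the top of the detergent titration — the protected active-site substrate
— while the additional lipid-II molecules are stripped, reproducing the
1:1 protein–lipid complex the competition assay is designed to reveal.

The same analyses are available from the shell:

```sh
lipidex simulate --fixture leut_cdl_sites --out demo/
lipidex koff --traces demo/leut_cdl_sites_traces.csv --dt 0.5 --gap 5 --boot 1000 --seed 7
lipidex run --config myrun.yaml
```

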