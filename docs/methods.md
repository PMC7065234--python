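# Methods

## Scope and units

`lipidex` quantifies lipid–detergent exchange at membrane-protein binding
sites from two kinds of evidence: native-MS adduct spectra across a
detergent titration, and per-site binding/contact time series. Time is kept
in nanoseconds internally; rates are reported in μs⁻¹ (k[μs⁻¹] =
1000/τ[ns]), matching the scale on which lipid residencies at
coarse-grained resolution are usually discussed. All molecular masses are
*average* masses: intact-protein native MS at 33–57 kDa resolves average,
not monoisotopic, masses. Charging uses the average proton mass
(1.00728 Da) and assumes positive-ion mode. Formula masses are computed
with pyteomics' average atomic-mass tables. Detergent concentrations are
% w/v; the conversion to molar is 10 × (% w/v) / M_avg (g/mol).

## Spectrum model and measurement

A simulated profile spectrum is a sum of Gaussian peaks, one per
(charge state, adduct composition), centred at
(M_protein + Σ adduct masses + z·1.00728)/z with amplitude
(envelope weight of z) × (composition probability). Peak width is a
configurable FWHM (default 8 m/z — broad enough that neighbouring adduct
peaks overlap but remain countable; the protease fixture uses 1.2 m/z so
that PE and PG adducts, 31 Da apart, are resolved at z = 10–13). Noise is
additive Gaussian, scaled to the tallest noiseless point, on top of a small
constant baseline offset (5 noise SDs) that keeps intensities non-negative
without clipping the noise distribution. No isotope structure, micelle
background or collision-energy effects are modelled.

Measurement reverses this: peak picking thresholds local maxima at
baseline + SNR × noise floor, where the baseline is the median intensity
and the noise floor the normal-consistent MAD (1.4826 × median absolute
deviation). A matching prominence requirement stops noise riding on a broad
peak from splitting it. Integration bounds descend from each apex
tolerating upticks up to 3 × noise, so boundaries land at genuine saddles
rather than at the first noise wiggle; areas (not apex heights) are used
for quantification because overlapping adduct shoulders distort apexes
more than integrals. Apex positions are intensity-weighted centroids of the
upper 70 % of the peak, which suppresses grid-quantization error (a raw
apex on a 0.25 m/z grid can be off by 0.125 m/z ≈ 1.7 Da at z = 14,
most of the 2.5 Da assignment tolerance).

Assignment searches every composition with at most `max_adducts` (default
3) total lipids over the candidate list, at every charge in the protein's
range, and accepts matches within a tolerance of 2.5 Da at the
deconvolved-mass scale — wide enough for centroid jitter, narrow enough to
separate PE (718.0 Da) from PG (749.0 Da) trivially while deliberately
exposing the near-collision between one cardiolipin and two PEs. When more
than one composition falls inside the window the assignment is flagged
ambiguous and resolved deterministically (fewer total adducts, then earlier
candidates, then smaller error) — never silently. A bound-lipid population
is considered detectable when its intensity fraction is ≥ 0.03; this
operationalizes "all bound lipids removed".

## Competition model

The titration readout is modelled as single-site competitive Langmuir
binding: θ = (L/K_L)/(1 + L/K_L + D_eff/K_D), with D_eff = max(0, D − CMC)
because only detergent above its critical micelle concentration provides
the micellar sink that dilutes lipids away from the protein. This is the
minimal equilibrium model consistent with the competition cartoon the assay
rests on; no equation is inherited from elsewhere, and kinetic (slow
approach to equilibrium) competition is deliberately out of scope. A
protected site is simply unreachable by detergent: θ = (L/K_L)/(1 + L/K_L)
at any D.

K_L and K_D are fitted by least squares (lmfit) with L fixed and known;
a series that shows no detergent response at all is reported as a protected
site rather than letting K_D diverge. Classification does not depend on the
fit: the retention index R = θ(max D)/θ(min D) is computed from observed
endpoints, and R ≤ 0.5 ⇒ annular, R > 0.5 ⇒ non-annular. The midpoint
threshold is the least presumptive split for a qualitative
removed-vs-retained contrast and is configurable. Lipid classes (and
binding positions within a class) are fitted independently; no joint model
is attempted. In the pipeline, the bound fraction of "position j" of a
lipid class with m sites is P(adduct count ≥ j), which maps the protected
site of the flippase fixture onto position 1.

## Dwell-time kinetics

Contact traces are binarized with a dual cutoff: a contact starts when the
distance drops below d_on (default 0.55 nm, a typical coarse-grained
lipid-contact distance) and ends only when it exceeds d_off (default
1.0 nm). The hysteresis band absorbs "rattling" — brief excursions of a
genuinely bound lipid that a single cutoff would count as dissociation
events. Defaults are config-overridable. Dwells are maximal bound runs;
unbound gaps ≤ a gap tolerance (default 5 ns) are merged into the
surrounding dwell, and dwells touching either trace end are censored.

For a single-rate (memoryless) process the censored exponential MLE is
k_off = n_uncensored / Σ(all durations, censored included). Dropping
censored dwells instead would bias k_off upward (long dwells are the ones
cut short); the test suite demonstrates that bias on a truncated-horizon
fixture and verifies the MLE does not share it. Uncertainty is a
percentile bootstrap over dwell resampling (default 1000 replicates,
seeded). The Kaplan–Meier survival curve (lifelines) provides an
independent cross-check: for exponential dwells the slope of log S(t)
reproduces the MLE within 15 %. A single-exponential model is the default
and only fitted form, since per-site rates are summarized as single k_off
values; multi-exponential resolution is out of scope.

Site comparison sorts estimates ascending and reports pairwise fold ratios
k_off(fast)/k_off(slow), flagging pairs whose bootstrap CIs overlap.
Accessibility profiling is deliberately simpler: per (conformational state,
residue) the fraction of frames with distance < d_contact (default
0.55 nm) — frequencies, not kinetics — with absent cells recorded as
missing, not zero.

## Synthetic generators and fixtures

Dwell generators draw i.i.d. exponential durations at the configured true
rate. Trace generators run a continuous-time two-state (telegraph) process
with exponential unbound/bound periods at rates k_on/k_off, inject rattles
inside bound periods as a Poisson process of short exponential gaps, and
sample the state at frame midpoints; with no rattling, occupancy converges
to k_on/(k_on + k_off). In distance mode, bound/rattle/unbound segments
emit noisy distances near 0.45 / 0.78 / 1.6 nm — the rattle level sits
inside the hysteresis band, so the dual-cutoff scheme (but not a single
cutoff) rides through it.

The packaged fixtures encode the three study conditions. The protease
fixture (33 kDa, z = 10–13, 50 μM lipids, nonylglucoside titrated
0.2 → 0.5 % w/v above its 0.2 % CMC) gives every lipid class one
exchangeable site whose occupancy collapses below the detection threshold
at the top of the titration. The transporter fixture names three
cardiolipin sites by flanking-residue pairs with true rates 8 / 32.5 /
75 μs⁻¹ and k_on chosen so the interfacial site is occupied > 90 % of the
time; per-site event counts (3000 / 5000 / 5000) keep estimator noise well
below the 3-fold contrasts of interest. The flippase fixture (57 kDa,
z = 13–17, 10 μM lipid-II) has one protected active site plus two
exchangeable positions, octylglucoside titrated 0 → 0.5 % w/v with an
effective CMC of 0.05 % (mixed micelles with the LDAO background), and a
charge envelope that shifts upward across the titration to mimic the
mitigation of charge stripping by added detergent. The accessibility
fixture gives the membrane-facing residue a high contact rate in every
state, the active-site residues sporadic access in the inward states,
k_on = 0 in the inward-closed state, and full exposure in the outward
state. Occupancy parameters are *effective* values: free vs
micelle-partitioned lipid fractions are not modelled.

What the generators do not emulate — and hence what passing tests cannot
show about real data: instrument-specific peak shapes and baselines,
adduct stripping in the gas phase, heterogeneous lipid acyl chains,
multi-exponential or diffusion-limited binding kinetics, and correlations
between sites. The fixtures establish that the estimators recover known
truths under the stated statistical model, not that the model is complete
for any particular instrument or force field.

## Numerical choices and degenerate inputs

Gaussian peaks are evaluated within ±6σ windows. Flat spectra yield an
empty peak list, not an error. k_off estimation refuses fewer than 10
uncensored dwells, and survival curves require at least one uncensored
dwell. Degenerate generator inputs (k_on = 0, empty concentration lists,
grids not covering a theoretical peak) raise informative errors, the last
naming the missing peak. A frame interval ≥ half the mean dwell triggers a
discretization warning. Bootstrap replicates that happen to contain no
uncensored dwell are dropped from the percentile computation.

## Known limitations

* At high-occupancy sites (mean unbound gap comparable to the gap
  tolerance) gap merging joins genuinely distinct visits, biasing
  trace-derived k_off low — e.g. the interfacial transporter site (true
  8 μs⁻¹, mean unbound gap 10 ns) estimates near 5 μs⁻¹ through the full
  trace pipeline, while direct dwell-set estimation is unbiased. The
  ordering and > 3-fold contrasts between sites are unaffected; fold
  ratios from the trace pipeline should nevertheless be read as
  conservative for slow, nearly-saturated sites.
* Retention-index classification uses observed endpoints and is only as
  good as the bound-fraction estimates at the extremes of the titration;
  positions whose baseline occupancy is already near the detection
  threshold classify noisily.
* The competitive isotherm assumes equilibrium endpoints; if lipid removal
  is kinetically limited on the experimental timescale, K_D estimates
  absorb that and lose their thermodynamic meaning (the classification
  remains a valid empirical contrast).
* The mzML support is a minimal single-spectrum reader/writer
  (uncompressed or zlib, 32/64-bit float arrays), sufficient for data
  exchange of profile spectra, not a general-purpose mzML implementation.

## Problem sizes

The test suite and the reproduction script run entirely on synthetic data
at desk scale: dwell sets of 500–10 000 events, traces of 10⁵–8×10⁵
frames, spectra of ~5 000–6 600 grid points, 100-replicate refit studies
and 200-replicate coverage studies. The full suite completes in a few
seconds on one CPU; the reproduction script in well under a minute.
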