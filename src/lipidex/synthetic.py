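"""Seeded generators for spectra, titrations and binding trajectories.

Everything downstream is testable against these generators' ground truth:

* dwell times are i.i.d. exponential at a configured true rate;
* contact traces are a continuous-time two-state (telegraph) process with
  exponential bound/unbound periods, optionally decorated with "rattling" —
  a Poisson process of brief detachments inside genuine bound periods that
  the dual-cutoff/gap-merge machinery must absorb;
* spectra are sums of Gaussian charge-state/adduct peaks whose amplitudes
  follow the same competitive occupancy model the fitting module assumes,
  with independent binding sites per lipid class (so the adduct-count
  distribution is Poisson-binomial over the per-site occupancies).

Units: time in ns, rates in us^-1 (k[us^-1] = 1000/tau[ns]); masses are
average masses in Da; detergent concentrations in % w/v.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .competition import OccupancyModelParams, TitrationSeries, occupancy
from .kinetics import BindingSite, ContactTrace, DwellTimeSet, warn_if_coarse
from .species import DetergentSpecies, LipidSpecies, ProteinSpecies, mz_of
from .spectra import MassSpectrum

#: Distance levels (nm) emitted for distance-mode traces.
BOUND_DISTANCE = 0.45
RATTLE_DISTANCE = 0.78  # between the default dual cutoffs: rattles look
# detached to a single cutoff but not to the hysteresis scheme
UNBOUND_DISTANCE = 1.6


def simulate_dwell_times(
    k_off_true: float, n_events: int, seed: int | None = None, site_id: str = ""
) -> DwellTimeSet:
    """Draw n_events i.i.d. exponential dwell durations (ns).

    The theoretical mean dwell is 1000/k_off_true ns. Same seed, same output.
    """
    if k_off_true <= 0:
        raise ValueError("k_off_true must be positive")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    durations = rng.exponential(1000.0 / k_off_true, n_events)
    return DwellTimeSet(durations, np.zeros(n_events, dtype=bool), site_id)


def simulate_contact_trace(
    site: BindingSite,
    duration: float,
    dt: float,
    rattle_rate: float = 0.0,
    rattle_mean: float = 0.0,
    seed: int | None = None,
    emit: str = "state",
) -> ContactTrace:
    """Discretized two-state binding trajectory for one site.

    Alternating unbound/bound periods with exponential durations at rates
    ``site.k_on`` and ``site.k_off_true`` (us^-1). During bound periods,
    spurious detachments ("rattles") of exponential mean length
    ``rattle_mean`` ns are injected as a Poisson process at ``rattle_rate``
    per us of bound time. With ``emit="distance"`` frames carry noisy
    distances (bound near 0.45 nm, rattles near 0.78 nm, unbound near 1.6 nm)
    instead of 0/1 states.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < 100 * dt:
        raise ValueError("duration must cover at least 100 frames")
    if site.k_off_true is None:
        raise ValueError("site needs a k_off_true to simulate")
    warn_if_coarse(dt, site.k_off_true)
    rng = np.random.default_rng(seed)

    n_frames = int(round(duration / dt))
    if site.k_on == 0:
        values = np.zeros(n_frames, dtype=np.int8)
        return _emit(site.site_id, dt, values, emit, rng)

    mean_unbound = 1000.0 / site.k_on
    mean_bound = 1000.0 / site.k_off_true
    # 0 = unbound, 1 = bound, 2 = rattle (inside a bound period)
    bounds: list[float] = [0.0]
    states: list[int] = []
    t, state = 0.0, 0
    while t < duration:
        if state == 0:
            length = rng.exponential(mean_unbound)
            t += length
            bounds.append(t)
            states.append(0)
            state = 1
        else:
            length = rng.exponential(mean_bound)
            segs = _rattled_segments(length, rattle_rate, rattle_mean, rng)
            for seg_len, seg_state in segs:
                t += seg_len
                bounds.append(t)
                states.append(seg_state)
            state = 0
    frame_t = (np.arange(n_frames) + 0.5) * dt
    seg_idx = np.searchsorted(bounds, frame_t, side="right") - 1
    seg_idx = np.clip(seg_idx, 0, len(states) - 1)
    values = np.asarray(states, dtype=np.int8)[seg_idx]
    return _emit(site.site_id, dt, values, emit, rng)


def _rattled_segments(length, rattle_rate, rattle_mean, rng):
    """Split one bound period into bound(1)/rattle(2) segments."""
    if rattle_rate <= 0 or rattle_mean <= 0:
        return [(length, 1)]
    n_rattles = rng.poisson(rattle_rate * length / 1000.0)
    if n_rattles == 0:
        return [(length, 1)]
    starts = np.sort(rng.uniform(0, length, n_rattles))
    gaps = rng.exponential(rattle_mean, n_rattles)
    segs, cursor = [], 0.0
    for s, g in zip(starts, gaps):
        if s <= cursor:
            continue
        segs.append((s - cursor, 1))
        segs.append((g, 2))
        cursor = s + g
    if cursor < length:
        segs.append((length - cursor, 1))
    return segs or [(length, 1)]


def _emit(site_id, dt, values, emit, rng):
    if emit == "state":
        return ContactTrace(site_id, dt, (values == 1).astype(np.int8), kind="state")
    if emit != "distance":
        raise ValueError("emit must be 'state' or 'distance'")
    levels = np.array([UNBOUND_DISTANCE, BOUND_DISTANCE, RATTLE_DISTANCE])
    sds = np.array([0.15, 0.04, 0.05])
    d = levels[values] + rng.normal(0, 1, values.size) * sds[values]
    return ContactTrace(site_id, dt, np.clip(d, 0.05, None), kind="distance")


@dataclass(frozen=True)
class SpectrumFixtureSpec:
    """Everything needed to synthesize one native-MS spectrum.

    ``lipids`` maps each lipid species to its binding sites (one occupancy
    parameter set per site); sites bind independently, so the per-class
    adduct-count distribution is the Poisson-binomial over site occupancies.
    """

    protein: ProteinSpecies
    lipids: tuple[tuple[LipidSpecies, tuple[OccupancyModelParams, ...]], ...]
    detergent: DetergentSpecies
    detergent_conc: float  # % w/v
    lipid_conc: float  # same units as each site's K_L
    charge_envelope: dict[int, float]
    peak_fwhm: float = 8.0  # m/z units
    noise_sd: float = 0.0  # relative to the tallest noiseless point
    mz_grid: tuple[float, float, float] = (1000.0, 5000.0, 0.25)
    seed: int | None = None

    def __post_init__(self) -> None:
        w = sum(self.charge_envelope.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"charge envelope weights sum to {w}, expected 1")
        if self.peak_fwhm <= 0:
            raise ValueError("peak_fwhm must be positive")
        if self.mz_grid[2] <= 0:
            raise ValueError("mz grid step must be positive")
        for z in self.charge_envelope:
            if z not in self.protein.charges:
                raise ValueError(f"envelope charge {z} outside protein charge range")

    def site_occupancies(self, detergent_conc: float | None = None) -> dict[str, list[float]]:
        """True per-site bound fractions at a detergent concentration."""
        D = self.detergent_conc if detergent_conc is None else detergent_conc
        return {
            lip.name: [
                occupancy(p, self.lipid_conc, D, self.detergent.cmc) for p in sites
            ]
            for lip, sites in self.lipids
        }

    def count_distributions(self, detergent_conc: float | None = None) -> dict[str, np.ndarray]:
        """Per-class adduct-count distribution (Poisson-binomial over sites)."""
        out = {}
        for lip, _ in self.lipids:
            thetas = self.site_occupancies(detergent_conc)[lip.name]
            dist = np.array([1.0])
            for th in thetas:
                dist = np.convolve(dist, [1 - th, th])
            out[lip.name] = dist
        return out


def simulate_spectrum(
    spec: SpectrumFixtureSpec,
    detergent_conc: float | None = None,
    charge_envelope: dict[int, float] | None = None,
    seed: int | None = None,
) -> MassSpectrum:
    """Profile spectrum: Gaussian peaks per (charge, adduct composition).

    Peak centres sit at (M_protein + sum of adduct masses + z * 1.00728)/z;
    amplitudes are envelope weight x composition probability under the
    occupancy model; seeded additive Gaussian noise is applied last (clipped
    at zero intensity).
    """
    envelope = charge_envelope or spec.charge_envelope
    lo, hi, step = spec.mz_grid
    mz = np.arange(lo, hi + step / 2, step)
    intensity = np.zeros_like(mz)
    sigma = spec.peak_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    dists = spec.count_distributions(detergent_conc)
    lipid_names = [lip.name for lip, _ in spec.lipids]
    lipid_masses = {lip.name: lip.mass for lip, _ in spec.lipids}
    count_ranges = [range(len(dists[n])) for n in lipid_names]

    total_amp = 0.0
    for z, w in envelope.items():
        if w <= 0:
            continue
        for counts in itertools.product(*count_ranges):
            prob = float(np.prod([dists[n][c] for n, c in zip(lipid_names, counts)]))
            if prob < 1e-12:
                continue
            adduct_mass = sum(lipid_masses[n] * c for n, c in zip(lipid_names, counts))
            centre = mz_of(spec.protein.average_mass + adduct_mass, z)
            if centre < lo or centre > hi:
                comp = {n: c for n, c in zip(lipid_names, counts) if c}
                raise ValueError(
                    f"m/z grid [{lo}, {hi}] does not cover the peak at "
                    f"{centre:.2f} (z={z}, adducts {comp or 'apo'})"
                )
            amp = w * prob
            total_amp += amp
            win = np.abs(mz - centre) < 6 * sigma
            intensity[win] += amp * np.exp(-0.5 * ((mz[win] - centre) / sigma) ** 2)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        sd = spec.noise_sd * intensity.max()
        # a 5-sigma baseline offset keeps intensities non-negative (detector
        # offset) without distorting the noise distribution by clipping
        intensity = intensity + 5 * sd + rng.normal(0, sd, intensity.size)
        intensity = np.clip(intensity, 0, None)
    return MassSpectrum(mz, intensity)


def blend_envelopes(
    base: dict[int, float], high: dict[int, float], f: float
) -> dict[int, float]:
    """Linear blend of two charge envelopes (f=0 -> base, f=1 -> high)."""
    zs = sorted(set(base) | set(high))
    return {z: (1 - f) * base.get(z, 0.0) + f * high.get(z, 0.0) for z in zs}


def simulate_titration(
    spec: SpectrumFixtureSpec,
    detergent_concs: list[float],
    charge_envelope_high: dict[int, float] | None = None,
    seed: int | None = None,
) -> tuple[TitrationSeries, list[MassSpectrum]]:
    """One spectrum per detergent concentration plus the true bound fractions.

    The returned series carries, per lipid class, the true occupancy of every
    site (labelled ``"<lipid>:site<i>"``): monotone non-increasing in
    detergent for exchangeable sites, constant for protected ones. If a
    high-detergent charge envelope is given (charge stripping mitigated by
    the added detergent), envelopes are blended linearly across the titration.
    """
    if len(detergent_concs) < 2:
        raise ValueError("need at least 2 detergent concentrations")
    if any(b < a for a, b in zip(detergent_concs, detergent_concs[1:])):
        raise ValueError("detergent concentrations must be non-decreasing")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    d_lo, d_hi = detergent_concs[0], detergent_concs[-1]
    spectra = []
    rows = []
    for D in detergent_concs:
        envelope = spec.charge_envelope
        if charge_envelope_high is not None and d_hi > d_lo:
            envelope = blend_envelopes(
                spec.charge_envelope, charge_envelope_high, (D - d_lo) / (d_hi - d_lo)
            )
        spectra.append(
            simulate_spectrum(
                spec, detergent_conc=D, charge_envelope=envelope,
                seed=int(rng.integers(2**31)),
            )
        )
        for lip_name, thetas in spec.site_occupancies(D).items():
            for i, th in enumerate(thetas):
                rows.append(
                    {
                        "detergent_conc": D,
                        "label": f"{lip_name}:site{i + 1}",
                        "bound_fraction": th,
                    }
                )
    series = TitrationSeries(pd.DataFrame(rows), lipid_conc=spec.lipid_conc)
    return series, spectra
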