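"""Residency-time extraction and k_off estimation from contact traces.

A lipid's dwell at a binding site is read off a per-frame contact trace.
Three steps separate the raw trace from a dissociation rate:

1. **Dual-cutoff binarization** — a contact starts when the lipid comes
   closer than ``d_on`` and ends only when it moves beyond ``d_off``
   (hysteresis). This suppresses "rattling": brief excursions of a genuinely
   bound lipid past a single cutoff that would otherwise shred one long dwell
   into many short ones.
2. **Dwell extraction with gap merging** — maximal bound runs become dwells;
   unbound gaps no longer than a tolerance are absorbed into the surrounding
   dwell. Dwells touching either end of the trace are censored: their true
   length is only known to exceed the observed one.
3. **Censored exponential MLE** — for a single-rate (memoryless) process the
   maximum-likelihood dissociation rate is

       k_off = n_uncensored / sum(all durations, censored included),

   reported in us^-1 (durations are ns; k_off[us^-1] = 1000 / tau[ns]).
   Uncertainty is a percentile bootstrap over dwell resampling. A
   Kaplan-Meier survival curve provides an independent visual and numeric
   cross-check: for exponential dwells, -d log S / dt equals k_off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

DEFAULT_D_ON = 0.55  # nm
DEFAULT_D_OFF = 1.0  # nm
DEFAULT_GAP_TOLERANCE = 5.0  # ns
MIN_UNCENSORED = 10


@dataclass(frozen=True)
class BindingSite:
    """A lipid-binding site named by a flanking-residue pair, with synthetic
    ground-truth on/off rates (us^-1) used by the generators."""

    site_id: str
    label: str = ""
    k_on: float = 0.0
    k_off_true: float | None = None

    def __post_init__(self) -> None:
        if self.k_on < 0:
            raise ValueError(f"{self.site_id}: k_on must be >= 0")
        if self.k_off_true is not None and self.k_off_true <= 0:
            raise ValueError(f"{self.site_id}: k_off_true must be positive")


@dataclass
class ContactTrace:
    """A per-frame trace for one site: binary bound state or distance in nm."""

    site_id: str
    dt: float  # ns per frame
    values: np.ndarray
    kind: str = "state"  # "state" (binary) or "distance" (nm)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.kind not in ("state", "distance"):
            raise ValueError("kind must be 'state' or 'distance'")
        if self.kind == "distance":
            self.values = self.values.astype(float)
            if np.any(self.values < 0):
                raise ValueError("distances must be non-negative")
        else:
            vals = np.asarray(self.values)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("state traces must be 0/1")
            self.values = vals.astype(np.int8)

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        return self.n_frames * self.dt


@dataclass
class DwellTimeSet:
    """Extracted residency durations (ns) with trace-end censoring flags."""

    durations: np.ndarray
    censored: np.ndarray
    site_id: str = ""

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.durations.shape != self.censored.shape:
            raise ValueError("durations and censored flags must align")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be positive")

    @property
    def n_events(self) -> int:
        return int(self.durations.size)

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    @property
    def n_uncensored(self) -> int:
        return self.n_events - self.n_censored


@dataclass
class SurvivalCurve:
    """S(t): fraction of dwells lasting at least t (Kaplan-Meier)."""

    times: np.ndarray  # ns
    S: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if np.any(np.diff(self.S) > 1e-12):
            raise ValueError("S must be monotone non-increasing")

    def at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.S[max(i, 0)])


@dataclass
class KoffEstimate:
    k_off: float  # us^-1
    ci_low: float
    ci_high: float
    n_events: int
    n_censored: int
    site_id: str = ""
    method: str = "mle_censored"

    @property
    def residency_time(self) -> float:
        """Mean residency time in ns (1000 / k_off)."""
        return 1000.0 / self.k_off


def binarize_contacts(
    trace: ContactTrace, d_on: float = DEFAULT_D_ON, d_off: float = DEFAULT_D_OFF
) -> ContactTrace:
    """Dual-cutoff (hysteresis) contact definition on a distance trace.

    Bound begins when the distance drops below ``d_on`` and ends only when it
    exceeds ``d_off``; frames in between keep the previous state. Binary
    traces pass through unchanged.
    """
    if d_off < d_on or d_on <= 0:
        raise ValueError("need d_off >= d_on > 0")
    if trace.kind == "state":
        return trace
    d = trace.values
    sig = np.full(d.size, -1, dtype=np.int8)
    sig[d < d_on] = 1
    sig[d > d_off] = 0
    # forward-fill undecided frames from the last decided one; start unbound
    decided = sig >= 0
    idx = np.where(decided, np.arange(d.size), -1)
    np.maximum.accumulate(idx, out=idx)
    state = np.where(idx >= 0, sig[np.maximum(idx, 0)], 0).astype(np.int8)
    return ContactTrace(trace.site_id, trace.dt, state, kind="state")


def extract_dwells(
    trace: ContactTrace, gap_tolerance: float = DEFAULT_GAP_TOLERANCE
) -> DwellTimeSet:
    """Maximal bound runs as dwells, merging short unbound gaps.

    An unbound gap of length <= ``gap_tolerance`` (ns) between two bound runs
    is absorbed, and the merged dwell spans the gap. Dwells touching the first
    or last frame are flagged censored.
    """
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    if trace.kind != "state":
        raise ValueError("binarize the trace first (extract_dwells needs 0/1 states)")
    v = trace.values
    if v.size == 0 or not v.any():
        return DwellTimeSet(np.empty(0), np.empty(0, dtype=bool), trace.site_id)
    # run-length encode
    edges = np.flatnonzero(np.diff(v) != 0) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [v.size]))  # exclusive
    bound = v[starts] == 1

    intervals: list[list[int]] = []  # [start, end) frame indices of dwells
    i = 0
    n_runs = starts.size
    while i < n_runs:
        if not bound[i]:
            i += 1
            continue
        s, e = int(starts[i]), int(ends[i])
        j = i + 1
        while j + 1 < n_runs and not bound[j] and bound[j + 1]:
            gap_len = (ends[j] - starts[j]) * trace.dt
            if gap_len <= gap_tolerance:
                e = int(ends[j + 1])
                j += 2
            else:
                break
        intervals.append([s, e])
        i = j
    durations = np.array([(e - s) * trace.dt for s, e in intervals])
    censored = np.array([s == 0 or e == v.size for s, e in intervals])
    return DwellTimeSet(durations, censored, trace.site_id)


def survival_curve(dwells: DwellTimeSet) -> SurvivalCurve:
    """Kaplan-Meier survival function of the dwell durations.

    Censored dwells contribute at-risk time up to their observed length.
    """
    if dwells.n_uncensored < 1:
        raise ValueError(
            "all dwells are censored; record longer traces to observe complete dwells"
        )
    kmf = KaplanMeierFitter()
    kmf.fit(dwells.durations, event_observed=~dwells.censored)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    S = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    if times[0] != 0.0:
        times = np.concatenate(([0.0], times))
        S = np.concatenate(([1.0], S))
    return SurvivalCurve(times, S)


def koff_from_survival(curve: SurvivalCurve, s_floor: float = 0.05) -> float:
    """Cross-check rate (us^-1) from the slope of log S(t).

    Weighted least squares on log S over the region S > ``s_floor``, where the
    exponential model predicts a straight line through (0, 0).
    """
    mask = (curve.S > s_floor) & (curve.times >= 0)
    t = curve.times[mask]
    logS = np.log(curve.S[mask])
    if t.size < 3:
        raise ValueError("survival curve too short for a slope fit")
    slope = float(np.dot(t, logS) / np.dot(t, t))  # line through the origin
    return -slope * 1000.0


def estimate_koff(
    dwells: DwellTimeSet,
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> KoffEstimate:
    """Censored exponential MLE of k_off with a percentile bootstrap CI.

    The point estimate is n_uncensored / total observed dwell time (censored
    dwells included in the denominator), converted to us^-1. The CI resamples
    dwells (duration, censored flag) with replacement ``n_boot`` times.
    """
    if dwells.n_uncensored < MIN_UNCENSORED:
        raise ValueError(
            f"need at least {MIN_UNCENSORED} uncensored dwells "
            f"(got {dwells.n_uncensored}); the estimate would be unstable"
        )
    k_ns = dwells.n_uncensored / float(dwells.durations.sum())
    k = 1000.0 * k_ns

    rng = np.random.default_rng(seed)
    n = dwells.n_events
    uncensored = (~dwells.censored).astype(float)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        n_unc = uncensored[idx].sum()
        tot = dwells.durations[idx].sum()
        reps[b] = 1000.0 * n_unc / tot if n_unc > 0 else np.nan
    alpha = 1.0 - ci_level
    lo, hi = np.nanpercentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return KoffEstimate(
        k_off=k,
        ci_low=float(lo),
        ci_high=float(hi),
        n_events=n,
        n_censored=dwells.n_censored,
        site_id=dwells.site_id,
    )


@dataclass
class SiteComparison:
    """Sites ordered by k_off with pairwise fold ratios and CI-overlap flags."""

    order: list[str]  # site ids, ascending k_off (slowest first)
    pairs: pd.DataFrame  # columns: slow, fast, fold, ci_overlap


def compare_sites(estimates: list[KoffEstimate]) -> SiteComparison:
    """Rank sites by dissociation rate and compute pairwise fold separations.

    Fold ratio is k_off(fast)/k_off(slow) for every pair; pairs whose
    bootstrap CIs overlap are flagged (their separation is not resolved).
    """
    if len(estimates) < 2:
        raise ValueError("need at least 2 site estimates to compare")
    est = sorted(estimates, key=lambda e: e.k_off)
    rows = []
    for i, slow in enumerate(est):
        for fast in est[i + 1 :]:
            overlap = (slow.ci_high >= fast.ci_low) and (fast.ci_high >= slow.ci_low)
            rows.append(
                {
                    "slow": slow.site_id,
                    "fast": fast.site_id,
                    "fold": fast.k_off / slow.k_off,
                    "ci_overlap": overlap,
                }
            )
    return SiteComparison([e.site_id for e in est], pd.DataFrame(rows))


def site_occupancy(trace: ContactTrace) -> float:
    """Fraction of frames in the bound state."""
    if trace.n_frames == 0:
        raise ValueError("empty trace")
    if trace.kind != "state":
        raise ValueError("binarize the trace first")
    return float(trace.values.mean())


@dataclass
class AccessibilityProfile:
    """Contact frequency of a substrate lipid with named residues, per
    conformational state. Missing (state, residue) cells are NaN (absent, not
    zero)."""

    matrix: pd.DataFrame  # index: states, columns: residues

    def frequency(self, state: str, residue: str) -> float:
        return float(self.matrix.loc[state, residue])


def contact_frequency(
    traces: dict[tuple[str, str], ContactTrace], d_contact: float = DEFAULT_D_ON
) -> AccessibilityProfile:
    """Per-(state, residue) fraction of frames with distance < d_contact.

    A single cutoff: this measures accessibility frequencies, not kinetics.
    Binary traces are used as-is.
    """
    states = sorted({s for s, _ in traces})
    residues = sorted({r for _, r in traces})
    mat = pd.DataFrame(np.nan, index=states, columns=residues)
    for (state, residue), trace in traces.items():
        if trace.kind == "distance":
            freq = float((trace.values < d_contact).mean())
        else:
            freq = float(trace.values.mean())
        mat.loc[state, residue] = freq
    return AccessibilityProfile(mat)


def warn_if_coarse(dt: float, k_off_true: float) -> None:
    """Warn when the frame interval is too coarse for the dwell scale."""
    mean_dwell = 1000.0 / k_off_true
    if dt >= mean_dwell / 2:
        warnings.warn(
            f"frame interval dt={dt} ns is >= half the mean dwell "
            f"({mean_dwell:.1f} ns); discretization will bias dwell times",
            stacklevel=3,
        )
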