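"""Peak picking, lipid-adduct assignment and bound-fraction quantification.

This is the measurement step of the detergent-competition assay: a native mass
spectrum of an intact membrane protein shows, for each charge state z, a ladder
of peaks spaced by (lipid mass)/z. Assigning those peaks against a known
protein mass and a candidate lipid list yields per-charge-state adduct
stoichiometries, from which bound fractions are quantified by peak area.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .species import PROTON_MASS, LipidSpecies, ProteinSpecies, mz_of

#: Intensity fraction below which a lipid-bound population is considered
#: undetectable (operationalizes "effectively removes all bound lipids").
DETECTION_THRESHOLD = 0.03

#: Default assignment tolerance in Da at the deconvolved-mass scale.
DEFAULT_TOLERANCE = 2.5


@dataclass(frozen=True)
class MassSpectrum:
    """A profile or centroid spectrum: strictly increasing m/z, intensities >= 0."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            bad = int(np.argmax(np.diff(mz) <= 0))
            raise ValueError(f"mz must be strictly increasing (violated at index {bad + 1})")
        if np.any(inten < 0):
            bad = int(np.argmax(inten < 0))
            raise ValueError(f"intensity must be non-negative (violated at index {bad})")

    def scaled(self, factor: float) -> "MassSpectrum":
        return MassSpectrum(self.mz, self.intensity * factor)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    area: float


@dataclass(frozen=True)
class PeakList:
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        apexes = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(apexes, apexes[1:])):
            raise ValueError("peak apexes must be strictly increasing")
        if any(p.intensity <= 0 for p in self.peaks):
            raise ValueError("peak intensities must be positive")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass
class AdductAssignment:
    """One peak assigned to a (charge, lipid-count) composition."""

    charge: int
    adduct_counts: dict[str, int]
    theoretical_mz: float
    observed_mz: float
    mass_error: float  # Da, at the deconvolved (neutral-mass) scale
    intensity: float  # peak area used for quantification
    intensity_share: float = np.nan  # within-charge-state fraction
    ambiguous: bool = False
    alternatives: list[dict[str, int]] = field(default_factory=list)

    @property
    def total_adducts(self) -> int:
        return sum(self.adduct_counts.values())


@dataclass
class AssignmentResult:
    assignments: list[AdductAssignment]
    unassigned: list[Peak]


def pick_peaks(
    spectrum: MassSpectrum, min_snr: float = 5.0, min_spacing: float = 1.5
) -> PeakList:
    """Find local maxima above a noise-relative threshold.

    The baseline is the median intensity and the noise floor the (normal-
    consistent, 1.4826x) median absolute deviation around it — both robust to
    the sparse peaks riding on the baseline. Maxima below
    ``baseline + min_snr * noise_floor`` are rejected, and of any two apexes
    closer than ``min_spacing`` m/z only the taller is kept; a matching
    prominence requirement stops noise riding on a broad peak from splitting
    it. Apex intensities are refined by three-point parabolic interpolation;
    apex positions are intensity-weighted centroids of the upper part of the
    peak (robust to grid quantization and noise); areas are trapezoidal
    integrals of the baseline-subtracted signal between the flanking local
    minima.
    """
    if min_snr <= 0:
        raise ValueError("min_snr must be positive")
    y = spectrum.intensity
    x = spectrum.mz
    if y.size < 3 or np.ptp(y) == 0:
        return PeakList(())
    baseline = float(np.median(y))
    noise = 1.4826 * float(np.median(np.abs(y - baseline)))
    threshold = baseline + min_snr * noise
    idx, _ = signal.find_peaks(
        y,
        height=threshold if threshold > 0 else None,
        prominence=min_snr * noise if noise > 0 else None,
    )
    if idx.size == 0:
        return PeakList(())

    # greedy tall-first suppression of near-duplicate apexes
    order = idx[np.argsort(y[idx])[::-1]]
    kept: list[int] = []
    for i in order:
        if all(abs(x[i] - x[j]) >= min_spacing for j in kept):
            kept.append(i)
    kept.sort()

    peaks = []
    eps = 3.0 * noise  # tolerated uptick while descending through noise
    for i in kept:
        lo, run_min = i, y[i]
        while lo > 0 and y[lo - 1] <= run_min + eps:
            lo -= 1
            run_min = min(run_min, y[lo])
        hi, run_min = i, y[i]
        while hi < y.size - 1 and y[hi + 1] <= run_min + eps:
            hi += 1
            run_min = min(run_min, y[hi])
        seg = np.clip(y[lo : hi + 1] - baseline, 0, None)
        xs = x[lo : hi + 1]
        area = float(np.trapezoid(seg, xs))
        _, apex_int = _parabolic_apex(x, y, i)
        # centroid over the upper part of the peak: robust apex position
        core = seg >= 0.3 * seg.max()
        apex_mz = float(np.average(xs[core], weights=seg[core]))
        peaks.append(Peak(apex_mz, apex_int, area))
    peaks.sort(key=lambda p: p.mz)
    # interpolation can collapse two grid-adjacent apexes; keep the taller
    dedup: list[Peak] = []
    for p in peaks:
        if dedup and p.mz - dedup[-1].mz < 1e-9:
            if p.intensity > dedup[-1].intensity:
                dedup[-1] = p
        else:
            dedup.append(p)
    return PeakList(tuple(dedup))


def _parabolic_apex(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    if i == 0 or i == y.size - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = 0.5 * (x[i + 1] - x[i - 1])
    return float(x[i] + delta * step), float(y1 - 0.25 * (y0 - y2) * delta)


def _compositions(n_candidates: int, max_adducts: int):
    for total in range(max_adducts + 1):
        for cuts in itertools.combinations_with_replacement(range(n_candidates), total):
            counts = [0] * n_candidates
            for c in cuts:
                counts[c] += 1
            yield tuple(counts)


def assign_adducts(
    peaks: PeakList,
    protein: ProteinSpecies,
    candidates: list[LipidSpecies],
    max_adducts: int = 3,
    tolerance: float = DEFAULT_TOLERANCE,
) -> AssignmentResult:
    """Match peaks to (charge, lipid-adduct-count) compositions.

    Every composition with at most ``max_adducts`` total lipids is considered
    at every charge of the protein's range; a peak is assigned to the
    composition whose theoretical neutral mass lies within ``tolerance`` Da of
    the deconvolved observed mass. When several compositions fall inside the
    tolerance window the assignment is flagged ambiguous and resolved
    deterministically: fewer total adducts first, then earlier candidates in
    the supplied list, then smaller mass error — never a silent choice.
    """
    if not candidates:
        raise ValueError("candidate lipid list must be non-empty")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    names = [lip.name for lip in candidates]
    masses = np.array([lip.mass for lip in candidates])
    comps = list(_compositions(len(candidates), max_adducts))
    comp_masses = np.array([float(np.dot(c, masses)) for c in comps])

    assignments: list[AdductAssignment] = []
    unassigned: list[Peak] = []
    for peak in peaks:
        matches = []  # (total, order_key, |err|, z, comp_index, err)
        for z in protein.charges:
            obs_mass = peak.mz * z - z * PROTON_MASS
            errs = obs_mass - (protein.average_mass + comp_masses)
            for k in np.flatnonzero(np.abs(errs) <= tolerance):
                comp = comps[k]
                order_key = tuple(-c for c in comp)
                matches.append(
                    (sum(comp), order_key, abs(float(errs[k])), z, int(k), float(errs[k]))
                )
        if not matches:
            unassigned.append(peak)
            continue
        matches.sort(key=lambda m: m[:3])
        total, _, _, z, k, err = matches[0]
        comp = comps[k]
        theo_mass = protein.average_mass + float(comp_masses[k])
        assignments.append(
            AdductAssignment(
                charge=z,
                adduct_counts={n: c for n, c in zip(names, comp) if c > 0},
                theoretical_mz=mz_of(theo_mass, z),
                observed_mz=peak.mz,
                mass_error=err,
                intensity=peak.area if peak.area > 0 else peak.intensity,
                ambiguous=len(matches) > 1,
                alternatives=[
                    {n: c for n, c in zip(names, comps[m[4]]) if c > 0}
                    for m in matches[1:4]
                ],
            )
        )

    # within-charge-state intensity shares
    for z in {a.charge for a in assignments}:
        group = [a for a in assignments if a.charge == z]
        tot = sum(a.intensity for a in group)
        for a in group:
            a.intensity_share = a.intensity / tot if tot > 0 else np.nan
    return AssignmentResult(assignments, unassigned)


def quantify_bound_fractions(
    assignments: list[AdductAssignment],
    envelope_weights: dict[int, float] | None = None,
) -> dict[str, dict[int, float]]:
    """Adduct-count intensity fractions per lipid and overall.

    Fractions are computed per charge state from intensity shares and then
    aggregated across charge states as an envelope-weight-weighted mean
    (observed per-charge total intensity when no weights are supplied).
    Returns ``{lipid_name or "any": {adduct_count: fraction}}``; each inner
    map sums to 1.
    """
    if not assignments:
        raise ValueError("no assignments to quantify (all peaks unassigned?)")
    charges = sorted({a.charge for a in assignments})
    if envelope_weights is None:
        envelope_weights = {
            z: sum(a.intensity for a in assignments if a.charge == z) for z in charges
        }
    wtot = sum(envelope_weights.get(z, 0.0) for z in charges)
    if wtot <= 0:
        raise ValueError("zero total envelope weight over assigned charge states")

    lipid_names = sorted({n for a in assignments for n in a.adduct_counts})
    out: dict[str, dict[int, float]] = {}
    for key in lipid_names + ["any"]:
        counts_of = (
            (lambda a: a.total_adducts)
            if key == "any"
            else (lambda a, k=key: a.adduct_counts.get(k, 0))
        )
        agg: dict[int, float] = {}
        for z in charges:
            group = [a for a in assignments if a.charge == z]
            tot = sum(a.intensity for a in group)
            if tot <= 0:
                continue
            w = envelope_weights.get(z, 0.0) / wtot
            for a in group:
                c = counts_of(a)
                agg[c] = agg.get(c, 0.0) + w * a.intensity / tot
        norm = sum(agg.values())
        out[key] = {c: v / norm for c, v in sorted(agg.items())}
    return out


def average_charge(assignments: list[AdductAssignment]) -> float:
    """Intensity-weighted mean charge state of the assigned peaks."""
    if not assignments:
        raise ValueError("no assignments")
    tot = sum(a.intensity for a in assignments)
    if tot <= 0:
        raise ValueError("zero total intensity")
    return sum(a.charge * a.intensity for a in assignments) / tot


def fraction_bound(fractions: dict[int, float], min_count: int = 1) -> float:
    """P(adduct count >= min_count) from a count-fraction map."""
    return sum(v for c, v in fractions.items() if c >= min_count)
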