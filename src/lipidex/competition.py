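"""Competitive lipid-vs-detergent displacement model and titration fitting.

The assay reads out the bound fraction of a lipid as the detergent
concentration is stepped up. Exchangeable (annular) lipids are displaced;
lipids in protected sites (an oligomer interface, a buried active site) are
not. The model is a single-site competitive Langmuir isotherm,

    theta = (L/K_L) / (1 + L/K_L + D_eff/K_D),      D_eff = max(0, D - CMC),

where L is the (fixed) lipid concentration, D the detergent concentration,
K_L the lipid half-occupancy constant, K_D the detergent half-displacement
constant, and only detergent above its critical micelle concentration
competes. A site flagged ``protected`` is unreachable by detergent:
theta = (L/K_L)/(1 + L/K_L) at any D.

Classification uses the retention index R = theta(max D) / theta(min D);
R at or below a threshold (default 0.5) means annular (exchangeable),
R above it means non-annular (detergent-resistant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model

DEFAULT_R_THRESHOLD = 0.5
#: Max observed spread in theta across the titration (with detectable binding)
#: below which a site is reported protected rather than fitted.
FLATNESS_TOL = 1e-3


@dataclass(frozen=True)
class OccupancyModelParams:
    """Parameters of the competitive occupancy model for one site.

    K_L and the lipid concentration share units (e.g. uM); K_D shares units
    with the detergent concentration (% w/v here).
    """

    K_L: float
    K_D: float | None = None
    protected: bool = False

    def __post_init__(self) -> None:
        if self.K_L <= 0:
            raise ValueError("K_L must be positive")
        if not self.protected:
            if self.K_D is None or self.K_D <= 0:
                raise ValueError("K_D must be positive for an unprotected site")


def occupancy(
    params: OccupancyModelParams, L: float, D: float, cmc: float = 0.0
) -> float:
    """Equilibrium bound fraction theta for one site.

    Parameters
    ----------
    params : site constants (and protected flag).
    L : lipid concentration (same units as K_L); >= 0.
    D : total detergent concentration (same units as K_D and cmc); >= 0.
    cmc : critical micelle concentration; only D above it competes.
    """
    if L < 0 or D < 0:
        raise ValueError("concentrations must be non-negative")
    x = L / params.K_L
    if params.protected:
        return x / (1.0 + x)
    d_eff = max(0.0, D - cmc)
    return x / (1.0 + x + d_eff / params.K_D)


@dataclass
class TitrationSeries:
    """Observed bound fractions across a detergent titration.

    ``data`` holds one row per (detergent_conc, label) with the observed bound
    fraction; ``label`` identifies a lipid class or a binding position within
    one. The lipid concentration is fixed over the series.
    """

    data: pd.DataFrame  # columns: detergent_conc, label, bound_fraction
    lipid_conc: float

    def __post_init__(self) -> None:
        required = {"detergent_conc", "label", "bound_fraction"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"series needs columns {sorted(required)}")
        theta = self.data["bound_fraction"].to_numpy(dtype=float)
        if np.any(theta < -1e-9) or np.any(theta > 1 + 1e-6):
            raise ValueError("bound fractions must lie in [0, 1]")
        for label, grp in self.data.groupby("label"):
            if len(grp) < 2:
                raise ValueError(f"label {label!r}: need at least 2 titration points")

    @property
    def labels(self) -> list[str]:
        return sorted(self.data["label"].unique())

    def thetas(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        grp = self.data[self.data["label"] == label].sort_values("detergent_conc")
        return (
            grp["detergent_conc"].to_numpy(dtype=float),
            grp["bound_fraction"].to_numpy(dtype=float),
        )


@dataclass
class CompetitionFit:
    """Fitted displacement model and annular/non-annular classification."""

    label: str
    params: OccupancyModelParams | None
    retention_index: float
    residual: float
    classification: str
    theta_low: float  # observed theta at the lowest detergent concentration
    theta_high: float  # observed theta at the highest
    detail: dict = field(default_factory=dict)


def classify_exchange(
    fit: CompetitionFit, r_threshold: float = DEFAULT_R_THRESHOLD
) -> str:
    """'annular' if the retention index is at or below the threshold, else 'non-annular'."""
    return "annular" if fit.retention_index <= r_threshold else "non-annular"


def _retention_index(theta_low: float, theta_high: float) -> float:
    if theta_low <= 1e-12:
        return 1.0 if theta_high > 1e-12 else 0.0
    return theta_high / theta_low


def fit_competition(
    series: TitrationSeries,
    cmc: float,
    r_threshold: float = DEFAULT_R_THRESHOLD,
) -> dict[str, CompetitionFit]:
    """Fit (K_L, K_D) per label and classify each as annular / non-annular.

    The lipid concentration is fixed and known; a least-squares fit of the
    competitive isotherm is attempted when the series has at least three
    distinct detergent concentrations. A series whose bound fraction does not
    respond to detergent at all (flat, above the detection floor) is reported
    as a protected site instead of letting K_D diverge. With only two points
    the retention index (and classification) is still computed, without model
    parameters.
    """
    fits: dict[str, CompetitionFit] = {}
    L = series.lipid_conc
    for label in series.labels:
        D, theta = series.thetas(label)
        theta_low, theta_high = float(theta[0]), float(theta[-1])
        R = _retention_index(theta_low, theta_high)
        flat = np.ptp(theta) < FLATNESS_TOL and np.ptp(D) > 0
        params: OccupancyModelParams | None = None
        residual = float("nan")
        detail: dict = {}
        if flat and np.mean(theta) > 1e-6:
            tbar = float(np.clip(np.mean(theta), 1e-9, 1 - 1e-9))
            params = OccupancyModelParams(K_L=L * (1 - tbar) / tbar, protected=True)
            residual = float(np.sqrt(np.mean((theta - tbar) ** 2)))
            R = 1.0
            detail["protected_reason"] = "no detergent response across titration"
        elif len(np.unique(D)) >= 3:
            params, residual, detail = _ls_fit(D, theta, L, cmc)
        fit = CompetitionFit(
            label=label,
            params=params,
            retention_index=R,
            residual=residual,
            classification="",
            theta_low=theta_low,
            theta_high=theta_high,
            detail=detail,
        )
        fit.classification = classify_exchange(fit, r_threshold)
        fits[label] = fit
    return fits


def _ls_fit(D, theta, L, cmc):
    def model(D, K_L, K_D):
        x = L / K_L
        d_eff = np.maximum(0.0, D - cmc)
        return x / (1.0 + x + d_eff / K_D)

    t0 = float(np.clip(theta[0], 1e-6, 1 - 1e-6))
    kl0 = L * (1 - t0) / t0
    d_eff = np.maximum(0.0, D - cmc)
    pos = d_eff[d_eff > 0]
    kd0 = float(np.median(pos)) if pos.size else 0.1
    m = Model(model)
    m.set_param_hint("K_L", value=kl0, min=1e-9)
    m.set_param_hint("K_D", value=kd0, min=1e-9)
    try:
        res = m.fit(theta, D=D)
    except Exception as exc:  # singular fits on degenerate series
        return None, float("nan"), {"fit_error": str(exc)}
    params = OccupancyModelParams(
        K_L=float(res.params["K_L"].value), K_D=float(res.params["K_D"].value)
    )
    residual = float(np.sqrt(np.mean(res.residual**2)))
    detail = {
        "K_L_stderr": float(res.params["K_L"].stderr or np.nan),
        "K_D_stderr": float(res.params["K_D"].stderr or np.nan),
        "success": bool(res.success),
    }
    return params, residual, detail
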