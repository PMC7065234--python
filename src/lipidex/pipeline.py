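"""Configuration-driven orchestration of the three analyses.

A ``RunConfig`` names one analysis — ``titration`` (spectra -> adduct
assignment -> competition fit -> annular/non-annular labels), ``kinetics``
(contact traces -> dwells -> k_off estimates -> site comparison) or
``accessibility`` (per-state contact frequencies) — and either a packaged
fixture or input files. ``run`` executes it deterministically and returns a
``Report`` whose tables are written as TSV plus a single structured JSON.
Every parameter that fell back to a default is logged, so model choices are
always visible in the output.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import fixtures as fixture_lib
from . import io as lio
from .competition import DEFAULT_R_THRESHOLD, TitrationSeries, fit_competition
from .kinetics import (
    DEFAULT_D_OFF,
    DEFAULT_D_ON,
    DEFAULT_GAP_TOLERANCE,
    DwellTimeSet,
    binarize_contacts,
    compare_sites,
    contact_frequency,
    estimate_koff,
    extract_dwells,
    site_occupancy,
)
from .spectra import (
    DEFAULT_TOLERANCE,
    assign_adducts,
    average_charge,
    fraction_bound,
    pick_peaks,
    quantify_bound_fractions,
)
from .synthetic import simulate_contact_trace, simulate_titration

ANALYSES = ("titration", "kinetics", "accessibility")

_PARAM_DEFAULTS = {
    "titration": {
        "min_snr": 5.0,
        "min_spacing": 1.5,
        "max_adducts": 3,
        "tolerance": DEFAULT_TOLERANCE,
        "r_threshold": DEFAULT_R_THRESHOLD,
        "cmc": None,  # required for input-mode runs; fixtures carry their own
        "lipid_conc": None,
    },
    "kinetics": {
        "d_on": DEFAULT_D_ON,
        "d_off": DEFAULT_D_OFF,
        "gap_tolerance": DEFAULT_GAP_TOLERANCE,
        "dt": 1.0,
        "n_boot": 1000,
    },
    "accessibility": {
        "d_contact": DEFAULT_D_ON,
        "dt": 1.0,
    },
}


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every problem found."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n  - " + "\n  - ".join(errors))


@dataclass
class RunConfig:
    analysis: str
    fixture: str | None = None
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    outdir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        errors = []
        analysis = cfg.get("analysis")
        if analysis not in ANALYSES:
            errors.append(f"analysis must be one of {ANALYSES}, got {analysis!r}")
        fixture = cfg.get("fixture")
        inputs = cfg.get("inputs") or {}
        if (fixture is None) == (not inputs):
            errors.append("exactly one of 'fixture' or 'inputs' must be given")
        if fixture is not None and fixture not in fixture_lib.fixture_names():
            errors.append(
                f"unknown fixture {fixture!r}; available: {fixture_lib.fixture_names()}"
            )
        seed = cfg.get("seed", 0)
        if not isinstance(seed, int):
            errors.append(f"seed must be an integer, got {seed!r}")
        params = cfg.get("params") or {}
        known = _PARAM_DEFAULTS.get(analysis, {})
        for key, val in params.items():
            if analysis in _PARAM_DEFAULTS and key not in known:
                errors.append(f"unknown parameter {key!r} for analysis {analysis!r}")
                continue
            if val is not None and not isinstance(val, (int, float)):
                errors.append(f"parameter {key!r} must be numeric, got {val!r}")
        for key in ("min_snr", "tolerance", "d_on", "d_off", "dt", "d_contact"):
            if isinstance(params.get(key), (int, float)) and params[key] <= 0:
                errors.append(f"parameter {key!r} must be positive")
        if isinstance(params.get("gap_tolerance"), (int, float)) and params["gap_tolerance"] < 0:
            errors.append("parameter 'gap_tolerance' must be >= 0")
        if all(isinstance(params.get(k), (int, float)) for k in ("d_on", "d_off")):
            if params["d_off"] < params["d_on"]:
                errors.append("parameter 'd_off' must be >= 'd_on'")
        rt = params.get("r_threshold")
        if isinstance(rt, (int, float)) and not (0 < rt < 1):
            errors.append("parameter 'r_threshold' must lie in (0, 1)")
        if errors:
            raise ConfigError(errors)
        return cls(
            analysis=analysis,
            fixture=fixture,
            inputs=dict(inputs),
            params=dict(params),
            outdir=cfg.get("outdir"),
            seed=seed,
        )

    def resolved_params(self) -> tuple[dict, list[str]]:
        """Parameters with defaults filled in, plus the names defaulted."""
        defaults = _PARAM_DEFAULTS[self.analysis]
        resolved, defaulted = {}, []
        for key, default in defaults.items():
            if key in self.params and self.params[key] is not None:
                resolved[key] = self.params[key]
            else:
                resolved[key] = default
                defaulted.append(key)
        return resolved, defaulted

    def to_dict(self) -> dict:
        return {
            "analysis": self.analysis,
            "fixture": self.fixture,
            "inputs": self.inputs,
            "params": self.params,
            "seed": self.seed,
        }


@dataclass
class Report:
    tables: dict[str, pd.DataFrame]
    provenance: dict

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        doc = {
            "provenance": self.provenance,
            "tables": {
                name: json.loads(t.to_json(orient="records", double_precision=12))
                for name, t in self.tables.items()
            },
        }
        (outdir / "report.json").write_text(json.dumps(doc, indent=2, sort_keys=True))
        log = [
            f"timestamp: {datetime.now(timezone.utc).isoformat()}",
            f"version: {self.provenance['version']}",
            f"config_hash: {self.provenance['config_hash']}",
            f"seed: {self.provenance['seed']}",
            "parameters:",
        ] + [
            f"  {k} = {v}"
            + ("  [default]" if k in self.provenance["defaulted_params"] else "")
            for k, v in self.provenance["params"].items()
        ]
        (outdir / "run.log").write_text("\n".join(log) + "\n")
        return outdir / "report.json"


def _provenance(config: RunConfig, params: dict, defaulted: list[str]) -> dict:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "params": params,
        "defaulted_params": defaulted,
    }


def run(config: RunConfig) -> Report:
    """Execute one analysis; deterministic given the config (incl. seeds)."""
    params, defaulted = config.resolved_params()
    if config.analysis == "titration":
        tables = _run_titration(config, params)
    elif config.analysis == "kinetics":
        tables = _run_kinetics(config, params)
    else:
        tables = _run_accessibility(config, params)
    report = Report(tables, _provenance(config, params, defaulted))
    if config.outdir:
        report.write(config.outdir)
    return report


# ---------------------------------------------------------------- titration

def _run_titration(config: RunConfig, params: dict) -> dict[str, pd.DataFrame]:
    if config.fixture:
        fx = fixture_lib.load_fixture(config.fixture)
        if not isinstance(fx, fixture_lib.TitrationFixture):
            raise ConfigError([f"fixture {config.fixture!r} is not a titration fixture"])
        return _titration_from_fixture(fx, params, config.seed)
    series = lio.read_titration_csv(
        config.inputs["series"], lipid_conc=params.get("lipid_conc")
    )
    if params["cmc"] is None:
        raise ConfigError(["parameter 'cmc' is required for input-mode titration"])
    fits = fit_competition(series, cmc=params["cmc"], r_threshold=params["r_threshold"])
    return {"competition_fits": _fits_table(fits)}


def _titration_from_fixture(fx, params, seed) -> dict[str, pd.DataFrame]:
    spec = fx.spec
    truth_series, spectra = simulate_titration(
        spec, list(fx.detergent_concs),
        charge_envelope_high=fx.charge_envelope_high,
        seed=spec.seed if seed == 0 else seed,
    )
    candidates = [lip for lip, _ in spec.lipids]
    n_sites = {lip.name: len(sites) for lip, sites in spec.lipids}

    assign_rows, frac_rows, charge_rows, obs_rows = [], [], [], []
    for D, spectrum in zip(fx.detergent_concs, spectra):
        peaks = pick_peaks(spectrum, params["min_snr"], params["min_spacing"])
        result = assign_adducts(
            peaks, spec.protein, candidates,
            max_adducts=int(params["max_adducts"]), tolerance=params["tolerance"],
        )
        for a in result.assignments:
            assign_rows.append({
                "detergent_conc": D,
                "charge": a.charge,
                "adducts": ";".join(f"{n}x{c}" for n, c in a.adduct_counts.items()) or "apo",
                "observed_mz": a.observed_mz,
                "mass_error_da": a.mass_error,
                "intensity_share": a.intensity_share,
                "ambiguous": a.ambiguous,
            })
        fractions = quantify_bound_fractions(result.assignments)
        for lipid, counts in fractions.items():
            for c, frac in counts.items():
                frac_rows.append({
                    "detergent_conc": D, "lipid": lipid, "adduct_count": c,
                    "fraction": frac,
                })
        charge_rows.append({
            "detergent_conc": D, "average_charge": average_charge(result.assignments),
        })
        for lipid, m in n_sites.items():
            counts = fractions.get(lipid, {0: 1.0})
            for j in range(1, m + 1):
                obs_rows.append({
                    "detergent_conc": D,
                    "label": f"{lipid}[pos{j}]",
                    "bound_fraction": min(1.0, fraction_bound(counts, j)),
                })

    obs_series = TitrationSeries(pd.DataFrame(obs_rows), lipid_conc=spec.lipid_conc)
    cmc = spec.detergent.cmc if params["cmc"] is None else params["cmc"]
    fits_obs = fit_competition(obs_series, cmc=cmc, r_threshold=params["r_threshold"])
    fits_truth = fit_competition(truth_series, cmc=cmc, r_threshold=params["r_threshold"])
    return {
        "assignments": pd.DataFrame(assign_rows),
        "bound_fractions": pd.DataFrame(frac_rows),
        "average_charge": pd.DataFrame(charge_rows),
        "competition_fits": _fits_table(fits_obs),
        "competition_fits_truth": _fits_table(fits_truth),
    }


def _fits_table(fits) -> pd.DataFrame:
    rows = []
    for label, fit in sorted(fits.items()):
        rows.append({
            "label": label,
            "K_L": fit.params.K_L if fit.params else math.nan,
            "K_D": (fit.params.K_D if fit.params and fit.params.K_D else math.nan),
            "protected": bool(fit.params.protected) if fit.params else False,
            "retention_index": fit.retention_index,
            "theta_low_D": fit.theta_low,
            "theta_high_D": fit.theta_high,
            "residual": fit.residual,
            "classification": fit.classification,
        })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- kinetics

def _run_kinetics(config: RunConfig, params: dict) -> dict[str, pd.DataFrame]:
    if config.fixture:
        fx = fixture_lib.load_fixture(config.fixture)
        if not isinstance(fx, fixture_lib.KineticsFixture):
            raise ConfigError([f"fixture {config.fixture!r} is not a kinetics fixture"])
        return _kinetics_from_fixture(fx, params, config.seed)
    traces = lio.read_contact_table(config.inputs["traces"], dt=params["dt"])
    dwell_sets, occ_rows = [], []
    for site_id, trace in sorted(traces.items()):
        binary = binarize_contacts(trace, params["d_on"], params["d_off"])
        dwell_sets.append(extract_dwells(binary, params["gap_tolerance"]))
        occ_rows.append({"site_id": site_id, "occupancy": site_occupancy(binary)})
    return _kinetics_tables(dwell_sets, occ_rows, int(params["n_boot"]), config.seed)


def _kinetics_from_fixture(fx, params, seed) -> dict[str, pd.DataFrame]:
    rng = np.random.default_rng(fx.seed if seed == 0 else seed)
    dwell_sets, occ_rows = [], []
    for site in fx.sites:
        mean_cycle = 1000.0 / site.k_on + 1000.0 / site.k_off_true
        n_traces = max(1, math.ceil(fx.n_events[site.site_id] * mean_cycle / fx.duration))
        pooled_d, pooled_c, occ = [], [], []
        for _ in range(n_traces):
            trace = simulate_contact_trace(
                site, fx.duration, fx.dt,
                rattle_rate=fx.rattle_rate, rattle_mean=fx.rattle_mean,
                seed=int(rng.integers(2**31)), emit="distance",
            )
            binary = binarize_contacts(trace, fx.d_on, fx.d_off)
            dwells = extract_dwells(binary, fx.gap_tolerance)
            pooled_d.append(dwells.durations)
            pooled_c.append(dwells.censored)
            occ.append(site_occupancy(binary))
        dwell_sets.append(DwellTimeSet(
            np.concatenate(pooled_d), np.concatenate(pooled_c), site.site_id
        ))
        occ_rows.append({
            "site_id": site.site_id,
            "occupancy": float(np.mean(occ)),
            "occupancy_expected": site.k_on / (site.k_on + site.k_off_true),
            "k_off_true": site.k_off_true,
        })
    return _kinetics_tables(dwell_sets, occ_rows, fx.n_boot, int(rng.integers(2**31)))


def _kinetics_tables(dwell_sets, occ_rows, n_boot, seed) -> dict[str, pd.DataFrame]:
    rng = np.random.default_rng(seed)
    estimates = [
        estimate_koff(d, n_boot=n_boot, seed=int(rng.integers(2**31)))
        for d in dwell_sets
    ]
    est_rows = [{
        "site_id": e.site_id,
        "k_off_us": e.k_off,
        "ci_low": e.ci_low,
        "ci_high": e.ci_high,
        "mean_residency_ns": e.residency_time,
        "max_dwell_ns": float(d.durations.max()),
        "n_events": e.n_events,
        "n_censored": e.n_censored,
        "method": e.method,
    } for e, d in zip(estimates, dwell_sets)]
    comparison = compare_sites(estimates) if len(estimates) >= 2 else None
    tables = {
        "koff_estimates": pd.DataFrame(est_rows),
        "occupancy": pd.DataFrame(occ_rows),
    }
    if comparison is not None:
        tables["fold_ratios"] = comparison.pairs
    return tables


# ------------------------------------------------------------- accessibility

def _run_accessibility(config: RunConfig, params: dict) -> dict[str, pd.DataFrame]:
    if config.fixture:
        fx = fixture_lib.load_fixture(config.fixture)
        if not isinstance(fx, fixture_lib.AccessibilityFixture):
            raise ConfigError(
                [f"fixture {config.fixture!r} is not an accessibility fixture"]
            )
        rng = np.random.default_rng(fx.seed if config.seed == 0 else config.seed)
        traces = {
            key: simulate_contact_trace(
                site, fx.duration, fx.dt, seed=int(rng.integers(2**31)),
                emit="distance",
            )
            for key, site in sorted(fx.sites.items())
        }
        d_contact = fx.d_contact
    else:
        traces = {}
        for state, path in sorted(config.inputs.items()):
            for residue, trace in lio.read_contact_table(path, dt=params["dt"]).items():
                traces[(state, residue)] = trace
        d_contact = params["d_contact"]
    profile = contact_frequency(traces, d_contact=d_contact)
    table = profile.matrix.reset_index(names="state")
    return {"accessibility": table}
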