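"""Packaged synthetic study fixtures and their loader.

Each fixture is a YAML config describing one of the three study systems:
``psh_titration`` (annular-lipid displacement), ``leut_cdl_sites``
(per-site residency kinetics) and ``murj_lipid2`` / ``murj_access``
(protected-substrate competition and state-dependent accessibility).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from ..competition import OccupancyModelParams
from ..kinetics import BindingSite
from ..species import DetergentSpecies, LipidSpecies, ProteinSpecies
from ..synthetic import SpectrumFixtureSpec


def fixture_names() -> list[str]:
    root = resources.files(__package__)
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_fixture_config(name: str) -> dict:
    """Raw fixture config as a dict; raises KeyError for unknown names."""
    root = resources.files(__package__)
    path = root / f"{name}.yaml"
    if not path.is_file():
        raise KeyError(f"unknown fixture {name!r}; available: {fixture_names()}")
    return yaml.safe_load(path.read_text())


@dataclass(frozen=True)
class TitrationFixture:
    name: str
    spec: SpectrumFixtureSpec
    detergent_concs: tuple[float, ...]
    charge_envelope_high: dict[int, float] | None


@dataclass(frozen=True)
class KineticsFixture:
    name: str
    sites: tuple[BindingSite, ...]
    n_events: dict[str, int]
    dt: float
    duration: float
    rattle_rate: float
    rattle_mean: float
    gap_tolerance: float
    d_on: float
    d_off: float
    n_boot: int
    seed: int


@dataclass(frozen=True)
class AccessibilityFixture:
    name: str
    sites: dict[tuple[str, str], BindingSite]  # (state, residue) -> rates
    dt: float
    duration: float
    d_contact: float
    seed: int


def load_fixture(name: str):
    cfg = load_fixture_config(name)
    kind = cfg.get("kind")
    if kind == "titration":
        return _titration_fixture(cfg)
    if kind == "kinetics":
        return _kinetics_fixture(cfg)
    if kind == "accessibility":
        return _accessibility_fixture(cfg)
    raise ValueError(f"fixture {name!r} has unknown kind {kind!r}")


def _titration_fixture(cfg: dict) -> TitrationFixture:
    protein = ProteinSpecies(
        name=cfg["protein"]["name"],
        average_mass=float(cfg["protein"]["average_mass"]),
        charge_states=tuple(cfg["protein"]["charge_states"]),
    )
    detergent = DetergentSpecies(
        name=cfg["detergent"]["name"],
        average_mass=float(cfg["detergent"]["average_mass"]),
        cmc=float(cfg["detergent"]["cmc"]),
    )
    lipids = []
    for entry in cfg["lipids"]:
        sp = entry["species"]
        lipid = LipidSpecies(
            name=sp["name"],
            lipid_class=sp["lipid_class"],
            formula=sp.get("formula"),
            average_mass=sp.get("average_mass"),
        )
        sites = tuple(
            OccupancyModelParams(
                K_L=float(s["K_L"]),
                K_D=float(s["K_D"]) if "K_D" in s else None,
                protected=bool(s.get("protected", False)),
            )
            for s in entry["sites"]
        )
        lipids.append((lipid, sites))
    spec = SpectrumFixtureSpec(
        protein=protein,
        lipids=tuple(lipids),
        detergent=detergent,
        detergent_conc=float(cfg["titration"]["detergent_concs"][0]),
        lipid_conc=float(cfg["lipid_conc"]),
        charge_envelope={int(z): float(w) for z, w in cfg["charge_envelope"].items()},
        peak_fwhm=float(cfg["peak_fwhm"]),
        noise_sd=float(cfg.get("noise_sd", 0.0)),
        mz_grid=tuple(cfg["mz_grid"]),
        seed=int(cfg["seed"]),
    )
    high = cfg.get("charge_envelope_high")
    if high is not None:
        high = {int(z): float(w) for z, w in high.items()}
    return TitrationFixture(
        name=cfg["name"],
        spec=spec,
        detergent_concs=tuple(float(d) for d in cfg["titration"]["detergent_concs"]),
        charge_envelope_high=high,
    )


def _kinetics_fixture(cfg: dict) -> KineticsFixture:
    sites = tuple(
        BindingSite(
            site_id=s["site_id"],
            label=s.get("label", ""),
            k_on=float(s["k_on"]),
            k_off_true=float(s["k_off_true"]),
        )
        for s in cfg["sites"]
    )
    n_events = {s["site_id"]: int(s["n_events"]) for s in cfg["sites"]}
    tr = cfg["trace"]
    return KineticsFixture(
        name=cfg["name"],
        sites=sites,
        n_events=n_events,
        dt=float(tr["dt"]),
        duration=float(tr["duration"]),
        rattle_rate=float(tr.get("rattle_rate", 0.0)),
        rattle_mean=float(tr.get("rattle_mean", 0.0)),
        gap_tolerance=float(cfg.get("gap_tolerance", 5.0)),
        d_on=float(cfg.get("d_on", 0.55)),
        d_off=float(cfg.get("d_off", 1.0)),
        n_boot=int(cfg.get("n_boot", 1000)),
        seed=int(cfg["seed"]),
    )


def _accessibility_fixture(cfg: dict) -> AccessibilityFixture:
    sites = {}
    for state, residues in cfg["states"].items():
        for residue, rates in residues.items():
            sites[(state, residue)] = BindingSite(
                site_id=f"{state}/{residue}",
                k_on=float(rates["k_on"]),
                k_off_true=float(rates["k_off"]),
            )
    tr = cfg["trace"]
    return AccessibilityFixture(
        name=cfg["name"],
        sites=sites,
        dt=float(tr["dt"]),
        duration=float(tr["duration"]),
        d_contact=float(cfg.get("d_contact", 0.55)),
        seed=int(cfg["seed"]),
    )
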