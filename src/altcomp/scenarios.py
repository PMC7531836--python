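"""Declarative in-silico experiments.

A :class:`ScenarioConfig` describes one experiment — context (closed
in-vitro sample vs open in-vivo system), serum fraction, cell type and
density, regulator knockouts, readout time, optional dosing — and the
runners build the appropriate submodel and integrate it:

* fluid-phase activation assays (no cells; reactions 1-36 only),
* hemolytic assays with rabbit/human/PNH erythrocytes (AP reactions only;
  the sample is closed, lysed cells are not removed),
* the in-vivo homeostatic model (all 226 reactions) for PNH biomarkers and
  eculizumab treatment.

Serum dilutions scale the initial concentration of every serum-derived
protein; regulator knockouts are total (complete blockage).  Suppression of
FH can be restricted to the surface (``FH_surface`` zeroes only the
FH-to-surface-C3b association) or complete (``FH_total``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from . import catalog
from .constants import AVOGADRO, SECONDS_PER_DAY
from .engine import CompiledNetwork, SolverOptions, Trajectory, simulate, \
    simulate_with_doses, steady_state
from .hemolysis import HemolysisModel, macs_per_cell, percent_hemolysis
from .network import ConfigurationError, ReactionNetwork, Tag, configure_surface, \
    subset_fluid_phase
from .pharmacology import DrugParams, Regimen, dose_to_concentration

#: regulator knockouts understood by scenario configs
KNOCKOUTS = {"FH_surface", "FH_total", "FI", "CR1", "DAF", "CD59", "Vn", "Cn", "P"}

#: species zeroed by each total knockout (initial level and, in vivo, synthesis)
_KNOCKOUT_SPECIES = {
    "FH_total": ("FH",),
    "FI": ("FI",),
    "CR1": ("CR1", "CR1f"),
    "DAF": ("DAF",),
    "CD59": ("CD59",),
    "Vn": ("Vn",),
    "Cn": ("Cn",),
    "P": ("P",),
}

FLUID_MARKERS = ["C3", "C3b", "iC3b", "C3a", "Ba", "Bb", "C3dg"]


@dataclass(frozen=True)
class ScenarioConfig:
    context: str = "in_vitro"              # in_vitro | in_vivo
    serum_fraction: float = 1.0
    cell_type: str = "none"                # none | rabbit | human | pnh2 | pnh3
    cell_concentration: float = 0.0        # cells L^-1 (in vitro)
    knockouts: frozenset = frozenset()
    readout_time: float = 1800.0           # s (in vitro) / days (in vivo)
    initial_overrides: dict = field(default_factory=dict)   # species -> M
    only_species: dict | None = None       # purified-protein assay: replace serum
    eculizumab: float = 0.0                # in-vitro drug concentration, M
    regimen: Regimen | None = None
    normalization: str = "water"           # water | NHS_control | none
    nhs_reference: float | None = None     # percent lysis of the NHS control
    pnh_clone_fraction: float = 1.0
    seed: int = 0
    solver: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self):
        if self.context not in ("in_vitro", "in_vivo"):
            raise ConfigurationError(f"unknown context {self.context!r}")
        if not 0.0 <= self.serum_fraction <= 1.0:
            raise ConfigurationError("serum_fraction must lie in [0, 1]")
        if self.context == "in_vivo" and self.serum_fraction != 1.0:
            raise ConfigurationError("in-vivo scenarios run at serum_fraction 1")
        unknown = set(self.knockouts) - KNOCKOUTS
        if unknown:
            raise ConfigurationError(f"unknown knockouts {sorted(unknown)}")
        if self.normalization not in ("water", "NHS_control", "none"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")


# ----------------------------------------------------------------------
# network assembly per scenario

def _apply_knockouts(net: ReactionNetwork, knockouts) -> tuple[ReactionNetwork, dict]:
    """Parameter and species-level changes realizing total knockouts."""
    param_overrides: dict[str, float] = {}
    species_zero: set[str] = set()
    for ko in knockouts:
        if ko == "FH_surface":
            param_overrides["kp_C3bH_surf"] = 0.0
            continue
        for sid in _KNOCKOUT_SPECIES[ko]:
            species_zero.add(sid)
            sname = f"s_{sid}"
            if sname in net.params:
                param_overrides[sname] = 0.0
    if param_overrides:
        net = ReactionNetwork(net.species, net.reactions,
                              net.params.with_values(param_overrides), net.volume)
    zero_overrides = {sid: 0.0 for sid in species_zero if net.has_species(sid)}
    return net, zero_overrides


def _invitro_submodel(net: ReactionNetwork, with_cells: bool,
                      with_drug: bool) -> ReactionNetwork:
    """Closed in-vitro system: AP reactions only (plus, optionally, the
    reversible drug-binding reaction; no synthesis, elimination or PK)."""
    tags = {Tag.AP_FLUID}
    if with_cells:
        tags.add(Tag.AP_SURFACE)
    reactions = [r for r in net.reactions if r.tag in tags]
    if with_drug:
        reactions += [r for r in net.reactions if r.id == 224]
    keep: set[str] = set()
    for r in reactions:
        keep.update(sid for sid, _ in (*r.reactants, *r.products))
        keep.update(r.modifiers)
        if r.enzyme:
            keep.add(r.enzyme)
    species = [s for s in net.species if s.id in keep]
    return ReactionNetwork(species, reactions, net.params, net.volume)


def _build_scenario_network(cfg: ScenarioConfig) -> tuple[ReactionNetwork, dict]:
    params = catalog.default_parameters(context=cfg.context)
    net = catalog.build_full_network(params)
    if cfg.cell_type != "none":
        net = configure_surface(net, cfg.cell_type,
                                cfg.cell_concentration or None)
    net, ko_overrides = _apply_knockouts(net, cfg.knockouts)
    return net, ko_overrides


# ----------------------------------------------------------------------
# runners

def run_fluid_phase_assay(cfg: ScenarioConfig, n_times: int = 120):
    """Fluid-phase activation assay: marker time courses (closed system).

    Returns a tidy DataFrame of the activation markers plus the trajectory.
    """
    if cfg.cell_type != "none":
        raise ConfigurationError("fluid-phase assay admits no cells")
    net, ko_overrides = _build_scenario_network(cfg)
    fluid = subset_fluid_phase(net)
    y0 = _initial_state(fluid, cfg, ko_overrides)
    t_grid = np.linspace(0.0, cfg.readout_time, n_times)
    traj = simulate(fluid, y0, t_grid, cfg.solver)
    markers = [m for m in FLUID_MARKERS if fluid.has_species(m)]
    return traj.to_frame(markers), traj


def _initial_state(net: ReactionNetwork, cfg: ScenarioConfig,
                   ko_overrides: dict) -> np.ndarray:
    overrides = dict(ko_overrides)
    if cfg.only_species is not None:
        # purified-protein experiment: serum proteins absent except as listed
        for s in net.species:
            if s.serum_scaled:
                overrides.setdefault(s.id, 0.0)
        overrides.update(cfg.only_species)
    overrides.update(cfg.initial_overrides)
    if cfg.eculizumab > 0 and net.has_species("Ecu"):
        overrides["Ecu"] = cfg.eculizumab
    return net.initial_state(context=cfg.context,
                             serum_fraction=cfg.serum_fraction,
                             overrides=overrides)


def run_hemolytic_assay(cfg: ScenarioConfig, return_trajectory: bool = False):
    """Percent hemolysis of an in-vitro assay at the readout time."""
    if cfg.cell_type == "none":
        raise ConfigurationError("hemolytic assay requires cells")
    if cfg.context != "in_vitro":
        raise ConfigurationError("hemolytic assay is an in-vitro scenario")
    if cfg.readout_time <= 0:
        raise ConfigurationError("readout time must be positive")
    net, ko_overrides = _build_scenario_network(cfg)
    sub = _invitro_submodel(net, with_cells=True, with_drug=cfg.eculizumab > 0)
    y0 = _initial_state(sub, cfg, ko_overrides)
    if cfg.serum_fraction == 0.0:
        raw = 0.0
        traj = None
    else:
        t_grid = np.linspace(0.0, cfg.readout_time, 40)
        traj = simulate(sub, y0, t_grid, cfg.solver)
        cell_conc = cfg.cell_concentration
        mac = max(traj.final("MAC"), 0.0)
        model = _hemolysis_model(net)
        raw = percent_hemolysis(macs_per_cell(mac, cell_conc), model)
    result = normalize_hemolysis(raw, cfg.nhs_reference, cfg.normalization)
    if return_trajectory:
        return result, traj
    return result


def _hemolysis_model(net: ReactionNetwork) -> HemolysisModel:
    p = net.params
    return HemolysisModel(gamma=p.value("gamma"), mac50=p.value("mac50"),
                          tau=p.value("tau"))


def normalize_hemolysis(raw: float, reference: float | None, mode: str) -> float:
    """Normalize percent lysis to water (identity) or to an NHS control."""
    if mode in ("water", "none"):
        return raw
    if mode == "NHS_control":
        if not reference:
            raise ConfigurationError("NHS normalization requires a positive reference")
        return 100.0 * raw / reference
    raise ConfigurationError(f"unknown normalization {mode!r}")


def run_knockout_grid(base_cfg: ScenarioConfig, regulators: list[str]):
    """Pairwise regulator-suppression grid (percent hemolysis).

    Returns a symmetric DataFrame whose diagonal holds the single
    knockouts.
    """
    import pandas as pd

    for reg in regulators:
        if reg not in KNOCKOUTS:
            raise ConfigurationError(f"unknown regulator {reg!r}")
    n = len(regulators)
    grid = np.zeros((n, n))
    cache: dict[frozenset, float] = {}
    for i, a in enumerate(regulators):
        for j_, b in enumerate(regulators[: i + 1]):
            kos = frozenset({a, b})
            if kos not in cache:
                cfg = dc_replace(base_cfg, knockouts=frozenset(base_cfg.knockouts | kos))
                cache[kos] = run_hemolytic_assay(cfg)
            grid[i, j_] = grid[j_, i] = cache[kos]
    return pd.DataFrame(grid, index=regulators, columns=regulators)


def _invivo_solver(cfg: ScenarioConfig) -> SolverOptions:
    """In-vivo runs resolve MAC densities of 1e-6..1e-3 pores/cell; the
    absolute tolerance must sit well below that scale."""
    if cfg.solver == SolverOptions():
        return SolverOptions(atol=1e-22)
    return cfg.solver


def run_pnh_steady_state(pnh_type: int | None, cfg: ScenarioConfig | None = None,
                         horizon_days: float = 600.0) -> dict:
    """In-vivo steady state with full turnover; returns the biomarker panel.

    ``pnh_type`` 2 or 3 selects the PNH erythrocyte phenotype; ``None``
    gives the healthy reference.
    """
    cell_type = {None: "human", 2: "pnh2", 3: "pnh3"}.get(pnh_type)
    if cell_type is None:
        raise ConfigurationError(f"unknown PNH type {pnh_type!r}")
    cfg = cfg or ScenarioConfig(context="in_vivo", cell_type=cell_type)
    if cfg.context != "in_vivo":
        raise ConfigurationError("PNH steady state is an in-vivo scenario")
    cfg = dc_replace(cfg, cell_type=cell_type)
    net, ko_overrides = _build_scenario_network(cfg)
    y0 = _disease_initial_state(net, cfg)
    y = steady_state(net, _invivo_solver(cfg), init=y0,
                     horizon_s=horizon_days * SECONDS_PER_DAY)
    return _invivo_panel(net, y)


_HEALTHY_SS_CACHE: dict = {}


def healthy_steady_state(solver: SolverOptions | None = None):
    """Cached homeostatic state of the healthy in-vivo model."""
    key = "healthy"
    if key not in _HEALTHY_SS_CACHE:
        cfg = ScenarioConfig(context="in_vivo", cell_type="human",
                             solver=solver or SolverOptions(atol=1e-22))
        net, _ = _build_scenario_network(cfg)
        y = steady_state(net, cfg.solver)
        _HEALTHY_SS_CACHE[key] = (net, y)
    return _HEALTHY_SS_CACHE[key]


def _disease_initial_state(net: ReactionNetwork, cfg: ScenarioConfig) -> np.ndarray:
    """In-vivo initial condition: the healthy homeostatic state with the
    membrane-regulator pools switched to the configured (diseased) levels.
    Starting from homeostasis avoids the artificial activation burst of a
    cold start where every intermediate is zero."""
    _, y_healthy = healthy_steady_state(_invivo_solver(cfg))
    y0 = y_healthy.copy()
    for sid in ("CD59", "DAF", "CR1"):
        y0[net.species_index(sid)] = net.species_def(sid).invivo_concentration
    for sid, v in cfg.initial_overrides.items():
        y0[net.species_index(sid)] = v
    return y0


def _invivo_panel(net: ReactionNetwork, y: np.ndarray) -> dict:
    from .biomarkers import panel

    cells_per_ul = y[net.species_index("E")] * AVOGADRO / 1e6  # cells/L -> cells/uL
    out = panel(cells_per_ul)
    cell_m = y[net.species_index("E")]
    mac_m = y[net.species_index("MAC")]
    mac_per_cell = mac_m / cell_m if cell_m > 0 else 0.0
    out["mac_per_cell"] = mac_per_cell
    out["hemolysis_pct"] = percent_hemolysis(mac_per_cell, _hemolysis_model(net))
    out["free_C5_molar"] = float(y[net.species_index("C5")])
    return out


def run_treatment(cfg: ScenarioConfig, months: float = 36.0,
                  n_times: int = 160, drug: DrugParams = DrugParams()):
    """Eculizumab treatment of a PNH patient: biomarker time course.

    Starts from the untreated diseased steady state, then applies the
    regimen as instantaneous intravenous boluses.  Returns a DataFrame
    (time_days, hemoglobin, hematocrit, LDH, cells, free C5, drug).
    """
    import pandas as pd

    if cfg.context != "in_vivo":
        raise ConfigurationError("treatment is an in-vivo scenario")
    if cfg.regimen is None or not cfg.regimen.doses:
        raise ConfigurationError("treatment requires a non-empty regimen")
    net, ko_overrides = _build_scenario_network(cfg)
    solver = _invivo_solver(cfg)
    y0 = steady_state(net, solver, init=_disease_initial_state(net, cfg))
    horizon = months * 30.4375 * SECONDS_PER_DAY
    t_grid = np.unique(np.concatenate(
        [np.linspace(0.0, horizon, n_times),
         [t * SECONDS_PER_DAY for t, _, _ in cfg.regimen.doses if
          t * SECONDS_PER_DAY <= horizon]]))
    doses = [(t * SECONDS_PER_DAY, "Ecu", dose_to_concentration(mg, drug))
             for t, mg, _ in cfg.regimen.doses if t * SECONDS_PER_DAY <= horizon]
    traj = simulate_with_doses(net, y0, t_grid, doses, solver)
    from .biomarkers import hematocrit, hemoglobin, ldh

    cells_ul = traj.conc("E") * AVOGADRO / 1e6  # cells/L -> cells/uL
    hb = np.array([hemoglobin(c) for c in cells_ul])
    frame = pd.DataFrame({
        "time_days": traj.times / SECONDS_PER_DAY,
        "cells_per_ul": cells_ul,
        "hemoglobin_g_dl": hb,
        "hematocrit_pct": [hematocrit(c) for c in cells_ul],
        "ldh_u_l": ldh(hb),
        "free_C5_molar": traj.conc("C5"),
        "eculizumab_molar": traj.conc("Ecu"),
    })
    return frame, traj


# ----------------------------------------------------------------------
# canonical assay conditions (reconstructed per simulated figure panel)

def standard_rabbit_assay(serum_fraction: float = 0.20,
                          cells_per_l: float = 1.0e11,
                          readout_s: float = 1800.0, **kw) -> ScenarioConfig:
    """The standard rabbit-erythrocyte hemolytic setup: 20% serum,
    1e11 cells/L, 30-minute readout."""
    return ScenarioConfig(context="in_vitro", serum_fraction=serum_fraction,
                          cell_type="rabbit", cell_concentration=cells_per_l,
                          readout_time=readout_s, **kw)


def human_regulation_assay(serum_fraction: float = 0.25,
                           cells_per_l: float = 1.0e11,
                           readout_s: float = 1800.0, **kw) -> ScenarioConfig:
    """Human-erythrocyte assay with intact regulation; knockouts are added
    per experiment.  Readout 30 minutes."""
    return ScenarioConfig(context="in_vitro", serum_fraction=serum_fraction,
                          cell_type="human", cell_concentration=cells_per_l,
                          readout_time=readout_s, **kw)


def pnh_inhibition_assay(eculizumab_molar: float,
                         serum_fraction: float = 0.86,
                         cells_per_l: float = 1.0e11,
                         readout_s: float = 1800.0, **kw) -> ScenarioConfig:
    """Acidified-serum lysis of PNH type-2 erythrocytes under eculizumab.

    Acidified serum activates the pathway; the assay runs at high serum
    fraction, and activation is represented by the in-vitro
    parameterization itself."""
    return ScenarioConfig(context="in_vitro", serum_fraction=serum_fraction,
                          cell_type="pnh2", cell_concentration=cells_per_l,
                          readout_time=readout_s, eculizumab=eculizumab_molar,
                          **kw)
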