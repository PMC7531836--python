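"""Configuration loading, result serialization and SBML Level-3 export.

Scenario documents are YAML/JSON mappings of :class:`ScenarioConfig`
fields.  Networks export to SBML Level 3 Version 2 (species, reactions
with kinetic-law parameters, compartment); the importer restores counts
and numeric rate-constant values bit-for-bit so round-trips are lossless
for everything the simulator consumes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml
from lxml import etree

from . import __version__
from .engine import SolverOptions, Trajectory
from .network import (ConfigurationError, ParameterEntry, ParameterSet, Phase,
                      RateLaw, RateLawKind, Reaction, ReactionNetwork,
                      SpeciesDef, Tag)
from .pharmacology import Regimen
from .scenarios import KNOCKOUTS, ScenarioConfig

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"


class IOError_(ValueError):
    pass


# ----------------------------------------------------------------------
# scenario documents

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(ScenarioConfig)}


def load_scenario(path) -> ScenarioConfig:
    """Load and validate a YAML/JSON scenario document."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigurationError("scenario document must be a mapping")
    return scenario_from_dict(doc)


def scenario_from_dict(doc: dict) -> ScenarioConfig:
    unknown = set(doc) - _CONFIG_FIELDS
    if unknown:
        raise ConfigurationError(f"unknown scenario fields {sorted(unknown)}")
    kw = dict(doc)
    if "knockouts" in kw:
        kos = set(kw["knockouts"] or ())
        bad = kos - KNOCKOUTS
        if bad:
            raise ConfigurationError(f"unknown knockouts {sorted(bad)}")
        kw["knockouts"] = frozenset(kos)
    if "regimen" in kw and kw["regimen"] is not None:
        reg = kw["regimen"]
        if reg == "clinical_default":
            kw["regimen"] = Regimen.clinical_default()
        else:
            kw["regimen"] = Regimen(tuple((float(t), float(d), str(r))
                                          for t, d, r in reg))
    if "solver" in kw and isinstance(kw["solver"], dict):
        kw["solver"] = SolverOptions(**kw["solver"])
    return ScenarioConfig(**kw)


def scenario_to_dict(cfg: ScenarioConfig) -> dict:
    doc = dataclasses.asdict(cfg)
    doc["knockouts"] = sorted(cfg.knockouts)
    if cfg.regimen is not None:
        doc["regimen"] = [list(d) for d in cfg.regimen.doses]
    return doc


def save_scenario(cfg: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(cfg),
                                         sort_keys=False))


# ----------------------------------------------------------------------
# trajectory / table output

def write_trajectory(traj: Trajectory, path, species=None,
                     time_unit: str = "s") -> None:
    """Tidy CSV (time, species, concentration) with a unit header line."""
    frame = traj.to_frame(species, time_unit=time_unit)
    with open(path, "w") as fh:
        fh.write(f"# time_unit: {time_unit}; concentration_unit: M\n")
        frame.to_csv(fh, index=False)


def write_run_record(path, cfg: ScenarioConfig, net: ReactionNetwork,
                     outputs: list[str]) -> None:
    """Reproducibility record: config snapshot, parameter digest, outputs."""
    digest = {e.name: {"value": net.params.value(e.name),
                       "provenance": e.provenance} for e in net.params}
    record = {
        "software_version": __version__,
        "scenario": scenario_to_dict(cfg),
        "parameter_digest": digest,
        "outputs": outputs,
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str))


# ----------------------------------------------------------------------
# SBML Level 3

_KIND_TO_SBML = {k: k.value for k in RateLawKind}


def export_sbml(net: ReactionNetwork, path=None) -> bytes:
    """Serialize a network to an SBML Level 3 document.

    Rate laws are written as parameterized kinetic laws with the rate-law
    kind annotated; numeric parameter values are carried in full repr
    precision so a re-import restores them bit-for-bit.
    """
    root = etree.Element("sbml", nsmap={None: SBML_NS})
    root.set("level", "3")
    root.set("version", "2")
    model = etree.SubElement(root, "model")
    model.set("id", "alternative_complement_pathway")

    comps = etree.SubElement(model, "listOfCompartments")
    comp = etree.SubElement(comps, "compartment")
    comp.set("id", "plasma")
    comp.set("size", repr(net.volume))
    comp.set("constant", "true")

    sp_list = etree.SubElement(model, "listOfSpecies")
    for s in net.species:
        el = etree.SubElement(sp_list, "species")
        el.set("id", s.id)
        el.set("compartment", "plasma")
        el.set("initialConcentration", repr(s.initial_concentration))
        el.set("hasOnlySubstanceUnits", "false")
        el.set("boundaryCondition", "false")
        el.set("constant", "false")
        el.set("metaid", f"phase_{s.phase.value}")
        # package-specific attributes kept in a dedicated namespace-free
        # annotation block
        ann = etree.SubElement(el, "annotation")
        x = etree.SubElement(ann, "altcompSpecies")
        x.set("invivo", repr(s.invivo_concentration))
        x.set("mw", "" if s.molecular_weight is None else repr(s.molecular_weight))
        x.set("serum_scaled", str(int(s.serum_scaled)))
        x.set("surface_bound", str(int(s.surface_bound)))
        x.set("c3_moiety", str(s.c3_moiety))

    par_list = etree.SubElement(model, "listOfParameters")
    for e in net.params:
        el = etree.SubElement(par_list, "parameter")
        el.set("id", e.name)
        el.set("value", repr(e.value))
        el.set("constant", "true")
        el.set("units", "dimensionless")
        ann = etree.SubElement(el, "annotation")
        x = etree.SubElement(ann, "altcompParameter")
        x.set("units_text", e.units)
        x.set("category", e.category)
        x.set("provenance", e.provenance)

    rx_list = etree.SubElement(model, "listOfReactions")
    for r in net.reactions:
        el = etree.SubElement(rx_list, "reaction")
        el.set("id", f"r{r.id}")
        el.set("reversible",
               str(r.rate_law.kind == RateLawKind.REVERSIBLE_MASS_ACTION).lower())
        if r.reactants:
            lst = etree.SubElement(el, "listOfReactants")
            for sid, nu in r.reactants:
                ref = etree.SubElement(lst, "speciesReference")
                ref.set("species", sid)
                ref.set("stoichiometry", str(nu))
                ref.set("constant", "true")
        if r.products:
            lst = etree.SubElement(el, "listOfProducts")
            for sid, nu in r.products:
                ref = etree.SubElement(lst, "speciesReference")
                ref.set("species", sid)
                ref.set("stoichiometry", str(nu))
                ref.set("constant", "true")
        mods = [*( (r.enzyme,) if r.enzyme else () ), *r.modifiers]
        if mods:
            lst = etree.SubElement(el, "listOfModifiers")
            for sid in mods:
                ref = etree.SubElement(lst, "modifierSpeciesReference")
                ref.set("species", sid)
        kl = etree.SubElement(el, "kineticLaw")
        ann = etree.SubElement(kl, "annotation")
        x = etree.SubElement(ann, "altcompRateLaw")
        x.set("kind", r.rate_law.kind.value)
        x.set("tag", r.tag.value)
        x.set("rate_scale", repr(r.rate_scale))
        x.set("enzyme", r.enzyme or "")
        x.set("modifiers", ",".join(r.modifiers))
        x.set("params", json.dumps(dict(r.rate_law.params)))

    data = etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")
    if path is not None:
        Path(path).write_bytes(data)
    return data


def import_sbml(source) -> ReactionNetwork:
    """Rebuild a :class:`ReactionNetwork` from an exported document."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        tree = etree.parse(str(source))
        root = tree.getroot()
    else:
        root = etree.fromstring(source)
    ns = {"s": SBML_NS}
    model = root.find("s:model", ns)
    if model is None:
        raise IOError_("not an SBML document")
    volume = float(model.find("s:listOfCompartments/s:compartment", ns)
                   .get("size"))

    species = []
    for el in model.findall("s:listOfSpecies/s:species", ns):
        x = el.find("s:annotation/s:altcompSpecies", ns)
        mw = x.get("mw")
        species.append(SpeciesDef(
            id=el.get("id"),
            phase=Phase(el.get("metaid").removeprefix("phase_")),
            initial_concentration=float(el.get("initialConcentration")),
            invivo_concentration=float(x.get("invivo")),
            molecular_weight=None if mw == "" else float(mw),
            serum_scaled=bool(int(x.get("serum_scaled"))),
            surface_bound=bool(int(x.get("surface_bound"))),
            c3_moiety=int(x.get("c3_moiety"))))

    entries = []
    for el in model.findall("s:listOfParameters/s:parameter", ns):
        x = el.find("s:annotation/s:altcompParameter", ns)
        entries.append(ParameterEntry(
            name=el.get("id"), value=float(el.get("value")),
            units=x.get("units_text"), category=x.get("category"),
            provenance=x.get("provenance")))
    params = ParameterSet(entries)

    reactions = []
    for el in model.findall("s:listOfReactions/s:reaction", ns):
        x = el.find("s:kineticLaw/s:annotation/s:altcompRateLaw", ns)
        reactants = tuple(
            (ref.get("species"), int(float(ref.get("stoichiometry"))))
            for ref in el.findall("s:listOfReactants/s:speciesReference", ns))
        products = tuple(
            (ref.get("species"), int(float(ref.get("stoichiometry"))))
            for ref in el.findall("s:listOfProducts/s:speciesReference", ns))
        modifiers = tuple(m for m in x.get("modifiers").split(",") if m)
        reactions.append(Reaction(
            id=int(el.get("id")[1:]), tag=Tag(x.get("tag")),
            reactants=reactants, products=products,
            rate_law=RateLaw(RateLawKind(x.get("kind")),
                             json.loads(x.get("params"))),
            enzyme=x.get("enzyme") or None, modifiers=modifiers,
            rate_scale=float(x.get("rate_scale"))))

    net = ReactionNetwork(species, reactions, params, volume)
    net.validate()
    return net
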