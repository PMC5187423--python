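"""Network, flux-dataset, strain-design and parameterization I/O.

Tabular dialect (UTF-8 CSV), one model per directory:

``metabolites.csv``
    ``id,name,compartment,cofactor,boundary,conc_lo,conc_hi``
``reactions.csv``
    ``id,stoichiometry,reversible,enzymes,subsystem,exchange,lb,ub`` where
    ``stoichiometry`` is ``"met:coeff;met:coeff"`` (negative = consumed) and
    ``enzymes`` is a ``|``-separated isozyme list.
``regulations.csv``
    ``regulator,target,mode`` with mode one of ``competitive-inhibition``,
    ``uncompetitive-inhibition``, ``mixed-inhibition``, ``activation``.
``network.json``
    ``{"schema": 1, "biomass": <rxn id>, "uptake": <rxn id>,
    "uptake_basis": 100.0}``

Flux datasets are a single CSV with columns
``strain,condition,genotype,uptake_reaction,reaction,mean,sd`` (``sd`` may be
blank; see :func:`read_flux_datasets` for the wild-type CV reuse rule).
Strain designs use
``design,condition,interventions,product_metabolite,product_reaction,y_exp``.

All fluxes are stored internally on the "uptake = 100" basis.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from . import config

REGULATION_MODES = (
    "competitive-inhibition",
    "uncompetitive-inhibition",
    "mixed-inhibition",
    "activation",
)

SCHEMA_VERSION = 1


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """A record violates a structural invariant."""


class DanglingReferenceError(ValidationError):
    """A record references an id that does not exist in the network."""

    def __init__(self, kind: str, offending_id: str, context: str = ""):
        self.kind = kind
        self.offending_id = offending_id
        msg = f"dangling {kind} reference: {offending_id!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class SchemaVersionError(ParseError):
    """File schema version does not match this package."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    cofactor: bool = False
    boundary: bool = False
    #: reference (wild-type) concentration range in mM, if known
    conc_range: tuple[float, float] | None = None


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    enzymes: list[str] = field(default_factory=list)
    subsystem: str = ""
    exchange: bool = False
    lb: float | None = None
    ub: float | None = None

    @property
    def reactants(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    def default_bounds(self) -> tuple[float, float]:
        lb = self.lb if self.lb is not None else (
            -config.FLUX_BOUND if self.reversible else 0.0)
        ub = self.ub if self.ub is not None else config.FLUX_BOUND
        return lb, ub


@dataclass
class Regulation:
    regulator: str
    target: str
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in REGULATION_MODES:
            raise ValidationError(f"unknown regulation mode {self.mode!r}")


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    regulations: list[Regulation] = field(default_factory=list)
    biomass_id: str | None = None
    uptake_id: str | None = None
    uptake_basis: float = config.UPTAKE_BASIS

    def __post_init__(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    # -- lookups ------------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        try:
            return self._met_index[mid]
        except KeyError:
            raise DanglingReferenceError("metabolite", mid) from None

    def reaction(self, rid: str) -> Reaction:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise DanglingReferenceError("reaction", rid) from None

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    @property
    def enzyme_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            for e in r.enzymes:
                seen.setdefault(e)
        return list(seen)

    def reactions_of_enzyme(self, enzyme: str) -> list[Reaction]:
        return [r for r in self.reactions if enzyme in r.enzymes]

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.boundary]

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        ids = [m.id for m in self.metabolites]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate metabolite ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise ValidationError(f"duplicate reaction ids: {dup}")
        for r in self.reactions:
            for mid in r.stoichiometry:
                if mid not in self._met_index:
                    raise DanglingReferenceError(
                        "metabolite", mid, f"reaction {r.id}")
            if not r.exchange:
                if not r.reactants or not r.products:
                    raise ValidationError(
                        f"non-exchange reaction {r.id} must have >=1 "
                        f"reactant and >=1 product")
            if r.enzymes is not None and any(not e for e in r.enzymes):
                raise ValidationError(f"empty isozyme id on reaction {r.id}")
        for reg in self.regulations:
            if reg.target not in self._rxn_index:
                raise DanglingReferenceError("reaction", reg.target,
                                             "regulation target")
            if reg.regulator not in self._met_index:
                raise DanglingReferenceError("metabolite", reg.regulator,
                                             "regulation regulator")
        if self.biomass_id is not None and \
                self.biomass_id not in self._rxn_index:
            raise DanglingReferenceError("reaction", self.biomass_id,
                                         "biomass designation")
        if self.uptake_id is not None and \
                self.uptake_id not in self._rxn_index:
            raise DanglingReferenceError("reaction", self.uptake_id,
                                         "uptake designation")


# ---------------------------------------------------------------------------
# genotype / conditions / flux datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Condition:
    substrate: str = "glucose"
    aerobic: bool = True

    def __str__(self) -> str:
        return f"{'aerobic' if self.aerobic else 'anaerobic'}:{self.substrate}"

    @classmethod
    def parse(cls, text: str) -> "Condition":
        text = text.strip()
        if not text:
            return cls()
        parts = text.split(":")
        if len(parts) != 2 or parts[0] not in ("aerobic", "anaerobic"):
            raise ParseError(f"bad condition {text!r}")
        return cls(substrate=parts[1], aerobic=parts[0] == "aerobic")


@dataclass(frozen=True)
class Genotype:
    """Deleted enzymes, isozyme deletions and per-enzyme level bounds."""

    knockouts: tuple[str, ...] = ()
    isozyme_deletions: tuple[str, ...] = ()
    level_bounds: tuple[tuple[str, float, float], ...] = ()

    @property
    def is_wildtype(self) -> bool:
        return not (self.knockouts or self.isozyme_deletions
                    or self.level_bounds)

    def __str__(self) -> str:
        parts = [f"ko:{e}" for e in self.knockouts]
        parts += [f"iso:{e}" for e in self.isozyme_deletions]
        parts += [f"level:{e}={lo:g}..{hi:g}"
                  for e, lo, hi in self.level_bounds]
        return ";".join(parts)

    @classmethod
    def parse(cls, text: str) -> "Genotype":
        text = text.strip()
        if not text:
            return cls()
        kos: list[str] = []
        isos: list[str] = []
        levels: list[tuple[str, float, float]] = []
        for token in text.split(";"):
            token = token.strip()
            if not token:
                continue
            kind, _, rest = token.partition(":")
            if kind == "ko":
                kos.append(rest)
            elif kind == "iso":
                isos.append(rest)
            elif kind == "level":
                name, _, rng = rest.partition("=")
                lo_s, _, hi_s = rng.partition("..")
                try:
                    levels.append((name, float(lo_s), float(hi_s)))
                except ValueError:
                    raise ParseError(f"bad level token {token!r}") from None
            else:
                raise ParseError(f"bad genotype token {token!r}")
        return cls(tuple(kos), tuple(isos), tuple(levels))


@dataclass
class FluxMeasurement:
    mean: float
    sd: float | None
    cv: float

    def interval(self) -> tuple[float, float]:
        """1-s.d. range around the mean."""
        sd = self.sd if self.sd is not None else self.cv * abs(self.mean)
        return (self.mean - sd, self.mean + sd)


@dataclass
class FluxDataset:
    strain: str
    genotype: Genotype
    condition: Condition
    measurements: dict[str, FluxMeasurement]
    uptake_reaction: str
    basis: float = config.UPTAKE_BASIS
    lethal: bool = False

    def validate(self) -> None:
        for rid, m in self.measurements.items():
            if not (m.cv > 0):
                raise ValidationError(
                    f"nonpositive CV for reaction {rid} in strain "
                    f"{self.strain}")
            if m.sd is not None and m.mean != 0:
                if abs(m.cv - abs(m.sd / m.mean)) > 1e-6:
                    raise ValidationError(
                        f"CV inconsistent with s.d./|mean| for {rid} in "
                        f"strain {self.strain}")


# ---------------------------------------------------------------------------
# strain designs
# ---------------------------------------------------------------------------

INTERVENTION_KINDS = ("knockout", "upregulate", "downregulate")
_INT_SHORT = {"ko": "knockout", "up": "upregulate", "down": "downregulate"}
_INT_LONG = {v: k for k, v in _INT_SHORT.items()}


@dataclass
class StrainDesign:
    design_id: str
    interventions: dict[str, str]  # enzyme id -> intervention kind
    condition: Condition
    product_metabolite: str
    product_reaction: str
    y_exp: float

    def validate(self, network: MetabolicNetwork | None = None) -> None:
        if self.y_exp < 0:
            raise ValidationError(
                f"design {self.design_id}: measured yield must be >= 0")
        for enz, kind in self.interventions.items():
            if kind not in INTERVENTION_KINDS:
                raise ValidationError(
                    f"design {self.design_id}: unknown intervention {kind!r}")
            if network is not None and not network.reactions_of_enzyme(enz):
                raise DanglingReferenceError(
                    "enzyme", enz, f"design {self.design_id}")
        if network is not None and \
                not network.has_reaction(self.product_reaction):
            raise DanglingReferenceError(
                "reaction", self.product_reaction,
                f"design {self.design_id}")


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------


def _fmt_stoich(stoich: Mapping[str, float]) -> str:
    return ";".join(f"{m}:{c:g}" for m, c in stoich.items())


def _parse_stoich(text: str, context: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        met, sep, coeff = token.rpartition(":")
        if not sep:
            raise ParseError(f"bad stoichiometry token {token!r} in {context}")
        try:
            out[met] = float(coeff)
        except ValueError:
            raise ParseError(
                f"bad stoichiometry coefficient {coeff!r} in {context}"
            ) from None
    return out


def _bool(text: str) -> bool:
    return text.strip().lower() in ("1", "true", "yes", "y")


def write_network(network: MetabolicNetwork, path: str) -> None:
    """Write a network to the tabular-dialect model directory at *path*."""
    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, "metabolites.csv"), "w", newline="",
              encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "name", "compartment", "cofactor", "boundary",
                    "conc_lo", "conc_hi"])
        for m in network.metabolites:
            lo, hi = ("", "") if m.conc_range is None else \
                (repr(m.conc_range[0]), repr(m.conc_range[1]))
            w.writerow([m.id, m.name, m.compartment, int(m.cofactor),
                        int(m.boundary), lo, hi])
    with open(os.path.join(path, "reactions.csv"), "w", newline="",
              encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "stoichiometry", "reversible", "enzymes",
                    "subsystem", "exchange", "lb", "ub"])
        for r in network.reactions:
            w.writerow([r.id, _fmt_stoich(r.stoichiometry), int(r.reversible),
                        "|".join(r.enzymes), r.subsystem, int(r.exchange),
                        "" if r.lb is None else repr(r.lb),
                        "" if r.ub is None else repr(r.ub)])
    with open(os.path.join(path, "regulations.csv"), "w", newline="",
              encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["regulator", "target", "mode"])
        for reg in network.regulations:
            w.writerow([reg.regulator, reg.target, reg.mode])
    with open(os.path.join(path, "network.json"), "w",
              encoding="utf-8") as fh:
        json.dump({"schema": SCHEMA_VERSION,
                   "biomass": network.biomass_id,
                   "uptake": network.uptake_id,
                   "uptake_basis": network.uptake_basis}, fh, indent=1)


def read_network(path: str, format: str = "tabular") -> MetabolicNetwork:
    """Read and validate a network definition.

    Parameters
    ----------
    path:
        Model directory (tabular dialect) or SBML file.
    format:
        ``"tabular"`` (default) or ``"sbml"`` (stoichiometry only; enzyme and
        regulation assignments are read from sidecar CSVs if present next to
        the file).
    """
    if format == "sbml":
        net = _read_sbml(path)
    elif format == "tabular":
        net = _read_tabular(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    net.validate()
    return net


def _read_tabular(path: str) -> MetabolicNetwork:
    def _open(name: str):
        full = os.path.join(path, name)
        if not os.path.exists(full):
            raise ParseError(f"missing model file {full}")
        return open(full, newline="", encoding="utf-8")

    metabolites = []
    with _open("metabolites.csv") as fh:
        for row in csv.DictReader(fh):
            rng = None
            if row.get("conc_lo", "") not in ("", None):
                rng = (float(row["conc_lo"]), float(row["conc_hi"]))
            metabolites.append(Metabolite(
                id=row["id"], name=row.get("name", ""),
                compartment=row.get("compartment", "c"),
                cofactor=_bool(row.get("cofactor", "0")),
                boundary=_bool(row.get("boundary", "0")),
                conc_range=rng))
    reactions = []
    with _open("reactions.csv") as fh:
        for row in csv.DictReader(fh):
            enz = [e for e in row.get("enzymes", "").split("|") if e]
            reactions.append(Reaction(
                id=row["id"],
                stoichiometry=_parse_stoich(row["stoichiometry"],
                                            f"reaction {row['id']}"),
                reversible=_bool(row.get("reversible", "0")),
                enzymes=enz, subsystem=row.get("subsystem", ""),
                exchange=_bool(row.get("exchange", "0")),
                lb=float(row["lb"]) if row.get("lb") else None,
                ub=float(row["ub"]) if row.get("ub") else None))
    regulations = []
    reg_path = os.path.join(path, "regulations.csv")
    if os.path.exists(reg_path):
        with open(reg_path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                regulations.append(Regulation(
                    regulator=row["regulator"], target=row["target"],
                    mode=row["mode"]))
    meta = {"schema": SCHEMA_VERSION, "biomass": None, "uptake": None,
            "uptake_basis": config.UPTAKE_BASIS}
    meta_path = os.path.join(path, "network.json")
    if os.path.exists(meta_path):
        with open(meta_path, encoding="utf-8") as fh:
            meta.update(json.load(fh))
    if meta.get("schema") != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"network schema {meta.get('schema')} != {SCHEMA_VERSION}")
    return MetabolicNetwork(
        metabolites=metabolites, reactions=reactions,
        regulations=regulations, biomass_id=meta["biomass"],
        uptake_id=meta["uptake"],
        uptake_basis=float(meta["uptake_basis"]))


def _read_sbml(path: str) -> MetabolicNetwork:
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover - env-dependent
        raise ParseError("python-libsbml is required for SBML input") from exc
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors() > 0 and \
            doc.getError(0).getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
        raise ParseError(f"SBML parse failure: {doc.getError(0).getMessage()}")
    model = doc.getModel()
    if model is None:
        raise ParseError("SBML file contains no model")
    metabolites = [
        Metabolite(id=s.getId(), name=s.getName() or "",
                   compartment=s.getCompartment() or "c",
                   boundary=bool(s.getBoundaryCondition()))
        for s in model.getListOfSpecies()]
    reactions = []
    for r in model.getListOfReactions():
        stoich: dict[str, float] = {}
        for sr in r.getListOfReactants():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) \
                - sr.getStoichiometry()
        for sr in r.getListOfProducts():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) \
                + sr.getStoichiometry()
        reactions.append(Reaction(
            id=r.getId(), stoichiometry=stoich,
            reversible=bool(r.getReversible()),
            exchange=len(stoich) <= 1 or not (
                any(c < 0 for c in stoich.values())
                and any(c > 0 for c in stoich.values()))))
    # enzymes/regulations via optional sidecar CSVs next to the SBML file
    base = os.path.splitext(path)[0]
    regulations = []
    if os.path.exists(base + ".regulations.csv"):
        with open(base + ".regulations.csv", newline="",
                  encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                regulations.append(Regulation(row["regulator"], row["target"],
                                              row["mode"]))
    if os.path.exists(base + ".enzymes.csv"):
        rxn_by_id = {r.id: r for r in reactions}
        with open(base + ".enzymes.csv", newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                rxn = rxn_by_id.get(row["reaction"])
                if rxn is None:
                    raise DanglingReferenceError("reaction", row["reaction"],
                                                 "enzyme sidecar")
                rxn.enzymes = [e for e in row["enzymes"].split("|") if e]
    return MetabolicNetwork(metabolites=metabolites, reactions=reactions,
                            regulations=regulations)


# ---------------------------------------------------------------------------
# flux dataset I/O
# ---------------------------------------------------------------------------

_FLUX_COLUMNS = ["strain", "condition", "genotype", "uptake_reaction",
                 "reaction", "mean", "sd"]


def write_flux_datasets(datasets: Sequence[FluxDataset], path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_FLUX_COLUMNS)
        for ds in datasets:
            for rid, m in ds.measurements.items():
                w.writerow([ds.strain, str(ds.condition), str(ds.genotype),
                            ds.uptake_reaction, rid, repr(m.mean),
                            "" if m.sd is None else repr(m.sd)])


def read_flux_datasets(path: str,
                       basis: float = config.UPTAKE_BASIS
                       ) -> list[FluxDataset]:
    """Load per-strain flux datasets from a CSV file.

    Fluxes are rescaled so the uptake reaction carries ``basis`` flux. Rows
    without an s.d. inherit the CV of the wild-type strain's row for the same
    reaction (the strain with an empty genotype, preferring one under the same
    condition). It is an error if no wild-type CV is available for a CV-less
    reaction.
    """
    rows: list[dict] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_FLUX_COLUMNS[:6]) - set(reader.fieldnames or [])
        if missing:
            raise ParseError(f"flux CSV missing columns: {sorted(missing)}")
        for row in reader:
            rows.append(row)
    # group rows by strain, preserving file order
    by_strain: dict[str, list[dict]] = {}
    for row in rows:
        by_strain.setdefault(row["strain"], []).append(row)

    # wild-type CV table: (condition, reaction) and reaction fallback
    wt_cv: dict[tuple[str, str], float] = {}
    wt_cv_any: dict[str, float] = {}
    for row in rows:
        if Genotype.parse(row.get("genotype", "")).is_wildtype and \
                row.get("sd"):
            mean = float(row["mean"])
            if mean != 0:
                cv = abs(float(row["sd"]) / mean)
                wt_cv.setdefault((row["condition"], row["reaction"]), cv)
                wt_cv_any.setdefault(row["reaction"], cv)

    datasets = []
    for strain, srows in by_strain.items():
        first = srows[0]
        condition = Condition.parse(first.get("condition", ""))
        genotype = Genotype.parse(first.get("genotype", ""))
        uptake = first["uptake_reaction"]
        raw = {}
        for row in srows:
            mean = float(row["mean"])
            sd = float(row["sd"]) if row.get("sd") else None
            raw[row["reaction"]] = (mean, sd)
        if uptake not in raw:
            raise ParseError(
                f"strain {strain}: uptake reaction {uptake} has no "
                f"measurement to rescale against")
        scale = basis / raw[uptake][0]
        measurements: dict[str, FluxMeasurement] = {}
        for rid, (mean, sd) in raw.items():
            mean_s = mean * scale
            sd_s = None if sd is None else sd * abs(scale)
            if sd_s is not None:
                if mean_s == 0:
                    raise ValidationError(
                        f"strain {strain}, reaction {rid}: zero mean with "
                        f"reported s.d. yields undefined CV")
                cv = abs(sd_s / mean_s)
            else:
                key = (str(condition), rid)
                cv = wt_cv.get(key, wt_cv_any.get(rid))
                if cv is None:
                    raise ValidationError(
                        f"strain {strain}, reaction {rid}: no s.d. and no "
                        f"wild-type CV available")
            if not cv > 0:
                raise ValidationError(
                    f"strain {strain}, reaction {rid}: nonpositive CV")
            measurements[rid] = FluxMeasurement(mean=mean_s, sd=sd_s, cv=cv)
        ds = FluxDataset(strain=strain, genotype=genotype,
                         condition=condition, measurements=measurements,
                         uptake_reaction=uptake, basis=basis)
        ds.validate()
        datasets.append(ds)
    return datasets


# ---------------------------------------------------------------------------
# strain design I/O
# ---------------------------------------------------------------------------

_DESIGN_COLUMNS = ["design", "condition", "interventions",
                   "product_metabolite", "product_reaction", "y_exp"]


def write_strain_designs(designs: Sequence[StrainDesign], path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_DESIGN_COLUMNS)
        for d in designs:
            inter = ";".join(f"{_INT_LONG[kind]}:{enz}"
                             for enz, kind in d.interventions.items())
            w.writerow([d.design_id, str(d.condition), inter,
                        d.product_metabolite, d.product_reaction,
                        repr(d.y_exp)])


def read_strain_designs(path: str,
                        network: MetabolicNetwork | None = None
                        ) -> list[StrainDesign]:
    designs = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_DESIGN_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ParseError(f"design CSV missing columns: {sorted(missing)}")
        for row in reader:
            interventions: dict[str, str] = {}
            for token in row["interventions"].split(";"):
                token = token.strip()
                if not token:
                    continue
                short, _, enz = token.partition(":")
                if short not in _INT_SHORT:
                    raise ParseError(f"bad intervention token {token!r}")
                interventions[enz] = _INT_SHORT[short]
            d = StrainDesign(
                design_id=row["design"],
                interventions=interventions,
                condition=Condition.parse(row["condition"]),
                product_metabolite=row["product_metabolite"],
                product_reaction=row["product_reaction"],
                y_exp=float(row["y_exp"]))
            d.validate(network)
            designs.append(d)
    return designs


# ---------------------------------------------------------------------------
# parameterization I/O (JSON ensemble files)
# ---------------------------------------------------------------------------


def write_parameterization(params, path: str) -> None:
    """Write one Parameterization or a sequence of them to a JSON file."""
    from .kinetics import Parameterization  # local import: avoid cycle

    if isinstance(params, Parameterization):
        params = [params]
    payload = {"schema": SCHEMA_VERSION,
               "ensemble": [p.to_dict() for p in params]}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def read_parameterization(path: str) -> list:
    """Read an ensemble JSON file; returns a (possibly empty) list."""
    from .kinetics import Parameterization  # local import: avoid cycle

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("schema") != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"parameterization schema {payload.get('schema')} != "
            f"{SCHEMA_VERSION}")
    out = []
    for entry in payload.get("ensemble", []):
        p = Parameterization.from_dict(entry)
        p.validate()
        out.append(p)
    return out
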