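"""Stoichiometric network data model, standard-format I/O and matrix utilities.

A :class:`MetabolicModel` is an ordered collection of metabolites and
reactions with flux bounds (mmol/gDW/h), gene-protein-reaction (GPR) rules
and subsystem labels.  Reaction order is explicit and preserved: downstream
ensemble procedures permute it deliberately.

Conventions
-----------
* Metabolite ids are compartment-suffixed (``o2s_c``, ``h2o2_m``); the
  compartment code is the suffix after the last underscore.
* Exchange reactions are single-metabolite boundary reactions written as
  ``met ->``: positive flux is secretion, negative flux is uptake.
* The stoichiometric matrix ``S`` (metabolites x reactions) holds signed
  coefficients; its binarized form ``Sb`` replaces every non-zero entry by 1
  and feeds the metabolite-connectivity analysis.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "StoichiometricMatrix",
    "BinaryMatrix",
    "ModelValidationError",
    "build_stoichiometric_matrix",
    "binarize",
    "read_model",
    "write_model",
    "validate_mass_charge_balance",
    "parse_formula",
    "parse_gpr",
    "gpr_genes",
    "eval_gpr",
]

#: numerical zero for coefficient pruning / binarization (below LP precision)
ZERO_TOL = 1e-12

#: default cap on otherwise unbounded fluxes, mmol/gDW/h (COBRA convention)
DEFAULT_BOUND = 1000.0

_ID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class ModelValidationError(ValueError):
    """Raised when a model or model file violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.compartment and "_" in self.id:
            self.compartment = self.id.rsplit("_", 1)[1]


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    subsystem: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        self.stoichiometry = {
            m: float(c) for m, c in self.stoichiometry.items() if abs(c) > ZERO_TOL
        }
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")

    @property
    def is_exchange(self) -> bool:
        """Boundary reaction touching a single metabolite (``met ->``)."""
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=self.gpr,
            subsystem=self.subsystem,
            name=self.name,
        )


class MetabolicModel:
    """Ordered metabolite/reaction container with a single flux objective."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        objective_id: str | None = None,
        id: str = "model",
    ) -> None:
        self.id = id
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.objective_id = objective_id
        self._validate()

    # -- structural checks -------------------------------------------------

    def _validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dupes}")
        known = set(met_ids)
        for rxn in self.reactions:
            for mid in rxn.stoichiometry:
                if mid not in known:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references undeclared metabolite {mid!r}"
                    )
        if self.objective_id is not None and self.objective_id not in set(rxn_ids):
            raise ModelValidationError(
                f"objective_id {self.objective_id!r} does not resolve to a reaction"
            )
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- lookups -----------------------------------------------------------

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self._met_index[mid]]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions:
            out |= gpr_genes(rxn.gpr)
        return out

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[
                Metabolite(m.id, m.name, m.compartment, m.formula, m.charge)
                for m in self.metabolites
            ],
            reactions=[r.copy() for r in self.reactions],
            objective_id=self.objective_id,
            id=self.id,
        )

    def subset(self, reaction_ids: Iterable[str]) -> "MetabolicModel":
        """Submodel restricted to *reaction_ids* (order preserved), dropping
        metabolites no longer referenced."""
        keep = set(reaction_ids)
        rxns = [r.copy() for r in self.reactions if r.id in keep]
        used = set()
        for r in rxns:
            used |= set(r.stoichiometry)
        mets = [m for m in self.metabolites if m.id in used]
        obj = self.objective_id if self.objective_id in keep else None
        return MetabolicModel(mets, rxns, objective_id=obj, id=self.id)

    def reorder_reactions(self, order: Iterable[int]) -> "MetabolicModel":
        order = list(order)
        if sorted(order) != list(range(len(self.reactions))):
            raise ModelValidationError("reorder_reactions: not a permutation")
        m = self.copy()
        m.reactions = [m.reactions[i] for i in order]
        m._validate()
        return m

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, objective={self.objective_id!r}>"
        )


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


@dataclass
class StoichiometricMatrix:
    """Dense m x n matrix S with row/column identity."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ModelValidationError("StoichiometricMatrix: shape/id mismatch")


@dataclass
class BinaryMatrix:
    """m x n matrix over {0,1}; entry 1 iff the S entry is non-zero."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        vals = set(np.unique(self.values))
        if not vals <= {0.0, 1.0}:
            raise ModelValidationError("BinaryMatrix: entries must be 0/1")


def build_stoichiometric_matrix(model: MetabolicModel) -> StoichiometricMatrix:
    """S[i, j] = coefficient of metabolite i in reaction j (0 if absent)."""
    m, n = len(model.metabolites), len(model.reactions)
    S = np.zeros((m, n))
    midx = {mid: i for i, mid in enumerate(model.metabolite_ids)}
    for j, rxn in enumerate(model.reactions):
        for mid, coef in rxn.stoichiometry.items():
            S[midx[mid], j] = coef
    return StoichiometricMatrix(S, model.metabolite_ids, model.reaction_ids)


def binarize(S: StoichiometricMatrix | BinaryMatrix, tol: float = ZERO_TOL) -> BinaryMatrix:
    """Erase sign and magnitude: Sb[i, j] = 1 iff |S[i, j]| > *tol*."""
    return BinaryMatrix(
        (np.abs(S.values) > tol).astype(float), list(S.row_ids), list(S.col_ids)
    )


# ---------------------------------------------------------------------------
# GPR boolean expressions
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(gpr: str):
    """Parse a GPR string into a nested tuple tree.

    Grammar: ``expr := term (OR term)* ; term := factor (AND factor)* ;
    factor := gene | '(' expr ')'``.  Returns ``None`` for the empty rule,
    a gene id string for a leaf, or ``("or"|"and", [children])``.
    """
    tokens = _GPR_TOKEN.findall(gpr or "")
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def expect_factor():
        nonlocal pos
        tok = peek()
        if tok is None:
            raise ModelValidationError(f"malformed GPR {gpr!r}: unexpected end")
        if tok == "(":
            pos += 1
            node = expr()
            if peek() != ")":
                raise ModelValidationError(f"malformed GPR {gpr!r}: missing ')'")
            pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelValidationError(f"malformed GPR {gpr!r}: unexpected {tok!r}")
        pos += 1
        return tok

    def term():
        nonlocal pos
        parts = [expect_factor()]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            parts.append(expect_factor())
        return parts[0] if len(parts) == 1 else ("and", parts)

    def expr():
        nonlocal pos
        parts = [term()]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            parts.append(term())
        return parts[0] if len(parts) == 1 else ("or", parts)

    tree = expr()
    if pos != len(tokens):
        raise ModelValidationError(f"malformed GPR {gpr!r}: trailing tokens")
    return tree


def gpr_genes(gpr: str) -> set[str]:
    tree = parse_gpr(gpr)
    out: set[str] = set()

    def walk(node):
        if node is None:
            return
        if isinstance(node, str):
            out.add(node)
        else:
            for child in node[1]:
                walk(child)

    walk(tree)
    return out


def eval_gpr(gpr: str, presence: Mapping[str, bool], default: bool = False) -> bool | None:
    """Evaluate a GPR tree: OR = any operand, AND = all operands.

    Genes missing from *presence* evaluate to *default*.  Returns ``None``
    for an empty GPR (no gene evidence either way).
    """
    tree = parse_gpr(gpr)
    if tree is None:
        return None

    def walk(node) -> bool:
        if isinstance(node, str):
            return bool(presence.get(node, default))
        op, children = node
        if op == "and":
            return all(walk(c) for c in children)
        return any(walk(c) for c in children)

    return walk(tree)


# ---------------------------------------------------------------------------
# elemental formulas and balance checking
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """``'C6H12O6' -> {'C': 6, 'H': 12, 'O': 6}``."""
    if not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula or ""):
        raise ModelValidationError(f"cannot parse formula {formula!r}")
    counts: dict[str, int] = {}
    for elem, num in _FORMULA_RE.findall(formula):
        if elem:
            counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    return counts


def validate_mass_charge_balance(model: MetabolicModel) -> list[dict]:
    """Per-reaction elemental and charge residuals (report-only).

    Exchange/demand (single-metabolite) reactions are exempt.  Reactions
    whose metabolites lack formulas are reported as ``checked=False``.
    A reaction is balanced when every element residual and the charge
    residual are zero.
    """
    report = []
    for rxn in model.reactions:
        if rxn.is_exchange:
            continue
        mets = [model.metabolite(mid) for mid in rxn.stoichiometry]
        if any(m.formula is None for m in mets):
            report.append(
                {"reaction_id": rxn.id, "checked": False, "balanced": None,
                 "element_residuals": {}, "charge_residual": None}
            )
            continue
        residuals: dict[str, float] = {}
        charge = 0.0
        for mid, coef in rxn.stoichiometry.items():
            met = model.metabolite(mid)
            for elem, cnt in parse_formula(met.formula).items():
                residuals[elem] = residuals.get(elem, 0.0) + coef * cnt
            charge += coef * (met.charge or 0)
        residuals = {e: r for e, r in residuals.items() if abs(r) > 1e-9}
        balanced = not residuals and abs(charge) < 1e-9
        report.append(
            {"reaction_id": rxn.id, "checked": True, "balanced": balanced,
             "element_residuals": residuals, "charge_residual": charge}
        )
    return report


# ---------------------------------------------------------------------------
# JSON dialect (COBRA-style)
# ---------------------------------------------------------------------------


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula is not None else {}),
                **({"charge": m.charge} if m.charge is not None else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr,
                "subsystem": r.subsystem,
                "objective_coefficient": 1.0 if r.id == model.objective_id else 0.0,
            }
            for r in model.reactions
        ],
        "genes": [{"id": g, "name": g} for g in sorted(model.genes)],
        "compartments": {
            c: c for c in sorted({m.compartment for m in model.metabolites if m.compartment})
        },
        "version": "1",
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    mets = []
    for md in data.get("metabolites", []):
        mets.append(
            Metabolite(
                id=md["id"],
                name=md.get("name", ""),
                compartment=md.get("compartment", ""),
                formula=md.get("formula"),
                charge=md.get("charge"),
            )
        )
    known = {m.id for m in mets}
    rxns = []
    objective_id = None
    for rd in data.get("reactions", []):
        if "lower_bound" not in rd or "upper_bound" not in rd:
            raise ModelValidationError(
                f"reaction {rd.get('id')!r}: missing lower_bound/upper_bound"
            )
        for mid in rd.get("metabolites", {}):
            if mid not in known:
                raise ModelValidationError(
                    f"reaction {rd.get('id')!r} references undeclared metabolite {mid!r}"
                )
        rxns.append(
            Reaction(
                id=rd["id"],
                stoichiometry=dict(rd["metabolites"]),
                lower_bound=float(rd["lower_bound"]),
                upper_bound=float(rd["upper_bound"]),
                gpr=rd.get("gene_reaction_rule", ""),
                subsystem=rd.get("subsystem", ""),
                name=rd.get("name", ""),
            )
        )
        if rd.get("objective_coefficient", 0):
            objective_id = rd["id"]
    return MetabolicModel(mets, rxns, objective_id=objective_id, id=data.get("id", "model"))


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC (+ groups for subsystems)
# ---------------------------------------------------------------------------


def _sbml_check(value, message: str) -> None:
    import libsbml

    if value is None:
        raise ModelValidationError(f"SBML: {message}")
    if isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise ModelValidationError(f"SBML: {message} (code {value})")


def _require_sane_id(sid: str) -> str:
    if not _ID_RE.match(sid):
        raise ModelValidationError(
            f"id {sid!r} is not SBML-compatible ([A-Za-z_][A-Za-z0-9_]*)"
        )
    return sid


def _write_sbml(model: MetabolicModel, path: str) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    ns.addPackageNamespace("groups", 1)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    doc.setPackageRequired("groups", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_require_sane_id(model.id))
    fbc = sbml_model.getPlugin("fbc")
    fbc.setStrict(True)

    compartments = sorted({m.compartment or "c" for m in model.metabolites})
    for comp in compartments:
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for met in model.metabolites:
        s = sbml_model.createSpecies()
        s.setId("M_" + _require_sane_id(met.id))
        s.setName(met.name or met.id)
        s.setCompartment(met.compartment or "c")
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        splug = s.getPlugin("fbc")
        if met.charge is not None:
            splug.setCharge(int(met.charge))
        if met.formula is not None:
            splug.setChemicalFormula(met.formula)

    for gene in sorted(model.genes):
        gp = fbc.createGeneProduct()
        gp.setId("G_" + _require_sane_id(gene))
        gp.setLabel(gene)

    # one parameter per distinct bound value
    bound_params: dict[float, str] = {}

    def bound_id(value: float) -> str:
        if value not in bound_params:
            pid = f"bnd_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    def set_gpr(rplug, tree) -> None:
        gpa = rplug.createGeneProductAssociation()

        def build(node, parent):
            if isinstance(node, str):
                ref = parent.createGeneProductRef()
                ref.setGeneProduct("G_" + node)
                return
            op, children = node
            assoc = parent.createAnd() if op == "and" else parent.createOr()
            for child in children:
                build(child, assoc)

        if isinstance(tree, str):
            ref = gpa.createGeneProductRef()
            ref.setGeneProduct("G_" + tree)
        else:
            build(tree, gpa)

    for rxn in model.reactions:
        r = sbml_model.createReaction()
        r.setId("R_" + _require_sane_id(rxn.id))
        r.setName(rxn.name or rxn.id)
        r.setFast(False)
        r.setReversible(rxn.lower_bound < 0)
        for mid, coef in sorted(rxn.stoichiometry.items()):
            ref = r.createReactant() if coef < 0 else r.createProduct()
            ref.setSpecies("M_" + mid)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_id(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_id(rxn.upper_bound))
        tree = parse_gpr(rxn.gpr)
        if tree is not None:
            set_gpr(rplug, tree)

    if model.objective_id is not None:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + model.objective_id)
        fo.setCoefficient(1.0)
        fbc.setActiveObjectiveId("obj")

    gplug = sbml_model.getPlugin("groups")
    subsystems: dict[str, list[str]] = {}
    for rxn in model.reactions:
        if rxn.subsystem:
            subsystems.setdefault(rxn.subsystem, []).append(rxn.id)
    for i, (name, rids) in enumerate(sorted(subsystems.items())):
        grp = gplug.createGroup()
        grp.setId(f"group_{i}")
        grp.setName(name)
        grp.setKind("partonomy")
        for rid in rids:
            member = grp.createMember()
            member.setIdRef("R_" + rid)

    libsbml.writeSBMLToFile(doc, str(path))


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _read_sbml(path: str) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelValidationError(f"SBML parse error: {err.getMessage()}")
    sbml_model = doc.getModel()
    _sbml_check(sbml_model, "file contains no model")
    fbc = sbml_model.getPlugin("fbc")
    _sbml_check(fbc, "missing fbc package (bounds/objective/GPR)")

    mets = []
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        splug = s.getPlugin("fbc")
        mets.append(
            Metabolite(
                id=_strip_prefix(s.getId(), "M_"),
                name=s.getName(),
                compartment=s.getCompartment(),
                formula=(splug.getChemicalFormula() or None)
                if splug is not None and splug.isSetChemicalFormula()
                else None,
                charge=splug.getCharge()
                if splug is not None and splug.isSetCharge()
                else None,
            )
        )

    gene_labels = {}
    for i in range(fbc.getNumGeneProducts()):
        gp = fbc.getGeneProduct(i)
        gene_labels[gp.getId()] = gp.getLabel() or _strip_prefix(gp.getId(), "G_")

    def gpr_to_string(assoc) -> str:
        import libsbml as _l

        if assoc is None:
            return ""
        if isinstance(assoc, _l.GeneProductRef):
            return gene_labels.get(assoc.getGeneProduct(),
                                   _strip_prefix(assoc.getGeneProduct(), "G_"))
        op = " and " if isinstance(assoc, _l.FbcAnd) else " or "
        parts = []
        for i in range(assoc.getNumAssociations()):
            child = assoc.getAssociation(i)
            sub = gpr_to_string(child)
            if isinstance(child, (_l.FbcAnd, _l.FbcOr)):
                sub = f"({sub})"
            parts.append(sub)
        return op.join(parts)

    # subsystems from groups
    subsystem_of: dict[str, str] = {}
    gplug = sbml_model.getPlugin("groups")
    if gplug is not None:
        for i in range(gplug.getNumGroups()):
            grp = gplug.getGroup(i)
            for j in range(grp.getNumMembers()):
                rid = _strip_prefix(grp.getMember(j).getIdRef(), "R_")
                subsystem_of[rid] = grp.getName() or grp.getId()

    rxns = []
    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        rid = _strip_prefix(r.getId(), "R_")
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = r.getPlugin("fbc")
        if (
            rplug is None
            or not rplug.isSetLowerFluxBound()
            or not rplug.isSetUpperFluxBound()
        ):
            raise ModelValidationError(
                f"SBML reaction {rid!r}: missing fbc flux bounds"
            )
        lb_param = sbml_model.getParameter(rplug.getLowerFluxBound())
        ub_param = sbml_model.getParameter(rplug.getUpperFluxBound())
        _sbml_check(lb_param, f"reaction {rid!r}: unresolved lower bound parameter")
        _sbml_check(ub_param, f"reaction {rid!r}: unresolved upper bound parameter")
        gpr = ""
        if rplug.isSetGeneProductAssociation():
            gpr = gpr_to_string(rplug.getGeneProductAssociation().getAssociation())
        rxns.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb_param.getValue(),
                upper_bound=ub_param.getValue(),
                gpr=gpr,
                subsystem=subsystem_of.get(rid, ""),
                name=r.getName(),
            )
        )

    objective_id = None
    active = fbc.getActiveObjective()
    if active is not None and active.getNumFluxObjectives() > 0:
        objective_id = _strip_prefix(active.getFluxObjective(0).getReaction(), "R_")
    if objective_id is None:
        raise ModelValidationError(
            "SBML: missing fbc active objective (fbc:listOfObjectives)"
        )
    return MetabolicModel(mets, rxns, objective_id=objective_id, id=sbml_model.getId())


# ---------------------------------------------------------------------------
# public I/O surface
# ---------------------------------------------------------------------------


def _infer_format(path: str) -> str:
    p = str(path).lower()
    if p.endswith((".json",)):
        return "json"
    if p.endswith((".xml", ".sbml")):
        return "sbml"
    raise ModelValidationError(f"cannot infer model format from {path!r}")


def read_model(path: str, format: str | None = None) -> MetabolicModel:
    fmt = format or _infer_format(path)
    if fmt == "json":
        with open(path) as fh:
            return _model_from_dict(json.load(fh))
    if fmt == "sbml":
        return _read_sbml(path)
    raise ModelValidationError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: str, format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=False)
            fh.write("\n")
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise ModelValidationError(f"unknown model format {fmt!r}")
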