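"""Genome-scale metabolic models as pure gene–reaction–metabolite knowledge bases.

A GEM is used here only for its connectivity: which metabolites participate in
which reactions (and on which side), and which enzyme-coding genes catalyze
those reactions.  No flux simulation is performed and Boolean gene–protein-
reaction (GPR) logic is never evaluated — every gene referenced in a reaction's
GPR annotation is treated as an associated gene.

Supported input formats:

* ``sbml-fbc`` — SBML Level 3 with the flux-balance-constraints extension
  (read through :mod:`cobra`).
* ``toy-json`` — a small JSON dialect for fixtures and tests (schema below).
* ``toy-tsv`` — a one-reaction-per-row TSV twin of the JSON dialect.

Toy JSON schema::

    {
      "metabolites": [{"id", "name", "compartment", "boundary"?}, ...],
      "reactions":   [{"id", "stoich": {met_id: coeff}, "reversible",
                       "genes": [...], "subsystem"?}, ...],
      "genes":       [{"id", "symbol"?}, ...]
    }

Negative stoichiometric coefficients mark reactants (consumed), positive
coefficients mark products.

Toy TSV columns (tab-separated, header row required)::

    reaction_id  stoich  reversible  genes  [subsystem]

where ``stoich`` is ``met_id:coeff;met_id:coeff;...`` and ``genes`` is a
semicolon-joined list (empty string for uncatalyzed reactions).  Metabolites
and genes are inferred from the reaction rows; a metabolite id of the form
``name[comp]`` is split into name and compartment, otherwise the compartment
defaults to ``"c"``.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FormatError, IntegrityError

KIND_EXCHANGE = "exchange"
KIND_TRANSPORT = "transport"
KIND_ENZYMATIC = "enzymatic"
KIND_UNCATALYZED = "uncatalyzed"

_COMPARTMENT_SUFFIX = re.compile(r"^(?P<name>.*?)\[(?P<comp>[^\[\]]+)\]$")


def normalize_name(name: str) -> str:
    """Normalize a metabolite name: trim, case-fold, collapse internal spaces."""
    return " ".join(name.strip().split()).casefold()


def split_compartment_suffix(met_id: str, compartments: set[str] | None = None):
    """Split a ``name[comp]`` or ``name_comp`` identifier into (name, comp).

    The underscore form is only stripped when the suffix is a declared
    compartment code, to avoid mangling ordinary identifiers.
    """
    m = _COMPARTMENT_SUFFIX.match(met_id)
    if m:
        return m.group("name"), m.group("comp")
    if compartments and "_" in met_id:
        stem, _, suffix = met_id.rpartition("_")
        if suffix in compartments:
            return stem, suffix
    return met_id, ""


@dataclass(frozen=True)
class Metabolite:
    """One compartmentalized species of the model."""

    id: str
    name: str
    compartment: str = "c"
    is_boundary: bool = False


@dataclass(frozen=True)
class Gene:
    id: str
    symbol: str | None = None


@dataclass
class Reaction:
    """A reaction with signed stoichiometry and a flattened gene set.

    ``stoichiometry`` maps metabolite id to a signed coefficient: negative
    for reactants, positive for products.  ``gene_ids`` is the flat set of
    every gene referenced by the reaction's GPR annotation.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    gene_ids: frozenset[str] = field(default_factory=frozenset)
    subsystem: str | None = None
    kind: str | None = None

    @property
    def reactant_ids(self) -> set[str]:
        return {m for m, c in self.stoichiometry.items() if c < 0}

    @property
    def product_ids(self) -> set[str]:
        return {m for m, c in self.stoichiometry.items() if c > 0}


class GEMModel:
    """An indexed, read-only view of a genome-scale metabolic model.

    Construction validates referential integrity (every metabolite and gene a
    reaction references must be declared), classifies every reaction and builds
    the traversal indexes:

    ``met_index``
        metabolite id → set of reaction ids the metabolite participates in.
    ``gene_index``
        gene id → set of reaction ids the gene catalyzes.
    ``name_index``
        normalized metabolite name → set of metabolite ids (all compartment
        instances of the species).
    """

    def __init__(
        self,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        genes: list[Gene],
        name: str = "",
    ):
        self.name = name
        self.metabolites: dict[str, Metabolite] = {}
        for m in metabolites:
            if m.id in self.metabolites:
                raise IntegrityError(f"duplicate metabolite id {m.id!r}")
            self.metabolites[m.id] = m
        self.genes: dict[str, Gene] = {}
        for g in genes:
            if g.id in self.genes:
                raise IntegrityError(f"duplicate gene id {g.id!r}")
            self.genes[g.id] = g
        self.reactions: dict[str, Reaction] = {}
        self.met_index: dict[str, set[str]] = {m: set() for m in self.metabolites}
        self.gene_index: dict[str, set[str]] = {g: set() for g in self.genes}
        for r in reactions:
            if r.id in self.reactions:
                raise IntegrityError(f"duplicate reaction id {r.id!r}")
            if not r.stoichiometry:
                raise IntegrityError(f"reaction {r.id!r} has empty stoichiometry")
            for mid, coeff in r.stoichiometry.items():
                if mid not in self.metabolites:
                    raise IntegrityError(
                        f"reaction {r.id!r} references undeclared metabolite {mid!r}"
                    )
                if coeff == 0:
                    raise IntegrityError(
                        f"reaction {r.id!r} has zero coefficient for {mid!r}"
                    )
            for gid in r.gene_ids:
                if gid not in self.genes:
                    raise IntegrityError(
                        f"reaction {r.id!r} references undeclared gene {gid!r}"
                    )
            self.reactions[r.id] = r
            for mid in r.stoichiometry:
                self.met_index[mid].add(r.id)
            for gid in r.gene_ids:
                self.gene_index[gid].add(r.id)

        self.name_index: dict[str, set[str]] = {}
        for m in self.metabolites.values():
            self.name_index.setdefault(normalize_name(m.name), set()).add(m.id)

        self.compartments: set[str] = {
            m.compartment for m in self.metabolites.values() if m.compartment
        }
        for r in self.reactions.values():
            r.kind = classify_reaction(r, self)

    # -- queries ---------------------------------------------------------

    def species_name(self, met_id: str) -> str:
        """The compartment-stripped, normalized species name of a metabolite."""
        met = self.metabolites[met_id]
        name, _ = split_compartment_suffix(met.name, self.compartments)
        return normalize_name(name)

    def mapping_eligible(self, rxn: Reaction) -> bool:
        """A reaction can link metabolites to genes only when it carries genes
        and is not a boundary (exchange) pseudo-reaction."""
        return bool(rxn.gene_ids) and rxn.kind != KIND_EXCHANGE

    def eligible_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if self.mapping_eligible(r)]

    def gene_metabolite_names(self, gene_id: str) -> set[str]:
        """Compartment-collapsed species names reachable from a gene through
        its mapping-eligible reactions."""
        names: set[str] = set()
        for rid in self.gene_index.get(gene_id, ()):
            r = self.reactions[rid]
            if self.mapping_eligible(r):
                names.update(self.species_name(m) for m in r.stoichiometry)
        return names

    def universe_size(self, universe: str = "collapsed") -> int:
        """Number of metabolites in the background universe.

        ``collapsed`` counts unique species names across compartments (the
        default, matching the compartment-collapsed signature space);
        ``species`` counts raw compartmentalized species.
        """
        if universe == "species":
            return len(self.metabolites)
        if universe == "collapsed":
            return len({self.species_name(m) for m in self.metabolites})
        raise ValueError(f"unknown universe convention {universe!r}")


def classify_reaction(rxn: Reaction, model: GEMModel) -> str:
    """Classify a reaction as exchange, transport, uncatalyzed or enzymatic.

    * exchange — involves a boundary species, or is single-sided (all
      coefficients share one sign), i.e. a system-boundary pseudo-reaction;
    * transport — the multiset of compartment-stripped species names is
      identical on both sides but the compartments differ;
    * uncatalyzed — carries no genes and is neither of the above;
    * enzymatic — everything else.
    """
    mets = [model.metabolites[m] for m in rxn.stoichiometry]
    if any(m.is_boundary for m in mets):
        return KIND_EXCHANGE
    signs = {c > 0 for c in rxn.stoichiometry.values()}
    if len(signs) == 1:
        return KIND_EXCHANGE

    def side_names(ids):
        return Counter(model.species_name(m) for m in ids)

    reactants, products = rxn.reactant_ids, rxn.product_ids
    if side_names(reactants) == side_names(products):
        comp_r = {model.metabolites[m].compartment for m in reactants}
        comp_p = {model.metabolites[m].compartment for m in products}
        if comp_r != comp_p:
            return KIND_TRANSPORT
    if not rxn.gene_ids:
        return KIND_UNCATALYZED
    return KIND_ENZYMATIC


def model_stats(model: GEMModel) -> tuple[int, int, int, int]:
    """(n_metabolites, n_reactions, n_genes, n_mapping_eligible_reactions)."""
    return (
        len(model.metabolites),
        len(model.reactions),
        len(model.genes),
        len(model.eligible_reactions()),
    )


# ---------------------------------------------------------------------------
# Loading / saving
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|\bAND\b|\bOR\b")


def flatten_gpr(gpr: str) -> frozenset[str]:
    """Collect every gene identifier referenced in a Boolean GPR string.

    The AND/OR structure (isoenzymes vs complexes) is deliberately discarded:
    the model is a knowledge base of associations, not a predictor of
    reaction activity.
    """
    cleaned = _GPR_TOKEN.sub(" ", gpr)
    return frozenset(tok for tok in cleaned.split() if tok)


def load_gem(source, format: str = "toy-json") -> GEMModel:
    """Load a GEM from ``source`` (path or readable stream) in the given format.

    Formats: ``sbml-fbc``, ``toy-json``, ``toy-tsv``.
    """
    if format == "toy-json":
        return _load_toy_json(source)
    if format == "toy-tsv":
        return _load_toy_tsv(source)
    if format == "sbml-fbc":
        return _load_sbml(source)
    raise ValueError(f"unknown model format {format!r}")


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    return Path(source).read_text()


def _load_toy_json(source) -> GEMModel:
    try:
        doc = json.loads(_read_text(source))
    except json.JSONDecodeError as exc:
        raise FormatError(f"toy-json parse failure: {exc}") from exc
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", m["id"]),
                compartment=m.get("compartment", "c"),
                is_boundary=bool(m.get("boundary", False)),
            )
            for m in doc["metabolites"]
        ]
        genes = [Gene(id=g["id"], symbol=g.get("symbol")) for g in doc["genes"]]
        rxns = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoich"].items()},
                reversible=bool(r.get("reversible", False)),
                gene_ids=frozenset(r.get("genes", ())),
                subsystem=r.get("subsystem"),
            )
            for r in doc["reactions"]
        ]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"toy-json schema violation: {exc}") from exc
    return GEMModel(mets, rxns, genes, name=doc.get("name", ""))


def save_toy_json(model: GEMModel, path) -> None:
    """Write a model back out in the toy-json dialect (round-trip safe)."""
    doc = {
        "name": model.name,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "boundary": m.is_boundary,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": dict(r.stoichiometry),
                "reversible": r.reversible,
                "genes": sorted(r.gene_ids),
                **({"subsystem": r.subsystem} if r.subsystem else {}),
            }
            for r in model.reactions.values()
        ],
        "genes": [
            {"id": g.id, **({"symbol": g.symbol} if g.symbol else {})}
            for g in model.genes.values()
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def _load_toy_tsv(source) -> GEMModel:
    text = _read_text(source)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("toy-tsv: empty file")
    header = lines[0].rstrip("\n").split("\t")
    required = ["reaction_id", "stoich", "reversible", "genes"]
    if header[: len(required)] != required:
        raise FormatError(f"toy-tsv: bad header {header!r}, expected {required}")
    has_subsystem = len(header) > 4 and header[4] == "subsystem"

    rxns: list[Reaction] = []
    met_ids: set[str] = set()
    gene_ids: set[str] = set()
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 4:
            raise FormatError(f"toy-tsv line {lineno}: expected ≥4 fields")
        rid, stoich_str, rev_str, genes_str = fields[:4]
        stoich: dict[str, float] = {}
        for item in stoich_str.split(";"):
            if not item:
                continue
            try:
                mid, coeff = item.rsplit(":", 1)
                stoich[mid] = float(coeff)
            except ValueError as exc:
                raise FormatError(
                    f"toy-tsv line {lineno}: bad stoichiometry item {item!r}"
                ) from exc
        genes = frozenset(g for g in genes_str.split(";") if g)
        met_ids.update(stoich)
        gene_ids.update(genes)
        rxns.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                reversible=rev_str.strip().lower() in {"1", "true", "yes"},
                gene_ids=genes,
                subsystem=fields[4] if has_subsystem and len(fields) > 4 else None,
            )
        )
    comps = set()
    mets = []
    for mid in sorted(met_ids):
        name, comp = split_compartment_suffix(mid)
        comps.add(comp or "c")
        mets.append(Metabolite(id=mid, name=name, compartment=comp or "c"))
    genes = [Gene(id=g) for g in sorted(gene_ids)]
    return GEMModel(mets, rxns, genes)


def _load_sbml(source) -> GEMModel:
    from cobra.io import read_sbml_model

    try:
        cmodel = read_sbml_model(str(source))
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise FormatError(f"SBML parse failure for {source}: {exc}") from exc

    mets = [
        Metabolite(
            id=m.id,
            name=m.name or m.id,
            compartment=m.compartment or "c",
            is_boundary=bool(getattr(m, "boundary_condition", False)),
        )
        for m in cmodel.metabolites
    ]
    genes = [Gene(id=g.id, symbol=g.name or None) for g in cmodel.genes]
    rxns = []
    for r in cmodel.reactions:
        # reversibility from bounds: lower < 0 and upper > 0
        reversible = r.lower_bound < 0 and r.upper_bound > 0
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                reversible=reversible,
                gene_ids=flatten_gpr(r.gene_reaction_rule),
                subsystem=r.subsystem or None,
            )
        )
    return GEMModel(mets, rxns, genes, name=cmodel.id or "")
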