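"""Resolve metabolite signatures against a GEM and map them to genes.

The mapping is reaction-centric.  Each signature metabolite is located in the
model by exact (normalized) name match; its mapping-eligible reactions are
collected; and the genes of those reactions become the mapped gene set.  Two
rules are supported:

* **non-directional** — any participation (reactant or product) links the
  metabolite to the reaction's genes;
* **directional** — only production links: the metabolite must appear as a
  product, or the reaction must be reversible (in which case every participant
  is treated as both reactant and product).

Currency metabolites (ATP, NADH, H2O, ...) receive no special handling — the
specificity score, not the mapping, is what down-weights promiscuous links.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .model import GEMModel, Reaction, normalize_name, split_compartment_suffix
from .specificity import MappedGene, WeightParams, sigmoid_weight, specificity_score

log = logging.getLogger(__name__)

RULE_NON_DIRECTIONAL = "non-directional"
RULE_DIRECTIONAL = "directional"
_RULE_ALIASES = {
    "nd": RULE_NON_DIRECTIONAL,
    "non-directional": RULE_NON_DIRECTIONAL,
    "nondirectional": RULE_NON_DIRECTIONAL,
    "d": RULE_DIRECTIONAL,
    "directional": RULE_DIRECTIONAL,
}


def canonical_rule(rule: str) -> str:
    try:
        return _RULE_ALIASES[rule.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown mapping rule {rule!r}; expected one of {sorted(_RULE_ALIASES)}"
        ) from None


@dataclass
class MetaboliteSignature:
    """A named list of metabolite names (RefMet-style), optionally directed."""

    label: str
    names: list[str]
    direction: str | None = None  # {"up", "down", None}

    def __post_init__(self):
        if not self.names:
            raise ValueError(f"signature {self.label!r} is empty")
        seen, unique = set(), []
        for n in self.names:
            key = normalize_name(n)
            if key in seen:
                warnings.warn(
                    f"signature {self.label!r}: duplicate metabolite {n!r} removed"
                )
                continue
            seen.add(key)
            unique.append(n)
        self.names = unique


@dataclass
class ResolvedSignature:
    """Outcome of matching a signature's names against a model."""

    signature: MetaboliteSignature
    resolved: dict[str, set[str]]  # input name -> model metabolite ids
    unresolved: list[str]
    collapse_compartments: bool = True

    @property
    def S(self) -> int:
        """Number of resolved signature metabolites."""
        return len(self.resolved)

    def species_names(self, model: GEMModel) -> set[str]:
        """Compartment-collapsed species names covered by the signature."""
        out: set[str] = set()
        for ids in self.resolved.values():
            out.update(model.species_name(i) for i in ids)
        return out


@dataclass
class MappingResult:
    """Ranked gene list for one signature under one mapping rule."""

    rule: str
    mapped_genes: list[MappedGene]
    resolved_signature: ResolvedSignature
    params: WeightParams
    universe: str = "collapsed"

    @property
    def gene_ids(self) -> set[str]:
        return {g.gene_id for g in self.mapped_genes}

    @property
    def weights(self) -> dict[str, float]:
        return {g.gene_id: g.w_i for g in self.mapped_genes}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "symbol": g.symbol or "",
                    "n_reactions": g.n_reactions,
                    "metabolites": ";".join(g.metabolites_in_signature),
                    "A_i": g.A_i,
                    "a_i": g.a_i,
                    "s_i": g.s_i,
                    "w_i": g.w_i,
                    "rank": g.rank,
                }
                for g in self.mapped_genes
            ],
            columns=[
                "gene_id",
                "symbol",
                "n_reactions",
                "metabolites",
                "A_i",
                "a_i",
                "s_i",
                "w_i",
                "rank",
            ],
        )


def read_signature(path, label: str | None = None) -> list[MetaboliteSignature]:
    """Read a signature file: one name per line, or 2-column TSV (name, up/down).

    Directed files yield one signature per direction (label suffixed ``_up`` /
    ``_down``); undirected files yield a single signature.
    """
    path = Path(path)
    label = label or path.stem
    plain: list[str] = []
    directed: dict[str, list[str]] = {"up": [], "down": []}
    has_direction = False
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) >= 2 and parts[1].strip().lower() in ("up", "down"):
            has_direction = True
            directed[parts[1].strip().lower()].append(parts[0].strip())
        else:
            plain.append(parts[0].strip())
    if has_direction:
        out = []
        for direction, names in directed.items():
            if names:
                out.append(
                    MetaboliteSignature(f"{label}_{direction}", names, direction)
                )
        return out
    return [MetaboliteSignature(label, plain)]


def load_synonyms(path) -> dict[str, str]:
    """Optional user-supplied synonym table: 2-column TSV, input-name → model-name."""
    out: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) >= 2:
            out[normalize_name(parts[0])] = parts[1].strip()
    return out


def resolve_signature(
    sig: MetaboliteSignature,
    model: GEMModel,
    collapse_compartments: bool = True,
    synonyms: dict[str, str] | None = None,
) -> ResolvedSignature:
    """Match signature names against the model by normalized exact match.

    Matching is case-insensitive against metabolite names (compartment
    suffixes stripped) and against raw metabolite ids, so toy models resolve
    by id too.  With ``collapse_compartments`` (default) every compartment
    instance of a matched species counts as a single signature metabolite.
    Unresolved names are reported, never dropped silently.
    """
    # species-name index: compartment-stripped normalized name -> ids
    by_species: dict[str, set[str]] = {}
    for mid in model.metabolites:
        by_species.setdefault(model.species_name(mid), set()).add(mid)
    by_id = {normalize_name(mid): mid for mid in model.metabolites}

    resolved: dict[str, set[str]] = {}
    unresolved: list[str] = []
    for raw in sig.names:
        key = normalize_name(raw)
        if synonyms and key in synonyms:
            key = normalize_name(synonyms[key])
        ids: set[str] = set()
        if key in model.name_index:
            ids |= model.name_index[key]
        if key in by_species:
            ids |= by_species[key]
        if key in by_id:
            ids.add(by_id[key])
        if ids:
            if not collapse_compartments:
                resolved[raw] = ids
            else:
                resolved[raw] = ids
        else:
            unresolved.append(raw)
    if unresolved:
        log.warning(
            "signature %s: %d of %d names unresolved",
            sig.label,
            len(unresolved),
            len(sig.names),
        )
    return ResolvedSignature(sig, resolved, unresolved, collapse_compartments)


def _metabolite_links(
    rsig: ResolvedSignature, model: GEMModel, rule: str
) -> dict[str, set[str]]:
    """gene id -> set of signature metabolite names supporting the link."""
    links: dict[str, set[str]] = {}
    for input_name, met_ids in rsig.resolved.items():
        rxn_ids: set[str] = set()
        for mid in met_ids:
            rxn_ids.update(model.met_index[mid])
        for rid in sorted(rxn_ids):
            rxn = model.reactions[rid]
            if not model.mapping_eligible(rxn):
                continue
            if rule == RULE_DIRECTIONAL:
                # production only; reversible reactions count both sides
                produced = any(
                    rxn.stoichiometry.get(mid, 0) > 0 for mid in met_ids
                )
                if not (produced or rxn.reversible):
                    continue
            for gid in rxn.gene_ids:
                links.setdefault(gid, set()).add(input_name)
    return links


def map_to_genes(
    rsig: ResolvedSignature,
    model: GEMModel,
    rule: str = RULE_NON_DIRECTIONAL,
    weight_params: WeightParams = WeightParams(),
    universe: str = "collapsed",
) -> MappingResult:
    """Map a resolved signature to genes and score each gene's specificity.

    Genes are ranked ascending by specificity score ``s_i`` (smaller = more
    specific), with ties broken by the number of catalyzed reactions, then by
    gene id.
    """
    rule = canonical_rule(rule)
    if rsig.S == 0:
        log.warning(
            "signature %s: no resolvable metabolites, empty mapping",
            rsig.signature.label,
        )
        return MappingResult(rule, [], rsig, weight_params, universe)

    M = model.universe_size(universe)
    if universe == "collapsed":
        sig_names = rsig.species_names(model)
    else:
        sig_names = {mid for ids in rsig.resolved.values() for mid in ids}
    S = len(sig_names)

    links = _metabolite_links(rsig, model, rule)
    mapped: list[MappedGene] = []
    for gid, supporting in links.items():
        if universe == "collapsed":
            neigh = model.gene_metabolite_names(gid)
        else:
            neigh = {
                mid
                for rid in model.gene_index[gid]
                if model.mapping_eligible(model.reactions[rid])
                for mid in model.reactions[rid].stoichiometry
            }
        A_i = len(neigh)
        a_i = len(neigh & sig_names)
        s_i = specificity_score(M, S, A_i, a_i)
        mapped.append(
            MappedGene(
                gene_id=gid,
                symbol=model.genes[gid].symbol,
                metabolites_in_signature=tuple(sorted(supporting)),
                A_i=A_i,
                a_i=a_i,
                s_i=s_i,
                w_i=sigmoid_weight(s_i, weight_params),
                n_reactions=len(model.gene_index[gid]),
            )
        )
    mapped.sort(key=lambda g: (g.s_i, g.n_reactions, g.gene_id))
    for i, g in enumerate(mapped, start=1):
        g.rank = i
    return MappingResult(rule, mapped, rsig, weight_params, universe)


def signature_to_genes(
    sigs: list[MetaboliteSignature] | MetaboliteSignature,
    model: GEMModel,
    rule: str = RULE_NON_DIRECTIONAL,
    weight_params: WeightParams = WeightParams(),
    collapse_compartments: bool = True,
    universe: str = "collapsed",
    synonyms: dict[str, str] | None = None,
) -> list[MappingResult]:
    """Batch driver: resolve, map, score and rank one or more signatures.

    Per-signature failures are logged and yield an empty result rather than
    aborting the batch.
    """
    if isinstance(sigs, MetaboliteSignature):
        sigs = [sigs]
    if not sigs:
        raise ValueError("need at least one signature")
    out: list[MappingResult] = []
    for sig in sigs:
        try:
            rsig = resolve_signature(sig, model, collapse_compartments, synonyms)
            out.append(map_to_genes(rsig, model, rule, weight_params, universe))
        except ValueError:
            raise
        except Exception:  # pragma: no cover - defensive batch isolation
            log.exception("signature %s failed; emitting empty result", sig.label)
            rsig = ResolvedSignature(sig, {}, list(sig.names), collapse_compartments)
            out.append(
                MappingResult(canonical_rule(rule), [], rsig, weight_params, universe)
            )
    return out
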