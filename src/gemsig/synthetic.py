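"""Seeded toy GEMs and planted metabolite signatures.

The generator produces small, fully-valid metabolic network fixtures with
known ground truth, so every pipeline stage — loading, classification,
mapping, specificity scoring, enrichment — can be exercised without any
external model.  The networks are combinatorial objects, not biochemistry:
there is no mass balance or thermodynamics, only the gene–reaction–metabolite
connectivity the mapping algorithm consumes.

All randomness flows through a single ``numpy`` generator derived from the
seed, consumed in a fixed order (reaction topology, reversibility, gene
attachment, then signature draws), so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mapping import MetaboliteSignature
from .model import GEMModel, Gene, Metabolite, Reaction


@dataclass(frozen=True)
class ToyGEMSpec:
    """Size and shape parameters for a generated toy model."""

    n_metabolites: int = 30
    n_reactions: int = 25
    n_genes: int = 12
    reversible_fraction: float = 0.3
    exchange_fraction: float = 0.15
    promiscuity: float = 2.0  # mean reactions per gene
    seed: int = 0

    def __post_init__(self):
        if min(self.n_metabolites, self.n_reactions, self.n_genes) < 1:
            raise ValueError("counts must be >= 1")
        for f in (self.reversible_fraction, self.exchange_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.promiscuity < 1:
            raise ValueError("promiscuity must be >= 1")


@dataclass(frozen=True)
class PlantedSignature:
    """A signature seeded from one target gene's metabolite neighborhood."""

    target_gene: str
    coverage: float = 1.0  # fraction of the target's metabolites included
    noise: int = 0  # random non-target metabolites added
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must lie in (0, 1]")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def _met_name(i: int) -> str:
    return f"MET{i + 1:04d}"


def generate_gem(spec: ToyGEMSpec) -> GEMModel:
    """Generate a connected toy GEM, deterministic given the seed.

    Non-exchange reactions draw 1–3 reactants and 1–3 products; every gene is
    attached to at least one reaction, with 1–3 genes per catalyzed reaction
    and the expected number of attachments per gene set by ``promiscuity``.
    Exchange reactions are single-sided boundary pseudo-reactions carrying no
    genes.
    """
    n_exchange = int(round(spec.exchange_fraction * spec.n_reactions))
    n_internal = spec.n_reactions - n_exchange
    if n_exchange > spec.n_metabolites:
        raise ValueError(
            f"infeasible: {n_exchange} exchange reactions but only "
            f"{spec.n_metabolites} metabolites"
        )
    if n_internal < 1:
        raise ValueError("need at least one non-exchange reaction")
    if spec.n_metabolites < 2:
        raise ValueError("need >= 2 metabolites for internal reactions")

    rng = np.random.default_rng(spec.seed)
    met_ids = [f"m{i + 1:04d}" for i in range(spec.n_metabolites)]
    mets = [
        Metabolite(id=mid, name=_met_name(i), compartment="c")
        for i, mid in enumerate(met_ids)
    ]
    gene_ids = [f"g{i + 1:04d}" for i in range(spec.n_genes)]
    genes = [Gene(id=gid, symbol=gid.upper()) for gid in gene_ids]

    reactions: list[Reaction] = []
    # internal reactions: chained so the network stays connected — each
    # reaction after the first consumes at least one previously used metabolite
    used: list[str] = []
    for j in range(n_internal):
        max_side = min(3, spec.n_metabolites // 2)
        n_react = int(rng.integers(1, max_side + 1))
        n_prod = int(rng.integers(1, max_side + 1))
        pool = list(met_ids)
        reactants: list[str] = []
        if used:
            anchor = used[int(rng.integers(0, len(used)))]
            reactants.append(anchor)
            pool.remove(anchor)
        while len(reactants) < n_react:
            pick = pool[int(rng.integers(0, len(pool)))]
            pool.remove(pick)
            reactants.append(pick)
        products: list[str] = []
        while len(products) < n_prod:
            pick = pool[int(rng.integers(0, len(pool)))]
            pool.remove(pick)
            products.append(pick)
        stoich = {m: -1.0 for m in reactants}
        stoich.update({m: 1.0 for m in products})
        reversible = bool(rng.random() < spec.reversible_fraction)
        reactions.append(
            Reaction(
                id=f"r{j + 1:04d}",
                stoichiometry=stoich,
                reversible=reversible,
            )
        )
        used.extend(reactants + products)

    # exchange reactions: single-sided import/export of one metabolite, no genes
    ex_mets = rng.choice(spec.n_metabolites, size=n_exchange, replace=False)
    for j, mi in enumerate(ex_mets):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        reactions.append(
            Reaction(
                id=f"ex{j + 1:04d}",
                stoichiometry={met_ids[int(mi)]: sign},
                reversible=bool(rng.random() < spec.reversible_fraction),
            )
        )

    # gene attachment: every gene gets >= 1 internal reaction; extra
    # attachments bring the mean up to `promiscuity`; 1–3 genes per reaction
    # emerge from the draw and are capped by reassignment.
    attachments: dict[str, set[str]] = {g: set() for g in gene_ids}
    internal_ids = [r.id for r in reactions[:n_internal]]
    for gid in gene_ids:
        rid = internal_ids[int(rng.integers(0, len(internal_ids)))]
        attachments[gid].add(rid)
    n_extra = max(0, int(round(spec.promiscuity * spec.n_genes)) - spec.n_genes)
    for _ in range(n_extra):
        gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
        rid = internal_ids[int(rng.integers(0, len(internal_ids)))]
        attachments[gid].add(rid)

    rxn_genes: dict[str, set[str]] = {r.id: set() for r in reactions}
    for gid, rids in attachments.items():
        for rid in rids:
            rxn_genes[rid].add(gid)
    # cap at 3 genes per reaction: overflow genes keep their other attachments
    # or get moved to the least-loaded internal reaction
    for rid in internal_ids:
        while len(rxn_genes[rid]) > 3:
            gid = sorted(rxn_genes[rid])[-1]
            rxn_genes[rid].discard(gid)
            attachments[gid].discard(rid)
            if not attachments[gid]:
                target = min(
                    (r for r in internal_ids if len(rxn_genes[r]) < 3),
                    key=lambda r: (len(rxn_genes[r]), r),
                    default=None,
                )
                if target is None:  # every reaction full: leave gene here
                    rxn_genes[rid].add(gid)
                    attachments[gid].add(rid)
                    break
                rxn_genes[target].add(gid)
                attachments[gid].add(target)

    reactions = [
        Reaction(
            id=r.id,
            stoichiometry=r.stoichiometry,
            reversible=r.reversible,
            gene_ids=frozenset(rxn_genes[r.id]),
        )
        for r in reactions
    ]
    return GEMModel(mets, reactions, genes, name=f"toy-seed{spec.seed}")


def plant_signature(
    model: GEMModel, spec: PlantedSignature
) -> tuple[MetaboliteSignature, dict]:
    """Build a signature from a target gene's metabolite neighborhood.

    Returns the signature and a truth record with the target gene, the
    sampled neighborhood names and the noise names.  When the coverage sample
    is empty by construction the record flags that recovery is not guaranteed.
    """
    if spec.target_gene not in model.genes:
        raise ValueError(f"target gene {spec.target_gene!r} not in model")
    neighborhood = sorted(model.gene_metabolite_names(spec.target_gene))
    if not neighborhood:
        raise ValueError(
            f"target gene {spec.target_gene!r} has no associated metabolites"
        )
    rng = np.random.default_rng(spec.seed)
    n_take = int(round(spec.coverage * len(neighborhood)))
    take = sorted(
        rng.choice(len(neighborhood), size=n_take, replace=False).tolist()
    )
    core = [neighborhood[i] for i in take]

    all_names = sorted({model.species_name(m) for m in model.metabolites})
    others = [n for n in all_names if n not in set(neighborhood)]
    n_noise = min(spec.noise, len(others))
    noise_idx = sorted(rng.choice(len(others), size=n_noise, replace=False).tolist())
    noise = [others[i] for i in noise_idx]

    names = core + noise
    if not names:
        raise ValueError("planted signature is empty (coverage sample and noise empty)")
    truth = {
        "target_gene": spec.target_gene,
        "neighborhood": neighborhood,
        "core": core,
        "noise": noise,
        "recovery_guaranteed": bool(core),
    }
    label = f"planted-{spec.target_gene}-seed{spec.seed}"
    return MetaboliteSignature(label, names), truth
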