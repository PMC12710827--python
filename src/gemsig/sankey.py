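"""Machine-readable three-layer Sankey export.

Connects a metabolite signature, its enriched metabolite sets, and the gene
sets enriched in the GEM-mapped genes.  Edge weights between the metabolite
and metabolite-set layers are shared-metabolite counts; edges between the
metabolite-set and gene-set layers carry the overlap between the genes mapped
from the set's shared metabolites and the gene set's members.  Only the
node/edge list is emitted (JSON); drawing is out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path

from .enrichment import GeneSetCollection, ORAReport
from .mapping import MappingResult
from .model import GEMModel, normalize_name


def build_sankey(
    model: GEMModel,
    mapping: MappingResult,
    mset_report: ORAReport,
    mset_collection: GeneSetCollection,
    gset_report: ORAReport,
    gset_collection: GeneSetCollection,
) -> dict:
    """Three-layer node/edge structure: metabolites → metabolite sets → gene sets."""
    sig_names = {normalize_name(n) for n in mapping.resolved_signature.resolved}
    enriched_msets = [r.set_name for r in mset_report.significant]
    enriched_gsets = [r.set_name for r in gset_report.significant]

    nodes = (
        [{"id": f"met:{n}", "layer": "metabolite", "label": n} for n in sorted(sig_names)]
        + [{"id": f"mset:{s}", "layer": "metabolite_set", "label": s} for s in enriched_msets]
        + [{"id": f"gset:{s}", "layer": "gene_set", "label": s} for s in enriched_gsets]
    )

    # gene support per signature metabolite (normalized input name -> genes)
    met_genes: dict[str, set[str]] = {}
    for g in mapping.mapped_genes:
        for met in g.metabolites_in_signature:
            met_genes.setdefault(normalize_name(met), set()).add(g.gene_id)

    edges = []
    for mset in enriched_msets:
        members = {normalize_name(m) for m in mset_collection.members(mset)}
        shared = sig_names & members
        if shared:
            edges.append(
                {
                    "source": "metabolite_signature",
                    "target": f"mset:{mset}",
                    "weight": len(shared),
                    "shared_metabolites": sorted(shared),
                }
            )
        genes_from_shared: set[str] = set()
        for met in shared:
            genes_from_shared |= met_genes.get(met, set())
        for gset in enriched_gsets:
            overlap = genes_from_shared & set(gset_collection.members(gset))
            if overlap:
                edges.append(
                    {
                        "source": f"mset:{mset}",
                        "target": f"gset:{gset}",
                        "weight": len(overlap),
                        "shared_genes": sorted(overlap),
                    }
                )
    return {"nodes": nodes, "edges": edges}


def write_sankey(sankey: dict, path) -> None:
    Path(path).write_text(json.dumps(sankey, indent=1) + "\n")
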