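import pytest

from gemsig.mapping import (
    MetaboliteSignature,
    canonical_rule,
    map_to_genes,
    read_signature,
    resolve_signature,
    signature_to_genes,
)
from gemsig.specificity import specificity_score
from gemsig.synthetic import PlantedSignature, ToyGEMSpec, generate_gem, plant_signature


def test_signature_deduplicates_with_warning():
    with pytest.warns(UserWarning):
        sig = MetaboliteSignature("s", ["ATP", "atp ", "ADP"])
    assert sig.names == ["ATP", "ADP"]


def test_empty_signature_rejected():
    with pytest.raises(ValueError):
        MetaboliteSignature("s", [])


def test_resolution_collapses_compartments(small_model):
    sig = MetaboliteSignature("s", ["Alanine", "Nonexistent-X"])
    rsig = resolve_signature(sig, small_model)
    assert rsig.resolved == {"Alanine": {"A[c]", "A[e]"}}
    assert rsig.unresolved == ["Nonexistent-X"]
    assert rsig.S == 1


def test_resolution_is_case_insensitive(small_model):
    rsig = resolve_signature(MetaboliteSignature("s", ["  aTp  "]), small_model)
    assert rsig.resolved == {"  aTp  ": {"B[c]"}}


def test_all_unresolved_gives_empty_mapping(small_model):
    rsig = resolve_signature(MetaboliteSignature("s", ["nope1", "nope2"]), small_model)
    assert rsig.S == 0
    res = map_to_genes(rsig, small_model)
    assert res.mapped_genes == []


def test_synonym_table(small_model):
    rsig = resolve_signature(
        MetaboliteSignature("s", ["2-aminopropanoate"]),
        small_model,
        synonyms={"2-aminopropanoate": "Alanine"},
    )
    assert rsig.S == 1


def test_directional_rule_excludes_pure_reactants(small_model):
    # Alanine is only consumed: by irreversible r1 (g1) and transporter r3
    # (g3, produced there), and produced by nothing else
    sig = MetaboliteSignature("s", ["ATP"])  # B[c]: consumed by r1 only
    rsig = resolve_signature(sig, small_model)
    nd = map_to_genes(rsig, small_model, rule="nd")
    d = map_to_genes(rsig, small_model, rule="d")
    assert nd.gene_ids == {"g1"}
    assert d.gene_ids == set()


def test_directional_rule_keeps_reversible_reactions(small_model):
    # Citrate is consumed by reversible r2: the reversibility clause keeps g2
    sig = MetaboliteSignature("s", ["Aspartate"])  # D[c], product of rev r2
    rsig = resolve_signature(sig, small_model)
    assert map_to_genes(rsig, small_model, rule="d").gene_ids == {"g2"}
    # Citrate is produced by r1 and consumed by reversible r2: both genes map
    sig2 = MetaboliteSignature("s2", ["Citrate"])
    rsig2 = resolve_signature(sig2, small_model)
    assert map_to_genes(rsig2, small_model, rule="d").gene_ids == {"g1", "g2"}


def test_invalid_rule_token(small_model):
    with pytest.raises(ValueError):
        canonical_rule("sideways")


def test_exchange_only_genes_never_mapped(exchange_gene_model):
    sig = MetaboliteSignature("s", ["Xylose", "Tyrosine"])
    rsig = resolve_signature(sig, exchange_gene_model)
    for rule in ("nd", "d"):
        res = map_to_genes(rsig, exchange_gene_model, rule=rule)
        assert "gX" not in res.gene_ids
    assert map_to_genes(rsig, exchange_gene_model, rule="nd").gene_ids == {"gY"}


@pytest.mark.parametrize("seed", range(8))
def test_directional_subset_of_non_directional(seed):
    model = generate_gem(ToyGEMSpec(seed=seed))
    names = sorted({model.species_name(m) for m in model.metabolites})[::3]
    rsig = resolve_signature(MetaboliteSignature("s", names), model)
    nd = map_to_genes(rsig, model, rule="nd")
    d = map_to_genes(rsig, model, rule="d")
    assert d.gene_ids <= nd.gene_ids


@pytest.mark.parametrize("rule", ["nd", "d"])
def test_adding_metabolite_is_monotone(rule):
    model = generate_gem(ToyGEMSpec(seed=11))
    names = sorted({model.species_name(m) for m in model.metabolites})
    base, extra = names[:6], names[6]
    small = map_to_genes(
        resolve_signature(MetaboliteSignature("s", base), model), model, rule=rule
    )
    grown = map_to_genes(
        resolve_signature(MetaboliteSignature("s", base + [extra]), model),
        model,
        rule=rule,
    )
    assert small.gene_ids <= grown.gene_ids


def test_mapped_sets_permutation_invariant():
    model = generate_gem(ToyGEMSpec(seed=5))
    names = sorted({model.species_name(m) for m in model.metabolites})[:8]
    fwd = map_to_genes(
        resolve_signature(MetaboliteSignature("s", names), model), model
    )
    rev = map_to_genes(
        resolve_signature(MetaboliteSignature("s", names[::-1]), model), model
    )
    assert fwd.gene_ids == rev.gene_ids
    assert [g.gene_id for g in fwd.mapped_genes] == [g.gene_id for g in rev.mapped_genes]


def test_ranking_ascending_in_score_with_deterministic_ties():
    model = generate_gem(ToyGEMSpec(seed=3))
    names = sorted({model.species_name(m) for m in model.metabolites})[:10]
    res = map_to_genes(resolve_signature(MetaboliteSignature("s", names), model), model)
    keys = [(g.s_i, g.n_reactions, g.gene_id) for g in res.mapped_genes]
    assert keys == sorted(keys)
    assert [g.rank for g in res.mapped_genes] == list(range(1, len(keys) + 1))
    assert all(g.a_i >= 1 for g in res.mapped_genes)


def test_covering_signature_ranks_target_first():
    """A signature equal to one gene's full neighborhood puts that gene at the
    minimum specificity score, verified by brute-force scoring of every gene."""
    model = generate_gem(ToyGEMSpec(seed=21))
    # choose the gene with the smallest neighborhood (most specific target)
    target = min(
        (g for g in model.genes if model.gene_metabolite_names(g)),
        key=lambda g: (len(model.gene_metabolite_names(g)), g),
    )
    sig, _ = plant_signature(model, PlantedSignature(target, coverage=1.0, noise=0))
    res = map_to_genes(resolve_signature(sig, model), model)

    M = model.universe_size()
    S = len(res.resolved_signature.species_names(model))
    sig_names = res.resolved_signature.species_names(model)
    brute = {}
    for g in model.genes:
        neigh = model.gene_metabolite_names(g)
        if neigh & sig_names:
            brute[g] = specificity_score(M, S, len(neigh), len(neigh & sig_names))
    assert res.mapped_genes[0].s_i == pytest.approx(min(brute.values()))
    assert res.mapped_genes[0].s_i == pytest.approx(brute[target])


def test_batch_driver_independent_signatures(small_model):
    sigs = [
        MetaboliteSignature("up", ["Alanine", "Citrate"], "up"),
        MetaboliteSignature("down", ["no-such-metabolite"], "down"),
    ]
    results = signature_to_genes(sigs, small_model)
    assert len(results) == 2
    assert results[0].gene_ids
    assert results[1].mapped_genes == []
    assert results[1].resolved_signature.unresolved == ["no-such-metabolite"]


def test_read_signature_formats(tmp_path):
    plain = tmp_path / "plain.txt"
    plain.write_text("ATP\nADP\n# comment\n")
    [sig] = read_signature(plain)
    assert sig.names == ["ATP", "ADP"]

    directed = tmp_path / "directed.tsv"
    directed.write_text("ATP\tup\nADP\tdown\nAMP\tup\n")
    sigs = read_signature(directed)
    assert {s.direction: s.names for s in sigs} == {
        "up": ["ATP", "AMP"],
        "down": ["ADP"],
    }
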