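import json

import pytest

from gemsig.model import GEMModel, Gene, Metabolite, Reaction, load_gem


def small_network_doc():
    """A hand-built six-metabolite network: one enzymatic reaction, one
    reversible enzymatic reaction, one gene-carrying transporter and one
    exchange pseudo-reaction.  Three of the four reactions are
    mapping-eligible (the exchange reaction is not)."""
    return {
        "metabolites": [
            {"id": "A[c]", "name": "Alanine", "compartment": "c"},
            {"id": "B[c]", "name": "ATP", "compartment": "c"},
            {"id": "C[c]", "name": "Citrate", "compartment": "c"},
            {"id": "D[c]", "name": "Aspartate", "compartment": "c"},
            {"id": "E[c]", "name": "Glutamate", "compartment": "c"},
            {"id": "A[e]", "name": "Alanine", "compartment": "e"},
        ],
        "reactions": [
            {
                "id": "r1",
                "stoich": {"A[c]": -1, "B[c]": -1, "C[c]": 1},
                "reversible": False,
                "genes": ["g1"],
            },
            {
                "id": "r2",
                "stoich": {"C[c]": -1, "D[c]": 1, "E[c]": 1},
                "reversible": True,
                "genes": ["g2"],
            },
            {
                "id": "r3",
                "stoich": {"A[e]": -1, "A[c]": 1},
                "reversible": False,
                "genes": ["g3"],
            },
            {"id": "ex1", "stoich": {"A[e]": 1}, "reversible": True, "genes": []},
        ],
        "genes": [
            {"id": "g1", "symbol": "G1"},
            {"id": "g2", "symbol": "G2"},
            {"id": "g3", "symbol": "G3"},
        ],
    }


@pytest.fixture
def small_model(tmp_path):
    path = tmp_path / "small.json"
    path.write_text(json.dumps(small_network_doc()))
    return load_gem(path, "toy-json")


@pytest.fixture
def small_model_path(tmp_path):
    path = tmp_path / "small.json"
    path.write_text(json.dumps(small_network_doc()))
    return path


@pytest.fixture
def exchange_gene_model():
    """A model whose gene gX catalyzes only an exchange reaction; gY is the
    control gene on an ordinary enzymatic reaction."""
    mets = [
        Metabolite("X[c]", "Xylose", "c"),
        Metabolite("Y[c]", "Tyrosine", "c"),
    ]
    rxns = [
        Reaction("exX", {"X[c]": -1.0}, reversible=True, gene_ids=frozenset({"gX"})),
        Reaction(
            "rY", {"X[c]": -1.0, "Y[c]": 1.0}, reversible=False,
            gene_ids=frozenset({"gY"}),
        ),
    ]
    genes = [Gene("gX"), Gene("gY")]
    return GEMModel(mets, rxns, genes)


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "S1\tfirst set\tg1\tg2\n"
        "S2\tsecond set\tg2\tg3\tg4\n"
        "S3\tthird set\tg9\n"
    )
    return path
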