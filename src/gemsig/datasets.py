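"""Packaged benchmark tables from the published paired-omics evaluation.

Eleven phenotype comparisons across ten paired metabolomics–proteomics /
metabolomics–transcriptomics studies (EMT, serine starvation, NECS age and
extreme-longevity, four M005 mouse tissues, ROSMAP, and COVID-19 urine/serum)
were evaluated for concordance between GEM-mapped enzyme-coding genes and the
paired omics signatures.  The transcribed overlap counts and hypergeometric
p-values are shipped here at two levels:

* single-molecule — one row per comparison: mapped-gene / DE-gene overlap
  under the non-directional and directional rules;
* pathway — one row per comparison x gene-set collection (Hallmark, KEGG,
  REACTOME, GOBP, GOMF): enriched-pathway overlap under both rules.

These tables drive the global uniformity (KS) and significance-counting
analyses without requiring any of the original omics data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_P_COLS = ["p_nd", "p_d"]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("gemsig").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_single_molecule_benchmark() -> pd.DataFrame:
    """Per-comparison single-molecule overlap counts and p-values."""
    return _read("single_molecule_benchmark.tsv")


def load_pathway_benchmark() -> pd.DataFrame:
    """Per-comparison, per-collection pathway overlap counts and p-values."""
    return _read("pathway_benchmark.tsv")


def single_molecule_pvalue_table() -> pd.DataFrame:
    """The 11 x 2 p-value matrix (rows: comparisons; columns: mapping rules)."""
    df = load_single_molecule_benchmark()
    return df.set_index("dataset")[_P_COLS]


def pathway_pvalue_table() -> pd.DataFrame:
    """The 55 x 2 p-value matrix (rows: comparison x collection)."""
    df = load_pathway_benchmark()
    return df.set_index(["dataset", "collection"])[_P_COLS]


def pathway_pvalue_table_by_dataset() -> pd.DataFrame:
    """Per-comparison matrix of the 10 pathway p-values (5 collections x 2 rules).

    Suitable for any-column significance counting at the comparison level.
    """
    df = load_pathway_benchmark()
    wide = df.pivot(index="dataset", columns="collection", values=_P_COLS)
    wide.columns = [f"{p}_{c}" for p, c in wide.columns]
    # preserve the original comparison order
    order = list(dict.fromkeys(df["dataset"]))
    return wide.loc[order]
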