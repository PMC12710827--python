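"""Paired-omics concordance evaluation and p-value uniformity testing.

Two levels of concordance between GEM-mapped genes and independently derived
omics signatures are assessed:

* **single-molecule** — do the mapped enzyme-coding genes overlap the
  differentially expressed proteins/transcripts more than chance?  The
  background is the intersection of the model's enzyme-coding genes with the
  genes/proteins actually measured in the paired layer.
* **pathway** — do gene sets enriched in the mapped genes overlap gene sets
  enriched in the paired omics signature?  The background is the family of
  pathways sufficiently represented on both sides.

Both use the one-sided upper-tail hypergeometric test.  A global check across
many comparisons asks whether the collection of overlap p-values is skewed
toward zero, via a one-sided Kolmogorov–Smirnov test against Uniform(0, 1)
(statistic D+ = max_i(i/n - x_(i))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .enrichment import hypergeom_upper_tail

ALT_SKEW_TO_ZERO = "skew-to-zero"
ALT_TWO_SIDED = "two-sided"


@dataclass
class OverlapTestResult:
    n_a: int
    n_b: int
    overlap: int
    N_bg: int
    p: float


@dataclass
class KSResult:
    n: int
    D: float
    p: float
    alternative: str


def overlap_from_counts(N_bg: int, n_a: int, n_b: int, overlap: int) -> OverlapTestResult:
    """Upper-tail hypergeometric overlap test from pre-tabulated counts."""
    if overlap > min(n_a, n_b):
        raise ValueError("overlap cannot exceed either set size")
    p = hypergeom_upper_tail(N_bg, n_b, n_a, overlap)
    return OverlapTestResult(n_a=n_a, n_b=n_b, overlap=overlap, N_bg=N_bg, p=p)


def single_molecule_overlap(
    mapped: set[str],
    de: set[str],
    gem_genes: set[str],
    measured: set[str],
) -> OverlapTestResult:
    """Overlap of mapped genes with differentially expressed genes/proteins.

    The background is ``gem_genes & measured``; both input sets are restricted
    to it before testing.  Callers supply the *union* of up- and
    down-signature mapped genes and the union of up/down DE molecules.
    """
    bg = gem_genes & measured
    if not bg:
        raise ValueError("empty background: GEM genes and measured genes are disjoint")
    a = mapped & bg
    b = de & bg
    return overlap_from_counts(len(bg), len(a), len(b), len(a & b))


def pathway_overlap(
    enriched_a: set[str],
    enriched_b: set[str],
    eligible: set[str],
) -> OverlapTestResult:
    """Overlap of two enriched-pathway name sets over an eligible background."""
    if not eligible:
        raise ValueError("empty eligible pathway background")
    import warnings

    for label, s in (("a", enriched_a), ("b", enriched_b)):
        extra = s - eligible
        if extra:
            warnings.warn(
                f"{len(extra)} enriched pathways in set {label} outside the "
                "eligible background were dropped"
            )
    a = enriched_a & eligible
    b = enriched_b & eligible
    return overlap_from_counts(len(eligible), len(a), len(b), len(a & b))


def eligible_pathways(
    collection_sets: dict[str, frozenset[str]],
    universe_a: set[str],
    universe_b: set[str],
    min_genes: int = 5,
) -> set[str]:
    """Pathways sufficiently represented in both gene universes.

    A pathway qualifies when at least ``min_genes`` of its members lie in each
    side's universe.  The threshold is a parameter because "sufficient
    representation" has no canonical value.
    """
    return {
        name
        for name, members in collection_sets.items()
        if len(members & universe_a) >= min_genes
        and len(members & universe_b) >= min_genes
    }


def ks_uniform(pvals, alternative: str = ALT_SKEW_TO_ZERO) -> KSResult:
    """Kolmogorov–Smirnov test of p-values against Uniform(0, 1).

    ``skew-to-zero`` (default) is the one-sided alternative that the sample
    ECDF lies *above* the uniform CDF — small p-values are over-represented —
    with statistic D+ = max_i(i/n - x_(i)) and the exact one-sided Smirnov
    p-value.  ``two-sided`` uses D = max(D+, D-) with the two-sided KS
    distribution.
    """
    x = np.asarray(list(pvals), dtype=float)
    if x.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = x.size
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    d_plus = float(max((i / n - xs).max(), 0.0))
    d_minus = float(max((xs - (i - 1) / n).max(), 0.0))
    if alternative == ALT_SKEW_TO_ZERO:
        D = d_plus
        p = float(special.smirnov(n, D))
    elif alternative == ALT_TWO_SIDED:
        D = max(d_plus, d_minus)
        p = float(np.clip(stats.kstwo.sf(D, n), 0.0, 1.0))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return KSResult(n=n, D=D, p=p, alternative=alternative)


def count_significant(
    p_table: pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "any-column",
):
    """Count significant rows of a (comparisons x rules) p-value table.

    ``any-column`` counts rows whose minimum across columns is strictly below
    ``alpha``; ``per-column`` returns a per-column Series of counts.
    Significance is strict (p < alpha), matching the usual reporting
    convention.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if p_table.empty:
        return 0 if mode == "any-column" else pd.Series(dtype=int)
    if mode == "any-column":
        return int((p_table.min(axis=1) < alpha).sum())
    if mode == "per-column":
        return (p_table < alpha).sum(axis=0)
    raise ValueError(f"unknown mode {mode!r}")
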