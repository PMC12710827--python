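"""Specificity-weighted hypergeometric over-representation analysis.

Classical ORA asks whether a query gene list ``n`` drawn from a background of
``N`` genes contains surprisingly many members ``k`` of a gene set of size
``K``, via the upper-tail hypergeometric probability

    p = sum_{j=k}^{min(n, K)} C(K, j) C(N-K, n-j) / C(N, n).

The weighted variant replaces the raw counts ``n`` and ``k`` with sums of the
mapped genes' sigmoid weights, rounded half-up to integers:

    n_w = floor(1/2 + sum_i w_i),   k_w = floor(1/2 + sum_{i in set} w_i)

``N`` and ``K`` are never weight-adjusted.  With all weights equal to 1 the
procedure reduces exactly to classical ORA.  p-values are adjusted per
collection with Benjamini–Hochberg.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FormatError
from .mapping import MappingResult
from .specificity import hypergeom_sf_exact

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (typically one GMT file)."""

    name: str
    sets: dict[str, tuple[str, frozenset[str]]]  # set name -> (description, members)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_name: str) -> frozenset[str]:
        return self.sets[set_name][1]


@dataclass
class EnrichmentRow:
    set_name: str
    N: int
    K: int
    n_raw: int
    k_raw: int
    n_w: int
    k_w: int
    p: float
    p_adj: float = float("nan")
    hits: tuple[str, ...] = ()


@dataclass
class ORAReport:
    """Per-collection over-representation report, rows sorted by p."""

    collection: str
    rows: list[EnrichmentRow]
    use_weights: bool
    alpha: float
    background_size: int

    @property
    def significant(self) -> list[EnrichmentRow]:
        return [r for r in self.rows if r.p_adj < self.alpha]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "set_name": r.set_name,
                    "N": r.N,
                    "K": r.K,
                    "n_raw": r.n_raw,
                    "k_raw": r.k_raw,
                    "n_w": r.n_w,
                    "k_w": r.k_w,
                    "p": r.p,
                    "p_adj": r.p_adj,
                    "hits": ";".join(r.hits),
                }
                for r in self.rows
            ],
            columns=[
                "set_name", "N", "K", "n_raw", "k_raw",
                "n_w", "k_w", "p", "p_adj", "hits",
            ],
        )


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, tab-separated members.

    Duplicate members within a set are deduplicated; an empty file yields an
    empty collection with a warning.
    """
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path.name}:{lineno}: GMT line needs >= 3 tab-separated fields"
            )
        name, desc = fields[0], fields[1]
        members = frozenset(g for g in fields[2:] if g)
        if name in sets:
            raise FormatError(f"{path.name}:{lineno}: duplicate set name {name!r}")
        sets[name] = (desc, members)
    if not sets:
        warnings.warn(f"GMT file {path} contains no gene sets")
    return GeneSetCollection(name=path.stem, sets=sets)


def round_half_up(x: float) -> int:
    """floor(1/2 + x): round-half-up, the rounding the weighted counts use."""
    return math.floor(0.5 + x)


def weighted_counts(
    weights: dict[str, float],
    members: frozenset[str] | set[str],
    background: frozenset[str] | set[str],
) -> tuple[int, int]:
    """Weight-adjusted (n_w, k_w) for one gene set.

    Both sums run over weighted genes inside the background; after rounding,
    ``k_w`` is clamped to ``min(n_w, K)`` so the hypergeometric support is
    respected.
    """
    in_bg = {g: w for g, w in weights.items() if g in background}
    n_w = round_half_up(sum(in_bg.values()))
    k_w = round_half_up(sum(w for g, w in in_bg.items() if g in members))
    K = len(set(members) & set(background))
    k_w = min(k_w, n_w, K)
    return n_w, k_w


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) drawing ``n`` genes from ``N`` of which ``K`` are set members."""
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return hypergeom_sf_exact(k, N, K, n)


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (statsmodels-backed)."""
    if not pvals:
        return []
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(pvals, method="fdr_bh")[1])


def run_ora(
    mapping: MappingResult,
    collections: list[GeneSetCollection] | GeneSetCollection,
    background: set[str] | None = None,
    use_weights: bool = True,
    alpha: float = 0.05,
) -> list[ORAReport]:
    """Weighted (or classical) ORA of a mapping result against collections.

    ``background`` defaults to all genes of the model the mapping was computed
    on is not known here, so callers normally pass ``set(model.genes)``; any
    mapped gene outside the background is dropped with a warning.  BH
    adjustment is applied within each collection separately.  Degenerate rows
    (no set members in the background, or a zero weighted query) are reported
    with p = 1 rather than dropped, so row counts are stable for downstream
    pathway-overlap tests.
    """
    if isinstance(collections, GeneSetCollection):
        collections = [collections]
    if not mapping.mapped_genes:
        raise ValueError("mapping result is empty; nothing to enrich")
    if background is not None and not background:
        raise ValueError("background is empty")

    weights = mapping.weights
    if not use_weights:
        weights = {g: 1.0 for g in weights}
    if background is None:
        background = set(weights)
    dropped = set(weights) - set(background)
    if dropped:
        log.warning(
            "%d mapped genes outside the background dropped: %s",
            len(dropped),
            sorted(dropped)[:5],
        )
    in_bg = {g: w for g, w in weights.items() if g in background}
    N = len(background)
    n_raw = len(in_bg)

    reports = []
    for coll in collections:
        rows: list[EnrichmentRow] = []
        for set_name in coll.sets:
            members = coll.members(set_name) & background
            K = len(members)
            hits = tuple(sorted(g for g in in_bg if g in members))
            k_raw = len(hits)
            n_w, k_w = weighted_counts(in_bg, members, background)
            if K == 0 or n_w == 0:
                p = 1.0
            else:
                p = hypergeom_upper_tail(N, K, n_w, k_w)
            rows.append(
                EnrichmentRow(
                    set_name=set_name,
                    N=N,
                    K=K,
                    n_raw=n_raw,
                    k_raw=k_raw,
                    n_w=n_w,
                    k_w=k_w,
                    p=p,
                    hits=hits,
                )
            )
        adj = bh_adjust([r.p for r in rows])
        for r, q in zip(rows, adj):
            r.p_adj = q
        rows.sort(key=lambda r: (r.p, r.set_name))
        reports.append(
            ORAReport(
                collection=coll.name,
                rows=rows,
                use_weights=use_weights,
                alpha=alpha,
                background_size=N,
            )
        )
    return reports
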