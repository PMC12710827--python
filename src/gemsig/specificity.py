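"""Gene-specificity scores and sigmoid weights.

A mapped gene's specificity is the upper-tail hypergeometric probability of
its observed overlap with the signature: out of ``M`` metabolites in the model
universe, ``S`` belong to the signature, the gene is associated with ``A_i``
metabolites, and ``a_i`` of those fall inside the signature.  Then

    s_i = P(X >= a_i) = sum_{x=a_i}^{min(A_i, S)} C(A_i, x) C(M-A_i, S-x) / C(M, S)

Small ``s_i`` means the gene's metabolite neighborhood is unusually
concentrated in the signature — a *specific* association.  The score is turned
into a weight for downstream enrichment through a sigmoid on the log10 scale:

    w_i = 1 / (1 + exp(a * log10(s_i) - b))

which is strictly decreasing in ``s_i`` and bounded in (0, 1).  ``b`` sets the
inflection point (w = 0.5 at s = 10**(b/a)) and ``a > 0`` the steepness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "WeightParams",
    "MappedGene",
    "specificity_score",
    "sigmoid_weight",
]

# Exact rational evaluation is used whenever the binomial denominator fits a
# machine word; beyond that the tail is accumulated in log-space.
_EXACT_LIMIT = 2**63


@dataclass(frozen=True)
class WeightParams:
    """Sigmoid parameters for turning specificity scores into weights.

    ``a`` is the steepness (> 0, dimensionless); ``b`` the offset on the
    ``a * log10(s)`` scale.  The half-point — the score receiving weight 0.5 —
    sits at ``s = 10**(b / a)``.  The defaults anchor the half-point at
    s = 0.05 with steepness 2.
    """

    a: float = 2.0
    b: float = 2.0 * math.log10(0.05)

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError(f"sigmoid steepness a must be > 0, got {self.a}")

    @classmethod
    def from_half_point(cls, half_point_s: float, a: float = 2.0) -> "WeightParams":
        """Parameterize by the score at which the weight equals 0.5."""
        if not 0 < half_point_s <= 1:
            raise ValueError("half_point_s must lie in (0, 1]")
        return cls(a=a, b=a * math.log10(half_point_s))

    @property
    def half_point(self) -> float:
        return 10 ** (self.b / self.a)


@dataclass
class MappedGene:
    """One gene's association record within a mapping result."""

    gene_id: str
    symbol: str | None
    metabolites_in_signature: tuple[str, ...]
    A_i: int
    a_i: int
    s_i: float
    w_i: float
    n_reactions: int
    rank: int = 0


def _validate(M: int, S: int, A_i: int, a_i: int) -> None:
    if not (0 <= S <= M):
        raise ValueError(f"need 0 <= S <= M, got S={S}, M={M}")
    if not (0 <= A_i <= M):
        raise ValueError(f"need 0 <= A_i <= M, got A_i={A_i}, M={M}")
    if not (0 <= a_i <= min(A_i, S)):
        raise ValueError(
            f"need 0 <= a_i <= min(A_i, S), got a_i={a_i}, A_i={A_i}, S={S}"
        )


def hypergeom_sf_exact(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, n), exactly when feasible.

    ``M`` population size, ``K`` marked items, ``n`` draws.  Uses integer
    arithmetic when C(M, n) fits a machine word, otherwise a log-space sum.
    """
    hi = min(K, n)
    if k <= 0:
        return 1.0
    if k > hi:
        return 0.0
    denom = math.comb(M, n)
    if denom < _EXACT_LIMIT:
        num = sum(math.comb(K, j) * math.comb(M - K, n - j) for j in range(k, hi + 1))
        return num / denom
    log_denom = math.lgamma(M + 1) - math.lgamma(n + 1) - math.lgamma(M - n + 1)

    def log_comb(a: int, b: int) -> float:
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    terms = [
        log_comb(K, j) + log_comb(M - K, n - j) - log_denom for j in range(k, hi + 1)
    ]
    m = max(terms)
    return min(1.0, math.exp(m) * sum(math.exp(t - m) for t in terms))


def specificity_score(M: int, S: int, A_i: int, a_i: int) -> float:
    """Upper-tail hypergeometric probability of at least ``a_i`` overlaps.

    Parameters
    ----------
    M : total metabolites in the model universe.
    S : signature metabolites within that universe.
    A_i : metabolites associated with the gene.
    a_i : of those, metabolites overlapping the signature.

    Returns a score in (0, 1]; smaller is more specific.
    """
    _validate(M, S, A_i, a_i)
    # Overlap count is hypergeometric: S draws from M with A_i marked.
    return hypergeom_sf_exact(a_i, M, A_i, S)


def sigmoid_weight(s_i: float, params: WeightParams = WeightParams()) -> float:
    """Sigmoid transform of a specificity score into a weight in (0, 1)."""
    if not 0 < s_i <= 1:
        raise ValueError(f"specificity score must lie in (0, 1], got {s_i}")
    z = params.a * math.log10(s_i) - params.b
    if z >= 0:
        ez = math.exp(-z)
        return ez / (1.0 + ez)
    return 1.0 / (1.0 + math.exp(z))
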