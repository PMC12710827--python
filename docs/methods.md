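# Methods

## Model as knowledge base

A genome-scale metabolic model is loaded as a pure association structure:
metabolites, reactions with signed stoichiometry (negative = consumed,
positive = produced), and the set of genes referenced by each reaction's
gene–protein–reaction (GPR) annotation. GPR Boolean logic distinguishes
isoenzymes (OR) from complex subunits (AND); because the model is never used
to predict whether a reaction can carry flux, that structure is deliberately
flattened — every referenced gene is treated as associated with the
reaction. Reversibility comes from an explicit flag in the toy dialects and
from the bounds sign test (lower < 0 < upper) for SBML-fbc input, since SBML
encodings vary in whether they carry a usable `reversible` attribute.

Reactions are classified on load:

* **exchange** — touches a boundary-condition species, or is single-sided
  (all stoichiometric coefficients share one sign). These are system-boundary
  pseudo-reactions and are never mapping-eligible.
* **transport** — the multiset of compartment-stripped species names is the
  same on both sides but the compartments differ.
* **uncatalyzed** — no gene annotation and neither of the above.
* **enzymatic** — everything else.

Mapping eligibility is: carries at least one gene, and is not an exchange
reaction. This removes uncatalyzed transport automatically while keeping
enzyme-catalyzed transporters, which do encode a real gene–metabolite link.
Compartment codes are stripped from a trailing `[x]` bracket, or from a
trailing `_x` suffix only when `x` is a declared compartment code, to avoid
mangling ordinary identifiers.

## Name resolution and the metabolite universe

Signature names are matched exactly after normalization (trim, case-fold,
collapse internal whitespace, strip compartment suffixes). Fuzzy or synonym
matching is off by default — silent approximate matches are a correctness
hazard in metabolite nomenclature — but a user-supplied synonym TSV is
honored. Unresolved names are always reported, never dropped silently.

By default all compartment instances of a species collapse to a single
signature metabolite, because measured metabolomes carry no compartment
information. Consistently, the specificity universe *M* defaults to the
number of unique compartment-collapsed species in the model
(`universe="collapsed"`); `universe="species"` switches to raw
compartmentalized species for users who want the alternative background
convention. A gene's neighborhood *Aᵢ* is counted over the same convention,
restricted to its mapping-eligible reactions, so *aᵢ ≤ min(Aᵢ, S)* always
holds.

## Specificity score and weight

The score is the upper-tail hypergeometric probability of the observed
gene–signature overlap (see README for the formula). Evaluation is exact —
integer arithmetic via `math.comb` — whenever `C(M, S)` fits a 64-bit word,
and switches to a log-gamma/log-sum-exp accumulation beyond that; both paths
agree with `scipy.stats.hypergeom.sf` to ≤ 1e−9 relative error in tests, and
with exhaustive enumeration to ≤ 1e−12 absolute for small universes.

The sigmoid weight `wᵢ = 1/(1 + exp(a·log10 sᵢ − b))` is implemented exactly
in this offset form. Because the original weighting constants are not
standardized anywhere, the defaults anchor the half-point at a conventional
significance level: `a = 2`, `b = 2·log10(0.05) ≈ −2.602`, i.e. a gene with
sᵢ = 0.05 receives weight 0.5. An alternative `half_point_s`
parameterization (`b = a·log10(half_point_s)`) is exposed for users who
prefer to think in score units; both are available in the library, the
pipeline config and the CLI.

Ranking of mapped genes is ascending in sᵢ, with ties broken by the number
of catalyzed reactions and then lexicographic gene id, so output order is
fully deterministic.

## Weighted over-representation analysis

Weight-adjusted counts use round-half-up, `⌊½ + x⌋`, not banker's rounding —
this is the convention the weighted test is defined with, and the reduction
property (all weights 1 ⇒ classical ORA, field by field) depends on it.
Only the query-side counts `n_w` and `k_w` are weighted; the background size
*N* and set size *K* are not. This asymmetry is a documented convention of
the weighted test, not an oversight: weights encode confidence in the
*query* membership of each mapped gene. After rounding, `k_w` is clamped to
`min(n_w, K)` so the tail sum is always over valid support.

The default background is the model's full enzyme-coding gene complement;
custom backgrounds are accepted (mapped genes outside it are dropped with a
warning). Degenerate rows — a set with no members in the background, or a
weighted query that rounds to zero — are kept with p = 1 rather than
dropped, so row counts stay stable for downstream pathway-overlap testing.
Benjamini–Hochberg adjustment (statsmodels' step-up implementation,
cross-checked in tests against an independently coded oracle) is applied
within each collection separately.

## Evaluation statistics

The single-molecule concordance test restricts both the mapped-gene set and
the differentially-expressed set to the background `GEM genes ∩ measured
genes` and applies the one-sided upper-tail hypergeometric test; it is
numerically identical to Fisher's exact test with the `greater` alternative
on the corresponding 2×2 table (verified on random tables in the suite).
The one-sided form is the primary contract because the overlap hypothesis is
directional. The pathway-level test is the same statistic over
enriched-pathway name sets, with an eligibility background of pathways
having at least `min_genes` (default 5, configurable) members in each side's
gene universe — the representation threshold has no canonical value, so it
is surfaced as a parameter rather than hidden.

The global uniformity check is a Kolmogorov–Smirnov test against
Uniform(0,1). The default alternative is skew-to-zero:
`D⁺ = maxᵢ(i/n − x₍ᵢ₎)` with the exact one-sided Smirnov p-value, matching
the directional hypothesis that overlap p-values pile up near zero; the
two-sided statistic and distribution are available as an option. On the
packaged benchmark columns the one- and two-sided statistics coincide.
Significance counting over p-value matrices uses strict inequality
(p < α).

## Packaged benchmark tables

`gemsig/data/` ships the transcribed overlap counts and p-values of an
eleven-comparison paired-omics benchmark (two mapping rules; single-molecule
level, and pathway level across five gene-set collections). Three of the
four KS statistics recomputed from these columns (0.77 and 0.62 at the
single-molecule level, 0.33 pathway non-directional) match the published
values to two decimals, and the recomputed non-directional pathway p-value
matches to all printed digits. The pathway-directional column yields
D = 0.3456 from the printed p-values, whereas the published statistic/p-value
pair (0.34, 2.32e−6) is internally consistent only with D ≈ 0.337 — the
printed per-comparison table and the published summary statistic evidently
derive from slightly different analysis runs, and the package reports the
value computed from the shipped inputs. Similarly, recomputing the
single-molecule p-values from the shipped counts reproduces 8 of 11
comparisons exactly under both rules; three directional entries differ from
the printed p-values by exact powers of ten (identical mantissas), and one
comparison (M005 liver) disagrees substantively, so the transcribed p-values
— not recomputations — drive the KS and counting analyses.

## Synthetic fixtures

The generator emulates only the combinatorial structure the algorithm
consumes: 1–3 reactants and products per internal reaction (chained so the
network is connected), a configurable fraction of single-sided exchange
reactions carrying no genes, reversibility as a Bernoulli draw, and gene
attachment with a configurable mean number of reactions per gene
(promiscuity) capped at 3 genes per reaction. Default sizes (30 metabolites,
25 reactions, 12 genes, 30% reversible, 15% exchange, promiscuity 2) give
networks small enough to brute-force but rich enough that specificity
ranking is non-trivial. Metabolite names are synthetic (`MET0001`, …);
nomenclature realism is out of scope, so resolution tests exercise exact
matching only. What passing tests show is that the mapping, scoring and
enrichment machinery is correct on known ground truth; they say nothing
about name-resolution coverage or annotation quality on real metabolomes,
which depend on the input nomenclature and the chosen GEM.

All randomness in a generator call flows from one seeded `numpy` generator
consumed in fixed order (topology, reversibility, gene attachment, signature
draws), so outputs are byte-reproducible across platforms.

Problem sizes used in the shipped analyses: exhaustive-enumeration
cross-checks run over every parameter combination with universe ≤ 12 in the
test suite and ≤ 10 in the acceptance script; reduction checks use 100
random configurations with backgrounds up to 120 genes; structural and
recovery checks use 50 seeded 30-metabolite models each. These sizes make
every oracle exactly enumerable while keeping the full analysis suite in the
order of seconds.

## Known limitations

* Name resolution is exact-match only; real signatures annotated outside the
  model's nomenclature need an external mapping step (or the synonym table).
* The weighted test's integer rounding makes p-values step-wise in the
  weights; very small weight changes may not change the result at all.
* The directional rule trusts the model's stoichiometric orientation;
  models with arbitrarily oriented reversible reactions blur the
  directional/non-directional distinction (reversible reactions are counted
  on both sides by design).
* No metabolite identifier translation (HMDB/KEGG/ChEBI), no flux analysis,
  no rank-based GSEA, and no bundled organism models.
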