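# Methods

## Viability calling

Each mouse line contributes genotyped pup counts from a heterozygote ×
heterozygote intercross, where Mendelian segregation predicts 25%
homozygous-null pups. The per-line decision rule, applied in order:

1. hemizygous lines are excluded;
2. litters under 28 pups: viable if ≥ 4 homozygotes were still seen
   (≥ 14% had 28 pups been genotyped), otherwise insufficient;
3. zero homozygotes ⇒ lethal;
4. homozygote fraction < 12.5% **and** one-sided exact binomial
   lower-tail P(X ≤ k; n, 0.25) < α (default 0.05) ⇒ subviable;
5. otherwise viable.

Subviability requires the conjunction of both criteria. The published
rule text is ambiguous on this point, but the conjunction is what makes
the small-litter exception coherent (3/28 = 10.7% is below 12.5% yet
stays viable because P(X ≤ 3) = 0.055), and a one-sided lower-tail test
is the natural choice for a one-directional deficit. The binomial CDF
comes from `scipy.stats.binom`; `call_probabilities` exposes the exact
probability of each call given a true homozygote rate and litter size,
which the synthetic generator uses to flag borderline genes (below).

Gene-level resolution: hemizygous lines exclude the gene; insufficient
lines carry no category; unanimous substantive calls win; disagreement
excludes the gene as conflicting.

**Windows of lethality.** Embryos are scored for a heartbeat at E9.5,
E12.5, E14.5/15.5 and E18.5. A stage is *dead* when 0 live homozygotes
were seen among ≥ 28 scored embryos (the same minimum as the adult
screen), *alive* when any live homozygote was seen. The implementation
enumerates every death interval consistent with the scored stages and
maps each to its group (before E9.5 → early; E9.5–E14.5/15.5 → mid; all
later intervals, including survival to E18.5 in a preweaning-lethal
gene → late). If the consistent intervals span more than one group the
gene is unassigned. This formulation makes the assignment monotone: an
extra "alive" record at a later stage can never move the window
earlier. Cross-stage contradictions (alive after dead) yield
unassigned; same-stage contradictions raise.

## Orthologue selection

Orthologue inferences carry a support count out of 12 methods (tiers:
9–12 good, 5–8 moderate, 1–4 low, 0 none). Pairs are kept when support
is ≥ 5, at least one partner is protein coding, and the edge is the
strict unique maximum among surviving edges of *both* its genes — ties
are rejected, which is how "duplicated maximum scores" are filtered.
One subtlety: removing a rejected edge can only grow the accepted set
(competitor sets shrink), but it can genuinely grow it when the removed
edge was a tied local maximum, so the useful invariant is monotonicity,
not invariance.

## Cell essentiality

Per-gene mean proliferation score over non-missing cell lines (missing
cells are ignored, never imputed; genes with no scores are dropped with
a warning). A gene is essential iff its mean is ≤ the threshold; the
boundary is essential, matching the "≤ −0.45" convention. The threshold
can be refit by maximising F1 (2TP/(2TP+FP+FN), essentials positive)
over a grid, default −1.50…0.00 in 0.01 steps — fine enough to
represent −0.45 exactly; the published search resolution is unstated.
Ties in the maximal F1 are broken toward the grid value closest to the
midpoint of the tied run (then the lower value), which is deterministic
and centres the cut in a separable gap.

## FUSIL binning

lethal+essential → CL; lethal+non-essential → DL;
subviable+non-essential → SV; viable+non-essential → VP (≥ 1
significant phenotype) or VN (none). Essential-scored subviable/viable
genes become SV.outlier / V.outlier; viable genes with < 50% of
scheduled phenotyping procedures complete become V.insuffProcedures
(completeness = procedures_done / procedures_total; the denominator is
the scheduled total, the published note gives only the 50% cut).

Summary percentages are computed by exact decimal division and rounded
half-to-even at two decimals. Half-to-even (rather than half away from
zero) is what reproduces the published table on the exact-half cells:
2/320 = 0.625% prints as 0.62 and 318/320 = 99.375% as 99.38, which is
R's default rounding.

## Enrichment statistics

2×2 tables per (bin, resource): disease genes in/outside the bin versus
genes annotated in *no* resource in/outside the bin — genes annotated
only in other resources drop out of that resource's table. The
comparison universe is the five FUSIL bins only (exclusion labels are
not part of it). The Wald odds ratio is (ad)/(bc) with the log-scale
normal CI exp(ln OR ± z·√(1/a+1/b+1/c+1/d)); zero-cell tables report
0/∞ with an undefined CI and a degenerate flag (no continuity
correction by default; a Haldane-corrected variant is provided
separately). Fisher's two-sided p uses the probability-ordering
convention and is computed in exact integer arithmetic: conditioned on
the margins, every table's hypergeometric probability shares the
denominator C(n, c1), so "at most as probable as observed" reduces to
an integer comparison of numerators and the tie handling is exact
rather than subject to a floating-point epsilon. Benjamini–Hochberg
adjustment (via statsmodels) is applied across the bins of each
resource; its output equals the direct step-up formula and is monotone
in the inputs, and the adjusted vector is a fixed point of the step-up
monotone envelope — note that re-applying the *full* adjustment is not
an identity ([0.1, 0.9] → [0.2, 0.9] → [0.4, 0.9]), so idempotence
holds only in the envelope sense. Term over-representation is a
one-sided hypergeometric upper tail against an explicit universe, BH
across terms.

## Gene features

* **Recombination:** each rate interval is assigned to the gene with
  minimal genomic distance on its chromosome (0 for overlaps; 0-based
  half-open coordinates), distance ties to the upstream gene; per-gene
  rate is the unweighted mean of assigned interval rates. Whether the
  original mapping used interval midpoints is unstated; full-interval
  distance is used here.
* **Expression decorrelation:** greedy, input-order retention — keep a
  tissue iff |Spearman ρ| ≤ 0.8 against every already-retained tissue
  (the published cut-off is unstated; 0.8 is the package default).
  Constant columns have undefined ρ and are retained with a warning.
* **Network:** edges with combined score > 0.7 form an undirected
  simple graph. Topological coefficient of node n with k_n ≥ 2
  neighbours: average over all nodes m sharing ≥ 1 neighbour of
  J(n,m)/k_n, J = shared neighbours + 1 if directly linked; nodes with
  k_n < 2 get 0 (the standard network-analyzer definition, reimplemented
  because networkx does not ship it).
* **Paralogues:** a gene is paralogue-free when it has no partner at
  ≥ 30% amino-acid identity.
* **Onset / systems:** earliest onset category in a fixed order
  (antenatal < … < elderly); affected systems = count of unique
  top-level phenotype terms.
* **Pairwise bin comparisons:** two-sided Wilcoxon rank-sum per bin
  pair, BH across the pairs of one feature (the published figure
  reports pairwise significance without naming the test; the rank-sum
  test matches the notched-box-plot presentation). Pairs with < 3 genes
  in a bin are skipped.

## Prioritisation

Funnel: DL genes → not in any disease resource → constraint
disjunction (HI < 10 | LOEUF < 0.35 | pLI > 0.90; a missing score fails
its own clause only, so a gene lacking all three cannot pass) →
consortium evidence (Venn over 100KGP/DDD/CMG) → final criteria:
100KGP evidence **and** (DDD **or** CMG), variants absent from gnomAD,
o/e missense < 0.8 (intolerant genes kept). Shared-annotation rates
against a reference set (protein family, lowest-level pathway, direct
high-confidence interaction) exclude self-matches when a gene is itself
in the reference. gnomAD presence is consumed as a per-gene boolean;
variant-level allele matching is out of scope.

## Synthetic data generator

Defaults define the simulated study conditions:

| parameter | default | rationale |
|---|---|---|
| class proportions | CL .09, DL .17, SV .09, VP .42, VN .07, V.insuff .14, outliers .01+.01 | margins of the published cross-tabulation; the 2% remainder split equally between the outlier groups |
| homozygote rate | 0 (lethal), U(0.01, 0.08) (subviable), 0.25 (viable) | lethal = no live homozygotes; subviable = below half the Mendelian rate |
| litter total | 28 + Poisson(20), 2% forced to U{10..27} | litter-size distributions are not published; this keeps every fully-powered line at ≥ 28 pups while exercising the small-litter paths |
| mean score | N(−1, 0.2) essential, N(0, 0.2) non-essential; per-cell-line noise sd 0.3; 1% missing cells | the −1/0 separation implied by the score distributions of essential vs non-essential genes |
| outlier scores | U(−0.60, −0.46) | "below but very close to" the −0.45 threshold |
| disease flags | baseline 0.20; true_bin_or {DL: 2.6} | the headline DL enrichment; other bins at baseline so the planted odds ratio is identifiable from the bin-vs-rest table |
| candidates | 10% of DL non-disease genes; passing constraints; consortium hit rates 0.95/0.75/0.50 vs 0.05 background; gnomAD 0.05 vs 0.5 | makes funnel recall/precision measurable |
| orthology | support U{9..12}; 2% of genes get a duplicated-maximum decoy edge | exercises the tie-rejection path |

Feature tables (recombination, expression, network degree, complex and
paralogue membership, onset, systems) are drawn from class-conditional
families with monotone trends across bins (e.g. CL lowest
recombination, highest expression and degree); only the ordering, and
for constraint scores the position relative to the filter thresholds,
carries signal.

**Borderline genes.** The truth table flags genes whose *latent
parameters* put them at material risk of an honest miscall:
essentiality-borderline when the latent mean score is within 0.1 of the
−0.45 threshold, and viability-borderline when the exact binomial
probability of the caller returning a different category than the
latent one (given the latent homozygote rate and realised litter size)
exceeds 1%, or the litter is under 28 pups. The flag is computed at
generation time from the truth alone, never from pipeline output. Under
the default litter distribution a truly viable line is miscalled
subviable with probability ≈ 1–1.7% depending on litter size, so most
viable genes carry the flag; the end-to-end recovery statistic is
therefore reported on the non-borderline subset, which is exactly the
subset for which near-perfect recovery is an informative check rather
than a coin flip on the binomial tail.

**What the generator does not emulate:** multiple lines/alleles per
gene (one line per gene by default), centre effects, litter structure,
copy-number artefacts in the score matrix, realistic network topology
(degree-weighted random pairing, not scale-free), ontology structure in
the term tables, or real identifier schemes. Passing tests therefore
show the pipeline's logic is correct under the stated generative
assumptions, not that real-data idiosyncrasies are handled.

## Determinism and problem sizes

All randomness flows from a single seeded `numpy.random.Generator`; a
fixed config and seed reproduce every table and report bit for bit
(checked by file checksums). The test suite and the acceptance script
use 5000-gene simulations for calibration checks (200 replicates for
the odds-ratio recovery, 50 for threshold recovery) and smaller bundles
(600–2000 genes) for behavioural tests; these sizes give comfortable
Monte-Carlo margins for the thresholds being asserted.

## Known limitations

* The conjunction reading of the subviability rule and the one-sided
  test are documented choices, not a verified restatement of the
  production statistical pipeline.
* Fisher's exact arithmetic enumerates the full support; tables with
  margins in the tens of thousands would be slow (the analysis uses a
  handful of tables per run, so this is not a practical constraint).
* The embryo screen generator emits consistent records per window; the
  window-assignment code handles ambiguity and contradictions, but
  those paths are exercised only by hand-written cases.
* GO/Reactome content, semantic reduction of enriched terms, phenotype
  similarity scoring and variant-level annotation are out of scope;
  term→gene and evidence tables are plain inputs.
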