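# fusil

Cross-species gene essentiality binning and disease-gene prioritisation.

## The problem

Knowing how intolerant a gene is to loss of function (LoF) helps decide
whether a candidate variant found in a patient is plausibly causal. Two
large-scale resources measure essentiality in complementary ways: mouse
knockout programmes genotype pups from heterozygote intercrosses to call
each gene **lethal**, **subviable** or **viable** at the organism level,
and CRISPR proliferation screens across hundreds of cancer cell lines
score how much each gene's loss impairs cell survival. Crossing the two
axes yields the **FUSIL** categorisation (Full Spectrum of Intolerance
to Loss-of-function) — five mutually exclusive bins:

| bin | mouse | human cells |
|-----|-------|-------------|
| CL  | lethal | essential (mean proliferation score ≤ −0.45) |
| DL  | lethal | non-essential |
| SV  | subviable | non-essential |
| VP  | viable, ≥1 significant phenotype | non-essential |
| VN  | viable, no significant phenotype | non-essential |

The **DL** bin — genes a mouse embryo cannot develop without, yet which
cells tolerate losing — is strongly enriched for Mendelian and
especially developmental-disorder genes, which motivates a staged
candidate funnel: DL genes → not yet disease-associated → likely
haploinsufficient (HI percentile < 10 **or** LOEUF < 0.35 **or**
pLI > 0.90) → replicated de novo evidence across sequencing consortia →
variants absent from gnomAD and o/e missense < 0.8.

This package implements the whole analysis as a tested, reusable
library: viability calling (exact binomial deficit test against the
Mendelian 25%), windows-of-lethality assignment from embryo heartbeat
screens, one-to-one orthologue selection, F1-optimised essentiality
thresholding, FUSIL binning, Wald/Fisher/BH disease-gene enrichment,
per-gene feature computation (recombination rates, network degree and
topological coefficient, expression, paralogy, onset, affected
systems), and the prioritisation funnel — plus a synthetic-data
generator with configurable latent truth so every stage is testable
end to end without any external download.

## Worked example

```bash
python examples/05_full_pipeline.py
```

simulates 2000 genes × 50 cell lines, runs the full cascade and prints:

```
cross-tabulation (mouse category x cell essentiality):
                      mouse_category cell_category  n_genes  pct_overlap
                              Lethal     Essential      175        33.91
                              Lethal Non-essential      341        66.09
                           Subviable     Essential       13         6.77
                           Subviable Non-essential      179        93.23
...
DL disease enrichment (omim-like resource): OR=2.49 [1.88, 3.30], adjusted p=4.20e-09

prioritisation funnel: {'dl': 341, 'non_disease': 220, 'prioritised': 84, 'with_any_evidence': 36, 'final': 16}

label recovery on non-borderline genes: 0.9982
```

Reading the numbers: about a third of mouse-lethal genes are also cell
essential (CL) and two thirds are developmental lethal (DL), matching
the configured class proportions; the simulated DL disease enrichment
(generated at odds ratio 2.6) is estimated at 2.49 with a significant
BH-adjusted Fisher p; the funnel shrinks monotonically from 341 DL
genes to 16 final candidates; and 99.8% of genes far from the decision
boundaries are assigned their true latent bin.

The other `examples/` scripts each demonstrate one capability
(simulation, viability calls, threshold fitting, enrichment recovery,
lethality windows). A thin CLI wraps the same functions:
`fusil simulate|call-viability|map-orthologues|call-essentiality|run`.

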