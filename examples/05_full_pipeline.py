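"""Run the full cascade on simulated data and audit it against truth.

Simulation -> viability -> orthology -> essentiality -> FUSIL binning
-> enrichment -> features -> prioritisation, with a truth-vs-called
label recovery summary at the end.
"""

from fusil.pipeline import PipelineConfig, run_pipeline
from fusil.synthetic_data import SyntheticConfig

config = PipelineConfig(
    simulate=SyntheticConfig(n_genes=2000, n_cell_lines=50, seed=7),
    outdir="scratch/example_run",
)
report = run_pipeline(config)

print("cross-tabulation (mouse category x cell essentiality):")
print(report.table1.to_string(index=False))

dl = report.enrichment.query("resource == 'omim' and group == 'DL'").iloc[0]
print(f"\nDL disease enrichment (omim-like resource): "
      f"OR={dl.odds_ratio:.2f} [{dl.ci_low:.2f}, {dl.ci_high:.2f}], "
      f"adjusted p={dl.p_adjusted:.2e}")

print(f"\nprioritisation funnel: {report.funnel_counts}")
print(f"final candidates: {report.final_genes}")
print(f"\nlabel recovery on non-borderline genes: {report.recovery_rate:.4f}")
print("Recovery counts the genes whose assigned bin equals their latent "
      "class among genes far from the decision boundaries.")
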