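"""Primary viability calls from genotyped pup counts.

A het x het intercross should yield 25% homozygous-null pups; zero
homozygotes among >= 28 pups means lethal, a significant deficit below
12.5% means subviable, and small litters need >= 4 homozygotes for a
viable call.
"""

from fusil.viability import ViabilityObservation, call_primary_viability

cases = [
    ("zero homozygotes", 28, 0),
    ("Mendelian ratio", 28, 7),
    ("deficit, significant", 28, 2),
    ("deficit, not significant", 28, 3),
    ("small litter, enough homs", 27, 4),
    ("small litter, too few", 20, 1),
]
for label, n_total, n_hom in cases:
    obs = ViabilityObservation("L1", "G1", "autosomal", n_total, n_hom)
    call = call_primary_viability(obs)
    p = f", binomial p={call.binom_p:.4f}" if call.binom_p == call.binom_p else ""
    print(f"{label:28s} {n_hom:>2d}/{n_total:<3d} -> {call.call}{p}")

print("\n2/28 is subviable (p=0.0166 < 0.05) while 3/28 stays viable "
      "(p=0.055): both the <12.5% fraction and the binomial test must agree.")
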