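"""Paired differential expression and E/S histo-molecular deconvolution.

Builds a paired expression matrix with known epithelioid/sarcomatoid
mixtures and planted DE genes, calls DE with the FPKM>=1 / |delta VST|>1
rule and recovers the E/S scores per biopsy.
"""

from mesohet.expression import call_de_genes, deconvolve_es, es_heterogeneity
from mesohet.synthetic import (
    build_truth,
    make_reference_profiles,
    simulate_clone_structure,
    simulate_expression_pair,
)

tree, comps = simulate_clone_structure(5, 1, 3, "mixed", seed=3)
truth = build_truth(tree, comps)
e_prof, s_prof = make_reference_profiles(n_genes=1000, seed=3)
pair = simulate_expression_pair(
    truth, n_genes=1000, e_profile=e_prof, s_profile=s_prof,
    noise_sd=0.2, n_de=50, seed=4,
    es_scores={"A": (0.80, 0.20), "B": (0.62, 0.38)},
)

de = call_de_genes(pair)
print(f"DE genes called: {len(de)} (planted: {len(truth.de_genes)})")

scores = {s: deconvolve_es(pair.vst[s], e_prof, s_prof) for s in pair.sites}
for s, sc in scores.items():
    print(f"site {s}: E.score={sc.e_score:.3f}  S.score={sc.s_score:.3f}")
flag, delta = es_heterogeneity(scores["A"], scores["B"])
print(f"E/S heterogeneity (>10% change): {flag}  (delta={delta:.3f})")
# The deconvolved scores recover the simulated mixture proportions; a delta
# above 0.10 marks a histo-molecular gradient shift between the two sites.
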