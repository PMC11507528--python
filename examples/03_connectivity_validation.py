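"""Score perturbation profiles for connectivity with a disease signature.

Generates ranked expression profiles for three in-silico perturbations —
one planted to mimic the disease signature (up-set near the top, down-set
near the bottom), one to reverse it, one random — then computes each
profile's WTCS and its signed percentile against 1000 random-permutation
null profiles.  |percentile| > 90 flags a strong match or reversal.
"""

import omixprox as ox

up = [f"UPGENE{i:02d}" for i in range(15)]
down = [f"DNGENE{i:02d}" for i in range(10)]
profiles = ox.gen_perturbation_profiles(
    n_profiles=3, n_genes=400,
    planted=["positive", "negative", "null"], seed=3,
    query_up=up, query_down=down,
    perturbed_genes=["SPP1", "SMAD3", "CTRL"],
)
results = ox.connectivity_scores(profiles, up, down, n_null=1000, seed=3)
for r in results:
    print(f"{r.perturbed_gene:6s} {r.perturbation:15s} "
          f"wtcs={r.wtcs:+.3f} percentile={r.percentile:+7.1f} flag={r.flag}")
# A positive flag means the perturbation drives the transcriptome toward
# the disease profile; a negative flag means it reverses the profile,
# which is the pattern sought in a repurposing candidate.
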