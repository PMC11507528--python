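"""Rank candidate genes by summed network distance to omics signatures.

Builds a scored interaction network with three candidate genes planted at
known hop distances from the transcriptome, genome, and protein-level
signature sets, filters to high-confidence edges (score >= 700), computes
each candidate's distance profile (d_T, d_G, d_P) and sum, and applies the
selection rule: every component 0 or 1 with at least one 0.
"""

import omixprox as ox

net = ox.gen_network(
    n_nodes=80, mean_degree=3.0, seed=7,
    sig_sizes={"transcriptome": 5, "genome": 5, "protein": 5},
    planted_geometry={
        "CANDA": {"transcriptome": 0, "genome": 1, "protein": 1},
        "CANDB": {"transcriptome": 1, "genome": 1, "protein": 1},
        "CANDC": {"transcriptome": 0, "genome": 1, "protein": 2},
    },
)
interactome = ox.filter_by_score(net.edges, min_score=700)
print("network:", interactome.stats())

sig = net.signatures
pool = ox.direct_neighbors(
    interactome, [sig["transcriptome"], sig["genome"], sig["protein"]]
)
profiles = ox.distance_profiles(
    interactome, sig["transcriptome"], sig["genome"], sig["protein"], pool
)
ranked = ox.rank_candidates(profiles)
cand = ranked[ranked["gene"].str.startswith("CAND")]
print(cand.to_string(index=False))
print("selected:", sorted(ox.select_candidates(profiles)))
# CANDA sits at distances (0, 1, 1): a transcriptome signature gene that
# directly interacts with genome- and protein-level signature genes, so it
# alone satisfies the selection rule; CANDB has no level of its own and
# CANDC is two hops from the protein level.
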