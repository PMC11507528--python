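"""Distance-based candidate ranking and the 0/1 selection rule.

For each candidate gene i the model computes the minimal hop distance to
the signature genes of each omics level (transcriptomics d_T, genomics
d_G, protein-level d_P = proteome plus metabolome-derived proteins) and
sums them:

    d_sum(i) = min_j d_ij(T) + min_j d_ij(G) + min_j d_ij(P)

A distance of 0 on a level means the candidate is itself a signature gene
on that level; a distance of 1 means it directly interacts with one.
The prioritized set consists of candidates whose every component is 0 or 1
with at least one 0 — signature genes on some level that are also direct
neighbors of signature genes on the other levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import InteractionNetwork, multi_source_distance

__all__ = ["distance_profiles", "select_candidates", "rank_candidates"]

_UNREACHABLE = np.inf


def distance_profiles(
    net: InteractionNetwork,
    sig_t,
    sig_g,
    sig_p,
    pool,
) -> pd.DataFrame:
    """One distance profile (d_T, d_G, d_P, d_sum) per pool gene.

    ``sig_t``, ``sig_g``, ``sig_p`` are the transcriptome, genome, and
    protein-level signature sets (SignatureSet or plain gene sets).
    Unreachable components are inf, and any unreachable component makes
    d_sum inf.
    """
    pool = sorted({g.upper() for g in pool})
    if not pool:
        raise ValueError("candidate pool must be non-empty")
    levels = {"d_T": sig_t, "d_G": sig_g, "d_P": sig_p}
    cols: dict[str, list[float]] = {}
    for name, sig in levels.items():
        genes = sig.genes if hasattr(sig, "genes") else set(sig)
        if not genes:
            raise ValueError(f"empty signature set for level {name[2:]}")
        dist = multi_source_distance(net, genes)
        cols[name] = [dist.get(g, _UNREACHABLE) for g in pool]
    profiles = pd.DataFrame({"gene": pool, **cols})
    profiles["d_sum"] = profiles[["d_T", "d_G", "d_P"]].sum(axis=1)
    return profiles


def select_candidates(
    profiles: pd.DataFrame,
    max_component: int = 1,
    min_zero_levels: int = 1,
) -> set[str]:
    """Genes whose every distance component is <= max_component and that
    are signature genes (component 0) on at least min_zero_levels levels.

    Unreachable components disqualify a gene: an infinite distance means no
    interaction evidence links it to that omics level.
    """
    comp = profiles[["d_T", "d_G", "d_P"]].to_numpy(float)
    ok = (comp <= max_component).all(axis=1) & (
        (comp == 0).sum(axis=1) >= min_zero_levels
    )
    return set(profiles.loc[ok, "gene"])


def rank_candidates(profiles: pd.DataFrame) -> pd.DataFrame:
    """Deterministic total ordering of candidates by overall proximity.

    Ascending d_sum (unreachable last); ties broken by the number of zero
    components (more first), then gene symbol.  Adds ``rank`` (1-based) and
    ``selected`` (0/1 under the default selection rule).
    """
    out = profiles.copy()
    comp = out[["d_T", "d_G", "d_P"]].to_numpy(float)
    out["_zeros"] = (comp == 0).sum(axis=1)
    out = out.sort_values(
        by=["d_sum", "_zeros", "gene"],
        ascending=[True, False, True],
        ignore_index=True,
    ).drop(columns="_zeros")
    out["rank"] = np.arange(1, len(out) + 1)
    selected = select_candidates(profiles)
    out["selected"] = out["gene"].isin(selected).astype(int)
    return out
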