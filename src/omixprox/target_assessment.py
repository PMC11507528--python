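"""Druggability annotation, drug joining, and connectivity scoring.

Candidate genes are annotated with druggable-genome tiers (Tier 1 =
targets of approved drugs or clinical candidates, Tiers 2-3 = similarity
to known targets) and joined against a flat drug-target table.  In-silico
validation scores each perturbation expression profile (knockout or
over-expression of a candidate gene in a cell line) for connectivity with
the disease signature: a Kolmogorov-Smirnov running-sum enrichment score
for the up- and down-regulated query sets is combined into a weighted
total connectivity score (WTCS) in [-1, 1], then converted to a signed
percentile in [-100, 100] against an ensemble of random-permutation null
profiles.  |percentile| > 90 flags a strong match (positive: the
perturbation mimics the disease profile) or reversal (negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transcriptomics import bh_adjust, hypergeometric_overlap

__all__ = [
    "DruggabilityRecord",
    "PerturbationProfile",
    "ConnectivityResult",
    "annotate_druggability",
    "map_drugs",
    "weighted_ks_es",
    "wtcs",
    "null_rankings",
    "percentile_normalize",
    "connectivity_scores",
    "go_overrepresentation",
]

VALID_TIERS = {"1", "2", "3", "none"}


@dataclass(frozen=True)
class DruggabilityRecord:
    gene: str
    tier: str  # "1" | "2" | "3" | "none"


@dataclass
class PerturbationProfile:
    """A complete ranking of profile genes after perturbing one gene.

    rank 1 = most up-regulated.  ``ranking`` is a permutation of the
    profile's gene universe.
    """

    perturbed_gene: str
    perturbation: str  # knockout | overexpression
    cell_line: str
    ranking: list[str]

    def __post_init__(self) -> None:
        if self.perturbation not in ("knockout", "overexpression"):
            raise ValueError("perturbation must be knockout or overexpression")
        if len(set(self.ranking)) != len(self.ranking):
            raise ValueError("ranking must be a permutation (no duplicates)")


@dataclass(frozen=True)
class ConnectivityResult:
    profile_id: str
    perturbed_gene: str
    perturbation: str
    wtcs: float
    percentile: float
    flag: str  # positive | negative | none


def annotate_druggability(genes, table: pd.DataFrame):
    """Annotate each gene with its druggability tier.

    ``table`` has columns ``gene`` and ``tier`` (values 1, 2, 3).  Genes
    absent from the table get tier ``none``.  Returns ``(records, counts)``
    where counts maps tier -> number of genes.
    """
    if not {"gene", "tier"} <= set(table.columns):
        raise ValueError("druggability table needs gene and tier columns")
    tiers = {}
    for g, t in zip(table["gene"], table["tier"]):
        t = str(t).strip()
        if t not in VALID_TIERS - {"none"}:
            raise ValueError(f"malformed tier value {t!r} for gene {g}")
        tiers[str(g).upper()] = t
    records = [
        DruggabilityRecord(gene=g, tier=tiers.get(g, "none"))
        for g in sorted({x.upper() for x in genes})
    ]
    counts = {t: 0 for t in ("1", "2", "3", "none")}
    for r in records:
        counts[r.tier] += 1
    return records, counts


def map_drugs(genes, drug_targets: pd.DataFrame) -> pd.DataFrame:
    """Inner-join candidate genes to a drug-target table.

    ``drug_targets`` has columns ``drug_id``, ``drug_name``, ``gene``.
    Deduplicates by (drug_id, gene).  The result carries one row per
    retained pair, sorted for deterministic output.
    """
    required = {"drug_id", "drug_name", "gene"}
    if not required <= set(drug_targets.columns):
        raise ValueError(f"drug-target table needs columns {sorted(required)}")
    genes = {g.upper() for g in genes}
    hits = drug_targets.assign(gene=drug_targets["gene"].astype(str).str.upper())
    hits = hits[hits["gene"].isin(genes)]
    hits = hits.drop_duplicates(subset=["drug_id", "gene"])
    return hits.sort_values(["gene", "drug_id"], ignore_index=True)


def weighted_ks_es(ranking, query) -> float:
    """KS running-sum enrichment score of a query gene set in a ranking.

    Walking the ranking from rank 1, the running sum gains 1/|Q| at each
    query gene and loses 1/(N-|Q|) at each non-query gene; the score is the
    deviation of largest magnitude, so a query concentrated at the top
    scores toward +1 and at the bottom toward -1.
    """
    ranking = list(ranking.ranking) if hasattr(ranking, "ranking") else list(ranking)
    query = {g.upper() for g in query}
    if not query:
        raise ValueError("query set must be non-empty")
    universe = [g.upper() for g in ranking]
    missing = query - set(universe)
    if missing:
        raise ValueError(f"query genes missing from profile: {sorted(missing)}")
    n = len(universe)
    nq = len(query)
    if nq == n:
        return 0.0  # degenerate: every gene is a hit
    is_hit = np.fromiter((g in query for g in universe), bool, count=n)
    steps = np.where(is_hit, 1.0 / nq, -1.0 / (n - nq))
    running = np.cumsum(steps)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    # deviation of largest magnitude; exact ties resolve positive
    if running[i_max] >= -running[i_min]:
        return float(running[i_max])
    return float(running[i_min])


def wtcs(profile, up, down) -> float:
    """Weighted total connectivity score of an up/down query signature.

    ES is computed for the up- and down-set separately; when the two have
    opposite signs (the coherent case: up-set enriched where the down-set
    is depleted) the score is (ES_up - ES_down)/2, otherwise 0.
    """
    up = {g.upper() for g in up}
    down = {g.upper() for g in down}
    if up & down:
        raise ValueError(f"up and down sets overlap: {sorted(up & down)}")
    es_up = weighted_ks_es(profile, up)
    es_down = weighted_ks_es(profile, down)
    if es_up * es_down < 0:
        return (es_up - es_down) / 2.0
    return 0.0


def null_rankings(universe, n: int, seed: int) -> list[list[str]]:
    """Seeded ensemble of uniformly random permutations of the universe."""
    rng = np.random.default_rng(seed)
    universe = list(universe)
    return [list(rng.permutation(universe)) for _ in range(n)]


def percentile_normalize(wtcs_value: float, nulls, up, down):
    """Signed percentile of a WTCS against a null ensemble.

    ``nulls`` is a sequence of null rankings (>= 100 for stable
    percentiles; see :func:`null_rankings`) or a precomputed array of null
    WTCS values.  The percentile is the percentage of null |WTCS| values
    strictly below |wtcs_value|, carrying the sign of ``wtcs_value``
    (0 stays 0).  Returns ``(percentile, flag)`` with flag positive when
    percentile > 90, negative when < -90, else none.
    """
    nulls = list(nulls)
    if len(nulls) < 100:
        raise ValueError("need >= 100 null profiles for stable percentiles")
    if np.isscalar(nulls[0]):
        null_vals = np.asarray(nulls, dtype=float)
    else:
        null_vals = np.array([wtcs(r, up, down) for r in nulls])
    pct = 100.0 * float(np.mean(np.abs(null_vals) < abs(wtcs_value)))
    if wtcs_value < 0:
        pct = -pct
    elif wtcs_value == 0:
        pct = 0.0
    flag = "positive" if pct > 90 else "negative" if pct < -90 else "none"
    return pct, flag


def connectivity_scores(
    profiles,
    up,
    down,
    n_null: int = 1000,
    seed: int = 0,
) -> list[ConnectivityResult]:
    """Score every perturbation profile against the disease signature.

    All profiles are assumed to share one gene universe (taken from the
    first profile); one seeded null ensemble serves them all.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no perturbation profiles given")
    universe = profiles[0].ranking
    nulls = null_rankings(universe, n_null, seed)
    null_vals = np.array([wtcs(r, up, down) for r in nulls])
    results = []
    for i, prof in enumerate(profiles):
        w = wtcs(prof, up, down)
        pct, flag = percentile_normalize(w, list(null_vals), up, down)
        results.append(
            ConnectivityResult(
                profile_id=f"profile_{i:03d}",
                perturbed_gene=prof.perturbed_gene,
                perturbation=prof.perturbation,
                wtcs=w,
                percentile=pct,
                flag=flag,
            )
        )
    return results


def go_overrepresentation(
    genes,
    annotation: dict[str, set[str]],
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a gene set.

    Each term's member set is tested for overlap with ``genes`` against
    ``universe``; p values are BH-adjusted across terms and rows with
    adj_p < alpha are returned sorted by adj_p, then descending overlap.
    """
    if not annotation:
        raise ValueError("annotation must be non-empty")
    genes = {g.upper() for g in genes}
    universe = {g.upper() for g in universe}
    rows = []
    for term, members in annotation.items():
        members = {m.upper() for m in members} & universe
        if not members:
            continue
        p = hypergeometric_overlap(genes, members, universe)
        rows.append(
            {"term": term, "n_term": len(members),
             "n_overlap": len(genes & members), "p": p}
        )
    table = pd.DataFrame(rows)
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    table = table[table["adj_p"] < alpha]
    return table.sort_values(
        ["adj_p", "n_overlap"], ascending=[True, False], ignore_index=True
    )
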