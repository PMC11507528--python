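"""Synthetic inputs with planted ground truth for every pipeline stage.

Generators for the five input families the pipeline consumes: a two-group
log2 expression study with planted differentially expressed genes, a
scored undirected interaction network with signature sets planted at exact
hop distances, ranked perturbation profiles with planted
positive/negative connectivity, a scored metabolite-reaction-protein
table, and toy druggability/drug-target tables.  Every generator is a
pure function of its seed, and the network generator re-derives its truth
distances from the emitted graph by BFS — construction is verified, never
trusted.

Writers emit the same plain-text dialects the pipeline readers consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionStudy",
    "PlantedNetwork",
    "GeometryError",
    "gen_expression",
    "gen_network",
    "gen_perturbation_profiles",
    "gen_reaction_table",
    "gen_target_tables",
    "gen_pipeline_inputs",
    "write_expression_study",
    "write_network_files",
    "write_profiles",
]

NETWORK_LEVELS = ("transcriptome", "genome", "protein")
MIN_PLANTED_SCORE = 700  # planted-path edges always survive the filter


class GeometryError(ValueError):
    """Requested planted geometry cannot be realized exactly."""


@dataclass
class ExpressionStudy:
    """Two-group log2 expression matrix with planted effect truth.

    ``matrix`` is genes x samples; ``groups`` maps sample id -> label;
    ``truth`` records each gene's planted status (up/down/null) and the
    planted log2 fold change.
    """

    matrix: pd.DataFrame
    groups: pd.Series
    truth: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.matrix.columns) - set(self.groups.index):
            raise ValueError("every sample needs a group label")
        if set(self.matrix.index) != set(self.truth.index):
            raise ValueError("every gene needs a truth entry")
        if self.matrix.isna().any().any():
            raise ValueError("matrix must have no missing values")


@dataclass
class PlantedNetwork:
    """Scored edge list with signature sets at known graph distances.

    ``truth_distances`` maps (gene, level) to the exact hop distance on the
    score-filtered graph, or None when unreachable.
    """

    edges: pd.DataFrame  # gene1, gene2, combined_score
    signatures: dict[str, set[str]]
    truth_distances: dict[tuple[str, str], int | None]
    nodes: list[str] = field(default_factory=list)


def gen_expression(
    n_genes: int,
    n_per_group: int,
    n_up: int,
    n_down: int,
    lfc: float = 3.0,
    sigma: float = 0.25,
    seed: int = 0,
    case_label: str = "GOLD4",
    control_label: str = "control",
    baseline: float = 8.0,
) -> ExpressionStudy:
    """Two-group log2 expression study with planted fold changes.

    The first ``n_up`` genes get a +lfc shift of the case-group mean, the
    next ``n_down`` a -lfc shift, the rest none; i.i.d. Gaussian noise with
    SD ``sigma`` (log2 units) is added everywhere.
    """
    if n_genes <= 0 or n_per_group < 2:
        raise ValueError("need n_genes > 0 and n_per_group >= 2")
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down must not exceed n_genes")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    samples = [f"CTL{i:03d}" for i in range(n_per_group)] + [
        f"CASE{i:03d}" for i in range(n_per_group)
    ]
    status = np.array(["up"] * n_up + ["down"] * n_down +
                      ["null"] * (n_genes - n_up - n_down))
    planted = np.where(status == "up", lfc, np.where(status == "down", -lfc, 0.0))
    means = np.tile(baseline, (n_genes, 2 * n_per_group))
    means[:, n_per_group:] += planted[:, None]
    matrix = pd.DataFrame(
        means + rng.normal(0.0, sigma, size=means.shape),
        index=genes, columns=samples,
    )
    groups = pd.Series(
        [control_label] * n_per_group + [case_label] * n_per_group,
        index=samples, name="group",
    )
    truth = pd.DataFrame({"status": status, "planted_lfc": planted}, index=genes)
    return ExpressionStudy(matrix=matrix, groups=groups, truth=truth)


def gen_network(
    n_nodes: int,
    mean_degree: float,
    seed: int,
    sig_sizes: dict[str, int],
    planted_geometry: dict[str, dict[str, int | None]],
) -> PlantedNetwork:
    """Random scored network with candidates planted at exact hop distances.

    ``sig_sizes`` gives, per level, either the number of signature genes to
    auto-name or an explicit collection of gene names (keys are usually
    :data:`NETWORK_LEVELS`); ``planted_geometry`` maps a candidate
    gene name to {level: hops} where hops = 0 plants the candidate inside
    that level's signature set, hops >= 1 builds a dedicated path of
    high-score edges to a level anchor, and None leaves the level
    unreachable from the candidate.

    Planted paths use fresh intermediate nodes and per-(candidate, level)
    anchors; decoy edges are high-score only among background nodes, and
    low-score (< 700) anywhere, so the score filter removes them.  After
    construction all truth distances are re-derived by BFS on the filtered
    graph and a :class:`GeometryError` is raised if any requested hop count
    is not realized exactly.
    """
    if mean_degree >= n_nodes:
        raise ValueError("mean_degree must be below n_nodes")
    rng = np.random.default_rng(seed)
    levels = list(sig_sizes)
    signatures: dict[str, set[str]] = {}
    for lvl, spec in sig_sizes.items():
        if isinstance(spec, int):
            if spec < 1:
                raise ValueError("signature sizes must be >= 1")
            signatures[lvl] = {
                f"SIG{lvl[:1].upper()}{i:03d}" for i in range(spec)
            }
        else:
            signatures[lvl] = {str(g).upper() for g in spec}
            if not signatures[lvl]:
                raise ValueError("signature sizes must be >= 1")
    anchor_pool = {lvl: sorted(signatures[lvl]) for lvl in levels}
    anchor_idx = {lvl: 0 for lvl in levels}
    edges: list[tuple[str, str, int]] = []

    def high_score() -> int:
        return int(rng.integers(MIN_PLANTED_SCORE, 1000))

    for gene, hops in planted_geometry.items():
        gene = gene.upper()
        for lvl, h in hops.items():
            if lvl not in signatures:
                raise ValueError(f"unknown level {lvl!r} in geometry")
            if h is None:
                continue
            if h == 0:
                signatures[lvl].add(gene)
                continue
            anchor = anchor_pool[lvl][anchor_idx[lvl] % len(anchor_pool[lvl])]
            anchor_idx[lvl] += 1
            prev = gene
            for step in range(h):
                nxt = (anchor if step == h - 1
                       else f"VIA_{gene}_{lvl[:1].upper()}{step}")
                edges.append((prev, nxt, high_score()))
                prev = nxt

    structured = sorted(
        set().union(*signatures.values())
        | {g.upper() for g in planted_geometry}
        | {e[0] for e in edges} | {e[1] for e in edges}
    )
    if len(structured) > n_nodes:
        raise GeometryError(
            f"geometry needs {len(structured)} nodes but n_nodes={n_nodes}"
        )
    background = [f"BG{i:04d}" for i in range(n_nodes - len(structured))]
    all_nodes = structured + background

    # decoy edges: fill to the requested mean degree
    n_target_edges = int(round(mean_degree * n_nodes / 2))
    existing = {tuple(sorted(e[:2])) for e in edges}
    attempts = 0
    while len(existing) < n_target_edges and attempts < 20 * n_target_edges:
        attempts += 1
        if background and rng.random() < 0.5:
            # high-score decoy, background only: cannot shortcut planted paths
            a, b = rng.choice(len(background), 2, replace=False)
            pair = tuple(sorted((background[a], background[b])))
            score = high_score()
        else:
            a, b = rng.choice(len(all_nodes), 2, replace=False)
            pair = tuple(sorted((all_nodes[a], all_nodes[b])))
            score = int(rng.integers(0, MIN_PLANTED_SCORE))  # filtered out
        if pair in existing:
            continue
        existing.add(pair)
        edges.append((pair[0], pair[1], score))

    edge_df = (
        pd.DataFrame(edges, columns=["gene1", "gene2", "combined_score"])
        .sort_values(["gene1", "gene2"], ignore_index=True)
    )

    # verify: truth distances re-derived from the filtered graph
    g = nx.Graph()
    g.add_nodes_from(all_nodes)
    kept = edge_df[edge_df["combined_score"] >= MIN_PLANTED_SCORE]
    g.add_edges_from(kept[["gene1", "gene2"]].itertuples(index=False))
    truth: dict[tuple[str, str], int | None] = {}
    for lvl in levels:
        dist: dict[str, int] = {}
        for s in signatures[lvl]:
            for node, d in nx.single_source_shortest_path_length(g, s).items():
                if node not in dist or d < dist[node]:
                    dist[node] = d
        for gene, hops in planted_geometry.items():
            gene = gene.upper()
            actual = dist.get(gene)
            truth[(gene, lvl)] = actual
            requested = hops.get(lvl)
            if requested is not None and actual != requested:
                raise GeometryError(
                    f"{gene}: requested {requested} hops to {lvl}, "
                    f"realized {actual}"
                )
        for s in signatures[lvl]:
            truth[(s, lvl)] = 0
    return PlantedNetwork(
        edges=edge_df, signatures=signatures, truth_distances=truth,
        nodes=all_nodes,
    )


def gen_perturbation_profiles(
    n_profiles: int,
    n_genes: int,
    planted,
    seed: int,
    query_up,
    query_down,
    perturbed_genes=None,
    cell_line: str = "A549",
    band: float = 0.08,
):
    """Ranked perturbation profiles with planted connectivity signs.

    ``planted`` is a sequence of ``"positive"`` / ``"negative"`` /
    ``"null"`` of length ``n_profiles``.  A positive profile places the
    query up-set within the top ``band`` fraction of the ranking and the
    down-set within the bottom fraction (a perturbation mimicking the
    disease signature); negative profiles reverse the two; null profiles
    are uniform permutations.  Returns a list of
    :class:`~omixprox.target_assessment.PerturbationProfile`.
    """
    from .target_assessment import PerturbationProfile

    planted = list(planted)
    if len(planted) != n_profiles:
        raise ValueError("planted must give one sign per profile")
    up = [g.upper() for g in query_up]
    down = [g.upper() for g in query_down]
    if set(up) & set(down):
        raise ValueError("query up and down sets overlap")
    n_query = len(up) + len(down)
    if n_genes < n_query:
        raise ValueError("n_genes must cover the query sets")
    rng = np.random.default_rng(seed)
    fillers = [f"BGGENE{i:05d}" for i in range(n_genes - n_query)]
    universe = up + down + fillers
    band_n = max(len(up), len(down), int(math.ceil(band * n_genes)))
    if 2 * band_n > n_genes:
        raise ValueError("band too wide for the universe size")
    profiles = []
    perturbations = ("knockout", "overexpression")
    for i, sign in enumerate(planted):
        if sign == "null":
            ranking = [str(g) for g in rng.permutation(universe)]
        elif sign in ("positive", "negative"):
            top_set, bottom_set = (up, down) if sign == "positive" else (down, up)
            top_pos = sorted(rng.choice(band_n, len(top_set), replace=False))
            bot_pos = sorted(
                n_genes - band_n + rng.choice(band_n, len(bottom_set),
                                              replace=False)
            )
            others = list(rng.permutation(
                [g for g in universe if g not in set(top_set) | set(bottom_set)]
            ))
            ranking: list[str] = []
            top_iter = iter(list(rng.permutation(top_set)))
            bot_iter = iter(list(rng.permutation(bottom_set)))
            top_pos_set, bot_pos_set = set(top_pos), set(bot_pos)
            k = 0
            for j in range(n_genes):
                if j in top_pos_set:
                    ranking.append(str(next(top_iter)))
                elif j in bot_pos_set:
                    ranking.append(str(next(bot_iter)))
                else:
                    ranking.append(str(others[k]))
                    k += 1
        else:
            raise ValueError(f"unknown planted sign {sign!r}")
        gene = (perturbed_genes[i] if perturbed_genes is not None
                else f"PERT{i:03d}")
        profiles.append(
            PerturbationProfile(
                perturbed_gene=gene,
                perturbation=perturbations[i % 2],
                cell_line=cell_line,
                ranking=ranking,
            )
        )
    return profiles


def gen_reaction_table(metabolites, proteins, scores, gene_map) -> pd.DataFrame:
    """Scored metabolite-reaction-protein table with gene mappings.

    ``scores`` maps (metabolite, protein) pairs to confidence scores;
    proteins absent from ``gene_map`` get an empty gene and are flagged in
    the ``unmapped`` column.
    """
    rows = []
    for (met, prot), score in scores.items():
        if met not in set(metabolites) or prot not in set(proteins):
            raise ValueError(f"scored pair ({met}, {prot}) not in the listed "
                             "metabolites/proteins")
        if not np.isfinite(score):
            raise ValueError(f"non-finite score for ({met}, {prot})")
        gene = gene_map.get(prot, "")
        rows.append(
            {"metabolite": met, "protein": prot, "confidence_score": score,
             "gene": gene, "unmapped": prot not in gene_map}
        )
    return pd.DataFrame(
        rows, columns=["metabolite", "protein", "confidence_score", "gene",
                       "unmapped"]
    ).sort_values(["metabolite", "protein"], ignore_index=True)


def gen_target_tables(genes, seed: int = 0, tier_probs=(0.3, 0.2, 0.2),
                      drugs_per_tier1: int = 3):
    """Toy druggability-tier and drug-target tables for a gene set.

    Each gene is assigned tier 1/2/3 with the given probabilities (the
    remainder is left out of the table = non-druggable); every tier-1 gene
    gets ``drugs_per_tier1`` drugs.  Returns ``(druggability, drug_targets)``
    DataFrames.
    """
    rng = np.random.default_rng(seed)
    genes = sorted({g.upper() for g in genes})
    p1, p2, p3 = tier_probs
    rows, drug_rows = [], []
    drug_no = 0
    for g in genes:
        u = rng.random()
        if u < p1:
            tier = "1"
        elif u < p1 + p2:
            tier = "2"
        elif u < p1 + p2 + p3:
            tier = "3"
        else:
            continue
        rows.append({"gene": g, "tier": tier})
        if tier == "1":
            for _ in range(drugs_per_tier1):
                drug_rows.append(
                    {"drug_id": f"DB{drug_no:05d}",
                     "drug_name": f"compound_{drug_no:05d}", "gene": g}
                )
                drug_no += 1
    return pd.DataFrame(rows, columns=["gene", "tier"]), pd.DataFrame(
        drug_rows, columns=["drug_id", "drug_name", "gene"]
    )


def gen_pipeline_inputs(outdir, seed: int = 11):
    """Write a complete, coherent set of synthetic pipeline inputs.

    The network's transcriptome signature is the expression study's
    planted DEG set, so the DE stage feeds the distance model the same
    genes the generator planted; one planted candidate satisfies the 0/1
    selection rule and is a tier-1 drug target, and the perturbation
    profiles carry one planted-positive, one planted-negative, and one
    null profile.  Returns ``(config_kwargs, truth)`` where
    ``config_kwargs`` are keyword arguments for
    :class:`~omixprox.pipeline.PipelineConfig` (everything except
    ``outdir``) and ``truth`` records the planted ground truth, including
    the genes expected to satisfy the selection rule.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = gen_expression(
        n_genes=300, n_per_group=10, n_up=12, n_down=6,
        lfc=3.0, sigma=0.25, seed=seed,
    )
    paths = write_expression_study(study, outdir)
    planted_up = sorted(study.truth.index[study.truth["status"] == "up"])
    planted_down = sorted(study.truth.index[study.truth["status"] == "down"])
    sig_t = set(planted_up) | set(planted_down)

    sig_g = {f"GSIG{i:02d}" for i in range(8)}
    (outdir / "sig_genome.txt").write_text(
        "".join(f"{g}\n" for g in sorted(sig_g))
    )
    sig_prot = {f"PSIG{i:02d}" for i in range(6)}
    (outdir / "sig_proteome.txt").write_text(
        "".join(f"{g}\n" for g in sorted(sig_prot))
    )
    metabolites = ["M01", "M02", "M03"]
    (outdir / "metabolites.txt").write_text(
        "".join(f"{m}\n" for m in metabolites)
    )
    reactions = gen_reaction_table(
        metabolites,
        ["PROTA", "PROTB", "PROTC"],
        {("M01", "PROTA"): 5.0, ("M02", "PROTB"): 6.0, ("M03", "PROTC"): 3.0},
        {"PROTA": "MSIG1", "PROTB": "MSIG2", "PROTC": "MSIG3"},
    )
    reactions.to_csv(outdir / "reactions.tsv", sep="\t", index=False)
    sig_m = {"MSIG1", "MSIG2"}  # PROTC scores below the > 4 cutoff
    sig_p = sig_prot | sig_m

    geometry = {
        planted_up[0]: {"transcriptome": 0, "genome": 1, "protein": 1},
        planted_up[1]: {"transcriptome": 0, "genome": 1, "protein": 2},
        "XNODE": {"transcriptome": 1, "genome": 1, "protein": 1},
    }
    net = gen_network(
        n_nodes=80, mean_degree=3.0, seed=seed + 1,
        sig_sizes={"transcriptome": sig_t, "genome": sig_g, "protein": sig_p},
        planted_geometry=geometry,
    )
    net_paths = write_network_files(net, outdir)

    # the planted rule-satisfying gene is made a tier-1 target with drugs so
    # the annotation and join stages operate on a non-empty selected set
    drugg, drug_targets = gen_target_tables(
        (sig_t | sig_g | sig_p | {"XNODE"}) - {planted_up[0]}, seed=seed + 2
    )
    drugg = pd.concat(
        [drugg, pd.DataFrame([{"gene": planted_up[0], "tier": "1"}])],
        ignore_index=True,
    )
    drug_targets = pd.concat(
        [drug_targets, pd.DataFrame([
            {"drug_id": "DB99901", "drug_name": "synthovir",
             "gene": planted_up[0]},
            {"drug_id": "DB99902", "drug_name": "planterol",
             "gene": planted_up[0]},
        ])],
        ignore_index=True,
    )
    drugg.to_csv(outdir / "druggability.tsv", sep="\t", index=False)
    drug_targets.to_csv(outdir / "drug_targets.tsv", sep="\t", index=False)

    profiles = gen_perturbation_profiles(
        n_profiles=3, n_genes=150,
        planted=["positive", "negative", "null"], seed=seed + 3,
        query_up=planted_up, query_down=planted_down,
        perturbed_genes=[planted_up[0], "GSIG00", "PSIG00"],
    )
    write_profiles(profiles, outdir / "profiles")

    config_kwargs = dict(
        expression=str(paths["expression"]),
        groups=str(paths["groups"]),
        sig_genome=str(outdir / "sig_genome.txt"),
        sig_proteome=str(outdir / "sig_proteome.txt"),
        metabolites=str(outdir / "metabolites.txt"),
        reactions=str(outdir / "reactions.tsv"),
        edges=str(net_paths["edges"]),
        aliases=str(net_paths["aliases"]),
        druggability=str(outdir / "druggability.tsv"),
        drug_targets=str(outdir / "drug_targets.tsv"),
        profiles_dir=str(outdir / "profiles"),
        n_null=150,
        seed=seed,
    )
    truth = {
        "selected": {planted_up[0]},
        "sig_sizes": {
            "transcriptome": len(sig_t), "genome": len(sig_g),
            "proteome": len(sig_prot), "metabolome_derived": len(sig_m),
        },
        "planted_up": planted_up,
        "planted_down": planted_down,
        "network": net,
    }
    return config_kwargs, truth


# ---------------------------------------------------------------------------
# writers: the same plain-text dialects the pipeline readers consume

def write_expression_study(study: ExpressionStudy, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "truth": outdir / "expression_truth.tsv",
    }
    study.matrix.to_csv(paths["expression"], sep="\t", float_format="%.6f")
    study.groups.rename_axis("sample_id").reset_index().to_csv(
        paths["groups"], sep="\t", index=False
    )
    study.truth.rename_axis("gene").to_csv(paths["truth"], sep="\t")
    return paths


def write_network_files(net: PlantedNetwork, outdir,
                        protein_prefix: str = "9606.") -> dict[str, Path]:
    """Emit STRING-dialect links + alias table + signature lists + truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {
        "edges": outdir / "links.txt",
        "aliases": outdir / "aliases.tsv",
        "truth": outdir / "truth_distances.tsv",
    }
    with open(paths["edges"], "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for r in net.edges.itertuples(index=False):
            fh.write(f"{protein_prefix}{r.gene1} {protein_prefix}{r.gene2} "
                     f"{r.combined_score}\n")
    with open(paths["aliases"], "w") as fh:
        fh.write("protein_id\tgene_symbol\n")
        for node in sorted(net.nodes):
            fh.write(f"{protein_prefix}{node}\t{node}\n")
    for lvl, genes in net.signatures.items():
        p = outdir / f"sig_{lvl}.txt"
        p.write_text("".join(f"{g}\n" for g in sorted(genes)))
        paths[f"sig_{lvl}"] = p
    with open(paths["truth"], "w") as fh:
        fh.write("gene\tlevel\tdistance\n")
        for (gene, lvl), d in sorted(net.truth_distances.items()):
            fh.write(f"{gene}\t{lvl}\t{'NA' if d is None else d}\n")
    return paths


def write_profiles(profiles, outdir) -> dict[str, Path]:
    """One ranking TSV per profile plus a metadata table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {"meta": outdir / "profiles_meta.tsv"}
    with open(paths["meta"], "w") as fh:
        fh.write("profile_id\tperturbed_gene\tperturbation\tcell_line\n")
        for i, prof in enumerate(profiles):
            pid = f"profile_{i:03d}"
            fh.write(f"{pid}\t{prof.perturbed_gene}\t{prof.perturbation}\t"
                     f"{prof.cell_line}\n")
            p = outdir / f"{pid}.tsv"
            with open(p, "w") as pf:
                pf.write("gene\trank\n")
                for rank, gene in enumerate(prof.ranking, start=1):
                    pf.write(f"{gene}\t{rank}\n")
            paths[pid] = p
    return paths
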