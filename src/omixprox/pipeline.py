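"""End-to-end orchestration: one config, seeded determinism, a manifest.

Runs the stages in order — differential expression, signature assembly,
network filtering, distance profiling and selection, druggability/drug
annotation, and connectivity validation — writing each stage's output as
TSV under a run directory, plus a MANIFEST.json recording the seed, all
thresholds, and SHA-256 checksums of inputs and outputs.  Outputs carry no
timestamps, so re-running the same config and seed reproduces every file
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import network as net_mod
from . import prioritize, signatures, target_assessment, transcriptomics

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "validate_signatures", "read_profiles"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    # input paths
    expression: str
    groups: str
    sig_genome: str
    sig_proteome: str
    metabolites: str
    reactions: str
    edges: str
    aliases: str
    druggability: str
    drug_targets: str
    outdir: str
    profiles_dir: str | None = None
    # thresholds
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    min_score: int = 700
    magi_min_score: float = 4.0
    max_component: int = 1
    min_zero_levels: int = 1
    connectivity_cutoff: float = 90.0
    n_null: int = 1000
    # contrast
    case_label: str = "GOLD4"
    control_label: str = "control"
    seed: int = 0
    _path_fields = ("expression", "groups", "sig_genome", "sig_proteome",
                    "metabolites", "reactions", "edges", "aliases",
                    "druggability", "drug_targets")

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 <= self.min_score <= 999):
            raise ValueError("min_score must lie in [0, 999]")
        if self.lfc_threshold < 0 or self.max_component < 0:
            raise ValueError("thresholds must be nonnegative")
        if not (0 <= self.connectivity_cutoff <= 100):
            raise ValueError("connectivity_cutoff must lie in [0, 100]")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in self._path_fields:
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.profiles_dir is not None and not Path(self.profiles_dir).is_dir():
            raise FileNotFoundError(f"profiles_dir not found: {self.profiles_dir}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def read_profiles(profiles_dir):
    """Load perturbation profiles written by the profile writer dialect."""
    profiles_dir = Path(profiles_dir)
    meta = pd.read_csv(profiles_dir / "profiles_meta.tsv", sep="\t")
    out = []
    for row in meta.itertuples(index=False):
        tab = pd.read_csv(profiles_dir / f"{row.profile_id}.tsv", sep="\t")
        ranking = list(tab.sort_values("rank")["gene"].astype(str))
        out.append(
            target_assessment.PerturbationProfile(
                perturbed_gene=row.perturbed_gene,
                perturbation=row.perturbation,
                cell_line=row.cell_line,
                ranking=ranking,
            )
        )
    return out


def _fmt_dist(x: float) -> str:
    return "NA" if np.isinf(x) else str(int(x))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return a report bundle (paths + key numbers)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"outputs": {}}
    stage = "config"
    t0 = time.perf_counter()
    try:
        config.validate_paths()

        stage = "transcriptomics"
        matrix, groups = transcriptomics.read_expression(
            config.expression, config.groups
        )
        study = _Study(matrix, groups)
        de = transcriptomics.differential_expression(
            study, config.case_label, config.control_label
        )
        de["adj_p"] = transcriptomics.bh_adjust(de["p"].to_numpy())
        summary = transcriptomics.classify_degs(
            de, alpha=config.alpha, lfc_threshold=config.lfc_threshold,
            stage=config.case_label,
        )
        de_path = outdir / f"de_{config.case_label}.tsv"
        de.to_csv(de_path, sep="\t", index=False, float_format="%.6g")
        report["outputs"]["de"] = de_path
        report["n_up"], report["n_down"] = summary.n_up, summary.n_down
        sig_t = signatures.SignatureSet(
            level="transcriptome", genes=summary.deg_set,
            provenance=f"DE {config.case_label} vs {config.control_label}",
        )

        stage = "signatures"
        sig_g = signatures.load_signature(config.sig_genome, "genome")
        sig_prot = signatures.load_signature(config.sig_proteome, "proteome")
        mets = [
            line.strip() for line in
            Path(config.metabolites).read_text().splitlines() if line.strip()
        ]
        reactions = pd.read_csv(config.reactions, sep="\t")
        sig_m = signatures.metabolite_to_genes(
            mets, reactions, min_score=config.magi_min_score
        )
        sig_p = signatures.protein_level_union(sig_prot, sig_m)
        membership, regions, multi = signatures.cross_level_overlap(
            [sig_t, sig_g, sig_prot, sig_m]
        )
        overlap_path = outdir / "signature_overlap.tsv"
        membership.rename_axis("gene").to_csv(overlap_path, sep="\t")
        report["outputs"]["signature_overlap"] = overlap_path
        report["signature_sizes"] = {
            "transcriptome": len(sig_t), "genome": len(sig_g),
            "proteome": len(sig_prot), "metabolome_derived": len(sig_m),
        }
        report["multi_level_genes"] = multi

        stage = "network"
        edges = net_mod.read_string_edges(config.edges, config.aliases)
        net = net_mod.filter_by_score(edges, min_score=config.min_score)
        stats = net.stats()
        stats_path = outdir / "network_stats.tsv"
        pd.DataFrame([stats]).to_csv(stats_path, sep="\t", index=False)
        report["outputs"]["network_stats"] = stats_path
        report["network"] = stats

        stage = "prioritize"
        pool = net_mod.direct_neighbors(net, [sig_t, sig_g, sig_p])
        profiles = prioritize.distance_profiles(net, sig_t, sig_g, sig_p, pool)
        ranked = prioritize.rank_candidates(profiles)
        selected = prioritize.select_candidates(
            profiles, max_component=config.max_component,
            min_zero_levels=config.min_zero_levels,
        )
        ranked_out = ranked.copy()
        for col in ("d_T", "d_G", "d_P", "d_sum"):
            ranked_out[col] = ranked_out[col].map(_fmt_dist)
        ranked_path = outdir / "ranked_candidates.tsv"
        ranked_out.to_csv(ranked_path, sep="\t", index=False)
        sel_path = outdir / "selected_genes.txt"
        sel_path.write_text("".join(f"{g}\n" for g in sorted(selected)))
        report["outputs"]["ranked"] = ranked_path
        report["outputs"]["selected"] = sel_path
        report["pool_size"] = len(pool)
        report["selected"] = sorted(selected)

        stage = "target_assessment"
        drugg = pd.read_csv(config.druggability, sep="\t")
        records, tier_counts = target_assessment.annotate_druggability(
            selected, drugg
        )
        drugg_path = outdir / "druggability.tsv"
        pd.DataFrame([asdict(r) for r in records]).to_csv(
            drugg_path, sep="\t", index=False
        )
        tier1 = {r.gene for r in records if r.tier == "1"}
        drug_tab = pd.read_csv(config.drug_targets, sep="\t")
        drugs = target_assessment.map_drugs(tier1, drug_tab)
        drugs_path = outdir / "drugs.tsv"
        drugs.to_csv(drugs_path, sep="\t", index=False)
        report["outputs"]["druggability"] = drugg_path
        report["outputs"]["drugs"] = drugs_path
        report["tier_counts"] = tier_counts
        report["n_druggable"] = sum(
            v for k, v in tier_counts.items() if k != "none"
        )
        report["n_unique_drugs"] = int(drugs["drug_id"].nunique())

        if config.profiles_dir is not None:
            stage = "connectivity"
            perts = read_profiles(config.profiles_dir)
            universe = set(perts[0].ranking)
            up = summary.up_set & universe
            down = summary.down_set & universe
            if not up or not down:
                raise ValueError(
                    "disease up/down query sets do not overlap the profile "
                    "gene universe"
                )
            conn = target_assessment.connectivity_scores(
                perts, up, down, n_null=config.n_null, seed=config.seed
            )
            conn_path = outdir / "connectivity.tsv"
            pd.DataFrame([asdict(c) for c in conn]).round(
                {"wtcs": 6, "percentile": 2}
            ).to_csv(conn_path, sep="\t", index=False)
            report["outputs"]["connectivity"] = conn_path
            report["connectivity_flags"] = {
                c.perturbed_gene: c.flag for c in conn if c.flag != "none"
            }

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "thresholds": {
                "alpha": config.alpha,
                "lfc_threshold": config.lfc_threshold,
                "min_score": config.min_score,
                "magi_min_score": config.magi_min_score,
                "max_component": config.max_component,
                "min_zero_levels": config.min_zero_levels,
                "connectivity_cutoff": config.connectivity_cutoff,
                "n_null": config.n_null,
            },
            "contrast": [config.case_label, config.control_label],
            "inputs": {
                name: _sha256(getattr(config, name))
                for name in config._path_fields
            },
            "outputs": {
                name: _sha256(p) for name, p in report["outputs"].items()
            },
        }
        manifest_path = outdir / "MANIFEST.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True)
                                 + "\n")
        report["outputs"]["manifest"] = manifest_path
        report["manifest"] = manifest
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return report


class _Study:
    """Minimal matrix+groups holder for the DE stage."""

    def __init__(self, matrix: pd.DataFrame, groups: pd.Series):
        self.matrix = matrix
        self.groups = groups


def validate_signatures(discovery, validation, universe,
                        validation_ranking=None) -> dict:
    """Gene- and set-level support for a discovery signature.

    Gene level: upper-tail hypergeometric p of the discovery/validation
    overlap within ``universe``.  Set level (when a ranked gene list from
    the validation study is supplied): KS running-sum enrichment score of
    the discovery set in that ranking.
    """
    d_genes = discovery.genes if hasattr(discovery, "genes") else set(discovery)
    v_genes = validation.genes if hasattr(validation, "genes") else set(validation)
    out = {
        "overlap": len(d_genes & v_genes),
        "overlap_p": transcriptomics.hypergeometric_overlap(
            d_genes, v_genes, universe
        ),
    }
    if validation_ranking is not None:
        out["enrichment_score"] = target_assessment.weighted_ks_es(
            validation_ranking, d_genes & set(validation_ranking)
        )
    return out
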