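"""Differential expression across disease stages and cohort statistics.

Two-group comparisons of log2 expression (case stage vs. healthy control)
with an unequal-variance t test, Benjamini–Hochberg correction, and
classification into up/down/ns by adjusted-p and |log2 fold change|
thresholds.  Also provides the set-overlap and summary-statistic tests used
to validate signatures and to check cohort balance (chi-square on a
contingency table, one-way ANOVA reconstructed from group means/SDs/ns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StageSummary",
    "differential_expression",
    "bh_adjust",
    "classify_degs",
    "stage_overlap",
    "hypergeometric_overlap",
    "contingency_chi_square",
    "anova_from_summary",
    "read_expression",
]

# Variance floor for degenerate (zero-variance) genes, log2-units squared.
_VAR_FLOOR = 1e-12


@dataclass
class StageSummary:
    """Differentially expressed genes called for one disease stage."""

    stage: str
    n_up: int
    n_down: int
    deg_set: set[str]
    up_set: set[str] = field(default_factory=set)
    down_set: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.n_up + self.n_down != len(self.deg_set):
            raise ValueError("n_up + n_down must equal |deg_set|")


def differential_expression(
    study,
    case_label: str,
    control_label: str = "control",
) -> pd.DataFrame:
    """Per-gene Welch t test of case vs. control log2 expression.

    Parameters
    ----------
    study
        An object with ``matrix`` (genes x samples DataFrame of log2
        intensity) and ``groups`` (Series mapping sample id -> group label),
        e.g. an :class:`~omixprox.synthetic_data.ExpressionStudy`.
    case_label, control_label
        Group labels to contrast.  log2fc = mean(case) - mean(control).

    Returns
    -------
    DataFrame indexed like the matrix with columns ``gene``, ``log2fc``,
    ``p``.  Adjusted p values are added separately by :func:`bh_adjust`.

    Notes
    -----
    The test statistic is an unequal-variance (Welch) two-sample t with a
    1e-12 floor on each group's variance term, so genes that are constant
    within both groups still yield a defined statistic (a warning is
    emitted when the floor engages).
    """
    matrix, groups = study.matrix, study.groups
    if matrix.shape[0] == 0:
        raise ValueError("expression matrix has no genes")
    case_cols = groups.index[groups == case_label]
    ctrl_cols = groups.index[groups == control_label]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError(
            f"need >= 2 samples per group; got {len(case_cols)} "
            f"({case_label}) and {len(ctrl_cols)} ({control_label})"
        )
    x = matrix[case_cols].to_numpy(float)
    y = matrix[ctrl_cols].to_numpy(float)
    n1, n0 = x.shape[1], y.shape[1]
    m1, m0 = x.mean(axis=1), y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1)
    v0 = y.var(axis=1, ddof=1)
    if np.any(v1 < _VAR_FLOOR) or np.any(v0 < _VAR_FLOOR):
        warnings.warn(
            "zero-variance gene(s) encountered; variance floored at 1e-12",
            RuntimeWarning,
            stacklevel=2,
        )
    v1 = np.maximum(v1, _VAR_FLOOR)
    v0 = np.maximum(v0, _VAR_FLOOR)
    se2 = v1 / n1 + v0 / n0
    t = (m1 - m0) / np.sqrt(se2)
    # Welch–Satterthwaite degrees of freedom
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {"gene": matrix.index, "log2fc": m1 - m0, "p": p}
    ).reset_index(drop=True)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_degs(
    results: pd.DataFrame,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    stage: str = "case",
) -> StageSummary:
    """Assign up/down/ns status and summarise one stage's DEG call.

    A gene is ``up`` when adj_p < alpha and log2fc >= lfc_threshold, ``down``
    when adj_p < alpha and log2fc <= -lfc_threshold, else ``ns``.  On natural
    scale lfc_threshold = 1 is the familiar "fold change > 2 or < 0.5" rule.
    Mutates ``results`` by adding/overwriting a ``status`` column.
    """
    if "adj_p" not in results.columns:
        raise ValueError("results must carry an adj_p column (run bh_adjust)")
    sig = results["adj_p"] < alpha
    up = sig & (results["log2fc"] >= lfc_threshold)
    down = sig & (results["log2fc"] <= -lfc_threshold)
    status = np.where(up, "up", np.where(down, "down", "ns"))
    results["status"] = status
    up_set = set(results.loc[up, "gene"])
    down_set = set(results.loc[down, "gene"])
    return StageSummary(
        stage=stage,
        n_up=len(up_set),
        n_down=len(down_set),
        deg_set=up_set | down_set,
        up_set=up_set,
        down_set=down_set,
    )


def stage_overlap(summaries: list[StageSummary]) -> pd.DataFrame:
    """Per-gene status across stages, for genes dysregulated anywhere.

    Returns a DataFrame indexed by gene with one column per stage
    (``up``/``down``/``ns``) plus ``n_stages`` (stages where the gene is a
    DEG), ``consistent`` (``up``/``down`` when the gene is dysregulated in
    >= 2 stages always in the same direction, else empty), and
    ``status_change`` (True when a gene flips between up and down).
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 stages to compute an overlap")
    all_genes = sorted(set().union(*(s.deg_set for s in summaries)))
    rows = {}
    for g in all_genes:
        statuses = [
            "up" if g in s.up_set else "down" if g in s.down_set else "ns"
            for s in summaries
        ]
        rows[g] = statuses
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=[s.stage for s in summaries]
    )
    deg_mask = table.isin(["up", "down"])
    table["n_stages"] = deg_mask.sum(axis=1)
    has_up = (table[[s.stage for s in summaries]] == "up").any(axis=1)
    has_down = (table[[s.stage for s in summaries]] == "down").any(axis=1)
    table["status_change"] = has_up & has_down
    consistent = np.where(
        (table["n_stages"] >= 2) & has_up & ~has_down,
        "up",
        np.where((table["n_stages"] >= 2) & has_down & ~has_up, "down", ""),
    )
    table["consistent"] = consistent
    return table


def hypergeometric_overlap(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> float:
    """Upper-tail hypergeometric p for observing >= |A ∩ B| shared genes.

    Models |A ∩ B| as the overlap of a size-|B| draw without replacement
    from ``universe`` with the fixed set A.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    k = len(set_a & set_b)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(set_a), len(set_b)))


def contingency_chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a counts matrix.

    Returns ``(statistic, df, p)`` with df = (rows-1)(cols-1).  Raises on a
    zero row or column margin, where expected counts are undefined.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("table must contain nonnegative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero row/column margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def anova_from_summary(means, sds, ns) -> tuple[float, int, int, float]:
    """One-way ANOVA F and p reconstructed from per-group summaries.

    Between-group SS comes from the group means and sizes, within-group SS
    from the group SDs: SS_w = sum (n_i - 1) s_i^2.  Returns
    ``(F, df_between, df_within, p)``.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if not (means.shape == sds.shape == ns.shape) or means.ndim != 1:
        raise ValueError("means, sds, ns must be equal-length 1-D sequences")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    if np.any(sds <= 0):
        raise ValueError("group SDs must be positive")
    k = means.size
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    df1, df2 = k - 1, int(n_total) - k
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def read_expression(expr_path, groups_path):
    """Read an expression TSV (genes x samples) and a sample-annotation TSV.

    The annotation file needs columns ``sample_id`` and ``group``.  Returns
    ``(matrix, groups)`` with groups reindexed to the matrix columns.
    """
    matrix = pd.read_csv(expr_path, sep="\t", index_col=0)
    ann = pd.read_csv(groups_path, sep="\t")
    if not {"sample_id", "group"} <= set(ann.columns):
        raise ValueError("annotation file needs sample_id and group columns")
    groups = ann.set_index("sample_id")["group"]
    missing = [c for c in matrix.columns if c not in groups.index]
    if missing:
        raise ValueError(f"samples missing from annotation: {missing[:5]}")
    return matrix, groups.reindex(matrix.columns)
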