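"""Evaluation metrics, aggressiveness markers and perturbation-screen gates.

Covers confusion-matrix statistics behind the reported sensitivity and
specificity figures, hypergeometric (Fisher) enrichment, percent genome
altered (PGA), median-of-genes scores (hypoxia), and the gating rules used
to nominate synthetic-lethality candidates from pooled CRISPR gene-effect
screens, an isogenic RB1-knockout screen, and drug-response (dr-AUC)
profiling.  Mean-threshold gates are applied *before* any significance
test: a gene or compound failing a gate is never tested.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionTable",
    "confusion_metrics",
    "fisher_enrichment",
    "compute_pga",
    "median_gene_score",
    "crispr_sl_candidates",
    "isogenic_screen_candidates",
    "drug_sensitivity_candidates",
    "cell_line_rb1_defective",
]

GROUP_LABELS = ("rb1_defective", "rbness", "low", "other")


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int


def confusion_metrics(truth, calls):
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) from binary
    truth/call vectors.  With no positives (or negatives) in the truth the
    corresponding metric is undefined and returned as None."""
    t = np.asarray(truth, dtype=bool)
    c = np.asarray(calls, dtype=bool)
    if t.size == 0 or t.shape != c.shape:
        raise ValueError("truth and calls must be equal-length nonempty vectors")
    table = ConfusionTable(
        tp=int((t & c).sum()),
        fp=int((~t & c).sum()),
        tn=int((~t & ~c).sum()),
        fn=int((t & ~c).sum()),
    )
    sens = table.tp / (table.tp + table.fn) if (table.tp + table.fn) else None
    spec = table.tn / (table.tn + table.fp) if (table.tn + table.fp) else None
    return sens, spec, table


def fisher_enrichment(a: int, b: int, c: int, d: int):
    """Odds ratio and one-sided hypergeometric enrichment p for the 2x2
    table [[a, b], [c, d]].

    The odds ratio is the sample (cross-product) OR; when a zero cell makes
    it degenerate, 0.5 is added to every cell and ``continuity=True`` is
    flagged.  Returns (odds_ratio, p, continuity).
    """
    cells = (a, b, c, d)
    if any((not float(x).is_integer()) or x < 0 for x in cells):
        raise ValueError("cell counts must be nonnegative integers")
    a, b, c, d = (int(x) for x in cells)
    if a + b + c + d == 0:
        raise ValueError("table total must be positive")
    continuity = False
    if (b == 0 or c == 0 or a == 0 or d == 0) and (a * d != 0 or b * c != 0):
        if b * c == 0:  # infinite/zero OR: apply Haldane-Anscombe correction
            continuity = True
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = 0.0
    elif b * c == 0:
        orr = math.nan  # all-zero margins
    else:
        orr = (a * d) / (b * c)
    # one-sided enrichment p: P(X >= a) with X ~ Hypergeom(N, a+b, a+c)
    p = float(stats.hypergeom.sf(a - 1, a + b + c + d, a + b, a + c))
    return orr, p, continuity


def compute_pga(segments: pd.DataFrame, threshold: float = 0.2, by_count: bool = False) -> pd.Series:
    """Percent genome altered per sample: the proportion of the segmented
    genome with |log2 ratio| strictly above ``threshold``.

    Default is length-weighted over 1-based inclusive segments; ``by_count``
    gives the unweighted fraction of altered segments instead.
    """
    required = {"sample", "start", "end", "log2_ratio"}
    missing = required - set(segments.columns)
    if missing:
        raise ValueError(f"segments missing columns {sorted(missing)}")
    df = segments.copy()
    df["length"] = df["end"] - df["start"] + 1
    if (df["length"] <= 0).any():
        raise ValueError("segment end < start")
    df["altered"] = df["log2_ratio"].abs() > threshold
    out = {}
    for sample, grp in df.groupby("sample", sort=False):
        if by_count:
            out[sample] = float(grp["altered"].mean())
        else:
            total = int(grp["length"].sum())
            if total <= 0:
                raise ValueError(f"sample {sample!r}: zero total segmented length")
            out[sample] = float(grp.loc[grp["altered"], "length"].sum() / total)
    return pd.Series(out, name="pga")


def median_gene_score(matrix, genes) -> pd.Series:
    """Per-sample median over the available listed genes (e.g. the hypoxia
    score over a hypoxia signature's genes)."""
    avail = [g for g in genes if g in matrix.data.index]
    if not avail:
        raise ValueError("none of the listed genes are present in the matrix")
    return matrix.data.loc[avail].median(axis=0)


def _welch_one_sided_less(xa: np.ndarray, xb: np.ndarray) -> float:
    """One-sided Welch's t (Satterthwaite df), alternative: mean(a) < mean(b)."""
    return float(stats.ttest_ind(xa, xb, equal_var=False, alternative="less").pvalue)


def crispr_sl_candidates(
    dependency: pd.DataFrame,
    labels: pd.Series,
    group_a: str = "rb1_defective",
    low_label: str = "low",
    alpha: float = 0.05,
    gate_group_a: float = -0.5,
    gate_low: float = -0.75,
    fdr: bool = False,
) -> pd.DataFrame:
    """Synthetic-lethality candidates from a gene x cell-line gene-effect
    (GE) matrix.

    A gene is testable only when mean GE in group A (< -0.5, at least
    synthetic sickness), mean GE in the signature-low group (> -0.75, not
    broadly essential) and mean GE(A) < mean GE(low) all hold; testable
    genes receive a one-sided Welch's t p value (group A lower) and
    candidates are those with p < 0.05 (uncorrected, unless ``fdr``).
    """
    if group_a not in GROUP_LABELS:
        raise ValueError(f"group_a must be one of {GROUP_LABELS}")
    a_lines = labels.index[labels == group_a].tolist()
    low_lines = labels.index[labels == low_label].tolist()
    if len(a_lines) < 3:
        raise ValueError(f"fewer than 3 cell lines in group {group_a!r}")
    if len(low_lines) < 3:
        raise ValueError(f"fewer than 3 cell lines in group {low_label!r}")
    xa = dependency[a_lines].to_numpy(dtype=float)
    xlow = dependency[low_lines].to_numpy(dtype=float)
    mean_a = xa.mean(axis=1)
    mean_low = xlow.mean(axis=1)
    testable = (mean_a < gate_group_a) & (mean_low > gate_low) & (mean_a < mean_low)
    rows = []
    for i in np.flatnonzero(testable):
        p = _welch_one_sided_less(xa[i], xlow[i])
        rows.append(
            {
                "gene": dependency.index[i],
                "mean_ge_group_a": mean_a[i],
                "mean_ge_low": mean_low[i],
                "p": p,
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "mean_ge_group_a", "mean_ge_low", "p"]).set_index("gene")
    if fdr and len(out):
        from .de import bh_adjust

        out["q"] = bh_adjust(out["p"].to_numpy())
        out["candidate"] = out["q"] < alpha
    else:
        out["candidate"] = out["p"] < alpha
    return out


def isogenic_screen_candidates(records: pd.DataFrame) -> list[str]:
    """Candidate vulnerabilities from an isogenic knockout-vs-parent screen
    of gene-level sgRNA z-scores: delta = z_knockout - z_parent < -2, with
    z_knockout < -2 and z_parent > -4 (the parental line itself must remain
    broadly viable for the gene)."""
    for col in ("z_knockout", "z_parent"):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    delta = records["z_knockout"] - records["z_parent"]
    keep = (delta < -2) & (records["z_knockout"] < -2) & (records["z_parent"] > -4)
    return records.index[keep].tolist()


def drug_sensitivity_candidates(
    drugs: pd.DataFrame,
    labels: pd.Series,
    group_a: str = "rb1_defective",
    low_label: str = "low",
    alpha: float = 0.05,
    gate_group_a: float = -0.5,
    gate_low: float = 0.0,
) -> pd.DataFrame:
    """Candidate sensitising compounds from a compound x cell-line matrix of
    z-transformed dose-response AUCs.  Testable when mean dr-AUC in the
    signature-low group >= 0 and mean dr-AUC in group A < -0.5; one-sided
    Welch's t (group A lower), candidates at p < 0.05."""
    a_lines = labels.index[labels == group_a].tolist()
    low_lines = labels.index[labels == low_label].tolist()
    if len(a_lines) < 3 or len(low_lines) < 3:
        raise ValueError("need at least 3 cell lines per compared group")
    xa = drugs[a_lines].to_numpy(dtype=float)
    xlow = drugs[low_lines].to_numpy(dtype=float)
    mean_a = xa.mean(axis=1)
    mean_low = xlow.mean(axis=1)
    testable = (mean_low >= gate_low) & (mean_a < gate_group_a)
    rows = []
    for i in np.flatnonzero(testable):
        p = _welch_one_sided_less(xa[i], xlow[i])
        rows.append(
            {
                "compound": drugs.index[i],
                "mean_drauc_group_a": mean_a[i],
                "mean_drauc_low": mean_low[i],
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["compound", "mean_drauc_group_a", "mean_drauc_low", "p"]
    ).set_index("compound")
    out["candidate"] = out["p"] < alpha
    return out


def cell_line_rb1_defective(
    mutation_damaging: bool | None = None,
    deep_deletion: bool | None = None,
    rb1_fusion: bool | None = None,
    mrna_z: float | None = None,
) -> bool:
    """RB1-defective call for a cell line: damaging mutation, deep deletion,
    RB1 gene fusion, or RB1 mRNA z-score strictly below -2."""
    if mutation_damaging is None and deep_deletion is None and rb1_fusion is None and mrna_z is None:
        raise ValueError("at least one modality is required")
    return bool(mutation_damaging) or bool(deep_deletion) or bool(rb1_fusion) or (
        mrna_z is not None and mrna_z < -2
    )
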