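"""Moderated two-group differential expression and the leave-one-out
robustness procedure (LOOL) used to extract subsampling-stable signatures.

The significance engine is a per-gene two-group linear model with
empirical-Bayes variance shrinkage: gene variances are assumed to follow a
scaled inverse-chi-square prior whose parameters (prior df ``d0``, prior
variance ``s0^2``) are fitted by moment matching on the log sample
variances; the posterior variance ``s2_post = (d0*s0^2 + d*s2)/(d0 + d)``
replaces the per-gene variance in an ordinary pooled t statistic with
``d + d0`` degrees of freedom.  With the prior disabled (``prior_df=0``)
this reduces exactly to the ordinary pooled two-sample t-test.

LOOL (leave-one-out robustness) reruns the moderated fit over all n*m
subsets obtained by removing one defective and one proficient sample at a
time and records, per gene, the fraction of subsets in which the gene stays
significant at strict thresholds (|log2FC| >= 1, BH q < 0.1).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .rb_status import DiscoveryGroups
from .scoring import Signature

__all__ = [
    "ModeratedStats",
    "LoolResult",
    "bh_adjust",
    "fit_moderated_de",
    "initial_gene_selection",
    "lool",
    "final_gene_filter",
    "lool_pancancer_fraction",
]

LOOL_SUBSET_CAP = 250_000


@dataclass
class ModeratedStats:
    """Fitted variance prior: prior df d0, prior variance s0^2, and the
    per-gene posterior variances."""

    prior_df: float
    prior_var: float
    posterior_var: np.ndarray


@dataclass
class LoolResult:
    """Per-gene LOOL robustness summary over the n*m leave-one-out subsets."""

    table: pd.DataFrame  # robustness_fraction, mean_z_defective, direction_consistency
    n_subsets: int


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _inverse_trigamma(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    return optimize.brentq(lambda x: special.polygamma(1, x) - y, 1e-8, 1e8, xtol=1e-12)


def _fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Moment-matching fit of the scaled inverse-chi-square variance prior
    on log sample variances.  Returns (d0, s0^2); d0 = inf means complete
    shrinkage to the common value (observed variance spread no larger than
    expected from sampling alone)."""
    ok = s2 > 0
    if not ok.any():
        return math.inf, 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2) + math.log(d / 2)
    if e.size < 2:
        return math.inf, float(np.exp(z.mean()))
    evar = float(np.var(e, ddof=1))
    surplus = evar - special.polygamma(1, d / 2)
    if surplus <= 1e-12:
        # log-variance spread explained by sampling noise alone
        return math.inf, float(np.exp(z.mean()))
    half_d0 = _inverse_trigamma(surplus)
    d0 = 2 * half_d0
    s02 = float(np.exp(e.mean() + special.digamma(half_d0) - math.log(half_d0)))
    return d0, s02


def _moderated_core(
    xa: np.ndarray, xb: np.ndarray, prior_df: float | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, ModeratedStats]:
    """Vectorised moderated fit on numpy arrays (genes x samples per group).
    Returns (log2fc, t, p, stats)."""
    na, nb = xa.shape[1], xb.shape[1]
    d = na + nb - 2
    ma = xa.mean(axis=1)
    mb = xb.mean(axis=1)
    fc = ma - mb
    ss = ((xa - ma[:, None]) ** 2).sum(axis=1) + ((xb - mb[:, None]) ** 2).sum(axis=1)
    s2 = ss / d
    if prior_df is None:
        d0, s02 = _fit_variance_prior(s2, d)
    else:
        d0, s02 = float(prior_df), 0.0
        if d0 > 0:
            _, s02 = _fit_variance_prior(s2, d)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = math.inf
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d + d0
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fc / np.where(se > 0, se, 1.0), np.where(fc == 0, 0.0, np.inf * np.sign(fc)))
    if math.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isfinite(t), p, 0.0)
    p = np.where((se == 0) & (fc == 0), 1.0, p)
    return fc, t, p, ModeratedStats(prior_df=d0, prior_var=s02, posterior_var=s2_post)


def fit_moderated_de(matrix, group_a, group_b, prior_df: float | None = None) -> pd.DataFrame:
    """Moderated-t differential expression, group A minus group B.

    Returns a per-gene frame with columns log2fc (group-mean difference on
    the matrix's log2/z scale), t, p and BH-adjusted q.  ``prior_df`` forces
    the prior df (0 disables shrinkage and yields the ordinary pooled t);
    by default the prior is estimated from the data.
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    unknown = [s for s in group_a + group_b if s not in matrix.data.columns]
    if unknown:
        raise KeyError(f"unknown samples: {unknown}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 samples per group")
    xa = matrix.data[group_a].to_numpy(dtype=float)
    xb = matrix.data[group_b].to_numpy(dtype=float)
    fc, t, p, _ = _moderated_core(xa, xb, prior_df)
    return pd.DataFrame(
        {"log2fc": fc, "t": t, "p": p, "q": bh_adjust(p)}, index=matrix.data.index
    )


def initial_gene_selection(de: pd.DataFrame, min_abs_fc: float = 0.585, max_q: float = 0.1) -> list[str]:
    """Genes of interest from the full-population fit: |log2FC| >= 0.585
    (1.5-fold) and BH q < 0.1 (strict)."""
    mask = (de["log2fc"].abs() >= min_abs_fc) & (de["q"] < max_q)
    return de.index[mask].tolist()


def lool(
    matrix,
    groups: DiscoveryGroups,
    candidate_genes,
    min_abs_fc: float = 1.0,
    max_q: float = 0.1,
    prior_df: float | None = None,
    subset_cap: int = LOOL_SUBSET_CAP,
) -> LoolResult:
    """Leave-one-out robustness of the candidate genes.

    For each of the n*m subsets formed by removing one defective and one
    proficient sample, the moderated fit is rerun restricted to the
    candidates and a pass is recorded at |log2FC| >= ``min_abs_fc`` and
    BH q < ``max_q``.  Alongside the pass fraction, the mean z over the full
    defective group and the direction consistency (fraction of defective
    samples whose z sign matches the sign of that mean; z exactly 0 never
    matches) are reported.
    """
    candidate_genes = list(candidate_genes)
    n, m = groups.n, groups.m
    if n < 2 or m < 2:
        raise ValueError("LOOL needs at least 2 samples per discovery group")
    if n * m > subset_cap:
        raise ValueError(
            f"{n}*{m} leave-one-out subsets exceed the cap of {subset_cap}; "
            "subsample the discovery groups first"
        )
    if not candidate_genes:
        return LoolResult(
            table=pd.DataFrame(
                columns=["robustness_fraction", "mean_z_defective", "direction_consistency"]
            ),
            n_subsets=n * m,
        )
    sub = matrix.subset_genes(candidate_genes)
    xa = sub.data[groups.defective].to_numpy(dtype=float)
    xb = sub.data[groups.proficient].to_numpy(dtype=float)
    passes = np.zeros(len(candidate_genes), dtype=int)
    for i in range(n):
        xa_i = np.delete(xa, i, axis=1)
        for j in range(m):
            xb_j = np.delete(xb, j, axis=1)
            fc, _, p, _ = _moderated_core(xa_i, xb_j, prior_df)
            q = bh_adjust(p)
            passes += (np.abs(fc) >= min_abs_fc) & (q < max_q)
    mean_z = xa.mean(axis=1)
    sign = np.sign(mean_z)
    consistency = (np.sign(xa) == sign[:, None]).mean(axis=1)
    consistency[sign == 0] = 0.0
    table = pd.DataFrame(
        {
            "robustness_fraction": passes / (n * m),
            "mean_z_defective": mean_z,
            "direction_consistency": consistency,
        },
        index=candidate_genes,
    )
    return LoolResult(table=table, n_subsets=n * m)


def final_gene_filter(
    lool_result: LoolResult,
    min_fraction: float = 0.20,
    min_mean_z: float = 0.2,
    min_consistency: float = 0.60,
    meta=None,
) -> Signature:
    """Final signature filter: robust in at least ``min_fraction`` of the
    leave-one-out subsets, |mean defective z| >= 0.2 and a consistent
    direction in at least 60% of defective samples.  Per-gene directions are
    the sign of the mean defective z.  An empty outcome is returned as an
    invalid signature rather than raising."""
    t = lool_result.table
    keep = (
        (t["robustness_fraction"] >= min_fraction)
        & (t["mean_z_defective"].abs() >= min_mean_z)
        & (t["direction_consistency"] >= min_consistency)
    )
    genes = t.index[keep].tolist()
    meta = dict(meta or {})
    meta.setdefault("min_fraction", min_fraction)
    return Signature(
        genes=genes,
        directions={g: (1 if t.loc[g, "mean_z_defective"] > 0 else -1) for g in genes},
        mean_z={g: float(t.loc[g, "mean_z_defective"]) for g in genes},
        meta=meta,
        valid=bool(genes),
    )


def lool_pancancer_fraction(n_initial_genes: int) -> float:
    """Pan-cancer robustness cut: 50% of the LOOL subsets when more than 20
    genes were initially found, 20% otherwise (the boundary of exactly 20
    genes takes the lenient branch)."""
    if n_initial_genes < 0:
        raise ValueError("gene count cannot be negative")
    return 0.50 if n_initial_genes > 20 else 0.20
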