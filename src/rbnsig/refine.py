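"""Multiscale relevance-network refinement of a candidate signature.

At each RB1-expression scale alpha in {0.4, 0.6, 0.8, 1.0}, the samples
with RB1 z-score beyond +/-alpha are selected, a Spearman correlation
matrix over the signature genes is computed across them, and a relevance
network is built by thresholding the correlations at c (an edge where
C_ij >= c, i != j).  Genes left without any edge are filtered out.  The
threshold c* is grid-searched over [0.10, 0.80] in steps of 0.02 for the
value whose connected gene set best separates (by alignment-score
classification accuracy) the RB1-low from the RB1-high samples.  The final
refinement keeps genes connected at all scales (strict consensus, large
signatures of more than 50 genes) or at least two scales (tolerant,
smaller signatures).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import Signature

__all__ = [
    "RelevanceNetwork",
    "ScaleResult",
    "DEFAULT_ALPHAS",
    "threshold_grid",
    "select_scale_samples",
    "build_relevance_network",
    "scale_accuracy",
    "optimize_threshold",
    "multiscale_consensus",
    "refine_signature",
]

DEFAULT_ALPHAS = (0.4, 0.6, 0.8, 1.0)


def threshold_grid() -> np.ndarray:
    """The inclusive c grid [0.10, 0.80] in steps of 0.02 (36 values)."""
    return np.round(0.10 + 0.02 * np.arange(36), 2)


@dataclass
class RelevanceNetwork:
    alpha: float
    samples: list[str]
    correlation: pd.DataFrame  # Spearman, genes x genes
    threshold: float
    adjacency: pd.DataFrame  # binary, zero diagonal
    connected_genes: list[str]  # degree >= 1


@dataclass
class ScaleResult:
    alpha: float
    usable: bool
    c_star: float | None = None
    accuracy: float | None = None
    connected_genes: list[str] = field(default_factory=list)
    accuracy_curve: pd.DataFrame | None = None  # c vs accuracy (for reporting)


def select_scale_samples(matrix, rb1_gene: str, alpha: float):
    """Samples with RB1 z strictly above alpha (high set) and strictly below
    -alpha (low set); |z| <= alpha is excluded on both sides."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if rb1_gene not in matrix.data.index:
        raise KeyError(f"RB1 gene {rb1_gene!r} not in matrix")
    z = matrix.data.loc[rb1_gene]
    high = z.index[z > alpha].tolist()
    low = z.index[z < -alpha].tolist()
    return high, low


def build_relevance_network(matrix, genes, samples, c: float) -> RelevanceNetwork:
    """Relevance network over ``genes`` across ``samples`` at threshold c.

    Spearman correlations use average ranks; a gene constant over the
    selected samples has undefined correlations and is treated as
    disconnected (with a warning).  Self-correlation never creates an edge.
    """
    genes = list(genes)
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError("need at least 3 selected samples for correlations")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    corr = _spearman_matrix(matrix, genes, samples)
    adj = (corr.to_numpy() >= c) & ~np.eye(len(genes), dtype=bool)
    adj &= ~np.isnan(corr.to_numpy())
    adjacency = pd.DataFrame(adj.astype(int), index=genes, columns=genes)
    connected = [g for g, deg in zip(genes, adj.sum(axis=1)) if deg > 0]
    return RelevanceNetwork(
        alpha=float("nan"),
        samples=samples,
        correlation=corr,
        threshold=c,
        adjacency=adjacency,
        connected_genes=connected,
    )


def _spearman_matrix(matrix, genes, samples) -> pd.DataFrame:
    x = matrix.data.loc[genes, samples].to_numpy(dtype=float)
    constant = x.std(axis=1) == 0
    if constant.any():
        names = [g for g, c in zip(genes, constant) if c]
        warnings.warn(f"genes constant over selected samples treated as disconnected: {names}")
    with np.errstate(invalid="ignore"):
        rho = stats.spearmanr(x, axis=1).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses 2x2 to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    return pd.DataFrame(rho, index=genes, columns=genes)


def scale_accuracy(connected_genes, directions, high_set, low_set, matrix,
                   invert_sides: bool = False) -> float:
    """Accuracy with which alignment over the connected genes separates the
    RB1-low from the RB1-high samples.

    Each sample is classified defective-like when its alignment over the
    connected genes exceeds 0.5 (an alignment of exactly 0.5 counts as
    proficient-like).  RB1-low samples are expected defective-like, since
    signature directions are defined on RB1-defective samples;
    ``invert_sides`` swaps the expectation.
    """
    connected_genes = list(connected_genes)
    if not connected_genes:
        raise ValueError("empty connected gene set")
    if not high_set or not low_set:
        raise ValueError("both sample sides must be nonempty")
    d = np.array([directions[g] for g in connected_genes])[:, None]
    expected_high, expected_low = ("defective", "proficient") if invert_sides else ("proficient", "defective")
    correct = 0
    for samples, expected in ((list(high_set), expected_high), (list(low_set), expected_low)):
        z = matrix.data.loc[connected_genes, samples].to_numpy(dtype=float)
        align = (np.sign(z) == d).mean(axis=0)
        predicted_defective = align > 0.5
        correct += int(predicted_defective.sum()) if expected == "defective" else int((~predicted_defective).sum())
    return correct / (len(high_set) + len(low_set))


def optimize_threshold(matrix, genes, directions, high_set, low_set,
                       invert_sides: bool = False, alpha: float = float("nan")) -> ScaleResult:
    """Grid search c over [0.10, 0.80] (step 0.02) for the network whose
    connected genes classify the two sample sides most accurately; ties
    break toward the smallest c (keeping more genes connected)."""
    genes = list(genes)
    samples = list(high_set) + list(low_set)
    corr = _spearman_matrix(matrix, genes, samples).to_numpy()
    np.fill_diagonal(corr, -np.inf)  # self-correlation never an edge
    d = np.array([directions[g] for g in genes])[:, None]
    z = matrix.data.loc[genes, samples].to_numpy(dtype=float)
    concord = (np.sign(z) == d)
    n_high = len(high_set)
    rows = []
    best = None
    for c in threshold_grid():
        with np.errstate(invalid="ignore"):
            connected = np.nansum(corr >= c, axis=1) > 0
        if not connected.any():
            rows.append({"c": c, "accuracy": np.nan, "n_connected": 0})
            continue
        align = concord[connected].mean(axis=0)
        pred_def = align > 0.5
        if invert_sides:
            acc = (pred_def[:n_high].sum() + (~pred_def[n_high:]).sum()) / len(samples)
        else:
            acc = ((~pred_def[:n_high]).sum() + pred_def[n_high:].sum()) / len(samples)
        rows.append({"c": c, "accuracy": acc, "n_connected": int(connected.sum())})
        if best is None or acc > best[1] + 1e-12:
            best = (c, acc, [g for g, k in zip(genes, connected) if k])
    curve = pd.DataFrame(rows)
    if best is None:
        return ScaleResult(alpha=alpha, usable=False, accuracy_curve=curve)
    c_star, accuracy, connected_genes = best
    return ScaleResult(
        alpha=alpha,
        usable=True,
        c_star=float(c_star),
        accuracy=float(accuracy),
        connected_genes=connected_genes,
        accuracy_curve=curve,
    )


def multiscale_consensus(scale_results, mode: str = "auto",
                         candidate_signature: Signature | None = None) -> Signature:
    """Cross-scale consensus of the connected gene sets.

    strict: genes connected at every scale; tolerant: genes connected at two
    or more scales (with a single usable scale, at that scale).  ``auto``
    picks strict for candidate signatures of more than 50 genes, tolerant
    otherwise.  Unusable scales (an empty sample side, or no threshold with
    a connected gene) are dropped from the tolerant denominator; in strict
    mode any unusable scale forces a tolerant fallback with a warning.
    """
    results = list(scale_results)
    usable = [r for r in results if r.usable]
    if not usable:
        raise ValueError("no usable scale")
    if mode == "auto":
        if candidate_signature is None:
            raise ValueError("auto mode needs the candidate signature to pick strict/tolerant")
        mode = "strict" if len(candidate_signature) > 50 else "tolerant"
    if mode not in ("strict", "tolerant"):
        raise ValueError(f"mode must be strict, tolerant or auto, got {mode!r}")
    if mode == "strict" and len(usable) < len(results):
        warnings.warn(
            "strict consensus impossible with unusable scales; falling back to tolerant"
        )
        mode = "tolerant"
    need = len(usable) if mode == "strict" else min(2, len(usable))
    counts: dict[str, int] = {}
    order: list[str] = []
    for r in usable:
        for g in r.connected_genes:
            if g not in counts:
                counts[g] = 0
                order.append(g)
            counts[g] += 1
    genes = [g for g in order if counts[g] >= need]
    if candidate_signature is not None:
        directions = {g: candidate_signature.directions[g] for g in genes}
        mean_z = {g: candidate_signature.mean_z[g] for g in genes if g in candidate_signature.mean_z}
        meta = dict(candidate_signature.meta)
    else:
        raise ValueError("candidate signature required to carry directions through consensus")
    meta.update({"refined": True, "consensus_mode": mode, "n_usable_scales": len(usable)})
    return Signature(genes=genes, directions=directions, mean_z=mean_z, meta=meta,
                     valid=bool(genes))


def refine_signature(matrix, signature: Signature, rb1_gene: str = "RB1",
                     mode: str = "auto", alphas=DEFAULT_ALPHAS,
                     invert_sides: bool = False):
    """Full multiscale refinement.  Returns (refined signature, scale results)."""
    if not signature.genes:
        raise ValueError("cannot refine an empty signature")
    genes = [g for g in signature.genes if g in matrix.data.index]
    if len(genes) < 2:
        raise ValueError("fewer than 2 signature genes present in the matrix")
    results = []
    for alpha in alphas:
        high, low = select_scale_samples(matrix, rb1_gene, alpha)
        if len(high) + len(low) < 3 or not high or not low:
            warnings.warn(f"scale alpha={alpha} unusable: empty or too-small sample side")
            results.append(ScaleResult(alpha=alpha, usable=False))
            continue
        results.append(
            optimize_threshold(matrix, genes, signature.directions, high, low,
                               invert_sides=invert_sides, alpha=alpha)
        )
    refined = multiscale_consensus(results, mode=mode, candidate_signature=signature)
    return refined, results
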