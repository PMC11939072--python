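"""Signature objects, alignment scoring, SVD metagene scores and set overlap.

A signature is an ordered gene list with a per-gene direction (+1/-1), the
sign of the mean expression z-score across RB1-defective discovery samples.
A sample's *alignment score* is the fraction of available signature genes
whose z-score sign matches the signature direction; samples are called
signature-high (>0.55), signature-low (<0.45) or no-confidence (the
inclusive 0.45-0.55 band).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Signature",
    "AlignmentResult",
    "OverlapResult",
    "signature_direction",
    "alignment_score",
    "classify_alignment",
    "score_cohort",
    "svd_signature_score",
    "build_core_signature",
    "overlap_coefficient",
]

ALIGNMENT_HIGH = 0.55
ALIGNMENT_LOW = 0.45


@dataclass
class Signature:
    """Ordered gene list with per-gene direction and provenance metadata.

    ``directions`` maps gene -> +1/-1; ``mean_z`` optionally records the mean
    defective-group z-score each direction was derived from.  ``valid`` is
    False for signatures that came out empty of a discovery/refinement stage.
    """

    genes: list[str]
    directions: dict[str, int]
    mean_z: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    valid: bool = True

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValueError(f"duplicate signature genes: {dupes}")
        missing = [g for g in self.genes if g not in self.directions]
        if missing:
            raise ValueError(f"genes without a direction: {missing}")
        bad = [g for g in self.genes if self.directions[g] not in (-1, 1)]
        if bad:
            raise ValueError(f"directions must be +1 or -1; offending genes: {bad}")

    def __len__(self) -> int:
        return len(self.genes)

    def direction_vector(self) -> np.ndarray:
        return np.array([self.directions[g] for g in self.genes], dtype=int)


@dataclass
class AlignmentResult:
    """Per-sample alignment scores and three-way classes."""

    scores: pd.Series  # sample -> alignment in [0, 1]
    n_genes_used: pd.Series  # sample -> available signature genes
    classes: pd.Series  # sample -> {"low", "no_confidence", "high"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alignment": self.scores,
                "n_genes_used": self.n_genes_used,
                "class": self.classes,
            }
        )


@dataclass
class OverlapResult:
    oc: float
    intersection: int
    min_size: int


def signature_direction(matrix, defective_samples, genes, meta=None) -> Signature:
    """Set per-gene directions from the sign of the mean z-score across the
    RB1-defective discovery samples.  Genes whose mean is exactly zero carry
    no usable direction and are dropped with a warning.
    """
    defective_samples = list(defective_samples)
    if not defective_samples:
        raise ValueError("defective_samples must be nonempty")
    missing = [g for g in genes if g not in matrix.data.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    sub = matrix.data.loc[list(genes), defective_samples]
    mean_z = sub.mean(axis=1)
    zero = mean_z.index[mean_z == 0.0].tolist()
    if zero:
        warnings.warn(f"dropping genes with mean z exactly 0: {zero}")
    kept = [g for g in genes if g not in set(zero)]
    if not kept:
        raise ValueError("all genes have zero mean z; no direction can be set")
    return Signature(
        genes=kept,
        directions={g: (1 if mean_z[g] > 0 else -1) for g in kept},
        mean_z={g: float(mean_z[g]) for g in kept},
        meta=dict(meta or {}),
    )


def alignment_score(sample_z: pd.Series, signature: Signature) -> float:
    """Fraction of available signature genes whose z-score sign matches the
    signature direction.  z exactly 0 has sign 0 and counts as discordant.
    Only genes measured in the sample's dataset are used.
    """
    avail = [g for g in signature.genes if g in sample_z.index]
    if not avail:
        raise ValueError(
            f"no signature gene available in sample (signature meta={signature.meta})"
        )
    z = sample_z[avail].to_numpy(dtype=float)
    d = np.array([signature.directions[g] for g in avail])
    return float(np.mean(np.sign(z) == d))


def classify_alignment(score: float) -> str:
    """Three-way call: >0.55 high, <0.45 low, inclusive middle no_confidence."""
    if not (0.0 <= score <= 1.0) or not math.isfinite(score):
        raise ValueError(f"alignment score out of [0, 1]: {score}")
    if score > ALIGNMENT_HIGH:
        return "high"
    if score < ALIGNMENT_LOW:
        return "low"
    return "no_confidence"


def score_cohort(matrix, signature: Signature) -> AlignmentResult:
    """Alignment scores and classes for every sample of a z-scored matrix."""
    avail = [g for g in signature.genes if g in matrix.data.index]
    if not avail:
        raise ValueError(
            f"no signature gene available in matrix (signature meta={signature.meta})"
        )
    z = matrix.data.loc[avail].to_numpy(dtype=float)
    d = np.array([signature.directions[g] for g in avail])[:, None]
    concord = np.sign(z) == d
    scores = pd.Series(concord.mean(axis=0), index=matrix.samples, name="alignment")
    classes = scores.map(classify_alignment)
    n_used = pd.Series(len(avail), index=matrix.samples, name="n_genes_used")
    return AlignmentResult(scores=scores, n_genes_used=n_used, classes=classes)


def svd_signature_score(matrix, genes) -> pd.DataFrame:
    """SVD metagene score for benchmarking arbitrary gene-list signatures.

    Signature gene rows are standardized to mean 0 / SD 1 and the per-sample
    score is the projection onto the first right-singular vector.  The sign of
    a singular vector is arbitrary, so the score is oriented to correlate
    positively with the mean standardized expression of the signature's
    up-regulated genes (all genes when the list carries no directions).
    Samples are trichotomized by tertiles into low / mid / high.
    """
    if isinstance(genes, Signature):
        gene_list = genes.genes
        up = [g for g in gene_list if genes.directions[g] > 0] or gene_list
    else:
        gene_list = list(genes)
        up = gene_list
    avail = [g for g in gene_list if g in matrix.data.index]
    if len(avail) < 2:
        raise ValueError("need at least 2 signature genes present in the matrix")
    if len(matrix.samples) < 3:
        raise ValueError("need at least 3 samples")
    x = matrix.data.loc[avail].to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all signature genes are constant")
    avail = [g for g, k in zip(avail, keep) if k]
    x = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    score = vt[0]
    up_avail = [g for g in up if g in avail]
    ref = x[[avail.index(g) for g in up_avail]].mean(axis=0) if up_avail else x.mean(axis=0)
    if np.dot(score, ref) < 0:
        score = -score
    q1, q2 = np.quantile(score, [1 / 3, 2 / 3])
    tertile = np.where(score <= q1, "low", np.where(score <= q2, "mid", "high"))
    return pd.DataFrame({"score": score, "tertile": tertile}, index=matrix.samples)


def build_core_signature(signatures: list[Signature], min_types: int | None = None) -> Signature:
    """Pan-cancer core: genes recurring in at least ``min_types`` of the
    per-cancer-type signatures (default max(3, ceil(0.2 * n_types)), which
    reproduces the 3-of-14 rule).  Core direction is the majority sign of the
    member directions; zero-sum genes are dropped with a warning.
    """
    if len(signatures) < 2:
        raise ValueError("need at least 2 input signatures")
    n_types = len(signatures)
    if min_types is None:
        min_types = max(3, math.ceil(0.2 * n_types))
    counts: dict[str, int] = {}
    sums: dict[str, int] = {}
    order: list[str] = []
    for sig in signatures:
        for g in sig.genes:
            if g not in counts:
                counts[g] = 0
                sums[g] = 0
                order.append(g)
            counts[g] += 1
            sums[g] += sig.directions[g]
    members = [g for g in order if counts[g] >= min_types]
    zero = [g for g in members if sums[g] == 0]
    if zero:
        warnings.warn(f"dropping core genes with tied directions: {zero}")
    kept = [g for g in members if sums[g] != 0]
    return Signature(
        genes=kept,
        directions={g: (1 if sums[g] > 0 else -1) for g in kept},
        meta={"kind": "core", "min_types": min_types, "n_types": n_types},
        valid=bool(kept),
    )


def overlap_coefficient(genes_a, genes_b, exclude=frozenset({"RB1"})) -> OverlapResult:
    """Overlap coefficient |A∩B| / min(|A|,|B|) after removing excluded genes
    (RB1 by default, to adjust for the single-count overlap bias of RB1 being
    a member of every RB1-dysfunction signature).
    """
    a = set(genes_a) - set(exclude)
    b = set(genes_b) - set(exclude)
    if not a or not b:
        raise ValueError("gene set empty after exclusion")
    inter = len(a & b)
    min_size = min(len(a), len(b))
    return OverlapResult(oc=inter / min_size, intersection=inter, min_size=min_size)
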