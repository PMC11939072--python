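"""Per-sample RB1 status calling and discovery-group assembly.

Two variants are implemented.  The proteogenomic variant calls a sample
RB1-defective when it shows low total Rb protein, hyperphosphorylated Rb
with low total Rb, a truncating RB1 mutation, or an RB1 deep deletion, and
RB1-proficient when it carries none of the genomic defects, has Rb protein
above 0 and RB1 mRNA z-score >= 0.2.  Missense RB1 mutations are excluded
from both groups (indeterminate) because their functional consequence is
uncertain.  The genomic (pan-cancer) variant, used where proteomics is
unavailable, treats truncating or splice-site mutations and copy-number
deletion as defects and balances the groups by taking the top-M samples by
RB1 mRNA z-score as proficient.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import normalize_variant_class

__all__ = [
    "CnaCall",
    "RbStatusCall",
    "DiscoveryGroups",
    "LOW_RB_CUTS",
    "call_cna_state",
    "median_prb",
    "call_rb_status",
    "select_discovery_groups",
    "select_discovery_groups_genomic",
]

# Platform-specific low-Rb protein cuts.  The CPTAC phase 2/3 cut is chosen
# to match the proportion of low-Rb patients seen on the TCGA platform.
LOW_RB_CUTS = {"tcga": -0.2, "cptac23": -0.7}

DEFECT_FLAGS = frozenset({"low_rb", "hyperphospho", "truncating_mut", "splice_mut", "deep_deletion"})


@dataclass(frozen=True)
class CnaCall:
    log2_ratio: float
    state: str  # deep_deletion | loss | neutral | gain | amplification


@dataclass(frozen=True)
class RbStatusCall:
    sample: str
    status: str  # defective | proficient | indeterminate
    evidence: frozenset = field(default_factory=frozenset)


@dataclass
class DiscoveryGroups:
    """Disjoint RB1-defective (size n, written M in the genomic variant) and
    RB1-proficient (size m) discovery sample lists."""

    defective: list[str]
    proficient: list[str]
    platform: str

    def __post_init__(self) -> None:
        overlap = set(self.defective) & set(self.proficient)
        if overlap:
            raise ValueError(f"groups overlap: {sorted(overlap)}")

    @property
    def n(self) -> int:
        return len(self.defective)

    @property
    def m(self) -> int:
        return len(self.proficient)


def call_cna_state(log2_ratio: float) -> CnaCall:
    """Copy-number state from a log2 ratio: |r| < 0.3 neutral, 0.3 <= |r| <= 1
    gain/loss, |r| > 1 amplification/deep deletion."""
    r = float(log2_ratio)
    if not math.isfinite(r):
        raise ValueError(f"non-finite log2 ratio: {log2_ratio}")
    a = abs(r)
    if a < 0.3:
        return CnaCall(r, "neutral")
    if a <= 1.0:
        return CnaCall(r, "gain" if r > 0 else "loss")
    return CnaCall(r, "amplification" if r > 0 else "deep_deletion")


def median_prb(site_values) -> float | None:
    """Median phospho-Rb abundance across the phospho-sites measured for a
    sample.  With no phospho data the hyperphosphorylation rule is
    unevaluable (not failed): returns None."""
    values = [float(v) for v in site_values]
    if not values:
        return None
    return float(np.median(values))


def call_rb_status(
    sample: str,
    rb: float | None = None,
    prb_sites=(),
    mutation_class: str | None = None,
    cna_log2: float | None = None,
    mrna_z: float | None = None,
    platform: str = "tcga",
) -> RbStatusCall:
    """Proteogenomic RB1 status call for one sample.

    Missing modalities are allowed (the corresponding rules are simply
    unevaluable); a sample with no modality at all raises.
    """
    if platform not in LOW_RB_CUTS:
        raise ValueError(f"platform must be one of {sorted(LOW_RB_CUTS)}, got {platform!r}")
    mutation = normalize_variant_class(mutation_class) if mutation_class is not None else None
    if rb is None and not list(prb_sites) and mutation is None and cna_log2 is None and mrna_z is None:
        raise ValueError(f"sample {sample!r}: all modalities missing")

    if mutation == "missense":
        return RbStatusCall(sample, "indeterminate", frozenset({"missense_excluded"}))

    flags = set()
    low_cut = LOW_RB_CUTS[platform]
    if rb is not None and rb <= low_cut:
        flags.add("low_rb")
    prb = median_prb(prb_sites)
    # the pRb - Rb >= 0.2 boundary is inclusive; allow for float representation
    if prb is not None and rb is not None and prb >= 0.3 and rb <= 0.2 and prb - rb >= 0.2 - 1e-9:
        flags.add("hyperphospho")
    if mutation == "truncating":
        flags.add("truncating_mut")
    deep_del = cna_log2 is not None and call_cna_state(cna_log2).state == "deep_deletion"
    if deep_del:
        flags.add("deep_deletion")

    if flags:
        return RbStatusCall(sample, "defective", frozenset(flags))

    proficient = (
        mutation != "truncating"
        and not deep_del
        and rb is not None
        and rb > 0
        and mrna_z is not None
        and mrna_z >= 0.2
    )
    if proficient:
        return RbStatusCall(sample, "proficient", frozenset({"high_rb_mrna"}))
    return RbStatusCall(sample, "indeterminate", frozenset())


def select_discovery_groups(calls, platform: str = "tcga") -> DiscoveryGroups:
    """Assemble the discovery population from per-sample status calls.

    The defective group is the union of samples called defective by any rule
    (a sample defective by two rules is counted once); the proficient group
    is every sample called proficient.  Either group empty is an error.
    """
    defective, proficient, seen = [], [], set()
    for call in calls:
        if call.sample in seen:
            raise ValueError(f"duplicate call for sample {call.sample!r}")
        seen.add(call.sample)
        if call.status == "defective":
            defective.append(call.sample)
        elif call.status == "proficient":
            proficient.append(call.sample)
    if not defective:
        raise ValueError("empty RB1-defective discovery group")
    if not proficient:
        raise ValueError("empty RB1-proficient discovery group")
    return DiscoveryGroups(defective=defective, proficient=proficient, platform=platform)


def select_discovery_groups_genomic(
    mutation_class: pd.Series,
    cna_log2: pd.Series,
    mrna_z: pd.Series,
    include_loss: bool = False,
    min_defective: int = 3,
) -> DiscoveryGroups:
    """Genomic-variant discovery groups for cohorts without proteomics.

    Defective = truncating or splice-site RB1 mutation, or RB1 copy-number
    deep deletion (``include_loss`` additionally accepts shallow loss).  The
    proficient group is the top-M samples by RB1 mRNA z-score among the
    remaining samples, M being the defective group size, which balances the
    two groups.  Ties at the M-th z value break by lexicographic sample id.
    """
    samples = list(mrna_z.index)
    defective = []
    for s in samples:
        mut = mutation_class.get(s)
        mut = normalize_variant_class(mut) if mut is not None and not pd.isna(mut) else "other"
        cna = cna_log2.get(s)
        state = call_cna_state(cna).state if cna is not None and not pd.isna(cna) else "neutral"
        cna_defect = state == "deep_deletion" or (include_loss and state == "loss")
        if mut in ("truncating", "splice") or cna_defect:
            defective.append(s)
    m = len(defective)
    if m < min_defective:
        raise ValueError(
            f"genomic variant needs at least {min_defective} RB1-defective samples, found {m}"
        )
    rest = [s for s in samples if s not in set(defective)]
    if len(rest) < m:
        raise ValueError("not enough non-defective samples to balance the groups")
    ranked = sorted(rest, key=lambda s: (-float(mrna_z[s]), s))
    proficient = ranked[:m]
    return DiscoveryGroups(defective=defective, proficient=proficient, platform="genomic")
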