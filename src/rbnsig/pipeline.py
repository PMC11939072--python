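"""End-to-end chains: status calling on a cohort, signature discovery
(initial selection -> LOOL -> final filters), and refinement + scoring
conveniences used by the command line and the test-bench."""
from __future__ import annotations

import pandas as pd

from . import de, rb_status, refine as refine_mod, scoring
from .io import ExpressionMatrix, zscore_by_gene
from .simulate import RB1, SyntheticCohort

__all__ = [
    "call_cohort_status",
    "cohort_discovery_groups",
    "discover_signature",
    "discover_from_cohort",
]


def call_cohort_status(cohort: SyntheticCohort, platform: str = "tcga"):
    """Proteogenomic status calls for every sample of a synthetic cohort."""
    z = zscore_by_gene(cohort.expression)
    rb1_z = z.data.loc[RB1]
    mut = {}
    for _, row in cohort.mutations.iterrows():
        if row["gene"] == RB1:
            # truncating dominates missense which dominates the rest
            prev = mut.get(row["sample"])
            rank = {"truncating": 3, "splice": 2, "missense": 1, "other": 0}
            if prev is None or rank[row["variant_class"]] > rank[prev]:
                mut[row["sample"]] = row["variant_class"]
    cna = cohort.cna[cohort.cna["gene"] == RB1].set_index("sample")["log2_ratio"]
    calls = []
    for s in cohort.expression.samples:
        calls.append(
            rb_status.call_rb_status(
                s,
                rb=float(cohort.protein[s]),
                prb_sites=list(cohort.phospho.get(s, {}).values()),
                mutation_class=mut.get(s),
                cna_log2=float(cna[s]) if s in cna.index else None,
                mrna_z=float(rb1_z[s]),
                platform=platform,
            )
        )
    return calls


def cohort_discovery_groups(cohort: SyntheticCohort, platform: str = "tcga"):
    return rb_status.select_discovery_groups(call_cohort_status(cohort, platform), platform)


def discover_signature(
    matrix: ExpressionMatrix,
    groups: rb_status.DiscoveryGroups,
    initial_abs_fc: float = 0.585,
    lool_abs_fc: float = 1.0,
    max_q: float = 0.1,
    min_fraction: float | None = 0.20,
    min_mean_z: float = 0.2,
    min_consistency: float = 0.60,
    meta=None,
):
    """Unrefined signature discovery on a z-scored matrix.

    Fits the moderated model on the full discovery population, selects genes
    of interest (|log2FC| >= 0.585, q < 0.1), evaluates their leave-one-out
    robustness, and applies the final filters.  ``min_fraction=None``
    chooses the pan-cancer branch from the initial gene count (50% when more
    than 20 genes were initially found, else 20%).  Returns
    (signature, lool_result, de_table).
    """
    if matrix.value_kind != "zscore":
        raise ValueError("discovery expects a z-scored matrix; call zscore_by_gene first")
    de_table = de.fit_moderated_de(matrix, groups.defective, groups.proficient)
    candidates = de.initial_gene_selection(de_table, min_abs_fc=initial_abs_fc, max_q=max_q)
    if min_fraction is None:
        min_fraction = de.lool_pancancer_fraction(len(candidates))
    lool_result = de.lool(matrix, groups, candidates, min_abs_fc=lool_abs_fc, max_q=max_q)
    meta = dict(meta or {})
    meta.update({"platform": groups.platform, "n": groups.n, "m": groups.m,
                 "n_initial": len(candidates)})
    signature = de.final_gene_filter(
        lool_result,
        min_fraction=min_fraction,
        min_mean_z=min_mean_z,
        min_consistency=min_consistency,
        meta=meta,
    )
    return signature, lool_result, de_table


def discover_from_cohort(cohort: SyntheticCohort, platform: str = "tcga",
                         refine: bool = False, **kwargs):
    """Convenience chain on a synthetic cohort: z-score, call status, build
    discovery groups, discover, optionally refine.  Returns (signature,
    groups, z-matrix)."""
    z = zscore_by_gene(cohort.expression)
    groups = cohort_discovery_groups(cohort, platform)
    signature, _, _ = discover_signature(z, groups, **kwargs)
    if refine and signature.valid:
        signature, _ = refine_mod.refine_signature(z, signature, rb1_gene=RB1)
    return signature, groups, z
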