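"""Synthetic proteogenomic cohorts with planted RB1-defective and phenocopy
structure.

The generator emulates the statistical shape of a proteogenomic discovery
cohort: a gene x sample log2-ratio-like expression matrix with a planted
signature gene set shifted by a chosen |log2 fold change| in the defective
and phenocopy samples; per-sample total-Rb protein and phospho-Rb site
abundances (iTRAQ-ratio-like); an MAF-like mutation table; per-gene
copy-number log2 ratios; and ground-truth labels.  Each defective sample
is made to pass exactly one randomly chosen defective criterion (low Rb,
hyperphosphorylated Rb, truncating mutation, or deep deletion) so the
status-calling rules can be exercised in isolation; phenocopy samples
carry the planted expression shift but no genomic or proteomic lesion.

Screen tables (CRISPR gene effect and drug-response dr-AUC) with planted
synthetic-lethal genes are generated separately.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .io import ExpressionMatrix
from .scoring import Signature

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "plant_correlated_block",
    "generate_screen_tables",
    "generate_refinement_benchmark",
]

RB1 = "RB1"
_MECHANISMS = ("low_rb", "hyperphospho", "truncating_mut", "deep_deletion")
_PHOSPHO_SITES = ("S807", "S811", "T826", "S780", "T373")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


class CohortSpec(BaseModel):
    """Study conditions for one synthetic cohort.

    Defaults describe the discovery conditions exercised throughout the test
    suite: 2000 genes of which 40 carry a planted |log2FC| of 1.5, a cohort
    of 100 samples with 20 RB1-defective, 10 phenocopy and 25 designated
    proficient samples, per-gene noise SD 0.5, and 10% of samples missing
    phospho-site data.
    """

    model_config = ConfigDict(frozen=True)

    n_genes: int = Field(default=2000, gt=1)
    n_samples: int = Field(default=100, gt=3)
    n_signature_genes: int = Field(default=40, gt=0)
    frac_defective: float = Field(default=0.20, ge=0.0, le=1.0)
    frac_phenocopy: float = Field(default=0.10, ge=0.0, le=1.0)
    n_proficient: int = Field(default=25, ge=0)
    effect_log2fc: float = Field(default=1.5, ge=0.0)
    noise_sd: float = Field(default=0.5, gt=0.0)
    frac_missing_phospho: float = Field(default=0.10, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if self.frac_defective + self.frac_phenocopy > 1.0:
            raise ValueError("frac_defective + frac_phenocopy must not exceed 1")
        if self.n_signature_genes >= self.n_genes:
            raise ValueError("n_signature_genes must be smaller than n_genes")
        if self.n_defective + self.n_phenocopy + self.n_proficient > self.n_samples:
            raise ValueError("defective + phenocopy + proficient exceed n_samples")
        return self

    # group sizes use round-half-up on frac * n_samples so tests are exact
    @property
    def n_defective(self) -> int:
        return _round_half_up(self.frac_defective * self.n_samples)

    @property
    def n_phenocopy(self) -> int:
        return _round_half_up(self.frac_phenocopy * self.n_samples)


@dataclass
class SyntheticCohort:
    """Matched synthetic modalities plus the planted ground truth."""

    spec: CohortSpec
    expression: ExpressionMatrix  # log2-ratio-like values, RB1 included
    protein: pd.Series  # sample -> total Rb abundance
    phospho: dict  # sample -> {site: value} (empty dict = missing phospho)
    mutations: pd.DataFrame  # sample, gene, variant_class
    cna: pd.DataFrame  # sample, gene, log2_ratio
    truth: pd.Series  # sample -> defective | phenocopy | background
    truth_genes: Signature  # planted signature genes with planted directions

    def phospho_long(self) -> pd.DataFrame:
        rows = [
            {"sample": s, "site": site, "value": v}
            for s, sites in self.phospho.items()
            for site, v in sites.items()
        ]
        return pd.DataFrame(rows, columns=["sample", "site", "value"])


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate one cohort.  Identical spec (including seed) gives a
    bit-identical cohort."""
    rng = np.random.default_rng(spec.seed)
    n_def, n_phe, n_pro = spec.n_defective, spec.n_phenocopy, spec.n_proficient
    samples = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    defective = samples[:n_def]
    phenocopy = samples[n_def : n_def + n_phe]
    proficient = samples[n_def + n_phe : n_def + n_phe + n_pro]
    other = samples[n_def + n_phe + n_pro :]
    shifted = set(defective) | set(phenocopy)

    sig_genes = [f"SIG{i + 1:04d}" for i in range(spec.n_signature_genes)]
    n_noise = spec.n_genes - spec.n_signature_genes - 1
    noise_genes = [f"G{i + 1:05d}" for i in range(n_noise)]
    genes = [RB1] + sig_genes + noise_genes

    x = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_samples))
    directions = rng.choice([-1, 1], size=spec.n_signature_genes)
    shift_cols = np.array([s in shifted for s in samples])
    x[1 : 1 + spec.n_signature_genes, shift_cols] += (
        directions[:, None] * spec.effect_log2fc
    )
    # RB1 expression is part of the phenotype: suppressed in defective and
    # phenocopy samples, elevated in designated proficient samples.
    rb1_row = np.empty(spec.n_samples)
    for i, s in enumerate(samples):
        if s in shifted:
            rb1_row[i] = rng.normal(-1.8, spec.noise_sd)
        elif s in set(proficient):
            rb1_row[i] = rng.normal(1.8, 0.25)
        else:
            rb1_row[i] = rng.normal(0.0, 0.4)
    x[0] = rb1_row
    expression = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples), "log2")

    mechanisms = {s: _MECHANISMS[rng.integers(len(_MECHANISMS))] for s in defective}
    protein = pd.Series(0.0, index=samples, name="rb")
    phospho: dict[str, dict[str, float]] = {}
    mut_rows = []
    cna_rb1 = pd.Series(rng.uniform(-0.2, 0.2, size=spec.n_samples), index=samples)

    for s in samples:
        mech = mechanisms.get(s)
        if mech == "low_rb":
            protein[s] = rng.uniform(-0.8, -0.25)
            phospho[s] = _low_phospho(rng)
        elif mech == "hyperphospho":
            # passes only the hyperphosphorylation rule: Rb in (-0.1, 0.15],
            # pRb site median >= 0.35, so pRb - Rb >= 0.2 holds
            protein[s] = rng.uniform(-0.1, 0.15)
            phospho[s] = {site: rng.uniform(0.35, 0.6) for site in _PHOSPHO_SITES}
        elif mech == "truncating_mut":
            protein[s] = rng.uniform(-0.1, 0.3)
            phospho[s] = _low_phospho(rng)
            mut_rows.append({"sample": s, "gene": RB1, "variant_class": "truncating"})
        elif mech == "deep_deletion":
            protein[s] = rng.uniform(-0.15, 0.0)
            phospho[s] = _low_phospho(rng)
            cna_rb1[s] = rng.uniform(-2.0, -1.2)
        elif s in set(phenocopy):
            # no proteomic/genomic lesion; fails proficiency through low RB1 mRNA
            protein[s] = rng.uniform(0.3, 0.8)
            phospho[s] = _low_phospho(rng)
        elif s in set(proficient):
            protein[s] = rng.uniform(0.3, 0.8)
            phospho[s] = _low_phospho(rng)
        else:
            # background: neither defective nor proficient (Rb <= 0)
            protein[s] = rng.uniform(-0.15, 0.0)
            phospho[s] = _low_phospho(rng)

    # a sprinkle of non-defect mutations: RB1 missense on background samples
    # and unrelated mutations elsewhere, to exercise the alias/exclusion paths
    for s in other[:2]:
        mut_rows.append({"sample": s, "gene": RB1, "variant_class": "missense"})
    for s in rng.choice(samples, size=min(5, spec.n_samples), replace=False):
        gene = noise_genes[int(rng.integers(len(noise_genes)))] if noise_genes else sig_genes[0]
        klass = ("missense", "other", "truncating")[int(rng.integers(3))]
        mut_rows.append({"sample": str(s), "gene": gene, "variant_class": klass})

    # missing phospho data, only where no hyperphospho evidence is required
    n_missing = _round_half_up(spec.frac_missing_phospho * spec.n_samples)
    eligible = [s for s in samples if mechanisms.get(s) != "hyperphospho"]
    for s in rng.choice(eligible, size=min(n_missing, len(eligible)), replace=False):
        phospho[str(s)] = {}

    mutations = pd.DataFrame(mut_rows, columns=["sample", "gene", "variant_class"])
    cna = pd.DataFrame({"sample": samples, "gene": RB1, "log2_ratio": cna_rb1.to_numpy()})

    truth = pd.Series("background", index=samples, name="truth")
    truth[defective] = "defective"
    truth[phenocopy] = "phenocopy"

    truth_genes = Signature(
        genes=sig_genes,
        directions={g: int(d) for g, d in zip(sig_genes, directions)},
        meta={"kind": "planted", "effect_log2fc": spec.effect_log2fc},
    )
    return SyntheticCohort(
        spec=spec,
        expression=expression,
        protein=protein,
        phospho=phospho,
        mutations=mutations,
        cna=cna,
        truth=truth,
        truth_genes=truth_genes,
    )


def _low_phospho(rng) -> dict[str, float]:
    return {site: rng.uniform(-0.2, 0.2) for site in _PHOSPHO_SITES}


def plant_correlated_block(
    matrix: ExpressionMatrix,
    genes,
    rho: float,
    seed: int,
    latent: np.ndarray | None = None,
    scale: float = 1.0,
) -> ExpressionMatrix:
    """Replace the listed gene rows with a correlated block.

    The block is induced by a single shared factor: each row becomes
    ``scale * (sqrt(rho) * latent + sqrt(1 - rho) * noise)``, giving an
    expected pairwise (Pearson, and for Gaussian data near-Spearman)
    correlation of rho.  The factor defaults to fresh standard-normal draws;
    passing ``latent`` couples the block to an external covariate such as
    RB1 expression.  Non-block genes are untouched; an empty gene set
    returns the matrix unchanged.
    """
    genes = list(genes)
    if not genes:
        return matrix
    missing = [g for g in genes if g not in matrix.data.index]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    if not (0 < rho < 1):
        raise ValueError("rho must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(matrix.samples)
    f = np.asarray(latent, dtype=float) if latent is not None else rng.standard_normal(n)
    if f.shape != (n,):
        raise ValueError(f"latent factor must have length {n}")
    data = matrix.data.copy()
    for g in genes:
        eps = rng.standard_normal(n)
        data.loc[g] = scale * (math.sqrt(rho) * f + math.sqrt(1 - rho) * eps)
    return ExpressionMatrix(data, matrix.value_kind)


def generate_refinement_benchmark(
    seed: int,
    n_samples: int = 2000,
    n_block: int = 30,
    n_decoy: int = 25,
    rho: float = 0.5,
):
    """Benchmark matrix for multiscale network refinement.

    A z-scored cohort at contemporary-cohort scale with an RB1 gene, a block
    of ``n_block`` signature genes driven by (anti-)RB1 expression through a
    single shared factor (pairwise correlation ``rho``, each gene carrying
    independent residual noise), and ``n_decoy`` candidate genes that are
    pure noise with random directions — the kind of gene a leave-one-out
    differential-expression pass can admit but that carries no coherent
    RB1-linked co-expression.  Block + decoys exceed 50 genes, so automatic
    consensus runs in strict mode.

    Returns (z_matrix, candidate_signature, block_gene_set, decoy_gene_set).
    """
    from .io import zscore_by_gene

    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:05d}" for i in range(n_samples)]
    block = [f"B{i + 1:03d}" for i in range(n_block)]
    decoy = [f"D{i + 1:03d}" for i in range(n_decoy)]
    genes = [RB1] + block + decoy
    x = rng.standard_normal((len(genes), n_samples))
    z = zscore_by_gene(ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples), "log2"))
    rb1_z = z.data.loc[RB1].to_numpy()
    planted = plant_correlated_block(z, block, rho=rho, seed=seed + 1_000_000, latent=-rb1_z)
    z = zscore_by_gene(ExpressionMatrix(planted.data, "log2"))
    directions = {g: 1 for g in block}
    directions.update({g: int(d) for g, d in zip(decoy, rng.choice([-1, 1], n_decoy))})
    signature = Signature(
        genes=block + decoy,
        directions=directions,
        meta={"kind": "refinement-benchmark", "rho": rho},
    )
    return z, signature, set(block), set(decoy)


def generate_screen_tables(
    n_genes: int,
    n_lines: int,
    sl_genes,
    group_labels: pd.Series | None = None,
    seed: int = 0,
    margin: float = 0.6,
):
    """Gene-effect and drug-response tables with planted synthetic-lethal
    structure.

    Planted genes (``sl_genes``) have their mean gene effect lowered by
    ``margin`` in the rb1_defective and rbness lines relative to the
    signature-low lines; all other genes are exchangeable across groups.
    The drug table plants one sensitising compound per planted gene (plus
    exchangeable decoy compounds) against the same groups.  Returns
    (dependency_table, drug_table, labels).
    """
    rng = np.random.default_rng(seed)
    sl_genes = list(sl_genes)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    unknown = [g for g in sl_genes if g not in genes]
    if unknown:
        raise KeyError(f"sl_genes outside the gene universe: {unknown}")
    lines = [f"CL{i + 1:04d}" for i in range(n_lines)]
    if group_labels is None:
        per = n_lines // 3
        labels = ["rb1_defective"] * per + ["rbness"] * per + ["low"] * (n_lines - 2 * per)
        group_labels = pd.Series(labels, index=lines)
    else:
        group_labels = pd.Series(group_labels.to_numpy(), index=lines)
    a_mask = group_labels.isin(["rb1_defective", "rbness"]).to_numpy()

    ge = rng.normal(-0.1, 0.15, size=(n_genes, n_lines))
    sl_idx = [genes.index(g) for g in sl_genes]
    for i in sl_idx:
        ge[i, a_mask] -= margin
    dependency = pd.DataFrame(ge, index=genes, columns=lines)

    compounds = [f"D{i + 1:04d}" for i in range(max(len(sl_genes), 1) + 20)]
    dr = rng.normal(0.3, 0.2, size=(len(compounds), n_lines))
    dr[:, ~a_mask] = rng.normal(0.3, 0.2, size=(len(compounds), int((~a_mask).sum())))
    for k in range(len(sl_genes)):
        dr[k, a_mask] = rng.normal(0.3 - margin - 0.4, 0.2, size=int(a_mask.sum()))
    drug = pd.DataFrame(dr, index=compounds, columns=lines)
    return dependency, drug, group_labels
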