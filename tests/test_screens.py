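"""Confusion metrics, enrichment, PGA, hypoxia-style median scores and the
perturbation-screen gating rules."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

import rbnsig.screens as screens
from rbnsig.screens import (
    cell_line_rb1_defective,
    compute_pga,
    confusion_metrics,
    crispr_sl_candidates,
    drug_sensitivity_candidates,
    fisher_enrichment,
    isogenic_screen_candidates,
    median_gene_score,
)
from rbnsig.simulate import generate_screen_tables

from conftest import matrix_from


def test_confusion_metrics_worked_examples():
    # 7 resistant samples all called positive: 100% sensitivity
    truth = [1] * 7 + [0] * 38
    calls = [1] * 7 + [1] * 12 + [0] * 26  # 12 of 38 negatives called positive
    sens, spec, table = confusion_metrics(truth, calls)
    assert sens == 1.0
    assert round(spec * 100, 2) == 68.42
    assert (table.tp, table.fp, table.tn, table.fn) == (7, 12, 26, 0)


def test_confusion_metrics_sentinels():
    sens, spec, _ = confusion_metrics([1, 1], [1, 0])
    assert spec is None and sens == 0.5
    sens, spec, _ = confusion_metrics([0, 0], [1, 0])
    assert sens is None and spec == 0.5
    with pytest.raises(ValueError):
        confusion_metrics([], [])


def fisher_oracle(a, b, c, d):
    """Exhaustive one-sided enrichment p over all tables with fixed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    total = 0.0
    for a2 in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        if a2 >= a:
            total += (
                math.comb(r1, a2) * math.comb(n - r1, c1 - a2) / math.comb(n, c1)
            )
    return total


def test_fisher_enrichment_balanced_and_degenerate():
    orr, p, cont = fisher_enrichment(10, 10, 10, 10)
    assert orr == 1.0 and not cont
    orr, p, cont = fisher_enrichment(5, 0, 0, 5)
    assert cont and orr > 100  # degenerate table, continuity-corrected OR
    assert p == pytest.approx(1 / 252)


def test_fisher_enrichment_matches_enumeration_small_margins():
    for a, b, c, d in itertools.product(range(0, 5), repeat=4):
        if a + b + c + d == 0:
            continue
        _, p, _ = fisher_enrichment(a, b, c, d)
        assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)


def test_fisher_enrichment_rejects_negatives():
    with pytest.raises(ValueError):
        fisher_enrichment(-1, 2, 3, 4)


def _seg(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "log2_ratio"])


def test_pga_conventions():
    segs = _seg([("s1", "1", 1, 100, 0.5), ("s1", "1", 101, 400, 0.1)])
    assert compute_pga(segs)["s1"] == pytest.approx(100 / 400)  # length-weighted
    assert compute_pga(segs, by_count=True)["s1"] == pytest.approx(0.5)
    quiet = _seg([("s1", "1", 1, 10, 0.2), ("s1", "2", 1, 10, -0.15)])
    assert compute_pga(quiet)["s1"] == 0.0  # |r| > 0.2 is strict
    equal = _seg([("s1", "1", 1, 50, 0.5), ("s1", "1", 51, 100, 0.0)])
    assert compute_pga(equal)["s1"] == pytest.approx(0.5)
    assert compute_pga(equal, by_count=True)["s1"] == pytest.approx(0.5)


def test_pga_invariant_to_order_and_splitting():
    segs = _seg([("s1", "1", 1, 100, 0.5), ("s1", "1", 101, 400, 0.1)])
    shuffled = segs.iloc[::-1].reset_index(drop=True)
    assert compute_pga(segs)["s1"] == compute_pga(shuffled)["s1"]
    split = _seg([
        ("s1", "1", 1, 50, 0.5), ("s1", "1", 51, 100, 0.5), ("s1", "1", 101, 400, 0.1),
    ])
    assert compute_pga(split)["s1"] == compute_pga(segs)["s1"]


def test_median_gene_score():
    m = matrix_from([[1.0, 5.0], [2.0, 6.0], [9.0, 7.0]])
    out = median_gene_score(m, ["g1", "g2", "g3"])
    assert out["s1"] == 2.0 and out["s2"] == 6.0
    # missing listed genes: median over the available ones
    out2 = median_gene_score(m, ["g1", "g2", "NOPE"])
    assert out2["s1"] == 1.5
    with pytest.raises(ValueError):
        median_gene_score(m, ["NOPE"])


def _dep_fixture(mean_a, mean_low, n=10, sd=0.1):
    # deterministic vectors with exact means and population SD = sd
    half = [(-sd), sd] * (n // 2)
    a = [mean_a + h for h in half]
    low = [mean_low + h for h in half]
    lines = [f"A{i}" for i in range(n)] + [f"L{i}" for i in range(n)]
    dep = pd.DataFrame([a + low], index=["gene1"], columns=lines)
    labels = pd.Series(["rb1_defective"] * n + ["low"] * n, index=lines)
    return dep, labels


@pytest.mark.parametrize(
    "mean_a,mean_low,testable",
    [
        (-0.8, -0.2, True),   # clean synthetic sickness
        (-0.8, -0.9, False),  # low group itself essential
        (-0.4, 0.0, False),   # group A effect too weak
    ],
)
def test_crispr_gating(mean_a, mean_low, testable):
    dep, labels = _dep_fixture(mean_a, mean_low)
    out = crispr_sl_candidates(dep, labels)
    assert (len(out) == 1) is testable
    if testable:
        # Welch p for these constructed vectors is far below 0.05
        assert out.loc["gene1", "p"] < 0.05
        assert bool(out.loc["gene1", "candidate"])


def test_crispr_gating_never_tests_gated_genes(monkeypatch):
    dep, labels = _dep_fixture(-0.4, 0.0)
    called = []
    original = screens._welch_one_sided_less
    monkeypatch.setattr(screens, "_welch_one_sided_less", lambda *a: called.append(1) or original(*a))
    crispr_sl_candidates(dep, labels)
    assert called == []  # gate failed: no statistical test was run


def test_crispr_group_size_validation():
    dep, labels = _dep_fixture(-0.8, -0.2, n=10)
    labels.iloc[:8] = "other"  # only 2 rb1_defective lines remain
    with pytest.raises(ValueError, match="rb1_defective"):
        crispr_sl_candidates(dep, labels)


@pytest.mark.parametrize(
    "z_ko,z_parent,candidate",
    [
        (-3.0, -0.5, True),   # delta -2.5, ko essential, parent viable
        (-3.0, -5.0, False),  # parent itself dead (<= -4)
        (-2.5, -1.0, False),  # delta -1.5 too small
        (-1.5, 1.0, False),   # ko z above -2
    ],
)
def test_isogenic_filters(z_ko, z_parent, candidate):
    df = pd.DataFrame({"z_knockout": [z_ko], "z_parent": [z_parent]}, index=["g"])
    assert (isogenic_screen_candidates(df) == ["g"]) is candidate


def test_isogenic_missing_column():
    with pytest.raises(ValueError, match="z_parent"):
        isogenic_screen_candidates(pd.DataFrame({"z_knockout": [1.0]}))


@pytest.mark.parametrize(
    "mean_low,mean_a,testable",
    [(0.1, -0.6, True), (-0.2, -0.8, False), (0.3, -0.4, False)],
)
def test_drug_gating(mean_low, mean_a, testable):
    dep, labels = _dep_fixture(mean_a, mean_low)
    dep.index = ["compound1"]
    out = drug_sensitivity_candidates(dep, labels)
    assert (len(out) == 1) is testable


def test_planted_sl_recovery_and_null():
    sl = [f"G{i + 1:05d}" for i in range(0, 30, 2)]
    dep, _, labels = generate_screen_tables(200, 60, sl, seed=4, margin=0.6)
    out = crispr_sl_candidates(dep, labels)
    hits = set(out.index[out["candidate"]])
    recall = len(hits & set(sl)) / len(sl)
    fdp = len(hits - set(sl)) / max(len(hits), 1)
    assert recall >= 0.9 and fdp <= 0.1
    # with nothing planted, almost nothing passes the gates
    dep0, _, labels0 = generate_screen_tables(200, 60, [], seed=5)
    out0 = crispr_sl_candidates(dep0, labels0)
    assert int(out0["candidate"].sum()) <= 0.05 * 200 * 2


def test_cell_line_defective_rule():
    assert cell_line_rb1_defective(mrna_z=-2.5)
    assert cell_line_rb1_defective(rb1_fusion=True, mrna_z=0.0)
    assert cell_line_rb1_defective(mutation_damaging=True)
    assert not cell_line_rb1_defective(mrna_z=-1.9)
    with pytest.raises(ValueError):
        cell_line_rb1_defective()
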