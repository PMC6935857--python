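"""Paralog/ortholog branch partition, the per-branch episodic-selection
test, selected fractions and the paired Wilcoxon comparison."""

import numpy as np
import pytest
from scipy import stats

from ciliaevol import (
    BranchTestResult,
    LabeledTree,
    OmegaDistribution,
    branch_selection_test,
    compare_fractions,
    label_tree,
    mark_paralog_branches,
    selected_fractions,
    screen_branches,
)
from ciliaevol.branch_selection import GroupFractions, ParalogOrthologSummary
from ciliaevol.simulate import (
    AlignmentConfig,
    TreeConfig,
    gen_codon_alignment,
    gen_labeled_tree,
)


# ---------------------------------------------------------------------------
# branch partition
# ---------------------------------------------------------------------------


def test_all_singletons_no_paralog_branches():
    lt = LabeledTree.from_newick("((A:1,B:1):1,C:1);")
    part = mark_paralog_branches(lt, {"A": "sp1", "B": "sp2", "C": "sp3"})
    assert all(
        v == ("other" if "|" in k else "ortholog") for k, v in part.items()
    )


def test_multi_copy_species_counts():
    lt = LabeledTree.from_newick(
        "((a1:1,(a2:1,a3:1):1):1,((b:1,c:1):1,(d:1,e:1):1):1);"
    )
    seq_to_species = {
        "a1": "A", "a2": "A", "a3": "A",
        "b": "B", "c": "C", "d": "D", "e": "E",
    }
    part = mark_paralog_branches(lt, seq_to_species)
    paralogs = {k for k, v in part.items() if v == "paralog"}
    orthologs = {k for k, v in part.items() if v == "ortholog"}
    assert paralogs == {"a1", "a2", "a3"}
    assert orthologs == {"b", "c", "d", "e"}


def test_unmapped_leaf_errors():
    lt = LabeledTree.from_newick("(A:1,B:1);")
    with pytest.raises(ValueError, match="B"):
        mark_paralog_branches(lt, {"A": "sp1"})


@pytest.mark.parametrize("seed", [6, 7])
def test_partition_matches_multiplicity_oracle(seed):
    rng = np.random.default_rng(seed)
    copies = {f"K_sp{i:02d}": int(rng.integers(1, 4)) for i in range(4)}
    lt, truth = gen_labeled_tree(
        TreeConfig(seed=seed, taxa_per_group={"K": 4, "NEF": 3},
                   paralog_copies=copies)
    )
    seq_to_species = truth.truth["seq_to_species"]
    part = mark_paralog_branches(lt, seq_to_species)
    mult = {}
    for sp in seq_to_species.values():
        mult[sp] = mult.get(sp, 0) + 1
    for leaf in lt.leaf_labels():
        expected = "paralog" if mult[seq_to_species[leaf]] >= 2 else "ortholog"
        assert part[leaf] == expected


# ---------------------------------------------------------------------------
# the per-branch test
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def paralog_tree():
    lt, truth = gen_labeled_tree(
        TreeConfig(seed=2, taxa_per_group={"K": 4, "NEF": 4},
                   paralog_copies={"K_sp00": 3, "NEF_sp01": 2})
    )
    return lt, truth


def test_branch_test_nesting_and_boundary_p(paralog_tree):
    lt, _ = paralog_tree
    aln, _ = gen_codon_alignment(lt, AlignmentConfig(seed=3, n_codons=150))
    r = branch_selection_test(aln, lt, "K_sp03")
    assert r.logL_alt >= r.logL_null
    assert 0 <= r.p_value <= 1
    if r.lrt == 0:
        assert r.p_value == 1.0
    assert r.corrected_p >= r.p_value - 1e-12


def test_branch_test_power_on_planted_selection(paralog_tree):
    """A branch simulated with 30% of sites at omega = 5 is flagged far
    more often than a purifying-only branch."""
    lt, _ = paralog_tree
    focal = "K_sp03"
    planted = OmegaDistribution((0.2, 0.2, 5.0), (0.35, 0.35, 0.30))
    power_p, null_p = [], []
    for seed in range(6):
        aln, _ = gen_codon_alignment(
            lt, AlignmentConfig(seed=100 + seed, n_codons=300,
                                branch_overrides={focal: planted})
        )
        power_p.append(branch_selection_test(aln, lt, focal).p_value)
        aln0, _ = gen_codon_alignment(
            lt,
            AlignmentConfig(
                seed=200 + seed, n_codons=300,
                reference_dist=OmegaDistribution(
                    (0.2, 0.2, 1.0), (0.4, 0.3, 0.3)
                ),
            ),
        )
        null_p.append(branch_selection_test(aln0, lt, focal).p_value)
    assert np.median(power_p) < 0.1
    assert sum(p < 0.05 for p in power_p) > sum(p < 0.05 for p in null_p)


def test_holm_correction_is_monotone_and_never_smaller(paralog_tree):
    lt, _ = paralog_tree
    aln, _ = gen_codon_alignment(lt, AlignmentConfig(seed=9, n_codons=100))
    terminal = [l for l in lt.leaf_labels()][:5]
    results = screen_branches(aln, lt, branches=terminal)
    by_raw = sorted(results, key=lambda r: r.p_value)
    for a, b in zip(by_raw, by_raw[1:]):
        assert a.corrected_p <= b.corrected_p + 1e-12
    for r in results:
        assert r.corrected_p >= r.p_value - 1e-12


def test_too_short_alignment_flagged():
    lt = LabeledTree.from_newick("(A:0.1,B:0.1);")
    label_tree(lt, {"A": "K", "B": "K"})
    aln, _ = gen_codon_alignment(lt, AlignmentConfig(seed=1, n_codons=10))
    r = branch_selection_test(aln, lt, "A")
    assert r.p_value == 1.0
    assert not r.selected


# ---------------------------------------------------------------------------
# fractions and their comparison
# ---------------------------------------------------------------------------


def _result(branch, selected):
    return BranchTestResult(
        branch=branch, omega_background=0.3, omega_classes=(0.2, 2.0),
        weights=(0.8, 0.2), logL_null=0.0, logL_alt=0.0, lrt=0.0,
        p_value=0.01 if selected else 0.9,
        corrected_p=0.01 if selected else 0.9, selected=selected,
    )


def test_selected_fractions_arithmetic():
    partition = {
        **{f"p{i}": "paralog" for i in range(4)},
        **{f"o{i}": "ortholog" for i in range(5)},
        "internal": "other",
    }
    groups = {f"p{i}": "K" for i in range(4)}
    groups.update({f"o{i}": "K" for i in range(5)})
    results = [
        _result("p0", True), _result("p1", True),
        _result("p2", False), _result("p3", False),
        _result("o0", True),
        *[_result(f"o{i}", False) for i in range(1, 5)],
    ]
    summary = selected_fractions(results, partition, groups, "gf1")
    f = summary.fractions["K"]
    assert f.paralog_fraction == pytest.approx(0.5)
    assert f.ortholog_fraction == pytest.approx(0.2)
    # order invariance
    summary2 = selected_fractions(results[::-1], partition, groups, "gf1")
    assert summary2.fractions["K"].paralog_fraction == pytest.approx(0.5)


def test_group_without_both_categories_excluded():
    partition = {"p0": "paralog", "o0": "ortholog"}
    groups = {"p0": "K", "o0": "H"}
    summary = selected_fractions(
        [_result("p0", False), _result("o0", False)], partition, groups
    )
    assert summary.fractions == {}


def _summary(name, par, ort):
    return ParalogOrthologSummary(
        alignment=name,
        fractions={
            "K": GroupFractions(
                group="K",
                paralog_total=10, paralog_selected=int(round(par * 10)),
                ortholog_total=10, ortholog_selected=int(round(ort * 10)),
            )
        },
    )


def test_compare_fractions_identical_pairs_p_one():
    summaries = [_summary(f"a{i}", 0.3, 0.3) for i in range(8)]
    cmp = compare_fractions(summaries, "K")
    assert cmp.p_value == 1.0


def test_compare_fractions_matches_exact_wilcoxon():
    """Constant paired difference across 8 alignments: p equals the exact
    two-sided signed-rank enumeration value 2 * 2^-8."""
    summaries = [_summary(f"a{i}", 0.6, 0.1) for i in range(8)]
    cmp = compare_fractions(summaries, "K")
    ref = stats.wilcoxon([0.6] * 8, [0.1] * 8, alternative="two-sided")
    assert cmp.p_value == pytest.approx(float(ref.pvalue))
    assert cmp.p_value == pytest.approx(2 * 0.5**8)
    assert cmp.paralog_median == pytest.approx(0.6)


def test_compare_fractions_requires_five_pairs():
    with pytest.raises(ValueError, match=">= 5"):
        compare_fractions([_summary("a", 0.5, 0.2)] * 4, "K")


def test_wilcoxon_type_one_error_on_exchangeable_fractions():
    """Swapping paralog/ortholog fractions at random gives ~5% rejections."""
    rng = np.random.default_rng(17)
    rejections = 0
    n_rep = 1000
    for _ in range(n_rep):
        base = rng.uniform(0, 1, size=(12, 2))
        swap = rng.random(12) < 0.5
        par = np.where(swap, base[:, 0], base[:, 1])
        ort = np.where(swap, base[:, 1], base[:, 0])
        res = stats.wilcoxon(par, ort, alternative="two-sided")
        rejections += res.pvalue < 0.05
    assert rejections / n_rep == pytest.approx(0.05, abs=0.02)
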