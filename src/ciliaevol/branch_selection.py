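"""Per-branch episodic diversifying selection and the paralog/ortholog
comparison.

A simplified branch-site random-effects test in the spirit of aBSREL with a
fixed two-class focal branch model: background branches share one omega; the
focal branch mixes a constrained class (omega <= 1) with a free class whose
null value is 1.  Evidence of omega > 1 on the branch is assessed by a
likelihood-ratio test against the boundary mixture 1/2 chi2_0 + 1/2 chi2_1,
with Holm-Bonferroni correction across the branches tested in one tree.

Terminal branches are split into paralog branches (their species contributes
two or more sequences to the alignment) and ortholog branches (exactly one);
per alignment and group, the fractions of selected branches among each class
are compared across alignments with a paired two-sided Wilcoxon signed-rank
test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .codon_model import CodonAlignment, PruningEngine, hky_exchangeabilities
from .genetic_code import GeneticCode, PRESET_CODES
from .phylo import LabeledTree
from .relax import prefit_scale_kappa


def mark_paralog_branches(
    ltree: LabeledTree,
    seq_to_species: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Partition branches into {"paralog", "ortholog", "other"}.

    A terminal branch is a paralog branch iff its species contributes >= 2
    sequences to the tree, an ortholog branch iff exactly 1; internal
    branches are "other".  Species come from ``seq_to_species`` or the
    leaves' ``species`` attribute.
    """
    species_of = {}
    for leaf in ltree.leaves():
        name = leaf.taxon.label if leaf.taxon else leaf.label
        if seq_to_species is not None:
            if name not in seq_to_species:
                raise ValueError(f"leaf {name!r} not mapped to a species")
            species_of[name] = seq_to_species[name]
        else:
            sp = getattr(leaf, "species", None)
            if sp is None:
                raise ValueError(f"leaf {name!r} has no species annotation")
            species_of[name] = sp
    multiplicity: dict[str, int] = {}
    for sp in species_of.values():
        multiplicity[sp] = multiplicity.get(sp, 0) + 1
    partition = {}
    for node in ltree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        key = LabeledTree.node_key(node)
        if node.is_leaf():
            partition[key] = (
                "paralog" if multiplicity[species_of[key]] >= 2 else "ortholog"
            )
        else:
            partition[key] = "other"
    return partition


@dataclass
class BranchTestConfig:
    code: GeneticCode = field(
        default_factory=lambda: PRESET_CODES["universal"]
    )
    omega2_max: float = 1e4
    alpha: float = 0.05
    prefit: bool = True
    kappa: float = 2.0
    min_codons: int = 20  # below this the model is not identifiable


@dataclass
class BranchTestResult:
    branch: str
    omega_background: float
    omega_classes: tuple[float, float]  # (constrained <= 1, free)
    weights: tuple[float, float]
    logL_null: float
    logL_alt: float
    lrt: float
    p_value: float
    corrected_p: float
    selected: bool

    def to_dict(self) -> dict:
        return {
            "branch": self.branch,
            "omega_background": self.omega_background,
            "omega_classes": list(self.omega_classes),
            "weights": list(self.weights),
            "logL_null": self.logL_null,
            "logL_alt": self.logL_alt,
            "LRT": self.lrt,
            "p_value": self.p_value,
            "corrected_p": self.corrected_p,
            "selected": self.selected,
        }


def _branch_nll_factory(engine, focal_edge, exch, scale):
    edges = engine.tindex.edges

    def nll(x, omega2_fixed=None):
        log_bg, a1, b = x[0], x[1], x[2]
        omega_bg = math.exp(log_bg)
        omega1 = 1.0 / (1.0 + math.exp(-a1))
        w1 = 1.0 / (1.0 + math.exp(-b))
        omega2 = math.exp(x[3]) if omega2_fixed is None else omega2_fixed
        omegas = {}
        weights = {}
        for e in edges:
            if e == focal_edge:
                omegas[e] = (omega1, omega2)
                weights[e] = (w1, 1.0 - w1)
            else:
                omegas[e] = (omega_bg,)
                weights[e] = (1.0,)
        P = engine.branch_mixture_probs(omegas, weights, exch, scale)
        return -engine.loglik_from_probs(P)

    return nll


def branch_selection_test(
    aln: CodonAlignment,
    ltree: LabeledTree,
    branch: str,
    config: BranchTestConfig = BranchTestConfig(),
    engine: PruningEngine | None = None,
    prefit: tuple[float, float] | None = None,
) -> BranchTestResult:
    """Two-class episodic selection test for one branch.

    The alternative frees (omega_bg, omega_1 <= 1, omega_2 >= 1, weight);
    the null pins omega_2 = 1.  The LRT p-value uses the boundary mixture
    1/2 chi2_0 + 1/2 chi2_1.  ``corrected_p`` is filled by
    :func:`screen_branches`; standalone calls leave it equal to the raw p.
    """
    if engine is None:
        engine = PruningEngine(aln, ltree, config.code)
    if prefit is not None:
        scale, kappa = prefit
    elif config.prefit:
        scale, kappa, _ = prefit_scale_kappa(engine, config.kappa)
    else:
        scale, kappa = 1.0, config.kappa
    exch = hky_exchangeabilities(kappa)

    keys = {engine.tindex.keys[e]: e for e in engine.tindex.edges}
    if branch not in keys:
        raise KeyError(f"branch {branch!r} not in tree")
    focal = keys[branch]

    if aln.n_codons < config.min_codons:
        # too short for the mixture to be identifiable
        return BranchTestResult(
            branch, float("nan"), (float("nan"),) * 2, (float("nan"),) * 2,
            float("nan"), float("nan"), 0.0, 1.0, 1.0, False,
        )

    nll = _branch_nll_factory(engine, focal, exch, scale)

    bounds3 = [(-9.0, 3.0), (-20.0, 20.0), (-20.0, 20.0)]
    x0 = np.array([math.log(0.3), 0.0, 1.0])
    res0 = optimize.minimize(
        lambda x: nll(x, omega2_fixed=1.0),
        x0,
        method="L-BFGS-B",
        bounds=bounds3,
        options={"maxiter": 300},
    )
    logL_null = -float(res0.fun)

    bounds4 = bounds3 + [(0.0, math.log(config.omega2_max))]
    x0_alt = np.concatenate([res0.x, [math.log(1.5)]])
    res1 = optimize.minimize(
        nll, x0_alt, method="L-BFGS-B", bounds=bounds4,
        options={"maxiter": 300},
    )
    # also try a start at the boundary to guard against a local optimum
    res1b = optimize.minimize(
        nll,
        np.concatenate([res0.x, [1e-3]]),
        method="L-BFGS-B",
        bounds=bounds4,
        options={"maxiter": 300},
    )
    if res1b.fun < res1.fun:
        res1 = res1b
    logL_alt = max(-float(res1.fun), logL_null)

    lrt = max(2.0 * (logL_alt - logL_null), 0.0)
    p = 1.0 if lrt <= 0 else 0.5 * float(stats.chi2.sf(lrt, 1))
    omega_bg = math.exp(res1.x[0])
    omega1 = 1.0 / (1.0 + math.exp(-res1.x[1]))
    w1 = 1.0 / (1.0 + math.exp(-res1.x[2]))
    omega2 = math.exp(res1.x[3])
    return BranchTestResult(
        branch=branch,
        omega_background=omega_bg,
        omega_classes=(omega1, omega2),
        weights=(w1, 1.0 - w1),
        logL_null=logL_null,
        logL_alt=logL_alt,
        lrt=lrt,
        p_value=p,
        corrected_p=p,
        selected=p <= config.alpha,
    )


def screen_branches(
    aln: CodonAlignment,
    ltree: LabeledTree,
    branches: Sequence[str] | None = None,
    config: BranchTestConfig = BranchTestConfig(),
) -> list[BranchTestResult]:
    """Run the per-branch test on every branch (default) or the given ones,
    with Holm-Bonferroni correction across the tested branches."""
    engine = PruningEngine(aln, ltree, config.code)
    if config.prefit:
        scale, kappa, _ = prefit_scale_kappa(engine, config.kappa)
    else:
        scale, kappa = 1.0, config.kappa
    if branches is None:
        branches = [engine.tindex.keys[e] for e in engine.tindex.edges]
    results = [
        branch_selection_test(
            aln, ltree, b, config, engine=engine, prefit=(scale, kappa)
        )
        for b in branches
    ]
    raw = [r.p_value for r in results]
    _, corrected, _, _ = multipletests(raw, method="holm")
    for r, cp in zip(results, corrected):
        r.corrected_p = float(max(cp, r.p_value))
        r.selected = r.corrected_p <= config.alpha
    return results


# ---------------------------------------------------------------------------
# paralog vs ortholog selected fractions
# ---------------------------------------------------------------------------


@dataclass
class GroupFractions:
    group: str
    paralog_total: int
    paralog_selected: int
    ortholog_total: int
    ortholog_selected: int

    @property
    def paralog_fraction(self) -> float:
        return self.paralog_selected / self.paralog_total

    @property
    def ortholog_fraction(self) -> float:
        return self.ortholog_selected / self.ortholog_total


@dataclass
class ParalogOrthologSummary:
    """Per-alignment, per-group selected-branch fractions."""

    alignment: str
    fractions: dict[str, GroupFractions]

    def to_rows(self) -> list[dict]:
        return [
            {
                "alignment": self.alignment,
                "group": g,
                "paralog_total": f.paralog_total,
                "paralog_selected": f.paralog_selected,
                "ortholog_total": f.ortholog_total,
                "ortholog_selected": f.ortholog_selected,
                "paralog_fraction": f.paralog_fraction,
                "ortholog_fraction": f.ortholog_fraction,
            }
            for g, f in self.fractions.items()
        ]


def selected_fractions(
    results: Sequence[BranchTestResult],
    partition: Mapping[str, str],
    leaf_groups: Mapping[str, str],
    alignment: str = "aln",
) -> ParalogOrthologSummary:
    """Fractions of selected branches among paralog and ortholog terminal
    branches, per group.  Groups lacking either category are omitted."""
    by_branch = {r.branch: r for r in results}
    tall: dict[str, dict[str, list[int]]] = {}
    for branch, cls in partition.items():
        if cls == "other":
            continue
        if branch not in leaf_groups:
            continue
        g = leaf_groups[branch]
        rec = tall.setdefault(g, {"paralog": [], "ortholog": []})
        r = by_branch.get(branch)
        rec[cls].append(1 if (r is not None and r.selected) else 0)
    fractions = {}
    for g, rec in sorted(tall.items()):
        if not rec["paralog"] or not rec["ortholog"]:
            continue
        fractions[g] = GroupFractions(
            group=g,
            paralog_total=len(rec["paralog"]),
            paralog_selected=sum(rec["paralog"]),
            ortholog_total=len(rec["ortholog"]),
            ortholog_selected=sum(rec["ortholog"]),
        )
    return ParalogOrthologSummary(alignment=alignment, fractions=fractions)


@dataclass
class FractionComparison:
    group: str
    n_alignments: int
    paralog_median: float
    ortholog_median: float
    paralog_mean: float
    ortholog_mean: float
    statistic: float
    p_value: float


def compare_fractions(
    summaries: Sequence[ParalogOrthologSummary], group: str
) -> FractionComparison:
    """Paired two-sided Wilcoxon signed-rank test of paralog vs ortholog
    selected fractions across alignments (one pair per alignment)."""
    pairs = [
        (
            s.fractions[group].paralog_fraction,
            s.fractions[group].ortholog_fraction,
        )
        for s in summaries
        if group in s.fractions
    ]
    if len(pairs) < 5:
        raise ValueError(
            f"need >= 5 paired fraction records for group {group!r}, "
            f"got {len(pairs)}"
        )
    par = np.array([p for p, _ in pairs])
    ort = np.array([o for _, o in pairs])
    diffs = par - ort
    if np.all(diffs == 0):
        statistic, p = 0.0, 1.0
    else:
        res = stats.wilcoxon(par, ort, alternative="two-sided")
        statistic, p = float(res.statistic), float(res.pvalue)
    return FractionComparison(
        group=group,
        n_alignments=len(pairs),
        paralog_median=float(np.median(par)),
        ortholog_median=float(np.median(ort)),
        paralog_mean=float(par.mean()),
        ortholog_mean=float(ort.mean()),
        statistic=statistic,
        p_value=p,
    )
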