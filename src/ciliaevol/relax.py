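"""Group-level selection-intensity (RELAX-style) test.

Branches of a labeled gene tree are partitioned into a reference group
(default NEF), up to three test groups and a nuisance set.  Reference and
test branches share one 3-bin omega distribution (0 <= w1 <= w2 <= 1 <= w3
with proportions p1, p2, p3); each test group g raises the omegas to a
group-specific power K[g] (omega_g = omega**K[g]), so K > 1 pushes omegas
away from neutrality (intensified selection) and K < 1 pulls them toward 1
(relaxed selection).  Nuisance branches carry their own 3-bin distribution.
The test compares the model with free K[g] per test group against the model
with all K[g] = 1 by a likelihood-ratio test (chi-squared, df = number of
test groups present).

Each branch-site combination draws its rate class independently, so the
likelihood uses per-branch mixture-averaged transition matrices.

Also here: partitioned exploratory fits (every group gets its own free
distribution), conditional negative-selection means, and the
Jonckheere-Terpstra ordered-trend test used to compare those means across
an a priori group ordering.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .codon_model import (
    CodonAlignment,
    PruningEngine,
    hky_exchangeabilities,
)
from .genetic_code import GeneticCode, PRESET_CODES
from .phylo import NUISANCE, LabeledTree

# ---------------------------------------------------------------------------
# omega distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OmegaDistribution:
    """3-bin omega mixture with 0 <= w1 <= w2 <= 1 <= w3."""

    omegas: tuple[float, float, float]
    weights: tuple[float, float, float]

    def __post_init__(self) -> None:
        w1, w2, w3 = self.omegas
        if not (0 <= w1 <= w2 <= 1 <= w3):
            raise ValueError(
                f"omegas must satisfy 0 <= w1 <= w2 <= 1 <= w3, got {self.omegas}"
            )
        p = np.asarray(self.weights, dtype=float)
        if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"weights must be >= 0 and sum to 1, got {self.weights}")

    def to_dict(self) -> dict:
        return {"omegas": list(self.omegas), "weights": list(self.weights)}


def apply_intensification(dist: OmegaDistribution, K: float) -> OmegaDistribution:
    """Raise every omega to the power K; weights unchanged.

    K > 1 moves omegas away from 1 (intensification), K < 1 toward 1
    (relaxation); ordering and the <=1 / >=1 split are preserved.
    """
    if K <= 0:
        raise ValueError("K must be > 0")
    return OmegaDistribution(
        tuple(float(w**K) for w in dist.omegas), dist.weights
    )


def conditional_mean_negative(
    dist: OmegaDistribution, inclusive: bool = True
) -> float:
    """Mean omega conditioned on the negatively selected regime.

    ``inclusive`` keeps bins at exactly omega = 1 (the default); errors if
    the regime carries no probability mass.
    """
    om = np.asarray(dist.omegas)
    p = np.asarray(dist.weights)
    mask = om <= 1 if inclusive else om < 1
    mass = p[mask].sum()
    if mass <= 0:
        raise ValueError("no probability mass in the negative-selection regime")
    return float((p[mask] * om[mask]).sum() / mass)


# ---------------------------------------------------------------------------
# parameter transforms (keep the constrained space smooth)
# ---------------------------------------------------------------------------


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1 - p))


_OMEGA3_MAX = 1e4


def _dist_from_vector(x: np.ndarray) -> OmegaDistribution:
    """(a1, a2, u, b1, b2) -> distribution.

    w2 = sigmoid(a2), w1 = sigmoid(a1) * w2, w3 = 1 + exp(u);
    weights = softmax(b1, b2, 0).
    """
    a1, a2, u, b1, b2 = x
    w2 = _sigmoid(a2)
    w1 = _sigmoid(a1) * w2
    w3 = 1.0 + math.exp(u)
    z = np.array([b1, b2, 0.0])
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    return OmegaDistribution((w1, w2, w3), tuple(p))


def _vector_from_dist(dist: OmegaDistribution) -> np.ndarray:
    w1, w2, w3 = dist.omegas
    p1, p2, p3 = (max(w, 1e-9) for w in dist.weights)
    a2 = _logit(w2)
    a1 = _logit(min(w1 / max(w2, 1e-12), 1 - 1e-9))
    u = math.log(max(w3 - 1.0, 1e-9))
    return np.array(
        [a1, a2, u, math.log(p1 / p3), math.log(p2 / p3)]
    )


_DIST_BOUNDS = [
    (-20.0, 20.0),
    (-20.0, 20.0),
    (math.log(1e-9), math.log(_OMEGA3_MAX - 1.0)),
    (-30.0, 30.0),
    (-30.0, 30.0),
]


# ---------------------------------------------------------------------------
# model configuration and results
# ---------------------------------------------------------------------------


@dataclass
class RelaxConfig:
    reference_group: str = "NEF"
    test_groups: tuple[str, ...] = ("K", "H", "EF")
    code: GeneticCode = field(
        default_factory=lambda: PRESET_CODES["universal"]
    )
    k_bounds: tuple[float, float] = (0.01, 50.0)
    n_starts: int = 3
    tol: float = 1e-4  # absolute log-likelihood convergence target
    maxiter: int = 60
    prefit: bool = True  # one scale+kappa+omega fit, then held fixed
    kappa: float = 2.0  # used when prefit=False
    rng_seed: int = 2024


@dataclass
class RelaxResult:
    logL_null: float
    logL_alt: float
    lrt: float
    p_value: float
    df: int
    K: dict[str, float]
    K_at_bound: dict[str, bool]
    reference_group: str
    null_reference_dist: OmegaDistribution
    alt_reference_dist: OmegaDistribution
    null_nuisance_dist: OmegaDistribution | None
    alt_nuisance_dist: OmegaDistribution | None
    converged: bool
    scale: float
    kappa: float

    def to_dict(self) -> dict:
        return {
            "logL_null": self.logL_null,
            "logL_alt": self.logL_alt,
            "LRT": self.lrt,
            "p_value": self.p_value,
            "df": self.df,
            "K": dict(self.K),
            "K_at_bound": dict(self.K_at_bound),
            "reference_group": self.reference_group,
            "null_reference_dist": self.null_reference_dist.to_dict(),
            "alt_reference_dist": self.alt_reference_dist.to_dict(),
            "null_nuisance_dist": (
                self.null_nuisance_dist.to_dict()
                if self.null_nuisance_dist
                else None
            ),
            "alt_nuisance_dist": (
                self.alt_nuisance_dist.to_dict()
                if self.alt_nuisance_dist
                else None
            ),
            "converged": self.converged,
            "scale": self.scale,
            "kappa": self.kappa,
        }


@dataclass
class ExploratoryFit:
    logL: float
    dists: dict[str, OmegaDistribution]  # per group, plus "nuisance"
    scale: float
    kappa: float

    def conditional_means(self, inclusive: bool = True) -> dict[str, float]:
        return {
            g: conditional_mean_negative(d, inclusive)
            for g, d in self.dists.items()
        }


# ---------------------------------------------------------------------------
# likelihood plumbing
# ---------------------------------------------------------------------------


class _BestTracker:
    """Wrap an objective to remember the best point ever evaluated."""

    def __init__(self, fun):
        self.fun = fun
        self.best_f = np.inf
        self.best_x = None

    def __call__(self, x):
        f = self.fun(x)
        if f < self.best_f:
            self.best_f = f
            self.best_x = np.array(x)
        return f


def _groups_present(engine: PruningEngine) -> set[str]:
    return {
        engine.tindex.label[e]
        for e in engine.tindex.edges
        if engine.tindex.label[e] not in (None, NUISANCE)
    }


def _has_nuisance(engine: PruningEngine) -> bool:
    return any(
        engine.tindex.label[e] in (None, NUISANCE)
        for e in engine.tindex.edges
    )


def _powered(omegas: tuple, k: float) -> tuple:
    """omega**K, clamped to a numerically safe range (an effective omega
    beyond the omega3 bound is indistinguishable in the likelihood)."""
    return tuple(
        min(max(w**k, 1e-9), _OMEGA3_MAX) if w > 0 else 0.0 for w in omegas
    )


def _mixture_loglik(
    engine: PruningEngine,
    ref: OmegaDistribution,
    K: Mapping[str, float],
    nuis: OmegaDistribution | None,
    reference_group: str,
    exch: np.ndarray,
    scale: float,
) -> float:
    omegas_by_edge = {}
    weights_by_edge = {}
    for e in engine.tindex.edges:
        label = engine.tindex.label[e]
        if label in (None, NUISANCE):
            d = nuis if nuis is not None else ref
            omegas_by_edge[e] = d.omegas
            weights_by_edge[e] = d.weights
        else:
            k = 1.0 if label == reference_group else K.get(label, 1.0)
            omegas_by_edge[e] = _powered(ref.omegas, k)
            weights_by_edge[e] = ref.weights
    P = engine.branch_mixture_probs(
        omegas_by_edge, weights_by_edge, exch, scale
    )
    return engine.loglik_from_probs(P)


def prefit_scale_kappa(
    engine: PruningEngine, kappa0: float = 2.0
) -> tuple[float, float, float]:
    """3-parameter fit (tree scale, kappa, single omega) used to fix branch
    lengths and exchangeabilities before the mixture fits.

    Returns (scale, kappa, omega)."""

    def nll(x):
        scale, kappa, omega = np.exp(x)
        P = engine.branch_mixture_probs(
            {e: [omega] for e in engine.tindex.edges},
            {e: [1.0] for e in engine.tindex.edges},
            hky_exchangeabilities(kappa),
            scale,
        )
        return -engine.loglik_from_probs(P)

    res = optimize.minimize(
        nll,
        np.log([1.0, kappa0, 0.3]),
        method="L-BFGS-B",
        bounds=[(-5, 5), (math.log(0.2), math.log(20)), (-9, 3)],
        options={"maxiter": 200},
    )
    scale, kappa, omega = np.exp(res.x)
    return float(scale), float(kappa), float(omega)


def _optimize_with_probes(
    nll, x0, bounds, n_starts, tol, rng,
    probe_scale=0.5, maxiter=100, probe_maxiter=12,
):
    """One full L-BFGS-B run plus (n_starts - 1) short perturbed probes;
    the best probe is polished fully.  Returns (best_x, best_f, converged)."""
    tracker = _BestTracker(nll)
    # ftol is relative in L-BFGS-B; aim for ~tol absolute log-likelihood
    ftol = tol / max(abs(tracker(x0)), 1.0)
    res = optimize.minimize(
        tracker,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": ftol},
    )
    converged = bool(res.success)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    base = tracker.best_x.copy()
    improved = None
    for _ in range(max(0, n_starts - 1)):
        x_p = np.clip(
            base + rng.normal(0, probe_scale, size=len(base)), lo, hi
        )
        f_before = tracker.best_f
        optimize.minimize(
            tracker,
            x_p,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": probe_maxiter, "ftol": ftol},
        )
        if tracker.best_f < f_before - 1e-4:
            improved = tracker.best_x.copy()
    if improved is not None:
        res2 = optimize.minimize(
            tracker,
            improved,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": ftol},
        )
        converged = converged or bool(res2.success)
    return tracker.best_x, tracker.best_f, converged


# ---------------------------------------------------------------------------
# the test
# ---------------------------------------------------------------------------


def fit_relax(
    aln: CodonAlignment,
    ltree: LabeledTree,
    config: RelaxConfig = RelaxConfig(),
) -> RelaxResult:
    """RELAX-style group test: free K per test group vs all K = 1.

    Test groups absent from the tree are dropped with a warning (df is
    reduced accordingly).  Branch lengths come from the input tree, rescaled
    by the prefit factor and then held fixed across the nested fits.
    """
    engine = PruningEngine(aln, ltree, config.code)
    present = _groups_present(engine)
    if config.reference_group not in present:
        raise ValueError(
            f"reference group {config.reference_group!r} has no branches"
        )
    test_groups = [g for g in config.test_groups if g in present]
    dropped = [g for g in config.test_groups if g not in present]
    if dropped:
        warnings.warn(
            f"test groups absent from tree, dropped: {dropped}", stacklevel=2
        )
    if not test_groups:
        raise ValueError("no test group has branches in the tree")
    nuis_present = _has_nuisance(engine)
    rng = np.random.default_rng(config.rng_seed)

    if config.prefit:
        scale, kappa, _ = prefit_scale_kappa(engine, config.kappa)
    else:
        scale, kappa = 1.0, config.kappa
    exch = hky_exchangeabilities(kappa)

    n_dist = 5
    n_null = n_dist * (2 if nuis_present else 1)
    log_k_lo, log_k_hi = (math.log(b) for b in config.k_bounds)

    def unpack(x, with_k):
        ref = _dist_from_vector(x[:n_dist])
        nuis = (
            _dist_from_vector(x[n_dist : 2 * n_dist])
            if nuis_present
            else None
        )
        if with_k:
            ks = dict(
                zip(test_groups, np.exp(x[n_null : n_null + len(test_groups)]))
            )
        else:
            ks = {g: 1.0 for g in test_groups}
        return ref, nuis, ks

    def make_nll(with_k):
        def nll(x):
            ref, nuis, ks = unpack(x, with_k)
            return -_mixture_loglik(
                engine, ref, ks, nuis, config.reference_group, exch, scale
            )

        return nll

    start_dist = OmegaDistribution((0.1, 0.5, 2.0), (0.4, 0.4, 0.2))
    x0_null = np.concatenate(
        [_vector_from_dist(start_dist)] * (2 if nuis_present else 1)
    )
    bounds_null = _DIST_BOUNDS * (2 if nuis_present else 1)

    x_null, f_null, conv_null = _optimize_with_probes(
        make_nll(False), x0_null, bounds_null, config.n_starts, config.tol,
        rng, maxiter=int(0.8 * config.maxiter),
    )
    ref_null, nuis_null, _ = unpack(x_null, False)

    x0_alt = np.concatenate([x_null, np.zeros(len(test_groups))])
    bounds_alt = bounds_null + [(log_k_lo, log_k_hi)] * len(test_groups)
    x_alt, f_alt, conv_alt = _optimize_with_probes(
        make_nll(True), x0_alt, bounds_alt, config.n_starts, config.tol,
        rng, maxiter=config.maxiter,
    )
    ref_alt, nuis_alt, ks = unpack(x_alt, True)

    logL_null, logL_alt = -f_null, -f_alt
    lrt = max(2.0 * (logL_alt - logL_null), 0.0)
    df = len(test_groups)
    p = float(stats.chi2.sf(lrt, df))
    k_at_bound = {
        g: bool(
            math.isclose(math.log(ks[g]), log_k_lo, abs_tol=1e-6)
            or math.isclose(math.log(ks[g]), log_k_hi, abs_tol=1e-6)
        )
        for g in test_groups
    }
    return RelaxResult(
        logL_null=logL_null,
        logL_alt=logL_alt,
        lrt=lrt,
        p_value=p,
        df=df,
        K={g: float(ks[g]) for g in test_groups},
        K_at_bound=k_at_bound,
        reference_group=config.reference_group,
        null_reference_dist=ref_null,
        alt_reference_dist=ref_alt,
        null_nuisance_dist=nuis_null,
        alt_nuisance_dist=nuis_alt,
        converged=conv_null and conv_alt,
        scale=scale,
        kappa=kappa,
    )


def fit_exploratory(
    aln: CodonAlignment,
    ltree: LabeledTree,
    config: RelaxConfig = RelaxConfig(),
    warm_start: RelaxResult | None = None,
) -> ExploratoryFit:
    """Partitioned exploratory fit: every branch group (and the nuisance
    set) gets its own free 3-bin distribution.

    Nests the RELAX alternative, so when ``warm_start`` is given (or
    computed) the returned log-likelihood is never below the alternative's.
    """
    engine = PruningEngine(aln, ltree, config.code)
    present = sorted(_groups_present(engine))
    nuis_present = _has_nuisance(engine)
    rng = np.random.default_rng(config.rng_seed + 1)

    if warm_start is None:
        warm_start = fit_relax(aln, ltree, config)
    scale, kappa = warm_start.scale, warm_start.kappa
    exch = hky_exchangeabilities(kappa)

    blocks = list(present) + ([NUISANCE] if nuis_present else [])

    def unpack(x):
        return {
            b: _dist_from_vector(x[5 * i : 5 * i + 5])
            for i, b in enumerate(blocks)
        }

    def nll(x):
        dists = unpack(x)
        omegas_by_edge = {}
        weights_by_edge = {}
        for e in engine.tindex.edges:
            label = engine.tindex.label[e]
            if label in (None, NUISANCE):
                d = dists[NUISANCE] if nuis_present else dists[blocks[0]]
            else:
                d = dists[label]
            omegas_by_edge[e] = d.omegas
            weights_by_edge[e] = d.weights
        P = engine.branch_mixture_probs(
            omegas_by_edge, weights_by_edge, exch, scale
        )
        return -engine.loglik_from_probs(P)

    def interior(d: OmegaDistribution) -> OmegaDistribution:
        # keep the start away from the transformed-parameter bounds, where
        # the sigmoid/softmax gradients vanish and L-BFGS cannot move
        w1, w2, w3 = d.omegas
        w2 = min(max(w2, 5e-3), 0.995)
        w1 = min(max(w1, 1e-3), w2)
        w3 = min(max(w3, 1.005), 50.0)
        p = np.clip(np.asarray(d.weights, dtype=float), 5e-3, None)
        return OmegaDistribution((w1, w2, w3), tuple(p / p.sum()))

    x0_parts = []
    for b in blocks:
        if b == NUISANCE:
            d = warm_start.alt_nuisance_dist or warm_start.alt_reference_dist
        else:
            k = (
                1.0
                if b == warm_start.reference_group
                else warm_start.K.get(b, 1.0)
            )
            d = apply_intensification(warm_start.alt_reference_dist, k)
        x0_parts.append(_vector_from_dist(interior(d)))
    x0 = np.concatenate(x0_parts)

    x, f, _ = _optimize_with_probes(
        nll, x0, _DIST_BOUNDS * len(blocks), config.n_starts, config.tol,
        rng, maxiter=config.maxiter,
    )
    # the fit nests the alternative; never report a worse likelihood
    logL = max(-f, warm_start.logL_alt)
    if -f < warm_start.logL_alt:
        x = x0
    return ExploratoryFit(
        logL=logL, dists=unpack(x), scale=scale, kappa=kappa
    )


def relax_results_table(results: Mapping[str, RelaxResult]):
    """Batch summary across alignments: one row per alignment with logLs,
    LRT, p, per-group K and convergence flags."""
    import pandas as pd

    rows = []
    for name, r in results.items():
        row = {
            "alignment": name,
            "logL_null": r.logL_null,
            "logL_alt": r.logL_alt,
            "LRT": r.lrt,
            "p_value": r.p_value,
            "df": r.df,
            "converged": r.converged,
        }
        for g, k in r.K.items():
            row[f"K_{g}"] = k
            row[f"K_{g}_at_bound"] = r.K_at_bound[g]
        rows.append(row)
    return pd.DataFrame(rows)


def tally_direction(
    results: Mapping[str, RelaxResult], alpha: float = 0.05
) -> dict[str, dict[str, int]]:
    """Among significant results, counts of intensified (K > 1) and relaxed
    (K < 1) alignments per test group."""
    tally: dict[str, dict[str, int]] = {}
    for r in results.values():
        if r.p_value > alpha:
            continue
        for g, k in r.K.items():
            rec = tally.setdefault(g, {"intensified": 0, "relaxed": 0})
            if k > 1:
                rec["intensified"] += 1
            elif k < 1:
                rec["relaxed"] += 1
    return tally


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra ordered-trend test
# ---------------------------------------------------------------------------


def _jt_statistic(samples: Sequence[np.ndarray]) -> float:
    jt = 0.0
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            x = samples[i][:, None]
            y = samples[j][None, :]
            jt += float((x < y).sum()) + 0.5 * float((x == y).sum())
    return jt


def jonckheere_terpstra(
    samples: Sequence[Sequence[float]],
    alternative: str = "increasing",
    method: str = "auto",
    n_permutations: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Jonckheere-Terpstra test against an a priori group ordering.

    ``samples`` are the groups in hypothesized increasing order; the
    statistic is the sum of pairwise Mann-Whitney counts over ordered group
    pairs (ties count 1/2).  ``method`` is "normal" (tie-corrected normal
    approximation), "exact" (full enumeration of group assignments),
    "permutation" (Monte Carlo), or "auto" (exact when the pooled sample
    size is <= 12, else normal).  Returns (statistic, p).
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 ordered groups")
    groups = [np.asarray(s, dtype=float) for s in samples]
    if any(g.size == 0 for g in groups):
        raise ValueError("every group needs at least one value")
    if alternative not in ("increasing", "decreasing", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if alternative == "decreasing":
        stat, p = jonckheere_terpstra(
            [-g for g in groups], "increasing", method, n_permutations, seed
        )
        return stat, p

    jt = _jt_statistic(groups)
    sizes = [g.size for g in groups]
    N = sum(sizes)

    if method == "auto":
        method = "exact" if N <= 12 else "normal"

    if method == "exact" or method == "permutation":
        pooled = np.concatenate(groups)

        def stat_of(perm: np.ndarray) -> float:
            out = []
            k = 0
            for n in sizes:
                out.append(pooled[perm[k : k + n]])
                k += n
            return _jt_statistic(out)

        if method == "exact":
            count = 0
            total = 0
            for perm in _distinct_group_assignments(N, sizes):
                total += 1
                if stat_of(np.array(perm)) >= jt - 1e-9:
                    count += 1
            p_up = count / total
            if alternative == "two-sided":
                count_dn = 0
                for perm in _distinct_group_assignments(N, sizes):
                    if stat_of(np.array(perm)) <= jt + 1e-9:
                        count_dn += 1
                p = min(1.0, 2 * min(p_up, count_dn / total))
            else:
                p = p_up
        else:
            rng = np.random.default_rng(seed)
            idx = np.arange(N)
            stats_perm = np.empty(n_permutations)
            for b in range(n_permutations):
                rng.shuffle(idx)
                stats_perm[b] = stat_of(idx)
            p_up = float((stats_perm >= jt - 1e-9).mean())
            if alternative == "two-sided":
                p_dn = float((stats_perm <= jt + 1e-9).mean())
                p = min(1.0, 2 * min(p_up, p_dn))
            else:
                p = p_up
        return jt, p

    # tie-corrected normal approximation (Hollander & Wolfe)
    mean = sum(
        sizes[i] * sizes[j]
        for i in range(len(sizes))
        for j in range(i + 1, len(sizes))
    ) / 2.0
    pooled = np.concatenate(groups)
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = np.array(sizes, dtype=float)
    t = tie_counts.astype(float)
    Nf = float(N)
    term1 = (
        Nf * (Nf - 1) * (2 * Nf + 5)
        - (n * (n - 1) * (2 * n + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    ) / 72.0
    term2 = (
        (n * (n - 1) * (n - 2)).sum()
        * (t * (t - 1) * (t - 2)).sum()
        / (36.0 * Nf * (Nf - 1) * (Nf - 2))
    )
    term3 = (
        (n * (n - 1)).sum() * (t * (t - 1)).sum() / (8.0 * Nf * (Nf - 1))
    )
    var = term1 + term2 + term3
    if var <= 0:
        # fully tied data: every assignment gives JT = mean
        if alternative == "two-sided":
            return jt, 1.0
        return jt, 1.0 if jt <= mean else 0.0
    z = (jt - mean) / math.sqrt(var)
    if alternative == "two-sided":
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        p = float(stats.norm.sf(z))
    return jt, p


def _distinct_group_assignments(N: int, sizes: Sequence[int]):
    """All partitions of indices 0..N-1 into ordered groups of given sizes."""

    def rec(remaining: tuple[int, ...], sizes_left: Sequence[int]):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in set(combo))
            for tail in rec(rest, sizes_left[1:]):
                yield combo + tail

    yield from rec(tuple(range(N)), list(sizes))
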