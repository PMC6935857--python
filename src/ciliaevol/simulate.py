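"""Seeded synthetic-data generators.

Every pipeline stage can be exercised without downloads: transcriptomes
generated under a chosen genetic code (reassigned stops appearing in frame
at coding density, terminal stop, short 3'UTR and poly(A) tail), zero-
inflated gene-family count matrices with group-specific paralog means,
group-labeled random trees, and codon alignments simulated under known
omega distributions and per-group intensification coefficients K.

Each generator is a pure function of its config (the seed fixes every
random stream) and ships a :class:`GroundTruth` record so downstream
recovery tests can compare against the generating parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_model import CodonAlignment, CodonSpace, NT_INDEX, SpectralQ, build_rate_matrix, hky_exchangeabilities
from .diversity import GFCountMatrix
from .genetic_code import (
    CANONICAL_STOPS,
    GeneticCode,
    ReferenceAlignment,
    forced_translation,
    get_code,
)
from .phylo import LabeledTree, label_tree
from .relax import OmegaDistribution, apply_intensification
from .transcripts import Transcript

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: AT-rich positional nucleotide frequencies typical of ciliate coding
#: regions, order ACGT; also the F3x4 structure assumed by the fits.
DEFAULT_POSITIONAL_FREQS = (
    (0.30, 0.20, 0.20, 0.30),
    (0.30, 0.20, 0.20, 0.30),
    (0.30, 0.20, 0.20, 0.30),
)


@dataclass
class GroundTruth:
    """Generating parameters and latent variables emitted beside a dataset."""

    kind: str
    params: dict
    truth: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"kind": self.kind, "params": self.params, "truth": self.truth},
                fh,
                indent=1,
                default=_jsonable,
            )


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, OmegaDistribution):
        return x.to_dict()
    if isinstance(x, frozenset):
        return sorted(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _codon_probs(
    codons: Sequence[str], positional_freqs
) -> np.ndarray:
    pf = np.asarray(positional_freqs, dtype=float)
    p = np.array(
        [
            pf[0, NT_INDEX[c[0]]] * pf[1, NT_INDEX[c[1]]] * pf[2, NT_INDEX[c[2]]]
            for c in codons
        ]
    )
    return p / p.sum()


# ---------------------------------------------------------------------------
# transcriptomes under a chosen genetic code
# ---------------------------------------------------------------------------


@dataclass
class TranscriptomeConfig:
    """Defaults are the reference conditions used throughout the tests:
    50 transcripts of 300 codons with reassigned stops at 2 per 100 codons."""

    seed: int = 0
    code_name: str = "ciliate"
    n_transcripts: int = 50
    n_codons: int = 300
    reassigned_usage_rate: float = 0.02  # total across reassigned stops
    utr_length: int = 15  # random 3'UTR nucleotides before the poly(A)
    polya_length: int = 30
    taxon: str = "synthetic_sp"
    positional_freqs: tuple = DEFAULT_POSITIONAL_FREQS

    def __post_init__(self) -> None:
        if self.reassigned_usage_rate < 0:
            raise ValueError("usage rate must be >= 0")


def gen_transcriptome(
    config: TranscriptomeConfig,
) -> tuple[list[Transcript], GroundTruth]:
    """Simulate transcripts under a named genetic code.

    Coding codons are drawn from an AT-rich codon distribution excluding all
    canonical stops; reassigned stops are then inserted in frame at the
    configured per-codon rate; a terminal functional stop, a short random
    3'UTR and a poly(A) tail are appended.  True protein sequences (under
    the generating code) are emitted in the ground truth for building
    reference alignments.
    """
    code = get_code(config.code_name)
    rng = np.random.default_rng(config.seed)
    reassigned = sorted(code.reassigned_stops)
    if config.reassigned_usage_rate > 0 and not reassigned:
        raise ValueError(
            f"code {code.name!r} reassigns no stop codon; in-frame usage "
            "rate must be 0"
        )
    base_codons = [
        c for c in code.sense_codons if c not in CANONICAL_STOPS
    ]
    base_p = _codon_probs(base_codons, config.positional_freqs)
    terminal_pool = sorted(code.stops) or list(CANONICAL_STOPS)

    transcripts = []
    coding = {}
    proteins = {}
    for i in range(config.n_transcripts):
        idx = rng.choice(len(base_codons), size=config.n_codons, p=base_p)
        codons = [base_codons[k] for k in idx]
        if reassigned and config.reassigned_usage_rate > 0:
            mask = rng.random(config.n_codons) < config.reassigned_usage_rate
            for pos in np.flatnonzero(mask):
                codons[pos] = reassigned[rng.integers(len(reassigned))]
        stop = terminal_pool[rng.integers(len(terminal_pool))]
        utr = "".join(
            "ACGT"[k] for k in rng.integers(0, 4, size=config.utr_length)
        )
        seq = "".join(codons) + stop + utr + "A" * config.polya_length
        tid = f"t{i:04d}"
        transcripts.append(
            Transcript(id=tid, seq=seq, taxon=config.taxon)
        )
        coding[tid] = codons
        proteins[tid] = "".join(code.table[c] for c in codons)
    truth = GroundTruth(
        kind="transcriptome",
        params=vars(config).copy(),
        truth={
            "code_name": code.name,
            "functional_stops": sorted(code.stops),
            "reassigned_stops": dict(code.reassigned_stops),
            "context_dependent": code.context_dependent,
            "coding_codons": coding,
            "proteins": proteins,
        },
    )
    return transcripts, truth


def gen_reference_alignments(
    truth: GroundTruth,
    n_refs: int = 8,
    divergence: float = 0.1,
    seed: int = 0,
) -> list[ReferenceAlignment]:
    """Reference protein alignments for reassignment inference.

    For each simulated transcript, the query row is its coding region
    force-translated with stop markers, aligned (trivially, the true frame
    is known) to ``n_refs`` reference sequences derived from the true
    protein with random substitutions at rate ``divergence``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for tid, codons in truth.truth["coding_codons"].items():
        query = forced_translation(codons)
        protein = truth.truth["proteins"][tid]
        rows = {tid: query}
        for r in range(n_refs):
            chars = list(protein)
            mask = rng.random(len(chars)) < divergence
            for pos in np.flatnonzero(mask):
                chars[pos] = _AA20[rng.integers(20)]
            rows[f"ref{r}"] = "".join(chars)
        out.append(ReferenceAlignment(query_id=tid, rows=rows))
    return out


# ---------------------------------------------------------------------------
# gene-family count matrices
# ---------------------------------------------------------------------------


@dataclass
class GFMatrixConfig:
    """Zero-inflated Poisson counts per (species, GF).

    Default group means echo the per-GF-per-taxon averages reported for the
    four focal ciliate groups (H 1.25, EF 0.92, NEF 0.67, K 0.18), with
    species counts per group and a 509-GF universe on the same scale as the
    conserved gene families those estimates come from.
    """

    seed: int = 0
    n_gfs: int = 509
    species_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"K": 11, "H": 8, "EF": 12, "NEF": 15}
    )
    group_means: Mapping[str, float] = field(
        default_factory=lambda: {"K": 0.18, "NEF": 0.67, "EF": 0.92, "H": 1.25}
    )
    zero_inflation: Mapping[str, float] = field(
        default_factory=lambda: {"K": 0.6, "NEF": 0.45, "EF": 0.4, "H": 0.35}
    )


def gen_gf_matrix(
    config: GFMatrixConfig,
) -> tuple[GFCountMatrix, dict[str, str], GroundTruth]:
    """Counts ~ zero-inflated Poisson with group-specific (mean, inflation);
    the Poisson rate is mean / (1 - inflation) so the marginal mean matches
    the configured group mean."""
    rng = np.random.default_rng(config.seed)
    gfs = [f"GF{j:04d}" for j in range(config.n_gfs)]
    rows = {}
    group_map = {}
    for group in sorted(config.species_per_group):
        n_sp = config.species_per_group[group]
        mean = float(config.group_means[group])
        pi0 = float(config.zero_inflation[group])
        if mean < 0 or not 0.0 <= pi0 <= 1.0:
            raise ValueError(f"invalid parameters for group {group!r}")
        lam = mean / (1 - pi0) if pi0 < 1 else 0.0
        for s in range(n_sp):
            name = f"{group}_sp{s:02d}"
            group_map[name] = group
            counts = rng.poisson(lam, size=config.n_gfs)
            zeros = rng.random(config.n_gfs) < pi0
            counts[zeros] = 0
            rows[name] = counts
    m = GFCountMatrix(
        pd.DataFrame(rows, index=gfs).T[gfs]
    )
    truth = GroundTruth(
        kind="gf_matrix",
        params={
            "seed": config.seed,
            "n_gfs": config.n_gfs,
            "species_per_group": dict(config.species_per_group),
            "group_means": dict(config.group_means),
            "zero_inflation": dict(config.zero_inflation),
        },
        truth={"group_map": group_map},
    )
    return m, group_map, truth


# ---------------------------------------------------------------------------
# group-labeled trees
# ---------------------------------------------------------------------------


@dataclass
class TreeConfig:
    seed: int = 0
    taxa_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"K": 4, "H": 4, "EF": 4, "NEF": 4}
    )
    mean_branch_length: float = 0.1
    monophyletic: bool = True  # False mixes groups, exercising nuisance labels
    paralog_copies: Mapping[str, int] = field(default_factory=dict)


def _random_join(parts: list[str], rng, mean_bl: float) -> str:
    parts = list(parts)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        la, lb = rng.exponential(mean_bl, size=2)
        parts.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return parts[0]


def gen_labeled_tree(config: TreeConfig) -> tuple[LabeledTree, GroundTruth]:
    """Random group-labeled tree.

    Groups are monophyletic blocks by default (so their internal branches
    are labeled and the connecting spine is nuisance); species listed in
    ``paralog_copies`` contribute that many leaf sequences (ids suffixed
    ``_p<i>``), creating paralog terminal branches.
    """
    if any(n < 1 for n in config.taxa_per_group.values()):
        raise ValueError("every group needs at least one taxon")
    rng = np.random.default_rng(config.seed)
    species_to_group = {}
    seq_to_species = {}
    group_leaf_sets = {}
    for group in sorted(config.taxa_per_group):
        leaves = []
        for s in range(config.taxa_per_group[group]):
            sp = f"{group}_sp{s:02d}"
            species_to_group[sp] = group
            copies = config.paralog_copies.get(sp, 1)
            if copies == 1:
                names = [sp]
            else:
                names = [f"{sp}_p{c}" for c in range(copies)]
            for nm in names:
                seq_to_species[nm] = sp
            leaves.extend(names)
        group_leaf_sets[group] = leaves

    if config.monophyletic:
        blocks = [
            _random_join(group_leaf_sets[g], rng, config.mean_branch_length)
            for g in sorted(group_leaf_sets)
        ]
        newick = _random_join(blocks, rng, config.mean_branch_length) + ";"
    else:
        pool = [lf for g in sorted(group_leaf_sets) for lf in group_leaf_sets[g]]
        newick = _random_join(pool, rng, config.mean_branch_length) + ";"

    ltree = LabeledTree.from_newick(newick)
    for leaf in ltree.leaves():
        leaf.species = seq_to_species[leaf.taxon.label]
    label_tree(ltree, species_to_group)
    truth = GroundTruth(
        kind="tree",
        params={
            "seed": config.seed,
            "taxa_per_group": dict(config.taxa_per_group),
            "mean_branch_length": config.mean_branch_length,
            "monophyletic": config.monophyletic,
            "paralog_copies": dict(config.paralog_copies),
        },
        truth={
            "newick": newick,
            "species_to_group": species_to_group,
            "seq_to_species": seq_to_species,
        },
    )
    return ltree, truth


# ---------------------------------------------------------------------------
# codon alignments under the group-intensification model
# ---------------------------------------------------------------------------


@dataclass
class AlignmentConfig:
    """Codon alignment simulated on a labeled tree.

    Each branch-site combination draws its omega bin independently (shared
    proportions); branch omegas are the reference omegas raised to the
    branch group's K; nuisance branches use ``nuisance_dist`` (defaulting to
    the reference distribution).  ``branch_overrides`` pins specific
    branches (by node key) to their own distribution, e.g. to plant episodic
    positive selection on one focal branch.
    """

    seed: int = 0
    n_codons: int = 200
    code_name: str = "universal"
    reference_dist: OmegaDistribution = field(
        default_factory=lambda: OmegaDistribution(
            (0.05, 0.4, 2.0), (0.6, 0.3, 0.1)
        )
    )
    K: Mapping[str, float] = field(
        default_factory=lambda: {"K": 1.0, "H": 1.0, "EF": 1.0}
    )
    reference_group: str = "NEF"
    nuisance_dist: OmegaDistribution | None = None
    nuisance_from_reference: bool = True
    kappa: float = 2.0
    positional_freqs: tuple = DEFAULT_POSITIONAL_FREQS
    branch_overrides: Mapping[str, OmegaDistribution] = field(
        default_factory=dict
    )


def _sample_states(P_rows: np.ndarray, rng) -> np.ndarray:
    """One categorical draw per row of a stack of probability vectors."""
    cum = np.cumsum(P_rows, axis=1)
    u = rng.random(P_rows.shape[0]) * cum[:, -1]
    return np.minimum(
        (cum < u[:, None]).sum(axis=1), P_rows.shape[1] - 1
    )


def gen_codon_alignment(
    ltree: LabeledTree, config: AlignmentConfig
) -> tuple[CodonAlignment, GroundTruth]:
    """Simulate codon states down the labeled tree.

    Root states are drawn from the equilibrium codon distribution (an F3x4
    product form, so the estimator used by the fits is correctly
    specified)."""
    code = get_code(config.code_name)
    space = CodonSpace(code)
    pi = _codon_probs(space.codons, config.positional_freqs)
    exch = hky_exchangeabilities(config.kappa)
    rng = np.random.default_rng(config.seed)

    def dist_for(node) -> OmegaDistribution:
        key = LabeledTree.node_key(node)
        if key in config.branch_overrides:
            return config.branch_overrides[key]
        label = getattr(node, "group", None)
        if label is None or label == "nuisance":
            if config.nuisance_dist is not None:
                return config.nuisance_dist
            if not config.nuisance_from_reference:
                raise ValueError(
                    f"unlabeled branch {key!r} and no nuisance distribution"
                )
            return config.reference_dist
        if label == config.reference_group:
            return config.reference_dist
        if label in config.K:
            return apply_intensification(
                config.reference_dist, config.K[label]
            )
        return config.reference_dist

    spectral: dict[float, SpectralQ] = {}

    def spec_for(om: float) -> SpectralQ:
        key = round(float(om), 12)
        if key not in spectral:
            Q = build_rate_matrix(space, pi, exch, key)
            spectral[key] = SpectralQ(Q, pi)
        return spectral[key]

    n = config.n_codons
    root = ltree.tree.seed_node
    states = {id(root): rng.choice(space.n, size=n, p=pi)}
    regimes = {}
    taxa, seqs = [], []
    for node in ltree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        d = dist_for(node)
        regimes[LabeledTree.node_key(node)] = d.to_dict()
        t = node.edge.length or 0.0
        parent = states[id(node.parent_node)]
        cats = rng.choice(3, size=n, p=np.asarray(d.weights))
        child = np.empty(n, dtype=int)
        for k in range(3):
            mask = cats == k
            if not mask.any():
                continue
            P = spec_for(d.omegas[k]).probs(np.array([t]))[0]
            child[mask] = _sample_states(P[parent[mask]], rng)
        states[id(node)] = child
        if node.is_leaf():
            taxa.append(node.taxon.label)
            seqs.append("".join(space.codons[s] for s in child))
    aln = CodonAlignment(taxa, seqs)
    truth = GroundTruth(
        kind="codon_alignment",
        params={
            "seed": config.seed,
            "n_codons": config.n_codons,
            "code_name": config.code_name,
            "kappa": config.kappa,
            "reference_group": config.reference_group,
        },
        truth={
            "reference_dist": config.reference_dist.to_dict(),
            "K": dict(config.K),
            "nuisance_dist": (
                config.nuisance_dist.to_dict()
                if config.nuisance_dist
                else config.reference_dist.to_dict()
            ),
            "branch_regimes": regimes,
            "equilibrium": pi,
        },
    )
    return aln, truth
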