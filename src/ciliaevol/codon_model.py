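"""Codon substitution models and phylogenetic likelihood.

The engine underlying the selection tests: an MG94xREV-style codon rate
matrix over the sense codons of a genetic code (nonsynonymous rates scaled
by omega = dN/dS), transition probabilities by matrix exponential, and tree
log-likelihood by Felsenstein pruning with per-site scaling.  Branch-specific
omegas are looked up through the branch group labels, and omega mixtures are
supported both as per-branch mixtures (each branch-site combination draws
its own rate class, the convention of branch-site random-effects selection
tests) and as shared site-level categories.

Because the rate matrix is time-reversible it is symmetrizable, and all
transition probabilities are computed from one symmetric eigendecomposition
per distinct omega; this is what keeps the test fits at interactive speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.linalg import expm

from .genetic_code import GeneticCode, PRESET_CODES
from .phylo import NUISANCE, LabeledTree

NT = "ACGT"
NT_INDEX = {n: i for i, n in enumerate(NT)}

#: order of the six symmetric nucleotide exchangeabilities
EXCH_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"),
              ("C", "G"), ("C", "T"), ("G", "T"))
_PAIR_INDEX = {p: i for i, p in enumerate(EXCH_PAIRS)}
_PAIR_INDEX.update({(b, a): i for (a, b), i in list(_PAIR_INDEX.items())})


def hky_exchangeabilities(kappa: float) -> np.ndarray:
    """REV exchangeabilities with transitions (A<->G, C<->T) at ``kappa``."""
    e = np.ones(6)
    e[_PAIR_INDEX[("A", "G")]] = kappa
    e[_PAIR_INDEX[("C", "T")]] = kappa
    return e


class CodonSpace:
    """Sense-codon state space of a genetic code, with the single-nucleotide
    neighbor structure needed to build rate matrices."""

    def __init__(self, code: GeneticCode):
        self.code = code
        self.codons = code.sense_codons
        self.index = {c: i for i, c in enumerate(self.codons)}
        self.n = len(self.codons)
        ii, jj, pair, nonsyn = [], [], [], []
        for i, ci in enumerate(self.codons):
            for j in range(i + 1, self.n):
                cj = self.codons[j]
                diffs = [p for p in range(3) if ci[p] != cj[p]]
                if len(diffs) != 1:
                    continue
                p = diffs[0]
                ii.append(i)
                jj.append(j)
                pair.append(_PAIR_INDEX[(ci[p], cj[p])])
                nonsyn.append(not code.is_synonymous(ci, cj))
        self.ii = np.array(ii)
        self.jj = np.array(jj)
        self.pair = np.array(pair)
        self.nonsyn = np.array(nonsyn, dtype=bool)

    def encode(self, codon: str) -> int:
        """Sense-codon index; -1 for gap/ambiguous codons."""
        if codon in self.index:
            return self.index[codon]
        if "-" in codon or "N" in codon or "." in codon:
            return -1
        if self.code.table.get(codon) == "*":
            raise ValueError(
                f"in-frame stop codon {codon} under code {self.code.name!r}"
            )
        return -1


@dataclass
class CodonModelParams:
    """Parameters of one rate category.

    ``omega`` may be a scalar or a mapping from branch-group label to omega
    (key ``"nuisance"`` covers unlabeled branches); ``frequencies`` is the
    equilibrium distribution over the code's sense codons (None = estimate
    by F3x4 from the alignment at hand).
    """

    code: GeneticCode
    omega: float | Mapping[str, float] = 1.0
    frequencies: np.ndarray | None = None
    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6)
    )

    def omega_for_label(self, label: str | None) -> float:
        if isinstance(self.omega, Mapping):
            key = label if label is not None else NUISANCE
            if key not in self.omega:
                raise KeyError(f"no omega for branch label {key!r}")
            return float(self.omega[key])
        return float(self.omega)


def build_rate_matrix(
    space: CodonSpace,
    frequencies: np.ndarray,
    exchangeabilities: np.ndarray,
    omega: float,
    scale: bool = True,
) -> np.ndarray:
    """MG94xREV-style generator over sense codons.

    q_ij for single-nucleotide neighbors is exchangeability x target codon
    frequency x omega (nonsynonymous only); rows sum to zero.  Scaling
    divides by the equilibrium substitution rate of the *neutral* (omega=1)
    matrix with the same frequencies and exchangeabilities, so branch
    lengths are expected substitutions per codon under neutrality and —
    crucially for omega mixtures — categories with different omegas keep
    their relative rates (a category at omega=5 really evolves faster than
    one at omega=0.1; normalizing each matrix separately would reduce omega
    to a pattern-only effect).
    """
    pi = np.asarray(frequencies, dtype=float)
    if pi.shape != (space.n,):
        raise ValueError(f"frequencies must have length {space.n}")
    if np.any(pi <= 0):
        raise ValueError("codon frequencies must be strictly positive")
    ex = np.asarray(exchangeabilities, dtype=float)
    if ex.shape != (6,) or np.any(ex <= 0):
        raise ValueError("need 6 positive exchangeabilities")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    Q = np.zeros((space.n, space.n))
    rates = ex[space.pair] * np.where(space.nonsyn, omega, 1.0)
    Q[space.ii, space.jj] = rates * pi[space.jj]
    Q[space.jj, space.ii] = rates * pi[space.ii]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        # equilibrium rate of the neutral matrix: 2 * sum_pairs r * pi_i * pi_j
        mu1 = 2.0 * float(
            np.sum(ex[space.pair] * pi[space.ii] * pi[space.jj])
        )
        if mu1 > 0:
            Q /= mu1
    return Q


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to 1, entries >= 0."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if t == 0:
        return np.eye(Q.shape[0])
    P = expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


class SpectralQ:
    """Symmetric eigendecomposition of a reversible generator.

    P(t) = A exp(diag(lam) t) B for any t, enabling batched transition
    matrices across branch lengths.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        S = Q * (d[:, None] / d[None, :])
        S = 0.5 * (S + S.T)
        lam, U = np.linalg.eigh(S)
        self.lam = np.minimum(lam, 0.0)  # generator spectrum is <= 0
        self.pi = np.asarray(pi, dtype=float)
        self.A = U / d[:, None]
        self.B = U.T * d[None, :]

    def probs(self, ts: np.ndarray) -> np.ndarray:
        """Transition matrices for a vector of branch lengths: (nt, S, S)."""
        ts = np.atleast_1d(np.asarray(ts, dtype=float))
        nt = ts.shape[0]
        S = self.lam.shape[0]
        with np.errstate(under="ignore"):
            E = np.exp(np.outer(ts, self.lam))  # (nt, S)
        AE = self.A[None, :, :] * E[:, None, :]
        P = (AE.reshape(nt * S, S) @ self.B).reshape(nt, S, S)
        np.clip(P, 0.0, None, out=P)
        sums = P.sum(axis=2, keepdims=True)
        # rows that underflowed entirely are at the ergodic limit
        degenerate = sums[..., 0] < 1e-12
        if degenerate.any():
            P[degenerate] = self.pi
            sums = P.sum(axis=2, keepdims=True)
        P /= sums
        return P


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """An in-frame alignment stored as one nucleotide string per taxon."""

    taxa: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.seqs):
            raise ValueError("taxa/seqs length mismatch")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        (L,) = lengths
        if L % 3 != 0:
            raise ValueError(f"alignment length {L} not divisible by 3")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3

    def codon(self, row: int, site: int) -> str:
        return self.seqs[row][3 * site : 3 * site + 3]

    def encode(self, space: CodonSpace) -> np.ndarray:
        """Integer state matrix (taxa x sites); -1 marks missing data."""
        out = np.empty((len(self.taxa), self.n_codons), dtype=np.int64)
        for r in range(len(self.taxa)):
            for s in range(self.n_codons):
                out[r, s] = space.encode(self.codon(r, s))
        return out

    @classmethod
    def from_file(cls, path: str | Path, fmt: str = "fasta") -> "CodonAlignment":
        """Read an aligned FASTA or relaxed PHYLIP file."""
        schema = "phylip-relaxed" if fmt in ("phylip", "phylip-relaxed") else fmt
        aln = AlignIO.read(str(path), schema)
        return cls([r.id for r in aln], [str(r.seq) for r in aln])

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s), id=t, description="")
            for t, s in zip(self.taxa, self.seqs)
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f" {len(self.taxa)} {len(self.seqs[0])}\n")
            for t, s in zip(self.taxa, self.seqs):
                fh.write(f"{t}  {s}\n")


def f3x4_frequencies(aln: CodonAlignment, space: CodonSpace) -> np.ndarray:
    """F3x4 codon frequencies: product of empirical per-position nucleotide
    frequencies, restricted to sense codons and renormalized."""
    counts = np.zeros((3, 4))
    for seq in aln.seqs:
        for s in range(len(seq) // 3):
            codon = seq[3 * s : 3 * s + 3]
            for p, nt in enumerate(codon):
                if nt in NT_INDEX:
                    counts[p, NT_INDEX[nt]] += 1
    counts += 0.5  # pseudo-count keeps frequencies strictly positive
    pos = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos[0, NT_INDEX[c[0]]]
            * pos[1, NT_INDEX[c[1]]]
            * pos[2, NT_INDEX[c[2]]]
            for c in space.codons
        ]
    )
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# tree indexing and pruning
# ---------------------------------------------------------------------------


class TreeIndex:
    """Array view of a labeled tree for fast pruning."""

    def __init__(self, ltree: LabeledTree, taxa: Sequence[str]):
        taxon_row = {t: i for i, t in enumerate(taxa)}
        nodes = list(ltree.tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        self.node_of = {id(nd): i for i, nd in enumerate(nodes)}
        self.postorder = list(range(self.n_nodes))
        self.children: list[list[int]] = [[] for _ in nodes]
        self.blen = np.zeros(self.n_nodes)
        self.label: list[str | None] = [None] * self.n_nodes
        self.leaf_row = np.full(self.n_nodes, -1, dtype=int)
        self.is_leaf = np.zeros(self.n_nodes, dtype=bool)
        self.keys: list[str] = [""] * self.n_nodes
        for i, nd in enumerate(nodes):
            self.keys[i] = LabeledTree.node_key(nd)
            if nd.parent_node is not None:
                self.children[self.node_of[id(nd.parent_node)]].append(i)
                self.blen[i] = nd.edge.length or 0.0
            self.label[i] = getattr(nd, "group", None)
            if nd.is_leaf():
                self.is_leaf[i] = True
                name = nd.taxon.label if nd.taxon else nd.label
                if name not in taxon_row:
                    raise ValueError(
                        f"tree leaf {name!r} not among alignment taxa"
                    )
                self.leaf_row[i] = taxon_row[name]
        self.root = self.n_nodes - 1
        present = {self.leaf_row[i] for i in range(self.n_nodes) if self.is_leaf[i]}
        missing = set(range(len(taxa))) - present
        if missing:
            raise ValueError(
                f"alignment taxa absent from tree: "
                f"{sorted(taxa[i] for i in missing)}"
            )
        self.edges = [i for i in range(self.n_nodes) if i != self.root]


def compress_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique alignment columns and their multiplicities."""
    patterns, weights = np.unique(codes, axis=1, return_counts=True)
    return patterns, weights.astype(float)


class PruningEngine:
    """Felsenstein pruning over compressed site patterns.

    Bound to one alignment/tree/code; transition matrices for the branches
    are supplied per call, so nested model fits reuse all indexing and the
    spectral cache.
    """

    def __init__(
        self,
        aln: CodonAlignment,
        ltree: LabeledTree,
        code: GeneticCode | None = None,
        frequencies: np.ndarray | None = None,
    ):
        self.code = code or PRESET_CODES["universal"]
        self.space = CodonSpace(self.code)
        self.aln = aln
        self.tindex = TreeIndex(ltree, aln.taxa)
        codes = aln.encode(self.space)
        self.patterns, self.pattern_weights = compress_patterns(codes)
        self.npat = self.patterns.shape[1]
        self.n_sites = aln.n_codons
        self.pi = (
            np.asarray(frequencies, dtype=float)
            if frequencies is not None
            else f3x4_frequencies(aln, self.space)
        )
        self._spectral_cache: dict[tuple, SpectralQ] = {}
        # per-omega transition-matrix stacks and mixture-averaged stacks,
        # reused heavily across optimizer iterations and finite-difference
        # gradients (branch lengths are fixed within a fit)
        self._probs_cache: dict[tuple, np.ndarray] = {}
        self._mix_cache: dict[tuple, np.ndarray] = {}

    # -- rate matrices -------------------------------------------------

    def spectral_for(
        self, omega: float, exchangeabilities: np.ndarray
    ) -> SpectralQ:
        key = (float(omega), tuple(exchangeabilities))
        spec = self._spectral_cache.get(key)
        if spec is None:
            Q = build_rate_matrix(
                self.space, self.pi, exchangeabilities, omega
            )
            spec = SpectralQ(Q, self.pi)
            if len(self._spectral_cache) > 512:
                self._spectral_cache.clear()
            self._spectral_cache[key] = spec
        return spec

    # -- transition matrices for branch mixtures ------------------------

    def mixture_stack(
        self,
        omegas: Sequence[float],
        weights: Sequence[float],
        edges: tuple[int, ...],
        exchangeabilities: np.ndarray,
        scale: float,
    ) -> np.ndarray:
        """sum_k w_k P(omega_k, scale * t_e) on the given edges, cached by
        the full category signature.

        Returns an (n_edges, S, S) stack aligned with ``edges``.  Keys are
        raw floats: within a fit the optimizer revisits bit-identical
        parameter values (warm starts, line searches, unchanged coordinates
        during finite differencing), which is where the cache pays off.
        """
        sig = (
            tuple(float(o) for o in omegas),
            tuple(float(w) for w in weights),
            edges,
            tuple(exchangeabilities),
            float(scale),
        )
        st = self._mix_cache.get(sig)
        if st is None:
            idx = list(edges)
            st = None
            for om, w in zip(sig[0], sig[1]):
                if w == 0.0:
                    continue
                term = w * self._edge_probs(om, exchangeabilities, scale)[idx]
                st = term if st is None else st + term
            if len(self._mix_cache) > 128:
                self._mix_cache.clear()
            self._mix_cache[sig] = st
        return st

    def _edge_probs(
        self, omega: float, exchangeabilities: np.ndarray, scale: float
    ) -> np.ndarray:
        """(n_nodes, S, S) transition matrices for every edge at one omega,
        cached: one omega is typically shared by several branch classes."""
        key = (float(omega), tuple(exchangeabilities), float(scale))
        P = self._probs_cache.get(key)
        if P is None:
            spec = self.spectral_for(omega, exchangeabilities)
            P = np.zeros((self.tindex.n_nodes,) + (self.space.n,) * 2)
            edges = np.array(self.tindex.edges)
            P[edges] = spec.probs(scale * self.tindex.blen[edges])
            if len(self._probs_cache) > 128:
                self._probs_cache.clear()
            self._probs_cache[key] = P
        return P

    def branch_mixture_probs(
        self,
        omegas_by_edge: Mapping[int, Sequence[float]],
        weights_by_edge: Mapping[int, Sequence[float]],
        exchangeabilities: np.ndarray,
        scale: float = 1.0,
    ) -> np.ndarray:
        """Per-edge mixture-averaged transition matrices.

        For each edge e with categories (w_k, omega_k), computes
        sum_k w_k P(omega_k, scale * t_e).  Edges sharing one category
        signature (the common case: branch groups) are computed and cached
        together.
        """
        by_sig: dict[tuple, list[int]] = {}
        for e in self.tindex.edges:
            sig = (
                tuple(float(o) for o in omegas_by_edge[e]),
                tuple(float(w) for w in weights_by_edge[e]),
            )
            by_sig.setdefault(sig, []).append(e)
        S = self.space.n
        P = np.zeros((self.tindex.n_nodes, S, S))
        for (oms, ws), edge_list in by_sig.items():
            edges = tuple(edge_list)
            st = self.mixture_stack(oms, ws, edges, exchangeabilities, scale)
            P[list(edges)] = st
        return P

    # -- pruning --------------------------------------------------------

    def loglik_from_probs(self, P: np.ndarray) -> float:
        """Total log-likelihood given per-edge transition matrices."""
        per_pat = self._pattern_logliks(P)
        return float(self.pattern_weights @ per_pat)

    def _pattern_logliks(self, P: np.ndarray) -> np.ndarray:
        ti = self.tindex
        npat, S = self.npat, self.space.n
        partial = {}
        logscale = np.zeros(npat)
        for node in ti.postorder:
            if ti.is_leaf[node]:
                continue
            M = np.ones((npat, S))
            for c in ti.children[node]:
                Pc = P[c]
                if ti.is_leaf[c]:
                    codes = self.patterns[ti.leaf_row[c]]
                    Mc = Pc.T[codes]  # row per pattern: P[:, state]
                    miss = codes < 0
                    if miss.any():
                        Mc = Mc.copy()
                        Mc[miss] = 1.0
                else:
                    Mc = partial.pop(c) @ Pc.T
                M *= Mc
            scale = M.max(axis=1)
            scale[scale == 0.0] = np.finfo(float).tiny
            M /= scale[:, None]
            logscale += np.log(scale)
            partial[node] = M
        root_lik = partial[ti.root] @ self.pi
        root_lik[root_lik == 0.0] = np.finfo(float).tiny
        return np.log(root_lik) + logscale

    def site_mixture_loglik(
        self,
        categories: Sequence[tuple[float, Mapping[int, float]]],
        exchangeabilities: np.ndarray,
        scale: float = 1.0,
    ) -> float:
        """Shared site-category mixture: sites draw one category that applies
        to every branch.  ``categories`` is a list of (weight, omega-per-edge
        mapping)."""
        weights = np.array([w for w, _ in categories])
        if not np.isclose(weights.sum(), 1.0):
            raise ValueError("category weights must sum to 1")
        logliks = []
        for _, omega_by_edge in categories:
            P = self.branch_mixture_probs(
                {e: [om] for e, om in omega_by_edge.items()},
                {e: [1.0] for e in omega_by_edge},
                exchangeabilities,
                scale,
            )
            logliks.append(self._pattern_logliks(P))
        logliks = np.stack(logliks)  # (ncat, npat)
        m = logliks.max(axis=0)
        mix = m + np.log(
            np.maximum(
                (weights[:, None] * np.exp(logliks - m)).sum(axis=0),
                np.finfo(float).tiny,
            )
        )
        return float(self.pattern_weights @ mix)


def tree_log_likelihood(
    aln: CodonAlignment,
    ltree: LabeledTree,
    site_model: Sequence[tuple[float, CodonModelParams]],
) -> float:
    """Log-likelihood under a site-level mixture of codon models.

    Each category is (weight, params); omegas may vary across branches via
    the params' label map.  Frequencies default to F3x4 from the alignment;
    all categories must share the same genetic code.
    """
    if not site_model:
        raise ValueError("empty site model")
    codes = {p.code.name for _, p in site_model}
    if len(codes) != 1:
        raise ValueError("all mixture categories must share one genetic code")
    base = site_model[0][1]
    engine = PruningEngine(aln, ltree, base.code, base.frequencies)
    categories = []
    for w, params in site_model:
        omega_by_edge = {
            e: params.omega_for_label(engine.tindex.label[e])
            for e in engine.tindex.edges
        }
        categories.append((w, omega_by_edge))
    # categories may differ in exchangeabilities only if identical;
    # use the first category's exchangeabilities for all.
    return engine.site_mixture_loglik(
        categories, base.exchangeabilities
    )
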