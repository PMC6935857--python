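"""Rate matrices, transition probabilities and pruning likelihood, checked
against truncated-series and exhaustive-enumeration oracles."""

import itertools

import numpy as np
import pytest

from ciliaevol import (
    CodonAlignment,
    CodonModelParams,
    CodonSpace,
    LabeledTree,
    PRESET_CODES,
    PruningEngine,
    build_rate_matrix,
    f3x4_frequencies,
    hky_exchangeabilities,
    transition_probabilities,
    tree_log_likelihood,
)
from ciliaevol.simulate import _codon_probs, DEFAULT_POSITIONAL_FREQS


SPACE = CodonSpace(PRESET_CODES["universal"])


def _random_params(seed):
    rng = np.random.default_rng(seed)
    pi = rng.dirichlet(np.ones(SPACE.n) * 5)
    ex = rng.uniform(0.5, 3.0, size=6)
    return pi, ex


def test_state_space_sizes_follow_the_code():
    assert CodonSpace(PRESET_CODES["universal"]).n == 61
    assert CodonSpace(PRESET_CODES["ciliate"]).n == 63
    assert CodonSpace(PRESET_CODES["blepharisma"]).n == 62
    assert CodonSpace(PRESET_CODES["condylostoma"]).n == 64


def test_omega_zero_kills_nonsynonymous_rates():
    pi, ex = _random_params(1)
    Q = build_rate_matrix(SPACE, pi, ex, omega=0.0)
    assert np.all(Q[SPACE.ii[SPACE.nonsyn], SPACE.jj[SPACE.nonsyn]] == 0)
    assert np.any(Q[SPACE.ii[~SPACE.nonsyn], SPACE.jj[~SPACE.nonsyn]] > 0)


def test_neutral_equal_rates_symmetric():
    pi = np.full(SPACE.n, 1 / SPACE.n)
    Q = build_rate_matrix(SPACE, pi, np.ones(6), omega=1.0, scale=False)
    off = Q[SPACE.ii, SPACE.jj]
    assert np.allclose(off, off[0])  # all single-step neighbors equal


def test_rows_sum_to_zero_and_equilibrium_is_left_null_vector():
    pi, ex = _random_params(4)
    Q = build_rate_matrix(SPACE, pi, ex, omega=0.7)
    assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-10)
    assert np.allclose(pi @ Q, 0.0, atol=1e-10)
    # the neutral matrix has unit equilibrium rate; an omega=0.7 matrix is
    # proportionally slower on its nonsynonymous component
    Q1 = build_rate_matrix(SPACE, pi, ex, omega=1.0)
    assert -pi @ np.diag(Q1) == pytest.approx(1.0)
    assert 0.7 < -pi @ np.diag(Q) < 1.0


def test_rate_matrix_rejects_bad_inputs():
    pi, ex = _random_params(2)
    with pytest.raises(ValueError, match="positive"):
        bad = pi.copy()
        bad[0] = 0.0
        build_rate_matrix(SPACE, bad, ex, 1.0)
    with pytest.raises(ValueError):
        build_rate_matrix(SPACE, pi, ex, omega=-0.5)


def test_transition_probabilities_identity_at_zero():
    pi, ex = _random_params(3)
    Q = build_rate_matrix(SPACE, pi, ex, 1.2)
    assert np.array_equal(transition_probabilities(Q, 0.0), np.eye(SPACE.n))
    with pytest.raises(ValueError):
        transition_probabilities(Q, -0.1)


def test_transition_probabilities_reach_equilibrium():
    pi, ex = _random_params(5)
    Q = build_rate_matrix(SPACE, pi, ex, 0.8)
    P = transition_probabilities(Q, 500.0)
    assert np.allclose(P, np.tile(pi, (SPACE.n, 1)), atol=1e-6)


def test_transition_probabilities_match_series_oracle():
    """3-state toy generator: expm equals the truncated Taylor series."""
    Q = np.array([[-1.0, 0.6, 0.4], [0.3, -0.5, 0.2], [0.5, 0.5, -1.0]])
    for t in (0.05, 0.3, 1.0):
        series = np.eye(3)
        term = np.eye(3)
        for k in range(1, 60):
            term = term @ (Q * t) / k
            series += term
        P = transition_probabilities(Q, t)
        assert np.allclose(P, series, atol=1e-8)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.all(P >= 0)


def test_spectral_probs_match_expm():
    from ciliaevol.codon_model import SpectralQ

    pi, ex = _random_params(6)
    Q = build_rate_matrix(SPACE, pi, ex, 1.5)
    spec = SpectralQ(Q, pi)
    for t in (0.01, 0.2, 2.0):
        assert np.allclose(
            spec.probs(np.array([t]))[0],
            transition_probabilities(Q, t),
            atol=1e-9,
        )


# ---------------------------------------------------------------------------
# alignments and frequencies
# ---------------------------------------------------------------------------


def test_alignment_validation():
    with pytest.raises(ValueError, match="divisible by 3"):
        CodonAlignment(["a", "b"], ["ACGTA", "ACGTA"])
    with pytest.raises(ValueError, match="length"):
        CodonAlignment(["a", "b"], ["ACGACG", "ACG"])
    aln = CodonAlignment(["a", "b"], ["ATGAAA", "ATG---"])
    codes = aln.encode(SPACE)
    assert codes[1, 1] == -1  # gap codon is missing data
    with pytest.raises(ValueError, match="stop"):
        CodonAlignment(["a"], ["ATGTAA"]).encode(SPACE)


def test_alignment_file_round_trip(tmp_path):
    aln = CodonAlignment(["tax1", "tax2"], ["ATGAAACCC", "ATGAAAGGG"])
    fa = tmp_path / "aln.fasta"
    ph = tmp_path / "aln.phy"
    aln.to_fasta(fa)
    aln.to_phylip(ph)
    for path, fmt in ((fa, "fasta"), (ph, "phylip")):
        back = CodonAlignment.from_file(path, fmt)
        assert back.taxa == aln.taxa
        assert back.seqs == aln.seqs


def test_f3x4_matches_hand_computed_product_form():
    rng = np.random.default_rng(9)
    pi_true = _codon_probs(SPACE.codons, DEFAULT_POSITIONAL_FREQS)
    idx = rng.choice(SPACE.n, p=pi_true, size=20000)
    seq = "".join(SPACE.codons[i] for i in idx)
    aln = CodonAlignment(["a"], [seq])
    pi_hat = f3x4_frequencies(aln, SPACE)
    # independent recomputation of the product form from raw counts
    counts = np.zeros((3, 4))
    lut = {n: i for i, n in enumerate("ACGT")}
    for s in range(len(seq) // 3):
        for p in range(3):
            counts[p, lut[seq[3 * s + p]]] += 1
    pos = (counts + 0.5) / (counts + 0.5).sum(axis=1, keepdims=True)
    expected = np.array(
        [pos[0, lut[c[0]]] * pos[1, lut[c[1]]] * pos[2, lut[c[2]]]
         for c in SPACE.codons]
    )
    expected /= expected.sum()
    assert np.allclose(pi_hat, expected, atol=1e-12)
    assert pi_hat.sum() == pytest.approx(1.0)
    # close to the generating distribution up to the stop-exclusion bias
    assert np.allclose(pi_hat, pi_true, atol=0.012)


# ---------------------------------------------------------------------------
# pruning likelihood vs enumeration oracles
# ---------------------------------------------------------------------------


def _two_taxon_direct(aln, t1, t2, pi, ex, omega):
    Q = build_rate_matrix(SPACE, pi, ex, omega)
    P1 = transition_probabilities(Q, t1)
    P2 = transition_probabilities(Q, t2)
    codes = aln.encode(SPACE)
    total = 0.0
    for s in range(aln.n_codons):
        a, b = codes[:, s]
        total += np.log(np.sum(pi * P1[:, a] * P2[:, b]))
    return total


def test_two_taxon_likelihood_matches_direct_sum():
    lt = LabeledTree.from_newick("(A:0.2,B:0.35);")
    aln = CodonAlignment(["A", "B"], ["ATGAAACCCGGG", "ATGAACCCAGGG"])
    pi = f3x4_frequencies(aln, SPACE)
    ex = hky_exchangeabilities(2.0)
    params = CodonModelParams(
        code=PRESET_CODES["universal"], omega=0.5, exchangeabilities=ex
    )
    got = tree_log_likelihood(aln, lt, [(1.0, params)])
    expected = _two_taxon_direct(aln, 0.2, 0.35, pi, ex, 0.5)
    assert got == pytest.approx(expected, abs=1e-8)


def test_duplicated_sites_double_the_loglik():
    lt = LabeledTree.from_newick("((A:0.1,B:0.2):0.05,(C:0.1,D:0.3):0.1);")
    aln = CodonAlignment(
        ["A", "B", "C", "D"],
        ["ATGAAACCC", "ATGAACCCC", "ATGAAAGCC", "ATGTTACCC"],
    )
    # pin frequencies: F3x4 has a pseudo-count, so letting each call
    # re-estimate them would couple the likelihood to the alignment length
    pi = f3x4_frequencies(aln, SPACE)
    params = CodonModelParams(
        code=PRESET_CODES["universal"], omega=0.8, frequencies=pi
    )
    single = tree_log_likelihood(aln, lt, [(1.0, params)])
    doubled = CodonAlignment(aln.taxa, [s + s for s in aln.seqs])
    assert tree_log_likelihood(doubled, lt, [(1.0, params)]) == pytest.approx(
        2 * single, rel=1e-12
    )


def _toy_reduced_code():
    """A code whose only sense codons are the 8 codons over {A, C}: keeps
    exhaustive ancestral-state enumeration at 8^3 combinations."""
    from ciliaevol.genetic_code import ALL_CODONS, GeneticCode, _standard_table

    table = _standard_table()
    for c in ALL_CODONS:
        if not set(c) <= {"A", "C"}:
            table[c] = "*"
    return GeneticCode("toy-reduced", table)


def _enumeration_loglik(aln, space, categories, pi, ex):
    """Exhaustive sum over all internal-node state assignments for the
    4-taxon tree ((A:0.1,B:0.2):0.05,(C:0.1,D:0.2):0.3);.  Independent of
    the pruning recursion."""
    codes = aln.encode(space)
    row = {t: i for i, t in enumerate(aln.taxa)}
    S = space.n
    site_liks = np.zeros((len(categories), aln.n_codons))
    for ci, (_, omega) in enumerate(categories):
        Q = build_rate_matrix(space, pi, ex, omega)
        P = {
            t: transition_probabilities(Q, t)
            for t in (0.1, 0.2, 0.05, 0.3)
        }
        for s in range(aln.n_codons):
            a, b, c, d = (codes[row[x], s] for x in "ABCD")
            lik = 0.0
            for r, x, y in itertools.product(range(S), repeat=3):
                lik += (
                    pi[r]
                    * P[0.05][r, x]
                    * P[0.1][x, a]
                    * P[0.2][x, b]
                    * P[0.3][r, y]
                    * P[0.1][y, c]
                    * P[0.2][y, d]
                )
            site_liks[ci, s] = lik
    weights = np.array([w for w, _ in categories])
    return float(np.log(weights @ site_liks).sum())


def test_pruning_matches_exhaustive_enumeration():
    """4-taxon, 10-codon mixture likelihood equals brute-force enumeration
    over ancestral states, on a reduced two-letter codon alphabet."""
    toy = _toy_reduced_code()
    space = CodonSpace(toy)
    assert space.n == 8
    rng = np.random.default_rng(12)
    seqs = {
        t: "".join(rng.choice(space.codons) for _ in range(10))
        for t in "ABCD"
    }
    aln = CodonAlignment(list("ABCD"), [seqs[t] for t in "ABCD"])
    lt = LabeledTree.from_newick("((A:0.1,B:0.2):0.05,(C:0.1,D:0.2):0.3);")
    pi = f3x4_frequencies(aln, space)
    ex = hky_exchangeabilities(1.7)
    categories = [(0.6, 0.2), (0.4, 2.5)]

    site_model = [
        (w, CodonModelParams(toy, omega=om, frequencies=pi,
                             exchangeabilities=ex))
        for w, om in categories
    ]
    got = tree_log_likelihood(aln, lt, site_model)
    oracle = _enumeration_loglik(aln, space, categories, pi, ex)
    assert got == pytest.approx(oracle, abs=1e-8)


def test_likelihood_invariant_to_leaf_order():
    lt = LabeledTree.from_newick("((A:0.1,B:0.2):0.05,(C:0.1,D:0.3):0.1);")
    seqs = dict(zip("ABCD", ["ATGAAACCC", "ATGAACCCC", "ATGAAAGCC", "ATGTTACCC"]))
    params = CodonModelParams(code=PRESET_CODES["universal"], omega=0.8)
    order1 = CodonAlignment(list("ABCD"), [seqs[t] for t in "ABCD"])
    order2 = CodonAlignment(list("DCBA"), [seqs[t] for t in "DCBA"])
    # fix frequencies so both runs use the same equilibrium
    pi = f3x4_frequencies(order1, SPACE)
    params.frequencies = pi
    assert tree_log_likelihood(order1, lt, [(1.0, params)]) == pytest.approx(
        tree_log_likelihood(order2, lt, [(1.0, params)]), rel=1e-12
    )


def test_fully_ambiguous_column_contributes_zero():
    lt = LabeledTree.from_newick("(A:0.2,B:0.35);")
    params = CodonModelParams(code=PRESET_CODES["universal"], omega=0.5)
    base = CodonAlignment(["A", "B"], ["ATGAAA", "ATGAAC"])
    pi = f3x4_frequencies(base, SPACE)
    params.frequencies = pi
    with_gap = CodonAlignment(["A", "B"], ["ATGAAA---", "ATGAAC---"])
    assert tree_log_likelihood(with_gap, lt, [(1.0, params)]) == pytest.approx(
        tree_log_likelihood(base, lt, [(1.0, params)]), rel=1e-12
    )


def test_taxon_mismatch_error():
    lt = LabeledTree.from_newick("(A:0.2,B:0.35);")
    aln = CodonAlignment(["A", "X"], ["ATGAAA", "ATGAAC"])
    params = CodonModelParams(code=PRESET_CODES["universal"])
    with pytest.raises(ValueError):
        tree_log_likelihood(aln, lt, [(1.0, params)])
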