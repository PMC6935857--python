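"""Forced ORFs, stop-usage profiles, stop classification and reassignment
inference, checked against brute-force scans and constructed alignments."""

import numpy as np
import pytest

from ciliaevol import (
    CANONICAL_STOPS,
    PRESET_CODES,
    CodeInferenceParams,
    ReferenceAlignment,
    Transcript,
    classify_stops,
    forced_orf,
    get_code,
    infer_code,
    infer_reassignments,
    stop_usage_profile,
)
from ciliaevol.genetic_code import (
    SchemeCounts,
    StopUsageProfile,
    no_stop_qualifies,
    tally_conserved_columns,
)
from ciliaevol.simulate import (
    TranscriptomeConfig,
    gen_reference_alignments,
    gen_transcriptome,
)

from conftest import random_seq


# ---------------------------------------------------------------------------
# genetic code presets
# ---------------------------------------------------------------------------


def test_presets_cover_64_codons_and_expected_stops():
    expected_stops = {
        "universal": {"TAA", "TAG", "TGA"},
        "ciliate": {"TGA"},
        "blepharisma": {"TAA", "TAG"},
        "euplotes": {"TAA", "TAG"},
        "chilodonella": {"TAA"},
        "mesodinium": {"TGA"},
        "vorticella": {"TGA"},
        "condylostoma": set(),
    }
    for name, code in PRESET_CODES.items():
        assert len(code.table) == 64
        assert set(code.stops) == expected_stops[name]
        assert len(code.sense_codons) == 64 - len(code.stops)
    assert PRESET_CODES["ciliate"].reassigned_stops == {"TAA": "Q", "TAG": "Q"}
    assert PRESET_CODES["euplotes"].reassigned_stops == {"TGA": "C"}
    assert PRESET_CODES["condylostoma"].context_dependent


# ---------------------------------------------------------------------------
# forced ORFs
# ---------------------------------------------------------------------------


def test_forced_orf_stops_at_forced_stop():
    # in the coding frame the run ends at the forced stop
    orf = forced_orf("ATGAAATAA", {"TAA"}, frames=[0])
    assert orf.frame == 0
    assert orf.codons == ("ATG", "AAA")
    assert (orf.start, orf.end) == (0, 6)
    # over all six frames the longest run wins wherever it lies: here the
    # reverse strand (TTATTTCAT) has a 3-codon TAA-free run
    assert len(forced_orf("ATGAAATAA", {"TAA"})) == 3
    # ... unless the reverse strand is also interrupted
    orf6 = forced_orf("ATGTTAAAATAA", {"TAA"})
    assert orf6.frame == 0
    assert orf6.codons == ("ATG", "TTA", "AAA")


def test_forced_orf_passes_non_forced_stop():
    orf = forced_orf("ATGTGAAAATAA", {"TAA"}, frames=[0])
    assert orf.codons == ("ATG", "TGA", "AAA")


def test_forced_orf_short_sequence_empty():
    assert len(forced_orf("AT", {"TAA"})) == 0


def _brute_force_orf(seq, stop_set):
    """Exhaustive scan over all 6 frames, independent of the implementation."""
    rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    best_len, best = -1, None
    for frame in range(6):
        strand = seq if frame < 3 else rc
        off = frame % 3
        codons = [strand[i:i + 3] for i in range(off, len(strand) - 2, 3)]
        run = []
        runs = []
        for c in codons:
            if c in stop_set:
                runs.append(run)
                run = []
            else:
                run.append(c)
        runs.append(run)
        for r in runs:
            if len(r) > best_len:
                best_len, best = len(r), (frame, tuple(r))
    return best


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_forced_orf_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    seq = random_seq(rng, 3000)
    for stop_set in ({"TAA"}, {"TGA"}, {"TAA", "TAG"}):
        orf = forced_orf(seq, stop_set)
        frame, codons = _brute_force_orf(seq, stop_set)
        assert len(orf) == len(codons)
        assert orf.codons == codons


def test_forced_orf_rejects_bad_stop_set():
    with pytest.raises(ValueError):
        forced_orf("ATGAAA", set())
    with pytest.raises(ValueError):
        forced_orf("ATGAAA", {"AAA"})


# ---------------------------------------------------------------------------
# stop-usage profile
# ---------------------------------------------------------------------------


def test_profile_counts_single_orf():
    """One 100-codon ORF with exactly one interior TGA under scheme TAA:
    the in-frame frequency is 1 per 100 codons scanned."""
    from ciliaevol.simulate import _codon_probs

    rng = np.random.default_rng(4)
    pool = [c for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
            if c not in CANONICAL_STOPS]
    probs = _codon_probs(pool, ((0.3, 0.2, 0.2, 0.3),) * 3)
    codons = list(rng.choice(pool, size=99, p=probs))
    codons.insert(50, "TGA")  # interior: survives the tail trim
    t = Transcript(id="t", seq="".join(codons), taxon="s")
    # 6-frame per-scheme mode: frame 0 is the unique longest TAA-free run
    prof = stop_usage_profile(
        [t], min_orf_codons=50, anchor_frame=False, orf_tail_trim=25
    )
    sc = prof.schemes["TAA"]
    assert sc.codons_scanned == 100
    assert sc.in_frame_counts["TGA"] == 1
    assert sc.frequencies()["TGA"] == pytest.approx(0.01)
    # trimming the tail excludes a stop sitting near the run's end
    codons_tail = codons[:100]
    codons_tail[95] = "TGA"
    codons_tail[50] = pool[0]
    t2 = Transcript(id="t2", seq="".join(codons_tail), taxon="s")
    prof2 = stop_usage_profile(
        [t2], min_orf_codons=50, anchor_frame=False, orf_tail_trim=25
    )
    assert prof2.schemes["TAA"].in_frame_counts["TGA"] == 0


def test_profile_universal_code_all_zero():
    tr, _ = gen_transcriptome(
        TranscriptomeConfig(seed=1, code_name="universal",
                            reassigned_usage_rate=0.0)
    )
    prof = stop_usage_profile(tr)
    for c, f in prof.pooled_frequencies().items():
        assert f <= 5e-4, (c, f)


def test_profile_ciliate_usage_rate_recovered():
    """Under the TGA-only scheme, in-frame UAR frequency matches the
    generating usage rate of 2 per 100 codons."""
    tr, _ = gen_transcriptome(TranscriptomeConfig(seed=7, code_name="ciliate"))
    prof = stop_usage_profile(tr)
    sc = prof.schemes["TGA"]
    f = sc.frequencies()
    assert f["TAA"] + f["TAG"] == pytest.approx(0.02, abs=0.005)
    # the functional stop is rare in frame under the other two schemes
    assert prof.pooled_frequency("TGA") < 0.004


def test_profile_min_orf_error():
    t = Transcript(id="t", seq="ATGAAA" * 3, taxon="s")
    with pytest.raises(ValueError, match="TAA"):
        stop_usage_profile([t], min_orf_codons=50)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _profile_from_freqs(freqs, scanned=100_000):
    """Build a profile whose pooled frequencies equal ``freqs``."""
    schemes = {}
    for forced in CANONICAL_STOPS:
        others = [c for c in CANONICAL_STOPS if c != forced]
        schemes[forced] = SchemeCounts(
            forced_stop=forced,
            codons_scanned=scanned,
            n_orfs=1,
            in_frame_counts={c: int(round(freqs[c] * scanned)) for c in others},
        )
    return StopUsageProfile(schemes)


def test_classify_all_zero_is_universal():
    prof = _profile_from_freqs({"TAA": 0, "TAG": 0, "TGA": 0})
    assert classify_stops(prof) == frozenset(CANONICAL_STOPS)


def test_classify_ciliate_pattern():
    prof = _profile_from_freqs({"TAA": 0.018, "TAG": 0.012, "TGA": 0.0002})
    assert classify_stops(prof, ratio_threshold=0.1, floor=0.001) == {"TGA"}


def test_classify_blepharisma_pattern():
    prof = _profile_from_freqs({"TGA": 0.02, "TAA": 0.0001, "TAG": 0.0001})
    assert classify_stops(prof) == {"TAA", "TAG"}


def test_classify_monotone_in_frequency():
    """Raising one codon's in-frame frequency never adds it to the
    functional set."""
    grid = [0.0, 0.0005, 0.001, 0.003, 0.01, 0.02]
    for f_others in (0.0, 0.01):
        previous_member = True
        for f in grid:
            prof = _profile_from_freqs(
                {"TAA": f, "TAG": f_others, "TGA": f_others}
            )
            member = "TAA" in classify_stops(prof)
            assert member <= previous_member  # once out, never back in
            previous_member = member


def test_context_dependent_pattern():
    prof = _profile_from_freqs({"TAA": 0.008, "TAG": 0.007, "TGA": 0.009})
    assert no_stop_qualifies(prof)
    # classify_stops still returns the minimum-frequency codon
    assert classify_stops(prof) == {"TAG"}


# ---------------------------------------------------------------------------
# reassignment from conserved columns
# ---------------------------------------------------------------------------


def test_conserved_column_tallied_above_half():
    rows = {"q": "A#A", **{f"r{i}": "AQA" for i in range(6)},
            **{f"s{i}": "ALA" for i in range(4)}}
    aln = ReferenceAlignment(query_id="q", rows=rows)
    tally = tally_conserved_columns([aln])
    assert tally["TAG"] == {"Q": 1}  # 6/10 = 0.6 > 0.5


def test_column_at_exactly_half_not_tallied():
    rows = {"q": "A*A", **{f"r{i}": "AQA" for i in range(5)},
            **{f"s{i}": "ALA" for i in range(5)}}
    aln = ReferenceAlignment(query_id="q", rows=rows)
    tally = tally_conserved_columns([aln])
    assert tally["TAA"] == {}  # 5/10 is not strictly > 0.5


def test_reassignment_uncertain_below_min_sites_and_on_ties():
    rows = {"q": "#@", "r0": "QW", "r1": "QW", "r2": "QW"}
    aln = ReferenceAlignment(query_id="q", rows=rows)
    calls = infer_reassignments([aln], ["TAG", "TGA"], min_sites=10)
    assert all(c.amino_acid == "uncertain" for c in calls)
    calls = infer_reassignments([aln], ["TAG", "TGA"], min_sites=1)
    assert {c.codon: c.amino_acid for c in calls} == {"TAG": "Q", "TGA": "W"}
    # tie in the tally -> uncertain
    tie_rows = {"q": "##", "r0": "QK", "r1": "QK", "r2": "QK"}
    calls = infer_reassignments(
        [ReferenceAlignment(query_id="q", rows=tie_rows)], ["TAG"], min_sites=2
    )
    assert calls[0].amino_acid == "uncertain"
    assert calls[0].support == 2


def test_no_qualifying_columns_gives_support_zero():
    rows = {"q": "AAA", "r0": "AAA"}
    aln = ReferenceAlignment(query_id="q", rows=rows)
    calls = infer_reassignments([aln], ["TGA"])
    assert calls[0].support == 0
    assert calls[0].amino_acid == "uncertain"


# ---------------------------------------------------------------------------
# end-to-end code inference
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "code_name,seed",
    [("universal", 1), ("ciliate", 7), ("blepharisma", 11),
     ("condylostoma", 13)],
)
def test_infer_code_recovers_generating_code(code_name, seed):
    rate = 0.0 if code_name == "universal" else 0.02
    tr, truth = gen_transcriptome(
        TranscriptomeConfig(seed=seed, code_name=code_name,
                            reassigned_usage_rate=rate)
    )
    alns = gen_reference_alignments(truth, seed=seed)
    res = infer_code(tr, alns)
    code = get_code(code_name)
    assert res.code.name == code_name
    assert res.functional_stops == code.stops
    assert res.context_dependent == code.context_dependent
    inferred = {
        c.codon: c.amino_acid
        for c in res.reassignments
        if c.support >= CodeInferenceParams().min_sites
    }
    assert inferred == code.reassigned_stops
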