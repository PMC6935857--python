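"""Stop-codon usage and genetic-code inference from transcriptomes.

Ciliates repeatedly reassign canonical stop codons (UAA/UAG/UGA, written
here in DNA as TAA/TAG/TGA) to sense codons.  This module infers, for a
transcriptome, (i) which canonical stops still terminate translation and
(ii) the amino acid each reassigned stop encodes, using two signals:

* *forced translation*: the longest open reading frame when each canonical
  stop in turn is treated as the only stop codon; reassigned stops then show
  up in-frame at roughly coding density, whereas true stops are rare in
  frame;
* *conserved alignment columns*: where the query carries an in-frame stop,
  the modal amino acid among reference sequences (when conserved across
  >50% of the column) votes for the reassigned identity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from .transcripts import COMPLEMENT, Transcript

CANONICAL_STOPS = ("TAA", "TAG", "TGA")

#: in forced translations each canonical stop is rendered as its own marker
STOP_MARKERS = {"TAA": "*", "TAG": "#", "TGA": "@"}
MARKER_TO_CODON = {v: k for k, v in STOP_MARKERS.items()}

NUCS = "TCAG"
ALL_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]


def _standard_table() -> dict[str, str]:
    table = dict(_STANDARD.forward_table)
    for stop in _STANDARD.stop_codons:
        table[stop] = "*"
    return {c: table[c] for c in ALL_CODONS}


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table.

    ``table`` maps every DNA codon to a one-letter amino acid or ``*`` for
    STOP.  ``context_dependent`` marks codes (Condylostoma-like) in which all
    three canonical stops are reassigned and termination depends on mRNA
    context; such codes may have no ``*`` entry.
    """

    name: str
    table: Mapping[str, str]
    context_dependent: bool = False

    def __post_init__(self) -> None:
        if set(self.table) != set(ALL_CODONS):
            raise ValueError("genetic code table must cover all 64 codons")
        if not self.context_dependent and "*" not in self.table.values():
            raise ValueError(
                f"code {self.name!r} has no stop codon and is not flagged "
                "context_dependent"
            )

    @property
    def stops(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa == "*")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.table[c] != "*")

    @property
    def reassigned_stops(self) -> dict[str, str]:
        """Canonical stops translated as amino acids under this code."""
        return {
            c: self.table[c]
            for c in CANONICAL_STOPS
            if self.table[c] != "*"
        }

    def translate(self, codon: str) -> str:
        return self.table[codon]

    def is_synonymous(self, a: str, b: str) -> bool:
        return self.table[a] == self.table[b]


def _make_code(
    name: str, reassign: dict[str, str], context_dependent: bool = False
) -> GeneticCode:
    table = _standard_table()
    table.update(reassign)
    return GeneticCode(name, table, context_dependent)


#: Named genetic codes observed across the ciliate phylogeny.
PRESET_CODES: dict[str, GeneticCode] = {
    "universal": _make_code("universal", {}),
    "ciliate": _make_code("ciliate", {"TAA": "Q", "TAG": "Q"}),
    "blepharisma": _make_code("blepharisma", {"TGA": "W"}),
    "euplotes": _make_code("euplotes", {"TGA": "C"}),
    "chilodonella": _make_code("chilodonella", {"TAG": "Q", "TGA": "Q"}),
    "mesodinium": _make_code("mesodinium", {"TAA": "Y", "TAG": "Y"}),
    "vorticella": _make_code("vorticella", {"TAA": "E", "TAG": "E"}),
    "condylostoma": _make_code(
        "condylostoma",
        {"TAA": "Q", "TAG": "Q", "TGA": "W"},
        context_dependent=True,
    ),
}


def get_code(name: str) -> GeneticCode:
    try:
        return PRESET_CODES[name]
    except KeyError:
        raise KeyError(
            f"unknown genetic code {name!r}; available: "
            f"{sorted(PRESET_CODES)}"
        ) from None


# ---------------------------------------------------------------------------
# forced ORFs and the stop-usage profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForcedOrf:
    """Longest stop-free codon run over all six reading frames.

    ``frame`` is 0-2 on the forward strand and 3-5 on the reverse
    complement; ``start``/``end`` are 0-based half-open nucleotide
    coordinates on the reported strand.
    """

    frame: int
    start: int
    end: int
    codons: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.codons)


def _frame_codons(seq: str, frame: int) -> list[str]:
    strand = seq if frame < 3 else seq.translate(COMPLEMENT)[::-1]
    offset = frame % 3
    return [strand[i : i + 3] for i in range(offset, len(strand) - 2, 3)]


def _longest_run(seq: str, frame: int, stop_set: set[str]) -> ForcedOrf:
    codons = _frame_codons(seq, frame)
    offset = frame % 3
    best = ForcedOrf(frame, offset, offset, ())
    run_start = 0
    n = len(codons)
    for i in range(n + 1):
        if i == n or codons[i] in stop_set:
            if i - run_start > len(best):
                best = ForcedOrf(
                    frame,
                    offset + 3 * run_start,
                    offset + 3 * i,
                    tuple(codons[run_start:i]),
                )
            run_start = i + 1
    return best


def forced_orf(
    seq: str, stop_set: Iterable[str], frames: Sequence[int] = range(6)
) -> ForcedOrf:
    """Longest run of codons free of ``stop_set``, over all 6 frames
    (or the given subset).

    Ties are broken by (frame index ascending, start ascending).  A
    sequence shorter than 3 nt yields an empty ORF.
    """
    stop_set = set(stop_set)
    if not stop_set or not stop_set <= set(CANONICAL_STOPS):
        raise ValueError(
            f"stop_set must be a non-empty subset of {CANONICAL_STOPS}"
        )
    seq = seq.upper()
    best = None
    for frame in frames:
        cand = _longest_run(seq, frame, stop_set)
        if best is None or len(cand) > len(best):
            best = cand
    return best


@dataclass
class SchemeCounts:
    """Tallies for one forced-stop scheme (one codon treated as sole stop)."""

    forced_stop: str
    codons_scanned: int = 0
    n_orfs: int = 0
    in_frame_counts: dict[str, int] = field(default_factory=dict)

    def frequencies(self) -> dict[str, float]:
        if self.codons_scanned == 0:
            return {c: 0.0 for c in self.in_frame_counts}
        return {
            c: n / self.codons_scanned
            for c, n in self.in_frame_counts.items()
        }


@dataclass
class StopUsageProfile:
    """Per-scheme in-frame frequencies of the non-forced canonical stops."""

    schemes: dict[str, SchemeCounts]

    def pooled_frequency(self, codon: str) -> float:
        """In-frame frequency of ``codon`` pooled over the schemes where it
        is not the forced stop."""
        count = 0
        scanned = 0
        for s, sc in self.schemes.items():
            if s == codon:
                continue
            count += sc.in_frame_counts.get(codon, 0)
            scanned += sc.codons_scanned
        return count / scanned if scanned else 0.0

    def pooled_frequencies(self) -> dict[str, float]:
        return {c: self.pooled_frequency(c) for c in CANONICAL_STOPS}

    def to_dict(self) -> dict:
        return {
            "schemes": {
                s: {
                    "codons_scanned": sc.codons_scanned,
                    "n_orfs": sc.n_orfs,
                    "in_frame_counts": dict(sc.in_frame_counts),
                    "in_frame_frequencies": sc.frequencies(),
                }
                for s, sc in self.schemes.items()
            },
            "pooled_frequencies": self.pooled_frequencies(),
        }


def stop_usage_profile(
    transcripts: Sequence[Transcript],
    min_orf_codons: int = 30,
    anchor_frame: bool = True,
    orf_tail_trim: int = 25,
) -> StopUsageProfile:
    """Force-translate every transcript under each of the three schemes and
    count the other two canonical stops appearing in frame.

    With ``anchor_frame`` (default) the transcript's reading frame is fixed
    before counting: candidate frames are those whose longest forced ORF
    (over the three schemes) comes within 10% of the overall longest, and
    among candidates the frame with the longest *worst-scheme* run wins.
    The scheme matching the true code leaves the coding frame unbroken, so
    the coding frame is always a candidate; the worst-scheme tie-break
    rejects the occasional wrong frame that happens to lack one particular
    stop codon over the whole transcript, because such frames are still
    interrupted by random stops under the other schemes.  Per-scheme runs
    are then taken within the anchored frame.  Without anchoring, each
    scheme independently picks its longest run over all six frames, which
    lets wrong-strand runs pollute the counts whenever the forced stop is a
    reassigned (hence frequent) codon.

    Frequencies are per codon scanned, summed over forced ORFs of at least
    ``min_orf_codons`` codons.  Stops are tallied only in the ORF interior,
    ignoring the last ``orf_tail_trim`` codons of each run: when a forced
    stop differs from the true one, the run sweeps past the real
    termination codon into the 3'UTR, and trimming the tail keeps that
    termination region out of the usage estimate (the denominator remains
    the full run length).  A scheme under which no ORF passes the length
    filter raises an error naming the scheme.
    """
    if not transcripts:
        raise ValueError("no transcripts given")
    frames: dict[str, Sequence[int]] = {}
    for t in transcripts:
        if anchor_frame:
            seq = t.seq.upper()
            runs = np.array(
                [
                    [
                        len(_longest_run(seq, frame, {s}))
                        for s in CANONICAL_STOPS
                    ]
                    for frame in range(6)
                ]
            )
            frame_max = runs.max(axis=1)
            frame_min = runs.min(axis=1)
            cutoff = 0.9 * frame_max.max()
            best = max(
                (f for f in range(6) if frame_max[f] >= cutoff),
                key=lambda f: (frame_min[f], frame_max[f], -f),
            )
            frames[t.id] = (int(best),)
        else:
            frames[t.id] = range(6)
    schemes = {}
    for forced in CANONICAL_STOPS:
        others = [c for c in CANONICAL_STOPS if c != forced]
        sc = SchemeCounts(
            forced_stop=forced, in_frame_counts={c: 0 for c in others}
        )
        for t in transcripts:
            orf = forced_orf(t.seq, {forced}, frames=frames[t.id])
            if len(orf) < min_orf_codons:
                continue
            sc.n_orfs += 1
            sc.codons_scanned += len(orf)
            interior = (
                orf.codons[: -orf_tail_trim]
                if orf_tail_trim > 0
                else orf.codons
            )
            for codon in interior:
                if codon in sc.in_frame_counts:
                    sc.in_frame_counts[codon] += 1
        if sc.n_orfs == 0:
            raise ValueError(
                f"no forced ORF of >= {min_orf_codons} codons under the "
                f"{forced}-only scheme"
            )
        schemes[forced] = sc
    return StopUsageProfile(schemes)


# ---------------------------------------------------------------------------
# classification of functional stops
# ---------------------------------------------------------------------------


def classify_stops(
    profile: StopUsageProfile,
    ratio_threshold: float = 0.3,
    floor: float = 0.002,
) -> frozenset[str]:
    """Canonical stops with substantially lower in-frame frequency.

    A codon is functional iff its pooled in-frame frequency is <= ``floor``
    or <= ``ratio_threshold`` times the maximum frequency among the three.
    If all three fall at or below the floor the universal code is implied
    and all three are returned; if none qualifies, the minimum-frequency
    codon is returned (the context-dependent pattern is flagged separately
    by :func:`infer_code`).
    """
    freqs = profile.pooled_frequencies()
    fmax = max(freqs.values())
    functional = frozenset(
        c
        for c, f in freqs.items()
        if f <= floor or f <= ratio_threshold * fmax
    )
    if all(f <= floor for f in freqs.values()):
        return frozenset(CANONICAL_STOPS)
    if not functional:
        cmin = min(CANONICAL_STOPS, key=lambda c: (freqs[c], c))
        return frozenset({cmin})
    return functional


def no_stop_qualifies(
    profile: StopUsageProfile,
    ratio_threshold: float = 0.3,
    floor: float = 0.002,
) -> bool:
    """True when every canonical stop is used in frame at substantial
    frequency — the all-reassigned, context-dependent-termination pattern."""
    freqs = profile.pooled_frequencies()
    fmax = max(freqs.values())
    return all(
        f > floor and f > ratio_threshold * fmax for f in freqs.values()
    )


# ---------------------------------------------------------------------------
# reassignment from conserved alignment columns
# ---------------------------------------------------------------------------


def forced_translation(
    codons: Sequence[str], code: GeneticCode | None = None
) -> str:
    """Translate a forced ORF, rendering canonical stops as markers.

    TAA, TAG and TGA become ``*``, ``#`` and ``@`` respectively so the
    codon identity behind each in-frame stop survives into the protein
    alignment.  Other codons translate under the standard code (codons with
    N translate to X).
    """
    table = (code or PRESET_CODES["universal"]).table
    out = []
    for codon in codons:
        if codon in STOP_MARKERS:
            out.append(STOP_MARKERS[codon])
        elif "N" in codon:
            out.append("X")
        else:
            aa = table[codon]
            out.append("X" if aa == "*" else aa)
    return "".join(out)


@dataclass(frozen=True)
class ReferenceAlignment:
    """An amino-acid alignment pairing one forced-translated query row
    (stop markers included) with reference sequences."""

    query_id: str
    rows: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.query_id not in self.rows:
            raise ValueError(f"query row {self.query_id!r} missing")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")


@dataclass
class ReassignmentCall:
    """Inferred amino-acid identity of a reassigned stop codon."""

    codon: str
    amino_acid: str
    support: int
    tally: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "codon": self.codon,
            "amino_acid": self.amino_acid,
            "support": self.support,
            "tally": dict(self.tally),
        }


def tally_conserved_columns(
    alignments: Sequence[ReferenceAlignment],
    conservation_min: float = 0.5,
) -> dict[str, dict[str, int]]:
    """Vote counts per stop codon from conserved alignment columns.

    For every column where the query carries a stop marker and the modal
    reference amino acid (non-gap, query excluded) strictly exceeds
    ``conservation_min`` of the non-gap reference residues, the modal
    residue is tallied under that stop codon.
    """
    tallies: dict[str, dict[str, int]] = {c: {} for c in CANONICAL_STOPS}
    for aln in alignments:
        query = aln.rows[aln.query_id]
        refs = [s for rid, s in aln.rows.items() if rid != aln.query_id]
        for col, qchar in enumerate(query):
            if qchar not in MARKER_TO_CODON:
                continue
            residues = [
                s[col] for s in refs if s[col] not in "-.*#@X"
            ]
            if not residues:
                continue
            counts: dict[str, int] = {}
            for r in residues:
                counts[r] = counts.get(r, 0) + 1
            modal = max(sorted(counts), key=counts.get)
            if counts[modal] / len(residues) > conservation_min:
                codon = MARKER_TO_CODON[qchar]
                tallies[codon][modal] = tallies[codon].get(modal, 0) + 1
    return tallies


def infer_reassignments(
    alignments: Sequence[ReferenceAlignment],
    non_functional_stops: Iterable[str],
    conservation_min: float = 0.5,
    min_sites: int = 10,
) -> list[ReassignmentCall]:
    """One :class:`ReassignmentCall` per non-functional canonical stop.

    The call is the argmax of the conserved-column tally when the total
    support reaches ``min_sites`` and the argmax is unique; otherwise
    ``"uncertain"``.
    """
    tallies = tally_conserved_columns(alignments, conservation_min)
    calls = []
    for codon in CANONICAL_STOPS:
        if codon not in set(non_functional_stops):
            continue
        tally = tallies[codon]
        support = sum(tally.values())
        if support >= min_sites:
            best = max(tally.values())
            winners = [aa for aa, n in tally.items() if n == best]
            amino_acid = winners[0] if len(winners) == 1 else "uncertain"
        else:
            amino_acid = "uncertain"
        calls.append(ReassignmentCall(codon, amino_acid, support, tally))
    return calls


# ---------------------------------------------------------------------------
# end-to-end code inference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodeInferenceParams:
    min_orf_codons: int = 30
    ratio_threshold: float = 0.3
    floor: float = 0.002
    conservation_min: float = 0.5
    min_sites: int = 10


@dataclass
class InferredCode:
    code: GeneticCode
    functional_stops: frozenset[str]
    context_dependent: bool
    profile: StopUsageProfile
    reassignments: list[ReassignmentCall]

    def to_dict(self) -> dict:
        return {
            "code_name": self.code.name,
            "functional_stops": sorted(self.functional_stops),
            "context_dependent": self.context_dependent,
            "profile": self.profile.to_dict(),
            "reassignments": [r.to_dict() for r in self.reassignments],
        }


def _match_preset(
    functional: frozenset[str],
    reassign: dict[str, str],
    context_dependent: bool,
) -> Optional[GeneticCode]:
    for code in PRESET_CODES.values():
        if code.context_dependent != context_dependent:
            continue
        if not context_dependent and code.stops != functional:
            continue
        if code.reassigned_stops == reassign:
            return code
    return None


def infer_code(
    transcripts: Sequence[Transcript],
    reference_alignments: Sequence[ReferenceAlignment],
    params: CodeInferenceParams = CodeInferenceParams(),
) -> InferredCode:
    """Compose profile -> stop classification -> reassignment inference.

    Returns a named preset code when the inferred pattern matches one,
    otherwise a custom table.  When no codon passes the functional-stop
    criterion the result is flagged context-dependent (all three stops
    reassigned)."""
    profile = stop_usage_profile(transcripts, params.min_orf_codons)
    context_dependent = no_stop_qualifies(
        profile, params.ratio_threshold, params.floor
    )
    functional = (
        frozenset()
        if context_dependent
        else classify_stops(profile, params.ratio_threshold, params.floor)
    )
    non_functional = [
        c for c in CANONICAL_STOPS if c not in functional
    ]
    calls = infer_reassignments(
        reference_alignments,
        non_functional,
        params.conservation_min,
        params.min_sites,
    )
    reassign = {
        c.codon: c.amino_acid
        for c in calls
        if c.amino_acid != "uncertain"
    }
    code = _match_preset(functional, reassign, context_dependent)
    if code is None:
        table = _standard_table()
        for c in CANONICAL_STOPS:
            if c in functional:
                table[c] = "*"
            else:
                table[c] = reassign.get(c, "X")
        code = GeneticCode("custom", table, context_dependent)
    return InferredCode(
        code=code,
        functional_stops=functional,
        context_dependent=context_dependent,
        profile=profile,
        reassignments=calls,
    )
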