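"""Redundancy removal among single-cell transcripts of one species.

Single-cell transcriptomes of the same species contain pools of alleles,
very recent paralogs and assembly fragments.  Before counting transcript
diversity, transcripts that are near-identical (by default >98% nucleotide
identity) to a longer transcript over most of their own length (by default
>=70%) are collapsed onto that longer transcript.  When several cells of the
same species were sequenced, their transcriptomes are merged by pooling and
applying the same rule.

Identity is computed over the aligned non-gap columns of a local alignment
of the shorter sequence against the longer; coverage is the aligned span of
the shorter divided by its full length.  Both strands are compared because
single-cell transcripts are unstranded, and N bases never count as matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from .transcripts import Transcript


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the redundancy rule.

    identity_min : a transcript is redundant only if identity strictly
        exceeds this fraction (default 0.98).
    coverage_min : the aligned span must cover at least this fraction of the
        shorter sequence (default 0.70).
    both_strands : also compare the reverse complement (default True).
    """

    identity_min: float = 0.98
    coverage_min: float = 0.70
    both_strands: bool = True

    def __post_init__(self) -> None:
        for name in ("identity_min", "coverage_min"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -2.0
    a.extend_gap_score = -0.5
    return a


def local_identity_coverage(
    shorter: str, longer: str, aligner: Align.PairwiseAligner | None = None
) -> tuple[float, float]:
    """Best local alignment of ``shorter`` against ``longer``.

    Returns
    -------
    (identity, coverage) where identity = matches / aligned non-gap columns
    (N never matches) and coverage = aligned span on the shorter sequence /
    its length.  (0, 0) if no alignment is found.
    """
    if aligner is None:
        aligner = _aligner()
    alns = aligner.align(longer, shorter)
    # never call len(alns): low-complexity runs (poly-A tails) can have an
    # astronomically large number of co-optimal alignments
    try:
        aln = alns[0]
    except IndexError:  # pragma: no cover - local alignments always exist
        return 0.0, 0.0
    blocks_long, blocks_short = aln.aligned
    matches = 0
    columns = 0
    for (ls, le), (ss, se) in zip(blocks_long, blocks_short):
        columns += le - ls
        for cl, cs in zip(longer[ls:le], shorter[ss:se]):
            if cl == cs and cl != "N":
                matches += 1
    if columns == 0:
        return 0.0, 0.0
    span = blocks_short[-1][1] - blocks_short[0][0]
    identity = matches / columns
    coverage = span / len(shorter)
    return identity, coverage


def is_redundant(
    shorter: Transcript,
    longer: Transcript,
    params: FilterParams,
    aligner: Align.PairwiseAligner | None = None,
) -> bool:
    """True if ``shorter`` collapses onto the larger transcript.

    "Larger" follows the (length desc, id asc) order, so an identical-length
    transcript with an earlier id also counts as larger (this is what makes
    exact duplicates collapse to one copy).
    """
    if (len(longer), shorter.id) < (len(shorter), longer.id):
        return False
    ident, cov = local_identity_coverage(shorter.seq, longer.seq, aligner)
    if ident > params.identity_min and cov >= params.coverage_min:
        return True
    if params.both_strands:
        ident, cov = local_identity_coverage(
            shorter.revcomp(), longer.seq, aligner
        )
        if ident > params.identity_min and cov >= params.coverage_min:
            return True
    return False


def collapse_redundant(
    transcripts: Sequence[Transcript],
    params: FilterParams = FilterParams(),
) -> list[Transcript]:
    """Remove transcripts redundant with a longer retained transcript.

    Transcripts are considered longest-first (ties broken by id, the
    earlier transcript counting as the larger); each candidate is removed
    iff some larger *retained* transcript matches it above the
    identity/coverage thresholds.  Output preserves input order.  All
    transcripts must share one taxon.
    """
    transcripts = list(transcripts)
    if not transcripts:
        return []
    taxa = {t.taxon for t in transcripts}
    if len(taxa) > 1:
        raise ValueError(f"mixed taxa in input: {sorted(taxa)}")

    aligner = _aligner()
    order = sorted(transcripts, key=lambda t: (-len(t), t.id))
    retained: list[Transcript] = []
    retained_ids: set[str] = set()
    for cand in order:
        if any(
            is_redundant(cand, keeper, params, aligner) for keeper in retained
        ):
            continue
        retained.append(cand)
        retained_ids.add(cand.id)
    return [t for t in transcripts if t.id in retained_ids]


def merge_cells(
    transcript_sets: Sequence[Sequence[Transcript]],
    params: FilterParams = FilterParams(),
) -> list[Transcript]:
    """Pool per-cell transcript sets of one species and collapse redundancy.

    Equivalent to :func:`collapse_redundant` on the concatenation.
    """
    pooled = [t for ts in transcript_sets for t in ts]
    return collapse_redundant(pooled, params)
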