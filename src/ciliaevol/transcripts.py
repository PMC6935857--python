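"""Transcript records and their FASTA/TSV I/O.

A :class:`Transcript` is the unit that gets filtered for redundancy,
force-translated for genetic-code inference, and counted into gene-family
(GF) matrices.  Annotations (taxon, gene family, cell of origin) travel in a
sidecar TSV because FASTA headers in the wild are not reliable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_NT = set("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Transcript:
    """An annotated nucleotide transcript.

    Parameters
    ----------
    id : unique identifier within a dataset.
    seq : nucleotide sequence over {A, C, G, T, N} (uppercased on access).
    taxon : species label.
    gf : optional gene-family identifier.
    cell : optional cell-of-origin label.
    """

    id: str
    seq: str
    taxon: str
    gf: Optional[str] = None
    cell: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.seq.upper()) - _VALID_NT
        if bad:
            raise ValueError(
                f"transcript {self.id!r}: invalid characters {sorted(bad)}"
            )
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)

    def revcomp(self) -> str:
        return self.seq.translate(COMPLEMENT)[::-1]


def check_unique_ids(transcripts: Iterable[Transcript]) -> None:
    seen = set()
    for t in transcripts:
        if t.id in seen:
            raise ValueError(f"duplicate transcript id {t.id!r}")
        seen.add(t.id)


def read_transcripts(
    fasta_path: str | Path,
    annotations: str | Path | pd.DataFrame | None = None,
    default_taxon: str | None = None,
) -> list[Transcript]:
    """Read transcripts from FASTA plus an optional annotation table.

    The annotation table (TSV path or DataFrame) must have an ``id`` column
    and may carry ``taxon``, ``gf`` and ``cell`` columns.  Records without a
    taxon fall back to ``default_taxon``.
    """
    ann: dict[str, dict] = {}
    if annotations is not None:
        df = (
            annotations
            if isinstance(annotations, pd.DataFrame)
            else pd.read_csv(annotations, sep="\t", dtype=str)
        )
        if "id" not in df.columns:
            raise ValueError("annotation table needs an 'id' column")
        ann = df.set_index("id").to_dict("index")

    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        a = ann.get(rec.id, {})
        taxon = a.get("taxon") or default_taxon
        if taxon is None or (isinstance(taxon, float)):
            raise ValueError(f"no taxon for transcript {rec.id!r}")

        def _clean(v):
            return None if v is None or pd.isna(v) else str(v)

        out.append(
            Transcript(
                id=rec.id,
                seq=str(rec.seq),
                taxon=str(taxon),
                gf=_clean(a.get("gf")),
                cell=_clean(a.get("cell")),
            )
        )
    check_unique_ids(out)
    return out


def write_transcripts(
    transcripts: Iterable[Transcript],
    fasta_path: str | Path,
    annotations_path: str | Path | None = None,
) -> None:
    transcripts = list(transcripts)
    records = [
        SeqRecord(Seq(t.seq), id=t.id, description="") for t in transcripts
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if annotations_path is not None:
        pd.DataFrame(
            {
                "id": [t.id for t in transcripts],
                "taxon": [t.taxon for t in transcripts],
                "gf": [t.gf for t in transcripts],
                "cell": [t.cell for t in transcripts],
            }
        ).to_csv(annotations_path, sep="\t", index=False)
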