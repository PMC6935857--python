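"""Transcript-diversity statistics over gene families (GFs).

The substrate is a species x GF matrix of unique-transcript counts; species
belong to one of four focal groups — Karyorelictea (K), Heterotrichea (H),
extensive fragmenters (EF) and non-extensive fragmenters (NEF) — and the
questions are how many paralogs each group keeps per gene family and how
variable that number is.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .transcripts import Transcript

GROUPS = ("K", "H", "EF", "NEF")


@dataclass
class GFCountMatrix:
    """Species x gene-family transcript counts (non-negative integers)."""

    counts: pd.DataFrame  # index: species, columns: GF ids

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype(int)

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def gfs(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GFCountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (species, group) -> dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    return dict(zip(df[cols[0]], df[cols[1]]))


def _group_species(
    m: GFCountMatrix, groups: Mapping[str, str], group: str
) -> list[str]:
    missing = [s for s in m.species if s not in groups]
    if missing:
        raise ValueError(f"species without group assignment: {missing}")
    members = [s for s in m.species if groups[s] == group]
    if not members:
        raise ValueError(f"group {group!r} has no species in the matrix")
    return members


def build_count_matrix(
    transcripts: Sequence[Transcript],
    gf_universe: Sequence[str],
    species: Sequence[str] | None = None,
) -> GFCountMatrix:
    """Count transcripts per (species, GF) over a fixed GF universe.

    Transcripts annotated to GFs outside the universe are ignored; absent
    combinations count 0.  ``species`` fixes the row universe (defaults to
    the species seen among the transcripts); a transcript of a species
    outside an explicit row universe is an error.
    """
    if not gf_universe:
        raise ValueError("gf_universe must be non-empty")
    gf_set = set(gf_universe)
    if species is None:
        seen: list[str] = []
        for t in transcripts:
            if t.taxon not in seen:
                seen.append(t.taxon)
        species = seen
    species_set = set(species)
    counts = pd.DataFrame(
        0, index=list(species), columns=list(gf_universe), dtype=int
    )
    for t in transcripts:
        if t.taxon not in species_set:
            raise ValueError(f"transcript {t.id!r} has unknown taxon {t.taxon!r}")
        if t.gf in gf_set:
            counts.loc[t.taxon, t.gf] += 1
    return GFCountMatrix(counts)


def group_mean_diversity(
    m: GFCountMatrix,
    groups: Mapping[str, str],
    include_zeros: bool = True,
) -> dict[str, float]:
    """Mean transcript count per GF per species, by group.

    With ``include_zeros`` the mean runs over every (species, GF) cell of
    the group; without, only over cells with at least one transcript (NaN if
    the group has no non-zero cell).
    """
    out = {}
    for group in sorted(set(groups.values())):
        members = _group_species(m, groups, group)
        cells = m.counts.loc[members].values.ravel().astype(float)
        if not include_zeros:
            cells = cells[cells >= 1]
        out[group] = float(np.mean(cells)) if cells.size else float("nan")
    return out


def per_gf_group_average(
    m: GFCountMatrix, groups: Mapping[str, str], group: str
) -> pd.Series:
    """Per-GF mean count across the group's species (zeros included)."""
    members = _group_species(m, groups, group)
    return m.counts.loc[members].mean(axis=0)


def dispersion_ratio(values: Sequence[float]) -> float:
    """Interquartile range over median, with type-7 (linear interpolation)
    quantiles.  Errors on a zero median."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    if med == 0:
        raise ValueError("median is zero; IQR/median undefined")
    return float((q3 - q1) / med)


def single_transcript_gf_fraction(
    m: GFCountMatrix,
    groups: Mapping[str, str],
    group: str,
    strict: bool = False,
) -> float:
    """Fraction of GFs where the group never exceeds one transcript.

    Default mode counts a GF when the group's maximum count is <= 1 (a
    species may lack the GF); ``strict`` requires every species of the
    group to have exactly one transcript.
    """
    members = _group_species(m, groups, group)
    sub = m.counts.loc[members]
    if strict:
        hits = (sub == 1).all(axis=0)
    else:
        hits = sub.max(axis=0) <= 1
    return float(hits.sum() / sub.shape[1])


def group_samples(
    m: GFCountMatrix,
    groups: Mapping[str, str],
    include_zeros: bool = True,
    per_gf_average: bool = False,
) -> dict[str, np.ndarray]:
    """Per-group samples fed to the rank tests.

    Default: per-(species, GF) cell values, zeros included (the headline
    analysis).  ``per_gf_average`` switches to per-GF group means.
    """
    out = {}
    for group in sorted(set(groups.values())):
        if per_gf_average:
            vals = per_gf_group_average(m, groups, group).values
        else:
            members = _group_species(m, groups, group)
            vals = m.counts.loc[members].values.ravel().astype(float)
            if not include_zeros:
                vals = vals[vals >= 1]
        out[group] = np.asarray(vals, dtype=float)
    return out


@dataclass
class GroupComparison:
    kruskal_statistic: float
    kruskal_p: float
    pairwise: dict[tuple[str, str], tuple[float, float]]  # (U, p)

    def to_dict(self) -> dict:
        return {
            "kruskal_statistic": self.kruskal_statistic,
            "kruskal_p": self.kruskal_p,
            "pairwise": {
                f"{a}_vs_{b}": {"U": u, "p": p}
                for (a, b), (u, p) in self.pairwise.items()
            },
        }


def group_comparison_tests(
    samples: Mapping[str, Sequence[float]]
) -> GroupComparison:
    """Kruskal-Wallis across all groups plus pairwise two-sided
    Mann-Whitney tests (tie-corrected)."""
    names = sorted(samples)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(samples[g], dtype=float) for g in names}
    for g, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    if len(names) > 2:
        kw = stats.kruskal(*[arrays[g] for g in names])
        kstat, kp = float(kw.statistic), float(kw.pvalue)
    else:
        kstat, kp = float("nan"), float("nan")
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = stats.mannwhitneyu(
                arrays[a], arrays[b], alternative="two-sided"
            )
            pairwise[(a, b)] = (float(res.statistic), float(res.pvalue))
    return GroupComparison(kstat, kp, pairwise)
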