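"""Tests for association between regulatory sequence motifs and codon
optimality.

Genes carrying a given promoter/UTR motif (significant instance count >= 1
within a fixed background gene set) are compared with genes lacking it by
a one-sided Wilcoxon rank-sum test on a per-gene optimality score (tAI_g
or percent-optimal content), with Bonferroni correction over the motif
family.  Near-identical motif variants (e.g. TATTTAT / TATTTA / ATTTAT)
are merged into one group by summing instance counts per gene before
testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MotifAnnotation:
    """Significant instance counts of one motif across the background genes."""

    motif_id: str
    location: Literal["promoter", "5'UTR", "3'UTR"]
    rate_association: Literal["long half-life", "short half-life", "fast synthesis"]
    gene_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = {g: n for g, n in self.gene_counts.items() if n < 0}
        if bad:
            raise ValueError(f"{self.motif_id}: negative instance counts {bad}")

    def carriers(self, background: Iterable[str]) -> set[str]:
        return {g for g in background if self.gene_counts.get(g, 0) >= 1}


@dataclass
class MotifTestResult:
    motif_id: str
    direction: Literal["greater", "less"]
    statistic: float
    p_raw: float
    p_bonferroni: float
    n_with: int
    n_without: int


def group_motif_variants(
    annotations: Sequence[MotifAnnotation],
    groups: Mapping[str, Sequence[str]],
) -> list[MotifAnnotation]:
    """Merge motif variants into named groups by summing per-gene counts.

    Group members must share a location; members are removed from the
    returned list and replaced by the grouped annotation (which keeps the
    members' shared location and rate association).
    """
    by_id = {a.motif_id: a for a in annotations}
    grouped_members: set[str] = set()
    out: list[MotifAnnotation] = []
    for group_id, members in groups.items():
        missing = [m for m in members if m not in by_id]
        if missing:
            raise ValueError(f"group {group_id}: unknown motif(s) {missing}")
        locs = {by_id[m].location for m in members}
        if len(locs) > 1:
            raise ValueError(
                f"group {group_id}: members span locations {sorted(locs)}"
            )
        counts: dict[str, int] = {}
        for m in members:
            for g, n in by_id[m].gene_counts.items():
                counts[g] = counts.get(g, 0) + n
        first = by_id[members[0]]
        out.append(
            MotifAnnotation(
                motif_id=group_id,
                location=first.location,
                rate_association=first.rate_association,
                gene_counts=counts,
            )
        )
        grouped_members.update(members)
    out.extend(a for a in annotations if a.motif_id not in grouped_members)
    return out


def motif_wilcoxon(
    scores: pd.Series,
    annotation: MotifAnnotation,
    direction: Literal["greater", "less"],
    background: Iterable[str] | None = None,
    method: Literal["asymptotic", "exact"] = "asymptotic",
) -> MotifTestResult:
    """One-sided Wilcoxon rank-sum test of motif-bearing vs motif-free genes.

    ``direction="greater"`` tests the alternative that motif-bearing genes
    have greater scores.  Average ranks for ties, normal approximation
    with tie correction, continuity correction applied; ``method="exact"``
    switches to the exact null distribution (small, tie-free samples).
    The returned ``p_bonferroni`` is left equal to ``p_raw``; family-wise
    correction is applied afterwards with :func:`bonferroni`.
    """
    scores = scores.dropna()
    bg = set(background) if background is not None else set(scores.index)
    bg &= set(scores.index)
    with_ids = annotation.carriers(bg)
    without_ids = bg - with_ids
    if not with_ids or not without_ids:
        raise ValueError(
            f"motif {annotation.motif_id}: empty group "
            f"(n_with={len(with_ids)}, n_without={len(without_ids)})"
        )
    x = scores.loc[sorted(with_ids)].to_numpy(dtype=float)
    y = scores.loc[sorted(without_ids)].to_numpy(dtype=float)
    stat, p = stats.mannwhitneyu(
        x, y, alternative=direction, method=method, use_continuity=True
    )
    return MotifTestResult(
        motif_id=annotation.motif_id,
        direction=direction,
        statistic=float(stat),
        p_raw=float(p),
        p_bonferroni=float(p),
        n_with=len(x),
        n_without=len(y),
    )


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Multiply each p by the family size m (default: number of tests),
    capping at 1."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError(f"family size m={m} smaller than number of tests {len(p)}")
    return np.minimum(1.0, p * m)


def motif_test_table(
    score_sets: Mapping[str, pd.Series],
    annotations: Sequence[MotifAnnotation],
    background: Iterable[str],
    m: int | None = None,
) -> pd.DataFrame:
    """Run greater/less tests for every motif under every score metric.

    Returns a table in the layout of the published motif summary: one row
    per motif, Bonferroni-corrected greater/less p-value columns per score
    metric.  The family size ``m`` defaults to (number of motifs) x 2
    directions, applied within each score metric.
    """
    background = set(background)
    rows = []
    for ann in annotations:
        row: dict[str, object] = {
            "motif": ann.motif_id,
            "location": ann.location,
            "rate": ann.rate_association,
        }
        rows.append(row)
    family = m if m is not None else 2 * len(annotations)
    for metric, scores in score_sets.items():
        for direction in ("greater", "less"):
            raws = [
                motif_wilcoxon(scores, ann, direction, background).p_raw
                for ann in annotations
            ]
            corrected = bonferroni(raws, family)
            for row, p in zip(rows, corrected):
                row[f"{metric}_{direction}"] = p
    return pd.DataFrame(rows).set_index("motif")
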