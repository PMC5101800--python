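"""Codon optimality metrics: tAI adaptiveness weights, gene-level tAI_g,
percent-optimal content, and binary cTE/nTE classifications.

The tRNA adaptation index assigns each sense codon *i* an absolute weight

    W_i = sum_j (1 - s_{class(i,j)}) * tGCN_j

over the anticodons *j* that can decode it, where tGCN_j is the genomic
copy number of the tRNA carrying anticodon *j* (a proxy for its cellular
concentration) and s is a pairing-class penalty: 0 for Watson-Crick
pairing and a value in (0,1] for each wobble class.  Relative weights are
w_i = W_i / max_k W_k; codons left with W_i = 0 (no decoding tRNA gene)
receive the geometric mean of the nonzero w values.  A gene's tAI_g is the
geometric mean of w over its codons with multiplicity.

Binary optimal/non-optimal classifications (cTE: tAI-ranked translation
efficiency; nTE: the same supply weight normalised by abundance-weighted
codon demand) are treated as inputs loaded from file; a demand-normalised
nTE weight construction is provided as a convenience.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .codon_core import BASES, SENSE_CODONS, CodonProfile

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: wobble pairing-class penalties of the standard tAI parameterisation:
#: selective constraints s for G:U, I:C, I:A, U:G pairs and the
#: lysidine-modified C:A pair used by bacterial tRNA-Ile(k2CAU).
DEFAULT_PENALTIES: dict[str, float] = {
    "wc": 0.0,
    "gu": 0.41,
    "ic": 0.28,
    "ia": 0.9999,
    "ug": 0.68,
    "la": 0.89,
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class WobblePenalties:
    """Pairing-class penalties s in [0, 1]; Watson-Crick is pinned at 0."""

    wc: float = 0.0
    gu: float = DEFAULT_PENALTIES["gu"]
    ic: float = DEFAULT_PENALTIES["ic"]
    ia: float = DEFAULT_PENALTIES["ia"]
    ug: float = DEFAULT_PENALTIES["ug"]
    la: float = DEFAULT_PENALTIES["la"]

    def __post_init__(self) -> None:
        if self.wc != 0.0:
            raise ValueError("Watson-Crick penalty must be 0")
        for name in ("gu", "ic", "ia", "ug", "la"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"penalty {name}={v} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("wc", "gu", "ic", "ia", "ug", "la")}


@dataclass
class TRNAGeneCopyTable:
    """tRNA gene copy numbers keyed by anticodon (5'->3' triplet)."""

    entries: Mapping[str, int]

    def __post_init__(self) -> None:
        for ac, n in self.entries.items():
            if len(ac) != 3 or set(ac) - set(BASES):
                raise ValueError(f"invalid anticodon {ac!r}")
            if n < 0:
                raise ValueError(f"negative copy number for {ac}")
        if not any(n > 0 for n in self.entries.values()):
            raise ValueError("tRNA copy table has no positive copy number")

    def copies(self, anticodon: str) -> int:
        return int(self.entries.get(anticodon, 0))

    @classmethod
    def from_tsv(cls, path) -> "TRNAGeneCopyTable":
        df = pd.read_csv(path, sep="\t", dtype={"anticodon": str})
        if not {"anticodon", "copies"} <= set(df.columns):
            raise ValueError("tGCN table needs columns: anticodon, copies")
        return cls(dict(zip(df["anticodon"].str.upper(), df["copies"].astype(int))))


@dataclass
class AdaptivenessWeights:
    """Per-codon relative adaptiveness w in (0, 1]."""

    w: Mapping[str, float]
    provenance: Literal["computed", "loaded"] = "computed"

    def __post_init__(self) -> None:
        missing = set(SENSE_CODONS) - set(self.w)
        if missing:
            raise ValueError(f"weights missing for codons: {sorted(missing)[:5]} ...")
        for c in SENSE_CODONS:
            v = self.w[c]
            if not (np.isnan(v) or 0.0 < v <= 1.0):
                raise ValueError(f"weight for {c} is {v}, outside (0, 1]")

    def as_series(self) -> pd.Series:
        return pd.Series({c: self.w[c] for c in SENSE_CODONS}, name="w")


@dataclass
class OptimalityClassification:
    """Binary optimal flag for each of the 61 sense codons under one metric."""

    metric: Literal["cTE", "nTE"]
    optimal: Mapping[str, bool]

    def __post_init__(self) -> None:
        missing = set(SENSE_CODONS) - set(self.optimal)
        if missing:
            raise ValueError(f"classification missing codons: {sorted(missing)[:5]} ...")
        flags = [bool(self.optimal[c]) for c in SENSE_CODONS]
        if all(flags) or not any(flags):
            raise ValueError("classification must have both classes non-empty")

    @property
    def n_optimal(self) -> int:
        return sum(bool(self.optimal[c]) for c in SENSE_CODONS)

    def optimal_set(self) -> frozenset[str]:
        return frozenset(c for c in SENSE_CODONS if self.optimal[c])


@dataclass
class GeneOptimality:
    gene_id: str
    tai_g: float
    pct_optimal: dict[str, float] = field(default_factory=dict)


def decoding_pairings(
    codon: str, lysidine_ata: bool = False
) -> list[tuple[str, str]]:
    """Enumerate the (anticodon, pairing-class) pairs that can decode a codon.

    The wobble position is the codon's third base pairing with the
    anticodon's first (position 34).  Besides the Watson-Crick anticodon,
    each codon admits one wobble reader:

    * codon ...U : G34 anticodon (G:U)
    * codon ...C : A34 anticodon, read as inosine (I:C)
    * codon ...A : A34 anticodon, read as inosine (I:A)
    * codon ...G : U34 anticodon (U:G)

    AUG is decoded only by the elongator Met tRNA (CAU, Watson-Crick); with
    ``lysidine_ata`` the bacterial rule applies to AUA: lysidine-modified
    CAU (L:A) instead of the generic readers.
    """
    wc = reverse_complement(codon)
    if codon == "ATG":
        return [(wc, "wc")]
    if codon == "ATA" and lysidine_ata:
        return [("CAT", "la")]
    wobble_class = {"T": "gu", "C": "ic", "A": "ia", "G": "ug"}[codon[2]]
    wobble_first = {"T": "G", "C": "A", "A": "A", "G": "T"}[codon[2]]
    wobble = wobble_first + wc[1:]
    return [(wc, "wc"), (wobble, wobble_class)]


def relative_adaptiveness(
    tgcn: TRNAGeneCopyTable,
    s: WobblePenalties | None = None,
    lysidine_ata: bool = False,
) -> AdaptivenessWeights:
    """Compute per-codon tAI weights from tRNA gene copy numbers.

    Absolute weights sum (1 - s) * tGCN over the decoding anticodons; the
    vector is normalised by its maximum and zero entries are replaced by
    the geometric mean of the nonzero relative weights.
    """
    s = s or WobblePenalties()
    sdict = s.as_dict()
    W = {}
    for codon in SENSE_CODONS:
        W[codon] = sum(
            (1.0 - sdict[cls]) * tgcn.copies(ac)
            for ac, cls in decoding_pairings(codon, lysidine_ata)
        )
    wmax = max(W.values())
    if wmax == 0:
        raise ValueError("all absolute tAI weights are zero for this tRNA table")
    w = {c: Wc / wmax for c, Wc in W.items()}
    nonzero = [v for v in w.values() if v > 0]
    gmean = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
    n_zero = sum(1 for v in w.values() if v == 0)
    if n_zero:
        warnings.warn(
            f"{n_zero} codons with no decoding tRNA; assigned geometric-mean "
            f"weight {gmean:.4g}",
            stacklevel=2,
        )
    w = {c: (gmean if v == 0 else v) for c, v in w.items()}
    return AdaptivenessWeights(w=w, provenance="computed")


def load_weights(path) -> AdaptivenessWeights:
    """Load per-codon weights from a TSV with columns codon, w."""
    df = pd.read_csv(path, sep="\t", dtype={"codon": str})
    if not {"codon", "w"} <= set(df.columns):
        raise ValueError("weights table needs columns: codon, w")
    w = dict(zip(df["codon"].str.upper(), df["w"].astype(float)))
    missing = set(SENSE_CODONS) - set(w)
    if missing:
        raise ValueError(f"weights table missing codon(s): {sorted(missing)}")
    for c in SENSE_CODONS:
        if not 0.0 < w[c] <= 1.0:
            raise ValueError(f"weight for {c} is {w[c]}, outside (0, 1]")
    return AdaptivenessWeights(w={c: w[c] for c in SENSE_CODONS}, provenance="loaded")


def load_classifications(path) -> dict[str, OptimalityClassification]:
    """Load cTE/nTE optimal-codon flags from a TSV with columns
    codon, metric, optimal."""
    df = pd.read_csv(path, sep="\t", dtype={"codon": str, "metric": str})
    out = {}
    for metric, sub in df.groupby("metric"):
        flags = dict(zip(sub["codon"].str.upper(), sub["optimal"].astype(int) != 0))
        out[metric] = OptimalityClassification(metric=metric, optimal=flags)
    return out


def tai_g(profile: CodonProfile, weights: AdaptivenessWeights) -> float:
    """Gene-level tAI: the count-weighted geometric mean of codon weights,

        tAI_g = exp( sum_c n_c ln w_c / sum_c n_c )

    over the gene's sense codons.  NaN when the gene has no sense codons.
    """
    counts = profile.sense_counts()
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    log_sum = sum(n * math.log(weights.w[c]) for c, n in counts.items() if n)
    return math.exp(log_sum / total)


def percent_optimal(profile: CodonProfile, cls: OptimalityClassification) -> float:
    """Percentage of a gene's sense codons classified optimal, in [0, 100]."""
    counts = profile.sense_counts()
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    n_opt = sum(n for c, n in counts.items() if cls.optimal[c])
    return 100.0 * n_opt / total


def tai_g_matrix(counts: pd.DataFrame, weights: AdaptivenessWeights) -> pd.Series:
    """Vectorised tAI_g over a gene x 61 sense-codon count matrix."""
    w = weights.as_series().reindex(counts.columns).to_numpy()
    n = counts.to_numpy(dtype=float)
    totals = n.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.exp(n @ np.log(w) / totals)
    vals[totals == 0] = np.nan
    return pd.Series(vals, index=counts.index, name="tai_g")


def percent_optimal_matrix(
    counts: pd.DataFrame, cls: OptimalityClassification
) -> pd.Series:
    flags = np.array([bool(cls.optimal[c]) for c in counts.columns], dtype=float)
    n = counts.to_numpy(dtype=float)
    totals = n.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = 100.0 * (n @ flags) / totals
    vals[totals == 0] = np.nan
    return pd.Series(vals, index=counts.index, name=f"pct_optimal_{cls.metric}")


def compute_nte(
    weights: AdaptivenessWeights,
    counts: pd.DataFrame,
    abundance: pd.Series,
    mode: Literal["counts", "frequency"] = "counts",
) -> AdaptivenessWeights:
    """Demand-normalised codon weights.

    Codon demand d_i is the abundance-weighted codon usage of the
    transcriptome, d_i = sum_g n_{g,i} m_g (``mode="counts"``) or
    sum_g x_{g,i} m_g over frequencies (``mode="frequency"``), scaled so
    max d = 1.  The normalised weight is w_i / d_i, rescaled so the maximum
    is 1.  Codons with zero demand get a missing weight with a warning.
    """
    common = counts.index.intersection(abundance.dropna().index)
    if len(common) == 0:
        raise ValueError("no genes shared between count matrix and abundance")
    m = abundance.loc[common].astype(float)
    if (m <= 0).any():
        raise ValueError("abundance must be positive for included genes")
    usage = counts.loc[common].to_numpy(dtype=float)
    if mode == "frequency":
        totals = usage.sum(axis=1, keepdims=True)
        usage = np.divide(usage, totals, out=np.zeros_like(usage), where=totals > 0)
    elif mode != "counts":
        raise ValueError(f"unknown demand mode {mode!r}")
    d = usage.T @ m.to_numpy()
    d = d / d.max()
    wvec = weights.as_series().reindex(counts.columns).to_numpy()
    with np.errstate(divide="ignore"):
        nte = wvec / d
    zero = d == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} codons with zero demand; nTE set missing",
            stacklevel=2,
        )
        nte[zero] = np.nan
    nte = nte / np.nanmax(nte)
    return AdaptivenessWeights(
        w=dict(zip(counts.columns, nte)), provenance="computed"
    )


def gene_optimality_table(
    counts: pd.DataFrame,
    weights: AdaptivenessWeights,
    classifications: Mapping[str, OptimalityClassification] | None = None,
) -> pd.DataFrame:
    """Per-gene tAI_g and percent-optimal columns, one row per gene."""
    out = pd.DataFrame({"tai_g": tai_g_matrix(counts, weights)})
    for metric, cls in (classifications or {}).items():
        out[f"pct_optimal_{metric}"] = percent_optimal_matrix(counts, cls)
    out.index.name = "gene_id"
    return out
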