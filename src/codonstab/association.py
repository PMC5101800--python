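"""Association statistics between codon usage and mRNA kinetics.

Core quantities:

* **CSC** (codon occurrence to mRNA stability correlation coefficient):
  for each sense codon, the Spearman correlation across genes between the
  codon's within-gene frequency and the gene's mRNA half-life.
* **CPC** (codon occurrence to mRNA production correlation coefficient):
  the same construction against mRNA synthesis rates (or RNAPII occupancy
  as a proxy).
* **Sign-partition chi-square**: codons are split by the sign of their
  CSC/CPC and cross-tabulated against a binary optimal/non-optimal
  classification in a 2x2 table; association is tested with a
  Yates-corrected chi-square (df = 1).  The summary reports, in the layout
  of the published contingency tables, the number of positive-coefficient
  codons ("Total"), the optimal codons among them ("Observed"), and the
  null expectation n_opt * Total / n_codons ("Expected").
* **Partial Spearman correlation** controlling for mRNA abundance, to
  separate the optimality-kinetics association from the long-known
  enrichment of optimal codons in highly expressed genes.
* **Frameshift control**: the CSC-vs-adaptiveness correlation recomputed
  after +1/+2 frameshifts, which should collapse if the signal is carried
  by codon identity rather than nucleotide composition.

All correlations use average ranks for ties and a t approximation for the
two-sided p-value (n-2 df for plain, n-3 for first-order partial
correlations), matching the conventions of standard statistical software;
an exact permutation p is available for very small samples.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_core import (
    FrameShift,
    SENSE_CODONS,
    CodingSequence,
    codon_counts,
    codon_frequency_matrix,
)
from .optimality import AdaptivenessWeights, OptimalityClassification


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int


@dataclass
class PartialCorrelationResult:
    rho_partial: float
    p: float
    n: int
    controlled: str = "abundance"


@dataclass
class CodonCorrelationVector:
    """Per-codon CSC or CPC values on the 61-codon support."""

    kind: Literal["CSC", "CPC"]
    values: Mapping[str, float]
    n_genes: int
    frame: FrameShift = field(default_factory=FrameShift)

    def as_series(self) -> pd.Series:
        return pd.Series(
            {c: self.values.get(c, np.nan) for c in SENSE_CODONS}, name=self.kind
        )


@dataclass
class ContingencySummary:
    """2x2 sign-vs-optimality table in the published summary layout."""

    total_pos: int
    observed: int
    expected: float
    n_opt: int
    n_codons: int
    chi2: float
    p: float

    def cells(self) -> tuple[int, int, int, int]:
        """(opt+, nonopt+, opt-, nonopt-), summing to n_codons."""
        a = self.observed
        b = self.total_pos - self.observed
        c = self.n_opt - self.observed
        d = self.n_codons - self.n_opt - b
        return a, b, c, d


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return math.nan
    return float((xc @ yc) / denom)


def _t_pvalue(r: float, df: int) -> float:
    if math.isnan(r) or df <= 0:
        return math.nan
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    return 2.0 * stats.t.sf(abs(t), df)


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["t", "exact"] = "t",
) -> CorrelationResult:
    """Spearman rank correlation with pairwise-complete deletion.

    Ties receive average ranks; the two-sided p comes from the t
    approximation on n-2 degrees of freedom, or from exhaustive
    permutation of one margin when ``method="exact"`` (n <= 9).
    A constant margin yields a missing rho with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return CorrelationResult(rho=math.nan, p=math.nan, n=n)
    rx, ry = _rank(x), _rank(y)
    rho = _pearson(rx, ry)
    if method == "exact":
        if n > 9:
            raise ValueError("exact permutation p limited to n <= 9")
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = _pearson(rx, np.asarray(perm))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return CorrelationResult(rho=rho, p=count / total, n=n)
    return CorrelationResult(rho=rho, p=_t_pvalue(rho, n - 2), n=n)


def _columnwise_spearman(freq: pd.DataFrame, y: pd.Series) -> tuple[dict, int]:
    """Spearman rho of each frequency column against y, pairwise-complete."""
    common = freq.index.intersection(y.dropna().index)
    sub = freq.loc[common]
    yv = y.loc[common].to_numpy(dtype=float)
    values: dict[str, float] = {}
    X = sub.to_numpy(dtype=float)
    complete_rows = ~np.isnan(X).any(axis=1)
    if complete_rows.all() and len(common) >= 3:
        # fast path: rank everything once
        ry = _rank(yv)
        ryc = ry - ry.mean()
        sy = math.sqrt(ryc @ ryc)
        RX = np.apply_along_axis(_rank, 0, X)
        RXc = RX - RX.mean(axis=0)
        sx = np.sqrt((RXc * RXc).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            rhos = (RXc.T @ ryc) / (sx * sy)
        for j, codon in enumerate(sub.columns):
            if sx[j] == 0:
                values[codon] = math.nan
            else:
                values[codon] = float(rhos[j])
        return values, len(common)
    for codon in sub.columns:
        col = X[:, list(sub.columns).index(codon)]
        mask = ~np.isnan(col)
        if mask.sum() < 3 or np.all(col[mask] == col[mask][0]):
            values[codon] = math.nan
            continue
        values[codon] = _pearson(_rank(col[mask]), _rank(yv[mask]))
    return values, len(common)


def compute_csc(
    freq_matrix: pd.DataFrame, half_lives: pd.Series, frame: FrameShift | int = 0
) -> CodonCorrelationVector:
    """Per-codon Spearman correlation of codon frequency with mRNA half-life.

    Codons with constant frequency across the analysed genes (e.g. absent
    everywhere) get a missing entry.
    """
    fs = frame if isinstance(frame, FrameShift) else FrameShift(frame)
    values, n = _columnwise_spearman(freq_matrix, half_lives)
    if n < 3:
        raise ValueError(f"need >= 3 genes with frequency and half-life, got {n}")
    return CodonCorrelationVector(kind="CSC", values=values, n_genes=n, frame=fs)


def compute_cpc(
    freq_matrix: pd.DataFrame, synthesis_rates: pd.Series, frame: FrameShift | int = 0
) -> CodonCorrelationVector:
    """Per-codon Spearman correlation of codon frequency with mRNA synthesis
    rate (or RNAPII occupancy as a proxy)."""
    fs = frame if isinstance(frame, FrameShift) else FrameShift(frame)
    values, n = _columnwise_spearman(freq_matrix, synthesis_rates)
    if n < 3:
        raise ValueError(f"need >= 3 genes with frequency and synthesis rate, got {n}")
    return CodonCorrelationVector(kind="CPC", values=values, n_genes=n, frame=fs)


def sign_partition(
    vec: CodonCorrelationVector,
) -> tuple[frozenset[str], frozenset[str]]:
    """Split codons by coefficient sign; exactly-zero values go to the
    non-positive group, and missing entries are dropped with a warning."""
    missing = [c for c in SENSE_CODONS if not np.isfinite(vec.values.get(c, np.nan))]
    if missing:
        warnings.warn(
            f"dropping {len(missing)} codons with missing {vec.kind} from the "
            "sign partition",
            stacklevel=2,
        )
    positive = frozenset(
        c for c in SENSE_CODONS
        if c not in missing and vec.values[c] > 0
    )
    nonpositive = frozenset(
        c for c in SENSE_CODONS
        if c not in missing and vec.values[c] <= 0
    )
    return positive, nonpositive


def _chi2_2x2(a: int, b: int, c: int, d: int, correction: bool) -> tuple[float, float]:
    table = np.array([[a, b], [c, d]], dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def contingency_from_cells(
    a: int, b: int, c: int, d: int, correction: bool = True
) -> ContingencySummary:
    """Build the summary from explicit 2x2 cells
    (opt+, nonopt+, opt-, nonopt-)."""
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    n_codons = a + b + c + d
    total_pos = a + b
    n_opt = a + c
    if total_pos in (0, n_codons) or n_opt in (0, n_codons):
        raise ValueError("zero marginal: chi-square test undefined")
    chi2, p = _chi2_2x2(a, b, c, d, correction)
    return ContingencySummary(
        total_pos=total_pos,
        observed=a,
        expected=n_opt * total_pos / n_codons,
        n_opt=n_opt,
        n_codons=n_codons,
        chi2=chi2,
        p=p,
    )


def contingency_from_marginals(
    total: int,
    observed: int,
    n_opt: int,
    n_codons: int = 61,
    correction: bool = True,
) -> ContingencySummary:
    """Reconstruct the 2x2 test from the published summary columns
    (Total, Observed) and the classification size n_opt."""
    return contingency_from_cells(
        observed, total - observed, n_opt - observed,
        n_codons - n_opt - (total - observed), correction=correction,
    )


def chisq_sign_test(
    vec: CodonCorrelationVector,
    cls: OptimalityClassification,
    correction: bool = True,
) -> ContingencySummary:
    """Test whether positive-coefficient codons are enriched for optimal
    codons (Yates-corrected 2x2 chi-square by default)."""
    positive, nonpositive = sign_partition(vec)
    considered = positive | nonpositive
    opt = cls.optimal_set() & considered
    a = len(positive & opt)
    b = len(positive - opt)
    c = len(opt - positive)
    d = len(considered) - a - b - c
    return contingency_from_cells(a, b, c, d, correction=correction)


def partial_spearman(
    x: Sequence[float], y: Sequence[float], z: Sequence[float],
    controlled: str = "abundance",
) -> PartialCorrelationResult:
    """First-order partial Spearman correlation of x and y controlling z.

    All three variables are rank-transformed (average ranks), then

        r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)),

    with a two-sided p from the t statistic on n-3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
    x, y, z = x[mask], y[mask], z[mask]
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 complete triples, got {n}")
    if np.all(z == z[0]):
        raise ValueError("constant control variable: partial correlation undefined")
    rx, ry, rz = _rank(x), _rank(y), _rank(z)
    r_xy = _pearson(rx, ry)
    r_xz = _pearson(rx, rz)
    r_yz = _pearson(ry, rz)
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise ValueError("control variable perfectly correlated with an input")
    rho = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    rho = max(-1.0, min(1.0, rho))
    return PartialCorrelationResult(
        rho_partial=rho, p=_t_pvalue(rho, n - 3), n=n, controlled=controlled
    )


def correlate_with_weights(
    vec: CodonCorrelationVector, weights: AdaptivenessWeights
) -> CorrelationResult:
    """Spearman correlation of a CSC/CPC vector with the per-codon
    adaptiveness weights, over codons with a defined coefficient."""
    s = vec.as_series()
    w = weights.as_series()
    return spearman(s.to_numpy(), w.to_numpy())


def frameshift_control(
    cds_collection: Iterable[CodingSequence],
    kinetic_values: pd.Series,
    weights: AdaptivenessWeights,
    shifts: Sequence[int] = (0, 1, 2),
    kind: Literal["CSC", "CPC"] = "CSC",
) -> dict[int, CorrelationResult]:
    """Recompute the coefficient-vs-adaptiveness correlation per frame.

    For each shift the codon frequencies, the CSC/CPC vector, and its
    Spearman correlation with the tAI weights are recomputed from scratch.
    A codon-identity-driven association should be positive in frame 0 and
    collapse toward zero in shifted frames.
    """
    cds_collection = list(cds_collection)
    results: dict[int, CorrelationResult] = {}
    compute = compute_csc if kind == "CSC" else compute_cpc
    for shift in shifts:
        profiles = [codon_counts(s, shift) for s in cds_collection]
        freq = codon_frequency_matrix(profiles)
        vec = compute(freq, kinetic_values, frame=shift)
        results[shift] = correlate_with_weights(vec, weights)
    return results


def correlation_vector_table(vec: CodonCorrelationVector) -> pd.DataFrame:
    out = vec.as_series().rename("value").to_frame()
    out["n"] = vec.n_genes
    out.index.name = "codon"
    return out


def contingency_table_row(summary: ContingencySummary) -> dict[str, float]:
    """One row in the layout of the published summary tables."""
    return {
        "Total": summary.total_pos,
        "Observed": summary.observed,
        "Expected": round(summary.expected, 1),
        "P value": summary.p,
    }
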