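"""Steady-state RNA kinetics and dataset harmonisation.

Published RNA kinetic datasets report different subsets of {half-life,
synthesis rate, abundance} in different units.  Under the steady-state
assumption synthesis balances decay plus growth dilution,

    lambda = ln(2) / hl          (decay rate, min^-1)
    mu     = m * (alpha + lambda)   (synthesis rate, molecules min^-1 cell^-1)
    alpha  = ln(2) / ccl         (growth-dilution rate from cell-cycle length)

which lets any missing member of the triple be recovered from the other
two.  Working units throughout: minutes, molecules per cell, molecules per
minute per cell.  Datasets from transcription-shutoff protocols (where
growth is halted) use alpha = 0; labeling datasets may derive alpha from
the cell-cycle length (e.g. 150 min for budding yeast in minimal medium).

Relative abundance measurements are placed on the molecules-per-cell scale
by scaling to a total mRNA content per cell (60,000 for S. cerevisiae,
41,000 for S. pombe).

Missing inputs propagate to missing outputs; nothing is imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))

#: total mRNA molecules per cell used to scale relative abundance
TOTAL_MRNA_PER_CELL = {"S. cerevisiae": 60_000, "S. pombe": 41_000}


def decay_rate(hl):
    """Decay rate lambda = ln(2)/hl [min^-1]; NaN for missing/non-positive hl."""
    hl = np.asarray(hl, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(hl > 0, LN2 / hl, np.nan)
    return float(lam) if lam.ndim == 0 else lam


def growth_rate(ccl: float | None, policy: Literal["zero", "from_ccl"] = "from_ccl") -> float:
    """Growth-dilution rate alpha = ln(2)/ccl; 0 under the ``zero`` policy."""
    if policy == "zero":
        return 0.0
    if ccl is None or not ccl > 0:
        raise ValueError("alpha_policy 'from_ccl' requires a positive cell-cycle length")
    return LN2 / ccl


def synthesis_rate(m, hl, alpha: float = 0.0):
    """Steady-state synthesis rate mu = m * (alpha + ln2/hl)."""
    m = np.asarray(m, dtype=float)
    lam = decay_rate(hl)
    with np.errstate(invalid="ignore"):
        mu = np.where((m >= 0) & ~np.isnan(lam), m * (alpha + lam), np.nan)
    # m = 0 is a valid boundary: no molecules, no synthesis
    mu = np.where(m == 0, 0.0, mu)
    return float(mu) if mu.ndim == 0 else mu


def half_life_from(mu, m, alpha: float = 0.0):
    """Invert the steady-state relation: hl = ln(2)/(mu/m - alpha).

    mu/m <= alpha is non-physical under steady state and yields NaN with a
    warning.
    """
    mu = np.asarray(mu, dtype=float)
    m = np.asarray(m, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        net = mu / m - alpha
        hl = np.where(net > 0, LN2 / net, np.nan)
    bad = np.asarray((net <= 0) & ~np.isnan(net))
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} records with mu/m <= alpha: half-life undefined "
            "under steady state",
            stacklevel=2,
        )
    return float(hl) if hl.ndim == 0 else hl


def scale_abundance(relative, total: float) -> np.ndarray:
    """Scale relative abundances so they sum to ``total`` molecules per cell."""
    rel = np.asarray(relative, dtype=float)
    if (rel < 0).any():
        raise ValueError("relative abundance must be non-negative")
    s = np.nansum(rel)
    if s == 0:
        raise ValueError("cannot scale an all-zero abundance vector")
    return rel * (total / s)


@dataclass(frozen=True)
class DatasetMeta:
    """Provenance and unit policy of one kinetic dataset."""

    name: str
    organism: Literal["S. cerevisiae", "S. pombe"]
    method: Literal["shutoff", "labeling", "chase", "GRO", "ChIP"]
    alpha_policy: Literal["zero", "from_ccl"] = "zero"
    ccl: float | None = None
    total_mrna_per_cell: int | None = None

    def __post_init__(self) -> None:
        if self.alpha_policy == "from_ccl" and not (self.ccl and self.ccl > 0):
            raise ValueError(f"{self.name}: alpha_policy 'from_ccl' requires ccl > 0")

    @property
    def alpha(self) -> float:
        return growth_rate(self.ccl, self.alpha_policy)

    @property
    def total_mrna(self) -> int:
        if self.total_mrna_per_cell is not None:
            return self.total_mrna_per_cell
        return TOTAL_MRNA_PER_CELL[self.organism]


@dataclass
class GeneFilter:
    """Ordered include/exclude rules applied to a kinetic table."""

    include: Sequence[str] | None = None
    exclude: Sequence[str] = ()
    exclude_multicistronic: bool = False
    multicistronic_ids: Sequence[str] = ()
    removal_log: dict[str, int] = field(default_factory=dict)


def apply_filters(records: pd.DataFrame, filt: GeneFilter) -> pd.DataFrame:
    """Apply include-list, exclude-list and multicistronic rules in order.

    The per-rule removal counts are stored on ``filt.removal_log``.
    """
    out = records
    filt.removal_log = {}
    if filt.include is not None:
        keep = out.index.isin(set(filt.include))
        filt.removal_log["include_list"] = int((~keep).sum())
        out = out.loc[keep]
    if len(filt.exclude):
        drop = out.index.isin(set(filt.exclude))
        filt.removal_log["exclude_list"] = int(drop.sum())
        out = out.loc[~drop]
    if filt.exclude_multicistronic:
        drop = out.index.isin(set(filt.multicistronic_ids))
        filt.removal_log["multicistronic"] = int(drop.sum())
        out = out.loc[~drop]
    if out.empty:
        warnings.warn("gene filter removed every record", stacklevel=2)
    for rule, n in filt.removal_log.items():
        logger.info("filter %s removed %d genes", rule, n)
    return out


def load_kinetics_tsv(path) -> pd.DataFrame:
    """Read a kinetic table (gene_id, half_life_min, synthesis_rate, abundance);
    absent columns are filled with NaN."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    for col in ("half_life_min", "synthesis_rate", "abundance"):
        if col not in df.columns:
            df[col] = np.nan
    return df[["half_life_min", "synthesis_rate", "abundance"]].astype(float)


def harmonize(records: pd.DataFrame, meta: DatasetMeta, rescale_abundance: bool = False) -> pd.DataFrame:
    """Complete a kinetic table under the steady-state model.

    Adds decay rate, fills synthesis rate from (m, hl) or half-life from
    (mu, m) where missing, and optionally rescales abundance to the
    organism's total mRNA per cell.  Columns: half_life_min, lam,
    synthesis_rate, abundance, alpha.
    """
    out = records.copy()
    alpha = meta.alpha
    if rescale_abundance and out["abundance"].notna().any():
        vals = out["abundance"].to_numpy(dtype=float)
        mask = ~np.isnan(vals)
        vals[mask] = scale_abundance(vals[mask], meta.total_mrna)
        out["abundance"] = vals
    hl = out["half_life_min"].to_numpy(dtype=float)
    mu = out["synthesis_rate"].to_numpy(dtype=float)
    m = out["abundance"].to_numpy(dtype=float)
    need_mu = np.isnan(mu) & ~np.isnan(hl) & ~np.isnan(m)
    if need_mu.any():
        mu = np.where(need_mu, synthesis_rate(m, hl, alpha), mu)
    need_hl = np.isnan(hl) & ~np.isnan(mu) & ~np.isnan(m)
    if need_hl.any():
        hl = np.where(need_hl, half_life_from(mu, m, alpha), hl)
    out["half_life_min"] = hl
    out["lam"] = decay_rate(hl)
    out["synthesis_rate"] = mu
    out["alpha"] = alpha
    return out[["half_life_min", "lam", "synthesis_rate", "abundance", "alpha"]]


def load_registry(path) -> dict[str, DatasetMeta]:
    """Read a dataset registry (YAML list of DatasetMeta fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    metas = {}
    for entry in raw["datasets"]:
        meta = DatasetMeta(**entry)
        metas[meta.name] = meta
    return metas
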