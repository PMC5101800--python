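"""Synthetic genomes and kinetic datasets with known optimality-expression
coupling.

Each gene receives a latent optimality score u_g ~ Uniform(0,1).  Codons
are drawn within synonymous families under an exponential tilt

    p_c  proportional to  exp(tilt * u_g * w_c),

so amino-acid composition is identical in expectation across genes and
only synonymous codon choice carries the signal -- the quantity the
codon-level statistics are meant to isolate.  Kinetics follow the
steady-state model generatively, with log-normal noise (half-lives are
positive and right-skewed in real data):

    direct regime:      log hl = log hl0 + beta  * (u - 1/2) + eps
                        log mu = log mu0 + gamma * (u - 1/2) + eps'
                        m      = mu / (alpha + ln2/hl)
    mediated regime:    log m  = log m0  + beta * (u - 1/2) + eps
                        log hl = log hl0 + kappa * (log m - log m0) + eps'
                        mu     = m * (alpha + ln2/hl)

In the direct regime codon optimality is coupled to stability itself; in
the abundance-mediated regime it reaches half-life only through
abundance, so a partial correlation controlling for abundance should
collapse -- the two regimes exercise the opposing interpretations the
partial-correlation analysis is designed to separate.

With a fixed seed every output is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .codon_core import (
    SENSE_CODONS,
    SYNONYMOUS_FAMILIES,
    CodingSequence,
    count_matrix,
    codon_counts,
)
from .kinetics import LN2
from .motif_association import MotifAnnotation
from .optimality import AdaptivenessWeights, OptimalityClassification, tai_g_matrix


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one synthetic dataset.

    Defaults give a fission-yeast-like genome: ~5000-gene scale is scaled
    to ``n_genes`` = 500 for routine runs, 28 of 61 codons optimal, gene
    lengths 100-400 codons, median half-life 20 min and synthesis rate
    0.5 molecules/min/cell, and a clear optimality-stability coupling.
    """

    n_genes: int = 500
    gene_length_range: tuple[int, int] = (100, 400)
    n_optimal: int = 28
    tilt: float = 3.0
    coupling_beta: float = 1.0
    synthesis_coupling: float = 1.0
    noise_sd: float = 0.4
    abundance_noise_sd: float = 0.0
    alpha: float = 0.0
    base_half_life: float = 20.0
    base_synthesis: float = 0.5
    base_abundance: float = 10.0
    mediation_kappa: float = 0.5
    motif_effect_delta: float = 2.0
    motif_base_rate: float = 0.3
    regime: Literal["direct", "abundance_mediated"] = "direct"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("need n_genes >= 10")
        if self.gene_length_range[0] < 30:
            raise ValueError("gene lengths must be >= 30 codons")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 1 <= self.n_optimal <= 60:
            raise ValueError("n_optimal must leave both classes non-empty")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SyntheticDataset:
    """A simulated genome with matching kinetics, annotations, and truth."""

    config: SimulationConfig
    weights: AdaptivenessWeights
    classification: OptimalityClassification
    truth: pd.DataFrame  # per-gene u, tai_g, half_life_min, synthesis_rate, abundance
    counts: pd.DataFrame  # gene x 61 sense-codon counts
    kinetics: pd.DataFrame  # gene_id-indexed half_life_min, synthesis_rate, abundance
    motifs: list[MotifAnnotation] = field(default_factory=list)
    sequences: list[CodingSequence] = field(default_factory=list)


def simulate_weights(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[AdaptivenessWeights, OptimalityClassification]:
    """Sample per-codon adaptiveness weights in (0, 1] with max = 1 and
    classify the top-``n_optimal`` codons by weight as optimal."""
    rng = rng if rng is not None else config.rng()
    w = rng.uniform(0.05, 1.0, size=len(SENSE_CODONS))
    w /= w.max()
    weights = AdaptivenessWeights(w=dict(zip(SENSE_CODONS, w)), provenance="computed")
    order = np.argsort(w)[::-1]
    optimal_idx = set(order[: config.n_optimal])
    cls = OptimalityClassification(
        metric="cTE",
        optimal={c: (i in optimal_idx) for i, c in enumerate(SENSE_CODONS)},
    )
    return weights, cls


def _family_probs(
    w: np.ndarray, codon_index: dict[str, int], tilt_u: float
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per synonymous family: (codon column indices, tilted probabilities)."""
    out = []
    for codons in SYNONYMOUS_FAMILIES.values():
        idx = np.array([codon_index[c] for c in codons])
        logits = tilt_u * w[idx]
        p = np.exp(logits - logits.max())
        out.append((idx, p / p.sum()))
    return out


def simulate_profiles(
    config: SimulationConfig,
    weights: AdaptivenessWeights,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw per-gene codon counts under the tilted-synonymous-choice model.

    Returns the gene x 61 count matrix and the latent u vector.  This is
    the count-level equivalent of :func:`simulate_genome` (identical
    sampling law, no sequence materialisation).
    """
    rng = rng if rng is not None else config.rng()
    codon_index = {c: i for i, c in enumerate(SENSE_CODONS)}
    w = weights.as_series().to_numpy()
    aa_sizes = np.array([len(v) for v in SYNONYMOUS_FAMILIES.values()])
    aa_probs = aa_sizes / aa_sizes.sum()
    lo, hi = config.gene_length_range
    u = rng.uniform(0.0, 1.0, size=config.n_genes)
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    counts = np.zeros((config.n_genes, len(SENSE_CODONS)), dtype=np.int64)
    for g in range(config.n_genes):
        fam_counts = rng.multinomial(lengths[g], aa_probs)
        for (idx, p), n_aa in zip(
            _family_probs(w, codon_index, config.tilt * u[g]), fam_counts
        ):
            if n_aa:
                counts[g, idx] += rng.multinomial(n_aa, p)
    gene_ids = [f"g{g:05d}" for g in range(config.n_genes)]
    mat = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                       columns=list(SENSE_CODONS))
    return mat, u


def simulate_genome(
    config: SimulationConfig,
    weights: AdaptivenessWeights,
    rng: np.random.Generator | None = None,
) -> tuple[list[CodingSequence], pd.DataFrame, np.ndarray]:
    """Materialise coding sequences under the tilted sampling model.

    Each CDS is a start codon, the shuffled sampled codons, and a TAA stop
    -- a strict-mode-valid ORF.  Returns (sequences, count matrix of the
    sampled body codons, u).
    """
    rng = rng if rng is not None else config.rng()
    counts, u = simulate_profiles(config, weights, rng)
    sequences = []
    codons = np.array(list(SENSE_CODONS))
    for gene_id, row in zip(counts.index, counts.to_numpy()):
        body = np.repeat(codons, row)
        rng.shuffle(body)
        seq = "ATG" + "".join(body) + "TAA"
        sequences.append(CodingSequence(gene_id=gene_id, sequence=seq))
    return sequences, counts, u


def simulate_kinetics(
    u: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Generate steady-state-consistent kinetics from the latent scores.

    Every record satisfies mu = m * (alpha + ln2/hl) exactly; see the
    module docstring for the direct vs abundance-mediated regimes.
    """
    rng = rng if rng is not None else config.rng()
    n = len(u)
    if gene_ids is None:
        gene_ids = [f"g{g:05d}" for g in range(n)]
    eps1 = rng.normal(0.0, config.noise_sd, size=n)
    eps2 = rng.normal(0.0, config.noise_sd, size=n)
    centered = u - 0.5
    if config.regime == "direct":
        hl = config.base_half_life * np.exp(config.coupling_beta * centered + eps1)
        mu = config.base_synthesis * np.exp(
            config.synthesis_coupling * centered + eps2
        )
        m = mu / (config.alpha + LN2 / hl)
    elif config.regime == "abundance_mediated":
        log_m_dev = config.coupling_beta * centered + eps1
        m = config.base_abundance * np.exp(log_m_dev)
        hl = config.base_half_life * np.exp(
            config.mediation_kappa * log_m_dev + eps2
        )
        mu = m * (config.alpha + LN2 / hl)
    else:
        raise ValueError(f"unknown regime {config.regime!r}")
    if config.abundance_noise_sd > 0:
        # measurement error on abundance: reported m comes from independent
        # studies, so the emitted triple is steady-state-exact only for the
        # latent abundance, not the observed one
        m = m * np.exp(rng.normal(0.0, config.abundance_noise_sd, size=n))
    return pd.DataFrame(
        {
            "half_life_min": hl,
            "synthesis_rate": mu,
            "abundance": m,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


#: motif panel emulating a promoter/UTR motif table: name, location,
#: published direction of the kinetic association, and whether the
#: simulator couples its presence to the latent optimality score.
MOTIF_PANEL: tuple[tuple[str, str, str, bool], ...] = (
    ("CAGTCACA", "promoter", "long half-life", True),
    ("AACCAC", "5'UTR", "long half-life", True),
    ("TATTTAT", "3'UTR", "short half-life", False),
    ("ACTAAT", "3'UTR", "short half-life", False),
)


def simulate_motifs(
    u: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    gene_ids: Sequence[str] | None = None,
) -> list[MotifAnnotation]:
    """Assign motif instance counts: stabilising motifs with probability
    increasing in u (logistic slope ``motif_effect_delta``), destabilising
    motifs independently of u."""
    rng = rng if rng is not None else config.rng()
    n = len(u)
    if gene_ids is None:
        gene_ids = [f"g{g:05d}" for g in range(n)]
    base_logit = np.log(config.motif_base_rate / (1 - config.motif_base_rate))
    out = []
    for motif_id, location, rate, coupled in MOTIF_PANEL:
        if coupled:
            logits = base_logit + config.motif_effect_delta * (u - 0.5)
            p = 1.0 / (1.0 + np.exp(-logits))
        else:
            p = np.full(n, config.motif_base_rate)
        present = rng.random(n) < p
        extra = rng.poisson(0.3, size=n)
        counts = present.astype(int) * (1 + extra)
        out.append(
            MotifAnnotation(
                motif_id=motif_id,
                location=location,
                rate_association=rate,
                gene_counts={g: int(c) for g, c in zip(gene_ids, counts) if c},
            )
        )
    return out


def simulate_dataset(
    config: SimulationConfig, with_sequences: bool = True
) -> SyntheticDataset:
    """Run the full generative model from one seed.

    A single generator drives weights, genome, kinetics and motifs in a
    fixed order, so identical configs give byte-identical outputs.
    """
    rng = config.rng()
    weights, cls = simulate_weights(config, rng)
    if with_sequences:
        sequences, counts, u = simulate_genome(config, weights, rng)
    else:
        sequences = []
        counts, u = simulate_profiles(config, weights, rng)
    kin = simulate_kinetics(u, config, rng, gene_ids=list(counts.index))
    motifs = simulate_motifs(u, config, rng, gene_ids=list(counts.index))
    truth = pd.DataFrame(
        {"u": u, "tai_g": tai_g_matrix(counts, weights)}, index=counts.index
    ).join(kin)
    return SyntheticDataset(
        config=config,
        weights=weights,
        classification=cls,
        truth=truth,
        counts=counts,
        kinetics=kin,
        motifs=motifs,
        sequences=sequences,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write the dataset in the formats the analysis pipeline reads:
    FASTA CDS, kinetics TSV, weights TSV, classification TSV, motif TSV,
    and the ground-truth TSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if ds.sequences:
        with open(outdir / "cds.fasta", "w") as fh:
            for s in ds.sequences:
                fh.write(f">{s.gene_id}\n")
                for i in range(0, len(s.sequence), 60):
                    fh.write(s.sequence[i : i + 60] + "\n")
    ds.kinetics.to_csv(outdir / "kinetics.tsv", sep="\t")
    ds.weights.as_series().rename("w").rename_axis("codon").to_csv(
        outdir / "weights.tsv", sep="\t"
    )
    pd.DataFrame(
        {
            "codon": list(SENSE_CODONS),
            "metric": ds.classification.metric,
            "optimal": [int(ds.classification.optimal[c]) for c in SENSE_CODONS],
        }
    ).to_csv(outdir / "classification.tsv", sep="\t", index=False)
    rows = []
    for ann in ds.motifs:
        for g, c in sorted(ann.gene_counts.items()):
            rows.append((g, ann.motif_id, ann.location, ann.rate_association, c))
    pd.DataFrame(
        rows, columns=["gene_id", "motif_id", "location", "rate", "count"]
    ).to_csv(outdir / "motifs.tsv", sep="\t", index=False)
    ds.truth.to_csv(outdir / "truth.tsv", sep="\t")


def profiles_from_sequences(sequences: Sequence[CodingSequence], shift: int = 0):
    """Convenience: codon profiles of a simulated genome in a given frame."""
    return [codon_counts(s, shift) for s in sequences]


def frequency_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    from .codon_core import frequency_matrix_from_counts

    return frequency_matrix_from_counts(counts)


__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_weights",
    "simulate_profiles",
    "simulate_genome",
    "simulate_kinetics",
    "simulate_motifs",
    "simulate_dataset",
    "write_dataset",
    "count_matrix",
]
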