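"""Synthetic paired two-tissue expression data with known truth.

The generator emulates the statistical features a dual-tissue
differential-expression study exercises: a shared set of samples measured
in two tissues, a small fraction of truly differential genes whose effect
strength differs between tissues (the first tissue carries the stronger
signal, as a spinal cord vs. neocortex comparison would), and
between-gene correlation in blocks. It works directly on the log2 scale:
per-gene baselines are drawn from a normal distribution of log2
expression levels, disease samples of a differential gene are shifted by
a signed effect, and noise is block-equicorrelated Gaussian, independent
between the two tissues.

Defaults follow the study design the methods are aimed at: 3000 genes,
16 samples split 8 normal / 8 disease, 65 differential genes (~2%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, PairedDatasets, write_expression, write_labels

__all__ = ["SimConfig", "TruthTable", "simulate_tissue_pair", "export_fixture", "read_truth"]


@dataclass
class SimConfig:
    """Parameters of the paired-tissue generator.

    Effects are mean log2 shifts in units of the within-gene noise SD
    (``dispersion``); each differential gene's realized effect is jittered
    by +-25% around the tissue mean and carries a random sign shared
    between tissues.
    """

    n_genes: int = 3000
    n_samples: int = 16
    n_de: int = 65
    frac_de_first_only: float = 0.30
    frac_de_second_only: float = 0.10
    frac_de_both: float = 0.60
    effect_first: float = 1.5
    effect_second: float = 0.75
    block_size: int = 20
    block_rho: float = 0.3
    baseline_mean_log: float = 6.0
    baseline_sd_log: float = 2.0
    dispersion: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if self.n_samples % 2:
            raise ValueError("n_samples must be even (balanced design)")
        if self.n_samples < 8:
            raise ValueError("need at least 4 samples per class")
        fracs = (self.frac_de_first_only, self.frac_de_second_only, self.frac_de_both)
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("DE fractions must be nonnegative and sum to 1")
        if self.effect_first < 0 or self.effect_second < 0:
            raise ValueError("effect sizes must be nonnegative")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must lie in [0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    @property
    def de_counts(self) -> tuple[int, int, int]:
        """(first-only, second-only, both) differential gene counts."""
        n_first = int(round(self.frac_de_first_only * self.n_de))
        n_second = int(round(self.frac_de_second_only * self.n_de))
        n_both = self.n_de - n_first - n_second
        if n_both < 0:
            raise ValueError("DE partition rounds to a negative 'both' count")
        return n_first, n_second, n_both


@dataclass
class TruthTable:
    """Which genes are differential in which tissue, with realized effects."""

    gene_ids: list[str]
    de_first: np.ndarray
    de_second: np.ndarray
    effect_first: np.ndarray
    effect_second: np.ndarray

    @property
    def truth_any(self) -> set[str]:
        flag = (self.de_first == 1) | (self.de_second == 1)
        return {g for g, f in zip(self.gene_ids, flag) if f}

    @property
    def truth_first(self) -> set[str]:
        return {g for g, f in zip(self.gene_ids, self.de_first == 1) if f}

    @property
    def truth_second(self) -> set[str]:
        return {g for g, f in zip(self.gene_ids, self.de_second == 1) if f}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "de_first": self.de_first.astype(int),
                "de_second": self.de_second.astype(int),
                "effect_first": self.effect_first,
                "effect_second": self.effect_second,
            }
        )


def _block_noise(rng: np.random.Generator, n_genes: int, n_samples: int,
                 block_size: int, rho: float, sd: float) -> np.ndarray:
    """Block-equicorrelated Gaussian noise: within a block of consecutive
    genes every pair correlates at ``rho``, across blocks genes are
    independent."""
    eps = rng.standard_normal((n_genes, n_samples))
    if rho == 0.0:
        return sd * eps
    n_blocks = int(np.ceil(n_genes / block_size))
    factors = rng.standard_normal((n_blocks, n_samples))
    shared = np.repeat(factors, block_size, axis=0)[:n_genes]
    return sd * (np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps)


def simulate_tissue_pair(config: SimConfig) -> tuple[PairedDatasets, TruthTable]:
    """Draw one paired-tissue dataset plus its truth table.

    Deterministic given ``config.seed``. The two tissues share samples,
    labels and per-gene baselines but have independent noise; a gene
    differential in both tissues shifts with the same sign in both.
    """
    rng = np.random.default_rng(config.seed)
    G, n = config.n_genes, config.n_samples
    half = n // 2
    y = np.array([0] * half + [1] * half)
    gene_ids = [f"gene{i:05d}" for i in range(G)]
    sample_ids = [f"mouse{j:02d}" for j in range(n)]

    baselines = rng.normal(config.baseline_mean_log, config.baseline_sd_log, size=G)

    n_first, n_second, n_both = config.de_counts
    de_idx = rng.choice(G, size=config.n_de, replace=False)
    idx_first = de_idx[:n_first]
    idx_second = de_idx[n_first : n_first + n_second]
    idx_both = de_idx[n_first + n_second :]

    sign = rng.choice([-1.0, 1.0], size=G)
    jitter = lambda size: 1.0 + rng.uniform(-0.25, 0.25, size=size)  # noqa: E731

    eff1 = np.zeros(G)
    eff2 = np.zeros(G)
    active1 = np.concatenate([idx_first, idx_both])
    active2 = np.concatenate([idx_second, idx_both])
    eff1[active1] = config.effect_first * config.dispersion * jitter(active1.size) * sign[active1]
    eff2[active2] = config.effect_second * config.dispersion * jitter(active2.size) * sign[active2]

    datasets = []
    for tissue, eff in (("first", eff1), ("second", eff2)):
        noise = _block_noise(rng, G, n, config.block_size, config.block_rho, config.dispersion)
        X = baselines[:, None] + eff[:, None] * y[None, :] + noise
        datasets.append(ExpressionDataset(gene_ids, sample_ids, X, y, tissue=tissue))

    truth = TruthTable(
        gene_ids=gene_ids,
        de_first=(eff1 != 0).astype(int),
        de_second=(eff2 != 0).astype(int),
        effect_first=eff1,
        effect_second=eff2,
    )
    return PairedDatasets(datasets[0], datasets[1]), truth


def export_fixture(pair: PairedDatasets, truth: TruthTable, out_dir: str | Path) -> dict[str, Path]:
    """Write the pair and truth as four TSVs into an existing directory."""
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {out_dir}")
    paths = {
        "first": out_dir / "first.tsv",
        "second": out_dir / "second.tsv",
        "labels": out_dir / "labels.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_expression(pair.first, paths["first"])
    write_expression(pair.second, paths["second"])
    write_labels(pair.first, paths["labels"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_truth(path: str | Path) -> TruthTable:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return TruthTable(
        gene_ids=frame["gene_id"].tolist(),
        de_first=frame["de_first"].to_numpy(),
        de_second=frame["de_second"].to_numpy(),
        effect_first=frame["effect_first"].to_numpy(),
        effect_second=frame["effect_second"].to_numpy(),
    )
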