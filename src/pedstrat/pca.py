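"""Genotype principal components analysis on a chosen variant panel.

Dosage columns are standardized the way genotype PCA is normally done:
centered by twice the sample alternate-allele frequency 2p̂ and scaled by
sqrt(2p̂(1-p̂)), the binomial standard deviation under Hardy–Weinberg, with
p̂ always taken over the full sample so that scores are comparable across
families.  Eigen-structure comes from an economy SVD of the standardized
matrix; component signs are fixed by making the largest-magnitude loading
of each component positive.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genoio import GenotypeMatrix, compute_freq

__all__ = [
    "PCAResult",
    "sample_panel",
    "run_pca",
    "components_for_fraction",
    "write_scores",
    "write_eigen",
    "scree_plot",
]


@dataclass
class PCAResult:
    """Scores for the requested leading components plus the full computed
    spectrum (all min(n-1, m) nonzero eigenvalues), so cumulative-variance
    queries do not require a re-run."""

    scores: np.ndarray            # (n_individuals, n_components)
    eigenvalues: np.ndarray       # all computed, non-increasing
    variance_fraction: np.ndarray  # eigenvalue / total variance
    panel_ids: list[str]
    sample_ids: pd.DataFrame      # fid, iid aligned to score rows

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def sample_panel(
    matrix: GenotypeMatrix,
    n: int,
    maf_threshold: float,
    rng: np.random.Generator | int,
) -> list[str]:
    """Uniform random sample of ``n`` variant ids, without replacement, among
    variants with whole-sample MAF strictly > ``maf_threshold``."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    freq = compute_freq(matrix)
    maf = freq.set_index("variant_id")["maf"]
    eligible = [v for v in matrix.variant_ids if np.isfinite(maf[v]) and maf[v] > maf_threshold]
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} variants with MAF > {maf_threshold}, need {n}"
        )
    pick = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in np.sort(pick)]


def run_pca(
    matrix: GenotypeMatrix,
    panel_ids: Sequence[str] | None = None,
    n_components: int = 10,
) -> PCAResult:
    """PCA of the standardized dosage matrix restricted to ``panel_ids``
    (default: all variants).  Monomorphic panel variants are excluded with a
    warning; ``n_components`` beyond the available rank is capped."""
    if panel_ids is None:
        panel_ids = matrix.variant_ids
    sub = matrix.subset_variants(panel_ids)

    p_hat = np.nanmean(sub.dosage, axis=0) / 2.0
    poly = (p_hat > 0.0) & (p_hat < 1.0)
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic variants from PCA panel",
            stacklevel=2,
        )
    used = [v for v, ok in zip(sub.variant_ids, poly) if ok]
    dosage = sub.dosage[:, poly]
    p_hat = p_hat[poly]

    Z = (dosage - 2.0 * p_hat) / np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    Z = np.nan_to_num(Z)  # missing -> mean after centering

    n = Z.shape[0]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / (n - 1)
    # fix signs: largest-|loading| entry positive per component
    for j in range(len(s)):
        k = np.argmax(np.abs(Vt[j]))
        if Vt[j, k] < 0:
            Vt[j] *= -1
            U[:, j] *= -1

    total = eig.sum()
    frac = eig / total if total > 0 else np.zeros_like(eig)
    k = min(n_components, len(s))
    scores = U[:, :k] * s[:k]
    return PCAResult(scores, eig, frac, used, sub.samples.copy())


def components_for_fraction(result: PCAResult, fraction: float) -> int:
    """Smallest k whose cumulative variance fraction reaches ``fraction``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    cum = np.cumsum(result.variance_fraction)
    hit = np.flatnonzero(cum >= fraction - 1e-12)
    if hit.size == 0:
        raise ValueError(
            f"computed components explain only {cum[-1]:.4f} < {fraction}; "
            "run a full decomposition"
        )
    return int(hit[0]) + 1


def write_scores(result: PCAResult, path: str | Path, seed: int | None = None) -> None:
    df = result.sample_ids.copy()
    for j in range(result.n_components):
        df[f"PC{j+1}"] = result.scores[:, j]
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_eigen(result: PCAResult, path: str | Path, seed: int | None = None) -> None:
    df = pd.DataFrame(
        {
            "component": np.arange(1, len(result.eigenvalues) + 1),
            "eigenvalue": result.eigenvalues,
            "variance_fraction": result.variance_fraction,
            "cumulative_fraction": np.cumsum(result.variance_fraction),
        }
    )
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def scree_plot(result: PCAResult, path: str | Path, n_show: int = 30) -> Path:
    """Eigenvalue-by-rank scree plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = min(n_show, len(result.eigenvalues))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(1, k + 1), result.eigenvalues[:k], "o-")
    ax.set_xlabel("component")
    ax.set_ylabel("eigenvalue")
    ax.set_title("Scree plot")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
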