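"""Planted-block synthetic benchmark for the whole pipeline.

Generates two-condition expression matrices from a zero-mean multivariate
normal whose correlation matrix is block structured: rho_in within planted
gene blocks (the ground-truth communities), rho_out between them, plus
optional independent Gaussian jitter. The second ("disease-like") condition
decorrelates a subset of blocks, emulating the sparser network a pathology
produces. Planted many-to-one-or-many pathway candidate sets accompany the
blocks so the pathway-projection stage is testable end to end.

Sampling uses the symmetric (eigen) square root of the target correlation:
X = C^{1/2} Z with Z standard normal, so the rows of X have correlation C
in expectation. With jitter of standard deviation s, off-diagonal
correlations shrink by the factor 1/(1+s^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .communities import Partition
from .expression import ExpressionMatrix
from .pathways import PathwayAnnotation

#: eigenvalues above this (negative) tolerance are accepted and clipped at 0,
#: admitting the degenerate rho_in = 1 perfectly-correlated block
_PSD_TOL = -1e-8


@dataclass
class SyntheticSpec:
    """Parameters of the planted-block generator.

    Defaults follow the benchmark condition used throughout the test suite:
    4 blocks of 10 genes, rho_in = 0.95, rho_out = 0, 50 samples per
    condition, no jitter; the disease-like condition decorrelates the last
    two blocks to rho 0.2.
    """

    n_blocks: int = 4
    block_sizes: tuple[int, ...] = (10, 10, 10, 10)
    rho_in: float = 0.95
    rho_out: float = 0.0
    n_samples_a: int = 50
    n_samples_b: int = 50
    noise_sd: float = 0.0
    decorrelated_blocks: tuple[int, ...] | None = None
    rho_in_b: float = 0.2
    pathway_scheme: tuple[tuple[str, ...], ...] | None = None
    condition_a: str = "normal"
    condition_b: str = "dmd"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.block_sizes, int):
            self.block_sizes = (self.block_sizes,) * self.n_blocks
        self.block_sizes = tuple(int(b) for b in self.block_sizes)
        if len(self.block_sizes) != self.n_blocks:
            raise ValueError("block_sizes length must equal n_blocks")
        if any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be >= 1")
        if not (-1 < self.rho_out < 1 and -1 < self.rho_in <= 1):
            raise ValueError("correlations must lie in (-1, 1] / (-1, 1)")
        if self.rho_in <= self.rho_out:
            raise ValueError("rho_in must exceed rho_out")
        if self.decorrelated_blocks is None:
            self.decorrelated_blocks = tuple(range(self.n_blocks // 2, self.n_blocks))
        if self.pathway_scheme is None:
            self.pathway_scheme = tuple(
                (f"hsa{i + 1:05d}",) for i in range(self.n_blocks)
            )
        if len(self.pathway_scheme) != self.n_blocks:
            raise ValueError("pathway_scheme length must equal n_blocks")

    @property
    def n_genes(self) -> int:
        return sum(self.block_sizes)

    def block_of(self) -> list[int]:
        out: list[int] = []
        for i, size in enumerate(self.block_sizes):
            out.extend([i] * size)
        return out


def _target_correlation(
    sizes: Sequence[int], rho_in_per_block: Sequence[float], rho_out: float
) -> np.ndarray:
    n = sum(sizes)
    c = np.full((n, n), rho_out, dtype=float)
    start = 0
    for size, rho in zip(sizes, rho_in_per_block):
        c[start : start + size, start : start + size] = rho
        start += size
    np.fill_diagonal(c, 1.0)
    return c


def _psd_sqrt(c: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(c)
    if w.min() < _PSD_TOL:
        raise ValueError(
            f"target correlation is not positive semidefinite (min eig {w.min():.3g})"
        )
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T


def generate(
    spec: SyntheticSpec,
) -> tuple[dict[str, ExpressionMatrix], Partition, PathwayAnnotation]:
    """Sample both conditions; return matrices, truth partition, annotation.

    Deterministic: the same spec (including seed) yields bit-identical
    matrices. Raises before sampling if a target correlation matrix is not
    (numerically) positive semidefinite.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"g{i:04d}" for i in range(spec.n_genes)]
    blocks = spec.block_of()

    rho_a = [spec.rho_in] * spec.n_blocks
    rho_b = [
        spec.rho_in_b if i in set(spec.decorrelated_blocks) else spec.rho_in
        for i in range(spec.n_blocks)
    ]
    roots = {
        spec.condition_a: _psd_sqrt(
            _target_correlation(spec.block_sizes, rho_a, spec.rho_out)
        ),
        spec.condition_b: _psd_sqrt(
            _target_correlation(spec.block_sizes, rho_b, spec.rho_out)
        ),
    }
    n_samples = {spec.condition_a: spec.n_samples_a, spec.condition_b: spec.n_samples_b}

    exprs: dict[str, ExpressionMatrix] = {}
    for cond in (spec.condition_a, spec.condition_b):
        z = rng.standard_normal((spec.n_genes, n_samples[cond]))
        x = roots[cond] @ z
        if spec.noise_sd > 0:
            x = x + spec.noise_sd * rng.standard_normal(x.shape)
        samples = [f"{cond}_s{j:03d}" for j in range(n_samples[cond])]
        exprs[cond] = ExpressionMatrix(
            values=pd.DataFrame(x, index=gene_ids, columns=samples),
            conditions={s: cond for s in samples},
        )

    truth = Partition(
        assignment=dict(zip(gene_ids, blocks)), k=spec.n_blocks
    )
    gene_to_pathways = {
        g: frozenset(spec.pathway_scheme[b]) for g, b in zip(gene_ids, blocks)
    }
    names = {
        p: f"Synthetic pathway {p}" for ps in spec.pathway_scheme for p in ps
    }
    annotation = PathwayAnnotation(gene_to_pathways=gene_to_pathways, names=names)
    return exprs, truth, annotation


def evaluate_recovery(found: Partition, truth: Partition) -> float:
    """Adjusted Rand index between two partitions of the same vertex set."""
    if set(found.assignment) != set(truth.assignment):
        raise ValueError("partitions cover different vertex sets")
    order = sorted(found.assignment, key=str)
    a = [found.assignment[v] for v in order]
    b = [truth.assignment[v] for v in order]
    return float(adjusted_rand_score(b, a))


def write_synthetic(
    spec: SyntheticSpec, outdir: str | Path
) -> dict[str, Path]:
    """Write expression TSVs, label/truth/annotation TSVs for a spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exprs, truth, ann = generate(spec)
    paths: dict[str, Path] = {}
    labels: list[tuple[str, str]] = []
    for cond, expr in exprs.items():
        p = outdir / f"expression_{cond}.tsv"
        expr.values.to_csv(p, sep="\t", index_label="gene")
        paths[f"expression_{cond}"] = p
        labels.extend((s, cond) for s in expr.sample_ids)
    combined = pd.concat([exprs[c].values for c in exprs], axis=1)
    paths["expression"] = outdir / "expression.tsv"
    combined.to_csv(paths["expression"], sep="\t", index_label="gene")
    paths["labels"] = outdir / "labels.tsv"
    pd.DataFrame(labels).to_csv(paths["labels"], sep="\t", index=False, header=False)
    paths["truth"] = outdir / "truth_partition.tsv"
    pd.DataFrame(
        sorted(truth.assignment.items()), columns=["gene", "community_id"]
    ).to_csv(paths["truth"], sep="\t", index=False)
    rows = [
        (g, p, ann.names.get(p, ""))
        for g, ps in sorted(ann.gene_to_pathways.items())
        for p in sorted(ps)
    ]
    paths["annotations"] = outdir / "annotations.tsv"
    pd.DataFrame(rows).to_csv(paths["annotations"], sep="\t", index=False, header=False)
    return paths
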