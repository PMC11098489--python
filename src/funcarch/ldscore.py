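"""Partitioned LD scores from a reference panel.

The LD score of SNP j with respect to annotation class C,

    ℓ(j, C) = Σ_{k in window(j), k ∈ C}  adj_r²(r²_jk, n_ref),

sums the (bias-adjusted) squared sample correlation between SNP j and every
class-C SNP within a physical window on the same chromosome, including the
self term (adjusted self r² = 1 exactly).  The adjustment

    adj_r²(r², n) = r² − (1 − r²)/(n − 2)

removes the finite-reference-sample inflation of r², so that scores are
unbiased; small negative entries are expected and permitted.

Chromosomes are processed independently (no cross-chromosome LD); the
window is a fixed ±``window_bp`` physical window, symmetric by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import AnnotationMatrix
from .simdata import SnpPanel

__all__ = ["PartitionedLDScores", "adjusted_r2", "partitioned_ld_scores",
           "read_ldscores", "write_ldscores"]

DEFAULT_WINDOW_BP = 1_000_000


@dataclass
class PartitionedLDScores:
    """Per-SNP LD score vector per class plus provenance of its computation."""

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    class_names: list[str]
    scores: np.ndarray  # M x C
    window_bp: int
    n_ref: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.snp_id), len(self.class_names)):
            raise ValueError("LD score matrix shape mismatch")
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite LD scores")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.class_names)
        df.insert(0, "BP", self.pos)
        df.insert(0, "CHR", self.chrom)
        df.insert(0, "SNP", self.snp_id)
        return df


def adjusted_r2(r2, n_ref: int):
    """Unbiased adjustment of a squared sample correlation.

    For independent variables E[r²] = 1/(n−1); subtracting (1 − r²)/(n − 2)
    makes the expectation zero while leaving perfect LD (r² = 1) unchanged.
    """
    if n_ref <= 2:
        raise ValueError("n_ref must exceed 2 for the r² adjustment")
    r2 = np.asarray(r2, dtype=float)
    out = r2 - (1.0 - r2) / (n_ref - 2)
    return float(out) if out.ndim == 0 else out


def partitioned_ld_scores(
    panel: SnpPanel,
    annot: AnnotationMatrix,
    window_bp: int = DEFAULT_WINDOW_BP,
    chunk: int = 256,
) -> PartitionedLDScores:
    """Compute ℓ(j, C) for every panel SNP and annotation class.

    Windows are |pos_k − pos_j| ≤ ``window_bp`` on the same chromosome
    (symmetric: k is in j's window iff j is in k's).  Genotypes are
    standardized per SNP on the reference panel before correlation.
    Computation is blocked over column chunks so only an O(chunk × window)
    correlation slab is in memory at a time.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if annot.n_snps != panel.M or not (annot.snp_ids == panel.snp_id).all():
        raise ValueError("annotation matrix does not align with panel SNPs")
    n_ref = panel.n_ref
    A = annot.matrix.astype(np.float64)
    scores = np.empty((panel.M, A.shape[1]))
    for c in np.unique(panel.chrom):
        idx = np.where(panel.chrom == c)[0]
        pos = panel.pos[idx]
        order = np.argsort(pos, kind="stable")
        idx = idx[order]
        pos = pos[order]
        X = panel.genotypes[:, idx].astype(np.float64)
        X -= X.mean(axis=0)
        X /= X.std(axis=0)
        Ac = A[idx]
        lo = np.searchsorted(pos, pos - window_bp, side="left")
        hi = np.searchsorted(pos, pos + window_bp, side="right")
        m = idx.size
        for j0 in range(0, m, chunk):
            j1 = min(j0 + chunk, m)
            w0 = int(lo[j0:j1].min())
            w1 = int(hi[j0:j1].max())
            r = X[:, j0:j1].T @ X[:, w0:w1] / n_ref
            cols = np.arange(w0, w1)
            # pin the self term: r_jj = 1 exactly, immune to rounding
            self_mask = np.arange(j0, j1)[:, None] == cols[None, :]
            r[self_mask] = 1.0
            r2a = adjusted_r2(r**2, n_ref)
            mask = (cols[None, :] >= lo[j0:j1, None]) & (cols[None, :] < hi[j0:j1, None])
            scores[idx[j0:j1]] = (r2a * mask) @ Ac[w0:w1]
    return PartitionedLDScores(
        snp_id=panel.snp_id.copy(),
        chrom=panel.chrom.copy(),
        pos=panel.pos.copy(),
        class_names=list(annot.class_names),
        scores=scores,
        window_bp=window_bp,
        n_ref=n_ref,
    )


def write_ldscores(ldsc: PartitionedLDScores, path: str | Path) -> None:
    df = ldsc.to_frame()
    df.attrs = {}
    header = df.to_csv(sep="\t", index=False)
    with open(path, "w") as fh:
        fh.write(f"# window_bp={ldsc.window_bp}\tn_ref={ldsc.n_ref}\n")
        fh.write(header)


def read_ldscores(path: str | Path) -> PartitionedLDScores:
    window_bp, n_ref = DEFAULT_WINDOW_BP, 0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        fields = dict(kv.split("=") for kv in first[1:].split())
        window_bp = int(fields.get("window_bp", window_bp))
        n_ref = int(fields.get("n_ref", n_ref))
    df = pd.read_csv(path, sep="\t", comment="#")
    names = [c for c in df.columns if c not in ("SNP", "CHR", "BP")]
    return PartitionedLDScores(
        snp_id=df.SNP.to_numpy(),
        chrom=df.CHR.to_numpy(),
        pos=df.BP.to_numpy(),
        class_names=names,
        scores=df[names].to_numpy(),
        window_bp=window_bp,
        n_ref=n_ref,
    )
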