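"""Stratified LD-score regression (S-LDSR) on GWAS summary statistics.

Fits the stratified model

    E[χ²_j] = N Σ_C τ_C ℓ(j, C) + intercept

by weighted least squares, where ℓ(j, C) are partitioned LD scores and τ_C
is the per-SNP per-class variance coefficient.  From the fitted τ the
module completes the heritability partition: for possibly overlapping
classes the per-SNP variance is v_j = Σ_{C∋j} τ_C, and

    h²(C)       = Σ_{j∈C} v_j
    prop_h2(C)  = h²(C) / h²(base)
    enrichment  = prop_h2(C) / proportion_of_snps(C).

The base class has enrichment and proportion exactly 1 by construction.
Standard errors for every reported quantity come from a delete-one-block
jackknife over contiguous SNP blocks, applied to the quantity itself (not
via the delta method).  Estimates are unbiased and may be negative when a
class's true contribution is small relative to its sampling noise.

Two data hygiene steps accompany the regression: winsorisation of extreme
chi-squares (default cap 22), which limits the leverage of the strongly
right-skewed tail of GWAS effect sizes, and exclusion of configured
high-LD regions, handled upstream in :func:`funcarch.annotate.filter_snps`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import AnnotationMatrix
from .ldscore import PartitionedLDScores

logger = logging.getLogger(__name__)

__all__ = [
    "SumStats",
    "HeritabilityPartition",
    "winsorise_chisq",
    "fit_sldsr",
    "partition_heritability",
    "read_sumstats",
    "write_sumstats",
    "read_results",
]

DEFAULT_WINSOR_CAP = 22.0
DEFAULT_N_BLOCKS = 200


@dataclass
class SumStats:
    """Per-SNP GWAS association statistics for one phenotype."""

    snp_id: np.ndarray
    n: float | np.ndarray  # scalar sample size, or per-SNP
    chisq: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id)
        self.chisq = np.asarray(self.chisq, dtype=float)
        if len(np.unique(self.snp_id)) != len(self.snp_id):
            raise ValueError("duplicate SNP ids in summary statistics")
        if (self.chisq < 0).any() or not np.isfinite(self.chisq).all():
            raise ValueError("chisq must be finite and >= 0")
        if not np.isscalar(self.n):
            self.n = np.asarray(self.n, dtype=float)
            if self.n.shape != self.chisq.shape:
                raise ValueError("per-SNP N length mismatch")
        if np.min(self.n) <= 1:
            raise ValueError("N must exceed 1")

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def n_per_snp(self) -> np.ndarray:
        if np.isscalar(self.n):
            return np.full(self.n_snps, float(self.n))
        return self.n


def winsorise_chisq(stats: SumStats, cap: float = DEFAULT_WINSOR_CAP) -> SumStats:
    """Cap chi-square statistics at ``cap``; never changes the SNP count.

    The default cap of 22 corresponds to a strongly genome-wide-significant
    single-SNP P value; capping prevents a handful of huge association
    peaks from dominating the least-squares fit.
    """
    if cap <= 0:
        raise ValueError("winsorisation cap must be positive")
    capped = int((stats.chisq > cap).sum())
    if capped:
        logger.info("winsorised %d of %d chi-square values at %.3g",
                    capped, stats.n_snps, cap)
    return SumStats(stats.snp_id.copy(), stats.n, np.minimum(stats.chisq, cap))


def winsor_cap_from_p(p: float) -> float:
    """Chi-square (1 df) cap equivalent to a two-sided P-value threshold."""
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    return float(sps.chi2.isf(p, df=1))


@dataclass
class HeritabilityPartition:
    """Per-class τ, h², proportions, enrichments and jackknife SEs."""

    class_names: list[str]
    tau: np.ndarray
    se_tau: np.ndarray
    intercept: float
    se_intercept: float
    h2: np.ndarray
    se_h2: np.ndarray
    prop_h2: np.ndarray
    se_prop: np.ndarray
    prop_snps: np.ndarray
    enrichment: np.ndarray
    se_enrich: np.ndarray
    n_blocks: int
    n_snps: int

    @property
    def h2_total(self) -> float:
        return float(self.h2[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.class_names,
                "tau": self.tau,
                "se_tau": self.se_tau,
                "h2": self.h2,
                "se_h2": self.se_h2,
                "prop_h2": self.prop_h2,
                "se_prop": self.se_prop,
                "prop_snps": self.prop_snps,
                "enrichment": self.enrichment,
                "se_enrich": self.se_enrich,
            }
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# intercept={self.intercept!r}\tse_intercept={self.se_intercept!r}"
                f"\tn_snps={self.n_snps}\tn_blocks={self.n_blocks}\n"
            )
            self.to_frame().to_csv(fh, index=False)


def partition_heritability(
    tau: np.ndarray,
    annot: AnnotationMatrix,
    cross: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complete (h², prop_h2, enrichment) from fitted τ.

    ``cross`` may supply the precomputed class co-membership matrix AᵀA.
    Proportions are undefined (NaN, with a warning) when total h² <= 0 —
    unbiased regression estimates can be negative.
    """
    if cross is None:
        A = annot.matrix.astype(float)
        cross = A.T @ A
    h2 = cross @ np.asarray(tau, dtype=float)
    total = h2[0]
    if total <= 0:
        warnings.warn("total h² estimate <= 0; proportions undefined")
        prop = np.full_like(h2, np.nan)
    else:
        prop = h2 / total
    enrich = prop / annot.proportion_of_snps
    return h2, prop, enrich


def _collinear_pairs(design: np.ndarray, names: list[str]) -> list[tuple[str, str]]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant columns
        c = np.corrcoef(design, rowvar=False)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(c[i, j]) > 1 - 1e-10:
                pairs.append((names[i], names[j]))
    return pairs


def fit_sldsr(
    stats: SumStats,
    ldsc: PartitionedLDScores,
    annot: AnnotationMatrix,
    n_blocks: int = DEFAULT_N_BLOCKS,
    weighting: str = "two-pass",
) -> HeritabilityPartition:
    """Fit the stratified regression and jackknife every reported quantity.

    SNPs are intersected by id across summary statistics and LD scores
    (keeping genomic order); the heritability partition itself aggregates
    over the full annotation matrix.  ``weighting="two-pass"`` uses
    1/max(1, ℓ_base) weights in a first pass and adds heteroskedasticity
    weighting 1/(2·fitted²) from the pass-1 fitted means; ``"ols"`` uses
    unit weights (useful for closed-form checks).
    """
    if weighting not in {"two-pass", "ols"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    if ldsc.class_names != annot.class_names:
        raise ValueError("LD score classes do not match annotation classes")
    idx = pd.Index(ldsc.snp_id)
    loc = idx.get_indexer(stats.snp_id)
    if (loc < 0).all():
        raise ValueError("no SNPs shared between sumstats and LD scores")
    keep = loc >= 0
    order = np.argsort(loc[keep], kind="stable")
    stat_rows = np.where(keep)[0][order]
    ld_rows = loc[keep][order]
    m = ld_rows.size
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if n_blocks > m:
        raise ValueError(f"n_blocks={n_blocks} exceeds {m} regression SNPs")

    ell = ldsc.scores[ld_rows]  # m x C
    chisq = stats.chisq[stat_rows]
    n_snp = stats.n_per_snp()[stat_rows]
    C = ell.shape[1]
    names = list(annot.class_names)

    design = np.column_stack([n_snp[:, None] * ell, np.ones(m)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        pairs = _collinear_pairs(design[:, :C], names)
        raise ValueError(
            "singular regression design; collinear classes: "
            + (", ".join(f"{a}~{b}" for a, b in pairs) if pairs else "rank deficient")
        )

    w = 1.0 / np.maximum(1.0, ell[:, 0])
    if weighting == "ols":
        w = np.ones(m)

    def wls(weights: np.ndarray) -> np.ndarray:
        sw = np.sqrt(weights)
        theta, *_ = np.linalg.lstsq(design * sw[:, None], chisq * sw, rcond=None)
        return theta

    theta = wls(w)
    if weighting == "two-pass":
        fitted = design @ theta
        w = w / (2.0 * np.maximum(fitted, 0.1) ** 2)
        theta = wls(w)

    # delete-one-block jackknife via per-block sufficient statistics
    sw = np.sqrt(w)
    Xw = design * sw[:, None]
    yw = chisq * sw
    xtx = Xw.T @ Xw
    xty = Xw.T @ yw
    bounds = np.linspace(0, m, n_blocks + 1).astype(int)
    A = annot.matrix.astype(float)
    cross = A.T @ A
    prop_snps = annot.proportion_of_snps

    theta = np.linalg.solve(xtx, xty)
    tau_full, intercept = theta[:C], float(theta[C])
    h2_full, prop_full, enr_full = partition_heritability(tau_full, annot, cross)

    g = n_blocks
    delete_theta = np.empty((g, C + 1))
    for b in range(g):
        s = slice(bounds[b], bounds[b + 1])
        xtx_b = Xw[s].T @ Xw[s]
        xty_b = Xw[s].T @ yw[s]
        delete_theta[b] = np.linalg.solve(xtx - xtx_b, xty - xty_b)

    def jack_se(full_vals: np.ndarray, delete_vals: np.ndarray) -> np.ndarray:
        pseudo = g * full_vals[None, :] - (g - 1) * delete_vals
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.sqrt(np.nanvar(pseudo, axis=0, ddof=1) / g)

    se_theta = jack_se(theta, delete_theta)
    delete_h2 = np.empty((g, C))
    delete_prop = np.empty((g, C))
    delete_enr = np.empty((g, C))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(g):
            h2b, pb, eb = partition_heritability(delete_theta[b, :C], annot, cross)
            delete_h2[b], delete_prop[b], delete_enr[b] = h2b, pb, eb
    se_h2 = jack_se(h2_full, delete_h2)
    se_prop = jack_se(prop_full, delete_prop)
    se_enr = jack_se(enr_full, delete_enr)
    # base proportion and enrichment are identically 1; their SE is 0
    se_prop[0] = 0.0
    se_enr[0] = 0.0

    return HeritabilityPartition(
        class_names=names,
        tau=tau_full,
        se_tau=se_theta[:C],
        intercept=intercept,
        se_intercept=float(se_theta[C]),
        h2=h2_full,
        se_h2=se_h2,
        prop_h2=prop_full,
        se_prop=se_prop,
        prop_snps=prop_snps,
        enrichment=enr_full,
        se_enrich=se_enr,
        n_blocks=g,
        n_snps=m,
    )


# ---------------------------------------------------------------------------
# I/O


def read_sumstats(path: str | Path) -> SumStats:
    """Read a `SNP  N  CHISQ` TSV; a `Z` column is accepted and squared."""
    df = pd.read_csv(path, sep=r"\s+")
    cols = {c.upper(): c for c in df.columns}
    if "SNP" not in cols or "N" not in cols:
        raise ValueError("sumstats file must have SNP and N columns")
    if "CHISQ" in cols:
        chisq = df[cols["CHISQ"]].to_numpy(dtype=float)
    elif "Z" in cols:
        chisq = df[cols["Z"]].to_numpy(dtype=float) ** 2
    else:
        raise ValueError("sumstats file must have a CHISQ or Z column")
    n = df[cols["N"]].to_numpy(dtype=float)
    n_field: float | np.ndarray = float(n[0]) if (n == n[0]).all() else n
    return SumStats(df[cols["SNP"]].to_numpy(), n_field, chisq)


def write_sumstats(stats: SumStats, path: str | Path) -> None:
    pd.DataFrame(
        {"SNP": stats.snp_id, "N": stats.n_per_snp(), "CHISQ": stats.chisq}
    ).to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a per-class results CSV written by ``HeritabilityPartition.write``."""
    df = pd.read_csv(path, comment="#")
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for kv in first[1:].strip().split("\t"):
            k, v = kv.split("=")
            df.attrs[k] = float(v) if "." in v or "e" in v or "nan" in v else int(v)
    return df
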