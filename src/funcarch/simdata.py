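"""Synthetic data with known partitioned genetic architecture.

Every downstream stage of the pipeline (annotation, LD scores, stratified
regression, empirical Bayes, architecture comparison) is exercised against
data generated here under a known truth:

* **Reference panels** — diploid genotypes from a Gaussian-copula threshold
  model.  Each haplotype is a latent first-order autoregressive Gaussian
  within LD blocks (correlation ``rho`` between adjacent SNPs, independence
  across blocks), dichotomised at the quantile matching the SNP's allele
  frequency and summed over two haplotypes.  This gives tunable, analytically
  checkable block LD: realized r² decays monotonically with intra-block lag
  and is noise-level across blocks.
* **Annotations** — random interval classes grown until their realized SNP
  coverage hits a target proportion, plus a synthetic conservation track.
* **GWAS summary statistics** — per-SNP effects β_j ~ N(0, Σ_{C∋j} τ_C) on
  the standardized genotype scale, an explicitly simulated cohort of
  ``n_gwas`` individuals drawn from the same LD process, phenotype = genetic
  value + noise scaled to unit variance, and 1-df marginal score-test
  chi-squares χ²_j = N·r²(g_j, y).  LD-induced inflation of χ² therefore
  arises mechanistically, exactly as the stratified regression model assumes:
  E[χ²_j] = N Σ_C τ_C ℓ(j,C) + 1.  Under the null all τ_C = 0 and
  E[χ²] = 1; with no LD, mean χ² ≈ 1 + N·h²/M.
* **Architecture profiles** — phenotype × class matrices as group mean +
  Gaussian noise, the test bed for the MDS / discriminant stage.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import (
    AnnotationMatrix,
    BASE_CLASS,
    ConservationTrack,
    IntervalSet,
    build_annotation_matrix,
)

__all__ = [
    "ClassSpec",
    "SimConfig",
    "SnpPanel",
    "AnnotationBundle",
    "generate_panel",
    "generate_annotations",
    "simulate_sumstats",
    "generate_architecture_profiles",
    "read_panel",
    "write_panel",
]


@dataclass(frozen=True)
class ClassSpec:
    """One simulated annotation class: name, target SNP coverage, per-SNP τ."""

    name: str
    coverage: float
    tau: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError(f"class {self.name!r}: coverage must be in [0, 1]")
        if not np.isfinite(self.tau):
            raise ValueError(f"class {self.name!r}: tau must be finite")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Parameters
    ----------
    M : number of SNPs.
    n_ref : LD reference-panel size (individuals).
    n_gwas : GWAS cohort size N.
    block_len : SNPs per independent LD block.
    rho : adjacent-SNP latent correlation within a block, in [0, 1).
    class_spec : simulated annotation classes.  A class named ``base`` sets
        the baseline per-SNP τ applied to every SNP; other classes add their
        τ on top for member SNPs.  Total implied h² must stay below 1.
    maf_range : allele frequencies drawn uniformly from this range.
    spacing_bp : physical distance between adjacent SNPs (one chromosome).
    seed : RNG seed; identical configs with identical seeds reproduce bit-
        identical data.
    """

    M: int
    n_ref: int
    n_gwas: int
    block_len: int = 20
    rho: float = 0.8
    class_spec: tuple[ClassSpec, ...] = ()
    maf_range: tuple[float, float] = (0.05, 0.5)
    spacing_bp: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 2 or self.n_ref < 2 or self.n_gwas < 2:
            raise ValueError("M, n_ref and n_gwas must all be >= 2")
        if self.block_len < 1:
            raise ValueError("block_len must be >= 1")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        names = [c.name for c in self.class_spec]
        if len(set(names)) != len(names):
            raise ValueError("duplicate class names in class_spec")
        h2 = self.implied_h2()
        if not (0.0 <= h2 < 1.0):
            raise ValueError(f"implied h² = {h2:.3f} outside [0, 1)")

    def implied_h2(self) -> float:
        """Expected total h² = Σ_j Σ_{C∋j} τ_C under target coverages."""
        return self.M * sum(
            c.tau * (1.0 if c.name == BASE_CLASS else c.coverage)
            for c in self.class_spec
        )


@dataclass
class SnpPanel:
    """A diploid genotype panel used as the LD reference.

    ``genotypes`` is n_ref × M with entries in {0, 1, 2}; positions are
    strictly increasing within each chromosome; every SNP is polymorphic.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    genotypes: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes)
        self.maf = np.asarray(self.maf, dtype=float)
        M = len(self.snp_id)
        if self.genotypes.shape[1] != M or self.pos.shape[0] != M:
            raise ValueError("panel field lengths disagree")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on chrom {c}")
        g = self.genotypes
        if g.min() < 0 or g.max() > 2:
            raise ValueError("genotype entries must be 0/1/2")
        freq = g.mean(axis=0) / 2.0
        if (freq <= 0).any() or (freq >= 1).any():
            raise ValueError("monomorphic SNP in panel")
        if (self.maf <= 0).any() or (self.maf > 0.5).any():
            raise ValueError("maf must lie in (0, 0.5]")

    @property
    def n_ref(self) -> int:
        return self.genotypes.shape[0]

    @property
    def M(self) -> int:
        return self.genotypes.shape[1]

    def standardized(self) -> np.ndarray:
        """Genotypes centered and scaled to unit sample variance (float64)."""
        g = self.genotypes.astype(np.float64)
        g -= g.mean(axis=0)
        sd = g.std(axis=0)
        return g / sd


def _ar1_chol(block_len: int, rho: float) -> np.ndarray:
    idx = np.arange(block_len)
    cov = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(cov)


def _haplotypes(
    rng: np.random.Generator,
    n: int,
    M: int,
    block_len: int,
    rho: float,
    thresholds: np.ndarray,
) -> np.ndarray:
    """One haplotype matrix (n × M, uint8) from the latent AR(1) block model."""
    n_blocks = -(-M // block_len)
    width = n_blocks * block_len
    # float32 latents: they are only compared against a threshold
    z = rng.standard_normal((n, width), dtype=np.float32)
    if rho > 0 and block_len > 1:
        L = _ar1_chol(block_len, rho).astype(np.float32)
        z = (z.reshape(n * n_blocks, block_len) @ L.T).reshape(n, width)
    return (z[:, :M] > thresholds.astype(np.float32)).astype(np.uint8)


def _draw_genotypes(
    rng: np.random.Generator,
    n: int,
    M: int,
    block_len: int,
    rho: float,
    freq: np.ndarray,
    row_chunk: int = 4096,
) -> np.ndarray:
    """Diploid genotypes, generated in row chunks to bound peak memory."""
    thresholds = sps.norm.ppf(1.0 - freq)
    out = np.empty((n, M), dtype=np.int8)
    for lo in range(0, n, row_chunk):
        hi = min(lo + row_chunk, n)
        h1 = _haplotypes(rng, hi - lo, M, block_len, rho, thresholds)
        h2 = _haplotypes(rng, hi - lo, M, block_len, rho, thresholds)
        out[lo:hi] = (h1 + h2).astype(np.int8)
    return out


def generate_panel(config: SimConfig) -> SnpPanel:
    """Draw the LD reference panel for the given study conditions.

    Deterministic given ``config.seed``; monomorphic columns (possible only
    for tiny panels) are redrawn so the panel invariant holds.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    lo, hi = config.maf_range
    freq = rng.uniform(lo, hi, size=config.M)
    g = _draw_genotypes(
        rng, config.n_ref, config.M, config.block_len, config.rho, freq
    )
    # redraw any monomorphic columns (prob ~ (1-2f)^{2 n_ref}, negligible
    # except for toy panels)
    for _ in range(100):
        mono = (g == g[0]).all(axis=0)
        if not mono.any():
            break
        cols = np.where(mono)[0]
        thr = sps.norm.ppf(1.0 - freq[cols])
        h1 = rng.standard_normal((config.n_ref, cols.size)) > thr
        h2 = rng.standard_normal((config.n_ref, cols.size)) > thr
        g[:, cols] = (h1.astype(np.int8) + h2.astype(np.int8))
    else:
        raise RuntimeError("could not make all SNPs polymorphic")
    pos = config.spacing_bp * (1 + np.arange(config.M, dtype=np.int64))
    return SnpPanel(
        snp_id=np.array([f"rs{i}" for i in range(config.M)]),
        chrom=np.ones(config.M, dtype=np.int64),
        pos=pos,
        genotypes=g,
        maf=freq,
    )


@dataclass
class AnnotationBundle:
    """Interval classes, the SNP membership matrix, and a conservation track."""

    interval_sets: dict[str, IntervalSet]
    matrix: AnnotationMatrix
    conservation: ConservationTrack


def generate_annotations(
    panel: SnpPanel,
    config: SimConfig,
    tolerance: float = 0.01,
) -> AnnotationBundle:
    """Random interval classes with realized SNP coverage near target.

    For each class, intervals spanning short runs of consecutive SNPs are
    added until the realized coverage is within ``tolerance`` of the target
    (exact for targets 0 and 1).  Also emits a synthetic conservation track
    (uniform scores over random intervals) so the annotation-derivation
    operations have an input.  The ``base`` entry of ``class_spec`` has no
    intervals; it is realized as the all-ones column of the matrix.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    pos = panel.pos
    chrom = panel.chrom
    M = panel.M
    sets: dict[str, IntervalSet] = {}
    for spec in config.class_spec:
        if spec.name == BASE_CLASS:
            continue
        target = spec.coverage
        if target > 1.0:
            raise ValueError(f"coverage target {target} unreachable")
        if target >= 1.0:
            ivs = [
                (str(c), int(pos[chrom == c].min()) - 1, int(pos[chrom == c].max()))
                for c in np.unique(chrom)
            ]
            sets[spec.name] = IntervalSet(spec.name, tuple(ivs)).normalized()
            continue
        covered = np.zeros(M, dtype=bool)
        goal = int(round(target * M))
        cap = int(np.floor((target + tolerance) * M))
        ivs = []
        while covered.sum() < max(goal, 1) and target > 0:
            start = int(rng.integers(0, M))
            run = int(min(1 + rng.geometric(0.4), max(1, cap - covered.sum())))
            stop = min(start + run, M)
            if chrom[start] != chrom[stop - 1]:  # clip runs to one chromosome
                stop = start + int(np.argmax(chrom[start:stop] != chrom[start]))
            if covered[start:stop].all():
                continue
            covered[start:stop] = True
            ivs.append((str(chrom[start]), int(pos[start]) - 1, int(pos[stop - 1])))
        sets[spec.name] = IntervalSet(spec.name, tuple(ivs)).normalized()
    matrix = build_annotation_matrix(panel, list(sets.values()))
    # synthetic conservation: random non-overlapping scored windows
    span = int(pos.max())
    n_iv = max(1, M // 2)
    cuts = np.sort(rng.integers(1, span, size=2 * n_iv))
    starts, ends = cuts[0::2], cuts[1::2]
    keep = starts < ends  # drop zero-length; sorted cuts cannot overlap
    starts, ends = starts[keep], ends[keep]
    scores = rng.uniform(0.0, 1.0, size=starts.size)
    track = ConservationTrack(
        "synthetic_cons",
        tuple(
            (str(chrom[0]), int(s), int(e), float(v))
            for s, e, v in zip(starts, ends, scores)
        ),
    )
    return AnnotationBundle(sets, matrix, track)


def simulate_sumstats(
    panel: SnpPanel,
    annot: AnnotationMatrix,
    config: SimConfig,
    return_truth: bool = False,
):
    """GWAS summary statistics from an explicitly simulated cohort.

    Effects are drawn per SNP with variance Σ_{C∋j} τ_C (standardized
    genotype scale); a fresh cohort of ``config.n_gwas`` individuals is
    drawn from the same LD process as the panel; the phenotype is the
    genetic value plus Gaussian noise scaled so the phenotypic variance is
    1; per-SNP chi-squares are N·r² marginal score statistics.

    Returns a :class:`~funcarch.sldsr.SumStats`; with ``return_truth`` also
    returns a dict holding the drawn β and realized h².
    """
    from .sldsr import SumStats

    if annot.n_snps != panel.M or not (annot.snp_ids == panel.snp_id).all():
        raise ValueError("annotation matrix does not align with panel SNPs")
    tau = np.zeros(len(annot.class_names))
    by_name = {c.name: c.tau for c in config.class_spec}
    unknown = set(by_name) - set(annot.class_names)
    if unknown:
        raise ValueError(f"class_spec classes missing from annotation: {sorted(unknown)}")
    for i, name in enumerate(annot.class_names):
        tau[i] = by_name.get(name, 0.0)
    sigma2 = annot.matrix.astype(float) @ tau
    if (sigma2 < 0).any():
        raise ValueError("negative per-SNP effect variance implied by class_spec")
    h2_implied = float(sigma2.sum())
    if h2_implied >= 1.0:
        raise ValueError(f"implied h² = {h2_implied:.3f} >= 1")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 37]))
    beta = rng.standard_normal(panel.M) * np.sqrt(sigma2)
    cohort = _draw_genotypes(
        rng, config.n_gwas, panel.M, config.block_len, config.rho, panel.maf
    )
    n = config.n_gwas
    col_sum = cohort.sum(axis=0, dtype=np.int64)
    col_sq = np.einsum("ij,ij->j", cohort, cohort, dtype=np.int64)
    mean = col_sum / n
    var = col_sq / n - mean**2
    if (var <= 0).any():
        bad = int((var <= 0).sum())
        raise ValueError(f"{bad} monomorphic SNPs in simulated cohort; increase n_gwas")
    sd = np.sqrt(var)

    # genetic values on the standardized scale, computed in row chunks
    w = beta / sd
    gvalue = np.empty(n)
    chunk = 4096
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        gvalue[lo:hi] = cohort[lo:hi].astype(np.float64) @ w
    gvalue -= mean @ w
    noise_sd = np.sqrt(max(1.0 - h2_implied, 1e-12))
    y = gvalue + noise_sd * rng.standard_normal(n)

    gy = np.empty(panel.M)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        block = cohort[lo:hi].astype(np.float64).T @ y[lo:hi]
        if lo == 0:
            gy = block
        else:
            gy += block
    ybar = y.mean()
    yss = float(((y - ybar) ** 2).sum())
    corr = (gy - col_sum * ybar) / (np.sqrt(n * var) * np.sqrt(yss))
    chisq = n * corr**2

    stats = SumStats(snp_id=panel.snp_id.copy(), n=n, chisq=chisq)
    if return_truth:
        realized_h2 = float((beta**2).sum())
        return stats, {"beta": beta, "h2_implied": h2_implied, "h2_realized": realized_h2}
    return stats


def generate_architecture_profiles(
    n_per_group: int,
    group_means: Mapping[str, Sequence[float]],
    noise_sd: float,
    seed: int,
    class_names: Sequence[str] | None = None,
):
    """Phenotype × class profile matrix: group mean + iid Gaussian noise.

    The test bed for the architecture-comparison stage; rows get labels
    ``{group}_{i}`` and the given group assignments.
    """
    from .archcompare import ArchitectureMatrix

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    means = {g: np.asarray(v, dtype=float) for g, v in group_means.items()}
    dims = {v.shape for v in means.values()}
    if len(dims) != 1 or means and next(iter(dims)) == ():
        raise ValueError("group mean vectors must share one class dimension")
    C = next(iter(dims))[0]
    if class_names is None:
        class_names = [f"class_{j}" for j in range(C)]
    if len(class_names) != C:
        raise ValueError("class_names length does not match mean vectors")
    rng = np.random.default_rng(seed)
    rows, labels, groups = [], [], []
    for g, mu in means.items():
        noise = rng.standard_normal((n_per_group, C)) * noise_sd
        rows.append(mu[None, :] + noise)
        labels.extend(f"{g}_{i}" for i in range(n_per_group))
        groups.extend([g] * n_per_group)
    values = pd.DataFrame(np.vstack(rows), index=labels, columns=list(class_names))
    return ArchitectureMatrix(values=values, groups=pd.Series(groups, index=labels))


# ---------------------------------------------------------------------------
# panel I/O (SNP table TSV + plain genotype matrix)


def write_panel(panel: SnpPanel, snp_table: str | Path, genotype_file: str | Path) -> None:
    pd.DataFrame(
        {"snp_id": panel.snp_id, "chrom": panel.chrom, "pos": panel.pos,
         "maf": panel.maf}
    ).to_csv(snp_table, sep="\t", index=False)
    np.savetxt(genotype_file, panel.genotypes, fmt="%d")


def read_panel(snp_table: str | Path, genotype_file: str | Path) -> SnpPanel:
    df = pd.read_csv(snp_table, sep="\t")
    g = np.loadtxt(genotype_file, dtype=np.int8, ndmin=2)
    return SnpPanel(
        snp_id=df.snp_id.to_numpy(),
        chrom=df.chrom.to_numpy(),
        pos=df.pos.to_numpy(),
        genotypes=g,
        maf=df.maf.to_numpy(),
    )
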