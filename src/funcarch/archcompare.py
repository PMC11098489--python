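"""Comparing phenotypes' functional genetic architectures.

Given a phenotype × class matrix of (shrunken) heritability proportions or
enrichment ratios, this module

* computes an L1 (city-block) distance matrix between phenotypes — the sum
  over classes of absolute differences in estimated heritability;
* embeds the phenotypes in 2-D by Kruskal's non-metric MDS (iterative
  stress-1 minimization with monotone regression on dissimilarity ranks,
  initialized from classical Torgerson scaling);
* fits a Fisher linear discriminant between two phenotype groups
  (e.g. psychiatric/behavioral vs neurological) with a small ridge on the
  pooled covariance, and assesses it by leave-one-out cross-validation.

Discriminant weights are reportable per class: positive weights mark classes
whose elevated values push a phenotype toward the first group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "GROUPS",
    "ArchitectureMatrix",
    "MdsEmbedding",
    "DiscriminantModel",
    "l1_distance_matrix",
    "nonmetric_mds",
    "fit_discriminant",
    "loo_cross_validate",
]

GROUPS = ("psychiatric/behavioral", "neurological", "control/other")


@dataclass
class ArchitectureMatrix:
    """Phenotype × class values with per-phenotype group labels.

    ``values`` rows are phenotypes, columns are annotation classes;
    ``groups`` assigns each phenotype a label from a declared finite set
    (defaults to :data:`GROUPS`).
    """

    values: pd.DataFrame
    groups: pd.Series
    quantity: str = "prop_h2"
    allowed_groups: tuple[str, ...] = GROUPS

    def __post_init__(self) -> None:
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 phenotypes")
        if self.values.isna().any().any():
            raise ValueError("missing values in architecture matrix")
        if not self.groups.index.equals(self.values.index):
            self.groups = self.groups.reindex(self.values.index)
        if self.groups.isna().any():
            raise ValueError("every phenotype needs a group label")
        bad = set(self.groups) - set(self.allowed_groups)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def phenotypes(self) -> list[str]:
        return list(self.values.index)

    @property
    def class_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MdsEmbedding:
    coords: pd.DataFrame  # phenotype x 2
    stress: float  # Kruskal stress-1
    n_iter: int
    seed: int


@dataclass
class DiscriminantModel:
    class_names: list[str]
    weights: np.ndarray
    threshold: float
    group_positive: str  # group predicted when score > threshold
    group_negative: str
    ridge: float

    def score(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) @ self.weights - self.threshold

    def predict(self, values: np.ndarray) -> np.ndarray:
        s = self.score(values)
        return np.where(s > 0, self.group_positive, self.group_negative)


def l1_distance_matrix(arch: ArchitectureMatrix) -> pd.DataFrame:
    """d(i, k) = Σ_C |v_iC − v_kC|; symmetric, zero diagonal, a true metric."""
    v = arch.values.to_numpy(dtype=float)
    d = cdist(v, v, metric="cityblock")
    return pd.DataFrame(d, index=arch.values.index, columns=arch.values.index)


def _torgerson(d: np.ndarray, n_dim: int = 2) -> np.ndarray:
    """Classical (metric) scaling used to initialize the Kruskal iteration."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_dim]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)[None, :]


def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = float((dist**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist - disp) ** 2).sum() / denom))


def nonmetric_mds(
    distances: pd.DataFrame | np.ndarray,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> MdsEmbedding:
    """Kruskal non-metric MDS into 2 dimensions.

    Alternates monotone (pool-adjacent-violators) regression of embedded
    distances on dissimilarity ranks — ties handled by Kruskal's primary
    approach — with a Guttman majorization update of the configuration.
    Stress-1 is non-increasing across iterations and the run is
    deterministic given the init and seed.  An all-zero distance matrix is
    degenerate: returns coincident points with stress 0 and a warning.
    """
    if isinstance(distances, pd.DataFrame):
        labels = list(distances.index)
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        labels = [f"p{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if n < 3:
        raise ValueError("need at least 3 points")
    if (d < 0).any():
        raise ValueError("negative distances")
    iu = np.triu_indices(n, k=1)
    delta = d[iu]
    if (delta == 0).all():
        warnings.warn("all distances zero: returning coincident points")
        coords = pd.DataFrame(np.zeros((n, 2)), index=labels, columns=["dim1", "dim2"])
        return MdsEmbedding(coords, 0.0, 0, seed)

    rng = np.random.default_rng(seed)
    x = _torgerson(d)
    if np.allclose(x, 0):  # degenerate init (e.g. duplicated points): jitter
        x = rng.standard_normal((n, 2)) * 1e-3
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    prev_stress = np.inf
    stress = np.inf
    best_stress = np.inf
    best_x = x.copy()
    it = 0
    for it in range(1, max_iter + 1):
        dist = pdist(x)
        # primary tie treatment: within tied dissimilarities, order by the
        # current embedded distances so ties impose no constraint
        order = np.lexsort((dist, delta))
        fitted = iso.fit_transform(np.arange(delta.size), dist[order])
        disp = np.empty_like(fitted)
        disp[order] = fitted
        stress = _stress1(dist, disp)
        if stress < best_stress:
            best_stress, best_x = stress, x.copy()
        if prev_stress - stress < tol:
            break
        prev_stress = stress
        # Guttman transform
        dm = squareform(dist)
        ratio = np.zeros_like(dm)
        nz = dm > 0
        ratio[nz] = squareform(disp)[nz] / dm[nz]
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = b @ x / n
    coords = pd.DataFrame(best_x, index=labels, columns=["dim1", "dim2"])
    return MdsEmbedding(coords, float(best_stress), it, seed)


def _two_groups(arch: ArchitectureMatrix) -> tuple[str, str]:
    present = [g for g in arch.allowed_groups if (arch.groups == g).any()]
    if len(present) != 2:
        raise ValueError(
            f"discriminant needs exactly 2 groups present, found {present}"
        )
    return present[0], present[1]


def default_ridge(pooled_cov: np.ndarray) -> float:
    return 1e-3 * float(np.trace(pooled_cov)) / pooled_cov.shape[0]


def fit_discriminant(
    arch: ArchitectureMatrix,
    ridge: float | None = None,
) -> DiscriminantModel:
    """Fisher linear discriminant between the two groups present.

    w ∝ (Σ_pooled + ridge·I)⁻¹ (μ₁ − μ₂), threshold at the projected
    midpoint of the group means, weights oriented so the first declared
    group (psychiatric/behavioral by default) scores positive.  With ~20
    phenotypes and ~14 classes the pooled covariance is near-singular, so a
    small default ridge (1e−3·trace(Σ)/C) is applied; pass ``ridge=0`` to
    disable (duplicate class columns then raise, naming the collinearity).
    """
    g1, g2 = _two_groups(arch)
    v = arch.values.to_numpy(dtype=float)
    y = arch.groups.to_numpy()
    x1, x2 = v[y == g1], v[y == g2]
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs >= 2 members")
    mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
    pooled = (
        (len(x1) - 1) * np.cov(x1, rowvar=False)
        + (len(x2) - 1) * np.cov(x2, rowvar=False)
    ) / (len(x1) + len(x2) - 2)
    pooled = np.atleast_2d(pooled)
    if ridge is None:
        ridge = default_ridge(pooled)
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    sigma = pooled + ridge * np.eye(pooled.shape[0])
    try:
        cond = np.linalg.cond(sigma)
        if cond > 1e12:
            raise np.linalg.LinAlgError
        w = np.linalg.solve(sigma, mu1 - mu2)
    except np.linalg.LinAlgError:
        names = arch.class_names
        c = np.corrcoef(v, rowvar=False)
        pairs = [
            f"{names[i]}~{names[j]}"
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(c[i, j]) > 1 - 1e-10
        ]
        raise ValueError(
            "singular pooled covariance"
            + (f"; collinear classes: {', '.join(pairs)}" if pairs else "")
            + "; raise the ridge regularization"
        ) from None
    if not np.any(w):
        raise ValueError("degenerate discriminant: all weights zero")
    threshold = float(w @ (mu1 + mu2) / 2.0)
    if w @ mu1 < threshold:  # orient so group 1 scores positive
        w, threshold = -w, -threshold
    return DiscriminantModel(
        class_names=arch.class_names,
        weights=w,
        threshold=threshold,
        group_positive=g1,
        group_negative=g2,
        ridge=float(ridge),
    )


def loo_cross_validate(
    arch: ArchitectureMatrix,
    ridge: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Leave-one-out cross-validated group prediction.

    Refits the discriminant with each phenotype held out in turn and
    predicts its group; each group needs >= 3 members so every training
    fold keeps two.  Returns the per-phenotype prediction table and the
    overall accuracy.
    """
    g1, g2 = _two_groups(arch)
    counts = arch.groups.value_counts()
    if counts.get(g1, 0) < 3 or counts.get(g2, 0) < 3:
        raise ValueError("leave-one-out needs >= 3 phenotypes per group")
    preds = []
    for phen in arch.phenotypes:
        rest = ArchitectureMatrix(
            values=arch.values.drop(index=phen),
            groups=arch.groups.drop(index=phen),
            quantity=arch.quantity,
            allowed_groups=arch.allowed_groups,
        )
        model = fit_discriminant(rest, ridge=ridge)
        pred = model.predict(arch.values.loc[[phen]].to_numpy())[0]
        preds.append(pred)
    table = pd.DataFrame(
        {"group": arch.groups, "predicted": preds}, index=arch.phenotypes
    )
    accuracy = float((table.group == table.predicted).mean())
    return table, accuracy


# ---------------------------------------------------------------------------
# I/O


def read_architecture(
    values_csv: str | Path,
    metadata_tsv: str | Path,
    quantity: str = "prop_h2",
) -> ArchitectureMatrix:
    """Read a phenotype × class CSV plus a (phenotype, group) metadata TSV."""
    values = pd.read_csv(values_csv, index_col=0)
    meta = pd.read_csv(metadata_tsv, sep="\t").set_index("phenotype")
    groups = meta["group"].reindex(values.index)
    return ArchitectureMatrix(values=values, groups=groups, quantity=quantity)
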