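"""Community diversity statistics: alpha diversity, group tests, Bray-Curtis,
PCoA, PERMANOVA.

Conventions
-----------
* Shannon index in nats: ``H = -sum p ln p`` over species with p > 0.
* Simpson index is the Gini-Simpson form ``1 - sum p^2`` by default (the
  convention of the vegan family of tools); the dominance form ``sum p^2`` is
  available by flag.
* Bray-Curtis dissimilarity ``d(x, y) = sum|x - y| / sum(x + y)``.
* PCoA is classical scaling (double-centering + eigendecomposition).
  Bray-Curtis is non-Euclidean, so negative eigenvalues can appear; they are
  dropped from the axis-proportion denominator (logged) and no Cailliez
  correction is applied by default.
* PERMANOVA uses the pseudo-F from the among/within partition of squared
  distances with ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``,
  seed-controlled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import AnalysisError
from .io_formats import AbundanceTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    shannon: float      # nats; 0 <= H <= ln(k) for k observed species
    simpson: float      # Gini-Simpson, in [0, 1 - 1/k]


def alpha_diversity(table: AbundanceTable,
                    simpson_form: str = "gini") -> list[DiversityResult]:
    """Shannon and Simpson indices per sample.

    Requires normalized columns (sums 1); zero-abundance species are ignored,
    so the indices are invariant to padding the table with absent species.
    """
    if simpson_form not in ("gini", "dominance"):
        raise AnalysisError(f"unknown simpson_form {simpson_form!r}")
    out = []
    for sample in table.samples:
        p = table.sample_vector(sample)
        total = p.sum()
        if total <= 0:
            raise AnalysisError(f"all-zero sample {sample!r}")
        if abs(total - 1) > 1e-6:
            raise AnalysisError(f"sample {sample!r} not normalized "
                                f"(sum {total:.6g})")
        p = p[p > 0]
        shannon = float(-(p * np.log(p)).sum()) + 0.0   # avoid -0.0
        d = float((p * p).sum())
        simpson = 1.0 - d if simpson_form == "gini" else d
        out.append(DiversityResult(sample_id=sample, shannon=shannon,
                                   simpson=simpson))
    return out


def diversity_frame(results: Sequence[DiversityResult]) -> pd.DataFrame:
    return pd.DataFrame([(r.sample_id, r.shannon, r.simpson) for r in results],
                        columns=["sample_id", "shannon", "simpson"])


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    method: str                      # "anova_tukey" | "kruskal_dunn"
    statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's rank-based z tests with tie correction (no p adjustment)."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_rank = {}
    i = 0
    for g in names:
        k = len(groups[g])
        mean_rank[g] = ranks[i:i + k].mean()
        i += k
    _vals, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (12 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    out = {}
    for a, b in ((a, b) for i, a in enumerate(names) for b in names[i + 1:]):
        se = np.sqrt(var_base * (1 / len(groups[a]) + 1 / len(groups[b])))
        if se == 0:
            out[(a, b)] = 1.0
            continue
        z = (mean_rank[a] - mean_rank[b]) / se
        out[(a, b)] = float(2 * stats.norm.sf(abs(z)))
    return out


def group_compare(values: Sequence[float], labels: Sequence[str],
                  method: str = "auto", gate_alpha: float = 0.05,
                  bh_correct: bool = False,
                  pairwise: bool = True) -> GroupComparison:
    """Omnibus + pairwise comparison of one variable across >= 2 groups.

    ``auto`` gates on Shapiro-Wilk normality (per group) and Levene
    homogeneity at ``gate_alpha``; if both hold the route is one-way ANOVA
    with Tukey HSD pairwise, otherwise Kruskal-Wallis (tie-corrected H,
    chi-square approximation) with Dunn pairwise.  Groups of fewer than three
    observations cannot be normality-tested and take the rank route.  When
    every observation is identical, H = 0 and p = 1 (degenerate tie
    correction handled explicitly).  ``pairwise=False`` skips the post hoc
    tests (useful in calibration loops that only need the omnibus p).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise AnalysisError("values and labels must align")
    names = list(pd.unique(labels))
    groups = {g: values[labels == g] for g in names}
    if len(names) < 2:
        raise AnalysisError("need >= 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise AnalysisError(f"group {g!r} has < 2 observations")
    if method not in ("auto", "anova_tukey", "kruskal"):
        raise AnalysisError(f"unknown method {method!r}")
    if method == "auto":
        if all(len(v) >= 3 for v in groups.values()) and np.ptp(values) > 0:
            normal = all(stats.shapiro(v).pvalue > gate_alpha
                         for v in groups.values() if np.ptp(v) > 0)
            homo = stats.levene(*groups.values()).pvalue > gate_alpha
            method = "anova_tukey" if (normal and homo) else "kruskal"
        else:
            method = "kruskal"
    if method == "anova_tukey":
        f_stat, p = stats.f_oneway(*groups.values())
        pw = {}
        if pairwise:
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            tk = pairwise_tukeyhsd(values, labels, alpha=0.05)
            res = tk.summary().data[1:]
            pw = {(str(r[0]), str(r[1])): float(r[3]) for r in res}
        comp = GroupComparison(method="anova_tukey", statistic=float(f_stat),
                               p_value=float(p), pairwise=pw)
    else:
        if np.ptp(values) == 0:
            comp = GroupComparison(method="kruskal_dunn", statistic=0.0,
                                   p_value=1.0,
                                   pairwise={(str(a), str(b)): 1.0
                                             for i, a in enumerate(names)
                                             for b in names[i + 1:]})
        else:
            h_stat, p = stats.kruskal(*groups.values())
            comp = GroupComparison(
                method="kruskal_dunn", statistic=float(h_stat),
                p_value=float(p),
                pairwise=_dunn_pairwise(groups) if pairwise else {})
    if bh_correct and comp.pairwise:
        from statsmodels.stats.multitest import multipletests

        keys = list(comp.pairwise)
        _r, adj, _a, _b = multipletests([comp.pairwise[k] for k in keys],
                                        method="fdr_bh")
        comp.pairwise = dict(zip(keys, (float(x) for x in adj)))
    return comp


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between samples (square, symmetric,
    zero diagonal, values in [0, 1] for non-negative data)."""
    if isinstance(table, AbundanceTable):
        mat = table.values.T
        ids = table.samples
    else:
        mat = table.to_numpy(dtype=float).T
        ids = list(table.columns)
    if (mat < 0).any():
        raise AnalysisError("negative abundances")
    if (mat.sum(axis=1) == 0).sum() >= 2:
        raise AnalysisError("Bray-Curtis undefined between all-zero samples")
    d = squareform(pdist(mat, metric="braycurtis"))
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass
class OrdinationResult:
    """PCoA embedding: sample coordinates on the retained (positive-eigenvalue)
    axes, each axis's share of the positive-eigenvalue total, and optionally a
    PERMANOVA p-value for a grouping of the same samples."""

    coordinates: pd.DataFrame
    proportions: np.ndarray
    eigenvalues: np.ndarray
    permanova_p: float | None = None


def _check_distance_matrix(dm: pd.DataFrame | np.ndarray) -> np.ndarray:
    d = dm.to_numpy(dtype=float) if isinstance(dm, pd.DataFrame) else \
        np.asarray(dm, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise AnalysisError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise AnalysisError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise AnalysisError("distance matrix must have a zero diagonal")
    return d


def pcoa(dm: pd.DataFrame | np.ndarray, n_axes: int | None = None
         ) -> OrdinationResult:
    """Classical scaling of a distance matrix.

    Axes are ordered by eigenvalue; proportions are eigenvalues over the sum
    of *positive* eigenvalues only (negative eigenvalues from non-Euclidean
    dissimilarities are logged and excluded from the denominator).  On
    Euclidean input the embedding over all positive axes reproduces the
    distances to numerical precision.
    """
    d = _check_distance_matrix(dm)
    ids = (list(dm.index) if isinstance(dm, pd.DataFrame)
           else [f"s{i}" for i in range(d.shape[0])])
    n = d.shape[0]
    b = -0.5 * (d ** 2)
    b = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-10
    pos = eigval > tol
    if (eigval < -tol).any():
        logger.info("pcoa: %d negative eigenvalue(s) excluded from the "
                    "proportion denominator", int((eigval < -tol).sum()))
    n_pos = int(pos.sum())
    keep = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = eigvec[:, :keep] * np.sqrt(eigval[:keep])
    proportions = eigval[:n_pos] / eigval[:n_pos].sum() if n_pos else \
        np.zeros(0)
    cols = [f"PCo{i + 1}" for i in range(keep)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=cols),
        proportions=proportions[:keep], eigenvalues=eigval)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return np.inf       # perfect separation: no within-group spread
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(dm: pd.DataFrame | np.ndarray, labels: Sequence[str],
              n_permutations: int = 999,
              seed: int | np.random.Generator | None = None
              ) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F comes from the among/within sum-of-squares partition of the
    squared distances; the p-value is ``(1 + #{F_perm >= F_obs}) /
    (1 + n_permutations)``, deterministic given ``seed``.
    """
    d = _check_distance_matrix(dm)
    labels = np.asarray(labels)
    if len(labels) != d.shape[0]:
        raise AnalysisError("labels must match the distance matrix")
    if n_permutations < 1:
        raise AnalysisError("n_permutations must be >= 1")
    names, codes = np.unique(labels, return_inverse=True)
    if len(names) < 2:
        raise AnalysisError("need >= 2 groups")
    sizes = np.bincount(codes)
    if len(names) == 2 and sizes.min() < 2:
        raise AnalysisError("a group of size 1 with only 2 groups is "
                            "untestable")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    d2 = d ** 2
    f_obs = _pseudo_f(d2, codes, len(names))
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, len(names)) >= f_obs - 1e-12:
            count += 1
    return PermanovaResult(pseudo_f=float(f_obs),
                           p_value=(1 + count) / (1 + n_permutations),
                           n_permutations=n_permutations)


def ordinate(table: AbundanceTable, labels: Sequence[str] | None = None,
             n_permutations: int = 999,
             seed: int | None = None) -> OrdinationResult:
    """Bray-Curtis -> PCoA, with a PERMANOVA p attached when a grouping is
    given — the standard ordination summary for one segment's samples."""
    dm = bray_curtis(table)
    result = pcoa(dm)
    if labels is not None:
        result.permanova_p = permanova(dm, labels, n_permutations,
                                       seed).p_value
    return result
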