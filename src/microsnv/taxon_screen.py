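"""Spearman correlation screen for taxa tracking the focal probiotic.

A candidate species passes the screen when its Spearman correlation with the
focal taxon across the chosen samples satisfies p < 0.05 and |rho| > 0.5
(both inequalities strict; a species at rho exactly 0.5 is excluded).
No multiple-testing correction is applied by default, matching common
practice for this screen; Benjamini–Hochberg is available by flag.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .io_formats import AbundanceTable, SampleMeta

logger = logging.getLogger(__name__)

#: at or below this sample size the two-sided p comes from full enumeration
EXACT_ENUMERATION_MAX_N = 8


@dataclass(frozen=True)
class ScreenThresholds:
    max_p: float = 0.05
    min_abs_rho: float = 0.5


@dataclass(frozen=True)
class CorrelationEdge:
    """One species that passed the screen, with its correlation evidence."""

    species_id: str
    rho: float
    p_value: float
    sign: str
    n: int

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.rho <= 1 + 1e-12:
            raise AnalysisError(f"|rho| > 1 for {self.species_id}")
        if self.sign != ("+" if self.rho > 0 else "-"):
            raise AnalysisError(f"sign inconsistent with rho for "
                                f"{self.species_id}")


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-aware Spearman rank correlation with a documented p-value scheme.

    rho is the Pearson correlation of midranks.  The two-sided p-value is
    computed by *full permutation enumeration* for n <= 8 (exact null, valid
    under ties), and by the usual t approximation with n - 2 degrees of
    freedom otherwise.  A constant input makes rho undefined: (nan, nan) is
    returned and callers must exclude the species from the screen.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 4:
        raise AnalysisError(f"need n >= 4 samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_ENUMERATION_MAX_N:
        perms = np.array(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - ry.mean()
        num = pc @ rxc
        den = math.sqrt(float(rxc @ rxc)) * np.sqrt((pc * pc).sum(axis=1))
        rho_null = num / den
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho * rho))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def screen_taxa(table: AbundanceTable, focal_species: str,
                thresholds: ScreenThresholds = ScreenThresholds(),
                samples: Sequence[str] | None = None,
                bh_correct: bool = False) -> list[CorrelationEdge]:
    """One :class:`CorrelationEdge` per species passing the screen.

    ``samples`` restricts which columns enter the correlation (the usual
    choice is all treatment samples of one intestinal segment); the default
    uses every column.  The focal species is never a candidate.  Species with
    undefined rho (constant abundance) are logged and excluded.
    """
    if focal_species not in table.species:
        raise AnalysisError(f"focal species {focal_species!r} not in table")
    sample_ids = list(samples) if samples is not None else table.samples
    focal = table.species_vector(focal_species, sample_ids)
    results = []
    for sp in table.species:
        if sp == focal_species:
            continue
        rho, p = spearman(focal, table.species_vector(sp, sample_ids))
        if math.isnan(rho):
            logger.info("screen: %s has constant abundance — excluded", sp)
            continue
        results.append((sp, rho, p))
    if bh_correct and results:
        from statsmodels.stats.multitest import multipletests

        _rej, p_adj, _a, _b = multipletests([r[2] for r in results],
                                            method="fdr_bh")
        results = [(sp, rho, float(pa))
                   for (sp, rho, _p), pa in zip(results, p_adj)]
    edges = []
    for sp, rho, p in results:
        if p < thresholds.max_p and abs(rho) > thresholds.min_abs_rho:
            edges.append(CorrelationEdge(species_id=sp, rho=rho, p_value=p,
                                         sign="+" if rho > 0 else "-",
                                         n=len(sample_ids)))
    return edges


def treatment_segment_samples(metadata: Sequence[SampleMeta],
                              segment: str) -> list[str]:
    """Sample ids entering the default screen: all treatment-group samples of
    one segment, days pooled."""
    return [m.sample_id for m in metadata
            if m.group == "treatment" and m.segment == segment]


def edge_table_export(edges: Sequence[CorrelationEdge], path: str | Path,
                      focal_species: str) -> None:
    """Write a network-ready edge table (source, target, rho, p, sign, n) —
    directly loadable as a Cytoscape edge table."""
    rows = [(focal_species, e.species_id, f"{e.rho:.6f}", f"{e.p_value:.6g}",
             e.sign, e.n) for e in edges]
    pd.DataFrame(rows, columns=["source", "target", "rho", "p_value", "sign",
                                "n"]).to_csv(path, sep="\t", index=False)


def read_edge_table(path: str | Path) -> list[CorrelationEdge]:
    df = pd.read_csv(path, sep="\t")
    return [CorrelationEdge(species_id=r.target, rho=float(r.rho),
                            p_value=float(r.p_value), sign=r.sign, n=int(r.n))
            for r in df.itertuples(index=False)]
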