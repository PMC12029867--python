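"""Downstream summaries of the filtered (intervention-induced) SNV set.

Covers the per-species/day count matrix behind SNV heatmaps, the ordinary
least-squares test of whether SNV counts track species abundance, the
region/codon-effect breakdown (synonymous / nonsynonymous / noncoding-genic /
intergenic proportions), and a codon-by-codon verifier for printed worked
examples such as the alpha-glucosidase gene fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .snv_profiler import SnvRecord, translate_codon

BREAKDOWN_CATEGORIES = ("synonymous", "nonsynonymous", "noncoding_genic",
                        "intergenic")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def snv_count_matrix(retained: Mapping[tuple[str, str, int], set],
                     species: Sequence[str], days: Sequence[int],
                     segment: str) -> pd.DataFrame:
    """Species x day table of retained SNV counts for one segment.

    Rows are zero-filled for screened species with no SNVs, so species that
    passed the correlation screen but acquired no variants still appear.
    """
    mat = pd.DataFrame(0, index=list(species),
                       columns=[f"day{d}" for d in days], dtype=int)
    for (sp, seg, day), keys in retained.items():
        if seg != segment or sp not in mat.index:
            continue
        mat.loc[sp, f"day{day}"] = len(keys)
    mat.index.name = "species_id"
    return mat


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    """OLS fit of SNV count on relative abundance, with a 95% pointwise
    confidence band for the mean response (symmetric about the fitted line)."""

    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int
    x: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    band_halfwidth: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "fitted": self.fitted,
                             "band_halfwidth": self.band_halfwidth})


def abundance_snv_regression(abundances: Sequence[float],
                             counts: Sequence[float]) -> RegressionFit:
    """Ordinary least squares of SNV count on species abundance.

    Reports the two-sided t test on the slope (n - 2 df) and the pointwise
    95% confidence band ``t * s * sqrt(1/n + (x - xbar)^2 / Sxx)``.  A
    non-significant slope is the expected outcome when mutation accumulation
    is not driven by how abundant a species is.
    """
    x = np.asarray(abundances, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("paired 1-D observations required")
    n = len(x)
    if n < 3:
        raise AnalysisError(f"need n >= 3 paired observations, got {n}")
    if np.ptp(x) == 0:
        raise AnalysisError("zero variance in abundances")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    resid = y - fitted
    s2 = float(resid @ resid) / (n - 2)
    sxx = float(((x - x.mean()) ** 2).sum())
    t_crit = stats.t.ppf(0.975, df=n - 2)
    half = t_crit * np.sqrt(s2 * (1.0 / n + (x - x.mean()) ** 2 / sxx))
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue) ** 2,
                         p_slope=float(res.pvalue), n=n, x=x, fitted=fitted,
                         band_halfwidth=half)


# ---------------------------------------------------------------------------
# breakdown
# ---------------------------------------------------------------------------

def record_category(record: SnvRecord) -> str:
    if record.region_class is None:
        raise AnalysisError(f"record at {record.contig}:{record.pos} is "
                            f"unannotated")
    if record.region_class == "coding":
        return record.mutation_class
    return record.region_class


def mutation_breakdown(records_by_cell: Mapping[tuple[str, int],
                                                Iterable[SnvRecord]]
                       ) -> pd.DataFrame:
    """Counts and proportions over the four mutation categories per
    (species, day).

    Counts sum to the cell's total; proportions sum to 1 when the total is
    positive and are NaN (printed ``.``) for empty cells, which are emitted
    rather than dropped — days with no annotated mutations are data.
    """
    rows = []
    for (species, day), records in sorted(records_by_cell.items()):
        counts = dict.fromkeys(BREAKDOWN_CATEGORIES, 0)
        for rec in records:
            counts[record_category(rec)] += 1
        total = sum(counts.values())
        row = {"species_id": species, "day": day, "total": total}
        for cat in BREAKDOWN_CATEGORIES:
            row[f"n_{cat}"] = counts[cat]
            row[f"prop_{cat}"] = counts[cat] / total if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# codon-level worked-example verifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonChange:
    codon_index: int          # 0-based codon number within the fragment
    codon_ref: str
    codon_alt: str
    aa_ref: str
    aa_alt: str

    @property
    def synonymous(self) -> bool:
        return self.aa_ref == self.aa_alt


@dataclass
class CodonReport:
    changes: list[CodonChange]
    diff_offsets: list[int]   # 1-based positions of differing bases

    @property
    def n_nonsynonymous(self) -> int:
        return sum(1 for c in self.changes if not c.synonymous)

    @property
    def n_synonymous(self) -> int:
        return sum(1 for c in self.changes if c.synonymous)

    def to_frame(self) -> pd.DataFrame:
        rows = [(c.codon_index + 1, c.codon_ref, c.codon_alt, c.aa_ref,
                 c.aa_alt,
                 "synonymous" if c.synonymous else "nonsynonymous")
                for c in self.changes]
        return pd.DataFrame(rows, columns=["codon", "codon_ref", "codon_alt",
                                           "aa_ref", "aa_alt", "verdict"])


def verify_codon_example(control_context: str, variant_context: str,
                         frame_offset: int = 0) -> CodonReport:
    """Codon-by-codon comparison of two equal-length in-frame fragments.

    Aligns the fragments codon by codon (``frame_offset`` bases are trimmed
    from the start first), translates both with the bacterial genetic code,
    and reports every changed codon with its amino acids and a
    synonymous/nonsynonymous verdict.  ``diff_offsets`` lists the 1-based
    offsets of differing bases within the untrimmed fragments, so printed
    genome positions can be cross-checked against offset spacing.
    """
    a = control_context.upper().strip()
    b = variant_context.upper().strip()
    if len(a) != len(b):
        raise AnalysisError(f"length mismatch: {len(a)} vs {len(b)}")
    diff_offsets = [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]
    a, b = a[frame_offset:], b[frame_offset:]
    if len(a) % 3 != 0:
        raise AnalysisError(f"in-frame length {len(a)} not divisible by 3")
    changes = []
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if ca != cb:
            changes.append(CodonChange(codon_index=i // 3, codon_ref=ca,
                                       codon_alt=cb,
                                       aa_ref=translate_codon(ca),
                                       aa_alt=translate_codon(cb)))
    return CodonReport(changes=changes, diff_offsets=diff_offsets)
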