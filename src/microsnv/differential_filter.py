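"""Two-stage negative-control filter isolating intervention-induced SNVs.

The filter operates on *sets of variant identities* per
(group, segment, day, species) cell — a variant is identified by
(species, contig, position, alternate base); two alternate alleles at one
position are distinct variants, and allele frequency plays no part in
identity.

Stage 1 (reference-selection artifacts): any variant seen in the control
group of the same segment — by default on *any* day — is attributed to the
chosen reference strain differing from the resident strain, and removed.

Stage 2 (natural/temporal variation): any surviving variant also seen in the
day-matched control cell arose over time rather than from the intervention,
and is removed.

What remains is labelled ``induced``.  Both stages are plain set
subtractions, so their order cannot change the retained set — only the
per-stage attribution, which is fixed as artifact-first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .errors import AnalysisError, MicrosnvError
from .io_formats import SampleMeta
from .snv_profiler import SnvRecord

logger = logging.getLogger(__name__)

AGGREGATION_MODES = ("union", "intersection", "majority")
STAGE1_SCOPES = ("all_days", "day_matched")


class SnvKey(NamedTuple):
    """The identity under which set removals operate."""

    species_id: str
    contig: str
    pos: int
    alt_base: str


class GroupCell(NamedTuple):
    group: str
    segment: str
    day: int
    species_id: str


def key_of(record: SnvRecord) -> SnvKey:
    return SnvKey(record.species_id, record.contig, record.pos,
                  record.alt_base)


def aggregate_replicates(
    records_by_sample: Mapping[str, Iterable[SnvRecord]],
    metadata: Sequence[SampleMeta],
    mode: str = "union",
) -> dict[GroupCell, set[SnvKey]]:
    """Collapse per-sample calls into one variant set per design cell.

    ``union`` (default): present in any replicate; ``majority``: present in
    more than half the replicates of the cell; ``intersection``: present in
    every replicate.  Unknown sample ids are an error.
    """
    if mode not in AGGREGATION_MODES:
        raise AnalysisError(f"unknown aggregation mode {mode!r}")
    meta_by_id = {m.sample_id: m for m in metadata}
    tallies: dict[GroupCell, dict[SnvKey, int]] = {}
    samples_per_cell: dict[tuple[str, str, int], int] = {}
    for m in metadata:
        cell = (m.group, m.segment, m.day)
        samples_per_cell[cell] = samples_per_cell.get(cell, 0) + 1
    for sample_id, records in records_by_sample.items():
        meta = meta_by_id.get(sample_id)
        if meta is None:
            raise AnalysisError(f"unknown sample id {sample_id!r}")
        seen_here: set[tuple[GroupCell, SnvKey]] = set()
        for rec in records:
            cell = GroupCell(meta.group, meta.segment, meta.day,
                             rec.species_id)
            k = (cell, key_of(rec))
            if k in seen_here:       # one vote per sample per variant
                continue
            seen_here.add(k)
            tallies.setdefault(cell, {})
            tallies[cell][k[1]] = tallies[cell].get(k[1], 0) + 1
    out: dict[GroupCell, set[SnvKey]] = {}
    for cell, votes in tallies.items():
        n = samples_per_cell[(cell.group, cell.segment, cell.day)]
        if mode == "union":
            keep = set(votes)
        elif mode == "majority":
            keep = {k for k, v in votes.items() if v > n / 2}
        else:
            keep = {k for k, v in votes.items() if v == n}
        out[cell] = keep
    return out


def remove_reference_artifacts(
    treatment_set: set[SnvKey], control_sets_all_days: Iterable[set[SnvKey]]
) -> tuple[set[SnvKey], set[SnvKey]]:
    """Stage 1: subtract the union of the control sets (same segment/species)."""
    control_union: set[SnvKey] = set()
    for s in control_sets_all_days:
        control_union |= s
    removed = treatment_set & control_union
    return treatment_set - removed, removed


def remove_natural_variation(
    surviving_set: set[SnvKey], control_set_same_day: set[SnvKey]
) -> tuple[set[SnvKey], set[SnvKey]]:
    """Stage 2: subtract the day-matched control set; what remains is the
    induced candidate set."""
    removed = surviving_set & control_set_same_day
    return surviving_set - removed, removed


@dataclass
class FilterCell:
    species_id: str
    segment: str
    day: int
    n_input: int
    n_removed_artifact: int
    n_removed_natural: int
    n_retained: int
    retained: set[SnvKey] = field(default_factory=set)
    removed_artifact: set[SnvKey] = field(default_factory=set)
    removed_natural: set[SnvKey] = field(default_factory=set)


@dataclass
class FilterReport:
    """Per-(species, segment, day) bookkeeping of the two removal stages.

    Conservation (``n_input = n_removed_artifact + n_removed_natural +
    n_retained``) and disjointness of the removal sets are enforced at
    construction — a violation is an internal bug, not bad input.
    """

    cells: list[FilterCell]
    aggregation_mode: str = "union"
    stage1_scope: str = "all_days"

    def __post_init__(self) -> None:
        for c in self.cells:
            if c.n_input != (c.n_removed_artifact + c.n_removed_natural
                             + c.n_retained):
                raise MicrosnvError(
                    f"filter bookkeeping violated for "
                    f"({c.species_id}, {c.segment}, day {c.day}): "
                    f"{c.n_input} != {c.n_removed_artifact} + "
                    f"{c.n_removed_natural} + {c.n_retained}")
            if (c.removed_artifact & c.removed_natural
                    or c.removed_artifact & c.retained
                    or c.removed_natural & c.retained):
                raise MicrosnvError("filter removal sets overlap")

    def retained_by_cell(self) -> dict[tuple[str, str, int], set[SnvKey]]:
        return {(c.species_id, c.segment, c.day): set(c.retained)
                for c in self.cells}

    def to_frame(self) -> pd.DataFrame:
        rows = [(c.species_id, c.segment, c.day, c.n_input,
                 c.n_removed_artifact, c.n_removed_natural, c.n_retained)
                for c in self.cells]
        return pd.DataFrame(rows, columns=[
            "species_id", "segment", "day", "n_input", "n_removed_artifact",
            "n_removed_natural", "n_retained"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def run_differential_filter(
    records_by_sample: Mapping[str, Iterable[SnvRecord]],
    metadata: Sequence[SampleMeta],
    aggregation_mode: str = "union",
    stage1_scope: str = "all_days",
) -> FilterReport:
    """Aggregate replicates, run both removal stages, and return the report.

    ``stage1_scope`` controls the negative control for reference artifacts:
    ``all_days`` (default) subtracts control variants of the segment pooled
    over every sampling day; ``day_matched`` restricts stage 1 to the same
    day (stage 2 is always day-matched).
    """
    if stage1_scope not in STAGE1_SCOPES:
        raise AnalysisError(f"unknown stage1_scope {stage1_scope!r}")
    cells = aggregate_replicates(records_by_sample, metadata, aggregation_mode)
    days = sorted({m.day for m in metadata})
    segments = sorted({m.segment for m in metadata})
    species = sorted({c.species_id for c in cells})
    out_cells: list[FilterCell] = []
    for sp in species:
        for seg in segments:
            control_by_day = {
                d: cells.get(GroupCell("control", seg, d, sp), set())
                for d in days}
            for day in days:
                treat = cells.get(GroupCell("treatment", seg, day, sp), set())
                if stage1_scope == "all_days":
                    stage1_controls = list(control_by_day.values())
                else:
                    stage1_controls = [control_by_day[day]]
                surviving, rm_artifact = remove_reference_artifacts(
                    treat, stage1_controls)
                retained, rm_natural = remove_natural_variation(
                    surviving, control_by_day[day])
                out_cells.append(FilterCell(
                    species_id=sp, segment=seg, day=day, n_input=len(treat),
                    n_removed_artifact=len(rm_artifact),
                    n_removed_natural=len(rm_natural),
                    n_retained=len(retained), retained=retained,
                    removed_artifact=rm_artifact, removed_natural=rm_natural))
    report = FilterReport(cells=out_cells, aggregation_mode=aggregation_mode,
                          stage1_scope=stage1_scope)
    logger.info("differential filter: %d cells, %d retained variants total",
                len(out_cells), sum(c.n_retained for c in out_cells))
    return report


def label_retained_records(
    records_by_sample: Mapping[str, Iterable[SnvRecord]],
    metadata: Sequence[SampleMeta],
    report: FilterReport,
) -> list[SnvRecord]:
    """Treatment-sample records whose identity survived the filter — the
    provenance-labelled ("induced") SNV rows written to filtered SNVs.tsv."""
    meta_by_id = {m.sample_id: m for m in metadata}
    retained = report.retained_by_cell()
    out = []
    for sample_id, records in records_by_sample.items():
        meta = meta_by_id[sample_id]
        if meta.group != "treatment":
            continue
        for rec in records:
            cell = (rec.species_id, meta.segment, meta.day)
            if key_of(rec) in retained.get(cell, set()):
                out.append(rec)
    return out
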