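"""End-to-end orchestration: simulate -> profile -> screen -> filter ->
summarize, as one reproducible, seeded run with a manifest.

Every stage output is a pure function of the declared inputs and the seed, so
two runs with the same config produce byte-identical TSVs.  The manifest
records the package version, the config (with every override visible), its
hash, and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .community_profile import (alpha_diversity, bray_curtis, diversity_frame,
                                group_compare, ordinate)
from .differential_filter import (label_retained_records,
                                  run_differential_filter, AGGREGATION_MODES,
                                  STAGE1_SCOPES)
from .io_formats import write_snv_table
from .snv_profiler import (CallerParams, GeneIndex, annotate_records,
                           call_snvs, position_frequency_track,
                           substitution_spectrum)
from .snv_summary import (abundance_snv_regression, mutation_breakdown,
                          snv_count_matrix)
from .synthetic_data import (SimulationConfig, config_from_mapping,
                             config_to_mapping, emit_study, simulate_study)
from .taxon_screen import (ScreenThresholds, edge_table_export, screen_taxa,
                           treatment_segment_samples)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.  The seed governs the simulation
    and every permutation test."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    caller: CallerParams = field(default_factory=CallerParams)
    screen: ScreenThresholds = field(default_factory=ScreenThresholds)
    filter_aggregation: str = "union"
    filter_stage1_scope: str = "all_days"
    n_permutations: int = 999
    log_level: str = "INFO"

    def to_mapping(self) -> dict:
        return {
            "seed": self.seed,
            "simulation": config_to_mapping(self.simulation),
            "caller": dataclasses.asdict(self.caller),
            "screen": dataclasses.asdict(self.screen),
            "filter": {"aggregation": self.filter_aggregation,
                       "stage1_scope": self.filter_stage1_scope},
            "n_permutations": self.n_permutations,
            "log_level": self.log_level,
        }


_TOP_KEYS = {"seed", "simulation", "caller", "screen", "filter",
             "n_permutations", "log_level"}


def validate_config(source: Mapping | str | Path) -> RunConfig:
    """Schema-check a config mapping or YAML file into a :class:`RunConfig`.

    Unknown keys are rejected and all type/range violations are reported at
    once.  Omitted sections take the documented defaults (caller -c 100
    -f 0.49; screen p < 0.05, |rho| > 0.5).
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            mapping = yaml.safe_load(fh) or {}
    else:
        mapping = dict(source)
    problems: list[str] = []
    unknown = set(mapping) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown key(s): {sorted(unknown)}")
    seed = mapping.get("seed", 0)
    if not isinstance(seed, int):
        problems.append("seed must be an integer")
        seed = 0
    sim = SimulationConfig(seed=seed)
    if "simulation" in mapping:
        try:
            sim_map = dict(mapping["simulation"])
            sim_map.setdefault("seed", seed)
            sim = config_from_mapping(sim_map)
        except (ConfigError, TypeError, ValueError) as exc:
            problems.append(f"simulation: {exc}")
    caller = CallerParams()
    if "caller" in mapping:
        cmap = dict(mapping["caller"])
        unknown = set(cmap) - {"min_coverage", "min_freq", "min_alt_count"}
        if unknown:
            problems.append(f"caller: unknown key(s) {sorted(unknown)}")
        else:
            try:
                caller = CallerParams(**cmap)
            except (ConfigError, TypeError) as exc:
                problems.append(f"caller: {exc}")
    screen = ScreenThresholds()
    if "screen" in mapping:
        smap = dict(mapping["screen"])
        unknown = set(smap) - {"max_p", "min_abs_rho"}
        if unknown:
            problems.append(f"screen: unknown key(s) {sorted(unknown)}")
        else:
            try:
                screen = ScreenThresholds(**smap)
                if not 0 < screen.max_p <= 1:
                    problems.append("screen.max_p must be in (0, 1]")
                if not 0 <= screen.min_abs_rho <= 1:
                    problems.append("screen.min_abs_rho must be in [0, 1]")
            except TypeError as exc:
                problems.append(f"screen: {exc}")
    agg, scope = "union", "all_days"
    if "filter" in mapping:
        fmap = dict(mapping["filter"])
        unknown = set(fmap) - {"aggregation", "stage1_scope"}
        if unknown:
            problems.append(f"filter: unknown key(s) {sorted(unknown)}")
        agg = fmap.get("aggregation", agg)
        scope = fmap.get("stage1_scope", scope)
        if agg not in AGGREGATION_MODES:
            problems.append(f"filter.aggregation must be one of "
                            f"{AGGREGATION_MODES}")
        if scope not in STAGE1_SCOPES:
            problems.append(f"filter.stage1_scope must be one of "
                            f"{STAGE1_SCOPES}")
    n_perm = mapping.get("n_permutations", 999)
    if not isinstance(n_perm, int) or n_perm < 1:
        problems.append("n_permutations must be a positive integer")
        n_perm = 999
    if problems:
        raise ConfigError("invalid config:\n  - " + "\n  - ".join(problems))
    return RunConfig(seed=seed, simulation=sim, caller=caller, screen=screen,
                     filter_aggregation=agg, filter_stage1_scope=scope,
                     n_permutations=n_perm,
                     log_level=str(mapping.get("log_level", "INFO")))


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_mapping(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage end to end; returns the manifest (also written as
    ``manifest.json``).  Any stage failure aborts with the stage named."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: "
                                           "%(message)s"))
    root = logging.getLogger("microsnv")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    stage = "setup"
    counts: dict[str, int] = {}
    try:
        # ---- simulate -------------------------------------------------
        stage = "simulate"
        study = simulate_study(config.simulation)
        emit_study(study, out / "data")
        metadata = study.samples
        abundance = study.abundance
        segments = list(config.simulation.segments)

        # ---- community statistics ------------------------------------
        stage = "community"
        diversity = alpha_diversity(abundance)
        diversity_frame(diversity).to_csv(out / "diversity.tsv", sep="\t",
                                          index=False, float_format="%.6f")
        shannon = {r.sample_id: r.shannon for r in diversity}
        gt_rows = []
        for seg in segments:
            metas = [m for m in metadata if m.segment == seg]
            ids = [m.sample_id for m in metas]
            labels = [f"{m.group}-D{m.day}" for m in metas]
            sub = abundance.data[ids]
            from .io_formats import AbundanceTable
            sub_table = AbundanceTable(sub, normalize=False)
            bray_curtis(sub_table).to_csv(out / f"distances_{seg}.tsv",
                                          sep="\t", float_format="%.6f")
            ordination = ordinate(sub_table, labels=[m.group for m in metas],
                                  n_permutations=config.n_permutations,
                                  seed=config.seed)
            ord_df = ordination.coordinates.copy()
            ord_df.index.name = "sample_id"
            ord_df.to_csv(out / f"ordination_{seg}.tsv", sep="\t",
                          float_format="%.6f")
            with open(out / f"ordination_{seg}.tsv", "a",
                      encoding="utf-8") as fh:
                props = "\t".join(f"{p:.6f}" for p in ordination.proportions)
                fh.write(f"#proportions\t{props}\n")
                fh.write(f"#permanova_p\t{ordination.permanova_p:.6f}\n")
            if all(labels.count(l) >= 2 for l in set(labels)):
                comp = group_compare([shannon[i] for i in ids], labels)
                gt_rows.append((seg, "shannon", comp.method, comp.statistic,
                                comp.p_value))
        pd.DataFrame(gt_rows, columns=["segment", "index", "method",
                                       "statistic", "p_value"]
                     ).to_csv(out / "group_tests.tsv", sep="\t", index=False,
                              float_format="%.6f")

        # ---- screen ---------------------------------------------------
        stage = "screen"
        focal = config.simulation.focal_species
        profiled: dict[str, list[str]] = {}
        for seg in segments:
            ids = treatment_segment_samples(metadata, seg)
            edges = screen_taxa(abundance, focal, config.screen, samples=ids)
            edge_table_export(edges, out / f"edges_{seg}.tsv", focal)
            genome_ids = {g.species_id for g in study.genomes}
            hit = sorted({e.species_id for e in edges} & genome_ids)
            if not hit:
                logger.warning("screen found no genome-backed species in "
                               "segment %s; profiling all genomes", seg)
                hit = sorted(genome_ids)
            profiled[seg] = hit
        counts["screened_species"] = sum(len(v) for v in profiled.values())

        # ---- profile --------------------------------------------------
        stage = "profile"
        indexes = {g.species_id: GeneIndex(g.genes) for g in study.genomes}
        records_by_sample: dict[str, list] = {m.sample_id: []
                                              for m in metadata}
        for meta in metadata:
            for sp in profiled[meta.segment]:
                genome = study.genome(sp)
                pileup = study.pileup_for(meta.sample_id, sp)
                recs = call_snvs(pileup, genome, config.caller,
                                 sample_id=meta.sample_id)
                recs = annotate_records(recs, genome, indexes[sp])
                records_by_sample[meta.sample_id].extend(recs)
        all_records = [r for m in metadata
                       for r in records_by_sample[m.sample_id]]
        write_snv_table(all_records, out / "calls.SNVs.tsv")
        counts["called_records"] = len(all_records)

        # ---- filter ---------------------------------------------------
        stage = "filter"
        report = run_differential_filter(
            records_by_sample, metadata,
            aggregation_mode=config.filter_aggregation,
            stage1_scope=config.filter_stage1_scope)
        report.write(out / "filter_report.tsv")
        retained_records = label_retained_records(records_by_sample, metadata,
                                                  report)
        write_snv_table(retained_records, out / "filtered.SNVs.tsv")
        retained = report.retained_by_cell()
        counts["retained_variants"] = sum(
            len(v) for v in retained.values())

        # ---- summarize ------------------------------------------------
        stage = "summarize"
        meta_by_id = {m.sample_id: m for m in metadata}
        days = list(config.simulation.days)
        reg_rows = []
        for seg in segments:
            mat = snv_count_matrix(retained, profiled[seg], days, seg)
            mat.to_csv(out / f"counts_{seg}.tsv", sep="\t")
            seg_records = [r for r in retained_records
                           if meta_by_id[r.sample_id].segment == seg]
            # one row per variant identity per day for breakdown/spectrum
            uniq: dict = {}
            for r in seg_records:
                day = meta_by_id[r.sample_id].day
                uniq.setdefault((r.species_id, day, r.contig, r.pos,
                                 r.alt_base, r.gene_id), r)
            cells = {(sp, d): [] for sp in profiled[seg] for d in days}
            for (sp, day, *_k), r in uniq.items():
                cells[(sp, day)].append(r)
            mutation_breakdown(cells).to_csv(
                out / f"breakdown_{seg}.tsv", sep="\t", index=False,
                float_format="%.6f", na_rep=".")
            spectrum = substitution_spectrum(uniq.values())
            sp_df = spectrum.to_frame()
            sp_df.to_csv(out / f"spectrum_{seg}.tsv", sep="\t", index=False)
            position_frequency_track(seg_records).to_csv(
                out / f"position_track_{seg}.tsv", sep="\t", index=False,
                float_format="%.6f")
            # per-sample pairing: abundance vs per-sample retained-call count
            xs, ys = [], []
            for meta in metadata:
                if meta.segment != seg or meta.group != "treatment":
                    continue
                for sp in profiled[seg]:
                    kept = retained.get((sp, seg, meta.day), set())
                    y = len({(r.contig, r.pos, r.alt_base)
                             for r in records_by_sample[meta.sample_id]
                             if r.species_id == sp and
                             (r.species_id, r.contig, r.pos, r.alt_base)
                             in kept})
                    xs.append(abundance.data.loc[sp, meta.sample_id])
                    ys.append(y)
            if len(xs) >= 3 and len(set(xs)) > 1:
                fit = abundance_snv_regression(xs, ys)
                reg_rows.append((seg, fit.slope, fit.intercept, fit.r_squared,
                                 fit.p_slope, fit.n))
        pd.DataFrame(reg_rows, columns=["segment", "slope", "intercept",
                                        "r_squared", "p_slope", "n"]
                     ).to_csv(out / "regression.tsv", sep="\t", index=False,
                              float_format="%.6g")

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_mapping(),
            "config_hash": config_hash(config),
            "counts": counts,
            "outputs": sorted(p.relative_to(out).as_posix()
                              for p in out.rglob("*.tsv")),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        return manifest
    except Exception as exc:
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
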