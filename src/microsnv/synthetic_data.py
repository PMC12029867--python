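"""Synthetic study generator: genomes, gene models, pileups, abundances.

Emulates a single-gavage probiotic intervention study: two groups (treatment /
control), two intestinal segments (small / large), sampling days 1, 3 and 7,
``n_replicates`` animals per cell.  Every generated dataset carries a truth
table so each downstream stage (caller, differential filter, correlation
screen) can be scored exactly.

Three provenance classes of planted variants mirror what the differential
filter must separate:

* ``induced`` — intervention-induced: present only in treatment samples of one
  segment, from a start day onward;
* ``artifact`` — reference-selection artifact: the chosen reference strain
  differs from the resident strain, so the variant appears in *every* sample
  of its segment, both groups, all days;
* ``natural`` — temporal/natural variation: appears in both groups of its
  segment on one designated day.

Everything is deterministic under a fixed seed: per-(sample, species) pileups
are generated from independent, reproducible substreams, so they can be
materialized lazily and in any order.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError
from .io_formats import (AbundanceTable, BASES, GeneModel, GenomeAnnotation,
                         SampleMeta, write_abundance, write_fasta, write_gff3,
                         write_metadata, write_pileup)

logger = logging.getLogger(__name__)

_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_PRODUCTS = ("alpha-glucosidase", "glycerate kinase", "DMT family transporter",
             "LytTR family DNA-binding domain", "ABC transporter permease",
             "hypothetical protein")

# substream tags so the per-purpose RNGs never collide
_GENOME_STREAM, _PLANT_STREAM, _PILEUP_STREAM, _ABUND_STREAM = 11, 23, 37, 53


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults encode the emulated design: 6 replicates per cell (six mice per
    group per day), mean per-site depth 150 so the ``-c 100`` gate is
    comfortably cleared, planted alternate-allele frequency 0.6 so the
    ``-f 0.49`` gate is cleared on the call side, and a 2:1
    transition:transversion bias so substitution spectra are testably
    non-uniform.
    """

    seed: int = 0
    n_species: int = 5
    genome_length: int = 50_000
    genes_per_genome: int = 40
    mean_depth: float = 150.0
    error_rate: float = 0.0
    n_replicates: int = 6
    days: tuple[int, ...] = (1, 3, 7)
    segments: tuple[str, ...] = ("small", "large")
    planted_counts: dict[str, int] = field(
        default_factory=lambda: {"induced": 12, "artifact": 6, "natural": 6})
    induced_allele_freq: float = 0.6
    transition_bias: float = 2.0
    #: "deterministic": alt reads = ceil(depth * freq), so the planted
    #: frequency is guaranteed and threshold semantics are crisp;
    #: "binomial": alt reads ~ Binomial(depth, freq).
    allele_count_mode: str = "deterministic"
    # --- abundance design ---
    focal_species: str = "Lp082"
    focal_day1_abundance: float = 0.01
    focal_decay: float = 0.5
    abundance_noise_sd: float = 0.35
    n_background_species: int = 6
    background_abundance: float = 0.13
    correlation_design: dict[str, str] | None = None

    def __post_init__(self) -> None:
        problems = []
        if self.n_species < 1:
            problems.append("n_species must be >= 1")
        if not 0 <= self.error_rate < 0.25:
            problems.append("error_rate must be in [0, 0.25)")
        if not 0 < self.induced_allele_freq <= 1:
            problems.append("induced_allele_freq must be in (0, 1]")
        if any(v < 0 for v in self.planted_counts.values()):
            problems.append("planted_counts must be non-negative")
        if set(self.planted_counts) - {"induced", "artifact", "natural"}:
            problems.append("planted_counts keys must be "
                            "induced/artifact/natural")
        if self.allele_count_mode not in ("deterministic", "binomial"):
            problems.append("allele_count_mode must be deterministic|binomial")
        if self.n_replicates < 1:
            problems.append("n_replicates must be >= 1")
        if self.transition_bias <= 0:
            problems.append("transition_bias must be > 0")
        if problems:
            raise ConfigError("; ".join(problems))

    @property
    def species_ids(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]

    def design_of(self, species_id: str) -> str:
        """Target relation of a genome species to the focal taxon."""
        if self.correlation_design is not None:
            return self.correlation_design.get(species_id, "none")
        idx = self.species_ids.index(species_id)
        if idx < 2:
            return "positive"
        if idx == 2 and self.n_species >= 3:
            return "negative"
        return "none"


def demo_config(seed: int = 0) -> SimulationConfig:
    """A seconds-fast preset for demos and end-to-end determinism checks."""
    return SimulationConfig(seed=seed, n_species=2, genome_length=6_000,
                            genes_per_genome=6, n_replicates=2,
                            planted_counts={"induced": 6, "artifact": 3,
                                            "natural": 3})


def near_threshold_config(seed: int = 0, freq: float = 0.49) -> SimulationConfig:
    """Plants variants at a frequency at (0.49) or just below (0.45) the
    caller's threshold, pinning the >= boundary semantics; deterministic
    allele counts guarantee the planted frequency exactly."""
    return SimulationConfig(seed=seed, n_species=2, genome_length=10_000,
                            genes_per_genome=8, n_replicates=2,
                            induced_allele_freq=freq,
                            planted_counts={"induced": 10, "artifact": 0,
                                            "natural": 0})


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedVariant:
    species_id: str
    contig: str
    pos: int
    ref_base: str
    alt_base: str
    provenance: str          # induced | artifact | natural
    segment: str
    groups: tuple[str, ...]  # groups in which the variant is present
    days: tuple[int, ...]    # days on which the variant is present

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.species_id, self.contig, self.pos, self.alt_base)


@dataclass
class SyntheticTruth:
    """Provenance labels of every planted variant plus the designed
    correlation signs — the ground truth every filter stage is scored against."""

    planted: list[PlantedVariant]
    true_correlation_sign: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        per_species: dict[str, set[int]] = {}
        for v in self.planted:
            seen = per_species.setdefault(v.species_id, set())
            if v.pos in seen:
                raise ConfigError(f"colliding planted position "
                                  f"{v.species_id}:{v.pos}")
            seen.add(v.pos)

    def present_in(self, sample: SampleMeta, species_id: str
                   ) -> list[PlantedVariant]:
        return [v for v in self.planted
                if v.species_id == species_id and v.segment == sample.segment
                and sample.group in v.groups and sample.day in v.days]

    def keys_by_provenance(self, provenance: str, species_id: str,
                           segment: str, day: int) -> set:
        return {v.key for v in self.planted
                if v.provenance == provenance and v.species_id == species_id
                and v.segment == segment and day in v.days}

    def to_frame(self) -> pd.DataFrame:
        rows = [(v.species_id, v.contig, v.pos, v.ref_base, v.alt_base,
                 v.provenance, v.segment, ",".join(v.groups),
                 ",".join(str(d) for d in v.days)) for v in self.planted]
        return pd.DataFrame(rows, columns=["species", "contig", "pos", "ref",
                                           "alt", "provenance", "segment",
                                           "groups", "days"])


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)
    sign_path = Path(path).with_suffix(".signs.json")
    sign_path.write_text(json.dumps(truth.true_correlation_sign,
                                    sort_keys=True, indent=1) + "\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "contig": str})
    planted = [PlantedVariant(
        species_id=r.species, contig=r.contig, pos=int(r.pos), ref_base=r.ref,
        alt_base=r.alt, provenance=r.provenance, segment=r.segment,
        groups=tuple(r.groups.split(",")),
        days=tuple(int(d) for d in str(r.days).split(",")))
        for r in df.itertuples(index=False)]
    signs_path = Path(path).with_suffix(".signs.json")
    signs = json.loads(signs_path.read_text()) if signs_path.exists() else {}
    return SyntheticTruth(planted=planted, true_correlation_sign=signs)


# ---------------------------------------------------------------------------
# design / genomes / variants
# ---------------------------------------------------------------------------

def make_design(config: SimulationConfig) -> list[SampleMeta]:
    """The full sample sheet, in canonical order.

    Sample ids follow the A/B/C/D convention: A = treatment small intestine,
    B = treatment large, C = control small, D = control large; e.g. ``AD3_r2``
    is treatment / small / day 3 / replicate 2.
    """
    letter = {("treatment", "small"): "A", ("treatment", "large"): "B",
              ("control", "small"): "C", ("control", "large"): "D"}
    metas = []
    for group in ("treatment", "control"):
        for segment in config.segments:
            for day in config.days:
                for rep in range(1, config.n_replicates + 1):
                    sid = f"{letter[(group, segment)]}D{day}_r{rep}"
                    metas.append(SampleMeta(sample_id=sid, group=group,
                                            segment=segment, day=day,
                                            replicate=rep))
    return metas


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed,) + key))


def generate_genomes(config: SimulationConfig) -> list[GenomeAnnotation]:
    """I.i.d.-uniform A/C/G/T genomes with non-overlapping CDS gene models
    (mixed strands) plus one structural-RNA gene each; deterministic per seed."""
    genomes = []
    for si, species in enumerate(config.species_ids):
        rng = _rng(config, _GENOME_STREAM, si)
        seq = "".join(np.array(BASES)[rng.integers(0, 4, config.genome_length)])
        contig = f"{species}_c1"
        genes: list[GeneModel] = []
        rna_slot = int(rng.integers(0, config.genes_per_genome + 1))
        cursor = 0
        n_placed = 0
        for slot in range(config.genes_per_genome + 1):
            is_rna = slot == rna_slot
            length = 75 if is_rna else 3 * int(rng.integers(60, 151))
            gap = int(rng.integers(20, 81))
            start = cursor + gap + 1
            end = start + length - 1
            if end > config.genome_length:
                raise ConfigError(
                    f"genes_per_genome={config.genes_per_genome} infeasible "
                    f"for genome_length={config.genome_length}")
            strand = "+" if rng.random() < 0.5 else "-"
            if is_rna:
                genes.append(GeneModel(gene_id=f"{species}_trna1",
                                       contig_id=contig, start=start, end=end,
                                       strand=strand, feature_class="rna_gene",
                                       product="tRNA-Ala"))
            else:
                n_placed += 1
                genes.append(GeneModel(
                    gene_id=f"{species}_g{n_placed:03d}", contig_id=contig,
                    start=start, end=end, strand=strand, feature_class="CDS",
                    product=_PRODUCTS[n_placed % len(_PRODUCTS)]))
            cursor = end
        genomes.append(GenomeAnnotation(species_id=species,
                                        contigs=[(contig, seq)], genes=genes))
    return genomes


def plant_variants(genomes: Sequence[GenomeAnnotation],
                   config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Draw planted variants: positions uniform without collision, alternate
    base != reference with a 2:1 transition:transversion bias by default."""
    planted: list[PlantedVariant] = []
    for si, genome in enumerate(genomes):
        g_rng = rng or _rng(config, _PLANT_STREAM, si)
        contig, seq = genome.contigs[0]
        total = sum(config.planted_counts.values())
        if total > len(seq):
            raise ConfigError(f"{total} planted variants exceed "
                              f"{len(seq)} available positions")
        positions = g_rng.choice(len(seq), size=total, replace=False) + 1
        labels = ([("induced",)] * config.planted_counts.get("induced", 0)
                  + [("artifact",)] * config.planted_counts.get("artifact", 0)
                  + [("natural",)] * config.planted_counts.get("natural", 0))
        seg_cycle = itertools.cycle(config.segments)
        day_cycle = itertools.cycle(config.days)
        p_ti = config.transition_bias / (config.transition_bias + 1.0)
        for pos, (provenance,) in zip(positions, labels):
            ref = seq[pos - 1]
            if g_rng.random() < p_ti:
                alt = _TRANSITION_OF[ref]
            else:
                tv = [b for b in BASES if b != ref and b != _TRANSITION_OF[ref]]
                alt = tv[int(g_rng.integers(0, 2))]
            segment = next(seg_cycle)
            if provenance == "induced":
                start_day = next(day_cycle)
                days = tuple(d for d in config.days if d >= start_day)
                groups: tuple[str, ...] = ("treatment",)
            elif provenance == "artifact":
                days = tuple(config.days)
                groups = ("treatment", "control")
            else:
                days = (next(day_cycle),)
                groups = ("treatment", "control")
            planted.append(PlantedVariant(
                species_id=genome.species_id, contig=contig, pos=int(pos),
                ref_base=ref, alt_base=alt, provenance=provenance,
                segment=segment, groups=groups, days=days))
    signs = {}
    for sp in config.species_ids:
        signs[sp] = {"positive": "+", "negative": "-", "none": "0"}[
            config.design_of(sp)]
    return SyntheticTruth(planted=planted, true_correlation_sign=signs)


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

def pileup_counts(genome: GenomeAnnotation, truth: SyntheticTruth,
                  config: SimulationConfig, sample: SampleMeta,
                  sample_index: int, species_index: int) -> pd.DataFrame:
    """Simulated pileup for one (sample, species) pair.

    Depth is Poisson(``mean_depth``) per site.  Non-variant sites carry
    reference reads, with per-base miscalls at ``error_rate`` spread uniformly
    over the other three bases.  At a planted variant present in this sample,
    the alternate read count is ``ceil(depth * induced_allele_freq)``
    (deterministic mode, the default) or Binomial(depth, freq); the remaining
    reads are reference.
    """
    rng = _rng(config, _PILEUP_STREAM, species_index, sample_index)
    contig, seq = genome.contigs[0]
    length = len(seq)
    depth = rng.poisson(config.mean_depth, size=length)
    counts = np.zeros((length, 4), dtype=np.int64)
    ref_idx = np.frombuffer(seq.encode(), dtype="S1")
    ref_codes = np.zeros(length, dtype=np.int64)
    for i, b in enumerate(BASES):
        ref_codes[ref_idx == b.encode()] = i
    counts[np.arange(length), ref_codes] = depth
    if config.error_rate > 0:
        errs = rng.binomial(depth, config.error_rate)
        e1 = rng.binomial(errs, 1 / 3)
        e2 = rng.binomial(errs - e1, 1 / 2)
        e3 = errs - e1 - e2
        others = np.array([[j for j in range(4) if j != i] for i in range(4)])
        oth = others[ref_codes]                      # (length, 3)
        counts[np.arange(length), ref_codes] -= errs
        np.add.at(counts, (np.arange(length), oth[:, 0]), e1)
        np.add.at(counts, (np.arange(length), oth[:, 1]), e2)
        np.add.at(counts, (np.arange(length), oth[:, 2]), e3)
    base_to_idx = {b: i for i, b in enumerate(BASES)}
    for v in truth.present_in(sample, genome.species_id):
        i = v.pos - 1
        d = int(depth[i])
        if d == 0:
            continue
        if config.allele_count_mode == "deterministic":
            alt = int(np.ceil(d * config.induced_allele_freq))
        else:
            alt = int(rng.binomial(d, config.induced_allele_freq))
        counts[i, :] = 0
        counts[i, base_to_idx[v.alt_base]] = alt
        counts[i, base_to_idx[v.ref_base]] += d - alt
    return pd.DataFrame({"contig": contig, "pos": np.arange(1, length + 1),
                         "A": counts[:, 0], "C": counts[:, 1],
                         "G": counts[:, 2], "T": counts[:, 3]})


# ---------------------------------------------------------------------------
# abundances
# ---------------------------------------------------------------------------

def generate_abundance(config: SimulationConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[AbundanceTable, dict[str, str]]:
    """Relative-abundance table over the full design, plus true signs.

    The focal probiotic is absent from control samples and decays over days in
    treatment samples (single gavage, transient carriage), with a
    deterministic replicate-to-replicate spread so its ranks are well defined
    even at zero noise.  Positive-design species are exactly proportional to
    the focal taxon (rank-preserving under compositional closure);
    negative-design species decrease affinely in it; background species are
    independent lognormal noise around a common baseline.
    """
    rng = rng or _rng(config, _ABUND_STREAM)
    metas = make_design(config)
    species = config.species_ids
    backgrounds = [f"bg{i + 1:02d}" for i in range(config.n_background_species)]
    all_species = species + backgrounds + [config.focal_species]
    sd = config.abundance_noise_sd

    def noise1() -> float:
        return float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0

    def noise(n: int) -> np.ndarray:
        return np.exp(rng.normal(0.0, sd, size=n)) if sd > 0 else np.ones(n)

    a0 = config.focal_day1_abundance
    x_cap = 2.0 * a0
    columns = {}
    for m in metas:
        if m.group == "treatment":
            jitter = 1.0 + 0.04 * (m.replicate - (config.n_replicates + 1) / 2)
            x = a0 * config.focal_decay ** (m.day - 1) * jitter
        else:
            x = 0.0
        vals = []
        for sp in species:
            design = config.design_of(sp)
            if design == "positive":
                vals.append(2.0 * x * noise1())
            elif design == "negative":
                vals.append(0.5 * (x_cap - x) * noise1())
            else:
                vals.append(0.01 * noise1())
        vals.extend(config.background_abundance * noise(len(backgrounds)))
        vals.append(x)
        columns[m.sample_id] = vals
    df = pd.DataFrame(columns, index=all_species)
    table = AbundanceTable(df, normalize=True)
    signs = {sp: {"positive": "+", "negative": "-", "none": "0"}[
        config.design_of(sp)] for sp in species}
    signs.update({bg: "0" for bg in backgrounds})
    return table, signs


# ---------------------------------------------------------------------------
# bundled run
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """Everything one synthetic run produces, with lazy pileup generation."""

    config: SimulationConfig
    genomes: list[GenomeAnnotation]
    truth: SyntheticTruth
    samples: list[SampleMeta]
    abundance: AbundanceTable

    def genome(self, species_id: str) -> GenomeAnnotation:
        for g in self.genomes:
            if g.species_id == species_id:
                return g
        raise KeyError(species_id)

    def pileup_for(self, sample_id: str, species_id: str) -> pd.DataFrame:
        sidx = next(i for i, m in enumerate(self.samples)
                    if m.sample_id == sample_id)
        spidx = next(i for i, g in enumerate(self.genomes)
                     if g.species_id == species_id)
        return pileup_counts(self.genomes[spidx], self.truth, self.config,
                             self.samples[sidx], sidx, spidx)

    def iter_pileups(self) -> Iterable[tuple[SampleMeta, str, pd.DataFrame]]:
        for sidx, m in enumerate(self.samples):
            for spidx, g in enumerate(self.genomes):
                yield m, g.species_id, pileup_counts(
                    g, self.truth, self.config, m, sidx, spidx)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    genomes = generate_genomes(config)
    truth = plant_variants(genomes, config)
    samples = make_design(config)
    abundance, signs = generate_abundance(config)
    truth.true_correlation_sign.update(signs)
    return SimulatedStudy(config=config, genomes=genomes, truth=truth,
                          samples=samples, abundance=abundance)


def emit_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, int]:
    """Write every io_formats dialect for a simulated study; returns per-kind
    file counts for the run manifest."""
    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "pileups").mkdir(parents=True, exist_ok=True)
    for g in study.genomes:
        write_fasta(g, out / "genomes" / f"{g.species_id}.fna")
        write_gff3(g.genes, out / "genomes" / f"{g.species_id}.gff3",
                   contig_lengths=g.contig_lengths())
    n_pileups = 0
    for meta, species_id, df in study.iter_pileups():
        write_pileup(df, out / "pileups"
                     / f"{meta.sample_id}.{species_id}.pileup.tsv")
        n_pileups += 1
    write_abundance(study.abundance, out / "abundance.tsv")
    write_metadata(study.samples, out / "metadata.tsv")
    write_truth(study.truth, out / "truth.tsv")
    logger.info("simulated study written to %s (%d pileups)", out, n_pileups)
    return {"genomes": len(study.genomes), "pileups": n_pileups,
            "samples": len(study.samples)}


def config_from_mapping(mapping: Mapping) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain dict (YAML), rejecting
    unknown keys."""
    import dataclasses

    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown simulation key(s): {sorted(unknown)}")
    kwargs = dict(mapping)
    for key in ("days", "segments"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SimulationConfig(**kwargs)


def config_to_mapping(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["days"] = list(d["days"])
    d["segments"] = list(d["segments"])
    return d
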