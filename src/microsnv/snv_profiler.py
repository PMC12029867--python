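"""Consensus-threshold SNV calling and annotation.

A site is called as an SNV when its read depth reaches ``min_coverage`` and
the most frequent **non-reference** base accounts for at least ``min_freq`` of
the depth (defaults ``-c 100 -f 0.49``).  With a frequency threshold just
under one half this is consensus-style calling: the resident strain's
consensus differs from the chosen reference at the site.  The reference base
always comes from the reference genome, never from the pileup majority — a
site whose majority differs from the reference is precisely an SNV candidate.

Each called variant is then classified by genomic region (coding /
noncoding-genic / intergenic), by codon effect for coding sites (synonymous vs
nonsynonymous under the bacterial genetic code, NCBI table 11), and by
directed substitution type (transition vs transversion).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import reverse_complement

from .errors import AnalysisError, ConfigError
from .io_formats import BASES, GeneModel, GenomeAnnotation

logger = logging.getLogger(__name__)

#: the four transitions; everything else among directed base pairs is a transversion
TRANSITIONS = frozenset({"A>G", "G>A", "C>T", "T>C"})

#: all 12 directed substitution types, in fixed reporting order
SUBSTITUTION_TYPES = tuple(f"{a}>{b}" for a in BASES for b in BASES if a != b)

_CODE11 = unambiguous_dna_by_id[11]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; ``*`` for a stop (table 11).

    Table 11 differs from the standard code only in its start-codon set, so
    every sense-codon translation here coincides with table 1.
    """
    codon = codon.upper()
    if codon in _CODE11.stop_codons:
        return "*"
    return _CODE11.forward_table[codon]


# ---------------------------------------------------------------------------
# record + parameters
# ---------------------------------------------------------------------------

@dataclass
class SnvRecord:
    """One called single-nucleotide variant.

    ``allele_freq`` is ``alt_count / depth``.  ``mutation_class`` is non-null
    exactly for coding variants; codon/aa fields are reported on the coding
    strand while ``ref_base``/``alt_base`` stay in reference-strand
    orientation.
    """

    species_id: str
    contig: str
    pos: int
    ref_base: str
    alt_base: str
    ref_count: int
    alt_count: int
    depth: int
    region_class: str | None = None
    mutation_class: str | None = None
    gene_id: str = "."
    codon_ref: str | None = None
    codon_alt: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.ref_base not in BASES or self.alt_base not in BASES:
            raise AnalysisError(f"bad bases {self.ref_base!r}>{self.alt_base!r}")
        if self.ref_base == self.alt_base:
            raise AnalysisError(f"ref == alt ({self.ref_base}) at "
                                f"{self.contig}:{self.pos}")
        if self.depth <= 0 or self.alt_count <= 0:
            raise AnalysisError(f"non-positive depth/alt_count at "
                                f"{self.contig}:{self.pos}")
        if self.alt_count > self.depth:
            raise AnalysisError(f"alt_count > depth at {self.contig}:{self.pos}")
        if self.region_class not in (None, "coding", "noncoding_genic",
                                     "intergenic"):
            raise AnalysisError(f"bad region_class {self.region_class!r}")
        if self.mutation_class not in (None, "synonymous", "nonsynonymous"):
            raise AnalysisError(f"bad mutation_class {self.mutation_class!r}")
        if (self.mutation_class is not None) != (self.region_class == "coding"):
            if self.region_class is not None:
                raise AnalysisError(
                    "mutation_class must be set exactly for coding variants")

    @property
    def allele_freq(self) -> float:
        return self.alt_count / self.depth

    @property
    def substitution(self) -> str:
        return f"{self.ref_base}>{self.alt_base}"

    @property
    def is_transition(self) -> bool:
        return self.substitution in TRANSITIONS


@dataclass(frozen=True)
class CallerParams:
    """Coverage/frequency thresholds of the consensus caller.

    Both thresholds are inclusive (a site at exactly ``min_coverage`` reads or
    exactly ``min_freq`` alternate fraction is called).  ``min_alt_count`` is
    an additional floor on alternate reads (default 1, i.e. inactive).
    """

    min_coverage: int = 100
    min_freq: float = 0.49
    min_alt_count: int = 1

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ConfigError("min_coverage must be >= 1")
        if not 0 < self.min_freq <= 1:
            raise ConfigError("min_freq must be in (0, 1]")
        if self.min_alt_count < 1:
            raise ConfigError("min_alt_count must be >= 1")


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_snvs(pileup: pd.DataFrame, genome: GenomeAnnotation,
              params: CallerParams = CallerParams(),
              sample_id: str | None = None) -> list[SnvRecord]:
    """Call SNVs from a pileup DataFrame (columns contig/pos/A/C/G/T).

    A site is called iff ``depth >= min_coverage`` and
    ``max(non-reference count) / depth >= min_freq``; the alternate allele is
    the most frequent non-reference base, ties broken A < C < G < T.  Sites
    whose reference base is not A/C/G/T (masked ambiguity codes) are never
    called.  A pileup contig absent from the genome is an error.
    """
    records: list[SnvRecord] = []
    base_to_idx = {b: i for i, b in enumerate(BASES)}
    for contig, sub in pileup.groupby("contig", sort=False):
        try:
            seq = genome.sequence(str(contig))
        except KeyError:
            raise AnalysisError(
                f"pileup contig {contig!r} absent from genome "
                f"{genome.species_id}") from None
        pos = sub["pos"].to_numpy()
        if len(pos) and (pos.max() > len(seq) or pos.min() < 1):
            raise AnalysisError(f"pileup position outside contig {contig} "
                                f"(length {len(seq)})")
        counts = sub[list(BASES)].to_numpy(dtype=np.int64)
        depth = counts.sum(axis=1)
        seq_arr = np.frombuffer(seq.encode(), dtype="S1")[pos - 1]
        ref_idx = np.full(len(pos), -1, dtype=np.int64)
        for b, i in base_to_idx.items():
            ref_idx[seq_arr == b.encode()] = i
        callable_mask = ref_idx >= 0
        nonref = counts.copy()
        rows = np.arange(len(pos))
        nonref[rows[callable_mask], ref_idx[callable_mask]] = -1
        alt_idx = nonref.argmax(axis=1)          # first max -> A<C<G<T tie order
        alt_count = np.take_along_axis(counts, alt_idx[:, None], axis=1)[:, 0]
        with np.errstate(invalid="ignore", divide="ignore"):
            freq_ok = alt_count >= params.min_freq * depth
        called = (callable_mask & (depth >= params.min_coverage) & freq_ok
                  & (alt_count >= params.min_alt_count))
        for i in np.flatnonzero(called):
            ref_b = BASES[ref_idx[i]]
            records.append(SnvRecord(
                species_id=genome.species_id, contig=str(contig),
                pos=int(pos[i]), ref_base=ref_b, alt_base=BASES[alt_idx[i]],
                ref_count=int(counts[i, ref_idx[i]]),
                alt_count=int(alt_count[i]), depth=int(depth[i]),
                sample_id=sample_id))
    return records


# ---------------------------------------------------------------------------
# region + codon classification
# ---------------------------------------------------------------------------

class GeneIndex:
    """Sorted-interval lookup of gene models, built once per genome."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._by_contig: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_contig.setdefault(g.contig_id, []).append(g)
        self._starts: dict[str, np.ndarray] = {}
        self._maxlen: dict[str, int] = {}
        for cid, gl in self._by_contig.items():
            gl.sort(key=lambda g: (g.start, g.end))
            self._starts[cid] = np.array([g.start for g in gl])
            self._maxlen[cid] = max(g.length for g in gl)

    def overlapping(self, contig: str, pos: int) -> list[GeneModel]:
        gl = self._by_contig.get(contig, [])
        if not gl:
            return []
        hi = int(np.searchsorted(self._starts[contig], pos, side="right"))
        out = []
        for g in reversed(gl[:hi]):
            if g.end >= pos:
                out.append(g)
            elif pos - g.start >= self._maxlen[contig]:
                break   # no earlier gene can reach this far right
        out.reverse()
        return out


def classify_region(record: SnvRecord, genes: Sequence[GeneModel] | GeneIndex
                    ) -> list[tuple[str, GeneModel | None]]:
    """Region contexts for one variant.

    Returns a list of ``(region_class, gene)`` pairs: one per overlapping CDS
    (``"coding"``), else one ``("noncoding_genic", gene)`` per overlapping RNA
    gene, else a single ``("intergenic", None)``.  A variant under overlapping
    CDSs is deliberately reported once per gene context.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(list(genes))
    hits = index.overlapping(record.contig, record.pos)
    cds = [g for g in hits if g.feature_class == "CDS"]
    if cds:
        return [("coding", g) for g in cds]
    rna = [g for g in hits if g.feature_class == "rna_gene"]
    if rna:
        return [("noncoding_genic", g) for g in rna]
    return [("intergenic", None)]


def classify_codon(record: SnvRecord, genome: GenomeAnnotation,
                   gene: GeneModel) -> SnvRecord:
    """Fill codon/amino-acid fields of a coding variant, in place.

    The codon index is ``offset-within-CDS // 3`` on the coding strand (the
    reverse complement for ``-`` strand genes); the alternate base is
    substituted at the in-codon position and both codons are translated with
    the bacterial code.  Synonymous iff the amino acids agree; an alternate
    codon that creates a stop is nonsynonymous with ``aa_alt = "*"``.
    """
    if not gene.contains(record.pos):
        raise AnalysisError(f"position {record.pos} outside gene {gene.gene_id}")
    if gene.feature_class != "CDS":
        raise AnalysisError(f"gene {gene.gene_id} is not a CDS")
    seq = genome.sequence(record.contig)
    if seq[record.pos - 1] != record.ref_base:
        raise AnalysisError(
            f"reference mismatch at {record.contig}:{record.pos}: genome has "
            f"{seq[record.pos - 1]!r}, record has {record.ref_base!r}")
    if gene.strand == "+":
        offset = record.pos - gene.start
        cds_seq = seq[gene.start - 1:gene.end]
        alt_coding = record.alt_base
    else:
        offset = gene.end - record.pos
        cds_seq = reverse_complement(seq[gene.start - 1:gene.end])
        alt_coding = record.alt_base.translate(_COMPLEMENT)
    codon_idx, in_codon = divmod(offset, 3)
    codon_ref = cds_seq[3 * codon_idx:3 * codon_idx + 3]
    codon_alt = (codon_ref[:in_codon] + alt_coding + codon_ref[in_codon + 1:])
    aa_ref = translate_codon(codon_ref)
    aa_alt = translate_codon(codon_alt)
    if aa_alt == "*" and aa_ref != "*":
        logger.debug("variant %s:%d creates a stop codon in %s",
                     record.contig, record.pos, gene.gene_id)
    record.region_class = "coding"
    record.gene_id = gene.gene_id
    record.codon_ref = codon_ref
    record.codon_alt = codon_alt
    record.aa_ref = aa_ref
    record.aa_alt = aa_alt
    record.mutation_class = ("synonymous" if aa_ref == aa_alt
                             else "nonsynonymous")
    return record


def annotate_records(records: Iterable[SnvRecord], genome: GenomeAnnotation,
                     index: GeneIndex | None = None) -> list[SnvRecord]:
    """Classify every record by region and (for coding contexts) codon effect.

    Variants under overlapping CDSs are emitted once per gene context, so the
    output may be longer than the input.
    """
    from dataclasses import replace

    index = index or GeneIndex(genome.genes)
    out: list[SnvRecord] = []
    for rec in records:
        contexts = classify_region(rec, index)
        for region, gene in contexts:
            r = replace(rec) if len(contexts) > 1 else rec
            if region == "coding":
                classify_codon(r, genome, gene)
            else:
                r.region_class = region
                r.gene_id = gene.gene_id if gene else "."
                r.mutation_class = None
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# spectra + tracks
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionSpectrum:
    """Counts over the 12 directed substitution types plus a ti/tv summary."""

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return sum(self.counts.values())

    @property
    def n_transitions(self) -> int:
        return sum(v for k, v in self.counts.items() if k in TRANSITIONS)

    @property
    def n_transversions(self) -> int:
        return self.n_records - self.n_transitions

    @property
    def ti_tv(self) -> float | None:
        """Transition/transversion ratio; None (printed ``.``) when no
        transversions were observed."""
        if self.n_transversions == 0:
            return None
        return self.n_transitions / self.n_transversions

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"substitution": list(SUBSTITUTION_TYPES),
             "count": [self.counts.get(s, 0) for s in SUBSTITUTION_TYPES]})


def substitution_spectrum(records: Iterable[SnvRecord]) -> SubstitutionSpectrum:
    counter = Counter(r.substitution for r in records)
    spectrum = SubstitutionSpectrum(
        counts={s: counter.get(s, 0) for s in SUBSTITUTION_TYPES})
    return spectrum


def position_frequency_track(records: Iterable[SnvRecord],
                             genome: GenomeAnnotation | None = None
                             ) -> pd.DataFrame:
    """Per-locus table (contig, pos, sample, substitution, allele_freq), sorted
    by position — the data behind a circular genome mutation-frequency plot.

    Duplicate positions across samples are retained, distinguished by
    ``sample_id``.
    """
    rows = []
    for r in records:
        if genome is not None:
            genome.base_at(r.contig, r.pos)    # bounds check
        rows.append((r.contig, r.pos, r.sample_id or ".", r.substitution,
                     round(r.allele_freq, 6)))
    df = pd.DataFrame(rows, columns=["contig", "pos", "sample_id",
                                     "substitution", "allele_freq"])
    return df.sort_values(["contig", "pos", "sample_id"],
                          kind="mergesort").reset_index(drop=True)
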