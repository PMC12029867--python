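"""Readers and writers for every external representation the pipeline touches.

Formats and dialects
--------------------
* reference genomes: standard FASTA (sequences uppercased on read, ambiguity
  codes rejected by default);
* gene models: GFF3, 1-based inclusive coordinates;
* alignment evidence: pileup TSV with columns ``contig  pos  A  C  G  T``
  (per-site read-base counts, the stand-in for a sorted BAM);
* species relative abundances: TSV, first column ``species``, one column per
  sample, renormalized to sum to 1 per sample on load;
* sample metadata: TSV with columns
  ``sample_id  group  segment  day  replicate``;
* called variants: ``SNVs.tsv`` as documented in :func:`write_snv_table`.

All coordinates are **1-based inclusive** at every interface, matching GFF3;
any 0-based indexing is internal only.  All TSVs are UTF-8, tab-delimited,
with ``.`` for missing values.  Readers reject rather than silently repair;
every writer produces files its paired reader round-trips exactly (floats at
the stated printed precision).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_BASE_SET = frozenset(BASES)

#: feature types mapped to the ``rna_gene`` class when reading GFF3
DEFAULT_RNA_FEATURES = ("rRNA", "tRNA", "ncRNA", "tmRNA")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One gene on a reference genome, 1-based inclusive coordinates.

    ``feature_class`` is ``"CDS"`` for protein-coding genes (length divisible
    by 3) or ``"rna_gene"`` for structural-RNA genes (rRNA/tRNA/...).  Genes on
    the ``-`` strand are translated from the reverse complement; coordinates
    always refer to the forward reference strand.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    feature_class: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.feature_class not in ("CDS", "rna_gene"):
            raise FormatError(
                f"gene {self.gene_id}: bad feature_class {self.feature_class!r}"
            )
        if self.feature_class == "CDS" and self.length % 3 != 0:
            raise FormatError(
                f"gene {self.gene_id}: CDS length {self.length} not divisible by 3"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class GenomeAnnotation:
    """A reference genome: contig sequences plus (optionally) gene models.

    This is the coordinate frame every SNV lives in.  Contig sequences contain
    only A/C/G/T (or N where ambiguity codes were masked on request).
    """

    species_id: str
    contigs: list[tuple[str, str]] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, _seq in self.contigs:
            if cid in seen:
                raise FormatError(f"duplicate contig id {cid!r}")
            seen.add(cid)
        lengths = self.contig_lengths()
        for g in self.genes:
            if g.contig_id not in lengths:
                raise FormatError(
                    f"gene {g.gene_id} on unknown contig {g.contig_id!r}"
                )
            if g.end > lengths[g.contig_id]:
                raise FormatError(
                    f"gene {g.gene_id} extends past contig {g.contig_id} "
                    f"({g.end} > {lengths[g.contig_id]})"
                )

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _cid, seq in self.contigs)

    def contig_lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.contigs}

    def sequence(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    def base_at(self, contig_id: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        seq = self.sequence(contig_id)
        if not 1 <= pos <= len(seq):
            raise FormatError(
                f"position {pos} outside contig {contig_id} (length {len(seq)})"
            )
        return seq[pos - 1]


@dataclass(frozen=True)
class PileupColumn:
    """Per-site A/C/G/T read counts for one sample — the caller's sole evidence."""

    contig_id: str
    pos: int
    counts: dict[str, int] = field(hash=False)

    def __post_init__(self) -> None:
        if set(self.counts) != _BASE_SET:
            raise FormatError(f"pileup column at {self.contig_id}:{self.pos} "
                              f"must have exactly A/C/G/T counts")
        if any(c < 0 for c in self.counts.values()):
            raise FormatError(f"negative count at {self.contig_id}:{self.pos}")
        if self.pos < 1:
            raise FormatError(f"pileup position {self.pos} is not 1-based")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SampleMeta:
    """One sample of the 2-group x 2-segment x 3-day x n-replicate design."""

    sample_id: str
    group: str
    segment: str
    day: int
    replicate: int

    def __post_init__(self) -> None:
        if self.group not in ("treatment", "control"):
            raise FormatError(f"sample {self.sample_id}: bad group {self.group!r}")
        if self.segment not in ("small", "large"):
            raise FormatError(f"sample {self.sample_id}: bad segment {self.segment!r}")
        if self.replicate < 1:
            raise FormatError(f"sample {self.sample_id}: replicate must be >= 1")


class AbundanceTable:
    """Species x samples relative-abundance matrix.

    Columns are renormalized to sum to 1 on construction (tolerating
    percent-scaled input; the original scale is logged).  Species and sample
    labels must be unique.
    """

    def __init__(self, data: pd.DataFrame, normalize: bool = True):
        if data.index.has_duplicates:
            raise FormatError("duplicate species labels in abundance table")
        if data.columns.has_duplicates:
            raise FormatError("duplicate sample labels in abundance table")
        values = data.to_numpy(dtype=float)
        if (values < 0).any():
            raise FormatError("negative abundance value")
        totals = values.sum(axis=0)
        if (totals == 0).any():
            bad = data.columns[totals == 0].tolist()
            raise FormatError(f"all-zero abundance column(s): {bad}")
        if normalize:
            scale = float(np.median(totals))
            if not math.isclose(scale, 1.0, rel_tol=0.05):
                logger.info("abundance table renormalized (median column sum %.4g)",
                            scale)
            values = values / totals
        self.data = pd.DataFrame(values, index=data.index.astype(str),
                                 columns=data.columns.astype(str))

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self.data[sample_id].to_numpy()

    def species_vector(self, species_id: str, samples: Sequence[str] | None = None
                       ) -> np.ndarray:
        row = self.data.loc[species_id]
        if samples is not None:
            row = row[list(samples)]
        return row.to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return self.data.equals(other.data)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, species_id: str | None = None,
               on_ambiguous: str = "reject") -> GenomeAnnotation:
    """Read a FASTA reference into a :class:`GenomeAnnotation` (contigs only).

    Sequences are uppercased.  Characters outside A/C/G/T are rejected with an
    error naming the offending record and position (``on_ambiguous="reject"``,
    the default) or masked to ``N`` (``on_ambiguous="mask"``; masked sites are
    never callable downstream).
    """
    path = Path(path)
    if on_ambiguous not in ("reject", "mask"):
        raise FormatError(f"on_ambiguous must be 'reject' or 'mask', "
                          f"got {on_ambiguous!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    contigs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad_at = next((i for i, b in enumerate(seq) if b not in _BASE_SET), None)
        if bad_at is not None:
            if on_ambiguous == "reject":
                raise FormatError(
                    f"{path}: record {rec.id!r} contains non-ACGT character "
                    f"{seq[bad_at]!r} at position {bad_at + 1}"
                )
            seq = "".join(b if b in _BASE_SET else "N" for b in seq)
            logger.warning("%s: record %s: ambiguity codes masked to N",
                           path, rec.id)
        contigs.append((rec.id, seq))
    return GenomeAnnotation(species_id=species_id or path.stem, contigs=contigs)


def write_fasta(genome: GenomeAnnotation, path: str | Path,
                width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid, seq in genome.contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path,
              rna_features: Sequence[str] = DEFAULT_RNA_FEATURES
              ) -> list[GeneModel]:
    """Read gene models from GFF3.

    ``CDS`` rows become ``feature_class="CDS"``; the configured RNA feature
    types become ``rna_gene``.  A CDS whose length is not divisible by 3 is
    excluded with a logged warning; ``start > end`` is a format error.
    """
    import gffutils

    path = Path(path)
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            sort_attribute_values=True)
    wanted = {"CDS": "CDS"}
    wanted.update({ft: "rna_gene" for ft in rna_features})
    genes: list[GeneModel] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        fclass = wanted.get(feat.featuretype)
        if fclass is None:
            continue
        if feat.start > feat.end:
            raise FormatError(
                f"{path}: feature {feat.id!r} has start {feat.start} > end {feat.end}"
            )
        length = feat.end - feat.start + 1
        if fclass == "CDS" and length % 3 != 0:
            logger.warning("%s: CDS %s length %d not divisible by 3 — excluded",
                           path, feat.id, length)
            continue
        attrs = feat.attributes
        product = (attrs.get("product") or attrs.get("Name")
                   or attrs.get("gene") or [""])[0]
        gene_id = (attrs.get("ID") or attrs.get("locus_tag") or [feat.id])[0]
        genes.append(GeneModel(gene_id=gene_id, contig_id=feat.seqid,
                               start=feat.start, end=feat.end,
                               strand=feat.strand if feat.strand in "+-" else "+",
                               feature_class=fclass, product=product))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path,
               contig_lengths: dict[str, int] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for cid, length in contig_lengths.items():
                fh.write(f"##sequence-region {cid} 1 {length}\n")
        for g in genes:
            ftype = "CDS" if g.feature_class == "CDS" else "tRNA"
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write("\t".join([g.contig_id, "microsnv", ftype, str(g.start),
                                str(g.end), ".", g.strand, "0", attrs]) + "\n")


# ---------------------------------------------------------------------------
# pileup TSV
# ---------------------------------------------------------------------------

PILEUP_COLUMNS = ["contig", "pos", "A", "C", "G", "T"]


def read_pileup(path: str | Path) -> pd.DataFrame:
    """Read a pileup TSV into a DataFrame with columns contig/pos/A/C/G/T."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    if list(df.columns) != PILEUP_COLUMNS:
        raise FormatError(f"{path}: expected columns {PILEUP_COLUMNS}, "
                          f"got {list(df.columns)}")
    for col in ("pos", "A", "C", "G", "T"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise FormatError(f"{path}: column {col} must be integer")
    if (df[["A", "C", "G", "T"]].to_numpy() < 0).any():
        raise FormatError(f"{path}: negative base count")
    if (df["pos"] < 1).any():
        raise FormatError(f"{path}: positions must be 1-based (>= 1)")
    return df


def write_pileup(df: pd.DataFrame, path: str | Path) -> None:
    df[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def pileup_columns(df: pd.DataFrame) -> Iterable[PileupColumn]:
    """Iterate a pileup DataFrame as validated :class:`PileupColumn` objects."""
    for row in df.itertuples(index=False):
        yield PileupColumn(contig_id=row.contig, pos=int(row.pos),
                           counts={"A": int(row.A), "C": int(row.C),
                                   "G": int(row.G), "T": int(row.T)})


# ---------------------------------------------------------------------------
# abundance + metadata TSV
# ---------------------------------------------------------------------------

def read_abundance(path: str | Path, normalize: bool = True) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "species":
        raise FormatError(f"{path}: first column must be named 'species'")
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    return AbundanceTable(df, normalize=normalize)


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    out = table.data.copy()
    out.index.name = "species"
    out.to_csv(path, sep="\t", float_format="%.8f")


def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str,
                                            "segment": str})
    expected = ["sample_id", "group", "segment", "day", "replicate"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, "
                          f"got {list(df.columns)}")
    metas = [SampleMeta(sample_id=r.sample_id, group=r.group, segment=r.segment,
                        day=int(r.day), replicate=int(r.replicate))
             for r in df.itertuples(index=False)]
    keys = [(m.group, m.segment, m.day, m.replicate) for m in metas]
    if len(set(keys)) != len(keys):
        raise FormatError(f"{path}: duplicate (group, segment, day, replicate)")
    if len({m.sample_id for m in metas}) != len(metas):
        raise FormatError(f"{path}: duplicate sample_id")
    return metas


def write_metadata(metas: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [(m.sample_id, m.group, m.segment, m.day, m.replicate) for m in metas]
    pd.DataFrame(rows, columns=["sample_id", "group", "segment", "day",
                                "replicate"]).to_csv(path, sep="\t", index=False)


def metadata_by_id(metas: Iterable[SampleMeta]) -> dict[str, SampleMeta]:
    return {m.sample_id: m for m in metas}


# ---------------------------------------------------------------------------
# SNVs.tsv
# ---------------------------------------------------------------------------

SNV_COLUMNS = [
    "sample_id", "species_id", "contig", "pos", "ref_base", "alt_base",
    "ref_count", "alt_count", "depth", "allele_freq", "region_class",
    "mutation_class", "gene_id", "substitution", "is_transition",
    "codon_ref", "codon_alt", "aa_ref", "aa_alt",
]


def write_snv_table(records: Iterable, path: str | Path) -> None:
    """Serialize SNV records to the ``SNVs.tsv`` dialect.

    One row per called variant: position (1-based), reference and alternate
    base with their read counts, the alternate allele frequency printed to six
    decimals, region and mutation classes, the directed substitution
    (e.g. ``C>A``), its transition status, and — for coding variants — the
    reference/alternate codons and amino acids.  Missing values are ``.``.
    """
    rows = []
    for r in records:
        rows.append([
            r.sample_id or ".", r.species_id, r.contig, r.pos, r.ref_base,
            r.alt_base, r.ref_count, r.alt_count, r.depth,
            f"{r.allele_freq:.6f}",
            r.region_class or ".", r.mutation_class or ".", r.gene_id or ".",
            r.substitution, "true" if r.is_transition else "false",
            r.codon_ref or ".", r.codon_alt or ".",
            r.aa_ref or ".", r.aa_alt or ".",
        ])
    pd.DataFrame(rows, columns=SNV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_snv_table(path: str | Path) -> list:
    """Read ``SNVs.tsv`` back into :class:`~microsnv.snv_profiler.SnvRecord`
    objects; malformed rows raise with their row number."""
    from .snv_profiler import SnvRecord

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != SNV_COLUMNS:
        raise FormatError(f"{path}: expected columns {SNV_COLUMNS}, "
                          f"got {list(df.columns)}")

    def opt(v: str) -> str | None:
        return None if v == "." else v

    records: list[SnvRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = SnvRecord(
                species_id=row.species_id, contig=row.contig, pos=int(row.pos),
                ref_base=row.ref_base, alt_base=row.alt_base,
                ref_count=int(row.ref_count), alt_count=int(row.alt_count),
                depth=int(row.depth),
                region_class=opt(row.region_class),
                mutation_class=opt(row.mutation_class),
                gene_id=row.gene_id,
                codon_ref=opt(row.codon_ref), codon_alt=opt(row.codon_alt),
                aa_ref=opt(row.aa_ref), aa_alt=opt(row.aa_alt),
                sample_id=opt(row.sample_id),
            )
            if row.substitution != rec.substitution:
                raise FormatError(f"substitution column {row.substitution!r} "
                                  f"inconsistent with bases")
            if row.is_transition not in ("true", "false"):
                raise FormatError(f"bad is_transition {row.is_transition!r}")
            if (row.is_transition == "true") != rec.is_transition:
                raise FormatError("is_transition column inconsistent with bases")
            if abs(float(row.allele_freq) - rec.allele_freq) > 5e-7:
                raise FormatError(f"allele_freq column {row.allele_freq} "
                                  f"inconsistent with counts")
        except (ValueError, KeyError) as exc:
            raise FormatError(f"{path}: malformed row {i}: {exc}") from exc
        records.append(rec)
    return records
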