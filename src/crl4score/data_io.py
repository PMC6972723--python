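"""Readers, writers and genomic-interval bookkeeping for the gene-panel analysis.

Two coordinate conventions are used consistently throughout the package:
VCF records are 1-based (as in the format itself), while every in-memory
interval is 0-based, half-open.  Gene models describe a single transcript
per gene, as in a targeted sequencing panel covering exons, UTRs and a
fixed intronic flank on each side of every exon.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

Interval = tuple[int, int]

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class Location(str, enum.Enum):
    """Panel region a variant falls in."""

    CODING = "coding"
    UTR5 = "utr5"
    UTR3 = "utr3"
    INTRONIC_FLANK = "intronic_flank"
    OUT_OF_PANEL = "out_of_panel"


class CodingEffect(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"


#: categories reported in a panel-vs-reference location comparison
PANEL_CATEGORIES = (
    Location.CODING.value,
    Location.UTR5.value,
    Location.UTR3.value,
    Location.INTRONIC_FLANK.value,
)


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed; carries the offending record number."""

    def __init__(self, message: str, record: int | None = None):
        self.record = record
        if record is not None:
            message = f"{message} (at VCF record {record})"
        super().__init__(message)


@dataclass(frozen=True)
class Variant:
    """A single biallelic variant (one ALT allele)."""

    chrom: str
    pos: int  # 1-based, as in the VCF
    ref: str
    alt: str
    vid: str
    gene: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) for {self.vid}")
        for allele in (self.ref, self.alt):
            if not allele or set(allele.upper()) - set("ACGT"):
                raise ValueError(f"allele {allele!r} not over ACGT for {self.vid}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def span(self) -> Interval:
        """0-based half-open interval covered by the REF allele."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))


class GenotypeMatrix:
    """Individuals x variants alt-allele dosage, values in {0, 1, 2, NaN}."""

    def __init__(self, dosage: pd.DataFrame):
        bad = dosage.stack().dropna().unique()
        if len(set(bad) - {0.0, 1.0, 2.0}) > 0:
            raise ValueError(f"dosage values outside {{0,1,2,NaN}}: {sorted(set(bad))}")
        self.dosage = dosage.astype(float)

    @property
    def individuals(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def vids(self) -> list[str]:
        return list(self.dosage.columns)

    def __eq__(self, other):
        return isinstance(other, GenotypeMatrix) and self.dosage.equals(other.dosage)

    def subset(self, individuals: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage.loc[list(individuals)])


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _covered(pos: int, intervals: Sequence[Interval]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def _subset_of(inner: Sequence[Interval], outer: Sequence[Interval]) -> bool:
    merged = merge_intervals(outer)
    for s, e in inner:
        if not any(ms <= s and e <= me for ms, me in merged):
            return False
    return True


@dataclass
class GeneModel:
    """Single-transcript gene model with panel windows.

    ``critical_exons`` holds 1-based exon numbers (counted in transcript
    orientation) whose loss would remove an essential protein domain; a
    splicing-relevant variant upstream of the first critical exon is
    treated as maximally severe by the scoring modifier.
    """

    gene: str
    transcript: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    flank: int = 50
    critical_exons: tuple[int, ...] = ()
    chrom: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for name in ("exons", "cds", "utr5", "utr3"):
            ivs = sorted(getattr(self, name))
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"{name} intervals overlap in {self.gene}")
            if any(s >= e for s, e in ivs):
                raise ValueError(f"empty/inverted {name} interval in {self.gene}")
            setattr(self, name, ivs)
        for name in ("cds", "utr5", "utr3"):
            if not _subset_of(getattr(self, name), self.exons):
                raise ValueError(f"{name} not contained in exons for {self.gene}")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def panel_windows(self) -> list[Interval]:
        return merge_intervals(
            (max(0, s - self.flank), e + self.flank) for s, e in self.exons
        )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def exon_number(self, genomic_index: int) -> int:
        """1-based exon number in transcript orientation for exon at genomic rank i."""
        if not 0 <= genomic_index < self.n_exons:
            raise IndexError(genomic_index)
        return genomic_index + 1 if self.strand == "+" else self.n_exons - genomic_index

    def nearest_exon_number(self, pos0: int) -> int | None:
        """Exon number containing pos0 or whose flank window contains it; None if out of panel."""
        best = None  # (distance, exon number)
        for i, (s, e) in enumerate(self.exons):
            if s <= pos0 < e:
                return self.exon_number(i)
            d = s - pos0 if pos0 < s else pos0 - (e - 1)
            if d <= self.flank and (best is None or d < best[0]):
                best = (d, self.exon_number(i))
        return best[1] if best else None

    def cds_position(self, pos0: int) -> int | None:
        """Map a genomic position to a 0-based spliced-CDS coordinate (strand aware)."""
        offset = 0
        for s, e in self.cds:
            if s <= pos0 < e:
                fwd = offset + (pos0 - s)
                if self.strand == "+":
                    return fwd
                return self.cds_length - 1 - fwd
            offset += e - s
        return None

    def extract_cds(self, chrom_seq: str) -> str:
        """Spliced CDS sequence in translation orientation."""
        seq = "".join(chrom_seq[s:e] for s, e in self.cds)
        return seq if self.strand == "+" else revcomp(seq)


def classify_location(v: Variant, gm: GeneModel) -> Location:
    """Assign the panel category of a variant.

    The REF span is tested against CDS, then UTRs, then the exon +/- flank
    windows; anything outside the windows is flagged ``out_of_panel``.
    """
    span = range(*v.span)
    for loc, ivs in (
        (Location.CODING, gm.cds),
        (Location.UTR5, gm.utr5),
        (Location.UTR3, gm.utr3),
    ):
        if any(_covered(p, ivs) for p in span):
            return loc
    if any(_covered(p, gm.panel_windows) for p in span):
        return Location.INTRONIC_FLANK
    return Location.OUT_OF_PANEL


def coding_effect(v: Variant, gm: GeneModel, cds_seq: str) -> CodingEffect:
    """Subtype a coding SNV using the spliced CDS sequence.

    The CDS must be in translation orientation (what :meth:`GeneModel.extract_cds`
    returns); the alternative base is reverse-complemented for minus-strand genes.
    """
    from Bio.Data import CodonTable

    if not v.is_snv:
        raise ValueError("coding effect subtyping implemented for SNVs only")
    cpos = gm.cds_position(v.pos - 1)
    if cpos is None:
        raise ValueError(f"{v.vid} is not inside the CDS of {gm.gene}")
    table = CodonTable.unambiguous_dna_by_id[1]
    ci, within = divmod(cpos, 3)
    codon = cds_seq[3 * ci : 3 * ci + 3].upper()
    ref_base = v.ref.upper() if gm.strand == "+" else revcomp(v.ref).upper()
    alt_base = v.alt.upper() if gm.strand == "+" else revcomp(v.alt).upper()
    if codon[within] != ref_base:
        raise ValueError(
            f"REF mismatch for {v.vid}: CDS codon {codon} position {within} "
            f"is {codon[within]}, expected {ref_base}"
        )
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    if alt_codon in table.stop_codons:
        return CodingEffect.NONSENSE
    if codon in table.stop_codons:
        raise ValueError(f"reference codon of {v.vid} is a stop codon")
    if table.forward_table[codon] == table.forward_table[alt_codon]:
        return CodingEffect.SYNONYMOUS
    return CodingEffect.MISSENSE


def truncate1(x: float) -> float:
    """Truncate (not round) to one decimal place."""
    return math.floor(x * 10) / 10


@dataclass
class LocationDistribution:
    """Per-category variant counts for one named sample."""

    sample: str
    counts: dict[str, int]
    per_gene: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def n_in_panel(self) -> int:
        return sum(self.counts.get(c, 0) for c in PANEL_CATEGORIES)

    def percentages(self) -> dict[str, float]:
        """In-panel category shares, truncated to one decimal place."""
        total = self.n_in_panel
        if total == 0:
            return {c: 0.0 for c in PANEL_CATEGORIES}
        return {c: truncate1(100.0 * self.counts.get(c, 0) / total) for c in PANEL_CATEGORIES}


def location_counts(
    variants: Iterable[Variant],
    models: Mapping[str, GeneModel],
    sample: str = "sample",
) -> LocationDistribution:
    counts: dict[str, int] = {c: 0 for c in PANEL_CATEGORIES}
    counts[Location.OUT_OF_PANEL.value] = 0
    per_gene: dict[str, dict[str, int]] = {}
    for v in variants:
        if v.gene not in models:
            raise KeyError(f"no gene model for {v.gene!r} (variant {v.vid})")
        loc = classify_location(v, models[v.gene]).value
        counts[loc] = counts.get(loc, 0) + 1
        gc = per_gene.setdefault(v.gene, {c: 0 for c in counts})
        gc[loc] = gc.get(loc, 0) + 1
    return LocationDistribution(sample=sample, counts=counts, per_gene=per_gene)


# ---------------------------------------------------------------------------
# file formats


def read_vcf(
    path: str | Path, cohort_ids: Sequence[str] | None = None
) -> tuple[list[Variant], GenotypeMatrix]:
    """Read a VCF into biallelic variants and a dosage matrix.

    Multi-allelic records are decomposed into one :class:`Variant` per ALT
    allele; per-sample dosage is the count of that ALT in the GT field, with
    any missing allele giving a missing (NaN) dosage.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    if cohort_ids is not None:
        missing = set(cohort_ids) - set(samples)
        if missing:
            raise VcfParseError(f"samples absent from VCF: {sorted(missing)}")
        samples = list(cohort_ids)
    variants: list[Variant] = []
    rows: list[list[float]] = []
    recno = 0
    try:
        for rec in vf:
            recno += 1
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                base = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
                vid = base if len(alts) == 1 else f"{base}:{rec.ref}>{alt}"
                gene = rec.info.get("GENE", "")
                if isinstance(gene, tuple):
                    gene = gene[0]
                variants.append(
                    Variant(rec.chrom, rec.pos, rec.ref, alt, vid=vid, gene=gene or "")
                )
                row = []
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt):
                        row.append(float("nan"))
                    else:
                        row.append(float(sum(1 for a in gt if a == ai)))
                rows.append(row)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}", record=recno + 1) from exc
    vids = [v.vid for v in variants]
    if len(set(vids)) != len(vids):
        raise VcfParseError("duplicate variant identifiers after decomposition")
    dosage = pd.DataFrame(
        list(map(list, zip(*rows))) if rows else [[] for _ in samples],
        index=samples,
        columns=vids,
        dtype=float,
    )
    return variants, GenotypeMatrix(dosage)


def write_vcf(
    variants: Sequence[Variant],
    gmatrix: GenotypeMatrix,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write biallelic records (one per variant) with GT genotypes."""
    header = pysam.VariantHeader()
    contigs: dict[str, int] = dict(contig_lengths or {})
    for v in variants:
        contigs.setdefault(v.chrom, 0)
        contigs[v.chrom] = max(contigs[v.chrom], v.pos + len(v.ref) + 1000)
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.info.add("GENE", 1, "String", "Panel gene symbol")
    header.formats.add("GT", 1, "String", "Genotype")
    for ind in gmatrix.individuals:
        header.add_sample(ind)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
                id=v.vid,
            )
            if v.gene:
                rec.info["GENE"] = v.gene
            for ind in gmatrix.individuals:
                d = gmatrix.dosage.at[ind, v.vid]
                if pd.isna(d):
                    rec.samples[ind]["GT"] = (None, None)
                else:
                    rec.samples[ind]["GT"] = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(d)]
            out.write(rec)


_GM_FEATURES = {"exon", "cds", "utr5", "utr3", "critical_exon"}


def read_gene_models(path: str | Path, flank: int = 50) -> dict[str, GeneModel]:
    """Read gene models from a 7-column TSV.

    Columns: gene, transcript, chrom, strand, feature, start, end with
    feature in {exon, cds, utr5, utr3, critical_exon}.  Coordinates are
    0-based half-open.  For ``critical_exon`` rows, ``start`` holds the
    1-based exon number and ``end`` is ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "transcript": str, "chrom": str})
    required = {"gene", "transcript", "chrom", "strand", "feature", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"gene model TSV missing columns: {sorted(required - set(df.columns))}")
    unknown = set(df["feature"]) - _GM_FEATURES
    if unknown:
        raise ValueError(f"unknown gene-model features: {sorted(unknown)}")
    models: dict[str, GeneModel] = {}
    for gene, sub in df.groupby("gene", sort=False):
        kw: dict[str, list[Interval]] = {"exons": [], "cds": [], "utr5": [], "utr3": []}
        critical: list[int] = []
        for _, r in sub.iterrows():
            if r.feature == "critical_exon":
                critical.append(int(r.start))
            else:
                key = "exons" if r.feature == "exon" else r.feature
                kw[key].append((int(r.start), int(r.end)))
        models[gene] = GeneModel(
            gene=gene,
            transcript=sub["transcript"].iloc[0],
            chrom=sub["chrom"].iloc[0],
            strand=sub["strand"].iloc[0],
            flank=flank,
            critical_exons=tuple(sorted(critical)),
            **kw,
        )
    return models


def write_gene_models(models: Mapping[str, GeneModel], path: str | Path) -> None:
    rows = []
    for gm in models.values():
        for feature, ivs in (
            ("exon", gm.exons),
            ("cds", gm.cds),
            ("utr5", gm.utr5),
            ("utr3", gm.utr3),
        ):
            for s, e in ivs:
                rows.append((gm.gene, gm.transcript, gm.chrom, gm.strand, feature, s, e))
        for ce in gm.critical_exons:
            rows.append((gm.gene, gm.transcript, gm.chrom, gm.strand, "critical_exon", ce, ce))
    pd.DataFrame(
        rows, columns=["gene", "transcript", "chrom", "strand", "feature", "start", "end"]
    ).to_csv(path, sep="\t", index=False)


ENDOPHENOTYPES = ("pre_axial_longitudinal", "intercalary_transverse", "other", "none")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype table: individual, cohort in {case, reference}, endophenotype."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual", "cohort", "endophenotype"}
    if not required <= set(df.columns):
        raise ValueError(f"phenotype TSV missing columns: {sorted(required - set(df.columns))}")
    if df["individual"].duplicated().any():
        raise ValueError("duplicate individual ids in phenotype table")
    bad = set(df["cohort"]) - {"case", "reference"}
    if bad:
        raise ValueError(f"unknown cohort labels: {sorted(bad)}")
    bad = set(df["endophenotype"]) - set(ENDOPHENOTYPES)
    if bad:
        raise ValueError(f"unknown endophenotypes: {sorted(bad)}")
    return df


def read_location_counts(path: str | Path, sample: str = "reference") -> LocationDistribution:
    """Reference location-distribution counts from a two-column TSV (category, count)."""
    df = pd.read_csv(path, sep="\t")
    counts = {str(r.category): int(r["count"]) for _, r in df.iterrows()}
    unknown = set(counts) - set(PANEL_CATEGORIES) - {Location.OUT_OF_PANEL.value}
    if unknown:
        warnings.warn(f"ignoring unknown location categories: {sorted(unknown)}")
    return LocationDistribution(sample=sample, counts=counts)


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
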