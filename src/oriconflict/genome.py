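"""Circular bacterial genome model with bidirectional replication geometry.

A circular chromosome replicated bidirectionally from a single origin is split
into two replichores: the *right* replichore is the arc traversed from the
origin in the direction of increasing coordinate (wrapping at the genome
length) up to, but not including, the terminus; the *left* replichore is the
remainder.  A gene transcribed in the same direction the replication fork
travels through its locus is *codirectional* (CD); a gene transcribed against
the fork is *head-on* (HO).  On the forward reference strand this reduces to:
forward-strand genes on the right replichore and reverse-strand genes on the
left replichore are CD; all others are HO.

Each parental strand also has a replication role at every position: it is
either the leading-strand template (LDST) or the lagging-strand template
(LGST).  On the right replichore the forward strand templates the lagging
strand (LGST) and the reverse strand templates the leading strand (LDST);
the roles swap on the left replichore.  Consequently the transcribed
(template) strand of a CD gene is always the LDST and that of an HO gene is
always the LGST.

Coordinates are 1-based inclusive externally (GFF3 convention); internal
arithmetic converts to 0-based where convenient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import pandas as pd

Strand = Literal["forward", "reverse"]
Replichore = Literal["right", "left"]
Template = Literal["LDST", "LGST"]
Orientation = Literal["CD", "HO"]

GENE_CATEGORIES = {
    "tRNA",
    "ribosomal",
    "essential",
    "rpoS_up",
    "rpoS_low",
    "sos_all",
    "sos_damage",
    "lexA",
    "highly_expressed",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    """A position or interval falls outside the genome."""


@dataclass(frozen=True)
class Gene:
    """A coding sequence on the forward-coordinate frame.

    ``start <= end`` unless the CDS wraps the origin of the coordinate
    system, in which case ``wraps_origin`` is set and the CDS covers
    ``[start..length] + [1..end]``.
    """

    gene_id: str
    start: int
    end: int
    strand: Strand
    name: str = ""
    wraps_origin: bool = False
    categories: frozenset[str] = field(default_factory=frozenset)
    tpm_lag: float | None = None
    tpm_log: float | None = None
    tpm_stat: float | None = None

    def cds_length(self, genome_length: int | None = None) -> int:
        if not self.wraps_origin:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError("genome_length required for a wrapping CDS")
        return (genome_length - self.start + 1) + self.end


@dataclass(frozen=True)
class Promoter:
    promoter_id: str
    tss_pos: int
    strand: Strand
    gene_id: str | None = None


@dataclass(frozen=True)
class OrientationCall:
    gene_id: str
    replichore: Replichore
    orientation: Orientation
    transcribed_strand_template: Template


@dataclass
class GenomeAnnotation:
    genome_id: str
    length: int
    origin_pos: int
    sequence: str
    terminus_pos: int | None = None
    genes: list[Gene] = field(default_factory=list)
    promoters: list[Promoter] = field(default_factory=list)
    is_circular: bool = True

    def __post_init__(self) -> None:
        if self.terminus_pos is None:
            self.terminus_pos = default_terminus(self.origin_pos, self.length)
        if not (1 <= self.origin_pos <= self.length):
            raise CoordinateError(f"origin_pos {self.origin_pos} outside [1, {self.length}]")
        if not (1 <= self.terminus_pos <= self.length):
            raise CoordinateError(f"terminus_pos {self.terminus_pos} outside [1, {self.length}]")
        if self.origin_pos == self.terminus_pos:
            raise ValueError("origin and terminus must differ")
        if len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )
        for g in self.genes:
            for p in (g.start, g.end):
                if not (1 <= p <= self.length):
                    raise CoordinateError(f"gene {g.gene_id} coordinate {p} outside genome")
        for pr in self.promoters:
            if not (1 <= pr.tss_pos <= self.length):
                raise CoordinateError(f"promoter {pr.promoter_id} TSS outside genome")

    def base_at(self, pos: int) -> str:
        if not (1 <= pos <= self.length):
            raise CoordinateError(f"position {pos} outside [1, {self.length}]")
        return self.sequence[pos - 1]

    def gene_by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def default_terminus(origin_pos: int, length: int) -> int:
    """Terminus halfway around the circle from the origin."""
    return (origin_pos - 1 + length // 2) % length + 1


def classify_replichore(pos: int, genome: GenomeAnnotation) -> Replichore:
    """Replichore of a position: ``right`` iff it lies on the arc from the
    origin (inclusive) walking in increasing coordinate, wrapping at the
    genome length, up to but not including the terminus."""
    if not (1 <= pos <= genome.length):
        raise CoordinateError(f"position {pos} outside [1, {genome.length}]")
    ori, ter = genome.origin_pos, genome.terminus_pos
    if ori < ter:
        return "right" if ori <= pos < ter else "left"
    return "right" if (pos >= ori or pos < ter) else "left"


def circular_midpoint(start: int, end: int, length: int, wraps_origin: bool = False) -> int:
    """Midpoint of a (possibly origin-wrapping) 1-based inclusive interval."""
    if not wraps_origin:
        return (start + end) // 2
    span = (length - start + 1) + end
    return (start - 1 + (span - 1) // 2) % length + 1


def strand_template(pos: int, strand: Strand, genome: GenomeAnnotation) -> Template:
    """Replication role of a parental strand at a position.

    Right replichore: forward strand -> LGST, reverse strand -> LDST;
    mirrored on the left replichore.  This is the unique assignment under
    which every CD gene's transcribed strand is the LDST and every HO
    gene's is the LGST.
    """
    rep = classify_replichore(pos, genome)
    if rep == "right":
        return "LGST" if strand == "forward" else "LDST"
    return "LDST" if strand == "forward" else "LGST"


def classify_orientation(gene: Gene, genome: GenomeAnnotation) -> OrientationCall:
    """CD/HO call for a gene, decided at its circular CDS midpoint."""
    mid = circular_midpoint(gene.start, gene.end, genome.length, gene.wraps_origin)
    rep = classify_replichore(mid, genome)
    cd = (gene.strand == "forward") == (rep == "right")
    orientation: Orientation = "CD" if cd else "HO"
    # transcribed (template) strand is the opposite of the coding strand
    template_strand: Strand = "reverse" if gene.strand == "forward" else "forward"
    tmpl = strand_template(mid, template_strand, genome)
    return OrientationCall(
        gene_id=gene.gene_id,
        replichore=rep,
        orientation=orientation,
        transcribed_strand_template=tmpl,
    )


def orientation_table(genome: GenomeAnnotation) -> pd.DataFrame:
    """Per-gene orientation calls as a DataFrame indexed by gene_id."""
    rows = []
    for g in genome.genes:
        call = classify_orientation(g, genome)
        rows.append(
            {
                "gene_id": g.gene_id,
                "strand": g.strand,
                "replichore": call.replichore,
                "orientation": call.orientation,
                "transcribed_strand_template": call.transcribed_strand_template,
                "cds_length": g.cds_length(genome.length),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "strand",
            "replichore",
            "orientation",
            "transcribed_strand_template",
            "cds_length",
        ],
    )
    return df.set_index("gene_id")


def partition_counts(genome: GenomeAnnotation) -> tuple[int, int]:
    """(n_CD, n_HO) over all annotated genes."""
    n_cd = sum(1 for g in genome.genes if classify_orientation(g, genome).orientation == "CD")
    return n_cd, len(genome.genes) - n_cd


def classify_promoter_orientation(promoter: Promoter, genome: GenomeAnnotation) -> Orientation:
    rep = classify_replichore(promoter.tss_pos, genome)
    return "CD" if (promoter.strand == "forward") == (rep == "right") else "HO"


# ---------------------------------------------------------------------------
# I/O: FASTA + GFF3 + gene_meta sidecar
# ---------------------------------------------------------------------------

_STRAND_TO_GFF = {"forward": "+", "reverse": "-"}
_GFF_TO_STRAND = {"+": "forward", "-": "reverse"}


def write_fasta(genome: GenomeAnnotation, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.genome_id, description="circular")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: str | Path) -> tuple[str, str]:
    """(record id, sequence) of a single-record FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    return records[0].id, str(records[0].seq).upper()


def write_gff3(genome: GenomeAnnotation, path: str | Path) -> None:
    lines = ["##gff-version 3", f"##sequence-region {genome.genome_id} 1 {genome.length}"]
    for g in sorted(genome.genes, key=lambda g: (g.start, g.gene_id)):
        attrs = f"ID={g.gene_id}"
        if g.name:
            attrs += f";Name={g.name}"
        if g.wraps_origin:
            attrs += ";wraps_origin=true"
        lines.append(
            "\t".join(
                [
                    genome.genome_id,
                    "oriconflict",
                    "gene",
                    str(g.start),
                    str(g.end),
                    ".",
                    _STRAND_TO_GFF[g.strand],
                    ".",
                    attrs,
                ]
            )
        )
    for p in sorted(genome.promoters, key=lambda p: (p.tss_pos, p.promoter_id)):
        attrs = f"ID={p.promoter_id}"
        if p.gene_id:
            attrs += f";gene_id={p.gene_id}"
        lines.append(
            "\t".join(
                [
                    genome.genome_id,
                    "oriconflict",
                    "promoter",
                    str(p.tss_pos),
                    str(p.tss_pos),
                    ".",
                    _STRAND_TO_GFF[p.strand],
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_gff_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | Path) -> tuple[list[Gene], list[Promoter]]:
    """Parse ``gene`` and ``promoter``/``TSS`` features from a GFF3 file."""
    genes: list[Gene] = []
    promoters: list[Promoter] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        _, _, ftype, start, end, _, strand_sym, _, attr_text = fields
        attrs = _parse_gff_attrs(attr_text)
        strand = _GFF_TO_STRAND.get(strand_sym)
        if strand is None:
            raise ValueError(f"feature without strand: {line!r}")
        if ftype in ("gene", "CDS"):
            genes.append(
                Gene(
                    gene_id=attrs.get("ID", f"gene_{len(genes) + 1}"),
                    name=attrs.get("Name", ""),
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    wraps_origin=attrs.get("wraps_origin", "").lower() == "true",
                )
            )
        elif ftype in ("promoter", "TSS"):
            promoters.append(
                Promoter(
                    promoter_id=attrs.get("ID", f"prom_{len(promoters) + 1}"),
                    tss_pos=int(start),
                    strand=strand,
                    gene_id=attrs.get("gene_id") or None,
                )
            )
    return genes, promoters


def write_gene_meta(genome: GenomeAnnotation, path: str | Path) -> None:
    rows = []
    for g in sorted(genome.genes, key=lambda g: g.gene_id):
        rows.append(
            {
                "gene_id": g.gene_id,
                "categories": ";".join(sorted(g.categories)),
                "tpm_lag": "" if g.tpm_lag is None else repr(g.tpm_lag),
                "tpm_log": "" if g.tpm_log is None else repr(g.tpm_log),
                "tpm_stat": "" if g.tpm_stat is None else repr(g.tpm_stat),
            }
        )
    pd.DataFrame(rows, columns=["gene_id", "categories", "tpm_lag", "tpm_log", "tpm_stat"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_meta(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "categories": str})
    df["categories"] = df["categories"].fillna("")
    return df.set_index("gene_id")


def read_genome(
    fasta_path: str | Path,
    gff3_path: str | Path | None = None,
    gene_meta_path: str | Path | None = None,
    origin_pos: int = 1,
    terminus_pos: int | None = None,
) -> GenomeAnnotation:
    """Assemble a GenomeAnnotation from FASTA + GFF3 + gene_meta sidecar."""
    genome_id, sequence = read_fasta(fasta_path)
    genes: list[Gene] = []
    promoters: list[Promoter] = []
    if gff3_path is not None:
        genes, promoters = read_gff3(gff3_path)
    if gene_meta_path is not None and genes:
        meta = read_gene_meta(gene_meta_path)
        enriched = []
        for g in genes:
            if g.gene_id in meta.index:
                row = meta.loc[g.gene_id]
                cats = frozenset(c for c in str(row["categories"]).split(";") if c)

                def _tpm(v):
                    return None if pd.isna(v) or v == "" else float(v)

                g = replace(
                    g,
                    categories=cats,
                    tpm_lag=_tpm(row.get("tpm_lag")),
                    tpm_log=_tpm(row.get("tpm_log")),
                    tpm_stat=_tpm(row.get("tpm_stat")),
                )
            enriched.append(g)
        genes = enriched
    return GenomeAnnotation(
        genome_id=genome_id,
        length=len(sequence),
        origin_pos=origin_pos,
        terminus_pos=terminus_pos,
        sequence=sequence,
        genes=genes,
        promoters=promoters,
    )
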