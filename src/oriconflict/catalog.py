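"""Mutation catalogs from mutation accumulation (MA) experiments.

A catalog row is one called mutation — a base-pair substitution (BPS) or a
small insertion/deletion of at most 4 bp — recorded on forward-strand
coordinates with line/experiment provenance.  Strand interpretation (which
parental strand carried the mutated base) is always derived from the genome
geometry downstream, never stored.

Indels are left-normalized on read: an indel inside or adjacent to a
homopolymer is shifted to its leftmost equivalent position, which makes the
later attribution of indels to mononucleotide runs deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .genome import GenomeAnnotation

MAX_INDEL_LEN = 4  # larger events are not detectable by the upstream calling

MutationKind = Literal["BPS", "insertion", "deletion"]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


class CatalogValidationError(ValueError):
    """A catalog row is inconsistent with the genome sequence."""


@dataclass(frozen=True)
class BpsClass:
    """A base-pair substitution collapsed to the mutated base pair.

    The six BPS types are the two transitions (A:T>G:C, G:C>A:T) and the
    four transversions grouped by the mutated pair (A:T>T:A, A:T>C:G,
    G:C>T:A, G:C>C:G).
    """

    pair_class: Literal["AT", "GC"]
    change_class: Literal["transition", "transversion"]
    canonical_label: str


@dataclass(frozen=True)
class Mutation:
    mutation_id: str
    experiment_id: str
    line_id: str
    pos: int
    kind: MutationKind
    ref: str  # BPS: reference base; deletion: deleted bases; insertion: ""
    alt: str  # BPS: alternate base; insertion: inserted bases; deletion: ""
    indel_len: int = 0

    @property
    def is_bps(self) -> bool:
        return self.kind == "BPS"

    @property
    def is_indel(self) -> bool:
        return self.kind in ("insertion", "deletion")

    @property
    def indel_unit(self) -> str:
        """The inserted or deleted bases."""
        return self.alt if self.kind == "insertion" else self.ref

    def bps_class(self) -> BpsClass:
        if not self.is_bps:
            raise ValueError(f"{self.mutation_id} is not a BPS")
        return classify_bps(self.ref, self.alt)


@dataclass(frozen=True)
class ExperimentMeta:
    experiment_id: str
    line_id: str
    generations: float
    genotype_tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.generations > 0:
            raise ValueError(f"nonpositive generations for line {self.line_id}")


def classify_bps(ref: str, alt: str) -> BpsClass:
    """Collapse an ordered (ref, alt) base change to its pair class.

    A>G and T>C are both the A:T>G:C transition, etc.  Out of the 12
    ordered single-base changes, 4 are transitions and 8 transversions.
    """
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"non-ACGT bases: {ref}>{alt}")
    if ref == alt:
        raise ValueError(f"ref equals alt: {ref}")
    pair_class = "AT" if ref in "AT" else "GC"
    change_class = "transition" if (ref, alt) in _TRANSITIONS else "transversion"
    # canonical label written with the purine (A or G) of the mutated pair first
    if ref in "TC":
        r, a = _COMPLEMENT[ref], _COMPLEMENT[alt]
    else:
        r, a = ref, alt
    pair_of = {"A": "AT", "T": "TA", "G": "GC", "C": "CG"}
    label = f"{pair_of[r]}>{pair_of[a]}"
    return BpsClass(pair_class=pair_class, change_class=change_class, canonical_label=label)


def left_normalize(pos: int, unit: str, sequence: str) -> tuple[int, str]:
    """Shift an indel to its leftmost equivalent position.

    ``pos`` is the 1-based position of the first affected base (for an
    insertion: the bases are inserted so that the first inserted base ends
    up at ``pos``).  While the reference base immediately left of ``pos``
    equals the last base of the indel unit, the event can be slid one base
    left with the unit rotated; inside a homopolymer the rotation is the
    identity.  The slide stops at position 1 (the linear convention; a
    wrap-around slide would make positions line-dependent).
    """
    while pos > 1 and sequence[pos - 2] == unit[-1]:
        pos -= 1
        unit = unit[-1] + unit[:-1]
    return pos, unit


def total_exposure(meta: Sequence[ExperimentMeta]) -> float:
    """Total line-generations across an experiment set (rate denominator)."""
    if not meta:
        raise ValueError("empty experiment metadata")
    return float(sum(m.generations for m in meta))


# ---------------------------------------------------------------------------
# TSV / VCF I/O
# ---------------------------------------------------------------------------

_CATALOG_COLUMNS = [
    "mutation_id",
    "experiment_id",
    "line_id",
    "pos",
    "kind",
    "ref",
    "alt",
    "indel_len",
]


def _infer_kind(ref: str, alt: str) -> MutationKind:
    if ref and alt:
        if len(ref) != 1 or len(alt) != 1:
            raise CatalogValidationError(f"unsupported allele pair {ref}>{alt}")
        return "BPS"
    if alt and not ref:
        return "insertion"
    if ref and not alt:
        return "deletion"
    raise CatalogValidationError("row with empty ref and alt")


def read_catalog(
    path: str | Path,
    genome: GenomeAnnotation,
    strict: bool = True,
) -> tuple[list[Mutation], int]:
    """Read, validate and normalize a mutation TSV.

    Returns ``(mutations, n_rejected)`` where rejected rows are indels
    longer than 4 bp (undetectable upstream, dropped with a count).  A BPS
    whose ref base disagrees with the genome raises
    :class:`CatalogValidationError` naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"experiment_id", "line_id", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogValidationError(f"catalog missing columns: {sorted(missing)}")
    muts: list[Mutation] = []
    rejected = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        ref = row.ref.strip().upper()
        alt = row.alt.strip().upper()
        pos = int(row.pos)
        kind = _infer_kind(ref, alt)
        if kind == "BPS":
            if not (1 <= pos <= genome.length):
                raise CatalogValidationError(f"line {i}: position {pos} outside genome")
            if genome.base_at(pos) != ref:
                raise CatalogValidationError(
                    f"line {i}: ref {ref} at pos {pos} does not match genome base "
                    f"{genome.base_at(pos)}"
                )
            classify_bps(ref, alt)  # raises on non-ACGT
            indel_len = 0
        else:
            unit = alt if kind == "insertion" else ref
            if len(unit) > MAX_INDEL_LEN:
                rejected += 1
                continue
            if kind == "deletion":
                seg = genome.sequence[pos - 1 : pos - 1 + len(unit)]
                if strict and seg != unit:
                    raise CatalogValidationError(
                        f"line {i}: deleted bases {unit} do not match genome {seg} at {pos}"
                    )
            pos, unit = left_normalize(pos, unit, genome.sequence)
            ref = unit if kind == "deletion" else ""
            alt = unit if kind == "insertion" else ""
            indel_len = len(unit)
        mut_id = getattr(row, "mutation_id", "") or f"m{i - 1:06d}"
        muts.append(
            Mutation(
                mutation_id=mut_id,
                experiment_id=row.experiment_id,
                line_id=row.line_id,
                pos=pos,
                kind=kind,
                ref=ref,
                alt=alt,
                indel_len=indel_len,
            )
        )
    muts.sort(key=lambda m: (m.pos, m.line_id, m.mutation_id))
    return muts, rejected


def write_catalog(mutations: Iterable[Mutation], path: str | Path) -> None:
    rows = [
        {
            "mutation_id": m.mutation_id,
            "experiment_id": m.experiment_id,
            "line_id": m.line_id,
            "pos": m.pos,
            "kind": m.kind,
            "ref": m.ref,
            "alt": m.alt,
            "indel_len": m.indel_len,
        }
        for m in mutations
    ]
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def write_vcf(mutations: Iterable[Mutation], genome: GenomeAnnotation, path: str | Path) -> None:
    """Minimal VCF 4.2 export (indels anchored on the preceding base)."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={genome.genome_id},length={genome.length}>",
        '##INFO=<ID=LINE,Number=1,Type=String,Description="MA line id">',
        '##INFO=<ID=EXP,Number=1,Type=String,Description="Experiment id">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for m in sorted(mutations, key=lambda m: (m.pos, m.line_id, m.mutation_id)):
        if m.kind == "BPS":
            pos, ref, alt = m.pos, m.ref, m.alt
        else:
            anchor_pos = max(m.pos - 1, 1)
            anchor = genome.base_at(anchor_pos)
            if m.kind == "insertion":
                pos, ref, alt = anchor_pos, anchor, anchor + m.alt
            else:
                pos, ref, alt = anchor_pos, anchor + m.ref, anchor
        lines.append(
            f"{genome.genome_id}\t{pos}\t{m.mutation_id}\t{ref}\t{alt}\t.\t.\t"
            f"LINE={m.line_id};EXP={m.experiment_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_experiments(path: str | Path) -> list[ExperimentMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    metas = []
    for row in df.itertuples(index=False):
        tags = frozenset(
            t for t in getattr(row, "genotype_tags", "").split(";") if t
        )
        metas.append(
            ExperimentMeta(
                experiment_id=row.experiment_id,
                line_id=row.line_id,
                generations=float(row.generations),
                genotype_tags=tags,
            )
        )
    return metas


def write_experiments(metas: Iterable[ExperimentMeta], path: str | Path) -> None:
    rows = [
        {
            "experiment_id": m.experiment_id,
            "line_id": m.line_id,
            "generations": m.generations,
            "genotype_tags": ";".join(sorted(m.genotype_tags)),
        }
        for m in metas
    ]
    pd.DataFrame(rows, columns=["experiment_id", "line_id", "generations", "genotype_tags"]).to_csv(
        path, sep="\t", index=False
    )
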