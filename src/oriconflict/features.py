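"""Mapping mutations onto genomic features.

Covers four feature classes: gene coding sequences (CDSs), promoter windows
(60 bp upstream of a TSS through the TSS itself), maximal mononucleotide
runs (homopolymer tracts, the dominant indel hotspots), and candidate -10
promoter elements.  Also labels every transition by which parental strand
carried the mutated A (for A:T transitions) or C (for G:C transitions) —
the leading-strand template (LDST) or the lagging-strand template (LGST) —
which is the quantity that separates a replication strand bias from a
transcription orientation bias.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .catalog import Mutation, classify_bps
from .genome import (
    GenomeAnnotation,
    Promoter,
    Strand,
    classify_promoter_orientation,
    strand_template,
)

PlacementClass = Literal["A_on_LGST", "A_on_LDST", "C_on_LGST", "C_on_LDST"]

PLACEMENT_CLASSES: tuple[str, ...] = ("A_on_LGST", "A_on_LDST", "C_on_LGST", "C_on_LDST")

MINUS10_CONSENSUS = "TATAAT"


@dataclass(frozen=True)
class MononucleotideRun:
    """A maximal homopolymer tract on the forward strand."""

    start: int  # 1-based inclusive
    end: int
    base: str
    wraps_origin: bool = False

    @property
    def pair_class(self) -> str:
        return "AT" if self.base in "AT" else "GC"

    def run_len(self, genome_length: int | None = None) -> int:
        if not self.wraps_origin:
            return self.end - self.start + 1
        return (genome_length - self.start + 1) + self.end


@dataclass
class CdsAssignment:
    """Per-gene mutation counts plus assignment bookkeeping.

    ``gene_counts`` is indexed by gene_id with columns n_bps, n_indel and
    the per-pair-class BPS breakdowns.  Multi-assigned mutations increment
    every containing gene; ``n_multi`` counts them once each so that
    unique + multi + intergenic equals the catalog size.
    """

    gene_counts: pd.DataFrame
    mutation_genes: dict[str, list[str]]
    n_multi: int
    n_intergenic: int


_COUNT_COLUMNS = [
    "n_bps",
    "n_indel",
    "n_at_transition",
    "n_gc_transition",
    "n_at_transversion",
    "n_gc_transversion",
]


def _gene_segments(start: int, end: int, length: int, wraps: bool) -> list[tuple[int, int]]:
    if not wraps:
        return [(start, end)]
    return [(start, length), (1, end)]


def assign_to_cds(mutations: Sequence[Mutation], genome: GenomeAnnotation) -> CdsAssignment:
    """Assign every mutation to each CDS containing its position.

    Indels are located by the position of the first affected base (the
    left-normalized position).  A mutation inside several overlapping CDSs
    increments each of them and is counted once in ``n_multi``.
    """
    tree = IntervalTree()
    for g in genome.genes:
        for s, e in _gene_segments(g.start, g.end, genome.length, g.wraps_origin):
            tree.addi(s, e + 1, g.gene_id)  # half-open

    counts = pd.DataFrame(
        0, index=[g.gene_id for g in genome.genes], columns=_COUNT_COLUMNS, dtype=int
    )
    counts.index.name = "gene_id"
    mutation_genes: dict[str, list[str]] = {}
    n_multi = 0
    n_intergenic = 0
    for m in mutations:
        hits = sorted({iv.data for iv in tree.at(m.pos)})
        mutation_genes[m.mutation_id] = hits
        if not hits:
            n_intergenic += 1
        elif len(hits) > 1:
            n_multi += 1
        for gid in hits:
            if m.is_bps:
                counts.at[gid, "n_bps"] += 1
                c = m.bps_class()
                col = f"n_{c.pair_class.lower()}_{c.change_class}"
                counts.at[gid, col] += 1
            else:
                counts.at[gid, "n_indel"] += 1
    return CdsAssignment(
        gene_counts=counts,
        mutation_genes=mutation_genes,
        n_multi=n_multi,
        n_intergenic=n_intergenic,
    )


def promoter_window(
    promoter: Promoter, genome: GenomeAnnotation, width: int = 60
) -> list[tuple[int, int]]:
    """The upstream window of a promoter, TSS included (61 nt for width 60).

    Forward strand: [tss - width, tss]; reverse strand: [tss, tss + width].
    Returned as one or two 1-based inclusive segments (two when the window
    wraps around the circular coordinate origin).
    """
    L = genome.length
    if promoter.strand == "forward":
        lo, hi = promoter.tss_pos - width, promoter.tss_pos
    else:
        lo, hi = promoter.tss_pos, promoter.tss_pos + width
    if lo >= 1 and hi <= L:
        return [(lo, hi)]
    if lo < 1:
        return [(lo + L, L), (1, hi)]
    return [(lo, L), (1, hi - L)]


def assign_to_promoters(
    mutations: Sequence[Mutation],
    genome: GenomeAnnotation,
    width: int = 60,
) -> pd.DataFrame:
    """Per-promoter BPS/indel counts over the upstream windows."""
    tree = IntervalTree()
    for p in genome.promoters:
        for s, e in promoter_window(p, genome, width):
            tree.addi(s, e + 1, p.promoter_id)
    counts = pd.DataFrame(
        0, index=[p.promoter_id for p in genome.promoters], columns=["n_bps", "n_indel"], dtype=int
    )
    counts.index.name = "promoter_id"
    for m in mutations:
        for iv in tree.at(m.pos):
            counts.at[iv.data, "n_bps" if m.is_bps else "n_indel"] += 1
    return counts


def find_runs(
    sequence: str, min_len: int = 5, circular: bool = False
) -> list[MononucleotideRun]:
    """Maximal mononucleotide runs of at least ``min_len`` nt.

    With ``circular=True`` a run spanning the coordinate origin is merged
    into a single wrapping run (unless the whole sequence is one base).
    """
    runs: list[MononucleotideRun] = []
    pos = 1
    for base, group in itertools.groupby(sequence):
        n = sum(1 for _ in group)
        runs.append(MononucleotideRun(start=pos, end=pos + n - 1, base=base))
        pos += n
    if circular and len(runs) > 1 and runs[0].base == runs[-1].base:
        first, last = runs[0], runs[-1]
        merged = MononucleotideRun(
            start=last.start, end=first.end, base=first.base, wraps_origin=True
        )
        runs = [merged] + runs[1:-1]
    L = len(sequence)
    return [r for r in runs if r.run_len(L) >= min_len]


def run_census(sequence: str) -> dict[int, float]:
    """Fraction of nucleotides sitting in maximal runs of each length.

    Computed over all run lengths >= 1; the length-weighted fractions sum
    to 1 over the whole sequence.
    """
    total = len(sequence)
    census: dict[int, float] = {}
    for _, group in itertools.groupby(sequence):
        n = sum(1 for _ in group)
        census[n] = census.get(n, 0.0) + n
    return {k: v / total for k, v in sorted(census.items())}


def assign_indels_to_runs(
    mutations: Sequence[Mutation],
    runs: Sequence[MononucleotideRun],
    genome_length: int | None = None,
) -> tuple[dict[str, int | None], pd.Series]:
    """Attribute left-normalized indels to mononucleotide runs.

    A single-base indel belongs to a run when its position lies within the
    run or immediately 5'-adjacent (one base left of the run start, where a
    left-normalized insertion extending the run lands) and its base equals
    the run base.  Multi-base indels must be homopolymers of the run base
    with every affected position inside the run.  Returns a mapping
    mutation_id -> run index (None = non-run) and per-run indel counts.
    """
    per_run = pd.Series(0, index=range(len(runs)), dtype=int)
    mapping: dict[str, int | None] = {}
    for m in mutations:
        if not m.is_indel:
            continue
        unit = m.indel_unit
        assigned: int | None = None
        for i, r in enumerate(runs):
            if set(unit) != {r.base}:
                continue
            if r.wraps_origin and genome_length is not None:
                in_run = m.pos >= r.start or m.pos <= r.end
                adjacent = m.pos == r.start - 1
            else:
                in_run = r.start <= m.pos <= r.end
                adjacent = m.pos == r.start - 1
            if len(unit) == 1:
                ok = in_run or adjacent
            else:
                ok = in_run and (m.pos + len(unit) - 1 <= r.end or r.wraps_origin)
            if ok:
                assigned = i
                break
        mapping[m.mutation_id] = assigned
        if assigned is not None:
            per_run[assigned] += 1
    return mapping, per_run


def classify_transition_placement(mutation: Mutation, genome: GenomeAnnotation) -> PlacementClass:
    """Which parental strand holds the A (A:T transitions) or C (G:C
    transitions) of the mutated pair: LDST or LGST.

    The forward-strand ref base determines which strand carries the
    diagnostic base: ref A/C -> it is on the forward strand; ref T/G -> the
    A/C sits on the reverse strand.  The strand's replication role at that
    position completes the label.
    """
    if not mutation.is_bps:
        raise ValueError("placement is defined for transitions only")
    c = mutation.bps_class()
    if c.change_class != "transition":
        raise ValueError("placement is defined for transitions only")
    ref = mutation.ref
    if c.pair_class == "AT":
        base = "A"
        strand: Strand = "forward" if ref == "A" else "reverse"
    else:
        base = "C"
        strand = "forward" if ref == "C" else "reverse"
    tmpl = strand_template(mutation.pos, strand, genome)
    return f"{base}_on_{tmpl}"  # type: ignore[return-value]


def placement_counts(mutations: Sequence[Mutation], genome: GenomeAnnotation) -> pd.Series:
    """Counts of transitions per placement class (partition of transitions)."""
    counts = pd.Series(0, index=list(PLACEMENT_CLASSES), dtype=int)
    for m in mutations:
        if m.is_bps and m.bps_class().change_class == "transition":
            counts[classify_transition_placement(m, genome)] += 1
    return counts


# ---------------------------------------------------------------------------
# -10 element scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Minus10Hit:
    promoter_id: str
    mutation_id: str
    distance_to_tss: int  # of the mutated T, in nt upstream of the TSS
    hexamer: str
    matches: int
    orientation: str  # CD / HO of the promoter
    is_t_minus7: bool  # mutated T is the 3' T of a hexamer ending 7 nt upstream


def _sense_upstream(promoter: Promoter, genome: GenomeAnnotation, n: int) -> str:
    """Sense-strand sequence of the n bases upstream of the TSS, ordered
    from farthest (index 0) to the base just before the TSS (index n-1)."""
    L = genome.length
    out = []
    if promoter.strand == "forward":
        for d in range(n, 0, -1):
            out.append(genome.base_at((promoter.tss_pos - 1 - d) % L + 1))
    else:
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for d in range(n, 0, -1):
            out.append(comp[genome.base_at((promoter.tss_pos - 1 + d) % L + 1)])
    return "".join(out)


def scan_minus10(
    promoters: Sequence[Promoter],
    mutations: Sequence[Mutation],
    genome: GenomeAnnotation,
    window: int = 20,
    min_matches: int = 4,
    end_offsets: tuple[int, int] = (5, 9),
) -> list[Minus10Hit]:
    """Search for transitions at the 3' T of candidate -10 elements.

    For every A:T transition within ``window`` nt upstream of a TSS, scan
    the promoter's sense strand for a hexamer whose 3' base is the mutated
    T, whose 3' end lies ``end_offsets`` nt upstream of the TSS, and which
    matches the TATAAT consensus at >= ``min_matches`` of 6 positions.
    A hexamer ending exactly 7 nt upstream marks the classic T-7 position.
    """
    L = genome.length
    transitions = [
        m
        for m in mutations
        if m.is_bps
        and m.bps_class().change_class == "transition"
        and m.bps_class().pair_class == "AT"
    ]
    hits: list[Minus10Hit] = []
    depth = max(window, end_offsets[1] + 5)
    for p in promoters:
        sense = _sense_upstream(p, genome, depth)
        for m in transitions:
            if p.strand == "forward":
                d = (p.tss_pos - m.pos) % L  # distance upstream
                mut_sense_is_t = m.ref == "T"
            else:
                d = (m.pos - p.tss_pos) % L
                mut_sense_is_t = m.ref == "A"  # sense strand is the reverse complement
            if not (1 <= d <= window) or not mut_sense_is_t:
                continue
            # sense string index of the mutated base (distance d upstream)
            mut_idx = depth - d
            for end_d in range(end_offsets[0], end_offsets[1] + 1):
                end_idx = depth - end_d  # index of the hexamer's 3' base
                if end_idx != mut_idx or end_idx - 5 < 0:
                    continue
                hexamer = sense[end_idx - 5 : end_idx + 1]
                if hexamer[-1] != "T":
                    continue
                matches = sum(a == b for a, b in zip(hexamer, MINUS10_CONSENSUS))
                if matches >= min_matches:
                    hits.append(
                        Minus10Hit(
                            promoter_id=p.promoter_id,
                            mutation_id=m.mutation_id,
                            distance_to_tss=d,
                            hexamer=hexamer,
                            matches=matches,
                            orientation=classify_promoter_orientation(p, genome),
                            is_t_minus7=(end_d == 7),
                        )
                    )
    return hits
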