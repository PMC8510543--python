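"""Synthetic mutation-accumulation (MA) experiment generator.

Generates a circular genome with bidirectional replication, a dense gene
complement with a configurable codirectional (CD) fraction, per-phase
expression values, and a mutation catalog with the statistical structure an
MA experiment on a mismatch-repair-deficient strain produces:

* transitions dominate, with a strand-placement bias — the rate at an A:T
  pair is higher when its A templates the lagging strand (LGST) than when
  it templates the leading strand, by the factor ``strand_bias_rho``
  (G:C pairs analogous, with C as the diagnostic base);
* indel rates grow exponentially with mononucleotide-run length
  (rate per run = mu0 * growth^(len - ref_len), saturating at
  ``run_saturation_len``), so long homopolymers are hotspots;
* mutation counts per line are Poisson with exposure equal to the line's
  generations — no within-line lineage structure and no selection, the
  regime MA designs approximate.

Named scenarios: ``null`` (no strand bias, no engineered hotspots),
``strand_bias`` (rho = 2), ``trna_artifact`` (a tRNA-like gene family in
which four identical members carry an 8 bp G:C run and a 5 bp G:C run,
three placed head-on and one codirectional — the configuration that makes
a naive orientation comparison overstate head-on mutability), and
``expression_coupled`` (per-gene substitution rate scales with expression,
to exercise the correlation machinery).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd

from .catalog import ExperimentMeta, Mutation, left_normalize, write_catalog, write_experiments
from .features import find_runs
from .genome import Gene, GenomeAnnotation, Promoter, revcomp, write_fasta, write_gene_meta, write_gff3

# tRNA-like cassette: the hotspot variant carries an 8 bp C run and a 5 bp
# G run on its sense strand (the two runs that base-pair in the TPsiC stem
# of a tRNA); the plain variant has no run longer than 3 nt.
HOTSPOT_TRNA_SEQ = (
    "GCGAAGGTGGCGGAATTGGTAGACGCGCTAGCCCCCCCCTAGTAGGGGGTTCGAGTCCCTCTCCTTCCGCCA"
)
PLAIN_TRNA_SEQ = (
    "GCGGATGTAGCCAAGTGGATCAAGGCAGTGGATTGTGAATCCACCATGCGCGGGTTCAATTCCCGTCATCCGCC"
)


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic MA generator.

    Rates are per base pair (or per run) per generation.  Defaults give a
    desk-scale genome whose catalog has the gross composition of a
    mismatch-repair-deficient accumulation experiment: transitions at A:T
    pairs about 3x those at G:C pairs per site, sparse transversions, and
    run-length-driven indels.
    """

    seed: int = 0
    genome_length: int = 500_000
    gc_content: float = 0.5
    n_genes: int = 500
    cd_fraction: float = 0.55
    gene_length_mean: float = 900.0
    gene_length_sd: float = 300.0
    gene_length_min: int = 120
    n_lines: int = 200
    generations_per_line: float = 1000.0
    mu_ts_AT: float = 2.0e-8
    mu_ts_GC: float = 1.2e-8
    strand_bias_rho: float = 1.0
    mu_tv: float = 1.0e-9
    indel_mu0: float = 1.0e-7  # per run per generation at the reference length
    indel_growth: float = 10.0
    run_ref_len: int = 5
    run_saturation_len: int = 8
    indel_background: float = 2.0e-10
    expression_log10_mean: float = 1.0
    expression_between_sd: float = 0.5
    expression_within_sd: float = 0.15
    expression_coupling: float = 0.0
    scenario: str = "null"
    n_trna: int = 40  # trna_artifact only: total tRNA-like genes (4 hotspots)
    origin_pos: int = 1

    def __post_init__(self) -> None:
        for name in ("mu_ts_AT", "mu_ts_GC", "mu_tv", "indel_mu0", "indel_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.cd_fraction <= 1):
            raise ValueError("cd_fraction must be in [0, 1]")
        if self.strand_bias_rho <= 0:
            raise ValueError("strand_bias_rho must be > 0")


def preset(scenario: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Named scenario presets."""
    base = {"seed": seed, "scenario": scenario}
    if scenario == "null":
        base["strand_bias_rho"] = 1.0
    elif scenario == "strand_bias":
        base["strand_bias_rho"] = 2.0
    elif scenario == "trna_artifact":
        base["strand_bias_rho"] = 1.0
    elif scenario == "expression_coupled":
        base["expression_coupling"] = 0.5
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: GenomeAnnotation
    tpm: pd.DataFrame
    mutations: list[Mutation]
    experiments: list[ExperimentMeta]
    hotspot_gene_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def _replichore_is_right(pos: np.ndarray, ori: int, ter: int) -> np.ndarray:
    if ori < ter:
        return (pos >= ori) & (pos < ter)
    return (pos >= ori) | (pos < ter)


def generate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeAnnotation, list[str]]:
    """Random circular genome with non-overlapping genes laid around the
    circle, strands chosen to hit the target CD fraction in expectation.

    Returns (genome, hotspot_gene_ids); the hotspot list is non-empty only
    for the ``trna_artifact`` scenario, where four identical tRNA-like
    genes carrying the run cassette are placed 3 head-on / 1 codirectional
    among a family of plain tRNA-like genes split evenly CD/HO.
    """
    rng = rng or np.random.default_rng(config.seed)
    L = config.genome_length
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(np.array(list("ACGT")), size=L, p=probs)

    trna_mode = config.scenario == "trna_artifact"
    n_hot = 4 if trna_mode else 0
    n_trna = config.n_trna if trna_mode else 0
    if trna_mode and n_trna < n_hot:
        raise ValueError("n_trna must be at least 4 in the trna_artifact scenario")
    n_regular = config.n_genes - n_trna
    if n_regular < 0:
        raise ValueError("n_genes smaller than the tRNA family")

    lengths = rng.normal(config.gene_length_mean, config.gene_length_sd, size=n_regular)
    lengths = np.maximum(lengths, config.gene_length_min).round().astype(int)
    trna_lengths = [len(HOTSPOT_TRNA_SEQ)] * n_hot + [len(PLAIN_TRNA_SEQ)] * (n_trna - n_hot)
    all_lengths = np.concatenate([lengths, np.array(trna_lengths, dtype=int)])
    n = len(all_lengths)
    total = int(all_lengths.sum())
    slack = L - total
    if slack < n + 1:
        raise ValueError(
            f"infeasible packing: {total} nt of genes + {n} gaps exceed genome length {L}"
        )
    # interleave tRNA genes among the others so both replichores get some
    order = rng.permutation(n)
    gaps = rng.multinomial(slack - n - 1, np.full(n, 1.0 / n)) + 1

    genome_stub = GenomeAnnotation(
        genome_id="synthetic_genome",
        length=L,
        origin_pos=config.origin_pos,
        sequence="A" * L,  # geometry only; replaced below
    )
    ori, ter = genome_stub.origin_pos, genome_stub.terminus_pos

    # tRNA orientations: hotspots 1 CD + 3 HO; plain split to 20/20 overall
    trna_orients = ["CD"] + ["HO"] * 3
    n_plain = n_trna - n_hot
    n_plain_cd = max(n_trna // 2 - 1, 0)
    trna_orients += ["CD"] * n_plain_cd + ["HO"] * (n_plain - n_plain_cd)

    genes: list[Gene] = []
    hotspot_ids: list[str] = []
    pos = 1
    trna_seen = 0
    for k, gi in enumerate(order):
        pos += int(gaps[k])
        glen = int(all_lengths[gi])
        start, end = pos, pos + glen - 1
        mid = (start + end) // 2
        on_right = bool(_replichore_is_right(np.array([mid]), ori, ter)[0])
        is_trna = gi >= n_regular
        if is_trna:
            idx = gi - n_regular
            want_cd = trna_orients[idx] == "CD"
            is_hot = idx < n_hot
            cassette = HOTSPOT_TRNA_SEQ if is_hot else PLAIN_TRNA_SEQ
            strand = "forward" if (on_right == want_cd) else "reverse"
            gene_id = f"trna{idx + 1:03d}"
            cats = frozenset({"tRNA", "highly_expressed"})
            written = cassette if strand == "forward" else revcomp(cassette)
            seq[start - 1 : end] = list(written)
            if is_hot:
                hotspot_ids.append(gene_id)
            trna_seen += 1
        else:
            is_cd = rng.random() < config.cd_fraction
            strand = "forward" if (on_right == is_cd) else "reverse"
            gene_id = f"g{gi + 1:04d}"
            cats = frozenset()
        genes.append(
            Gene(gene_id=gene_id, start=start, end=end, strand=strand, categories=cats)
        )
        pos = end + 1

    promoters = []
    for g in genes:
        if g.strand == "forward":
            tss = (g.start - 1 - 25) % L + 1
        else:
            tss = (g.end - 1 + 25) % L + 1
        promoters.append(
            Promoter(promoter_id=f"p_{g.gene_id}", tss_pos=tss, strand=g.strand, gene_id=g.gene_id)
        )

    genome = GenomeAnnotation(
        genome_id="synthetic_genome",
        length=L,
        origin_pos=config.origin_pos,
        sequence="".join(seq),
        genes=sorted(genes, key=lambda g: g.start),
        promoters=promoters,
    )
    return genome, hotspot_ids


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def generate_expression(
    genome: GenomeAnnotation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    hotspot_gene_ids: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-gene TPM for three growth phases (lag, log, stationary).

    log10(TPM) = per-gene effect (between-gene SD) + per-phase noise
    (within-gene SD) around a common mean.  Genes flagged tRNA (including
    the hotspot cassette genes) are forced into the top expression stratum
    in every phase, mirroring constitutively high structural-RNA output.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    ids = [g.gene_id for g in genome.genes]
    n = len(ids)
    gene_effect = rng.normal(0.0, config.expression_between_sd, size=n)
    total_sd = float(np.hypot(config.expression_between_sd, config.expression_within_sd))
    data = {}
    for phase in ("tpm_lag", "tpm_log", "tpm_stat"):
        log10 = config.expression_log10_mean + gene_effect + rng.normal(
            0.0, config.expression_within_sd, size=n
        )
        data[phase] = log10
    df = pd.DataFrame(data, index=pd.Index(ids, name="gene_id"))
    forced = {g.gene_id for g in genome.genes if "tRNA" in g.categories} | set(hotspot_gene_ids)
    if forced:
        top = config.expression_log10_mean + 2.5 * total_sd
        df.loc[df.index.isin(forced)] = top
    return 10.0**df


def attach_expression(genome: GenomeAnnotation, tpm: pd.DataFrame) -> GenomeAnnotation:
    """Return a genome whose genes carry the TPM values."""
    genes = []
    for g in genome.genes:
        if g.gene_id in tpm.index:
            row = tpm.loc[g.gene_id]
            g = dc_replace(
                g,
                tpm_lag=float(row["tpm_lag"]),
                tpm_log=float(row["tpm_log"]),
                tpm_stat=float(row["tpm_stat"]),
            )
        genes.append(g)
    return GenomeAnnotation(
        genome_id=genome.genome_id,
        length=genome.length,
        origin_pos=genome.origin_pos,
        terminus_pos=genome.terminus_pos,
        sequence=genome.sequence,
        genes=genes,
        promoters=genome.promoters,
    )


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _tv_partners(base: str) -> str:
    # the two bases that are neither the original nor its transition partner
    return "".join(b for b in "ACGT" if b not in (base, _TS_PARTNER[base]))


def simulate_mutations(
    genome: GenomeAnnotation,
    tpm: pd.DataFrame | None,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[Mutation], list[ExperimentMeta]]:
    """Draw a full mutation catalog for ``n_lines`` independent MA lines.

    Per-class counts are Poisson with exposure = line generations; events
    are placed by the per-site rate fields described in the module
    docstring.  Repeat hits at one site are recorded as separate rows.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    L = genome.length
    seq = np.frombuffer(genome.sequence.encode(), dtype="S1")
    pos_arr = np.arange(1, L + 1)
    on_right = _replichore_is_right(pos_arr, genome.origin_pos, genome.terminus_pos)

    rho = config.strand_bias_rho
    # per-site transition rate; the diagnostic base (A of A:T, C of G:C)
    # is on the LGST when: base A or C and right replichore (forward
    # strand = LGST there), or base T or G and left replichore.
    r_ts = np.zeros(L)
    diag_on_lgst = np.zeros(L, dtype=bool)
    for base, mu in (("A", config.mu_ts_AT), ("T", config.mu_ts_AT),
                     ("C", config.mu_ts_GC), ("G", config.mu_ts_GC)):
        mask = seq == base.encode()
        lgst = on_right if base in "AC" else ~on_right
        r_ts[mask] = mu
        diag_on_lgst[mask] = lgst[mask]
    r_ts = np.where(diag_on_lgst, r_ts * rho, r_ts)

    mult = np.ones(L)
    if config.expression_coupling != 0 and tpm is not None:
        log10 = np.log10(tpm["tpm_log"].astype(float).clip(lower=1e-3))
        center = float(log10.mean())
        for g in genome.genes:
            if g.gene_id in log10.index:
                m = 10.0 ** (config.expression_coupling * (log10[g.gene_id] - center))
                if g.wraps_origin:
                    mult[g.start - 1 :] = m
                    mult[: g.end] = m
                else:
                    mult[g.start - 1 : g.end] = m
    r_ts = r_ts * mult
    r_tv = config.mu_tv * mult

    if float(max(r_ts.max(), r_tv.max())) > 1.0:
        raise ValueError("per-site per-generation rate exceeds 1; lower the rates")

    exposure_total = config.n_lines * config.generations_per_line
    muts: list[tuple[int, int, str, str, str]] = []  # (pos, line, kind, ref, alt)

    # transitions
    lam_ts = r_ts.sum() * exposure_total
    n_ts = int(rng.poisson(lam_ts))
    if n_ts:
        p = r_ts / r_ts.sum()
        sites = rng.choice(L, size=n_ts, p=p)
        lines = rng.integers(0, config.n_lines, size=n_ts)
        for s, ln in zip(sites, lines):
            ref = seq[s].decode()
            muts.append((int(s) + 1, int(ln), "BPS", ref, _TS_PARTNER[ref]))

    # transversions
    lam_tv = r_tv.sum() * exposure_total
    n_tv = int(rng.poisson(lam_tv))
    if n_tv:
        if config.expression_coupling != 0:
            sites = rng.choice(L, size=n_tv, p=r_tv / r_tv.sum())
        else:
            sites = rng.integers(0, L, size=n_tv)
        lines = rng.integers(0, config.n_lines, size=n_tv)
        picks = rng.integers(0, 2, size=n_tv)
        for s, ln, k in zip(sites, lines, picks):
            ref = seq[s].decode()
            muts.append((int(s) + 1, int(ln), "BPS", ref, _tv_partners(ref)[k]))

    # run-length-dependent indels
    runs = find_runs(genome.sequence, min_len=2, circular=genome.is_circular)
    if runs:
        run_lens = np.array([r.run_len(L) for r in runs])
        capped = np.minimum(run_lens, config.run_saturation_len)
        run_rates = config.indel_mu0 * config.indel_growth ** (
            capped.astype(float) - config.run_ref_len
        )
        counts = rng.poisson(run_rates * exposure_total)
        for r, c in zip(runs, counts):
            if c == 0:
                continue
            lines = rng.integers(0, config.n_lines, size=c)
            is_ins = rng.integers(0, 2, size=c)
            for ln, ins in zip(lines, is_ins):
                if ins:
                    muts.append((r.start, int(ln), "insertion", "", r.base))
                else:
                    muts.append((r.start, int(ln), "deletion", r.base, ""))

    # background indels at isolated (run-length-1) sites
    left = np.roll(seq, 1)
    right = np.roll(seq, -1)
    iso = (seq != left) & (seq != right)
    iso_pos = pos_arr[iso]
    if len(iso_pos) and config.indel_background > 0:
        n_bg = int(rng.poisson(len(iso_pos) * config.indel_background * exposure_total))
        if n_bg:
            sites = rng.choice(iso_pos, size=n_bg)
            lines = rng.integers(0, config.n_lines, size=n_bg)
            is_ins = rng.integers(0, 2, size=n_bg)
            for s, ln, ins in zip(sites, lines, is_ins):
                base = genome.sequence[s - 1]
                p_norm, unit = left_normalize(int(s), base, genome.sequence)
                if ins:
                    muts.append((p_norm, int(ln), "insertion", "", unit))
                else:
                    muts.append((p_norm, int(ln), "deletion", unit, ""))

    muts.sort(key=lambda t: (t[0], t[1], t[2], t[3], t[4]))
    line_ids = [f"L{i + 1:03d}" for i in range(config.n_lines)]
    catalog = [
        Mutation(
            mutation_id=f"m{i + 1:06d}",
            experiment_id="simexp",
            line_id=line_ids[ln],
            pos=pos,
            kind=kind,  # type: ignore[arg-type]
            ref=ref,
            alt=alt,
            indel_len=0 if kind == "BPS" else len(ref or alt),
        )
        for i, (pos, ln, kind, ref, alt) in enumerate(muts)
    ]
    tags = frozenset({"MMR_minus"})
    experiments = [
        ExperimentMeta(
            experiment_id="simexp",
            line_id=lid,
            generations=config.generations_per_line,
            genotype_tags=tags,
        )
        for lid in line_ids
    ]
    return catalog, experiments


def simulate(config: SimulationConfig) -> SimulationResult:
    """End-to-end draw: genome, expression, catalog — fully reproducible
    from (config, seed)."""
    rng = np.random.default_rng(config.seed)
    genome, hotspot_ids = generate_genome(config, rng)
    tpm = generate_expression(genome, config, rng, hotspot_ids)
    genome = attach_expression(genome, tpm)
    mutations, experiments = simulate_mutations(genome, tpm, config, rng)
    return SimulationResult(
        config=config,
        genome=genome,
        tpm=tpm,
        mutations=mutations,
        experiments=experiments,
        hotspot_gene_ids=hotspot_ids,
    )


def write_simulation(result: SimulationResult, outdir: str | Path) -> None:
    """Write FASTA, GFF3, gene_meta.tsv, tpm.tsv, mutations.tsv,
    experiments.tsv and a manifest.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.genome, outdir / "genome.fa")
    write_gff3(result.genome, outdir / "genes.gff3")
    write_gene_meta(result.genome, outdir / "gene_meta.tsv")
    result.tpm.to_csv(outdir / "tpm.tsv", sep="\t")
    write_catalog(result.mutations, outdir / "mutations.tsv")
    write_experiments(result.experiments, outdir / "experiments.tsv")
    manifest = {
        "scenario": result.config.scenario,
        "seed": result.config.seed,
        "genome_length": result.config.genome_length,
        "n_genes": len(result.genome.genes),
        "n_lines": result.config.n_lines,
        "generations_per_line": result.config.generations_per_line,
        "n_mutations": len(result.mutations),
        "hotspot_gene_ids": result.hotspot_gene_ids,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
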