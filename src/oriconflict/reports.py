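"""Analysis tables: CD-vs-HO comparisons, correlation tables, tRNA hotspot
decomposition, and strand-placement summaries.

The central comparison is between genes transcribed codirectionally (CD)
with the replication fork and genes transcribed head-on (HO).  For each
mutation metric (BPSs/CDS, BPSs/CDS/nt, indels/CDS, indels/CDS/nt) a
comparison row carries the group means and SDs, the percent excess of the
HO mean over the CD mean (dHO), and raw plus Benjamini-Hochberg-adjusted
p-values from the pooled t and Mann-Whitney tests.  The BH family is, by
default, every p-value emitted in one report run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import stats as st
from .catalog import Mutation, total_exposure
from .features import (
    CdsAssignment,
    PLACEMENT_CLASSES,
    assign_to_cds,
    assign_indels_to_runs,
    find_runs,
    placement_counts,
    run_census,
)
from .genome import GenomeAnnotation, classify_orientation, orientation_table
from .rates import frequency_per_cds, pair_class_targets, rates_table

DEFAULT_METRICS = (
    "bps_per_cds",
    "bps_per_cds_per_nt",
    "indel_per_cds",
    "indel_per_cds_per_nt",
)


@dataclass(frozen=True)
class GeneSubset:
    name: str
    gene_ids: frozenset[str]
    definition: str = ""

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class ComparisonRow:
    subset_name: str
    metric: str
    n_all: int
    n_cd: int
    n_ho: int
    mean_all: float
    sd_all: float
    mean_cd: float
    sd_cd: float
    mean_ho: float
    sd_ho: float
    delta_ho: float | None
    p_t: float
    p_mw: float
    p_t_adj: float | None = None
    p_mw_adj: float | None = None
    flag: str = ""


# ---------------------------------------------------------------------------
# Gene subsets
# ---------------------------------------------------------------------------


def subset_by_category(genome: GenomeAnnotation, category: str, name: str | None = None) -> GeneSubset:
    ids = frozenset(g.gene_id for g in genome.genes if category in g.categories)
    return GeneSubset(name or category, ids, definition=f"category == {category}")


def subset_all(genome: GenomeAnnotation) -> GeneSubset:
    return GeneSubset("all_genes", frozenset(g.gene_id for g in genome.genes), "all genes")


def subset_minus(base: GeneSubset, excluded: Iterable[str], name: str) -> GeneSubset:
    return GeneSubset(name, base.gene_ids - frozenset(excluded), f"{base.name} minus exclusions")


def select_highly_expressed(
    tpm: pd.DataFrame,
    mode: str = "any_phase",
    include_zero: bool = False,
) -> GeneSubset:
    """Genes whose log10(TPM) is >= mean + 1 SD in at least one growth
    phase (``mode='all_phases'``: in every phase).

    Phase means and SDs are computed over genes with TPM > 0 unless
    ``include_zero`` (zero-TPM genes then enter with log10 of a small
    floor).  Genes with zero TPM in a phase never satisfy that phase's
    criterion.
    """
    phases = [c for c in ("tpm_lag", "tpm_log", "tpm_stat") if c in tpm.columns]
    if not phases:
        raise ValueError("no TPM phase columns found")
    values = tpm[phases].astype(float)
    if (values.fillna(0) <= 0).all().all():
        raise ValueError("all-zero TPM table")
    hits = pd.DataFrame(False, index=tpm.index, columns=phases)
    for ph in phases:
        v = values[ph]
        if include_zero:
            logv = np.log10(v.clip(lower=1e-3))
            pool = logv[v.notna()]
        else:
            pool = np.log10(v[v > 0])
        if len(pool) < 2 or pool.std(ddof=1) == 0:
            continue
        thr = pool.mean() + pool.std(ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            logv = np.log10(v.where(v > 0))
        hits[ph] = logv >= thr
    sel = hits.all(axis=1) if mode == "all_phases" else hits.any(axis=1)
    return GeneSubset(
        f"highly_expressed_{mode}",
        frozenset(tpm.index[sel]),
        "log10(TPM) >= mean + 1 SD per phase, "
        + ("all phases" if mode == "all_phases" else "any phase"),
    )


def tpm_table(genome: GenomeAnnotation) -> pd.DataFrame:
    rows = {
        g.gene_id: {"tpm_lag": g.tpm_lag, "tpm_log": g.tpm_log, "tpm_stat": g.tpm_stat}
        for g in genome.genes
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    return df


# ---------------------------------------------------------------------------
# Comparison and correlation tables
# ---------------------------------------------------------------------------


def delta_ho_percent(mean_cd: float, mean_ho: float) -> float | None:
    """Percent excess of the HO mean over the CD mean (undefined at CD 0)."""
    if mean_cd <= 0:
        return None
    return 100.0 * (mean_ho / mean_cd - 1.0)


def delta_ho_ci(cd_values, ho_values, conf: float = 0.95) -> tuple[float, float, float]:
    """dHO with a delta-method normal CI on the ratio of means."""
    cd = np.asarray(cd_values, dtype=float)
    ho = np.asarray(ho_values, dtype=float)
    mcd, mho = cd.mean(), ho.mean()
    if mcd <= 0:
        raise ValueError("CD mean must be positive for dHO")
    ratio = mho / mcd
    var_ratio = (cd.var(ddof=1) / len(cd)) * (mho**2 / mcd**4)
    var_ratio += (ho.var(ddof=1) / len(ho)) / mcd**2
    z = sp_stats.norm.ppf(0.5 + conf / 2)
    half = z * np.sqrt(var_ratio)
    return (100 * (ratio - 1), 100 * (ratio - half - 1), 100 * (ratio + half - 1))


def comparison_table(
    freq: pd.DataFrame,
    orientation: pd.DataFrame,
    subset: GeneSubset | None = None,
    metrics: Sequence[str] = DEFAULT_METRICS,
) -> pd.DataFrame:
    """One row per metric comparing CD vs HO genes of a subset.

    ``freq`` is the per-gene frequency table (see
    :func:`oriconflict.rates.frequency_per_cds`) and ``orientation`` the
    per-gene orientation table.  An empty orientation class yields a row
    flagged ``NA (no genes)`` with missing statistics rather than a crash.
    """
    ids = freq.index if subset is None else freq.index.intersection(list(subset.gene_ids))
    name = subset.name if subset is not None else "all_genes"
    ori = orientation.loc[ids, "orientation"]
    rows = []
    for metric in metrics:
        v_all = freq.loc[ids, metric].to_numpy(dtype=float)
        v_cd = freq.loc[ids[ori == "CD"], metric].to_numpy(dtype=float)
        v_ho = freq.loc[ids[ori == "HO"], metric].to_numpy(dtype=float)
        row = ComparisonRow(
            subset_name=name,
            metric=metric,
            n_all=len(v_all),
            n_cd=len(v_cd),
            n_ho=len(v_ho),
            mean_all=_mean(v_all),
            sd_all=_sd(v_all),
            mean_cd=_mean(v_cd),
            sd_cd=_sd(v_cd),
            mean_ho=_mean(v_ho),
            sd_ho=_sd(v_ho),
            delta_ho=None,
            p_t=float("nan"),
            p_mw=float("nan"),
        )
        if len(v_cd) >= 2 and len(v_ho) >= 2:
            row.delta_ho = delta_ho_percent(row.mean_cd, row.mean_ho)
            row.p_t = st.two_sample_t(v_cd, v_ho).p_raw
            row.p_mw = st.mann_whitney(v_cd, v_ho).p_raw
        else:
            row.flag = "NA (no genes)" if min(len(v_cd), len(v_ho)) == 0 else "NA (n < 2)"
        rows.append(row.__dict__)
    return pd.DataFrame(rows)


def _mean(v: np.ndarray) -> float:
    return float(v.mean()) if len(v) else float("nan")


def _sd(v: np.ndarray) -> float:
    return float(v.std(ddof=1)) if len(v) >= 2 else float("nan")


def correlation_table(
    freq: pd.DataFrame,
    orientation: pd.DataFrame,
    predictor: str,
    predictor_values: pd.Series,
    subset: GeneSubset | None = None,
    metrics: Sequence[str] = ("bps_per_cds", "indel_per_cds"),
    log_predictor: bool = False,
) -> pd.DataFrame:
    """Pearson and Spearman correlations of mutation metrics against a
    predictor (CDS length or per-phase TPM), per orientation class."""
    ids = freq.index if subset is None else freq.index.intersection(list(subset.gene_ids))
    name = subset.name if subset is not None else "all_genes"
    pred = predictor_values.reindex(ids).astype(float)
    if log_predictor:
        pred = np.log10(pred.where(pred > 0))
    valid = pred.notna()
    ids = ids[valid]
    pred = pred[valid]
    ori = orientation.loc[ids, "orientation"]
    rows = []
    for metric in metrics:
        for cls, mask in (("All", np.ones(len(ids), bool)), ("CD", (ori == "CD").to_numpy()), ("HO", (ori == "HO").to_numpy())):
            x = pred.to_numpy()[mask]
            y = freq.loc[ids[mask], metric].to_numpy(dtype=float)
            if len(x) < 3:
                rows.append(
                    {
                        "subset_name": name,
                        "metric": metric,
                        "predictor": predictor,
                        "class": cls,
                        "n": len(x),
                        "rho_pearson": float("nan"),
                        "p_pearson": float("nan"),
                        "rho_spearman": float("nan"),
                        "p_spearman": float("nan"),
                        "flag": "NA (n < 3)",
                    }
                )
                continue
            pe = st.pearson(x, y)
            spr = st.spearman(x, y)
            rows.append(
                {
                    "subset_name": name,
                    "metric": metric,
                    "predictor": predictor,
                    "class": cls,
                    "n": len(x),
                    "rho_pearson": pe.statistic,
                    "p_pearson": pe.p_raw,
                    "rho_spearman": spr.statistic,
                    "p_spearman": spr.p_raw,
                    "flag": pe.note,
                }
            )
    return pd.DataFrame(rows)


def apply_bh_family(tables: dict[str, pd.DataFrame]) -> int:
    """One BH pass over every raw p-value column of every table in a run.

    Mutates the tables in place, filling ``*_adj`` columns; returns the
    family size.  With a single comparison the adjusted value equals the
    raw one.
    """
    p_cols = {"p_t": "p_t_adj", "p_mw": "p_mw_adj", "p_pearson": "p_pearson_adj", "p_spearman": "p_spearman_adj"}
    slots: list[tuple[pd.DataFrame, str, int]] = []
    values: list[float] = []
    for df in tables.values():
        for raw_col in p_cols:
            if raw_col not in df.columns:
                continue
            for i in df.index:
                p = df.at[i, raw_col]
                if pd.notna(p):
                    slots.append((df, raw_col, i))
                    values.append(float(p))
    if not values:
        return 0
    adj = st.benjamini_hochberg(values)
    for (df, raw_col, i), a in zip(slots, adj):
        adj_col = p_cols[raw_col]
        if adj_col not in df.columns:
            df[adj_col] = np.nan
        df.at[i, adj_col] = a
    return len(values)


# ---------------------------------------------------------------------------
# tRNA hotspot decomposition
# ---------------------------------------------------------------------------


def trna_decomposition(
    freq: pd.DataFrame,
    orientation: pd.DataFrame,
    trna_subset: GeneSubset,
    hotspot_gene_ids: Sequence[str],
    indel_run_mapping: dict[str, int | None] | None = None,
    mutation_genes: dict[str, list[str]] | None = None,
) -> dict:
    """Per-tRNA mutation counts, with and without declared hotspot genes,
    a chi-square homogeneity test across the hotspot homologues, and the
    fraction of tRNA indels attributable to mononucleotide runs."""
    ids = freq.index.intersection(list(trna_subset.gene_ids))
    out: dict = {"n_trna": len(ids)}
    if len(ids) == 0:
        out.update(per_gene=pd.DataFrame(), hotspot_counts={}, chi2_p=float("nan"))
        return out
    per_gene = freq.loc[ids, ["n_bps", "n_indel"]].copy()
    per_gene["orientation"] = orientation.loc[ids, "orientation"]
    out["per_gene"] = per_gene
    out["total_indels"] = int(per_gene["n_indel"].sum())
    out["total_bps"] = int(per_gene["n_bps"].sum())

    hotspots = [g for g in hotspot_gene_ids if g in per_gene.index]
    hot_counts = {g: int(per_gene.at[g, "n_indel"]) for g in hotspots}
    out["hotspot_counts"] = hot_counts
    out["hotspot_indels"] = sum(hot_counts.values())
    if hotspots:
        chi = st.chi_square_homogeneity(list(hot_counts.values()))
        out["chi2_stat"], out["chi2_p"] = chi.statistic, chi.p_raw
    else:
        out["chi2_p"] = float("nan")

    def _ratio(frame: pd.DataFrame) -> float:
        cd = frame.loc[frame["orientation"] == "CD", "n_indel"]
        ho = frame.loc[frame["orientation"] == "HO", "n_indel"]
        if len(cd) == 0 or len(ho) == 0 or cd.mean() == 0:
            return float("nan")
        return float(ho.mean() / cd.mean())

    out["ho_cd_indel_ratio"] = _ratio(per_gene)
    out["ho_cd_indel_ratio_minus_hotspots"] = _ratio(per_gene.drop(index=hotspots))

    if indel_run_mapping is not None and mutation_genes is not None:
        trna_ids = set(ids)
        in_trna = [
            mid
            for mid, genes in mutation_genes.items()
            if mid in indel_run_mapping and any(g in trna_ids for g in genes)
        ]
        if in_trna:
            assigned = sum(1 for mid in in_trna if indel_run_mapping[mid] is not None)
            out["run_attributed_fraction"] = assigned / len(in_trna)
        else:
            out["run_attributed_fraction"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# Strand placement summary
# ---------------------------------------------------------------------------


def placement_site_targets(genome: GenomeAnnotation) -> pd.Series:
    """Number of base pairs whose diagnostic base (A of an A:T pair, C of a
    G:C pair) sits on each template class."""
    seq = np.frombuffer(genome.sequence.encode(), dtype="S1")
    pos = np.arange(1, genome.length + 1)
    ori, ter = genome.origin_pos, genome.terminus_pos
    if ori < ter:
        on_right = (pos >= ori) & (pos < ter)
    else:
        on_right = (pos >= ori) | (pos < ter)
    is_a, is_t = seq == b"A", seq == b"T"
    is_c, is_g = seq == b"C", seq == b"G"
    # forward strand is LGST on the right replichore, LDST on the left
    a_lgst = int((is_a & on_right).sum() + (is_t & ~on_right).sum())
    a_ldst = int((is_a & ~on_right).sum() + (is_t & on_right).sum())
    c_lgst = int((is_c & on_right).sum() + (is_g & ~on_right).sum())
    c_ldst = int((is_c & ~on_right).sum() + (is_g & on_right).sum())
    return pd.Series(
        {"A_on_LGST": a_lgst, "A_on_LDST": a_ldst, "C_on_LGST": c_lgst, "C_on_LDST": c_ldst}
    )


def poisson_ratio_ci(
    n1: int, t1: float, n2: int, t2: float, conf: float = 0.95
) -> tuple[float, float, float]:
    """Rate ratio (n1/t1)/(n2/t2) with an exact conditional CI.

    Conditional on n1+n2, n1 is binomial; the Clopper-Pearson interval on
    its proportion maps to the rate ratio through the odds times t2/t1.
    """
    if n2 == 0 or t1 <= 0 or t2 <= 0:
        return float("inf"), float("nan"), float("nan")
    ratio = (n1 / t1) / (n2 / t2)
    ntot = n1 + n2
    alpha = 1 - conf
    p_lo = sp_stats.beta.ppf(alpha / 2, n1, n2 + 1) if n1 > 0 else 0.0
    p_hi = sp_stats.beta.ppf(1 - alpha / 2, n1 + 1, n2) if n1 < ntot else 1.0
    scale = t2 / t1
    lo = (p_lo / (1 - p_lo)) * scale if p_lo < 1 else float("inf")
    hi = (p_hi / (1 - p_hi)) * scale if p_hi < 1 else float("inf")
    return ratio, lo, hi


def placement_summary(
    mutations: Sequence[Mutation],
    genome: GenomeAnnotation,
    assignment: CdsAssignment | None = None,
) -> dict:
    """Strand-placement table for transitions.

    Reports genome-wide counts per placement class, per-site-normalized
    LGST/LDST rate ratios with exact CIs, and (when a CDS assignment is
    supplied) per-CDS transition frequencies split by gene orientation and
    by whether the diagnostic base lies on the transcribed strand, with
    box statistics and CD-vs-HO tests.
    """
    counts = placement_counts(mutations, genome)
    targets = placement_site_targets(genome)
    out: dict = {"counts": counts, "site_targets": targets}
    out["at_ratio"] = poisson_ratio_ci(
        int(counts["A_on_LGST"]), targets["A_on_LGST"], int(counts["A_on_LDST"]), targets["A_on_LDST"]
    )
    out["gc_ratio"] = poisson_ratio_ci(
        int(counts["C_on_LGST"]), targets["C_on_LGST"], int(counts["C_on_LDST"]), targets["C_on_LDST"]
    )
    if assignment is None:
        return out

    gene_strand = {g.gene_id: g.strand for g in genome.genes}
    per_gene = pd.DataFrame(
        0,
        index=assignment.gene_counts.index,
        columns=["at_ts_on_transcribed", "at_ts_off_transcribed", "gc_ts_on_transcribed", "gc_ts_off_transcribed"],
        dtype=int,
    )
    for m in mutations:
        if not (m.is_bps and m.bps_class().change_class == "transition"):
            continue
        cls = m.bps_class()
        # strand carrying the diagnostic base (A or C) of the mutated pair
        if cls.pair_class == "AT":
            base_strand = "forward" if m.ref == "A" else "reverse"
            prefix = "at"
        else:
            base_strand = "forward" if m.ref == "C" else "reverse"
            prefix = "gc"
        for gid in assignment.mutation_genes.get(m.mutation_id, []):
            transcribed = "reverse" if gene_strand[gid] == "forward" else "forward"
            col = f"{prefix}_ts_{'on' if base_strand == transcribed else 'off'}_transcribed"
            per_gene.at[gid, col] += 1
    ori = orientation_table(genome)["orientation"].reindex(per_gene.index)
    per_gene["orientation"] = ori
    out["per_gene"] = per_gene

    groups: dict[str, dict] = {}
    for prefix in ("at", "gc"):
        for placement in ("on", "off"):
            col = f"{prefix}_ts_{placement}_transcribed"
            cd = per_gene.loc[ori == "CD", col].to_numpy(dtype=float)
            ho = per_gene.loc[ori == "HO", col].to_numpy(dtype=float)
            entry: dict = {
                "mean_cd": _mean(cd),
                "mean_ho": _mean(ho),
                "box_cd": st.box_stats(cd) if len(cd) else None,
                "box_ho": st.box_stats(ho) if len(ho) else None,
            }
            if len(cd) >= 2 and len(ho) >= 2:
                entry["p_t"] = st.two_sample_t(cd, ho).p_raw
                entry["p_mw"] = st.mann_whitney(cd, ho).p_raw
            groups[col] = entry
    out["groups"] = groups
    return out


# ---------------------------------------------------------------------------
# Report orchestration
# ---------------------------------------------------------------------------


def standard_subsets(genome: GenomeAnnotation) -> list[GeneSubset]:
    """The subset ladder used by the full report, built from annotated gene
    categories (absent categories yield empty subsets that are skipped)."""
    subsets = [subset_all(genome)]
    trna = subset_by_category(genome, "tRNA")
    ribo = subset_by_category(genome, "ribosomal")
    if trna.gene_ids or ribo.gene_ids:
        subsets.append(
            subset_minus(subset_all(genome), trna.gene_ids | ribo.gene_ids, "minus_trna_ribosomal")
        )
    he = subset_by_category(genome, "highly_expressed")
    if he.gene_ids:
        subsets.append(he)
        subsets.append(subset_minus(he, trna.gene_ids | ribo.gene_ids, "highly_expressed_minus_trna_ribosomal"))
        subsets.append(subset_minus(he, trna.gene_ids, "highly_expressed_minus_trna"))
    for cat in ("essential", "ribosomal", "tRNA", "rpoS_up", "rpoS_low", "sos_all", "sos_damage", "lexA"):
        s = subset_by_category(genome, cat)
        if s.gene_ids:
            subsets.append(s)
    return [s for s in subsets if len(s) > 0]


def run_report(
    genome: GenomeAnnotation,
    mutations: Sequence[Mutation],
    experiments: Sequence,
    outdir: str | Path,
    hotspot_gene_ids: Sequence[str] = (),
    seed: int | None = None,
) -> dict:
    """Full analysis run: assignments, frequency tables, comparison and
    correlation tables, rates, run census, placement summary; TSV outputs
    plus a JSON manifest.  Deterministic for identical inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    assignment = assign_to_cds(mutations, genome)
    freq = frequency_per_cds(assignment.gene_counts, genome)
    ori = orientation_table(genome)
    subsets = standard_subsets(genome)

    tables: dict[str, pd.DataFrame] = {}
    comp_frames = [comparison_table(freq, ori, s) for s in subsets]
    tables["table3_comparisons"] = pd.concat(comp_frames, ignore_index=True)

    bps_metrics = (
        "at_transition_per_cds",
        "at_transition_per_cds_per_nt",
        "gc_transition_per_cds",
        "gc_transition_per_cds_per_nt",
        "at_transversion_per_cds",
        "gc_transversion_per_cds",
    )
    tables["table7_bps_types"] = pd.concat(
        [comparison_table(freq, ori, s, metrics=bps_metrics) for s in subsets[:1]],
        ignore_index=True,
    )

    lengths = freq["cds_length"]
    corr_frames = [
        correlation_table(freq, ori, "cds_length", lengths, s) for s in subsets
    ]
    tables["table1_length_correlations"] = pd.concat(corr_frames, ignore_index=True)

    tpm = tpm_table(genome)
    tpm_frames = []
    for phase in ("tpm_lag", "tpm_log", "tpm_stat"):
        if tpm[phase].notna().any():
            for s in subsets[:3]:
                tpm_frames.append(
                    correlation_table(freq, ori, phase, tpm[phase], s, log_predictor=True)
                )
    if tpm_frames:
        tables["table2_expression_correlations"] = pd.concat(tpm_frames, ignore_index=True)

    family_size = apply_bh_family(tables)

    # rates (Garwood CIs)
    exposure = total_exposure(list(experiments))
    targets = pair_class_targets(genome.sequence)
    class_counts = {
        "bps_total": sum(1 for m in mutations if m.is_bps),
        "indel_total": sum(1 for m in mutations if m.is_indel),
        "at_transition": sum(
            1
            for m in mutations
            if m.is_bps and m.bps_class().change_class == "transition" and m.bps_class().pair_class == "AT"
        ),
        "gc_transition": sum(
            1
            for m in mutations
            if m.is_bps and m.bps_class().change_class == "transition" and m.bps_class().pair_class == "GC"
        ),
    }
    class_targets = {
        "bps_total": float(genome.length),
        "indel_total": float(genome.length),
        "at_transition": float(targets["AT"]),
        "gc_transition": float(targets["GC"]),
    }
    tables["fig2_rates"] = rates_table(class_counts, exposure, class_targets)

    census = run_census(genome.sequence)
    tables["run_census"] = pd.DataFrame(
        {"run_length": list(census), "fraction_of_nt": list(census.values())}
    )

    placement = placement_summary(mutations, genome, assignment)
    tables["fig4_placement"] = pd.DataFrame(
        {
            "placement": list(PLACEMENT_CLASSES),
            "count": [int(placement["counts"][c]) for c in PLACEMENT_CLASSES],
            "site_target": [int(placement["site_targets"][c]) for c in PLACEMENT_CLASSES],
        }
    )

    trna = subset_by_category(genome, "tRNA")
    trna_report = None
    if trna.gene_ids:
        runs = find_runs(genome.sequence, min_len=5, circular=genome.is_circular)
        mapping, _ = assign_indels_to_runs(
            [m for m in mutations if m.is_indel], runs, genome.length
        )
        trna_report = trna_decomposition(
            freq, ori, trna, list(hotspot_gene_ids), mapping, assignment.mutation_genes
        )
        tables["table4_trna"] = pd.concat(
            [comparison_table(freq, ori, trna),
             comparison_table(freq, ori, subset_minus(trna, hotspot_gene_ids, "tRNA_minus_hotspots"))],
            ignore_index=True,
        )

    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)

    manifest = {
        "seed": seed,
        "n_mutations": len(mutations),
        "n_genes": len(genome.genes),
        "n_promoters": len(genome.promoters),
        "total_generations": exposure,
        "bh_family_size": family_size,
        "n_multi_assigned": assignment.n_multi,
        "n_intergenic": assignment.n_intergenic,
        "tables": sorted(tables),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "tables": tables,
        "assignment": assignment,
        "freq": freq,
        "orientation": ori,
        "placement": placement,
        "trna": trna_report,
        "manifest": manifest,
    }
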