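"""Mutation frequencies and conditional per-generation, per-nucleotide rates.

A conditional rate divides the count of mutations of a class by the product
of total line-generations and the number of eligible nucleotides (or base
pairs of the relevant class: an A:T pair counts once, regardless of which
strand carries the A).  95% confidence limits use the exact Poisson
(Garwood) interval on the count, divided by the exposure; a nonparametric
between-line bootstrap is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeAnnotation


@dataclass(frozen=True)
class RateEstimate:
    numerator: int
    generations: float
    nt_target: float
    rate: float
    ci_low: float
    ci_high: float
    method: str = "garwood"


def garwood_interval(count: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact Poisson confidence limits on a count (chi-square form)."""
    alpha = 1.0 - conf
    lo = 0.0 if count == 0 else stats.chi2.ppf(alpha / 2, 2 * count) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2
    return lo, hi


def conditional_rate(
    count: int,
    generations: float,
    nt_target: float,
    conf: float = 0.95,
    method: str = "garwood",
    per_line_counts: np.ndarray | None = None,
    per_line_generations: np.ndarray | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> RateEstimate:
    """Rate = count / (generations * nt_target), with confidence limits.

    ``method='bootstrap'`` resamples lines (requires per-line counts and
    generations) instead of assuming Poisson counts.
    """
    if generations <= 0 or nt_target <= 0:
        raise ValueError("exposure must be positive")
    exposure = generations * nt_target
    rate = count / exposure
    if method == "garwood":
        lo, hi = garwood_interval(count, conf)
        return RateEstimate(count, generations, nt_target, rate, lo / exposure, hi / exposure)
    if method == "bootstrap":
        if per_line_counts is None or per_line_generations is None:
            raise ValueError("bootstrap needs per-line counts and generations")
        rng = np.random.default_rng(seed)
        counts = np.asarray(per_line_counts, dtype=float)
        gens = np.asarray(per_line_generations, dtype=float)
        n = len(counts)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = counts[idx].sum(axis=1) / (gens[idx].sum(axis=1) * nt_target)
        alpha = 1.0 - conf
        lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
        return RateEstimate(count, generations, nt_target, rate, float(lo), float(hi), "bootstrap")
    raise ValueError(f"unknown CI method {method!r}")


def rate_delta(rate_a: float, rate_b: float) -> int:
    """Percent change of rate_a over rate_b, to the nearest integer percent."""
    if rate_b == 0:
        raise ZeroDivisionError("reference rate is zero")
    return int(round(100.0 * (rate_a - rate_b) / rate_b))


def mean_per_cds(total_count: int, n_cds: int) -> float:
    """Mean mutations per CDS from a total count and a CDS count."""
    if n_cds <= 0:
        raise ValueError("n_cds must be positive")
    return total_count / n_cds


def frequency_per_cds(
    gene_counts: pd.DataFrame,
    genome: GenomeAnnotation,
    per_nt_scale: float = 1e3,
) -> pd.DataFrame:
    """Per-gene frequency table: raw counts plus per-nt variants.

    Per-nt frequencies divide by CDS length; the reporting scale multiplies
    them by 10^3 (so a value of 6.5 means 6.5 mutations per kb of CDS).
    """
    lengths = pd.Series(
        {g.gene_id: g.cds_length(genome.length) for g in genome.genes}, name="cds_length"
    )
    lengths = lengths.reindex(gene_counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("missing or zero-length CDS")
    out = gene_counts.copy()
    out["cds_length"] = lengths
    out["bps_per_cds"] = out["n_bps"].astype(float)
    out["indel_per_cds"] = out["n_indel"].astype(float)
    out["bps_per_cds_per_nt"] = out["n_bps"] / lengths * per_nt_scale
    out["indel_per_cds_per_nt"] = out["n_indel"] / lengths * per_nt_scale
    for cls in ("at_transition", "gc_transition", "at_transversion", "gc_transversion"):
        col = f"n_{cls}"
        if col in out.columns:
            out[f"{cls}_per_cds"] = out[col].astype(float)
            out[f"{cls}_per_cds_per_nt"] = out[col] / lengths * per_nt_scale
    return out


def pair_class_targets(sequence: str) -> dict[str, int]:
    """Base-pair targets per pair class: an A:T pair counted once."""
    at = sum(1 for b in sequence if b in "AT")
    return {"AT": at, "GC": len(sequence) - at}


def rates_table(
    class_counts: dict[str, int],
    generations: float,
    targets: dict[str, float],
    scope: str = "genome",
    conf: float = 0.95,
) -> pd.DataFrame:
    """Conditional rate per mutation class with confidence limits."""
    rows = []
    for cls, count in class_counts.items():
        est = conditional_rate(count, generations, targets[cls], conf=conf)
        rows.append(
            {
                "class": cls,
                "scope": scope,
                "count": count,
                "exposure": est.generations * est.nt_target,
                "rate": est.rate,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    return pd.DataFrame(rows)
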