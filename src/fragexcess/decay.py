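"""Rifampicin-chase mRNA decay kinetics.

After rifampicin blocks transcription initiation, transcript abundance
follows first-order decay, level(t) = level(0) * exp(-k t), so a
log-linear fit of abundance on time recovers the decay rate k and the
half-life ln(2)/k.  With sampling restricted to a few minutes after the
chase, very fast and very slow decay fall outside the observable window:
half-lives below ``min_hl`` (default 1 min) or above ``max_hl`` (default
15 min) are flagged not calculable rather than reported as numbers.

Abundances may be RPKM series from Rif-seq, bulk mRNA fractions, or
relative qPCR levels (2^-ddCt).  Half-life is invariant to multiplicative
rescaling of a series, so the normalization choice only affects the
intercept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_MIN_HALF_LIFE = 1.0  # min; faster decay is not calculable
DEFAULT_MAX_HALF_LIFE = 15.0  # min; slower decay is not calculable


@dataclass(frozen=True)
class DecaySeries:
    """Time-stamped relative abundances for one transcript (or the bulk)."""

    gene: str
    time_points: tuple[float, ...]
    levels: tuple[float, ...]
    normalization: str = "rpkm"  # rpkm | fraction | ddct

    def __post_init__(self) -> None:
        if len(self.time_points) != len(self.levels):
            raise ValueError("time_points and levels must have equal length")
        t = self.time_points
        if t and (t[0] != 0 or any(b <= a for a, b in zip(t, t[1:]))):
            raise ValueError("time_points must be strictly ascending from 0")
        if self.normalization not in ("rpkm", "fraction", "ddct"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def rescaled(self, factor: float) -> "DecaySeries":
        return DecaySeries(
            self.gene,
            self.time_points,
            tuple(v * factor for v in self.levels),
            self.normalization,
        )


@dataclass(frozen=True)
class HalfLifeResult:
    """Fitted decay rate and half-life with calculability status.

    ``status`` is ``ok`` when the half-life lies inside the calculable
    window; ``too_fast``/``too_stable`` flag estimates outside it, and
    ``half_life`` is then NaN (not calculable).
    """

    gene: str
    rate_k: float  # 1/min (negative slope of ln-level vs time)
    half_life: float  # min; NaN unless status == "ok"
    fit_r2: float
    status: str  # ok | too_fast | too_stable
    n_points: int
    intercept: float = math.nan

    def summary(self) -> str:
        hl = f"{self.half_life:.3g} min" if self.status == "ok" else "not calculable"
        return (
            f"Exponential decay fit: {self.gene}\n"
            f"  points used    {self.n_points}\n"
            f"  rate k         {self.rate_k:.4g} /min\n"
            f"  half-life      {hl} ({self.status})\n"
            f"  R^2            {self.fit_r2:.4f}"
        )

    def predicted(self, times: Sequence[float]) -> np.ndarray:
        """Model abundance at the given times from the fitted line."""
        t = np.asarray(times, dtype=float)
        return np.exp(self.intercept - self.rate_k * t)


class ExponentialDecay:
    """Log-linear first-order decay model for one abundance series.

    ``fit`` regresses ln(level) on time by ordinary least squares with a
    free intercept; the decay rate is the negated slope.  Non-positive
    levels carry no log-scale information and are dropped with a warning;
    at least three usable points are required.
    """

    def __init__(self, series: DecaySeries) -> None:
        self.series = series

    def fit(
        self,
        min_hl: float = DEFAULT_MIN_HALF_LIFE,
        max_hl: float = DEFAULT_MAX_HALF_LIFE,
    ) -> HalfLifeResult:
        t = np.asarray(self.series.time_points, dtype=float)
        y = np.asarray(self.series.levels, dtype=float)
        usable = y > 0
        if not usable.all():
            logger.warning(
                "%s: dropping %d non-positive level(s) from the fit",
                self.series.gene,
                int((~usable).sum()),
            )
        t, y = t[usable], y[usable]
        if t.size < 3:
            raise ValueError(
                f"{self.series.gene}: need >=3 positive levels, have {t.size}"
            )
        fit = stats.linregress(t, np.log(y))
        rate_k = -float(fit.slope)
        r2 = float(fit.rvalue) ** 2
        if rate_k <= 0:
            status, half_life = "too_stable", math.nan
        else:
            hl = math.log(2.0) / rate_k
            if hl > max_hl:
                status, half_life = "too_stable", math.nan
            elif hl < min_hl:
                status, half_life = "too_fast", math.nan
            else:
                status, half_life = "ok", hl
        return HalfLifeResult(
            gene=self.series.gene,
            rate_k=rate_k,
            half_life=half_life,
            fit_r2=r2,
            status=status,
            n_points=int(t.size),
            intercept=float(fit.intercept),
        )


def fit_exponential_decay(
    series: DecaySeries,
    min_hl: float = DEFAULT_MIN_HALF_LIFE,
    max_hl: float = DEFAULT_MAX_HALF_LIFE,
) -> HalfLifeResult:
    """Convenience wrapper: ``ExponentialDecay(series).fit(min_hl, max_hl)``."""
    return ExponentialDecay(series).fit(min_hl=min_hl, max_hl=max_hl)


# -- normalizations ----------------------------------------------------------


def rpkm(reads: int, gene_length_bp: int, total_mapped: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length_bp < 1 or total_mapped < 1:
        raise ValueError("gene length and total mapped reads must be >= 1")
    if reads < 0:
        raise ValueError("read count must be non-negative")
    return reads / (gene_length_bp / 1000.0) / (total_mapped / 1e6)


def bulk_mrna_fraction(
    mrna_reads: Sequence[int],
    total_reads: Sequence[int],
    time_points: Sequence[float],
) -> DecaySeries:
    """Fraction of reads that are mRNA at each chase time point.

    Dividing mRNA reads by total reads per time point yields a series whose
    exponential fit gives the bulk mRNA half-life.
    """
    if not len(mrna_reads) == len(total_reads) == len(time_points):
        raise ValueError("mrna_reads, total_reads and time_points lengths differ")
    if any(t <= 0 for t in total_reads):
        raise ValueError("total reads must be positive at every time point")
    if any(m > t for m, t in zip(mrna_reads, total_reads)):
        raise ValueError("mRNA reads cannot exceed total reads")
    fractions = tuple(m / t for m, t in zip(mrna_reads, total_reads))
    return DecaySeries(
        gene="bulk", time_points=tuple(time_points), levels=fractions,
        normalization="fraction",
    )


def ddct_ratio(
    ct_target_t: float, ct_ref_t: float, ct_target_t0: float, ct_ref_t0: float
) -> float:
    """2^-ddCt relative expression against a reference gene and t0.

    dCt at each time is target Ct minus reference-gene Ct; ddCt subtracts
    the t0 baseline, and the returned ratio is 2**-ddCt.
    """
    for ct in (ct_target_t, ct_ref_t, ct_target_t0, ct_ref_t0):
        if not math.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_t - ct_ref_t) - (ct_target_t0 - ct_ref_t0)
    return 2.0 ** (-ddct)


def ddct_series(
    ct_table: pd.DataFrame, target_gene: str, reference_gene: str
) -> DecaySeries:
    """Relative-abundance series for one gene from a qPCR Ct table.

    ``ct_table`` has columns sample, gene, ct, time; Ct values are
    averaged over samples per (gene, time), and each time point is
    quantified as 2^-ddCt against the internal reference gene and t0.
    """
    needed = {"sample", "gene", "ct", "time"}
    if not needed <= set(ct_table.columns):
        raise ValueError(f"Ct table needs columns {sorted(needed)}")
    mean_ct = (
        ct_table.groupby(["gene", "time"])["ct"].mean().unstack("time")
    )
    for gene in (target_gene, reference_gene):
        if gene not in mean_ct.index:
            raise ValueError(f"gene {gene!r} absent from Ct table")
    times = sorted(mean_ct.columns)
    if times[0] != 0:
        raise ValueError("Ct table must include the t0 reference time point")
    levels = tuple(
        ddct_ratio(
            mean_ct.loc[target_gene, t], mean_ct.loc[reference_gene, t],
            mean_ct.loc[target_gene, times[0]], mean_ct.loc[reference_gene, times[0]],
        )
        for t in times
    )
    return DecaySeries(
        gene=target_gene, time_points=tuple(float(t) for t in times),
        levels=levels, normalization="ddct",
    )


# -- inference ---------------------------------------------------------------


def welch_t_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, float]:
    """Two-sided t-test of unequal variance (Welch).

    Returns (t, Welch-Satterthwaite df, two-sided p).  When both groups
    are constant with equal means, p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, float(
            a.size + b.size - 2
        ), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# -- tables ------------------------------------------------------------------


def rpkm_table(
    counts: pd.DataFrame,
    times: Sequence[float],
    totals: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-gene RPKM for each time point of a counts table.

    ``counts`` must have columns ``gene``, ``length_bp`` and one count
    column per time point (same order as ``times``).  ``totals`` gives the
    total mapped reads per time point; when omitted the column sums of the
    table are used.
    """
    count_cols = [c for c in counts.columns if c not in ("gene", "length_bp")]
    if len(count_cols) != len(times):
        raise ValueError("one count column per time point required")
    if totals is None:
        totals = counts[count_cols].sum(axis=0)
    else:
        totals = pd.Series(list(totals), index=count_cols)
        if len(totals) != len(count_cols):
            raise ValueError("one total per time point required")
    if (totals < 1).any():
        raise ValueError("every time point needs at least one mapped read")
    out = counts[["gene", "length_bp"]].copy()
    for col, total in zip(count_cols, totals):
        out[col] = (
            counts[col] / (counts["length_bp"] / 1000.0) / (total / 1e6)
        )
    return out


def fit_halflife_table(
    counts: pd.DataFrame,
    times: Sequence[float],
    min_hl: float = DEFAULT_MIN_HALF_LIFE,
    max_hl: float = DEFAULT_MAX_HALF_LIFE,
    totals: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-gene half-life fits from a counts table (RPKM-normalized).

    Genes with fewer than three positive levels are reported with status
    ``insufficient_data`` rather than dropped silently.
    """
    table = rpkm_table(counts, times, totals=totals)
    count_cols = [c for c in table.columns if c not in ("gene", "length_bp")]
    rows = []
    for _, row in table.iterrows():
        levels = tuple(float(row[c]) for c in count_cols)
        try:
            series = DecaySeries(str(row["gene"]), tuple(times), levels)
            est = fit_exponential_decay(series, min_hl=min_hl, max_hl=max_hl)
            rows.append(
                (est.gene, est.rate_k, est.half_life, est.fit_r2, est.status)
            )
        except ValueError:
            rows.append((str(row["gene"]), math.nan, math.nan, math.nan,
                         "insufficient_data"))
    return pd.DataFrame(
        rows, columns=["gene", "rate_k", "half_life", "r2", "status"]
    )


def compare_halflives(
    tables_a: Sequence[pd.DataFrame], tables_b: Sequence[pd.DataFrame]
) -> pd.DataFrame:
    """Per-gene Welch comparison of replicate decay rates between strains.

    Each input is one replicate's ``fit_halflife_table`` output; rates
    (not half-lives) are compared so non-calculable but finite-rate genes
    still contribute.  P-values are Benjamini-Hochberg adjusted.
    """
    def stack(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
        return pd.concat(tables, ignore_index=True)

    a, b = stack(tables_a), stack(tables_b)
    genes = sorted(set(a["gene"]) & set(b["gene"]))
    rows = []
    for gene in genes:
        ra = a.loc[(a["gene"] == gene) & np.isfinite(a["rate_k"]), "rate_k"]
        rb = b.loc[(b["gene"] == gene) & np.isfinite(b["rate_k"]), "rate_k"]
        if len(ra) < 2 or len(rb) < 2:
            rows.append((gene, math.nan, math.nan, math.nan, "insufficient_replicates"))
            continue
        t, df, p = welch_t_test(ra, rb)
        rows.append((gene, t, df, p, "ok"))
    out = pd.DataFrame(rows, columns=["gene", "t", "df", "p", "status"])
    ok = out["status"] == "ok"
    out["p_adj"] = math.nan
    out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out
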