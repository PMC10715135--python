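"""Fragmentation-excess statistic and Bayesian Error Rate decision.

Given depth-equalized, replicate-merged 5' profiles for a mutant and a
wild-type strain, every genomic position with at least one read start in
either strain gets a proportion

    P_i = mutant_i / (mutant_i + wt_i)

P = 1 marks a position seen only in the mutant, P = 0 only in the wild
type.  Random fragmentation intrinsic to library preparation produces a
background of strain-exclusive positions in both directions; an *excess*
of P = 1 positions over P = 0 positions signals accumulation of RNA decay
intermediates in the mutant.

The decision model treats the two extreme-bin counts n0 (= #P=0) and
n1 (= #P=1) as draws from two equal-prior Gaussian classes whose common
standard deviation sigma is estimated from the interior of the P
histogram (the 99 bins strictly between 0 and 1, the background noise).
The Bayesian Error Rate of that two-class decision problem,

    BER = Phi(-|n1 - n0| / (2 sigma)),

is the probability that an optimal classifier confuses the two classes;
BER below alpha (default 0.01) declares the excess significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .profiles import FivePrimeProfile, Key

N_INTERIOR_BINS = 99


class DegenerateStatisticsError(ValueError):
    """Raised when the excess statistic is undefined (e.g. n0 = 0)."""


# -- proportion field --------------------------------------------------------


class ProportionField:
    """Per-position proportions P = mutant/(mutant+wt), stored columnar.

    Only positions with a nonzero combined count are represented, so every
    stored P is defined and lies in [0, 1].
    """

    def __init__(self) -> None:
        self._data: dict[Key, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def n_positions(self) -> int:
        return int(sum(pos.size for pos, _ in self._data.values()))

    def keys(self) -> list[Key]:
        return sorted(self._data)

    def arrays(self, key: Key) -> tuple[np.ndarray, np.ndarray]:
        if key in self._data:
            return self._data[key]
        return np.array([], dtype=np.int64), np.array([], dtype=float)

    def all_values(self) -> np.ndarray:
        if not self._data:
            return np.array([], dtype=float)
        return np.concatenate([v for _, v in self._data.values()])

    def as_dict(self) -> dict[tuple[str, str, int], float]:
        out: dict[tuple[str, str, int], float] = {}
        for (ref, strand), (pos, val) in sorted(self._data.items()):
            for p, v in zip(pos.tolist(), val.tolist()):
                out[(ref, strand, p)] = v
        return out


def compute_proportions(
    mutant: FivePrimeProfile, wt: FivePrimeProfile
) -> ProportionField:
    """P_i = mutant_i/(mutant_i + wt_i) over the union of covered positions."""
    if mutant.total_reads == 0 and wt.total_reads == 0:
        raise ValueError("both profiles are empty; proportions undefined")
    keys = sorted(set(mutant.keys()) | set(wt.keys()))
    out = ProportionField()
    for key in keys:
        mpos, mcnt = mutant.arrays(key)
        wpos, wcnt = wt.arrays(key)
        upos = np.union1d(mpos, wpos)
        m = np.zeros(upos.size, dtype=np.int64)
        w = np.zeros(upos.size, dtype=np.int64)
        m[np.searchsorted(upos, mpos)] = mcnt
        w[np.searchsorted(upos, wpos)] = wcnt
        total = m + w
        out._data[key] = (upos, m / total)
    return out


# -- histogram and background ------------------------------------------------


@dataclass(frozen=True)
class ExcessHistogram:
    """Histogram of P with exact-equality extreme classes.

    ``n0`` and ``n1`` count positions with P exactly 0 and exactly 1
    (these values arise only from an integer zero numerator or zero
    complement, so exact floating-point equality is safe).  The open
    interval (0, 1) is split into 99 equal-width bins, left-closed
    right-open with the last bin right-closed.
    """

    n0: int
    n1: int
    interior_bin_counts: np.ndarray  # length 99
    n_positions: int

    def __post_init__(self) -> None:
        if self.interior_bin_counts.shape != (N_INTERIOR_BINS,):
            raise ValueError("expected 99 interior bins")
        if self.n0 + self.n1 + int(self.interior_bin_counts.sum()) != self.n_positions:
            raise ValueError("histogram does not partition the proportion field")

    @property
    def bin_edges(self) -> np.ndarray:
        """Edges of the 99 interior bins over (0, 1)."""
        return np.linspace(0.0, 1.0, N_INTERIOR_BINS + 1)


def histogram(p_field: ProportionField) -> ExcessHistogram:
    """Bin a proportion field into n0, n1 and 99 interior bin counts."""
    values = p_field.all_values()
    if values.size == 0:
        raise ValueError("empty proportion field")
    n0 = int(np.count_nonzero(values == 0.0))
    n1 = int(np.count_nonzero(values == 1.0))
    interior = values[(values > 0.0) & (values < 1.0)]
    idx = np.minimum((interior * N_INTERIOR_BINS).astype(np.int64), N_INTERIOR_BINS - 1)
    counts = np.bincount(idx, minlength=N_INTERIOR_BINS).astype(np.int64)
    return ExcessHistogram(
        n0=n0, n1=n1, interior_bin_counts=counts, n_positions=int(values.size)
    )


def excess_ratio(n0: int, n1: int) -> float:
    """Percent excess of mutant-exclusive over wt-exclusive positions.

    Returns ``100 * (n1/n0 - 1)``; e.g. n0=100, n1=178 -> 78.0.  When
    n0 = 0 the ratio is undefined and ``inf`` is returned as an
    infinite-excess flag.
    """
    if n0 < 0 or n1 < 0:
        raise ValueError("counts must be non-negative")
    if n0 == 0:
        return math.inf
    return 100.0 * (n1 / n0 - 1.0)


def pooled_background_sd(hist: ExcessHistogram) -> float:
    """Background noise scale: sample SD of the 99 interior bin counts.

    The interior of the P histogram (everything except the biologically
    relevant P = 0 and P = 1 classes) is taken as background; zero-count
    bins are included.  Sample SD uses the N-1 denominator.
    """
    counts = np.asarray(hist.interior_bin_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 interior bins")
    # sort first so the result is bitwise invariant under bin permutation
    # (strain swap reverses the bin order)
    return float(np.std(np.sort(counts), ddof=1))


def bayes_error_rate(n0: int, n1: int, sigma: float) -> float:
    """Equal-prior two-class Gaussian misclassification rate.

    Two Gaussian classes with means n0 and n1 and common SD ``sigma``
    yield BER = Phi(-|n1-n0| / (2 sigma)).  With sigma = 0 the classes
    are point masses: BER is 0 unless the counts coincide (then 0.5).
    """
    if n0 < 0 or n1 < 0 or sigma < 0:
        raise ValueError("n0, n1 and sigma must be non-negative")
    delta = abs(n1 - n0)
    if sigma == 0:
        return 0.0 if delta > 0 else 0.5
    return float(stats.norm.cdf(-delta / (2.0 * sigma)))


def decide(ber: float, alpha: float = 0.01) -> bool:
    """Significance call: strictly BER < alpha."""
    if not 0 <= ber <= 0.5:
        raise ValueError("BER must lie in [0, 0.5]")
    return ber < alpha


def hypergeometric_overlap(
    size_a: int, size_b: int, overlap: int, universe: int
) -> float:
    """Upper-tail hypergeometric probability of an overlap at least this large.

    P(X >= overlap) where X is the overlap of a random ``size_b``-subset
    with a fixed ``size_a``-subset of a ``universe``-element population.
    Symmetric in size_a and size_b.
    """
    if not (0 <= size_a <= universe and 0 <= size_b <= universe):
        raise ValueError("set sizes must lie within the universe")
    if not 0 <= overlap <= min(size_a, size_b):
        raise ValueError("overlap must not exceed either set size")
    return float(stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))


# -- model / results ---------------------------------------------------------


class FragmentationExcess:
    """Model of fragmentation excess between a mutant and a wild-type strain.

    Built from two depth-equalized, replicate-merged
    :class:`~fragexcess.profiles.FivePrimeProfile` objects; :meth:`fit`
    computes the proportion field, its histogram, the Gaussian background
    scale and the Bayesian Error Rate, returning a
    :class:`FragmentationExcessResult`.

    Parameters
    ----------
    mutant, wt
        Merged per-strain 5' profiles over the same reference space.
    collapse_strands
        Sum the two strands' counts per position before computing P
        (default False: P is computed per (strand, position), the natural
        reading for stranded libraries).
    """

    def __init__(
        self,
        mutant: FivePrimeProfile,
        wt: FivePrimeProfile,
        *,
        collapse_strands: bool = False,
    ) -> None:
        if collapse_strands:
            mutant = mutant.collapse_strands()
            wt = wt.collapse_strands()
        self.mutant = mutant
        self.wt = wt
        self.collapse_strands = collapse_strands

    def fit(self, alpha: float = 0.01) -> "FragmentationExcessResult":
        if not 0 < alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
        p_field = compute_proportions(self.mutant, self.wt)
        hist = histogram(p_field)
        sigma = pooled_background_sd(hist)
        ber = bayes_error_rate(hist.n0, hist.n1, sigma)
        return FragmentationExcessResult(
            model=self,
            proportions=p_field,
            histogram=hist,
            n0=hist.n0,
            n1=hist.n1,
            excess_percent=excess_ratio(hist.n0, hist.n1),
            sigma=sigma,
            ber=ber,
            significant=decide(ber, alpha),
            alpha=alpha,
        )


@dataclass
class FragmentationExcessResult:
    """Fitted fragmentation-excess statistics for one strain pair."""

    model: FragmentationExcess
    proportions: ProportionField
    histogram: ExcessHistogram
    n0: int
    n1: int
    excess_percent: float
    sigma: float
    ber: float
    significant: bool
    alpha: float

    @property
    def infinite_excess(self) -> bool:
        """True when n0 = 0 and the excess ratio is undefined."""
        return self.n0 == 0

    def to_dict(self) -> dict:
        return {
            "n0": self.n0,
            "n1": self.n1,
            "excess_percent": None if self.infinite_excess else self.excess_percent,
            "infinite_excess": self.infinite_excess,
            "sigma": self.sigma,
            "ber": self.ber,
            "significant": self.significant,
            "alpha": self.alpha,
        }

    def summary(self) -> str:
        lines = [
            "Fragmentation excess (mutant vs wild type)",
            "==========================================",
            f"positions with coverage     {self.histogram.n_positions:>12d}",
            f"n0  (P = 0, wt-exclusive)   {self.n0:>12d}",
            f"n1  (P = 1, mutant-excl.)   {self.n1:>12d}",
            (
                f"excess of P=1 over P=0      {'undefined (n0 = 0)':>12s}"
                if self.infinite_excess
                else f"excess of P=1 over P=0      {self.excess_percent:>11.1f}%"
            ),
            f"background sigma            {self.sigma:>12.2f}",
            f"Bayesian Error Rate         {self.ber:>12.3g}",
            f"significant (BER < {self.alpha:g})   {str(self.significant):>12s}",
        ]
        return "\n".join(lines)

    def plot_histogram(self, ax=None):
        """Bar plot of the P histogram (n0, 99 interior bins, n1)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        edges = self.histogram.bin_edges
        centers = (edges[:-1] + edges[1:]) / 2
        width = edges[1] - edges[0]
        ax.bar(centers, self.histogram.interior_bin_counts, width=width,
               color="0.6", label="interior (background)")
        ax.bar([0.0], [self.n0], width=width, color="C0", label="P = 0")
        ax.bar([1.0], [self.n1], width=width, color="C3", label="P = 1")
        ax.set_xlabel("P = mutant / (mutant + wt)")
        ax.set_ylabel("genomic positions")
        ax.legend()
        return ax
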