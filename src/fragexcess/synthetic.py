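"""Synthetic alignments, 5' profiles and decay series with planted structure.

The fragmentation generator emulates the data regime of a two-strain 5'
read-start comparison: a set of cleavage sites shared by both strains,
whose per-replicate read-start counts are Poisson, plus mutant-exclusive
decay-intermediate sites planted at a chosen rate.  Strain-exclusive
positions (P = 0 or P = 1 downstream) then arise from two sources, exactly
as in real libraries: Poisson undersampling of shared sites (the
symmetric background) and the planted mutant-only sites (the signal).

Every generator is deterministic under its scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .decay import DecaySeries
from .profiles import AlignmentRecord, FivePrimeProfile

#: Defaults mirror a bacterial whole-genome comparison at realistic scale:
#: a ~4 Mb genome (Caulobacter crescentus NA1000 is 4.0 Mb), three
#: biological replicates per strain, stranded libraries with sites split
#: evenly between strands, and a per-site per-replicate start rate low
#: enough that most covered positions hold only a handful of reads --
#: the regime in which strain-exclusive positions are common.
DEFAULT_GENOME_LENGTH = 4_000_000
DEFAULT_N_SHARED_SITES = 200_000
DEFAULT_LAMBDA = 0.3
DEFAULT_REPLICATES = 3
DEFAULT_REFERENCE = "synthetic_genome"


@dataclass(frozen=True)
class FragmentationScenario:
    """Generative parameters for a two-strain fragmentation comparison."""

    genome_length: int = DEFAULT_GENOME_LENGTH
    n_shared_sites: int = DEFAULT_N_SHARED_SITES
    lambda_shared: float = DEFAULT_LAMBDA
    n_exclusive_sites: int = 0
    lambda_exclusive: float = DEFAULT_LAMBDA
    n_replicates_per_strain: int = DEFAULT_REPLICATES
    strand_fraction: float = 0.5
    seed: int = 0
    reference: str = DEFAULT_REFERENCE

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if self.n_shared_sites < 0 or self.n_exclusive_sites < 0:
            raise ValueError("site counts must be non-negative")
        total = self.n_shared_sites + self.n_exclusive_sites
        if total > 2 * self.genome_length:
            raise ValueError(
                f"{total} sites exceed the {2 * self.genome_length} available "
                "(strand, position) slots"
            )
        if self.lambda_shared <= 0 or self.lambda_exclusive <= 0:
            raise ValueError("site rates must be positive")
        if self.n_replicates_per_strain < 1:
            raise ValueError("need at least one replicate per strain")
        if not 0 <= self.strand_fraction <= 1:
            raise ValueError("strand_fraction must lie in [0, 1]")
        n_fwd = round(self.strand_fraction * total)
        if n_fwd > self.genome_length or total - n_fwd > self.genome_length:
            raise ValueError("site count on one strand exceeds genome length")

    @property
    def merged_rate_shared(self) -> float:
        """Expected merged (replicate-summed) count at a shared site."""
        return self.lambda_shared * self.n_replicates_per_strain

    @property
    def merged_rate_exclusive(self) -> float:
        return self.lambda_exclusive * self.n_replicates_per_strain

    def expected_background_exclusive(self) -> float:
        """Expected n0 (= symmetric part of n1) from Poisson sampling alone.

        A shared site contributes to n0 when its merged mutant count is 0
        and its merged wt count is positive: probability q(1-q) with
        q = exp(-replicates * lambda_shared).
        """
        q = math.exp(-self.merged_rate_shared)
        return self.n_shared_sites * q * (1.0 - q)

    def expected_excess_percent(self) -> float:
        """Closed-form percent excess of E[n1] over E[n0] for this scenario."""
        background = self.expected_background_exclusive()
        planted = self.n_exclusive_sites * (
            1.0 - math.exp(-self.merged_rate_exclusive)
        )
        return 100.0 * planted / background

    @classmethod
    def with_planted_excess(
        cls, target_excess_percent: float, **kwargs
    ) -> "FragmentationScenario":
        """Scenario whose expected n1/n0 excess equals the target percent.

        The number of mutant-exclusive sites is solved in closed form from
        the planted Poisson model:

            E = (target/100) * S q (1 - q) / (1 - q_e),

        with q = exp(-R lambda_shared), q_e = exp(-R lambda_exclusive).
        """
        base = cls(**kwargs)
        q_e = math.exp(-base.merged_rate_exclusive)
        n_exclusive = round(
            target_excess_percent / 100.0
            * base.expected_background_exclusive()
            / (1.0 - q_e)
        )
        return replace(base, n_exclusive_sites=n_exclusive)


@dataclass(frozen=True)
class SiteLayout:
    """Planted (strand, position) slots, shared sites first."""

    strands: np.ndarray  # "+" / "-" per site
    positions: np.ndarray  # 1-based
    n_shared: int

    @property
    def shared(self) -> tuple[np.ndarray, np.ndarray]:
        return self.strands[: self.n_shared], self.positions[: self.n_shared]

    @property
    def exclusive(self) -> tuple[np.ndarray, np.ndarray]:
        return self.strands[self.n_shared:], self.positions[self.n_shared:]


def _place_sites(scenario: FragmentationScenario, rng: np.random.Generator) -> SiteLayout:
    """Sample distinct (strand, position) slots; exclusive sites are the
    tail of one permutation, hence disjoint from shared sites."""
    total = scenario.n_shared_sites + scenario.n_exclusive_sites
    n_fwd = round(scenario.strand_fraction * total)
    fwd = rng.choice(scenario.genome_length, size=n_fwd, replace=False) + 1
    rev = rng.choice(scenario.genome_length, size=total - n_fwd, replace=False) + 1
    strands = np.array(["+"] * n_fwd + ["-"] * (total - n_fwd))
    positions = np.concatenate([fwd, rev]).astype(np.int64)
    order = rng.permutation(total)
    return SiteLayout(strands[order], positions[order], scenario.n_shared_sites)


def _profile_from_sites(
    reference: str,
    strands: np.ndarray,
    positions: np.ndarray,
    counts: np.ndarray,
) -> FivePrimeProfile:
    profile = FivePrimeProfile(references=[reference])
    for strand in ("+", "-"):
        mask = (strands == strand) & (counts > 0)
        pos = positions[mask]
        cnt = counts[mask]
        order = np.argsort(pos, kind="stable")
        profile._set_arrays((reference, strand), pos[order], cnt[order])
    return profile


def generate_profiles(
    scenario: FragmentationScenario,
) -> tuple[list[FivePrimeProfile], list[FivePrimeProfile]]:
    """Per-replicate 5' profiles for (mutant, wild type).

    Shared sites draw independent Poisson(lambda_shared) counts per
    replicate in both strains; exclusive sites draw
    Poisson(lambda_exclusive) in mutant replicates only.
    """
    rng = np.random.default_rng(scenario.seed)
    layout = _place_sites(scenario, rng)
    sh_strands, sh_pos = layout.shared
    ex_strands, ex_pos = layout.exclusive
    mutant, wildtype = [], []
    for _ in range(scenario.n_replicates_per_strain):
        wt_counts = rng.poisson(scenario.lambda_shared, scenario.n_shared_sites)
        mut_shared = rng.poisson(scenario.lambda_shared, scenario.n_shared_sites)
        mut_excl = rng.poisson(scenario.lambda_exclusive, scenario.n_exclusive_sites)
        wildtype.append(
            _profile_from_sites(scenario.reference, sh_strands, sh_pos, wt_counts)
        )
        mutant.append(
            _profile_from_sites(
                scenario.reference,
                np.concatenate([sh_strands, ex_strands]),
                np.concatenate([sh_pos, ex_pos]),
                np.concatenate([mut_shared, mut_excl]),
            )
        )
    return mutant, wildtype


# -- alignment-record expansion ---------------------------------------------


@dataclass(frozen=True)
class SyntheticAlignments:
    """Per-replicate alignment records plus the profiles they encode."""

    mutant: tuple[tuple[AlignmentRecord, ...], ...]
    wildtype: tuple[tuple[AlignmentRecord, ...], ...]
    mutant_profiles: tuple[FivePrimeProfile, ...]
    wildtype_profiles: tuple[FivePrimeProfile, ...]


def _records_for_profile(
    profile: FivePrimeProfile,
    genome_length: int,
    read_length: int,
    paired: bool,
) -> tuple[AlignmentRecord, ...]:
    records: list[AlignmentRecord] = []
    for ref, strand in profile.keys():
        positions, counts = profile.arrays((ref, strand))
        for pos, count in zip(positions.tolist(), counts.tolist()):
            if strand == "+":
                span = (pos, min(pos + read_length - 1, genome_length))
                mate_right = min(pos + 2 * read_length - 1, genome_length)
                mate = (max(1, mate_right - read_length + 1), mate_right)
                mate_strand = "-"
            else:
                span = (max(1, pos - read_length + 1), pos)
                mate_left = max(1, pos - 2 * read_length + 1)
                mate = (mate_left, min(mate_left + read_length - 1, genome_length))
                mate_strand = "+"
            for _ in range(count):
                if paired:
                    records.append(
                        AlignmentRecord(ref, span[0], span[1], strand,
                                        is_paired=True, is_read2=True)
                    )
                    # the mate R1 is non-informative and must be filtered out
                    records.append(
                        AlignmentRecord(ref, mate[0], mate[1], mate_strand,
                                        is_paired=True, is_read2=False)
                    )
                else:
                    records.append(
                        AlignmentRecord(ref, span[0], span[1], strand)
                    )
    return tuple(records)


def generate_alignments(
    scenario: FragmentationScenario,
    read_length: int = 50,
    paired: bool = True,
) -> SyntheticAlignments:
    """Alignment records whose informative 5' ends reproduce, exactly, the
    profiles drawn by :func:`generate_profiles` under the same seed.

    In paired mode every fragment emits an R2 (informative, 5' end at the
    site) and an R1 (non-informative, to be removed by the read filter);
    in single mode every record is informative.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    mut_profiles, wt_profiles = generate_profiles(scenario)
    expand = lambda p: _records_for_profile(
        p, scenario.genome_length, read_length, paired
    )
    return SyntheticAlignments(
        mutant=tuple(expand(p) for p in mut_profiles),
        wildtype=tuple(expand(p) for p in wt_profiles),
        mutant_profiles=tuple(mut_profiles),
        wildtype_profiles=tuple(wt_profiles),
    )


# -- decay series ------------------------------------------------------------


@dataclass(frozen=True)
class DecayScenario:
    """Generative parameters for one rifampicin-chase abundance series.

    ``true_half_life`` may be ``math.inf`` to emulate a non-decaying
    transcript (decay rate 0).  ``noise_cv`` is the coefficient of
    variation of multiplicative log-normal noise.
    """

    true_half_life: float = 3.0
    time_points: tuple[float, ...] = (0.0, 1.0, 3.0, 9.0)
    initial_level: float = 1.0
    noise_cv: float = 0.0
    seed: int = 0
    gene: str = "synthetic"

    def __post_init__(self) -> None:
        if self.true_half_life <= 0:
            raise ValueError("true_half_life must be positive (inf allowed)")
        t = self.time_points
        if not t or t[0] != 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("time_points must be strictly ascending from 0")
        if self.initial_level <= 0:
            raise ValueError("initial_level must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def generate_decay_series(scenario: DecayScenario) -> DecaySeries:
    """level(t) = initial * 2^(-t / half_life) * exp(eps_t).

    eps_t is N(0, sigma^2) with sigma = sqrt(ln(1 + cv^2)), the log-normal
    scale whose multiplicative coefficient of variation is ``noise_cv``.
    """
    t = np.asarray(scenario.time_points, dtype=float)
    if math.isinf(scenario.true_half_life):
        clean = np.full(t.shape, scenario.initial_level)
    else:
        clean = scenario.initial_level * 2.0 ** (-t / scenario.true_half_life)
    if scenario.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + scenario.noise_cv**2))
        rng = np.random.default_rng(scenario.seed)
        clean = clean * np.exp(rng.normal(0.0, sigma, size=t.size))
    return DecaySeries(
        gene=scenario.gene,
        time_points=tuple(t.tolist()),
        levels=tuple(clean.tolist()),
        normalization="rpkm",
    )
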