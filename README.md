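# fragexcess

Genome-wide detection of RNA decay-intermediate accumulation from 5′
read-start profiles, with rifampicin-chase mRNA half-life estimation.

## The problem

The bacterial RNA degradosome couples endonucleolytic cleavage (RNase E)
to exonucleolytic destruction of the fragments, assisted by a DEAD-box
RNA helicase that unwinds structured substrates. When the helicase is
missing, cleaved RNAs can linger as *decay intermediates*. Each
intermediate exposes a new 5′ end, and in a stranded RNA-seq library
that 5′ end becomes a new read-start position. Comparing where sequenced
fragments *begin* in a mutant versus its wild type therefore reveals
incomplete RNA processing genome-wide — without any annotation, peak
calling, or differential-expression machinery.

This package is for microbiologists and transcriptomics analysts who
have stranded RNA-seq alignments (or qPCR/Rif-seq decay data) for a
mutant/wild-type pair and want a calibrated, reproducible answer to
"does the mutant accumulate decay intermediates?"

## The statistic

For every genomic position *i* (per strand), let mutantᵢ and wtᵢ be the
number of sequenced fragments whose 5′ end maps there, after all
libraries are equalized to 90 % of the smallest library's unique-read
depth and replicates are merged. The proportion

> *P*ᵢ = mutantᵢ / (mutantᵢ + wtᵢ)

is 1 at mutant-exclusive positions and 0 at wt-exclusive positions.
Library preparation fragments RNA at random, so both extremes occur as
background; decay intermediates add an *excess* of *P* = 1 positions.

Let n₀ = #{*P*ᵢ = 0}, n₁ = #{*P*ᵢ = 1}, and let σ be the sample standard
deviation of the 99 interior histogram bin counts over (0, 1) — the
background noise on the count scale. Modelling the two extreme classes
as equal-prior Gaussians with common σ, the Bayesian Error Rate of the
optimal two-class decision is

> BER = Φ( −|n₁ − n₀| / 2σ ),

and BER < 0.01 declares the excess significant. The companion decay
module fits ln(level) ~ time by ordinary least squares after a
rifampicin chase (half-life = ln 2 / k), flags half-lives outside the
calculable 1–15 min window, and provides RPKM, bulk mRNA-fraction,
Welch-test, Benjamini–Hochberg, and 2^−ΔΔCt utilities.

## Worked example

Plant a known 78 % excess of mutant-only cleavage sites, rebuild the
profiles, and fit the model:

```python
from fragexcess import (
    FragmentationExcess, FragmentationScenario,
    generate_profiles, merge_replicates,
)

scenario = FragmentationScenario.with_planted_excess(
    78.0, genome_length=200_000, n_shared_sites=10_000,
    lambda_shared=0.3, n_replicates_per_strain=3, seed=7,
)
mutant, wt = generate_profiles(scenario)
result = FragmentationExcess(
    merge_replicates(mutant), merge_replicates(wt)
).fit()
print(result.summary())
```

```
Fragmentation excess (mutant vs wild type)
==========================================
positions with coverage            10219
n0  (P = 0, wt-exclusive)           2427
n1  (P = 1, mutant-excl.)           4249
excess of P=1 over P=0             75.1%
background sigma                  186.55
Bayesian Error Rate             5.21e-07
significant (BER < 0.01)           True
```

Read: 2 427 positions were seen only in the wild type (random
fragmentation background) but 4 249 only in the mutant — a 75 % excess,
close to the planted 78 %. That separation is ~18 background standard
deviations wide, so the misclassification probability of calling the two
extreme classes apart is ~5 × 10⁻⁷: the mutant accumulates decay
intermediates. A null scenario (no planted sites) yields an excess near
0 % and BER ≈ 0.5.

The same objects drive the command line:

```sh
fragx simulate --shared-sites 10000 --exclusive-sites 500 --out sim/
fragx fragexcess --mutant sim/mutant_rep1.sam --mutant sim/mutant_rep2.sam \
                 --wt sim/wt_rep1.sam --wt sim/wt_rep2.sam \
                 --fraction 0.9 --seed 1 --out run/
fragx decay --counts wt=wt_counts.tsv --counts mut=mut_counts.tsv --out decay/
```

`fragexcess` writes merged per-strand BEDGraph profiles, the *P*
histogram (TSV), a JSON result record and a manifest that reproduces the
run bit-for-bit; `decay` writes per-gene half-life tables, bulk
half-lives and a Welch/BH comparison table.

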