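"""Contrast chromatin compactness between two simulated genotypes.

Simulates a wild-type genome (decay exponent 1.0) and a mildly
decondensed mutant (exponent 0.7: contact mass shifted to longer range)
on two chromosomes, computes per-bin compactness (sum of balanced cis
contacts within 200 kb of each 10-kb bin), and compares the genotypes
per chromosome with a two-sided Mann-Whitney U test. The mutant should
show a lower compactness median on every chromosome with a tiny p-value;
its mean trans-contact fraction is also reported.
"""

import numpy as np

from nucleoform import (
    HiCSimParams,
    balance_ice,
    compactness_profile,
    compare_genotypes,
    simulate_contact_map,
    trans_contact_profile,
)

GENOME = {"chrA": 2_500_000, "chrB": 2_000_000}


def genotype_profile(alpha: float, seed: int):
    params = HiCSimParams(
        chrom_lengths=GENOME, bin_size=10_000, alpha=alpha,
        territory_strength=0.05, depth=1e6, seed=seed,
    )
    matrix = simulate_contact_map(params)
    balanced = balance_ice(matrix)
    return compactness_profile(balanced, window=200_000), trans_contact_profile(balanced)


wt_compact, wt_trans = genotype_profile(alpha=1.0, seed=0)
mut_compact, mut_trans = genotype_profile(alpha=0.7, seed=1)

comparison = compare_genotypes(wt_compact, mut_compact)
print(comparison.table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print()
print(f"wild-type mean trans fraction: {np.nanmean(wt_trans.fraction):.4f}")
print(f"mutant    mean trans fraction: {np.nanmean(mut_trans.fraction):.4f}")
print()
print("Negative median_diff on every chromosome with p << 0.01 means the")
print("mutant's short-range (<=200 kb) contact share dropped: decondensation.")
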