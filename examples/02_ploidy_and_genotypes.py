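"""Classify clone ploidy and call per-site genotypes on simulated clones.

Each clone's allele-frequency spectrum is compared under a diploid
(peaks 0, 1/2, 1) versus triploid (peaks 0, 1/3, 2/3, 1) binomial
mixture; genotypes are then MAP copy-number calls given the ploidy.
"""

import numpy as np

from lineagetrack import SimConfig, call_all_ploidies, call_genotypes, simulate_truth
from lineagetrack.simulator import sample_clone_set

truth = simulate_truth(SimConfig(seed=7))
clone_vm, clone_map, _ = sample_clone_set(truth)

calls = call_all_ploidies(clone_vm, clone_vm.samples[:6])
print(f"{'clone':>14} {'called':>7} {'true':>5} {'dLogL':>9} {'sites':>6}")
for c in calls:
    true_k = truth.ploidy[clone_map[c.clone]]
    print(f"{c.clone:>14} {c.ploidy:>7} {true_k:>5} {c.delta_loglik:>9.1f} {c.n_sites:>6}")
# dLogL > 0 favors diploid, < 0 triploid; |dLogL| < 10 would be flagged.

geno, excluded = call_genotypes(clone_vm, call_all_ploidies(clone_vm, clone_vm.samples))
g = geno.g_matrix()
print(f"\ngenotyped {len(geno.clones)} clones x {geno.n_sites} sites; "
      f"{np.isnan(g).mean():.1%} missing (depth/posterior gates)")
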