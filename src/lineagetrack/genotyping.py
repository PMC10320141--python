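"""Per-site genotype calling for clonal isolates.

Given a clone's ploidy, each site's alternate-allele copy number
c in {0, ..., ploidy} is inferred from its read counts under a binomial
model with error-adjusted success probability

    p'_c = (c/ploidy)(1 - e) + (1 - c/ploidy) e

and a uniform prior over copy-number states.  The called genotype is the
MAP copy fraction g = c/ploidy; calls below a posterior threshold or a
depth gate are recorded as missing rather than imputed, since downstream
synapomorphy selection budgets explicitly for missingness.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

from .io_formats import VariantMatrix
from .ploidy import PloidyCall

DEFAULT_MIN_DEPTH = 8
DEFAULT_POSTERIOR_THRESHOLD = 0.95
DEFAULT_ERROR_RATE = 0.005

MISSING = -1  # copy-number sentinel


def genotype_posterior(
    x: int, d: int, ploidy: int, error_rate: float = DEFAULT_ERROR_RATE
) -> np.ndarray:
    """Posterior over copy-number states 0..ploidy for one site.

    Uniform prior; returns a vector of length ploidy+1 summing to 1.
    """
    if not 0 <= x <= d:
        raise ValueError(f"require 0 <= x <= d, got x={x}, d={d}")
    if not 0 < error_rate < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    c = np.arange(ploidy + 1)
    g = c / ploidy
    p = g * (1 - error_rate) + (1 - g) * error_rate
    loglik = binom.logpmf(x, d, p)
    return np.exp(loglik - logsumexp(loglik))


@dataclasses.dataclass
class CloneGenotypeMatrix:
    """Clones x sites matrix of called copy numbers plus per-clone ploidy.

    ``copy_number[i, s]`` is the MAP alternate-allele copy number of clone
    i at site s, or MISSING.  The copy *fraction* g = c/ploidy is exposed
    via :meth:`g_matrix` with NaN for missing entries.
    """

    clones: list[str]
    ploidies: dict[str, int]
    copy_number: np.ndarray  # int, (n_clones, n_sites), MISSING for no call
    n_sites: int

    def __post_init__(self) -> None:
        self.copy_number = np.asarray(self.copy_number, dtype=np.int64)
        if self.copy_number.shape != (len(self.clones), self.n_sites):
            raise ValueError("copy_number shape inconsistent with clones x sites")
        for i, clone in enumerate(self.clones):
            k = self.ploidies[clone]
            row = self.copy_number[i]
            if np.any((row != MISSING) & ((row < 0) | (row > k))):
                raise ValueError(f"clone {clone}: copy number outside 0..{k}")

    def clone_index(self, clone: str) -> int:
        try:
            return self.clones.index(clone)
        except ValueError:
            raise KeyError(f"clone {clone!r} not genotyped") from None

    def g_matrix(self) -> np.ndarray:
        """Copy fractions (clones x sites), NaN where missing."""
        k = np.array([self.ploidies[c] for c in self.clones], dtype=float)
        g = self.copy_number / k[:, None]
        g[self.copy_number == MISSING] = np.nan
        return g

    def subset_clones(self, names: list[str]) -> "CloneGenotypeMatrix":
        idx = [self.clone_index(n) for n in names]
        return CloneGenotypeMatrix(
            clones=list(names),
            ploidies={n: self.ploidies[n] for n in names},
            copy_number=self.copy_number[idx, :],
            n_sites=self.n_sites,
        )


def write_genotype_matrix(geno: CloneGenotypeMatrix, path) -> None:
    """TSV: one row per clone (clone, ploidy, then per-site copy numbers
    encoded as integers, "." for missing)."""
    import pandas as pd

    cols = {"clone": geno.clones, "ploidy": [geno.ploidies[c] for c in geno.clones]}
    for s in range(geno.n_sites):
        col = geno.copy_number[:, s]
        cols[f"s{s}"] = ["." if v == MISSING else str(v) for v in col]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_genotype_matrix(path) -> CloneGenotypeMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    clones = list(df["clone"])
    ploidies = {c: int(k) for c, k in zip(clones, df["ploidy"])}
    site_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    site_cols.sort(key=lambda c: int(c[1:]))
    cn = np.full((len(clones), len(site_cols)), MISSING, dtype=np.int64)
    for j, col in enumerate(site_cols):
        vals = df[col]
        ok = vals != "."
        cn[ok.to_numpy(), j] = vals[ok].astype(int).to_numpy()
    return CloneGenotypeMatrix(clones, ploidies, cn, len(site_cols))


def call_genotypes(
    vm: VariantMatrix,
    ploidy_calls: list[PloidyCall],
    min_depth: int = DEFAULT_MIN_DEPTH,
    posterior_threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> tuple[CloneGenotypeMatrix, list[str]]:
    """MAP-call every (clone, site); returns the matrix and a report of
    clones excluded for unknown ploidy.

    Entries are missing when depth < min_depth or the MAP posterior falls
    below posterior_threshold.
    """
    usable = [pc for pc in ploidy_calls if pc.ploidy is not None]
    excluded = [pc.clone for pc in ploidy_calls if pc.ploidy is None]
    clones = [pc.clone for pc in usable]
    ploidies = {pc.clone: pc.ploidy for pc in usable}
    cn = np.full((len(clones), vm.n_sites), MISSING, dtype=np.int64)
    for i, clone in enumerate(clones):
        x, d = vm.column(clone)
        k = ploidies[clone]
        cvals = np.arange(k + 1)
        g = cvals / k
        p = g * (1 - error_rate) + (1 - g) * error_rate
        # vectorize over sites: loglik matrix (states x sites)
        loglik = binom.logpmf(x[None, :], d[None, :], p[:, None])
        post = np.exp(loglik - logsumexp(loglik, axis=0, keepdims=True))
        map_state = np.argmax(post, axis=0)
        map_post = post[map_state, np.arange(vm.n_sites)]
        ok = (d >= min_depth) & (map_post >= posterior_threshold)
        cn[i, ok] = map_state[ok]
    return (
        CloneGenotypeMatrix(clones, ploidies, cn, vm.n_sites),
        excluded,
    )
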