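"""Back-of-envelope population-genetic calculations and clonal diversity
summaries for an industrial fermentation season.

The season arithmetic: a population that grows ~10% per fed-batch cycle
goes through log2(1.1) doublings per cycle, so an 8-month season at 2
cycles/day (30 days/month) gives 480 * log2(1.1) ~ 66 generations.  The
mutation supply over the season is mu * genome * ploidy * N * G, and the
expected per-generation occurrence count of one specific substitution is
(mu/3) * ploidy * N — mu/3 because each site has three possible
alternate bases.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .genotyping import CloneGenotypeMatrix

DAYS_PER_MONTH = 30  # convention used for the season-length conversion
DEFAULT_HAPLOID_GENOME_BP = 1.2e7  # S288c-scale haploid genome; an assumption


@dataclasses.dataclass
class SeasonParams:
    season_months: float = 8.0
    cycles_per_day: float = 2.0  # ~12-h fed-batch cycles
    growth_per_cycle: float = 0.10  # fractional growth per cycle
    population_size: float = 1e17
    mutation_rate: float = 5e-10  # per bp per generation
    genome_bp: float = DEFAULT_HAPLOID_GENOME_BP
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2, 3):
            raise ValueError("ploidy must be 1, 2 or 3")
        for name in (
            "season_months",
            "cycles_per_day",
            "population_size",
            "mutation_rate",
            "genome_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_cycles(self) -> float:
        return self.season_months * DAYS_PER_MONTH * self.cycles_per_day


def generations_from_growth(n_cycles: float, r: float) -> float:
    """Generations (doublings) in n_cycles of fractional growth r each."""
    if r <= -1:
        raise ValueError("growth fraction must exceed -1")
    if n_cycles < 0:
        raise ValueError("n_cycles must be non-negative")
    return n_cycles * math.log2(1.0 + r)


def mutation_supply(
    mu: float, genome_bp: float, ploidy: int, n: float, generations: float
) -> float:
    """Expected total mutations over the season: mu * genome * ploidy * N * G."""
    if min(mu, genome_bp, ploidy, n, generations) < 0:
        raise ValueError("all arguments must be non-negative")
    return mu * genome_bp * ploidy * n * generations


def per_site_substitution_supply(mu: float, ploidy: int, n: float) -> float:
    """Expected occurrences per generation of one *specific* substitution
    at one site: (mu/3) * ploidy * N (three possible alternate bases)."""
    if min(mu, ploidy, n) < 0:
        raise ValueError("all arguments must be non-negative")
    return (mu / 3.0) * ploidy * n


def season_summary(params: SeasonParams) -> dict[str, float]:
    g = generations_from_growth(params.n_cycles, params.growth_per_cycle)
    return {
        "generations": g,
        "mutation_supply": mutation_supply(
            params.mutation_rate,
            params.genome_bp,
            params.ploidy,
            params.population_size,
            g,
        ),
        "per_site_substitution_supply": per_site_substitution_supply(
            params.mutation_rate, params.ploidy, params.population_size
        ),
    }


def diversity_summary(genotypes: CloneGenotypeMatrix) -> dict:
    """Site-frequency summary of a clonal genotype matrix.

    Counts, for every segregating site, the number of clones carrying the
    alternate allele (g > 0); reports singletons (exactly one carrier)
    and fixed sites (all clones carry), as counts and as percentages of
    all segregating sites, plus the full carrier-count histogram.
    """
    g = genotypes.g_matrix()
    if g.size == 0:
        raise ValueError("empty genotype matrix")
    carriers = (np.nan_to_num(g) > 0).sum(axis=0)
    segregating = carriers > 0
    n_seg = int(segregating.sum())
    if n_seg == 0:
        raise ValueError("no segregating sites in genotype matrix")
    counts = carriers[segregating]
    n_clones = len(genotypes.clones)
    hist = {int(k): int(v) for k, v in zip(*np.unique(counts, return_counts=True))}
    n_singletons = hist.get(1, 0)
    n_fixed = hist.get(n_clones, 0)
    return {
        "n_segregating": n_seg,
        "n_singletons": n_singletons,
        "pct_singletons": 100.0 * n_singletons / n_seg,
        "n_fixed": n_fixed,
        "pct_fixed": 100.0 * n_fixed / n_seg,
        "histogram": hist,
    }


def singleton_percentage(n_singletons: int, n_sites: int) -> float:
    """Percentage of sites that are singletons, e.g. from printed counts."""
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    return 100.0 * n_singletons / n_sites


def catalogue_overlap(
    a: set[tuple], b: set[tuple]
) -> dict[str, float]:
    """Overlap between two variant catalogues keyed by (chrom, pos, alt).

    Returns the intersection size and the percentage of each catalogue
    recovered by the other."""
    inter = len(a & b)
    return {
        "intersection": inter,
        "pct_of_a": 100.0 * inter / len(a) if a else 0.0,
        "pct_of_b": 100.0 * inter / len(b) if b else 0.0,
    }
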