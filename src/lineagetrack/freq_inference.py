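"""Joint maximum-likelihood inference of nested lineage frequencies.

At one metagenomic timepoint, each marker m of lineage l contributes a
binomial term for its alternate read count x_lm out of depth d_lm, with
expected allele frequency g_m * F_l, where F_l is the lineage's inclusive
frequency (genome-copy fraction) and g_m the marker's shared copy
fraction.  All lineages are inferred jointly under the nesting
constraints: every F_l is in [0, 1], the summed frequencies of sister
lineages never exceed their parent's, and top-level frequencies sum to at
most 1 — the shortfall is the residual, i.e. population diversity not
represented among sequenced clones.

The feasible set is mapped to the unit box by stick-breaking (each
lineage takes a fraction of what remains of its parent's frequency after
earlier siblings), so plain bounded local optimization applies; a
multi-start strategy guards against local optima.  Timepoints are
inferred independently — no dynamical model links them.

Frequencies are genome-copy (DNA) fractions, which is what reads
measure; :func:`cell_fractions` offers a post-hoc, ploidy-aware
conversion for users who need cell fractions.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.stats import binom

from .io_formats import VariantMatrix
from .lineage_model import LineageModel

DEFAULT_EPSILON = 0.002
DEFAULT_MIN_MARKER_DEPTH = 10
DEFAULT_RESTARTS = 5
CONSTRAINT_TOL = 1e-6


@dataclasses.dataclass
class InferenceConfig:
    epsilon: float = DEFAULT_EPSILON  # floor/ceiling on expected marker frequency
    restarts: int = DEFAULT_RESTARTS
    tol: float = 1e-9  # optimizer convergence tolerance
    min_marker_depth: int = DEFAULT_MIN_MARKER_DEPTH
    seed: int = 0  # for the random restart generator

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")
        if self.restarts < 1:
            raise ValueError("need at least one restart")


@dataclasses.dataclass
class FrequencyEstimate:
    """Inclusive frequencies at one timepoint plus optimizer diagnostics."""

    timepoint: float
    inclusive: dict[str, float]
    children: dict[str, list[str]]  # lineage id -> child ids; "" key = top level
    loglik: float
    converged: bool
    n_restarts: int

    def exclusive(self) -> dict[str, float]:
        """E_l = F_l minus the summed inclusive frequencies of children."""
        out = {}
        for lid, f in self.inclusive.items():
            csum = sum(self.inclusive[c] for c in self.children.get(lid, []))
            e = f - csum
            if e < -CONSTRAINT_TOL:
                raise ValueError(
                    f"lineage {lid}: children frequencies exceed parent by {-e:.2e}"
                )
            out[lid] = max(e, 0.0)
        return out

    def residual(self) -> float:
        top = sum(self.inclusive[c] for c in self.children.get("", []))
        r = 1.0 - top
        if r < -CONSTRAINT_TOL:
            raise ValueError(f"top-level frequencies exceed 1 by {-r:.2e}")
        return max(r, 0.0)


def exclusive_frequencies(estimate: FrequencyEstimate) -> tuple[dict[str, float], float]:
    """Per-lineage exclusive frequencies and the residual; their sum is 1."""
    excl = estimate.exclusive()
    r = estimate.residual()
    total = sum(excl.values()) + r
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"exclusive frequencies + residual sum to {total}, not 1")
    return excl, r


def expected_marker_freq(f_l: float, g_m: float, epsilon: float) -> float:
    """Expected alternate-allele frequency of one marker: g_m * F_l,
    clamped to [epsilon, 1 - epsilon] so boundary frequencies stay
    finite-likelihood."""
    return float(np.clip(g_m * f_l, epsilon, 1.0 - epsilon))


@dataclasses.dataclass
class _MarkerData:
    """Flattened usable markers at one timepoint."""

    lineage_index: np.ndarray  # per marker, index into the lineage order
    g: np.ndarray
    x: np.ndarray
    d: np.ndarray


def _collect_markers(
    model: LineageModel,
    order: list[str],
    x_col: np.ndarray,
    d_col: np.ndarray,
    min_marker_depth: int,
) -> _MarkerData:
    li, gs, xs, ds = [], [], [], []
    pos = {lid: i for i, lid in enumerate(order)}
    for lid in order:
        for site, g in model.lineages[lid].markers:
            if d_col[site] >= min_marker_depth:
                li.append(pos[lid])
                gs.append(g)
                xs.append(x_col[site])
                ds.append(d_col[site])
    return _MarkerData(
        np.array(li, dtype=int),
        np.array(gs, dtype=float),
        np.array(xs, dtype=float),
        np.array(ds, dtype=float),
    )


def _loglik_from_vector(f: np.ndarray, md: _MarkerData, epsilon: float) -> float:
    p = np.clip(md.g * f[md.lineage_index], epsilon, 1.0 - epsilon)
    return float(np.sum(binom.logpmf(md.x, md.d, p)))


def log_likelihood(
    f: dict[str, float],
    model: LineageModel,
    counts: VariantMatrix,
    sample: str,
    config: InferenceConfig | None = None,
) -> float:
    """Binomial log-likelihood of inclusive frequencies ``f`` given one
    metagenomic sample's counts; markers below the depth gate are
    skipped for this sample only."""
    config = config or InferenceConfig()
    x_col, d_col = counts.column(sample)
    order = model.topological_order()
    md = _collect_markers(model, order, x_col, d_col, config.min_marker_depth)
    if len(md.x) == 0:
        raise ValueError(f"no usable markers in sample {sample!r}")
    fvec = np.array([f[lid] for lid in order])
    return _loglik_from_vector(fvec, md, config.epsilon)


# -- stick-breaking map -----------------------------------------------------


def _sticks_to_freqs(u: np.ndarray, order: list[str], model: LineageModel) -> np.ndarray:
    """Map box coordinates u in [0,1]^L to feasible inclusive frequencies.

    Siblings (in sorted id order) successively take a fraction u_l of
    what remains of the parent's frequency; the virtual root has F = 1.
    """
    pos = {lid: i for i, lid in enumerate(order)}
    f = np.empty(len(order))
    remaining: dict[str | None, float] = {None: 1.0}
    for lid in order:  # parents precede children; siblings in sorted order
        parent = model.lineages[lid].parent
        if parent not in remaining:
            remaining[parent] = f[pos[parent]]
        f[pos[lid]] = u[pos[lid]] * remaining[parent]
        remaining[parent] -= f[pos[lid]]
    return f


def _freqs_to_sticks(f: np.ndarray, order: list[str], model: LineageModel) -> np.ndarray:
    pos = {lid: i for i, lid in enumerate(order)}
    u = np.empty(len(order))
    remaining: dict[str | None, float] = {None: 1.0}
    for lid in order:
        parent = model.lineages[lid].parent
        if parent not in remaining:
            remaining[parent] = f[pos[parent]]
        avail = remaining[parent]
        u[pos[lid]] = 0.0 if avail <= 0 else np.clip(f[pos[lid]] / avail, 0.0, 1.0)
        remaining[parent] = max(avail - f[pos[lid]], 0.0)
    return u


def _closed_form_init(
    model: LineageModel, order: list[str], md: _MarkerData
) -> np.ndarray:
    """Pooled per-lineage moment estimates F ~ sum x / sum(d g), clamped
    to feasibility top-down."""
    f0 = np.zeros(len(order))
    for i in range(len(order)):
        sel = md.lineage_index == i
        denom = float(np.sum(md.d[sel] * md.g[sel]))
        f0[i] = float(np.sum(md.x[sel])) / denom if denom > 0 else 0.0
    f0 = np.clip(f0, 0.0, 1.0)
    # enforce nesting: scale each sibling group into its parent's frequency
    pos = {lid: i for i, lid in enumerate(order)}
    for parent in [None] + order:
        kids = (
            model.top_level() if parent is None else model.children_of(parent)
        )
        if not kids:
            continue
        cap = 1.0 if parent is None else f0[pos[parent]]
        total = sum(f0[pos[k]] for k in kids)
        if total > cap and total > 0:
            for k in kids:
                f0[pos[k]] *= cap / total
    return f0


def infer_frequencies_at_t(
    model: LineageModel,
    counts: VariantMatrix,
    sample: str,
    timepoint: float,
    config: InferenceConfig | None = None,
) -> FrequencyEstimate:
    """Maximize the joint marker likelihood at one timepoint.

    Multi-start bounded L-BFGS-B in stick-breaking coordinates: one start
    from pooled closed-form estimates, the rest from random feasible
    points of a seeded generator.  The best restart is returned; if no
    restart converges the estimate is still returned with its
    non-converged flag set.
    """
    config = config or InferenceConfig()
    order = model.topological_order()
    x_col, d_col = counts.column(sample)
    md = _collect_markers(model, order, x_col, d_col, config.min_marker_depth)
    if len(md.x) == 0:
        raise ValueError(f"no usable markers at timepoint {timepoint} ({sample!r})")

    def objective(u: np.ndarray) -> float:
        return -_loglik_from_vector(
            _sticks_to_freqs(u, order, model), md, config.epsilon
        )

    rng = np.random.default_rng(config.seed)
    starts = [_freqs_to_sticks(_closed_form_init(model, order, md), order, model)]
    for _ in range(config.restarts - 1):
        starts.append(rng.uniform(0.0, 1.0, size=len(order)))

    best = None
    any_converged = False
    bounds = [(0.0, 1.0)] * len(order)
    for u0 in starts:
        res = minimize(
            objective, u0, method="L-BFGS-B", bounds=bounds, tol=config.tol
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    f = _sticks_to_freqs(np.clip(best.x, 0.0, 1.0), order, model)
    children = {"": model.top_level()}
    for lid in order:
        children[lid] = model.children_of(lid)
    return FrequencyEstimate(
        timepoint=timepoint,
        inclusive={lid: float(f[i]) for i, lid in enumerate(order)},
        children=children,
        loglik=-float(best.fun),
        converged=any_converged,
        n_restarts=config.restarts,
    )


def infer_trajectories(
    model: LineageModel,
    counts: VariantMatrix,
    timepoint_samples: list[tuple[float, str]],
    config: InferenceConfig | None = None,
    failures: list[tuple[float, str]] | None = None,
) -> list[FrequencyEstimate]:
    """One independent estimate per timepoint, ordered by time.

    Per-timepoint failures (e.g. no usable markers) are appended to
    ``failures`` and do not affect other timepoints.
    """
    if not timepoint_samples:
        raise ValueError("need at least one timepoint")
    estimates = []
    for t, sample in sorted(timepoint_samples):
        try:
            estimates.append(
                infer_frequencies_at_t(model, counts, sample, t, config)
            )
        except ValueError as exc:
            if failures is None:
                raise
            failures.append((t, str(exc)))
    return estimates


def cell_fractions(
    estimate: FrequencyEstimate,
    lineage_ploidy: dict[str, int],
    residual_ploidy: float = 2.0,
) -> tuple[dict[str, float], float]:
    """Post-hoc conversion of exclusive genome-copy fractions to cell
    fractions: divide each by its lineage's ploidy (the residual by an
    assumed ploidy) and renormalize.  Not applied by default — reads
    measure DNA, and inferred frequencies stay on that scale."""
    excl, r = exclusive_frequencies(estimate)
    w = {lid: e / lineage_ploidy[lid] for lid, e in excl.items()}
    wr = r / residual_ploidy
    total = sum(w.values()) + wr
    if total == 0:
        return {lid: 0.0 for lid in excl}, 0.0
    return {lid: v / total for lid, v in w.items()}, wr / total


def grid_search_max_loglik(
    model: LineageModel,
    counts: VariantMatrix,
    sample: str,
    step: float = 0.005,
    config: InferenceConfig | None = None,
) -> tuple[float, dict[str, float]]:
    """Exhaustive grid search over feasible frequency vectors (validation
    utility for small models, <= ~3 lineages).

    Exploits the separability of the log-likelihood: per-lineage profiles
    are precomputed on the grid, then summed over all grid combinations,
    keeping only those satisfying the nesting constraints.
    """
    config = config or InferenceConfig()
    order = model.topological_order()
    if len(order) > 4:
        raise ValueError("grid search is only meant for small models")
    x_col, d_col = counts.column(sample)
    md = _collect_markers(model, order, x_col, d_col, config.min_marker_depth)
    grid = np.arange(0.0, 1.0 + step / 2, step)
    profiles = []
    for i in range(len(order)):
        sel = md.lineage_index == i
        p = np.clip(np.outer(grid, md.g[sel]), config.epsilon, 1 - config.epsilon)
        profiles.append(binom.logpmf(md.x[sel], md.d[sel], p).sum(axis=1))
    total = np.zeros([len(grid)] * len(order))
    for i, prof in enumerate(profiles):
        shape = [1] * len(order)
        shape[i] = len(grid)
        total = total + prof.reshape(shape)
    # feasibility mask from nesting constraints
    mesh = np.meshgrid(*([grid] * len(order)), indexing="ij")
    feasible = np.ones(total.shape, dtype=bool)
    pos = {lid: i for i, lid in enumerate(order)}
    for parent in [None] + order:
        kids = model.top_level() if parent is None else model.children_of(parent)
        if not kids:
            continue
        cap = 1.0 if parent is None else mesh[pos[parent]]
        ksum = sum(mesh[pos[k]] for k in kids)
        feasible &= ksum <= cap + 1e-12
    total = np.where(feasible, total, -np.inf)
    flat = int(np.argmax(total))
    idx = np.unravel_index(flat, total.shape)
    best_f = {lid: float(grid[idx[pos[lid]]]) for lid in order}
    return float(total[idx]), best_f
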