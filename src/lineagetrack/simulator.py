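"""Synthetic fermentation seasons with known lineage structure.

Generates a nested lineage tree (starter lineages plus optional
invaders), per-lineage ploidy (2n or 3n, constant within each top-level
subtree so every clade's marker copy fraction is well defined), planted
synapomorphic markers, exclusive-frequency trajectories under
discrete-time logistic competition (F' proportional to F exp(s),
renormalized each step, with the residual acting as a neutral
competitor), and finally clone and metagenome sequencing samples with
binomial read sampling and a small per-read error rate.

Defaults mirror the study system this package targets: an ~8-month
season observed at 15 timepoints, metagenomes at ~90x mean depth and
clonal isolates at ~25x, a few thousand segregating sites.

Per-site random streams are keyed by (seed, timepoint, site id), so two
scenarios sharing a site draw identical counts wherever the expected
frequency coincides — which makes paired with/without-a-lineage
comparisons free of sampling-noise differences.
"""

from __future__ import annotations

import dataclasses

import dendropy
import numpy as np

from .io_formats import SampleSheet, VariantMatrix, VariantSite
from .lineage_model import LineageModel

_CHROMS = [f"chr{i}" for i in range(1, 17)]


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class SimConfig:
    n_lineages: int = 8
    n_top: int = 3  # top-level lineages (starters + invaders)
    n_invaders: int = 1  # top-level lineages entering mid-season
    p_triploid: float = 0.4
    markers_per_lineage: int = 20
    background_sites: int = 500
    bg_carrier_prob: float = 0.15
    n_timepoints: int = 15
    season_days: float = 210.0
    fitness_sd: float = 0.2  # per-step log-fitness spread
    invasion_time_frac: float = 0.4  # fraction of season before invaders enter
    invasion_freq: float = 0.02
    initial_residual: float = 0.1  # diversity never represented by lineages
    clones_per_timepoint: int = 3
    clone_depth: float = 25.0
    metagenome_depth: float = 90.0
    error_rate: float = 0.005
    wright_fisher_n: int | None = None  # optional multinomial jitter, off by default
    fitness: list[float] | None = None  # explicit per-lineage log-fitness override
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_top > self.n_lineages:
            raise ConfigError("n_top cannot exceed n_lineages")
        if self.n_invaders >= self.n_top:
            raise ConfigError("need at least one non-invading top-level lineage")
        if self.n_invaders * self.invasion_freq >= 1:
            raise ConfigError("invader initial frequencies sum to >= 1")
        if not 0 <= self.initial_residual < 1:
            raise ConfigError("initial_residual must be in [0, 1)")
        if self.metagenome_depth < 1 or self.clone_depth < 1:
            raise ConfigError("depths must be >= 1")


@dataclasses.dataclass
class SimTruth:
    """Ground truth of one simulated season."""

    config: SimConfig
    lineage_ids: list[str]
    parents: dict[str, str | None]
    ploidy: dict[str, int]
    fitness: dict[str, float]
    markers: dict[str, list[tuple[int, float]]]  # lineage -> (site id, g_m)
    background: dict[int, dict[str, float]]  # site id -> lineage -> g
    sites: list[VariantSite]
    timepoints: np.ndarray  # days
    exclusive_traj: np.ndarray  # (n_timepoints, n_lineages)

    def lineage_index(self, lid: str) -> int:
        return self.lineage_ids.index(lid)

    def children_of(self, lid: str | None) -> list[str]:
        return sorted(k for k, v in self.parents.items() if v == lid)

    def top_ancestor(self, lid: str) -> str:
        cur = lid
        while self.parents[cur] is not None:
            cur = self.parents[cur]
        return cur

    def subtree(self, lid: str) -> list[str]:
        out, stack = [], [lid]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(self.children_of(cur))
        return sorted(out)

    def inclusive_traj(self) -> np.ndarray:
        """Inclusive frequencies (timepoints x lineages): exclusive mass
        summed over each lineage's subtree."""
        incl = np.zeros_like(self.exclusive_traj)
        for j, lid in enumerate(self.lineage_ids):
            idx = [self.lineage_index(k) for k in self.subtree(lid)]
            incl[:, j] = self.exclusive_traj[:, idx].sum(axis=1)
        return incl

    def residual_traj(self) -> np.ndarray:
        top = [self.lineage_index(k) for k in self.children_of(None)]
        incl = self.inclusive_traj()
        return 1.0 - incl[:, top].sum(axis=1)

    def marker_site_to_lineage(self) -> dict[int, str]:
        return {s: lid for lid, ms in self.markers.items() for s, _ in ms}

    def lineage_tree_newick(self) -> str:
        def render(lid: str) -> str:
            kids = self.children_of(lid)
            if not kids:
                return lid
            return "(" + ",".join(render(k) for k in kids) + ")" + lid

        tops = self.children_of(None)
        return "(" + ",".join(render(t) for t in tops) + ")root;"


def _valid_fractions(ploidy: int) -> list[float]:
    return [c / ploidy for c in range(1, ploidy + 1)]


def simulate_truth(config: SimConfig) -> SimTruth:
    """Build tree, ploidies, markers, background sites and trajectories."""
    rng = np.random.default_rng([config.seed, 101])
    ids = [f"T{i}" for i in range(config.n_lineages)]
    parents: dict[str, str | None] = {}
    invaders = set(ids[config.n_top - config.n_invaders : config.n_top])
    for i, lid in enumerate(ids):
        if i < config.n_top:
            parents[lid] = None
        else:
            # attach below a random non-invader lineage so invading
            # subtrees stay leaves and enter as a unit
            host = rng.choice([l for l in ids[:i] if l not in invaders])
            parents[lid] = str(host)

    truth = SimTruth(
        config=config,
        lineage_ids=ids,
        parents=parents,
        ploidy={},
        fitness={},
        markers={},
        background={},
        sites=[],
        timepoints=np.linspace(0.0, config.season_days, config.n_timepoints),
        exclusive_traj=np.zeros((config.n_timepoints, config.n_lineages)),
    )
    # ploidy per top-level subtree
    for top in truth.children_of(None):
        k = 3 if rng.random() < config.p_triploid else 2
        for lid in truth.subtree(top):
            truth.ploidy[lid] = k
    if config.fitness is not None:
        if len(config.fitness) != config.n_lineages:
            raise ConfigError("fitness override length must equal n_lineages")
        for lid, s in zip(ids, config.fitness):
            truth.fitness[lid] = float(s)
    else:
        for lid in ids:
            truth.fitness[lid] = float(rng.normal(0.0, config.fitness_sd))

    # plant markers, then background sites
    site_id = 0
    for lid in ids:
        fracs = _valid_fractions(truth.ploidy[lid])
        ms = []
        for _ in range(config.markers_per_lineage):
            g = float(rng.choice(fracs))
            ms.append((site_id, g))
            site_id += 1
        truth.markers[lid] = ms
    for _ in range(config.background_sites):
        carriers = {}
        for lid in ids:
            if rng.random() < config.bg_carrier_prob:
                carriers[lid] = float(rng.choice(_valid_fractions(truth.ploidy[lid])))
        truth.background[site_id] = carriers
        site_id += 1
    bases = ["A", "C", "G", "T"]
    for s in range(site_id):
        ref = bases[s % 4]
        alt = bases[(s + 1) % 4]
        truth.sites.append(VariantSite(_CHROMS[s % 16], s // 16 + 1, ref, alt))

    # trajectories: exclusive masses compete logistically; the residual is
    # a neutral competitor holding unrepresented diversity
    e = np.zeros(config.n_lineages)
    is_invading = np.array([truth.top_ancestor(l) in invaders for l in ids])
    init = rng.dirichlet(np.ones(int((~is_invading).sum())))
    e[~is_invading] = init * (1.0 - config.initial_residual)
    resid = config.initial_residual
    s_vec = np.array([truth.fitness[l] for l in ids])
    inv_step = int(np.floor(config.invasion_time_frac * (config.n_timepoints - 1)))
    for t in range(config.n_timepoints):
        if t == inv_step and invaders:
            entering = [truth.lineage_index(l) for l in sorted(invaders)]
            f0 = config.invasion_freq
            scale = 1.0 - f0 * len(entering)
            e *= scale
            resid *= scale
            for j in entering:
                e[j] = f0
        truth.exclusive_traj[t] = e
        # step forward
        w = e * np.exp(s_vec)
        wr = resid  # residual has fitness 0
        total = w.sum() + wr
        e = w / total
        resid = wr / total
        if config.wright_fisher_n:
            rng_wf = np.random.default_rng([config.seed, 77, t])
            probs = np.append(e, resid)
            counts = rng_wf.multinomial(config.wright_fisher_n, probs)
            e = counts[:-1] / config.wright_fisher_n
            resid = counts[-1] / config.wright_fisher_n
    return truth


def _clone_copy_fractions(truth: SimTruth, lineage: str) -> np.ndarray:
    """True per-site copy fraction of a clone of the given lineage: the
    markers of the lineage and all its ancestors, plus the lineage's
    background carriage."""
    g = np.zeros(len(truth.sites))
    cur: str | None = lineage
    while cur is not None:
        for s, gm in truth.markers[cur]:
            g[s] = gm
        cur = truth.parents[cur]
    for s, carriers in truth.background.items():
        if lineage in carriers:
            g[s] = carriers[lineage]
    return g


def _expected_meta_freq(truth: SimTruth, t_index: int) -> np.ndarray:
    """Population expected alternate-allele frequency per site."""
    p = np.zeros(len(truth.sites))
    incl = truth.inclusive_traj()[t_index]
    for lid, ms in truth.markers.items():
        f = incl[truth.lineage_index(lid)]
        for s, gm in ms:
            p[s] = gm * f
    excl = truth.exclusive_traj[t_index]
    for s, carriers in truth.background.items():
        p[s] = sum(g * excl[truth.lineage_index(l)] for l, g in carriers.items())
    return p


def sample_metagenome(
    truth: SimTruth,
    t_index: int,
    depth: float | None = None,
    error_rate: float | None = None,
    seed: int | None = None,
    sample_name: str | None = None,
) -> VariantMatrix:
    """One metagenomic sample: per site, depth ~ Poisson(mean depth) and
    x ~ Binomial(d, p) with p the error-mixed expected frequency."""
    cfg = truth.config
    depth = cfg.metagenome_depth if depth is None else depth
    error_rate = cfg.error_rate if error_rate is None else error_rate
    seed = cfg.seed if seed is None else seed
    if not 0 <= t_index < cfg.n_timepoints:
        raise IndexError(f"timepoint index {t_index} out of range")
    p0 = _expected_meta_freq(truth, t_index)
    p = p0 * (1 - error_rate) + (1 - p0) * error_rate
    n = len(truth.sites)
    x = np.zeros(n, dtype=np.int64)
    d = np.zeros(n, dtype=np.int64)
    for s in range(n):
        rng = np.random.default_rng([seed, 11, t_index, s])
        d[s] = rng.poisson(depth)
        x[s] = rng.binomial(d[s], p[s]) if d[s] > 0 else 0
    name = sample_name or f"meta_t{t_index}"
    return VariantMatrix(list(truth.sites), [name], x[:, None], d[:, None])


def sample_metagenome_series(
    truth: SimTruth,
    depth: float | None = None,
    error_rate: float | None = None,
    seed: int | None = None,
) -> tuple[VariantMatrix, list[tuple[float, str]]]:
    """All timepoints as one VariantMatrix plus (timepoint, sample) pairs."""
    cols = [
        sample_metagenome(truth, t, depth, error_rate, seed)
        for t in range(truth.config.n_timepoints)
    ]
    vm = VariantMatrix(
        list(truth.sites),
        [c.samples[0] for c in cols],
        np.hstack([c.alt_counts for c in cols]),
        np.hstack([c.depths for c in cols]),
    )
    pairs = [
        (float(truth.timepoints[t]), cols[t].samples[0])
        for t in range(truth.config.n_timepoints)
    ]
    return vm, pairs


class SamplingError(RuntimeError):
    pass


def sample_clones(
    truth: SimTruth,
    t_index: int,
    n_clones: int,
    clone_depth: float | None = None,
    error_rate: float | None = None,
    seed: int | None = None,
    name_prefix: str | None = None,
) -> tuple[VariantMatrix, dict[str, str]]:
    """Pick clones at one timepoint, lineage drawn proportionally to
    exclusive frequency (mass in the residual is unsampleable and
    redrawn), and sequence each at ~clone_depth with binomial noise.

    Returns the clone variant matrix and the clone -> lineage map."""
    cfg = truth.config
    clone_depth = cfg.clone_depth if clone_depth is None else clone_depth
    error_rate = cfg.error_rate if error_rate is None else error_rate
    seed = cfg.seed if seed is None else seed
    excl = truth.exclusive_traj[t_index]
    if excl.sum() <= 0:
        raise SamplingError(f"all population mass is residual at timepoint {t_index}")
    probs = excl / excl.sum()  # conditional on landing outside the residual
    n_sites = len(truth.sites)
    xs = np.zeros((n_sites, n_clones), dtype=np.int64)
    ds = np.zeros((n_sites, n_clones), dtype=np.int64)
    names, clone_map = [], {}
    prefix = name_prefix or f"clone_t{t_index}"
    for c in range(n_clones):
        rng = np.random.default_rng([seed, 23, t_index, c])
        lid = truth.lineage_ids[rng.choice(len(probs), p=probs)]
        name = f"{prefix}_{c}"
        names.append(name)
        clone_map[name] = lid
        g = _clone_copy_fractions(truth, lid)
        p = g * (1 - error_rate) + (1 - g) * error_rate
        d = rng.poisson(clone_depth, size=n_sites)
        xs[:, c] = rng.binomial(d, p)
        ds[:, c] = d
    vm = VariantMatrix(list(truth.sites), names, xs, ds)
    return vm, clone_map


def sample_clone_set(
    truth: SimTruth,
    clones_per_timepoint: int | None = None,
    seed: int | None = None,
) -> tuple[VariantMatrix, dict[str, str], dict[str, float]]:
    """Clones across all timepoints per the configured sampling plan.

    Returns (variant matrix, clone -> lineage, clone -> timepoint days)."""
    cfg = truth.config
    k = cfg.clones_per_timepoint if clones_per_timepoint is None else clones_per_timepoint
    mats, maps, times = [], {}, {}
    for t in range(cfg.n_timepoints):
        vm, cmap = sample_clones(truth, t, k, seed=seed)
        mats.append(vm)
        maps.update(cmap)
        for name in vm.samples:
            times[name] = float(truth.timepoints[t])
    vm = VariantMatrix(
        list(truth.sites),
        [s for m in mats for s in m.samples],
        np.hstack([m.alt_counts for m in mats]),
        np.hstack([m.depths for m in mats]),
    )
    return vm, maps, times


def clone_tree(truth: SimTruth, clone_map: dict[str, str]) -> dendropy.Tree:
    """The clonal phylogeny implied by the lineage tree: each clone is a
    tip under its lineage's node; lineage nodes without sampled clones in
    their subtree are pruned."""

    def render(lid: str) -> str | None:
        parts = [r for k in truth.children_of(lid) if (r := render(k))]
        parts += [c for c, l in sorted(clone_map.items()) if l == lid]
        if not parts:
            return None
        if len(parts) == 1:
            return parts[0]
        return "(" + ",".join(parts) + ")"

    tops = [r for t in truth.children_of(None) if (r := render(t))]
    newick = "(" + ",".join(tops) + ");"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def sample_sheet(
    clone_times: dict[str, float],
    meta_pairs: list[tuple[float, str]],
    site_year: str = "sim_2018",
) -> SampleSheet:
    import pandas as pd

    rows = [
        {"sample": s, "role": "metagenome", "site_year": site_year, "timepoint_days": t}
        for t, s in meta_pairs
    ] + [
        {"sample": c, "role": "clone", "site_year": site_year, "timepoint_days": t}
        for c, t in sorted(clone_times.items())
    ]
    return SampleSheet(pd.DataFrame(rows))


def truth_lineage_model(truth: SimTruth) -> LineageModel:
    """The exact lineage model implied by the simulator truth: one
    lineage per simulated lineage, markers as planted, one exemplar
    pseudo-clone per lineage.  Lets inference be exercised independently
    of clone sampling and model building."""
    from .genotyping import CloneGenotypeMatrix
    from .lineage_model import Lineage

    exemplars = {lid: f"ex_{lid}" for lid in truth.lineage_ids}
    n_sites = len(truth.sites)
    cn = np.zeros((len(truth.lineage_ids), n_sites), dtype=np.int64)
    for i, lid in enumerate(truth.lineage_ids):
        g = _clone_copy_fractions(truth, lid)
        cn[i] = np.rint(g * truth.ploidy[lid]).astype(np.int64)
    geno = CloneGenotypeMatrix(
        clones=[exemplars[l] for l in truth.lineage_ids],
        ploidies={exemplars[l]: truth.ploidy[l] for l in truth.lineage_ids},
        copy_number=cn,
        n_sites=n_sites,
    )
    lineages = {}
    for lid in truth.lineage_ids:
        members = frozenset(exemplars[k] for k in truth.subtree(lid))
        depth = 0
        cur = truth.parents[lid]
        while cur is not None:
            depth += 1
            cur = truth.parents[cur]
        lineages[lid] = Lineage(
            id=lid,
            parent=truth.parents[lid],
            members=members,
            markers=sorted(truth.markers[lid]),
            depth=depth,
            singleton=len(members) == 1,
        )
    return LineageModel(
        lineages=lineages, genotypes=geno, discarded=[], unassigned_sites=[]
    )


def add_unmodeled_lineage(
    truth: SimTruth,
    n_markers: int = 20,
    max_freq: float = 0.5,
    seed: int = 0,
) -> SimTruth:
    """A paired scenario with one extra top-level lineage whose private
    markers exist only in the metagenome (never sampled as clones).

    The extra lineage's mass is carved out of the residual, so every
    original lineage keeps its exact trajectory; its new marker sites are
    appended after all existing sites, so shared sites keep their ids and
    (with the per-site random streams) their sampled counts."""
    import copy

    rng = np.random.default_rng([seed, 55])
    resid = truth.residual_traj()
    extra_freq = np.minimum(max_freq, 0.8 * resid)
    if np.all(extra_freq <= 0):
        raise ConfigError("no residual mass available for an extra lineage")
    t2 = copy.deepcopy(truth)
    xid = "X_unmodeled"
    t2.lineage_ids = list(truth.lineage_ids) + [xid]
    t2.parents = dict(truth.parents)
    t2.parents[xid] = None
    t2.ploidy = dict(truth.ploidy)
    t2.ploidy[xid] = 2
    t2.fitness = dict(truth.fitness)
    t2.fitness[xid] = 0.0
    site_id = len(truth.sites)
    bases = ["A", "C", "G", "T"]
    ms = []
    t2.sites = list(truth.sites)
    for _ in range(n_markers):
        g = float(rng.choice([0.5, 1.0]))
        ms.append((site_id, g))
        t2.sites.append(
            VariantSite(
                _CHROMS[site_id % 16], site_id // 16 + 1, bases[site_id % 4],
                bases[(site_id + 1) % 4],
            )
        )
        site_id += 1
    t2.markers = dict(truth.markers)
    t2.markers[xid] = ms
    t2.exclusive_traj = np.hstack(
        [truth.exclusive_traj, extra_freq[:, None]]
    )
    return t2


def true_ploidy_calls(truth: SimTruth, clone_map: dict[str, str]):
    """Ploidy calls taken from simulator truth (bypassing the classifier),
    for scenarios too small to carry enough heterozygous sites."""
    from .ploidy import PloidyCall

    return [
        PloidyCall(
            clone=c,
            ploidy=truth.ploidy[lid],
            delta_loglik=0.0,
            n_sites=0,
            low_confidence=False,
        )
        for c, lid in sorted(clone_map.items())
    ]


# ---------------------------------------------------------------------------
# model/truth matching and the rarefaction harness


def match_lineages(model: LineageModel, truth: SimTruth) -> dict[str, str]:
    """Map model lineages to truth lineages by majority vote over their
    marker sites' true planting; lineages whose markers are mostly
    background noise stay unmatched."""
    site_owner = truth.marker_site_to_lineage()
    out = {}
    for lid, lin in model.lineages.items():
        votes: dict[str, int] = {}
        for s, _ in lin.markers:
            owner = site_owner.get(s)
            if owner is not None:
                votes[owner] = votes.get(owner, 0) + 1
        if votes:
            winner, n = max(votes.items(), key=lambda kv: kv[1])
            # background sites exclusive to one lineage are genuine markers
            # but carry no planted label; they abstain rather than dilute
            if n > sum(votes.values()) / 2:
                out[lid] = winner
    return out


def recovery_rmse(
    estimates: list,
    model: LineageModel,
    truth: SimTruth,
) -> float:
    """RMSE between inferred and true inclusive frequencies over all
    matched lineage-timepoints."""
    matched = match_lineages(model, truth)
    if not matched:
        return float("nan")
    incl = truth.inclusive_traj()
    t_lookup = {float(t): i for i, t in enumerate(truth.timepoints)}
    sq, n = 0.0, 0
    for est in estimates:
        ti = t_lookup[float(est.timepoint)]
        for mid, tid in matched.items():
            err = est.inclusive[mid] - incl[ti, truth.lineage_index(tid)]
            sq += err * err
            n += 1
    return float(np.sqrt(sq / n)) if n else float("nan")


def rarefaction_experiment(
    truth: SimTruth,
    clone_vm: VariantMatrix,
    clone_map: dict[str, str],
    meta_vm: VariantMatrix,
    meta_pairs: list[tuple[float, str]],
    subsample_sizes: list[int],
    seeds: list[int],
    min_markers: int = 5,
    inference_config=None,
):
    """Rebuild the lineage model from clone subsets and re-infer.

    For each (subsample size, seed): draw that many clones without
    replacement, run ploidy -> genotypes -> lineage model -> inference,
    and record RMSE against truth restricted to lineages still
    identifiable.  Subsamples too small to build any model are recorded
    as NaN, not raised.  Returns a tidy DataFrame (size, seed, n_lineages,
    rmse)."""
    import pandas as pd

    from .freq_inference import infer_trajectories
    from .genotyping import call_genotypes
    from .lineage_model import ModelError, build_lineage_model
    from .ploidy import call_all_ploidies

    rows = []
    all_clones = list(clone_vm.samples)
    for size in subsample_sizes:
        for seed in seeds:
            rng = np.random.default_rng([seed, 31, size])
            chosen = sorted(
                rng.choice(all_clones, size=min(size, len(all_clones)), replace=False)
            )
            sub_vm = clone_vm.take_samples(chosen)
            calls = call_all_ploidies(sub_vm, chosen)
            geno, _ = call_genotypes(sub_vm, calls)
            tree = clone_tree(truth, {c: clone_map[c] for c in geno.clones})
            try:
                model = build_lineage_model(tree, geno, min_markers=min_markers)
            except ModelError:
                rows.append(
                    {"size": size, "seed": seed, "n_lineages": 0, "rmse": float("nan")}
                )
                continue
            failures: list = []
            ests = infer_trajectories(
                model, meta_vm, meta_pairs, inference_config, failures=failures
            )
            rows.append(
                {
                    "size": size,
                    "seed": seed,
                    "n_lineages": len(model.lineages),
                    "rmse": recovery_rmse(ests, model, truth),
                }
            )
    return pd.DataFrame(rows)
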