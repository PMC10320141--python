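"""Lineage (clade) enumeration and synapomorphic-marker selection.

Asexual lineages nest into the clades of the clonal phylogeny.  A site is
a synapomorphic marker of a clade when every scored clade member carries
the alternate allele at one identical copy fraction g_m > 0 and every
scored clone outside the clade carries g = 0, with the fraction of
missing calls bounded on both sides.  Markers are polarized on the
alternate allele only: sites whose defining state would be the reference
allele are simply not usable as markers, which costs marker density but
never correctness.

A site whose carrier set matches no clade (homoplasy, past recombination,
mutation reversal) is left unassigned and reported, never fatal.
"""

from __future__ import annotations

import dataclasses

import dendropy
import numpy as np

from .genotyping import CloneGenotypeMatrix

DEFAULT_MIN_MARKERS = 10
DEFAULT_MAX_MISSING_FRAC = 0.2


class ModelError(ValueError):
    """No trackable lineages could be built."""


@dataclasses.dataclass
class Lineage:
    """A clade of the clonal tree with its synapomorphic marker set."""

    id: str
    parent: str | None  # None for top-level lineages
    members: frozenset[str]
    markers: list[tuple[int, float]]  # (site index, shared copy fraction g_m)
    depth: int  # root-distance in the lineage hierarchy
    singleton: bool = False
    mixed_ploidy: bool = False

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclasses.dataclass
class LineageModel:
    """Rooted hierarchy of lineages sharing one genotype matrix.

    Marker sets are disjoint across lineages; child member sets are
    subsets of their parent's.  ``discarded`` records clades that failed
    the marker rules, with reasons; ``unassigned_sites`` are sites whose
    carrier pattern defines no clade.
    """

    lineages: dict[str, Lineage]
    genotypes: CloneGenotypeMatrix
    discarded: list[tuple[frozenset[str], str]]
    unassigned_sites: list[int]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for lin in self.lineages.values():
            sites = {s for s, _ in lin.markers}
            if sites & seen:
                raise ValueError("marker sets must be disjoint across lineages")
            seen |= sites
            if lin.parent is not None:
                parent = self.lineages[lin.parent]
                if not lin.members < parent.members:
                    raise ValueError(
                        f"lineage {lin.id} members not a proper subset of parent"
                    )

    def children_of(self, lid: str | None) -> list[str]:
        return sorted(l.id for l in self.lineages.values() if l.parent == lid)

    def top_level(self) -> list[str]:
        return self.children_of(None)

    def topological_order(self) -> list[str]:
        """Parents before children, deterministic order."""
        order: list[str] = []
        stack = self.top_level()[::-1]
        while stack:
            lid = stack.pop()
            order.append(lid)
            stack.extend(self.children_of(lid)[::-1])
        return order


def enumerate_clades(tree: dendropy.Tree) -> list[frozenset[str]]:
    """All clades of a rooted tree: one per internal node plus one
    singleton per tip; the root clade is the full tip set.  Ordered by
    decreasing size, ties broken lexicographically."""
    clades = []
    for node in tree.preorder_node_iter():
        tips = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        clades.append(tips)
    uniq = sorted(set(clades), key=lambda c: (-len(c), sorted(c)))
    return uniq


def _site_carrier_pattern(
    g_col: np.ndarray, clones: list[str]
) -> tuple[frozenset[str], float | None, bool]:
    """(carriers, shared g if constant else None, any_missing)."""
    missing = np.isnan(g_col)
    carriers = frozenset(
        c for c, g, m in zip(clones, g_col, missing) if not m and g > 0
    )
    carrier_gs = {round(float(g), 9) for g, m in zip(g_col, missing) if not m and g > 0}
    shared = carrier_gs.pop() if len(carrier_gs) == 1 else None
    return carriers, shared, bool(missing.any())


def find_synapomorphies(
    clade: frozenset[str],
    genotypes: CloneGenotypeMatrix,
    max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC,
    min_markers: int = DEFAULT_MIN_MARKERS,
) -> tuple[list[tuple[int, float]], str | None]:
    """Marker set of one clade, or (partial set, rejection reason).

    A site qualifies iff (i) all non-missing members share one identical
    g > 0, (ii) all non-missing non-members have g = 0, and (iii) the
    missing fraction among members and among non-members are each at most
    max_missing_frac.  Returns (markers, None) on success or
    (markers, reason) when fewer than min_markers qualify.
    """
    unknown = clade - set(genotypes.clones)
    if unknown:
        raise ValueError(f"clade members not in genotype matrix: {sorted(unknown)}")
    g = genotypes.g_matrix()
    member_idx = np.array(
        [i for i, c in enumerate(genotypes.clones) if c in clade], dtype=int
    )
    other_idx = np.array(
        [i for i, c in enumerate(genotypes.clones) if c not in clade], dtype=int
    )
    gm = g[member_idx, :]  # members x sites
    go = g[other_idx, :] if len(other_idx) else np.zeros((0, g.shape[1]))

    m_missing = np.isnan(gm)
    o_missing = np.isnan(go)
    m_missing_frac = m_missing.mean(axis=0)
    o_missing_frac = o_missing.mean(axis=0) if len(other_idx) else np.zeros(g.shape[1])

    gm_f = np.where(m_missing, np.nan, gm)
    with np.errstate(invalid="ignore"):
        m_min = np.nanmin(np.where(m_missing, np.inf, gm_f), axis=0)
        m_max = np.nanmax(np.where(m_missing, -np.inf, gm_f), axis=0)
        all_members_scored_zero = np.all(m_missing, axis=0)
        members_constant_pos = (
            ~all_members_scored_zero
            & np.isclose(m_min, m_max, atol=1e-9)
            & (m_min > 0)
        )
        others_all_zero = (
            np.all(o_missing | np.isclose(go, 0.0, atol=1e-9), axis=0)
            if len(other_idx)
            else np.ones(g.shape[1], dtype=bool)
        )
    ok = (
        members_constant_pos
        & others_all_zero
        & (m_missing_frac <= max_missing_frac)
        & (o_missing_frac <= max_missing_frac)
    )
    markers = [(int(s), float(m_min[s])) for s in np.flatnonzero(ok)]
    if len(markers) < min_markers:
        return markers, f"only {len(markers)} markers (< {min_markers})"
    return markers, None


def build_lineage_model(
    tree: dendropy.Tree,
    genotypes: CloneGenotypeMatrix,
    max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC,
    min_markers: int = DEFAULT_MIN_MARKERS,
) -> LineageModel:
    """Select the clades with enough synapomorphic markers.

    Each qualifying site is assigned to the single (most specific) clade
    it defines; clades below min_markers are recorded as discarded;
    single-clone lineages are kept but flagged.
    """
    tips = set(
        leaf.taxon.label for leaf in tree.leaf_node_iter()
    )
    extra = tips - set(genotypes.clones)
    if extra:
        raise ValueError(f"tree tips missing from genotype matrix: {sorted(extra)}")
    scored = genotypes.subset_clones([c for c in genotypes.clones if c in tips])
    clades = enumerate_clades(tree)

    # Candidate markers per clade; a site's carrier set determines the one
    # clade it can define, so assign each site to the smallest qualifying
    # clade and drop it from larger ones.
    per_clade: dict[frozenset[str], list[tuple[int, float]]] = {}
    for clade in clades:
        markers, _ = find_synapomorphies(
            clade, scored, max_missing_frac=max_missing_frac, min_markers=0
        )
        per_clade[clade] = markers

    assigned: dict[int, frozenset[str]] = {}
    for clade in sorted(per_clade, key=len):  # smallest first = most specific
        for site, _ in per_clade[clade]:
            assigned.setdefault(site, clade)
    for clade in per_clade:
        per_clade[clade] = [(s, g) for s, g in per_clade[clade] if assigned[s] == clade]

    kept: dict[frozenset[str], list[tuple[int, float]]] = {}
    discarded: list[tuple[frozenset[str], str]] = []
    for clade in clades:
        markers = per_clade[clade]
        if len(markers) >= max(min_markers, 1):
            kept[clade] = markers
        else:
            discarded.append(
                (clade, f"only {len(markers)} markers (< {min_markers})")
            )
    if not kept:
        raise ModelError("no trackable lineages: every clade was rejected")

    # Hierarchy over kept clades: parent = smallest kept strict superset.
    ordered = sorted(kept, key=lambda c: (-len(c), sorted(c)))
    ids = {clade: f"L{i}" for i, clade in enumerate(ordered)}
    ploidy_of = genotypes.ploidies
    lineages: dict[str, Lineage] = {}
    for clade in ordered:
        supersets = [c for c in ordered if clade < c]
        parent = min(supersets, key=len) if supersets else None
        depth = 0 if parent is None else lineages[ids[parent]].depth + 1
        ploidies = {ploidy_of[c] for c in clade}
        lineages[ids[clade]] = Lineage(
            id=ids[clade],
            parent=ids[parent] if parent is not None else None,
            members=clade,
            markers=sorted(kept[clade]),
            depth=depth,
            singleton=len(clade) == 1,
            mixed_ploidy=len(ploidies) > 1,
        )
    g_all = np.nan_to_num(scored.g_matrix())
    marker_sites = {m for lin in lineages.values() for m, _ in lin.markers}
    unassigned = sorted(
        s
        for s in np.flatnonzero(np.any(g_all > 0, axis=0))
        if int(s) not in marker_sites
    )
    unassigned = [int(s) for s in unassigned]
    return LineageModel(
        lineages=lineages,
        genotypes=scored,
        discarded=discarded,
        unassigned_sites=unassigned,
    )


def neighbor_joining_tree(genotypes: CloneGenotypeMatrix) -> dendropy.Tree:
    """Convenience neighbor-joining tree from genotype Hamming distances.

    Unsupported plumbing for users without a phylogeny: pairwise distance
    is the mean absolute difference in copy fraction over sites scored in
    both clones.  Not a substitute for a proper ML phylogeny.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    g = genotypes.g_matrix()
    n = len(genotypes.clones)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(g[i]) & ~np.isnan(g[j])
            d = float(np.mean(np.abs(g[i, both] - g[j, both]))) if both.any() else 0.0
            dist[i, j] = dist[j, i] = d
    import io

    dm = DistanceMatrix(dist, ids=genotypes.clones)
    buf = io.StringIO()
    nj(dm).write(buf)
    tree = dendropy.Tree.get(
        data=buf.getvalue(), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree
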