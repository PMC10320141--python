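import numpy as np
import pytest

from lineagetrack.genotyping import CloneGenotypeMatrix
from lineagetrack.io_formats import VariantMatrix, VariantSite
from lineagetrack.lineage_model import Lineage, LineageModel


def make_sites(n):
    bases = ["A", "C", "G", "T"]
    return [
        VariantSite(f"chr{i % 16 + 1}", i // 16 + 1, bases[i % 4], bases[(i + 1) % 4])
        for i in range(n)
    ]


@pytest.fixture
def toy_genotypes():
    """4 diploid clones A-D, 6 sites:

    s0: het in A,B only        -> marker of {A,B}, g=1/2
    s1: A het, B hom           -> unequal copy number, no clade
    s2: het in all four        -> marker of the root clade
    s3: hom in C,D only        -> marker of {C,D}, g=1
    s4: private het in A       -> marker of singleton {A}
    s5: absent everywhere      -> not a marker
    """
    cn = np.array(
        [
            # s0 s1 s2 s3 s4 s5
            [1, 1, 1, 0, 1, 0],  # A
            [1, 2, 1, 0, 0, 0],  # B
            [0, 0, 1, 2, 0, 0],  # C
            [0, 0, 1, 2, 0, 0],  # D
        ]
    )
    return CloneGenotypeMatrix(
        clones=["A", "B", "C", "D"],
        ploidies={c: 2 for c in "ABCD"},
        copy_number=cn,
        n_sites=6,
    )


@pytest.fixture
def toy_tree():
    import dendropy

    tree = dendropy.Tree.get(
        data="((A,B),(C,D));", schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


def single_sample_counts(sites_x_d, sample="meta"):
    """VariantMatrix with one sample from [(x, d), ...]."""
    x = np.array([p[0] for p in sites_x_d])[:, None]
    d = np.array([p[1] for p in sites_x_d])[:, None]
    return VariantMatrix(make_sites(len(sites_x_d)), [sample], x, d)


def manual_model(structure, markers, ploidy=2):
    """LineageModel from {lineage: parent} and {lineage: [(site, g)]}.

    Members are synthesized so that nesting holds; genotypes carry the
    markers exactly (copy number = g * ploidy).
    """
    n_sites = 1 + max(s for ms in markers.values() for s, _ in ms)
    clones = [f"c_{lid}" for lid in structure]
    cn = np.zeros((len(clones), n_sites), dtype=np.int64)

    def ancestors(lid):
        out = [lid]
        while structure[out[-1]] is not None:
            out.append(structure[out[-1]])
        return out

    for i, lid in enumerate(structure):
        for anc in ancestors(lid):
            for s, g in markers[anc]:
                cn[i, s] = round(g * ploidy)
    geno = CloneGenotypeMatrix(
        clones=clones,
        ploidies={c: ploidy for c in clones},
        copy_number=cn,
        n_sites=n_sites,
    )
    lineages = {}
    for lid, parent in structure.items():
        members = frozenset(
            f"c_{k}" for k in structure if lid in ancestors(k)
        )
        depth = len(ancestors(lid)) - 1
        lineages[lid] = Lineage(
            id=lid,
            parent=parent,
            members=members,
            markers=sorted(markers[lid]),
            depth=depth,
            singleton=len(members) == 1,
        )
    return LineageModel(
        lineages=lineages, genotypes=geno, discarded=[], unassigned_sites=[]
    )
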