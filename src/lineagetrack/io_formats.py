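"""Readers and writers for the formats the pipeline touches.

Variant tables arrive either as VCF (v4.x, with per-sample AD fields as
emitted by common callers) or as a documented TSV dialect; trees are
Newick; sample sheets and all outputs are TSV.  Coordinates are kept
1-based throughout to match VCF — no coordinate arithmetic is performed,
so no half-open convention is needed.

The TSV variant dialect has columns::

    chrom  pos  ref  alt  <sample>:alt  <sample>:depth  [...]

with one ``<name>:alt`` / ``<name>:depth`` column pair per sample.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


@dataclasses.dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP: chromosome, 1-based position, ref and alt base."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt allele must differ")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt_allele)


@dataclasses.dataclass
class VariantMatrix:
    """Per-site, per-sample alternate-allele counts x and depths d.

    ``alt_counts`` and ``depths`` are integer arrays of shape
    (n_sites, n_samples).  Sites with d=0 in a sample are retained and
    treated as masked (frequency undefined), never imputed as 0.
    ``raw_alt_lists`` optionally carries the original per-site alternate
    allele lists, used by :func:`filter_biallelic_snps`.
    """

    sites: list[VariantSite]
    samples: list[str]
    alt_counts: np.ndarray
    depths: np.ndarray
    raw_alt_lists: list[list[str]] | None = None

    def __post_init__(self) -> None:
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        self.depths = np.asarray(self.depths, dtype=np.int64)
        shape = (len(self.sites), len(self.samples))
        if self.alt_counts.shape != shape or self.depths.shape != shape:
            raise ValueError(
                f"matrix shapes {self.alt_counts.shape}/{self.depths.shape} "
                f"inconsistent with {len(self.sites)} sites x {len(self.samples)} samples"
            )
        if np.any(self.alt_counts < 0) or np.any(self.alt_counts > self.depths):
            raise ValueError("require 0 <= alt_counts <= depths elementwise")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in variant matrix") from None

    def column(self, sample: str) -> tuple[np.ndarray, np.ndarray]:
        """(alt counts, depths) for one sample across all sites."""
        j = self.sample_index(sample)
        return self.alt_counts[:, j], self.depths[:, j]

    def allele_freq(self) -> np.ma.MaskedArray:
        """x/d with d=0 entries masked."""
        with np.errstate(divide="ignore", invalid="ignore"):
            f = self.alt_counts / self.depths
        return np.ma.masked_invalid(f)

    def take_sites(self, idx: Sequence[int]) -> "VariantMatrix":
        idx = list(idx)
        return VariantMatrix(
            sites=[self.sites[i] for i in idx],
            samples=list(self.samples),
            alt_counts=self.alt_counts[idx, :],
            depths=self.depths[idx, :],
            raw_alt_lists=(
                [self.raw_alt_lists[i] for i in idx] if self.raw_alt_lists else None
            ),
        )

    def take_samples(self, names: Sequence[str]) -> "VariantMatrix":
        js = [self.sample_index(s) for s in names]
        return VariantMatrix(
            sites=list(self.sites),
            samples=list(names),
            alt_counts=self.alt_counts[:, js],
            depths=self.depths[:, js],
            raw_alt_lists=self.raw_alt_lists,
        )


@dataclasses.dataclass
class SampleSheet:
    """Sample roles and collection timepoints.

    Columns: sample, role in {clone, metagenome, starter}, site_year,
    timepoint_days (days since season start; required for metagenomes).
    """

    table: pd.DataFrame

    ROLES = {"clone", "metagenome", "starter"}

    def __post_init__(self) -> None:
        required = {"sample", "role", "site_year", "timepoint_days"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample"].duplicated().any():
            dupes = self.table.loc[self.table["sample"].duplicated(), "sample"]
            raise ValueError(f"duplicate sample identifiers: {sorted(set(dupes))}")
        bad_roles = set(self.table["role"]) - self.ROLES
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")
        meta = self.table[self.table["role"] == "metagenome"]
        if meta["timepoint_days"].isna().any():
            raise ValueError("every metagenome sample needs a timepoint")
        t = pd.to_numeric(self.table["timepoint_days"], errors="coerce")
        if (t.dropna() < 0).any():
            raise ValueError("timepoints must be non-negative")

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t"))

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def samples_with_role(self, role: str) -> list[str]:
        return list(self.table.loc[self.table["role"] == role, "sample"])

    def timepoint_of(self, sample: str) -> float:
        row = self.table[self.table["sample"] == sample]
        if row.empty:
            raise KeyError(f"sample {sample!r} not in sheet")
        return float(row["timepoint_days"].iloc[0])

    def metagenomes_by_time(self) -> list[tuple[float, str]]:
        meta = self.table[self.table["role"] == "metagenome"]
        pairs = sorted(
            (float(t), s) for t, s in zip(meta["timepoint_days"], meta["sample"])
        )
        return pairs


# ---------------------------------------------------------------------------
# variant tables


def read_variant_table(path: str | Path, dialect: str = "tsv") -> VariantMatrix:
    """Read a variant table into a :class:`VariantMatrix`.

    dialect "vcf": per-sample AD fields (ref count, alt count[s]); the
    depth is defined as the sum of ref and alt counts, not the DP field.
    dialect "tsv": the documented column dialect (module docstring).
    Multi-allelic records are carried through with their raw alt lists so
    :func:`filter_biallelic_snps` can drop them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf(path: Path) -> VariantMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    alt_lists: list[list[str]] = []
    xs: list[np.ndarray] = []
    ds: list[np.ndarray] = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise FormatError(
                f"{path}: record {rec.CHROM}:{rec.POS} lacks per-sample AD field"
            )
        ad = np.asarray(ad, dtype=np.int64)
        ad[ad < 0] = 0  # cyvcf2 encodes missing as negative sentinels
        alts = list(rec.ALT) if rec.ALT else []
        first_alt = alts[0] if alts else "N"
        sites.append(VariantSite(rec.CHROM, rec.POS, rec.REF, first_alt))
        alt_lists.append(alts)
        xs.append(ad[:, 1:].sum(axis=1))
        ds.append(ad.sum(axis=1))
    if not sites:
        z = np.zeros((0, len(samples)), dtype=np.int64)
        return VariantMatrix(sites, samples, z, z.copy(), raw_alt_lists=[])
    return VariantMatrix(
        sites,
        samples,
        np.vstack(xs),
        np.vstack(ds),
        raw_alt_lists=alt_lists,
    )


def _read_tsv(path: Path) -> VariantMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        z = np.zeros((0, 0), dtype=np.int64)
        return VariantMatrix([], [], z, z.copy(), raw_alt_lists=[])
    fixed = ["chrom", "pos", "ref", "alt"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    alt_cols = [c for c in df.columns if c.endswith(":alt")]
    samples = [c[: -len(":alt")] for c in alt_cols]
    for s in samples:
        if f"{s}:depth" not in df.columns:
            raise FormatError(f"{path}: sample {s!r} has :alt but no :depth column")
    sites = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            pos = int(row.pos)
        except (TypeError, ValueError):
            raise FormatError(f"{path}: malformed coordinate at line {i + 2}") from None
        sites.append(VariantSite(str(row.chrom), pos, str(row.ref), str(row.alt)))
    x = df[[f"{s}:alt" for s in samples]].to_numpy(dtype=np.int64)
    d = df[[f"{s}:depth" for s in samples]].to_numpy(dtype=np.int64)
    return VariantMatrix(
        sites, samples, x, d, raw_alt_lists=[[s.alt_allele] for s in sites]
    )


def write_variant_table(vm: VariantMatrix, path: str | Path) -> None:
    """Write a VariantMatrix in the TSV dialect (lossless round trip)."""
    cols: dict[str, object] = {
        "chrom": [s.chrom for s in vm.sites],
        "pos": [s.pos for s in vm.sites],
        "ref": [s.ref_allele for s in vm.sites],
        "alt": [s.alt_allele for s in vm.sites],
    }
    for j, name in enumerate(vm.samples):
        cols[f"{name}:alt"] = vm.alt_counts[:, j]
        cols[f"{name}:depth"] = vm.depths[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def filter_biallelic_snps(
    vm: VariantMatrix, raw_alt_allele_lists: list[list[str]] | None = None
) -> VariantMatrix:
    """Keep only single-alternate-allele SNP sites.

    Sites with more than one alternate allele are dropped outright (not
    split into pseudo-biallelic records), and ref/alt must both be single
    bases.  Idempotent; never increases the site count.
    """
    lists = raw_alt_allele_lists if raw_alt_allele_lists is not None else vm.raw_alt_lists
    if lists is None:
        lists = [[s.alt_allele] for s in vm.sites]
    if len(lists) != vm.n_sites:
        raise ValueError(
            f"allele lists ({len(lists)}) misaligned with sites ({vm.n_sites})"
        )
    bases = {"A", "C", "G", "T"}
    keep = [
        i
        for i, (site, alts) in enumerate(zip(vm.sites, lists))
        if len(alts) == 1
        and site.ref_allele.upper() in bases
        and alts[0].upper() in bases
    ]
    return vm.take_sites(keep)


# ---------------------------------------------------------------------------
# trees


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree; tip labels must be unique."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        seen, dupes = set(), set()
        for lab in labels:
            (dupes if lab in seen else seen).add(lab)
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# frequency tables

FREQ_COLUMNS = ["timepoint", "lineage", "inclusive_freq", "exclusive_freq", "residual"]


def write_frequency_table(estimates: list, path: str | Path) -> None:
    """Write one row per (timepoint, lineage): inclusive and exclusive
    frequency plus the per-timepoint residual; 6-decimal, losslessly
    re-readable at that precision.
    """
    rows = []
    lineage_sets = {tuple(sorted(e.inclusive.keys())) for e in estimates}
    if len(lineage_sets) > 1:
        raise ValueError("estimates carry inconsistent lineage sets")
    for est in sorted(estimates, key=lambda e: e.timepoint):
        excl = est.exclusive()
        for lid in sorted(est.inclusive.keys()):
            rows.append(
                {
                    "timepoint": est.timepoint,
                    "lineage": lid,
                    "inclusive_freq": round(est.inclusive[lid], 6),
                    "exclusive_freq": round(excl[lid], 6),
                    "residual": round(est.residual(), 6),
                }
            )
    pd.DataFrame(rows, columns=FREQ_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_frequency_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(FREQ_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df
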