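"""End-to-end pipeline: ploidy -> genotyping -> lineage model -> inference.

A single master seed fans out to per-stage seeds through a fixed
derivation (SeedSequence over (master, stage index)), so any stage can be
rerun in isolation and reproduce its part of a full run.  Run metadata
(tool version, seed, config hash) is written alongside the outputs; the
same config and seed always produce identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .freq_inference import InferenceConfig, infer_trajectories
from .genotyping import call_genotypes, write_genotype_matrix
from .io_formats import (
    SampleSheet,
    read_newick,
    read_variant_table,
    filter_biallelic_snps,
    write_frequency_table,
)
from .lineage_model import build_lineage_model
from .ploidy import call_all_ploidies

_STAGES = ["simulate", "ploidy", "genotype", "lineages", "infer"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence([int(master_seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclasses.dataclass
class RunConfig:
    variant_table: str
    tree: str
    sample_sheet: str
    outdir: str
    dialect: str = "tsv"
    seed: int = 0
    ploidy_params: dict = dataclasses.field(default_factory=dict)
    genotyping_params: dict = dataclasses.field(default_factory=dict)
    lineage_params: dict = dataclasses.field(default_factory=dict)
    inference_params: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def validate_inputs(config: RunConfig) -> dict:
    """Cross-consistency report for sample sheet, variant table and tree;
    never raises — problems are listed in the returned report."""
    problems: list[str] = []
    try:
        vm = read_variant_table(config.variant_table, dialect=config.dialect)
    except Exception as exc:  # noqa: BLE001 - reported, not raised
        return {"problems": [f"variant table unreadable: {exc}"], "ok": False}
    try:
        sheet = SampleSheet.read(config.sample_sheet)
    except Exception as exc:  # noqa: BLE001
        return {"problems": [f"sample sheet unreadable: {exc}"], "ok": False}
    for s in sheet.table["sample"]:
        if s not in vm.samples:
            problems.append(f"sheet sample {s!r} absent from variant table")
    meta = sheet.table[sheet.table["role"] == "metagenome"]
    for s, t in zip(meta["sample"], meta["timepoint_days"]):
        if t is None or (isinstance(t, float) and np.isnan(t)):
            problems.append(f"metagenome sample {s!r} missing timepoint")
    try:
        tree = read_newick(config.tree)
        clones = set(sheet.samples_with_role("clone"))
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label not in clones:
                problems.append(
                    f"tree tip {leaf.taxon.label!r} is not a clone in the sheet"
                )
            if leaf.taxon.label not in vm.samples:
                problems.append(
                    f"tree tip {leaf.taxon.label!r} absent from variant table"
                )
    except Exception as exc:  # noqa: BLE001
        problems.append(f"tree unreadable: {exc}")
    return {"problems": problems, "ok": not problems}


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; outputs land in config.outdir.

    A stage failure aborts downstream stages with the failing stage named;
    stage outputs are only written once that stage completed, so a partial
    run never leaves silently truncated tables.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    vm = read_variant_table(config.variant_table, dialect=config.dialect)
    vm = filter_biallelic_snps(vm)
    sheet = SampleSheet.read(config.sample_sheet)
    tree = read_newick(config.tree)
    clones = [c for c in sheet.samples_with_role("clone") if c in vm.samples]

    try:
        calls = call_all_ploidies(vm, clones, **config.ploidy_params)
        _write_ploidy_table(calls, outdir / "ploidy.tsv")
    except Exception as exc:
        raise StageError("ploidy", str(exc)) from exc

    try:
        geno, excluded = call_genotypes(vm, calls, **config.genotyping_params)
        write_genotype_matrix(geno, outdir / "genotypes.tsv")
    except Exception as exc:
        raise StageError("genotype", str(exc)) from exc

    try:
        model = build_lineage_model(tree, geno, **config.lineage_params)
        _write_lineage_tables(model, outdir)
    except Exception as exc:
        raise StageError("lineages", str(exc)) from exc

    try:
        inf_cfg = InferenceConfig(
            seed=stage_seed(config.seed, "infer"), **config.inference_params
        )
        failures: list = []
        pairs = [
            (t, s) for t, s in sheet.metagenomes_by_time() if s in vm.samples
        ]
        estimates = infer_trajectories(model, vm, pairs, inf_cfg, failures=failures)
        write_frequency_table(estimates, outdir / "frequencies.tsv")
        diagnostics = {
            "n_timepoints": len(estimates),
            "all_converged": all(e.converged for e in estimates),
            "failures": [{"timepoint": t, "error": m} for t, m in failures],
            "excluded_clones": excluded,
            "discarded_clades": len(model.discarded),
            "unassigned_sites": len(model.unassigned_sites),
        }
        (outdir / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
    except Exception as exc:
        raise StageError("infer", str(exc)) from exc

    metadata = {
        "tool": "lineagetrack",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
    }
    (outdir / "run_metadata.json").write_text(json.dumps(metadata, indent=2))
    return outdir


def _write_ploidy_table(calls, path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "clone": c.clone,
                "ploidy": c.ploidy if c.ploidy is not None else "unknown",
                "delta_loglik": round(c.delta_loglik, 4),
                "n_sites": c.n_sites,
                "flag": "low_confidence" if c.low_confidence else "ok",
                "reason": c.reason,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def _write_lineage_tables(model, outdir: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "lineage": lin.id,
                "parent": lin.parent or "",
                "n_members": len(lin.members),
                "members": ",".join(sorted(lin.members)),
                "n_markers": lin.n_markers,
                "singleton": lin.singleton,
            }
            for lin in model.lineages.values()
        ]
    ).to_csv(outdir / "lineages.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"site": s, "lineage": lin.id, "g_m": g}
            for lin in model.lineages.values()
            for s, g in lin.markers
        ]
    ).to_csv(outdir / "markers.tsv", sep="\t", index=False)
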