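"""End-to-end orchestration: simulate -> per-experiment DE -> vote counting
-> Fisher meta-statistic -> downstream tables, with a manifest that makes a
run reconstructible and byte-reproducible from its config and seed."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, egwas as egwas_mod, io as eio, sam as sam_mod
from .interpret import AnnotationSet, enrich, hub_rank
from .synth import (
    CompendiumConfig,
    ExpressionExperiment,
    generate_compendium,
    synthetic_annotation,
    synthetic_edges,
    synthetic_positions,
    write_compendium,
)

log = logging.getLogger(__name__)

PRESETS = {"desk", "paper-shape"}
ENGINES = {"sam", "ttest-bh"}


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run (YAML-loadable)."""

    out_dir: str = "runs/run"
    seed: int = 1
    preset: str = "desk"
    simulate: bool = True
    simulate_overrides: dict[str, Any] = field(default_factory=dict)
    engine: str = "sam"
    fdr_target: float = 0.05
    permutations: int = 100
    threshold: float = egwas_mod.DEFAULT_THRESHOLD
    bonferroni_exact: bool = False
    alternative: str = egwas_mod.TWO_SIDED
    candidate_fallback: int = 25
    # external inputs (used when simulate is false; synthetic ones are
    # generated alongside the compendium otherwise)
    experiments: list[dict[str, str]] = field(default_factory=list)
    universe: str | None = None
    positions: str | None = None
    annotation: str | None = None
    edges: str | None = None
    plot: bool = False

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {sorted(PRESETS)}")
        if self.engine not in ENGINES:
            raise ValueError(f"engine must be one of {sorted(ENGINES)}")
        if not (0.0 < self.fdr_target <= 1.0):
            raise ValueError("fdr_target must be in (0, 1]")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def compendium_config(self) -> CompendiumConfig:
        base = (
            CompendiumConfig.desk(seed=self.seed)
            if self.preset == "desk"
            else CompendiumConfig(seed=self.seed)
        )
        return base.replace(**self.simulate_overrides) if self.simulate_overrides else base

    def effective(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class ValidationReport:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Check input files for matrix/label agreement, duplicate gene ids,
    NaNs and label vocabulary. Fatal problems abort; surplus annotation is a
    warning only."""
    report = ValidationReport()
    if config.simulate:
        try:
            config.compendium_config()
        except (ValueError, TypeError) as exc:
            report.fatal.append(f"simulate: invalid compendium config: {exc}")
        return report

    universe: set[str] = set()
    if config.universe:
        try:
            universe = set(eio.read_universe(config.universe))
        except (OSError, ValueError) as exc:
            report.fatal.append(f"universe: {exc}")
    else:
        report.fatal.append("universe file required when simulate is false")

    for spec in config.experiments:
        exp_id = spec.get("id", spec.get("matrix", "?"))
        try:
            matrix = pd.read_csv(spec["matrix"], sep="\t", index_col=0)
            labels_df = pd.read_csv(spec["labels"], sep="\t", index_col=0)
        except (OSError, KeyError) as exc:
            report.fatal.append(f"{exp_id}: unreadable input ({exc})")
            continue
        labels = labels_df.iloc[:, 0].astype(str)
        missing = [s for s in matrix.columns if s not in labels.index]
        for sample in missing:
            report.fatal.append(f"{exp_id}: sample {sample!r} has no label")
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        if dups:
            report.fatal.append(f"{exp_id}: duplicate gene ids {dups}")
        if np.isnan(matrix.to_numpy(dtype=float)).any():
            report.fatal.append(f"{exp_id}: matrix contains NaN values")
        bad = set(labels.unique()) - {"case", "control"}
        if bad:
            report.fatal.append(f"{exp_id}: unknown labels {sorted(bad)}")
        if universe:
            outside = set(matrix.index) - universe
            if outside:
                report.fatal.append(
                    f"{exp_id}: genes outside the universe {sorted(outside)[:5]}"
                )
    if config.annotation and universe:
        try:
            terms = eio.read_gmt(config.annotation)
            unused = [t for t, g in terms.items() if not (g & universe)]
            if unused:
                report.warnings.append(
                    f"annotation: {len(unused)} terms share no genes with the universe"
                )
        except (OSError, ValueError) as exc:
            report.fatal.append(f"annotation: {exc}")
    return report


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute the configured pipeline; returns the run directory.

    Rerunning with an identical config and seed reproduces every output file
    byte for byte (the manifest records no timestamps).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "egwaskit",
        "version": __version__,
        "libs": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": config.seed,
        "config": config.effective(),
        "stages": {},
        "files": {},
    }
    outputs: list[Path] = []

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(name, exc) from exc
            return result

        return deco

    @stage("simulate")
    def _simulate():
        if not config.simulate:
            return None
        cc = config.compendium_config()
        experiments, truth = generate_compendium(cc)
        data_dir = out / "data"
        files = write_compendium(experiments, truth, data_dir)
        positions = synthetic_positions(truth.universe)
        ppath = data_dir / "positions.tsv"
        positions.to_csv(ppath, sep="\t", index=False)
        gmt = synthetic_annotation(truth.universe, truth, seed=config.seed)
        apath = eio.write_gmt(gmt, data_dir / "annotation.gmt")
        hub = sorted(truth.true_genes)[0] if truth.true_genes else None
        epath = data_dir / "edges.tsv"
        synthetic_edges(sorted(truth.true_genes), hub=hub, seed=config.seed).to_csv(
            epath, sep="\t", index=False
        )
        outputs.extend(files + [ppath, apath, epath])
        manifest["stages"]["simulate"] = {
            "n_experiments": len(experiments),
            "n_genes": cc.n_genes,
            "n_true": cc.n_true,
        }
        return data_dir

    data_dir = _simulate

    @stage("load")
    def _load() -> tuple[list[ExpressionExperiment], list[str]]:
        if config.simulate:
            universe = eio.read_universe(data_dir / "universe.txt")
            exps = [
                eio.read_experiment(m, data_dir / f"{m.stem.removesuffix('_matrix')}_labels.tsv")
                for m in sorted(data_dir.glob("*_matrix.tsv"))
            ]
        else:
            report = validate_inputs(config)
            if not report.ok:
                raise ValueError("; ".join(report.fatal))
            universe = eio.read_universe(config.universe)
            exps = [
                eio.read_experiment(spec["matrix"], spec["labels"], spec.get("id"))
                for spec in config.experiments
            ]
        return exps, universe

    experiments, universe = _load

    @stage("de")
    def _de() -> list[sam_mod.DECallSet]:
        calls_dir = out / "calls"
        calls_dir.mkdir(exist_ok=True)
        call_sets = []
        for idx, exp in enumerate(experiments):
            if config.engine == "sam":
                result = sam_mod.sam_analyze(
                    exp,
                    fdr_target=config.fdr_target,
                    B=config.permutations,
                    seed=[config.seed, 1000 + idx],
                )
                calls = result.calls
            else:
                calls = sam_mod.ttest_bh_calls(exp, fdr_target=config.fdr_target)
            path = calls_dir / f"{exp.experiment_id}_calls.tsv"
            eio.write_call_set(calls.table, path)
            outputs.append(path)
            call_sets.append(calls)
        manifest["stages"]["de"] = {
            "engine": config.engine,
            "per_experiment_calls": {
                cs.experiment_id: len(cs.called) for cs in call_sets
            },
        }
        return call_sets

    call_sets = _de

    @stage("egwas")
    def _egwas() -> egwas_mod.EgwasResult:
        votes = egwas_mod.vote_count(call_sets, universe)
        result = egwas_mod.run_egwas(
            votes,
            threshold=config.threshold,
            bonferroni_exact=config.bonferroni_exact,
            alternative=config.alternative,
        )
        rpath = out / "egwas_results.tsv"
        res = result.table.copy()
        res.index.name = "gene_id"
        res.to_csv(rpath, sep="\t", float_format="%.8g")
        upath = out / "unmeasured_genes.txt"
        upath.write_text("\n".join(result.unmeasured) + ("\n" if result.unmeasured else ""))
        outputs.extend([rpath, upath])
        manifest["stages"]["egwas"] = {
            "n_scored": len(result.table),
            "n_unmeasured": len(result.unmeasured),
            "n_universe": len(universe),
            "n_significant": len(result.significant),
            "threshold": result.threshold,
        }
        return result

    result = _egwas

    candidates = result.significant
    if not candidates:
        candidates = result.table.index[: config.candidate_fallback].tolist()
        log.info(
            "no gene passed the threshold; using the top %d ranked genes "
            "as the candidate list for downstream stages", len(candidates),
        )

    positions_path = (data_dir / "positions.tsv") if config.simulate else config.positions
    if positions_path:
        @stage("manhattan")
        def _manhattan():
            table, ref = egwas_mod.manhattan_table(result, eio.read_positions(positions_path))
            mpath = out / "manhattan.tsv"
            t = table.copy()
            t.index.name = "gene_id"
            t.to_csv(mpath, sep="\t", float_format="%.8g")
            outputs.append(mpath)
            manifest["stages"]["manhattan"] = {"n_rows": len(table), "reference_line": ref}
            if config.plot:
                _plot_manhattan(t, ref, out / "manhattan.png")

    annotation_path = (data_dir / "annotation.gmt") if config.simulate else config.annotation
    if annotation_path:
        @stage("enrich")
        def _enrich():
            ann = AnnotationSet(eio.read_gmt(annotation_path))
            rows = enrich(set(candidates), set(universe), ann)
            epath = out / "enrichment.tsv"
            rows.to_csv(epath, sep="\t", index=False, float_format="%.8g")
            outputs.append(epath)
            manifest["stages"]["enrich"] = {"n_terms": len(rows)}

    edges_path = (data_dir / "edges.tsv") if config.simulate else config.edges
    if edges_path:
        @stage("hub")
        def _hub():
            ranking = hub_rank(set(candidates), eio.read_edges(edges_path))
            hpath = out / "hubs.tsv"
            ranking.to_csv(hpath, sep="\t", index=False)
            outputs.append(hpath)
            manifest["stages"]["hub"] = {"n_nodes": len(ranking)}

    manifest["files"] = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(set(outputs))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("run complete: %s (%d output files)", out, len(outputs))
    return out


def _plot_manhattan(table: pd.DataFrame, ref_line: float, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    chroms = list(dict.fromkeys(table["chrom"]))
    offset, ticks = 0.0, []
    for i, chrom in enumerate(chroms):
        sub = table[table["chrom"] == chrom]
        x = sub["position"].to_numpy(dtype=float) + offset
        ax.scatter(x, sub["neg_log10_p"], s=4, color="C0" if i % 2 else "C2")
        ticks.append((offset + x.max()) / 2 if len(x) else offset)
        offset = x.max() + 1 if len(x) else offset
    ax.axhline(ref_line, color="red", lw=1)
    ax.set_xticks(ticks, chroms, rotation=90, fontsize=6)
    ax.set_ylabel(r"$-\log_{10} P$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
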