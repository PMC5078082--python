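"""Seeded synthetic multi-study expression compendia with planted signal genes.

The generator emulates a cross-study case/control microarray compendium:
``n_experiments`` independent experiments measure overlapping random subsets
of a shared gene universe (partial platform coverage), each gene has its own
baseline level and noise scale, and a small set of "true" genes is shifted in
cases — with a per-gene fixed sign, so *consistent* dysregulation across
experiments is well defined. Gene-wise noise SDs are drawn from a scaled
inverse-chi-square so that genuinely low-variance genes exist; those are the
genes that make a moderated (fudge-factor) test statistic necessary.

All randomness flows from a single integer seed. Per-experiment substreams
are derived from fixed seed offsets, so the e-th experiment is reproducible
no matter which other experiments are generated.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: default full-scale compendium shape: 13 case/control experiments totalling
#: 251 cases and 428 controls over a 30,663-gene universe
DEFAULT_N_GENES = 30663
DEFAULT_N_EXPERIMENTS = 13
DEFAULT_TOTAL_CASES = 251
DEFAULT_TOTAL_CONTROLS = 428

CASE = "case"
CONTROL = "control"


def split_total(total: int, k: int) -> tuple[int, ...]:
    """Split ``total`` samples over ``k`` experiments as evenly as possible."""
    if k <= 0 or total < k:
        raise ValueError(f"cannot split {total} samples over {k} experiments")
    base, rem = divmod(total, k)
    return tuple(base + (i < rem) for i in range(k))


@dataclass(frozen=True)
class CompendiumConfig:
    """Shape and signal parameters of a synthetic compendium.

    Defaults follow the full-scale study design: 13 experiments, 251 cases
    and 428 controls in total (split evenly), a 30,663-gene universe with 90%
    per-platform coverage, and 20 planted genes shifted by 1.5 within-gene
    SDs in 90% of experiments. ``swap_case_control`` exchanges the two totals
    for the alternative 428-case/251-control reading of the design.
    """

    n_genes: int = DEFAULT_N_GENES
    n_experiments: int = DEFAULT_N_EXPERIMENTS
    cases_per_experiment: tuple[int, ...] | None = None
    controls_per_experiment: tuple[int, ...] | None = None
    coverage_fraction: float = 0.9
    n_true: int = 20
    effect_size: float = 1.5
    activity_prob: float = 0.9
    noise_sd_shape: float = 4.0
    noise_sd_scale: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    swap_case_control: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_experiments <= 0:
            raise ValueError("n_genes and n_experiments must be positive")
        if not (0.0 < self.coverage_fraction <= 1.0):
            raise ValueError("coverage_fraction must be in (0, 1]")
        if not (0.0 <= self.activity_prob <= 1.0):
            raise ValueError("activity_prob must be in [0, 1]")
        if not (0 <= self.n_true < self.n_genes):
            raise ValueError("n_true must satisfy 0 <= n_true < n_genes")
        if self.noise_sd_shape <= 0 or self.noise_sd_scale <= 0:
            raise ValueError("noise SD parameters must be positive")
        for name in ("cases_per_experiment", "controls_per_experiment"):
            counts = getattr(self, name)
            if counts is not None:
                if len(counts) != self.n_experiments:
                    raise ValueError(f"{name} must have length n_experiments")
                if min(counts) < 2:
                    raise ValueError(f"{name}: every experiment needs >= 2 samples per class")

    @property
    def case_counts(self) -> tuple[int, ...]:
        if self.cases_per_experiment is not None:
            return tuple(self.cases_per_experiment)
        total = DEFAULT_TOTAL_CONTROLS if self.swap_case_control else DEFAULT_TOTAL_CASES
        return split_total(total, self.n_experiments)

    @property
    def control_counts(self) -> tuple[int, ...]:
        if self.controls_per_experiment is not None:
            return tuple(self.controls_per_experiment)
        total = DEFAULT_TOTAL_CASES if self.swap_case_control else DEFAULT_TOTAL_CONTROLS
        return split_total(total, self.n_experiments)

    @classmethod
    def desk(cls, seed: int = 1, **overrides) -> "CompendiumConfig":
        """Small configuration for interactive runs: 3 experiments, 500 genes."""
        params = dict(
            n_genes=500,
            n_experiments=3,
            cases_per_experiment=(10, 10, 10),
            controls_per_experiment=(15, 15, 15),
            n_true=10,
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)

    def replace(self, **changes) -> "CompendiumConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class ExpressionExperiment:
    """One study: a genes x samples log2-intensity matrix plus sample labels."""

    experiment_id: str
    matrix: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            dups = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise ValueError(f"{self.experiment_id}: duplicate gene ids {dups[:5]}")
        if list(self.matrix.columns) != list(self.labels.index):
            raise ValueError(f"{self.experiment_id}: matrix columns and label index disagree")
        bad = set(self.labels.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"{self.experiment_id}: unknown labels {sorted(bad)}")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError(f"{self.experiment_id}: need >= 2 samples in each class")
        if np.isnan(self.matrix.to_numpy()).any():
            raise ValueError(f"{self.experiment_id}: matrix contains NaN values")

    @property
    def genes(self) -> list[str]:
        return self.matrix.index.tolist()

    @property
    def case_mask(self) -> np.ndarray:
        return (self.labels == CASE).to_numpy()

    @property
    def n_cases(self) -> int:
        return int((self.labels == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.labels == CONTROL).sum())


@dataclass
class TruthLedger:
    """Which genes were planted, their fixed sign, and per-experiment activity.

    ``table`` is indexed by gene id with a ``sign`` column (+1/-1) and one
    0/1 activity column per experiment id.
    """

    table: pd.DataFrame
    universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.universe and not set(self.table.index) <= set(self.universe):
            raise ValueError("true genes must be a subset of the universe")

    @property
    def true_genes(self) -> set[str]:
        return set(self.table.index)

    def active_genes(self, experiment_id: str) -> set[str]:
        col = self.table[experiment_id]
        return set(col.index[col.astype(bool)])


def gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


def _experiment_rng(seed: int, index: int) -> np.random.Generator:
    # substream e+1; offset 0 is reserved for universe-level draws
    return np.random.default_rng([seed, index])


def generate_compendium(
    config: CompendiumConfig,
) -> tuple[list[ExpressionExperiment], TruthLedger]:
    """Generate a seeded compendium and its truth ledger.

    Per gene g a baseline mean mu_g ~ Normal(baseline_mean, baseline_sd) and a
    noise SD sigma_g = scale * sqrt(shape / ChiSquare(shape)) are drawn once.
    Per experiment, a Bernoulli(coverage_fraction) subset of genes is on the
    platform; each planted gene is active with probability ``activity_prob``
    and, when active, shifts case means by ``sign_g * effect_size * sigma_g``.
    """
    cfg = config
    G, E = cfg.n_genes, cfg.n_experiments
    universe = gene_ids(G)
    rng_u = _experiment_rng(cfg.seed, 0)
    mu = rng_u.normal(cfg.baseline_mean, cfg.baseline_sd, size=G)
    sigma = cfg.noise_sd_scale * np.sqrt(
        cfg.noise_sd_shape / rng_u.chisquare(cfg.noise_sd_shape, size=G)
    )
    true_idx = np.sort(rng_u.choice(G, size=cfg.n_true, replace=False))
    signs = rng_u.choice([-1, 1], size=cfg.n_true)

    case_counts, control_counts = cfg.case_counts, cfg.control_counts
    experiments: list[ExpressionExperiment] = []
    activity = np.zeros((cfg.n_true, E), dtype=int)
    exp_ids = [f"E{e + 1:02d}" for e in range(E)]

    for e, exp_id in enumerate(exp_ids):
        rng_e = _experiment_rng(cfg.seed, e + 1)
        measured = rng_e.random(G) < cfg.coverage_fraction
        n1, n2 = case_counts[e], control_counts[e]
        X = mu[:, None] + sigma[:, None] * rng_e.normal(size=(G, n1 + n2))
        active = rng_e.random(cfg.n_true) < cfg.activity_prob
        activity[:, e] = active.astype(int)
        shift = signs * cfg.effect_size * sigma[true_idx]
        X[true_idx[active], :n1] += shift[active, None]

        samples = [f"{exp_id}_case{j + 1:02d}" for j in range(n1)] + [
            f"{exp_id}_ctrl{j + 1:02d}" for j in range(n2)
        ]
        matrix = pd.DataFrame(
            X[measured], index=np.asarray(universe)[measured], columns=samples
        )
        labels = pd.Series([CASE] * n1 + [CONTROL] * n2, index=samples, name="label")
        experiments.append(ExpressionExperiment(exp_id, matrix, labels))

    truth_table = pd.DataFrame(
        {"sign": signs, **{exp_ids[e]: activity[:, e] for e in range(E)}},
        index=np.asarray(universe)[true_idx],
    )
    truth_table.index.name = "gene_id"
    return experiments, TruthLedger(truth_table, universe)


def write_compendium(
    experiments: Sequence[ExpressionExperiment],
    truth: TruthLedger,
    directory: str | Path,
) -> list[Path]:
    """Write one matrix TSV and one label TSV per experiment plus the truth
    ledger and universe list. Round-trips through :mod:`egwaskit.io`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for exp in experiments:
        mpath = directory / f"{exp.experiment_id}_matrix.tsv"
        lpath = directory / f"{exp.experiment_id}_labels.tsv"
        out = exp.matrix.copy()
        out.index.name = "gene_id"
        out.to_csv(mpath, sep="\t", float_format="%.6f")
        exp.labels.rename_axis("sample_id").to_frame().to_csv(lpath, sep="\t")
        written += [mpath, lpath]
    tpath = directory / "truth.tsv"
    truth.table.to_csv(tpath, sep="\t")
    upath = directory / "universe.txt"
    upath.write_text("\n".join(truth.universe) + "\n")
    written += [tpath, upath]
    return written


def synthetic_positions(
    universe: Sequence[str], n_chromosomes: int = 22, spacing: int = 100_000
) -> pd.DataFrame:
    """Deterministic BED-like gene positions (round-robin over chromosomes).

    Plumbing for Manhattan output on synthetic compendia; real runs supply a
    genuine gene-position table instead.
    """
    rows = []
    per_chrom = -(-len(universe) // n_chromosomes)
    for i, gene in enumerate(universe):
        chrom = i // per_chrom + 1
        rank = i % per_chrom
        rows.append((gene, f"chr{chrom}", rank * spacing))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start"])


def synthetic_annotation(
    universe: Sequence[str],
    truth: TruthLedger,
    n_terms: int = 25,
    term_size: int = 40,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random gene-set annotation with one term seeded by the planted genes.

    Synthetic stand-in for a real GO/pathway GMT: ``TERM_SIGNAL`` contains all
    planted genes padded with random ones; the remaining terms are uniform
    draws from the universe.
    """
    rng = np.random.default_rng([seed, 9001])
    universe = list(universe)
    terms: dict[str, set[str]] = {}
    planted = sorted(truth.true_genes)
    pad = [g for g in universe if g not in truth.true_genes]
    pad_pick = rng.choice(len(pad), size=max(0, term_size - len(planted)), replace=False)
    terms["TERM_SIGNAL"] = set(planted) | {pad[i] for i in pad_pick}
    for t in range(n_terms - 1):
        pick = rng.choice(len(universe), size=term_size, replace=False)
        terms[f"TERM_{t + 1:03d}"] = {universe[i] for i in pick}
    return terms


def synthetic_edges(
    candidates: Sequence[str],
    hub: str | None = None,
    n_background: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Random interaction edge list with an optional planted hub.

    Synthetic stand-in for a curated interaction network: the hub is joined to
    every other candidate; background edges are uniform random pairs.
    """
    rng = np.random.default_rng([seed, 9002])
    candidates = list(candidates)
    rows = []
    if hub is not None:
        rows += [(hub, other, "planted") for other in candidates if other != hub]
    for _ in range(n_background):
        i, j = rng.choice(len(candidates), size=2, replace=False)
        rows.append((candidates[i], candidates[j], "random"))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "source"])
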