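"""Validation benchmarks: independent oracles and calibration experiments.

Everything here measures the pipeline from the outside — exact rational
enumeration for the Fisher statistic, the closed-form 2x2 chi-square,
combinatorial hypergeometric tails, and seeded simulation experiments scored
against the generator's truth ledger. The oracles deliberately share no code
with the implementations they check.
"""
from __future__ import annotations

import hashlib
from fractions import Fraction
from math import comb
from pathlib import Path

import numpy as np

from .egwas import fisher_gene_p, ranking_auc, run_egwas, vote_count
from .ihc import ScoreTable, chi_square
from .interpret import AnnotationSet, enrich
from .pipeline import RunConfig, run_all
from .sam import sam_analyze
from .synth import CompendiumConfig, generate_compendium


def _hypergeom_pmf_exact(k: int, t: int, m: int, n_all: int) -> Fraction:
    """Exact P(X = k), X ~ Hypergeometric(n_all, m, t), written as products
    of at most t factors so huge-background tables stay cheap:

        C(t,k) * [prod_{i<k} (m-i)] * [prod_{i<t-k} (n_all-m-i)]
               / [prod_{i<t} (n_all-i)]
    """
    num = comb(t, k)
    for i in range(k):
        num *= m - i
    for i in range(t - k):
        num *= n_all - m - i
    den = 1
    for i in range(t):
        den *= n_all - i
    return Fraction(num, den)


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational enumeration of all same-margin
    tables (minimum-likelihood rule)."""
    t, m, n_all = a + b, a + c, a + b + c + d
    lo, hi = max(0, m - (c + d)), min(t, m)
    probs = {k: _hypergeom_pmf_exact(k, t, m, n_all) for k in range(lo, hi + 1)}
    obs = probs[a]
    return float(sum(p for p in probs.values() if p <= obs))


def random_vote_tables(
    n_tables: int, seed: int, max_row_total: int = 13, max_background: int = 1_000_000
) -> list[tuple[int, int, int, int]]:
    """Seeded grid of 2x2 vote tables with gene-row totals <= max_row_total."""
    rng = np.random.default_rng(seed)
    tables = []
    for _ in range(n_tables):
        t = int(rng.integers(1, max_row_total + 1))
        a = int(rng.integers(0, t + 1))
        c = int(rng.integers(0, max_background))
        d = int(rng.integers(1, max_background))
        tables.append((a, t - a, c, d))
    return tables


def fisher_grid_max_rel_err(n_tables: int = 1000, seed: int = 0) -> float:
    """Worst relative disagreement between fisher_gene_p and the exact
    rational oracle over a seeded grid of tables."""
    worst = 0.0
    for a, b, c, d in random_vote_tables(n_tables, seed):
        p = fisher_gene_p(a, b, c, d)
        q = fisher_two_sided_oracle(a, b, c, d)
        worst = max(worst, abs(p - q) / q)
    return worst


def chi2_2x2_closed_form(table: np.ndarray) -> float:
    """Closed-form Pearson statistic N(ad-bc)^2 / (r1 r2 c1 c2)."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def chi2_grid_max_rel_err(n_tables: int = 200, seed: int = 0) -> float:
    """Worst relative disagreement between the chi-square implementation and
    the 2x2 closed form over a seeded grid of positive-margin tables."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        counts = rng.integers(1, 200, size=(2, 2))
        result = chi_square(ScoreTable(["g1", "g2"], ["-", "+"], counts))
        ref = chi2_2x2_closed_form(counts)
        if ref > 0:
            worst = max(worst, abs(result.statistic - ref) / ref)
    return worst


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by rational enumeration."""
    denom = comb(N, n)
    total = sum(
        Fraction(comb(K, j) * comb(N - K, n - j), denom)
        for j in range(k, min(K, n) + 1)
    )
    return float(total)


def enrichment_grid_max_rel_err(n_cases: int = 200, seed: int = 0) -> float:
    """Worst relative disagreement between enrich() p-values and the exact
    combinatorial tail over a seeded grid of random term/hit configurations."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        N = int(rng.integers(10, 120))
        universe = [f"U{i:03d}" for i in range(N)]
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        term = set(rng.choice(universe, size=K, replace=False))
        hits = set(rng.choice(universe, size=n, replace=False))
        rows = enrich(hits, universe, AnnotationSet({"T": term}))
        k = int(rows.loc[0, "k"])
        ref = hypergeom_tail_oracle(k, N, K, n) if k > 0 else 1.0
        worst = max(worst, abs(float(rows.loc[0, "p"]) - ref) / ref)
    return worst


def null_calibration(
    n_seeds: int = 20,
    n_genes: int = 2000,
    B: int = 100,
    fdr_target: float = 0.05,
    alpha: float = 0.05,
    base_seed: int = 100,
) -> dict:
    """Zero-effect compendia: per-experiment SAM call rates and the fraction
    of eGWAS p-values below alpha, over ``n_seeds`` seeded replicates of the
    13-experiment design."""
    call_rates, exceedance = [], []
    for s in range(n_seeds):
        seed = base_seed + s
        cfg = CompendiumConfig(n_genes=n_genes, n_true=0, effect_size=0.0, seed=seed)
        experiments, truth = generate_compendium(cfg)
        call_sets = []
        for i, exp in enumerate(experiments):
            result = sam_analyze(exp, fdr_target=fdr_target, B=B, seed=[seed, 1000 + i])
            call_rates.append(len(result.calls.called) / len(exp.genes))
            call_sets.append(result.calls)
        scored = run_egwas(vote_count(call_sets, truth.universe)).table
        exceedance.append(float((scored["p"] < alpha).mean()))
    call_rates = np.asarray(call_rates)
    exceedance = np.asarray(exceedance)
    # binomial Monte-Carlo SD of a per-run rate, pooled over runs
    mc_sd = np.sqrt(fdr_target * (1 - fdr_target) / n_genes)
    return {
        "call_rate_mean": float(call_rates.mean()),
        "call_rate_bound": fdr_target + 3 * mc_sd / np.sqrt(call_rates.size),
        "n_runs": int(call_rates.size),
        "egwas_exceedance_mean": float(exceedance.mean()),
        "egwas_bound": alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_genes) / np.sqrt(n_seeds),
        "n_genes": n_genes,
    }


def recovery_benchmark(
    seed: int = 1,
    n_genes: int = 2000,
    n_true: int = 20,
    effect_size: float = 1.5,
    activity_prob: float = 0.9,
    coverage: float = 0.9,
    B: int = 100,
    top: int = 50,
) -> dict:
    """Planted-signal compendium: how well does the Fisher ranking recover
    the planted genes?"""
    cfg = CompendiumConfig(
        n_genes=n_genes,
        n_true=n_true,
        effect_size=effect_size,
        activity_prob=activity_prob,
        coverage_fraction=coverage,
        seed=seed,
    )
    experiments, truth = generate_compendium(cfg)
    call_sets = [
        sam_analyze(exp, B=B, seed=[seed, 1000 + i]).calls
        for i, exp in enumerate(experiments)
    ]
    result = run_egwas(vote_count(call_sets, truth.universe))
    scored = result.table
    planted = [g for g in sorted(truth.true_genes) if g in scored.index]
    ranks = scored.loc[planted, "rank"]
    return {
        "n_planted": n_true,
        "n_planted_scored": len(planted),
        "n_in_top": int((ranks <= top).sum()),
        "top": top,
        "max_planted_rank": int(ranks.max()),
        "auc": ranking_auc(result, truth.true_genes),
        "n_significant": len(result.significant),
    }


def _tree_hashes(directory: Path) -> dict[str, str]:
    return {
        str(p.relative_to(directory)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(directory.rglob("*"))
        if p.is_file()
    }


def determinism_check(workdir: str | Path, seed: int = 1) -> dict:
    """Run the full desk-preset pipeline twice with one config+seed and
    compare every output file byte for byte."""
    workdir = Path(workdir)
    config = RunConfig(out_dir=str(workdir / "run"), seed=seed, preset="desk")
    run_all(config)
    first = _tree_hashes(workdir / "run")
    run_all(config)
    second = _tree_hashes(workdir / "run")
    return {
        "identical": first == second,
        "n_files": len(first),
        "differing": sorted(k for k in first if first[k] != second.get(k)),
    }
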