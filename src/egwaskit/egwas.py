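"""Cross-study vote counting and the per-gene Fisher exact meta-statistic.

The method ranks genes by how improbably often they are called differentially
expressed across independent case/control experiments. For each gene g we
tally ``n_pos`` (experiments where g was called up or down) and ``n_neg``
(experiments where g was measured but not called), then test the 2x2 table

    [[n_pos(g),        n_neg(g)       ],
     [N_pos - n_pos(g), N_neg - n_neg(g)]]

— the gene against the pooled votes of all *other* genes — with a two-sided
Fisher exact test. Small p means g is called far more (or less) often than a
typical gene. Candidates are declared below a family-wise threshold, by
default the printed constant 1.0e-5 used in the original 30,663-gene study;
an exact 0.05/G Bonferroni cut is available as an option.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb, inf, log, log1p
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sam import NONE, DECallSet

logger = logging.getLogger(__name__)

#: family-wise significance threshold used by the original study
DEFAULT_THRESHOLD = 1.0e-5

TWO_SIDED = "two-sided"
UPPER = "greater"


@dataclass
class VoteTable:
    """Per-gene counts of positive vs measured-but-negative experiments.

    ``table`` is indexed by gene id with columns ``n_pos``, ``n_neg``,
    ``n_measured``, plus per-direction counts ``n_up`` / ``n_down`` retained
    for inspection.
    """

    table: pd.DataFrame
    n_experiments: int

    @property
    def totals(self) -> tuple[int, int]:
        """(N_pos, N_neg) summed over all genes."""
        return int(self.table["n_pos"].sum()), int(self.table["n_neg"].sum())


@dataclass
class EgwasResult:
    """Ranked meta-analysis output.

    ``table`` (one row per scored gene): n_pos, n_neg, p, rank, significant.
    Genes measured in zero experiments are excluded from scoring and listed
    in ``unmeasured``.
    """

    table: pd.DataFrame
    threshold: float
    unmeasured: list[str] = field(default_factory=list)

    @property
    def significant(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()


def vote_count(call_sets: Sequence[DECallSet], universe: Iterable[str]) -> VoteTable:
    """Tally, per gene, significant vs measured-but-not-significant
    experiments. Experiments not measuring a gene contribute to neither
    count; direction is ignored for ``n_pos`` (up and down both count)."""
    universe = list(universe)
    uni_set = set(universe)
    ids = [cs.experiment_id for cs in call_sets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate experiment ids in call sets")
    counts = pd.DataFrame(
        0, index=pd.Index(universe, name="gene_id"),
        columns=["n_pos", "n_neg", "n_up", "n_down"], dtype=int,
    )
    for cs in call_sets:
        outside = set(cs.table.index) - uni_set
        if outside:
            raise ValueError(
                f"{cs.experiment_id}: calls for genes outside the universe: "
                f"{sorted(outside)[:5]}"
            )
        calls = cs.table["call"]
        pos = calls.index[calls != NONE]
        neg = calls.index[calls == NONE]
        counts.loc[pos, "n_pos"] += 1
        counts.loc[neg, "n_neg"] += 1
        counts.loc[calls.index[calls == "up"], "n_up"] += 1
        counts.loc[calls.index[calls == "down"], "n_down"] += 1
    counts["n_measured"] = counts["n_pos"] + counts["n_neg"]
    cols = ["n_pos", "n_neg", "n_measured", "n_up", "n_down"]
    return VoteTable(counts[cols], n_experiments=len(call_sets))


def _log_pmf(k: int, t: int, m: int, n_all: int) -> float:
    """log P(X=k), X ~ Hypergeometric(n_all, m, t), via the t-factor
    reduction C(t,k) * prod(m-i) * prod(n_all-m-i) / prod(n_all-i); the short
    exact products keep full double precision even for huge backgrounds."""
    lp = log(comb(t, k))
    for i in range(k):
        lp += log(m - i)
    for i in range(t - k):
        lp += log(n_all - m - i)
    for i in range(t):
        lp -= log(n_all - i)
    return lp


@lru_cache(maxsize=200_000)
def _fisher_cached(a: int, b: int, c: int, d: int, alternative: str) -> float:
    t = a + b  # gene row total: support has at most t+1 tables
    m = a + c  # positive-column margin
    n_all = a + b + c + d
    if n_all == 0:
        raise ValueError("zero grand total")
    lo, hi = max(0, m - (c + d)), min(t, m)
    logp = {k: _log_pmf(k, t, m, n_all) for k in range(lo, hi + 1)}
    obs = logp[a]
    if alternative == UPPER:
        sel = [lp for k, lp in logp.items() if k >= a]
    elif alternative == TWO_SIDED:
        # minimum-likelihood rule with a small relative tolerance, in log space
        cut = obs + log1p(1e-7)
        sel = [lp for lp in logp.values() if lp <= cut]
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    mx = max(sel)
    return float(min(1.0, np.exp(mx) * sum(np.exp(lp - mx) for lp in sel)))


def fisher_gene_p(
    n_pos_g: int,
    n_neg_g: int,
    n_pos_rest: int,
    n_neg_rest: int,
    alternative: str = TWO_SIDED,
) -> float:
    """Exact Fisher p for one gene's votes against the pooled background.

    Two-sided by the minimum-likelihood rule (sum of hypergeometric
    probabilities of all same-margin tables no more likely than the observed
    one), computed in log space over the gene-row support; ``greater`` gives
    the upper tail (over-calling) only.
    """
    cells = (n_pos_g, n_neg_g, n_pos_rest, n_neg_rest)
    if any(x < 0 for x in cells):
        raise ValueError("counts must be nonnegative")
    if n_pos_g + n_neg_g < 1:
        raise ValueError("gene must be measured in at least one experiment")
    return _fisher_cached(*cells, alternative)


def run_egwas(
    votes: VoteTable,
    threshold: float = DEFAULT_THRESHOLD,
    bonferroni_exact: bool = False,
    alternative: str = TWO_SIDED,
) -> EgwasResult:
    """Score and rank every measured gene.

    Per gene, the Fisher p is computed with that gene excluded from the
    background sums. Ranking is ascending in p with ties broken by descending
    n_pos then gene id; significance is p < threshold (or p < 0.05/G with
    ``bonferroni_exact``).
    """
    tab = votes.table
    if len(tab) < 2:
        raise ValueError("need a vote table over at least 2 genes")
    measured = tab[tab["n_measured"] > 0].copy()
    unmeasured = tab.index[tab["n_measured"] == 0].tolist()
    if unmeasured:
        logger.info("excluding %d genes measured in zero experiments", len(unmeasured))
    N_pos, N_neg = votes.totals
    measured["p"] = [
        fisher_gene_p(np_g, nn_g, N_pos - np_g, N_neg - nn_g, alternative)
        for np_g, nn_g in zip(measured["n_pos"], measured["n_neg"])
    ]
    if bonferroni_exact:
        threshold = 0.05 / len(measured)
    # ascending p; ties by descending n_pos, then lexicographic gene id
    measured = measured.sort_index().sort_values(
        ["p", "n_pos"], ascending=[True, False], kind="mergesort"
    )
    measured["rank"] = np.arange(1, len(measured) + 1)
    measured["significant"] = measured["p"] < threshold
    return EgwasResult(measured, threshold=threshold, unmeasured=unmeasured)


def manhattan_table(
    result: EgwasResult, positions: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Rows (gene, chrom, position, -log10 p) sorted by chromosome then
    position, plus the -log10 reference line of the significance threshold.
    Scored genes lacking positions are logged and dropped."""
    pos = positions.set_index("gene_id")
    scored = result.table
    missing = [g for g in scored.index if g not in pos.index]
    if missing:
        logger.warning("dropping %d scored genes without positions", len(missing))
    keep = scored.index.intersection(pos.index)
    if keep.empty:
        raise ValueError("positions cover no scored gene")
    out = pd.DataFrame(
        {
            "chrom": pos.loc[keep, "chrom"],
            "position": pos.loc[keep, "start"],
            "neg_log10_p": -np.log10(scored.loc[keep, "p"]),
        },
        index=keep,
    )

    def _chrom_key(c: pd.Series) -> pd.Series:
        def one(v: str) -> tuple[int, str]:
            s = str(v).removeprefix("chr")
            return (int(s), "") if s.isdigit() else (inf, s)

        return c.map(one)

    out = out.sort_values(["chrom", "position"], key=lambda col:
                          _chrom_key(col) if col.name == "chrom" else col)
    return out, float(-np.log10(result.threshold))


def ranking_auc(result: EgwasResult, true_genes: Iterable[str]) -> float:
    """Probability that a random planted gene outranks a random null gene
    (rank-based AUC over the scored table)."""
    from scipy.stats import rankdata

    truth = result.table.index.isin(set(true_genes))
    n1, n0 = int(truth.sum()), int((~truth).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both planted and null genes among scored genes")
    score = -result.table["rank"].to_numpy(dtype=float)  # higher = better
    ranks = rankdata(score)
    return float((ranks[truth].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
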