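"""Two-class unpaired SAM: moderated d-statistic, fudge factor, permutation FDR.

For gene g with case/control samples the relative difference is

    d_g = r_g / (s_g + s0),   r_g = mean(case) - mean(control),
    s_g = sqrt(a * (SS_case + SS_control)),  a = (1/n1 + 1/n2) / (n1 + n2 - 2)

where ``s0`` (the fudge factor) damps the otherwise explosive d of genes with
tiny pooled standard error. Significance is assessed against the expected
order statistics of d under label permutation: gene i (in d-sorted order) is
called when its d departs from the permutation mean order statistic by more
than a threshold delta, and the FDR of the resulting call set is estimated
from the median number of permuted d values falling beyond the call cutoffs,
deflated by an estimate of the true-null fraction pi0.

Label permutations are unrestricted uniform permutations (valid for the
unpaired two-class design) and fully seeded. When the requested number of
permutations exceeds the number of distinct case assignments, the engine
falls back to full enumeration.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .synth import ExpressionExperiment

log = logging.getLogger(__name__)

UP, DOWN, NONE = "up", "down", "none"

#: candidate s0 grid: percentiles of the gene-wise standard errors
S0_PERCENTILES = np.arange(0, 101, 5)


@dataclass
class DECallSet:
    """Per-experiment differential-expression calls.

    ``table`` is indexed by gene id with columns ``d`` (the statistic),
    ``call`` in {up, down, none} and ``q`` (smallest estimated FDR at which
    the gene enters the call set).
    """

    experiment_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.table["call"].unique()) - {UP, DOWN, NONE}
        if bad:
            raise ValueError(f"{self.experiment_id}: invalid calls {sorted(bad)}")

    @property
    def called(self) -> set[str]:
        mask = self.table["call"] != NONE
        return set(self.table.index[mask])


@dataclass
class SamResult:
    """Full SAM output for one experiment (statistics plus calling state)."""

    experiment_id: str
    table: pd.DataFrame  # r, s, d per gene
    s0: float
    dbar: np.ndarray  # expected order statistics of d under permutation
    delta: float
    fdr: float
    calls: DECallSet


def _rsd(X: np.ndarray, case_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n1 = int(case_mask.sum())
    n2 = int((~case_mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples in each class")
    Xc, Xn = X[:, case_mask], X[:, ~case_mask]
    m1, m2 = Xc.mean(axis=1), Xn.mean(axis=1)
    ss1 = ((Xc - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((Xn - m2[:, None]) ** 2).sum(axis=1)
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    return m1 - m2, np.sqrt(a * (ss1 + ss2))


def sam_statistics(experiment: ExpressionExperiment, s0: float = 0.0) -> pd.DataFrame:
    """Per-gene (r, s, d) for one experiment at a given fudge factor."""
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    X = experiment.matrix.to_numpy(dtype=float)
    r, s = _rsd(X, experiment.case_mask)
    denom = s + s0
    if np.any(denom == 0):
        raise ValueError("s + s0 is zero for at least one gene; increase s0")
    return pd.DataFrame({"r": r, "s": s, "d": r / denom}, index=experiment.matrix.index)


def choose_s0(r: np.ndarray, s: np.ndarray, n_bins: int = 100) -> float:
    """Pick the fudge factor minimising the coefficient of variation of d's
    spread across the standard-error range.

    Candidates are the percentiles 0, 5, ..., 100 of s. For each candidate the
    genes are split into ``n_bins`` quantile bins of s, the median absolute
    deviation of d is taken within each bin, and the candidate with the
    smallest CV of those MADs wins; ties go to the smallest s0.
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if r.shape != s.shape:
        raise ValueError("r and s must have the same length")
    if np.ptp(s) == 0:
        return float(s[0])
    candidates = np.percentile(s, S0_PERCENTILES)
    # quantile bins of s are shared by all candidates
    edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
    order = np.argsort(bins, kind="stable")
    bins_sorted = bins[order]
    boundaries = np.flatnonzero(np.diff(bins_sorted)) + 1
    best_cv, best_s0 = np.inf, float(candidates[0])
    for cand in candidates:
        d = r / (s + cand)
        groups = np.split(d[order], boundaries)
        mads = np.array([np.median(np.abs(g - np.median(g))) for g in groups])
        mean = mads.mean()
        cv = np.inf if mean == 0 else mads.std(ddof=1) / mean
        if cv < best_cv - 1e-12 or (abs(cv - best_cv) <= 1e-12 and cand < best_s0):
            best_cv, best_s0 = cv, float(cand)
    return best_s0


def _case_assignments(n: int, n1: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean (n x B) matrix of permuted case assignments; enumerates all
    distinct assignments when B is at least their number."""
    total = comb(n, n1)
    if B >= total:
        M = np.zeros((n, total), dtype=bool)
        for b, idx in enumerate(combinations(range(n), n1)):
            M[list(idx), b] = True
        return M
    M = np.zeros((n, B), dtype=bool)
    for b in range(B):
        M[rng.permutation(n)[:n1], b] = True
    return M


class PermutationNull:
    """Permutation distribution of d for one experiment at a fixed s0.

    Precomputes the (genes x permutations) matrix of permuted d values, the
    expected order statistics ``dbar`` and the pi0 estimate, so delta tuning
    and q-value computation reuse one set of permutations.
    """

    def __init__(
        self,
        experiment: ExpressionExperiment,
        s0: float,
        B: int = 100,
        seed: int = 0,
    ) -> None:
        if B < 50:
            raise ValueError("need at least 50 permutations")
        X = experiment.matrix.to_numpy(dtype=float)
        case_mask = experiment.case_mask
        n, n1 = X.shape[1], int(case_mask.sum())
        rng = np.random.default_rng(seed)
        M = _case_assignments(n, n1, B, rng).astype(float)
        n2 = n - n1
        T, Tsq = X.sum(axis=1), (X**2).sum(axis=1)
        S1 = X @ M
        S1sq = (X**2) @ M
        m1 = S1 / n1
        m2 = (T[:, None] - S1) / n2
        ss1 = S1sq - n1 * m1**2
        ss2 = (Tsq[:, None] - S1sq) - n2 * m2**2
        a = (1.0 / n1 + 1.0 / n2) / (n - 2)
        s_perm = np.sqrt(np.clip(a * (ss1 + ss2), 0.0, None))
        self.d_perm = (m1 - m2) / (s_perm + s0)  # genes x B
        self.dbar = np.sort(self.d_perm, axis=0).mean(axis=1)
        stats_obs = sam_statistics(experiment, s0)
        self.d_obs = stats_obs["d"].to_numpy()
        self.obs_table = stats_obs
        self.genes = stats_obs.index
        self.experiment_id = experiment.experiment_id
        self.s0 = float(s0)
        self.B = self.d_perm.shape[1]
        q25, q75 = np.quantile(self.d_perm, [0.25, 0.75])
        in_iqr = int(((self.d_obs >= q25) & (self.d_obs <= q75)).sum())
        self.pi0 = min(1.0, 2.0 * in_iqr / self.d_obs.size)

    def cutoffs(self, delta: float) -> tuple[float, float]:
        """(cut_low, cut_up): smallest sorted d exceeding its expected order
        statistic by >= delta, and largest falling short by <= -delta.

        The up (down) search is restricted to nonnegative (nonpositive) d, as
        in the standard SAM scan: an excursion above the expected order
        statistic deep in the opposite tail must not set the cutoff.
        """
        d_sorted = np.sort(self.d_obs)
        diff = d_sorted - self.dbar
        up = d_sorted[(diff >= delta) & (d_sorted >= 0)]
        low = d_sorted[(diff <= -delta) & (d_sorted <= 0)]
        cut_up = float(up.min()) if up.size else np.inf
        cut_low = float(low.max()) if low.size else -np.inf
        return cut_low, cut_up

    def call_mask(self, delta: float) -> tuple[np.ndarray, np.ndarray]:
        """(up_mask, down_mask) at a given delta. In the degenerate case
        where the cutoffs overlap, a doubly-eligible gene follows its sign."""
        cut_low, cut_up = self.cutoffs(delta)
        up = self.d_obs >= cut_up
        down = self.d_obs <= cut_low
        both = up & down
        up[both] = self.d_obs[both] >= 0
        down[both] = self.d_obs[both] < 0
        return up, down

    def fdr(self, delta: float) -> float:
        """Estimated FDR at delta: pi0 * median permuted exceedance count
        over the observed call count (0 when nothing is called)."""
        cut_low, cut_up = self.cutoffs(delta)
        up, down = self.call_mask(delta)
        n_called = int(up.sum() + down.sum())
        if n_called == 0:
            return 0.0
        beyond = ((self.d_perm >= cut_up) | (self.d_perm <= cut_low)).sum(axis=0)
        return float(min(1.0, self.pi0 * np.median(beyond) / n_called))

    def delta_grid(self, size: int = 40) -> np.ndarray:
        span = float(np.max(np.abs(np.sort(self.d_obs) - self.dbar)))
        return np.linspace(0.0, span, size)


def _monotone_fdr(fdrs: np.ndarray) -> np.ndarray:
    # running minimum keeps the reported FDR path non-increasing in delta
    return np.minimum.accumulate(fdrs)


def tune_delta(
    experiment: ExpressionExperiment,
    s0: float,
    B: int,
    fdr_target: float,
    seed: int = 0,
    grid_size: int = 40,
    null: PermutationNull | None = None,
) -> float:
    """Smallest delta on a fixed grid whose (monotonised) estimated FDR is at
    most ``fdr_target``. Returns the grid maximum with a warning when no
    delta achieves the target."""
    if not (0.0 < fdr_target <= 1.0):
        raise ValueError("fdr_target must be in (0, 1]")
    null = null or PermutationNull(experiment, s0, B=B, seed=seed)
    grid = null.delta_grid(grid_size)
    fdrs = _monotone_fdr(np.array([null.fdr(delta) for delta in grid]))
    ok = np.flatnonzero(fdrs <= fdr_target)
    if ok.size == 0:
        log.warning(
            "%s: no delta on the grid reaches FDR <= %g (min %.3g); using grid max",
            experiment.experiment_id, fdr_target, fdrs.min(),
        )
        return float(grid[-1])
    return float(grid[ok[0]])


def _qvalues(null: PermutationNull, grid: np.ndarray) -> np.ndarray:
    """Per-gene q: the smallest monotonised FDR at which the gene is called,
    scanned over the delta grid (1 for genes never called)."""
    fdrs = _monotone_fdr(np.array([null.fdr(d) for d in grid]))
    q = np.ones(null.d_obs.size)
    for delta, fdr in zip(grid, fdrs):
        up, down = null.call_mask(delta)
        called = up | down
        q[called] = np.minimum(q[called], fdr)
    return q


def sam_permutation_calls(
    experiment: ExpressionExperiment,
    s0: float,
    B: int,
    delta: float,
    seed: int = 0,
    null: PermutationNull | None = None,
) -> tuple[DECallSet, float]:
    """Call genes at a fixed delta and estimate the FDR of the call set."""
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    null = null or PermutationNull(experiment, s0, B=B, seed=seed)
    up, down = null.call_mask(delta)
    call = np.where(up, UP, np.where(down, DOWN, NONE))
    q = _qvalues(null, null.delta_grid())
    table = pd.DataFrame({"d": null.d_obs, "call": call, "q": q}, index=null.genes)
    return DECallSet(null.experiment_id, table), null.fdr(delta)


def sam_analyze(
    experiment: ExpressionExperiment,
    fdr_target: float = 0.05,
    B: int = 100,
    seed: int = 0,
    s0: float | None = None,
    delta: float | None = None,
    grid_size: int = 40,
) -> SamResult:
    """End-to-end SAM for one experiment: s0 selection, permutation null,
    delta tuning to the FDR target, calls and q-values."""
    base = sam_statistics(experiment, 0.0)
    if s0 is None:
        s0 = choose_s0(base["r"].to_numpy(), base["s"].to_numpy())
    null = PermutationNull(experiment, s0, B=B, seed=seed)
    if delta is None:
        delta = tune_delta(experiment, s0, B, fdr_target, seed=seed,
                           grid_size=grid_size, null=null)
    calls, fdr = sam_permutation_calls(experiment, s0, B, delta, seed=seed, null=null)
    return SamResult(experiment.experiment_id, null.obs_table, s0, null.dbar,
                     delta, fdr, calls)


def ttest_bh_calls(
    experiment: ExpressionExperiment, fdr_target: float = 0.05
) -> DECallSet:
    """Fallback DE engine: Welch t-test with Benjamini-Hochberg adjustment.

    A conventional alternative to SAM used as a cross-check; ``d`` holds the
    Welch t statistic and ``q`` the BH-adjusted p-value.
    """
    from statsmodels.stats.multitest import multipletests

    X = experiment.matrix.to_numpy(dtype=float)
    case = experiment.case_mask
    t, p = stats.ttest_ind(X[:, case], X[:, ~case], axis=1, equal_var=False)
    padj = multipletests(p, method="fdr_bh")[1]
    sig = padj <= fdr_target
    call = np.where(sig & (t > 0), UP, np.where(sig & (t < 0), DOWN, NONE))
    table = pd.DataFrame({"d": t, "call": call, "q": padj},
                         index=experiment.matrix.index)
    return DECallSet(experiment.experiment_id, table)
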