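"""Intensity-difference differential-expression screen.

A gene's between-group difference is judged against the empirical
distribution of differences among genes of *similar average intensity*:
genes are ranked by their overall mean log expression, and for each gene
the mean and SD of the between-group differences are estimated inside a
sliding window of the ``w`` rank-nearest genes.  The resulting z-score is
referred to a normal tail (the window supplies a large empirical null
sample).  This makes the screen robust to the strong mean–variance
relationship of expression data without fitting a count model.

Per gene, evidence is combined across group pairs through the extreme
pairwise z-score (a gene differential anywhere in the time course is of
interest) referred to its exact null — the studentized-range distribution
for all-pairs comparisons — and then Benjamini–Hochberg adjusted across
genes.
"""
from __future__ import annotations

import functools
import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

MIN_WINDOW = 50


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DataError("bh_adjust expects a non-empty 1-d vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@functools.lru_cache(maxsize=8)
def _range_sf_table(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Survival function of the range of ``k`` iid standard normals,
    tabulated on a grid (``P(W_k > w) = 1 - k * int phi(u) [Phi(u+w) -
    Phi(u)]^{k-1} du``)."""
    u = np.linspace(-8.5, 8.5, 1701)
    phi = norm.pdf(u)
    cdf_u = norm.cdf(u)
    grid = np.linspace(0.0, 16.0, 1601)
    cdf = np.empty_like(grid)
    for i, w in enumerate(grid):
        inner = np.maximum(norm.cdf(u + w) - cdf_u, 0.0) ** (k - 1)
        cdf[i] = k * np.trapezoid(phi * inner, u)
    sf = np.clip(1.0 - cdf, 0.0, 1.0)
    return grid, sf


def range_survival(w, k: int) -> np.ndarray:
    """``P(range of k iid N(0,1) > w)``, the exact multiplicity-corrected
    tail for the maximum absolute pairwise z-score among ``k`` equal-size
    groups (``max |z| = range / sqrt(2)``).  For ``k = 2`` this reduces to
    the two-sided normal tail of a single comparison."""
    grid, sf = _range_sf_table(k)
    return np.interp(np.asarray(w, dtype=float), grid, sf)


def _window_bounds(n: int, w: int) -> np.ndarray:
    """Start of the rank window for every sorted position.

    Windows are contiguous in intensity rank, centred on the gene's own
    position and clipped at the ends so every window holds exactly ``w``
    genes (the gene itself included).
    """
    return np.clip(np.arange(n) - (w - 1) // 2, 0, n - w)


#: Trim threshold (in MAD-scaled SDs) and the matching normal-consistency
#: variance factor Var[N(0,1) | |z| < 2.5] = 1 - 2*2.5*phi(2.5)/(2*Phi(2.5)-1).
_TRIM_Z = 2.0
_TRIM_VAR = 1.0 - 2.0 * _TRIM_Z * norm.pdf(_TRIM_Z) / (2.0 * norm.cdf(_TRIM_Z) - 1.0)
_TRIM_ITER = 3
_FINAL_Z = 2.5
_FINAL_VAR = 1.0 - 2.0 * _FINAL_Z * norm.pdf(_FINAL_Z) / (2.0 * norm.cdf(_FINAL_Z) - 1.0)


def _running_median(v: np.ndarray, span: int) -> np.ndarray:
    """Centred running median with clipped (shrinking) edge windows:
    position ``i`` uses ``v[max(0, i - span//2) : i + span//2 + 1]``."""
    half = span // 2
    out = np.empty_like(v, dtype=float)
    for i in range(v.size):
        out[i] = np.median(v[max(0, i - half) : i + half + 1])
    return out


def _window_mean_sd(
    d_sorted: np.ndarray, w: int, robust: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Null mean and SD of ``d`` inside each sliding rank window.

    The window is the local null sample, but it inevitably contains some of
    the very differential genes the screen is after, which inflates a plain
    SD and destroys power once the signal fraction is non-trivial.  The
    robust estimator therefore starts from the window median and MAD,
    discards entries beyond ``2.5`` scaled SDs, recomputes mean/SD (ddof=1,
    with the normal-consistency correction for the trimming) and iterates
    the trim a fixed number of times so the scale converges onto the null
    bulk.  ``robust=False`` gives the plain mean/SD of the whole window.
    """
    n = d_sorted.size
    starts = _window_bounds(n, w)
    uniq = np.arange(n - w + 1)
    windows = np.lib.stride_tricks.sliding_window_view(d_sorted, w)  # (n-w+1, w)
    if not robust:
        mu_u = windows.mean(axis=1)
        sd_u = windows.std(axis=1, ddof=1)
        return mu_u[starts], sd_u[starts]
    med = np.median(windows, axis=1)
    mad = np.median(np.abs(windows - med[:, None]), axis=1)
    centre = med
    # MAD start; the trim radius is monotone non-increasing across
    # iterations so the scale converges down onto the null bulk instead of
    # re-admitting the fringe of a separated signal cluster
    radius = _TRIM_Z * 1.4826 * mad
    for _ in range(_TRIM_ITER):
        keep = np.abs(windows - centre[:, None]) <= np.where(radius > 0, radius, np.inf)[:, None]
        k = keep.sum(axis=1)
        s = np.where(keep, windows, 0.0).sum(axis=1)
        s2 = np.where(keep, windows**2, 0.0).sum(axis=1)
        centre = s / k
        scale = np.sqrt(np.maximum(s2 - s * s / k, 0.0) / np.maximum(k - 1, 1) / _TRIM_VAR)
        radius = np.minimum(radius, _TRIM_Z * scale)
    # final pass at a wider radius around the converged scale: uses nearly
    # the whole null bulk (lower estimator noise) while still excluding a
    # well-separated signal cluster
    radius = _FINAL_Z * scale
    keep = np.abs(windows - centre[:, None]) <= np.where(radius > 0, radius, np.inf)[:, None]
    k = keep.sum(axis=1)
    s = np.where(keep, windows, 0.0).sum(axis=1)
    s2 = np.where(keep, windows**2, 0.0).sum(axis=1)
    mu_u = s / k
    var_u = np.maximum(s2 - s * s / k, 0.0) / np.maximum(k - 1, 1) / _FINAL_VAR
    # variance-trend smoothing: the true scale is a smooth function of
    # intensity rank, so a running median across neighbouring windows
    # removes per-window estimator noise (which otherwise inflates the far
    # z tail).  The span is several window lengths because adjacent windows
    # share w-1 genes and their estimation errors are strongly correlated.
    var_u = _running_median(var_u, span=5 * w)
    # a zero-MAD window (ties) falls back to the plain estimator
    degenerate = mad == 0
    if degenerate.any():
        mu_u[degenerate] = windows[degenerate].mean(axis=1)
        var_u[degenerate] = windows[degenerate].var(axis=1, ddof=1)
    assert len(mu_u) == len(uniq)
    return mu_u[starts], np.sqrt(var_u)[starts]


@dataclass
class DEResult:
    """Per-gene screen results plus the per-pair statistics behind them.

    ``table`` has one row per gene: mean intensity, the combined raw p (the
    extreme pairwise z referred to its multiplicity-corrected null),
    BH-adjusted p, significance flag, and the pair and z-score that were
    most extreme.  ``pair_stats`` is the long table of
    per-(pair, gene) differences, window statistics, z and raw p.
    """

    table: pd.DataFrame
    pair_stats: pd.DataFrame
    alpha: float
    window: int
    mode: str

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def intensity_difference_filter(
    matrix: ExpressionMatrix,
    group_key: str = "replicate_group",
    window_fraction: float = 0.01,
    alpha: float = 0.05,
    mode: str = "pairwise",
    robust: bool = True,
) -> DEResult:
    """Run the intensity-difference screen on a log-scale matrix.

    ``mode="pairwise"`` compares every pair of sample groups;
    ``mode="vs-rest"`` compares each group against the pooled mean of all
    other samples.  ``robust`` selects the trimmed window estimator (see
    :func:`_window_mean_sd`); genes inside a zero-variance window get
    p = 1 (logged).
    """
    if matrix.scale not in ("log", "log_centered"):
        raise DataError(f"intensity-difference filter expects log-scale data, got {matrix.scale!r}")
    if not 0 < window_fraction <= 1:
        raise ConfigError("window_fraction must be in (0, 1]")
    if not 0 < alpha < 1:
        raise ConfigError("alpha must be in (0, 1)")
    if mode not in ("pairwise", "vs-rest"):
        raise ConfigError(f"mode must be 'pairwise' or 'vs-rest', got {mode!r}")
    groups = matrix.sample_groups(group_key)
    if len(groups) < 2:
        raise DataError("need at least 2 sample groups")
    n = matrix.n_genes
    w = max(MIN_WINDOW, int(round(window_fraction * n)))
    if w > n:
        raise DataError(f"fewer genes ({n}) than the minimum window ({w})")

    x = matrix.values.to_numpy(dtype=float)
    genes = matrix.values.index
    a = x.mean(axis=1)
    order = np.argsort(a, kind="stable")  # ties broken by gene order
    pos = np.empty(n, dtype=int)
    pos[order] = np.arange(n)

    group_means = {g: x[:, [matrix.sample_ids.index(s) for s in members]].mean(axis=1) for g, members in groups.items()}
    if mode == "pairwise":
        comparisons = [(g, h) for g, h in itertools.combinations(groups.keys(), 2)]
    else:
        all_cols = np.arange(matrix.n_samples)
        comparisons = []
        rest_means = {}
        for g, members in groups.items():
            cols = [matrix.sample_ids.index(s) for s in members]
            rest = np.setdiff1d(all_cols, cols)
            rest_means[g] = x[:, rest].mean(axis=1)
            comparisons.append((g, "rest"))

    records = []
    max_abs_z = np.zeros(n)
    min_p = np.ones(n)
    best_z = np.zeros(n)
    best_pair = np.array([""] * n, dtype=object)
    n_sigma_zero = 0
    for g, h in comparisons:
        d = (rest_means[g] if h == "rest" else group_means[h]) - group_means[g]
        if h == "rest":
            d = -d  # group minus rest, so positive z means elevated in g
        mu_pos, sd_pos = _window_mean_sd(d[order], w, robust=robust)
        mu = mu_pos[pos]
        sd = sd_pos[pos]
        ok = sd > 0
        n_sigma_zero += int((~ok).sum())
        z = np.where(ok, (d - mu) / np.where(ok, sd, 1.0), 0.0)
        p = np.where(ok, 2.0 * norm.sf(np.abs(z)), 1.0)
        records.append(
            pd.DataFrame(
                {
                    "pair": f"{g}.vs.{h}",
                    "gene_id": genes,
                    "diff": d,
                    "window_mean": mu,
                    "window_sd": sd,
                    "z": z,
                    "p": p,
                }
            )
        )
        better = np.abs(z) > np.abs(best_z)
        max_abs_z = np.maximum(max_abs_z, np.abs(z))
        min_p = np.minimum(min_p, p)
        best_z = np.where(better, z, best_z)
        best_pair = np.where(better, f"{g}.vs.{h}", best_pair)
    if n_sigma_zero:
        log.warning("%d (pair, gene) windows had zero SD; p set to 1 for those genes", n_sigma_zero)

    # evidence combination across comparisons: the per-gene statistic is the
    # extreme z, whose null distribution is known exactly for all-pairs
    # comparisons of equal-size groups (the studentized range); an
    # uncorrected minimum p would be anticonservative by roughly the number
    # of effective comparisons.  vs-rest comparisons are not exchangeable
    # pairs, so they get a Sidak correction instead.
    if mode == "pairwise":
        combined_p = range_survival(np.sqrt(2.0) * max_abs_z, k=len(groups))
    else:
        combined_p = 1.0 - (1.0 - min_p) ** len(comparisons)
    p_adj = bh_adjust(combined_p)
    table = pd.DataFrame(
        {
            "mean_intensity": a,
            "combined_p": combined_p,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
            "best_pair": best_pair,
            "best_z": best_z,
        },
        index=genes,
    )
    return DEResult(
        table=table,
        pair_stats=pd.concat(records, ignore_index=True),
        alpha=alpha,
        window=w,
        mode=mode,
    )
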