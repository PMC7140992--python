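"""Procrustes ANOVA with residual-randomization inference, and repeatability.

Aligned shapes are flattened to 2k-vectors and decomposed sequentially
(Type I) along an ordered, hierarchically nested factor list: each model term
refines the grouping of the terms before it (species > individuals > device >
observers > trials), so effect sums of squares are differences between
successive group-mean projections, pooled over all coordinates.

Significance uses the residual randomization permutation procedure (RRPP):
for each term, residuals of the reduced model holding all preceding terms are
permuted across records, the term's statistic is recomputed, and
``p = (count of permuted >= observed + 1) / (nperm + 1)``.  Effect sizes Z
are standard deviates of the log-transformed statistic against its
permutation distribution.

Repeatability follows the classic variance-component protocol for repeated
measurements: ``s2_among = (MS_among - MS_within) / m`` (floored at zero),
``R = s2_among / (s2_among + s2_within)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .gpa_core import AlignedDataset, gpa
from .landmark_io import DatasetError, LandmarkDataset

__all__ = [
    "procrustes_anova",
    "pairwise_error",
    "repeatability",
    "RepeatabilityResult",
]


@dataclass
class RepeatabilityResult:
    """Repeatability R of repeated measurements on the same individuals."""

    ms_among: float
    ms_within: float
    m: int
    s2_among: float
    s2_within: float
    r: float  # in [0, 1]; NaN when both variance components vanish


def repeatability(ms_among: float, ms_within: float, m: int) -> RepeatabilityResult:
    """Repeatability from among/within mean squares with ``m`` replicates.

    ``R = s2_among / (s2_among + s2_within)`` with
    ``s2_among = (ms_among - ms_within) / m`` floored at zero (a negative
    among-individual component is reported as 0, not as negative
    repeatability).  When both components are zero R is undefined and NaN is
    returned.
    """
    if m < 2:
        raise ValueError(f"repeatability needs m >= 2 replicates, got {m}")
    if ms_among < 0 or ms_within < 0:
        raise ValueError("mean squares must be non-negative")
    s2_within = float(ms_within)
    s2_among = max((float(ms_among) - s2_within) / m, 0.0)
    total = s2_among + s2_within
    r = float("nan") if total == 0.0 else min(max(s2_among / total, 0.0), 1.0)
    return RepeatabilityResult(ms_among=float(ms_among), ms_within=float(ms_within),
                               m=int(m), s2_among=s2_among, s2_within=s2_within, r=r)


# ---------------------------------------------------------------------------
# Procrustes ANOVA


def _groupings(factors: pd.DataFrame, model) -> list[tuple[np.ndarray, int]]:
    """Integer group codes for each cumulative (nested) grouping level."""
    levels = []
    g_prev = 1
    for i, term in enumerate(model):
        cols = list(model[: i + 1])
        codes = factors.groupby(cols, sort=True).ngroup().to_numpy()
        g = int(codes.max()) + 1
        if g <= g_prev:
            raise ValueError(
                f"term {term!r} adds no degrees of freedom "
                f"(single level within the preceding grouping?)"
            )
        levels.append((codes, g))
        g_prev = g
    return levels


def _mean_operator(codes: np.ndarray, g: int, n: int) -> sparse.csr_matrix:
    counts = np.bincount(codes, minlength=g).astype(float)
    data = 1.0 / counts[codes]
    return sparse.csr_matrix((data, (codes, np.arange(n))), shape=(g, n))


def procrustes_anova(coords, factors: pd.DataFrame, model, nperm: int = 999,
                     seed=None) -> pd.DataFrame:
    """Sequential (Type I) ANOVA of flattened shape coordinates with RRPP.

    Parameters
    ----------
    coords
        ``(n, k, 2)`` aligned shapes, an :class:`AlignedDataset`, or an
        ``(n, p)`` matrix (``p = 1`` recovers classic univariate ANOVA).
    factors
        One row per record with a column for every name in ``model``.
    model
        Ordered factor names; each successive term is treated as nested
        within the crossing of all preceding terms.
    nperm
        Number of random permutations (999 in the standard protocol); with
        the observed arrangement the p denominator is ``nperm + 1``.
    seed
        Seed for the permutation stream; fixed seed gives bit-reproducible
        tables.

    Returns a DataFrame with columns effect/df/SS/MS/R2/F/Z/p, plus a
    Residual row when the finest grouping does not exhaust the records.  A
    term whose entering model leaves no residual degrees of freedom has no F
    ratio; its permutation statistic is the effect mean square.
    """
    if isinstance(coords, AlignedDataset):
        y = coords.flat()
    else:
        y = np.asarray(coords, float)
        if y.ndim == 3:
            y = y.reshape(y.shape[0], -1)
    n = y.shape[0]
    if len(factors) != n:
        raise ValueError(f"{len(factors)} factor rows for {n} records")
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    model = list(model)
    levels = _groupings(factors.reset_index(drop=True), model)
    ops = [_mean_operator(codes, g, n) for codes, g in levels]
    codes_list = [codes for codes, _ in levels]

    def fits(mat):
        """Successive group-mean projections: grand mean, then each level."""
        out = [np.broadcast_to(mat.mean(axis=0), mat.shape)]
        for op, codes in zip(ops, codes_list):
            out.append((op @ mat)[codes])
        return out

    rng = np.random.default_rng(seed)
    fit_obs = fits(y)
    ss_total = float(((y - fit_obs[0]) ** 2).sum())
    ss_resid = float(((y - fit_obs[-1]) ** 2).sum())
    df_resid = n - levels[-1][1]

    rows = []
    for i, term in enumerate(model):
        g_prev = 1 if i == 0 else levels[i - 1][1]
        g_cur = levels[i][1]
        df = g_cur - g_prev
        ss = float(((fit_obs[i + 1] - fit_obs[i]) ** 2).sum())
        ms = ss / df
        # denominator: residual of the model in which the term enters
        ss_below = float(((y - fit_obs[i + 1]) ** 2).sum())
        df_below = n - g_cur
        if df_below > 0:
            ms_below = ss_below / df_below
            f_obs = ms / ms_below if ms_below > 0 else (np.inf if ms > 0 else np.nan)
        else:
            f_obs = np.nan
        stat_obs = f_obs if df_below > 0 else ms

        # RRPP: permute residuals of the reduced model (terms before this one)
        reduced = fit_obs[i]
        resid = y - reduced
        op_cur, codes_cur = ops[i], codes_list[i]
        stats = np.empty(nperm)
        for b in range(nperm):
            yp = reduced + resid[rng.permutation(n)]
            if i == 0:
                fit_lo = np.broadcast_to(yp.mean(axis=0), yp.shape)
            else:
                fit_lo = (ops[i - 1] @ yp)[codes_list[i - 1]]
            fit_hi = (op_cur @ yp)[codes_cur]
            ss_p = float(((fit_hi - fit_lo) ** 2).sum())
            if df_below > 0:
                ss_below_p = float(((yp - fit_hi) ** 2).sum())
                if ss_below_p > 0:
                    stats[b] = (ss_p / df) / (ss_below_p / df_below)
                else:
                    stats[b] = np.inf if ss_p > 0 else np.nan
            else:
                stats[b] = ss_p / df
        finite_obs = np.isfinite(stat_obs)
        tol = 1e-12 * max(abs(stat_obs) if finite_obs else 1.0, 1.0)
        with np.errstate(invalid="ignore"):
            n_ge = int(np.sum(stats >= (stat_obs - tol if finite_obs else np.inf)))
        p = (1 + n_ge) / (nperm + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_all = np.log(np.concatenate([[stat_obs], stats]))
            log_all = log_all[np.isfinite(log_all)]
            sd = log_all.std(ddof=1) if log_all.size > 1 else 0.0
            z = (np.log(stat_obs) - log_all.mean()) / sd if sd > 0 else np.nan
        rows.append({"effect": term, "df": df, "SS": ss, "MS": ms,
                     "R2": ss / ss_total if ss_total > 0 else np.nan,
                     "F": f_obs, "Z": float(z), "p": p})

    if df_resid > 0:
        rows.append({"effect": "Residual", "df": df_resid, "SS": ss_resid,
                     "MS": ss_resid / df_resid,
                     "R2": ss_resid / ss_total if ss_total > 0 else np.nan,
                     "F": np.nan, "Z": np.nan, "p": np.nan})
    table = pd.DataFrame(rows, columns=["effect", "df", "SS", "MS", "R2", "F", "Z", "p"])
    table.attrs["ss_total"] = ss_total
    table.attrs["df_total"] = n - 1
    table.attrs["nperm"] = nperm
    return table


def pairwise_error(data_a: LandmarkDataset, data_b: LandmarkDataset,
                   nperm: int = 999, seed=None, tol: float = 1e-8,
                   max_iter: int = 100):
    """Two-level error decomposition of one replicated dataset pair.

    The two datasets (same specimens measured twice) are jointly
    re-superimposed by a single GPA, then decomposed into among-individual
    and within-individual (replicate, m = 2) variation.  The replicate term's
    R2 is the pairwise error measure ("ProcANOVA R2 %"); repeatability is
    computed from the two mean squares.

    Returns ``(anova_table, RepeatabilityResult)``.
    """
    ids_a, ids_b = set(data_a.specimen_ids), set(data_b.specimen_ids)
    if ids_a != ids_b:
        diff = sorted(ids_a.symmetric_difference(ids_b))
        raise DatasetError(f"specimen sets differ between datasets: {diff}")
    order = data_a.specimen_ids
    data_b = data_b.reordered(order)
    stacked = np.concatenate([data_a.coords_array(), data_b.coords_array()])
    aligned = gpa(stacked, tol=tol, max_iter=max_iter)
    factors = pd.DataFrame({
        "specimen": order + order,
        "replicate": ["r1"] * len(order) + ["r2"] * len(order),
    })
    table = procrustes_anova(aligned.shapes, factors, ["specimen", "replicate"],
                             nperm=nperm, seed=seed)
    ms_among = float(table.loc[table["effect"] == "specimen", "MS"].iloc[0])
    ms_within = float(table.loc[table["effect"] == "replicate", "MS"].iloc[0])
    rep = repeatability(ms_among, ms_within, m=2)
    return table, rep
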