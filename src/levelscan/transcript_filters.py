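"""RNA-seq normalization/noise-filter chain and junction/polyA classifiers.

The expression chain assumes gene-length-normalized counts arrive from
upstream quantification and proceeds: counts-per-million within sample, a
pedestal of 2 before log2 (stabilizing low counts), cyclic loess across
samples, a per-condition CV~mean noise model whose threshold removes
noise-biased genes, and Welch t differential testing on the survivors.

Two rule-based classifiers operate on upstream event tables: splice
junctions are *cryptic* when they gain inclusion in the knockdown
(delta-PSI > 10%) while being present in fewer than 5% of control samples
(or the mirrored loss rule), and polyA events are lengthening/shortening
calls at |compositional fold change| >= 0.25 with FDR < 0.05.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .screen_scoring import bh_fdr

__all__ = [
    "cpm_pedestal_log2",
    "cyclic_loess_normalize",
    "noise_filter",
    "differential_expression",
    "classify_junctions",
    "filter_polya_events",
    "outlier_report",
]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def cpm_pedestal_log2(matrix: pd.DataFrame, pedestal: float = 2.0) -> pd.DataFrame:
    """log2(CPM + pedestal) per sample; CPM columns sum to 1e6 beforehand."""
    mat = matrix.to_numpy(dtype=float)
    colsum = mat.sum(axis=0)
    if np.any(colsum <= 0):
        bad = [c for c, t in zip(matrix.columns, colsum) if t <= 0]
        raise ValueError(f"zero-sum sample column(s): {bad}")
    cpm = mat * (1e6 / colsum)
    return pd.DataFrame(
        np.log2(cpm + pedestal), index=matrix.index, columns=matrix.columns
    )


def cyclic_loess_normalize(
    log_matrix: pd.DataFrame, iterations: int = 3, frac: float = 0.3
) -> pd.DataFrame:
    """Remove intensity-dependent between-sample bias by cyclic loess.

    For every sample pair a lowess trend of M = x_i - x_j against
    A = (x_i + x_j)/2 is fitted and half of it subtracted from each member.
    Corrections from all pairs are accumulated and applied simultaneously at
    the end of each iteration, scaled by 2/n — for a constant per-sample
    offset this removes the deviation from the sample consensus exactly in
    one iteration — which also makes the result independent of pair
    ordering.  The lowess smoother is linear in M, so swapping the members
    of a pair flips the fitted trend exactly and the update is symmetric.
    """
    X = log_matrix.to_numpy(dtype=float).copy()
    n = X.shape[1]
    if n < 2:
        warnings.warn("cyclic loess needs >= 2 samples; returning input")
        return log_matrix.copy()
    for _ in range(iterations):
        adj = np.zeros_like(X)
        for i in range(n):
            for j in range(i + 1, n):
                A = (X[:, i] + X[:, j]) / 2.0
                M = X[:, i] - X[:, j]
                f = lowess(M, A, frac=frac, return_sorted=False)
                adj[:, i] -= f / 2.0
                adj[:, j] += f / 2.0
        X += adj * (2.0 / n)
    return pd.DataFrame(X, index=log_matrix.index, columns=log_matrix.columns)


# ---------------------------------------------------------------------------
# Noise filter
# ---------------------------------------------------------------------------


def noise_filter(
    normalized: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    pedestal: float = 2.0,
    cv_scale: str = "linear",
    ceiling_mads: float = 2.0,
    lowess_frac: float = 0.3,
) -> tuple[pd.DataFrame, dict[str, float], pd.DataFrame]:
    """Remove genes in the low-mean/high-CV noise regime, per condition.

    For each condition the per-gene mean and CV are computed (by default on
    the linearized scale ``2**value - pedestal``; ``cv_scale="log"`` uses the
    log-scale values directly), a lowess CV~mean trend is fitted against
    log10(mean) — expression spans orders of magnitude, so the smoother
    bandwidth must be multiplicative — and the noise threshold is the
    expression level where the fitted trend crosses a CV ceiling of
    median(CV) + ``ceiling_mads`` * MAD(CV) coming down.  A gene is
    noise-biased — and removed — only if its mean falls below the threshold
    in *every* condition.

    Returns ``(kept_matrix, thresholds_by_group, report)`` where the report
    table carries per-gene means, CVs and the removal flag.
    """
    groups = pd.Series(groups)
    sample_cols = list(normalized.columns)
    if not set(sample_cols) <= set(groups.index):
        raise ValueError("every sample needs a group label")

    report = pd.DataFrame(index=normalized.index)
    thresholds: dict[str, float] = {}
    below = np.ones(len(normalized), dtype=bool)
    for gname in pd.unique(groups.loc[sample_cols]):
        cols = [s for s in sample_cols if groups[s] == gname]
        if len(cols) < 2:
            raise ValueError(f"group {gname!r} needs >= 2 samples")
        vals = normalized[cols].to_numpy(dtype=float)
        if cv_scale == "linear":
            vals = np.maximum(2.0**vals - pedestal, 0.0)
        mean = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, sd / mean, np.inf)
        finite = np.isfinite(cv) & (mean > 0)
        med = float(np.median(cv[finite]))
        mad = float(np.median(np.abs(cv[finite] - med)))
        ceiling = med + ceiling_mads * mad

        fit = lowess(cv[finite], np.log10(mean[finite]),
                     frac=lowess_frac, return_sorted=True)
        xs, ys = fit[:, 0], fit[:, 1]
        thr = _crossing_point(xs, ys, ceiling)
        thr = 10.0**thr if thr is not None else None
        if thr is None:  # degenerate: trend never exceeds the ceiling
            thr = float(mean[finite].min())
            warnings.warn(
                f"CV trend for group {gname!r} never exceeds the ceiling; "
                "noise threshold set to the minimum mean (nothing filtered)"
            )
        thresholds[str(gname)] = thr
        below &= mean < thr
        report[f"mean_{gname}"] = mean
        report[f"cv_{gname}"] = cv
    report["noise_biased"] = below
    kept = normalized.loc[~below]
    return kept, thresholds, report


def _crossing_point(xs: np.ndarray, ys: np.ndarray, ceiling: float) -> float | None:
    """First downward crossing of a fitted trend through the ceiling.

    The trend is evaluated on the sorted mean grid; the threshold is the
    linearly interpolated x where the fit drops below the ceiling, i.e. the
    largest mean that is still noise-dominated.  None when the trend starts
    below the ceiling already.
    """
    above = ys > ceiling
    if not above.any():
        return None
    if above.all():
        return float(xs[-1])
    # last index that is above the ceiling before staying below
    idx = int(np.max(np.flatnonzero(above)))
    if idx + 1 >= xs.size:
        return float(xs[-1])
    x0, x1 = xs[idx], xs[idx + 1]
    y0, y1 = ys[idx], ys[idx + 1]
    if y0 == y1:
        return float(x1)
    t = (ceiling - y0) / (y1 - y0)
    return float(x0 + t * (x1 - x0))


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def differential_expression(
    matrix: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    group_a: str,
    group_b: str,
    lfc_cut: float = 1.0,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch t-test of group_b vs group_a on normalized values.

    Zero-variance genes take an exact-equality fast path (p = 1 when the
    group means agree).  Reports BH q-values and up/down calls at the
    configured |lfc| and p cuts; the lfc is the difference of group means on
    the log2 scale.
    """
    groups = pd.Series(groups)
    a_cols = [s for s in matrix.columns if groups.get(s) == group_a]
    b_cols = [s for s in matrix.columns if groups.get(s) == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    A = matrix[a_cols].to_numpy(dtype=float)
    B = matrix[b_cols].to_numpy(dtype=float)
    lfc = B.mean(axis=1) - A.mean(axis=1)

    tiny = np.finfo(float).tiny
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(B, A, axis=1, equal_var=False).pvalue
    zero_var = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    p = np.where(zero_var, np.where(lfc == 0, 1.0, tiny), p)
    p = np.clip(np.nan_to_num(p, nan=1.0), tiny, 1.0)

    out = pd.DataFrame(
        {
            "gene": matrix.index,
            "lfc": lfc,
            "p": p,
            "q": bh_fdr(p),
        }
    ).reset_index(drop=True)
    out["call"] = "none"
    sig = (np.abs(out["lfc"]) >= lfc_cut) & (out["q"] < p_cut)
    out.loc[sig & (out["lfc"] > 0), "call"] = "up"
    out.loc[sig & (out["lfc"] < 0), "call"] = "down"
    return out


# ---------------------------------------------------------------------------
# Junction and polyA classifiers
# ---------------------------------------------------------------------------


def classify_junctions(
    psi: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    control_group: str = "control",
    test_group: str = "knockdown",
    dpsi_cut: float = 0.10,
    presence_low: float = 0.05,
    presence_high: float = 0.10,
    detection_floor: float = 0.01,
) -> pd.DataFrame:
    """Classify splice junctions from a PSI table.

    delta-PSI is mean(test) - mean(control); a junction is *present* in a
    sample when PSI exceeds the detection floor.  Classes:

    * ``cryptic_gain`` — dpsi > dpsi_cut and control presence < presence_low
    * ``cryptic_loss`` — dpsi < -dpsi_cut and control presence > presence_high
    * ``significant_noncryptic`` — |dpsi| > dpsi_cut otherwise
    * ``none`` — below threshold
    """
    groups = pd.Series(groups)
    sample_cols = [c for c in psi.columns if c in groups.index]
    meta_cols = [c for c in psi.columns if c not in groups.index]
    vals = psi[sample_cols].to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("PSI values must lie in [0, 1]")
    ctrl = [s for s in sample_cols if groups[s] == control_group]
    test = [s for s in sample_cols if groups[s] == test_group]
    if not ctrl or not test:
        raise ValueError("both groups must be represented in the PSI table")

    dpsi = psi[test].mean(axis=1).to_numpy() - psi[ctrl].mean(axis=1).to_numpy()
    presence = (psi[ctrl].to_numpy(dtype=float) > detection_floor).mean(axis=1)

    cls = np.full(len(psi), "none", dtype=object)
    big = np.abs(dpsi) > dpsi_cut
    cls[big] = "significant_noncryptic"
    cls[(dpsi > dpsi_cut) & (presence < presence_low)] = "cryptic_gain"
    cls[(dpsi < -dpsi_cut) & (presence > presence_high)] = "cryptic_loss"

    out = psi[meta_cols].copy() if meta_cols else pd.DataFrame(index=psi.index)
    out["dpsi"] = dpsi
    out["control_presence"] = presence
    out["class"] = cls
    return out.reset_index()


def filter_polya_events(
    events: pd.DataFrame, cfc_cut: float = 0.25, fdr_cut: float = 0.05
) -> pd.DataFrame:
    """Classify polyA events by compositional fold change and FDR.

    ``lengthening`` when cFC >= cfc_cut and fdr < fdr_cut; ``shortening``
    when cFC <= -cfc_cut and fdr < fdr_cut; else ``none``.  The cFC boundary
    is inclusive, the FDR boundary exclusive.
    """
    fdr = events["fdr"].to_numpy(dtype=float)
    if np.any((fdr <= 0) | (fdr > 1)):
        raise ValueError("fdr must lie in (0, 1]")
    cfc = events["cFC"].to_numpy(dtype=float)
    cls = np.full(len(events), "none", dtype=object)
    sig = fdr < fdr_cut
    cls[sig & (cfc >= cfc_cut)] = "lengthening"
    cls[sig & (cfc <= -cfc_cut)] = "shortening"
    out = events.copy()
    out["class"] = cls
    return out


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def outlier_report(
    normalized: pd.DataFrame, n_components: int = 2, mad_cut: float = 4.0
) -> pd.DataFrame:
    """Flag candidate outlier samples (report only, never auto-removal).

    Samples are projected onto the top principal components of the
    normalized matrix; a sample is flagged when its distance from the
    per-component median exceeds ``mad_cut`` robust SDs on any component.
    """
    X = normalized.to_numpy(dtype=float).T
    X = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, s.size)
    scores = u[:, :k] * s[:k]
    flagged = np.zeros(X.shape[0], dtype=bool)
    for c in range(k):
        med = np.median(scores[:, c])
        mad = np.median(np.abs(scores[:, c] - med)) * 1.4826
        if mad > 0:
            flagged |= np.abs(scores[:, c] - med) > mad_cut * mad
    var = s**2
    out = pd.DataFrame(
        scores, index=normalized.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    out["flagged_outlier"] = flagged
    out.attrs["explained_variance_ratio"] = (var / var.sum())[:k].tolist()
    return out
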