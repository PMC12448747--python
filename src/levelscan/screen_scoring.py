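"""Dual-guide FACS screen scoring: guide-pair calls to gene-level rankings.

The stage order mirrors how a sorted-bin CRISPRi screen is analysed:

1. :func:`filter_recombined_pairs` — drop reads whose two guides target
   different genes (lentiviral template-switching recombinants).
2. :func:`aggregate_counts` — tally calls into per-cassette, per-bin counts.
3. :func:`filter_low_count_guides` / :func:`normalize_counts` — low-count
   removal and median-ratio size-factor normalization.
4. :func:`guide_nb_test` — one-sided negative-binomial p-values per cassette
   for enrichment in / depletion from the high bin, with a mean–variance
   trend fitted across cassettes.
5. :func:`gene_rra` — robust rank aggregation (Beta order-statistic minimum)
   with a guide-label permutation null, per direction.
6. :func:`screen_summary` — a per-gene (effect, p) exchange table for
   meta-analysis.

Non-targeting (NT) control cassettes participate in the rank background but
are scored as pseudo-genes, never merged into real genes.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import NT_GENE

__all__ = [
    "filter_recombined_pairs",
    "aggregate_counts",
    "filter_low_count_guides",
    "normalize_counts",
    "guide_nb_test",
    "nb_tail_probabilities",
    "rra_rho",
    "gene_rra",
    "score_genes",
    "screen_summary",
    "score_screen",
    "rank_plot_table",
]


# ---------------------------------------------------------------------------
# Parsing / counting
# ---------------------------------------------------------------------------


def filter_recombined_pairs(
    calls: pd.DataFrame, library: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep calls whose two guides target the same gene.

    NT–NT pairs are kept as controls (all NT guides share one sentinel gene,
    so NT recombinants are indistinguishable and retained).  Calls with a
    guide id absent from the library are excluded and tallied under
    ``unknown_guide`` rather than silently dropped.

    Returns ``(kept_calls, tally)`` with tally keys ``recombined`` and
    ``unknown_guide``.
    """
    gene_of = library.set_index("guide_id")["gene"]
    gene_a = calls["guide_a"].map(gene_of)
    gene_b = calls["guide_b"].map(gene_of)
    unknown = gene_a.isna() | gene_b.isna()
    same = (gene_a == gene_b) & ~unknown
    tally = {
        "recombined": int((~same & ~unknown).sum()),
        "unknown_guide": int(unknown.sum()),
    }
    return calls.loc[same.to_numpy()].reset_index(drop=True), tally


def aggregate_counts(
    calls: pd.DataFrame,
    library: pd.DataFrame,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tally filtered calls into a cassette x sample count table.

    Cassette identity is taken from ``guide_a``'s cassette in the library
    annotation.  Every library cassette appears in the output; cassettes with
    no calls get explicit zero rows.
    """
    pair_of = library.set_index("guide_id")["guide_pair_id"]
    cassettes = library.drop_duplicates("guide_pair_id")[["guide_pair_id", "gene"]]
    out = cassettes.set_index("guide_pair_id")
    if samples is None:
        samples = sorted(calls["sample"].unique())
    pair = calls["guide_a"].map(pair_of)
    for s in samples:
        tab = pair[calls["sample"].to_numpy() == s].value_counts()
        out[s] = tab.reindex(out.index).fillna(0).astype(int)
    return out.reset_index()


def filter_low_count_guides(
    counts: pd.DataFrame,
    min_count: float = 10.0,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Retain cassettes whose mean count across ``samples`` is >= min_count."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if samples is None:
        samples = [c for c in counts.columns if c not in ("guide_pair_id", "gene")]
    keep = counts[list(samples)].mean(axis=1) >= min_count
    return counts.loc[keep.to_numpy()].reset_index(drop=True)


def normalize_counts(
    counts: pd.DataFrame, method: str = "median_ratio"
) -> tuple[pd.DataFrame, pd.Series]:
    """Size-factor normalization of a cassette count table.

    ``median_ratio`` computes, per sample, the median across cassettes of
    count / geometric-row-mean (rows containing any zero are excluded from
    the reference); when fewer than 100 usable rows remain it falls back to
    total-count scaling, as does ``method="total"``.  Returns the normalized
    table and the size factors.
    """
    sample_cols = [c for c in counts.columns if c not in ("guide_pair_id", "gene")]
    if not sample_cols:
        raise ValueError("count table has no sample columns")
    mat = counts[sample_cols].to_numpy(dtype=float)
    colsum = mat.sum(axis=0)
    if np.any(colsum <= 0):
        bad = [s for s, t in zip(sample_cols, colsum) if t <= 0]
        raise ValueError(f"all-zero sample(s): {bad}")

    size = None
    if method == "median_ratio":
        nonzero = (mat > 0).all(axis=1)
        if int(nonzero.sum()) >= 100:
            log_gm = np.log(mat[nonzero]).mean(axis=1)
            ratios = mat[nonzero] / np.exp(log_gm)[:, None]
            size = np.median(ratios, axis=0)
    elif method != "total":
        raise ValueError(f"unknown normalization method: {method}")
    if size is None:  # total-count fallback
        size = colsum / colsum.mean()

    norm = counts.copy()
    norm[sample_cols] = mat / size
    return norm, pd.Series(size, index=sample_cols, name="size_factor")


# ---------------------------------------------------------------------------
# NB guide test
# ---------------------------------------------------------------------------


def fit_mean_variance_trend(mat: np.ndarray) -> tuple[float, float] | None:
    """Fit var(mu) = mu + k * mu**b by regressing log(var - mean) on log(mean).

    Uses per-cassette sample mean/variance across the provided columns.
    Returns (k, b), or None when the fit degenerates (too few over-dispersed
    cassettes, or a non-positive k), in which case the caller should fall
    back to the Poisson model var = mu.
    """
    mean = mat.mean(axis=1)
    var = mat.var(axis=1, ddof=1)
    ok = (var > mean) & (mean > 0)
    if int(ok.sum()) < 10:
        return None
    x = np.log(mean[ok])
    y = np.log(var[ok] - mean[ok])
    b, logk = np.polyfit(x, y, 1)
    k = math.exp(logk)
    if not (np.isfinite(k) and k > 0 and np.isfinite(b)):
        return None
    return k, b


def nb_tail_probabilities(
    obs: np.ndarray, mu: np.ndarray, var: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper tail probabilities of NB(mean=mu, variance=var) at obs.

    ``p_low`` = P(X <= obs), ``p_high`` = P(X >= obs).  Entries with
    var <= mu fall back to the Poisson distribution (the NB size parameter
    diverges there).
    """
    obs = np.atleast_1d(np.asarray(obs, dtype=np.int64))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    var = np.atleast_1d(np.asarray(var, dtype=float))
    p_low = np.empty(mu.size)
    p_high = np.empty(mu.size)
    overdisp = var > mu
    if overdisp.any():
        r = mu[overdisp] ** 2 / (var[overdisp] - mu[overdisp])
        pnb = r / (r + mu[overdisp])
        p_high[overdisp] = stats.nbinom.sf(obs[overdisp] - 1, r, pnb)
        p_low[overdisp] = stats.nbinom.cdf(obs[overdisp], r, pnb)
    if (~overdisp).any():
        m = mu[~overdisp]
        p_high[~overdisp] = stats.poisson.sf(obs[~overdisp] - 1, m)
        p_low[~overdisp] = stats.poisson.cdf(obs[~overdisp], m)
    return p_low, p_high


def guide_nb_test(
    norm_counts: pd.DataFrame,
    high: Sequence[str],
    low: Sequence[str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-cassette one-sided NB p-values for the high vs low bin comparison.

    The low-bin mean is the NB reference mean mu (floored at ``pseudocount``
    when zero); variance follows the trend fitted across cassettes from all
    normalized bin counts, with a Poisson fallback when the trend fit
    degenerates or implies var <= mu.  ``p_high`` = P(X >= high_obs) tests
    enrichment in the high bin; ``p_low`` = P(X <= high_obs) tests depletion.
    ``lfc`` is the pseudocounted log2 high/low ratio.
    """
    high = list(high)
    low = list(low)
    mat = norm_counts[high + low].to_numpy(dtype=float)
    trend = fit_mean_variance_trend(mat)

    high_val = norm_counts[high].mean(axis=1).to_numpy(dtype=float)
    low_val = norm_counts[low].mean(axis=1).to_numpy(dtype=float)
    mu = np.maximum(low_val, pseudocount)
    if trend is None:
        var = mu.copy()
    else:
        k, b = trend
        var = mu + k * np.power(mu, b)

    obs = np.round(high_val).astype(np.int64)
    p_low, p_high = nb_tail_probabilities(obs, mu, var)
    tiny = np.finfo(float).tiny
    out = norm_counts[["guide_pair_id", "gene"]].copy()
    out["lfc"] = np.log2((high_val + pseudocount) / (low_val + pseudocount))
    out["p_low"] = np.clip(p_low, tiny, 1.0)
    out["p_high"] = np.clip(p_high, tiny, 1.0)
    out["base_mean"] = mu
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Robust rank aggregation
# ---------------------------------------------------------------------------


def rra_rho(ranks, m: int | None = None) -> float:
    """RRA score for a gene's guide percentile ranks.

    With the selected ranks sorted ascending, the score is the minimum over
    j of P(Beta(j, m - j + 1) <= r_(j)) — the probability that the j-th
    order statistic of m uniforms falls at or below the observed j-th rank.
    ``m`` defaults to the number of ranks given (it differs when some of the
    gene's guides failed the alpha selection and contribute nothing).
    """
    r = np.sort(np.asarray(ranks, dtype=float))
    if r.size == 0:
        return 1.0
    if m is None:
        m = r.size
    if m < r.size:
        raise ValueError("m must be >= the number of contributing ranks")
    j = np.arange(1, r.size + 1)
    return float(np.min(stats.beta.cdf(r, j, m - j + 1)))


def _rho(ranks: np.ndarray, selected: np.ndarray, m: int) -> float:
    return rra_rho(ranks[selected], m)


def _rho_batch(r_mat: np.ndarray, sel_mat: np.ndarray, m: int) -> np.ndarray:
    """Vectorized RRA scores for many rank sets of equal size m."""
    r = np.where(sel_mat, r_mat, np.inf)
    r.sort(axis=1)
    n_sel = sel_mat.sum(axis=1)
    j = np.arange(1, m + 1)
    with np.errstate(invalid="ignore"):
        cdf = stats.beta.cdf(np.clip(r, 0.0, 1.0), j, m - j + 1)
    cdf = np.where(j[None, :] <= n_sel[:, None], cdf, 1.0)
    rho = cdf.min(axis=1)
    rho[n_sel == 0] = 1.0
    return rho


def gene_rra(
    guide_stats: pd.DataFrame,
    direction: str,
    alpha: float = 0.25,
    n_perm: int = 1000,
    seed: int | None = None,
    nt_pseudogene_size: int | None = None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Gene scores by robust rank aggregation of directional guide p-values.

    All cassettes (including NT controls) are ranked by ``p_low``
    (direction ``"neg"``: depletion from the high bin) or ``p_high``
    (``"pos"``); ties break by stable cassette-id order and percentile ranks
    are (rank - 0.5)/N.  Per gene, only guides with p < ``alpha`` contribute
    (select-only); with none selected the score is 1.  Significance comes
    from a guide-label permutation null — m cassettes drawn without
    replacement from the ranked background — with the +1 correction, so the
    smallest attainable p is 1/(n_perm+1).  BH FDR is computed within the
    direction over emitted genes.

    NT cassettes are never aggregated into real genes; when
    ``nt_pseudogene_size`` is given they are grouped, in stable id order,
    into pseudo-genes of that size (flagged ``is_control``) as an empirical
    false-positive readout.  ``exhaustive=True`` replaces the Monte Carlo
    null by full enumeration of all C(N, m) guide subsets (small instances
    only).
    """
    if direction not in ("neg", "pos"):
        raise ValueError("direction must be 'neg' or 'pos'")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    if not exhaustive and n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    pcol = "p_low" if direction == "neg" else "p_high"

    df = guide_stats.sort_values(
        [pcol, "guide_pair_id"], kind="mergesort"
    ).reset_index(drop=True)
    n = len(df)
    if n == 0:
        raise ValueError("no guides to rank")
    ranks = (np.arange(n) + 0.5) / n
    selected = df[pcol].to_numpy() < alpha

    gene_label = df["gene"].astype(str).to_numpy(dtype=object).copy()
    is_control = gene_label == NT_GENE
    if nt_pseudogene_size is not None and is_control.any():
        nt_rows = np.flatnonzero(is_control)
        order = nt_rows[np.argsort(df["guide_pair_id"].to_numpy()[nt_rows])]
        for i, row in enumerate(order):
            gene_label[row] = f"NTPSEUDO_{i // nt_pseudogene_size + 1:03d}"
    keep = gene_label != NT_GENE  # leftover NT cassettes stay background-only

    rng = np.random.default_rng(seed)
    rows = []
    groups = pd.Series(np.arange(n)[keep]).groupby(gene_label[keep], sort=True)
    null_cache: dict[int, np.ndarray] = {}
    for gene, idx in groups:
        idx = idx.to_numpy()
        m = idx.size
        rho = _rho(ranks[idx], selected[idx], m)
        if exhaustive:
            null = _exhaustive_null(ranks, selected, m)
            p = float(np.mean(null <= rho + 1e-15))
            p = max(p, 1.0 / (null.size + 1))
        else:
            if m not in null_cache:
                null_cache[m] = _permutation_null(rng, ranks, selected, m, n_perm)
            null = null_cache[m]
            p = (1.0 + float(np.sum(null <= rho + 1e-15))) / (n_perm + 1.0)
        rows.append(
            {
                "gene": gene,
                "n_guides": m,
                f"rho_{direction}": rho,
                f"p_{direction}": p,
                "gene_lfc": float(np.median(df["lfc"].to_numpy()[idx])),
                "is_control": bool(is_control[idx].all()),
            }
        )
    out = pd.DataFrame(rows)
    out[f"fdr_{direction}"] = bh_fdr(out[f"p_{direction}"].to_numpy())
    return out


def _permutation_null(
    rng: np.random.Generator,
    ranks: np.ndarray,
    selected: np.ndarray,
    m: int,
    n_perm: int,
) -> np.ndarray:
    n = ranks.size
    # m distinct background positions per permutation
    idx = np.argpartition(rng.random((n_perm, n)), m - 1, axis=1)[:, :m]
    return _rho_batch(ranks[idx], selected[idx], m)


def _exhaustive_null(
    ranks: np.ndarray, selected: np.ndarray, m: int, limit: int = 2_000_000
) -> np.ndarray:
    n = ranks.size
    if math.comb(n, m) > limit:
        raise ValueError("exhaustive null too large; use the Monte Carlo null")
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), m)),
        dtype=int,
    ).reshape(-1, m)
    return _rho_batch(ranks[combos], selected[combos], m)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (delegates to statsmodels)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def score_genes(
    guide_stats: pd.DataFrame,
    alpha: float = 0.25,
    n_perm: int = 1000,
    seed: int | None = None,
    nt_pseudogene_size: int | None = None,
) -> pd.DataFrame:
    """Run RRA in both directions and merge into one gene score table."""
    neg = gene_rra(guide_stats, "neg", alpha, n_perm, seed,
                   nt_pseudogene_size=nt_pseudogene_size)
    pos = gene_rra(guide_stats, "pos", alpha, n_perm,
                   None if seed is None else seed + 1,
                   nt_pseudogene_size=nt_pseudogene_size)
    merged = neg.merge(
        pos[["gene", "rho_pos", "p_pos", "fdr_pos"]], on="gene", validate="1:1"
    )
    return merged


def screen_summary(gene_scores: pd.DataFrame, screen_id: str = "screen") -> pd.DataFrame:
    """Collapse two-directional gene scores into a (gene, effect, p) summary.

    effect is the median guide LFC; p is the smaller directional permutation
    p, Bonferroni-doubled for the two-sided look and capped at 1.
    """
    df = gene_scores.loc[~gene_scores["is_control"]].copy()
    p_neg = df["p_neg"].to_numpy()
    p_pos = df["p_pos"].to_numpy()
    p = np.minimum(1.0, 2.0 * np.minimum(p_neg, p_pos))
    out = pd.DataFrame(
        {
            "gene": df["gene"],
            "effect": df["gene_lfc"],
            "p": p,
            "direction": np.where(p_neg <= p_pos, "neg", "pos"),
        }
    ).reset_index(drop=True)
    out.attrs["screen_id"] = screen_id
    return out


def rank_plot_table(gene_scores: pd.DataFrame) -> pd.DataFrame:
    """Rank-plot export: genes ordered by effect with signed -log10 p."""
    df = gene_scores.copy()
    p = np.minimum(df["p_neg"], df["p_pos"]).clip(lower=np.finfo(float).tiny)
    sign = np.where(df["p_neg"] <= df["p_pos"], -1.0, 1.0)
    df["signed_log10_p"] = sign * (-np.log10(p))
    df = df.sort_values("gene_lfc").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df[["gene", "rank", "gene_lfc", "signed_log10_p", "is_control"]]


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


def score_screen(
    calls: pd.DataFrame,
    library: pd.DataFrame,
    high: Sequence[str],
    low: Sequence[str],
    min_count: float = 10.0,
    alpha: float = 0.25,
    n_perm: int = 1000,
    seed: int | None = None,
    nt_pseudogene_size: int | None = None,
) -> dict[str, object]:
    """Full screen scoring chain from guide-pair calls to a screen summary.

    Returns a dict with the intermediate tables: ``tally``, ``counts``,
    ``size_factors``, ``guide_stats``, ``gene_scores``, ``summary``.
    """
    kept, tally = filter_recombined_pairs(calls, library)
    counts = aggregate_counts(kept, library, samples=list(high) + list(low))
    counts = filter_low_count_guides(counts, min_count=min_count)
    norm, size_factors = normalize_counts(counts)
    guide_stats = guide_nb_test(norm, high=high, low=low)
    gene_scores = score_genes(
        guide_stats, alpha=alpha, n_perm=n_perm, seed=seed,
        nt_pseudogene_size=nt_pseudogene_size,
    )
    return {
        "tally": tally,
        "counts": counts,
        "size_factors": size_factors,
        "guide_stats": guide_stats,
        "gene_scores": gene_scores,
        "summary": screen_summary(gene_scores),
    }
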