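"""Fixed-effects meta-analysis of genetic screens with novelty detection.

Screens reporting per-gene effects and p-values on heterogeneous scales are
harmonized to a standard-normal scale: effects become per-screen z-scored
betas, p-values are truncated to a representable range and converted to
signed z-scores, and standard errors are derived as |beta / z|.  Genes are
then pooled across screens by inverse-variance weighting (one common effect
is assumed; Cochran's Q and I² quantify heterogeneity but never switch the
model).  A gene is a *novel* hit when it reaches FDR significance in the
meta-analysis while reaching it in none of the constituent screens.
Term enrichment of hit lists uses the upper-tail hypergeometric test with a
permutation-based FDR.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screen_scoring import bh_fdr

__all__ = [
    "harmonize",
    "fixed_effect_pool",
    "meta_all_combinations",
    "bh_fdr",
    "classify_novelty",
    "hypergeom_enrichment",
    "read_gmt",
    "MetaRecord",
]

P_FLOOR = 1e-300
P_CEIL_EPS = 1e-16


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def harmonize(
    summary: pd.DataFrame,
    p_floor: float = P_FLOOR,
    standardize: bool = True,
    two_sided: bool = True,
) -> pd.DataFrame:
    """Convert one screen's (gene, effect, p) table to the z/beta/SE scale.

    p-values are clamped to [p_floor, 1 - 1e-16] before inversion — extreme
    values are truncated rather than propagated, which makes the pooled test
    conservative for the most significant genes.  The z-score takes the sign
    of the effect; ``standardize`` z-scores the effect column within the
    screen so screens on different phenotype scales become comparable.
    Rows with effect exactly 0 get a weight-0 sentinel (infinite SE) and are
    flagged ``zero_effect``.
    """
    p = summary["p"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    effect = summary["effect"].to_numpy(dtype=float)

    p_trunc = np.clip(p, p_floor, 1.0 - P_CEIL_EPS)
    quant = stats.norm.isf(p_trunc / 2.0) if two_sided else stats.norm.isf(p_trunc)
    z = np.sign(effect) * quant

    if standardize:
        sd = float(np.std(effect))
        if sd <= 0:
            raise ValueError("cannot standardize a constant effect column")
        beta = (effect - 0.0) / sd  # scale-only standardization keeps the sign
    else:
        beta = effect

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.abs(beta / z)
    zero = z == 0
    se = np.where(zero | ~np.isfinite(se) | (se == 0), np.inf, se)

    return pd.DataFrame(
        {
            "gene": summary["gene"].to_numpy(),
            "z": z,
            "beta_std": beta,
            "se": se,
            "p_trunc": p_trunc,
            "zero_effect": zero,
        }
    )


# ---------------------------------------------------------------------------
# Inverse-variance pooling
# ---------------------------------------------------------------------------


@dataclass
class MetaRecord:
    """Pooled fixed-effects result for one gene."""

    gene: str
    pooled_beta: float
    pooled_se: float
    z_meta: float
    p_meta: float
    Q: float
    df: int
    I2: float
    k: int


def fixed_effect_pool(
    gene: str, betas: Sequence[float], ses: Sequence[float]
) -> MetaRecord:
    """Inverse-variance fixed-effects pooling of one gene across screens.

    Weights are 1/SE²; heterogeneity Q = sum w (b - pooled)² with k-1 degrees
    of freedom and I² = max(0, (Q - df)/Q).  Records with non-finite or
    non-positive SE must be excluded by the caller.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("no usable records to pool")
    if np.any(~np.isfinite(s) | (s <= 0)):
        raise ValueError("all SEs must be finite and positive")
    w = 1.0 / s**2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    z = pooled / pooled_se
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
    Q = float(np.sum(w * (b - pooled) ** 2))
    df = b.size - 1
    I2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    return MetaRecord(gene, pooled, pooled_se, z, p, Q, df, I2, b.size)


def _pool_frame(harmonized: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Vectorized fixed-effects pooling over the union of genes.

    Genes absent from a screen (or carrying a weight-0 sentinel) are pooled
    over the screens that do contain them; ``coverage`` records how many.
    """
    ids = list(harmonized)
    beta = pd.DataFrame({sid: h.set_index("gene")["beta_std"] for sid, h in
                         harmonized.items()})
    se = pd.DataFrame({sid: h.set_index("gene")["se"] for sid, h in
                       harmonized.items()})
    b = beta.to_numpy(dtype=float)
    s = se.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        w = 1.0 / s**2
    usable = np.isfinite(s) & (s > 0) & np.isfinite(b) & (w > 0)
    w = np.where(usable, w, 0.0)
    b0 = np.where(usable, b, 0.0)

    k = usable.sum(axis=1)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = (w * b0).sum(axis=1) / wsum
        pooled_se = wsum**-0.5
        Q = (w * (b0 - pooled[:, None]) ** 2 * usable).sum(axis=1)
    df_het = np.maximum(k - 1, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        I2 = np.where(Q > 0, np.maximum(0.0, (Q - df_het) / Q), 0.0)
    z = pooled / pooled_se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)

    out = pd.DataFrame(
        {
            "gene": beta.index,
            "pooled_beta": pooled,
            "pooled_se": pooled_se,
            "z_meta": z,
            "p_meta": p,
            "Q": Q,
            "df": df_het,
            "I2": I2,
            "coverage": k,
            "screens": ",".join(ids),
        }
    ).reset_index(drop=True)
    skipped = out["coverage"] == 0
    report = out.loc[skipped, "gene"].tolist()
    out = out.loc[~skipped].reset_index(drop=True)
    out["q_meta"] = bh_fdr(out["p_meta"].to_numpy())
    out.attrs["skipped_genes"] = report
    return out


def meta_all_combinations(
    summaries: Mapping[str, pd.DataFrame],
    p_floor: float = P_FLOOR,
    standardize: bool = True,
    min_subset: int = 2,
) -> dict[tuple[str, ...], pd.DataFrame]:
    """Fixed-effects meta-analysis for every screen subset of size >= 2.

    Screens are harmonized once; each subset is pooled over the union of its
    genes, with per-gene coverage recorded.  Returns a mapping from the
    screen-id tuple to the pooled table.
    """
    ids = list(summaries)
    if len(ids) < 2:
        raise ValueError("need at least 2 screens")
    harmonized = {
        sid: harmonize(df, p_floor=p_floor, standardize=standardize)
        for sid, df in summaries.items()
    }
    out: dict[tuple[str, ...], pd.DataFrame] = {}
    for r in range(max(2, min_subset), len(ids) + 1):
        for subset in itertools.combinations(ids, r):
            table = _pool_frame({sid: harmonized[sid] for sid in subset})
            if table.empty:
                import warnings

                warnings.warn(f"empty gene set for subset {subset}")
            out[subset] = table
    return out


# ---------------------------------------------------------------------------
# Novelty classification
# ---------------------------------------------------------------------------


def classify_novelty(
    meta: pd.DataFrame,
    summaries: Mapping[str, pd.DataFrame],
    q_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    effect_filtered: Iterable[str] = (),
) -> pd.DataFrame:
    """Flag genes significant in the pooled analysis but in no single screen.

    Per-screen q-values are BH-computed within each constituent screen.  A
    gene is *novel* iff q_meta < q_threshold and every constituent q is
    >= q_threshold; genes missing a constituent q are ineligible and flagged.
    For screens named in ``effect_filtered`` (reporter-level screens whose
    effects are log fold changes), the gene must additionally deviate from
    the screen's mean effect by at least ``lfc_threshold``.  Direction of
    novelty is the sign of the pooled effect.
    """
    out = meta.copy()
    qcols = []
    for sid, df in summaries.items():
        q = pd.Series(bh_fdr(df["p"].to_numpy()), index=df["gene"].to_numpy())
        out[f"q_{sid}"] = out["gene"].map(q)
        qcols.append(f"q_{sid}")

    qmat = out[qcols].to_numpy(dtype=float)
    missing = np.isnan(qmat).any(axis=1)
    all_constituents_null = (qmat >= q_threshold).all(axis=1)
    novel = (
        (out["q_meta"].to_numpy() < q_threshold) & all_constituents_null & ~missing
    )

    for sid in effect_filtered:
        df = summaries[sid]
        eff = pd.Series(df["effect"].to_numpy(), index=df["gene"].to_numpy())
        centered = (out["gene"].map(eff) - float(eff.mean())).to_numpy(dtype=float)
        passes = np.abs(centered) >= lfc_threshold
        novel &= np.where(np.isnan(centered), False, passes)

    out["novel"] = novel
    out["novelty_direction"] = np.where(
        novel, np.where(out["pooled_beta"] > 0, "up", "down"), ""
    )
    out["novelty_ineligible_missing"] = missing
    return out


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT annotation file: term <tab> description <tab> genes..."""
    terms: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        terms[parts[0]] = set(parts[2:])
    return terms


def hypergeom_enrichment(
    hits: Iterable[str],
    terms: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric term enrichment with a permutation FDR.

    For each term, ``p_hyper`` is the upper-tail probability of observing at
    least k of the n hits inside the K-gene term within an N-gene universe.
    The permutation FDR draws ``n_perm`` random hit sets of size n from the
    universe, recomputes all term p-values, and reports the mean ratio of
    null to observed discoveries at each observed p (clamped to [0, 1]).
    """
    universe = sorted(set(universe))
    uni_index = {g: i for i, g in enumerate(universe)}
    hits = sorted(set(hits) & set(universe))
    if set(hits) - set(universe):
        raise ValueError("hit set must be a subset of the universe")
    n = len(hits)
    N = len(universe)
    if n == 0:
        return pd.DataFrame(
            columns=["term", "k", "K", "n", "N", "p_hyper", "perm_fdr"]
        )

    term_ids = list(terms)
    member = np.zeros((len(term_ids), N), dtype=bool)
    for t, tid in enumerate(term_ids):
        idx = [uni_index[g] for g in terms[tid] if g in uni_index]
        member[t, idx] = True
    K = member.sum(axis=1)

    hit_mask = np.zeros(N, dtype=bool)
    hit_mask[[uni_index[g] for g in hits]] = True
    k = member[:, hit_mask].sum(axis=1)
    p_obs = stats.hypergeom.sf(k - 1, N, K, n)
    p_obs = np.clip(p_obs, np.finfo(float).tiny, 1.0)

    rng = np.random.default_rng(seed)
    n_obs_at = np.array([(p_obs <= p).sum() for p in p_obs], dtype=float)
    null_ge = np.zeros(p_obs.size)
    for _ in range(n_perm):
        perm = rng.choice(N, size=n, replace=False)
        kp = member[:, perm].sum(axis=1)
        p_null = stats.hypergeom.sf(kp - 1, N, K, n)
        # for each observed p, how many null terms reach it this round
        null_ge += (p_null[None, :] <= p_obs[:, None]).sum(axis=1)
    perm_fdr = np.clip(null_ge / n_perm / np.maximum(1.0, n_obs_at), 0.0, 1.0)

    return pd.DataFrame(
        {
            "term": term_ids,
            "k": k,
            "K": K,
            "n": n,
            "N": N,
            "p_hyper": p_obs,
            "perm_fdr": perm_fdr,
        }
    )
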