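"""Protein half-lives from pulse-SILAC heavy/light ratios.

After a switch to heavy-isotope media, newly synthesised protein is heavy
and pre-existing protein is light; at steady-state turnover the heavy/light
ratio R after labeling time t_s gives the half-life from a single time point:

    t_half = t_s * ln(2) / ln(1 + R)

Peptide-level half-lives are aggregated to the protein level by the harmonic
mean over unique peptide sequences.  Upstream filters drop contaminant
peptides, peptides with total intensity below 1000, and heavy/light ratios
outside [0.01, 100] (boundaries kept — the removal rules are strict
inequalities).  Condition contrasts use Welch t-tests on log2 half-lives
with BH correction; volcano-style cut-offs default to |log2 FC| >= 0.5 and
p < 0.05 for half-lives, |log2 FC| >= 1 for abundances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .screen_scoring import bh_fdr

__all__ = [
    "filter_peptides",
    "peptide_half_life",
    "peptide_table_half_lives",
    "protein_half_life",
    "contrast_half_life",
    "contrast_abundance",
]


def filter_peptides(
    records: pd.DataFrame,
    min_intensity: float = 1000.0,
    ratio_bounds: tuple[float, float] = (0.01, 100.0),
    intensity_mode: str = "total",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove contaminant, low-intensity, and extreme-ratio peptides.

    ``intensity_mode="total"`` applies the intensity floor to light + heavy
    (``"either"`` requires each channel to pass).  A record failing several
    rules is tallied once, under the first failing rule in the order
    contaminant -> intensity -> ratio.  Boundary values (intensity == 1000,
    ratio == 0.01 or 100) are kept.
    """
    df = records
    ratio = _ratios(df)
    if intensity_mode == "total":
        intensity = df["intensity_light"].to_numpy(float) + df[
            "intensity_heavy"
        ].to_numpy(float)
        low_int = intensity < min_intensity
    elif intensity_mode == "either":
        low_int = (df["intensity_light"].to_numpy(float) < min_intensity) | (
            df["intensity_heavy"].to_numpy(float) < min_intensity
        )
    else:
        raise ValueError("intensity_mode must be 'total' or 'either'")

    contam = df["contaminant"].to_numpy(bool) if "contaminant" in df else np.zeros(
        len(df), bool
    )
    bad_ratio = (ratio < ratio_bounds[0]) | (ratio > ratio_bounds[1])

    reason = np.full(len(df), "", dtype=object)
    reason[bad_ratio] = "extreme_ratio"
    reason[low_int] = "low_intensity"
    reason[contam] = "contaminant"
    tally = {
        "contaminant": int((reason == "contaminant").sum()),
        "low_intensity": int((reason == "low_intensity").sum()),
        "extreme_ratio": int((reason == "extreme_ratio").sum()),
    }
    kept = df.loc[reason == ""].reset_index(drop=True)
    return kept, tally


def _ratios(df: pd.DataFrame, flag_tolerance: float = 0.01) -> np.ndarray:
    """Heavy/light ratios: reported column when present, else recomputed.

    When both are available and disagree by more than ``flag_tolerance``
    (relative), the discrepancy count is recorded in ``df.attrs``.
    """
    light = df["intensity_light"].to_numpy(float)
    heavy = df["intensity_heavy"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        computed = np.where(light > 0, heavy / light, np.nan)
    if "ratio_hl" in df.columns:
        ratio = df["ratio_hl"].to_numpy(float)
        both = np.isfinite(ratio) & np.isfinite(computed) & (computed > 0)
        with np.errstate(invalid="ignore"):
            rel = np.abs(ratio[both] / computed[both] - 1.0)
        df.attrs["ratio_discrepancies"] = int((rel > flag_tolerance).sum())
        return ratio
    return computed


def peptide_half_life(ratio, label_time_days):
    """Single-time-point half-life: t_s * ln2 / ln(1 + R).  Vectorized.

    Requires R > 0 and t_s > 0; invalid inputs yield NaN so callers can skip
    the record with a reason rather than fail.
    """
    r = np.asarray(ratio, dtype=float)
    t_s = np.asarray(label_time_days, dtype=float)
    if np.any(t_s <= 0):
        raise ValueError("label time must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(r > 0, t_s * np.log(2.0) / np.log1p(r), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def peptide_table_half_lives(records: pd.DataFrame) -> pd.DataFrame:
    """Per-peptide half-lives with charge states collapsed by median.

    Duplicate peptide sequences within a protein x condition x replicate
    group (e.g. charge states or repeated identifications) are collapsed to
    their median ratio before the half-life formula is applied, so each
    unique sequence contributes one value.
    """
    df = records.copy()
    df["_ratio"] = _ratios(df)
    df = df.loc[df["_ratio"] > 0]
    keys = ["protein_id", "condition", "replicate", "label_time_days", "peptide_seq"]
    collapsed = df.groupby(keys, sort=False, as_index=False)["_ratio"].median()
    collapsed["t_half_days"] = peptide_half_life(
        collapsed["_ratio"], collapsed["label_time_days"]
    )
    return collapsed.drop(columns="_ratio")


def protein_half_life(peptide_halflives: pd.DataFrame) -> pd.DataFrame:
    """Harmonic-mean protein half-life per protein x condition x replicate.

    t_half = n / sum(1/t_i) over the unique peptide half-lives of the
    protein; ``n_unique_peptides`` records n.
    """
    df = peptide_halflives.loc[peptide_halflives["t_half_days"].notna()]
    grouped = df.groupby(
        ["protein_id", "condition", "replicate"], sort=False, as_index=False
    ).agg(
        t_half_days=("t_half_days", lambda t: len(t) / np.sum(1.0 / t.to_numpy())),
        n_unique_peptides=("t_half_days", "size"),
    )
    return grouped


def compute_protein_turnover(records: pd.DataFrame, **filter_kwargs) -> pd.DataFrame:
    """Filter peptides, compute peptide half-lives, aggregate to proteins."""
    kept, _ = filter_peptides(records, **filter_kwargs)
    return protein_half_life(peptide_table_half_lives(kept))


def _welch_contrast(
    values: pd.DataFrame,
    value_col: str,
    group_a: str,
    group_b: str,
    lfc_cut: float,
    p_cut: float,
) -> pd.DataFrame:
    """Shared volcano machinery: per-protein Welch t on log2 values."""
    tiny = np.finfo(float).tiny
    rows = []
    for prot, sub in values.groupby("protein_id", sort=True):
        a = sub.loc[sub["condition"] == group_a, value_col].to_numpy(float)
        b = sub.loc[sub["condition"] == group_b, value_col].to_numpy(float)
        a = a[a > 0]
        b = b[b > 0]
        if a.size == 0 or b.size == 0:
            continue
        lfc = float(np.log2(b.mean() / a.mean()))
        if a.size >= 2 and b.size >= 2:
            la, lb = np.log2(a), np.log2(b)
            if la.var(ddof=1) == 0 and lb.var(ddof=1) == 0:
                p = 1.0 if la.mean() == lb.mean() else tiny
            else:
                p = float(stats.ttest_ind(lb, la, equal_var=False).pvalue)
                p = max(p, tiny)
        else:
            p = np.nan
        rows.append(
            {
                "protein_id": prot,
                "lfc": lfc,
                "p": p,
                "n_a": a.size,
                "n_b": b.size,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(q=[], significant=[])
    valid = out["p"].notna()
    q = np.full(len(out), np.nan)
    q[valid.to_numpy()] = bh_fdr(out.loc[valid, "p"].to_numpy())
    out["q"] = q
    out["significant"] = (
        valid & (np.abs(out["lfc"]) >= lfc_cut) & (out["p"] < p_cut)
    )
    return out


def contrast_half_life(
    turnover: pd.DataFrame,
    group_a: str,
    group_b: str,
    lfc_cut: float = 0.5,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Half-life contrast (group_b vs group_a) across replicates.

    ``lfc`` is log2(mean_b / mean_a) of protein half-lives; p from a Welch
    t-test on log2 half-lives across replicates; q by BH over testable
    proteins.  Proteins lacking >= 2 replicates per group are emitted with a
    missing p and excluded from the q computation.
    """
    return _welch_contrast(turnover, "t_half_days", group_a, group_b, lfc_cut, p_cut)


def contrast_abundance(
    intensities: pd.DataFrame,
    group_a: str,
    group_b: str,
    lfc_cut: float = 1.0,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Protein abundance contrast on the same machinery, volcano cuts |lfc|>=1.

    Expects columns protein_id, condition, replicate, intensity.
    """
    return _welch_contrast(intensities, "intensity", group_a, group_b, lfc_cut, p_cut)
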