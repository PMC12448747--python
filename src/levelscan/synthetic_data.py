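"""Generators for every input family the pipeline consumes, with known ground truth.

Each generator emulates the statistical structure of one experimental readout:

* :func:`simulate_sorting_screen` — a dual-guide CRISPRi FACS screen in which
  cells carrying a guide cassette express a fluorescent reporter, are sorted
  into high/low quantile bins, and per-cassette read counts are sequenced
  from each bin at fixed depth.
* :func:`simulate_screen_summaries` — per-gene effect/p summaries for several
  screens sharing a subset of true hits (fixture for meta-analysis).
* :func:`simulate_silac_peptides` — pulse-SILAC peptide reports in which the
  heavy/light ratio encodes protein turnover at steady state.
* :func:`simulate_junction_psi` — splice-junction percent-spliced-in (PSI)
  tables with planted cryptic junctions that are near-absent in controls.
* :func:`simulate_expression_counts` — negative-binomial gene counts with a
  decreasing dispersion~mean trend, planted differential genes and a planted
  low-mean/high-CV "noise-biased" block.

All randomness flows from one `numpy.random.Generator` seeded per call; a
given seed + config reproduces every table exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Gene label shared by all non-targeting (NT) control guides.
NT_GENE = "non-targeting"


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimConfig:
    """Design of a quantile-sorted dual-guide reporter screen.

    Parameters are in the units of the assay: reporter effects are expressed
    in within-cell reporter standard deviations, ``sort_fraction`` is the
    quantile collected into each bin (0.25 = top/bottom quarters), and
    ``reads_per_bin`` is the fixed sequencing depth of each sorted fraction.
    """

    n_genes: int = 500
    guides_per_gene: int = 4
    n_control_guides: int = 100
    frac_true_hits: float = 0.05
    effect_size_sd_units: float = -1.0
    cells_per_guide: float = 1000.0
    sort_fraction: float = 0.25
    reads_per_bin: int = 1_000_000
    recombination_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_genes > 0, "n_genes must be positive")
        _require(self.guides_per_gene > 0, "guides_per_gene must be positive")
        _require(self.n_control_guides >= 0, "n_control_guides must be >= 0")
        _require(0.0 <= self.frac_true_hits <= 1.0, "frac_true_hits must be in [0,1]")
        _require(self.cells_per_guide > 0, "cells_per_guide must be positive")
        _require(0.0 < self.sort_fraction <= 0.5, "sort_fraction must be in (0, 0.5]")
        _require(self.reads_per_bin > 0, "reads_per_bin must be a positive integer")
        _require(
            0.0 <= self.recombination_rate < 1.0, "recombination_rate must be in [0,1)"
        )


@dataclass
class MetaSimConfig:
    """Multi-screen fixture: shared hits, screen-specific hits, and nulls."""

    n_screens: int = 3
    n_genes: int = 2000
    shared_hit_count: int = 100
    screen_specific_hit_count: int = 0
    shared_effect: float = 3.0
    noise_se: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_screens >= 1, "n_screens must be >= 1")
        _require(self.n_genes > 0, "n_genes must be positive")
        _require(self.shared_hit_count >= 0, "shared_hit_count must be >= 0")
        _require(self.screen_specific_hit_count >= 0, "screen_specific_hit_count >= 0")
        _require(
            self.shared_hit_count + self.screen_specific_hit_count <= self.n_genes,
            "hit counts exceed n_genes",
        )
        _require(self.noise_se > 0, "noise_se must be positive")


@dataclass
class TurnoverSimConfig:
    """Pulse-SILAC design: media switch to heavy label, one harvest time.

    Default label time of 2 days matches a day-5 media switch with a day-7
    harvest; a day-15 harvest corresponds to ``label_time_days=10``.
    """

    n_proteins: int = 500
    peptides_per_protein: tuple[int, int] = (3, 15)
    true_halflife_days: tuple[float, float] = (0.5, 30.0)  # log-uniform bounds
    label_time_days: float = 2.0
    ratio_noise_cv: float = 0.2
    contaminant_fraction: float = 0.02
    extreme_ratio_fraction: float = 0.02
    low_intensity_fraction: float = 0.02
    condition: str = "NT"
    replicate: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_proteins > 0, "n_proteins must be positive")
        lo, hi = self.peptides_per_protein
        _require(1 <= lo <= hi, "peptides_per_protein must be a valid int range")
        tlo, thi = self.true_halflife_days
        _require(0 < tlo <= thi, "true half-life bounds must be positive")
        _require(self.label_time_days > 0, "label_time_days must be positive")
        _require(self.ratio_noise_cv >= 0, "ratio_noise_cv must be >= 0")
        for name in ("contaminant_fraction", "extreme_ratio_fraction",
                     "low_intensity_fraction"):
            _require(0.0 <= getattr(self, name) < 1.0, f"{name} must be in [0,1)")


# ---------------------------------------------------------------------------
# Sorting-screen simulator
# ---------------------------------------------------------------------------


def _screen_library(config: ScreenSimConfig) -> pd.DataFrame:
    """Cassette catalog: one row per guide, with cassette and target gene."""
    genes = [f"GENE{i:04d}" for i in range(config.n_genes)]
    rows = []
    for g in genes:
        for k in range(config.guides_per_gene):
            cid = f"{g}_c{k + 1}"
            rows.append((f"{cid}_a", cid, g))
            rows.append((f"{cid}_b", cid, g))
    for k in range(config.n_control_guides):
        cid = f"NT_c{k + 1:03d}"
        rows.append((f"{cid}_a", cid, NT_GENE))
        rows.append((f"{cid}_b", cid, NT_GENE))
    return pd.DataFrame(rows, columns=["guide_id", "guide_pair_id", "gene"])


def sorting_bin_probabilities(
    effects: np.ndarray, weights: np.ndarray, sort_fraction: float
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Analytic bin-membership probabilities under the Gaussian reporter model.

    The pooled reporter distribution is a mixture of unit-variance normals
    centred at the cassette effects, weighted by relative cell numbers.  Bin
    thresholds are the pooled quantiles at ``sort_fraction`` and
    ``1 - sort_fraction``; the returned arrays give P(cell in low bin) and
    P(cell in high bin) for each cassette.  Used as the quadrature oracle for
    the stochastic simulator.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    effects = np.asarray(effects, dtype=float)

    def mixture_cdf(x: float) -> float:
        return float(np.sum(w * norm.cdf(x - effects)))

    lo = float(effects.min() - 8.0)
    hi = float(effects.max() + 8.0)
    q_low = brentq(lambda x: mixture_cdf(x) - sort_fraction, lo, hi)
    q_high = brentq(lambda x: mixture_cdf(x) - (1.0 - sort_fraction), lo, hi)
    p_low = norm.cdf(q_low - effects)
    p_high = norm.sf(q_high - effects)
    return p_low, p_high, q_low, q_high


def simulate_sorting_screen(
    config: ScreenSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a quantile-sorted dual-guide screen.

    Returns ``(calls, counts, truth, library)``:

    * ``calls`` — read-level guide-pair calls (read_id, sample, guide_a,
      guide_b); a fraction ``recombination_rate`` of reads carries guide B
      from an independently drawn cassette (lentiviral template switching).
    * ``counts`` — the clean per-cassette counts per bin (pre-recombination),
      columns guide_pair_id, gene, high, low; per-bin counts sum exactly to
      ``reads_per_bin``.
    * ``truth`` — gene, true_effect (0 for non-hits).
    * ``library`` — guide annotation (guide_id, guide_pair_id, gene).
    """
    rng = np.random.default_rng(config.seed)
    library = _screen_library(config)
    cassettes = library.drop_duplicates("guide_pair_id")[
        ["guide_pair_id", "gene"]
    ].reset_index(drop=True)
    n_cassettes = len(cassettes)
    genes = [f"GENE{i:04d}" for i in range(config.n_genes)]

    n_hits = int(round(config.frac_true_hits * config.n_genes))
    hit_genes = rng.choice(config.n_genes, size=n_hits, replace=False)
    gene_effect = np.zeros(config.n_genes)
    gene_effect[hit_genes] = config.effect_size_sd_units
    effect_by_gene = dict(zip(genes, gene_effect))
    effect_by_gene[NT_GENE] = 0.0
    cassette_effect = cassettes["gene"].map(effect_by_gene).to_numpy(dtype=float)

    # Cell numbers per cassette: lognormal around the configured mean
    # (sigma 0.5 on the log scale, mean-corrected), at least one cell.
    sigma = 0.5
    mu = math.log(config.cells_per_guide) - sigma**2 / 2.0
    n_cells = np.maximum(1, np.round(rng.lognormal(mu, sigma, n_cassettes))).astype(int)

    # Per-cell reporter values; bins gated on pooled population quantiles.
    cassette_idx = np.repeat(np.arange(n_cassettes), n_cells)
    reporter = rng.standard_normal(cassette_idx.size) + cassette_effect[cassette_idx]
    q_low, q_high = np.quantile(
        reporter, [config.sort_fraction, 1.0 - config.sort_fraction]
    )
    in_low = reporter <= q_low
    in_high = reporter >= q_high
    cells_low = np.bincount(cassette_idx[in_low], minlength=n_cassettes)
    cells_high = np.bincount(cassette_idx[in_high], minlength=n_cassettes)

    # Fixed sequencing depth per bin: multinomial over cassettes weighted by
    # the number of that cassette's cells in the bin.
    def bin_counts(cells_in_bin: np.ndarray) -> np.ndarray:
        total = cells_in_bin.sum()
        _require(total > 0, "empty sorted bin; increase cells_per_guide")
        return rng.multinomial(config.reads_per_bin, cells_in_bin / total)

    counts_high = bin_counts(cells_high)
    counts_low = bin_counts(cells_low)

    counts = cassettes.copy()
    counts["high"] = counts_high
    counts["low"] = counts_low

    # Emit read-level calls with recombination applied per read.
    pair_ids = cassettes["guide_pair_id"].to_numpy()
    frames = []
    for sample, cvec, cells_in_bin in (
        ("high", counts_high, cells_high),
        ("low", counts_low, cells_low),
    ):
        idx_a = np.repeat(np.arange(n_cassettes), cvec)
        idx_b = idx_a.copy()
        recomb = rng.random(idx_a.size) < config.recombination_rate
        k = int(recomb.sum())
        if k:
            weights = cells_in_bin / cells_in_bin.sum()
            idx_b[recomb] = rng.choice(n_cassettes, size=k, p=weights)
        frames.append(
            pd.DataFrame(
                {
                    "read_id": [f"{sample}:{i}" for i in range(idx_a.size)],
                    "sample": sample,
                    "guide_a": pd.Categorical.from_codes(
                        idx_a, categories=[p + "_a" for p in pair_ids]
                    ),
                    "guide_b": pd.Categorical.from_codes(
                        idx_b, categories=[p + "_b" for p in pair_ids]
                    ),
                }
            )
        )
    calls = pd.concat(frames, ignore_index=True)

    truth = pd.DataFrame({"gene": genes, "true_effect": gene_effect})
    return calls, counts, truth, library


# ---------------------------------------------------------------------------
# Multi-screen summary simulator
# ---------------------------------------------------------------------------


def simulate_screen_summaries(
    config: MetaSimConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate per-gene (effect, p) summaries for ``n_screens`` screens.

    Gene effects decompose as shared + screen-specific + Normal(0, SE) noise;
    two-sided p-values come from z = effect / SE.  Returns a mapping
    screen_id -> summary table and a truth table labelling each gene as
    ``shared``, ``specific`` (with its screen) or ``null``.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(config.seed)
    genes = [f"GENE{i:05d}" for i in range(config.n_genes)]
    labels = np.array(["null"] * config.n_genes, dtype=object)
    specific_screen = np.array([""] * config.n_genes, dtype=object)

    shared = np.zeros(config.n_genes)
    shared[: config.shared_hit_count] = config.shared_effect
    labels[: config.shared_hit_count] = "shared"

    specific = np.zeros((config.n_screens, config.n_genes))
    start = config.shared_hit_count
    for j in range(config.screen_specific_hit_count):
        s = j % config.n_screens
        g = start + j
        specific[s, g] = config.shared_effect
        labels[g] = "specific"
        specific_screen[g] = f"screen_{s + 1}"

    summaries: dict[str, pd.DataFrame] = {}
    for s in range(config.n_screens):
        beta = shared + specific[s] + rng.normal(0.0, config.noise_se, config.n_genes)
        z = beta / config.noise_se
        p = np.clip(2.0 * norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
        summaries[f"screen_{s + 1}"] = pd.DataFrame(
            {"gene": genes, "effect": beta, "p": p, "z": z}
        )

    truth = pd.DataFrame(
        {
            "gene": genes,
            "label": labels,
            "true_effect": shared + specific.sum(axis=0),
            "specific_screen": specific_screen,
        }
    )
    return summaries, truth


# ---------------------------------------------------------------------------
# Pulse-SILAC peptide simulator
# ---------------------------------------------------------------------------


def simulate_silac_peptides(
    config: TurnoverSimConfig,
    halflives: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a MaxQuant-style peptide report for one condition/replicate.

    For a protein with true half-life T and label time t_s the noiseless
    heavy/light ratio is R* = 2**(t_s/T) - 1 (steady-state turnover).  The
    observed ratio is R* times a lognormal multiplier whose coefficient of
    variation equals ``ratio_noise_cv``.  Contaminant peptides, out-of-range
    ratios, and sub-floor intensities are injected at the configured
    fractions and flagged in the returned table so downstream filters can be
    validated against ground truth.

    ``halflives`` overrides the drawn true half-lives (e.g. to reuse one set
    of proteins across conditions with a known fold change).
    """
    rng = np.random.default_rng(config.seed)
    proteins = [f"PROT{i:04d}" for i in range(config.n_proteins)]
    if halflives is None:
        lo, hi = config.true_halflife_days
        halflives = np.exp(rng.uniform(math.log(lo), math.log(hi), config.n_proteins))
    else:
        halflives = np.asarray(halflives, dtype=float)
        _require(halflives.shape == (config.n_proteins,), "halflives length mismatch")
    _require(bool(np.all(halflives > 0)), "true half-lives must be positive")

    plo, phi = config.peptides_per_protein
    n_pep = rng.integers(plo, phi + 1, config.n_proteins)
    prot_idx = np.repeat(np.arange(config.n_proteins), n_pep)
    total = prot_idx.size

    t_s = config.label_time_days
    r_true = 2.0 ** (t_s / halflives[prot_idx]) - 1.0
    if config.ratio_noise_cv > 0:
        sig = math.sqrt(math.log(1.0 + config.ratio_noise_cv**2))
        noise = rng.lognormal(-sig**2 / 2.0, sig, total)  # mean-1 multiplier
    else:
        noise = np.ones(total)
    ratio = r_true * noise

    light = rng.lognormal(math.log(1e6), 1.0, total)
    contaminant = rng.random(total) < config.contaminant_fraction
    extreme = (~contaminant) & (rng.random(total) < config.extreme_ratio_fraction)
    if extreme.any():
        sign = rng.random(int(extreme.sum())) < 0.5
        ratio[extreme] = np.where(sign, 1e3 * (1 + rng.random(sign.size)),
                                  1e-3 / (1 + rng.random(sign.size)))
    low_int = (~contaminant) & (~extreme) & (
        rng.random(total) < config.low_intensity_fraction
    )
    if low_int.any():
        # rescale so light + heavy falls below the 1000 intensity floor
        light[low_int] = rng.uniform(10, 900, int(low_int.sum())) / (
            1.0 + ratio[low_int]
        )
    heavy = light * ratio

    peptides = pd.DataFrame(
        {
            "protein_id": np.array(proteins, dtype=object)[prot_idx],
            "peptide_seq": [
                f"{proteins[i]}_pep{j}"
                for i, j in zip(prot_idx, _within_group_index(prot_idx))
            ],
            "intensity_light": light,
            "intensity_heavy": heavy,
            "ratio_hl": ratio,
            "condition": config.condition,
            "replicate": config.replicate,
            "label_time_days": t_s,
            "contaminant": contaminant,
            "injected_extreme_ratio": extreme,
            "injected_low_intensity": low_int,
        }
    )
    truth = pd.DataFrame({"protein_id": proteins, "t_half_true_days": halflives})
    return peptides, truth


def _within_group_index(group_idx: np.ndarray) -> np.ndarray:
    """0-based running index within consecutive runs of equal values."""
    out = np.zeros(group_idx.size, dtype=int)
    if group_idx.size:
        same = np.r_[False, group_idx[1:] == group_idx[:-1]]
        run = np.cumsum(~same) - 1
        out = np.arange(group_idx.size) - np.flatnonzero(~same)[run]
    return out


# ---------------------------------------------------------------------------
# Splice-junction PSI simulator
# ---------------------------------------------------------------------------


def simulate_junction_psi(
    n_junctions: int,
    n_samples_per_group: int,
    cryptic_fraction: float,
    seed: int,
    *,
    delta_psi: float | tuple[float, float] = 0.3,
    control_presence_rate: float = 0.02,
    detection_floor: float = 0.01,
    noise_sd: float = 0.02,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate a PSI table for control vs knockdown groups.

    Canonical junctions share a common Beta-distributed mean PSI across
    groups; planted cryptic junctions have control PSI at (or occasionally
    just above) zero — present above the detection floor in fewer than 5% of
    control samples — and knockdown PSI elevated by ``delta_psi`` (a scalar
    or uniform bounds).  Returns ``(psi, groups, truth)`` where ``psi`` is a
    junctions x samples table, ``groups`` maps sample -> group label and
    ``truth`` records planted status and realized group-mean difference.
    """
    _require(n_samples_per_group >= 2, "need >= 2 samples per group")
    _require(0.0 <= cryptic_fraction <= 1.0, "cryptic_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    n_cryptic = int(round(cryptic_fraction * n_junctions))
    is_cryptic = np.zeros(n_junctions, dtype=bool)
    is_cryptic[rng.choice(n_junctions, n_cryptic, replace=False)] = True

    samples = [f"ctrl_{i + 1}" for i in range(n_samples_per_group)] + [
        f"kd_{i + 1}" for i in range(n_samples_per_group)
    ]
    groups = pd.Series(
        ["control"] * n_samples_per_group + ["knockdown"] * n_samples_per_group,
        index=samples,
        name="group",
    )

    psi = np.zeros((n_junctions, 2 * n_samples_per_group))
    # canonical junctions: common mean, modest Beta noise around it
    canon = ~is_cryptic
    base = rng.beta(2.0, 2.0, int(canon.sum()))
    conc = 80.0
    psi[canon] = rng.beta(
        np.outer(base, np.ones(2 * n_samples_per_group)) * conc + 1e-6,
        np.outer(1.0 - base, np.ones(2 * n_samples_per_group)) * conc + 1e-6,
    )
    # cryptic junctions: control near zero, knockdown elevated by delta
    if n_cryptic:
        if isinstance(delta_psi, tuple):
            delta = rng.uniform(delta_psi[0], delta_psi[1], n_cryptic)
        else:
            delta = np.full(n_cryptic, float(delta_psi))
        ctrl = np.where(
            rng.random((n_cryptic, n_samples_per_group)) < control_presence_rate,
            rng.uniform(detection_floor * 1.5, detection_floor * 4,
                        (n_cryptic, n_samples_per_group)),
            0.0,
        )
        kd = delta[:, None] + (
            rng.normal(0.0, noise_sd, (n_cryptic, n_samples_per_group))
            if noise_sd > 0
            else 0.0
        )
        psi[is_cryptic, :n_samples_per_group] = ctrl
        psi[is_cryptic, n_samples_per_group:] = np.clip(kd, 0.0, 1.0)
    psi = np.clip(psi, 0.0, 1.0)

    junction_ids = [f"junc_{i:05d}" for i in range(n_junctions)]
    psi_df = pd.DataFrame(psi, index=pd.Index(junction_ids, name="junction_id"),
                          columns=samples)
    psi_df.insert(0, "gene", [f"GENE{i // 4:04d}" for i in range(n_junctions)])

    ctrl_cols = samples[:n_samples_per_group]
    kd_cols = samples[n_samples_per_group:]
    truth = pd.DataFrame(
        {
            "junction_id": junction_ids,
            "planted_cryptic": is_cryptic,
            "realized_dpsi": psi_df[kd_cols].mean(axis=1).to_numpy()
            - psi_df[ctrl_cols].mean(axis=1).to_numpy(),
        }
    )
    return psi_df, groups, truth


# ---------------------------------------------------------------------------
# NB expression-count simulator
# ---------------------------------------------------------------------------


def simulate_expression_counts(
    n_genes: int,
    groups: Mapping[str, int],
    de_fraction: float,
    seed: int,
    *,
    de_lfc: float = 2.0,
    mean_bounds: tuple[float, float] = (100.0, 1e4),
    dispersion: str | float = "trend",
    noise_gene_fraction: float = 0.05,
    noise_mean_bounds: tuple[float, float] = (0.5, 2.0),
    noise_dispersion: tuple[float, float] = (2.0, 4.0),
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate an NB count matrix with planted DE and noise-biased genes.

    Dispersion follows a decreasing trend phi(mu) = 0.05 + 2/mu unless a
    scalar is given (``dispersion=0`` is the Poisson limit).  DE genes get a
    ``de_lfc`` log2 fold change (random sign) in every non-reference group.
    A separate planted block of low-mean/high-dispersion genes models the
    noise-biased regime removed by the CV~mean filter; its mean range is
    disjoint from ``mean_bounds`` so the block is a well-defined truth set.

    Returns ``(counts, sample_groups, truth)``.
    """
    _require(len(groups) >= 1 and all(n >= 2 for n in groups.values()),
             "need >= 2 samples per group")
    _require(0.0 <= de_fraction <= 1.0, "de_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)

    n_noise = int(round(noise_gene_fraction * n_genes))
    n_regular = n_genes - n_noise
    mu = np.empty(n_genes)
    mu[:n_regular] = np.exp(
        rng.uniform(math.log(mean_bounds[0]), math.log(mean_bounds[1]), n_regular)
    )
    mu[n_regular:] = np.exp(
        rng.uniform(
            math.log(noise_mean_bounds[0]), math.log(noise_mean_bounds[1]), n_noise
        )
    )
    is_noise = np.zeros(n_genes, dtype=bool)
    is_noise[n_regular:] = True

    if dispersion == "trend":
        phi = 0.05 + 2.0 / mu
    else:
        phi = np.full(n_genes, float(dispersion))
    if n_noise:
        phi[n_regular:] = rng.uniform(*noise_dispersion, n_noise)

    n_de = int(round(de_fraction * n_regular))
    de_idx = rng.choice(n_regular, n_de, replace=False)
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[de_idx] = True
    signs = rng.choice([-1.0, 1.0], n_de)
    lfc = np.zeros(n_genes)
    lfc[de_idx] = de_lfc * signs

    group_names = list(groups)
    sample_names: list[str] = []
    sample_groups: list[str] = []
    cols = {}
    for gi, gname in enumerate(group_names):
        gmu = mu * (2.0**lfc if gi > 0 else 1.0)  # first group is reference
        for r in range(groups[gname]):
            sname = f"{gname}_{r + 1}"
            sample_names.append(sname)
            sample_groups.append(gname)
            cols[sname] = _nb_draw(rng, gmu, phi)
    counts = pd.DataFrame(
        cols, index=pd.Index([f"GENE{i:05d}" for i in range(n_genes)], name="gene")
    )
    truth = pd.DataFrame(
        {
            "gene": counts.index,
            "is_de": is_de,
            "true_lfc": lfc,
            "is_noise_biased": is_noise,
            "true_mean": mu,
            "true_dispersion": phi,
        }
    ).reset_index(drop=True)
    return counts, pd.Series(sample_groups, index=sample_names, name="group"), truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mu, var = mu + phi*mu^2) draw; phi=0 falls back to Poisson."""
    out = np.empty(mu.size, dtype=int)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mu[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    """Write a table as TSV (the package's universal exchange format)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def write_screen_dataset(
    out_dir: str | Path,
    calls: pd.DataFrame,
    counts: pd.DataFrame,
    truth: pd.DataFrame,
    library: pd.DataFrame,
) -> dict[str, Path]:
    out = Path(out_dir)
    return {
        "calls": write_table(calls, out / "guide_calls.tsv"),
        "counts": write_table(counts, out / "guide_counts.tsv"),
        "truth": write_table(truth, out / "screen_truth.tsv"),
        "library": write_table(library, out / "guide_library.tsv"),
    }


def write_summaries(out_dir: str | Path,
                    summaries: Mapping[str, pd.DataFrame]) -> dict[str, Path]:
    out = Path(out_dir)
    return {
        sid: write_table(df, out / f"summary_{sid}.tsv") for sid, df in summaries.items()
    }
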