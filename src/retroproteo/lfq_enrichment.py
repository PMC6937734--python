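"""Label-free quantitative IP-MS differential enrichment.

Implements the post-processing chain for affinity-purification /
mass-spectrometry (AP-MS) experiments quantified by MaxQuant-style LFQ:

1. **Preprocessing** — drop reverse/contaminant entries and configurable
   exclusions (default IGHG1, the mouse-IgG heavy chain that dominates
   mock IPs), log2-transform, mask zeros as missing, drop all-missing rows.
2. **Imputation, all-missing groups** — proteins undetected in every
   replicate of a group receive left-censored draws, uniform on
   [μ_c − 3σ_c, μ_c − 2σ_c] per replicate column c.
3. **Imputation, partially missing groups** — proteins with some but not
   all replicates observed receive model-based draws: from fully observed
   proteins a distribution of relative replicate differences
   delta = (Int_rep1 − Int_rep2) / mean(Int_rep1, Int_rep2) is fitted,
   then delta_new ~ Normal(μ_delta, sd_delta/(ρ̄·√2)) with ρ̄ the mean
   pairwise correlation of the group's replicate columns, and
   I_new = mean(observed replicates) · |1 + delta_new|.
4. **Comparison** — per-protein two-sample t-test (Welch by default),
   Benjamini–Hochberg adjustment within the comparison, log2 fold change
   as case mean − control mean.  A protein is significant when
   p.adj ≤ 0.05, log2FC ≥ 1, and ≥ 2 case replicates are non-imputed.
5. **Integration** — per-protein count of comparisons passed and a tier
   summary (≥1, ≥2, ≥3 comparisons).

Also houses the gel-band identification ranking heuristic
(:func:`rank_band_ids`).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import RawIntensityTable

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

#: Protein-id substrings removed during preprocessing by default.
DEFAULT_EXCLUSIONS = ("IGHG1",)


@dataclass
class IntensityMatrix:
    """Log2 protein-by-sample intensities with explicit missing/imputed masks."""

    protein_ids: list[str]
    samples: list[str]
    groups: list[str]  # per-sample, CASE or CONTROL
    log2_values: np.ndarray  # NaN where missing
    imputed_mask: np.ndarray

    def __post_init__(self) -> None:
        self.log2_values = np.asarray(self.log2_values, dtype=float)
        n, m = len(self.protein_ids), len(self.samples)
        if self.log2_values.shape != (n, m):
            raise ValueError("log2_values shape mismatch")
        if len(self.groups) != m:
            raise ValueError("one group label per sample required")
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros((n, m), dtype=bool)
        self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
        if self.imputed_mask.shape != (n, m):
            raise ValueError("imputed_mask shape mismatch")

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            protein_ids=list(self.protein_ids),
            samples=list(self.samples),
            groups=list(self.groups),
            log2_values=self.log2_values.copy(),
            imputed_mask=self.imputed_mask.copy(),
        )

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.groups])


@dataclass
class ImputationModel:
    """Replicate-difference model fitted from fully observed proteins."""

    mu_delta: float
    sd_delta: float
    mean_pairwise_correlation: float
    per_replicate_mean: dict[str, float] = field(default_factory=dict)
    per_replicate_sd: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_delta < 0:
            raise ValueError("sd_delta must be non-negative")


@dataclass
class ComparisonResult:
    """Per-protein statistics for one case-vs-control comparison."""

    protein_id: str
    log2_fold_change: float
    p_value: float
    p_adjusted: float
    n_nonimputed_case: int
    significant: bool


# ---------------------------------------------------------------------------
# Preprocessing


def preprocess(
    raw: RawIntensityTable,
    groups: Sequence[str],
    exclusions: Sequence[str] = DEFAULT_EXCLUSIONS,
) -> IntensityMatrix:
    """Filter, log2-transform and mask a raw intensity table.

    Removes reverse/contaminant-flagged rows and rows whose protein id
    contains any exclusion substring; log2-transforms non-zero values with
    zeros becoming missing (NaN); drops rows missing everywhere.  ``groups``
    assigns each sample column to ``case`` or ``control``.
    """
    if len(groups) != len(raw.sample_columns):
        raise ValueError("one group label per sample column required")
    for g in groups:
        if g not in (CASE, CONTROL):
            raise ValueError(f"group label must be {CASE!r} or {CONTROL!r}, got {g!r}")
    keep = ~(raw.reverse_flags | raw.contaminant_flags)
    for i, pid in enumerate(raw.protein_ids):
        if any(x in pid for x in exclusions):
            keep[i] = False
    values = raw.values[keep]
    ids = [pid for pid, k in zip(raw.protein_ids, keep) if k]
    with np.errstate(divide="ignore"):
        log2 = np.where(values > 0, np.log2(np.maximum(values, 1e-300)), np.nan)
    observed = np.isfinite(log2)
    row_keep = observed.any(axis=1)
    log2 = log2[row_keep]
    ids = [pid for pid, k in zip(ids, row_keep) if k]
    if not ids:
        raise ValueError("no proteins remain after filtering")
    return IntensityMatrix(
        protein_ids=ids,
        samples=list(raw.sample_columns),
        groups=list(groups),
        log2_values=log2,
        imputed_mask=np.zeros_like(log2, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Imputation


def impute_group_missing(
    matrix: IntensityMatrix, group: str, seed: int
) -> IntensityMatrix:
    """Left-censored imputation for proteins missing in ALL group replicates.

    Each missing cell of such a protein is drawn uniformly from
    [μ_c − 3σ_c, μ_c − 2σ_c], where μ_c and σ_c are the mean and standard
    deviation of the replicate column's non-missing log2 values.
    Reproducible under a fixed seed; observed values are never altered.
    """
    out = matrix.copy()
    cols = np.nonzero(out.group_columns(group))[0]
    if len(cols) == 0:
        raise ValueError(f"no samples in group {group!r}")
    missing = ~np.isfinite(out.log2_values)
    all_missing_rows = np.nonzero(missing[:, cols].all(axis=1))[0]
    rng = np.random.default_rng(seed)
    mu = np.empty(len(cols))
    sigma = np.empty(len(cols))
    for k, c in enumerate(cols):
        observed = out.log2_values[~missing[:, c], c]
        if len(observed) < 2:
            raise ValueError(
                f"column {out.samples[c]!r} has fewer than 2 observed values; sd undefined"
            )
        mu[k] = observed.mean()
        sigma[k] = observed.std(ddof=1)
    for r in all_missing_rows:
        for k, c in enumerate(cols):
            lo, hi = mu[k] - 3 * sigma[k], mu[k] - 2 * sigma[k]
            out.log2_values[r, c] = rng.uniform(lo, hi)
            out.imputed_mask[r, c] = True
    return out


def fit_imputation_model(
    matrix: IntensityMatrix,
    group: str,
    seed: int = 0,
    correlation: Callable[[np.ndarray], float] | None = None,
) -> ImputationModel:
    """Fit the replicate-difference model from fully observed proteins.

    ``delta = (Int_rep1 − Int_rep2)/mean(Int_rep1, Int_rep2)`` is collected
    over all replicate pairs of the group, restricted to proteins observed
    (non-imputed) in every group replicate.  ``mean_pairwise_correlation``
    defaults to the mean Pearson correlation among the group's replicate
    columns on those proteins; pass ``correlation`` to plug in another
    definition.
    """
    cols = np.nonzero(matrix.group_columns(group))[0]
    if len(cols) < 2:
        raise ValueError("need at least 2 replicates to fit the model")
    observed = np.isfinite(matrix.log2_values) & ~matrix.imputed_mask
    full = observed[:, cols].all(axis=1)
    values = matrix.log2_values[np.ix_(full, cols)]
    if values.shape[0] < 3:
        raise ValueError("need at least 3 fully observed proteins to fit the model")
    deltas = []
    for a, b in itertools.combinations(range(values.shape[1]), 2):
        x, y = values[:, a], values[:, b]
        m = (x + y) / 2.0
        ok = m != 0
        deltas.append((x[ok] - y[ok]) / m[ok])
    delta = np.concatenate(deltas)
    if correlation is not None:
        rho_bar = float(correlation(values))
    else:
        rhos = [
            stats.pearsonr(values[:, a], values[:, b]).statistic
            for a, b in itertools.combinations(range(values.shape[1]), 2)
        ]
        rho_bar = float(np.mean(rhos))
    return ImputationModel(
        mu_delta=float(delta.mean()),
        sd_delta=float(delta.std(ddof=1)),
        mean_pairwise_correlation=rho_bar,
        per_replicate_mean={matrix.samples[c]: float(np.nanmean(matrix.log2_values[:, c])) for c in cols},
        per_replicate_sd={matrix.samples[c]: float(np.nanstd(matrix.log2_values[:, c], ddof=1)) for c in cols},
        seed=seed,
    )


def impute_partial_missing(
    matrix: IntensityMatrix,
    group: str,
    model: ImputationModel,
    seed: int,
) -> IntensityMatrix:
    """Model-based imputation for proteins missing in SOME group replicates.

    For each missing cell: ``delta_new ~ Normal(μ_delta,
    sd_delta/(ρ̄·√2))`` and ``I_new = mean(observed replicates) ·
    |1 + delta_new|``.  Raises when ρ̄ ≤ 0, since the draw's scale is then
    undefined — inspect the replicate correlations before imputing.
    """
    if model.mean_pairwise_correlation <= 0:
        raise ValueError(
            "mean pairwise replicate correlation is <= 0; the imputation scale "
            "sd_delta/(rho*sqrt(2)) is undefined — check replicate quality"
        )
    out = matrix.copy()
    cols = np.nonzero(out.group_columns(group))[0]
    missing = ~np.isfinite(out.log2_values)
    rng = np.random.default_rng(seed)
    scale = model.sd_delta / (model.mean_pairwise_correlation * np.sqrt(2.0))
    for r in range(out.log2_values.shape[0]):
        miss = [c for c in cols if missing[r, c]]
        obs = [c for c in cols if not missing[r, c] and not out.imputed_mask[r, c]]
        if not miss or not obs:
            continue
        mean_other = out.log2_values[r, obs].mean()
        for c in miss:
            delta_new = rng.normal(model.mu_delta, scale)
            out.log2_values[r, c] = mean_other * abs(1.0 + delta_new)
            out.imputed_mask[r, c] = True
    return out


def impute(matrix: IntensityMatrix, seed: int) -> IntensityMatrix:
    """Run both imputation stages for both groups.

    All-missing groups first (left-censored draws), then partially missing
    groups (replicate-difference model, fitted before any imputed values
    exist).  One seeded generator stream per stage/group, derived from
    ``seed``.
    """
    models = {
        g: fit_imputation_model(matrix, g, seed=seed)
        for g in (CASE, CONTROL)
    }
    out = matrix
    for i, g in enumerate((CASE, CONTROL)):
        out = impute_group_missing(out, g, seed=seed + 1 + i)
    for i, g in enumerate((CASE, CONTROL)):
        out = impute_partial_missing(out, g, models[g], seed=seed + 11 + i)
    return out


# ---------------------------------------------------------------------------
# Comparison and integration


def compare(
    matrix: IntensityMatrix,
    alpha: float = 0.05,
    min_log2_fc: float = 1.0,
    min_nonimputed_case: int = 2,
    equal_var: bool = False,
) -> list[ComparisonResult]:
    """Per-protein case-vs-control t-tests with BH adjustment.

    Welch's t-test by default (``equal_var=True`` for pooled-variance
    Student's).  log2FC = case mean − control mean.  Significance requires
    p.adj ≤ ``alpha``, log2FC ≥ ``min_log2_fc`` and at least
    ``min_nonimputed_case`` non-imputed case replicates.  Zero variance in
    both groups with equal means yields p = 1 by convention.
    """
    case_cols = np.nonzero(matrix.group_columns(CASE))[0]
    ctrl_cols = np.nonzero(matrix.group_columns(CONTROL))[0]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need at least 2 samples per group")
    values = matrix.log2_values
    if not np.isfinite(values).all():
        raise ValueError("missing values remain; run imputation first")
    x, y = values[:, case_cols], values[:, ctrl_cols]
    fold = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = stats.ttest_ind(x, y, axis=1, equal_var=equal_var).pvalue
    degenerate = (x.std(axis=1, ddof=1) == 0) & (y.std(axis=1, ddof=1) == 0)
    if degenerate.any():
        logger.info("%d proteins with zero variance in both groups", int(degenerate.sum()))
        pvals = np.where(degenerate, np.where(fold == 0, 1.0, 0.0), pvals)
    pvals = np.nan_to_num(pvals, nan=1.0)
    padj = multipletests(pvals, method="fdr_bh")[1]
    nonimp = (~matrix.imputed_mask[:, case_cols]).sum(axis=1)
    results = []
    for i, pid in enumerate(matrix.protein_ids):
        significant = bool(
            padj[i] <= alpha and fold[i] >= min_log2_fc and nonimp[i] >= min_nonimputed_case
        )
        results.append(
            ComparisonResult(
                protein_id=pid,
                log2_fold_change=float(fold[i]),
                p_value=float(pvals[i]),
                p_adjusted=float(padj[i]),
                n_nonimputed_case=int(nonimp[i]),
                significant=significant,
            )
        )
    return results


def integrate(
    comparisons: Sequence[tuple[str, Sequence[ComparisonResult]]]
) -> tuple[pd.Series, dict[int, int]]:
    """Count, per protein, the comparisons in which it was significant.

    Returns the per-protein counts (proteins with count ≥ 1 only) and a
    tier table mapping k → number of proteins significant in ≥ k
    comparisons, for k = 1..number of comparisons.
    """
    if not comparisons:
        raise ValueError("need at least one comparison")
    counts: dict[str, int] = {}
    for _, results in comparisons:
        for r in results:
            if r.significant:
                counts[r.protein_id] = counts.get(r.protein_id, 0) + 1
    series = pd.Series(counts, dtype=int).sort_values(ascending=False)
    tiers = {
        k: int((series >= k).sum()) for k in range(1, len(comparisons) + 1)
    }
    return series, tiers


# ---------------------------------------------------------------------------
# Gel-band identification ranking


@dataclass
class BandCandidate:
    """One search-engine protein identification from an excised gel band."""

    protein_id: str
    logE: float
    psm_count: int
    is_keratin: bool = False
    is_human: bool = True
    homology_group: Optional[str] = None


def rank_band_ids(
    ids: Sequence[BandCandidate], trypsin_id: str
) -> list[BandCandidate]:
    """Rank and prune gel-band protein identifications.

    Sort ascending by log E-value (most significant first; ties by higher
    PSM count, then id).  Drop keratins, non-human proteins, and anything
    ranked strictly below trypsin (trypsin itself included).  Then, from
    rank 2 down, drop entries homologous to a retained higher rank and
    entries with fewer than 50% of the top retained entry's PSMs.  The
    operation is idempotent.
    """
    ranked = sorted(ids, key=lambda c: (c.logE, -c.psm_count, c.protein_id))
    trypsin_rank = next(
        (i for i, c in enumerate(ranked) if c.protein_id == trypsin_id), None
    )
    if trypsin_rank is None:
        logger.info("trypsin id %r absent from band; no trypsin cut applied", trypsin_id)
    else:
        ranked = ranked[:trypsin_rank]
    ranked = [c for c in ranked if not c.is_keratin and c.is_human]
    if not ranked:
        return []
    retained = [ranked[0]]
    for c in ranked[1:]:
        if c.homology_group is not None and any(
            c.homology_group == r.homology_group for r in retained
        ):
            continue
        if c.psm_count < 0.5 * retained[0].psm_count:
            continue
        retained.append(c)
    return retained
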