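"""Per-view normalisation, batch correction, imputation and differential filters.

RNA counts go through median-of-ratios size factors and a ``log2(x/sf + 1)``
transform; protein and phosphopeptide log-abundances are median-centred per
sample, batch-corrected by a joint least-squares fit, and completed by a
two-stage imputation (condition-specific draws, then a down-shifted tail for
missing-not-at-random gaps).  Differential statistics per treatment time point
use Welch's t against the time-0 control, and the layer-specific filters keep
features with |log2FC| > 1 at any treated time point — with the additional
``p < 0.05`` and protein-coding requirements on the RNA layer only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one per sample).

    Only features with positive counts in every sample contribute; the factor
    of sample j is the median over those features of ``count_ij / geomean_i``.
    """
    mat = counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("counts must be non-negative")
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no feature has positive counts in all samples; "
                         "add a pseudocount before computing size factors")
    sub = mat[expressed]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def transform_counts(counts: pd.DataFrame,
                     factors: pd.Series | None = None) -> pd.DataFrame:
    """Variance-taming transform ``log2(count / size_factor + 1)``."""
    if factors is None:
        factors = size_factors(counts)
    f = factors.reindex(counts.columns).to_numpy(dtype=float)
    if np.any(f <= 0):
        raise ValueError("size factors must be strictly positive")
    return pd.DataFrame(np.log2(counts.to_numpy(dtype=float) / f + 1.0),
                        index=counts.index, columns=counts.columns)


def remove_batch(matrix: pd.DataFrame, batch_labels,
                 preserve=None) -> pd.DataFrame:
    """Subtract least-squares batch offsets while retaining condition effects.

    Batch coefficients are estimated jointly with the preserved condition
    terms (one-hot, intercept absorbed by the condition block) and subtracted.
    A single batch returns the input unchanged; a batch perfectly aliased
    with a condition raises, naming the pair.
    """
    batch = pd.Series(np.asarray(batch_labels), index=matrix.columns)
    levels = batch.unique()
    if len(levels) < 2:
        return matrix.copy()
    if preserve is not None:
        cond = pd.Series(np.asarray(preserve), index=matrix.columns)
        for b in levels:
            span = cond[batch == b].unique()
            if len(cond.unique()) > 1 and len(span) < 2:
                raise ValueError(
                    f"batch {b!r} is confounded with condition {span[0]!r}: "
                    "batch spans a single condition")
        cond_design = pd.get_dummies(cond, dtype=float)
    else:
        cond_design = pd.DataFrame(
            {"intercept": np.ones(matrix.shape[1])}, index=matrix.columns)
    batch_design = pd.get_dummies(batch, dtype=float, drop_first=True)
    X = np.hstack([cond_design.to_numpy(), batch_design.to_numpy()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("batch and condition designs are aliased "
                         f"(batches {list(levels)} vs conditions "
                         f"{sorted(set(np.asarray(preserve)))})")
    Y = matrix.to_numpy(dtype=float).T  # samples x features
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    n_cond = cond_design.shape[1]
    batch_part = X[:, n_cond:] @ coef[n_cond:]
    return pd.DataFrame((Y - batch_part).T, index=matrix.index,
                        columns=matrix.columns)


def normalize_abundance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Centre each sample so its median over observed values is zero."""
    mat = matrix.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(mat), axis=0)
    if np.any(n_obs == 0):
        bad = matrix.columns[n_obs == 0].tolist()
        raise ValueError(f"samples with no observed values: {bad}")
    med = np.nanmedian(mat, axis=0)
    return pd.DataFrame(mat - med, index=matrix.index, columns=matrix.columns)


def impute(matrix: pd.DataFrame, condition_labels,
           min_observed_frac: float = 0.5, tail_shift: float = 1.8,
           tail_sd_scale: float = 0.3, seed: int = 0) -> pd.DataFrame:
    """Two-stage imputation; observed entries are never altered.

    Stage 1 (condition-specific): a feature missing in a condition where at
    least ``min_observed_frac`` of replicates are observed is filled by draws
    from Normal(condition mean, condition sd).  Stage 2 (tail-based): all
    remaining gaps are drawn from a down-shifted normal,
    Normal(sample mean - tail_shift * sample sd, tail_sd_scale * sample sd),
    emulating abundances below the detection limit.
    """
    if not 0.0 < min_observed_frac <= 1.0:
        raise ValueError("min_observed_frac must lie in (0, 1]")
    cond = pd.Series(np.asarray(condition_labels), index=matrix.columns)
    if cond.isna().any():
        raise ValueError("condition labels must cover all samples")
    rng = np.random.default_rng(int(seed) % (2**31))
    out = matrix.to_numpy(dtype=float).copy()
    for level in cond.unique():
        idx = np.flatnonzero((cond == level).to_numpy())
        block = out[:, idx]
        obs = ~np.isnan(block)
        frac = obs.mean(axis=1)
        n_obs = np.maximum(obs.sum(axis=1), 1)
        filled = np.where(obs, block, 0.0)
        cmean = filled.sum(axis=1) / n_obs
        csd = np.sqrt(np.maximum(
            (np.where(obs, (block - cmean[:, None]) ** 2, 0.0)).sum(axis=1)
            / n_obs, 0.0))
        eligible = (frac >= min_observed_frac) & (frac < 1.0)
        for i in np.flatnonzero(eligible):
            gaps = idx[~obs[i]]
            out[i, gaps] = rng.normal(cmean[i], csd[i], size=gaps.size)
    # stage 2: per-sample down-shifted tail
    still = np.isnan(out)
    if still.any():
        smean = np.nanmean(out, axis=0)
        ssd = np.nanstd(out, axis=0, ddof=0)
        for j in range(out.shape[1]):
            gaps = np.flatnonzero(still[:, j])
            if gaps.size:
                out[gaps, j] = rng.normal(smean[j] - tail_shift * ssd[j],
                                          tail_sd_scale * ssd[j],
                                          size=gaps.size)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def differential(view: pd.DataFrame, meta: pd.DataFrame,
                 reference_time: float = 0.0) -> pd.DataFrame:
    """Welch-t differential statistics per feature and treated time point.

    Input values are assumed log2-scale, so the group mean difference is the
    log2 fold change.  Returns a long table (feature, time, log2FC, p,
    mean_treated, mean_control).
    """
    times = meta.loc[view.columns, "time"].astype(float)
    ref_cols = times.index[times == reference_time]
    if len(ref_cols) < 2:
        raise ValueError("need >= 2 reference (control) replicates")
    ref = view[ref_cols].to_numpy(dtype=float)
    results = []
    for t in sorted(times.unique()):
        if t == reference_time:
            continue
        cols = times.index[times == t]
        if len(cols) < 2:
            raise ValueError(f"time {t}: need >= 2 replicates for a variance estimate")
        trt = view[cols].to_numpy(dtype=float)
        lfc = trt.mean(axis=1) - ref.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(trt, ref, axis=1, equal_var=False)
        # identical degenerate groups (zero variance, zero difference) -> p = 1
        p = np.where(np.isnan(p), np.where(lfc == 0.0, 1.0, _P_FLOOR), p)
        p = np.clip(p, _P_FLOOR, 1.0)
        results.append(pd.DataFrame({
            "feature": view.index, "time": t, "log2FC": lfc, "p": p,
            "mean_treated": trt.mean(axis=1), "mean_control": ref.mean(axis=1)}))
    return pd.concat(results, ignore_index=True)


def filter_regulated(results: pd.DataFrame, layer: str,
                     feature_meta: pd.DataFrame | None = None,
                     lfc_thresh: float = 1.0,
                     p_thresh: float = 0.05) -> list[str]:
    """Layer-specific regulated-feature filter (strict inequalities).

    RNA: protein-coding features with ``|log2FC| > 1`` and ``p < 0.05`` at
    >= 1 treated time point.  Protein / phospho: ``|log2FC| > 1`` at >= 1
    treated time point, with no p-value requirement.
    """
    if layer not in ("rna", "protein", "phospho"):
        raise ValueError(f"unknown layer {layer!r}")
    hits = results["log2FC"].abs() > lfc_thresh
    if layer == "rna":
        hits &= results["p"] < p_thresh
    surv = results.loc[hits, "feature"].unique().tolist()
    if layer == "rna" and feature_meta is not None:
        coding = set(feature_meta.index[feature_meta["is_coding"].astype(bool)])
        surv = [f for f in surv if f in coding]
    logger.info("filter_regulated[%s]: %d features in, %d kept",
                layer, results["feature"].nunique(), len(surv))
    return sorted(surv)


def ddct(ct_table: pd.DataFrame, housekeeping_genes: list[str],
         control_group: str) -> pd.DataFrame:
    """Relative qPCR quantification by the delta-delta-Ct method.

    ``ct_table`` is long-format with columns (gene, group, ct); replicate Ct
    values are averaged per gene and group.  Per group, each target gene's
    dCt is its Ct minus the mean housekeeping Ct; ddCt subtracts the control
    group's dCt and relative expression is ``2 ** (-ddCt)``.
    """
    if not np.isfinite(ct_table["ct"]).all():
        raise ValueError("Ct values must be finite")
    mean_ct = ct_table.groupby(["group", "gene"])["ct"].mean().unstack()
    missing_hk = [g for g in housekeeping_genes
                  if g not in mean_ct.columns or mean_ct[g].isna().any()]
    if missing_hk:
        raise ValueError(f"housekeeping genes missing in some samples: {missing_hk}")
    hk = mean_ct[housekeeping_genes].mean(axis=1)
    targets = [g for g in mean_ct.columns if g not in housekeeping_genes]
    dct = mean_ct[targets].sub(hk, axis=0)
    if control_group not in dct.index:
        raise ValueError(f"control group {control_group!r} absent from table")
    ddct_vals = dct.sub(dct.loc[control_group], axis=1)
    rel = 2.0 ** (-ddct_vals)
    out = rel.reset_index().melt(id_vars="group", var_name="gene",
                                 value_name="relative_expression")
    return out
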