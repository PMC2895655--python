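"""Differential expression on two-colour mutant-vs-wild-type arrays.

Mutant and stage-matched wild-type cDNA are hybridised directly against
each other, so each spot carries M = log2(mutant/wt) and A = mean log
intensity. Arrays are normalised per print-tip group with loess
(tricube-weighted local linear regression of M on A), then genes are
tested per timepoint with a one-class SAM statistic

    d_i = mean_i / (se_i + s0)

where s0 is a small exchangeability offset stabilising genes with tiny
variance. The null is generated by random sign flips of each gene's
replicate vector after centring it on the gene mean and rescaling the
residuals by sqrt(n/(n-1)) (restoring the variance removed with the
mean): replicate noise is symmetric about zero under the null, and
centring keeps genuinely regulated genes from contaminating the null
with their own signal. q-values are the permutation FDR made monotone
in |d|. A gene is differentially regulated at a timepoint when
q < q_max and |mean log2 fold change| exceeds log2fc_min.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "loess_normalize",
    "choose_s0",
    "sam_statistics",
    "sam_qvalues",
    "call_differential",
    "analyze_timecourse",
]


def loess_normalize(array: pd.DataFrame, span: float = 0.4) -> pd.DataFrame:
    """Print-tip loess normalisation of a two-colour array.

    ``array`` has columns ``M``, ``A`` and ``tip_group``. Within each
    tip group the loess fit of M on A is subtracted from M; A is left
    unchanged. Groups with fewer than 30 spots fall back (with a
    warning) to a global fit across the whole array; a single group
    with fewer than 10 spots is an error.
    """
    required = {"M", "A", "tip_group"}
    missing = required - set(array.columns)
    if missing:
        raise ValueError(f"array is missing columns: {sorted(missing)}")
    if not np.isfinite(array[["M", "A"]].to_numpy()).all():
        raise ValueError("non-finite M or A values")
    groups = array.groupby("tip_group", sort=False)
    if groups.ngroups == 1 and len(array) < 10:
        raise ValueError("single tip group with fewer than 10 spots")

    out = array.copy()
    global_fit: np.ndarray | None = None
    small = [name for name, g in groups if len(g) < 30]
    if small:
        warnings.warn(
            f"tip groups {small} have < 30 spots; using a global loess fit",
            stacklevel=2,
        )
        global_fit = lowess(
            array["M"].to_numpy(),
            array["A"].to_numpy(),
            frac=span,
            it=0,
            return_sorted=False,
        )
    for name, g in groups:
        if len(g) < 30:
            fitted = global_fit[array.index.get_indexer(g.index)]
        else:
            fitted = lowess(
                g["M"].to_numpy(), g["A"].to_numpy(), frac=span, it=0,
                return_sorted=False,
            )
        out.loc[g.index, "M"] = g["M"].to_numpy() - fitted
    return out


def _mean_se(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = values.shape[1]
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    return mean, sd / np.sqrt(n)


def choose_s0(log_ratios: np.ndarray, rule: str = "cv_min") -> float:
    """Choose the SAM exchangeability offset s0.

    ``cv_min`` scans percentiles of the per-gene standard errors and
    picks the candidate minimising the coefficient of variation of the
    d-statistic's spread across se-ordered windows (so d's variability
    is as independent of se as possible). ``median`` is the
    deterministic fallback, also used automatically when there are too
    few genes to form stable windows.
    """
    mean, se = _mean_se(log_ratios)
    if rule == "median":
        return float(np.median(se))
    if rule != "cv_min":
        raise ValueError(f"unknown s0 rule {rule!r}")
    n_genes = len(se)
    if n_genes < 50:
        return float(np.median(se))
    order = np.argsort(se, kind="stable")
    windows = np.array_split(order, 10)
    candidates = np.percentile(se, np.arange(0, 101, 5))
    best_s0, best_cv = float(np.median(se)), np.inf
    for s0 in candidates:
        d = mean / (se + s0)
        spreads = np.array([np.std(d[w], ddof=1) for w in windows])
        m = spreads.mean()
        if m <= 0:
            continue
        cv = spreads.std(ddof=1) / m
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_statistics(
    log_ratios: pd.DataFrame, s0_rule: str = "cv_min", s0: float | None = None
) -> pd.DataFrame:
    """One-class SAM statistic per gene on a genes x replicates matrix.

    Returns a DataFrame with ``mean``, ``se`` and ``d_stat``; the s0
    actually used is stored in ``attrs["s0"]``. With s0 = 0 the
    statistic reduces to the one-sample t statistic.
    """
    values = log_ratios.to_numpy(dtype=float)
    if values.shape[1] < 3:
        raise ValueError(
            f"need >= 3 replicates for SAM, got {values.shape[1]}"
        )
    if not np.isfinite(values).all():
        raise ValueError("non-finite log ratios")
    if s0 is None:
        s0 = choose_s0(values, rule=s0_rule)
    mean, se = _mean_se(values)
    d = mean / (se + s0)
    out = pd.DataFrame(
        {"mean": mean, "se": se, "d_stat": d}, index=log_ratios.index
    )
    out.attrs["s0"] = float(s0)
    return out


def _null_residuals(values: np.ndarray) -> np.ndarray:
    """Centred, variance-restored residuals used for the sign-flip null.

    Subtracting the gene mean removes any true signal so regulated
    genes cannot contaminate the null; the sqrt(n/(n-1)) factor puts
    back the variance lost with the mean.
    """
    n = values.shape[1]
    r = values - values.mean(axis=1, keepdims=True)
    return r * np.sqrt(n / (n - 1))


def _null_d(residuals: np.ndarray, signs: np.ndarray, s0: float) -> np.ndarray:
    """d statistics after applying sign matrices; signs: (B, genes, reps)."""
    flipped = residuals[None, :, :] * signs
    n = residuals.shape[1]
    mean = flipped.mean(axis=2)
    se = flipped.std(axis=2, ddof=1) / np.sqrt(n)
    return mean / (se + s0)


def sam_qvalues(
    log_ratios: pd.DataFrame,
    stats: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> pd.Series:
    """Permutation q-values for the SAM statistic via sign-flip nulls.

    Null statistics come from sign flips of each gene's centred,
    variance-restored residuals (see :func:`_null_residuals`). For each
    candidate threshold |d_i| (genes sorted by decreasing |d|), the FDR
    is the median over permutations of the null count of |d| >= |d_i|,
    divided by the observed count i; q-values are the running minimum
    of these FDRs so they are monotone non-increasing in |d|. With
    ``exhaustive=True`` (default for small matrices) all 2^n sign
    patterns per gene are enumerated and the mean null count replaces
    the median over random draws.
    """
    values = log_ratios.to_numpy(dtype=float)
    n_genes, n_reps = values.shape
    s0 = float(stats.attrs["s0"])
    d_obs = stats["d_stat"].to_numpy()
    residuals = _null_residuals(values)
    if exhaustive is None:
        exhaustive = n_genes * 2**n_reps <= 20_000
    if exhaustive:
        patterns = np.array(
            list(itertools.product((1.0, -1.0), repeat=n_reps))
        )  # (2^n, reps)
        signs = patterns[:, None, :] * np.ones((1, n_genes, 1))
        d_null = _null_d(residuals, signs, s0)  # (2^n, genes)
        abs_null = np.abs(d_null).ravel()
        abs_null.sort()
        order = np.argsort(-np.abs(d_obs), kind="stable")
        abs_sorted = np.abs(d_obs)[order]
        # mean null count of |d_null| >= threshold, per sign assignment
        counts = (len(abs_null) - np.searchsorted(abs_null, abs_sorted, side="left"))
        null_counts = counts / 2**n_reps
    else:
        if n_perm < 100:
            warnings.warn(
                f"n_perm={n_perm} is small; q-values will be noisy",
                stacklevel=2,
            )
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n_genes, n_reps))
        d_null = _null_d(residuals, signs, s0)  # (n_perm, genes)
        order = np.argsort(-np.abs(d_obs), kind="stable")
        abs_sorted = np.abs(d_obs)[order]
        abs_null = np.sort(np.abs(d_null), axis=1)
        # per-permutation count of |d_null| >= threshold, then median
        counts = d_null.shape[1] - np.apply_along_axis(
            np.searchsorted, 1, abs_null, abs_sorted, side="left"
        )
        null_counts = np.median(counts, axis=0)

    i = np.arange(1, n_genes + 1)
    fdr = np.clip(null_counts / i, 0.0, 1.0)
    # q_i = min_{j >= i} fdr_j: monotone non-increasing in |d|
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(n_genes)
    q[order] = q_sorted
    return pd.Series(q, index=log_ratios.index, name="q_value")


def call_differential(
    results: pd.DataFrame, q_max: float = 0.01, log2fc_min: float = 0.7
) -> pd.DataFrame:
    """Per-timepoint significance flags and the gene-level union call.

    ``results`` is a long DataFrame with columns ``gene``, ``mutant``,
    ``timepoint``, ``mean_log2fc``, ``q_value`` (one row per gene per
    mutant per timepoint). Adds a boolean ``significant`` column and
    returns it; the gene-level union (significant at >= 1 timepoint in
    a given mutant, i.e. genetically downstream) is available from
    :func:`gene_level_calls`.
    """
    out = results.copy()
    out["significant"] = (
        (out["q_value"] < q_max) & (out["mean_log2fc"].abs() > log2fc_min)
    )
    return out


def gene_level_calls(results: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-timepoint calls to one row per gene per mutant."""
    grouped = results.groupby(["gene", "mutant"], sort=True)
    rows = []
    for (gene, mutant), g in grouped:
        sig = g[g["significant"]]
        direction = 0
        if len(sig):
            # direction of the strongest significant timepoint
            top = sig.loc[sig["mean_log2fc"].abs().idxmax()]
            direction = int(np.sign(top["mean_log2fc"]))
        rows.append(
            {
                "gene": gene,
                "mutant": mutant,
                "n_significant_timepoints": int(len(sig)),
                "downstream": bool(len(sig)),
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


def analyze_timecourse(
    tensors: dict[str, np.ndarray],
    gene_ids: list[str],
    q_max: float = 0.01,
    log2fc_min: float = 0.7,
    n_perm: int = 1000,
    seed: int | None = None,
    s0_rule: str = "cv_min",
) -> pd.DataFrame:
    """Run SAM per mutant and timepoint over a full timecourse.

    ``tensors`` maps mutant name to an array of shape
    (genes, timepoints, replicates) of normalised log2(mutant/wt)
    ratios. Returns the long DEResult table with significance flags.
    """
    frames = []
    seed_seq = np.random.SeedSequence(seed)
    for mutant in sorted(tensors):
        tensor = tensors[mutant]
        n_tp = tensor.shape[1]
        children = seed_seq.spawn(n_tp)
        for t in range(n_tp):
            ratios = pd.DataFrame(tensor[:, t, :], index=gene_ids)
            stats = sam_statistics(ratios, s0_rule=s0_rule)
            q = sam_qvalues(
                ratios, stats, n_perm=n_perm,
                seed=children[t], exhaustive=False,
            )
            frames.append(
                pd.DataFrame(
                    {
                        "gene": gene_ids,
                        "mutant": mutant,
                        "timepoint": t + 1,
                        "mean_log2fc": stats["mean"].to_numpy(),
                        "d_stat": stats["d_stat"].to_numpy(),
                        "q_value": q.to_numpy(),
                    }
                )
            )
    results = pd.concat(frames, ignore_index=True)
    return call_differential(results, q_max=q_max, log2fc_min=log2fc_min)
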