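"""Consensus reference construction and agreement statistics.

The reference standard for each dimension on each frame is the median across
experts of each expert's own median measurement (with two blinded readings an
expert's median is the mean of the pair).  Every method — the AI and each
expert treated as an individual — is then compared against this consensus
through signed deviations (measurement − reference):

* **bias** — mean signed deviation;
* **precision SD** — sample SD (n−1) of signed deviations;
* **absolute-error quantiles** at 50/80/90/95 % (linear interpolation between
  order statistics, the R type-7 default);
* **ICC(2,1)** — two-way random-effects, absolute-agreement, single-rater
  intraclass correlation of (method, reference) across frames, with F-based
  95 % CI;
* **F test** for equality of SDs and **Wilcoxon signed-rank** for paired
  absolute errors (their folded-normal distribution rules out a t test).

By design the consensus includes the evaluated expert's own readings (as in
the study design, where this slightly favours each expert); a leave-one-out
flag supports sensitivity analysis.  A pooled-readings consensus (median over
all 26 readings rather than 13 per-expert medians) is available behind
``consensus="pooled"``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .measure import DIMENSIONS

QUANTILE_PROBS = (0.5, 0.8, 0.9, 0.95)
DEFAULT_MIN_EXPERTS = 3
PHASES = ("ED", "ES")


# ---------------------------------------------------------------------------
# Scalar consensus operations


def per_expert_measurement(readings: Iterable[float]) -> float:
    """Median of one expert's non-missing readings (NaN if none).

    With the study's two readings this is their mean; with a single available
    reading it is that reading.
    """
    vals = np.asarray([v for v in readings if not np.isnan(v)], dtype=float)
    if vals.size == 0:
        return float("nan")
    return float(np.median(vals))


def consensus_reference(
    expert_measurements: Iterable[float],
    min_experts: int = DEFAULT_MIN_EXPERTS,
) -> float:
    """Median across experts' individual measurements.

    Even counts take the mean of the two middle values.  Returns NaN when
    fewer than ``min_experts`` experts contribute.
    """
    vals = np.asarray([v for v in expert_measurements if not np.isnan(v)], dtype=float)
    if vals.size < min_experts:
        return float("nan")
    return float(np.median(vals))


# ---------------------------------------------------------------------------
# Table-level consensus


def _dim_col(dim: str) -> str:
    return f"{dim}_mm"


def per_expert_table(measurements: pd.DataFrame, expert_ids: Sequence[str]) -> pd.DataFrame:
    """Per-expert median measurement per frame and dimension.

    ``measurements`` is the per-reading table from
    :func:`echodim.measure.measurements_table`.
    """
    m = measurements[measurements["rater_id"].isin(expert_ids)]
    cols = [_dim_col(d) for d in DIMENSIONS]
    out = (
        m.groupby(["frame_id", "rater_id", "phase"], as_index=False)[cols]
        .median()  # skips NaN readings; all-NaN -> NaN
        .sort_values(["frame_id", "rater_id"])
        .reset_index(drop=True)
    )
    return out


def _consensus_from_matrix(mat: pd.DataFrame, min_experts: int) -> pd.Series:
    counts = mat.notna().sum(axis=1)
    med = mat.median(axis=1, skipna=True)
    med[counts < min_experts] = np.nan
    return med


def consensus_table(
    measurements: pd.DataFrame,
    expert_ids: Sequence[str],
    *,
    min_experts: int = DEFAULT_MIN_EXPERTS,
    method: str = "per-expert-median",
) -> pd.DataFrame:
    """Consensus reference per frame (wide: one column per dimension).

    ``method="per-expert-median"`` (default) first reduces each expert to
    their median reading, then takes the median across experts;
    ``"pooled"`` pools every expert reading directly.
    """
    if method == "per-expert-median":
        base = per_expert_table(measurements, expert_ids)
    elif method == "pooled":
        base = measurements[measurements["rater_id"].isin(expert_ids)]
    else:
        raise ValueError(f"unknown consensus method {method!r}")
    out = {}
    for dim in DIMENSIONS:
        mat = base.pivot_table(
            index="frame_id", columns="rater_id", values=_dim_col(dim), aggfunc="median"
        )
        out[_dim_col(dim)] = _consensus_from_matrix(mat, min_experts)
    return pd.DataFrame(out)


def leave_one_out_consensus(
    measurements: pd.DataFrame,
    expert_ids: Sequence[str],
    *,
    min_experts: int = DEFAULT_MIN_EXPERTS,
) -> dict[str, pd.DataFrame]:
    """Per-expert consensus tables that exclude that expert's own readings."""
    out = {}
    for rid in expert_ids:
        others = [e for e in expert_ids if e != rid]
        out[rid] = consensus_table(measurements, others, min_experts=min_experts)
    return out


def method_measurements_long(
    measurements: pd.DataFrame,
    expert_ids: Sequence[str],
    ai_id: str = "AI",
) -> pd.DataFrame:
    """Long per-method measurement table (one value per frame, method, dim).

    Experts are reduced to their per-expert median; the AI contributes its
    single reading.
    """
    experts = per_expert_table(measurements, expert_ids)
    ai = measurements[measurements["rater_id"] == ai_id][
        ["frame_id", "rater_id", "phase"] + [_dim_col(d) for d in DIMENSIONS]
    ]
    wide = pd.concat([experts, ai], ignore_index=True).rename(
        columns={"rater_id": "method_id"}
    )
    long = wide.melt(
        id_vars=["frame_id", "method_id", "phase"],
        value_vars=[_dim_col(d) for d in DIMENSIONS],
        var_name="dimension",
        value_name="measurement_mm",
    )
    long["dimension"] = long["dimension"].str.removesuffix("_mm")
    return long


def signed_deviations(
    method_measurements: pd.DataFrame,
    reference: pd.DataFrame,
    *,
    loo_reference: dict[str, pd.DataFrame] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Deviation table: per-frame measurement − reference, per method and dim.

    ``method_measurements`` is the long table from
    :func:`method_measurements_long`; ``reference`` the wide consensus table.
    When ``loo_reference`` is given, each expert method is compared against
    the consensus excluding that expert (the AI always uses the full one).
    Rows where either side is missing are excluded; the count of exclusions
    is returned alongside.
    """
    ref_long = (
        reference.reset_index()
        .melt(id_vars="frame_id", var_name="dimension", value_name="reference_mm")
    )
    ref_long["dimension"] = ref_long["dimension"].str.removesuffix("_mm")
    dev = method_measurements.merge(ref_long, on=["frame_id", "dimension"], how="left")

    if loo_reference:
        for rid, ref in loo_reference.items():
            rl = (
                ref.reset_index()
                .melt(id_vars="frame_id", var_name="dimension", value_name="loo_mm")
            )
            rl["dimension"] = rl["dimension"].str.removesuffix("_mm")
            mask = dev["method_id"] == rid
            sub = dev.loc[mask, ["frame_id", "dimension"]].merge(
                rl, on=["frame_id", "dimension"], how="left"
            )
            dev.loc[mask, "reference_mm"] = sub["loo_mm"].to_numpy()

    complete = dev["measurement_mm"].notna() & dev["reference_mm"].notna()
    n_excluded = int((~complete).sum())
    dev = dev[complete].copy()
    dev["signed_deviation_mm"] = dev["measurement_mm"] - dev["reference_mm"]
    cols = [
        "frame_id",
        "method_id",
        "phase",
        "dimension",
        "measurement_mm",
        "reference_mm",
        "signed_deviation_mm",
    ]
    return dev[cols].reset_index(drop=True), n_excluded


# ---------------------------------------------------------------------------
# Agreement statistics


def bias_and_precision(deviations) -> tuple[float, float]:
    """(mean, sample SD with n−1 denominator) of signed deviations; n ≥ 2."""
    d = np.asarray(deviations, dtype=float)
    if d.size < 2:
        raise ValueError("bias/precision require at least 2 deviations")
    return float(np.mean(d)), float(np.std(d, ddof=1))


def abs_quantiles(deviations, probs: Sequence[float] = QUANTILE_PROBS) -> np.ndarray:
    """Quantiles of |deviation| with linear order-statistic interpolation."""
    d = np.asarray(deviations, dtype=float)
    if d.size == 0:
        raise ValueError("abs_quantiles requires a nonempty sample")
    return np.quantile(np.abs(d), probs, method="linear")


def cumulative_error_curve(deviations) -> tuple[np.ndarray, np.ndarray]:
    """Empirical cumulative curve of absolute deviations.

    Returns (fractions, |deviation|) through the order statistics at plotting
    positions k/(n−1); linear interpolation of the curve reproduces
    :func:`abs_quantiles` at any probability.
    """
    d = np.abs(np.asarray(deviations, dtype=float))
    if d.size == 0:
        raise ValueError("cumulative_error_curve requires a nonempty sample")
    d = np.sort(d)
    if d.size == 1:
        return np.array([1.0]), d
    fracs = np.arange(d.size) / (d.size - 1)
    return fracs, d


def icc_absolute_agreement(
    method, reference, alpha: float = 0.05
) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the two-way ANOVA mean squares of the paired (method,
    reference) values across frames — targets are frames, the two "raters"
    are the method and the consensus reference — with the F-based
    McGraw–Wong confidence interval, clipped to [−1, 1].  Requires ≥ 3
    complete pairs and nonzero total variance.  Degenerate cases (e.g. exact
    agreement, where the residual mean square is zero) return NaN bounds.
    """
    x = np.asarray(method, dtype=float)
    y = np.asarray(reference, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("ICC requires at least 3 complete (method, reference) pairs")
    data = np.column_stack([x, y])  # n targets x k raters
    k = 2
    if np.var(data) == 0:
        raise ValueError("ICC undefined: zero total variance")

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: zero total variance")
    icc = float((msr - mse) / denom)

    with np.errstate(divide="ignore", invalid="ignore"):
        a = k * icc / (n * (1.0 - icc)) if icc != 1.0 else np.inf
        b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc != 1.0 else np.inf
        num_v = (a * msc + b * mse) ** 2
        den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num_v / den_v if den_v > 0 else np.nan
        lo = hi = np.nan
        if np.isfinite(v) and v > 0:
            f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (
                n * (msr - f1 * mse)
                / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            )
            hi = (
                n * (f2 * msr - mse)
                / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
            )
    if np.isfinite(lo):
        lo = float(np.clip(lo, -1.0, 1.0))
    else:
        lo = float("nan")
    if np.isfinite(hi):
        hi = float(np.clip(hi, -1.0, 1.0))
    else:
        hi = float("nan")
    return icc, lo, hi


def f_test_sd(deviations_a, deviations_b) -> tuple[float, float]:
    """Variance-ratio F test for equality of two standard deviations.

    F = var(a)/var(b) on (n_a−1, n_b−1) degrees of freedom with a two-sided
    p-value (twice the smaller tail), as in R's ``var.test``.
    """
    a = np.asarray(deviations_a, dtype=float)
    b = np.asarray(deviations_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("F test requires at least 2 observations per sample")
    var_a, var_b = np.var(a, ddof=1), np.var(b, ddof=1)
    if var_b == 0:
        raise ValueError("F test undefined: zero variance in denominator sample")
    f = float(var_a / var_b)
    dist = sps.f(a.size - 1, b.size - 1)
    p = float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))
    return f, p


def wilcoxon_abs_errors(errors_a, errors_b=None) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired absolute errors.

    Pass two paired samples, or a single sample of differences.  Zero
    differences are dropped; the returned statistic is W+ (sum of ranks of
    positive differences).  The null distribution is exact for n ≤ 25 and a
    normal approximation with continuity correction above.
    """
    a = np.asarray(errors_a, dtype=float)
    d = a if errors_b is None else a - np.asarray(errors_b, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("Wilcoxon test requires at least one nonzero difference")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        try:
            res = sps.wilcoxon(d, zero_method="wilcox", method="exact")
        except (ValueError, NotImplementedError):
            res = sps.wilcoxon(d, zero_method="wilcox", method="approx", correction=True)
    else:
        res = sps.wilcoxon(d, zero_method="wilcox", method="approx", correction=True)
    return w_plus, float(res.pvalue)


# ---------------------------------------------------------------------------
# Stratified summaries and comparisons


def _summary_row(sub: pd.DataFrame, method_id: str, dimension: str, phase: str) -> dict:
    row: dict = {
        "method_id": method_id,
        "dimension": dimension,
        "phase": phase,
        "n": int(len(sub)),
        "available": len(sub) >= 2,
    }
    nanfill = {
        "bias_mm": np.nan,
        "precision_sd_mm": np.nan,
        **{f"abs_q{int(p * 100)}_mm": np.nan for p in QUANTILE_PROBS},
        "icc": np.nan,
        "icc_ci_low": np.nan,
        "icc_ci_high": np.nan,
    }
    if len(sub) < 2:
        row.update(nanfill)
        return row
    devs = sub["signed_deviation_mm"].to_numpy()
    bias, sd = bias_and_precision(devs)
    q = abs_quantiles(devs)
    row.update(
        {
            "bias_mm": bias,
            "precision_sd_mm": sd,
            **{
                f"abs_q{int(p * 100)}_mm": float(v)
                for p, v in zip(QUANTILE_PROBS, q)
            },
        }
    )
    try:
        icc, lo, hi = icc_absolute_agreement(
            sub["measurement_mm"].to_numpy(), sub["reference_mm"].to_numpy()
        )
    except ValueError:
        icc = lo = hi = np.nan
    row.update({"icc": icc, "icc_ci_low": lo, "icc_ci_high": hi})
    return row


def stratified_summaries(deviation_table: pd.DataFrame) -> pd.DataFrame:
    """Agreement summaries per (method, dimension, phase ∈ {ED, ES, pooled}).

    Strata with fewer than 2 deviations are marked unavailable (NaN
    statistics).  The pooled stratum concatenates both phases.
    """
    rows = []
    for (method_id, dimension), sub in deviation_table.groupby(
        ["method_id", "dimension"], sort=True
    ):
        for phase in PHASES:
            rows.append(
                _summary_row(sub[sub["phase"] == phase], method_id, dimension, phase)
            )
        rows.append(_summary_row(sub, method_id, dimension, "pooled"))
    return pd.DataFrame(rows)


def comparison_tests(
    deviation_table: pd.DataFrame,
    ai_id: str = "AI",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Headline significance tests per dimension.

    For each dimension: F tests of precision SD (AI vs pooled individual
    experts; ES vs ED within the AI and within the experts) and a Wilcoxon
    signed-rank test of the AI absolute error against the per-frame median
    expert absolute error.  ``significant`` applies the two-sided threshold
    ``alpha`` with no multiplicity adjustment.
    """
    rows = []

    def _add(comparison, dimension, statistic_name, statistic, p, n_a, n_b):
        rows.append(
            {
                "comparison": comparison,
                "dimension": dimension,
                "statistic_name": statistic_name,
                "statistic": statistic,
                "p": p,
                "n_a": n_a,
                "n_b": n_b,
                "significant": bool(p < alpha),
            }
        )

    for dimension, sub in deviation_table.groupby("dimension", sort=True):
        ai = sub[sub["method_id"] == ai_id]
        experts = sub[sub["method_id"] != ai_id]
        pairs = [
            (
                "ai_vs_experts_sd",
                ai["signed_deviation_mm"],
                experts["signed_deviation_mm"],
            ),
            (
                "ai_es_vs_ed_sd",
                ai.loc[ai["phase"] == "ES", "signed_deviation_mm"],
                ai.loc[ai["phase"] == "ED", "signed_deviation_mm"],
            ),
            (
                "experts_es_vs_ed_sd",
                experts.loc[experts["phase"] == "ES", "signed_deviation_mm"],
                experts.loc[experts["phase"] == "ED", "signed_deviation_mm"],
            ),
        ]
        for name, a, b in pairs:
            try:
                f, p = f_test_sd(a, b)
            except ValueError:
                continue
            _add(name, dimension, "F", f, p, len(a), len(b))

        expert_abs = (
            experts.assign(abs_dev=experts["signed_deviation_mm"].abs())
            .groupby("frame_id")["abs_dev"]
            .median()
        )
        ai_abs = ai.set_index("frame_id")["signed_deviation_mm"].abs()
        paired = pd.concat([ai_abs.rename("ai"), expert_abs.rename("experts")], axis=1).dropna()
        if len(paired) >= 2 and (paired["ai"] != paired["experts"]).any():
            w, p = wilcoxon_abs_errors(paired["ai"].to_numpy(), paired["experts"].to_numpy())
            _add(
                "ai_vs_experts_abs_error",
                dimension,
                "W+",
                w,
                p,
                len(paired),
                len(paired),
            )
    return pd.DataFrame(rows)
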