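"""Agreement and diagnostic-accuracy statistics for paired Pd/Pa data.

Quantitative agreement between invasively measured (mPd/Pa) and simulated
(vPd/Pa) resting pressure ratios is summarized Bland-Altman style: the mean
and standard deviation of the paired differences (measured - virtual), the
t-based 95% CI of the mean difference, limits of agreement at +/- 2 SD, the
mean absolute error, and Pearson's r.

Diagnostic accuracy treats the measured ratio as the reference and the
virtual ratio as the index test, both dichotomized at the resting
significance threshold (<= 0.9 after rounding to 2 decimals).  Sensitivity,
specificity, predictive values and overall accuracy carry exact
Clopper-Pearson binomial 95% confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import nan

import numpy as np
import pandas as pd
from scipy import stats

from .extraction import SIGNIFICANCE_THRESHOLD, classify_physiological_significance


class AgreementError(ValueError):
    pass


@dataclass(frozen=True)
class PairedSeries:
    """Paired measured/virtual pressure ratios for a set of stenoses."""

    case_ids: tuple[str, ...]
    measured: np.ndarray
    virtual: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.measured, dtype=float)
        v = np.asarray(self.virtual, dtype=float)
        if len(m) != len(v) or len(m) != len(self.case_ids):
            raise AgreementError("case_ids, measured and virtual lengths differ")
        if len(m) < 2:
            raise AgreementError("need at least 2 pairs")
        if np.any(m <= 0.0) or np.any(v <= 0.0):
            raise AgreementError("pressure ratios must be > 0")
        object.__setattr__(self, "measured", m)
        object.__setattr__(self, "virtual", v)

    def __len__(self) -> int:
        return len(self.measured)

    @classmethod
    def from_csv(cls, path) -> "PairedSeries":
        df = pd.read_csv(path)
        required = {"case_id", "mPdPa", "vPdPa"}
        if not required.issubset(df.columns):
            raise AgreementError(
                f"pairs CSV must have columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        return cls(
            case_ids=tuple(str(c) for c in df["case_id"]),
            measured=df["mPdPa"].to_numpy(),
            virtual=df["vPdPa"].to_numpy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": self.case_ids,
                "mPdPa": self.measured,
                "vPdPa": self.virtual,
            }
        )


def bland_altman(pairs: PairedSeries) -> dict:
    """Mean difference (measured - virtual), SD, limits, and t-based 95% CI.

    The SD uses the n-1 denominator and the CI half-width is
    t(0.975, n-1) * SD / sqrt(n); limits of agreement are mean +/- 2 SD.
    """
    d = pairs.measured - pairs.virtual
    n = len(d)
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    ci_halfwidth = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    return {
        "n": n,
        "mean_difference": mean_diff,
        "sd_differences": sd,
        "ci_mean_difference_halfwidth": ci_halfwidth,
        "limits_of_agreement": (mean_diff - 2.0 * sd, mean_diff + 2.0 * sd),
    }


def mean_absolute_error(pairs: PairedSeries) -> float:
    return float(np.abs(pairs.measured - pairs.virtual).mean())


def percentage_error_variants(pairs: PairedSeries) -> dict:
    """Two conventional relative-error summaries (%), reported side by side.

    ``mae_over_mean_measured``: MAE / mean(measured); ``mean_relative``:
    mean of case-wise |difference| / measured.  Both are computed because
    'percentage error' has no single convention.
    """
    d = np.abs(pairs.measured - pairs.virtual)
    return {
        "mae_over_mean_measured": float(100.0 * d.mean() / pairs.measured.mean()),
        "mean_relative": float(100.0 * (d / pairs.measured).mean()),
    }


def pearson_r(pairs: PairedSeries) -> float:
    """Sample Pearson product-moment correlation of the paired series."""
    if len(pairs) < 3:
        raise AgreementError("Pearson r needs at least 3 pairs")
    if pairs.measured.std() == 0.0 or pairs.virtual.std() == 0.0:
        raise AgreementError("Pearson r undefined for zero-variance series")
    return float(stats.pearsonr(pairs.measured, pairs.virtual).statistic)


def binomial_ci(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Clopper-Pearson exact confidence interval for a proportion."""
    if trials < 1:
        raise AgreementError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise AgreementError("successes must be in [0, trials]")
    alpha = 1.0 - level
    lo = (
        0.0
        if successes == 0
        else float(stats.beta.ppf(alpha / 2.0, successes, trials - successes + 1))
    )
    hi = (
        1.0
        if successes == trials
        else float(stats.beta.ppf(1.0 - alpha / 2.0, successes + 1, trials - successes))
    )
    return lo, hi


def _metric(successes: int, trials: int) -> dict:
    if trials == 0:
        return {"value": nan, "ci": (nan, nan), "k": 0, "n": 0}
    return {
        "value": successes / trials,
        "ci": binomial_ci(successes, trials),
        "k": successes,
        "n": trials,
    }


def diagnostic_accuracy(
    pairs: PairedSeries, threshold: float = SIGNIFICANCE_THRESHOLD
) -> dict:
    """Confusion matrix and diagnostic metrics with exact binomial CIs.

    Reference = measured, test = virtual; a case is positive when its ratio,
    rounded to 2 decimals, is <= threshold.  Metrics with a zero denominator
    are reported as NaN ("undefined"), not raised.
    """
    ref = np.array(
        [classify_physiological_significance(m, threshold) for m in pairs.measured]
    )
    test = np.array(
        [classify_physiological_significance(v, threshold) for v in pairs.virtual]
    )
    tp = int(np.sum(ref & test))
    fn = int(np.sum(ref & ~test))
    fp = int(np.sum(~ref & test))
    tn = int(np.sum(~ref & ~test))
    n = len(pairs)
    return {
        "confusion": {"TP": tp, "FP": fp, "TN": tn, "FN": fn},
        "sensitivity": _metric(tp, tp + fn),
        "specificity": _metric(tn, tn + fp),
        "ppv": _metric(tp, tp + fp),
        "npv": _metric(tn, tn + fn),
        "accuracy": _metric(tp + tn, n),
    }


@dataclass
class AgreementReport:
    """Full quantitative + diagnostic agreement summary."""

    pairs: PairedSeries
    bland_altman: dict
    mean_absolute_error: float
    percentage_error: dict
    pearson_r: float
    diagnostics: dict
    threshold: float = SIGNIFICANCE_THRESHOLD

    def to_dict(self) -> dict:
        diag = {}
        for key, val in self.diagnostics.items():
            if key == "confusion":
                diag[key] = val
            else:
                diag[key] = {
                    "value": val["value"],
                    "ci95": list(val["ci"]),
                    "k": val["k"],
                    "n": val["n"],
                }
        ba = dict(self.bland_altman)
        ba["limits_of_agreement"] = list(ba["limits_of_agreement"])
        return {
            "n_pairs": len(self.pairs),
            "threshold": self.threshold,
            "bland_altman": ba,
            "mean_absolute_error": self.mean_absolute_error,
            "percentage_error": self.percentage_error,
            "pearson_r": self.pearson_r,
            "diagnostics": diag,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)

    def summary_text(self) -> str:
        ba = self.bland_altman
        dg = self.diagnostics

        def fm(m):
            if np.isnan(m["value"]):
                return "undefined"
            return f"{m['value']:.2f} (95% CI {m['ci'][0]:.2f}-{m['ci'][1]:.2f})"

        lines = [
            f"Paired agreement, n = {ba['n']} stenoses",
            f"  mean difference (measured - virtual): {ba['mean_difference']:+.3f}"
            f" +/- {ba['ci_mean_difference_halfwidth']:.2f} (95% CI)",
            f"  SD of differences: {ba['sd_differences']:.3f}",
            f"  limits of agreement: [{ba['limits_of_agreement'][0]:.3f}, "
            f"{ba['limits_of_agreement'][1]:.3f}]",
            f"  mean absolute error: {self.mean_absolute_error:.3f}",
            f"  Pearson r: {self.pearson_r:.3f}",
            f"Diagnostic accuracy at Pd/Pa <= {self.threshold}",
            f"  confusion: {dg['confusion']}",
            f"  sensitivity: {fm(dg['sensitivity'])}",
            f"  specificity: {fm(dg['specificity'])}",
            f"  PPV: {fm(dg['ppv'])}",
            f"  NPV: {fm(dg['npv'])}",
            f"  accuracy: {fm(dg['accuracy'])}",
        ]
        return "\n".join(lines)


def agreement_report(
    pairs: PairedSeries, threshold: float = SIGNIFICANCE_THRESHOLD
) -> AgreementReport:
    return AgreementReport(
        pairs=pairs,
        bland_altman=bland_altman(pairs),
        mean_absolute_error=mean_absolute_error(pairs),
        percentage_error=percentage_error_variants(pairs),
        pearson_r=pearson_r(pairs),
        diagnostics=diagnostic_accuracy(pairs, threshold),
        threshold=threshold,
    )


def export_validation_figures(
    pairs: PairedSeries, report: AgreementReport, out_dir
) -> dict:
    """Write plot data (CSV) and rendered figures (SVG) for the validation set.

    Produces a side-by-side bar chart of measured vs virtual ratios, a
    Bland-Altman plot with the mean-difference line and +/- 2 SD boundaries,
    and a scatter with the identity line and the ordinary-least-squares
    best-fit of virtual on measured.  Returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    m, v = pairs.measured, pairs.virtual
    ids = list(pairs.case_ids)

    # --- bar chart data
    bar_df = pairs.to_frame()
    paths["bars_csv"] = out / "pdpa_bars.csv"
    bar_df.to_csv(paths["bars_csv"], index=False)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    xpos = np.arange(len(ids))
    ax.bar(xpos - 0.2, m, width=0.4, label="measured")
    ax.bar(xpos + 0.2, v, width=0.4, label="virtual")
    ax.set_xticks(xpos, ids)
    ax.set_ylabel("Pd/Pa")
    ax.set_ylim(0.0, 1.1)
    ax.legend()
    paths["bars_svg"] = out / "pdpa_bars.svg"
    fig.savefig(paths["bars_svg"], bbox_inches="tight")
    plt.close(fig)

    # --- Bland-Altman
    ba = report.bland_altman
    means = 0.5 * (m + v)
    diffs = m - v
    ba_df = pd.DataFrame({"case_id": ids, "mean": means, "difference": diffs})
    paths["bland_altman_csv"] = out / "bland_altman.csv"
    ba_df.to_csv(paths["bland_altman_csv"], index=False)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs)
    ax.axhline(ba["mean_difference"], color="k")
    for lim in ba["limits_of_agreement"]:
        ax.axhline(lim, color="k", linestyle=":")
    ax.set_xlabel("mean of mPd/Pa and vPd/Pa")
    ax.set_ylabel("mPd/Pa - vPd/Pa")
    paths["bland_altman_svg"] = out / "bland_altman.svg"
    fig.savefig(paths["bland_altman_svg"], bbox_inches="tight")
    plt.close(fig)

    # --- correlation scatter with OLS best fit of virtual on measured
    slope, intercept = np.polyfit(m, v, 1)
    fit_df = pd.DataFrame(
        {"slope": [slope], "intercept": [intercept], "pearson_r": [report.pearson_r]}
    )
    paths["correlation_csv"] = out / "correlation_fit.csv"
    fit_df.to_csv(paths["correlation_csv"], index=False)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(m, v)
    lims = np.array([min(m.min(), v.min()) - 0.05, max(m.max(), v.max()) + 0.05])
    ax.plot(lims, lims, color="gray", linestyle="--", label="identity")
    ax.plot(lims, slope * lims + intercept, color="k", label="best fit")
    ax.set_xlabel("mPd/Pa")
    ax.set_ylabel("vPd/Pa")
    ax.legend()
    paths["correlation_svg"] = out / "pdpa_correlation.svg"
    fig.savefig(paths["correlation_svg"], bbox_inches="tight")
    plt.close(fig)
    return {k: str(p) for k, p in paths.items()}
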