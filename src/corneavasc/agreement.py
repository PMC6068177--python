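"""Method-agreement statistics: Bland-Altman, paired tests, normality.

For paired density measurements from two imaging modalities over matched
regions of interest, agreement is summarized the standard way: differences
``d_i = a_i - b_i``; mean difference with a t-based 95% confidence interval;
limits of agreement (LoA) ``mean +/- 1.96 * SD`` with the sample (n-1) SD;
Pearson correlation of the raw pairs; a two-sided paired t-test on the
differences; and a Kolmogorov-Smirnov normality check per method, with the
Lilliefors correction by default since the normal parameters are estimated
from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.diagnostic import lilliefors

_REPORT_COLUMNS = [
    "pair", "n", "mean_diff", "sd_diff", "loa_lower", "loa_upper",
    "ci_lower", "ci_upper", "pearson_r", "t_p", "ks_p_a", "ks_p_b", "flags",
]


@dataclass
class PairedDensities:
    """Matched density series from two methods over the same ROIs."""

    method_a: str
    method_b: str
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.shape != self.values_b.shape or self.values_a.ndim != 1:
            raise ValueError("values_a and values_b must be equal-length 1-D")
        if self.n < 3:
            raise ValueError("at least 3 pairs are required")
        for v in (self.values_a, self.values_b):
            if v.min() < 0.0 or v.max() > 100.0:
                raise ValueError("densities must lie in [0, 100]")

    @property
    def n(self) -> int:
        return len(self.values_a)


@dataclass
class AgreementReport:
    """Bland-Altman + paired-test summary for one modality pair."""

    method_a: str
    method_b: str
    n: int
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_mean_lower: float
    ci_mean_upper: float
    pearson_r: float
    paired_t_p: float
    ks_p_a: float
    ks_p_b: float
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)
    flags: tuple[str, ...] = ()


class BlandAltmanAgreement(BaseEstimator):
    """Fit-shaped Bland-Altman agreement analysis.

    After ``fit(a, b)`` the fitted attributes hold the full agreement
    summary (``mean_diff_``, ``sd_diff_``, ``loa_lower_``/``loa_upper_``,
    ``ci_mean_``, ``pearson_r_``, ``paired_t_p_``, ``ks_p_a_``/``ks_p_b_``).

    Parameters
    ----------
    loa_multiplier : float
        SD multiple defining the limits of agreement (conventional 1.96 for
        a nominal 95% range).
    ci_level : float
        Confidence level of the t-based CI on the mean difference.
    lilliefors_correction : bool
        Use the Lilliefors KS variant (normal parameters estimated from the
        sample); plain one-sample KS against the fitted normal otherwise.
    """

    def __init__(
        self,
        loa_multiplier: float = 1.96,
        ci_level: float = 0.95,
        lilliefors_correction: bool = True,
    ):
        self.loa_multiplier = loa_multiplier
        self.ci_level = ci_level
        self.lilliefors_correction = lilliefors_correction

    def _ks_p(self, values: np.ndarray) -> float:
        if values.std(ddof=1) < 1e-12:
            return np.nan
        if self.lilliefors_correction:
            if len(values) < 4:  # Lilliefors tables start at n = 4
                return np.nan
            return float(lilliefors(values, dist="norm")[1])
        z = (values - values.mean()) / values.std(ddof=1)
        return float(stats.kstest(z, "norm").pvalue)

    def fit(self, a, b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("a and b must be equal-length 1-D arrays")
        n = len(a)
        if n < 3:
            raise ValueError("at least 3 pairs are required")
        d = a - b
        flags: list[str] = []
        self.n_ = n
        self.diffs_ = d
        self.means_ = 0.5 * (a + b)
        self.mean_diff_ = float(d.mean())
        self.sd_diff_ = float(d.std(ddof=1))
        if self.sd_diff_ < 1e-12:
            flags.append("degenerate_variance")
        self.loa_lower_ = self.mean_diff_ - self.loa_multiplier * self.sd_diff_
        self.loa_upper_ = self.mean_diff_ + self.loa_multiplier * self.sd_diff_
        tcrit = stats.t.ppf(0.5 + self.ci_level / 2.0, n - 1)
        half = tcrit * self.sd_diff_ / np.sqrt(n)
        self.ci_mean_ = (self.mean_diff_ - half, self.mean_diff_ + half)
        # paired comparison
        if np.std(a) < 1e-12 or np.std(b) < 1e-12:
            self.pearson_r_ = np.nan
            flags.append("correlation_undefined")
        else:
            self.pearson_r_ = float(stats.pearsonr(a, b).statistic)
        if self.sd_diff_ < 1e-12:
            # zero-variance differences: no evidence against equality
            self.paired_t_p_ = 1.0
        else:
            self.paired_t_p_ = float(stats.ttest_rel(a, b).pvalue)
        self.ks_p_a_ = self._ks_p(a)
        self.ks_p_b_ = self._ks_p(b)
        self.flags_ = tuple(flags)
        return self

    def report(self, method_a: str = "A", method_b: str = "B") -> AgreementReport:
        return AgreementReport(
            method_a=method_a,
            method_b=method_b,
            n=self.n_,
            mean_diff=self.mean_diff_,
            sd_diff=self.sd_diff_,
            loa_lower=self.loa_lower_,
            loa_upper=self.loa_upper_,
            ci_mean_lower=self.ci_mean_[0],
            ci_mean_upper=self.ci_mean_[1],
            pearson_r=self.pearson_r_,
            paired_t_p=self.paired_t_p_,
            ks_p_a=self.ks_p_a_,
            ks_p_b=self.ks_p_b_,
            means=self.means_,
            diffs=self.diffs_,
            flags=self.flags_,
        )


def bland_altman(
    pairs: PairedDensities, loa_multiplier: float = 1.96, ci_level: float = 0.95
) -> AgreementReport:
    """Bland-Altman agreement report for one modality pair."""
    est = BlandAltmanAgreement(loa_multiplier, ci_level)
    est.fit(pairs.values_a, pairs.values_b)
    return est.report(pairs.method_a, pairs.method_b)


def paired_comparison(
    pairs: PairedDensities, lilliefors_correction: bool = True
) -> tuple[float, float, float, float]:
    """(pearson_r, paired_t_p, ks_p_a, ks_p_b) for one modality pair."""
    est = BlandAltmanAgreement(lilliefors_correction=lilliefors_correction)
    est.fit(pairs.values_a, pairs.values_b)
    return est.pearson_r_, est.paired_t_p_, est.ks_p_a_, est.ks_p_b_


def report(agreements: list[AgreementReport], out: str | Path) -> list[Path]:
    """Write a summary CSV plus one Bland-Altman plot per modality pair.

    No multiple-testing correction is applied to the reported p-values
    (noted in the CSV metadata header row comment in the docs, not the file).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not agreements:
        raise ValueError("at least one AgreementReport is required")
    out = Path(out)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create report directory {out}: {exc}") from exc
    rows = []
    written: list[Path] = []
    for rep in agreements:
        pair = f"{rep.method_a}:{rep.method_b}"
        rows.append(
            dict(
                pair=pair, n=rep.n,
                mean_diff=rep.mean_diff, sd_diff=rep.sd_diff,
                loa_lower=rep.loa_lower, loa_upper=rep.loa_upper,
                ci_lower=rep.ci_mean_lower, ci_upper=rep.ci_mean_upper,
                pearson_r=rep.pearson_r, t_p=rep.paired_t_p,
                ks_p_a=rep.ks_p_a, ks_p_b=rep.ks_p_b,
                flags=";".join(rep.flags),
            )
        )
        if rep.means is not None:
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.scatter(rep.means, rep.diffs, s=18, color="tab:blue")
            ax.axhline(rep.mean_diff, color="k", label="mean")
            ax.axhline(0.0, color="gray", linestyle=":", label="zero")
            for loa in (rep.loa_lower, rep.loa_upper):
                ax.axhline(loa, color="k", linestyle="--")
            ax.set_xlabel("mean of methods (%)")
            ax.set_ylabel(f"{rep.method_a} - {rep.method_b} (%)")
            ax.set_title(f"Bland-Altman: {pair}")
            ax.legend(loc="best", fontsize=8)
            fig.tight_layout()
            plot_path = out / f"bland_altman_{rep.method_a}_{rep.method_b}.png"
            fig.savefig(plot_path, dpi=120)
            plt.close(fig)
            written.append(plot_path)
    csv_path = out / "agreement_summary.csv"
    pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(csv_path, index=False)
    written.insert(0, csv_path)
    return written


def sd_from_ci(ci_lower: float, ci_upper: float, n: int, ci_level: float = 0.95) -> tuple[float, float]:
    """Recover (mean, SD) of paired differences from a printed t-based CI.

    The CI half-width equals ``t_{1-(1-level)/2, n-1} * SD / sqrt(n)``;
    useful for reconstructing agreement summaries from published values.
    """
    mean = 0.5 * (ci_lower + ci_upper)
    half = 0.5 * (ci_upper - ci_lower)
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, n - 1)
    return mean, half * np.sqrt(n) / tcrit
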