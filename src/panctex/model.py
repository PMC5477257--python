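"""Texture–survival association model, statsmodels-style.

:class:`TextureSurvivalModel` is built from a cohort table (one row per
subject, tumor and normal feature columns plus survival), and ``fit()``
returns a :class:`TextureSurvivalResults` that carries the three analysis
tables — tumor-vs-normal rank-sum comparison, univariate Cox fits, ROC
analysis — together with median-split Kaplan–Meier curves, a ``summary()``
report and plotting helpers.

Subjects with an undefined (NaN) feature value — e.g. a degenerate GLCM
correlation — are dropped pairwise per analysis, with the count logged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import survival as surv
from .exceptions import DivergenceError, NonIdentifiableError
from .texture import TEXTURE_FEATURES

logger = logging.getLogger(__name__)

__all__ = ["TextureSurvivalModel", "TextureSurvivalResults", "ANALYSIS_FEATURES"]

#: Features carried through Cox/ROC/KM: the five texture statistics plus
#: tumor size and mean intensity.
ANALYSIS_FEATURES = TEXTURE_FEATURES + ("size_mm2", "mean_intensity")

#: Features compared between tumor and normal tissue (size has no
#: normal-tissue counterpart of interest).
COMPARISON_FEATURES = TEXTURE_FEATURES + ("mean_intensity",)


class TextureSurvivalModel:
    """Association of per-subject texture features with overall survival.

    Parameters
    ----------
    cohort : DataFrame with columns ``tumor_<feature>`` (and optionally
        ``normal_<feature>``) for each analysis feature, plus
        ``time_months`` (> 0) and ``event`` (0/1).
    ties : Cox tie handling, "breslow" (default) or "efron".
    binarization : outcome rule for ROC — "median" (long survivor iff
        time ≥ cohort median) or a number interpreted as a fixed horizon
        in months.
    """

    def __init__(self, cohort: pd.DataFrame, ties: str = "breslow", binarization="median"):
        required = {"time_months", "event"}
        missing = required - set(cohort.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if len(cohort) < 2:
            raise ValueError(f"need at least 2 subjects, got {len(cohort)}")
        if (cohort["time_months"] <= 0).any():
            raise ValueError("survival times must be positive")
        self.cohort = cohort.reset_index(drop=True)
        self.ties = ties
        self.binarization = binarization
        self.features = [
            f for f in ANALYSIS_FEATURES if f"tumor_{f}" in cohort.columns
        ]
        if not self.features:
            raise ValueError("no tumor feature columns found (expected tumor_<feature>)")

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, **kwargs) -> "TextureSurvivalModel":
        return cls(cohort, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TextureSurvivalModel":
        return cls(pd.read_csv(path), **kwargs)

    # ---- fitting -----------------------------------------------------

    def _outcome(self) -> np.ndarray:
        time = self.cohort["time_months"].to_numpy(dtype=float)
        if self.binarization == "median":
            return surv.dichotomize_survival(time)
        horizon = float(self.binarization)
        return (time >= horizon).astype(int)

    def fit(self) -> "TextureSurvivalResults":
        time = self.cohort["time_months"].to_numpy(dtype=float)
        event = self.cohort["event"].to_numpy(dtype=int)
        outcome = self._outcome()

        comparison = self._fit_comparison()
        cox = self._fit_cox(time, event)
        roc = self._fit_roc(outcome)
        km = self._fit_km(time, event)
        return TextureSurvivalResults(
            model=self, comparison=comparison, cox=cox, roc=roc, km=km
        )

    def _fit_comparison(self) -> pd.DataFrame:
        rows = []
        for feat in COMPARISON_FEATURES:
            tcol, ncol = f"tumor_{feat}", f"normal_{feat}"
            if tcol not in self.cohort.columns or ncol not in self.cohort.columns:
                continue
            t = self.cohort[tcol].to_numpy(dtype=float)
            n = self.cohort[ncol].to_numpy(dtype=float)
            t, n = t[~np.isnan(t)], n[~np.isnan(n)]
            dropped = 2 * len(self.cohort) - t.size - n.size
            if dropped:
                logger.info("comparison %s: dropped %d undefined values", feat, dropped)
            u, p = surv.mann_whitney(t, n)
            rows.append(
                {
                    "feature": feat,
                    "tumor_median": np.median(t),
                    "tumor_q1": np.percentile(t, 25),
                    "tumor_q3": np.percentile(t, 75),
                    "normal_median": np.median(n),
                    "normal_q1": np.percentile(n, 25),
                    "normal_q3": np.percentile(n, 75),
                    "U": u,
                    "p": p,
                }
            )
        return pd.DataFrame(rows)

    def _fit_cox(self, time, event) -> pd.DataFrame:
        rows = []
        for feat in self.features:
            x = self.cohort[f"tumor_{feat}"].to_numpy(dtype=float)
            keep = ~np.isnan(x)
            if (~keep).sum():
                logger.info("cox %s: dropped %d subjects with undefined value", feat, int((~keep).sum()))
            try:
                fit = surv.cox_univariate(x[keep], time[keep], event[keep], ties=self.ties)
                rows.append(
                    {
                        "feature": feat,
                        "B": fit.beta,
                        "SE": fit.se,
                        "wald": fit.wald,
                        "p": fit.p,
                        "n": fit.n,
                        "n_events": fit.n_events,
                    }
                )
            except (NonIdentifiableError, DivergenceError) as exc:
                logger.warning("cox %s: %s", feat, exc)
                rows.append(
                    {"feature": feat, "B": np.nan, "SE": np.nan, "wald": np.nan,
                     "p": np.nan, "n": int(keep.sum()), "n_events": int(event[keep].sum())}
                )
        return pd.DataFrame(rows)

    def _fit_roc(self, outcome) -> pd.DataFrame:
        rows = []
        for feat in self.features:
            x = self.cohort[f"tumor_{feat}"].to_numpy(dtype=float)
            keep = ~np.isnan(x)
            try:
                r = surv.roc_analysis(x[keep], outcome[keep])
            except ValueError as exc:
                logger.warning("roc %s: %s", feat, exc)
                continue
            rows.append(
                {
                    "feature": feat,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "auc": r.auc,
                    "threshold": r.threshold,
                    "ci_lo": r.ci95[0],
                    "ci_hi": r.ci95[1],
                    "p": r.p,
                    "flipped": r.flipped,
                }
            )
        return pd.DataFrame(rows)

    def _fit_km(self, time, event) -> dict:
        km = {}
        for feat in self.features:
            x = self.cohort[f"tumor_{feat}"].to_numpy(dtype=float)
            keep = ~np.isnan(x)
            try:
                low, high, stat, p = surv.median_split_km(x[keep], time[keep], event[keep])
            except ValueError as exc:
                logger.warning("km %s: %s", feat, exc)
                continue
            km[feat] = {"low": low, "high": high, "statistic": stat, "p": p}
        return km


class TextureSurvivalResults:
    """Fitted tables and curves from :class:`TextureSurvivalModel`.

    Attributes
    ----------
    comparison : tumor vs normal medians/IQRs with rank-sum p per feature.
    cox : univariate Cox B / SE / Wald / p per feature.
    roc : sensitivity / specificity / AUC / Youden threshold / 95% CI / p.
    km : per-feature median-split Kaplan–Meier curves with log-rank test.
    """

    def __init__(self, model, comparison, cox, roc, km):
        self.model = model
        self.comparison = comparison
        self.cox = cox
        self.roc = roc
        self.km = km

    @property
    def significant_features(self) -> list[str]:
        """Features with Cox Wald p < 0.05 (raw, no multiplicity correction)."""
        sig = self.cox[self.cox["p"] < 0.05]
        return list(sig["feature"])

    def summary(self) -> str:
        n = len(self.model.cohort)
        n_events = int(self.model.cohort["event"].sum())
        lines = [
            "Texture–survival association analysis",
            "=" * 70,
            f"subjects: {n}    events: {n_events}    "
            f"ties: {self.model.ties}    binarization: {self.model.binarization}",
            "",
        ]
        if len(self.comparison):
            lines += [
                "Tumor vs normal tissue (Mann–Whitney rank test)",
                "-" * 70,
                self.comparison.to_string(
                    index=False,
                    float_format=lambda v: f"{v:.4g}",
                    columns=["feature", "tumor_median", "normal_median", "U", "p"],
                ),
                "",
            ]
        lines += [
            "Univariate Cox regression (Wald test, chi-square 1 df)",
            "-" * 70,
            self.cox.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "",
            "ROC analysis for the dichotomized survival outcome",
            "-" * 70,
            self.roc.to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
                columns=["feature", "sensitivity", "specificity", "auc",
                         "threshold", "ci_lo", "ci_hi", "p"],
            ),
            "",
            "p-values are raw (no multiple-testing correction applied).",
        ]
        return "\n".join(lines)

    def plot_km(self, feature: str, ax=None):
        """Median-split Kaplan–Meier plot for one feature."""
        import matplotlib.pyplot as plt

        if feature not in self.km:
            raise KeyError(f"no KM split available for {feature!r}")
        if ax is None:
            _, ax = plt.subplots()
        entry = self.km[feature]
        for name, curve in (("below median", entry["low"]), ("≥ median", entry["high"])):
            ax.step(curve.timeline, curve.survival, where="post", label=name)
        ax.set_xlabel("months")
        ax.set_ylabel("cumulative survival")
        ax.set_ylim(0, 1.05)
        ax.set_title(f"{feature} (log-rank p = {entry['p']:.3f})")
        ax.legend()
        return ax

    def plot_histogram(self, feature: str, ax=None, bins: int = 10):
        """Histogram of a tumor feature across the cohort."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.model.cohort[f"tumor_{feature}"].dropna()
        ax.hist(x, bins=bins, edgecolor="black")
        ax.set_xlabel(feature)
        ax.set_ylabel("subjects")
        return ax

    def to_csv(self, out_dir) -> dict[str, Path]:
        """Write the three report tables as CSV; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "comparison": out / "table3_comparison.csv",
            "cox": out / "table4_cox.csv",
            "roc": out / "table5_roc.csv",
        }
        self.comparison.to_csv(paths["comparison"], index=False)
        self.cox.to_csv(paths["cox"], index=False)
        self.roc.to_csv(paths["roc"], index=False)
        return paths
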