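"""Statistical layer: rank-sum comparison, univariate Cox, ROC, Kaplan–Meier.

Everything here operates on plain numpy arrays: a covariate (one texture
feature per subject), survival times in months and an event indicator
(1 = death observed, 0 = right-censored).

The Cox fit is univariate by design — at a cohort of a few dozen subjects a
multivariate model is not identifiable — and uses the Breslow tie
approximation by default (Efron available), with standard errors from the
observed information. Kaplan–Meier estimation and the log-rank test are
delegated to lifelines.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .exceptions import DivergenceError, NonIdentifiableError

logger = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "ROCResult",
    "KMCurve",
    "wald_statistic",
    "mann_whitney",
    "cox_univariate",
    "dichotomize_survival",
    "roc_analysis",
    "km_curve",
    "median_split_km",
]


def wald_statistic(beta: float, se: float) -> float:
    """Wald chi-square statistic (beta/se)², 1 degree of freedom."""
    return (beta / se) ** 2


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann–Whitney U (for the first sample) and the two-sided p-value.

    Ties share mid-ranks. The p-value is exact (full enumeration of the
    rank distribution) when the pooled sample has at most 12 observations
    and no ties, and otherwise uses the normal approximation with the
    tie-corrected variance and no continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclasses.dataclass(frozen=True)
class CoxFit:
    """Univariate Cox proportional-hazards fit.

    beta is the log-hazard per unit of the covariate; wald = (beta/se)²
    by construction, referred to chi-square with 1 df.
    """

    beta: float
    se: float
    n: int
    n_events: int
    iterations: int
    ties: str

    @property
    def wald(self) -> float:
        return wald_statistic(self.beta, self.se)

    @property
    def p(self) -> float:
        return float(stats.chi2.sf(self.wald, df=1))

    @property
    def hazard_ratio(self) -> float:
        return math.exp(self.beta)


def _cox_score_info(beta, x, time, event, ties):
    """Score and observed information of the partial log-likelihood at beta."""
    w = np.exp(beta * x)
    score = 0.0
    info = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        deaths = (time == t) & (event == 1)
        d = int(deaths.sum())
        s0 = w[at_risk].sum()
        s1 = (w[at_risk] * x[at_risk]).sum()
        s2 = (w[at_risk] * x[at_risk] ** 2).sum()
        xsum = x[deaths].sum()
        if ties == "breslow":
            score += xsum - d * s1 / s0
            info += d * (s2 / s0 - (s1 / s0) ** 2)
        else:  # efron
            d0 = w[deaths].sum()
            d1 = (w[deaths] * x[deaths]).sum()
            d2 = (w[deaths] * x[deaths] ** 2).sum()
            for r in range(d):
                f = r / d
                z0 = s0 - f * d0
                z1 = s1 - f * d1
                z2 = s2 - f * d2
                score += xsum / d - z1 / z0
                info += z2 / z0 - (z1 / z0) ** 2
    return score, info


def cox_univariate(
    covariate,
    time,
    event,
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Newton–Raphson fit of the univariate Cox partial likelihood.

    Converges on the score (|U(β)| < tol). The covariate is centred and
    scaled internally for numerical stability and the estimate mapped back
    to the raw scale, which leaves beta and the Wald statistic exact.

    Raises :class:`NonIdentifiableError` for a constant covariate and
    :class:`DivergenceError` when the likelihood is monotone (perfect
    risk ordering, no finite maximum).
    """
    x = np.asarray(covariate, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (x.shape == time.shape == event.shape):
        raise ValueError("covariate, time and event must have equal length")
    if np.isnan(x).any():
        raise ValueError("covariate contains NaN; drop undefined subjects first")
    if ties not in ("breslow", "efron"):
        raise ValueError(f"ties must be 'breslow' or 'efron', got {ties!r}")
    n_events = int(event.sum())
    if n_events < 2:
        raise ValueError(f"need at least 2 events, got {n_events}")
    sd = x.std()
    if sd == 0:
        raise NonIdentifiableError("covariate is constant; beta not identifiable")
    xs = (x - x.mean()) / sd

    beta_s = 0.0
    for iteration in range(1, max_iter + 1):
        score, info = _cox_score_info(beta_s, xs, time, event, ties)
        if info <= 0:
            raise DivergenceError(
                f"non-positive information at beta={beta_s / sd:.4g}; "
                "likelihood has no interior maximum"
            )
        step = score / info
        beta_s += np.clip(step, -5.0, 5.0)  # damp early overshoot
        if abs(beta_s) > 50:
            raise DivergenceError(
                "monotone partial likelihood: |beta| diverges "
                "(covariate perfectly orders the event times)"
            )
        if abs(score) < tol:
            break
    else:
        raise DivergenceError(f"Newton–Raphson did not converge in {max_iter} iterations")

    _, info = _cox_score_info(beta_s, xs, time, event, ties)
    se_s = 1.0 / math.sqrt(info)
    return CoxFit(
        beta=beta_s / sd,
        se=se_s / sd,
        n=int(x.size),
        n_events=n_events,
        iterations=iteration,
        ties=ties,
    )


def dichotomize_survival(time) -> np.ndarray:
    """Binary outcome: 1 iff survival time ≥ the cohort median time.

    The median uses the mid-point convention for even cohorts. With all
    times equal every label is 1.
    """
    time = np.asarray(time, dtype=float)
    if time.size < 2:
        raise ValueError("need at least 2 subjects to dichotomize")
    return (time >= np.median(time)).astype(int)


@dataclasses.dataclass(frozen=True)
class ROCResult:
    """ROC summary for one feature against a binary outcome.

    auc ≥ 0.5 by orientation choice; ``flipped`` records whether the
    decision direction is "feature ≤ threshold ⇒ positive" (True) rather
    than "feature ≥ threshold ⇒ positive" (False). The threshold maximizes
    Youden's J; the CI is the Hanley–McNeil 95% interval; p tests
    AUC = 0.5 through the equivalent Mann–Whitney statistic.
    """

    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    ci95: tuple[float, float]
    p: float
    flipped: bool


def _auc_from_ranks(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the rank statistic U/(n1·n0); tied pairs count 0.5."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n1, n0 = pos.size, neg.size
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_analysis(feature, outcome) -> ROCResult:
    """ROC analysis of one feature for a binary outcome.

    AUC via the rank/U identity; orientation chosen so AUC ≥ 0.5; the
    operating threshold maximizes sensitivity + specificity − 1, ties
    resolved toward the lower threshold.
    """
    feature = np.asarray(feature, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    pos = feature[outcome == 1]
    neg = feature[outcome == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both outcome classes must be present")

    auc = _auc_from_ranks(pos, neg)
    flipped = auc < 0.5
    oriented = -feature if flipped else feature
    opos = oriented[outcome == 1]
    oneg = oriented[outcome == 0]
    if flipped:
        auc = 1.0 - auc

    # Candidate thresholds: every observed value, rule "oriented ≥ t".
    best = None
    for t in np.unique(oriented):
        sens = float((opos >= t).mean())
        spec = float((oneg < t).mean())
        j = sens + spec - 1.0
        orig_t = -t if flipped else t
        # tie-break: lower threshold in original feature units
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and orig_t < best[1]
        ):
            best = (j, orig_t, sens, spec)
    _, threshold, sensitivity, specificity = best

    n1, n0 = pos.size, neg.size
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    _, p = mann_whitney(pos, neg)
    return ROCResult(
        auc=auc,
        threshold=float(threshold),
        sensitivity=sensitivity,
        specificity=specificity,
        ci95=ci,
        p=p,
        flipped=bool(flipped),
    )


@dataclasses.dataclass(frozen=True)
class KMCurve:
    """Kaplan–Meier product-limit estimate.

    timeline starts at 0 with S = 1; survival is non-increasing in [0, 1];
    at_risk counts subjects still under observation at each timeline point.
    """

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def km_curve(time, event) -> KMCurve:
    """Product-limit estimator; censored-at-event-time subjects stay at risk."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need at least 1 subject")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    timeline = np.asarray(kmf.survival_function_.index, dtype=float)
    survival = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(timeline).to_numpy(dtype=float)
    return KMCurve(
        timeline=timeline,
        survival=survival,
        at_risk=at_risk,
        n=int(time.size),
        n_events=int(event.sum()),
    )


def median_split_km(
    feature, time, event
) -> tuple[KMCurve, KMCurve, float, float]:
    """Kaplan–Meier curves for the feature-≥-median vs below-median groups.

    Returns (low-group curve, high-group curve, log-rank chi-square, p).
    """
    feature = np.asarray(feature, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    med = np.median(feature)
    high = feature >= med
    if high.all() or not high.any():
        raise ValueError("degenerate median split: all feature values on one side")
    res = logrank_test(
        time[~high], time[high], event_observed_A=event[~high], event_observed_B=event[high]
    )
    return (
        km_curve(time[~high], event[~high]),
        km_curve(time[high], event[high]),
        float(res.test_statistic),
        float(res.p_value),
    )
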