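"""Gene-level survival prognosis and signature enrichment.

For each gene, a Cox proportional-hazards model
``survival ~ age + gender + stage + expression`` yields a hazard ratio
and Wald p for the expression term; patients in the top and bottom
expression quartiles are compared by Kaplan-Meier estimation and a
log-rank test.  A gene correlates *negatively* with survival when its
hazard ratio is significantly above 1, the quartile log-rank test is
significant, and the top-quartile median survival is shorter; it
correlates *positively* when its hazard ratio is significantly below 1
(no Kaplan-Meier requirement).  Everything else is *neither*.

Given genome-wide classification fractions ``frac_neg`` and ``frac_pos``,
the probability that a random signature of ``n`` genes contains at least
``k`` negative genes and no positive gene is the trinomial tail

    sum_{i=k}^{n} C(n, i) * frac_neg^i * (1 - frac_neg - frac_pos)^(n-i)

evaluated term-wise in log space.  ``run_prognostic_screen`` assembles
the full procedure: classify the genome to estimate the fractions,
classify the signature, and score the enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.special import gammaln, logsumexp

__all__ = [
    "KMEstimate",
    "GenePrognosis",
    "ScreenResult",
    "km_estimate",
    "logrank_test",
    "fit_cox",
    "classify_gene",
    "enrichment_probability",
    "run_prognostic_screen",
    "RESERVED_COLUMNS",
]

NEGATIVE = "negative"
POSITIVE = "positive"
NEITHER = "neither"

RESERVED_COLUMNS = ("patient_id", "time", "event", "age", "gender", "stage",
                    "sample_type")


@dataclass
class KMEstimate:
    """Product-limit survival curve: right-continuous step function."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    median: float | None    # earliest time with S <= 0.5, None if never

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class GenePrognosis:
    gene: str
    hazard_ratio: float
    wald_p: float
    logrank_p: float
    median_top: float | None
    median_bottom: float | None
    prognosis_class: str
    flagged: bool = False


@dataclass
class ScreenResult:
    gene_table: pd.DataFrame
    frac_neg: float
    frac_pos: float
    n_tested: int
    k_min: int
    enrichment_p: float
    dropped_genes: list[str]


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be binary")
    return times, events.astype(int)


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator with median survival.

    The median is the earliest time at which the curve reaches 0.5 or
    below, None when the curve never does.
    """
    times, events = _check_surv(times, events)
    if events.sum() == 0:
        # fully censored: the estimator stays at 1, median undefined
        return KMEstimate(times=np.unique(times),
                          survival=np.ones(np.unique(times).size),
                          median=None)
    kmf = KaplanMeierFitter().fit(times, events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0
    t, s = t[keep], s[keep]
    med = kmf.median_survival_time_
    median = None if math.isinf(med) else float(med)
    return KMEstimate(times=t, survival=s, median=median)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    ta, ea = _check_surv(times_a, events_a)
    tb, eb = _check_surv(times_b, events_b)
    if ea.sum() == 0 or eb.sum() == 0:
        raise ValueError("both groups need at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _design(cohort: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Covariate frame for the Cox model: gender as binary indicator,
    stage as ordered integer codes, expression continuous."""
    gender = cohort["gender"]
    if gender.dtype.kind not in "if":
        gender = pd.Categorical(gender).codes
    stage = cohort["stage"]
    if stage.dtype.kind not in "if":
        stage = pd.Categorical(stage, ordered=True).codes
    return pd.DataFrame({
        "time": cohort["time"].astype(float),
        "event": cohort["event"].astype(int),
        "age": cohort["age"].astype(float),
        "gender": np.asarray(gender, dtype=float),
        "stage": np.asarray(stage, dtype=float),
        "expr": cohort[gene].astype(float),
    })


def fit_cox(cohort: pd.DataFrame, gene: str) -> tuple[float, float, bool]:
    """Cox PH fit of survival ~ age + gender + stage + expression.

    Maximum partial likelihood with Efron tie handling.  Returns
    (hazard ratio, two-sided Wald p) for the expression term and a flag
    set on non-convergence or degenerate input; flagged genes carry
    hazard_ratio = 1, p = 1.
    """
    df = _design(cohort, gene)
    if df["expr"].nunique() <= 1:
        return 1.0, 1.0, True
    # drop constant covariates (e.g. a single-gender cohort) rather than fail
    covs = [c for c in ("age", "gender", "stage") if df[c].nunique() > 1]
    df = df[["time", "event", "expr"] + covs]
    try:
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return 1.0, 1.0, True
    hr = float(np.exp(cph.params_["expr"]))
    p = float(cph.summary.loc["expr", "p"])
    if not (np.isfinite(hr) and np.isfinite(p)):
        return 1.0, 1.0, True
    return hr, p, False


def _quartile_masks(expr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strict bottom/top 25% by expression rank, floor(n/4) patients each;
    ties broken by stable patient order."""
    n = expr.size
    k = n // 4
    order = np.argsort(expr, kind="stable")
    return order[:k], order[-k:]


def classify_gene(cohort: pd.DataFrame, gene: str, alpha: float = 0.05) -> GenePrognosis:
    """Classify one gene's prognosis: negative / positive / neither.

    Negative requires HR > 1 with Wald p < alpha, a significant quartile
    log-rank test, and shorter top-quartile median survival; positive
    only requires HR < 1 with Wald p < alpha.  An undefined median in
    either quartile fails the negative criterion.
    """
    hr, wald_p, flagged = fit_cox(cohort, gene)
    expr = cohort[gene].to_numpy(dtype=float)
    bot, top = _quartile_masks(expr)
    t = cohort["time"].to_numpy(dtype=float)
    e = cohort["event"].to_numpy()
    logrank_p = float("nan")
    median_top = median_bottom = None
    try:
        _, logrank_p = logrank_test(t[top], e[top], t[bot], e[bot])
        median_top = km_estimate(t[top], e[top]).median
        median_bottom = km_estimate(t[bot], e[bot]).median
    except ValueError:
        pass  # no events in a quartile: negative-class criterion fails

    cls = NEITHER
    if not flagged:
        if hr < 1 and wald_p < alpha:
            cls = POSITIVE
        elif (hr > 1 and wald_p < alpha
              and np.isfinite(logrank_p) and logrank_p < alpha
              and median_top is not None and median_bottom is not None
              and median_top < median_bottom):
            cls = NEGATIVE
    return GenePrognosis(gene, hr, wald_p, logrank_p, median_top,
                         median_bottom, cls, flagged)


def enrichment_probability(n_tested: int, k_min: int,
                           frac_neg: float, frac_pos: float) -> float:
    """Tail probability of >= k_min negative and zero positive genes in a
    random n-gene signature, under genome-wide class fractions.

    sum_{i=k_min}^{n} C(n, i) * frac_neg^i * (1-frac_neg-frac_pos)^(n-i),
    each term in log space.
    """
    if not (0 <= frac_neg and 0 <= frac_pos and frac_neg + frac_pos < 1):
        raise ValueError("need frac_neg, frac_pos >= 0 and their sum < 1")
    if not 0 <= k_min <= n_tested:
        raise ValueError("k_min must lie in [0, n_tested]")
    if frac_neg == 0.0:
        return 0.0 if k_min >= 1 else (1.0 - frac_pos) ** n_tested
    i = np.arange(k_min, n_tested + 1)
    log_terms = (gammaln(n_tested + 1) - gammaln(i + 1) - gammaln(n_tested - i + 1)
                 + i * np.log(frac_neg)
                 + (n_tested - i) * np.log1p(-frac_neg - frac_pos))
    return float(np.exp(logsumexp(log_terms)))


def _dedupe_patients(cohort: pd.DataFrame) -> pd.DataFrame:
    """One row per patient; the primary-tumour sample takes precedence when
    a patient has multiple samples."""
    if "patient_id" not in cohort.columns:
        return cohort
    if "sample_type" in cohort.columns:
        prio = cohort["sample_type"].astype(str).str.lower().map(
            lambda s: 0 if s in ("01", "primary") else 1)
        cohort = cohort.assign(_prio=prio).sort_values(
            ["patient_id", "_prio"], kind="stable")
        cohort = cohort.drop_duplicates("patient_id").drop(columns="_prio")
    else:
        cohort = cohort.drop_duplicates("patient_id")
    return cohort.reset_index(drop=True)


def run_prognostic_screen(
    cohort: pd.DataFrame,
    signature_genes: list[str],
    genome_genes: list[str] | None = None,
    alpha: float = 0.05,
) -> ScreenResult:
    """Full prognostic screen with signature enrichment.

    Classifies every genome gene to estimate the genome-wide negative and
    positive fractions, classifies the measured signature genes (dropping
    and reporting unmeasured ones), and returns the trinomial enrichment
    tail probability with n_tested = measured signature size and k_min =
    the observed negative count in the signature.
    """
    cohort = _dedupe_patients(cohort)
    for col in ("time", "event", "age", "gender", "stage"):
        if col not in cohort.columns:
            raise ValueError(f"cohort missing required column {col!r}")
    if genome_genes is None:
        genome_genes = [c for c in cohort.columns if c not in RESERVED_COLUMNS]
    measured = set(genome_genes)
    dropped = [g for g in signature_genes if g not in measured]
    sig = [g for g in signature_genes if g in measured]
    if not sig:
        raise ValueError("no signature genes measured in the cohort")

    rows = {g: classify_gene(cohort, g, alpha) for g in genome_genes}
    table = pd.DataFrame([{
        "gene": r.gene, "hazard_ratio": r.hazard_ratio, "wald_p": r.wald_p,
        "logrank_p": r.logrank_p, "median_top": r.median_top,
        "median_bottom": r.median_bottom, "class": r.prognosis_class,
        "flagged": r.flagged, "in_signature": r.gene in set(sig),
    } for r in rows.values()])

    classes = table.set_index("gene")["class"]
    frac_neg = float((classes == NEGATIVE).mean())
    frac_pos = float((classes == POSITIVE).mean())
    k_min = int((classes.loc[sig] == NEGATIVE).sum())
    p = enrichment_probability(len(sig), k_min, frac_neg, frac_pos)
    return ScreenResult(table, frac_neg, frac_pos, len(sig), k_min, p, dropped)
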