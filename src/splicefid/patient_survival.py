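"""Patient-level splicing-burden scoring and survival stratification.

Two burden scores are implemented: (1) the count of "high inclusion" cassette
events per patient, where an event is high in a patient when its PSI is at
least the cohort median for that event plus a shift (default 0.1); (2) the
count of highly expressed circRNAs per patient, where "high" means at or
above the cohort 75th percentile for that circRNA. Patients are stratified
into low / mid / high groups by score quartiles and compared with
Kaplan-Meier curves, log-rank tests and Cox proportional-hazards ratios
(both reported). Quantiles use linear interpolation; ties at a threshold go
to the lower stratum (low is <= 25th percentile, high is > 75th).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "PatientCohort",
    "StrataResult",
    "classify_inclusion",
    "patient_event_score",
    "stratify_quartiles",
    "km_logrank",
    "cox_hr",
    "circ_burden",
    "zscore_correlation",
]


@dataclass
class PatientCohort:
    """Survival endpoints plus molecular matrices on shared patients.

    time: survival/follow-up time in days (> 0); event: 1 = relapse or
    progression, 0 = censored. psi is an event x patient matrix in [0, 1]
    (NaN = missing); circ_counts is a circRNA x patient count matrix;
    regulator is per-patient expression of the splicing regulator.
    """

    time: pd.Series
    event: pd.Series
    psi: pd.DataFrame | None = None
    circ_counts: pd.DataFrame | None = None
    regulator: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.time <= 0).any():
            raise ValueError("survival times must be positive")
        if not self.event.isin([0, 1]).all():
            raise ValueError("event flags must be 0 or 1")
        for mat in (self.psi, self.circ_counts):
            if mat is not None and list(mat.columns) != list(self.time.index):
                raise ValueError("matrix patients do not match survival table")

    @property
    def patients(self) -> list[str]:
        return list(self.time.index)


@dataclass(frozen=True)
class StrataResult:
    scores: pd.Series
    groups: pd.Series  # per-patient label in {low, mid, high}
    low_threshold: float
    high_threshold: float


def classify_inclusion(
    psi: pd.DataFrame, delta: float = 0.1, medians: pd.Series | None = None
) -> pd.DataFrame:
    """Boolean high-inclusion matrix: PSI >= (event population median + delta).

    The per-event population median is computed from the matrix itself unless
    `medians` supplies reference values (e.g. to score new patients against an
    existing cohort). Missing PSIs stay missing (NA); all-missing events are
    dropped with a warning. With an all-equal event the shift makes every
    patient low.
    """
    all_missing = psi.isna().all(axis=1)
    if medians is None and all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} events with no PSI values"
        )
        psi = psi.loc[~all_missing]
    if medians is None:
        medians = psi.median(axis=1, skipna=True)
    else:
        medians = medians.reindex(psi.index)
    high = psi.ge(medians + delta, axis=0)
    return high.where(psi.notna(), other=pd.NA).astype("boolean")


def patient_event_score(high_matrix: pd.DataFrame) -> pd.Series:
    """Per-patient count of high-inclusion events; missing entries count 0."""
    return high_matrix.fillna(False).astype(bool).sum(axis=0).astype(int)


def stratify_quartiles(
    scores: pd.Series, low_pct: float = 25.0, high_pct: float = 75.0
) -> StrataResult:
    """Split patients at score quartiles: low <= P25 < mid <= P75 < high.

    Quantiles use linear interpolation. With heavily tied scores the high
    group can be empty (score > P75 never holds); this degenerate outcome is
    reported with a warning rather than an error.
    """
    if len(scores) < 8:
        raise ValueError("need >= 8 patients to stratify")
    lo = float(np.percentile(scores.to_numpy(dtype=float), low_pct))
    hi = float(np.percentile(scores.to_numpy(dtype=float), high_pct))
    groups = pd.Series("mid", index=scores.index, dtype=object)
    groups[scores <= lo] = "low"
    groups[scores > hi] = "high"
    if (groups == "high").sum() == 0:
        warnings.warn("degenerate stratification: no patient above the high threshold")
    return StrataResult(scores=scores, groups=groups,
                        low_threshold=lo, high_threshold=hi)


def km_logrank(
    groups: pd.Series, time: pd.Series, event: pd.Series
) -> dict:
    """Kaplan-Meier curves per group plus a log-rank test across groups."""
    labels = [g for g in ("low", "mid", "high") if (groups == g).any()]
    if not labels:
        labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need >= 2 non-empty groups")
    curves = {}
    for g in labels:
        mask = (groups == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask], label=str(g))
        curves[g] = kmf.survival_function_
    lr = multivariate_logrank_test(time, groups, event)
    return {
        "curves": curves,
        "logrank_statistic": float(lr.test_statistic),
        "logrank_p": float(lr.p_value),
        "group_sizes": {g: int((groups == g).sum()) for g in labels},
    }


def cox_hr(
    covariate: pd.Series, time: pd.Series, event: pd.Series
) -> dict:
    """Cox proportional-hazards ratio for a single covariate.

    A numeric covariate is used as-is (HR per unit). A categorical covariate
    with levels from {low, mid, high} is coded against the *high* reference
    level, so the reported HRs describe the risk of low/mid patients relative
    to high. Non-convergence is reported in the result, never silently
    dropped.
    """
    df = pd.DataFrame({"time": time, "event": event})
    if covariate.dtype == object or isinstance(covariate.dtype, pd.CategoricalDtype):
        levels = [l for l in ("low", "mid", "high") if (covariate == l).any()]
        if "high" not in levels:
            raise ValueError("categorical covariate needs a 'high' reference group")
        cols = []
        for l in levels:
            if l == "high":
                continue
            col = f"vs_high_{l}"
            df[col] = (covariate == l).astype(float)
            cols.append(col)
    else:
        df["score"] = covariate.astype(float)
        cols = ["score"]
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # noqa: BLE001 - surfaced to the caller
        return {"converged": False, "error": str(exc)}
    out = {"converged": True, "terms": {}}
    for col in cols:
        hr = float(np.exp(cph.params_[col]))
        out["terms"][col] = {
            "hr": hr,
            "log2_hr": float(np.log2(hr)),
            "p": float(cph.summary.loc[col, "p"]),
        }
    return out


def circ_burden(
    circ_counts: pd.DataFrame,
    regulator: pd.Series | None = None,
    high_pct: float = 75.0,
) -> dict:
    """Per-patient count of highly expressed circRNAs, strata, and the
    regulator-expression contrast between the high- and low-burden strata.

    A circRNA is highly expressed in a patient when its count is at or above
    the cohort `high_pct` percentile for that circRNA. The regulator contrast
    is a two-sided rank-sum test of regulator expression in high- vs
    low-burden patients (under a repressor model the high-burden stratum has
    the lower regulator expression).
    """
    if regulator is not None and list(regulator.index) != list(circ_counts.columns):
        raise ValueError("regulator patients do not match circRNA count matrix")
    thresholds = circ_counts.apply(
        lambda row: np.percentile(row.to_numpy(dtype=float), high_pct), axis=1
    )
    # a zero count is never "highly expressed": the circRNA is simply not
    # detected in that patient, even if the cohort percentile is also zero
    high = circ_counts.ge(thresholds, axis=0) & (circ_counts > 0)
    burden = high.sum(axis=0).astype(int)
    strata = stratify_quartiles(burden)
    out = {"burden": burden, "strata": strata, "high_matrix": high}
    if regulator is not None:
        hi = regulator[strata.groups == "high"]
        lo = regulator[strata.groups == "low"]
        if len(hi) and len(lo):
            out["regulator_contrast"] = {
                "median_high_burden": float(hi.median()),
                "median_low_burden": float(lo.median()),
                "ranksum_p": float(stats.ranksums(hi, lo).pvalue),
            }
    return out


def zscore_correlation(
    circ_counts: pd.DataFrame, regulator: pd.Series
) -> tuple[float, float]:
    """Pearson correlation of z-scored circRNA counts with z-scored regulator
    expression, pooled over (circRNA, sample) pairs.

    Each circRNA row and the regulator vector are standardised across
    samples; zero-variance circRNAs are dropped with a warning. Returns
    (r, p).
    """
    if list(regulator.index) != list(circ_counts.columns):
        raise ValueError("regulator samples do not match circRNA count matrix")
    if circ_counts.shape[1] < 3:
        raise ValueError("need >= 3 paired samples")
    sds = circ_counts.std(axis=1, ddof=1)
    keep = sds > 0
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance circRNAs")
    counts = circ_counts.loc[keep]
    cz = counts.sub(counts.mean(axis=1), axis=0).div(sds[keep], axis=0)
    r_sd = float(regulator.std(ddof=1))
    if r_sd == 0:
        raise ValueError("regulator expression has zero variance")
    rz = (regulator - regulator.mean()) / r_sd
    x = cz.to_numpy().ravel()
    y = np.tile(rz.to_numpy(), (len(counts), 1)).ravel()
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
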