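"""Per-bin survival association (Cox proportional hazards and Kaplan-Meier)
and the signed survival-score transform.

The survival score makes protective and harmful effects symmetric: it equals
the hazard ratio when HR >= 1 and -1/HR when HR < 1, so |score| >= 1 always
and score(HR) = -score(1/HR).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)


def survival_score(hr):
    """Signed survival score: HR for HR >= 1, -1/HR for HR < 1 (HR=1 -> 1)."""
    hr = np.asarray(hr, dtype=float)
    if np.any(hr <= 0):
        raise ValueError("hazard ratio must be positive")
    score = np.where(hr >= 1.0, hr, -1.0 / hr)
    return float(score) if score.ndim == 0 else score


def cox_per_bin(
    states: pd.DataFrame,
    surv: pd.DataFrame,
    directions: tuple = ("gain", "loss"),
    min_events: int = 10,
    min_group: int = 3,
) -> pd.DataFrame:
    """Univariate Cox fit of each bin's gain (and loss) indicator on survival.

    `states` is a samples x bins categorical matrix ({gain, loss, neutral,
    missing}); `surv` has columns time (>0) and event (0/1) indexed by sample.
    Each bin is tested separately for its gain indicator and its loss
    indicator (matching the positive/negative split of per-CNA bubble plots).
    Ties use the Efron approximation (lifelines default); no covariates are
    included. Bins whose indicator is constant, or with fewer than `min_group`
    samples on either side, are flagged untestable.
    """
    samples = states.index.intersection(surv.index)
    sv = surv.loc[samples]
    if (sv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if int(sv["event"].sum()) < min_events:
        raise ValueError(f"fewer than {min_events} events overall")
    rows = []
    for b in states.columns:
        for direction in directions:
            ind = (states.loc[samples, b] == direction).astype(int)
            n_with, n_without = int(ind.sum()), int((1 - ind).sum())
            if min(n_with, n_without) < min_group:
                rows.append((b, direction, n_with, n_without, np.nan, np.nan, np.nan, False))
                continue
            df = pd.DataFrame({"time": sv["time"], "event": sv["event"], "x": ind})
            cph = CoxPHFitter()
            try:
                cph.fit(df, duration_col="time", event_col="event")
            except Exception as exc:  # convergence failure on degenerate data
                logger.warning("Cox fit failed for %s/%s: %s", b, direction, exc)
                rows.append((b, direction, n_with, n_without, np.nan, np.nan, np.nan, False))
                continue
            hr = float(np.exp(cph.params_["x"]))
            p = float(cph.summary.loc["x", "p"])
            rows.append((b, direction, n_with, n_without, hr, p, survival_score(hr), True))
    return pd.DataFrame(
        rows,
        columns=["bin", "direction", "n_with", "n_without", "HR", "p", "score", "testable"],
    )


def km_strata(groups: pd.Series, surv: pd.DataFrame) -> tuple[dict, float]:
    """Kaplan-Meier curves per group plus the overall log-rank p-value.

    `groups` labels each sample; at least two non-empty groups are required.
    Returns ({label: DataFrame(time, survival)}, logrank_p). Curves start at
    1.0 and are non-increasing; an all-censored group stays at 1.0.
    """
    samples = groups.index.intersection(surv.index)
    g = groups.loc[samples]
    sv = surv.loc[samples]
    labels = g.dropna().unique()
    if len(labels) < 2:
        raise ValueError("need at least two non-empty groups")
    curves = {}
    for label in labels:
        members = g[g == label].index
        kmf = KaplanMeierFitter()
        kmf.fit(sv.loc[members, "time"], sv.loc[members, "event"])
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    res = multivariate_logrank_test(sv["time"], g, sv["event"])
    return curves, float(res.p_value)
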