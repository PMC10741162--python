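"""Time/treatment differential statistics on normalized feature tables.

Two layers of testing mirror the study's analysis plan:

* a per-feature two-way fixed-effects ANOVA (factors: day and treatment,
  with interaction, Type-II sums of squares) on log2 intensities, scanned
  across all features of one wound type, with Benjamini-Hochberg control
  across features; and
* per-day two-group Student's t-tests (pooled variance, log2 scale) with
  Bonferroni correction and a linear-scale fold change, feeding a volcano
  rule (p_bonf < 0.1 and |FC| > 1.5) that flags treatment responders.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datamodel import FeatureTable, ValidationError

MIN_RESIDUAL_DF = 3


def _study_frame(table: FeatureTable, wound_type: str) -> tuple[np.ndarray, pd.DataFrame]:
    mask = table.study_mask(wound_type)
    if not mask.any():
        raise ValidationError(f"no study samples with wound type {wound_type!r}")
    meta = table.sample_frame().loc[mask]
    return table.intensities[:, mask], meta


def two_way_anova_scan(table: FeatureTable, wound_type: str) -> pd.DataFrame:
    """Per-feature two-way ANOVA (day x treatment, Type-II SS) on log2 scale.

    Features with fewer than ``MIN_RESIDUAL_DF`` residual degrees of
    freedom after dropping missing values, or whose complete cases no
    longer span 2 levels of both factors, get NaN p-values and are
    excluded from BH correction.
    """
    values, meta = _study_frame(table, wound_type)
    days = meta["day"].to_numpy()
    treatments = meta["treatment"].to_numpy()
    for name, levels in (("Time", np.unique(days)), ("Treatment", np.unique(treatments))):
        if len(levels) < 2:
            raise ValidationError(f"factor {name!r} has a single level: {levels.tolist()}")

    p_time = np.full(values.shape[0], np.nan)
    p_treat = np.full(values.shape[0], np.nan)
    p_inter = np.full(values.shape[0], np.nan)
    base = pd.DataFrame({"day": pd.Categorical(days), "treatment": pd.Categorical(treatments)})
    for i in range(values.shape[0]):
        row = values[i]
        ok = ~np.isnan(row) & (row > 0)
        if ok.sum() < 4:
            continue
        df = base.loc[ok].copy()
        if df["day"].nunique() < 2 or df["treatment"].nunique() < 2:
            continue
        df["y"] = np.log2(row[ok])
        fit = smf.ols("y ~ C(day) * C(treatment)", data=df).fit()
        if fit.df_resid < MIN_RESIDUAL_DF:
            continue
        tbl = sm.stats.anova_lm(fit, typ=2)
        p_time[i] = tbl.loc["C(day)", "PR(>F)"]
        p_treat[i] = tbl.loc["C(treatment)", "PR(>F)"]
        p_inter[i] = tbl.loc["C(day):C(treatment)", "PR(>F)"]

    out = pd.DataFrame(
        {
            "p_time": p_time,
            "p_treatment": p_treat,
            "p_interaction": p_inter,
            "q_time": bh_adjust(p_time),
            "q_treatment": bh_adjust(p_treat),
        },
        index=pd.Index(table.feature_ids, name="feature_id"),
    )
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries pass through."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def features_of_interest(anova: pd.DataFrame, q_thresh: float = 0.05,
                         p_thresh: float = 0.05) -> list[str]:
    """Time-significant features: BH q on the time effect within Q and raw
    p below the stated cut (conjunction rule)."""
    sel = (anova["q_time"] <= q_thresh) & (anova["p_time"] < p_thresh)
    return anova.index[sel.fillna(False)].tolist()


def day_ttest(table: FeatureTable, wound_type: str, day: int,
              group_a: str, group_b: str) -> pd.DataFrame:
    """Per-feature Student's t-test between two treatments at one day.

    Tests are two-sided with pooled variance on log2 intensities; the
    fold change is the ratio of arithmetic group means on the linear
    (normalized, unlogged) scale, treatment ``group_a`` over ``group_b``.
    Bonferroni scaling uses the number of features actually tested.
    """
    values, meta = _study_frame(table, wound_type)
    sel_day = meta["day"].to_numpy() == day
    in_a = sel_day & (meta["treatment"].to_numpy() == group_a)
    in_b = sel_day & (meta["treatment"].to_numpy() == group_b)
    if not in_a.any() or not in_b.any():
        raise ValidationError(
            f"no samples for {group_a!r} vs {group_b!r} at day {day} in {wound_type}"
        )

    n_feat = values.shape[0]
    p_raw = np.full(n_feat, np.nan)
    fc = np.full(n_feat, np.nan)
    for i in range(n_feat):
        a = values[i, in_a]
        b = values[i, in_b]
        a = a[~np.isnan(a) & (a > 0)]
        b = b[~np.isnan(b) & (b > 0)]
        if a.size < 2 or b.size < 2:
            continue
        la, lb = np.log2(a), np.log2(b)
        if la.var(ddof=1) == 0 and lb.var(ddof=1) == 0:
            p_raw[i] = 1.0 if np.isclose(la.mean(), lb.mean()) else 0.0
        else:
            p_raw[i] = sps.ttest_ind(la, lb, equal_var=True).pvalue
        fc[i] = a.mean() / b.mean()

    m = int(np.sum(~np.isnan(p_raw)))
    p_bonf = np.minimum(1.0, p_raw * max(m, 1))
    return pd.DataFrame(
        {"p_raw": p_raw, "p_bonf": p_bonf, "fc": fc, "n_tested": m},
        index=pd.Index(table.feature_ids, name="feature_id"),
    )


def volcano_classify(ttest: pd.DataFrame, p_thresh: float = 0.1,
                     fc_thresh: float = 1.5) -> pd.DataFrame:
    """Flag responders: Bonferroni p below ``p_thresh`` and fold change
    beyond ``fc_thresh`` in either direction; records the direction
    (up in group A vs up in group B)."""
    p = ttest["p_bonf"]
    fc = ttest["fc"]
    up_a = fc > fc_thresh
    up_b = fc < 1.0 / fc_thresh
    responder = (p < p_thresh) & (up_a | up_b)
    responder = responder.fillna(False)
    direction = np.where(responder & up_a, "up_in_a",
                         np.where(responder & up_b, "up_in_b", ""))
    return pd.DataFrame({"responder": responder, "direction": direction},
                        index=ttest.index)


def responders(volcano: pd.DataFrame) -> set[str]:
    return set(volcano.index[volcano["responder"]])
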