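"""Hyper-responder classification and ND-vs-T2D group contrasts.

A donor is a *fat hyper-responder* when the baseline-subtracted AUC of the
fatty-acid stimulus at basal glucose strictly exceeds the 15 mM glucose AUC,
and a *protein (leucine) hyper-responder* when the leucine-at-basal-glucose
AUC does; donors meeting both rules are classed ``both``.  Donors whose
15 mM glucose AUC is non-positive cannot be ranked against it and are
excluded from prevalence denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust

__all__ = [
    "HyperResponderClassifier",
    "classify_hyper_responders",
    "prevalence",
    "group_compare",
    "t2d_effect_summary",
    "GroupContrast",
]


@dataclass
class GroupContrast:
    """Two-group comparison of one secretion feature."""

    feature: str
    mean_ref: float
    mean_alt: float
    percent_difference: float  # 100 * (1 - mean_alt / mean_ref)
    test: str
    statistic: float
    p: float
    n_ref: int
    n_alt: int
    q: float = np.nan


class HyperResponderClassifier:
    """Rule-based nutrient hyper-responder classifier (sklearn-style).

    Parameters
    ----------
    fat_segment, leu_segment, glucose_segment
        Segment names in the secretion feature table holding the fat-at-basal,
        leucine-at-basal and 15 mM glucose AUCs.
    strict
        Use a strict inequality (a tie is a typical responder).
    """

    def __init__(self, fat_segment: str = "fat", leu_segment: str = "leucine",
                 glucose_segment: str = "glucose15", strict: bool = True):
        self.fat_segment = fat_segment
        self.leu_segment = leu_segment
        self.glucose_segment = glucose_segment
        self.strict = strict

    def get_params(self, deep: bool = True) -> dict:
        return {"fat_segment": self.fat_segment, "leu_segment": self.leu_segment,
                "glucose_segment": self.glucose_segment, "strict": self.strict}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, features: pd.DataFrame, y=None):
        needed = {self.fat_segment, self.leu_segment, self.glucose_segment}
        missing = needed - set(features["segment"].unique())
        if missing:
            raise ValueError(f"feature table lacks segments {sorted(missing)}")
        self.n_donors_ = features["donor_id"].nunique()
        return self

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        """Per-donor responder calls with AUC ratios and QC flags."""
        self.fit(features)
        piv = features.pivot_table(index="donor_id", columns="segment",
                                   values="auc", aggfunc="first")
        rows = []
        for donor_id, row in piv.iterrows():
            g15 = row.get(self.glucose_segment, np.nan)
            fat = row.get(self.fat_segment, np.nan)
            leu = row.get(self.leu_segment, np.nan)
            flag = ""
            if np.isnan(g15) or np.isnan(fat) or np.isnan(leu):
                flag, cls, fr, lr = "unclassifiable", "unclassifiable", np.nan, np.nan
            elif g15 <= 0:
                flag, cls, fr, lr = "nonpositive_glucose_auc", "unclassifiable", np.nan, np.nan
            else:
                fr, lr = fat / g15, leu / g15
                if self.strict:
                    is_fat, is_leu = fat > g15, leu > g15
                else:
                    is_fat, is_leu = fat >= g15, leu >= g15
                cls = ("both" if is_fat and is_leu else
                       "fat_hr" if is_fat else
                       "leu_hr" if is_leu else "typical")
            rows.append({"donor_id": donor_id, "fat_ratio": fr, "leu_ratio": lr,
                         "responder_class": cls, "qc_flag": flag})
        return pd.DataFrame(rows)


def classify_hyper_responders(features: pd.DataFrame, strict: bool = True,
                              ) -> pd.DataFrame:
    """Classify every donor in a secretion feature table."""
    return HyperResponderClassifier(strict=strict).predict(features)


def prevalence(calls: pd.DataFrame, responder_class: str,
               conf_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Class prevalence among classifiable donors with Clopper-Pearson CI."""
    ok = calls[calls["responder_class"] != "unclassifiable"]
    n = len(ok)
    if n == 0:
        raise ValueError("no classifiable donors")
    k = int((ok["responder_class"] == responder_class).sum())
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=conf_level,
                                             method="exact")
    return k / n, (float(ci.low), float(ci.high))


def group_compare(values, groups, test: str = "t", ref: str | None = None,
                  feature: str = "") -> GroupContrast:
    """Two-sided two-group contrast: Welch t or Mann-Whitney U.

    ``ref`` names the reference group (defaults to the first label
    encountered); percent difference is 100 * (1 - mean_alt / mean_ref).
    Constant inputs under the t-test fall back to Mann-Whitney with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    if ref is None:
        ref = labels[0]
    alt = [l for l in labels if l != ref][0]
    a, b = values[groups == ref], values[groups == alt]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 donors per group")
    if test == "t" and (np.ptp(a) == 0 and np.ptp(b) == 0):
        warnings.warn("constant inputs; falling back to Mann-Whitney",
                      stacklevel=2)
        test = "mwu"
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mwu":
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
    elif test == "mwu_exact":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        raise ValueError(f"unknown test {test!r}")
    mean_ref, mean_alt = float(a.mean()), float(b.mean())
    pct = 100.0 * (1.0 - mean_alt / mean_ref) if mean_ref != 0 else np.nan
    return GroupContrast(
        feature=feature, mean_ref=mean_ref, mean_alt=mean_alt,
        percent_difference=pct, test=test, statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)), n_ref=len(a), n_alt=len(b),
    )


_CONTRAST_METRICS = ("auc", "first_phase_auc", "second_phase_auc",
                     "peak_rate", "time_to_peak")


def t2d_effect_summary(features: pd.DataFrame, donors: pd.DataFrame,
                       test: str = "t", metrics=_CONTRAST_METRICS,
                       ) -> pd.DataFrame:
    """ND-vs-T2D contrast of every segment feature, BH-adjusted.

    One row per segment x metric (plus the per-donor baseline rate); percent
    difference is relative to the ND group mean.
    """
    grp = donors.set_index("donor_id")["group"]
    if set(grp.unique()) != {"ND", "T2D"}:
        raise ValueError("donors must contain both ND and T2D groups")
    out = []
    feat = features[~features["missing"].astype(bool)]
    for metric in metrics:
        for seg, sub in feat.groupby("segment", sort=True):
            vals = sub.set_index("donor_id")[metric].dropna()
            if vals.empty:
                continue
            gc = group_compare(vals.to_numpy(), grp.reindex(vals.index),
                               test=test, ref="ND",
                               feature=f"{seg}:{metric}")
            out.append(gc)
    base = feat.groupby("donor_id")["baseline_rate"].mean().dropna()
    out.append(group_compare(base.to_numpy(), grp.reindex(base.index),
                             test=test, ref="ND", feature="baseline_rate"))
    table = pd.DataFrame([dataclass_asdict(c) for c in out])
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table


def dataclass_asdict(c: GroupContrast) -> dict:
    return {
        "feature": c.feature, "mean_nd": c.mean_ref, "mean_t2d": c.mean_alt,
        "percent_difference": c.percent_difference, "test": c.test,
        "statistic": c.statistic, "p": c.p, "n_nd": c.n_ref, "n_t2d": c.n_alt,
    }
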