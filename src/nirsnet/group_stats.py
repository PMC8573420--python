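"""Inferential layer: condition contrasts and behavior correlations.

Three analyses mirror the study design:

* *transfer distance* — paired t-test of each connectivity feature between
  the near- and far-transfer conditions, matched by subject;
* *prior cognitive level* — subjects are split into top and bottom 27%
  groups by prior score (the classical item-analysis fraction; with n = 31
  that gives 9 per group) and the groups are compared feature-wise with a
  paired t-test after rank-matching (k-th best vs k-th best), giving
  df = group size - 1;
* *transfer performance* — Pearson correlation of each feature with the
  behavioral performance score.

Features are ROI-level band wavelet amplitudes and ROI-pair band WPCO
values, one row per (subject, condition). P-values are reported
uncorrected, with Benjamini–Hochberg q-values alongside.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .network import ROI_ORDER, RoiMap, RoiNetwork
from .recording import Recording
from .wavelet import ANALYSIS_BAND, WaveletSpec, amplitude, band_average, cwt_morlet

__all__ = [
    "TTestResult",
    "paired_t",
    "quantile_split",
    "pearson",
    "ContrastDesign",
    "contrast_report",
    "roi_amplitudes",
    "feature_row",
    "build_feature_table",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


def paired_t(x: np.ndarray, y: np.ndarray) -> TTestResult:
    """Paired-sample t-test of matched vectors.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``d = x - y`` and the sample
    SD; ``df = n - 1``; two-sided p. A zero-variance difference vector is
    flagged degenerate (t is 0 when the mean difference is 0, signed
    infinite otherwise; p is NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matched 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if d.std(ddof=1) == 0:
        md = d.mean()
        t = 0.0 if md == 0 else math.copysign(math.inf, md)
        return TTestResult(t=t, p=math.nan, df=n - 1, degenerate=True)
    res = sps.ttest_rel(x, y)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=n - 1)


def quantile_split(
    scores: pd.Series, fraction: float = 0.27
) -> tuple[list, list]:
    """Top/bottom quantile grouping of per-subject scores.

    Group size is ``ceil(fraction * n)`` (so 27% of 31 subjects gives 9 per
    group). Returns ``(high_ids, low_ids)``, each ordered from the most
    extreme score inward; ties are broken by subject id order, and the two
    groups are always disjoint.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    s = pd.Series(scores)
    n = s.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    g = math.ceil(fraction * n)
    if 2 * g > n:
        raise ValueError(f"groups of {g} overlap with only {n} subjects")
    ordered = s.sort_index(kind="stable").sort_values(kind="stable", ascending=True)
    low = list(ordered.index[:g])
    high = list(ordered.index[-g:])[::-1]  # most extreme first
    return high, low


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided p-value.

    p follows from ``t = r sqrt((n-2) / (1-r^2))`` on n-2 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matched 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Feature construction


def roi_amplitudes(
    rec: Recording,
    roi_map: RoiMap,
    spec: WaveletSpec | None = None,
    band: tuple[float, float] = ANALYSIS_BAND,
) -> dict[str, float]:
    """Band-averaged wavelet amplitude per ROI (mean over its channels)."""
    spec = (spec or WaveletSpec()).restrict(band)
    freqs = spec.frequencies()
    per_channel: dict[str, float] = {}
    for label, x in zip(rec.channel_labels, rec.samples):
        d = cwt_morlet(x, spec=spec, fs=rec.fs, frequencies=freqs)
        per_channel[label] = band_average(amplitude(d), freqs, band)
    return {
        roi: float(np.mean([per_channel[ch] for ch in sorted(roi_map[roi])]))
        for roi in ROI_ORDER
    }


def feature_row(
    amplitudes: dict[str, float], net: RoiNetwork
) -> dict[str, float]:
    """Flatten ROI amplitudes and ROI-pair WPCO into one feature mapping."""
    row = {f"amp_{roi}": amplitudes[roi] for roi in ROI_ORDER}
    for a, b in itertools.combinations(net.labels, 2):
        row[f"wpco_{a}-{b}"] = net.edge(a, b)
    return row


def build_feature_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-(subject, condition) feature rows into a FeatureTable.

    Each row dict must carry ``subject`` and ``condition`` keys plus the
    feature columns from :func:`feature_row`.
    """
    frame = pd.DataFrame(rows)
    if frame.duplicated(["subject", "condition"]).any():
        raise ValueError("duplicate (subject, condition) rows")
    return frame.set_index(["subject", "condition"]).sort_index()


# ---------------------------------------------------------------------------
# Contrast reports


@dataclass(frozen=True)
class ContrastDesign:
    """What to contrast and on which features.

    ``kind``: ``distance`` (near vs far, paired by subject), ``prior``
    (top vs bottom prior-score groups, rank-matched) or ``performance``
    (Pearson correlation with transfer performance). ``feature_set``
    selects amplitude features, WPCO features or both. ``condition`` is
    the condition whose features feed the prior/performance analyses.
    """

    kind: str = "distance"
    feature_set: str = "both"
    condition: str = "far"
    fraction: float = 0.27

    def __post_init__(self) -> None:
        if self.kind not in ("distance", "prior", "performance"):
            raise ValueError("kind must be distance|prior|performance")
        if self.feature_set not in ("amplitude", "wpco", "both"):
            raise ValueError("feature_set must be amplitude|wpco|both")


def _select_features(features: pd.DataFrame, feature_set: str) -> list[str]:
    cols = [c for c in features.columns if c.startswith(("amp_", "wpco_"))]
    if feature_set == "amplitude":
        cols = [c for c in cols if c.startswith("amp_")]
    elif feature_set == "wpco":
        cols = [c for c in cols if c.startswith("wpco_")]
    return cols


def contrast_report(
    features: pd.DataFrame,
    design: ContrastDesign,
    behavior: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tidy statistics table, one row per feature.

    Columns: feature, estimate (mean paired difference or r), stat (t or
    r), df, p, q (Benjamini–Hochberg adjusted).
    """
    cols = _select_features(features, design.feature_set)
    if not cols:
        raise ValueError("no matching feature columns")
    rows = []

    if design.kind == "distance":
        near = features.xs("near", level="condition")
        far = features.xs("far", level="condition")
        subjects = near.index.intersection(far.index)
        if len(subjects) < 2:
            raise ValueError("need near and far features for at least 2 subjects")
        if len(subjects) < len(near.index.union(far.index)):
            raise ValueError("missing cells: near/far features not matched")
        for col in cols:
            res = paired_t(near.loc[subjects, col].values, far.loc[subjects, col].values)
            rows.append(
                {
                    "feature": col,
                    "contrast": "near-far",
                    "estimate": float(
                        (near.loc[subjects, col] - far.loc[subjects, col]).mean()
                    ),
                    "stat": res.t,
                    "df": res.df,
                    "p": res.p,
                    "degenerate": res.degenerate,
                }
            )
    elif design.kind == "prior":
        if behavior is None:
            raise ValueError("prior contrast requires the behavioral table")
        prior = behavior.set_index("subject_id")["prior_score"]
        high, low = quantile_split(prior, design.fraction)
        sel = features.xs(design.condition, level="condition")
        missing = [s for s in high + low if s not in sel.index]
        if missing:
            raise ValueError(f"missing cells for subjects {missing}")
        for col in cols:
            res = paired_t(sel.loc[high, col].values, sel.loc[low, col].values)
            rows.append(
                {
                    "feature": col,
                    "contrast": "high-low prior",
                    "estimate": float(
                        sel.loc[high, col].values.mean() - sel.loc[low, col].values.mean()
                    ),
                    "stat": res.t,
                    "df": res.df,
                    "p": res.p,
                    "degenerate": res.degenerate,
                }
            )
    else:  # performance
        if behavior is None:
            raise ValueError("performance correlation requires the behavioral table")
        perf = behavior.set_index("subject_id")[f"performance_{design.condition}"]
        sel = features.xs(design.condition, level="condition")
        subjects = [s for s in perf.index if s in sel.index]
        if len(subjects) < len(perf.index):
            raise ValueError("missing cells: features absent for some subjects")
        for col in cols:
            x = sel.loc[subjects, col].values
            if np.std(x) == 0:
                rows.append(
                    {
                        "feature": col,
                        "contrast": f"performance_{design.condition}",
                        "estimate": math.nan,
                        "stat": math.nan,
                        "df": len(subjects) - 2,
                        "p": math.nan,
                        "degenerate": True,
                    }
                )
                continue
            r, p = pearson(x, perf.loc[subjects].values)
            rows.append(
                {
                    "feature": col,
                    "contrast": f"performance_{design.condition}",
                    "estimate": r,
                    "stat": r,
                    "df": len(subjects) - 2,
                    "p": p,
                    "degenerate": False,
                }
            )

    report = pd.DataFrame(rows)
    ok = report["p"].notna()
    q = np.full(len(report), np.nan)
    if ok.any():
        q[ok.values] = multipletests(report.loc[ok, "p"].values, method="fdr_bh")[1]
    report["q"] = q
    return report
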