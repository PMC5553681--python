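"""RT-qPCR confirmation arm: reference normalization and passage tests.

Targets are normalized by the geometric mean of five reference small RNAs
(SNORD61/68/72/95/96A).  On the abundance scale (2**-Cq) the geometric mean
of the references equals the arithmetic mean of their Cq values, so the
normalized expression is

    dCq = mean(reference Cq) - target Cq      (log2 abundance units)

which increases as the target Cq decreases.  A target is *detected* in a
sample when its median Cq across well replicates is below 35; undetected
targets are excluded from fold-change tests.  Passage fold changes are
2**(mean ddCq) across matched lines (paired t-test by default), with an
unpaired switch; cross-set and MSC-vs-cohort contrasts are two-sample
t-tests on the per-line quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential_expression import fold_from_log2diff
from .synthetic_data import REFERENCE_TARGETS

__all__ = ["QpcrResult", "normalize_qpcr", "passage_fold_tests",
           "cross_set_tests", "cohort_tests"]

DETECTION_CQ = 35.0
#: acceptance band for the positive PCR control; outside it the run is suspect
PPC_BAND = (14.0, 26.0)


@dataclass
class QpcrResult:
    """Per-(sample, target) medians, detection flags and normalized values."""

    #: rows: sample_id, cohort, passage_label, target_id, median_cq,
    #: detected, delta_cq
    values: pd.DataFrame
    #: samples dropped because a reference target was undetected
    excluded_samples: list[str]

    def pivot(self, column: str = "delta_cq") -> pd.DataFrame:
        return self.values.pivot(index="target_id", columns="sample_id",
                                 values=column)


def normalize_qpcr(plate: pd.DataFrame,
                   references=REFERENCE_TARGETS,
                   detection_cq: float = DETECTION_CQ) -> QpcrResult:
    """Median-collapse well replicates and normalize to the reference geomean.

    Samples with any undetected reference target are flagged and excluded
    with a warning.  Run controls (PPC/miRTC) are checked against their
    acceptance band but never used in normalization.
    """
    ppc = plate[plate["control_role"] == "PPC"]
    if len(ppc):
        bad = ppc.groupby("sample_id")["cq"].median()
        bad = bad[(bad < PPC_BAND[0]) | (bad > PPC_BAND[1])]
        if len(bad):
            warnings.warn(
                f"PPC control outside acceptance band for samples: "
                f"{sorted(bad.index)}"
            )
    assay = plate[plate["control_role"] == "none"]
    med = (
        assay.groupby(["sample_id", "cohort", "passage_label", "target_id"],
                      as_index=False)["cq"]
        .median()
        .rename(columns={"cq": "median_cq"})
    )
    med["detected"] = med["median_cq"].notna() & (med["median_cq"] < detection_cq)

    ref = med[med["target_id"].isin(references)]
    ref_ok = ref.groupby("sample_id")["detected"].all()
    ref_n = ref.groupby("sample_id")["target_id"].nunique()
    complete = ref_ok & (ref_n == len(references))
    excluded = sorted(complete.index[~complete])
    if excluded:
        warnings.warn(
            f"samples excluded (undetected/missing reference target): {excluded}"
        )
    keep = med["sample_id"].isin(complete.index[complete])
    med = med[keep].copy()
    ref_mean = (
        med[med["target_id"].isin(references)]
        .groupby("sample_id")["median_cq"].mean()
    )
    med["delta_cq"] = med["sample_id"].map(ref_mean) - med["median_cq"]
    med.loc[~med["detected"], "delta_cq"] = np.nan
    med["is_reference"] = med["target_id"].isin(references)
    return QpcrResult(values=med, excluded_samples=excluded)


def _line_of(sample_id: str, passage: str) -> str:
    suffix = f"_{passage}"
    return sample_id[:-len(suffix)] if sample_id.endswith(suffix) else sample_id


def _paired_table(result: QpcrResult, cohort: str, early: str, late: str,
                  target: str) -> pd.DataFrame:
    v = result.values
    sub = v[(v["cohort"] == cohort) & (v["target_id"] == target)
            & v["passage_label"].isin([early, late])].copy()
    sub["line"] = [
        _line_of(s, p) for s, p in zip(sub["sample_id"], sub["passage_label"])
    ]
    wide = sub.pivot(index="line", columns="passage_label", values="delta_cq")
    det = sub.pivot(index="line", columns="passage_label", values="detected")
    wide = wide[det.fillna(False).all(axis=1)]
    return wide.dropna()


def passage_fold_tests(result: QpcrResult, cohort: str, early: str, late: str,
                       targets=None, paired: bool = True,
                       references=REFERENCE_TARGETS) -> pd.DataFrame:
    """Late-vs-early fold change and t-test per target within one MSC set.

    Targets undetected in any of the set's samples are excluded (fold and p
    reported as NaN with ``tested=False``).  Requires >=3 matched lines.
    """
    v = result.values
    if targets is None:
        targets = sorted(
            set(v.loc[~v["is_reference"], "target_id"]) - set(references)
        )
    rows = []
    for t in targets:
        wide = _paired_table(result, cohort, early, late, t)
        n_lines_total = v[(v["cohort"] == cohort) & (v["target_id"] == t)][
            "sample_id"].nunique() // 2
        if len(wide) < max(3, n_lines_total):
            rows.append({"target_id": t, "n_lines": len(wide), "tested": False,
                         "ddcq": np.nan, "fold_change": np.nan,
                         "p_value": np.nan})
            continue
        ddcq = (wide[late] - wide[early]).to_numpy()
        mean_dd = float(ddcq.mean())
        if paired:
            sd = ddcq.std(ddof=1)
            if sd == 0.0:
                warnings.warn(f"degenerate variance for target {t!r}: p set to 0")
                p = 0.0 if mean_dd != 0 else 1.0
            else:
                p = float(stats.ttest_1samp(ddcq, 0.0).pvalue)
        else:
            p = float(stats.ttest_ind(wide[late], wide[early]).pvalue)
        rows.append({
            "target_id": t, "n_lines": len(wide), "tested": True,
            "ddcq": mean_dd, "fold_change": fold_from_log2diff(mean_dd),
            "p_value": p,
        })
    return pd.DataFrame(rows).set_index("target_id")


def cross_set_tests(result: QpcrResult, sets: dict[str, tuple[str, str, str]],
                    targets=None, references=REFERENCE_TARGETS) -> pd.DataFrame:
    """Is the late-minus-early change different between two MSC sets?

    ``sets`` maps a set name to ``(cohort, early, late)``; exactly two sets
    are compared with a two-sample t-test on the per-line ddCq values.
    """
    if len(sets) != 2:
        raise ValueError("cross_set_tests compares exactly two sets")
    (name_a, (coh_a, e_a, l_a)), (name_b, (coh_b, e_b, l_b)) = sets.items()
    v = result.values
    if targets is None:
        targets = sorted(
            set(v.loc[~v["is_reference"], "target_id"]) - set(references)
        )
    rows = []
    for t in targets:
        wa = _paired_table(result, coh_a, e_a, l_a, t)
        wb = _paired_table(result, coh_b, e_b, l_b, t)
        da = (wa[l_a] - wa[e_a]).to_numpy()
        db = (wb[l_b] - wb[e_b]).to_numpy()
        if len(da) < 2 or len(db) < 2:
            rows.append({"target_id": t, "tested": False,
                         "diff_ddcq": np.nan, "p_value": np.nan})
            continue
        res = stats.ttest_ind(da, db)
        rows.append({
            "target_id": t, "tested": True,
            "diff_ddcq": float(da.mean() - db.mean()),
            "p_value": float(res.pvalue),
            f"n_{name_a}": len(da), f"n_{name_b}": len(db),
        })
    return pd.DataFrame(rows).set_index("target_id")


def cohort_tests(result: QpcrResult, msc_cohorts, other_cohort: str,
                 msc_passages, targets=None,
                 references=REFERENCE_TARGETS) -> pd.DataFrame:
    """MSC (early passage) vs non-MSC cohort, two-sample t per target."""
    v = result.values
    if targets is None:
        targets = sorted(
            set(v.loc[~v["is_reference"], "target_id"]) - set(references)
        )
    msc = v[v["cohort"].isin(msc_cohorts) & v["passage_label"].isin(msc_passages)]
    other = v[v["cohort"] == other_cohort]
    rows = []
    for t in targets:
        a = msc.loc[(msc["target_id"] == t) & msc["detected"], "delta_cq"].dropna()
        b = other.loc[(other["target_id"] == t) & other["detected"],
                      "delta_cq"].dropna()
        if len(a) < 2 or len(b) < 2:
            rows.append({"target_id": t, "tested": False,
                         "diff_dcq": np.nan, "p_value": np.nan})
            continue
        res = stats.ttest_ind(a, b)
        rows.append({
            "target_id": t, "tested": True,
            "diff_dcq": float(b.mean() - a.mean()),
            "fold_change": fold_from_log2diff(float(b.mean() - a.mean())),
            "p_value": float(res.pvalue),
            "n_msc": len(a), "n_other": len(b),
        })
    return pd.DataFrame(rows).set_index("target_id")
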