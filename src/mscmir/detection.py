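"""Negative-control background cutoffs and expression detection calls.

A sequence is called *expressed* for a donor/passage group when the median of
its values over that group's technical-replicate arrays exceeds the group's
background cutoff (mean + 1 SD of the group's pooled negative controls).  A
sequence expressed in every donor/passage group is *commonly expressed*; the
miRNA-level roll-up excludes sequences annotated as tRNA/rRNA.

Arrays with extremely elevated background are flagged from raw
(pre-normalization) negative-control means — quantile normalization would
erase exactly the signature being screened for — and excluded downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BackgroundCutoffs",
    "DetectionCalls",
    "background_cutoffs",
    "flag_outlier_arrays",
    "detection_calls",
    "duplicate_length_comparison",
]


@dataclass
class BackgroundCutoffs:
    """Per-group and global negative-control background cutoffs (log2)."""

    #: (donor_id, passage_label) -> mean + n_sd * SD of pooled group negctls
    group_cutoffs: pd.Series
    global_mean: float
    global_sd: float
    n_sd: float

    @property
    def global_cutoff(self) -> float:
        return self.global_mean + self.n_sd * self.global_sd


@dataclass
class DetectionCalls:
    """Expressed flags per group, per sequence, and the miRNA roll-up."""

    #: sequence x group boolean matrix
    expressed: pd.DataFrame
    #: per-sequence flag: expressed in every group
    commonly_expressed: pd.Series
    #: per-sequence table: mirna, rna_class, median expression, flag
    sequence_table: pd.DataFrame
    #: per-miRNA table: commonly_expressed (>=1 sequence, tRNA/rRNA excluded)
    #: and median expression over its commonly-expressed sequences
    mirna_table: pd.DataFrame


def background_cutoffs(negctl: pd.DataFrame, sheet: pd.DataFrame,
                       n_sd: float = 1.0, pool_replicates: bool = True,
                       ) -> BackgroundCutoffs:
    """Compute background cutoffs from normalized negative-control values.

    ``negctl`` is the (negative-control probe) x array log2 matrix.  Each
    donor/passage group's cutoff is mean + ``n_sd`` SD of the group's pooled
    negative controls (all technical-replicate arrays together, the default)
    or the mean over arrays of per-array cutoffs with
    ``pool_replicates=False``.
    """
    sheet = sheet[sheet["array_id"].isin(negctl.columns)]
    groups = {}
    for (donor, passage), sub in sheet.groupby(["donor_id", "passage_label"]):
        vals = negctl.loc[:, sub["array_id"]].to_numpy().ravel()
        if pool_replicates:
            groups[(donor, passage)] = vals.mean() + n_sd * vals.std(ddof=1)
        else:
            per_array = [
                negctl[a].mean() + n_sd * negctl[a].std(ddof=1)
                for a in sub["array_id"]
            ]
            groups[(donor, passage)] = float(np.mean(per_array))
    pooled = negctl.to_numpy().ravel()
    cuts = pd.Series(groups, name="cutoff")
    cuts.index.names = ["donor_id", "passage_label"]
    return BackgroundCutoffs(
        group_cutoffs=cuts,
        global_mean=float(pooled.mean()),
        global_sd=float(pooled.std(ddof=1)),
        n_sd=n_sd,
    )


def flag_outlier_arrays(probes: pd.DataFrame, k: float = 5.0) -> set[str]:
    """Flag arrays whose raw negative-control background is extremely elevated.

    An array is flagged when its mean log2 negative-control signal exceeds
    the median + ``k`` * MAD of the per-array means.  With fewer than 3
    arrays flagging is disabled (warning).
    """
    neg = probes[probes["control_type"] == "negative"]
    means = neg.groupby("array_id")["raw_signal"].apply(
        lambda s: float(np.log2(s).mean())
    )
    if len(means) < 3:
        warnings.warn("fewer than 3 arrays: outlier flagging disabled")
        return set()
    med = float(means.median())
    mad = float(stats.median_abs_deviation(means))
    if not np.isfinite(k):
        return set()
    flagged = set(means.index[means > med + k * mad])
    if flagged:
        warnings.warn(f"outlier arrays flagged (elevated background): {sorted(flagged)}")
    return flagged


def detection_calls(matrix: pd.DataFrame, sheet: pd.DataFrame,
                    cutoffs: BackgroundCutoffs,
                    annotations: pd.DataFrame | None = None) -> DetectionCalls:
    """Expressed / commonly-expressed calls per the background cutoffs.

    ``annotations`` (sequence-indexed, columns ``mirna_name`` and
    ``rna_class``) drives the miRNA-level roll-up; without it the roll-up
    treats each sequence as its own miRNA of class miRNA.
    """
    sheet = sheet[sheet["array_id"].isin(matrix.columns)]
    flags = {}
    for key, sub in sheet.groupby(["donor_id", "passage_label"]):
        arrays = [a for a in sub["array_id"] if a in matrix.columns]
        if not arrays:
            warnings.warn(f"group {key} has no arrays; excluded from detection")
            continue
        if key not in cutoffs.group_cutoffs.index:
            raise ValueError(f"no background cutoff for group {key}")
        med = matrix.loc[:, arrays].median(axis=1)
        flags[key] = med > cutoffs.group_cutoffs[key]
    expressed = pd.DataFrame(flags)
    expressed.columns = pd.MultiIndex.from_tuples(
        expressed.columns, names=["donor_id", "passage_label"]
    )
    common = expressed.all(axis=1)
    common.name = "commonly_expressed"

    if annotations is None:
        annotations = pd.DataFrame(
            {"mirna_name": matrix.index, "rna_class": "miRNA"}, index=matrix.index
        )
    ann = annotations.loc[matrix.index]
    seq_table = pd.DataFrame({
        "mirna_name": ann["mirna_name"],
        "rna_class": ann["rna_class"],
        "median_expression": matrix.median(axis=1),
        "commonly_expressed": common,
    })
    eligible = seq_table[~seq_table["rna_class"].isin(["tRNA", "rRNA"])]
    all_mirnas = pd.Index(sorted(set(seq_table["mirna_name"])), name="mirna_name")
    mirna_common = (
        eligible.groupby("mirna_name")["commonly_expressed"].any()
        .reindex(all_mirnas, fill_value=False)
    )
    med_expr = (
        eligible[eligible["commonly_expressed"]]
        .groupby("mirna_name")["median_expression"].median()
    )
    mirna_table = pd.DataFrame({
        "commonly_expressed": mirna_common,
        "median_expression": med_expr.reindex(mirna_common.index),
    })
    return DetectionCalls(
        expressed=expressed,
        commonly_expressed=common,
        sequence_table=seq_table,
        mirna_table=mirna_table,
    )


@dataclass
class DuplicateComparison:
    fold_change: float
    mean_log2_diff: float
    t_statistic: float
    p_value: float
    n_pairs: int


def duplicate_length_comparison(matrix: pd.DataFrame,
                                pairs: list[tuple[str, str, float]] | list[tuple[str, str]],
                                restrict: set[str] | None = None,
                                ) -> DuplicateComparison:
    """Paired comparison of long vs short members of duplicate sequences.

    Each pair contributes the difference of its members' mean log2 expression
    across all arrays (long minus short); a paired t-test is run over pairs.
    ``restrict`` limits the test to pairs whose members are both in the set
    (e.g. commonly expressed sequences).  A zero-variance difference vector
    yields p = 0 with a degeneracy warning (p = 1 if the difference is also
    zero).
    """
    diffs = []
    for pair in pairs:
        long_s, short_s = pair[0], pair[1]
        if restrict is not None and (long_s not in restrict or short_s not in restrict):
            continue
        if long_s not in matrix.index or short_s not in matrix.index:
            continue
        diffs.append(matrix.loc[long_s].mean() - matrix.loc[short_s].mean())
    if len(diffs) < 2:
        raise ValueError(
            f"duplicate comparison needs >=2 usable pairs, got {len(diffs)}"
        )
    diffs = np.asarray(diffs)
    mean_d = float(diffs.mean())
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        warnings.warn("zero-variance paired differences: degenerate t-test")
        t = np.inf * np.sign(mean_d) if mean_d != 0 else 0.0
        p = 0.0 if mean_d != 0 else 1.0
    else:
        t, p = stats.ttest_1samp(diffs, 0.0)
        t, p = float(t), float(p)
    fold = float(2.0 ** mean_d if mean_d >= 0 else -(2.0 ** -mean_d))
    return DuplicateComparison(
        fold_change=fold, mean_log2_diff=mean_d,
        t_statistic=t, p_value=p, n_pairs=len(diffs),
    )
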