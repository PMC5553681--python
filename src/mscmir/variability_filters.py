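"""The four-stage variability/magnitude filter cascade.

Sequences enter downstream differential-expression modeling only if the
passage difference they show is measurable against the platform's technical
noise and their signal sits above background:

1. *within-chip*: |mean endpoint difference| must exceed the sequence's
   within-chip technical variability — the median over arrays of the SD of
   its on-array probe replicates;
2. *between-chip*: the same difference must exceed the between-chip
   technical variability — the median over donor/passage groups of the SD
   across the group's technical-replicate arrays;
3. *biological variability*: a paired t-test of donor-level endpoint values
   must reach the alpha level (default p <= 0.05 keeps);
4. *magnitude*: mean expression at every passage must exceed the global
   negative-control background cutoff.

Stages apply in order; a sequence failing stage *i* has later stages
recorded as not-evaluated.  The FilterTrace frame records every cutoff,
statistic and flag per sequence and is the pipeline's auditable spine.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import probe_matrix, quantile_normalize, afe_tgs_p75

__all__ = [
    "within_chip_cutoffs",
    "between_chip_cutoffs",
    "donor_level_means",
    "apply_cascade",
    "cascade_counts",
]

STAGES = ["within", "between", "biological", "magnitude"]


def within_chip_cutoffs(probes: pd.DataFrame, scheme: str = "quantile",
                        arrays: list[str] | None = None) -> pd.Series:
    """Per-sequence within-chip technical variability.

    The probe-level matrix (experimental + negative controls, so background
    probes inform the normalization) is normalized, then the sample SD of
    each sequence's probe replicates is taken per array, and the median SD
    over arrays is the cutoff.  Sequences with a single probe everywhere get
    cutoff 0 with a warning.
    """
    sub = probes[probes["control_type"].isin(["experimental", "negative"])]
    if arrays is not None:
        sub = sub[sub["array_id"].isin(arrays)]
    pm = probe_matrix(sub)
    normalize = quantile_normalize if scheme == "quantile" else afe_tgs_p75
    log2 = normalize(pm)
    exp = probes[probes["control_type"] == "experimental"]
    probe_to_seq = (
        exp[["probe_id", "sequence_id"]].drop_duplicates("probe_id")
        .set_index("probe_id")["sequence_id"]
    )
    vals = log2.loc[probe_to_seq.index]
    per_array_sd = vals.groupby(probe_to_seq).std(ddof=1)
    singletons = per_array_sd.isna().all(axis=1)
    if singletons.any():
        warnings.warn(
            f"{int(singletons.sum())} sequence(s) have a single probe per "
            "array; within-chip cutoff set to 0"
        )
    cutoff = per_array_sd.median(axis=1).fillna(0.0)
    cutoff.name = "within_cutoff"
    cutoff.index.name = "sequence_id"
    return cutoff


def between_chip_cutoffs(matrix: pd.DataFrame, sheet: pd.DataFrame) -> pd.Series:
    """Per-sequence between-chip technical variability.

    For each donor/passage group with >=2 technical-replicate arrays, the SD
    of the collapsed sequence value across the group's arrays is computed;
    the cutoff is the median over groups.
    """
    sheet = sheet[sheet["array_id"].isin(matrix.columns)]
    group_sds = []
    for _key, sub in sheet.groupby(["donor_id", "passage_label"]):
        arrays = list(sub["array_id"])
        if len(arrays) < 2:
            continue
        group_sds.append(matrix.loc[:, arrays].std(axis=1, ddof=1))
    if not group_sds:
        raise ValueError("no donor/passage group has >=2 technical replicates")
    cutoff = pd.concat(group_sds, axis=1).median(axis=1)
    cutoff.name = "between_cutoff"
    return cutoff


def donor_level_means(matrix: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical-replicate arrays to donor/passage means.

    Returns a sequence x (donor, passage) frame of mean log2 values.
    """
    sheet = sheet[sheet["array_id"].isin(matrix.columns)]
    cols = {}
    for key, sub in sheet.groupby(["donor_id", "passage_label"]):
        cols[key] = matrix.loc[:, list(sub["array_id"])].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(
        out.columns, names=["donor_id", "passage_label"]
    )
    return out


def apply_cascade(matrix: pd.DataFrame, sheet: pd.DataFrame,
                  within: pd.Series, between: pd.Series,
                  magnitude_cutoff: float, alpha: float = 0.05,
                  early: str = "P3", late: str = "P7",
                  passages: list[str] | None = None) -> pd.DataFrame:
    """Run the four-stage cascade and return the FilterTrace frame.

    Only donors observed at both endpoint passages contribute to the
    contrast; donor-level values are means over technical replicates.
    ``passages`` (default: all passages in the sheet) defines the levels the
    magnitude stage must each clear.
    """
    units = donor_level_means(matrix, sheet)
    donors = units.columns.get_level_values("donor_id")
    passages_present = set(units.columns.get_level_values("passage_label"))
    if passages is None:
        passages = sorted(passages_present)
    have_early = set(donors[units.columns.get_level_values("passage_label") == early])
    have_late = set(donors[units.columns.get_level_values("passage_label") == late])
    complete = sorted(have_early & have_late)
    if len(complete) < 2:
        raise ValueError(
            f"need >=2 donors observed at both {early} and {late}, got {len(complete)}"
        )
    early_vals = units.loc[:, [(d, early) for d in complete]].to_numpy()
    late_vals = units.loc[:, [(d, late) for d in complete]].to_numpy()
    diffs = late_vals - early_vals
    mean_diff = diffs.mean(axis=1)
    abs_diff = np.abs(mean_diff)

    # paired t-test across donors, vectorized; zero-variance rows degenerate
    n = len(complete)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = mean_diff / (sd / np.sqrt(n))
    bio_p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 1)
    degenerate = sd == 0.0
    bio_p[degenerate & (mean_diff != 0)] = 0.0
    bio_p[degenerate & (mean_diff == 0)] = 1.0

    trace = pd.DataFrame(index=matrix.index)
    trace["within_cutoff"] = within.reindex(matrix.index)
    trace["between_cutoff"] = between.reindex(matrix.index)
    trace["contrast_abs_diff"] = abs_diff
    trace["contrast_mean_diff"] = mean_diff
    trace["bio_p"] = bio_p
    for p in passages:
        cols = [c for c in units.columns if c[1] == p]
        trace[f"mean_{p}"] = units.loc[:, cols].mean(axis=1)
    trace["magnitude_cutoff"] = magnitude_cutoff

    pass_within = trace["contrast_abs_diff"] > trace["within_cutoff"]
    pass_between = trace["contrast_abs_diff"] > trace["between_cutoff"]
    pass_bio = trace["bio_p"] <= alpha
    pass_mag = np.logical_and.reduce(
        [trace[f"mean_{p}"] > magnitude_cutoff for p in passages]
    )

    flags = pd.DataFrame({
        "pass_within": pass_within,
        "pass_between": pass_between,
        "pass_biological": pass_bio,
        "pass_magnitude": pd.Series(pass_mag, index=matrix.index),
    }).astype("boolean")
    # stages after the first failure are not evaluated
    failed = ~flags["pass_within"].fillna(False)
    for later in ["pass_between", "pass_biological", "pass_magnitude"]:
        flags.loc[failed, later] = pd.NA
        failed = failed | ~flags[later].fillna(True)

    trace = pd.concat([trace, flags], axis=1)
    trace["final_eligible"] = flags.fillna(False).all(axis=1).astype(bool)
    trace.index.name = "sequence_id"
    return trace


def cascade_counts(trace: pd.DataFrame) -> dict[str, int]:
    """Per-stage elimination counts; they sum with the eligible set to the total."""
    counts = {"total": int(len(trace))}
    remaining = trace
    for stage, col in zip(STAGES, ["pass_within", "pass_between",
                                   "pass_biological", "pass_magnitude"]):
        failed = remaining[remaining[col].fillna(False).astype(bool) == False]  # noqa: E712
        counts[f"eliminated_{stage}"] = int(len(failed))
        remaining = remaining[remaining[col].fillna(False).astype(bool)]
    counts["eligible"] = int(len(remaining))
    return counts
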