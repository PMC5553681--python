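"""Passage and group differential expression.

The passage analysis is a repeated-measures ANOVA per sequence with a
compound-symmetry correlation structure across passages within a donor
(equivalently a donor random intercept).  For the balanced, complete
donor x passage tables the model requires, the REML/GLS solution coincides
with the classical randomized-block ANOVA, which is used in closed form:

    MSE  = SS(donor x passage interaction) / ((n-1)(k-1))
    F    = MS(passage) / MSE  on (k-1, (n-1)(k-1)) df
    pairwise contrast a-b:  t = (ybar_a - ybar_b) / sqrt(2 MSE / n)
                            on (n-1)(k-1) df

Technical replicates are averaged to donor/passage units before modeling —
the repeated measure is the donor across passages — and donors missing a
passage are dropped with a warning.  Benjamini-Hochberg adjustment is
applied per contrast family across sequences (configurable to pool all
families).  Fold changes are reported with the signed convention: a log2
difference d maps to 2**d when d >= 0 and to -(2**-d) otherwise, so the sign
marks the direction at the later passage.

The MSC-vs-cancer comparison is a classic pooled-variance (unequal sample
size, equal variance) two-sample t-test per sequence on biological-unit
means, with its own technical-variability and magnitude pre-filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variability_filters import donor_level_means

__all__ = [
    "fold_from_log2diff",
    "benjamini_hochberg",
    "rm_anova_cs",
    "pooled_t_group_contrast",
    "PassageDEResult",
    "GroupDEResult",
]


def fold_from_log2diff(d):
    """Signed fold change from a log2 difference.

    ``d >= 0 -> 2**d``; ``d < 0 -> -(2**-d)``, so e.g. -1 maps to -2.0
    (2-fold down) and folds never land in (-1, 1).
    """
    d = np.asarray(d, dtype=float)
    out = np.where(d >= 0, 2.0 ** d, -(2.0 ** (-d)))
    return out if out.ndim else float(out)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values.

    Returns adjusted values in the input order: p_(i) * m / i, cumulative
    minimum from the largest rank down, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class PassageDEResult:
    """Per-sequence ANOVA F tests and pairwise passage contrasts."""

    #: per-sequence F statistic and overall p-value
    anova: pd.DataFrame
    #: per-(late, early) contrast: estimate, raw p, adjusted p, fold, flag
    contrasts: dict[tuple[str, str], pd.DataFrame]
    donors_used: list[str]

    def significant(self, contrast: tuple[str, str]) -> pd.Index:
        t = self.contrasts[contrast]
        return t.index[t["significant"]]

    def table(self) -> pd.DataFrame:
        """One row per sequence with per-contrast adjusted p and fold."""
        parts = [self.anova]
        for (late, early), t in self.contrasts.items():
            tag = f"{late}_vs_{early}"
            parts.append(t[["p_raw", "p_adj", "fold_change", "significant"]]
                         .add_prefix(f"{tag}_"))
        return pd.concat(parts, axis=1)


def rm_anova_cs(matrix: pd.DataFrame, sheet: pd.DataFrame,
                eligible=None, passages: list[str] | None = None,
                alpha_adj: float = 0.05,
                adjust_scope: str = "per_contrast") -> PassageDEResult:
    """Repeated-measures ANOVA with compound symmetry, per sequence.

    ``eligible`` restricts the tested sequences (default: all rows of
    ``matrix``).  Donors missing any passage are dropped with a warning;
    fewer than 3 complete donors is an error.  BH adjustment runs across
    sequences within each pairwise contrast family (``per_contrast``) or
    across all families pooled (``pooled``).
    """
    units = donor_level_means(matrix, sheet)
    if passages is None:
        passages = sorted(set(units.columns.get_level_values("passage_label")))
    k = len(passages)
    if k < 2:
        raise ValueError("need at least two passages")
    donors_all = sorted(set(units.columns.get_level_values("donor_id")))
    complete = [d for d in donors_all
                if all((d, p) in units.columns for p in passages)]
    dropped = sorted(set(donors_all) - set(complete))
    if dropped:
        warnings.warn(f"donors missing a passage dropped from ANOVA: {dropped}")
    n = len(complete)
    if n < 3:
        raise ValueError(f"need >=3 complete donors, got {n}")
    if eligible is None:
        eligible = matrix.index
    eligible = pd.Index(eligible)

    # y: sequences x donors x passages
    y = np.stack(
        [units.loc[eligible, [(d, p) for d in complete]].to_numpy()
         for p in passages],
        axis=2,
    )
    grand = y.mean(axis=(1, 2), keepdims=True)
    donor_mean = y.mean(axis=2, keepdims=True)
    pass_mean = y.mean(axis=1, keepdims=True)
    resid = y - donor_mean - pass_mean + grand
    ss_pass = (n * (pass_mean - grand) ** 2).sum(axis=(1, 2))
    df_err = (n - 1) * (k - 1)
    mse = (resid ** 2).sum(axis=(1, 2)) / df_err
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_pass / (k - 1)) / mse
    p_overall = stats.f.sf(F, k - 1, df_err)
    zero = mse == 0.0
    F[zero] = 0.0
    p_overall[zero & (ss_pass == 0.0)] = 1.0
    p_overall[zero & (ss_pass > 0.0)] = 0.0

    pass_means = y.mean(axis=1)  # sequences x passages
    anova = pd.DataFrame(
        {"F": F, "p_overall": p_overall}, index=eligible
    )

    contrasts = {}
    raw_ps = {}
    for i, early in enumerate(passages):
        for late in passages[i + 1:]:
            est = pass_means[:, passages.index(late)] - pass_means[:, passages.index(early)]
            with np.errstate(divide="ignore", invalid="ignore"):
                t = est / np.sqrt(2.0 * mse / n)
            p = 2.0 * stats.t.sf(np.abs(t), df=df_err)
            p[zero & (est != 0.0)] = 0.0
            p[zero & (est == 0.0)] = 1.0
            t[zero] = 0.0
            raw_ps[(late, early)] = (est, t, p)

    if adjust_scope == "pooled":
        all_p = np.concatenate([v[2] for v in raw_ps.values()])
        all_adj = benjamini_hochberg(all_p)
        offsets = np.cumsum([0] + [len(v[2]) for v in raw_ps.values()])
        adj_by_key = {
            key: all_adj[offsets[i]:offsets[i + 1]]
            for i, key in enumerate(raw_ps)
        }
    elif adjust_scope == "per_contrast":
        adj_by_key = {key: benjamini_hochberg(v[2]) for key, v in raw_ps.items()}
    else:
        raise ValueError(f"unknown adjust_scope {adjust_scope!r}")

    for key, (est, t, p) in raw_ps.items():
        adj = adj_by_key[key]
        contrasts[key] = pd.DataFrame({
            "estimate_log2": est,
            "t": t,
            "p_raw": p,
            "p_adj": adj,
            "fold_change": fold_from_log2diff(est),
            "significant": adj < alpha_adj,
        }, index=eligible)
    return PassageDEResult(anova=anova, contrasts=contrasts, donors_used=complete)


@dataclass
class GroupDEResult:
    """Pooled-variance group contrast with its pre-filter trace."""

    table: pd.DataFrame
    filter_trace: pd.DataFrame
    n_a: int
    n_b: int

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"].fillna(False)]


def pooled_t_group_contrast(units_a: pd.DataFrame, units_b: pd.DataFrame,
                            within: pd.Series | None = None,
                            between: pd.Series | None = None,
                            magnitude_cutoff: float | None = None,
                            alpha_adj: float = 0.01) -> GroupDEResult:
    """Pooled-variance t-test of group B vs group A per sequence.

    ``units_a`` / ``units_b`` are sequence x biological-unit matrices (e.g.
    donor means at P3 vs cancer sample means).  When ``within``/``between``
    cutoffs are given, sequences whose |mean difference| does not exceed
    both are excluded before testing, and ``magnitude_cutoff`` further
    requires the mean expression to clear background in at least one group;
    BH runs across the surviving sequences.  Fold signs follow group B.
    """
    if units_a.shape[1] < 2 or units_b.shape[1] < 2:
        raise ValueError("both groups need >=2 biological units")
    common = units_a.index.intersection(units_b.index)
    a = units_a.loc[common].to_numpy()
    b = units_b.loc[common].to_numpy()
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    diff = mean_b - mean_a

    trace = pd.DataFrame(index=common)
    trace["abs_diff"] = np.abs(diff)
    tested = pd.Series(True, index=common)
    if within is not None:
        trace["within_cutoff"] = within.reindex(common)
        tested &= trace["abs_diff"] > trace["within_cutoff"]
    if between is not None:
        trace["between_cutoff"] = between.reindex(common)
        tested &= trace["abs_diff"] > trace["between_cutoff"]
    trace["pass_technical"] = tested
    if magnitude_cutoff is not None:
        above = (pd.Series(mean_a, index=common) > magnitude_cutoff) | (
            pd.Series(mean_b, index=common) > magnitude_cutoff
        )
        trace["pass_magnitude"] = above
        tested &= above
    trace["tested"] = tested

    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(np.abs(t), df=na + nb - 2)
    zero = sp2 == 0.0
    p[zero & (diff != 0.0)] = 0.0
    p[zero & (diff == 0.0)] = 1.0
    t[zero] = 0.0

    table = pd.DataFrame({
        "estimate_log2": diff,
        "t": t,
        "p_raw": p,
        "fold_change": fold_from_log2diff(diff),
    }, index=common)
    table["p_adj"] = np.nan
    sel = tested.to_numpy()
    if sel.any():
        table.loc[sel, "p_adj"] = benjamini_hochberg(p[sel])
    table["significant"] = table["p_adj"] < alpha_adj
    table.loc[~sel, "significant"] = False
    return GroupDEResult(table=table, filter_trace=trace, n_a=na, n_b=nb)
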