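"""Pipeline driver, PCA views, figures and machine-readable summaries.

``run_pipeline`` composes the full workflow on a probe table + sample sheet:
outlier-array removal, joint normalization, detection calls, the duplicate
long/short comparison, the four-stage filter cascade, repeated-measures
ANOVA with BH-adjusted passage contrasts, and (when a cancer cohort is
present) the pooled-t group contrast — writing the filter trace, result
tables, figures and a summary JSON to an output directory.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats, normalization, detection, variability_filters
from . import differential_expression as de

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "pca_views", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Knobs for one pipeline run; all alphas in (0, 1)."""

    scheme: str = "quantile"
    collapse_first: bool = True
    outlier_k: float = 5.0
    background_n_sd: float = 1.0
    cascade_alpha: float = 0.05
    de_alpha: float = 0.05
    group_alpha: float = 0.01
    adjust_scope: str = "per_contrast"
    early_passage: str = "P3"
    late_passage: str = "P7"
    make_plots: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("cascade_alpha", "de_alpha", "group_alpha"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")


def pca_views(matrix: pd.DataFrame, labels: pd.Series,
              subset=None, n_components: int = 3) -> pd.DataFrame:
    """Centered (unscaled) PCA of arrays over the selected sequences.

    ``subset`` restricts to a sequence set ("supervised" view when it is a
    significant set); must contain >=2 sequences.  Returns array
    coordinates on the first ``n_components`` components with the label
    column attached.
    """
    from sklearn.decomposition import PCA

    if subset is not None:
        subset = [s for s in subset if s in matrix.index]
        if len(subset) < 2:
            raise ValueError("PCA subset must contain >=2 sequences")
        matrix = matrix.loc[subset]
    X = matrix.to_numpy().T  # arrays x sequences
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    out = pd.DataFrame(
        coords, index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    out["label"] = labels.reindex(out.index)
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_
    return out


def _plot_all(outdir: Path, expr, sheet, trace, de_result, calls, config):
    """Volcano, parallel, heatmap and PCA figures (Agg backend, PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    late, early = config.late_passage, config.early_passage
    key = (late, early)
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)

    # volcano of the endpoint contrast over all sequences (cascade stats)
    fig, ax = plt.subplots(figsize=(5, 4))
    x = trace["contrast_mean_diff"]
    y = -np.log10(np.clip(trace["bio_p"], 1e-300, None))
    ax.scatter(x, y, s=4, c="grey", alpha=0.5)
    sig = de_result.significant(key) if key in de_result.contrasts else []
    ax.scatter(x.loc[sig], y.loc[sig], s=10, c="red")
    ax.set_xlabel(f"mean log2({late}) - log2({early})")
    ax.set_ylabel("-log10 p (paired t)")
    fig.savefig(figdir / "volcano.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    # |diff| vs technical cutoffs (the filter scatter)
    for stage in ("within", "between"):
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(trace[f"{stage}_cutoff"], trace["contrast_abs_diff"],
                   s=4, alpha=0.5)
        lim = max(trace[f"{stage}_cutoff"].max(), trace["contrast_abs_diff"].max())
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel(f"{stage}-chip variability cutoff (log2)")
        ax.set_ylabel(f"|mean {late} - {early}| (log2)")
        fig.savefig(figdir / f"cutoff_{stage}.png", dpi=120, bbox_inches="tight")
        plt.close(fig)

    sig_seqs = list(sig)
    msc = sheet[sheet["cohort"].str.startswith("MSC")]
    if len(sig_seqs) >= 2:
        sub = expr.loc[sig_seqs, msc["array_id"]]
        # parallel plot of significant sequences, centered per sequence
        fig, ax = plt.subplots(figsize=(7, 4))
        centered = sub.sub(sub.mean(axis=1), axis=0)
        for _, row in centered.iterrows():
            ax.plot(range(sub.shape[1]), row.to_numpy(), lw=0.8, alpha=0.7)
        ax.set_xlabel("array")
        ax.set_ylabel("log2 expression - sequence mean")
        fig.savefig(figdir / "parallel.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        # average-linkage, correlation-distance heatmap
        try:
            g = sns.clustermap(sub, method="average", metric="correlation",
                               cmap="vlag", figsize=(8, 6),
                               col_cluster=True, row_cluster=True)
            g.savefig(figdir / "heatmap.png", dpi=120)
            plt.close(g.fig)
        except Exception as exc:  # degenerate rows can break clustering
            log.warning("heatmap skipped: %s", exc)

    labels = msc.set_index("array_id")["passage_label"]
    for name, subset in (("unsupervised", None),
                         ("supervised", sig_seqs if len(sig_seqs) >= 2 else None)):
        if name == "supervised" and subset is None:
            continue
        coords = pca_views(expr[msc["array_id"]], labels, subset=subset)
        fig, ax = plt.subplots(figsize=(5, 4))
        for lab, grp in coords.groupby("label"):
            ax.scatter(grp["PC1"], grp["PC2"], s=18, label=str(lab))
        ax.legend(title="passage")
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        fig.savefig(figdir / f"pca_{name}.png", dpi=120, bbox_inches="tight")
        plt.close(fig)


def run_pipeline(probes: pd.DataFrame, sheet: pd.DataFrame,
                 annotations: pd.DataFrame | None = None,
                 duplicate_pairs=None,
                 config: PipelineConfig | None = None,
                 outdir=None) -> dict:
    """Execute the full analysis; returns the summary dict.

    When ``outdir`` is given, the filter trace, detection and DE tables,
    figures and ``summary.json`` are written there.
    """
    config = config or PipelineConfig()
    config.validate()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    summary: dict = {"config": {k: v for k, v in asdict(config).items()}}

    # 1. outlier arrays, from raw negative-control background
    outliers = detection.flag_outlier_arrays(probes, k=config.outlier_k)
    summary["outlier_arrays"] = sorted(outliers)
    probes = probes[~probes["array_id"].isin(outliers)]
    sheet = sheet[~sheet["array_id"].isin(outliers)].reset_index(drop=True)
    summary["n_arrays"] = int(sheet["array_id"].nunique())

    msc_sheet = sheet[sheet["cohort"].str.startswith("MSC")]
    msc_arrays = list(msc_sheet["array_id"])
    msc_probes = probes[probes["array_id"].isin(msc_arrays)]

    # 2. normalization (controls mapped onto the expression scale)
    expr, negctl = normalization.prepare_matrices(
        msc_probes, scheme=config.scheme, collapse_first=config.collapse_first
    )

    # 3. detection calls
    cutoffs = detection.background_cutoffs(
        negctl, msc_sheet, n_sd=config.background_n_sd
    )
    calls = detection.detection_calls(expr, msc_sheet, cutoffs, annotations)
    summary["n_groups"] = int(calls.expressed.shape[1])
    summary["negctl_global_mean"] = round(cutoffs.global_mean, 3)
    summary["negctl_global_sd"] = round(cutoffs.global_sd, 3)
    summary["n_commonly_expressed_sequences"] = int(
        calls.commonly_expressed.sum()
    )
    mt = calls.mirna_table
    summary["n_commonly_expressed_mirnas"] = int(mt["commonly_expressed"].sum())

    # 4. duplicate long/short comparison among commonly expressed sequences
    if duplicate_pairs:
        try:
            dup = detection.duplicate_length_comparison(
                expr, duplicate_pairs,
                restrict=set(calls.commonly_expressed.index[calls.commonly_expressed]),
            )
            summary["duplicate_comparison"] = {
                "fold_change": round(dup.fold_change, 3),
                "p_value": dup.p_value,
                "n_pairs": dup.n_pairs,
            }
        except ValueError as exc:
            log.warning("duplicate comparison skipped: %s", exc)

    # 5. filter cascade on the endpoint contrast
    within = variability_filters.within_chip_cutoffs(
        msc_probes, scheme=config.scheme
    )
    between = variability_filters.between_chip_cutoffs(expr, msc_sheet)
    trace = variability_filters.apply_cascade(
        expr, msc_sheet, within, between,
        magnitude_cutoff=cutoffs.global_cutoff, alpha=config.cascade_alpha,
        early=config.early_passage, late=config.late_passage,
    )
    counts = variability_filters.cascade_counts(trace)
    summary["cascade"] = counts

    # 6. repeated-measures ANOVA on the eligible set
    eligible = trace.index[trace["final_eligible"]]
    de_result = None
    if len(eligible) > 0:
        donors_complete = None
        try:
            de_result = de.rm_anova_cs(
                expr, msc_sheet, eligible=eligible,
                alpha_adj=config.de_alpha, adjust_scope=config.adjust_scope,
            )
            key = (config.late_passage, config.early_passage)
            sig = de_result.significant(key)
            summary["n_significant_sequences"] = int(len(sig))
            folds = de_result.contrasts[key].loc[sig, "fold_change"]
            summary["significant_folds"] = {
                s: round(float(f), 3) for s, f in folds.items()
            }
            donors_complete = de_result.donors_used
        except ValueError as exc:
            log.warning("ANOVA stage skipped: %s", exc)
            summary["n_significant_sequences"] = 0
        summary["donors_in_anova"] = donors_complete
    else:
        summary["n_significant_sequences"] = 0

    # 7. group contrast vs a cancer cohort, when present
    if (sheet["cohort"] == "cancer").any():
        cancer_sheet = sheet[sheet["cohort"] == "cancer"]
        p3_sheet = msc_sheet[msc_sheet["passage_label"] == config.early_passage]
        sub_sheet = pd.concat([p3_sheet, cancer_sheet])
        sub_probes = probes[probes["array_id"].isin(sub_sheet["array_id"])]
        sub_expr, sub_neg = normalization.prepare_matrices(
            sub_probes, scheme=config.scheme,
            collapse_first=config.collapse_first,
        )
        sub_cut = detection.background_cutoffs(
            sub_neg, sub_sheet, n_sd=config.background_n_sd
        )
        w2 = variability_filters.within_chip_cutoffs(
            sub_probes, scheme=config.scheme
        )
        b2 = variability_filters.between_chip_cutoffs(sub_expr, sub_sheet)
        units_msc = variability_filters.donor_level_means(
            sub_expr, p3_sheet
        )
        units_msc.columns = units_msc.columns.get_level_values("donor_id")
        units_cancer = variability_filters.donor_level_means(
            sub_expr, cancer_sheet
        )
        units_cancer.columns = units_cancer.columns.get_level_values("donor_id")
        group = de.pooled_t_group_contrast(
            units_msc, units_cancer, within=w2, between=b2,
            magnitude_cutoff=sub_cut.global_cutoff,
            alpha_adj=config.group_alpha,
        )
        ft = group.filter_trace
        summary["group_contrast"] = {
            "negctl_mean": round(sub_cut.global_mean, 3),
            "negctl_sd": round(sub_cut.global_sd, 3),
            "n_arrays": int(sub_sheet["array_id"].nunique()),
            "n_pass_technical": int(ft["pass_technical"].sum()),
            "n_tested": int(ft["tested"].sum()),
            "n_significant": int(len(group.significant)),
            "max_abs_fold": round(
                float(group.table.loc[group.significant, "fold_change"]
                      .abs().max()), 3
            ) if len(group.significant) else None,
        }
        if outdir is not None:
            group.table.to_csv(outdir / "group_contrast.tsv", sep="\t",
                               index_label="sequence_id")

    if outdir is not None:
        io_formats.write_filter_trace(trace, outdir / "filter_trace.tsv")
        io_formats.write_expression_matrix(expr, outdir / "expression.tsv")
        calls.sequence_table.to_csv(outdir / "detection_sequences.tsv",
                                    sep="\t", index_label="sequence_id")
        calls.mirna_table.to_csv(outdir / "detection_mirnas.tsv", sep="\t",
                                 index_label="mirna_name")
        if de_result is not None:
            de_result.table().to_csv(outdir / "passage_de.tsv", sep="\t",
                                     index_label="sequence_id")
        if config.make_plots and de_result is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _plot_all(outdir, expr, sheet, trace, de_result, calls, config)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
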