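"""Probe collapsing and array normalization.

Two normalization schemes are supported for single-color probe signals:

* ``quantile`` — cross-array quantile normalization of the raw signal with no
  background correction.  Every array is mapped rank-wise onto the mean of
  the arrays' order statistics; tied values receive the mean of the tied
  ranks' reference values.  This is the default input to all downstream
  analysis.
* ``afe_tgs_p75`` — 75th-percentile scaling of total gene signal: each array
  is scaled so its 75th percentile equals the geometric mean of all arrays'
  75th percentiles.

Both return log2-scale matrices.  Probe replicates of a sequence are
collapsed to their median on the raw scale; by default collapsing happens
before normalization (the collapsed matrix is normalized), with a switch to
normalize at probe level first.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "collapse_probe_replicates",
    "probe_matrix",
    "quantile_normalize",
    "afe_tgs_p75",
    "prepare_matrices",
]


def collapse_probe_replicates(probes: pd.DataFrame,
                              control_type: str = "experimental") -> pd.DataFrame:
    """Collapse on-array probe replicates to one value per (sequence, array).

    Returns a sequence x array matrix of the median raw signal of each
    sequence's probe replicates.  Singleton groups pass through unchanged.
    """
    sub = probes[probes["control_type"] == control_type]
    mat = sub.pivot_table(index="sequence_id", columns="array_id",
                          values="raw_signal", aggfunc="median")
    mat.columns.name = None
    return mat


def probe_matrix(probes: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long probe table to a probe x array raw-signal matrix."""
    mat = probes.pivot(index="probe_id", columns="array_id", values="raw_signal")
    mat.columns.name = None
    return mat


def _quantile_map(values: pd.DataFrame) -> pd.DataFrame:
    arr = values.to_numpy(dtype=float)
    n, m = arr.shape
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(m):
        order = np.argsort(arr[:, j], kind="stable")
        col = np.empty(n)
        col[order] = reference
        # ties get the mean of the tied ranks' reference values
        s = pd.Series(col).groupby(pd.Series(arr[:, j])).transform("mean")
        out[:, j] = s.to_numpy()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a raw-signal matrix across arrays, then log2.

    All values must be positive.  A single-array input is returned log2'd
    unchanged (with a warning): there is nothing to normalize against.
    """
    if (raw.to_numpy() <= 0).any():
        raise ValueError("quantile_normalize requires strictly positive signals")
    if raw.shape[1] < 2:
        warnings.warn("single-array input: quantile normalization is a no-op")
        out = np.log2(raw)
    else:
        out = np.log2(_quantile_map(raw))
    out.attrs["provenance"] = "quantile_raw"
    return out


def afe_tgs_p75(raw: pd.DataFrame) -> pd.DataFrame:
    """Scale each array to a common 75th percentile, then log2.

    The common target is the geometric mean of the arrays' 75th percentiles;
    any fixed target cancels in downstream differences.
    """
    if (raw.to_numpy() <= 0).any():
        raise ValueError("afe_tgs_p75 requires strictly positive signals")
    p75 = raw.quantile(0.75, axis=0)
    if raw.shape[1] < 2:
        warnings.warn("single-array input: percentile scaling is a no-op")
        scaled = raw
    else:
        target = np.exp(np.log(p75).mean())
        scaled = raw * (target / p75)
    out = np.log2(scaled)
    out.attrs["provenance"] = "afe_tgs_p75"
    return out


_SCHEMES = {"quantile": quantile_normalize, "afe_tgs_p75": afe_tgs_p75}


def _map_through(raw_col: np.ndarray, norm_col: np.ndarray,
                 values: np.ndarray) -> np.ndarray:
    """Send ``values`` through the monotone raw -> normalized map of one array."""
    order = np.argsort(raw_col, kind="stable")
    x, y = raw_col[order], norm_col[order]
    # collapse duplicate x for interp monotonicity
    x, idx = np.unique(x, return_index=True)
    return np.interp(values, x, y[idx])


def prepare_matrices(probes: pd.DataFrame, scheme: str = "quantile",
                     collapse_first: bool = True):
    """Produce the normalized expression and negative-control matrices.

    The normalization map of each array is built from experimental probes
    only; negative controls are then sent through that array's monotone
    raw-to-normalized map, so they land on the expression scale (detection
    cutoffs are comparable) without their random scatter perturbing the
    experimental ranks.  Returns ``(expression, negative_controls)``, both
    log2.

    With ``collapse_first`` (default) probe replicates are collapsed to
    sequence medians and the collapsed matrix is normalized; otherwise the
    full experimental probe-level matrix is normalized and then collapsed
    on the log2 scale.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    normalize = _SCHEMES[scheme]
    neg = probes[probes["control_type"] == "negative"]
    neg_mat = neg.pivot(index="probe_id", columns="array_id", values="raw_signal")
    neg_mat.columns.name = None

    if collapse_first:
        basis = collapse_probe_replicates(probes)
        normed = normalize(basis)
        expr = normed
    else:
        pm = probe_matrix(probes[probes["control_type"] == "experimental"])
        basis = pm
        normed = normalize(pm)
        exp_probes = probes.loc[
            probes["control_type"] == "experimental",
            ["probe_id", "sequence_id"],
        ].drop_duplicates("probe_id").set_index("probe_id")
        expr = normed.loc[exp_probes.index].groupby(
            exp_probes["sequence_id"]).median()
        expr.index.name = "sequence_id"

    neg_mat = neg_mat.loc[:, basis.columns]
    negctl = pd.DataFrame(
        {a: _map_through(basis[a].to_numpy(), normed[a].to_numpy(),
                         neg_mat[a].to_numpy())
         for a in basis.columns},
        index=neg_mat.index,
    )
    expr.attrs["provenance"] = normed.attrs.get("provenance", scheme)
    return expr, negctl
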