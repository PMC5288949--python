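"""Preprocessing chain for probe-level expression matrices.

The chain runs in a fixed order:

1. drop probes whose missing fraction reaches the threshold (default 20%),
2. impute the remaining missing entries by local least squares (regression
   on the most-correlated complete probes),
3. merge the probes of each feature by the per-sample maximum,
4. normalize each sample (column) by median centering and MAD scaling so all
   samples share a similar background.

The MAD is the raw median of absolute deviations from the median, without
the Gaussian consistency constant: the goal is background equalization, not
a variance estimate, and any constant factor cancels once features are
z-scored ahead of kernel computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ProbeMatrix",
    "MissingPolicy",
    "filter_missing",
    "impute_lls",
    "merge_probes",
    "mad_normalize",
    "preprocess_chain",
    "read_probe_matrix",
]


@dataclass
class ProbeMatrix:
    """Probe-by-sample matrix with NaN marking missing entries."""

    values: np.ndarray
    probe_ids: list
    probe_to_feature: dict
    sample_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("values shape must be (probes, samples)")
        unmapped = [p for p in self.probe_ids if p not in self.probe_to_feature]
        if unmapped:
            raise ValueError(f"probes without a feature mapping: {unmapped}")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=1)


@dataclass(frozen=True)
class MissingPolicy:
    """Missingness filter threshold and imputation neighborhood size."""

    max_missing_fraction: float = 0.20
    neighbor_count: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.max_missing_fraction < 1.0:
            raise ValueError("max_missing_fraction must lie in (0, 1)")
        if self.neighbor_count < 1:
            raise ValueError("neighbor_count must be >= 1")


def filter_missing(pm: ProbeMatrix, pol: MissingPolicy = MissingPolicy()) -> ProbeMatrix:
    """Drop probes whose missing fraction is >= the threshold (strict '< 20%' keep rule)."""
    frac = pm.missing_fraction()
    keep = frac < pol.max_missing_fraction
    if not keep.any():
        raise ValueError("missingness filter dropped every probe")
    ids = [p for p, k in zip(pm.probe_ids, keep) if k]
    return ProbeMatrix(
        values=pm.values[keep],
        probe_ids=ids,
        probe_to_feature={p: pm.probe_to_feature[p] for p in ids},
        sample_ids=list(pm.sample_ids),
    )


def impute_lls(pm: ProbeMatrix, pol: MissingPolicy = MissingPolicy()) -> ProbeMatrix:
    """Local least-squares imputation.

    Each probe with missing entries is regressed (with intercept) on its
    ``neighbor_count`` most-correlated complete probes over the jointly
    observed samples; the fit predicts the missing entries. Probes constant
    over their observed samples are filled with that constant. If fewer
    complete probes than ``neighbor_count`` exist, all probes fall back to
    row-median filling with a warning.
    """
    V = pm.values.copy()
    mask = np.isnan(V)
    if not mask.any():
        return ProbeMatrix(V, list(pm.probe_ids), dict(pm.probe_to_feature), list(pm.sample_ids))

    complete = ~mask.any(axis=1)
    incomplete_rows = np.flatnonzero(mask.any(axis=1))
    if complete.sum() < pol.neighbor_count:
        warnings.warn(
            f"only {int(complete.sum())} complete probes < neighbor_count={pol.neighbor_count}; "
            "falling back to row-median imputation",
            stacklevel=2,
        )
        for i in incomplete_rows:
            V[i, mask[i]] = np.nanmedian(V[i])
        return ProbeMatrix(V, list(pm.probe_ids), dict(pm.probe_to_feature), list(pm.sample_ids))

    Xc = V[complete]  # complete probes x samples
    for i in incomplete_rows:
        obs = ~mask[i]
        target = V[i, obs]
        if np.ptp(target) == 0:  # constant over observed samples; correlation undefined
            V[i, mask[i]] = target[0]
            continue
        neigh_obs = Xc[:, obs]
        with np.errstate(invalid="ignore", divide="ignore"):
            c = _rowwise_abs_corr(neigh_obs, target)
        order = np.argsort(-c, kind="stable")[: pol.neighbor_count]
        A = np.column_stack([np.ones(obs.sum()), neigh_obs[order].T])
        coef, *_ = np.linalg.lstsq(A, target, rcond=None)
        miss = mask[i]
        A_miss = np.column_stack([np.ones(miss.sum()), Xc[order][:, miss].T])
        V[i, miss] = A_miss @ coef
    return ProbeMatrix(V, list(pm.probe_ids), dict(pm.probe_to_feature), list(pm.sample_ids))


def _rowwise_abs_corr(rows: np.ndarray, target: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    tc = target - target.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (tc**2).sum())
    num = rc @ tc
    out = np.zeros(len(rows))
    ok = denom > 0
    out[ok] = np.abs(num[ok] / denom[ok])
    return out


def merge_probes(pm: ProbeMatrix) -> tuple:
    """Collapse probes to features by the per-sample maximum.

    Returns ``(matrix, feature_ids)`` with features ordered by first probe
    appearance. Requires a fully imputed matrix.
    """
    if np.isnan(pm.values).any():
        raise ValueError("merge_probes requires an imputed (NaN-free) matrix")
    order: list = []
    rows: dict = {}
    for i, p in enumerate(pm.probe_ids):
        f = pm.probe_to_feature[p]
        if f not in rows:
            rows[f] = pm.values[i].copy()
            order.append(f)
        else:
            np.maximum(rows[f], pm.values[i], out=rows[f])
    return np.vstack([rows[f] for f in order]), order


def mad_normalize(X: np.ndarray, sample_ids: Optional[list] = None) -> np.ndarray:
    """Center each sample (column) at its median and scale by its raw MAD."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("mad_normalize requires a NaN-free matrix")
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    zero = np.flatnonzero(mad == 0)
    if len(zero):
        name = sample_ids[zero[0]] if sample_ids else f"column {zero[0]}"
        raise ValueError(f"zero MAD in sample {name}; cannot normalize")
    return (X - med) / mad


def preprocess_chain(pm: ProbeMatrix, pol: MissingPolicy = MissingPolicy()) -> tuple:
    """filter -> impute -> merge -> normalize; returns (matrix, feature_ids, sample_ids)."""
    pm = filter_missing(pm, pol)
    pm = impute_lls(pm, pol)
    merged, features = merge_probes(pm)
    return mad_normalize(merged, pm.sample_ids), features, list(pm.sample_ids)


def read_probe_matrix(path, map_path, sep: str = "\t") -> ProbeMatrix:
    """Delimited probe matrix (probes as rows, header of sample ids; empty or
    NA cells are missing) plus a two-column probe-to-feature map."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    mp = pd.read_csv(map_path, sep=sep, header=None, names=["probe", "feature"], dtype=str)
    mapping = dict(zip(mp["probe"], mp["feature"]))
    return ProbeMatrix(
        values=df.to_numpy(dtype=float),
        probe_ids=[str(p) for p in df.index],
        probe_to_feature=mapping,
        sample_ids=[str(s) for s in df.columns],
    )
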