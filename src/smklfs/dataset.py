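"""Labeled expression dataset container, delimited-text I/O, and run config.

Expression matrices are stored feature-by-sample (the GEO series-matrix
habit); labels are +1 for tumor and -1 for adjacent normal. Paired designs
carry a per-sample pair key appearing exactly twice with opposite labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = ["ExpressionDataset", "RunConfig", "read_expression", "write_expression", "read_feature_list"]

_LABEL_MAP = {"tumor": 1, "normal": -1, "+1": 1, "-1": -1, "1": 1}


@dataclass
class ExpressionDataset:
    X: np.ndarray  # features x samples
    y: np.ndarray  # +1 / -1 per sample
    feature_ids: list
    sample_ids: list
    pair_ids: Optional[list] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("expression matrix must be 2-D (features x samples)")
        p, n = self.X.shape
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length does not match matrix rows")
        if len(self.sample_ids) != n or len(self.y) != n:
            raise ValueError("sample_ids / labels length does not match matrix columns")
        if len(set(self.feature_ids)) != p:
            raise ValueError("duplicate feature identifiers")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers")
        if not set(np.unique(self.y)) <= {-1.0, 1.0}:
            raise ValueError("labels must be +1 or -1")
        if self.pair_ids is not None:
            if len(self.pair_ids) != n:
                raise ValueError("pair_ids length does not match samples")
            for key in set(self.pair_ids):
                idx = [i for i, k in enumerate(self.pair_ids) if k == key]
                if len(idx) != 2 or self.y[idx[0]] * self.y[idx[1]] != -1:
                    raise ValueError(f"pair {key!r} must appear exactly twice with opposite labels")

    @property
    def n_features(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    def samples_by_features(self) -> np.ndarray:
        """The matrix transposed to the sample-by-feature layout kernels use."""
        return self.X.T

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionDataset":
        idx = list(idx)
        return ExpressionDataset(
            X=self.X[:, idx],
            y=self.y[idx],
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            pair_ids=None if self.pair_ids is None else [self.pair_ids[i] for i in idx],
        )

    def feature_index(self, names: Sequence[str]) -> np.ndarray:
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in names if f not in pos]
        if missing:
            raise KeyError(f"features not in dataset: {missing}")
        return np.array([pos[f] for f in names], dtype=int)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with the package defaults.

    ``kernel_bank`` entries are ``{"family": ..., parameter fields...}``;
    an empty list means the default three-kernel bank.
    """

    kernel_bank: list = field(default_factory=list)
    C: float = 1.0
    dual_gap_tol: float = 1e-3
    max_outer_iter: int = 200
    qp_tol: float = 1e-8
    n_star: int = 100
    r_max: int = 10
    skip_stage1: bool = False
    zscore: bool = True
    trace_normalize: bool = True
    folds: int = 10
    resamples_k: int = 10
    resample_fraction: float = 0.9
    chain_length: int = 10
    classifier: str = "mkl"  # or "linear"
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**(data or {}))

    def to_dict(self) -> dict:
        return asdict(self)


def _parse_label(raw: str, sample: str):
    key = str(raw).strip().lower()
    if key in _LABEL_MAP:
        return _LABEL_MAP[key]
    try:
        v = int(float(key))
    except ValueError:
        raise ValueError(f"unparseable label {raw!r} for sample {sample!r}")
    if v in (1, -1):
        return v
    raise ValueError(f"label for sample {sample!r} must be tumor/normal or +1/-1, got {raw!r}")


def read_expression(
    path,
    labels_path,
    sep: str = "\t",
    samples_as_rows: bool = False,
    pairs_path=None,
) -> ExpressionDataset:
    """Read a delimited expression matrix plus a sample-label table.

    The matrix has features as rows, a header of sample ids and the feature
    id in the first column (``samples_as_rows`` flips the orientation). The
    label file has two columns, sample id and tumor/normal (or +1/-1); an
    optional pairs file maps sample id to pair key.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if samples_as_rows:
        df = df.T
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature identifiers: {dupes}")
    vals = df.to_numpy()
    non_numeric = df.dtypes[~df.dtypes.apply(lambda t: np.issubdtype(t, np.number))]
    if len(non_numeric):
        col = non_numeric.index[0]
        bad_rows = [i for i, v in enumerate(df[col]) if not _is_number(v)]
        raise ValueError(f"non-numeric cell at feature {df.index[bad_rows[0]]!r}, sample {col!r}")

    labels = pd.read_csv(labels_path, sep=sep, header=None, names=["sample", "label"], dtype=str)
    label_of = {str(r["sample"]): _parse_label(r["label"], r["sample"]) for _, r in labels.iterrows()}
    unknown = set(label_of) - set(map(str, df.columns))
    if unknown:
        raise ValueError(f"labels reference unknown samples: {sorted(unknown)}")
    missing = [s for s in map(str, df.columns) if s not in label_of]
    if missing:
        raise ValueError(f"no label for samples: {missing}")
    y = np.array([label_of[str(s)] for s in df.columns], dtype=float)

    pair_ids = None
    if pairs_path is not None:
        pairs = pd.read_csv(pairs_path, sep=sep, header=None, names=["sample", "pair"], dtype=str)
        pair_of = dict(zip(pairs["sample"], pairs["pair"]))
        pair_ids = [pair_of[str(s)] for s in df.columns]

    return ExpressionDataset(
        X=vals.astype(float),
        y=y,
        feature_ids=[str(f) for f in df.index],
        sample_ids=[str(s) for s in df.columns],
        pair_ids=pair_ids,
    )


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_expression(ds: ExpressionDataset, path, sep: str = "\t", float_format: str = "%.10g") -> None:
    df = pd.DataFrame(ds.X, index=ds.feature_ids, columns=ds.sample_ids)
    df.index.name = "feature_id"
    df.to_csv(path, sep=sep, float_format=float_format)


def write_labels(ds: ExpressionDataset, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for s, lab in zip(ds.sample_ids, ds.y):
            fh.write(f"{s}{sep}{'+1' if lab > 0 else '-1'}\n")


def read_feature_list(path) -> list:
    """One feature identifier per line; used for external method rankings."""
    out = []
    for line in Path(path).read_text().splitlines():
        tok = line.strip().split()
        if tok:
            out.append(tok[0])
    return out
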