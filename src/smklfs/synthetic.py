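"""Seeded generators of expression data with planted structure.

The generator emulates the feature taxonomy of two-class expression studies:
a small set of class-informative features carrying an additive standardized
effect, correlated redundant copies of them, and a large background of
irrelevant noise features, over paired tumor/normal samples. It exists so
the selection, preprocessing and evaluation machinery can be exercised with
known ground truth and no external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dataset import ExpressionDataset
from .preprocess import ProbeMatrix

__all__ = ["SyntheticSpec", "generate", "generate_probe_fixture", "PROBE_FIXTURE_EXPECTED_MERGED"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Planted-model parameters.

    n_pairs
        Number of tumor/normal pairs; the dataset has 2 * n_pairs samples.
    p
        Total feature count.
    k_informative / k_redundant
        Counts of class-informative features and of correlated copies of them.
    effect
        Standardized between-class mean shift Delta on informative features
        (class means at +/- Delta/2, unit within-class sd).
    redundancy_rho
        Correlation of each redundant copy with its informative parent.
    noise_sd
        Within-class standard deviation of irrelevant features and of the
        innovation term of redundant copies.
    missing_rate
        Missing-at-random fraction; NaN entries in the returned matrix.
    pair_intercept_sd
        SD of a per-pair random intercept shared by both samples of a pair
        (default 0), exercising paired resampling logic.
    lognormal
        Exponentiate values to mimic the positivity of raw expression data.
    """

    n_pairs: int = 30
    p: int = 200
    k_informative: int = 10
    k_redundant: int = 10
    effect: float = 2.0
    redundancy_rho: float = 0.9
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0
    pair_intercept_sd: float = 0.0
    lognormal: bool = False

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.p < 1:
            raise ValueError("n_pairs and p must be positive")
        if self.k_informative + self.k_redundant > self.p:
            raise ValueError("k_informative + k_redundant must not exceed p")
        if self.k_redundant > 0 and self.k_informative == 0:
            raise ValueError("redundant features need informative parents")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if not 0.0 <= self.redundancy_rho <= 1.0:
            raise ValueError("redundancy_rho must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def generate(spec: SyntheticSpec) -> tuple:
    """Draw one dataset; returns ``(ExpressionDataset, roles)``.

    ``roles`` is a length-p array over {"informative", "redundant",
    "irrelevant"} aligned with the feature order. Fully reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_pairs
    y = np.empty(n)
    y[0::2] = 1.0
    y[1::2] = -1.0
    pair_ids = [f"pair{p:04d}" for p in range(spec.n_pairs) for _ in range(2)]
    sample_ids = [f"s{i:04d}{'t' if y[i] > 0 else 'n'}" for i in range(n)]

    ki, kr = spec.k_informative, spec.k_redundant
    X = np.empty((spec.p, n))
    X[ki + kr:] = rng.normal(0.0, spec.noise_sd, size=(spec.p - ki - kr, n))
    X[:ki] = rng.normal(0.0, 1.0, size=(ki, n)) + (spec.effect / 2.0) * y
    if kr:
        parents = np.arange(kr) % max(ki, 1)
        innov = rng.normal(0.0, spec.noise_sd, size=(kr, n))
        rho = spec.redundancy_rho
        X[ki:ki + kr] = rho * X[parents] + np.sqrt(1.0 - rho**2) * innov
    if spec.pair_intercept_sd > 0:
        icpt = rng.normal(0.0, spec.pair_intercept_sd, size=spec.n_pairs)
        X += np.repeat(icpt, 2)[None, :]
    if spec.lognormal:
        X = np.exp(X)
    if spec.missing_rate > 0:
        mask = rng.random(X.shape) < spec.missing_rate
        X = X.copy()
        X[mask] = np.nan

    roles = np.array(["informative"] * ki + ["redundant"] * kr + ["irrelevant"] * (spec.p - ki - kr))
    feature_ids = [f"gene{j:05d}" for j in range(spec.p)]
    ds = ExpressionDataset(X=X, y=y, feature_ids=feature_ids, sample_ids=sample_ids, pair_ids=pair_ids)
    return ds, roles


# ---------------------------------------------------------------------------
# Probe-level fixture for the preprocessing chain (synthetic, hand-checked).
#
# 12 probes, 8 features, 6 samples, 3 masked cells. Each masked probe is an
# exact affine function of complete probes, so local least-squares imputation
# with neighbor_count=2 recovers the masked entries exactly and the merged
# matrix below can be verified by hand.
# ---------------------------------------------------------------------------

_FIXTURE_VALUES = np.array([
    [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],       # p01 -> F1 (complete)
    [2.0, 4.0, np.nan, 8.0, 10.0, 12.0],  # p02 -> F1 (= 2*p01; masked s3 -> 6)
    [5.0, 1.0, 4.0, 2.0, 6.0, 3.0],       # p03 -> F2 (complete)
    [4.0, 0.0, 3.0, np.nan, 5.0, 2.0],    # p04 -> F2 (= p03 - 1; masked s4 -> 1)
    [3.0, 3.0, 3.0, 3.0, np.nan, 3.0],    # p05 -> F3 (constant 3; masked s5 -> 3)
    [0.0, 7.0, 2.0, 9.0, 4.0, 1.0],       # p06 -> F3 (complete)
    [6.0, 5.0, 9.0, 2.0, 7.0, 8.0],       # p07 -> F4 (complete)
    [1.0, 1.0, 2.0, 2.0, 3.0, 3.0],       # p08 -> F4 (complete, always lowest)
    [2.0, 9.0, 4.0, 6.0, 1.0, 8.0],       # p09 -> F5
    [7.0, 3.0, 8.0, 1.0, 9.0, 5.0],       # p10 -> F6
    [4.0, 6.0, 2.0, 8.0, 3.0, 7.0],       # p11 -> F7
    [9.0, 2.0, 7.0, 5.0, 6.0, 4.0],       # p12 -> F8
])

_FIXTURE_PROBE_IDS = [f"p{i:02d}" for i in range(1, 13)]
_FIXTURE_FEATURES = ["F1", "F1", "F2", "F2", "F3", "F3", "F4", "F4", "F5", "F6", "F7", "F8"]
_FIXTURE_SAMPLES = [f"s{i}" for i in range(1, 7)]

# Per-feature, per-sample maximum over that feature's probes after exact
# imputation of the three masked cells (6, 1, 3 respectively).
PROBE_FIXTURE_EXPECTED_MERGED = np.array([
    [2.0, 4.0, 6.0, 8.0, 10.0, 12.0],  # F1 = p02 (2*p01 dominates)
    [5.0, 1.0, 4.0, 2.0, 6.0, 3.0],    # F2 = p03 (p04 = p03 - 1 never wins)
    [3.0, 7.0, 3.0, 9.0, 4.0, 3.0],    # F3 = max(const 3, p06)
    [6.0, 5.0, 9.0, 2.0, 7.0, 8.0],    # F4 = p07 (p08 always lowest)
    [2.0, 9.0, 4.0, 6.0, 1.0, 8.0],    # F5
    [7.0, 3.0, 8.0, 1.0, 9.0, 5.0],    # F6
    [4.0, 6.0, 2.0, 8.0, 3.0, 7.0],    # F7
    [9.0, 2.0, 7.0, 5.0, 6.0, 4.0],    # F8
])


def generate_probe_fixture(seed: int = 0, with_missing: bool = True) -> ProbeMatrix:
    """The fixed probe-level fixture used by the preprocessing tests.

    ``seed`` is accepted for interface uniformity; the fixture is a fixed,
    hand-checked table (12 probes, 8 features, 6 samples, 3 masked cells).
    ``with_missing=False`` returns the same table with the masked cells
    restored to their exact values.
    """
    vals = _FIXTURE_VALUES.copy()
    if not with_missing:
        vals[1, 2] = 6.0
        vals[3, 3] = 1.0
        vals[4, 4] = 3.0
    return ProbeMatrix(
        values=vals,
        probe_ids=list(_FIXTURE_PROBE_IDS),
        probe_to_feature=dict(zip(_FIXTURE_PROBE_IDS, _FIXTURE_FEATURES)),
        sample_ids=list(_FIXTURE_SAMPLES),
    )
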