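"""Microarray-style normalization of raw expression intensities.

The procedure mirrors standard single-colour Agilent workflows: raw signals
are floored at a detection threshold, log2-transformed, shifted so each
sample's 75th percentile is zero, then baseline-transformed by subtracting
each feature's median across samples. The result is a matrix in which
sample-level scale differences and feature-level baselines are removed,
leaving relative expression suitable for correlation screening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix


@dataclass(frozen=True)
class NormalizationParams:
    """Parameters of the floor / log2 / percentile-shift / baseline chain.

    floor
        Detection floor applied to raw intensities before the log transform
        (raw values below it are raised to it). Must be positive.
    percentile
        Per-sample percentile subtracted in the shift step. The percentile
        is computed with linear interpolation between order statistics; the
        vendor convention is not standardised, so it is configurable.
    baseline
        Baseline transform; only ``"median_all_samples"`` (subtract each
        feature's across-sample median) is defined.
    """

    floor: float = 1.0
    percentile: float = 75.0
    baseline: str = "median_all_samples"

    def __post_init__(self) -> None:
        if self.floor <= 0:
            raise ValueError("floor must be positive")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")
        if self.baseline != "median_all_samples":
            raise ValueError(f"unknown baseline transform: {self.baseline!r}")


def normalize_microarray(
    raw: ExpressionMatrix,
    params: NormalizationParams | None = None,
    return_stages: bool = False,
) -> ExpressionMatrix | dict[str, ExpressionMatrix]:
    """Floor, log2-transform, percentile-shift and baseline-centre a matrix.

    Steps, in order: values below ``params.floor`` are raised to the floor;
    log2 transform; each sample (column) has its own ``params.percentile``-th
    percentile subtracted (after which that percentile is exactly zero per
    sample); each feature (row) has its across-sample median subtracted
    (after which each feature's median is exactly zero). Dimensions and
    annotations are preserved. With ``return_stages=True`` the intermediate
    matrices are returned as ``{"log2", "shifted", "normalized"}`` so each
    step's invariant can be checked where it holds.

    Raises
    ------
    ValueError
        If the matrix has fewer than two samples (the baseline median is
        meaningless) or contains negative raw intensities.
    """
    if params is None:
        params = NormalizationParams()
    if raw.n_samples < 2:
        raise ValueError("normalization requires at least 2 samples")
    x = raw.values.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("raw intensities must be non-negative")

    def wrap(arr: np.ndarray) -> ExpressionMatrix:
        values = pd.DataFrame(arr, index=raw.values.index, columns=raw.values.columns)
        return ExpressionMatrix(values=values, symbols=raw.symbols.copy(), groups=raw.groups)

    logged = np.log2(np.maximum(x, params.floor))
    shifted = logged - np.percentile(logged, params.percentile, axis=0, keepdims=True)
    centred = shifted - np.median(shifted, axis=1, keepdims=True)
    if return_stages:
        return {"log2": wrap(logged), "shifted": wrap(shifted), "normalized": wrap(centred)}
    return wrap(centred)
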