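"""Modified MA-plot normalization of per-bin tag counts.

Sequencing depth and signal-to-noise differ between the two CLIP-seq
libraries, so raw per-bin log ratios are biased. Following the MA-plot
idea from two-channel microarray normalization, each bin's counts are
mapped to

    M = ln(x1 + c) - ln(x2 + c)        (log fold change)
    A = ln(x1 + c) + ln(x2 + c)        (log overall abundance)

with pseudocount c > 0, a straight line M = a + b*A is fitted by ordinary
least squares over bins where both raw counts exceed a cutoff (bins with
confident signal in both conditions, which mostly represent common
binding), and the fitted value is subtracted from every bin's raw M. The
residual, adjusted M, is the normalized differential-binding signal the
HMM consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NormalizationConfig:
    pseudocount_c: float = 1.0
    joint_count_cutoff: int = 5

    def __post_init__(self) -> None:
        if self.pseudocount_c <= 0:
            raise ValueError("pseudocount_c must be > 0 (guards the logarithm)")
        if self.joint_count_cutoff < 0:
            raise ValueError("joint_count_cutoff must be >= 0")


@dataclass
class NormalizationModel:
    """OLS fit M = a + b*A over the jointly high-count bins."""

    a: float
    b: float
    n_fit: int

    def predict(self, A: np.ndarray) -> np.ndarray:
        return self.a + self.b * np.asarray(A, dtype=float)


def compute_ma(x1, x2, c: float = 1.0):
    """(M, A) for counts x1, x2 with pseudocount c; natural logs.

    Accepts scalars or arrays.
    """
    l1 = np.log(np.asarray(x1, dtype=float) + c)
    l2 = np.log(np.asarray(x2, dtype=float) + c)
    return l1 - l2, l1 + l2


def add_ma_columns(bins: pd.DataFrame, config: NormalizationConfig) -> pd.DataFrame:
    """Fill M_raw and A for every bin (in place; returns the frame)."""
    M, A = compute_ma(bins["x1"].to_numpy(), bins["x2"].to_numpy(),
                      config.pseudocount_c)
    bins["M_raw"] = M
    bins["A"] = A
    return bins


def fit_normalization(bins: pd.DataFrame, config: NormalizationConfig) -> NormalizationModel:
    """Fit the MA regression on bins with x1 > cutoff and x2 > cutoff.

    The cutoff is strict on both counts. Raises if fewer than two
    qualifying bins exist or their A values are all identical, since the
    line is then undefined.
    """
    if "M_raw" not in bins:
        add_ma_columns(bins, config)
    cut = config.joint_count_cutoff
    mask = (bins["x1"] > cut) & (bins["x2"] > cut)
    sub = bins.loc[mask]
    if len(sub) < 2 or sub["A"].nunique() < 2:
        raise ValueError(
            f"only {len(sub)} bins qualify for the MA regression at "
            f"joint_count_cutoff={cut}; lower the cutoff"
        )
    res = stats.linregress(sub["A"].to_numpy(), sub["M_raw"].to_numpy())
    return NormalizationModel(a=float(res.intercept), b=float(res.slope),
                              n_fit=int(len(sub)))


def adjust_m(bins: pd.DataFrame, model: NormalizationModel) -> pd.DataFrame:
    """M_adj = M_raw - (a + b*A) for every bin in every cluster, including
    bins that did not enter the fit (in place; returns the frame)."""
    bins["M_adj"] = bins["M_raw"].to_numpy() - model.predict(bins["A"].to_numpy())
    return bins


def normalize_bins(bins: pd.DataFrame, config: NormalizationConfig
                   ) -> tuple[pd.DataFrame, NormalizationModel]:
    """Convenience: compute (M, A), fit the regression, adjust all bins."""
    add_ma_columns(bins, config)
    model = fit_normalization(bins, config)
    return adjust_m(bins, model), model
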