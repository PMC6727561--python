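"""Control-based normalization for digital counting panels.

The scheme mirrors the vendor default workflow: a per-lane positive-control
factor equalizes the geometric mean of the spike-in ladder across lanes; low
values are floored at a background threshold count (default 20); a
housekeeping content factor (geometric mean of housekeeping probes, computed
after positive-control scaling and thresholding) equalizes RNA content; the
result is log2-transformed and restricted to endogenous probes.

Out-of-range lanes are flagged, never dropped: positive factors outside
[0.3, 3] and housekeeping factors outside [0.1, 10] get QC flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_core import CountsExperiment

__all__ = [
    "NormalizationFactors",
    "NormalizedMatrix",
    "control_factors",
    "normalize_counts",
]

POS_FACTOR_RANGE = (0.3, 3.0)
HK_FACTOR_RANGE = (0.1, 10.0)


@dataclass
class NormalizationFactors:
    """Per-lane scaling factors and background estimates.

    ``background_lambda`` is the arithmetic mean of the lane's negative
    controls (used by differential expression as the additive background).
    """

    pos_factor: pd.Series
    hk_factor: pd.Series
    background_lambda: pd.Series
    threshold: int
    flags: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class NormalizedMatrix:
    """Lanes x endogenous-probes log2 expression with provenance."""

    data: pd.DataFrame
    factors: NormalizationFactors | None = None
    flags: dict[str, set[str]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


def _geomean_rows(mat: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-lane geometric mean; zeros are mapped to 1 before the log.

    Returns (geomean, had_zero) where had_zero marks lanes with any zero.
    """
    arr = mat.to_numpy(dtype=float)
    had_zero = (arr == 0).any(axis=1)
    safe = np.where(arr == 0, 1.0, arr)
    gm = np.exp(np.log(safe).mean(axis=1))
    return (pd.Series(gm, index=mat.index),
            pd.Series(had_zero, index=mat.index))


def control_factors(exp: CountsExperiment, threshold: int = 20,
                    hk_mean: str = "geometric") -> NormalizationFactors:
    """Compute positive-control and housekeeping factors plus background.

    pos_factor_j = mean-over-lanes(pos geomean) / pos geomean of lane j, so
    that after scaling every lane has the same positive-control geometric
    mean. The housekeeping factor is computed the same way on housekeeping
    counts after positive-control scaling and threshold flooring.
    ``hk_mean`` selects geometric (default) or arithmetic lane averaging for
    the housekeeping content factor.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    panel = exp.panel
    panel.require_controls()
    flags: dict[str, set[str]] = {sid: set() for sid in exp.sample_ids}

    pos = exp.counts[panel.positive_ctrl]
    pos_gm, pos_zero = _geomean_rows(pos)
    for sid in pos_gm.index[pos_zero]:
        flags[sid].add("zero_control")
    pos_factor = pos_gm.mean() / pos_gm

    scaled = exp.counts[panel.housekeeping].to_numpy(dtype=float) \
        * pos_factor.to_numpy()[:, None]
    scaled = np.maximum(scaled, float(threshold))
    hk = pd.DataFrame(scaled, index=exp.counts.index,
                      columns=panel.housekeeping)
    if hk_mean == "geometric":
        hk_gm, hk_zero = _geomean_rows(hk)
        for sid in hk_gm.index[hk_zero]:
            flags[sid].add("zero_control")
    elif hk_mean == "arithmetic":
        hk_gm = hk.mean(axis=1)
    else:
        raise ValueError(f"unknown hk_mean {hk_mean!r}")
    hk_factor = hk_gm.mean() / hk_gm

    lam = exp.counts[panel.negative_ctrl].mean(axis=1).astype(float)

    for sid in exp.sample_ids:
        if not (POS_FACTOR_RANGE[0] <= pos_factor[sid] <= POS_FACTOR_RANGE[1]):
            flags[sid].add("pos_factor_out_of_range")
        if not (HK_FACTOR_RANGE[0] <= hk_factor[sid] <= HK_FACTOR_RANGE[1]):
            flags[sid].add("hk_factor_out_of_range")

    return NormalizationFactors(
        pos_factor=pos_factor, hk_factor=hk_factor,
        background_lambda=lam, threshold=int(threshold), flags=flags,
    )


def normalize_counts(exp: CountsExperiment,
                     factors: NormalizationFactors) -> NormalizedMatrix:
    """Apply factors: pos scaling -> threshold floor -> hk scaling -> log2.

    Output is restricted to endogenous probes. Values below the threshold are
    SET TO the threshold (not subtracted), which keeps log2 finite.
    """
    if set(exp.sample_ids) != set(factors.pos_factor.index):
        raise ValueError("factor lane set does not match experiment lanes")
    endo = exp.panel.endogenous
    arr = exp.counts[endo].to_numpy(dtype=float)
    pos = factors.pos_factor.loc[exp.sample_ids].to_numpy()
    hk = factors.hk_factor.loc[exp.sample_ids].to_numpy()
    scaled = arr * pos[:, None]
    # floor at a tiny positive value even when threshold = 0 so log2 is finite
    scaled = np.maximum(scaled, max(float(factors.threshold), 1e-9))
    scaled = scaled * hk[:, None]
    data = pd.DataFrame(np.log2(scaled), index=exp.counts.index.copy(),
                        columns=endo)
    return NormalizedMatrix(data=data, factors=factors,
                            flags={k: set(v) for k, v in factors.flags.items()})


def normalize(exp: CountsExperiment, threshold: int = 20,
              hk_mean: str = "geometric") -> NormalizedMatrix:
    """Convenience: control_factors + normalize_counts in one call."""
    return normalize_counts(exp, control_factors(exp, threshold, hk_mean))
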