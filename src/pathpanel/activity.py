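"""Two-profile pathway-activity scoring.

Each signature carries a baseline profile (mean log2 expression of its genes
in GFP control lanes, mu0), an activated profile (overexpression lanes, mu1)
and a pooled SD per gene. A test sample's activity is the precision-weighted
projection of its expression onto the mu0 -> mu1 axis, clamped to [0, 1]:

    a* = clamp( sum_g w_g * d_g * (y_g - mu0_g) / s_g^2
                / sum_g w_g * d_g^2 / s_g^2 , 0, 1),  d_g = mu1_g - mu0_g

With adaptive gene selection off all weights are 1 (closed form). With it on,
weights are re-estimated per sample from a two-component responsibility: a
"consistent" component N(y; (1-a)mu0 + a*mu1, s^2) with prior 0.8 against a
wide baseline component N(y; mu0, (3s)^2), iterating weight and activity
updates to a fixed point. Down-weighting suppresses genes whose behavior in
the test sample is inconsistent with the training contrast.

Samples are scored independently, so results do not depend on cohort
composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_core import CountsExperiment
from .normalization import NormalizedMatrix, normalize
from .signature_design import Signature

__all__ = [
    "ReferenceProfiles",
    "ActivityScores",
    "fit_reference_profiles",
    "score_activity",
]

SIGMA_FLOOR = 0.1  # log2 units
UNINFORMATIVE_DELTA = 0.05
ADAPTIVE_PI = 0.8
ADAPTIVE_WIDE_SD_MULT = 3.0
ADAPTIVE_TOL = 1e-6
ADAPTIVE_MAX_ITER = 100


@dataclass
class ReferenceProfiles:
    """Per-gene baseline/activated means and pooled SD for one signature."""

    pathway: str
    table: pd.DataFrame  # index: gene; columns: mu0, mu1, sigma
    uninformative: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.table["sigma"] < SIGMA_FLOOR - 1e-12).any():
            raise ValueError("sigma below floor in reference profiles")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


@dataclass
class ActivityScores:
    """Sample x pathway activity matrix plus scoring metadata."""

    scores: pd.DataFrame
    adaptive: bool
    weights: dict[str, pd.DataFrame] | None = None  # pathway -> sample x gene
    iterations: dict[str, pd.Series] | None = None
    flags: dict[str, set[str]] = field(default_factory=dict)


def fit_reference_profiles(training: CountsExperiment, signature: Signature,
                           threshold: int = 20) -> ReferenceProfiles:
    """Estimate mu0/mu1/sigma from a GFP-vs-overexpression experiment.

    The training experiment is normalized internally. Genes with
    |mu1 - mu0| < 0.05 are flagged uninformative but retained.
    """
    genes = signature.symbols
    missing = sorted(set(genes) - set(training.panel.endogenous))
    if missing:
        raise ValueError(f"signature genes absent from panel: {missing}")
    groups = training.groups
    gfp = groups.index[groups == "GFP"]
    act = groups.index[groups == signature.pathway]
    if len(gfp) < 2 or len(act) < 2:
        raise ValueError("need >=2 lanes in each training arm")
    norm = normalize(training, threshold=threshold).data[genes]
    y0, y1 = norm.loc[gfp], norm.loc[act]
    mu0, mu1 = y0.mean(axis=0), y1.mean(axis=0)
    pooled_var = ((y0.var(axis=0, ddof=1) * (len(gfp) - 1)
                   + y1.var(axis=0, ddof=1) * (len(act) - 1))
                  / (len(gfp) + len(act) - 2))
    sigma = np.sqrt(pooled_var).clip(lower=SIGMA_FLOOR).fillna(SIGMA_FLOOR)
    table = pd.DataFrame({"mu0": mu0, "mu1": mu1, "sigma": sigma})
    uninf = list(table.index[(table["mu1"] - table["mu0"]).abs()
                             < UNINFORMATIVE_DELTA])
    return ReferenceProfiles(pathway=signature.pathway, table=table,
                             uninformative=uninf)


def _closed_form(y: np.ndarray, mu0: np.ndarray, delta: np.ndarray,
                 sigma2: np.ndarray, w: np.ndarray) -> float | None:
    denom = float(np.sum(w * delta**2 / sigma2))
    if denom == 0.0:
        return None
    num = float(np.sum(w * delta * (y - mu0) / sigma2))
    return float(np.clip(num / denom, 0.0, 1.0))


def _norm_pdf(x: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    z = (x - mean) / sd
    return np.exp(-0.5 * z * z) / (sd * np.sqrt(2.0 * np.pi))


def score_activity(profiles: ReferenceProfiles, samples: NormalizedMatrix,
                   adaptive: bool = False) -> ActivityScores:
    """Score each sample against one signature's reference profiles.

    Missing profile genes are dropped with a warning when at least 80% of the
    signature remains; otherwise an error is raised. A degenerate signature
    (zero total weight x effect) yields a = 0.5 with flag
    ``degenerate_signature``.
    """
    present = [g for g in profiles.genes if g in samples.data.columns]
    frac = len(present) / len(profiles.genes)
    if frac < 0.8:
        raise ValueError(
            f"only {len(present)}/{len(profiles.genes)} signature genes "
            "present in sample matrix (<80%)")
    if len(present) < len(profiles.genes):
        dropped = sorted(set(profiles.genes) - set(present))
        warnings.warn(f"dropping absent signature genes: {dropped}",
                      stacklevel=2)
    tab = profiles.table.loc[present]
    mu0 = tab["mu0"].to_numpy()
    mu1 = tab["mu1"].to_numpy()
    sigma = tab["sigma"].to_numpy()
    delta = mu1 - mu0
    sigma2 = sigma**2

    scores: dict[str, float] = {}
    weights = pd.DataFrame(1.0, index=samples.data.index, columns=present)
    iters = pd.Series(0, index=samples.data.index, dtype=int)
    flags: dict[str, set[str]] = {}

    for sid in samples.data.index:
        y = samples.data.loc[sid, present].to_numpy(dtype=float)
        w = np.ones_like(delta)
        a = _closed_form(y, mu0, delta, sigma2, w)
        if a is None:
            scores[sid] = 0.5
            flags.setdefault(sid, set()).add("degenerate_signature")
            continue
        n_iter = 0
        if adaptive:
            for n_iter in range(1, ADAPTIVE_MAX_ITER + 1):
                mixed = (1.0 - a) * mu0 + a * mu1
                num = ADAPTIVE_PI * _norm_pdf(y, mixed, sigma)
                den = num + (1.0 - ADAPTIVE_PI) * _norm_pdf(
                    y, mu0, ADAPTIVE_WIDE_SD_MULT * sigma)
                w = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
                a_new = _closed_form(y, mu0, delta, sigma2, w)
                if a_new is None:
                    a = 0.5
                    flags.setdefault(sid, set()).add("degenerate_signature")
                    break
                if abs(a_new - a) < ADAPTIVE_TOL:
                    a = a_new
                    break
                a = a_new
        scores[sid] = a
        weights.loc[sid] = w
        iters[sid] = n_iter

    frame = pd.DataFrame({profiles.pathway: pd.Series(scores)})
    frame = frame.loc[samples.data.index]
    return ActivityScores(
        scores=frame, adaptive=adaptive,
        weights={profiles.pathway: weights} if adaptive else None,
        iterations={profiles.pathway: iters} if adaptive else None,
        flags=flags,
    )


def score_many(profiles_list: list[ReferenceProfiles],
               samples: NormalizedMatrix,
               adaptive: bool | dict[str, bool] = False) -> ActivityScores:
    """Score several signatures; ``adaptive`` may be a per-pathway mapping."""
    cols = {}
    flags: dict[str, set[str]] = {}
    any_adaptive = False
    for prof in profiles_list:
        ad = (adaptive.get(prof.pathway, False)
              if isinstance(adaptive, dict) else adaptive)
        any_adaptive = any_adaptive or ad
        res = score_activity(prof, samples, adaptive=ad)
        cols[prof.pathway] = res.scores[prof.pathway]
        for sid, f in res.flags.items():
            flags.setdefault(sid, set()).update(f)
    return ActivityScores(scores=pd.DataFrame(cols), adaptive=any_adaptive,
                          flags=flags)
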