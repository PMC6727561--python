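"""Synthetic data generator for every input class of the pipeline.

Emulates, with known ground truth, the statistical structure of a custom
digital counting assay study: a probe panel with control classes,
overexpression-vs-GFP training contrasts, patient cohorts with graded latent
pathway activity, proteomics readouts linearly related to activity, drug EC50
negatively rank-correlated with activity, and exponential survival times
whose hazard depends on activity.

Count model: endogenous counts are negative binomial with mean
``d_j * 2**(mu_g + a * delta_g) + lambda`` and variance ``m + phi * m**2``
(phi = 0 degenerates to Poisson); ``d_j`` is a lognormal lane size factor,
``lambda`` the background mean. Positive controls are Poisson with mean
proportional to the nominal concentration; negative controls Poisson(lambda).

Random streams are split per component (panel / counts / survival /
ancillary) from one seed, so adding samples to one component does not
reshuffle draws in another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .cohort_stats import ClinicalTable
from .panel_core import CountsExperiment, Panel, Probe, ProbeClass

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "AncillaryTables",
    "simulate_panel",
    "simulate_overexpression_experiment",
    "simulate_cohort",
    "default_ground_truth",
]

#: counts per fM for positive-control spike-ins
POS_CTRL_COUNTS_PER_FM = 200.0


@dataclass
class SimulationConfig:
    """Assay-level generator parameters.

    Defaults model a 336-query-gene + 9-housekeeping panel with the standard
    six-step positive-control ladder, moderate lane-to-lane size variation
    (sd 0.15 on the natural-log scale), NB dispersion 0.05 and background
    mean 5 counts.
    """

    n_endogenous: int = 336
    n_housekeeping: int = 9
    pos_ctrl_concs: tuple[float, ...] = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)
    neg_ctrl_count: int = 8
    baseline_log2_mean_range: tuple[float, float] = (5.0, 11.0)
    lane_size_factor_sd: float = 0.15
    nb_dispersion: float = 0.05
    background_mean: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.background_mean <= 0:
            raise ValueError("background_mean must be > 0")
        lo, hi = self.baseline_log2_mean_range
        if hi < lo:
            raise ValueError("baseline_log2_mean_range must be (lo, hi)")


@dataclass
class GroundTruth:
    """Latent quantities the analysis tries to recover.

    ``signature_genes`` maps pathway -> {gene -> true log2 effect};
    ``sample_activity`` (optional) maps sample -> pathway -> activity in
    [0, 1]; ``survival_hazard_coef`` is the log-hazard slope on activity.
    """

    signature_genes: dict[str, dict[str, float]]
    sample_activity: dict[str, dict[str, float]] | None = None
    survival_hazard_coef: float = 2.0
    proteomics_noise_sd: float = 0.1
    ec50_rank_rho: float = -0.8
    ec50_pathway: str | None = None
    survival_pathway: str | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.ec50_rank_rho <= 0.0:
            raise ValueError("ec50_rank_rho must be in [-1, 0]")
        if self.sample_activity is not None:
            for s, d in self.sample_activity.items():
                for p, a in d.items():
                    if not 0.0 <= a <= 1.0:
                        raise ValueError(
                            f"activity {a} for {s}/{p} outside [0, 1]")

    @property
    def pathways(self) -> list[str]:
        return sorted(self.signature_genes)

    def pathway_for(self, role: str) -> str:
        chosen = getattr(self, f"{role}_pathway")
        return chosen if chosen is not None else self.pathways[0]

    def check_panel(self, panel: Panel) -> None:
        endo = set(panel.endogenous)
        for pw, genes in self.signature_genes.items():
            missing = sorted(set(genes) - endo)
            if missing:
                raise ValueError(
                    f"signature {pw!r} genes not on panel: {missing}")


@dataclass
class AncillaryTables:
    """Ground-truth-linked side tables generated with a cohort."""

    true_activity: pd.DataFrame  # sample x pathway
    proteomics: pd.DataFrame  # sample x pathway
    ec50: pd.Series  # per sample


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_panel(config: SimulationConfig) -> Panel:
    """Build a synthetic panel with the configured class counts."""
    if config.n_housekeeping < 1:
        raise ValueError("panel needs >=1 housekeeping probe for normalization")
    if len(set(config.pos_ctrl_concs)) != len(config.pos_ctrl_concs):
        raise ValueError("pos_ctrl_concs must be distinct")
    probes = [Probe(f"GENE{i + 1:04d}", ProbeClass.ENDOGENOUS)
              for i in range(config.n_endogenous)]
    probes += [Probe(f"HK{i + 1:02d}", ProbeClass.HOUSEKEEPING)
               for i in range(config.n_housekeeping)]
    probes += [Probe(f"POS_{chr(65 + i)}", ProbeClass.POSITIVE_CTRL, conc)
               for i, conc in enumerate(config.pos_ctrl_concs)]
    probes += [Probe(f"NEG_{chr(65 + i)}", ProbeClass.NEGATIVE_CTRL)
               for i in range(config.neg_ctrl_count)]
    return Panel(probes=probes, name="synthetic_panel")


def _baseline_means(panel: Panel, config: SimulationConfig) -> pd.Series:
    """Per-gene baseline log2 means, deterministic in the config seed."""
    rng = _streams(config.seed, 4)[0]
    lo, hi = config.baseline_log2_mean_range
    names = panel.endogenous + panel.housekeeping
    return pd.Series(rng.uniform(lo, hi, size=len(names)), index=names)


def _draw_nb(rng: np.random.Generator, mean: np.ndarray,
             phi: float) -> np.ndarray:
    """NB draw with variance mean + phi*mean^2; Poisson when phi = 0."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    # Gamma-Poisson mixture keeps the parameterization explicit
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def _simulate_counts(panel: Panel, config: SimulationConfig,
                     activity: pd.DataFrame, truth: GroundTruth,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Counts for lanes whose per-pathway activities are given.

    ``activity`` is sample x pathway in [0, 1]; gene means are shifted by
    ``sum_p a_sp * delta_g(p)`` on the log2 scale.
    """
    base = _baseline_means(panel, config)
    samples = list(activity.index)
    n = len(samples)
    d = np.exp(rng.normal(0.0, config.lane_size_factor_sd, size=n))

    gene_names = panel.endogenous + panel.housekeeping
    shift = pd.DataFrame(0.0, index=samples, columns=gene_names)
    for pw in activity.columns:
        for g, delta in truth.signature_genes.get(pw, {}).items():
            shift[g] = shift[g] + activity[pw].to_numpy() * delta

    mu = 2.0 ** (base.to_numpy()[None, :] + shift.to_numpy())
    mean = d[:, None] * mu + config.background_mean
    counts = _draw_nb(rng, mean, config.nb_dispersion)

    pos_conc = panel.positive_concs
    pos_mean = d[:, None] * POS_CTRL_COUNTS_PER_FM * pos_conc.to_numpy()[None, :]
    pos_counts = rng.poisson(pos_mean)
    neg_counts = rng.poisson(config.background_mean,
                             size=(n, len(panel.negative_ctrl)))

    out = pd.DataFrame(
        np.hstack([counts, pos_counts, neg_counts]).astype(np.int64),
        index=pd.Index(samples, name="sample_id"),
        columns=gene_names + panel.positive_ctrl + panel.negative_ctrl,
    )
    return out[panel.probe_names]


def simulate_overexpression_experiment(
        panel: Panel, pathway: str, n_control: int, n_active: int,
        truth: GroundTruth, config: SimulationConfig) -> CountsExperiment:
    """GFP-control vs pathway-overexpression training experiment.

    Active lanes get the full signature effect (activity 1), GFP lanes
    activity 0. Group labels are "GFP" and the pathway name.
    """
    if pathway not in truth.signature_genes:
        raise ValueError(f"pathway {pathway!r} not in ground truth")
    if n_control < 2 or n_active < 2:
        raise ValueError("need >=2 lanes per arm for reference profiles")
    truth.check_panel(panel)
    rng = _streams(config.seed, 4)[1]
    samples = [f"GFP_{i + 1}" for i in range(n_control)] + \
              [f"{pathway}_{i + 1}" for i in range(n_active)]
    activity = pd.DataFrame(
        {pathway: [0.0] * n_control + [1.0] * n_active}, index=samples)
    counts = _simulate_counts(panel, config, activity, truth, rng)
    lanes = pd.DataFrame({
        "sample_id": samples,
        "group": ["GFP"] * n_control + [pathway] * n_active,
    })
    return CountsExperiment(panel=panel, lanes=lanes, counts=counts)


def _solve_ec50_tau(activity: np.ndarray, target_rho: float,
                    noise: np.ndarray) -> float:
    """Bisection on the noise scale tau so Spearman(a, -a + tau*noise)
    is close to target_rho (within 0.05 where attainable)."""
    def rho(tau: float) -> float:
        z = -activity + tau * noise
        r = spearmanr(activity, z).statistic
        return 0.0 if np.isnan(r) else float(r)

    if target_rho <= -0.999:
        return 0.0
    lo, hi = 0.0, 64.0
    # rho(tau) increases from about -1 toward 0 as tau grows
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if rho(mid) < target_rho:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(panel: Panel, truth: GroundTruth, n_samples: int,
                    subtype_labels: list[str], config: SimulationConfig,
                    ) -> tuple[CountsExperiment, ClinicalTable, AncillaryTables]:
    """Patient-like cohort with planted activity, outcomes and side tables.

    Returns (counts experiment, clinical table, ancillary tables). The
    clinical table has columns sample_id, subtype, rfs_months, rfs_event,
    os_months, os_event. Survival times are exponential with hazard
    ``h0 * exp(gamma * a_s)`` on the designated survival pathway, censored
    by an independent Uniform(0, 1.5 * median survival) time.
    """
    if n_samples < 4:
        raise ValueError("cohort needs >= 4 samples")
    if not subtype_labels:
        raise ValueError("at least one subtype label required")
    if any(not isinstance(s, str) or not s for s in subtype_labels):
        raise ValueError(f"unknown subtype label in {subtype_labels!r}")
    truth.check_panel(panel)
    rng_counts, rng_surv, rng_anc = _streams(config.seed, 4)[1:4]

    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    pathways = truth.pathways
    if truth.sample_activity is not None:
        missing = [s for s in samples if s not in truth.sample_activity]
        if missing:
            raise ValueError(f"sample_activity missing samples: {missing}")
        activity = pd.DataFrame(
            [[truth.sample_activity[s][p] for p in pathways]
             for s in samples],
            index=samples, columns=pathways)
    else:
        activity = pd.DataFrame(
            rng_anc.uniform(0.0, 1.0, size=(n_samples, len(pathways))),
            index=samples, columns=pathways)

    counts = _simulate_counts(panel, config, activity, truth, rng_counts)
    subtype = [subtype_labels[i % len(subtype_labels)]
               for i in range(n_samples)]

    gamma = truth.survival_hazard_coef
    a_surv = activity[truth.pathway_for("survival")].to_numpy()
    clin = {"sample_id": samples, "subtype": subtype}
    for endpoint, h0 in (("rfs", 1.0 / 24.0), ("os", 1.0 / 36.0)):
        hazard = h0 * np.exp(gamma * a_surv)
        t = rng_surv.exponential(1.0 / hazard)
        c = rng_surv.uniform(0.0, 1.5 * np.median(t), size=n_samples)
        clin[f"{endpoint}_months"] = np.minimum(t, c)
        clin[f"{endpoint}_event"] = (t <= c).astype(int)
    clinical = ClinicalTable(data=pd.DataFrame(clin))

    prot = activity + rng_anc.normal(
        0.0, truth.proteomics_noise_sd, size=activity.shape)
    a_ec = activity[truth.pathway_for("ec50")].to_numpy()
    noise = rng_anc.normal(0.0, 1.0, size=n_samples)
    tau = _solve_ec50_tau(a_ec, truth.ec50_rank_rho, noise)
    z = -a_ec + tau * noise
    # rank-remap onto a log-spaced concentration scale (uM)
    ranks = np.argsort(np.argsort(z))
    scale = np.logspace(-2, 1, n_samples)
    ec50 = pd.Series(scale[ranks], index=samples, name="ec50")

    anc = AncillaryTables(true_activity=activity, proteomics=prot, ec50=ec50)
    lanes = pd.DataFrame({"sample_id": samples, "group": subtype})
    exp = CountsExperiment(panel=panel, lanes=lanes, counts=counts)
    return exp, clinical, anc


def default_ground_truth(panel: Panel, pathways: list[str] | None = None,
                         genes_per_pathway: int = 30, effect: float = 2.0,
                         **kwargs) -> GroundTruth:
    """Convenience truth: disjoint signatures of equal size and effect."""
    if pathways is None:
        pathways = ["PW1"]
    endo = panel.endogenous
    need = genes_per_pathway * len(pathways)
    if need > len(endo):
        raise ValueError("panel too small for requested signatures")
    sig: dict[str, dict[str, float]] = {}
    for i, pw in enumerate(pathways):
        block = endo[i * genes_per_pathway:(i + 1) * genes_per_pathway]
        sig[pw] = {g: effect for g in block}
    return GroundTruth(signature_genes=sig, **kwargs)
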