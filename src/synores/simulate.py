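"""Ground-truthed synthetic cohorts for end-to-end testing.

The generator emulates the structure of a three-arm biologic trial with
baseline synovial RNA-Seq: negative-binomial counts with a mean-dispersion
trend ``alpha(mu) = a1/mu + a0``, per-sample library-size factors,
arm-specific response rates (defaults 57% etanercept, 74% tocilizumab,
61% rituximab), response signal carried by a chosen set of informative
genes (additive log2 fold change in responders) plus clinical covariates
through a logistic link, coherent DAS28-ESR endpoints (response iff
DAS28-ESR < 3.2), latent molecular cluster structure, optional muscle
contamination in a sample subset, and per-gene linear calibration truth
for simulating paired hybridisation-count (nCounter) runs.

Every random draw flows from a single seed, so outputs are byte-identical
across runs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .containers import ARMS, GeneCountMatrix, RESPONSE_DAS28_CUTOFF, VSTMatrix
from .counts import MUSCLE_GENES, transform_clinical
from .ncounter import LOG_OFFSET, NCounterRun

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_ncounter_run",
    "permute_response",
]

#: Printed arm response rates the defaults reproduce.
DEFAULT_ARMS = (("etanercept", 0.57), ("tocilizumab", 0.74), ("rituximab", 0.61))


@dataclass
class SimulationConfig:
    """Cohort-level generative parameters.

    ``clinical_effects`` maps transformed covariate names (e.g. ``logCRP``)
    to logistic-regression coefficients on the response; ``dispersion_trend``
    is ``(a0, a1)`` of ``alpha(mu) = a1/mu + a0`` with ``a0 > 0``.
    """

    n_samples: int = 120
    n_genes: int = 1000
    arms: tuple = DEFAULT_ARMS
    n_informative_genes: int = 40
    effect_size_log2fc: float = 1.0
    signal_mode: str = "latent"
    dispersion_trend: tuple[float, float] = (0.05, 2.0)
    library_size_range: tuple[float, float] = (0.5, 2.0)
    clinical_effects: dict = field(default_factory=lambda: {"logCRP": -0.4})
    latent_effect: float = 1.9
    muscle_contamination_fraction: float = 0.0
    muscle_log2_shift: float = 5.0
    n_clusters: int = 3
    cluster_genes_per_block: int = 0
    cluster_log2_shift: float = 1.5
    baseline_meanlog: float = 4.0
    baseline_sdlog: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for arm, rate in self.arms:
            if not 0.0 < rate < 1.0:
                raise ValueError(f"response rate for {arm} must be in (0, 1)")
        if self.n_informative_genes > self.n_genes:
            raise ValueError("n_informative_genes exceeds n_genes")
        a0, a1 = self.dispersion_trend
        if a0 <= 0 or a1 < 0:
            raise ValueError("dispersion trend needs a0 > 0 and a1 >= 0")
        lo, hi = self.library_size_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("library sizes must be positive with min <= max")
        if not 0.0 <= self.muscle_contamination_fraction <= 1.0:
            raise ValueError("muscle_contamination_fraction must be in [0, 1]")
        if self.signal_mode not in ("latent", "group"):
            raise ValueError("signal_mode must be 'latent' or 'group'")


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would estimate."""

    informative_genes: dict[str, list[str]]  # per arm
    true_log2fc: pd.Series  # per gene (responder shift within its arm)
    response: pd.Series  # bool per sample
    das28: pd.Series
    calibration_b0: pd.Series
    calibration_b1: pd.Series
    cluster_labels: pd.Series
    contaminated_samples: list[str]
    size_factors: pd.Series
    latent_severity: pd.DataFrame | None = None  # samples x arms


def _nb_draw(rng, mu: np.ndarray, a0: float, a1: float) -> np.ndarray:
    """NB counts with per-entry dispersion alpha(mu) = a1/mu + a0."""
    mu = np.maximum(mu, 1e-8)
    alpha = a1 / mu + a0
    # gamma-Poisson mixture: shape 1/alpha, scale alpha*mu
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def _calibrate_intercept(linear: np.ndarray, rate: float) -> float:
    """Intercept making mean responder probability equal the target rate."""
    f = lambda b0: expit(b0 + linear).mean() - rate  # noqa: E731
    lo, hi = -30.0, 30.0
    return float(optimize.brentq(f, lo, hi))


def simulate_cohort(config: SimulationConfig):
    """Generate (GeneCountMatrix, clinical table, GroundTruth).

    Counts are NB with mean ``q_g * s_s * fold_gs``; the fold of the
    informative genes carries the response signal (latent-severity scaled
    by default, fixed responder shift in "group" mode; see the fold-change
    block) plus cluster and contamination shifts. Response labels come
    from a logistic model on latent severity and clinical covariates whose
    intercept is solved per arm so the expected response rate equals the
    configured one; DAS28-ESR is drawn from truncated normals on either
    side of 3.2 so the binary dichotomy is exact.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, G = cfg.n_samples, cfg.n_genes
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    gene_ids = [f"G{i + 1:05d}" for i in range(G)]
    if cfg.muscle_contamination_fraction > 0:
        if G < len(MUSCLE_GENES):
            raise ValueError("need at least 17 genes to carry the muscle markers")
        for i, g in enumerate(MUSCLE_GENES):
            gene_ids[G - len(MUSCLE_GENES) + i] = g

    # per-arm assignment, proportional sizes
    arm_names = [a for a, _ in cfg.arms]
    arm_of = np.array([arm_names[i % len(arm_names)] for i in range(n)])
    rng.shuffle(arm_of)

    # baseline gene means on the count scale (log-normal across genes)
    q = rng.lognormal(mean=cfg.baseline_meanlog, sigma=cfg.baseline_sdlog, size=G)

    # informative genes per arm (disjoint, never the muscle markers)
    candidates = [g for g in gene_ids if g not in MUSCLE_GENES]
    rng.shuffle(candidates)
    informative: dict[str, list[str]] = {}
    pos = 0
    for arm in arm_names:
        informative[arm] = sorted(candidates[pos : pos + cfg.n_informative_genes])
        pos += cfg.n_informative_genes
        if pos > len(candidates):
            raise ValueError("not enough genes for disjoint informative sets")

    # clinical covariates (raw scale)
    clinical = pd.DataFrame(
        {
            "tjc28": rng.binomial(28, 0.35, size=n),
            "sjc28": rng.binomial(28, 0.25, size=n),
            "vas": np.round(np.clip(rng.normal(60, 18, size=n), 0, 100), 0),
            "rf_titre": np.round(rng.lognormal(3.0, 1.2, size=n), 1),
            "ccp_titre": np.round(rng.lognormal(3.5, 1.5, size=n), 1),
            "esr": np.round(np.clip(rng.gamma(2.5, 12.0, size=n), 1, None), 0),
            "crp": np.round(rng.gamma(1.5, 8.0, size=n), 1),
            "arm": arm_of,
        },
        index=sample_ids,
    )

    # per-arm latent severity drives the arm's informative genes and (with
    # the clinical covariates) the response label within that arm
    U = rng.normal(0.0, 1.0, size=(n, len(arm_names)))
    transformed = transform_clinical(clinical)
    clin_lin = np.zeros(n)
    for cov, coef in cfg.clinical_effects.items():
        if cov not in transformed.columns:
            raise ValueError(f"unknown clinical covariate {cov!r} in clinical_effects")
        v = transformed[cov].to_numpy()
        clin_lin = clin_lin + coef * (v - v.mean())
    response = np.zeros(n, dtype=bool)
    for a, (arm, rate) in enumerate(cfg.arms):
        mask = arm_of == arm
        lin = cfg.latent_effect * U[mask, a] + clin_lin[mask]
        b0 = _calibrate_intercept(lin, rate)
        response[mask] = rng.random(mask.sum()) < expit(b0 + lin)

    # DAS28-ESR coherent with the binary response
    das28 = np.empty(n)
    resp_dist = stats.truncnorm(
        (0.5 - 2.4) / 0.8, (RESPONSE_DAS28_CUTOFF - 1e-9 - 2.4) / 0.8, loc=2.4, scale=0.8
    )
    nonresp_dist = stats.truncnorm(
        (RESPONSE_DAS28_CUTOFF - 4.8) / 1.2, (9.4 - 4.8) / 1.2, loc=4.8, scale=1.2
    )
    das28[response] = resp_dist.rvs(size=int(response.sum()), random_state=rng)
    das28[~response] = nonresp_dist.rvs(size=int((~response).sum()), random_state=rng)
    das28 = np.round(das28, 2)
    # rounding must not cross the dichotomy
    das28[response] = np.minimum(das28[response], RESPONSE_DAS28_CUTOFF - 0.01)
    das28[~response] = np.maximum(das28[~response], RESPONSE_DAS28_CUTOFF)
    clinical["das28_esr_wk16"] = das28
    clinical["response_binary"] = response

    # fold-change matrix: in "latent" mode the informative genes of arm a
    # shift with every sample's latent severity for that arm (response is
    # then a noisy readout of the genes); in "group" mode responders of
    # the arm get a fixed additive log2 shift (exact group log2FC truth).
    log2fold = np.zeros((G, n))
    true_lfc = pd.Series(0.0, index=gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for a, arm in enumerate(arm_names):
        rows = [gene_pos[g] for g in informative[arm]]
        if cfg.signal_mode == "latent":
            log2fold[rows, :] += cfg.effect_size_log2fc * U[:, a][None, :]
        else:
            cols = np.flatnonzero((arm_of == arm) & response)
            log2fold[np.ix_(rows, cols)] += cfg.effect_size_log2fc
        true_lfc.iloc[rows] = cfg.effect_size_log2fc

    # latent molecular clusters shift gene blocks
    cluster = rng.integers(0, cfg.n_clusters, size=n)
    if cfg.cluster_genes_per_block > 0:
        free = candidates[pos:]
        for c in range(cfg.n_clusters):
            block = free[c * cfg.cluster_genes_per_block : (c + 1) * cfg.cluster_genes_per_block]
            rows = [gene_pos[g] for g in block]
            cols = np.flatnonzero(cluster == c)
            log2fold[np.ix_(rows, cols)] += cfg.cluster_log2_shift

    # muscle contamination spikes the muscle markers in a sample subset
    n_cont = int(round(cfg.muscle_contamination_fraction * n))
    cont_idx = rng.choice(n, size=n_cont, replace=False) if n_cont else np.array([], dtype=int)
    if n_cont:
        rows = [gene_pos[g] for g in MUSCLE_GENES]
        log2fold[np.ix_(rows, cont_idx)] += cfg.muscle_log2_shift

    lo, hi = cfg.library_size_range
    s = rng.uniform(lo, hi, size=n)
    s = s / np.exp(np.log(s).mean())  # geometric mean 1
    mu = q[:, None] * s[None, :] * 2.0**log2fold
    a0, a1 = cfg.dispersion_trend
    counts = _nb_draw(rng, mu, a0, a1)
    count_matrix = GeneCountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))

    truth = GroundTruth(
        informative_genes=informative,
        true_log2fc=true_lfc,
        response=pd.Series(response, index=sample_ids, name="response"),
        das28=pd.Series(das28, index=sample_ids, name="das28_esr_wk16"),
        calibration_b0=pd.Series(rng.normal(0.0, 0.5, size=G), index=gene_ids),
        calibration_b1=pd.Series(
            np.clip(rng.normal(1.0, 0.1, size=G), 0.5, None), index=gene_ids
        ),
        cluster_labels=pd.Series(cluster, index=sample_ids, name="cluster"),
        contaminated_samples=[sample_ids[i] for i in cont_idx],
        size_factors=pd.Series(s, index=sample_ids, name="true_size_factor"),
        latent_severity=pd.DataFrame(U, index=sample_ids, columns=arm_names),
    )
    return count_matrix, clinical, truth


def simulate_ncounter_run(
    expression: VSTMatrix | pd.DataFrame,
    truth: GroundTruth,
    noise_sd: float = 0.1,
    lane_factors=None,
    seed: int = 0,
    n_hk: int = 6,
    n_pos: int = 6,
    n_neg: int = 6,
) -> NCounterRun:
    """Simulate a hybridisation-count run from latent VST expression.

    Inverts the stored calibration truth per gene: the latent log count is
    ``(VST - b0) / b1`` plus Gaussian noise, exponentiated (undoing the
    ``+offset`` convention of the bridge), scaled by the lane factor and
    rounded to a non-negative integer. Housekeeping probes (stable high
    expressors), positive controls (known concentration ladder) and
    negative controls (near-zero Poisson) are appended.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    expr = expression.values if isinstance(expression, VSTMatrix) else expression
    missing = [g for g in expr.index if g not in truth.calibration_b0.index]
    if missing:
        raise KeyError(f"genes lack stored calibration truth: {missing[:5]}")
    b0 = truth.calibration_b0.loc[expr.index].to_numpy()
    b1 = truth.calibration_b1.loc[expr.index].to_numpy()
    zero_slope = expr.index[b1 == 0].tolist()
    if zero_slope:
        raise ValueError(f"zero calibration slope for gene(s): {zero_slope[:5]}")
    n_lanes = expr.shape[1]
    if lane_factors is None:
        lane_factors = np.ones(n_lanes)
    lane_factors = np.asarray(lane_factors, dtype=float)
    if lane_factors.shape != (n_lanes,) or (lane_factors <= 0).any():
        raise ValueError("lane_factors must be positive, one per sample")
    rng = np.random.default_rng(seed)
    logc = (expr.to_numpy(dtype=float) - b0[:, None]) / b1[:, None]
    if noise_sd > 0:
        logc = logc + rng.normal(0.0, noise_sd, size=logc.shape)
    endo = np.maximum(np.exp(logc) - LOG_OFFSET, 0.0) * lane_factors[None, :]
    endo = np.round(endo).astype(np.int64)

    hk_base = rng.uniform(8.0, 10.0, size=n_hk)  # stable high expressors (log scale)
    hk = np.round(np.exp(hk_base)[:, None] * lane_factors[None, :]).astype(np.int64)
    pos_conc = 2.0 ** np.arange(n_pos)  # known concentration ladder
    pos = np.round(200.0 * pos_conc[:, None] * lane_factors[None, :]).astype(np.int64)
    neg = rng.poisson(2.0, size=(n_neg, n_lanes)).astype(np.int64)

    names = (
        list(expr.index)
        + [f"HK{i + 1}" for i in range(n_hk)]
        + [f"POS_{chr(65 + i)}" for i in range(n_pos)]
        + [f"NEG_{chr(65 + i)}" for i in range(n_neg)]
    )
    classes = (
        ["Endogenous"] * expr.shape[0]
        + ["Housekeeping"] * n_hk
        + ["Positive"] * n_pos
        + ["Negative"] * n_neg
    )
    counts = pd.DataFrame(
        np.vstack([endo, hk, pos, neg]), index=names, columns=expr.columns
    )
    probe_info = pd.DataFrame(
        {"CodeClass": classes, "Accession": ["SYN_" + n for n in names]}, index=names
    )
    lane_attrs = pd.DataFrame(
        {"CartridgeID": ["CART1"] * n_lanes}, index=list(expr.columns)
    )
    return NCounterRun(counts, probe_info, lane_attrs)


def permute_response(clinical: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Null cohort: permute response within each treatment arm.

    The DAS28-ESR endpoint is carried along with its label so the
    label/score coherence invariant (response iff DAS28-ESR < 3.2) is
    preserved; every other column is untouched.
    """
    if "response_binary" not in clinical.columns:
        raise ValueError("clinical table lacks a response_binary column")
    rng = np.random.default_rng(seed)
    out = clinical.copy()
    groups = out["arm"] if "arm" in out.columns else pd.Series("all", index=out.index)
    move = ["response_binary"] + (
        ["das28_esr_wk16"] if "das28_esr_wk16" in out.columns else []
    )
    for arm in groups.unique():
        idx = out.index[groups == arm]
        perm = rng.permutation(len(idx))
        out.loc[idx, move] = out.loc[idx[perm], move].to_numpy()
    out["response_binary"] = out["response_binary"].astype(bool)
    return out
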