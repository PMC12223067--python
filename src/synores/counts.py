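"""Count normalisation, variance-stabilising transformation and filters.

The model throughout is a negative-binomial count ``n_gs`` for gene ``g``
in sample ``s`` with mean ``mu_gs = q_g * s_s`` and dispersion following the
parametric trend ``alpha(mu) = a1/mu + a0``, giving variance
``v(mu) = mu * (1 + a1) + a0 * mu**2``.

The VST is the closed-form antiderivative of ``1/sqrt(v(mu))`` rescaled to
log2 units, so that ``vst(q) - log2(q) -> 0`` as ``q -> inf``:

    vst(q) = 2 * log2( sqrt(a0*q) + sqrt(a0*q + 1 + a1) ) - log2(4*a0)

Expression filters implement the three rules used at different pipeline
stages: a low-expression filter ahead of differential expression, an
edgeR-filterByExpr-style rule ahead of clustering, and a mean-VST floor for
machine-learning features.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GeneCountMatrix, VSTMatrix

__all__ = [
    "MUSCLE_GENES",
    "size_factors",
    "fit_dispersion_trend",
    "vst_transform",
    "filter_genes",
    "transform_clinical",
    "muscle_pc1",
]

#: Skeletal-muscle marker genes used to build the tissue-contamination
#: covariate (supervised PC1). Biopsies can carry muscle tissue; these
#: genes are highly specific to it.
MUSCLE_GENES = (
    "ACTA1", "ACTN2", "MYBPC1", "MYBPC2", "MYH1", "MYH2", "MYH7", "MYH8",
    "MYL1", "MYL2", "NEB", "TCAP", "TNNC2", "TNNI1", "TNNI2", "TNNT1",
    "TNNT3",
)


def size_factors(counts: GeneCountMatrix) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For genes with a positive geometric mean across samples, the factor of
    sample ``s`` is the median of ``n_gs / geomean_g``. Factors are rescaled
    so their geometric mean is 1.
    """
    mat = counts.counts.to_numpy(dtype=float)
    if mat.sum() == 0:
        raise ValueError("all-zero count matrix")
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    log_geomean = logs.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    log_ratios = logs[usable] - log_geomean[usable, None]
    log_sf = np.median(log_ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    sf = np.exp(log_sf)
    return pd.Series(sf, index=counts.sample_ids, name="size_factor")


def _normalised(counts: GeneCountMatrix, sf: pd.Series | None = None) -> pd.DataFrame:
    if sf is None:
        sf = size_factors(counts)
    return counts.counts / sf.to_numpy()[None, :]


def fit_dispersion_trend(
    counts: GeneCountMatrix,
    sf: pd.Series | None = None,
    min_mean: float = 1.0,
) -> tuple[tuple[float, float], pd.Series]:
    """Fit the mean-dispersion trend ``alpha(mu) = a1/mu + a0``.

    Per-gene dispersions are method-of-moments estimates on normalised
    counts, ``alpha_g = max(0, (var - mean) / mean**2)``. The trend is an
    ordinary least-squares fit of the raw (unclamped) moment estimates
    against ``1/mean`` — clamping before the fit would bias both
    coefficients upward under Poisson noise — with the fitted ``(a0, a1)``
    clamped at zero. Zero-variance genes and genes with mean normalised
    count below ``min_mean`` are excluded from the fit: at sub-``min_mean``
    means the moment ratio is dominated by the random denominator and
    would drag the trend.

    Returns ``((a0, a1), per_gene_dispersion)``.
    """
    if counts.shape[1] < 2:
        raise ValueError("dispersion estimation needs at least 2 samples")
    q = _normalised(counts, sf).to_numpy()
    mu = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mu) / mu**2
    alpha = pd.Series(
        np.where(mu > 0, np.maximum(raw, 0.0), 0.0),
        index=counts.gene_ids,
        name="dispersion",
    )
    use = (mu > min_mean) & (var > 0)
    if use.sum() < 2:
        raise ValueError("too few variable genes to fit a dispersion trend")
    X = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
    coef, *_ = np.linalg.lstsq(X, raw[use], rcond=None)
    a0, a1 = float(max(coef[0], 0.0)), float(max(coef[1], 0.0))
    return (a0, a1), alpha


def vst_transform(
    counts: GeneCountMatrix,
    trend: tuple[float, float] | None = None,
    sf: pd.Series | None = None,
    fallback_log2: bool = False,
) -> VSTMatrix:
    """Variance-stabilising transformation of normalised counts.

    Uses the closed-form antiderivative for the parametric dispersion trend
    (module docstring). Requires ``a0 > 0``; for dispersion-free data pass
    ``fallback_log2=True`` to get ``log2(q + 1)`` instead.
    """
    if sf is None:
        sf = size_factors(counts)
    if trend is None:
        trend, _ = fit_dispersion_trend(counts, sf)
    a0, a1 = trend
    q = _normalised(counts, sf)
    if a0 <= 0:
        if not fallback_log2:
            raise ValueError(
                "dispersion trend a0 must be positive for the closed-form VST; "
                "pass fallback_log2=True for a log2(q+1) transform"
            )
        values = np.log2(q + 1.0)
    else:
        if a1 < 0:
            raise ValueError("dispersion trend a1 must be non-negative")
        values = vst_curve(q.to_numpy(), a0, a1)
        values = pd.DataFrame(values, index=q.index, columns=q.columns)
    return VSTMatrix(values=pd.DataFrame(values, index=q.index, columns=q.columns),
                     size_factors=sf, dispersion_trend=(a0, a1))


def vst_curve(q, a0: float, a1: float):
    """The scalar VST curve applied to normalised counts ``q >= 0``."""
    q = np.asarray(q, dtype=float)
    b = 1.0 + a1
    return 2.0 * np.log2(np.sqrt(a0 * q) + np.sqrt(a0 * q + b)) - np.log2(4.0 * a0)


def filter_genes(
    data,
    rule: str,
    *,
    min_samples: int = 18,
    min_norm_count: float = 9.0,
    min_count: float = 20.0,
    min_total_count: float = 5e5,
    large_n: int = 10,
    min_prop: float = 0.7,
    vst_mean: float = 6.0,
    sf: pd.Series | None = None,
) -> list[str]:
    """Return gene IDs passing the named expression filter.

    Rules
    -----
    ``de_low_expr``
        Keep genes with a normalised count of at least ``min_norm_count``
        in at least ``min_samples`` samples (differential-expression
        pre-filter). ``data`` is a :class:`GeneCountMatrix`.
    ``cluster_expr``
        edgeR ``filterByExpr``-style rule with design-free grouping: keep
        genes whose CPM exceeds the CPM equivalent of ``min_count`` (at the
        median library size) in at least ``large_n + (n - large_n) * min_prop``
        samples, and whose total count is at least ``min_total_count``.
        ``data`` is a :class:`GeneCountMatrix`.
    ``ml_feature``
        Keep genes with mean VST expression >= ``vst_mean``. ``data`` is a
        :class:`VSTMatrix`.
    """
    if rule == "de_low_expr":
        if not isinstance(data, GeneCountMatrix):
            raise TypeError("de_low_expr operates on a GeneCountMatrix")
        q = _normalised(data, sf)
        keep = (q >= min_norm_count).sum(axis=1) >= min_samples
        return list(q.index[keep])
    if rule == "cluster_expr":
        if not isinstance(data, GeneCountMatrix):
            raise TypeError("cluster_expr operates on a GeneCountMatrix")
        mat = data.counts.to_numpy(dtype=float)
        lib = mat.sum(axis=0)
        if (lib == 0).any():
            raise ValueError("sample with zero total count")
        cpm = mat / lib[None, :] * 1e6
        cpm_cutoff = min_count / np.median(lib) * 1e6
        n = mat.shape[1]
        n_min = n if n <= large_n else large_n + (n - large_n) * min_prop
        keep = ((cpm >= cpm_cutoff).sum(axis=1) >= n_min) & (
            mat.sum(axis=1) >= min_total_count
        )
        return list(np.asarray(data.gene_ids)[keep])
    if rule == "ml_feature":
        if not isinstance(data, VSTMatrix):
            raise TypeError("ml_feature operates on a VSTMatrix")
        keep = data.values.mean(axis=1) >= vst_mean
        return list(data.values.index[keep])
    raise ValueError(f"unknown filter rule: {rule!r}")


def transform_clinical(clinical: pd.DataFrame, crp_offset: float = 1.0) -> pd.DataFrame:
    """Standard covariate transforms for modelling.

    Square-root transforms the joint counts and ESR, natural-log transforms
    CRP (after adding ``crp_offset`` mg/L to handle zeros); VAS and the
    RF/CCP titres pass through unchanged.
    """
    out = {}
    for col, new in (("tjc28", "sqTJC"), ("sjc28", "sqSJC"), ("esr", "sqESR")):
        if col in clinical:
            v = clinical[col].to_numpy(dtype=float)
            if (v < 0).any():
                raise ValueError(f"negative values in {col}")
            out[new] = np.sqrt(v)
    if "crp" in clinical:
        v = clinical["crp"].to_numpy(dtype=float)
        if (v < 0).any():
            raise ValueError("negative values in crp")
        out["logCRP"] = np.log(v + crp_offset)
    for col in ("vas", "rf_titre", "ccp_titre"):
        if col in clinical:
            v = clinical[col].to_numpy(dtype=float)
            if (v < 0).any():
                raise ValueError(f"negative values in {col}")
            out[col] = v
    return pd.DataFrame(out, index=clinical.index)


def muscle_pc1(
    vst: VSTMatrix,
    muscle_genes=MUSCLE_GENES,
    scale: bool = False,
) -> pd.Series:
    """Per-sample muscle-contamination covariate.

    First principal component of the centred (optionally unit-variance
    scaled) muscle-gene submatrix, sign-fixed so that a higher score means
    higher mean muscle expression.
    """
    present = [g for g in muscle_genes if g in vst.values.index]
    if len(present) < 2:
        missing = [g for g in muscle_genes if g not in vst.values.index]
        raise ValueError(
            f"need >=2 muscle genes in the matrix, found {len(present)}; "
            f"missing: {missing}"
        )
    sub = vst.values.loc[present].to_numpy().T  # samples x genes
    centred = sub - sub.mean(axis=0)
    if scale:
        sd = centred.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        centred = centred / sd
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    score = u[:, 0] * s[0]
    mean_expr = sub.mean(axis=1)
    if np.dot(score, mean_expr - mean_expr.mean()) < 0:
        score = -score
    return pd.Series(score, index=vst.sample_ids, name="muscle_pc1")
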