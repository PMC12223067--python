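"""Differential expression and gene-set level testing.

Per-gene negative-binomial generalised linear models with a log link are
fitted by iteratively reweighted least squares, vectorised across genes.
The dispersion of each gene is held fixed at its trend value
``alpha(mu) = a1/mu + a0`` evaluated at the gene's mean normalised count,
and the group coefficient is tested with a two-sided Wald test against a
standard normal. Multiplicity is handled with Storey's q-value.

``polar_categorise`` implements the three-drug comparison: a gene
significant for exactly one drug gets that drug's label (E+, R+ or T+),
for exactly two a mixed label (E+R+, E+T+ or R+T+), and genes significant
in all three are excluded. Each gene also gets polar coordinates from
projecting its three log2 fold changes onto axes at 90deg (E), 210deg (T)
and 330deg (R).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneCountMatrix
from .counts import fit_dispersion_trend, size_factors as _size_factors

__all__ = [
    "nb_wald_de",
    "storey_qvalue",
    "polar_categorise",
    "module_activity_test",
    "ora_enrich",
]

LN2 = np.log(2.0)

#: Polar axis angles in degrees for the three drugs.
POLAR_AXES = {"E": 90.0, "T": 210.0, "R": 330.0}


def nb_wald_de(
    counts: GeneCountMatrix,
    group,
    covariates: pd.DataFrame | None = None,
    trend: tuple[float, float] | None = None,
    sf: pd.Series | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
    min_dispersion: float = 1e-8,
) -> pd.DataFrame:
    """Negative-binomial Wald differential expression, responders vs not.

    Parameters
    ----------
    group
        Binary per-sample labels (1 = responder); the reported log2 fold
        change is responders over non-responders.
    covariates
        Optional samples x covariates design columns (e.g. the muscle PC1
        score), centred internally.

    Returns a per-gene DataFrame with ``base_mean``, ``log2fc``,
    ``se_log2fc``, ``wald_stat``, ``p_value``, ``q_value`` and a
    ``converged`` flag. Non-converged genes keep their estimates but get a
    missing p-value.
    """
    y = counts.counts.to_numpy(dtype=float)  # G x n
    g_ids = counts.gene_ids
    grp = np.asarray(group, dtype=float)
    if set(np.unique(grp)) - {0.0, 1.0}:
        raise ValueError("group must be binary 0/1")
    if grp.sum() == 0 or grp.sum() == len(grp):
        raise ValueError("both groups must be non-empty")
    if sf is None:
        sf = _size_factors(counts)
    if trend is None:
        trend, _ = fit_dispersion_trend(counts, sf)
    a0, a1 = trend

    n = y.shape[1]
    cols = [np.ones(n), grp - 0.0]
    if covariates is not None:
        cov = covariates.to_numpy(dtype=float)
        cov = cov - cov.mean(axis=0)
        keep = cov.std(axis=0) > 0  # constant covariates are the intercept
        cols.extend(cov[:, keep].T)
    X = np.column_stack(cols)  # n x p
    p = X.shape[1]
    if n <= p:
        raise ValueError("more design columns than samples")

    offset = np.log(sf.to_numpy())  # per sample
    q = y / sf.to_numpy()[None, :]
    base_mean = q.mean(axis=1)
    alpha = np.maximum(a1 / np.maximum(base_mean, 1e-8) + a0, min_dispersion)

    G = y.shape[0]
    beta = np.zeros((G, p))
    # init: intercept at log mean normalised count, group effect from group means
    m1 = (q * grp).sum(axis=1) / grp.sum()
    m0 = (q * (1 - grp)).sum(axis=1) / (1 - grp).sum()
    beta[:, 0] = np.log(np.maximum(m0, 0.5 / n))
    beta[:, 1] = np.log(np.maximum(m1, 0.5 / n)) - beta[:, 0]

    converged = np.zeros(G, dtype=bool)
    active = ~converged
    for _ in range(max_iter):
        eta = beta @ X.T + offset[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)  # NB working weights
        z = (eta - offset[None, :]) + (y - mu) / mu
        xtwx = np.einsum("gn,np,nq->gpq", w, X, X)
        xtwz = np.einsum("gn,np,gn->gp", w, X, z)
        try:
            new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_beta = np.array(
                [np.linalg.lstsq(a, b, rcond=None)[0] for a, b in zip(xtwx, xtwz)]
            )
        step = new_beta - beta
        beta = new_beta
        just_done = np.abs(step).max(axis=1) < tol
        converged |= just_done
        if converged.all():
            break

    eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    xtwx = np.einsum("gn,np,nq->gpq", w, X, X)
    se = np.empty(G)
    for i in range(G):
        try:
            se[i] = np.sqrt(np.linalg.inv(xtwx[i])[1, 1])
        except np.linalg.LinAlgError:
            se[i] = np.nan
            converged[i] = False

    # constant genes: identical counts in every sample => no group effect
    const = y.std(axis=1) == 0
    beta[const, 1] = 0.0
    converged |= const

    log2fc = beta[:, 1] / LN2
    se_log2 = se / LN2
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = np.where(se > 0, beta[:, 1] / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    pvals[~converged] = np.nan
    n_failed = int((~converged).sum())
    if n_failed:
        warnings.warn(f"{n_failed} gene(s) did not converge; p set to missing")
    ok = ~np.isnan(pvals)
    qvals = np.full(G, np.nan)
    if ok.any():
        qvals[ok] = storey_qvalue(pvals[ok])
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se_log2fc": se_log2,
            "wald_stat": wald,
            "p_value": pvals,
            "q_value": qvals,
            "converged": converged,
        },
        index=g_ids,
    )


def storey_qvalue(p, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values with a single-lambda pi0 estimate.

    ``pi0 = #{p > lambda} / ((1 - lambda) * m)`` clamped to (0, 1];
    ``q_(i) = min_{j >= i} pi0 * m * p_(j) / j`` on the sorted p-values.
    When ``pi0 = 1`` this reduces to Benjamini-Hochberg.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = (p > lambda_).sum() / ((1.0 - lambda_) * m)
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def polar_categorise(
    de_E: pd.DataFrame,
    de_R: pd.DataFrame,
    de_T: pd.DataFrame,
    q_cut: float = 0.05,
    direction: str = "responder-up",
    use_q: bool = True,
) -> pd.DataFrame:
    """Three-drug significance categories and polar-plot coordinates."""
    if direction not in ("responder-up", "nonresponder-up"):
        raise ValueError("direction must be 'responder-up' or 'nonresponder-up'")
    genes = de_E.index
    if not (genes.equals(de_R.index) and genes.equals(de_T.index)):
        raise ValueError("the three DE tables must share the same gene universe")
    sign = 1.0 if direction == "responder-up" else -1.0
    tables = {"E": de_E, "R": de_R, "T": de_T}
    flags = {}
    for d, tab in tables.items():
        crit = tab["q_value"] if use_q else tab["p_value"]
        flags[d] = (crit < q_cut) & (sign * tab["log2fc"] > 0)
    lfc = np.column_stack([tables[d]["log2fc"].to_numpy() for d in ("E", "T", "R")])
    ang = np.deg2rad([POLAR_AXES[d] for d in ("E", "T", "R")])
    x = lfc @ np.cos(ang)
    yv = lfc @ np.sin(ang)
    angle = np.rad2deg(np.arctan2(yv, x)) % 360.0
    radius = np.hypot(x, yv)
    n_sig = sum(f.to_numpy().astype(int) for f in flags.values())
    cats = []
    for i in range(len(genes)):
        on = [d for d in ("E", "R", "T") if flags[d].iloc[i]]
        if len(on) == 0:
            cats.append("none")
        elif len(on) == 3:
            cats.append("excluded")
        else:
            cats.append("".join(f"{d}+" for d in on))
    return pd.DataFrame(
        {
            "sig_E": flags["E"],
            "sig_R": flags["R"],
            "sig_T": flags["T"],
            "category": cats,
            "angle": angle,
            "radius": radius,
        },
        index=genes,
    )


def module_activity_test(
    de: pd.DataFrame,
    module_genes,
    correlation_adjust: bool = False,
    residuals: pd.DataFrame | None = None,
    df_per_gene: float = np.inf,
) -> dict:
    """Aggregate gene-level fold changes into a module-activity test.

    The module log2 fold change is the mean of the member genes' fold
    changes; its squared standard error is ``sum(se_g^2) / m^2``, inflated
    by a variance-inflation factor ``1 + (m - 1) * rho_bar`` when
    ``correlation_adjust`` is set, with ``rho_bar`` the mean pairwise
    residual correlation of the member genes (floored at 0; requires
    ``residuals``, genes x samples). Degrees of freedom follow
    Welch-Satterthwaite over the member genes; with infinite per-gene df
    the reference is normal. This is a deliberately simple aggregation,
    not a full posterior-convolution gene-set test.
    """
    members = [g for g in module_genes if g in de.index]
    if len(members) < 2:
        raise ValueError(f"need >=2 module genes present, found {len(members)}")
    sub = de.loc[members]
    m = len(members)
    lfc = float(sub["log2fc"].mean())
    se2 = float((sub["se_log2fc"] ** 2).sum()) / m**2
    if correlation_adjust:
        if residuals is None:
            raise ValueError("correlation_adjust requires residuals (genes x samples)")
        r = residuals.loc[[g for g in members if g in residuals.index]].to_numpy()
        c = np.corrcoef(r)
        iu = np.triu_indices_from(c, k=1)
        rho = max(float(np.nanmean(c[iu])), 0.0) if iu[0].size else 0.0
        vif = 1.0 + (m - 1) * rho
        se2 *= vif
    se = np.sqrt(se2)
    if np.isfinite(df_per_gene):
        s4 = (sub["se_log2fc"] ** 4).to_numpy()
        denom = (s4 / df_per_gene).sum()
        df = float((sub["se_log2fc"] ** 2).sum() ** 2 / denom) if denom > 0 else np.inf
    else:
        df = np.inf
    if se == 0:
        p = 0.0 if lfc != 0 else 1.0
    elif np.isfinite(df):
        p = float(2.0 * stats.t.sf(abs(lfc) / se, df))
    else:
        p = float(2.0 * stats.norm.sf(abs(lfc) / se))
    return {"module_log2fc": lfc, "se": se, "df": df, "p_value": p, "n_genes": m}


def ora_enrich(hits, universe, library: dict[str, list[str]]) -> pd.DataFrame:
    """Over-representation analysis against a GMT-style gene-set library.

    One-sided hypergeometric tail ``P(X >= k)`` per set, Benjamini-Hochberg
    adjusted across sets. Set membership is intersected with the universe.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    hits = list(dict.fromkeys(hits))
    stray = [h for h in hits if h not in uni]
    if stray:
        raise ValueError(f"hit gene(s) not in universe: {stray[:5]}")
    N, n = len(uni), len(hits)
    hit_set = set(hits)
    rows = []
    for name, genes in library.items():
        in_uni = uni.intersection(genes)
        K = len(in_uni)
        k = len(hit_set & in_uni)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, p))
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p_value"]).set_index("set")
    df["q_value"] = _bh(df["p_value"].to_numpy())
    return df


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = m * p[order] / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
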