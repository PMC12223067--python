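"""Cell-subset module scoring of bulk profiles and abundance testing.

Bulk samples are scored against single-cell-derived subset marker sets
with an expression-bin-matched control scheme: genes are binned by average
expression, each member gene draws control genes from its own bin, and the
score is the mean member expression minus the mean control expression per
sample. This makes scores shift-invariant and roughly centred at zero for
uninformative sets.

B-cell rich/poor classification uses the mean of per-gene z-scored
expression over a B-cell module, split at a predefined cutoff (-0.0413,
the reference-cohort median); a boundary score equal to the cutoff is
labelled poor.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import VSTMatrix

__all__ = [
    "BCELL_CUTOFF",
    "module_score",
    "classify_bcell",
    "subset_abundance_test",
    "cluster_samples_by_scores",
]

#: Predefined B-cell module cutoff (median module score of the reference
#: validation cohort); scores strictly above are "B-cell rich".
BCELL_CUTOFF = -0.0413


def _values(vst) -> pd.DataFrame:
    return vst.values if isinstance(vst, VSTMatrix) else vst


def module_score(
    vst,
    sets: dict[str, list[str]],
    n_bins: int = 24,
    n_control: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression-bin-matched module scores, subsets x samples.

    For each gene set, every member gene contributes ``n_control`` control
    genes sampled without replacement (seeded) from its average-expression
    bin; the per-sample score is mean(member expression) minus
    mean(control expression). Member genes never serve as their own
    controls (the pool widens to neighbouring bins when a bin holds only
    members). Member genes absent from the matrix are dropped with a
    warning; a set with no matched genes is an error.
    """
    expr = _values(vst)
    if not sets:
        raise ValueError("no gene sets supplied")
    if expr.shape[0] < n_bins:
        raise ValueError(f"matrix has {expr.shape[0]} genes < n_bins={n_bins}")
    rng = np.random.default_rng(seed)
    avg = expr.mean(axis=1)
    # rank-based binning so ties cannot collapse bins
    bins = pd.qcut(avg.rank(method="first"), n_bins, labels=False)
    bin_members: dict[int, np.ndarray] = {
        b: np.asarray(expr.index[bins == b]) for b in range(n_bins)
    }
    rows = {}
    for name, genes in sets.items():
        present = [g for g in genes if g in expr.index]
        missing = [g for g in genes if g not in expr.index]
        if not present:
            raise ValueError(f"gene set {name!r}: no member gene found in matrix")
        if missing:
            warnings.warn(f"gene set {name!r}: dropping {len(missing)} absent gene(s)")
        member_set = set(present)
        controls: list[str] = []
        for g in present:
            b = int(bins.loc[g])
            pool = [x for x in bin_members[b] if x not in member_set]
            # widen to neighbouring bins if the member's own bin is all members
            offset = 1
            while not pool and (b - offset >= 0 or b + offset < n_bins):
                for bb in (b - offset, b + offset):
                    if 0 <= bb < n_bins:
                        pool.extend(x for x in bin_members[bb] if x not in member_set)
                offset += 1
            if not pool:
                raise ValueError(f"gene set {name!r}: no control genes available")
            k = min(n_control, len(pool))
            controls.extend(rng.choice(pool, size=k, replace=False))
        member_mean = expr.loc[present].mean(axis=0)
        control_mean = expr.loc[controls].mean(axis=0)
        rows[name] = member_mean - control_mean
    out = pd.DataFrame(rows).T
    out.columns = expr.columns
    return out


def classify_bcell(
    vst,
    bcell_genes,
    cutoff: float = BCELL_CUTOFF,
) -> pd.Series:
    """Label samples B-cell rich/poor from a B-cell module score.

    Score = mean over module genes of per-gene z-scored (normalised and
    scaled) expression; rich iff score strictly exceeds ``cutoff``.
    """
    expr = _values(vst)
    present = [g for g in bcell_genes if g in expr.index]
    if not present:
        raise ValueError("no B-cell module gene found in matrix")
    sub = expr.loc[present].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mu) / sd
    score = z.mean(axis=0)
    labels = np.where(score > cutoff, "B-cell rich", "B-cell poor")
    return pd.Series(labels, index=expr.columns, name="bcell_status")


def bcell_score(vst, bcell_genes) -> pd.Series:
    """The raw mean z-scored B-cell module score per sample."""
    expr = _values(vst)
    present = [g for g in bcell_genes if g in expr.index]
    if not present:
        raise ValueError("no B-cell module gene found in matrix")
    sub = expr.loc[present].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    return pd.Series(z.mean(axis=0), index=expr.columns, name="bcell_score")


def subset_abundance_test(
    scores: pd.DataFrame,
    response,
    moderation: bool = False,
) -> pd.DataFrame:
    """Differential subset abundance, responders vs non-responders.

    Per subset, an ordinary least-squares fit of the score on the response
    indicator (equivalent to an equal-variance two-sample t-test): the
    ``fold_change`` is the group-difference coefficient on the score scale,
    with a 95% CI and two-sided t p-value. With ``moderation``, residual
    variances are shrunk towards a cross-subset inverse-gamma prior fitted
    by moment matching on the log residual variances (an empirical-Bayes
    scheme in the spirit of moderated t-statistics).
    """
    y = np.asarray(response, dtype=float)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if min(n1, n0) < 3:
        raise ValueError("both response groups need >= 3 samples")
    n = n1 + n0
    X = scores.to_numpy(dtype=float)  # subsets x samples
    m1 = X[:, y == 1].mean(axis=1)
    m0 = X[:, y == 0].mean(axis=1)
    diff = m1 - m0
    ss = X[:, y == 1].var(axis=1, ddof=1) * (n1 - 1) + X[:, y == 0].var(
        axis=1, ddof=1
    ) * (n0 - 1)
    df = n - 2
    s2 = ss / df
    if moderation:
        s2_mod, df_mod = _squeeze_var(s2, df)
    else:
        s2_mod, df_mod = s2, np.full_like(s2, float(df))
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n0))
    degenerate = s2_mod == 0
    if degenerate.any():
        warnings.warn("constant scores in some subsets; p set to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_mod)
    p[degenerate] = 1.0
    tcrit = stats.t.ppf(0.975, df_mod)
    out = pd.DataFrame(
        {
            "fold_change": diff,
            "ci_low": diff - tcrit * se,
            "ci_high": diff + tcrit * se,
            "t": t,
            "p_value": p,
        },
        index=scores.index,
    )
    from .diffexp import _bh

    out["q_value"] = _bh(out["p_value"].to_numpy())
    return out


def _squeeze_var(s2: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Moment-matched inverse-gamma shrinkage of sample variances.

    Fits the prior (d0, s0^2) from the moments of log(s2) using the
    scaled-F marginal of the variances, then returns posterior variances
    ``(d0*s0^2 + df*s2) / (d0 + df)`` and total df ``d0 + df``.
    """
    from scipy.special import digamma, polygamma

    pos = s2 > 0
    if pos.sum() < 2:
        return s2, np.full_like(s2, float(df))
    z = np.log(s2[pos])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = max(z.var(ddof=1) - polygamma(1, df / 2.0), 1e-8)
    # invert trigamma by Newton iteration
    x = 0.5 + 1.0 / evar
    for _ in range(50):
        f = polygamma(1, x) - evar
        x = x - f / polygamma(2, x)
        x = max(x, 1e-3)
    d0 = 2.0 * x
    s02 = np.exp(e.mean() + digamma(x) - np.log(x))
    post = (d0 * s02 + df * s2) / (d0 + df)
    return post, np.full_like(s2, d0 + df)


def cluster_samples_by_scores(scores: pd.DataFrame, k: int) -> pd.Series:
    """Hierarchical clustering of samples on their module scores.

    Euclidean distance, complete linkage, cut to ``k`` clusters. Cluster
    labels are integers 1..k in dendrogram order.
    """
    n = scores.shape[1]
    if n < 2:
        raise ValueError("need >= 2 samples")
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples ({n})")
    d = pdist(scores.to_numpy().T, metric="euclidean")
    Z = hierarchy.linkage(d, method="complete")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=scores.columns, name="cluster")
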