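"""Phylogenetic comparative statistics: PGLS and a binary-trait test.

PGLS assumes Brownian-motion residuals, so the error covariance is the
shared root-to-MRCA path length matrix C. Slopes, standard errors and
t-tests come from generalized least squares with that known (up to scale)
covariance. The reported ``r2_pred`` is the conditional-prediction R2:
1 - SSE(model)/SSE(null), where each tip's prediction conditions on all
other tips' residuals through the fitted covariance (leave-one-out
kriging), for both the model of interest and the intercept-only null.

The binary-trait test is a phylogenetic ANOVA: the observed |mean(LONG) -
mean(SHORT)| is referred to its null distribution over Brownian
simulations on the same tree with the Brownian rate matched to the
observed sample variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError
from .traits import TraitMap
from .tree import Phylogeny

__all__ = ["PglsResult", "pgls_fit", "phylo_binary_test"]


@dataclass
class PglsResult:
    coefficients: pd.DataFrame  # index: term; columns: estimate, se, t, p
    r2_pred: float
    sigma2: float
    n: int
    method: str = "pgls-brownian; r2_pred=conditional-LOO"

    def __getitem__(self, term: str) -> pd.Series:
        return self.coefficients.loc[term]


def _covariance(tree: Phylogeny, tips: list[str]) -> np.ndarray:
    c = tree.brownian_covariance().loc[tips, tips].to_numpy()
    # guard against exactly duplicated tips (zero patristic distance)
    if np.linalg.matrix_rank(c) < len(tips):
        raise ValidationError(
            "singular phylogenetic covariance (duplicated/zero-length tips?)"
        )
    return c


def _conditional_loo(y: np.ndarray, mu: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Leave-one-out conditional predictions under N(mu, sigma2*C);
    sigma2 cancels in the conditional mean."""
    n = len(y)
    resid = y - mu
    pred = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        sub = c[np.ix_(mask, mask)]
        cross = c[i, mask]
        pred[i] = mu[i] + cross @ np.linalg.solve(sub, resid[mask])
    return pred


def pgls_fit(y: pd.Series, x: pd.DataFrame, tree: Phylogeny) -> PglsResult:
    """Generalized least squares under Brownian covariance on the tree.

    ``y`` and ``x`` are indexed by tip labels; an intercept column is
    added automatically.
    """
    tips = [t for t in tree.tip_labels if t in y.index]
    if x.isna().to_numpy().any() or y.loc[tips].isna().any():
        raise ValidationError("NaN in PGLS inputs")
    yv = y.loc[tips].to_numpy(dtype=float)
    xm = sm.add_constant(x.loc[tips].astype(float), has_constant="add")
    c = _covariance(tree, tips)

    xtx = xm.to_numpy().T @ np.linalg.solve(c, xm.to_numpy())
    if np.linalg.cond(xtx) > 1e12:
        raise ValidationError("collinear covariates in PGLS design")

    fit = sm.GLS(yv, xm, sigma=c).fit()
    coefs = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )

    mu_full = xm.to_numpy() @ fit.params.to_numpy()
    pred_full = _conditional_loo(yv, mu_full, c)
    ones = pd.DataFrame({"const": np.ones(len(tips))}, index=tips)
    null_fit = sm.GLS(yv, ones, sigma=c).fit()
    mu_null = np.full(len(yv), float(null_fit.params.iloc[0]))
    pred_null = _conditional_loo(yv, mu_null, c)

    sse_full = float(np.sum((yv - pred_full) ** 2))
    sse_null = float(np.sum((yv - pred_null) ** 2))
    r2_pred = 1.0 - sse_full / sse_null if sse_null > 0 else float("nan")

    return PglsResult(
        coefficients=coefs,
        r2_pred=r2_pred,
        sigma2=float(fit.scale),
        n=len(tips),
    )


def phylo_binary_test(
    y: pd.Series,
    traits: TraitMap,
    tree: Phylogeny,
    n_sims: int = 999,
    seed: int | np.random.Generator = 0,
) -> float:
    """Phylogenetic ANOVA p-value for a LONG/SHORT difference in ``y``.

    The null resamples ``y`` from Brownian motion on the tree with the
    rate chosen so the expected sample variance matches the observed one;
    p = (1 + #{null >= observed}) / (n_sims + 1).
    """
    rng = np.random.default_rng(seed)
    tips = [t for t in tree.tip_labels if t in y.index]
    tmap = traits.restricted(tips)
    ll = [t for t in tips if tmap[t] == "LONG"]
    sl = [t for t in tips if tmap[t] == "SHORT"]
    if not ll or not sl:
        raise ValidationError("both classes required for the binary test")

    yv = y.loc[tips].to_numpy(dtype=float)
    is_ll = np.array([t in set(ll) for t in tips])
    obs = abs(yv[is_ll].mean() - yv[~is_ll].mean())

    c = _covariance(tree, tips)
    n = len(tips)
    # E[sample variance] of N(0, s2*C) is s2 * (tr(C) - 1'C1/n) / (n-1)
    var_factor = (np.trace(c) - c.sum() / n) / (n - 1)
    s2 = np.var(yv, ddof=1) / var_factor if var_factor > 0 else 0.0
    if s2 == 0.0:
        return 1.0
    chol = np.linalg.cholesky(c)
    sims = yv.mean() + np.sqrt(s2) * (rng.standard_normal((n_sims, n)) @ chol.T)
    null = np.abs(sims[:, is_ll].mean(axis=1) - sims[:, ~is_ll].mean(axis=1))
    return float((1 + np.sum(null >= obs)) / (n_sims + 1))
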