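"""Wald and likelihood-ratio tests for a prespecified attribute hierarchy.

The Wald test asks whether the structural probabilities of the patterns an
attribute hierarchy forbids are jointly zero in the saturated model:

    W = (R pi_hat)' (R Sigma_pipi R')^{-1} (R pi_hat),

with R the selector matrix of the impermissible positions and Sigma_pipi the
structural block of the free-parameter covariance (from the XPD or Obs
information).  The LR test compares the saturated fit with the
hierarchy-restricted fit, LR = 2 (l_s - l_r).  Both statistics are referred
to a chi-square upper tail: W with df equal to the rank of R Sigma_pipi R'
(the number of impermissible patterns in the regular case), LR with df equal
to the difference in free-parameter counts.  Failing to reject supports the
hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .em import ModelFit
from .hierarchy import AttributeHierarchy, constraint_matrix
from .information import CovarianceEstimate

__all__ = ["TestResult", "wald_test", "lr_test", "chisq_pvalue"]

EIG_TOL = 1e-6  # eigenvalue floor (relative) for the tested covariance block


@dataclass
class TestResult:
    """Outcome of one attribute-hierarchy test."""

    method: str                 # "Wald-XPD" | "Wald-Obs" | "LR"
    statistic: float
    df: int
    p_value: float
    alpha: float
    reject: bool
    warnings_: list = field(default_factory=list)

    def __str__(self) -> str:
        return (f"{self.method}: statistic={self.statistic:.3f}, df={self.df}, "
                f"p={self.p_value:.3f} ({'reject' if self.reject else 'retain'} "
                f"H0 at alpha={self.alpha})")


def chisq_pvalue(stat: float, df: int) -> float:
    """Upper-tail chi-square probability."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if stat < 0:
        raise ValueError(f"statistic must be >= 0, got {stat}")
    return float(stats.chi2.sf(stat, df))


def wald_test(
    fit: ModelFit,
    cov: CovarianceEstimate,
    hierarchy: AttributeHierarchy,
    alpha: float = 0.05,
) -> TestResult:
    """Wald test that the hierarchy's impermissible structural parameters are
    jointly zero, using the covariance estimate supplied (XPD or Obs).

    ``fit`` must be the saturated model.  If the middle matrix
    ``R Sigma_pipi R'`` is singular it is pseudo-inverted and the degrees of
    freedom reduced to its rank, with a warning recorded on the result.
    """
    if fit.hierarchy is not None:
        raise ValueError("the Wald test requires the saturated fit")
    R = constraint_matrix(hierarchy, fit.space)
    pi_free = fit.pi[fit.support[:-1]]
    r = R @ pi_free
    M = R @ cov.sigma_pp @ R.T
    M = 0.5 * (M + M.T)
    # The Obs information is not guaranteed positive definite at
    # boundary-adjacent structural estimates, so the tested block can come
    # out indefinite or singular.  Repair it to the nearest positive definite
    # matrix by flooring eigenvalues at EIG_TOL * lambda_max (the standard
    # nearPD-style fix) and keep the nominal degrees of freedom.
    lam, V = np.linalg.eigh(M)
    lam_max = lam[-1]
    df = R.shape[0]
    notes = list(cov.warnings_)
    if lam_max <= 0:
        # every tested parameter sits on the boundary with zero variance:
        # the constraint vector is (numerically) zero and W degenerates to 0
        notes.append("all tested structural parameters at the zero boundary")
        W = 0.0
    else:
        n_bad = int((lam < EIG_TOL * lam_max).sum())
        if n_bad:
            notes.append(
                f"R Sigma_pipi R' not positive definite: {n_bad} eigenvalue(s) "
                f"floored at {EIG_TOL:.0e} * lambda_max")
        lam = np.maximum(lam, EIG_TOL * lam_max)
        z = V.T @ r
        W = float(np.sum(z ** 2 / lam))
    p = chisq_pvalue(W, df)
    return TestResult(
        method=f"Wald-{cov.estimator}", statistic=W, df=df, p_value=p,
        alpha=alpha, reject=bool(p < alpha), warnings_=notes,
    )


def lr_test(fit_saturated: ModelFit, fit_restricted: ModelFit, alpha: float = 0.05) -> TestResult:
    """Likelihood-ratio test of the restricted (hierarchical) model against
    the saturated model fitted to the same data.

    The statistic is twice the log-likelihood difference; negative values
    beyond -1e-6 signal a convergence failure and raise, small negatives are
    clipped to zero with a warning.
    """
    if fit_restricted.npar >= fit_saturated.npar:
        raise ValueError("restricted model must have fewer free parameters")
    stat = 2.0 * (fit_saturated.loglik - fit_restricted.loglik)
    notes = []
    if stat < -1e-6:
        raise ValueError(
            f"negative LR statistic ({stat:.3g}): nested fits are inconsistent "
            "(likely a convergence failure)")
    if stat < 0:
        notes.append(f"small negative LR ({stat:.3g}) clipped to 0")
        stat = 0.0
    df = fit_saturated.npar - fit_restricted.npar
    p = chisq_pvalue(stat, df)
    return TestResult(
        method="LR", statistic=stat, df=df, p_value=p, alpha=alpha,
        reject=bool(p < alpha), warnings_=notes,
    )
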