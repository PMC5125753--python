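"""The statistical test battery used across the pipeline.

Exact small-sample behaviour is part of the contract: the one-tailed
binomial test is an exact tail sum, and the rank tests switch from exact
enumeration to the tie-corrected normal approximation above a fixed,
documented sample-size crossover (8 per group).  Mixed-effects p-values
come from a likelihood-ratio test of the fixed effect with models fitted
by maximum likelihood (not REML), so that the two likelihoods are
comparable.  No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ParameterError, QpcrSample

__all__ = [
    "binomial_one_tailed",
    "wilcoxon_rank_sum",
    "wilcoxon_one_sample",
    "t_test",
    "lmm_fixed_effect_p",
    "ddct_fold_change",
    "EXACT_N_MAX",
]

# crossover from exact enumeration to the normal approximation
EXACT_N_MAX = 8


def binomial_one_tailed(k: int, n: int) -> float:
    """Exact upper-tail binomial p-value: P(X >= k | n, 1/2)."""
    if n <= 0:
        raise ParameterError("binomial test needs n >= 1 trials")
    if not (0 <= k <= n):
        raise ParameterError(f"k must be in [0, {n}], got {k}")
    return float(sps.binomtest(k, n, 0.5, alternative="greater").pvalue)


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both groups have at most ``EXACT_N_MAX``
    observations and no ties span the groups; otherwise the normal
    approximation with mid-rank tie correction and continuity
    correction.  Degenerate all-tied input returns p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size <= EXACT_N_MAX and b.size <= EXACT_N_MAX and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(min(res.pvalue, 1.0))


def wilcoxon_one_sample(x: Sequence[float], mu: float = 0.0) -> float:
    """Two-sided Wilcoxon signed-rank test of location ``mu``.

    Zeros are dropped (Wilcoxon's convention); an all-zero difference
    vector is maximally consistent with the null and returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ParameterError("sample must be non-empty")
    d = x - mu
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    has_ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 2 * EXACT_N_MAX and not has_ties) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(d, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def t_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value for two independent samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("t-test needs >= 2 observations per group")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ParameterError("t-test undefined for zero-variance input")
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def lmm_fixed_effect_p(response: Sequence[float], fixed: Sequence,
                       oocyte: Sequence, movie: Optional[Sequence] = None) -> float:
    """Likelihood-ratio p-value for a fixed effect in a random-intercept model.

    Fits ``response ~ fixed`` with a random intercept per oocyte and,
    when movie labels are given, an additional random intercept per
    movie nested within oocyte, against the same model without the fixed
    effect.  Both models are fitted by maximum likelihood and compared
    with a chi-square likelihood-ratio test.  ``fixed`` may be
    categorical (group labels) or numeric (a covariate such as distance
    from the anterior).
    """
    import statsmodels.formula.api as smf

    response = np.asarray(response, dtype=float)
    fixed = np.asarray(fixed)
    oocyte = np.asarray(oocyte).astype(str)
    df = pd.DataFrame({"y": response, "x": fixed, "oocyte": oocyte})
    if np.issubdtype(fixed.dtype, np.number):
        fixed_term, df_fixed = "x", 1
    else:
        df["x"] = df["x"].astype(str)
        levels = df["x"].nunique()
        if levels < 2:
            raise ParameterError("fixed factor needs >= 2 levels")
        fixed_term, df_fixed = "C(x)", levels - 1
    vc = None
    if movie is not None:
        df["movie"] = np.asarray(movie).astype(str)
        vc = {"movie": "0 + C(movie)"}

    def _fit(formula):
        m = smf.mixedlm(formula, df, groups=df["oocyte"], vc_formula=vc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return m.fit(reml=False)

    try:
        full = _fit(f"y ~ {fixed_term}")
        null = _fit("y ~ 1")
    except Exception as exc:  # pragma: no cover - surface optimiser failures
        raise RuntimeError(f"mixed model failed to fit: {exc}") from exc
    if not (full.converged and null.converged):
        warnings.warn("mixed model did not fully converge; p-value may be unreliable")
    lr = 2.0 * (full.llf - null.llf)
    lr = max(lr, 0.0)
    return float(sps.chi2.sf(lr, df_fixed))


def ddct_fold_change(sampleA: QpcrSample, sampleB: QpcrSample) -> float:
    """Comparative-CT fold change 2^(-ΔΔCT) of sample A relative to sample B."""
    ddct = sampleA.delta_ct - sampleB.delta_ct
    return float(2.0 ** (-ddct))
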