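"""Cell-state composition statistics.

* :func:`dpa_test` — differential proportion analysis: a permutation test
  for per-cluster proportion shifts between two conditions.
* :func:`two_proportion_chi2` — Pearson chi-squared on a 2x2 table.
* :func:`limiting_dilution_frequency` — single-hit Poisson (ELDA-style)
  stem-cell frequency from dose-response transplantation data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("statekit")

__all__ = ["dpa_test", "two_proportion_chi2",
           "limiting_dilution_frequency", "LimitingDilutionResult"]


def dpa_test(labels, condition, n_perm: int = 100000, seed: int = 0
             ) -> pd.DataFrame:
    """Permutation test for per-cluster proportion differences.

    For each cluster k the observed statistic is
    ``p_k(A) - p_k(B)`` (within-condition proportions). The null is built
    by permuting condition labels over the pooled cells, keeping the
    condition totals fixed; the two-sided p is
    ``(1 + #{|delta*| >= |delta_obs|}) / (n_perm + 1)``. Deterministic
    given ``seed``. Also reports a BH adjustment across clusters; the
    per-cluster p is primary.
    """
    labels = np.asarray(labels)
    condition = np.asarray(condition)
    conds = sorted(pd.unique(condition).tolist())
    if len(conds) != 2:
        raise ValueError(f"exactly two conditions required, got {conds}")
    in_a = condition == conds[0]
    n_a, n_b = int(in_a.sum()), int((~in_a).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("a condition has zero cells")
    clusters, lab_codes = np.unique(labels, return_inverse=True)
    K = len(clusters)
    count_a = np.bincount(lab_codes[in_a], minlength=K)
    count_b = np.bincount(lab_codes[~in_a], minlength=K)
    obs = count_a / n_a - count_b / n_b

    rng = np.random.default_rng(seed)
    total = np.bincount(lab_codes, minlength=K)
    exceed = np.zeros(K, dtype=np.int64)
    # canonical order makes p invariant to joint reshuffling of the input
    codes = np.sort(lab_codes)
    scale = 1.0 / n_a + 1.0 / n_b
    for _ in range(n_perm):
        rng.shuffle(codes)
        ca = np.bincount(codes[:n_a], minlength=K)
        # delta* = ca/n_a - (total-ca)/n_b
        delta = ca * scale - total / n_b
        exceed += np.abs(delta) >= np.abs(obs) - 1e-12
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    table = pd.DataFrame({
        "cluster": clusters,
        f"count_{conds[0]}": count_a,
        f"count_{conds[1]}": count_b,
        f"prop_{conds[0]}": count_a / n_a,
        f"prop_{conds[1]}": count_b / n_b,
        "delta": obs,
        "p": pvals,
        "q": multipletests(pvals, method="fdr_bh")[1],
    })
    return table


def two_proportion_chi2(k1: int, n1: int, k2: int, n2: int
                        ) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) comparing
    ``k1/n1`` against ``k2/n2``."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if k1 > n1 or k2 > n2 or k1 < 0 or k2 < 0:
        raise ValueError("successes must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if table.sum(axis=0).min() == 0:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


@dataclass
class LimitingDilutionResult:
    """Single-hit frequency estimate, reported as '1 in 1/f'."""

    frequency: float
    one_in: float
    ci_lower: float          # lower bound on f
    ci_upper: float
    degenerate: bool = False

    def __str__(self) -> str:
        return f"1 in {self.one_in:.1f} (95% CI 1 in " \
               f"{1 / self.ci_upper:.1f} to 1 in {1 / self.ci_lower:.1f})"


def limiting_dilution_frequency(data: pd.DataFrame
                                ) -> LimitingDilutionResult:
    """ELDA-style single-hit Poisson frequency from limiting dilutions.

    ``data`` columns: ``dose`` (cells transplanted), ``n_tested``
    (recipients), ``n_responding`` (engrafted). Model:
    ``P(respond | dose d) = 1 - exp(-f d)``, fit as a binomial GLM with a
    complementary log-log link and offset ``ln d``; ``f = exp(intercept)``,
    Wald 95% CI on the log scale. All-responding (or none-responding) data
    yield an unbounded estimate, returned as a flagged bound.
    """
    import statsmodels.api as sm
    req = {"dose", "n_tested", "n_responding"}
    if not req.issubset(data.columns):
        raise ValueError(f"columns {sorted(req)} required")
    if (data["dose"] <= 0).any():
        raise ValueError("doses must be positive")
    if ((data["n_responding"] < 0)
            | (data["n_responding"] > data["n_tested"])).any():
        raise ValueError("0 <= n_responding <= n_tested violated")
    r = data["n_responding"].to_numpy(dtype=float)
    n = data["n_tested"].to_numpy(dtype=float)
    if r.sum() == 0 or (n - r).sum() == 0:
        # no informative dose: only a one-sided bound exists
        total_cells = float((data["dose"] * data["n_tested"]).sum())
        if r.sum() == 0:
            f = 1e-12
            bound = -np.log(0.5) / total_cells
            return LimitingDilutionResult(f, 1 / f, 0.0, bound,
                                          degenerate=True)
        f = 1.0
        return LimitingDilutionResult(f, 1.0, -np.log(0.5) / total_cells,
                                      np.inf, degenerate=True)
    endog = np.column_stack([r, n - r])
    exog = np.ones((len(data), 1))
    offset = np.log(data["dose"].to_numpy(dtype=float))
    glm = sm.GLM(endog, exog,
                 family=sm.families.Binomial(sm.families.links.CLogLog()),
                 offset=offset)
    import warnings
    with warnings.catch_warnings():
        # saturated single-dose designs have zero residual df; the Wald SE
        # of the intercept is unaffected
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = glm.fit()
    b, se = float(fit.params[0]), float(fit.bse[0])
    f = np.exp(b)
    lo, hi = np.exp(b - 1.959963984540054 * se), \
        np.exp(b + 1.959963984540054 * se)
    return LimitingDilutionResult(f, 1.0 / f, lo, hi)
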