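"""Statistical primitives for the polarity analyses.

Every hypothesis test used by the pipeline lives here so that conventions
(two-sided definitions, tie handling, missing-value policy) are fixed in one
place.  Standard tests are delegated to scipy/statsmodels; the conventions
wrapped around them (sign-test small/large-n switch, rank-based partial
correlation, complete-case handling) are this module's job.

Missing values are represented as NaN and removed per analysis
(complete-case); every result records the effective sample size actually
used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "ContingencyTable2x2",
    "exact_sign_test",
    "mann_whitney",
    "spearman",
    "partial_spearman",
    "fisher_2x2",
    "kruskal_wallis",
    "bh_fdr",
    "residualize",
    "binary_encode",
]

#: Largest number of informative pairs for which the sign test is computed
#: from the exact binomial distribution; above this the classic
#: continuity-corrected normal approximation is used.
SIGN_TEST_EXACT_MAX = 25

#: Largest per-group size for which the Mann-Whitney p-value is computed by
#: exact enumeration (only when the pooled sample is tie-free).
MANN_WHITNEY_EXACT_MAX = 8


@dataclass
class TestResult:
    """Outcome of a single hypothesis test.

    Attributes
    ----------
    method : str
        Name of the test.
    statistic : float
        The test statistic (U, rho, H, odds ratio, ... depending on method).
    p_value : float
        Two-sided p-value in (0, 1].
    n : int | tuple
        Effective sample size(s) after missing-value removal.
    extras : dict
        Method-specific values (group medians, means, degrees of freedom...).
    """

    __test__ = False  # not a pytest collection target

    method: str
    statistic: float
    p_value: float
    n: Any
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """A 2x2 contingency table with cells [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 or x != int(x) for x in cells):
            raise ValueError("contingency cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def _clean(x: Sequence[float]) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[~np.isnan(arr)]


def exact_sign_test(n_greater: int, n_less: int) -> TestResult:
    """Two-sided sign test on paired greater/less counts (ties pre-excluded).

    For ``n = n_greater + n_less`` up to 25 informative pairs the p-value is
    the exact two-sided binomial probability (minimum-likelihood convention);
    for larger n the continuity-corrected normal approximation is used, the
    convention of classic statistical packages for the paired sign test.

    The result is symmetric in its two arguments.
    """
    if n_greater < 0 or n_less < 0:
        raise ValueError("counts must be non-negative")
    n = n_greater + n_less
    if n == 0:
        raise ValueError("sign test requires at least one informative pair")
    if n <= SIGN_TEST_EXACT_MAX:
        p = sps.binomtest(n_greater, n, 0.5).pvalue
        method = "sign-test-exact"
        stat = float(n_greater)
    else:
        z = (abs(n_greater - n / 2.0) - 0.5) / math.sqrt(n / 4.0)
        p = float(2.0 * sps.norm.sf(z))
        method = "sign-test-normal"
        stat = z
    return TestResult(method, stat, min(float(p), 1.0), n,
                      {"n_greater": n_greater, "n_less": n_less})


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when both groups have at most 8 observations and
    the pooled sample is tie-free; otherwise the normal approximation with
    tie and continuity corrections.  Group sizes, medians and means are
    reported alongside U.
    """
    a, b = _clean(sample_a), _clean(sample_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires two non-empty samples")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if a.size <= MANN_WHITNEY_EXACT_MAX and b.size <= MANN_WHITNEY_EXACT_MAX and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(
        f"mann-whitney-{method}", float(res.statistic), float(res.pvalue),
        (int(a.size), int(b.size)),
        {
            "median_a": float(np.median(a)), "median_b": float(np.median(b)),
            "mean_a": float(np.mean(a)), "mean_b": float(np.mean(b)),
        },
    )


def _complete_rows(*cols: Sequence[float]) -> list[np.ndarray]:
    arrs = [np.asarray(c, dtype=float) for c in cols]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("inputs must have equal length")
    mask = ~np.any(np.isnan(np.vstack(arrs)), axis=0)
    return [a[mask] for a in arrs]


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with midranks for ties.

    The two-sided p-value uses the t approximation on n - 2 degrees of
    freedom (appropriate for the sample sizes the pipeline works at).
    """
    xc, yc = _complete_rows(x, y)
    if xc.size < 4:
        raise ValueError("spearman requires at least 4 complete pairs")
    if np.unique(xc).size < 2 or np.unique(yc).size < 2:
        raise ValueError("spearman undefined for constant input")
    rho, p = sps.spearmanr(xc, yc)
    return TestResult("spearman", float(rho), float(p), int(xc.size), {})


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    controls: Sequence[Sequence[float]] = (),
    control_names: Sequence[str] | None = None,
) -> TestResult:
    """Rank-based partial correlation of ``x`` and ``y`` given ``controls``.

    All variables are converted to midranks over the complete-case rows.
    The x- and y-ranks are each residualized on the control ranks by least
    squares (with intercept) and the partial rho is the Pearson correlation
    of the two residual series.  The two-sided p-value uses the t
    approximation on n - 2 - k degrees of freedom, k the number of controls.
    With no controls this reduces exactly to :func:`spearman`.
    """
    controls = list(controls)
    k = len(controls)
    names = list(control_names) if control_names is not None else [
        f"control_{i}" for i in range(k)]
    cols = _complete_rows(x, y, *controls)
    xc, yc, ctl = cols[0], cols[1], cols[2:]
    n = xc.size
    if n < k + 4:
        raise ValueError("partial_spearman requires at least k + 4 complete rows")
    rx = sps.rankdata(xc)
    ry = sps.rankdata(yc)
    if np.unique(rx).size < 2 or np.unique(ry).size < 2:
        raise ValueError("partial_spearman undefined for constant input")
    if k:
        design = np.column_stack([np.ones(n)] + [sps.rankdata(c) for c in ctl])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            # identify the first control whose rank column is linearly
            # dependent on the previous ones
            for j in range(1, design.shape[1]):
                if np.linalg.matrix_rank(design[:, : j + 1]) < j + 1:
                    raise ValueError(
                        f"collinear control variable: {names[j - 1]}")
        rx = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
        ry = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("partial_spearman undefined: residuals are constant")
    if k:
        rho = float(rx @ ry) / denom
    else:
        rho = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    rho_c = max(min(rho, 1.0), -1.0)
    if abs(rho_c) == 1.0:
        p = 0.0
    else:
        t = rho_c * math.sqrt(df / (1.0 - rho_c * rho_c))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult("partial-spearman", rho_c, p, n,
                      {"df": df, "n_controls": k})


def fisher_2x2(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities not exceeding that of the
    observed table (minimum-likelihood convention); the sample odds ratio is
    reported as the statistic.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("fisher_2x2 requires all margins to be positive")
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult("fisher-exact", float(odds), float(p), int(arr.sum()), {})


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test across two or more groups, with tie correction."""
    cleaned = [_clean(g) for g in groups]
    cleaned = [g for g in cleaned if g.size > 0]
    if len(cleaned) < 2:
        raise ValueError("kruskal_wallis requires at least 2 non-empty groups")
    pooled = np.concatenate(cleaned)
    if np.unique(pooled).size == 1:
        # all observations identical: H = 0 by definition, no evidence
        return TestResult("kruskal-wallis", 0.0, 1.0,
                          tuple(int(g.size) for g in cleaned),
                          {"df": len(cleaned) - 1})
    h, p = sps.kruskal(*cleaned)
    return TestResult("kruskal-wallis", float(h), float(p),
                      tuple(int(g.size) for g in cleaned),
                      {"df": len(cleaned) - 1})


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def residualize(y: Sequence[float], x: Sequence[float]) -> np.ndarray:
    """Residuals of the OLS fit of ``y`` on ``x`` (with intercept).

    Rows where either value is missing propagate NaN; the fit uses
    complete cases only.  Residuals are aligned with the input order.
    """
    ya = np.asarray(y, dtype=float)
    xa = np.asarray(x, dtype=float)
    if ya.size != xa.size:
        raise ValueError("inputs must have equal length")
    mask = ~(np.isnan(ya) | np.isnan(xa))
    if mask.sum() < 3:
        raise ValueError("residualize requires at least 3 complete pairs")
    xs, ys = xa[mask], ya[mask]
    if np.unique(xs).size < 2:
        raise ValueError("residualize requires a non-constant predictor")
    design = np.column_stack([np.ones(xs.size), xs])
    beta = np.linalg.lstsq(design, ys, rcond=None)[0]
    out = np.full(ya.size, np.nan)
    out[mask] = ys - design @ beta
    return out


def binary_encode(position_classes: Mapping[str, str]) -> dict[str, float]:
    """Encode position classes as a binary variable: upstream 1, downstream 0.

    Intermediate and isolated genes get NaN (they do not enter the
    upstream-vs-downstream contrast).
    """
    code = {"upstream": 1.0, "downstream": 0.0}
    return {g: code.get(c, float("nan")) for g, c in position_classes.items()}
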