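"""Between-group inference on activity compositions and breeding success.

Per-bird time budgets (p_water, p_flight, p_forage) are compositional: the
three parts sum to 1, so their 3-D covariance is singular and a bird that
flies more necessarily does something else less. Group comparisons therefore
operate on the 2-D sub-composition (p_water, p_flight) by default (an
isometric log-ratio transform is available as an alternative for strictly
positive compositions) and use James's (1954) two-sample statistic for
multivariate means with unequal group covariances,

    J = (x̄_a − x̄_b)ᵀ (S_a/n_a + S_b/n_b)⁻¹ (x̄_a − x̄_b),

with a nonparametric p-value from a bootstrap null: each group is centered at
the pooled mean, birds are resampled with replacement within groups, and
p = (1 + #{J* ≥ J_obs}) / (n_boot + 1). James's second-order chi-square
critical-value expansion is provided for reference output.

Breeding success is summarized as the standard stage-wise nest proportions:
laying (eggs/nests), hatching (hatched/eggs), fledging (fledged/hatched) and
overall (fledged/nests), which is their product when all stages are defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan

import numpy as np
from scipy import stats as _sps

__all__ = [
    "subcomposition",
    "ilr_transform",
    "james_statistic",
    "james_bootstrap_p",
    "james_critical_value",
    "JamesResult",
    "breeding_success",
    "BreedingSuccess",
]


def subcomposition(comps: np.ndarray, drop: int = 2) -> np.ndarray:
    """Drop one component of an (n, 3) composition array (default the third,
    p_forage), removing the sum-to-1 degeneracy."""
    comps = np.asarray(comps, dtype=float)
    keep = [i for i in range(comps.shape[1]) if i != drop]
    return comps[:, keep]


def ilr_transform(comps: np.ndarray) -> np.ndarray:
    """Isometric log-ratio coordinates of an (n, 3) composition (requires all
    parts > 0); an alternative de-degenerated representation."""
    c = np.asarray(comps, dtype=float)
    if np.any(c <= 0):
        raise ValueError("ilr requires strictly positive components")
    z1 = np.sqrt(0.5) * np.log(c[:, 0] / c[:, 1])
    z2 = np.sqrt(2.0 / 3.0) * np.log(np.sqrt(c[:, 0] * c[:, 1]) / c[:, 2])
    return np.column_stack([z1, z2])


def _prep(group: np.ndarray) -> np.ndarray:
    g = np.atleast_2d(np.asarray(group, dtype=float))
    if g.ndim != 2:
        raise ValueError("group must be a 2-D array (birds x components)")
    return g


def james_statistic(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """James's two-sample quadratic-form statistic for multivariate means.

    Inputs are (n, p) arrays of per-bird coordinates (already
    de-degenerated, e.g. via :func:`subcomposition`). Covariances use n−1
    denominators. Symmetric in group order; zero iff the means coincide.
    """
    a, b = _prep(group_a), _prep(group_b)
    n_a, n_b = len(a), len(b)
    if n_a < 3 or n_b < 3:
        raise ValueError("James statistic needs at least 3 samples per group")
    d = a.mean(axis=0) - b.mean(axis=0)
    V = np.cov(a, rowvar=False, ddof=1) / n_a + np.cov(b, rowvar=False, ddof=1) / n_b
    V = np.atleast_2d(V)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0 or logdet < -200:
        raise np.linalg.LinAlgError(
            "singular combined covariance; drop a redundant component or regularize"
        )
    return float(d @ np.linalg.solve(V, d))


def james_critical_value(group_a: np.ndarray, group_b: np.ndarray, alpha: float = 0.05) -> float:
    """James's (1954) second-order chi-square critical value for J at level
    alpha — the series-expansion calibration, reported for reference (the
    bootstrap p-value is the headline inference)."""
    a, b = _prep(group_a), _prep(group_b)
    p = a.shape[1]
    W = []
    for g in (a, b):
        W.append(np.atleast_2d(np.cov(g, rowvar=False, ddof=1)) / len(g))
    V = W[0] + W[1]
    Vinv = np.linalg.inv(V)
    tr1 = [np.trace(Vinv @ Wi) for Wi in W]
    tr2 = [np.trace(Vinv @ Wi @ Vinv @ Wi) for Wi in W]
    nu = [len(a) - 1, len(b) - 1]
    A = 1.0 + (1.0 / (2.0 * p)) * sum(t**2 / v for t, v in zip(tr1, nu))
    B = (1.0 / (p * (p + 2.0))) * (
        sum(t / v for t, v in zip(tr2, nu)) + 0.5 * sum(t**2 / v for t, v in zip(tr1, nu))
    )
    chi2 = _sps.chi2.ppf(1.0 - alpha, df=p)
    return float(chi2 * (A + B * chi2))


@dataclass(frozen=True)
class JamesResult:
    statistic: float
    df_dim: int
    p_boot: float
    n_boot: int
    seed: int | None


def _boot_statistics(a: np.ndarray, b: np.ndarray, n_boot: int, rng) -> np.ndarray:
    """Vectorized recomputation of J over bootstrap resamples of two
    (already centered) groups."""
    out = np.empty(n_boot)
    n_a, n_b = len(a), len(b)
    p = a.shape[1]
    ia = rng.integers(0, n_a, size=(n_boot, n_a))
    ib = rng.integers(0, n_b, size=(n_boot, n_b))
    xa = a[ia]  # (B, n_a, p)
    xb = b[ib]
    ma = xa.mean(axis=1)
    mb = xb.mean(axis=1)
    ca = xa - ma[:, None, :]
    cb = xb - mb[:, None, :]
    Sa = np.einsum("bij,bik->bjk", ca, ca) / (n_a - 1)
    Sb = np.einsum("bij,bik->bjk", cb, cb) / (n_b - 1)
    V = Sa / n_a + Sb / n_b
    d = ma - mb
    for r in range(n_boot):
        try:
            out[r] = d[r] @ np.linalg.solve(V[r], d[r])
        except np.linalg.LinAlgError:
            out[r] = np.inf  # degenerate resample counts against H0 conservatively
    _ = p
    return out


def james_bootstrap_p(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
) -> JamesResult:
    """James statistic with a bootstrap p-value (default 1000 resamples).

    The null is imposed by translating each group to the pooled mean, which
    preserves within-group covariance while equalizing means. The +1
    continuity correction keeps p strictly positive.
    """
    a, b = _prep(group_a), _prep(group_b)
    j_obs = james_statistic(a, b)
    pooled = np.vstack([a, b]).mean(axis=0)
    a0 = a - a.mean(axis=0) + pooled
    b0 = b - b.mean(axis=0) + pooled
    rng = np.random.default_rng(seed)
    j_star = _boot_statistics(a0, b0, n_boot, rng)
    p = (1.0 + np.sum(j_star >= j_obs)) / (n_boot + 1.0)
    return JamesResult(statistic=j_obs, df_dim=a.shape[1], p_boot=float(p), n_boot=n_boot, seed=seed)


@dataclass(frozen=True)
class BreedingSuccess:
    """Stage-wise nest proportions; undefined stages (zero denominator) are NaN."""

    laying: float
    hatching: float
    fledging: float
    overall: float


def breeding_success(
    n_nests: int, n_with_eggs: int, n_hatched: int, n_fledged: int
) -> BreedingSuccess:
    """Laying, hatching, fledging and overall breeding success of one
    colony-year's monitored nests.

    Counts must be monotone non-increasing through the stages. Overall
    success (fledged/nests) equals laying × hatching × fledging whenever all
    three are defined.
    """
    counts = (n_nests, n_with_eggs, n_hatched, n_fledged)
    if any(c < 0 for c in counts):
        raise ValueError("negative nest count")
    if not (n_nests >= n_with_eggs >= n_hatched >= n_fledged):
        raise ValueError(f"nest counts must be monotone non-increasing, got {counts}")
    if n_nests == 0:
        raise ValueError("no nests monitored")
    laying = n_with_eggs / n_nests
    hatching = n_hatched / n_with_eggs if n_with_eggs > 0 else nan
    fledging = n_fledged / n_hatched if n_hatched > 0 else nan
    overall = n_fledged / n_nests
    return BreedingSuccess(laying=laying, hatching=hatching, fledging=fledging, overall=overall)
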