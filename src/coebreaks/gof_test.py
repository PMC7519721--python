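"""Equal-probability chi-squared goodness-of-fit with Monte-Carlo p-value.

The null hypothesis is that each scored pair falls into each category with
equal probability.  The test statistic is Pearson's X² = Σ (Oᵢ−Eᵢ)²/Eᵢ
with Eᵢ = pᵢ·N; its null distribution is approximated by drawing B
multinomial(N, p) replicates rather than relying on the asymptotic χ²
distribution, and the p-value uses the add-one estimator
(1 + #{T_b ≥ T_obs}) / (B + 1), which never returns zero.

The across-boundary test uses three categories (break / uncertain /
homogeneity) with equal thirds; the within-centre test two categories
(break / homogeneity) with equal halves.

An exact small-sample p-value by full multinomial enumeration is provided
as an independent check for tiny instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import isclose
from typing import Sequence, Tuple

import numpy as np
from scipy.stats import multinomial as _scipy_multinomial

__all__ = ["GofResult", "chisq_stat", "mc_pvalue", "exact_pvalue_small"]


@dataclass(frozen=True)
class GofResult:
    """Outcome of one Monte-Carlo goodness-of-fit test."""

    observed: Tuple[int, ...]
    probs: Tuple[float, ...]
    statistic: float
    df: int  # k-1, reported for reference only
    p_mc: float
    replicates: int
    seed: int


def _validate(observed: Sequence[int], probs: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(probs, dtype=float)
    if o.ndim != 1 or p.ndim != 1 or o.size != p.size or o.size < 2:
        raise ValueError(
            f"need matching 1-d observed/probs of length >= 2, got {o.shape} vs {p.shape}"
        )
    if (o < 0).any() or o.sum() <= 0:
        raise ValueError("observed counts must be non-negative with a positive total")
    if not isclose(p.sum(), 1.0, abs_tol=1e-12):
        raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
    if (p <= 0).any():
        raise ValueError("zero expected count in a category; drop it or adjust probs")
    return o, p


def chisq_stat(observed: Sequence[int], probs: Sequence[float]) -> float:
    """Pearson chi-squared statistic against expected proportions ``probs``."""
    o, p = _validate(observed, probs)
    e = p * o.sum()
    return float(((o - e) ** 2 / e).sum())


def mc_pvalue(
    observed: Sequence[int],
    probs: Sequence[float],
    B: int = 10_000,
    seed: int = 0,
) -> GofResult:
    """Monte-Carlo goodness-of-fit test; deterministic given ``seed``.

    Draws ``B`` multinomial(N, probs) replicate tallies, computes their
    chi-squared statistics and returns p = (1 + #{T_b >= T_obs}) / (B + 1).
    """
    o, p = _validate(observed, probs)
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    n = int(round(o.sum()))
    t_obs = chisq_stat(observed, probs)
    rng = np.random.default_rng(seed)
    reps = rng.multinomial(n, p, size=B).astype(float)
    e = p * n
    t_rep = ((reps - e) ** 2 / e).sum(axis=1)
    # tiny slack guards against FP noise when a replicate equals the observed
    exceed = int((t_rep >= t_obs - 1e-9).sum())
    return GofResult(
        observed=tuple(int(x) for x in o),
        probs=tuple(float(x) for x in p),
        statistic=t_obs,
        df=len(o) - 1,
        p_mc=(1 + exceed) / (B + 1),
        replicates=B,
        seed=seed,
    )


def _compositions(total: int, k: int):
    """All k-part compositions of ``total`` (ordered, non-negative)."""
    for cuts in combinations(range(total + k - 1), k - 1):
        prev, parts = -1, []
        for c in cuts:
            parts.append(c - prev - 1)
            prev = c
        parts.append(total + k - 2 - prev)
        yield tuple(parts)


def exact_pvalue_small(observed: Sequence[int], probs: Sequence[float]) -> float:
    """Exact P(T >= T_obs) by full multinomial enumeration.

    Tractable only for small instances (N <= 20, at most 3 categories);
    intended as a test oracle for :func:`mc_pvalue`.
    """
    o, p = _validate(observed, probs)
    n = int(round(o.sum()))
    k = o.size
    if n > 20 or k > 3:
        raise ValueError(f"instance too large for enumeration: N={n}, k={k}")
    t_obs = chisq_stat(observed, probs)
    total = 0.0
    for counts in _compositions(n, k):
        t = chisq_stat(counts, p) if sum(counts) else 0.0
        if t >= t_obs - 1e-9:
            total += float(_scipy_multinomial.pmf(counts, n, p))
    return min(total, 1.0)
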