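"""Individual-based and coverage-based rarefaction, diversity partitioning, β_C.

Observed richness differences between samples confound two processes: samples
with more individuals capture more of the regional pool purely by passive
sampling (the N-component), and samples may genuinely draw from differently
even abundance distributions or pools (the SAD-component).  Rarefying every
trap to a common number of individuals ``n_ref`` isolates the SAD part:

    SAD-component = E[S_{n_ref}]          (expected richness at n_ref)
    N-component   = S_obs - E[S_{n_ref}]  (richness owed to extra individuals)

so the two components add back to observed richness.

Between-sample (beta) diversity is biased by sample completeness, so pooled
(gamma) and mean per-trap (alpha) richness are first standardized to a common
sample *coverage* C (the estimated fraction of individuals in the assemblage
belonging to sampled taxa):

    beta_C = S_gamma(C) / mean_i S_alpha_i(C)   >= 1

Coverage at a rarefied size n is one minus the rarefaction-curve slope,
``C_n = 1 - (E[S_{n+1}] - E[S_n])``; full-sample coverage uses the
singleton/doubleton estimator.  The resampling null draws fixed-size trap
subsets and recomputes beta_C, yielding a distribution per lifecycle group.

All binomial coefficients are evaluated in log space (gammaln) so large
assemblages do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "rarefied_richness",
    "rarefaction_curve",
    "filter_traps",
    "reference_subsample_size",
    "partition_diversity",
    "expected_coverage",
    "coverage_profile",
    "richness_at_coverage",
    "max_standardizable_coverage",
    "beta_C",
    "beta_C_distribution",
    "shuffle_null_beta_C",
    "BetaCResult",
]

_TOL = 1e-9


def _counts_array(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=np.int64).ravel()
    if (c < 0).any():
        raise ValueError("negative abundances")
    return c[c > 0]


def rarefied_richness(counts, n: int) -> float:
    """Expected richness E[S_n] in a subsample of ``n`` individuals.

    Exact expectation under sampling without replacement (hypergeometric):
    ``E[S_n] = sum_i [1 - C(N - n_i, n) / C(N, n)]``, computed in log space.
    Requires ``1 <= n <= N``; no extrapolation.
    """
    c = _counts_array(counts)
    N = int(c.sum())
    if N == 0:
        raise ValueError("empty assemblage")
    if not 1 <= n <= N:
        raise ValueError(f"subsample size n={n} outside [1, N={N}]")
    # log C(N - n_i, n) - log C(N, n); zero probability when N - n_i < n
    rem = N - c
    with np.errstate(invalid="ignore"):
        log_num = gammaln(rem + 1) - gammaln(n + 1) - gammaln(rem - n + 1)
    log_den = gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)
    p_absent = np.where(rem >= n, np.exp(log_num - log_den), 0.0)
    return float(np.sum(1.0 - p_absent))


def rarefaction_curve(counts) -> np.ndarray:
    """E[S_n] for n = 1..N (index 0 holds n = 1), vectorized over n."""
    c = _counts_array(counts)
    N = int(c.sum())
    if N == 0:
        raise ValueError("empty assemblage")
    n = np.arange(1, N + 1)
    rem = N - c  # per-taxon individuals outside the taxon
    log_num = (
        gammaln(rem[:, None] + 1)
        - gammaln(n[None, :] + 1)
        - gammaln(np.maximum(rem[:, None] - n[None, :], 0) + 1)
    )
    log_den = gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)
    valid = rem[:, None] >= n[None, :]
    p_absent = np.where(valid, np.exp(log_num - log_den[None, :]), 0.0)
    return (1.0 - p_absent).sum(axis=0)


def filter_traps(matrix: pd.DataFrame) -> pd.Index:
    """Traps whose total abundance strictly exceeds their observed richness.

    ``matrix`` is a trap x taxon count table (traps as the index).  Returns
    the index of retained traps: N > S_obs, strictly.
    """
    counts = matrix.to_numpy()
    N = counts.sum(axis=1)
    S = (counts > 0).sum(axis=1)
    return matrix.index[N > S]


def reference_subsample_size(matrix: pd.DataFrame, prefilter: bool = True) -> int:
    """Minimum per-trap total abundance across (filtered) traps.

    This is the common subsample size for the N/SAD partition.  By default the
    N > S trap filter is applied first.
    """
    if prefilter:
        matrix = matrix.loc[filter_traps(matrix)]
    if matrix.shape[0] == 0:
        raise ValueError("no traps remain after filtering")
    return int(matrix.sum(axis=1).min())


def partition_diversity(
    matrix: pd.DataFrame,
    n_ref: int | None = None,
    scale: str = "additive",
) -> pd.DataFrame:
    """Partition each trap's observed richness into SAD and N components.

    ``SAD = E[S_{n_ref}]`` and, on the default additive scale,
    ``N = S_obs - SAD`` so the components sum to observed richness.  The
    multiplicative variant returns ``N = log(S_obs) - log(SAD)`` and
    ``SAD = log E[S_{n_ref}]`` (components sum to ``log S_obs``).

    Traps are pre-filtered with :func:`filter_traps`; when ``n_ref`` is None
    it is the filtered minimum per-trap N.
    """
    if scale not in ("additive", "multiplicative"):
        raise ValueError("scale must be 'additive' or 'multiplicative'")
    included = filter_traps(matrix)
    sub = matrix.loc[included]
    if n_ref is None:
        n_ref = reference_subsample_size(sub, prefilter=False)
    totals = sub.sum(axis=1)
    if (totals < n_ref).any():
        bad = totals.index[totals < n_ref].tolist()
        raise ValueError(f"n_ref={n_ref} exceeds total abundance at traps {bad}")
    rows = []
    for trap_id, row in sub.iterrows():
        c = row.to_numpy()
        s_obs = float((c > 0).sum())
        sad = rarefied_richness(c, n_ref)
        if scale == "additive":
            rows.append((trap_id, s_obs, sad, s_obs - sad, n_ref))
        else:
            rows.append((trap_id, s_obs, np.log(sad), np.log(s_obs) - np.log(sad), n_ref))
    return pd.DataFrame(
        rows, columns=["trap_id", "s_obs", "sad_component", "n_component", "n_ref"]
    ).set_index("trap_id")


def expected_coverage(counts, n: int) -> float:
    """Expected sample coverage C_n at rarefied size ``n``.

    For ``1 <= n <= N - 1`` this is the rarefaction-slope identity
    ``C_n = 1 - (E[S_{n+1}] - E[S_n])``; at ``n = N`` the singleton/doubleton
    estimator ``1 - (f1/N) * ((N-1) f1 / ((N-1) f1 + 2 f2))`` is used
    (coverage 1 when there are no singletons).
    """
    c = _counts_array(counts)
    N = int(c.sum())
    if not 1 <= n <= N:
        raise ValueError(f"n={n} outside [1, N={N}]")
    if n == N:
        f1 = int((c == 1).sum())
        f2 = int((c == 2).sum())
        if f1 == 0:
            return 1.0
        denom = (N - 1) * f1 + 2 * f2
        return float(1.0 - (f1 / N) * ((N - 1) * f1 / denom))
    return float(1.0 - (rarefied_richness(c, n + 1) - rarefied_richness(c, n)))


def coverage_profile(counts) -> np.ndarray:
    """C_n for n = 1..N.  Non-decreasing in n."""
    c = _counts_array(counts)
    N = int(c.sum())
    es = rarefaction_curve(c)
    prof = np.empty(N)
    prof[: N - 1] = 1.0 - np.diff(es)
    prof[N - 1] = expected_coverage(c, N)
    return prof


def richness_at_coverage(counts, c_target: float, below_c1: str = "floor") -> float:
    """Expected richness rarefied to coverage ``c_target``.

    Finds the largest integer n with ``C_n <= c_target`` and linearly
    interpolates E[S] between n and n+1 on the coverage scale.  Coverage above
    the assemblage's full-sample coverage raises (no extrapolation).  A target
    below C_1 is handled per ``below_c1``: ``"floor"`` returns E[S_1] (the
    default boundary rule), ``"extend"`` anchors the curve at (C=0, S=0) and
    interpolates — the convention used inside beta_C so heavily dominated
    pooled assemblages are not clipped — and ``"error"`` raises.
    """
    if below_c1 not in ("floor", "extend", "error"):
        raise ValueError("below_c1 must be 'floor', 'extend' or 'error'")
    c = _counts_array(counts)
    N = int(c.sum())
    prof = coverage_profile(c)
    es = rarefaction_curve(c)
    if c_target > prof[-1] + _TOL:
        raise ValueError(
            f"target coverage {c_target} exceeds attainable coverage {prof[-1]:.6f}"
        )
    if c_target < prof[0]:
        if below_c1 == "floor":
            return float(es[0])
        if below_c1 == "extend":
            return float(es[0] * c_target / prof[0]) if prof[0] > 0 else float(es[0])
        raise ValueError(f"target coverage {c_target} below C_1 = {prof[0]:.6f}")
    # largest n (1-based) with C_n <= c_target
    idx = int(np.searchsorted(prof, c_target, side="right")) - 1
    idx = max(0, min(idx, N - 1))
    if idx == N - 1 or abs(prof[idx] - c_target) <= _TOL:
        return float(es[idx])
    c0, c1 = prof[idx], prof[idx + 1]
    if c1 - c0 <= _TOL:
        return float(es[idx])
    t = (c_target - c0) / (c1 - c0)
    return float(es[idx] + t * (es[idx + 1] - es[idx]))


def max_standardizable_coverage(matrix: pd.DataFrame, prefilter: bool = True) -> float:
    """Largest coverage every trap in the group can be rarefied to (MC).

    The minimum over included traps of the trap's full-sample coverage C_N.
    Requires at least two included traps.
    """
    if prefilter:
        matrix = matrix.loc[filter_traps(matrix)]
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 included traps to standardize coverage")
    covs = []
    for _, row in matrix.iterrows():
        c = row.to_numpy()
        covs.append(expected_coverage(c, int(c.sum())))
    return float(min(covs))


def _multinomial_coverage(p: np.ndarray, n: float) -> float:
    return float(1.0 - np.sum(p * np.power(1.0 - p, n)))


def _multinomial_depth_at_coverage(p: np.ndarray, c_target: float) -> float:
    """Real-valued depth n at which the with-replacement coverage of the
    composition ``p`` reaches ``c_target`` (bisection; coverage is monotone
    in n and attains any target below 1)."""
    if not 0.0 <= c_target < 1.0:
        raise ValueError(f"coverage target {c_target} outside [0, 1)")
    lo, hi = 0.0, 1.0
    while _multinomial_coverage(p, hi) < c_target and hi < 1e12:
        hi *= 2.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _multinomial_coverage(p, mid) < c_target:
            lo = mid
        else:
            hi = mid
    # depths below one individual are degenerate (and break the concavity
    # argument that bounds beta at 1); clamp to n = 1
    return max(0.5 * (lo + hi), 1.0)


def _multinomial_richness(p: np.ndarray, n: float) -> float:
    """Coleman curve ``E[S_n] = sum_i [1 - (1 - p_i)^n]`` at real depth n;
    depends only on relative abundances."""
    return float(np.sum(1.0 - np.power(1.0 - p[p > 0], n)))


def beta_C(matrix: pd.DataFrame, c_target: float, method: str = "coverage") -> float:
    """Coverage-standardized beta diversity of a set of traps.

    ``beta_C = S_gamma(C) / mean_i S_alpha_i(C)``.  Two variants of the
    underlying standardization are provided:

    * ``"coverage"`` (default): hypergeometric richness-at-coverage of the raw
      pooled assemblage over the mean per-trap richness-at-coverage.  This
      variant is null-calibrated — its mean under random placement of
      individuals is 1 within Monte-Carlo error — but carries a small
      finite-size boundary bias (identical traps give ~0.99 rather than 1).
    * ``"composition"``: with-replacement (Coleman) curves on relative
      abundances, all evaluated at the single real-valued depth n* at which
      the mean trap composition reaches the target coverage.  Because richness
      at fixed depth is concave in composition, this variant is provably >= 1
      and exactly 1 when all traps share a composition, at the cost of a
      small positive bias under the random-placement null.
    """
    counts = matrix.to_numpy(dtype=float)
    if counts.shape[0] == 0:
        raise ValueError("empty trap subset")
    if method == "coverage":
        pooled = counts.sum(axis=0)
        gamma = richness_at_coverage(pooled, c_target, below_c1="extend")
        alphas = [
            richness_at_coverage(row, c_target, below_c1="extend") for row in counts
        ]
    elif method == "composition":
        props = counts / counts.sum(axis=1, keepdims=True)
        p_bar = props.mean(axis=0)
        n_star = _multinomial_depth_at_coverage(p_bar, c_target)
        gamma = _multinomial_richness(p_bar, n_star)
        alphas = [_multinomial_richness(row, n_star) for row in props]
    else:
        raise ValueError("method must be 'coverage' or 'composition'")
    return float(gamma / np.mean(alphas))


@dataclass
class BetaCResult:
    """Resampled beta_C distribution for one lifecycle group."""

    group: str
    mc: float
    c_target: float
    subset_size: int
    n_randomizations: int
    seed: int
    beta_values: np.ndarray = field(repr=False)

    @property
    def mean(self) -> float:
        return float(np.mean(self.beta_values))

    @property
    def sd(self) -> float:
        return float(np.std(self.beta_values, ddof=1)) if len(self.beta_values) > 1 else 0.0


def beta_C_distribution(
    matrix: pd.DataFrame,
    lifecycles: pd.Series | dict,
    group: str,
    subset_size: int = 99,
    n_rand: int = 9999,
    seed: int = 0,
    c_target: float | None = None,
    method: str = "coverage",
) -> BetaCResult:
    """Trap-resampling distribution of beta_C for one lifecycle group.

    The trap x taxon matrix is restricted to the group's taxa and filtered
    (N > S); each randomization draws ``subset_size`` traps uniformly without
    replacement and computes beta_C at the shared target coverage.  When
    ``c_target`` is None it is ``min(MC_terrestrial, MC_aquatic) - 0.01``,
    computed from this same matrix, so the two groups are standardized to a
    common coverage.
    """
    life = pd.Series(lifecycles)
    if c_target is None:
        mcs = []
        for g in ("terrestrial", "aquatic"):
            cols = [c for c in matrix.columns if life.get(c) == g]
            if cols:
                sub_g = matrix[cols]
                sub_g = sub_g.loc[filter_traps(sub_g)]
                if sub_g.shape[0] >= 2:
                    mcs.append(max_standardizable_coverage(sub_g, prefilter=False))
        if not mcs:
            raise ValueError("no lifecycle group with enough traps to set coverage")
        c_target = min(mcs) - 0.01
    cols = [c for c in matrix.columns if life.get(c) == group]
    if not cols:
        raise ValueError(f"no taxa in lifecycle group {group!r}")
    sub = matrix[cols]
    sub = sub.loc[filter_traps(sub)]
    n_traps = sub.shape[0]
    if n_traps < subset_size:
        raise ValueError(f"subset_size {subset_size} exceeds the {n_traps} included traps")
    mc = max_standardizable_coverage(sub, prefilter=False)
    counts = sub.to_numpy(dtype=float)
    # per-trap alpha richness at C is subset-independent: precompute once
    if method == "coverage":
        alphas = np.array(
            [richness_at_coverage(row, c_target, below_c1="extend") for row in counts]
        )
    elif method == "composition":
        props = counts / counts.sum(axis=1, keepdims=True)
    else:
        raise ValueError("method must be 'coverage' or 'composition'")
    rng = np.random.default_rng(seed)
    betas = np.empty(n_rand)
    for r in range(n_rand):
        idx = rng.choice(n_traps, size=subset_size, replace=False)
        if method == "coverage":
            pooled = counts[idx].sum(axis=0)
            gamma = richness_at_coverage(pooled, c_target, below_c1="extend")
            betas[r] = gamma / alphas[idx].mean()
        else:
            sub_p = props[idx]
            p_bar = sub_p.mean(axis=0)
            n_star = _multinomial_depth_at_coverage(p_bar, c_target)
            gamma = _multinomial_richness(p_bar, n_star)
            a = np.mean([_multinomial_richness(row, n_star) for row in sub_p])
            betas[r] = gamma / a
    return BetaCResult(group, mc, c_target, subset_size, n_rand, seed, betas)


def shuffle_null_beta_C(
    matrix: pd.DataFrame,
    c_target: float,
    n_rand: int = 199,
    seed: int = 0,
    method: str = "coverage",
) -> np.ndarray:
    """Individual-shuffle null: beta_C after pooling and redistributing.

    Individuals are shuffled among traps preserving per-trap totals and the
    pooled species-abundance distribution; under this null mean beta_C
    approaches 1.  Because a shuffle can lower a trap's full-sample coverage
    below the requested target, the effective target for each draw is capped
    at that draw's own maximum standardizable coverage minus 0.01.  Returns
    the null beta_C values.
    """
    counts = matrix.to_numpy()
    totals = counts.sum(axis=1)
    pooled = counts.sum(axis=0)
    taxa_of_individual = np.repeat(np.arange(counts.shape[1]), pooled)
    rng = np.random.default_rng(seed)
    out = np.empty(n_rand)
    n_taxa = counts.shape[1]
    for r in range(n_rand):
        perm = rng.permutation(taxa_of_individual)
        new = np.zeros_like(counts)
        start = 0
        for i, tot in enumerate(totals):
            seg = perm[start : start + tot]
            new[i] = np.bincount(seg, minlength=n_taxa)
            start += tot
        df = pd.DataFrame(new, index=matrix.index, columns=matrix.columns)
        attainable = min(
            expected_coverage(row, int(row.sum())) for row in new if row.sum() > 0
        )
        c_eff = min(c_target, attainable - 0.01)
        out[r] = beta_C(df, c_eff, method=method)
    return out
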