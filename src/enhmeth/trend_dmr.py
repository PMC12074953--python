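"""Jonckheere–Terpstra ordered-trend testing and DMR calling.

The Jonckheere–Terpstra statistic for k ordered groups is the sum of
pairwise Mann–Whitney counts over ordered group pairs,

    U = sum_{i<j} ( #{(x, y) in g_i x g_j : y > x} + 1/2 #{y = x} ),

with null mean (N^2 - sum n_i^2)/4 and a tie-corrected null variance.
A block is called hypermethylated when the two-sided trend p-value falls
below the threshold (0.01 by default) and the effect Δβ — mean β of the
last group minus mean β of the first — is positive; hypomethylated when
negative. Raw p-values are thresholded; a Benjamini–Hochberg column is
emitted for information only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BetaMatrix, SampleMetadata
from .errors import CapacityError, InsufficientDataError

EXACT_ENUM_LIMIT = 1_000_000  # multinomial arrangement bound for exact_enum


@dataclass
class TrendResult:
    block_id: str
    U: float
    z: float
    p: float
    delta_beta: float
    direction: str  # hyper / hypo / none


def _clean_groups(groups) -> list[np.ndarray]:
    out = []
    for g in groups:
        arr = np.asarray(g, dtype=float).ravel()
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            raise InsufficientDataError("empty group in trend test")
        out.append(arr)
    if len(out) < 2:
        raise InsufficientDataError("trend test needs >= 2 groups")
    return out


def jt_statistic(groups) -> float:
    """Jonckheere–Terpstra U: cross-pair ascending counts with half-ties."""
    groups = _clean_groups(groups)
    u = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            x = groups[i][:, None]
            y = groups[j][None, :]
            u += np.sum(y > x) + 0.5 * np.sum(y == x)
    return float(u)


def jt_null_moments(groups) -> tuple[float, float, float]:
    """(mean, variance, max_pairs) of U under the null, tie-corrected.

    Variance uses the standard tie-corrected formula built from group
    sizes n_i and pooled tie-group sizes t_j.
    """
    groups = _clean_groups(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    N = n.sum()
    pooled = np.concatenate(groups)
    _, counts = np.unique(pooled, return_counts=True)
    t = counts.astype(float)
    mean = (N**2 - np.sum(n**2)) / 4.0
    term1 = (
        N * (N - 1) * (2 * N + 5)
        - np.sum(n * (n - 1) * (2 * n + 5))
        - np.sum(t * (t - 1) * (2 * t + 5))
    ) / 72.0
    term2 = 0.0
    term3 = 0.0
    if N > 2:
        term2 = (
            np.sum(n * (n - 1) * (n - 2))
            * np.sum(t * (t - 1) * (t - 2))
            / (36.0 * N * (N - 1) * (N - 2))
        )
    term3 = np.sum(n * (n - 1)) * np.sum(t * (t - 1)) / (8.0 * N * (N - 1))
    var = term1 + term2 + term3
    max_pairs = (N**2 - np.sum(n**2)) / 2.0
    return float(mean), float(max(var, 0.0)), float(max_pairs)


def _mw_counts(m: int, n: int) -> np.ndarray:
    """Count vector of the Mann–Whitney U null distribution for sizes (m, n).

    Entry u holds the number of arrangements with U = u; computed as the
    Gaussian binomial coefficient expansion by dynamic programming.
    """
    counts = np.zeros(m * n + 1, dtype=float)
    counts[0] = 1.0
    # multiply by (1 + q + ... + q^m) for each of the n elements, i.e. the
    # bounded-part partition recurrence
    for i in range(1, n + 1):
        new = np.zeros_like(counts)
        # new[u] = sum_{j=0..m} counts[u-j]; use cumulative sums
        cs = np.concatenate([[0.0], np.cumsum(counts)])
        for u in range(m * n + 1):
            lo = max(0, u - m)
            new[u] = cs[u + 1] - cs[lo]
        counts = new
    return counts


_KURTOSIS_CACHE: dict[tuple[int, ...], float] = {}


def _jt_excess_kurtosis(sizes: tuple[int, ...]) -> float:
    """Excess kurtosis of the tie-free JT null distribution.

    Uses the classical decomposition of U into independent Mann–Whitney
    components (group j against the pooled earlier groups), whose exact
    pmfs are computed by dynamic programming; the fourth cumulant is the
    sum of component fourth cumulants.
    """
    sizes = tuple(int(s) for s in sizes)
    if sizes in _KURTOSIS_CACHE:
        return _KURTOSIS_CACHE[sizes]
    kappa4 = 0.0
    var = 0.0
    m = sizes[0]
    for n in sizes[1:]:
        counts = _mw_counts(m, n)
        pmf = counts / counts.sum()
        u = np.arange(len(pmf), dtype=float)
        mu = float(pmf @ u)
        c = u - mu
        v = float(pmf @ c**2)
        mu4 = float(pmf @ c**4)
        var += v
        kappa4 += mu4 - 3 * v**2
        m += n
    g2 = kappa4 / var**2 if var > 0 else 0.0
    _KURTOSIS_CACHE[sizes] = g2
    return g2


def _normal_tail_pair(u: float, mean: float, sd: float, g2: float) -> tuple[float, float]:
    """(P(U' >= u), P(U' <= u)) under the refined normal approximation.

    Continuity-corrected normal with an Edgeworth fourth-cumulant term;
    ``g2`` = 0 reduces to the plain corrected normal.
    """

    def cdf(z: float) -> float:
        base = stats.norm.cdf(z)
        if g2:
            base -= g2 / 24.0 * (z**3 - 3 * z) * stats.norm.pdf(z)
        return float(np.clip(base, 0.0, 1.0))

    p_ge = 1.0 - cdf((u - 0.5 - mean) / sd)
    p_le = cdf((u + 0.5 - mean) / sd)
    return p_ge, p_le


def _multinomial_count(sizes) -> int:
    from math import comb

    total, out = sum(sizes), 1
    for s in sizes:
        out *= comb(total, s)
        total -= s
    return out


def _enumerate_u(pooled: np.ndarray, sizes: list[int]):
    """Yield U over every distinct assignment of pooled positions to groups."""
    idx = list(range(len(pooled)))

    def rec(remaining, sizes_left, chosen):
        if not sizes_left:
            yield jt_statistic([pooled[list(c)] for c in chosen])
            return
        s = sizes_left[0]
        for combo in itertools.combinations(remaining, s):
            rest = [i for i in remaining if i not in set(combo)]
            yield from rec(rest, sizes_left[1:], chosen + [combo])

    yield from rec(idx, sizes, [])


def jt_test(
    groups,
    method: str = "normal_approx",
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided trend test; returns (z, p).

    ``normal_approx`` standardizes U with the tie-corrected null variance
    and a 0.5 continuity correction; ``exact_enum`` enumerates all
    arrangements (bounded at 10^6); ``permutation`` resamples group
    assignments. Zero null variance (all values equal) gives z = 0, p = 1.
    Two-sided p = 2 * min(P(U' >= U), P(U' <= U)), capped at 1.
    """
    groups = _clean_groups(groups)
    u = jt_statistic(groups)
    mean, var, _ = jt_null_moments(groups)
    if var <= 0:
        return 0.0, 1.0
    sd = np.sqrt(var)
    z = (u - mean) / sd

    if method == "normal_approx":
        pooled = np.concatenate(groups)
        tie_free = len(np.unique(pooled)) == len(pooled)
        g2 = _jt_excess_kurtosis(tuple(len(g) for g in groups)) if tie_free else 0.0
        p_ge, p_le = _normal_tail_pair(u, mean, sd, g2)
        return float(z), float(min(1.0, 2.0 * min(p_ge, p_le)))

    if method == "exact_enum":
        sizes = [len(g) for g in groups]
        count = _multinomial_count(sizes)
        if count > EXACT_ENUM_LIMIT:
            raise CapacityError(
                f"{count} arrangements exceed the exact bound "
                f"{EXACT_ENUM_LIMIT}; use method='permutation'"
            )
        pooled = np.concatenate(groups)
        us = np.fromiter(_enumerate_u(pooled, sizes), dtype=float, count=count)
        tol = 1e-9
        p_ge = np.mean(us >= u - tol)
        p_le = np.mean(us <= u + tol)
        return float(z), float(min(1.0, 2.0 * min(p_ge, p_le)))

    if method == "permutation":
        rng = np.random.default_rng(seed)
        sizes = [len(g) for g in groups]
        pooled = np.concatenate(groups)
        splits = np.cumsum(sizes)[:-1]
        n_ge = n_le = 0
        tol = 1e-9
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            up = jt_statistic(np.split(perm, splits))
            n_ge += up >= u - tol
            n_le += up <= u + tol
        p_ge = (n_ge + 1) / (n_perm + 1)
        p_le = (n_le + 1) / (n_perm + 1)
        return float(z), float(min(1.0, 2.0 * min(p_ge, p_le)))

    raise ValueError(f"unknown method {method!r}")


def _jt_row(values: np.ndarray, group_cols: list[np.ndarray]) -> tuple[float, float, float]:
    """Fast per-block (U, z, p) with normal approximation; NaN-aware."""
    groups = [values[c] for c in group_cols]
    groups = [g[np.isfinite(g)] for g in groups]
    if any(len(g) < 2 for g in groups):
        return np.nan, np.nan, np.nan
    u = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            diff = groups[j][None, :] - groups[i][:, None]
            u += np.sum(diff > 0) + 0.5 * np.sum(diff == 0)
    n = np.array([len(g) for g in groups], dtype=float)
    N = n.sum()
    pooled = np.concatenate(groups)
    _, counts = np.unique(pooled, return_counts=True)
    t = counts.astype(float)
    mean = (N**2 - np.sum(n**2)) / 4.0
    var = (
        N * (N - 1) * (2 * N + 5)
        - np.sum(n * (n - 1) * (2 * n + 5))
        - np.sum(t * (t - 1) * (2 * t + 5))
    ) / 72.0
    var += (
        np.sum(n * (n - 1) * (n - 2)) * np.sum(t * (t - 1) * (t - 2))
        / (36.0 * N * (N - 1) * (N - 2))
    )
    var += np.sum(n * (n - 1)) * np.sum(t * (t - 1)) / (8.0 * N * (N - 1))
    if var <= 0:
        return u, 0.0, 1.0
    sd = np.sqrt(var)
    tie_free = len(counts) == len(pooled)
    g2 = _jt_excess_kurtosis(tuple(len(g) for g in groups)) if tie_free else 0.0
    p_ge, p_le = _normal_tail_pair(u, mean, sd, g2)
    return u, (u - mean) / sd, min(1.0, 2.0 * min(p_ge, p_le))


def call_trend_dmrs(
    block_matrix: BetaMatrix,
    metadata: SampleMetadata,
    p_thr: float = 0.01,
    delta_thr: float = 0.0,
) -> pd.DataFrame:
    """Per-block trend test and hyper/hypo DMR calls.

    Returns one row per block: block_id, U, z, p, fdr (Benjamini–Hochberg,
    informational), delta_beta and direction. A block with fewer than two
    non-missing values in any trend group gets p = NA and direction
    ``none``.
    """
    metadata.validate_against(block_matrix)
    trend_samples = metadata.trend_groups()
    if any(len(s) == 0 for s in trend_samples):
        raise InsufficientDataError("all three trend groups must be present")
    cols = block_matrix.values.columns
    group_cols = [
        np.array([cols.get_loc(s) for s in samples]) for samples in trend_samples
    ]
    arr = block_matrix.values.to_numpy(dtype=float)
    n_blocks = arr.shape[0]
    U = np.empty(n_blocks)
    Z = np.empty(n_blocks)
    P = np.empty(n_blocks)
    for i in range(n_blocks):
        U[i], Z[i], P[i] = _jt_row(arr[i], group_cols)

    first = arr[:, group_cols[0]]
    last = arr[:, group_cols[-1]]
    with np.errstate(invalid="ignore"):
        delta = np.nanmean(last, axis=1) - np.nanmean(first, axis=1)

    direction = np.full(n_blocks, "none", dtype=object)
    sig = np.isfinite(P) & (P < p_thr)
    direction[sig & (delta > delta_thr)] = "hyper"
    direction[sig & (delta < -delta_thr)] = "hypo"

    fdr = np.full(n_blocks, np.nan)
    ok = np.isfinite(P)
    if ok.any():
        fdr[ok] = stats.false_discovery_control(P[ok], method="bh")

    return pd.DataFrame(
        {
            "block_id": block_matrix.row_ids,
            "U": U,
            "z": Z,
            "p": P,
            "fdr": fdr,
            "delta_beta": delta,
            "direction": direction,
        }
    )


def context_enrichment(
    dmr_ids: set[str],
    universe: set[str],
    category_of,
) -> pd.DataFrame:
    """Per-category enrichment of a DMR set against the block universe.

    ``category_of`` maps a block id to a label (or an iterable of labels;
    a block counts toward each). For every label a 2x2 table (in DMR set x
    in category) is tested with the two-sided Fisher exact test
    (hypergeometric point-mass summation). Fractions of the DMR set and of
    the universe carrying the label are reported.
    """
    if not dmr_ids:
        raise InsufficientDataError("empty DMR set")
    extra = set(dmr_ids) - set(universe)
    if extra:
        raise InsufficientDataError(f"DMR ids outside universe: {sorted(extra)[:5]}")

    def labels_of(block_id):
        lab = category_of(block_id) if callable(category_of) else category_of[block_id]
        if isinstance(lab, str):
            return [lab]
        return list(lab)

    label_members: dict[str, set[str]] = {}
    for b in universe:
        for lab in labels_of(b):
            label_members.setdefault(lab, set()).add(b)

    n_univ, n_dmr = len(universe), len(dmr_ids)
    rows = []
    for lab in sorted(label_members):
        members = label_members[lab]
        a = len(dmr_ids & members)
        b = n_dmr - a
        c = len(members) - a
        d = n_univ - n_dmr - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "category": lab,
                "n_dmr_in_category": a,
                "fraction_dmr": a / n_dmr,
                "fraction_universe": len(members) / n_univ,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
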