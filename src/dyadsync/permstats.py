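"""Permutation inference and small-sample statistics for paired designs.

The central routine is a mass-univariate one-way repeated-measures ANOVA
across electrode pairs with family-wise error control by the
max-statistic permutation scheme: condition labels are shuffled within
every dyad, the largest F across pairs is retained per permutation, and
each pair's p-value is the proportion of permutations whose maximum
exceeds its observed F. For two conditions with few dyads the scheme is
enumerated exhaustively (all sign assignments) instead of sampled.

Monte-Carlo p-values use the add-one convention (1 + count)/(1 + n_perm),
which never returns zero; exhaustive p-values are exact proportions over
all assignments.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as spstats

from .datatypes import BandSpec, GroupConnectivity, MassUnivariateResult, MatchedDyadEpochs, PairGrid
from .synth import stream

__all__ = [
    "rm_anova_map",
    "max_f_permutation",
    "pseudo_dyad_null",
    "change_score",
    "exclude_3sd",
    "paired_t",
    "pearson",
]

_F_INF = np.inf  # sentinel for zero error variance


def _rm_anova_arrays(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way RM-ANOVA.

    ``data`` has shape (n_subjects, k_conditions, n_tests). Returns
    per-test F and partial eta squared. Zero error variance yields an
    infinite F sentinel (with a warning) unless the effect is also zero,
    in which case F = 0.
    """
    n, k, _ = data.shape
    grand = data.mean(axis=(0, 1), keepdims=True)
    cond_mean = data.mean(axis=0, keepdims=True)
    subj_mean = data.mean(axis=1, keepdims=True)
    ss_cond = n * ((cond_mean - grand) ** 2).sum(axis=(0, 1))
    resid = data - cond_mean - subj_mean + grand
    ss_err = (resid**2).sum(axis=(0, 1))
    # flush rounding-level sums of squares (e.g. bit-identical condition
    # columns) so degenerate fixtures give F = 0, not a 0/0 artifact
    floor = 1e-12 * ((data - grand) ** 2).sum(axis=(0, 1))
    ss_cond = np.where(ss_cond <= floor, 0.0, ss_cond)
    ss_err = np.where(ss_err <= floor, 0.0, ss_err)
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_cond / df_cond) / (ss_err / df_err)
        eta = ss_cond / (ss_cond + ss_err)
    zero_err = ss_err <= 0
    if np.any(zero_err):
        F = np.where(zero_err & (ss_cond > 0), _F_INF, F)
        F = np.where(zero_err & (ss_cond <= 0), 0.0, F)
        eta = np.where(zero_err & (ss_cond <= 0), 0.0, eta)
        eta = np.where(zero_err & (ss_cond > 0), 1.0, eta)
        if np.any(zero_err & (ss_cond > 0)):
            warnings.warn("zero error variance: F reported as +inf for some pairs")
    return F, eta


def rm_anova_map(
    group: GroupConnectivity, conditions: tuple[str, str] | list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair repeated-measures ANOVA F and partial eta squared.

    For two conditions F is algebraically the squared paired-t
    statistic with df = (1, n - 1).
    """
    cond = list(conditions) if conditions is not None else list(group.conditions)
    if len(cond) < 2:
        raise ValueError("need at least two conditions to contrast")
    if group.n_dyads < 3:
        raise ValueError("need at least 3 complete dyads")
    idx = [group.condition_index(c) for c in cond]
    return _rm_anova_arrays(group.values[:, idx, :])


def _sign_flip_F(d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """F maps for sign-flipped paired differences.

    ``d``: (n, p) within-dyad differences; ``signs``: (m, n) in {-1, +1}.
    Exploits that sum_i d_i^2 is flip-invariant: F = t^2 with
    t^2 = (n-1) * n*mean^2 / (sum d^2 - n*mean^2). Returns (m, p).
    """
    n = d.shape[0]
    q = (d**2).sum(axis=0)  # (p,)
    means = signs @ d / n  # (m, p)
    nm2 = n * means**2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (n - 1) * nm2 / (q[None, :] - nm2)
    F = np.where(q[None, :] - nm2 <= 1e-300, np.where(nm2 > 0, _F_INF, 0.0), F)
    return F


def max_f_permutation(
    group: GroupConnectivity,
    conditions: tuple[str, str] | list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive_limit: int = 4096,
    alpha: float = 0.05,
) -> MassUnivariateResult:
    """Mass-univariate RM-ANOVA with max-F permutation FWER control.

    Condition labels are shuffled independently within every dyad; for
    two conditions this is a per-dyad sign flip of the paired
    difference, enumerated exhaustively when ``2**n_dyads`` does not
    exceed ``exhaustive_limit``. Deterministic given ``seed``.
    """
    cond = list(conditions) if conditions is not None else list(group.conditions)
    k = len(cond)
    if group.n_dyads < 2:
        raise ValueError("need at least 2 dyads")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution will be poor")
    idx = [group.condition_index(c) for c in cond]
    data = group.values[:, idx, :]
    n, _, p = data.shape
    F_obs, eta = _rm_anova_arrays(data)
    df = (k - 1, (k - 1) * (n - 1))

    exhaustive = k == 2 and 2**n <= exhaustive_limit
    if k == 2:
        d = data[:, 0, :] - data[:, 1, :]
        if exhaustive:
            m = 2**n
            bits = (np.arange(m)[:, None] >> np.arange(n)[None, :]) & 1
            signs = 1.0 - 2.0 * bits
            null_max = _sign_flip_F(d, signs).max(axis=1)
            count = (null_max[:, None] >= F_obs[None, :] - 1e-12).sum(axis=0)
            p_perm = count / m
            n_used = m
        else:
            rng = stream(seed, "max_f_permutation")
            signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
            null_max = _sign_flip_F(d, signs).max(axis=1)
            count = (null_max[:, None] >= F_obs[None, :] - 1e-12).sum(axis=0)
            p_perm = (1.0 + count) / (1.0 + n_perm)
            n_used = n_perm
    else:
        rng = stream(seed, "max_f_permutation")
        null_max = np.empty(n_perm)
        for b in range(n_perm):
            perm = data.copy()
            for i in range(n):
                perm[i] = perm[i, rng.permutation(k), :]
            null_max[b] = _rm_anova_arrays(perm)[0].max()
        count = (null_max[:, None] >= F_obs[None, :] - 1e-12).sum(axis=0)
        p_perm = (1.0 + count) / (1.0 + n_perm)
        n_used = n_perm
        exhaustive = False

    p_naive = spstats.f.sf(F_obs, df[0], df[1])
    return MassUnivariateResult(
        pairs=list(group.pairs),
        F=F_obs,
        eta_sq_p=eta,
        p_perm=p_perm,
        p_naive=p_naive,
        null_max_F=null_max,
        alpha=alpha,
        n_perm=n_used,
        seed=seed,
        exhaustive=exhaustive,
        df=df,
    )


def pseudo_dyad_null(
    epochs_by_dyad: dict[str, MatchedDyadEpochs],
    adult_channel: str,
    infant_channel: str,
    band: BandSpec | None = None,
    M: int = 1000,
    seed: int = 0,
    min_epochs: int = 20,
) -> tuple[float, np.ndarray, float]:
    """Surrogate-pair (pseudo-dyad) null for one target electrode pair.

    Each surrogate dataset pairs every adult with a non-partner infant
    from the same condition (a random derangement of dyads) and
    recomputes wPLI at the target pair from the raw epochs. Returns the
    real group mean, the null distribution of surrogate group means,
    and p = (1 + #{null >= real}) / (1 + M).
    """
    from scipy.signal.windows import hann

    band = band or BandSpec()
    dyads = sorted(epochs_by_dyad)
    n = len(dyads)
    if n < 5:
        raise ValueError("pseudo-dyad null needs at least 5 dyads")
    if M < 100:
        warnings.warn(f"M={M} is low for a surrogate null")

    # precompute Hann-windowed spectra at the band bins once per dyad;
    # surrogates then only combine spectra, never re-transform
    from .interbrain import _band_bins

    adult_spec: dict[str, np.ndarray] = {}
    infant_spec: dict[str, np.ndarray] = {}
    for d in dyads:
        m = epochs_by_dyad[d]
        if m.n_matched < min_epochs:
            raise ValueError(f"dyad {d!r} has fewer than {min_epochs} matched epochs")
        nsamp = m.infant_data.shape[2]
        idx, _ = _band_bins(nsamp, m.sampling_rate, band)
        win = hann(nsamp, sym=False)
        a = m.adult_data[:, m.adult_channels.index(adult_channel), :]
        i = m.infant_data[:, m.infant_channels.index(infant_channel), :]
        a = (a - a.mean(axis=1, keepdims=True)) * win
        i = (i - i.mean(axis=1, keepdims=True)) * win
        adult_spec[d] = np.fft.rfft(a, axis=1)[:, idx]
        infant_spec[d] = np.fft.rfft(i, axis=1)[:, idx]

    def pair_wpli(A: np.ndarray, I: np.ndarray) -> float:
        e = min(A.shape[0], I.shape[0])
        im = np.imag(A[:e] * np.conj(I[:e]))
        num = np.abs(im.sum(axis=0))
        den = np.abs(im).sum(axis=0)
        per_bin = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return float(per_bin.mean())

    real_mean = float(np.mean([pair_wpli(adult_spec[d], infant_spec[d]) for d in dyads]))

    rng = stream(seed, "pseudo_dyad")
    null = np.empty(M)
    for m_i in range(M):
        while True:  # rejection-sample a derangement
            perm = rng.permutation(n)
            if not np.any(perm == np.arange(n)):
                break
        null[m_i] = np.mean(
            [pair_wpli(adult_spec[dyads[i]], infant_spec[dyads[j]]) for i, j in enumerate(perm)]
        )
    p = (1.0 + np.sum(null >= real_mean)) / (1.0 + M)
    return real_mean, null, p


def change_score(a: float, b: float) -> float:
    """Bounded normalized paired difference: (a - b) / max(a, b).

    Defined for non-negative inputs; 0/0 is 0 by convention. Lies in
    [-1, 1], is antisymmetric in its arguments and invariant to common
    positive rescaling.
    """
    if a < 0 or b < 0:
        raise ValueError("change_score requires non-negative inputs")
    m = max(a, b)
    if m == 0:
        return 0.0
    return (a - b) / m


def exclude_3sd(values: np.ndarray) -> np.ndarray:
    """Single-pass 3-SD outlier mask (True = excluded).

    Mean and sample SD (ddof=1) are computed once on the full vector;
    zero variance excludes nothing.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values")
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros(values.size, dtype=bool)
    return np.abs(values - values.mean()) > 3.0 * sd


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.allclose(d, 0):
        return 0.0, n - 1, 1.0
    if d.std(ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    res = spstats.ttest_rel(a, b)
    return float(res.statistic), n - 1, float(res.pvalue)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Pearson correlation; returns (r, p) with df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = spstats.pearsonr(x, y)
    return float(r), float(p)
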