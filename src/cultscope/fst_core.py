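"""Cultural F_ST for binary traits: estimators, oracle, permutation test.

Cultural F_ST is the fraction of total variance in a binary trait (here,
adoption of a management practice) that lies between groups:

    F_ST = sum_g w_g (p_g - p_bar)^2 / (p_bar (1 - p_bar))

with group adoption frequencies ``p_g``, weights ``w_g`` (by default the
group share of non-missing responses, ``n_g / N``) and grand mean
``p_bar = sum_g w_g p_g``.  By the law of total variance the denominator
equals the between- plus within-group variance, so the naive estimator is
identical to a raw-data variance decomposition — an identity this module
exploits as an exact test oracle.

Two estimators are provided.  The *naive* estimator plugs observed
frequencies into the definition; it describes the differentiation of the
sampled groups and is biased toward zero as an estimate of the
differentiation of the process that generated them.  The *corrected*
estimator is a method-of-moments estimator of that generating
differentiation: it removes the expected within-group sampling
contribution from the between-group sum of squares, rescales for the
finite number of groups (a variance taken around the sample grand mean
loses a factor ``1 - sum w_g^2``), and unbiases the denominator for the
sampling variance of the grand mean.  With many large groups the two
estimators coincide.

Missing adoption entries are handled by per-practice pairwise deletion: a
grower is excluded only for the practices they did not answer.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from cultscope.io_survey import AdoptionMatrix

logger = logging.getLogger(__name__)

Weighting = Literal["size", "equal"]


class InsufficientGroupsError(ValueError):
    """Raised when fewer than two groups have usable responses."""


@dataclass(frozen=True)
class GroupFrequencies:
    """Per-group adoption summary for one practice.

    ``n`` counts non-missing responses per group and ``p`` is the adoption
    frequency among them; groups are ordered as in ``group_ids``.
    """

    practice_id: str
    group_ids: tuple[str, ...]
    n: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "n", np.asarray(self.n, dtype=int))
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        if not (len(self.group_ids) == len(self.n) == len(self.p)):
            raise ValueError("group_ids, n and p must have equal length")
        if len(self.group_ids) < 2:
            raise InsufficientGroupsError(
                "insufficient groups for differentiation "
                f"(practice {self.practice_id!r})"
            )
        if (self.n < 1).any():
            raise ValueError("every included group needs n_g >= 1")
        if ((self.p < 0) | (self.p > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_total(self) -> int:
        return int(self.n.sum())

    def weights(self, weighting: Weighting = "size") -> np.ndarray:
        if weighting == "size":
            return self.n / self.n.sum()
        if weighting == "equal":
            return np.full(len(self.n), 1.0 / len(self.n))
        raise ValueError(f"unknown weighting {weighting!r}")

    @property
    def w(self) -> np.ndarray:
        return self.weights("size")

    @property
    def p_bar(self) -> float:
        return float(self.w @ self.p)


@dataclass(frozen=True)
class FstResult:
    """F_ST estimate for one practice.

    ``defined`` is False when the pooled frequency is 0 or 1 (no total
    variance); in that case ``fst`` is NaN rather than being coerced to 0,
    since "no variation" and "no differentiation" are different states.
    """

    practice_id: str
    fst: float
    defined: bool
    fst_corrected: float | None = None
    permutation_p: float | None = None
    freqs: GroupFrequencies | None = None


# ---------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------

def group_frequencies(
    adoption: AdoptionMatrix, practice_id: str, min_n: int = 1
) -> GroupFrequencies:
    """Per-group counts and adoption frequencies for one practice.

    Groups with fewer than ``min_n`` non-missing responses are excluded
    (and logged); fewer than two eligible groups raises
    :class:`InsufficientGroupsError`.
    """
    if practice_id not in adoption.adoption.columns:
        raise KeyError(f"unknown practice {practice_id!r}")
    values = adoption.adoption[practice_id]
    grouped = values.groupby(adoption.groups, observed=True)
    n = grouped.count()
    p = grouped.mean()

    eligible = n.index[n >= max(min_n, 1)]
    dropped = [g for g in n.index if g not in set(eligible)]
    if dropped:
        logger.warning(
            "practice %r: excluding group(s) %s with fewer than %d responses",
            practice_id,
            dropped,
            max(min_n, 1),
        )
    if len(eligible) < 2:
        raise InsufficientGroupsError(
            f"insufficient groups for differentiation (practice {practice_id!r}: "
            f"{len(eligible)} eligible group(s))"
        )
    eligible = sorted(eligible)
    return GroupFrequencies(
        practice_id=practice_id,
        group_ids=tuple(eligible),
        n=n.loc[eligible].to_numpy(),
        p=p.loc[eligible].to_numpy(),
    )


# ---------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------

def _between(w: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    p_bar = float(w @ p)
    return float(w @ (p - p_bar) ** 2), p_bar


def cultural_fst(
    freqs: GroupFrequencies, weighting: Weighting = "size"
) -> FstResult:
    """Naive (plug-in) cultural F_ST.

    Undefined (``defined=False``, NaN) when the pooled frequency is 0 or 1.
    """
    w = freqs.weights(weighting)
    between, p_bar = _between(w, freqs.p)
    total = p_bar * (1.0 - p_bar)
    if total == 0.0:
        return FstResult(freqs.practice_id, float("nan"), False, freqs=freqs)
    fst = min(max(between / total, 0.0), 1.0)
    return FstResult(freqs.practice_id, fst, True, freqs=freqs)


def _beta_central_moments(mu: float, fst: float) -> tuple[float, float, float]:
    """Variance, third central moment and excess kurtosis of the Beta
    distribution with mean ``mu`` and variance ``fst * mu * (1 - mu)``."""
    fst = min(max(fst, 1e-12), 1.0 - 1e-9)
    theta = (1.0 - fst) / fst
    a, b = mu * theta, (1.0 - mu) * theta
    s = a + b
    var = a * b / (s**2 * (s + 1.0))
    skew = 2.0 * (b - a) * np.sqrt(s + 1.0) / ((s + 2.0) * np.sqrt(a * b))
    mu3 = skew * var**1.5
    g2 = (
        6.0
        * ((a - b) ** 2 * (s + 1.0) - a * b * (s + 2.0))
        / (a * b * (s + 2.0) * (s + 3.0))
    )
    return var, mu3, g2


def cultural_fst_corrected(
    freqs: GroupFrequencies, weighting: Weighting = "size"
) -> FstResult:
    """Finite-sample-corrected cultural F_ST.

    Estimates the differentiation of the process that generated the
    groups (a Balding-Nichols-style superpopulation F) rather than the
    realized differentiation of the sample.  Three corrections are
    applied on top of the naive estimator.  With weights ``w_g`` and the
    unbiased within-group sampling variance
    ``v_g = p_g (1 - p_g) / (n_g - 1)``:

    1. numerator: ``sigma2 = [sum w_g (p_g - p_bar)^2
       - sum w_g (1 - w_g) v_g] / (1 - sum w_g^2)``, floored at 0.  The
       subtraction removes the expected within-group sampling spread and
       the ``1 - sum w_g^2`` factor is the finite-number-of-groups
       analogue of Bessel's correction.
    2. denominator: ``p_bar (1 - p_bar) + sum w_g^2 (sigma2 + v_g)``
       restores the sampling variance of the grand mean.
    3. ratio bias: with few groups the ratio of the two unbiased
       components is still biased downward (Jensen's inequality plus the
       numerator-denominator covariance).  A second-order delta-method
       correction is subtracted, with the required higher moments of the
       group-frequency distribution evaluated in closed form under the
       Beta model at the plug-in estimates.

    The result is clipped to [0, 1].  Note the corrected estimate
    usually *exceeds* the naive one — the naive estimator underestimates
    the generating differentiation — and the two estimators answer
    different questions (sample description vs. process inference).
    Requires every ``n_g >= 2``; undefined when the pooled frequency is
    0 or 1.  The returned result carries the naive estimate in ``fst``
    alongside ``fst_corrected``.
    """
    if (freqs.n < 2).any():
        raise ValueError(
            f"correction requires n_g >= 2 (practice {freqs.practice_id!r})"
        )
    naive = cultural_fst(freqs, weighting)
    if not naive.defined:
        return naive
    w = freqs.weights(weighting)
    between, p_bar = _between(w, freqs.p)
    v = freqs.p * (1.0 - freqs.p) / (freqs.n - 1)
    sigma2 = (between - float(w * (1.0 - w) @ v)) / (1.0 - float(w @ w))
    sigma2 = max(sigma2, 0.0)
    denom = p_bar * (1.0 - p_bar) + float(w**2 @ (sigma2 + v))
    f0 = min(max(sigma2 / denom, 0.0), 1.0)
    if f0 == 0.0:  # floored numerator: nothing to bias-correct
        return dataclasses.replace(naive, fst_corrected=0.0)

    # delta-method ratio-bias correction (moments from the Beta model)
    n_groups = len(freqs.p)
    var, mu3, g2 = _beta_central_moments(p_bar, f0)
    var_num = var**2 * (2.0 / (n_groups - 1) + g2 / n_groups)
    slope = 1.0 - 2.0 * p_bar
    cov_nd = slope * mu3 / n_groups + var_num / n_groups
    var_den = (
        slope**2 * var / n_groups
        + var_num / n_groups**2
        + 2.0 * slope * mu3 / n_groups**2
    )
    bias = -cov_nd / denom**2 + sigma2 * var_den / denom**3
    corrected = min(max(f0 - bias, 0.0), 1.0)
    return dataclasses.replace(naive, fst_corrected=corrected)


def pairwise_fst(
    adoption: AdoptionMatrix,
    practice_id: str,
    group_pair: Sequence[str],
    weighting: Weighting = "size",
    min_n: int = 1,
) -> FstResult:
    """Cultural F_ST restricted to two named groups."""
    if len(group_pair) != 2:
        raise ValueError("group_pair must name exactly two groups")
    sub = adoption.subset_groups(list(group_pair))
    return cultural_fst(group_frequencies(sub, practice_id, min_n), weighting)


# ---------------------------------------------------------------------
# oracle
# ---------------------------------------------------------------------

def fst_oracle(indicators: Sequence[float], labels: Sequence[str]) -> float:
    """Raw-data variance-decomposition F_ST (independent reference).

    Computes the between-group and within-group variance components
    directly from the 0/1 indicators and returns between / (between +
    within).  By the law of total variance this equals the naive
    estimator exactly; it is implemented independently so it can serve as
    a test oracle.  Returns NaN when the data carry no variance.
    """
    indicators = np.asarray(indicators, dtype=float)
    labels = np.asarray(labels)
    if indicators.shape != labels.shape:
        raise ValueError("indicators and labels must have matching lengths")
    if len(np.unique(labels)) < 2:
        raise InsufficientGroupsError("oracle requires at least 2 groups")
    n_total = len(indicators)
    between = 0.0
    within = 0.0
    grand = indicators.mean()
    for g in np.unique(labels):
        vals = indicators[labels == g]
        share = len(vals) / n_total
        between += share * (vals.mean() - grand) ** 2
        within += share * vals.var()  # population variance within group g
    total = between + within
    if total == 0.0:
        return float("nan")
    return between / total


# ---------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------

def permutation_test(
    adoption: AdoptionMatrix,
    practice_id: str,
    n_perm: int,
    seed: int,
    min_n: int = 1,
) -> FstResult:
    """Permutation test of group differentiation for one practice.

    Group labels are permuted over the growers with non-missing responses;
    the p-value uses the add-one correction
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)`` so it is valid for any
    number of permutations.  When F_ST is undefined the p-value is left
    undefined too.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    freqs = group_frequencies(adoption, practice_id, min_n)
    observed = cultural_fst(freqs)
    if not observed.defined:
        return observed

    keep = adoption.groups.isin(freqs.group_ids).to_numpy()
    values = adoption.adoption[practice_id].to_numpy(dtype=float)[keep]
    labels = adoption.groups.to_numpy()[keep]
    mask = ~np.isnan(values)
    values, labels = values[mask], labels[mask]

    # permuting labels is equivalent to permuting values against fixed
    # labels; the total variance p_bar(1-p_bar) is permutation-invariant,
    # so the between-group sum of squares orders permutations like F_ST
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, len(values))), axis=1)
    permuted = values[order]  # (n_perm, N)
    w = freqs.n / freqs.n.sum()
    p_bar = float(w @ freqs.p)
    between = np.zeros(n_perm)
    obs_between = 0.0
    for g, w_g in zip(freqs.group_ids, w):
        m = labels == g
        between += w_g * (permuted[:, m].mean(axis=1) - p_bar) ** 2
        obs_between += w_g * (values[m].mean() - p_bar) ** 2
    exceed = int(np.sum(between >= obs_between - 1e-12))
    p_value = (1 + exceed) / (1 + n_perm)
    return dataclasses.replace(observed, permutation_p=p_value)


# ---------------------------------------------------------------------
# per-practice convenience
# ---------------------------------------------------------------------

def fst_table(
    adoption: AdoptionMatrix,
    estimator: Literal["naive", "corrected"] = "naive",
    weighting: Weighting = "size",
    n_perm: int = 0,
    seed: int = 0,
    min_n: int | None = None,
) -> tuple[list[FstResult], list[tuple[str, str]]]:
    """Estimate F_ST for every practice in the matrix.

    Returns ``(results, warnings)`` where each warning is a
    ``(practice_id, message)`` pair for practices that could not be
    estimated (these do not appear in ``results``).
    """
    if min_n is None:
        min_n = 2 if estimator == "corrected" else 1
    results: list[FstResult] = []
    warnings: list[tuple[str, str]] = []
    for j, practice in enumerate(adoption.practice_ids):
        try:
            freqs = group_frequencies(adoption, practice, min_n)
            if estimator == "corrected":
                res = cultural_fst_corrected(freqs, weighting)
            else:
                res = cultural_fst(freqs, weighting)
            if n_perm > 0 and res.defined:
                # one independent stream per practice, derived from seed
                perm = permutation_test(
                    adoption,
                    practice,
                    n_perm,
                    np.random.SeedSequence(seed, spawn_key=(j,)),
                    min_n,
                )
                res = dataclasses.replace(res, permutation_p=perm.permutation_p)
        except (InsufficientGroupsError, ValueError) as exc:
            warnings.append((practice, str(exc)))
            continue
        results.append(res)
    return results, warnings
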