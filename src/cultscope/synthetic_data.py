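"""Synthetic survey generator with controlled between-group differentiation.

The generator emulates the structure of a two-survey field study: three
regional groups of winegrape growers (822 respondents in all) reporting
0/1 adoption of 44 management practices, and a statewide panel of 120
experts rating each practice's individual cost, individual benefit and
public environmental benefit on 1-7 Likert scales.

Group adoption frequencies follow the Balding-Nichols Beta construction:
for a practice with grand mean ``p_bar`` and target differentiation
``F``, group frequencies are i.i.d. draws from

    Beta( p_bar (1-F)/F,  (1-p_bar)(1-F)/F )

whose mean is ``p_bar`` and whose variance is ``F p_bar (1 - p_bar)`` —
so the expected between-group variance matches the target F_ST in closed
form, which makes parameter-recovery tests analytic.  Growers are
independent Bernoulli draws at their group's frequency; Likert items are
normal draws rounded and clamped to 1-7; missingness is completely at
random.

Reproducibility: a single master seed is carried in the config, and each
(sampler, practice) pair receives its own deterministic child stream via
``numpy.random.SeedSequence(seed, spawn_key=(stream, practice))``.
Adding a practice therefore never perturbs the draws of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from cultscope.io_survey import AdoptionMatrix, RATING_COLUMNS

# stream identifiers for SeedSequence spawn keys
_STREAM_PARAMS = 0       # per-practice parameter draws (when not supplied)
_STREAM_FREQS = 1        # group frequencies
_STREAM_ADOPTION = 2     # grower Bernoulli draws
_STREAM_ADOPT_MISS = 3   # adoption missingness
_STREAM_LIKERT = 4       # expert Likert draws (substream per item)
_STREAM_RATE_MISS = 5    # rating item missingness


def _rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, or a ready Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SyntheticStudyConfig:
    """Study-scale configuration for :func:`generate_study`.

    Defaults mirror the emulated study: 3 regional groups totalling 822
    growers, 44 practices, 120 experts.  Per-practice parameters
    (``p_bar``, ``target_fst``, Likert means) may be given explicitly;
    when left ``None`` they are drawn once from the master seed, with
    grand means spanning [0.2, 0.8], targets spanning [0.01, 0.4] and
    Likert means spanning [2, 6] so the generated study covers the
    qualitative range of interest.
    """

    n_groups: int = 3
    group_sizes: tuple[int, ...] | None = None  # default: 274 each (822 total)
    n_practices: int = 44
    n_experts: int = 120
    p_bar: Sequence[float] | None = None
    target_fst: Sequence[float] | None = None
    cost_mean: Sequence[float] | None = None
    private_benefit_mean: Sequence[float] | None = None
    public_benefit_mean: Sequence[float] | None = None
    likert_sigma: float = 1.5
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_sizes is None:
            self.group_sizes = tuple([274] * self.n_groups)
        self.group_sizes = tuple(int(s) for s in self.group_sizes)
        if len(self.group_sizes) != self.n_groups:
            raise ValueError("group_sizes length must equal n_groups")
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups")
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if self.n_practices < 1 or self.n_experts < 1:
            raise ValueError("n_practices and n_experts must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.likert_sigma <= 0:
            raise ValueError("likert_sigma must be positive")
        for name in ("p_bar", "target_fst", "cost_mean",
                     "private_benefit_mean", "public_benefit_mean"):
            vals = getattr(self, name)
            if vals is not None and len(vals) != self.n_practices:
                raise ValueError(f"{name} must have one value per practice")

    @property
    def group_ids(self) -> list[str]:
        return [f"region_{i + 1}" for i in range(self.n_groups)]

    @property
    def practice_ids(self) -> list[str]:
        width = max(2, len(str(self.n_practices)))
        return [f"p{j + 1:0{width}d}" for j in range(self.n_practices)]


# ---------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------

def sample_group_frequencies(
    p_bar: float, target_fst: float, n_groups: int, seed
) -> np.ndarray:
    """Draw per-group adoption frequencies with expected differentiation.

    Balding-Nichols construction: Beta shape parameters
    ``p_bar (1-F)/F`` and ``(1-p_bar)(1-F)/F``.  ``target_fst = 0``
    returns all groups fixed at ``p_bar`` exactly; ``target_fst = 1`` is
    rejected (degenerate Beta), as are ``p_bar`` of 0 or 1.
    """
    if not 0.0 < p_bar < 1.0:
        raise ValueError("p_bar must lie strictly inside (0, 1)")
    if not 0.0 <= target_fst < 1.0:
        raise ValueError("target_fst must lie in [0, 1)")
    if n_groups < 1:
        raise ValueError("n_groups must be positive")
    if target_fst == 0.0:
        return np.full(n_groups, p_bar)
    scale = (1.0 - target_fst) / target_fst
    rng = _rng(seed)
    return rng.beta(p_bar * scale, (1.0 - p_bar) * scale, size=n_groups)


def sample_adoption(
    p_g: Sequence[float],
    group_sizes: Sequence[int],
    seed,
    practice_id: str = "p01",
    group_ids: Sequence[str] | None = None,
) -> AdoptionMatrix:
    """Bernoulli adoption draws for one practice.

    Each grower in group ``g`` adopts independently with probability
    ``p_g``; grower and group identifiers are synthesized
    deterministically.
    """
    p_g = np.asarray(p_g, dtype=float)
    sizes = [int(s) for s in group_sizes]
    if len(p_g) != len(sizes):
        raise ValueError("p_g and group_sizes must have matching lengths")
    if group_ids is None:
        group_ids = [f"region_{i + 1}" for i in range(len(sizes))]
    rng = _rng(seed)
    labels: list[str] = []
    growers: list[str] = []
    values: list[np.ndarray] = []
    for gid, n, p in zip(group_ids, sizes, p_g):
        labels.extend([gid] * n)
        growers.extend(f"{gid}-{i + 1:05d}" for i in range(n))
        values.append((rng.random(n) < p).astype(float))
    adoption = pd.DataFrame(
        {practice_id: np.concatenate(values)},
        index=pd.Index(growers, name="grower_id"),
    )
    groups = pd.Series(labels, index=adoption.index, name="group_id")
    return AdoptionMatrix(adoption, groups)


def sample_likert(mean: float, sigma: float, n: int, seed) -> np.ndarray:
    """Integer Likert draws: normal(mean, sigma), rounded, clamped to [1, 7]."""
    if not 1.0 <= mean <= 7.0:
        raise ValueError("mean must lie in [1, 7]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = _rng(seed)
    draws = np.rint(rng.normal(mean, sigma, size=n))
    return np.clip(draws, 1, 7).astype(int)


def inject_missingness(adoption: AdoptionMatrix, rate: float, seed) -> AdoptionMatrix:
    """Set each non-missing adoption cell to missing with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return AdoptionMatrix(adoption.adoption.copy(), adoption.groups.copy())
    rng = _rng(seed)
    values = adoption.adoption.to_numpy(dtype=float).copy()
    hit = rng.random(values.shape) < rate
    values[hit & ~np.isnan(values)] = np.nan
    out = pd.DataFrame(
        values, index=adoption.adoption.index, columns=adoption.adoption.columns
    )
    return AdoptionMatrix(out, adoption.groups.copy())


# ---------------------------------------------------------------------
# study composition
# ---------------------------------------------------------------------

def _child(seed: int, stream: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed, spawn_key=(stream, *key))


def generate_study(
    config: SyntheticStudyConfig,
) -> tuple[AdoptionMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic study from one config.

    Returns ``(adoption, ratings, ground_truth)``: the adoption matrix
    and expert ratings frame feed the pipeline, and the ground-truth
    frame (true per-group frequencies, target F_ST, true Likert means
    per practice) supports recovery tests.  Fully reproducible from
    ``config.seed``.
    """
    seed = config.seed
    practice_ids = config.practice_ids
    group_ids = config.group_ids

    # per-practice parameters, drawn once when not supplied; each practice
    # uses its own child stream so the draws are stable under n_practices
    drawn = np.empty((config.n_practices, 5))
    for j in range(config.n_practices):
        r = _rng(_child(seed, _STREAM_PARAMS, j))
        drawn[j] = [
            r.uniform(0.2, 0.8),    # grand-mean adoption
            r.uniform(0.01, 0.4),   # target differentiation
            r.uniform(2.0, 6.0),    # cost mean
            r.uniform(2.0, 6.0),    # private-benefit mean
            r.uniform(2.0, 6.0),    # public-benefit mean
        ]

    def pick(supplied, col):
        if supplied is not None:
            return np.asarray(supplied, dtype=float)
        return drawn[:, col]

    p_bar = pick(config.p_bar, 0)
    target = pick(config.target_fst, 1)
    cost_mean = pick(config.cost_mean, 2)
    benefit_mean = pick(config.private_benefit_mean, 3)
    public_mean = pick(config.public_benefit_mean, 4)

    # adoption: per-practice frequency and Bernoulli streams
    columns: dict[str, np.ndarray] = {}
    truth_rows = []
    index = None
    groups = None
    for j, pid in enumerate(practice_ids):
        p_g = sample_group_frequencies(
            p_bar[j], target[j], config.n_groups, _child(seed, _STREAM_FREQS, j)
        )
        one = sample_adoption(
            p_g,
            config.group_sizes,
            _child(seed, _STREAM_ADOPTION, j),
            practice_id=pid,
            group_ids=group_ids,
        )
        if index is None:
            index, groups = one.adoption.index, one.groups
        vals = one.adoption[pid].to_numpy()
        if config.missing_rate > 0:
            # per-practice stream so adding practices never perturbs
            # earlier columns' missingness patterns
            miss_rng = _rng(_child(seed, _STREAM_ADOPT_MISS, j))
            vals = vals.copy()
            vals[miss_rng.random(len(vals)) < config.missing_rate] = np.nan
        columns[pid] = vals
        truth = {
            "practice_id": pid,
            "p_bar": p_bar[j],
            "target_fst": target[j],
            "cost_mean": cost_mean[j],
            "private_benefit_mean": benefit_mean[j],
            "public_benefit_mean": public_mean[j],
            "net_cost_mean": cost_mean[j] - benefit_mean[j],
        }
        truth.update({f"true_p_{g}": p for g, p in zip(group_ids, p_g)})
        truth_rows.append(truth)

    adoption = AdoptionMatrix(pd.DataFrame(columns, index=index), groups)

    # expert panel: every expert rates every practice; items go missing
    # independently at the same completely-at-random rate
    expert_ids = [f"expert_{i + 1:03d}" for i in range(config.n_experts)]
    frames = []
    for j, pid in enumerate(practice_ids):
        items = {}
        for k, (name, mu) in enumerate(
            (("cost", cost_mean[j]),
             ("private_benefit", benefit_mean[j]),
             ("public_benefit", public_mean[j]))
        ):
            items[name] = sample_likert(
                mu, config.likert_sigma, config.n_experts,
                _child(seed, _STREAM_LIKERT, j, k),
            ).astype(float)
        frame = pd.DataFrame(
            {"expert_id": expert_ids, "practice_id": pid, **items}
        )
        if config.missing_rate > 0:
            miss_rng = _rng(_child(seed, _STREAM_RATE_MISS, j))
            for name in ("cost", "private_benefit", "public_benefit"):
                hit = miss_rng.random(config.n_experts) < config.missing_rate
                frame.loc[hit, name] = np.nan
        frames.append(frame)
    ratings = pd.concat(frames, ignore_index=True)[list(RATING_COLUMNS)]

    return adoption, ratings, pd.DataFrame(truth_rows)
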