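"""Readers, writers and validated containers for the survey tables.

Two inputs drive the analysis: a grower table recording which of the
binary management practices each grower has adopted (one row per grower,
with a regional group label), and an expert table of 7-point Likert
ratings of each practice's individual economic cost, individual economic
benefit and public environmental benefit.  Everything is plain CSV with a
header row; the missing-value token and column names are declared in a
small spec object so exports from different survey platforms can be read
without editing the files.

I/O is side-effect free with respect to analysis policy: practices that
have no responses in some group are flagged at read time but never
dropped here — exclusion decisions belong to the estimators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: number of significant digits used when writing floating-point columns;
#: chosen so a write/read round trip is lossless for float64.
_FLOAT_FORMAT = "%.17g"


class SurveyFormatError(ValueError):
    """Raised when an input table violates the declared format."""


class KeyMismatchError(ValueError):
    """Raised when two per-practice tables do not share the same keys."""


@dataclass(frozen=True)
class AdoptionTableSpec:
    """Column mapping for a grower adoption table.

    Parameters
    ----------
    grower_col, group_col
        Names of the grower-identifier and group-label columns.
    practice_cols
        Explicit practice columns; ``None`` means every column other than
        the grower and group columns.
    missing_token
        Cell value mapped to "missing".  Empty cells are always missing.
    truthy, falsy
        Accepted spellings (case-insensitive) for adopted / not adopted.
    """

    grower_col: str = "grower_id"
    group_col: str = "group_id"
    practice_cols: tuple[str, ...] | None = None
    missing_token: str = "NA"
    truthy: tuple[str, ...] = ("1", "yes", "y", "true")
    falsy: tuple[str, ...] = ("0", "no", "n", "false")


@dataclass(frozen=True)
class RatingsTableSpec:
    """Column mapping for an expert Likert ratings table."""

    expert_col: str = "expert_id"
    practice_col: str = "practice_id"
    cost_col: str = "cost"
    private_benefit_col: str = "private_benefit"
    public_benefit_col: str = "public_benefit"
    missing_token: str = "NA"


@dataclass(frozen=True)
class ExpertRating:
    """One expert's Likert triple for one practice (items may be missing)."""

    expert_id: str
    practice_id: str
    cost: int | None
    private_benefit: int | None
    public_benefit: int | None


RATING_COLUMNS = (
    "expert_id",
    "practice_id",
    "cost",
    "private_benefit",
    "public_benefit",
)


@dataclass
class AdoptionMatrix:
    """Growers x practices binary adoption with group labels.

    Attributes
    ----------
    adoption
        Float frame indexed by grower id, one column per practice, values
        0.0, 1.0 or NaN (missing).
    groups
        Group label per grower, aligned with ``adoption.index``.
    """

    adoption: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        idx = self.adoption.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise SurveyFormatError(f"duplicate grower_id: {dup!r}")
        if not idx.equals(self.groups.index):
            raise SurveyFormatError("groups index does not match adoption index")
        if self.groups.isna().any():
            raise SurveyFormatError("every grower must carry a group label")
        if self.groups.nunique() < 2:
            raise SurveyFormatError(
                f"fewer than 2 groups (found {self.groups.nunique()})"
            )
        if self.adoption.shape[1] < 1:
            raise SurveyFormatError("at least one practice column is required")
        values = self.adoption.to_numpy(dtype=float)
        bad = ~(np.isnan(values) | (values == 0.0) | (values == 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SurveyFormatError(
                f"adoption value {values[i, j]!r} at grower {idx[i]!r}, "
                f"practice {self.adoption.columns[j]!r} is not 0/1/missing"
            )

    # -- convenience --------------------------------------------------
    @property
    def n_growers(self) -> int:
        return len(self.adoption)

    @property
    def practice_ids(self) -> list[str]:
        return list(self.adoption.columns)

    @property
    def group_ids(self) -> list[str]:
        return sorted(self.groups.unique())

    def practices_unobserved_in_some_group(self) -> dict[str, list[str]]:
        """Practices with zero non-missing responses in at least one group.

        Returned as ``{practice_id: [group_id, ...]}``; these are flagged
        for the caller but intentionally not removed.
        """
        counts = self.adoption.notna().groupby(self.groups, observed=True).sum()
        flagged: dict[str, list[str]] = {}
        for practice in self.adoption.columns:
            empty = counts.index[counts[practice] == 0]
            if len(empty):
                flagged[practice] = list(empty)
        return flagged

    def subset_groups(self, keep: Sequence[str]) -> "AdoptionMatrix":
        """Restrict to growers in the named groups (order preserved)."""
        unknown = set(keep) - set(self.groups.unique())
        if unknown:
            raise KeyError(f"unknown group label(s): {sorted(unknown)}")
        mask = self.groups.isin(keep).to_numpy()
        return AdoptionMatrix(self.adoption.loc[mask], self.groups.loc[mask])


# ---------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------

def _read_csv(path) -> pd.DataFrame:
    # all-string parse: value interpretation is governed by the spec,
    # not by pandas' NA heuristics
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_adoption_table(
    path, spec: AdoptionTableSpec | None = None
) -> AdoptionMatrix:
    """Read and validate a grower adoption CSV.

    Raises :class:`SurveyFormatError` on duplicate grower ids, fewer than
    two groups, or any adoption cell outside {truthy, falsy, missing}.
    """
    spec = spec or AdoptionTableSpec()
    raw = _read_csv(path)
    for col in (spec.grower_col, spec.group_col):
        if col not in raw.columns:
            raise SurveyFormatError(f"missing required column {col!r}")
    if spec.practice_cols is None:
        practice_cols = [
            c for c in raw.columns if c not in (spec.grower_col, spec.group_col)
        ]
    else:
        missing_cols = [c for c in spec.practice_cols if c not in raw.columns]
        if missing_cols:
            raise SurveyFormatError(f"practice column(s) not found: {missing_cols}")
        practice_cols = list(spec.practice_cols)
    if not practice_cols:
        raise SurveyFormatError("no practice columns found")

    truthy = {t.lower() for t in spec.truthy}
    falsy = {f.lower() for f in spec.falsy}
    missing = {spec.missing_token.lower(), ""}

    def decode(value: str, row: int, col: str) -> float:
        v = value.strip().lower()
        if v in missing:
            return np.nan
        if v in truthy:
            return 1.0
        if v in falsy:
            return 0.0
        raise SurveyFormatError(
            f"unrecognized adoption value {value!r} at row {row + 2}, "
            f"column {col!r}"  # +2: header line plus 1-based numbering
        )

    data = {
        col: [decode(v, i, col) for i, v in enumerate(raw[col])]
        for col in practice_cols
    }
    adoption = pd.DataFrame(data, index=pd.Index(raw[spec.grower_col], name="grower_id"))
    groups = pd.Series(
        raw[spec.group_col].to_numpy(), index=adoption.index, name="group_id"
    )
    if (groups.str.strip() == "").any():
        raise SurveyFormatError("empty group label encountered")

    matrix = AdoptionMatrix(adoption, groups)
    flagged = matrix.practices_unobserved_in_some_group()
    for practice, groups_missing in flagged.items():
        logger.warning(
            "practice %r has no non-missing responses in group(s) %s",
            practice,
            groups_missing,
        )
    return matrix


def read_expert_ratings(
    path, spec: RatingsTableSpec | None = None
) -> pd.DataFrame:
    """Read and validate an expert ratings CSV.

    Returns a frame with columns ``expert_id, practice_id, cost,
    private_benefit, public_benefit``; Likert items are floats with NaN
    for missing.  Raises :class:`SurveyFormatError` for out-of-range
    Likert values or duplicated (expert, practice) pairs.
    """
    spec = spec or RatingsTableSpec()
    raw = _read_csv(path)
    needed = {
        spec.expert_col: "expert_id",
        spec.practice_col: "practice_id",
        spec.cost_col: "cost",
        spec.private_benefit_col: "private_benefit",
        spec.public_benefit_col: "public_benefit",
    }
    for col in needed:
        if col not in raw.columns:
            raise SurveyFormatError(f"missing required column {col!r}")

    missing = {spec.missing_token.lower(), ""}

    def decode(value: str, row: int, col: str) -> float:
        v = value.strip()
        if v.lower() in missing:
            return np.nan
        try:
            x = float(v)
        except ValueError:
            raise SurveyFormatError(
                f"non-numeric Likert value {value!r} at row {row + 2}, column {col!r}"
            ) from None
        if x != int(x) or not (1 <= x <= 7):
            raise SurveyFormatError(
                f"Likert value {value!r} outside 1-7 at row {row + 2}, column {col!r}"
            )
        return x

    out = pd.DataFrame(
        {
            "expert_id": raw[spec.expert_col].to_numpy(),
            "practice_id": raw[spec.practice_col].to_numpy(),
            "cost": [decode(v, i, spec.cost_col) for i, v in enumerate(raw[spec.cost_col])],
            "private_benefit": [
                decode(v, i, spec.private_benefit_col)
                for i, v in enumerate(raw[spec.private_benefit_col])
            ],
            "public_benefit": [
                decode(v, i, spec.public_benefit_col)
                for i, v in enumerate(raw[spec.public_benefit_col])
            ],
        }
    )
    dup = out.duplicated(subset=["expert_id", "practice_id"])
    if dup.any():
        first = out.loc[dup, ["expert_id", "practice_id"]].iloc[0]
        raise SurveyFormatError(
            f"duplicated (expert, practice) pair: "
            f"({first['expert_id']!r}, {first['practice_id']!r})"
        )
    return out


def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory ratings frame against the same invariants."""
    missing_cols = [c for c in RATING_COLUMNS if c not in ratings.columns]
    if missing_cols:
        raise SurveyFormatError(f"ratings frame missing column(s): {missing_cols}")
    for col in ("cost", "private_benefit", "public_benefit"):
        vals = ratings[col].to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals == np.round(vals)) & (vals >= 1) & (vals <= 7))
        if not ok.all():
            i = int(np.argmin(ok))
            raise SurveyFormatError(
                f"Likert value {vals[i]!r} outside 1-7 in column {col!r} (row {i})"
            )
    if ratings.duplicated(subset=["expert_id", "practice_id"]).any():
        raise SurveyFormatError("duplicated (expert, practice) pair")
    return ratings


# ---------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------

def write_adoption_table(
    matrix: AdoptionMatrix, path, spec: AdoptionTableSpec | None = None
) -> None:
    """Write an adoption matrix in the dialect :func:`read_adoption_table` reads."""
    spec = spec or AdoptionTableSpec()
    out = pd.DataFrame(index=matrix.adoption.index)
    out[spec.group_col] = matrix.groups
    for col in matrix.adoption.columns:
        vals = matrix.adoption[col]
        out[col] = np.where(
            vals.isna(), spec.missing_token, vals.fillna(0).astype(int).astype(str)
        )
    out.index.name = spec.grower_col
    out.to_csv(path)


def write_expert_ratings(
    ratings: pd.DataFrame, path, spec: RatingsTableSpec | None = None
) -> None:
    """Write a ratings frame in the dialect :func:`read_expert_ratings` reads."""
    spec = spec or RatingsTableSpec()
    validate_ratings(ratings)
    out = pd.DataFrame(
        {
            spec.expert_col: ratings["expert_id"],
            spec.practice_col: ratings["practice_id"],
        }
    )
    for src, dst in (
        ("cost", spec.cost_col),
        ("private_benefit", spec.private_benefit_col),
        ("public_benefit", spec.public_benefit_col),
    ):
        vals = ratings[src]
        out[dst] = np.where(
            vals.isna(), spec.missing_token, vals.fillna(0).astype(int).astype(str)
        )
    out.to_csv(path, index=False)


def write_scope_table(scopes, econs, path) -> pd.DataFrame:
    """Write the per-practice scope table as CSV.

    ``scopes`` is a collection of :class:`~cultscope.selection_scope.PracticeScope`
    and ``econs`` of :class:`~cultscope.cost_benefit.PracticeEconomics`; both
    must be keyed by the same practice identifiers.  Returns the frame that
    was written.  The numeric columns round-trip losslessly through
    :func:`read_scope_table`.
    """
    scope_keys = [s.practice_id for s in scopes]
    econ_by_key = {e.practice_id: e for e in econs}
    missing = [k for k in scope_keys if k not in econ_by_key]
    extra = [k for k in econ_by_key if k not in set(scope_keys)]
    if missing or extra:
        raise KeyMismatchError(
            f"practice keys differ between scopes and economics; "
            f"missing economics for {missing}, unmatched economics {extra}"
        )

    group_ids: list[str] = []
    for s in scopes:
        if s.freqs is not None:
            for g in s.freqs.group_ids:
                if g not in group_ids:
                    group_ids.append(g)

    rows = []
    for s in scopes:
        e = econ_by_key[s.practice_id]
        row: dict[str, object] = {"practice_id": s.practice_id}
        for g in group_ids:
            n_g, p_g = np.nan, np.nan
            if s.freqs is not None and g in s.freqs.group_ids:
                i = s.freqs.group_ids.index(g)
                n_g, p_g = s.freqs.n[i], s.freqs.p[i]
            row[f"n_{g}"] = n_g
            row[f"p_{g}"] = p_g
        row["p_bar"] = s.freqs.p_bar if s.freqs is not None else np.nan
        row["fst"] = s.fst
        row["fst_corrected"] = np.nan if s.fst_corrected is None else s.fst_corrected
        row["mls_threshold"] = s.mls_threshold
        row["mean_net_private_cost"] = e.mean_net_private_cost
        row["mean_public_benefit"] = e.mean_public_benefit
        row["n_cost_raters"] = e.n_cost_raters
        row["n_public_raters"] = e.n_public_raters
        row["regime"] = s.regime.value
        row["permutation_p"] = (
            np.nan if s.permutation_p is None else s.permutation_p
        )
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return frame


def read_scope_table(path) -> pd.DataFrame:
    """Read back a scope table written by :func:`write_scope_table`."""
    return pd.read_csv(path)
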