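import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cultscope import AdoptionMatrix

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_adoption(values_by_group: dict[str, list], practice_id: str = "p1") -> AdoptionMatrix:
    """Build a one-practice adoption matrix from per-group value lists.

    Values may include ``None``/NaN for missing responses.
    """
    growers, labels, vals = [], [], []
    for group, entries in values_by_group.items():
        for i, v in enumerate(entries):
            growers.append(f"{group}-{i}")
            labels.append(group)
            vals.append(np.nan if v is None else float(v))
    idx = pd.Index(growers, name="grower_id")
    return AdoptionMatrix(
        pd.DataFrame({practice_id: vals}, index=idx),
        pd.Series(labels, index=idx, name="group_id"),
    )


def make_ratings(rows: list[tuple]) -> pd.DataFrame:
    """Rows of (expert, practice, cost, private_benefit, public_benefit)."""
    return pd.DataFrame(
        rows,
        columns=["expert_id", "practice_id", "cost", "private_benefit", "public_benefit"],
    ).astype({"cost": float, "private_benefit": float, "public_benefit": float})


@pytest.fixture
def adoption_two_groups() -> AdoptionMatrix:
    # p_A = 0.2, p_B = 0.8, equal sizes of 5
    return make_adoption({"A": [1, 0, 0, 0, 0], "B": [1, 1, 1, 1, 0]})
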