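"""Core containers shared across the pipeline.

The expression matrix is a plain :class:`pandas.DataFrame` (rows = samples,
columns = genes, values = log2 expression); :func:`validate_expression`
enforces its invariants.  The cohort design wraps the sample -> (group,
pair) assignment of a 1:1 matched case-control study and is the unit of
resampling for the pair bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"

_GROUP_ALIASES = {
    "case": CASE,
    "control": CONTROL,
    "ctrl": CONTROL,
}


def normalize_group(label: str) -> str:
    """Map a group label (case-insensitively) to ``'case'`` / ``'control'``."""
    key = str(label).strip().lower()
    if key not in _GROUP_ALIASES:
        raise ValueError(f"unknown group label {label!r}: expected 'case' or 'control'")
    return _GROUP_ALIASES[key]


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants and return the matrix.

    Rows are samples, columns are genes, values log2-scale expression.
    Missing values are an input error, never a state.
    """
    if not isinstance(matrix, pd.DataFrame):
        raise TypeError("expression matrix must be a pandas DataFrame (samples x genes)")
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"duplicate sample label {dup!r}")
    if matrix.columns.has_duplicates:
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise ValueError(f"duplicate gene label {dup!r}")
    values = matrix.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise ValueError("expression matrix must be numeric")
    if values.size and not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite expression value at sample {matrix.index[bad[0]]!r}, "
            f"gene {matrix.columns[bad[1]]!r}"
        )
    return matrix


@dataclass(frozen=True)
class CohortDesign:
    """Sample -> group and matched-pair assignment of a 1:1 matched cohort.

    ``table`` is indexed by sample id with columns ``group`` (``'case'`` /
    ``'control'``) and ``pair_id``.  Every pair id maps to exactly one case
    and one control; this is validated at construction.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"group", "pair_id"}
        if not required.issubset(t.columns):
            raise ValueError(f"design table needs columns {sorted(required)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in design")
        groups = t["group"].map(normalize_group)
        t = t.assign(group=groups)
        object.__setattr__(self, "table", t)
        pairs = t["pair_id"]
        case_counts = pairs[groups == CASE].value_counts()
        control_counts = pairs[groups == CONTROL].value_counts()
        unique_pairs = pairs.unique()
        ok = (
            case_counts.reindex(unique_pairs, fill_value=0).eq(1).all()
            and control_counts.reindex(unique_pairs, fill_value=0).eq(1).all()
        )
        if not ok:
            for pid in unique_pairs:
                nc = int(case_counts.get(pid, 0))
                nk = int(control_counts.get(pid, 0))
                if nc != 1 or nk != 1:
                    raise ValueError(
                        f"pair {pid!r} must contain exactly one case and one "
                        f"control (got {nc} cases, {nk} controls)"
                    )

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def pair_ids(self) -> list:
        seen: dict = {}
        for pid in self.table["pair_id"]:
            seen.setdefault(pid, None)
        return list(seen)

    @property
    def n_pairs(self) -> int:
        return self.table["pair_id"].nunique()

    def y(self, sample_ids=None) -> np.ndarray:
        """Binary status vector (case = 1, control = 0) in the given order."""
        t = self.table if sample_ids is None else self.table.loc[list(sample_ids)]
        return (t["group"] == CASE).to_numpy(dtype=int)

    def members(self, pair_id) -> tuple:
        """(case sample id, control sample id) for one pair."""
        sub = self.table[self.table["pair_id"] == pair_id]
        case = sub.index[sub["group"] == CASE][0]
        control = sub.index[sub["group"] == CONTROL][0]
        return case, control

    def check_matches(self, matrix: pd.DataFrame) -> None:
        """Require matrix samples and design samples to be the same set."""
        missing = self.table.index.difference(matrix.index)
        if len(missing):
            raise ValueError(f"design sample {missing[0]!r} absent from expression matrix")
        extra = matrix.index.difference(self.table.index)
        if len(extra):
            raise ValueError(f"expression sample {extra[0]!r} absent from design")

    @classmethod
    def from_records(cls, records) -> "CohortDesign":
        """Build from an iterable of (sample_id, group, pair_id)."""
        df = pd.DataFrame(records, columns=["sample_id", "group", "pair_id"])
        return cls(df.set_index("sample_id"))
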