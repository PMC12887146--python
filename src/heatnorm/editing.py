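"""Test-day record editing, contemporary groups and class assignment.

Editing rules for first-lactation test-day milk yield records:

* records restricted to days in milk (DIM) 5-305;
* lactation duration (last test DIM) at least 90 days;
* first test-day before DIM 75;
* at least four test-days per lactation;
* cow aged 22-60 months at calving;
* at least one known parent;
* contemporary groups (CG) = herd-year-month of test with at least four
  distinct animals;
* records beyond 3.0 SD from their CG mean removed (single pass).

DIM classes use a 50-day grid (5-54, ..., 255-305); residual classes cross
three DIM groups (class 1, classes 2-4, classes 5-6) with two THI groups
(classes 60-62 vs. 64-80), giving six combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("animal", "herd", "date", "dim", "milk_kg", "age_months")

DIM_MIN, DIM_MAX = 5, 305
N_DIM_CLASSES = 6
N_RESIDUAL_CLASSES = 6


@dataclass
class EditReport:
    """Counts of records/lactations removed per rule, in application order."""

    n_input_records: int = 0
    n_output_records: int = 0
    steps: list[dict] = field(default_factory=list)

    def add(self, rule: str, records_removed: int, lactations_removed: int | None = None):
        self.steps.append(
            {
                "rule": rule,
                "records_removed": int(records_removed),
                "lactations_removed": None
                if lactations_removed is None
                else int(lactations_removed),
            }
        )

    @property
    def total_removed(self) -> int:
        return sum(s["records_removed"] for s in self.steps)

    def check_conservation(self) -> bool:
        return self.n_input_records == self.n_output_records + self.total_removed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _require(records: pd.DataFrame, cols=REQUIRED_COLUMNS):
    missing = set(cols) - set(records.columns)
    if missing:
        raise ValueError(f"records missing required columns: {sorted(missing)}")


def apply_lactation_filters(
    records: pd.DataFrame, parents: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, EditReport]:
    """Apply the five lactation-level rules (plus the DIM 5-305 restriction).

    ``parents`` is a frame with columns ``animal, sire, dam`` (0 or NA =
    unknown) used for the known-parent rule; if omitted, ``records`` itself
    must carry ``sire``/``dam`` columns.
    """
    _require(records)
    rep = EditReport(n_input_records=len(records))
    df = records.copy()
    df["date"] = pd.to_datetime(df["date"])

    in_range = (df["dim"] >= DIM_MIN) & (df["dim"] <= DIM_MAX)
    rep.add("dim outside 5-305", (~in_range).sum())
    df = df[in_range]

    if parents is None:
        if not {"sire", "dam"}.issubset(df.columns):
            raise ValueError("parents table required (or sire/dam columns in records)")
        parents = df[["animal", "sire", "dam"]].drop_duplicates("animal")
    par = parents.drop_duplicates("animal").set_index("animal")

    def _known(x):
        return x.notna() & (x.astype(str) != "0")

    has_parent = (_known(par["sire"]) | _known(par["dam"])).to_dict()

    grp = df.groupby("animal")
    stats = pd.DataFrame(
        {
            "duration": grp["dim"].max(),
            "first_test": grp["dim"].min(),
            "n_tests": grp["dim"].size(),
            "age": grp["age_months"].first(),
        }
    )
    stats["known_parent"] = [has_parent.get(a, False) for a in stats.index]

    rules = [
        ("min lactation duration 90 d", stats["duration"] >= 90),
        ("first test-day before DIM 75", stats["first_test"] < 75),
        ("min four test-days", stats["n_tests"] >= 4),
        ("age at calving 22-60 months", (stats["age"] >= 22) & (stats["age"] <= 60)),
        ("at least one known parent", stats["known_parent"]),
    ]
    surviving = pd.Series(True, index=stats.index)
    for name, ok in rules:
        newly_removed = surviving & ~ok
        n_lact = int(newly_removed.sum())
        n_rec = int(df["animal"].isin(newly_removed[newly_removed].index).sum())
        rep.add(name, n_rec, n_lact)
        surviving &= ok
    df = df[df["animal"].isin(surviving[surviving].index)]
    rep.n_output_records = len(df)
    return df, rep


def contemporary_group_key(df: pd.DataFrame) -> pd.Series:
    """CG id = herd-year-month of the test date."""
    d = pd.to_datetime(df["date"])
    return (
        df["herd"].astype(str)
        + "-"
        + d.dt.year.astype(str)
        + "-"
        + d.dt.month.astype(str).str.zfill(2)
    )


def form_contemporary_groups(
    records: pd.DataFrame, min_size: int = 4
) -> tuple[pd.DataFrame, EditReport]:
    """Assign CG ids and drop CGs with fewer than ``min_size`` distinct animals."""
    _require(records, ("animal", "herd", "date"))
    rep = EditReport(n_input_records=len(records))
    df = records.copy()
    df["cg"] = contemporary_group_key(df)
    sizes = df.groupby("cg")["animal"].nunique()
    keep = sizes[sizes >= min_size].index
    removed = int((~df["cg"].isin(keep)).sum())
    rep.add(f"CG with fewer than {min_size} animals", removed)
    df = df[df["cg"].isin(keep)]
    rep.n_output_records = len(df)
    return df, rep


def remove_cg_outliers(
    records: pd.DataFrame, k: float = 3.0
) -> tuple[pd.DataFrame, EditReport]:
    """Single-pass removal of records beyond ``k`` SD from their CG mean.

    Mean and SD (population denominator) are computed on the input values.
    Singleton CGs (SD undefined) retain their record, flagged in the report.
    """
    if "cg" not in records.columns:
        raise ValueError("contemporary groups must be formed first")
    rep = EditReport(n_input_records=len(records))
    df = records.copy()
    g = df.groupby("cg")["milk_kg"]
    mean = g.transform("mean")
    sd = g.transform(lambda x: x.std(ddof=0))
    size = g.transform("size")
    dev = (df["milk_kg"] - mean).abs()
    with np.errstate(invalid="ignore"):
        outlier = (dev > k * sd) & (sd > 0) & (size > 1)
    rep.add(f"beyond {k} SD of CG mean", int(outlier.sum()))
    n_singleton = int((size == 1).sum())
    if n_singleton:
        rep.add("singleton CG (retained, SD undefined)", 0)
    df = df[~outlier]
    rep.n_output_records = len(df)
    return df, rep


def assign_dim_class(dim):
    """DIM class 1..6 on the 50-day grid 5-54, ..., 255-305 (class 6: 51 days)."""
    d = np.asarray(dim)
    if np.any((d < DIM_MIN) | (d > DIM_MAX)):
        raise ValueError(f"DIM outside [{DIM_MIN}, {DIM_MAX}]")
    cls = np.minimum((d - DIM_MIN) // 50 + 1, N_DIM_CLASSES).astype(int)
    if cls.ndim == 0:
        return int(cls)
    return cls


def assign_residual_class(dim_class, thi_class):
    """Residual class 1..6 from (DIM group, THI group) in row-major order.

    DIM groups: {1}, {2,3,4}, {5,6}; THI groups: classes <= 62 vs. >= 64.
    """
    dc = np.asarray(dim_class)
    tc = np.asarray(thi_class)
    if np.any((dc < 1) | (dc > N_DIM_CLASSES)):
        raise ValueError("invalid DIM class")
    if np.any((tc < 60) | (tc > 80) | (tc % 2 != 0)):
        raise ValueError("invalid THI class")
    dim_group = np.where(dc == 1, 1, np.where(dc <= 4, 2, 3))
    thi_group = np.where(tc <= 62, 1, 2)
    out = ((dim_group - 1) * 2 + thi_group).astype(int)
    if out.ndim == 0:
        return int(out)
    return out


def edit_records(
    records: pd.DataFrame,
    parents: pd.DataFrame | None = None,
    min_cg_size: int = 4,
    k_outlier: float = 3.0,
) -> tuple[pd.DataFrame, EditReport]:
    """Full editing pipeline: lactation filters -> CG formation/size -> outliers.

    Also attaches ``dim_class`` and, when a ``thi_class`` column is present,
    the ``resid_class``.
    """
    rep = EditReport(n_input_records=len(records))
    df, r1 = apply_lactation_filters(records, parents)
    df, r2 = form_contemporary_groups(df, min_size=min_cg_size)
    df, r3 = remove_cg_outliers(df, k=k_outlier)
    for r in (r1, r2, r3):
        rep.steps.extend(r.steps)
    df = df.copy()
    df["dim_class"] = assign_dim_class(df["dim"].to_numpy())
    if "thi_class" in df.columns:
        df["resid_class"] = assign_residual_class(
            df["dim_class"].to_numpy(), df["thi_class"].to_numpy()
        )
    rep.n_output_records = len(df)
    return df, rep
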