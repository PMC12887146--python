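"""Forward validation of genomic and pedigree-based predictions.

A reduced data set drops all test-day records from the cutoff year onward,
mimicking selection decisions taken before the youngest animals had
phenotypes.  Predictions for the validation animals (the youngest genotyped
ones) from the reduced data are regressed against their complete-data
305-day values per THI class:

    y_complete = b0 + b1 * a_reduced + e

b1 indicates bias (1 = unbiased) and accuracy r = sqrt(r2), signed by the
correlation.  Variance components are not re-estimated on the reduced data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .surfaces import BreedingValueSet


def make_reduced_dataset(
    records: pd.DataFrame,
    genotyped_ids,
    birth_dates: pd.Series,
    cutoff_year: int = 2010,
    n_validation: int = 150,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Drop records dated >= ``cutoff_year``; pick the validation animals.

    Validation animals are the ``n_validation`` youngest genotyped animals
    (latest birth date, ties broken by id).
    """
    if n_validation < 1:
        raise ValueError("n_validation must be >= 1")
    genotyped_ids = list(genotyped_ids)
    if len(genotyped_ids) < n_validation:
        raise ValueError(
            f"only {len(genotyped_ids)} genotyped animals for "
            f"n_validation={n_validation}"
        )
    dates = pd.to_datetime(records["date"])
    reduced = records[dates.dt.year < cutoff_year].copy()
    bd = pd.to_datetime(birth_dates.loc[genotyped_ids])
    order = pd.DataFrame({"birth": bd, "id": bd.index.astype(str)}).sort_values(
        ["birth", "id"], ascending=[False, True]
    )
    validation = order.index[:n_validation].to_numpy()
    return reduced, validation


def validate(
    bv_complete: BreedingValueSet,
    bv_reduced: BreedingValueSet,
    validation_ids,
) -> pd.DataFrame:
    """Per-THI regression of complete-data values on reduced-data predictions.

    Returns a frame with columns ``thi, b0, b1, r2, r`` (r carries the sign
    of the correlation).  Raises if the predictor has zero variance.
    """
    ids = np.asarray(list(validation_ids), dtype=object)
    fc = bv_complete.as_frame().loc[ids]
    fr = bv_reduced.as_frame().loc[ids]
    if list(fc.columns) != list(fr.columns):
        raise ValueError("BV sets evaluated on different THI grids")
    rows = []
    for thi in fc.columns:
        x = fr[thi].to_numpy(float)
        y = fc[thi].to_numpy(float)
        if np.std(x) == 0:
            raise ValueError(f"zero variance in predictor at THI {thi}")
        res = stats.linregress(x, y)
        rows.append(
            {
                "thi": thi,
                "b0": res.intercept,
                "b1": res.slope,
                "r2": res.rvalue**2,
                "r": abs(res.rvalue) * np.sign(res.rvalue),
            }
        )
    return pd.DataFrame(rows)


def accuracy_range(result: pd.DataFrame) -> float:
    """Spread of validation accuracy across the THI scale."""
    return float(result["r"].max() - result["r"].min())
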