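"""Epigenetic age acceleration (EAA) outcome assembly.

EAA for an age clock is the residual from ordinary least squares of the
clock's estimate on chronological age: positive values mean a child is
epigenetically older than expected for their age.  The two pace-of-aging
measures are already rates and enter the outcome vector unresidualized.
The canonical 10-outcome order used throughout the package is fixed here.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OUTCOME_NAMES",
    "EAAError",
    "compute_eaa",
    "assemble_outcomes",
    "eaa_correlations",
]

#: canonical outcome order: eight residualized EAA columns, then the two
#: pace measures (passed through as-is)
OUTCOME_NAMES = (
    "EAA_PedBE",
    "EAA_Wu",
    "EAA_Horvath",
    "EAA_Hannum",
    "EAA_SkinBlood",
    "EAA_PhenoAge",
    "EAA_GrimAge2",
    "EAA_DNAmTL",
    "DunedinPACE",
    "DunedinPoAm38",
)

RESIDUALIZED = OUTCOME_NAMES[:8]
PACE_MEASURES = OUTCOME_NAMES[8:]


class EAAError(ValueError):
    pass


def compute_eaa(estimates: pd.Series, ages: pd.Series) -> pd.Series:
    """Residuals of OLS regression of clock estimates on chronological age.

    The residuals have mean zero and are exactly orthogonal to age (up to
    floating point), which is what makes EAA an age-independent measure.
    """
    est, age = estimates.align(ages, join="inner")
    if len(est) < len(estimates) or len(est) < len(ages):
        raise EAAError("sample ids of estimates and ages do not align")
    if len(est) < 3:
        raise EAAError("need at least 3 samples to residualize")
    a = age.to_numpy(dtype=float)
    y = est.to_numpy(dtype=float)
    ac = a - a.mean()
    denom = ac @ ac
    if denom == 0.0:
        raise EAAError("constant ages: regression on age is singular")
    slope = (ac @ y) / denom
    resid = y - y.mean() - slope * ac  # centred form: exactly mean-0, age-orthogonal
    return pd.Series(resid, index=est.index, name=estimates.name)


def assemble_outcomes(
    eaa_columns: Mapping[str, pd.Series],
    pace_columns: Mapping[str, pd.Series],
    child_to_mother: pd.Series,
) -> pd.DataFrame:
    """Join the 8 residualized columns and 2 pace columns into the canonical
    10-column outcome table.

    Pace columns are passed through bitwise; ids must align across all
    inputs and with the child-to-mother map.
    """
    cols = dict(eaa_columns) | dict(pace_columns)
    missing = [n for n in OUTCOME_NAMES if n not in cols]
    if missing:
        raise EAAError(f"missing outcome columns: {missing}")
    df = pd.DataFrame({n: cols[n] for n in OUTCOME_NAMES})
    if df.isna().any().any():
        offenders = sorted(df.index[df.isna().any(axis=1)].tolist())
        raise EAAError(f"sample ids not aligned across outcomes: {offenders[:5]}")
    unmapped = df.index.difference(child_to_mother.index)
    if len(unmapped):
        raise EAAError(f"children without mother ids: {list(unmapped[:5])}")
    out = df.copy()
    out.insert(0, "mother_id", child_to_mother.loc[df.index].to_numpy())
    out.insert(0, "child_id", df.index.to_numpy())
    return out.reset_index(drop=True)


def eaa_correlations(table: pd.DataFrame, ages: pd.Series) -> pd.DataFrame:
    """Pearson correlations among the 10 outcomes and chronological age."""
    if len(table) < 3:
        raise EAAError("need at least 3 rows for correlations")
    df = table.set_index("child_id")[list(OUTCOME_NAMES)].copy()
    df["age"] = ages
    if df["age"].isna().any():
        raise EAAError("ages missing for some children")
    sd = df.std(ddof=1)
    if (sd == 0.0).any():
        raise EAAError(
            f"undefined correlation for zero-variance columns "
            f"{list(sd.index[sd == 0.0])}"
        )
    return df.corr(method="pearson")
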