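"""Linear epigenetic-clock scoring.

An epigenetic clock is a linear predictor over CpG methylation beta values:
``score = intercept + sum_k weight_k * beta_k``, optionally passed through a
per-clock output transform (e.g. the log-linear age calibration used by the
Horvath-family clocks).  Clock definitions are pluggable: any CSV of
``cpg,weight,median`` rows plus a JSON sidecar describing intercept and
transform can be scored, so the engine is agnostic to which published clock
(PedBE, Wu, Horvath, Hannum, skin & blood, PhenoAge, GrimAge2, DNAmTL,
DunedinPACE, DunedinPoAm38, ...) a definition encodes.

Scoring enforces two rules: a per-sample coverage threshold (by default at
least 80% of a clock's CpGs must be present) and median imputation — CpGs
missing from the matrix are filled with reference medians carried inside the
clock definition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "ClockDefinition",
    "ClockEstimates",
    "ClockError",
    "CoverageError",
    "estimate_clock",
    "horvath_forward",
    "horvath_inverse",
    "clock_correlations",
]


class ClockError(ValueError):
    """Invalid clock definition or scoring input."""


class CoverageError(ClockError):
    """Too few of a clock's CpGs are present for a sample."""


TRANSFORMS = ("identity", "horvath_age", "telomere_kb", "pace")


@dataclass
class BetaMatrix:
    """CpG-by-sample matrix of methylation beta values in [0, 1].

    Wraps a pandas DataFrame indexed by CpG id with sample-id columns.
    Missing values (NaN) are allowed and handled by median imputation at
    scoring time.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ClockError("duplicate CpG ids in beta matrix")
        if self.values.columns.has_duplicates:
            raise ClockError("duplicate sample ids in beta matrix")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ClockError("beta values must lie in [0, 1]")

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "cpg"
        out.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BetaMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)


@dataclass
class ClockDefinition:
    """One linear clock: intercept, CpG weights, transform, reference medians.

    Parameters
    ----------
    name : str
        Clock identifier.
    intercept : float
        Intercept on the transform (linear-score) scale.
    weights : mapping of CpG id to weight
        Per-CpG regression weights on the linear-score scale per beta unit.
    transform : str
        One of ``identity``, ``horvath_age`` (log-linear age calibration,
        needs ``adult_age``), ``telomere_kb`` or ``pace`` (both identity
        maps kept as distinct unit labels).
    reference_medians : mapping of CpG id to beta
        Fill-in values for CpGs absent from a beta matrix; must cover every
        weighted CpG.
    min_coverage : float
        Minimum fraction of weighted CpGs that must be present per sample.
    adult_age : float
        Calibration knot of the Horvath age transform, in years.
    """

    name: str
    intercept: float
    weights: Mapping[str, float]
    transform: str = "identity"
    reference_medians: Mapping[str, float] = field(default_factory=dict)
    min_coverage: float = 0.80
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if not self.weights:
            raise ClockError(f"clock {self.name!r}: empty weight set")
        if self.transform not in TRANSFORMS:
            raise ClockError(
                f"clock {self.name!r}: unknown transform {self.transform!r}"
            )
        if not (0.0 < self.min_coverage <= 1.0):
            raise ClockError(f"clock {self.name!r}: min_coverage must be in (0, 1]")
        missing = set(self.weights) - set(self.reference_medians)
        if missing:
            raise ClockError(
                f"clock {self.name!r}: {len(missing)} weighted CpGs lack a "
                f"reference median (e.g. {sorted(missing)[:3]})"
            )
        if self.transform == "horvath_age" and self.adult_age <= 0:
            raise ClockError(f"clock {self.name!r}: adult_age must be positive")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.weights)

    def apply_transform(self, score: np.ndarray) -> np.ndarray:
        if self.transform == "horvath_age":
            return horvath_inverse(score, self.adult_age)
        return np.asarray(score, dtype=float)

    def invert_transform(self, target: np.ndarray) -> np.ndarray:
        """Map a clock-output target back to the linear-score scale."""
        if self.transform == "horvath_age":
            return horvath_forward(np.asarray(target, dtype=float), self.adult_age)
        return np.asarray(target, dtype=float)

    # -- persistence: CSV of cpg,weight,median + JSON sidecar ---------------

    def to_files(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = pd.DataFrame(
            {
                "cpg": list(self.weights),
                "weight": [self.weights[c] for c in self.weights],
                "median": [self.reference_medians[c] for c in self.weights],
            }
        )
        rows.to_csv(directory / f"{self.name}.csv", index=False)
        meta = {
            "name": self.name,
            "intercept": self.intercept,
            "transform": self.transform,
            "adult_age": self.adult_age,
            "min_coverage": self.min_coverage,
        }
        (directory / f"{self.name}.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_files(cls, csv_path: str | Path) -> "ClockDefinition":
        csv_path = Path(csv_path)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        rows = pd.read_csv(csv_path, dtype={"cpg": str})
        return cls(
            name=meta["name"],
            intercept=float(meta["intercept"]),
            weights=dict(zip(rows["cpg"], rows["weight"].astype(float))),
            transform=meta.get("transform", "identity"),
            reference_medians=dict(zip(rows["cpg"], rows["median"].astype(float))),
            min_coverage=float(meta.get("min_coverage", 0.80)),
            adult_age=float(meta.get("adult_age", 20.0)),
        )


def load_clock_directory(directory: str | Path) -> list[ClockDefinition]:
    """Load every ``<name>.csv`` + ``<name>.json`` clock pair in a directory."""
    directory = Path(directory)
    clocks = [
        ClockDefinition.from_files(p)
        for p in sorted(directory.glob("*.csv"))
        if p.with_suffix(".json").exists()
    ]
    if not clocks:
        raise ClockError(f"no clock definitions found in {directory}")
    return clocks


@dataclass
class ClockEstimates:
    """Per-sample clock output plus the fraction of required CpGs present."""

    clock_name: str
    estimates: pd.Series  # indexed by sample id, clock output units
    coverage: pd.Series  # fraction of weighted CpGs present per sample


def horvath_forward(age: np.ndarray | float, adult_age: float = 20.0) -> np.ndarray:
    """Log-linear age calibration F(age): log-compressed below adult_age.

    F(age) = log(age + 1) - log(adult_age + 1)     for age < adult_age
           = (age - adult_age) / (adult_age + 1)   otherwise
    """
    if adult_age <= 0:
        raise ClockError("adult_age must be positive")
    a = np.asarray(age, dtype=float)
    if np.any(a <= -1.0):
        raise ClockError("age must exceed -1 year for the log-linear transform")
    return np.where(
        a < adult_age,
        np.log(a + 1.0) - math.log(adult_age + 1.0),
        (a - adult_age) / (adult_age + 1.0),
    )


def horvath_inverse(score: np.ndarray | float, adult_age: float = 20.0) -> np.ndarray:
    """Exact inverse of :func:`horvath_forward`, mapping scores to years."""
    if adult_age <= 0:
        raise ClockError("adult_age must be positive")
    s = np.asarray(score, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ClockError("non-finite clock score")
    return np.where(
        s < 0,
        (adult_age + 1.0) * np.exp(s) - 1.0,
        adult_age + s * (adult_age + 1.0),
    )


def estimate_clock(beta: BetaMatrix, clock: ClockDefinition) -> ClockEstimates:
    """Score every sample in ``beta`` against ``clock``.

    A CpG is *present* for a sample when its row exists in the matrix and the
    value is not NaN.  Samples whose present fraction falls below the clock's
    ``min_coverage`` raise :class:`CoverageError`; the remaining gaps are
    filled with the clock's reference medians before the weighted sum.
    """
    if beta.values.empty:
        raise ClockError("empty beta matrix")
    cpgs = clock.cpg_ids
    # rows for the clock's CpGs, NaN where the CpG is absent from the matrix
    sub = beta.values.reindex(cpgs)
    present = sub.notna()
    coverage = present.sum(axis=0) / len(cpgs)
    bad = coverage[coverage < clock.min_coverage]
    if len(bad):
        sid, frac = bad.index[0], float(bad.iloc[0])
        raise CoverageError(
            f"clock {clock.name!r}: sample {sid!r} supplies only "
            f"{frac:.0%} of {len(cpgs)} required CpGs "
            f"(threshold {clock.min_coverage:.0%})"
        )
    medians = pd.Series({c: clock.reference_medians[c] for c in cpgs})
    filled = sub.apply(lambda col: col.fillna(medians))
    w = np.array([clock.weights[c] for c in cpgs], dtype=float)
    score = clock.intercept + w @ filled.to_numpy(dtype=float)
    out = pd.Series(
        clock.apply_transform(score), index=beta.sample_ids, name=clock.name
    )
    return ClockEstimates(clock_name=clock.name, estimates=out, coverage=coverage)


def clock_correlations(
    estimates: Sequence[ClockEstimates], ages: pd.Series
) -> pd.DataFrame:
    """Pearson correlation matrix among clock outputs and chronological age.

    Raises on zero-variance columns (correlation undefined) and on fewer than
    three aligned samples.
    """
    cols = {e.clock_name: e.estimates for e in estimates}
    cols["age"] = ages
    df = pd.DataFrame(cols)
    if df.isna().any().any():
        raise ClockError("sample ids are not aligned across clock estimates")
    if len(df) < 3:
        raise ClockError("need at least 3 samples for correlations")
    sd = df.std(ddof=1)
    degenerate = sd[sd == 0.0]
    if len(degenerate):
        raise ClockError(
            f"undefined correlation: zero-variance column(s) "
            f"{list(degenerate.index)}"
        )
    return df.corr(method="pearson")
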