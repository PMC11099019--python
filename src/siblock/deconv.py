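"""Reference-based salivary cell-type deconvolution.

Whole-saliva methylation is a mixture of epithelial, fibroblast and immune
cell signals.  Each sample's beta profile is regressed on reference
cell-type profiles with iteratively reweighted least squares (Huber
weighting, in the robust-partial-correlation style), negative coefficients
are truncated to zero and the result renormalized onto the simplex.  The
immune-cell fraction serves as the reference category when the fractions
later enter the regression model as covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .clocks import BetaMatrix

__all__ = ["CellReference", "DeconvError", "estimate_fractions"]

CELL_TYPES = ("epi", "fib", "ic")


class DeconvError(ValueError):
    pass


@dataclass
class CellReference:
    """CpG-by-cell-type matrix of mean beta values for pure cell populations."""

    profiles: pd.DataFrame  # index: cpg ids, columns: cell types

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise DeconvError("need at least 2 cell types")
        arr = self.profiles.to_numpy(dtype=float)
        if np.isnan(arr).any() or arr.min() < 0.0 or arr.max() > 1.0:
            raise DeconvError("reference profiles must be beta values in [0, 1]")
        if np.linalg.matrix_rank(arr) < self.profiles.shape[1]:
            raise DeconvError("reference profile columns are linearly dependent")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)

    def to_csv(self, path: str | Path) -> None:
        out = self.profiles.copy()
        out.index.name = "cpg"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CellReference":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        return cls(df)


def estimate_fractions(
    beta: BetaMatrix,
    ref: CellReference,
    huber_t: float = 1.345,
    maxiter: int = 50,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Per-sample cell-type fractions via robust regression on the reference.

    Returns a sample-by-cell-type frame of non-negative fractions summing
    to one.  Raises when fewer CpGs are shared between matrix and reference
    than there are cell types (rank-deficient system) or when every raw
    coefficient for a sample is non-positive (degenerate sample).
    """
    shared = beta.cpg_ids.intersection(ref.profiles.index)
    k = len(ref.cell_types)
    if len(shared) < k:
        raise DeconvError(
            f"only {len(shared)} CpGs shared with the reference; "
            f"need at least {k}"
        )
    X = ref.profiles.loc[shared].to_numpy(dtype=float)
    sub = beta.values.loc[shared]
    out = np.empty((len(beta.sample_ids), k))
    for s, sid in enumerate(beta.sample_ids):
        y = sub[sid].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < k:
            raise DeconvError(f"sample {sid!r}: fewer finite CpGs than cell types")
        rlm = sm.RLM(y[ok], X[ok], M=sm.robust.norms.HuberT(t=huber_t))
        with warnings.catch_warnings():
            # a noise-free mixture fits perfectly (zero scale); that is fine
            warnings.simplefilter("ignore", ConvergenceWarning)
            coefs = rlm.fit(maxiter=maxiter, tol=tol).params
        coefs = np.maximum(coefs, 0.0)
        total = coefs.sum()
        if total <= 0.0:
            raise DeconvError(f"sample {sid!r}: all cell-type coefficients are zero")
        out[s] = coefs / total
    return pd.DataFrame(out, index=beta.sample_ids, columns=ref.cell_types)


def make_toy_reference(
    n_cpgs: int = 60, cell_types=CELL_TYPES, seed: int = 0
) -> CellReference:
    """Synthetic 3-cell-type reference panel with well-separated profiles."""
    rng = np.random.default_rng(seed)
    profiles = rng.uniform(0.05, 0.95, size=(n_cpgs, len(cell_types)))
    idx = [f"dc{k:04d}" for k in range(n_cpgs)]
    return CellReference(pd.DataFrame(profiles, index=idx, columns=list(cell_types)))
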