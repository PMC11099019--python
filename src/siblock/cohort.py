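"""Synthetic sibling-pair cohort generation with known ground truth.

Emulates the structure of a drought-exposure sibling study: each mother
contributes one child exposed to drought in utero and one or more same-sex
unexposed siblings, with the exposed sibling strictly older (exposure during
a past drought forces this ordering).  Covariates (gravida, sex, birth
season, salivary cell proportions), per-mother random intercepts and a
10-dimensional outcome vector per child are drawn from a generative model
whose parameters are recorded exactly, so that estimation code can be tested
for parameter recovery.

The module also builds toy clock definitions and beta matrices by inverse
construction — distributing each clock's target score across its CpGs — so
that the scoring engine applied to a noise-free matrix returns the targeted
clock values exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clocks import BetaMatrix, ClockDefinition, ClockError
from .eaa import OUTCOME_NAMES

__all__ = [
    "CohortSpec",
    "TrueParams",
    "CohortSpecError",
    "generate_cohort",
    "generate_outcomes",
    "generate_beta_matrix",
    "generate_rainfall_series",
    "make_toy_clocks",
    "covariate_matrix",
    "COVARIATE_NAMES",
    "CLOCK_NAMES",
]

CLOCK_NAMES = (
    "PedBE",
    "Wu",
    "Horvath",
    "Hannum",
    "SkinBlood",
    "PhenoAge",
    "GrimAge2",
    "DNAmTL",
    "DunedinPACE",
    "DunedinPoAm38",
)

#: covariates entering the mixed model (immune fraction is the reference
#: category and is deliberately absent)
COVARIATE_NAMES = ("gravida", "sex_male", "season_wet", "epi_prop", "fib_prop")

N_OUTCOMES = len(OUTCOME_NAMES)


class CohortSpecError(ValueError):
    """Invalid cohort specification."""


def _default_beta1() -> np.ndarray:
    # nonzero exposure effects on the Hannum, GrimAge2 and DNAmTL outcomes
    b = np.zeros(N_OUTCOMES)
    b[OUTCOME_NAMES.index("EAA_Hannum")] = 1.34
    b[OUTCOME_NAMES.index("EAA_GrimAge2")] = 1.31
    b[OUTCOME_NAMES.index("EAA_DNAmTL")] = -0.12
    return b

# per-outcome total SDs the generator targets (EAA-scale dispersion of the
# eight clocks, kb-like for the telomere outcome, rate units for the pace
# measures); split evenly between mother-level and child-level variance
_TOTAL_SD = np.array([0.69, 1.21, 1.92, 3.35, 0.73, 0.69, 1.77, 0.28, 0.14, 0.07])
_EXCH_CORR = 0.3


def _default_cov(scale: float) -> np.ndarray:
    d = _TOTAL_SD * np.sqrt(scale)
    corr = np.full((N_OUTCOMES, N_OUTCOMES), _EXCH_CORR)
    np.fill_diagonal(corr, 1.0)
    return np.outer(d, d) * corr


@dataclass
class CohortSpec:
    """Generating parameters for a synthetic sibling-pair cohort.

    Age ranges, gravida moments, sex/season probabilities and cell-type
    means default to the descriptive statistics of the study population the
    generator emulates; the exposure effect vector defaults to nonzero
    effects on the Hannum-EAA, GrimAge2-EAA and telomere outcomes.
    """

    n_mothers: int = 100
    sibs_per_mother: int = 2
    age_range_exposed: tuple[float, float] = (7.0, 9.61)
    age_range_unexposed: tuple[float, float] = (1.81, 7.0)
    p_female: float = 0.54
    gravida_mean: float = 3.08
    gravida_sd: float = 2.21
    p_wet_season: float = 0.59
    cell_dirichlet_means: tuple[float, float, float] = (0.24, 0.02, 0.74)
    cell_concentration: float = 50.0
    beta1_true: np.ndarray = field(default_factory=_default_beta1)
    sigma_b_true: np.ndarray = field(default_factory=lambda: _default_cov(0.5))
    sigma_e_true: np.ndarray = field(default_factory=lambda: _default_cov(0.5))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mothers < 2:
            raise CohortSpecError("n_mothers must be at least 2")
        if self.sibs_per_mother < 2:
            raise CohortSpecError("each sibship needs >= 2 children")
        for lo, hi in (self.age_range_exposed, self.age_range_unexposed):
            if not (0.0 < lo < hi <= 10.0):
                raise CohortSpecError(f"age range ({lo}, {hi}) not within (0, 10]")
        for p, name in ((self.p_female, "p_female"), (self.p_wet_season, "p_wet_season")):
            if not (0.0 <= p <= 1.0):
                raise CohortSpecError(f"{name} must be a probability")
        means = np.asarray(self.cell_dirichlet_means, dtype=float)
        if means.shape != (3,) or not np.isclose(means.sum(), 1.0):
            raise CohortSpecError("cell_dirichlet_means must be a 3-vector summing to 1")
        self.beta1_true = np.asarray(self.beta1_true, dtype=float)
        if self.beta1_true.shape != (N_OUTCOMES,):
            raise CohortSpecError(f"beta1_true must have length {N_OUTCOMES}")
        for mat, name, strict in (
            (self.sigma_b_true, "sigma_b_true", False),
            (self.sigma_e_true, "sigma_e_true", True),
        ):
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (N_OUTCOMES, N_OUTCOMES) or not np.allclose(mat, mat.T):
                raise CohortSpecError(f"{name} must be symmetric {N_OUTCOMES}x{N_OUTCOMES}")
            eig = np.linalg.eigvalsh(mat)
            if eig.min() < (1e-12 if strict else -1e-10):
                kind = "positive definite" if strict else "positive semidefinite"
                raise CohortSpecError(f"{name} must be {kind}")
        self.sigma_b_true = np.asarray(self.sigma_b_true, dtype=float)
        self.sigma_e_true = np.asarray(self.sigma_e_true, dtype=float)


@dataclass
class TrueParams:
    """The generating truth, recorded exactly as used in simulation."""

    beta0: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray  # (n_covariates, n_outcomes)
    sigma_b: np.ndarray
    sigma_e: np.ndarray
    b: pd.DataFrame  # per-mother random intercepts, mothers x outcomes

    def to_json(self, path: str | Path) -> None:
        payload = {
            "outcome_names": list(OUTCOME_NAMES),
            "covariate_names": list(COVARIATE_NAMES),
            "beta0": self.beta0.tolist(),
            "beta1": self.beta1.tolist(),
            "beta2": self.beta2.tolist(),
            "sigma_b": self.sigma_b.tolist(),
            "sigma_e": self.sigma_e.tolist(),
            "b": {m: row.tolist() for m, row in self.b.iterrows()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrueParams":
        d = json.loads(Path(path).read_text())
        b = pd.DataFrame.from_dict(d["b"], orient="index", columns=d["outcome_names"])
        return cls(
            beta0=np.array(d["beta0"]),
            beta1=np.array(d["beta1"]),
            beta2=np.array(d["beta2"]),
            sigma_b=np.array(d["sigma_b"]),
            sigma_e=np.array(d["sigma_e"]),
            b=b,
        )


def covariate_matrix(sheet: pd.DataFrame) -> np.ndarray:
    """Model covariates from a sample sheet: gravida, male sex, wet-season
    birth, and the epithelial/fibroblast fractions (immune as reference)."""
    return np.column_stack(
        [
            sheet["gravida"].to_numpy(dtype=float),
            (sheet["sex"] == "M").to_numpy(dtype=float),
            (sheet["birth_season"] == "wet").to_numpy(dtype=float),
            sheet["epi_prop"].to_numpy(dtype=float),
            sheet["fib_prop"].to_numpy(dtype=float),
        ]
    )


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, TrueParams]:
    """Draw a sibling-pair sample sheet plus the generating truth.

    Every mother contributes exactly ``spec.sibs_per_mother`` children of one
    sex; exactly one child per mother is exposed, and the exposed child is
    strictly older than each unexposed sibling.  Gravida (prior pregnancies)
    is a rounded zero-truncated normal for the exposed (first simulated)
    pregnancy and increments by one per later sibling.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    n_b_j = len(str(spec.n_mothers))
    lo_u, hi_u = spec.age_range_unexposed
    for j in range(spec.n_mothers):
        mother = f"M{j + 1:0{n_b_j}d}"
        sex = "F" if rng.random() < spec.p_female else "M"
        g = -1.0
        while g < 0:
            g = rng.normal(spec.gravida_mean, spec.gravida_sd)
        gravida0 = int(round(g))
        age_exp = rng.uniform(*spec.age_range_exposed)
        hi = min(hi_u, age_exp)
        if hi <= lo_u:
            raise CohortSpecError(
                "unexposed age range incompatible with exposed sibling age"
            )
        for k in range(spec.sibs_per_mother):
            exposed = int(k == 0)
            age = age_exp if exposed else rng.uniform(lo_u, hi)
            cells = rng.dirichlet(
                spec.cell_concentration * np.asarray(spec.cell_dirichlet_means)
            )
            rows.append(
                {
                    "child_id": f"{mother}_s{k + 1}",
                    "mother_id": mother,
                    "exposed": exposed,
                    "age_years": age,
                    "sex": sex,
                    "gravida": gravida0 + k,
                    "birth_season": "wet" if rng.random() < spec.p_wet_season else "dry",
                    "epi_prop": cells[0],
                    "fib_prop": cells[1],
                }
            )
    sheet = pd.DataFrame(rows)
    b_draws = rng.multivariate_normal(
        np.zeros(N_OUTCOMES), spec.sigma_b_true, size=spec.n_mothers,
        method="cholesky" if _is_pd(spec.sigma_b_true) else "svd",
    )
    b = pd.DataFrame(
        b_draws, index=sheet["mother_id"].unique(), columns=list(OUTCOME_NAMES)
    )
    params = TrueParams(
        beta0=np.zeros(N_OUTCOMES),
        beta1=spec.beta1_true.copy(),
        beta2=np.zeros((len(COVARIATE_NAMES), N_OUTCOMES)),
        sigma_b=spec.sigma_b_true.copy(),
        sigma_e=spec.sigma_e_true.copy(),
        b=b,
    )
    return sheet, params


def _is_pd(mat: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(mat)
        return True
    except np.linalg.LinAlgError:
        return False


def generate_outcomes(
    sheet: pd.DataFrame, params: TrueParams, seed: int
) -> pd.DataFrame:
    """Draw the 10-outcome vector per child from the linear mixed model
    Y_ij = beta0 + beta1*T_ij + beta2'X_ij + b_j + eps_ij."""
    X = covariate_matrix(sheet)
    if params.beta2.shape != (X.shape[1], N_OUTCOMES):
        raise ValueError(
            f"beta2 shape {params.beta2.shape} does not match "
            f"({X.shape[1]}, {N_OUTCOMES})"
        )
    missing = set(sheet["mother_id"]) - set(params.b.index)
    if missing:
        raise ValueError(f"no random intercept for mothers {sorted(missing)[:3]}")
    rng = np.random.default_rng(seed)
    T = sheet["exposed"].to_numpy(dtype=float)[:, None]
    mean = params.beta0[None, :] + T * params.beta1[None, :] + X @ params.beta2
    mean = mean + params.b.loc[sheet["mother_id"]].to_numpy()
    if np.allclose(params.sigma_e, 0.0):
        eps = np.zeros_like(mean)
    else:
        eps = rng.multivariate_normal(
            np.zeros(N_OUTCOMES), params.sigma_e, size=len(sheet),
            method="cholesky" if _is_pd(params.sigma_e) else "svd",
        )
    out = pd.DataFrame(mean + eps, columns=list(OUTCOME_NAMES))
    out.insert(0, "mother_id", sheet["mother_id"].to_numpy())
    out.insert(0, "child_id", sheet["child_id"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# toy clocks and inverse beta-matrix construction
# ---------------------------------------------------------------------------

# transform assigned to each toy clock; age clocks track chronological age,
# the telomere clock shortens and the pace measures drift slowly with age
_TOY_TRANSFORM = {
    "PedBE": "horvath_age",
    "Wu": "identity",
    "Horvath": "horvath_age",
    "Hannum": "identity",
    "SkinBlood": "identity",
    "PhenoAge": "identity",
    "GrimAge2": "identity",
    "DNAmTL": "telomere_kb",
    "DunedinPACE": "pace",
    "DunedinPoAm38": "pace",
}


def default_targets(clock: ClockDefinition, ages: pd.Series) -> pd.Series:
    """Target clock output per sample derived from chronological age."""
    a = ages.astype(float)
    if clock.transform == "telomere_kb":
        return 7.19 - 0.016 * (a - 6.72)
    if clock.transform == "pace":
        if "PoAm" in clock.name:
            return 1.16 + 0.006 * (a - 6.72)
        return 1.32 - 0.025 * (a - 6.72)
    return a


def make_toy_clocks(
    seed: int = 0, n_cpgs: int = 50, names: Sequence[str] = CLOCK_NAMES
) -> list[ClockDefinition]:
    """Small synthetic clock definitions with disjoint CpG sets.

    Weights are drawn once per clock; intercepts are centred so that
    mid-childhood targets map to betas near 0.5, leaving headroom for the
    inverse construction across the whole age range.
    """
    rng = np.random.default_rng(seed)
    clocks = []
    for idx, name in enumerate(names):
        transform = _TOY_TRANSFORM.get(name, "identity")
        cpgs = [f"cg{idx:02d}{k:04d}" for k in range(n_cpgs)]
        w = rng.uniform(0.8, 1.2, size=n_cpgs)
        clock = ClockDefinition(
            name=name,
            intercept=0.0,
            weights=dict(zip(cpgs, w)),
            transform=transform,
            reference_medians=dict.fromkeys(cpgs, 0.5),
        )
        # centre: mid-range target should need exactly the 0.5 baseline
        mid = float(default_targets(clock, pd.Series([6.72])).iloc[0])
        clock.intercept = float(clock.invert_transform(mid)) - 0.5 * w.sum()
        clocks.append(clock)
    return clocks


def generate_beta_matrix(
    sheet: pd.DataFrame,
    clocks: Sequence[ClockDefinition],
    noise_sd: float = 0.0,
    seed: int = 0,
    targets: pd.DataFrame | None = None,
) -> BetaMatrix:
    """Construct a beta matrix whose clock scores hit given targets.

    For each clock the target output is mapped back to the linear-score
    scale and the shortfall relative to the 0.5-baseline contribution is
    spread equally across the clock's CpGs, so scoring the noise-free matrix
    reproduces the targets exactly.  ``targets`` is a clock-by-sample frame;
    when omitted, targets derive from chronological age.  Gaussian noise
    (sd in beta units) is added afterwards and values clipped to [0, 1];
    at ``noise_sd=0`` an out-of-range beta raises instead of clipping.
    """
    rng = np.random.default_rng(seed)
    ages = pd.Series(
        sheet["age_years"].to_numpy(dtype=float), index=sheet["child_id"]
    )
    blocks = []
    for clock in clocks:
        tgt = (
            targets.loc[clock.name]
            if targets is not None and clock.name in getattr(targets, "index", [])
            else default_targets(clock, ages)
        )
        tgt = pd.Series(np.asarray(tgt, dtype=float), index=ages.index)
        linear = clock.invert_transform(tgt.to_numpy()) - clock.intercept
        w = np.array([clock.weights[c] for c in clock.cpg_ids])
        deficit = linear - 0.5 * w.sum()  # per-sample shortfall
        # equal per-CpG contribution: each term w_k * beta_k moves by d/m
        betas = 0.5 + deficit[None, :] / (len(w) * w[:, None])
        if betas.min() < 0.0 or betas.max() > 1.0:
            raise ClockError(
                f"clock {clock.name!r}: targets unreachable within [0, 1] "
                f"(beta range {betas.min():.3f}..{betas.max():.3f})"
            )
        if noise_sd > 0:
            betas = np.clip(betas + rng.normal(0.0, noise_sd, betas.shape), 0.0, 1.0)
        blocks.append(pd.DataFrame(betas, index=clock.cpg_ids, columns=ages.index))
    return BetaMatrix(pd.concat(blocks))


def generate_rainfall_series(
    n_years: int,
    seasonal_means: Sequence[float],
    seed: int = 0,
    cv: float = 0.3,
) -> pd.Series:
    """Monthly rainfall totals (mm) with a fixed seasonal profile.

    Each month's total is a gamma draw with the calendar month's mean and
    coefficient of variation ``cv``; ``cv=0`` returns the means exactly.
    """
    if n_years < 2:
        raise ValueError("need at least 2 years of rainfall")
    means = np.asarray(seasonal_means, dtype=float)
    if means.shape != (12,) or (means < 0).any():
        raise ValueError("seasonal_means must be 12 non-negative monthly values")
    profile = np.tile(means, n_years)
    if cv == 0:
        values = profile
    else:
        rng = np.random.default_rng(seed)
        shape = 1.0 / cv**2
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(
                profile > 0, rng.gamma(shape, np.maximum(profile, 1e-12) / shape), 0.0
            )
    idx = pd.RangeIndex(12 * n_years, name="month_index")
    return pd.Series(values, index=idx, name="rainfall_mm")
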