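"""End-to-end orchestration: simulate -> clocks -> deconv -> eaa -> fit -> report.

Also hosts the small descriptive computations: seasonal rainfall z-scores
(anomaly of a cumulative rainfall window against the same calendar window
over a historical baseline) and the cohort descriptive table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from .clocks import BetaMatrix, estimate_clock, load_clock_directory
from .cohort import (
    CLOCK_NAMES,
    CohortSpec,
    default_targets,
    generate_beta_matrix,
    generate_cohort,
    generate_outcomes,
    make_toy_clocks,
)
from .deconv import CellReference, estimate_fractions, make_toy_reference
from .eaa import OUTCOME_NAMES, PACE_MEASURES, RESIDUALIZED, assemble_outcomes, compute_eaa, eaa_correlations
from .mlme import GibbsConfig, MLMEPriors, MultivariateMixedLM

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "rainfall_zscore",
    "descriptive_table",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    ``mode='simulate'`` generates everything from ``seed``; ``mode='files'``
    starts from user-supplied sheet / beta / clock-directory / reference
    paths, which must exist before any compute starts.
    """

    outdir: str | Path = "siblock_run"
    seed: int = 0
    mode: str = "simulate"
    n_mothers: int = 100
    noise_sd: float = 0.01
    residualize_pace: bool = False
    make_plots: bool = False
    gibbs: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    sheet_path: str | None = None
    beta_path: str | None = None
    clock_dir: str | None = None
    reference_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise PipelineError(f"unknown mode {self.mode!r}")
        if self.mode == "files":
            for name in ("sheet_path", "beta_path", "clock_dir", "reference_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise PipelineError(f"{name} missing or does not exist: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, write every intermediate artifact under
    ``config.outdir`` and return the manifest (also written as JSON).

    In simulate mode the latent outcome draws are injected into the clock
    targets, so the scored-and-residualized EAAs carry the generating
    exposure effects, cluster correlation and noise — the full analysis
    path is exercised, not just the model fit.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, **kw) -> Path:
        path = outdir / name
        df.to_csv(path, index=False, **kw)
        written.append(path)
        return path

    try:
        if config.mode == "simulate":
            spec = CohortSpec(
                n_mothers=config.n_mothers, seed=rng_seed, **config.cohort
            )
            sheet, params = generate_cohort(spec)
            latent = generate_outcomes(sheet, params, seed=rng_seed + 1)
            clocks = make_toy_clocks(seed=rng_seed)
            ages = pd.Series(
                sheet["age_years"].to_numpy(), index=sheet["child_id"]
            )
            # clock target = age trend + latent outcome, so scoring then
            # residualizing recovers the latent mixed-model structure;
            # log-scale age clocks need targets above -1 year
            target_cols = {}
            for clock, out in zip(clocks, OUTCOME_NAMES):
                t = default_targets(clock, ages).to_numpy() + latent[out].to_numpy()
                if clock.transform == "horvath_age":
                    t = np.maximum(t, 0.05)
                target_cols[clock.name] = t
            targets = pd.DataFrame(target_cols, index=ages.index).T
            beta = generate_beta_matrix(
                sheet, clocks, noise_sd=config.noise_sd, seed=rng_seed + 2,
                targets=targets,
            )
            ref = make_toy_reference(seed=rng_seed)
            mix = np.column_stack(
                [
                    sheet["epi_prop"],
                    sheet["fib_prop"],
                    1.0 - sheet["epi_prop"] - sheet["fib_prop"],
                ]
            )
            deconv_rng = np.random.default_rng(rng_seed + 3)
            deconv_vals = np.clip(
                ref.profiles.to_numpy() @ mix.T
                + deconv_rng.normal(0.0, config.noise_sd, (len(ref.profiles), len(sheet))),
                0.0,
                1.0,
            )
            deconv_beta = BetaMatrix(
                pd.DataFrame(
                    deconv_vals, index=ref.profiles.index, columns=sheet["child_id"]
                )
            )
            beta = BetaMatrix(pd.concat([beta.values, deconv_beta.values]))
            clock_dir = outdir / "clocks"
            for c in clocks:
                c.to_files(clock_dir)
            written.extend(sorted(clock_dir.iterdir()))
            emit(sheet, "sample_sheet.csv")
            beta_path = outdir / "beta.tsv"
            beta.to_tsv(beta_path)
            written.append(beta_path)
            ref_path = outdir / "cell_reference.csv"
            ref.to_csv(ref_path)
            written.append(ref_path)
            params_path = outdir / "true_params.json"
            params.to_json(params_path)
            written.append(params_path)
        else:
            sheet = pd.read_csv(config.sheet_path)
            beta = BetaMatrix.from_tsv(config.beta_path)
            clocks = load_clock_directory(config.clock_dir)
            ref = CellReference.from_csv(config.reference_path)
            ages = pd.Series(
                sheet["age_years"].to_numpy(), index=sheet["child_id"]
            )

        # clocks stage
        estimates = {c.name: estimate_clock(beta, c) for c in clocks}
        est_df = pd.DataFrame({n: e.estimates for n, e in estimates.items()})
        est_out = est_df.copy()
        est_out.insert(0, "child_id", est_out.index)
        emit(est_out, "clock_estimates.csv")

        # deconvolution stage: estimated fractions replace sheet fractions
        fractions = estimate_fractions(beta, ref)
        frac_out = fractions.rename(
            columns={"epi": "epi_prop", "fib": "fib_prop", "ic": "ic_prop"}
        )
        frac_out.insert(0, "sample_id", frac_out.index)
        emit(frac_out, "cell_fractions.csv")
        sheet_fit = sheet.copy()
        sheet_fit["epi_prop"] = fractions.loc[sheet["child_id"], "epi"].to_numpy()
        sheet_fit["fib_prop"] = fractions.loc[sheet["child_id"], "fib"].to_numpy()

        # eaa stage
        resid_cols = {}
        for name, out_name in zip(CLOCK_NAMES[:8], RESIDUALIZED):
            resid_cols[out_name] = compute_eaa(estimates[name].estimates, ages)
        pace_cols = {}
        for name, out_name in zip(CLOCK_NAMES[8:], PACE_MEASURES):
            col = estimates[name].estimates
            pace_cols[out_name] = compute_eaa(col, ages) if config.residualize_pace else col
        child_to_mother = pd.Series(
            sheet["mother_id"].to_numpy(), index=sheet["child_id"]
        )
        outcomes = assemble_outcomes(resid_cols, pace_cols, child_to_mother)
        emit(outcomes, "eaa_table.csv")
        corr = eaa_correlations(outcomes, ages)
        corr_out = corr.copy()
        corr_out.insert(0, "variable", corr_out.index)
        emit(corr_out, "outcome_correlations.csv")

        # fit stage
        gibbs = GibbsConfig(seed=rng_seed + 4, **config.gibbs)
        model = MultivariateMixedLM.from_dataframes(outcomes, sheet_fit)
        res = model.fit(priors=MLMEPriors(), config=gibbs)
        emit(res.exposure_summary, "exposure_summary.csv")
        emit(res.summary_frame(), "coefficient_summary.csv")
        emit(res.diagnostics(), "diagnostics.csv")
        if config.make_plots:
            plot_path = outdir / "trace_exposure.png"
            res.trace_plot(plot_path)

        # report stage
        desc = descriptive_table(sheet_fit)
        emit(desc, "descriptive_table.csv")
        cfg_path = outdir / "config.json"
        cfg_dict = dataclasses.asdict(config)
        cfg_dict["outdir"] = str(cfg_dict["outdir"])
        cfg_dict["gibbs_resolved"] = dataclasses.asdict(gibbs)
        cfg_dict["outcome_order"] = list(OUTCOME_NAMES)
        cfg_path.write_text(json.dumps(cfg_dict, indent=2))
        written.append(cfg_path)
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001 - annotate with stage context
        raise PipelineError(f"pipeline failed: {err}") from err

    manifest = {
        "seed": rng_seed,
        "outcome_order": list(OUTCOME_NAMES),
        "files": {
            str(p.relative_to(outdir)): {"sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in written
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def rainfall_zscore(
    monthly_series: pd.Series,
    window_end: int,
    window_len: int = 3,
    history_years: int = 40,
) -> float:
    """Z-score of a cumulative rainfall window against the historical mean.

    The target window is the ``window_len`` months ending at ``window_end``
    (inclusive, 0-based index into the monthly series).  The baseline is
    the same calendar window in each of the ``history_years`` preceding
    years; the z-score is (window total - baseline mean) / baseline SD,
    with the sample SD over the historical windows.
    """
    x = np.asarray(monthly_series, dtype=float)
    start = window_end - window_len + 1
    if start < 0 or window_end >= x.size:
        raise ValueError("target window outside the series")
    history = []
    for back in range(1, history_years + 1):
        s, e = start - 12 * back, window_end - 12 * back
        if s < 0:
            raise ValueError(
                f"series too short: {history_years} historical windows needed, "
                f"only {back - 1} available"
            )
        history.append(x[s : e + 1].sum())
    hist = np.asarray(history)
    sd = hist.std(ddof=1)
    if sd == 0.0:
        raise ValueError("historical window totals have zero variance; z undefined")
    return float((x[start : window_end + 1].sum() - hist.mean()) / sd)


def _count_row(label: str, n: int, total: int) -> dict:
    return {"variable": label, "value": f"{n}/{total} ({n / total:.0%})"}


def _mean_sd_row(label: str, values: pd.Series) -> dict:
    return {
        "variable": label,
        "value": f"{values.mean():.2f} ({values.std(ddof=1):.2f})",
    }


def descriptive_table(sheet: pd.DataFrame) -> pd.DataFrame:
    """Cohort descriptives: counts (whole-percent) for exposure, sex and
    birth season; mean (SD) for gravida and cell proportions."""
    if sheet.empty:
        raise ValueError("empty sample sheet")
    n = len(sheet)
    rows = [
        _count_row("Drought exposed", int((sheet["exposed"] == 1).sum()), n),
        _count_row("Unexposed", int((sheet["exposed"] == 0).sum()), n),
        _count_row("Female", int((sheet["sex"] == "F").sum()), n),
        _count_row("Male", int((sheet["sex"] == "M").sum()), n),
        _mean_sd_row("Gravida", sheet["gravida"].astype(float)),
        _count_row("Wet-season birth", int((sheet["birth_season"] == "wet").sum()), n),
        _count_row("Dry-season birth", int((sheet["birth_season"] == "dry").sum()), n),
        _mean_sd_row("Epithelial cell proportion", sheet["epi_prop"]),
        _mean_sd_row("Fibroblast cell proportion", sheet["fib_prop"]),
    ]
    return pd.DataFrame(rows)
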