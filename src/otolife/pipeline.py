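"""End-to-end orchestration of the life-history analysis.

``run_pipeline`` executes the stages in order — input assembly (synthetic
generation when no CSVs are supplied), reader-precision statistics,
bomb-radiocarbon age validation, DIC depth regression, and the Bayesian
growth/mortality fit — writing per-stage CSVs, a consolidated JSON report
and a free-form log. The report is a pure function of the configuration and
master seed; versions and runtimes go to the log only, so identical
config + seed reproduce a byte-identical report.

Stages with missing inputs are skipped with a logged notice; a stage failure
is logged, partial outputs are kept, and the error propagates as
``PipelineError``.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dic import fit_depth_regression, slope_per_100m
from .growth import GridSpec, GrowthParams, hewitt_hoenig_m, mortality_summary
from .io import (
    read_core_samples,
    read_dic_profile,
    read_fish_records,
    read_reference_series,
    write_dic_profile,
    write_fish_records,
    write_reference_series,
)
from .loess import fit_loess
from .mcmc import McmcConfig, PriorSpec, convergence_diagnostics, default_priors, run_mcmc
from .precision import precision_summary
from .radiocarbon import check_birth_years, residual_test, ssr_bias_profiles
from .synthetic import (
    BombCurveConfig,
    DicProfileConfig,
    ReaderErrorModel,
    generate_dic_profile,
    generate_double_reads,
    generate_population_sample,
    generate_reference_series,
)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Inputs, method settings and output location for a full run."""

    outdir: str = "otolife_out"
    seed: int = 1

    # input CSVs; None means "generate synthetically" (fish/reference/dic).
    # Core samples have no synthetic fallback here: they are either measured
    # data or constructed explicitly by the caller.
    fish_csv: str | None = None
    reference_csv: str | None = None
    cores_csv: str | None = None
    dic_csv: str | None = None

    # synthetic generation settings
    synthetic: bool = True
    n_fish: int = 1338
    true_params: GrowthParams = field(
        default_factory=lambda: GrowthParams(
            linf=1533.0, k=0.14, t0=1.82, cv_len=0.17,
            l50=812.0, sel_steepness=78.8, m_nat=0.066, f_mort=0.34,
        )
    )
    bomb_config: BombCurveConfig | None = None
    dic_config: DicProfileConfig | None = None
    reader_error: ReaderErrorModel | None = None

    # method settings
    loess_degree: int = 2
    loess_span: float = 0.20
    dic_window: tuple = (200.0, 600.0)
    priors: PriorSpec = field(default_factory=default_priors)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    run_growth: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        simple = {
            "outdir", "seed", "fish_csv", "reference_csv", "cores_csv", "dic_csv",
            "synthetic", "n_fish", "loess_degree", "loess_span", "run_growth",
        }
        for key in simple & raw.keys():
            kwargs[key] = raw[key]
        if "dic_window" in raw:
            kwargs["dic_window"] = tuple(raw["dic_window"])
        if "true_params" in raw:
            kwargs["true_params"] = GrowthParams(**raw["true_params"])
        if "priors" in raw:
            kwargs["priors"] = PriorSpec(
                medians=raw["priors"]["medians"], log_sds=raw["priors"]["log_sds"]
            )
        if "mcmc" in raw:
            kwargs["mcmc"] = McmcConfig(**raw["mcmc"])
        if "bomb_config" in raw:
            kwargs["bomb_config"] = BombCurveConfig(**raw["bomb_config"])
        if "dic_config" in raw:
            kwargs["dic_config"] = DicProfileConfig(**raw["dic_config"])
        return cls(**kwargs)


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _assemble_inputs(config: PipelineConfig, out: Path, notes: list):
    """Load observed CSVs or generate synthetic stand-ins; returns a dict."""
    data: dict = {"fish": None, "reference": None, "cores": None, "dic": None}
    if config.fish_csv:
        data["fish"] = read_fish_records(config.fish_csv)
    elif config.synthetic:
        fish = generate_population_sample(
            config.true_params, config.n_fish, seed=config.seed, spec=config.grid
        )
        rem = config.reader_error or ReaderErrorModel(seed=config.seed + 1)
        reads = generate_double_reads(fish["age_years"].to_numpy(), rem)
        fish["read1"] = reads[:, 0]
        fish["read2"] = reads[:, 1]
        # downstream ages are the first reader's opaque-zone counts
        fish["age_years"] = reads[:, 0]
        write_fish_records(fish, out / "fish_records.csv")
        data["fish"] = fish
    else:
        notes.append("no fish records: precision and growth stages will be skipped")

    if config.reference_csv:
        data["reference"] = read_reference_series(config.reference_csv)
    elif config.synthetic:
        bc = config.bomb_config or BombCurveConfig(seed=config.seed + 2)
        data["reference"] = generate_reference_series(bc)
        write_reference_series(data["reference"], out / "reference_series.csv")

    if config.cores_csv:
        data["cores"] = read_core_samples(config.cores_csv)
    else:
        notes.append("no otolith-core samples: radiocarbon stage will be skipped")

    if config.dic_csv:
        data["dic"] = read_dic_profile(config.dic_csv)
    elif config.synthetic:
        dc = config.dic_config or DicProfileConfig(seed=config.seed + 3)
        data["dic"] = generate_dic_profile(dc)
        write_dic_profile(data["dic"], out / "dic_profile.csv")
    return data


def _stage_precision(fish, out: Path):
    if fish is None or not {"read1", "read2"} <= set(fish.columns):
        return None
    summary = precision_summary(fish[["read1", "read2"]].to_numpy(float))
    pd.DataFrame([summary]).to_csv(out / "precision_summary.csv", index=False)
    return summary


def _stage_radiocarbon(reference, cores, config: PipelineConfig, out: Path):
    if reference is None or cores is None:
        return None
    samples, printed = cores
    fit = fit_loess(reference, degree=config.loess_degree, span=config.loess_span)
    printed_clean = [
        s.birth_year if (isinstance(p, float) and np.isnan(p)) else int(p)
        for s, p in zip(samples, printed)
    ]
    years = pd.DataFrame(check_birth_years(samples, printed_clean))
    years.to_csv(out / "birth_years.csv", index=False)
    rep = residual_test(fit, samples)
    profiles = ssr_bias_profiles(fit, samples)
    ssr_rows = [
        {"mode": mode, "shift": k, "ssr": v}
        for mode, prof in profiles.items()
        for k, v in sorted(prof.ssr.items())
    ]
    pd.DataFrame(ssr_rows).to_csv(out / "ssr_profile.csv", index=False)
    return {
        "n_comparable": rep.n_comparable,
        "excluded_ids": rep.excluded_ids,
        "inconsistent_rows": years.loc[~years["consistent"], "sample_id"].tolist(),
        "shapiro_p": rep.shapiro_p,
        "levene_p": rep.levene_p,
        "mean_zero_p": rep.mean_zero_p,
        "consistent": bool(rep.consistent),
        "ssr": {m: p.ssr for m, p in profiles.items()},
        "min_shift": {m: p.min_shift for m, p in profiles.items()},
    }


def _stage_dic(dic, config: PipelineConfig, out: Path):
    if dic is None:
        return None
    rep = fit_depth_regression(dic, window=config.dic_window)
    row = {
        "slope_permil_per_m": rep.slope,
        "slope_permil_per_100m": slope_per_100m(rep.slope),
        "intercept": rep.intercept,
        "r_squared": rep.r_squared,
        "p_value": rep.p_value,
        "n": rep.n,
    }
    pd.DataFrame([row]).to_csv(out / "dic_regression.csv", index=False)
    return row


def _stage_growth(fish, config: PipelineConfig, out: Path):
    if fish is None or not config.run_growth:
        return None
    obs = fish[["age_years", "tl_mm"]].to_numpy(float)
    cfg = McmcConfig(
        n_chains=config.mcmc.n_chains,
        burn_in=config.mcmc.burn_in,
        n_samples=config.mcmc.n_samples,
        thin=config.mcmc.thin,
        initial_scale=config.mcmc.initial_scale,
        seed=config.seed + 10,
    )
    result = run_mcmc(obs, config.priors, cfg, spec=config.grid)
    result.summary_table().to_csv(out / "posterior_summary.csv", index=False)
    # thinned draws file (log scale), capped at ~5,000 rows per chain
    step = max(1, result.draws.shape[1] // 5000)
    thin = result.draws[:, ::step, :]
    rows = pd.DataFrame(
        thin.reshape(-1, thin.shape[-1]), columns=list(result.param_names)
    )
    rows.insert(0, "chain", np.repeat(np.arange(thin.shape[0]), thin.shape[1]))
    rows.to_csv(out / "posterior_draws_log.csv", index=False)
    diag = (
        convergence_diagnostics(result)
        if cfg.n_chains >= 2 and result.draws.shape[1] >= 100
        else None
    )
    post = result.posterior_mean()
    t_max = int(fish["age_years"].max())
    ms = mortality_summary(post["f_mort"], post["m_nat"])
    return {
        "posterior_mean": post,
        "posterior_log_sd": result.posterior_log_sd(),
        "acceptance_mean": float(result.acceptance.mean()),
        "diagnostics_pass": (None if diag is None else bool(diag.passed)),
        "psrf": (None if diag is None else diag.psrf),
        "geweke_z": (None if diag is None else diag.geweke),
        "t_max_observed": t_max,
        "hewitt_hoenig_m": hewitt_hoenig_m(t_max),
        "z_total": ms.z,
        "f_over_m": ms.f_over_m,
        "f_over_m_reported": ms.f_over_m_reported,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the consolidated report dict.

    Writes <outdir>/report.json, <outdir>/run.log and per-stage CSVs.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    notes: list[str] = [f"master seed {config.seed}"]
    report: dict = {"seed": config.seed, "stages": {}}
    runtimes: dict = {}

    def run_stage(name, fn, *args):
        t0 = time.perf_counter()
        try:
            res = fn(*args)
        except Exception as exc:
            notes.append(f"stage {name}: FAILED: {exc}")
            _write_log(out, notes, runtimes)
            raise PipelineError(f"stage {name} failed: {exc}") from exc
        runtimes[name] = time.perf_counter() - t0
        if res is None and name != "inputs":
            notes.append(f"stage {name}: skipped")
        else:
            notes.append(f"stage {name}: ok")
        return res

    data = run_stage("inputs", _assemble_inputs, config, out, notes)

    for name, fn, args in [
        ("precision", _stage_precision, (data["fish"], out)),
        ("radiocarbon", _stage_radiocarbon, (data["reference"], data["cores"], config, out)),
        ("dic", _stage_dic, (data["dic"], config, out)),
        ("growth", _stage_growth, (data["fish"], config, out)),
    ]:
        res = run_stage(name, fn, *args)
        if res is not None:
            report["stages"][name] = _round_floats(res)

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    _write_log(out, notes, runtimes)
    return report


def _write_log(out: Path, notes: list, runtimes: dict) -> None:
    header = [
        f"otolife {__version__} | python {sys.version.split()[0]} | numpy {np.__version__}",
        f"runtimes_s: {json.dumps({k: round(v, 2) for k, v in runtimes.items()})}",
    ]
    (out / "run.log").write_text("\n".join(header + notes) + "\n")
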