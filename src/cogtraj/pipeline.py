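"""End-to-end study replica: demographics → trajectory fits → divergences → regressions.

``run_all`` executes, on one cohort (read from CSV or freshly simulated):

* the demographics and genotype summary tables;
* five Bayesian trajectory comparisons — mutation carriers vs
  non-carriers, then e4+ vs e4− and e2+ vs e2− within each PSEN1 stratum —
  each followed by the 99% credible-band divergence age;
* four genotype × education OLS regressions (e4 and e2, each stratum).

Every analysis writes its own CSV (and difference-curve plot); a single
machine-readable ``summary.json`` collects divergence ages and regression
coefficients, and ``MANIFEST.json`` records per-stage completion. A stage
whose comparison group is absent (e.g. no e2+ carriers) is skipped with a
logged reason; any other stage failure aborts the run naming the stage.
All randomness derives from one seed, so a rerun with the same
configuration reproduces the summary byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import bayes, regression
from .bayes import MCMC_PRESETS, McmcConfig, PosteriorDraws, fit_group_trajectories
from .cohort import Cohort, apoe_group_counts, demographics_table, genotype_table, read_cohort
from .divergence import DivergenceResult, compute_divergence
from .simulate import GeneratorParams, generate_cohort, write_truth

logger = logging.getLogger("cogtraj")

#: (name, group, stratum, direction) for the five trajectory comparisons.
TRAJECTORY_ANALYSES = (
    ("carriers_vs_noncarriers", "psen1", "all", "lower"),
    ("e4_carriers", "e4", "carriers", "lower"),
    ("e4_noncarriers", "e4", "noncarriers", "lower"),
    ("e2_carriers", "e2", "carriers", "upper"),
    ("e2_noncarriers", "e2", "noncarriers", "upper"),
)

REGRESSION_ANALYSES = (
    ("e4_carriers", "carriers", "e4"),
    ("e4_noncarriers", "noncarriers", "e4"),
    ("e2_carriers", "carriers", "e2"),
    ("e2_noncarriers", "noncarriers", "e2"),
)

#: Types of the summary.json leaves, checked by validate_report.
REPORT_SCHEMA = {
    "seed": int,
    "preset": str,
    "n_participants": int,
    "divergence": {
        name: {
            "divergence_age": (float, type(None)),
            "direction": str,
            "level": float,
            "skipped": bool,
            "reason": (str, type(None)),
        }
        for name, *_ in TRAJECTORY_ANALYSES
    },
    "regression": {
        name: {
            "skipped": bool,
            "reason": (str, type(None)),
            "coefficients": (dict, type(None)),
            "n": (int, type(None)),
        }
        for name, *_ in REGRESSION_ANALYSES
    },
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    outdir: str | Path = "cogtraj_run"
    cohort_path: str | Path | None = None
    generator_params: GeneratorParams | None = None
    preset: str = "desk"
    mcmc: McmcConfig | None = None  # overrides preset when given
    n_knots: int = 5
    level: float = 0.99
    grid_step: float = 0.1
    seed: int = 0
    make_plots: bool = True
    save_fits: bool = False

    def mcmc_config(self, seed: int) -> McmcConfig:
        base = self.mcmc if self.mcmc is not None else MCMC_PRESETS[self.preset]
        return McmcConfig(
            chains=base.chains,
            iterations=base.iterations,
            thin=base.thin,
            warmup=base.warmup,
            n_leapfrog=base.n_leapfrog,
            target_accept=base.target_accept,
            seed=seed,
        )


def validate_report(report: dict, schema: dict = REPORT_SCHEMA) -> None:
    """Recursively check the summary against the published schema."""
    for key, expected in schema.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        value = report[key]
        if isinstance(expected, dict):
            if not isinstance(value, dict):
                raise ValueError(f"report[{key!r}] should be a mapping")
            validate_report(value, expected)
        elif not isinstance(value, expected):
            raise ValueError(
                f"report[{key!r}] has type {type(value).__name__}, expected {expected}"
            )


def _setup_logging(outdir: Path) -> None:
    # one file handler per run directory; drop handlers from earlier runs
    for handler in [h for h in logger.handlers if isinstance(h, logging.FileHandler)]:
        handler.close()
        logger.removeHandler(handler)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)


def _plot_divergence(result: DivergenceResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(result.ages, result.lower, result.upper, alpha=0.3, color="tab:red")
    ax.plot(result.ages, result.median, color="tab:red")
    ax.axhline(0.0, color="black", lw=0.8)
    if result.divergence_age is not None:
        ax.axvline(result.divergence_age, color="gray", ls="--", lw=0.8)
        ax.set_title(
            f"{result.label_a} − {result.label_b}: diverges at {result.divergence_age:.1f} y"
        )
    else:
        ax.set_title(f"{result.label_a} − {result.label_b}: no divergence")
    ax.set_xlabel("Age (years)")
    ax.set_ylabel("Difference in MMSE")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _load_or_generate(config: RunConfig, outdir: Path) -> Cohort:
    if config.cohort_path is not None:
        return read_cohort(config.cohort_path)
    params = config.generator_params or GeneratorParams(seed=config.seed)
    cohort, truth = generate_cohort(params)
    from .cohort import write_cohort

    write_cohort(cohort, outdir / "cohort.csv")
    write_truth(truth, outdir / "truth.csv")
    return cohort


def run_all(config: RunConfig) -> dict:
    """Run the full analysis battery; returns the summary report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    manifest: dict[str, str] = {}
    report: dict = {
        "seed": int(config.seed),
        "preset": config.preset if config.mcmc is None else "custom",
        "divergence": {},
        "regression": {},
    }

    def finish_stage(stage: str, status: str) -> None:
        manifest[stage] = status
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2) + "\n")

    def run_stage(stage: str, fn):
        logger.info("stage %s: start", stage)
        try:
            result = fn()
        except (ValueError, KeyError) as exc:
            finish_stage(stage, f"failed: {exc}")
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        finish_stage(stage, "done")
        return result

    cohort = run_stage("load_cohort", lambda: _load_or_generate(config, outdir))
    report["n_participants"] = len(cohort)
    df = cohort.to_frame()

    def demographics() -> None:
        genotype_table(cohort).to_csv(outdir / "genotype_table.csv")
        apoe_group_counts(cohort).to_csv(outdir / "apoe_group_counts.csv")
        for stratum in ("carriers", "noncarriers"):
            for allele in ("e4", "e2"):
                try:
                    table = demographics_table(cohort, allele=allele, stratum=stratum)
                except ValueError as exc:
                    logger.warning("demographics %s/%s skipped: %s", allele, stratum, exc)
                    continue
                table.to_frame().to_csv(outdir / f"demographics_{allele}_{stratum}.csv")

    run_stage("demographics", demographics)

    seed_root = np.random.SeedSequence(config.seed)
    fit_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in seed_root.spawn(len(TRAJECTORY_ANALYSES))]

    for (name, group, stratum, direction), fit_seed in zip(TRAJECTORY_ANALYSES, fit_seeds):
        stage = f"trajectory_{name}"
        entry = {
            "divergence_age": None,
            "direction": direction,
            "level": float(config.level),
            "skipped": False,
            "reason": None,
        }

        def fit_and_diverge() -> DivergenceResult | None:
            # pre-check group presence: an absent group is a documented skip
            _, mask_a, mask_b, (la, lb) = bayes._group_masks(cohort, group, stratum)
            k = config.n_knots
            for label, m in ((la, mask_a), (lb, mask_b)):
                if int(m.sum()) < k + 2:
                    entry["skipped"] = True
                    entry["reason"] = (
                        f"group {label!r} has {int(m.sum())} participants; need ≥ {k + 2}"
                    )
                    logger.warning("%s skipped: %s", stage, entry["reason"])
                    return None
            fit = fit_group_trajectories(
                cohort,
                group=group,
                stratum=stratum,
                n_knots=config.n_knots,
                config=config.mcmc_config(fit_seed),
            )
            if config.save_fits:
                bayes.save_fit(fit, outdir / f"fit_{name}.npz")
            result = compute_divergence(
                fit, level=config.level, grid_step=config.grid_step, direction=direction
            )
            result.to_frame().to_csv(outdir / f"divergence_{name}.csv", index=False)
            if config.make_plots:
                _plot_divergence(result, outdir / f"divergence_{name}.png")
            entry["divergence_age"] = (
                None if result.divergence_age is None else float(result.divergence_age)
            )
            return result

        run_stage(stage, fit_and_diverge)
        report["divergence"][name] = entry

    for name, stratum, allele in REGRESSION_ANALYSES:
        stage = f"regression_{name}"
        entry = {"skipped": False, "reason": None, "coefficients": None, "n": None}

        def regress() -> None:
            sub = df[df["psen1_carrier"]] if stratum == "carriers" else df[~df["psen1_carrier"]]
            flag = sub[f"{allele}_positive"]
            if len(sub) == 0 or flag.nunique() < 2:
                entry["skipped"] = True
                entry["reason"] = f"stratum {stratum!r} lacks both {allele} genotype groups"
                logger.warning("%s skipped: %s", stage, entry["reason"])
                return
            fit = regression.education_model(cohort, stratum=stratum, allele=allele)
            fit.to_frame().to_csv(outdir / f"regression_{name}.csv", index=False)
            entry["coefficients"] = {
                n: {"estimate": float(e), "se": float(s), "p": float(p)}
                for n, e, s, p in zip(fit.names, fit.estimates, fit.std_errors, fit.p_values)
            }
            entry["n"] = fit.n

        run_stage(stage, regress)
        report["regression"][name] = entry

    validate_report(report)
    (outdir / "summary.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    finish_stage("summary", "done")
    logger.info("run complete: %s", outdir / "summary.json")
    return report
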