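"""End-to-end orchestration: simulate -> derive -> screen -> elicit -> fit ->
diagnose -> report.

A run is fully described by a YAML config plus a root seed; every stage
derives its own seed from the root, writes its intermediates to the output
directory, and rerunning the same config+seed reproduces every numeric
output exactly.  Any stage failure aborts the run with the stage name and a
machine-readable error record (``error.json`` in the output directory).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import model_sequence
from .model import MultilevelLogit
from .priors import PriorSpec, combine_priors, fit_historical_wave
from .screening import prevalence_table, screen_wave
from .simulate import DEFAULT_BETA, SimConfig, generate_wave, read_wave, write_wave
from .terms import TERMS, coefficient_names
from .variables import derive

__all__ = ["RunConfig", "ModelReport", "PipelineError", "run_pipeline",
           "render_tables", "demo_config_path"]


def demo_config_path() -> Path:
    """Path of the packaged scaled-down demonstration config."""
    return Path(__file__).parent / "data" / "demo.yaml"

log = logging.getLogger(__name__)

_DEFAULT_MCMC = {"n_chains": 3, "n_burnin": 1000, "n_kept": 3000}
_DEFAULT_HIST_MCMC = {"n_chains": 2, "n_burnin": 400, "n_kept": 1200}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying error."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {error}")
        self.stage = stage
        self.error = error

    def record(self) -> dict:
        return {"stage": self.stage, "error_type": type(self.error).__name__,
                "message": str(self.error)}


@dataclass
class RunConfig:
    """Validated run configuration (see the packaged demo YAML)."""

    seed: int = 0
    out: str = "runs/out"
    simulate: dict | None = None
    waves: list[str] | None = None
    model: dict = field(default_factory=dict)
    screening: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    historical_mcmc: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    save_draws: bool = False

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.waves is None):
            raise ValueError("config must give exactly one of 'simulate' or 'waves'")
        if self.waves is not None:
            missing = [p for p in self.waves if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"wave file(s) not found: {missing}")
            if len(self.waves) < 3:
                raise ValueError("need at least three waves "
                                 "(two historical for elicitation + current)")
        terms = self.model.get("terms", ["intention"])
        unknown = [t for t in terms if t not in TERMS]
        if unknown:
            raise ValueError(f"unknown model terms: {unknown}")
        if "intention" not in terms:
            raise ValueError("the exposure 'intention' must be a model term")
        outcomes = self.model.get("outcomes", ["y_any", "y_four"])
        bad = [o for o in outcomes if o not in ("y_any", "y_four")]
        if bad:
            raise ValueError(f"unknown outcomes: {bad}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out", None)          # output location does not affect results
        return json.dumps(d, sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


@dataclass
class ModelReport:
    """The final, rendered-table-shaped result of a run."""

    rows: pd.DataFrame                     # outcome/term/category/OR rows
    icc: dict                              # outcome -> final-model latent ICC
    information: dict                      # outcome -> {aic, bic}
    convergence: dict                      # outcome -> {max_rc, converged}
    selected: list[str]
    prevalence: pd.DataFrame
    comparison: pd.DataFrame | None
    provenance: dict

    def to_json(self) -> str:
        payload = {
            "rows": self.rows.to_dict(orient="records"),
            "icc": self.icc,
            "information": self.information,
            "convergence": self.convergence,
            "selected": self.selected,
            "prevalence": self.prevalence.to_dict(orient="records"),
            "comparison": None if self.comparison is None
            else self.comparison.to_dict(orient="records"),
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=1, sort_keys=True, default=str)


def _stage_seed(root_seed: int, stage: int) -> int:
    return int((root_seed * 1_000_003 + 97 * stage + 13) % (2 ** 31 - 1))


def _sim_configs(cfg: RunConfig) -> list[SimConfig]:
    sim = dict(cfg.simulate or {})
    years = sim.pop("years", [2004, 2007, 2011, 2014])
    drift = sim.pop("drift", {})
    base_beta = sim.pop("beta", dict(DEFAULT_BETA))
    configs = []
    for i, year in enumerate(years):
        beta = dict(base_beta)
        beta.update(drift.get(year, drift.get(str(year), {})))
        configs.append(SimConfig(year_label=int(year), beta=beta,
                                 seed=_stage_seed(cfg.seed, 100 + i), **sim))
    return configs


def run_pipeline(cfg: RunConfig, out_dir=None) -> ModelReport:
    """Execute every stage in order; returns the report and writes artifacts."""
    out = Path(out_dir if out_dir is not None else cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ---- simulate / load -------------------------------------------
        stage = "simulate"
        if cfg.simulate is not None:
            waves = [generate_wave(c) for c in _sim_configs(cfg)]
            for w in waves:
                write_wave(w, out / "waves")
        else:
            waves = [read_wave(p) for p in cfg.waves]
        waves.sort(key=lambda w: w.year_label)
        years = [w.year_label for w in waves]
        log.info("stage simulate: %d waves (%s)", len(waves), years)

        # ---- derive ----------------------------------------------------
        stage = "derive"
        derived, audits = {}, {}
        (out / "derived").mkdir(exist_ok=True)
        for w in waves:
            d, audit = derive(w.women)
            derived[w.year_label] = d
            audits[w.year_label] = audit
            d.to_csv(out / "derived" / f"derived_{w.year_label}.csv", index=False)
            (out / "derived" / f"audit_{w.year_label}.json").write_text(
                json.dumps(audit, indent=1, sort_keys=True))
            log.info("stage derive %s: %d -> %d rows (%s)", w.year_label,
                     audit["n_input"], audit["n_analysis"], audit["exclusions"])

        current_year = years[-1]
        current = derived[current_year]
        terms = list(cfg.model.get("terms", ["intention"]))
        outcomes = list(cfg.model.get("outcomes", ["y_any", "y_four"]))

        # ---- screen ----------------------------------------------------
        stage = "screen"
        (out / "screening").mkdir(exist_ok=True)
        threshold = float(cfg.screening.get("threshold", 0.20))
        candidates = [t for t in terms]
        screen_table, selected = screen_wave(current, candidates,
                                             outcomes=tuple(outcomes),
                                             threshold=threshold)
        prev_tables = [prevalence_table(current, "intention")]
        for oc in outcomes:
            prev_tables.append(prevalence_table(current, oc))
        prevalence = pd.concat(prev_tables, ignore_index=True)
        prevalence.to_csv(out / "screening" / "table1.csv", index=False)
        screen_table.to_csv(out / "screening" / "table2.csv", index=False)
        (out / "screening" / "selection.json").write_text(json.dumps(
            {"threshold": threshold, "selected": selected, "seed": cfg.seed},
            indent=1))
        final_terms = [t for t in terms if t in selected]
        log.info("stage screen: %d/%d variables retained at p<=%.2f",
                 len(final_terms), len(candidates), threshold)

        # ---- elicit ----------------------------------------------------
        stage = "elicit"
        (out / "priors").mkdir(exist_ok=True)
        hist_settings = {**_DEFAULT_HIST_MCMC, **cfg.historical_mcmc}
        priors: dict[str, PriorSpec] = {}
        target = coefficient_names(final_terms)
        for oi, outcome in enumerate(outcomes):
            posts = []
            for hi, year in enumerate(years[:-1]):
                posts.append(fit_historical_wave(
                    derived[year], outcome, final_terms,
                    seed=_stage_seed(cfg.seed, 200 + 10 * oi + hi),
                    **hist_settings))
            priors[outcome] = combine_priors(posts, source_waves=years[:-1],
                                             target_coefficients=target)
            (out / "priors" / f"prior_{outcome}.json").write_text(
                priors[outcome].to_json())
        log.info("stage elicit: informative priors from waves %s", years[:-1])

        # ---- fit -------------------------------------------------------
        stage = "fit"
        (out / "fits").mkdir(exist_ok=True)
        mcmc = {**_DEFAULT_MCMC, **cfg.mcmc}
        fits, icc, information, convergence = {}, {}, {}, {}
        rhat_all = {"seed": cfg.seed}
        for oi, outcome in enumerate(outcomes):
            model = MultilevelLogit.from_dataframe(current, outcome, final_terms)
            ml = model.fit()
            bayes = model.fit_bayes(priors[outcome], ml_results=ml,
                                    seed=_stage_seed(cfg.seed, 300 + oi), **mcmc)
            fits[outcome] = bayes
            icc[outcome] = bayes.icc
            information[outcome] = {"aic": ml.aic, "bic": ml.bic}
            rc_by_param = bayes.gelman_rubin()
            rhat_all[outcome] = rc_by_param
            rc = max(rc_by_param.values())
            convergence[outcome] = {"max_rc": rc, "converged": bool(rc < 1.1)}
            summary = bayes.summary().reset_index()
            payload = {"summary": summary.to_dict(orient="records"),
                       "icc": icc[outcome], "sigma_u2": bayes.sigma_u2_mean,
                       "aic": ml.aic, "bic": ml.bic,
                       "convergence": convergence[outcome],
                       "seed": bayes.seed}
            (out / "fits" / f"posterior_{outcome}.json").write_text(
                json.dumps(payload, indent=1, sort_keys=True))
            if cfg.save_draws:
                flat = bayes.chains.reshape(-1, len(bayes.param_names))
                pd.DataFrame(flat, columns=bayes.param_names).to_csv(
                    out / "fits" / f"draws_{outcome}.csv", index=False)
            log.info("stage fit %s: max Rc %.3f, ICC %.4f", outcome, rc,
                     icc[outcome])
        (out / "fits" / "rhat.json").write_text(
            json.dumps(rhat_all, indent=1, sort_keys=True))

        # ---- diagnose --------------------------------------------------
        stage = "diagnose"
        comparison = None
        diag = cfg.diagnostics
        if diag.get("run", True):
            comparison = model_sequence(
                current, prior=priors[outcomes[0]], outcomes=tuple(outcomes),
                run_mcmc=bool(diag.get("run_mcmc", False)),
                mcmc_settings=diag.get("mcmc"),
                seed=_stage_seed(cfg.seed, 400))
            comparison.to_csv(out / "comparison.csv", index=False)
            log.info("stage diagnose: preferred %s", comparison.attrs["preferred"])

        # ---- report ----------------------------------------------------
        stage = "report"
        rows = _report_rows(fits, final_terms, outcomes)
        report = ModelReport(
            rows=rows, icc=icc, information=information, convergence=convergence,
            selected=final_terms, prevalence=prevalence, comparison=comparison,
            provenance={"seed": cfg.seed, "config_hash": cfg.config_hash,
                        "ancbayes_version": __version__,
                        "numpy_version": np.__version__,
                        "years": years, "audits": audits})
        (out / "report.json").write_text(report.to_json())
        render_tables(report, out)
        log.info("stage report: written to %s", out)
        return report
    except PipelineError:
        raise
    except Exception as exc:
        err = PipelineError(stage, exc)
        try:
            (out / "error.json").write_text(json.dumps(err.record(), indent=1))
        except OSError:
            pass
        raise err from exc


def _report_rows(fits, final_terms, outcomes) -> pd.DataFrame:
    """Assemble odds-ratio table rows with one '(ref)' row per categorical term."""
    rows = []
    summaries = {oc: fits[oc].odds_ratios() for oc in outcomes}
    for term in final_terms:
        levels = TERMS[term]
        if levels is None:
            for oc in outcomes:
                s = summaries[oc].loc[term]
                rows.append({"outcome": oc, "term": term, "category": "",
                             "reference": False, "or": s["or"],
                             "or_lower": s["or_lower"], "or_upper": s["or_upper"]})
            continue
        for oc in outcomes:
            rows.append({"outcome": oc, "term": term, "category": levels[0],
                         "reference": True, "or": np.nan,
                         "or_lower": np.nan, "or_upper": np.nan})
            for lev in levels[1:]:
                s = summaries[oc].loc[f"{term}[{lev}]"]
                rows.append({"outcome": oc, "term": term, "category": lev,
                             "reference": False, "or": s["or"],
                             "or_lower": s["or_lower"], "or_upper": s["or_upper"]})
    for oc in outcomes:
        s = summaries[oc].loc["Intercept"]
        rows.append({"outcome": oc, "term": "Constant", "category": "",
                     "reference": False, "or": s["or"],
                     "or_lower": s["or_lower"], "or_upper": s["or_upper"]})
    return pd.DataFrame(rows)


def render_tables(report: ModelReport, out_dir) -> dict[str, Path]:
    """Render the report as CSV and markdown tables.

    Odds ratios are rounded to 2 decimals and intervals shown as
    "lower–upper"; reference rows carry "(ref)" and no interval; prevalences
    are shown to 1 decimal.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = report.rows.copy()

    def fmt(row, col_or="or"):
        if row["reference"]:
            return "(ref)"
        return f"{row[col_or]:.2f} ({row['or_lower']:.2f}–{row['or_upper']:.2f})"

    rendered = rows.copy()
    rendered["aOR (95% Cred. I)"] = rows.apply(fmt, axis=1)
    table3 = rendered.pivot_table(index=["term", "category"],
                                  columns="outcome",
                                  values="aOR (95% Cred. I)",
                                  aggfunc="first", sort=False)
    paths = {}
    paths["table3_csv"] = out / "table3.csv"
    table3.to_csv(paths["table3_csv"])
    md_lines = ["| Term | Category | " + " | ".join(table3.columns) + " |",
                "|---|---|" + "---|" * len(table3.columns)]
    for (term, cat), row in table3.iterrows():
        md_lines.append(f"| {term} | {cat} | " +
                        " | ".join(str(v) for v in row.values) + " |")
    for oc, val in report.icc.items():
        md_lines.append(f"| ICC ({oc}) |  | {val:.4g} |")
    paths["table3_md"] = out / "table3.md"
    paths["table3_md"].write_text("\n".join(md_lines) + "\n")

    prev = report.prevalence.copy()
    for col in ("prevalence_pct", "ci_lower", "ci_upper"):
        prev[col] = prev[col].map(lambda v: f"{v:.1f}")
    paths["table1_csv"] = out / "table1_rendered.csv"
    prev.to_csv(paths["table1_csv"], index=False)
    return paths
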