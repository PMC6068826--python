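"""End-to-end pipeline: synthetic cohort -> gait statistics -> design range.

Ties the modules together behind one configuration object and emits the
machine artifacts (CSV/JSON) and a human-readable report.  Every number
in the report is traceable to an operation output; all randomness flows
from the single configured seed, so two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__, reference
from .cohort import (
    CohortConfig,
    generate_cohort,
    generate_trials,
    trials_to_frame,
    write_cohort_csv,
)
from .design import combine_subranges, parameter_table
from .gait import ReferencePolicy, select_reference_parameters, summarize
from .growth import default_growth_models, project_design_range
from .stability import ModelParams, StaircaseSpec, UpperRule, audit_staircase, study_sites

__all__ = [
    "PipelineConfig",
    "AuditReport",
    "ConfigError",
    "validate_config",
    "run_pipeline",
    "render_table5",
]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid pipeline configuration; carries the full error list."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in self.errors))


class PipelineConfig(BaseModel):
    """Configuration of a full analysis run.

    Defaults reproduce the study conditions: the three experiment-site
    staircases, all three scenarios, alpha = 0.05, flight lengths 7-12,
    a 30-year service life and the table-precision reference policy.
    """

    model_config = dict(frozen=True)

    cohort: CohortConfig = Field(default_factory=CohortConfig)
    staircases: tuple[StaircaseSpec, ...] = Field(
        default_factory=lambda: tuple(study_sites().values())
    )
    scenarios: tuple[str, ...] = ("alone", "paired", "evacuation")
    alpha: float = Field(default=reference.ALPHA, gt=0, lt=1)
    n_range: tuple[int, int] = reference.STEP_RANGE
    service_life: float = Field(default=30.0, ge=0)
    policy: str = "table5"
    upper_rule: UpperRule = "tread"
    seed: int = 0

    def cross_validate(self) -> list[str]:
        """Cross-field checks beyond per-field validation (not fail-fast)."""
        errors = []
        if not self.staircases:
            errors.append("staircases: at least one staircase is required")
        if not self.scenarios:
            errors.append("scenarios: at least one scenario is required")
        lo, hi = self.n_range
        if lo > hi:
            errors.append(f"n_range: empty range ({lo}, {hi})")
        if lo < 2:
            errors.append(f"n_range: flight lengths must be >= 2, got {lo}")
        for s in self.staircases:
            if hi > s.n_steps:
                errors.append(
                    f"n_range: upper end {hi} exceeds {s.name!r}'s {s.n_steps} steps"
                )
        try:
            ReferencePolicy.parse(self.policy)
        except ValueError as exc:
            errors.append(f"policy: {exc}")
        return errors


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and cross-validate a YAML/JSON config file.

    Collects every violation (pydantic's field errors plus cross-field
    checks) into one :class:`ConfigError` rather than failing fast.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    try:
        payload = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError([f"unreadable config: {exc}"])
    try:
        config = PipelineConfig(**payload)
    except ValidationError as exc:
        raise ConfigError([
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ])
    errors = config.cross_validate()
    if errors:
        raise ConfigError(errors)
    return config


@dataclass(frozen=True)
class AuditReport:
    """Everything one run computes, JSON-serialisable and round-trippable."""

    schema_version: int
    package_version: str
    seed: int
    config_sha256: str
    config: dict
    gait_summaries: list
    reference_parameters: dict
    parameter_table: dict
    design_range: dict
    projection: dict
    recommendation: dict
    staircase_audits: list
    warnings: list

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "AuditReport":
        return cls(**json.loads(text))


def _config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _assign_sites(cohort: pd.DataFrame, staircases) -> dict[str, pd.DataFrame]:
    """Contiguous subject blocks per site, as in the study (1-24/25-48/49-72)."""
    blocks = {}
    n = len(cohort)
    k = len(staircases)
    size = n // k
    for i, st in enumerate(staircases):
        stop = (i + 1) * size if i < k - 1 else n
        blocks[st.name] = cohort.iloc[i * size:stop]
    return blocks


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> AuditReport:
    """Run the full analysis and optionally write its artifacts.

    Stages: generate the cohort, simulate descent trials per site and
    scenario, summarise gait, select the reference parameters, estimate
    intervals, combine the design range, project it over the service
    life, and audit each staircase at the reference parameters.
    """
    if not config.staircases or not config.scenarios:
        raise ConfigError(config.cross_validate() or ["empty staircases/scenarios"])
    policy = ReferencePolicy.parse(config.policy)
    cohort_cfg = config.cohort.model_copy(update={"seed": config.seed})
    caught: list[str] = []

    cohort = generate_cohort(cohort_cfg)
    if cohort.empty:
        raise ConfigError(["generated cohort is empty"])
    depths = {s.name: s.step_depth for s in config.staircases}
    trials = []
    for site_name, block in _assign_sites(cohort, config.staircases).items():
        spec = next(s for s in config.staircases if s.name == site_name)
        for scenario in config.scenarios:
            trials.extend(generate_trials(block, spec, scenario, cohort_cfg))

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        by_scenario_site = summarize(trials, depths, by=("scenario", "site"))
        by_scenario = summarize(trials, depths, by=("scenario",))
        refs = select_reference_parameters(by_scenario, policy)

        # anthropometric estimates from the cohort itself (per-subject, n = cohort size)
        samples = {}
        for name, col in (("eta", "eta_m"), ("l", "l_m"), ("L", "foot_length_m")):
            mean, sd = float(cohort[col].mean()), float(cohort[col].std(ddof=1))
            mean, sd = policy.round(name, mean, sd)
            samples[name] = (mean, sd, len(cohort))
        for name in ("v", "pfc"):
            samples[name] = (refs[name].mean, refs[name].sd, refs[name].n)

        table = parameter_table(samples, alpha=config.alpha, n_range=config.n_range)
        current = combine_subranges(table, upper_rule=config.upper_rule)
        projection = project_design_range(
            table, horizon=config.service_life, upper_rule=config.upper_rule
        )

        ref_params = ModelParams(
            v=table["v"].mean, l=table["l"].mean, L=table["L"].mean,
            eta=table["eta"].mean, pfc=table["pfc"].mean,
        )
        audits = [
            audit_staircase(s, ref_params,
                            n_range=range(config.n_range[0],
                                          min(config.n_range[1], s.n_steps) + 1))
            for s in config.staircases
        ]
    caught.extend(str(w.message) for w in wlist)
    for est in table.values():
        caught.extend(est.notes)

    report = AuditReport(
        schema_version=SCHEMA_VERSION,
        package_version=__version__,
        seed=config.seed,
        config_sha256=_config_hash(config),
        config=config.model_dump(mode="json"),
        gait_summaries=by_scenario_site.to_dict("records"),
        reference_parameters={k: asdict(v) for k, v in refs.items()},
        parameter_table={k: asdict(v) for k, v in table.items()},
        design_range=current.to_dict(),
        projection=projection.to_dict(),
        recommendation=asdict(projection.recommended),
        staircase_audits=[asdict(a) for a in audits],
        warnings=caught,
    )

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(cohort, out / "cohort.csv")
        trials_to_frame(trials).to_csv(out / "trials.csv", index=False)
        by_scenario_site.to_csv(out / "summaries.csv", index=False)
        (out / "report.json").write_text(report.to_json() + "\n")
        (out / "design_range.json").write_text(
            json.dumps(current.to_dict(), sort_keys=True, indent=2) + "\n"
        )
        t5_frame, t5_text = render_table5(report)
        t5_frame.to_csv(out / "table5.csv", index=False)
        (out / "table5.txt").write_text(t5_text + "\n")
        (out / "report.txt").write_text(render_text_report(report) + "\n")
    return report


def render_table5(report: AuditReport) -> tuple[pd.DataFrame, str]:
    """Design-range table artifact with published-vs-computed columns.

    One row per swept parameter: sample mean +/- SD, the computed
    interval, the published interval, the computed per-parameter
    subranges of both depth bounds, the published ones, and the
    differences (display-rounded to 3 decimals; full precision lives in
    the JSON report).
    """
    if not report.parameter_table or not report.design_range:
        raise ValueError("report lacks a parameter table or design range")
    table = report.parameter_table
    sub = report.design_range["subranges"]
    rows = []
    for name in ("pfc", "eta", "v", "l", "N"):
        est = table[name]
        pub = reference.PUBLISHED_SUBRANGES[name]
        if name == "N":
            mean_sd = f"{est['fixed_range'][0]} to {est['fixed_range'][1]}"
            ci = tuple(est["fixed_range"])
        else:
            mean_sd = f"{est['mean']:.3g} +/- {est['sd']:.2g}"
            ci = (est["ci_low"], est["ci_high"])
        row = dict(
            parameter=name,
            sample=mean_sd,
            ci_low=round(ci[0], 3), ci_high=round(ci[1], 3),
            published_ci_low=pub["ci"][0], published_ci_high=pub["ci"][1],
            ci_discrepancy=round(max(abs(ci[0] - pub["ci"][0]),
                                     abs(ci[1] - pub["ci"][1])), 3),
        )
        for side in ("lower", "upper"):
            mn, mx = sub[name][side]
            row[f"{side}_min"] = round(mn, 3)
            row[f"{side}_max"] = round(mx, 3)
            row[f"published_{side}_min"] = pub[side][0]
            row[f"published_{side}_max"] = pub[side][1]
        rows.append(row)
    df = pd.DataFrame(rows)

    d_low, d_high = report.design_range["d_low"], report.design_range["d_high"]
    pub_lo, pub_hi = reference.PUBLISHED_DESIGN_RANGE
    lines = ["Parameter floating ranges and the step-depth design range", ""]
    lines.append(df.to_string(index=False))
    lines.append("")
    lines.append(
        f"combined design range: [{d_low:.3f}, {d_high:.3f}] m "
        f"(published [{pub_lo:.3f}, {pub_hi:.3f}]; "
        f"residuals {d_low - pub_lo:+.3f} / {d_high - pub_hi:+.3f})"
    )
    return df, "\n".join(lines)


def render_text_report(report: AuditReport) -> str:
    """Short human-readable run summary (stdout-style)."""
    rec = report.recommendation
    dr = report.design_range
    proj = report.projection
    lines = [
        f"stairsafe v{report.package_version} run (seed {report.seed}, "
        f"config {report.config_sha256[:12]})",
        "",
        "Gait summaries (per scenario/site):",
    ]
    for row in report.gait_summaries:
        lines.append(
            f"  {row['scenario']:>10} @ {row['site']:<10} n={row['n']:>3}  "
            f"v = {row['mean_speed']:.3f} +/- {row['sd_speed']:.3f} m/s  "
            f"PFC = {row['mean_pfc']:.3f} m  AFC = {row['mean_afc']:.3f} m"
        )
    lines.append("")
    lines.append(
        f"Design range today: [{dr['d_low']:.3f}, {dr['d_high']:.3f}] m "
        f"(rule: {dr['provenance']['upper_rule']})"
    )
    horizon = proj["horizon"]
    last = proj["ranges"][str(horizon)] if str(horizon) in proj["ranges"] else None
    if last:
        lines.append(
            f"Projected at +{horizon:.0f} y: [{last['d_low']:.3f}, {last['d_high']:.3f}] m"
        )
    lines.append(
        f"Recommended step depth: [{rec['low']:.3f}, {rec['high']:.3f}] m "
        f"(prefer the larger value)"
    )
    lines.append("")
    for audit in report.staircase_audits:
        verdict = "SAFE" if audit["safe"] else "UNSAFE"
        lines.append(
            f"  {audit['staircase']['name']:<10} d = "
            f"{audit['staircase']['step_depth']:.3f} m -> {verdict} "
            f"(window [{audit['d_low']:.3f}, {audit['d_high']:.3f}] m)"
        )
    if report.warnings:
        lines.append("")
        lines.append("Notes and flagged discrepancies:")
        for w in dict.fromkeys(report.warnings):
            lines.append(f"  - {w}")
    return "\n".join(lines)
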