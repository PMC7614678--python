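"""Structured run configuration: loading, validation, dispatch, reports.

A run configuration names exactly one scenario source (a built-in label, a
CSV of summaries, or inline summaries), the Gamma-mixture prior settings,
one criterion block and one variance block.  ``run`` executes
prior synthesis -> sample-size solver -> optional Monte-Carlo check and
writes a JSON report (full precision) plus an optional CSV row; the report
echoes every input so a run can be reproduced from its own output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .evaluation import get_scenario, simulate_average_properties
from .posterior import DesignSpec, VariancePrior
from .priors import CommensuratePriorSpec, HistoricalSummary, collective_prior
from .sample_size import (
    CriterionSpec,
    acc_known,
    alc_known,
    alc_unknown,
    acc_unknown,
    apvc_known,
    apvc_unknown,
    variance_prior_from_collective,
)

__all__ = ["RunConfig", "load_config", "run", "load_summaries_csv"]

logger = logging.getLogger("cpssd")

_PRIOR_DEFAULTS = {"a01": 2.0, "b01": 2.0, "a02": 18.0, "b02": 3.0, "s0": 0.05}


def load_summaries_csv(path: str | Path) -> list[HistoricalSummary]:
    """Read summaries from CSV with columns label, mean, variance, w."""
    df = pd.read_csv(path)
    required = {"mean", "variance", "w"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summaries CSV missing columns: {sorted(missing)}")
    return [
        HistoricalSummary(
            mean=float(r["mean"]),
            variance=float(r["variance"]),
            weight=float(r["w"]),
            label=str(r.get("label", i)),
        )
        for i, r in df.iterrows()
    ]


@dataclass
class RunConfig:
    """Validated configuration for one sample-size run."""

    sources: list[HistoricalSummary]
    prior_spec: CommensuratePriorSpec
    criterion: CriterionSpec
    variance_mode: str  # "known" | "unknown"
    sigma0_sq: float | None = None
    c: float | None = None
    allocation_ratio: float = 1.0
    scenario_label: str | None = None
    evaluate_reps: int | None = None
    seed: int = 20220328
    output_json: str | None = None
    output_csv: str | None = None
    raw: dict = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a JSON/YAML run configuration file."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping")
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> RunConfig:
    scenario_keys = [k for k in ("scenario", "summaries_csv", "summaries") if k in doc]
    if len(scenario_keys) != 1:
        raise ValueError(
            "exactly one of 'scenario', 'summaries_csv' or 'summaries' is required; "
            f"got {scenario_keys or 'none'}"
        )
    src_key = scenario_keys[0]
    scenario_label = None
    prior_doc = dict(_PRIOR_DEFAULTS)
    prior_doc.update(doc.get("prior", {}))
    unknown_prior = set(prior_doc) - set(_PRIOR_DEFAULTS)
    if unknown_prior:
        raise ValueError(f"unknown prior fields: {sorted(unknown_prior)}")
    spec = CommensuratePriorSpec(**{k: float(v) for k, v in prior_doc.items()})

    if src_key == "scenario":
        scenario_label = str(doc["scenario"])
        sc = get_scenario(scenario_label)
        sources = list(sc.sources)
        if "prior" not in doc:
            spec = sc.spec
    elif src_key == "summaries_csv":
        sources = load_summaries_csv(doc["summaries_csv"])
    else:
        sources = [
            HistoricalSummary(
                mean=float(s["mean"]),
                variance=float(s["variance"]),
                weight=float(s["w"]),
                label=str(s.get("label", i)),
            )
            for i, s in enumerate(doc["summaries"])
        ]

    crit_doc = doc.get("criterion")
    if not isinstance(crit_doc, dict) or "name" not in crit_doc:
        raise ValueError("a 'criterion' block with a 'name' field is required")
    name = str(crit_doc["name"]).lower()
    criterion = CriterionSpec(
        name,
        hpd_length=(float(crit_doc["length"]) if "length" in crit_doc else None),
        coverage=(float(crit_doc["coverage"]) if "coverage" in crit_doc else None),
        variance_target=(
            float(crit_doc["variance_target"]) if "variance_target" in crit_doc else None
        ),
    )

    var_doc = doc.get("variance")
    if not isinstance(var_doc, dict) or "mode" not in var_doc:
        raise ValueError("a 'variance' block with a 'mode' field is required")
    mode = str(var_doc["mode"])
    sigma0_sq = var_doc.get("sigma0_sq")
    c = var_doc.get("c")
    if mode == "known":
        if sigma0_sq is None:
            raise ValueError("known variance requires 'sigma0_sq'")
        if c is not None:
            raise ValueError("known variance must not set 'c'")
        sigma0_sq = float(sigma0_sq)
    elif mode == "unknown":
        if c is None:
            raise ValueError("unknown variance requires 'c'")
        if sigma0_sq is not None:
            raise ValueError("unknown variance must not set 'sigma0_sq'")
        c = float(c)
    else:
        raise ValueError(f"variance mode must be 'known' or 'unknown', got {mode!r}")

    return RunConfig(
        sources=sources,
        prior_spec=spec,
        criterion=criterion,
        variance_mode=mode,
        sigma0_sq=sigma0_sq,
        c=c,
        allocation_ratio=float(doc.get("allocation_ratio", 1.0)),
        scenario_label=scenario_label,
        evaluate_reps=(int(doc["evaluate_reps"]) if "evaluate_reps" in doc else None),
        seed=int(doc.get("seed", 20220328)),
        output_json=doc.get("output_json"),
        output_csv=doc.get("output_csv"),
        raw=doc,
    )


def run(config: RunConfig) -> dict:
    """Execute prior synthesis, the solver and the optional MC check.

    Returns the report as a dict and writes it to the configured JSON/CSV
    paths.  The report echoes all inputs (audit trail) and, in unknown
    mode, the prior expectation of sigma0^2 when it exists.
    """
    prior = collective_prior(config.sources, config.prior_spec)
    logger.info(
        "collective prior: mean=%.6f variance=%.6f p=%s",
        prior.mean, prior.variance, [round(c[0], 4) for c in prior.components],
    )
    crit = config.criterion
    if config.variance_mode == "known":
        vp = VariancePrior.known(config.sigma0_sq)
        fn = {"acc": acc_known, "alc": alc_known, "apvc": apvc_known}[crit.criterion]
        result = fn(prior, crit, config.sigma0_sq, config.allocation_ratio)
    else:
        vp = variance_prior_from_collective(prior, config.c)
        fn = {"acc": acc_unknown, "alc": alc_unknown, "apvc": apvc_unknown}[
            crit.criterion
        ]
        result = fn(prior, crit, vp, config.allocation_ratio)
        if config.c > 2:
            logger.info("E[sigma0^2] = %.6f", vp.mean_sigma0_sq)
    logger.info(
        "%s solution: continuous total %.4f, integer total %d%s",
        crit.criterion.upper(), result.continuous_total, result.integer_total,
        " (prior alone suffices)" if result.binding else "",
    )

    report = {
        "inputs": {
            "scenario": config.scenario_label,
            "summaries": [
                {"label": s.label, "mean": s.mean, "variance": s.variance, "w": s.weight}
                for s in config.sources
            ],
            "prior": {
                "a01": config.prior_spec.a01, "b01": config.prior_spec.b01,
                "a02": config.prior_spec.a02, "b02": config.prior_spec.b02,
                "s0": config.prior_spec.s0,
            },
            "criterion": {
                "name": crit.criterion,
                "length": crit.hpd_length,
                "coverage": crit.coverage,
                "variance_target": crit.variance_target,
            },
            "variance": {
                "mode": config.variance_mode,
                "sigma0_sq": config.sigma0_sq,
                "c": config.c,
            },
            "allocation_ratio": config.allocation_ratio,
            "seed": config.seed,
        },
        "collective_prior": prior.to_dict(),
        "result": result.to_dict(),
    }

    if config.evaluate_reps:
        total = result.integer_total
        if total >= 2:
            design = DesignSpec(*result.integer_per_group)
            mc = simulate_average_properties(
                prior, design, vp, crit, reps=config.evaluate_reps, seed=config.seed
            )
            report["mc_check"] = mc.to_dict()

    if config.output_json:
        Path(config.output_json).write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    if config.output_csv:
        flat = {
            "criterion": crit.criterion,
            "variance_mode": config.variance_mode,
            "prior_mean": prior.mean,
            "prior_variance": prior.variance,
            "continuous_total": result.continuous_total,
            "integer_total": result.integer_total,
            "binding": result.binding,
        }
        pd.DataFrame([flat]).to_csv(config.output_csv, index=False)
    return report
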