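"""Per-domain analysis pipeline: curation, summary, model fit, verdict.

``run_pipeline`` takes a config (dict, or YAML via the CLI) naming one or
more domains, each with an input systems CSV, an ordered list of curation
steps, a predicted parity for conservative tie-breaking, and a model
choice.  Every curation filter logs records in and out, so the pipeline
leaves the same audit trail a careful survey curation narrative would.
Errors in one domain are captured in that domain's report; other domains
still run.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    ParityDataset,
    ParityFit,
    SamplerConfig,
    classify_preference,
    fit_parity_glm,
    fit_parity_model,
    prob_even,
)
from .survey import (
    ParitySummary,
    SystemRecord,
    dedupe_by_glottocode,
    largest_per_language,
    parity_summary,
    read_system_records,
)

__all__ = ["DomainReport", "run_pipeline", "reports_to_json", "reports_to_tsv"]

logger = logging.getLogger("catsym")

CURATION_STEPS = (
    "dedupe_by_glottocode",
    "largest_per_language",
    "drop_missing_glottocode",
)


@dataclass
class DomainReport:
    """Everything the analysis produced for one domain."""

    domain: str
    n_systems: int
    summary: Optional[ParitySummary]
    curation_log: list[dict]
    verdict: Optional[str] = None
    prob_even_mean: Optional[float] = None
    ci95: Optional[tuple[float, float]] = None
    rhat: Optional[dict[str, float]] = None
    converged: Optional[bool] = None
    glm_estimate: Optional[float] = None
    glm_ci95: Optional[tuple[float, float]] = None
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.error is None and (self.converged is not False)

    def to_dict(self) -> dict:
        return {
            "domain": self.domain,
            "n_systems": self.n_systems,
            "summary": self.summary.to_dict() if self.summary else None,
            "curation_log": self.curation_log,
            "verdict": self.verdict,
            "prob_even_mean": self.prob_even_mean,
            "ci95": list(self.ci95) if self.ci95 else None,
            "rhat": self.rhat,
            "converged": self.converged,
            "glm_estimate": self.glm_estimate,
            "glm_ci95": list(self.glm_ci95) if self.glm_ci95 else None,
            "error": self.error,
        }


def _apply_curation(
    records: list[SystemRecord],
    steps: Sequence[str],
    predicted_parity: str,
    log: list[dict],
) -> list[SystemRecord]:
    for step in steps:
        n_in = len(records)
        if step == "dedupe_by_glottocode":
            records = dedupe_by_glottocode(records, predicted_parity)
        elif step == "largest_per_language":
            records = largest_per_language(records)
        elif step == "drop_missing_glottocode":
            records = [r for r in records if r.glottocode]
        else:
            raise ValueError(
                f"unknown curation step {step!r}; expected one of "
                f"{CURATION_STEPS}"
            )
        log.append({"step": step, "n_in": n_in, "n_out": len(records)})
        logger.info(
            "%s: %d records in, %d out", step, n_in, len(records)
        )
    return records


def _analyse_domain(spec: dict, sampler: SamplerConfig) -> DomainReport:
    domain = spec["name"]
    log: list[dict] = []
    if "records" in spec:
        records = list(spec["records"])
    else:
        records = read_system_records(spec["path"])
    log.append({"step": "read", "n_in": len(records), "n_out": len(records)})
    if not records:
        raise ValueError(f"domain {domain!r}: no input records")
    predicted = spec.get("predicted_parity", "none")
    records = _apply_curation(
        records, spec.get("curation", ()), predicted, log
    )
    if not records:
        raise ValueError(f"domain {domain!r}: curation removed every record")
    summary = parity_summary(records)
    report = DomainReport(
        domain=domain,
        n_systems=len(records),
        summary=summary,
        curation_log=log,
    )
    model = spec.get("model", "bayes")
    if model == "none":
        return report
    data = ParityDataset.from_records(records)
    if data.n < len(records):
        log.append(
            {
                "step": "drop_missing_glottocode_for_regression",
                "n_in": len(records),
                "n_out": data.n,
            }
        )
    if model == "glm":
        glm = fit_parity_glm(data)
        report.glm_estimate = glm.estimate
        report.glm_ci95 = glm.ci95
        if not glm.separated:
            report.verdict = classify_preference(glm.ci95)
        else:
            report.verdict = (
                "even_preferring" if glm.estimate >= 0.5 else "odd_preferring"
            )
        return report
    fit = fit_parity_model(data, config=sampler)
    mean, ci = prob_even(fit)
    report.prob_even_mean = mean
    report.ci95 = ci
    report.rhat = fit.rhat
    report.converged = fit.converged
    report.verdict = classify_preference(ci)
    return report


def run_pipeline(config: dict) -> list[DomainReport]:
    """Run every domain in the config; one report per domain.

    Config keys: ``seed`` (master seed), ``sampler`` (chains/iterations/
    warmup overrides), ``domains`` — a list of dicts with ``name``,
    ``path`` (systems CSV) or ``records``, optional ``predicted_parity``,
    ``curation`` (ordered step names), and ``model`` (``bayes`` |
    ``glm`` | ``none``).
    """
    sampler_kwargs = dict(config.get("sampler", {}))
    sampler_kwargs.setdefault("seed", config.get("seed", 0))
    sampler = SamplerConfig(**sampler_kwargs)
    reports = []
    for spec in config["domains"]:
        try:
            reports.append(_analyse_domain(spec, sampler))
        except Exception as exc:  # noqa: BLE001 - reported per domain
            logger.error("domain %s failed: %s", spec.get("name"), exc)
            reports.append(
                DomainReport(
                    domain=spec.get("name", "?"),
                    n_systems=0,
                    summary=None,
                    curation_log=[],
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    return reports


def reports_to_json(reports: Sequence[DomainReport]) -> str:
    return json.dumps(
        [r.to_dict() for r in reports], indent=2, sort_keys=True
    )


def reports_to_tsv(reports: Sequence[DomainReport]) -> str:
    """Verdict table, one row per domain."""
    lines = ["domain\tn\tprob_even\tci_low\tci_high\tverdict\terror"]
    for r in reports:
        mean = f"{r.prob_even_mean:.3f}" if r.prob_even_mean is not None else (
            f"{r.glm_estimate:.3f}" if r.glm_estimate is not None else ""
        )
        ci = r.ci95 or r.glm_ci95
        lo = f"{ci[0]:.3f}" if ci else ""
        hi = f"{ci[1]:.3f}" if ci else ""
        lines.append(
            f"{r.domain}\t{r.n_systems}\t{mean}\t{lo}\t{hi}\t"
            f"{r.verdict or ''}\t{r.error or ''}"
        )
    return "\n".join(lines) + "\n"
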