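"""Report assembly and the end-to-end pipeline runner.

A :class:`ReportBundle` collects everything a downstream database needs:
run metadata, the dataset summary, the preparation record, the applied
(post-degradation) model, and the framework result, with the genotype
effect p-value surfaced at the fixed top-level key ``genotype_pvalue``
regardless of framework.  Serialization is deterministic: fixed key
order, round-trippable floats, and non-finite numbers encoded as null
next to a sibling ``<key>_nonfinite`` flag.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .fisher import ContingencyResult, analyze_categorical
from .lmm import FitError, LMMResult, analyze_continuous
from .phen_data import (FISHER, LMM, RRPLUS, ModelSpec, PhenDataset,
                        ValidationError, default_spec, load_table, prepare,
                        summarize_dataset)
from .rrplus import RRResult, analyze_rr

log = logging.getLogger("phenoscreen")

SCHEMA_VERSION = "1.0"

#: required top-level keys, in serialization order
REPORT_SCHEMA = {
    "schema_version": str,
    "metadata": dict,
    "status": str,
    "status_reasons": list,
    "genotype_pvalue": (float, int, type(None)),
    "input_summary": (dict, type(None)),
    "preparation": (dict, type(None)),
    "model": (dict, type(None)),
    "result": (dict, type(None)),
}

STATUSES = ("OK", "Degraded", "NotTestable", "Failed")


def validate_report(doc: Mapping[str, Any]) -> None:
    """Structural check of a parsed report against the packaged schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in doc:
            raise ValidationError(f"report missing key {key!r}")
        if not isinstance(doc[key], typ):
            raise ValidationError(f"report key {key!r} has wrong type")
    if doc["status"] not in STATUSES:
        raise ValidationError(f"unknown status {doc['status']!r}")
    if doc["status"] == "Failed" and doc["result"] is not None:
        raise ValidationError("Failed report must not carry a result")


@dataclass
class ReportBundle:
    metadata: dict[str, Any]
    status: str
    status_reasons: list[str] = field(default_factory=list)
    genotype_pvalue: float | None = None
    input_summary: dict[str, Any] | None = None
    preparation: dict[str, Any] | None = None
    model: dict[str, Any] | None = None
    result: dict[str, Any] | None = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "metadata": self.metadata,
            "status": self.status,
            "status_reasons": list(self.status_reasons),
            "genotype_pvalue": self.genotype_pvalue,
            "input_summary": self.input_summary,
            "preparation": self.preparation,
            "model": self.model,
            "result": self.result,
        }


def _spec_dict(spec: ModelSpec) -> dict[str, Any]:
    return {
        "framework": spec.framework,
        "response": spec.response,
        "fixed_terms": list(spec.fixed_terms),
        "random_groups": list(spec.random_groups),
        "reference_genotype": spec.reference_genotype,
        "rr_quantile": spec.rr_quantile,
        "optimize": spec.optimize,
        "mc_draws": spec.mc_draws,
        "seed": spec.seed,
    }


def _metadata(source: str, seed: int | None,
              timestamp: bool = True) -> dict[str, Any]:
    md: dict[str, Any] = {"tool_version": __version__, "seed": seed}
    md["timestamp"] = (datetime.now(timezone.utc).isoformat()
                       if timestamp else None)
    try:
        md["input_digest"] = hashlib.sha256(
            Path(source).read_bytes()).hexdigest()
    except OSError:
        md["input_digest"] = None
    return md


def build_report(ds: PhenDataset, spec: ModelSpec,
                 result: LMMResult | ContingencyResult | RRResult,
                 timestamp: bool = True) -> ReportBundle:
    """Assemble the bundle for a completed analysis."""
    expected = {LMM: LMMResult, FISHER: ContingencyResult, RRPLUS: RRResult}
    if not isinstance(result, expected[spec.framework]):
        raise ValidationError(
            f"framework {spec.framework} cannot carry a "
            f"{type(result).__name__}")
    reasons = list(ds.prep.degradations)
    status = "OK"
    genotype_p = result.genotype_p
    if isinstance(result, LMMResult) and not result.final.converged:
        status = "Degraded"
        reasons.append("final model did not converge")
    if isinstance(result, RRResult):
        for label, entry in result.strata.items():
            if entry.get("degenerate"):
                reasons.append(f"stratum {label}: {entry['degenerate']}")
    if isinstance(result, ContingencyResult):
        for label, entry in result.strata.items():
            if entry.get("not_testable"):
                reasons.append(f"stratum {label}: {entry['not_testable']}")
    if genotype_p is None:
        status = "NotTestable"
        reasons.append("no testable genotype contrast")
    elif reasons:
        status = "Degraded"
    source = "in-memory"
    return ReportBundle(
        metadata=_metadata(source, spec.seed, timestamp),
        status=status, status_reasons=reasons,
        genotype_pvalue=genotype_p,
        input_summary=summarize_dataset(ds),
        preparation=ds.prep.to_dict(),
        model=_spec_dict(ds.spec),
        result=result.to_dict(),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _encode(obj: Any, key: str | None = None) -> Any:
    """Recursively make ``obj`` JSON-safe: tuples to lists, numpy scalars
    to Python, NaN/inf to None (the parent dict gains a flag sibling)."""
    if isinstance(obj, dict):
        out: dict[str, Any] = {}
        for k, v in obj.items():
            k = str(k)
            enc = _encode(v, k)
            out[k] = enc
            if isinstance(v, float) and not math.isfinite(v):
                out[f"{k}_nonfinite"] = ("nan" if math.isnan(v)
                                         else "inf" if v > 0 else "-inf")
        return out
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if hasattr(obj, "item") and not isinstance(obj, (str, bytes)):
        try:
            obj = obj.item()
        except Exception:
            pass
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def serialize_json(bundle: ReportBundle) -> str:
    """Deterministic UTF-8 JSON text of the bundle (validates first)."""
    doc = _encode(bundle.to_dict())
    validate_report(doc)
    return json.dumps(doc, indent=2, ensure_ascii=False, allow_nan=False)


def render_summary(bundle: ReportBundle) -> str:
    """Human-readable block for terminals and logs."""
    lines = [f"phenoscreen {bundle.metadata.get('tool_version')} — "
             f"status: {bundle.status}"]
    for r in bundle.status_reasons:
        lines.append(f"  note: {r}")
    if bundle.status == "Failed":
        return "\n".join(lines) + "\n"
    summ = bundle.input_summary or {}
    lines.append(f"rows: {summ.get('n_rows')}")
    for gc in summ.get("group_counts", []):
        desc = ", ".join(f"{k}={v}" for k, v in gc.items() if k != "n")
        lines.append(f"  {desc}: n={gc['n']}")
    model = bundle.model or {}
    lines.append(f"framework: {model.get('framework')}  "
                 f"terms: {' + '.join(model.get('fixed_terms', []))}")
    lines.append(f"genotype p-value: {bundle.genotype_pvalue}")
    result = bundle.result or {}
    if result.get("framework") == "LMM":
        fe = result.get("final_model", {}).get("fixed_estimates", {})
        for name, est in fe.items():
            if name == "Intercept":
                continue
            lines.append(
                f"  {name}: est={est['estimate']:.4g} "
                f"CI=({est['ci_low']:.4g}, {est['ci_high']:.4g}) p={est['p']:.4g}")
        for k in ("overall", "female", "male", "interaction"):
            sub = result.get("submodels", {}).get(k)
            if sub:
                lines.append(f"  {k} genotype effect: est={sub['estimate']:.4g} "
                             f"p={sub['p']:.4g}")
        diag = result.get("diagnostics", {})
        sw = diag.get("shapiro_wilk")
        if sw:
            lines.append(f"  Shapiro-Wilk: W={sw['statistic']:.4f} p={sw['p']:.4g}")
        ks = diag.get("kolmogorov_smirnov")
        if ks:
            lines.append(f"  Kolmogorov-Smirnov: D={ks['statistic']:.4f} "
                         f"p={ks['p']:.4g}")
    elif result.get("framework") in ("FisherExact", "RRplus"):
        for label, entry in result.get("strata", {}).items():
            if result["framework"] == "FisherExact":
                out = entry.get("outcome")
                p = out["p_value"] if out else None
                lines.append(f"  stratum {label}: p={p}")
                if entry.get("table"):
                    lines.append(f"    counts={entry['table']['counts']}")
            else:
                for d in ("high_test", "low_test"):
                    o = entry.get(d)
                    if o:
                        lines.append(f"  stratum {label} {d}: p={o.get('p_value')}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _detect_response(df: pd.DataFrame, requested: str | None) -> str:
    if requested:
        if requested not in df.columns:
            raise ValidationError(f"response column {requested!r} absent")
        return requested
    for c in df.columns:
        if c.lower() == "response":
            return c
    roles = {"genotype", "sex", "gender", "batch", "bodyweight", "weight",
             "body_weight", "lifestage", "date_of_experiment", "assay_date",
             "biological_sample_group"}
    for c in df.columns:
        if c.lower() not in roles:
            return c
    raise ValidationError("could not identify a response column")


def analyze(ds: PhenDataset) -> LMMResult | ContingencyResult | RRResult:
    """Dispatch to the framework named in the bound spec."""
    if ds.spec.framework == LMM:
        return analyze_continuous(ds)
    if ds.spec.framework == FISHER:
        return analyze_categorical(ds)
    return analyze_rr(ds)


def run_pipeline(input_path: str | Path, config: Mapping[str, Any] | None = None,
                 out_path: str | Path | None = None) -> tuple[int, ReportBundle]:
    """Load -> normalize -> missing -> redundancy -> validate -> analyze ->
    report.  Every failure becomes a ``Failed`` bundle with a reason and a
    nonzero exit status; nothing raises out of this function.
    """
    cfg = dict(config or {})
    timestamp = not cfg.get("no_timestamp", False)
    seed = cfg.get("seed")
    try:
        raw = load_table(input_path, delimiter=cfg.get("delimiter"))
        response = _detect_response(raw.data, cfg.get("response"))
        if response.lower() == "response":
            response = "Response"  # normalized name
        framework = cfg.get("framework")
        if framework is None:
            col = cfg.get("response") or next(
                c for c in raw.data.columns
                if c.lower() == response.lower())
            numeric = pd.api.types.is_numeric_dtype(raw.data[col])
            framework = LMM if numeric else FISHER
        overrides: dict[str, Any] = {"response": response, "seed": seed}
        if cfg.get("fixed_terms"):
            overrides["fixed_terms"] = list(cfg["fixed_terms"])
        if cfg.get("random_groups") is not None:
            overrides["random_groups"] = list(cfg["random_groups"])
        if cfg.get("reference"):
            overrides["reference_genotype"] = cfg["reference"]
        if cfg.get("rr_quantile"):
            overrides["rr_quantile"] = float(cfg["rr_quantile"])
        if cfg.get("mc_draws"):
            overrides["mc_draws"] = int(cfg["mc_draws"])
        if cfg.get("optimize"):
            overrides["optimize"] = cfg["optimize"]
        spec = default_spec(framework, **overrides)
        ds = prepare(raw, spec,
                     missing_threshold=float(cfg.get("missing_threshold", 0.5)),
                     substitutions=cfg.get("substitutions"))
        result = analyze(ds)
        bundle = build_report(ds, ds.spec, result, timestamp=timestamp)
        bundle.metadata.update(_metadata(str(input_path), seed, timestamp))
    except (ValidationError, FitError, OSError, OverflowError) as exc:
        log.error("pipeline failed: %s", exc)
        bundle = ReportBundle(
            metadata=_metadata(str(input_path), seed, timestamp),
            status="Failed",
            status_reasons=[f"{type(exc).__name__}: {exc}"])
    text = serialize_json(bundle)
    if out_path is not None:
        Path(out_path).write_text(text, encoding="utf-8")
    exit_code = 1 if bundle.status == "Failed" else 0
    return exit_code, bundle
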