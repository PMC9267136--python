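"""End-to-end characterization: triage → quantify → classify → combine.

A run is described by a configuration dictionary (typically loaded from
YAML): transcript definitions, a variant list with either precomputed
event quantifications (r. description + carrier/control percents) or
paths to per-sample SJ.out.tab files and an optional per-read TSV, plus
curator evidence strings and thresholds.  The output is one report row
per variant mirroring the clinical summary-table layout, and a structured
log of every threshold decision taken along the way.
"""

from __future__ import annotations

import io
import os

import pandas as pd
import yaml

from . import acmg
from .classify import SplicingResult, classify_splicing
from .events import event_from_r, frame_effect, hgvs_r, name_events
from .junctions import (
    EventQuantification,
    NoCoverage,
    allele_fulllength_fraction,
    compare_to_controls,
    detect_aberrant,
    quantify_event,
    read_reads_tsv,
    read_sj_tab,
)
from .transcript import TranscriptModel, variant_c_position
from .triage import ScorePanel, select_for_rna

__all__ = [
    "DEFAULT_THRESHOLDS",
    "load_config",
    "run_characterization",
    "render_report",
    "format_percent",
]

DEFAULT_THRESHOLDS = {
    "noise_alt_percent": 1.0,
    "min_carrier_percent": 0.1,
    "fold_over_controls": 3.0,
    "insignificance_threshold": 2.0,
    "spliceai_gate_conjunctive": True,
}

REPORT_COLUMNS = [
    "variant",
    "gene",
    "variant_type",
    "events",
    "r_descriptions",
    "frame_effects",
    "carrier_percents",
    "control_mean_percents",
    "total_aberrant_percent",
    "alt_fulllength_percent",
    "splicing_class",
    "suggested_functional_evidence",
    "evidence",
    "acmg_class",
    "selected_for_rna",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, variant: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for {variant}: {cause}")
        self.stage = stage
        self.variant = variant


def load_config(path: str) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    base = os.path.dirname(os.path.abspath(path))
    _validate_paths(config, base)
    config["_base_dir"] = base
    return config


def _validate_paths(config: dict, base: str) -> None:
    for v in config.get("variants", []):
        for key in ("carrier_sj", "reads_tsv"):
            p = v.get(key)
            if p and not os.path.exists(os.path.join(base, p)):
                raise FileNotFoundError(f"{key} for {v.get('variant')}: {p}")
        for p in v.get("control_sj", []) or []:
            if not os.path.exists(os.path.join(base, p)):
                raise FileNotFoundError(f"control_sj for {v.get('variant')}: {p}")


def _thresholds(config: dict) -> dict:
    th = dict(DEFAULT_THRESHOLDS)
    th.update(config.get("thresholds") or {})
    bad = set(th) - set(DEFAULT_THRESHOLDS)
    if bad:
        raise ValueError(f"unknown threshold keys: {sorted(bad)}")
    return th


def run_characterization(config: dict) -> tuple[pd.DataFrame, list[str]]:
    """Characterize every variant in the config; returns (report, log)."""
    th = _thresholds(config)
    base = config.get("_base_dir", ".")
    models = {
        t.get("id") or t.get("transcript_id"): TranscriptModel.from_dict(t)
        for t in config.get("transcripts", [])
    }
    log: list[str] = [f"thresholds: {th}"]
    rows = []
    for vcfg in config.get("variants", []):
        name = vcfg.get("variant", "?")
        try:
            rows.append(_characterize_one(vcfg, models, th, base, log))
        except PipelineError:
            raise
        except Exception as exc:  # attribute failures to their variant
            stage = getattr(exc, "_stage", "characterize")
            raise PipelineError(stage, name, exc) from exc
    return pd.DataFrame(rows, columns=REPORT_COLUMNS), log


def _characterize_one(vcfg, models, th, base, log) -> dict:
    name = vcfg["variant"]
    model = models[vcfg["transcript"]]
    kind = vcfg.get("kind", "other")
    pos = variant_c_position(name)
    site = model.variant_site_class(pos)

    selected = None
    if vcfg.get("scores"):
        sel = select_for_rna(
            ScorePanel(**vcfg["scores"]),
            spliceai_gate_conjunctive=th["spliceai_gate_conjunctive"],
        )
        selected = sel.selected
        log.append(f"{name}: triage selected={sel.selected} "
                   f"rules={list(sel.triggered_rules)}")

    alt_fl = vcfg.get("alt_fulllength_percent")
    if vcfg.get("events") is not None:
        quants = _precomputed_events(vcfg, model, th, log)
    else:
        quants, alt_fl = _events_from_files(vcfg, model, th, base, log)
        if vcfg.get("alt_fulllength_percent") is not None:
            alt_fl = vcfg["alt_fulllength_percent"]

    result = SplicingResult(
        variant=name,
        events=quants,
        tag_available=kind != "intronic" and alt_fl is not None,
        alt_fulllength_percent=alt_fl,
    )
    classify_splicing(result, noise_alt_percent=th["noise_alt_percent"])
    log.append(f"{name}: splicing class {result.splicing_class} "
               f"(total aberrant {result.total_aberrant_percent:g}%, "
               f"tag={'yes' if result.tag_available else 'no'})")

    suggestion = acmg.derive_functional_evidence(
        result.splicing_class,
        result.tag_available,
        result.total_aberrant_percent,
        "silent" if kind in ("silent", "synonymous") else kind,
        insignificance_threshold=th["insignificance_threshold"],
    )
    if suggestion is not None and suggestion.render() == "PS3-m":
        log.append(f"{name}: PS3 downgraded to moderate (no exonic tag or "
                   "completeness undetermined)")
    evidence = acmg.parse_evidence(vcfg.get("evidence", ""), variant=name)
    acmg_class = evidence.combined_class if evidence.items else None
    log.append(f"{name}: evidence [{evidence.render()}] -> {acmg_class}")

    frames = []
    for q in quants:
        try:
            frames.append(frame_effect(q.event, model).classification)
        except Exception:
            frames.append("indeterminate")
    return {
        "variant": name,
        "gene": model.gene,
        "variant_type": site,
        "events": ",".join(q.event.symbol for q in quants),
        "r_descriptions": ",".join(hgvs_r(q.event, model) for q in quants),
        "frame_effects": ",".join(frames),
        "carrier_percents": ",".join(
            format_percent(q.carrier_percent) for q in quants
        ),
        "control_mean_percents": ",".join(
            format_percent(sum(q.control_percents) / len(q.control_percents))
            if q.control_percents else "ND"
            for q in quants
        ),
        "total_aberrant_percent": format_percent(result.total_aberrant_percent),
        "alt_fulllength_percent": (
            format_percent(alt_fl) if alt_fl is not None else "ND"
        ),
        "splicing_class": result.splicing_class,
        "suggested_functional_evidence": (
            suggestion.render() if suggestion else ""
        ),
        "evidence": evidence.render(),
        "acmg_class": acmg_class or "",
        "selected_for_rna": "" if selected is None else str(selected),
    }


def _precomputed_events(vcfg, model, th, log) -> list[EventQuantification]:
    quants = []
    events = []
    for ecfg in vcfg["events"]:
        ev = event_from_r(ecfg["r"], model, support=ecfg["carrier_percent"])
        events.append((ev, ecfg))
    name_events([ev for ev, _ in events])
    for ev, ecfg in events:
        controls = list(ecfg.get("control_percents") or [0.0] * 5)
        associated, why = compare_to_controls(
            ecfg["carrier_percent"], controls,
            min_carrier_percent=th["min_carrier_percent"],
            fold_over_controls=th["fold_over_controls"],
        )
        log.append(f"{vcfg['variant']}: {ev.symbol} {why}")
        quants.append(
            EventQuantification(ev, ecfg["carrier_percent"], controls,
                                variant_associated=associated, rationale=why)
        )
    return quants


def _events_from_files(vcfg, model, th, base, log):
    carrier = read_sj_tab(os.path.join(base, vcfg["carrier_sj"]), "carrier")
    controls = [
        read_sj_tab(os.path.join(base, p), f"control-{i}")
        for i, p in enumerate(vcfg.get("control_sj") or [], start=1)
    ]
    events = detect_aberrant(carrier, model)
    quants = []
    for ev in events:
        try:
            pct = quantify_event(ev, carrier, model)
        except NoCoverage as exc:
            log.append(f"{vcfg['variant']}: {ev.symbol} not quantifiable: {exc}")
            continue
        ctrl_pcts = []
        for ct in controls:
            try:
                ctrl_pcts.append(quantify_event(ev, ct, model))
            except NoCoverage:
                ctrl_pcts.append(0.0)
        if ctrl_pcts:
            associated, why = compare_to_controls(
                pct, ctrl_pcts,
                min_carrier_percent=th["min_carrier_percent"],
                fold_over_controls=th["fold_over_controls"],
            )
        else:
            associated, why = pct >= th["min_carrier_percent"], "no controls"
        log.append(f"{vcfg['variant']}: {ev.symbol} carrier "
                   f"{pct:.2f}% — {why}")
        quants.append(EventQuantification(ev, pct, ctrl_pcts,
                                          variant_associated=associated,
                                          rationale=why))
    alt_fl = None
    if vcfg.get("reads_tsv"):
        reads = read_reads_tsv(os.path.join(base, vcfg["reads_tsv"]),
                               model.chrom, model.strand)
        split = allele_fulllength_fraction(reads, model)
        if split is not None:
            alt_fl = split["alt"]
            log.append(f"{vcfg['variant']}: full-length alt "
                       f"{split['alt']:.2f}% / ref {split['ref']:.2f}%")
        else:
            log.append(f"{vcfg['variant']}: no exonic tag in reads")
    return quants, alt_fl


def format_percent(x: float) -> str:
    """Report-style percent: one decimal, but sub-0.1 values keep their
    leading significant digits (0.04 renders as 0.04, not 0.0)."""
    if 0 < x < 0.1:
        return f"{x:.2g}"
    return f"{x:.1f}"


def render_report(report: pd.DataFrame, fmt: str = "tsv",
                  path: str | None = None) -> str:
    """Serialize the report as TSV or a GitHub-style markdown table."""
    if fmt == "tsv":
        text = report.to_csv(sep="\t", index=False)
    elif fmt == "markdown":
        buf = io.StringIO()
        cols = list(report.columns)
        buf.write("| " + " | ".join(cols) + " |\n")
        buf.write("|" + "|".join(["---"] * len(cols)) + "|\n")
        for _, row in report.iterrows():
            buf.write("| " + " | ".join(str(row[c]) for c in cols) + " |\n")
        text = buf.getvalue()
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
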