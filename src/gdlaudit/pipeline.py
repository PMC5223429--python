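"""End-to-end compliance audit: map -> check -> oracle -> compare -> report."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from .compliance import MatchReport, compare, compute_rates, report
from .errors import GDLError, PipelineError
from .engine import run_cohort
from .gdl.parser import parse_guideline
from .gdl.validate import validate_guideline
from .manifest import build_manifest
from .oracle import oracle_rates
from .registry import default_mapping, load_mapping, read_registry_csv, split_registry

logger = logging.getLogger(__name__)


def load_guideline_dir(guideline_dir=None) -> list:
    """Parse and validate every ``.gdl2t`` file in a directory.

    Defaults to the shipped guideline set.  Returns ``(guideline, source
    text)`` pairs; any validation *error* aborts.
    """
    from .compliance import builtin_guideline_dir

    gdir = Path(guideline_dir) if guideline_dir is not None else builtin_guideline_dir()
    paths = sorted(gdir.glob("*.gdl2t"))
    if not paths:
        raise GDLError(f"no .gdl2t guideline files in {gdir}")
    loaded = []
    for path in paths:
        text = path.read_text(encoding="utf-8")
        guideline = parse_guideline(text)
        errors = [i for i in validate_guideline(guideline) if i.severity == "error"]
        if errors:
            raise GDLError(
                f"{path.name}: " + "; ".join(i.message for i in errors)
            )
        loaded.append((guideline, text))
    return loaded


def engine_rates(registry: pd.DataFrame, guidelines, mapping=None) -> list:
    """The GDL-engine arm: split the registry and run every guideline."""
    mapping = mapping if mapping is not None else default_mapping()
    datasets = split_registry(registry, mapping)
    frames = []
    for guideline in guidelines:
        outcome = run_cohort(guideline, datasets)
        outcome["contraindication_id"] = guideline.id
        frames.append(outcome)
    outcomes = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["patient_id", "period", "flag", "contraindication_id"])
    )
    return compute_rates(outcomes), outcomes


def run_end_to_end(
    registry_csv,
    out_dir,
    guideline_dir=None,
    mapping_path=None,
    seed: Optional[int] = None,
):
    """Full audit of one registry file; writes report + manifest to ``out_dir``.

    Returns ``(engine_results, oracle_results, match, manifest)``.  Any
    stage failure raises :class:`PipelineError` naming the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(name, err) from err

    registry = stage("read-registry", read_registry_csv, registry_csv)
    logger.info("read %d patients from %s", len(registry), registry_csv)
    loaded = stage("load-guidelines", load_guideline_dir, guideline_dir)
    labels = {g.id: g.name for g, _ in loaded}
    mapping = stage(
        "load-mapping",
        lambda: load_mapping(mapping_path) if mapping_path else default_mapping(),
    )
    engine_results, outcomes = stage(
        "check", engine_rates, registry, [g for g, _ in loaded], mapping
    )
    outcomes.to_csv(out_dir / "outcomes.csv", index=False, lineterminator="\n")
    oracle_results = stage("oracle", oracle_rates, registry)
    match: MatchReport = stage("compare", compare, engine_results, oracle_results)
    stage("report", report, match, out_dir, labels)
    manifest = build_manifest(
        inputs=[registry_csv], guideline_texts=[t for _, t in loaded], seed=seed
    )
    manifest.write(out_dir / "manifest.json")
    logger.info(
        "complete match: %s (%d cells)", match.complete_match, len(match.rows)
    )
    return engine_results, oracle_results, match, manifest
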