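"""End-to-end analysis runs with machine-readable outputs and a manifest.

``run_full_analysis`` drives the whole pipeline — curation, rate ratios,
same-temperature control, data-vs-control comparison, per-reaction slope
screen with Bonferroni flags, and (optionally) the mirrored stability
analysis — writing one TSV per stage plus JSON summaries, so every number
in the summary can be recomputed from the stage tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .curation import curate, subset_reactions
from .io import (
    SYNTHETIC_KINETIC,
    SYNTHETIC_STABILITY,
    Dialect,
    ValueType,
    read_growth_temperatures,
    read_kinetic_entries,
    read_stability_records,
    write_table,
)
from .stability import family_fold_changes, fit_tm_vs_tgrowth, match_stability_t_growth
from .stats import (
    SlopeFit,
    bonferroni_threshold,
    compare_to_control,
    control_fold_changes,
    fit_reaction_slope,
    rate_ratio,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs for one full analysis run."""

    kinetic_path: str
    t_growth_path: str
    stability_path: Optional[str] = None
    value_type: ValueType = ValueType.KCAT
    assay_temperature_C: Optional[float] = None
    min_t_growth_span_C: Optional[float] = None
    strip_strains: bool = False
    alpha: float = 0.05
    bootstrap_reps: int = 10_000
    seed: int = 0
    kinetic_dialect: Dialect = SYNTHETIC_KINETIC
    stability_dialect: Dialect = SYNTHETIC_STABILITY

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        return cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage(name: str):
    logger.info("[%s] starting", name)


def run_full_analysis(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full pipeline and write all outputs under ``outdir``.

    Returns the comparison summary dict (also written to
    ``comparison.json``).  Any missing input raises immediately, naming the
    file; stage failures propagate with the stage name in the log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for label, path in (("kinetic table", config.kinetic_path),
                        ("growth-temperature table", config.t_growth_path)):
        if not Path(path).exists():
            raise FileNotFoundError(f"missing input: {label} at {path}")
    if config.stability_path and not Path(config.stability_path).exists():
        raise FileNotFoundError(f"missing input: stability table at {config.stability_path}")

    manifest: dict = {
        "software": {"name": "coldcomp", "version": __version__},
        "config": {
            k: (v.value if isinstance(v, ValueType) else v)
            for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, dict)
        },
        "inputs": {
            "kinetic": {"path": str(config.kinetic_path), "sha256": _digest(config.kinetic_path)},
            "t_growth": {"path": str(config.t_growth_path), "sha256": _digest(config.t_growth_path)},
        },
        "seed": config.seed,
        "started_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        "stages": {},
    }
    if config.stability_path:
        manifest["inputs"]["stability"] = {
            "path": str(config.stability_path),
            "sha256": _digest(config.stability_path),
        }

    _stage("curate")
    entries, read_report = read_kinetic_entries(
        config.kinetic_path, dialect=config.kinetic_dialect, value_type=config.value_type
    )
    t_table = read_growth_temperatures(config.t_growth_path)
    reactions, report = curate(
        entries, t_table, value_type=config.value_type, strip_strain=config.strip_strains
    )
    if config.assay_temperature_C is not None or config.min_t_growth_span_C is not None:
        reactions = subset_reactions(
            reactions,
            assay_temperature_C=config.assay_temperature_C,
            min_t_growth_span_C=config.min_t_growth_span_C,
        )
    curation_out = {
        "read": {
            "n_rows": read_report.n_rows,
            "n_accepted": read_report.n_accepted,
            "n_rejected": read_report.n_rejected,
            "reasons": dict(read_report.reasons),
        },
        "funnel": dataclasses.asdict(report),
        "n_reactions_after_subset": len(reactions),
    }
    (outdir / "curation_report.json").write_text(json.dumps(curation_out, indent=1))
    manifest["stages"]["curate"] = {"n_reactions": len(reactions)}

    _stage("ratios")
    ratios = [r for r in map(rate_ratio, reactions) if r is not None]
    write_table(ratios, outdir / "rate_ratios.tsv", "tsv")
    manifest["stages"]["ratios"] = {"n": len(ratios)}

    _stage("control")
    controls = control_fold_changes(reactions)
    write_table(controls, outdir / "control_fold_changes.tsv", "tsv")
    manifest["stages"]["control"] = {"n": len(controls)}

    _stage("compare")
    comparison = compare_to_control(
        ratios, controls, reps=config.bootstrap_reps, seed=config.seed
    )
    summary = {
        "schema_version": 1,
        "value_type": ValueType(config.value_type).value,
        "n_reactions": len(reactions),
        "rate_ratio": dataclasses.asdict(comparison.data_summary),
        "control": dataclasses.asdict(comparison.control_summary),
        "mann_whitney": dataclasses.asdict(comparison.utest),
        "partition": {
            "n_above_one": comparison.n_above_one,
            "n_below_one": comparison.n_below_one,
            "n_equal_one": comparison.n_equal_one,
        },
    }

    _stage("slopes")
    slopes = [s for s in map(fit_reaction_slope, reactions) if s is not None]
    threshold = bonferroni_threshold(config.alpha, len(slopes)) if slopes else None
    write_table(slopes, outdir / "slope_fits.tsv", "tsv", record_type=SlopeFit)
    significant = [s for s in slopes if threshold is not None and s.p_value < threshold]
    summary["slopes"] = {
        "n_tested": len(slopes),
        "alpha": config.alpha,
        "bonferroni_threshold": threshold,
        "significant_negative": [
            {"ec_number": s.reaction_key[0], "substrate": s.reaction_key[1],
             "m_rate": s.m_rate, "p_value": s.p_value}
            for s in significant if s.m_rate < 0
        ],
        "significant_positive": [
            {"ec_number": s.reaction_key[0], "substrate": s.reaction_key[1],
             "m_rate": s.m_rate, "p_value": s.p_value}
            for s in significant if s.m_rate >= 0
        ],
    }
    (outdir / "comparison.json").write_text(json.dumps(summary, indent=1))
    manifest["stages"]["slopes"] = {"n": len(slopes), "n_significant": len(significant)}

    if config.stability_path:
        _stage("stability")
        records, stab_read = read_stability_records(
            config.stability_path, dialect=config.stability_dialect
        )
        matched, n_unmatched = match_stability_t_growth(
            records, t_table, strip_strain=config.strip_strains
        )
        fit = fit_tm_vs_tgrowth(matched)
        folds, n_warm_more_stable = family_fold_changes(matched)
        write_table(folds, outdir / "family_fold_changes.tsv", "tsv")
        stability_out = {
            "read": {"n_rows": stab_read.n_rows, "n_accepted": stab_read.n_accepted,
                     "n_rejected": stab_read.n_rejected, "reasons": dict(stab_read.reasons)},
            "n_unmatched": n_unmatched,
            "fit": dataclasses.asdict(fit),
            "n_families": len(folds),
            "n_warm_more_stable": n_warm_more_stable,
        }
        (outdir / "stability.json").write_text(json.dumps(stability_out, indent=1))
        manifest["stages"]["stability"] = {
            "n_records": len(matched), "n_families": len(folds)
        }

    manifest["finished_utc"] = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return summary
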