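"""End-to-end orchestration over directories of slides.

Reads every per-slide cell table in an input directory, counts layers,
writes per-slide results, assembles the cohort table (joining diagnosis and
survival metadata when provided) and runs the statistics stage.  Failures
are isolated per slide: one corrupt table does not abort the run, it is
logged and listed in the manifest.  A manifest records parameters, seed,
package version and input hashes so that identical configs reproduce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cell_model import COHORT_COLUMNS, read_cell_table, write_results
from .cohort_stats import compare_groups, plot_km, survival_split
from .errors import EpilayerError, ParameterError
from .onion_peeling import count_layers, summarize_slide

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run (defaults are the method's thresholds)."""

    input_dir: str
    out_dir: str
    metadata: str | None = None     # optional CSV: slide_id, diagnosis_group, pfi_time, pfi_event
    max_edge_len: float = 500.0     # neighbor-relation cutoff, 40x px
    min_component_size: int = 20    # epithelial components below this are dropped
    quantile: float = 0.5           # slide thickness = this quantile of inner-edge counts
    margin: int = 50                # sub-window discard margin, 40x px
    pseudo_spacing: float = 60.0    # pseudo-point pitch, 40x px
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.max_edge_len > 0:
            raise ParameterError("max_edge_len must be > 0")
        if self.min_component_size < 1:
            raise ParameterError("min_component_size must be >= 1")
        if not 0 < self.quantile < 1:
            raise ParameterError("quantile must be in (0, 1)")
        if not 0 <= self.margin < 250:
            raise ParameterError("margin must be in [0, 250)")
        if not self.pseudo_spacing > 0:
            raise ParameterError("pseudo_spacing must be > 0")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run fuse-free slide processing: count layers per table, then statistics.

    Returns the manifest dict (also written to ``manifest.json``).  Per-slide
    outputs are ``<slide>.result.csv`` + JSON sidecar; the cohort table goes
    to ``cohort.csv`` and, when metadata with diagnosis/survival fields is
    supplied, the statistics report to ``report.json`` and ``km.png``.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = sorted(Path(config.input_dir).glob("*.csv"))
    if not tables:
        raise EpilayerError(f"no cell tables (*.csv) found in {config.input_dir}")

    rows, failures, input_hashes = [], [], {}
    for path in tables:
        slide_id = path.stem
        input_hashes[path.name] = _sha256(path)
        try:
            cells = read_cell_table(path)
            result = count_layers(
                cells,
                max_edge_len=config.max_edge_len,
                min_component_size=config.min_component_size,
                slide_id=slide_id,
                seed=config.seed,
            )
            write_results(result, out_dir / f"{slide_id}.result.csv")
            summary = summarize_slide(result, quantile=config.quantile)
            rows.append({"slide_id": slide_id, **summary,
                         "n_unreachable": len(result.unreachable_ids)})
        except Exception as exc:  # per-slide isolation
            logger.error("slide %s failed: %s", slide_id, exc)
            failures.append({"slide_id": slide_id, "error": str(exc)})

    cohort = pd.DataFrame(rows)
    report = None
    if config.metadata and not cohort.empty:
        meta = pd.read_csv(config.metadata)
        cohort = cohort.merge(meta, on="slide_id", how="left")
    cohort.to_csv(out_dir / "cohort.csv", index=False)

    if not cohort.empty and all(c in cohort.columns for c in COHORT_COLUMNS):
        anova_median = compare_groups(cohort, "median_layers")
        anova_sd = compare_groups(cohort, "sd_layers")
        surv = survival_split(cohort)
        plot_km(surv, out_dir / "km.png")
        report = {
            "anova_median_layers": {"F": anova_median.f_statistic, "p": anova_median.p_value,
                                    "groups": anova_median.group_stats},
            "anova_sd_layers": {"F": anova_sd.f_statistic, "p": anova_sd.p_value,
                                "groups": anova_sd.group_stats},
            "survival": {
                "threshold": surv.threshold,
                "group_sizes": surv.group_sizes,
                "hazard_ratio": surv.hazard_ratio,
                "p_wald": surv.p_wald,
                "p_likelihood_ratio": surv.p_likelihood_ratio,
            },
        }
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))

    manifest = {
        "version": __version__,
        "parameters": {k: v for k, v in dataclasses.asdict(config).items()
                       if k not in ("input_dir", "out_dir", "metadata", "log_level")},
        "n_slides": len(rows),
        "failures": failures,
        "input_hashes": input_hashes,
        "output_hashes": {
            p.name: _sha256(p) for p in sorted(out_dir.glob("*.result.csv*"))
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
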