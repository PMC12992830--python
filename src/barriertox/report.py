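"""Pipeline runner: evaluate every rule x model x assay and write reports.

Thin orchestration over the library stages — scoring, exposure,
diagnostics, threshold sweep and correlation — producing delimited-text
tables plus a JSON summary, with a log of every censoring decision and
undefined rate.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .diagnostics import (DEFAULT_REDUCTION_CUTOFF, RULES, correlation_matrix,
                          evaluate_assay, threshold_sweep)
from .exposure import DEFAULT_MOS_THRESHOLD, exposure_table
from .panel import Assay, DrugPanel, Model, bundled_panel, load_panel
from .scoring import DEFAULT_REFERENCE_THRESHOLD, reference_labels, score_panel

logger = logging.getLogger("barriertox")

COMBOS = [(Model.HIEC, Assay.TEER), (Model.CACO2, Assay.TEER),
          (Model.HIEC, Assay.ATP), (Model.CACO2, Assay.ATP)]


@dataclass
class RunConfig:
    """Configuration for one end-to-end pipeline run."""

    panel_path: Optional[str] = None  # None -> bundled reference panel
    out_dir: str = "barriertox_out"
    rules: tuple[str, ...] = RULES
    cutoff: float = DEFAULT_REDUCTION_CUTOFF
    mos_threshold: float = DEFAULT_MOS_THRESHOLD
    label_threshold: int = DEFAULT_REFERENCE_THRESHOLD
    auc_convention: str = "both"  # binarized | continuous | both
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.cutoff <= 100:
            raise ValueError(f"cutoff must be within [0, 100], got {self.cutoff}")
        bad = [r for r in self.rules if r not in RULES]
        if bad:
            raise ValueError(f"unknown rule(s) {bad}; expected subset of {RULES}")
        if self.auc_convention not in ("binarized", "continuous", "both"):
            raise ValueError(f"unknown AUC convention {self.auc_convention!r}")

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``out_dir``.

    Writes: ``scores.csv``, ``exposure_<model>_<assay>.csv``,
    ``diagnostics.csv``, ``correlations.csv``,
    ``threshold_sweep_<model>_<assay>.csv`` and ``summary.json``.
    Returns the summary dictionary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("barriertox %s, config %s", __version__, config.config_hash())

    panel = load_panel(config.panel_path) if config.panel_path else bundled_panel()
    labels = reference_labels(panel, config.label_threshold)
    logger.info("panel: %d drugs, %d reference-positive", len(panel),
                sum(labels.values()))

    scores = score_panel(panel, config.label_threshold)
    scores.to_csv(out / "scores.csv", index=False)

    diag_rows = []
    for model, assay in COMBOS:
        exp = exposure_table(panel, model, assay, config.mos_threshold)
        exp.to_csv(out / f"exposure_{model.value}_{assay.value}.csv", index=False)
        for _, row in exp[exp["mos15_censored"]].iterrows():
            logger.info("censored IC15 for %s %s/%s: MOS lower bound %.3g, "
                        "classified nontoxic by policy", row["drug"],
                        model.value, assay.value, row["mos15_lower_bound"])
        for rule in config.rules:
            rep = evaluate_assay(panel, model, assay, rule,
                                 cutoff=config.cutoff,
                                 mos_threshold=config.mos_threshold,
                                 label_threshold=config.label_threshold)
            for name in rep.undefined:
                logger.warning("%s %s/%s: %s undefined (zero denominator)",
                               rule, model.value, assay.value, name)
            d = {"model": model.value, "assay": assay.value, "rule": rule}
            d.update(rep.to_dict())
            if config.auc_convention == "binarized":
                d.pop("auc_continuous", None)
                d.pop("auc_continuous_ci_low", None)
                d.pop("auc_continuous_ci_high", None)
                d.pop("p_value_continuous", None)
            elif config.auc_convention == "continuous" and "auc_continuous" in d:
                d["auc"] = d.pop("auc_continuous")
                d["auc_ci_low"] = d.pop("auc_continuous_ci_low")
                d["auc_ci_high"] = d.pop("auc_continuous_ci_high")
                d["p_value"] = d.pop("p_value_continuous")
            diag_rows.append(d)

        reductions = [s.pct_reduction for s in panel.summaries_for(model, assay)]
        lab = [labels[s.drug] for s in panel.summaries_for(model, assay)]
        curve = threshold_sweep(reductions, lab)
        curve.to_frame().to_csv(
            out / f"threshold_sweep_{model.value}_{assay.value}.csv", index=False)

    diagnostics = pd.DataFrame(diag_rows)
    diagnostics.to_csv(out / "diagnostics.csv", index=False)

    corr = correlation_matrix(panel, config.label_threshold)
    corr.matrix.to_csv(out / "correlations.csv")

    summary = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "n_drugs": len(panel),
        "n_reference_positive": int(sum(labels.values())),
        "diagnostics": diag_rows,
        "correlations": {
            f"{a} vs {b}": corr.entry(a, b)
            for a in corr.variables for b in corr.variables if a < b
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
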