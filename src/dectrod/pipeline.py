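"""End-to-end orchestration: simulate -> derive -> compare -> model -> roc.

Produces a JSON report bundle holding the group-comparison tables, the
univariable screen, the forward-selected pathology/morphology model, the
DECT-with-node-size model (shortest diameter + node 40-keV attenuation +
transformed ROD of 40-keV attenuation, the study's head-to-head comparison),
and the ROC tables for the full cohort and the small-node (shortest diameter
below the subgroup cut, default 5 mm) stratum, plus a provenance block.

All randomness flows from one top-level seed: the cohort stage consumes the
seed itself; any later stage that needed randomness would take the next
spawn of the same ``numpy.random.SeedSequence``, so stages remain
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, default_cohort_config, generate_cohort, read_cohort
from .diagnostics import evaluate_markers
from .modeling import Candidate, LogisticModelSpec, fit_logistic, forward_select
from .params import derive_columns
from .stats import compare_groups

__all__ = ["PipelineError", "RunConfig", "run_pipeline"]

log = logging.getLogger("dectrod.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Either ``cohort_csv`` (an existing cohort file) or ``cohort_config``
    (generator settings; defaults calibrated to the study) must be supplied.
    """

    seed: int = 0
    n_patients: int = 137
    cohort_csv: Optional[str] = None
    cohort_config: Optional[CohortConfig] = None
    subgroup_cut_mm: float = 5.0
    entry_threshold: float = 0.001

    def __post_init__(self) -> None:
        if self.subgroup_cut_mm <= 0:
            raise ValueError("subgroup_cut_mm must be > 0")


#: variables of the univariable comparison tables, (name, kind)
COMPARISON_VARIABLES = [
    ("lesion_size_mm", "continuous"),
    ("ki67_pct", "continuous"),
    ("er_positive", "categorical"),
    ("nuclear_grade", "categorical"),
    ("node_short_mm", "continuous"),
    ("node_long_mm", "continuous"),
    ("hilum_present", "categorical"),
    ("node_att40_hu", "continuous"),
    ("node_att70_hu", "continuous"),
    ("lambda_hu_node", "continuous"),
    ("node_ic_mgcm3", "continuous"),
    ("norm_ic_node", "continuous"),
    ("node_wc_mgcm3", "continuous"),
    ("norm_wc_node", "continuous"),
    ("node_effz", "continuous"),
    ("norm_effz_node", "continuous"),
    ("rod_att40", "continuous"),
    ("rod_att70", "continuous"),
    ("rod_lambda", "continuous"),
    ("rod_ic", "continuous"),
    ("rod_wc", "continuous"),
    ("rod_effz", "continuous"),
]

#: pathology / morphology candidates for the forward-selected model
PATH_MORPH_CANDIDATES = (
    Candidate("node_short_mm", "continuous"),
    Candidate("node_long_mm", "continuous"),
    Candidate("hilum_present", "categorical"),
    Candidate("er_positive", "categorical"),
    Candidate("ki67_pct", "continuous"),
    Candidate("lesion_size_mm", "continuous"),
)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("simulate")
def _load_or_simulate(cfg: RunConfig) -> pd.DataFrame:
    if cfg.cohort_csv is not None:
        df = read_cohort(cfg.cohort_csv)
        log.info("loaded cohort from %s: %d rows", cfg.cohort_csv, len(df))
        return df
    cc = cfg.cohort_config or default_cohort_config(cfg.n_patients, seed=cfg.seed)
    df = generate_cohort(cc)
    log.info("simulated cohort: %d rows (seed %d)", len(df), cc.seed)
    return df


@_stage("derive")
def _derive(df: pd.DataFrame) -> pd.DataFrame:
    out = derive_columns(df)
    log.info("derived columns: %d rows, %d columns", *out.shape)
    return out


@_stage("compare")
def _compare(df: pd.DataFrame) -> List[dict]:
    groups = df["group"].unique()
    if len(groups) < 2:
        raise ValueError(
            "cohort contains a single outcome group; comparisons are undefined"
        )
    rows = [compare_groups(df, v, k).to_dict() for v, k in COMPARISON_VARIABLES]
    log.info("compared %d variables between groups", len(rows))
    return rows


@_stage("model")
def _model(df: pd.DataFrame, cfg: RunConfig) -> dict:
    spec = LogisticModelSpec(
        outcome="group",
        candidates=PATH_MORPH_CANDIDATES,
        entry_threshold=cfg.entry_threshold,
    )
    selected, fit, trace = forward_select(spec, df)
    path_morph = {
        "selected": selected,
        "fit": fit.summary_frame().to_dict(orient="records"),
        "converged": fit.converged,
        "trace": trace,
    }
    # the study's DECT-with-node-size head-to-head model (fixed terms)
    design = pd.DataFrame(
        {
            "node_short_mm": df["node_short_mm"].to_numpy(float),
            "node_att40_hu": df["node_att40_hu"].to_numpy(float),
            "rod_att40_similarity": 10.0 * (1.0 - df["rod_att40"].to_numpy(float)),
        }
    )
    dect_fit = fit_logistic(design, df["group"].to_numpy(float))
    log.info(
        "models fitted: path/morph selected %s; DECT model converged=%s",
        selected, dect_fit.converged,
    )
    return {
        "pathological_morphological": path_morph,
        "dect_with_node_size": {
            "fit": dect_fit.summary_frame().to_dict(orient="records"),
            "converged": dect_fit.converged,
        },
    }


@_stage("roc")
def _roc(df: pd.DataFrame, cfg: RunConfig) -> dict:
    full = evaluate_markers(df, stratum="full")
    small_mask = df["node_short_mm"] < cfg.subgroup_cut_mm
    small = evaluate_markers(
        df, subgroup=small_mask, stratum=f"node_short_mm<{cfg.subgroup_cut_mm:g}"
    )
    log.info("ROC: %d markers, small-node stratum %d rows", len(full), int(small_mask.sum()))
    return {
        "full": [r.to_dict() for r in full],
        "small_node": [r.to_dict() for r in small],
    }


def run_pipeline(cfg: RunConfig, out_path: Optional[str] = None) -> dict:
    """Run the full analysis; return (and optionally write) the report bundle."""
    df = _load_or_simulate(cfg)
    df = _derive(df)
    comparisons = _compare(df)
    models = _model(df, cfg)
    roc = _roc(df, cfg)

    cc = cfg.cohort_config or (
        None if cfg.cohort_csv else default_cohort_config(cfg.n_patients, seed=cfg.seed)
    )
    cfg_hash = hashlib.sha256(
        json.dumps(cc.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16] if cc is not None else None
    report = {
        "provenance": {
            "software": "dectrod",
            "version": __version__,
            "seed": cfg.seed,
            "n_patients": int(len(df)),
            "n_metastasis": int((df["group"] == 1).sum()),
            "cohort_config_sha256_16": cfg_hash,
            "cohort_source": cfg.cohort_csv or "simulated",
            "subgroup_cut_mm": cfg.subgroup_cut_mm,
        },
        "comparisons": comparisons,
        "models": models,
        "roc": roc,
    }
    if out_path is not None:
        out = Path(out_path)
        tmp = out.with_suffix(out.suffix + ".tmp")
        try:
            with open(tmp, "w") as fh:
                json.dump(report, fh, indent=2, default=_json_default)
            tmp.replace(out)
        except Exception:
            tmp.unlink(missing_ok=True)
            raise
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
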