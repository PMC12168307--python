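"""End-to-end orchestration: cohort -> volumetry -> features -> selection
-> model grid -> statistics.

A single master seed determines every stochastic choice (phantoms, noise
filters, fold partitions, bootstraps); the run manifest echoes the
configuration and derived seeds so a run is reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import volumetry
from .cohort import CohortSpec, default_cohort_spec, generate_cohort
from .errors import ConfigurationError
from .features import default_bank_manifest, feature_table, restricted_manifest
from .filters import DEFAULT_FILTER_BANK, FilterBankConfig
from .grid import GridConfig, fit_evaluate_grid, select_best
from .io import read_cohort_dir
from .selection import (
    SelectionConfig,
    SelectionReport,
    combined_voting,
    cv_feature_voting,
    report_table,
)
from .stats import clinical_comparison_report, delong_test

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cohort_spec: CohortSpec | None = None
    input_dir: str | None = None
    image_types: list[str] | None = None  # None = full 15-type bank
    filter_bank: FilterBankConfig = field(default_factory=lambda: DEFAULT_FILTER_BANK)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    master_seed: int = 0
    out_dir: str | None = None
    write_cohort_files: bool = False

    def __post_init__(self) -> None:
        if (self.cohort_spec is None) == (self.input_dir is None):
            raise ConfigurationError(
                "exactly one of cohort_spec / input_dir must be provided"
            )


def _derived_seed(master: int, tag: str) -> int:
    h = hashlib.sha256(f"{master}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _fallback_final_set(report: SelectionReport, table: pd.DataFrame, labels,
                        minimum: int = 2) -> list[str]:
    """If voting produced an empty final set, fall back to the top-voted
    features (or, with no votes at all, the strongest label-correlated
    features) so the downstream grid still has a model to fit."""
    if report.final_set:
        return report.final_set
    ranked = sorted(report.voting_count.items(), key=lambda kv: (-kv[1], kv[0]))
    fallback = [k for k, v in ranked[:minimum] if v > 0]
    if not fallback:
        y = (labels == np.asarray(labels).max()).astype(float)
        r = table.apply(lambda c: abs(np.corrcoef(c, y)[0, 1]) if c.std() > 0 else 0.0)
        fallback = list(r.sort_values(ascending=False).index[:minimum])
    logger.warning("empty final set after voting; falling back to %s", fallback)
    return fallback


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the in-memory artifact bundle and
    writes CSV/JSON artifacts when ``out_dir`` is set."""
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    stage = "cohort"
    try:
        if cfg.cohort_spec is not None:
            bundle = generate_cohort(
                cfg.cohort_spec,
                out_dir=(out / "cohort") if (out and cfg.write_cohort_files) else None,
            )
            subjects, clinical = bundle.subjects, bundle.clinical
        else:
            subjects, clinical = read_cohort_dir(cfg.input_dir)

        stage = "volumetry"
        vol_table = volumetry.volumetry_table(subjects, clinical)
        correlations = volumetry.per_class_correlations(vol_table, clinical)

        stage = "features"
        manifest = (
            restricted_manifest(cfg.image_types) if cfg.image_types else default_bank_manifest()
        )
        noise_seed = _derived_seed(cfg.master_seed, "noise")
        tables = {
            seq: feature_table(
                subjects, seq, manifest=manifest, filter_cfg=cfg.filter_bank,
                noise_seed=noise_seed,
            )
            for seq in ("t2w", "adc")
        }
        clinical = clinical.set_index("subject_id").loc[tables["t2w"].index].reset_index()
        labels = clinical["class_label"].to_numpy()

        stage = "selection"
        sel_cfg = SelectionConfig(
            **{**vars(cfg.selection), "fold_seed": _derived_seed(cfg.master_seed, "folds")}
        )
        reports = {seq: cv_feature_voting(tables[seq], labels, sel_cfg) for seq in ("t2w", "adc")}
        combined_report = combined_voting(
            tables["t2w"], tables["adc"], labels, reports["t2w"], reports["adc"], sel_cfg
        )
        pooled = pd.concat(
            [tables["t2w"].add_prefix("t2w__"), tables["adc"].add_prefix("adc__")], axis=1
        )
        model_features = {
            "t2w": tables["t2w"].loc[:, _fallback_final_set(reports["t2w"], tables["t2w"], labels)],
            "adc": tables["adc"].loc[:, _fallback_final_set(reports["adc"], tables["adc"], labels)],
            "combined": pooled.loc[:, _fallback_final_set(combined_report, pooled, labels)],
        }

        stage = "grid"
        grid_cfg = GridConfig(
            **{**vars(cfg.grid), "seed": _derived_seed(cfg.master_seed, "grid")}
        )
        grids = {name: fit_evaluate_grid(X, labels, grid_cfg) for name, X in model_features.items()}
        best = {name: select_best(g) for name, g in grids.items()}

        stage = "stats"
        flag_names = [c for c in clinical.columns
                      if c not in ("subject_id", "age_months", "sex", "class_label")]
        contingency = clinical_comparison_report(clinical, flag_names)
        delong_rows = []
        pairs = [("t2w", "adc"), ("t2w", "combined"), ("adc", "combined")]
        for m1, m2 in pairs:
            key1 = tuple(best[m1].pipeline.split("|"))
            key2 = tuple(best[m2].pipeline.split("|"))
            for fold in range(grid_cfg.n_folds):
                s1, y1 = grids[m1].fold_scores[key1][fold]
                s2, _ = grids[m2].fold_scores[key2][fold]
                res = delong_test(y1, s1, s2)
                delong_rows.append(
                    {"comparison": f"{m1} vs {m2}", "fold": fold, "auc_a": res.auc_a,
                     "auc_b": res.auc_b, "p_value": res.p_value}
                )
        delong_table = pd.DataFrame(delong_rows)
    except Exception:
        if out:
            (out / "FAILED").write_text(f"pipeline failed at stage: {stage}\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise

    artifacts = {
        "clinical": clinical,
        "volumetry": vol_table,
        "correlations": correlations,
        "features": tables,
        "selection": {"t2w": reports["t2w"], "adc": reports["adc"], "combined": combined_report},
        "grids": grids,
        "best": best,
        "contingency": contingency,
        "delong": delong_table,
    }
    if out:
        _write_artifacts(cfg, artifacts, out)
    return artifacts


def _write_artifacts(cfg: PipelineConfig, artifacts: dict, out: Path) -> None:
    artifacts["volumetry"].to_csv(out / "volumetry.csv", index=False)
    artifacts["correlations"].to_csv(out / "age_volume_correlations.csv", index=False)
    for seq, df in artifacts["features"].items():
        df.to_csv(out / f"features_{seq}.csv")
    sel = {k: v.to_jsonable() for k, v in artifacts["selection"].items()}
    (out / "selection_report.json").write_text(json.dumps(sel, indent=2, sort_keys=True))
    for name, rep in artifacts["selection"].items():
        report_table(rep).to_csv(out / f"selected_features_{name}.csv", index=False)
    for name, g in artifacts["grids"].items():
        g.fold_metrics.to_csv(out / f"grid_{name}_folds.csv", index=False)
        g.summary.to_csv(out / f"grid_{name}_summary.csv", index=False)
    best = {name: row.to_dict() for name, row in artifacts["best"].items()}
    (out / "best_models.json").write_text(json.dumps(best, indent=2, sort_keys=True))
    artifacts["contingency"].to_csv(out / "clinical_contingency.csv", index=False)
    artifacts["delong"].to_csv(out / "delong_foldwise.csv", index=False)
    feature_hash = hashlib.sha256(
        artifacts["features"]["t2w"].to_csv().encode()
    ).hexdigest()
    manifest = {
        "master_seed": cfg.master_seed,
        "image_types": cfg.image_types,
        "selection": vars(cfg.selection),
        "grid": {k: list(v) if isinstance(v, tuple) else v for k, v in vars(cfg.grid).items()},
        "t2w_feature_csv_sha256": feature_hash,
        "cohort_spec": cfg.cohort_spec.to_jsonable() if cfg.cohort_spec else None,
        "input_dir": cfg.input_dir,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def default_pipeline_config(
    n_per_class: int = 50,
    master_seed: int = 0,
    coarse: bool = True,
    image_types: list[str] | None = None,
    out_dir: str | None = None,
    null: bool = False,
) -> PipelineConfig:
    """Convenience config for a synthetic-cohort run."""
    from .cohort import coarse_grid

    spec = default_cohort_spec(
        n_per_class=n_per_class,
        master_seed=master_seed,
        grid=coarse_grid() if coarse else None,
        null=null,
    )
    return PipelineConfig(
        cohort_spec=spec,
        image_types=image_types,
        master_seed=master_seed,
        out_dir=out_dir,
    )
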