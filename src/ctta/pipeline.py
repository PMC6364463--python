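"""End-to-end orchestration: generate/load -> validate -> filter -> extract
-> compare -> ROC, as one reproducible, logged run.

Outputs written to the run directory:

* ``features.csv``   — one row per subject x phase x filter channel;
* ``table1.csv``     — the full phase x feature x filter comparison grid
  (group means +/- SD, Welch t, raw and BH-adjusted p);
* ``table2.csv``     — ROC results (AUC, Youden cutoff, sensitivity,
  specificity) for the FDR-significant cells;
* ``roc.svg``        — ROC curves for those cells;
* ``provenance.json``— config, seed, software version and every resolved
  paper-silent default (sigma units, filter mode, binning, kurtosis
  convention, superposition rule, test variant);
* ``run.log``        — stage-by-stage log.

Any stage failure aborts with the stage name; partial outputs are flagged by
an ``INVALID`` marker file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import ctta
from ctta.features import HistogramSpec, extract_cohort
from ctta.io import read_manifest, validate_cohort
from ctta.stats import compare_groups, roc_analysis, significant_cells
from ctta.synthetic import PhantomSpec, generate_cohort


@dataclass
class RunConfig:
    """Everything a run needs; exactly one of ``manifest``/``phantom`` is set."""

    out_dir: str | Path
    manifest: str | Path | None = None
    phantom: PhantomSpec | None = None
    null_cohort: bool = False
    seed: int = 0
    n_bins: int = 256
    filter_mode: str = "2d"
    sigma_fine: float = 1.0
    sigma_coarse: float = 2.5
    sigma_units: str = "voxel"
    alpha: float = 0.05
    equal_var: bool = False
    superposition_rule: str = "union"
    force: bool = False  # keep subjects that fail validation
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.phantom is None):
            raise ValueError("exactly one of manifest or phantom must be given")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        phantom = raw.pop("phantom", None)
        if phantom is not None:
            phantom = PhantomSpec(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in phantom.items()
            })
        known = {f.name for f in dataclasses.fields(cls)} - {"phantom", "extra"}
        kwargs = {k: raw.pop(k) for k in list(raw) if k in known}
        return cls(phantom=phantom, extra=raw, **kwargs)


@dataclass
class RunResult:
    out_dir: Path
    features: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame
    failures: pd.DataFrame
    validation: pd.DataFrame


def _provenance(config: RunConfig) -> dict:
    phantom = config.phantom
    return {
        "software": {"name": "ctta", "version": ctta.__version__},
        "seed": config.seed,
        "config": {
            "out_dir": str(config.out_dir),
            "manifest": str(config.manifest) if config.manifest else None,
            "phantom": dataclasses.asdict(phantom) if phantom else None,
            "null_cohort": config.null_cohort,
            "alpha": config.alpha,
        },
        "resolved_defaults": {
            "filter.sigma_fine": config.sigma_fine,
            "filter.sigma_coarse": config.sigma_coarse,
            "filter.mode": config.filter_mode,
            "filter.sigma_units": config.sigma_units,
            "filter.boundary": "reflect",
            "filter.truncate": 6.0,
            "filter.response_normalization": "none",
            "histogram.n_bins": config.n_bins,
            "histogram.range_rule": "per-ROI min-max",
            "entropy.base": 2,
            "kurtosis.convention": "non-excess (Gaussian = 3)",
            "sd.estimator": "sample (n-1)",
            "roi.superposition_rule": config.superposition_rule,
            "stats.test": "pooled Student t" if config.equal_var else "Welch t",
            "stats.sides": "two-sided",
            "stats.fdr": "Benjamini-Hochberg, joint family over all tested cells",
            "roc.cutoff": "Youden J, midpoint-between-observations",
        },
    }


def _plot_roc(features: pd.DataFrame, table2: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from ctta.stats import _cell_values, _roc_points

    fig, ax = plt.subplots(figsize=(5, 5))
    for row in table2.itertuples(index=False):
        low, high = _cell_values(features, row.phase, row.feature, row.filter)
        labels = np.r_[np.zeros(len(low)), np.ones(len(high))]
        scores = np.r_[low, high]
        if row.positive_direction == "high-grade-low-values":
            scores = -scores
        fpr, tpr, auc = _roc_points(labels, scores)
        ax.plot(fpr, tpr, label=f"{row.phase[:6]} {row.feature} ({row.filter}), AUC={auc:.2f}")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def run(config: RunConfig) -> RunResult:
    """Execute the full analysis described by ``config``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    invalid_marker = out_dir / "INVALID"
    invalid_marker.write_text("run in progress\n")

    log = logging.getLogger(f"ctta.run.{id(config)}")
    log.setLevel(logging.INFO)
    log.handlers.clear()
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)

    stage = "setup"
    try:
        prov = _provenance(config)
        (out_dir / "provenance.json").write_text(json.dumps(prov, indent=2) + "\n")
        for key, val in prov["resolved_defaults"].items():
            log.info("default %s = %s", key, val)

        if config.phantom is not None:
            stage = "generate"
            spec = dataclasses.replace(config.phantom, seed=config.seed)
            if config.null_cohort:
                spec = spec.as_null()
            log.info("generating phantom cohort (n=%d+%d, seed=%d, null=%s)",
                     spec.n_low, spec.n_high, spec.seed, config.null_cohort)
            manifest = generate_cohort(spec, out_dir / "cohort")
        else:
            stage = "load"
            manifest = read_manifest(config.manifest)
        log.info("manifest: %d rows", len(manifest))

        stage = "validate"
        validation = validate_cohort(manifest)
        n_fail = int((~validation["passed"]).sum())
        for row in validation[~validation["passed"]].itertuples(index=False):
            log.warning("subject %s failed validation: %s", row.subject_id, row.reasons)
        if n_fail and not config.force:
            ok = set(validation.loc[validation["passed"], "subject_id"])
            manifest = manifest[manifest["subject_id"].isin(ok)]
            log.info("excluded %d failing subjects", n_fail)

        stage = "extract"
        features, failures = extract_cohort(
            manifest,
            HistogramSpec(n_bins=config.n_bins),
            mode=config.filter_mode,
            sigma_fine=config.sigma_fine,
            sigma_coarse=config.sigma_coarse,
            sigma_units=config.sigma_units,
        )
        for row in failures.itertuples(index=False):
            log.warning("extraction failed for %s/%s: %s",
                        row.subject_id, row.phase, row.reason)
        features.to_csv(out_dir / "features.csv", index=False)
        log.info("extracted %d feature records", len(features))

        stage = "compare"
        table1 = compare_groups(features, alpha=config.alpha,
                                equal_var=config.equal_var)
        table1.to_csv(out_dir / "table1.csv", index=False)
        log.info("comparison grid: %d cells, %d significant after FDR",
                 len(table1), int(table1["significant"].sum()))

        stage = "roc"
        selected = significant_cells(table1)
        table2 = roc_analysis(features, selected)
        table2.to_csv(out_dir / "table2.csv", index=False)
        if len(table2):
            _plot_roc(features, table2, out_dir / "roc.svg")
        log.info("ROC analysis: %d cells", len(table2))
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        invalid_marker.write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        handler.close()
        log.removeHandler(handler)

    invalid_marker.unlink()
    return RunResult(out_dir, features, table1, table2, failures, validation)
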