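"""End-to-end pipeline: descriptors -> selection -> split -> train -> validate.

``run_pipeline`` is deterministic for a fixed configuration and writes all
intermediate artifacts (descriptor matrix, contingency scores, split,
model, report) so each stage can be audited; the report embeds the fully
resolved configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import chem_io, contingency, splitting, synthetic, validation
from .bqsar import BQSARParams, fit_binary_qsar
from .chem_io import ActivityConfig, assign_activity_labels, read_compound_table
from .descriptors import DescriptorMatrix, compute_descriptor_matrix

logger = logging.getLogger("binqsar")


@dataclass
class PipelineConfig:
    """Fully resolved pipeline settings; defaults match the canonical protocol for this series
    (threshold 7.0, smooth 0.01, 75% Tanimoto, min cluster 5, 6+10 random
    test compounds, ten random repeats)."""

    input_path: str | None = None
    input_format: str = "smiles_csv"
    synthetic_seed: int | None = None      # use the benchmark_library fixture instead of a file
    descriptor_set: str = "vsa_ind"
    activity_threshold: float = 7.0
    contingency_threshold: float | None = None  # None = no contingency selection
    contingency_bins: int = contingency.DEFAULT_N_BINS
    split_method: str = "diversity"
    sim_threshold: float = splitting.DEFAULT_SIM_THRESHOLD
    min_cluster_size: int = splitting.DEFAULT_MIN_CLUSTER_SIZE
    test_fraction: float = splitting.DEFAULT_TEST_FRACTION
    n_test_active: int = splitting.DEFAULT_N_TEST_ACTIVE
    n_test_inactive: int = splitting.DEFAULT_N_TEST_INACTIVE
    random_seeds: tuple[int, ...] = tuple(range(1, 11))
    smooth: float = 0.01
    decision_threshold: float = 0.5
    out_dir: str = "binqsar_out"

    def bqsar_params(self) -> BQSARParams:
        return BQSARParams(smooth=self.smooth, decision_threshold=self.decision_threshold)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full workflow and return the report dictionary.

    Writes ``matrix.csv``, ``scores.csv`` (when contingency selection is
    on), ``split.json``, ``model.json`` and ``report.json`` into
    ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- load or simulate compounds ---------------------------------------
    if cfg.synthetic_seed is not None:
        logger.info("generating benchmark_library synthetic library (seed %d)", cfg.synthetic_seed)
        records, y = synthetic.benchmark_dataset(
            seed=cfg.synthetic_seed, threshold=cfg.activity_threshold
        )
    else:
        if cfg.input_path is None:
            raise ValueError("either input_path or synthetic_seed must be set")
        records, report = read_compound_table(cfg.input_path, cfg.input_format)
        for idx, reason in report.failures:
            logger.warning("input record %d skipped: %s", idx, reason)
        records, counts = assign_activity_labels(
            records, ActivityConfig(cfg.activity_threshold)
        )
        logger.info("labelled %(active)d active / %(inactive)d inactive", counts)
        y = np.array(chem_io.labels_to_binary(records))

    # --- descriptors -------------------------------------------------------
    matrix = compute_descriptor_matrix(records, cfg.descriptor_set)
    matrix.to_csv(out / "matrix.csv")
    logger.info("descriptor matrix: %d x %d (%s)", *matrix.frame.shape, cfg.descriptor_set)

    # --- contingency selection ---------------------------------------------
    if cfg.contingency_threshold is not None:
        names, scores = contingency.select_descriptors(
            matrix, y, cfg.contingency_threshold, cfg.contingency_bins
        )
        scores.to_csv(out / "scores.csv", index=False)
        if not names:
            raise RuntimeError("contingency selection rejected every descriptor")
        matrix = DescriptorMatrix(frame=matrix.frame[names], set_tag="contingency_selected")
        logger.info("contingency selected %d descriptors: %s", len(names), ", ".join(names))

    X = matrix.values
    params = cfg.bqsar_params()

    # --- split + validate ---------------------------------------------------
    report: dict = {"config": _config_dict(cfg), "n_compounds": len(records),
                    "n_active": int(y.sum()), "n_inactive": int(len(y) - y.sum())}
    if cfg.split_method == "diversity":
        fps = [splitting.maccs_fingerprint(r.mol) for r in records]
        clusters = splitting.cluster_fingerprints(fps, cfg.sim_threshold)
        split = splitting.diversity_split(
            clusters, y, cfg.min_cluster_size, cfg.test_fraction
        )
        _write_json(out / "split.json", split.to_dict())
        vr = validation.evaluate_split(split, X, y, params)
        report["diversity"] = vr.to_dict()
        report["diversity"]["split"] = split.class_counts
    elif cfg.split_method == "random":
        per_seed = []
        reports = []
        for seed in cfg.random_seeds:
            split = splitting.random_split(
                y, cfg.n_test_active, cfg.n_test_inactive, seed=seed
            )
            vr = validation.evaluate_split(split, X, y, params)
            reports.append(vr)
            per_seed.append({"seed": seed, **vr.to_dict()})
        _write_json(out / "split.json", {"seeds": list(cfg.random_seeds)})
        report["random"] = {
            "per_seed": per_seed,
            "aggregate": validation.aggregate_reports(reports),
        }
    else:
        raise ValueError(f"unknown split method {cfg.split_method!r}")

    # --- final model on everything ------------------------------------------
    model = fit_binary_qsar(X, y, params, columns=matrix.names)
    chem_io.write_model(model, out / "model.json")
    _write_json(out / "report.json", report)
    logger.info("pipeline complete; artifacts in %s", out)
    return report


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["random_seeds"] = list(cfg.random_seeds)
    return d


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")
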