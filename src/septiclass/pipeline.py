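"""End-to-end study orchestration and file contracts.

Binds the stages together — simulate a three-cohort study, optionally
route it through raw-curve quantification, screen markers, then run the
random-partition / permutation-null evaluation for the four pairwise
cohort comparisons at the full and reduced panel sizes — writing every
intermediate artifact as TSV/JSON with the resolved root seed recorded.

File contracts (all TSV with header rows, all results JSON):

* expression matrix: first column ``sample_id``, remaining columns markers;
* sample metadata: ``sample_id``, ``cohort``;
* curve table (long): ``well_id``, ``marker_id``, ``role``, ``sample_id``,
  ``cycle``, ``fluorescence``;
* evaluation result JSON: comparison, panel size, full observed and null
  AUC samples, mean/SD/p, seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import quantification, screening
from .evaluation import (
    ClassifierConfig,
    EvaluationResult,
    PartitionScheme,
    evaluate_comparison,
    summarize_table,
)
from .synthetic import (
    AmplificationCurve,
    CohortDesign,
    CurveModel,
    EffectModel,
    PanelSpec,
    WellRole,
    WellSpec,
    generate_cohort_design,
    simulate_amplification_curves,
    simulate_expression,
)

__all__ = [
    "RunConfig",
    "run_study",
    "comparison_labels",
    "COMPARISONS",
    "write_matrix",
    "read_matrix",
    "write_metadata",
    "read_metadata",
    "write_curves",
    "read_curves",
    "write_result",
    "read_result",
]

logger = logging.getLogger("septiclass")

#: The four pairwise cohort comparisons reported by the study, as
#: (label, positive cohorts, negative cohorts).
COMPARISONS: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...] = (
    ("MI Vs HC", ("PS", "SEPSIS"), ("HC",)),
    ("Sepsis Vs HC", ("SEPSIS",), ("HC",)),
    ("PS Vs HC", ("PS",), ("HC",)),
    ("Sepsis Vs PS", ("SEPSIS",), ("PS",)),
)


@dataclass(frozen=True)
class RunConfig:
    """Single-document configuration for a full study run."""

    # cohort sizes
    n_hc: int = 20
    n_ps: int = 38
    n_sepsis: int = 27
    # panel
    n_markers: int = 42
    n_normalizers: int = 3
    subset_size: int = 7
    # effect model (log2 fold-change scale)
    n_informative: int = 20
    sepsis_vs_ps_shift: float = 0.75
    mi_vs_hc_shift: float = 1.5
    noise_sd: float = 1.0
    # optional raw-curve simulation + quantification stage
    simulate_curves: bool = False
    reference_takeoff: float = 24.0
    curve_slope: float = 0.6
    curve_f_max: float = 100.0
    curve_baseline: float = 2.0
    curve_noise_sd: float = 0.0
    curve_n_cycles: int = 40
    efficiency: float = 2.0
    # classifier
    boosting_iterations: int = 50
    z_max: float = 4.0
    # partition scheme
    n_partitions: int = 500
    train_fraction: float = 2.0 / 3.0
    stratified: bool = True
    # provenance
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        obj = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)


# ---------------------------------------------------------------------------
# file contracts


def write_matrix(matrix: pd.DataFrame, path: Path | str) -> None:
    out = matrix.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_matrix(path: Path | str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    return frame.set_index("sample_id")


def write_metadata(design: CohortDesign, path: Path | str) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_metadata(path: Path | str) -> CohortDesign:
    return CohortDesign.from_frame(pd.read_csv(path, sep="\t"))


def write_curves(curves: list[AmplificationCurve], path: Path | str) -> None:
    rows = []
    for c in curves:
        for cycle, fluo in zip(c.cycles, c.fluorescence):
            rows.append(
                {
                    "well_id": c.well_id,
                    "marker_id": c.marker_id,
                    "role": c.role.value,
                    "sample_id": c.sample_id if c.sample_id is not None else "",
                    "cycle": cycle,
                    "fluorescence": fluo,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_curves(path: Path | str) -> list[AmplificationCurve]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    curves = []
    for well_id, grp in frame.groupby("well_id", sort=False):
        grp = grp.sort_values("cycle")
        curves.append(
            AmplificationCurve(
                well_id=str(well_id),
                marker_id=str(grp["marker_id"].iloc[0]),
                role=WellRole(grp["role"].iloc[0]),
                sample_id=str(grp["sample_id"].iloc[0]) or None,
                cycles=grp["cycle"].to_numpy(dtype=float),
                fluorescence=grp["fluorescence"].to_numpy(dtype=float),
            )
        )
    return curves


def write_result(result: EvaluationResult, path: Path | str) -> None:
    obj = {
        "comparison": result.comparison,
        "panel_size": result.panel_size,
        "seed": result.seed,
        "aucs": None if result.aucs is None else [float(a) for a in result.aucs],
        "null_aucs": None
        if result.null_aucs is None
        else [float(a) for a in result.null_aucs],
    }
    if result.aucs is not None:
        obj["mean_auc"] = result.mean_auc
        obj["sd_auc"] = result.sd_auc
    if result.null_aucs is not None:
        obj["null_mean"] = result.null_mean
    if result.aucs is not None and result.null_aucs is not None:
        obj["p_value"] = result.p_value
    Path(path).write_text(json.dumps(obj, indent=1))


def read_result(path: Path | str) -> EvaluationResult:
    obj = json.loads(Path(path).read_text())
    return EvaluationResult(
        comparison=obj["comparison"],
        panel_size=int(obj["panel_size"]),
        seed=obj.get("seed"),
        aucs=None if obj["aucs"] is None else np.array(obj["aucs"]),
        null_aucs=None if obj["null_aucs"] is None else np.array(obj["null_aucs"]),
    )


# ---------------------------------------------------------------------------
# orchestration


def comparison_labels(
    design: CohortDesign, positive: tuple[str, ...], negative: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Row mask and 0/1 labels for one pairwise cohort comparison."""
    cohorts = design.labels()
    pos = np.isin(cohorts, list(positive))
    neg = np.isin(cohorts, list(negative))
    mask = pos | neg
    return mask, pos[mask].astype(int)


def _derived_seed(root: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(root), *key]).generate_state(1)[0] & 0x7FFFFFFF)


def _simulate_plate(
    design: CohortDesign,
    panel: PanelSpec,
    matrix: pd.DataFrame,
    config: RunConfig,
) -> tuple[list[AmplificationCurve], dict[str, float], CurveModel]:
    """Raw traces realizing the simulated log2 fold changes.

    With efficiency 2, a log2 fold change L on a marker corresponds to a
    take-off L cycles earlier than the reference, so the sample take-off
    is reference_takeoff - L; normalization markers share the reference
    take-off (loading is identical by construction).
    """
    model = CurveModel(
        f_max=config.curve_f_max,
        slope=config.curve_slope,
        baseline=config.curve_baseline,
        noise_sd=config.curve_noise_sd,
        n_cycles=config.curve_n_cycles,
        efficiency=config.efficiency,
    )
    wells: list[WellSpec] = []
    ref = config.reference_takeoff
    for sid in design.sample_ids:
        for marker in panel.marker_ids:
            wells.append(
                WellSpec(
                    well_id=f"{sid}:{marker}",
                    marker_id=marker,
                    role=WellRole.TARGET,
                    takeoff=ref - float(matrix.loc[sid, marker]),
                    sample_id=sid,
                )
            )
        for norm in panel.normalizer_ids:
            wells.append(
                WellSpec(
                    well_id=f"{sid}:{norm}",
                    marker_id=norm,
                    role=WellRole.NORMALIZER,
                    takeoff=ref,
                    sample_id=sid,
                )
            )
    for i in range(1, 6):
        wells.append(WellSpec(f"NEG{i}", "CTRL", WellRole.NEGATIVE_CONTROL))
        wells.append(WellSpec(f"POS{i}", "CTRL", WellRole.POSITIVE_CONTROL, takeoff=ref))
    curves = simulate_amplification_curves(
        wells, model, seed=_derived_seed(config.seed, 2)
    )
    reference_takeoffs = {m: ref for m in (*panel.marker_ids, *panel.normalizer_ids)}
    return curves, reference_takeoffs, model


def _quantify_plate(
    curves: list[AmplificationCurve],
    reference_takeoffs: dict[str, float],
    panel: PanelSpec,
    design: CohortDesign,
    efficiency: float,
) -> tuple[pd.DataFrame, quantification.PlateQC]:
    qc = quantification.plate_qc(curves)
    by_sample: dict[str, list[AmplificationCurve]] = {}
    for c in curves:
        if c.sample_id is not None:
            by_sample.setdefault(c.sample_id, []).append(c)
    rows = {}
    for sid in design.sample_ids:
        results = quantification.quantify_sample(
            by_sample[sid],
            reference_takeoffs,
            panel,
            sample_id=sid,
            efficiencies=efficiency,
            qc=qc,
        )
        rows[sid] = {r.marker_id: r.log2_fold_change for r in results}
    matrix = pd.DataFrame.from_dict(rows, orient="index")[list(panel.marker_ids)]
    matrix.index.name = None
    return matrix, qc


def run_study(config: RunConfig, out_dir: Path | str) -> dict:
    """Execute the full study replica and write all artifacts.

    Stages: simulate expression (and optionally raw curves, which are then
    quantified back into the working matrix) -> moderated-t screening of
    inflamed vs healthy -> repeated-partition + permutation-null
    evaluation of the four cohort comparisons at the full panel and a
    seeded random sub-panel.  Returns the evaluation results and paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    design = generate_cohort_design(config.n_hc, config.n_ps, config.n_sepsis)
    panel = PanelSpec.default(config.n_markers, config.n_normalizers)
    effects = EffectModel.default(
        panel,
        n_informative=config.n_informative,
        sepsis_vs_ps=config.sepsis_vs_ps_shift,
        mi_vs_hc=config.mi_vs_hc_shift,
        sigma=config.noise_sd,
    )
    matrix = simulate_expression(design, panel, effects, seed=_derived_seed(config.seed, 1))
    logger.info(
        "simulate: %d samples × %d markers (seed %d)", len(design), panel.n_markers, config.seed
    )

    (out / "config.json").write_text(config.to_json())
    write_metadata(design, out / "metadata.tsv")
    write_matrix(matrix, out / "expression.tsv")

    qc = None
    if config.simulate_curves:
        curves, reference_takeoffs, _ = _simulate_plate(design, panel, matrix, config)
        write_curves(curves, out / "curves.tsv")
        matrix, qc = _quantify_plate(
            curves, reference_takeoffs, panel, design, config.efficiency
        )
        write_matrix(matrix, out / "expression_quantified.tsv")
        (out / "plate_qc.json").write_text(
            json.dumps(dataclasses.asdict(qc), indent=1)
        )
        logger.info("quantify: plate QC passed=%s", qc.passed)

    mi = design.mi_mask()
    screen_tbl = screening.moderated_t(matrix, mi)
    screen_tbl.to_csv(out / "screening.tsv", sep="\t")
    logger.info("screen: %d markers tested (MI vs HC)", len(screen_tbl))

    rng = np.random.default_rng(_derived_seed(config.seed, 3))
    subset = sorted(
        rng.choice(list(panel.marker_ids), size=config.subset_size, replace=False)
    )

    clf = ClassifierConfig(M=config.boosting_iterations, z_max=config.z_max)
    results: list[EvaluationResult] = []
    for idx, (label, positive, negative) in enumerate(COMPARISONS):
        mask, y = comparison_labels(design, positive, negative)
        X_cmp = matrix.loc[mask]
        for panel_markers in (list(panel.marker_ids), subset):
            scheme = PartitionScheme(
                n_iterations=config.n_partitions,
                train_fraction=config.train_fraction,
                stratified=config.stratified,
                seed=_derived_seed(config.seed, 4, idx, len(panel_markers)),
            )
            res = evaluate_comparison(
                X_cmp[panel_markers], y, scheme, clf, comparison=label
            )
            results.append(res)
            fname = f"result_{label.replace(' ', '_')}_{len(panel_markers)}.json"
            write_result(res, out / fname)
            logger.info(
                "evaluate: %s, %d markers: mean AUC %.3f (B=%d)",
                label,
                len(panel_markers),
                res.mean_auc,
                scheme.n_iterations,
            )

    table = summarize_table(results)
    table.to_csv(out / "table.tsv", sep="\t", index=False)
    (out / "run.log").write_text(
        "\n".join(
            [
                f"seed\t{config.seed}",
                f"samples\t{len(design)}",
                f"markers\t{panel.n_markers}",
                f"subset\t{','.join(subset)}",
                f"partitions\t{config.n_partitions}",
                f"plate_qc_passed\t{qc.passed if qc is not None else 'not run'}",
            ]
        )
        + "\n"
    )
    return {"design": design, "matrix": matrix, "results": results, "table": table, "subset": subset}
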