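"""End-to-end orchestration of the synthetic sticky-trap study.

Stage order: simulate -> detect -> landscape -> diversity -> ordination ->
fit.  Each stage consumes the previous stage's artifacts, every stochastic
stage gets its own child seed derived from the global seed (so toggling one
stage never shifts another stage's random stream), and all tabular outputs
are CSV with a JSON manifest recording the parameter hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect as _detect
from . import divstat, fitstat, io, landcov, ordin, synthio

__all__ = ["RunConfig", "ResultBundle", "run", "demo_config", "validate_against_deposit"]

_STAGES = ("simulate", "detect", "landscape", "diversity", "ordination", "fit")
_STAGE_IDS = {name: i + 1 for i, name in enumerate(_STAGES)}


@dataclass
class RunConfig:
    """All stage parameters for one pipeline run."""

    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    design: synthio.DesignConfig = field(default_factory=synthio.study_config)
    effects: synthio.CommunityEffects = field(default_factory=synthio.default_effects)
    error_model: synthio.DetectionErrorModel = field(
        default_factory=synthio.default_error_model
    )
    abundance_scale: float = 1.0  # multiplies expected counts (demo downscaling)
    counts_path: str | None = None  # supply counts directly, skipping simulate/detect
    traps_path: str | None = None
    n_folds: int = 5
    iou_threshold: float = 0.5
    min_training: int = 30
    radius: float = 100.0
    subset_size: int = 99
    n_rand: int = 9999
    k_grid: tuple[int, ...] = tuple(range(1, 21))

    def validate(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages:
            if self.counts_path is None or self.traps_path is None:
                raise ValueError(
                    "without the simulate stage, counts_path and traps_path are required"
                )
            for p in (self.counts_path, self.traps_path):
                if not Path(p).exists():
                    raise FileNotFoundError(p)

    def parameter_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    """Manifest, per-stage outputs and run log of one pipeline run."""

    manifest: dict
    outputs: dict
    log: list[dict]


def demo_config(out_dir: str, seed: int = 0) -> RunConfig:
    """A reduced-size configuration that completes quickly on one CPU.

    Keeps the 236-trap design and effect sizes but scales expected abundance
    down and shrinks the randomization/knot grids.
    """
    return RunConfig(
        out_dir=out_dir,
        seed=seed,
        abundance_scale=0.12,
        n_rand=199,
        subset_size=60,
        k_grid=(1, 3, 5, 8, 12),
    )


def _stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(global_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def run(config: RunConfig) -> ResultBundle:
    """Execute the configured stages in dependency order.

    A failed stage raises immediately (halting downstream stages); re-running
    with an identical config and seed reproduces all outputs bit-for-bit
    except the log timestamps.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    outputs: dict = {}

    def note(stage: str, **info):
        log.append({"t": time.time(), "stage": stage, **info})

    traps = counts = forest = None
    lifecycles = dict(config.effects.taxa)

    if "simulate" in config.stages:
        seed = _stage_seed(config.seed, "simulate")
        traps = synthio.generate_design(config.design)
        raster = synthio.raster_for_design(traps, seed=seed)
        landcov.write_ascii_grid(raster, out / "landcover.asc")
        cover = landcov.batch_cover(raster, traps, radius=config.radius)
        forest = cover.set_index("trap_id")["forest_cover"]
        effects = config.effects
        if config.abundance_scale != 1.0:
            effects = dataclasses.replace(
                effects,
                intercepts={
                    k: v + float(np.log(config.abundance_scale))
                    for k, v in effects.intercepts.items()
                },
            )
        counts = synthio.generate_counts(traps, forest, effects, seed=seed + 1)
        truths, image_ids = synthio.generate_truth_boxes(
            counts, forest, effects, seed=seed + 2
        )
        detections, _prov = synthio.generate_detections(
            truths, image_ids, config.error_model, n_folds=config.n_folds, seed=seed + 3
        )
        traps.to_csv(out / "traps.csv", index=False)
        io.write_counts(counts, out / "counts_true.csv")
        io.write_coco(truths, out / "truth.json", synthio.IMAGE_SIZE, image_ids)
        io.write_coco(detections, out / "detections.json", synthio.IMAGE_SIZE, image_ids)
        outputs["simulate"] = {
            "traps": str(out / "traps.csv"),
            "counts_true": str(out / "counts_true.csv"),
            "truth": str(out / "truth.json"),
            "detections": str(out / "detections.json"),
        }
        note("simulate", n_traps=len(traps), n_truth=len(truths), n_detections=len(detections))
    else:
        traps = io.read_traps(config.traps_path)
        counts = io.read_counts(config.counts_path)
        note("simulate", skipped=True)

    if "detect" in config.stages:
        if "simulate" not in config.stages:
            raise RuntimeError("detect stage requires the simulate stage's detections")
        calibrations, curves = _detect.calibrate(
            detections, truths, n_folds=config.n_folds, iou_match=config.iou_threshold
        )
        training_counts = pd.Series([t.class_label for t in truths]).value_counts().to_dict()
        calibrations = _detect.apply_exclusions(
            calibrations,
            training_counts,
            {c: True for c in calibrations},
            min_training=config.min_training,
        )
        thresholded = _detect.apply_thresholds(detections, calibrations)
        by_side: dict[tuple[str, str], list] = {}
        for d in thresholded:
            by_side.setdefault((d.image_id, d.side), []).append(d)
        merged = []
        for key in sorted(by_side):
            merged.extend(_detect.merge_folds(by_side[key], config.iou_threshold))
        image_to_trap = {im: im.rsplit("_", 1)[0] for im in image_ids}
        trait = _detect.build_trait_table(merged, image_to_trap)
        cal_rows = [
            {
                "class": c.class_label,
                "n_training": c.n_training_annotations,
                "retained": c.retained,
                "exclusion_reason": c.exclusion_reason,
                **{f"threshold_fold_{f}": t for f, t in sorted(c.fold_thresholds.items())},
            }
            for c in calibrations.values()
        ]
        pd.DataFrame(cal_rows).to_csv(out / "calibration.csv", index=False)
        trait.to_csv(out / "trait_table.csv", index=False)
        io.write_coco(merged, out / "merged.json", synthio.IMAGE_SIZE, image_ids)
        # trap x taxon abundance matrix from the detection pipeline
        counts = (
            trait.pivot_table(index="trap_id", columns="taxon", values="abundance",
                              fill_value=0, aggfunc="sum")
            .reindex(traps["trap_id"], fill_value=0)
            .astype(int)
        )
        counts.index.name = "trap_id"
        io.write_counts(counts, out / "counts_detected.csv")
        outputs["detect"] = {
            "calibration": str(out / "calibration.csv"),
            "merged": str(out / "merged.json"),
            "trait_table": str(out / "trait_table.csv"),
            "counts": str(out / "counts_detected.csv"),
        }
        note("detect", n_merged=len(merged),
             n_retained_classes=sum(c.retained for c in calibrations.values()))
    else:
        note("detect", skipped=True)

    if "landscape" in config.stages:
        if forest is None:
            raster = landcov.read_ascii_grid(out / "landcover.asc") \
                if (out / "landcover.asc").exists() else None
            if raster is None:
                raise RuntimeError("landscape stage requires a raster (run simulate)")
            cover = landcov.batch_cover(raster, traps, radius=config.radius)
            forest = cover.set_index("trap_id")["forest_cover"]
        cover_df = forest.rename("forest_cover").reset_index()
        cover_df.to_csv(out / "forest_cover.csv", index=False)
        outputs["landscape"] = {"forest_cover": str(out / "forest_cover.csv")}
        note("landscape", mean_cover=float(forest.mean()))

    analysis_rows = None
    if "diversity" in config.stages:
        seed = _stage_seed(config.seed, "diversity")
        included = divstat.filter_traps(counts)
        filtered = counts.loc[included]
        n_ref = divstat.reference_subsample_size(filtered, prefilter=False)
        parts = []
        for group in ("terrestrial", "aquatic"):
            cols = [c for c in counts.columns if lifecycles.get(c) == group]
            sub = filtered[cols]
            sub = sub.loc[sub.sum(axis=1) >= n_ref]
            if sub.empty:
                continue
            comp = divstat.partition_diversity(sub, n_ref=n_ref)
            comp["lifecycle"] = group
            parts.append(comp.reset_index())
        components = pd.concat(parts, ignore_index=True)
        components.to_csv(out / "diversity_components.csv", index=False)
        beta_rows = []
        beta_results = {}
        for group in ("terrestrial", "aquatic"):
            try:
                res = divstat.beta_C_distribution(
                    counts, lifecycles, group,
                    subset_size=config.subset_size, n_rand=config.n_rand, seed=seed,
                )
            except ValueError as exc:
                note("diversity", group=group, beta_c_skipped=str(exc))
                continue
            beta_results[group] = res
            beta_rows.append(
                {"group": group, "mc": res.mc, "c_target": res.c_target,
                 "mean": res.mean, "sd": res.sd, "n_rand": res.n_randomizations}
            )
            pd.DataFrame({"beta_c": res.beta_values}).to_csv(
                out / f"beta_c_{group}.csv", index=False
            )
        pd.DataFrame(beta_rows).to_csv(out / "beta_c_summary.csv", index=False)
        outputs["diversity"] = {
            "components": str(out / "diversity_components.csv"),
            "beta_c_summary": str(out / "beta_c_summary.csv"),
            "n_ref": n_ref,
        }
        note("diversity", n_ref=n_ref, n_included=len(included),
             beta_means={g: r.mean for g, r in beta_results.items()})
        analysis_rows = components

    scores = {}
    if "ordination" in config.stages:
        included = divstat.filter_traps(counts)
        filtered = counts.loc[included]
        for metric, fn in (("abundance", ordin.bray_curtis), ("occurrence", ordin.jaccard)):
            dist = fn(filtered)
            ordd = ordin.pcoa(dist)
            ax1 = ordin.axis1_scores(ordd, filtered, lifecycles)
            scores[metric] = ax1
            ordd.scores.to_csv(out / f"pcoa_{metric}_scores.csv")
        pd.DataFrame(scores).to_csv(out / "composition_axis1.csv")
        outputs["ordination"] = {"axis1": str(out / "composition_axis1.csv")}
        note("ordination", metrics=list(scores))

    if "fit" in config.stages:
        if analysis_rows is None or forest is None:
            raise RuntimeError("fit stage requires diversity and landscape outputs")
        xy = traps.set_index("trap_id")[["x", "y"]]
        table = analysis_rows.merge(
            forest.rename("forest_cover"), left_on="trap_id", right_index=True
        ).merge(xy, left_on="trap_id", right_index=True)
        fits = {}
        for response in ("sad_component", "n_component"):
            spec = fitstat.ModelSpec(response=response, group="lifecycle",
                                     family="gaussian")
            fit = fitstat.select_k(table, spec, k_grid=config.k_grid)
            mi = fitstat.morans_i(fit.residuals, table[["x", "y"]].to_numpy())
            fits[response] = _fit_summary(fit, mi)
        for metric, ax1 in scores.items():
            comp = ax1.rename("axis1").reset_index().rename(columns={"index": "trap_id"})
            comp = comp.merge(forest.rename("forest_cover"), left_on="trap_id",
                              right_index=True)
            comp = comp.merge(xy, left_on="trap_id", right_index=True)
            spec = fitstat.ModelSpec(response="axis1", family="gaussian")
            fit = fitstat.select_k(comp, spec, k_grid=config.k_grid)
            mi = fitstat.morans_i(fit.residuals, comp[["x", "y"]].to_numpy())
            fits[f"composition_{metric}"] = _fit_summary(fit, mi)
        with open(out / "model_summaries.json", "w") as fh:
            json.dump(fits, fh, indent=1)
        outputs["fit"] = {"model_summaries": str(out / "model_summaries.json")}
        note("fit", responses=list(fits))

    manifest = {
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "stages": list(config.stages),
        "outputs": outputs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    with open(out / "log.jsonl", "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry, default=str) + "\n")
    return ResultBundle(manifest=manifest, outputs=outputs, log=log)


def _fit_summary(fit, moran) -> dict:
    return {
        "family": fit.spec.family,
        "k_requested": fit.spec.k,
        "k_used": fit.k_used,
        "edf": fit.edf,
        "aic": fit.aic,
        "deviance_explained_pct": fit.deviance_explained,
        "coefficients": {
            name: {
                "estimate": float(fit.params[name]),
                "se": float(fit.se[name]),
                "statistic": float(fit.statistics[name]),
                "p": float(fit.pvalues[name]),
            }
            for name in fit.params.index
            if not name.startswith("s(x,y)")
        },
        "moran_i": {"i": moran.i, "expected": moran.expected, "p": moran.p},
    }


# Expected summary statistics documented for the deposited Balbina dataset;
# used only to report deltas when the user supplies the deposit locally.
DEPOSIT_REFERENCE = {
    "total_individuals": 22471,
    "top_taxon_share_pct": 68.51,
    "min_trap_abundance": 4,
}


def validate_against_deposit(
    counts_csv: str | None = None,
    reference: dict | None = None,
) -> dict:
    """Recompute headline statistics from a locally supplied data deposit.

    The deposit is never fetched automatically.  When ``counts_csv`` is
    missing or absent on disk the validation is skipped cleanly.  The counts
    file must be a trap x taxon CSV with a ``trap_id`` column.
    """
    reference = dict(DEPOSIT_REFERENCE if reference is None else reference)
    if counts_csv is None or not Path(counts_csv).exists():
        return {"status": "skipped", "message": "deposit not supplied; nothing validated"}
    try:
        counts = io.read_counts(counts_csv)
    except (ValueError, KeyError) as exc:
        return {
            "status": "error",
            "message": f"schema mismatch: {exc}; expected a trap x taxon CSV "
            "with a trap_id index column",
        }
    numeric = counts.select_dtypes("number")
    total = int(numeric.to_numpy().sum())
    taxon_totals = numeric.sum(axis=0)
    top = taxon_totals.idxmax()
    top_share = float(100.0 * taxon_totals.max() / total) if total else float("nan")
    trap_totals = numeric.sum(axis=1)
    report = {
        "status": "ok",
        "total_individuals": total,
        "top_taxon": str(top),
        "top_taxon_share_pct": top_share,
        "min_trap_abundance": int(trap_totals[trap_totals > 0].min()) if total else 0,
    }
    for key, ref in reference.items():
        if key in report:
            report[f"delta_{key}"] = float(report[key]) - float(ref)
    return report
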