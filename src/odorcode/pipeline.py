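"""End-to-end pipeline orchestration.

Runs the stages in method order — synthesis (optional), respiration,
response metrics, population correlations, decoding, latency-mixture
fitting, slopes — logging each stage's parameters and seed, and writes a
manifest of output files with content hashes so that determinism can be
checked by hash equality.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import decode, latmix, metrics, popgeom, slopes, synth
from .io import Dataset, PipelineConfig, write_manifest, write_table

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""


def _stage(name):
    def wrap(fn):
        def inner(ctx, *a, **kw):
            t0 = time.perf_counter()
            logger.info("stage %s: start (seed=%s)", name, ctx["seed"])
            try:
                fn(ctx, *a, **kw)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.1fs", name,
                        time.perf_counter() - t0)
        return inner
    return wrap


@_stage("synth")
def _run_synth(ctx):
    cfg = synth.SyntheticConfig(**ctx["config"].synth)
    if "seed" not in ctx["config"].synth:
        cfg.seed = ctx["seed"]
    ds = synth.generate_dataset(cfg)
    ds.save(ctx["outdir"])
    (ctx["outdir"] / "synth_config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=2, default=str))
    ctx["dataset"] = ds


@_stage("respiration")
def _run_respiration(ctx):
    ds: Dataset = ctx["dataset"]
    if ds.inhalation_onsets is None:
        logger.info("no breath events available; using fixed windows")
        return
    ev = pd.DataFrame({
        "onset_type": ["inhalation"] * len(ds.inhalation_onsets),
        "time_s": ds.inhalation_onsets})
    write_table(ev, ctx["outdir"] / "breath_events.csv")


@_stage("metrics")
def _run_metrics(ctx):
    ds = ctx["dataset"]
    cfg = metrics.PSTHConfig(**ctx["config"].psth)
    stats = metrics.response_stats_table(ds, alpha=ctx["config"].alpha,
                                         config=cfg)
    write_table(stats, ctx["outdir"] / "response_stats.csv")
    nominal = ctx["nominal"]
    classes = metrics.classify_polarity(stats, nominal, ctx["config"].alpha)
    write_table(classes, ctx["outdir"] / "cell_classes.csv")
    sl = metrics.lifetime_sparseness_table(stats, nominal)
    write_table(sl, ctx["outdir"] / "tuning.csv")
    ctx["stats"] = stats


@_stage("popgeom")
def _run_popgeom(ctx):
    counts, info = popgeom.build_vectors(ctx["dataset"], region="PCx")
    corr = popgeom.correlation_by_condition(counts, info)
    write_table(corr, ctx["outdir"] / "correlations.csv")


@_stage("decode")
def _run_decode(ctx):
    ds = ctx["dataset"]
    opts = dict(ctx["config"].decode)
    sizes = opts.pop("population_sizes", [25, 100])
    n_perm = opts.pop("n_permutations", 20)
    frames = []
    for scheme in decode.SCHEMES:
        feats = decode.encode(
            ds, decode.EncodingConfig(
                scheme=scheme, **ctx["config"].encoding), region="PCx")
        for task in decode.TASKS:
            res = decode.run_task(
                feats, task, sizes, n_permutations=n_perm,
                seed=ctx["seed"], nominal_concentration=ctx["nominal"])
            frames.append(res.to_frame())
    df = pd.concat(frames, ignore_index=True)
    write_table(df, ctx["outdir"] / "decode_results.csv")
    summary = df.groupby(["task", "scheme"])["mean_accuracy"].max()
    (ctx["outdir"] / "decode_summary.json").write_text(
        json.dumps({f"{t}/{s}": v for (t, s), v in summary.items()},
                   indent=2, sort_keys=True))


@_stage("latmix")
def _run_latmix(ctx):
    ds = ctx["dataset"]
    stats = ctx.get("stats")
    if stats is None:
        stats = metrics.response_stats_table(ds, alpha=ctx["config"].alpha)
    samples = latmix.latency_samples(stats, ds.units)
    opts = dict(ctx["config"].mixture)
    k = opts.pop("k", 3)
    n_boot = opts.pop("n_boot", 0)
    out = {}
    for region in sorted({r for r, _ in samples}):
        by_conc = {c: v for (r, c), v in samples.items()
                   if r == region and len(v) >= 5 * k}
        if len(by_conc) < 2:
            continue
        summary = latmix.two_phase_summary(by_conc, k=k, n_boot=n_boot,
                                           seed=ctx["seed"], **opts)
        out[region] = summary.to_dict(orient="records")
    (ctx["outdir"] / "mixture_fits.json").write_text(
        json.dumps(out, indent=2, default=float))


@_stage("slopes")
def _run_slopes(ctx):
    df = slopes.slopes_table(ctx["dataset"])
    write_table(df, ctx["outdir"] / "slopes.csv")
    if len(df):
        by_region = {r: grp["slope"].to_numpy()
                     for r, grp in df.groupby("region")}
        if {"OB", "PCx"} <= set(by_region) and \
                min(len(v) for v in by_region.values()) >= 2:
            cmp = slopes.compare_regions(by_region["OB"], by_region["PCx"])
            (ctx["outdir"] / "slope_comparison.json").write_text(
                json.dumps(cmp, indent=2))


_STAGES = {
    "synth": _run_synth,
    "respiration": _run_respiration,
    "metrics": _run_metrics,
    "popgeom": _run_popgeom,
    "decode": _run_decode,
    "latmix": _run_latmix,
    "slopes": _run_slopes,
}


def run_pipeline(config: PipelineConfig,
                 dataset: Dataset | None = None) -> Path:
    """Execute the configured stages in order and return the output dir.

    When ``dataset`` is given (or the ``synth`` stage is disabled and
    canonical tables exist in ``config.outdir``), synthesis is skipped.
    Every stage derives its randomness from ``config.seed``; two runs
    with identical config produce identical manifests.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nominal = config.synth.get("nominal_concentration", 0.003)
    ctx = {"config": config, "outdir": outdir, "seed": config.seed,
           "nominal": nominal, "dataset": dataset}
    stages = list(config.stages)
    if dataset is not None and "synth" in stages:
        stages.remove("synth")
    if ctx["dataset"] is None and "synth" not in stages:
        ctx["dataset"] = Dataset.load(outdir)
    for name in stages:
        if name not in _STAGES:
            raise StageError(f"unknown stage {name!r}")
        _STAGES[name](ctx)
    # normalize the run-specific output path so manifests of identical
    # runs hash identically
    emitted = dataclasses.replace(config, outdir=".")
    emitted.to_yaml(outdir / "pipeline_config.yaml")
    write_manifest(outdir, {"seed": config.seed})
    return outdir
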