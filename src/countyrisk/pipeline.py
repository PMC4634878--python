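"""End-to-end pipeline: records -> counts -> posteriors -> tables.

Every artifact written embeds the configuration digest and seed in a
leading comment line, so any output directory is self-describing and two
runs with the same configuration are identical in all deterministic
outputs (and in posterior summaries at a fixed seed).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .hierarchical import PosteriorDraws, ShootingRateModel
from .ratios import (
    RESULTS_RATIO_FAMILIES,
    RatioSpec,
    county_ratio_draws,
    ratio_table,
)
from .records import (
    aggregate_counts,
    clean_records,
    deduplicate,
    read_census,
    read_covariates,
    read_records,
)
from .regression import regression_table, summarize_log_rr

__all__ = ["parse_ratio_spec", "run_pipeline", "write_csv"]

logger = logging.getLogger("countyrisk")


def parse_ratio_spec(text: str) -> RatioSpec:
    """Parse a compact ratio label like ``"BU/WU"`` into a RatioSpec."""
    try:
        num, den = text.strip().upper().split("/")
        return RatioSpec((num[0], num[1]), (den[0], den[1]))
    except (ValueError, IndexError) as exc:
        raise ValueError(f"cannot parse ratio spec {text!r}; expected e.g. 'BU/WU'") from exc


def write_csv(df: pd.DataFrame, path: Path, meta: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {meta}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run clean -> fit -> ratios -> regression and write all artifacts.

    Returns a dict with the in-memory objects (counts, posterior, tables)
    for programmatic use.
    """
    config.validate()
    if not (config.records_csv and config.census_csv):
        raise ValueError("run_pipeline requires records_csv and census_csv")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = f"config={config.digest()} seed={config.seed}"
    config.to_yaml(out / "config.yaml")

    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    results: dict = {}
    try:
        t0 = time.perf_counter()
        records = read_records(config.records_csv)
        cleaned, report = clean_records(records)
        deduped, n_dupes = deduplicate(cleaned)
        report.duplicates_dropped = n_dupes
        census = read_census(config.census_csv)
        agg = aggregate_counts(deduped, census)
        report.to_json(out / "cleaning_report.json")
        write_csv(agg.counts, out / "counts.csv", meta)
        if agg.uncovered:
            (out / "uncovered_counties.json").write_text(
                json.dumps(agg.uncovered, indent=2) + "\n"
            )
        logger.info(
            "clean: %d records in, %d kept, %d duplicates, %d counties (%.1fs)",
            report.n_input, report.n_kept, n_dupes, len(agg.counts),
            time.perf_counter() - t0,
        )
        results["counts"], results["cleaning_report"] = agg.counts, report

        t0 = time.perf_counter()
        s1 = config.stage1
        model = ShootingRateModel(
            chains=s1.chains, warmup=s1.warmup, draws=s1.draws, seed=config.seed,
            target_accept=s1.target_accept, max_treedepth=s1.max_treedepth,
            rhat_threshold=s1.rhat_threshold,
        ).fit(agg.counts)
        post: PosteriorDraws = model.posterior_
        post.save(out / "posterior")
        logger.info(
            "fit stage 1: %d counties, rhat_max=%.4f ess_min=%.0f (%.1fs)",
            len(post.fips), model.rhat_max_, model.ess_min_,
            time.perf_counter() - t0,
        )
        results["posterior"] = post

        t0 = time.perf_counter()
        specs = (
            [parse_ratio_spec(s) for s in config.ratio_specs]
            if config.ratio_specs
            else list(RESULTS_RATIO_FAMILIES)
        )
        ratios = ratio_table(post, specs, pooled_method=config.pooled_method)
        write_csv(ratios, out / "ratios.csv", meta + f" pooled={config.pooled_method}")
        logger.info("ratios: %d rows (%.1fs)", len(ratios), time.perf_counter() - t0)
        results["ratios"] = ratios

        if config.covariates_csv:
            covariates = read_covariates(config.covariates_csv)
            s2 = config.stage2
            results["regressions"] = {}
            for outcome in config.eco_outcomes:
                t0 = time.perf_counter()
                spec = parse_ratio_spec(outcome)
                draws_by_county = {
                    f: county_ratio_draws(post, f, spec) for f in post.fips
                }
                outcomes = summarize_log_rr(draws_by_county)
                table = regression_table(
                    outcomes, covariates, model_ids=tuple(config.eco_models),
                    chains=s2.chains, warmup=s2.warmup, draws=s2.draws,
                    seed=config.seed, target_accept=s2.target_accept,
                    rhat_threshold=s2.rhat_threshold,
                )
                stem = f"regression_{outcome.replace('/', '_')}"
                write_csv(table, out / f"{stem}.csv", meta + f" outcome={outcome}")
                (out / f"{stem}.json").write_text(
                    json.dumps(table.to_dict(orient="records"), indent=2) + "\n"
                )
                logger.info(
                    "regression %s: %d models (%.1fs)", outcome,
                    len(config.eco_models), time.perf_counter() - t0,
                )
                results["regressions"][outcome] = table
        return results
    finally:
        logger.removeHandler(handler)
        handler.close()
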