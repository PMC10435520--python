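"""Orchestration of the three analyses over file-based inputs.

Binds the stages together: isotopologue correction -> enrichment /
anaplerosis / contribution statistics (tracing analysis), reference
normalisation -> glog -> batch correction -> differential tests
(steady-state analysis), and per-row exchange-rate computation.  All
interchange is long-format delimited text; every run writes a log
capturing versions, seed, correction and transform parameters, and
dropped-record counts.  Results are computed fully in memory before any
file is written, so partial outputs are never left behind silently.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    anaplerosis_table,
    contribution_table,
    enrichment_table,
    nutrient_contribution_profile,
)
from .flux import exchange_table
from .isotope import (
    CorrectionSettings,
    correct_table,
    default_registry,
    load_registry,
    read_isotopologue_table,
)
from .stats import compare_table
from .steady_state import (
    batch_correct_to_control,
    normalize_to_reference,
    top_k_by_score,
    transform_and_centre,
)

logger = logging.getLogger("tcatrace")

__all__ = ["RunConfig", "run_tracing_analysis", "run_steady_state",
           "run_exchange"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run (round-trips via YAML)."""

    isotopologue_table: str | None = None
    metadata_table: str | None = None
    abundance_matrix: str | None = None
    exchange_table: str | None = None
    registry: str | None = None
    outdir: str = "results"
    mode: str = "paired"  # paired | unpaired
    p13c: float = 0.0107
    tracer_purity: float = 1.0
    nonneg: bool = True
    q: float = 0.10
    strong_q: float = 0.05
    weak_q: float = 0.10
    fdr_method: str = "bky"
    steady_fdr_method: str = "bh"
    lambda_mode: str = "global"
    control_condition: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("paired", "unpaired"):
            raise ValueError(f"mode must be 'paired' or 'unpaired', got "
                             f"{self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def correction_settings(self) -> CorrectionSettings:
        return CorrectionSettings(self.p13c, self.tracer_purity, self.nonneg)

    def load_registry(self):
        return load_registry(self.registry) if self.registry else default_registry()


def _write_runlog(
    outdir: Path, config: RunConfig, lines: list[str]
) -> None:
    header = f"# run log written {datetime.datetime.now().isoformat()}"
    body = [
        f"tcatrace_version: {__version__}",
        f"seed: {config.seed}",
        f"p13c: {config.p13c}",
        f"tracer_purity: {config.tracer_purity}",
        f"mode: {config.mode}",
        f"q: {config.q}",
    ] + lines
    (outdir / "runlog.txt").write_text("\n".join([header] + body) + "\n")


def _read_metadata(path: str, required: tuple[str, ...]) -> pd.DataFrame:
    meta = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata {path}: missing columns {missing}")
    return meta


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def run_tracing_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Correction -> enrichment -> anaplerosis/contribution -> statistics.

    Requires ``isotopologue_table`` and ``metadata_table`` (with sample_id,
    condition, pair_id, batch, tracer).  Statistics are computed per
    tracer on fractional enrichment, and on the PC/PDH ratio for malate,
    citrate and aspartate under the glucose tracer.  Returns the result
    tables and writes them plus a run log under ``outdir``.
    """
    if not config.isotopologue_table or not config.metadata_table:
        raise ValueError("tracing analysis needs isotopologue_table and "
                         "metadata_table")
    registry = config.load_registry()
    settings = config.correction_settings()
    raw = read_isotopologue_table(config.isotopologue_table)
    if raw.empty:
        raise ValueError(f"{config.isotopologue_table}: empty input table")
    meta = _read_metadata(
        config.metadata_table,
        ("sample_id", "condition", "pair_id", "batch", "tracer"),
    )
    unknown_samples = sorted(set(raw["sample_id"]) - set(meta["sample_id"]))
    if unknown_samples:
        raise ValueError(
            f"samples in data but not metadata: {unknown_samples}"
        )

    log_lines: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        corrected = correct_table(raw, registry, settings)
        enr = enrichment_table(corrected, registry)
        contrib = contribution_table(corrected, registry, meta)
        profile = nutrient_contribution_profile(
            contrib.merge(meta[["sample_id", "condition"]], on="sample_id")
        )

        stats_parts, volcano_parts = [], []
        for tracer, sample_ids in meta.groupby("tracer")["sample_id"]:
            sub = enr[enr["sample_id"].isin(sample_ids)]
            if sub.empty:
                continue
            st = compare_table(
                sub,
                meta,
                value_col="fraction_enrichment",
                paired=config.mode == "paired",
                q=config.q,
                fdr_method=config.fdr_method,
                control_condition=config.control_condition,
            )
            st.insert(0, "tracer", tracer)
            st.insert(1, "statistic", "fraction_enrichment")
            stats_parts.append(st)

        glucose_ids = meta.loc[meta["tracer"] == "glucose", "sample_id"]
        ana = anaplerosis_table(
            corrected[corrected["sample_id"].isin(glucose_ids)], registry
        )
        ana_stats = None
        if not ana.empty:
            ana_stats = compare_table(
                ana.dropna(subset=["pc_pdh_ratio"]),
                meta,
                value_col="pc_pdh_ratio",
                paired=config.mode == "paired",
                q=config.q,
                fdr_method=config.fdr_method,
                control_condition=config.control_condition,
            )
            ana_stats.insert(0, "tracer", "glucose")
            ana_stats.insert(1, "statistic", "pc_pdh_ratio")

    for w in caught:
        log_lines.append(f"warning: {w.message}")
    if not stats_parts:
        raise ValueError("no tracer group produced testable statistics")
    stats_all = pd.concat(stats_parts, ignore_index=True)
    n_in = len(raw)
    n_used = len(corrected)
    log_lines += [
        f"input_rows: {n_in}",
        f"corrected_rows: {n_used}",
        f"undefined_ratio_values: {int(ana['pc_pdh_ratio'].isna().sum()) if not ana.empty else 0}",
    ]

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = {
        "corrected": corrected,
        "enrichment": enr,
        "anaplerosis": ana,
        "contributions": contrib,
        "nutrient_contribution": profile,
        "stats": stats_all,
    }
    _write_csv(corrected, outdir / "corrected.csv")
    _write_csv(enr, outdir / "enrichment.csv")
    _write_csv(ana, outdir / "anaplerosis.csv")
    _write_csv(contrib, outdir / "contributions.csv")
    _write_csv(profile, outdir / "nutrient_contribution.csv")
    _write_csv(stats_all, outdir / "stats.csv")
    _write_csv(
        stats_all[
            ["tracer", "statistic", "metabolite", "log10_fc", "neg_log10_q",
             "tier"]
        ],
        outdir / "volcano.csv",
    )
    if ana_stats is not None:
        results["anaplerosis_stats"] = ana_stats
        _write_csv(ana_stats, outdir / "anaplerosis_stats.csv")
    _write_runlog(outdir, config, log_lines)
    logger.info("tracing analysis written to %s", outdir)
    return results


def run_steady_state(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Normalise -> glog+centre -> batch-correct -> test -> top-25 list.

    Requires ``abundance_matrix`` (wide, samples x metabolites, first
    column sample_id) and ``metadata_table`` with sample_id, condition,
    pair_id, batch and acquisition_order columns.  The effect size is the
    post-transform mean difference rescaled to log10 units (exact for
    abundances well above the glog lambda).
    """
    if not config.abundance_matrix or not config.metadata_table:
        raise ValueError("steady-state analysis needs abundance_matrix and "
                         "metadata_table")
    matrix = pd.read_csv(
        config.abundance_matrix, sep=None, engine="python", index_col=0
    )
    if matrix.empty:
        raise ValueError(f"{config.abundance_matrix}: empty matrix")
    meta = _read_metadata(
        config.metadata_table,
        ("sample_id", "condition", "pair_id", "batch", "acquisition_order"),
    )
    missing = sorted(set(matrix.index) - set(meta["sample_id"]))
    if missing:
        raise ValueError(f"samples in matrix but not metadata: {missing}")

    log_lines: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        normalized = normalize_to_reference(matrix, meta)
        transformed, lam = transform_and_centre(normalized, config.lambda_mode)
        corrected = batch_correct_to_control(
            transformed, meta, config.control_condition
        )
        long = corrected.reset_index(names="sample_id").melt(
            id_vars="sample_id", var_name="metabolite", value_name="value"
        )
        st = compare_table(
            long.dropna(subset=["value"]),
            meta,
            value_col="value",
            paired=config.mode == "paired",
            q=config.q,
            fdr_method=config.steady_fdr_method,
            control_condition=config.control_condition,
            log_transform=False,
        )
    # glog2 mean difference -> log10 units
    st["log10_fc"] = st["log10_fc"] * np.log10(2.0)
    top = top_k_by_score(st, k=25)
    for w in caught:
        log_lines.append(f"warning: {w.message}")
    lam_repr = (
        f"{lam:.6g}" if np.isscalar(lam) else "feature-wise (see transform)"
    )
    log_lines += [f"glog_lambda: {lam_repr}",
                  f"lambda_mode: {config.lambda_mode}"]

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transformed_out = corrected.reset_index(names="sample_id")
    _write_csv(transformed_out, outdir / "transformed_matrix.csv")
    _write_csv(st, outdir / "steady_stats.csv")
    _write_csv(
        st[["metabolite", "log10_fc", "neg_log10_q", "tier"]],
        outdir / "volcano_steady.csv",
    )
    (outdir / "top25.txt").write_text("\n".join(top) + "\n")
    _write_runlog(outdir, config, log_lines)
    logger.info("steady-state analysis written to %s", outdir)
    return {"transformed": corrected, "stats": st, "top25": pd.DataFrame(
        {"metabolite": top})}


def run_exchange(config: RunConfig) -> pd.DataFrame:
    """Exchange-rate computation for every row of the medium table."""
    if not config.exchange_table:
        raise ValueError("exchange analysis needs exchange_table")
    df = pd.read_csv(config.exchange_table, sep=None, engine="python")
    if df.empty:
        raise ValueError(f"{config.exchange_table}: empty input table")
    rates = exchange_table(df)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_csv(rates, outdir / "exchange_rates.csv")
    _write_runlog(outdir, config, [f"exchange_rows: {len(rates)}"])
    logger.info("exchange rates written to %s", outdir)
    return rates
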