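"""Config-driven orchestration of the full MVT analysis.

A run takes survey records from one source (a CSV on disk, the synthetic
generator, or a previously fetched OSF deposit directory), applies the
exclusion rule and subset filters, optionally runs both exploratory cluster
analyses, fits the gain curve by orthogonal-distance regression, assembles
the diagnostics, evaluates travel-time predictions, and writes a
machine-readable summary plus per-stage artifacts. Identical config and
seed give an identical summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import plots
from .diagnostics import build_gain_diagnostics, welch_t_test
from .model import gain
from .odr import fit_gain_odr
from .preprocess import (
    KEY_COLUMNS,
    SubsetReport,
    categorize,
    exclude_incomplete,
    median_split,
    read_survey,
)
from .simulate import SimulationConfig, simulate_foragers, write_survey
from .travel import evaluate_travel_predictions

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "fetch_osf"]

#: Dummy-variable families entering the socioeconomic (Jaccard) clustering.
SOCIO_DUMMY_PREFIXES = (
    "main_patch__", "trip_type__", "shop_freq_cat__", "household_cat__",
    "group_size__", "age_cat__", "gender__", "transport__", "work_status__",
    "exhaustion__",
)
#: Metric variables entering the Euclidean clustering (raw units).
METRIC_COLUMNS = ("travel_time_min", "patch_time_min", "gain_euro")


@dataclass
class RunConfig:
    """Parameterization of one end-to-end run.

    Exactly one input source applies: ``source="csv"`` with ``csv_path``,
    or ``source="simulate"`` with ``sim`` options (the master ``seed``
    overrides the generator's own seed so one integer controls the run).
    """

    source: str = "simulate"              # {simulate | csv}
    csv_path: str | None = None
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    gain_operationalization: str = "euro"  # {euro | n_products}
    filter_main_patch: bool = True
    filter_home_roundtrip: bool = True
    filter_foot: bool = True
    do_cluster: bool = True
    cluster_k_max: int = 10
    standardize_fit: bool = True
    absolute_travel: bool = False
    make_plots: bool = True
    outdir: str = "mvt_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.source not in ("simulate", "csv"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "csv" and not self.csv_path:
            raise ValueError("source='csv' requires csv_path")
        if self.gain_operationalization not in ("euro", "n_products"):
            raise ValueError(
                f"unknown gain operationalization {self.gain_operationalization!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run config keys: {sorted(unknown)}")
        return cls(sim=sim, **raw)


def _gain_column(config: RunConfig) -> str:
    return "gain_euro" if config.gain_operationalization == "euro" else "n_products"


def _apply_filters(records: pd.DataFrame, config: RunConfig):
    """Exclusion plus the enabled subset filters, with attrition accounting."""
    kept, excluded = exclude_incomplete(records)
    n_input = len(records)
    cur = kept
    drops = {"main_patch": 0, "home_roundtrip": 0, "foot": 0}
    if config.filter_main_patch:
        m = cur["main_patch"].fillna(False).astype(bool)
        drops["main_patch"] = int((~m).sum())
        cur = cur[m]
    if config.filter_home_roundtrip:
        m = cur["trip_type"] == "home_roundtrip"
        drops["home_roundtrip"] = int((~m).sum())
        cur = cur[m]
    if config.filter_foot:
        m = cur["transport"] == "foot"
        drops["foot"] = int((~m).sum())
        cur = cur[m]
    report = SubsetReport(
        n_input=n_input,
        n_excluded_incomplete=len(excluded),
        n_after_exclusion=len(kept),
        drop_not_main_patch=drops["main_patch"],
        drop_not_home_roundtrip=drops["home_roundtrip"],
        drop_not_foot=drops["foot"],
        n_subset=len(cur),
    )
    return cur.copy(), report


def _cluster_stage(full: pd.DataFrame, config: RunConfig, outdir: Path) -> dict:
    out: dict = {}
    cat = categorize(full)
    dummy_cols = [
        c for c in cat.columns if c.startswith(SOCIO_DUMMY_PREFIXES)
    ]
    socio = cat[dummy_cols].dropna()
    if len(socio) > config.cluster_k_max:
        D = cl.jaccard_distance_matrix(socio.to_numpy())
        dendro = cl.complete_linkage(D, labels=socio.index.astype(str))
        elbow = cl.scree_elbow(dendro, config.cluster_k_max)
        dendro.to_json(outdir / "dendrogram_socio.json")
        elbow.series_frame().to_csv(outdir / "scree_socio.csv", index=False)
        if config.make_plots:
            plots.plot_scree(elbow, outdir / "scree_socio.png")
            plots.plot_dendrogram(dendro, outdir / "dendrogram_socio.png")
        out["socio"] = {"n": len(socio), "elbow_k": elbow.k,
                        "no_elbow": elbow.no_elbow}
    metric = full[list(METRIC_COLUMNS)].dropna()
    if len(metric) > config.cluster_k_max:
        D = cl.euclidean_distance_matrix(metric.to_numpy())
        dendro = cl.complete_linkage(D, labels=metric.index.astype(str))
        elbow = cl.scree_elbow(dendro, config.cluster_k_max)
        dendro.to_json(outdir / "dendrogram_metric.json")
        elbow.series_frame().to_csv(outdir / "scree_metric.csv", index=False)
        if config.make_plots:
            plots.plot_scree(elbow, outdir / "scree_metric.png")
            plots.plot_dendrogram(dendro, outdir / "dendrogram_metric.png")
        out["metric"] = {"n": len(metric), "elbow_k": elbow.k,
                         "no_elbow": elbow.no_elbow}
    return out


def _welch_stage(subset: pd.DataFrame) -> dict:
    """Exploratory group comparisons of patch residence times."""
    out: dict = {}
    T = subset["patch_time_min"]
    gender = subset.get("gender")
    if gender is not None:
        male = T[gender == "male"].dropna()
        female = T[gender == "female"].dropna()
        if len(male) >= 2 and len(female) >= 2:
            out["gender_male_vs_female"] = welch_t_test(male, female)
    age = subset.get("age")
    if age is not None and age.notna().sum() >= 4:
        present = subset[age.notna()]
        labels = median_split(present["age"])
        low = present["patch_time_min"][labels == "low"]
        high = present["patch_time_min"][labels == "high"]
        if len(low) >= 2 and len(high) >= 2:
            out["age_low_vs_high"] = welch_t_test(low, high)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the summary bundle (also on disk).

    On an empty subset the run aborts gracefully: the attrition report and a
    summary with an ``error`` field are still written. A fit failure leaves
    a partial bundle with the error recorded.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    # one master seed; the generator gets a derived stream
    sim_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31))
    summary: dict = {
        "config": {
            "source": config.source,
            "gain_operationalization": config.gain_operationalization,
            "seed": config.seed,
            "sim_seed": sim_seed,
        }
    }

    if config.source == "simulate":
        sim_cfg = dataclasses.replace(config.sim, seed=sim_seed)
        records = simulate_foragers(sim_cfg)
        write_survey(records, outdir / "simulated_survey.csv")
        summary["config"]["sim"] = dataclasses.asdict(sim_cfg)
    else:
        records = read_survey(config.csv_path)
    logger.info("stage=input n=%d (%.2fs)", len(records), time.perf_counter() - t0)

    subset, report = _apply_filters(records, config)
    report.to_json(outdir / "subset_report.json")
    summary["subset"] = {
        "n_input": report.n_input,
        "n_excluded_incomplete": report.n_excluded_incomplete,
        "n_subset": report.n_subset,
    }
    if len(subset) == 0:
        summary["error"] = "empty subset after filtering; see subset_report.json"
        _write_summary(summary, outdir)
        return summary

    if config.do_cluster:
        try:
            kept_full, _ = exclude_incomplete(records)
            summary["clustering"] = _cluster_stage(kept_full, config, outdir)
        except ValueError as err:
            summary["clustering"] = {"error": str(err)}
    logger.info("stage=cluster (%.2fs)", time.perf_counter() - t0)

    gcol = _gain_column(config)
    pts = subset[["patch_time_min", gcol]].dropna().to_numpy(dtype=float)
    try:
        fit = fit_gain_odr(pts, standardize=config.standardize_fit)
    except (ValueError, RuntimeError) as err:
        summary["error"] = f"gain-curve fit failed: {err}"
        _write_summary(summary, outdir)
        return summary
    fit.to_json(outdir / "fit_gain.json")
    summary["gain_fit"] = {
        "A_hat": fit.A_hat, "k_hat": fit.k_hat, "n": fit.n,
        "objective": fit.objective, "s2_resid": fit.s2_resid,
        "se_resid": fit.se_resid, "converged": fit.converged,
    }
    logger.info(
        "stage=fit A=%.3f k=%.4f se=%.3f (%.2fs)",
        fit.A_hat, fit.k_hat, fit.se_resid, time.perf_counter() - t0,
    )

    g_obs = pts[:, 1]
    T_obs = pts[:, 0]
    g_pred = np.asarray(gain(fit.curve, T_obs))
    diag = build_gain_diagnostics(g_obs, g_pred, fit.residual_lengths**2)
    diag.welch_tests = _welch_stage(subset)
    diag.to_json(outdir / "diagnostics_gain.json")
    summary["gain_diagnostics"] = {
        "bias_intercept": diag.bias.intercept,
        "bias_slope": diag.bias.slope,
        "paired_t": diag.paired_test.as_dict(),
        "welch": {k: v.as_dict() for k, v in diag.welch_tests.items()},
    }

    travel = evaluate_travel_predictions(fit, subset, absolute=config.absolute_travel)
    travel.to_json(outdir / "travel_eval.json")
    summary["travel_eval"] = {
        "s2_resid": travel.s2_resid,
        "se_resid": travel.se_resid,
        "paired_t": travel.paired_test.as_dict(),
        "n": travel.n,
    }
    logger.info("stage=travel se=%.3f (%.2fs)", travel.se_resid,
                time.perf_counter() - t0)

    if config.make_plots:
        plots.plot_gain_fit(fit, T_obs, g_obs, outdir / "fig_gain_fit.png")
        plots.plot_diagnostic_panels(
            diag, g_pred, outdir / "fig_gain_diagnostics.png",
            squared_residuals=fit.residual_lengths**2,
        )
        plots.plot_travel_panels(travel, fit, T_obs, outdir / "fig_travel.png")

    _write_summary(summary, outdir)
    return summary


def _write_summary(summary: dict, outdir: Path) -> None:
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


# --- OSF deposit fetch ------------------------------------------------------

OSF_API = "https://api.osf.io/v2/nodes/{node}/files/osfstorage/"


def fetch_osf(node: str, outdir: str | Path, checksums: dict[str, str] | None = None,
              timeout: float = 30.0) -> list[Path]:
    """Download all files of an OSF deposit's osfstorage into ``outdir``.

    ``checksums`` optionally maps file names to expected SHA-256 digests; a
    mismatch raises. Requires network access; analysis runs never do — point
    the pipeline at the downloaded CSV afterwards (with a column-mapping
    YAML if the deposit's headers differ from the documented ones).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with urllib.request.urlopen(OSF_API.format(node=node), timeout=timeout) as resp:
        listing = json.load(resp)
    paths: list[Path] = []
    for item in listing.get("data", []):
        name = item["attributes"]["name"]
        url = item["links"].get("download")
        if not url:
            continue
        dest = outdir / name
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
        if checksums and name in checksums:
            digest = hashlib.sha256(data).hexdigest()
            if digest != checksums[name]:
                raise ValueError(
                    f"checksum mismatch for {name}: got {digest}"
                )
        dest.write_bytes(data)
        paths.append(dest)
        logger.info("fetched %s (%d bytes)", name, len(data))
    return paths
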