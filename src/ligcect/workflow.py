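"""End-to-end pipeline: simulate -> mechanics -> cect -> segment -> report.

A single :class:`RunConfig` (JSON-serializable) drives a reproducible run:
a synthetic paired cohort is generated, every tensile trace is reduced to
its viscoelastic/damage parameters, every subsample's phantom immersion
series is calibrated, segmented and fit for (Pmax, tau), two
nanoparticle volumes get a structural fascicle/IFM segmentation, and the
report stage writes group summary tables (parameter means +- SD with paired
Wilcoxon p; per-agent uptake curves and Pmax/tau) plus the
biomechanics-vs-uptake correlation screen and a checksummed manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cect import bulk_partition, fit_uptake, hu_calibrate, segment_tissue
from .io import ValidationError, write_report
from .mechanics import DAMAGE_PARAMETER_NAMES, analyze_test
from .stats import correlation_screen, wilcoxon_signed_rank
from .structure import region_contrast, roi_stats, segment_fascicles
from .synthetic import CohortNoise, gen_cohort, gen_ct_phantom

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and sample id."""

    def __init__(self, stage: str, sample: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {sample!r}: {cause}")
        self.stage = stage
        self.sample = sample


@dataclass
class RunConfig:
    """Protocol constants and analysis options for one reproducible run."""

    seed: int = 0
    n_ligaments: int = 11
    out_dir: str = "run"
    agents: tuple[str, ...] = ("iodixanol", "Ta2O5-cNP")
    # protocol constants
    preload_mpa: float = 0.05
    frequencies: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0)
    # noise (study conditions)
    mech_stress_sd_frac: float = 0.02
    ct_noise_sd_hu: float = 22.0
    # analysis options
    modulus_window: tuple[float, float] = (0.04, 0.08)
    yield_threshold: float = 0.7
    clustering_seed: int = 0
    # phantom size for cohort runs; the sample must survive the 10-px shrink
    # and 2000-px area filter, hence the 128-px cross-section
    ct_shape: tuple[int, int, int] = (24, 128, 128)
    n_structural_samples: int = 2

    def __post_init__(self) -> None:
        if self.preload_mpa <= 0 or self.n_ligaments < 2:
            raise ValidationError("invalid protocol constants")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("agents", "frequencies", "modulus_window", "ct_shape"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.10g")
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def mechanics_stage(table, config: RunConfig) -> pd.DataFrame:
    rows = []
    for (lig, group), test in sorted(table.traces.items()):
        try:
            res = analyze_test(
                test,
                frequencies=config.frequencies,
                modulus_window=config.modulus_window,
                yield_threshold=config.yield_threshold,
            )
        except Exception as exc:  # noqa: BLE001 - stage failures must name the sample
            raise StageError("mechanics", f"{lig}-{group}", exc) from exc
        rows.append({"ligament_id": lig, "group": group, **res["parameters"]})
    return pd.DataFrame(rows)


def cect_stage(table, config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Quantitative CECT per subsample; returns (fits, partition curves, cache).

    Phantom volumes are regenerated from the per-subsample truth seeds and
    discarded after analysis; the cache keeps only what the structural stage
    reuses (the last-timepoint nanoparticle volumes of the first subsamples).
    """
    fit_rows, curve_rows = [], []
    keep: dict = {}
    n_kept = 0
    for key in sorted(table.truth["cect"]):
        lig, group, agent = key
        entry = table.truth["cect"][key]
        sid = f"{lig}-{group}-{agent}"
        try:
            if key in table.volumes:
                native, *series = table.volumes[key]
            else:
                native, series, entry["ct_truth"] = gen_ct_phantom(
                    shape=config.ct_shape,
                    truth=entry["ct_truth"],
                    seed=entry["seed"],
                    sample_id=sid,
                )
            native = hu_calibrate(native)
            series = [hu_calibrate(v) for v in series]
            masks = [
                segment_tissue(v, seed=config.clustering_seed).mask
                for v in [native, *series]
            ]
            diff = bulk_partition(native, series, masks)
            fit = fit_uptake(diff)
        except Exception as exc:  # noqa: BLE001
            raise StageError("cect", sid, exc) from exc
        fit_rows.append(
            {
                "ligament_id": lig, "group": group, "agent": agent,
                "Pmax": fit.Pmax, "tau_h": fit.tau_h, "rmse": fit.rmse,
                "n_points": fit.n_points,
            }
        )
        curve_rows.extend(
            {
                "ligament_id": lig, "group": group, "agent": agent,
                "timepoint_h": float(t), "partition": float(p),
            }
            for t, p in zip(diff.timepoints_h, diff.partition)
        )
        if agent == "Ta2O5-cNP" and n_kept < config.n_structural_samples:
            keep[key] = (series[-1], masks[-1], entry["ct_truth"])
            n_kept += 1
    return pd.DataFrame(fit_rows), pd.DataFrame(curve_rows), keep


def structure_stage(cached: dict, config: RunConfig) -> pd.DataFrame:
    rows = []
    for (lig, group, agent), (volume, tissue_mask, _truth) in sorted(cached.items()):
        sid = f"{lig}-{group}-{agent}"
        try:
            masks = segment_fascicles(volume, tissue_mask, seed=config.clustering_seed)
            stats = {s.label: s for s in roi_stats(volume, masks)}
            diff, ratio = region_contrast(stats["fascicle"], stats["ifm"])
        except Exception as exc:  # noqa: BLE001
            raise StageError("segment", sid, exc) from exc
        for label in ("fascicle", "ifm"):
            s = stats[label]
            rows.append(
                {
                    "ligament_id": lig, "group": group, "region": label,
                    "mean_HU": s.mean_HU, "sd_HU": s.sd_HU,
                    "voxel_count": s.voxel_count,
                    "ifm_fascicle_diff_HU": diff,
                    "ifm_fascicle_ratio": ratio,
                }
            )
    return pd.DataFrame(rows)


def _group_summary(biomech: pd.DataFrame) -> pd.DataFrame:
    """Parameter-by-group summary with paired Wilcoxon p where paired."""
    params = [c for c in biomech.columns if c not in ("ligament_id", "group")]
    ctrl = biomech[biomech["group"] == "control"].set_index("ligament_id")
    dmg = biomech[biomech["group"] == "damaged"].set_index("ligament_id")
    shared = sorted(set(ctrl.index) & set(dmg.index))
    rows = []
    for p in params:
        damage_specific = p in DAMAGE_PARAMETER_NAMES
        c_vals = ctrl.loc[shared, p].to_numpy() if not damage_specific else np.array([])
        d_vals = dmg.loc[shared, p].to_numpy()
        row = {
            "parameter": p,
            "control_mean": float(np.nanmean(c_vals)) if c_vals.size else float("nan"),
            "control_sd": float(np.nanstd(c_vals, ddof=1)) if c_vals.size > 1 else float("nan"),
            "damaged_mean": float(np.nanmean(d_vals)),
            "damaged_sd": float(np.nanstd(d_vals, ddof=1)) if d_vals.size > 1 else float("nan"),
            "n_pairs": len(shared),
        }
        if not damage_specific and c_vals.size:
            try:
                row["p_value"] = wilcoxon_signed_rank(c_vals, d_vals, parameter=p).p_value
            except ValidationError:
                row["p_value"] = float("nan")
        else:
            row["p_value"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def _uptake_summary(cect: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (agent, param), sub in cect.melt(
        id_vars=["ligament_id", "group", "agent"],
        value_vars=["Pmax", "tau_h"],
        var_name="parameter",
    ).groupby(["agent", "parameter"], sort=True):
        ctrl = sub[sub["group"] == "control"].set_index("ligament_id")["value"]
        dmg = sub[sub["group"] == "damaged"].set_index("ligament_id")["value"]
        shared = sorted(set(ctrl.index) & set(dmg.index))
        try:
            p = wilcoxon_signed_rank(
                ctrl.loc[shared].to_numpy(), dmg.loc[shared].to_numpy(), parameter=param
            ).p_value
        except ValidationError:
            p = float("nan")
        rows.append(
            {
                "agent": agent, "parameter": param,
                "control_mean": float(ctrl.mean()), "control_sd": float(ctrl.std()),
                "damaged_mean": float(dmg.mean()), "damaged_sd": float(dmg.std()),
                "n_pairs": len(shared), "p_value": p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on a synthetic cohort and write the run directory.

    Returns the manifest (also written as ``manifest.json``), which lists
    every output file with a SHA-256 checksum, the configuration, and the
    package version.  Identical configurations produce identical files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    logger.info("stage simulate: n=%d seed=%d", config.n_ligaments, config.seed)
    try:
        table = gen_cohort(
            n_ligaments=config.n_ligaments,
            noise=CohortNoise(
                mech_stress_sd_frac=config.mech_stress_sd_frac,
                ct_noise_sd_hu=config.ct_noise_sd_hu,
            ),
            seed=config.seed,
            agents=config.agents,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", "cohort", exc) from exc

    logger.info("stage mechanics: %d traces", len(table.traces))
    biomech = mechanics_stage(table, config)
    written.append(_write_csv(biomech, out / "biomechanics.csv"))

    logger.info("stage cect: %d subsamples", len(table.truth["cect"]))
    cect_fits, curves, cached = cect_stage(table, config)
    written.append(_write_csv(cect_fits, out / "uptake_fits.csv"))
    written.append(_write_csv(curves, out / "uptake_series.csv"))

    logger.info("stage segment: %d volumes", len(cached))
    structure = structure_stage(cached, config)
    written.append(_write_csv(structure, out / "structure_regions.csv"))

    logger.info("stage report")
    summary_params = _group_summary(biomech)
    written.append(_write_csv(summary_params, out / "summary_parameters.csv"))
    summary_uptake = _uptake_summary(cect_fits)
    written.append(_write_csv(summary_uptake, out / "summary_uptake.csv"))
    correlations = correlation_screen(biomech, cect_fits)
    written.append(_write_csv(correlations, out / "correlations.csv"))

    long_rows = biomech.melt(
        id_vars=["ligament_id", "group"], var_name="parameter", value_name="value"
    ).rename(columns={"ligament_id": "sample_id"})
    written.append(write_report(long_rows, out / "report.csv"))
    written.append(out / "report.summary.json")

    (out / "config.json").write_text(config.to_json())
    written.append(out / "config.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


__all__ = ["RunConfig", "StageError", "run_pipeline", "mechanics_stage",
           "cect_stage", "structure_stage"]
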