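"""Table and recording I/O, run configuration and the pipeline driver.

CSV files are comma-separated UTF-8 with a mandatory header row and "."
decimals.  Times are seconds; rates are pumps/min except in L1 mode,
where the column name flags the pumps-per-55 s scale.  Recordings travel
as a per-frame CSV plus a YAML sidecar holding stimulus timing and frame
rate.  Every pipeline run writes a manifest listing its configuration
hash, seeds, package version and a content hash of each output file, so
any run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .imaging import TwoChannelRecording

logger = logging.getLogger("famfeed")

__all__ = [
    "TableValidationError",
    "load_table",
    "load_feeding_table",
    "load_cellcount_table",
    "write_recording",
    "read_recording",
    "RunConfig",
    "run_pipeline",
]


class TableValidationError(ValueError):
    """A table row violates its schema; the message names row and field."""


RECORDING_COLUMNS = ["time_s", "cyan", "yellow", "background_cyan", "background_yellow"]

FEEDING_COLUMNS = [
    "animal_id", "genotype", "training_food", "test_food", "stage", "window_s",
]
CELLCOUNT_COLUMNS = ["animal_id", "condition", "experiment", "count"]


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path)


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing columns {missing}")


def load_feeding_table(path) -> pd.DataFrame:
    """Load and validate a per-animal pump-count table.

    Required columns: ``animal_id, genotype, training_food, test_food,
    stage, window_s`` plus ``count1..countK`` (K = 3 for adults, 2 for
    L1 larvae).  Every row is checked through the
    :class:`~famfeed.feeding.FeedingObservation` invariants.
    """
    from .feeding import FeedingObservation, StatsError

    df = _read_csv(path)
    _check_columns(df, FEEDING_COLUMNS, path)
    count_cols = sorted(c for c in df.columns if c.startswith("count"))
    if not count_cols:
        raise TableValidationError(f"{path}: no count1..countK columns")
    if df.empty:
        warnings.warn(f"{path}: empty table (header only)")
        logger.warning("%s: empty table", path)
        return df
    for i, row in df.iterrows():
        try:
            counts = tuple(int(row[c]) for c in count_cols if pd.notna(row[c]))
            FeedingObservation(
                animal_id=str(row["animal_id"]),
                genotype=str(row["genotype"]),
                training_food=str(row["training_food"]),
                test_food=str(row["test_food"]),
                counts=counts,
                window_s=float(row["window_s"]),
                stage=str(row["stage"]),
            )
        except (StatsError, ValueError) as err:
            raise TableValidationError(f"{path}: row {i}: {err}") from err
    return df


def load_cellcount_table(path) -> pd.DataFrame:
    """Load and validate a per-animal serotonin-positive cell-count table
    (columns ``animal_id, condition, experiment, count``; counts 0..3)."""
    from .cellcounts import CountObservation
    from .feeding import StatsError

    df = _read_csv(path)
    _check_columns(df, CELLCOUNT_COLUMNS, path)
    if df.empty:
        warnings.warn(f"{path}: empty table (header only)")
        logger.warning("%s: empty table", path)
        return df
    for i, row in df.iterrows():
        try:
            CountObservation(
                animal_id=str(row["animal_id"]),
                condition=str(row["condition"]),
                experiment=int(row["experiment"]),
                count=int(row["count"]),
            )
        except (StatsError, ValueError) as err:
            raise TableValidationError(f"{path}: row {i}: {err}") from err
    return df


_SCHEMAS = {"feeding": load_feeding_table, "cellcounts": load_cellcount_table}


def load_table(path, schema: str) -> pd.DataFrame:
    """Load a validated table; ``schema`` is ``"feeding"`` or
    ``"cellcounts"``."""
    try:
        loader = _SCHEMAS[schema]
    except KeyError:
        raise TableValidationError(
            f"unknown schema {schema!r}; use one of {sorted(_SCHEMAS)}"
        ) from None
    return loader(path)


# ---------------------------------------------------------------------------
# recordings


def write_recording(rec: TwoChannelRecording, csv_path, frame_rate_hz: float | None = None) -> None:
    """Write a recording as CSV plus a YAML sidecar (same stem, .yaml)."""
    csv_path = Path(csv_path)
    pd.DataFrame(
        {
            "time_s": rec.time_s,
            "cyan": rec.i_480,
            "yellow": rec.i_535,
            "background_cyan": rec.bg_480,
            "background_yellow": rec.bg_535,
        }
    ).to_csv(csv_path, index=False)
    if frame_rate_hz is None:
        frame_rate_hz = float(1.0 / np.median(np.diff(rec.time_s)))
    sidecar = {
        "stimulus_onset_s": float(rec.stimulus_onset_s),
        "frame_rate_hz": float(frame_rate_hz),
    }
    csv_path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def read_recording(csv_path) -> TwoChannelRecording:
    """Read a recording CSV and its YAML sidecar."""
    csv_path = Path(csv_path)
    df = _read_csv(csv_path)
    _check_columns(df, RECORDING_COLUMNS, csv_path)
    sidecar_path = csv_path.with_suffix(".yaml")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = yaml.safe_load(sidecar_path.read_text())
    return TwoChannelRecording(
        time_s=df["time_s"].to_numpy(float),
        i_480=df["cyan"].to_numpy(float),
        i_535=df["yellow"].to_numpy(float),
        bg_480=df["background_cyan"].to_numpy(float),
        bg_535=df["background_yellow"].to_numpy(float),
        stimulus_onset_s=float(sidecar["stimulus_onset_s"]),
    )


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run.

    Processing defaults match the study conventions: bleed-through 0.65,
    10 s bins, signed-area window 0-120 s, Welch-Satterthwaite degrees of
    freedom.
    """

    seed: int = 0
    out_dir: str = "famfeed_run"
    bleed: float = 0.65
    bin_width_s: float = 10.0
    window: tuple[float, float] = (0.0, 120.0)
    df_policy: str = "welch-satterthwaite"
    imaging: dict | None = field(default_factory=dict)
    feeding: dict | None = field(default_factory=dict)
    cellcounts: dict | None = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise TableValidationError(f"unknown config keys {sorted(unknown)}")
        if "window" in raw:
            raw["window"] = tuple(float(x) for x in raw["window"])
        return cls(**raw)

    def content_hash(self) -> str:
        enc = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()},
            sort_keys=True,
        ).encode()
        return hashlib.sha256(enc).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Simulate, process and analyse per the configuration.

    Stages (each optional, enabled by its config section):

    * ``imaging``  — simulate ``n_animals`` recordings, run the ΔR/R
      pipeline, write per-animal ΔR/R traces, the cross-animal binned
      time course and the signed-area table;
    * ``feeding``  — simulate the four-condition feeding dataset and
      write the familiar-vs-novel conservative test table;
    * ``cellcounts`` — simulate the multi-experiment cell-count dataset
      and write per-experiment contrasts plus the Fisher combination.

    Returns the run directory; a ``manifest.json`` lists every output
    with its SHA-256 content hash.
    """
    from . import __version__
    from .cellcounts import CellCountFamiliarityModel
    from .feeding import familiar_vs_novel_tests
    from .imaging import CalciumResponseModel, average_binned
    from .simulate import (
        CellCountDesign,
        FeedingDesign,
        ImagingSimParams,
        default_feeding_design,
        gen_cellcount_dataset,
        gen_feeding_dataset,
        gen_imaging_recording,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    if config.imaging is not None:
        opts = dict(config.imaging)
        n_animals = int(opts.pop("n_animals", 5))
        binned_all, areas = [], []
        delta_frames = {}
        for i in range(n_animals):
            params = ImagingSimParams(seed=config.seed + i, **opts)
            rec, _ = gen_imaging_recording(params)
            res = CalciumResponseModel(
                rec, bleed=config.bleed, bin_width_s=config.bin_width_s,
                window=config.window,
            ).fit()
            binned_all.append(res.binned)
            areas.append(res.signed_area)
            delta_frames[f"animal{i}"] = pd.Series(
                res.delta_r.values, index=res.delta_r.time_s
            )
        delta_path = out / "delta_r_per_animal.csv"
        pd.DataFrame(delta_frames).rename_axis("time_s").to_csv(delta_path)
        group = average_binned(binned_all)
        tc_path = out / "timecourse_binned.csv"
        pd.DataFrame(
            {
                "bin_start_s": group.bin_edges[:-1],
                "bin_end_s": group.bin_edges[1:],
                "mean_delta_r": group.means,
                "n_animals": group.counts,
            }
        ).to_csv(tc_path, index=False)
        area_path = out / "signed_areas.csv"
        pd.DataFrame(
            {"animal": [f"animal{i}" for i in range(n_animals)],
             "signed_area_s": areas}
        ).to_csv(area_path, index=False)
        outputs += [delta_path, tc_path, area_path]
        logger.info("imaging stage: %d animals", n_animals)

    if config.feeding is not None:
        opts = dict(config.feeding)
        if opts:
            design = FeedingDesign(seed=config.seed, **opts)
        else:
            design = default_feeding_design(seed=config.seed)
        table = gen_feeding_dataset(design)
        obs_path = out / "feeding_observations.csv"
        table.to_csv(obs_path, index=False)
        results = familiar_vs_novel_tests(table)
        res_path = out / "feeding_tests.csv"
        results.to_csv(res_path, index=False)
        outputs += [obs_path, res_path]
        logger.info("feeding stage: %d animals", len(table))

    if config.cellcounts is not None:
        design = CellCountDesign(seed=config.seed, **dict(config.cellcounts))
        table = gen_cellcount_dataset(design)
        counts_path = out / "cell_counts.csv"
        table.to_csv(counts_path, index=False)
        combined = {}
        for comparison in ("HHvsDH", "DDvsHD"):
            res = CellCountFamiliarityModel(
                table, comparison=comparison, df_policy=config.df_policy
            ).fit()
            per_path = out / f"cellcount_contrasts_{comparison}.csv"
            res.per_experiment.to_csv(per_path, index=False)
            outputs.append(per_path)
            combined[comparison] = {
                "chi2": res.fisher.chi2,
                "df": res.fisher.df,
                "p_combined": res.fisher.p_combined,
                "per_experiment_p": list(res.fisher.per_experiment_p),
            }
        fisher_path = out / "cellcount_fisher.json"
        fisher_path.write_text(json.dumps(combined, indent=2))
        outputs += [counts_path, fisher_path]
        logger.info("cell-count stage: %d animals", len(table))

    manifest = {
        "package": "famfeed",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
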