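"""File formats, configuration, manifest and the end-to-end pipeline driver.

All tables are RFC-4180 CSV with a mandatory header row; lengths are
serialized in micrometres with six decimal places and angles in degrees, so
write -> read round trips are exact at the recorded precision.  Experiment
configurations are YAML; the run manifest is JSON.  Row ranks are encoded as
integers 1-5 or the literal token ``unranked``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import ImageView, reconstruct_bundle
from .morphometry import classify_tip_link, Link
from .stats import compare_groups
from .synthetic import (
    BundleSpec,
    CohortData,
    NoiseSpec,
    TreatmentSpec,
    default_bundle_spec,
    default_treatment_spec,
    generate_cohort,
    standard_views,
)

__all__ = [
    "MEASUREMENT_COLUMNS",
    "ExperimentConfig",
    "RunManifest",
    "parse_row",
    "read_measurements",
    "write_table",
    "read_table",
    "load_config",
    "config_from_dict",
    "morphometry_tables",
    "run_pipeline",
    "simulate_stage",
    "reconstruct_stage",
    "morphometry_stage",
    "stats_stage",
]

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "bundle_id", "cell_type", "stereocilium_id", "row", "kind", "side",
    "stage_tilt_deg", "parallel_angle_deg", "value_um",
]

_NUMERIC_REQUIRED = ["stage_tilt_deg", "value_um"]
_NUMERIC_OPTIONAL = ["parallel_angle_deg", "row_spacing_um", "noise_sd_um"]

FLOAT_FORMAT = "%.6f"

_VALID_ROWS = {"1": 1, "2": 2, "3": 3, "4": 4, "5": 5, "unranked": "unranked"}


def parse_row(value) -> int | str:
    """Normalize a row-rank token to int 1-5 or the literal 'unranked'."""
    token = str(value).strip()
    try:
        return _VALID_ROWS[token]
    except KeyError:
        raise ValueError(
            f"invalid row rank {value!r}: expected 1-5 or 'unranked'") from None


# ---------------------------------------------------------------------------
# Measurement CSV
# ---------------------------------------------------------------------------


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a measurement-table CSV.

    Rows whose numeric fields do not parse are rejected with their 1-based
    file line numbers; a missing required column raises an error naming it.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty measurement file") from None
    if raw.empty and raw.columns.empty:
        raise ValueError(f"{path}: empty measurement file")
    for col in MEASUREMENT_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"{path}: missing required column {col!r}")

    df = raw.copy()
    bad_lines: list[int] = []
    for col in _NUMERIC_REQUIRED + [c for c in _NUMERIC_OPTIONAL if c in df.columns]:
        text = df[col].str.strip()
        parsed = pd.to_numeric(text.replace("", np.nan), errors="coerce")
        if col in _NUMERIC_REQUIRED:
            bad = parsed.isna()
        else:
            bad = parsed.isna() & (text != "") & text.str.lower().ne("nan")
        # header is file line 1, data starts on line 2
        bad_lines.extend((df.index[bad] + 2).tolist())
        df[col] = parsed
    if bad_lines:
        raise ValueError(
            f"{path}: unparseable numeric values on lines "
            f"{sorted(set(bad_lines))}")

    df["row"] = [parse_row(v) for v in df["row"]]
    return df


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Everything one simulated experiment needs; the seed is mandatory for
    every stochastic stage."""

    seed: int
    bundle_spec: BundleSpec = field(default_factory=BundleSpec)
    treatment_spec: TreatmentSpec = field(default_factory=TreatmentSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_bundles_per_group: int = 10
    views: Optional[list[ImageView]] = None
    output_dir: str = "out"

    def to_dict(self) -> dict:
        d = dict(
            seed=self.seed,
            bundle_spec=_spec_dict(self.bundle_spec),
            treatment_spec=_spec_dict(self.treatment_spec),
            noise=_spec_dict(self.noise),
            n_bundles_per_group=self.n_bundles_per_group,
            views=None if self.views is None else [
                dict(stage_tilt_theta=v.stage_tilt_theta, side=v.side,
                     parallel_angle_theta0=v.parallel_angle_theta0)
                for v in self.views],
            output_dir=self.output_dir,
        )
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _spec_dict(spec) -> dict:
    d = asdict(spec)
    for k, v in d.items():
        if isinstance(v, frozenset):
            d[k] = sorted(v, key=str)
        elif isinstance(v, tuple):
            d[k] = list(v)
    return d


def _build_spec(cls, base, overrides: dict):
    if not overrides:
        return base
    valid = {f.name for f in dc_fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    merged = {**_spec_dict(base), **overrides}
    for k, v in merged.items():
        if isinstance(v, list):
            merged[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
    if "affects_rows" in merged:
        merged["affects_rows"] = frozenset(merged["affects_rows"])
    return cls(**merged)


def config_from_dict(data: dict) -> ExperimentConfig:
    if "seed" not in data:
        raise ValueError("experiment config must declare a seed")
    cell_type = data.get("cell_type", "OHC")
    bundle_spec = _build_spec(BundleSpec, default_bundle_spec(cell_type),
                              data.get("bundle_spec", {}))
    treat = dict(data.get("treatment", {}))
    drug = treat.pop("drug", "benzamil")
    treatment_spec = _build_spec(
        TreatmentSpec, default_treatment_spec(drug, cell_type), treat)
    noise = _build_spec(NoiseSpec, NoiseSpec(), data.get("noise", {}))

    views = None
    vconf = data.get("views")
    if vconf:
        views = standard_views(
            bundle_spec.insertion_tilt_alpha,
            back_taus=tuple(vconf.get("back_taus", (-40.0, -20.0))),
            front_tau=float(vconf.get("front_tau", 40.0)),
        )
    return ExperimentConfig(
        seed=int(data["seed"]),
        bundle_spec=bundle_spec,
        treatment_spec=treatment_spec,
        noise=noise,
        n_bundles_per_group=int(data.get("n_bundles_per_group", 10)),
        views=views,
        output_dir=str(data.get("output_dir", "out")),
    )


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    noise_seed: int
    version: str
    row_counts: dict

    def write(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Morphometry assembly
# ---------------------------------------------------------------------------


def _tip_links_by_stereocilium(links: pd.DataFrame) -> set[str]:
    found: set[str] = set()
    for _, r in links.iterrows():
        link = Link(
            origin_stereocilium_id=str(r["origin_stereocilium_id"]),
            target_stereocilium_id=str(r["target_stereocilium_id"]),
            origin_region=str(r["origin_region"]),
            direction_axis_component=int(r["axis_sign"]),
            elevation_sign=int(r["elevation_sign"]),
        )
        if classify_tip_link(link, parse_row(r["origin_row"]),
                             parse_row(r["target_row"])):
            found.add(str(r["origin_stereocilium_id"]))
    return found


def morphometry_tables(
    reconstruction: pd.DataFrame,
    measurements: pd.DataFrame,
    links: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the tidy per-stereocilium and per-cell morphometry tables.

    Per stereocilium: reconstructed height, height relative to the bundle's
    row-1 mean, staircase step from row 1 (rows 2-3), measured wedge-tip
    height and diameter-profile points.  Per cell: tip-link percentage over
    rows 2-3 and the supernumerary count (rank >= 4 or unranked).
    """
    recon = reconstruction.copy()
    recon["row"] = [parse_row(v) for v in recon["row"]]

    h1 = (recon[recon["row"] == 1].groupby("bundle_id")["height_um"]
          .mean().rename("h1_mean"))
    recon = recon.merge(h1, on="bundle_id", how="left")
    recon["relative_height_pct"] = 100.0 * recon["height_um"] / recon["h1_mean"]
    is23 = recon["row"].isin([2, 3])
    recon["step_from_row1_um"] = np.where(
        is23, recon["h1_mean"] - recon["height_um"], np.nan)

    per_st = recon[["bundle_id", "stereocilium_id", "row", "height_um",
                    "method", "relative_height_pct", "step_from_row1_um"]].copy()

    cell_types = (measurements[["bundle_id", "cell_type"]]
                  .drop_duplicates("bundle_id"))
    per_st = per_st.merge(cell_types, on="bundle_id", how="left")

    wedge = measurements[measurements["kind"] == "wedge_tip"]
    if len(wedge):
        per_st = per_st.merge(
            wedge[["stereocilium_id", "value_um"]]
            .rename(columns={"value_um": "wedge_tip_height_um"}),
            on="stereocilium_id", how="left")
    else:
        per_st["wedge_tip_height_um"] = np.nan

    diam = measurements[measurements["kind"] == "diameter"]
    if len(diam) and "position" in diam.columns:
        wide = (diam.pivot_table(index="stereocilium_id", columns="position",
                                 values="value_um", aggfunc="mean")
                .add_prefix("diameter_"))
        per_st = per_st.merge(wide, on="stereocilium_id", how="left")

    tip_linked = _tip_links_by_stereocilium(links) if links is not None else set()
    per_st["has_tip_link"] = per_st["stereocilium_id"].astype(str).isin(tip_linked)

    # per-cell table
    meas_rows = measurements.copy()
    meas_rows["row"] = [parse_row(v) for v in meas_rows["row"]]
    ids = meas_rows.drop_duplicates("stereocilium_id")[
        ["bundle_id", "cell_type", "stereocilium_id", "row"]]
    cells = []
    for bundle_id, grp in ids.groupby("bundle_id", sort=True):
        short = grp[grp["row"].isin([2, 3])]
        n_short = len(short)
        n_linked = short["stereocilium_id"].astype(str).isin(tip_linked).sum()
        n_super = int(sum(
            (r == "unranked") or (isinstance(r, int) and r >= 4)
            for r in grp["row"]))
        cells.append(dict(
            bundle_id=bundle_id,
            cell_type=grp["cell_type"].iloc[0],
            n_row23=n_short,
            n_with_tip_link=int(n_linked),
            tip_link_pct=(100.0 * n_linked / n_short) if n_short else np.nan,
            n_supernumerary=n_super,
        ))
    per_cell = pd.DataFrame(cells, columns=[
        "bundle_id", "cell_type", "n_row23", "n_with_tip_link",
        "tip_link_pct", "n_supernumerary"])
    return per_st.sort_values(["bundle_id", "stereocilium_id"]).reset_index(drop=True), per_cell


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

_GROUPS = ("control", "treated")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
            logger.info("stage=%s elapsed_s=%.3f", name, time.perf_counter() - t0)
            return result
        wrapped.__name__ = fn.__name__
        wrapped.__doc__ = fn.__doc__
        return wrapped
    return deco


@_stage("simulate")
def simulate_stage(config: ExperimentConfig, out_dir) -> CohortData:
    """Generate the cohort and write measurement/link/ground-truth CSVs."""
    out = Path(out_dir)
    cohort = generate_cohort(config)
    for group in _GROUPS:
        write_table(getattr(cohort, f"{group}_measurements"),
                    out / f"measurements_{group}.csv")
        write_table(getattr(cohort, f"{group}_links"), out / f"links_{group}.csv")
        write_table(getattr(cohort, f"{group}_truth"),
                    out / f"ground_truth_{group}.csv")
    return cohort


@_stage("reconstruct")
def reconstruct_stage(out_dir, row_spacing_d: Optional[float] = None) -> dict:
    """Reconstruct heights from the measurement CSVs in ``out_dir``."""
    out = Path(out_dir)
    recons = {}
    for group in _GROUPS:
        meas = read_measurements(out / f"measurements_{group}.csv")
        proj = meas[meas["kind"].isin(
            ["full_length", "step_1_to_2", "step_1_to_3"])]
        recon = reconstruct_bundle(proj, row_spacing_d=row_spacing_d)
        write_table(recon, out / f"reconstruction_{group}.csv")
        recons[group] = recon
    return recons


@_stage("morphometry")
def morphometry_stage(out_dir) -> dict:
    """Assemble morphometry tables from reconstruction + measurements."""
    out = Path(out_dir)
    tables = {}
    for group in _GROUPS:
        recon = read_table(out / f"reconstruction_{group}.csv")
        meas = read_measurements(out / f"measurements_{group}.csv")
        links_path = out / f"links_{group}.csv"
        links = pd.read_csv(links_path) if links_path.exists() else None
        if links is not None and links.empty:
            links = None
        per_st, per_cell = morphometry_tables(recon, meas, links)
        write_table(per_st, out / f"morphometry_{group}.csv")
        write_table(per_cell, out / f"per_cell_{group}.csv")
        tables[group] = (per_st, per_cell)
    return tables


@_stage("stats")
def stats_stage(out_dir) -> pd.DataFrame:
    """Compare control vs treated morphometry; write the comparison CSV."""
    out = Path(out_dir)
    per_st = []
    per_cell = []
    for group in _GROUPS:
        st = read_table(out / f"morphometry_{group}.csv")
        st["group"] = group
        per_st.append(st)
        pc = read_table(out / f"per_cell_{group}.csv")
        pc["group"] = group
        per_cell.append(pc)
    st = pd.concat(per_st, ignore_index=True)
    pc = pd.concat(per_cell, ignore_index=True)

    st_measures = [c for c in st.columns
                   if c.startswith(("height_um", "relative_height_pct",
                                    "step_from_row1_um", "wedge_tip_height_um",
                                    "diameter_"))]
    cmp_st = compare_groups(st, group_col="group", measures=st_measures,
                            groups=_GROUPS)
    cmp_pc = compare_groups(pc, group_col="group",
                            measures=["tip_link_pct", "n_supernumerary"],
                            row_col="__none__", groups=_GROUPS)
    comparisons = pd.concat([cmp_st, cmp_pc], ignore_index=True)
    write_table(comparisons, out / "comparisons.csv")
    return comparisons


def run_pipeline(config: ExperimentConfig, out_dir=None) -> Path:
    """simulate -> reconstruct -> morphometry -> stats, plus the manifest.

    Re-running with an identical config (and hence identical seeds) yields
    byte-identical CSVs.
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    simulate_stage(config, out)
    reconstruct_stage(out, row_spacing_d=config.bundle_spec.row_spacing_d)
    morphometry_stage(out)
    stats_stage(out)

    counts = {}
    for f in sorted(out.glob("*.csv")):
        counts[f.name] = int(len(pd.read_csv(f)))
    RunManifest(
        config_hash=config.content_hash(),
        seed=config.seed,
        noise_seed=config.noise.seed,
        version=__version__,
        row_counts=counts,
    ).write(out / "manifest.json")
    logger.info("pipeline complete: %s", out)
    return out
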