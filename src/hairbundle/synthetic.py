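"""Synthetic hair-bundle generator, treatment models and SEM forward renderer.

Generates ground-truth 3D staircase bundles (three ranked rows plus
supernumerary stereocilia, shared insertion tilt, inter-row base spacing,
power-law tip profiles, tip links), applies dose-dependent MET-blocker
effect models that shorten and thin rows 2-3 while leaving the tallest row
untouched, and renders noisy projection measurements through the forward
model in :mod:`hairbundle.geometry`.

The blocker dose-response is single-site saturation,
``blocked_fraction = dose / (dose + IC50)``; default IC50s are back-solved
from the expected block at the experimental concentrations (~75% at 100 uM
amiloride, ~90% at 30 uM benzamil), giving 33.33 uM and 3.333 uM.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import Bundle, ImageView, StereociliumGeometry, render_projection
from .morphometry import (
    DEFAULT_DIAMETER_POSITIONS,
    Link,
    SHAFT_SENTINEL,
    TipProfile,
    diameter_profile,
    wedge_tip_height,
)

__all__ = [
    "BundleSpec",
    "TreatmentSpec",
    "NoiseSpec",
    "CohortData",
    "AMILORIDE_IC50_UM",
    "BENZAMIL_IC50_UM",
    "blocked_fraction",
    "default_bundle_spec",
    "default_treatment_spec",
    "generate_bundle",
    "apply_treatment",
    "standard_views",
    "render_experiment",
    "links_table",
    "ground_truth_table",
    "generate_cohort",
]

#: Back-solved from ~75% block at the experimental 100 uM amiloride.
AMILORIDE_IC50_UM = 100.0 / 3.0
#: Back-solved from ~90% block at the experimental 30 uM benzamil.
BENZAMIL_IC50_UM = 10.0 / 3.0


def blocked_fraction(dose: float, ic50: float) -> float:
    """Fraction of the MET current blocked at a given dose.

    Single-site saturation (Hill coefficient 1): ``dose / (dose + ic50)``.
    """
    if ic50 <= 0:
        raise ValueError(f"ic50 must be > 0, got {ic50}")
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    return dose / (dose + ic50)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BundleSpec:
    """Statistical description of one control bundle population.

    Default geometry (outer hair cell: row mean heights 2.4/1.4/0.7 um,
    base spacing d = 0.4 um, insertion tilt 10 degrees) is a package
    fixture chosen to look like a mid-cochlear early-postnatal bundle; all
    recovery scoring is against generated ground truth, never against these
    defaults as truth.
    """

    cell_type: str = "OHC"
    n_per_row: tuple[int, int, int] = (10, 10, 10)
    n_supernumerary_mean: float = 10.9
    row_height_means: tuple[float, float, float] = (2.4, 1.4, 0.7)
    row_height_sds: tuple[float, float, float] = (0.12, 0.10, 0.08)
    insertion_tilt_alpha: float = 10.0
    row_spacing_d: float = 0.4
    shaft_diameters: tuple[float, float, float] = (0.25, 0.20, 0.18)
    tip_profile_defaults: tuple[tuple[float, float], ...] = (
        (0.15, 0.5),  # row 1: blunt, rounded
        (0.20, 1.0),  # row 2: tensioned conical wedge
        (0.20, 1.0),  # row 3
    )
    tip_link_prob: float = 0.95
    supernumerary_height_mean: float = 0.35
    supernumerary_height_sd: float = 0.08

    def __post_init__(self) -> None:
        m1, m2, m3 = self.row_height_means
        if not m1 > m2 > m3 > 0:
            raise ValueError("row_height_means must be strictly decreasing and > 0")
        if any(sd < 0 for sd in self.row_height_sds):
            raise ValueError("row_height_sds must be >= 0")
        if not 0.0 <= self.tip_link_prob <= 1.0:
            raise ValueError("tip_link_prob must be in [0, 1]")


@dataclass(frozen=True)
class TreatmentSpec:
    """Dose-dependent MET-blocker effect model.

    Effects scale with ``f = blocked_fraction(dose, ic50) * duration_scale``.
    Each affected stereocilium either undergoes deep retraction (probability
    ``retract_prob_max * f``; height multiplied by ``1 - U(lo, hi)``) or
    graded shortening (normal loss with mean ``shorten_mean_max * f`` and SD
    ``shorten_sd_max * variance_inflation * f``, truncated at >= 0 loss);
    its tip taper exponent increases by ``taper_gamma_shift_max * f``
    (thinner, more pointed tips).  The tallest row is never affected and
    tip-link presence is unchanged.  ``variance_inflation`` > 1 models
    blockers that broaden the height distribution (amiloride-like);
    ``duration_scale`` < 1 models short incubations realizing a fraction of
    the full effect.
    """

    drug: str = "benzamil"
    dose: float = 30.0
    ic50: float = BENZAMIL_IC50_UM
    retract_prob_max: float = 0.15
    retract_fraction_range: tuple[float, float] = (0.5, 0.9)
    shorten_mean_max: float = 0.45
    shorten_sd_max: float = 0.15
    taper_gamma_shift_max: float = 1.0
    variance_inflation: float = 1.0
    duration_scale: float = 1.0
    affects_rows: frozenset = frozenset({2, 3, "supernumerary"})
    supernumerary_prune_max: float = 0.5

    def __post_init__(self) -> None:
        if 1 in self.affects_rows:
            raise ValueError("the tallest row is never an affected row")
        bf = blocked_fraction(self.dose, self.ic50)
        if not 0.0 <= bf < 1.0:
            raise ValueError("blocked_fraction must lie in [0, 1)")

    @property
    def effect_fraction(self) -> float:
        return blocked_fraction(self.dose, self.ic50) * self.duration_scale


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for the renderer.

    ``projection_noise_cv`` is the coefficient of variation of multiplicative
    Gaussian noise on projected lengths (an examiner's tracing error scales
    with the measured length); diameters get additive Gaussian noise.
    """

    projection_noise_cv: float = 0.05
    diameter_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.projection_noise_cv < 0:
            raise ValueError("projection_noise_cv must be >= 0")
        if self.diameter_noise_sd < 0:
            raise ValueError("diameter_noise_sd must be >= 0")


def default_bundle_spec(cell_type: str = "OHC") -> BundleSpec:
    """Control-condition spec for OHC or IHC bundles.

    IHC stereocilia are taller and thicker, with more supernumerary
    stereocilia per cell.
    """
    if cell_type.upper() == "OHC":
        return BundleSpec()
    if cell_type.upper() == "IHC":
        return BundleSpec(
            cell_type="IHC",
            n_per_row=(8, 8, 8),
            n_supernumerary_mean=25.1,
            row_height_means=(4.0, 2.0, 1.0),
            row_height_sds=(0.20, 0.15, 0.10),
            insertion_tilt_alpha=10.0,
            row_spacing_d=0.5,
            shaft_diameters=(0.40, 0.30, 0.25),
        )
    raise ValueError(f"unknown cell_type {cell_type!r} (expected OHC or IHC)")


def default_treatment_spec(drug: str = "benzamil", cell_type: str = "OHC") -> TreatmentSpec:
    """Named-blocker presets.

    Amiloride blocks less at its working concentration but broadens the
    height distribution; IHC effect magnitudes are smaller than OHC.
    """
    drug = drug.lower()
    if drug == "benzamil":
        spec = TreatmentSpec()
    elif drug == "amiloride":
        spec = TreatmentSpec(drug="amiloride", dose=100.0, ic50=AMILORIDE_IC50_UM,
                             variance_inflation=2.0)
    else:
        raise ValueError(f"no preset for drug {drug!r}")
    if cell_type.upper() == "IHC":
        spec = replace(spec, shorten_mean_max=spec.shorten_mean_max * 0.5,
                       retract_prob_max=spec.retract_prob_max * 0.5)
    return spec


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _truncated_normal(rng: np.random.Generator, mean, sd, size=None,
                      lower: float = 0.0) -> np.ndarray:
    """Normal draws rejected-and-redrawn until strictly above ``lower``."""
    x = np.atleast_1d(rng.normal(mean, sd, size=size)).astype(float)
    if np.all(np.asarray(sd) == 0):
        return x if size is not None else x
    for _ in range(1000):
        bad = x <= lower
        if not bad.any():
            break
        x[bad] = rng.normal(np.broadcast_to(mean, x.shape)[bad] if np.ndim(mean) else mean,
                            np.broadcast_to(sd, x.shape)[bad] if np.ndim(sd) else sd)
    return x


_SUPER_ROWS = np.array([4, 5, -1])  # -1 encodes "unranked"


def generate_bundle(spec: BundleSpec, seed: int, bundle_id: str = "b0") -> Bundle:
    """Draw one ground-truth bundle; a pure function of (spec, seed)."""
    rng = np.random.default_rng(seed)
    stereocilia: list[StereociliumGeometry] = []

    for row_idx in range(3):
        row = row_idx + 1
        n = spec.n_per_row[row_idx]
        heights = _truncated_normal(rng, spec.row_height_means[row_idx],
                                    spec.row_height_sds[row_idx], size=n)
        L, gamma = spec.tip_profile_defaults[row_idx]
        for k in range(n):
            stereocilia.append(StereociliumGeometry(
                id=f"{bundle_id}_r{row}_{k}",
                row=row,
                height_h=float(heights[k]),
                base_offset=-(row - 1) * spec.row_spacing_d,
                shaft_diameter=spec.shaft_diameters[row_idx],
                tip_profile=TipProfile(L, gamma),
            ))

    n_super = int(rng.poisson(spec.n_supernumerary_mean))
    if n_super:
        ranks = rng.choice(_SUPER_ROWS, size=n_super, p=(0.4, 0.3, 0.3))
        heights = _truncated_normal(rng, spec.supernumerary_height_mean,
                                    spec.supernumerary_height_sd, size=n_super)
        for k in range(n_super):
            row = "unranked" if ranks[k] == -1 else int(ranks[k])
            offset_rank = 3 if row == "unranked" else row - 1
            stereocilia.append(StereociliumGeometry(
                id=f"{bundle_id}_s_{k}",
                row=row,
                height_h=float(heights[k]),
                base_offset=-offset_rank * spec.row_spacing_d,
                shaft_diameter=spec.shaft_diameters[2] * 0.8,
                tip_profile=TipProfile(0.1, 0.5),
            ))

    bundle = Bundle(
        id=bundle_id,
        cell_type=spec.cell_type,
        insertion_tilt_alpha=spec.insertion_tilt_alpha,
        row_spacing_d=spec.row_spacing_d,
        stereocilia=stereocilia,
    )
    _assign_tip_links(bundle, spec.tip_link_prob, rng)
    return bundle


def _assign_tip_links(bundle: Bundle, tip_link_prob: float,
                      rng: np.random.Generator) -> None:
    """Bernoulli tip links from rows 2-3 toward the next taller row, plus
    occasional lateral shaft links that must classify as non-tip links."""
    by_row: dict = {}
    for s in bundle.stereocilia:
        by_row.setdefault(s.row, []).append(s)
    for row in (2, 3):
        taller = by_row.get(row - 1, [])
        for idx, s in enumerate(by_row.get(row, [])):
            if taller and rng.random() < tip_link_prob:
                target = taller[min(idx, len(taller) - 1)]
                s.links.append(Link(
                    origin_stereocilium_id=s.id,
                    target_stereocilium_id=target.id,
                    origin_region="top_cap",
                    direction_axis_component=+1,
                    elevation_sign=+1,
                ))
            peers = by_row[row]
            if len(peers) > 1 and rng.random() < 0.3:
                neighbor = peers[(idx + 1) % len(peers)]
                s.links.append(Link(
                    origin_stereocilium_id=s.id,
                    target_stereocilium_id=neighbor.id,
                    origin_region="shaft",
                    direction_axis_component=0,
                    elevation_sign=0,
                ))


def apply_treatment(bundle: Bundle, treatment: TreatmentSpec, seed: int) -> Bundle:
    """Apply a dose-dependent blocker model; returns a new Bundle.

    Row-1 stereocilia are carried over untouched (exact invariance, not
    statistical); tip-link presence is unchanged.  Supernumerary stereocilia
    are additionally thinned (removed) with probability
    ``supernumerary_prune_max * f`` when the treatment affects them.
    """
    rng = np.random.default_rng(seed)
    f = treatment.effect_fraction
    out: list[StereociliumGeometry] = []

    for s in bundle.stereocilia:
        affected = (
            (isinstance(s.row, int) and s.row in treatment.affects_rows)
            or (s.is_supernumerary and "supernumerary" in treatment.affects_rows)
        )
        s2 = copy.deepcopy(s)
        if affected and f > 0:
            if s2.is_supernumerary and rng.random() < treatment.supernumerary_prune_max * f:
                continue  # pruned
            if rng.random() < treatment.retract_prob_max * f:
                lo, hi = treatment.retract_fraction_range
                s2.height_h = s2.height_h * (1.0 - rng.uniform(lo, hi))
            else:
                loss = float(_truncated_normal(
                    rng, treatment.shorten_mean_max * f,
                    treatment.shorten_sd_max * treatment.variance_inflation * f,
                    size=1, lower=0.0)[0]) if treatment.shorten_mean_max * f > 0 else 0.0
                s2.height_h = max(s2.height_h - max(loss, 0.0), 0.05)
            profile = s2.tip_profile or TipProfile()
            s2.tip_profile = TipProfile(
                profile.tip_length_L,
                profile.taper_gamma + treatment.taper_gamma_shift_max * f,
            )
        out.append(s2)

    return Bundle(
        id=bundle.id,
        cell_type=bundle.cell_type,
        cochlear_position=bundle.cochlear_position,
        insertion_tilt_alpha=bundle.insertion_tilt_alpha,
        row_spacing_d=bundle.row_spacing_d,
        stereocilia=out,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def standard_views(alpha: float, back_taus: Sequence[float] = (-40.0, -20.0),
                   front_tau: float = 40.0) -> list[ImageView]:
    """The acquisition plan the reconstruction cascade expects: two lateral
    ("back") views at negative angles of view with the parallel angle
    determined, and one medial ("front") view for step projections."""
    views = [ImageView(alpha + t, side="lateral", parallel_angle_theta0=alpha)
             for t in back_taus]
    views.append(ImageView(alpha + front_tau, side="medial",
                           parallel_angle_theta0=alpha))
    return views


_MEAS_COLUMNS = [
    "bundle_id", "cell_type", "stereocilium_id", "row", "kind", "side",
    "stage_tilt_deg", "parallel_angle_deg", "value_um", "position",
    "row_spacing_um",
]


def render_experiment(
    bundles: Iterable[Bundle],
    views: Sequence[ImageView],
    noise: NoiseSpec,
    diameter_positions: Sequence = DEFAULT_DIAMETER_POSITIONS,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Render a tidy measurement table from ground-truth bundles.

    Full-length projections of every stereocilium are measured in each
    lateral/top view; step projections of rows 2-3 and tip measurements
    (diameter profile points and the wedge-tip height) are measured in the
    first medial view.  Projections carry multiplicative Gaussian noise of
    the given CV; tip measurements carry additive noise.  Deterministic
    given the noise seed.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    rows: list[dict] = []

    def noisy_p(value: float) -> float:
        return value * (1.0 + rng.normal(0.0, noise.projection_noise_cv)) \
            if noise.projection_noise_cv > 0 else value

    def noisy_d(value: float) -> float:
        return value + rng.normal(0.0, noise.diameter_noise_sd) \
            if noise.diameter_noise_sd > 0 else value

    for bundle in bundles:
        front = next((v for v in views if v.side == "medial"), None)
        for view in views:
            if view.side == "medial":
                continue
            for s in bundle.stereocilia:
                p = render_projection(s, bundle, view, "full_length")
                rows.append(_meas_row(bundle, s.id, s.row, "full_length", view,
                                      noisy_p(p)))
        if front is not None:
            for s in bundle.stereocilia:
                if s.row in (2, 3):
                    kind = f"step_1_to_{s.row}"
                    p = render_projection(s, bundle, front, kind)
                    rows.append(_meas_row(bundle, s.id, s.row, kind, front,
                                          noisy_p(p)))
                if s.row in (1, 2, 3):
                    profile = s.tip_profile or TipProfile()
                    for pos, dia in zip(
                            diameter_positions,
                            diameter_profile(profile, s.shaft_diameter,
                                             diameter_positions)):
                        label = pos if isinstance(pos, str) else f"{pos:g}um"
                        rows.append(_meas_row(bundle, s.id, s.row, "diameter",
                                              front, noisy_d(dia), position=label))
                    rows.append(_meas_row(
                        bundle, s.id, s.row, "wedge_tip", front,
                        noisy_d(wedge_tip_height(profile, s.shaft_diameter))))
    return pd.DataFrame(rows, columns=_MEAS_COLUMNS)


def _meas_row(bundle: Bundle, sid: str, row, kind: str, view: ImageView,
              value: float, position: str = "") -> dict:
    return dict(
        bundle_id=bundle.id,
        cell_type=bundle.cell_type,
        stereocilium_id=sid,
        row=row,
        kind=kind,
        side=view.side,
        stage_tilt_deg=view.stage_tilt_theta,
        parallel_angle_deg=(np.nan if view.parallel_angle_theta0 is None
                            else view.parallel_angle_theta0),
        value_um=value,
        position=position,
        row_spacing_um=bundle.row_spacing_d,
    )


def links_table(bundles: Iterable[Bundle]) -> pd.DataFrame:
    """Per-link annotation table for the tip-link classifier."""
    rows = []
    for bundle in bundles:
        rows_by_id = {s.id: s.row for s in bundle.stereocilia}
        for s in bundle.stereocilia:
            for link in s.links:
                rows.append(dict(
                    bundle_id=bundle.id,
                    origin_stereocilium_id=link.origin_stereocilium_id,
                    origin_row=rows_by_id[link.origin_stereocilium_id],
                    target_stereocilium_id=link.target_stereocilium_id,
                    target_row=rows_by_id[link.target_stereocilium_id],
                    origin_region=link.origin_region,
                    axis_sign=link.direction_axis_component,
                    elevation_sign=link.elevation_sign,
                ))
    return pd.DataFrame(rows, columns=[
        "bundle_id", "origin_stereocilium_id", "origin_row",
        "target_stereocilium_id", "target_row", "origin_region", "axis_sign",
        "elevation_sign"])


def ground_truth_table(bundles: Iterable[Bundle]) -> pd.DataFrame:
    """Hidden ground truth for recovery scoring."""
    rows = []
    for bundle in bundles:
        rows_by_id = {s.id: s.row for s in bundle.stereocilia}
        for s in bundle.stereocilia:
            profile = s.tip_profile or TipProfile()
            has_tl = any(
                link.origin_region == "top_cap"
                for link in s.links
            )
            rows.append(dict(
                bundle_id=bundle.id,
                cell_type=bundle.cell_type,
                stereocilium_id=s.id,
                row=s.row,
                height_um=s.height_h,
                shaft_diameter_um=s.shaft_diameter,
                tip_length_um=profile.tip_length_L,
                taper_gamma=profile.taper_gamma,
                has_tip_link=has_tl,
                supernumerary=s.is_supernumerary,
                insertion_tilt_deg=bundle.insertion_tilt_alpha,
                row_spacing_um=bundle.row_spacing_d,
            ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortData:
    """Parallel control/treated datasets plus hidden ground truth."""

    control_measurements: pd.DataFrame
    treated_measurements: pd.DataFrame
    control_links: pd.DataFrame
    treated_links: pd.DataFrame
    control_truth: pd.DataFrame
    treated_truth: pd.DataFrame


def generate_cohort(config) -> CohortData:
    """Generate a paired control/treated experiment from an experiment
    config (see :class:`hairbundle.io.ExperimentConfig`).

    Control and treated bundles are drawn from the same spec with distinct
    child seeds (parallel processing of independent explants); the treatment
    model is then applied to the treated arm only.  The structure seed
    (``config.seed``) and the noise seed (``config.noise.seed``) are
    separated so that measurement noise can be re-rolled without changing
    the ground truth.
    """
    spec: BundleSpec = config.bundle_spec
    treatment: TreatmentSpec = config.treatment_spec
    noise: NoiseSpec = config.noise
    n = int(config.n_bundles_per_group)

    ss = np.random.SeedSequence(int(config.seed))
    seeds = ss.generate_state(2 * n + n, dtype=np.uint32)
    control = [generate_bundle(spec, int(seeds[i]), bundle_id=f"ctl{i}")
               for i in range(n)]
    treated_base = [generate_bundle(spec, int(seeds[n + i]), bundle_id=f"trt{i}")
                    for i in range(n)]
    treated = [apply_treatment(b, treatment, int(seeds[2 * n + i]))
               for i, b in enumerate(treated_base)]

    views = getattr(config, "views", None) or standard_views(spec.insertion_tilt_alpha)
    noise_rng = np.random.default_rng(noise.seed)
    return CohortData(
        control_measurements=render_experiment(control, views, noise, rng=noise_rng),
        treated_measurements=render_experiment(treated, views, noise, rng=noise_rng),
        control_links=links_table(control),
        treated_links=links_table(treated),
        control_truth=ground_truth_table(control),
        treated_truth=ground_truth_table(treated),
    )
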