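"""Synthetic STGD1/control cohort and segmentation-surface generators.

The cohort generator inverts the longitudinal analysis model: each
(layer, subfield) thickness trajectory is linear in years since baseline,
with group-specific baseline means and rates, patient-level and
eye-within-patient random intercepts and slopes, and three measurement
rows per true value — two independent graders and an uncorrected
automated segmentation with a layer-specific bias. Ground truth (the
realized random effects and noiseless trajectories) is recorded so that
parameter-recovery tests can compare fitted estimates against what was
actually simulated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GRID, ETDRSGrid, SurfaceStack
from .layers import DEFAULT_SCHEME, LayerScheme
from .reference import BASELINE_PROFILE, DEFAULT_SLOPE_DIFF, DEFAULT_UNCORRECTED_BIAS

__all__ = [
    "LayerEffects",
    "VarianceComponents",
    "GraderModel",
    "CohortParams",
    "GroundTruth",
    "simulate_cohort",
    "GridSpec",
    "RadialStepProfile",
    "simulate_surfaces",
    "default_fixed_effects",
]


@dataclass(frozen=True)
class LayerEffects:
    """Fixed effects for one (layer, subfield): µm and µm/yr."""

    control_mean: float
    group_diff: float = 0.0
    control_slope: float = 0.0
    slope_diff: float = 0.0
    laterality_effect: float = 0.0


@dataclass(frozen=True)
class VarianceComponents:
    """Random-effect SDs (µm, µm/yr) and intercept-slope correlations."""

    sd_patient_intercept: float = 8.0
    sd_patient_slope: float = 0.6
    corr_patient: float = 0.0
    sd_eye_intercept: float = 3.0
    sd_eye_slope: float = 0.3
    corr_eye: float = 0.0
    sd_residual: float = 2.5

    def validate(self) -> None:
        for name in ("sd_patient_intercept", "sd_patient_slope",
                     "sd_eye_intercept", "sd_eye_slope", "sd_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"variance_components.{name} must be >= 0")
        for name in ("corr_patient", "corr_eye"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"variance_components.{name} must be in [-1, 1]")

    def cov(self, level: str) -> np.ndarray:
        if level == "patient":
            s1, s2, r = self.sd_patient_intercept, self.sd_patient_slope, self.corr_patient
        else:
            s1, s2, r = self.sd_eye_intercept, self.sd_eye_slope, self.corr_eye
        return np.array([[s1 ** 2, r * s1 * s2], [r * s1 * s2, s2 ** 2]])


@dataclass(frozen=True)
class GraderModel:
    """Measurement model: grader noise and uncorrected-segmentation bias.

    ``uncorrected_bias`` maps a layer name (or a (layer, subfield) pair)
    to the systematic µm offset of the automated segmentation relative to
    the grader-corrected truth.
    """

    uncorrected_bias: dict = field(
        default_factory=lambda: dict(DEFAULT_UNCORRECTED_BIAS)
    )
    sd_uncorrected: float = 3.0
    sd_grader: float = 1.5

    def validate(self) -> None:
        if self.sd_uncorrected < 0:
            raise ValueError("grader_model.sd_uncorrected must be >= 0")
        if self.sd_grader < 0:
            raise ValueError("grader_model.sd_grader must be >= 0")

    def bias_for(self, layer: str, subfield: str) -> float:
        if (layer, subfield) in self.uncorrected_bias:
            return float(self.uncorrected_bias[(layer, subfield)])
        return float(self.uncorrected_bias.get(layer, 0.0))


def default_fixed_effects(
    slope_diff: dict[str, float] | None = None,
) -> dict[tuple[str, str], LayerEffects]:
    """Fixed effects at the published cohort's baseline profile.

    Control slopes default to 0 (stable controls); STGD1 rate differences
    follow the per-layer defaults (outer-retina thinning dominated by the
    ONL, slight INL thickening).
    """
    sd = dict(DEFAULT_SLOPE_DIFF)
    if slope_diff:
        sd.update(slope_diff)
    return {
        (layer, subfield): LayerEffects(
            control_mean=mean,
            group_diff=diff,
            control_slope=0.0,
            slope_diff=sd.get(layer, 0.0),
        )
        for (layer, subfield), (mean, diff) in BASELINE_PROFILE.items()
    }


@dataclass
class CohortParams:
    """Generative parameters of a two-group longitudinal OCT cohort."""

    n_patients_control: int = 40
    n_patients_stgd: int = 63
    p_both_eyes: float = 0.45
    followup_years_range: tuple[float, float] = (1.2, 8.2)
    fixed_effects: dict[tuple[str, str], LayerEffects] = field(
        default_factory=default_fixed_effects
    )
    variance_components: VarianceComponents = field(default_factory=VarianceComponents)
    grader_model: GraderModel = field(default_factory=GraderModel)
    n_visits: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients_control < 1:
            raise ValueError("n_patients_control must be >= 1")
        if self.n_patients_stgd < 0:
            raise ValueError("n_patients_stgd must be >= 0")
        if not 0.0 <= self.p_both_eyes <= 1.0:
            raise ValueError("p_both_eyes must be a probability")
        lo, hi = self.followup_years_range
        if lo < 1.0:
            raise ValueError(
                "followup_years_range minimum must be >= 1.0 years "
                "(scan pairs are at least 12 months apart)"
            )
        if hi < lo:
            raise ValueError("followup_years_range must be (min, max) with max >= min")
        if self.n_visits < 2:
            raise ValueError("n_visits must be >= 2")
        if not self.fixed_effects:
            raise ValueError("fixed_effects must not be empty")
        for key, fe in self.fixed_effects.items():
            if not isinstance(fe, LayerEffects):
                raise ValueError(f"fixed_effects[{key}] must be a LayerEffects")
        self.variance_components.validate()
        self.grader_model.validate()


@dataclass
class GroundTruth:
    """Realized random effects and noiseless trajectories of one cohort."""

    params: CohortParams
    patients: pd.DataFrame      # patient_id, group, n_eyes
    patient_effects: pd.DataFrame  # patient_id, layer, subfield, intercept, slope
    eye_effects: pd.DataFrame   # patient_id, eye, followup_years, layer, subfield, intercept, slope
    truth: pd.DataFrame         # noiseless thickness per (patient, eye, visit, layer, subfield)

    def to_json(self, path: str | Path) -> None:
        fe = {
            f"{l}|{s}": asdict(v) for (l, s), v in self.params.fixed_effects.items()
        }
        gm = asdict(self.params.grader_model)
        gm["uncorrected_bias"] = {
            (k if isinstance(k, str) else f"{k[0]}|{k[1]}"): v
            for k, v in self.params.grader_model.uncorrected_bias.items()
        }
        payload = {
            "params": {
                "n_patients_control": self.params.n_patients_control,
                "n_patients_stgd": self.params.n_patients_stgd,
                "p_both_eyes": self.params.p_both_eyes,
                "followup_years_range": list(self.params.followup_years_range),
                "fixed_effects": fe,
                "variance_components": asdict(self.params.variance_components),
                "grader_model": gm,
                "n_visits": self.params.n_visits,
                "seed": self.params.seed,
            },
            "patients": self.patients.to_dict(orient="list"),
            "patient_effects": self.patient_effects.to_dict(orient="list"),
            "eye_effects": self.eye_effects.to_dict(orient="list"),
            "truth": self.truth.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))


def simulate_cohort(params: CohortParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a long-format cohort table plus its ground truth.

    For each patient: a group label, one or two eyes, and ``n_visits``
    scans per eye (baseline at year 0, follow-up(s) up to a per-eye
    interval drawn uniformly from ``followup_years_range``). For each
    (eye, visit, layer, subfield) the noiseless truth is the fixed part
    plus patient and eye random effects; three measurement rows are
    emitted per truth value (grader A, grader B, uncorrected). The output
    is deterministic under ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    vc = params.variance_components
    gm = params.grader_model
    keys = list(params.fixed_effects)
    n_keys = len(keys)

    cov_p = vc.cov("patient")
    cov_e = vc.cov("eye")

    patients = []
    pat_eff_rows = []
    eye_eff_rows = []
    truth_rows = []
    records = []

    groups = (["control"] * params.n_patients_control
              + ["stgd1"] * params.n_patients_stgd)
    for idx, group in enumerate(groups):
        pid = f"{'C' if group == 'control' else 'S'}{idx:04d}"
        both = rng.random() < params.p_both_eyes
        if both:
            eyes = ["OD", "OS"]
        else:
            eyes = ["OD" if rng.random() < 0.5 else "OS"]
        patients.append({"patient_id": pid, "group": group, "n_eyes": len(eyes)})

        # one (intercept, slope) pair per (layer, subfield), independent
        # across layer/subfield combinations
        p_eff = rng.multivariate_normal([0.0, 0.0], cov_p, size=n_keys)
        for (layer, subfield), (pi, ps) in zip(keys, p_eff):
            pat_eff_rows.append(
                {"patient_id": pid, "layer": layer, "subfield": subfield,
                 "intercept": pi, "slope": ps}
            )

        for eye in eyes:
            followup = rng.uniform(*params.followup_years_range)
            if params.n_visits == 2:
                visit_years = np.array([0.0, followup])
            else:
                interior = np.sort(
                    rng.uniform(0.0, followup, size=params.n_visits - 2)
                )
                visit_years = np.r_[0.0, interior, followup]
            e_eff = rng.multivariate_normal([0.0, 0.0], cov_e, size=n_keys)
            for (layer, subfield), (ei, es) in zip(keys, e_eff):
                eye_eff_rows.append(
                    {"patient_id": pid, "eye": eye, "followup_years": followup,
                     "layer": layer, "subfield": subfield,
                     "intercept": ei, "slope": es}
                )

            for visit_index, years in enumerate(visit_years):
                for k, (layer, subfield) in enumerate(keys):
                    fe = params.fixed_effects[(layer, subfield)]
                    is_stgd = group == "stgd1"
                    mean = (
                        fe.control_mean
                        + (fe.group_diff if is_stgd else 0.0)
                        + (fe.control_slope + (fe.slope_diff if is_stgd else 0.0)) * years
                        + (fe.laterality_effect if eye == "OS" else 0.0)
                    )
                    truth = (mean + p_eff[k, 0] + p_eff[k, 1] * years
                             + e_eff[k, 0] + e_eff[k, 1] * years)
                    truth_rows.append(
                        {"patient_id": pid, "eye": eye, "visit_index": visit_index,
                         "years_since_baseline": years, "layer": layer,
                         "subfield": subfield, "thickness_um": truth}
                    )
                    base = {
                        "patient_id": pid, "group": group, "eye": eye,
                        "visit_index": visit_index,
                        "years_since_baseline": years,
                        "layer": layer, "subfield": subfield,
                    }
                    noise = rng.normal(0.0, 1.0, size=4)
                    # scan-level deviation: shared by every source measuring
                    # this scan (it cancels in between-source differences but
                    # contributes to the longitudinal residual)
                    scan = truth + vc.sd_residual * noise[3]
                    records.append(
                        {**base, "source": "grader_a",
                         "thickness_um": scan + gm.sd_grader * noise[0]}
                    )
                    records.append(
                        {**base, "source": "grader_b",
                         "thickness_um": scan + gm.sd_grader * noise[1]}
                    )
                    records.append(
                        {**base, "source": "uncorrected",
                         "thickness_um": scan + gm.bias_for(layer, subfield)
                         + gm.sd_uncorrected * noise[2]}
                    )

    cols = ["patient_id", "group", "eye", "visit_index", "years_since_baseline",
            "source", "layer", "subfield", "thickness_um"]
    table = pd.DataFrame(records)[cols]
    gt = GroundTruth(
        params=params,
        patients=pd.DataFrame(patients),
        patient_effects=pd.DataFrame(pat_eff_rows),
        eye_effects=pd.DataFrame(eye_eff_rows),
        truth=pd.DataFrame(truth_rows),
    )
    return table, gt


# ---------------------------------------------------------------------------
# Segmentation-surface fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """B-scan/A-scan counts, mm spacings and fovea position of a volume."""

    n_bscans: int = 61
    n_ascans: int = 61
    spacing_bscan_mm: float = 0.1
    spacing_ascan_mm: float = 0.1
    fovea: tuple[float, float] | None = None  # defaults to grid center

    def fovea_or_center(self) -> tuple[float, float]:
        if self.fovea is not None:
            return self.fovea
        return ((self.n_bscans - 1) / 2.0, (self.n_ascans - 1) / 2.0)


class RadialStepProfile:
    """Piecewise-constant thickness as a function of radial distance (mm).

    ``breaks`` are the step radii; ``values`` has one more entry than
    ``breaks``: values[i] applies for breaks[i-1] < r <= breaks[i].
    """

    def __init__(self, breaks: Sequence[float], values: Sequence[float]):
        if len(values) != len(breaks) + 1:
            raise ValueError("need len(values) == len(breaks) + 1")
        self.breaks = np.asarray(breaks, dtype=float)
        self.values = np.asarray(values, dtype=float)

    def __call__(self, r: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.breaks, r, side="left")
        return self.values[idx]


def simulate_surfaces(
    layer_thickness_profile: Sequence[float | Callable[[np.ndarray], np.ndarray]],
    grid_spec: GridSpec = GridSpec(),
    seed: int = 0,
    noise_sd_um: float = 0.0,
    eye_laterality: str = "OD",
    grid: ETDRSGrid = DEFAULT_GRID,
    scheme: LayerScheme = DEFAULT_SCHEME,
) -> tuple[SurfaceStack, pd.DataFrame]:
    """Build an 11-surface stack from per-sublayer radial thickness profiles.

    ``layer_thickness_profile`` gives, per raw sublayer (10 entries), either
    a constant thickness (µm) or a callable of radial distance (mm).
    Surfaces are cumulative sums of the sublayer thicknesses, so they never
    cross. Alongside the stack, the expected subfield means implied by the
    noiseless profiles are returned (computed by direct pixel enumeration
    with the same membership rule the extractor uses), for testing.
    """
    if len(layer_thickness_profile) != len(scheme.raw_sublayers):
        raise ValueError(
            f"need {len(scheme.raw_sublayers)} sublayer profiles, "
            f"got {len(layer_thickness_profile)}"
        )
    nb, na = grid_spec.n_bscans, grid_spec.n_ascans
    fovea = grid_spec.fovea_or_center()
    b = (np.arange(nb) - fovea[0]) * grid_spec.spacing_bscan_mm
    a = (np.arange(na) - fovea[1]) * grid_spec.spacing_ascan_mm
    r = np.hypot(b[:, None], a[None, :])

    thick = []
    for prof in layer_thickness_profile:
        t = prof(r) if callable(prof) else np.full((nb, na), float(prof))
        t = np.asarray(t, dtype=float)
        if (t < 0).any():
            bb, aa = map(int, np.argwhere(t < 0)[0])
            raise ValueError(f"negative sublayer thickness at pixel (b={bb}, a={aa})")
        thick.append(t)

    surfaces = np.zeros((len(thick) + 1, nb, na))
    for k, t in enumerate(thick):
        surfaces[k + 1] = surfaces[k] + t
    if noise_sd_um > 0:
        rng = np.random.default_rng(seed)
        # a common axial jitter per pixel keeps surfaces non-crossing
        surfaces += rng.normal(0.0, noise_sd_um, size=(nb, na))[None, :, :]

    stack = SurfaceStack(
        surfaces=surfaces,
        spacing_bscan_mm=grid_spec.spacing_bscan_mm,
        spacing_ascan_mm=grid_spec.spacing_ascan_mm,
        fovea=fovea,
        eye_laterality=eye_laterality,
    )

    # expected subfield means by direct enumeration of the noiseless profiles
    per_layer: dict[str, np.ndarray] = {}
    for name, t in zip(scheme.raw_sublayers, thick):
        per_layer[name] = t
    merged: dict[str, np.ndarray] = {}
    for name in scheme.analyzed_layers:
        if name == "OS":
            merged["OS"] = sum(per_layer[s] for s in scheme.os_merge)
        else:
            merged[name] = per_layer[name]
    for cname, parts in scheme.combined.items():
        merged[cname] = sum(merged[p] for p in parts)
    masks = grid.subfield_masks(r)
    exp_rows = []
    for subfield, mask in masks.items():
        for name, t in merged.items():
            val = float(t[mask].mean()) if mask.any() else np.nan
            exp_rows.append({"layer": name, "subfield": subfield,
                             "expected_um": val, "n_pixels": int(mask.sum())})
    return stack, pd.DataFrame(exp_rows)
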