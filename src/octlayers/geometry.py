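"""ETDRS-grid sublayer thickness extraction from segmented OCT surfaces.

A segmented macular volume is represented as a stack of 11 boundary
surfaces (depth grids over B-scan x A-scan positions, inner to outer).
Per-pixel sublayer thickness is the depth difference between consecutive
surfaces; subfield means are unweighted averages of the pixels whose
centers fall inside each ETDRS zone (center disc of 1 mm diameter, inner
ring 1-3 mm, outer ring 3-6 mm), measured in millimetres from the fovea
with anisotropic pixel spacing.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .layers import DEFAULT_SCHEME, LayerScheme

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceStack",
    "ETDRSGrid",
    "extract_subfield_thickness",
    "combine_layers",
    "grader_average",
    "save_surface_stack",
    "load_surface_stack",
]


@dataclass
class SurfaceStack:
    """One eye/visit's segmentation: 11 surface depth grids plus geometry.

    Parameters
    ----------
    surfaces : ndarray, shape (11, n_bscans, n_ascans)
        Depth of each boundary surface in µm from an arbitrary axial
        reference, ordered inner (ILM) to outer (outer RPE boundary).
    spacing_bscan_mm, spacing_ascan_mm : float
        Physical distance between adjacent B-scans / A-scans, mm.
    fovea : (float, float)
        Continuous 0-based (b, a) grid coordinates of the fovea.
    eye_laterality : str
        "OD" or "OS".
    missing_mask : ndarray of bool, shape (n_bscans, n_ascans), optional
        True where the pixel carries valid segmentation. Defaults to all
        valid.
    """

    surfaces: np.ndarray
    spacing_bscan_mm: float
    spacing_ascan_mm: float
    fovea: tuple[float, float]
    eye_laterality: str = "OD"
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.surfaces = np.asarray(self.surfaces, dtype=float)
        if self.surfaces.ndim != 3:
            raise ValueError("surfaces must be a (n_surfaces, n_bscans, n_ascans) array")
        if self.missing_mask is None:
            self.missing_mask = np.ones(self.surfaces.shape[1:], dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.surfaces.shape[1:]:
                raise ValueError("missing_mask shape does not match surface grids")
        if self.spacing_bscan_mm <= 0 or self.spacing_ascan_mm <= 0:
            raise ValueError("pixel spacings must be positive")
        nb, na = self.surfaces.shape[1:]
        fb, fa = self.fovea
        if not (0 <= fb <= nb - 1 and 0 <= fa <= na - 1):
            raise ValueError(f"fovea {self.fovea} outside grid ({nb} x {na})")
        if self.eye_laterality not in ("OD", "OS"):
            raise ValueError(f"eye_laterality must be OD or OS, got {self.eye_laterality!r}")
        self._check_monotone()

    def _check_monotone(self) -> None:
        diffs = np.diff(self.surfaces, axis=0)
        bad = (diffs < -1e-9) & self.missing_mask[None, :, :]
        if bad.any():
            k, b, a = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"crossing surfaces: surface {k + 1} above surface {k} "
                f"at pixel (b={b}, a={a})"
            )

    @property
    def n_bscans(self) -> int:
        return self.surfaces.shape[1]

    @property
    def n_ascans(self) -> int:
        return self.surfaces.shape[2]

    def radial_distance_mm(self) -> np.ndarray:
        """Euclidean distance of every pixel center from the fovea, mm."""
        b = (np.arange(self.n_bscans) - self.fovea[0]) * self.spacing_bscan_mm
        a = (np.arange(self.n_ascans) - self.fovea[1]) * self.spacing_ascan_mm
        return np.hypot(b[:, None], a[None, :])


@dataclass(frozen=True)
class ETDRSGrid:
    """ETDRS subfield radii (mm) and the minimum pixel coverage required
    before a subfield mean is reported rather than emitted as missing."""

    center_radius_mm: float = 0.5
    inner_radius_mm: float = 1.5
    outer_radius_mm: float = 3.0
    min_coverage_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.center_radius_mm < self.inner_radius_mm < self.outer_radius_mm):
            raise ValueError("ETDRS radii must satisfy 0 < center < inner < outer")
        if not (0 <= self.min_coverage_fraction <= 1):
            raise ValueError("min_coverage_fraction must be a probability")

    def subfield_masks(self, r: np.ndarray) -> dict[str, np.ndarray]:
        """Half-open annulus membership: r <= 0.5 center; 0.5 < r <= 1.5
        inner ring; 1.5 < r <= 3.0 outer ring."""
        return {
            "center": r <= self.center_radius_mm,
            "inner_ring": (r > self.center_radius_mm) & (r <= self.inner_radius_mm),
            "outer_ring": (r > self.inner_radius_mm) & (r <= self.outer_radius_mm),
        }

    def subfield_area_mm2(self, subfield: str) -> float:
        r = {
            "center": (0.0, self.center_radius_mm),
            "inner_ring": (self.center_radius_mm, self.inner_radius_mm),
            "outer_ring": (self.inner_radius_mm, self.outer_radius_mm),
        }[subfield]
        return float(np.pi * (r[1] ** 2 - r[0] ** 2))


DEFAULT_GRID = ETDRSGrid()


def extract_subfield_thickness(
    stack: SurfaceStack,
    grid: ETDRSGrid = DEFAULT_GRID,
    scheme: LayerScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Mean sublayer thickness per ETDRS subfield.

    Returns one row per (layer, subfield) for the 9 analyzed layers plus
    the two combined layers, with columns ``layer``, ``subfield``,
    ``thickness_um`` (NaN when coverage is insufficient), ``n_pixels`` and
    ``coverage``. Coverage is the valid-pixel area within the subfield
    relative to the subfield's analytic area, so truncated or masked scans
    yield missing subfields rather than extrapolated means.
    """
    if stack.surfaces.shape[0] != scheme.n_surfaces:
        raise ValueError(
            f"expected {scheme.n_surfaces} surfaces, got {stack.surfaces.shape[0]}"
        )
    per_pixel = {
        name: stack.surfaces[k + 1] - stack.surfaces[k]
        for k, name in enumerate(scheme.raw_sublayers)
    }
    # merge the outer-segment sub-bands
    merged = {}
    for name in scheme.analyzed_layers:
        if name == "OS":
            merged["OS"] = sum(per_pixel[s] for s in scheme.os_merge)
        else:
            merged[name] = per_pixel[name]
    for cname, parts in scheme.combined.items():
        merged[cname] = sum(merged[p] for p in parts)

    r = stack.radial_distance_mm()
    masks = grid.subfield_masks(r)
    pixel_area = stack.spacing_bscan_mm * stack.spacing_ascan_mm
    valid = stack.missing_mask

    rows = []
    for subfield, member in masks.items():
        sel = member & valid
        n = int(sel.sum())
        coverage = n * pixel_area / grid.subfield_area_mm2(subfield)
        ok = coverage >= grid.min_coverage_fraction and n > 0
        for name in tuple(scheme.analyzed_layers) + tuple(scheme.combined):
            val = float(merged[name][sel].mean()) if ok else np.nan
            rows.append(
                {
                    "layer": name,
                    "subfield": subfield,
                    "thickness_um": val,
                    "n_pixels": n,
                    "coverage": coverage,
                }
            )
    return pd.DataFrame(rows)


def combine_layers(records: pd.DataFrame, scheme: LayerScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Augment a long-format cohort table with combined layers.

    Adds OS (from OS_a + OS_b, when the raw sub-bands are present) and the
    inner/outer-retina sums per observation key. A missing or absent
    constituent makes the combined value missing (never 0); partially
    present constituent sets are logged.
    """
    key_cols = [c for c in ("patient_id", "group", "eye", "visit_index",
                            "years_since_baseline", "source", "subfield")
                if c in records.columns]
    if "layer" not in records.columns or "thickness_um" not in records.columns:
        raise ValueError("records must carry 'layer' and 'thickness_um' columns")

    wide = records.pivot_table(index=key_cols, columns="layer",
                               values="thickness_um", aggfunc="first",
                               dropna=False)
    combos: dict[str, tuple[str, ...]] = {}
    if all(s in wide.columns for s in scheme.os_merge) and "OS" not in wide.columns:
        combos["OS"] = tuple(scheme.os_merge)
    combos.update(scheme.combined)

    out = [records]
    for cname, parts in combos.items():
        if cname in records["layer"].unique():
            continue
        present = [p for p in parts if p in wide.columns]
        if len(present) < len(parts):
            missing_parts = sorted(set(parts) - set(present))
            warnings.warn(
                f"combined layer {cname!r}: constituents {missing_parts} absent; "
                "emitting missing values"
            )
            vals = pd.Series(np.nan, index=wide.index)
        else:
            vals = wide[list(parts)].sum(axis=1, min_count=len(parts))
        # later combinations may build on this one (e.g. outer retina on
        # the merged OS band)
        wide[cname] = vals
        block = vals.rename("thickness_um").reset_index()
        block["layer"] = cname
        out.append(block)
    result = pd.concat(out, ignore_index=True)
    return result


def grader_average(records: pd.DataFrame) -> pd.DataFrame:
    """Per-observation mean of the two graders' corrected thicknesses.

    Rows with source ``grader_a``/``grader_b`` are averaged per
    (patient, eye, visit, layer, subfield); a single available grader is
    used as-is. The result is tagged with source ``grader_avg`` and
    appended to the input records.
    """
    graders = records[records["source"].isin(["grader_a", "grader_b"])]
    if graders.empty:
        raise ValueError("no grader_a/grader_b rows to average")
    key_cols = [c for c in records.columns
                if c not in ("source", "thickness_um")]
    avg = (
        graders.groupby(key_cols, dropna=False, sort=False, observed=True)["thickness_um"]
        .mean()
        .reset_index()
    )
    avg["source"] = "grader_avg"
    return pd.concat(
        [records[records["source"] != "grader_avg"], avg[records.columns.tolist()]],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# Plain-text serialization: one CSV per surface + a JSON sidecar
# ---------------------------------------------------------------------------


def save_surface_stack(stack: SurfaceStack, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k in range(stack.surfaces.shape[0]):
        np.savetxt(out / f"surface_{k:02d}.csv", stack.surfaces[k],
                   delimiter=",", fmt="%.6f")
    meta = {
        "spacing_bscan_mm": stack.spacing_bscan_mm,
        "spacing_ascan_mm": stack.spacing_ascan_mm,
        "fovea": list(stack.fovea),
        "eye_laterality": stack.eye_laterality,
        "n_surfaces": int(stack.surfaces.shape[0]),
    }
    if not stack.missing_mask.all():
        np.savetxt(out / "missing_mask.csv", stack.missing_mask.astype(int),
                   delimiter=",", fmt="%d")
        meta["missing_mask"] = "missing_mask.csv"
    (out / "stack.json").write_text(json.dumps(meta, indent=2))
    return out


def load_surface_stack(in_dir: str | Path) -> SurfaceStack:
    src = Path(in_dir)
    meta = json.loads((src / "stack.json").read_text())
    surfaces = np.stack([
        np.loadtxt(src / f"surface_{k:02d}.csv", delimiter=",", ndmin=2)
        for k in range(meta["n_surfaces"])
    ])
    mask = None
    if "missing_mask" in meta:
        mask = np.loadtxt(src / meta["missing_mask"], delimiter=",", ndmin=2).astype(bool)
    return SurfaceStack(
        surfaces=surfaces,
        spacing_bscan_mm=meta["spacing_bscan_mm"],
        spacing_ascan_mm=meta["spacing_ascan_mm"],
        fovea=tuple(meta["fovea"]),
        eye_laterality=meta["eye_laterality"],
        missing_mask=mask,
    )
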