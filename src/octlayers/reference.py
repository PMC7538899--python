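"""Published STGD1 cohort baseline profile used as generator defaults.

Baseline sublayer thickness estimates (µm) per ETDRS subfield for healthy
controls and ABCA4-associated Stargardt (STGD1) patients, from a published
longitudinal OCT cohort (40 control / 63 STGD1 patients). These printed
group-level estimates parameterize the synthetic cohort generator's fixed
effects, so that simulated cohorts carry realistic layer-by-subfield effect
sizes (e.g. profound ONL thinning in the central macula, mild NFL and RPE
thickening).

Values are (control mean µm, STGD1 - control difference µm).
"""

from __future__ import annotations

#: (layer, subfield) -> (control baseline mean µm, group difference µm).
BASELINE_PROFILE: dict[tuple[str, str], tuple[float, float]] = {
    ("NFL", "center"): (7.6, 3.5),
    ("NFL", "inner_ring"): (28.7, 3.4),
    ("NFL", "outer_ring"): (39.1, -0.1),
    ("GCL", "center"): (17.4, 0.3),
    ("GCL", "inner_ring"): (52.5, -12.6),
    ("GCL", "outer_ring"): (33.4, -5.0),
    ("IPL", "center"): (26.8, -7.1),
    ("IPL", "inner_ring"): (39.5, -5.5),
    ("IPL", "outer_ring"): (34.4, -4.6),
    ("INL", "center"): (21.9, -4.5),
    ("INL", "inner_ring"): (40.4, -7.3),
    ("INL", "outer_ring"): (32.0, -2.9),
    ("OPL", "center"): (20.1, -7.1),
    ("OPL", "inner_ring"): (29.5, -7.9),
    ("OPL", "outer_ring"): (25.5, -2.2),
    ("ONL", "center"): (116.9, -92.9),
    ("ONL", "inner_ring"): (91.4, -53.0),
    ("ONL", "outer_ring"): (75.0, -25.7),
    ("EZ", "center"): (16.1, -8.8),
    ("EZ", "inner_ring"): (14.8, -4.6),
    ("EZ", "outer_ring"): (14.2, -1.8),
    ("OS", "center"): (32.5, -20.5),
    ("OS", "inner_ring"): (28.1, -12.5),
    ("OS", "outer_ring"): (24.9, -3.8),
    ("RPE", "center"): (20.0, 0.7),
    ("RPE", "inner_ring"): (20.0, 2.0),
    ("RPE", "outer_ring"): (21.1, 1.9),
}

#: Default rate-of-change differences (STGD1 - control, µm/yr) per layer.
#: The cohort's aggregate outer-retina thinning is about -3 µm/yr across
#: subfields, dominated by the ONL, with controls essentially stable; the
#: inner retina shows slight thickening over time attributed to remodelling.
DEFAULT_SLOPE_DIFF: dict[str, float] = {
    "NFL": 0.0,
    "GCL": 0.0,
    "IPL": 0.0,
    "INL": 0.2,
    "OPL": 0.0,
    "ONL": -2.0,
    "EZ": -0.3,
    "OS": -0.7,
    "RPE": 0.0,
}

#: Default uncorrected-segmentation bias per layer (µm): the automated
#: segmentation tends to underestimate inner retinal layers (GCL-INL) and
#: overestimate outer layers (ONL-RPE), most strongly for the ONL.
DEFAULT_UNCORRECTED_BIAS: dict[str, float] = {
    "NFL": 0.0,
    "GCL": -1.5,
    "IPL": -1.5,
    "INL": -1.5,
    "OPL": 0.0,
    "ONL": 4.0,
    "EZ": 1.0,
    "OS": 2.0,
    "RPE": 1.5,
}
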