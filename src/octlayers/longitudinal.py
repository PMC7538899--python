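"""Layer-by-subfield longitudinal analysis and the baseline/rate report.

Each of the 9 analyzed sublayers plus the two combined layers is modeled
per ETDRS subfield (33 models in total) as

    thickness ~ years + group + years:group

with correlated random intercepts and years-slopes per patient and per
eye within patient, fitted by REML. Group baseline means and rates with
SEs and 95% CIs come from the fitted fixed effects; two-sided p-values
use Wald t-tests with containment degrees of freedom; statistical
significance is Bonferroni-controlled across the 33 models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .layers import ANALYZED_LAYERS, COMBINED_LAYERS, SUBFIELDS
from .lmm import NestedMixedModel, estimate_group_profiles, wald_inference

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisPlan",
    "LongitudinalAnalysis",
    "run_analysis",
    "bonferroni_threshold",
    "percent_difference",
    "snellen_to_logmar",
]


@dataclass(frozen=True)
class AnalysisPlan:
    """The set of layer x subfield models: 9 individual layers and 2
    combined layers across 3 subfields (27 + 6 = 33)."""

    individual_layers: tuple[str, ...] = ANALYZED_LAYERS
    combined_layers: tuple[str, ...] = tuple(COMBINED_LAYERS)
    subfields: tuple[str, ...] = SUBFIELDS

    @property
    def n_individual(self) -> int:
        return len(self.individual_layers) * len(self.subfields)

    @property
    def n_models(self) -> int:
        return (len(self.individual_layers) + len(self.combined_layers)) * len(self.subfields)

    def entries(self) -> list[tuple[str, str]]:
        layers = self.individual_layers + self.combined_layers
        return [(layer, sf) for layer in layers for sf in self.subfields]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m (full precision)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def display_threshold(alpha: float, m: int) -> float:
    """The threshold as displayed, rounded to 4 decimals."""
    return round(bonferroni_threshold(alpha, m), 4)


def percent_difference(control_mean: float, stgd_mean: float) -> int:
    """Percent thinning/thickening of STGD1 relative to controls,
    100 * (stgd - control) / control, rounded to the nearest integer."""
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    return int(round(100.0 * (stgd_mean - control_mean) / control_mean))


def snellen_to_logmar(numerator: float, denominator: float) -> float:
    """logMAR visual acuity from a Snellen fraction: -log10(num/den)."""
    if numerator <= 0 or denominator <= 0:
        raise ValueError("Snellen numerator and denominator must be positive")
    return float(-np.log10(numerator / denominator))


def _format_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


class LongitudinalAnalysis(BaseEstimator):
    """Fit the full analysis plan and assemble the report table.

    Parameters
    ----------
    plan : AnalysisPlan
    alpha : float
        Family-wise error rate for the Bonferroni correction.
    m : int or None
        Number of tests for Bonferroni; defaults to the plan size.
    include_laterality : bool
        Add an OD/OS fixed effect to every model.
    average_laterality : bool
        Report group means averaged over laterality rather than at the
        OD reference (only meaningful with ``include_laterality``).
    source : str
        Which measurement source to analyze (default the grader average).

    Attributes
    ----------
    report_ : DataFrame
        One row per plan entry with group baselines, rates, differences,
        p-values and Bonferroni flags.
    fits_ : dict
        (layer, subfield) -> LMMFit for converged models.
    """

    def __init__(self, plan: AnalysisPlan = AnalysisPlan(), alpha: float = 0.05,
                 m: int | None = None, include_laterality: bool = False,
                 average_laterality: bool = False, source: str = "grader_avg",
                 n_restarts: int = 5):
        self.plan = plan
        self.alpha = alpha
        self.m = m
        self.include_laterality = include_laterality
        self.average_laterality = average_laterality
        self.source = source
        self.n_restarts = n_restarts

    def fit(self, X: pd.DataFrame, y=None) -> "LongitudinalAnalysis":
        records = X
        if "source" in records.columns:
            records = records[records["source"] == self.source]
            if records.empty:
                raise ValueError(f"no rows with source {self.source!r}")
        m = self.m if self.m is not None else self.plan.n_models
        threshold = bonferroni_threshold(self.alpha, m)

        terms = ["intercept", "years", "group", "years:group"]
        if self.include_laterality:
            terms.insert(2, "laterality")

        rows = []
        fits = {}
        for layer, subfield in self.plan.entries():
            sel = records[(records["layer"] == layer)
                          & (records["subfield"] == subfield)]
            sel = sel.loc[sel["thickness_um"].notna()]
            row: dict = {"layer": layer, "subfield": subfield}
            if sel.empty or sel["patient_id"].nunique() < 2:
                logger.warning("no usable data for %s/%s", layer, subfield)
                row.update({"converged": False, "absent": True})
                rows.append(row)
                continue
            model = NestedMixedModel(
                fixed_terms=tuple(terms),
                random_structure="nested_intercept_slope",
                response="thickness_um",
                n_restarts=self.n_restarts,
            )
            try:
                model.fit(sel)
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("fit failed for %s/%s: %s", layer, subfield, exc)
                row.update({"converged": False, "absent": False})
                rows.append(row)
                continue
            fit = model.result_
            fits[(layer, subfield)] = fit
            row["converged"] = fit.converged
            row["absent"] = False
            if not fit.converged:
                rows.append(row)
                continue
            prof = estimate_group_profiles(fit, self.average_laterality)
            wg = wald_inference(fit, "group")
            wi = wald_inference(fit, "years:group")
            for grp in ("control", "stgd1"):
                b = prof[grp]["baseline"]
                s = prof[grp]["slope"]
                row[f"{grp}_baseline"] = b["estimate"]
                row[f"{grp}_baseline_se"] = b["se"]
                row[f"{grp}_baseline_ci_lo"] = b["ci"][0]
                row[f"{grp}_baseline_ci_hi"] = b["ci"][1]
                row[f"{grp}_slope"] = s["estimate"]
                row[f"{grp}_slope_se"] = s["se"]
                row[f"{grp}_slope_ci_lo"] = s["ci"][0]
                row[f"{grp}_slope_ci_hi"] = s["ci"][1]
            row["baseline_diff"] = wg.estimate
            row["baseline_p"] = wg.p
            row["baseline_p_display"] = _format_p(wg.p)
            row["rate_diff"] = wi.estimate
            row["rate_p"] = wi.p
            row["rate_p_display"] = _format_p(wi.p)
            row["baseline_sig_bonferroni"] = wg.p < threshold
            row["rate_sig_bonferroni"] = wi.p < threshold
            row["significant_bonferroni"] = row["baseline_sig_bonferroni"]
            rows.append(row)

        self.report_ = pd.DataFrame(rows)
        self.fits_ = fits
        self.threshold_ = threshold
        self.m_ = m
        return self


def run_analysis(records: pd.DataFrame, plan: AnalysisPlan = AnalysisPlan(),
                 **kwargs) -> pd.DataFrame:
    """Fit every plan entry and return the report table (see
    :class:`LongitudinalAnalysis`)."""
    est = LongitudinalAnalysis(plan=plan, **kwargs)
    est.fit(records)
    return est.report_


def spaghetti_plot(records: pd.DataFrame, layer: str, subfield: str,
                   fit, path, source: str = "grader_avg") -> None:
    """Per-eye thickness trajectories with thin individual fits and thick
    group-level fitted lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sel = records[(records["layer"] == layer) & (records["subfield"] == subfield)]
    if "source" in sel.columns:
        sel = sel[sel["source"] == source]
    fig, ax = plt.subplots(figsize=(5.5, 4))
    colors = {"control": "tab:green", "stgd1": "tab:orange"}
    for (_, _, grp), eye_df in sel.groupby(["patient_id", "eye", "group"]):
        ax.plot(eye_df["years_since_baseline"], eye_df["thickness_um"],
                color=colors[grp], alpha=0.35, linewidth=0.8)
    if fit is not None and fit.converged:
        prof = estimate_group_profiles(fit)
        xs = np.linspace(0, sel["years_since_baseline"].max(), 20)
        for grp, style in (("control", ":"), ("stgd1", "--")):
            b = prof[grp]["baseline"]["estimate"]
            s = prof[grp]["slope"]["estimate"]
            ax.plot(xs, b + s * xs, "k", linestyle=style, linewidth=2)
    ax.set_xlabel("years since baseline")
    ax.set_ylabel("thickness (µm)")
    ax.set_title(f"{layer} / {subfield}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
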