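"""Repeated-measures Bland–Altman agreement with mixed-model limits.

Measurement agreement (uncorrected automated segmentation vs grader
average, or grader A vs grader B) is summarized per layer x subfield by a
mean bias and 95% limits of agreement that respect the repeated-measures
structure: differences are modeled with nested random intercepts (patient,
eye within patient), the mean bias mu comes from an intercept-only model,
and the spread from a second model that additionally adjusts for years
since baseline. The limits are

    mu +/- 1.96 * sqrt(var_patient + var_eye + var_residual)

with the variances taken from the time-adjusted model. Confidence
intervals for the bias and both limits come from a stratified cluster
bootstrap: patients are resampled with replacement within strata defined
by their number of scans, redrawn patients count as fresh clusters, and
both models are refit per replicate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .geometry import grader_average
from .lmm import ClusterSet, _optimize_reml, _reml_profile

logger = logging.getLogger(__name__)

__all__ = [
    "DifferencePair",
    "LoAResult",
    "LimitsOfAgreement",
    "bland_altman_table",
    "compute_loa",
    "bootstrap_loa",
]

COMPARISONS = {
    "uncorrected": ("uncorrected", "grader_avg"),
    "graders": ("grader_a", "grader_b"),
}


@dataclass
class DifferencePair:
    """Per-observation differences for one source comparison.

    ``rows`` columns: patient_id, eye, visit_index, years_since_baseline,
    layer, subfield, difference (µm). The sign convention is
    first-source minus second-source.
    """

    comparison: str
    rows: pd.DataFrame

    def subset(self, layer: str, subfield: str) -> pd.DataFrame:
        sel = self.rows[(self.rows["layer"] == layer)
                        & (self.rows["subfield"] == subfield)]
        return sel.loc[sel["difference"].notna()]


@dataclass
class LoAResult:
    """Mean bias, limits of agreement and bootstrap CIs for one layer x subfield."""

    comparison: str
    layer: str
    subfield: str
    bias: float
    loa_lower: float
    loa_upper: float
    var_patient: float
    var_eye: float
    var_residual: float
    converged: bool
    n_obs: int
    n_patients: int
    bias_ci: tuple[float, float] | None = None
    loa_lower_ci: tuple[float, float] | None = None
    loa_upper_ci: tuple[float, float] | None = None
    n_boot_used: int = 0

    @property
    def total_sd(self) -> float:
        return float(np.sqrt(self.var_patient + self.var_eye + self.var_residual))

    def to_row(self) -> dict:
        row = {
            "comparison": self.comparison,
            "layer": self.layer,
            "subfield": self.subfield,
            "bias": self.bias,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "var_patient": self.var_patient,
            "var_eye": self.var_eye,
            "var_residual": self.var_residual,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_patients": self.n_patients,
            "n_boot_used": self.n_boot_used,
        }
        for name, ci in (("bias", self.bias_ci), ("loa_lower", self.loa_lower_ci),
                         ("loa_upper", self.loa_upper_ci)):
            row[f"{name}_ci_lo"] = None if ci is None else ci[0]
            row[f"{name}_ci_hi"] = None if ci is None else ci[1]
        return row


def bland_altman_table(records: pd.DataFrame) -> dict[str, DifferencePair]:
    """Difference tables for both comparisons.

    (a) ``uncorrected``: uncorrected segmentation minus grader average;
    (b) ``graders``: grader A minus grader B. Observations missing either
    source are skipped with a logged count.
    """
    if "grader_avg" not in set(records["source"]):
        records = grader_average(records)
    key_cols = ["patient_id", "eye", "visit_index", "years_since_baseline",
                "layer", "subfield"]
    wide = records.pivot_table(index=key_cols, columns="source",
                               values="thickness_um", aggfunc="first",
                               dropna=False)
    out: dict[str, DifferencePair] = {}
    for name, (first, second) in COMPARISONS.items():
        missing_src = [s for s in (first, second) if s not in wide.columns]
        if missing_src:
            raise ValueError(f"comparison {name!r} needs sources {missing_src}")
        diff = (wide[first] - wide[second]).rename("difference")
        n_skip = int(diff.isna().sum())
        if n_skip:
            logger.info("comparison %s: skipped %d rows missing a source",
                        name, n_skip)
        rows = diff.reset_index()
        out[name] = DifferencePair(comparison=name, rows=rows)
    return out


# ---------------------------------------------------------------------------
# Model fitting on a difference subset
# ---------------------------------------------------------------------------


def _cluster_sets(sub: pd.DataFrame) -> tuple[ClusterSet, ClusterSet | None]:
    """ClusterSets for the intercept-only and time-adjusted models.

    Returns (cs1, cs2); cs2 is None when years has no variation, in which
    case the time-adjusted model coincides with the intercept-only one.
    """
    y = sub["difference"].to_numpy(float)
    years = sub["years_since_baseline"].to_numpy(float)
    pat = pd.factorize(sub["patient_id"].to_numpy())[0]
    eye_key = (sub["patient_id"].astype(str) + "|" + sub["eye"].astype(str)).to_numpy()
    eye = pd.factorize(eye_key)[0]
    X1 = np.ones((len(y), 1))
    cs1 = ClusterSet(y, X1, years, pat, eye, "nested_intercepts")
    if np.ptp(years) > 0:
        X2 = np.column_stack([np.ones(len(y)), years])
        cs2 = ClusterSet(y, X2, years, pat, eye, "nested_intercepts")
    else:
        cs2 = None
    return cs1, cs2


def _fit_loa_point(cs1: ClusterSet, cs2: ClusterSet | None,
                   theta0_1=None, theta0_2=None, warm_only=False):
    """Point estimates (bias, variance components) from the two models.

    Returns (bias, (var_p, var_e, var_resid), converged, theta1, theta2).
    """
    g1 = cs1.full_groups()
    r1 = _optimize_reml(cs1, g1, cs1.n_obs, theta0=theta0_1, warm_only=warm_only)
    p1 = _reml_profile(r1.x, cs1, g1, cs1.n_obs)
    bias = float(p1.beta[0])
    if cs2 is None:
        r2, cs2_, g2 = r1, cs1, g1
    else:
        cs2_ = cs2
        g2 = cs2.full_groups()
        r2 = _optimize_reml(cs2_, g2, cs2_.n_obs, theta0=theta0_2, warm_only=warm_only)
    p2 = _reml_profile(r2.x, cs2_, g2, cs2_.n_obs)
    s2 = p2.sigma2
    var_p = s2 * np.exp(2 * r2.x[0])
    var_e = s2 * np.exp(2 * r2.x[1])
    conv = bool(r1.success and r2.success)
    return bias, (float(var_p), float(var_e), float(s2)), conv, r1.x, r2.x


def compute_loa(diff: DifferencePair, layer: str, subfield: str) -> LoAResult:
    """Point limits of agreement for one layer x subfield (no bootstrap)."""
    sub = diff.subset(layer, subfield)
    if sub["patient_id"].nunique() < 2:
        raise ValueError(
            f"need >= 2 patients with data for {layer}/{subfield}, "
            f"got {sub['patient_id'].nunique()}"
        )
    cs1, cs2 = _cluster_sets(sub)
    bias, (vp, ve, vr), conv, _, _ = _fit_loa_point(cs1, cs2)
    half = 1.96 * float(np.sqrt(vp + ve + vr))
    return LoAResult(
        comparison=diff.comparison, layer=layer, subfield=subfield,
        bias=bias, loa_lower=bias - half, loa_upper=bias + half,
        var_patient=vp, var_eye=ve, var_residual=vr,
        converged=conv, n_obs=cs1.n_obs, n_patients=cs1.n_patients,
    )


def _strata(sub: pd.DataFrame, mode: str) -> dict[int, np.ndarray]:
    """Cluster ids per stratum. Clusters are patients ordered as in
    ClusterSet (factorize order of patient_id)."""
    pat_codes, uniques = pd.factorize(sub["patient_id"].to_numpy())
    counts = np.bincount(pat_codes)
    if mode == "scans_per_patient":
        key = counts
    elif mode == "visits_per_eye":
        eye_key = (sub["patient_id"].astype(str) + "|" + sub["eye"].astype(str)).to_numpy()
        n_eyes = pd.DataFrame({"p": pat_codes, "e": eye_key}).groupby("p")["e"].nunique()
        key = np.rint(counts / n_eyes.sort_index().to_numpy()).astype(int)
    else:
        raise ValueError(f"unknown stratification mode {mode!r}")
    out: dict[int, np.ndarray] = {}
    for stratum in np.unique(key):
        out[int(stratum)] = np.flatnonzero(key == stratum)
    return out


def bootstrap_loa(
    diff: DifferencePair,
    layer: str,
    subfield: str,
    n_boot: int = 1999,
    seed: int | None = None,
    stratify: str = "scans_per_patient",
) -> LoAResult:
    """Limits of agreement with stratified cluster-bootstrap 95% CIs.

    Strata are the distinct numbers of scans per patient; within each
    stratum, patients are resampled with replacement preserving the
    stratum size, and repeated draws enter as fresh independent clusters.
    Both agreement models are refit per replicate (warm-started at the
    full-data estimates); CI bounds are the empirical 2.5% and 97.5%
    quantiles over the replicates that converged. More than 5% failed
    replicates triggers a warning; all failing is an error.
    """
    point = compute_loa(diff, layer, subfield)
    sub = diff.subset(layer, subfield)
    cs1, cs2 = _cluster_sets(sub)
    _, _, _, theta1, theta2 = _fit_loa_point(cs1, cs2)

    strata = _strata(sub, stratify)
    rng = np.random.default_rng(seed)
    bias_s, lo_s, hi_s = [], [], []
    n_fail = 0
    for _ in range(n_boot):
        ids: list[int] = []
        for members in strata.values():
            ids.extend(rng.choice(members, size=len(members), replace=True))
        g1, n1 = cs1.resampled_groups(ids)
        r1 = _optimize_reml(cs1, g1, n1, theta0=theta1, warm_only=True)
        p1 = _reml_profile(r1.x, cs1, g1, n1)
        if cs2 is None:
            r2, p2 = r1, p1
        else:
            g2, n2 = cs2.resampled_groups(ids)
            r2 = _optimize_reml(cs2, g2, n2, theta0=theta2, warm_only=True)
            p2 = _reml_profile(r2.x, cs2, g2, n2)
        if not (r1.success and r2.success):
            n_fail += 1
            continue
        b = float(p1.beta[0])
        s2 = p2.sigma2
        total = s2 * (1.0 + np.exp(2 * r2.x[0]) + np.exp(2 * r2.x[1]))
        half = 1.96 * float(np.sqrt(total))
        bias_s.append(b)
        lo_s.append(b - half)
        hi_s.append(b + half)

    n_used = len(bias_s)
    if n_used == 0:
        raise RuntimeError("all bootstrap replicates failed to converge")
    if n_fail > 0.05 * n_boot:
        warnings.warn(
            f"{n_fail}/{n_boot} bootstrap replicates failed to converge; "
            f"CIs use {n_used} replicates"
        )

    def ci(v):
        return (float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975)))

    point.bias_ci = ci(bias_s)
    point.loa_lower_ci = ci(lo_s)
    point.loa_upper_ci = ci(hi_s)
    point.n_boot_used = n_used
    return point


class LimitsOfAgreement(BaseEstimator):
    """Mixed-model limits of agreement for one layer x subfield.

    Parameters
    ----------
    layer, subfield : str
        The sublayer and ETDRS subfield to analyze.
    n_boot : int
        Bootstrap replicates for CIs; 0 skips the bootstrap.
    seed : int or None
        Bootstrap seed.
    stratify : str
        ``"scans_per_patient"`` (default) or ``"visits_per_eye"``.

    Attributes
    ----------
    result_ : LoAResult
    bias_, loa_lower_, loa_upper_ : float
    """

    def __init__(self, layer: str = "ONL", subfield: str = "center",
                 n_boot: int = 1999, seed: int | None = None,
                 stratify: str = "scans_per_patient"):
        self.layer = layer
        self.subfield = subfield
        self.n_boot = n_boot
        self.seed = seed
        self.stratify = stratify

    def fit(self, X: DifferencePair | pd.DataFrame, y=None) -> "LimitsOfAgreement":
        diff = X if isinstance(X, DifferencePair) else DifferencePair("custom", X)
        if self.n_boot and self.n_boot > 0:
            self.result_ = bootstrap_loa(diff, self.layer, self.subfield,
                                         n_boot=self.n_boot, seed=self.seed,
                                         stratify=self.stratify)
        else:
            self.result_ = compute_loa(diff, self.layer, self.subfield)
        self.bias_ = self.result_.bias
        self.loa_lower_ = self.result_.loa_lower
        self.loa_upper_ = self.result_.loa_upper
        return self


def bland_altman_plot(records: pd.DataFrame, diff: DifferencePair,
                      result: LoAResult, path) -> None:
    """Mean-vs-difference scatter with bias and limits for one layer x subfield."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    first, second = COMPARISONS[result.comparison]
    key_cols = ["patient_id", "eye", "visit_index", "layer", "subfield"]
    wide = records.pivot_table(index=key_cols, columns="source",
                               values="thickness_um", aggfunc="first")
    wide = wide.reset_index()
    sel = (wide["layer"] == result.layer) & (wide["subfield"] == result.subfield)
    mean_vals = (wide.loc[sel, first] + wide.loc[sel, second]) / 2.0
    diff_vals = wide.loc[sel, first] - wide.loc[sel, second]

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean_vals, diff_vals, s=12, alpha=0.6)
    for yv, style in ((result.bias, "-"), (result.loa_lower, "--"),
                      (result.loa_upper, "--")):
        ax.axhline(yv, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel(f"mean of {first} and {second} (µm)")
    ax.set_ylabel(f"{first} − {second} (µm)")
    ax.set_title(f"{result.layer} / {result.subfield}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
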