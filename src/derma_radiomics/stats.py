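"""Statistical harness for the longitudinal delta-radiomics analysis.

The analysis plan mirrors a classical repeated-measures design with two
within-subject factors, breast side (treated vs untreated) and time
(four visits):

* per feature, a two-way repeated-measures ANOVA with Mauchly's test of
  sphericity per effect and the Greenhouse-Geisser correction applied
  when sphericity is violated (p < 0.05);
* per post-baseline visit, a paired comparison of the treated and
  untreated side, using a paired t-test when both samples pass the
  Shapiro-Wilk normality test (p >= 0.05) and the Wilcoxon signed-rank
  test otherwise, judged against the Bonferroni-adjusted level
  alpha / 3 = 0.0167 for the three post-baseline visits;
* correlations (Pearson when both variables pass Shapiro-Wilk,
  Spearman otherwise) of skin dose against deltas, and of day-7 deltas
  against later deltas, with Benjamini-Hochberg adjustment across the
  18-feature family of each mode.

The repeated-measures ANOVA is computed from orthonormal within-subject
contrasts: for an effect with q contrasts collected in the rows of M,
the per-subject contrast scores z_i give F = (n * |mean z|^2 / q) /
(sum_i |z_i - mean z|^2 / ((n-1) q)); Mauchly's W = det(S) /
(tr(S)/q)^q on the contrast covariance S with the standard chi-square
approximation, and the Greenhouse-Geisser epsilon = tr(S)^2 /
(q * tr(S^2)) deflates both degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .glcm import FEATURE_NAMES

__all__ = [
    "EffectResult",
    "AnovaResult",
    "PairedTestResult",
    "CorrelationResult",
    "rm_anova_two_way",
    "gated_paired_test",
    "gated_correlation",
    "bonferroni_threshold",
    "bh_adjust",
    "run_full_inference",
    "InferenceReport",
]

SHAPIRO_ALPHA = 0.05
MAUCHLY_ALPHA = 0.05


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


@dataclass(frozen=True)
class EffectResult:
    """One within-subject effect of the RM-ANOVA."""

    F: float
    df1: float
    df2: float
    p_uncorrected: float
    mauchly_W: float
    mauchly_p: float
    gg_epsilon: float
    correction_applied: bool
    p: float  # corrected where applied, else uncorrected


@dataclass(frozen=True)
class AnovaResult:
    group: EffectResult
    time: EffectResult
    interaction: EffectResult


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the unit vector."""
    if k < 2:
        raise ValueError("a factor needs at least 2 levels")
    basis = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]]))[0]
    return basis[:, 1:].T


def _effect_from_scores(z: np.ndarray) -> EffectResult:
    """F, Mauchly and Greenhouse-Geisser from n x q contrast scores."""
    n, q = z.shape
    zbar = z.mean(axis=0)
    ss_effect = n * float(zbar @ zbar)
    resid = z - zbar
    ss_error = float((resid**2).sum())
    df1, df2 = float(q), float(q * (n - 1))
    if ss_error <= 0:
        raise ValueError("zero residual variance in repeated-measures ANOVA")
    F = (ss_effect / df1) / (ss_error / df2)
    p_unc = float(sps.f.sf(F, df1, df2))
    if q == 1:
        # a single contrast: sphericity holds trivially
        W, p_m, eps = 1.0, 1.0, 1.0
    else:
        S = np.cov(z, rowvar=False, ddof=1)
        tr = float(np.trace(S))
        det = float(np.linalg.det(S))
        W = det / (tr / q) ** q if tr > 0 else np.nan
        if not np.isfinite(W) or W <= 0:
            W, p_m = 0.0, 0.0  # singular contrast covariance: sphericity rejected
        else:
            stat = -(n - 1 - (2 * q**2 + q + 2) / (6.0 * q)) * np.log(W)
            df_m = q * (q + 1) / 2 - 1
            p_m = float(sps.chi2.sf(stat, df_m))
        eps = tr**2 / (q * float(np.trace(S @ S))) if tr > 0 else 1.0
        eps = float(min(1.0, eps))
    corrected = q > 1 and p_m < MAUCHLY_ALPHA
    if corrected:
        p = float(sps.f.sf(F, eps * df1, eps * df2))
    else:
        p = p_unc
    return EffectResult(
        F=float(F), df1=df1, df2=df2, p_uncorrected=p_unc,
        mauchly_W=float(W), mauchly_p=float(p_m), gg_epsilon=float(eps),
        correction_applied=corrected, p=p,
    )


def rm_anova_two_way(data: np.ndarray) -> AnovaResult:
    """Two-way fully within-subject ANOVA on an n x a x b grid.

    Axis 0 indexes subjects, axis 1 the first factor (side/group, a
    levels), axis 2 the second factor (time, b levels).  The grid must
    be complete (no NaN) with n >= 3 subjects.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected an n x a x b array")
    n, a, b = data.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not np.isfinite(data).all():
        raise ValueError("incomplete grid: NaN or infinite cells present")
    Ma = _orthonormal_contrasts(a)
    Mb = _orthonormal_contrasts(b)
    group = _effect_from_scores(data.mean(axis=2) @ Ma.T)
    time = _effect_from_scores(data.mean(axis=1) @ Mb.T)
    interaction = _effect_from_scores(data.reshape(n, a * b) @ np.kron(Ma, Mb).T)
    return AnovaResult(group=group, time=time, interaction=interaction)


# ---------------------------------------------------------------------------
# gated pairwise tests and correlations


@dataclass(frozen=True)
class PairedTestResult:
    test_used: str  # "paired_t" | "wilcoxon_signed_rank" | "degenerate"
    statistic: float
    p: float
    normality_ps: tuple[float, float]
    n: int
    degenerate: bool = False


def gated_paired_test(x, y, force_test: str | None = None) -> PairedTestResult:
    """Paired comparison with a Shapiro-Wilk normality gate.

    Both samples normal at the 5% level -> paired t-test; otherwise the
    Wilcoxon signed-rank test (zero differences dropped; exact null
    distribution up to n = 25 without ties, normal approximation with
    tie correction beyond).  All differences zero is degenerate and
    reported as p = 1 with a flag.  ``force_test`` ("paired_t" or
    "wilcoxon_signed_rank") bypasses the gate for auditing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    sw_x = float(sps.shapiro(x).pvalue) if np.ptp(x) > 0 else 0.0
    sw_y = float(sps.shapiro(y).pvalue) if np.ptp(y) > 0 else 0.0
    d = x - y
    if np.all(d == 0):
        return PairedTestResult(
            test_used="degenerate", statistic=np.nan, p=1.0,
            normality_ps=(sw_x, sw_y), n=len(x), degenerate=True,
        )
    parametric = sw_x >= SHAPIRO_ALPHA and sw_y >= SHAPIRO_ALPHA
    if force_test is not None:
        parametric = force_test == "paired_t"
    if parametric:
        res = sps.ttest_rel(x, y)
        return PairedTestResult(
            test_used="paired_t", statistic=float(res.statistic), p=float(res.pvalue),
            normality_ps=(sw_x, sw_y), n=len(x),
        )
    nz = d[d != 0]
    ranks_tied = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not ranks_tied) else "approx"
    res = sps.wilcoxon(x, y, zero_method="wilcox", method=method)
    return PairedTestResult(
        test_used="wilcoxon_signed_rank", statistic=float(res.statistic),
        p=float(res.pvalue), normality_ps=(sw_x, sw_y), n=len(x),
    )


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    r: float
    p: float
    normality_ps: tuple[float, float]
    n: int
    p_adjusted: float = np.nan


def gated_correlation(x, y, force_method: str | None = None) -> CorrelationResult:
    """Correlation with a Shapiro-Wilk gate on both variables.

    Both normal at the 5% level -> Pearson; otherwise Spearman (scipy's
    rank correlation handles ties by midranks).  Two-sided p.
    ``force_method`` ("pearson" or "spearman") bypasses the gate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an input")
    sw_x = float(sps.shapiro(x).pvalue)
    sw_y = float(sps.shapiro(y).pvalue)
    parametric = sw_x >= SHAPIRO_ALPHA and sw_y >= SHAPIRO_ALPHA
    if force_method is not None:
        parametric = force_method == "pearson"
    if parametric:
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(
        method=method, r=float(r), p=float(p), normality_ps=(sw_x, sw_y), n=len(x)
    )


def bonferroni_threshold(alpha: float, m: int, decimals: int = 4) -> float:
    """Bonferroni-adjusted significance level alpha / m.

    Rounded to ``decimals`` places for display (0.05 / 3 -> 0.0167).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return round(alpha / m, decimals)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the full analysis over the assembled tables


@dataclass
class InferenceReport:
    """Tidy result tables of the full longitudinal analysis."""

    anova: pd.DataFrame  # mode x feature x effect
    paired: pd.DataFrame  # mode x feature x post-baseline timepoint
    dose_correlation: pd.DataFrame  # mode x feature x timepoint
    carryover_correlation: pd.DataFrame  # mode x feature x later timepoint
    feature_flags: pd.DataFrame  # mode x feature: anova_significant, paired_all_significant
    alpha: float = 0.05
    pairwise_threshold: float = 0.0167

    def to_json_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "pairwise_threshold": self.pairwise_threshold,
            "anova": self.anova.to_dict(orient="records"),
            "paired": self.paired.to_dict(orient="records"),
            "dose_correlation": self.dose_correlation.to_dict(orient="records"),
            "carryover_correlation": self.carryover_correlation.to_dict(orient="records"),
            "feature_flags": self.feature_flags.to_dict(orient="records"),
        }


def _anova_grid(patient_values: pd.DataFrame, mode: str, feature: str,
                sides: tuple[str, str], timepoints: tuple[str, ...]) -> np.ndarray:
    sub = patient_values[patient_values["mode"] == mode]
    pivot = sub.pivot_table(
        index="patient_id", columns=["side", "timepoint"], values=feature, sort=False
    )
    patients = pivot.index
    grid = np.full((len(patients), len(sides), len(timepoints)), np.nan)
    for i, side in enumerate(sides):
        for j, tp in enumerate(timepoints):
            grid[:, i, j] = pivot[(side, tp)].to_numpy()
    return grid


def run_full_inference(
    patient_values: pd.DataFrame,
    deltas: pd.DataFrame,
    doses: pd.DataFrame,
    alpha: float = 0.05,
    baseline: str = "Before_RT",
) -> InferenceReport:
    """Run the complete statistical analysis over one cohort.

    ``patient_values``: per-breast deltas (from ``aggregate_points``);
    ``deltas``: per-point deltas (analysis unit of the dose
    correlations, dose and delta taken at the same anatomical point);
    ``doses``: columns patient_id, point_site, dose_cGy.
    """
    modes = sorted(patient_values["mode"].unique())
    timepoints = [t for t in patient_values["timepoint"].unique()]
    # keep the natural visit order if present
    order = ["Before_RT", "RT_D7", "RT_D14", "After_RT_D10"]
    timepoints = [t for t in order if t in timepoints] + [
        t for t in timepoints if t not in order
    ]
    post = [t for t in timepoints if t != baseline]
    sides = ("ipsilateral", "contralateral")
    threshold = bonferroni_threshold(alpha, len(post))

    anova_rows, paired_rows, flag_rows = [], [], []
    for mode in modes:
        for feat in FEATURE_NAMES:
            grid = _anova_grid(patient_values, mode, feat, sides, tuple(timepoints))
            try:
                res = rm_anova_two_way(grid)
                for eff_name, eff in (
                    ("group", res.group), ("time", res.time), ("interaction", res.interaction)
                ):
                    anova_rows.append(
                        {
                            "mode": mode, "feature": feat, "effect": eff_name,
                            "F": eff.F, "df1": eff.df1, "df2": eff.df2,
                            "mauchly_W": eff.mauchly_W, "mauchly_p": eff.mauchly_p,
                            "gg_epsilon": eff.gg_epsilon,
                            "correction_applied": eff.correction_applied,
                            "p_uncorrected": eff.p_uncorrected, "p": eff.p,
                        }
                    )
                anova_ok = res.time.p < alpha and res.interaction.p < alpha
            except (ValueError, KeyError) as exc:
                anova_rows.append(
                    {"mode": mode, "feature": feat, "effect": "error", "note": str(exc)}
                )
                anova_ok = False

            all_paired_sig = True
            sub = patient_values[patient_values["mode"] == mode]
            pivot = sub.pivot_table(
                index="patient_id", columns=["side", "timepoint"], values=feat, sort=False
            )
            for tp in post:
                try:
                    x = pivot[("ipsilateral", tp)].to_numpy()
                    y = pivot[("contralateral", tp)].to_numpy()
                    keep = np.isfinite(x) & np.isfinite(y)
                    pt = gated_paired_test(x[keep], y[keep])
                    significant = pt.p < threshold
                    paired_rows.append(
                        {
                            "mode": mode, "feature": feat, "timepoint": tp,
                            "test_used": pt.test_used, "statistic": pt.statistic,
                            "p": pt.p, "n": pt.n,
                            "shapiro_p_ipsi": pt.normality_ps[0],
                            "shapiro_p_contra": pt.normality_ps[1],
                            "significant": bool(significant),
                        }
                    )
                except (ValueError, KeyError) as exc:
                    paired_rows.append(
                        {"mode": mode, "feature": feat, "timepoint": tp, "note": str(exc)}
                    )
                    significant = False
                all_paired_sig = all_paired_sig and significant
            flag_rows.append(
                {
                    "mode": mode, "feature": feat,
                    "anova_significant": bool(anova_ok),
                    "paired_all_significant": bool(all_paired_sig),
                }
            )

    # dose vs delta, per point, treated side only; BH family = 18 features
    # within one mode x timepoint
    dose_rows = []
    ipsi = deltas[deltas["side"] == "ipsilateral"].merge(
        doses, on=["patient_id", "point_site"], how="inner"
    )
    for mode in modes:
        for tp in post:
            sub = ipsi[(ipsi["mode"] == mode) & (ipsi["timepoint"] == tp)]
            fam = []
            for feat in FEATURE_NAMES:
                pair = sub[[feat, "dose_cGy"]].dropna()
                try:
                    cr = gated_correlation(pair[feat], pair["dose_cGy"])
                    fam.append(
                        {
                            "mode": mode, "timepoint": tp, "feature": feat,
                            "method": cr.method, "r": cr.r, "p": cr.p, "n": cr.n,
                        }
                    )
                except ValueError as exc:
                    fam.append(
                        {"mode": mode, "timepoint": tp, "feature": feat, "note": str(exc)}
                    )
            ps = [row["p"] for row in fam if "p" in row]
            adj = iter(bh_adjust(ps)) if ps else iter([])
            for row in fam:
                row["p_adjusted"] = float(next(adj)) if "p" in row else np.nan
            dose_rows.extend(fam)

    # day-7 delta vs later deltas, treated side, per breast; BH family =
    # 18 features within one mode x later timepoint
    carry_rows = []
    pv_ipsi = patient_values[patient_values["side"] == "ipsilateral"]
    first_post = post[0] if post else None
    for mode in modes:
        sub = pv_ipsi[pv_ipsi["mode"] == mode]
        for tp in post[1:]:
            fam = []
            for feat in FEATURE_NAMES:
                wide = sub.pivot_table(
                    index="patient_id", columns="timepoint", values=feat, sort=False
                )
                pair = wide[[first_post, tp]].dropna()
                try:
                    cr = gated_correlation(pair[first_post], pair[tp])
                    fam.append(
                        {
                            "mode": mode, "timepoint": tp, "feature": feat,
                            "method": cr.method, "r": cr.r, "p": cr.p, "n": cr.n,
                        }
                    )
                except ValueError as exc:
                    fam.append(
                        {"mode": mode, "timepoint": tp, "feature": feat, "note": str(exc)}
                    )
            ps = [row["p"] for row in fam if "p" in row]
            adj = iter(bh_adjust(ps)) if ps else iter([])
            for row in fam:
                row["p_adjusted"] = float(next(adj)) if "p" in row else np.nan
            carry_rows.extend(fam)

    return InferenceReport(
        anova=pd.DataFrame(anova_rows),
        paired=pd.DataFrame(paired_rows),
        dose_correlation=pd.DataFrame(dose_rows),
        carryover_correlation=pd.DataFrame(carry_rows),
        feature_flags=pd.DataFrame(flag_rows),
        alpha=alpha,
        pairwise_threshold=threshold,
    )
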