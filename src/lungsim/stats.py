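"""Cohort statistics: correlations, Fisher z, ANCOVA slopes, Holm-Bonferroni.

The analysis layer applied to a processed cohort table: univariate
relationships of VDP with lung-function and model-impedance measures
(Pearson by default, Spearman when a Shapiro-Wilk screen rejects normality),
comparison of correlation magnitudes via the Fisher z transformation, slope
homogeneity across frequencies via analysis of covariance, and step-down
Holm-Bonferroni control over each comparison family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .errors import DomainError, FormatError, ValidationError


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    r: float
    n: int
    p_value: float
    normal_x: bool | None = None
    normal_y: bool | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "r": self.r,
            "n": self.n,
            "p_value": self.p_value,
            "normal_x": self.normal_x,
            "normal_y": self.normal_y,
        }


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    normality_alpha: float = 0.05,
) -> CorrelationResult:
    """Correlation of two variables with an automatic parametric/rank switch.

    With ``method="auto"`` each variable is screened with the Shapiro-Wilk
    test at ``normality_alpha``; Pearson is used when both pass, Spearman
    otherwise. ``method="pearson"``/``"spearman"`` force the choice (the
    screen is still reported).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise DomainError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for a zero-variance variable")
    normal_x = bool(sps.shapiro(x).pvalue > normality_alpha)
    normal_y = bool(sps.shapiro(y).pvalue > normality_alpha)
    if method == "auto":
        method = "pearson" if (normal_x and normal_y) else "spearman"
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise DomainError("method must be 'auto', 'pearson' or 'spearman'")
    return CorrelationResult(
        method=method,
        r=float(r),
        n=int(x.size),
        p_value=float(p),
        normal_x=normal_x,
        normal_y=normal_y,
    )


def fisher_z_compare(
    r1: float,
    n1: int,
    r2: float,
    n2: int,
    use_magnitude: bool = False,
) -> tuple[float, float]:
    """Two-sided comparison of two independent correlation coefficients.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), p from the standard
    normal. With ``use_magnitude`` the transform is applied to |r|, which is the
    appropriate mode when comparing the strength of correlations of opposite
    sign.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise DomainError("|r| must be < 1 for the Fisher z transform")
    for n in (n1, n2):
        if n <= 3:
            raise DomainError("need n > 3 in each sample")
    a, b = (abs(r1), abs(r2)) if use_magnitude else (r1, r2)
    z = (np.arctanh(a) - np.arctanh(b)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def fisher_z_compare_dependent(
    r1: float, r2: float, r12: float, n: int
) -> tuple[float, float]:
    """Steiger's test for two correlations sharing a variable (optional mode).

    ``r1`` and ``r2`` both involve the shared variable; ``r12`` is the
    correlation between the two non-shared variables, which the independent-
    samples formula cannot account for.
    """
    for r in (r1, r2, r12):
        if abs(r) >= 1:
            raise DomainError("|r| must be < 1")
    if n <= 3:
        raise DomainError("need n > 3")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar = (r1 + r2) / 2.0
    # Steiger (1980) Z1*: covariance of the two dependent correlations
    cov = r12 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r12**2)
    s = cov / ((1 - rbar**2) ** 2)
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - s)))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


@dataclass(frozen=True)
class AncovaResult:
    f_interaction: float
    p_interaction: float
    df_num: int
    df_den: int
    slopes: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "f_interaction": self.f_interaction,
            "p_interaction": self.p_interaction,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "slopes": list(self.slopes),
        }


def ancova_slopes(groups: Sequence[tuple[Sequence[float], Sequence[float]]]) -> AncovaResult:
    """Slope-homogeneity test across groups: y ~ group + x + group:x.

    Fits the full general linear model with per-group intercepts and slopes and
    the reduced model with a pooled slope; the interaction F statistic compares
    their residual sums of squares. Per-group slopes come from the full fit.
    """
    if len(groups) < 2:
        raise DomainError("need at least 2 groups")
    xs, ys, gs = [], [], []
    for gi, (x, y) in enumerate(groups):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size or x.size < 3:
            raise DomainError("each group needs >= 3 paired observations")
        xs.append(x)
        ys.append(y)
        gs.append(np.full(x.size, gi))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    g = np.concatenate(gs).astype(int)
    k = len(groups)
    n = x.size
    # full design: per-group intercept and per-group slope
    full = np.zeros((n, 2 * k))
    for gi in range(k):
        sel = g == gi
        full[sel, gi] = 1.0
        full[sel, k + gi] = x[sel]
    # reduced design: per-group intercept, single pooled slope
    reduced = np.column_stack([full[:, :k], x])
    if np.linalg.matrix_rank(full) < 2 * k:
        raise ValidationError("rank-deficient ANCOVA design (degenerate group)")
    fit_full = sm.OLS(y, full).fit()
    fit_red = sm.OLS(y, reduced).fit()
    df_num = k - 1
    df_den = n - 2 * k
    if df_den <= 0:
        raise DomainError("not enough observations for the interaction test")
    num = (fit_red.ssr - fit_full.ssr) / df_num
    den = fit_full.ssr / df_den
    f = float(num / den) if den > 0 else np.inf
    p = float(sps.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0
    slopes = tuple(float(b) for b in fit_full.params[k:])
    return AncovaResult(
        f_interaction=f, p_interaction=p, df_num=df_num, df_den=df_den, slopes=slopes
    )


def holm_bonferroni(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm-Bonferroni correction.

    Returns (reject flags, adjusted p-values) in the original order; adjusted
    p-values are the running maximum of (m - i + 1) * p_(i), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, p_adj


# ---------------------------------------------------------------------------
# cohort-level report
# ---------------------------------------------------------------------------

_SLOPE_METRICS = (
    "rrs0_2",
    "rrs5",
    "rrs20",
    "rrs0_2_5",
    "rrs5_20",
    "xrs0_2",
    "xrs5",
    "xrs20",
    "ers0_2",
    "ers5",
)


@dataclass
class CohortReport:
    """Correlation/slope analysis of a processed cohort table."""

    correlations: dict[str, CorrelationResult]
    fisher_comparisons: list[dict]
    slopes: dict[str, dict[str, float]]  # per closure generation
    ancova: dict[str, AncovaResult]
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "correlations": {k: v.to_dict() for k, v in self.correlations.items()},
            "fisher_comparisons": self.fisher_comparisons,
            "slopes": self.slopes,
            "ancova": {k: v.to_dict() for k, v in self.ancova.items()},
            "notes": self.notes,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def analyze_cohort(
    records: pd.DataFrame,
    closure_generations: Sequence[int] = (9, 14),
    vdp_column: str = "est_vdp",
    alpha: float = 0.05,
) -> CohortReport:
    """Reproduce the study's analysis matrix on a processed cohort table.

    Computes pooled-across-conditions correlations of VDP with FEV1 %pred,
    baseline Raw %pred and the 5 Hz impedance predictions per closure
    generation; compares correlation magnitudes with the Fisher z
    transformation under Holm-Bonferroni control; fits per-metric regression
    slopes against VDP; and tests slope homogeneity across frequencies with
    ANCOVA for resistance and reactance separately.

    Conditions are pooled as repeated measures treated as independent samples
    (n = subjects x conditions), which inflates effective n; the report flags
    this in ``notes``.
    """
    required = {vdp_column, "fev1_pct_pred", "condition"}
    missing = required - set(records.columns)
    if missing:
        raise FormatError(f"cohort table missing columns: {sorted(missing)}")
    vdp = records[vdp_column].to_numpy(dtype=float)
    correlations: dict[str, CorrelationResult] = {}
    correlations["fev1"] = correlate(vdp, records["fev1_pct_pred"].to_numpy(float))
    if "raw_pct_pred" in records.columns:
        base = records[records["condition"] == "baseline"]
        if len(base) >= 3:
            correlations["raw"] = correlate(
                base[vdp_column].to_numpy(float), base["raw_pct_pred"].to_numpy(float)
            )
    for gen in closure_generations:
        for metric in ("rrs5", "xrs5"):
            col = f"{metric}_g{gen}"
            if col in records.columns:
                correlations[f"{metric}_g{gen}"] = correlate(
                    vdp, records[col].to_numpy(float)
                )

    # correlation-magnitude comparisons (|r|), Holm-corrected as one family
    comparisons = []
    pairs = []
    for gen in closure_generations:
        key = f"rrs5_g{gen}"
        if key in correlations:
            pairs.append((key, "fev1"))
    if all(f"xrs5_g{g}" in correlations for g in closure_generations[:2]) and len(
        closure_generations
    ) >= 2:
        g1, g2 = closure_generations[0], closure_generations[1]
        pairs.append((f"xrs5_g{g2}", f"xrs5_g{g1}"))
        pairs.append((f"rrs5_g{g2}", f"rrs5_g{g1}"))
    pvals = []
    for a, b in pairs:
        ca, cb = correlations[a], correlations[b]
        if max(abs(ca.r), abs(cb.r)) >= 1.0 - 1e-12:
            # degenerate (perfectly collinear) cohort: the transform diverges
            notes_extra = f"fisher comparison {a} vs {b} skipped (|r| = 1)"
            comparisons.append(
                {"stronger": a, "against": b, "z": None, "p_value": None,
                 "note": notes_extra}
            )
            continue
        z, p = fisher_z_compare(ca.r, ca.n, cb.r, cb.n, use_magnitude=True)
        comparisons.append({"stronger": a, "against": b, "z": z, "p_value": p})
        pvals.append(p)
    if pvals:
        reject, p_adj = holm_bonferroni(pvals, alpha=alpha)
        tested = [c for c in comparisons if c["p_value"] is not None]
        for c, rej, pa in zip(tested, reject, p_adj):
            c["p_holm"] = float(pa)
            c["significant"] = bool(rej)

    # per-metric slopes and frequency-wise ANCOVA
    slopes: dict[str, dict[str, float]] = {}
    ancova: dict[str, AncovaResult] = {}
    for gen in closure_generations:
        gen_slopes = {}
        for metric in _SLOPE_METRICS:
            col = f"{metric}_g{gen}"
            if col in records.columns:
                gen_slopes[metric] = _ols_slope(vdp, records[col].to_numpy(float))
        if gen_slopes:
            slopes[f"g{gen}"] = gen_slopes
        r_cols = [f"rrs0_2_g{gen}", f"rrs5_g{gen}", f"rrs20_g{gen}"]
        x_cols = [f"xrs0_2_g{gen}", f"xrs5_g{gen}", f"xrs20_g{gen}"]
        if all(c in records.columns for c in r_cols):
            ancova[f"rrs_vs_frequency_g{gen}"] = ancova_slopes(
                [(vdp, records[c].to_numpy(float)) for c in r_cols]
            )
        if all(c in records.columns for c in x_cols):
            ancova[f"xrs_vs_frequency_g{gen}"] = ancova_slopes(
                [(vdp, records[c].to_numpy(float)) for c in x_cols]
            )

    notes = [
        "conditions pooled as independent observations (n = subjects x conditions), "
        "mirroring the repeated-measures pooling of the emulated study design"
    ]
    return CohortReport(
        correlations=correlations,
        fisher_comparisons=comparisons,
        slopes=slopes,
        ancova=ancova,
        notes=notes,
    )
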