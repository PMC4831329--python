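"""Synthetic cohorts: three conditions per subject, end-to-end simulation.

A cohort emulates a bronchoprovocation study: each subject is imaged at
baseline, post-methacholine and post-salbutamol. Per-condition true ventilation
defect percent (VDP) is drawn from truncated normals with (mean, sd) = (4, 4),
(11, 10) and (4, 2) percent respectively, truncated to [0, 60]. FEV1 %predicted
is drawn per condition with a configurable negative coupling to the subject's
VDP (default r = -0.6); airways resistance %predicted (plethysmography, one
pre-challenge measurement per subject) is positively coupled to the subject's
baseline VDP (default r = +0.7). The coupling defaults are design choices of
the generator, documented, not measured values.

``run_cohort`` pushes every subject-condition through the full pipeline:
phantom -> cavity segmentation -> ventilation clustering -> VDP and defect
regions -> fiducial registration -> closure plans at the configured target
generations -> narrowed impedance sweeps and band metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .closure import select_branches_for_defects, simulate_condition
from .coregister import apply_transform, dice_coefficient, rigid_from_fiducials
from .errors import DomainError
from .mechanics import (
    DEFAULT_FREQUENCIES,
    ElastanceModel,
    GasProperties,
    ImpedanceEngine,
    RespiratoryConfig,
)
from .morphometry import default_morphometry
from .phantom import PhantomSpec, generate_phantom
from .pipeline import process_subject_images
from .tree import AirwayTree, generate_tree, scale_to_frc

CONDITIONS = ("baseline", "post_methacholine", "post_salbutamol")

#: metric column suffixes written per closure generation
_METRIC_COLS = (
    ("rrs0_2", "rrs_0p2"),
    ("rrs5", "rrs_5"),
    ("rrs20", "rrs_20"),
    ("rrs0_2_5", "rrs_0p2_5"),
    ("rrs5_20", "rrs_5_20"),
    ("xrs0_2", "xrs_0p2"),
    ("xrs5", "xrs_5"),
    ("xrs20", "xrs_20"),
    ("ers0_2", "ers_0p2"),
    ("ers5", "ers_5"),
)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_subjects: int = 25
    vdp_mean_sd: dict = field(
        default_factory=lambda: {
            "baseline": (4.0, 4.0),
            "post_methacholine": (11.0, 10.0),
            "post_salbutamol": (4.0, 2.0),
        }
    )
    vdp_bounds: tuple[float, float] = (0.0, 60.0)
    fev1_mean_sd: dict = field(
        default_factory=lambda: {
            "baseline": (84.0, 15.0),
            "post_methacholine": (64.0, 15.0),
            "post_salbutamol": (87.0, 15.0),
        }
    )
    raw_mean_sd: tuple[float, float] = (126.0, 69.0)
    fev1_vdp_corr: float = -0.6
    raw_vdp_corr: float = 0.7
    snr: float = 20.0
    closure_generations: tuple[int, ...] = (9, 14)
    margin_voxels: int = 2
    diameter_factor: float = 0.1
    fiducial_noise_mm: float = 1.0
    frequencies_hz: tuple[float, ...] = DEFAULT_FREQUENCIES
    frc_linear_factor: float = 0.8
    tree_seed: int = 1


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    if sd <= 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    n_subjects: int = 25,
    seed: int = 0,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Ground-truth cohort table: one row per subject-condition.

    Columns: subject, condition, true_vdp (%), fev1_pct_pred, raw_pct_pred
    (constant within subject). Deterministic under ``seed``.
    """
    if n_subjects < 2:
        raise DomainError("need at least 2 subjects")
    cfg = config or CohortConfig()
    if config is not None and config.n_subjects != n_subjects:
        cfg = replace(config, n_subjects=n_subjects)
    rng = np.random.default_rng(seed)
    lo, hi = cfg.vdp_bounds
    rows = []
    vdp_by_cond = {}
    for cond in CONDITIONS:
        mean, sd = cfg.vdp_mean_sd[cond]
        vdp_by_cond[cond] = _truncated_normal(rng, mean, sd, lo, hi, n_subjects)
    # Raw %pred: single plethysmography value per subject, measured before the
    # challenge, hence coupled to the baseline VDP
    m_raw, s_raw = cfg.raw_mean_sd
    m_v, s_v = cfg.vdp_mean_sd["baseline"]
    z_base = (vdp_by_cond["baseline"] - m_v) / max(s_v, 1e-12)
    rho = cfg.raw_vdp_corr
    eps = rng.standard_normal(n_subjects) if s_raw > 0 else np.zeros(n_subjects)
    raw = m_raw + s_raw * (rho * z_base + np.sqrt(max(0.0, 1 - rho**2)) * eps)
    raw = np.clip(raw, 10.0, None)
    for cond in CONDITIONS:
        mean, sd = cfg.vdp_mean_sd[cond]
        m_f, s_f = cfg.fev1_mean_sd[cond]
        z_v = (vdp_by_cond[cond] - mean) / max(sd, 1e-12)
        rho_f = cfg.fev1_vdp_corr
        eps = rng.standard_normal(n_subjects) if s_f > 0 else np.zeros(n_subjects)
        fev1 = m_f + s_f * (rho_f * z_v + np.sqrt(max(0.0, 1 - rho_f**2)) * eps)
        for i in range(n_subjects):
            rows.append(
                {
                    "subject": i + 1,
                    "condition": cond,
                    "true_vdp": float(vdp_by_cond[cond][i]),
                    "fev1_pct_pred": float(fev1[i]),
                    "raw_pct_pred": float(raw[i]),
                }
            )
    frame = pd.DataFrame(rows)
    return frame.sort_values(["subject", "condition"], key=_condition_key).reset_index(
        drop=True
    )


def _condition_key(col: pd.Series) -> pd.Series:
    if col.name == "condition":
        order = {c: i for i, c in enumerate(CONDITIONS)}
        return col.map(order)
    return col


def default_tree(config: CohortConfig | None = None) -> AirwayTree:
    """The cohort's shared airway tree: morphometry fixture, deflated to FRC."""
    cfg = config or CohortConfig()
    tree = generate_tree(default_morphometry(), seed=cfg.tree_seed)
    return scale_to_frc(tree, cfg.frc_linear_factor)


def run_cohort(
    cohort: pd.DataFrame,
    tree: AirwayTree | None = None,
    seed: int = 0,
    config: CohortConfig | None = None,
    gas: GasProperties = GasProperties(),
    elastance: ElastanceModel = ElastanceModel(),
    respiratory: RespiratoryConfig | None = None,
) -> pd.DataFrame:
    """Full pipeline over a ground-truth cohort table.

    Returns the input table extended with estimated VDP, registration quality,
    closed-branch counts and impedance band metrics per closure generation
    (columns like ``rrs5_g9``, ``xrs5_g14``). One shared airway tree is used
    for all subjects, as in a generic-model study design.
    """
    cfg = config or CohortConfig()
    respiratory = respiratory or RespiratoryConfig()
    if tree is None:
        tree = default_tree(cfg)
    engine = ImpedanceEngine(tree, gas, elastance, respiratory, cfg.frequencies_hz)
    rng = np.random.default_rng(seed)
    out_rows = []
    for _, row in cohort.iterrows():
        row_seed = int(rng.integers(2**31))
        spec = PhantomSpec(
            defect_fraction_pct=float(row["true_vdp"]),
            snr=cfg.snr,
            fiducial_noise_mm=cfg.fiducial_noise_mm,
            seed=row_seed,
        )
        phantom = generate_phantom(spec, tree=tree)
        imaging = process_subject_images(
            phantom.proton, phantom.ventilation, seed=row_seed
        )
        transform = rigid_from_fiducials(
            phantom.fiducials_model_mm, phantom.fiducials_image_mm
        )
        mapped = apply_transform(tree, transform, phantom.grid)
        model_mask = phantom.registered_model_mask(transform)
        rec = dict(row)
        rec["phantom_vdp"] = phantom.true_vdp
        rec["est_vdp"] = imaging.vdp
        rec["n_defect_regions"] = len(imaging.defect_regions)
        rec["fre_mm"] = transform.fre
        rec["cavity_dice"] = dice_coefficient(model_mask, imaging.cavity_mask)
        for gen in cfg.closure_generations:
            plan = select_branches_for_defects(
                tree,
                mapped,
                imaging.defect_regions,
                generation=gen,
                margin_voxels=cfg.margin_voxels,
                diameter_factor=cfg.diameter_factor,
            )
            result = simulate_condition(
                tree,
                plan,
                gas,
                elastance,
                respiratory,
                cfg.frequencies_hz,
                engine=engine,
            )
            rec[f"n_closed_g{gen}"] = plan.n_branches
            metrics = result.metrics
            for col, attr in _METRIC_COLS:
                rec[f"{col}_g{gen}"] = getattr(metrics, attr)
        out_rows.append(rec)
    return pd.DataFrame(out_rows)
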