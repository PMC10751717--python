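"""TG-43 source characterization: air-kerma strength Sk, dose-rate constant
Lambda, and the uncertainty budget.

Sk is scored with the source in vacuum, in a coaxial air ring cell of
0.1 cm radial width and 0.1 cm height at 10 cm on the transverse axis;
Sk = K_air * d^2 (1 U = 1 uGy m2/h = 1 cGy cm2/h).  Lambda is the water
collisional-kerma rate in a ring cell of 0.5 mm radial thickness and 1 mm
height at 1 cm on the transverse axis, with the source centered in a 40 cm
radius water sphere (full scatter), divided by Sk.

The ring cells extend the stated transverse cells over the full azimuth:
by the cylindrical symmetry of both scoring geometries this is an exact
variance reduction, not an approximation.  With photon-only transport and
vacuum surroundings no free-air-chamber style electron filtering or
scatter corrections apply to the Sk geometry.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import run_characterize
from .geometry import SourceCapsule
from .materials import EmissionSpectrum
from .tallies import CylinderCell

__all__ = [
    "TG43Result", "UncertaintyBudget", "BudgetSummary", "SkResult",
    "compute_sk", "compute_lambda", "quadrature_budget",
    "default_budget_dose_rate", "default_budget_sk", "write_report",
    "EV_PER_G_TO_GY", "U_PER_GY_CM2_PER_H",
]

EV_PER_G_TO_GY = 1.602176634e-16  # 1 eV/g in Gy
U_PER_GY_CM2_PER_H = 100.0  # 1 Gy cm2/h = 100 U
SK_REFERENCE_DISTANCE_CM = 10.0


@dataclass
class SkResult:
    """Air-kerma strength of a modeled source."""

    sk_u_per_bq: float  # U per Bq (1 U = 1 uGy m2 h-1)
    sk_per_history_ev_g_cm2: float  # ring kerma * d^2, eV/g per history
    type_a_rel_k1: float
    n_histories: int
    yield_per_decay: float


@dataclass
class TG43Result:
    """Source characterization summary."""

    sk: float  # U per Bq
    lam: float  # cGy / (h U)
    type_a_uncertainty: float  # %, at coverage factor k
    coverage_factor: int = 1

    def __post_init__(self):
        if self.sk <= 0:
            raise ValueError("Sk must be > 0")
        if not (0.5 < self.lam < 1.5):
            raise ValueError(
                f"dose-rate constant {self.lam} outside the physically "
                "plausible window (0.5, 1.5) for Ir-192-class sources")


def sk_cell() -> CylinderCell:
    """Transverse air cell of the Sk geometry (ring, 0.1 x 0.1 cm)."""
    return CylinderCell(inner_radius=SK_REFERENCE_DISTANCE_CM - 0.05,
                        outer_radius=SK_REFERENCE_DISTANCE_CM + 0.05,
                        half_height=0.05, material="air")


def lambda_cell() -> CylinderCell:
    """Transverse water cell at 1 cm (ring, 0.5 mm thick, 1 mm high)."""
    return CylinderCell(inner_radius=0.975, outer_radius=1.025,
                        half_height=0.05, material="water")


def compute_sk(capsule: SourceCapsule | None, spectrum: EmissionSpectrum,
               histories: int, seed: int) -> SkResult:
    """Air-kerma strength per unit activity, from a vacuum run.

    ``capsule=None`` scores a bare (hypothetical) point source.
    """
    res = run_characterize(capsule, spectrum, [sk_cell()], mode="sk",
                           n_histories=histories, seed=seed)
    kerma = float(res.mean[0])  # eV/g per history (one photon per history)
    if kerma <= 0:
        raise RuntimeError(
            "no photon reached the Sk scoring cell; increase the number "
            "of histories")
    per_decay = kerma * spectrum.total_yield
    sk = (per_decay * EV_PER_G_TO_GY * 3600.0
          * SK_REFERENCE_DISTANCE_CM**2 * U_PER_GY_CM2_PER_H)
    return SkResult(
        sk_u_per_bq=sk,
        sk_per_history_ev_g_cm2=kerma * SK_REFERENCE_DISTANCE_CM**2,
        type_a_rel_k1=float(res.relative_uncertainty[0]),
        n_histories=histories,
        yield_per_decay=spectrum.total_yield,
    )


def compute_lambda(capsule: SourceCapsule | None,
                   spectrum: EmissionSpectrum, histories: int, seed: int,
                   sk_result: SkResult,
                   sphere_radius: float = 40.0,
                   full_scatter: bool = True) -> TG43Result:
    """Dose-rate constant from a full-scatter water-sphere run.

    ``full_scatter=False`` truncates the medium just outside the scoring
    cell (1.5 cm radius), removing backscatter — a diagnostic mode.
    """
    radius = sphere_radius if full_scatter else 1.5
    res = run_characterize(capsule, spectrum, [lambda_cell()],
                           mode="lambda", n_histories=histories, seed=seed,
                           environment_material="water",
                           sphere_radius=radius)
    kerma = float(res.mean[0])  # eV/g per history, water, at 1 cm
    if kerma <= 0:
        raise RuntimeError(
            "no photon reached the 1 cm scoring cell; increase histories")
    dose_rate_cgy_h = (kerma * spectrum.total_yield * EV_PER_G_TO_GY
                       * 3600.0 * 100.0)  # cGy/h per Bq
    lam = dose_rate_cgy_h / sk_result.sk_u_per_bq
    rel_a = float(np.hypot(res.relative_uncertainty[0],
                           sk_result.type_a_rel_k1))
    return TG43Result(sk=sk_result.sk_u_per_bq, lam=lam,
                      type_a_uncertainty=100.0 * 2.0 * rel_a,
                      coverage_factor=2)


# ---------------------------------------------------------------------------
# Uncertainty budget
# ---------------------------------------------------------------------------

@dataclass
class UncertaintyBudget:
    """Component list (label, 'A'|'B', percent at k=1) for one quantity."""

    quantity: str
    components: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self):
        if not self.components:
            raise ValueError("budget needs at least one component")
        for label, typ, val in self.components:
            if typ not in ("A", "B"):
                raise ValueError(f"component {label!r}: type must be A or B")
            if val < 0:
                raise ValueError(f"component {label!r}: negative value")


@dataclass
class BudgetSummary:
    type_a: float  # % at k=1, quadrature sum
    type_b: float
    total_k1: float
    total_k2: float


def quadrature_budget(budget: UncertaintyBudget) -> BudgetSummary:
    """Root-sum-square within each type, then across types; k=2 doubles."""
    a = np.sqrt(sum(v**2 for _, t, v in budget.components if t == "A"))
    b = np.sqrt(sum(v**2 for _, t, v in budget.components if t == "B"))
    tot = float(np.hypot(a, b))
    return BudgetSummary(type_a=float(a), type_b=float(b), total_k1=tot,
                         total_k2=2.0 * tot)


def default_budget_dose_rate(tally_statistics_pct: float = 0.01
                             ) -> UncertaintyBudget:
    """Standard component budget for the dose rate at 1 cm (generic
    HDR Ir-192 source); the Type A entry is the run's own statistics."""
    return UncertaintyBudget("dose rate at 1 cm", [
        ("Monte-Carlo physics", "B", 0.05),
        ("phantom composition", "B", 0.01),
        ("phantom cross section (mu/rho)", "B", 0.01),
        ("dose calculation (muen/rho)", "B", 0.07),
        ("tally volume averaging", "B", 0.20),
        ("tally statistics", "A", tally_statistics_pct),
    ])


def default_budget_sk(tally_statistics_pct: float = 0.015
                      ) -> UncertaintyBudget:
    """Standard component budget for the air-kerma strength."""
    return UncertaintyBudget("air-kerma strength", [
        ("Monte-Carlo physics", "B", 0.05),
        ("phantom composition", "B", 0.01),
        ("phantom cross section (mu/rho)", "B", 0.001),
        ("dose calculation (muen/rho)", "B", 0.07),
        ("tally volume averaging", "B", 0.02),
        ("tally statistics", "A", tally_statistics_pct),
    ])


def write_report(path, result: TG43Result, sk_result: SkResult,
                 budgets: list[UncertaintyBudget], seed: int,
                 metadata: dict | None = None) -> None:
    """Structured-text characterization report."""
    lines = [
        "# TG-43 source characterization report",
        f"Sk_U_per_Bq: {result.sk:.6e}",
        f"dose_rate_constant_cGy_per_hU: {result.lam:.5f}",
        f"type_A_pct_k{result.coverage_factor}: "
        f"{result.type_a_uncertainty:.4f}",
        f"n_histories_sk: {sk_result.n_histories}",
        f"seed: {seed}",
        "physics: photon-only, 1 keV cut-off, free-electron Klein-Nishina "
        "Compton, local photoelectric deposition, ring-cell symmetrization",
    ]
    for k, v in (metadata or {}).items():
        lines.append(f"{k}: {v}")
    for b in budgets:
        s = quadrature_budget(b)
        lines.append(f"## budget: {b.quantity}")
        for label, typ, val in b.components:
            lines.append(f"  {label} ({typ}): {val:.3f} %")
        lines.append(f"  quadrature A: {s.type_a:.2f} %  B: {s.type_b:.2f} %"
                     f"  total k=1: {s.total_k1:.2f} %"
                     f"  k=2: {s.total_k2:.2f} %")
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")
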