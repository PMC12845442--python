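"""Case-study presets and the synthetic-data generator.

The presets are illustrative parameterizations of three classes of
subgingival delivery system — a chlorhexidine chip with a biphasic
burst/zero-order profile, PLGA minocycline microspheres with
diffusion-plus-relaxation (Peppas–Sahlin) kinetics, and a doxycycline
in situ gel depositing directly into the pocket — together with plain
healthy/inflamed pocket physiologies that differ only in crevicular-fluid
flow.  They are labelled "<drug>_like" deliberately: parameter values are
mid-range physiological choices, not product label claims.

The interface areas A_SM = 4, A_SB = 2, A_BP = 0.1 and A_SP = 0.05 cm² are
fixed assumptions: only the saliva–mucosa area has a published typical range
(2–6 cm²); the others are geometric judgement calls for a posterior
interproximal site and are the same across presets so scenario comparisons
isolate flow and release effects.

``synth_release_data`` is the fixture generator used throughout the test
suite: it samples a release model on a log-spaced grid and perturbs it with
multiplicative Gaussian noise from a seeded PCG64 generator, so every
fixture is reproducible across platforms.
"""

from __future__ import annotations


from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import DoseEvent, DoseRoute, OralPhysiology
from .pbpk import SimulationGrid, simulate
from .pkpd import summarize
from .release import ReleaseData, ReleaseModel, biphasic_model, time_to_fraction

__all__ = [
    "ScenarioPreset",
    "PRESET_NAMES",
    "preset",
    "synth_release_data",
    "sweep",
]

PRESET_NAMES = (
    "healthy_pocket",
    "inflamed_pocket",
    "periochip_like",
    "arestin_like",
    "atridox_like",
)

# mid-range physiology shared by all presets; Q_GCF varies by pocket status
_BASE = dict(
    V_S=0.8,  # mL, resting saliva volume
    Q_S=0.4,  # mL/min, resting flow
    A_SM=4.0,  # cm² (assumption, mid 2–6 range)
    A_SB=2.0,  # cm² (assumption)
    A_SP=0.05,  # cm² (assumption; pocket is semi-isolated from saliva)
    Gamma_max=10.0,  # µg/cm²
    k_ads=0.5,  # mL·cm⁻²·min⁻¹
    k_des=0.05,  # 1/min
    P_SM=5e-5,  # cm/min
    K_p_T=5.0,
    V_T=0.075,  # mL
    CL_local=0.05,  # mL/min
    D_eff=3e-7,  # cm²/s
    k_bind=2e-4,  # 1/s, weak reversible-binding sink within the biofilm
    L_B=0.02,  # cm (200 µm)
    A_BP=0.1,  # cm² (assumption)
    V_P=1.0,  # µL
    R_in=0.0,
)

_Q_GCF_HEALTHY = 0.075  # µL/min, mid healthy range 0.05–0.1
_Q_GCF_INFLAMED = 0.3  # µL/min, mid inflamed range 0.2–0.5


@dataclass(frozen=True)
class ScenarioPreset:
    """A named, fully specified simulation scenario."""

    name: str
    physiology: OralPhysiology
    release: ReleaseModel | None
    doses: tuple[DoseEvent, ...]
    mic: float  # µg/mL; placeholder reference value, not a clinical breakpoint
    note: str
    default_grid: SimulationGrid
    far_boundary: str | None = None  # None -> simulate() auto-selects

    def simulate(self, grid: SimulationGrid | None = None, **kwargs):
        kwargs.setdefault("far_boundary", self.far_boundary)
        return simulate(
            self.physiology,
            self.doses,
            release=self.release,
            grid=grid or self.default_grid,
            **kwargs,
        )


def _physiology(q_gcf: float, **overrides) -> OralPhysiology:
    return OralPhysiology(**{**_BASE, "Q_GCF": q_gcf, **overrides})


def preset(name: str) -> ScenarioPreset:
    """Look up a scenario preset by name (see ``PRESET_NAMES``)."""
    if name == "healthy_pocket":
        return ScenarioPreset(
            name=name,
            physiology=_physiology(_Q_GCF_HEALTHY),
            release=None,
            doses=(DoseEvent(amount=2000.0, route=DoseRoute.SALIVA_BOLUS),),
            mic=1.0,
            note=(
                "Plain healthy pocket (Q_GCF mid healthy range) receiving a "
                "salivary rinse-style bolus; drug reaches the pocket by "
                "diffusing through the biofilm (coupled far boundary)."
            ),
            default_grid=SimulationGrid(t_end=240.0, dt_out=1.0),
            far_boundary="coupled",
        )
    if name == "inflamed_pocket":
        healthy = preset("healthy_pocket")
        return replace(
            healthy,
            name=name,
            physiology=healthy.physiology.replace(Q_GCF=_Q_GCF_INFLAMED),
            note=(
                "Identical to healthy_pocket except Q_GCF raised to the mid "
                "inflamed range; inflammation accelerates pocket wash-out."
            ),
        )
    if name == "periochip_like":
        # biphasic chip: ~24 h first-order burst of 40% of the dose, the
        # remainder zero-order over 8.5 days (mid 7–10 day window)
        t_end = 8.5 * 24 * 60.0
        model = biphasic_model(
            burst_fraction=0.4, burst_rate=4e-3, t_end=t_end, m_inf=2500.0
        )
        return ScenarioPreset(
            name=name,
            physiology=_physiology(_Q_GCF_INFLAMED),
            release=model,
            doses=(
                DoseEvent(
                    amount=2500.0,
                    route=DoseRoute.POCKET_FORMULATION,
                    duration=t_end,
                ),
            ),
            mic=0.5,
            note=(
                "Chlorhexidine-chip-like biphasic release (24 h burst then "
                "quasi-zero-order to day ~8.5) into an inflamed pocket with "
                "pellicle binding active. MIC is a placeholder reference."
            ),
            default_grid=SimulationGrid(t_end=t_end, dt_out=30.0),
        )
    if name == "arestin_like":
        # PLGA microspheres: diffusion + polymer relaxation over ~14 days
        model = ReleaseModel(
            "peppas_sahlin", {"k1": 0.008, "k2": 4e-5, "m": 0.45}, m_inf=1000.0
        )
        t_end = 14 * 24 * 60.0
        return ScenarioPreset(
            name=name,
            physiology=_physiology(_Q_GCF_INFLAMED),
            release=model,
            doses=(
                DoseEvent(
                    amount=1000.0, route=DoseRoute.POCKET_FORMULATION, duration=t_end
                ),
            ),
            mic=1.0,
            note=(
                "Minocycline-microsphere-like Peppas–Sahlin release into an "
                "inflamed pocket; pair with the Q_GCF-lowered healthy variant "
                "to see inflammation-driven wash-out."
            ),
            default_grid=SimulationGrid(t_end=t_end, dt_out=60.0),
        )
    if name == "atridox_like":
        # in situ gel: direct pocket deposition sustained over ~7 days with a
        # modest early burst; salivary coupling is structurally minimal
        # because the formulation bypasses saliva entirely
        t_end = 7 * 24 * 60.0
        model = biphasic_model(
            burst_fraction=0.2, burst_rate=2e-3, t_end=t_end, m_inf=50000.0
        )
        return ScenarioPreset(
            name=name,
            physiology=_physiology(_Q_GCF_INFLAMED),
            release=model,
            doses=(
                DoseEvent(
                    amount=50000.0, route=DoseRoute.POCKET_FORMULATION, duration=t_end
                ),
            ),
            mic=2.0,
            note=(
                "Doxycycline-gel-like sustained ~7-day direct pocket release; "
                "clearance is dominated by GCF flow and biofilm uptake."
            ),
            default_grid=SimulationGrid(t_end=t_end, dt_out=30.0),
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def healthy_variant(p: ScenarioPreset) -> ScenarioPreset:
    """The same scenario in a healthy (low Q_GCF) pocket."""
    return replace(
        p,
        name=f"{p.name}_healthy",
        physiology=p.physiology.replace(Q_GCF=_Q_GCF_HEALTHY),
    )


def synth_release_data(
    model: ReleaseModel,
    n_points: int = 15,
    noise_cv: float = 0.05,
    seed: int = 0,
    t_max: float | None = None,
) -> ReleaseData:
    """Noisy in vitro release curve on a log-spaced sampling grid.

    Times span three decades up to ``t_max`` (default: the time the model
    reaches 95% release).  Observations are F(t)·(1 + cv·ε) with ε ~ N(0, 1)
    from a PCG64 generator seeded with ``seed``, clamped to [0, 1.05] to
    mimic the small overshoot real dissolution data can show.
    """
    if not 0.0 <= noise_cv <= 0.3:
        raise ValueError("noise_cv must lie in [0, 0.3]")
    if n_points < 3:
        raise ValueError("need at least 3 sampling points")
    if t_max is None:
        t_max = time_to_fraction(model, 0.95)
    times = np.geomspace(t_max * 1e-3, t_max, n_points)
    clean = np.asarray(model.fraction(times), dtype=float)
    rng = np.random.Generator(np.random.PCG64(seed))
    noisy = clean * (1.0 + noise_cv * rng.standard_normal(n_points))
    return ReleaseData(times, np.clip(noisy, 0.0, 1.05))


def sweep(
    scenario: ScenarioPreset,
    parameter: str,
    values,
    grid: SimulationGrid | None = None,
    site: str = "pocket",
) -> pd.DataFrame:
    """Re-simulate a preset across values of one physiology parameter.

    Returns one row of MIC-referenced indices per value, sorted by value;
    failed runs are kept in the table with the error message instead of
    numbers.
    """
    if not hasattr(scenario.physiology, parameter) or parameter == "unit_system":
        raise ValueError(f"{parameter!r} is not an OralPhysiology field")
    rows = []
    for v in sorted(float(v) for v in values):
        if v <= 0:
            raise ValueError("sweep values must be positive")
        row: dict[str, object] = {parameter: v}
        try:
            res = simulate(
                scenario.physiology.replace(**{parameter: v}),
                scenario.doses,
                release=scenario.release,
                grid=grid or scenario.default_grid,
                far_boundary=scenario.far_boundary,
            )
            row.update(summarize(res.profile(site), scenario.mic).to_dict())
            row["error"] = ""
        except Exception as exc:  # propagate per-run failures into the table
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
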