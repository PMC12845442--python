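"""Classical compartmental pharmacokinetics.

For locally delivered periodontal therapies the systemically absorbed
fraction is small, but interpreting it still needs the standard machinery:
one-compartment IV bolus kinetics, the Bateman function for first-order
absorption (with flip-flop detection when absorption is the slower step) and
Michaelis–Menten saturable clearance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ClassicalPKParams",
    "iv_bolus_concentration",
    "clearance",
    "bateman_concentration",
    "mm_elimination_ode",
    "mm_concentration",
]

# relative k_a ≈ k window in which the removable-singularity limit is used
_BATEMAN_DEGENERATE = 1e-9


@dataclass(frozen=True)
class ClassicalPKParams:
    """One-compartment disposition parameters."""

    V: float  # distribution volume [mL]
    k: float  # first-order elimination rate [1/min]
    k_a: float = 0.0  # first-order absorption rate [1/min] (oral only)
    F_bio: float = 1.0  # bioavailable fraction (0, 1]
    Vmax: float = 0.0  # saturable elimination capacity [µg/min]
    Km: float = 0.0  # Michaelis constant [µg/mL]

    def __post_init__(self) -> None:
        if self.V <= 0 or self.k <= 0:
            raise ValueError("V and k must be positive")
        if not 0.0 < self.F_bio <= 1.0:
            raise ValueError("F_bio must lie in (0, 1]")
        for name in ("k_a", "Vmax", "Km"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def clearance(V: float, k: float) -> float:
    """Linear clearance CL = V·k [mL/min]."""
    return V * k


def iv_bolus_concentration(C0: float, k: float, t):
    """Mono-exponential IV bolus C(t) = C0·e^{−kt}."""
    t = np.asarray(t, dtype=float)
    out = C0 * np.exp(-k * t)
    return float(out) if out.ndim == 0 else out


def bateman_concentration(
    dose: float,
    F_bio: float,
    V: float,
    k_a: float,
    k: float,
    t,
) -> tuple[np.ndarray | float, bool]:
    """Bateman oral-absorption profile and the flip-flop flag.

    C(t) = F·dose·k_a / (V·(k_a − k)) · (e^{−kt} − e^{−k_a·t}).  The function
    is symmetric under swapping k_a and k; the returned flag is True when
    k_a < k (flip-flop kinetics: the terminal slope reflects absorption, not
    elimination).  The removable singularity at k_a = k is evaluated by its
    analytic limit (F·dose/V)·k·t·e^{−kt}.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    if abs(k_a - k) < _BATEMAN_DEGENERATE * k:
        out = (F_bio * dose / V) * k * t_arr * np.exp(-k * t_arr)
    else:
        out = (
            F_bio * dose * k_a / (V * (k_a - k))
            * (np.exp(-k * t_arr) - np.exp(-k_a * t_arr))
        )
    flip_flop = k_a < k
    return (float(out) if out.ndim == 0 else out), flip_flop


def mm_elimination_ode(C: float, Vmax: float, Km: float, V: float) -> float:
    """dC/dt for saturable elimination.

    The concentration-dependent clearance is CL(C) = Vmax/(Km + C), so the
    elimination rate is CL(C)·C and dC/dt = −Vmax·C / ((Km + C)·V).  At
    C ≪ Km this is first-order with k = Vmax/(Km·V); at C ≫ Km it is
    zero-order at Vmax/V.
    """
    if C < 0:
        raise ValueError("C must be non-negative")
    return -Vmax * C / ((Km + C) * V)


def mm_concentration(
    C0: float,
    Vmax: float,
    Km: float,
    V: float,
    t_eval,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Integrated Michaelis–Menten decline from C0 on the given time grid."""
    t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(
        lambda t, y: [mm_elimination_ode(max(y[0], 0.0), Vmax, Km, V)],
        (t_eval[0], t_eval[-1]),
        [C0],
        t_eval=t_eval,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"Michaelis–Menten integration failed: {sol.message}")
    return np.clip(sol.y[0], 0.0, None)
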