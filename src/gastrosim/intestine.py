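"""1-D advection-reaction transport of nutrient along the small intestine.

The lumen is a plug-flow segment z in [0, L] carrying a nutrient linear
density [g/m].  Content advects at the mean axial velocity ``u_bar``,
undergoes first-order luminal absorption at rate ``K_a``, and enters as a
point bolus at z = l_0 (the radius of the gastric ejection bolus).  The
scheme is explicit forward-Euler in time with a backward (upwind)
difference in space; a zero-gradient condition is applied at both ends,
which at the inlet annihilates the advective term and at the outlet lets
the upwind flux u_bar * density[-1] leave the domain as outflow.

Mass bookkeeping of the discrete scheme is exact: per step,
change in (sum(density)*dz) = injected - absorbed - outflow to round-off,
provided nothing occupies the inlet node (injection is interior).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import StabilityError

#: Default small-intestine length [m].
DEFAULT_L = 2.85
#: Default mean axial velocity [m/s].
DEFAULT_U_BAR = 1.7e-4
#: Default injection position / bolus radius [m] (sphere of ~65 ml).
DEFAULT_L0 = 0.025


@dataclass
class IntestineField:
    """Discretised nutrient linear density along the intestinal axis.

    ``densities[i]`` is the density [g/m] at node ``z_nodes[i]`` on a
    uniform grid of spacing ``dz`` spanning [0, L].
    """

    densities: np.ndarray
    dz: float
    L: float = DEFAULT_L
    u_bar: float = DEFAULT_U_BAR
    K_a: float = 0.0
    l_0: float = DEFAULT_L0

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if self.dz <= 0:
            raise ValueError("dz must be > 0")
        if not (0 < self.l_0 < self.L):
            raise ValueError("l_0 must lie strictly inside (0, L)")
        if self.K_a < 0 or self.u_bar < 0:
            raise ValueError("K_a and u_bar must be >= 0")
        n_expected = round(self.L / self.dz) + 1
        if self.densities.shape != (n_expected,):
            raise ValueError(
                f"densities must have {n_expected} nodes for L={self.L}, "
                f"dz={self.dz}"
            )

    # -- constructors ------------------------------------------------------

    @classmethod
    def empty(
        cls,
        n_cells: int = 570,
        L: float = DEFAULT_L,
        u_bar: float = DEFAULT_U_BAR,
        K_a: float = 0.0,
        l_0: float = DEFAULT_L0,
    ) -> "IntestineField":
        """An all-zero field with ``n_cells`` uniform cells (n_cells+1
        nodes)."""
        dz = L / n_cells
        return cls(np.zeros(n_cells + 1), dz=dz, L=L, u_bar=u_bar,
                   K_a=K_a, l_0=l_0)

    @property
    def z_nodes(self) -> np.ndarray:
        return np.arange(self.densities.size) * self.dz

    @property
    def injection_index(self) -> int:
        """Node nearest the bolus entry position z = l_0, clamped to the
        first interior node: the inlet node must stay empty for the
        zero-gradient inlet condition to be conservative."""
        return min(max(1, int(round(self.l_0 / self.dz))),
                   self.densities.size - 2)

    def total_mass(self) -> float:
        """Total luminal nutrient mass [g], by the rectangle rule that the
        stepping scheme conserves exactly."""
        return float(self.densities.sum() * self.dz)

    def max_stable_dt(self) -> float:
        """Largest dt [s] satisfying both the CFL bound and the reaction
        sub-step bound."""
        bounds = []
        if self.u_bar > 0:
            bounds.append(self.dz / self.u_bar)
        if self.K_a > 0:
            bounds.append(1.0 / self.K_a)
        return min(bounds) if bounds else np.inf


def inject_bolus(f: IntestineField, inflow_mass: float,
                 inplace: bool = False) -> IntestineField:
    """Add ``inflow_mass`` [g] as a point bolus at the node nearest l_0.

    The node density increases by inflow_mass/dz, so total luminal mass
    increases by exactly inflow_mass.
    """
    if inflow_mass < 0:
        raise ValueError("inflow_mass must be >= 0")
    out = f if inplace else replace(f, densities=f.densities.copy())
    out.densities[out.injection_index] += inflow_mass / out.dz
    return out


def step_transport(
    f: IntestineField, dt: float, inplace: bool = False
) -> tuple[IntestineField, float, float]:
    """Advance the field one explicit step of length ``dt`` [s].

    Returns ``(field, absorbed_mass, outflow_mass)`` in grams.  Raises
    :class:`StabilityError` when dt violates the CFL condition
    ``u_bar*dt/dz <= 1`` or the reaction bound ``K_a*dt < 1``, naming the
    admissible step.
    """
    courant = f.u_bar * dt / f.dz
    if courant > 1.0 or f.K_a * dt >= 1.0:
        raise StabilityError(
            f"dt={dt:g} s unstable (Courant={courant:.3g}, "
            f"K_a*dt={f.K_a * dt:.3g}); require dt <= {f.max_stable_dt():g} s"
        )
    d = f.densities
    absorbed = dt * f.K_a * d.sum() * f.dz
    outflow = dt * f.u_bar * d[-1]
    new = d - dt * f.K_a * d
    # upwind advection; zero-gradient ghost at the inlet makes the node-0
    # advective term vanish
    new[1:] -= courant * (d[1:] - d[:-1])
    if inplace:
        f.densities = new
        out = f
    else:
        out = replace(f, densities=new)
    return out, float(absorbed), float(outflow)


def absorption_rate(f: IntestineField) -> float:
    """Instantaneous absorption rate A = K_a * integral of density [g/s],
    by the trapezoidal rule on the grid."""
    return float(f.K_a * np.trapezoid(f.densities, dx=f.dz))
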