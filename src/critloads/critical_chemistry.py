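"""Critical leaching chemistry: the acceptable ANC export under the gibbsite
equilibrium and the Bc/Al criterion, and the critical nitrogen leaching.

The acceptable acidity export is the ANC leaching flux at the point where the
soil-solution molar Bc:Al ratio sits exactly at its ecosystem-specific
critical value while [Al] and [H] obey the gibbsite equilibrium
[Al] = K_gibb [H]^3. With Q the runoff (m/yr) and the net base-cation supply
bc_net = Bc_dep + Bc_w - Bc_u:

    Al_le = 1.5 * bc_net / (Bc/Al)_crit                   (eq/m2/yr)
    H_le  = Q^(2/3) * (Al_le / K_gibb)^(1/3)              (eq/m2/yr)
    ANC_le,crit = -(H_le + Al_le)

The 1.5 converts the equivalent ratio to the molar ratio under the
divalent-Bc / trivalent-Al convention ((1/2)/(1/3) = 1.5). External fluxes
are keq/ha/yr; the formula is evaluated internally in eq/m2/yr with K_gibb
in m6/eq2, which makes it dimensionally exact. A bisection-based oracle that
solves the two equilibrium conditions for the concentrations directly is
provided as an independent cross-check of the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .parameters import InvalidInputError

__all__ = [
    "ChemistryInputs",
    "anc_leaching_critical",
    "critical_point_oracle",
    "n_leaching_critical",
    "KEQ_PER_HA_PER_EQ_PER_M2",
]

#: 1 eq/m2/yr = 10 keq/ha/yr (1e4 m2/ha, 1e3 eq/keq)
KEQ_PER_HA_PER_EQ_PER_M2 = 10.0

N_EQUIVALENT_WEIGHT = 14.0  # g N per eq


@dataclass(frozen=True)
class ChemistryInputs:
    """Per-cell inputs of the critical-chemistry stage.

    ``bc_net`` must arrive already clamped to >= 0 (cells where uptake
    exceeds supply are clamped and flagged upstream).
    """

    runoff_q: float       # m/yr
    bc_net: float         # keq/ha/yr, Bc_dep + Bc_w - Bc_u, clamped >= 0
    kgibb: float          # m6/eq2
    bcal_crit: float      # molar Bc:Al ratio
    n_conc_crit: float = 0.0  # mg N/L

    def __post_init__(self) -> None:
        if self.runoff_q < 0:
            raise InvalidInputError(f"runoff must be >= 0: {self.runoff_q}")
        if self.bc_net < 0:
            raise InvalidInputError(
                f"bc_net must be clamped to >= 0 upstream, got {self.bc_net}"
            )
        if not self.kgibb > 0 or not self.bcal_crit > 0:
            raise InvalidInputError("kgibb and bcal_crit must be > 0")


def anc_leaching_critical(c: ChemistryInputs) -> float:
    """Critical ANC leaching (keq/ha/yr, <= 0), closed form."""
    return float(
        anc_le_crit_from_fields(c.runoff_q, c.bc_net, c.kgibb, c.bcal_crit)
    )


def anc_le_crit_from_fields(runoff_q, bc_net, kgibb, bcal_crit):
    """Vectorized closed form; inputs broadcast, fluxes in keq/ha/yr."""
    q = np.asarray(runoff_q, dtype=np.float64)
    bc = np.asarray(bc_net, dtype=np.float64) / KEQ_PER_HA_PER_EQ_PER_M2
    al_le = 1.5 * bc / np.asarray(bcal_crit)
    h_le = q ** (2.0 / 3.0) * (al_le / np.asarray(kgibb)) ** (1.0 / 3.0)
    return -(h_le + al_le) * KEQ_PER_HA_PER_EQ_PER_M2


def critical_point_oracle(c: ChemistryInputs) -> float:
    """Critical ANC leaching by numerically solving the equilibrium.

    Finds concentrations [H], [Al] (eq/m3) satisfying the gibbsite relation
    [Al] = K_gibb [H]^3 and the Bc/Al criterion expressed at leaching fluxes,
    Q [Al] = 1.5 bc_net / (Bc/Al)_crit, by bisection on [H]; returns
    -Q ([H] + [Al]) in keq/ha/yr. Independent of the closed form.
    """
    if c.bc_net == 0.0:
        return 0.0
    if c.runoff_q == 0.0:
        # no water flux: H-leaching vanishes, only the Al criterion flux
        return float(-1.5 * (c.bc_net / KEQ_PER_HA_PER_EQ_PER_M2)
                     / c.bcal_crit * KEQ_PER_HA_PER_EQ_PER_M2)
    al_flux = 1.5 * (c.bc_net / KEQ_PER_HA_PER_EQ_PER_M2) / c.bcal_crit

    def residual(h):  # Q * K_gibb * [H]^3 - required Al flux
        return c.runoff_q * c.kgibb * h**3 - al_flux

    hi = (al_flux / (c.runoff_q * c.kgibb)) ** (1.0 / 3.0)
    h = brentq(residual, 0.0, hi * 2.0, xtol=1e-300, rtol=1e-15, maxiter=500)
    al = c.kgibb * h**3
    return float(-c.runoff_q * (h + al) * KEQ_PER_HA_PER_EQ_PER_M2)


def n_leaching_critical(runoff_q, n_conc_crit):
    """Critical nitrogen leaching N_le,crit (keq/ha/yr).

    Q (m/yr) times the ecosystem's critical N concentration (mg N/L = g/m3),
    converted at 14 g N per equivalent.
    """
    q = np.asarray(runoff_q, dtype=np.float64)
    n = np.asarray(n_conc_crit, dtype=np.float64)
    if np.any(q < 0) or np.any(n < 0):
        raise InvalidInputError("runoff and critical N concentration must be >= 0")
    out = q * n / N_EQUIVALENT_WEIGHT * KEQ_PER_HA_PER_EQ_PER_M2
    return float(out) if np.isscalar(runoff_q) else out
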