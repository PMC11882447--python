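"""Allosteric two-state model (ATSM).

A ligand-free receptor equilibrates between an inactive and an active
conformation.  With equilibrium constant K_R = [active]/[inactive], the basal
activity is the active-state fraction,

    BA = K_R / (1 + K_R),        K_R = exp(-dG_apo / RT),

so dG_apo = -RT ln[BA / (1 - BA)].  BA(dG) is logistic and therefore
quasi-linear near its inflection (BA ~ 0.5), which is what licenses comparing
measured basal activities directly with computed conformational energy
differences on a linear scale.

Energies may arrive in forcefield units (REU); a scale factor kappa
(kcal/mol per REU, default 1) converts them before the RT arithmetic.
Correlation coefficients are invariant to kappa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

R_GAS = 1.98720425864083e-3  # kcal/(mol*K)


@dataclass(frozen=True)
class ThermoParams:
    T: float = 298.0  # K
    kappa: float = 1.0  # kcal/mol per REU

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    @property
    def RT(self) -> float:
        return R_GAS * self.T


@dataclass
class ActivityRecord:
    design_id: str
    basal_activity: float  # fraction of maximal agonist-induced WT activity
    ligand_induced: float | None = None
    sem: float | None = None


@dataclass
class EnergyRecord:
    design_id: str
    dG_inactive: float  # REU, relative to reference
    dG_active: float
    ddG_apo: float  # dG_active - dG_inactive, relative to reference

    @property
    def K_R(self) -> float:
        """Equilibrium constant at kappa = 1, RT at 298 K."""
        return float(np.exp(-self.ddG_apo / (R_GAS * 298.0)))


def ba_from_dg(dG_apo: float, params: ThermoParams | None = None) -> float:
    """Basal activity from the apo inactive->active free-energy difference.

    ``dG_apo`` is in energy units scaled by ``params.kappa`` to kcal/mol
    (kappa = 1 for inputs already in kcal/mol).
    """
    params = params or ThermoParams()
    x = params.kappa * dG_apo / params.RT
    return float(1.0 / (1.0 + np.exp(np.clip(x, -700, 700))))


def dg_from_ba(BA: float, params: ThermoParams | None = None) -> float:
    """Inverse of :func:`ba_from_dg`: dG_apo = -RT ln[BA/(1-BA)] (then /kappa)."""
    params = params or ThermoParams()
    if not 0.0 < BA < 1.0:
        raise ValueError(f"basal activity must lie strictly in (0,1); got {BA}")
    return float(-params.RT * np.log(BA / (1.0 - BA)) / params.kappa)


@dataclass
class QuasilinearityReport:
    max_abs_deviation: float
    r_squared: float
    slope: float
    intercept: float
    dg_range: tuple[float, float]


def quasilinearity_check(
    ba_range: tuple[float, float],
    params: ThermoParams | None = None,
    n_samples: int = 2001,
) -> QuasilinearityReport:
    """How linear BA(dG) is over the dG interval implied by a BA range.

    Samples the logistic densely, fits a least-squares line, and reports the
    maximum absolute residual and R^2.  Near BA = 0.5 the curve is almost
    exactly linear; over wide BA ranges the sigmoid shape shows.
    """
    params = params or ThermoParams()
    lo, hi = sorted(ba_range)
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("ba_range must be a nondegenerate interval inside (0,1)")
    dg_hi = dg_from_ba(lo, params)
    dg_lo = dg_from_ba(hi, params)
    dgs = np.linspace(dg_lo, dg_hi, n_samples)
    bas = np.array([ba_from_dg(g, params) for g in dgs])
    slope, intercept = np.polyfit(dgs, bas, 1)
    fitted = slope * dgs + intercept
    resid = bas - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((bas - bas.mean()) ** 2))
    return QuasilinearityReport(
        max_abs_deviation=float(np.max(np.abs(resid))),
        r_squared=1.0 - ss_res / ss_tot,
        slope=float(slope),
        intercept=float(intercept),
        dg_range=(float(dg_lo), float(dg_hi)),
    )


@dataclass
class ActivityEnergyFit:
    slope: float
    intercept: float
    pearson_r: float
    n: int


def fit_activity_energy(
    activities: list[ActivityRecord],
    energies: list[EnergyRecord],
) -> ActivityEnergyFit:
    """OLS of basal activity on ddG_apo over designs present in both tables.

    Pearson r is reported with its sign; r is invariant to any positive
    rescaling of the energies.
    """
    e_by_id = {e.design_id: e for e in energies}
    pairs = [(a.basal_activity, e_by_id[a.design_id].ddG_apo)
             for a in activities if a.design_id in e_by_id]
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 paired records, got {len(pairs)}")
    ba = np.array([p[0] for p in pairs])
    dg = np.array([p[1] for p in pairs])
    if np.ptp(dg) == 0:
        raise ValueError("zero variance in ddG_apo: fit is degenerate")
    res = stats.linregress(dg, ba)
    return ActivityEnergyFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        n=len(pairs),
    )


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------


def load_activity_table(path) -> list[ActivityRecord]:
    """Activity TSV: ``design_id  basal_frac  induced_frac  sem``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ActivityRecord(
            design_id=str(r.design_id),
            basal_activity=float(r.basal_frac),
            ligand_induced=float(r.induced_frac) if "induced_frac" in df.columns else None,
            sem=float(r.sem) if "sem" in df.columns else None,
        )
        for r in df.itertuples(index=False)
    ]


def load_energy_table(path) -> list[EnergyRecord]:
    """Energy TSV: ``design_id  dG_inactive  dG_active  ddG_apo``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        EnergyRecord(
            design_id=str(r.design_id),
            dG_inactive=float(r.dG_inactive),
            dG_active=float(r.dG_active),
            ddG_apo=float(r.ddG_apo),
        )
        for r in df.itertuples(index=False)
    ]
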