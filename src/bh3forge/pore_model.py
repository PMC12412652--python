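"""Liposome dose-response analysis and the concentration-threshold mechanism.

Release percent normalizes fluorescence between a buffer-only control (Fmin,
0%) and a detergent control (Fmax, 100%). Dose-response curves are fitted
with the variable-slope four-parameter logistic (4PL).

The mechanism module is an equilibrium reading of the binder
activation/inhibition schematic for pore-forming effectors (BAK/BAX):

1. binder B engages target T in the BH3 groove with dissociation constant
   Kd_app = Kd_bind * (1 + K9), where K9 is the intramolecular
   groove-occupancy constant of the target's own C-terminal helix
   (0 for BAK and truncated BAX, large for full-length cytosolic BAX);
2. engagement activates the target (partial unfolding); because binding is
   transient, one binder molecule can activate several targets over the
   assay (hit-and-run turnover ``nu``), so the activated pool exceeds the
   instantaneous occupancy: A_tot = T*(1 - exp(-nu*theta)) with theta the
   binder occupancy; an external activator (e.g. cBID) activates the pool
   independently;
3. activated targets that are NOT currently binder-bound dimerize with
   association constant K_dim; the dye-release readout saturates in dimer
   concentration: release% = 100 * D / (D + K_release).

At low binder dose the activated-but-free pool grows (activation branch);
at saturating dose every target is binder-occupied, free activated monomer
vanishes and release returns to baseline (inhibition branch). For a tight
binder the descending IC50 tracks the total target concentration - the
stoichiometric inhibition threshold.
"""

from __future__ import annotations

import dataclasses

import lmfit
import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ReleaseMeasurement",
    "release_percent",
    "DoseResponseFit",
    "fit_4pl",
    "MechanismParams",
    "simulate_dose_response",
    "threshold_summary",
    "ThresholdSummary",
]


@dataclasses.dataclass
class ReleaseMeasurement:
    """Raw fluorescence plus normalized release percent (clamped + raw)."""

    fluorescence: float
    fmin: float
    fmax: float

    def __post_init__(self) -> None:
        if self.fmax <= self.fmin:
            raise ValueError("Fmax must exceed Fmin")

    @property
    def raw_percent(self) -> float:
        return 100.0 * (self.fluorescence - self.fmin) / (self.fmax - self.fmin)

    @property
    def percent(self) -> float:
        return float(np.clip(self.raw_percent, 0.0, 100.0))

    @property
    def out_of_range(self) -> bool:
        return not (0.0 <= self.raw_percent <= 100.0)


def release_percent(f: float, fmin: float, fmax: float) -> float:
    """Percent of maximal (detergent-control) release: 100*(F-Fmin)/(Fmax-Fmin)."""
    return ReleaseMeasurement(f, fmin, fmax).raw_percent


# -- 4PL dose-response -----------------------------------------------------


@dataclasses.dataclass
class DoseResponseFit:
    """Variable-slope four-parameter logistic fit."""

    bottom: float  # %
    top: float  # %
    ic50: float  # molar
    hill: float
    direction: str  # "inhibition" (response falls with dose) or "activation"
    ic50_stderr: float | None = None
    hill_stderr: float | None = None
    residual_norm: float = 0.0

    def predict(self, dose: np.ndarray) -> np.ndarray:
        return _four_pl(np.asarray(dose, float), self.bottom, self.top, self.ic50, self.hill)

    def summary(self) -> str:
        return "\n".join(
            [
                "4PL dose-response fit",
                f"  direction: {self.direction}",
                f"  bottom:    {self.bottom:.3g} %",
                f"  top:       {self.top:.3g} %",
                f"  IC50:      {self.ic50:.4g} M ({self.ic50 * 1e9:.3g} nM)"
                + (f" +/- {self.ic50_stderr * 1e9:.2g} nM" if self.ic50_stderr else ""),
                f"  hill:      {self.hill:.3g}",
                f"  residual:  {self.residual_norm:.3g}",
            ]
        )


def _four_pl(x: np.ndarray, bottom: float, top: float, ic50: float, hill: float) -> np.ndarray:
    # signed hill encodes orientation; y(ic50) = (top+bottom)/2 by construction
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, ic50 / x, np.inf)
    return bottom + (top - bottom) / (1.0 + ratio**hill)


def fit_4pl(dose: np.ndarray, response: np.ndarray) -> DoseResponseFit:
    """Fit y = bottom + (top-bottom)/(1+(ic50/x)^hill); orientation auto-detected.

    A negative fitted hill corresponds to response decreasing with dose
    (inhibition); the reported fit normalizes so top >= bottom with the
    direction flag carrying the orientation.
    """
    dose = np.asarray(dose, float)
    response = np.asarray(response, float)
    if dose.shape != response.shape or dose.size < 4:
        raise ValueError("need matching dose/response arrays with >= 4 points")
    if np.any(dose <= 0):
        raise ValueError("doses must be positive")
    if np.allclose(response, response[0]):
        raise ValueError("flat response: nothing to fit")

    order = np.argsort(dose)
    falling = response[order][-1] < response[order][0]

    params = lmfit.Parameters()
    lo, hi = float(response.min()), float(response.max())
    span = hi - lo
    params.add("bottom", value=lo, min=lo - 2 * span, max=hi + 2 * span)
    params.add("top", value=hi, min=lo - 2 * span, max=hi + 2 * span)
    mid = (lo + hi) / 2.0
    # dose nearest the half-response as the IC50 seed
    seed = float(dose[np.argmin(np.abs(response - mid))])
    params.add("log_ic50", value=np.log10(seed), min=np.log10(dose.min()) - 4, max=np.log10(dose.max()) + 4)
    params.add("hill", value=-1.0 if falling else 1.0, min=-8.0, max=8.0)

    def residuals(p: lmfit.Parameters) -> np.ndarray:
        return _four_pl(dose, p["bottom"].value, p["top"].value, 10.0 ** p["log_ic50"].value, p["hill"].value) - response

    out = lmfit.minimize(residuals, params, method="leastsq")
    if not out.success:
        raise RuntimeError(f"4PL fit did not converge: residual {np.sqrt(out.chisqr):.3g}")
    bottom = out.params["bottom"].value
    top = out.params["top"].value
    ic50 = 10.0 ** out.params["log_ic50"].value
    hill = out.params["hill"].value
    direction = "inhibition" if (hill < 0) == (top >= bottom) else "activation"
    if top < bottom:  # normalize orientation: top >= bottom, sign moves to hill
        bottom, top, hill = top, bottom, -hill
    ic50_err = None
    if out.params["log_ic50"].stderr is not None:
        ic50_err = float(ic50 * np.log(10.0) * out.params["log_ic50"].stderr)
    hill_err = out.params["hill"].stderr
    return DoseResponseFit(
        bottom=float(bottom), top=float(top), ic50=float(ic50), hill=float(hill),
        direction=direction, ic50_stderr=ic50_err,
        hill_stderr=float(hill_err) if hill_err is not None else None,
        residual_norm=float(np.sqrt(out.chisqr)),
    )


# -- threshold mechanism ---------------------------------------------------


@dataclasses.dataclass
class MechanismParams:
    """Species and constants of the equilibrium threshold mechanism."""

    t_total: float = 38e-9  # molar target (e.g. 38 nM BAK in the liposome assay)
    kd_bind: float = 0.4e-9  # binder-target dissociation constant (M)
    k9: float = 0.0  # intramolecular C-terminal-helix groove occupancy (unitless)
    activation: bool = True  # binder engagement activates the target
    turnover: float = 10.0  # hit-and-run engagements per occupancy unit (nu)
    k_dim: float = 1e8  # dimerization association constant of free activated monomers (M^-1)
    k_release: float = 0.1e-9  # dimer concentration at half-maximal dye release (M)
    activator: float = 0.0  # external activator (cBID) concentration (M); 0 = none
    activator_k: float = 5e-9  # activator engagement constant (M)
    baseline: float = 0.0  # percent release with nothing activated

    def __post_init__(self) -> None:
        if min(self.t_total, self.kd_bind, self.k_dim, self.k_release) <= 0:
            raise ValueError("t_total, kd_bind, k_dim, k_release must be positive")
        if self.k9 < 0 or self.turnover < 0 or self.activator < 0:
            raise ValueError("k9, turnover, activator must be nonnegative")

    @property
    def kd_app(self) -> float:
        """Apparent binder affinity after intramolecular competition: Kd*(1+K9)."""
        return self.kd_bind * (1.0 + self.k9)


def _occupancy(b_total: float, t_total: float, kd: float, tol: float = 1e-10) -> float:
    """Bound complex TB from total binder/target by bisection on free binder.

    Conservation: B_total = B_free + T_total*B_free/(B_free+Kd); monotone in
    B_free, solved to relative tolerance ``tol``.
    """
    if b_total <= 0:
        return 0.0

    def g(b_free: float) -> float:
        return b_free + t_total * b_free / (b_free + kd) - b_total

    hi = b_total
    lo = 0.0
    b_free = brentq(g, lo, hi, rtol=tol, xtol=1e-300)
    return t_total * b_free / (b_free + kd)


def _dimer(pool: float, k_dim: float) -> float:
    """Dimer concentration from the activated free pool: P = M + 2D, D = K*M^2."""
    if pool <= 0:
        return 0.0
    # 2K*M^2 + M - P = 0
    m = (-1.0 + np.sqrt(1.0 + 8.0 * k_dim * pool)) / (4.0 * k_dim)
    return k_dim * m * m


def simulate_dose_response(p: MechanismParams, doses: np.ndarray) -> np.ndarray:
    """Equilibrium release percent at each binder dose.

    Solves, per dose: binder occupancy (bisection to 1e-10 relative), the
    activated pool (engagement-counts semantics with turnover ``nu`` plus
    any external activator), monomer-dimer partition of the activated free
    pool, and the saturating release readout. With activation on and no
    activator the curve is biphasic (activation at substoichiometric doses,
    inhibition at saturating doses).
    """
    doses = np.asarray(doses, float)
    out = np.empty_like(doses)
    act_frac_ext = p.activator / (p.activator + p.activator_k) if p.activator > 0 else 0.0
    for i, b in enumerate(doses):
        tb = _occupancy(float(b), p.t_total, p.kd_app)
        theta = tb / p.t_total
        if p.activation:
            engaged = 1.0 - np.exp(-p.turnover * theta)
        else:
            engaged = 0.0
        act_frac = 1.0 - (1.0 - engaged) * (1.0 - act_frac_ext)
        a_tot = p.t_total * act_frac
        # activated targets currently binder-bound cannot dimerize
        free_pool = max(a_tot - tb, 0.0)
        d = _dimer(free_pool, p.k_dim)
        rel = 100.0 * d / (d + p.k_release)
        out[i] = p.baseline + (100.0 - p.baseline) * rel / 100.0
    return out


@dataclasses.dataclass
class ThresholdSummary:
    """Activation peak, inhibition IC50 and stoichiometric fold excess."""

    peak_dose: float | None  # molar; None if the curve has no interior maximum
    peak_release: float | None
    inhibition_ic50: float  # molar (4PL on the descending branch)
    fold_excess: float  # ic50 / t_total

    def summary(self) -> str:
        lines = ["concentration-threshold summary"]
        if self.peak_dose is not None:
            lines.append(f"  activation peak: {self.peak_dose * 1e9:.3g} nM ({self.peak_release:.1f} % release)")
        else:
            lines.append("  activation peak: absent (monotone curve)")
        lines.append(f"  inhibition IC50: {self.inhibition_ic50 * 1e9:.4g} nM")
        lines.append(f"  fold excess over target: {self.fold_excess:.3g}x")
        return "\n".join(lines)


def threshold_summary(
    p: MechanismParams,
    dose_min: float = 1e-11,
    dose_max: float = 1e-4,
    n_doses: int = 60,
) -> ThresholdSummary:
    """Locate the activation peak and fit the descending-branch 4PL IC50.

    Doses are log-spaced. The activation peak is the interior maximum of the
    simulated curve (reported absent for monotone curves); the inhibition
    IC50 comes from a 4PL fit to the doses at and beyond the peak; fold
    excess is IC50 / T_total.
    """
    doses = np.geomspace(dose_min, dose_max, n_doses)
    release = simulate_dose_response(p, doses)
    imax = int(np.argmax(release))
    interior = 0 < imax < len(doses) - 1 and release[imax] > release[0] + 1e-6 and release[imax] > release[-1] + 1e-6
    peak_dose = float(doses[imax]) if interior else None
    peak_release = float(release[imax]) if interior else None
    start = imax if interior else int(np.argmax(release))
    branch_d = doses[start:]
    branch_r = release[start:]
    if branch_d.size < 5 or branch_r[0] - branch_r[-1] < 1.0:
        raise ValueError("no resolvable descending branch on the dose grid")
    fit = fit_4pl(branch_d, branch_r)
    return ThresholdSummary(peak_dose, peak_release, fit.ic50, fit.ic50 / p.t_total)
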