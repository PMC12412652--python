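"""1:1 biosensor (BLI) binding kinetics: simulation and global fitting.

The observable follows the standard Langmuir 1:1 model. During association
at analyte concentration C::

    R(t) = Req * (1 - exp(-(kon*C + koff) * t)),   Req = Rmax * C / (C + Kd)

and during dissociation (t past the association end t1)::

    R(t) = R(t1) * exp(-koff * (t - t1))

Fitting is global: kon, koff and Rmax are shared across all traces of a
titration (plus one free baseline offset per trace), parameters live in
log10 space for positivity, and a small multistart guards against local
minima. Kd = koff/kon holds exactly in every emitted fit.
"""

from __future__ import annotations

import dataclasses

import lmfit
import numpy as np
import pandas as pd

__all__ = ["BLITrace", "KineticFit", "simulate_1to1", "fit_1to1", "rate_plane"]


@dataclasses.dataclass
class BLITrace:
    """One sensor trace: time, signal, phase boundaries, analyte concentration."""

    time: np.ndarray  # seconds, monotone
    signal: np.ndarray  # response units
    t_assoc: float  # association start (s)
    t_dissoc: float  # dissociation start (s)
    concentration: float  # molar

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.signal = np.asarray(self.signal, float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal shapes differ")
        if np.any(np.diff(self.time) < 0):
            raise ValueError("time must be monotone")
        if not (self.t_assoc < self.t_dissoc <= self.time[-1] + 1e-9):
            raise ValueError("phase boundaries must satisfy assoc < dissoc <= end")
        if self.concentration <= 0:
            raise ValueError("analyte concentration must be positive")


def _model_1to1(
    t: np.ndarray, t_assoc: float, t_dissoc: float, conc: float,
    kon: float, koff: float, rmax: float, baseline: float = 0.0,
) -> np.ndarray:
    kd = koff / kon
    req = rmax * conc / (conc + kd)
    kobs = kon * conc + koff
    ta = np.clip(t - t_assoc, 0.0, None)
    r_assoc = req * (1.0 - np.exp(-kobs * ta))
    r_at_t1 = req * (1.0 - np.exp(-kobs * max(t_dissoc - t_assoc, 0.0)))
    td = np.clip(t - t_dissoc, 0.0, None)
    out = np.where(t < t_dissoc, r_assoc, r_at_t1 * np.exp(-koff * td))
    return out + baseline


def simulate_1to1(
    kon: float,
    koff: float,
    rmax: float,
    concentrations: list[float],
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    t_dissoc: float | None = None,
) -> list[BLITrace]:
    """Simulate a multi-concentration titration under the 1:1 model.

    ``times`` spans both phases; association starts at t=0 and dissociation
    at ``t_dissoc`` (default: 60% of the time span). Gaussian noise of SD
    ``noise_sd`` response units is added per point.
    """
    if min(kon, koff, rmax) <= 0:
        raise ValueError("kon, koff, Rmax must be positive")
    times = np.asarray(times, float)
    if t_dissoc is None:
        t_dissoc = 0.6 * times[-1]
    rng = np.random.default_rng(seed)
    traces = []
    for conc in concentrations:
        sig = _model_1to1(times, 0.0, t_dissoc, conc, kon, koff, rmax)
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd, size=times.shape)
        traces.append(BLITrace(times.copy(), sig, 0.0, t_dissoc, conc))
    return traces


@dataclasses.dataclass
class KineticFit:
    """Result of a global 1:1 fit: rate constants, Kd, uncertainties."""

    kon: float  # M^-1 s^-1
    koff: float  # s^-1
    rmax: float  # response units
    kon_stderr: float | None
    koff_stderr: float | None
    residual_norm: float
    n_traces: int
    low_confidence: bool = False

    @property
    def kd(self) -> float:
        return self.koff / self.kon

    def summary(self) -> str:
        kd = self.kd
        lines = [
            "1:1 binding kinetics (global fit)",
            f"  traces:   {self.n_traces}" + ("  [single-trace: low confidence]" if self.low_confidence else ""),
            f"  kon:      {self.kon:.4g} M^-1 s^-1" + (f" +/- {self.kon_stderr:.2g}" if self.kon_stderr else ""),
            f"  koff:     {self.koff:.4g} s^-1" + (f" +/- {self.koff_stderr:.2g}" if self.koff_stderr else ""),
            f"  Rmax:     {self.rmax:.4g} RU",
            f"  Kd:       {kd:.4g} M ({kd * 1e9:.3g} nM)",
            f"  residual: {self.residual_norm:.4g}",
        ]
        return "\n".join(lines)


def fit_1to1(traces: list[BLITrace], n_starts: int = 5, seed: int = 0) -> KineticFit:
    """Global nonlinear least-squares fit of the 1:1 model to a titration.

    kon, koff, Rmax are shared across traces; each trace gets a free
    baseline offset. Invariant to a common time-origin shift. Single-trace
    fits are flagged low-confidence.
    """
    if not traces:
        raise ValueError("no traces")
    n_conc = len({t.concentration for t in traces})

    def residuals(params: lmfit.Parameters) -> np.ndarray:
        kon = 10.0 ** params["log_kon"].value
        koff = 10.0 ** params["log_koff"].value
        rmax = 10.0 ** params["log_rmax"].value
        res = []
        for i, tr in enumerate(traces):
            model = _model_1to1(
                tr.time, tr.t_assoc, tr.t_dissoc, tr.concentration,
                kon, koff, rmax, params[f"base_{i}"].value,
            )
            res.append(model - tr.signal)
        return np.concatenate(res)

    sig_max = max(float(np.nanmax(np.abs(t.signal))) for t in traces) or 1.0
    conc_mid = float(np.median([t.concentration for t in traces]))
    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        params = lmfit.Parameters()
        jitter = rng.uniform(-1.0, 1.0, size=3) if start else np.zeros(3)
        params.add("log_kon", value=5.0 + jitter[0], min=0.0, max=12.0)
        params.add("log_koff", value=-3.0 + jitter[1], min=-8.0, max=2.0)
        params.add("log_rmax", value=float(np.log10(sig_max)) + 0.2 * jitter[2], min=-3.0, max=6.0)
        for i in range(len(traces)):
            params.add(f"base_{i}", value=0.0)
        try:
            out = lmfit.minimize(residuals, params, method="leastsq")
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        raise RuntimeError("1:1 kinetic fit failed to converge from all starts")

    kon = 10.0 ** best.params["log_kon"].value
    koff = 10.0 ** best.params["log_koff"].value
    rmax = 10.0 ** best.params["log_rmax"].value

    def stderr_of(name: str, value: float) -> float | None:
        p = best.params[name]
        if p.stderr is None:
            return None
        return float(value * np.log(10.0) * p.stderr)  # delta method from log10 space

    return KineticFit(
        kon=kon,
        koff=koff,
        rmax=rmax,
        kon_stderr=stderr_of("log_kon", kon),
        koff_stderr=stderr_of("log_koff", koff),
        residual_norm=float(np.sqrt(best.chisqr)),
        n_traces=len(traces),
        low_confidence=n_conc < 2,
    )


def rate_plane(fits: list[KineticFit]) -> pd.DataFrame:
    """Plot-ready on-rate/off-rate table with iso-Kd diagonal labels.

    On log axes, constant-Kd lines are diagonals: log10 kon = log10 koff -
    log10 Kd. The returned frame carries log10 kon, log10 koff, Kd and the
    nearest decade iso-Kd label for each fit.
    """
    rows = []
    for f in fits:
        kd = f.kd
        rows.append(
            {
                "log10_kon": np.log10(f.kon),
                "log10_koff": np.log10(f.koff),
                "Kd_M": kd,
                "iso_Kd_label": f"1e{int(round(np.log10(kd)))} M",
            }
        )
    return pd.DataFrame(rows)
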