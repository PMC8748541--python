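"""Hill-equation enzyme kinetics and active-site titration.

Initial velocities over a substrate titration are fitted to the Hill
equation ``v = Vmax * S^n / (K^n + S^n)`` by multi-start nonlinear least
squares; with ``n = 1`` this reduces to Michaelis-Menten. Active enzyme
concentration is determined by titration with an irreversible inhibitor
(the x-intercept of residual activity vs inhibitor concentration), from
which ``kcat = Vmax / [E]`` and the catalytic efficiency ``kcat / K``
follow. Velocity units are left abstract (fluorescence/min is fine);
deriving kcat in s^-1 requires calibrated velocity units, which are the
caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class KineticDataset:
    """A substrate titration: concentrations (uM) and initial velocities."""

    substrate_conc: np.ndarray
    initial_velocity: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate_conc, dtype=float)
        v = np.asarray(self.initial_velocity, dtype=float)
        object.__setattr__(self, "substrate_conc", s)
        object.__setattr__(self, "initial_velocity", v)
        if len(s) != len(v):
            raise ValueError("substrate and velocity arrays differ in length")
        if (s < 0).any():
            raise ValueError("substrate concentrations must be >= 0")
        if len(np.unique(s)) < 5:
            raise ValueError("need >= 5 distinct substrate concentrations")

    @classmethod
    def from_tsv(cls, path) -> "KineticDataset":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


@dataclass(frozen=True)
class HillFitResults:
    """Fitted Hill parameters with optional derived catalytic constants."""

    vmax: float
    k_half: float
    hill_n: float
    residual_norm: float
    converged: bool
    enzyme_conc: float | None = None
    kcat: float | None = None
    kcat_over_k: float | None = None

    def predict(self, substrate: np.ndarray) -> np.ndarray:
        return hill_velocity(np.asarray(substrate, float),
                             self.vmax, self.k_half, self.hill_n)

    def summary(self) -> str:
        lines = [
            "Hill Equation Fit",
            "=" * 40,
            f"Vmax         {self.vmax:.6g}",
            f"K (uM)       {self.k_half:.6g}",
            f"Hill n       {self.hill_n:.6g}",
            f"residual     {self.residual_norm:.3g}",
            f"converged    {self.converged}",
        ]
        if self.enzyme_conc is not None:
            lines += [f"[E] (uM)     {self.enzyme_conc:.6g}"]
        if self.kcat is not None:
            lines += [f"kcat         {self.kcat:.6g}",
                      f"kcat/K       {self.kcat_over_k:.6g}"]
        return "\n".join(lines)


def hill_velocity(s: np.ndarray, vmax: float, k: float, n: float) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = vmax * s**n / (k**n + s**n)
    return np.where(s == 0, 0.0, out)


class HillModel:
    """Nonlinear least-squares Hill fit with multi-start initialization.

    Hill fits can be multimodal when ``n`` is weakly identified, so the fit
    starts from several K values at the data's concentration quantiles and
    keeps the best optimum.
    """

    def __init__(self, data: KineticDataset, fix_n: float | None = None):
        if np.allclose(data.initial_velocity, 0.0):
            raise ValueError("all velocities are zero; nothing to fit")
        self.data = data
        self.fix_n = fix_n

    def fit(self, n_starts: int = 5, seed: int = 0) -> HillFitResults:
        s = self.data.substrate_conc
        v = self.data.initial_velocity
        vmax0 = float(v.max())
        pos = s[s > 0]
        k_starts = np.quantile(pos, np.linspace(0.15, 0.85, max(n_starts, 2)))
        best = None
        for k0 in k_starts:
            for n0 in ([1.0, 2.0] if self.fix_n is None else [self.fix_n]):
                try:
                    if self.fix_n is None:
                        popt, _ = curve_fit(
                            hill_velocity, s, v, p0=[vmax0, k0, n0],
                            bounds=([1e-12, 1e-12, 0.05], [np.inf, np.inf, 20.0]),
                            maxfev=20000,
                        )
                        vm, kk, nn = popt
                    else:
                        nn = float(self.fix_n)
                        popt, _ = curve_fit(
                            lambda ss, vm_, kk_: hill_velocity(ss, vm_, kk_, nn),
                            s, v, p0=[vmax0, k0],
                            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                            maxfev=20000,
                        )
                        vm, kk = popt
                except RuntimeError:
                    continue
                resid = float(np.linalg.norm(v - hill_velocity(s, vm, kk, nn)))
                if best is None or resid < best[0]:
                    best = (resid, vm, kk, nn)
        if best is None:
            return HillFitResults(np.nan, np.nan, np.nan, np.inf, converged=False)
        resid, vm, kk, nn = best
        return HillFitResults(float(vm), float(kk), float(nn), resid, converged=True)


def fit_hill(data: KineticDataset, fix_n: float | None = None,
             n_starts: int = 5, seed: int = 0) -> HillFitResults:
    return HillModel(data, fix_n=fix_n).fit(n_starts=n_starts, seed=seed)


def active_site_titration(
    inhibitor_conc: np.ndarray,
    residual_activity: np.ndarray,
    monotone_tol: float = 0.05,
) -> float:
    """Active enzyme concentration from irreversible-inhibitor titration.

    Fits a line to residual activity vs inhibitor concentration over the
    declining regime (points before activity bottoms out) and returns its
    x-intercept — the inhibitor concentration that stoichiometrically
    titrates the active sites. Activities must be non-increasing up to a
    relative tolerance of the dynamic range.
    """
    c = np.asarray(inhibitor_conc, dtype=float)
    a = np.asarray(residual_activity, dtype=float)
    order = np.argsort(c)
    c, a = c[order], a[order]
    if len(c) < 3:
        raise ValueError("need >= 3 titration points")
    span = a.max() - a.min()
    if span <= 0:
        raise ValueError("activity does not decline over the titration")
    rises = np.diff(a) > monotone_tol * span
    if rises.any():
        raise ValueError("residual activity is not monotonically non-increasing")
    floor = a.min() + 0.02 * span
    declining = a > floor
    declining[np.argmax(~declining)] = True  # include first floor point as anchor
    cs, As = c[declining], a[declining]
    if len(cs) < 2:
        cs, As = c[:3], a[:3]
    slope, intercept = np.polyfit(cs, As, 1)
    if slope >= 0:
        raise ValueError("titration slope is non-negative; cannot find intercept")
    return float(-intercept / slope)


def derive_catalytic_constants(fit: HillFitResults, enzyme_conc: float) -> HillFitResults:
    """Attach ``kcat = Vmax/[E]`` and ``kcat/K`` to a Hill fit.

    ``Vmax`` must already be in concentration/time units for kcat to be a
    true turnover number.
    """
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be > 0")
    kcat = fit.vmax / enzyme_conc
    return _dc_replace(fit, enzyme_conc=float(enzyme_conc), kcat=float(kcat),
                       kcat_over_k=float(kcat / fit.k_half))
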