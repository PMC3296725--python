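"""Two-state equilibrium denaturation fits (Santoro-Bolen model).

The observed optical signal of a reversibly, two-state unfolding protein
at denaturant concentration C is

    S(C) = [S_n(C) + S_u(C) * exp(-(dG_U - m C)/RT)]
           / [1 + exp(-(dG_U - m C)/RT)]

with dG_U the unfolding free energy in water, m the denaturant dependence
and S_n, S_u pre-/post-transition baselines. Baselines may be linear
(Y + slope*C), exponential (I_c + I_0 exp(-C/s), the form that captures a
signal settling to a constant before the transition) or quadratic
polynomials. The midpoint is C_m = dG_U / m. A fit with a non-linear
baseline is conventionally reported as dG_U*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import R_KCAL


class MeltingError(ValueError):
    """Raised for unusable melting-curve input or failed fits."""


BASELINE_KINDS = ("linear", "exponential", "polynomial")


@dataclass
class BaselineModel:
    """One pre- or post-transition baseline.

    Parameters by kind: linear -> (intercept, slope); exponential ->
    (asymptote I_c, amplitude I_0, decay scale s > 0, molar); polynomial
    -> quadratic coefficients (c0, c1, c2).
    """

    kind: str
    params: tuple[float, ...]

    def __call__(self, C):
        C = np.asarray(C, float)
        p = self.params
        if self.kind == "linear":
            return p[0] + p[1] * C
        if self.kind == "exponential":
            return p[0] + p[1] * np.exp(-C / p[2])
        if self.kind == "polynomial":
            return p[0] + p[1] * C + p[2] * C * C
        raise MeltingError(f"unknown baseline kind {self.kind!r}")


_N_PARAMS = {"linear": 2, "exponential": 3, "polynomial": 3}
_PARAM_NAMES = {
    "linear": ("Y", "m_slope"),
    "exponential": ("I_c", "I_0", "s"),
    "polynomial": ("c0", "c1", "c2"),
}


@dataclass
class MeltingCurve:
    """Denaturation data: (C molar, signal in arbitrary units) pairs."""

    concentrations: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, float)
        self.signals = np.asarray(self.signals, float)
        if self.concentrations.shape != self.signals.shape:
            raise MeltingError("concentration and signal arrays differ in length")
        if np.any(self.concentrations < 0):
            raise MeltingError("denaturant concentrations must be >= 0")
        order = np.argsort(self.concentrations, kind="stable")
        self.concentrations = self.concentrations[order]
        self.signals = self.signals[order]
        if len(self.concentrations) < 8:
            warnings.warn("melting curve must be adequately defined with "
                          "sufficient data points (fewer than 8 given)")

    def __len__(self) -> int:
        return len(self.concentrations)


def two_state_signal(C, dg_u: float, m: float, pre: BaselineModel,
                     post: BaselineModel, T: float):
    """Evaluate the two-state model signal at concentration(s) C."""
    C = np.asarray(C, float)
    # exp(-(dG - mC)/RT) == K_unf(C); guard the exponent for far baselines
    expo = np.clip(-(dg_u - m * C) / (R_KCAL * T), -500.0, 500.0)
    k = np.exp(expo)
    return (pre(C) + post(C) * k) / (1.0 + k)


@dataclass
class ModelEquation:
    """Structured description of one composite fitting equation."""

    pre_kind: str
    post_kind: str
    parameter_names: tuple[str, ...]
    n_parameters: int
    lower_bounds: tuple[float, ...]
    upper_bounds: tuple[float, ...]


def build_model_equation(pre_kind: str, post_kind: str) -> ModelEquation:
    """Describe the composite equation for a choice of baseline kinds.

    Thermodynamic parameters (dG_U, m) always come last. s-parameters of
    exponential baselines and m are bounded positive.
    """
    for kind in (pre_kind, post_kind):
        if kind not in BASELINE_KINDS:
            raise MeltingError(f"unknown baseline kind {kind!r}; choose from "
                               f"{BASELINE_KINDS}")
    names: list[str] = []
    lo: list[float] = []
    hi: list[float] = []
    for side, kind in (("n", pre_kind), ("u", post_kind)):
        for pname in _PARAM_NAMES[kind]:
            names.append(f"{pname}_{side}")
            if pname == "s":
                lo.append(1e-3)
                hi.append(np.inf)
            else:
                lo.append(-np.inf)
                hi.append(np.inf)
    names += ["dG_U", "m"]
    lo += [-np.inf, 1e-6]
    hi += [np.inf, np.inf]
    return ModelEquation(pre_kind, post_kind, tuple(names), len(names),
                         tuple(lo), tuple(hi))


@dataclass
class TwoStateFit:
    """Result of a Santoro-Bolen fit."""

    dg_u: float                 # kcal/mol (dG_U* when a baseline is non-linear)
    m: float                    # kcal/mol/M
    pre: BaselineModel
    post: BaselineModel
    rss: float
    converged: bool
    temperature: float
    model: ModelEquation
    n_points: int
    aic: float = field(init=False)

    def __post_init__(self) -> None:
        k = self.model.n_parameters
        n = self.n_points
        self.aic = n * np.log(max(self.rss, 1e-300) / n) + 2 * k

    @property
    def cm(self) -> float:
        """Transition midpoint C_m = dG_U / m, molar."""
        return self.dg_u / self.m

    @property
    def is_starred(self) -> bool:
        """True when a non-linear baseline was used (report dG_U as dG_U*)."""
        return "linear" != self.pre.kind or "linear" != self.post.kind

    def report(self) -> str:
        label = "dG_U*" if self.is_starred else "dG_U"
        lines = [
            f"two-state fit ({self.pre.kind} pre / {self.post.kind} post "
            f"baselines, T = {self.temperature:g} K)",
            f"  {label:6s} = {self.dg_u:8.3f} kcal/mol",
            f"  m      = {self.m:8.3f} kcal/mol/M",
            f"  C_m    = {self.cm:8.3f} M",
            f"  RSS    = {self.rss:.3e} over {self.n_points} points "
            f"({self.model.n_parameters} parameters, AIC {self.aic:.1f})",
        ]
        return "\n".join(lines)


def _split_params(theta: np.ndarray, model: ModelEquation
                  ) -> tuple[float, float, BaselineModel, BaselineModel]:
    n_pre = _N_PARAMS[model.pre_kind]
    n_post = _N_PARAMS[model.post_kind]
    pre = BaselineModel(model.pre_kind, tuple(theta[:n_pre]))
    post = BaselineModel(model.post_kind, tuple(theta[n_pre:n_pre + n_post]))
    dg_u, m = theta[n_pre + n_post], theta[n_pre + n_post + 1]
    return dg_u, m, pre, post


def _baseline_seed(kind: str, C: np.ndarray, S: np.ndarray, cm_guess: float,
                   pre_side: bool) -> list[float]:
    n = max(3, len(C) // 4)
    seg = slice(0, n) if pre_side else slice(len(C) - n, len(C))
    c_seg, s_seg = C[seg], S[seg]
    slope, intercept = np.polyfit(c_seg, s_seg, 1)
    if kind == "linear":
        return [intercept, slope]
    if kind == "exponential":
        i_c = float(s_seg[-1] if pre_side else s_seg[0])
        i_0 = float(s_seg[0] - i_c if pre_side else s_seg[-1] - i_c)
        if i_0 == 0.0:
            i_0 = 0.1 * (np.ptp(S) or 1.0)
        return [i_c, i_0, max(0.3 * cm_guess, 0.1)]
    return [intercept, slope, 0.0]


def fit_melting(curve: MeltingCurve, pre_kind: str = "linear",
                post_kind: str = "linear", T: float = 298.0,
                n_starts: int = 20) -> TwoStateFit:
    """Nonlinear least-squares fit of all baseline + thermodynamic parameters.

    Multi-start initialization: C_m guesses on a fixed grid across the
    observed concentration range crossed with a fixed ladder of m guesses;
    the best residual wins (deterministic ordering). Raises on degenerate
    curves (no resolvable transition inside the data range) and when no
    start converges.
    """
    model = build_model_equation(pre_kind, post_kind)
    C, S = curve.concentrations, curve.signals
    span = float(np.ptp(S))
    if span == 0.0:
        raise MeltingError("degenerate curve: signal is constant (no transition)")
    c_lo, c_hi = float(C.min()), float(C.max())
    if c_hi <= c_lo:
        raise MeltingError("degenerate curve: single denaturant concentration")

    # Fixed grid of starts: 5 midpoints x 4 m values = 20 (default).
    n_cm = max(1, n_starts // 4)
    cm_grid = np.linspace(c_lo + 0.15 * (c_hi - c_lo),
                          c_hi - 0.15 * (c_hi - c_lo), n_cm)
    m_grid = np.array([1.0, 2.0, 4.0, 8.0])

    def residuals(theta: np.ndarray) -> np.ndarray:
        d, m_val, pre, post = _split_params(theta, model)
        return two_state_signal(C, d, m_val, pre, post, T) - S

    best = None
    for cm0 in cm_grid:
        for m0 in m_grid:
            theta0 = (_baseline_seed(pre_kind, C, S, cm0, True)
                      + _baseline_seed(post_kind, C, S, cm0, False)
                      + [m0 * cm0, m0])
            try:
                res = least_squares(
                    residuals, theta0,
                    bounds=(model.lower_bounds, model.upper_bounds),
                    method="trf", max_nfev=5000)
            except Exception:
                continue
            rss = float(2.0 * res.cost)
            if best is None or rss < best[0] - 1e-15:
                best = (rss, res)
    if best is None:
        raise MeltingError("fit failed to converge from every start; check "
                           "that the curve shows a transition")
    rss, res = best
    dg_u, m, pre, post = _split_params(res.x, model)
    fit = TwoStateFit(float(dg_u), float(m), pre, post, rss,
                      bool(res.success), T, model, len(curve))
    if not (c_lo - 0.5 <= fit.cm <= c_hi + 0.5):
        raise MeltingError(
            f"degenerate curve: fitted midpoint {fit.cm:.2f} M lies outside "
            "the observed concentration range (no transition resolved)")
    # A real transition separates the baselines by much more than the
    # residual scatter at the midpoint.
    amplitude = abs(float(post(fit.cm) - pre(fit.cm)))
    noise = np.sqrt(rss / len(curve))
    if amplitude < 5.0 * noise or amplitude < 0.1 * span:
        raise MeltingError(
            "degenerate curve: transition amplitude indistinguishable from "
            "baseline scatter (no transition resolved)")
    return fit
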