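"""Candidate dose-response curve families, fitting, and lack-of-fit testing.

Four families map dose x (Gy) to the expected number of rosette-shaped
apoptotic clusters per optic tectum:

* ``linear``            y = c x                    (c >= 0)
* ``linear_quadratic``  y = alpha x + beta x^2     (alpha, beta >= 0)
* ``quadratic``         y = beta x^2               (beta >= 0)
* ``shifted_power``     y = (x + a)^p + b          (p an odd integer)

The shifted-power family is the one that describes the steep iron-ion
response; with the through-origin constraint b = -a^p the curve passes
exactly through (0, 0).  Because p is odd, (x + a)^p is monotone increasing
for every real a, so each member is non-decreasing on [0, inf).

Whether a family "can be fitted" is decided by the classical pure-error
lack-of-fit F test on the replicated design: the model's residual mean
square at the dose means is compared against the pooled within-group
variance.  A family is rejected when that test is significant at the
configured level (default 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .data import DoseResponseDataset
from .exceptions import (
    DataValidationError,
    DegenerateDataError,
    DegenerateVarianceError,
    UnderdeterminedFitError,
)

__all__ = [
    "FAMILIES",
    "DoseResponseModel",
    "FitResult",
    "LackOfFit",
    "evaluate",
    "odd_root",
    "lack_of_fit",
    "fit_model",
    "select_model",
]

FAMILIES = ("linear", "linear_quadratic", "quadratic", "shifted_power")

ALLOWED_EXPONENTS = (3, 5, 7, 9)

#: Continuous parameters per family (the discrete exponent search for
#: shifted_power counts as one fitted quantity).
N_PARAMS = {
    "linear": 1,
    "quadratic": 1,
    "linear_quadratic": 2,
    "shifted_power": 2,  # (a, p); +1 when the offset b is free
}


@dataclass(frozen=True)
class DoseResponseModel:
    """A parameterised dose-response curve.

    ``params`` is family-specific:

    * linear: ``{"c": slope}``;
    * linear_quadratic: ``{"alpha": ..., "beta": ...}``;
    * quadratic: ``{"beta": ...}``;
    * shifted_power: ``{"a": shift (Gy), "p": odd exponent, "b": offset}``.
    """

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise DataValidationError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        p = dict(self.params)
        if self.family == "shifted_power":
            missing = {"a", "p", "b"} - p.keys()
            if missing:
                raise DataValidationError(f"shifted_power needs params a, p, b; missing {missing}")
            exponent = p["p"]
            if exponent != int(exponent) or int(exponent) not in ALLOWED_EXPONENTS:
                raise DataValidationError(
                    f"shifted_power exponent must be one of {ALLOWED_EXPONENTS}, got {exponent}"
                )
            p["p"] = int(exponent)
        else:
            required = {"linear": {"c"}, "quadratic": {"beta"}, "linear_quadratic": {"alpha", "beta"}}[
                self.family
            ]
            missing = required - p.keys()
            if missing:
                raise DataValidationError(f"{self.family} needs params {required}; missing {missing}")
            if any(p[k] < 0 for k in required):
                raise DataValidationError(
                    f"{self.family} coefficients must be non-negative (effect cannot "
                    f"decrease with dose), got {p}"
                )
        object.__setattr__(self, "params", p)

    @property
    def through_origin(self) -> bool:
        """True when the curve passes exactly through (0, 0)."""
        if self.family == "shifted_power":
            a, p, b = self.params["a"], self.params["p"], self.params["b"]
            return b == -(a**p)
        return True

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "DoseResponseModel":
        return cls(family=d["family"], params=dict(d["params"]))


def evaluate(model: DoseResponseModel, dose) -> np.ndarray | float:
    """Expected clusters/OT at ``dose`` (scalar or array, Gy, >= 0).

    For the shifted-power family the ordinary real power is used; negative
    bases are fine because the exponent is odd.
    """
    x = np.asarray(dose, dtype=float)
    if np.any(x < 0):
        raise DataValidationError("dose must be >= 0 Gy")
    pars = model.params
    if model.family == "linear":
        y = pars["c"] * x
    elif model.family == "quadratic":
        y = pars["beta"] * x**2
    elif model.family == "linear_quadratic":
        y = pars["alpha"] * x + pars["beta"] * x**2
    else:  # shifted_power; p odd so the sign survives the power
        base = x + pars["a"]
        y = np.sign(base) * np.abs(base) ** pars["p"] + pars["b"]
    return y if y.ndim else float(y)


def odd_root(value: float, p: int) -> float:
    """Real p-th root for odd p: sign(value) * |value|^(1/p).

    The exact inverse of the odd power, negative arguments included.
    """
    p = int(p)
    if p < 1 or p % 2 == 0:
        raise DataValidationError(f"odd_root requires an odd positive exponent, got {p}")
    return math.copysign(abs(value) ** (1.0 / p), value) if value != 0 else 0.0


class LackOfFit(NamedTuple):
    """Pure-error lack-of-fit F test on a replicated design."""

    F: float
    p: float
    df_lack: int
    df_pure: int
    ms_lack: float
    ms_pure: float


def _pure_error(ds: DoseResponseDataset) -> tuple[float, int]:
    """Pooled within-group SS and its df, from group SDs (n-1 denominator)."""
    ss = float(((ds.ns - 1) * ds.sds**2).sum())
    df = int(ds.total_n - len(ds.groups))
    return ss, df


def lack_of_fit(
    ds: DoseResponseDataset, model: DoseResponseModel, n_params: Optional[int] = None
) -> LackOfFit:
    """Test the fitted curve against pure replicate error.

    MS_lack = sum_i n_i (m_i - yhat_i)^2 / (k - n_params),
    MS_pure = sum_i (n_i - 1) s_i^2 / (N - k);
    F = MS_lack / MS_pure on (k - n_params, N - k) df.
    """
    if n_params is None:
        n_params = N_PARAMS[model.family]
        if model.family == "shifted_power" and not model.through_origin:
            n_params += 1
    k = len(ds.groups)
    if k <= n_params:
        raise UnderdeterminedFitError(
            f"lack-of-fit needs more groups ({k}) than parameters ({n_params})"
        )
    ss_pure, df_pure = _pure_error(ds)
    if df_pure < 1 or ss_pure <= 0:
        raise DegenerateVarianceError(
            "pooled within-group variance is zero; add replicate noise or use raw counts"
        )
    pred = np.asarray(evaluate(model, ds.doses))
    ss_lack = float((ds.ns * (ds.means - pred) ** 2).sum())
    df_lack = k - n_params
    ms_lack = ss_lack / df_lack
    ms_pure = ss_pure / df_pure
    F = ms_lack / ms_pure
    p = float(stats.f.sf(F, df_lack, df_pure))
    return LackOfFit(F=F, p=p, df_lack=df_lack, df_pure=df_pure, ms_lack=ms_lack, ms_pure=ms_pure)


@dataclass(frozen=True)
class FitResult:
    """A fitted curve plus its lack-of-fit verdict.

    ``sse`` is the n-weighted residual sum of squares on the group means
    (equal to per-embryo least squares when summaries came from raw
    counts).  ``accepted`` is False when the lack-of-fit test rejects at
    ``alpha`` or a coefficient constraint is violated.
    """

    model: DoseResponseModel
    sse: float
    lack_of_fit_F: float
    lack_of_fit_p: float
    df_lack: int
    df_pure: int
    accepted: bool
    n_params: int
    alpha: float
    constrain_origin: bool = True
    warning: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "sse": self.sse,
            "lack_of_fit": {
                "F": self.lack_of_fit_F,
                "p": self.lack_of_fit_p,
                "df1": self.df_lack,
                "df2": self.df_pure,
            },
            "accepted": self.accepted,
            "n_params": self.n_params,
            "alpha": self.alpha,
            "constrain_origin": self.constrain_origin,
            "warning": self.warning,
        }


def _wsse(ds: DoseResponseDataset, pred: np.ndarray) -> float:
    return float((ds.ns * (ds.means - pred) ** 2).sum())


def _fit_linear(x, m, w) -> dict:
    c = float((w * x * m).sum() / (w * x**2).sum())
    return {"c": max(c, 0.0)}


def _fit_quadratic(x, m, w) -> dict:
    beta = float((w * x**2 * m).sum() / (w * x**4).sum())
    return {"beta": max(beta, 0.0)}


def _fit_linear_quadratic(x, m, w) -> dict:
    # non-negative least squares on the sqrt(n)-weighted design
    rw = np.sqrt(w)
    A = np.column_stack([x, x**2]) * rw[:, None]
    coef, _ = optimize.nnls(A, m * rw)
    return {"alpha": float(coef[0]), "beta": float(coef[1])}


def _shifted_power_objective(a_values: np.ndarray, p: int, constrain: bool, x, m, w):
    """Vectorised weighted SSE over a grid of shifts; returns (sse, b)."""
    base = x[None, :] + a_values[:, None]
    powered = np.sign(base) * np.abs(base) ** p
    if constrain:
        b = -np.sign(a_values) * np.abs(a_values) ** p
    else:
        # optimal offset is the weighted mean residual
        b = (w * (m[None, :] - powered)).sum(axis=1) / w.sum()
    resid = m[None, :] - powered - b[:, None]
    return (w * resid**2).sum(axis=1), b


def _fit_shifted_power(x, m, w, constrain: bool, p_grid: Sequence[int]) -> dict:
    """Grid over a (auto-expanding when the optimum hits the edge) plus
    bounded local refinement, exhaustive over the odd exponents."""
    best = None
    for p in p_grid:
        lo, hi = -3.0, 3.0
        while True:
            grid = np.arange(lo, hi + 0.005, 0.01)
            sse, _ = _shifted_power_objective(grid, p, constrain, x, m, w)
            i = int(np.argmin(sse))
            at_edge = i in (0, len(grid) - 1)
            if not at_edge or (hi - lo) >= 60.0:
                break
            lo, hi = lo - 3.0, hi + 3.0  # optimum at the boundary: widen

        def obj(a: float) -> float:
            s, _ = _shifted_power_objective(np.array([a]), p, constrain, x, m, w)
            return float(s[0])

        res = optimize.minimize_scalar(
            obj,
            bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
            method="bounded",
            options={"xatol": 1e-8},
        )
        a = float(res.x)
        _, b_arr = _shifted_power_objective(np.array([a]), p, constrain, x, m, w)
        cand = (float(res.fun), int(p), a, float(b_arr[0]))
        if best is None or cand[0] < best[0]:
            best = cand
    sse, p, a, b = best
    if constrain:
        b = -math.copysign(abs(a) ** p, a) if a != 0 else 0.0  # b = -a^p exactly
    return {"a": a, "p": p, "b": b}


def fit_model(
    ds: DoseResponseDataset,
    family: str,
    constrain_origin: bool = True,
    p_grid: Sequence[int] = ALLOWED_EXPONENTS,
    alpha: float = 0.05,
    lack_of_fit_test: bool = True,
) -> FitResult:
    """Weighted least-squares fit of one family to a dataset's group means.

    The objective is sum_i n_i (m_i - y(x_i))^2.  ``constrain_origin``
    binds the shifted-power offset to b = -a^p so the curve passes through
    (0, 0); the other families pass through the origin by construction.

    The returned :class:`FitResult` carries the pure-error lack-of-fit
    verdict: ``accepted`` is True only when the test does not reject at
    ``alpha``.  ``lack_of_fit_test=False`` skips the test (for callers that
    only need the curve, e.g. bootstrap refits on resampled data whose
    pure error may be degenerate); the F and p fields are then NaN and
    ``accepted`` reflects only the parameter constraints.
    """
    if family not in FAMILIES:
        raise DataValidationError(f"unknown family {family!r}")
    k = len(ds.groups)
    if k < 2:
        raise UnderdeterminedFitError("fitting needs at least 2 dose groups")
    n_params = N_PARAMS[family]
    if family == "shifted_power":
        bad = [p for p in p_grid if p % 2 == 0 or p not in ALLOWED_EXPONENTS]
        if bad or not p_grid:
            raise DataValidationError(f"p_grid must be a non-empty subset of {ALLOWED_EXPONENTS}")
        if not constrain_origin:
            n_params += 1
    if k < n_params + 1:
        raise UnderdeterminedFitError(
            f"{family} has {n_params} parameters but only {k} dose groups"
        )
    x, m, w = ds.doses, ds.means, ds.ns.astype(float)
    if np.all(m == 0):
        raise DegenerateDataError("all group means are zero; nothing to fit")

    if family == "linear":
        params = _fit_linear(x, m, w)
    elif family == "quadratic":
        params = _fit_quadratic(x, m, w)
    elif family == "linear_quadratic":
        params = _fit_linear_quadratic(x, m, w)
    else:
        params = _fit_shifted_power(x, m, w, constrain_origin, tuple(p_grid))
    model = DoseResponseModel(family=family, params=params)
    sse = _wsse(ds, np.asarray(evaluate(model, x)))

    if not lack_of_fit_test:
        return FitResult(
            model=model,
            sse=sse,
            lack_of_fit_F=float("nan"),
            lack_of_fit_p=float("nan"),
            df_lack=0,
            df_pure=0,
            accepted=True,
            n_params=n_params,
            alpha=alpha,
            constrain_origin=constrain_origin if family == "shifted_power" else True,
            warning="lack-of-fit not assessed",
        )
    lof = lack_of_fit(ds, model, n_params=n_params)
    accepted = bool(lof.p >= alpha)
    warning = None
    if not accepted:
        warning = (
            f"lack-of-fit rejects {family} at alpha={alpha} "
            f"(F={lof.F:.3g} on ({lof.df_lack}, {lof.df_pure}) df, p={lof.p:.3g})"
        )
    return FitResult(
        model=model,
        sse=sse,
        lack_of_fit_F=lof.F,
        lack_of_fit_p=lof.p,
        df_lack=lof.df_lack,
        df_pure=lof.df_pure,
        accepted=accepted,
        n_params=n_params,
        alpha=alpha,
        constrain_origin=constrain_origin if family == "shifted_power" else True,
        warning=warning,
    )


def select_model(
    ds: DoseResponseDataset,
    candidates: Sequence[str] = FAMILIES,
    constrain_origin: bool = True,
    p_grid: Sequence[int] = ALLOWED_EXPONENTS,
    alpha: float = 0.05,
) -> FitResult:
    """Fit every candidate family and pick a winner.

    Among fits that survive the lack-of-fit test the lowest-SSE one wins,
    except that a richer family only displaces a simpler accepted one when
    its SSE advantage exceeds one pure-error mean square per extra
    parameter (otherwise the gain is indistinguishable from noise and the
    fits count as tied; ties go to fewer parameters, then candidate
    order).  If no family survives, the lowest-SSE fit is returned with
    ``accepted=False`` and a warning naming every rejected family.
    """
    if not candidates:
        raise DataValidationError("candidates must be non-empty")
    fits = [
        fit_model(ds, fam, constrain_origin=constrain_origin, p_grid=p_grid, alpha=alpha)
        for fam in candidates
    ]
    order = {fam: i for i, fam in enumerate(candidates)}

    def key(f: FitResult):
        return (f.sse, f.n_params, order[f.model.family])

    accepted = [f for f in fits if f.accepted]
    if accepted:
        best = min(accepted, key=key)
        ss_pure, df_pure = _pure_error(ds)
        ms_pure = ss_pure / df_pure if df_pure > 0 else 0.0
        rivals = [
            f
            for f in accepted
            if f.n_params < best.n_params
            and f.sse - best.sse <= ms_pure * (best.n_params - f.n_params)
        ]
        if rivals:
            best = min(rivals, key=lambda f: (f.n_params, f.sse, order[f.model.family]))
        return best
    best = min(fits, key=key)
    warning = (
        "no candidate family survives the lack-of-fit test at "
        f"alpha={alpha} (rejected: {', '.join(f.model.family for f in fits)}); "
        f"returning the lowest-SSE fit ({best.model.family})"
    )
    return FitResult(**{**best.__dict__, "warning": warning})
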