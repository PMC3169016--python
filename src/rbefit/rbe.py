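"""Iso-effect dose inversion and relative biological effectiveness (RBE).

RBE is the ratio of the reference-radiation dose (X-rays) to the
test-radiation dose (iron-ions) that produces the same effect level — here
the same expected number of rosette-shaped apoptotic clusters per optic
tectum.  Both doses come from inverting fitted dose-response curves at the
chosen effect level y.

The shifted-power family inverts in closed form,

    x = odd_root(y - b, p) - a,

the polynomial families by bracketed root finding.  A percentile bootstrap
(embryo-level resampling within each dose group, refit per replicate)
supplies an uncertainty interval for the RBE point estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize

from .data import DoseGroup, DoseResponseDataset
from .exceptions import (
    BootstrapFailureError,
    DataValidationError,
    InversionError,
    RbefitError,
)
from .models import DoseResponseModel, evaluate, fit_model, odd_root

__all__ = ["RBEEstimate", "invert_dose", "compute_rbe", "rbe_profile", "bootstrap_rbe"]


@dataclass(frozen=True)
class RBEEstimate:
    """Iso-effect doses for a curve pair and their ratio.

    ``rbe = dose_reference / dose_test``: how many times more effective the
    test radiation is per Gy than the reference radiation at this effect
    level.
    """

    effect_level: float
    dose_test: float
    dose_reference: float
    rbe: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_boot: Optional[int] = None
    seed: Optional[int] = None
    n_skipped: int = 0

    def to_dict(self) -> dict:
        d = {
            "effect_level": self.effect_level,
            "dose_test_gy": self.dose_test,
            "dose_reference_gy": self.dose_reference,
            "rbe": self.rbe,
        }
        if self.ci_low is not None:
            d["ci"] = [self.ci_low, self.ci_high]
            d["n_boot"] = self.n_boot
            d["seed"] = self.seed
        return d


def invert_dose(model: DoseResponseModel, effect: float, tol: float = 1e-9) -> float:
    """Dose (Gy) at which the curve reaches ``effect`` clusters/OT.

    Requires ``effect >= evaluate(model, 0)`` and a non-decreasing curve on
    the bracketing interval (all families satisfy monotonicity on [0, inf)
    under their constraints).
    """
    y0 = float(evaluate(model, 0.0))
    if effect < y0:
        raise InversionError(
            f"effect {effect} lies below the curve's value {y0:.6g} at 0 Gy"
        )
    if model.family == "shifted_power":
        pars = model.params
        x = odd_root(effect - pars["b"], pars["p"]) - pars["a"]
        if x < 0:
            # only possible through rounding at the origin
            if x > -1e-9:
                return 0.0
            raise InversionError(f"closed-form inverse {x} is negative at effect {effect}")
        return float(x)
    if effect == y0:
        return 0.0
    hi = 1.0
    while float(evaluate(model, hi)) < effect:
        hi *= 2.0
        if hi > 1e12:
            raise InversionError(f"curve never reaches effect {effect}")
    x = optimize.brentq(lambda d: float(evaluate(model, d)) - effect, 0.0, hi, xtol=tol)
    return float(x)


def compute_rbe(
    test_model: DoseResponseModel,
    reference_model: DoseResponseModel,
    effect: float,
) -> RBEEstimate:
    """RBE of the test radiation relative to the reference at one effect level."""
    if effect <= 0:
        raise DataValidationError("effect level must be positive")
    try:
        dose_test = invert_dose(test_model, effect)
    except RbefitError as exc:
        raise InversionError(f"test curve: {exc}") from exc
    try:
        dose_reference = invert_dose(reference_model, effect)
    except RbefitError as exc:
        raise InversionError(f"reference curve: {exc}") from exc
    if dose_test <= 0:
        raise InversionError(f"test curve reaches effect {effect} at dose 0")
    return RBEEstimate(
        effect_level=float(effect),
        dose_test=dose_test,
        dose_reference=dose_reference,
        rbe=dose_reference / dose_test,
    )


def rbe_profile(
    test_model: DoseResponseModel,
    reference_model: DoseResponseModel,
    effects: Sequence[float],
) -> list[RBEEstimate]:
    """One RBE estimate per effect level, order preserved."""
    effects = list(effects)
    if not effects:
        raise DataValidationError("effects list must be non-empty")
    return [compute_rbe(test_model, reference_model, e) for e in effects]


def _resample_group(group: DoseGroup, rng: np.random.Generator) -> DoseGroup:
    """One bootstrap replicate of a dose group.

    Raw counts: resample embryos with replacement.  Summary-only groups:
    parametric draw from a moment-matched negative binomial (Poisson when
    the variance does not exceed the mean; point mass at 0 for a zero
    mean).
    """
    n = group.n
    if group.counts is not None:
        counts = rng.choice(np.asarray(group.counts), size=n, replace=True)
        return DoseGroup.from_counts(group.dose, counts.tolist())
    mu, var = group.mean, group.sd**2
    if mu == 0:
        counts = np.zeros(n, dtype=int)
    elif var <= mu:
        counts = rng.poisson(mu, size=n)
    else:
        size = mu**2 / (var - mu)  # NB dispersion from the moment equations
        counts = rng.negative_binomial(size, size / (size + mu), n)
    return DoseGroup.from_counts(group.dose, counts.tolist())


def bootstrap_rbe(
    ds_test: DoseResponseDataset,
    reference: Union[DoseResponseDataset, DoseResponseModel],
    effect: float,
    n_boot: int = 500,
    seed: int = 0,
    family: str = "shifted_power",
    constrain_origin: bool = True,
    max_skip_frac: float = 0.2,
) -> RBEEstimate:
    """Percentile bootstrap interval for the RBE at one effect level.

    Embryos are resampled within each dose group of the test dataset (and
    of the reference dataset, when a dataset rather than a fixed curve is
    given), the chosen family is refit to each replicate, and the RBE is
    recomputed.  ``ci_low``/``ci_high`` are the 2.5 and 97.5 percentiles.
    Deterministic given ``seed``.  Replicates whose refit or inversion
    fails are skipped; more than ``max_skip_frac`` skipped aborts.
    """
    if n_boot < 100:
        raise DataValidationError("n_boot must be >= 100")
    fixed_reference = isinstance(reference, DoseResponseModel)

    def fit_curve(ds: DoseResponseDataset) -> DoseResponseModel:
        # only the curve is needed; resampled replicates may have zero
        # pure error, so the lack-of-fit test is skipped here
        return fit_model(ds, family, constrain_origin=constrain_origin, lack_of_fit_test=False).model

    test_model = fit_curve(ds_test)
    ref_model = reference if fixed_reference else fit_curve(reference)
    point = compute_rbe(test_model, ref_model, effect)

    rng = np.random.default_rng(seed)
    values = []
    skipped = 0
    for _ in range(n_boot):
        try:
            boot_test = DoseResponseDataset(
                label=ds_test.label,
                groups=tuple(_resample_group(g, rng) for g in ds_test.groups),
            )
            boot_ref = ref_model
            if not fixed_reference:
                boot_ref = fit_curve(
                    DoseResponseDataset(
                        label=reference.label,
                        groups=tuple(_resample_group(g, rng) for g in reference.groups),
                    )
                )
            est = compute_rbe(fit_curve(boot_test), boot_ref, effect)
            values.append(est.rbe)
        except RbefitError:
            skipped += 1
    if skipped > max_skip_frac * n_boot:
        raise BootstrapFailureError(
            f"{skipped}/{n_boot} bootstrap replicates failed to fit or invert"
        )
    lo, hi = np.percentile(values, [2.5, 97.5])
    return replace(
        point, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot, seed=seed, n_skipped=skipped
    )
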