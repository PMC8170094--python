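"""Alchemical free-energy estimation from per-window work samples.

The electron-transfer reaction free energy is built from two alchemical
legs: FEP1 discharges the reactant charge state (electrostatics scaled to
zero through a coupling parameter lambda) and FEP2 recharges the product
state, each traversed in a ladder of lambda windows run in both forward
and backward mode.  Per window, the free-energy increment is estimated
either by exponential (Zwanzig) averaging,
``ddG_i = -kBT ln < exp(-dU_i / kBT) >``, or by the Bennett acceptance
ratio, which combines forward and backward work samples at the minimum
asymptotic variance.  The BAR increment solves the self-consistency

    mean_F f((W_F - C)/kBT) = mean_B f((W_B + C)/kBT),
    C = dG + kBT ln(n_B / n_F),

with f the Fermi (logistic) function; the root is found by bracketed
bisection/Brent iteration started from the two exponential estimates.
The forward/backward hysteresis of the exponential totals is kept as a
convergence diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .errors import EstimationError
from .thermo import Thermo

Method = Literal["exp", "bar"]
Leg = Literal["FEP1", "FEP2"]

#: Default number of lambda windows per transformation.
DEFAULT_N_WINDOWS = 16
#: Absolute tolerance on the BAR root, kcal/mol.
BAR_TOL = 1e-8


@dataclass
class FepWindow:
    """One lambda window with forward and backward work samples (kcal/mol).

    Work samples are stored in the forward direction of their own
    transformation: ``backward`` holds the work measured when stepping
    lambda_to -> lambda_from.
    """

    index: int
    lambda_from: float
    lambda_to: float
    forward: np.ndarray
    backward: np.ndarray

    def __post_init__(self) -> None:
        self.forward = np.atleast_1d(np.asarray(self.forward, float))
        self.backward = np.atleast_1d(np.asarray(self.backward, float))
        for lam in (self.lambda_from, self.lambda_to):
            if not 0.0 <= lam <= 1.0:
                raise ValueError("lambda values must lie in [0, 1]")
        if self.forward.size == 0 and self.backward.size == 0:
            raise ValueError("window needs samples on at least one side")


@dataclass
class FepTransformation:
    """An ordered ladder of lambda windows for one alchemical leg."""

    leg: Leg
    model: Literal["I", "II"]
    windows: list[FepWindow]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("transformation needs >= 1 window")
        lams = [w.lambda_from for w in self.windows] + [self.windows[-1].lambda_to]
        diffs = np.diff(lams)
        if not (np.all(diffs >= 0) or np.all(diffs <= 0)):
            raise ValueError("lambda schedule must be monotone")


@dataclass
class FepEstimate:
    """Accumulated free-energy change for one transformation."""

    leg: Leg
    model: Literal["I", "II"]
    method: Literal["exp_forward", "exp_backward", "bar"]
    per_window: np.ndarray  # ddG_i, kcal/mol
    total: float  # kcal/mol
    hysteresis: float | None = None  # kcal/mol
    uncertainty: float | None = None  # kcal/mol


def exp_estimator(samples, thermo: Thermo) -> float:
    """Zwanzig exponential average, computed through log-sum-exp.

    Stable for |dU|/kBT up to the exp overflow range (~700) because the
    Boltzmann weights are never materialized individually.
    """
    w = np.atleast_1d(np.asarray(samples, float))
    if w.size == 0:
        raise ValueError("need >= 1 work sample")
    kbt = thermo.kbt
    return float(-kbt * (logsumexp(-w / kbt) - np.log(w.size)))


def bar_estimator(
    forward, backward, thermo: Thermo, tol: float = BAR_TOL
) -> tuple[float, float]:
    """Bennett acceptance ratio estimate and its asymptotic uncertainty.

    Returns ``(dG, sigma)`` in kcal/mol.  The self-consistency equation is
    solved by Brent root finding on a bracket grown around the midpoint of
    the two exponential estimates.
    """
    wf = np.atleast_1d(np.asarray(forward, float))
    wb = np.atleast_1d(np.asarray(backward, float))
    if wf.size == 0 or wb.size == 0:
        raise ValueError("BAR needs samples on both sides")
    kbt = thermo.kbt
    m = kbt * np.log(wb.size / wf.size)

    def imbalance(dg: float) -> float:
        c = dg + m
        # f(x) = 1/(1 + e^x) = expit(-x); the difference is increasing in dg
        return float(
            np.mean(expit(-(wf - c) / kbt)) - np.mean(expit(-(wb + c) / kbt))
        )

    init = 0.5 * (exp_estimator(wf, thermo) - exp_estimator(wb, thermo))
    lo, hi = init - 1.0, init + 1.0
    for _ in range(80):
        if imbalance(lo) < 0 < imbalance(hi):
            break
        lo -= max(1.0, abs(lo))
        hi += max(1.0, abs(hi))
    else:
        raise EstimationError(
            "no sign change found for the BAR self-consistency equation",
            {"init": init, "lo": lo, "hi": hi, "f_lo": imbalance(lo), "f_hi": imbalance(hi)},
        )
    dg = float(brentq(imbalance, lo, hi, xtol=tol))

    c = dg + m
    ff = expit(-(wf - c) / kbt)
    fb = expit(-(wb + c) / kbt)
    var = kbt**2 * (
        (np.mean(ff**2) / np.mean(ff) ** 2 - 1.0) / wf.size
        + (np.mean(fb**2) / np.mean(fb) ** 2 - 1.0) / wb.size
    )
    return dg, float(np.sqrt(max(var, 0.0)))


def accumulate(
    transformation: FepTransformation,
    method: Method = "bar",
    thermo: Thermo | None = None,
) -> FepEstimate:
    """Sum per-window increments into a leg total.

    For both methods the exponential totals of the forward and of the
    reversed transformation are evaluated and their residual
    ``|dG_fwd + dG_bwd|`` reported as the hysteresis.  BAR additionally
    carries the quadrature sum of per-window asymptotic uncertainties.
    """
    thermo = thermo or Thermo()
    fwd = np.array(
        [exp_estimator(w.forward, thermo) if w.forward.size else np.nan
         for w in transformation.windows]
    )
    bwd = np.array(
        [exp_estimator(w.backward, thermo) if w.backward.size else np.nan
         for w in transformation.windows]
    )
    hysteresis = None
    if not (np.isnan(fwd).any() or np.isnan(bwd).any()):
        hysteresis = float(abs(fwd.sum() + bwd.sum()))

    if method == "exp":
        per_window = fwd
        if np.isnan(per_window).any():
            raise ValueError("exponential method needs forward samples in every window")
        return FepEstimate(
            transformation.leg, transformation.model, "exp_forward",
            per_window, float(per_window.sum()), hysteresis,
        )
    if method != "bar":
        raise ValueError(f"unknown method {method!r}")
    per_window = np.empty(len(transformation.windows))
    variances = np.empty_like(per_window)
    for i, w in enumerate(transformation.windows):
        per_window[i], sigma = bar_estimator(w.forward, w.backward, thermo)
        variances[i] = sigma**2
    return FepEstimate(
        transformation.leg, transformation.model, "bar",
        per_window, float(per_window.sum()), hysteresis,
        float(np.sqrt(variances.sum())),
    )


def combine_legs(fep1: FepEstimate, fep2: FepEstimate) -> tuple[float, float | None]:
    """Reaction dG0 = dG(discharge reactant) + dG(recharge product).

    Uncertainties, where present on both legs, add in quadrature.  The two
    legs must belong to the same electron-transfer model.
    """
    if fep1.model != fep2.model:
        raise ValueError(f"leg models differ: {fep1.model} vs {fep2.model}")
    total = fep1.total + fep2.total
    sigma = None
    if fep1.uncertainty is not None and fep2.uncertainty is not None:
        sigma = float(np.hypot(fep1.uncertainty, fep2.uncertainty))
    return float(total), sigma


# ---------------------------------------------------------------------------
# CSV I/O: columns leg, direction, window_index, lambda_from, lambda_to,
# work_kcal_mol (one row per work sample); model carried per-file or per-row.

CSV_COLUMNS = [
    "leg", "direction", "window_index", "lambda_from", "lambda_to", "work_kcal_mol",
]


def read_fep_table(path, model: Literal["I", "II"] = "I") -> list[FepTransformation]:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"FEP table missing columns: {sorted(missing)}")
    if "model" in df.columns:
        models = df["model"].unique()
        if len(models) > 1:
            raise ValueError("one FEP table must hold a single model")
        model = str(models[0])
    out = []
    for leg, leg_df in df.groupby("leg", sort=False):
        windows = []
        for idx, w_df in leg_df.groupby("window_index", sort=True):
            fwd = w_df.loc[w_df["direction"] == "forward", "work_kcal_mol"]
            bwd = w_df.loc[w_df["direction"] == "backward", "work_kcal_mol"]
            lam = w_df.iloc[0]
            windows.append(
                FepWindow(int(idx), float(lam["lambda_from"]),
                          float(lam["lambda_to"]),
                          fwd.to_numpy(float), bwd.to_numpy(float))
            )
        out.append(FepTransformation(str(leg), model, windows))
    return out


def write_fep_table(
    transformations: Sequence[FepTransformation], path
) -> None:
    rows = []
    for tr in transformations:
        for w in tr.windows:
            for direction, samples in (("forward", w.forward), ("backward", w.backward)):
                for work in samples:
                    rows.append(
                        {"leg": tr.leg, "model": tr.model, "direction": direction,
                         "window_index": w.index, "lambda_from": w.lambda_from,
                         "lambda_to": w.lambda_to, "work_kcal_mol": work}
                    )
    pd.DataFrame(rows, columns=["model"] + CSV_COLUMNS[:2] + CSV_COLUMNS[2:]).to_csv(
        path, index=False
    )
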