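"""Linear-response free-energy curves along the energy-gap coordinate.

For a one-electron transfer the vertical energy gap
``dU = U_product - U_reactant`` (both potentials evaluated on the same
nuclear coordinates, differing only in the assigned charge state) is a
natural reaction coordinate.  Sampling dU in equilibrium simulations of
the reactant and of the product state gives, via
``G = -kBT ln rho(dU) + const``, one free-energy branch per state.  When
the gap fluctuations are Gaussian each branch is a parabola with
curvature ``kBT / (2 sigma^2)`` and vertex at the state's mean gap.  After
shifting the product branch so the two curves intersect at dU = 0, the
driving force dG0 is the difference between the two minima and the
reorganization energies Lambda_p / Lambda_r follow from each parabola's
curvature times the squared vertex separation.  Under exact linear
response (equal variances) the closed forms dG0 = (m_r + m_p)/2 and
Lambda = sigma^2 / (2 kBT) hold; unequal curvatures give the
Lambda_p != Lambda_r asymmetry seen in real gap sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .thermo import Thermo

State = Literal["reactant", "product"]

#: |skewness| above which a normality warning is raised.
SKEW_WARN = 0.5


@dataclass
class GapSampleSet:
    """Energy-gap samples dU for one redox state."""

    state: State
    samples: np.ndarray
    u_product: np.ndarray | None = None
    u_reactant: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if self.u_product is not None and self.u_reactant is not None:
            dU = np.asarray(self.u_product, float) - np.asarray(self.u_reactant, float)
            if not np.allclose(dU, self.samples):
                raise ValueError("samples inconsistent with paired energies")

    @property
    def n(self) -> int:
        return self.samples.size


@dataclass
class GaussianSummary:
    mean: float  # <dU>, kcal/mol
    sd: float  # sample sd, kcal/mol
    skewness: float  # adjusted Fisher-Pearson
    n: int


@dataclass
class Parabola:
    """G(x) = a (x - vertex)^2 + offset, energies in kcal/mol."""

    a: float  # curvature, (kcal/mol)^-1
    vertex: float
    offset: float = 0.0

    def g(self, x):
        return self.a * (np.asarray(x, float) - self.vertex) ** 2 + self.offset


@dataclass
class FreeEnergyDiagram:
    """Aligned two-state free-energy diagram with extracted parameters."""

    reactant: Parabola
    product: Parabola
    delta_g0: float  # kcal/mol
    lambda_p: float  # kcal/mol, product-state reorganization energy
    lambda_r: float  # kcal/mol, reactant-state reorganization energy
    reactant_summary: GaussianSummary | None = None
    product_summary: GaussianSummary | None = None
    reactant_curve: tuple[np.ndarray, np.ndarray] | None = None
    product_curve: tuple[np.ndarray, np.ndarray] | None = None


def gap_from_energies(u_product, u_reactant) -> np.ndarray:
    """Elementwise energy gap dU = U_product - U_reactant."""
    up = np.asarray(u_product, float)
    ur = np.asarray(u_reactant, float)
    if up.shape != ur.shape:
        raise ValueError("energy series lengths differ")
    return up - ur


def summarize_gaps(gap_set: GapSampleSet) -> GaussianSummary:
    """Mean, sample sd and skewness of the gap samples.

    Raises a warning when |skewness| exceeds 0.5 — the free-energy
    parabolas assume near-Gaussian fluctuations within the sampled basin.
    """
    x = gap_set.samples
    if x.size < 2:
        raise ValueError("need >= 2 samples")
    skew = float(stats.skew(x, bias=False))
    if abs(skew) > SKEW_WARN:
        warnings.warn(
            f"{gap_set.state} gaps have |skewness| = {abs(skew):.2f} > {SKEW_WARN}; "
            "Gaussian linear response may be inaccurate"
        )
    return GaussianSummary(
        mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)), skewness=skew, n=x.size
    )


def empirical_free_energy_curve(
    gap_set: GapSampleSet, thermo: Thermo, bins="fd"
) -> tuple[np.ndarray, np.ndarray]:
    """G = -kBT ln(histogram density), shifted so min G = 0.

    Empty bins are excluded.  Freedman-Diaconis binning by default; pass
    an integer to override.
    """
    x = gap_set.samples
    if x.size < 50:
        raise ValueError("need >= 50 samples for an empirical curve")
    if np.ptp(x) == 0:
        raise ValueError("all samples identical: degenerate histogram")
    density, edges = np.histogram(x, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = density > 0
    g = -thermo.kbt * np.log(density[mask])
    return centers[mask], g - g.min()


def parabola_from_summary(summary: GaussianSummary, thermo: Thermo) -> Parabola:
    """Gaussian-statistics parabola: curvature kBT/(2 sigma^2), vertex <dU>."""
    if summary.sd <= 0:
        raise ValueError("sd must be positive")
    return Parabola(a=thermo.kbt / (2.0 * summary.sd**2), vertex=summary.mean)


def align_and_extract(reactant: Parabola, product: Parabola) -> FreeEnergyDiagram:
    """Shift the product branch to intersect the reactant branch at dU = 0
    and read off dG0, Lambda_p and Lambda_r.

    With the reactant offset fixed at 0, the product offset satisfying
    G_p(0) = G_r(0) equals a_r v_r^2 - a_p v_p^2, which is also dG0 (the
    difference of the minima).  The reorganization energies are each
    branch's rise over the vertex separation:
    Lambda_p = a_p (v_r - v_p)^2, Lambda_r = a_r (v_r - v_p)^2.
    """
    for p in (reactant, product):
        if not (np.isfinite(p.vertex) and p.a > 0):
            raise ValueError("parabolas need finite vertices and positive curvature")
    r = Parabola(reactant.a, reactant.vertex, 0.0)
    offset = r.a * r.vertex**2 - product.a * product.vertex**2
    p = Parabola(product.a, product.vertex, offset)
    sep = r.vertex - p.vertex
    if sep == 0:
        warnings.warn("equal vertices: zero reorganization energy")
    return FreeEnergyDiagram(
        reactant=r,
        product=p,
        delta_g0=float(p.g(p.vertex) - r.g(r.vertex)),
        lambda_p=float(p.a * sep**2),
        lambda_r=float(r.a * sep**2),
    )


def full_linear_response(
    reactant: GapSampleSet,
    product: GapSampleSet,
    thermo: Thermo | None = None,
    bins="fd",
) -> FreeEnergyDiagram:
    """Summaries -> parabolas -> alignment, with empirical curves attached.

    The empirical curves cover only the sampled gap ranges (the thick
    segments of a free-energy diagram); the parabolas extrapolate beyond.
    """
    thermo = thermo or Thermo()
    rs, ps = summarize_gaps(reactant), summarize_gaps(product)
    diagram = align_and_extract(
        parabola_from_summary(rs, thermo), parabola_from_summary(ps, thermo)
    )
    diagram.reactant_summary, diagram.product_summary = rs, ps
    if reactant.n >= 50:
        c, g = empirical_free_energy_curve(reactant, thermo, bins)
        diagram.reactant_curve = (c, g + _curve_anchor(diagram.reactant, c, g))
    if product.n >= 50:
        c, g = empirical_free_energy_curve(product, thermo, bins)
        diagram.product_curve = (c, g + _curve_anchor(diagram.product, c, g))
    return diagram


def _curve_anchor(parabola: Parabola, centers: np.ndarray, g: np.ndarray) -> float:
    """Offset that pins an empirical curve to its parabola at the vertex."""
    i = int(np.argmin(np.abs(centers - parabola.vertex)))
    return float(parabola.g(centers[i]) - g[i])
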