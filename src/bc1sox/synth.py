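"""Synthetic inputs with known ground truth for every analysis stage.

Each generator emulates the statistical structure of one class of
simulation-derived input — Gaussian energy-gap fluctuations obeying the
linear-response identity, Crooks-consistent alchemical work samples,
exponential ligand dwell times, distance traces with scheduled binding
events, and fragment spin-density tables for the two electron-transfer
outcomes — so that the downstream estimators can be validated by
parameter recovery without any external data.

Randomness: every generator draws from an independent substream derived
from ``(seed, generator id)``, so adding samples to one stage never
perturbs another.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigError
from .fep import FepTransformation, FepWindow
from .kinetics import BindingEvent, DistanceTrace
from .linres import GapSampleSet
from .spin import FragmentSpinRecord
from .thermo import KB_KCAL_MOL_K

_STREAM_IDS = {"gaps": 1, "fep": 2, "dwell": 3, "trace": 4, "spin": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAM_IDS[stream],))
    )


class GapGenConfig(BaseModel):
    """Two-state Gaussian energy-gap samples with analytic ground truth."""

    model_config = ConfigDict(frozen=True)

    delta_g0_true: float  # kcal/mol
    lambda_true: float = Field(gt=0)  # kcal/mol
    sigma_ratio: float = Field(default=1.0, gt=0)  # product sd / reactant sd
    temperature: float = Field(default=300.0, gt=0)  # K
    n_samples: int = Field(ge=2)
    seed: int = 0


class FepGenConfig(BaseModel):
    """Crooks-consistent per-window work samples for one alchemical leg."""

    model_config = ConfigDict(frozen=True)

    window_delta_g: list[float] = Field(min_length=1)  # kcal/mol, per window
    sigma_w: float = Field(default=1.0, ge=0)  # kcal/mol
    n_samples: int = Field(default=100, ge=1)  # per window and direction
    temperature: float = Field(default=300.0, gt=0)
    seed: int = 0


class DwellGenConfig(BaseModel):
    """Exponential bound dwell times."""

    model_config = ConfigDict(frozen=True)

    tau_true: float = Field(gt=0)  # ns
    n_events: int = Field(ge=1)
    seed: int = 0


class TraceGenConfig(BaseModel):
    """Distance trace with scheduled binding events.

    Noise is zero-mean and truncated so that it can never carry a bound
    frame above the 9 A opening threshold or a baseline frame below the
    20 A closing threshold: the noiseless segmentation stays the ground
    truth by construction.
    """

    model_config = ConfigDict(frozen=True)

    dt_ps: float = Field(default=10.0, gt=0)
    events: list[tuple[float, float]] = Field(default_factory=list)  # (entry, dwell) ps
    baseline_A: float = Field(default=25.0, gt=20)
    bound_A: float = Field(default=5.0, gt=0, lt=9)
    noise_A: float = Field(default=0.5, ge=0)
    duration_ps: float | None = None
    escape_sides: list[str] | None = None  # per event: "positive" | "negative"
    seed: int = 0

    @model_validator(mode="after")
    def _check_schedule(self):
        last_end = -float("inf")
        for entry, dwell in self.events:
            if entry < 0 or dwell <= 0:
                raise ValueError("event entries must be >= 0 with positive dwell")
            if entry <= last_end:
                raise ValueError("scheduled events overlap")
            last_end = entry + dwell
        if self.duration_ps is not None and self.events:
            if last_end >= self.duration_ps:
                raise ValueError("events extend past the trace duration")
        if self.escape_sides is not None:
            if len(self.escape_sides) != len(self.events):
                raise ValueError("escape_sides must match the event schedule")
            if any(s not in ("positive", "negative") for s in self.escape_sides):
                raise ValueError("escape sides must be 'positive' or 'negative'")
        return self

    @property
    def resolved_duration_ps(self) -> float:
        if self.duration_ps is not None:
            return self.duration_ps
        if self.events:
            entry, dwell = self.events[-1]
            return entry + dwell + 1000.0
        return 1000.0


class SpinGenConfig(BaseModel):
    """Labeled fragment spin tables emulating the QC snapshot ensemble.

    Default class counts and energy statistics follow the O2 spin-up
    ensemble of the reference snapshot study (77 / 0 / 44 / 6 with the
    model II class ~39 kcal/mol below the no-transfer mean).
    """

    model_config = ConfigDict(frozen=True)

    n_no_et: int = Field(default=77, ge=0)
    n_model_i: int = Field(default=0, ge=0)
    n_model_ii: int = Field(default=44, ge=0)
    n_outlier: int = Field(default=6, ge=0)
    spin_noise_sd: float = Field(default=0.02, ge=0)
    energy_mean_no_et: float = 0.0  # kcal/mol (absolute anchor, arbitrary)
    energy_sd_no_et: float = Field(default=14.730, ge=0)
    energy_mean_model_i: float = 2.0507
    energy_sd_model_i: float = Field(default=11.399, ge=0)
    energy_mean_model_ii: float = -39.333
    energy_sd_model_ii: float = Field(default=12.906, ge=0)
    outlier_energy_offset: float = -150.0  # beyond any sane outlier threshold
    o2_spin_orientation: str = Field(default="up", pattern="^(up|down)$")
    seed: int = 0


# ---------------------------------------------------------------------------


def gen_gap_samples(cfg: GapGenConfig) -> tuple[GapSampleSet, GapSampleSet]:
    """Reactant/product energy-gap samples under linear response.

    Means sit at dG0 +/- Lambda; the reactant sd obeys the equal-variance
    identity sigma = sqrt(2 Lambda kBT) and the product sd is scaled by
    ``sigma_ratio`` (a ratio != 1 produces the unequal-curvature case
    where Lambda_p != Lambda_r).
    """
    rng = _rng(cfg.seed, "gaps")
    kbt = KB_KCAL_MOL_K * cfg.temperature
    sigma_r = float(np.sqrt(2.0 * cfg.lambda_true * kbt))
    sigma_p = cfg.sigma_ratio * sigma_r
    meta = {
        "delta_g0_true": cfg.delta_g0_true,
        "lambda_true": cfg.lambda_true,
        "sigma_reactant": sigma_r,
        "sigma_product": sigma_p,
        "temperature": cfg.temperature,
    }
    reactant = rng.normal(cfg.delta_g0_true + cfg.lambda_true, sigma_r, cfg.n_samples)
    product = rng.normal(cfg.delta_g0_true - cfg.lambda_true, sigma_p, cfg.n_samples)
    return (
        GapSampleSet("reactant", reactant, meta=dict(meta)),
        GapSampleSet("product", product, meta=dict(meta)),
    )


def gen_fep_windows(
    cfg: FepGenConfig, leg: str = "FEP1", model: str = "I"
) -> FepTransformation:
    """Per-window forward/backward work samples satisfying Crooks.

    Forward work ~ N(dG_i + sigma^2/(2 kBT), sigma) and backward work
    ~ N(-dG_i + sigma^2/(2 kBT), sigma): the log density ratio
    p_F(W)/p_B(-W) is then exactly (W - dG_i)/kBT.
    """
    rng = _rng(cfg.seed, "fep")
    kbt = KB_KCAL_MOL_K * cfg.temperature
    n_windows = len(cfg.window_delta_g)
    lams = np.linspace(0.0, 1.0, n_windows + 1)
    dissipation = (
        cfg.sigma_w**2 / (2.0 * kbt) if cfg.sigma_w > 0 else 0.0
    )
    windows = []
    for i, dg in enumerate(cfg.window_delta_g):
        if cfg.sigma_w == 0:
            fwd = np.full(cfg.n_samples, float(dg))
            bwd = np.full(cfg.n_samples, float(-dg))
        else:
            fwd = rng.normal(dg + dissipation, cfg.sigma_w, cfg.n_samples)
            bwd = rng.normal(-dg + dissipation, cfg.sigma_w, cfg.n_samples)
        windows.append(FepWindow(i, float(lams[i]), float(lams[i + 1]), fwd, bwd))
    return FepTransformation(
        leg, model, windows,
        meta={"window_delta_g_true": list(cfg.window_delta_g),
              "total_delta_g_true": float(np.sum(cfg.window_delta_g)),
              "sigma_w": cfg.sigma_w, "temperature": cfg.temperature},
    )


def gen_dwell_times(cfg: DwellGenConfig) -> np.ndarray:
    """I.i.d. exponential dwell times (ns) with mean ``tau_true``."""
    return _rng(cfg.seed, "dwell").exponential(cfg.tau_true, cfg.n_events)


def gen_distance_trace(
    cfg: TraceGenConfig,
) -> tuple[DistanceTrace, list[BindingEvent]]:
    """Distance trace realizing the scheduled events, plus its ground truth.

    The noiseless trace sits at the baseline distance and drops to the
    bound distance for frames with entry <= t <= entry + dwell; the
    returned events are the segmentation of that noiseless trace under the
    9/13/20 A rule.  If ``escape_sides`` is set, a membrane-normal z
    channel is attached that excursions to +/-25 A after each event.
    """
    rng = _rng(cfg.seed, "trace")
    duration = cfg.resolved_duration_ps
    n = int(np.floor(duration / cfg.dt_ps)) + 1
    t = np.arange(n) * cfg.dt_ps
    d = np.full(n, cfg.baseline_A)
    truth: list[BindingEvent] = []
    for entry, dwell in cfg.events:
        mask = (t >= entry - 1e-9) & (t <= entry + dwell + 1e-9)
        d[mask] = cfg.bound_A
        idx = np.nonzero(mask)[0]
        if idx.size:
            start, end = int(idx[0]), int(idx[-1])
            truth.append(BindingEvent(start, end, (end - start) * cfg.dt_ps * 1e-3))

    if cfg.noise_A > 0:
        noise = rng.uniform(-cfg.noise_A, cfg.noise_A, n)
        margin_bound = 0.99 * (9.0 - cfg.bound_A)
        margin_base = 0.99 * (cfg.baseline_A - 20.0)
        bound = d == cfg.bound_A
        noise[bound] = np.clip(noise[bound], -margin_bound, margin_bound)
        noise[~bound] = np.clip(noise[~bound], -margin_base, margin_base)
        d = d + noise

    z = None
    if cfg.escape_sides is not None:
        z = np.zeros(n)
        for event, side in zip(truth, cfg.escape_sides):
            sign = 1.0 if side == "positive" else -1.0
            start = event.end_index + 1
            ramp = np.linspace(0.0, sign * 25.0, 11)[1:]
            stop = min(start + ramp.size, n)
            z[start:stop] = ramp[: stop - start]
            hold_stop = min(start + ramp.size + 40, n)
            z[stop:hold_stop] = sign * 25.0
            event.escape_side = side
    return DistanceTrace(cfg.dt_ps, d, z), truth


_BASE_SPINS = {
    # orientation "up": O2 triplet spin +2; the semiquinone's unpaired
    # electron is anti-parallel so that donating it reduces |s(O2)| to 1.
    "up": {"O2": 2.0, "SQ": -1.0, "Fe1": -4.0, "Fe2": 4.0, "S1": 0.25, "S2": 0.25,
           "Y147": 0.0, "H156": 0.0, "WAT": 0.0},
    "down": {"O2": -2.0, "SQ": 1.0, "Fe1": -4.0, "Fe2": 4.0, "S1": 0.25, "S2": 0.25,
             "Y147": 0.0, "H156": 0.0, "WAT": 0.0},
}
#: Share of the donated electron on each Fe2S2 fragment in model II.
_CLUSTER_SHARES = {"Fe2": 0.5, "S1": 0.25, "S2": 0.25}


def noiseless_spins(label: str, orientation: str) -> dict[str, float]:
    """Idealized fragment spins for one class and O2 orientation.

    Spin is conserved: the electron received by O2 (changing its spin by
    -/+1 for orientation up/down) is matched by an equal and opposite
    change on the donor pool — entirely on SQ for model I, split over
    Fe2/S1/S2 for model II.  Outliers reuse the no-transfer pattern;
    their signature is the energy, not the spins.
    """
    spins = dict(_BASE_SPINS[orientation])
    if label in ("no_ET", "outlier"):
        return spins
    o2_delta = -1.0 if orientation == "up" else 1.0
    spins["O2"] += o2_delta
    if label == "model_I":
        spins["SQ"] -= o2_delta
    elif label == "model_II":
        for frag, share in _CLUSTER_SHARES.items():
            spins[frag] -= o2_delta * share
    else:
        raise ConfigError(f"unknown class label {label!r}")
    return spins


def gen_spin_tables(
    cfg: SpinGenConfig,
) -> tuple[list[FragmentSpinRecord], list[str]]:
    """Labeled synthetic spin tables (records shuffled, labels aligned)."""
    rng = _rng(cfg.seed, "spin")
    plan = (
        ["no_ET"] * cfg.n_no_et
        + ["model_I"] * cfg.n_model_i
        + ["model_II"] * cfg.n_model_ii
        + ["outlier"] * cfg.n_outlier
    )
    energy_params = {
        "no_ET": (cfg.energy_mean_no_et, cfg.energy_sd_no_et),
        "model_I": (cfg.energy_mean_no_et + cfg.energy_mean_model_i, cfg.energy_sd_model_i),
        "model_II": (cfg.energy_mean_no_et + cfg.energy_mean_model_ii, cfg.energy_sd_model_ii),
        "outlier": (cfg.energy_mean_no_et + cfg.outlier_energy_offset, 10.0),
    }
    order = rng.permutation(len(plan))
    records, labels = [], []
    for new_id, k in enumerate(order):
        label = plan[k]
        spins = noiseless_spins(label, cfg.o2_spin_orientation)
        if cfg.spin_noise_sd > 0:
            spins = {
                f: s + rng.normal(0.0, cfg.spin_noise_sd) for f, s in spins.items()
            }
        mean, sd = energy_params[label]
        energy = float(rng.normal(mean, sd)) if sd > 0 else float(mean)
        if label != "outlier" and sd > 0:
            # truncate at 3 sd so class membership stays decidable by the
            # default 50 kcal/mol median-deviation outlier rule
            energy = float(np.clip(energy, mean - 3 * sd, mean + 3 * sd))
        records.append(
            FragmentSpinRecord(
                f"s{new_id:04d}", cfg.o2_spin_orientation, spins, energy
            )
        )
        labels.append(label)
    return records, labels
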