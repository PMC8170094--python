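"""Classification of electron-transfer outcomes from fragment spin densities.

Each quantum-chemistry snapshot of the Q_o-site reports, after geometry
optimization, a Mulliken-style local spin density per molecular fragment
(the bound O2, the semiquinone head group SQ, the four atoms of the Rieske
Fe2S2 cluster, nearby residues and waters) plus the total energy.  In its
triplet ground state O2 carries a spin density of ±2; when it has accepted
an electron and become superoxide, the magnitude drops to ±1.  That
dichotomy classifies each snapshot as "no electron transfer" or
"transferred".  For transferred snapshots the donor is identified from the
change in spin density relative to the mean over no-transfer snapshots:
the compensating spin change sits either on the semiquinone (model I,
Q^.- + O2 -> Q + O2^.-) or distributed over the Fe2S2 cluster (model II,
Fe2S2^- + O2 -> Fe2S2 + O2^.-).  Snapshots whose total energy falls far
from their group's median are flagged as outliers (these typically involve
unrelated stray electron transfers).
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AnomalousSpinError,
    InsufficientReferenceError,
    UnattributableError,
)

logger = logging.getLogger(__name__)

SpinState = Literal["up", "down"]
Label = Literal["no_ET", "model_I", "model_II", "outlier"]

#: Fragments forming the iron-sulfur donor pool of model II.
CLUSTER_FRAGMENTS: tuple[str, ...] = ("Fe1", "Fe2", "S1", "S2")
#: Fragment forming the semiquinone donor pool of model I.
SQ_FRAGMENT = "SQ"
#: Midpoint between the observed |spin| = 2 (triplet O2) and |spin| = 1
#: (superoxide) outcomes.
DEFAULT_SPIN_THRESHOLD = 1.5
#: Below this |spin| the record is not interpretable as either outcome.
ANOMALY_FLOOR = 0.5
#: Default energy-outlier cut from the group median, kcal/mol (roughly
#: 3-4 within-class standard deviations).
DEFAULT_OUTLIER_THRESHOLD = 50.0
#: Minimum summed |delta s| a donor pool must carry to be credited.
MIN_POOL_DELTA = 0.5


@dataclass
class FragmentSpinRecord:
    """One QC snapshot: per-fragment spin densities and total energy."""

    snapshot_id: str
    o2_spin_state: SpinState
    spins: dict[str, float]
    total_energy: float  # kcal/mol
    converged: bool = True

    def __post_init__(self) -> None:
        if "O2" not in self.spins:
            raise ValueError(f"record {self.snapshot_id}: O2 fragment missing")
        if self.converged and not math.isfinite(self.total_energy):
            raise ValueError(
                f"record {self.snapshot_id}: non-finite energy on a converged record"
            )


@dataclass
class EtClassification:
    """Outcome label and, for transfers, the donor attribution."""

    snapshot_id: str
    label: Label
    donor_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label in ("no_ET", "outlier") and self.donor_weights:
            raise ValueError("donor_weights must be empty for non-transfer labels")
        if self.donor_weights:
            total = sum(self.donor_weights.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"donor weights sum to {total}, expected 1")


@dataclass
class ClassStat:
    n: int
    mean_rel: float | None  # kcal/mol, relative to the no-transfer mean
    sd: float | None  # sample (n-1) standard deviation, kcal/mol


@dataclass
class ClassEnergyStats:
    """Per-class snapshot counts and energy statistics.

    Energies are reported relative to the mean energy of the no-transfer
    class, whose ``mean_rel`` is therefore exactly 0.  Outliers carry a
    count only.
    """

    classes: dict[str, ClassStat]

    @property
    def total(self) -> int:
        return sum(s.n for s in self.classes.values())


def classify_o2_transfer(
    record: FragmentSpinRecord, threshold: float = DEFAULT_SPIN_THRESHOLD
) -> Literal["no_ET", "transferred"]:
    """Classify one snapshot from the magnitude of the O2 spin density.

    |s| above `threshold` means the triplet survived (no transfer); |s|
    between the anomaly floor and the threshold means O2 accepted an
    electron.  The sign must agree with the prepared O2 spin orientation.

    Raises
    ------
    AnomalousSpinError
        If |s| < 0.5 or the sign contradicts ``o2_spin_state``.  Callers
        typically route such records to the outlier bin.
    """
    if not record.converged:
        raise ValueError(f"record {record.snapshot_id} is unconverged")
    s = record.spins["O2"]
    expected_sign = 1.0 if record.o2_spin_state == "up" else -1.0
    if abs(s) < ANOMALY_FLOOR:
        raise AnomalousSpinError(
            f"{record.snapshot_id}: |s(O2)| = {abs(s):.3f} below {ANOMALY_FLOOR}"
        )
    if s * expected_sign <= 0:
        raise AnomalousSpinError(
            f"{record.snapshot_id}: s(O2) = {s:+.3f} contradicts spin-"
            f"{record.o2_spin_state} preparation"
        )
    return "no_ET" if abs(s) > threshold else "transferred"


def reference_mean_spins(
    records: Sequence[FragmentSpinRecord],
) -> dict[str, float]:
    """Per-fragment mean spin density over the no-transfer snapshots."""
    if not records:
        raise InsufficientReferenceError("no no_ET records to average")
    fragments = set(records[0].spins)
    for r in records[1:]:
        if set(r.spins) != fragments:
            raise ValueError(
                f"record {r.snapshot_id} has a different fragment set"
            )
    return {
        f: float(np.mean([r.spins[f] for r in records])) for f in sorted(fragments)
    }


def delta_spin(
    record: FragmentSpinRecord, reference: Mapping[str, float]
) -> dict[str, float]:
    """Spin-density change of one snapshot relative to the reference mean."""
    if set(record.spins) != set(reference):
        raise ValueError(
            f"record {record.snapshot_id}: fragment set differs from reference"
        )
    return {f: record.spins[f] - reference[f] for f in record.spins}


def attribute_donor(
    delta: Mapping[str, float],
    o2_spin_state: SpinState,
    min_pool_delta: float = MIN_POOL_DELTA,
) -> tuple[Literal["model_I", "model_II"], dict[str, float]]:
    """Attribute the transferred electron to semiquinone or the Fe2S2 pool.

    The winning pool is the one with the larger summed |delta s|; weights
    are the normalized |delta s| within that pool.  Exact ties go to
    model II (deterministic, documented tie-break).
    """
    sq_total = abs(delta.get(SQ_FRAGMENT, 0.0))
    cluster = {f: abs(delta[f]) for f in CLUSTER_FRAGMENTS if f in delta}
    cluster_total = sum(cluster.values())
    if max(sq_total, cluster_total) < min_pool_delta:
        raise UnattributableError(
            f"summed |ds| too small: SQ {sq_total:.3f}, cluster {cluster_total:.3f}"
        )
    if cluster_total >= sq_total:
        weights = {f: v / cluster_total for f, v in cluster.items() if v > 0}
        return "model_II", weights
    return "model_I", {SQ_FRAGMENT: 1.0}


def flag_outliers(
    records: Sequence[FragmentSpinRecord],
    labels: Mapping[str, str],
    threshold: float = DEFAULT_OUTLIER_THRESHOLD,
) -> set[str]:
    """Snapshots whose energy sits > `threshold` from their group median.

    Groups are formed by (O2 spin orientation, label); the median makes the
    rule robust to the outliers themselves.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    groups: dict[tuple[str, str], list[FragmentSpinRecord]] = defaultdict(list)
    for r in records:
        if r.snapshot_id in labels:
            groups[(r.o2_spin_state, labels[r.snapshot_id])].append(r)
    flagged: set[str] = set()
    for members in groups.values():
        med = float(np.median([r.total_energy for r in members]))
        for r in members:
            if abs(r.total_energy - med) > threshold:
                flagged.add(r.snapshot_id)
    return flagged


def classify_records(
    records: Iterable[FragmentSpinRecord],
    spin_threshold: float = DEFAULT_SPIN_THRESHOLD,
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD,
) -> list[EtClassification]:
    """Full classification chain for an ensemble of snapshots.

    Unconverged records are dropped (with a logged count).  Records are
    split by O2 spin magnitude, the donor is attributed for the transferred
    records against the no-transfer reference means, and energy outliers
    are then flagged within (orientation, label) groups — the label-wise
    grouping keeps the median rule meaningful when the transfer classes
    sit at different energies.  Anomalous-spin and unattributable records
    go to the outlier bin directly.
    """
    records = list(records)
    kept = [r for r in records if r.converged]
    if len(kept) < len(records):
        logger.info(
            "dropped %d unconverged of %d records", len(records) - len(kept), len(records)
        )

    prelim: dict[str, str] = {}
    for r in kept:
        try:
            prelim[r.snapshot_id] = classify_o2_transfer(r, spin_threshold)
        except AnomalousSpinError:
            prelim[r.snapshot_id] = "outlier"

    by_state: dict[SpinState, list[FragmentSpinRecord]] = defaultdict(list)
    for r in kept:
        if prelim[r.snapshot_id] == "no_ET":
            by_state[r.o2_spin_state].append(r)
    references = {
        state: reference_mean_spins(recs) for state, recs in by_state.items() if recs
    }

    labels: dict[str, str] = {}
    weights_of: dict[str, dict[str, float]] = {}
    for r in kept:
        sid = r.snapshot_id
        if prelim[sid] != "transferred":
            labels[sid] = prelim[sid]
            continue
        ref = references.get(r.o2_spin_state)
        if ref is None:
            raise InsufficientReferenceError(
                f"no no_ET reference for spin-{r.o2_spin_state} snapshots"
            )
        try:
            label, weights = attribute_donor(delta_spin(r, ref), r.o2_spin_state)
            labels[sid], weights_of[sid] = label, weights
        except UnattributableError:
            labels[sid] = "outlier"

    flagged = flag_outliers(
        [r for r in kept if labels[r.snapshot_id] != "outlier"],
        labels,
        outlier_threshold,
    )
    out: list[EtClassification] = []
    for r in kept:
        sid = r.snapshot_id
        label = "outlier" if sid in flagged else labels[sid]
        weights = weights_of.get(sid, {}) if label in ("model_I", "model_II") else {}
        out.append(EtClassification(sid, label, weights))
    return out


def class_energy_stats(
    records: Sequence[FragmentSpinRecord],
    classifications: Sequence[EtClassification],
) -> ClassEnergyStats:
    """Per-class N, mean energy relative to the no-transfer mean, and sd.

    The no-transfer class's relative mean is 0 by construction; classes
    with a single member report no sd; outliers report N only.
    """
    label_of = {c.snapshot_id: c.label for c in classifications}
    energies: dict[str, list[float]] = defaultdict(list)
    for r in records:
        if r.snapshot_id in label_of:
            energies[label_of[r.snapshot_id]].append(r.total_energy)
    if len(energies.get("no_ET", [])) < 2:
        raise InsufficientReferenceError("need >= 2 no_ET records for reference mean")
    e0 = float(np.mean(energies["no_ET"]))
    classes: dict[str, ClassStat] = {}
    for label, es in energies.items():
        n = len(es)
        if label == "outlier":
            classes[label] = ClassStat(n, None, None)
            continue
        mean_rel = 0.0 if label == "no_ET" else float(np.mean(es) - e0)
        sd = float(np.std(es, ddof=1)) if n >= 2 else None
        classes[label] = ClassStat(n, mean_rel, sd)
    return ClassEnergyStats(classes)


@dataclass
class GaussianClassFit:
    mean: float
    sd: float
    degenerate: bool = False


def gaussian_class_fit(stats: ClassEnergyStats) -> dict[str, GaussianClassFit]:
    """Moment-matched normal density parameters per class (no free fit).

    Classes without a defined sd (N < 2, outliers) are rejected; an sd of
    zero is returned flagged as a degenerate spike.
    """
    fits: dict[str, GaussianClassFit] = {}
    for label, st in stats.classes.items():
        if label == "outlier":
            continue
        if st.n < 2 or st.sd is None or st.mean_rel is None:
            raise ValueError(f"class {label}: N = {st.n} < 2, no density fit")
        if st.sd == 0:
            warnings.warn(f"class {label}: zero sd, degenerate density")
            fits[label] = GaussianClassFit(st.mean_rel, 0.0, degenerate=True)
        else:
            fits[label] = GaussianClassFit(st.mean_rel, st.sd)
    if not fits:
        raise ValueError("no classes eligible for a density fit")
    return fits


# ---------------------------------------------------------------------------
# CSV I/O: one row per (snapshot, fragment)

CSV_COLUMNS = [
    "snapshot_id",
    "o2_spin_state",
    "fragment",
    "spin",
    "total_energy_kcal_mol",
    "converged",
]


def read_spin_table(path) -> list[FragmentSpinRecord]:
    """Read snapshots from the long-format CSV (one row per fragment)."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spin table missing columns: {sorted(missing)}")
    records = []
    for (sid, state, energy, conv), grp in df.groupby(
        ["snapshot_id", "o2_spin_state", "total_energy_kcal_mol", "converged"],
        sort=False,
    ):
        spins = dict(zip(grp["fragment"], grp["spin"].astype(float)))
        records.append(
            FragmentSpinRecord(str(sid), state, spins, float(energy), bool(conv))
        )
    return records


def write_spin_table(records: Sequence[FragmentSpinRecord], path) -> None:
    rows = [
        {
            "snapshot_id": r.snapshot_id,
            "o2_spin_state": r.o2_spin_state,
            "fragment": f,
            "spin": s,
            "total_energy_kcal_mol": r.total_energy,
            "converged": r.converged,
        }
        for r in records
        for f, s in r.spins.items()
    ]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def write_classifications(classifications: Sequence[EtClassification], path) -> None:
    rows = [
        {
            "snapshot_id": c.snapshot_id,
            "label": c.label,
            "donor_weights": ";".join(
                f"{f}:{w:.6f}" for f, w in sorted(c.donor_weights.items())
            ),
        }
        for c in classifications
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
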