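"""Drop encapsulation statistics and sorter decision logic.

Simulates the dripping-regime encapsulation of aggregates into millimetric
drops (Poisson occupancy with mean λ = C·Vd), the per-drop deflection
decision (with co-encapsulation mitigation), multi-step re-sorting of the
waste vial, and the resulting population statistics (purity, yield,
median/IQR of the sorted size distribution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import ConfigurationError, InputError
from .imaging import FeatureVector, GateConfig
from .synthetic import ArrivalStream, MCAGeometry

__all__ = [
    "EncapsulationModel",
    "TimingConfig",
    "DropOccupancy",
    "DecisionPolicy",
    "StepResult",
    "SortResult",
    "occupancy_pmf",
    "encapsulate",
    "decide",
    "gate_size",
    "run_sort",
    "distribution_summary",
    "event_spectrum",
    "actuation_schedule",
    "projected_diameter",
    "population_frame",
]


@dataclass
class EncapsulationModel:
    """Mean drop occupancy λ, optionally derived from C (per mL) × Vd (µL)."""

    lam: Optional[float] = None
    C_per_mL: Optional[float] = None
    Vd_uL: float = 50.0

    def __post_init__(self) -> None:
        if self.lam is None:
            if self.C_per_mL is None:
                raise ConfigurationError("provide lam or C_per_mL")
            self.lam = self.C_per_mL * self.Vd_uL / 1000.0
        elif self.C_per_mL is not None:
            implied = self.C_per_mL * self.Vd_uL / 1000.0
            if not math.isclose(self.lam, implied, rel_tol=1e-6):
                raise ConfigurationError(
                    f"lam={self.lam} inconsistent with C*Vd={implied}"
                )
        if self.lam < 0:
            raise ConfigurationError("lam must be >= 0")


@dataclass
class TimingConfig:
    """Drop production timing: frequency fd, period Td and actuation window."""

    fd: float = 3.8
    actuation_factor: float = 1.5
    detection_lead: float = 0.01

    def __post_init__(self) -> None:
        if self.fd <= 0:
            raise ConfigurationError("fd must be positive")
        if self.actuation_factor <= 1:
            raise ConfigurationError("actuation window must exceed one drop period")

    @property
    def Td(self) -> float:
        return 1.0 / self.fd

    @property
    def actuation_window(self) -> float:
        return self.actuation_factor * self.Td


@dataclass
class DropOccupancy:
    """One drop: the aggregates it contains and their detection labels."""

    drop_id: int
    mca_ids: List[int] = field(default_factory=list)
    detect_times: List[float] = field(default_factory=list)
    labels: List[str] = field(default_factory=list)

    @property
    def Ns(self) -> int:
        return len(self.mca_ids)


@dataclass
class DecisionPolicy:
    """Deflection rule for multi-occupancy drops.

    strict: any drop with two or more aggregates is never deflected.
    lenient: a multi-occupancy drop is deflected only if every aggregate in
    it is classified as a target (a single waste object vetoes the drop).
    Empty drops are never deflected under either mode.
    """

    mode: str = "lenient"

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "lenient"):
            raise ConfigurationError("mode must be 'strict' or 'lenient'")


@dataclass
class StepResult:
    """Counts for one sorting step."""

    step: int
    n_in: int
    n_drops: int
    n_sorted_targets: int
    n_sorted_waste: int
    purity: Optional[float]
    cumulative_purity: Optional[float]
    cumulative_yield: float


@dataclass
class SortResult:
    """Outcome of a multi-step sort: pooled vial contents and metrics."""

    steps: List[StepResult]
    sorted_ids: List[int]
    waste_ids: List[int]
    purity: Optional[float]
    yield_: float
    seed: Optional[int]


def occupancy_pmf(lam: float, n: Union[int, np.ndarray]) -> Union[float, np.ndarray]:
    """Poisson probability of finding n aggregates in one drop."""
    if lam < 0:
        raise ConfigurationError("lam must be >= 0")
    n_arr = np.asarray(n)
    if np.any(n_arr < 0) or not np.issubdtype(n_arr.dtype, np.integer):
        raise InputError("n must be a non-negative integer")
    out = _stats.poisson.pmf(n_arr, lam)
    return float(out) if np.isscalar(n) or n_arr.ndim == 0 else out


def encapsulate(
    source: Union[ArrivalStream, float],
    n_drops: Optional[int] = None,
    Td: float = 1 / 3.8,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[DropOccupancy]:
    """Assign aggregates to drops.

    From an :class:`~mcascreen.synthetic.ArrivalStream`: each arrival at time
    t falls into the pendant drop ``floor(t / Td)``.  From a mean occupancy λ
    (a float): occupancies are drawn i.i.d. Poisson(λ) for ``n_drops`` drops.
    The total number of aggregates is conserved in both paths.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(source, ArrivalStream):
        n = n_drops if n_drops is not None else max(1, math.ceil(source.duration / Td))
        drops = [DropOccupancy(drop_id=i) for i in range(n)]
        for mca_id, t in enumerate(source.timestamps):
            idx = int(t // Td)
            if idx >= n:
                continue
            drops[idx].mca_ids.append(mca_id)
            drops[idx].detect_times.append(float(t))
        return drops
    lam = float(source)
    if lam < 0:
        raise ConfigurationError("lam must be >= 0")
    if n_drops is None or n_drops < 1:
        raise ConfigurationError("n_drops must be >= 1 when drawing from lam")
    counts = rng.poisson(lam, size=n_drops)
    drops = []
    next_id = 0
    for i, c in enumerate(counts):
        ids = list(range(next_id, next_id + int(c)))
        next_id += int(c)
        drops.append(DropOccupancy(drop_id=i, mca_ids=ids))
    return drops


def decide(drop: DropOccupancy, policy: DecisionPolicy | None = None) -> bool:
    """Whether to deflect a drop given the labels of its contents.

    Empty drops and drops containing any waste object are never deflected; a
    single target is always deflected; all-target multi-occupancy drops are
    deflected only under the lenient policy.
    """
    policy = policy or DecisionPolicy()
    if drop.Ns == 0:
        return False
    if len(drop.labels) != drop.Ns:
        raise InputError("every aggregate in the drop needs a label")
    all_targets = all(lab == "target" for lab in drop.labels)
    if drop.Ns == 1:
        return all_targets
    if policy.mode == "strict":
        return False
    return all_targets


def gate_size(fv: Union[FeatureVector, float], gate: GateConfig) -> str:
    """Size gate: 'target' iff Dmin <= D <= Dmax (boundaries per config)."""
    D = fv.D if isinstance(fv, FeatureVector) else float(fv)
    if gate.inclusive:
        ok = gate.Dmin <= D <= gate.Dmax
    else:
        ok = gate.Dmin < D < gate.Dmax
    return "target" if ok else "waste"


def projected_diameter(
    a: float, b: float, rng: np.random.Generator
) -> float:
    """Measured equivalent diameter of a prolate ellipsoid at random orientation.

    The aggregate (semi-axes a >= b = b) is projected along a uniformly random
    viewing direction; the projected ellipse has semi-axes
    ``(sqrt(a² sin²ψ + b² cos²ψ), b)`` with ψ the angle between the long axis
    and the optical axis, so the apparent equivalent diameter varies between
    2b and 2√(ab).  This models the orientation dependence of the in-flow
    size measurement.
    """
    cos_psi = rng.random()  # uniform orientation: cos(psi) ~ U[0, 1]
    a_proj = math.sqrt(a**2 * (1 - cos_psi**2) + b**2 * cos_psi**2)
    return 2.0 * math.sqrt(a_proj * b)


def measure_population(
    population: pd.DataFrame, seed: Optional[int] = None, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Simulate one screening pass: measured diameter of every aggregate.

    Each aggregate is re-projected at an independent random orientation (see
    :func:`projected_diameter`), emulating the orientation dependence of an
    in-flow diameter measurement.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    return np.array(
        [projected_diameter(a, b, rng) for a, b in zip(population["a_um"], population["b_um"])]
    )


def population_frame(geometries: Sequence[MCAGeometry]) -> pd.DataFrame:
    """Tabulate a geometry population for :func:`run_sort`."""
    return pd.DataFrame(
        {
            "id": np.arange(len(geometries)),
            "kind": [g.kind for g in geometries],
            "D_um": [g.D for g in geometries],
            "a_um": [g.a for g in geometries],
            "b_um": [g.b for g in geometries],
        }
    )


def _purity(n_targets: int, n_waste: int) -> Optional[float]:
    total = n_targets + n_waste
    return n_targets / total if total else None


def run_sort(
    population: pd.DataFrame,
    gate: Optional[GateConfig] = None,
    classifier: Optional[Callable[[pd.Series, np.random.Generator], str]] = None,
    policy: DecisionPolicy | None = None,
    n_steps: int = 3,
    lam: float = 0.26,
    seed: Optional[int] = None,
    target_kind: str = "cyst",
) -> SortResult:
    """Multi-step sort of a population with waste-vial re-sorting.

    ``population`` needs columns id, kind, D_um, a_um, b_um (see
    :func:`population_frame`).  Step 1 sorts the input; each later step
    re-sorts the previous waste vial; deflected drops are pooled across
    steps, so an aggregate is selected if it is marked target once in
    ``n_steps`` attempts.

    Per-aggregate detection labels come either from a size gate (the measured
    diameter is re-drawn each step from the random-orientation projection
    model, emulating a fresh pass through the capillary) or from a
    ``classifier(row, rng) -> "target"/"waste"`` callable; with neither, the
    true phenotype (``kind == target_kind``) is used.

    True-target status for the purity/yield metrics is the size gate applied
    to the true equivalent diameter in gate mode, and ``kind == target_kind``
    otherwise.  Purity is n_targets/(n_targets+n_waste) over the pooled
    sorted vial; yield is the fraction of initial true targets recovered.
    """
    if n_steps < 1:
        raise ConfigurationError("n_steps must be >= 1")
    if lam <= 0:
        raise ConfigurationError("lam must be positive (drops must eventually fill)")
    policy = policy or DecisionPolicy()
    rng = np.random.default_rng(seed)
    if len(population) == 0:
        return SortResult(steps=[], sorted_ids=[], waste_ids=[], purity=None, yield_=0.0, seed=seed)

    pop = population.reset_index(drop=True)
    if gate is not None:
        true_target = np.array([gate_size(d, gate) == "target" for d in pop["D_um"]])
    else:
        true_target = (pop["kind"] == target_kind).to_numpy()
    n_targets_initial = int(true_target.sum())

    current = list(pop.index)
    sorted_pool: List[int] = []
    steps: List[StepResult] = []
    for step in range(1, n_steps + 1):
        if not current:
            break
        order = rng.permutation(len(current))
        shuffled = [current[i] for i in order]
        # enough drops to hold everyone under Poisson occupancy
        step_sorted: List[int] = []
        step_waste: List[int] = []
        pos = 0
        drop_id = 0
        while pos < len(shuffled):
            ns = int(rng.poisson(lam))
            members = shuffled[pos : pos + ns]
            pos += ns
            if not members:
                drop_id += 1
                continue
            labels = []
            for idx in members:
                row = pop.loc[idx]
                if gate is not None:
                    d_meas = projected_diameter(row["a_um"], row["b_um"], rng)
                    labels.append(gate_size(d_meas, gate))
                elif classifier is not None:
                    labels.append(classifier(row, rng))
                else:
                    labels.append("target" if row["kind"] == target_kind else "waste")
            drop = DropOccupancy(drop_id=drop_id, mca_ids=members, labels=labels)
            if decide(drop, policy):
                step_sorted.extend(members)
            else:
                step_waste.extend(members)
            drop_id += 1
        sorted_pool.extend(step_sorted)
        nt = int(true_target[step_sorted].sum()) if step_sorted else 0
        nw = len(step_sorted) - nt
        cum_t = int(true_target[sorted_pool].sum()) if sorted_pool else 0
        cum_w = len(sorted_pool) - cum_t
        steps.append(
            StepResult(
                step=step,
                n_in=len(current),
                n_drops=drop_id,
                n_sorted_targets=nt,
                n_sorted_waste=nw,
                purity=_purity(nt, nw),
                cumulative_purity=_purity(cum_t, cum_w),
                cumulative_yield=cum_t / n_targets_initial if n_targets_initial else 0.0,
            )
        )
        current = step_waste

    cum_t = int(true_target[sorted_pool].sum()) if sorted_pool else 0
    cum_w = len(sorted_pool) - cum_t
    return SortResult(
        steps=steps,
        sorted_ids=sorted(sorted_pool),
        waste_ids=sorted(current),
        purity=_purity(cum_t, cum_w),
        yield_=cum_t / n_targets_initial if n_targets_initial else 0.0,
        seed=seed,
    )


def distribution_summary(values: Sequence[float]) -> Tuple[float, float, int]:
    """Median and interquartile range (linear-interpolation quartiles)."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise InputError("cannot summarise an empty sample")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return float(med), float(q3 - q1), int(vals.size)


def event_spectrum(
    timestamps: Sequence[float], duration: float, bins: int = 256
) -> Tuple[np.ndarray, np.ndarray]:
    """Discrete Fourier transform of a binned event-indicator series.

    Events are histogrammed over [0, duration]; the DC component is removed
    by subtracting the mean count before the FFT; amplitudes are normalised
    by the event count.  A periodic drop-detachment train shows a sharp peak
    at the drop frequency, while Poisson aggregate arrivals give a flat
    spectrum.
    """
    ts = np.asarray(timestamps, dtype=float)
    if duration <= 0:
        raise InputError("duration must be positive")
    counts, _ = np.histogram(ts, bins=bins, range=(0.0, duration))
    series = counts - counts.mean()
    amps = np.abs(np.fft.rfft(series))
    n_events = max(ts.size, 1)
    freqs = np.fft.rfftfreq(bins, d=duration / bins)
    return freqs, amps / n_events


def actuation_schedule(
    detect_times: Sequence[float], timing: TimingConfig | None = None
) -> List[Tuple[float, float]]:
    """Acoustic-burst windows for a sequence of positive detections.

    Each detection at t opens the window
    [t + detection_lead, t + detection_lead + actuation_factor * Td];
    overlapping windows are merged.
    """
    timing = timing or TimingConfig()
    times = sorted(float(t) for t in detect_times)
    intervals: List[Tuple[float, float]] = []
    for t in times:
        start = t + timing.detection_lead
        end = start + timing.actuation_window
        if intervals and start <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], end))
        else:
            intervals.append((start, end))
    return intervals
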