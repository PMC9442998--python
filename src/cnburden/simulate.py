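"""Synthetic advanced-prostate-cancer cohort generator with known ground truth.

Emulates the statistical structure the downstream analyses assume:

* ordered accumulation of segmental copy-number events (losses first, gains
  increasingly likely as events accumulate), drawn without replacement from a
  stage-ordered catalogue (:mod:`cnburden.regions`);
* metastatic-state-dependent event loads (M1 > M0N1 > M0N0 on average);
* negative-binomial read counts over 500-kb bins at shallow coverage, with
  tumour-cellularity dilution of the copy-ratio signal;
* multi-region core biopsies sharing truncal events (early events are truncal
  in every core by construction) with private events per core;
* five time-to-event outcomes whose log-hazard is a saturating (by default
  logarithmic) function of the true index-core burden plus metastatic-state
  offsets, with administrative censoring.

Everything is deterministic given the integer master seed: per-patient random
streams are spawned from a :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeBins
from .regions import EVENT_CATALOGUE, GAIN, LOSS, STAGES, RegionEvent

STATES = ("M0N0", "M0N1", "M1low", "M1high")
OUTCOMES = ("OS", "PCSS", "FFS", "PFS", "MPFS")

#: copy state encoding: 2 diploid-equivalent neutral, 1 loss, 3 gain
NEUTRAL_STATE = 2


@dataclass
class HazardSpec:
    """Survival-time model: h(t) = baseline * exp(g(burden) + state offset).

    ``shape`` is ``"ln"`` (g = coefficient * ln(burden%)) or a float power p
    (g = coefficient * (burden%/10)**p).  ``zero_shift`` (in burden %) is
    substituted for a burden of exactly 0 under the ln shape so the log is
    defined; positive burdens are never shifted, keeping hazard ratios between
    positive burdens in closed form.
    """

    shape: str | float = "ln"
    coefficient: float = 0.8
    baseline: dict = field(default_factory=lambda: {
        "OS": 0.012, "PCSS": 0.010, "FFS": 0.030, "PFS": 0.022, "MPFS": 0.018})
    state_offsets: dict = field(default_factory=lambda: {
        "M0N0": 0.0, "M0N1": 0.25, "M1low": 0.8, "M1high": 1.1})
    zero_shift: float = 0.1

    def log_relative_hazard(self, burden_pct: float) -> float:
        b = float(burden_pct)
        if self.shape == "ln":
            b = b if b > 0 else self.zero_shift
            return self.coefficient * np.log(b)
        return self.coefficient * (b / 10.0) ** float(self.shape)


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort."""

    n_patients: int = 300
    state_mix: dict = field(default_factory=lambda: {
        "M0N0": 0.264, "M0N1": 0.197, "M1low": 0.254, "M1high": 0.285})
    event_count_by_state: dict = field(default_factory=lambda: {
        "M0N0": 9.0, "M0N1": 11.0, "M1low": 13.0, "M1high": 14.0})
    # P(event k is a gain) = min(gain_cap, gain_slope * max(0, k - gain_lag)),
    # k = events already present: the first events are losses, gains ramp up later
    gain_slope: float = 0.08
    gain_cap: float = 0.55
    gain_lag: int = 3
    depth_mean: float = 100.0        # expected reads per 500-kb bin
    dispersion: float = 0.1          # NB overdispersion: var = m + dispersion * m^2
    cores_per_patient_range: tuple = (1, 13)
    multiregion_fraction: float = 0.373   # fraction of patients with >= 2 cores
    extra_cores_mean: float = 2.2    # multi-region cores = 2 + Poisson(extra_cores_mean)
    truncal_fraction: float = 0.7    # non-early events truncal with this probability
    private_presence: float = 0.6    # P(private event present in a given core)
    cellularity_range: tuple = (0.4, 1.0)
    hazard: HazardSpec = field(default_factory=HazardSpec)
    censor_time: float = 7.0         # years of administrative censoring
    seed: int = 0

    def validate(self) -> None:
        if set(self.state_mix) != set(STATES):
            raise ValueError(f"state_mix must cover exactly {STATES}")
        total = sum(self.state_mix.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"state_mix proportions sum to {total}, expected 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")

    def gain_fraction(self, k: int) -> float:
        """Probability the (k+1)-th accumulated event is a gain.

        Monotone non-decreasing in ``k``; zero for the first ``gain_lag + 1``
        events, so low-burden tumours are loss-dominated by construction.
        """
        return min(self.gain_cap, self.gain_slope * max(0, k - self.gain_lag))

    # -- round-trippable config files -------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["cores_per_patient_range"] = list(self.cores_per_patient_range)
        d["cellularity_range"] = list(self.cellularity_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "hazard" in d and isinstance(d["hazard"], dict):
            d["hazard"] = HazardSpec(**d["hazard"])
        for key in ("cores_per_patient_range", "cellularity_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthProfile:
    """Ground-truth copy states of one tumour core."""

    patient_id: str
    core_id: int
    states: np.ndarray              # int8 per bin; 2 = neutral
    events: list                    # [(RegionEvent, truncal: bool), ...]
    cellularity: float
    bins: GenomeBins

    def _pct(self, mask_extra) -> float:
        auto = self.bins.autosomal
        return 100.0 * np.count_nonzero(mask_extra & auto) / np.count_nonzero(auto)

    @property
    def burden_pct(self) -> float:
        return self._pct(self.states != NEUTRAL_STATE)

    @property
    def loss_pct(self) -> float:
        return self._pct(self.states < NEUTRAL_STATE)

    @property
    def gain_pct(self) -> float:
        return self._pct(self.states > NEUTRAL_STATE)


@dataclass
class Cohort:
    """Everything one simulation run produces."""

    config: SimConfig
    bins: GenomeBins
    clinical: pd.DataFrame          # one row per patient
    truth: pd.DataFrame             # one row per core
    profiles: dict                  # sample_id -> TruthProfile
    counts: dict                    # sample_id -> int read-count vector


def sample_id(patient_id: str, core_id: int) -> str:
    return f"{patient_id}_C{core_id:02d}"


# ---------------------------------------------------------------------------
# event accumulation


#: Stage preference as a function of the number of events already present:
#: early events dominate the first draws, late events become accessible as
#: the tumour accumulates alterations.
_STAGE_FACTORS = {
    "early": lambda k: max(1.0 - 0.12 * k, 0.15),
    "intermediate": lambda k: min(0.35 + 0.05 * k, 1.0),
    "late": lambda k: max(0.12 * (k - 3), 0.05),
}


def draw_patient_events(config: SimConfig, state: str, rng: np.random.Generator,
                        catalogue=EVENT_CATALOGUE) -> list[RegionEvent]:
    """Draw an ordered event list for one tumour.

    The number of events is Poisson with a state-dependent mean.  Events are
    drawn without replacement; the direction of each added event is a gain
    with probability ``config.gain_fraction(k)`` (monotone non-decreasing in
    the number of events already present ``k``), and within a direction
    events are weighted by ``base_weight`` times a stage preference that
    shifts from early toward late as ``k`` grows, so low-burden tumours
    carry predominantly early losses while late events (5q21 loss, the 8q
    gains) concentrate in high-burden tumours.
    """
    if state not in STATES:
        raise ValueError(f"unknown metastatic state {state!r}")
    target = int(rng.poisson(config.event_count_by_state[state]))
    remaining = {d: [e for e in catalogue if e.direction == d] for d in (LOSS, GAIN)}
    drawn: list[RegionEvent] = []
    for k in range(target):
        want_gain = rng.random() < config.gain_fraction(k)
        order = (GAIN, LOSS) if want_gain else (LOSS, GAIN)
        event = None
        for direction in order:
            pool = remaining[direction]
            if pool:
                w = np.array([e.base_weight * _STAGE_FACTORS[e.stage](k) for e in pool])
                event = pool.pop(int(rng.choice(len(pool), p=w / w.sum())))
                break
        if event is None:
            warnings.warn(f"event catalogue exhausted after {k} of {target} events; truncating")
            break
        drawn.append(event)
    return drawn


def _states_from_events(events, bins: GenomeBins) -> np.ndarray:
    states = np.full(bins.n_bins, NEUTRAL_STATE, dtype=np.int8)
    for ev in events:
        lo, hi = ev.bin_span(bins)
        states[lo:hi] = 3 if ev.direction == GAIN else 1
    return states


def simulate_true_profile(config: SimConfig, state: str, rng: np.random.Generator,
                          bins: GenomeBins, patient_id: str = "P0000",
                          catalogue=EVENT_CATALOGUE) -> TruthProfile:
    """Single-core ground truth for one patient."""
    events = draw_patient_events(config, state, rng, catalogue)
    cellularity = rng.uniform(*config.cellularity_range)
    return TruthProfile(patient_id=patient_id, core_id=1,
                        states=_states_from_events(events, bins),
                        events=[(e, True) for e in events],
                        cellularity=cellularity, bins=bins)


def simulate_multiregion(config: SimConfig, state: str, rng: np.random.Generator,
                         bins: GenomeBins, patient_id: str = "P0000",
                         n_cores: int | None = None,
                         catalogue=EVENT_CATALOGUE) -> list[TruthProfile]:
    """Multi-core ground truth sharing truncal events.

    Early-stage events are truncal in every core by construction; other
    events are truncal with probability ``truncal_fraction``; private events
    are present in each core independently with probability
    ``private_presence``.
    """
    events = draw_patient_events(config, state, rng, catalogue)
    truncal = [ev.stage == "early" or rng.random() < config.truncal_fraction for ev in events]
    if n_cores is None:
        lo, hi = config.cores_per_patient_range
        if hi < 2 or rng.random() >= config.multiregion_fraction:
            n_cores = max(lo, 1)
        else:
            n_cores = min(hi, 2 + int(rng.poisson(config.extra_cores_mean)))
    profiles = []
    for core in range(1, n_cores + 1):
        present = [(ev, tr) for ev, tr in zip(events, truncal)
                   if tr or rng.random() < config.private_presence]
        profiles.append(TruthProfile(
            patient_id=patient_id, core_id=core,
            states=_states_from_events([ev for ev, _ in present], bins),
            events=present,
            cellularity=rng.uniform(*config.cellularity_range), bins=bins))
    return profiles


# ---------------------------------------------------------------------------
# read counts


def simulate_bin_counts(truth: TruthProfile, config: SimConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial shallow-coverage read counts for one core.

    The expected count of a bin with copy state ``s`` at cellularity ``c`` is
    ``depth_mean * (1 + c * (s - 2) / 2)`` — the tumour signal diluted toward
    neutral by the admixed normal cells.
    """
    if config.depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    if not (0 < truth.cellularity <= 1):
        raise ValueError("cellularity must be in (0, 1]")
    r = 1.0 + truth.cellularity * (truth.states.astype(float) - NEUTRAL_STATE) / 2.0
    mean = config.depth_mean * r
    if config.dispersion <= 1e-12:
        return rng.poisson(mean).astype(np.int64)
    size = 1.0 / config.dispersion
    return rng.negative_binomial(size, size / (size + mean)).astype(np.int64)


# ---------------------------------------------------------------------------
# survival


def simulate_survival(burden_pct: float, state: str, hazard: HazardSpec,
                      censor_time: float, rng: np.random.Generator) -> dict:
    """(time, event) per outcome from an exponential model with censoring."""
    if burden_pct < 0:
        raise ValueError("burden must be >= 0")
    g = hazard.log_relative_hazard(burden_pct) + hazard.state_offsets[state]
    out = {}
    for oc in OUTCOMES:
        rate = hazard.baseline[oc] * np.exp(g)
        t = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        out[oc] = (float(min(t, censor_time)), int(t <= censor_time))
    return out


# ---------------------------------------------------------------------------
# clinical covariates

_GG_PROBS = {
    "M0N0": (0.05, 0.12, 0.18, 0.20, 0.45),
    "M0N1": (0.03, 0.08, 0.15, 0.19, 0.55),
    "M1low": (0.01, 0.05, 0.12, 0.17, 0.65),
    "M1high": (0.01, 0.03, 0.09, 0.15, 0.72),
}


def _draw_clinical(state: str, rng: np.random.Generator) -> dict:
    is_m1 = state.startswith("M1")
    age = float(np.clip(rng.normal(67, 7), 45, 85))
    psa = float(np.exp(rng.normal(3.0 + (0.6 if is_m1 else 0.0), 1.0)))
    gg = int(rng.choice(5, p=_GG_PROBS[state])) + 1
    return {"age": age, "psa": psa, "grading_group": gg}


# ---------------------------------------------------------------------------
# cohort orchestrator


def simulate_cohort(config: SimConfig, bins: GenomeBins | None = None) -> Cohort:
    """Full cohort: truth profiles, bin counts, clinical table with outcomes.

    Deterministic given ``config.seed``; each patient gets an independent
    spawned random stream.  The index core is the highest-cellularity core
    (ties broken toward the lowest core id).
    """
    config.validate()
    if bins is None:
        bins = GenomeBins.grch37()
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(config.n_patients + 1)
    rng0 = np.random.default_rng(streams[0])
    probs = np.array([config.state_mix[s] for s in STATES])
    patient_states = [STATES[i] for i in rng0.choice(len(STATES), size=config.n_patients,
                                                     p=probs / probs.sum())]
    clinical_rows, truth_rows = [], []
    profiles, counts = {}, {}
    for i, state in enumerate(patient_states):
        rng = np.random.default_rng(streams[i + 1])
        pid = f"P{i:04d}"
        cores = simulate_multiregion(config, state, rng, bins, patient_id=pid)
        # index core: highest cellularity, tie -> lowest core id
        index_core = max(cores, key=lambda c: (c.cellularity, -c.core_id)).core_id
        for core in cores:
            sid = sample_id(pid, core.core_id)
            profiles[sid] = core
            counts[sid] = simulate_bin_counts(core, config, rng)
            truth_rows.append({
                "patient_id": pid, "core_id": core.core_id, "sample_id": sid,
                "is_index": core.core_id == index_core,
                "cellularity": core.cellularity, "n_events": len(core.events),
                "true_burden": core.burden_pct, "true_loss": core.loss_pct,
                "true_gain": core.gain_pct,
            })
        index_truth = next(c for c in cores if c.core_id == index_core)
        row = {"patient_id": pid, "state": state, "n_cores": len(cores),
               "index_core": index_core,
               "cellularity": round(index_truth.cellularity * 100, 1)}
        row.update(_draw_clinical(state, rng))
        surv = simulate_survival(index_truth.burden_pct, state, config.hazard,
                                 config.censor_time, rng)
        for oc, (t, e) in surv.items():
            row[f"{oc}_time"], row[f"{oc}_event"] = t, e
        clinical_rows.append(row)
    return Cohort(config=config, bins=bins,
                  clinical=pd.DataFrame(clinical_rows),
                  truth=pd.DataFrame(truth_rows),
                  profiles=profiles, counts=counts)
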