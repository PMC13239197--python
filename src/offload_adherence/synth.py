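"""Synthetic multi-monitor adherence studies with exact ground truth.

Emulates the validation study's two phases for any number of subjects:

* an **in-lab session** — a scripted sequence of daily-living activities
  (three walking speeds, sitting, bending, lying, with unlogged standing
  between them), performed first with both devices doffed (*device-off*)
  and then worn (*device-on*), with an investigator log of every activity;
* a **24-h community day** — a bout-structured free-living day in which
  the subject alternates between wearing the RCW alone, the lift alone or
  both, and keeps a (noisy) don/doff diary.

Device-monitor variance is drawn from truncated lognormal bands that
depend on wear state and activity: a low band while worn during standing,
a high band while worn during walking, a near-zero band while worn but
sedentary, and exactly zero while doffed except for occasional handling
"spikes" (someone moving the doffed device).  The default bands are
strictly separable, which is what the in-lab validation of the threshold
algorithm implies about real devices.  Every output is a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    DEVICE_ROLES,
    DiaryInterval,
    EpochTable,
    InvestigatorLogEntry,
    build_epoch_table,
    normalize_diary,
)


class ConfigError(ValueError):
    """Scenario configuration violates its invariants."""


@dataclass(frozen=True)
class VarianceBand:
    """Truncated lognormal distribution for per-axis epoch variation.

    ``median`` and ``sigma`` parameterize the underlying lognormal; samples
    are restricted to [lo, hi] by inverse-CDF truncation, so band supports
    can be made strictly disjoint.
    """

    lo: float
    hi: float
    median: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0 <= self.lo < self.hi:
            raise ConfigError(f"need 0 <= lo < hi in {self}")
        if self.median <= 0 or self.sigma <= 0:
            raise ConfigError(f"need positive median and sigma in {self}")

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        dist = stats.lognorm(s=self.sigma, scale=self.median)
        u = rng.uniform(dist.cdf(self.lo), dist.cdf(self.hi), size=size)
        return np.clip(dist.ppf(u), self.lo, self.hi)


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic study; defaults are the study conditions.

    High-noise subjects (the last ``n_high_noise_subjects`` indices) model
    participants whose doffed devices were repeatedly moved by the
    investigator during the lab session, inflating their device-off spike
    rate; they behave normally in the community day.
    """

    n_subjects: int = 30
    seed: int = 0
    epoch_length: float = 15.0

    # device-variance bands per (wear-state, activity)
    standing_band: VarianceBand = field(
        default_factory=lambda: VarianceBand(0.05, 0.9, 0.30, 0.5)
    )
    walking_band: VarianceBand = field(
        default_factory=lambda: VarianceBand(1.5, 6.0, 2.8, 0.4)
    )
    sedentary_band: VarianceBand = field(
        default_factory=lambda: VarianceBand(0.001, 0.3, 0.02, 1.0)
    )
    allow_overlap: bool = False

    # doffed-device artifacts: a handled device moves like a worn one, so
    # spike magnitudes are a mixture of the standing- and walking-band laws
    p_spike: float = 0.01
    p_spike_high: float = 0.8
    n_high_noise_subjects: int = 3
    handling_p_spike: float = 0.5
    spike_walklike_p: float = 0.3

    # gait
    cadence: dict = field(
        default_factory=lambda: {"walk_habitual": 27.0, "walk_fast": 33.0, "walk_slow": 20.0}
    )
    cadence_subject_sd: float = 2.0
    cadence_epoch_sd: float = 1.5

    # community day structure
    awake_epochs: int = 3840  # 16 h at 15 s
    sleep_epochs: int = 1920  # 8 h
    activity_level_sigma: float = 0.5
    walk_weight: float = 0.15
    stand_weight: float = 0.22
    lie_weight: float = 0.05
    bout_mean_epochs: dict = field(
        default_factory=lambda: {"walk": 8.0, "stand": 6.0, "sit": 25.0, "lie": 20.0}
    )
    wear_segment_epochs: tuple[int, int] = (60, 160)  # 15–40 min per configuration

    # diary noise
    diary_jitter_sd_s: float = 300.0
    diary_omit_p: float = 0.05

    inlab_start: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2024-03-04 09:00:00"))
    community_start: pd.Timestamp = field(
        default_factory=lambda: pd.Timestamp("2024-03-04 12:00:00")
    )

    def __post_init__(self) -> None:
        for name in ("p_spike", "p_spike_high", "handling_p_spike", "diary_omit_p"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.n_high_noise_subjects < 0:
            raise ConfigError("n_high_noise_subjects must be >= 0")
        if self.standing_band.hi >= self.walking_band.lo and not self.allow_overlap:
            raise ConfigError(
                "standing and walking variance bands overlap; "
                "set allow_overlap=True for overlap stress scenarios"
            )
        if self.diary_jitter_sd_s < 0:
            raise ConfigError("diary_jitter_sd_s must be >= 0")

    def overlapping(self) -> "ScenarioConfig":
        """Variant whose standing band overlaps the walking band (stress mode)."""
        return replace(
            self,
            standing_band=VarianceBand(0.05, 2.0, 0.5, 0.6),
            allow_overlap=True,
        )

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    def is_high_noise(self, subject_index: int) -> bool:
        # the last k subjects; k clamps to the cohort size for tiny studies
        k = min(self.n_high_noise_subjects, self.n_subjects)
        return subject_index >= self.n_subjects - k


@dataclass
class GroundTruth:
    """Exact per-epoch and per-device truth for one generated subject."""

    activity: np.ndarray  # per-epoch label
    worn: dict[str, np.ndarray]  # device -> per-epoch bool
    wear_intervals: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]]
    true_adherent_steps: dict[str, int]
    true_adherent_standing_s: dict[str, float]
    total_steps: int
    total_standing_s: float


@dataclass
class InLabSession:
    subject_id: str
    thigh: EpochTable
    devices: dict[str, EpochTable]
    log: list[InvestigatorLogEntry]
    truth: GroundTruth


@dataclass
class CommunityDay:
    subject_id: str
    thigh: EpochTable
    devices: dict[str, EpochTable]
    diary: list[DiaryInterval]
    truth: GroundTruth


WALK_LABELS = ("walk_habitual", "walk_fast", "walk_slow", "walk")
STANDING_LABELS = ("stand", "bend")


def _subject_rng(config: ScenarioConfig, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        [int(config.seed) % (2**31), int(subject_index), int(stream)]
    )


def _thigh_frame(
    config: ScenarioConfig,
    start: pd.Timestamp,
    activity: np.ndarray,
    rng: np.random.Generator,
    cadence_offset: float,
) -> pd.DataFrame:
    n = len(activity)
    L = config.epoch_length
    starts = pd.date_range(start, periods=n, freq=pd.Timedelta(seconds=L))
    walking = np.isin(activity, WALK_LABELS)
    standing = np.isin(activity, STANDING_LABELS)
    steps = np.zeros(n, dtype=int)
    for label in WALK_LABELS:
        mask = activity == label
        if not mask.any():
            continue
        base = config.cadence.get(label, config.cadence["walk_habitual"])
        steps[mask] = np.clip(
            np.round(rng.normal(base + cadence_offset, config.cadence_epoch_sd, mask.sum())),
            1,
            None,
        ).astype(int)
    return pd.DataFrame(
        {
            "epoch_start": starts,
            "steps": steps,
            "walking_time_s": np.where(walking, L, 0.0),
            "upright_time_s": np.where(walking | standing, L, 0.0),
        }
    )


def _device_frame(
    config: ScenarioConfig,
    thigh: pd.DataFrame,
    activity: np.ndarray,
    worn: np.ndarray,
    rng: np.random.Generator,
    p_spike: float,
    handling: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-epoch axis variations plus synthetic VANE output for one device."""
    n = len(activity)
    axes = np.zeros((n, 3))
    walking = np.isin(activity, WALK_LABELS)
    standing = np.isin(activity, STANDING_LABELS)

    for mask, band in (
        (worn & walking, config.walking_band),
        (worn & standing, config.standing_band),
        (worn & ~walking & ~standing, config.sedentary_band),
    ):
        if mask.any():
            axes[mask] = band.sample(rng, (int(mask.sum()), 3))

    p = np.where(worn, 0.0, p_spike)
    if handling is not None:
        p = np.where(handling & ~worn, config.handling_p_spike, p)
    spikes = rng.uniform(size=n) < p
    if spikes.any():
        m = int(spikes.sum())
        walklike = rng.uniform(size=m) < config.spike_walklike_p
        mags = np.where(
            walklike[:, None],
            config.walking_band.sample(rng, (m, 3)),
            config.standing_band.sample(rng, (m, 3)),
        )
        axes[spikes] = mags

    L = config.epoch_length
    steps = thigh["steps"].to_numpy()
    vane_steps = np.zeros(n)
    vane_walk = np.zeros(n)
    vane_up = np.zeros(n)
    ww = worn & walking
    if ww.any():
        m = int(ww.sum())
        vane_steps[ww] = np.round(steps[ww] * rng.lognormal(np.log(0.75), 0.6, m))
        vane_walk[ww] = L * np.clip(rng.normal(0.85, 0.15, m), 0.0, 1.0)
        vane_up[ww] = np.minimum(L, vane_walk[ww] + L * np.clip(rng.normal(0.08, 0.05, m), 0.0, 1.0))
    ws = worn & standing
    if ws.any():
        m = int(ws.sum())
        vane_up[ws] = L * np.clip(rng.normal(0.9, 0.2, m), 0.0, 1.0)
    wq = worn & ~walking & ~standing
    if wq.any():
        m = int(wq.sum())
        ghost = rng.uniform(size=m) < 0.05
        vane_up[wq] = np.where(ghost, rng.uniform(1.0, 5.0, m), 0.0)

    return pd.DataFrame(
        {
            "epoch_start": thigh["epoch_start"],
            "var_x": axes[:, 0],
            "var_y": axes[:, 1],
            "var_z": axes[:, 2],
            "vane_steps": vane_steps,
            "vane_walking_time_s": vane_walk,
            "vane_upright_time_s": vane_up,
        }
    )


def _truth(
    thigh: pd.DataFrame,
    activity: np.ndarray,
    worn: dict[str, np.ndarray],
    wear_intervals: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]],
) -> GroundTruth:
    steps = thigh["steps"].to_numpy()
    standing_s = (thigh["upright_time_s"] - thigh["walking_time_s"]).to_numpy()
    return GroundTruth(
        activity=activity,
        worn=worn,
        wear_intervals=wear_intervals,
        true_adherent_steps={d: int(steps[m].sum()) for d, m in worn.items()},
        true_adherent_standing_s={d: float(standing_s[m].sum()) for d, m in worn.items()},
        total_steps=int(steps.sum()),
        total_standing_s=float(standing_s.sum()),
    )


# ---------------------------------------------------------------------------
# in-lab session

#: One condition block of the scripted lab protocol: (activity, epochs, logged).
#: Standing fillers between activities are observed by the thigh monitor but
#: not logged; walking bout lengths get a per-subject ±1 epoch tweak.
_LAB_BLOCK = [
    ("stand", 2, False),
    ("walk_habitual", 6, True),
    ("stand", 1, False),
    ("walk_fast", 6, True),
    ("stand", 1, False),
    ("walk_slow", 6, True),
    ("sit", 4, True),
    ("stand", 1, False),
    ("bend", 2, True),
    ("lie", 4, True),
    ("stand", 1, False),
]

_DON_GAP_EPOCHS = 4  # devices being donned between conditions; unlabeled


def generate_inlab_session(config: ScenarioConfig, subject_index: int) -> InLabSession:
    """Scripted lab protocol: device-off block, donning gap, device-on block."""
    rng = _subject_rng(config, subject_index, 1)
    subject_id = config.subject_ids()[subject_index]
    cadence_offset = rng.normal(0.0, config.cadence_subject_sd)

    def _block() -> list[tuple[str, int, bool]]:
        # walking bouts and standing pauses vary a little between subjects
        out = []
        for activity, length, logged in _LAB_BLOCK:
            if activity.startswith("walk"):
                length = int(length + rng.integers(-1, 2))
            elif activity == "stand":
                length = int(length + rng.integers(0, 3))
            out.append((activity, length, logged))
        return out

    blocks = {"device_off": _block(), "device_on": _block()}
    activity: list[str] = []
    segments: list[tuple[str, int, int, bool, str]] = []  # activity, i0, i1, logged, condition
    for condition in ("device_off", "device_on"):
        if condition == "device_on":
            activity.extend(["sit"] * _DON_GAP_EPOCHS)
        for act, length, logged in blocks[condition]:
            segments.append((act, len(activity), len(activity) + length, logged, condition))
            activity.extend([act] * length)
    activity = np.array(activity)
    n = len(activity)

    thigh_df = _thigh_frame(config, config.inlab_start, activity, rng, cadence_offset)

    condition = np.full(n, None, dtype=object)
    for act, i0, i1, logged, cond in segments:
        condition[i0:i1] = cond
    # standing fillers inherit the condition of the surrounding block
    for i in range(n):
        if condition[i] is None and activity[i] == "stand":
            condition[i] = condition[i - 1] if i > 0 else "device_off"

    on = condition == "device_on"
    gap = condition == None  # noqa: E711  (elementwise on object array)
    p_spike = config.p_spike_high if config.is_high_noise(subject_index) else config.p_spike

    worn: dict[str, np.ndarray] = {}
    devices: dict[str, EpochTable] = {}
    for role in DEVICE_ROLES:
        worn[role] = on.copy()
        dev_df = _device_frame(
            config, thigh_df, activity, worn[role], rng, p_spike, handling=gap
        )
        devices[role] = build_epoch_table(
            dev_df, role, monitor_id=f"{subject_id}_{role}", epoch_length=config.epoch_length
        )

    log: list[InvestigatorLogEntry] = []
    L = pd.Timedelta(seconds=config.epoch_length)
    steps = thigh_df["steps"].to_numpy()
    for act, i0, i1, logged, cond in segments:
        if not logged:
            continue
        log.append(
            InvestigatorLogEntry(
                activity=act,
                start=config.inlab_start + i0 * L,
                end=config.inlab_start + i1 * L,
                observed_steps=int(steps[i0:i1].sum()),
                condition=cond,
            )
        )

    on_ts = thigh_df["epoch_start"][on]
    wear_intervals = {
        role: [(on_ts.iloc[0], on_ts.iloc[-1] + L)] for role in DEVICE_ROLES
    }
    thigh = build_epoch_table(
        thigh_df, "thigh", monitor_id=f"{subject_id}_thigh", epoch_length=config.epoch_length
    )
    return InLabSession(
        subject_id=subject_id,
        thigh=thigh,
        devices=devices,
        log=log,
        truth=_truth(thigh.data, activity, worn, wear_intervals),
    )


# ---------------------------------------------------------------------------
# 24-h community day

_WEAR_STATES = ("rcw", "lift", "both")


def _community_activity(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Bout-structured awake activity sequence followed by a sleep block."""
    # lognormal heterogeneity, clipped to a plausible healthy-adult range
    a = float(np.clip(rng.lognormal(0.0, config.activity_level_sigma), 0.35, 2.2))
    w = {
        "walk": config.walk_weight * a,
        "stand": config.stand_weight * a,
        "lie": config.lie_weight,
    }
    w["sit"] = max(1.0 - sum(w.values()), 0.1)
    labels = list(w)
    probs = np.array([w[k] for k in labels])
    probs /= probs.sum()

    seq: list[str] = []
    while len(seq) < config.awake_epochs:
        act = labels[rng.choice(len(labels), p=probs)]
        mean = config.bout_mean_epochs[act]
        length = int(np.clip(np.round(rng.exponential(mean)), 2, 4 * mean))
        seq.extend([act] * length)
    seq = seq[: config.awake_epochs]
    seq.extend(["lie"] * config.sleep_epochs)
    return np.array(seq)


def _wear_masks(
    config: ScenarioConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Alternating rcw-only / lift-only / both segments over the awake period."""
    n = config.awake_epochs + config.sleep_epochs
    worn = {role: np.zeros(n, dtype=bool) for role in DEVICE_ROLES}
    cursor = 0
    order: list[str] = []
    while cursor < config.awake_epochs:
        if not order:
            order = list(rng.permutation(_WEAR_STATES))
        state = order.pop(0)
        length = int(rng.integers(config.wear_segment_epochs[0], config.wear_segment_epochs[1] + 1))
        end = min(cursor + length, config.awake_epochs)
        if state in ("rcw", "both"):
            worn["rcw"][cursor:end] = True
        if state in ("lift", "both"):
            worn["lift"][cursor:end] = True
        cursor = end
    return worn


def _mask_intervals(
    mask: np.ndarray, start: pd.Timestamp, epoch_length: float
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    edges = np.flatnonzero(np.diff(np.concatenate([[False], mask, [False]]).astype(int)))
    L = pd.Timedelta(seconds=epoch_length)
    return [
        (start + int(i0) * L, start + int(i1) * L)
        for i0, i1 in zip(edges[::2], edges[1::2])
    ]


def _noisy_diary(
    config: ScenarioConfig,
    truth_intervals: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]],
    horizon: tuple[pd.Timestamp, pd.Timestamp],
    rng: np.random.Generator,
) -> list[DiaryInterval]:
    out: list[DiaryInterval] = []
    for role in DEVICE_ROLES:
        for don, doff in truth_intervals[role]:
            if rng.uniform() < config.diary_omit_p:
                continue
            jd = pd.Timedelta(seconds=round(rng.normal(0.0, config.diary_jitter_sd_s)))
            jf = pd.Timedelta(seconds=round(rng.normal(0.0, config.diary_jitter_sd_s)))
            a = max(don + jd, horizon[0])
            b = min(doff + jf, horizon[1])
            if b <= a:  # jitter collapsed a short interval; keep the original span
                a, b = don, doff
            out.append(DiaryInterval(role, a, b))
    return normalize_diary(out)


def generate_community_day(config: ScenarioConfig, subject_index: int) -> CommunityDay:
    """One free-living 24-h day (5760 epochs at 15 s) with diary and truth."""
    rng = _subject_rng(config, subject_index, 2)
    subject_id = config.subject_ids()[subject_index]
    cadence_offset = rng.normal(0.0, config.cadence_subject_sd)

    activity = _community_activity(config, rng)
    thigh_df = _thigh_frame(config, config.community_start, activity, rng, cadence_offset)
    worn = _wear_masks(config, rng)

    n = len(activity)
    L = pd.Timedelta(seconds=config.epoch_length)
    horizon = (config.community_start, config.community_start + n * L)

    devices: dict[str, EpochTable] = {}
    for role in DEVICE_ROLES:
        dev_df = _device_frame(config, thigh_df, activity, worn[role], rng, config.p_spike)
        devices[role] = build_epoch_table(
            dev_df, role, monitor_id=f"{subject_id}_{role}", epoch_length=config.epoch_length
        )

    wear_intervals = {
        role: _mask_intervals(worn[role], config.community_start, config.epoch_length)
        for role in DEVICE_ROLES
    }
    diary = _noisy_diary(config, wear_intervals, horizon, rng)
    thigh = build_epoch_table(
        thigh_df, "thigh", monitor_id=f"{subject_id}_thigh", epoch_length=config.epoch_length
    )
    return CommunityDay(
        subject_id=subject_id,
        thigh=thigh,
        devices=devices,
        diary=diary,
        truth=_truth(thigh.data, activity, worn, wear_intervals),
    )


def ground_truth_summary(truth: GroundTruth) -> dict:
    """True adherent totals per device, for parameter-recovery checks."""
    return {
        "total_steps": truth.total_steps,
        "total_standing_s": truth.total_standing_s,
        "devices": {
            d: {
                "true_adherent_steps": truth.true_adherent_steps[d],
                "true_adherent_standing_s": truth.true_adherent_standing_s[d],
            }
            for d in truth.worn
        },
    }
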