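"""Water-status and leaf statistics for pot drought experiments.

The soil water constraint in a pot experiment is tracked through the
fraction of transpirable soil water (FTSW).  A calibration defines the
total transpirable soil water (TTSW) as the difference between the pot
weight at field capacity and the pot weight at the permanent wilting
point; FTSW on a given day is then the fraction of that reservoir still
available.  Two harvest rules are supported: a fixed-duration stress
(FDS), where every plant is harvested on the first day at least half of
the treated plants have dropped below FTSW 0.35, and a fixed-intensity
stress (FIS), where each treated plant (with its paired control) is
harvested on the first day its own FTSW drops below 0.1.

Leaf statistics: relative water content RWC = (Fw-Dw)/(Tw-Dw) from
fresh, turgid and dry masses, and leaf mass per area LMA = dry mass per
disc area.  The integrated transpired water ITW accumulates (1 - FTSW)
over treatment days and captures either stress intensity (FDS) or
duration (FIS).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: FDS harvest rule: day when >= 50% of treated plants are below this FTSW.
FDS_FTSW_THRESHOLD = 0.35
#: FIS harvest rule: per-plant day when FTSW first drops below this value.
FIS_FTSW_THRESHOLD = 0.1

PHENOTYPE_COLUMNS = ["ITW", "E", "gs", "OP", "RWC", "LMA", "CID", "PHe", "CoD", "TLA"]


@dataclass
class PotTimeSeries:
    """Daily pot-weight record for one plant, with the derived FTSW trajectory.

    ``day`` is the integer day index counted from the day irrigation was
    stopped; ``weight`` is the pot weight in grams at the daily weighing;
    ``water_added`` is the water restored to control plants after weighing.
    """

    plant_id: str
    is_control: bool
    day: np.ndarray
    weight: np.ndarray
    water_added: np.ndarray
    initial_weight: float
    final_weight: float
    ftsw: np.ndarray | None = field(default=None)

    @property
    def ttsw(self) -> float:
        return compute_ttsw(self.initial_weight, self.final_weight)

    def with_ftsw(self) -> "PotTimeSeries":
        self.ftsw = compute_ftsw_series(self)
        return self


def compute_ttsw(initial_weight: float, final_weight: float) -> float:
    """Total transpirable soil water: initial minus final calibration weight.

    Raises ``ValueError`` when the difference is not positive (degenerate
    calibration).
    """
    ttsw = initial_weight - final_weight
    if ttsw <= 0:
        raise ValueError(
            f"TTSW must be positive: initial {initial_weight} g <= final {final_weight} g"
        )
    return ttsw


def compute_ftsw_series(series: PotTimeSeries, allow_gaps: bool = False) -> np.ndarray:
    """FTSW per day: clamp((weight - final_weight) / TTSW, 0, 1).

    Control plants are forced to 1 every day (their transpired water is
    restored daily).  Negative raw values (pot drier than the wilting-point
    calibration) clamp to 0 with a warning.  Day gaps are rejected unless
    ``allow_gaps`` is set.
    """
    day = np.asarray(series.day)
    if len(day) > 1 and not allow_gaps:
        if not np.all(np.diff(day) == 1):
            raise ValueError(
                f"plant {series.plant_id}: non-consecutive day indices {day}"
            )
    if series.is_control:
        return np.ones(len(day))
    ttsw = series.ttsw
    raw = (np.asarray(series.weight, dtype=float) - series.final_weight) / ttsw
    if np.any(raw < -1e-12):
        logger.warning(
            "plant %s: %d FTSW value(s) below 0 clamped", series.plant_id, int((raw < 0).sum())
        )
    return np.clip(raw, 0.0, 1.0)


def compute_itw(ftsw: np.ndarray, day_range: slice | None = None) -> float:
    """Integrated transpired water: sum of (1 - FTSW) over treatment days.

    A daily rectangle sum matching the daily weighing cadence.  An empty
    range yields 0 with a warning.
    """
    values = np.asarray(ftsw, dtype=float)
    if day_range is not None:
        values = values[day_range]
    if values.size == 0:
        warnings.warn("ITW over an empty day range is 0", stacklevel=2)
        return 0.0
    return float(np.sum(1.0 - values))


def compute_rwc(Fw: float, Tw: float, Dw: float, clamp: bool = False) -> float:
    """Relative water content (Fw - Dw) / (Tw - Dw).

    Values slightly outside [0, 1] arise from measurement noise and are
    reported with a warning, clamped only when ``clamp`` is set.
    """
    if Tw <= Dw:
        raise ValueError(f"turgid mass {Tw} must exceed dry mass {Dw}")
    rwc = (Fw - Dw) / (Tw - Dw)
    if not 0.0 <= rwc <= 1.0:
        warnings.warn(f"RWC {rwc:.4f} outside [0, 1]", stacklevel=2)
        if clamp:
            rwc = min(1.0, max(0.0, rwc))
    return rwc


def compute_lma(disc_dry_mass: float, disc_area: float) -> float:
    """Leaf mass per area: disc dry mass divided by disc area (g / m^2)."""
    if disc_area <= 0:
        raise ValueError(f"disc area must be positive, got {disc_area}")
    return disc_dry_mass / disc_area


def schedule_fds_harvest(
    treated: list[PotTimeSeries], threshold: float = FDS_FTSW_THRESHOLD
) -> int:
    """Common harvest day: earliest day >= 50% of treated plants below ``threshold``.

    The 50% rule is inclusive (exactly half counts); ties resolve to the
    earlier day.  All plants of the scenario, treated and control, share
    this day.
    """
    if not treated:
        raise ValueError("FDS scheduling requires at least one treated plant")
    mats = []
    for s in treated:
        ftsw = s.ftsw if s.ftsw is not None else compute_ftsw_series(s)
        mats.append(np.asarray(ftsw))
    n_days = min(len(f) for f in mats)
    below = np.stack([f[:n_days] < threshold for f in mats])  # plants x days
    frac = below.mean(axis=0)
    hit = np.nonzero(frac >= 0.5)[0]
    if hit.size == 0:
        raise ValueError(
            "FDS criterion never met; fraction below threshold on last day "
            f"= {frac[-1]:.3f} ({int(below[:, -1].sum())}/{below.shape[0]} plants)"
        )
    return int(hit[0])


def schedule_fis_harvest(
    series: PotTimeSeries, threshold: float = FIS_FTSW_THRESHOLD
) -> int:
    """Per-plant harvest day: first day the plant's FTSW is strictly below ``threshold``."""
    ftsw = series.ftsw if series.ftsw is not None else compute_ftsw_series(series)
    hit = np.nonzero(np.asarray(ftsw) < threshold)[0]
    if hit.size == 0:
        raise ValueError(
            f"plant {series.plant_id} never crosses FTSW {threshold} "
            f"(minimum {np.min(ftsw):.3f})"
        )
    return int(hit[0])


# ---------------------------------------------------------------------------
# File-level interface


def read_pot_weights(path) -> list[PotTimeSeries]:
    """Load per-plant daily pot weights from long-format CSV.

    Expected columns: plant_id, day, weight_g, water_added_g, is_control,
    initial_weight_g, final_weight_g (the last three constant per plant).
    """
    df = pd.read_csv(path)
    out = []
    for pid, grp in df.groupby("plant_id", sort=False):
        grp = grp.sort_values("day")
        out.append(
            PotTimeSeries(
                plant_id=str(pid),
                is_control=bool(grp["is_control"].iloc[0]),
                day=grp["day"].to_numpy(),
                weight=grp["weight_g"].to_numpy(dtype=float),
                water_added=grp["water_added_g"].to_numpy(dtype=float),
                initial_weight=float(grp["initial_weight_g"].iloc[0]),
                final_weight=float(grp["final_weight_g"].iloc[0]),
            ).with_ftsw()
        )
    return out


def write_pot_weights(series_list: list[PotTimeSeries], path) -> None:
    rows = []
    for s in series_list:
        ftsw = s.ftsw if s.ftsw is not None else compute_ftsw_series(s)
        for i, d in enumerate(s.day):
            rows.append(
                {
                    "plant_id": s.plant_id,
                    "day": int(d),
                    "weight_g": s.weight[i],
                    "water_added_g": s.water_added[i],
                    "is_control": s.is_control,
                    "initial_weight_g": s.initial_weight,
                    "final_weight_g": s.final_weight,
                    "ftsw": ftsw[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
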