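"""GPS fix processing: censoring, diel and season labels, step scales.

Fixes are held in a pandas DataFrame with columns ``animal_id``,
``timestamp`` (tz-aware UTC), ``easting_km`` and ``northing_km``. Every
removal is accounted for in a :class:`FilterLedger`, whose conservation
identities are enforced rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

FIX_COLUMNS = ["animal_id", "timestamp", "easting_km", "northing_km"]

SEASONS = ("PRE", "FIRST", "SECOND", "POST")

#: inclusive date windows per season, both monitoring years
DEFAULT_SEASON_WINDOWS: tuple[tuple[date, date, str], ...] = (
    (date(2014, 8, 27), date(2014, 9, 26), "PRE"),
    (date(2015, 8, 30), date(2015, 9, 25), "PRE"),
    (date(2014, 9, 27), date(2014, 11, 18), "FIRST"),
    (date(2015, 9, 26), date(2015, 11, 17), "FIRST"),
    (date(2014, 11, 19), date(2015, 1, 10), "SECOND"),
    (date(2015, 11, 18), date(2016, 1, 9), "SECOND"),
    (date(2015, 1, 11), date(2015, 1, 31), "POST"),
    (date(2016, 1, 10), date(2016, 1, 31), "POST"),
)

FINE_MAX_KM = 0.33
RELOCATION_MIN_KM = 25.0


# ---------------------------------------------------------------------------
# Ledger
# ---------------------------------------------------------------------------


@dataclass
class FilterLedger:
    """Accounting of fix removals through the movement filter.

    ``total`` counts scale-classified movements (one per fix with an
    incoming step); the identities ``total = fine + relocation + local`` and
    ``final = local - out_of_extent`` must hold.
    """

    total: int = 0
    censored_initial: int = 0
    fine: int = 0
    relocation: int = 0
    local: int = 0
    out_of_extent: int = 0
    final: int = 0
    animals_marked: int = 0
    animals_censored: int = 0
    animals_analysed: int = 0

    @classmethod
    def from_counts(
        cls,
        total: int,
        fine: int,
        relocation: int,
        out_of_extent: int = 0,
        censored_initial: int = 0,
        animals_marked: int = 0,
        animals_censored: int = 0,
    ) -> "FilterLedger":
        """Derive the dependent counts (local, final) from the primary ones."""
        local = total - fine - relocation
        ledger = cls(
            total=total,
            censored_initial=censored_initial,
            fine=fine,
            relocation=relocation,
            local=local,
            out_of_extent=out_of_extent,
            final=local - out_of_extent,
            animals_marked=animals_marked,
            animals_censored=animals_censored,
            animals_analysed=animals_marked - animals_censored,
        )
        ledger.validate()
        return ledger

    def validate(self) -> None:
        if self.total - self.fine - self.relocation != self.local:
            raise ValueError("ledger violates total = fine + relocation + local")
        if self.local - self.out_of_extent != self.final:
            raise ValueError("ledger violates final = local - out_of_extent")
        if any(
            v < 0
            for v in (self.total, self.fine, self.relocation, self.local, self.out_of_extent, self.final)
        ):
            raise ValueError("ledger counts must be non-negative")

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_fixes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FIX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fix CSV missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    df = df.sort_values(["animal_id", "timestamp"], kind="stable").reset_index(drop=True)
    _check_fixes(df)
    return df


def write_fixes(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def _check_fixes(df: pd.DataFrame) -> None:
    if not np.isfinite(df[["easting_km", "northing_km"]].to_numpy()).all():
        raise ValueError("fix coordinates must be finite")
    dup = df.groupby("animal_id")["timestamp"].apply(lambda s: (s.diff().dt.total_seconds() <= 0).any())
    if dup.any():
        bad = dup[dup].index.tolist()
        raise ValueError(f"timestamps not strictly increasing for animal(s): {bad}")


# ---------------------------------------------------------------------------
# Censoring
# ---------------------------------------------------------------------------


def censor_initial(fixes: pd.DataFrame, days: float = 4.0) -> tuple[pd.DataFrame, dict]:
    """Drop each animal's fixes within ``days`` (as 24-h periods) of its
    first fix, to let animals recover from capture and transmitter
    attachment; animals with no fixes left are dropped and counted."""
    if fixes.empty:
        return fixes.copy(), {
            "fixes_removed": 0,
            "animals_marked": 0,
            "animals_censored": 0,
            "animals_analysed": 0,
        }
    first = fixes.groupby("animal_id")["timestamp"].transform("min")
    keep = fixes["timestamp"] >= first + timedelta(days=days)
    out = fixes[keep].reset_index(drop=True)
    marked = fixes["animal_id"].nunique()
    analysed = out["animal_id"].nunique()
    return out, {
        "fixes_removed": int((~keep).sum()),
        "animals_marked": int(marked),
        "animals_censored": int(marked - analysed),
        "animals_analysed": int(analysed),
    }


# ---------------------------------------------------------------------------
# Diel and season labels
# ---------------------------------------------------------------------------


def classify_diel(t: datetime, solar, margin_min: float = 30.0) -> str:
    """Diurnal iff t falls in [sunrise - margin, sunset + margin] (legal
    shooting time); nocturnal otherwise."""
    sunrise, sunset = solar(t)
    margin = timedelta(minutes=margin_min)
    return "diurnal" if sunrise - margin <= t <= sunset + margin else "nocturnal"


def label_diel(fixes: pd.DataFrame, solar, margin_min: float = 30.0) -> pd.DataFrame:
    out = fixes.copy()
    out["diel"] = [
        classify_diel(t.to_pydatetime(), solar, margin_min) for t in out["timestamp"]
    ]
    return out


def assign_season(
    t: datetime | date, windows: tuple[tuple[date, date, str], ...] = DEFAULT_SEASON_WINDOWS
) -> str:
    d = t.date() if isinstance(t, datetime) else t
    for start, end, label in windows:
        if start <= d <= end:
            return label
    return "out_of_window"


def label_seasons(
    fixes: pd.DataFrame, windows: tuple[tuple[date, date, str], ...] = DEFAULT_SEASON_WINDOWS
) -> pd.DataFrame:
    out = fixes.copy()
    out["season"] = [assign_season(t.to_pydatetime(), windows) for t in out["timestamp"]]
    return out


# ---------------------------------------------------------------------------
# Steps and scales
# ---------------------------------------------------------------------------


def steps_and_scales(
    fixes: pd.DataFrame,
    fine_max_km: float = FINE_MAX_KM,
    relocation_min_km: float = RELOCATION_MIN_KM,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterLedger]:
    """Consecutive-fix steps, scale classes, and retained-fix flags.

    A step is fine below ``fine_max_km``, a relocation above
    ``relocation_min_km``, local otherwise (boundaries inclusive on the local
    side). A fix is retained for the selection analysis iff its incoming step
    is local; the first fix of an animal has no incoming step and is never
    retained. Returns (steps, fixes-with-scale, ledger); the ledger's
    ``out_of_extent``/``final`` are settled later by choice-set construction.
    """
    fixes = fixes.sort_values(["animal_id", "timestamp"], kind="stable").reset_index(drop=True)
    same_animal = fixes["animal_id"].eq(fixes["animal_id"].shift())
    dx = fixes["easting_km"].diff()
    dy = fixes["northing_km"].diff()
    length = np.hypot(dx, dy).where(same_animal)

    scale = pd.Series(pd.NA, index=fixes.index, dtype="object")
    has_step = same_animal.to_numpy()
    lv = length.to_numpy()
    scale[has_step & (lv < fine_max_km)] = "fine"
    scale[has_step & (lv > relocation_min_km)] = "relocation"
    scale[has_step & (lv >= fine_max_km) & (lv <= relocation_min_km)] = "local"

    out = fixes.copy()
    out["step_km"] = length
    out["scale"] = scale
    out["retained"] = (scale == "local").to_numpy()

    steps = out.loc[has_step, ["animal_id", "timestamp", "step_km", "scale"]].copy()
    steps["from_easting_km"] = fixes["easting_km"].shift()[has_step]
    steps["from_northing_km"] = fixes["northing_km"].shift()[has_step]
    steps["to_easting_km"] = fixes["easting_km"][has_step]
    steps["to_northing_km"] = fixes["northing_km"][has_step]

    counts = scale.value_counts()
    ledger = FilterLedger.from_counts(
        total=int(has_step.sum()),
        fine=int(counts.get("fine", 0)),
        relocation=int(counts.get("relocation", 0)),
    )
    return steps, out, ledger


# ---------------------------------------------------------------------------
# Descriptive statistics (season x diel)
# ---------------------------------------------------------------------------


def round_trim(x: float, decimals: int = 2) -> str:
    """Half-even rounding then trailing-zero trimming (37.9, not 37.90)."""
    s = f"{np.round(x, decimals):.{decimals}f}"
    return s.rstrip("0").rstrip(".") if "." in s else s


def descriptive_table(fixes: pd.DataFrame) -> pd.DataFrame:
    """Per season x diel: distinct animals, fixes, mean/SD/range of fixes
    per individual. Mean is N/IDs; SD is the sample SD of per-animal counts
    (0 when only one animal)."""
    rows = []
    diel_order = ("diurnal", "nocturnal")
    for season in SEASONS:
        for diel in diel_order:
            sub = fixes[(fixes["season"] == season) & (fixes["diel"] == diel)]
            if sub.empty:
                rows.append((season, diel, 0, 0, 0.0, "0", 0.0, 0, 0))
                continue
            per_animal = sub.groupby("animal_id").size()
            ids, n = len(per_animal), len(sub)
            mean = n / ids
            sd = float(per_animal.std(ddof=1)) if ids > 1 else 0.0
            rows.append(
                (season, diel, ids, n, mean, round_trim(mean), round(sd, 2),
                 int(per_animal.min()), int(per_animal.max()))
            )
    return pd.DataFrame(
        rows,
        columns=["season", "diel", "ids", "n", "mean", "mean_display", "sd", "min", "max"],
    )
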