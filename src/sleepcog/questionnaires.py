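"""Scoring and validation of self-report sleep measures.

Four instruments are consumed as precomputed totals:

* **PSQI** — Pittsburgh Sleep Quality Index, here a three-component sum
  (0–9), each component scored 0–3.
* **AIS** — Athens Insomnia Scale total (0–24).
* **GSQS** — Groningen Sleep Quality Scale, prior night (0–14); Study 2 only.
* **Sleep diary** — nightly-average composite (0–12); Study 2 only.

Sleeper categories (good / moderate / poor) follow the published band
boundaries for each instrument; the poor band is extended to the scale's
obtainable maximum so that every in-range total is classifiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SCALE_RANGES",
    "CATEGORY_BANDS",
    "SleeperCategory",
    "ScaleValidationError",
    "validate_scales",
    "validate_table",
    "categorize_sleeper",
    "extreme_groups",
    "psqi_component_sum",
    "sleeper_category_table",
]

#: Obtainable score range per instrument (inclusive).
SCALE_RANGES: dict[str, tuple[int, int]] = {
    "psqi": (0, 9),
    "ais": (0, 24),
    "gsqs": (0, 14),
    "diary": (0, 12),
}

#: Category bands per instrument: label -> (low, high), inclusive.
#: The diary defines no poor band; scores >= 2 are "moderate".
CATEGORY_BANDS: dict[str, dict[str, tuple[int, int]]] = {
    "psqi": {"good": (0, 1), "moderate": (2, 4), "poor": (5, 9)},
    "ais": {"good": (0, 2), "moderate": (3, 6), "poor": (7, 24)},
    "gsqs": {"good": (0, 1), "moderate": (2, 7), "poor": (8, 14)},
    "diary": {"good": (0, 1), "moderate": (2, 12)},
}

#: Scales collected only in Study 2.
STUDY2_ONLY_SCALES = ("gsqs", "diary")

#: Default PSQI components making up the 0-9 sum (configurable; the trio
#: of subjective quality, latency and disturbances is the conventional
#: short form used here).
DEFAULT_PSQI_COMPONENTS = (
    "subjective_sleep_quality",
    "sleep_latency",
    "sleep_disturbances",
)


class ScaleValidationError(ValueError):
    """A sleep-scale total is out of range or present in the wrong study."""


@dataclass(frozen=True)
class SleeperCategory:
    """Sleeper category assignment derived from one instrument."""

    label: str  # "good" | "moderate" | "poor"
    scale: str  # instrument the category derives from


def _check_range(scale: str, total: float) -> None:
    lo, hi = SCALE_RANGES[scale]
    if not (lo <= total <= hi):
        raise ScaleValidationError(
            f"{scale.upper()} out of range: {total!r} not in [{lo}, {hi}]"
        )


def validate_scales(record: Mapping) -> Mapping:
    """Validate the sleep-scale totals of one participant record.

    ``record`` must carry ``study`` and whatever of ``psqi``, ``ais``,
    ``gsqs``, ``diary`` the participant has. Totals must lie within the
    obtainable ranges; GSQS and diary totals may only appear for Study-2
    participants (they were only collected there). Missing optional scales
    are tolerated for Studies 1 and 3.

    Returns the record unchanged; raises :class:`ScaleValidationError`
    naming the offending scale otherwise.
    """
    study = int(record["study"])
    for scale in SCALE_RANGES:
        value = record.get(scale) if hasattr(record, "get") else record[scale]
        if value is None or (isinstance(value, float) and pd.isna(value)):
            continue
        if scale in STUDY2_ONLY_SCALES and study != 2:
            raise ScaleValidationError(
                f"{scale.upper()} only collected in Study 2 (got study={study})"
            )
        _check_range(scale, value)
    return record


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate every row of a participant table (see :func:`validate_scales`)."""
    for idx, row in table.iterrows():
        try:
            validate_scales(row)
        except ScaleValidationError as err:
            raise ScaleValidationError(f"row {idx}: {err}") from None
    return table


def categorize_sleeper(scale: str, total: int) -> SleeperCategory:
    """Assign the good/moderate/poor sleeper category for one total."""
    if scale not in CATEGORY_BANDS:
        raise ScaleValidationError(f"unknown scale {scale!r}")
    _check_range(scale, total)
    for label, (lo, hi) in CATEGORY_BANDS[scale].items():
        if lo <= total <= hi:
            return SleeperCategory(label=label, scale=scale)
    raise ScaleValidationError(  # pragma: no cover - bands partition the range
        f"no category band covers {scale}={total}"
    )


def extreme_groups(records: pd.DataFrame | pd.Series) -> tuple[pd.Index, pd.Index]:
    """Split participants into extreme PSQI groups.

    Good sleepers score 0 or 1 on the PSQI; poor sleepers score 5 or above.
    The middle band is excluded. Returns the two row-index sets
    ``(good, poor)``.
    """
    psqi = records["psqi"] if isinstance(records, pd.DataFrame) else records
    psqi = pd.to_numeric(psqi)
    good = psqi.index[psqi <= 1]
    poor = psqi.index[psqi >= 5]
    return good, poor


def psqi_component_sum(
    components: Mapping[str, int],
    component_names: Sequence[str] = DEFAULT_PSQI_COMPONENTS,
) -> int:
    """Sum three named 0–3 PSQI component scores into the 0–9 total."""
    if len(component_names) != 3:
        raise ScaleValidationError("PSQI short total requires exactly 3 components")
    total = 0
    for name in component_names:
        try:
            value = components[name]
        except KeyError:
            raise ScaleValidationError(f"missing PSQI component {name!r}") from None
        if not (0 <= value <= 3):
            raise ScaleValidationError(
                f"PSQI component {name!r} out of range: {value!r} not in [0, 3]"
            )
        total += int(value)
    return total


def sleeper_category_table(
    table: pd.DataFrame, scales: Iterable[str] = ("psqi", "ais", "gsqs", "diary")
) -> pd.DataFrame:
    """Per-instrument descriptive summary: mean, SD and category percentages.

    Mirrors the conventional questionnaire-descriptives layout (one row per
    instrument; category columns show the percentage of non-missing
    participants in each band).
    """
    rows = []
    for scale in scales:
        if scale not in table.columns:
            continue
        values = pd.to_numeric(table[scale], errors="coerce").dropna()
        if values.empty:
            continue
        cats = values.astype(int).map(lambda v, s=scale: categorize_sleeper(s, v).label)
        pct = cats.value_counts(normalize=True) * 100.0
        rows.append(
            {
                "scale": scale,
                "n": int(values.size),
                "mean": values.mean(),
                "sd": values.std(ddof=1),
                "good_pct": float(pct.get("good", 0.0)),
                "moderate_pct": float(pct.get("moderate", 0.0)),
                "poor_pct": float(pct.get("poor", 0.0)),
            }
        )
    return pd.DataFrame(rows)
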