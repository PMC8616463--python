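"""Developmental age labels and their numeric day coding.

Eight mouse brain-development time points: embryonic days E10.5-E16.5 and
postnatal day 0.  Embryonic labels map to their literal day values; P0 is
coded as day 22 (birth at ~E19 plus the postnatal offset used throughout the
age regressions), so one regression unit is one day of development.
"""

from __future__ import annotations

AGE_LABELS: tuple[str, ...] = (
    "E10.5", "E11.5", "E12.5", "E13.5", "E14.5", "E15.5", "E16.5", "P0",
)

AGE_DAYS: dict[str, float] = {
    "E10.5": 10.5,
    "E11.5": 11.5,
    "E12.5": 12.5,
    "E13.5": 13.5,
    "E14.5": 14.5,
    "E15.5": 15.5,
    "E16.5": 16.5,
    "P0": 22.0,
}


def days_for(labels) -> list[float]:
    """Map an iterable of age labels to day values, validating each label."""
    out = []
    for lab in labels:
        if lab not in AGE_DAYS:
            raise KeyError(f"unknown age label: {lab!r}")
        out.append(AGE_DAYS[lab])
    return out
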