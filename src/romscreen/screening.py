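"""The Boolean referral rule for shoulder range-of-motion restriction.

A subject is flagged for rehabilitation referral when, with
T = normal_rom_deg * threshold_fraction (126 deg at the defaults: 70% of a
180-deg normal shoulder elevation):

    refer = (x_AA < T) and (x_AF < T) and ((x_PA < T) or (x_PF < T))

i.e. BOTH active movements (abduction AA, flexion AF) are restricted and
at least one passive movement (PA, PF) is restricted.  Inequalities are
strict; values at exactly T do not trigger referral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = ["ScreeningDecision", "ref_decision", "screen_cohort"]


@dataclass(frozen=True)
class ScreeningDecision:
    """Referral outcome for one subject's four adjusted ROM values (deg)."""

    subject_id: str
    x_AA: float
    x_AF: float
    x_PA: float
    x_PF: float
    refer: bool
    threshold_fraction: float = 0.7
    normal_rom_deg: float = 180.0


def ref_decision(
    x_AA: float,
    x_AF: float,
    x_PA: float,
    x_PF: float,
    threshold_fraction: float = 0.7,
    normal_rom_deg: float = 180.0,
) -> bool:
    """Apply the referral rule to one subject's four adjusted ROM values."""
    values = (x_AA, x_AF, x_PA, x_PF)
    if any(not math.isfinite(v) for v in values):
        raise ValueError(f"non-finite ROM value in {values}")
    if not 0 < threshold_fraction <= 1:
        raise ValueError(f"threshold_fraction must lie in (0, 1], got {threshold_fraction}")
    t = normal_rom_deg * threshold_fraction
    return (x_AA < t) and (x_AF < t) and ((x_PA < t) or (x_PF < t))


def screen_cohort(
    rom_table: Mapping[str, Mapping[str, float]] | Iterable[tuple[str, Mapping[str, float]]],
    threshold_fraction: float = 0.7,
    normal_rom_deg: float = 180.0,
) -> tuple[list[ScreeningDecision], list[str]]:
    """Screen a cohort of subjects with adjusted ROM quadruples.

    ``rom_table`` maps subject_id to a mapping with keys AA, AF, PA, PF
    (degrees).  Subjects missing any of the four movements are not
    screened; their ids are returned separately.

    Returns ``(decisions, unscreenable_subject_ids)``.
    """
    items = rom_table.items() if isinstance(rom_table, Mapping) else rom_table
    decisions: list[ScreeningDecision] = []
    unscreenable: list[str] = []
    for subject_id, roms in items:
        if any(m not in roms for m in ("AA", "AF", "PA", "PF")):
            unscreenable.append(subject_id)
            continue
        decisions.append(
            ScreeningDecision(
                subject_id=subject_id,
                x_AA=float(roms["AA"]),
                x_AF=float(roms["AF"]),
                x_PA=float(roms["PA"]),
                x_PF=float(roms["PF"]),
                refer=ref_decision(
                    roms["AA"], roms["AF"], roms["PA"], roms["PF"],
                    threshold_fraction, normal_rom_deg,
                ),
                threshold_fraction=threshold_fraction,
                normal_rom_deg=normal_rom_deg,
            )
        )
    return decisions, unscreenable
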