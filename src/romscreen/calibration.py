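"""Calibration of motion-capture angles against manual goniometry.

For each movement type and angle method, an ordinary least-squares line
maps the capture ROM (x) to the goniometric ROM (y) — goniometry being the
clinical reference scale the screening rule operates on.  Alongside slope
and intercept the fit reports the Pearson correlation r, its two-sided
p-value from the exact t statistic r*sqrt((n-2)/(1-r^2)) with n-2 degrees
of freedom, and post-hoc power from the Fisher z-transform normal
approximation:

    power = Phi( sqrt(n-3) * atanh(|r|) - z_{1-alpha/2} ).

With two angle methods tested per movement, the Bonferroni-corrected
per-test significance level at family alpha 0.05 is 0.025.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationModel",
    "fit_calibration",
    "adjust_rom",
    "bonferroni_alpha",
    "save_calibrations",
    "load_calibrations",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Least-squares line from capture ROM (deg) to goniometric ROM (deg)."""

    movement: str
    method: str
    slope: float
    intercept: float
    r: float
    p: float
    n: int
    power: float
    alpha: float = 0.025

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def correlation_power(r: float, n: int, alpha: float = 0.025) -> float:
    """Post-hoc power to detect correlation r at level alpha (Fisher z)."""
    if n <= 3:
        return 0.0
    z = math.atanh(min(abs(r), 1 - 1e-15))
    crit = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(math.sqrt(n - 3) * z - crit))


def fit_calibration(
    capture_rom,
    gonio_rom,
    movement: str,
    method: str,
    alpha: float = 0.025,
) -> CalibrationModel:
    """Fit goniometric ROM on capture ROM by ordinary least squares.

    Requires at least 3 paired samples and nonzero variance in both lists.
    """
    x = np.asarray(capture_rom, dtype=float)
    y = np.asarray(gonio_rom, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("capture and goniometry lists must be equal-length 1D")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in capture or goniometry values")
    fit = stats.linregress(x, y)
    return CalibrationModel(
        movement=movement,
        method=method,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        n=int(n),
        power=correlation_power(float(fit.rvalue), n, alpha),
        alpha=alpha,
    )


def adjust_rom(model: CalibrationModel, capture_rom_deg: float) -> float:
    """Map a capture ROM onto the goniometric scale, clamped to [0, 180]."""
    if not math.isfinite(model.slope) or not math.isfinite(model.intercept):
        raise ValueError("calibration model is degenerate")
    if not math.isfinite(capture_rom_deg):
        raise ValueError("capture ROM must be finite")
    value = model.slope * capture_rom_deg + model.intercept
    return float(min(max(value, 0.0), 180.0))


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test significance level controlling the family-wise error rate."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not 0 < family_alpha <= 1:
        raise ValueError(f"family_alpha must lie in (0, 1], got {family_alpha}")
    return family_alpha / n_tests


def save_calibrations(models: list[CalibrationModel], path: str | Path) -> None:
    data = {f"{m.movement}:{m.method}": asdict(m) for m in models}
    Path(path).write_text(json.dumps(data, indent=1) + "\n", encoding="utf-8")


def load_calibrations(path: str | Path) -> dict[tuple[str, str], CalibrationModel]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return {
        (m["movement"], m["method"]): CalibrationModel(**m) for m in data.values()
    }
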