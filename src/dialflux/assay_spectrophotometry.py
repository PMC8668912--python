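"""Spectrophotometric quantification of meropenem and the stability check.

Meropenem absorbs at 300 nm; over the working range the assay is linear, so
Beer–Lambert applies: ``A = epsilon * l * C`` with molar-free units
(``epsilon`` in absorbance·L·mg⁻¹·cm⁻¹, path length ``l`` in cm, ``C`` in
mg/L).  The extinction coefficient is instrument/batch-specific and must be
supplied by the user — no default is assumed.

The stability check operationalises "no significant change" in the container
controls (samples at 0, 2 and 4 h) as a relative range criterion
``(max - min)/mean <= tolerance``: with three single measurements a hypothesis
test has no power, so a plain tolerance convention is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .exceptions import (
    InsufficientDataError,
    InvalidInputError,
    InvalidMeasurementError,
)

__all__ = [
    "AssayParams",
    "MeasurementRecord",
    "StabilityResult",
    "PORTS",
    "absorbance_to_concentration",
    "concentration_to_absorbance",
    "stability_check",
]

#: Valid sampling ports: access line, return line, effluent line, and the
#: container control samples.
PORTS = ("AL", "RL", "EL", "CONTROL")


@dataclass(frozen=True)
class AssayParams:
    """Beer–Lambert assay configuration.

    ``extinction_coefficient`` (absorbance·L·mg⁻¹·cm⁻¹) has no default: it is
    a property of the instrument and drug batch.  ``noise_cv`` is the
    coefficient of variation of the multiplicative measurement noise used by
    the synthetic generator (2% is typical of UV spectrophotometry).
    """

    extinction_coefficient: float
    wavelength_nm: float = 300.0
    path_length_cm: float = 1.0
    noise_cv: float = 0.02

    def __post_init__(self) -> None:
        if not self.extinction_coefficient > 0:
            raise InvalidInputError(
                f"extinction_coefficient must be > 0, got {self.extinction_coefficient}"
            )
        if not self.path_length_cm > 0:
            raise InvalidInputError(
                f"path_length_cm must be > 0, got {self.path_length_cm}"
            )
        if not (0.0 <= self.noise_cv < 1.0):
            raise InvalidInputError(f"noise_cv must be in [0, 1), got {self.noise_cv}")


@dataclass(frozen=True)
class MeasurementRecord:
    """One sampled observation, bench or synthetic.

    At least one of ``absorbance``/``concentration`` must be present; when
    both are, they must agree under the assay parameters (checked by
    :meth:`check_consistency`, not at construction, since the record does not
    carry its assay).
    """

    port: str
    time_min: float
    setting_label: str
    replicate: int = 1
    absorbance: float | None = None
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.port not in PORTS:
            raise InvalidInputError(f"port must be one of {PORTS}, got {self.port!r}")
        if self.replicate < 1:
            raise InvalidInputError(f"replicate must be >= 1, got {self.replicate}")
        if self.absorbance is None and self.concentration is None:
            raise InvalidInputError(
                "at least one of absorbance/concentration must be present"
            )
        if self.absorbance is not None and self.absorbance < 0:
            raise InvalidMeasurementError(
                f"absorbance must be >= 0, got {self.absorbance}"
            )

    def check_consistency(self, assay: AssayParams, rtol: float = 1e-9) -> bool:
        """True if absorbance and concentration agree under Beer–Lambert.

        Vacuously true when only one of the two is present.
        """
        if self.absorbance is None or self.concentration is None:
            return True
        expected = concentration_to_absorbance(self.concentration, assay)
        scale = max(abs(expected), abs(self.absorbance), 1e-300)
        return abs(self.absorbance - expected) <= rtol * scale

    def resolve_concentration(self, assay: AssayParams | None = None) -> float:
        """Concentration in mg/L, converting from absorbance if needed."""
        if self.concentration is not None:
            return self.concentration
        if assay is None:
            raise InvalidInputError(
                "record carries only absorbance; assay parameters required"
            )
        return absorbance_to_concentration(self.absorbance, assay)


def concentration_to_absorbance(c: float, assay: AssayParams) -> float:
    """Beer–Lambert forward map, ``A = epsilon * l * C``."""
    if c < 0:
        raise InvalidInputError(f"concentration must be >= 0, got {c}")
    return c * assay.extinction_coefficient * assay.path_length_cm


def absorbance_to_concentration(a: float, assay: AssayParams) -> float:
    """Beer–Lambert inverse map, ``C = A / (epsilon * l)``."""
    if a < 0:
        raise InvalidMeasurementError(f"absorbance must be >= 0, got {a}")
    return a / (assay.extinction_coefficient * assay.path_length_cm)


@dataclass(frozen=True)
class StabilityResult:
    """Outcome of the control-sample stability check."""

    passed: bool
    max_relative_deviation: float
    n_controls: int
    tolerance: float


def stability_check(
    controls: Sequence[MeasurementRecord] | Iterable[MeasurementRecord],
    tolerance: float = 0.05,
    assay: AssayParams | None = None,
) -> StabilityResult:
    """Check container controls for degradation over the session.

    Computes the relative range ``(max - min)/mean`` of the control
    concentrations; passes iff it does not exceed ``tolerance``.  The
    statistic is reported either way, and is invariant to the order of the
    records.
    """
    records = list(controls)
    if len(records) < 2:
        raise InsufficientDataError(
            f"stability check needs >= 2 control records, got {len(records)}"
        )
    concs = [r.resolve_concentration(assay) for r in records]
    mean = sum(concs) / len(concs)
    if mean <= 0:
        raise InvalidInputError("control concentrations have nonpositive mean")
    deviation = (max(concs) - min(concs)) / mean
    return StabilityResult(
        passed=deviation <= tolerance,
        max_relative_deviation=deviation,
        n_controls=len(records),
        tolerance=tolerance,
    )
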