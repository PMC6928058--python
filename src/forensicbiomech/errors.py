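"""Exception hierarchy for the toolkit.

All toolkit errors derive from :class:`ForensicBiomechError` so callers can
catch everything with one clause; the subclasses mirror the failure modes of
the individual models (bad tables, degenerate mechanisms, diverging
simulations, ...).
"""

from __future__ import annotations


class ForensicBiomechError(Exception):
    """Base class for all toolkit errors."""


class DomainError(ForensicBiomechError, ValueError):
    """An input lies outside the physical domain of the model."""


class InvalidTableError(ForensicBiomechError, ValueError):
    """A proportion table is malformed or references unknown segments."""


class StructuralError(ForensicBiomechError, KeyError):
    """A mannequin lacks a segment or joint an operation requires."""


class MissingMassError(ForensicBiomechError, ValueError):
    """A geometry-only mannequin was passed to a mass-dependent operation."""


class SingularMechanismError(ForensicBiomechError, ZeroDivisionError):
    """A lever arm or contact area is zero, making the mechanism singular."""


class SimulationFailure(ForensicBiomechError, RuntimeError):
    """Forward integration produced a non-finite state.

    Carries ``last_valid_time``, the latest time at which the state was
    still finite.
    """

    def __init__(self, message: str, last_valid_time: float | None = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class NotTerminatedError(ForensicBiomechError, RuntimeError):
    """Outcome classification was requested on a non-quiescent trajectory."""
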