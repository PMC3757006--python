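"""Exception hierarchy.

All package errors derive from :class:`CardioRamanError` so callers can
catch one type at a pipeline boundary.
"""


class CardioRamanError(Exception):
    """Base class for all package errors."""


class ValidationError(CardioRamanError, ValueError):
    """An object violates one of its declared invariants."""


class SpectrumFormatError(CardioRamanError, ValueError):
    """A spectrum file cannot be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = f"{path}" if path is not None else "<stream>"
        if line is not None:
            loc += f", line {line}"
        super().__init__(f"{loc}: {message}")


class RangeError(CardioRamanError, ValueError):
    """A requested shift interval is not covered by the spectrum."""


class UndefinedRatioError(CardioRamanError, ZeroDivisionError):
    """A ratio's denominator is zero (e.g. zero I_sum or zero 1127 band)."""


class CalibrationError(CardioRamanError, ValueError):
    """The scattering-efficiency calibration could not be computed."""


class BaselineConvergenceError(CardioRamanError, RuntimeError):
    """Baseline estimation did not converge; carries iteration diagnostics."""

    def __init__(self, iterations: int, delta: float, max_iter: int):
        self.iterations = iterations
        self.delta = delta
        self.max_iter = max_iter
        super().__init__(
            f"baseline weights did not stabilize after {iterations} iterations "
            f"(max_iter={max_iter}, last weight change={delta:.3g})"
        )
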