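"""Exception types shared across the package."""


class LimbSSMError(Exception):
    """Base class for package errors."""


class InputError(LimbSSMError, ValueError):
    """Invalid or inconsistent user input."""


class DegenerateGeometryError(LimbSSMError, ValueError):
    """Geometric configuration does not admit the requested construction
    (collinear points, coplanar sphere samples, parallel axes, ...)."""


class MissingLandmarkError(InputError, KeyError):
    """A named landmark required by an operation is absent."""

    def __init__(self, name: str, context: str = ""):
        self.landmark = name
        msg = f"missing landmark {name!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class FitError(LimbSSMError, RuntimeError):
    """A model fit could not be computed (e.g. singular design matrix)."""
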