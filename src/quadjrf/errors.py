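"""Exception hierarchy shared across the pipeline."""


class QuadJRFError(Exception):
    """Base class for all package errors."""


class MeshFormatError(QuadJRFError):
    """A mesh file could not be parsed in the declared format."""


class DegenerateSiteError(QuadJRFError):
    """An attachment site has zero total surface area."""


class DegenerateMuscleError(QuadJRFError):
    """A muscle's origin and insertion centroids coincide."""


class DegenerateDirectionError(QuadJRFError):
    """A load direction is undefined (target coincides with a vertex)."""


class ZeroVectorError(QuadJRFError):
    """A direction was requested for a (near-)zero vector."""


class SingularConfigurationError(QuadJRFError):
    """The three constraint points are collinear; reactions are not solvable."""


class UnstableOrientationError(QuadJRFError):
    """A reaction is too small for its orientation to be meaningful."""


class LandmarkError(QuadJRFError):
    """A landmark file is missing required names or contains bad values."""


class TreeError(QuadJRFError):
    """A phylogeny failed validation (missing branch lengths, bad labels...)."""


class ConfigError(QuadJRFError):
    """A run configuration failed validation."""


class GenerationError(QuadJRFError):
    """Synthetic-specimen construction was infeasible for the parameters."""
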