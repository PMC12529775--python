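"""Exception types shared across the package."""


class PredkinError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(PredkinError):
    """Degenerate or inconsistent molecular geometry (e.g. collinear
    atoms in a dihedral, a single-atom rotor)."""


class StationaryPointError(PredkinError):
    """A conformer's imaginary-mode count disagrees with its declared
    stationary-point type (minimum vs. transition state)."""


class EmptySelectionError(PredkinError):
    """A conformer filter removed every member of an ensemble; no rate or
    partition function can be computed from zero conformers."""


class PartitionError(PredkinError):
    """Invalid host/guest atom partition of a system."""


class ManifestError(PredkinError):
    """Malformed ensemble manifest or referenced data file."""
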