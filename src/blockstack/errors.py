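"""Exception hierarchy for the blockstack pipeline."""


class BlockstackError(Exception):
    """Base class for all blockstack-specific failures."""


class DetectionError(BlockstackError):
    """Fiducial detection found fewer markers than expected.

    Attributes
    ----------
    n_found : int
        Number of circle hypotheses that survived the score floor.
    n_expected : int
        Number of markers that were requested.
    """

    def __init__(self, message: str, n_found: int, n_expected: int):
        super().__init__(message)
        self.n_found = n_found
        self.n_expected = n_expected


class AmbiguityError(BlockstackError):
    """Two detections fell into the same image quadrant.

    Attributes
    ----------
    quadrant : str
        Corner label ('TL', 'TR', 'BL', 'BR') of the contested quadrant.
    """

    def __init__(self, message: str, quadrant: str):
        super().__init__(message)
        self.quadrant = quadrant


class DegenerateGeometryError(BlockstackError):
    """Marker geometry too degenerate (coincident/collinear points) to fit a transform."""


class AnisotropyError(BlockstackError):
    """In-plane resolution does not match the slice spacing; the volume would not be isotropic."""


class ConfigError(BlockstackError):
    """Invalid or inconsistent pipeline configuration."""
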