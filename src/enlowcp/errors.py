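"""Exception hierarchy for the counterpart-analysis toolkit."""


class EnlowError(Exception):
    """Base class for all toolkit errors."""


class DegenerateGeometryError(EnlowError):
    """A geometric construction is underdetermined or singular.

    Raised e.g. for coincident points defining a line, collinear points
    defining a plane, parallel lines being intersected, or a two-point
    plane whose defining segment is parallel to the reference normal.
    The message names the offending landmarks where known.
    """


class NonOrthogonalSetupError(EnlowError):
    """Orientation triplets define nearly parallel axial/coronal planes."""


class IncompleteLandmarkSetError(EnlowError):
    """Required landmarks are missing from a landmark set."""

    def __init__(self, missing, dimensionality=""):
        self.missing = sorted(missing)
        dim = f"{dimensionality} " if dimensionality else ""
        super().__init__(
            f"incomplete {dim}landmark set; missing: {', '.join(self.missing)}"
        )


class DegenerateTestError(EnlowError):
    """A statistical test cannot be computed (e.g. zero-variance differences)."""


class LandmarkFileError(EnlowError):
    """A landmark file failed to parse or validate."""
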