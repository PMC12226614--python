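"""Exception hierarchy for cleftrecon."""


class CleftReconError(Exception):
    """Base class for all package errors."""


class BehindCameraError(CleftReconError):
    """A 3D point has non-positive depth in the camera frame."""

    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(
            f"points behind camera (non-positive depth) at indices {self.indices[:10]}"
            + ("..." if len(self.indices) > 10 else "")
        )


class InsufficientCorrespondencesError(CleftReconError):
    """Fewer than the minimum number of 2D-3D correspondences for pose estimation."""


class ConvergenceError(CleftReconError):
    """An iterative optimization produced a non-finite cost or failed to converge."""


class TopologyError(CleftReconError):
    """Mesh does not match the expected template topology."""


class InvalidParameterError(CleftReconError):
    """A parameter is outside its valid range."""


class InsufficientDataError(CleftReconError):
    """Not enough samples to perform the requested computation."""
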