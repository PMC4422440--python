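"""Exception hierarchy shared across the package."""


class ConnparcError(Exception):
    """Base class for all connparc errors."""


class InvalidConfigError(ConnparcError, ValueError):
    """A configuration object violates its invariants."""


class GridError(ConnparcError, ValueError):
    """Incompatible voxel grids or a non-integer downsampling ratio."""


class ZeroVarianceError(ConnparcError, ValueError):
    """Seed rows with zero variance make Pearson correlation undefined.

    Carries the offending voxel indices so the caller can drop or repair them.
    """

    def __init__(self, voxel_indices):
        self.voxel_indices = list(voxel_indices)
        super().__init__(
            f"{len(self.voxel_indices)} seed voxel(s) have zero-variance "
            f"connectivity rows (indices {self.voxel_indices[:10]}...); "
            "pass zero_variance='drop' to remove them from the parcellation"
        )


class AlignmentError(ConnparcError, ValueError):
    """Objects that must share an element ordering or transform do not."""


class DomainError(ConnparcError, ValueError):
    """An operation was called outside its mathematical domain."""


class ParseError(ConnparcError, ValueError):
    """A connectivity or mask file could not be parsed."""
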