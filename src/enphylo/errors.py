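"""Exception hierarchy shared across the package."""


class EnphyloError(Exception):
    """Base class for all package errors."""


class InputError(EnphyloError, ValueError):
    """Invalid user input (empty lists, bad parameters, malformed tables)."""


class AlignmentError(EnphyloError, ValueError):
    """Raster grids do not share shape, origin or cell size."""


class ModelRejectedError(EnphyloError):
    """Every candidate model fell below the AUC acceptance threshold."""


class ExcludedSpeciesError(EnphyloError, ValueError):
    """Species cannot be modelled (e.g. occupies a single grid cell)."""
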