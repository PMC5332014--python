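"""Exception hierarchy.

Exit-code mapping used by the CLI: input/parameter problems -> 2,
integrity/capacity violations -> 3.
"""


class WpbScreenError(Exception):
    """Base class for all package errors."""


class ParameterError(WpbScreenError, ValueError):
    """An argument is outside its documented domain."""


class InputError(WpbScreenError, ValueError):
    """Missing or malformed input data (files, manifests, identifiers)."""


class CapacityError(WpbScreenError, RuntimeError):
    """More objects than a label raster of the given bit depth can encode.

    An 8-bit raster holds 2**8 = 256 grey shades, i.e. 255 object labels
    plus the reserved 0; a 16-bit raster holds at most 65535 labels with
    0 reserved for background / the Voronoi mesh.
    """


class PlacementError(WpbScreenError, RuntimeError):
    """Rejection sampling could not place an object (density too high)."""


class IntegrityError(WpbScreenError, RuntimeError):
    """A pipeline postcondition failed (e.g. an object straddles the mesh)."""


class DegenerateScaleError(WpbScreenError, ValueError):
    """A robust scale estimate (MAD or SD) is zero where a nonzero one is required."""
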