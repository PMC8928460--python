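"""Exception hierarchy shared by all structatlas modules."""


class StructAtlasError(Exception):
    """Base class for every error raised by structatlas."""


class IdCollision(StructAtlasError):
    """An identifier (node, edge, subject) is already in use."""


class GeometryMismatch(StructAtlasError):
    """A voxel representation does not share the graph's volume geometry."""


class NotFound(StructAtlasError):
    """A referenced entity (node, edge, referential, page...) does not exist."""


class LabelNotInNomenclature(StructAtlasError):
    """A label is not present in the attached nomenclature."""


class UnlabeledSource(StructAtlasError):
    """Copying a label from a node that carries no identification."""


class CutIneffective(StructAtlasError):
    """A fold cut left the voxel set in a single connected component."""


class AmbiguousCut(StructAtlasError):
    """A fold cut produced more than two connected components."""


class SeedOffStructure(StructAtlasError):
    """No cut seed point lies close enough to the fold's voxel set."""


class NoRepresentation(StructAtlasError):
    """An operation requires a voxel representation the node lacks."""


class NotComposable(StructAtlasError):
    """A transform chain contains a non-affine step and cannot collapse to one matrix."""


class Unreachable(StructAtlasError):
    """No transform path joins the two referentials."""


class OutOfField(StructAtlasError):
    """A point falls outside a deformation field's sampled support."""


class DegenerateInput(StructAtlasError):
    """Input geometry is degenerate (zero depth, collapsed curve...)."""


class ParseError(StructAtlasError):
    """A file could not be parsed; the message carries file/field context."""


class UnsupportedVersion(StructAtlasError):
    """A file declares a format version newer than this library supports."""


class MissingFile(StructAtlasError):
    """A manifest references a file that does not exist."""
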