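"""Exception hierarchy for the fontanflow pipeline."""


class FontanFlowError(Exception):
    """Base class for all fontanflow errors."""


class FormatError(FontanFlowError):
    """Input files are inconsistent (shape/spacing mismatch, bad layout)."""


class MetadataError(FontanFlowError):
    """Required acquisition metadata (e.g. VENC) is missing or invalid."""


class ContractError(FontanFlowError):
    """An operation was called with arguments violating its contract."""


class EmptySegmentationError(FontanFlowError):
    """Segmentation or ROI restriction produced an empty mask."""


class TopologyError(FontanFlowError):
    """Centerline extraction failed: degenerate or disconnected mask."""


class LabelingError(FontanFlowError):
    """Branch/segment labeling failed (wrong number of endpoints, no junction)."""


class GeometryError(FontanFlowError):
    """A geometric query (plane, cross-section) missed the vessel."""


class NormalizationError(FontanFlowError):
    """Energetics normalization is undefined (non-positive inflow/length)."""


class SpecError(FontanFlowError):
    """A synthetic-data specification is invalid (overlap, non-PSD matrix)."""
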