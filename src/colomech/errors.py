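"""Package exception hierarchy."""


class ColomechError(Exception):
    """Base class for package-specific failures."""


class OnsetNotFoundError(ColomechError):
    """No qualifying post-conditioning onset found in a load record."""


class SegmentationError(ColomechError):
    """A frame could not be segmented into specimen and background."""
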