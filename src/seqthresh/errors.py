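"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class AlignmentError(ValueError):
    """Patient identifiers cannot be matched across data sources."""
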