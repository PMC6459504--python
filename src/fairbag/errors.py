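"""Exception hierarchy for fairbag."""


class FairbagError(Exception):
    """Base class for all fairbag errors."""


class InputError(FairbagError):
    """Bad user-supplied input (missing file, malformed value)."""


class ConfigurationError(FairbagError):
    """Unsupported option, e.g. an unknown checksum algorithm."""


class NotABagError(FairbagError):
    """The given location is not a BagIt bag (no bagit.txt)."""


class BagParseError(FairbagError):
    """A bag file (fetch.txt, manifest, bag-info) could not be parsed."""


class ConflictError(FairbagError):
    """An operation would duplicate an existing entry."""


class ConsistencyError(FairbagError):
    """Research Object metadata refers to something the bag does not hold."""


class AbsentMetadataError(FairbagError):
    """An operation requires an RO manifest the bag does not have."""


class RegistryError(FairbagError):
    """Identifier registry failure (exhausted suffix retries, bad store)."""


class NotFoundError(RegistryError):
    """CURIE does not resolve to a record."""


class CurieParseError(RegistryError):
    """Text is not a well-formed prefix:suffix CURIE."""


class ImmutableRecordError(RegistryError):
    """Attempted mutation of a tombstoned identifier record."""


class ManifestFormatError(InputError):
    """Metadata table violates the expected column/row contract."""


class BedParseError(InputError):
    """A BED line could not be parsed into a valid interval record."""


class IncompleteDescriptorError(FairbagError):
    """Rubric descriptor has unset flags that cannot be derived."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"descriptor flags unset and underivable: {', '.join(self.missing)}")
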