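"""Exception hierarchy shared across the warehouse."""


class LatebindError(Exception):
    """Base class for all package errors."""


class MissingKeyError(LatebindError):
    """A record is missing a field named in its domain's key spec."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"missing key field: {field!r}")


class OutOfOrderWriteError(LatebindError):
    """A write carried a timestamp earlier than the record's latest version."""


class NotFoundError(LatebindError):
    """Referenced record id does not exist in the store."""


class RowShapeError(LatebindError):
    """A CSV data row does not match the header arity."""


class TransactionTargetError(LatebindError):
    """An update/remove transaction referenced a record never inserted."""


class StrictColumnError(LatebindError):
    """A map step referenced a column absent from the row (strict mode)."""


class AmbiguousJoinError(LatebindError):
    """More than one right-hand row matched a join key."""


class PivotCollisionError(LatebindError):
    """Two input rows share the same (key tuple, attribute) in a pivot."""

    def __init__(self, key: tuple, attribute: str):
        self.key = key
        self.attribute = attribute
        super().__init__(f"pivot collision at key={key!r}, attribute={attribute!r}")


class MapDefinitionError(LatebindError):
    """A map step's parameters are invalid for its kind."""


class FilterSyntaxError(MapDefinitionError):
    """A filter predicate failed to parse."""


class RetiredMapError(LatebindError):
    """Attempted to edit a retired map."""


class NoActiveMapError(LatebindError):
    """No output-domain definition was active at the requested map timestamp."""


class PanelError(LatebindError):
    """The reference panel is empty or malformed."""


class ParameterError(LatebindError):
    """An operation received an out-of-range parameter."""
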